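"""Processive double histone exchange watched in three colours.

Blue-excited frames report histone exchange as stepwise FRET gains
(0 -> ~0.4/0.6 -> ~0.8); red-excited frames report SWR1 binding.  The
second exchange (1/227 s^-1) competes with loss of the red signal
(1/301 s^-1), so the fraction of binding events with both exchanges is
k_ex2/(k_ex2+k_loss) = 0.57.  Loss-terminated intermediates enter the
tau2 fit as right-censored observations — dropping them would bias tau2
toward the much faster competing-risk mean.
"""

import flipkin as fk
from flipkin.pipeline import analyze_exchange_ensemble

params = fk.ExchangeParams()  # tau1 = 36 s, tau2 = 227 s, k_loss = 1/301
traces, manifest = fk.simulate_exchange_ensemble(
    params, n_traces=150, duration=1500.0, seed=3
)
report = analyze_exchange_ensemble(traces, manifest, three_colour=True, seed=3)

t1, t2 = report["tau1_fit"], report["tau2_fit"]
pr = report["processivity"]
print(f"tau1 (binding -> first exchange) = {t1.tau1:5.1f} s  (truth 36 s, n={t1.n_dwells})")
print(f"tau2 (first -> second exchange)  = {t2.tau1:5.1f} s  (truth 227 s, n={t2.n_dwells})")
print(f"double-exchange fraction = {pr['processive_fraction']:.2f} "
      f"(truth 0.57; doubles {pr['n_double']}, singles {pr['n_single']}, "
      f"distributive {pr['n_distributive']})")
inter = report["intermediate"]
print("intermediate FRET components: "
      + ", ".join(f"{m:.2f} (weight {w:.2f})" for m, w in zip(inter["means"], inter["weights"]))
      + "  (truth 0.40 / 0.60, 45:55)")
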