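"""Nucleosome flipping on SWR1: biphasic dwell kinetics from smFRET traces.

Simulates a small two-colour flipping ensemble (donor on the nucleosome,
acceptor on SWR1; apparent FRET 0.1 = dye-distal face, 0.4 = dye-proximal
face), runs the selection gate, HMM idealization and censored dwell fits,
and prints the recovered biexponential lifetimes next to the configured
truth (slow 4.5 s, fast 0.7 s, 38.4% slow entries).
"""

import flipkin as fk
from flipkin.dwells import slow_time_fraction
from flipkin.pipeline import analyze_flipping_ensemble

params = fk.FlippingParams()
traces, manifest = fk.simulate_flipping_ensemble(
    params, "canonical", n_traces=80, duration=400.0, seed=7
)
report = analyze_flipping_ensemble(traces, manifest, seed=7)

print(f"accepted {report['n_accepted']}/{report['n_traces']} molecules")
for label, frac in report["fractions"].items():
    print(f"  {label:16s} {frac['fraction']:.2f} (n={frac['n']})")
print(f"emission means: distal {report['emission_means']['distal']:.3f}, "
      f"proximal {report['emission_means']['proximal']:.3f}  (truth 0.10 / 0.40)")
for face in ("distal", "proximal"):
    f = report["face_fits"][face]["chosen"]
    print(f"{face:8s}: A1={f.A1:.2f} tau_slow={f.tau1:.2f}s tau_fast={f.tau2:.2f}s "
          f"tau_ave={f.tau_ave:.2f}s slow-time={slow_time_fraction(f):.2f} "
          f"(truth 4.5s / 0.7s, slow-time 0.80)")

# The ~equal tau_ave on both faces is the signature of symmetric flipping;
# the ~80% slow-time fraction reflects the engaged sub-state occupancy.
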