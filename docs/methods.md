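# Methods

`flipkin` models and analyses two single-molecule fluorescence
experiments on the SWR1 chromatin remodeller: (i) *flipping* — a
surface-immobilized nucleosome bound by SWR1 rotates between two
pseudo-symmetric orientations, read out as two apparent-FRET levels
(~0.1 dye-distal, ~0.4 dye-proximal); and (ii) *histone exchange* — the
two-step replacement of H2A–H2B dimers by labelled Htz1–H2B, read out
as a staircase of FRET gains while a red dye on SWR1 reports binding.
Because no raw trajectories are publicly deposited for these
experiments, the package pairs a generative model (kinetic schemes +
camera renderer) with the full analysis chain, and validation is
parameter recovery: simulate at the published rate constants, analyse
blind, and require the published numbers back.

## Kinetic model

**Flipping.** Each nucleosome face is modelled as two serially
unresolvable sub-states — an *engaged* (slow, lifetime τ_s) and a
*loose* (fast, τ_f) conformation — entered with fixed probability
p_slow on arrival ("mixture on entry"). Per-face dwell times are then
the biexponential f(t) = A₁/τ₁·e^(−t/τ₁) + A₂/τ₂·e^(−t/τ₂) with
amplitudes equal to the entry probabilities, which is exactly the form
fitted downstream. Defaults: τ_s = 4.5 s, τ_f = 0.7 s on both faces
and p_slow = 0.384, chosen so that the occupancy of the engaged
sub-state, p·τ_s/(p·τ_s+(1−p)·τ_f), is 80%. Whether the two phases
interconvert without a flip is not observable by FRET alone;
mixture-on-entry is the minimal scheme consistent with biexponential
dwells. The ensemble is a mixture of dynamic molecules (started at the
chain's stationary distribution) and statically bound molecules;
canonical defaults 68/10/22% dynamic/static-distal/static-proximal.

Substrate variants change one face: heterotypic nucleosomes carry
Htz1–H2B on the dye-distal face, reducing it to a single fast
exponential (0.63 s) — the kinetic-proofreading step — with statics
almost all proximal (59/4/37%); hexasomes have the vacant site distal
(single 4.5-s state), a very short-lived proximal excursion (0.2 s; the
source experiments report it only as "very short lived", so this value
is a modelling choice), and only 14% dynamic molecules.

**Exchange.** States pre → intermediate (one dimer exchanged) → final,
with SWR1 binding resolved: binding at k_bind (default 1/30 s⁻¹;
invented, it only positions the start of events inside the window),
first exchange at k_ex1 = 1/36 s⁻¹ splitting 55:45 toward the
dye-proximal intermediate (FRET 0.6) over the dye-distal one (0.4),
second exchange at k_ex2 = 1/227 s⁻¹ competing with loss of the red
signal (dissociation or red-dye bleaching) at k_loss = 1/301 s⁻¹.
Processivity is therefore emergent: P(double) = k_ex2/(k_ex2+k_loss) =
0.57. Unbound intermediates rebind a fresh labelled SWR1 at k_rebind =
4×10⁻⁴ s⁻¹, chosen once so that distributive completions within the
1500-s observation window make up roughly the observed ~10% of
exchange events. A single-exchange variant (heterotypic substrate,
k_ex = 1/100 s⁻¹) goes directly pre → final. The two-colour variant
(no red channel) uses the effective τ₂ = 246 s with no explicit loss.

## Synthetic traces

State paths are sampled exactly (Gillespie). The renderer produces
per-frame counts at 100 ms/frame: donor = I(1−E)+bg, acceptor = I·E +
β·donor_signal + bg, with Gaussian read noise (sd 60 counts on I = 1000;
β = 0.08, bg = 100 — invented but recorded in every manifest). Within
a frame the FRET level is the occupancy-weighted mean of the visited
states, so sub-frame dwells blur realistically. Excitation schedules:
continuous donor excitation; a ~15-s red localization block followed by
donor excitation (flipping); or 1-Hz donor/red alternation (three-colour
exchange). Each dye photobleaches once, with exposure clocks that run
only while the dye is excited; the acceptor delivered by the exchanged
dimer starts its clock at incorporation. Flipping presets use bleach
means of 300 s (donor) and 400 s (acceptor); exchange presets use
4000/5000 s (different dyes and 50% duty cycle) and fold red-dye loss
into k_loss rather than double-counting it in the optics. Simulated
ensembles deliberately omit several features of real data: shot-noise
scaling, triplet blinking, baseline drift, gamma (detection-efficiency)
imbalance, and multi-molecule aggregates other than the constructed
negative fixtures.

Per-molecule randomness is spawned from the run seed by molecule index,
so results are reproducible and insensitive to the number of traces
requested.

## Analysis chain

**Selection.** Apparent FRET is computed as E = I_A/(I_A+I_D) after
background subtraction and bleed-through correction (β and bg taken
from configuration; manifests carry the truth). The gate mirrors the
laboratory criteria: a stable direct-excitation acceptor signal (≥90%
of red-block frames above bg+4σ) and a single-step photobleach of
either dye, with the series truncated to the frames before the bleach.
Donor bleaching is detected as a change point of the summed channels
down to background; acceptor bleaching as a persistent drop of E below
0.05 with the donor rising (the total is conserved in that case, so a
total-intensity detector cannot see it). A descent to background
through two or more comparable plateaus is classified as an aggregate
and rejected.

**Idealization.** Gaussian-emission HMMs fitted by maximum-likelihood
EM (Baum–Welch; numba inner loops), five quantile-initialized restarts
per fit, emission sd floored at 0.01 and tied across states — a pooled
sd keeps the Viterbi decision boundary at the midpoint of the means so
boundary frames split evenly and dwell durations stay unbiased (with
per-state sds the noisier low-FRET state captures boundary frames and
systematically shortens the other state's dwells). Model size is chosen
by BIC over k = 1..k_max; ML-EM+BIC replaces the variational-Bayes
idealizers common in the field deliberately: it is seed-deterministic,
and the kinetic inference is carried by the dwell fits, not the
idealizer's posterior. Viterbi paths are cleaned by folding runs
shorter than 2 frames (the detection floor) into their neighbours.
States map to faces by emission mean with a 0.25 threshold, midway
between the two levels.

**Dwell fitting.** Dwells are maximal same-face runs; the first and
last dwell of every trace are censored by the observation window and
excluded, matching the gating rule (the censoring-bias demonstration
test shows the underestimate incurred if they are kept). Fits maximize
a left-truncated likelihood at t_min = 0.2 s (2 frames) with two
measurement effects built in:

* *Frame quantization* — durations are integer frame counts, so each
  observation contributes the interval probability
  S(t−Δ/2)−S(t+Δ/2). Fitting the continuous density to quantized
  dwells biases a ~7-frame lifetime low by ~18%.
* *Missed-event merging* — an opposite-face excursion shorter than the
  dead time (t_min−Δ/2 = 0.15 s) goes unseen and fuses the flanking
  dwells, so the apparent density is (1−q)f + q(f∗f) with the
  self-convolution in closed form. q is not identifiable from one
  face's dwells (the biexponential family absorbs the shape), so it is
  fixed at the probability, under the *other* face's current fit, of a
  dwell shorter than the dead time, and the two faces are iterated to a
  fixed point (two passes suffice). This is a first-order analogue of
  classical missed-event corrections in single-channel analysis.

Both corrections were adopted after parameter-recovery experiments on
synthetic truth showed the naive estimator's ±10–20% biases; with them
the recovered lifetimes sit within a few percent of truth at the study's
sample sizes. One- vs two-component fits are compared by BIC (ties to
fewer); τ_ave = (A₁τ₁²+A₂τ₂²)/(A₁τ₁+A₂τ₂) is the survival-weighted
mean lifetime, and the "slow-time fraction" A₁τ₁/(A₁τ₁+A₂τ₂) is the
occupancy reading of the amplitudes. Molecules are *dynamic* iff the
idealized path makes ≥1 face transition (no threshold is stated for the
original classification; one transition is the minimal choice).
Bootstrap (default 200 resamples) provides standard errors on request.

**Exchange analysis.** FRET steps are found by recursive binary
change-point splitting with a BIC-style stopping penalty (3 ln n times
the robust noise variance); steps are positive level changes ≥0.12
persisting ≥5 FRET frames (≈1 s wall time under 1-Hz alternation —
10 frames would make sub-2-s intermediate dwells undetectable and
measurably inflate τ₂ through mis-censoring; the flat-trace false-step
rate is <1% at either setting). Binding intervals threshold the red
channel at bg+4σ with 3-frame hysteresis. Steps pair to the interval
containing them (±1 s); unpaired steps (red dye bleached) are reported
and excluded. τ₁ pools uncensored binding→first-step times with
step-free intervals as censored attempts; τ₂ pools every
post-first-exchange bound interval as exposure — second exchange as the
event, red loss or trace end as right-censoring. Including the
loss-censored intermediates is essential, not cosmetic: uncensored
double-exchange dwells alone are Exp(k_ex2+k_loss) with mean ≈135 s,
and would read back ~40% below the true τ₂ = 227 s. The processive
fraction counts processive doubles over all molecules with ≥1 paired
step (singles + both kinds of doubles), the denominator under which it
equals k_ex2/(k_ex2+k_loss); the distributive fraction is reported on
the same denominator. Intermediate-face identity comes from a
two-Gaussian EM fit of per-event mean intermediate FRET (fits with
component means closer than 0.05 are flagged degenerate).

## Numerical and design notes

* Stationary distributions solve πQ = 0 by stacked least squares;
  reducible chains raise an error naming the absorbing component(s).
* The exponential-mixture optimizer uses Nelder–Mead from four
  quantile-based starts on (logit A₁, log τ₁, log τ₂); components are
  reordered so component 1 is slow.
* Alternating-renewal occupancy uses the ordinary mean dwell
  (A₁τ₁+A₂τ₂), not τ_ave; for the heterotypic scheme this gives a
  proximal occupancy of 0.774.
* Problem sizes in the validation suite and acceptance script follow
  the study (300–400 molecules per condition, 500-s flipping and
  1500-s exchange windows); examples use smaller ensembles.
* Known limitations: no gamma correction (apparent, not absolute,
  FRET); missed-event correction is first order (double merges are
  neglected); the exchange renderer gives each molecule a single
  acceptor bleach clock even though a second exchanged dimer would
  carry a fresh dye; heterotypic static/dynamic proportions beyond the
  published two figures are assigned, not measured.
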