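"""Analysis of histone-exchange traces.

Exchange of an unlabelled H2A–H2B dimer for an acceptor-labelled
Htz1–H2B dimer appears as a stepwise gain in apparent FRET; SWR1
binding is a plateau of direct-excitation red intensity.  This module
detects the FRET steps (piecewise-constant segmentation), detects
binding intervals (thresholding with hysteresis), pairs them into
per-molecule exchange events, fits the binding-to-first-exchange time
τ1 and the first-to-second-exchange time τ2, and computes the
processive fraction and the intermediate-FRET face statistics.

τ2 is fit with right-censoring: when the red signal vanishes after a
single exchange, the unobserved remainder of the intermediate dwell is
censored, not discarded — the second exchange competes with SWR1 loss,
and ignoring the losses would bias τ2 toward the much shorter mean of
the competing-risk mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from ._segmentation import binary_segment, estimate_noise_sd, segment_means
from .dwells import ExpFit, _wilson_ci, fit_exponential_mixture

__all__ = [
    "Step",
    "ExchangeEvent",
    "detect_steps",
    "detect_binding",
    "pair_events",
    "fit_exchange_times",
    "processive_fraction",
    "intermediate_histogram",
]


@dataclass
class Step:
    """A positive FRET level change: time (s) and flanking levels."""

    time: float
    level_before: float
    level_after: float

    @property
    def amplitude(self) -> float:
        return self.level_after - self.level_before


@dataclass
class ExchangeEvent:
    """Per-molecule pairing of FRET steps with SWR1-binding intervals."""

    molecule_id: str
    binding_intervals: list[tuple[float, float]]
    steps: list[Step]
    paired: list[int] = field(default_factory=list)  # binding-interval index per step, -1 unpaired
    classification: str = "none"  # none | single | double | double_distributive
    tau1: float | None = None
    tau1_censored: bool = False
    tau2: float | None = None
    tau2_censored: bool = False
    loss_cause: str | None = None  # red_vanished | trace_end
    intermediate_fret: float | None = None
    # exposure accounting for the censored MLEs: (duration, censored)
    tau1_attempts: list[tuple[float, bool]] = field(default_factory=list)
    tau2_exposures: list[tuple[float, bool]] = field(default_factory=list)

    @property
    def n_paired_steps(self) -> int:
        return sum(1 for p in self.paired if p >= 0)


def detect_steps(
    time_s: np.ndarray,
    E: np.ndarray,
    min_amplitude: float = 0.12,
    min_persist_frames: int = 10,
    noise_sd: float | None = None,
) -> list[Step]:
    """Stepwise FRET increases from a piecewise-constant segmentation.

    The series is segmented by recursive binary splitting with a
    BIC-style stopping rule; steps are the positive level changes of at
    least ``min_amplitude`` whose new level persists for at least
    ``min_persist_frames`` frames.
    """
    E = np.asarray(E, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    finite = np.isfinite(E)
    E, time_s = E[finite], time_s[finite]
    if len(E) < 2 * min_persist_frames:
        return []
    breaks = binary_segment(E, min_size=min(min_persist_frames, 5), noise_sd=noise_sd)
    starts, means = segment_means(E, breaks)
    lengths = np.diff(np.append(starts, len(E)))
    steps: list[Step] = []
    for i in range(1, len(means)):
        if means[i] - means[i - 1] >= min_amplitude and lengths[i] >= min_persist_frames:
            steps.append(Step(float(time_s[starts[i]]), float(means[i - 1]), float(means[i])))
    return steps


def detect_binding(
    red_time: np.ndarray,
    red: np.ndarray,
    background: float,
    noise_sd: float | None = None,
    threshold_sigma: float = 4.0,
    hysteresis_frames: int = 3,
) -> list[tuple[float, float]]:
    """On/off intervals of the red (SWR1) channel.

    Threshold at background + ``threshold_sigma``·noise with a
    ``hysteresis_frames``-frame cleanup: on- and off-runs shorter than
    the hysteresis are absorbed into their neighbours.  Intervals are
    returned in seconds on the red-frame time axis.
    """
    red = np.asarray(red, dtype=float)
    red_time = np.asarray(red_time, dtype=float)
    finite = np.isfinite(red)
    red, red_time = red[finite], red_time[finite]
    if len(red) == 0:
        return []
    if noise_sd is None:
        noise_sd = estimate_noise_sd(red)
    on = red > background + threshold_sigma * noise_sd

    # run-length cleanup, shortest runs first
    def _runs(mask):
        edges = np.concatenate([[0], np.flatnonzero(np.diff(mask.astype(int))) + 1, [len(mask)]])
        return [(a, b, bool(mask[a])) for a, b in zip(edges[:-1], edges[1:])]

    changed = True
    while changed:
        changed = False
        runs = _runs(on)
        if len(runs) <= 1:
            break
        lengths = [b - a for a, b, _ in runs]
        j = int(np.argmin(lengths))
        if lengths[j] < hysteresis_frames:
            a, b, v = runs[j]
            on[a:b] = not v
            changed = True

    intervals = []
    dt = np.median(np.diff(red_time)) if len(red_time) > 1 else 0.0
    for a, b, v in _runs(on):
        if v:
            intervals.append((float(red_time[a]), float(red_time[b - 1] + dt)))
    return intervals


def pair_events(
    molecule_id: str,
    steps: Sequence[Step],
    binding_intervals: Sequence[tuple[float, float]],
    duration: float,
    E: np.ndarray | None = None,
    time_s: np.ndarray | None = None,
    tolerance_s: float = 1.0,
    end_margin_s: float = 5.0,
) -> ExchangeEvent:
    """Assign steps to the binding interval containing them and classify.

    Steps outside every interval are flagged unpaired and excluded from
    the kinetics (these cover red-dye bleaching, where SWR1 is present
    but invisible).  Two paired steps in one interval → ``double``;
    paired steps in different intervals → ``double_distributive``.
    τ1 runs from interval start to the first paired step; τ2 from first
    to second step, right-censored at the interval end (red vanished) or
    trace end when no second step is seen.
    """
    ev = ExchangeEvent(molecule_id, [tuple(map(float, iv)) for iv in binding_intervals], list(steps))
    for s in steps:
        idx = -1
        for i, (a, b) in enumerate(binding_intervals):
            if a - tolerance_s <= s.time < b + tolerance_s:
                idx = i
                break
        ev.paired.append(idx)
    paired = [(s, i) for s, i in zip(steps, ev.paired) if i >= 0]
    if not paired:
        ev.classification = "none"
        # every step-free binding interval is a censored first-exchange attempt
        ev.tau1_attempts = [(max(b - a, 1e-9), True) for a, b in binding_intervals]
        return ev

    first, i1 = paired[0]
    ev.tau1 = max(first.time - binding_intervals[i1][0], 1e-9)
    ev.tau1_attempts = [
        (max(b - a, 1e-9), True) for a, b in binding_intervals[:i1]
    ] + [(ev.tau1, False)]

    # intermediate exposure: time visibly bound after the first exchange,
    # interval by interval, until the second exchange or the last interval
    second = paired[1] if len(paired) > 1 else None
    for j in range(i1, len(binding_intervals)):
        a, b = binding_intervals[j]
        start = max(a, first.time)
        if second is not None and second[1] == j:
            ev.tau2_exposures.append((max(second[0].time - start, 1e-9), False))
            break
        if b - start > 0:
            ev.tau2_exposures.append((b - start, True))

    if second is None:
        iv_end = binding_intervals[i1][1]
        ev.classification = "single"
        if iv_end < duration - end_margin_s:
            ev.loss_cause = "red_vanished"
            ev.tau2 = max(iv_end - first.time, 1e-9)
        else:
            ev.loss_cause = "trace_end"
            ev.tau2 = max(duration - first.time, 1e-9)
        ev.tau2_censored = True
    else:
        s2, i2 = second
        ev.tau2 = max(s2.time - first.time, 1e-9)
        ev.classification = "double" if i2 == i1 else "double_distributive"
        ev.tau2_censored = i2 != i1  # first-interval exposure was interrupted

    if E is not None and time_s is not None:
        t_stop = paired[1][0].time if len(paired) > 1 else min(
            binding_intervals[i1][1], float(np.asarray(time_s)[-1])
        )
        sel = (np.asarray(time_s) >= first.time) & (np.asarray(time_s) < t_stop)
        if sel.any():
            ev.intermediate_fret = float(np.nanmean(np.asarray(E)[sel]))
    return ev


def fit_exchange_times(
    events: Sequence[ExchangeEvent],
    t_min: float = 0.0,
    seed: int = 0,
    n_boot: int = 0,
) -> tuple[ExpFit, ExpFit]:
    """Single-exponential censored MLE for τ1 and τ2.

    τ1 uses all first paired steps (uncensored) plus step-free binding
    intervals as right-censored attempts.  τ2 uses first→second step
    dwells from processive doubles (uncensored) plus the censored
    intermediate dwells of single and distributive events.
    """
    t1, c1, t2, c2 = [], [], [], []
    for ev in events:
        for dur, cens in ev.tau1_attempts:
            t1.append(dur)
            c1.append(cens)
        for dur, cens in ev.tau2_exposures:
            t2.append(dur)
            c2.append(cens)
    fit1 = fit_exponential_mixture(np.array(t1), 1, t_min, right_censored=np.array(c1),
                                   seed=seed, n_boot=n_boot)
    try:
        fit2 = fit_exponential_mixture(np.array(t2), 1, t_min, right_censored=np.array(c2),
                                       seed=seed + 1, n_boot=n_boot)
    except ValueError:
        fit2 = None  # e.g. single-exchange substrates: no second step
    return fit1, fit2


def processive_fraction(
    events: Sequence[ExchangeEvent], exclude_unresolved: bool = True
) -> dict:
    """Double-exchange fraction among molecules with >= 1 paired step.

    The denominator includes single, processive-double and distributive-
    double molecules; the distributive fraction is reported separately
    on the same denominator, so the two numerators are disjoint.  A
    "single" whose observation window ended while SWR1 was still bound
    (``loss_cause == "trace_end"``) is unresolved — the binding event
    neither completed nor terminated — and is excluded from the
    categorical count by default (it still contributes censored exposure
    to the tau2 fit); the count is reported as ``n_unresolved``.
    """
    singles = [e for e in events if e.classification == "single"]
    if exclude_unresolved:
        n_unres = sum(1 for e in singles if e.loss_cause == "trace_end")
        n_single = len(singles) - n_unres
    else:
        n_unres = 0
        n_single = len(singles)
    n_double = sum(1 for e in events if e.classification == "double")
    n_distr = sum(1 for e in events if e.classification == "double_distributive")
    n = n_single + n_double + n_distr
    frac = n_double / n if n else np.nan
    return {
        "processive_fraction": frac,
        "ci95": _wilson_ci(n_double, n),
        "distributive_fraction": n_distr / n if n else np.nan,
        "n_single": n_single,
        "n_double": n_double,
        "n_distributive": n_distr,
        "n_unresolved": n_unres,
    }


def intermediate_histogram(
    events: Sequence[ExchangeEvent], n_gaussians: int = 2, seed: int = 0
) -> dict:
    """Two-Gaussian decomposition of per-event intermediate FRET.

    The component means identify the donor-distal (~0.4) and
    donor-proximal (~0.6) first-exchange intermediates; the weight of
    the higher-mean component estimates the proximal-face preference.
    A fit whose means are closer than 0.05 FRET is flagged degenerate.
    """
    values = np.array([e.intermediate_fret for e in events if e.intermediate_fret is not None])
    if len(values) < 5 * n_gaussians:
        raise ValueError("too few intermediate-FRET values for the mixture fit")
    gm = GaussianMixture(n_components=n_gaussians, n_init=5, random_state=int(seed) % (2**31))
    gm.fit(values.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    weights = gm.weights_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    degenerate = bool(n_gaussians > 1 and np.min(np.diff(means)) < 0.05)
    return {
        "means": means,
        "weights": weights,
        "sds": sds,
        "degenerate": degenerate,
        "n": len(values),
        "values": values,
    }
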