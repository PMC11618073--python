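"""From raw traces to selected, truncated FRET series.

The chain mirrors the lab workflow: demultiplex the excitation
schedule, subtract the camera background, correct donor→acceptor
bleed-through, compute apparent FRET E = I_A / (I_A + I_D), find the
photobleaching event, and apply the selection gate — the red-excitation
block must confirm a stably present acceptor-labelled SWR1, and the
trace must end in a clean single-step bleach of either dye.  Accepted
series are truncated to the FRETing region preceding the bleach.

The thresholds here (red-presence fraction, sigma multipliers) are
explicit operationalizations of what was done by manual inspection in
the original experiments; all are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from ._segmentation import binary_segment, estimate_noise_sd, segment_means
from .traceio import Trace, TraceFormatError

__all__ = [
    "FretSeries",
    "demultiplex",
    "correct_bleedthrough",
    "compute_fret",
    "detect_photobleach",
    "select_and_truncate",
    "qc_summary",
]


@dataclass
class FretSeries:
    """Apparent-FRET time series of one molecule plus gate outcomes."""

    molecule_id: str
    time_s: np.ndarray
    E: np.ndarray
    qc: dict[str, Any] = field(default_factory=dict)

    @property
    def accepted(self) -> bool:
        return bool(self.qc.get("accepted", False))

    def __len__(self) -> int:
        return len(self.E)


def demultiplex(trace: Trace) -> dict[str, np.ndarray]:
    """Split a trace by excitation label.

    Returns arrays for the donor-excited (green or blue) frames —
    ``fret_time``, ``donor``, ``acceptor``, ``fret_frame`` — and the
    red-excited frames — ``red_time``, ``red``.
    """
    df = trace.frames
    exc = df["excitation"].to_numpy()
    is_fret = (exc == "G") | (exc == "B")
    is_red = exc == "R"
    if not is_fret.any() and not is_red.any():
        raise TraceFormatError(f"{trace.molecule_id}: no recognizable excitation labels")
    return {
        "fret_time": df["time_s"].to_numpy(dtype=float)[is_fret],
        "fret_frame": df["frame"].to_numpy(dtype=int)[is_fret],
        "donor": df["donor"].to_numpy(dtype=float)[is_fret],
        "acceptor": df["acceptor"].to_numpy(dtype=float)[is_fret],
        "red_time": df["time_s"].to_numpy(dtype=float)[is_red],
        "red": df["red"].to_numpy(dtype=float)[is_red],
    }


def correct_bleedthrough(donor: np.ndarray, acceptor: np.ndarray, beta: float) -> np.ndarray:
    """Remove donor leakage: corrected acceptor = acceptor - beta * donor."""
    if not 0.0 <= beta < 1.0:
        raise ValueError("beta must lie in [0, 1)")
    return np.asarray(acceptor, dtype=float) - beta * np.asarray(donor, dtype=float)


def compute_fret(
    donor: np.ndarray, acceptor_corrected: np.ndarray, min_total: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Apparent FRET E = A / (A + D) with an invalid-frame mask.

    Frames whose total intensity falls at or below ``min_total`` are
    flagged invalid (E set to NaN) rather than computed.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor_corrected, dtype=float)
    if donor.shape != acceptor.shape:
        raise ValueError("donor and acceptor arrays must have the same length")
    total = donor + acceptor
    valid = total > min_total
    E = np.full_like(total, np.nan)
    np.divide(acceptor, total, out=E, where=valid)
    return E, valid


def detect_photobleach(
    donor: np.ndarray,
    acceptor: np.ndarray,
    background: float,
    noise_sd: float | None = None,
    beta: float = 0.0,
    min_frames: int = 50,
    zero_fret: float = 0.05,
    min_persist: int = 10,
) -> dict[str, Any]:
    """Locate the photobleaching event on the donor-excited frames.

    Donor bleach is a change point of the background-corrected total
    (donor + acceptor) intensity down to within 3 noise-sd of zero;
    acceptor bleach is a persistent drop of apparent FRET below
    ``zero_fret`` (the donor rises to compensate, so the total carries
    no signature).  Returns the earliest bleach frame, its kind, and a
    ``single_step`` flag that is False when the total reaches
    background through multiple comparable sub-steps (aggregates) or no
    bleach is found (frame = trace end).
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    n = len(donor)
    if n < min_frames:
        raise ValueError(f"need >= {min_frames} donor-excited frames")
    d = donor - background
    a = correct_bleedthrough(d, acceptor - background, beta)
    total = d + a
    if noise_sd is None:
        noise_sd = estimate_noise_sd(total) / np.sqrt(2.0)
    tot_noise = noise_sd * np.sqrt(2.0)

    breaks = binary_segment(total, min_size=3, noise_sd=tot_noise)
    starts, means = segment_means(total, breaks)
    at_bg = np.abs(means) <= 3.0 * tot_noise
    donor_bleach = None
    n_down_steps = 0
    for i in range(1, len(means)):
        if means[i] < means[i - 1] - 3.0 * tot_noise:
            n_down_steps += 1
        if at_bg[i] and not at_bg[i - 1]:
            donor_bleach = int(starts[i])
            # everything after must stay at background (no recovery)
            if not at_bg[i:].all():
                donor_bleach = None
                continue
            break

    # acceptor bleach: E persistently ~0 before the donor bleach
    end = donor_bleach if donor_bleach is not None else n
    acceptor_bleach = None
    if end >= 2 * min_persist:
        E, _ = compute_fret(d[:end], a[:end], min_total=0.2 * max(np.median(total[:end]), 1.0))
        Ef = np.where(np.isfinite(E), E, 0.0)
        e_noise = estimate_noise_sd(Ef)
        ebreaks = binary_segment(Ef, min_size=min_persist, noise_sd=max(e_noise, 0.01))
        estarts, emeans = segment_means(Ef, ebreaks)
        for i in range(1, len(emeans)):
            if emeans[i] < zero_fret and emeans[i - 1] >= zero_fret:
                if (emeans[i:] < zero_fret).all():  # irreversible
                    acceptor_bleach = int(estarts[i])
                break

    candidates = [(f, kind) for f, kind in
                  ((donor_bleach, "donor"), (acceptor_bleach, "acceptor")) if f is not None]
    if not candidates:
        return {"bleach_frame": n, "single_step": False, "kind": None}
    frame, kind = min(candidates)
    single = True
    if kind == "donor":
        # multiple large drops on the way to background mean more than
        # one emitter (an aggregate), not a single-molecule bleach
        upto = starts <= frame
        lv = means[upto]
        n_drops = int((lv[:-1] - lv[1:] > 4.0 * tot_noise).sum())
        if n_drops >= 2:
            single = False
    return {"bleach_frame": int(frame), "single_step": single, "kind": kind}


def select_and_truncate(
    trace: Trace,
    beta: float | None = None,
    background: float | None = None,
    noise_sd: float | None = None,
    accept_red_frac: float = 0.9,
    red_sigma: float = 4.0,
    min_accepted_frames: int = 50,
    bleach_guard_frames: int = 5,
    require_red: bool | None = None,
) -> FretSeries:
    """Apply the trace-selection gate and return the truncated FRET series.

    Acceptance requires (i) the red/direct-excitation signal above
    background + ``red_sigma``·noise for at least ``accept_red_frac`` of
    the red-excited frames (skipped when the schedule has no red
    frames), and (ii) a single-step photobleach of either dye; the
    accepted series covers only the frames preceding the bleach, minus a
    small guard (``bleach_guard_frames``) absorbing the change-point
    localization error so no post-bleach frames leak in.
    Rejected series carry the reason in ``qc["reason"]``.
    """
    meta = trace.metadata
    beta = float(meta.get("bleedthrough_beta", 0.0)) if beta is None else beta
    background = float(meta.get("background", 0.0)) if background is None else background
    noise_sd = meta.get("noise_sd", None) if noise_sd is None else noise_sd

    ch = demultiplex(trace)
    qc: dict[str, Any] = {"accepted": False, "reason": None}

    if require_red is None:
        require_red = len(ch["red"]) > 0
    if require_red:
        if len(ch["red"]) == 0:
            qc["reason"] = "no_red_frames"
            return FretSeries(trace.molecule_id, ch["fret_time"], np.array([]), qc)
        red = ch["red"]
        sd = noise_sd if noise_sd is not None else estimate_noise_sd(red)
        frac = float(np.mean(red > background + red_sigma * sd))
        qc["red_fraction_on"] = frac
        if frac < accept_red_frac:
            qc["reason"] = "unstable_acceptor"
            return FretSeries(trace.molecule_id, ch["fret_time"], np.array([]), qc)

    bl = detect_photobleach(
        ch["donor"], ch["acceptor"], background=background,
        noise_sd=noise_sd, beta=beta,
    )
    qc.update(bleach_frame=bl["bleach_frame"], bleach_kind=bl["kind"], single_step=bl["single_step"])
    if not bl["single_step"]:
        qc["reason"] = "no_single_step_bleach"
        return FretSeries(trace.molecule_id, ch["fret_time"], np.array([]), qc)
    stop = max(bl["bleach_frame"] - bleach_guard_frames, 0)
    if stop < min_accepted_frames:
        qc["reason"] = "too_short_before_bleach"
        return FretSeries(trace.molecule_id, ch["fret_time"][:stop], np.array([]), qc)

    d = ch["donor"][:stop] - background
    a = correct_bleedthrough(d, ch["acceptor"][:stop] - background, beta)
    E, valid = compute_fret(d, a, min_total=0.2 * max(float(np.median(d + a)), 1.0))
    qc["accepted"] = True
    qc["n_invalid_frames"] = int((~valid).sum())
    return FretSeries(trace.molecule_id, ch["fret_time"][:stop][valid], E[valid], qc)


def qc_summary(series_list) -> pd.DataFrame:
    """One QC row per molecule: accepted flag, reason, bleach frame."""
    rows = []
    for s in series_list:
        rows.append(
            {
                "molecule_id": s.molecule_id,
                "accepted": s.accepted,
                "reason": s.qc.get("reason"),
                "bleach_frame": s.qc.get("bleach_frame"),
                "bleach_kind": s.qc.get("bleach_kind"),
                "n_frames": len(s),
            }
        )
    return pd.DataFrame(rows)
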