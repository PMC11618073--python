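"""Kinetic schemes for SWR1–nucleosome flipping and histone exchange.

The substrates are surface-immobilized nucleosomes (or hexasomes /
heterotypic nucleosomes) bound by the SWR1 chromatin remodeller.  Two
families of continuous-time Markov chains (CTMCs) are defined here:

* **Flipping schemes** — the bound nucleosome presents either its
  dye-distal or dye-proximal face to the enzyme and flips between the
  two without dissociating.  Each face is modelled as two serially
  unresolvable sub-states (a long-lived "engaged" and a short-lived
  "loose" conformation) entered with a fixed probability on arrival, so
  the per-face dwell-time distribution is a biexponential mixture whose
  amplitudes equal the entry probabilities.
* **Exchange schemes** — the two-step replacement of H2A–H2B dimers with
  Htz1–H2B, observed as a staircase of apparent-FRET levels (0 →
  intermediate → final) while SWR1 binding is reported by a red dye.
  The second exchange competes with loss of the red signal (dissociation
  or dye bleaching), which makes processivity an emergent quantity
  k_ex2 / (k_ex2 + k_loss).

The module also provides the analytic properties used as oracles for the
downstream fitters: stationary occupancy, per-face dwell densities, the
survival-weighted mean lifetime τ_ave, and the kinetic-proofreading
selectivity ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components

__all__ = [
    "KineticScheme",
    "FaceKinetics",
    "FlippingParams",
    "ExchangeParams",
    "build_flipping_scheme",
    "build_exchange_scheme",
    "stationary_distribution",
    "face_dwell_density",
    "tau_ave",
    "selectivity",
]

Composition = Literal["canonical", "heterotypic", "hexasome"]


@dataclass
class KineticScheme:
    """A labelled CTMC: states, generator matrix, and observable classes.

    ``rate_matrix`` is the generator Q in s^-1 (off-diagonal >= 0, rows
    sum to zero).  ``fret_class`` maps each state to the label of the
    FRET level it emits; several states may share a class (aggregated
    Markov model).  ``bound_states`` marks states in which the
    red-labelled SWR1 complex is present on the nucleosome.
    """

    state_labels: list[str]
    rate_matrix: np.ndarray
    fret_class: dict[str, str]
    entry_distribution: np.ndarray
    bound_states: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        self.entry_distribution = np.asarray(self.entry_distribution, dtype=float)
        n = len(self.state_labels)
        if self.rate_matrix.shape != (n, n):
            raise ValueError("rate_matrix shape does not match state_labels")
        off = self.rate_matrix.copy()
        np.fill_diagonal(off, 0.0)
        if (off < 0).any():
            raise ValueError("off-diagonal rates must be >= 0")
        if np.abs(self.rate_matrix.sum(axis=1)).max() > 1e-12:
            raise ValueError("rate_matrix rows must sum to 0 (within 1e-12)")
        if abs(self.entry_distribution.sum() - 1.0) > 1e-9 or (self.entry_distribution < 0).any():
            raise ValueError("entry_distribution must be a probability vector")
        missing = set(self.state_labels) - set(self.fret_class)
        if missing:
            raise ValueError(f"states without a fret_class: {sorted(missing)}")

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def index(self, label: str) -> int:
        return self.state_labels.index(label)

    def class_of(self, i: int) -> str:
        return self.fret_class[self.state_labels[i]]

    def to_json(self) -> str:
        d = {
            "state_labels": self.state_labels,
            "rate_matrix": self.rate_matrix.tolist(),
            "fret_class": self.fret_class,
            "entry_distribution": self.entry_distribution.tolist(),
            "bound_states": sorted(self.bound_states),
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "KineticScheme":
        d = json.loads(s)
        return cls(
            state_labels=list(d["state_labels"]),
            rate_matrix=np.asarray(d["rate_matrix"], dtype=float),
            fret_class=dict(d["fret_class"]),
            entry_distribution=np.asarray(d["entry_distribution"], dtype=float),
            bound_states=frozenset(d.get("bound_states", [])),
        )


@dataclass
class FaceKinetics:
    """Biphasic dwell kinetics of one nucleosome face.

    ``tau_slow``/``tau_fast`` are the lifetimes (s) of the engaged and
    loose sub-states; ``p_slow_entry`` is the probability of arriving in
    the engaged sub-state.  A face with ``p_slow_entry == 1`` behaves as
    a single-exponential state of mean ``tau_slow``.
    """

    tau_slow: float = 4.5
    tau_fast: float = 0.7
    p_slow_entry: float = 0.384

    def __post_init__(self) -> None:
        if not (self.tau_slow > 0 and self.tau_fast > 0):
            raise ValueError("dwell lifetimes must be positive")
        if not 0.0 <= self.p_slow_entry <= 1.0:
            raise ValueError("p_slow_entry must lie in [0, 1]")


# Default mixture fractions: dynamic / static-distal / static-proximal.
_CANONICAL_FRACTIONS = (0.68, 0.10, 0.22)


@dataclass
class FlippingParams:
    """Ensemble parameters for the flipping experiments.

    Defaults reproduce the canonical-nucleosome conditions: biphasic
    dwells with lifetimes 4.5 s / 0.7 s on both faces, slow-entry
    probability 0.384 (which puts ~80% of the bound time in the engaged
    sub-state), apparent FRET levels 0.1 (distal) / 0.4 (proximal), and
    a 68/10/22 dynamic / static-distal / static-proximal molecule
    mixture.
    """

    distal: FaceKinetics = field(default_factory=FaceKinetics)
    proximal: FaceKinetics = field(default_factory=FaceKinetics)
    fret_distal: float = 0.1
    fret_proximal: float = 0.4
    fraction_dynamic: float = _CANONICAL_FRACTIONS[0]
    fraction_static_distal: float = _CANONICAL_FRACTIONS[1]
    fraction_static_proximal: float = _CANONICAL_FRACTIONS[2]

    def __post_init__(self) -> None:
        fr = (self.fraction_dynamic, self.fraction_static_distal, self.fraction_static_proximal)
        if any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("mixture fractions must be >= 0 and sum to 1")
        for level in (self.fret_distal, self.fret_proximal):
            if not 0.0 <= level <= 1.0:
                raise ValueError("FRET levels must lie in [0, 1]")

    def face(self, name: str) -> FaceKinetics:
        if name not in ("distal", "proximal"):
            raise ValueError(f"unknown face {name!r}")
        return getattr(self, name)


def heterotypic_flipping_params() -> FlippingParams:
    """Heterotypic nucleosome: Htz1–H2B on the dye-distal face.

    The Htz1-containing face shows a single fast exponential decay
    (0.63 s); the H2A face keeps canonical kinetics.  Static molecules
    are almost exclusively proximal (37% static-proximal, 59% dynamic).
    """
    return FlippingParams(
        distal=FaceKinetics(tau_slow=0.63, tau_fast=0.63, p_slow_entry=1.0),
        proximal=FaceKinetics(),
        fraction_dynamic=0.59,
        fraction_static_distal=0.04,
        fraction_static_proximal=0.37,
    )


def hexasome_flipping_params() -> FlippingParams:
    """Hexasome: the dye-distal face is the vacant dimer site.

    Nearly all molecules sit statically in the distal orientation; only
    14% flip, and excursions to the proximal face are very short-lived
    (0.2 s default — the source experiment reports them only as "very
    short lived", so the value is a modelling choice).
    """
    return FlippingParams(
        distal=FaceKinetics(tau_slow=4.5, tau_fast=4.5, p_slow_entry=1.0),
        proximal=FaceKinetics(tau_slow=0.2, tau_fast=0.2, p_slow_entry=0.5),
        fraction_dynamic=0.14,
        fraction_static_distal=0.84,
        fraction_static_proximal=0.02,
    )


@dataclass
class ExchangeParams:
    """Parameters of the two-step histone-exchange scheme.

    ``1/k_ex1`` is the SWR1-binding-to-first-exchange time (36 s),
    ``1/k_ex2`` the first-to-second exchange time (227 s), and
    ``k_loss`` the rate at which the red SWR1 signal is lost
    (dissociation or dye bleaching) while in the single-exchanged
    intermediate; 1/301 s^-1 makes the processive fraction
    k_ex2/(k_ex2+k_loss) = 0.57.  ``k_bind`` is the initial SWR1 on-rate
    (enzyme in solution finds the immobilized nucleosome within tens of
    seconds); ``k_rebind`` is the much slower rate at which a fresh
    labelled SWR1 binds an already single-exchanged, unbound
    intermediate (the distributive pathway).
    ``p_first_proximal`` sets the 55:45 preference for the
    first exchange occurring at the dye-proximal face (intermediate
    FRET ~0.6) over the dye-distal face (~0.4).
    """

    k_ex1: float = 1.0 / 36.0
    k_ex2: float = 1.0 / 227.0
    k_loss: float = 1.0 / 301.0
    k_bind: float = 1.0 / 30.0
    k_rebind: float = 4.0e-4
    p_first_proximal: float = 0.55
    fret_levels: dict[str, float] = field(
        default_factory=lambda: {
            "pre": 0.0,
            "intermediate_distal": 0.4,
            "intermediate_proximal": 0.6,
            "final": 0.8,
        }
    )
    double_exchange: bool = True

    def __post_init__(self) -> None:
        for r in (self.k_ex1, self.k_ex2, self.k_loss, self.k_bind, self.k_rebind):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.k_ex1 == 0 and self.k_ex2 == 0 and self.k_loss == 0 and self.k_rebind == 0:
            raise ValueError("all rates are zero")
        if not 0.0 <= self.p_first_proximal <= 1.0:
            raise ValueError("p_first_proximal must lie in [0, 1]")
        lv = self.fret_levels
        inter = [lv["intermediate_distal"], lv["intermediate_proximal"]]
        if not (lv["pre"] < min(inter) and max(inter) <= lv["final"]):
            raise ValueError("fret_levels must be monotone: pre < intermediates <= final")

    @property
    def tau1(self) -> float:
        return 1.0 / self.k_ex1

    @property
    def tau2(self) -> float:
        return 1.0 / self.k_ex2

    @property
    def processive_fraction(self) -> float:
        """P(second exchange beats red-signal loss) = k_ex2/(k_ex2+k_loss)."""
        return self.k_ex2 / (self.k_ex2 + self.k_loss)


def two_colour_exchange_params() -> ExchangeParams:
    """Two-colour exchange assay: no red SWR1 channel, τ2 = 246 s.

    Without the red channel SWR1 loss is unobservable, so the effective
    second-exchange time absorbs any interruptions; the slightly longer
    246 s (vs 227 s with explicit loss accounting) reflects that.
    """
    return ExchangeParams(k_ex2=1.0 / 246.0, k_loss=0.0, k_rebind=0.0)


def heterotypic_exchange_params() -> ExchangeParams:
    """Heterotypic substrate: a single exchangeable H2A–H2B dimer, ~100 s."""
    return ExchangeParams(k_ex1=1.0 / 100.0, double_exchange=False)


# ---------------------------------------------------------------------------
# scheme builders
# ---------------------------------------------------------------------------


def _face_states(face: str, kin: FaceKinetics, single: bool) -> list[tuple[str, float, float]]:
    """(label, exit rate, entry probability) for the sub-states of a face."""
    if single:
        return [(face, 1.0 / kin.tau_slow, 1.0)]
    return [
        (f"{face}_slow", 1.0 / kin.tau_slow, kin.p_slow_entry),
        (f"{face}_fast", 1.0 / kin.tau_fast, 1.0 - kin.p_slow_entry),
    ]


def build_flipping_scheme(params: FlippingParams, composition: Composition = "canonical") -> KineticScheme:
    """Build the flipping CTMC for a given substrate composition.

    Canonical nucleosomes give the 4-state chain (distal_slow,
    distal_fast, proximal_slow, proximal_fast); heterotypic and hexasome
    substrates carry a single sub-state on the non-canonical face
    (Htz1-containing or vacant, both dye-distal) giving 3 states.  Every
    exit from one face enters the other face's sub-states with
    probabilities (p_slow_entry, 1 - p_slow_entry); the exit rate of a
    sub-state is the reciprocal of its lifetime.
    """
    if composition == "canonical":
        single_distal = False
    elif composition in ("heterotypic", "hexasome"):
        single_distal = True
    else:
        raise ValueError(f"unknown composition {composition!r}")

    distal = _face_states("distal", params.distal, single_distal)
    proximal = _face_states("proximal", params.proximal, False)
    states = distal + proximal
    labels = [s[0] for s in states]
    n = len(states)
    faces = ["distal"] * len(distal) + ["proximal"] * len(proximal)

    Q = np.zeros((n, n))
    for i, (_, rate, _) in enumerate(states):
        targets = [j for j in range(n) if faces[j] != faces[i]]
        for j in targets:
            Q[i, j] = rate * states[j][2]
        Q[i, i] = -Q[i].sum()

    fret_class = {lab: face for lab, face in zip(labels, faces)}
    # Start molecules at the stationary distribution of the bound chain:
    # SWR1 is already engaged when imaging begins.
    scheme = KineticScheme(
        state_labels=labels,
        rate_matrix=Q,
        fret_class=fret_class,
        entry_distribution=np.full(n, 1.0 / n),
        bound_states=frozenset(labels),
    )
    scheme.entry_distribution = stationary_distribution(scheme)
    return scheme


def build_exchange_scheme(params: ExchangeParams) -> KineticScheme:
    """Build the histone-exchange CTMC.

    States: unbound_pre, bound_pre, then for each face an unbound and a
    bound single-exchanged intermediate, and an absorbing final
    (double-exchanged) state.  The first exchange from bound_pre splits
    p_first_proximal : (1 - p_first_proximal) between the faces; from a
    bound intermediate the second exchange (k_ex2) competes with red-
    signal loss (k_loss); unbound intermediates rebind at k_rebind.
    With ``double_exchange=False`` (heterotypic substrate, one
    exchangeable dimer) the first exchange leads directly to final.
    """
    if not params.double_exchange:
        labels = ["unbound_pre", "bound_pre", "final"]
        Q = np.zeros((3, 3))
        Q[0, 1] = params.k_bind
        Q[1, 2] = params.k_ex1
        Q[np.diag_indices(3)] = -Q.sum(axis=1)
        fret_class = {
            "unbound_pre": "pre",
            "bound_pre": "pre",
            "final": "final",
        }
        entry = np.array([1.0, 0.0, 0.0]) if params.k_bind > 0 else np.array([0.0, 1.0, 0.0])
        return KineticScheme(labels, Q, fret_class, entry,
                             bound_states=frozenset({"bound_pre", "final"}))

    labels = [
        "unbound_pre",
        "bound_pre",
        "unbound_intermediate_d",
        "unbound_intermediate_p",
        "bound_intermediate_d",
        "bound_intermediate_p",
        "final",
    ]
    ix = {lab: i for i, lab in enumerate(labels)}
    Q = np.zeros((7, 7))
    Q[ix["unbound_pre"], ix["bound_pre"]] = params.k_bind
    Q[ix["bound_pre"], ix["bound_intermediate_p"]] = params.k_ex1 * params.p_first_proximal
    Q[ix["bound_pre"], ix["bound_intermediate_d"]] = params.k_ex1 * (1.0 - params.p_first_proximal)
    for f in "dp":
        Q[ix[f"bound_intermediate_{f}"], ix["final"]] = params.k_ex2
        Q[ix[f"bound_intermediate_{f}"], ix[f"unbound_intermediate_{f}"]] = params.k_loss
        Q[ix[f"unbound_intermediate_{f}"], ix[f"bound_intermediate_{f}"]] = params.k_rebind
    Q[np.diag_indices(7)] = 0.0
    Q[np.diag_indices(7)] = -Q.sum(axis=1)

    fret_class = {
        "unbound_pre": "pre",
        "bound_pre": "pre",
        "unbound_intermediate_d": "intermediate_distal",
        "unbound_intermediate_p": "intermediate_proximal",
        "bound_intermediate_d": "intermediate_distal",
        "bound_intermediate_p": "intermediate_proximal",
        "final": "final",
    }
    entry = np.zeros(7)
    if params.k_bind > 0:
        entry[ix["unbound_pre"]] = 1.0
    else:
        entry[ix["bound_pre"]] = 1.0
    bound = frozenset({"bound_pre", "bound_intermediate_d", "bound_intermediate_p", "final"})
    return KineticScheme(labels, Q, fret_class, entry, bound_states=bound)


# ---------------------------------------------------------------------------
# analytic properties
# ---------------------------------------------------------------------------


def stationary_distribution(scheme: KineticScheme) -> np.ndarray:
    """Solve πQ = 0, Σπ = 1 for an irreducible scheme.

    Raises ``ValueError`` with an absorbing-component report when the
    chain is reducible (e.g. an exchange scheme with its absorbing final
    state).
    """
    Q = scheme.rate_matrix
    n = scheme.n_states
    adjacency = (Q > 0).astype(int)
    np.fill_diagonal(adjacency, 1)
    n_comp, comp = connected_components(adjacency, directed=True, connection="strong")
    if n_comp > 1:
        # States whose component has no outgoing edge form absorbing sets.
        absorbing = []
        for c in range(n_comp):
            members = np.flatnonzero(comp == c)
            outside = np.setdiff1d(np.arange(n), members)
            if not adjacency[np.ix_(members, outside)].any():
                absorbing.append([scheme.state_labels[i] for i in members])
        raise ValueError(f"chain is reducible; absorbing component(s): {absorbing}")
    # Append the normalization row and solve the stacked least-squares system.
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = scipy.linalg.lstsq(A, b)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def face_occupancy(scheme: KineticScheme) -> dict[str, float]:
    """Stationary probability mass per FRET class."""
    pi = stationary_distribution(scheme)
    occ: dict[str, float] = {}
    for i, p in enumerate(pi):
        occ[scheme.class_of(i)] = occ.get(scheme.class_of(i), 0.0) + p
    return occ


def face_dwell_density(params: FlippingParams, face: str, t) -> np.ndarray:
    """Biexponential dwell-time density of one face.

    f(t) = A1/τ1 e^(−t/τ1) + A2/τ2 e^(−t/τ2) with amplitudes equal to the
    sub-state entry probabilities; integrates to 1 on [0, ∞).
    """
    kin = params.face(face)
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("t must be >= 0")
    a1, a2 = kin.p_slow_entry, 1.0 - kin.p_slow_entry
    return a1 / kin.tau_slow * np.exp(-t / kin.tau_slow) + a2 / kin.tau_fast * np.exp(-t / kin.tau_fast)


def tau_ave(A1: float, tau1: float, A2: float, tau2: float) -> float:
    """Survival-weighted mean lifetime (A1τ1² + A2τ2²)/(A1τ1 + A2τ2).

    Scale-invariant in the amplitudes.  This equals ∫t·w(t)dt / ∫w(t)dt
    for the un-normalized survival mixture w(t) = A1 e^(−t/τ1) + A2
    e^(−t/τ2): the mean of the dwell population weighted by time spent.
    """
    if A1 < 0 or A2 < 0 or (A1 == 0 and A2 == 0):
        raise ValueError("amplitudes must be >= 0 and not both zero")
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("lifetimes must be positive")
    return (A1 * tau1**2 + A2 * tau2**2) / (A1 * tau1 + A2 * tau2)


def selectivity(fit_proximal, fit_distal) -> float:
    """Kinetic-proofreading selectivity: τ_ave(proximal) / τ_ave(distal).

    Arguments may be ``ExpFit`` objects (anything with a ``tau_ave``
    attribute) or plain numbers.
    """
    tp = getattr(fit_proximal, "tau_ave", fit_proximal)
    td = getattr(fit_distal, "tau_ave", fit_distal)
    if td <= 0 or tp <= 0:
        raise ValueError("tau_ave values must be positive")
    return tp / td


def params_to_json(params) -> str:
    """Serialize a parameter dataclass to JSON (rates s^-1, times s)."""
    return json.dumps(asdict(params), indent=1)
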