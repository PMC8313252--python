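"""Linear master-equation kinetics of phytate dephosphorylation.

Each enzyme is a position-preference model: removing phosphate p from
species S proceeds at rate ``k * w(p)``, first order in S (substrate well
below Km, no processivity — the preference depends on the position only,
not on the current species).  A community mixes several enzymes, optionally
with first-order sorption of InsP6 to an inert soil pool, first-order
scavenging of released Pi, and a logistic activation lag shared by all
enzymes.  The resulting system is linear, so trajectories are propagated
exactly with matrix exponentials (a fixed-step RK4 integrator is available
as a cross-check).

Alongside the time courses, a dynamic program over the dephosphorylation
DAG computes pathway flux: the probability that a degrading molecule passes
through each intermediate, which is what the isomer pattern on the
chromatogram reflects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .algebra import POSITIONS, Species, all_species, classify_species
from .profiles import FREE_INOSITOL, PI_POOL, ClassProfile

__all__ = [
    "EnzymeModel",
    "CommunityModel",
    "TimeCourse",
    "SPECIES_ORDER",
    "species_label",
    "build_rate_matrix",
    "simulate_timecourse",
    "pathway_flux",
    "class_flux",
    "class_profile",
    "initial_state",
]

#: Fixed species ordering for all matrices and time courses:
#: descending phosphorylation level, then lexicographic locants.
SPECIES_ORDER: list[Species] = all_species()
_INDEX: dict[Species, int] = {s: i for i, s in enumerate(SPECIES_ORDER)}
_INSP6 = frozenset(POSITIONS)
N_SPECIES = 64

#: Phytase class labels (EC-number families by initial position of attack).
CLASS_LABELS = ("BPP_3PHYTASE", "HAP_6PHYTASE", "FIVE_PHYTASE", "MINPP", "GENERIC")


def species_label(s: Species) -> str:
    """Unique per-species column label, e.g. ``Ins(1,2,4)P3``."""
    if not s:
        return FREE_INOSITOL
    locs = ",".join(str(p) for p in sorted(s))
    return f"Ins({locs})P{len(s)}"


@dataclass(frozen=True)
class EnzymeModel:
    """A named position-preference weight vector with an overall rate.

    ``weights[i]`` is the (non-negative, unnormalized) preference for
    attacking ring position ``i+1``; only ratios matter for flux shares.
    ``k`` is the overall first-order rate constant in 1/day.
    """

    name: str
    class_label: str
    weights: tuple[float, float, float, float, float, float]
    k: float

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if len(self.weights) != 6:
            raise ValueError("need exactly six position weights")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if self.k < 0:
            raise ValueError("rate constant must be non-negative")

    def w(self, position: int) -> float:
        return self.weights[position - 1]


@dataclass
class CommunityModel:
    """A mixture of enzymes with optional sorption, Pi uptake and lag.

    Rates are per day.  ``t_lag == 0`` means no lag (activation identically
    one); otherwise activation follows a logistic centred at ``t_lag`` with
    steepness ``tau`` and scales every enzyme rate (sorption and Pi uptake
    are abiotic/constitutive and are not lagged).
    """

    enzymes: list[tuple[EnzymeModel, float]] = field(default_factory=list)
    sorption_rate: float = 0.0
    pi_uptake_rate: float = 0.0
    t_lag: float = 0.0
    tau: float = 0.25

    def __post_init__(self) -> None:
        if self.sorption_rate < 0 or self.pi_uptake_rate < 0:
            raise ValueError("rates must be non-negative")
        if any(m < 0 for _, m in self.enzymes):
            raise ValueError("mixing weights must be non-negative")
        if self.enzymes and not any(m > 0 for _, m in self.enzymes):
            raise ValueError("at least one mixing weight must be positive")

    def activation(self, t: float) -> float:
        if self.t_lag == 0:
            return 1.0
        return 1.0 / (1.0 + math.exp(-(t - self.t_lag) / self.tau))


def _enzyme_generator(c: CommunityModel) -> np.ndarray:
    """Species-block generator of the enzymatic removals (columns = source)."""
    e = np.zeros((N_SPECIES, N_SPECIES))
    for enz, mix in c.enzymes:
        if mix == 0 or enz.k == 0:
            continue
        for s in SPECIES_ORDER:
            i = _INDEX[s]
            for p in s:
                r = mix * enz.k * enz.w(p)
                if r == 0:
                    continue
                e[_INDEX[s - {p}], i] += r
                e[i, i] -= r
    return e


def build_rate_matrix(c: CommunityModel, t: float = 0.0) -> np.ndarray:
    """The 64x64 master-equation rate matrix at time *t*.

    Entry (S - {p}, S) carries the activated removal rate; the InsP6
    diagonal additionally loses material to sorption.
    """
    q = c.activation(t) * _enzyme_generator(c)
    if c.sorption_rate > 0:
        i6 = _INDEX[_INSP6]
        q[i6, i6] -= c.sorption_rate
    return q


# Augmented state layout: [64 species, sorbed pool, Pi pool, cumulative uptake]
_I_SORB, _I_PI, _I_CUM = N_SPECIES, N_SPECIES + 1, N_SPECIES + 2
_N_AUG = N_SPECIES + 3


def _augmented_parts(c: CommunityModel) -> tuple[np.ndarray, np.ndarray]:
    """Decompose the augmented generator as A(t) = activation(t)*E + C."""
    e = np.zeros((_N_AUG, _N_AUG))
    e[:N_SPECIES, :N_SPECIES] = _enzyme_generator(c)
    # every removal event releases one phosphate into the Pi pool
    for enz, mix in c.enzymes:
        if mix == 0 or enz.k == 0:
            continue
        for s in SPECIES_ORDER:
            out = mix * enz.k * sum(enz.w(p) for p in s)
            e[_I_PI, _INDEX[s]] += out
    cst = np.zeros((_N_AUG, _N_AUG))
    if c.sorption_rate > 0:
        i6 = _INDEX[_INSP6]
        cst[i6, i6] -= c.sorption_rate
        cst[_I_SORB, i6] += c.sorption_rate
    if c.pi_uptake_rate > 0:
        cst[_I_PI, _I_PI] -= c.pi_uptake_rate
        cst[_I_CUM, _I_PI] += c.pi_uptake_rate
    return e, cst


@dataclass
class TimeCourse:
    """Species abundances plus phosphate bookkeeping over a time grid."""

    times: np.ndarray
    abundance: np.ndarray  # shape (T, 64), SPECIES_ORDER columns
    pi_pool: np.ndarray
    sorbed_pool: np.ndarray
    cumulative_uptake: np.ndarray

    def at(self, t: float) -> np.ndarray:
        """Species abundances at *t* (linear interpolation off-grid)."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(f"time {t} outside simulated range")
        return np.array(
            [np.interp(t, self.times, self.abundance[:, j]) for j in range(N_SPECIES)]
        )

    def pi_at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.pi_pool))

    def total_inositol(self) -> np.ndarray:
        return self.abundance.sum(axis=1) + self.sorbed_pool

    def total_phosphate(self) -> np.ndarray:
        levels = np.array([len(s) for s in SPECIES_ORDER], dtype=float)
        return (
            self.abundance @ levels
            + 6.0 * self.sorbed_pool
            + self.pi_pool
            + self.cumulative_uptake
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.abundance, columns=[species_label(s) for s in SPECIES_ORDER]
        )
        df.insert(0, "time_days", self.times)
        df["Pi"] = self.pi_pool
        df["sorbed"] = self.sorbed_pool
        df["Pi_taken_up"] = self.cumulative_uptake
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def initial_state(x0: "ClassProfile | Mapping[str, float] | Sequence[float]") -> tuple[np.ndarray, float]:
    """Build the species vector (and initial Pi) from an input description.

    Accepts a raw length-64 vector in :data:`SPECIES_ORDER`, or a class/
    species-name mapping (a :class:`ClassProfile` works).  Amounts given for
    an enantiomeric pair or a lumped class are split uniformly over the
    member species (racemic, as acid-reflux or commercial material is).
    """
    if not isinstance(x0, (ClassProfile, Mapping)):
        arr = np.asarray(x0, dtype=float)
        if arr.shape != (N_SPECIES,):
            raise ValueError(f"species vector must have length {N_SPECIES}")
        if np.any(arr < 0):
            raise ValueError("abundances must be non-negative")
        return arr.copy(), 0.0

    items = x0.items()
    by_label = {species_label(s): s for s in SPECIES_ORDER}
    by_class: dict[str, tuple[Species, ...]] = {}
    for s in SPECIES_ORDER:
        for lump in (False, True):
            c = classify_species(s, lumping=lump)
            by_class.setdefault(c.canonical_name, c.members)
    vec = np.zeros(N_SPECIES)
    pi0 = 0.0
    for name, amount in items:
        if amount < 0:
            raise ValueError(f"negative amount for {name!r}")
        if name == PI_POOL:
            pi0 += amount
        elif name == FREE_INOSITOL:
            vec[_INDEX[frozenset()]] += amount
        elif name in by_label:
            vec[_INDEX[by_label[name]]] += amount
        elif name in by_class:
            members = by_class[name]
            for m in members:
                vec[_INDEX[m]] += amount / len(members)
        else:
            raise KeyError(f"unknown species or class name {name!r}")
    return vec, pi0


def simulate_timecourse(
    c: CommunityModel,
    x0,
    times: Iterable[float],
    method: str = "expm",
    max_step: float = 0.01,
    rk4_step: float = 0.001,
    pi0: float | None = None,
) -> TimeCourse:
    """Propagate the community master equation over a time grid (days).

    ``method="expm"`` uses matrix exponentials: exact for lag-free
    communities, midpoint-activated substeps of ``max_step`` days under a
    lag.  ``method="rk4"`` is classical fixed-step Runge-Kutta with step
    ``rk4_step``.
    """
    t = np.asarray(list(times), dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("times must be a non-empty 1-D grid")
    if t[0] != 0:
        raise ValueError("time grid must start at 0")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")

    vec, pi_from_profile = initial_state(x0)
    y = np.zeros(_N_AUG)
    y[:N_SPECIES] = vec
    y[_I_PI] = pi_from_profile if pi0 is None else pi0

    e, cst = _augmented_parts(c)
    out = np.zeros((len(t), _N_AUG))
    out[0] = y

    lag_free = c.t_lag == 0

    if method == "expm":
        cache: dict[float, np.ndarray] = {}
        for i in range(1, len(t)):
            t0, t1 = t[i - 1], t[i]
            if lag_free:
                dt = t1 - t0
                if dt not in cache:
                    cache[dt] = expm((e + cst) * dt)
                y = cache[dt] @ y
            else:
                s = t0
                while s < t1 - 1e-12:
                    h = min(max_step, t1 - s)
                    act = c.activation(s + h / 2)
                    y = expm((act * e + cst) * h) @ y
                    s += h
            out[i] = y
    elif method == "rk4":
        def deriv(tt: float, yy: np.ndarray) -> np.ndarray:
            return (c.activation(tt) * e + cst) @ yy

        for i in range(1, len(t)):
            s, t1 = t[i - 1], t[i]
            while s < t1 - 1e-12:
                h = min(rk4_step, t1 - s)
                k1 = deriv(s, y)
                k2 = deriv(s + h / 2, y + h / 2 * k1)
                k3 = deriv(s + h / 2, y + h / 2 * k2)
                k4 = deriv(s + h, y + h * k3)
                y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                s += h
            out[i] = y
    else:
        raise ValueError(f"unknown method {method!r}")

    out = np.where(np.abs(out) < 1e-15, 0.0, out)
    if np.any(out < -1e-9):
        raise RuntimeError("solver produced negative abundances beyond tolerance")
    out = np.clip(out, 0.0, None)
    return TimeCourse(
        times=t,
        abundance=out[:, :N_SPECIES],
        pi_pool=out[:, _I_PI],
        sorbed_pool=out[:, _I_SORB],
        cumulative_uptake=out[:, _I_CUM],
    )


def pathway_flux(e: EnzymeModel) -> dict[Species, float]:
    """Probability that a degrading InsP6 molecule visits each species.

    Dynamic programming down the DAG: flux(InsP6) = 1 and splits at each
    species proportionally to the positive position weights it still
    carries; species with no attackable position are terminal sinks.
    """
    if not any(w > 0 for w in e.weights):
        raise ValueError("pathway flux needs at least one positive weight")
    flux: dict[Species, float] = {s: 0.0 for s in SPECIES_ORDER}
    flux[_INSP6] = 1.0
    for s in SPECIES_ORDER:  # descending level: topological for removals
        f = flux[s]
        if f == 0 or not s:
            continue
        wsum = sum(e.w(p) for p in s)
        if wsum == 0:
            continue  # terminal product
        for p in s:
            if e.w(p) > 0:
                flux[s - {p}] += f * e.w(p) / wsum
    return flux


def _aggregate(values: Mapping[Species, float], lumping: bool) -> dict[str, float]:
    agg: dict[str, float] = {}
    for s, v in values.items():
        if not s:
            continue  # free inositol: detector-invisible
        name = PI_POOL if len(s) == 1 else classify_species(s, lumping=lumping).canonical_name
        agg[name] = agg.get(name, 0.0) + v
    return agg


def class_flux(e: EnzymeModel, lumping: bool = True) -> ClassProfile:
    """Pathway flux aggregated to chromatographic classes.

    Per-level fluxes each sum to one (absent terminal products), so this is
    not a mole-fraction profile; it answers "which isomer classes does this
    enzyme route material through".
    """
    return ClassProfile(amounts=_aggregate(pathway_flux(e), lumping))


def class_profile(
    tc: TimeCourse,
    t: float,
    lumping: bool = True,
    normalize: bool = False,
    include_pi: bool = True,
) -> ClassProfile:
    """Chromatographic class profile of a time course at time *t*.

    Species abundances are summed within each class; all InsP1 species pool
    with inorganic phosphate (they co-elute at the solvent front); free
    inositol is excluded (no phosphate, no detector response).
    """
    x = tc.at(t)
    amounts = _aggregate(dict(zip(SPECIES_ORDER, x)), lumping)
    if include_pi:
        amounts[PI_POOL] = amounts.get(PI_POOL, 0.0) + tc.pi_at(t)
    elif PI_POOL in amounts:
        pass  # InsP1 species still pool at the solvent front
    prof = ClassProfile(amounts=amounts)
    if normalize:
        return prof.normalize(include_pi=False)
    return prof
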