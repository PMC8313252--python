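"""Forward and inverse chromatography: synthesize detector traces from
class profiles and recover profiles from traces.

The forward model renders each class as a Gaussian of fixed retention time
and width on a uniform time grid, plus a flat baseline and optional seeded
white noise.  The inverse path is standard peak work: smooth, find local
maxima above a signal-to-noise and prominence floor, refine apices by
parabolic interpolation, integrate trapezoidally over valley-bounded +/-3
sigma windows, assign each peak to the nearest retention-table entry within
tolerance, and convert areas to mole amounts through a response model.

Retention anchors from the gradient this emulates: inorganic phosphate
co-elutes with InsP1 at the solvent front (~2.8 min), InsP5 [1/3-OH] at
~28 min, InsP6 at ~37 min.  Other defaults are plausible interpolations,
monotone with phosphate number, and freely overridable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .profiles import FREE_INOSITOL, PI_POOL, ClassProfile

__all__ = [
    "RetentionTable",
    "Chromatogram",
    "Peak",
    "PeakSet",
    "default_retention_table",
    "synthesize",
    "detect_peaks",
    "integrate_and_assign",
    "quantify",
    "read_chromatogram",
    "write_chromatogram",
    "read_retention_table",
    "write_retention_table",
]


@dataclass(frozen=True)
class RetentionTable:
    """Retention time and peak width (minutes) per chromatographic class."""

    entries: dict[str, tuple[float, float]]  # class -> (rt_min, sigma_min)
    tolerance: float = 0.4  # assignment window, min

    def __post_init__(self) -> None:
        rts = sorted(rt for rt, _ in self.entries.values())
        if any(rt <= 0 for rt in rts):
            raise ValueError("retention times must be positive")
        if len(set(rts)) != len(rts):
            raise ValueError("retention times must be unique per class")
        gaps = np.diff(rts)
        if len(gaps) and self.tolerance >= gaps.min() / 2:
            raise ValueError(
                f"assignment tolerance {self.tolerance} must be below half the "
                f"minimum inter-class gap ({gaps.min():.3g} min)"
            )

    def rt(self, name: str) -> float:
        return self.entries[name][0]

    def sigma(self, name: str) -> float:
        return self.entries[name][1]

    def nearest(self, t: float) -> tuple[str | None, float]:
        name = min(self.entries, key=lambda c: abs(self.entries[c][0] - t))
        return name, abs(self.entries[name][0] - t)

    def with_tolerance(self, tolerance: float) -> "RetentionTable":
        return replace(self, tolerance=tolerance)


_DEFAULT_SIGMA = 0.25

#: Fig-2C-style ladder ordering of the InsP4 classes (standards first, then
#: the two orbits absent from the acid-reflux ladder in configurable slots).
_DEFAULT_RT: dict[str, float] = {
    PI_POOL: 2.8,          # anchored: solvent front
    "InsP2": 8.0,
    "InsP3": 14.0,
    "d/l-Ins(1,4,5,6)P4": 18.0,
    "Ins(2,4,5,6)P4": 19.0,
    "d/l-Ins(1,2,5,6)P4": 20.0,
    "d/l-Ins(1,3,4,5)P4": 21.0,
    "d/l-Ins(1,2,4,5)P4": 22.0,
    "d/l-Ins(1,2,3,4)P4": 23.0,
    "d/l-Ins(1,2,4,6)P4": 24.0,
    "Ins(1,2,3,5)P4": 25.0,   # not in the standards ladder; default slot
    "Ins(1,3,4,6)P4": 26.0,   # not in the standards ladder; default slot
    "InsP5 [2-OH]": 27.0,
    "InsP5 [1/3-OH]": 28.0,   # anchored
    "InsP5 [4/6-OH]": 29.5,
    "InsP5 [5-OH]": 31.0,
    "InsP6": 37.0,            # anchored
}


def default_retention_table(tolerance: float = 0.4) -> RetentionTable:
    """The packaged retention table (lumped levels <= 3, all 9 InsP4 orbits)."""
    return RetentionTable(
        entries={c: (rt, _DEFAULT_SIGMA) for c, rt in _DEFAULT_RT.items()},
        tolerance=tolerance,
    )


@dataclass
class Chromatogram:
    """A sampled detector trace on a uniform minute grid."""

    times: np.ndarray
    signal: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape or self.times.ndim != 1:
            raise ValueError("times and signal must be matching 1-D arrays")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")
        _check_uniform(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def _check_uniform(times: np.ndarray) -> None:
    if len(times) < 2:
        raise ValueError("trace needs at least two samples")
    d = np.diff(times)
    ref = np.median(d)
    bad = np.nonzero(np.abs(d - ref) > 1e-6 * max(ref, 1.0))[0]
    if len(bad):
        i = int(bad[0])
        raise ValueError(
            f"non-uniform time grid: interval {i} "
            f"({times[i]:.6g}..{times[i + 1]:.6g} min) differs from {ref:.6g} min"
        )


@dataclass
class Peak:
    apex_time: float
    height: float
    area: float = 0.0
    assigned: str | None = None


@dataclass
class PeakSet:
    peaks: list[Peak] = field(default_factory=list)

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def assigned(self) -> dict[str, Peak]:
        return {p.assigned: p for p in self.peaks if p.assigned is not None}

    def unassigned(self) -> list[Peak]:
        return [p for p in self.peaks if p.assigned is None]


def synthesize(
    profile: ClassProfile,
    rt: RetentionTable,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    t_max: float = 40.0,
    dt: float = 0.01,
    response: "str | dict[str, float]" = "equal",
    metadata: dict | None = None,
) -> Chromatogram:
    """Render a class profile as a detector trace.

    Each class contributes ``amount * response`` units of area in a Gaussian
    at its retention time; identical seeds give bit-identical noise.
    """
    times = np.arange(0.0, t_max + dt / 2, dt)
    signal = np.full_like(times, float(baseline))
    for name, amount in profile.items():
        if name == FREE_INOSITOL or amount == 0:
            continue  # free inositol: no phosphate, no detector response
        if name not in rt.entries:
            raise KeyError(f"class {name!r} missing from retention table")
        mu, sigma = rt.entries[name]
        resp = _response_factor(name, response)
        signal += (
            amount
            * resp
            / (sigma * np.sqrt(2 * np.pi))
            * np.exp(-0.5 * ((times - mu) / sigma) ** 2)
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=len(times))
    return Chromatogram(times=times, signal=signal, metadata=dict(metadata or {}))


def _phosphates(name: str) -> int:
    if name == PI_POOL:
        return 1
    if name.startswith("InsP"):
        return int(name[4])
    return int(name.rsplit("P", 1)[1])


def _response_factor(name: str, response: "str | dict[str, float]") -> float:
    if isinstance(response, dict):
        return response.get(name, 1.0)
    if response == "equal":
        return 1.0
    if response == "per_phosphate":
        return float(_phosphates(name))
    raise ValueError(f"unknown response model {response!r}")


def _estimate_baseline_noise(signal: np.ndarray) -> tuple[float, float]:
    baseline = float(np.median(signal))
    diffs = np.diff(signal)
    noise = 1.4826 * float(np.median(np.abs(diffs - np.median(diffs)))) / np.sqrt(2)
    return baseline, noise


def detect_peaks(
    c: Chromatogram,
    smooth_window: int = 11,
    min_snr: float = 5.0,
    min_prominence_frac: float = 0.005,
    merge_distance: float = 0.3,
) -> PeakSet:
    """Local-maxima peak picking on the smoothed trace.

    The floor is the larger of ``min_snr`` times the estimated noise and
    ``min_prominence_frac`` of the tallest excursion; apices are refined by
    parabolic interpolation; peaks closer than ``merge_distance`` minutes
    merge, keeping the taller apex.
    """
    if len(c.signal) <= smooth_window:
        raise ValueError("trace shorter than the smoothing window")
    if smooth_window >= 5:
        smoothed = savgol_filter(c.signal, smooth_window | 1, polyorder=3)
    else:
        smoothed = c.signal.astype(float)
    baseline, noise = _estimate_baseline_noise(smoothed)
    span = float(smoothed.max() - baseline)
    if span <= 0:
        return PeakSet()
    floor = max(min_snr * noise, min_prominence_frac * span, 1e-12)
    idx, props = find_peaks(smoothed, prominence=floor, height=baseline + floor)
    peaks: list[Peak] = []
    for i in idx:
        apex_t, apex_h = _parabolic_apex(c.times, smoothed, int(i))
        peaks.append(Peak(apex_time=apex_t, height=apex_h - baseline))
    peaks.sort(key=lambda p: p.apex_time)
    return PeakSet(peaks=_merge_close(peaks, merge_distance))


def _parabolic_apex(t: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    if i == 0 or i == len(y) - 1:
        return float(t[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(t[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1, 1))
    dt = t[1] - t[0]
    apex_t = float(t[i] + delta * dt)
    apex_y = float(y1 - 0.25 * (y0 - y2) * delta)
    return apex_t, apex_y


def _merge_close(peaks: list[Peak], merge_distance: float) -> list[Peak]:
    merged: list[Peak] = []
    for p in peaks:
        if merged and p.apex_time - merged[-1].apex_time < merge_distance:
            if p.height > merged[-1].height:
                merged[-1] = p
        else:
            merged.append(p)
    return merged


def integrate_and_assign(
    pk: PeakSet, c: Chromatogram, rt: RetentionTable
) -> PeakSet:
    """Trapezoidal areas over valley-bounded +/-3 sigma windows, then
    nearest-retention-time assignment within tolerance.

    Pi and InsP1 share the pooled solvent-front class.  If two peaks land on
    one class the taller apex keeps the class and absorbs the other's area
    (co-elution); truly unmatched peaks stay unassigned.
    """
    baseline, _ = _estimate_baseline_noise(c.signal)
    apices = sorted(p.apex_time for p in pk)
    out: list[Peak] = []
    for p in sorted(pk, key=lambda q: q.apex_time):
        name, dist = rt.nearest(p.apex_time)
        assigned = name if dist <= rt.tolerance else None
        sigma = rt.sigma(name) if assigned else _DEFAULT_SIGMA
        lo, hi = p.apex_time - 3 * sigma, p.apex_time + 3 * sigma
        # bound by the midpoint valleys towards neighbouring peaks
        i = apices.index(p.apex_time)
        if i > 0:
            lo = max(lo, (apices[i - 1] + p.apex_time) / 2)
        if i < len(apices) - 1:
            hi = min(hi, (p.apex_time + apices[i + 1]) / 2)
        sel = (c.times >= lo) & (c.times <= hi)
        # no pointwise clipping: negative noise excursions must cancel to
        # keep the area estimator unbiased
        area = max(0.0, float(np.trapezoid(c.signal[sel] - baseline, c.times[sel])))
        out.append(Peak(apex_time=p.apex_time, height=p.height, area=area, assigned=assigned))
    # enforce at most one peak per class: taller keeps it, areas pool
    by_class: dict[str, Peak] = {}
    final: list[Peak] = []
    for p in out:
        if p.assigned is None:
            final.append(p)
            continue
        if p.assigned in by_class:
            keeper = by_class[p.assigned]
            if p.height > keeper.height:
                p.area += keeper.area
                final.remove(keeper)
                by_class[p.assigned] = p
                final.append(p)
            else:
                keeper.area += p.area
        else:
            by_class[p.assigned] = p
            final.append(p)
    final.sort(key=lambda q: q.apex_time)
    return PeakSet(peaks=final)


def quantify(
    pk: PeakSet,
    response: "str | dict[str, float]" = "equal",
    normalize: bool = True,
    include_pi: bool = False,
) -> ClassProfile:
    """Convert assigned peak areas to mole amounts via the response model.

    With ``normalize=True`` amounts become mole fractions of total inositol
    phosphate (the Pi pool joins the basis only with ``include_pi=True``).
    Unassigned peaks are carried on the profile's ``unassigned`` list.
    """
    amounts = {
        name: p.area / _response_factor(name, response)
        for name, p in pk.assigned().items()
    }
    prof = ClassProfile(amounts=amounts, unassigned=list(pk.unassigned()))
    if normalize:
        prof = prof.normalize(include_pi=include_pi)
    return prof


def write_chromatogram(c: Chromatogram, path) -> None:
    """CSV export: header ``time_min,signal``, full float precision."""
    df = pd.DataFrame({"time_min": c.times, "signal": c.signal})
    df.to_csv(path, index=False, float_format="%.10g")


def read_chromatogram(path) -> Chromatogram:
    """Read a ``time_min,signal`` CSV; errors carry the offending line."""
    times: list[float] = []
    signal: list[float] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["time_min", "signal"]:
            raise ValueError(f"{path}: expected header 'time_min,signal', got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: line {lineno}: expected two columns")
            try:
                times.append(float(row[0]))
                signal.append(float(row[1]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return Chromatogram(times=np.array(times), signal=np.array(signal))


def write_retention_table(rt: RetentionTable, path) -> None:
    df = pd.DataFrame(
        [(c, v[0], v[1]) for c, v in rt.entries.items()],
        columns=["class", "rt_min", "sigma_min"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_retention_table(path, tolerance: float = 0.4) -> RetentionTable:
    df = pd.read_csv(path, sep="\t")
    required = {"class", "rt_min", "sigma_min"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: retention table needs columns {sorted(required)}")
    entries = {
        str(r["class"]): (float(r["rt_min"]), float(r["sigma_min"]))
        for _, r in df.iterrows()
    }
    return RetentionTable(entries=entries, tolerance=tolerance)
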