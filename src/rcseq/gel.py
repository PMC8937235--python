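"""Gel densitometry: extension efficiency, periodicity, velocities.

A denaturing-PAGE lane of a primer-extension reaction resolves products by
the number of triplets incorporated: band 0 is the unextended primer, band
``b`` the product extended through junction ``b``.  From quantified band
intensities ``I_0..I_n`` the per-junction extension efficiency is

    E_b = (sum of I_b..I_n) / (sum of I_(b-1)..I_n)

i.e. the fraction of molecules that reached band ``b-1`` and were extended
through junction ``b``.  The product of ``E_1..E_k`` telescopes to the
survival fraction at band ``k``.

On a small circular template, junctions facing the inside of the ring are
less accessible, so the efficiency series oscillates with the helical
period of A-form dsRNA (11.3 bp/turn); :func:`periodicity` recovers that
period by scanning sinusoid fits over the series mapped to nucleotide
coordinates (one triplet = 3 bp of new duplex).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "A_FORM_PITCH_BP",
    "LaneProfile",
    "EfficiencySeries",
    "TimeCourse",
    "DensitometryError",
    "extension_efficiency",
    "survival_fraction",
    "mean_efficiency",
    "periodicity",
    "band_velocity",
    "parity_size",
    "read_lane",
    "read_timecourse",
]

#: Helical pitch of A-form double-stranded RNA, bp per turn.
A_FORM_PITCH_BP = 11.3


class DensitometryError(ValueError):
    """A lane or series is unusable for the requested summary."""


@dataclass(frozen=True)
class LaneProfile:
    """Band intensities ``I_0..I_n`` of one lane (band 0 = unextended primer)."""

    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise DensitometryError("a lane needs at least bands 0 and 1")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise DensitometryError("band intensities must be finite and non-negative")
        object.__setattr__(self, "intensities", arr)

    @property
    def n(self) -> int:
        """Index of the highest detectable band."""
        return self.intensities.size - 1

    @property
    def total(self) -> float:
        return float(self.intensities.sum())


@dataclass(frozen=True)
class EfficiencySeries:
    """Per-junction efficiencies ``E_1..E_n``; NaN marks an undefined entry
    (zero denominator: no molecules reached the junction)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        defined = arr[~np.isnan(arr)]
        if np.any(defined < -1e-12) or np.any(defined > 1 + 1e-12):
            raise DensitometryError("defined efficiencies must lie in [0, 1]")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    def __getitem__(self, b: int) -> float:
        """1-based access: series[b] is E_b."""
        if not 1 <= b <= len(self):
            raise IndexError(f"junction index must be in 1..{len(self)}, got {b}")
        return float(self.values[b - 1])


def extension_efficiency(lane: LaneProfile) -> EfficiencySeries:
    """Eq.-style per-junction efficiencies from band intensities.

    ``E_b`` is the tail sum from band ``b`` divided by the tail sum from
    band ``b-1``; a zero denominator yields NaN (no signal is not the same
    as zero efficiency).
    """
    I = lane.intensities
    # tail[i] = sum of I_i..I_n
    tail = np.cumsum(I[::-1])[::-1]
    E = np.full(lane.n, np.nan)
    for b in range(1, lane.n + 1):
        denom = tail[b - 1]
        if denom > 0:
            E[b - 1] = tail[b] / denom
    return EfficiencySeries(E)


def survival_fraction(lane: LaneProfile, k: int) -> float:
    """Fraction of all molecules extended through at least ``k`` junctions."""
    if not 1 <= k <= lane.n:
        raise DensitometryError(f"k must be in 1..{lane.n}, got {k}")
    total = lane.total
    if total == 0:
        raise DensitometryError("empty lane: total intensity is zero")
    return float(lane.intensities[k:].sum() / total)


def mean_efficiency(
    series: EfficiencySeries, through: Optional[int] = None, kind: str = "arithmetic"
) -> float:
    """Mean of ``E_1..E_through`` (arithmetic by default; geometric optional,
    whose ``through``-th power is the survival fraction)."""
    through = len(series) if through is None else through
    if not 1 <= through <= len(series):
        raise DensitometryError(f"through must be in 1..{len(series)}, got {through}")
    vals = series.values[:through]
    if np.any(np.isnan(vals)):
        raise DensitometryError("series has undefined junctions within the requested range")
    if kind == "arithmetic":
        return float(np.mean(vals))
    if kind == "geometric":
        return float(np.exp(np.mean(np.log(np.clip(vals, 1e-300, None)))))
    raise DensitometryError(f"unknown mean kind {kind!r}")


def periodicity(
    series: EfficiencySeries,
    step_nt: float = 3.0,
    periods_bp: Optional[Sequence[float]] = None,
    r2_threshold: float = 0.2,
) -> tuple[Optional[float], float]:
    """Dominant period (bp) of an efficiency series and its fit R².

    The series is placed at nucleotide coordinates ``b * step_nt``, a linear
    trend is removed, and a sinusoid (sine + cosine pair) is least-squares
    fitted at each candidate period; the period maximizing variance
    explained wins.  Returns ``(None, best_r2)`` when no candidate explains
    at least ``r2_threshold`` of the variance (e.g. a flat series).

    Candidate periods shorter than twice the band spacing (``2 * step_nt``)
    are skipped: they lie beyond the Nyquist limit of a series sampled once
    per triplet and are indistinguishable from their aliases.
    """
    if periods_bp is None:
        periods_bp = np.arange(2.0, 20.0 + 1e-9, 0.1)
    periods_bp = [p for p in periods_bp if p >= 2 * step_nt]
    if not periods_bp:
        raise DensitometryError("no identifiable candidate periods (all below Nyquist)")
    vals = series.values
    mask = ~np.isnan(vals)
    if mask.sum() < 5:
        raise DensitometryError("periodicity needs at least 5 defined junctions")
    x = (np.nonzero(mask)[0] + 1).astype(float) * step_nt
    y = vals[mask]
    # the sinusoid is fitted jointly with a linear baseline so a drifting
    # trend neither masquerades as nor absorbs part of the oscillation;
    # R² is variance explained beyond the baseline-only fit
    base = np.column_stack([np.ones_like(x), x])
    coef0, *_ = np.linalg.lstsq(base, y, rcond=None)
    sstot = float(np.sum((y - base @ coef0) ** 2))
    # variance at the level of float rounding is a flat series, not a signal
    if sstot <= 1e-18 * max(float(np.sum(y**2)), 1.0):
        return None, 0.0
    best_period, best_r2 = None, -np.inf
    for p in periods_bp:
        w = 2 * np.pi / p
        design = np.column_stack([np.sin(w * x), np.cos(w * x), np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        ssres = float(np.sum((y - design @ coef) ** 2))
        r2 = 1 - ssres / sstot
        if r2 > best_r2:
            best_period, best_r2 = float(p), r2
    if best_r2 < r2_threshold:
        return None, max(best_r2, 0.0)
    return best_period, best_r2


@dataclass(frozen=True)
class TimeCourse:
    """Ordered (time, lane) pairs from one extension time course."""

    times: np.ndarray
    lanes: tuple[LaneProfile, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size != len(self.lanes):
            raise DensitometryError("one lane per timepoint required")
        if np.any(np.diff(t) <= 0):
            raise DensitometryError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "lanes", tuple(self.lanes))

    def band_fraction(self, band: int) -> np.ndarray:
        """Intensity of one band as fraction of lane total, per timepoint.

        Fractions (not absolute intensities) remove lane-loading variation.
        """
        out = np.empty(self.times.size)
        for i, lane in enumerate(self.lanes):
            if band > lane.n:
                out[i] = 0.0
            else:
                total = lane.total
                if total == 0:
                    raise DensitometryError(f"empty lane at timepoint {self.times[i]}")
                out[i] = lane.intensities[band] / total
        return out


def band_velocity(
    tc: TimeCourse, band: int, window: Optional[tuple[float, float]] = None
) -> float:
    """Rate of formation of one band: OLS slope of its lane fraction vs time."""
    frac = tc.band_fraction(band)
    t = tc.times
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, frac = t[sel], frac[sel]
    if t.size < 2:
        raise DensitometryError("band_velocity needs at least 2 timepoints in the window")
    slope = np.polynomial.polynomial.polyfit(t, frac, 1)[1]
    return float(slope)


def parity_size(
    points: Sequence[tuple[float, float]], linear_reference: float
) -> tuple[float, bool]:
    """Template size at which mean circular efficiency reaches the linear level.

    Fits an OLS line to (circle size, mean efficiency) points and solves for
    the size where the line equals ``linear_reference``.  Returns ``(size,
    extrapolated)`` where the flag is True when the crossing lies outside
    the observed size range.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or len(set(pts[:, 0])) < 2:
        raise DensitometryError("parity_size needs ≥ 2 points with distinct sizes")
    intercept, slope = np.polynomial.polynomial.polyfit(pts[:, 0], pts[:, 1], 1)
    size_span = float(pts[:, 0].max() - pts[:, 0].min())
    if abs(slope) * size_span < 1e-12 * max(1.0, abs(linear_reference)):
        if np.isclose(intercept, linear_reference):
            return float(pts[:, 0].mean()), False
        raise DensitometryError("flat trend never crosses the linear reference")
    size = (linear_reference - intercept) / slope
    eps = 1e-9 * max(size_span, 1.0)
    extrapolated = not (pts[:, 0].min() - eps <= size <= pts[:, 0].max() + eps)
    return float(size), extrapolated


# -- tabular input ------------------------------------------------------


def read_lane(path, metadata: Optional[dict] = None) -> LaneProfile:
    """Read a lane TSV with columns ``band_index`` (0-based) and ``intensity``."""
    frame = pd.read_csv(path, sep="\t")
    frame = frame.sort_values("band_index")
    idx = frame["band_index"].to_numpy()
    if not np.array_equal(idx, np.arange(len(idx))):
        raise DensitometryError(f"{path}: band_index must run 0..n without gaps")
    return LaneProfile(frame["intensity"].to_numpy(float), metadata=metadata or {})


def read_timecourse(path) -> TimeCourse:
    """Read a time course TSV with columns ``time``, ``band_index``, ``intensity``."""
    frame = pd.read_csv(path, sep="\t")
    times = sorted(frame["time"].unique())
    lanes = []
    for t in times:
        sub = frame[frame["time"] == t].sort_values("band_index")
        lanes.append(LaneProfile(sub["intensity"].to_numpy(float), metadata={"time": t}))
    return TimeCourse(np.asarray(times, dtype=float), tuple(lanes))
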