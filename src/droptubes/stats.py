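"""Condensation statistics: per-droplet intensity moments and aggregation.

As nanotubes polymerize inside a droplet, fluorescent signal condenses from
a diffuse free-tile background into a few bright pixels; the shape of the
droplet's pixel-intensity distribution therefore changes from roughly
symmetric to strongly right-tailed.  Skewness (third standardized moment)
and excess kurtosis (fourth, minus 3) quantify that change, and — being
shape statistics — are invariant to exposure as long as no pixel saturates.
They measure the ratio of condensed to free fluorophores, not nanotube
concentration, and cannot distinguish well-formed nanotubes from disordered
aggregates.

Two per-droplet modes are provided:

* ``"pixels"`` — ordinary occupancy-weighted sample moments of all interior
  pixel values (recommended);
* ``"unique"`` — moments of the list of *unique binned* brightness values
  (each occupied histogram bin contributes its representative value once,
  occupancy discarded), mirroring a published processing pipeline this
  package reproduces.  The two modes genuinely diverge: "unique" throws
  away occupancy weights.

Estimators are the bias-corrected G1/G2 (Fisher convention; a normal
distribution gives 0/0), matching ``pandas.Series.skew``/``.kurt`` and
``scipy.stats.skew/kurtosis(bias=False)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MomentSummary",
    "PopulationTimepoint",
    "Timecourse",
    "sample_skewness",
    "sample_excess_kurtosis",
    "unique_value_reduction",
    "summarize_droplet",
    "aggregate_population",
    "build_timecourse",
]

Mode = Literal["pixels", "unique"]


@dataclass
class MomentSummary:
    """Per-droplet moment summary; ``excluded_reason`` is None when valid."""

    droplet_id: int
    frame_index: int
    n_values: int
    mean_intensity: float
    sd_intensity: float
    skewness: float
    excess_kurtosis: float
    mode: str
    excluded_reason: str | None = None

    @property
    def valid(self) -> bool:
        return self.excluded_reason is None


@dataclass
class PopulationTimepoint:
    """Population mean +/- sample SD of the per-droplet moments at one time.

    SDs use the n-1 denominator; with a single droplet they are reported as
    0.0 and ``single_droplet`` is flagged, keeping CSV output numeric.
    """

    time_min: float
    n_droplets: int
    mean_skewness: float
    sd_skewness: float
    mean_kurtosis: float
    sd_kurtosis: float
    n_excluded: int = 0
    single_droplet: bool = False


@dataclass
class Timecourse:
    points: list[PopulationTimepoint]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "time_min": p.time_min,
                    "n_droplets": p.n_droplets,
                    "mean_skewness": p.mean_skewness,
                    "sd_skewness": p.sd_skewness,
                    "mean_kurtosis": p.mean_kurtosis,
                    "sd_kurtosis": p.sd_kurtosis,
                    "n_excluded": p.n_excluded,
                }
                for p in self.points
            ]
        )


def _central_moments(values: np.ndarray):
    n = values.size
    mean = values.mean()
    d = values - mean
    m2 = float(np.mean(d**2))
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    return n, mean, m2, m3, m4


def sample_skewness(values: Sequence[float], bias_corrected: bool = True) -> float:
    """Sample skewness; bias-corrected G1 by default.

    G1 = n^2 / ((n-1)(n-2)) * m3 / s^3 with m3 the third central moment and
    s the sample (n-1) standard deviation.  Requires n >= 3 and nonzero
    variance.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("skewness requires at least 3 values")
    n, _, m2, m3, _ = _central_moments(values)
    if m2 <= 0:
        raise ValueError("skewness undefined for zero-variance sample")
    g1 = m3 / m2**1.5
    if not bias_corrected:
        return g1
    return np.sqrt(n * (n - 1)) / (n - 2) * g1


def sample_excess_kurtosis(values: Sequence[float], bias_corrected: bool = True) -> float:
    """Sample excess kurtosis (Fisher convention); bias-corrected G2 default.

    G2 = ((n+1) g2 + 6) (n-1) / ((n-2)(n-3)) with g2 = m4/m2^2 - 3; a normal
    sample converges to 0.  Requires n >= 4 and nonzero variance.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("excess kurtosis requires at least 4 values")
    n, _, m2, _, m4 = _central_moments(values)
    if m2 <= 0:
        raise ValueError("kurtosis undefined for zero-variance sample")
    g2 = m4 / m2**2 - 3.0
    if not bias_corrected:
        return g2
    return ((n + 1) * g2 + 6.0) * (n - 1) / ((n - 2) * (n - 3))


def unique_value_reduction(values: Sequence[float], bin_width: float = 1.0) -> np.ndarray:
    """Reduce a pixel sample to its sorted unique binned brightness values.

    The sample is histogrammed with fixed ``bin_width`` bins anchored at the
    sample minimum; every occupied bin contributes its representative value
    (the left bin edge) exactly once — occupancy weights are discarded.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot reduce an empty sample")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = values.min()
    idx = np.floor((values - lo) / bin_width).astype(np.int64)
    return lo + np.unique(idx) * bin_width


def summarize_droplet(
    droplet,
    mode: Mode = "unique",
    bin_width: float = 1.0,
    bias_corrected: bool = True,
    droplet_id: int | None = None,
) -> MomentSummary:
    """Compute a MomentSummary for one detected droplet.

    ``droplet`` needs ``pixel_values`` and ``frame_index`` attributes (a
    DetectedDroplet).  Droplets that are degenerate after the selected
    reduction (zero variance, or fewer than 4 values) are returned with an
    ``excluded_reason`` instead of raising, so population aggregation can
    report exclusions explicitly.
    """
    if mode not in ("pixels", "unique"):
        raise ValueError("mode must be 'pixels' or 'unique'")
    raw = np.asarray(droplet.pixel_values, dtype=float)
    did = droplet_id if droplet_id is not None else getattr(droplet, "droplet_id", 0)
    frame = getattr(droplet, "frame_index", 0)

    def _excluded(reason: str, vals: np.ndarray) -> MomentSummary:
        return MomentSummary(
            droplet_id=did, frame_index=frame, n_values=int(vals.size),
            mean_intensity=float(vals.mean()) if vals.size else float("nan"),
            sd_intensity=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            skewness=float("nan"), excess_kurtosis=float("nan"),
            mode=mode, excluded_reason=reason,
        )

    if raw.size == 0:
        return _excluded("no pixels", raw)
    vals = unique_value_reduction(raw, bin_width) if mode == "unique" else raw
    if vals.size < 4:
        return _excluded("too few values", vals)
    if np.ptp(vals) == 0:
        return _excluded("zero variance", vals)
    return MomentSummary(
        droplet_id=did,
        frame_index=frame,
        n_values=int(vals.size),
        mean_intensity=float(vals.mean()),
        sd_intensity=float(vals.std(ddof=1)),
        skewness=float(sample_skewness(vals, bias_corrected)),
        excess_kurtosis=float(sample_excess_kurtosis(vals, bias_corrected)),
        mode=mode,
    )


def aggregate_population(
    summaries: Sequence[MomentSummary], time_min: float
) -> PopulationTimepoint:
    """Unweighted mean and sample SD of the per-droplet moments.

    Excluded droplets are counted separately; zero valid droplets is an
    error naming the frame.
    """
    valid = [s for s in summaries if s.valid]
    n_exc = len(summaries) - len(valid)
    if not valid:
        frame = summaries[0].frame_index if summaries else "?"
        raise ValueError(f"no valid droplets at time {time_min} (frame {frame})")
    sk = np.array([s.skewness for s in valid])
    ku = np.array([s.excess_kurtosis for s in valid])
    single = len(valid) == 1
    return PopulationTimepoint(
        time_min=float(time_min),
        n_droplets=len(valid),
        mean_skewness=float(sk.mean()),
        sd_skewness=0.0 if single else float(sk.std(ddof=1)),
        mean_kurtosis=float(ku.mean()),
        sd_kurtosis=0.0 if single else float(ku.std(ddof=1)),
        n_excluded=n_exc,
        single_droplet=single,
    )


def build_timecourse(
    frames: Sequence[tuple[float, Sequence[MomentSummary]]]
) -> Timecourse:
    """Aggregate per-frame summaries into a chronological timecourse."""
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    times = [t for t, _ in frames]
    if len(set(times)) != len(times):
        raise ValueError("duplicate timestamps in timecourse")
    points = [aggregate_population(s, t) for t, s in frames]
    points.sort(key=lambda p: p.time_min)
    return Timecourse(points=points)


def summaries_to_frame(summaries: Sequence[MomentSummary]) -> pd.DataFrame:
    """Tidy per-droplet table (one row per droplet per frame)."""
    return pd.DataFrame(
        [
            {
                "frame": s.frame_index,
                "droplet_id": s.droplet_id,
                "n_pixels": s.n_values,
                "mean": s.mean_intensity,
                "sd": s.sd_intensity,
                "skewness": s.skewness,
                "kurtosis": s.excess_kurtosis,
                "mode": s.mode,
                "excluded_reason": s.excluded_reason or "",
            }
            for s in summaries
        ]
    )
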