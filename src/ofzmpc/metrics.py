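"""Glycemic statistics and study-level reporting.

Band structure for time-in-range reporting: <54, 54-70, 70-180, 180-250
and >250 mg/dL (the five bands tile the positive axis).  Also provides
MedARD with a percentile bootstrap CI, the precision-based sample-size
formula, Pearson correlations and cohort mean/SD summaries, plus packaged
per-subject cohort fixtures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BANDS",
    "GlycemicReport",
    "SampleSizeSpec",
    "glycemic_report",
    "medard",
    "precision_sample_size",
    "pearson",
    "cohort_summary",
    "round_half_up",
    "load_cohort_outcomes",
]

#: (label, lower, upper) with lower-inclusive, upper-exclusive edges except
#: the normoglycemic band which is closed on both sides: [0,54), [54,70),
#: [70,180], (180,250], (250,inf).
BANDS = (
    ("<54", 0.0, 54.0),
    ("54-70", 54.0, 70.0),
    ("70-180", 70.0, 180.0),
    ("180-250", 180.0, 250.0),
    (">250", 250.0, math.inf),
)


def band_of(value: float) -> str:
    """Band label for a single glucose value (every value lands in exactly
    one band)."""
    if value < 54.0:
        return "<54"
    if value < 70.0:
        return "54-70"
    if value <= 180.0:
        return "70-180"
    if value <= 250.0:
        return "180-250"
    return ">250"


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal half-up rounding, matching printed-table conventions."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GlycemicReport:
    mean: float
    sd: float
    cv_pct: float
    band_pct: dict
    band_events: dict
    total_insulin: float | None
    insulin_per_day: float | None
    peak_glucose: float
    nadir_glucose: float
    n_samples: int

    @property
    def tir(self) -> float:
        """Percent time in 70-180 mg/dL."""
        return self.band_pct["70-180"]


def _count_events(in_band: np.ndarray, min_run: int, merge_gap: int) -> int:
    """Episodes = maximal runs of in-band samples lasting >= ``min_run``
    samples, with runs separated by < ``merge_gap`` samples merged."""
    idx = np.flatnonzero(in_band)
    if idx.size == 0:
        return 0
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i == prev + 1:
            prev = i
            continue
        runs.append((start, prev))
        start = prev = i
    runs.append((start, prev))
    merged = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] - 1 < merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return sum(1 for s, e in merged if e - s + 1 >= min_run)


def glycemic_report(
    glucose,
    insulin=None,
    *,
    period_min: float = 5.0,
    event_min_duration_min: float = 15.0,
    event_merge_gap_min: float = 30.0,
) -> GlycemicReport:
    """Summary statistics of a uniformly sampled glucose trace.

    Band occupancy is the fraction of samples in each band; episode counts
    use a configurable run rule (never part of the printed-table targets).
    """
    g = np.asarray(glucose, dtype=float)
    g = g[np.isfinite(g)]
    if g.size == 0:
        raise ValueError("glucose series is empty")
    mean = float(g.mean())
    sd = float(g.std(ddof=1)) if g.size > 1 else 0.0
    cv = 100.0 * sd / mean if mean != 0 else float("nan")

    labels = np.array([band_of(v) for v in g])
    band_pct = {name: 100.0 * float((labels == name).mean()) for name, _, _ in BANDS}
    min_run = max(1, int(round(event_min_duration_min / period_min)))
    merge_gap = max(1, int(round(event_merge_gap_min / period_min)))
    band_events = {
        name: _count_events(labels == name, min_run, merge_gap) for name, _, _ in BANDS
    }

    total_insulin = insulin_per_day = None
    if insulin is not None:
        ins = np.asarray(insulin, dtype=float)
        total_insulin = float(np.nansum(ins))
        days = len(ins) * period_min / (24 * 60.0)
        insulin_per_day = total_insulin / days if days > 0 else float("nan")

    return GlycemicReport(
        mean=mean,
        sd=sd,
        cv_pct=cv,
        band_pct=band_pct,
        band_events=band_events,
        total_insulin=total_insulin,
        insulin_per_day=insulin_per_day,
        peak_glucose=float(g.max()),
        nadir_glucose=float(g.min()),
        n_samples=int(g.size),
    )


def medard(
    predictions,
    references,
    n_boot: int = 5000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Median absolute relative difference (%) with a percentile bootstrap CI.

    ARD_i = |pred_i - ref_i| / ref_i * 100; pairs with non-positive or
    non-finite references are excluded (with a warning).  The CI resamples
    pairs with replacement, ``n_boot`` replicates, seeded.
    """
    pred = np.asarray(predictions, dtype=float)
    ref = np.asarray(references, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("predictions and references must have equal length")
    ok = np.isfinite(pred) & np.isfinite(ref) & (ref > 0)
    n_excluded = int((~ok).sum())
    if n_excluded:
        warnings.warn(
            f"medard: excluded {n_excluded} pairs with missing or "
            "non-positive references",
            stacklevel=2,
        )
    pred, ref = pred[ok], ref[ok]
    if pred.size == 0:
        raise ValueError("no valid prediction/reference pairs")
    ard = np.abs(pred - ref) / ref * 100.0
    point = float(np.median(ard))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, ard.size, size=(n_boot, ard.size))
    boots = np.median(ard[idx], axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return point, (float(lo), float(hi))


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs of the precision-based sample-size formula."""

    z: float = 1.96       # two-sided 95% critical value
    sigma: float = 11.45  # expected SD (mg/dL)
    margin: float = 6.0   # desired precision (mg/dL)

    def __post_init__(self) -> None:
        if self.z <= 0 or self.sigma <= 0:
            raise ValueError("z and sigma must be positive")
        if self.margin <= 0:
            raise ValueError("precision margin must be positive")


def precision_sample_size(spec: SampleSizeSpec) -> int:
    """n = ceil((z * sigma / margin)^2)."""
    return int(math.ceil((spec.z * spec.sigma / spec.margin) ** 2))


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson needs two equal-length series of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class ColumnSummary:
    mean: float
    sd: float          # n-1 sample SD
    sd_pop: float      # n denominator
    cv: float          # sd / mean (n-1 convention)
    cv_pop: float      # population convention
    n: int


def cohort_summary(table: pd.DataFrame, columns=None) -> dict[str, ColumnSummary]:
    """Per-column mean and SD over subjects.

    The printed cohort tables mix conventions: the AVG-row SDs follow the
    n-1 sample convention while the CV row follows the n convention, so
    both are reported, labeled.
    """
    if len(table) < 2:
        raise ValueError("cohort summary needs at least 2 subjects")
    columns = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    out = {}
    for col in columns:
        v = table[col].to_numpy(dtype=float)
        mean = float(v.mean())
        sd = float(v.std(ddof=1))
        sd_pop = float(v.std(ddof=0))
        out[col] = ColumnSummary(
            mean=mean,
            sd=sd,
            sd_pop=sd_pop,
            cv=sd / mean if mean else float("nan"),
            cv_pop=sd_pop / mean if mean else float("nan"),
            n=int(v.size),
        )
    return out


def load_cohort_outcomes() -> pd.DataFrame:
    """Packaged per-subject closed-loop outcome fixtures for the 13-rat
    cohort (glycemic summaries, insulin totals, body weights)."""
    with resources.files("ofzmpc.data").joinpath("rat_cohort_outcomes.csv").open() as fh:
        return pd.read_csv(fh)
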