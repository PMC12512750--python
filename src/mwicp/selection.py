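"""Correlation analysis and the Ordered Selection Scheme (OSS).

Every feature series is scored by its Pearson correlation with the
synchronized reference pressure; correlations are binned by strength for
reporting (heatmap/Sankey style summaries) and the OSS keeps the classes
whose |r| exceeds a threshold (default 0.8), ordered from strongest to
weakest. A significance gate (default p < 0.001) excludes features whose
correlation is not statistically solid regardless of |r|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import DegenerateInputError

__all__ = [
    "pearson",
    "bin_strength",
    "correlate_table",
    "aggregate_by_class",
    "oss_select",
    "OSSSelection",
    "STRENGTH_BINS",
]

# (label, lower-exclusive, upper-inclusive) on |r|; printed-boundary
# semantics: 0.8 itself is "strong", not "very strong".
STRENGTH_BINS = (
    ("very-strong", 0.8, 1.0),
    ("strong", 0.6, 0.8),
    ("weak+", 0.4, 0.6),
    ("weak", 0.2, 0.4),
    ("none", -1.0, 0.2),
)


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p value (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(x) < 3:
        raise DegenerateInputError("need at least 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("correlation undefined for zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bin_strength(r: float) -> str:
    """Correlation-strength label on |r| per the printed boundaries."""
    a = abs(float(r))
    if a > 1.0:
        raise ValueError("|r| must not exceed 1")
    for label, lo, hi in STRENGTH_BINS:
        if lo < a <= hi:
            return label
    return "none"  # a == 0


def correlate_table(feature_table: pd.DataFrame) -> pd.DataFrame:
    """Score every (sensor, trial, placement, variant, class) series.

    Expects the tidy table from ``features.extract_feature_table`` (which
    carries the aligned pressure per sweep). Series with masked sweeps are
    scored on their valid samples; series that remain degenerate (all-NaN
    or zero variance) are dropped with a logged reason.
    """
    rows = []
    keys = ["sensor", "trial", "placement", "variant", "class"]
    for key, grp in feature_table.groupby(keys, sort=True):
        v = grp["value"].to_numpy()
        p = grp["p_mmHg"].to_numpy()
        ok = np.isfinite(v) & np.isfinite(p)
        if ok.sum() < 3 or np.std(v[ok]) == 0 or np.std(p[ok]) == 0:
            warnings.warn(f"dropping degenerate feature series {key}")
            continue
        r, pval = pearson(v[ok], p[ok])
        rows.append(dict(zip(keys, key)) | {
            "r": r, "p_value": pval, "n": int(ok.sum()),
            "bin": bin_strength(r),
        })
    return pd.DataFrame(rows)


def aggregate_by_class(report: pd.DataFrame) -> pd.DataFrame:
    """Collapse a correlation report to one row per feature class.

    The class score is the median of r over trials/variants (median
    preserves sign for a consistently-signed class) and the median p value;
    used when the OSS must pick one class set for a whole sensor campaign.
    """
    out = (report.groupby("class")
           .agg(r=("r", "median"), p_value=("p_value", "median"),
                n=("n", "sum"))
           .reset_index())
    out["bin"] = out["r"].map(bin_strength)
    return out


@dataclass(frozen=True)
class OSSSelection:
    """Feature classes ordered by |r| descending with a selected prefix."""

    ordered: tuple[str, ...]
    selected: tuple[str, ...]
    threshold: float
    scores: dict[str, float] = field(default_factory=dict)


def oss_select(report: pd.DataFrame, threshold: float = 0.8,
               alpha: float = 0.001) -> OSSSelection:
    """Ordered Selection Scheme on a per-class correlation report.

    Stable-sorts classes by |r| descending (ties keep catalog order a..l),
    then selects the prefix with |r| strictly above ``threshold``; classes
    with p >= ``alpha`` are excluded regardless of |r|. Emits a warning if
    nothing survives.
    """
    if "class" not in report.columns:
        raise ValueError("report must carry a 'class' column")
    df = report.sort_values("class", kind="stable")
    df = df.sort_values("r", key=lambda s: s.abs(), ascending=False,
                        kind="stable")
    ordered = tuple(df["class"])
    significant = df["p_value"] < alpha if "p_value" in df else True
    keep = df[(df["r"].abs() > threshold) & significant]
    selected = tuple(keep["class"])
    if not selected:
        warnings.warn("OSS selected no features at threshold "
                      f"{threshold} (alpha={alpha})")
    return OSSSelection(
        ordered=ordered,
        selected=selected,
        threshold=threshold,
        scores=dict(zip(df["class"], df["r"])),
    )
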