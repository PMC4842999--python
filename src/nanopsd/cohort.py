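"""Cohort-level aggregation of per-structure measurements.

The statistical unit follows the published design: per-structure measures are
reduced to a median per mouse, and group statistics are the mean and SD of
those per-mouse medians (n = number of mice, typically 3).  Group comparisons
use one-way ANOVA with post-hoc Tukey HSD; distance-from-soma gradients use
Pearson correlation over per-image values binned in 20 um steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "RegionSummary",
    "GradientResult",
    "summarise_region",
    "compare_regions",
    "gradient_analysis",
    "subtype_consistency_report",
]

REGION_LABELS = ("CA1SO", "CA1SRP", "CA1SRD", "CA3SO", "CA3SL", "DGML", "DGPL")
SUBTYPES = ("1NC", "2NC", "3+NC")


@dataclass
class RegionSummary:
    region_label: str
    measure: str
    per_mouse_medians: dict[str, float]
    group_mean: float
    group_sd: float
    n_mice: int
    n_structures: int
    subtype_fractions: dict[str, float] = field(default_factory=dict)
    subtype_fraction_sd: dict[str, float] = field(default_factory=dict)
    single_mouse: bool = False


@dataclass
class GradientResult:
    distance_bins: np.ndarray   # bin centres, um
    bin_means: np.ndarray
    pearson_r: float
    p_value: float
    observation_level: str = "image"


def summarise_region(records: pd.DataFrame, measure: str,
                     region_label: str = "custom",
                     mouse_col: str = "mouse",
                     subtype_col: str = "subtype") -> RegionSummary:
    """Per-mouse median -> across-mouse mean +/- SD for one measure.

    ``records`` holds one structure per row with at least ``mouse_col`` and
    ``measure`` columns.  Subtype fractions, when a subtype column is present,
    are computed per mouse then averaged, with the across-mouse SD.
    A single-mouse summary reports SD 0 and sets ``single_mouse``.
    """
    if mouse_col not in records.columns:
        raise ValueError(f"records lack a '{mouse_col}' column")
    if measure not in records.columns:
        raise ValueError(f"records lack measure column '{measure}'")
    medians: dict[str, float] = {}
    for mouse, grp in records.groupby(mouse_col, sort=True):
        if len(grp) == 0 or grp[measure].dropna().empty:
            raise ValueError(f"mouse '{mouse}' has no usable '{measure}' values")
        medians[str(mouse)] = float(grp[measure].median())
    if not medians:
        raise ValueError("no mouse groups present")
    vals = np.array(list(medians.values()))
    single = len(vals) == 1
    subtype_fracs: dict[str, float] = {}
    subtype_sd: dict[str, float] = {}
    if subtype_col in records.columns:
        per_mouse = []
        for mouse, grp in records.groupby(mouse_col, sort=True):
            counts = grp[subtype_col].value_counts()
            total = counts.sum()
            per_mouse.append({s: 100.0 * counts.get(s, 0) / total for s in SUBTYPES})
        for s in SUBTYPES:
            f = np.array([pm[s] for pm in per_mouse])
            subtype_fracs[s] = float(f.mean())
            subtype_sd[s] = 0.0 if single else float(f.std(ddof=1))
    return RegionSummary(
        region_label=region_label,
        measure=measure,
        per_mouse_medians=medians,
        group_mean=float(vals.mean()),
        group_sd=0.0 if single else float(vals.std(ddof=1)),
        n_mice=len(vals),
        n_structures=int(len(records)),
        subtype_fractions=subtype_fracs,
        subtype_fraction_sd=subtype_sd,
        single_mouse=single,
    )


def compare_regions(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA with post-hoc Tukey HSD over per-mouse group values.

    Returns ``{"F", "p", "tukey": {(a, b): p_adj}}``.  Every group needs at
    least two values.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=np.float64)
        if v.size < 2:
            raise ValueError(f"group '{name}' has fewer than 2 values")
        arrays[name] = v
    f_stat, p = stats.f_oneway(*arrays.values())
    flat = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[name] * len(v) for name, v in arrays.items()])
    tk = pairwise_tukeyhsd(flat, labels)
    pairs = {}
    res = tk.summary().data[1:]
    for row in res:
        pairs[(str(row[0]), str(row[1]))] = float(row[3])
    return {"F": float(f_stat), "p": float(p), "tukey": pairs}


def gradient_analysis(records: pd.DataFrame, measure: str,
                      distance_col: str = "distance_um",
                      image_col: str = "image",
                      bin_width_um: float = 20.0,
                      bin_range_um: tuple[float, float] = (20.0, 140.0),
                      observation_level: str = "image") -> GradientResult:
    """Pearson correlation of a measure with distance from the soma layer.

    Structures are binned in ``bin_width_um`` steps over ``bin_range_um``
    (default seven 20 um steps, 20-140 um).  With ``observation_level =
    'image'`` the correlated observations are per-image means (each image
    paired with its bin distance); with ``'bin'`` they are the per-bin means.
    """
    lo, hi = bin_range_um
    edges = np.arange(lo - bin_width_um / 2.0, hi + bin_width_um, bin_width_um)
    centres = 0.5 * (edges[:-1] + edges[1:])
    d = records[distance_col].to_numpy(dtype=np.float64)
    which = np.searchsorted(edges, d, side="right") - 1
    ok = (which >= 0) & (which < len(centres))
    sub = records.loc[ok].copy()
    sub["_bin"] = centres[which[ok]]
    populated = sub["_bin"].nunique()
    if populated < 3:
        raise ValueError(f"only {populated} distance bins populated; need >= 3")
    bin_means = sub.groupby("_bin")[measure].mean()
    if observation_level == "image":
        if image_col not in sub.columns:
            raise ValueError(f"records lack an '{image_col}' column")
        obs = sub.groupby([image_col, "_bin"])[measure].mean().reset_index()
        x = obs["_bin"].to_numpy()
        y = obs[measure].to_numpy()
    elif observation_level == "bin":
        x = bin_means.index.to_numpy()
        y = bin_means.to_numpy()
    else:
        raise ValueError("observation_level must be 'image' or 'bin'")
    if np.std(y) == 0 or np.std(x) == 0:
        r, p = 0.0, 1.0
    else:
        r, p = stats.pearsonr(x, y)
    full_centres = centres
    full_means = np.array([bin_means.get(c, np.nan) for c in full_centres])
    return GradientResult(distance_bins=full_centres, bin_means=full_means,
                          pearson_r=float(r), p_value=float(p),
                          observation_level=observation_level)


def subtype_consistency_report(per_subtype_diameters,
                               subtype_fractions) -> float:
    """Fraction-weighted mean structure diameter across synapse subtypes.

    Weights are normalised by their sum; the result is rounded to the nearest
    nm.  Checks the arithmetic consistency between per-subtype diameters,
    their population fractions, and the whole-population value.
    """
    d = np.asarray(per_subtype_diameters, dtype=np.float64)
    f = np.asarray(subtype_fractions, dtype=np.float64)
    if d.shape != f.shape:
        raise ValueError("diameters and fractions must have equal length")
    if (f < 0).any():
        raise ValueError("fractions must be non-negative")
    if f.sum() == 0:
        raise ValueError("fractions sum to zero")
    return float(np.round(np.sum(d * f) / f.sum()))
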