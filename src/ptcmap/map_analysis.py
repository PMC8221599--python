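"""Gradient projection and map-level correlation / group statistics.

The unit of analysis for group tests is the hemisphere: per-hemisphere
correlations are Fisher z-converted and tested against zero with a
one-sample t test (two-sided p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr, ttest_1samp, ttest_rel

__all__ = [
    "SurfaceROI",
    "GroupStat",
    "axis_positions",
    "map_correlations",
    "group_ttest",
    "split_compare",
    "permutation_median_diff",
]


@dataclass
class SurfaceROI:
    """A set of surface vertices with a posterior-anterior reference axis."""

    vertex_ids: np.ndarray
    coordinates: np.ndarray  # (V, 3) mm
    hemisphere: str
    axis_start: np.ndarray  # posterior end
    axis_end: np.ndarray  # anterior end

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.axis_start = np.asarray(self.axis_start, dtype=float)
        self.axis_end = np.asarray(self.axis_end, dtype=float)
        if self.coordinates.shape[0] < 3:
            raise ValueError("SurfaceROI requires at least 3 vertices")
        if np.allclose(self.axis_start, self.axis_end):
            raise ValueError("degenerate axis: start equals end")


def axis_positions(roi: SurfaceROI) -> np.ndarray:
    """Project vertex positions onto the posterior-anterior axis, min-max to [0, 1]."""
    direction = roi.axis_end - roi.axis_start
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("degenerate axis: start equals end")
    proj = (roi.coordinates - roi.axis_start) @ (direction / norm)
    span = proj.max() - proj.min()
    if span == 0:
        raise ValueError("all vertices project to a single point on the axis")
    return (proj - proj.min()) / span


@dataclass
class GroupStat:
    per_hemisphere_r: np.ndarray
    fisher_z: np.ndarray
    t_value: float
    df: int
    p_two_sided: float
    method: str = "pearson"
    restriction: str | None = None
    excluded: int = 0


#: Supported correlation specifications: each maps a VertexTuningPair table
#: (columns below) to an (x, y) pair of columns.
_CORR_SPECS = {
    "sigma_vs_axis_spatial": ("axis_position", "spatial_sigma"),
    "sigma_vs_axis_face": ("axis_position", "face_sigma"),
    "mu_cross_map": ("spatial_mu", "face_mu"),
    "sigma_cross_map": ("spatial_sigma", "face_sigma"),
    "sigma_vs_eccentricity_spatial": ("spatial_ecc", "spatial_sigma"),
    "sigma_vs_eccentricity_face": ("face_ecc", "face_sigma"),
}

REQUIRED_COLUMNS = (
    "hemisphere",
    "axis_position",
    "spatial_mu",
    "spatial_sigma",
    "spatial_r2",
    "face_mu",
    "face_sigma",
    "face_r2",
)


def _qualify(table: pd.DataFrame, r2_threshold: float, restricted: bool) -> pd.DataFrame:
    mask = (table["spatial_r2"] > r2_threshold) & (table["face_r2"] > r2_threshold)
    if restricted:  # control: drop broad tuning and peaks outside the mapped area
        for dom in ("spatial", "face"):
            mask &= table[f"{dom}_sigma"] < 1.0
            mask &= (table[f"{dom}_mu"] > 0.0) & (table[f"{dom}_mu"] < 1.0)
    return table[mask]


def map_correlations(
    table: pd.DataFrame,
    spec: str,
    r2_threshold: float = 0.3,
    method: str = "pearson",
    restricted: bool = False,
) -> dict[str, float]:
    """Per-hemisphere correlation over threshold-passing vertices.

    ``spec`` selects the variable pair (see module source); ``restricted``
    applies the sigma < 1 and 0 < mu < 1 range restriction. Hemispheres
    with fewer than 3 qualifying vertices are omitted with a warning.
    """
    if spec not in _CORR_SPECS:
        raise ValueError(f"unknown correlation spec: {spec!r} (choose from {sorted(_CORR_SPECS)})")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method: {method!r}")
    xcol, ycol = _CORR_SPECS[spec]
    table = table.copy()
    for dom in ("spatial", "face"):
        table[f"{dom}_ecc"] = (table[f"{dom}_mu"] - 0.5).abs()
    selected = _qualify(table, r2_threshold, restricted)
    corr_fn = pearsonr if method == "pearson" else spearmanr
    out: dict[str, float] = {}
    for hemi in sorted(table["hemisphere"].unique()):
        sub = selected[selected["hemisphere"] == hemi]
        if len(sub) < 3:
            warnings.warn(
                f"hemisphere {hemi!r}: fewer than 3 qualifying vertices, omitted",
                RuntimeWarning, stacklevel=2,
            )
            continue
        r = corr_fn(sub[xcol].to_numpy(), sub[ycol].to_numpy())[0]
        out[str(hemi)] = float(r)
    return out


def group_ttest(per_hemisphere_r, method: str = "pearson",
                restriction: str | None = None) -> GroupStat:
    """Fisher-z one-sample t test of per-hemisphere correlations against zero."""
    if isinstance(per_hemisphere_r, dict):
        r = np.asarray(list(per_hemisphere_r.values()), dtype=float)
    else:
        r = np.asarray(per_hemisphere_r, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 hemispheres")
    finite = np.abs(r) < 1.0
    excluded = int((~finite).sum())
    if excluded:
        warnings.warn(
            f"{excluded} correlation(s) with |r| = 1 excluded (infinite Fisher z)",
            RuntimeWarning, stacklevel=2,
        )
    r = r[finite]
    if r.size < 2:
        raise ValueError("fewer than 2 usable hemispheres after exclusion")
    z = np.arctanh(r)
    if np.allclose(z, z[0]):
        raise ValueError("zero variance: all Fisher-z values identical")
    res = ttest_1samp(z, 0.0)
    return GroupStat(
        per_hemisphere_r=r,
        fisher_z=z,
        t_value=float(res.statistic),
        df=r.size - 1,
        p_two_sided=float(res.pvalue),
        method=method,
        restriction=restriction,
        excluded=excluded,
    )


def permutation_median_diff(
    r2_a: np.ndarray,
    r2_b: np.ndarray,
    n_permutations: int = 10_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation test of the difference of medians between two R2 samples.

    Pools the values, permutes group assignment, and reports the observed
    difference of medians (a - b) and the proportion of permuted absolute
    differences that are >= the observed absolute difference.
    """
    rng = np.random.default_rng() if rng is None else rng
    r2_a = np.asarray(r2_a, dtype=float)
    r2_b = np.asarray(r2_b, dtype=float)
    observed = float(np.median(r2_a) - np.median(r2_b))
    pooled = np.concatenate([r2_a, r2_b])
    n_a = r2_a.size
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        diff = np.median(perm[:n_a]) - np.median(perm[n_a:])
        if abs(diff) >= abs(observed):
            count += 1
    return observed, count / n_permutations


@dataclass
class SplitComparison:
    per_hemisphere_height_diff: dict[str, float]
    height_t: float
    height_df: int
    height_p: float
    median_r2_a: float
    median_r2_b: float
    r2_diff: float
    permutation_p: float
    n_permutations: int = field(default=10_000)


def split_compare(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    mu_column: str,
    r2_column: str,
    n_permutations: int = 10_000,
    rng: np.random.Generator | None = None,
) -> SplitComparison:
    """Compare paired sub-condition fits (e.g. eye- vs mouth-stimulus runs).

    Peak height is reported as 0.5 - mu (positive = higher in the mapped
    space); per-hemisphere median height differences are tested across
    hemispheres with a one-sample t test. Goodness of fit is compared via
    a permutation test on the pooled R-squared values.
    """
    if len(table_a) != len(table_b):
        raise ValueError("mismatched vertex sets between sub-conditions")
    if not np.array_equal(table_a["hemisphere"].to_numpy(), table_b["hemisphere"].to_numpy()):
        raise ValueError("mismatched vertex sets: hemisphere labels differ")

    height_a = 0.5 - table_a[mu_column].to_numpy()
    height_b = 0.5 - table_b[mu_column].to_numpy()
    hemis = table_a["hemisphere"].to_numpy()
    per_hemi: dict[str, float] = {}
    med_a, med_b = [], []
    for hemi in pd.unique(hemis):
        sel = hemis == hemi
        ma = float(np.median(height_a[sel]))
        mb = float(np.median(height_b[sel]))
        per_hemi[str(hemi)] = ma - mb
        med_a.append(ma)
        med_b.append(mb)
    res = ttest_rel(med_a, med_b)

    r2_a = table_a[r2_column].to_numpy()
    r2_b = table_b[r2_column].to_numpy()
    observed, p_perm = permutation_median_diff(r2_a, r2_b, n_permutations, rng)
    return SplitComparison(
        per_hemisphere_height_diff=per_hemi,
        height_t=float(res.statistic),
        height_df=len(med_a) - 1,
        height_p=float(res.pvalue),
        median_r2_a=float(np.median(r2_a)),
        median_r2_b=float(np.median(r2_b)),
        r2_diff=observed,
        permutation_p=p_perm,
        n_permutations=n_permutations,
    )
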