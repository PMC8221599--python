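"""Ground-truth tuning maps and simulated BOLD runs with known structure.

Cohorts carry the statistical structure the analysis assumes: axis
positions uniform on [0, 1], log2 tuning width linear in axis position
(correlated between the spatial and face domains), peak preferences drawn
from a central-space-biased distribution with a specified cross-domain
correlation, and additive per-run measurement noise. Everything is
reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hrf_model import CANONICAL_HRF, HRFParams, convolve_prediction, double_gamma_kernel
from .preprocessing import VertexTimeSeries, preprocess_runs
from .stimulus_design import RunDesign, build_aperture
from .tuning_fit import SIGMA_BOUNDS, neural_time_course

__all__ = [
    "GradientSpec",
    "CrossCorrSpec",
    "GroundTruth",
    "make_ground_truth",
    "simulate_runs",
    "simulate_dataset",
    "simulate_null",
    "calibrate_noise_sd",
]


@dataclass(frozen=True)
class GradientSpec:
    """Linear dependence of log2 sigma on axis position, plus jitter."""

    slope: float = 2.0  # log2 units over the full axis
    intercept: float = -3.0  # log2 sigma at the posterior end
    jitter_sd: float = 0.4
    domain_corr: float = 0.7  # correlation of the jitter across domains
    slope_jitter_sd: float = 0.2  # per-hemisphere slope variation


@dataclass(frozen=True)
class CrossCorrSpec:
    """Peak-preference distribution and its cross-domain correlation."""

    mu_center: float = 0.5
    mu_sd: float = 0.2
    r: float = 0.3

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("infeasible correlation spec: |r| > 1")


@dataclass
class GroundTruth:
    table: pd.DataFrame  # per-vertex truth
    hrf: HRFParams
    noise_model: str  # {'white', 'ar1'}
    ar1_rho: float
    noise_sd: float
    n_runs: int
    seed: int
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)


def _correlated_pair(rng, n, r):
    a = rng.standard_normal(n)
    b = r * a + np.sqrt(max(0.0, 1.0 - r**2)) * rng.standard_normal(n)
    return a, b


def make_ground_truth(
    n_vertices: int = 500,
    n_hemispheres: int = 4,
    gradient_spec: GradientSpec | None = None,
    cross_corr_spec: CrossCorrSpec | None = None,
    seed: int = 0,
    hrf: HRFParams = CANONICAL_HRF,
    noise_model: str = "white",
    ar1_rho: float = 0.3,
    noise_sd: float = 1.0,
    n_runs: int = 17,
) -> GroundTruth:
    """Draw a seeded cohort of per-vertex true tuning parameters.

    ``n_vertices`` is the total count, split evenly across hemispheres
    (at least 10 per hemisphere).
    """
    if n_vertices < 10 * n_hemispheres:
        raise ValueError("need at least 10 vertices per hemisphere")
    gspec = gradient_spec or GradientSpec()
    cspec = cross_corr_spec or CrossCorrSpec()
    rng = np.random.default_rng(seed)

    per_hemi = np.full(n_hemispheres, n_vertices // n_hemispheres)
    per_hemi[: n_vertices % n_hemispheres] += 1

    rows = []
    lo, hi = np.log2(SIGMA_BOUNDS[0]), np.log2(SIGMA_BOUNDS[1])
    for h in range(n_hemispheres):
        n = int(per_hemi[h])
        axis = rng.uniform(0.0, 1.0, n)
        slope = gspec.slope + gspec.slope_jitter_sd * rng.standard_normal()
        j_sp, j_fa = _correlated_pair(rng, n, gspec.domain_corr)
        log2_sigma_sp = gspec.intercept + slope * axis + gspec.jitter_sd * j_sp
        log2_sigma_fa = gspec.intercept + slope * axis + gspec.jitter_sd * j_fa
        m_sp, m_fa = _correlated_pair(rng, n, cspec.r)
        mu_sp = np.clip(cspec.mu_center + cspec.mu_sd * m_sp, 0.0, 1.0)
        mu_fa = np.clip(cspec.mu_center + cspec.mu_sd * m_fa, 0.0, 1.0)
        rows.append(
            pd.DataFrame(
                {
                    "vertex_id": np.arange(n),
                    "hemisphere": f"hemi{h:02d}",
                    "axis_position": axis,
                    "spatial_mu": mu_sp,
                    "spatial_sigma": 2.0 ** np.clip(log2_sigma_sp, lo, hi),
                    "face_mu": mu_fa,
                    "face_sigma": 2.0 ** np.clip(log2_sigma_fa, lo, hi),
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    table["vertex_id"] = np.arange(len(table))
    return GroundTruth(
        table=table,
        hrf=hrf,
        noise_model=noise_model,
        ar1_rho=ar1_rho,
        noise_sd=noise_sd,
        n_runs=n_runs,
        seed=seed,
    )


def _noise(rng, shape, model, rho):
    eps = rng.standard_normal(shape)
    if model == "white":
        return eps
    if model == "ar1":
        out = np.empty_like(eps)
        out[0] = eps[0]
        scale = np.sqrt(1.0 - rho**2)
        for t in range(1, shape[0]):
            out[t] = rho * out[t - 1] + scale * eps[t]
        return out
    raise ValueError(f"unknown noise model: {model!r}")


def simulate_runs(
    truth: GroundTruth,
    design: RunDesign,
    condition: str,
    rng: np.random.Generator,
    signal_amplitude: float = 1.0,
    n_bins: int = 200,
) -> list[np.ndarray]:
    """Raw runs (total_volumes x V) for one condition: signal + per-run noise."""
    aperture = build_aperture(design, n_bins=n_bins)
    mu = truth.table[f"{condition}_mu"].to_numpy()
    sigma = truth.table[f"{condition}_sigma"].to_numpy()
    neural = neural_time_course(mu, sigma, aperture)  # (V, T_active)
    kernel = double_gamma_kernel(truth.hrf, design.tr)
    bold = convolve_prediction(neural, kernel, design.tr)  # (V, T_active)
    # unit-SD signal so noise_sd is directly the per-run noise/signal ratio
    sd = bold.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    signal = signal_amplitude * bold / sd

    n_v, t_active = signal.shape
    total = design.total_volumes
    runs = []
    for _ in range(truth.n_runs):
        run = np.zeros((total, n_v))
        run[design.n_dummy :] = signal.T
        run += truth.noise_sd * _noise(rng, (total, n_v), truth.noise_model, truth.ar1_rho)
        runs.append(run)
    return runs


def simulate_dataset(
    truth: GroundTruth,
    designs: dict[str, RunDesign],
    signal_amplitude: float = 1.0,
    n_bins: int = 200,
    return_raw: bool = False,
):
    """Preprocessed series per condition for a ground-truth cohort.

    ``designs`` maps condition name ('spatial', 'face') to its RunDesign.
    Returns {condition: VertexTimeSeries}; with ``return_raw`` also the
    raw runs.
    """
    if not designs:
        raise ValueError("designs for at least one condition required")
    rng = np.random.default_rng(truth.seed + 1)
    out: dict[str, VertexTimeSeries] = {}
    raw_out: dict[str, list[np.ndarray]] = {}
    for condition, design in designs.items():
        runs = simulate_runs(truth, design, condition, rng, signal_amplitude, n_bins)
        out[condition] = preprocess_runs(runs, design, condition=condition)
        if return_raw:
            raw_out[condition] = runs
    if return_raw:
        return out, raw_out
    return out


def simulate_null(
    n_series: int,
    design: RunDesign,
    n_runs: int = 17,
    noise_model: str = "white",
    ar1_rho: float = 0.3,
    seed: int = 0,
) -> VertexTimeSeries:
    """Signal-free noise series passed through the identical preprocessing."""
    if n_series < 1:
        raise ValueError("n_series must be >= 1")
    rng = np.random.default_rng(seed)
    runs = [
        _noise(rng, (design.total_volumes, n_series), noise_model, ar1_rho)
        for _ in range(n_runs)
    ]
    return preprocess_runs(runs, design, condition="null")


def calibrate_noise_sd(
    target_median_r2: float,
    design: RunDesign,
    fit_fn,
    seed: int = 0,
    n_vertices: int = 100,
    n_hemispheres: int = 4,
    bracket: tuple[float, float] = (0.5, 30.0),
    tol: float = 0.02,
    max_iter: int = 12,
    **truth_kwargs,
) -> float:
    """Bisection on the per-run noise SD to hit a target median fit R-squared.

    ``fit_fn(series_matrix, design) -> r2 array`` runs the fitting pipeline
    on the preprocessed (T, V) series. Median R2 decreases monotonically in
    noise SD, so simple bisection suffices.
    """
    lo, hi = bracket

    def median_r2(noise_sd: float) -> float:
        truth = make_ground_truth(
            n_vertices=n_vertices, n_hemispheres=n_hemispheres, seed=seed,
            noise_sd=noise_sd, **truth_kwargs,
        )
        data = simulate_dataset(truth, {design.kind: design})
        r2 = fit_fn(data[design.kind].values, design)
        return float(np.median(r2))

    if median_r2(lo) < target_median_r2:
        return lo
    if median_r2(hi) > target_median_r2:
        return hi
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        m = median_r2(mid)
        if abs(m - target_median_r2) < tol:
            return mid
        if m > target_median_r2:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))
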