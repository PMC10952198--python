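"""Cramér-Rao bound for SPGR T1 mapping with B1+ map noise propagation.

The T1 estimate from a variable-flip-angle SPGR fit is bounded below by the
(T1, T1) element of the inverse Fisher information matrix for the parameter
vector theta = (M0, T1),

    F[k, j] = sum_i (1 / sigma_i^2) (dS_i/dtheta_k) (dS_i/dtheta_j),

where the total per-measurement noise variance carries two contributions —
the SPGR image noise and the uncertainty propagated from the B1+ map:

    sigma_i^2 = sigma_SPGR^2
              + (dS_i/dalpha_true * alpha_nominal[rad] * sigma_B1)^2 .

The bound is summarized as a coefficient of variation,
``COV = 100 * sqrt([F^-1]_T1,T1) / T1``, and the design criterion is its
worst case over a (T1, B1+) parameter grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spgr_model import NoiseSpec, SPGRSettings, TissueParams, spgr_partials

__all__ = [
    "ParamSpace",
    "FisherResult",
    "total_noise_variance",
    "fisher_matrix",
    "t1_cov_percent",
    "worst_case_cov",
    "pooled_weighted_variance",
]

#: Condition number above which the 2x2 Fisher matrix is treated as singular.
SINGULAR_CONDITION = 1e12


@dataclass(frozen=True)
class ParamSpace:
    """(T1, B1+) grid over which the worst-case COV is taken."""

    t1_grid_ms: tuple[float, ...]
    b1_grid: tuple[float, ...]

    def __post_init__(self) -> None:
        t1 = tuple(float(v) for v in self.t1_grid_ms)
        b1 = tuple(float(v) for v in self.b1_grid)
        if not t1 or not b1:
            raise ValueError("parameter grids must be non-empty")
        if any(np.diff(t1) <= 0) or any(np.diff(b1) <= 0):
            raise ValueError("parameter grids must be strictly ascending")
        if any(v <= 0 for v in t1 + b1):
            raise ValueError("parameter grids must be positive")
        object.__setattr__(self, "t1_grid_ms", t1)
        object.__setattr__(self, "b1_grid", b1)

    @classmethod
    def liver_3t(
        cls,
        t1_min_ms: float = 700.0,
        t1_max_ms: float = 1200.0,
        t1_step_ms: float = 100.0,
        b1_min: float = 0.59,
        b1_max: float = 1.14,
        b1_step: float = 0.05,
    ) -> "ParamSpace":
        """Liver parameter space at 3T: T1 700-1200 ms, B1+ factor 0.59-1.14."""
        t1 = np.round(np.arange(t1_min_ms, t1_max_ms + t1_step_ms / 2, t1_step_ms), 6)
        b1 = np.round(np.arange(b1_min, b1_max + b1_step / 2, b1_step), 6)
        return cls(tuple(t1), tuple(b1))


@dataclass(frozen=True)
class FisherResult:
    """2x2 Fisher information for theta = (M0, T1) and the derived T1 bound."""

    matrix: np.ndarray
    t1_variance: float
    t1_cov_percent: float
    singular: bool = False


def total_noise_variance(
    fa_nominal_deg,
    b1_factor: float,
    t1_ms: float,
    m0: float,
    tr_ms: float,
    noise: NoiseSpec,
):
    """Total per-measurement noise variance sigma_i^2 (vectorized over FAs).

    The B1+ contribution converts the factor uncertainty into a true-FA
    uncertainty of ``alpha_nominal[rad] * sigma_b1`` and scales it by the
    signal's flip-angle sensitivity at the true FA; it vanishes at the Ernst
    angle, where the signal is stationary in alpha.
    """
    fa_nom = np.asarray(fa_nominal_deg, dtype=float)
    _, _, ds_da = spgr_partials(b1_factor * fa_nom, tr_ms, t1_ms, m0)
    out = noise.sigma_spgr**2 + (ds_da * np.deg2rad(fa_nom) * noise.sigma_b1) ** 2
    return out if np.ndim(out) else float(out)


def _fisher_terms(scheme: SPGRSettings, tissue: TissueParams, noise: NoiseSpec):
    fa_nom = np.asarray(scheme.nominal_fas_deg, dtype=float)
    fa_true = tissue.b1_factor * fa_nom
    ds_dm0, ds_dt1, _ = spgr_partials(fa_true, scheme.tr_ms, tissue.t1_ms, scheme.m0)
    sig2 = total_noise_variance(fa_nom, tissue.b1_factor, tissue.t1_ms,
                                scheme.m0, scheme.tr_ms, noise)
    w = 1.0 / sig2
    f11 = float(np.sum(w * ds_dm0 * ds_dm0))
    f12 = float(np.sum(w * ds_dm0 * ds_dt1))
    f22 = float(np.sum(w * ds_dt1 * ds_dt1))
    return f11, f12, f22


def fisher_matrix(
    scheme: SPGRSettings, tissue: TissueParams, noise: NoiseSpec
) -> FisherResult:
    """Fisher information matrix and CRLB T1 variance for one design point.

    A singular or near-singular matrix (condition number above ``1e12``,
    e.g. a single distinct flip angle for two unknowns) is flagged and
    reported as infinite T1 variance rather than raising.
    """
    f11, f12, f22 = _fisher_terms(scheme, tissue, noise)
    mat = np.array([[f11, f12], [f12, f22]])
    det = f11 * f22 - f12 * f12
    # closed-form 2x2 spectral condition number
    tr_half = 0.5 * (f11 + f22)
    disc = np.sqrt(max(tr_half**2 - det, 0.0))
    lam_max, lam_min = tr_half + disc, tr_half - disc
    singular = (det <= 0) or (lam_min <= 0) or (lam_max / lam_min > SINGULAR_CONDITION)
    if singular:
        return FisherResult(mat, np.inf, np.inf, True)
    t1_var = f11 / det
    cov = 100.0 * np.sqrt(t1_var) / tissue.t1_ms
    return FisherResult(mat, t1_var, cov, False)


def t1_cov_percent(
    scheme: SPGRSettings, tissue: TissueParams, noise: NoiseSpec
) -> float:
    """CRLB T1 coefficient of variation, percent: 100 sqrt(var(T1)) / T1."""
    return fisher_matrix(scheme, tissue, noise).t1_cov_percent


def worst_case_cov(
    scheme: SPGRSettings, space: ParamSpace, noise: NoiseSpec
) -> tuple[float, float, float]:
    """Maximum CRLB T1 COV over the parameter grid and its location.

    Returns ``(cov_percent, argmax_t1_ms, argmax_b1)``.  Ties resolve to the
    first grid point in (T1 ascending, B1+ ascending) order.
    """
    worst = (-np.inf, np.nan, np.nan)
    for t1 in space.t1_grid_ms:
        for b1 in space.b1_grid:
            cov = t1_cov_percent(scheme, TissueParams(t1, b1), noise)
            if cov > worst[0]:
                worst = (cov, t1, b1)
    return worst


def pooled_weighted_variance(roi_means, roi_variances, weights) -> float:
    """Weighted pooled variance across ROIs (within + between components).

    ``sum_r w_r * (sigma_r^2 + (mu_r - mu_w)^2)`` with weights normalized to
    sum to one and ``mu_w`` the weighted mean of the ROI means.
    """
    mu = np.asarray(roi_means, dtype=float)
    var = np.asarray(roi_variances, dtype=float)
    w = np.asarray(weights, dtype=float)
    if mu.size == 0 or mu.shape != var.shape or mu.shape != w.shape:
        raise ValueError("roi_means, roi_variances, weights must be equal-length "
                         "and non-empty")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    mu_w = float(np.sum(w * mu))
    return float(np.sum(w * (var + (mu - mu_w) ** 2)))
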