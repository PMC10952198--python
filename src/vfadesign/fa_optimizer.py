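"""Min-max flip-angle optimization for variable-flip-angle SPGR T1 mapping.

The design criterion is the worst-case CRLB T1 coefficient of variation over
a (T1, B1+) parameter space; the search is exhaustive over integer-degree
flip-angle multisets (Fisher information is additive and order-free, so only
combinations with repetition need enumerating).  Also provides the
acquisition-budget trade-off (extra SPGR acquisitions vs extra B1+ mapping
flip angles) and the classic two-angle reference design in which both angles
give 0.71 of the Ernst-angle signal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .crlb import ParamSpace, worst_case_cov
from .spgr_model import (
    NoiseSpec,
    SPGRSettings,
    ernst_angle_deg,
    sigma_from_snr,
    spgr_partials,
    spgr_signal,
)

__all__ = [
    "FASearchSpec",
    "BudgetSpec",
    "optimize_fas",
    "evaluate_fa_set",
    "budget_tradeoff",
    "deoni_angles",
]


@dataclass(frozen=True)
class FASearchSpec:
    """Exhaustive-search space: number of acquisitions and integer FA bounds."""

    n_fas: int
    fa_min_deg: int = 1
    fa_max_deg: int = 15
    allow_repeats: bool = True

    def __post_init__(self) -> None:
        if not 2 <= self.n_fas <= 8:
            raise ValueError("n_fas must be between 2 and 8")
        if self.fa_min_deg < 1 or self.fa_max_deg <= self.fa_min_deg:
            raise ValueError("need 1 <= fa_min_deg < fa_max_deg")
        n_values = self.fa_max_deg - self.fa_min_deg + 1
        if not self.allow_repeats and self.n_fas > n_values:
            raise ValueError("more acquisitions than distinct FAs with "
                             "allow_repeats=False")


@dataclass(frozen=True)
class BudgetSpec:
    """Acquisition-budget grid: SPGR counts vs B1+ mapping FA counts.

    ``b1_sd_by_count`` maps the number of B1+ mapping flip angles to the
    resulting B1+ factor SD (averaging repeated B1+ acquisitions reduces the
    map noise; the default mapping is 2 FAs: 0.046, 4: 0.033, 6: 0.027).
    """

    spgr_counts: tuple[int, ...] = (2, 3, 4, 5)
    b1_fa_counts: tuple[int, ...] = (2, 4, 6)
    b1_sd_by_count: dict = field(
        default_factory=lambda: {2: 0.046, 4: 0.033, 6: 0.027})

    def __post_init__(self) -> None:
        missing = [n for n in self.b1_fa_counts if n not in self.b1_sd_by_count]
        if missing:
            raise ValueError(f"b1_sd_by_count missing entries for {missing}")


def _per_fa_fisher_tables(
    fa_values: np.ndarray,
    space: ParamSpace,
    tr_ms: float,
    m0: float,
    sigma_spgr: float,
    sigma_b1: float,
):
    """Per-candidate-FA Fisher contributions on the flattened parameter grid.

    Returns (A, B, C, t1_flat): each of shape (n_fa_values, n_grid) holding
    the weighted products dM0*dM0, dM0*dT1, dT1*dT1 of one acquisition at
    that FA, for every (T1, B1+) grid point.
    """
    t1g = np.asarray(space.t1_grid_ms)
    b1g = np.asarray(space.b1_grid)
    t1_flat = np.repeat(t1g, b1g.size)
    b1_flat = np.tile(b1g, t1g.size)

    fa_nom = fa_values[:, None]                      # (n_fa, 1)
    fa_true = b1_flat[None, :] * fa_nom              # (n_fa, n_grid)
    ds_dm0, ds_dt1, ds_da = spgr_partials(fa_true, tr_ms, t1_flat[None, :], m0)
    sig2 = sigma_spgr**2 + (ds_da * np.deg2rad(fa_nom) * sigma_b1) ** 2
    w = 1.0 / sig2
    return w * ds_dm0 * ds_dm0, w * ds_dm0 * ds_dt1, w * ds_dt1 * ds_dt1, t1_flat


def _batch_worst_cov(counts: np.ndarray, tables) -> np.ndarray:
    """Worst-case COV per candidate set given its FA-count matrix."""
    a_tab, b_tab, c_tab, t1_flat = tables
    f11 = counts @ a_tab
    f12 = counts @ b_tab
    f22 = counts @ c_tab
    det = f11 * f22 - f12 * f12
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = np.where(det > 0, 100.0 * np.sqrt(np.abs(f11 / det)) / t1_flat,
                       np.inf)
    return cov.max(axis=1)


def optimize_fas(
    spec: FASearchSpec,
    space: ParamSpace,
    tr_ms: float = 4.1,
    m0: float = 5000.0,
    snr: float = 12.5,
    sigma_b1: float = 0.046,
) -> tuple[tuple[int, ...], float]:
    """Exhaustive integer-degree min-max search for the optimal FA set.

    Enumerates all FA multisets of size ``spec.n_fas`` (combinations with
    repetition over ``fa_min_deg..fa_max_deg``), scores each by its
    worst-case CRLB T1 COV over ``space``, and returns the minimizing set
    (sorted ascending) with its worst-case COV in percent.  Ties (within
    1e-9 COV) resolve to the lexicographically smallest sorted set.

    ``snr`` is converted to an absolute noise SD at the standard reference
    point (true FA 2 deg, TR ``tr_ms``, T1 800 ms, M0 5000).
    """
    fa_values = np.arange(spec.fa_min_deg, spec.fa_max_deg + 1, dtype=float)
    sigma_spgr = sigma_from_snr(snr, tr_ms)
    tables = _per_fa_fisher_tables(fa_values, space, tr_ms, m0,
                                   sigma_spgr, sigma_b1)

    combine = (itertools.combinations_with_replacement if spec.allow_repeats
               else itertools.combinations)
    combos = np.array(list(combine(range(fa_values.size), spec.n_fas)))
    counts = np.zeros((combos.shape[0], fa_values.size))
    rows = np.repeat(np.arange(combos.shape[0]), spec.n_fas)
    np.add.at(counts, (rows, combos.ravel()), 1.0)

    worst = _batch_worst_cov(counts, tables)
    # combos are generated in lexicographic order, so the first strict
    # minimum is the lexicographically smallest optimal set
    best = int(np.argmin(np.where(worst <= worst.min() + 1e-9, worst, np.inf)))
    if not np.isfinite(worst[best]):
        raise ValueError("no invertible design in the search space")
    fa_set = tuple(int(fa_values[i]) for i in combos[best])
    return fa_set, float(worst[best])


def evaluate_fa_set(
    fa_set_deg,
    space: ParamSpace,
    tr_ms: float = 4.1,
    m0: float = 5000.0,
    snr: float = 12.5,
    sigma_b1: float = 0.046,
) -> float:
    """Worst-case CRLB T1 COV (percent) of a given FA set over the space."""
    sigma_spgr = sigma_from_snr(snr, tr_ms)
    scheme = SPGRSettings(tr_ms, m0, tuple(float(f) for f in fa_set_deg))
    noise = NoiseSpec(sigma_spgr, sigma_b1)
    return worst_case_cov(scheme, space, noise)[0]


def budget_tradeoff(
    budget: BudgetSpec,
    space: ParamSpace,
    tr_ms: float = 4.1,
    m0: float = 5000.0,
    snr: float = 25.0,
) -> pd.DataFrame:
    """Worst-case COV for every (SPGR count, B1+ FA count) budget cell.

    Each cell re-optimizes the SPGR FA set with the B1+ factor SD implied by
    that B1+ mapping budget, answering where an extra acquisition buys more
    T1 precision.
    """
    records = []
    for n_b1 in budget.b1_fa_counts:
        sigma_b1 = budget.b1_sd_by_count[n_b1]
        for n_spgr in budget.spgr_counts:
            fa_set, cov = optimize_fas(FASearchSpec(n_spgr), space, tr_ms, m0,
                                       snr, sigma_b1)
            records.append({"n_spgr": n_spgr, "n_b1": n_b1,
                            "sigma_b1": sigma_b1, "fa_set": fa_set,
                            "worst_cov_percent": cov})
    return pd.DataFrame.from_records(records)


def deoni_angles(
    tr_ms: float,
    t1_ms: float,
    fa_max_deg: float | None = None,
) -> tuple[float, float]:
    """The two flip angles giving 0.71 of the Ernst-angle signal.

    The classic two-point design places one angle on each side of the Ernst
    angle at the flip where the SPGR signal is 0.71 of its maximum; the
    result is independent of M0.  The upper root is capped at ``fa_max_deg``
    when given.
    """
    ernst = ernst_angle_deg(tr_ms, t1_ms)
    target = 0.71 * spgr_signal(ernst, tr_ms, t1_ms, 1.0)

    def offset(fa_deg: float) -> float:
        return spgr_signal(fa_deg, tr_ms, t1_ms, 1.0) - target

    lo = brentq(offset, 1e-9, ernst, xtol=1e-12)
    hi = brentq(offset, ernst, 180.0 - 1e-9, xtol=1e-12)
    if fa_max_deg is not None:
        hi = min(hi, float(fa_max_deg))
    return float(lo), float(hi)
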