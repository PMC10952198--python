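"""Spoiled-gradient-echo (SPGR) steady-state signal model.

The SPGR signal at flip angle ``alpha`` (the *true* angle exciting the
spins), repetition time ``TR`` and longitudinal relaxation time ``T1`` is

    S = M0 * (1 - E1) * sin(alpha) / (1 - E1 * cos(alpha)),   E1 = exp(-TR/T1)

with ``M0`` a lumped constant absorbing proton density, T2* decay at the
echo time and receive sensitivity.  All public interfaces take angles in
degrees (the acquisition convention); derivatives with respect to the flip
angle are returned per *radian*, which is the natural unit for error
propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SPGRSettings",
    "TissueParams",
    "NoiseSpec",
    "spgr_signal",
    "spgr_partials",
    "ernst_angle_deg",
    "sigma_from_snr",
]


@dataclass(frozen=True)
class SPGRSettings:
    """Nominal SPGR acquisition: repetition time, signal scale, flip angles.

    ``nominal_fas_deg`` may contain repeated values: repeating a flip angle
    is a legal (and, near the optimum, common) design.
    """

    tr_ms: float
    m0: float
    nominal_fas_deg: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ValueError(f"tr_ms must be positive, got {self.tr_ms}")
        if self.m0 <= 0:
            raise ValueError(f"m0 must be positive, got {self.m0}")
        fas = tuple(float(f) for f in self.nominal_fas_deg)
        if len(fas) == 0:
            raise ValueError("nominal_fas_deg must be non-empty")
        if any(not 0 < f < 180 for f in fas):
            raise ValueError("nominal flip angles must lie in (0, 180) degrees")
        object.__setattr__(self, "nominal_fas_deg", fas)


@dataclass(frozen=True)
class TissueParams:
    """Tissue/voxel parameters: T1 and the B1+ factor (true FA / nominal FA)."""

    t1_ms: float
    b1_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.t1_ms <= 0:
            raise ValueError(f"t1_ms must be positive, got {self.t1_ms}")
        if self.b1_factor <= 0:
            raise ValueError(f"b1_factor must be positive, got {self.b1_factor}")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise levels entering the total per-measurement variance.

    sigma_spgr : SD of the additive Gaussian noise on each SPGR measurement,
        in signal units (same scale as ``m0``).
    sigma_b1 : SD of the B1+ factor estimate (unitless, absolute — a value
        of 0.046 means an SD of 0.046 on a factor of order 1).
    """

    sigma_spgr: float
    sigma_b1: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_spgr < 0 or self.sigma_b1 < 0:
            raise ValueError("noise SDs must be non-negative")


def _check_positive(tr_ms, t1_ms) -> None:
    if np.any(np.asarray(tr_ms) <= 0):
        raise ValueError("tr_ms must be positive")
    if np.any(np.asarray(t1_ms) <= 0):
        raise ValueError("t1_ms must be positive")


def spgr_signal(fa_true_deg, tr_ms, t1_ms, m0):
    """Noiseless SPGR steady-state signal at the true flip angle (degrees).

    Vectorized over all arguments by broadcasting.
    """
    _check_positive(tr_ms, t1_ms)
    a = np.deg2rad(np.asarray(fa_true_deg, dtype=float))
    e1 = np.exp(-np.asarray(tr_ms, dtype=float) / np.asarray(t1_ms, dtype=float))
    out = m0 * (1.0 - e1) * np.sin(a) / (1.0 - e1 * np.cos(a))
    return out if out.ndim else float(out)


def spgr_partials(fa_true_deg, tr_ms, t1_ms, m0):
    """Analytic partial derivatives of the SPGR signal.

    Returns ``(dS_dM0, dS_dT1, dS_dalpha)`` where ``dS_dalpha`` is the
    sensitivity to the *true* flip angle, per radian.  ``dS_dM0 * m0``
    equals the signal exactly (the model is linear in M0).
    """
    _check_positive(tr_ms, t1_ms)
    a = np.deg2rad(np.asarray(fa_true_deg, dtype=float))
    tr = np.asarray(tr_ms, dtype=float)
    t1 = np.asarray(t1_ms, dtype=float)
    e1 = np.exp(-tr / t1)
    s, c = np.sin(a), np.cos(a)
    den = 1.0 - e1 * c

    ds_dm0 = (1.0 - e1) * s / den
    # dS/dE1 = m0 * s * (c - 1) / den^2 ;  dE1/dT1 = e1 * tr / t1^2
    ds_dt1 = m0 * s * (c - 1.0) / den**2 * e1 * tr / t1**2
    ds_dalpha = m0 * (1.0 - e1) * (c - e1) / den**2

    if np.ndim(ds_dm0) == 0:
        return float(ds_dm0), float(ds_dt1), float(ds_dalpha)
    return ds_dm0, ds_dt1, ds_dalpha


def ernst_angle_deg(tr_ms, t1_ms):
    """Flip angle (degrees) maximizing the SPGR signal: arccos(exp(-TR/T1))."""
    _check_positive(tr_ms, t1_ms)
    e1 = np.exp(-np.asarray(tr_ms, dtype=float) / np.asarray(t1_ms, dtype=float))
    out = np.rad2deg(np.arccos(e1))
    return out if out.ndim else float(out)


def sigma_from_snr(
    snr: float,
    tr_ms: float = 4.1,
    ref_t1_ms: float = 800.0,
    ref_m0: float = 5000.0,
    ref_fa_true_deg: float = 2.0,
) -> float:
    """Absolute SPGR noise SD implied by an SNR at a reference operating point.

    The SNR convention follows the liver protocol it was measured with: the
    reference signal is the SPGR signal at a *true* flip angle of 2 degrees,
    TR = 4.1 ms, T1 = 800 ms and M0 = 5000; the noise SD is that signal
    divided by the SNR.  All reference values can be overridden.
    """
    if snr <= 0:
        raise ValueError(f"snr must be positive, got {snr}")
    return spgr_signal(ref_fa_true_deg, tr_ms, ref_t1_ms, ref_m0) / snr
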