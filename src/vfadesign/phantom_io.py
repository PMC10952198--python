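"""Synthetic 3D phantom generation and NIfTI/CSV/JSON input-output.

The phantom emulates the liver imaging situation the design framework
targets: piecewise-constant T1 regions (ellipsoidal "tissue" compartments on
a background) in the 700-1200 ms range, a smooth second-order-polynomial B1+
factor field spanning 0.59-1.14 (transmit fields vary slowly in space), and
a positive M0 field.  A forward SPGR acquisition with additive Gaussian
noise at a prescribed SNR turns the phantom into multi-flip-angle volumes,
and :func:`fit_volume` closes the loop so end-to-end parameter recovery can
be tested without any external data.

All randomness flows through a counter-based generator keyed by the spec's
mandatory seed, so phantoms are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .crlb import total_noise_variance
from .spgr_model import NoiseSpec, sigma_from_snr, spgr_partials, spgr_signal
from .t1_fitting import T1_BOUNDS_MS, batched_fit

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "simulate_acquisition",
    "fit_volume",
    "save_nifti",
    "load_nifti",
    "save_sidecar",
    "load_sidecar",
    "save_table",
    "load_table",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Synthetic phantom description; the seed is mandatory."""

    seed: int
    shape: tuple[int, int, int] = (32, 32, 12)
    t1_range_ms: tuple[float, float] = (700.0, 1200.0)
    b1_range: tuple[float, float] = (0.59, 1.14)
    m0: float = 5000.0
    snr: float = 50.0
    sigma_b1_map_noise: float = 0.046
    n_regions: int = 4

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 4 for s in self.shape):
            raise ValueError("shape must be 3D with every dimension >= 4")
        lo, hi = self.t1_range_ms
        if not 0 < lo < hi:
            raise ValueError("t1_range_ms must be ascending and positive")
        blo, bhi = self.b1_range
        if not 0 < blo < bhi:
            raise ValueError("b1_range must be ascending and positive")
        if self.m0 <= 0:
            raise ValueError("m0 must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.sigma_b1_map_noise < 0:
            raise ValueError("sigma_b1_map_noise must be non-negative")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")


def generate_phantom(spec: PhantomSpec):
    """Deterministic ground-truth volumes ``(t1_vol, b1_vol, m0_vol)``.

    T1 is piecewise constant (background plus ellipsoidal regions with
    values drawn across the requested range); the B1+ field is a smooth
    random second-order polynomial rescaled to span the requested range
    exactly; M0 is the nominal scale with a mild smooth modulation.
    """
    rng = np.random.Generator(np.random.Philox(spec.seed))
    nx, ny, nz = spec.shape
    x, y, z = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), np.linspace(-1, 1, nz),
        indexing="ij",
    )

    t1_lo, t1_hi = spec.t1_range_ms
    t1_vol = np.full(spec.shape, rng.uniform(t1_lo, t1_hi))
    # region T1s spread across the range so recovery is tested everywhere
    region_t1 = np.linspace(t1_lo, t1_hi, spec.n_regions + 2)[1:-1]
    rng.shuffle(region_t1)
    for t1_val in region_t1:
        cx, cy, cz = rng.uniform(-0.55, 0.55, size=3)
        rx, ry, rz = rng.uniform(0.18, 0.4, size=3)
        mask = (((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2
                + ((z - cz) / rz) ** 2) <= 1.0
        t1_vol[mask] = t1_val

    # smooth low-order polynomial B1+ field, min-max normalized to the range
    coeffs = rng.standard_normal(9)
    raw = (coeffs[0] * x + coeffs[1] * y + coeffs[2] * z
           + coeffs[3] * x * y + coeffs[4] * x * z + coeffs[5] * y * z
           + coeffs[6] * x**2 + coeffs[7] * y**2 + coeffs[8] * z**2)
    lo, hi = spec.b1_range
    span = raw.max() - raw.min()
    if span <= 0:  # degenerate draw: flat field at mid-range
        b1_vol = np.full(spec.shape, 0.5 * (lo + hi))
    else:
        b1_vol = lo + (raw - raw.min()) * (hi - lo) / span

    m0_vol = spec.m0 * (1.0 + 0.05 * np.sin(np.pi * x) * np.cos(np.pi * y))
    return t1_vol, b1_vol, m0_vol


def simulate_acquisition(
    t1_vol: np.ndarray,
    b1_vol: np.ndarray,
    m0_vol: np.ndarray,
    nominal_fas_deg,
    tr_ms: float,
    snr: float,
    seed: int,
) -> list[np.ndarray]:
    """Forward SPGR volumes at each nominal FA with additive Gaussian noise.

    The noise SD follows the standard SNR convention (reference signal at a
    true FA of 2 degrees, T1 800 ms, M0 5000); ``snr = inf`` gives the
    noiseless forward model.
    """
    if not (t1_vol.shape == b1_vol.shape == m0_vol.shape):
        raise ValueError("t1_vol, b1_vol and m0_vol must have identical shapes")
    sigma = 0.0 if np.isinf(snr) else sigma_from_snr(snr, tr_ms)
    rng = np.random.Generator(np.random.Philox(seed))
    volumes = []
    for fa in nominal_fas_deg:
        clean = spgr_signal(b1_vol * fa, tr_ms, t1_vol, m0_vol)
        noisy = clean + sigma * rng.standard_normal(t1_vol.shape)
        volumes.append(noisy)
    return volumes


def _despot_init_batch(y: np.ndarray, fa_true: np.ndarray, tr_ms: float):
    """Vectorized DESPOT starting points for (n_vox, n_fa) signal arrays."""
    a = np.deg2rad(fa_true)
    xv = y / np.tan(a)
    yv = y / np.sin(a)
    xm = xv.mean(axis=1, keepdims=True)
    ym = yv.mean(axis=1, keepdims=True)
    denom = np.sum((xv - xm) ** 2, axis=1)
    num = np.sum((xv - xm) * (yv - ym), axis=1)
    slope = np.where(denom > 0, num / np.maximum(denom, 1e-300), np.nan)
    ok = np.isfinite(slope) & (slope > 0) & (slope < 1)
    slope_safe = np.where(ok, slope, 0.5)
    t1 = np.clip(-tr_ms / np.log(slope_safe), *T1_BOUNDS_MS)
    t1 = np.where(ok, t1, 800.0)
    m0 = (ym[:, 0] - slope_safe * xm[:, 0]) / (1.0 - slope_safe)
    fallback = np.abs(y).max(axis=1) / np.maximum(np.sin(a).max(axis=1), 1e-6)
    m0 = np.where(np.isfinite(m0) & (m0 > 0), m0, fallback)
    return m0, t1


def fit_volume(
    spgr_volumes,
    b1_vol: np.ndarray,
    nominal_fas_deg,
    tr_ms: float,
    noise: NoiseSpec,
):
    """Voxel-wise weighted NLLS (M0, T1) maps from multi-FA SPGR volumes.

    Returns ``(t1_map, m0_map, converged_map)``.  Residual weights use the
    total noise variance at each voxel's measured B1+ and its DESPOT-style
    initial T1 estimate.
    """
    fa_nom = np.asarray(nominal_fas_deg, dtype=float)
    vols = [np.asarray(v, dtype=float) for v in spgr_volumes]
    if len(vols) != fa_nom.size:
        raise ValueError("one SPGR volume per nominal FA is required")
    shape = vols[0].shape
    if any(v.shape != shape for v in vols) or b1_vol.shape != shape:
        raise ValueError("all volumes (SPGR and B1+) must share one shape")

    y = np.stack([v.ravel() for v in vols], axis=1)       # (n_vox, n_fa)
    b1 = b1_vol.ravel()
    fa_true = b1[:, None] * fa_nom[None, :]
    m0_init, t1_init = _despot_init_batch(y, fa_true, tr_ms)

    _, _, ds_da = spgr_partials(fa_true, tr_ms, t1_init[:, None],
                                m0_init[:, None])
    sig2 = noise.sigma_spgr**2 + (
        ds_da * np.deg2rad(fa_nom[None, :]) * noise.sigma_b1) ** 2
    weights = 1.0 / np.where(sig2 > 0, sig2, 1.0)

    m0_hat, t1_hat, converged = batched_fit(y, fa_true, weights, tr_ms,
                                            m0_init, t1_init)
    return (t1_hat.reshape(shape), m0_hat.reshape(shape),
            converged.reshape(shape))


# ---------------------------------------------------------------------------
# file formats


def save_nifti(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Write a volume as float32 NIfTI (identity affine by default)."""
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def load_nifti(path):
    """Read a NIfTI volume; returns ``(data, affine)``."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise ValueError(f"{path}: not a readable NIfTI file ({exc})") from exc
    return np.asarray(img.get_fdata(), dtype=np.float32), img.affine


def save_sidecar(meta: dict, path) -> None:
    """Write acquisition metadata (FA list order preserved) as JSON."""
    Path(path).write_text(json.dumps(meta, indent=2) + "\n")


def load_sidecar(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed JSON at line {exc.lineno}, "
                         f"column {exc.colno}") from exc


def save_table(frame: pd.DataFrame, path) -> None:
    """Write a results table as CSV (stable, documented columns)."""
    frame.to_csv(path, index=False)


def load_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
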