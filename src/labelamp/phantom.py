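"""Synthetic brain phantoms and motion-artifact corruption.

Real QC studies rate T1-weighted head scans whose dominant failure mode is
motion ghosting: replicated, shifted copies of anatomy along the
phase-encode direction. This module generates stand-in volumes — a nested
set of tissue shells (CSF / gray matter / white matter contrast) on a zero
background, with a flat-topped axial profile so that a long run of axial
slices covers the head — and corrupts 2D slices by perturbing the phase of
a subset of k-space phase-encode lines, which produces exactly that
ghosting appearance.

Quality is parameterised by ``severity`` in [0, 1]; the latent quality is
``q = 1 - severity`` and the binary ground-truth label is a threshold on q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Volume",
    "QualitySpec",
    "generate_phantom_volume",
    "apply_motion_artifact",
    "sample_severities",
    "DEFAULT_LABEL_THRESHOLD",
]

DEFAULT_LABEL_THRESHOLD = 0.5

# Intensities roughly mimic T1 contrast: bright white matter core,
# mid-gray cortical shell, dark CSF rim.
_T1_INTENSITY = {"csf": 0.2, "gm": 0.6, "wm": 1.0}


@dataclass
class Volume:
    """A 3D intensity volume with the axial direction along the third axis."""

    voxels: np.ndarray
    subject_id: str = "sub-000"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("Volume requires a 3D array")
        if (self.voxels < 0).any():
            raise ValueError("Volume intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def axial_slice(self, index: int) -> np.ndarray:
        return self.voxels[:, :, index]


@dataclass(frozen=True)
class QualitySpec:
    """Latent quality of one scan.

    severity drives the artifact model; q = 1 - severity is what raters
    respond to; the binary ground truth thresholds q (pass = 1).
    """

    severity: float
    label_threshold: float = DEFAULT_LABEL_THRESHOLD

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError(f"severity must be in [0, 1], got {self.severity}")

    @property
    def q(self) -> float:
        return 1.0 - self.severity

    @property
    def true_label(self) -> int:
        return int(self.q >= self.label_threshold)


@dataclass(frozen=True)
class HeadConfig:
    """Geometry of the synthetic head.

    In-plane semi-axes are fractions of the array half-extent; the axial
    profile is flat (full in-plane size) over ``flat_fraction`` of the
    axial semi-extent and tapers ellipsoidally beyond it, so a long
    contiguous run of axial slices shows a near-full head cross-section.
    """

    semi_axis_frac: tuple[float, float] = (0.97, 0.97)
    axial_semi_frac: float = 0.98
    flat_fraction: float = 0.85
    wm_frac: float = 0.60
    gm_frac: float = 0.90


def _radial_scale(z_rel: np.ndarray, flat: float) -> np.ndarray:
    """In-plane radius multiplier along the axial axis (1 on the flat top)."""
    out = np.zeros_like(z_rel)
    a = np.abs(z_rel)
    inside = a <= 1.0
    taper = inside & (a > flat)
    out[inside] = 1.0
    t = (a[taper] - flat) / (1.0 - flat)
    out[taper] = np.sqrt(np.clip(1.0 - t**2, 0.0, 1.0))
    out[~inside] = 0.0
    return out


def generate_phantom_volume(
    shape: tuple[int, int, int] = (128, 128, 220),
    structure_params: HeadConfig | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    subject_id: str = "sub-000",
) -> Volume:
    """Generate a head-like phantom volume on a zero background.

    Parameters
    ----------
    shape
        (nx, ny, nz); the axial direction is the third axis. The default
        in-plane size 128x128 makes a full head cross-section exceed
        10,000 non-zero pixels, and the default axial extent leaves well
        over 200 usable axial slices.
    structure_params
        Head geometry; defaults produce CSF/GM/WM nested shells.
    noise_sd
        SD of additive Gaussian noise applied inside the head support
        (clipped at zero). The background stays exactly zero so that
        pixel-count slice selection behaves as on skull-stripped data.
    seed
        Seeds the noise; generation is deterministic in (arguments, seed).
    """
    if len(shape) != 3 or any(int(s) < 1 for s in shape):
        raise ValueError(f"shape must be three positive integers, got {shape}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    cfg = structure_params or HeadConfig()
    nx, ny, nz = (int(s) for s in shape)

    x = np.linspace(-1.0, 1.0, nx)
    y = np.linspace(-1.0, 1.0, ny)
    z = np.linspace(-1.0, 1.0, nz) / cfg.axial_semi_frac
    scale = _radial_scale(z, cfg.flat_fraction)  # (nz,)

    ax, ay = cfg.semi_axis_frac
    # normalised in-plane radius per voxel, per slice scale
    r2 = (x[:, None] / ax) ** 2 + (y[None, :] / ay) ** 2  # (nx, ny)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(
            scale[None, None, :] > 0, np.sqrt(r2)[:, :, None] / scale[None, None, :], np.inf
        )

    vox = np.zeros((nx, ny, nz), dtype=float)
    vox[rel <= 1.0] = _T1_INTENSITY["csf"]
    vox[rel <= cfg.gm_frac] = _T1_INTENSITY["gm"]
    vox[rel <= cfg.wm_frac] = _T1_INTENSITY["wm"]

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        support = vox > 0
        noise = rng.normal(0.0, noise_sd, size=int(support.sum()))
        vox[support] = np.clip(vox[support] + noise, 0.0, None)

    return Volume(voxels=vox, subject_id=subject_id)


def apply_motion_artifact(
    image: np.ndarray, severity: float, seed: int = 0
) -> np.ndarray:
    """Corrupt a 2D slice with k-space phase-encode ghosting.

    A fraction of phase-encode lines (rows of the 2D Fourier transform,
    sparing the central 10% that carries gross contrast) receive a random
    phase offset; both the fraction (up to half the lines) and the phase
    magnitude (up to pi) scale linearly with ``severity``. The magnitude of
    the inverse transform is returned, so output intensities are
    non-negative and the output shape equals the input shape. For a fixed
    seed the corrupted line set is nested across severities, making the
    distortion monotone in severity realisation by realisation.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("apply_motion_artifact expects a 2D array")
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must be in [0, 1], got {severity}")

    n_rows = img.shape[0]
    rng = np.random.default_rng(seed)
    # candidate phase-encode lines: everything outside the k-space centre
    freqs = np.fft.fftfreq(n_rows)
    candidates = np.flatnonzero(np.abs(freqs) > 0.05)
    order = rng.permutation(candidates)
    phases_full = rng.uniform(-np.pi, np.pi, size=candidates.size)

    n_corrupt = int(round(0.5 * severity * candidates.size))
    k = np.fft.fft2(img)
    lines = order[:n_corrupt]
    k[lines, :] *= np.exp(1j * severity * phases_full[:n_corrupt])[:, None]
    out = np.abs(np.fft.ifft2(k))
    return out


def sample_severities(
    n: int,
    fail_fraction: float = 0.3,
    seed: int = 0,
) -> np.ndarray:
    """Draw per-scan severities from a bimodal mixture.

    Ratings of real scans pile up near "clearly fine" and "clearly
    unusable", so severities are drawn from a mixture of a low mode
    (Beta(1.5, 8)) and, with probability ``fail_fraction``, a high mode
    (Beta(8, 1.5)).
    """
    if not 0.0 <= fail_fraction <= 1.0:
        raise ValueError("fail_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    is_fail = rng.random(n) < fail_fraction
    sev = rng.beta(1.5, 8.0, size=n)
    sev[is_fail] = rng.beta(8.0, 1.5, size=int(is_fail.sum()))
    return sev
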