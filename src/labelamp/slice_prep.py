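"""Convert 3D volumes into the 2D axial slice set used for rating.

The selection rule mirrors common crowd-rating pipelines: five axial
slices, 40 slices apart, starting at the first (most inferior) slice with
more than 10,000 non-zero pixels. Candidate slices that run off the top of
the volume, or that fall below the pixel threshold, are dropped rather
than replaced, so a volume can legitimately yield fewer than five slices.
Slices are zero-padded to 256x256 (or 512x512 for larger fields of view)
and exported as 8-bit PNGs with a CSV manifest.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .phantom import QualitySpec, Volume

__all__ = [
    "SliceRecord",
    "ExportSummary",
    "select_slices",
    "pad_slice",
    "export_slices",
    "load_volume",
]

logger = logging.getLogger(__name__)


@dataclass
class SliceRecord:
    subject_id: str
    slice_index: int
    image: np.ndarray  # 2D, padded square

    @property
    def padded_size(self) -> int:
        return self.image.shape[0]


@dataclass
class ExportSummary:
    n_volumes: int
    n_slices: int
    n_skipped: int
    skipped: list[str]


def select_slices(
    volume: Volume | np.ndarray,
    n_slices: int = 5,
    step: int = 40,
    min_pixels: int = 10000,
) -> list[int]:
    """Return the axial slice indices selected for rating.

    The first index is the smallest one whose slice has strictly more than
    ``min_pixels`` non-zero pixels; subsequent indices follow at ``step``
    increments. Out-of-range or below-threshold candidates are dropped.
    An all-background volume yields an empty list.
    """
    if n_slices < 1 or step < 1:
        raise ValueError("n_slices and step must be >= 1")
    vox = volume.voxels if isinstance(volume, Volume) else np.asarray(volume)
    if vox.ndim != 3 or vox.size == 0:
        raise ValueError("select_slices expects a non-empty 3D volume")

    counts = np.count_nonzero(vox, axis=(0, 1))
    qualifying = counts > min_pixels
    first = np.flatnonzero(qualifying)
    if first.size == 0:
        return []
    i0 = int(first[0])
    out = [i0]
    for k in range(1, n_slices):
        idx = i0 + k * step
        if idx >= vox.shape[2] or not qualifying[idx]:
            continue
        out.append(idx)
    return out


def pad_slice(image: np.ndarray) -> np.ndarray:
    """Zero-pad a 2D slice to 256x256, or 512x512 for larger inputs.

    Pixels are preserved exactly; odd padding remainders place the extra
    row/column on the high-index side. Inputs larger than 512 in either
    dimension are unsupported.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("pad_slice expects a 2D array")
    h, w = img.shape
    if h > 512 or w > 512:
        raise ValueError(f"slice of size {img.shape} exceeds the supported 512x512")
    target = 256 if (h <= 256 and w <= 256) else 512
    pad_h, pad_w = target - h, target - w
    top, left = pad_h // 2, pad_w // 2
    return np.pad(img, ((top, pad_h - top), (left, pad_w - left)))


def _to_uint8(img: np.ndarray) -> np.ndarray:
    """Per-slice min-max scaling to 8 bits (constant slices map to 0)."""
    img = np.asarray(img, dtype=float)
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.round((img - lo) / (hi - lo) * 255).astype(np.uint8)


def load_volume(path: str | Path) -> Volume:
    """Load a NIfTI volume; the third array axis is treated as axial."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    data = np.clip(data, 0.0, None)
    return Volume(voxels=data, subject_id=Path(path).name.split(".")[0])


def export_slices(
    volumes,
    out_dir: str | Path,
    n_slices: int = 5,
    step: int = 40,
    min_pixels: int = 10000,
    quality: dict[str, QualitySpec] | None = None,
    artifact_seed: int = 0,
    manifest_name: str = "manifest.csv",
) -> tuple[pd.DataFrame, ExportSummary]:
    """Select, pad, and write slices for a cohort of volumes.

    Parameters
    ----------
    volumes
        Iterable of `Volume` objects or NIfTI paths. Unreadable paths are
        logged and skipped, and counted in the returned summary.
    quality
        Optional per-subject `QualitySpec`. When given, each exported
        slice is corrupted with a motion artifact at that severity
        (seeded per subject and slice) and the manifest carries severity,
        latent quality q, and the true label.

    Returns the manifest DataFrame (also written as CSV) and a summary.
    """
    from .phantom import apply_motion_artifact

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    skipped: list[str] = []
    n_volumes = 0
    for vol in volumes:
        if not isinstance(vol, Volume):
            try:
                vol = load_volume(vol)
            except Exception as exc:  # corrupt/unreadable file
                logger.warning("skipping unreadable volume %s: %s", vol, exc)
                skipped.append(str(vol))
                continue
        n_volumes += 1
        spec = quality.get(vol.subject_id) if quality else None
        for j, idx in enumerate(
            select_slices(vol, n_slices=n_slices, step=step, min_pixels=min_pixels)
        ):
            img = vol.axial_slice(idx)
            if spec is not None and spec.severity > 0:
                seed = (artifact_seed * 1_000_003 + zlib.crc32(vol.subject_id.encode()) + idx) % (
                    2**31
                )
                img = apply_motion_artifact(img, spec.severity, seed=seed)
            img = pad_slice(img)
            fname = f"{vol.subject_id}_slice{idx:03d}.png"
            iio.imwrite(out_dir / fname, _to_uint8(img))
            row = {
                "subject_id": vol.subject_id,
                "slice_index": idx,
                "slice_id": f"{vol.subject_id}_s{idx:03d}",
                "path": fname,
            }
            if spec is not None:
                row.update(severity=spec.severity, q=spec.q, true_label=spec.true_label)
            rows.append(row)

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / manifest_name, index=False)
    summary = ExportSummary(
        n_volumes=n_volumes, n_slices=len(rows), n_skipped=len(skipped), skipped=skipped
    )
    return manifest, summary
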