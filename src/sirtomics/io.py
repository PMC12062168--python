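"""NIfTI I/O and run provenance.

Volumes round-trip through nibabel with spacing carried on the affine
diagonal and origin in the translation column. Masks are validated to be
binary on read.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import GridMismatchError, VolumeGrid

__all__ = ["read_volume", "write_volume", "read_mask", "RunManifest"]


def write_volume(vol: VolumeGrid, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vol.spacing_mm
    affine[:3, 3] = vol.origin_mm
    img = nib.Nifti1Image(np.asarray(vol.values), affine)
    img.header.set_zooms(vol.spacing_mm)
    if vol.unit:
        img.header["descrip"] = vol.unit.encode()[:79]
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, unit: str = "") -> VolumeGrid:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    affine = img.affine
    spacing = tuple(float(abs(affine[i, i])) for i in range(3))
    origin = tuple(float(affine[i, 3]) for i in range(3))
    if not unit:
        descrip = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0]
        unit = descrip.decode(errors="ignore")
    return VolumeGrid(data, spacing_mm=spacing, origin_mm=origin, unit=unit)


def read_mask(path: str | Path, like: VolumeGrid | None = None) -> np.ndarray:
    """Read a binary mask, rejecting non-binary data and grid mismatches."""
    vol = read_volume(path)
    uniq = np.unique(vol.values)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"mask {path} is not binary (values {uniq[:6]})")
    if like is not None and not vol.same_grid(like):
        raise GridMismatchError(
            f"mask {path} grid {vol.shape}/{vol.spacing_mm} does not match "
            f"volume {like.shape}/{like.spacing_mm}"
        )
    return vol.values.astype(bool)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record of a pipeline run."""

    master_seed: int
    config_hash: str
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )
    versions: dict[str, str] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)  # path -> sha256
    stages_completed: list[str] = field(default_factory=list)

    @staticmethod
    def config_digest(config: dict) -> str:
        return hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()

    def record(self, path: str | Path) -> None:
        p = Path(path)
        self.artifacts[str(p)] = _sha256(p)

    def save(self, path: str | Path) -> Path:
        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(json.dumps(self.__dict__, indent=2, default=str))
        return p
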