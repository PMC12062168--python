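"""Channel-specific preprocessing before feature extraction.

Each image channel has its own preparation: CT is resampled to an isotropic
1.5 mm grid and clipped to [-500, 500] HU; SPECT is clipped between 0 and its
own 99.9th percentile (bremsstrahlung SPECT produces sparse very hot voxels
that would otherwise dominate the discretization range); dose maps are
clipped at fixed per-structure, per-radionuclide caps so that the gray-level
range is identical for every case. Discretization bin widths are fixed per
channel: 50 counts/s (SPECT), 20 HU (CT), 1 Gy (dose/BED).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..grid import VolumeGrid

__all__ = ["PreprocessConfig", "preprocess", "resample", "resample_mask", "channel_bin_width"]


@dataclass
class PreprocessConfig:
    ct_resample_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    ct_clip_HU: tuple[float, float] = (-500.0, 500.0)
    spect_clip_percentile: float = 99.9
    dose_clip_caps_Gy: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "MAA": {"tumor": 650.34, "npl": 158.02, "wnl": 127.08},
            "Y90": {"tumor": 416.25, "npl": 133.16, "wnl": 123.08},
        }
    )
    bin_width: dict[str, float] = field(
        default_factory=lambda: {"SPECT": 50.0, "CT": 20.0, "dose": 1.0}
    )

    def __post_init__(self) -> None:
        for ch, caps in self.dose_clip_caps_Gy.items():
            for s, cap in caps.items():
                if cap <= 0:
                    raise ValueError(f"dose cap for {ch}/{s} must be positive")
        if any(w <= 0 for w in self.bin_width.values()):
            raise ValueError("bin widths must be positive")
        if self.ct_clip_HU[0] > self.ct_clip_HU[1]:
            raise ValueError("CT clip lower bound exceeds upper bound")


def resample(volume: VolumeGrid, new_spacing_mm, order: int = 1) -> VolumeGrid:
    """Resample to a new isotropic/anisotropic spacing (spline order 1 = linear)."""
    zoom = [s_old / s_new for s_old, s_new in zip(volume.spacing_mm, new_spacing_mm)]
    vals = ndimage.zoom(np.asarray(volume.values, dtype=float), zoom, order=order,
                        mode="nearest", grid_mode=False)
    return VolumeGrid(vals, spacing_mm=tuple(new_spacing_mm),
                      origin_mm=volume.origin_mm, unit=volume.unit)


def resample_mask(mask: np.ndarray, old_spacing_mm, new_spacing_mm) -> np.ndarray:
    """Nearest-neighbour mask resampling preserving binarity."""
    zoom = [s_old / s_new for s_old, s_new in zip(old_spacing_mm, new_spacing_mm)]
    out = ndimage.zoom(mask.astype(np.uint8), zoom, order=0, mode="nearest")
    return out.astype(bool)


_CHANNEL_KIND = {
    "CT": "CT",
    "SPECT": "SPECT",
    "SPECT_MAA": "SPECT",
    "SPECT_Y90": "SPECT",
    "MAA_Dose": "dose",
    "MAA_BED": "dose",
    "Y90_Dose": "dose",
    "Y90_BED": "dose",
}


def channel_kind(channel: str) -> str:
    try:
        return _CHANNEL_KIND[channel]
    except KeyError:
        raise ValueError(f"unknown channel {channel!r}") from None


def channel_bin_width(channel: str, cfg: PreprocessConfig | None = None) -> float:
    cfg = cfg or PreprocessConfig()
    return cfg.bin_width[channel_kind(channel)]


def _dose_channel(channel: str) -> str:
    return "MAA" if channel.startswith("MAA") else "Y90"


def preprocess(
    volume: VolumeGrid,
    channel: str,
    structure: str = "tumor",
    cfg: PreprocessConfig | None = None,
) -> VolumeGrid:
    """Apply the channel's intensity preparation (and, for CT, resampling).

    The ``structure`` argument matters only for dose channels, whose clip cap
    is structure-specific ("fixed values used for all patients"). Masks for a
    resampled CT must be resampled separately with :func:`resample_mask`.
    """
    cfg = cfg or PreprocessConfig()
    kind = channel_kind(channel)
    if kind == "CT":
        out = resample(volume, cfg.ct_resample_mm, order=1)
        out.values = np.clip(out.values, *cfg.ct_clip_HU)
        return out
    if kind == "SPECT":
        hi = float(np.percentile(volume.values, cfg.spect_clip_percentile))
        return volume.with_values(np.clip(volume.values, 0.0, hi))
    # dose / BED
    cap = cfg.dose_clip_caps_Gy[_dose_channel(channel)][structure.lower()]
    return volume.with_values(np.clip(volume.values, 0.0, cap))
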