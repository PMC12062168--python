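"""The 107-feature extractor and cohort feature tables.

Each (structure, channel) pair yields 107 features: 18 first-order, 14
shape-3D, 24 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM and 14 GLDM. A channel table
covers tumor + NPL + WNL, hence 3 x 107 = 321 columns, named
``<family>_<feature>_<structure>``. Dosiomics is the same extractor applied
to dose/BED maps — there is no separate math path, only the dose channels'
clip caps and 1 Gy bin width.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ..grid import VolumeGrid
from . import texture
from .firstorder import FIRSTORDER_FEATURES, firstorder_features
from .preprocess import PreprocessConfig, channel_bin_width, preprocess, resample_mask
from .shape import SHAPE_FEATURES, shape_features

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_FAMILIES",
    "N_FEATURES_PER_STRUCTURE",
    "STRUCTURES",
    "extract_features",
    "feature_names",
    "extract_case_features",
    "build_feature_table",
]

FEATURE_FAMILIES: dict[str, list[str]] = {
    "firstorder": FIRSTORDER_FEATURES,
    "shape": SHAPE_FEATURES,
    "glcm": texture.GLCM_FEATURES,
    "glrlm": texture.GLRLM_FEATURES,
    "glszm": texture.GLSZM_FEATURES,
    "ngtdm": texture.NGTDM_FEATURES,
    "gldm": texture.GLDM_FEATURES,
}
N_FEATURES_PER_STRUCTURE = sum(len(v) for v in FEATURE_FAMILIES.values())  # 107
STRUCTURES = ("tumor", "npl", "wnl")


def feature_names(structure: str | None = None) -> list[str]:
    """Ordered feature names, optionally suffixed with a structure."""
    names = [f"{family}_{feat}" for family, feats in FEATURE_FAMILIES.items() for feat in feats]
    if structure is None:
        return names
    return [f"{n}_{structure}" for n in names]


def extract_features(image: VolumeGrid, mask: np.ndarray, bin_width: float) -> pd.Series:
    """All 107 features of one ROI on one (already preprocessed) image."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {image.shape}")
    if not mask.any():
        raise ValueError("empty ROI mask")

    out: dict[str, float] = {}
    fo = firstorder_features(image.values[mask], bin_width, image.voxel_volume_mm3)
    out.update({f"firstorder_{k}": v for k, v in fo.items()})
    sh = shape_features(mask, image.spacing_mm)
    out.update({f"shape_{k}": v for k, v in sh.items()})

    g = texture.discretize(image.values, mask, bin_width)
    for family, fn in (
        ("glcm", texture.glcm_features),
        ("glrlm", texture.glrlm_features),
        ("glszm", texture.glszm_features),
        ("ngtdm", texture.ngtdm_features),
        ("gldm", texture.gldm_features),
    ):
        out.update({f"{family}_{k}": v for k, v in fn(g, mask).items()})
    return pd.Series(out).reindex(feature_names())


def extract_case_features(
    volume: VolumeGrid,
    masks: dict[str, np.ndarray],
    channel: str,
    cfg: PreprocessConfig | None = None,
) -> pd.Series:
    """The 321-column feature row of one case for one channel.

    ``masks`` must provide tumor/npl/wnl on the raw grid; for the CT channel
    the volume is resampled and the masks are carried to the resampled grid.
    """
    cfg = cfg or PreprocessConfig()
    parts = []
    for structure in STRUCTURES:
        img = preprocess(volume, channel, structure, cfg)
        mask = masks[structure]
        if img.shape != mask.shape:  # CT was resampled
            mask = resample_mask(mask, volume.spacing_mm, img.spacing_mm)
            mask = mask[tuple(slice(0, n) for n in img.shape)]
        feats = extract_features(img, mask, channel_bin_width(channel, cfg))
        feats.index = [f"{n}_{structure}" for n in feats.index]
        parts.append(feats)
    return pd.concat(parts)


def _case_masks(case) -> dict[str, np.ndarray]:
    return {s: case.structures.mask(s) for s in STRUCTURES}


def _channel_volume(case, channel: str) -> VolumeGrid:
    if channel == "CT":
        return case.ct
    if channel == "SPECT_MAA":
        return case.spect_maa
    if channel == "SPECT_Y90":
        return case.spect_y90
    raise ValueError(
        f"channel {channel!r} is not stored on a case; dose channels must be "
        "passed explicitly via the volumes argument"
    )


def build_feature_table(
    cases,
    channel: str,
    cfg: PreprocessConfig | None = None,
    volumes: dict[str, VolumeGrid] | None = None,
) -> pd.DataFrame:
    """Feature table (cases x 321) for one channel, labels attached.

    ``cases`` is a list of phantom cases; for dose channels pass the per-case
    dose/BED maps through ``volumes`` (case_id -> VolumeGrid). Cases with
    missing or empty structures are excluded with a log entry.
    """
    cfg = cfg or PreprocessConfig()
    rows, labels, index = [], [], []
    for case in cases:
        try:
            if volumes is not None:
                vol = volumes[case.case_id]
            else:
                vol = _channel_volume(case, channel)
            row = extract_case_features(vol, _case_masks(case), channel, cfg)
        except (KeyError, ValueError, AttributeError) as exc:
            logger.warning("excluding case %s from %s table: %s", case.case_id, channel, exc)
            continue
        rows.append(row)
        labels.append(case.label)
        index.append(case.case_id)
    table = pd.DataFrame(rows, index=index)
    table.insert(0, "label", labels)
    table.attrs["channel"] = channel
    return table
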