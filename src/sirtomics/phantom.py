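"""Synthetic SPECT/CT phantom cohort generator.

Real ⁹⁰Y-SIRT cohorts are clinical images that cannot be redistributed, so the
pipeline is exercised on seeded synthetic cases built from spherical
primitives: a whole liver, a perfused lobe and a tumor, with heterogeneous
activity uptake at a controllable tumor-to-normal ratio (TNR), Poisson SPECT
counting noise, a liver-like CT in Hounsfield units, and a label-dependent
effect so that classifiers can (or, at zero effect, cannot) separate
responders from non-responders.

The generator is the study-condition definition for every downstream test:
its defaults emulate a 17-case cohort with 5 responders / 12 non-responders,
SPECT-like 4 mm voxels, and a ~2.8 GBq administered activity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import StructureSet, VolumeGrid

__all__ = [
    "PhantomConfig",
    "PhantomCase",
    "generate_case",
    "generate_cohort",
    "clinical_covariates",
    "CLINICAL_CONTINUOUS",
    "CLINICAL_CATEGORICAL",
]


class InvalidGeometryError(ValueError):
    """Tumor/liver geometry that cannot be realized."""


@dataclass
class PhantomConfig:
    """Parameters of one synthetic case.

    ``class_effect`` maps effect names to responder-only modifications:
    ``uptake_scale`` multiplies tumor uptake (dose shift), and
    ``texture_smoothing`` multiplies the correlation length of the intra-tumor
    uptake texture (granularity shift). Zero/unit values mean no effect.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    liver_radius_mm: float = 70.0
    lobe_radius_mm: float = 54.0
    tumor_radius_mm: float = 17.0
    tnr_true: float = 2.5
    noise_model: str = "poisson"  # "none" | "poisson"
    expected_total_counts: float = 2.0e6
    injected_activity_GBq: float = 2.8
    lsf: float = 0.05
    maa_mismatch: float = 0.0
    texture_sigma_mm: float = 8.0
    class_effect: dict[str, float] = field(
        default_factory=lambda: {"uptake_scale": 1.5, "texture_smoothing": 2.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tnr_true <= 0:
            raise ValueError(f"tnr_true must be > 0, got {self.tnr_true}")
        if not 0.0 <= self.lsf < 1.0:
            raise ValueError(f"lsf must lie in [0, 1), got {self.lsf}")
        if self.noise_model not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.tumor_radius_mm >= self.lobe_radius_mm:
            raise InvalidGeometryError(
                f"tumor radius {self.tumor_radius_mm} mm must be smaller than "
                f"the perfused lobe radius {self.lobe_radius_mm} mm"
            )
        if self.lobe_radius_mm >= self.liver_radius_mm:
            raise InvalidGeometryError(
                f"lobe radius {self.lobe_radius_mm} mm must be smaller than "
                f"the liver radius {self.liver_radius_mm} mm"
            )


@dataclass
class PhantomCase:
    """One synthetic case: CT, two SPECT channels, masks, ground truth, label."""

    case_id: str
    ct: VolumeGrid
    spect_maa: VolumeGrid
    spect_y90: VolumeGrid
    structures: StructureSet
    truth: dict[str, float]
    label: str  # "R" | "NR"
    config: PhantomConfig


def _sphere_mask(shape, spacing, center_mm, radius_mm) -> np.ndarray:
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    d2 = (
        (xx - center_mm[0]) ** 2
        + (yy - center_mm[1]) ** 2
        + (zz - center_mm[2]) ** 2
    )
    return d2 <= radius_mm**2


def _smooth_texture(rng, shape, spacing_mm, sigma_mm) -> np.ndarray:
    """A positive, smooth random field with mean ~1 (lognormal of smoothed noise)."""
    white = rng.standard_normal(shape)
    sigma_vox = [max(sigma_mm / s, 1e-6) for s in spacing_mm]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox)
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return np.exp(0.35 * smooth)


def _normalized_uptake(field_: np.ndarray, mask: np.ndarray, target_mean: float) -> np.ndarray:
    """Rescale ``field_`` on ``mask`` so its in-mask mean is exactly ``target_mean``."""
    out = np.zeros_like(field_)
    m = field_[mask].mean()
    out[mask] = field_[mask] * (target_mean / m)
    return out


def _activity_field(cfg: PhantomConfig, structures: StructureSet, rng, *, tnr: float,
                    texture_sigma_mm: float) -> np.ndarray:
    """Noiseless counts/s field with exact per-structure means.

    NPL mean uptake is 1 (arbitrary counts/s unit prior to count scaling),
    tumor mean uptake is exactly ``tnr``; liver tissue outside the perfused
    lobe carries a 0.3 uptake floor, mimicking the background that
    scatter-uncorrected bremsstrahlung reconstruction spreads over the organ.
    """
    tex = _smooth_texture(rng, cfg.grid_shape, cfg.spacing_mm, texture_sigma_mm)
    act = np.zeros(cfg.grid_shape, dtype=float)
    outside_lobe = structures.whole_liver & ~structures.perfused_lobe
    act += _normalized_uptake(tex, structures.npl, 1.0)
    act += _normalized_uptake(tex, structures.tumor, tnr)
    act += _normalized_uptake(tex, outside_lobe, 0.3)
    return act


def _apply_counting(act: np.ndarray, cfg: PhantomConfig, rng) -> np.ndarray:
    """Scale the uptake field to the expected total counts and apply noise."""
    total = act.sum()
    scaled = act * (cfg.expected_total_counts / total)
    if cfg.noise_model == "none":
        return scaled
    return rng.poisson(scaled).astype(float)


def _ct_volume(cfg: PhantomConfig, structures: StructureSet, rng, *, label: str) -> np.ndarray:
    """Piecewise-constant HU with mild texture: air background, soft-tissue
    body shell, liver parenchyma ~55 HU, tumor ~40 HU."""
    shape = cfg.grid_shape
    center = [0.5 * (n - 1) * s for n, s in zip(shape, cfg.spacing_mm)]
    body = _sphere_mask(shape, cfg.spacing_mm, center, cfg.liver_radius_mm * 1.5)
    ct = np.full(shape, -1000.0)
    ct[body] = 20.0 + 10.0 * rng.standard_normal(int(body.sum()))
    liver_noise = 8.0 * rng.standard_normal(int(structures.whole_liver.sum()))
    ct[structures.whole_liver] = 55.0 + liver_noise
    sm = cfg.class_effect.get("texture_smoothing", 1.0) if label == "R" else 1.0
    tumor_tex = _smooth_texture(
        rng, shape, cfg.spacing_mm, max(cfg.texture_sigma_mm * sm * 0.5, 1.0)
    )
    tvox = structures.tumor
    ct[tvox] = 40.0 + 12.0 * (tumor_tex[tvox] - tumor_tex[tvox].mean())
    return ct


# Default-config LDM constants used only to record the analytic dose truth;
# kept in sync with sirtomics.dosimetry defaults by a unit test.
_ENERGY_J_PER_GBQ = 49.67


def _mean_tumor_dose_true(act: np.ndarray, structures: StructureSet,
                          cfg: PhantomConfig) -> float:
    """Analytic mean tumor dose under the default LDM configuration
    (whole-liver self-calibration, uniform 1 g/cm3 density, no LSF deduction)."""
    voxel_mass_kg = float(np.prod(cfg.spacing_mm)) * 1e-3 * 1e-3  # mm3 * g/cm3 -> kg
    total_in_liver = act[structures.whole_liver].sum()
    energy_J = cfg.injected_activity_GBq * _ENERGY_J_PER_GBQ
    mean_counts_tumor = act[structures.tumor].mean()
    return float(mean_counts_tumor / total_in_liver * energy_J / voxel_mass_kg)


def generate_case(config: PhantomConfig, *, label: str = "NR",
                  case_id: str = "case_000") -> PhantomCase:
    """Generate one synthetic SPECT/CT case.

    Deterministic for a fixed config (including ``seed``). Responder cases
    (``label="R"``) carry the configured ``class_effect``: tumor uptake is
    multiplied by ``uptake_scale`` and the intra-tumor texture correlation
    length by ``texture_smoothing``.
    """
    if label not in ("R", "NR"):
        raise ValueError(f"label must be 'R' or 'NR', got {label!r}")
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    center = [0.5 * (n - 1) * s for n, s in zip(cfg.grid_shape, cfg.spacing_mm)]
    liver = _sphere_mask(cfg.grid_shape, cfg.spacing_mm, center, cfg.liver_radius_mm)
    lobe_center = list(center)
    lobe_center[0] += cfg.liver_radius_mm - cfg.lobe_radius_mm - cfg.spacing_mm[0]
    lobe = _sphere_mask(cfg.grid_shape, cfg.spacing_mm, lobe_center, cfg.lobe_radius_mm)
    tumor = _sphere_mask(cfg.grid_shape, cfg.spacing_mm, lobe_center, cfg.tumor_radius_mm)
    structures = StructureSet(tumor=tumor, perfused_lobe=lobe, whole_liver=liver)

    is_responder = label == "R"
    tnr_eff = cfg.tnr_true * (cfg.class_effect.get("uptake_scale", 1.0) if is_responder else 1.0)
    tex_sigma = cfg.texture_sigma_mm * (
        cfg.class_effect.get("texture_smoothing", 1.0) if is_responder else 1.0
    )

    act_y90 = _activity_field(cfg, structures, rng, tnr=tnr_eff, texture_sigma_mm=tex_sigma)
    if cfg.maa_mismatch > 0:
        # MAA surrogate imperfectly predicts the microsphere distribution:
        # blend the tumor contrast toward uniform uptake.
        tnr_maa = tnr_eff * (1.0 - cfg.maa_mismatch) + 1.0 * cfg.maa_mismatch
        act_maa = _activity_field(cfg, structures, rng, tnr=tnr_maa, texture_sigma_mm=tex_sigma)
    else:
        act_maa = act_y90

    spect_y90 = _apply_counting(act_y90, cfg, rng)
    spect_maa = _apply_counting(act_maa, cfg, rng)
    ct = _ct_volume(cfg, structures, rng, label=label)

    truth = {
        "tnr_true": float(tnr_eff),
        "injected_activity_GBq": float(cfg.injected_activity_GBq),
        "lsf": float(cfg.lsf),
        "mean_tumor_dose_true_Gy": _mean_tumor_dose_true(act_y90, structures, cfg),
    }

    def vol(arr, unit):
        return VolumeGrid(arr, spacing_mm=cfg.spacing_mm, unit=unit)

    return PhantomCase(
        case_id=case_id,
        ct=vol(ct, "HU"),
        spect_maa=vol(spect_maa, "counts/s"),
        spect_y90=vol(spect_y90, "counts/s"),
        structures=structures,
        truth=truth,
        label=label,
        config=cfg,
    )


def generate_cohort(
    n_cases: int,
    responder_fraction: float,
    base_config: PhantomConfig | None = None,
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate a labelled cohort with per-case parameter jitter.

    Label counts follow the rounded fraction (17 cases at 5/17 -> 5 R, 12 NR).
    Per-case tumor radius, TNR, activity and LSF are jittered around the base
    config so cases are not clones; responders carry the base ``class_effect``.
    """
    if not 0.0 < responder_fraction < 1.0:
        raise ValueError("responder_fraction must lie strictly in (0, 1)")
    if n_cases < 4:
        raise ValueError(f"need at least 4 cases to stratify, got {n_cases}")
    n_resp = int(round(n_cases * responder_fraction))
    if n_resp == 0 or n_resp == n_cases:
        raise ValueError(
            f"n_cases={n_cases} at fraction {responder_fraction} cannot realize both classes"
        )
    base = base_config or PhantomConfig()
    rng = np.random.default_rng(seed)
    labels = np.array(["R"] * n_resp + ["NR"] * (n_cases - n_resp))
    rng.shuffle(labels)

    cases = []
    for i, lab in enumerate(labels):
        cfg = replace(
            base,
            tumor_radius_mm=float(
                np.clip(base.tumor_radius_mm * rng.uniform(0.8, 1.2),
                        2 * max(base.spacing_mm), base.lobe_radius_mm - 1.0)
            ),
            tnr_true=float(base.tnr_true * rng.uniform(0.8, 1.25)),
            injected_activity_GBq=float(base.injected_activity_GBq * rng.uniform(0.7, 1.3)),
            lsf=float(np.clip(base.lsf * rng.uniform(0.5, 2.0), 0.0, 0.3)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cases.append(generate_case(cfg, label=str(lab), case_id=f"case_{i:03d}"))
    return cases


# ---------------------------------------------------------------------------
# Clinical covariates

CLINICAL_CONTINUOUS = [
    "age_y",
    "bmi",
    "afp_ng_ml",
    "bilirubin_mg_dl",
    "albumin_g_dl",
    "alt_u_l",
    "ast_u_l",
    "platelets_10e9_l",
    "tumor_diameter_cm",
]
CLINICAL_CATEGORICAL = [
    "cirrhosis",
    "hepatitis",
    "ecog_1",
    "multifocal",
    "prior_treatment",
]

_CLINICAL_MEANS = {
    "age_y": (66.0, 9.0),
    "bmi": (26.0, 4.0),
    "afp_ng_ml": (400.0, 300.0),
    "bilirubin_mg_dl": (1.0, 0.4),
    "albumin_g_dl": (3.8, 0.5),
    "alt_u_l": (45.0, 20.0),
    "ast_u_l": (50.0, 22.0),
    "platelets_10e9_l": (180.0, 60.0),
    "tumor_diameter_cm": (6.0, 2.0),
}
_CLINICAL_RATES = {
    "cirrhosis": 0.7,
    "hepatitis": 0.4,
    "ecog_1": 0.35,
    "multifocal": 0.3,
    "prior_treatment": 0.25,
}


def clinical_covariates(labels, seed: int = 0, label_association: float = 0.0) -> pd.DataFrame:
    """Simulated clinical table: 9 continuous + 5 categorical = 14 columns.

    This emulates the 14 usable covariates of a 16-feature clinical panel
    (sex and extrahepatic metastasis are excluded up front for extreme class
    imbalance and are never generated). ``label_association`` shifts the
    continuous means of responders by that many pooled standard deviations
    and tilts categorical rates; 0 produces pure noise covariates.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    is_r = labels == "R"
    n = len(labels)
    cols: dict[str, np.ndarray] = {}
    for name in CLINICAL_CONTINUOUS:
        mu, sd = _CLINICAL_MEANS[name]
        vals = rng.normal(mu, sd, size=n)
        vals[is_r] += label_association * sd
        cols[name] = vals
    for name in CLINICAL_CATEGORICAL:
        p = _CLINICAL_RATES[name]
        p_r = float(np.clip(p + 0.2 * label_association, 0.05, 0.95))
        pr = np.where(is_r, p_r, p)
        cols[name] = (rng.uniform(size=n) < pr).astype(int)
    return pd.DataFrame(cols)


def write_case(case: PhantomCase, out_dir: str | Path) -> Path:
    """Write one case as NIfTI volumes plus a JSON truth/label sidecar."""
    from . import io as _io

    out = Path(out_dir) / case.case_id
    out.mkdir(parents=True, exist_ok=True)
    _io.write_volume(case.ct, out / "ct.nii.gz")
    _io.write_volume(case.spect_maa, out / "spect_maa.nii.gz")
    _io.write_volume(case.spect_y90, out / "spect_y90.nii.gz")
    for name in ("tumor", "perfused_lobe", "whole_liver"):
        mask = case.structures.mask(name)
        _io.write_volume(
            case.ct.with_values(mask.astype(np.uint8), unit=""), out / f"mask_{name}.nii.gz"
        )
    sidecar = {"case_id": case.case_id, "label": case.label, "truth": case.truth}
    (out / "truth.json").write_text(json.dumps(sidecar, indent=2))
    return out
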