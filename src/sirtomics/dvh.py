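"""Cumulative dose-volume histograms (DVH/BVH) and dose-volume constraints.

All scalar metrics are computed from raw voxel doses, exact at voxel
granularity; the binned cumulative curve exists only for export/plotting.
The D_x convention is the descending-sorted voxel quantile without
interpolation: D_x is the dose of the coolest voxel within the hottest x% of
the structure's volume, the convention of treatment-planning-system exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .grid import DoseMap, GridMismatchError, StructureSet

__all__ = [
    "DVHCurve",
    "cumulative_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "tnr",
    "extract_dvcs",
    "DVC_D_LEVELS",
    "DVC_V_THRESHOLDS_ALL",
    "DVC_V_THRESHOLDS_NORMAL",
    "dvc_schema",
]

# D_x percentage levels reported per structure (D5 feeds the homogeneity index).
DVC_D_LEVELS = (5.0, 50.0, 70.0, 95.0, 98.0)
# V_x Gy thresholds: the high-dose triplet for every structure, the
# normal-tissue set additionally for NPL and WNL.
DVC_V_THRESHOLDS_ALL = (120.0, 205.0, 400.0)
DVC_V_THRESHOLDS_NORMAL = (20.0, 30.0, 50.0, 70.0, 90.0)


@dataclass
class DVHCurve:
    """Cumulative DVH: volume receiving at least each dose level."""

    dose_edges_Gy: np.ndarray
    volume_ml: np.ndarray
    volume_pct: np.ndarray
    structure_id: str
    total_volume_ml: float
    # raw in-mask voxel doses (ascending); metrics are computed from these
    voxel_doses_Gy: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    voxel_volume_ml: float = 0.0

    def to_dataframe(self, unit: str = "percent") -> pd.DataFrame:
        """Two-column export (dose_Gy, volume) of the binned curve."""
        vol = self.volume_pct if unit in ("percent", "%") else self.volume_ml
        name = "volume_pct" if unit in ("percent", "%") else "volume_ml"
        return pd.DataFrame({"dose_Gy": self.dose_edges_Gy, name: vol})


def _masked_doses(dose: DoseMap, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.values.shape:
        raise GridMismatchError(
            f"mask shape {mask.shape} does not match dose map {dose.values.shape}"
        )
    if not mask.any():
        raise ValueError("empty structure mask")
    return np.asarray(dose.values, dtype=float)[mask]


def cumulative_dvh(dose: DoseMap, mask: np.ndarray, bin_width_Gy: float = 0.1,
                   structure_id: str = "") -> DVHCurve:
    """Cumulative DVH of ``dose`` restricted to ``mask``.

    V(d) = voxel_volume x #{voxels in mask with dose >= d}.
    """
    if bin_width_Gy <= 0:
        raise ValueError("bin width must be positive")
    doses = np.sort(_masked_doses(dose, mask))
    vox_ml = dose.grid.voxel_volume_ml
    total_ml = doses.size * vox_ml
    n_bins = max(int(ceil(doses[-1] / bin_width_Gy)) + 1, 2)
    edges = np.arange(n_bins + 1) * bin_width_Gy
    # voxels with dose >= edge, via the ascending sort
    n_ge = doses.size - np.searchsorted(doses, edges, side="left")
    vol_ml = n_ge * vox_ml
    return DVHCurve(
        dose_edges_Gy=edges,
        volume_ml=vol_ml,
        volume_pct=100.0 * vol_ml / total_ml,
        structure_id=structure_id,
        total_volume_ml=total_ml,
        voxel_doses_Gy=doses,
        voxel_volume_ml=vox_ml,
    )


def dose_at_volume(curve: DVHCurve, percent: float) -> float:
    """D_x: the maximum dose d such that at least ``percent``% of the
    structure receives >= d (descending-sorted voxel convention)."""
    if not 0.0 < percent <= 100.0:
        raise ValueError(f"percent must lie in (0, 100], got {percent}")
    doses = curve.voxel_doses_Gy
    n = doses.size
    k = ceil(percent / 100.0 * n)  # hottest k voxels
    return float(doses[n - k])


def volume_at_dose(curve: DVHCurve, threshold_Gy: float, unit: str = "ml") -> float:
    """V_x: volume receiving at least ``threshold_Gy``, in ml or percent."""
    if threshold_Gy < 0:
        raise ValueError("threshold must be non-negative")
    doses = curve.voxel_doses_Gy
    n_ge = doses.size - np.searchsorted(doses, threshold_Gy, side="left")
    ml = n_ge * curve.voxel_volume_ml
    if unit == "ml":
        return float(ml)
    if unit in ("percent", "%"):
        return float(100.0 * ml / curve.total_volume_ml)
    raise ValueError(f"unknown unit {unit!r}")


def homogeneity_index(curve: DVHCurve) -> float:
    """HI = D5 / D95, the simplified EBRT-style tumor homogeneity index."""
    d95 = dose_at_volume(curve, 95.0)
    if d95 <= 0:
        return float("inf")
    return dose_at_volume(curve, 5.0) / d95


def tnr(dose: DoseMap, tumor_mask: np.ndarray, normal_mask: np.ndarray) -> float:
    """Tumor-to-normal mean dose ratio; invariant to global rescaling."""
    t = _masked_doses(dose, tumor_mask).mean()
    n = _masked_doses(dose, normal_mask).mean()
    if n <= 0:
        raise ZeroDivisionError("mean normal dose is zero; TNR undefined")
    return float(t / n)


_STRUCTURES = ("tumor", "npl", "wnl")
_CHANNELS = ("MAA", "Y90")
_KINDS = ("Dose", "BED")


def _structure_metrics(structure: str) -> list[str]:
    metrics = ["volume_ml", "D_mean", "D_max", "D_min"]
    metrics += [f"D{int(x)}" for x in DVC_D_LEVELS]
    thresholds = list(DVC_V_THRESHOLDS_ALL)
    if structure in ("npl", "wnl"):
        thresholds = sorted(thresholds + list(DVC_V_THRESHOLDS_NORMAL))
    for t in thresholds:
        metrics += [f"V{int(t)}_ml", f"V{int(t)}_pct"]
    if structure == "tumor":
        metrics.append("HI")
    return metrics


def dvc_schema() -> list[str]:
    """The fixed, ordered column list of a DVC record."""
    cols: list[str] = []
    for channel in _CHANNELS:
        for kind in _KINDS:
            for structure in _STRUCTURES:
                cols += [
                    f"{structure}_{channel}_{kind}_{m}" for m in _structure_metrics(structure)
                ]
            cols += [
                f"TNR_NPL_{channel}_{kind}",
                f"TNR_WNL_{channel}_{kind}",
            ]
    cols += ["LSF", "injected_activity_GBq"]
    return cols


def extract_dvcs(
    dose_maps: dict[tuple[str, str], DoseMap],
    structures: StructureSet,
    lsf: float,
    activity_GBq: float,
) -> pd.Series:
    """The full per-case dose-volume-constraint catalogue.

    ``dose_maps`` is keyed by (channel, kind) and must contain all four maps
    (MAA/Y90 x Dose/BED). Returns a fixed-schema Series with deterministic
    ``<structure>_<channel>_<kind>_<metric>`` names plus HI, TNR, LSF and
    injected activity.
    """
    missing = [
        f"{c}/{k}" for c in _CHANNELS for k in _KINDS if (c, k) not in dose_maps
    ]
    if missing:
        raise ValueError(f"missing dose maps for: {', '.join(missing)}")

    rec: dict[str, float] = {}
    for channel in _CHANNELS:
        for kind in _KINDS:
            dm = dose_maps[(channel, kind)]
            curves = {
                s: cumulative_dvh(dm, structures.mask(s), structure_id=s)
                for s in _STRUCTURES
            }
            for s in _STRUCTURES:
                cv = curves[s]
                prefix = f"{s}_{channel}_{kind}"
                rec[f"{prefix}_volume_ml"] = cv.total_volume_ml
                rec[f"{prefix}_D_mean"] = float(cv.voxel_doses_Gy.mean())
                rec[f"{prefix}_D_max"] = float(cv.voxel_doses_Gy.max())
                rec[f"{prefix}_D_min"] = float(cv.voxel_doses_Gy.min())
                for x in DVC_D_LEVELS:
                    rec[f"{prefix}_D{int(x)}"] = dose_at_volume(cv, x)
                thresholds = list(DVC_V_THRESHOLDS_ALL)
                if s in ("npl", "wnl"):
                    thresholds = sorted(thresholds + list(DVC_V_THRESHOLDS_NORMAL))
                for t in thresholds:
                    rec[f"{prefix}_V{int(t)}_ml"] = volume_at_dose(cv, t, "ml")
                    rec[f"{prefix}_V{int(t)}_pct"] = volume_at_dose(cv, t, "percent")
                if s == "tumor":
                    rec[f"{prefix}_HI"] = homogeneity_index(cv)
            rec[f"TNR_NPL_{channel}_{kind}"] = tnr(dm, structures.tumor, structures.npl)
            rec[f"TNR_WNL_{channel}_{kind}"] = tnr(dm, structures.tumor, structures.wnl)
    rec["LSF"] = float(lsf)
    rec["injected_activity_GBq"] = float(activity_GBq)
    return pd.Series(rec).reindex(dvc_schema())
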