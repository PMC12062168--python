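"""End-to-end pipeline: phantom -> dosimetry -> DVH -> features -> modeling.

`run_all` binds the stages into one seeded, manifest-tracked run; the
intermediate helpers (`compute_dose_maps`, `build_dvc_table`, `build_tables`)
are the programmatic interface used by the CLI, the tests and the
reproduction script.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import dosimetry, dvh
from .features import PreprocessConfig, build_feature_table
from .grid import DoseMap
from .io import RunManifest
from .modeling import ModelConfig, run_experiment
from .phantom import PhantomCase, PhantomConfig, clinical_covariates, generate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "compute_dose_maps",
    "build_dvc_table",
    "build_tables",
    "run_all",
    "DEFAULT_CONFIG",
    "ALL_CHANNELS",
]

ALL_CHANNELS = ("CT", "SPECT_MAA", "SPECT_Y90", "MAA_Dose", "MAA_BED", "Y90_Dose", "Y90_BED")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out": "runs/demo",
    "phantom": {"n_cases": 17, "responder_fraction": 5 / 17},
    "clinical": {"label_association": 0.0},
    "features": {"channels": list(ALL_CHANNELS)},
    "modeling": {},
}


def compute_dose_maps(
    case: PhantomCase, ldm_cfg: dosimetry.LDMConfig | None = None
) -> dict[tuple[str, str], DoseMap]:
    """The four dose maps of one case: (MAA|Y90) x (Dose|BED)."""
    ldm_cfg = ldm_cfg or dosimetry.LDMConfig()
    maps: dict[tuple[str, str], DoseMap] = {}
    for channel, spect in (("MAA", case.spect_maa), ("Y90", case.spect_y90)):
        dose = dosimetry.ldm_dose_map(
            spect,
            case.structures.whole_liver
            if ldm_cfg.calibration_region == "whole_liver"
            else np.ones(spect.shape, dtype=bool),
            case.truth["injected_activity_GBq"],
            ldm_cfg,
            nuclide_channel=channel,
            lsf=case.truth["lsf"],
            ct=case.ct,
        )
        maps[(channel, "Dose")] = dose
        maps[(channel, "BED")] = dosimetry.bed_map(dose, case.structures)
    return maps


def build_dvc_table(cases: list[PhantomCase],
                    ldm_cfg: dosimetry.LDMConfig | None = None) -> pd.DataFrame:
    """One wide DVC row per case, labels attached."""
    rows = []
    for case in cases:
        maps = compute_dose_maps(case, ldm_cfg)
        rec = dvh.extract_dvcs(
            maps, case.structures, case.truth["lsf"], case.truth["injected_activity_GBq"]
        )
        rec.name = case.case_id
        rows.append(rec)
    table = pd.DataFrame(rows)
    table.insert(0, "label", [c.label for c in cases])
    return table


def build_tables(
    cases: list[PhantomCase],
    channels: tuple[str, ...] = ALL_CHANNELS,
    preprocess_cfg: PreprocessConfig | None = None,
    ldm_cfg: dosimetry.LDMConfig | None = None,
    clinical_seed: int = 0,
    clinical_label_association: float = 0.0,
) -> dict[str, pd.DataFrame]:
    """All modeling inputs: per-channel feature tables, DVC table, clinical."""
    preprocess_cfg = preprocess_cfg or PreprocessConfig()
    dose_cache = {c.case_id: compute_dose_maps(c, ldm_cfg) for c in cases} if any(
        ch.endswith(("Dose", "BED")) for ch in channels
    ) else {}
    tables: dict[str, pd.DataFrame] = {}
    for channel in channels:
        if channel in ("CT", "SPECT_MAA", "SPECT_Y90"):
            tables[channel] = build_feature_table(cases, channel, preprocess_cfg)
        else:
            nuclide, kind = channel.split("_")
            volumes = {cid: maps[(nuclide, kind)].grid for cid, maps in dose_cache.items()}
            tables[channel] = build_feature_table(cases, channel, preprocess_cfg, volumes=volumes)
        logger.info("built %s table: %s", channel, tables[channel].shape)
    tables["DVC"] = build_dvc_table(cases, ldm_cfg)
    clin = clinical_covariates(
        [c.label for c in cases], seed=clinical_seed,
        label_association=clinical_label_association,
    )
    clin.index = [c.case_id for c in cases]
    tables["clinical"] = clin
    return tables


def run_all(config: dict | None = None) -> RunManifest:
    """Execute every stage under one master seed and write all artifacts."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    seed = int(cfg["seed"])
    out = Path(cfg["out"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        master_seed=seed,
        config_hash=RunManifest.config_digest(cfg),
        versions={
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    )

    ph = cfg.get("phantom", {})
    base = PhantomConfig(**ph.get("base_config", {}))
    cases = generate_cohort(
        int(ph.get("n_cases", 17)), float(ph.get("responder_fraction", 5 / 17)), base, seed=seed
    )
    labels = [c.label for c in cases]
    pd.DataFrame(
        {"case_id": [c.case_id for c in cases], "label": labels}
    ).to_csv(out / "cohort_manifest.csv", index=False)
    manifest.record(out / "cohort_manifest.csv")
    manifest.stages_completed.append("phantom")

    try:
        tables = build_tables(
            cases,
            channels=tuple(cfg.get("features", {}).get("channels", ALL_CHANNELS)),
            clinical_seed=seed + 1,
            clinical_label_association=float(
                cfg.get("clinical", {}).get("label_association", 0.0)
            ),
        )
        for name, table in tables.items():
            p = out / f"table_{name}.csv"
            table.to_csv(p)
            manifest.record(p)
        manifest.stages_completed.extend(["dosimetry", "dvh", "features"])

        model_cfg = ModelConfig(seed=seed, **cfg.get("modeling", {}))
        results_df, _ = run_experiment(tables, labels, model_cfg)
        results_df.to_csv(out / "results.csv", index=False)
        manifest.record(out / "results.csv")
        manifest.stages_completed.append("modeling")
    except Exception:
        manifest.save(out / "manifest.json")  # record partial completion
        raise
    manifest.save(out / "manifest.json")
    return manifest
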