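"""The 6 x 6 strategy grid.

Six input categories — radiomics, dosiomics and DVH-parameter models, each
for the pre-therapy MAA surrogate and the post-therapy ⁹⁰Y channel — times
six per-category input mixes give 36 strategies; each is later crossed with
5 feature selectors x 8 classifiers for 1440 models in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CATEGORIES = (
    "MAA-radiomics",
    "Y90-radiomics",
    "MAA-dosiomics",
    "Y90-dosiomics",
    "MAA-DVH",
    "Y90-DVH",
)
RADIOMICS_SUBCATEGORIES = (
    "CT",
    "SPECT",
    "CT+Clinical",
    "SPECT+Clinical",
    "CT+SPECT",
    "CT+SPECT+Clinical",
)
DOSE_SUBCATEGORIES = (
    "Dose",
    "BED",
    "Dose+BED",
    "Dose+Clinical",
    "BED+Clinical",
    "BED+Dose+Clinical",
)

# Clinical covariates excluded up front for extreme class imbalance.
EXCLUDED_CLINICAL = ("sex", "extrahepatic_metastasis")


@dataclass
class StrategySpec:
    """One of the 36 (category, subcategory) input definitions."""

    category: str
    subcategory: str
    required_tables: tuple[str, ...]
    satisfiable: bool = True
    missing: tuple[str, ...] = field(default_factory=tuple)

    @property
    def name(self) -> str:
        return f"{self.category}/{self.subcategory}"

    @property
    def uses_clinical(self) -> bool:
        return "Clinical" in self.subcategory


def _required_tables(category: str, subcategory: str) -> tuple[str, ...]:
    channel = "MAA" if category.startswith("MAA") else "Y90"
    parts = subcategory.split("+")
    tables: list[str] = []
    for part in parts:
        if part == "Clinical":
            tables.append("clinical")
        elif category.endswith("radiomics"):
            tables.append("CT" if part == "CT" else f"SPECT_{channel}")
        elif category.endswith("dosiomics"):
            tables.append(f"{channel}_{part}")  # e.g. Y90_Dose, MAA_BED
        else:  # DVH categories draw columns from the DVC table
            tables.append(f"DVC:{channel}:{part}")
    return tuple(tables)


def build_strategies(available_tables: dict[str, pd.DataFrame] | None = None) -> list[StrategySpec]:
    """Enumerate all 36 strategies, flagging those whose inputs are missing.

    ``available_tables`` maps table keys (``CT``, ``SPECT_MAA``, ``SPECT_Y90``,
    ``MAA_Dose``, ``MAA_BED``, ``Y90_Dose``, ``Y90_BED``, ``DVC``,
    ``clinical``) to feature tables; None enumerates without checking.
    """
    specs: list[StrategySpec] = []
    for category in CATEGORIES:
        subs = RADIOMICS_SUBCATEGORIES if category.endswith("radiomics") else DOSE_SUBCATEGORIES
        for sub in subs:
            required = _required_tables(category, sub)
            missing: tuple[str, ...] = ()
            if available_tables is not None:
                keys = {t.split(":")[0] for t in required}
                missing = tuple(sorted(k for k in keys if available_tables.get(k) is None))
            specs.append(
                StrategySpec(
                    category=category,
                    subcategory=sub,
                    required_tables=required,
                    satisfiable=not missing,
                    missing=missing,
                )
            )
    assert len(specs) == 36
    return specs


def _dvc_columns(dvc: pd.DataFrame, channel: str, kind: str) -> list[str]:
    """DVC table columns belonging to one channel and dose kind, plus the
    channel-independent personalized parameters (LSF, injected activity)."""
    tag = f"_{channel}_{kind}"
    cols = [c for c in dvc.columns if tag in c]
    cols += [c for c in ("LSF", "injected_activity_GBq") if c in dvc.columns]
    return cols


def resolve_strategy(spec: StrategySpec, tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Assemble the design matrix of one strategy.

    Columns are prefixed with their source table so that e.g. CT and SPECT
    radiomics of the same structure stay distinct in merged mixes. Label
    columns are dropped; excluded clinical covariates are never included.
    """
    if not spec.satisfiable:
        raise ValueError(f"strategy {spec.name} is unsatisfiable: missing {spec.missing}")
    blocks = []
    for req in spec.required_tables:
        if req.startswith("DVC:"):
            _, channel, kind = req.split(":")
            dvc = tables["DVC"]
            block = dvc[_dvc_columns(dvc, channel, kind)].copy()
            prefix = f"DVC_{channel}_{kind}"
        else:
            tab = tables[req]
            block = tab.drop(columns=["label"], errors="ignore").copy()
            if req == "clinical":
                block = block.drop(columns=list(EXCLUDED_CLINICAL), errors="ignore")
            prefix = req
        block.columns = [f"{prefix}__{c}" for c in block.columns]
        blocks.append(block)
    X = pd.concat(blocks, axis=1)
    if X.columns.duplicated().any():
        raise ValueError(f"duplicate columns when resolving {spec.name}")
    return X
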