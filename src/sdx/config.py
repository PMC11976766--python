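"""Runtime settings shared across the pipeline.

Every numeric threshold named in the documentation lives here so that a
single YAML/JSON file can override the defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class Settings:
    # --- preprocessing -------------------------------------------------
    af_threshold: float = 0.05          # drop records with population AF strictly above
    max_cohort_alleles: int = 13        # drop records seen in more cohort alt alleles than this
    af_info_key: str = "AF"
    gene_info_key: str = "GENE"

    # --- pathogenicity criteria thresholds -----------------------------
    pm2_max_af: float = 1e-4            # rarity bound for PM2 (absent AF also triggers)
    pp3_min_damage: float = 0.7
    bp4_max_damage: float = 0.3
    ba1_min_af: float = 0.05
    bs1_min_af: float = 0.01

    # --- phenotypic similarity -----------------------------------------
    score_combination: str = "max"      # "max" or "mean" of normalized gene/condition scores

    # --- quality feature ------------------------------------------------
    missing_filter_is_pass: bool = False  # FILTER "." counts as non-PASS by default

    # --- pedigree -------------------------------------------------------
    proband_id: Optional[str] = None    # override automatic proband selection

    # --- modelling ------------------------------------------------------
    model_kind: str = "ensemble"
    seed: int = 0

    def replace(self, **kwargs) -> "Settings":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "Settings":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown settings keys: {sorted(unknown)}")
        return cls(**data)


DEFAULT_SETTINGS = Settings()
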