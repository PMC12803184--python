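"""Pipeline configuration.

A single flat configuration object carries every tunable constant of the
pipeline: identification filters, imputation parameters, clustering and
term-selection thresholds, structural-calculation settings, and the seed
for all stochastic steps.  Defaults reproduce the published analysis
settings; a handful of parameters the original analysis left unstated
(probe radius, sphere point count, rank bins) carry documented field
conventions as defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

# Spectronaut PTMSiteReport column dialect.  Keys are internal names, values
# are the header strings expected in the report; override via
# PipelineConfig.column_map to adapt other tables.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "protein_id": "PG.ProteinGroups",
    "gene": "PG.Genes",
    "position": "PTM.SiteLocation",
    "mod_title": "PTM.ModificationTitle",
    "site_probability": "PTM.SiteProbability",
    "collapse_key": "PTM.CollapseKey",
    "flank": "PTM.FlankingRegion",
    "pg_qvalue": "PG.Qvalue",
    "eg_qvalue": "EG.Qvalue",
}

ACETYL_LABEL = "Acetyl (K)"


class ConfigError(ValueError):
    """Invalid configuration value or file."""


@dataclass
class PipelineConfig:
    """All pipeline constants in one place.

    Fractions are in [0, 1]; abundance units are log2 intensity; SASA
    settings are in Angstroms.
    """

    # --- identification filters -------------------------------------------
    site_prob_min: float = 0.75      # strict >: localization confidence
    qvalue_max: float = 0.01         # <=: PG.Qvalue and EG.Qvalue cutoff
    # --- detection / imputation -------------------------------------------
    min_replicates: int = 2          # per tissue x sex for "detected"
    impute_downshift: float = 1.8    # log2 units below the row mean
    impute_width: float = 0.3        # multiplier on the row sd
    median_norm_target: str = "tissue"  # "tissue" pooled median or "global"
    # --- clustering and group ORA -----------------------------------------
    cluster_metric: str = "euclidean"
    cluster_linkage: str = "average"
    n_cut_groups: int = 400
    ora_alpha: float = 0.05
    ora_alternative: str = "greater"  # one-sided over-representation
    # --- variance-based GO term selection ---------------------------------
    term_sd_min: float = 0.6         # across-tissue sd of -log10 p, strict >
    term_low_max: float = 0.6        # some tissue must fall strictly below
    term_high_min: float = 3.0       # some tissue must rise strictly above
    overlap_max: float = 0.9         # prune only when overlap strictly exceeds
    sd_ddof: int = 1                 # sample sd for across-tissue statistics
    top_k_unique: int = 10
    # --- motif -------------------------------------------------------------
    flank_radius: int = 7
    logo_pseudocount: float = 0.5
    # --- structure ----------------------------------------------------------
    sasa_probe_radius: float = 1.4   # water-probe convention, Angstrom
    sasa_n_points: int = 100
    sasa_include_hydrogens: bool = True
    sasa_include_hetero: bool = True
    # --- variants ------------------------------------------------------------
    n_rank_bins: int = 10            # abundance deciles
    # --- misc ----------------------------------------------------------------
    standardize_ddof: int = 0        # population sd for display z-scores
    rng_seed: int = 0
    column_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COLUMN_MAP)
    )

    def __post_init__(self) -> None:
        for name in ("site_prob_min", "qvalue_max", "ora_alpha", "overlap_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "min_replicates", "n_cut_groups", "flank_radius",
            "sasa_n_points", "n_rank_bins", "top_k_unique",
        ):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.sasa_probe_radius <= 0:
            raise ConfigError("sasa_probe_radius must be > 0")
        if self.median_norm_target not in ("tissue", "global"):
            raise ConfigError("median_norm_target must be 'tissue' or 'global'")
        if self.ora_alternative not in ("greater", "two-sided", "less"):
            raise ConfigError("ora_alternative must be greater/two-sided/less")

    # --- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat key: value YAML mapping of PipelineConfig fields."""
        try:
            with open(path) as fh:
                data = yaml.safe_load(fh)
        except OSError as exc:
            raise ConfigError(f"cannot read config file {path}: {exc}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a flat key/value mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
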