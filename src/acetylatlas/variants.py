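"""Clinical-variant mapping onto acetyl sites and abundance-rank enrichment.

Mouse acetyl-lysine sites are joined to human residue variants via a
per-residue mouse-to-human mapping table, clinical significance labels are
normalized, acetyl-mimicking substitutions (K→Q, which removes the lysine
positive charge like acetylation does) are flagged, and the fraction of
pathogenic-variant sites is profiled across abundance-ranked bins of all
acetyl sites as a fold enrichment over the overall pathogenic fraction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .ingest import SiteRecord

logger = logging.getLogger(__name__)

SIGNIFICANCE_MAP = {
    "pathogenic": "pathogenic",
    "likely pathogenic": "pathogenic",
    "benign": "non-pathogenic",
    "likely benign": "non-pathogenic",
}


@dataclass
class VariantRecord:
    """One (acetyl site, human variant) pair after joining."""

    mouse_protein: str
    mouse_position: int
    human_protein: str
    human_position: int
    ref_aa: str                    # K for all joined records
    alt_aa: str
    significance: str              # pathogenic / non-pathogenic / uncertain
    phenotype: str = ""
    collapse_key: str = ""

    @property
    def is_mimic(self) -> bool:
        """K→Q removes the positive charge, chemically mimicking acetylation."""
        return self.alt_aa == "Q"

    @property
    def charge_class(self) -> str:
        if self.alt_aa == "Q":
            return "mimic"
        if self.alt_aa == "R":
            return "charge-preserving"
        if self.alt_aa in ("E", "D"):
            return "charge-reversing"
        return "other"


@dataclass
class FoldEnrichmentCurve:
    """Pathogenic-variant fold enrichment over abundance-rank bins.

    Bin 0 holds the lowest-abundance sites.  fold = (bin pathogenic
    fraction) / (overall pathogenic fraction); the site-count-weighted
    mean of folds is exactly 1.
    """

    site_counts: np.ndarray
    pathogenic_counts: np.ndarray
    fold: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(len(self.fold)),
                "n_sites": self.site_counts,
                "n_pathogenic": self.pathogenic_counts,
                "fold_enrichment": self.fold,
            }
        )


def normalize_significance(label: str) -> str:
    return SIGNIFICANCE_MAP.get(label.strip().lower(), "uncertain")


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Tab-separated mouse↔human variant table keyed by (protein, position)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [
        "mouse_protein", "mouse_position", "human_protein",
        "human_position", "ref_aa", "alt_aa", "significance",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing column(s): {missing}")
    df["mouse_position"] = df["mouse_position"].astype(int)
    df["human_position"] = df["human_position"].astype(int)
    if "phenotype" not in df.columns:
        df["phenotype"] = ""
    return df


def join_sites_variants(
    sites: list[SiteRecord], variant_table: pd.DataFrame
) -> tuple[list[VariantRecord], int]:
    """One record per (site, variant) pair; returns (records, n_unmatched).

    Every variant row either joins a detected site or is counted
    unmatched, so the join is lossless on the variant side.  Joined rows
    whose reference residue is not lysine are excluded with a warning.
    """
    by_site: dict[tuple[str, int], list[SiteRecord]] = {}
    for s in sites:
        by_site.setdefault((s.protein_id, s.position), []).append(s)
    records: list[VariantRecord] = []
    n_unmatched = 0
    n_bad_ref = 0
    for row in variant_table.itertuples(index=False):
        key = (row.mouse_protein, int(row.mouse_position))
        matched = by_site.get(key)
        if not matched:
            n_unmatched += 1
            continue
        if row.ref_aa != "K":
            n_bad_ref += 1
            continue
        for site in matched:
            records.append(
                VariantRecord(
                    mouse_protein=row.mouse_protein,
                    mouse_position=int(row.mouse_position),
                    human_protein=row.human_protein,
                    human_position=int(row.human_position),
                    ref_aa=row.ref_aa,
                    alt_aa=row.alt_aa,
                    significance=normalize_significance(row.significance),
                    phenotype=getattr(row, "phenotype", ""),
                    collapse_key=site.collapse_key,
                )
            )
    if n_bad_ref:
        warnings.warn(
            f"{n_bad_ref} joined variant(s) with non-lysine reference excluded"
        )
    logger.info(
        "join_sites_variants: %d joined pairs, %d variant rows unmatched",
        len(records), n_unmatched,
    )
    return records, n_unmatched


def flag_acetyl_mimics(records: list[VariantRecord]) -> list[VariantRecord]:
    """The K→Q subset: substitutions that chemically mimic acetyl-lysine."""
    return [r for r in records if r.is_mimic]


def abundance_rank_enrichment(
    site_abundance: pd.Series,
    pathogenic_keys: set[str],
    cfg: PipelineConfig | None = None,
) -> FoldEnrichmentCurve:
    """Fold enrichment of pathogenic-variant sites across abundance ranks.

    ``site_abundance`` maps every acetyl site (collapse key) to its mean
    detected log2 abundance; sites are ranked ascending and split into
    ``n_rank_bins`` equal-count bins.  Ties are broken by key for
    determinism.
    """
    cfg = cfg or PipelineConfig()
    n = len(site_abundance)
    if cfg.n_rank_bins > n:
        raise ValueError(f"more bins ({cfg.n_rank_bins}) than sites ({n})")
    keys = (
        pd.DataFrame({"key": site_abundance.index, "ab": site_abundance.values})
        .sort_values(["ab", "key"], kind="stable")["key"]
        .to_numpy()
    )
    bins = np.array_split(keys, cfg.n_rank_bins)
    is_path = np.array([k in pathogenic_keys for k in keys])
    total_path = int(is_path.sum())
    overall = total_path / n if n else 0.0
    site_counts = np.array([len(b) for b in bins])
    path_counts = np.array(
        [sum(1 for k in b if k in pathogenic_keys) for b in bins]
    )
    if overall == 0:
        fold = np.zeros(len(bins))
    else:
        fold = (path_counts / site_counts) / overall
    return FoldEnrichmentCurve(site_counts, path_counts, fold)
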