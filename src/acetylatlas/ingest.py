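"""Site-report ingestion and identification filtering.

Reads tab-separated PTM site reports (Spectronaut PTMSiteReport dialect by
default) and the sample design table, then applies the identification
filters used for the acetylome atlas: the acetyl-lysine modification label,
a strict site-localization probability cutoff, and protein- and
precursor-level q-value cutoffs.  Duplicate site entries (same collapse
key) are merged into one record per unique site.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .config import ACETYL_LABEL, PipelineConfig

logger = logging.getLogger(__name__)


class SiteReportFormatError(ValueError):
    """Report file does not match the expected column dialect."""


class SiteReportRowError(ValueError):
    """A row holds an unparseable value."""


class IntegrityError(ValueError):
    """Records contradict each other (e.g. one collapse key, two proteins)."""


@dataclass(frozen=True)
class SampleDesign:
    """One LC-MS run and its place in the study design."""

    run_id: str
    tissue: str
    sex: str
    replicate: int
    enriched: bool = True


@dataclass
class SiteRecord:
    """One acetyl-site observation row from the site report."""

    protein_id: str
    gene: str
    position: int                       # 1-based residue index
    mod_title: str
    site_probability: float
    collapse_key: str
    flank: str                          # +/- flank_radius window, center = site
    pg_qvalue: float
    eg_qvalue: float
    intensities: dict[str, float] = field(default_factory=dict)


def read_design(path: str | Path) -> list[SampleDesign]:
    """Read the run design table (run_id, tissue, sex, replicate, enriched)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["run_id", "tissue", "sex", "replicate", "enriched"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SiteReportFormatError(
            f"design table missing required column(s): {missing}"
        )
    designs = [
        SampleDesign(
            run_id=row.run_id,
            tissue=row.tissue,
            sex=row.sex,
            replicate=int(row.replicate),
            enriched=str(row.enriched).strip().lower() in ("true", "1", "yes"),
        )
        for row in df.itertuples()
    ]
    ids = [d.run_id for d in designs]
    if len(set(ids)) != len(ids):
        raise IntegrityError("design table run_ids are not unique")
    return designs


def read_site_report(
    path: str | Path,
    design: list[SampleDesign],
    cfg: PipelineConfig | None = None,
) -> list[SiteRecord]:
    """Parse a tab-separated PTM site report into site records.

    Quantity columns are matched to design run_ids by exact header name;
    report columns that are neither dialect columns nor design runs are
    reported once at DEBUG level and ignored.
    """
    cfg = cfg or PipelineConfig()
    cmap = cfg.column_map
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [col for col in cmap.values() if col not in df.columns]
    if missing:
        raise SiteReportFormatError(
            f"site report missing required column(s): {missing}"
        )
    run_ids = [d.run_id for d in design]
    run_cols = [r for r in run_ids if r in df.columns]
    known = set(cmap.values()) | set(run_cols)
    unmatched = [c for c in df.columns if c not in known]
    if unmatched:
        logger.debug("ignoring %d unmatched column(s): %s", len(unmatched), unmatched)

    def _float(raw: str, what: str, idx: int) -> float:
        try:
            return float(raw)
        except ValueError as exc:
            raise SiteReportRowError(
                f"row {idx}: non-numeric {what}: {raw!r}"
            ) from exc

    records: list[SiteRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        intensities: dict[str, float] = {}
        for run in run_cols:
            raw = row_d[run].strip()
            if raw in ("", "NaN", "nan", "NA"):
                continue
            value = _float(raw, f"intensity in run {run}", idx)
            if not math.isnan(value):
                intensities[run] = value
        records.append(
            SiteRecord(
                protein_id=row_d[cmap["protein_id"]],
                gene=row_d[cmap["gene"]],
                position=int(_float(row_d[cmap["position"]], "position", idx)),
                mod_title=row_d[cmap["mod_title"]],
                site_probability=_float(
                    row_d[cmap["site_probability"]], "site probability", idx
                ),
                collapse_key=row_d[cmap["collapse_key"]],
                flank=row_d[cmap["flank"]],
                pg_qvalue=_float(row_d[cmap["pg_qvalue"]], "PG q-value", idx),
                eg_qvalue=_float(row_d[cmap["eg_qvalue"]], "EG q-value", idx),
                intensities=intensities,
            )
        )
    return records


def filter_acetyl_sites(
    records: list[SiteRecord], cfg: PipelineConfig | None = None
) -> list[SiteRecord]:
    """Keep confidently identified and localized acetyl-lysine rows.

    A row survives iff its modification title contains the acetyl-lysine
    label, its site probability is strictly above ``site_prob_min``, and
    both q-values are at or below ``qvalue_max``.
    """
    cfg = cfg or PipelineConfig()
    kept: list[SiteRecord] = []
    rejected = {"mod_title": 0, "site_probability": 0, "qvalue": 0}
    for rec in records:
        if ACETYL_LABEL not in rec.mod_title:
            rejected["mod_title"] += 1
        elif not rec.site_probability > cfg.site_prob_min:
            rejected["site_probability"] += 1
        elif rec.pg_qvalue > cfg.qvalue_max or rec.eg_qvalue > cfg.qvalue_max:
            rejected["qvalue"] += 1
        else:
            kept.append(rec)
    logger.info(
        "filter_acetyl_sites: kept %d/%d (rejected: %s)",
        len(kept), len(records), rejected,
    )
    return kept


def collapse_unique_sites(records: list[SiteRecord]) -> list[SiteRecord]:
    """One record per unique collapse key.

    Duplicates (several precursors covering the same site) are merged by
    taking the per-run maximum intensity — conservative and independent of
    row order.  Duplicate keys claiming different proteins or positions are
    an integrity error.
    """
    by_key: dict[str, SiteRecord] = {}
    for rec in records:
        prev = by_key.get(rec.collapse_key)
        if prev is None:
            by_key[rec.collapse_key] = replace(
                rec, intensities=dict(rec.intensities)
            )
            continue
        if (prev.protein_id, prev.position) != (rec.protein_id, rec.position):
            raise IntegrityError(
                f"collapse key {rec.collapse_key!r} maps to both "
                f"{prev.protein_id}:{prev.position} and "
                f"{rec.protein_id}:{rec.position}"
            )
        for run, value in rec.intensities.items():
            prev.intensities[run] = max(prev.intensities.get(run, value), value)
    return list(by_key.values())
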