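"""Stage orchestration with serialized intermediates and a run manifest.

Each stage reads its inputs from disk and writes tab-separated outputs
under ``<output-dir>/<stage>/``; the full pipeline is the composition of
the file-based stages, so stage-wise and single-process execution are
identical by construction.  A JSON manifest records the config snapshot,
input checksums, stage completion, output paths, and the seed, and is
written atomically at the end of the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster_stats, enrichment, motif, quantify, structure, variants
from .config import ConfigError, PipelineConfig
from .ingest import (
    SampleDesign,
    SiteRecord,
    collapse_unique_sites,
    filter_acetyl_sites,
    read_design,
    read_site_report,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

INPUT_KEYS = (
    "site_report", "design", "fasta", "ontology",
    "annotations", "variants", "structures_dir",
)


@dataclass
class PipelineInputs:
    site_report: str | None = None
    design: str | None = None
    fasta: str | None = None
    ontology: str | None = None
    annotations: str | None = None
    variants: str | None = None
    structures_dir: str | None = None


@dataclass
class RunManifest:
    config: dict
    inputs: dict[str, str | None]
    input_checksums: dict[str, str]
    stages: dict[str, str] = field(default_factory=dict)   # name -> status
    outputs: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0

    def write(self, path: str | Path) -> None:
        """Atomic write: full temp file, then rename."""
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        with open(tmp, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
        os.replace(tmp, path)


def load_run_config(path: str | Path) -> tuple[PipelineInputs, PipelineConfig]:
    """Split a flat YAML config into input paths and pipeline constants."""
    import yaml

    try:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a flat key/value mapping")
    inputs = PipelineInputs(
        **{k: data.pop(k) for k in list(data) if k in INPUT_KEYS}
    )
    return inputs, PipelineConfig.from_dict(data)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_dir(outdir: str | Path, stage: str) -> Path:
    d = Path(outdir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _write(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, **kw)
    return path


# --------------------------------------------------------------------------
# serialization helpers shared by stages


def write_sites(records: list[SiteRecord], design: list[SampleDesign],
                path: Path, cfg: PipelineConfig) -> None:
    """Serialize site records in the same dialect the reader consumes."""
    cmap = cfg.column_map
    cols = list(cmap.values()) + [d.run_id for d in design]
    rows = []
    for r in records:
        row = {
            cmap["protein_id"]: r.protein_id,
            cmap["gene"]: r.gene,
            cmap["position"]: r.position,
            cmap["mod_title"]: r.mod_title,
            cmap["site_probability"]: r.site_probability,
            cmap["collapse_key"]: r.collapse_key,
            cmap["flank"]: r.flank,
            cmap["pg_qvalue"]: r.pg_qvalue,
            cmap["eg_qvalue"]: r.eg_qvalue,
        }
        for d in design:
            row[d.run_id] = r.intensities.get(d.run_id, "")
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_sites(path: Path, design: list[SampleDesign],
               cfg: PipelineConfig) -> list[SiteRecord]:
    return read_site_report(path, design, cfg)


def write_abundance(am: quantify.AbundanceMatrix, prefix: Path) -> None:
    _write(am.values, prefix.with_name(prefix.name + "_values.tsv"))
    _write(am.imputed_mask.astype(int),
           prefix.with_name(prefix.name + "_mask.tsv"))


def read_abundance(prefix: Path,
                   design: list[SampleDesign]) -> quantify.AbundanceMatrix:
    values = pd.read_csv(
        prefix.with_name(prefix.name + "_values.tsv"), sep="\t", index_col=0
    )
    mask = pd.read_csv(
        prefix.with_name(prefix.name + "_mask.tsv"), sep="\t", index_col=0
    ).astype(bool)
    return quantify.AbundanceMatrix(values, list(design), mask)


# --------------------------------------------------------------------------
# stages


def stage_ingest(inputs: PipelineInputs, cfg: PipelineConfig,
                 outdir: Path) -> list[Path]:
    d = _stage_dir(outdir, "ingest")
    design = read_design(inputs.design)
    records = read_site_report(inputs.site_report, design, cfg)
    records = collapse_unique_sites(filter_acetyl_sites(records, cfg))
    write_sites(records, design, d / "sites.tsv", cfg)
    import shutil

    shutil.copyfile(inputs.design, d / "design.tsv")
    return [d / "sites.tsv", d / "design.tsv"]


def stage_quantify(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    d = _stage_dir(outdir, "quantify")
    design = read_design(Path(outdir) / "ingest" / "design.tsv")
    records = read_sites(Path(outdir) / "ingest" / "sites.tsv", design, cfg)
    matrix = quantify.build_matrix(records, design)
    matrix, pattern = quantify.detection_filter(matrix, cfg)
    matrix = quantify.log2_transform(matrix)
    matrix = quantify.median_normalize(matrix, cfg)
    rng = np.random.default_rng(cfg.rng_seed)
    imputed = quantify.impute_left_shifted(matrix, cfg, rng)
    summary = quantify.summarize_tissue_sex(matrix, imputed)
    zscores = quantify.standardize_rows(summary, ddof=cfg.standardize_ddof)
    write_abundance(matrix, d / "normalized")
    write_abundance(imputed, d / "imputed")
    out = [
        _write(pattern.detected.astype(int), d / "detection.tsv"),
        _write(summary, d / "summary.tsv"),
        _write(zscores, d / "zscores.tsv"),
        _write(
            quantify.site_mean_abundance(matrix, pattern)
            .rename("mean_abundance").to_frame(),
            d / "site_mean_abundance.tsv",
        ),
    ]
    return out + [d / "normalized_values.tsv", d / "imputed_values.tsv"]


def _site_proteins(outdir: Path, cfg: PipelineConfig) -> dict[str, str]:
    cmap = cfg.column_map
    sites = pd.read_csv(
        Path(outdir) / "ingest" / "sites.tsv", sep="\t", dtype=str
    )
    return dict(zip(sites[cmap["collapse_key"]], sites[cmap["protein_id"]]))


def _closed_annotations(inputs: PipelineInputs) -> tuple[
    enrichment.OntologyDAG, dict[str, set[str]]
]:
    dag = (
        enrichment.read_obo(inputs.ontology)
        if str(inputs.ontology).endswith(".obo")
        else enrichment.read_edge_list(inputs.ontology)
    )
    direct = enrichment.read_annotations(inputs.annotations)
    return dag, enrichment.ancestor_closure(dag, direct)


def stage_cluster(inputs: PipelineInputs, cfg: PipelineConfig,
                  outdir: Path) -> list[Path]:
    d = _stage_dir(outdir, "cluster")
    zscores = pd.read_csv(
        Path(outdir) / "quantify" / "zscores.tsv", sep="\t", index_col=0
    )
    dendro = cluster_stats.cluster_rows(zscores, cfg)
    k = min(cfg.n_cut_groups, len(zscores))
    groups = cluster_stats.cut_groups(dendro, k)
    out = [_write(groups.to_frame(), d / "groups.tsv")]
    if inputs.ontology and inputs.annotations:
        _, closed = _closed_annotations(inputs)
        ora = cluster_stats.group_ora(
            groups, _site_proteins(outdir, cfg), closed, cfg
        )
        out.append(_write(ora, d / "group_ora.tsv", index=False))
    res = cluster_stats.pca(zscores, cfg)
    out += [
        _write(res.scores, d / "pca_scores.tsv"),
        _write(res.loadings, d / "pca_loadings.tsv"),
        _write(
            pd.DataFrame(
                {"explained_variance_ratio": res.explained_variance_ratio},
                index=res.scores.columns,
            ),
            d / "pca_explained.tsv",
        ),
    ]
    return out


def stage_enrich(inputs: PipelineInputs, cfg: PipelineConfig,
                 outdir: Path) -> list[Path]:
    d = _stage_dir(outdir, "enrich")
    detected = pd.read_csv(
        Path(outdir) / "quantify" / "detection.tsv", sep="\t", index_col=0
    ).astype(bool)
    pattern = quantify.DetectionPattern(detected, detected.sum(axis=1))
    dag, closed = _closed_annotations(inputs)
    site_proteins = _site_proteins(outdir, cfg)
    if inputs.fasta:
        from Bio import SeqIO

        universe = {
            rec.id for rec in SeqIO.parse(str(inputs.fasta), "fasta")
        }
    else:
        universe = set(site_proteins.values())
    em = enrichment.tissue_enrichment(
        pattern, site_proteins, closed, universe, cfg
    )
    selected = enrichment.select_variable_terms(em, cfg)
    term_proteins = {
        t: {p for p in universe if t in closed.get(p, set())} for t in selected
    }
    pruned = enrichment.prune_overlapping_terms(selected, term_proteins, em, cfg)
    pruned = enrichment.prune_parent_child(pruned, dag)
    unique_rows = []
    for tissue in detected.columns:
        scores = enrichment.rank_unique_terms(em, tissue, cfg)
        for rank, (term, score) in enumerate(scores.items(), start=1):
            unique_rows.append((tissue, rank, term, score))
    return [
        _write(em.pvalues, d / "enrichment_pvalues.tsv"),
        _write(em.neglog10, d / "enrichment_neglog10.tsv"),
        _write(
            pd.DataFrame({"term": pruned}), d / "selected_terms.tsv",
            index=False,
        ),
        _write(
            pd.DataFrame(
                unique_rows, columns=["tissue", "rank", "term", "score"]
            ),
            d / "unique_terms.tsv", index=False,
        ),
    ]


def stage_motif(inputs: PipelineInputs, cfg: PipelineConfig,
                outdir: Path) -> list[Path]:
    d = _stage_dir(outdir, "motif")
    design = read_design(Path(outdir) / "ingest" / "design.tsv")
    records = read_sites(Path(outdir) / "ingest" / "sites.tsv", design, cfg)
    fg = motif.build_logo(motif.site_flanks(records), cfg)
    out = [
        _write(fg.counts, d / "site_counts.tsv"),
        _write(fg.probabilities, d / "site_probabilities.tsv"),
        _write(fg.information.rename("bits").to_frame(), d / "site_ic.tsv"),
    ]
    if inputs.fasta:
        bg = motif.build_logo(
            motif.extract_background_flanks(inputs.fasta, cfg), cfg
        )
        out += [
            _write(bg.probabilities, d / "background_probabilities.tsv"),
            _write(bg.information.rename("bits").to_frame(),
                   d / "background_ic.tsv"),
            _write(motif.compare_logos(fg, bg, cfg), d / "enrichment_log2.tsv"),
        ]
    return out


def stage_structure(inputs: PipelineInputs, cfg: PipelineConfig,
                    outdir: Path) -> list[Path]:
    d = _stage_dir(outdir, "structure")
    design = read_design(Path(outdir) / "ingest" / "design.tsv")
    records = read_sites(Path(outdir) / "ingest" / "sites.tsv", design, cfg)
    tables: dict[str, list[structure.ResidueStructure]] = {}
    rows = []
    for pdb in sorted(Path(inputs.structures_dir).glob("*.pdb")):
        pid = pdb.stem
        atoms = structure.parse_pdb(pdb, include_hetero=cfg.sasa_include_hetero)
        residues = structure.residue_structure_table(pid, atoms, cfg)
        tables[pid] = residues
        rows += [
            (pid, r.residue_index, r.amino_acid, r.plddt, r.sasa)
            for r in residues
        ]
    residue_df = pd.DataFrame(
        rows, columns=["protein_id", "residue_index", "amino_acid",
                       "plddt", "sasa"],
    )
    joined = structure.join_site_structure(records, tables)
    return [
        _write(residue_df, d / "residue_structure.tsv", index=False),
        _write(joined, d / "site_structure.tsv", index=False),
    ]


def stage_variants(inputs: PipelineInputs, cfg: PipelineConfig,
                   outdir: Path) -> list[Path]:
    d = _stage_dir(outdir, "variants")
    design = read_design(Path(outdir) / "ingest" / "design.tsv")
    records = read_sites(Path(outdir) / "ingest" / "sites.tsv", design, cfg)
    table = variants.read_variant_table(inputs.variants)
    joined, n_unmatched = variants.join_sites_variants(records, table)
    mimics = variants.flag_acetyl_mimics(joined)
    abundance = pd.read_csv(
        Path(outdir) / "quantify" / "site_mean_abundance.tsv",
        sep="\t", index_col=0,
    )["mean_abundance"]
    pathogenic = {
        r.collapse_key for r in joined if r.significance == "pathogenic"
    }
    curve = variants.abundance_rank_enrichment(abundance, pathogenic, cfg)

    def frame(recs: list[variants.VariantRecord]) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.collapse_key, r.mouse_protein, r.mouse_position,
                 r.human_protein, r.human_position, r.ref_aa, r.alt_aa,
                 r.significance, r.charge_class, r.phenotype)
                for r in recs
            ],
            columns=["collapse_key", "mouse_protein", "mouse_position",
                     "human_protein", "human_position", "ref_aa", "alt_aa",
                     "significance", "charge_class", "phenotype"],
        )

    out = [
        _write(frame(joined), d / "joined_variants.tsv", index=False),
        _write(frame(mimics), d / "mimics.tsv", index=False),
        _write(curve.to_frame(), d / "fold_curve.tsv", index=False),
    ]
    with open(d / "join_stats.json", "w") as fh:
        json.dump(
            {"n_joined": len(joined), "n_unmatched": n_unmatched,
             "n_mimics": len(mimics)}, fh,
        )
    return out + [d / "join_stats.json"]


STAGE_ORDER = [
    "ingest", "quantify", "cluster", "enrich", "motif", "structure", "variants",
]


def _stage_requirements(inputs: PipelineInputs) -> dict[str, str | None]:
    """Missing-input reason per stage, None when runnable."""
    def need(*names: str) -> str | None:
        missing = [n for n in names if not getattr(inputs, n)]
        return f"missing input(s): {missing}" if missing else None

    return {
        "ingest": need("site_report", "design"),
        "quantify": None,
        "cluster": None,
        "enrich": need("ontology", "annotations"),
        "motif": None,
        "structure": need("structures_dir"),
        "variants": need("variants"),
    }


def run_pipeline(
    inputs: PipelineInputs,
    cfg: PipelineConfig,
    outdir: str | Path,
) -> RunManifest:
    """Run every runnable stage in order; skipped stages log their reason."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksums = {
        k: _sha256(v)
        for k, v in dataclasses.asdict(inputs).items()
        if v and Path(v).is_file()
    }
    manifest = RunManifest(
        config=cfg.to_dict(),
        inputs=dataclasses.asdict(inputs),
        input_checksums=checksums,
        seed=cfg.rng_seed,
    )
    requirements = _stage_requirements(inputs)
    runners = {
        "ingest": lambda: stage_ingest(inputs, cfg, outdir),
        "quantify": lambda: stage_quantify(cfg, outdir),
        "cluster": lambda: stage_cluster(inputs, cfg, outdir),
        "enrich": lambda: stage_enrich(inputs, cfg, outdir),
        "motif": lambda: stage_motif(inputs, cfg, outdir),
        "structure": lambda: stage_structure(inputs, cfg, outdir),
        "variants": lambda: stage_variants(inputs, cfg, outdir),
    }
    for stage in STAGE_ORDER:
        reason = requirements[stage]
        if reason:
            logger.info("skipping stage %s: %s", stage, reason)
            manifest.stages[stage] = f"skipped ({reason})"
            continue
        try:
            paths = runners[stage]()
        except Exception as exc:
            manifest.stages[stage] = f"failed ({exc})"
            manifest.write(outdir / "manifest.json")
            raise
        manifest.stages[stage] = "complete"
        manifest.outputs[stage] = [str(p) for p in paths]
    manifest.write(outdir / "manifest.json")
    return manifest
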