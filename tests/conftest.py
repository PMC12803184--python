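"""Shared fixtures: synthetic datasets at two scales and tiny builders."""

from __future__ import annotations

from pathlib import Path

import pytest

from acetylatlas.config import PipelineConfig
from acetylatlas.ingest import SampleDesign, SiteRecord
from acetylatlas.pipeline import PipelineInputs, run_pipeline
from acetylatlas.synthetic_data import AtlasScenario, generate_atlas


def make_record(**kw) -> SiteRecord:
    defaults = dict(
        protein_id="P1", gene="p1", position=10, mod_title="Acetyl (K)",
        site_probability=0.95, collapse_key="P1_K10",
        flank="AAAAAAAKAAAAAAA", pg_qvalue=0.001, eg_qvalue=0.001,
        intensities={},
    )
    defaults.update(kw)
    return SiteRecord(**defaults)


def make_design(
    tissues=("liver", "heart"), sexes=("female", "male"), replicates=3
) -> list[SampleDesign]:
    return [
        SampleDesign(f"run_{t}_{s}_{r}", t, s, r)
        for t in tissues for s in sexes for r in range(1, replicates + 1)
    ]


SMALL_SCENARIO = AtlasScenario(
    n_tissues=4,
    n_proteins=60,
    n_background_proteins=120,
    n_sites=200,
    n_specific_proteins_per_tissue=4,
    n_structure_pairs=4,
    n_random_terms=10,
)


def inputs_for(simdir: Path) -> PipelineInputs:
    return PipelineInputs(
        site_report=str(simdir / "site_report.tsv"),
        design=str(simdir / "design.tsv"),
        fasta=str(simdir / "proteome.fasta"),
        ontology=str(simdir / "ontology_edges.tsv"),
        annotations=str(simdir / "annotations.tsv"),
        variants=str(simdir / "variants.tsv"),
        structures_dir=str(simdir / "structures"),
    )


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """Small synthetic dataset plus its ground truth."""
    simdir = tmp_path_factory.mktemp("small_sim")
    truth = generate_atlas(simdir, seed=0, scenario=SMALL_SCENARIO)
    return simdir, truth


@pytest.fixture(scope="session")
def small_run(small_sim, tmp_path_factory):
    """Full pipeline run on the small dataset."""
    simdir, truth = small_sim
    outdir = tmp_path_factory.mktemp("small_out")
    cfg = PipelineConfig(n_cut_groups=20, rng_seed=0)
    manifest = run_pipeline(inputs_for(simdir), cfg, outdir)
    return outdir, truth, manifest


@pytest.fixture(scope="session")
def atlas_run(tmp_path_factory):
    """Atlas-scale scenario (15 tissues x 2 sexes x 3 reps, 2000 sites)
    generated and run through the whole pipeline once per session."""
    simdir = tmp_path_factory.mktemp("atlas_sim")
    truth = generate_atlas(simdir, seed=0)
    outdir = tmp_path_factory.mktemp("atlas_out")
    manifest = run_pipeline(inputs_for(simdir), PipelineConfig(rng_seed=0), outdir)
    return simdir, outdir, truth, manifest
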