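"""Synthetic multi-tissue acetylome inputs with known ground truth.

Emulates the study design the pipeline targets — 15 tissues x 2 sexes x 3
replicates — and writes exactly the file formats the pipeline reads: a
PTM site report, a design table, a proteome FASTA, per-protein PDB
structures, an ontology edge list with protein annotations, and a
mouse-to-human variant table, together with a JSON truth record.

Planted structure in the data:

* tissue-specific sites live on dedicated proteins, abundant in their home
  tissue and below the detection regime elsewhere;
* missingness is left-censored: the probability a cell is missing is a
  logistic function of its latent log2 intensity (lower = more missing);
* one ontology term per tissue annotates exactly that tissue's specific
  proteins, so per-tissue enrichment should single it out;
* an acidic residue is planted upstream of the acetyl-lysine in a known
  fraction of site flanks;
* structure files carry buried/exposed lysine pairs (a shell of dummy
  heteroatoms occludes the buried one) and planted pLDDT in the B-factor;
* pathogenic variant labels are drawn with probability increasing in a
  site's true mean abundance.

Every generator is a pure function of its parameters and seed: the same
seed reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .ingest import SampleDesign

AMINO_ACIDS = list("ACDEFGHIKLMNPQRSTVWY")

TISSUES = [
    "brain", "heart", "liver", "kidney", "lung", "spleen", "pancreas",
    "skeletal_muscle", "brown_fat", "white_fat", "intestine", "stomach",
    "testis", "thymus", "skin",
]


@dataclass
class AtlasScenario:
    """Defaults describe the atlas-like desk-scale scenario."""

    n_tissues: int = 15
    sexes: tuple[str, ...] = ("female", "male")
    replicates: int = 3
    n_proteins: int = 400                 # proteins carrying acetyl sites
    n_background_proteins: int = 800      # detected but never acetylated
    protein_length: tuple[int, int] = (200, 400)
    n_sites: int = 2000
    tissue_specific_fraction: float = 0.2
    n_specific_proteins_per_tissue: int = 7
    base_mean: float = 20.0               # log2, common-site abundance center
    base_sd: float = 1.5
    specific_on_mean: float = 23.0        # home-tissue abundance of planted sites
    off_mean: float = 10.0                # latent level when a site is "off"
    tissue_on_prob: float = 0.6           # chance a common site is on in a tissue
    tissue_effect_sd: float = 0.3
    replicate_sd: float = 0.4
    missing_midpoint: float = 16.0        # log2 intensity of 50% missingness
    missing_width: float = 1.0
    filter_fail_fraction: float = 0.05    # decoy rows per failure mode
    motif_residue: str = "E"
    motif_position: int = -1
    motif_strength: float = 0.6
    n_structure_pairs: int = 20
    plddt_range: tuple[float, float] = (50.0, 95.0)
    n_random_terms: int = 40
    term_size: int = 30
    variant_prob: float = 1.0             # fraction of sites with a mapped variant
    variant_assoc_strength: float = 20.0  # logistic slope on abundance z-score
    variant_uncertain_frac: float = 0.1
    unmatched_variant_frac: float = 0.05


@dataclass
class SiteTruth:
    collapse_key: str
    protein_id: str
    position: int                          # 1-based
    flank: str
    kind: str                              # "common" | "specific"
    home_tissue: str | None
    tissue_means: dict[str, float]         # on-tissues only
    true_mean: float                       # mean latent log2 over on tissues
    motif_planted: bool


@dataclass
class SyntheticTruth:
    seed: int
    scenario: AtlasScenario
    tissues: list[str]
    sequences: dict[str, str] = field(repr=False, default_factory=dict)
    sites: list[SiteTruth] = field(default_factory=list)
    specific_proteins: dict[str, list[str]] = field(default_factory=dict)
    planted_terms: dict[str, str] = field(default_factory=dict)
    dag_edges: list[tuple[str, str]] = field(default_factory=list)
    direct_annotations: dict[str, list[str]] = field(default_factory=dict)
    structure_pairs: list[tuple[str, int, int]] = field(default_factory=list)
    plddt: dict[str, dict[int, float]] = field(default_factory=dict)
    pathogenic_keys: list[str] = field(default_factory=list)
    n_variant_rows: int = 0
    n_unmatched_variant_rows: int = 0

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d.pop("sequences")                   # the FASTA is the artifact
        d["scenario"] = asdict(self.scenario)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True, default=list)


# --------------------------------------------------------------------------
# design and proteome


def generate_design(
    n_tissues: int = 15,
    sexes: tuple[str, ...] = ("female", "male"),
    replicates: int = 3,
    seed: int = 0,
) -> list[SampleDesign]:
    """Full factorial tissue x sex x replicate run list (deterministic;
    the seed is accepted for interface symmetry and unused)."""
    if n_tissues < 1 or replicates < 1 or not sexes:
        raise ValueError("design counts must be positive")
    tissues = [
        TISSUES[i] if i < len(TISSUES) else f"tissue{i + 1}"
        for i in range(n_tissues)
    ]
    return [
        SampleDesign(
            run_id=f"run_{t}_{s}_{r}", tissue=t, sex=s, replicate=r,
            enriched=True,
        )
        for t in tissues for s in sexes for r in range(1, replicates + 1)
    ]


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _flank(seq: str, pos: int, radius: int = 7) -> str:
    i = pos - 1
    left = seq[max(0, i - radius): i].rjust(radius, "_")
    right = seq[i + 1: i + 1 + radius].ljust(radius, "_")
    return left + seq[i] + right


def _missing_prob(x: np.ndarray, midpoint: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(midpoint - x) / width))


# --------------------------------------------------------------------------
# truth assembly


def generate_truth(
    scenario: AtlasScenario, seed: int
) -> SyntheticTruth:
    """Draw the proteome, site placement, and planted abundance model."""
    sc = scenario
    rng = np.random.default_rng(seed)
    tissues = [
        TISSUES[i] if i < len(TISSUES) else f"tissue{i + 1}"
        for i in range(sc.n_tissues)
    ]
    truth = SyntheticTruth(seed=seed, scenario=sc, tissues=tissues)

    lo, hi = sc.protein_length
    site_proteins = [f"ACP{i:04d}" for i in range(1, sc.n_proteins + 1)]
    bg_proteins = [f"BGP{i:04d}" for i in range(1, sc.n_background_proteins + 1)]
    sequences = {
        p: _random_protein(rng, int(rng.integers(lo, hi + 1)))
        for p in site_proteins + bg_proteins
    }

    # dedicate proteins to each tissue's specific sites
    n_spec_prot = sc.n_specific_proteins_per_tissue
    needed = n_spec_prot * sc.n_tissues
    if needed > sc.n_proteins:
        raise ValueError("not enough proteins for the specific-site plan")
    for i, t in enumerate(tissues):
        truth.specific_proteins[t] = site_proteins[
            i * n_spec_prot: (i + 1) * n_spec_prot
        ]
    common_proteins = site_proteins[needed:]

    def lysines(proteins: list[str]) -> list[tuple[str, int]]:
        return [
            (p, i + 1)
            for p in proteins
            for i, aa in enumerate(sequences[p])
            if aa == "K"
        ]

    n_specific = int(round(sc.n_sites * sc.tissue_specific_fraction))
    per_tissue = n_specific // sc.n_tissues
    chosen: list[tuple[str, int, str, str | None]] = []  # protein,pos,kind,home
    for t in tissues:
        pool = lysines(truth.specific_proteins[t])
        take = min(per_tissue, len(pool))
        idx = rng.choice(len(pool), size=take, replace=False)
        chosen.extend((*pool[i], "specific", t) for i in sorted(idx))
    n_common = sc.n_sites - len(chosen)
    pool = lysines(common_proteins)
    if n_common > len(pool):
        raise ValueError("not enough lysines in common proteins for n_sites")
    idx = rng.choice(len(pool), size=n_common, replace=False)
    chosen.extend((*pool[i], "common", None) for i in sorted(idx))

    # plant the motif residue upstream of a fraction of acetyl sites
    site_positions = {(p, pos) for p, pos, _, _ in chosen}
    offset = sc.motif_position
    planted_flags: dict[tuple[str, int], bool] = {}
    for p, pos, _, _ in chosen:
        planted = False
        j = pos - 1 + offset                    # 0-based target index
        if 0 <= j < len(sequences[p]) and (p, j + 1) not in site_positions:
            if sequences[p][j] != "K" and rng.random() < sc.motif_strength:
                seq = sequences[p]
                sequences[p] = seq[:j] + sc.motif_residue + seq[j + 1:]
                planted = True
        planted_flags[(p, pos)] = planted
    truth.sequences = sequences

    # abundance model per site x tissue
    for p, pos, kind, home in chosen:
        if kind == "specific":
            mean = sc.specific_on_mean + rng.normal(0.0, 0.5)
            tissue_means = {home: mean}
        else:
            base = rng.normal(sc.base_mean, sc.base_sd)
            tissue_means = {
                t: base + rng.normal(0.0, sc.tissue_effect_sd)
                for t in tissues
                if rng.random() < sc.tissue_on_prob
            }
            if not tissue_means:                 # keep every site detectable
                t = tissues[int(rng.integers(len(tissues)))]
                tissue_means = {t: base}
        truth.sites.append(
            SiteTruth(
                collapse_key=f"{p}_K{pos}",
                protein_id=p,
                position=pos,
                flank=_flank(sequences[p], pos),
                kind=kind,
                home_tissue=home,
                tissue_means=tissue_means,
                true_mean=float(np.mean(list(tissue_means.values()))),
                motif_planted=planted_flags[(p, pos)],
            )
        )
    return truth


# --------------------------------------------------------------------------
# file writers


def write_fasta(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in truth.sequences:              # insertion order: stable
            seq = truth.sequences[pid]
            fh.write(f">{pid} synthetic protein\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i: i + 60] + "\n")


def write_design(design: list[SampleDesign], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("run_id\ttissue\tsex\treplicate\tenriched\n")
        for d in design:
            fh.write(
                f"{d.run_id}\t{d.tissue}\t{d.sex}\t{d.replicate}\t{d.enriched}\n"
            )


REPORT_COLUMNS = [
    "PG.ProteinGroups", "PG.Genes", "PTM.SiteLocation",
    "PTM.ModificationTitle", "PTM.SiteProbability", "PTM.CollapseKey",
    "PTM.FlankingRegion", "PG.Qvalue", "EG.Qvalue",
]


def generate_site_report(
    truth: SyntheticTruth,
    design: list[SampleDesign],
    path: str | Path,
    seed: int,
) -> None:
    """Write the PTM site report: latent log-normal intensities with
    left-censored missingness, plus decoy rows failing each filter."""
    sc = truth.scenario
    rng = np.random.default_rng(seed)
    run_meta = [(d.run_id, d.tissue) for d in design]

    def intensity_row(site: SiteTruth) -> list[str]:
        cells = []
        for _, tissue in run_meta:
            mean = site.tissue_means.get(tissue, sc.off_mean)
            x = mean + rng.normal(0.0, sc.replicate_sd)
            p_miss = 1.0 / (
                1.0 + math.exp(-(sc.missing_midpoint - x) / sc.missing_width)
            )
            if rng.random() < p_miss:
                cells.append("")
            else:
                cells.append(f"{2.0 ** x:.6g}")
        return cells

    def meta_row(
        site: SiteTruth, key: str, title: str, prob: float,
        pgq: float, egq: float,
    ) -> list[str]:
        return [
            site.protein_id, site.protein_id.lower(), str(site.position),
            title, f"{prob:.4f}", key, site.flank,
            f"{pgq:.6f}", f"{egq:.6f}",
        ]

    n_decoy = int(round(sc.filter_fail_fraction * sc.n_sites))
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS + [r for r, _ in run_meta]) + "\n")
        for site in truth.sites:
            row = meta_row(
                site, site.collapse_key, "Acetyl (K)",
                rng.uniform(0.76, 1.0),
                rng.uniform(0.0, 0.01), rng.uniform(0.0, 0.01),
            )
            fh.write("\t".join(row + intensity_row(site)) + "\n")
        # decoys: rows that each fail exactly one identification filter
        for mode, tag in (("prob", "DP"), ("qvalue", "DQ"), ("title", "DT")):
            for k in range(n_decoy):
                site = truth.sites[int(rng.integers(len(truth.sites)))]
                prob = rng.uniform(0.76, 1.0)
                pgq = egq = rng.uniform(0.0, 0.01)
                title = "Acetyl (K)"
                if mode == "prob":
                    prob = rng.uniform(0.4, 0.75)
                elif mode == "qvalue":
                    pgq = rng.uniform(0.011, 0.05)
                else:
                    title = "Phospho (STY)"
                row = meta_row(
                    site, f"DECOY_{tag}_{k:04d}", title, prob, pgq, egq
                )
                fh.write("\t".join(row + intensity_row(site)) + "\n")


# --------------------------------------------------------------------------
# ontology and annotations


def generate_ontology_and_annotations(
    truth: SyntheticTruth, seed: int
) -> tuple[list[tuple[str, str]], dict[str, list[str]]]:
    """Tree-plus-shortcut is-a DAG and direct protein annotations.

    One leaf term per tissue annotates exactly that tissue's dedicated
    specific proteins; random filler terms annotate random proteins.
    The DAG is acyclic by construction (every edge points from a deeper
    to a strictly shallower term).
    """
    sc = truth.scenario
    rng = np.random.default_rng(seed)
    root = "GO:0000001"
    branches = [f"GO:00001{i:02d}" for i in range(1, 6)]
    edges: list[tuple[str, str]] = [(b, root) for b in branches]
    # planted tissue terms under a common branch
    planted = {}
    for i, t in enumerate(truth.tissues):
        term = f"GO:00010{i + 1:02d}"
        planted[t] = term
        edges.append((term, branches[0]))
    # filler terms spread under the remaining branches, some with shortcuts
    filler = [f"GO:00020{i:02d}" for i in range(1, sc.n_random_terms + 1)]
    for i, term in enumerate(filler):
        edges.append((term, branches[1 + i % 4]))
        if i % 7 == 0:
            edges.append((term, root))           # shortcut, still acyclic
    truth.planted_terms = planted
    truth.dag_edges = edges

    annotations: dict[str, list[str]] = {}

    def annotate(protein: str, term: str) -> None:
        annotations.setdefault(protein, [])
        if term not in annotations[protein]:
            annotations[protein].append(term)

    for t, term in planted.items():
        for p in truth.specific_proteins[t]:
            annotate(p, term)
    proteins = list(truth.sequences)
    for term in filler:
        size = int(rng.integers(max(2, sc.term_size // 2), sc.term_size + 1))
        for i in rng.choice(len(proteins), size=min(size, len(proteins)),
                            replace=False):
            annotate(proteins[i], term)
    truth.direct_annotations = annotations
    return edges, annotations


def write_edge_list(edges: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# child\tparent\n")
        for child, parent in edges:
            fh.write(f"{child}\t{parent}\n")


def write_annotations(
    annotations: dict[str, list[str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("# protein\tterm\n")
        for protein in annotations:
            for term in annotations[protein]:
                fh.write(f"{protein}\t{term}\n")


# --------------------------------------------------------------------------
# structures


def _helix_coords(n_residues: int) -> np.ndarray:
    """CA trace of an ideal alpha-helix: 2.3 A radius, 1.5 A rise, 100 deg."""
    i = np.arange(n_residues, dtype=float)
    theta = np.deg2rad(100.0) * i
    return np.column_stack(
        (2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i)
    )


def _pdb_atom_line(
    serial: int, name: str, res_name: str, res_seq: int,
    xyz: np.ndarray, b: float, element: str, hetero: bool = False,
) -> str:
    record = "HETATM" if hetero else "ATOM  "
    # PDB v3.3 fixed columns: name 13-16, resName 18-20, chain 22,
    # resSeq 23-26, x/y/z 31-54, occupancy 55-60, B 61-66, element 77-78
    return (
        f"{record}{serial:5d} {name:<4s} {res_name:>3s} A{res_seq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{b:6.2f}"
        f"          {element:>2s}\n"
    )


def generate_structures(
    truth: SyntheticTruth, outdir: str | Path, seed: int
) -> None:
    """Write one PDB per chosen protein: helix CA trace, planted pLDDT in
    the B-factor, and a heteroatom shell burying one lysine per pair."""
    sc = truth.scenario
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # pick proteins that host at least two lysines, preferring site hosts
    site_hosts = sorted({s.protein_id for s in truth.sites})
    chosen: list[str] = []
    for p in site_hosts:
        if truth.sequences[p].count("K") >= 2:
            chosen.append(p)
        if len(chosen) == sc.n_structure_pairs:
            break
    aa3 = {v: k for k, v in {
        "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
        "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
        "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
        "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    }.items()}
    shell_unit = _fibonacci_sphere(40)
    lo, hi = sc.plddt_range
    for p in chosen:
        seq = truth.sequences[p]
        coords = _helix_coords(len(seq))
        k_pos = [i + 1 for i, aa in enumerate(seq) if aa == "K"]
        # keep the pair well separated so the burying shell cannot shadow
        # the exposed lysine
        order = rng.permutation(len(k_pos))
        buried, exposed = k_pos[order[0]], k_pos[order[1]]
        for j in order[1:]:
            if abs(k_pos[j] - buried) >= 4:
                exposed = k_pos[j]
                break
        truth.structure_pairs.append((p, buried, exposed))
        plddt = {
            i + 1: round(float(rng.uniform(lo, hi)), 2)
            for i in range(len(seq))
        }
        truth.plddt[p] = plddt
        with open(outdir / f"{p}.pdb", "w") as fh:
            serial = 1
            for i, aa in enumerate(seq):
                fh.write(_pdb_atom_line(
                    serial, "CA", aa3.get(aa, "UNK"), i + 1,
                    coords[i], plddt[i + 1], "C",
                ))
                serial += 1
            shell = coords[buried - 1] + 2.5 * shell_unit
            for j, xyz in enumerate(shell):
                fh.write(_pdb_atom_line(
                    serial, "C", "DUM", 9000 + j, xyz, 0.0, "C", hetero=True,
                ))
                serial += 1
            fh.write("END\n")


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    return np.column_stack((rho * np.cos(phi), rho * np.sin(phi), z))


# --------------------------------------------------------------------------
# variants


def generate_variant_table(
    truth: SyntheticTruth,
    path: str | Path,
    seed: int,
    association_strength: float | None = None,
) -> None:
    """Mouse-to-human residue variant table with a planted abundance link.

    Pathogenic labels are drawn with probability sigmoid(b * z) where z is
    the site's z-scored true mean abundance and b the association
    strength; strength 0 removes the link.  A small fraction of rows map
    to non-site lysines to exercise unmatched-row accounting.
    """
    sc = truth.scenario
    b = sc.variant_assoc_strength if association_strength is None else (
        association_strength
    )
    rng = np.random.default_rng(seed)
    means = np.array([s.true_mean for s in truth.sites])
    z = (means - means.mean()) / means.std(ddof=0)
    alt_pool = np.array(["Q", "R", "E", "T"])
    alt_probs = np.array([0.35, 0.30, 0.20, 0.15])
    pathogenic: list[str] = []
    rows: list[str] = []
    for site, zi in zip(truth.sites, z):
        if rng.random() >= sc.variant_prob:
            continue
        p_path = 1.0 / (1.0 + math.exp(-b * zi))
        u = rng.random()
        if u < p_path:
            sig = "Pathogenic" if rng.random() < 0.6 else "Likely pathogenic"
            pathogenic.append(site.collapse_key)
        elif rng.random() < sc.variant_uncertain_frac:
            sig = "Uncertain significance"
        else:
            sig = "Benign" if rng.random() < 0.6 else "Likely benign"
        alt = str(rng.choice(alt_pool, p=alt_probs))
        rows.append(
            f"{site.protein_id}\t{site.position}\th{site.protein_id}"
            f"\t{site.position}\tK\t{alt}\t{sig}"
            f"\tsynthetic phenotype {site.collapse_key}"
        )
    # unmatched rows at lysines that are not acetyl sites
    site_positions = {(s.protein_id, s.position) for s in truth.sites}
    n_unmatched = int(round(sc.unmatched_variant_frac * len(rows)))
    all_k = [
        (p, i + 1)
        for p in sorted(truth.sequences)
        for i, aa in enumerate(truth.sequences[p])
        if aa == "K" and (p, i + 1) not in site_positions
    ]
    for i in rng.choice(len(all_k), size=min(n_unmatched, len(all_k)),
                        replace=False):
        p, pos = all_k[i]
        rows.append(
            f"{p}\t{pos}\th{p}\t{pos}\tK\tR\tBenign\tsynthetic unmatched"
        )
    truth.pathogenic_keys = pathogenic
    truth.n_variant_rows = len(rows)
    truth.n_unmatched_variant_rows = min(n_unmatched, len(all_k))
    with open(path, "w") as fh:
        fh.write(
            "mouse_protein\tmouse_position\thuman_protein\thuman_position"
            "\tref_aa\talt_aa\tsignificance\tphenotype\n"
        )
        fh.write("\n".join(rows) + ("\n" if rows else ""))


# --------------------------------------------------------------------------
# one-call scenario


def generate_atlas(
    outdir: str | Path,
    seed: int = 0,
    scenario: AtlasScenario | None = None,
    association_strength: float | None = None,
) -> SyntheticTruth:
    """Generate every pipeline input under ``outdir`` and return the truth.

    Child seeds for each generator are derived deterministically from the
    master seed, so distinct stages use independent streams while the
    whole tree reproduces byte-for-byte from one integer.
    """
    sc = scenario or AtlasScenario()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = generate_design(sc.n_tissues, sc.sexes, sc.replicates, seed)
    truth = generate_truth(sc, seed)
    write_design(design, outdir / "design.tsv")
    write_fasta(truth, outdir / "proteome.fasta")
    generate_site_report(
        truth, design, outdir / "site_report.tsv", seed=(seed * 7 + 1) % (2**31)
    )
    edges, annotations = generate_ontology_and_annotations(
        truth, seed=(seed * 7 + 2) % (2**31)
    )
    write_edge_list(edges, outdir / "ontology_edges.tsv")
    write_annotations(annotations, outdir / "annotations.tsv")
    generate_structures(
        truth, outdir / "structures", seed=(seed * 7 + 3) % (2**31)
    )
    generate_variant_table(
        truth, outdir / "variants.tsv", seed=(seed * 7 + 4) % (2**31),
        association_strength=association_strength,
    )
    truth.to_json(outdir / "truth.json")
    return truth
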