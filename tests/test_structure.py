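"""PDB parsing, pLDDT extraction, Shrake-Rupley SASA, structural joins."""

import math

import numpy as np
import pytest

from acetylatlas.config import PipelineConfig
from acetylatlas.structure import (
    AtomRecord,
    PDBParseError,
    ResidueStructure,
    join_site_structure,
    parse_pdb,
    plddt_per_residue,
    residue_sasa,
    residue_structure_table,
    shrake_rupley,
    sphere_points,
)
from acetylatlas.synthetic_data import _helix_coords, _pdb_atom_line

from conftest import make_record


def atom(x=0.0, y=0.0, z=0.0, element="C", res=1, name="CA", b=0.0,
         res_name="LYS", serial=1, hetero=False):
    return AtomRecord(serial, name, element, res, res_name, (x, y, z), b,
                      hetero)


class TestParsePDB:
    def test_bfactor_field_identity(self, tmp_path):
        line = _pdb_atom_line(1, "CA", "LYS", 7, np.array([1.0, 2.0, 3.0]),
                              91.2, "C")
        (tmp_path / "m.pdb").write_text(line + "END\n")
        (a,) = parse_pdb(tmp_path / "m.pdb")
        assert a.b_factor == 91.2
        assert a.residue_index == 7
        assert a.coords == (1.0, 2.0, 3.0)
        assert a.element == "C"

    def test_hetatm_only_warns(self, tmp_path):
        line = _pdb_atom_line(1, "C", "DUM", 9000, np.zeros(3), 0.0, "C",
                              hetero=True)
        (tmp_path / "m.pdb").write_text(line)
        with pytest.warns(UserWarning, match="no ATOM records"):
            atoms = parse_pdb(tmp_path / "m.pdb")
        assert len(atoms) == 1 and atoms[0].is_hetero

    def test_malformed_line_reports_number(self, tmp_path):
        good = _pdb_atom_line(1, "CA", "ALA", 1, np.zeros(3), 10.0, "C")
        bad = good[:30] + "xxxxxxxx" + good[38:]
        (tmp_path / "m.pdb").write_text(good + bad)
        with pytest.raises(PDBParseError, match="line 2"):
            parse_pdb(tmp_path / "m.pdb")

    def test_multi_model_first_only(self, tmp_path):
        a1 = _pdb_atom_line(1, "CA", "ALA", 1, np.zeros(3), 10.0, "C")
        a2 = _pdb_atom_line(2, "CA", "ALA", 1, np.ones(3), 20.0, "C")
        (tmp_path / "m.pdb").write_text(
            "MODEL     1\n" + a1 + "ENDMDL\nMODEL     2\n" + a2 + "ENDMDL\n"
        )
        with pytest.warns(UserWarning, match="first model"):
            atoms = parse_pdb(tmp_path / "m.pdb")
        assert len(atoms) == 1 and atoms[0].b_factor == 10.0

    def test_synthetic_helix_roundtrip(self, tmp_path):
        coords = _helix_coords(12)
        lines = [
            _pdb_atom_line(i + 1, "CA", "ALA", i + 1, coords[i], 50.0, "C")
            for i in range(12)
        ]
        (tmp_path / "m.pdb").write_text("".join(lines))
        atoms = parse_pdb(tmp_path / "m.pdb")
        assert len(atoms) == 12
        got = np.array([a.coords for a in atoms])
        assert np.allclose(got, coords, atol=1e-3)   # %8.3f precision


class TestPlddt:
    def test_uniform_residue(self):
        atoms = [atom(res=1, b=91.2), atom(res=1, b=91.2, name="CB")]
        assert plddt_per_residue(atoms) == {1: 91.2}

    def test_disagreeing_atoms_mean_with_warning(self):
        atoms = [atom(res=1, b=90.0), atom(res=1, b=92.0, name="CB")]
        with pytest.warns(UserWarning, match="unequal"):
            out = plddt_per_residue(atoms)
        assert out == {1: 91.0}

    def test_empty(self):
        assert plddt_per_residue([]) == {}


class TestShrakeRupley:
    def test_isolated_atom_analytic(self):
        """Every spiral point of a lone atom is accessible, so SASA is
        exactly 4*pi*(r+probe)^2 ~ 120.76 A^2 for r=1.7, probe=1.4."""
        sasa = shrake_rupley([atom()], probe=1.4, n_points=100)
        expected = 4 * math.pi * 3.1**2
        assert sasa[0] == pytest.approx(expected, rel=1e-3)
        assert expected == pytest.approx(120.76, abs=0.01)

    def test_two_distant_atoms_unoccluded(self):
        atoms = [atom(), atom(x=100.0, serial=2)]
        sasa = shrake_rupley(atoms, probe=1.4, n_points=100)
        expected = 4 * math.pi * 3.1**2
        assert np.allclose(sasa, expected, rtol=1e-6)

    def test_engulfed_atom_zero(self):
        # hydrogen (r=1.2) at the center of a big custom sphere: use an
        # S atom (r=1.8) at the same point; expanded S sphere radius 3.2
        # strictly contains every H probe point at radius 2.6
        atoms = [atom(element="H"), atom(element="S", serial=2)]
        sasa = shrake_rupley(atoms, probe=1.4, n_points=200)
        assert sasa[0] == 0.0

    def test_two_sphere_cap_area_closed_form(self):
        """Equal intersecting spheres at distance d: per-atom SASA equals
        2*pi*R*(R + d/2), R = r + probe, within 2% at 960 points."""
        d = 2.0
        R = 1.7 + 1.4
        atoms = [atom(), atom(x=d, serial=2)]
        sasa = shrake_rupley(atoms, probe=1.4, n_points=960)
        expected = 2 * math.pi * R * (R + d / 2)
        assert sasa[0] == pytest.approx(expected, rel=0.02)
        assert sasa[1] == pytest.approx(expected, rel=0.02)

    def test_point_doubling_stability(self):
        a = shrake_rupley([atom()], n_points=480)[0]
        b = shrake_rupley([atom()], n_points=960)[0]
        assert abs(a - b) / b < 1e-3

    def test_monotone_under_occlusion(self):
        lone = shrake_rupley([atom()], n_points=100)[0]
        one = shrake_rupley([atom(), atom(x=3.0, serial=2)], n_points=100)[0]
        two = shrake_rupley(
            [atom(), atom(x=3.0, serial=2), atom(x=-3.0, serial=3)],
            n_points=100,
        )[0]
        assert lone >= one >= two
        assert (np.array([lone, one, two]) >= 0).all()

    def test_matches_biopython_on_helix(self):
        """Independent cross-check: Bio.PDB's Shrake-Rupley on the same
        helix agrees with this implementation per atom within 5%."""
        from Bio.PDB.SASA import ShrakeRupley as BioSR
        from Bio.PDB.StructureBuilder import StructureBuilder

        coords = _helix_coords(30)
        builder = StructureBuilder()
        builder.init_structure("s")
        builder.init_model(0)
        builder.init_chain("A")
        builder.init_seg("    ")
        atoms = []
        for i, xyz in enumerate(coords):
            builder.init_residue("ALA", " ", i + 1, " ")
            builder.init_atom("CA", xyz.astype(float), 0.0, 1.0, " ", " CA ",
                              i + 1, element="C")
            atoms.append(atom(*xyz, res=i + 1, serial=i + 1))
        structure = builder.get_structure()
        BioSR(probe_radius=1.4, n_points=960).compute(structure, level="A")
        theirs = np.array([a.sasa for a in structure.get_atoms()])
        ours = shrake_rupley(atoms, probe=1.4, n_points=960)
        assert np.allclose(ours, theirs, rtol=0.05)

    def test_sphere_points_quasi_uniform(self):
        pts = sphere_points(500)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.linalg.norm(pts.mean(axis=0)) < 0.01


class TestResidueSasa:
    def test_sum_conservation(self):
        atoms = [atom(res=1), atom(x=3, res=1, serial=2),
                 atom(x=10, res=2, serial=3)]
        per_atom = shrake_rupley(atoms, n_points=100)
        per_res = residue_sasa(atoms, per_atom)
        assert sum(per_res.values()) == pytest.approx(per_atom.sum())
        assert per_res[2] == pytest.approx(per_atom[2])

    def test_hetero_atoms_excluded_from_residues(self):
        atoms = [atom(res=1), atom(x=10, res=9000, serial=2, hetero=True)]
        per_atom = shrake_rupley(atoms, n_points=100)
        per_res = residue_sasa(atoms, per_atom)
        assert set(per_res) == {1}


class TestJoinSiteStructure:
    def residues(self, aa="K"):
        return {
            "P1": [ResidueStructure("P1", 10, aa, 91.2, 55.0)],
        }

    def test_lysine_joined(self):
        df = join_site_structure([make_record()], self.residues("K"))
        assert len(df) == 1
        assert df.loc[0, "plddt"] == 91.2
        assert not df.loc[0, "mismatch"]

    def test_non_lysine_flagged(self):
        df = join_site_structure([make_record()], self.residues("A"))
        assert bool(df.loc[0, "mismatch"])

    def test_missing_structure_dropped(self):
        df = join_site_structure([make_record(protein_id="P9")],
                                 self.residues())
        assert df.empty


def test_buried_sites_shift_sasa_distribution_left(tmp_path):
    """Sites planted at shell-buried lysines give a left-shifted SASA
    distribution versus all lysines (one-sided rank-sum)."""
    from scipy.stats import mannwhitneyu

    from acetylatlas.synthetic_data import AtlasScenario, generate_structures, generate_truth

    sc = AtlasScenario(
        n_tissues=2, n_proteins=30, n_background_proteins=0, n_sites=60,
        n_specific_proteins_per_tissue=2, n_structure_pairs=25,
    )
    truth = generate_truth(sc, seed=5)
    generate_structures(truth, tmp_path, seed=5)
    cfg = PipelineConfig(sasa_n_points=60)
    buried, all_lys = [], []
    for protein, b_pos, e_pos in truth.structure_pairs:
        atoms = parse_pdb(tmp_path / f"{protein}.pdb")
        table = residue_structure_table(protein, atoms, cfg)
        for r in table:
            if r.amino_acid == "K":
                all_lys.append(r.sasa)
                if r.residue_index == b_pos:
                    buried.append(r.sasa)
    stat = mannwhitneyu(buried, all_lys, alternative="less")
    assert stat.pvalue < 0.01


def test_compartment_filtered_joins_partition():
    """Mito/nuclear term sets split the joined sites correctly; a protein
    annotated to both compartments contributes to both."""
    from acetylatlas.structure import filter_sites_by_term

    sites = [
        make_record(protein_id="MITO1", collapse_key="m1"),
        make_record(protein_id="NUC1", collapse_key="n1"),
        make_record(protein_id="BOTH1", collapse_key="b1"),
        make_record(protein_id="NONE1", collapse_key="x1"),
    ]
    closed = {
        "MITO1": {"GO:mito"},
        "NUC1": {"GO:nucleus"},
        "BOTH1": {"GO:mito", "GO:nucleus"},
        "NONE1": set(),
    }
    mito = {s.collapse_key for s in filter_sites_by_term(sites, closed, "GO:mito")}
    nuc = {s.collapse_key
           for s in filter_sites_by_term(sites, closed, "GO:nucleus")}
    assert mito == {"m1", "b1"}
    assert nuc == {"n1", "b1"}
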