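"""Data model and coordinate file I/O."""

import numpy as np
import pytest

from crossbeta import (
    Atom,
    BuildSpec,
    Frame,
    Peptide,
    Residue,
    Trajectory,
    build_barrel,
    build_chain,
    end_to_end_distance,
    read_multimodel_pdb,
    reconstruct_amide_h,
    write_multimodel_pdb,
)
from crossbeta.errors import ParseError, StructureError
from crossbeta.io import read_plain, write_plain
from crossbeta.model import frame_has_amide_h
from crossbeta.synthetic import EXTENDED_RISE


def _coords(frame):
    return np.array(
        [a.position for p in frame.peptides for r in p.residues for a in r.atoms]
    )


def _strip_hydrogens(frame):
    for pep in frame.peptides:
        for res in pep.residues:
            res.atoms = [a for a in res.atoms if a.element != "H"]
    return frame


class TestModel:
    def test_atom_heavy_flag_follows_element(self):
        assert Atom("CA", (0, 0, 0)).is_heavy
        assert not Atom("H", (0, 0, 0), element="H").is_heavy

    def test_nonfinite_position_rejected(self):
        with pytest.raises(StructureError):
            Atom("CA", (0, np.nan, 0))

    def test_frame_requires_a_peptide(self):
        with pytest.raises(StructureError):
            Frame(0.0, [])

    def test_trajectory_times_strictly_increasing(self, hexamer_barrel):
        frame, _ = hexamer_barrel
        with pytest.raises(StructureError):
            Trajectory([Frame(1.0, frame.peptides), Frame(1.0, frame.peptides)])

    @pytest.mark.parametrize(
        "a, b, expected",
        [((0, 0, 0), (3, 4, 0), 5.0), ((1, 1, 1), (1, 1, 1), 0.0)],
    )
    def test_end_to_end_distance_examples(self, a, b, expected):
        residues = [
            Residue(0, "ALA", [Atom("CA", a)]),
            Residue(1, "ALA", [Atom("CA", b)]),
        ]
        assert end_to_end_distance(Peptide("A", residues)) == pytest.approx(expected)

    def test_end_to_end_single_residue_is_error(self):
        pep = Peptide("A", [Residue(0, "ALA", [Atom("CA", (0, 0, 0))])])
        with pytest.raises(StructureError):
            end_to_end_distance(pep)

    def test_extended_strand_rise(self):
        pep = build_chain("SSNNFGAILSS", -120.0, 120.0)
        rise = end_to_end_distance(pep) / (len(pep) - 1)
        assert rise == pytest.approx(EXTENDED_RISE, rel=0.05)


class TestAmideReconstruction:
    def test_existing_hydrogens_untouched(self):
        pep = build_chain("SSNN", -120.0, 120.0)
        frame = Frame(0.0, [pep])
        rebuilt = reconstruct_amide_h(frame)
        assert np.allclose(_coords(frame), _coords(rebuilt))

    def test_n_terminus_gets_no_h(self):
        frame = _strip_hydrogens(Frame(0.0, [build_chain("SSNN", -120.0, 120.0)]))
        rebuilt = reconstruct_amide_h(frame)
        assert rebuilt.peptides[0].residues[0].atom("H") is None
        assert frame_has_amide_h(rebuilt)

    def test_proline_never_receives_h(self):
        frame = _strip_hydrogens(Frame(0.0, [build_chain("SSPS", -120.0, 120.0)]))
        rebuilt = reconstruct_amide_h(frame)
        assert rebuilt.peptides[0].residues[2].atom("H") is None
        assert rebuilt.peptides[0].residues[3].atom("H") is not None

    def test_reconstruction_matches_generator_placement(self):
        """On an ideal strand the rebuilt H reproduces the builder's H."""
        reference = build_chain("SSNNFGAILSS", -120.0, 120.0)
        frame = _strip_hydrogens(
            Frame(0.0, [build_chain("SSNNFGAILSS", -120.0, 120.0)])
        )
        rebuilt = reconstruct_amide_h(frame)
        for res_new, res_ref in zip(rebuilt.peptides[0].residues, reference.residues):
            h_new, h_ref = res_new.atom("H"), res_ref.atom("H")
            assert (h_new is None) == (h_ref is None)
            if h_new is not None:
                assert np.linalg.norm(h_new.position - h_ref.position) < 0.05

    def test_missing_backbone_raises(self):
        pep = build_chain("SSNN", -120.0, 120.0)
        pep.residues[2].atoms = [
            a for a in pep.residues[2].atoms if a.name not in ("CA", "H")
        ]
        with pytest.raises(StructureError, match="residue"):
            reconstruct_amide_h(Frame(0.0, [pep]))


class TestPdbIO:
    def test_round_trip_preserves_structure_and_coordinates(self, tmp_path):
        frame, _ = build_barrel(BuildSpec("barrel", 6, seed=3))
        traj = Trajectory([frame])
        path = tmp_path / "barrel.pdb"
        write_multimodel_pdb(traj, path)
        back = read_multimodel_pdb(path)
        assert len(back.frames) == 1
        assert back.frames[0].n_peptides == 6
        names = [
            (p.chain_id, r.name, a.name)
            for p in back.frames[0].peptides
            for r in p.residues
            for a in r.atoms
        ]
        ref = [
            (p.chain_id, r.name, a.name)
            for p in frame.peptides
            for r in p.residues
            for a in r.atoms
        ]
        assert names == ref
        assert np.abs(_coords(back.frames[0]) - _coords(frame)).max() <= 1e-3

    def test_multi_model_order_preserved(self, tmp_path):
        frame, _ = build_barrel(BuildSpec("barrel", 4, seed=3))
        frames = [Frame(float(i) * 2.0, frame.peptides) for i in range(3)]
        path = tmp_path / "traj.pdb"
        write_multimodel_pdb(Trajectory(frames), path)
        back = read_multimodel_pdb(path)
        assert len(back.frames) == 3
        assert [f.time for f in back.frames] == [0.0, 2.0, 4.0]

    def test_biotite_reads_our_files(self, tmp_path):
        """Independent reader oracle: biotite sees the same coordinates."""
        biotite_pdb = pytest.importorskip("biotite.structure.io.pdb")
        frame, _ = build_barrel(BuildSpec("barrel", 5, seed=3))
        path = tmp_path / "b.pdb"
        write_multimodel_pdb(Trajectory([frame]), path)
        stack = biotite_pdb.PDBFile.read(str(path)).get_structure()
        assert np.abs(np.asarray(stack[0].coord) - _coords(frame)).max() <= 1e-3

    def test_malformed_atom_record_names_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        good = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00           N"
        )
        bad = good.replace("0.000   0.000", "0.0xx   0.000")
        path.write_text(f"MODEL     1\n{good}\n{bad}\nENDMDL\nEND\n")
        with pytest.raises(ParseError, match="line 3"):
            read_multimodel_pdb(path)

    def test_inconsistent_models_rejected(self, tmp_path):
        frame4, _ = build_barrel(BuildSpec("barrel", 4, seed=3))
        frame5, _ = build_barrel(BuildSpec("barrel", 5, seed=3))
        p4, p5 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_multimodel_pdb(Trajectory([frame4]), p4)
        write_multimodel_pdb(Trajectory([frame5]), p5)
        merged = (
            p4.read_text().replace("END\n", "")
            + p5.read_text().replace("MODEL     1", "MODEL     2")
        )
        path = tmp_path / "mixed.pdb"
        path.write_text(merged)
        with pytest.raises(StructureError, match="chain composition"):
            read_multimodel_pdb(path)

    def test_missing_hydrogens_flagged_not_fatal(self, tmp_path):
        frame, _ = build_barrel(BuildSpec("barrel", 4, seed=3))
        _strip_hydrogens(frame)
        path = tmp_path / "noh.pdb"
        write_multimodel_pdb(Trajectory([frame]), path)
        traj = read_multimodel_pdb(path)
        assert traj.metadata["needs_amide_h"] is True


class TestPlainDialect:
    def test_round_trip(self, tmp_path):
        frame, _ = build_barrel(BuildSpec("barrel", 4, seed=9))
        path = tmp_path / "t.xyzt"
        write_plain(Trajectory([frame]), path)
        back = read_plain(path)
        assert back.frames[0].n_peptides == 4
        assert np.abs(_coords(back.frames[0]) - _coords(frame)).max() <= 1e-5

    def test_truncated_block_names_line(self, tmp_path):
        frame, _ = build_barrel(BuildSpec("barrel", 4, seed=9))
        path = tmp_path / "t.xyzt"
        write_plain(Trajectory([frame]), path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-5]) + "\n")
        with pytest.raises(ParseError):
            read_plain(path)
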