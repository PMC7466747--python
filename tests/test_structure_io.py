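import gemmi
import numpy as np
import pytest

from ntckit.structure_io import (
    DinucleotideStep,
    EmptyStructureError,
    ResidueRef,
    detect_steps,
    read_structure,
    step_name,
)
from ntckit.synthetic import build_polymer, residues_to_structure

from conftest import random_rotation


@pytest.fixture()
def chain3(refset3):
    """3-residue, fully linked single chain (2 steps)."""
    code = refset3.codes[0]
    return build_polymer([code] * 2, refset3)


def write(structure, path, fmt):
    if fmt == "pdb":
        structure.write_pdb(str(path))
    else:
        structure.make_mmcif_document().write_file(str(path))
    return path


class TestReadStructure:
    def test_fixture_round_trip_both_formats(self, chain3, tmp_path):
        coords = {}
        for fmt in ("pdb", "mmcif"):
            path = write(chain3, tmp_path / f"c.{fmt}", fmt)
            st = read_structure(path, format=fmt)
            assert len(st) == 1
            chain = st[0][0]
            assert len(chain) == 3
            coords[fmt] = np.array([[a.pos.x, a.pos.y, a.pos.z]
                                    for r in chain for a in r])
        assert np.allclose(coords["pdb"], coords["mmcif"], atol=1e-3)

    def test_autodetect(self, chain3, tmp_path):
        path = write(chain3, tmp_path / "c.cif", "mmcif")
        st = read_structure(path, format="auto")
        assert sum(len(ch) for m in st for ch in m) == 3

    def test_missing_and_empty_files(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "nope.cif")
        empty = tmp_path / "empty.pdb"
        empty.write_text("HEADER    NOTHING\nEND\n")
        with pytest.raises(EmptyStructureError):
            read_structure(empty)

    def test_two_models_independently_iterable(self, chain3, tmp_path):
        st2 = chain3.clone()
        model2 = gemmi.Model(2)
        for chain in st2[0]:
            model2.add_chain(chain.clone())
        st2.add_model(model2)
        path = write(st2, tmp_path / "m2.cif", "mmcif")
        back = read_structure(path)
        assert len(back) == 2
        assert [m.num for m in back] == [1, 2]
        assert len(detect_steps(back, model_no=1)) == 2
        assert len(detect_steps(back, model_no=2)) == 2


class TestDetectSteps:
    def test_linked_chain_yields_n_minus_one_steps(self, chain3):
        steps = detect_steps(chain3)
        assert len(steps) == 2
        assert steps[0].second.res_seq == steps[1].first.res_seq

    def test_missing_atom_drops_both_touching_steps(self, chain3):
        st = chain3.clone()
        res2 = st[0][0][1]
        idx = next(i for i, a in enumerate(res2) if a.name == "C1'")
        del res2[idx]
        assert detect_steps(st) == []

    def test_two_chains_never_cross(self, refset3):
        code = refset3.codes[0]
        one = build_polymer([code], refset3)
        st = one.clone()
        chain_b = gemmi.Chain("B")
        for res in one[0][0]:
            moved = res.clone()
            for atom in moved:
                atom.pos = gemmi.Position(atom.pos.x + 50.0, atom.pos.y, atom.pos.z)
            chain_b.add_residue(moved)
        st[0].add_chain(chain_b)
        steps = detect_steps(st)
        assert len(steps) == 2
        assert {s.first.chain_id for s in steps} == {"A", "B"}
        assert all(s.first.chain_id == s.second.chain_id for s in steps)

    def test_linkage_cutoff_enforced(self, chain3):
        st = chain3.clone()
        # push residue 3 away: breaks the O3'(2)-P(3) linkage only
        for atom in st[0][0][2]:
            atom.pos = gemmi.Position(atom.pos.x + 10.0, atom.pos.y, atom.pos.z)
        steps = detect_steps(st)
        assert len(steps) == 1
        assert [steps[0].first.res_seq, steps[0].second.res_seq] == [1, 2]

    def test_rigid_transform_invariance(self, chain3):
        rng = np.random.default_rng(4)
        R = random_rotation(rng)
        t = rng.normal(scale=20.0, size=3)
        moved = chain3.clone()
        for model in moved:
            for chain in model:
                for res in chain:
                    for atom in res:
                        p = R @ np.array([atom.pos.x, atom.pos.y, atom.pos.z]) + t
                        atom.pos = gemmi.Position(*p)
        a = detect_steps(chain3)
        b = detect_steps(moved)
        assert [s.step_name for s in a] == [s.step_name for s in b]

    def test_rewritten_copy_detects_identical_steps(self, chain3, tmp_path):
        original = detect_steps(chain3)
        path = tmp_path / "copy.cif"
        chain3.make_mmcif_document().write_file(str(path))
        reread = detect_steps(read_structure(path))
        assert [s.step_name for s in original] == [s.step_name for s in reread]

    def test_altloc_expansion(self, b_like_step, tmp_path):
        from ntckit.synthetic import step_to_structure

        st = step_to_structure(b_like_step)
        res1 = st[0][0][0]
        # split C1' of residue 1 into two alternate positions
        idx = next(i for i, a in enumerate(res1) if a.name == "C1'")
        alt_b = res1[idx].clone()
        res1[idx].altloc = "A"
        res1[idx].occ = 0.5
        alt_b.altloc = "B"
        alt_b.occ = 0.5
        alt_b.pos = gemmi.Position(alt_b.pos.x + 0.2, alt_b.pos.y, alt_b.pos.z)
        res1.add_atom(alt_b)
        steps = detect_steps(st)
        assert len(steps) == 2
        assert [s.first.altloc for s in steps] == ["A", "B"]
        assert steps[0].step_name != steps[1].step_name


def grammar_oracle(pdb_id, model, multi, chain, r1, r2):
    """Independent implementation of the printed step-name grammar."""
    def seg(res):
        name, alt, num, ins = res
        out = name
        if alt:
            out += "." + alt
        out += str(num)
        if ins:
            out += "." + ins
        return out

    head = pdb_id + (f"-m{model}" if multi else "")
    return f"{head}_{chain}_{seg(r1)}_{seg(r2)}"


class TestStepName:
    def make_step(self, b_like_step, first, second):
        step = DinucleotideStep(first=first, second=second, atoms=b_like_step.atoms)
        return step

    def test_published_example(self, b_like_step):
        step = self.make_step(
            b_like_step,
            ResidueRef(1, "A", "G", 14), ResidueRef(1, "A", "A", 15))
        assert step_name(step, "1q93", multi_model=False) == "1q93_A_G14_A15"

    @pytest.mark.parametrize("model,multi,chain,r1,r2", [
        (2, True, "B", ("DC", "A", 5, ""), ("DG", "", 6, "")),
        (1, False, "A", ("DT", "", 7, "A"), ("DA", "", 8, "")),
        (3, True, "X", ("G", "B", 101, "C"), ("U", "A", 102, "D")),
    ])
    def test_matches_grammar_oracle(self, b_like_step, model, multi, chain, r1, r2):
        step = self.make_step(
            b_like_step,
            ResidueRef(model, chain, r1[0], r1[2], r1[3], r1[1]),
            ResidueRef(model, chain, r2[0], r2[2], r2[3], r2[1]))
        assert step_name(step, "xxxx", multi_model=multi) == \
            grammar_oracle("xxxx", model, multi, chain, r1, r2)

    def test_altloc_example_literal(self, b_like_step):
        step = self.make_step(
            b_like_step,
            ResidueRef(2, "B", "DC", 5, "", "A"), ResidueRef(2, "B", "DG", 6))
        assert step_name(step, "xxxx", multi_model=True) == "xxxx-m2_B_DC.A5_DG6"
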