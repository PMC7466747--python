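import numpy as np
import pytest
from scipy.stats import spearmanr

from ntckit.classify import Assignment, NtCClassifier
from ntckit.diagnostics import (
    connectivity,
    rmsd_band,
    similarity_profile,
    suggest_alternatives,
)
from ntckit.geometry import compute_step_parameters, wrap_angle
from ntckit.pipeline import run_pipeline
from ntckit.reference import NtCClass, ReferenceSet
from ntckit.structure_io import AtomRecord, DinucleotideStep, ResidueRef, detect_steps
from ntckit.synthetic import build_dinucleotide


def step_from_coords(coords, seq1=1):
    from ntckit.structure_io import ATOM_ROLES

    return DinucleotideStep(
        first=ResidueRef(1, "A", "DA", seq1), second=ResidueRef(1, "A", "DA", seq1 + 1),
        atoms={role: AtomRecord(name=role[1], element="C", xyz=xyz)
               for role, xyz in zip(ATOM_ROLES, coords)})


class TestSimilarityProfile:
    def test_representative_step_is_its_own_best_match(self, refset3):
        cls = refset3.classes[0]
        step = step_from_coords(cls.representative)
        profile = similarity_profile(step, compute_step_parameters(step), refset3)
        assert profile.rmsd[cls.ntc] == pytest.approx(0.0, abs=1e-6)
        assert profile.euclid[cls.ntc] == pytest.approx(0.0, abs=1e-6)
        others = [c for c in refset3.codes if c != cls.ntc]
        assert all(profile.rmsd[c] > profile.rmsd[cls.ntc] for c in others)
        assert all(profile.euclid[c] > profile.euclid[cls.ntc] for c in others)

    def test_rank_correlation_euclid_vs_rmsd(self, refset3):
        # over noisy steps the two metrics agree in rank on average
        rng = np.random.default_rng(13)
        rhos = []
        for cls in refset3.classes:
            for _ in range(3):
                t = {n: float(wrap_angle(m + rng.normal(0, 6.0)))
                     for n, m in zip(
                         ("delta1", "epsilon1", "zeta1", "alpha2", "beta2",
                          "gamma2", "delta2", "chi1", "chi2"), cls.means[:9])}
                step = build_dinucleotide(t)
                profile = similarity_profile(step, compute_step_parameters(step), refset3)
                codes = refset3.codes
                rho = spearmanr([profile.euclid[c] for c in codes],
                                [profile.rmsd[c] for c in codes]).statistic
                rhos.append(rho)
        assert np.mean(rhos) > 0.0

    def test_band_thresholds(self):
        assert rmsd_band(0.49) == "green"
        assert rmsd_band(0.5) == "yellow"
        assert rmsd_band(1.0) == "yellow"
        assert rmsd_band(1.01) == "red"


class TestConnectivity:
    def test_homogeneous_polymer_overlaps_perfectly(self, refset3, homopolymer):
        code = refset3.codes[0]
        steps = detect_steps(homopolymer)
        for a, b in zip(steps, steps[1:]):
            ov = connectivity(a, code, b, code, refset3)
            assert ov.c5 <= 1e-6 and ov.o3 <= 1e-6

    def test_wrong_class_produces_positive_distances(self, refset3, homopolymer):
        code, wrong = refset3.codes[0], refset3.codes[1]
        steps = detect_steps(homopolymer)
        ov = connectivity(steps[0], code, steps[1], wrong, refset3)
        assert ov.c5 > 1e-3 and ov.o3 > 1e-3

    def test_non_adjacent_steps_rejected(self, refset3, homopolymer):
        code = refset3.codes[0]
        steps = detect_steps(homopolymer)
        with pytest.raises(ValueError):
            connectivity(steps[0], code, steps[2], code, refset3)

    def test_symmetric_roles_in_pipeline(self, refset3, homopolymer):
        report = run_pipeline(homopolymer, refset3)
        for a, b in zip(report.steps, report.steps[1:]):
            assert a.connectivity.next_C5 == b.connectivity.prev_C5
            assert a.connectivity.next_O3 == b.connectivity.prev_O3

    def test_profile_rmsd_matches_assignment_rmsd(self, refset3, homopolymer):
        report = run_pipeline(homopolymer, refset3)
        for rec in report.steps:
            a = rec.assignment
            assert a.distance_profile.rmsd[a.ntc] == a.rmsd_to_assigned


def twin_refset(refset3):
    """Reference set where the second class is a near-copy of the first."""
    base = refset3.classes[0]
    twin_rep = base.representative + 1e-4
    twin = NtCClass(ntc="TW01", cana=base.cana, means=base.means.copy(),
                    esd=base.esd.copy(), representative=twin_rep)
    far = refset3.classes[2]
    return ReferenceSet(classes=[base, twin, far], version="twin")


class TestSuggestAlternatives:
    def make_assignment(self, refset, step):
        clf = NtCClassifier.from_reference(refset)
        params = compute_step_parameters(step)
        label, nn, votes = clf.predict_detail(params.as_array())[0]
        profile = similarity_profile(step, params, refset)
        a = Assignment(step_name="s", ntc=str(label), cana=refset.cana_of(str(label)),
                       nn_distance=nn, votes=votes, distance_profile=profile,
                       rmsd_to_assigned=profile.rmsd.get(str(label)))
        return a, profile

    def test_uniquely_close_assignment_has_no_alternatives(self, refset3):
        step = step_from_coords(refset3.classes[0].representative)
        a, profile = self.make_assignment(refset3, step)
        assert suggest_alternatives(a, profile, refset3, margin=0.05) == []

    def test_twin_class_listed_first(self, refset3):
        tw = twin_refset(refset3)
        step = step_from_coords(tw.classes[0].representative)
        a, profile = self.make_assignment(tw, step)
        alts = suggest_alternatives(a, profile, tw, margin=0.2)
        assert alts and alts[0] == "TW01"

    def test_ranking_matches_bruteforce_rescoring(self, refset3, homopolymer):
        report = run_pipeline(homopolymer, refset3)
        rec = report.steps[1]
        prev_rec, next_rec = report.steps[0], report.steps[2]
        neighbors = [(prev_rec.step, prev_rec.assignment.ntc, "prev"),
                     (next_rec.step, next_rec.assignment.ntc, "next")]
        margin = 10.0  # admit every class, then check the ordering
        alts = suggest_alternatives(rec.assignment, rec.assignment.distance_profile,
                                    refset3, step=rec.step, neighbors=neighbors,
                                    margin=margin, max_alternatives=10)

        def oracle_cost(code):
            ov_p = connectivity(prev_rec.step, prev_rec.assignment.ntc,
                                rec.step, code, refset3)
            ov_n = connectivity(rec.step, code, next_rec.step,
                                next_rec.assignment.ntc, refset3)
            return ov_p.c5 + ov_p.o3 + ov_n.c5 + ov_n.o3

        profile = rec.assignment.distance_profile
        expected = sorted(
            [c for c in refset3.codes if c != rec.assignment.ntc
             and profile.rmsd[c] <= profile.rmsd[rec.assignment.ntc] + margin],
            key=lambda c: (oracle_cost(c), profile.rmsd[c], c))
        assert alts == expected

    def test_unassigned_step_yields_empty_list(self, refset3):
        from ntckit.classify import DistanceProfile

        a = Assignment(step_name="s", ntc="NANT", cana="NAN", nn_distance=99.0)
        assert suggest_alternatives(a, DistanceProfile(), refset3) == []
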