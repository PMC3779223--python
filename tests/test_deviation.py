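import numpy as np
import pytest

from rebelscan import deviation as dv
from rebelscan import superposition as sp
from rebelscan.structure_io import DomainStructure, MultipleAlignment
from rebelscan.synthetic_data import (
    Perturbation,
    SyntheticSpec,
    generate_core_backbone,
    make_superfamily,
)

from oracles import naive_mean_rmsd, naive_pair_rmsd


def _struct(mid, coords, family="f"):
    return DomainStructure(mid, family,
                           tuple(f"A/ALA{k+1}" for k in range(len(coords))),
                           np.asarray(coords, dtype=float))


def _gapless_aln(ids, length):
    return MultipleAlignment.from_sequences(ids, ["X" * length] * len(ids))


class TestRmsdMatrix:
    def test_identical_identically_placed_members_zero(self):
        core = generate_core_backbone(30, seed=2)
        a, b = _struct("a", core), _struct("b", core)
        M = dv.rmsd_matrix(_gapless_aln(["a", "b"], 30), [a, b])
        assert M[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_translation_in_raw_frame_is_exact(self):
        core = generate_core_backbone(30, seed=2)
        a = _struct("a", core)
        b = _struct("b", core + np.array([0.0, 2.0, 0.0]))
        M = dv.rmsd_matrix(_gapless_aln(["a", "b"], 30), [a, b],
                           ensemble=None)
        assert M[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matrix_matches_independent_per_pair_rescan(
            self, small_superfamily):
        structures, aln, _, _ = small_superfamily
        ens = sp.multiple_superpose(aln, structures)
        M = dv.rmsd_matrix(aln, structures, ens)
        placed = {s.member_id: ens.superposed_coords(s) for s in structures}
        ids = aln.member_ids
        for i in range(len(ids)):
            assert M[i, i] == 0.0
            for j in range(i + 1, len(ids)):
                expected = naive_pair_rmsd(
                    aln.rows[ids[i]], aln.rows[ids[j]],
                    placed[ids[i]], placed[ids[j]])
                assert M[i, j] == pytest.approx(expected, abs=1e-9)
                assert M[i, j] == M[j, i]

    def test_repair_mode_never_exceeds_common_frame(self,
                                                    small_superfamily):
        structures, aln, _, _ = small_superfamily
        ens = sp.multiple_superpose(aln, structures)
        M_common = dv.rmsd_matrix(aln, structures, ens)
        M_repair = dv.rmsd_matrix(aln, structures, ens, mode="repair")
        off = ~np.eye(len(structures), dtype=bool)
        assert np.all(M_repair[off] <= M_common[off] + 1e-9)


class TestMeanRmsd:
    MATRIX = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 6.0], [4.0, 6.0, 0.0]])

    def test_arithmetic_example(self):
        assert dv.mean_rmsd(self.MATRIX, 0) == pytest.approx(3.0)
        assert dv.mean_rmsd(self.MATRIX, 1) == pytest.approx(4.0)
        assert dv.mean_rmsd(self.MATRIX, 2) == pytest.approx(5.0)

    def test_two_member_case_equals_single_pair(self):
        M = np.array([[0.0, 1.7], [1.7, 0.0]])
        assert dv.mean_rmsd(M, 0) == dv.mean_rmsd(M, 1) == 1.7

    def test_matches_naive_double_loop(self, rng):
        A = rng.uniform(0, 10, size=(10, 10))
        M = (A + A.T) / 2
        np.fill_diagonal(M, 0.0)
        M[2, 7] = M[7, 2] = np.nan  # missing pair is excluded
        for i in range(10):
            assert dv.mean_rmsd(M, i) == pytest.approx(
                naive_mean_rmsd(M, i), abs=1e-12)

    def test_all_missing_is_error(self):
        M = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError):
            dv.mean_rmsd(M, 0)


class TestTMScore:
    def test_identity_scores_exactly_one(self):
        core = generate_core_backbone(50, seed=4)
        a = _struct("a", core)
        aln = _gapless_aln(["a", "b"], 50)
        b = _struct("b", core)
        assert dv.tm_score(aln, a, b) == 1.0

    def test_all_pairs_at_d0_closed_form(self):
        # score of a fixed superposition with every distance exactly d0
        # and matched count == L_N is 0.5 by the term formula
        assert dv.tm_terms(np.full(40, 2.5), d0=2.5,
                           target_length=40) == pytest.approx(0.5)

    def test_invariant_to_rigid_motion(self, rng):
        from scipy.spatial.transform import Rotation
        core = generate_core_backbone(45, seed=6)
        noisy = core + rng.normal(scale=1.0, size=core.shape)
        aln = _gapless_aln(["a", "b"], 45)
        base = dv.tm_score(aln, _struct("a", core), _struct("b", noisy))
        R = Rotation.random(random_state=rng)
        moved = _struct("b", R.apply(noisy) + np.array([5.0, -3.0, 8.0]))
        assert dv.tm_score(aln, _struct("a", core), moved) == \
            pytest.approx(base, abs=1e-6)

    def test_symmetric_under_shorter_normalization(self, rng):
        core = generate_core_backbone(40, seed=8)
        noisy = core + rng.normal(scale=1.5, size=core.shape)
        aln = _gapless_aln(["a", "b"], 40)
        ab = dv.tm_score(aln, _struct("a", core), _struct("b", noisy))
        ba = dv.tm_score(aln, _struct("b", noisy), _struct("a", core))
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_d0_floor_for_short_domains(self):
        p = dv.TMScoreParams()
        assert p.d0(10) == pytest.approx(0.5)  # formula negative, floored
        assert p.d0(120) == pytest.approx(
            1.24 * np.cbrt(120 - 15) - 1.8)

    def test_monotone_noise_degrades_tm_and_inflates_rmsd(self):
        # expectation over seeds: more noise on one member -> higher mean
        # RMSD, lower TM
        mean_tm, mean_rmsd = {}, {}
        for sigma in (0.5, 3.0):
            tms, rmsds = [], []
            for seed in range(5):
                core = generate_core_backbone(60, seed=20 + seed)
                rng = np.random.default_rng(100 + seed)
                noisy = core + rng.normal(scale=sigma, size=core.shape)
                aln = _gapless_aln(["a", "b"], 60)
                a, b = _struct("a", core), _struct("b", noisy)
                tms.append(dv.tm_score(aln, a, b))
                _, r = sp.kabsch(a.coords, b.coords)
                rmsds.append(r)
            mean_tm[sigma] = np.mean(tms)
            mean_rmsd[sigma] = np.mean(rmsds)
        assert mean_tm[3.0] < mean_tm[0.5]
        assert mean_rmsd[3.0] > mean_rmsd[0.5]


class TestClassifyOutliers:
    def test_paper_thresholds_on_planted_ensemble(self, planted_superfamily):
        structures, aln, _, truth = planted_superfamily
        ens = sp.multiple_superpose(aln, structures)
        report = dv.classify_outliers(aln, structures, ens)
        assert report.outliers == truth.planted_outliers == {"mem00"}
        assert report.category == "single-outlier"
        assert report.mean_rmsd["mem00"] > 5.5
        assert report.tm_median["mem00"] < 0.5

    def test_clear_inlier_not_called(self, small_superfamily):
        structures, aln, _, _ = small_superfamily
        ens = sp.multiple_superpose(aln, structures)
        report = dv.classify_outliers(aln, structures, ens)
        assert report.outliers == frozenset()
        assert report.category == "no-outlier"

    def test_boundary_exactly_at_cut_is_not_outlier(self):
        # strict inequality at both thresholds
        assert dv.call_outliers({"a": 5.5, "b": 1.0},
                                {"a": 0.4, "b": 0.9}) == frozenset()
        assert dv.call_outliers({"a": 5.51, "b": 1.0},
                                {"a": 0.5, "b": 0.9}) == frozenset()
        assert dv.call_outliers({"a": 6.0, "b": 1.0},
                                {"a": 0.40, "b": 0.9}) == {"a"}

    def test_paper_worked_thresholds(self):
        # mean RMSD 6.0 with median TM 0.40 is an outlier; 3.0/0.80 is not
        assert dv.call_outliers({"a": 6.0}, {"a": 0.40}) == {"a"}
        assert dv.call_outliers({"a": 3.0}, {"a": 0.80}) == frozenset()

    def test_or_rule_flag(self):
        assert dv.call_outliers({"a": 6.0, "b": 1.0},
                                {"a": 0.8, "b": 0.9},
                                rule="or") == {"a"}

    def test_identical_ensemble_no_outliers(self):
        core = generate_core_backbone(36, seed=9)
        structures = [_struct(f"m{i}", core) for i in range(4)]
        aln = _gapless_aln([s.member_id for s in structures], 36)
        ens = sp.multiple_superpose(aln, structures)
        report = dv.classify_outliers(aln, structures, ens)
        assert all(v == pytest.approx(0.0, abs=1e-9)
                   for v in report.mean_rmsd.values())
        assert report.outliers == frozenset()

    def test_category_labels(self):
        assert dv.categorize(0) == "no-outlier"
        assert dv.categorize(1) == "single-outlier"
        assert dv.categorize(2) == "two-outlier"
        assert dv.categorize(5) == "multiple-outlier"


class TestFamilySpecificity:
    def _report(self, outliers, ids):
        n = len(ids)
        return dv.DeviationReport(
            member_ids=tuple(ids), rmsd_matrix=np.zeros((n, n)),
            mean_rmsd={m: 0.0 for m in ids},
            tm_matrix=np.full((n, n), np.nan),
            tm_median={m: np.nan for m in ids},
            outliers=frozenset(outliers),
            category=dv.categorize(len(outliers)),
            rmsd_cut=5.5, tm_cut=0.5)

    def test_two_outliers_one_family_absent_elsewhere(self):
        # mirrors the ADC-like case: both outliers in one family, the 14
        # non-outliers in other families
        ids = [f"d{i}" for i in range(16)]
        fams = {m: "other" for m in ids}
        fams["d0"] = fams["d1"] = "ADC"
        ok, label = dv.family_specificity(
            self._report({"d0", "d1"}, ids), fams)
        assert ok and label == "ADC"

    def test_outliers_in_different_families(self):
        ids = ["a", "b", "c", "d"]
        fams = dict(zip(ids, ["f1", "f2", "f3", "f3"]))
        ok, label = dv.family_specificity(self._report({"a", "b"}, ids),
                                          fams)
        assert not ok and label is None

    def test_family_shared_with_non_outlier(self):
        ids = ["a", "b", "c"]
        fams = {"a": "f1", "b": "f1", "c": "f2"}
        ok, _ = dv.family_specificity(self._report({"a"}, ids), fams)
        assert not ok

    def test_no_outliers(self):
        ids = ["a", "b"]
        ok, _ = dv.family_specificity(
            self._report(set(), ids), {"a": "f", "b": "f"})
        assert not ok


class TestGapRunSummary:
    def test_leading_extension(self):
        aln = MultipleAlignment.from_sequences(
            ["a", "b", "c"],
            ["XXXXXXXXXX" + "XXXX",
             "----------" + "XXXX",
             "----------" + "XXXX"])
        runs = dv.gap_run_summary(aln, "a")
        assert runs == [dv.GapRun("N-terminal-extension", 0, 10)]

    def test_gapless_alignment_empty(self):
        aln = MultipleAlignment.from_sequences(["a", "b"], ["XXXX", "XXXX"])
        assert dv.gap_run_summary(aln, "a") == []

    def test_planted_internal_insertion_recovered(self, small_superfamily):
        _, aln, _, truth = small_superfamily
        runs = dv.gap_run_summary(aln, "mem03")
        ins = [r for r in runs if r.kind == "insertion"]
        assert len(ins) == 1 and ins[0].length == 12
        planted_cols = [c for c, tag in enumerate(truth.column_tags)
                        if tag[0] == "ins"]
        assert ins[0].start == planted_cols[0]

    def test_planted_deletion_recovered(self):
        spec = SyntheticSpec(
            n_members=5, core_length=60, noise_sd=0.2,
            outlier_plan=((1, (Perturbation.deletion(20, 8),)),),
            seed=17)
        _, aln, _, _ = make_superfamily(spec)
        runs = dv.gap_run_summary(aln, "mem01")
        assert runs == [dv.GapRun("deletion", 20, 8)]


class TestCircularPermutation:
    def test_exact_copy_no_signal(self):
        core = generate_core_backbone(60, seed=10)
        a, b = _struct("a", core), _struct("b", core)
        res = dv.circular_permutation_score(a, b)
        assert res.best_shift == 0
        assert res.improvement == pytest.approx(0.0, abs=1e-9)
        assert not res.has_signal

    def test_planted_shift_recovered(self):
        spec = SyntheticSpec(
            n_members=2, core_length=90, noise_sd=0.2,
            outlier_plan=((1, (Perturbation.circular_permutation(30),)),),
            seed=13)
        structures, _, _, _ = make_superfamily(spec)
        res = dv.circular_permutation_score(structures[0], structures[1])
        assert res.best_shift == 60  # rolling by L - 30 undoes the CP
        assert res.has_signal
        assert res.rmsd_best < 1.0

    def test_unrelated_traces_no_signal(self):
        hits = 0
        for seed in range(20):
            a = _struct("a", generate_core_backbone(60, seed=200 + seed))
            b = _struct("b", generate_core_backbone(60, seed=400 + seed))
            if dv.circular_permutation_score(a, b).has_signal:
                hits += 1
        assert hits == 0

    def test_too_short_members_rejected(self):
        from rebelscan.errors import TooFewPointsError
        coords = generate_core_backbone(30, seed=1)[:15]
        with pytest.raises(TooFewPointsError):
            dv.circular_permutation_score(_struct("a", coords),
                                          _struct("b", coords))
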