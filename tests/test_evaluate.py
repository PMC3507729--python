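import numpy as np
import pytest

from helpers import make_prediction, point_fragment
from nucsite.assemble import SitePrediction
from nucsite.evaluate import (GroundTruth, best_threshold, classify_binder,
                              ground_truth_from_complex, kfold_splits, mcc,
                              module_correct, prf_at_threshold, site_correct,
                              topk_performance)


def _truth(positions, module_type="phosphate"):
    return GroundTruth(fragments=[point_fragment(module_type, p)
                                  for p in positions])


class TestModuleCorrect:
    @pytest.mark.parametrize("d,ok", [(4.9, True), (5.0, True), (5.1, False)])
    def test_five_angstrom_boundary(self, d, ok):
        pred = make_prediction("phosphate", [d, 0, 0])
        assert module_correct(pred, _truth([[0, 0, 0]])) is ok

    def test_nearest_same_type_fragment_counts(self):
        pred = make_prediction("phosphate", [10, 0, 0])
        assert module_correct(pred, _truth([[0, 0, 0], [12, 0, 0]]))

    def test_no_same_type_truth_is_false(self):
        pred = make_prediction("nucleobase", [0, 0, 0])
        assert not module_correct(pred, _truth([[0, 0, 0]], "phosphate"))


class TestTopk:
    def _ranked(self, first_correct_rank, n=12):
        preds = []
        for r in range(1, n + 1):
            pos = [0, 0, 0] if r == first_correct_rank else [50 + r, 0, 0]
            preds.append(make_prediction("phosphate", pos, rank=r))
        return preds

    def test_correct_at_rank_one_hits_everywhere(self):
        hits = topk_performance(self._ranked(1), _truth([[0, 0, 0]]))
        assert hits == {1: True, 3: True, 5: True, 10: True}

    def test_correct_at_rank_four(self):
        hits = topk_performance(self._ranked(4), _truth([[0, 0, 0]]))
        assert hits == {1: False, 3: False, 5: True, 10: True}

    def test_never_correct(self):
        hits = topk_performance(self._ranked(99), _truth([[0, 0, 0]]))
        assert hits == {1: False, 3: False, 5: False, 10: False}

    def test_monotone_in_k(self):
        hits = topk_performance(self._ranked(7), _truth([[0, 0, 0]]))
        flags = [hits[k] for k in (1, 3, 5, 10)]
        assert flags == sorted(flags)


class TestPrf:
    def test_perfect(self):
        preds = [make_prediction("phosphate", [0, 0, 0], total_score=10)]
        p, r, f, flags = prf_at_threshold(preds, _truth([[0, 0, 0]]), 5)
        assert (p, r, f) == (1.0, 1.0, 1.0)

    def test_constructed_half_half(self):
        # 4 positives, 2 correct; truth has 2 fragments, 1 covered
        truth = _truth([[0, 0, 0], [100, 0, 0]])
        preds = [make_prediction("phosphate", [0, 0, 0], total_score=10),
                 make_prediction("phosphate", [1, 0, 0], total_score=10),
                 make_prediction("phosphate", [50, 0, 0], total_score=10),
                 make_prediction("phosphate", [60, 0, 0], total_score=10)]
        p, r, f, _ = prf_at_threshold(preds, truth, 5)
        assert (p, r, f) == (0.5, 0.5, 0.5)

    def test_threshold_above_everything_flagged(self):
        preds = [make_prediction("phosphate", [0, 0, 0], total_score=1)]
        p, r, f, flags = prf_at_threshold(preds, _truth([[0, 0, 0]]), 99)
        assert (p, r, f) == (0.0, 0.0, 0.0)
        assert "no-positives" in flags

    def test_f_is_harmonic_mean(self):
        truth = _truth([[0, 0, 0]])
        preds = [make_prediction("phosphate", [0, 0, 0], total_score=10),
                 make_prediction("phosphate", [50, 0, 0], total_score=10),
                 make_prediction("phosphate", [60, 0, 0], total_score=10)]
        p, r, f, _ = prf_at_threshold(preds, truth, 5)
        assert f == pytest.approx(2 * p * r / (p + r))


class TestBestThreshold:
    def _protein(self, correct_scores, wrong_scores):
        truth = _truth([[0, 0, 0]])
        preds = [make_prediction("phosphate", [0, 0, 0], total_score=s)
                 for s in correct_scores]
        preds += [make_prediction("phosphate", [50, 0, 0], total_score=s)
                  for s in wrong_scores]
        return preds, truth

    def test_separable_scores(self):
        train = [self._protein([80, 90], [10, 20])]
        t = best_threshold(train)
        assert 20 < t <= 90
        p, r, f, _ = prf_at_threshold(*train[0], t)
        assert f == 1.0

    def test_matches_exhaustive_scan(self):
        train = [self._protein([80, 30], [40]),
                 self._protein([70], [30, 60]),
                 self._protein([90, 55], [50])]
        t = best_threshold(train)
        scores = sorted({p.total_score for preds, _ in train for p in preds})
        oracle = max(
            scores,
            key=lambda s: (np.mean([prf_at_threshold(pr, tr, s)[2]
                                    for pr, tr in train]), s))
        assert t == oracle

    def test_empty_training_raises(self):
        with pytest.raises(ValueError):
            best_threshold([])


class TestSiteCorrect:
    def _site(self, member_positions, types=("nucleobase", "carbohydrate")):
        mods = [make_prediction(t, p)
                for t, p in zip(types, member_positions)]
        return SitePrediction(architecture="NC", modules=mods,
                              score=sum(m.total_score for m in mods))

    def _nc_truth(self, positions):
        return GroundTruth(fragments=[
            point_fragment("nucleobase", positions[0]),
            point_fragment("carbohydrate", positions[1])])

    def test_coincident_true_under_all_criteria(self):
        site = self._site([[0, 0, 0], [4.5, 0, 0]])
        truth = self._nc_truth([[0, 0, 0], [4.5, 0, 0]])
        for crit in ("all_modules", "ligand_centroid", "rmsd"):
            assert site_correct(site, truth, crit)

    def test_four_and_six_offsets(self):
        site = self._site([[0, 0, 4], [4.5, 0, 6]])
        truth = self._nc_truth([[0, 0, 0], [4.5, 0, 0]])
        assert not site_correct(site, truth, "all_modules")
        # rms of (4, 6) = sqrt(26) ~ 5.10 > 5
        assert not site_correct(site, truth, "rmsd")
        # mean displacement is 5.0, not strictly below 5
        assert not site_correct(site, truth, "ligand_centroid")

    def test_boundary_inclusivity(self):
        site = self._site([[0, 0, 5.0], [4.5, 0, 0]])
        truth = self._nc_truth([[0, 0, 0], [4.5, 0, 0]])
        assert site_correct(site, truth, "all_modules")      # 5.0 inclusive
        assert site_correct(site, truth, "ligand_centroid")  # mean 2.5 < 5
        assert site_correct(site, truth, "rmsd")

    def test_all_modules_implies_rmsd(self, rng):
        for _ in range(20):
            offs = rng.uniform(0, 6, 2)
            site = self._site([[0, 0, offs[0]], [4.5, 0, offs[1]]])
            truth = self._nc_truth([[0, 0, 0], [4.5, 0, 0]])
            if site_correct(site, truth, "all_modules"):
                assert site_correct(site, truth, "rmsd")

    def test_repeated_type_uses_min_cost_bijection(self):
        site = SitePrediction(
            architecture="PP",
            modules=[make_prediction("phosphate", [0, 0, 1]),
                     make_prediction("phosphate", [10, 0, 1])],
            score=0.0)
        truth = _truth([[10, 0, 0], [0, 0, 0]])
        assert site_correct(site, truth, "all_modules")

    def test_architecture_longer_than_truth_raises(self):
        site = SitePrediction(
            architecture="PP",
            modules=[make_prediction("phosphate", [0, 0, 0]),
                     make_prediction("phosphate", [3, 0, 0])],
            score=0.0)
        with pytest.raises(ValueError):
            site_correct(site, _truth([[0, 0, 0]]), "rmsd")


class TestClassifierAndMcc:
    def test_binder_threshold(self):
        assert classify_binder(200.0)
        assert not classify_binder(100.0)
        assert classify_binder(166.33)
        assert not classify_binder(None)

    def test_mcc_perfect(self):
        val, flags = mcc(10, 10, 0, 0)
        assert val == 1.0 and flags == []

    def test_mcc_single_class_flagged_zero(self):
        val, flags = mcc(10, 0, 10, 0)
        assert val == 0.0 and "zero-denominator" in flags

    def test_mcc_hand_arithmetic(self):
        # (6*8 - 2*4) / sqrt(8 * 10 * 10 * 12)
        val, _ = mcc(6, 8, 2, 4)
        assert val == pytest.approx(40 / np.sqrt(9600))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mcc(-1, 0, 0, 0)


class TestGroundTruthAndSplits:
    def test_ground_truth_from_toy(self, amp_complex, defs):
        truth = ground_truth_from_complex(amp_complex, defs)
        assert truth.component_id == "AMP"
        assert {f.module_type for f in truth.fragments} == {
            "nucleobase", "carbohydrate", "phosphate"}

    def test_kfold_partitions(self):
        items = list(range(25))
        splits = kfold_splits(items, k=5, seed=3)
        all_test = sorted(i for _, test in splits for i in test)
        assert all_test == items
        for train, test in splits:
            assert sorted(train + test) == items

    def test_kfold_seeded_determinism(self):
        a = kfold_splits(list(range(30)), seed=4)
        b = kfold_splits(list(range(30)), seed=4)
        assert a == b
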