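import numpy as np
import pytest

from ltm_ood import (CertaintyMap, PhantomSpec, SegModelConfig, UNet3d, fp_count,
                     generate_cohort, label_tp_fp, lesion_scores,
                     predict_prob_stack, train_segmentation, voxel_certainty)
from ltm_ood.segmentation import LesionScore, _majority_vote

rng = np.random.default_rng(3)


# -- certainty ---------------------------------------------------------------

def test_certainty_closed_forms():
    full_agree = np.ones((3, 2, 2, 2))[:, ...] * 1.0       # p = 1 everywhere
    cert = voxel_certainty(full_agree, "ensemble_entropy")
    assert np.allclose(cert.values, 1.0)
    half = np.full((4, 2, 2, 2), 0.5)
    cert = voxel_certainty(half, "ensemble_entropy")
    assert np.allclose(cert.values, 1.0 - np.log(2), atol=1e-12)


def test_certainty_matches_scalar_loop_oracle():
    stack = rng.random((5, 3, 3, 3))
    got = voxel_certainty(stack, "dropout_entropy").values
    for i in range(3):
        for j in range(3):
            for k in range(3):
                p = float(np.mean([stack[m, i, j, k] for m in range(5)]))
                h = 0.0
                for q in (p, 1.0 - p):
                    if q > 0:
                        h -= q * np.log(q)
                assert got[i, j, k] == pytest.approx(1.0 - h, abs=1e-10)


def test_certainty_permutation_invariant_and_maximal_iff_agreement():
    stack = rng.random((4, 3, 3, 3))
    a = voxel_certainty(stack, "ensemble_entropy").values
    b = voxel_certainty(stack[::-1].copy(), "ensemble_entropy").values
    assert np.allclose(a, b)
    assert np.all(a <= 1.0)
    # certainty 1 only where the mean probability is exactly 0 or 1
    pbar = stack.mean(axis=0)
    assert np.array_equal(np.isclose(a, 1.0), (pbar == 0) | (pbar == 1))


def test_softmax_certainty_is_probability_itself():
    stack = rng.random((1, 4, 4, 4))
    cert = voxel_certainty(stack, "softmax")
    assert np.array_equal(cert.values, stack[0])
    with pytest.raises(ValueError):
        voxel_certainty(rng.random((3, 4, 4, 4)), "softmax")
    with pytest.raises(ValueError):
        voxel_certainty(stack * 2.0, "softmax")        # outside [0, 1]


# -- lesions -----------------------------------------------------------------

def _stack_from_mask(mask, n=5, p_fg=0.9):
    base = np.where(mask, p_fg, 0.05)
    return np.repeat(base[None], n, axis=0)


def test_majority_vote_three_of_five():
    stack = np.zeros((5, 1, 1, 1))
    stack[:3] = 0.9
    assert _majority_vote(stack)[0, 0, 0]
    stack[2] = 0.1
    assert not _majority_vote(stack)[0, 0, 0]


def test_lesion_scores_single_and_two_components():
    mask = np.zeros((8, 8, 8), dtype=bool)
    mask[1:3, 1:3, 1:3] = True
    mask[5:7, 5:7, 5:7] = True
    stack = _stack_from_mask(mask)
    cert_vals = np.where(mask, 0.0, 0.5)
    cert_vals[1:3, 1:3, 1:3] = 0.2
    cert_vals[5:7, 5:7, 5:7] = 0.8
    scores = lesion_scores(CertaintyMap(cert_vals, "ensemble_entropy"), stack)
    assert len(scores) == 2
    assert sorted(round(s.confidence, 6) for s in scores) == [0.2, 0.8]
    # per-voxel averaging oracle over labelled voxels
    for s in scores:
        vals = [cert_vals[tuple(v)] for v in s.voxel_set]
        assert s.confidence == pytest.approx(float(np.mean(vals)))
        assert min(vals) <= s.confidence <= max(vals)


def test_lesion_scores_empty_prediction():
    stack = np.full((5, 4, 4, 4), 0.1)
    cert = voxel_certainty(stack, "ensemble_entropy")
    assert lesion_scores(cert, stack) == []


def test_label_tp_fp_overlap_rule():
    gt = np.zeros((8, 8, 8), dtype=bool)
    gt[0:4, 0:4, 0:4] = True
    inside = LesionScore(1, np.argwhere(gt[:2, :2, :2])[:, :], 0.9)
    inside.voxel_set = np.argwhere(np.pad(gt[:2, :2, :2], ((0, 6), (0, 6), (0, 6))))
    scores = [inside]
    label_tp_fp(scores, gt)
    assert scores[0].is_tp                                  # fully inside

    half = np.zeros((8, 8, 8), dtype=bool)
    half[2:6, 0:1, 0:1] = True                              # 2 in, 2 out
    s_half = LesionScore(2, np.argwhere(half), 0.5)
    label_tp_fp([s_half], gt)
    assert s_half.is_tp                                     # exactly 50% counts

    outside = np.zeros((8, 8, 8), dtype=bool)
    outside[6:8, 6:8, 6:8] = True
    s_out = LesionScore(3, np.argwhere(outside), 0.5)
    label_tp_fp([s_out], gt)
    assert not s_out.is_tp


def test_per_lesion_auc_harness_separates_constructed_scores():
    """TP lesions at confidence 0.9 vs FP at 0.1 give AUC 1.0."""
    from ltm_ood import auc
    tp_scores = [0.9, 0.9, 0.9]
    fp_scores = [0.1, 0.1]
    assert auc(tp_scores, fp_scores, "low_is_ood") == 1.0


# -- networks ----------------------------------------------------------------

@pytest.fixture(scope="module")
def lesion_cohort():
    spec = PhantomSpec(grid_shape=(16, 16, 16), lesion_count_range=(1, 2), seed=6)
    return generate_cohort(spec, 8, base_seed=13)


@pytest.fixture(scope="module")
def trained_pair(lesion_cohort):
    cfg = SegModelConfig(features_per_level=(4, 8), epochs=2, seed=1)
    a = train_segmentation(lesion_cohort[:4], cfg)
    from dataclasses import replace
    b = train_segmentation(lesion_cohort[4:], replace(cfg, seed=2))
    return a, b


def test_untrained_model_rejected(lesion_cohort):
    model = UNet3d(SegModelConfig(features_per_level=(4, 8)))
    with pytest.raises(ValueError):
        predict_prob_stack(lesion_cohort[0], model)


def test_single_model_stack_and_probability_range(trained_pair, lesion_cohort):
    a, _ = trained_pair
    stack = predict_prob_stack(lesion_cohort[0], a)
    assert stack.shape == (1, 16, 16, 16)
    assert stack.min() >= 0 and stack.max() <= 1


def test_ensemble_members_disagree_somewhere(trained_pair, lesion_cohort):
    a, b = trained_pair
    stack = predict_prob_stack(lesion_cohort[0], [a, b])
    assert stack.shape[0] == 2
    assert not np.array_equal(stack[0], stack[1])


def test_dropout_passes_identical_when_dropout_zero(trained_pair, lesion_cohort):
    a, _ = trained_pair          # dropout_p = 0: stochastic passes collapse
    stack = predict_prob_stack(lesion_cohort[0], a, n_passes=3, mc_dropout=True)
    assert np.array_equal(stack[0], stack[1]) and np.array_equal(stack[1], stack[2])


def test_mc_dropout_passes_differ_with_dropout(lesion_cohort):
    cfg = SegModelConfig(features_per_level=(4, 8), dropout_p=0.5, epochs=1, seed=3)
    model = train_segmentation(lesion_cohort[:4], cfg)
    stack = predict_prob_stack(lesion_cohort[0], model, n_passes=3, mc_dropout=True)
    assert not np.array_equal(stack[0], stack[1])
    # without MC dropout, inference is deterministic
    det = predict_prob_stack(lesion_cohort[0], model)
    det2 = predict_prob_stack(lesion_cohort[0], model)
    assert np.array_equal(det, det2)


def test_fp_count_fixture_cases():
    gt = np.zeros((8, 8, 8), dtype=bool)
    gt[1:4, 1:4, 1:4] = True

    class _Fake:
        trained = True

        def __init__(self, prob):
            self.prob = prob

        def predict_prob(self, v):
            return self.prob

    empty = _Fake(np.zeros((8, 8, 8)))
    assert fp_count(None, [empty], gt) == 0
    perfect = _Fake(np.where(gt, 0.95, 0.02))
    assert fp_count(None, [perfect], gt) == 0
    spurious = np.where(gt, 0.95, 0.02)
    spurious[6:8, 6:8, 6:8] = 0.95
    assert fp_count(None, [_Fake(spurious)], gt) == 1
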