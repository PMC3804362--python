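"""Label-correlation ranking and combined mode selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphostage.selection import (LabelVector, combine_selections, mode_label_correlation,
                                   select_by_avcr, select_by_correlation, select_modes)
from morphostage.ssm import fit_ssm
from morphostage.synthetic import CohortSpec, generate_cohort
from conftest import cohort_vectors


class TestModeLabelCorrelation:
    def test_parallel_vectors_give_one(self):
        r = np.array([0.0, 1.0, 1.0, 0.0])
        assert np.isclose(mode_label_correlation(r, r), 1.0)

    def test_orthogonal_vectors_give_zero(self):
        assert np.isclose(mode_label_correlation([1.0, -1.0, 0.0, 0.0],
                                                 [0.0, 0.0, 1.0, 1.0]), 0.0)

    def test_hand_computed_example(self):
        # |3 + 4| / sqrt(2 * 30) = 7 / sqrt(60)
        value = mode_label_correlation([1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 1.0, 1.0])
        assert np.isclose(value, 7.0 / np.sqrt(60.0))
        assert np.isclose(value, 0.90369611)

    def test_uncentered_not_pearson(self):
        # constant-shifted coefficients change the uncentered cosine but
        # leave Pearson untouched
        b = np.array([1.0, 2.0, 3.0, 4.0])
        r = np.array([0.0, 0.0, 1.0, 1.0])
        assert not np.isclose(mode_label_correlation(b + 10.0, r),
                              mode_label_correlation(b, r))
        assert np.isclose(mode_label_correlation(b + 10.0, r, centered=True),
                          mode_label_correlation(b, r, centered=True))

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="undefined correlation"):
            mode_label_correlation(np.zeros(4), [0.0, 0.0, 1.0, 1.0])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-100, 100).map(lambda v: 0.0 if abs(v) < 1e-3 else v),
                    min_size=4, max_size=12),
           st.floats(0.01, 50.0), st.sampled_from([-1.0, 1.0]))
    def test_invariant_to_rescaling_and_sign_flip(self, coeffs, scale, sign):
        b = np.asarray(coeffs)
        r = np.zeros(len(b))
        r[: len(b) // 2] = 1.0
        if not np.any(b):
            return
        base = mode_label_correlation(b, r)
        assert np.isclose(mode_label_correlation(sign * scale * b, r), base, atol=1e-10)
        assert 0.0 <= base <= 1.0 + 1e-12


class TestSelectByCorrelation:
    def test_constructed_signal_mode_ranked_first(self):
        rng = np.random.default_rng(20)
        labels = np.array([0.0] * 10 + [1.0] * 10)
        coeffs = rng.normal(size=(20, 6))
        coeffs[:, 3] = labels * 2.0 + 0.01 * rng.normal(size=20)
        top = select_by_correlation(coeffs, labels, top_k=4)
        assert top[0] == 4  # 1-based
        # exhaustive oracle
        corrs = [mode_label_correlation(coeffs[:, j], labels) for j in range(6)]
        assert np.argmax(corrs) == 3

    def test_tie_break_toward_smaller_index(self):
        coeffs = np.tile(np.array([1.0, 2.0, 3.0, 4.0])[:, None], (1, 5))
        top = select_by_correlation(coeffs, [0.0, 0.0, 1.0, 1.0], top_k=3)
        assert top == (1, 2, 3)

    def test_top_k_equal_to_mode_count_returns_all(self):
        rng = np.random.default_rng(21)
        coeffs = rng.normal(size=(8, 3))
        top = select_by_correlation(coeffs, [0, 1] * 4, top_k=3)
        assert sorted(top) == [1, 2, 3]

    def test_excess_top_k_clipped_with_warning(self, caplog):
        rng = np.random.default_rng(22)
        with caplog.at_level("WARNING"):
            top = select_by_correlation(rng.normal(size=(6, 2)), [0, 1, 0, 1, 0, 1], top_k=4)
        assert len(top) == 2
        assert "clipping" in caplog.text

    def test_invariant_to_common_subject_permutation(self):
        rng = np.random.default_rng(23)
        coeffs = rng.normal(size=(12, 5))
        labels = np.array([0.0] * 6 + [1.0] * 6)
        perm = rng.permutation(12)
        assert select_by_correlation(coeffs, labels, 3) == \
            select_by_correlation(coeffs[perm], labels[perm], 3)


class TestSelectByAVCR:
    @pytest.fixture()
    def model(self):
        res = fit_ssm([np.zeros(8) + i for i in range(5)] )
        res.eigenvalues = np.array([4.0, 3.0, 2.0, 1.0])
        res.eigenshapes = np.eye(8)[:4]
        return res

    def test_threshold_prefix(self, model):
        assert select_by_avcr(model, threshold=0.65) == (1, 2)

    def test_threshold_one_returns_all(self, model):
        assert select_by_avcr(model, threshold=1.0) == (1, 2, 3, 4)

    def test_result_is_prefix(self, model):
        for thr in (0.2, 0.5, 0.8, 0.95):
            sel = select_by_avcr(model, threshold=thr)
            assert sel == tuple(range(1, len(sel) + 1))

    def test_count_mode(self, model):
        assert select_by_avcr(model, top_k=2) == (1, 2)

    def test_bad_threshold_rejected(self, model):
        with pytest.raises(ValueError):
            select_by_avcr(model, threshold=1.5)


class TestCombineSelections:
    def test_product_set_ordered_by_correlation(self):
        corrs = {1: 0.1, 2: 0.9, 3: 0.5, 7: 0.8, 9: 0.7}
        sel = combine_selections((1, 2, 3, 4, 5), (2, 7, 3, 9), corrs, final_count=None)
        assert sel.selected == (2, 3)
        assert not sel.fallback_used

    def test_final_count_keeps_strongest(self):
        corrs = {1: 0.1, 2: 0.9, 3: 0.5}
        sel = combine_selections((1, 2, 3), (2, 3), corrs, final_count=1)
        assert sel.selected == (2,)

    def test_disjoint_sets_fall_back_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            sel = combine_selections((1, 2), (5, 6), {1: 0.3, 2: 0.6, 5: 0.9, 6: 0.8})
        assert sel.fallback_used
        assert sel.selected == (2,)  # best correlation inside the AVCR set
        assert "product set" in caplog.text or "fallback" in caplog.text.lower()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            combine_selections((), (1,), {1: 0.5})


class TestStageLinkedModeRecovery:
    def test_selected_mode_tracks_stage_in_most_replicates(self):
        """Combined selection finds the generator's stage-linked joint mode
        in >= 90% of 50 seeded replicates."""
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            cohort = generate_cohort(CohortSpec(
                n_per_stage=(10, 5, 3), n_unstaged_abnormal=0,
                max_rotation_deg=0.0, max_translation_frac=0.0,
                permute_vertices=False, seed=1000 + rep, vertex_count=162))
            x = cohort_vectors(cohort, "joint")
            binary = np.array([s.binary_label for s in cohort], dtype=float)
            stage = np.array([s.stage for s in cohort], dtype=float)
            model = fit_ssm(list(x), layout="joint")
            coeffs = model.coefficient_matrix(x)
            sel = select_modes(model, coeffs, LabelVector(binary), final_count=1)
            # ground truth: mode whose coefficients best track the latent stage
            track = [abs(np.corrcoef(coeffs[:, j], stage)[0, 1]) if coeffs[:, j].std() > 0
                     else 0.0 for j in range(coeffs.shape[1])]
            if sel.selected[0] == int(np.argmax(track)) + 1:
                hits += 1
        assert hits / n_rep >= 0.90
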