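"""Test-retest reliability: ICC(3,1) and item removal."""

import numpy as np
import pandas as pd
import pytest

from leamq import (
    TestRetestConfig,
    ValidationError,
    drop_unreliable_items,
    generate_test_retest,
    icc_per_item,
    icc_test_retest,
)


def _icc31_by_hand(x, y):
    """Independent two-way ANOVA decomposition written out longhand."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    grand = (x.sum() + y.sum()) / (2 * n)
    subj = (x + y) / 2
    occ = np.array([x.mean(), y.mean()])
    ss_subj = 2 * ((subj - grand) ** 2).sum()
    ss_occ = n * ((occ - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum() + ((y - grand) ** 2).sum()
    msb = ss_subj / (n - 1)
    mse = (ss_tot - ss_subj - ss_occ) / (n - 1)
    return (msb - mse) / (msb + mse)


class TestICC:
    def test_perfect_agreement_is_exactly_one(self):
        scores = [3.0, 7.0, 1.0, 9.0, 4.0]
        assert icc_test_retest(scores, scores).icc == 1.0

    def test_additive_shift_keeps_consistency_icc_at_one(self):
        scores = np.array([3.0, 7.0, 1.0, 9.0, 4.0])
        res = icc_test_retest(scores, scores + 2.5)
        assert res.icc == pytest.approx(1.0, abs=1e-12)

    def test_common_rescaling_leaves_icc_unchanged(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        a = icc_test_retest(x, y).icc
        b = icc_test_retest(3.0 * x + 1.0, 3.0 * y + 1.0).icc
        assert a == pytest.approx(b, abs=1e-12)

    def test_six_subject_worked_dataset_matches_hand_anova(self):
        x = [12.0, 15.0, 9.0, 20.0, 14.0, 11.0]
        y = [13.0, 14.0, 10.0, 18.0, 15.0, 10.0]
        res = icc_test_retest(x, y)
        assert res.icc == pytest.approx(_icc31_by_hand(x, y), abs=1e-10)

    def test_matches_pingouin_icc3(self, rng):
        pg = pytest.importorskip("pingouin")
        x, y = rng.normal(10, 3, 30), None
        y = x + rng.normal(0, 2, 30)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(30), 2),
                "rater": np.tile(["t1", "t2"], 30),
                "score": np.column_stack([x, y]).ravel(),
            }
        )
        table = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        expected = float(table.set_index("Type").loc["ICC(C,1)", "ICC"])
        assert icc_test_retest(x, y).icc == pytest.approx(expected, abs=1e-10)

    def test_zero_between_subject_variance_yields_zero_with_warning(self):
        with pytest.warns(UserWarning, match="between-subject"):
            res = icc_test_retest([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.icc == 0.0

    def test_independent_noise_concentrates_near_zero(self, rng):
        iccs = [
            icc_test_retest(rng.normal(size=500), rng.normal(size=500)).icc
            for _ in range(20)
        ]
        assert abs(np.mean(iccs)) < 0.05

    def test_requires_three_subjects(self):
        with pytest.raises(ValidationError):
            icc_test_retest([1.0, 2.0], [1.0, 2.0])


class TestGeneratorAndItemRemoval:
    def test_zero_noise_gives_icc_one(self):
        pairs = generate_test_retest(TestRetestConfig(noise_sd=0.0), seed=3)
        assert icc_test_retest(pairs["test"], pairs["retest"]).icc == pytest.approx(1.0)

    def test_swap_symmetry(self):
        pairs = generate_test_retest(seed=5)
        a = icc_test_retest(pairs["test"], pairs["retest"]).icc
        b = icc_test_retest(pairs["retest"], pairs["test"]).icc
        assert a == pytest.approx(b, abs=1e-12)

    def test_target_icc_from_variance_ratio(self):
        cfg = TestRetestConfig.for_target_icc(0.71)
        assert cfg.target_icc == pytest.approx(0.71, abs=1e-12)

    def test_drop_unreliable_items_boundary_and_identity(self):
        iccs = pd.Series({"a": 0.9, "b": 0.8})
        assert drop_unreliable_items(iccs, 0.5) == (["a", "b"], [])
        iccs = pd.Series({"a": 0.9, "b": 0.31, "c": 0.8, "d": 0.12})
        retained, dropped = drop_unreliable_items(iccs, 0.5)
        assert dropped == ["b", "d"] and retained == ["a", "c"]
        assert drop_unreliable_items(pd.Series(dtype=float), 0.5) == ([], [])

    def test_per_item_iccs_track_targets(self):
        from leamq import generate_item_test_retest

        targets = {"q1": 0.9, "q2": 0.3}
        test, retest = generate_item_test_retest(targets, n_subjects=400, seed=9)
        iccs = icc_per_item(test, retest)
        assert iccs["q1"] > 0.8 and iccs["q2"] < 0.5
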