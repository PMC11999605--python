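"""Detection filter, censoring substitution (incl. reversed KM), subtraction
and WBC normalisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eicostats.datatypes import Metabolite, Panel
from eicostats.permtest import rank_sum
from eicostats.preprocess import (
    SubstitutionScheme,
    baseline_subtract,
    detection_filter,
    km_left_censored,
    substitute_censored,
    wbc_normalize,
)
from tests.conftest import make_matrix


def matrix_with_censoring(n_a, n_b, censored_a, censored_b):
    """10+10-style single-metabolite matrix with given censored counts."""
    n = n_a + n_b
    vals = np.linspace(1.0, 2.0, n).reshape(-1, 1)
    cens = np.zeros((n, 1), dtype=bool)
    cens[:censored_a, 0] = True
    cens[n_a : n_a + censored_b, 0] = True
    vals[cens] = 0.0
    groups = ["A"] * n_a + ["B"] * n_b
    return make_matrix("stimulated", vals, cens), groups


class TestDetectionFilter:
    @pytest.mark.parametrize(
        "ca,cb,kept",
        [
            (8, 8, False),  # "at least 80%" in both groups: excluded at boundary
            (8, 7, True),   # below threshold in one group: kept
            (0, 0, True),
            (10, 7, True),
            (10, 10, False),
        ],
    )
    def test_boundary_rule(self, ca, cb, kept):
        matrix, groups = matrix_with_censoring(10, 10, ca, cb)
        kept_ids, report = detection_filter(matrix, groups, threshold=0.8)
        assert (len(kept_ids) == 1) is kept
        assert report.table.loc["m1", "frac_a"] == ca / 10
        assert report.table.loc["m1", "frac_b"] == cb / 10

    def test_empty_group_raises(self):
        matrix, _ = matrix_with_censoring(4, 0, 0, 0)
        with pytest.raises(ValueError):
            detection_filter(matrix, ["A"] * 4, threshold=0.8)

    @given(
        ca=st.integers(0, 10),
        cb=st.integers(0, 10),
        t1=st.sampled_from([0.3, 0.5, 0.8, 1.0]),
        t2=st.sampled_from([0.3, 0.5, 0.8, 1.0]),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_kept_set_monotone_in_threshold(self, ca, cb, t1, t2):
        """Raising the threshold never excludes a previously kept metabolite."""
        lo, hi = min(t1, t2), max(t1, t2)
        matrix, groups = matrix_with_censoring(10, 10, ca, cb)
        kept_lo, _ = detection_filter(matrix, groups, threshold=lo)
        kept_hi, _ = detection_filter(matrix, groups, threshold=hi)
        assert set(kept_lo) <= set(kept_hi)


class TestSubstitution:
    panel = Panel((Metabolite("m1", frozenset({"COX"}), 0.01),))

    def test_half_lod_value(self):
        mat = make_matrix("baseline", [[0.0], [0.5]], [[True], [False]])
        out = substitute_censored(mat, self.panel, SubstitutionScheme("half_lod"))
        assert out.values.iloc[0, 0] == pytest.approx(0.005)
        assert out.values.iloc[1, 0] == 0.5

    def test_no_censoring_is_identity(self):
        mat = make_matrix("baseline", [[0.3], [0.5]])
        for kind in ("zero", "half_lod", "km"):
            out = substitute_censored(mat, self.panel, SubstitutionScheme(kind))
            pd.testing.assert_frame_equal(out.values, mat.values)

    def test_zero_scheme_writes_exact_zeros(self):
        mat = make_matrix(
            "baseline",
            [[0.002], [0.004], [0.3], [0.5]],
            [[True], [True], [False], [False]],
        )
        out = substitute_censored(mat, self.panel, SubstitutionScheme("zero"))
        assert (out.values.to_numpy() == 0).sum() == 2

    def test_all_censored_km_falls_back_to_zero(self, caplog):
        mat = make_matrix("baseline", [[0.0], [0.0]], [[True], [True]])
        with caplog.at_level("WARNING"):
            out = substitute_censored(mat, self.panel, SubstitutionScheme("km"))
        assert (out.values.to_numpy() == 0).all()
        assert "falls back to zero" in caplog.text

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            SubstitutionScheme("winsor")


def product_limit_oracle(values, censored, lod):
    """Brute-force flip-and-product-limit estimate (independent of lifelines).

    Returns atoms [(value, prob)] with the leftover mass at lod/2.
    """
    y = [(-lod if c else -v, not c) for v, c in zip(values, censored)]
    y.sort()
    n = len(y)
    at_risk = n
    surv = 1.0
    atoms = []
    i = 0
    while i < n:
        t = y[i][0]
        d = sum(1 for yy, ev in y if yy == t and ev)
        c = sum(1 for yy, ev in y if yy == t and not ev)
        if d:
            new = surv * (at_risk - d) / at_risk
            atoms.append((-t, surv - new))
            surv = new
        at_risk -= d + c
        i += d + c
    if surv > 1e-12:
        atoms.append((lod / 2.0, surv))
    return atoms


class TestKaplanMeierLeftCensored:
    def test_no_censoring_mean_is_arithmetic_mean(self):
        vals = np.array([0.2, 0.5, 0.9, 1.4])
        _, mean = km_left_censored(vals, np.zeros(4, bool), lod=0.1)
        assert mean == pytest.approx(vals.mean())

    def test_matches_brute_force_product_limit(self):
        vals = np.array([0.0, 0.2, 0.3, 0.4])
        cens = np.array([True, False, False, False])
        dist, mean = km_left_censored(vals, cens, lod=0.1)
        oracle = product_limit_oracle(vals, cens, 0.1)
        expected_mean = sum(v * p for v, p in oracle)
        assert mean == pytest.approx(expected_mean)
        # hand value: mass 1/4 on each of .2,.3,.4, leftover 1/4 at .05
        assert mean == pytest.approx(0.2375)

    def test_single_uncensored_with_k_censored_hand_computation(self):
        # k=1: product-limit puts 1/2 on v and 1/2 below LOD
        vals = np.array([0.0, 0.6])
        cens = np.array([True, False])
        dist, mean = km_left_censored(vals, cens, lod=0.1)
        probs = dict(zip(dist["value"], dist["prob"]))
        assert probs[0.6] == pytest.approx(0.5)
        assert probs[0.05] == pytest.approx(0.5)
        assert mean == pytest.approx(0.5 * 0.6 + 0.5 * 0.05)

    def test_all_censored_raises(self):
        with pytest.raises(ValueError):
            km_left_censored(np.zeros(3), np.ones(3, bool), lod=0.1)


class TestSubtractNormalize:
    def test_subtraction_arithmetic_and_sign(self):
        stim = make_matrix("stimulated", [[0.5], [0.1]])
        base = make_matrix("baseline", [[0.2], [0.4]])
        diff = baseline_subtract(stim, base)
        assert diff.iloc[0, 0] == pytest.approx(0.3)
        assert diff.iloc[1, 0] == pytest.approx(-0.3)  # negative retained

    def test_identical_matrices_give_zero(self):
        mat = make_matrix("stimulated", [[0.5], [0.1]])
        base = make_matrix("baseline", [[0.5], [0.1]])
        assert (baseline_subtract(mat, base) == 0).all().all()

    def test_subtraction_invariant_to_common_offset(self):
        rng = np.random.default_rng(0)
        a, b = rng.random((4, 3)), rng.random((4, 3))
        c = np.full((4, 3), 0.7)
        d1 = baseline_subtract(make_matrix("stimulated", a + c), make_matrix("baseline", b + c))
        d2 = baseline_subtract(make_matrix("stimulated", a), make_matrix("baseline", b))
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy())

    def test_misaligned_raises(self):
        stim = make_matrix("stimulated", [[0.5], [0.1]])
        base = make_matrix("baseline", [[0.5], [0.1]], subjects=["x1", "x2"])
        with pytest.raises(Exception):
            baseline_subtract(stim, base)

    def test_wbc_division(self):
        from eicostats.datatypes import SampleMeta

        diff = pd.DataFrame({"m1": [0.3, 0.3]}, index=pd.Index(["s1", "s2"], name="subject_id"))
        samples = [SampleMeta("s1", "control", False, 6.0), SampleMeta("s2", "control", False, 7.87)]
        net = wbc_normalize(diff, samples)
        assert net.values.loc["s1", "m1"] == pytest.approx(0.05)
        assert net.values.loc["s2", "m1"] == pytest.approx(0.3 / 7.87)
        assert net.provenance["unit"] == "ng per 10^6 leukocytes"

    def test_equal_wbc_preserves_ranks(self):
        from eicostats.datatypes import SampleMeta

        rng = np.random.default_rng(1)
        diff = pd.DataFrame(
            rng.random((6, 2)), index=pd.Index([f"s{i}" for i in range(6)], name="subject_id")
        )
        samples = [SampleMeta(f"s{i}", "control", False, 5.5) for i in range(6)]
        net = wbc_normalize(diff, samples)
        w_before = rank_sum(diff.iloc[:3, 0], diff.iloc[3:, 0])
        w_after = rank_sum(net.values.iloc[:3, 0], net.values.iloc[3:, 0])
        assert w_before == w_after


@given(const=st.floats(min_value=0.0, max_value=0.99))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_rank_invariance_of_substitution_constant(const):
    """Any common substitution constant strictly below every uncensored value
    yields the identical rank-sum statistic — the mechanism behind the
    equivalence of zero / half-LOD / KM substitution."""
    rng = np.random.default_rng(12)
    vals = rng.uniform(1.0, 2.0, size=12)  # uncensored values all >= 1
    cens = np.zeros(12, bool)
    cens[[0, 3, 7]] = True
    x = np.where(cens, const, vals)
    x0 = np.where(cens, 0.0, vals)
    labels = np.arange(12) < 6
    assert rank_sum(x[labels], x[~labels]) == rank_sum(x0[labels], x0[~labels])
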