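import numpy as np
import pytest

import pafkit as pk
from pafkit.paf_core import _MODEL_REGISTRY

RTOL = 1e-12


class TestLevin:
    @pytest.mark.parametrize(
        "p, r, expected",
        [
            (0.2, 1.6, 0.107),  # smoking worked example
            (0.5, 1.9, 0.310),  # hearing-loss worked example
        ],
    )
    def test_worked_examples_at_printed_precision(self, p, r, expected):
        assert round(pk.levin_paf(p, r), 3) == expected

    @pytest.mark.parametrize("p, r", [(0.0, 3.0), (0.7, 1.0), (0.0, 1.0)])
    def test_zero_when_no_exposure_or_no_excess(self, p, r):
        assert pk.levin_paf(p, r) == 0.0

    def test_protective_rr_is_negative_and_warns(self):
        with pytest.warns(UserWarning, match="prevented"):
            val = pk.levin_paf(0.5, 0.5)
        assert val < 0

    @pytest.mark.parametrize("p, r", [(-0.1, 1.5), (1.1, 1.5), (0.5, 0.0), (0.5, -2.0)])
    def test_domain_errors(self, p, r):
        with pytest.raises(ValueError):
            pk.levin_paf(p, r)


class TestInteractionModels:
    def test_multiplicative_doubly_exposed(self):
        r = pk.individual_risk((1, 1), (1.6, 1.9), "multiplicative")
        assert r.total == pytest.approx(3.04, rel=RTOL)
        assert r.attributable == pytest.approx(2.04, rel=RTOL)

    def test_multiplicative_singly_exposed(self):
        r = pk.individual_risk((1, 0), (1.6, 1.9), "multiplicative")
        assert r.total == pytest.approx(1.60, rel=RTOL)

    def test_additive_doubly_exposed(self):
        r = pk.individual_risk((1, 1), (1.6, 1.9), "additive")
        assert r.total == pytest.approx(2.5, rel=RTOL)
        assert r.attributable == pytest.approx(1.5, rel=RTOL)

    @pytest.mark.parametrize("model", ["multiplicative", "additive"])
    def test_unexposed_is_baseline(self, model):
        r = pk.individual_risk((0, 0, 0), (1.5, 2.0, 4.0), model)
        assert r.total == 1.0 and r.attributable == 0.0

    @pytest.mark.parametrize("model", ["multiplicative", "additive"])
    def test_single_factor_reduces_to_marginal_rr(self, model):
        assert pk.individual_risk((1,), (2.3,), model).total == pytest.approx(2.3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            pk.individual_risk((1, 0), (1.5,), "multiplicative")

    def test_nonpositive_total_rejected_not_clamped(self):
        # additive with strongly protective factors can push T below 0
        with pytest.raises(ValueError, match="non-positive"):
            pk.individual_risk((1, 1, 1), (0.1, 0.1, 0.1), "additive")

    def test_custom_model_contract_enforced_at_registration(self):
        with pytest.raises(ValueError, match="all-zeros"):
            pk.InteractionModel("broken", lambda x, r: np.sum(x * r, axis=-1))
        with pytest.raises(ValueError, match="marginal RR"):
            pk.InteractionModel(
                "broken2", lambda x, r: np.prod(x * (r - 1.0) + 1.0, axis=-1) ** 2
            )

    def test_register_custom_model(self):
        # geometric-mean-exponent rule: between additive and multiplicative
        def combine(x, r):
            return np.prod((x * (r - 1.0) + 1.0) ** 1.0, axis=-1)

        name = "custom_test_model"
        if name not in _MODEL_REGISTRY:
            pk.register_model(name, combine)
        assert pk.get_model(name).joint_rr((1.6, 1.9)) == pytest.approx(3.04)
        with pytest.raises(ValueError, match="already registered"):
            pk.register_model(name, combine)

    def test_unknown_model_name(self):
        with pytest.raises(ValueError, match="unknown interaction model"):
            pk.get_model("nope")


class TestCombinedPAF:
    def test_table2_multiplicative_sums_and_paf(self, table2, table2_specs):
        res = pk.combined_paf(table2, table2_specs, "multiplicative")
        assert res.sum_attributable == pytest.approx(6.24, abs=1e-9)
        assert res.sum_total == pytest.approx(16.24, abs=1e-9)
        assert round(res.paf, 3) == 0.384
        assert res.method == "individual_multiplicative"

    def test_table2_additive_matches_prevalence_form(self, table2, table2_specs):
        res = pk.combined_paf(table2, table2_specs, "additive")
        assert res.paf == pytest.approx(0.57 / 1.57, rel=RTOL)

    @pytest.mark.parametrize("model", ["multiplicative", "additive"])
    def test_single_factor_equals_levin(self, model):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(1, 50))
            col = rng.integers(0, 2, size=(n, 1))
            m = pk.ExposureMatrix(col, ("f",))
            rr = float(1.0 + rng.uniform(0, 3))
            res = pk.combined_paf(m, [pk.RiskFactorSpec("f", rr=rr)], model)
            assert res.paf == pytest.approx(
                pk.levin_paf(m.prevalences()[0], rr), rel=RTOL
            )

    def test_spec_order_is_matched_by_name(self, table2, table2_specs):
        res_fwd = pk.combined_paf(table2, table2_specs, "multiplicative")
        res_rev = pk.combined_paf(table2, table2_specs[::-1], "multiplicative")
        assert res_fwd.paf == res_rev.paf

    def test_mismatched_names_rejected(self, table2):
        specs = [pk.RiskFactorSpec("a", 1.5), pk.RiskFactorSpec("b", 1.5)]
        with pytest.raises(ValueError, match="do not match"):
            pk.combined_paf(table2, specs, "multiplicative")

    def test_protective_rr_needs_flag(self, table2):
        specs = [
            pk.RiskFactorSpec("smoking", 0.8),
            pk.RiskFactorSpec("hearing_loss", 1.9),
        ]
        with pytest.raises(ValueError, match="protective"):
            pk.combined_paf(table2, specs, "multiplicative")
        res = pk.combined_paf(
            table2, specs, "multiplicative", allow_protective=True
        )
        assert any("protective" in note for note in res.notes)

    def test_paf_bounds_when_rr_at_least_one(self):
        rng = np.random.default_rng(5)
        from conftest import random_exposure_matrix, random_specs

        for _ in range(30):
            m = random_exposure_matrix(rng)
            specs = random_specs(rng, m.factor_names)
            for model in ("multiplicative", "additive"):
                paf = pk.combined_paf(m, specs, model).paf
                assert 0.0 <= paf < 1.0


class TestContingencyPAF:
    def test_matches_worked_example(self):
        t = pk.ContingencyTable2x2(1, 1, 4, 4)
        assert round(pk.contingency_paf(t, 1.6, 1.9, "multiplicative").paf, 3) == 0.384
        assert pk.contingency_paf(t, 1.6, 1.9, "additive").paf == pytest.approx(
            5.7 / 15.7, rel=RTOL
        )

    def test_explicit_rxy_uses_general_four_cell_sum(self):
        t = pk.ContingencyTable2x2(1, 1, 4, 4)
        res = pk.contingency_paf(t, 1.6, 1.9, rxy=1.6 * 1.9)
        assert res.method == "custom"
        assert res.paf == pytest.approx(
            pk.contingency_paf(t, 1.6, 1.9, "multiplicative").paf, rel=RTOL
        )

    def test_unit_rrs_give_zero(self):
        t = pk.ContingencyTable2x2(0, 3, 4, 0)
        assert pk.contingency_paf(t, 1.0, 1.0, "multiplicative").paf == 0.0

    def test_invalid_inputs(self):
        t = pk.ContingencyTable2x2(1, 1, 4, 4)
        with pytest.raises(ValueError):
            pk.contingency_paf(t, 0.0, 1.9)
        with pytest.raises(ValueError):
            pk.contingency_paf(t, 1.6, 1.9, rxy=-1.0)


class TestPrevalenceAdditive:
    def test_two_factor_value(self, table2_specs):
        res = pk.prevalence_additive_paf(table2_specs)
        assert res.paf == pytest.approx(0.57 / 1.57, rel=RTOL)

    def test_single_factor_equals_levin(self):
        res = pk.prevalence_additive_paf(
            [pk.RiskFactorSpec("smoking", rr=1.6, prevalence=0.2)]
        )
        assert res.paf == pytest.approx(pk.levin_paf(0.2, 1.6), rel=RTOL)
        assert round(res.paf, 3) == 0.107

    def test_all_unit_rr_gives_zero(self):
        specs = [
            pk.RiskFactorSpec(f"f{j}", rr=1.0, prevalence=0.3) for j in range(4)
        ]
        assert pk.prevalence_additive_paf(specs).paf == 0.0

    def test_missing_prevalence_rejected(self):
        with pytest.raises(ValueError, match="prevalence missing"):
            pk.prevalence_additive_paf([pk.RiskFactorSpec("x", rr=1.5)])


class TestContributionDecomposition:
    def test_additive_split_is_direct(self, table2_specs):
        shares = pk.contribution_decomposition(table2_specs, "prevalence_additive")
        np.testing.assert_allclose(shares, [0.12 / 1.57, 0.45 / 1.57], rtol=RTOL)
        assert shares.sum() == pytest.approx(0.57 / 1.57, rel=RTOL)

    def test_multiplicative_split_is_proportional_to_levin(self, table2, table2_specs):
        shares = pk.contribution_decomposition(
            table2_specs, "individual_multiplicative", exposures=table2
        )
        combined = pk.combined_paf(table2, table2_specs, "multiplicative").paf
        singles = np.array([pk.levin_paf(0.2, 1.6), pk.levin_paf(0.5, 1.9)])
        np.testing.assert_allclose(
            shares, combined * singles / singles.sum(), rtol=RTOL
        )
        assert shares.sum() == pytest.approx(combined, rel=RTOL)

    def test_single_factor_share_is_the_paf_itself(self):
        specs = [pk.RiskFactorSpec("f", rr=1.6, prevalence=0.2)]
        shares = pk.contribution_decomposition(specs, "levin", combined=None)
        # with one factor the proportional split returns the Levin PAF
        assert shares[0] == pytest.approx(pk.levin_paf(0.2, 1.6), rel=RTOL)

    def test_shares_nonnegative_and_sum_to_combined(self, table2, table2_specs):
        for model in ("multiplicative", "additive"):
            res = pk.combined_paf(table2, table2_specs, model)
            assert np.all(res.contributions >= 0)
            assert res.contributions.sum() == pytest.approx(res.paf, rel=1e-10)

    def test_unknown_method_rejected(self, table2_specs):
        with pytest.raises(ValueError, match="unknown method"):
            pk.contribution_decomposition(table2_specs, "what_is_this")
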