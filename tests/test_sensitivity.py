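"""One-way DSA mechanics, threshold bisection, tornado ordering."""

import pytest

from markovcea.constants import MONTHS_PER_YEAR
from markovcea.inputs import (
    DoseTierCost,
    ModelInputs,
    ModelSettings,
    PathError,
    TreatmentArm,
)
from markovcea.scenarios import perturb_inputs
from markovcea.sensitivity import (
    DSAParameter,
    NoCrossingError,
    evaluate_comparison,
    load_dsa_spec,
    run_dsa,
    threshold_search,
    tornado,
)


def _toy_arm(name, cost, utility):
    return TreatmentArm(
        name=name,
        tier_costs=[DoseTierCost(tier=0, cycle_cost=cost)],
        pd_cycle_cost=1.0,
        u_pfs=utility, u_pd=0.5,
        p_prog=0.0, p_pfs_death=0.0, p_pd_death=0.0,
        p_reduce1=0.0, p_reduce2=0.0, p_disc=0.0,
    )


@pytest.fixture()
def linear_toy():
    """One-cycle, no-discount, end-of-cycle model: totals are linear in the
    cycle costs, so the conclusion-flip cutoff solves in closed form."""
    settings = ModelSettings(horizon_cycles=1, annual_discount_rate=0.0,
                             wcc_method="none", wtp=100_000.0)
    arms = [_toy_arm("a", 9_000.0, 0.9), _toy_arm("b", 2_000.0, 0.6)]
    return ModelInputs(settings=settings, arms=arms)


class TestRunDSA:
    def test_base_value_returns_base_decision(self, base_inputs):
        base = evaluate_comparison(
            base_inputs, ("ribociclib", "palbociclib")
        )
        same = evaluate_comparison(
            perturb_inputs(base_inputs, "arms.ribociclib.costs.tier0",
                           factor=1.0),
            ("ribociclib", "palbociclib"),
        )
        assert same == base

    def test_near_zero_bounds_are_trivially_robust(self, base_inputs):
        p = DSAParameter(path="arms.ribociclib.costs.tier0",
                         mode="percent", low=-1e-9, high=1e-9)
        report = run_dsa(base_inputs, [p], ("ribociclib", "palbociclib"))
        (row,) = report.rows
        assert row.conclusion == "robust"
        assert row.result_low.delta_cost == pytest.approx(
            report.base.delta_cost, rel=1e-6
        )

    def test_small_probabilities_are_excluded(self, base_inputs):
        params = [
            DSAParameter(path="arms.palbociclib.probabilities.reduce2",
                         low=-10, high=10),      # base 0.0066 < 1%
            DSAParameter(path="arms.palbociclib.probabilities.prog",
                         low=-10, high=10),      # base 0.0211 >= 1%
        ]
        report = run_dsa(base_inputs, params, ("ribociclib", "palbociclib"))
        assert len(report.rows) == 1
        assert report.rows[0].parameter.path.endswith("prog")
        assert len(report.excluded) == 1
        assert "reduce2" in report.excluded[0][0].path

    def test_probability_clipping_raises_a_diagnostic(self, base_inputs):
        p = DSAParameter(path="arms.ribociclib.probabilities.prog",
                         low=-200, high=10)      # low bound falls below 0
        report = run_dsa(base_inputs, [p], ("ribociclib", "palbociclib"))
        (row,) = report.rows
        assert row.clip_diagnostics
        assert "clipped" in row.clip_diagnostics[0]

    def test_unresolvable_path_raises(self, base_inputs):
        p = DSAParameter(path="arms.ribociclib.costs.tier7", low=-1, high=1)
        with pytest.raises(PathError):
            run_dsa(base_inputs, [p], ("ribociclib", "palbociclib"))

    def test_invalid_parameter_definitions(self):
        with pytest.raises(ValueError):
            DSAParameter(path="x", mode="relative", low=-1, high=1)
        with pytest.raises(ValueError):
            DSAParameter(path="x", low=1, high=1)


class TestThresholdSearch:
    def test_cutoff_matches_algebraic_solution(self, linear_toy):
        # One cycle, no deaths: dC = c_a - c_b, dE = (u_a - u_b)/12.
        # The decision flips where dC / dE = WTP.
        s = linear_toy.settings
        u_gap = (0.9 - 0.6) / MONTHS_PER_YEAR
        cutoff_expected = 2_000.0 + s.wtp * u_gap
        res = threshold_search(
            linear_toy, "arms.a.costs.tier0", ("a", "b"),
            lo=2_100.0, hi=9_000.0,
        )
        assert res.cutoff == pytest.approx(cutoff_expected, rel=1e-6)
        assert res.decision_low != res.decision_high

    def test_flip_is_verified_on_both_sides(self, linear_toy):
        res = threshold_search(
            linear_toy, "arms.a.costs.tier0", ("a", "b"),
            lo=2_100.0, hi=9_000.0,
        )
        for value, expect_preferred in (
            (res.cutoff * 0.999, "a"),
            (res.cutoff * 1.001, "b"),
        ):
            pert = perturb_inputs(linear_toy, "arms.a.costs.tier0",
                                  value=value)
            assert evaluate_comparison(pert, ("a", "b")).preferred \
                == expect_preferred

    def test_no_effect_parameter_has_no_crossing(self, linear_toy):
        # PD is never occupied, so its cost cannot move the decision.
        with pytest.raises(NoCrossingError):
            threshold_search(linear_toy, "arms.a.costs.pd", ("a", "b"),
                             lo=1.0, hi=1e6)

    def test_fixture_flip_exists_for_deep_palbociclib_price_cut(
        self, base_inputs
    ):
        base = 20215.75
        res = threshold_search(
            base_inputs, "arms.palbociclib.costs.tier0",
            ("ribociclib", "palbociclib"), lo=0.5 * base, hi=base,
        )
        assert 0.5 * base < res.cutoff < base


class TestTornado:
    def _params(self):
        return [
            DSAParameter(path="arms.ribociclib.costs.tier0",
                         low=-15, high=15, label="ribo full-dose cost"),
            DSAParameter(path="arms.palbociclib.costs.tier0",
                         low=-15, high=15, label="palbo full-dose cost"),
            DSAParameter(path="arms.letrozole.costs.tier0",
                         low=-15, high=15, label="letrozole cost"),
        ]

    def test_sorted_by_descending_span_and_zero_influence_last(
        self, base_inputs
    ):
        df = tornado(base_inputs, self._params(),
                     ("ribociclib", "palbociclib"))
        spans = df["span"].tolist()
        assert spans == sorted(spans, reverse=True)
        # letrozole's cost cannot move a ribo-vs-palbo comparison
        assert df.iloc[-1]["parameter"] == "letrozole cost"
        assert df.iloc[-1]["span"] == pytest.approx(0.0, abs=1e-6)

    def test_ordering_invariant_under_permutation(self, base_inputs):
        params = self._params()
        df1 = tornado(base_inputs, params, ("ribociclib", "palbociclib"))
        df2 = tornado(base_inputs, list(reversed(params)),
                      ("ribociclib", "palbociclib"))
        assert df1["parameter"].tolist() == df2["parameter"].tolist()

    def test_dominant_bound_is_flagged_not_faked(self, base_inputs):
        # Raising ribociclib's PFS utility by 10% makes it dominant over
        # palbociclib at the high bound: no ICER exists there.
        p = DSAParameter(path="arms.ribociclib.utilities.pfs",
                         low=-10, high=10)
        df = tornado(base_inputs, [p], ("ribociclib", "palbociclib"))
        row = df.iloc[0]
        assert row["icer_high"] is None or row["flag_high"] == "dominant"
        assert row["flag_high"] == "dominant"

    def test_single_parameter_single_bar(self, base_inputs):
        p = DSAParameter(path="arms.ribociclib.costs.tier0",
                         low=-15, high=15)
        df = tornado(base_inputs, [p], ("ribociclib", "palbociclib"))
        assert len(df) == 1
        assert df.iloc[0]["span"] == pytest.approx(
            abs(df.iloc[0]["icer_high"] - df.iloc[0]["icer_low"])
        )

    def test_empty_parameter_list_rejected(self, base_inputs):
        with pytest.raises(ValueError):
            tornado(base_inputs, [], ("ribociclib", "palbociclib"))


def test_packaged_dsa_specs_load(base_inputs):
    from markovcea.inputs import packaged_data_path

    for name, n in (
        ("dsa_ribociclib_vs_palbociclib.yaml", 14),
        ("dsa_ribociclib_vs_abemaciclib.yaml", 15),
    ):
        params = load_dsa_spec(packaged_data_path(name))
        assert len(params) == n
        assert all(p.low < p.high for p in params)
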