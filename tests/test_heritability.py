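import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import _oracles as oracle
from tactqg import (
    ConfigError,
    DegenerateDataError,
    InsufficientDataError,
    Pedigree,
    bartlett_test,
    heritability_from_slope,
    heritability_grid,
    offspring_interaction_model,
    parent_offspring_regression,
    test_slope as slope_tests,
    variance_ratio_test,
)
from tactqg.heritability import grid_frame
from conftest import make_frame


class TestBartlett:
    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        groups = {"a": rng.normal(0, 1, 30), "b": rng.normal(0, 2, 25), "c": rng.normal(0, 1.5, 40)}
        cmp = bartlett_test(groups)
        assert cmp.bartlett_k2 == pytest.approx(oracle.bartlett_k2(list(groups.values())), abs=1e-10)
        assert cmp.bartlett_df == 2

    def test_identical_variances_give_zero(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        cmp = bartlett_test({"a": base, "b": base + 10, "c": base - 5})
        assert cmp.bartlett_k2 == pytest.approx(0.0, abs=1e-12)
        assert cmp.bartlett_p == pytest.approx(1.0)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(DegenerateDataError):
            bartlett_test({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})

    def test_pairwise_included_for_every_pair(self):
        rng = np.random.default_rng(4)
        groups = {t: rng.normal(0, s, 20) for t, s in [("f", 1), ("h", 2), ("j", 1)]}
        cmp = bartlett_test(groups)
        assert set(cmp.pairwise) == {("f", "h"), ("f", "j"), ("h", "j")}


class TestVarianceRatio:
    def test_equal_samples_give_unit_F(self):
        a = np.array([1.0, 2.0, 4.0, 7.0])
        F, df1, df2, p = variance_ratio_test(a, a)
        assert F == 1.0 and df1 == df2 == 3
        assert p == pytest.approx(1.0)

    def test_reciprocity(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 15), rng.normal(0, 2, 20)
        Fa, d1a, d2a, pa = variance_ratio_test(a, b)
        Fb, d1b, d2b, pb = variance_ratio_test(b, a)
        assert Fa == pytest.approx(1 / Fb)
        assert (d1a, d2a) == (d2b, d1b)
        assert pa == pytest.approx(pb)

    def test_is_ratio_of_sample_variances(self):
        a = np.array([500.0, 520.0, 560.0, 610.0])
        b = np.array([420.0, 425.0, 431.0])
        F, _, _, _ = variance_ratio_test(a, b)
        assert F == pytest.approx(a.var(ddof=1) / b.var(ddof=1), abs=1e-14)


def _po_pedigree(parent_lengths, offspring_fn, parent_tactic="female", offspring_tactic="female"):
    """One parent per family, one offspring each with length offspring_fn(parent)."""
    rows = []
    psex = "female" if parent_tactic == "female" else "male"
    for i, pl in enumerate(parent_lengths):
        rows.append((f"P{i}", psex, parent_tactic, 2002, pl, 1, None, None, "parent"))
    # a co-parent of the opposite sex so links resolve
    if psex == "female":
        rows.append(("X0", "male", "hooknose", 2002, 700.0, len(parent_lengths), None, None, "parent"))
    else:
        rows.append(("X0", "female", "female", 2002, 700.0, len(parent_lengths), None, None, "parent"))
    osex = "female" if offspring_tactic == "female" else "male"
    for i, pl in enumerate(parent_lengths):
        dam, sire = (f"P{i}", "X0") if psex == "female" else ("X0", f"P{i}")
        rows.append((f"O{i}", osex, offspring_tactic, 2004, offspring_fn(pl), 0, dam, sire, "offspring"))
    return Pedigree(make_frame(rows))


class TestParentOffspringRegression:
    def test_perfect_resemblance_slope_one(self):
        ped = _po_pedigree([600.0, 650.0, 700.0, 750.0], lambda l: l)
        b, se, n = parent_offspring_regression(ped, "female", "female")
        assert b == pytest.approx(1.0, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-10)
        assert n == 4

    def test_matches_explicit_sum_oracle(self, large_ped):
        b, se, n = parent_offspring_regression(large_ped, "hooknose", "hooknose")
        df = large_ped.frame
        sires = df[df["generation"].eq("parent") & df["tactic"].eq("hooknose")]
        sons = df[df["generation"].eq("offspring") & df["tactic"].eq("hooknose")]
        sons = sons[sons["sire_id"].isin(set(sires["id"]))]
        y = sons.groupby("sire_id")["length_mm"].mean()
        x = sires.set_index("id").loc[y.index, "length_mm"]
        b0, se0 = oracle.ols_slope_se(x, y)
        assert b == pytest.approx(b0, abs=1e-10)
        assert se == pytest.approx(se0, abs=1e-10)
        assert n == len(y)

    def test_mean_offspring_per_parent_one_point_per_family(self):
        # two offspring of one dam average into a single regression point
        rows = [
            ("D1", "female", "female", 2002, 600.0, 2, None, None, "parent"),
            ("D2", "female", "female", 2002, 700.0, 2, None, None, "parent"),
            ("D3", "female", "female", 2002, 800.0, 1, None, None, "parent"),
            ("S1", "male", "hooknose", 2002, 700.0, 5, None, None, "parent"),
            ("O1", "female", "female", 2004, 640.0, 0, "D1", "S1", "offspring"),
            ("O2", "female", "female", 2004, 660.0, 0, "D1", "S1", "offspring"),
            ("O3", "female", "female", 2004, 700.0, 0, "D2", "S1", "offspring"),
            ("O4", "female", "female", 2004, 760.0, 0, "D3", "S1", "offspring"),
        ]
        b, se, n = parent_offspring_regression(Pedigree(make_frame(rows)), "female", "female")
        assert n == 3
        b0, _ = oracle.ols_slope_se([600, 700, 800], [650, 700, 760])
        assert b == pytest.approx(b0, abs=1e-12)

    def test_insufficient_families_names_cell(self, tiny_ped):
        with pytest.raises(InsufficientDataError, match="jack~female"):
            parent_offspring_regression(tiny_ped, "female", "jack")


class TestHeritabilityAlgebra:
    @pytest.mark.parametrize(
        "b_op,ratio,expected",
        [
            (-0.070, math.sqrt(0.415), -0.090),   # dam -> hooknose son, corrected
            (-0.045, math.sqrt(2.77), -0.150),    # hooknose sire -> jack son, corrected
            (-0.051, 1 / math.sqrt(2.77), -0.061),  # jack sire -> hooknose son, corrected
        ],
    )
    def test_corrected_cells_to_three_decimals(self, b_op, ratio, expected):
        est = heritability_from_slope(b_op, 0.1, sigma_p=ratio, sigma_o=1.0, corrected=True)
        assert round(est.h2, 3) == expected

    def test_uncorrected_doubling(self):
        est = heritability_from_slope(0.25, 0.1, sigma_p=50, sigma_o=60, corrected=False)
        assert est.h2 == pytest.approx(0.5)
        assert est.correction == 1.0
        assert est.null_slope_h2_one == pytest.approx(0.5)

    def test_zero_slope_gives_zero_h2(self):
        est = heritability_from_slope(0.0, 0.1, sigma_p=40, sigma_o=70, corrected=True)
        assert est.h2 == 0.0

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ConfigError):
            heritability_from_slope(0.1, 0.1, sigma_p=0.0, sigma_o=1.0, corrected=True)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        b=st.floats(-1, 1), se=st.floats(0.001, 1),
        sp=st.floats(1, 200), so=st.floats(1, 200),
        corrected=st.booleans(),
    )
    def test_algebraic_invariants(self, b, se, sp, so, corrected):
        """h2 = 2 b corr, ci = 3.92 se corr, null slope = 0.5/corr hold exactly,
        and a more-variable offspring tactic shrinks |h2| below |2b|."""
        est = heritability_from_slope(b, se, sp, so, corrected, n_families=50)
        corr = sp / so if corrected else 1.0
        assert est.h2 == pytest.approx(2 * b * corr, rel=1e-12)
        assert est.ci95 == pytest.approx(3.92 * se * corr, rel=1e-3)
        assert est.null_slope_h2_one == pytest.approx(0.5 / corr, rel=1e-12)
        if corrected and so > sp and b != 0:
            assert abs(est.h2) < abs(2 * b)


class TestSlopeTests:
    def test_null_value_equal_to_slope(self):
        res = slope_tests(0.3, 0.05, 40, null_value=0.3)
        assert res["F"] == pytest.approx(0.0)
        assert res["p_null"] == pytest.approx(1.0)

    def test_printed_hooknose_cell(self):
        # slope 0.433 +/- 0.080 against the 0.5 null: F near 0.7
        res = slope_tests(0.433, 0.080, 171, null_value=0.5)
        assert round(res["F"], 1) == 0.7
        assert res["df_F"] == (1, 169)

    def test_f_equals_t_squared_for_zero_null(self):
        res = slope_tests(0.21, 0.07, 30, null_value=0.0)
        assert res["F"] == pytest.approx(res["t"] ** 2, rel=1e-12)

    def test_preconditions(self):
        with pytest.raises(DegenerateDataError):
            slope_tests(0.1, 0.0, 30, 0.5)
        with pytest.raises(InsufficientDataError):
            slope_tests(0.1, 0.1, 2, 0.5)


@pytest.fixture(scope="module")
def grid(large_ped):
    return heritability_grid(large_ped)


class TestGrid:
    def test_nine_cells_present(self, grid):
        tactics = {"female", "hooknose", "jack"}
        assert set(grid) == {(p, o) for p in tactics for o in tactics}

    def test_diagonal_cells_never_corrected(self, grid):
        for t in ("female", "hooknose", "jack"):
            assert not grid[(t, t)].corrected
            assert grid[(t, t)].correction == 1.0

    def test_correction_flag_follows_variance_test(self, grid, large_ped):
        df = large_ped.frame
        for (pt, ot), est in grid.items():
            if pt == ot or isinstance(est, str):
                continue
            xp = df[df["generation"].eq("parent") & df["tactic"].eq(pt)]["length_mm"]
            xo = df[df["generation"].eq("offspring") & df["tactic"].eq(ot)]["length_mm"]
            _, _, _, p = variance_ratio_test(xp, xo)
            assert est.corrected == (p < 0.05)
            if est.corrected:
                assert est.correction == pytest.approx(
                    xp.std(ddof=1) / xo.std(ddof=1), rel=1e-12)

    def test_grid_is_asymmetric_by_construction(self, grid):
        a = grid[("female", "jack")]
        b = grid[("jack", "female")]
        assert a.n_families != b.n_families or a.b_op != b.b_op

    def test_empty_cells_report_reason(self, tiny_ped):
        grid = heritability_grid(tiny_ped)
        assert isinstance(grid[("jack", "jack")], str)

    def test_grid_frame_layout(self, grid):
        table = grid_frame(grid)
        assert len(table) == 9
        ok = table["note"].eq("")
        assert (table.loc[ok, "h2"] == pytest.approx(
            2 * table.loc[ok, "b_op"] * table.loc[ok, "correction"])) is not False


class TestOffspringInteractionModel:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        rows = []
        n = 40
        dams = 600 + 50 * rng.standard_normal(n)
        sires = 650 + 60 * rng.standard_normal(n)
        for i in range(n):
            rows.append((f"D{i}", "female", "female", 2002, dams[i], 1, None, None, "parent"))
            rows.append((f"S{i}", "male", "hooknose", 2002, sires[i], 1, None, None, "parent"))
        for i in range(n):
            tactic = "female" if i % 2 == 0 else "hooknose"
            sex = "female" if tactic == "female" else "male"
            y = 100 + 0.3 * dams[i] + (0.5 if tactic == "hooknose" else 0.2) * sires[i] + rng.normal(0, 5)
            rows.append((f"O{i}", sex, tactic, 2004, y, 0, f"D{i}", f"S{i}", "offspring"))
        ped = Pedigree(make_frame(rows))
        fit = offspring_interaction_model(ped)
        # independent design: treatment coding, "female" as reference level
        dummy = np.array([0.0 if i % 2 == 0 else 1.0 for i in range(n)])
        y = ped.frame.set_index("id").loc[[f"O{i}" for i in range(n)], "length_mm"].to_numpy()
        X = np.column_stack([np.ones(n), dummy, dams, sires, dams * dummy, sires * dummy])
        beta, _ = oracle.ols_normal_equations(X, y)
        got = fit.params
        assert got["Intercept"] == pytest.approx(beta[0], abs=1e-8)
        assert got["C(tactic)[T.hooknose]"] == pytest.approx(beta[1], abs=1e-8)
        assert got["dam_length"] == pytest.approx(beta[2], abs=1e-8)
        assert got["sire_length"] == pytest.approx(beta[3], abs=1e-8)
        assert got["dam_length:C(tactic)[T.hooknose]"] == pytest.approx(beta[4], abs=1e-8)
        assert got["sire_length:C(tactic)[T.hooknose]"] == pytest.approx(beta[5], abs=1e-8)
        assert fit.df_resid == n - 6

    def test_anova_terms_in_model_order(self, large_ped):
        fit = offspring_interaction_model(large_ped)
        terms = list(fit.anova.index)
        assert terms[:3] == ["dam_length", "sire_length", "C(tactic)"] or \
            terms[0] == "dam_length"  # sequential order starts with dam length
        assert "Residual" in terms[-1]

    def test_single_offspring_tactic_rejected(self):
        rows = [
            ("D1", "female", "female", 2002, 600.0, 1, None, None, "parent"),
            ("S1", "male", "hooknose", 2002, 700.0, 1, None, None, "parent"),
            ("O1", "female", "female", 2004, 640.0, 0, "D1", "S1", "offspring"),
            ("O2", "female", "female", 2004, 660.0, 0, "D1", "S1", "offspring"),
        ]
        with pytest.raises(DegenerateDataError):
            offspring_interaction_model(Pedigree(make_frame(rows)))
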