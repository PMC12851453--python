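import itertools

import numpy as np
import pytest
from scipy import stats

from culttrans import (
    Biases,
    GeneratorConfig,
    ParentalTypeTable,
    bootstrap_ci,
    classify_parental_type,
    estimate_biases,
    filter_networks,
    generate_binary_population,
    opposite_table,
    transmission_table,
    triangle_coordinates,
)
from conftest import binary_net, make_table, table_with_counts

# printed worked-example counts for the Environmentalism factor
ENV_P = {"VH": 156, "Vh": 119, "vH": 122, "vh": 185}
ENV_N = {"VH": 111, "Vh": 61, "vH": 66, "vh": 71}


# -- classification ----------------------------------------------------

@pytest.mark.parametrize(
    "v,h,expected", [(1, 1, "VH"), (1, 0, "Vh"), (0, 1, "vH"), (0, 0, "vh")]
)
def test_classify_parental_type(v, h, expected):
    assert classify_parental_type(v, h) == expected


def test_classify_undefined_component_directs_to_filter():
    with pytest.raises(ValueError, match="filter"):
        classify_parental_type(float("nan"), 1)


# -- transmission tables -----------------------------------------------

def test_worked_example_coefficients():
    tab = ParentalTypeTable.from_counts(ENV_P, ENV_N, factor="Environmentalism")
    assert round(tab.B["VH"], 3) == 0.712
    assert round(tab.B["Vh"], 3) == 0.513
    assert round(tab.B["vH"], 3) == 0.541
    assert round(tab.B["vh"], 3) == 0.384
    assert tab.n_networks == 582


def test_transmission_table_counts_exact():
    table = table_with_counts({"VH": 5, "Vh": 4, "vH": 3, "vh": 2},
                              {"VH": 4, "Vh": 2, "vH": 0, "vh": 1})
    tab = transmission_table(table, "F")
    assert tab.P.to_dict() == {"VH": 5, "Vh": 4, "vH": 3, "vh": 2}
    assert tab.N.to_dict() == {"VH": 4, "Vh": 2, "vH": 0, "vh": 1}
    assert tab.B["vH"] == 0.0
    # bit-identical on rerun
    tab2 = transmission_table(table, "F")
    assert tab.data.equals(tab2.data)


def test_transmission_table_empty_type_flagged():
    table = table_with_counts({"VH": 3, "Vh": 0, "vH": 0, "vh": 2},
                              {"VH": 2, "Vh": 0, "vH": 0, "vh": 1})
    tab = transmission_table(table, "F")
    assert np.isnan(tab.B["Vh"]) and np.isnan(tab.B["vH"])


def test_transmission_requires_filtered_networks():
    rows = [("n1", "student", "F", 0.5), ("n1", "mother", "F", 0.2)]  # no friend
    with pytest.raises(ValueError, match="parent_and_friend"):
        transmission_table(make_table(rows), "F")


def test_transmission_rejects_unknown_factor_and_empty_table():
    table = table_with_counts({"VH": 1, "Vh": 1, "vH": 1, "vh": 1},
                              {"VH": 1, "Vh": 0, "vH": 1, "vh": 0})
    with pytest.raises(ValueError, match="not present"):
        transmission_table(table, "G")


def test_tied_couple_counts_as_having_trait():
    """A couple split one-each-way averages to 0, and 0 maps to trait=1."""
    rows = [
        ("n1", "student", "F", 1.0),
        ("n1", "mother", "F", 1.0),
        ("n1", "father", "F", -1.0),
        ("n1", "friend1", "F", -1.0),
    ]
    tab = transmission_table(make_table(rows), "F")
    assert tab.P["Vh"] == 1  # vertical tie -> trait, friend without


# -- opposite-trait complementarity ------------------------------------

def test_opposite_table_worked_example():
    trait = ParentalTypeTable.from_counts(ENV_P, ENV_N, factor="Environmentalism")
    opp = opposite_table(trait)
    assert opp.polarity == "opposite"
    assert round(opp.B["VH"], 3) == 0.616  # 1 - B_vh
    assert round(opp.B["vh"], 3) == 0.288  # 1 - B_VH
    assert opp.P["VH"] == 185 and opp.N["VH"] == 114


def test_opposite_is_involution_and_complementary():
    trait = ParentalTypeTable.from_counts(ENV_P, ENV_N)
    opp = opposite_table(trait)
    back = opposite_table(opp)
    assert back.data[["P", "N"]].equals(trait.data[["P", "N"]])
    inverse = {"VH": "vh", "vh": "VH", "Vh": "vH", "vH": "Vh"}
    for i, j in inverse.items():
        assert opp.B[i] == pytest.approx(1 - trait.B[j])


def test_opposite_fixed_point_at_half():
    tab = ParentalTypeTable.from_counts(
        {"VH": 2, "Vh": 2, "vH": 2, "vh": 2}, {"VH": 1, "Vh": 1, "vH": 1, "vh": 1}
    )
    assert opposite_table(tab).B["VH"] == pytest.approx(0.5)


# -- bootstrap ---------------------------------------------------------

def test_bootstrap_degenerate_ci():
    table = table_with_counts({"VH": 10, "Vh": 5, "vH": 5, "vh": 5},
                              {"VH": 10, "Vh": 2, "vH": 3, "vh": 0})
    tab = bootstrap_ci(table, "F", n_boot=500, seed=1)
    assert tab.data.loc["VH", "ci_low"] == 1.0
    assert tab.data.loc["VH", "ci_high"] == 1.0


def test_bootstrap_matches_binomial_percentile_oracle():
    """A single-type population bootstraps to an exact Binomial(P, B)/P."""
    table = table_with_counts({"VH": 0, "Vh": 0, "vH": 0, "vh": 185},
                              {"VH": 0, "Vh": 0, "vH": 0, "vh": 71})
    tab = bootstrap_ci(table, "F", n_boot=10_000, seed=2)
    p = 71 / 185
    lo = stats.binom.ppf(0.025, 185, p) / 185
    hi = stats.binom.ppf(0.975, 185, p) / 185
    assert tab.data.loc["vh", "ci_low"] == pytest.approx(lo, abs=0.01)
    assert tab.data.loc["vh", "ci_high"] == pytest.approx(hi, abs=0.01)
    # empty types carry undefined CIs
    assert np.isnan(tab.data.loc["VH", "ci_low"])


def test_bootstrap_deterministic():
    table = table_with_counts({"VH": 20, "Vh": 15, "vH": 12, "vh": 18},
                              {"VH": 15, "Vh": 8, "vH": 5, "vh": 4})
    a = bootstrap_ci(table, "F", n_boot=400, seed=9)
    b = bootstrap_ci(table, "F", n_boot=400, seed=9)
    assert a.data.equals(b.data)


def test_bootstrap_opposite_cis_mirror():
    table = table_with_counts({"VH": 20, "Vh": 15, "vH": 12, "vh": 18},
                              {"VH": 15, "Vh": 8, "vH": 5, "vh": 4})
    trait = bootstrap_ci(table, "F", n_boot=400, seed=9)
    opp = opposite_table(trait)
    assert opp.data.loc["VH", "ci_low"] == pytest.approx(
        1 - trait.data.loc["vh", "ci_high"]
    )


# -- bias estimation ---------------------------------------------------

def brute_force_biases(trait, opp, objective, grid):
    """Independent oracle: plain nested-loop scan of the whole grid
    (pure scalar arithmetic, no shared code with the implementation)."""
    from math import log

    cells_t = list(zip(trait.N.tolist(), trait.P.tolist(), [1, 1, 0, 0], [1, 0, 1, 0]))
    cells_o = list(zip(opp.N.tolist(), opp.P.tolist(), [1, 1, 0, 0], [1, 0, 1, 0]))

    def cell_obj(cells, other, v, h):
        tot = 0.0
        for n, pp, hv, hh in cells:
            if pp == 0:
                continue
            prob = other + v * hv + h * hh
            if objective == "binomial_loglik":
                if (prob <= 0 and n > 0) or (prob >= 1 and n < pp):
                    return float("inf")
                if n > 0:
                    tot -= n * log(prob)
                if pp - n > 0:
                    tot -= (pp - n) * log(1 - prob)
            elif objective == "sse_proportions":
                tot += (n / pp - prob) ** 2
            else:
                tot += (n - pp * prob) ** 2
        return tot

    m = int(round(1 / grid))
    vals = [round(i * grid, 10) for i in range(m + 1)]
    best = (float("inf"), None)
    for v in vals:
        for h in vals:
            if v + h > 1 + 1e-9:
                continue
            for ot in vals:
                if ot > 1 - v - h + 1e-9:
                    continue
                for oo in vals:
                    if oo > 1 - v - h + 1e-9:
                        continue
                    obj = cell_obj(cells_t, ot, v, h) + cell_obj(cells_o, oo, v, h)
                    if obj < best[0]:
                        best = (obj, (v, h, ot, oo))
    return best


@pytest.mark.parametrize("objective", ["binomial_loglik", "sse_proportions", "sse_counts"])
def test_exactly_additive_input_recovered(objective):
    """B = {vh: .10, Vh: .52, vH: .28, VH: .70} with equal cell sizes has the
    exact solution (other=.10, vertical=.42, horizontal=.18)."""
    P = {t: 1000 for t in ("VH", "Vh", "vH", "vh")}
    N = {"VH": 700, "Vh": 520, "vH": 280, "vh": 100}
    trait = ParentalTypeTable.from_counts(P, N)
    est = estimate_biases(trait, objective=objective, grid_resolution=0.01)
    assert est.vertical == pytest.approx(0.42, abs=1e-9)
    assert est.horizontal == pytest.approx(0.18, abs=1e-9)
    assert est.other_trait == pytest.approx(0.10, abs=1e-9)
    assert est.other_opposite == pytest.approx(0.30, abs=1e-9)


@pytest.mark.parametrize("objective", ["binomial_loglik", "sse_proportions", "sse_counts"])
def test_grid_search_matches_brute_force_oracle(objective):
    trait = ParentalTypeTable.from_counts(ENV_P, ENV_N)
    opp = opposite_table(trait)
    grid = 0.04
    obj_oracle, argmin_oracle = brute_force_biases(trait, opp, objective, grid)
    est = estimate_biases(trait, opp, objective=objective, grid_resolution=grid)
    assert (est.vertical, est.horizontal, est.other_trait, est.other_opposite) == (
        pytest.approx(argmin_oracle, abs=1e-9)
    )
    assert est.objective_value == pytest.approx(obj_oracle, rel=1e-9, abs=1e-9)


def test_grid_refinement_consistent():
    trait = ParentalTypeTable.from_counts(ENV_P, ENV_N)
    coarse = estimate_biases(trait, objective="sse_proportions", grid_resolution=0.01)
    fine = estimate_biases(trait, objective="sse_proportions", grid_resolution=0.002)
    assert fine.objective_value <= coarse.objective_value + 1e-12
    for name in ("vertical", "horizontal", "other_trait", "other_opposite"):
        assert abs(getattr(fine, name) - getattr(coarse, name)) <= 0.01 + 1e-9


def test_optimum_beats_full_rescan():
    """The returned optimum is the grid-wide minimum at coarse resolution."""
    trait = ParentalTypeTable.from_counts(
        {"VH": 50, "Vh": 40, "vH": 30, "vh": 60}, {"VH": 35, "Vh": 18, "vH": 12, "vh": 9}
    )
    opp = opposite_table(trait)
    est = estimate_biases(trait, opp, objective="sse_counts", grid_resolution=0.05)
    obj_oracle, _ = brute_force_biases(trait, opp, "sse_counts", 0.05)
    assert est.objective_value == pytest.approx(obj_oracle, rel=1e-12, abs=1e-12)


def test_tie_break_lexicographic():
    """With both single-bias cells empty only other and vertical+horizontal
    are identified; the tie resolves to the smallest vertical."""
    trait = ParentalTypeTable.from_counts(
        {"VH": 100, "Vh": 0, "vH": 0, "vh": 100}, {"VH": 80, "Vh": 0, "vH": 0, "vh": 20}
    )
    est = estimate_biases(trait, objective="sse_proportions", grid_resolution=0.1)
    assert est.vertical == pytest.approx(0.0)
    assert est.horizontal == pytest.approx(0.6)
    assert est.other_trait == pytest.approx(0.2)


def test_recovery_under_null_generating_process():
    """vertical = horizontal = 0 in generation: estimates stay near zero."""
    cfg = GeneratorConfig.recovery_preset(10_000, {"F": Biases(0.0, 0.0, 0.4)}, seed=77)
    table, _ = generate_binary_population(cfg)
    tab = transmission_table(filter_networks(table, "parent_and_friend"), "F")
    for objective in ("binomial_loglik", "sse_proportions", "sse_counts"):
        est = estimate_biases(tab, objective=objective, grid_resolution=0.01)
        assert est.vertical < 0.03 and est.horizontal < 0.03


def test_estimate_validates_inputs():
    trait = ParentalTypeTable.from_counts(ENV_P, ENV_N)
    with pytest.raises(ValueError, match="objective"):
        estimate_biases(trait, objective="mse")
    with pytest.raises(ValueError, match="polarities"):
        estimate_biases(trait, trait)


# -- triangle coordinates ----------------------------------------------

def test_triangle_weights_normalised():
    from culttrans.transmission import BiasEstimate

    est = BiasEstimate(0.42, 0.18, 0.10, 0.30, "binomial_loglik", 0.0, 0.01)
    coords = triangle_coordinates(est)
    for pol in ("trait", "opposite"):
        w = coords[pol]
        assert w["vertical"] + w["horizontal"] + w["other"] == pytest.approx(1.0)
    assert coords["trait"]["vertical"] == pytest.approx(0.42 / 0.70)
    # zero horizontal bias puts the point on the vertical-other edge (x-weighting)
    est0 = BiasEstimate(0.0, 0.0, 0.0, 0.0, "binomial_loglik", 0.0, 0.01)
    c0 = triangle_coordinates(est0)
    assert c0["trait"]["vertical"] == pytest.approx(1 / 3)
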