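import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hwebench.genotype_io import PopMap
from hwebench.hwe_filter import (
    POOLED,
    DecisionMatrix,
    FilterConfig,
    apply_scheme,
    bh_adjust,
    build_decision_matrix,
    hwe_chisq,
)
from hwebench.sim_data import simulate_balding_nichols

from conftest import make_matrix


# ---------------------------------------------------------------- chi2 test

def bh_step_up(p):
    """Independent BH oracle: literal step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return np.minimum(q, 1.0)


def pearson_chi2_oracle(rr, ra, aa):
    """Textbook Pearson chi2 against HW expectations via scipy.chisquare."""
    n = rr + ra + aa
    p = (2 * rr + ra) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 0.0, 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    chi2, _ = stats.chisquare([rr, ra, aa], expected, ddof=1)
    return chi2, stats.chi2.sf(chi2, 1)


def test_chi2_exact_proportions_and_extreme_deficit():
    assert hwe_chisq(25, 50, 25) == (0.0, 1.0)
    chi2, p = hwe_chisq(50, 0, 50)
    assert chi2 == pytest.approx(100.0)


def test_chi2_hand_computed_example():
    chi2, p = hwe_chisq(21, 18, 11)
    assert chi2 == pytest.approx(3.125)
    assert p == pytest.approx(stats.chi2.sf(3.125, 1))


def test_chi2_matches_oracle_and_nF2_identity_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(300):
        rr, ra, aa = rng.integers(0, 60, size=3)
        if rr + ra + aa == 0:
            continue
        chi2, p = hwe_chisq(rr, ra, aa)
        ochi2, op = pearson_chi2_oracle(rr, ra, aa)
        assert chi2 == pytest.approx(ochi2, abs=1e-10)
        assert p == pytest.approx(op, abs=1e-10)
        # algebraic identity chi2 = n * F^2, F = 1 - Ho/He
        n = rr + ra + aa
        p_allele = (2 * rr + ra) / (2 * n)
        he = 2 * p_allele * (1 - p_allele)
        if he > 0:
            F = 1 - (ra / n) / he
            assert chi2 == pytest.approx(n * F * F, abs=1e-10)


def test_chi2_monomorphic_and_empty():
    assert hwe_chisq(10, 0, 0) == (0.0, 1.0)
    with pytest.raises(ValueError):
        hwe_chisq(0, 0, 0)


# ---------------------------------------------------------------- BH

def test_bh_worked_example_and_trivial_cases():
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_adjust([0.3]) == pytest.approx([0.3])
    assert bh_adjust([0.5, 0.5, 0.5]) == pytest.approx([0.5] * 3)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_matches_step_up_oracle(pvals):
    q = bh_adjust(pvals)
    assert q == pytest.approx(bh_step_up(pvals), abs=1e-12)
    assert (q >= np.asarray(pvals) - 1e-12).all()
    assert (q <= 1.0).all()


# ---------------------------------------------------------------- decisions

def test_forced_departure_flagged_in_exactly_one_stratum():
    # pop A in extreme het deficit at L0; everything else at HW proportions
    a_l0 = [0] * 25 + [2] * 25
    hw = [0] * 13 + [1] * 25 + [2] * 12
    calls = np.column_stack([a_l0 + hw, hw + hw, hw + hw]).astype(np.int8)
    g = make_matrix(calls)
    pm = PopMap({f"s{i}": ("A" if i < 50 else "B") for i in range(100)})
    D = build_decision_matrix(g, pm, alpha=0.05, pooled=True)
    assert bool(D.table.loc["A", "L0"])
    assert not D.table.loc["B"].any()
    assert not D.table.loc["A", ["L1", "L2"]].any()


def test_pooled_wahlund_extreme_departs():
    # two demes fixed for opposite alleles: chi2 = 60 in the pooled stratum
    calls = np.array([[0]] * 30 + [[2]] * 30, dtype=np.int8)
    g = make_matrix(calls)
    pm = PopMap({f"s{i}": ("A" if i < 30 else "B") for i in range(60)})
    D = build_decision_matrix(g, pm, alpha=0.05, pooled=True)
    assert bool(D.table.loc[POOLED, "L0"])
    row = D.results.query("stratum == @POOLED and locus == 'L0'").iloc[0]
    assert row["chi2"] == pytest.approx(60.0)
    # within each deme the locus is monomorphic, hence non-departing
    assert not D.table.loc["A", "L0"] and not D.table.loc["B", "L0"]


def test_fdr_controls_departure_rate_on_null_data():
    g, pm = simulate_balding_nichols(0.001, 4, 30, 2000, seed=11)
    D = build_decision_matrix(g, pm, alpha=0.05, pooled=False)
    assert D.table.to_numpy().mean() <= 0.05


def test_too_small_stratum_raises():
    g = make_matrix([[0, 1], [1, 1], [-1, -1]])
    pm = PopMap({"s0": "A", "s1": "A", "s2": "B"})
    with pytest.raises(ValueError, match="fewer than 2"):
        build_decision_matrix(g, pm, pooled=False)


# ---------------------------------------------------------------- schemes

def decisions_from_dict(strata_loci, loci, departures):
    table = pd.DataFrame(False, index=strata_loci, columns=loci)
    for locus, strata in departures.items():
        for s in strata:
            table.loc[s, locus] = True
    return DecisionMatrix(table=table, alpha=0.05)


@pytest.fixture
def spec_example():
    """3 populations, 4 loci; departures: L1 in all, L2 in {P1}, L4 in {P1, P2}."""
    calls = np.ones((6, 4), dtype=np.int8)
    calls[0, :] = 0
    g = make_matrix(calls)
    pm = PopMap(
        {"s0": "P1", "s1": "P1", "s2": "P2", "s3": "P2", "s4": "P3", "s5": "P3"}
    )
    D = decisions_from_dict(
        ["P1", "P2", "P3", POOLED],
        ["L0", "L1", "L2", "L3"],
        {"L0": ["P1", "P2", "P3"], "L1": ["P1"], "L3": ["P1", "P2"]},
    )
    return g, pm, D


def dropped(g, md):
    return set(g.loci.index) - set(md.genotypes.loci.index)


def test_scheme_worked_example(spec_example):
    g, pm, D = spec_example
    assert dropped(g, apply_scheme(g, pm, D, FilterConfig("out_all"))) == {"L0"}
    assert dropped(g, apply_scheme(g, pm, D, FilterConfig("out_any"))) == {
        "L0", "L1", "L3",
    }
    assert dropped(
        g, apply_scheme(g, pm, D, FilterConfig("out_some", out_some_min=2))
    ) == {"L0", "L3"}
    md = apply_scheme(g, pm, D, FilterConfig("out_within"))
    assert dropped(g, md) == set()
    assert md.masks == {
        "P1": {"L0", "L1", "L3"},
        "P2": {"L0", "L3"},
        "P3": {"L0"},
    }
    assert dropped(g, apply_scheme(g, pm, D, FilterConfig("no_filter"))) == set()


def test_no_departures_every_scheme_is_identity(spec_example):
    g, pm, _ = spec_example
    D = decisions_from_dict(["P1", "P2", "P3", POOLED], list(g.loci.index), {})
    for cfg in [
        FilterConfig("no_filter"),
        FilterConfig("out_any"),
        FilterConfig("out_all"),
        FilterConfig("out_some", out_some_min=2),
        FilterConfig("out_within"),
        FilterConfig("out_combo"),
    ]:
        md = apply_scheme(g, pm, D, cfg)
        assert md.genotypes.n_loci == g.n_loci
        assert not md.has_masks


def test_scheme_errors(spec_example):
    g, pm, D = spec_example
    with pytest.raises(ValueError, match="out_some_min"):
        FilterConfig("out_some")
    no_pooled = DecisionMatrix(table=D.table.drop(index=POOLED), alpha=0.05)
    with pytest.raises(ValueError, match="POOLED"):
        apply_scheme(g, pm, no_pooled, FilterConfig("out_combo"))
    with pytest.raises(ValueError, match="strictly between"):
        apply_scheme(g, pm, D, FilterConfig("out_some", out_some_min=3))


def test_out_some_proportion_converted_by_ceiling():
    cfg = FilterConfig("out_some", out_some_min=0.5)
    assert cfg.resolve_min(5) == 3  # ceil(2.5)
    assert cfg.resolve_min(4) == 2


def brute_force_schemes(table, pops, out_some_min):
    """Literal per-locus enumeration of the five removal rules."""
    drops = {s: set() for s in ("out_any", "out_all", "out_some", "out_combo")}
    masks = {p: set() for p in pops}
    for locus in table.columns:
        flags = [table.loc[p, locus] for p in pops]
        if any(flags):
            drops["out_any"].add(locus)
        if all(flags):
            drops["out_all"].add(locus)
        if sum(flags) >= out_some_min:
            drops["out_some"].add(locus)
        if POOLED in table.index and table.loc[POOLED, locus]:
            drops["out_combo"].add(locus)
        for p, f in zip(pops, flags):
            if f:
                masks[p].add(locus)
    return drops, masks


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    n_pops=st.integers(3, 6),
    n_loci=st.integers(1, 50),
    seed=st.integers(0, 10_000),
)
def test_schemes_match_brute_force_enumeration(n_pops, n_loci, seed):
    rng = np.random.default_rng(seed)
    pops = [f"P{i}" for i in range(n_pops)]
    loci = [f"L{j}" for j in range(n_loci)]
    table = pd.DataFrame(
        rng.random((n_pops + 1, n_loci)) < 0.35, index=pops + [POOLED], columns=loci
    )
    D = DecisionMatrix(table=table, alpha=0.05)
    calls = rng.integers(0, 3, size=(2 * n_pops, n_loci)).astype(np.int8)
    g = make_matrix(calls)
    pm = PopMap({f"s{i}": pops[i // 2] for i in range(2 * n_pops)})
    out_some_min = int(rng.integers(2, n_pops))
    expected_drops, expected_masks = brute_force_schemes(table, pops, out_some_min)
    for scheme in ("out_any", "out_all", "out_combo"):
        md = apply_scheme(g, pm, D, FilterConfig(scheme))
        assert dropped(g, md) == expected_drops[scheme], scheme
    md = apply_scheme(g, pm, D, FilterConfig("out_some", out_some_min=out_some_min))
    assert dropped(g, md) == expected_drops["out_some"]
    md = apply_scheme(g, pm, D, FilterConfig("out_within"))
    assert md.masks == expected_masks
    # set relations: all <= some <= any; union of within masks == any-drops
    assert expected_drops["out_all"] <= expected_drops["out_some"]
    assert expected_drops["out_some"] <= expected_drops["out_any"]
    assert set().union(*md.masks.values()) == expected_drops["out_any"]
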