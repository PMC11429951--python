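"""Partial-origin de novo posterior: decomposition, gates, filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnvsex.denovo import (
    DnvPriorConfig,
    TrioLikelihoods,
    de_novo_probability,
    evidence_gates,
    frequency_recurrence_filter,
    likelihoods_from_pl,
    paternal_age_regression,
    scenario_masses,
    threshold_sweep,
)

RR, RA, AA = 0, 1, 2


def oracle_masses(trio, q, priors):
    """Enumerate all 27 (g_m, g_f, g_c) configurations with mutation-aware
    transmission and sum the mass of each scenario label independently of
    the vectorized implementation."""
    pi = [(1 - q) ** 2, 2 * q * (1 - q), q ** 2]
    lm, lf, lc = trio.mother, trio.father, trio.child
    masses = dict(a=0.0, b=0.0, c=0.0, d=0.0, e=0.0)
    for gm in (RR, RA, AA):
        for gf in (RR, RA, AA):
            for gc in (RR, RA, AA):
                base = pi[gm] * pi[gf] * lm[gm] * lf[gf] * lc[gc]
                if gm == RR and gf == RR and gc == RA:
                    masses["a"] += base * priors.mu_total * priors.maternal_fraction
                    masses["b"] += base * priors.mu_total * (1 - priors.maternal_fraction)
                if gm in (RA, AA) and gf == RR and gc == RA:
                    masses["c"] += base * (0.5 if gm == RA else 1.0)
                if gf in (RA, AA) and gm == RR and gc == RA:
                    masses["d"] += base * (0.5 if gf == RA else 1.0)
                if gm == RR and gf == RR and gc in [
                        {"RR": RR, "RA": RA, "AA": AA}[s]
                        for s in priors.child_error_states]:
                    masses["e"] += base
    return tuple(masses[k] for k in "abcde")


def random_trio(rng):
    pls = rng.uniform(0, 80, size=(3, 3))
    pls -= pls.min(axis=1, keepdims=True)
    return TrioLikelihoods.from_pl(*pls)


def test_scenario_masses_match_enumeration_oracle(rng):
    priors = DnvPriorConfig(mu_total=1e-6, maternal_fraction=0.4,
                            child_error_states=("RR", "AA"))
    for _ in range(500):
        trio = random_trio(rng)
        q = 10 ** rng.uniform(-4, -0.5)
        got = scenario_masses(trio, q, priors)
        want = oracle_masses(trio, q, priors)
        np.testing.assert_allclose(got, want, rtol=1e-12)


def test_no_child_het_evidence_zeroes_dn_and_inherited():
    trio = TrioLikelihoods(child=[1.0, 0.0, 0.0], mother=[0.5, 0.3, 0.2],
                           father=[0.2, 0.5, 0.3])
    a, b, c, d, e = scenario_masses(trio, 0.01)
    assert a == b == c == d == 0.0
    assert e > 0
    assert de_novo_probability(a, b, c, d, e) == 0.0


def test_perfect_trio_closed_form():
    """Indicator likelihoods, child het, parents hom-ref, q at the floor:
    p_dn = mu / (mu + q(1-q)^2/(1-q)^4) from the five hand-computed products."""
    priors = DnvPriorConfig(mu_total=3e-8, af_floor=1e-4)
    trio = TrioLikelihoods(child=[0, 1, 0], mother=[1, 0, 0], father=[1, 0, 0])
    q = priors.af_floor
    a, b, c, d, e = scenario_masses(trio, 0.0, priors)
    mu = priors.mu_total
    pi_rr = (1 - q) ** 2
    pi_ra = 2 * q * (1 - q)
    assert a == pytest.approx(pi_rr ** 2 * mu / 2, rel=1e-12)
    assert b == pytest.approx(pi_rr ** 2 * mu / 2, rel=1e-12)
    assert c == d == 0.0   # parents' het likelihood is zero
    assert e == 0.0        # child hom-ref likelihood is zero
    assert de_novo_probability(a, b, c, d, e) == 1.0
    # soften the parents slightly: c/d reappear with the HWE carrier prior
    trio2 = TrioLikelihoods(child=[0, 1, 0], mother=[0.99, 0.01, 0],
                            father=[0.99, 0.01, 0])
    a2, b2, c2, d2, e2 = scenario_masses(trio2, 0.0, priors)
    want_c = pi_ra * (0.01 / 1.0) * 0.5 * pi_rr * 0.99
    assert c2 == pytest.approx(want_c, rel=1e-12)


def test_p_dn_arithmetic_and_degenerate_cases():
    assert de_novo_probability(0.3, 0.3, 0.2, 0.1, 0.1) == pytest.approx(0.6)
    assert de_novo_probability(0, 0, 1, 2, 3) == 0.0
    assert de_novo_probability(1, 2, 1, 1, 1) == pytest.approx(0.5)
    assert np.isnan(de_novo_probability(0, 0, 0, 0, 0))
    with pytest.raises(ValueError):
        de_novo_probability(-1, 0, 0, 0, 0)


@given(st.floats(1e-4, 0.5), st.floats(1e-4, 0.5), st.integers(0, 2 ** 31 - 1))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_p_dn_monotone_in_population_frequency(q1, q2, seed):
    """Rarer alleles give stronger de novo posteriors for fixed likelihoods."""
    trio = random_trio(np.random.default_rng(seed))
    lo, hi = sorted((q1, q2))
    p_lo = de_novo_probability(*scenario_masses(trio, lo))
    p_hi = de_novo_probability(*scenario_masses(trio, hi))
    assert p_lo >= p_hi - 1e-12


@given(st.floats(0.0, 1.0), st.integers(0, 2 ** 31 - 1))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_partial_origin_coherence(frac, seed):
    """a/(a+b) equals the maternal prior share whenever both parents carry
    symmetric evidence (the data cannot distinguish the origins)."""
    rng = np.random.default_rng(seed)
    pl = rng.uniform(0, 60, size=3)
    trio = TrioLikelihoods.from_pl(rng.uniform(0, 60, 3), pl, pl)
    a, b, *_ = scenario_masses(trio, 0.01, DnvPriorConfig(maternal_fraction=frac))
    if a + b > 0:
        assert a / (a + b) == pytest.approx(frac, abs=1e-12)


def test_p_dn_scale_invariant():
    masses = (0.3, 0.2, 0.15, 0.05, 0.1)
    scaled = tuple(m * 7.3e4 for m in masses)
    assert de_novo_probability(*masses) == pytest.approx(
        de_novo_probability(*scaled), rel=1e-12)


# ---------------------------------------------------------------------------
# evidence gates
# ---------------------------------------------------------------------------

def trio_with_evidence(**kw):
    base = dict(ab_child=0.5, ab_mother=0.0, ab_father=0.0,
                dp_child=30.0, dp_mother=30.0, dp_father=30.0, gq_child=60.0)
    base.update(kw)
    return TrioLikelihoods(child=[0, 1, 0], mother=[1, 0, 0], father=[1, 0, 0],
                           **base)


def test_gates_all_pass_on_clean_trio():
    gates = evidence_gates(trio_with_evidence())
    assert gates["all"] and all(gates.values())


def test_parent_ab_gate():
    gates = evidence_gates(trio_with_evidence(ab_father=0.15))
    assert not gates["parent_ab"] and not gates["all"]
    assert gates["child_ab"] and gates["depth_ratio"] and gates["gq"]


def test_depth_ratio_gate():
    gates = evidence_gates(trio_with_evidence(dp_child=10, dp_mother=20,
                                              dp_father=20))
    assert not gates["depth_ratio"]
    gates = evidence_gates(trio_with_evidence(dp_mother=0, dp_father=0))
    assert not gates["depth_ratio"]   # undefined ratio fails


def test_child_ab_gate_directions():
    low_ab = trio_with_evidence(ab_child=0.15)
    assert not evidence_gates(low_ab)["child_ab"]
    assert evidence_gates(low_ab, literal_child_ab=True)["child_ab"]


# ---------------------------------------------------------------------------
# threshold sweep
# ---------------------------------------------------------------------------

def test_sweep_flat_when_all_confident():
    sweep = threshold_sweep([1.0] * 17)
    assert (sweep["n_calls"] == 17).all()
    assert sweep["threshold"].iloc[0] == 0.5
    assert sweep["threshold"].iloc[-1] == pytest.approx(0.05)


def test_sweep_uniform_scores_match_analytic(rng):
    p = rng.uniform(0, 1, size=1000)
    sweep = threshold_sweep(p)
    for t, n in zip(sweep["threshold"], sweep["n_calls"]):
        assert n == pytest.approx(1000 * (1 - t), abs=60)
    assert (np.diff(sweep["n_calls"]) >= 0).all()


def test_sweep_empty():
    assert (threshold_sweep([])["n_calls"] == 0).all()


# ---------------------------------------------------------------------------
# AF / recurrence filter
# ---------------------------------------------------------------------------

def calls_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "child_id", "internal_af",
                                       "external_af"])


def test_af_filter_removes_common_calls():
    calls = calls_frame([
        ("1", 100, "A", "T", "c1", 0.002, 0.0),     # internal AF too high
        ("1", 200, "A", "T", "c1", 0.0001, 0.002),  # external AF too high
        ("1", 300, "A", "T", "c1", 0.0001, 0.0),    # keeps
    ])
    out = frequency_recurrence_filter(calls)
    assert out["pos"].tolist() == [300]


def test_recurrence_rule_and_inversion():
    rows = [("1", 100, "A", "T", f"c{i}", 0.0, 0.0) for i in range(5)]
    rows.append(("1", 200, "A", "T", "c9", 0.0, 0.0))
    calls = calls_frame(rows)
    kept = frequency_recurrence_filter(calls)
    assert kept["pos"].unique().tolist() == [200]       # 5 children removed
    inverted = frequency_recurrence_filter(calls, keep_recurrent=True)
    assert set(inverted["pos"]) == {100}


def test_missing_external_af_imputed():
    calls = calls_frame([("1", 100, "A", "T", "c1", 0.0, np.nan)])
    assert len(frequency_recurrence_filter(calls)) == 1


# ---------------------------------------------------------------------------
# paternal-age regression
# ---------------------------------------------------------------------------

def test_regression_noiseless_line():
    ages = np.linspace(240, 600, 50)
    fit = paternal_age_regression(0.13 * ages, ages)
    assert fit["slope"] == pytest.approx(0.13, abs=1e-10)
    assert fit["p"] < 1e-30


def test_regression_constant_counts_and_errors():
    ages = np.linspace(240, 600, 10)
    fit = paternal_age_regression(np.full(10, 5.0), ages)
    assert fit["slope"] == pytest.approx(0.0, abs=1e-10)
    with pytest.raises(ValueError):
        paternal_age_regression([1, 2, 3], [300, 300, 300])
    with pytest.raises(ValueError):
        paternal_age_regression([1, 2], [300, 301])


def test_regression_recovers_poisson_slope(rng):
    ages = rng.uniform(240, 600, size=900)
    counts = rng.poisson(13.4 + 0.13 * ages)
    fit = paternal_age_regression(counts, ages)
    assert fit["slope_ci_low"] <= 0.13 <= fit["slope_ci_high"]


def test_likelihoods_from_pl_normalized():
    lik = likelihoods_from_pl([0, 30, 60])
    assert lik.sum() == pytest.approx(1.0)
    assert lik[0] == pytest.approx(1 / (1 + 1e-3 + 1e-6))
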