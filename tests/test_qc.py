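"""Variant-QC cascade: HWE exact test, multiallelic split, filters."""

import math

import numpy as np
import pytest

from dnvsex.qc import (
    MISSING,
    QCThresholds,
    hq_common_filter,
    hq_rare_filter,
    hwe_exact_p,
    region_length_filter,
    site_metrics,
    split_multiallelic,
)
from tests.conftest import make_record


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_rr, n_het, n_aa):
    """Independent full enumeration of the exact HWE test with math.comb."""
    n = n_rr + n_het + n_aa
    rare = 2 * min(n_rr, n_aa) + n_het
    denom = math.comb(2 * n, rare)

    def prob(h):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        return (math.comb(n, hom_r) * math.comb(n - hom_r, h)
                * 2 ** h / denom)

    probs = {h: prob(h) for h in range(rare % 2, min(rare, 2 * n - rare) + 1, 2)}
    p_obs = probs[n_het]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


@pytest.mark.parametrize("counts", [
    (25, 50, 25), (50, 0, 50), (5, 1, 0), (40, 15, 3), (0, 1, 99),
    (10, 80, 10), (33, 34, 33), (90, 9, 1),
])
def test_hwe_matches_full_enumeration(counts):
    expected = hwe_enumeration_oracle(*counts)
    got = hwe_exact_p(*counts)
    assert got == pytest.approx(expected, rel=1e-9)


def test_hwe_extremes_and_symmetry():
    # perfectly HWE-proportioned sample: near-maximal p
    assert hwe_exact_p(25, 50, 25) > 0.9
    # all-homozygote split is astronomically unlikely under HWE
    assert hwe_exact_p(50, 0, 50) < 1e-12
    # allele relabeling leaves p unchanged
    assert hwe_exact_p(40, 15, 3) == pytest.approx(hwe_exact_p(3, 15, 40))
    assert math.isnan(hwe_exact_p(0, 0, 0))


# ---------------------------------------------------------------------------
# multiallelic split
# ---------------------------------------------------------------------------

def test_split_biallelic_identity():
    rec = make_record(gt=[0, 1, 2])
    out = split_multiallelic([rec])
    assert len(out) == 1
    np.testing.assert_array_equal(out[0].gt, rec.gt)
    assert out[0].alts == rec.alts


def test_split_two_alts_yields_two_records():
    n = 3
    # samples: 0/1, 0/2, 1/2
    gt = [(0, 1), (0, 2), (1, 2)]
    ad = [[10, 10, 0], [12, 0, 12], [0, 9, 9]]
    pl = [[0, 10, 20, 30, 40, 50]] * n
    rec = make_record(alts=("T", "G"), gt=gt, ad=ad, pl=pl, dp=[20, 24, 18])
    out = split_multiallelic([rec])
    assert len(out) == 2
    assert all(r.chrom == rec.chrom and r.pos == rec.pos and r.ref == rec.ref
               for r in out)
    assert [r.alt for r in out] == ["T", "G"]
    # allele localization: sample 2 (1/2) is het for each alt after split
    assert out[0].dosage().tolist() == [1, 0, 1]
    assert out[1].dosage().tolist() == [0, 1, 1]
    # AD collapses remaining depth onto ref
    np.testing.assert_allclose(out[0].ad[0], [10, 10])
    np.testing.assert_allclose(out[1].ad[1], [12, 12])
    # PL selects the {ref, alt} genotypes re-anchored at zero
    np.testing.assert_allclose(out[0].pl[0], [0, 10, 20])
    np.testing.assert_allclose(out[1].pl[0], [0, 30, 50])


def test_homref_pl_reconstruction():
    # hom-ref call with DP=30, GQ=50 and no stored PL -> [0, 50, 90]
    pl = np.full((1, 6), np.nan)
    ad = np.full((1, 3), np.nan)
    rec = make_record(alts=("T", "G"), gt=[(0, 0)], ad=ad, pl=pl,
                      dp=[30.0], gq=[50.0])
    out = split_multiallelic([rec])
    for r in out:
        np.testing.assert_allclose(r.pl[0], [0.0, 50.0, 90.0])
        np.testing.assert_allclose(r.ad[0], [30.0, 0.0])


def test_empty_lpl_slots_padded_with_max():
    pl = np.array([[0.0, 40.0, np.nan, 70.0, np.nan, 90.0]])
    rec = make_record(alts=("T", "G"), gt=[(0, 1)], ad=[[10, 10, 0]],
                      pl=pl, dp=[20.0])
    out = split_multiallelic([rec])
    # alt G genotypes (0/2, 2/2) at indices 3 and 5; RR=0
    np.testing.assert_allclose(out[1].pl[0], [0.0, 70.0, 90.0])
    # the nan slot for 1/1 was padded with max=90 before selection
    np.testing.assert_allclose(out[0].pl[0], [0.0, 40.0, 90.0])


def test_split_roundtrip_preserves_biallelic_calls():
    rec = make_record(gt=[0, 1, 2], dp=[30, 30, 30])
    out = split_multiallelic([rec])[0]
    np.testing.assert_array_equal(out.dosage(), rec.dosage())
    np.testing.assert_allclose(out.pl, rec.pl)


# ---------------------------------------------------------------------------
# region / length exclusion
# ---------------------------------------------------------------------------

def test_region_filter_coordinate_conventions():
    rec = make_record(pos=100)
    # BED [99,100) covers the 0-based coordinate 99 == VCF position 100
    assert region_length_filter([rec], [("1", 99, 100)]) == []
    # adjacent interval does not
    assert len(region_length_filter([rec], [("1", 100, 101)])) == 1
    # deletion footprint extends over REF length
    deletion = make_record(pos=100, ref="ACGTACGT", alts=("A",))
    assert region_length_filter([deletion], [("1", 105, 106)]) == []


def test_allele_length_rule_inclusive_at_50():
    keep = make_record(ref="A", alts=("A" + "T" * 48,))   # 49 bp allele
    drop = make_record(ref="A", alts=("A" + "T" * 49,))   # 50 bp allele
    out = region_length_filter([keep, drop], [])
    assert [r.pos for r in out] == [keep.pos]


# ---------------------------------------------------------------------------
# rare cascade
# ---------------------------------------------------------------------------

def scaled_thresholds(**overrides):
    th = QCThresholds()
    rare = {k: dict(v) for k, v in th.rare.items()}
    rare["hom_snv"]["an"] = 4          # AN floors rescaled to toy cohorts
    rare["hom_indel"]["an"] = 4
    for block, rules in overrides.items():
        rare[block].update(rules)
    return QCThresholds(rare=rare)


def boundary_het_snv():
    """Het SNV exactly at the printed cutoffs (all rules inclusive)."""
    return make_record(
        qual=7.5, gt=[1, 0, 0],
        ad=[[17, 17], [34, 0], [34, 0]],
        dp=[34, 34, 34], gq=[36, 36, 36],
    )


def test_rare_het_snv_passes_at_boundary():
    kept, tally = hq_rare_filter([boundary_het_snv()], scaled_thresholds())
    assert len(kept) == 1
    assert tally == {}


def test_rare_het_snv_ab_window():
    rec = boundary_het_snv()
    rec.ad[0] = [90, 10]   # AB = 0.1, below the 0.275 window
    kept, tally = hq_rare_filter([rec], scaled_thresholds())
    assert kept == []
    assert tally["het_snv.ab_min"] == 1


def test_rare_qual_below_cutoff_rejected():
    rec = boundary_het_snv()
    rec.qual = 7.49
    kept, tally = hq_rare_filter([rec], scaled_thresholds())
    assert kept == [] and tally["het_snv.qual"] == 1


def test_rare_hwe_floor_removes_site():
    # 60 founders split 30/0/30: exact HWE p far below 1e-12
    n = 60
    gt = [0] * 30 + [2] * 30
    ad = [[30, 0]] * 30 + [[0, 30]] * 30
    rec = make_record(qual=100.0, gt=gt, ad=ad, dp=[30] * n, gq=[60] * n)
    kept, tally = hq_rare_filter([rec], scaled_thresholds())
    assert kept == [] and tally["site.hwe"] == 1


def test_rare_call_rate_floor():
    gt = [1] + [MISSING] * 19
    rec = make_record(qual=100.0, gt=gt, n_samples=20,
                      dp=[34] * 20, gq=[60] * 20)
    kept, tally = hq_rare_filter([rec], scaled_thresholds())
    assert kept == [] and tally["site.call_rate"] == 1


def test_rare_cascade_idempotent_and_monotone():
    rng = np.random.default_rng(7)
    records = []
    for i in range(30):
        n = 12
        dos = rng.integers(0, 3, size=n)
        ad = np.stack([(2 - dos) * 17, dos * 17], axis=1).astype(float)
        records.append(make_record(
            pos=100 + i, qual=float(rng.uniform(5, 40)), gt=list(dos),
            ad=ad, dp=[34.0] * n, gq=list(rng.uniform(20, 80, n))))
    th = scaled_thresholds()
    once, _ = hq_rare_filter(records, th)
    twice, tally2 = hq_rare_filter(once, th)
    assert len(twice) == len(once)
    assert all((a.dosage() == b.dosage()).all() for a, b in zip(once, twice))
    # tightening any threshold never increases survivors
    tighter = scaled_thresholds(het_snv={"qual": 20.0})
    fewer, _ = hq_rare_filter(records, tighter)
    assert len(fewer) <= len(once)


# ---------------------------------------------------------------------------
# common cascade
# ---------------------------------------------------------------------------

def common_site(n=40, af=0.3, rng=None):
    rng = rng or np.random.default_rng(0)
    dos = rng.binomial(2, af, size=n)
    ad = np.stack([(2 - dos) * 15, dos * 15], axis=1).astype(float)
    return make_record(qual=500.0, gt=list(dos), ad=ad,
                       dp=[30.0] * n, gq=[60.0] * n)


def test_common_boundary_call_passes():
    rec = common_site()
    i = int(np.flatnonzero(rec.dosage() == 1)[0])
    rec.gq[i] = 20.0
    rec.dp[i] = 10.0
    rec.ad[i] = [8, 2]     # AB exactly 0.2
    kept, tally = hq_common_filter([rec])
    assert len(kept) == 1
    assert kept[0].dosage()[i] == 1


def test_common_call_rate_floor():
    rec = common_site(n=100)
    rec.gt[:6] = MISSING   # call rate 0.94
    kept, tally = hq_common_filter([rec])
    assert kept == [] and tally["site.call_rate"] == 1


def test_common_af_strictly_above_floor():
    # AF exactly 0.05 fails the "more than 0.05" rule
    n = 40
    dos = np.zeros(n, dtype=int)
    dos[:4] = 1           # AF = 4 / 80 = 0.05
    ad = np.stack([(2 - dos) * 15, dos * 15], axis=1).astype(float)
    rec = make_record(qual=500.0, gt=list(dos), ad=ad,
                      dp=[30.0] * n, gq=[60.0] * n)
    kept, tally = hq_common_filter([rec])
    assert kept == [] and tally["site.af"] == 1


def test_common_failing_het_ab_masks_call():
    rec = common_site()
    i = int(np.flatnonzero(rec.dosage() == 1)[0])
    rec.ad[i] = [29, 1]    # AB ~ 0.03
    kept, tally = hq_common_filter([rec])
    assert tally["call.het_ab"] == 1
    if kept:
        assert kept[0].dosage()[i] == MISSING


def test_site_metrics_founders_only():
    rec = make_record(gt=[1, 0, 1, 1], dp=[30] * 4, gq=[60] * 4)
    founders = np.array([True, True, False, False])
    m = site_metrics(rec, founders)
    assert m.internal_af == pytest.approx(0.25)
    assert m.an == 8
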