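"""Variant-level quality control for multi-sample trio VCFs.

Implements the preprocessing cascade applied before de novo calling and
polygenic scoring: multiallelic splitting with local-allele reconstruction,
low-complexity-region and allele-length exclusion, and two hard-filter
cascades — one tuned for high-quality *rare* variants (per genotype-class
blocks of QUAL / GQmean / DPmean / allele-balance cutoffs) and one for
high-quality *common* variants (per-call GQ/DP/AB plus site call-rate, HWE
and founder allele-frequency floors).

Genotype calls failing a block rule are set to missing rather than the whole
site being dropped; a site is removed when no alternate call survives or
when a site-level floor (call rate, Hardy–Weinberg exact P) fails.  Every
rejection is tallied per rule so a multi-rule cascade stays auditable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MISSING = -1

#: Phred cap applied when a genotype likelihood underflows to zero.
PL_CAP = 255


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """One site with per-sample calls (biallelic after :func:`split_multiallelic`).

    Genotypes are stored as allele-index pairs (``-1`` = missing).  ``ad``
    holds per-allele read depths with one column per allele (ref first),
    ``pl`` holds phred-scaled genotype likelihoods over the genotypes of the
    site's alleles in VCF order; ``NaN`` entries mean the field was absent.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float
    gt: np.ndarray        # (n_samples, 2) int
    ad: np.ndarray        # (n_samples, 1 + n_alts) float
    dp: np.ndarray        # (n_samples,) float
    gq: np.ndarray        # (n_samples,) float
    pl: np.ndarray        # (n_samples, n_genotypes) float

    @property
    def n_samples(self) -> int:
        return self.gt.shape[0]

    @property
    def alt(self) -> str:
        if len(self.alts) != 1:
            raise ValueError("site is not biallelic; split it first")
        return self.alts[0]

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage per sample (-1 where either allele is missing)."""
        d = (self.gt == 1).sum(axis=1)
        d[(self.gt == MISSING).any(axis=1)] = MISSING
        return d

    def copy(self) -> "VariantRecord":
        return replace(
            self,
            gt=self.gt.copy(), ad=self.ad.copy(), dp=self.dp.copy(),
            gq=self.gq.copy(), pl=self.pl.copy(),
        )


@dataclass
class SiteMetrics:
    an: int
    call_rate: float
    hwe_p: float
    gq_mean: float
    dp_mean: float
    ab: float             # alt-read fraction among het carriers (nan if none)
    internal_af: float


def site_metrics(rec: VariantRecord, founder_mask: np.ndarray | None = None) -> SiteMetrics:
    """Site-level QC metrics for a biallelic record.

    HWE and the internal allele frequency are computed on founders when a
    mask is given, to avoid the non-independence of trio offspring.
    """
    dos = rec.dosage()
    called = dos != MISSING
    n = rec.n_samples
    an = int(2 * called.sum())
    call_rate = called.sum() / n if n else 0.0
    gq_mean = float(np.nanmean(rec.gq[called])) if called.any() else float("nan")
    dp_mean = float(np.nanmean(rec.dp[called])) if called.any() else float("nan")

    het = called & (dos == 1)
    if het.any() and rec.ad.shape[1] >= 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            tot = rec.ad[het, 0] + rec.ad[het, 1]
            ab_v = np.where(tot > 0, rec.ad[het, 1] / np.maximum(tot, 1), np.nan)
        ab = float(np.nanmean(ab_v)) if np.isfinite(ab_v).any() else float("nan")
    else:
        ab = float("nan")

    fm = founder_mask if founder_mask is not None else np.ones(n, dtype=bool)
    fdos = dos[fm & called]
    if fdos.size:
        af = float(fdos.sum() / (2 * fdos.size))
        hwe = hwe_exact_p(int((fdos == 0).sum()), int((fdos == 1).sum()),
                          int((fdos == 2).sum()))
    else:
        af, hwe = float("nan"), float("nan")
    return SiteMetrics(an, call_rate, hwe, gq_mean, dp_mean, ab, af)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy–Weinberg equilibrium test P-value.

    Full enumeration of all heterozygote counts compatible with the observed
    genotype total and minor-allele count; the P-value is the sum of the
    probabilities of configurations no more probable than the observed one.
    Computed in log space so that tail P-values far below 1e-12 — where the
    rare-variant cascade draws its floor — remain accurate.

    Symmetric under allele relabeling.  Returns NaN for an empty sample.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return float("nan")
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # log P(het = h | n, rare) up to a shared constant:
    #   log C(n; hom_rare, h, hom_common) + h log 2
    lg = math.lgamma

    def logp(h: int) -> float:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        return (lg(n + 1) - lg(hom_r + 1) - lg(h + 1) - lg(hom_c + 1)
                + h * math.log(2) + lg(rare + 1) + lg(2 * n - rare + 1)
                - lg(2 * n + 1))
    hs = range(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    logs = {h: logp(h) for h in hs}
    m = max(logs.values())
    obs = logs[n_het]
    num = sum(math.exp(v - m) for v in logs.values() if v <= obs + 1e-12)
    den = sum(math.exp(v - m) for v in logs.values())
    return min(1.0, num / den)


# ---------------------------------------------------------------------------
# multiallelic split
# ---------------------------------------------------------------------------

def _pl_index(a: int, b: int) -> int:
    # VCF genotype ordering for unphased diploid genotypes
    a, b = min(a, b), max(a, b)
    return b * (b + 1) // 2 + a


def reconstruct_homref_pl(gq: float, dp: float) -> np.ndarray:
    """PL for a hom-ref call whose likelihoods were dropped upstream: [0, GQ, 3*DP]."""
    return np.array([0.0, gq, 3.0 * dp])


def split_multiallelic(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Split each multiallelic site into one biallelic record per alt allele.

    Per-sample fields are localized to the {ref, alt} pair: genotype alleles
    equal to the kept alt become 1 and every other allele 0; AD collapses the
    remaining depth onto the reference column; PL keeps the three genotypes
    over {ref, alt}, re-anchored at zero.  Hom-ref calls with absent AD get
    ``[DP, 0]``; hom-ref calls with absent PL get ``[0, GQ, 3*DP]``; empty PL
    slots are padded with the sample's maximum PL before selection.
    Biallelic records pass through unchanged.
    """
    out: list[VariantRecord] = []
    for rec in records:
        if rec.is_biallelic:
            out.append(_fill_missing_biallelic(rec))
            continue
        n_alt = len(rec.alts)
        for j in range(1, n_alt + 1):
            try:
                out.append(_take_allele(rec, j))
            except (ValueError, IndexError) as exc:  # malformed arrays
                logger.warning("rejecting %s:%d alt %s: %s",
                               rec.chrom, rec.pos, rec.alts[j - 1], exc)
        del rec
    return out


def _fill_missing_biallelic(rec: VariantRecord) -> VariantRecord:
    rec = rec.copy()
    homref = (rec.gt == 0).all(axis=1)
    for i in np.flatnonzero(homref):
        if not np.isfinite(rec.ad[i]).any():
            rec.ad[i] = [rec.dp[i], 0.0]
        if not np.isfinite(rec.pl[i]).any():
            rec.pl[i] = reconstruct_homref_pl(rec.gq[i], rec.dp[i])
    return rec


def _take_allele(rec: VariantRecord, j: int) -> VariantRecord:
    n = rec.n_samples
    n_all = 1 + len(rec.alts)
    if rec.ad.shape[1] != n_all:
        raise ValueError(f"AD has {rec.ad.shape[1]} columns for {n_all} alleles")
    gt = rec.gt.copy()
    keep = gt == j
    gt[(gt > 0) & ~keep] = 0
    gt[keep] = 1
    gt[rec.gt == MISSING] = MISSING

    ad = np.empty((n, 2))
    with np.errstate(invalid="ignore"):
        ad[:, 1] = rec.ad[:, j]
        ad[:, 0] = np.nansum(rec.ad, axis=1) - np.where(
            np.isfinite(rec.ad[:, j]), rec.ad[:, j], 0.0)

    idx = [_pl_index(0, 0), _pl_index(0, j), _pl_index(j, j)]
    pl = np.full((n, 3), np.nan)
    for i in range(n):
        row = rec.pl[i]
        if np.isfinite(row).any():
            filled = np.where(np.isfinite(row), row, np.nanmax(row))
            sub = filled[idx]
            pl[i] = sub - sub.min()
        elif (rec.gt[i] == 0).all():
            pl[i] = reconstruct_homref_pl(rec.gq[i], rec.dp[i])
        if not np.isfinite(rec.ad[i]).any() and (rec.gt[i] == 0).all():
            ad[i] = [rec.dp[i], 0.0]
    return VariantRecord(rec.chrom, rec.pos, rec.ref, (rec.alts[j - 1],),
                         rec.qual, gt, ad, rec.dp.copy(), rec.gq.copy(), pl)


# ---------------------------------------------------------------------------
# region / length exclusion
# ---------------------------------------------------------------------------

def region_length_filter(
    records: Iterable[VariantRecord],
    lcr_bed: Sequence[tuple[str, int, int]] = (),
    max_len: int = 50,
) -> list[VariantRecord]:
    """Drop records overlapping excluded regions or carrying long alleles.

    ``lcr_bed`` intervals are 0-based half-open; overlap is evaluated on the
    REF footprint ``[pos-1, pos-1+len(ref))`` of the 1-based VCF position.
    Alleles of length >= ``max_len`` are removed (the printed rule is an
    inclusive bound).  Unsorted BED input is sorted with a warning.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in lcr_bed:
        by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
    for chrom, ivs in by_chrom.items():
        if any(ivs[i] > ivs[i + 1] for i in range(len(ivs) - 1)):
            logger.warning("unsorted BED intervals on %s; sorting", chrom)
        ivs.sort()

    out = []
    for rec in records:
        if any(len(a) >= max_len for a in (rec.ref, *rec.alts)):
            continue
        start = rec.pos - 1
        end = start + len(rec.ref)
        ivs = by_chrom.get(rec.chrom, [])
        if any(s < end and start < e for s, e in ivs):
            continue
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# hard-filter cascades
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCThresholds:
    """Hard-filter cutoffs; defaults are the study's printed values.

    Rare-variant blocks key on genotype class; every inequality is inclusive
    as printed.  The AN floors (4312 / 3504 called alleles) are cohort-size
    dependent and should be rescaled for smaller cohorts.
    """

    rare: dict = field(default_factory=lambda: {
        "het_snv": {"qual": 7.5, "gq_mean": 36.0, "dp_mean": 34.0,
                    "ab_min": 0.275, "ab_max": 0.725},
        "het_indel": {"qual": 10.51, "gdp": 3.0,
                      "ab_min": 0.214, "ab_max": 0.786},
        "hom_snv": {"qual": 20.3, "an": 4312, "ab_min": 0.905,
                    "gq_mean": 15.7, "dp_mean": 12.0, "gq": 9.0, "gdp": 11.0},
        "hom_indel": {"qual": 24.78, "an": 3504, "gq_mean": 29.0,
                      "dp_mean": 11.55, "gq": 1.0, "gdp": 5.0,
                      "ab_min": 0.905},
    })
    rare_call_rate_min: float = 0.10
    rare_hwe_min: float = 1e-12
    common_gq: float = 20.0
    common_dp: float = 10.0
    common_het_ab: tuple[float, float] = (0.2, 0.8)
    common_hom_ab: float = 0.95
    common_call_rate_min: float = 0.95
    common_hwe_min: float = 1e-6
    common_af_min: float = 0.05       # strict: AF must exceed this
    max_allele_len: int = 50


def _call_ab(rec: VariantRecord, i: int) -> float:
    tot = rec.ad[i, 0] + rec.ad[i, 1]
    if not np.isfinite(tot) or tot <= 0:
        return float("nan")
    return float(rec.ad[i, 1] / tot)


def _genotype_class(rec: VariantRecord, dos: int) -> str:
    kind = "indel" if rec.is_indel else "snv"
    zyg = "het" if dos == 1 else "hom"
    return f"{zyg}_{kind}"


def hq_rare_filter(
    records: Iterable[VariantRecord],
    thresholds: QCThresholds | None = None,
    founder_mask: np.ndarray | None = None,
) -> tuple[list[VariantRecord], dict[str, int]]:
    """High-quality *rare* variant cascade.

    Alt-carrying genotype calls are tested against their genotype-class
    block; failing calls are set to missing.  Sites with call rate below the
    floor or Hardy–Weinberg exact P below 1e-12 are removed outright.  A
    record survives when at least one alt call survives.  Returns the
    surviving records and a per-rule rejection tally.
    """
    th = thresholds or QCThresholds()
    tally: dict[str, int] = {}

    def bump(key: str) -> None:
        tally[key] = tally.get(key, 0) + 1

    out = []
    for rec in records:
        rec = rec.copy()
        m = site_metrics(rec, founder_mask)
        if m.call_rate < th.rare_call_rate_min:
            bump("site.call_rate")
            continue
        if np.isfinite(m.hwe_p) and m.hwe_p < th.rare_hwe_min:
            bump("site.hwe")
            continue
        dos = rec.dosage()
        for i in np.flatnonzero(dos > 0):
            cls = _genotype_class(rec, int(dos[i]))
            block = th.rare[cls]
            failed = _check_block(rec, i, m, block)
            if failed:
                bump(f"{cls}.{failed}")
                rec.gt[i] = MISSING
        if (rec.dosage() > 0).any():
            out.append(rec)
        else:
            bump("site.no_alt_calls")
    return out, tally


def _check_block(rec: VariantRecord, i: int, m: SiteMetrics, block: dict) -> str | None:
    """Return the name of the first failing rule in a rare block, else None."""
    checks = {
        "qual": lambda v: rec.qual >= v,
        "gq_mean": lambda v: m.gq_mean >= v,
        "dp_mean": lambda v: m.dp_mean >= v,
        "an": lambda v: m.an >= v,
        "gq": lambda v: rec.gq[i] >= v,
        "gdp": lambda v: rec.dp[i] >= v,
        "ab_min": lambda v: _call_ab(rec, i) >= v,
        "ab_max": lambda v: _call_ab(rec, i) <= v,
    }
    for rule, limit in block.items():
        val = checks[rule](limit)
        if not val or (rule.startswith("ab") and not np.isfinite(_call_ab(rec, i))):
            return rule
    return None


def hq_common_filter(
    records: Iterable[VariantRecord],
    thresholds: QCThresholds | None = None,
    founder_mask: np.ndarray | None = None,
) -> tuple[list[VariantRecord], dict[str, int]]:
    """High-quality *common* variant cascade.

    Per-call GQ >= 20, DP >= 10, het AB within 0.2–0.8, hom-alt AB >= 0.95;
    site call rate >= 95%, HWE exact P >= 1e-6 and founder allele frequency
    strictly above 0.05.  Failing calls are set missing before the site
    floors are re-evaluated.
    """
    th = thresholds or QCThresholds()
    tally: dict[str, int] = {}

    def bump(key: str) -> None:
        tally[key] = tally.get(key, 0) + 1

    out = []
    for rec in records:
        rec = rec.copy()
        dos = rec.dosage()
        for i in np.flatnonzero(dos != MISSING):
            if not (np.isfinite(rec.gq[i]) and rec.gq[i] >= th.common_gq):
                bump("call.gq"); rec.gt[i] = MISSING; continue
            if not (np.isfinite(rec.dp[i]) and rec.dp[i] >= th.common_dp):
                bump("call.dp"); rec.gt[i] = MISSING; continue
            if dos[i] == 1:
                ab = _call_ab(rec, i)
                lo, hi = th.common_het_ab
                if not (np.isfinite(ab) and lo <= ab <= hi):
                    bump("call.het_ab"); rec.gt[i] = MISSING
            elif dos[i] == 2:
                ab = _call_ab(rec, i)
                if not (np.isfinite(ab) and ab >= th.common_hom_ab):
                    bump("call.hom_ab"); rec.gt[i] = MISSING
        m = site_metrics(rec, founder_mask)
        if m.call_rate < th.common_call_rate_min:
            bump("site.call_rate")
            continue
        if np.isfinite(m.hwe_p) and m.hwe_p < th.common_hwe_min:
            bump("site.hwe")
            continue
        if not (np.isfinite(m.internal_af) and m.internal_af > th.common_af_min):
            bump("site.af")
            continue
        out.append(rec)
    return out, tally
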