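"""Partial-origin trio de novo posterior caller.

For a biallelic site in a child–mother–father trio, the caller decomposes
the posterior mass over five mutually exclusive explanations of an apparent
de novo heterozygote:

  a. a de novo mutation on the maternally inherited haplotype;
  b. a de novo mutation on the paternally inherited haplotype;
  c. the mother carries the alternate allele and transmitted it;
  d. the father carries the alternate allele and transmitted it;
  e. the child's genotype call is wrong (the child is not heterozygous).

Each mass is the product of Hardy–Weinberg genotype priors at the site's
population frequency, the members' normalized genotype likelihoods, a
Mendelian transmission factor (1/2 for a het parent, 1 for a hom-alt
parent), and — for the de novo scenarios — a per-site mutation prior split
between the parental origins.  The de novo probability is the ratio

    p_dn = (a + b) / (a + b + c + d + e)

and ``a / (a + b)`` is the posterior probability of maternal origin.
Downstream: hard evidence gates on allele balance, depth ratio and GQ, a
probability-threshold sweep, allele-frequency / recurrence filtering, and
the paternal-age regression used both as a QC readout and to produce
age-adjusted counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from dnvsex.qc import MISSING, VariantRecord

logger = logging.getLogger(__name__)

RR, RA, AA = 0, 1, 2
_STATE_INDEX = {"RR": RR, "RA": RA, "AA": AA}


# ---------------------------------------------------------------------------
# inputs
# ---------------------------------------------------------------------------

def likelihoods_from_pl(pl: Sequence[float]) -> np.ndarray:
    """Normalized genotype likelihoods from a 3-entry PL vector."""
    pl = np.asarray(pl, dtype=float)
    if pl.shape != (3,) or not np.isfinite(pl).all():
        raise ValueError("PL must be three finite values")
    lik = 10.0 ** (-pl / 10.0)
    return lik / lik.sum()


@dataclass
class TrioLikelihoods:
    """Normalized per-genotype likelihoods and call-level evidence for one trio."""

    child: np.ndarray
    mother: np.ndarray
    father: np.ndarray
    ab_child: float = float("nan")
    ab_mother: float = float("nan")
    ab_father: float = float("nan")
    dp_child: float = float("nan")
    dp_mother: float = float("nan")
    dp_father: float = float("nan")
    gq_child: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("child", "mother", "father"):
            lik = np.asarray(getattr(self, name), dtype=float)
            if lik.shape != (3,) or (lik < 0).any():
                raise ValueError(f"{name} likelihoods must be 3 non-negative values")
            s = lik.sum()
            if s <= 0:
                raise ValueError(f"{name} likelihoods sum to zero")
            setattr(self, name, lik / s)

    @classmethod
    def from_pl(cls, pl_child, pl_mother, pl_father, **evidence) -> "TrioLikelihoods":
        return cls(likelihoods_from_pl(pl_child), likelihoods_from_pl(pl_mother),
                   likelihoods_from_pl(pl_father), **evidence)


@dataclass(frozen=True)
class DnvPriorConfig:
    """Priors of the scenario decomposition.

    ``mu_total`` is the prior probability of a de novo event at a site,
    split between maternal and paternal origin by ``maternal_fraction``.
    Population frequencies are floored at ``af_floor`` before entering the
    Hardy–Weinberg priors.  ``child_error_states`` lists the child genotype
    states counted as a miscall in scenario e (hom-ref by default).
    """

    mu_total: float = 3e-8
    maternal_fraction: float = 0.5
    af_floor: float = 1e-4
    child_error_states: tuple[str, ...] = ("RR",)

    def __post_init__(self) -> None:
        if not 0 < self.mu_total < 1:
            raise ValueError("mu_total must be in (0, 1)")
        if not 0 <= self.maternal_fraction <= 1:
            raise ValueError("maternal_fraction must be in [0, 1]")
        if self.af_floor <= 0:
            raise ValueError("af_floor must be positive")
        unknown = set(self.child_error_states) - set(_STATE_INDEX)
        if unknown:
            raise ValueError(f"unknown child error states: {unknown}")


@dataclass
class DeNovoCall:
    """A candidate de novo event with its scenario masses and filter flags."""

    chrom: str
    pos: int
    ref: str
    alt: str
    child_id: str
    a: float
    b: float
    c: float
    d: float
    e: float
    p_dn: float
    parent_of_origin_posterior: float  # P(maternal | de novo) = a / (a + b)
    gates: dict = field(default_factory=dict)
    gates_pass: bool = False
    internal_af: float = float("nan")
    external_af: float = float("nan")


# ---------------------------------------------------------------------------
# scenario decomposition
# ---------------------------------------------------------------------------

def hwe_priors(q: float) -> np.ndarray:
    """Hardy–Weinberg genotype priors (RR, RA, AA) at alt frequency q."""
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])


def scenario_masses(
    trio: TrioLikelihoods, q: float, priors: DnvPriorConfig | None = None
) -> tuple[float, float, float, float, float]:
    """Unnormalized posterior masses (a, b, c, d, e) for one trio site.

    ``q`` is the site's population alt-allele frequency, floored at
    ``priors.af_floor``; transmission is 1/2 from a het parent and 1 from a
    hom-alt parent.
    """
    p = priors or DnvPriorConfig()
    q = max(float(q), p.af_floor)
    if q <= 0 or q >= 1:
        raise ValueError("population frequency must lie in (0, 1) after flooring")
    pi = hwe_priors(q)
    lm, lf, lc = trio.mother, trio.father, trio.child

    both_ref = pi[RR] ** 2 * lm[RR] * lf[RR]
    a = both_ref * lc[RA] * p.mu_total * p.maternal_fraction
    b = both_ref * lc[RA] * p.mu_total * (1 - p.maternal_fraction)
    carrier_m = pi[RA] * lm[RA] * 0.5 + pi[AA] * lm[AA] * 1.0
    carrier_f = pi[RA] * lf[RA] * 0.5 + pi[AA] * lf[AA] * 1.0
    c = carrier_m * pi[RR] * lf[RR] * lc[RA]
    d = carrier_f * pi[RR] * lm[RR] * lc[RA]
    e = both_ref * sum(lc[_STATE_INDEX[s]] for s in p.child_error_states)
    return float(a), float(b), float(c), float(d), float(e)


def de_novo_probability(a: float, b: float, c: float, d: float, e: float) -> float:
    """p_dn = (a + b) / (a + b + c + d + e); NaN when all masses vanish."""
    masses = (a, b, c, d, e)
    if any(m < 0 for m in masses):
        raise ValueError("scenario masses must be non-negative")
    total = sum(masses)
    if total == 0:
        logger.warning("all scenario masses zero; de novo probability undefined")
        return float("nan")
    return (a + b) / total


# ---------------------------------------------------------------------------
# evidence gates
# ---------------------------------------------------------------------------

def evidence_gates(
    trio: TrioLikelihoods,
    min_child_ab: float = 0.3,
    max_parent_ab: float = 0.1,
    min_depth_ratio: float = 0.3,
    min_gq: float = 20.0,
    literal_child_ab: bool = False,
) -> dict[str, bool]:
    """Hard evidence gates evaluated independently of the posterior.

    * ``parent_ab``: both parents' alt-read fractions <= 0.1;
    * ``child_ab``: the child's alt-read fraction >= 0.3 (a well-supported
      het); ``literal_child_ab=True`` instead honors the printed text
      ``AB_child < 0.3`` as an acceptance condition;
    * ``depth_ratio``: DP_child / (DP_mother + DP_father) >= 0.3 — fails
      when the parental depth sum is zero;
    * ``gq``: child genotype quality >= 20.
    """
    parent_ab = bool(
        np.isfinite(trio.ab_mother) and np.isfinite(trio.ab_father)
        and trio.ab_mother <= max_parent_ab and trio.ab_father <= max_parent_ab
    )
    if literal_child_ab:
        child_ab = bool(np.isfinite(trio.ab_child) and trio.ab_child < min_child_ab)
    else:
        child_ab = bool(np.isfinite(trio.ab_child) and trio.ab_child >= min_child_ab)
    dp_par = trio.dp_mother + trio.dp_father
    depth_ratio = bool(np.isfinite(dp_par) and dp_par > 0
                       and trio.dp_child / dp_par >= min_depth_ratio)
    gq = bool(np.isfinite(trio.gq_child) and trio.gq_child >= min_gq)
    gates = {"parent_ab": parent_ab, "child_ab": child_ab,
             "depth_ratio": depth_ratio, "gq": gq}
    gates["all"] = all(gates.values())
    return gates


# ---------------------------------------------------------------------------
# cohort-level calling
# ---------------------------------------------------------------------------

def _trio_from_record(rec: VariantRecord, ic: int, im: int, if_: int) -> TrioLikelihoods | None:
    pls = []
    for i in (ic, im, if_):
        row = rec.pl[i]
        if not np.isfinite(row).all():
            return None
        pls.append(row)

    def ab(i: int) -> float:
        tot = rec.ad[i, 0] + rec.ad[i, 1]
        return float(rec.ad[i, 1] / tot) if np.isfinite(tot) and tot > 0 else float("nan")

    return TrioLikelihoods.from_pl(
        pls[0], pls[1], pls[2],
        ab_child=ab(ic), ab_mother=ab(im), ab_father=ab(if_),
        dp_child=float(rec.dp[ic]), dp_mother=float(rec.dp[im]),
        dp_father=float(rec.dp[if_]), gq_child=float(rec.gq[ic]),
    )


def call_trio(
    rec: VariantRecord,
    child_idx: int,
    mother_idx: int,
    father_idx: int,
    child_id: str,
    q: float,
    priors: DnvPriorConfig | None = None,
    **gate_kwargs,
) -> DeNovoCall | None:
    """Evaluate one trio at one biallelic site; None when PLs are unusable."""
    trio = _trio_from_record(rec, child_idx, mother_idx, father_idx)
    if trio is None:
        return None
    a, b, c, d, e = scenario_masses(trio, q, priors)
    p_dn = de_novo_probability(a, b, c, d, e)
    origin = a / (a + b) if (a + b) > 0 else float("nan")
    gates = evidence_gates(trio, **gate_kwargs)
    return DeNovoCall(rec.chrom, rec.pos, rec.ref, rec.alt, child_id,
                      a, b, c, d, e, p_dn, origin, gates, gates["all"])


def call_cohort(
    records: Iterable[VariantRecord],
    samples: Sequence[str],
    trios: Sequence[tuple[str, str, str]],
    site_af: dict | None = None,
    priors: DnvPriorConfig | None = None,
    founder_mask: np.ndarray | None = None,
    **gate_kwargs,
) -> pd.DataFrame:
    """Call candidate de novo events for every trio across a record stream.

    ``trios`` lists (child, mother, father) sample names.  Candidates are
    child genotype calls carrying the alt allele.  ``site_af`` optionally
    maps (chrom, pos, ref, alt) to an external population frequency;
    otherwise the founder-based internal frequency is used.  Returns one row
    per (site, child) candidate with masses, p_dn, gates and AFs.
    """
    idx = {s: i for i, s in enumerate(samples)}
    trio_idx = [(c, idx[c], idx[m], idx[f]) for c, m, f in trios]
    fmask = founder_mask
    if fmask is None:
        children = {c for c, _, _ in trios}
        fmask = np.array([s not in children for s in samples])
    rows = []
    for rec in records:
        dos = rec.dosage()
        carriers = dos > 0
        if not carriers.any():
            continue
        fdos = dos[fmask & (dos != MISSING)]
        internal_af = fdos.sum() / (2 * fdos.size) if fdos.size else float("nan")
        key = (rec.chrom, rec.pos, rec.ref, rec.alt)
        q = internal_af
        if site_af is not None and key in site_af:
            q = site_af[key]
        for child, ic, im, if_ in trio_idx:
            if dos[ic] != 1:
                continue
            call = call_trio(rec, ic, im, if_, child, q, priors, **gate_kwargs)
            if call is None:
                continue
            call.internal_af = internal_af
            if site_af is not None:
                call.external_af = site_af.get(key, float("nan"))
            rows.append({
                "chrom": call.chrom, "pos": call.pos, "ref": call.ref,
                "alt": call.alt, "child_id": call.child_id,
                "a": call.a, "b": call.b, "c": call.c, "d": call.d,
                "e": call.e, "p_dn": call.p_dn,
                "parent_of_origin_posterior": call.parent_of_origin_posterior,
                "gates_pass": call.gates_pass,
                **{f"gate_{k}": v for k, v in call.gates.items() if k != "all"},
                "internal_af": call.internal_af,
                "external_af": call.external_af,
            })
    cols = ["chrom", "pos", "ref", "alt", "child_id", "a", "b", "c", "d", "e",
            "p_dn", "parent_of_origin_posterior", "gates_pass",
            "gate_parent_ab", "gate_child_ab", "gate_depth_ratio", "gate_gq",
            "internal_af", "external_af"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# threshold sweep and downstream filters
# ---------------------------------------------------------------------------

def threshold_sweep(
    p_dn: Sequence[float],
    thresholds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Number of calls retained at each p_dn threshold, 0.5 down to 0.05.

    Counts are monotone non-decreasing as the threshold decreases; the
    operating default of the pipeline is 0.1.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.5, 0.0499, -0.05), 2)
    p = np.asarray(list(p_dn), dtype=float)
    counts = [int((p >= t).sum()) for t in thresholds]
    return pd.DataFrame({"threshold": list(thresholds), "n_calls": counts})


def frequency_recurrence_filter(
    calls: pd.DataFrame,
    max_af: float = 0.001,
    max_recurrence: int = 5,
    missing_external_af: float = 0.0,
    keep_recurrent: bool = False,
) -> pd.DataFrame:
    """Allele-frequency and recurrence filter on a de novo call table.

    Keeps calls whose internal and external AFs are both strictly below
    ``max_af`` and whose site is called de novo in fewer than
    ``max_recurrence`` children (recurrent sites are treated as artifacts;
    ``keep_recurrent=True`` inverts the recurrence reading).  Missing
    external AFs are imputed with ``missing_external_af`` (0 by default,
    logged).
    """
    df = calls.copy()
    ext = df["external_af"].astype(float)
    n_missing = int(ext.isna().sum())
    if n_missing:
        logger.warning("imputing %d missing external AFs as %g",
                       n_missing, missing_external_af)
        ext = ext.fillna(missing_external_af)
    keep = (df["internal_af"].astype(float) < max_af) & (ext < max_af)
    site = df[["chrom", "pos", "ref", "alt"]].astype(str).agg(":".join, axis=1)
    recurrence = site.map(site.value_counts())
    if keep_recurrent:
        keep &= recurrence >= max_recurrence
    else:
        keep &= recurrence < max_recurrence
    return df[keep].reset_index(drop=True)


def paternal_age_regression(
    counts: Sequence[float], ages_months: Sequence[float]
) -> dict[str, float]:
    """OLS of per-child de novo counts on paternal age at birth (months).

    Returns slope (DNVs per month), intercept, two-sided slope p-value and
    the 95% CI of the slope.  Requires >= 3 children and non-constant ages.
    """
    counts = np.asarray(counts, dtype=float)
    ages = np.asarray(ages_months, dtype=float)
    if counts.size != ages.size or counts.size < 3:
        raise ValueError("need >= 3 paired (count, age) observations")
    if np.ptp(ages) == 0:
        raise ValueError("ages are constant; slope undefined")
    X = sm.add_constant(ages)
    fit = sm.OLS(counts, X).fit()
    lo, hi = fit.conf_int()[1]
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "p": float(fit.pvalues[1]),
        "slope_ci_low": float(lo),
        "slope_ci_high": float(hi),
        "n": int(counts.size),
    }
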