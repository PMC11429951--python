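"""Variant prioritization and de novo burden / carrier / power statistics.

Variants are classified into PTV / missense / synonymous from their most
severe consequence term, with damaging flags for constrained PTVs
(LOEUF < 0.37) and damaging missense (MPC >= 2).  Group burden contrasts
use the one-sided exact binomial test on pooled counts (the null success
probability is the focal group's share of samples), carrier contrasts use
Fisher's exact test, and power for the burden design is computed from exact
binomial tails over a sample-size grid.  Per-child counts can be adjusted
for paternal age at birth by residualizing on an OLS fit and restoring the
grand mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from dnvsex.denovo import paternal_age_regression

logger = logging.getLogger(__name__)

PTV_TERMS = frozenset({
    "frameshift_variant", "splice_acceptor_variant", "splice_donor_variant",
    "stop_gain", "stop_gained",
})
MIS_TERMS = frozenset({
    "missense_variant", "stop_lost", "start_lost", "protein_altering_variant",
})
SYN_TERMS = frozenset({
    "synonymous_variant", "stop_retained_variant",
    "incomplete_terminal_codon_variant",
})
ALLOWED_LOFTEE_FLAGS = frozenset({"SINGLE_EXON"})

LOEUF_CONSTRAINED = 0.37
MPC_DAMAGING = 2.0


@dataclass(frozen=True)
class VariantClass:
    label: str                    # PTV | MIS | SYN | OTHER
    is_constrained_ptv: bool = False
    is_damaging_mis: bool = False


def classify_variant(
    consequence: str,
    loftee: str | None = None,
    loftee_flags: str = "",
    loeuf: float = float("nan"),
    mpc: float = float("nan"),
) -> VariantClass:
    """Classify a variant from its most severe consequence term.

    A PTV-class term only counts as PTV when LOFTEE calls it high
    confidence ("HC") with no flag other than SINGLE_EXON; otherwise it
    falls to OTHER.  Constrained-PTV and damaging-missense flags apply the
    LOEUF < 0.37 and MPC >= 2 prioritization (both as printed, the MPC
    bound inclusive).
    """
    term = (consequence or "").strip()
    if term in PTV_TERMS:
        flags = {f for f in (loftee_flags or "").replace(",", "&").split("&") if f}
        if loftee == "HC" and flags <= ALLOWED_LOFTEE_FLAGS:
            constrained = bool(np.isfinite(loeuf) and loeuf < LOEUF_CONSTRAINED)
            return VariantClass("PTV", is_constrained_ptv=constrained)
        return VariantClass("OTHER")
    if term in MIS_TERMS:
        damaging = bool(np.isfinite(mpc) and mpc >= MPC_DAMAGING)
        return VariantClass("MIS", is_damaging_mis=damaging)
    if term in SYN_TERMS:
        return VariantClass("SYN")
    if term not in PTV_TERMS | MIS_TERMS | SYN_TERMS:
        logger.debug("unrecognized consequence term %r -> OTHER", term)
    return VariantClass("OTHER")


@dataclass
class BurdenResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    k_a: float
    k_b: float
    rate_a: float
    rate_b: float
    rr: float
    p: float
    flagged: str = ""


def binomial_burden_test(
    k_a: int, k_b: int, n_a: int, n_b: int,
    direction: str = "greater",
    group_a: str = "A", group_b: str = "B",
) -> BurdenResult:
    """One-sided exact binomial burden test on pooled variant counts.

    Under the null the k_a + k_b events fall on group A with probability
    n_a / (n_a + n_b); ``direction`` tests enrichment ("greater") or
    depletion ("less") in group A.  The rate ratio is
    (k_a / n_a) / (k_b / n_b).
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("sample sizes must be positive")
    if k_a < 0 or k_b < 0:
        raise ValueError("counts must be non-negative")
    rate_a, rate_b = k_a / n_a, k_b / n_b
    total = k_a + k_b
    if total == 0:
        return BurdenResult(group_a, group_b, n_a, n_b, k_a, k_b,
                            rate_a, rate_b, float("nan"), 1.0,
                            flagged="no_events")
    null_p = n_a / (n_a + n_b)
    p = stats.binomtest(int(round(k_a)), int(round(total)), null_p,
                        alternative=direction).pvalue
    rr = rate_a / rate_b if rate_b > 0 else float("inf")
    return BurdenResult(group_a, group_b, n_a, n_b, k_a, k_b,
                        rate_a, rate_b, rr, float(p))


def rate_ratio(rate_a: float, rate_b: float, ndigits: int = 1) -> float:
    """Rate ratio of two per-sample variant rates, rounded for display."""
    if rate_b == 0:
        raise ValueError("denominator rate is zero")
    return round(rate_a / rate_b, ndigits)


def carrier_fisher(
    carriers_a: int, non_a: int, carriers_b: int, non_b: int,
    sided: str = "two-sided",
) -> dict[str, float]:
    """Fisher's exact test on a 2x2 carrier table with the sample OR and Wald CI."""
    table = np.array([[carriers_a, non_a], [carriers_b, non_b]], dtype=float)
    if (table < 0).any():
        raise ValueError("table entries must be non-negative")
    res = stats.fisher_exact(table, alternative=sided)
    if (table == 0).any():
        logger.warning("zero cell in carrier table; OR/CI use a 0.5 correction")
        t = table + 0.5
    else:
        t = table
    or_ = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    se = np.sqrt((1.0 / t).sum())
    lo, hi = np.exp(np.log(or_) + np.array([-1.96, 1.96]) * se)
    return {"odds_ratio": float(or_), "ci_low": float(lo), "ci_high": float(hi),
            "p": float(res.pvalue)}


def power_curve(
    null_p: float,
    alt_p: float,
    n_grid: Sequence[int],
    alpha: float = 0.05,
    direction: str = "greater",
) -> pd.DataFrame:
    """Exact power of the one-sided binomial test over a grid of trial counts.

    For each n the rejection region is the most extreme tail whose null
    probability does not exceed alpha; power is the alternative-distribution
    mass of that region.  With ``alt_p == null_p`` power is at most alpha
    (conservatism of the exact test).
    """
    if not (0 < null_p < 1 and 0 < alt_p < 1):
        raise ValueError("success probabilities must lie in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rows = []
    for n in n_grid:
        n = int(n)
        ks = np.arange(n + 1)
        if direction == "greater":
            tail = stats.binom.sf(ks - 1, n, null_p)   # P(X >= k | null)
            ok = np.nonzero(tail <= alpha)[0]
            if ok.size:
                k_crit = int(ks[ok[0]])
                power = float(stats.binom.sf(k_crit - 1, n, alt_p))
            else:
                k_crit, power = n + 1, 0.0
        elif direction == "less":
            tail = stats.binom.cdf(ks, n, null_p)
            ok = np.nonzero(tail <= alpha)[0]
            if ok.size:
                k_crit = int(ks[ok[-1]])
                power = float(stats.binom.cdf(k_crit, n, alt_p))
            else:
                k_crit, power = -1, 0.0
        else:
            raise ValueError("direction must be 'greater' or 'less'")
        rows.append({"n": n, "k_crit": k_crit, "power": power})
    return pd.DataFrame(rows)


def adjust_counts_paternal_age(
    counts: Sequence[float], ages_months: Sequence[float]
) -> np.ndarray:
    """Paternal-age adjustment of per-child counts: OLS residual + grand mean.

    The adjusted counts are orthogonal to age and preserve the raw mean
    exactly, so group contrasts on them remove the age confound without
    shifting the overall rate.
    """
    counts = np.asarray(counts, dtype=float)
    ages = np.asarray(ages_months, dtype=float)
    fit = paternal_age_regression(counts, ages)
    expected = fit["intercept"] + fit["slope"] * ages
    return counts - expected + counts.mean()
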