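"""Polygenic-score computation with cross-ancestry harmonization.

The scoring pipeline matches a GWAS-derived weight table against target
sites by position and normalized alleles (long alleles are abbreviated to
their first 13 bases plus the decimal remainder of their length), excludes
strand-ambiguous SNPs (A/T, C/G) and indel pairs that are reverses of each
other at the same locus, optionally screens matched SNPs whose target-vs-
reference allele-frequency difference is an outlier (per-SNP chi-square
screen and/or the 1-SD rule on AF differences), scores samples as the
dosage-weighted sum of effect sizes with flip-corrected orientation, and
standardizes scores against a declared reference distribution.  Group
statistics on standardized scores: Welch/pooled t contrasts in reference-SD
units and logistic regression odds ratios per SD.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_VALID = set("ACGTN")


def normalize_allele(allele: str) -> str:
    """Canonical allele representation: first 13 bases + (length - 13).

    Alleles of 13 bp or shorter are unchanged; longer alleles become their
    first 13 nucleotides concatenated with the decimal string of the
    remaining length.
    """
    if not allele:
        raise ValueError("empty allele")
    a = allele.upper()
    if set(a) - _VALID:
        raise ValueError(f"non-ACGTN characters in allele {allele!r}")
    if len(a) <= 13:
        return a
    return a[:13] + str(len(a) - 13)


def _is_indel(a1: str, a2: str) -> bool:
    return len(a1) != len(a2)


def match_snps(weights: pd.DataFrame, targets: pd.DataFrame) -> pd.DataFrame:
    """Match a weight table against target sites; returns the full ledger.

    ``weights`` needs columns chrom, pos, a1 (effect allele), a2, beta (an
    rsid column is carried through if present); ``targets`` needs chrom,
    pos, ref, alt.  Statuses: ``matched`` (a1=alt, a2=ref), ``flipped``
    (a1=ref, a2=alt; beta applies to the reference allele),
    ``excluded_ambiguous`` (A/T, C/G SNP), ``excluded_reverse_indel``
    (indel at the same locus with alleles reversed), ``unmatched``.
    Duplicate positions keep the first occurrence with a log entry.
    """
    w = weights.copy()
    t = targets.copy()
    for df, cols in ((w, ("a1", "a2")), (t, ("ref", "alt"))):
        for c in cols:
            df[c + "_norm"] = df[c].map(normalize_allele)
        dup = df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            logger.warning("dropping %d duplicate positions", int(dup.sum()))
            df.drop(index=df.index[dup], inplace=True)
    t_by_pos = t.set_index(["chrom", "pos"])

    rows = []
    for _, row in w.iterrows():
        status = "unmatched"
        target_key = None
        if (row["a1"].upper(), row["a2"].upper()) in AMBIGUOUS_PAIRS:
            status = "excluded_ambiguous"
        else:
            key = (row["chrom"], row["pos"])
            if key in t_by_pos.index:
                tr = t_by_pos.loc[key]
                ref, alt = tr["ref_norm"], tr["alt_norm"]
                a1, a2 = row["a1_norm"], row["a2_norm"]
                if (a1, a2) == (alt, ref):
                    status = "matched"
                elif (a1, a2) == (ref, alt):
                    if _is_indel(a1, a2):
                        status = "excluded_reverse_indel"
                    else:
                        status = "flipped"
                if status in ("matched", "flipped"):
                    target_key = (tr["ref"], tr["alt"])
        rows.append({
            "chrom": row["chrom"], "pos": row["pos"],
            "rsid": row.get("rsid", ""), "a1": row["a1"], "a2": row["a2"],
            "beta": row["beta"], "status": status,
            "target_ref": target_key[0] if target_key else "",
            "target_alt": target_key[1] if target_key else "",
        })
    return pd.DataFrame(rows)


def harmonize_af(
    ledger: pd.DataFrame,
    target_af: pd.Series | Sequence[float],
    ref_af: pd.Series | Sequence[float],
    n_target: int = 1000,
    n_ref: int = 1000,
    chi2_alpha: float | None = None,
    sd_rule: bool = True,
) -> pd.DataFrame:
    """Exclude matched SNPs whose AF contrast is an outlier.

    AFs are per matched row of the ledger, on the effect-allele scale.  Two
    screens are available and applied conjunctively: a per-SNP chi-square
    test on allele counts (active when ``chi2_alpha`` is set) and the 1-SD
    rule — a SNP is excluded when its target-minus-reference AF difference
    deviates from the mean difference of all matched SNPs by more than one
    SD of those differences.  Excluded rows get status
    ``excluded_af_outlier``.  When the SD of differences is zero nothing is
    excluded.
    """
    out = ledger.copy()
    matched = out["status"].isin(["matched", "flipped"]).to_numpy()
    ta = np.asarray(target_af, dtype=float)
    ra = np.asarray(ref_af, dtype=float)
    if ta.size != len(out) or ra.size != len(out):
        raise ValueError("AF vectors must align with the ledger rows")
    if ((ta[matched] <= 0) | (ta[matched] >= 1)).any() or \
       ((ra[matched] <= 0) | (ra[matched] >= 1)).any():
        raise ValueError("allele frequencies must lie in (0, 1)")

    exclude = np.zeros(len(out), dtype=bool)
    if chi2_alpha is not None:
        for i in np.flatnonzero(matched):
            tab = np.array([
                [ta[i] * 2 * n_target, (1 - ta[i]) * 2 * n_target],
                [ra[i] * 2 * n_ref, (1 - ra[i]) * 2 * n_ref],
            ])
            p = stats.chi2_contingency(tab, correction=False)[1]
            if p < chi2_alpha:
                exclude[i] = True
    if sd_rule:
        diff = ta - ra
        d = diff[matched]
        sd = d.std(ddof=0)
        if sd == 0:
            logger.info("AF differences have zero SD; 1-SD rule excludes nothing")
        else:
            exclude |= matched & (np.abs(diff - d.mean()) > sd)
    out.loc[exclude & matched, "status"] = "excluded_af_outlier"
    return out


def score_samples(ledger: pd.DataFrame, dosages: pd.DataFrame) -> pd.Series:
    """Raw polygenic score per sample: sum of effect-allele dosage x beta.

    ``dosages`` is samples x sites with columns labelled ``chrom:pos`` and
    entries in [0, 2] counting the target *alt* allele; flipped rows score
    the reference allele (2 - dosage).  Missing dosages are mean-imputed
    per SNP.  Raises when no SNP survives the ledger.
    """
    use = ledger[ledger["status"].isin(["matched", "flipped"])]
    if use.empty:
        raise ValueError("no matched SNPs to score")
    score = pd.Series(0.0, index=dosages.index)
    for _, row in use.iterrows():
        col = f"{row['chrom']}:{row['pos']}"
        if col not in dosages.columns:
            continue
        d = dosages[col].astype(float)
        if d.isna().any():
            logger.debug("mean-imputing %d missing dosages at %s",
                         int(d.isna().sum()), col)
            d = d.fillna(d.mean())
        if row["status"] == "flipped":
            d = 2.0 - d
        score += d * row["beta"]
    return score


def standardize(values: Sequence[float], reference: Sequence[float]) -> np.ndarray:
    """z-scores of ``values`` against the reference distribution (ddof=0)."""
    ref = np.asarray(reference, dtype=float)
    sd = ref.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("reference distribution is degenerate")
    return (np.asarray(values, dtype=float) - ref.mean()) / sd


def group_diff(
    z: Sequence[float], labels: Sequence, group_a, group_b,
    equal_var: bool = False,
) -> dict[str, float]:
    """Two-sample t contrast of standardized scores between two groups.

    Returns the mean difference (A minus B, in reference-SD units when z
    was standardized), the Welch (default) or pooled t statistic, its
    two-sided p-value and the 95% CI of the difference.
    """
    z = np.asarray(z, dtype=float)
    labels = np.asarray(labels)
    za, zb = z[labels == group_a], z[labels == group_b]
    if za.size < 2 or zb.size < 2:
        raise ValueError("each group needs at least two observations")
    res = stats.ttest_ind(za, zb, equal_var=equal_var)
    ci = res.confidence_interval(0.95)
    return {"delta": float(za.mean() - zb.mean()), "t": float(res.statistic),
            "p": float(res.pvalue), "ci_low": float(ci.low),
            "ci_high": float(ci.high), "n_a": int(za.size), "n_b": int(zb.size)}


def ps_logistic_or(z: Sequence[float], labels: Sequence[int]) -> dict[str, float]:
    """Logistic regression of a binary group label on the standardized score.

    Returns the odds ratio per 1 SD of score with its Wald 95% CI and
    p-value.  Perfect separation is flagged instead of reporting a
    diverging estimate.
    """
    z = np.asarray(z, dtype=float)
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both labels must be present")
    X = sm.add_constant(z)
    try:
        fit = sm.Logit(y, X).fit(disp=0)
    except Exception as exc:  # PerfectSeparationError and friends
        return {"odds_ratio": float("nan"), "ci_low": float("nan"),
                "ci_high": float("nan"), "p": float("nan"),
                "flagged": f"no_estimate: {exc}"}
    coef = fit.params[1]
    if (not fit.mle_retvals.get("converged", True) or abs(coef) > 30
            or not np.isfinite(fit.bse).all() or fit.bse[1] > 100):
        return {"odds_ratio": float("nan"), "ci_low": float("nan"),
                "ci_high": float("nan"), "p": float("nan"),
                "flagged": "separation"}
    lo, hi = fit.conf_int()[1]
    return {"odds_ratio": float(np.exp(coef)), "ci_low": float(np.exp(lo)),
            "ci_high": float(np.exp(hi)), "p": float(fit.pvalues[1]),
            "flagged": ""}
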