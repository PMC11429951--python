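"""Sex-ratio stratification and the sex-differential liability-threshold model.

The male-to-female ratio among affected individuals, its exact
(Clopper–Pearson) confidence interval mapped from the male proportion to
the ratio scale, odds ratios between severity strata (algebraically the
quotient of the strata's sex ratios), family-wise phenotype contrasts, and
a population liability simulator.

Under the liability-threshold model each individual carries a latent
liability — polygenic + rare de novo + residual components, standardized to
unit variance — and is affected when liability exceeds their sex's
threshold.  A higher female threshold yields (i) a male-biased affected sex
ratio, (ii) a ratio that declines across increasingly severe strata,
(iii) affected females with more de novo carriers, and (iv) unaffected
females tolerating more polygenic burden at lower expressed severity — the
patterns the stratified statistics quantify.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# sex ratios and stratum odds ratios
# ---------------------------------------------------------------------------

@dataclass
class SexRatioResult:
    n_male: int
    n_female: int
    ratio: float
    ci_low: float
    ci_high: float

    @property
    def display(self) -> float:
        """Ratio rounded to one decimal, matching reporting convention."""
        return round(self.ratio, 1)


def sex_ratio(n_male: int, n_female: int, conf: float = 0.95) -> SexRatioResult:
    """Male-to-female ratio with an exact binomial CI on the ratio scale.

    The Clopper–Pearson interval for the male proportion p among
    n_male + n_female individuals is transformed monotonically by
    p / (1 - p).  Requires at least one female.
    """
    if n_male < 0 or n_female < 1:
        raise ValueError("need non-negative male and >= 1 female counts")
    n = n_male + n_female
    ci = stats.binomtest(n_male, n).proportion_ci(conf, method="exact")
    to_ratio = lambda p: p / (1 - p) if p < 1 else float("inf")
    return SexRatioResult(n_male, n_female, n_male / n_female,
                          to_ratio(ci.low), to_ratio(ci.high))


def ratio_of_ratios(ratio_a: float, ratio_b: float, ndigits: int = 2) -> float:
    """Quotient of two male:female ratios, rounded for display."""
    if ratio_b == 0:
        raise ValueError("denominator ratio is zero")
    return round(ratio_a / ratio_b, ndigits)


@dataclass
class StratumOr:
    table: np.ndarray
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    flagged: str = ""


def stratum_or(table: Sequence[Sequence[float]]) -> StratumOr:
    """Sex-by-stratum 2x2 odds ratio with two-sided Fisher exact p.

    Rows are strata, columns (male, female) counts.  The OR equals the
    quotient of the two strata's male:female ratios exactly.  The 95% CI is
    the Wald interval on the log OR (0.5 added to every cell when a zero
    margin occurs, flagged).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    flag = ""
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        flag = "empty_margin"
        logger.warning("degenerate stratum table; OR flagged")
    p = stats.fisher_exact(t, alternative="two-sided").pvalue
    tc = t + 0.5 if (t == 0).any() else t
    or_ = (tc[0, 0] * tc[1, 1]) / (tc[0, 1] * tc[1, 0])
    se = math.sqrt((1.0 / tc).sum())
    lo, hi = np.exp(np.log(or_) + np.array([-1.96, 1.96]) * se)
    return StratumOr(t, float(or_), float(lo), float(hi), float(p), flag)


# ---------------------------------------------------------------------------
# liability simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LiabilityParams:
    """Parameters of the population liability simulator.

    Thresholds are in liability SD units; the three variance components
    must sum to one.  The de novo component is a rare large-effect carrier
    state (probability ``dnv_carrier_prob``) scaled to contribute
    ``var_denovo``.  ``severity_cutpoints`` are liability quantiles among
    the affected defining the normative / mild-moderate / severe strata.
    """

    threshold_female: float = 2.3
    threshold_male: float = 1.7
    var_polygenic: float = 0.5
    var_denovo: float = 0.05
    var_residual: float = 0.45
    dnv_carrier_prob: float = 0.02
    severity_cutpoints: tuple[float, ...] = (1 / 3, 2 / 3)
    n: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.threshold_female)
                and math.isfinite(self.threshold_male)):
            raise ValueError("thresholds must be finite")
        total = self.var_polygenic + self.var_denovo + self.var_residual
        if min(self.var_polygenic, self.var_denovo, self.var_residual) < 0:
            raise ValueError("variance components must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError("variance components must sum to 1")
        if self.n <= 0:
            raise ValueError("n must be positive")


SEVERITY_LABELS = ("normative", "mild_moderate", "severe")


def simulate_liability(params: LiabilityParams | None = None) -> pd.DataFrame:
    """Simulate a population cohort under the liability-threshold model.

    Returns one row per individual: sex, polygenic component, de novo
    carrier flag, total liability, affected status, and — among the
    affected — the severity stratum from the pooled liability quantiles.
    """
    p = params or LiabilityParams()
    rng = np.random.default_rng(p.seed)
    n = p.n
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    polygenic = rng.normal(0.0, math.sqrt(p.var_polygenic), n)
    carrier = rng.random(n) < p.dnv_carrier_prob
    q = p.dnv_carrier_prob
    effect = math.sqrt(p.var_denovo / (q * (1 - q))) if p.var_denovo > 0 else 0.0
    denovo = (carrier.astype(float) - q) * effect
    residual = rng.normal(0.0, math.sqrt(p.var_residual), n)
    liability = polygenic + denovo + residual
    thr = np.where(sex == "female", p.threshold_female, p.threshold_male)
    affected = liability > thr

    stratum = np.full(n, "", dtype=object)
    if affected.any():
        la = liability[affected]
        cuts = np.quantile(la, p.severity_cutpoints)
        idx = np.searchsorted(cuts, la, side="right")
        stratum[affected] = np.array(SEVERITY_LABELS)[idx]
    return pd.DataFrame({
        "sex": sex, "polygenic": polygenic, "dnv_carrier": carrier,
        "liability": liability, "affected": affected,
        "severity_stratum": stratum,
    })


def severity_sex_ratios(cohort: pd.DataFrame) -> pd.DataFrame:
    """Male:female ratio of affected individuals within each severity stratum."""
    rows = []
    aff = cohort[cohort["affected"]]
    for label in SEVERITY_LABELS:
        sub = aff[aff["severity_stratum"] == label]
        n_m = int((sub["sex"] == "male").sum())
        n_f = int((sub["sex"] == "female").sum())
        ratio = n_m / n_f if n_f else (float("inf") if n_m else float("nan"))
        rows.append({"stratum": label, "n_male": n_m, "n_female": n_f,
                     "ratio": ratio})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# family contrasts
# ---------------------------------------------------------------------------

def family_tolerance_report(
    samples: pd.DataFrame,
    ps_col: str = "ps_z",
    phenotype_cols: Sequence[str] = (),
) -> pd.DataFrame:
    """Sex contrasts of polygenic burden and phenotype severity within roles.

    For unaffected siblings and for parents, reports the female and male
    mean of the standardized polygenic score and of each phenotype column,
    with Welch t-test p-values and a Bonferroni adjustment by the number of
    phenotype features tested within the role (the polygenic contrast is
    reported unadjusted).  Roles with a missing sex group are skipped with
    a log entry.
    """
    rows = []
    groups = {"sibling": samples[samples["role"] == "sibling"],
              "parent": samples[samples["role"].isin(["mother", "father"])]}
    for role, df in groups.items():
        f = df[df["sex"] == "female"]
        m = df[df["sex"] == "male"]
        if len(f) < 2 or len(m) < 2:
            logger.warning("role %s lacks a sex group; skipped", role)
            continue
        features = [ps_col] + [c for c in phenotype_cols if c in df.columns]
        n_pheno = max(1, len(features) - 1)
        for feat in features:
            res = stats.ttest_ind(f[feat].astype(float), m[feat].astype(float),
                                  equal_var=False)
            p = float(res.pvalue)
            adj = p if feat == ps_col else min(1.0, p * n_pheno)
            rows.append({
                "role": role, "feature": feat,
                "mean_female": float(f[feat].mean()),
                "mean_male": float(m[feat].mean()),
                "diff_female_minus_male": float(f[feat].mean() - m[feat].mean()),
                "p": p, "p_adjusted": adj,
            })
    return pd.DataFrame(rows)


def pair_anova(
    data: pd.DataFrame,
    score_col: str,
    case_sex_col: str = "case_sex",
    sib_sex_col: str = "sib_sex",
    alpha: float = 0.05,
) -> dict:
    """Two-way ANOVA of a sibling phenotype on case sex x sibling sex.

    Fits ``score ~ C(case_sex) * C(sib_sex)`` with type-II sums of squares,
    then Tukey HSD over the four sex-pair cells (F_S-F_C, M_S-F_C, F_S-M_C,
    M_S-M_C); only Tukey-adjusted p-values below ``alpha`` are reported as
    significant.  Every cell must hold at least two observations.
    """
    df = data[[score_col, case_sex_col, sib_sex_col]].dropna().copy()
    cells = df.groupby([case_sex_col, sib_sex_col]).size()
    if len(cells) < 4 or (cells < 2).any():
        raise ValueError("each case-sex x sibling-sex cell needs >= 2 observations")
    model = smf.ols(
        f"{score_col} ~ C({case_sex_col}) * C({sib_sex_col})", data=df
    ).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    group = (df[sib_sex_col].str[0].str.upper() + "S-"
             + df[case_sex_col].str[0].str.upper() + "C")
    tukey = pairwise_tukeyhsd(df[score_col].to_numpy(dtype=float),
                              group.to_numpy(), alpha=alpha)
    tk = pd.DataFrame(tukey.summary().data[1:],
                      columns=tukey.summary().data[0])
    tk["p-adj"] = tk["p-adj"].astype(float)
    significant = tk[tk["p-adj"] < alpha]
    return {
        "anova": anova,
        "cell_means": df.groupby([case_sex_col, sib_sex_col])[score_col].mean(),
        "tukey": tk,
        "significant_pairs": significant,
    }
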