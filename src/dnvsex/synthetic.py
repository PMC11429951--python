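"""Synthetic trio-cohort generator.

Emulates the statistical structure the downstream analyses assume, so that
every pipeline stage is testable without access-controlled data:

* trio genotypes with Mendelian transmission from Hardy–Weinberg founder
  genotypes over a compact pseudo-genome of unlinked sites;
* planted de novo events at a per-child rate linear in paternal age
  (Poisson, matching the study's printed slope of 0.13 events per
  paternal-age month);
* a binomial read model: per-call depth is Poisson at the target coverage,
  alt reads are binomial at the true allele balance mixed with a per-base
  miscall rate, and PL/GQ/AD/DP follow standard VCF semantics from that
  same likelihood — so caller oracle tests are exact;
* polygenic scores with configurable group mean shifts (cases and parents
  above the population, in population-SD units);
* phenotypes generated under a sex-differential liability threshold, with
  severity scores affine in the liability excess over the sex's threshold.

Ground truth (planted de novo events, artifact sites) is persisted to a
ledger distinct from the emitted VCF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from dnvsex.qc import MISSING, PL_CAP, VariantRecord

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a synthetic trio cohort.

    Defaults mirror the study cohort: 673 families, a 5.6:1 male:female
    proband ratio, sibling availability of roughly one in three families,
    paternal ages uniform on 240–600 months, ~68 autosomal de novo events
    per child on average with a slope of 0.13 events per paternal-age
    month, a 0.32-SD case and 0.16-SD parent polygenic shift, and 30x
    coverage.
    """

    n_families: int = 673
    sibling_fraction: float = 213 / 673
    proband_sex_odds: float = 5.6            # male:female odds among probands
    paternal_age_months: tuple[int, int] = (240, 600)
    dnv_intercept: float = 13.4              # expected DNVs at age 0
    dnv_slope: float = 0.13                  # extra DNVs per month
    frac_ptv_constrained: float = 0.01
    ps_shift_case: float = 0.32
    ps_shift_parent: float = 0.16
    seq_error: float = 0.005
    mean_depth: float = 30.0
    n_inherited_sites: int = 200
    frac_indel: float = 0.1
    artifact_rate: float = 0.2               # expected artifact sites per child
    artifact_ab: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sibling_fraction", "frac_ptv_constrained", "seq_error",
                     "frac_indel", "artifact_ab"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_families <= 0:
            raise ValueError("n_families must be positive")
        if self.dnv_slope < 0:
            raise ValueError("dnv_slope must be non-negative")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


@dataclass(frozen=True)
class LiabilityLink:
    """Sex-differential liability model linking genetics to phenotypes.

    Liability is polygenic + de novo + residual with the given variance
    shares; an individual is affected when liability exceeds their sex's
    threshold.  Default thresholds put the upper-tail prevalence near 4.5%
    for males and 1.1% for females (about a 4:1 affected sex ratio in an
    unascertained population).  Severity instruments are affine in the
    liability excess over the sex threshold, truncated to declared ranges.
    """

    threshold_female: float = 2.3
    threshold_male: float = 1.7
    var_polygenic: float = 0.5
    var_denovo: float = 0.05
    var_residual: float = 0.45
    dnv_carrier_prob: float = 0.02

    def __post_init__(self) -> None:
        for t in (self.threshold_female, self.threshold_male):
            if not math.isfinite(t):
                raise ValueError("thresholds must be finite")
        total = self.var_polygenic + self.var_denovo + self.var_residual
        if min(self.var_polygenic, self.var_denovo, self.var_residual) < 0:
            raise ValueError("variance components must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError("variance components must sum to 1")

    def threshold(self, sex: str) -> float:
        return self.threshold_female if sex == "female" else self.threshold_male


#: Declared score ranges per instrument (clip bounds of the affine link).
INSTRUMENT_RANGES = {
    "srs_t": (30.0, 90.0),
    "fsiq": (40.0, 160.0),
    "vabs_composite": (20.0, 140.0),
    "ados_css": (1.0, 10.0),
    "ados_sa": (1.0, 10.0),
    "ados_rrb": (1.0, 10.0),
    "adir_a": (0.0, 30.0),
    "adir_b_verbal": (0.0, 26.0),
    "adir_b_nonverbal": (0.0, 14.0),
    "adir_c": (0.0, 12.0),
}


# ---------------------------------------------------------------------------
# de novo count model
# ---------------------------------------------------------------------------

def simulate_dnv_counts(
    ages_months: Sequence[float],
    intercept: float,
    slope: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-child de novo counts ~ Poisson(intercept + slope * age_months)."""
    ages = np.asarray(ages_months, dtype=float)
    lam = intercept + slope * ages
    if (lam < 0).any():
        raise ValueError("negative Poisson mean; check intercept/slope")
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# read model
# ---------------------------------------------------------------------------

def simulate_calls(
    dosage: np.ndarray,
    mean_depth: float,
    seq_error: float,
    rng: np.random.Generator,
    alt_fraction_override: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Simulate GT/AD/DP/GQ/PL for one site across samples.

    Depth is Poisson(mean_depth); alt reads are binomial at the genotype's
    true allele fraction mixed with the miscall rate; PL is the phred-scaled
    binomial likelihood over dosage hypotheses (capped at 255), GQ the gap
    between the two smallest PLs, and GT the maximum-likelihood dosage.
    ``alt_fraction_override`` forces the *read* alt fraction at selected
    samples (used for planted artifact sites) without touching truth.
    """
    dosage = np.asarray(dosage)
    n = dosage.size
    dp = rng.poisson(mean_depth, size=n)
    p_true = (dosage / 2.0) * (1 - seq_error) + (1 - dosage / 2.0) * seq_error
    if alt_fraction_override is not None:
        p_true = np.where(np.isnan(alt_fraction_override), p_true,
                          alt_fraction_override)
    alt = rng.binomial(dp, p_true)
    ref = dp - alt

    # log-likelihood of the read pile under each dosage hypothesis;
    # xlogy gives 0*log(0) = 0 and k*log(0) = -inf, so the error-free limit
    # stays exact
    p_hyp = np.array([seq_error, 0.5, 1 - seq_error])
    ll = (special.xlogy(alt[:, None], p_hyp[None, :])
          + special.xlog1py(ref[:, None], -p_hyp[None, :]))
    with np.errstate(invalid="ignore"):
        pl = -10.0 / np.log(10.0) * (ll - ll.max(axis=1, keepdims=True))
    pl = np.where(np.isnan(pl), PL_CAP, pl)
    pl = np.minimum(np.round(pl), PL_CAP)

    gt_dos = pl.argmin(axis=1)
    pl_sorted = np.sort(pl, axis=1)
    gq = pl_sorted[:, 1] - pl_sorted[:, 0]

    gt = np.empty((n, 2), dtype=np.int8)
    gt[:, 0] = (gt_dos >= 1).astype(np.int8)
    gt[:, 1] = (gt_dos == 2).astype(np.int8)
    gt[dp == 0] = MISSING

    ad = np.stack([ref, alt], axis=1).astype(float)
    out = {"gt": gt, "ad": ad, "dp": dp.astype(float),
           "gq": gq.astype(float), "pl": pl.astype(float)}
    return out


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A generated cohort: tables, VCF-shaped records and the truth ledger."""

    config: CohortConfig
    samples: pd.DataFrame          # sample_id, family_id, role, sex, ...
    ped: pd.DataFrame              # 6-column pedigree
    records: list[VariantRecord]
    truth: pd.DataFrame            # planted de novo / artifact ledger
    annotations: pd.DataFrame      # site consequence / LOEUF / MPC / external AF
    truth_gt: np.ndarray           # (n_sites, n_samples) true dosages
    site_index: pd.DataFrame       # chrom, pos, ref, alt per record

    @property
    def sample_names(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    def trios(self) -> list[tuple[str, str, str]]:
        out = []
        for _, row in self.samples.iterrows():
            if row["role"] in ("proband", "sibling"):
                fam = row["family_id"]
                out.append((row["sample_id"], f"{fam}_mo", f"{fam}_fa"))
        return out

    def founder_mask(self) -> np.ndarray:
        return self.samples["role"].isin(["mother", "father"]).to_numpy()


def _random_alleles(rng: np.random.Generator, indel: bool) -> tuple[str, str]:
    ref_b, alt_b = rng.choice(4, size=2, replace=False)
    if not indel:
        return _BASES[ref_b], _BASES[alt_b]
    ins_len = int(rng.integers(1, 6))
    tail = "".join(rng.choice(_BASES, size=ins_len))
    if rng.random() < 0.5:
        return _BASES[ref_b], _BASES[ref_b] + tail   # insertion
    return _BASES[ref_b] + tail, _BASES[ref_b]       # deletion


def _build_samples(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    p_male = cfg.proband_sex_odds / (1 + cfg.proband_sex_odds)
    rows = []
    for f in range(cfg.n_families):
        fam = f"F{f:04d}"
        rows.append((f"{fam}_fa", fam, "father", "male", np.nan, False))
        rows.append((f"{fam}_mo", fam, "mother", "female", np.nan, False))
        age_p = int(rng.integers(cfg.paternal_age_months[0],
                                 cfg.paternal_age_months[1] + 1))
        sex_p = "male" if rng.random() < p_male else "female"
        rows.append((f"{fam}_p1", fam, "proband", sex_p, age_p, True))
        if rng.random() < cfg.sibling_fraction:
            age_s = int(rng.integers(cfg.paternal_age_months[0],
                                     cfg.paternal_age_months[1] + 1))
            sex_s = "male" if rng.random() < 0.5 else "female"
            rows.append((f"{fam}_s1", fam, "sibling", sex_s, age_s, False))
    df = pd.DataFrame(rows, columns=["sample_id", "family_id", "role", "sex",
                                     "paternal_age_at_birth", "affected"])
    shift = df["role"].map({"proband": None, "sibling": cfg.ps_shift_parent,
                            "mother": cfg.ps_shift_parent,
                            "father": cfg.ps_shift_parent})
    shift = shift.fillna(0.0) + np.where(df["role"] == "proband",
                                         cfg.ps_shift_case, 0.0)
    df["ps_true"] = rng.normal(shift.to_numpy(dtype=float), 1.0)
    return df


def _annotate_site(rng: np.random.Generator, is_dnv: bool,
                   frac_ptv: float) -> dict:
    """Draw a consequence annotation for a site (DNVs get the PTV budget)."""
    u = rng.random()
    if is_dnv and u < frac_ptv:
        term = rng.choice(["stop_gain", "frameshift_variant",
                           "splice_acceptor_variant", "splice_donor_variant"])
        return {"consequence": term, "loftee": "HC", "loftee_flags": "",
                "loeuf": float(rng.uniform(0.03, 0.37)),
                "mpc": np.nan}
    u = rng.random()
    if u < 0.3:
        return {"consequence": "missense_variant", "loftee": "", "loftee_flags": "",
                "loeuf": float(rng.uniform(0.1, 2.0)),
                "mpc": float(rng.uniform(0.0, 4.0))}
    if u < 0.5:
        return {"consequence": "synonymous_variant", "loftee": "",
                "loftee_flags": "", "loeuf": float(rng.uniform(0.1, 2.0)),
                "mpc": np.nan}
    return {"consequence": "intron_variant", "loftee": "", "loftee_flags": "",
            "loeuf": np.nan, "mpc": np.nan}


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a full trio cohort; byte-identical for identical config."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    samples = _build_samples(cfg, rng)
    n_samples = len(samples)
    sample_pos = {s: i for i, s in enumerate(samples["sample_id"])}
    fam_members: dict[str, dict[str, int]] = {}
    for _, row in samples.iterrows():
        fam_members.setdefault(row["family_id"], {})[row["role"]] = \
            sample_pos[row["sample_id"]]

    children = samples[samples["role"].isin(["proband", "sibling"])]

    # --- site plan -------------------------------------------------------
    site_defs = []   # (ref, alt, af, kind, child_idx, origin)
    for _ in range(cfg.n_inherited_sites):
        indel = rng.random() < cfg.frac_indel
        ref, alt = _random_alleles(rng, indel)
        if rng.random() < 0.5:
            af = float(rng.uniform(0.05, 0.5))
        else:
            af = float(10 ** rng.uniform(-3, -1))
        site_defs.append((ref, alt, af, "inherited", None, None))

    dnv_counts = simulate_dnv_counts(
        children["paternal_age_at_birth"].to_numpy(dtype=float),
        cfg.dnv_intercept, cfg.dnv_slope, rng)
    for (_, child), k in zip(children.iterrows(), dnv_counts):
        ci = sample_pos[child["sample_id"]]
        for _ in range(int(k)):
            ref, alt = _random_alleles(rng, False)
            origin = "maternal" if rng.random() < 0.5 else "paternal"
            site_defs.append((ref, alt, 0.0, "de_novo", ci, origin))
        for _ in range(int(rng.poisson(cfg.artifact_rate))):
            ref, alt = _random_alleles(rng, False)
            site_defs.append((ref, alt, 0.0, "artifact", ci, None))

    order = rng.permutation(len(site_defs))
    site_defs = [site_defs[i] for i in order]

    # --- genotype truth + reads -----------------------------------------
    records: list[VariantRecord] = []
    truth_rows, annot_rows, site_rows = [], [], []
    truth_gt = np.zeros((len(site_defs), n_samples), dtype=np.int8)
    child_ids = samples["sample_id"].to_numpy()

    for s_i, (ref, alt, af, kind, ci, origin) in enumerate(site_defs):
        pos = (s_i + 1) * 100
        dosage = np.zeros(n_samples, dtype=np.int8)
        override = None
        if kind == "inherited":
            hap = {}
            for fam, members in fam_members.items():
                fa_h = rng.random(2) < af
                mo_h = rng.random(2) < af
                dosage[members["father"]] = fa_h.sum()
                dosage[members["mother"]] = mo_h.sum()
                hap[fam] = (mo_h, fa_h)
            for _, child in children.iterrows():
                mo_h, fa_h = hap[child["family_id"]]
                dosage[sample_pos[child["sample_id"]]] = (
                    mo_h[rng.integers(2)] + fa_h[rng.integers(2)])
        elif kind == "de_novo":
            dosage[ci] = 1
        else:  # artifact: everyone truly hom-ref; child reads contaminated
            override = np.full(n_samples, np.nan)
            override[ci] = cfg.artifact_ab
        truth_gt[s_i] = dosage

        calls = simulate_calls(dosage, cfg.mean_depth, cfg.seq_error, rng,
                               alt_fraction_override=override)
        qual = float(min(999.0, 20.0 + 3.0 * calls["ad"][:, 1].sum()))
        records.append(VariantRecord("1", pos, ref, (alt,), qual,
                                     calls["gt"], calls["ad"], calls["dp"],
                                     calls["gq"], calls["pl"]))
        site_rows.append(("1", pos, ref, alt))
        ann = _annotate_site(rng, kind == "de_novo", cfg.frac_ptv_constrained)
        annot_rows.append({"chrom": "1", "pos": pos, "ref": ref, "alt": alt,
                           "external_af": af if kind == "inherited" else 0.0,
                           **ann})
        if kind in ("de_novo", "artifact"):
            label = f"de_novo_{origin}" if kind == "de_novo" else "artifact"
            truth_rows.append({"chrom": "1", "pos": pos, "ref": ref,
                               "alt": alt, "child_id": child_ids[ci],
                               "truth_label": label, "population_af": af})

    ped = pd.DataFrame({
        "family_id": samples["family_id"],
        "sample_id": samples["sample_id"],
        "father_id": [f"{f}_fa" if r in ("proband", "sibling") else "0"
                      for f, r in zip(samples["family_id"], samples["role"])],
        "mother_id": [f"{f}_mo" if r in ("proband", "sibling") else "0"
                      for f, r in zip(samples["family_id"], samples["role"])],
        "sex": samples["sex"].map({"male": 1, "female": 2}),
        "phenotype": samples["affected"].map({True: 2, False: 1}),
    })
    truth = pd.DataFrame(truth_rows, columns=["chrom", "pos", "ref", "alt",
                                              "child_id", "truth_label",
                                              "population_af"])
    return Cohort(cfg, samples, ped, records, truth,
                  pd.DataFrame(annot_rows), truth_gt,
                  pd.DataFrame(site_rows, columns=["chrom", "pos", "ref", "alt"]))


# ---------------------------------------------------------------------------
# phenotypes under the sex-differential liability threshold
# ---------------------------------------------------------------------------

def _truncated_normal(rng, lower=-np.inf, upper=np.inf, size=1):
    return stats.truncnorm.rvs(lower, upper, size=size,
                               random_state=np.random.RandomState(
                                   rng.integers(2 ** 31)))


def generate_phenotypes(
    samples: pd.DataFrame,
    link: LiabilityLink | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach liability, affection status and instrument scores to a sample table.

    Liability = sqrt(var_polygenic) * ps_true + de novo component +
    sqrt(var_residual) * residual.  Probands are ascertained: their residual
    is drawn conditional on liability exceeding the sex threshold; all other
    roles are conditioned below it.  Severity instruments are deterministic
    affine maps of the liability excess over the sex's threshold (a second,
    partially correlated dimension drives the cognitive/adaptive scores),
    truncated to :data:`INSTRUMENT_RANGES`.
    """
    lk = link or LiabilityLink()
    rng = np.random.default_rng(seed)
    df = samples.copy()
    n = len(df)

    if "dnv_carrier" in df.columns:
        carrier = df["dnv_carrier"].to_numpy(dtype=bool)
    else:
        carrier = rng.random(n) < lk.dnv_carrier_prob
        df["dnv_carrier"] = carrier
    p = lk.dnv_carrier_prob
    effect = math.sqrt(lk.var_denovo / (p * (1 - p))) if lk.var_denovo > 0 else 0.0
    dn_comp = (carrier.astype(float) - p) * effect

    base = np.sqrt(lk.var_polygenic) * df["ps_true"].to_numpy(dtype=float) + dn_comp
    thr = df["sex"].map({"female": lk.threshold_female,
                         "male": lk.threshold_male}).to_numpy(dtype=float)
    sd_res = math.sqrt(lk.var_residual) if lk.var_residual > 0 else 0.0

    resid = np.empty(n)
    is_proband = (df["role"] == "proband").to_numpy()
    if sd_res > 0:
        lo = (thr - base) / sd_res
        for i in range(n):
            if is_proband[i]:
                resid[i] = _truncated_normal(rng, lower=lo[i])[0]
            else:
                resid[i] = _truncated_normal(rng, upper=lo[i])[0]
        liability = base + sd_res * resid
    else:
        liability = base
    df["liability"] = liability
    df["affected"] = liability > thr
    if sd_res > 0:
        # conditioning should make affection deterministic by role
        df.loc[is_proband, "affected"] = True

    excess = liability - thr
    l2 = 0.6 * liability + 0.8 * rng.normal(size=n)   # cognitive dimension

    def clip(name: str, values: np.ndarray) -> np.ndarray:
        lo_, hi_ = INSTRUMENT_RANGES[name]
        return np.clip(values, lo_, hi_)

    df["srs_t"] = clip("srs_t", 60.0 + 10.0 * excess)
    df["fsiq"] = clip("fsiq", 100.0 - 15.0 * l2)
    df["vabs_composite"] = clip("vabs_composite", 100.0 - 12.0 * l2)
    df["ados_css"] = clip("ados_css", np.round(5.0 + 2.0 * excess))
    df["ados_sa"] = clip("ados_sa", np.round(5.0 + 2.0 * excess))
    df["ados_rrb"] = clip("ados_rrb", np.round(4.0 + 1.5 * excess))
    df["adir_a"] = clip("adir_a", np.round(12.0 + 5.0 * excess))
    df["adir_b_verbal"] = clip("adir_b_verbal", np.round(10.0 + 4.0 * excess))
    df["adir_b_nonverbal"] = clip("adir_b_nonverbal", np.round(6.0 + 2.5 * excess))
    df["adir_c"] = clip("adir_c", np.round(4.0 + 2.0 * excess))
    return df
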