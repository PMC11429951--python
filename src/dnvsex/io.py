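"""VCF / PED / TSV / YAML interchange for cohorts and reports."""

from __future__ import annotations

import pathlib
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from dnvsex.qc import MISSING, VariantRecord
from dnvsex.synthetic import Cohort, CohortConfig


def write_vcf(path, records: Sequence[VariantRecord], samples: Sequence[str],
              contig_length: int = 100_000_000) -> None:
    """Write biallelic-or-multiallelic records as VCF 4.2 with GT:AD:DP:GQ:PL."""
    header = pysam.VariantHeader()
    header.add_line('##FILTER=<ID=PASS,Description="All filters passed">')
    for chrom in dict.fromkeys(r.chrom for r in records):
        header.contigs.add(chrom, length=contig_length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("PL", "G", "Integer", "Phred-scaled genotype likelihoods")
    for s in samples:
        header.add_sample(s)
    mode = "wz" if str(path).endswith(".gz") else "w"
    with pysam.VariantFile(str(path), mode, header=header) as vcf:
        for rec in records:
            out = vcf.new_record(contig=rec.chrom, start=rec.pos - 1,
                                 alleles=(rec.ref, *rec.alts),
                                 qual=float(rec.qual), filter="PASS")
            for i, s in enumerate(samples):
                call = out.samples[s]
                gt = rec.gt[i]
                call["GT"] = tuple(None if a == MISSING else int(a) for a in gt)
                if np.isfinite(rec.ad[i]).all():
                    call["AD"] = tuple(int(x) for x in rec.ad[i])
                if np.isfinite(rec.dp[i]):
                    call["DP"] = int(rec.dp[i])
                if np.isfinite(rec.gq[i]):
                    call["GQ"] = int(rec.gq[i])
                if np.isfinite(rec.pl[i]).all():
                    call["PL"] = tuple(int(x) for x in rec.pl[i])
            vcf.write(out)


def read_vcf(path) -> tuple[list[str], list[VariantRecord]]:
    """Read a VCF into in-memory records (one per site, alts kept together)."""
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        n = len(samples)
        for rec in vcf:
            alts = tuple(rec.alts or ())
            n_all = 1 + len(alts)
            n_geno = n_all * (n_all + 1) // 2
            gt = np.full((n, 2), MISSING, dtype=np.int8)
            ad = np.full((n, n_all), np.nan)
            dp = np.full(n, np.nan)
            gq = np.full(n, np.nan)
            pl = np.full((n, n_geno), np.nan)
            for i, s in enumerate(samples):
                call = rec.samples[s]
                alleles = call.get("GT")
                if alleles and all(a is not None for a in alleles):
                    gt[i] = alleles[:2]
                v = call.get("AD")
                if v is not None and all(x is not None for x in v):
                    ad[i, :len(v)] = v
                if call.get("DP") is not None:
                    dp[i] = call["DP"]
                if call.get("GQ") is not None:
                    gq[i] = call["GQ"]
                v = call.get("PL")
                if v is not None and all(x is not None for x in v):
                    pl[i, :len(v)] = v
            records.append(VariantRecord(
                rec.chrom, rec.pos, rec.ref, alts,
                float(rec.qual) if rec.qual is not None else float("nan"),
                gt, ad, dp, gq, pl))
    return samples, records


def write_ped(path, ped: pd.DataFrame) -> None:
    ped.to_csv(path, sep="\t", header=False, index=False)


def read_ped(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["family_id", "sample_id", "father_id",
                              "mother_id", "sex", "phenotype"],
                       dtype={"family_id": str, "sample_id": str,
                              "father_id": str, "mother_id": str})


def read_bed(path) -> list[tuple[str, int, int]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    return list(df.itertuples(index=False, name=None))


def load_config(path) -> CohortConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return CohortConfig(**data)


def write_cohort(cohort: Cohort, outdir) -> dict[str, pathlib.Path]:
    """Write a generated cohort to a directory (VCF, PED, tables, truth ledger)."""
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "ped": out / "cohort.ped",
        "samples": out / "samples.tsv",
        "truth": out / "truth_ledger.tsv",
        "annotations": out / "annotations.tsv",
    }
    write_vcf(paths["vcf"], cohort.records, cohort.sample_names)
    write_ped(paths["ped"], cohort.ped)
    cohort.samples.to_csv(paths["samples"], sep="\t", index=False)
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    cohort.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    return paths
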