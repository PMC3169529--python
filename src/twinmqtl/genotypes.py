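"""Genotype container, I/O, quality control, and Hardy–Weinberg testing.

Dosages count copies of the reference allele (0/1/2) with missing calls
stored as NaN.  Quality control mirrors standard GWAS practice for a typed +
imputed panel:

* best-guess genotypes from imputation probability triples (argmax, ties to
  the lower dosage);
* retain imputed SNPs only when the imputation quality score is strictly
  greater than a threshold (default 0.4);
* remove SNPs when (i) MAF < 1%, or (ii) call rate < 95% and MAF > 5%, or
  (iii) call rate < 99% and MAF < 5%, or when the exact Hardy–Weinberg test
  rejects at 1e-4;
* MAF and HWE are computed over unrelated individuals only (one twin per
  pair) when a cohort metadata table is supplied, since related genomes would
  distort both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Subjects × SNPs dosage matrix plus per-SNP metadata.

    ``dosages``: DataFrame indexed by subject id, one column per SNP id, with
    values in {0, 1, 2} or NaN.  ``snps``: DataFrame indexed by SNP id with at
    least ``chrom`` and ``pos`` (1-based) columns; ``ref``/``alt`` and an
    imputation quality ``info`` column are optional.
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.snps.index):
            raise GenotypeError("dosage columns must match SNP metadata index")
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise GenotypeError("dosages must be 0, 1, 2 or missing")

    @property
    def subjects(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def restrict_subjects(self, subjects: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[list(subjects)], self.snps)

    def restrict_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        ids = list(snp_ids)
        return GenotypeMatrix(self.dosages[ids], self.snps.loc[ids])

    def call_rate(self) -> pd.Series:
        return self.dosages.notna().mean(axis=0).rename("call_rate")

    def maf(self, subjects: Sequence[str] | None = None) -> pd.Series:
        """Minor allele frequency from non-missing dosages (optionally over a
        subject subset, e.g. unrelateds only)."""
        d = self.dosages if subjects is None else self.dosages.loc[list(subjects)]
        freq = d.mean(axis=0) / 2.0  # reference-allele frequency
        return np.minimum(freq, 1.0 - freq).rename("maf")

    def genotype_counts(self, subjects: Sequence[str] | None = None) -> pd.DataFrame:
        d = self.dosages if subjects is None else self.dosages.loc[list(subjects)]
        arr = d.to_numpy(dtype=float)
        return pd.DataFrame({
            "n0": np.nansum(arr == 0, axis=0),
            "n1": np.nansum(arr == 1, axis=0),
            "n2": np.nansum(arr == 2, axis=0),
        }, index=d.columns)

    # ---- I/O ------------------------------------------------------------
    def write_tsv(self, dosage_path: str | Path, snp_path: str | Path) -> None:
        self.dosages.to_csv(dosage_path, sep="\t", na_rep="NA",
                            index_label="subject_id")
        self.snps.to_csv(snp_path, sep="\t", na_rep="NA", index_label="snp")

    @classmethod
    def read_tsv(cls, dosage_path: str | Path,
                 snp_path: str | Path) -> "GenotypeMatrix":
        dos = pd.read_csv(dosage_path, sep="\t", index_col="subject_id",
                          na_values="NA", comment="#")
        snps = pd.read_csv(snp_path, sep="\t", index_col="snp",
                           na_values="NA", comment="#")
        return cls(dos, snps)

    @classmethod
    def read_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        """Import GT fields from a VCF; dosage counts the REF allele.
        Half-calls and missing GTs become NaN."""
        try:
            from cyvcf2 import VCF
        except ImportError as exc:  # pragma: no cover
            raise GenotypeError("VCF import requires cyvcf2") from exc
        vcf = VCF(str(path))
        subjects = list(vcf.samples)
        cols, meta = {}, []
        for var in vcf:
            gts = var.genotype.array()[:, :2].astype(float)
            gts[gts < 0] = np.nan
            # count REF alleles (allele code 0)
            dos = np.where(np.isnan(gts).any(axis=1), np.nan,
                           (gts == 0).sum(axis=1))
            snp_id = var.ID or f"{var.CHROM}:{var.POS}"
            cols[snp_id] = dos
            meta.append({"snp": snp_id, "chrom": var.CHROM, "pos": var.POS,
                         "ref": var.REF,
                         "alt": var.ALT[0] if var.ALT else "."})
        snps = pd.DataFrame(meta).set_index("snp")
        return cls(pd.DataFrame(cols, index=subjects), snps)


def unrelated_subjects(meta: pd.DataFrame) -> list[str]:
    """One twin per pair (twin index 1) plus all singletons."""
    subs = meta.drop_duplicates("subject_id")
    keep = subs[(subs["twin_index"] == 1) | (subs["zygosity"] == "NA")]
    return keep["subject_id"].tolist()


def best_guess_genotype(probs: Sequence[float] | np.ndarray) -> int | np.ndarray:
    """Most probable genotype from a (p0, p1, p2) imputation triple.

    Ties are broken toward the lower dosage.  Accepts a single triple or an
    (n, 3) array.  Probabilities must be non-negative and sum to ~1.
    """
    arr = np.asarray(probs, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 3:
        raise GenotypeError("expected genotype probability triples")
    if (arr < 0).any():
        raise GenotypeError("probabilities must be >= 0")
    if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
        raise GenotypeError("probability triples must sum to 1")
    out = np.argmax(arr, axis=1)  # argmax returns the first (lowest) on ties
    return int(out[0]) if single else out


def imputation_quality_filter(scores: pd.Series | dict,
                              min_score: float = 0.4) -> list:
    """SNPs whose imputation quality score is strictly greater than
    ``min_score`` (a score exactly at the threshold is dropped)."""
    s = pd.Series(scores, dtype=float)
    if ((s < 0) | (s > 1)).any():
        raise GenotypeError("imputation scores must lie in [0, 1]")
    return list(s.index[s > min_score])


def hwe_exact_test(n0: int, n1: int, n2: int) -> float:
    """Exact conditional Hardy–Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed count.  Returns a two-sided p-value in [0, 1].
    """
    n0, n1, n2 = int(n0), int(n1), int(n2)
    if min(n0, n1, n2) < 0:
        raise GenotypeError("genotype counts must be >= 0")
    n = n0 + n1 + n2
    if n == 0:
        raise GenotypeError("total genotype count must be > 0")
    na = 2 * n0 + n1          # minor-allele count (orientation irrelevant)
    na = min(na, 2 * n - na)
    # heterozygote counts share the parity of the allele count
    hets = np.arange(na % 2, na + 1, 2)
    # log P(n1 = h | allele counts) up to a constant:
    #   log n! - log n_AA! - log h! - log n_aa! + h log 2
    n_aa = (na - hets) // 2
    n_bb = n - n_aa - hets
    logp = (hets * math.log(2.0)
            - _lfact(n_aa) - _lfact(hets) - _lfact(n_bb))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = np.searchsorted(hets, n1)
    if obs >= len(hets) or hets[obs] != n1:
        raise GenotypeError("heterozygote count incompatible with allele counts")
    p_obs = prob[obs]
    p = prob[prob <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def _lfact(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln
    return gammaln(np.asarray(x, dtype=float) + 1.0)


def snp_qc(
    matrix: GenotypeMatrix,
    meta: pd.DataFrame | None = None,
    maf_low: float = 0.01,
    maf_mid: float = 0.05,
    call_hi: float = 0.99,
    call_lo: float = 0.95,
    hwe_alpha: float = 1e-4,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply SNP removal rules and return (filtered matrix, disposition log).

    Rules, evaluated in order with the first trigger recorded:
      (i)   MAF < ``maf_low``;
      (ii)  call rate < ``call_lo`` and MAF > ``maf_mid``;
      (iii) call rate < ``call_hi`` and MAF < ``maf_mid``;
      (hwe) exact HWE p-value < ``hwe_alpha``.
    A SNP with MAF exactly ``maf_mid`` triggers neither (ii) nor (iii)
    (literal strict inequalities).  MAF/HWE use unrelateds only when ``meta``
    is given.  The disposition log has one row per SNP with columns
    ``removed`` and ``rule``.
    """
    subjects = unrelated_subjects(meta) if meta is not None else None
    maf = matrix.maf(subjects)
    call = matrix.call_rate()
    counts = matrix.genotype_counts(subjects)

    rules = []
    for snp in matrix.snp_ids:
        m, c = maf[snp], call[snp]
        if m < maf_low:
            rules.append("maf_lt_1pct")
        elif c < call_lo and m > maf_mid:
            rules.append("callrate_lt_95pct_maf_gt_5pct")
        elif c < call_hi and m < maf_mid:
            rules.append("callrate_lt_99pct_maf_lt_5pct")
        else:
            n0, n1, n2 = counts.loc[snp, ["n0", "n1", "n2"]]
            if (n0 + n1 + n2) > 0 and hwe_exact_test(n0, n1, n2) < hwe_alpha:
                rules.append("hwe")
            else:
                rules.append("")
    log = pd.DataFrame({
        "snp": matrix.snp_ids,
        "maf": maf.to_numpy(),
        "call_rate": call.to_numpy(),
        "removed": [r != "" for r in rules],
        "rule": rules,
    }).set_index("snp")
    keep = log.index[~log["removed"]]
    return matrix.restrict_snps(list(keep)), log
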