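"""Genotype/allele frequencies and Hardy-Weinberg equilibrium testing.

For a biallelic SNP with observed genotype counts (hom1, het, hom2) the
allele frequency of the first-listed allele is ``p = f(hom1) + f(het)/2``
and HWE is assessed by a one-degree-of-freedom chi-square comparing the
observed genotype counts with the expected ``n * (p^2, 2pq, q^2)``
computed from the observed allele frequencies.  No continuity correction
is applied and the in-HWE flag uses a 0.05 threshold (the Haploview-era
convention).  Missing genotypes are excluded listwise per SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

__all__ = [
    "SnpCounts",
    "SnpFrequencies",
    "snp_counts",
    "genotype_frequencies",
    "allele_frequencies",
    "hwe_test",
    "frequency_table",
    "counts_from_frequencies",
]


@dataclass(frozen=True)
class SnpCounts:
    """Genotype counts at one biallelic SNP (orientation: allele1 first)."""

    name: str
    n_hom1: int
    n_het: int
    n_hom2: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hom1, self.n_het, self.n_hom2, self.n_missing) < 0:
            raise ValueError(f"negative genotype count at {self.name}")

    @property
    def n_typed(self) -> int:
        return self.n_hom1 + self.n_het + self.n_hom2

    def as_array(self) -> np.ndarray:
        return np.array([self.n_hom1, self.n_het, self.n_hom2], dtype=float)


@dataclass(frozen=True)
class SnpFrequencies:
    name: str
    genotype_freqs: tuple[float, float, float]
    p: float
    q: float
    chi2: float
    pvalue: float
    df: int
    in_hwe: bool


def snp_counts(geno: GenotypeMatrix, snp: str) -> SnpCounts:
    g = geno.calls[snp].to_numpy()
    return SnpCounts(
        name=snp,
        n_hom1=int((g == 0).sum()),
        n_het=int((g == 1).sum()),
        n_hom2=int((g == 2).sum()),
        n_missing=int((g < 0).sum()),
    )


def genotype_frequencies(counts: SnpCounts) -> np.ndarray:
    """Genotype frequencies (hom1, het, hom2) among typed animals."""
    n = counts.n_typed
    if n == 0:
        raise ValueError(f"SNP {counts.name}: all genotypes missing")
    return counts.as_array() / n


def allele_frequencies(genotype_freqs) -> tuple[float, float]:
    """(p, q) of allele1/allele2 from genotype frequencies."""
    f = np.asarray(genotype_freqs, dtype=float)
    # tolerate the rounding of published 4-decimal frequencies
    if abs(f.sum() - 1.0) > 5e-3:
        raise ValueError("genotype frequencies must sum to 1")
    p = f[0] + 0.5 * f[1]
    return float(p), float(1.0 - p)


def hwe_test(counts: SnpCounts, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Chi-square HWE test (df = 1): returns (chi2, p-value, in_hwe flag).

    Monomorphic SNPs (an expected cell of zero) are reported as exactly
    in equilibrium (chi2 = 0).
    """
    n = counts.n_typed
    if n == 0:
        raise ValueError(f"SNP {counts.name}: all genotypes missing")
    obs = counts.as_array()
    p, q = allele_frequencies(obs / n)
    exp = n * np.array([p * p, 2 * p * q, q * q])
    if np.any(exp == 0):
        return 0.0, 1.0, True
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    pvalue = float(stats.chi2.sf(chi2, df=1))
    return chi2, pvalue, pvalue >= alpha


def frequency_table(geno: GenotypeMatrix, alpha: float = 0.05, decimals: int = 4) -> pd.DataFrame:
    """Per-SNP frequency/HWE report mirroring a published frequency table.

    One row per SNP: genotype counts and frequencies, allele frequencies,
    HWE chi-square/p and the T/F equilibrium flag.  All-missing SNPs are
    flagged and excluded.
    """
    rows = []
    for snp in geno.snps:
        c = snp_counts(geno, snp)
        a1, a2 = geno.meta.loc[snp, ["allele1", "allele2"]]
        if c.n_typed == 0:
            rows.append({"snp": snp, "gene": geno.meta.loc[snp, "gene"], "excluded": True})
            continue
        f = genotype_frequencies(c)
        p, q = allele_frequencies(f)
        chi2, pval, ok = hwe_test(c, alpha=alpha)
        rows.append(
            {
                "snp": snp,
                "gene": geno.meta.loc[snp, "gene"],
                "excluded": False,
                f"n_{a1}{a1}": c.n_hom1,
                f"n_{a1}{a2}": c.n_het,
                f"n_{a2}{a2}": c.n_hom2,
                "n_missing": c.n_missing,
                f"freq_{a1}{a1}": round(float(f[0]), decimals),
                f"freq_{a1}{a2}": round(float(f[1]), decimals),
                f"freq_{a2}{a2}": round(float(f[2]), decimals),
                f"freq_{a1}": round(p, decimals),
                f"freq_{a2}": round(q, decimals),
                "hwe_chi2": round(chi2, decimals),
                "hwe_p": round(pval, decimals),
                "hwe": "T" if ok else "F",
            }
        )
    return pd.DataFrame(rows).set_index("snp")


def counts_from_frequencies(genotype_freqs, n: int) -> SnpCounts:
    """Reconstruct integer genotype counts from reported frequencies and n."""
    f = np.asarray(genotype_freqs, dtype=float)
    counts = np.rint(f * n).astype(int)
    return SnpCounts("reconstructed", *counts)
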