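"""Single-SNP and haplotype-combination association tables.

Loops the animal model over SNPs (or blocks) x traits x lactations and
assembles a published-style table: per-level record counts, LS-mean and
SE, Wald chi-square, raw and Bonferroni-corrected p, significance
letters, variance components, and for single SNPs the (a, d, alpha)
effect decomposition.  The Bonferroni family is the SNPs of the same
gene for single-SNP tests and the number of blocks for haplotype tests
(``per-gene`` mode), or all tests of that kind (``global``).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .animal_model import AnimalModel, bonferroni
from .effects import decompose_effects
from .freq import allele_frequencies, genotype_frequencies, snp_counts
from .genotypes import GenotypeMatrix
from .ld import HaplotypeBlock
from .pedigree import Pedigree

__all__ = ["single_snp_association", "haplotype_association", "DIPLOTYPE_MIN_COUNT"]

log = logging.getLogger(__name__)

#: haplotype combinations carried by fewer animals are left out of the model
DIPLOTYPE_MIN_COUNT = 30


def _genotype_factor(geno: GenotypeMatrix, snp: str) -> pd.Series:
    return geno.genotype_factor(snp)  # missing -> NaN, dropped by the model


def _fit_one(
    data: pd.DataFrame,
    trait: str,
    ped: Pedigree,
    factor_col: str,
    hys: str | None,
    covariate: str | None,
):
    model = AnimalModel(data, trait, ped, factor=factor_col, hys=hys, covariate=covariate)
    return model.fit()


def _result_rows(res, label: str, trait: str, lactation, extra: dict) -> list[dict]:
    chi2, df, pval = res.wald_test()
    lsm = res.ls_means().join(res.letters())
    rows = []
    for level, r in lsm.iterrows():
        rows.append(
            {
                "marker": label,
                "trait": trait,
                "lactation": lactation,
                "level": level,
                "n": int(r["n"]),
                "lsmean": r["lsmean"],
                "se": r["se"],
                "letters_005": r["letters_005"],
                "letters_001": r["letters_001"],
                "chi2": chi2,
                "df": df,
                "p_raw": pval,
                "sigma_a2": res.sigma_a2,
                "sigma_e2": res.sigma_e2,
                **extra,
            }
        )
    return rows


def single_snp_association(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    ped: Pedigree,
    traits: list[str],
    snps: list[str] | None = None,
    lactations: list | None = None,
    hys: str | None = "hys",
    covariate: str | None = "calving_age",
    correction: str = "per-gene",
) -> pd.DataFrame:
    """Animal-model association of each SNP with each trait per lactation."""
    snps = snps if snps is not None else geno.snps
    lactations = lactations if lactations is not None else sorted(pheno["lactation"].unique())
    family_size = {}
    if correction == "per-gene":
        # family = all panel SNPs of the same gene, not just those analyzed
        gene_counts = geno.meta["gene"].value_counts()
        for snp in snps:
            family_size[snp] = int(gene_counts[geno.meta.loc[snp, "gene"]])
    elif correction == "global":
        family_size = {snp: len(snps) for snp in snps}
    else:
        raise ValueError(f"unknown correction mode {correction!r}")

    rows = []
    for snp in snps:
        factor = _genotype_factor(geno, snp)
        counts = snp_counts(geno, snp)
        if counts.n_typed == 0:
            log.warning("SNP %s all-missing; skipped", snp)
            continue
        p, q = allele_frequencies(genotype_frequencies(counts))
        a1, a2 = geno.meta.loc[snp, ["allele1", "allele2"]]
        for lact in lactations:
            sub = pheno[pheno["lactation"] == lact].copy()
            sub["genotype"] = factor.reindex(sub["animal"]).to_numpy()
            for trait in traits:
                try:
                    res = _fit_one(sub, trait, ped, "genotype", hys, covariate)
                except (ValueError, np.linalg.LinAlgError) as exc:
                    log.warning("fit failed for %s/%s/L%s: %s", snp, trait, lact, exc)
                    continue
                extra = {"gene": geno.meta.loc[snp, "gene"], "p_allele1": p}
                new = _result_rows(res, snp, trait, lact, extra)
                lsm = res.ls_means()
                hom1, het, hom2 = a1 + a1, "".join(sorted(a1 + a2)), a2 + a2
                if {hom1, het, hom2} <= set(lsm.index):
                    eff = decompose_effects(
                        lsm.loc[hom1, "lsmean"], lsm.loc[het, "lsmean"], lsm.loc[hom2, "lsmean"],
                        p, q, hom1_label=hom1,
                    )
                    for r in new:
                        r.update({"a": eff.a, "d": eff.d, "alpha": eff.alpha})
                rows.extend(new)
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_corrected"] = [
            bonferroni(r.p_raw, family_size[r.marker]) for r in out.itertuples()
        ]
    return out


def haplotype_association(
    blocks: dict[str, HaplotypeBlock],
    pheno: pd.DataFrame,
    ped: Pedigree,
    traits: list[str],
    lactations: list | None = None,
    hys: str | None = "hys",
    covariate: str | None = "calving_age",
    min_count: int = DIPLOTYPE_MIN_COUNT,
    correction_family: int | None = None,
) -> pd.DataFrame:
    """Association of block haplotype combinations (diplotypes) with traits.

    Diplotype classes carried by fewer than ``min_count`` animals are
    excluded.  The Bonferroni family defaults to the number of blocks.
    """
    lactations = lactations if lactations is not None else sorted(pheno["lactation"].unique())
    m = correction_family if correction_family is not None else len(blocks)
    rows = []
    for name, block in blocks.items():
        dip = block.diplotypes["diplotype"]
        keep = dip.value_counts()
        common = set(keep[keep >= min_count].index)
        if not common:
            log.warning("block %s: no diplotype reaches the %d-animal threshold", name, min_count)
            continue
        factor = dip.where(dip.isin(common))
        for lact in lactations:
            sub = pheno[pheno["lactation"] == lact].copy()
            sub["diplotype"] = factor.reindex(sub["animal"]).to_numpy()
            for trait in traits:
                try:
                    res = _fit_one(sub, trait, ped, "diplotype", hys, covariate)
                except (ValueError, np.linalg.LinAlgError) as exc:
                    log.warning("fit failed for %s/%s/L%s: %s", name, trait, lact, exc)
                    continue
                rows.extend(_result_rows(res, name, trait, lact, {"gene": ""}))
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_corrected"] = [bonferroni(p, m) for p in out["p_raw"]]
    return out
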