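"""Genotype container and file I/O (TSV and VCF).

Genotypes are diploid, unphased, biallelic.  Internally a call is stored
as the count of the *second* allele (``allele2``), so 0 = hom allele1,
1 = het, 2 = hom allele2, -1 = missing.  ``allele1`` is the first-listed
allele of the SNP (the orientation used for allele frequency ``p`` and
for the sign of additive effects); for simulated and VCF data it is the
REF allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "read_genotype_tsv", "read_genotype_vcf"]

META_COLUMNS = ["chrom", "pos", "gene", "allele1", "allele2", "rsid"]


@dataclass
class GenotypeMatrix:
    """Animals x SNPs unphased diploid calls plus SNP metadata.

    Parameters
    ----------
    calls : pandas.DataFrame
        Integer allele2 counts (0/1/2, -1 missing); index = animal ids,
        columns = SNP names.
    meta : pandas.DataFrame
        Indexed by SNP name with columns ``chrom, pos, gene, allele1,
        allele2, rsid`` (rsid optional).
    phased : tuple of two DataFrames, optional
        Maternal/paternal haplotypes as 0/1 allele2 indicators (only
        available for simulated data).
    """

    calls: pd.DataFrame
    meta: pd.DataFrame
    phased: tuple[pd.DataFrame, pd.DataFrame] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in ("chrom", "pos", "allele1", "allele2") if c not in self.meta.columns]
        if missing:
            raise ValueError(f"genotype metadata lacks columns: {missing}")
        if "gene" not in self.meta.columns:
            self.meta = self.meta.assign(gene="")
        if "rsid" not in self.meta.columns:
            self.meta = self.meta.assign(rsid="")
        if list(self.calls.columns) != list(self.meta.index):
            self.meta = self.meta.loc[list(self.calls.columns)]

    @property
    def animals(self) -> list[str]:
        return [str(a) for a in self.calls.index]

    @property
    def snps(self) -> list[str]:
        return list(self.calls.columns)

    def snps_of_gene(self, gene: str) -> list[str]:
        return list(self.meta.index[self.meta["gene"] == gene])

    def genotype_factor(self, snp: str) -> pd.Series:
        """Per-animal genotype labels ('AA'/'AC'/'CC' style; missing -> NaN)."""
        a1, a2 = self.meta.loc[snp, ["allele1", "allele2"]]
        lut = {0: a1 + a1, 1: "".join(sorted(a1 + a2)), 2: a2 + a2}
        return self.calls[snp].map(lut)

    def genotype_string(self, animal: str, snp: str) -> str:
        a1, a2 = self.meta.loc[snp, ["allele1", "allele2"]]
        g = int(self.calls.loc[animal, snp])
        return {0: a1 + a1, 1: a1 + a2, 2: a2 + a2}.get(g, "NN")

    def subset(self, snps=None, animals=None) -> "GenotypeMatrix":
        calls = self.calls
        if animals is not None:
            calls = calls.loc[list(animals)]
        if snps is not None:
            calls = calls[list(snps)]
        phased = None
        if self.phased is not None:
            phased = tuple(h.loc[calls.index, calls.columns] for h in self.phased)
        return GenotypeMatrix(calls, self.meta.loc[calls.columns], phased)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        """Letter-pair table (animal rows, SNP columns, e.g. ``AC``)."""
        out = pd.DataFrame(index=self.calls.index, columns=self.calls.columns, dtype=object)
        for snp in self.snps:
            a1, a2 = self.meta.loc[snp, ["allele1", "allele2"]]
            lut = np.array([a1 + a1, a1 + a2, a2 + a2, "NN"], dtype=object)
            out[snp] = lut[self.calls[snp].to_numpy().clip(-1, 2)]
        out.index.name = "animal"
        out.to_csv(path, sep="\t")

    def to_vcf(self, path) -> None:
        order = self.meta.sort_values(["chrom", "pos"]).index
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom in pd.unique(self.meta["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write('##INFO=<ID=RS,Number=1,Type=String,Description="dbSNP id">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(self.animals) + "\n")
            gt_lut = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
            for snp in order:
                row = self.meta.loc[snp]
                info = f"RS={row['rsid']}" if row["rsid"] else "."
                gts = "\t".join(gt_lut[int(g)] for g in self.calls[snp])
                fh.write(
                    f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t{row['allele1']}"
                    f"\t{row['allele2']}\t.\t.\t{info}\tGT\t{gts}\n"
                )

    def write_meta(self, path) -> None:
        self.meta.rename_axis("snp").to_csv(path, sep="\t")


def read_genotype_tsv(path, meta: pd.DataFrame) -> GenotypeMatrix:
    """Read a letter-pair genotype table (first column = animal id).

    ``meta`` must be indexed by SNP name and provide ``allele1``/``allele2``
    so letter pairs can be oriented.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("animal")
    snps = [c for c in df.columns if c in meta.index]
    calls = pd.DataFrame(index=df.index, columns=snps, dtype=int)
    for snp in snps:
        a1, a2 = meta.loc[snp, ["allele1", "allele2"]]
        mapping = {
            a1 + a1: 0, a1 + a2: 1, a2 + a1: 1, a2 + a2: 2,
            "NN": -1, "": -1, "--": -1,
        }
        col = df[snp].fillna("NN").map(mapping)
        if col.isna().any():
            bad = df[snp][col.isna()].iloc[0]
            raise ValueError(f"unrecognized genotype {bad!r} at SNP {snp}")
        calls[snp] = col.astype(int)
    return GenotypeMatrix(calls, meta.loc[snps].copy())


def read_genotype_vcf(path, gene_map: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF (uses cyvcf2; plain or bgzipped)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    animals = list(vcf.samples)
    names, rows, meta_rows = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        name = var.ID or f"{var.CHROM}:g.{var.POS}{var.REF}>{var.ALT[0]}"
        counts = np.array(
            [a + b if a >= 0 and b >= 0 else -1 for a, b, *_ in var.genotypes], dtype=int
        )
        names.append(name)
        rows.append(counts)
        meta_rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "gene": (gene_map or {}).get(name, ""),
                "allele1": var.REF,
                "allele2": var.ALT[0],
                "rsid": var.ID or "",
            }
        )
    calls = pd.DataFrame(np.array(rows).T, index=animals, columns=names)
    meta = pd.DataFrame(meta_rows, index=names)
    return GenotypeMatrix(calls, meta)
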