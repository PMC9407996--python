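"""Synthetic half-sib dairy cohorts with known simulation truth.

The generator emulates a paternal half-sib design: unrelated founder
sires, each with a set of daughters out of unique unrelated founder
dams.  Genotypes are gene-dropped founder haplotypes (no recombination
within a haplotype block, free recombination between blocks), and
phenotypes follow the same animal model the analysis fits:

    y = mu + HYS + b * M + sum_snp G(g) + u + e

with genotype values coded ``+a`` (hom allele1), ``d`` (het), ``-a``
(hom allele2), a herd-year-season class effect drawn i.i.d. normal, a
uniform calving-age covariate M, breeding values ``u`` generated down
the pedigree (founders ``N(0, sigma_a^2)``, offspring the parent mean
plus a Mendelian-sampling deviate), and i.i.d. residuals.

Defaults mirror the Chinese Holstein study design this package targets:
44 sire families, 6-62 daughters each, 10 biallelic SNPs in two genes
with two intra-gene haplotype blocks, five milk production traits over
two partially overlapping lactations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

__all__ = [
    "ConfigError",
    "SnpSpec",
    "BlockSpec",
    "TraitSpec",
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedDataset",
    "default_config",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SnpSpec:
    """One biallelic SNP; ``freq1`` is the founder frequency of allele1.

    For SNPs inside a block, ``freq1`` is implied by the block haplotype
    frequencies and may be left as None.
    """

    name: str
    gene: str
    chrom: str
    pos: int
    allele1: str
    allele2: str
    freq1: float | None = None
    rsid: str = ""


@dataclass(frozen=True)
class BlockSpec:
    """SNP names (position order) and founder haplotype frequencies."""

    name: str
    snps: tuple[str, ...]
    haplotypes: dict[str, float]


@dataclass(frozen=True)
class TraitSpec:
    name: str
    mean: dict[int, float]  # per-lactation overall mean mu
    hys_sd: float
    age_coef: float
    sigma_a2: float
    sigma_e2: float
    additive: dict[str, float] = field(default_factory=dict)
    dominance: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SimulationConfig:
    snps: tuple[SnpSpec, ...]
    blocks: tuple[BlockSpec, ...]
    traits: tuple[TraitSpec, ...]
    n_sires: int = 44
    # uniform family sizes with mean 21 daughters/sire (the cohort's average,
    # within its observed 6-62 range), so 44 sires give ~924 daughters
    daughters_range: tuple[int, int] = (6, 36)
    n_farms: int = 5
    n_years: int = 3
    n_seasons: int = 4
    age_range: tuple[float, float] = (22.0, 36.0)
    lactations: tuple[int, ...] = (1, 2)
    lactation2_fraction: float = 635 / 924
    seed: int = 2022

    def __post_init__(self) -> None:
        lo, hi = self.daughters_range
        if not (1 <= lo <= hi):
            raise ConfigError(f"invalid family-size range {self.daughters_range}")
        if self.n_sires < 1:
            raise ConfigError("need at least one sire")
        seen: set[str] = set()
        names = {s.name for s in self.snps}
        for block in self.blocks:
            for snp in block.snps:
                if snp in seen:
                    raise ConfigError(f"SNP {snp} listed in two blocks")
                if snp not in names:
                    raise ConfigError(f"block {block.name} references unknown SNP {snp}")
                seen.add(snp)
            total = sum(block.haplotypes.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"block {block.name} haplotype frequencies sum to {total}")
            spec = {s.name: s for s in self.snps}
            for hap in block.haplotypes:
                if len(hap) != len(block.snps):
                    raise ConfigError(f"haplotype {hap} length != block {block.name} size")
                for letter, snp in zip(hap, block.snps):
                    if letter not in (spec[snp].allele1, spec[snp].allele2):
                        raise ConfigError(f"haplotype letter {letter} not an allele of {snp}")
        for s in self.snps:
            if s.name not in seen:
                if s.freq1 is None or not 0.0 <= s.freq1 <= 1.0:
                    raise ConfigError(f"SNP {s.name} needs a founder freq1 in [0, 1]")
        for t in self.traits:
            if t.sigma_a2 < 0:
                raise ConfigError(f"trait {t.name}: sigma_a2 must be >= 0")
            if t.sigma_e2 < 0:
                raise ConfigError(f"trait {t.name}: sigma_e2 must be >= 0")
        if not 0.0 <= self.lactation2_fraction <= 1.0:
            raise ConfigError("lactation2_fraction must be in [0, 1]")

    @property
    def independent_snps(self) -> list[SnpSpec]:
        in_block = {snp for b in self.blocks for snp in b.snps}
        return [s for s in self.snps if s.name not in in_block]

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class SimulationTruth:
    """Ground truth recorded by the generator for recovery tests."""

    trait_params: dict  # name -> {sigma_a2, sigma_e2, age_coef, additive, dominance}
    hys_effects: dict  # trait -> {class label -> effect}
    breeding_values: pd.DataFrame  # animals x traits
    haplotypes: tuple[pd.DataFrame, pd.DataFrame] | None

    def to_json(self) -> dict:
        return {
            "trait_params": self.trait_params,
            "hys_effects": self.hys_effects,
            "breeding_values": {
                t: self.breeding_values[t].round(6).to_dict() for t in self.breeding_values
            },
        }


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: SimulationTruth

    def write(self, outdir) -> None:
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.pedigree.to_csv(out / "pedigree.csv")
        self.genotypes.to_tsv(out / "genotypes.tsv")
        self.genotypes.to_vcf(out / "genotypes.vcf")
        self.genotypes.write_meta(out / "snp_meta.tsv")
        self.phenotypes.to_csv(out / "phenotypes.csv", index=False)
        (out / "truth.json").write_text(json.dumps(self.truth.to_json(), indent=1))


def _normalized(freqs: dict[str, float]) -> dict[str, float]:
    total = sum(freqs.values())
    return {k: v / total for k, v in freqs.items()}


def default_config(seed: int = 2022, **overrides) -> SimulationConfig:
    """Study-design defaults: 44 sire families, 10 SNPs, 2 blocks, 5 traits.

    Allele frequencies and block haplotype frequencies follow the
    published cohort (block frequencies, which are printed to a 0.998
    total, are proportionally normalized).
    """
    snps = (
        SnpSpec("26:g.17130318C>A", "ALDH18A1", "26", 17130318, "A", "C", 0.8274, "rs109124430"),
        SnpSpec("26:g.17118244G>A", "ALDH18A1", "26", 17118244, "A", "G", None, "rs133295794"),
        SnpSpec("26:g.17102977T>C", "ALDH18A1", "26", 17102977, "C", "T", None, "rs136218403"),
        SnpSpec("26:g.17100534G>T", "ALDH18A1", "26", 17100534, "G", "T", None, "rs110706194"),
        SnpSpec("26:g.17089560G>A", "ALDH18A1", "26", 17089560, "A", "G", None, "rs458180458"),
        SnpSpec("26:g.17088978A>G", "ALDH18A1", "26", 17088978, "A", "G", None, "rs41255559"),
        SnpSpec("26:g.17088098G>C", "ALDH18A1", "26", 17088098, "C", "G", None, "rs208352883"),
        SnpSpec("26:g.17086802T>A", "ALDH18A1", "26", 17086802, "A", "T", None, "rs109201383"),
        SnpSpec("11:g.49472723G>C", "MAT2A", "11", 49472723, "C", "G", 0.8003, "rs109079969"),
        SnpSpec("11:g.49465032C>T", "MAT2A", "11", 49465032, "C", "T", 0.6813, "rs110124316"),
    )
    block1 = BlockSpec(
        "Block1",
        (
            "26:g.17086802T>A",
            "26:g.17088098G>C",
            "26:g.17088978A>G",
            "26:g.17089560G>A",
            "26:g.17100534G>T",
        ),
        _normalized(
            {"ACGGG": 0.58, "TGGGG": 0.172, "TGAAG": 0.094, "TGAGG": 0.066, "TGAGT": 0.066, "AGGGG": 0.02}
        ),
    )
    block2 = BlockSpec(
        "Block2",
        ("26:g.17102977T>C", "26:g.17118244G>A"),
        _normalized({"TG": 0.874, "CA": 0.124}),
    )
    traits = (
        TraitSpec(
            "milk_yield", {1: 10250.0, 2: 10800.0}, hys_sd=300.0, age_coef=15.0,
            sigma_a2=4.0e5, sigma_e2=8.0e5, additive={"26:g.17088098G>C": 350.0},
        ),
        TraitSpec(
            "fat_yield", {1: 340.0, 2: 385.0}, hys_sd=15.0, age_coef=0.5,
            sigma_a2=900.0, sigma_e2=1800.0,
            additive={"26:g.17130318C>A": 20.0}, dominance={"26:g.17130318C>A": 15.0},
        ),
        TraitSpec("fat_pct", {1: 3.33, 2: 3.58}, hys_sd=0.05, age_coef=0.0, sigma_a2=0.04, sigma_e2=0.04),
        TraitSpec(
            "protein_yield", {1: 305.0, 2: 320.0}, hys_sd=12.0, age_coef=0.4,
            sigma_a2=600.0, sigma_e2=1200.0,
        ),
        TraitSpec("protein_pct", {1: 2.98, 2: 2.96}, hys_sd=0.02, age_coef=0.0, sigma_a2=0.01, sigma_e2=0.012),
    )
    return SimulationConfig(snps=snps, blocks=(block1, block2), traits=traits, seed=seed, **overrides)


# -- pedigree ---------------------------------------------------------------


def simulate_pedigree(config: SimulationConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Paternal half-sib families: each daughter has one founder sire shared
    within the family and her own unrelated founder dam."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.daughters_range
    rows = []
    dam_counter = 0
    for s in range(config.n_sires):
        sire = f"S{s + 1:03d}"
        rows.append((sire, "", ""))
        n_daughters = int(rng.integers(lo, hi + 1))
        for _ in range(n_daughters):
            dam_counter += 1
            dam = f"D{dam_counter:05d}"
            cow = f"C{dam_counter:05d}"
            rows.append((dam, "", ""))
            rows.append((cow, sire, dam))
    return Pedigree(pd.DataFrame(rows, columns=["animal", "sire", "dam"]))


# -- genotypes --------------------------------------------------------------


def _hap_codes(block: BlockSpec, spec: dict[str, SnpSpec]) -> tuple[np.ndarray, np.ndarray]:
    """(haplotype allele2-indicator matrix, frequency vector) for a block."""
    haps, freqs = [], []
    for hap, f in block.haplotypes.items():
        haps.append([0 if letter == spec[s].allele1 else 1 for letter, s in zip(hap, block.snps)])
        freqs.append(f)
    return np.array(haps, dtype=np.int8), np.array(freqs)


def simulate_genotypes(
    ped: Pedigree, config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Gene-drop founder haplotypes through the pedigree.

    Founders draw block haplotypes i.i.d. from the configured
    frequencies and independent-SNP alleles i.i.d. per locus; offspring
    receive one gamete from each parent with no recombination within a
    block and free recombination between blocks / independent SNPs.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    spec = {s.name: s for s in config.snps}
    snp_names = [s.name for s in config.snps]
    col = {name: k for k, name in enumerate(snp_names)}
    n = len(ped)
    m = len(snp_names)
    hap = np.zeros((n, m, 2), dtype=np.int8)  # 1 = allele2

    block_data = [( [col[s] for s in b.snps], *_hap_codes(b, spec)) for b in config.blocks]
    indep = [(col[s.name], s.freq1) for s in config.independent_snps]

    founder_mask = (ped.sire_idx < 0) & (ped.dam_idx < 0)
    founder_idx = np.flatnonzero(founder_mask)
    nf = len(founder_idx)
    for cols, codes, freqs in block_data:
        draws = rng.choice(len(freqs), size=(nf, 2), p=freqs)
        for gamete in (0, 1):
            hap[np.ix_(founder_idx, cols, [gamete])] = codes[draws[:, gamete]][:, :, None]
    for c, f1 in indep:
        hap[founder_idx, c, :] = (rng.random((nf, 2)) >= f1).astype(np.int8)

    for i in np.flatnonzero(~founder_mask):
        for parent_slot, p in enumerate((ped.sire_idx[i], ped.dam_idx[i])):
            if p < 0:  # unknown parent: draw a founder gamete
                for cols, codes, freqs in block_data:
                    hap[i, cols, parent_slot] = codes[rng.choice(len(freqs), p=freqs)]
                for c, f1 in indep:
                    hap[i, c, parent_slot] = np.int8(rng.random() >= f1)
                continue
            for cols, codes, freqs in block_data:
                gamete = int(rng.integers(2))  # whole block from one parental haplotype
                hap[i, cols, parent_slot] = hap[p, cols, gamete]
            for c, f1 in indep:
                hap[i, c, parent_slot] = hap[p, c, int(rng.integers(2))]

    calls = pd.DataFrame(hap.sum(axis=2), index=ped.ids, columns=snp_names, dtype=int)
    meta = pd.DataFrame(
        {
            "chrom": [spec[s].chrom for s in snp_names],
            "pos": [spec[s].pos for s in snp_names],
            "gene": [spec[s].gene for s in snp_names],
            "allele1": [spec[s].allele1 for s in snp_names],
            "allele2": [spec[s].allele2 for s in snp_names],
            "rsid": [spec[s].rsid for s in snp_names],
        },
        index=snp_names,
    )
    phased = (
        pd.DataFrame(hap[:, :, 0], index=ped.ids, columns=snp_names),
        pd.DataFrame(hap[:, :, 1], index=ped.ids, columns=snp_names),
    )
    return GenotypeMatrix(calls, meta, phased=phased)


# -- phenotypes -------------------------------------------------------------


def _breeding_values(ped: Pedigree, sigma_a2: float, F: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(ped)
    u = np.zeros(n)
    if sigma_a2 == 0:
        return u
    sd = np.sqrt(sigma_a2)
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s < 0 and d < 0:
            u[i] = rng.normal(0.0, sd)
        else:
            mean = 0.0
            mend_var = 1.0
            if s >= 0 and d >= 0:
                mean = 0.5 * (u[s] + u[d])
                mend_var = 0.5 - 0.25 * (F[s] + F[d])
            elif s >= 0:
                mean = 0.5 * u[s]
                mend_var = 0.75 - 0.25 * F[s]
            else:
                mean = 0.5 * u[d]
                mend_var = 0.75 - 0.25 * F[d]
            u[i] = mean + rng.normal(0.0, np.sqrt(mend_var * sigma_a2))
    return u


def simulate_phenotypes(
    ped: Pedigree,
    geno: GenotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate per-lactation trait records plus the simulation truth.

    Phenotyped animals are the daughters (animals with both parents
    known).  All daughters record lactation 1; a random
    ``lactation2_fraction`` subset also records lactation 2 (the study's
    two lactation cohorts overlapped only partially).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    daughters = [
        a for a, s, d in zip(ped.ids, ped.sire_idx, ped.dam_idx) if s >= 0 and d >= 0
    ]
    if not set(daughters) <= set(geno.animals):
        raise ConfigError("genotypes do not cover all phenotyped animals")
    F = ped.inbreeding().to_numpy()

    hys_labels = [
        f"F{f + 1}Y{y + 1}S{s + 1}"
        for f in range(config.n_farms)
        for y in range(config.n_years)
        for s in range(config.n_seasons)
    ]
    hys_effects = {
        t.name: dict(zip(hys_labels, rng.normal(0.0, t.hys_sd, size=len(hys_labels))))
        for t in config.traits
    }
    u_all = {t.name: _breeding_values(ped, t.sigma_a2, F, rng) for t in config.traits}
    pos = {a: i for i, a in enumerate(ped.ids)}

    # cohort structure
    farms = rng.integers(config.n_farms, size=len(daughters))
    age1 = rng.uniform(*config.age_range, size=len(daughters))
    records: list[dict] = []
    in_lact2: set[str] = set()
    if 2 in config.lactations:
        k = int(round(config.lactation2_fraction * len(daughters)))
        in_lact2 = set(rng.choice(daughters, size=k, replace=False))

    geno_calls = geno.calls
    for lact in config.lactations:
        for j, animal in enumerate(daughters):
            if lact == 2 and animal not in in_lact2:
                continue
            year = int(rng.integers(config.n_years))
            season = int(rng.integers(config.n_seasons))
            hys = f"F{farms[j] + 1}Y{year + 1}S{season + 1}"
            age = float(age1[j]) if lact == 1 else float(age1[j] + rng.uniform(11.0, 14.0))
            row = {
                "animal": animal,
                "lactation": lact,
                "farm": f"F{farms[j] + 1}",
                "year": f"Y{year + 1}",
                "season": f"S{season + 1}",
                "hys": hys,
                "calving_age": age,
            }
            g_row = geno_calls.loc[animal]
            for t in config.traits:
                value = t.mean[lact] + hys_effects[t.name][hys] + t.age_coef * age
                for snp, a_eff in t.additive.items():
                    g = int(g_row[snp])
                    value += a_eff if g == 0 else (-a_eff if g == 2 else 0.0)
                for snp, d_eff in t.dominance.items():
                    if int(g_row[snp]) == 1:
                        value += d_eff
                value += u_all[t.name][pos[animal]]
                value += rng.normal(0.0, np.sqrt(t.sigma_e2)) if t.sigma_e2 > 0 else 0.0
                row[t.name] = value
            records.append(row)

    phenotypes = pd.DataFrame(records)
    truth = SimulationTruth(
        trait_params={
            t.name: {
                "sigma_a2": t.sigma_a2,
                "sigma_e2": t.sigma_e2,
                "age_coef": t.age_coef,
                "mean": t.mean,
                "additive": dict(t.additive),
                "dominance": dict(t.dominance),
            }
            for t in config.traits
        },
        hys_effects=hys_effects,
        breeding_values=pd.DataFrame(
            {t.name: u_all[t.name] for t in config.traits}, index=ped.ids
        ),
        haplotypes=geno.phased,
    )
    return phenotypes, truth


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Full reproducible simulation: pedigree -> genotypes -> phenotypes."""
    rng = np.random.default_rng(config.seed)
    ped = simulate_pedigree(config, rng)
    geno = simulate_genotypes(ped, config, rng)
    pheno, truth = simulate_phenotypes(ped, geno, config, rng)
    return SimulatedDataset(config, ped, geno, pheno, truth)
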