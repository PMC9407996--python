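"""Linkage disequilibrium, haplotype blocks, and diplotype assignment.

Pairwise LD is estimated by the classical two-locus EM over the
double-heterozygote phase ambiguity; the normalized coefficient is

    D  = p_AB - p_A p_B
    D' = |D| / D_max,   D_max = min(p_A q_B, q_A p_B)  if D > 0
                        D_max = min(p_A p_B, q_A q_B)  if D < 0

with A/B the first-listed alleles at the two loci.  A 90% confidence
interval on D' is read off the normalized profile likelihood evaluated
on a grid (allele frequencies held at their MLEs), and blocks are found
by the Gabriel confidence-interval rule with the Haploview default
thresholds: a pair is in *strong LD* when its CI is [>= 0.70, >= 0.98],
shows *strong recombination* when the upper bound is < 0.90, and a run
of SNPs is a block when at least 95% of its informative pairs are in
strong LD.  Block haplotype frequencies come from a multi-locus EM; the
per-animal diplotype is the maximum-posterior consistent haplotype pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "PairwiseLD",
    "HaplotypeBlock",
    "em_two_locus",
    "dprime_ci",
    "pairwise_ld_table",
    "find_blocks",
    "em_block_phase",
]

log = logging.getLogger(__name__)

EM_TOL = 1e-8
EM_MAX_ITER = 1000
PRUNE_FREQ = 1e-4
MAX_BLOCK_SNPS = 12

# Gabriel / Haploview default thresholds
STRONG_LOW = 0.70
STRONG_HIGH = 0.98
RECOMB_HIGH = 0.90
INFORMATIVE_FRACTION = 0.95


@dataclass(frozen=True)
class PairwiseLD:
    snp1: str
    snp2: str
    hap_freqs: tuple[float, float, float, float]  # (AB, Ab, aB, ab)
    D: float
    dprime: float
    r2: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    defined: bool = True


@dataclass
class HaplotypeBlock:
    """Ordered SNP subset with EM haplotype frequencies and diplotypes."""

    snps: list[str]
    haplotypes: pd.DataFrame  # columns: label, sequence, frequency, retained
    diplotypes: pd.DataFrame  # index animal; columns: hap1, hap2, diplotype, posterior
    loglik: float = float("nan")

    @property
    def retained(self) -> pd.DataFrame:
        return self.haplotypes[self.haplotypes["retained"]]


def _pair_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 two-locus genotype count table over animals typed at both SNPs."""
    keep = (g1 >= 0) & (g2 >= 0)
    counts = np.zeros((3, 3))
    np.add.at(counts, (g1[keep], g2[keep]), 1.0)
    return counts


def _genotype_class_probs(f: np.ndarray) -> np.ndarray:
    """P(two-locus genotype class) from haplotype freqs f = (AB, Ab, aB, ab).

    Index [i, j] = (allele2 count at locus 1, allele2 count at locus 2);
    allele "A"/"B" = first-listed = count 0.
    """
    fAB, fAb, faB, fab = f
    return np.array(
        [
            [fAB**2, 2 * fAB * fAb, fAb**2],
            [2 * fAB * faB, 2 * (fAB * fab + fAb * faB), 2 * fAb * fab],
            [faB**2, 2 * faB * fab, fab**2],
        ]
    )


def _loglik(counts: np.ndarray, f: np.ndarray) -> float:
    probs = _genotype_class_probs(f)
    mask = counts > 0
    with np.errstate(divide="ignore"):
        lp = np.log(probs[mask])
    return float(np.sum(counts[mask] * lp))


def _dprime_from_freqs(f: np.ndarray) -> tuple[float, float, float]:
    """(D, D', r2) from haplotype frequencies."""
    fAB, fAb, faB, fab = f
    pA, pB = fAB + fAb, fAB + faB
    qA, qB = 1 - pA, 1 - pB
    D = fAB - pA * pB
    if D > 0:
        dmax = min(pA * qB, qA * pB)
    else:
        dmax = min(pA * pB, qA * qB)
    dprime = abs(D) / dmax if dmax > 0 else float("nan")
    denom = pA * qA * pB * qB
    r2 = D * D / denom if denom > 0 else float("nan")
    return float(D), float(min(dprime, 1.0)), float(r2)


def em_two_locus(g1: np.ndarray, g2: np.ndarray, snp1: str = "snp1", snp2: str = "snp2") -> PairwiseLD:
    """Two-locus haplotype-frequency EM from unphased genotypes.

    Parameters are allele2-count vectors (0/1/2, -1 missing).  Returns D,
    D' and r2; monomorphic pairs are flagged ``defined=False``.
    """
    counts = _pair_counts(np.asarray(g1), np.asarray(g2))
    n = counts.sum()
    if n < 2:
        raise ValueError("need at least 2 animals typed at both SNPs")
    pA = (2 * counts[0].sum() + counts[1].sum()) / (2 * n)
    pB = (2 * counts[:, 0].sum() + counts[:, 1].sum()) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return PairwiseLD(snp1, snp2, (np.nan,) * 4, np.nan, np.nan, np.nan, defined=False)

    qA, qB = 1 - pA, 1 - pB
    f = np.array([pA * pB, pA * qB, qA * pB, qA * qB])  # LE start
    # unambiguous haplotype contributions (everything except double hets)
    base = np.array(
        [
            2 * counts[0, 0] + counts[0, 1] + counts[1, 0],  # AB
            2 * counts[0, 2] + counts[0, 1] + counts[1, 2],  # Ab
            2 * counts[2, 0] + counts[2, 1] + counts[1, 0],  # aB
            2 * counts[2, 2] + counts[2, 1] + counts[1, 2],  # ab
        ]
    )
    n_dh = counts[1, 1]
    last = -np.inf
    for _ in range(EM_MAX_ITER):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        x = cis / (cis + trans) if cis + trans > 0 else 0.5
        new = base + n_dh * np.array([x, 1 - x, 1 - x, x])
        f = new / new.sum()
        ll = _loglik(counts, f)
        if ll + 1e-12 < last:
            raise AssertionError("EM log-likelihood decreased")
        if ll - last < EM_TOL:
            last = ll
            break
        last = ll
    D, dprime, r2 = _dprime_from_freqs(f)
    return PairwiseLD(snp1, snp2, tuple(float(x) for x in f), D, dprime, r2)


def _dprime_profile_loglik(counts: np.ndarray, pA: float, pB: float, sign: float, grid: np.ndarray) -> np.ndarray:
    """Log-likelihood of the genotype table along a D' grid (freqs at MLE)."""
    qA, qB = 1 - pA, 1 - pB
    dmax = min(pA * qB, qA * pB) if sign >= 0 else min(pA * pB, qA * qB)
    lls = np.empty(len(grid))
    for k, dp in enumerate(grid):
        D = sign * dp * dmax
        f = np.array([pA * pB + D, pA * qB - D, qA * pB - D, qA * qB + D])
        f = np.clip(f, 0.0, 1.0)
        lls[k] = _loglik(counts, f)
    return lls


def dprime_ci(
    pair: PairwiseLD, g1: np.ndarray, g2: np.ndarray, grid_points: int = 101, level: float = 0.90
) -> tuple[float, float]:
    """Confidence interval on D' from the normalized likelihood on a grid.

    Gabriel-style: evaluate the multinomial likelihood on ``grid_points``
    equally spaced D' values in [0, 1] with allele frequencies fixed at
    their MLEs and the sign of D fixed at its MLE, normalize to a
    probability mass, and take the central ``level`` interval.
    """
    if not pair.defined or not np.isfinite(pair.dprime):
        raise ValueError("D' undefined for this pair")
    counts = _pair_counts(np.asarray(g1), np.asarray(g2))
    n = counts.sum()
    pA = (2 * counts[0].sum() + counts[1].sum()) / (2 * n)
    pB = (2 * counts[:, 0].sum() + counts[:, 1].sum()) / (2 * n)
    sign = 1.0 if pair.D >= 0 else -1.0
    grid = np.linspace(0.0, 1.0, grid_points)
    lls = _dprime_profile_loglik(counts, pA, pB, sign, grid)
    if not np.any(np.isfinite(lls)):
        log.warning("degenerate D' likelihood for %s-%s; CI set to [0, 1]", pair.snp1, pair.snp2)
        return 0.0, 1.0
    w = np.exp(lls - np.nanmax(lls))
    w[~np.isfinite(w)] = 0.0
    total = w.sum()
    if total == 0:
        log.warning("degenerate D' likelihood for %s-%s; CI set to [0, 1]", pair.snp1, pair.snp2)
        return 0.0, 1.0
    cum = np.cumsum(w) / total
    tail = (1.0 - level) / 2.0
    low = grid[int(np.searchsorted(cum, tail))]
    high = grid[min(int(np.searchsorted(cum, 1.0 - tail)), len(grid) - 1)]
    # the point estimate must lie inside its own interval
    return float(min(low, pair.dprime)), float(max(high, pair.dprime))


def pairwise_ld_table(geno: GenotypeMatrix, snps: list[str] | None = None, with_ci: bool = True) -> pd.DataFrame:
    """All-pairs LD summary (within each chromosome), Haploview-like."""
    meta = geno.meta if snps is None else geno.meta.loc[snps]
    rows = []
    for chrom, sub in meta.groupby("chrom", sort=False):
        ordered = sub.sort_values("pos").index
        for s1, s2 in combinations(ordered, 2):
            g1 = geno.calls[s1].to_numpy()
            g2 = geno.calls[s2].to_numpy()
            pair = em_two_locus(g1, g2, s1, s2)
            row = {
                "chrom": chrom, "snp1": s1, "snp2": s2,
                "D": pair.D, "dprime": pair.dprime, "r2": pair.r2,
                "defined": pair.defined,
            }
            if with_ci and pair.defined:
                low, high = dprime_ci(pair, g1, g2)
                row["ci_low"], row["ci_high"] = low, high
            rows.append(row)
    return pd.DataFrame(rows)


def plot_ld_triangle(ld_table: pd.DataFrame, ax=None):
    """Haploview-style D' triangle from a :func:`pairwise_ld_table` frame.

    Requires matplotlib (the ``plot`` extra).  Returns the axes.
    """
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plot_ld_triangle needs matplotlib (install the 'plot' extra)") from exc

    snps = list(dict.fromkeys(list(ld_table["snp1"]) + list(ld_table["snp2"])))
    idx = {s: i for i, s in enumerate(snps)}
    if ax is None:
        _, ax = plt.subplots(figsize=(0.6 * len(snps) + 2, 0.6 * len(snps) + 1))
    for _, row in ld_table.iterrows():
        i, j = idx[row["snp1"]], idx[row["snp2"]]
        d = row["dprime"] if np.isfinite(row["dprime"]) else 0.0
        ax.add_patch(
            plt.Rectangle((min(i, j) + (abs(i - j) - 1) / 2, abs(i - j) - 1), 1, 1,
                          angle=45, color=plt.cm.Reds(d), ec="grey", lw=0.3)
        )
        ax.text(min(i, j) + abs(i - j) / 2, abs(i - j) - 0.45, f"{100 * d:.0f}",
                ha="center", va="center", fontsize=7)
    ax.set_xlim(-0.5, len(snps) + 0.5)
    ax.set_ylim(len(snps), -1.5)
    ax.set_xticks(range(len(snps)))
    ax.set_xticklabels(snps, rotation=90, fontsize=7)
    ax.set_yticks([])
    for side in ("top", "right", "left", "bottom"):
        ax.spines[side].set_visible(False)
    return ax


def _pair_class(low: float, high: float) -> str:
    if low >= STRONG_LOW and high >= STRONG_HIGH:
        return "strong"
    if high < RECOMB_HIGH:
        return "recomb"
    return "uninformative"


def find_blocks(geno: GenotypeMatrix, snps: list[str] | None = None) -> list[list[str]]:
    """Gabriel confidence-interval block detection.

    SNPs are ordered by position within chromosome; a candidate span is a
    block when >= 95% of its informative pairs (strong LD or strong
    recombination) are strong LD.  Maximal non-overlapping spans are
    chosen greedily, longest first.  Returns lists of member SNP names.
    """
    ld = pairwise_ld_table(geno, snps=snps, with_ci=True)
    if ld.empty:
        return []
    cls = {}
    for _, row in ld.iterrows():
        if row["defined"] and np.isfinite(row.get("ci_low", np.nan)):
            cls[(row["snp1"], row["snp2"])] = _pair_class(row["ci_low"], row["ci_high"])
        else:
            cls[(row["snp1"], row["snp2"])] = "uninformative"
    blocks: list[list[str]] = []
    meta = geno.meta if snps is None else geno.meta.loc[snps]
    for _, sub in meta.groupby("chrom", sort=False):
        ordered = list(sub.sort_values("pos").index)
        m = len(ordered)
        if m < 2:
            continue
        candidates = []
        for i in range(m):
            for j in range(i + 1, m):
                span = ordered[i : j + 1]
                kinds = [cls[(a, b)] for a, b in combinations(span, 2)]
                n_strong = kinds.count("strong")
                n_inf = n_strong + kinds.count("recomb")
                if n_inf > 0 and n_strong / n_inf >= INFORMATIVE_FRACTION and n_strong >= 1:
                    candidates.append((i, j))
        candidates.sort(key=lambda ij: (-(ij[1] - ij[0]), ij[0]))
        used: set[int] = set()
        for i, j in candidates:
            if any(k in used for k in range(i, j + 1)):
                continue
            used.update(range(i, j + 1))
            blocks.append(ordered[i : j + 1])
    return blocks


def _consistent_pairs(genotype: tuple[int, ...]) -> list[tuple[int, int]]:
    """Unordered haplotype-code pairs consistent with a multilocus genotype.

    Haplotype codes are bit fields, bit k set = allele2 at SNP k.
    """
    het = [k for k, g in enumerate(genotype) if g == 1]
    fixed = sum(1 << k for k, g in enumerate(genotype) if g == 2)
    het_mask = sum(1 << k for k in het)
    if not het:
        return [(fixed, fixed)]
    pairs = set()
    for bits in range(1 << len(het)):
        h1 = fixed
        for t, k in enumerate(het):
            if bits >> t & 1:
                h1 |= 1 << k
        h2 = fixed | (het_mask & ~(h1 & het_mask))
        pairs.add((min(h1, h2), max(h1, h2)))
    return sorted(pairs)


def em_block_phase(
    geno: GenotypeMatrix,
    snps: list[str],
    retain_threshold: float = 0.05,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> HaplotypeBlock:
    """Multi-locus EM haplotype frequencies and max-posterior diplotypes.

    Haplotypes with final frequency > ``retain_threshold`` are retained
    and labelled H1..Hk by descending frequency (all haplotypes are
    reported, with a retained flag).  Animals with a missing genotype in
    the block are excluded.  Diplotype ties are broken toward the pair
    containing the globally more frequent haplotype.
    """
    m = len(snps)
    if m > MAX_BLOCK_SNPS:
        raise ValueError(
            f"block of {m} SNPs exceeds the {MAX_BLOCK_SNPS}-SNP haplotype-space cap; "
            "phase in windows instead"
        )
    calls = geno.calls[snps]
    complete = calls.ge(0).all(axis=1)
    calls = calls[complete]
    genotypes = [tuple(int(g) for g in row) for row in calls.to_numpy()]
    classes: dict[tuple[int, ...], int] = {}
    for g in genotypes:
        classes[g] = classes.get(g, 0) + 1
    class_pairs = {g: _consistent_pairs(g) for g in classes}

    nhap = 1 << m
    f = np.full(nhap, 1.0 / nhap)
    n_total = sum(classes.values())
    last = -np.inf
    prev_pruned = False
    for _ in range(max_iter):
        expected = np.zeros(nhap)
        ll = 0.0
        for g, count in classes.items():
            weights = np.array([(2.0 if h1 != h2 else 1.0) * f[h1] * f[h2] for h1, h2 in class_pairs[g]])
            total = weights.sum()
            if total <= 0:
                continue
            ll += count * np.log(total)
            weights /= total
            for (h1, h2), w in zip(class_pairs[g], weights):
                expected[h1] += count * w
                expected[h2] += count * w
        f = expected / (2 * n_total)
        small = (f > 0) & (f < PRUNE_FREQ)
        f[small] = 0.0
        if f.sum() > 0:
            f /= f.sum()
        # monotone except across pruning steps (pruning may trade a sliver
        # of likelihood for a sparser haplotype support)
        if not prev_pruned and ll + 1e-9 < last:
            raise AssertionError("block EM log-likelihood decreased")
        prev_pruned = bool(small.any())
        if abs(ll - last) < tol:
            last = ll
            break
        last = ll

    alleles = geno.meta.loc[snps, ["allele1", "allele2"]].to_numpy()

    def hap_seq(code: int) -> str:
        return "".join(alleles[k][code >> k & 1] for k in range(m))

    order = np.argsort(-f, kind="stable")
    hap_rows = []
    labels: dict[int, str] = {}
    rank = 0
    for code in order:
        if f[code] <= 0:
            continue
        rank += 1
        labels[int(code)] = f"H{rank}"
        hap_rows.append(
            {
                "label": f"H{rank}",
                "sequence": hap_seq(int(code)),
                "frequency": float(f[code]),
                "retained": bool(f[code] > retain_threshold),
            }
        )
    haplotypes = pd.DataFrame(hap_rows)

    global_rank = {code: i for i, code in enumerate(order)}
    dip_rows = []
    for animal, g in zip(calls.index, genotypes):
        pairs = class_pairs[g]
        weights = np.array([(2.0 if h1 != h2 else 1.0) * f[h1] * f[h2] for h1, h2 in pairs])
        total = weights.sum()
        if total <= 0:
            continue
        post = weights / total
        best = np.max(post)
        tied = [k for k, w in enumerate(post) if w >= best - 1e-12]
        # tie-break toward the pair containing the globally most frequent haplotype
        k = min(tied, key=lambda t: min(global_rank[pairs[t][0]], global_rank[pairs[t][1]]))
        h1, h2 = pairs[k]
        l1, l2 = labels.get(h1), labels.get(h2)
        if l1 is None or l2 is None:
            continue
        first, second = sorted([l1, l2], key=lambda s: int(s[1:]))
        dip_rows.append(
            {
                "animal": animal,
                "hap1": first,
                "hap2": second,
                "diplotype": first + second,
                "posterior": float(post[k]),
            }
        )
    diplotypes = pd.DataFrame(dip_rows).set_index("animal") if dip_rows else pd.DataFrame(
        columns=["hap1", "hap2", "diplotype", "posterior"]
    )
    return HaplotypeBlock(snps=list(snps), haplotypes=haplotypes, diplotypes=diplotypes, loglik=last)
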