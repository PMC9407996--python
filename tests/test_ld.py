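"""Two-locus EM, D' confidence intervals, Gabriel blocks, block phasing."""

import numpy as np
import pandas as pd
import pytest
from helpers import pedigree_from_rows
from hypothesis import given
from hypothesis import strategies as st

import milkassoc as ma
from milkassoc.genotypes import GenotypeMatrix
from milkassoc.ld import _dprime_profile_loglik, _pair_counts, em_block_phase, em_two_locus


def _geno_from_hap_pairs(pairs):
    """Unphased two-locus genotypes from (hap1, hap2) tuples of 'AB'-style strings."""
    g1, g2 = [], []
    for h1, h2 in pairs:
        g1.append((h1[0] == "a") + (h2[0] == "a"))
        g2.append((h1[1] == "b") + (h2[1] == "b"))
    return np.array(g1), np.array(g2)


def _matrix(columns: dict, animals=None) -> GenotypeMatrix:
    calls = pd.DataFrame(columns)
    calls.index = animals or [f"X{i}" for i in range(len(calls))]
    meta = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(len(columns)) * 10 + 100,
            "gene": "G",
            "allele1": "A",
            "allele2": "B",
        },
        index=list(columns),
    )
    return GenotypeMatrix(calls, meta)


class TestTwoLocusEM:
    def test_two_haplotype_system_complete_ld(self):
        pairs = [("AB", "AB")] * 30 + [("AB", "ab")] * 20 + [("ab", "ab")] * 10
        g1, g2 = _geno_from_hap_pairs(pairs)
        assert em_two_locus(g1, g2).dprime == pytest.approx(1.0, abs=1e-6)

    def test_equilibrium_limit(self, rng):
        g1 = rng.binomial(2, 0.5, 10_000)
        g2 = rng.binomial(2, 0.5, 10_000)
        assert em_two_locus(g1, g2).dprime < 0.05

    def test_matches_counting_oracle_on_phase_known_data(self, rng):
        # 50 animals, never heterozygous at both loci -> phase known, EM must
        # equal direct haplotype counting
        pool = [("AB", "AB"), ("AB", "Ab"), ("Ab", "Ab"), ("AB", "aB"), ("aB", "aB"), ("ab", "ab")]
        pairs = [pool[i] for i in rng.integers(0, len(pool), 50)]
        g1, g2 = _geno_from_hap_pairs(pairs)
        est = em_two_locus(g1, g2).hap_freqs
        haps = [h for pair in pairs for h in pair]
        counted = [haps.count(h) / len(haps) for h in ("AB", "Ab", "aB", "ab")]
        assert np.abs(np.array(est) - counted).max() < 1e-6

    def test_monomorphic_flagged(self):
        pair = em_two_locus(np.zeros(20, dtype=int), np.array([0, 1, 2] * 7)[:20])
        assert not pair.defined

    def test_marginals_preserved(self, rng):
        g1 = rng.binomial(2, 0.3, 400)
        g2 = rng.binomial(2, 0.7, 400)
        f = em_two_locus(g1, g2).hap_freqs
        pA = f[0] + f[1]
        assert pA == pytest.approx(1 - g1.mean() / 2, abs=1e-6)

    @given(swap1=st.booleans(), swap2=st.booleans(), seed=st.integers(0, 20))
    def test_dprime_invariant_to_allele_label_swap(self, swap1, swap2, seed):
        rng = np.random.default_rng(seed)
        pairs = [("AB", "AB")] * 10 + [("AB", "ab")] * 10 + [("Ab", "aB")] * 5 + [("ab", "ab")] * 10
        g1, g2 = _geno_from_hap_pairs(pairs)
        base = em_two_locus(g1, g2).dprime
        h1 = 2 - g1 if swap1 else g1
        h2 = 2 - g2 if swap2 else g2
        assert em_two_locus(h1, h2).dprime == pytest.approx(base, abs=1e-9)


class TestDprimeCI:
    def test_perfect_ld_large_n(self):
        pairs = [("AB", "AB")] * 500 + [("AB", "ab")] * 300 + [("ab", "ab")] * 200
        g1, g2 = _geno_from_hap_pairs(pairs)
        low, high = ma.dprime_ci(em_two_locus(g1, g2), g1, g2)
        assert low >= 0.98

    def test_equilibrium_large_n(self, rng):
        g1 = rng.binomial(2, 0.5, 5000)
        g2 = rng.binomial(2, 0.5, 5000)
        _, high = ma.dprime_ci(em_two_locus(g1, g2), g1, g2)
        assert high < 0.9

    def test_refinement_oracle_fine_grid(self, rng):
        # brute-force 10^4-point likelihood integration written independently
        pairs = [("AB", "AB")] * 20 + [("AB", "ab")] * 15 + [("Ab", "aB")] * 3 + [("ab", "ab")] * 12
        g1, g2 = _geno_from_hap_pairs(pairs)
        pair = em_two_locus(g1, g2)
        low, high = ma.dprime_ci(pair, g1, g2, grid_points=101)

        counts = _pair_counts(g1, g2)
        n = counts.sum()
        pA = (2 * counts[0].sum() + counts[1].sum()) / (2 * n)
        pB = (2 * counts[:, 0].sum() + counts[:, 1].sum()) / (2 * n)
        qA, qB = 1 - pA, 1 - pB
        sign = 1.0 if pair.D >= 0 else -1.0
        dmax = min(pA * qB, qA * pB) if sign > 0 else min(pA * pB, qA * qB)
        grid = np.linspace(0, 1, 10_000)
        lls = np.empty(len(grid))
        for k, dp in enumerate(grid):
            D = sign * dp * dmax
            f = np.clip([pA * pB + D, pA * qB - D, qA * pB - D, qA * qB + D], 0, 1)
            probs = np.array(
                [
                    [f[0] ** 2, 2 * f[0] * f[1], f[1] ** 2],
                    [2 * f[0] * f[2], 2 * (f[0] * f[3] + f[1] * f[2]), 2 * f[1] * f[3]],
                    [f[2] ** 2, 2 * f[2] * f[3], f[3] ** 2],
                ]
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                lls[k] = np.nansum(np.where(counts > 0, counts * np.log(probs), 0.0))
        w = np.exp(lls - lls.max())
        cum = np.cumsum(w) / w.sum()
        low_fine = grid[np.searchsorted(cum, 0.05)]
        high_fine = grid[min(np.searchsorted(cum, 0.95), len(grid) - 1)]
        assert abs(low - low_fine) <= 0.01 + 1e-9
        assert abs(high - high_fine) <= 0.01 + 1e-9

    def test_interval_contains_point_estimate(self, rng):
        g1 = rng.binomial(2, 0.4, 300)
        g2 = rng.binomial(2, 0.6, 300)
        pair = em_two_locus(g1, g2)
        low, high = ma.dprime_ci(pair, g1, g2)
        assert low <= pair.dprime <= high


class TestFindBlocks:
    def test_mutual_perfect_ld_single_block(self, rng):
        base = rng.binomial(2, 0.5, 300)
        geno = _matrix({f"s{i}": base for i in range(4)})
        blocks = ma.find_blocks(geno)
        assert blocks == [[f"s{i}" for i in range(4)]]

    def test_independent_snps_no_blocks(self, rng):
        geno = _matrix({f"s{i}": rng.binomial(2, 0.5, 800) for i in range(4)})
        assert ma.find_blocks(geno) == []

    def test_fewer_than_two_snps(self, rng):
        geno = _matrix({"s0": rng.binomial(2, 0.5, 50)})
        assert ma.find_blocks(geno) == []

    def test_recovers_simulated_two_block_structure(self):
        cfg = ma.default_config(seed=31)
        ped = pedigree_from_rows([(f"U{i}", "", "") for i in range(924)])
        geno = ma.simulate_genotypes(ped, cfg)
        found = ma.find_blocks(geno, snps=geno.snps_of_gene("ALDH18A1"))
        truth = sorted(sorted(b.snps) for b in cfg.blocks)
        assert sorted(sorted(b) for b in found) == truth


class TestBlockPhasing:
    def test_counting_oracle_phase_known(self):
        # 3-SNP block, every animal het at <= 1 SNP -> phase unambiguous
        haps = ["AAA", "ABA", "BBB"]
        pairs = [(0, 0)] * 12 + [(0, 1)] * 8 + [(1, 1)] * 6 + [(2, 2)] * 9 + [(1, 2)] * 0
        calls = {}
        for k in range(3):
            calls[f"s{k}"] = [
                (haps[i][k] == "B") + (haps[j][k] == "B") for i, j in pairs
            ]
        geno = _matrix(calls)
        block = em_block_phase(geno, ["s0", "s1", "s2"])
        counted = {}
        for i, j in pairs:
            for h in (haps[i], haps[j]):
                counted[h] = counted.get(h, 0) + 1
        total = sum(counted.values())
        est = block.haplotypes.set_index("sequence")["frequency"]
        for seq, cnt in counted.items():
            assert est[seq] == pytest.approx(cnt / total, abs=1e-6)

    def test_single_snp_block_reduces_to_allele_frequencies(self, rng):
        g = rng.binomial(2, 0.3, 200)
        geno = _matrix({"s0": g})
        block = em_block_phase(geno, ["s0"])
        est = block.haplotypes.set_index("sequence")["frequency"]
        assert est["A"] == pytest.approx(1 - g.mean() / 2, abs=1e-9)
        assert est["B"] == pytest.approx(g.mean() / 2, abs=1e-9)

    def test_simulated_five_snp_block_recovery_and_filter(self):
        cfg = ma.default_config(seed=53)
        ped = pedigree_from_rows([(f"U{i}", "", "") for i in range(924)])
        geno = ma.simulate_genotypes(ped, cfg)
        block1 = next(b for b in cfg.blocks if len(b.snps) == 5)
        est = em_block_phase(geno, list(block1.snps)).haplotypes.set_index("sequence")
        for seq, truth in block1.haplotypes.items():
            got = float(est["frequency"].get(seq, 0.0))
            assert got == pytest.approx(truth, abs=0.02)
        rare = min(block1.haplotypes, key=block1.haplotypes.get)
        assert rare not in est.index or not est.loc[rare, "retained"]
        for seq, truth in block1.haplotypes.items():
            if 0.05 < truth < 0.1:
                assert est.loc[seq, "retained"]

    def test_diplotypes_consistent_with_genotypes(self, daughter_genotypes, dataset):
        block1 = next(b for b in dataset.config.blocks if len(b.snps) == 5)
        block = em_block_phase(daughter_genotypes, list(block1.snps))
        seqs = block.haplotypes.set_index("label")["sequence"]
        alleles = daughter_genotypes.meta.loc[list(block1.snps), ["allele1", "allele2"]]
        for animal, row in block.diplotypes.head(50).iterrows():
            s1, s2 = seqs[row["hap1"]], seqs[row["hap2"]]
            for k, snp in enumerate(block1.snps):
                g = daughter_genotypes.calls.loc[animal, snp]
                implied = (s1[k] == alleles.loc[snp, "allele2"]) + (
                    s2[k] == alleles.loc[snp, "allele2"]
                )
                assert implied == g

    def test_marginal_allele_frequencies_preserved(self, daughter_genotypes, dataset):
        block1 = next(b for b in dataset.config.blocks if len(b.snps) == 5)
        block = em_block_phase(daughter_genotypes, list(block1.snps))
        haps = block.haplotypes
        for k, snp in enumerate(block1.snps):
            a2 = daughter_genotypes.meta.loc[snp, "allele2"]
            marg = sum(r["frequency"] for _, r in haps.iterrows() if r["sequence"][k] == a2)
            g = daughter_genotypes.calls[snp]
            direct = g[g >= 0].mean() / 2
            assert marg == pytest.approx(direct, abs=1e-6)

    def test_oversized_block_rejected(self, rng):
        geno = _matrix({f"s{i}": rng.binomial(2, 0.5, 30) for i in range(13)})
        with pytest.raises(ValueError, match="window"):
            em_block_phase(geno, [f"s{i}" for i in range(13)])
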