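"""Independent oracles and fixture builders shared by the test modules."""

import numpy as np
import pandas as pd

from milkassoc import Pedigree


def pedigree_from_rows(rows):
    return Pedigree(pd.DataFrame(rows, columns=["animal", "sire", "dam"]))


def random_pedigree(rng, n_founders=10, n_offspring=30):
    """Random multi-generation pedigree (parents drawn from earlier animals)."""
    rows = [(f"F{i}", "", "") for i in range(n_founders)]
    ids = [r[0] for r in rows]
    for k in range(n_offspring):
        sire, dam = rng.choice(len(ids), size=2, replace=False)
        rows.append((f"O{k}", ids[sire], ids[dam]))
        ids.append(f"O{k}")
    return pedigree_from_rows(rows)


def gene_drop_kinship(ped, n_rep=1_000_000, seed=123):
    """Monte-Carlo additive relationships by gene dropping.

    Each founder gamete gets a unique allele id; offspring inherit one
    random allele per parent.  Twice the IBD probability of two random
    alleles estimates a_ij; the diagonal is 1 + P(the two alleles within
    an animal are IBD).
    """
    rng = np.random.default_rng(seed)
    n = len(ped.ids)
    alleles = np.zeros((n, 2, n_rep), dtype=np.int32)
    next_id = 0
    for i in range(n):
        for slot, p in enumerate((ped.sire_idx[i], ped.dam_idx[i])):
            if p < 0:
                alleles[i, slot, :] = next_id
                next_id += 1
            else:
                pick = rng.integers(2, size=n_rep)
                alleles[i, slot, :] = np.where(pick == 0, alleles[p, 0, :], alleles[p, 1, :])
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                A[i, i] = 1.0 + (alleles[i, 0] == alleles[i, 1]).mean()
            else:
                ibd = sum(
                    (alleles[i, a] == alleles[j, b]).mean() for a in (0, 1) for b in (0, 1)
                )
                A[i, j] = A[j, i] = ibd / 2.0
    return pd.DataFrame(A, index=ped.ids, columns=ped.ids)


def three_generation_pedigree():
    """8 animals over 3 generations with half-sib and inbred matings."""
    return pedigree_from_rows(
        [
            ("A", "", ""),
            ("B", "", ""),
            ("C", "", ""),
            ("D", "", ""),
            ("E", "A", "B"),
            ("F", "A", "C"),  # E and F are paternal half sibs
            ("G", "E", "F"),  # offspring of half sibs: F = 0.125
            ("H", "E", "D"),
        ]
    )
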