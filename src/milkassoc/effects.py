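"""Additive / dominance / allele-substitution effect decomposition.

From the genotype least-squares means of a biallelic SNP,

    a     = (AA - BB) / 2
    d     = AB - (AA + BB) / 2
    alpha = a + (q - p) * d

where AA is the homozygote of the allele whose frequency is p (the
first-listed allele), BB the other homozygote, and alpha the average
effect of allele substitution.  Swapping allele labels negates a and
alpha and leaves d unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["EffectDecomposition", "decompose_effects"]


@dataclass(frozen=True)
class EffectDecomposition:
    a: float
    d: float
    alpha: float
    p: float
    q: float
    hom1_label: str = "AA"

    def __post_init__(self) -> None:
        assert abs(self.alpha - (self.a + (self.q - self.p) * self.d)) < 1e-9


def decompose_effects(
    mean_hom1: float,
    mean_het: float,
    mean_hom2: float,
    p: float,
    q: float,
    hom1_label: str = "AA",
) -> EffectDecomposition:
    """Decompose genotype LS-means into (a, d, alpha).

    ``mean_hom1`` is the LS-mean of the homozygote for the allele with
    frequency ``p``; the returned record notes that orientation.
    """
    if abs(p + q - 1.0) > 1e-9:
        raise ValueError("allele frequencies must satisfy p + q = 1")
    for v in (mean_hom1, mean_het, mean_hom2):
        if not math.isfinite(v):
            raise ValueError("non-finite genotype mean")
    a = (mean_hom1 - mean_hom2) / 2.0
    d = mean_het - (mean_hom1 + mean_hom2) / 2.0
    alpha = a + (q - p) * d
    return EffectDecomposition(a=a, d=d, alpha=alpha, p=p, q=q, hom1_label=hom1_label)
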