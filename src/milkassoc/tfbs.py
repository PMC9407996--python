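"""Allele-differential transcription-factor binding-site prediction.

A JASPAR position frequency matrix (PFM) is turned into a log-odds
position weight matrix with the JASPAR pseudocount convention (a total
pseudocount of 0.8 split by the background frequencies):

    w[b, k] = log2( (c[b, k] + 0.8 * bg[b]) / (N_k + 0.8) / bg[b] )

A window of motif length L is scored by summing its per-position
weights; the *relative score* rescales the raw score to [0, 1] between
the minimal and maximal achievable scores (sum of column minima /
maxima).  A transcription factor is called present on an allele when
the best-scoring window overlapping the SNP, on either strand, reaches
the relative-score threshold (0.8 by default); comparing the two
alleles classifies each TF as gained, lost, retained, or absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import numpy as np
from Bio import motifs as bio_motifs
from Bio.Seq import Seq

__all__ = ["PWMotif", "TfbsHit", "AlleleTfbsDelta", "read_pfm", "relative_score", "best_hit", "scan_alleles"]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
JASPAR_PSEUDOCOUNT = 0.8


@dataclass(frozen=True)
class PWMotif:
    """A TF motif: counts, background, log-odds weights, score bounds."""

    name: str
    counts: np.ndarray  # 4 x L, rows A/C/G/T
    background: np.ndarray  # length 4
    pwm: np.ndarray  # 4 x L log2-odds
    smin: float
    smax: float

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmax(axis=0))

    @property
    def anticonsensus(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmin(axis=0))


def _build_motif(name: str, counts: np.ndarray, background) -> PWMotif:
    if counts.shape[0] != 4 or counts.shape[1] < 4:
        raise ValueError(f"motif {name}: need a 4 x L matrix with L >= 4")
    if np.any(counts < 0):
        raise ValueError(f"motif {name}: negative counts")
    colsum = counts.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError(f"motif {name}: empty column")
    bg = np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    freq = (counts + JASPAR_PSEUDOCOUNT * bg[:, None]) / (colsum + JASPAR_PSEUDOCOUNT)
    pwm = np.log2(freq / bg[:, None])
    smin = float(pwm.min(axis=0).sum())
    smax = float(pwm.max(axis=0).sum())
    if smax - smin <= 0:
        raise ValueError(f"motif {name}: degenerate (uniform) matrix, Smin == Smax")
    return PWMotif(name=name, counts=counts.astype(float), background=bg, pwm=pwm, smin=smin, smax=smax)


def read_pfm(source, background=(0.25, 0.25, 0.25, 0.25)) -> list[PWMotif]:
    """Parse JASPAR ``.jaspar``/``.pfm`` text (file path or raw string).

    Both dialects are accepted: a ``>`` header followed by four rows,
    with or without ``A [ ... ]`` base labels and brackets.
    """
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        text = Path(source).read_text()
    else:
        text = str(source)
    if not text.lstrip().startswith(">"):
        text = ">motif\n" + text
    try:
        parsed = bio_motifs.parse(StringIO(text), "jaspar")
    except Exception as exc:  # ragged rows, bad numbers
        raise ValueError(f"PFM format error: {exc}") from exc
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in BASES], dtype=float)
        name = m.name or m.matrix_id or "motif"
        out.append(_build_motif(str(name), counts, background))
    return out


def _window_score(window: str, motif: PWMotif) -> float:
    """Raw log-odds score; an N (or other ambiguity) takes the column minimum."""
    score = 0.0
    for k, base in enumerate(window.upper()):
        idx = BASE_INDEX.get(base)
        if idx is None:  # unknown base: worst case for this column
            score += float(motif.pwm[:, k].min())
        else:
            score += float(motif.pwm[idx, k])
    return score


def relative_score(window: str, motif: PWMotif) -> float:
    """(S - Smin) / (Smax - Smin) for a window of exactly motif length."""
    if len(window) != motif.length:
        raise ValueError(f"window length {len(window)} != motif length {motif.length}")
    return (_window_score(window, motif) - motif.smin) / (motif.smax - motif.smin)


@dataclass(frozen=True)
class TfbsHit:
    tf: str
    start: int  # 0-based on the forward sequence
    end: int
    strand: str  # "+" or "-"
    score: float
    relative: float
    window: str
    allele: str


@dataclass(frozen=True)
class AlleleTfbsDelta:
    snp: str
    tf: str
    classification: str  # gained | lost | retained | absent
    ref_best: TfbsHit | None
    alt_best: TfbsHit | None


def best_hit(seq: str, snp_offset: int, motif: PWMotif, allele_label: str) -> TfbsHit | None:
    """Best-scoring window overlapping the SNP position, both strands."""
    L = motif.length
    best: TfbsHit | None = None
    candidates = []
    for start in range(snp_offset - L + 1, snp_offset + 1):
        if start < 0 or start + L > len(seq):
            continue
        candidates.append((start, seq[start : start + L], "+"))
    rc = str(Seq(seq).reverse_complement())
    rc_offset = len(seq) - 1 - snp_offset
    for start in range(rc_offset - L + 1, rc_offset + 1):
        if start < 0 or start + L > len(rc):
            continue
        fwd_start = len(seq) - (start + L)
        candidates.append((fwd_start, rc[start : start + L], "-"))
    for fwd_start, window, strand in candidates:
        rel = relative_score(window, motif)
        if best is None or rel > best.relative:
            best = TfbsHit(
                tf=motif.name,
                start=fwd_start,
                end=fwd_start + L,
                strand=strand,
                score=_window_score(window, motif),
                relative=rel,
                window=window,
                allele=allele_label,
            )
    return best


def scan_alleles(
    flank: str,
    snp_offset: int,
    ref: str,
    alt: str,
    motifs: list[PWMotif],
    threshold: float = 0.8,
    snp_name: str = "snp",
) -> list[AlleleTfbsDelta]:
    """Classify each motif as gained/lost/retained/absent between alleles.

    ``flank`` is the forward-strand sequence containing the SNP at
    0-based ``snp_offset`` with the reference allele; it must extend at
    least L-1 bases on each side of the SNP for every motif.
    """
    flank = flank.upper()
    if not 0 <= snp_offset < len(flank):
        raise ValueError("SNP offset outside the flanking sequence")
    if flank[snp_offset] != ref.upper():
        raise ValueError(
            f"flank base {flank[snp_offset]!r} at offset {snp_offset} does not match "
            f"reference allele {ref!r}"
        )
    alt_seq = flank[:snp_offset] + alt.upper() + flank[snp_offset + 1 :]
    results = []
    for motif in motifs:
        if snp_offset < motif.length - 1 or len(flank) - snp_offset < motif.length:
            raise ValueError(
                f"flank too short for motif {motif.name} (length {motif.length}); "
                f"need {motif.length - 1} bases each side of the SNP"
            )
        ref_best = best_hit(flank, snp_offset, motif, ref.upper())
        alt_best = best_hit(alt_seq, snp_offset, motif, alt.upper())
        ref_on = ref_best is not None and ref_best.relative >= threshold
        alt_on = alt_best is not None and alt_best.relative >= threshold
        if ref_on and alt_on:
            cls = "retained"
        elif ref_on:
            cls = "lost"
        elif alt_on:
            cls = "gained"
        else:
            cls = "absent"
        results.append(
            AlleleTfbsDelta(snp=snp_name, tf=motif.name, classification=cls, ref_best=ref_best, alt_best=alt_best)
        )
    return results
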