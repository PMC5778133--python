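"""Metagenomic fragment recruitment: from read alignments to a filtered
gene x sample count/RPKM matrix with detection flags.

The paper-era mapping pipeline is emulated at the evidence level: a 25-mer
prefilter against the assembly, an identity filter (>= 95% mean identity)
and a low-complexity filter (the read must retain >= 30% high-complexity
bases under DUST), then tallying per (gene, sample), the detection rule
(one read at >= 95% identity over 100% of its length), and RPKM.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .types import AssemblyBundle, FormatError, ReadAlignment, RecruitmentMatrix

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_DNA = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def assembly_kmer_set(sequences: Iterable[str], k: int = 25) -> set[str]:
    if k <= 0:
        raise ValueError("k must be positive")
    kmers: set[str] = set()
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            kmers.add(seq[i:i + k])
    return kmers


def kmer_prefilter(
    reads: Mapping[str, str],
    assembly: AssemblyBundle | Iterable[str],
    k: int = 25,
) -> dict[str, str]:
    """Keep reads sharing at least one k-mer (either strand) with the assembly."""
    if isinstance(assembly, AssemblyBundle):
        seqs: Iterable[str] = (s.sequence for s in assembly.scaffolds.values())
    else:
        seqs = assembly
    kmers = assembly_kmer_set(seqs, k)
    kept = {}
    for rid, seq in reads.items():
        n = len(seq)
        hit = False
        for i in range(n - k + 1):
            km = seq[i:i + k]
            if km in kmers or reverse_complement(km) in kmers:
                hit = True
                break
        if hit:
            kept[rid] = seq
    return kept


# ---------------------------------------------------------------------------
# DUST low-complexity masking

def dust_mask(seq: str, window: int = 64, level: float = 20.0,
              step: Optional[int] = None) -> np.ndarray:
    """Classic windowed DUST triplet masking.

    Windows of ``window`` bp slide by ``step`` (half a window by default,
    plus an end-anchored window). Each window's score is

        10 * sum_t c_t (c_t - 1) / 2  /  n_triplets

    over its overlapping-triplet counts c_t; every base of a window scoring
    above ``level`` is masked. Triplets containing N never match each other,
    so runs of N score as complex. Returns a boolean mask (True = masked).
    """
    bad = set(seq) - _DNA
    if bad:
        raise FormatError(f"non-ACGTN symbols in sequence: {sorted(bad)!r}")
    L = len(seq)
    if L < 3:
        raise ValueError("sequence shorter than one triplet")
    if step is None:
        step = max(window // 2, 1)
    mask = np.zeros(L, dtype=bool)
    starts = list(range(0, max(L - window, 0) + 1, step))
    if starts[-1] + window < L:
        starts.append(max(L - window, 0))
    for s in starts:
        e = min(s + window, L)
        if e - s < 3:
            continue
        counts: dict[str, int] = {}
        sub = seq[s:e]
        for i in range(len(sub) - 2):
            t = sub[i:i + 3]
            if "N" in t:
                continue
            counts[t] = counts.get(t, 0) + 1
        n_trip = len(sub) - 2
        score = 10.0 * sum(c * (c - 1) // 2 for c in counts.values()) / n_trip
        if score > level:
            mask[s:e] = True
    return mask


def dust_high_complexity_fraction(seq: str, window: int = 64, level: float = 20.0) -> float:
    """Fraction of bases NOT masked as low-complexity by DUST."""
    mask = dust_mask(seq, window=window, level=level)
    return float(1.0 - mask.mean())


# ---------------------------------------------------------------------------
# alignment filtering and tallying

def filter_alignments(
    alignments: Iterable[ReadAlignment],
    min_identity: float = 95.0,
    min_complex_fraction: float = 0.30,
    check_complexity: bool = True,
) -> list[ReadAlignment]:
    """Discard alignments below 95% mean identity or with < 30% of
    high-complexity bases in the read."""
    kept = []
    for aln in alignments:
        if aln.percent_identity < min_identity:
            continue
        if check_complexity:
            if aln.read_sequence is None:
                raise ValueError(
                    f"read sequence required for complexity filter ({aln.read_id})"
                )
            if dust_high_complexity_fraction(aln.read_sequence) < min_complex_fraction:
                continue
        kept.append(aln)
    return kept


def tally_counts(
    alignments: Iterable[ReadAlignment],
    gene_lengths: pd.Series,
    sample_sequenced_totals: pd.Series,
    detect_identity: float = 95.0,
) -> RecruitmentMatrix:
    """Count kept alignments per (gene, sample) and set detection flags.

    A gene is detected in a sample when at least one alignment reaches
    ``detect_identity`` over 100% of the read length.
    """
    genes = list(gene_lengths.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    samples = list(sample_sequenced_totals.index)
    sample_pos = {s: i for i, s in enumerate(samples)}
    counts = np.zeros((len(genes), len(samples)), dtype=int)
    detected = np.zeros_like(counts, dtype=bool)
    for aln in alignments:
        gi = gene_pos.get(aln.gene_id)
        if gi is None:
            raise KeyError(f"alignment to unknown gene {aln.gene_id!r}")
        si = sample_pos.get(aln.sample)
        if si is None:
            raise KeyError(f"alignment in unknown sample {aln.sample!r}")
        counts[gi, si] += 1
        if aln.percent_identity >= detect_identity and aln.aligned_length == aln.read_length:
            detected[gi, si] = True
    return RecruitmentMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_lengths=gene_lengths.astype(float),
        sample_sequenced_totals=sample_sequenced_totals,
        detected=pd.DataFrame(detected, index=genes, columns=samples),
    )


def compute_rpkm(matrix: RecruitmentMatrix) -> RecruitmentMatrix:
    """RPKM(g, s) = counts / ((length_g / 1e3) * (mapped_total_s / 1e6)).

    The denominator uses reads mapped to this organism's gene set in the
    sample, not the sample-wide sequenced total.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    lengths = matrix.gene_lengths.to_numpy(dtype=float)
    totals = matrix.sample_mapped_totals.to_numpy(dtype=float)
    if ((totals == 0) & (counts.sum(axis=0) > 0)).any():
        raise ValueError("zero mapped total with nonzero counts")
    with np.errstate(divide="ignore", invalid="ignore"):
        rpkm = counts / ((lengths[:, None] / 1e3) * (totals[None, :] / 1e6))
    rpkm[:, totals == 0] = 0.0
    rpkm[counts == 0] = 0.0
    matrix.rpkm = pd.DataFrame(rpkm, index=matrix.genes, columns=matrix.samples)
    return matrix
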