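"""Inlier/outlier gene screening and relative-abundance estimation.

Relative abundance from short-read recruitment is confounded by genes that
attract cross-mapping reads (conserved orthologs, multi-copy genes, foreign
scaffolds). Assuming per-gene RPKM within a sample is roughly normal, an
iterative Grubbs test flags aberrant genes per sample; the per-sample lists
are merged into the outlier gene set, inliers drive the abundance
estimates, and scaffolds made up entirely of outlier genes are discarded
from the assembly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .types import AssemblyBundle, ReadAlignment, RecruitmentMatrix

log = logging.getLogger(__name__)


@dataclass
class OutlierReport:
    tested: dict[str, bool]
    per_sample: dict[str, set[str]]
    merged: set[str]
    inliers: set[str]
    discarded_scaffolds: set[str] = field(default_factory=set)

    def flag_counts(self) -> pd.Series:
        """Number of samples in which each merged outlier gene was flagged."""
        counts = {g: 0 for g in self.merged}
        for flagged in self.per_sample.values():
            for g in flagged:
                counts[g] += 1
        return pd.Series(counts, dtype=int)


def grubbs_critical_value(n: int, alpha: float, two_sided: bool = True) -> float:
    """Critical value G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)),
    t the upper alpha/(2n) (two-sided) or alpha/n (one-sided) quantile of
    the t-distribution with n-2 degrees of freedom."""
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    denom = 2 * n if two_sided else n
    t = stats.t.ppf(1 - alpha / denom, n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2))


def grubbs_outliers(
    values: np.ndarray,
    alpha: float = 0.05,
    two_sided: bool = True,
    log_transform: bool = False,
) -> list[int]:
    """Iterative Grubbs scan; returns indices of all rejected values.

    At each pass the most extreme studentized deviation G = max|x - mean|/sd
    is compared to the critical value for the current n; rejection removes
    the value and the scan repeats until no rejection. Degenerate inputs
    (n < 3, zero variance) yield no outliers. ``log_transform`` applies
    log1p first, for overdispersed data.
    """
    x = np.asarray(values, dtype=float)
    if log_transform:
        x = np.log1p(x)
    idx = np.arange(len(x))
    if len(x) < 3:
        log.warning("Grubbs scan skipped: only %d values", len(x))
        return []
    removed: list[int] = []
    while len(x) >= 3:
        mean = x.mean()
        sd = x.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(x - mean) if two_sided else x - mean
        i = int(np.argmax(dev))
        G = dev[i] / sd
        if G > grubbs_critical_value(len(x), alpha, two_sided):
            removed.append(int(idx[i]))
            x = np.delete(x, i)
            idx = np.delete(idx, i)
        else:
            break
    return removed


def station_outlier_scan(
    matrix: RecruitmentMatrix,
    min_detected_fraction: float = 0.20,
    alpha: float = 0.05,
    two_sided: bool = True,
    log_transform: bool = False,
) -> tuple[dict[str, bool], dict[str, set[str]]]:
    """Per-sample Grubbs scan on the RPKM of detected genes.

    A sample is tested only when at least ``min_detected_fraction`` of the
    organism's genes are detected there; untested samples contribute no
    outliers.
    """
    if matrix.rpkm is None:
        raise ValueError("RPKM not computed; call compute_rpkm first")
    frac = matrix.detected_fraction()
    tested: dict[str, bool] = {}
    per_sample: dict[str, set[str]] = {}
    for sample in matrix.samples:
        eligible = bool(frac[sample] >= min_detected_fraction)
        tested[sample] = eligible
        if not eligible:
            per_sample[sample] = set()
            continue
        det = matrix.detected[sample]
        genes = matrix.genes[det.to_numpy()]
        vals = matrix.rpkm.loc[genes, sample].to_numpy()
        flagged = grubbs_outliers(vals, alpha=alpha, two_sided=two_sided,
                                  log_transform=log_transform)
        per_sample[sample] = {genes[i] for i in flagged}
    return tested, per_sample


def merge_outliers(
    tested: Mapping[str, bool],
    per_sample: Mapping[str, set[str]],
    all_genes: Iterable[str],
    gene_scaffold: Optional[Mapping[str, str]] = None,
) -> OutlierReport:
    """Union the per-sample outlier lists; a scaffold is discarded when it
    has at least one gene and every one of its genes is a merged outlier."""
    merged: set[str] = set()
    for flagged in per_sample.values():
        merged |= flagged
    all_genes = set(all_genes)
    inliers = all_genes - merged
    discarded: set[str] = set()
    if gene_scaffold is not None:
        by_scaffold: dict[str, list[str]] = {}
        for g in all_genes:
            by_scaffold.setdefault(gene_scaffold[g], []).append(g)
        discarded = {sid for sid, gs in by_scaffold.items()
                     if gs and all(g in merged for g in gs)}
    return OutlierReport(dict(tested), dict(per_sample), merged, inliers, discarded)


# ---------------------------------------------------------------------------
# abundance algebra

def raw_abundance(matrix: RecruitmentMatrix, inliers: Iterable[str]) -> pd.Series:
    """Raw relative abundance per sample: summed inlier-gene mapped reads
    over the total reads sequenced in the sample."""
    totals = matrix.sample_sequenced_totals
    if (totals <= 0).any():
        raise ValueError("non-positive sequenced total")
    inlier_idx = matrix.genes.intersection(set(inliers))
    return matrix.counts.loc[inlier_idx].sum(axis=0) / totals


def correct_abundance(raw: pd.Series, bundle: AssemblyBundle) -> pd.Series:
    """corrected = raw * assembly_size / (mapped_gene_space * completion).

    Corrects for mapping against gene space only (intergenic bases recruit
    nothing) and for genome incompleteness.
    """
    if bundle.mapped_gene_space_bp <= 0:
        raise ValueError("mapped gene space must be positive")
    factor = bundle.assembly_size_bp / (bundle.mapped_gene_space_bp * bundle.completion)
    return raw * factor


def normalize_by_max(corrected: pd.DataFrame) -> pd.DataFrame:
    """Per organism (row), divide by the maximum over samples; organisms
    absent everywhere stay all-zero."""
    maxima = corrected.max(axis=1)
    out = corrected.div(maxima.where(maxima > 0, 1.0), axis=0)
    return out


def regional_means(values: pd.DataFrame, sample_region: Mapping[str, str]) -> pd.DataFrame:
    """Mean relative abundance per (organism, region), zeros included."""
    regions = pd.Series({s: sample_region[s] for s in values.columns})
    return values.T.groupby(regions).mean().T


def station_median_identity(
    alignments: Iterable[ReadAlignment],
    inliers: Iterable[str],
) -> pd.Series:
    """Median read percent identity per sample over inlier-gene alignments."""
    inliers = set(inliers)
    by_sample: dict[str, list[float]] = {}
    for aln in alignments:
        if aln.gene_id in inliers:
            by_sample.setdefault(aln.sample, []).append(aln.percent_identity)
    return pd.Series({s: float(np.median(v)) for s, v in by_sample.items()})


def abundance_table(
    matrices: Mapping[str, RecruitmentMatrix],
    bundles: Mapping[str, AssemblyBundle],
    inliers_by_organism: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Raw and corrected relative abundance per (organism, sample), plus the
    per-organism normalized value."""
    raw_rows = {}
    cor_rows = {}
    for org, matrix in matrices.items():
        raw = raw_abundance(matrix, inliers_by_organism[org])
        raw_rows[org] = raw
        cor_rows[org] = correct_abundance(raw, bundles[org])
    raw_df = pd.DataFrame(raw_rows).T
    cor_df = pd.DataFrame(cor_rows).T
    norm_df = normalize_by_max(cor_df)
    long = pd.concat(
        {"raw": raw_df.stack(), "corrected": cor_df.stack(), "normalized": norm_df.stack()},
        axis=1,
    )
    long.index.names = ["organism", "sample"]
    return long.reset_index()
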