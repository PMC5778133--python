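"""Pfam-repertoire comparison between genomes.

Pfam domains are counted once per protein, rarefied to a fixed depth
(1400 domains, ten independent draws per genome — 1414 being the smallest
repertoire among the compared genomes) to level out unequal genome
completeness, compared with Bray-Curtis dissimilarity and embedded by
non-metric multidimensional scaling. Bray-Curtis is used rather than a
correlation or Euclidean distance because it ignores double absences, so
adding a genome or a domain family absent from two repertoires cannot make
them look more similar.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis, pdist, squareform
from sklearn.manifold import MDS


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # index (genome, replicate), columns dim1..dimk
    stress: float  # Kruskal stress-1 of the best restart

    def genome_means(self) -> pd.DataFrame:
        return self.coordinates.groupby(level="genome").mean()


def count_pfam_occurrences(
    annotations: Iterable[tuple[str, str, str]],
) -> pd.DataFrame:
    """Genome x Pfam count matrix from (protein_id, genome_id, pfam_id) rows.

    Multiple occurrences of the same Pfam in one protein count as one; the
    count of a Pfam in a genome is the number of distinct proteins carrying
    it.
    """
    seen: set[tuple[str, str, str]] = set()
    counts: dict[str, dict[str, int]] = {}
    for protein, genome, pfam in annotations:
        key = (protein, genome, pfam)
        if key in seen:
            continue
        seen.add(key)
        counts.setdefault(genome, {}).setdefault(pfam, 0)
        counts[genome][pfam] += 1
    return pd.DataFrame(counts).T.fillna(0).astype(int).sort_index()


def rarefy_counts(
    table: pd.DataFrame,
    depth: int = 1400,
    replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Rarefy each genome's domain multiset to ``depth`` occurrences,
    ``replicates`` times, by sampling without replacement.

    Returns a table indexed by (genome, replicate); every row sums exactly
    to ``depth``.
    """
    rng = np.random.default_rng(seed)
    totals = table.sum(axis=1)
    short = totals[totals < depth]
    if len(short):
        raise ValueError(
            f"genome(s) with fewer than {depth} domains: "
            + ", ".join(f"{g} ({int(t)})" for g, t in short.items())
        )
    rows = {}
    for genome, row in table.iterrows():
        colors = row.to_numpy(dtype=np.int64)
        for rep in range(replicates):
            rows[(genome, rep)] = rng.multivariate_hypergeometric(colors, depth)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=table.columns)
    out.index = pd.MultiIndex.from_tuples(out.index, names=["genome", "replicate"])
    return out


def bray_curtis(a: Sequence[float], b: Sequence[float]) -> float:
    """BC(a, b) = sum|a_i - b_i| / sum(a_i + b_i), in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    if a.sum() + b.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(braycurtis(a, b))


def bray_curtis_matrix(table: pd.DataFrame) -> pd.DataFrame:
    D = squareform(pdist(table.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(D, index=table.index, columns=table.index)


def nmds_embed(
    distances: pd.DataFrame,
    k: int = 2,
    seed: int = 0,
    restarts: int = 20,
    max_iter: int = 1000,
    eps: float = 1e-14,
) -> OrdinationResult:
    """Non-metric MDS (Kruskal stress-1, monotone regression), best of
    ``restarts`` random initializations; coordinates centered at the origin."""
    D = distances.to_numpy(dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(D), 0):
        raise ValueError("dissimilarity matrix must have zero diagonal")
    mds = MDS(
        n_components=k,
        metric="precomputed",
        metric_mds=False,
        init="random",
        n_init=restarts,
        max_iter=max_iter,
        eps=eps,
        random_state=seed,
        normalized_stress=True,
    )
    coords = mds.fit_transform(D)
    coords = coords - coords.mean(axis=0)
    df = pd.DataFrame(coords, index=distances.index,
                      columns=[f"dim{i + 1}" for i in range(k)])
    return OrdinationResult(coordinates=df, stress=float(mds.stress_))


def group_mean_positions(
    result: OrdinationResult,
    group_of_genome: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Per-genome and per-group mean coordinates plus a separation summary.

    The summary reports the mean pairwise distance between replicate points
    within a group and between groups; within < between indicates the
    ordination separates the groups.
    """
    genome_means = result.genome_means()
    groups = pd.Series({g: group_of_genome[g] for g in genome_means.index})
    group_means = genome_means.groupby(groups).mean()

    pts = result.coordinates.to_numpy()
    labels = np.array([group_of_genome[g] for g, _ in result.coordinates.index])
    D = squareform(pdist(pts))
    same = labels[:, None] == labels[None, :]
    triu = np.triu(np.ones_like(same, dtype=bool), 1)
    within = float(D[same & triu].mean()) if (same & triu).any() else float("nan")
    between = float(D[~same & triu].mean()) if (~same & triu).any() else float("nan")
    stats = {"mean_within_group_distance": within,
             "mean_between_group_distance": between}
    return genome_means, group_means, stats
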