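"""Environmental association tests for lineage distributions.

For each physico-chemical parameter, a Kruskal-Wallis test asks whether the
parameter's values at the stations where each lineage occurs differ among
lineages, followed by post-hoc pairwise comparisons. Lineages detected at
too few stations are excluded. Separately, a lineage's samples can be split
by median read identity to the reference (near-reference vs divergent
genotypes) and the two groups' temperatures compared with a two-sided
rank-sum test.
"""
from __future__ import annotations

import itertools
import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import StationMeta

log = logging.getLogger(__name__)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Rank-based H with tie correction; p from chi-square with k-1 df."""
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def posthoc_pairwise(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    method: str = "tukey_ranks",
) -> pd.DataFrame:
    """Pairwise p-values after Kruskal-Wallis.

    ``tukey_ranks`` runs Tukey's HSD on the pooled rank-transformed values
    (following the original analysis despite its heterodoxy after a rank
    test); ``wilcoxon_holm`` runs pairwise rank-sum tests with Holm
    correction.
    """
    k = len(groups)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    table = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    if method == "tukey_ranks":
        pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
        ranks = stats.rankdata(pooled)
        out, start = [], 0
        for g in groups:
            out.append(ranks[start:start + len(g)])
            start += len(g)
        res = stats.tukey_hsd(*out)
        for i, j in itertools.combinations(range(k), 2):
            table.iloc[i, j] = table.iloc[j, i] = res.pvalue[i, j]
    elif method == "wilcoxon_holm":
        pairs = list(itertools.combinations(range(k), 2))
        raw = [wilcoxon_ranksum(groups[i], groups[j])[1] for i, j in pairs]
        order = np.argsort(raw)
        m = len(raw)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * raw[idx])
            adj[idx] = min(1.0, running)
        for (i, j), p in zip(pairs, adj):
            table.iloc[i, j] = table.iloc[j, i] = p
    else:
        raise ValueError(f"unknown post-hoc method {method!r}")
    return table


def wilcoxon_ranksum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact enumeration for small samples
    (min(n, m) <= 8, no ties), normal approximation with tie correction
    otherwise. U reported under the smaller-U convention."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u_x = float(res.statistic)
    u_min = min(u_x, len(x) * len(y) - u_x)
    return u_min, float(res.pvalue)


def eligible_samples(
    detected_fraction: pd.Series,
    min_detected_fraction: float = 0.20,
) -> list[str]:
    """Samples where at least 20% of the organism's genes were detected."""
    return list(detected_fraction.index[detected_fraction >= min_detected_fraction])


def parameter_association(
    stations: Sequence[StationMeta],
    eligible_by_lineage: Mapping[str, Sequence[str]],
    parameters: Optional[Sequence[str]] = None,
    min_eligible: int = 5,
) -> pd.DataFrame:
    """Kruskal-Wallis per parameter across lineages' eligible stations.

    Lineages with fewer than ``min_eligible`` eligible samples are excluded
    (the original analysis dropped one lineage present at too few
    stations). Returns a table (parameter, H, p, n_lineages) sorted by p.
    """
    meta = {s.sample: s for s in stations}
    if parameters is None:
        env_keys = sorted({k for s in stations for k in s.env})
        parameters = ["temperature_C"] + env_keys
    usable = {
        lin: [s for s in samples if s in meta]
        for lin, samples in eligible_by_lineage.items()
    }
    kept = {lin: ss for lin, ss in usable.items() if len(ss) >= min_eligible}
    dropped = set(usable) - set(kept)
    if dropped:
        log.info("lineages excluded (fewer than %d eligible stations): %s",
                 min_eligible, sorted(dropped))
    if len(kept) < 2:
        raise ValueError("fewer than two lineages with enough eligible stations")
    rows = []
    for param in parameters:
        groups = []
        for lin, samples in kept.items():
            vals = [
                meta[s].temperature_C if param == "temperature_C" else meta[s].env[param]
                for s in samples
            ]
            groups.append(vals)
        H, p = kruskal_wallis(groups)
        rows.append({"parameter": param, "H": H, "p": p, "n_lineages": len(kept)})
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)


def split_by_similarity(
    median_identity: pd.Series,
    values: pd.Series,
    threshold: float = 95.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split samples into near-reference (median identity >= threshold) and
    divergent groups and return the two groups' parameter values (e.g.,
    temperatures) for a rank-sum comparison."""
    common = median_identity.index.intersection(values.index)
    ident = median_identity[common]
    near = values[common[ident >= threshold]].to_numpy(dtype=float)
    far = values[common[ident < threshold]].to_numpy(dtype=float)
    if len(near) == 0 or len(far) == 0:
        log.warning("degenerate genotype split: all samples on one side of %.1f%%",
                    threshold)
    return near, far
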