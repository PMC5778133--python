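"""Alien-index computation and horizontal-gene-transfer candidate screening.

The alien index (AI) of a gene contrasts its best eukaryotic and best
prokaryotic homology e-values:

    AI = ln(E_euk + 1e-200) - ln(E_prok + 1e-200)

so purely eukaryotic genes are negative and prokaryote-like genes positive.
Genes with AI > 45 located internally on scaffolds of more than five genes
are putative HGTs; a phylogenetic tree of each candidate is then inspected —
if the gene clusters inside a supported clade (bootstrap > 50) containing
other eukaryotes the candidate is a false positive of the AI screen.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional

import dendropy

from .types import GeneModel, HitRecord

PSEUDOCOUNT = 1e-200
AI_THRESHOLD = 45.0
#: Superkingdoms counted as "non-eukaryotic" by default; viruses are excluded.
PROKARYOTE_DOMAINS = frozenset({"Bacteria", "Archaea"})


@dataclass
class AiRecord:
    gene_id: str
    best_euk_evalue: float
    best_prok_evalue: float
    ai: Optional[float]  # None when the gene had no usable hits


@dataclass
class HgtCall:
    gene_id: str
    ai: float
    scaffold_id: str
    scaffold_gene_count: int
    is_internal: bool
    status: str  # candidate | validated | rejected_false_positive


def best_domain_evalues(
    hits: Iterable[HitRecord],
    include_viruses: bool = False,
) -> tuple[float, float]:
    """Best (minimum) e-value per side; an absent side substitutes 1.0.

    1.0 is the BLAST "no signal" limit, so one-sided prokaryotic genes come
    out strongly positive and one-sided eukaryotic genes strongly negative.
    """
    prok = PROKARYOTE_DOMAINS | ({"Viruses"} if include_viruses else set())
    best_euk = math.inf
    best_prok = math.inf
    for h in hits:
        if h.subject_domain == "Eukaryota":
            best_euk = min(best_euk, h.evalue)
        elif h.subject_domain in prok:
            best_prok = min(best_prok, h.evalue)
    return (
        1.0 if math.isinf(best_euk) else best_euk,
        1.0 if math.isinf(best_prok) else best_prok,
    )


def alien_index(best_euk: float, best_prok: float) -> float:
    """AI = ln(best_euk + 1e-200) - ln(best_prok + 1e-200)."""
    if best_euk < 0 or best_prok < 0:
        raise ValueError("e-values must be non-negative")
    return math.log(best_euk + PSEUDOCOUNT) - math.log(best_prok + PSEUDOCOUNT)


def ai_table(
    hits_by_gene: Mapping[str, list[HitRecord]],
    all_genes: Iterable[str],
    include_viruses: bool = False,
) -> dict[str, AiRecord]:
    """AI per gene; undefined (None) when the gene has no euk or prok hits."""
    out = {}
    for gid in all_genes:
        hits = hits_by_gene.get(gid, [])
        e, p = best_domain_evalues(hits, include_viruses=include_viruses)
        defined = any(
            h.subject_domain == "Eukaryota" or h.subject_domain in PROKARYOTE_DOMAINS
            or (include_viruses and h.subject_domain == "Viruses")
            for h in hits
        )
        out[gid] = AiRecord(gid, e, p, alien_index(e, p) if defined else None)
    return out


def call_hgt_candidates(
    ai_records: Mapping[str, AiRecord],
    genes: Iterable[GeneModel],
    min_scaffold_genes: int = 6,
    threshold: float = AI_THRESHOLD,
) -> list[HgtCall]:
    """Putative HGTs: AI > 45, internal on a scaffold with > 5 genes.

    "Internal" means not the first or last gene in coordinate order on its
    scaffold — a guard against chimeric scaffold ends.
    """
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold_id, []).append(g)
    calls = []
    for sid, scaffold_genes in by_scaffold.items():
        scaffold_genes.sort(key=lambda g: g.start)
        n = len(scaffold_genes)
        for pos, g in enumerate(scaffold_genes):
            rec = ai_records.get(g.id)
            if rec is None or rec.ai is None:
                continue
            internal = 0 < pos < n - 1
            if rec.ai > threshold and internal and n >= min_scaffold_genes:
                calls.append(HgtCall(g.id, rec.ai, sid, n, internal, "candidate"))
    return calls


def _node_support(node: dendropy.Node) -> Optional[float]:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def validate_hgt_tree(
    tree: dendropy.Tree,
    query_leaf: str,
    leaf_domains: Mapping[str, str] | Callable[[str], str],
    support_threshold: float = 50.0,
) -> str:
    """Tree-based validation of one AI candidate.

    Walk from the query leaf toward the root; at the first ancestor whose
    bootstrap support exceeds ``support_threshold``, inspect the clade's
    other leaves: any eukaryote there means the gene clusters with
    eukaryotes ("rejected_false_positive"), none means the transfer
    hypothesis is supported ("validated"). With no supported ancestor at all
    the tree is "inconclusive" (summaries treat that as rejected).
    """
    domain_of = leaf_domains.__getitem__ if isinstance(leaf_domains, Mapping) else leaf_domains
    target = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == query_leaf:
            target = leaf
            break
    if target is None:
        raise KeyError(f"query leaf {query_leaf!r} not in tree")
    node = target.parent_node
    while node is not None:
        support = _node_support(node)
        if support is not None and support > support_threshold:
            for leaf in node.leaf_iter():
                if leaf is target:
                    continue
                if domain_of(leaf.taxon.label) == "Eukaryota":
                    return "rejected_false_positive"
            return "validated"
        node = node.parent_node
    return "inconclusive"


def validate_candidates(
    calls: Iterable[HgtCall],
    trees: Mapping[str, dendropy.Tree],
    leaf_domains: Mapping[str, str] | Callable[[str], str],
    support_threshold: float = 50.0,
) -> list[HgtCall]:
    """Apply tree validation to every candidate that has a tree.

    Inconclusive trees reject the candidate, as do trees where the gene
    clusters with eukaryotes; candidates without a tree stay candidates.
    """
    out = []
    for call in calls:
        tree = trees.get(call.gene_id)
        if tree is None:
            out.append(call)
            continue
        decision = validate_hgt_tree(tree, call.gene_id, leaf_domains, support_threshold)
        status = "validated" if decision == "validated" else "rejected_false_positive"
        out.append(HgtCall(call.gene_id, call.ai, call.scaffold_id,
                           call.scaffold_gene_count, call.is_internal, status))
    return out
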