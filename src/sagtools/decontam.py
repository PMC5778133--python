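"""Contamination screens for single-cell amplified genome assemblies.

Four screens are composed: cross-genera scaffold sharing (fragment matches
between distantly related taxa), organelle similarity, alien-index bacterial
scaffolds, and the eukaryotic-signature rule. Each screen returns a set of
scaffold ids; composition removes the union and reports each scaffold under
the first screen that caught it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .types import AssemblyBundle, GeneModel, HitRecord, Scaffold

log = logging.getLogger(__name__)

#: Report categories, in precedence order (removal itself is order-independent).
CATEGORIES = ("cross_taxon", "organelle", "bacterial_AI", "non_eukaryotic_signature")


@dataclass
class Fragment:
    """A window cut from a scaffold, 0-based half-open on the parent."""

    parent_scaffold: str
    start: int
    end: int
    sequence: str

    @property
    def id(self) -> str:
        return f"{self.parent_scaffold}|{self.start}-{self.end}"


@dataclass
class DecontamReport:
    verdicts: pd.DataFrame  # scaffold_id, verdict, length_bp, evidence
    removed_bp: dict[str, int]
    kept_bp: int

    @property
    def removed_total_bp(self) -> int:
        return sum(self.removed_bp.values())


def fragment_scaffold(scaffold: Scaffold, window: int = 1000, step: int = 500) -> list[Fragment]:
    """Cut a scaffold into overlapping windows for cross-genera screening.

    Windows of ``window`` bp every ``step`` bp; scaffolds shorter than the
    window yield a single whole-scaffold fragment; when the last regular
    window does not reach the scaffold end, an end-anchored window of full
    length is appended so every base is covered.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    L = scaffold.length_bp
    if L == 0:
        raise ValueError(f"scaffold {scaffold.id} has empty sequence")
    if L < window:
        return [Fragment(scaffold.id, 0, L, scaffold.sequence)]
    frags = []
    start = 0
    while start + window <= L:
        frags.append(Fragment(scaffold.id, start, start + window,
                              scaffold.sequence[start:start + window]))
        start += step
    if frags[-1].end < L:
        frags.append(Fragment(scaffold.id, L - window, L,
                              scaffold.sequence[L - window:L]))
    return frags


def fragment_parent(fragment_id: str) -> str:
    """Recover the parent scaffold id from a fragment id."""
    return fragment_id.rsplit("|", 1)[0]


def flag_cross_taxon(
    fragment_hits: Iterable[HitRecord],
    taxon_of_scaffold: Mapping[str, str],
    min_identity: float = 95.0,
    min_frag_coverage: float = 0.8,
) -> set[str]:
    """Flag scaffolds with a kept fragment match against a distant taxon.

    A match is kept when identity >= ``min_identity`` and the aligned span
    covers strictly more than ``min_frag_coverage`` of the fragment. The
    parent scaffold is flagged as soon as one kept match lands on an assembly
    from a different taxon group (chrysophytes vs MAST-3 vs MAST-4 level;
    hits within the same group are the expected self-similarity of sibling
    SAGs and never flag).
    """
    flagged: set[str] = set()
    for hit in fragment_hits:
        parent = fragment_parent(hit.query_id)
        if parent not in taxon_of_scaffold:
            raise KeyError(f"unresolvable fragment parent {parent!r}")
        subject_scaffold = fragment_parent(hit.subject_id)
        if subject_scaffold not in taxon_of_scaffold:
            raise KeyError(f"unresolvable subject {hit.subject_id!r}")
        if hit.percent_identity >= min_identity and hit.query_coverage > min_frag_coverage:
            if taxon_of_scaffold[parent] != taxon_of_scaffold[subject_scaffold]:
                flagged.add(parent)
    return flagged


def flag_organelle(
    nt_hits: Iterable[HitRecord],
    protein_hits: Iterable[HitRecord],
    genes: Iterable[GeneModel],
    min_bit_score: float = 1000.0,
    min_proteins: int = 3,
) -> set[str]:
    """Flag organelle scaffolds.

    A scaffold is organellar when a nucleotide hit against a sequenced
    organelle genome scores above ``min_bit_score``, or when at least
    ``min_proteins`` distinct genes on it hit the curated chloroplast (CHL)
    or mitochondrial (MTH) protein clusters; the two lists are unioned.
    """
    gene_scaffold = {g.id: g.scaffold_id for g in genes}
    by_score = {h.query_id for h in nt_hits if h.bit_score > min_bit_score}
    organelle_genes: dict[str, set[str]] = {}
    for h in protein_hits:
        if h.subject_class in ("CHL", "MTH") and h.query_id in gene_scaffold:
            organelle_genes.setdefault(gene_scaffold[h.query_id], set()).add(h.query_id)
    by_proteins = {sid for sid, gs in organelle_genes.items() if len(gs) >= min_proteins}
    return by_score | by_proteins


def assign_gene_domain(hits_by_gene: Mapping[str, list[HitRecord]],
                       all_genes: Iterable[str]) -> dict[str, str]:
    """Taxonomically assign each gene to its best hit's superkingdom.

    Genes without hits get "no_hit"; domains other than Eukaryota collapse
    to "other" for the eukaryotic-signature rule.
    """
    out: dict[str, str] = {}
    for gid in all_genes:
        hits = hits_by_gene.get(gid, [])
        if not hits:
            out[gid] = "no_hit"
            continue
        best = min(hits, key=lambda h: (h.evalue, -h.bit_score))
        out[gid] = "Eukaryota" if best.subject_domain == "Eukaryota" else "other"
    return out


def euk_signature_keep(
    gene_assignments: Mapping[str, str],
    genes_by_scaffold: Mapping[str, list[GeneModel]],
) -> set[str]:
    """Return the scaffolds KEPT by the eukaryotic-signature rule.

    A scaffold keeps its place when at least one of its genes is assigned to
    a eukaryote, or when none of its genes had any database similarity at
    all; scaffolds whose genes all hit non-eukaryotes are discarded. A
    scaffold with no genes is kept (the rule is vacuous) with a warning.
    """
    keep: set[str] = set()
    for sid, genes in genes_by_scaffold.items():
        if not genes:
            log.warning("scaffold %s has no genes; eukaryotic-signature rule vacuous", sid)
            keep.add(sid)
            continue
        assignments = [gene_assignments[g.id] for g in genes]
        if "Eukaryota" in assignments or all(a == "no_hit" for a in assignments):
            keep.add(sid)
    return keep


def flag_bacterial_scaffolds(
    ai_per_gene: Mapping[str, Optional[float]],
    genes_by_scaffold: Mapping[str, list[GeneModel]],
    threshold: float = 45.0,
) -> set[str]:
    """Flag scaffolds whose genes have alien index > 45 exclusively.

    Genes with undefined AI (no hits) neither qualify nor disqualify; a
    scaffold whose genes are all undefined is not flagged.
    """
    flagged = set()
    for sid, genes in genes_by_scaffold.items():
        ais = [ai_per_gene.get(g.id) for g in genes]
        defined = [a for a in ais if a is not None]
        if defined and all(a > threshold for a in defined):
            flagged.add(sid)
    return flagged


def apply_decontamination(
    bundle: AssemblyBundle,
    flags: Mapping[str, set[str]],
) -> tuple[AssemblyBundle, DecontamReport]:
    """Remove every flagged scaffold and report each under one category.

    ``flags`` maps category name (see CATEGORIES) to its flag set. A
    scaffold caught by several screens is counted once, under the earliest
    category in precedence order; removal itself is the plain set union.
    """
    unknown = set(flags) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown decontamination categories {sorted(unknown)}")
    rows = []
    removed_bp = {c: 0 for c in CATEGORIES}
    removed: set[str] = set()
    for sid, scaf in bundle.scaffolds.items():
        verdict = "kept"
        for category in CATEGORIES:
            if sid in flags.get(category, set()):
                verdict = category
                break
        evidence = ",".join(c for c in CATEGORIES if sid in flags.get(c, set()))
        rows.append({"scaffold_id": sid, "verdict": verdict,
                     "length_bp": scaf.length_bp, "evidence": evidence})
        if verdict != "kept":
            removed.add(sid)
            removed_bp[verdict] += scaf.length_bp
    cleaned = bundle.subset(set(bundle.scaffolds) - removed)
    report = DecontamReport(
        verdicts=pd.DataFrame(rows),
        removed_bp=removed_bp,
        kept_bp=cleaned.assembly_size_bp,
    )
    assert report.kept_bp + report.removed_total_bp == bundle.assembly_size_bp
    return cleaned, report
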