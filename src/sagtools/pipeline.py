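"""End-to-end composition of the pipeline stages.

These functions wire the per-module operations together the way the CLI
and the worked examples use them: screen assemblies, call HGTs, build
RPKM matrices, run the outlier screen and abundance estimation, ordinate
Pfam repertoires, and test environmental associations.
"""
from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

from . import biogeography, decontam, envstats, hgt, ordination
from .recruitment import compute_rpkm
from .types import AssemblyBundle, HitRecord, RecruitmentMatrix, StationMeta


def hits_by_query(hits: Sequence[HitRecord]) -> dict[str, list[HitRecord]]:
    out: dict[str, list[HitRecord]] = {}
    for h in hits:
        out.setdefault(h.query_id, []).append(h)
    return out


def decontaminate(
    bundles: Mapping[str, AssemblyBundle],
    gene_hits: Sequence[HitRecord],
    fragment_hits: Sequence[HitRecord],
    organelle_nt_hits: Sequence[HitRecord],
    organelle_protein_hits: Sequence[HitRecord],
) -> tuple[dict[str, AssemblyBundle], dict[str, decontam.DecontamReport]]:
    """Run all four contamination screens on every assembly."""
    taxon_of_scaffold = {
        sid: scaf.taxon_group
        for b in bundles.values() for sid, scaf in b.scaffolds.items()
    }
    by_gene = hits_by_query(gene_hits)
    cross_flags = decontam.flag_cross_taxon(fragment_hits, taxon_of_scaffold)

    cleaned: dict[str, AssemblyBundle] = {}
    reports: dict[str, decontam.DecontamReport] = {}
    for org, bundle in bundles.items():
        genes_by_scaffold = bundle.genes_by_scaffold()
        gene_ids = [g.id for g in bundle.genes]
        organelle_flags = decontam.flag_organelle(
            organelle_nt_hits, organelle_protein_hits, bundle.genes
        )
        assignments = decontam.assign_gene_domain(by_gene, gene_ids)
        keep = decontam.euk_signature_keep(assignments, genes_by_scaffold)
        signature_flags = set(bundle.scaffolds) - keep
        ai = {gid: rec.ai for gid, rec in hgt.ai_table(by_gene, gene_ids).items()}
        bacterial_flags = decontam.flag_bacterial_scaffolds(ai, genes_by_scaffold)
        flags = {
            "cross_taxon": cross_flags & set(bundle.scaffolds),
            "organelle": organelle_flags & set(bundle.scaffolds),
            "bacterial_AI": bacterial_flags,
            "non_eukaryotic_signature": signature_flags,
        }
        cleaned[org], reports[org] = decontam.apply_decontamination(bundle, flags)
    return cleaned, reports


def call_hgt(
    bundles: Mapping[str, AssemblyBundle],
    gene_hits: Sequence[HitRecord],
) -> dict[str, list[hgt.HgtCall]]:
    by_gene = hits_by_query(gene_hits)
    calls = {}
    for org, bundle in bundles.items():
        gene_ids = [g.id for g in bundle.genes]
        records = hgt.ai_table(by_gene, gene_ids)
        calls[org] = hgt.call_hgt_candidates(records, bundle.genes)
    return calls


def outlier_screen(
    matrix: RecruitmentMatrix,
    bundle: Optional[AssemblyBundle] = None,
    alpha: float = 0.05,
    min_detected_fraction: float = 0.20,
) -> biogeography.OutlierReport:
    """RPKM, per-station Grubbs scans, merged outlier list and scaffold
    discard for one organism."""
    if matrix.rpkm is None:
        compute_rpkm(matrix)
    tested, per_sample = biogeography.station_outlier_scan(
        matrix, min_detected_fraction=min_detected_fraction, alpha=alpha
    )
    gene_scaffold = ({g.id: g.scaffold_id for g in bundle.genes}
                     if bundle is not None else None)
    return biogeography.merge_outliers(tested, per_sample, matrix.genes, gene_scaffold)


def abundance_pipeline(
    matrices: Mapping[str, RecruitmentMatrix],
    bundles: Mapping[str, AssemblyBundle],
    stations: Sequence[StationMeta],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, biogeography.OutlierReport]]:
    """Outlier screen + abundance table + regional means for all organisms."""
    reports = {org: outlier_screen(m, bundles.get(org), alpha=alpha)
               for org, m in matrices.items()}
    inliers = {org: rep.inliers for org, rep in reports.items()}
    table = biogeography.abundance_table(matrices, bundles, inliers)
    sample_region = {s.sample: s.region for s in stations}
    corrected = table.pivot(index="organism", columns="sample", values="corrected")
    regions = biogeography.regional_means(corrected, sample_region)
    return table, regions, reports


def pfam_ordination(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    depth: int = 1400,
    replicates: int = 10,
    seed: int = 0,
    restarts: int = 20,
) -> tuple[ordination.OrdinationResult, pd.DataFrame, dict[str, float]]:
    """Rarefy, Bray-Curtis, NMDS, group positions."""
    rarefied = ordination.rarefy_counts(counts, depth=depth,
                                       replicates=replicates, seed=seed)
    D = ordination.bray_curtis_matrix(rarefied)
    result = ordination.nmds_embed(D, k=2, seed=seed, restarts=restarts)
    _, group_means, stats = ordination.group_mean_positions(result, groups)
    return result, group_means, stats


def environmental_tests(
    matrices: Mapping[str, RecruitmentMatrix],
    stations: Sequence[StationMeta],
    min_detected_fraction: float = 0.20,
    min_eligible: int = 5,
) -> pd.DataFrame:
    """Kruskal-Wallis association of each parameter with lineage presence."""
    eligible = {
        org: envstats.eligible_samples(m.detected_fraction(), min_detected_fraction)
        for org, m in matrices.items()
    }
    return envstats.parameter_association(stations, eligible,
                                          min_eligible=min_eligible)
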