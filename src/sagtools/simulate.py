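"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the statistical structure of a multi-SAG dataset of
uncultured marine protists: several assemblies from three taxon groups that
share verbatim contaminant scaffolds, carry organelle and bacterial
scaffolds and the occasional horizontally transferred gene; station x gene
read counts shaped by Gaussian temperature niches, with multi-copy /
cross-mapping genes inflated across many stations; and group-structured
Pfam repertoires. Every generator is a pure function of (config, seed) and
records what it planted in a truth ledger, so downstream screens can be
scored against known labels. Amplification (MDA) coverage bias and
read-level sequencing errors are deliberately not modelled.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .decontam import fragment_scaffold
from .types import (
    AssemblyBundle,
    GeneModel,
    HitRecord,
    RecruitmentMatrix,
    Scaffold,
    StationMeta,
    REGIONS,
)

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    seed: int = 0

    # assemblies
    taxon_groups: tuple[str, ...] = ("chrysophytes", "MAST-3", "MAST-4")
    n_organisms: int = 3
    scaffolds_per_organism: int = 40
    scaffold_length_range: tuple[int, int] = (3000, 12000)
    gene_length_mean: float = 1000.0
    gene_length_sd: float = 200.0
    intergenic_mean: float = 300.0
    completion_range: tuple[float, float] = (0.3, 0.9)

    # planted contamination (dataset-wide counts)
    n_cross_taxon: int = 10
    n_organelle: int = 5
    n_bacterial: int = 5
    n_hgt_genes: int = 10
    cross_taxon_mutation_rate: float = 0.0

    # homology-hit simulation
    no_hit_fraction: float = 0.10

    # recruitment
    n_stations: int = 30
    depth_layers: tuple[str, ...] = ("SRF", "DCM")
    temperature_range: tuple[float, float] = (-2.0, 30.0)
    niche_sigma: float = 4.0
    peak_reads_per_kb: float = 150.0
    station_total_reads: int = 190_000_000
    n_outlier_genes: int = 20
    outlier_inflation: float = 8.0
    outlier_station_breadth: float = 0.6
    overdispersion: float = 0.0  # gamma-mixing CV^2; 0 keeps pure Poisson

    # pfam repertoires
    pfam_n_groups: int = 3
    pfam_genomes_per_group: int = 10
    pfam_vocabulary: int = 300
    pfam_domains_per_genome: int = 1414
    pfam_group_weight: float = 0.75  # profile mass on the group's own block

    def __post_init__(self) -> None:
        if self.niche_sigma <= 0:
            raise ConfigError("niche sigma must be positive")
        if self.outlier_inflation <= 1:
            raise ConfigError("outlier inflation must exceed 1")
        if min(self.n_cross_taxon, self.n_organelle, self.n_bacterial,
               self.n_hgt_genes, self.n_outlier_genes) < 0:
            raise ConfigError("planted counts must be non-negative")


@dataclass
class TruthLedger:
    """Planted ground truth: one entry per generated entity."""

    scaffold_class: dict[str, str] = field(default_factory=dict)  # clean/cross_taxon/organelle/bacterial
    gene_class: dict[str, str] = field(default_factory=dict)      # native/hgt/outlier_multicopy
    organism_of_scaffold: dict[str, str] = field(default_factory=dict)
    cross_taxon_source: dict[str, str] = field(default_factory=dict)
    true_abundance: Optional[pd.DataFrame] = None                 # organism x sample
    genome_group: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"entity": sid, "kind": "scaffold", "truth": cls,
             "organism": self.organism_of_scaffold.get(sid, "")}
            for sid, cls in self.scaffold_class.items()
        ] + [
            {"entity": gid, "kind": "gene", "truth": cls, "organism": ""}
            for gid, cls in self.gene_class.items()
        ]
        return pd.DataFrame(rows)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    arr[hit] = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
    return "".join(arr)


def _tile_genes(rng: np.random.Generator, config: SimulationConfig,
                scaffold_id: str, length: int, prefix: str,
                min_genes: int = 0) -> list[GeneModel]:
    genes = []
    pos = int(rng.integers(0, 200))
    i = 0
    while True:
        glen = int(np.clip(rng.normal(config.gene_length_mean, config.gene_length_sd),
                           200, None))
        if pos + glen > length:
            break
        genes.append(GeneModel(id=f"{prefix}_g{i}", scaffold_id=scaffold_id,
                               start=pos, end=pos + glen,
                               strand="+" if rng.random() < 0.5 else "-"))
        pos += glen + int(rng.exponential(config.intergenic_mean))
        i += 1
    # very short scaffolds must still carry the minimum gene count
    while len(genes) < min_genes:
        start = len(genes) * 10
        genes.append(GeneModel(id=f"{prefix}_g{len(genes)}", scaffold_id=scaffold_id,
                               start=start, end=min(start + 200, length)))
    return genes


def simulate_assembly(config: SimulationConfig) -> tuple[dict[str, AssemblyBundle], TruthLedger]:
    """Generate per-organism assemblies with planted contaminant scaffolds.

    Cross-taxon contaminants are verbatim copies (optionally mutated at
    ``cross_taxon_mutation_rate``) of a clean scaffold from an organism in a
    different taxon group; organelle and bacterial scaffolds are fresh
    sequence marked in the ledger; HGT genes are internal genes on clean
    scaffolds with at least six genes.
    """
    rng = np.random.default_rng(config.seed)
    ledger = TruthLedger()
    n_planted = config.n_cross_taxon + config.n_organelle + config.n_bacterial
    if config.n_cross_taxon > 0 and len(set(config.taxon_groups)) < 2:
        raise ConfigError("cross-taxon contamination needs at least two taxon groups")

    organisms = []
    for i in range(config.n_organisms):
        group = config.taxon_groups[i % len(config.taxon_groups)]
        organisms.append((f"SAG{i + 1:02d}", group))

    bundles: dict[str, AssemblyBundle] = {}
    scaffold_pool: dict[str, list[str]] = {}  # organism -> clean scaffold ids
    lo, hi = config.scaffold_length_range
    for org, group in organisms:
        scaffolds: dict[str, Scaffold] = {}
        genes: list[GeneModel] = []
        for j in range(config.scaffolds_per_organism):
            sid = f"{org}_s{j:03d}"
            length = int(rng.integers(lo, hi + 1))
            scaffolds[sid] = Scaffold(id=sid, sequence=_random_dna(rng, length),
                                      taxon_group=group)
            genes.extend(_tile_genes(rng, config, sid, length, prefix=sid))
            ledger.scaffold_class[sid] = "clean"
            ledger.organism_of_scaffold[sid] = org
        completion = float(rng.uniform(*config.completion_range))
        bundles[org] = AssemblyBundle(organism_id=org, scaffolds=scaffolds,
                                      genes=genes, completion=completion)
        scaffold_pool[org] = list(scaffolds)
        ledger.genome_group[org] = group
        for g in genes:
            ledger.gene_class[g.id] = "native"

    if n_planted > config.n_organisms * config.scaffolds_per_organism:
        raise ConfigError("more planted contaminant scaffolds than scaffolds")

    org_ids = [o for o, _ in organisms]
    group_of = dict(organisms)

    def _add_scaffold(org: str, scaf: Scaffold, genes: list[GeneModel], cls: str) -> None:
        b = bundles[org]
        b.scaffolds[scaf.id] = scaf
        b.genes.extend(genes)
        b.genes.sort(key=lambda g: (g.scaffold_id, g.start))
        b.mapped_gene_space_bp = sum(g.length_bp for g in b.genes)
        ledger.scaffold_class[scaf.id] = cls
        ledger.organism_of_scaffold[scaf.id] = org
        for g in genes:
            ledger.gene_class.setdefault(g.id, "native")

    # cross-taxon: copy a clean scaffold from a different taxon group
    for k in range(config.n_cross_taxon):
        target = org_ids[k % len(org_ids)]
        donors = [o for o in org_ids if group_of[o] != group_of[target]]
        if not donors:
            raise ConfigError("no donor organism in a different taxon group")
        donor = donors[int(rng.integers(len(donors)))]
        src_id = scaffold_pool[donor][int(rng.integers(len(scaffold_pool[donor])))]
        src = bundles[donor].scaffolds[src_id]
        sid = f"{target}_ct{k:02d}"
        seq = _mutate(rng, src.sequence, config.cross_taxon_mutation_rate)
        scaf = Scaffold(id=sid, sequence=seq, taxon_group=group_of[target])
        genes = [GeneModel(id=f"{sid}_g{i}", scaffold_id=sid, start=g.start,
                           end=g.end, strand=g.strand)
                 for i, g in enumerate(bundles[donor].genes_by_scaffold()[src_id])]
        _add_scaffold(target, scaf, genes, "cross_taxon")
        ledger.cross_taxon_source[sid] = src_id

    # organelle scaffolds: >= 3 genes so the protein rule can fire
    for k in range(config.n_organelle):
        target = org_ids[(k + 1) % len(org_ids)]
        sid = f"{target}_org{k:02d}"
        length = int(rng.integers(lo, hi + 1))
        scaf = Scaffold(id=sid, sequence=_random_dna(rng, length),
                        taxon_group=group_of[target])
        genes = _tile_genes(rng, config, sid, length, prefix=sid, min_genes=3)
        _add_scaffold(target, scaf, genes, "organelle")

    # bacterial scaffolds: genes will receive AI > 45 hit structure
    for k in range(config.n_bacterial):
        target = org_ids[(k + 2) % len(org_ids)]
        sid = f"{target}_bac{k:02d}"
        length = int(rng.integers(lo, hi + 1))
        scaf = Scaffold(id=sid, sequence=_random_dna(rng, length),
                        taxon_group=group_of[target])
        genes = _tile_genes(rng, config, sid, length, prefix=sid, min_genes=1)
        _add_scaffold(target, scaf, genes, "bacterial")
        for g in genes:
            ledger.gene_class[g.id] = "bacterial"

    # HGT genes: internal position on clean scaffolds with >= 6 genes
    candidates = []
    for org in org_ids:
        for sid, gs in bundles[org].genes_by_scaffold().items():
            if ledger.scaffold_class[sid] == "clean" and len(gs) >= 6:
                candidates.extend(g.id for g in sorted(gs, key=lambda g: g.start)[1:-1])
    if config.n_hgt_genes > len(candidates):
        raise ConfigError(
            f"cannot place {config.n_hgt_genes} HGT genes: only "
            f"{len(candidates)} internal positions on >=6-gene clean scaffolds"
        )
    for gid in rng.choice(candidates, size=config.n_hgt_genes, replace=False):
        ledger.gene_class[str(gid)] = "hgt"

    return bundles, ledger


# ---------------------------------------------------------------------------
# homology hits

def _prokaryote_like_pair(rng: np.random.Generator) -> tuple[Optional[float], float]:
    """(best_euk or None, best_prok) guaranteed to satisfy AI > 45."""
    while True:
        e_prok = 10.0 ** -rng.uniform(30, 150)
        if rng.random() < 0.5:
            e_euk = None  # no eukaryotic hit at all; side substitutes 1.0
            euk_eff = 1.0
        else:
            euk_eff = min(1.0, e_prok * math.exp(rng.uniform(50, 250)))
            e_euk = euk_eff
        ai = math.log(euk_eff + 1e-200) - math.log(e_prok + 1e-200)
        if ai > 45:
            return e_euk, e_prok


def simulate_hits(
    bundles: Mapping[str, AssemblyBundle],
    ledger: TruthLedger,
    config: SimulationConfig,
) -> list[HitRecord]:
    """Gene-level homology hits shaped so the alien index recovers truth.

    Native (and organelle) genes get eukaryotic best hits far below their
    prokaryotic ones (AI < 0); bacterial-scaffold genes and HGT genes get
    prokaryotic best e-values at least e^45 smaller than the eukaryotic side
    (AI > 45); a configurable fraction of native genes has no hits at all.
    """
    rng = np.random.default_rng(config.seed + 1)
    hits: list[HitRecord] = []
    for org, bundle in bundles.items():
        for g in bundle.genes:
            cls = ledger.gene_class.get(g.id, "native")
            if cls in ("native", "outlier_multicopy"):
                if rng.random() < config.no_hit_fraction:
                    continue
                e_euk = 10.0 ** -rng.uniform(10, 150)
                hits.append(HitRecord(g.id, "euk_ref", 60.0, g.length_bp // 3,
                                      e_euk, 200.0, "Eukaryota"))
                if rng.random() < 0.6:
                    e_prok = min(1.0, e_euk * math.exp(rng.uniform(5, 200)))
                    hits.append(HitRecord(g.id, "bact_ref", 40.0, g.length_bp // 3,
                                          e_prok, 80.0, "Bacteria"))
                if rng.random() < 0.1:
                    hits.append(HitRecord(g.id, "virus_ref", 35.0, 100,
                                          10.0 ** -rng.uniform(5, 60), 60.0, "Viruses"))
            elif cls in ("hgt", "bacterial"):
                e_euk, e_prok = _prokaryote_like_pair(rng)
                domain = "Archaea" if rng.random() < 0.15 else "Bacteria"
                hits.append(HitRecord(g.id, "prok_ref", 55.0, g.length_bp // 3,
                                      e_prok, 180.0, domain))
                if e_euk is not None:
                    hits.append(HitRecord(g.id, "euk_ref", 35.0, g.length_bp // 3,
                                          e_euk, 70.0, "Eukaryota"))
    return hits


def simulate_fragment_hits(
    bundles: Mapping[str, AssemblyBundle],
    ledger: TruthLedger,
    config: SimulationConfig,
) -> list[HitRecord]:
    """Fragment-vs-assembly hits for the cross-genera screen.

    Every planted cross-taxon scaffold produces full-identity fragment hits
    onto its source scaffold in the donor assembly; a sample of clean
    scaffolds produces same-group sibling hits and sub-threshold distant
    hits, so the screen's thresholds are exercised in both directions.
    """
    rng = np.random.default_rng(config.seed + 2)
    hits: list[HitRecord] = []
    group_of_org = ledger.genome_group
    for sid, cls in ledger.scaffold_class.items():
        org = ledger.organism_of_scaffold[sid]
        bundle = bundles[org]
        if cls == "cross_taxon":
            src = ledger.cross_taxon_source[sid]
            for frag in fragment_scaffold(bundle.scaffolds[sid]):
                identity = 100.0 * (1 - config.cross_taxon_mutation_rate)
                hits.append(HitRecord(frag.id, src, identity,
                                      frag.end - frag.start, 1e-180, 1800.0,
                                      "Eukaryota", query_coverage=1.0))
        elif cls == "clean" and rng.random() < 0.2:
            frags = fragment_scaffold(bundle.scaffolds[sid])
            frag = frags[int(rng.integers(len(frags)))]
            siblings = [o for o in bundles if o != org
                        and group_of_org[o] == group_of_org[org]]
            if siblings and rng.random() < 0.5:
                # same taxon group at high identity: must never flag
                other = siblings[int(rng.integers(len(siblings)))]
                subject = next(iter(bundles[other].scaffolds))
                hits.append(HitRecord(frag.id, subject, 99.0,
                                      frag.end - frag.start, 1e-150, 1500.0,
                                      "Eukaryota", query_coverage=0.95))
            else:
                # distant group but below the identity/coverage thresholds
                others = [o for o in bundles if group_of_org[o] != group_of_org[org]]
                if not others:
                    continue
                other = others[int(rng.integers(len(others)))]
                subject = next(iter(bundles[other].scaffolds))
                low_ident = rng.random() < 0.5
                hits.append(HitRecord(
                    frag.id, subject,
                    float(rng.uniform(70, 94)) if low_ident else 98.0,
                    frag.end - frag.start, 1e-40, 300.0, "Eukaryota",
                    query_coverage=0.9 if low_ident else float(rng.uniform(0.2, 0.75)),
                ))
    return hits


def simulate_organelle_hits(
    bundles: Mapping[str, AssemblyBundle],
    ledger: TruthLedger,
    config: SimulationConfig,
) -> tuple[list[HitRecord], list[HitRecord]]:
    """(nucleotide hits vs organelle genomes, protein hits vs CHL/MTH).

    Planted organelle scaffolds get a strong nucleotide hit (bit score well
    above 1000) and at least three genes with CHL or MTH protein hits; a few
    clean scaffolds get sub-threshold decoys (bit score < 1000, fewer than
    three organelle-like proteins).
    """
    rng = np.random.default_rng(config.seed + 3)
    nt_hits: list[HitRecord] = []
    protein_hits: list[HitRecord] = []
    for sid, cls in ledger.scaffold_class.items():
        org = ledger.organism_of_scaffold[sid]
        genes = bundles[org].genes_by_scaffold().get(sid, [])
        if cls == "organelle":
            nt_hits.append(HitRecord(sid, "organelle_ref", 90.0, 2000,
                                     0.0, float(rng.uniform(1200, 3000)),
                                     "Eukaryota", "organelle_nt"))
            subject_class = "CHL" if rng.random() < 0.5 else "MTH"
            for g in genes[:max(3, len(genes) // 2)]:
                protein_hits.append(HitRecord(g.id, f"{subject_class.lower()}_ref",
                                              70.0, 300, 1e-60, 400.0,
                                              "Eukaryota", subject_class))
        elif cls == "clean" and rng.random() < 0.1:
            if rng.random() < 0.5:
                nt_hits.append(HitRecord(sid, "organelle_ref", 80.0, 500,
                                         1e-20, float(rng.uniform(100, 900)),
                                         "Eukaryota", "organelle_nt"))
            else:
                for g in genes[:2]:
                    protein_hits.append(HitRecord(g.id, "mth_ref", 50.0, 200,
                                                  1e-20, 150.0, "Eukaryota", "MTH"))
    return nt_hits, protein_hits


# ---------------------------------------------------------------------------
# stations and recruitment

def simulate_stations(config: SimulationConfig) -> list[StationMeta]:
    """Stations with SRF/DCM layers, temperatures, regions and uninformative
    extra environmental parameters (salinity, oxygen, nitrate)."""
    rng = np.random.default_rng(config.seed + 4)
    stations = []
    t_lo, t_hi = config.temperature_range
    for i in range(config.n_stations):
        sid = f"ST{i + 1:03d}"
        region = REGIONS[i % len(REGIONS)]
        t_surface = float(rng.uniform(t_lo, t_hi))
        for layer in config.depth_layers:
            temp = t_surface if layer == "SRF" else t_surface - float(rng.uniform(0, 3))
            stations.append(StationMeta(
                station_id=sid, depth_layer=layer, region=region,
                temperature_C=temp,
                total_reads=config.station_total_reads,
                env={
                    "salinity_PSU": float(rng.normal(35, 1)),
                    "oxygen_umol_kg": float(rng.normal(250, 30)),
                    "nitrate_umol_L": float(rng.lognormal(0.5, 0.8)),
                },
            ))
    return stations


def simulate_recruitment(
    bundles: Mapping[str, AssemblyBundle],
    stations: Sequence[StationMeta],
    config: SimulationConfig,
    t_opt: Optional[Mapping[str, float]] = None,
    exclude_outlier_genes: frozenset[str] = frozenset(),
) -> tuple[dict[str, RecruitmentMatrix], TruthLedger]:
    """Station x gene read counts under Gaussian temperature niches.

    The expected count of gene g in sample s is

        A * exp(-(T_s - T_opt)^2 / (2 sigma^2)) * (len_g / 1000) * depth_factor

    drawn from a Poisson law (optionally gamma-mixed when overdispersion is
    configured). Planted outlier genes have their expectation multiplied by
    the inflation factor in a fixed random subset of samples covering the
    configured breadth, emulating cross-mapping / multi-copy genes. Niche
    optima are evenly spread over the temperature range unless given.
    """
    rng = np.random.default_rng(config.seed + 5)
    ledger = TruthLedger()
    samples = [s.sample for s in stations]
    temps = np.array([s.temperature_C for s in stations])
    layers = [s.depth_layer for s in stations]
    t_lo, t_hi = config.temperature_range
    orgs = list(bundles)
    if t_opt is None:
        span = np.linspace(t_lo + 2, t_hi - 2, max(len(orgs), 2))[:len(orgs)]
        t_opt = {org: float(t) for org, t in zip(orgs, span)}

    matrices: dict[str, RecruitmentMatrix] = {}
    true_rows = {}
    for org in orgs:
        bundle = bundles[org]
        gene_ids = [g.id for g in bundle.genes]
        lengths = np.array([g.length_bp for g in bundle.genes], dtype=float)
        depth_factor = {"SRF": 1.0, "DCM": float(rng.uniform(0.2, 1.0))}
        niche = config.peak_reads_per_kb * np.exp(
            -((temps - t_opt[org]) ** 2) / (2 * config.niche_sigma ** 2)
        )
        per_sample = niche * np.array([depth_factor.get(l, 1.0) for l in layers])
        lam = np.outer(lengths / 1000.0, per_sample)

        eligible_idx = [i for i, g in enumerate(gene_ids)
                        if g not in exclude_outlier_genes]
        n_out = min(config.n_outlier_genes, len(eligible_idx))
        outlier_idx = rng.choice(eligible_idx, size=n_out, replace=False)
        n_breadth = int(math.ceil(config.outlier_station_breadth * len(samples)))
        for gi in outlier_idx:
            cols = rng.choice(len(samples), size=n_breadth, replace=False)
            lam[gi, cols] *= config.outlier_inflation
            ledger.gene_class[gene_ids[gi]] = "outlier_multicopy"
        for gid in gene_ids:
            ledger.gene_class.setdefault(gid, "native")

        if config.overdispersion > 0:
            shape = 1.0 / config.overdispersion
            lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.shape)
        counts = rng.poisson(lam)

        matrices[org] = RecruitmentMatrix(
            counts=pd.DataFrame(counts, index=gene_ids, columns=samples),
            gene_lengths=pd.Series(lengths, index=gene_ids),
            sample_sequenced_totals=pd.Series(
                [s.total_reads for s in stations], index=samples
            ),
        )
        true_rows[org] = pd.Series(lam.sum(axis=0) / np.array(
            [s.total_reads for s in stations], dtype=float), index=samples)
    ledger.true_abundance = pd.DataFrame(true_rows).T
    return matrices, ledger


# ---------------------------------------------------------------------------
# pfam repertoires

def simulate_pfams(config: SimulationConfig) -> tuple[pd.DataFrame, dict[str, str]]:
    """Group-structured Pfam count table (genome x Pfam).

    Each group owns a block of the vocabulary; a genome's counts are a
    multinomial draw of ``pfam_domains_per_genome`` domains from its group's
    profile, which places ``pfam_group_weight`` of its mass on the group's
    own block and spreads the rest over the shared remainder.
    """
    rng = np.random.default_rng(config.seed + 6)
    if config.pfam_domains_per_genome < 1:
        raise ConfigError("domains per genome must be >= 1")
    V = config.pfam_vocabulary
    G = config.pfam_n_groups
    block = V // (G + 1)  # one extra block shared by everyone
    pfams = [f"PF{i + 1:05d}" for i in range(V)]
    groups = [f"mode{g + 1}" for g in range(G)]
    profiles = {}
    for g, name in enumerate(groups):
        w = np.full(V, (1 - config.pfam_group_weight) / (V - block))
        w[g * block:(g + 1) * block] = config.pfam_group_weight / block
        profiles[name] = w / w.sum()
    table_rows = {}
    labels = {}
    for name in groups:
        for i in range(config.pfam_genomes_per_group):
            genome = f"{name}_gen{i + 1:02d}"
            table_rows[genome] = rng.multinomial(config.pfam_domains_per_genome,
                                                 profiles[name])
            labels[genome] = name
    table = pd.DataFrame.from_dict(table_rows, orient="index", columns=pfams)
    return table, labels
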