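"""Shared domain types for the SAG analysis pipeline.

Coordinates are 0-based half-open internally; GFF3 I/O converts to and from
1-based inclusive. Strand is carried on gene models but no downstream
computation is strand-sensitive.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

#: Superkingdom tokens accepted in taxonomy-annotated hit tables.
DOMAINS = frozenset({"Eukaryota", "Bacteria", "Archaea", "Viruses", "Unknown"})

#: Subject classes used by the organelle screen; "generic" for everything else.
SUBJECT_CLASSES = frozenset({"organelle_nt", "CHL", "MTH", "generic"})

#: Depth layers of the oceanographic samples (subsurface / deep chlorophyll maximum).
DEPTH_LAYERS = ("SRF", "DCM")

#: Geographic regions used for regional abundance means.
REGIONS = ("Atlantic", "Mediterranean", "Indian", "Southern", "Pacific")

_DNA = frozenset("ACGTN")


class FormatError(ValueError):
    """A file or record violates the expected format."""


class CoordinateError(ValueError):
    """A genomic interval falls outside its scaffold."""


def sample_key(station_id: str, depth_layer: str) -> str:
    """(station, depth layer) is the sample key; SRF and DCM are distinct samples."""
    if depth_layer not in DEPTH_LAYERS:
        raise FormatError(f"unknown depth layer {depth_layer!r}")
    return f"{station_id}:{depth_layer}"


@dataclass
class Scaffold:
    id: str
    sequence: str
    taxon_group: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _DNA
        if bad:
            raise FormatError(
                f"scaffold {self.id}: non-ACGTN symbols {sorted(bad)!r}"
            )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A gene span (intron plus exon) on a scaffold, 0-based half-open."""

    id: str
    scaffold_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"gene {self.id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.id}: bad strand {self.strand!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class AssemblyBundle:
    """Scaffolds plus gene models for one SAG lineage.

    ``completion`` is the BUSCO-style complete-gene fraction supplied as an
    input; ``mapped_gene_space_bp`` is the total length of the genes used for
    read recruitment (by default all genes) and enters the corrected-abundance
    formula as the "size of the mapped genome".
    """

    organism_id: str
    scaffolds: dict[str, Scaffold]
    genes: list[GeneModel]
    completion: float = 1.0
    mapped_gene_space_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.completion <= 1.0):
            raise ValueError(f"completion must be in (0, 1], got {self.completion}")
        seen: set[str] = set()
        for g in self.genes:
            if g.id in seen:
                raise FormatError(f"duplicate gene id {g.id!r}")
            seen.add(g.id)
            scaf = self.scaffolds.get(g.scaffold_id)
            if scaf is None:
                raise CoordinateError(f"gene {g.id}: unknown scaffold {g.scaffold_id!r}")
            if g.end > scaf.length_bp:
                raise CoordinateError(
                    f"gene {g.id}: end {g.end} beyond scaffold "
                    f"{g.scaffold_id} length {scaf.length_bp}"
                )
        self.genes.sort(key=lambda g: (g.scaffold_id, g.start))
        if self.mapped_gene_space_bp is None:
            self.mapped_gene_space_bp = sum(g.length_bp for g in self.genes)
        if self.mapped_gene_space_bp > self.assembly_size_bp:
            raise ValueError("mapped gene space exceeds assembly size")

    @property
    def assembly_size_bp(self) -> int:
        return sum(s.length_bp for s in self.scaffolds.values())

    def genes_by_scaffold(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {sid: [] for sid in self.scaffolds}
        for g in self.genes:
            out[g.scaffold_id].append(g)
        return out

    def gene_lengths(self) -> pd.Series:
        return pd.Series({g.id: g.length_bp for g in self.genes}, dtype=float)

    def subset(self, keep_scaffolds: Iterable[str]) -> "AssemblyBundle":
        keep = set(keep_scaffolds)
        return AssemblyBundle(
            organism_id=self.organism_id,
            scaffolds={k: v for k, v in self.scaffolds.items() if k in keep},
            genes=[g for g in self.genes if g.scaffold_id in keep],
            completion=self.completion,
        )


@dataclass
class HitRecord:
    """One homology hit (BLAST outfmt-6 dialect) with taxonomy annotation."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    evalue: float
    bit_score: float
    subject_domain: str = "Unknown"
    subject_class: str = "generic"
    query_coverage: float = 0.0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise FormatError(f"negative e-value for {self.query_id}")
        if not (0 <= self.percent_identity <= 100):
            raise FormatError(f"identity out of range for {self.query_id}")
        if self.subject_domain not in DOMAINS:
            raise FormatError(f"unknown taxonomy domain {self.subject_domain!r}")
        if self.subject_class not in SUBJECT_CLASSES:
            raise FormatError(f"unknown subject class {self.subject_class!r}")


@dataclass
class StationMeta:
    station_id: str
    depth_layer: str
    region: str
    temperature_C: float
    total_reads: int
    env: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth_layer not in DEPTH_LAYERS:
            raise FormatError(f"unknown depth layer {self.depth_layer!r}")
        if self.total_reads <= 0:
            raise FormatError("total_reads must be positive")

    @property
    def sample(self) -> str:
        return sample_key(self.station_id, self.depth_layer)


@dataclass
class ReadAlignment:
    """One read mapped onto a gene in one sample."""

    read_id: str
    station_id: str
    depth_layer: str
    gene_id: str
    read_length: int
    aligned_length: int
    percent_identity: float
    read_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.aligned_length > self.read_length:
            raise FormatError(f"aligned length exceeds read length for {self.read_id}")

    @property
    def sample(self) -> str:
        return sample_key(self.station_id, self.depth_layer)


@dataclass
class RecruitmentMatrix:
    """Gene x sample recruitment evidence for one organism.

    ``counts`` holds mapped-read counts, ``detected`` the per-cell detection
    flag (at least one read at >=95% identity over 100% of its length),
    ``rpkm`` the length- and depth-normalised coverage. Two denominators
    coexist deliberately: ``sample_mapped_totals`` (reads mapped to this
    organism's genes; the RPKM denominator) and ``sample_sequenced_totals``
    (reads sequenced in the sample; the raw-abundance denominator).
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    sample_sequenced_totals: pd.Series
    detected: Optional[pd.DataFrame] = None
    rpkm: Optional[pd.DataFrame] = None
    sample_mapped_totals: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative count in recruitment matrix")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            raise FormatError("gene length missing for some matrix rows")
        if self.sample_mapped_totals is None:
            self.sample_mapped_totals = self.counts.sum(axis=0)
        if self.detected is None:
            self.detected = self.counts >= 1
        if (self.detected & (self.counts < 1)).to_numpy().any():
            raise ValueError("detection flag set where count is zero")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def detected_fraction(self) -> pd.Series:
        """Fraction of the organism's genes detected, per sample."""
        return self.detected.sum(axis=0) / len(self.genes)
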