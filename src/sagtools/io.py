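"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython; Newick via dendropy; the GFF3 gene subset, hit tables
and TSV matrices are column-validated tab-separated files.
"""
from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Optional, Union

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    DOMAINS,
    SUBJECT_CLASSES,
    AssemblyBundle,
    CoordinateError,
    FormatError,
    GeneModel,
    HitRecord,
    ReadAlignment,
    RecruitmentMatrix,
    Scaffold,
    StationMeta,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

# 12 standard outfmt-6 columns plus two taxonomy columns.
HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "subject_domain", "subject_class",
]


# ---------------------------------------------------------------------------
# assemblies: FASTA + GFF3 subset

def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gff_genes(path: PathLike) -> list[GeneModel]:
    """Parse the gene subset of GFF3 (type=gene rows, ID= attribute).

    GFF coordinates are 1-based inclusive; internally genes are 0-based
    half-open, so start becomes start-1.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns")
            seqid, _source, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype != "gene":
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr_map.get("ID")
            if gid is None:
                raise FormatError(f"{path}:{lineno}: gene without ID attribute")
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            genes.append(
                GeneModel(id=gid, scaffold_id=seqid, start=start_i - 1, end=end_i,
                          strand=strand if strand in "+-" else "+")
            )
    return genes


def write_gff_genes(genes: Iterable[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.scaffold_id}\tsagtools\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.id}\n"
            )


def read_assembly(
    fasta_path: PathLike,
    gff_path: PathLike,
    organism_id: Optional[str] = None,
    completion: float = 1.0,
    taxon_group: str = "",
) -> AssemblyBundle:
    """Load a scaffold FASTA plus its GFF3 gene models into one bundle."""
    seqs = read_fasta(fasta_path)
    scaffolds = {sid: Scaffold(id=sid, sequence=s, taxon_group=taxon_group)
                 for sid, s in seqs.items()}
    genes = read_gff_genes(gff_path)
    for g in genes:
        if g.scaffold_id not in scaffolds:
            raise CoordinateError(f"gene {g.id}: scaffold {g.scaffold_id} not in FASTA")
    return AssemblyBundle(
        organism_id=organism_id or Path(fasta_path).stem,
        scaffolds=scaffolds,
        genes=genes,
        completion=completion,
    )


def write_assembly(bundle: AssemblyBundle, fasta_path: PathLike, gff_path: PathLike) -> None:
    write_fasta({s.id: s.sequence for s in bundle.scaffolds.values()}, fasta_path)
    write_gff_genes(bundle.genes, gff_path)


# ---------------------------------------------------------------------------
# hit tables

def read_hit_table(path: PathLike,
                   query_lengths: Optional[dict[str, int]] = None) -> list[HitRecord]:
    """Read a taxonomy-annotated BLAST tabular (outfmt-6 + 2 columns) file.

    When ``query_lengths`` is given, query coverage is derived from the
    qstart/qend span; otherwise it is left at 0 (screens that need coverage
    require lengths).
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(HIT_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(HIT_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            row = dict(zip(HIT_COLUMNS, fields))
            if row["subject_domain"] not in DOMAINS:
                raise FormatError(
                    f"{path}:{lineno}: unknown taxonomy domain {row['subject_domain']!r}"
                )
            if row["subject_class"] not in SUBJECT_CLASSES:
                raise FormatError(
                    f"{path}:{lineno}: unknown subject class {row['subject_class']!r}"
                )
            try:
                pident = float(row["pident"])
                length = int(row["length"])
                qstart, qend = int(row["qstart"]), int(row["qend"])
                evalue = float(row["evalue"])
                bitscore = float(row["bitscore"])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
            if not math.isfinite(evalue):
                raise FormatError(f"{path}:{lineno}: non-finite e-value")
            # query span is 1-based inclusive in outfmt 6
            qlen = (query_lengths or {}).get(row["qseqid"])
            coverage = (abs(qend - qstart) + 1) / qlen if qlen else 0.0
            hits.append(
                HitRecord(
                    query_id=row["qseqid"], subject_id=row["sseqid"],
                    percent_identity=pident, align_length=length,
                    evalue=evalue, bit_score=bitscore,
                    subject_domain=row["subject_domain"],
                    subject_class=row["subject_class"],
                    query_coverage=coverage,
                )
            )
    if not hits:
        log.warning("empty hit table: %s", path)
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: PathLike,
                    query_lengths: Optional[dict[str, int]] = None) -> None:
    with open(path, "w") as fh:
        for h in hits:
            qlen = (query_lengths or {}).get(h.query_id)
            span = int(round(h.query_coverage * qlen)) if qlen else h.align_length
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:g}\t"
                f"{h.align_length}\t0\t0\t1\t{max(span, 1)}\t1\t{h.align_length}\t"
                f"{h.evalue:g}\t{h.bit_score:g}\t{h.subject_domain}\t{h.subject_class}\n"
            )


# ---------------------------------------------------------------------------
# count matrices and station metadata

def read_count_matrix(
    path: PathLike,
    gene_lengths: Optional[pd.Series] = None,
    sample_sequenced_totals: Optional[pd.Series] = None,
) -> RecruitmentMatrix:
    """Read a gene x sample TSV of integer counts (first column gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        log.warning("missing cells in %s treated as 0", path)
        df = df.fillna(0)
    arr = df.to_numpy()
    if (arr < 0).any():
        raise FormatError(f"negative count in {path}")
    if (arr != arr.astype(int)).any():
        raise FormatError(f"non-integer count in {path}")
    counts = df.astype(int)
    if gene_lengths is None:
        gene_lengths = pd.Series(1000.0, index=counts.index)
    if sample_sequenced_totals is None:
        sample_sequenced_totals = pd.Series(1_000_000, index=counts.columns)
    return RecruitmentMatrix(
        counts=counts,
        gene_lengths=gene_lengths,
        sample_sequenced_totals=sample_sequenced_totals,
    )


def write_count_matrix(matrix: RecruitmentMatrix, path: PathLike) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_station_table(path: PathLike) -> list[StationMeta]:
    """Read station metadata (PANGAEA-style TSV).

    Required columns: station_id, depth_layer, region, temperature_C,
    total_reads. Any extra numeric column is kept as an environmental
    parameter.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"station_id", "depth_layer", "region", "temperature_C", "total_reads"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    extra = [c for c in df.columns if c not in required]
    out = []
    for _, row in df.iterrows():
        out.append(
            StationMeta(
                station_id=str(row["station_id"]),
                depth_layer=str(row["depth_layer"]),
                region=str(row["region"]),
                temperature_C=float(row["temperature_C"]),
                total_reads=int(row["total_reads"]),
                env={c: float(row[c]) for c in extra},
            )
        )
    keys = [s.sample for s in out]
    if len(set(keys)) != len(keys):
        raise FormatError(f"{path}: duplicate (station, depth_layer) keys")
    return out


def write_station_table(stations: Iterable[StationMeta], path: PathLike) -> None:
    stations = list(stations)
    env_cols = sorted({k for s in stations for k in s.env})
    rows = []
    for s in stations:
        row = {
            "station_id": s.station_id, "depth_layer": s.depth_layer,
            "region": s.region, "temperature_C": s.temperature_C,
            "total_reads": s.total_reads,
        }
        row.update({c: s.env.get(c, float("nan")) for c in env_cols})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_alignment_table(path: PathLike) -> list[ReadAlignment]:
    """Read a read-alignment TSV (read_id, station_id, depth_layer, gene_id,
    read_length, aligned_length, percent_identity[, read_sequence])."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        seq = row.get("read_sequence")
        out.append(
            ReadAlignment(
                read_id=str(row["read_id"]),
                station_id=str(row["station_id"]),
                depth_layer=str(row["depth_layer"]),
                gene_id=str(row["gene_id"]),
                read_length=int(row["read_length"]),
                aligned_length=int(row["aligned_length"]),
                percent_identity=float(row["percent_identity"]),
                read_sequence=None if pd.isna(seq) else str(seq),
            )
        )
    return out


# ---------------------------------------------------------------------------
# trees

def read_newick(source: str) -> dendropy.Tree:
    """Parse a Newick string (or file path) with internal-node labels read
    as bootstrap supports when numeric."""
    if "(" not in source:
        tree = dendropy.Tree.get(path=source, schema="newick",
                                 suppress_internal_node_taxa=True)
    else:
        try:
            tree = dendropy.Tree.get(data=source, schema="newick",
                                     suppress_internal_node_taxa=True)
        except Exception as exc:  # dendropy raises various parse errors
            raise FormatError(f"Newick parse error: {exc}") from exc
    for node in tree.internal_nodes():
        if node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                continue
            if not (0 <= support <= 100):
                raise FormatError(f"bootstrap support {support} outside [0, 100]")
    return tree
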