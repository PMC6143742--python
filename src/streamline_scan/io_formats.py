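"""Readers and writers for every external representation the pipeline touches.

Formats are deliberately minimal and plain-text: FASTA for contigs and
translated proteins, GFF3 (Prodigal CDS dialect) for gene coordinates, and
tab-delimited tables with a header row for QC records, family annotations,
read-count matrices and sample metadata. All coordinates are GFF3
convention — 1-based, inclusive on both ends — and every downstream
computation in this package uses that convention.

Writers emit UTF-8, tab-delimited, newline-terminated files so that a
write/read round trip is byte-faithful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DEPTH_LAYERS = ("SRF", "DCM", "MES", "OMZ")
"""Closed vocabulary of sample depth layers: surface, deep chlorophyll
maximum, mesopelagic, oxygen minimum zone."""


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


@dataclass(frozen=True)
class ContigSeq:
    """One assembly contig: an id and its nucleotide sequence.

    IUPAC ambiguity codes (N etc.) are allowed; they are excluded from GC
    computation downstream but still count toward assembly length.
    """

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError(f"contig {self.contig_id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneRecord:
    """A called gene (CDS): 1-based inclusive coordinates plus its protein.

    ``protein`` may be empty when no translation was supplied; letters
    outside the 20 standard amino acids (X, B, Z, U, ``*``) are retained
    here and skipped by ARSC computation.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    gene_id: str
    protein: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"gene {self.gene_id!r}: invalid coordinates "
                f"{self.start}..{self.end} (need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")


@dataclass
class GenomeAnnotation:
    """Contigs plus gene calls for a single genome.

    Genes are kept sorted by (contig_id, start); sorting is stable so the
    result does not depend on input order.
    """

    genome_id: str
    contigs: dict[str, ContigSeq]
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.contig_id, g.start))
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise FormatError(
                    f"genome {self.genome_id!r}: duplicate gene id {g.gene_id!r}"
                )
            seen.add(g.gene_id)
            contig = self.contigs.get(g.contig_id)
            if contig is None:
                raise FormatError(
                    f"gene {g.gene_id!r} references missing contig {g.contig_id!r}"
                )
            if g.end > len(contig):
                raise FormatError(
                    f"gene {g.gene_id!r} (end={g.end}) exceeds contig "
                    f"{g.contig_id!r} length {len(contig)}"
                )

    @property
    def proteins(self) -> list[str]:
        return [g.protein for g in self.genes if g.protein]

    @property
    def assembly_bp(self) -> int:
        return sum(len(c) for c in self.contigs.values())


@dataclass(frozen=True)
class SampleMetadata:
    """Metadata for one metagenome sample."""

    sample_id: str
    depth_layer: str
    region: str = ""

    def __post_init__(self) -> None:
        if self.depth_layer not in DEPTH_LAYERS:
            raise FormatError(
                f"sample {self.sample_id!r}: depth_layer {self.depth_layer!r} "
                f"not in {DEPTH_LAYERS}"
            )


@dataclass(frozen=True)
class QCRecord:
    """Per-genome assembly QC: length alpha, contamination beta, completeness gamma.

    ``contamination`` and ``completeness`` are fractions in [0, 1]; files and
    configs use percentages (0–100), converted exactly once at read time.
    """

    genome_id: str
    assembly_bp: int
    completeness: float
    contamination: float

    def __post_init__(self) -> None:
        if self.assembly_bp <= 0:
            raise FormatError(f"{self.genome_id}: assembly_bp must be positive")
        if not (0.0 <= self.contamination <= 1.0):
            raise FormatError(
                f"{self.genome_id}: contamination {self.contamination} outside [0,1]"
            )
        if not (0.0 <= self.completeness <= 1.0):
            raise FormatError(
                f"{self.genome_id}: completeness {self.completeness} outside [0,1]"
            )


class AnnotationTable:
    """Genome x family (COG/NOG id) annotation index.

    Stores (genome_id, gene_id, family_id) records; duplicates are dropped
    with a logged warning. Exposes per-genome distinct-family sets and
    per-family gene counts, the substrate for complex calling and
    enrichment testing.
    """

    def __init__(self, records: Iterable[tuple[str, str, str]] = ()) -> None:
        self._records: list[tuple[str, str, str]] = []
        self._seen: set[tuple[str, str, str]] = set()
        self._by_genome: dict[str, dict[str, int]] = {}
        for rec in records:
            self.add(*rec)

    def add(self, genome_id: str, gene_id: str, family_id: str) -> None:
        key = (genome_id, gene_id, family_id)
        if key in self._seen:
            logger.warning("duplicate annotation record %r dropped", key)
            return
        self._seen.add(key)
        self._records.append(key)
        fams = self._by_genome.setdefault(genome_id, {})
        fams[family_id] = fams.get(family_id, 0) + 1

    def add_genome(self, genome_id: str) -> None:
        """Register a genome with no annotations yet."""
        self._by_genome.setdefault(genome_id, {})

    @property
    def genomes(self) -> list[str]:
        return list(self._by_genome)

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self._by_genome

    def __len__(self) -> int:
        return len(self._records)

    def families(self, genome_id: str) -> frozenset[str]:
        return frozenset(self._by_genome.get(genome_id, ()))

    def family_counts(self, genome_id: str) -> dict[str, int]:
        return dict(self._by_genome.get(genome_id, {}))

    @property
    def records(self) -> list[tuple[str, str, str]]:
        return list(self._records)

    def copy(self) -> "AnnotationTable":
        out = AnnotationTable(self._records)
        for g in self._by_genome:
            out.add_genome(g)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._records, columns=["genome_id", "gene_id", "family_id"])


@dataclass
class AbundanceMatrix:
    """Genome x sample read counts plus per-genome assembly lengths (bp).

    Rows are genomes, columns are samples; orders are preserved from the
    source file. Counts are nonnegative; lengths strictly positive.
    TPM/log-TPM are computed by :mod:`streamline_scan.abundance_habitat`.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative read count in abundance matrix")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths[self.lengths.isna()].index.tolist()
            raise FormatError(f"missing genome length for {missing}")
        if (self.lengths <= 0).any():
            raise FormatError("genome lengths must be positive")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# FASTA + GFF3 genomes


def _parse_gff_cds(gff_path: Path) -> list[tuple[str, int, int, str, str]]:
    """Parse CDS features from a Prodigal-dialect GFF3 file.

    Returns (contig_id, start, end, strand, gene_id) tuples. Raises
    FormatError with the offending line number on malformed input.
    """
    out = []
    with open(gff_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{gff_path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            contig_id, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
            if ftype != "CDS":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"{gff_path}:{lineno}: unparseable coordinates "
                    f"{start_s!r}..{end_s!r}"
                ) from None
            gene_id = None
            for item in attrs.rstrip(";").split(";"):
                if item.startswith("ID="):
                    gene_id = item[3:]
                    break
            if not gene_id:
                raise FormatError(f"{gff_path}:{lineno}: CDS feature lacks ID attribute")
            if strand not in ("+", "-"):
                raise FormatError(f"{gff_path}:{lineno}: bad strand {strand!r}")
            out.append((contig_id, start, end, strand, gene_id))
    return out


def read_genome(
    fasta_path: str | Path,
    gff_path: str | Path,
    protein_fasta_path: str | Path | None = None,
    genome_id: str | None = None,
) -> GenomeAnnotation:
    """Read one genome: contig FASTA + CDS GFF3, optionally translated proteins.

    Proteins in ``protein_fasta_path`` are matched to genes by record id.
    Genes are returned sorted by (contig_id, start); a gene referencing a
    missing contig or exceeding contig bounds is a hard error naming the
    gene.
    """
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    contigs: dict[str, ContigSeq] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in contigs:
            raise FormatError(f"{fasta_path}: duplicate contig id {rec.id!r}")
        contigs[rec.id] = ContigSeq(rec.id, str(rec.seq).upper())

    prots: dict[str, str] = {}
    if protein_fasta_path is not None:
        for rec in SeqIO.parse(str(protein_fasta_path), "fasta"):
            prots[rec.id] = str(rec.seq).upper().rstrip("*")

    genes = [
        GeneRecord(contig_id, start, end, strand, gene_id, prots.get(gene_id, ""))
        for contig_id, start, end, strand, gene_id in _parse_gff_cds(gff_path)
    ]
    gid = genome_id if genome_id is not None else fasta_path.stem
    return GenomeAnnotation(gid, contigs, genes)


def write_genome(
    genome: GenomeAnnotation,
    fasta_path: str | Path,
    gff_path: str | Path,
    protein_fasta_path: str | Path | None = None,
) -> None:
    """Write contig FASTA, CDS GFF3 and (optionally) protein FASTA."""
    records = [
        SeqRecord(Seq(c.sequence), id=c.contig_id, description="")
        for c in genome.contigs.values()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(gff_path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            fh.write(
                f"{g.contig_id}\tstreamline_scan\tCDS\t{g.start}\t{g.end}\t."
                f"\t{g.strand}\t0\tID={g.gene_id};\n"
            )
    if protein_fasta_path is not None:
        precs = [
            SeqRecord(Seq(g.protein), id=g.gene_id, description="")
            for g in genome.genes
            if g.protein
        ]
        SeqIO.write(precs, str(protein_fasta_path), "fasta")


# ---------------------------------------------------------------------------
# Tabular formats


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_qc_table(tsv_path: str | Path) -> list[QCRecord]:
    """Read per-genome QC records; percentage columns land on [0, 100]."""
    df = _read_tsv(tsv_path, ["genome_id", "assembly_bp", "completeness_pct", "contamination_pct"])
    out = []
    for row in df.itertuples(index=False):
        comp, cont = float(row.completeness_pct), float(row.contamination_pct)
        for name, val in (("completeness_pct", comp), ("contamination_pct", cont)):
            if not (0.0 <= val <= 100.0):
                raise FormatError(
                    f"{tsv_path}: genome {row.genome_id}: {name}={val} outside [0,100]"
                )
        out.append(
            QCRecord(
                genome_id=str(row.genome_id),
                assembly_bp=int(row.assembly_bp),
                completeness=comp / 100.0,
                contamination=cont / 100.0,
            )
        )
    return out


def write_qc_table(records: Sequence[QCRecord], tsv_path: str | Path) -> None:
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("genome_id\tassembly_bp\tcompleteness_pct\tcontamination_pct\n")
        for r in records:
            fh.write(
                f"{r.genome_id}\t{r.assembly_bp}\t{r.completeness * 100:g}"
                f"\t{r.contamination * 100:g}\n"
            )


def read_annotation_table(tsv_path: str | Path) -> AnnotationTable:
    """Read a long-format genome/gene/family TSV into an AnnotationTable."""
    df = _read_tsv(tsv_path, ["genome_id", "gene_id", "family_id"])
    return AnnotationTable(
        (str(r.genome_id), str(r.gene_id), str(r.family_id))
        for r in df.itertuples(index=False)
    )


def write_annotation_table(table: AnnotationTable, tsv_path: str | Path) -> None:
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("genome_id\tgene_id\tfamily_id\n")
        for genome_id, gene_id, family_id in table.records:
            fh.write(f"{genome_id}\t{gene_id}\t{family_id}\n")


def read_sample_metadata(tsv_path: str | Path) -> list[SampleMetadata]:
    df = _read_tsv(tsv_path, ["sample_id", "depth_layer"])
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{tsv_path}: duplicate sample id(s) {dups}")
    region = df["region"] if "region" in df.columns else [""] * len(df)
    return [
        SampleMetadata(str(s), str(d), "" if pd.isna(r) else str(r))
        for s, d, r in zip(df["sample_id"], df["depth_layer"], region)
    ]


def write_sample_metadata(samples: Sequence[SampleMetadata], tsv_path: str | Path) -> None:
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tdepth_layer\tregion\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.depth_layer}\t{s.region}\n")


def read_counts_matrix(
    tsv_path: str | Path, metadata_path: str | Path
) -> tuple[AbundanceMatrix, list[SampleMetadata]]:
    """Read a genome x sample count matrix plus its sample metadata.

    The matrix TSV has columns ``genome_id``, ``length_bp``, then one column
    per sample. Every sample column must appear in the metadata file.
    """
    df = _read_tsv(tsv_path, ["genome_id", "length_bp"])
    df = df.set_index("genome_id")
    lengths = df.pop("length_bp").astype(float)
    counts = df.astype(float)
    samples = read_sample_metadata(metadata_path)
    known = {s.sample_id for s in samples}
    for col in counts.columns:
        if col not in known:
            raise FormatError(f"{tsv_path}: sample {col!r} absent from metadata")
    return AbundanceMatrix(counts, lengths), samples


def write_counts_matrix(matrix: AbundanceMatrix, tsv_path: str | Path) -> None:
    df = matrix.counts.copy()

    def _fmt(v: float) -> str:
        return str(int(v)) if float(v).is_integer() else repr(float(v))

    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("genome_id\tlength_bp\t" + "\t".join(df.columns) + "\n")
        for gid in df.index:
            vals = "\t".join(_fmt(v) for v in df.loc[gid])
            fh.write(f"{gid}\t{_fmt(matrix.lengths[gid])}\t{vals}\n")


def write_matrix_tsv(df: pd.DataFrame, tsv_path: str | Path, index_name: str = "genome_id") -> None:
    """Write a generic numeric matrix (e.g. TPM, log-TPM, distances) as TSV."""
    df = df.copy()
    df.index.name = index_name
    df.to_csv(tsv_path, sep="\t", float_format="%.10g")
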