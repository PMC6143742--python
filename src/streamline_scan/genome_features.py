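"""Per-genome streamlining metrics and the assembly QC filter.

Five quantities summarise how streamlined a genome is:

* percent GC content of the assembly,
* mean intergenic spacer (IGS) length in nucleotides,
* N-ARSC and C-ARSC — the mean number of nitrogen / carbon atoms in
  amino-acid side chains per residue across the proteome, proxies for the
  cell's nutrient investment in protein,
* estimated complete-genome size S = alpha * (1 - beta) / gamma, where
  alpha is assembly length, beta contamination and gamma completeness.

Genomes enter comparative analyses only if they pass the QC filter:
contamination strictly below 5% and completeness strictly above 40%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import ContigSeq, GenomeAnnotation, QCRecord

#: Heavy atoms (C, N) in each standard amino-acid side chain.
#: Glycine's side chain is a lone hydrogen, hence (0, 0); proline's ring
#: carbons count as side chain. Letters outside this table (X, B, Z, U, *)
#: are skipped entirely by ARSC computation.
SIDE_CHAIN_ATOMS: Mapping[str, tuple[int, int]] = {
    "G": (0, 0),
    "A": (1, 0),
    "S": (1, 0),
    "C": (1, 0),
    "T": (2, 0),
    "V": (3, 0),
    "P": (3, 0),
    "M": (3, 0),
    "D": (2, 0),
    "N": (2, 1),
    "E": (3, 0),
    "Q": (3, 1),
    "I": (4, 0),
    "L": (4, 0),
    "K": (4, 1),
    "R": (4, 3),
    "H": (4, 2),
    "F": (7, 0),
    "Y": (7, 0),
    "W": (9, 1),
}

#: QC thresholds as printed: contamination < 5%, completeness > 40%,
#: both strict. Stored as fractions.
CONTAMINATION_MAX = 0.05
COMPLETENESS_MIN = 0.40


@dataclass(frozen=True)
class FeatureVector:
    """The five streamlining metrics for one genome.

    ``mean_igs`` is None when the genome has no contig with two or more
    genes (the spacer mean is then undefined, not zero).
    """

    genome_id: str
    gc_percent: float
    mean_igs: float | None
    n_arsc: float
    c_arsc: float
    est_size: float


def gc_content(contigs: Iterable[ContigSeq]) -> float:
    """Percent GC over all contigs, IUPAC ambiguity codes excluded.

    GC% = 100 * (G + C) / (A + C + G + T); bases outside {A, C, G, T} are
    excluded from both numerator and denominator.
    """
    gc = at = 0
    for contig in contigs:
        seq = contig.sequence.upper()
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous (A/C/G/T) bases in assembly")
    return 100.0 * gc / (gc + at)


def mean_intergenic_length(genome: GenomeAnnotation) -> float | None:
    """Mean intergenic spacer length over adjacent gene pairs, per contig.

    Genes are taken in start order on each contig; the spacer between
    neighbours is ``start(next) - end(prev) - 1`` (1-based inclusive
    coordinates), clamped to 0 when genes overlap — a spacer is a physical
    stretch of DNA and cannot be negative. Contigs with fewer than two
    genes contribute no pairs; with no pairs at all the mean is undefined
    and None is returned.

    Strand is ignored: spacers are computed on linear gene order.
    """
    gaps: list[int] = []
    by_contig: dict[str, list] = {}
    for g in genome.genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    for genes in by_contig.values():
        genes.sort(key=lambda g: g.start)
        for prev, nxt in zip(genes, genes[1:]):
            gaps.append(max(0, nxt.start - prev.end - 1))
    if not gaps:
        return None
    return sum(gaps) / len(gaps)


def arsc(proteins: Iterable[str], element: str) -> float:
    """Atoms of ``element`` ('N' or 'C') per residue side chain, pooled.

    Residues are pooled across the whole proteome: total side-chain atoms
    of the element divided by total standard residues. Pooling makes the
    statistic independent of how residues are split into proteins and
    unbiased by protein length. Non-standard letters are skipped.
    """
    if element not in ("N", "C"):
        raise ValueError(f"element must be 'N' or 'C', got {element!r}")
    idx = 0 if element == "C" else 1
    atoms = 0
    residues = 0
    for protein in proteins:
        for aa in protein.upper():
            counts = SIDE_CHAIN_ATOMS.get(aa)
            if counts is None:
                continue
            atoms += counts[idx]
            residues += 1
    if residues == 0:
        raise ValueError("no standard residues in proteome")
    return atoms / residues


def estimate_genome_size(qc: QCRecord) -> float:
    """Estimated complete-genome size S = alpha * (1 - beta) / gamma.

    Contaminating base pairs are removed (factor 1 - beta) and the
    remainder is scaled up to the complete genome by dividing by the
    completeness fraction gamma.
    """
    if qc.completeness <= 0:
        raise ValueError(f"{qc.genome_id}: completeness must be > 0")
    return qc.assembly_bp * (1.0 - qc.contamination) / qc.completeness


def qc_pass(
    qc: QCRecord,
    contamination_max: float = CONTAMINATION_MAX,
    completeness_min: float = COMPLETENESS_MIN,
) -> bool:
    """True iff contamination < 5% and completeness > 40% (both strict)."""
    return qc.contamination < contamination_max and qc.completeness > completeness_min


def qc_filter(
    records: Sequence[QCRecord],
    contamination_max: float = CONTAMINATION_MAX,
    completeness_min: float = COMPLETENESS_MIN,
) -> list[str]:
    """Genome ids passing the QC filter, in input order."""
    return [
        r.genome_id
        for r in records
        if qc_pass(r, contamination_max, completeness_min)
    ]


def feature_vector(genome: GenomeAnnotation, qc: QCRecord) -> FeatureVector:
    """All five metrics for one genome."""
    return FeatureVector(
        genome_id=genome.genome_id,
        gc_percent=gc_content(genome.contigs.values()),
        mean_igs=mean_intergenic_length(genome),
        n_arsc=arsc(genome.proteins, "N"),
        c_arsc=arsc(genome.proteins, "C"),
        est_size=estimate_genome_size(qc),
    )


def feature_table(
    genomes: Sequence[GenomeAnnotation],
    qc_records: Sequence[QCRecord],
    only_pass: bool = True,
) -> list[FeatureVector]:
    """FeatureVectors for every genome, QC-filtered by default.

    Every genome must have a QC record; a missing record is a hard error.
    With ``only_pass`` (the default) genomes failing the QC filter are
    dropped from the output.
    """
    qc_by_id = {r.genome_id: r for r in qc_records}
    out = []
    for genome in genomes:
        qc = qc_by_id.get(genome.genome_id)
        if qc is None:
            raise KeyError(f"no QC record for genome {genome.genome_id!r}")
        if only_pass and not qc_pass(qc):
            continue
        out.append(feature_vector(genome, qc))
    return out
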