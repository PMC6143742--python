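"""Synthetic genomes, annotations and abundance matrices with known truth.

Every downstream stage of the pipeline is exercised on data produced here,
so each generator records the ground truth it embeds:

* :func:`simulate_genome` builds a prokaryote-like assembly — contigs of
  i.i.d. nucleotides at a target GC, genes packed densely with geometric
  intergenic gaps and occasional overlaps, proteins drawn i.i.d. from a
  20-letter weight vector — so realised GC, mean spacer length and
  N-/C-ARSC have analytically known expectations.
* :func:`spike_complex` plants k distinct subunit families of a named
  respiratory complex into an annotation table, the substrate for
  threshold-sweep tests of the complex caller.
* :func:`simulate_abundance` draws a two-block (epipelagic/mesopelagic)
  genome x sample count matrix from a negative-binomial model with a
  tunable fold-effect and overdispersion; at unit fold-effect there is no
  block structure at all.
* :func:`simulate_og_enrichment` plants habitat-enriched families among
  null families with common presence probability.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .complex_caller import DEFAULT_DEFINITIONS, ComplexDefinition
from .genome_features import SIDE_CHAIN_ATOMS
from .io_formats import (
    AbundanceMatrix,
    AnnotationTable,
    ContigSeq,
    GeneRecord,
    GenomeAnnotation,
    QCRecord,
    SampleMetadata,
)

#: Fixed amino-acid ordering for weight vectors.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: Default amino-acid sampling weights, loosely shaped like a typical
#: bacterial proteome (Leu/Ala-rich, Trp/Cys-poor); normalised at use.
DEFAULT_AA_WEIGHTS: dict[str, float] = {
    "A": 0.090, "C": 0.012, "D": 0.054, "E": 0.061, "F": 0.044,
    "G": 0.072, "H": 0.022, "I": 0.067, "K": 0.058, "L": 0.100,
    "M": 0.023, "N": 0.040, "P": 0.042, "Q": 0.039, "R": 0.050,
    "S": 0.060, "T": 0.054, "V": 0.068, "W": 0.013, "Y": 0.032,
}


def _normalise_weights(weights: Mapping[str, float]) -> np.ndarray:
    w = np.array([float(weights.get(aa, 0.0)) for aa in AA_ORDER])
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("aa_weights must be nonnegative with positive sum")
    return w / w.sum()


def expected_arsc(weights: Mapping[str, float], element: str) -> float:
    """ARSC expectation implied by an amino-acid weight vector."""
    idx = {"C": 0, "N": 1}[element]
    w = _normalise_weights(weights)
    atoms = np.array([SIDE_CHAIN_ATOMS[aa][idx] for aa in AA_ORDER])
    return float(w @ atoms)


@dataclass(frozen=True)
class GenomeTarget:
    """Ground-truth composition targets for one simulated genome."""

    target_gc: float
    expected_n_arsc: float
    expected_c_arsc: float


@dataclass
class SimTruth:
    """Ground truth accumulated across generators."""

    habitat_labels: dict[str, str] = field(default_factory=dict)
    enriched_families: dict[str, str] = field(default_factory=dict)  # family -> habitat
    genome_targets: dict[str, GenomeTarget] = field(default_factory=dict)

    def update(self, other: "SimTruth") -> "SimTruth":
        self.habitat_labels.update(other.habitat_labels)
        self.enriched_families.update(other.enriched_families)
        self.genome_targets.update(other.genome_targets)
        return self


@dataclass(frozen=True)
class GenomeSimSpec:
    """Parameters of one simulated genome assembly.

    Defaults give a small but realistically dense assembly: ~300-residue
    proteins, ~60 nt spacers, 5% gene overlaps, 40% GC.
    """

    n_contigs: int = 5
    genes_per_contig: int = 10
    gene_len_mean: int = 900
    igs_len_mean: int = 60
    overlap_prob: float = 0.05
    target_gc: float = 0.40
    aa_weights: Mapping[str, float] | None = None
    seed: int = 0
    max_contig_bp: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_contigs", "genes_per_contig", "gene_len_mean", "igs_len_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.overlap_prob <= 1.0):
            raise ValueError("overlap_prob must be in [0,1]")
        if not (0.0 <= self.target_gc <= 1.0):
            raise ValueError("target_gc must be in [0,1]")
        if self.aa_weights is not None:
            _normalise_weights(self.aa_weights)  # validates


def simulate_genome(
    spec: GenomeSimSpec,
    genome_id: str = "G1",
    completeness: float = 1.0,
    contamination: float = 0.0,
) -> tuple[GenomeAnnotation, QCRecord, SimTruth]:
    """Simulate one genome assembly with gene calls and proteins.

    Contig bases are i.i.d. with P(G) = P(C) = target_gc / 2; protein
    residues are i.i.d. from ``aa_weights``; intergenic gaps are geometric
    with mean ``igs_len_mean`` and become small overlaps with probability
    ``overlap_prob``. ``completeness`` and ``contamination`` are free QC
    parameters (assessing them from sequence is out of scope). If
    ``max_contig_bp`` is set and gene packing exceeds it, a ValueError is
    raised.
    """
    rng = np.random.default_rng(spec.seed)
    weights = _normalise_weights(spec.aa_weights or DEFAULT_AA_WEIGHTS)
    aa_letters = np.array(list(AA_ORDER))
    base_p = np.array(
        [(1 - spec.target_gc) / 2, spec.target_gc / 2,
         spec.target_gc / 2, (1 - spec.target_gc) / 2]
    )
    bases = np.array(list("ACGT"))

    contigs: dict[str, ContigSeq] = {}
    genes: list[GeneRecord] = []
    mean_aa = max(spec.gene_len_mean // 3, 6)
    for ci in range(spec.n_contigs):
        contig_id = f"{genome_id}_c{ci + 1}"
        pos = 1 + int(rng.geometric(1.0 / spec.igs_len_mean))
        for gi in range(spec.genes_per_contig):
            aa_len = max(5, int(rng.poisson(mean_aa)))
            nt_len = 3 * aa_len + 3  # stop codon included
            start, end = pos, pos + nt_len - 1
            protein = "".join(rng.choice(aa_letters, size=aa_len, p=weights))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneRecord(contig_id, start, end, strand,
                           f"{contig_id}_g{gi + 1}", protein)
            )
            if rng.random() < spec.overlap_prob:
                gap = -int(rng.integers(1, 5))
            else:
                gap = int(rng.geometric(1.0 / spec.igs_len_mean))
            pos = end + 1 + gap
        contig_len = genes[-1].end + int(rng.geometric(1.0 / spec.igs_len_mean))
        if spec.max_contig_bp is not None and contig_len > spec.max_contig_bp:
            raise ValueError(
                f"infeasible packing: contig {contig_id} needs {contig_len} bp "
                f"> max_contig_bp {spec.max_contig_bp}"
            )
        seq = "".join(rng.choice(bases, size=contig_len, p=base_p))
        contigs[contig_id] = ContigSeq(contig_id, seq)

    genome = GenomeAnnotation(genome_id, contigs, genes)
    qc = QCRecord(genome_id, genome.assembly_bp, completeness, contamination)
    wmap = dict(zip(AA_ORDER, weights))
    truth = SimTruth(
        genome_targets={
            genome_id: GenomeTarget(
                target_gc=spec.target_gc,
                expected_n_arsc=expected_arsc(wmap, "N"),
                expected_c_arsc=expected_arsc(wmap, "C"),
            )
        }
    )
    return genome, qc, truth


def spike_complex(
    table: AnnotationTable,
    genome_id: str,
    complex_name: str,
    k: int,
    definitions: Mapping[str, ComplexDefinition] | None = None,
) -> AnnotationTable:
    """Return a copy of ``table`` with k distinct subunit families added.

    The first k families of the complex's countable set are planted into
    ``genome_id`` (one synthetic gene each); k = 0 leaves the table
    unchanged apart from registering the genome.
    """
    defs = definitions if definitions is not None else DEFAULT_DEFINITIONS
    if complex_name not in defs:
        raise KeyError(
            f"unknown complex {complex_name!r}; known: {sorted(defs)}"
        )
    countable = defs[complex_name].countable_families
    if not (0 <= k <= len(countable)):
        raise ValueError(
            f"k={k} outside [0, {len(countable)}] for complex {complex_name}"
        )
    out = table.copy()
    out.add_genome(genome_id)
    for i, fam in enumerate(countable[:k]):
        out.add(genome_id, f"{genome_id}_spike_{complex_name}_{i + 1}", fam)
    return out


@dataclass(frozen=True)
class AbundanceSimSpec:
    """Two-block habitat structure for a genome x sample count matrix.

    Expected counts for a genome in its matching habitat's samples are
    ``depth_effect``-fold those in the other habitat's samples; counts are
    negative-binomial (gamma-Poisson) with variance mu * (1 + dispersion *
    mu), so dispersion -> 0 recovers Poisson sampling. OMZ layers are not
    simulated: the dichotomy under study is epipelagic vs mesopelagic.
    """

    n_epi_genomes: int = 20
    n_meso_genomes: int = 20
    n_epi_samples: int = 10
    n_meso_samples: int = 8
    depth_effect: float = 20.0
    dispersion: float = 0.3
    seed: int = 0
    base_mean: float = 200.0

    def __post_init__(self) -> None:
        for name in ("n_epi_genomes", "n_meso_genomes", "n_epi_samples", "n_meso_samples"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.depth_effect < 1.0:
            raise ValueError("depth_effect must be >= 1")
        if self.dispersion < 0.0:
            raise ValueError("dispersion must be >= 0")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0.0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate_abundance(
    spec: AbundanceSimSpec,
    lengths: Mapping[str, float] | None = None,
) -> tuple[AbundanceMatrix, list[SampleMetadata], SimTruth]:
    """Simulate a habitat-blocked genome x sample read-count matrix.

    Genome ids are E01.. / M01..; epipelagic samples alternate SRF and DCM
    layers, mesopelagic samples are MES. Per-sample library-size factors
    are lognormal, so raw column sums differ while TPM removes the effect.
    ``lengths`` may supply genome lengths (bp); otherwise lengths are drawn
    uniformly on 1.5-3.0 Mbp.
    """
    rng = np.random.default_rng(spec.seed)
    epi_ids = [f"E{i + 1:02d}" for i in range(spec.n_epi_genomes)]
    meso_ids = [f"M{i + 1:02d}" for i in range(spec.n_meso_genomes)]
    genome_ids = epi_ids + meso_ids

    samples = []
    for i in range(spec.n_epi_samples):
        layer = "SRF" if i % 2 == 0 else "DCM"
        samples.append(SampleMetadata(f"S_{layer}{i + 1:02d}", layer, "sim"))
    for i in range(spec.n_meso_samples):
        samples.append(SampleMetadata(f"S_MES{i + 1:02d}", "MES", "sim"))

    if lengths is None:
        lens = pd.Series(
            rng.uniform(1.5e6, 3.0e6, size=len(genome_ids)), index=genome_ids
        )
    else:
        lens = pd.Series({g: float(lengths[g]) for g in genome_ids})

    lib = rng.lognormal(mean=0.0, sigma=0.3, size=len(samples))
    is_epi_genome = np.array([g in set(epi_ids) for g in genome_ids])
    is_epi_sample = np.array([s.depth_layer in ("SRF", "DCM") for s in samples])
    matched = np.equal.outer(is_epi_genome, is_epi_sample)
    # expected counts scale with genome length relative to the cohort mean,
    # so base_mean stays meaningful at any simulated genome scale
    mu = spec.base_mean * (lens.to_numpy()[:, None] / lens.mean()) * lib[None, :]
    mu = np.where(matched, mu, mu / spec.depth_effect)
    counts = _nb_draw(rng, mu, spec.dispersion).astype(float)

    matrix = AbundanceMatrix(
        pd.DataFrame(counts, index=genome_ids, columns=[s.sample_id for s in samples]),
        lens,
    )
    truth = SimTruth(
        habitat_labels={g: ("epipelagic" if e else "mesopelagic")
                        for g, e in zip(genome_ids, is_epi_genome)}
    )
    return matrix, samples, truth


def simulate_og_enrichment(
    n_epi: int = 20,
    n_meso: int = 20,
    n_families: int = 100,
    n_enriched: int = 10,
    presence_hi: float = 0.9,
    presence_lo: float = 0.1,
    null_presence: float = 0.5,
    seed: int = 0,
    genome_ids: Sequence[str] | None = None,
) -> tuple[AnnotationTable, SimTruth]:
    """Simulate family presence/absence with planted habitat enrichment.

    ``n_enriched`` of the ``n_families`` families are enriched, alternating
    between the epipelagic and mesopelagic directions: present with
    probability ``presence_hi`` in the favoured group and ``presence_lo``
    in the other. The remaining families are null with the common
    ``null_presence`` probability in both groups.
    """
    if not (0.0 <= presence_lo < presence_hi <= 1.0):
        raise ValueError("need 0 <= presence_lo < presence_hi <= 1")
    if not (0.0 <= null_presence <= 1.0):
        raise ValueError("null_presence must be a probability")
    if not (0 <= n_enriched <= n_families):
        raise ValueError("n_enriched must be in [0, n_families]")
    rng = np.random.default_rng(seed)
    if genome_ids is None:
        genome_ids = [f"E{i + 1:02d}" for i in range(n_epi)] + [
            f"M{i + 1:02d}" for i in range(n_meso)
        ]
    elif len(genome_ids) != n_epi + n_meso:
        raise ValueError("genome_ids length must equal n_epi + n_meso")
    is_epi = [i < n_epi for i in range(n_epi + n_meso)]

    table = AnnotationTable()
    truth = SimTruth(
        habitat_labels={g: ("epipelagic" if e else "mesopelagic")
                        for g, e in zip(genome_ids, is_epi)}
    )
    for g in genome_ids:
        table.add_genome(g)
    for f in range(n_families):
        enriched = f < n_enriched
        if enriched:
            direction = "epipelagic" if f % 2 == 0 else "mesopelagic"
            fam = f"FAMENR{f + 1:04d}"
            truth.enriched_families[fam] = direction
        else:
            fam = f"FAM{f + 1:04d}"
        for g, epi in zip(genome_ids, is_epi):
            if enriched:
                favoured = (direction == "epipelagic") == epi
                p = presence_hi if favoured else presence_lo
            else:
                p = null_presence
            if rng.random() < p:
                table.add(g, f"{g}_{fam}", fam)
    return table, truth


# ---------------------------------------------------------------------------
# Coherent end-to-end study


@dataclass
class StudyData:
    """A full synthetic study: genomes, QC, annotations, abundances, truth."""

    genomes: list[GenomeAnnotation]
    qc_records: list[QCRecord]
    annotations: AnnotationTable
    abundance: AbundanceMatrix
    samples: list[SampleMetadata]
    truth: SimTruth


#: Habitat-specific genome composition defaults used by simulate_study.
#: Epipelagic genomes are streamlined: lower GC, shorter spacers, and
#: nitrogen-bearing residues downweighted (lower N-ARSC).
EPI_GC, MESO_GC = 0.34, 0.44
EPI_IGS, MESO_IGS = 40, 80
_EPI_AA = {
    aa: w * (0.7 if SIDE_CHAIN_ATOMS[aa][1] > 0 else 1.0)
    for aa, w in DEFAULT_AA_WEIGHTS.items()
}


def simulate_study(
    abundance_spec: AbundanceSimSpec | None = None,
    n_families: int = 100,
    n_enriched: int = 10,
    seed: int = 0,
    genes_per_contig: int = 10,
    n_contigs: int = 5,
) -> StudyData:
    """Generate a coherent synthetic study with habitat-linked structure.

    Epipelagic genomes get streamlined composition (GC 34%, 40 nt spacers,
    low-N proteomes) and an NQR spike; mesopelagic genomes get GC 44%,
    80 nt spacers and a cNDH spike; all genomes carry nNDH. Abundances use
    the simulated assembly lengths, and the enrichment table shares the
    genome ids, so every stage sees one consistent dataset.
    """
    rng = np.random.default_rng(seed)
    spec = abundance_spec or AbundanceSimSpec(seed=int(rng.integers(2**31)))

    # genomes first: their realised lengths feed TPM normalisation
    genome_specs: dict[str, GenomeSimSpec] = {}
    n_epi, n_meso = spec.n_epi_genomes, spec.n_meso_genomes
    ids = [f"E{i + 1:02d}" for i in range(n_epi)] + [
        f"M{i + 1:02d}" for i in range(n_meso)
    ]
    genomes, qc_records = [], []
    truth = SimTruth()
    for gid in ids:
        epi = gid.startswith("E")
        gspec = GenomeSimSpec(
            n_contigs=n_contigs,
            genes_per_contig=genes_per_contig,
            igs_len_mean=EPI_IGS if epi else MESO_IGS,
            target_gc=EPI_GC if epi else MESO_GC,
            aa_weights=_EPI_AA if epi else DEFAULT_AA_WEIGHTS,
            seed=int(rng.integers(2**31)),
        )
        genome, qc, gtruth = simulate_genome(
            gspec,
            genome_id=gid,
            completeness=float(rng.uniform(0.6, 1.0)),
            contamination=float(rng.uniform(0.0, 0.03)),
        )
        genomes.append(genome)
        qc_records.append(qc)
        truth.update(gtruth)

    lengths = {g.genome_id: float(g.assembly_bp) for g in genomes}
    abund_spec = AbundanceSimSpec(
        n_epi_genomes=n_epi,
        n_meso_genomes=n_meso,
        n_epi_samples=spec.n_epi_samples,
        n_meso_samples=spec.n_meso_samples,
        depth_effect=spec.depth_effect,
        dispersion=spec.dispersion,
        seed=spec.seed,
        base_mean=spec.base_mean,
    )
    abundance, samples, atruth = simulate_abundance(abund_spec, lengths=lengths)
    truth.update(atruth)

    annotations, etruth = simulate_og_enrichment(
        n_epi=n_epi,
        n_meso=n_meso,
        n_families=n_families,
        n_enriched=n_enriched,
        seed=int(rng.integers(2**31)),
        genome_ids=ids,
    )
    truth.update(etruth)
    for gid in ids:
        epi = gid.startswith("E")
        annotations = spike_complex(annotations, gid, "NQR" if epi else "cNDH",
                                    6 if epi else 12)
        annotations = spike_complex(annotations, gid, "nNDH", 8)

    return StudyData(genomes, qc_records, annotations, abundance, samples, truth)
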