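"""TPM normalisation, biogeographic clustering and habitat assignment.

Read counts recruited to each genome are normalised with the TPM metric
(transcripts per kilobase million), which corrects jointly for genome
length and library size: per sample, rate_i = counts_i / (length_i / 1000)
and TPM_i = 1e6 * rate_i / sum_j rate_j. TPM values are log10-transformed
with a pseudocount (default 1, so zero counts stay at zero log-abundance),
genome profiles are compared by Pearson correlation across samples, the
correlations are turned into distances as d = 1 - r, and genomes are
clustered by average-linkage (UPGMA-style) agglomeration. Cutting the
genome dendrogram into two groups and comparing each group's mean
log-abundance in epipelagic (SRF + DCM) versus mesopelagic (MES) samples
yields the habitat labels; OMZ samples are excluded from that vote but do
contribute to the distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_formats import AbundanceMatrix, SampleMetadata

logger = logging.getLogger(__name__)

EPIPELAGIC_LAYERS = frozenset({"SRF", "DCM"})
MESOPELAGIC_LAYERS = frozenset({"MES"})


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """TPM-normalise a genome x sample count matrix.

    Columns with any nonzero count sum to 1e6; an all-zero sample column
    stays all-zero.
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("all genome lengths must be positive")
    rate = counts.div(lengths / 1000.0, axis=0)
    colsum = rate.sum(axis=0)
    # avoid 0/0 for empty samples; their TPM column is defined as all zero
    safe = colsum.replace(0.0, np.nan)
    tpm = rate.div(safe, axis=1) * 1.0e6
    return tpm.fillna(0.0)


def log_transform(tpm: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log10(tpm + pseudocount)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return np.log10(tpm + pseudocount)


def correlation_distance(logtpm: pd.DataFrame) -> pd.DataFrame:
    """Pairwise distance d = 1 - Pearson r between row profiles.

    Requires at least two samples. Rows with zero variance have no defined
    correlation; their distances are NaN and they are excluded from
    clustering (with a warning) rather than given arbitrary values.
    """
    if logtpm.shape[1] < 2:
        raise ValueError("need >= 2 samples to correlate profiles")
    values = logtpm.to_numpy(dtype=float)
    sd = values.std(axis=1)
    degenerate = np.flatnonzero(sd == 0.0)
    if degenerate.size:
        logger.warning(
            "zero-variance profiles excluded from clustering: %s",
            [logtpm.index[i] for i in degenerate],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d[degenerate, :] = np.nan
    d[:, degenerate] = np.nan
    ok = np.isfinite(d)
    d[ok] = np.clip(d[ok], 0.0, 2.0)
    return pd.DataFrame(d, index=logtpm.index, columns=logtpm.index)


@dataclass
class ClusterResult:
    """Average-linkage hierarchy over a set of items plus a k-cut."""

    ids: list[str]
    linkage_matrix: np.ndarray
    groups: dict[str, int]
    excluded: list[str] = field(default_factory=list)

    def group_members(self, group: int) -> list[str]:
        return [i for i, g in self.groups.items() if g == group]


def cluster_from_distances(dist: pd.DataFrame, k: int = 2) -> ClusterResult:
    """Average-linkage clustering of a symmetric distance matrix, cut to k.

    Rows/columns whose distances are NaN (zero-variance profiles) are
    dropped before clustering and reported in ``excluded``.
    """
    mask = ~dist.isna().all(axis=1)
    usable = dist.loc[mask, mask.index[mask]]
    excluded = [i for i in dist.index if i not in usable.index]
    ids = list(usable.index)
    if len(ids) < k:
        raise ValueError(f"cannot cut {len(ids)} items into {k} groups")
    condensed = squareform(usable.to_numpy(dtype=float), checks=False)
    Z = linkage(condensed, method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(ids, Z, dict(zip(ids, (int(x) for x in labels))), excluded)


def cluster_genomes(dist: pd.DataFrame, k: int = 2) -> ClusterResult:
    """Cluster genome rows of a correlation-distance matrix."""
    return cluster_from_distances(dist, k=k)


def cluster_samples(logtpm: pd.DataFrame, k: int = 2) -> ClusterResult:
    """Cluster sample columns by the same correlation-distance recipe."""
    return cluster_from_distances(correlation_distance(logtpm.T), k=k)


def to_newick(result: ClusterResult) -> str:
    """Serialise the dendrogram as a Newick string with branch lengths."""
    from scipy.cluster.hierarchy import to_tree

    root = to_tree(result.linkage_matrix)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{result.ids[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    if root.is_leaf():
        return f"{result.ids[root.id]}:0;"
    left = render(root.left, root.dist)
    right = render(root.right, root.dist)
    return f"({left},{right});"


@dataclass
class HabitatAssignment:
    """Genome -> habitat labels plus the group evidence behind them."""

    labels: dict[str, str]
    groups: dict[str, int]
    group_layer_means: pd.DataFrame  # group x (epipelagic, mesopelagic) mean logtpm


def assign_habitat(
    clusters: ClusterResult,
    logtpm: pd.DataFrame,
    samples: Sequence[SampleMetadata],
) -> HabitatAssignment:
    """Label the two genome groups epipelagic / mesopelagic.

    For each group, mean log-TPM is computed over epipelagic-pool samples
    (SRF, DCM) and over mesopelagic samples (MES); the group with the
    larger epipelagic-minus-mesopelagic difference is epipelagic. OMZ
    samples do not vote.
    """
    group_ids = sorted(set(clusters.groups.values()))
    if len(group_ids) != 2:
        raise ValueError(f"habitat labeling needs exactly 2 groups, got {len(group_ids)}")
    layer = {s.sample_id: s.depth_layer for s in samples}
    missing = [c for c in logtpm.columns if c not in layer]
    if missing:
        raise KeyError(f"samples missing from metadata: {missing}")
    epi_cols = [c for c in logtpm.columns if layer[c] in EPIPELAGIC_LAYERS]
    mes_cols = [c for c in logtpm.columns if layer[c] in MESOPELAGIC_LAYERS]
    if not epi_cols or not mes_cols:
        raise ValueError("need both SRF/DCM and MES samples to determine habitat labels")

    rows = {}
    for g in group_ids:
        members = clusters.group_members(g)
        sub = logtpm.loc[members]
        rows[g] = {
            "epipelagic_mean": float(sub[epi_cols].to_numpy().mean()),
            "mesopelagic_mean": float(sub[mes_cols].to_numpy().mean()),
        }
    means = pd.DataFrame.from_dict(rows, orient="index")
    diff = means["epipelagic_mean"] - means["mesopelagic_mean"]
    epi_group = int(diff.idxmax())
    labels = {
        genome: ("epipelagic" if grp == epi_group else "mesopelagic")
        for genome, grp in clusters.groups.items()
    }
    return HabitatAssignment(labels, dict(clusters.groups), means)
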