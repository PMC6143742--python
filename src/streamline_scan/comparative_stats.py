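"""Between-habitat statistics: feature shifts and family enrichment.

Streamlining features are compared between epipelagic and mesopelagic
genomes with the two-sided Mann-Whitney U test, overall and within each
clade that has at least ``min_per_group`` genomes in BOTH habitat groups.
Family (orthologous-group) enrichment is tested per family with the
two-sided Fisher exact test on the presence/absence x habitat 2x2 table,
with Benjamini-Hochberg correction across families; a family is called
enriched when its corrected p-value falls below the q threshold
(default 0.01), in the direction of the higher presence fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import AnnotationTable

logger = logging.getLogger(__name__)

#: Largest n_A * n_B for which the exact Mann-Whitney null distribution is
#: enumerated (ties force the tie-corrected normal approximation).
EXACT_MWU_MAX_PRODUCT = 400

FEATURE_NAMES = ("gc_percent", "mean_igs", "n_arsc", "c_arsc", "est_size")


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class GroupComparison:
    """One feature x clade Mann-Whitney comparison between habitat groups."""

    feature: str
    clade: str
    n_epi: int
    n_meso: int
    U: float
    p: float

    @property
    def stars(self) -> str:
        return _stars(self.p)


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher-exact presence/absence enrichment for one family.

    The 2x2 table is (present, absent) x (epipelagic, mesopelagic):
    ``epi_present``/``epi_absent`` and ``meso_present``/``meso_absent``.
    """

    family_id: str
    epi_present: int
    epi_absent: int
    meso_present: int
    meso_absent: int
    odds_ratio: float
    p: float
    q: float
    enriched_in: str  # epipelagic | mesopelagic | none


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    The exact enumerated null distribution is used when n_x * n_y <= 400
    and the pooled data are tie-free; otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and x.size * y.size <= EXACT_MWU_MAX_PRODUCT:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_features(
    features: Mapping[str, Mapping[str, float | None]],
    habitat: Mapping[str, str],
    clades: Mapping[str, str] | None = None,
    min_per_group: int = 2,
) -> list[GroupComparison]:
    """Mann-Whitney comparisons of each feature, for "All" and per clade.

    ``features`` maps genome_id -> {feature name -> value}; missing values
    (None/NaN, e.g. an undefined intergenic mean) are dropped per feature.
    Clades with fewer than ``min_per_group`` genomes in either habitat
    group are skipped with a log entry, mirroring the exclusion of clades
    lacking multiple genomes in both groups.
    """
    genomes = [g for g in features if g in habitat]
    strata: list[tuple[str, list[str]]] = [("All", genomes)]
    if clades is not None:
        for clade in sorted(set(clades[g] for g in genomes if g in clades)):
            strata.append((clade, [g for g in genomes if clades.get(g) == clade]))

    out: list[GroupComparison] = []
    for label, members in strata:
        epi = [g for g in members if habitat[g] == "epipelagic"]
        meso = [g for g in members if habitat[g] == "mesopelagic"]
        if label != "All" and (len(epi) < min_per_group or len(meso) < min_per_group):
            logger.info(
                "clade %s skipped: %d epipelagic / %d mesopelagic genomes "
                "(need >= %d in both)", label, len(epi), len(meso), min_per_group,
            )
            continue
        for feat in FEATURE_NAMES:
            xv = [features[g].get(feat) for g in epi]
            yv = [features[g].get(feat) for g in meso]
            xv = [v for v in xv if v is not None and np.isfinite(v)]
            yv = [v for v in yv if v is not None and np.isfinite(v)]
            if not xv or not yv:
                continue
            U, p = mann_whitney(xv, yv)
            out.append(GroupComparison(feat, label, len(xv), len(yv), U, p))
    return out


def fisher_enrichment(
    table: AnnotationTable,
    habitat: Mapping[str, str],
    q_threshold: float = 0.01,
    method: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Per-family Fisher exact enrichment between the two habitat groups.

    Presence/absence (not copy number) of each family is crossed with the
    habitat label; the two-sided Fisher p is the hypergeometric tail sum
    over tables at most as probable as the observed one. Corrected
    q-values come from ``method`` (Benjamini-Hochberg by default;
    ``bonferroni`` and ``holm`` are accepted).
    """
    epi = [g for g in table.genomes if habitat.get(g) == "epipelagic"]
    meso = [g for g in table.genomes if habitat.get(g) == "mesopelagic"]
    if len(epi) < 2 or len(meso) < 2:
        raise ValueError("need >= 2 genomes per habitat group")
    families = sorted(set().union(*(table.families(g) for g in epi + meso)))

    results = []
    pvals = []
    for fam in families:
        a = sum(1 for g in epi if fam in table.families(g))
        b = len(epi) - a
        c = sum(1 for g in meso if fam in table.families(g))
        d = len(meso) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        results.append((fam, a, b, c, d, float(odds)))
        pvals.append(p)

    if not results:
        return []
    _, qvals, _, _ = multipletests(pvals, method=method)
    out = []
    for (fam, a, b, c, d, odds), p, q in zip(results, pvals, qvals):
        if q < q_threshold:
            frac_epi = a / (a + b)
            frac_meso = c / (c + d)
            direction = "epipelagic" if frac_epi > frac_meso else "mesopelagic"
        else:
            direction = "none"
        out.append(EnrichmentResult(fam, a, b, c, d, odds, float(p), float(q), direction))
    return out
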