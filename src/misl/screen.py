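"""Validation statistics for pooled shRNA screens and candidate lists.

Four independent analyses live here:

* dropout hit calling for barcode-count screens (read floor, redundancy
  requirement, per-construct reduction gate, per-gene mean-ratio gate);
* mutation-stratified essentiality ranking for per-cell-line score
  screens (per-construct Welch t-test, min-p construct per gene, score
  ``-log10(p) * (mean_wt - mean_mut)`` so more-essential-in-mutants is
  positive);
* preranked gene-set enrichment (weighted Kolmogorov-Smirnov running sum
  with a gene-label permutation null);
* overlap and same-pathway hypergeometric tests with redundancy pruning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import cached_fisher_two_sided
from .errors import MislError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class EssentialityRanking:
    """Genes ordered by differential-essentiality score (descending)."""

    scores: pd.Series  # index: gene, sorted descending, ties by symbol

    @property
    def ordering(self) -> list[str]:
        return list(self.scores.index)


@dataclass
class EnrichmentResult:
    es: float
    nes: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass
class PathwayEnrichment:
    pathway: str
    overlap_genes: set[str]
    p_value: float


def call_dropout_hits(
    screen: pd.DataFrame,
    baseline_condition: str,
    treated_condition: str,
    min_reads: int = 100,
    min_constructs: int = 3,
    reduction: float = 0.2,
    mean_ratio: float = 0.6,
    min_hit_constructs: int = 2,
    apply_reduction_gate: bool = True,
    apply_mean_ratio_gate: bool = True,
) -> set[str]:
    """Genes whose constructs drop out under treatment.

    Constructs with baseline reads below ``min_reads`` are excluded; genes
    with fewer than ``min_constructs`` surviving constructs are excluded.
    A construct qualifies if its treated/baseline ratio shows more than
    ``reduction`` reduction (ratio < 1 - reduction); a gene is a hit if at
    least ``min_hit_constructs`` constructs qualify and the mean ratio over
    its qualifying constructs is below ``mean_ratio``.  Each gate can be
    switched off independently.
    """
    for col in (baseline_condition, treated_condition):
        if col not in screen.columns:
            raise MislError(f"condition column {col!r} not in screen table")
    df = screen[screen[baseline_condition] >= max(min_reads, 1)].copy()
    df["ratio"] = df[treated_condition] / df[baseline_condition]
    counts = df.groupby("gene")["ratio"].count()
    eligible = set(counts.index[counts >= min_constructs])
    hits: set[str] = set()
    for gene, sub in df[df["gene"].isin(eligible)].groupby("gene"):
        qualifying = sub["ratio"][sub["ratio"] < 1.0 - reduction]
        if apply_reduction_gate and len(qualifying) < min_hit_constructs:
            continue
        if apply_mean_ratio_gate:
            pool = qualifying if apply_reduction_gate else sub["ratio"]
            if len(pool) == 0 or float(pool.mean()) >= mean_ratio:
                continue
        hits.add(gene)
    return hits


def score_mutation_essentiality(
    screen: pd.DataFrame,
    mutated_lines: list[str],
    wildtype_lines: list[str],
    min_constructs: int = 3,
) -> EssentialityRanking:
    """Rank genes by differential essentiality in mutated cell lines.

    ``screen`` holds per-cell-line shRNA summary scores (lower = more
    depleted = more essential).  Per construct, a Welch t-test compares
    mutated and wild-type lines; per gene the minimum-p construct is kept
    and scored ``-log10(p) * (mean_wt - mean_mut)``, so genes preferentially
    essential in mutants score positive.  Genes with fewer than
    ``min_constructs`` constructs are removed.
    """
    if not mutated_lines or not wildtype_lines:
        raise MislError("both line groups must be non-empty")
    for line in list(mutated_lines) + list(wildtype_lines):
        if line not in screen.columns:
            raise MislError(f"cell line {line!r} not in screen table")
    counts = screen.groupby("gene")["construct_id"].count()
    keep = set(counts.index[counts >= min_constructs])
    df = screen[screen["gene"].isin(keep)]
    mut = df[list(mutated_lines)].to_numpy(dtype=float)
    wt = df[list(wildtype_lines)].to_numpy(dtype=float)
    t, p = stats.ttest_ind(mut, wt, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    per_construct = pd.DataFrame(
        {
            "gene": df["gene"].to_numpy(),
            "p": p,
            "diff": wt.mean(axis=1) - mut.mean(axis=1),
        }
    )
    best = per_construct.loc[per_construct.groupby("gene")["p"].idxmin()]
    scores = pd.Series(
        (-np.log10(best["p"].to_numpy())) * best["diff"].to_numpy(),
        index=best["gene"].to_numpy(),
        name="score",
    )
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    return EssentialityRanking(scores=scores.loc[order])


def _running_sum_es(
    ordered_scores: np.ndarray, hit_mask: np.ndarray, weight: float
) -> float:
    """Signed enrichment score: the running-sum value of maximum deviation."""
    n = ordered_scores.size
    nh = int(hit_mask.sum())
    w = np.abs(ordered_scores) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit scores zero: fall back to unweighted steps
        hit_w = hit_mask.astype(float)
        total = float(nh)
    steps = hit_w / total - (~hit_mask) / float(n - nh)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def preranked_enrichment(
    ranking: EssentialityRanking,
    gene_set: set[str],
    n_permutations: int = 2000,
    weight: float = 1.0,
    seed: int = 0,
    min_overlap: int = 25,
) -> EnrichmentResult:
    """Weighted-KS preranked enrichment of ``gene_set`` in the ranking.

    The null distribution permutes gene-set labels (random sets of the
    same size over the ranked list); NES normalises the observed ES by the
    mean magnitude of same-sign null scores, and the permutation p-value
    carries the +1 floor so it is never zero.
    """
    genes = np.array(ranking.ordering)
    scores = ranking.scores.to_numpy(dtype=float)
    hit = np.isin(genes, sorted(gene_set))
    nh = int(hit.sum())
    if nh < min_overlap:
        raise MislError(
            f"gene set overlaps ranking in {nh} genes; >= {min_overlap} required for enrichment"
        )
    if nh == genes.size:
        raise MislError("gene set covers the entire ranking; enrichment undefined")
    es = _running_sum_es(scores, hit, weight)

    rng = np.random.default_rng(seed)
    n = genes.size
    # vectorised label permutations: each row marks nh random positions
    keys = rng.random((n_permutations, n))
    idx = np.argpartition(keys, nh - 1, axis=1)[:, :nh]
    null_es = np.empty(n_permutations)
    mask = np.zeros(n, dtype=bool)
    for i in range(n_permutations):
        mask[:] = False
        mask[idx[i]] = True
        null_es[i] = _running_sum_es(scores, mask, weight)

    # nominal p against the same-sign portion of the null, the standard
    # preranked convention; this is what makes null p-values uniform
    if es >= 0:
        same = null_es[null_es >= 0]
        p = (1 + int(np.sum(same >= es))) / (1 + same.size)
    else:
        same = null_es[null_es < 0]
        p = (1 + int(np.sum(same <= es))) / (1 + same.size)
    denom = float(np.abs(same).mean()) if same.size else float(np.abs(null_es).mean())
    nes = es / denom if denom > 0 else 0.0
    return EnrichmentResult(
        es=es, nes=float(nes), p_value=float(p), n_permutations=n_permutations, seed=seed
    )


def overlap_test(
    list_a: set[str], list_b: set[str], universe: set[str]
) -> tuple[int, float]:
    """Two-sided Fisher exact test of two gene sets' overlap in a universe."""
    if not universe:
        raise ValidationError("empty universe")
    if not (set(list_a) <= set(universe) and set(list_b) <= set(universe)):
        raise ValidationError("both gene lists must be subsets of the universe")
    a, b = set(list_a), set(list_b)
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(universe) - n11 - n10 - n01
    return n11, cached_fisher_two_sided(n11, n10, n01, n00)


def same_pathway_enrichment(
    candidates: set[str],
    mutation_gene: str,
    pathways: dict[str, set[str]],
    universe: set[str],
    max_pathway_size: int = 500,
) -> list[PathwayEnrichment]:
    """Hypergeometric enrichment of candidates in the mutation's pathways.

    Only pathways containing ``mutation_gene`` and with at most
    ``max_pathway_size`` members are tested.  Redundancy pruning: among
    pathways with identical candidate-overlap sets only the smallest-p one
    is kept, and a pathway whose overlap set is strictly contained in
    another retained pathway's overlap set is removed.
    """
    if not set(candidates) <= set(universe):
        raise ValidationError("candidates must be a subset of the universe")
    n_universe = len(universe)
    n_cand = len(candidates)
    results: list[PathwayEnrichment] = []
    for name in sorted(pathways):
        members = pathways[name] & universe
        if mutation_gene not in pathways[name]:
            continue
        if len(pathways[name]) > max_pathway_size:
            continue
        overlap = candidates & members
        k = len(overlap)
        # P(X >= k) drawing |candidates| from the universe with |members| marked
        p = float(stats.hypergeom.sf(k - 1, n_universe, len(members), n_cand)) if k else 1.0
        results.append(PathwayEnrichment(pathway=name, overlap_genes=overlap, p_value=p))

    # identical overlap sets: keep the smallest p (ties: first by name)
    by_overlap: dict[frozenset, PathwayEnrichment] = {}
    for r in results:
        key = frozenset(r.overlap_genes)
        prev = by_overlap.get(key)
        if prev is None or r.p_value < prev.p_value:
            by_overlap[key] = r
    deduped = list(by_overlap.values())
    # strict containment: drop pathways whose overlap is a proper subset of another's
    kept = [
        r
        for r in deduped
        if not any(
            r is not other and r.overlap_genes < other.overlap_genes for other in deduped
        )
    ]
    kept.sort(key=lambda r: (r.p_value, r.pathway))
    return kept
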