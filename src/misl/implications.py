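"""Boolean implication mining between alteration variables.

An implication ``A => B`` (HI-HI) or ``A => not B`` (HI-LO) is declared
when the 2x2 cross-tabulation of the two Boolean variables over the pooled
samples passes two gates:

1. dependence — two-sided Fisher exact p below a cutoff (always < 0.05,
   tightened by permutation FDR calibration), and
2. sparseness — a maximum-likelihood error-rate estimate for the quadrant
   the implication forbids below 0.1.  With ``a`` the sparse-quadrant
   count, ``r`` the other count in its row and ``c`` the other count in
   its column, ``e = 0.5 * (a/(a+r) + a/(a+c))`` — the average of the two
   conditional violation probabilities.

HI-HI extraction is augmented with artificial normal samples (all-false
columns) so that alterations present in nearly every tumour sample remain
testable; HI-LO extraction never is.

Variables are named ``GENE:mut``, ``GENE:amp``, ``GENE:del`` (and
``GENE:mut:<type>`` for per-type runs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from ._stats import cached_fisher_two_sided, fisher_p_array
from .booleanize import CancerCohort, PassengerAnnotation
from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_ERROR_CUTOFF = 0.1


class ImplicationKind(str, Enum):
    HI_HI = "hi_hi"
    HI_LO = "hi_lo"


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of (A, B) value pairs; A is always the antecedent."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValidationError("negative contingency count")
        if self.total == 0:
            raise ValidationError("empty contingency table")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass
class BooleanImplication:
    """A directed implication with the statistics of both gates."""

    antecedent: str
    consequent: str
    kind: ImplicationKind
    fisher_p: float
    error_rate: float
    sparse_quadrant_count: int
    n_samples: int
    cancer_types_used: list[str] = field(default_factory=list)


@dataclass
class FdrCalibration:
    """Permutation-FDR estimates over a grid of Fisher cutoffs."""

    cutoff_grid: list[float]
    observed_counts: list[int]
    null_mean_counts: list[float]
    fdr_at_cutoff: list[float]
    chosen_cutoff: float
    n_permutations: int
    seed: int


def parse_variable(var: str) -> tuple[str, str]:
    """Split ``GENE:class[:subtype]`` into (gene, class)."""
    parts = var.split(":")
    if len(parts) < 2 or parts[1] not in ("mut", "amp", "del"):
        raise ValidationError(f"bad variable id {var!r}; expected GENE:mut|amp|del")
    return parts[0], parts[1]


def contingency(a, b) -> ContingencyTable:
    """Exact pairwise counts of two equal-length Boolean vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("contingency requires equal-length 1-D vectors")
    if a.size == 0:
        raise ValidationError("empty vectors")
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n00 = int(a.size - n11 - n10 - n01)
    return ContingencyTable(n11, n10, n01, n00)


def fisher_p(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p; 1.0 for any zero margin."""
    return cached_fisher_two_sided(t.n11, t.n10, t.n01, t.n00)


def _sparse_quadrant(t: ContingencyTable, kind: ImplicationKind) -> tuple[int, int, int]:
    """(a, r, c): sparse count, row partner, column partner, per kind."""
    if kind == ImplicationKind.HI_HI:
        # A => B: sparse quadrant is (A=1, B=0)
        return t.n10, t.n11, t.n00
    # A => not B: sparse quadrant is (A=1, B=1)
    return t.n11, t.n10, t.n01


def error_rate(t: ContingencyTable, kind: ImplicationKind) -> float:
    """ML error-rate estimate for the forbidden quadrant of ``kind``."""
    a, r, c = _sparse_quadrant(t, kind)
    return _error_rate_arc(a, r, c)


def _error_rate_arc(a: int, r: int, c: int) -> float:
    if a == 0:
        return 0.0
    if a + r == 0 or a + c == 0:
        return 1.0
    return 0.5 * (a / (a + r) + a / (a + c))


def augment_artificial_normals(matrices, k: int):
    """Append ``k`` all-false samples to every alteration matrix.

    Accepts one DataFrame or a sequence of them; artificial sample columns
    are named ``__AN0__``...  Applied only during HI-HI extraction — the
    all-negative samples can never violate a HI-HI implication's sparse
    quadrant but restore a non-degenerate margin for near-ubiquitous
    alterations.
    """
    if k < 0:
        raise ValidationError("k must be >= 0")

    def one(m: pd.DataFrame) -> pd.DataFrame:
        if k == 0:
            return m
        extra = pd.DataFrame(
            False, index=m.index, columns=[f"__AN{i}__" for i in range(k)]
        )
        return pd.concat([m, extra], axis=1)

    if isinstance(matrices, pd.DataFrame):
        return one(matrices)
    return type(matrices)(one(m) for m in matrices)


def pair_statistics(
    A: np.ndarray, B: np.ndarray, kind: ImplicationKind
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fisher p, error rate and sparse count for every (row of A, row of B).

    ``A`` (antecedents) and ``B`` (consequents) are Boolean matrices over
    the same sample axis.  Cross-tabulation is done by matrix product and
    Fisher p computed once per distinct 2x2 table, which is what makes
    whole-cohort scans and permutation nulls tractable.
    """
    A = np.ascontiguousarray(np.asarray(A, dtype=bool))
    B = np.ascontiguousarray(np.asarray(B, dtype=bool))
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValidationError("pair_statistics requires matrices sharing the sample axis")
    n = A.shape[1]
    Ai = A.astype(np.int64)
    Bi = B.astype(np.int64)
    n11 = Ai @ Bi.T
    ra = Ai.sum(axis=1)[:, None]
    cb = Bi.sum(axis=1)[None, :]
    n10 = ra - n11
    n01 = cb - n11
    n00 = n - ra - cb + n11
    tables = np.stack([n11, n10, n01, n00], axis=-1)
    p = fisher_p_array(tables.reshape(-1, 4)).reshape(n11.shape)
    if kind == ImplicationKind.HI_HI:
        a, r, c = n10, n11, n00
    else:
        a, r, c = n11, n10, n01
    with np.errstate(divide="ignore", invalid="ignore"):
        e = 0.5 * (a / (a + r) + a / (a + c))
    e = np.where((a + r == 0) | (a + c == 0), 1.0, e)
    e = np.where(a == 0, 0.0, e)
    return p, e, a


def _passenger_map(
    passenger_filter, alteration: str
) -> dict[tuple[str, str], bool]:
    """(cancer_type, gene) -> is_passenger for the given alteration class."""
    out: dict[tuple[str, str], bool] = {}
    if passenger_filter is None:
        return out
    for ann in passenger_filter:
        if isinstance(ann, PassengerAnnotation):
            if ann.alteration == alteration:
                out[(ann.cancer_type, ann.gene)] = ann.is_passenger
        else:
            raise ValidationError("passenger_filter must contain PassengerAnnotation")
    return out


def _variable_vector(cohort: CancerCohort, var: str) -> np.ndarray:
    gene, cls = parse_variable(var)
    m = cohort.alteration_matrix(cls)
    if var.count(":") >= 2 and cls == "mut":  # per-type variable
        key = var.split(":", 1)[1]
        row = f"{gene}:{key.split(':', 1)[1]}"
    else:
        row = gene
    if row in m.index:
        return m.loc[row].to_numpy(dtype=bool)
    return np.zeros(cohort.n_samples, dtype=bool)


def scan_implications(
    cohorts: list[CancerCohort],
    anchor: str,
    kind: ImplicationKind,
    passenger_filter: list[PassengerAnnotation] | None = None,
    fisher_cutoff: float = 0.05,
    error_cutoff: float = DEFAULT_ERROR_CUTOFF,
    artificial_normal_k: int | None = None,
) -> list[BooleanImplication]:
    """All significant implications of ``kind`` between ``anchor`` and
    partner CNA variables over the pooled cohorts.

    For HI-LO the anchor (a mutation variable) is the antecedent and
    partner deletions are consequents (``X => not B_del``); for HI-HI the
    partner amplifications are antecedents and the anchor the consequent
    (``B_amp => X``), with ``artificial_normal_k`` all-negative samples
    appended (default: as many as pooled tumour samples).

    For each partner gene, only cohorts where that gene's alteration is not
    a passenger (per ``passenger_filter``) contribute samples; cohorts
    without copy-number data never contribute.
    """
    kind = ImplicationKind(kind)
    anchor_gene, _ = parse_variable(anchor)
    partner_class = "amp" if kind == ImplicationKind.HI_HI else "del"
    pmap = _passenger_map(passenger_filter, partner_class)

    anchor_found = any(_variable_vector(c, anchor).any() for c in cohorts)
    if not anchor_found:
        logger.warning("anchor %s absent from every cohort; empty scan", anchor)
        return []

    cna_cohorts = [c for c in cohorts if len(c.alteration_matrix(partner_class).index)]
    partners: dict[str, list[CancerCohort]] = {}
    for c in cna_cohorts:
        for gene in c.alteration_matrix(partner_class).index:
            if ":" in gene or gene == anchor_gene:
                continue
            if pmap.get((c.cancer_type, gene), False):
                continue
            partners.setdefault(gene, []).append(c)

    # group partner genes sharing the same contributing cohort set so the
    # pooled cross-tabulation is computed once per group
    groups: dict[tuple[str, ...], list[str]] = {}
    for gene, contribs in partners.items():
        key = tuple(c.cancer_type for c in contribs)
        groups.setdefault(key, []).append(gene)

    results: list[BooleanImplication] = []
    by_name = {c.cancer_type: c for c in cohorts}
    for key, genes in groups.items():
        contribs = [by_name[name] for name in key]
        anchor_vec = np.concatenate([_variable_vector(c, anchor) for c in contribs])
        n_pool = anchor_vec.size
        mats = []
        for c in contribs:
            m = c.alteration_matrix(partner_class)
            block = np.zeros((len(genes), c.n_samples), dtype=bool)
            present = [i for i, g in enumerate(genes) if g in m.index]
            if present:
                block[present] = m.loc[[genes[i] for i in present]].to_numpy(dtype=bool)
            mats.append(block)
        partner_mat = np.concatenate(mats, axis=1)

        if kind == ImplicationKind.HI_HI:
            k = n_pool if artificial_normal_k is None else artificial_normal_k
            if k:
                pad_a = np.zeros(k, dtype=bool)
                anchor_vec = np.concatenate([anchor_vec, pad_a])
                partner_mat = np.concatenate(
                    [partner_mat, np.zeros((len(genes), k), dtype=bool)], axis=1
                )
            A, B = partner_mat, anchor_vec[None, :]
            p, e, a = pair_statistics(A, B, kind)
            p, e, a = p[:, 0], e[:, 0], a[:, 0]
        else:
            A, B = anchor_vec[None, :], partner_mat
            p, e, a = pair_statistics(A, B, kind)
            p, e, a = p[0], e[0], a[0]

        sig = (p < fisher_cutoff) & (e < error_cutoff)
        for i in np.flatnonzero(sig):
            gene = genes[i]
            if kind == ImplicationKind.HI_HI:
                ante, cons = f"{gene}:amp", anchor
            else:
                ante, cons = anchor, f"{gene}:del"
            results.append(
                BooleanImplication(
                    antecedent=ante,
                    consequent=cons,
                    kind=kind,
                    fisher_p=float(p[i]),
                    error_rate=float(e[i]),
                    sparse_quadrant_count=int(a[i]),
                    n_samples=int(anchor_vec.size),
                    cancer_types_used=list(key),
                )
            )
    results.sort(key=lambda r: (r.fisher_p, r.error_rate, r.antecedent, r.consequent))
    return results


def _pooled_matrices(
    cohorts: list[CancerCohort], kind: ImplicationKind
) -> tuple[np.ndarray, list[str], np.ndarray, list[str]]:
    """Pooled (mutation-anchor, partner) matrices over all cohorts' samples."""
    partner_class = "amp" if kind == ImplicationKind.HI_HI else "del"
    anchors = sorted(
        {g for c in cohorts for g in c.mut.index if ":" not in g}
    )
    parts = sorted(
        {
            g
            for c in cohorts
            for g in c.alteration_matrix(partner_class).index
            if ":" not in g
        }
    )

    def pool(genes: list[str], cls: str) -> np.ndarray:
        blocks = []
        for c in cohorts:
            m = c.alteration_matrix(cls)
            block = np.zeros((len(genes), c.n_samples), dtype=bool)
            present = [i for i, g in enumerate(genes) if g in m.index]
            if present:
                block[present] = m.loc[[genes[i] for i in present]].to_numpy(dtype=bool)
            blocks.append(block)
        return np.concatenate(blocks, axis=1)

    return pool(anchors, "mut"), anchors, pool(parts, partner_class), parts


def _count_significant(
    A: np.ndarray,
    B: np.ndarray,
    kind: ImplicationKind,
    cutoffs: np.ndarray,
    error_cutoff: float,
    exclude_same_gene: np.ndarray | None = None,
) -> np.ndarray:
    if kind == ImplicationKind.HI_HI:
        k = A.shape[1]
        A = np.concatenate([A, np.zeros((A.shape[0], k), dtype=bool)], axis=1)
        B = np.concatenate([B, np.zeros((B.shape[0], k), dtype=bool)], axis=1)
        p, e, _ = pair_statistics(B, A, kind)  # partner amp antecedent
        p, e = p.T, e.T
    else:
        p, e, _ = pair_statistics(A, B, kind)
    if exclude_same_gene is not None:
        p = np.where(exclude_same_gene, 1.0, p)
    ok = e < error_cutoff
    return np.array([int(np.sum((p < c) & ok)) for c in cutoffs])


def calibrate_fdr(
    cohorts: list[CancerCohort],
    kind: ImplicationKind,
    cutoff_grid: list[float],
    n_permutations: int = 100,
    seed: int = 0,
    error_cutoff: float = DEFAULT_ERROR_CUTOFF,
    fdr_target: float = 0.05,
) -> FdrCalibration:
    """Permutation-FDR over a Fisher-cutoff grid.

    Observed counts scan every (mutation anchor, partner CNA) pair over the
    pooled samples.  The null permutes each variable's sample labels
    independently; the FDR estimate at a cutoff is the mean null count over
    the observed count (0/0 -> 0).  The chosen cutoff is the largest grid
    value (never above ``fdr_target`` = 0.05) whose estimated FDR is below
    ``fdr_target``; if none qualifies, the grid value with the smallest
    estimated FDR is chosen.
    """
    if n_permutations < 10:
        raise ValidationError("n_permutations must be >= 10")
    kind = ImplicationKind(kind)
    cutoffs = np.asarray(sorted(cutoff_grid))
    A, anchors, B, parts = _pooled_matrices(cohorts, kind)
    same = np.array([[a == b for b in parts] for a in anchors]) if anchors and parts else None

    observed = _count_significant(A, B, kind, cutoffs, error_cutoff, same)
    rng = np.random.default_rng(seed)
    null_sum = np.zeros(len(cutoffs))
    n = A.shape[1]
    for _ in range(n_permutations):
        # independent permutation per variable: permute each row of each
        # matrix; the induced pairing is a uniform random relabelling
        Ap = np.stack([row[rng.permutation(n)] for row in A]) if len(A) else A
        Bp = np.stack([row[rng.permutation(n)] for row in B]) if len(B) else B
        null_sum += _count_significant(Ap, Bp, kind, cutoffs, error_cutoff, same)
    null_mean = null_sum / n_permutations
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(observed > 0, null_mean / np.maximum(observed, 1), np.where(null_mean > 0, 1.0, 0.0))
    fdr = np.minimum(fdr, 1.0)

    candidates = [i for i, c in enumerate(cutoffs) if c <= fdr_target]
    passing = [i for i in candidates if fdr[i] < fdr_target]
    if passing:
        chosen = float(cutoffs[max(passing)])
    elif candidates:
        chosen = float(cutoffs[min(candidates, key=lambda i: fdr[i])])
    else:
        chosen = float(min(cutoffs.min(), fdr_target))
    return FdrCalibration(
        cutoff_grid=[float(c) for c in cutoffs],
        observed_counts=[int(x) for x in observed],
        null_mean_counts=[float(x) for x in null_mean],
        fdr_at_cutoff=[float(x) for x in fdr],
        chosen_cutoff=chosen,
        n_permutations=n_permutations,
        seed=seed,
    )
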