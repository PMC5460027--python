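"""From raw tables to per-cancer Boolean alteration matrices.

The unit of downstream analysis is the :class:`CancerCohort`: one cancer
type's aligned sample set carrying three Boolean genes x samples matrices
(mutation, amplification, deletion) plus the log2 expression matrix
restricted to the same samples.

Copy-number calls follow the level-3 segmented-data recipe: keep segments
with |segment mean| > 0.3 and >= 5 markers, drop tumour segments whose
length is more than half covered by the matched normal's retained segments,
then mark a gene amplified/deleted in a sample if it overlaps a retained
segment of the corresponding sign.

Passenger annotation separates driver-like copy-number events from genes
carried along in large chromosomal alterations: an event is a passenger
unless its own expression moves concordantly (Welch t-test p < 0.05 and
fold difference > 1.2 between altered and unaltered samples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import welch_t
from .errors import ValidationError

logger = logging.getLogger(__name__)

SEGMENT_MEAN_THRESHOLD = 0.3
MIN_MARKERS = 5
NORMAL_OVERLAP_THRESHOLD = 0.5


@dataclass
class CancerCohort:
    """One cancer type's aligned Boolean alteration + expression matrices.

    ``mut``, ``amp`` and ``del_`` are Boolean DataFrames (genes x samples)
    sharing the sample axis with ``expr``; a gene may appear in any subset
    of the three.  Cohorts without copy-number data carry empty ``amp`` /
    ``del_`` frames (zero rows) and participate in implication scans only
    through other cohorts' CNA matrices.
    """

    cancer_type: str
    samples: list[str]
    mut: pd.DataFrame
    amp: pd.DataFrame
    del_: pd.DataFrame
    expr: pd.DataFrame
    gene_chrom: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, m in (("mut", self.mut), ("amp", self.amp), ("del", self.del_)):
            if len(m.columns) and list(m.columns) != list(self.samples):
                raise ValidationError(
                    f"{self.cancer_type}: {name} matrix samples do not match cohort samples"
                )
        if len(self.amp.index) and len(self.del_.index):
            shared = self.amp.index.intersection(self.del_.index)
            if len(shared):
                both = (self.amp.loc[shared] & self.del_.loc[shared]).to_numpy()
                if both.any():
                    raise ValidationError(
                        f"{self.cancer_type}: gene amplified and deleted in the same sample"
                    )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def has_cna(self) -> bool:
        return len(self.amp.index) > 0 or len(self.del_.index) > 0

    def alteration_matrix(self, kind: str) -> pd.DataFrame:
        return {"mut": self.mut, "amp": self.amp, "del": self.del_}[kind]


@dataclass
class PassengerAnnotation:
    """Expression-concordance verdict for one (cancer, gene, alteration)."""

    cancer_type: str
    gene: str
    alteration: str  # "amp" | "del"
    is_passenger: bool
    p_value: float
    fold_difference: float

    def __post_init__(self) -> None:
        if self.fold_difference <= 0:
            raise ValidationError("fold_difference must be positive")


def booleanize_mutations(
    mut_table: pd.DataFrame, samples: list[str], per_type: bool = False
) -> pd.DataFrame:
    """Build the Boolean mutation matrix (genes x samples).

    A gene-level variable is true in a sample iff any mutation of that gene
    was recorded.  With ``per_type``, additional ``gene:type`` rows are
    emitted for each mutation type observed for that gene.
    """
    if not samples:
        raise ValidationError("samples must be non-empty")
    rows = mut_table[mut_table["sample_id"].isin(samples)]
    variables: dict[str, set[str]] = {}
    for gene, sub in rows.groupby("gene"):
        variables[gene] = set(sub["sample_id"])
        if per_type:
            for mtype, sub2 in sub.groupby("mutation_type"):
                variables[f"{gene}:{mtype}"] = set(sub2["sample_id"])
    index = sorted(variables)
    mat = pd.DataFrame(False, index=pd.Index(index, name="gene"), columns=samples)
    for var, carriers in variables.items():
        mat.loc[var, list(carriers)] = True
    return mat


def filter_segments(seg: pd.DataFrame) -> pd.DataFrame:
    """Keep segments with |segment_mean| > 0.3 (strict) and >= 5 markers."""
    keep = (seg["segment_mean"].abs() > SEGMENT_MEAN_THRESHOLD) & (
        seg["n_markers"] >= MIN_MARKERS
    )
    return seg[keep].reset_index(drop=True)


def _merged_intervals(starts: np.ndarray, ends: np.ndarray) -> list[tuple[int, int]]:
    order = np.argsort(starts)
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts[order], ends[order]):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], int(e)))
        else:
            merged.append((int(s), int(e)))
    return merged


def subtract_normal(tumour_seg: pd.DataFrame, normal_seg: pd.DataFrame) -> pd.DataFrame:
    """Drop tumour segments >50% covered by the same sample's normal segments.

    Coverage is the fraction of the tumour segment's length intersected by
    the union of the matched normal's retained segments on the same
    chromosome; the drop rule is strict (> 0.5).  Tumour samples without
    any normal record are kept unchanged.
    """
    if normal_seg.empty or tumour_seg.empty:
        return tumour_seg.reset_index(drop=True)
    normal_by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for (sample, chrom), sub in normal_seg.groupby(["sample_id", "chrom"]):
        normal_by_key[(sample, chrom)] = _merged_intervals(
            sub["start"].to_numpy(), sub["end"].to_numpy()
        )
    normal_samples = set(normal_seg["sample_id"])
    missing = sorted(set(tumour_seg["sample_id"]) - normal_samples)
    if missing:
        logger.info("no matched normal for %d tumour sample(s); kept unchanged", len(missing))

    keep_mask = np.ones(len(tumour_seg), dtype=bool)
    for i, row in enumerate(tumour_seg.itertuples(index=False)):
        intervals = normal_by_key.get((row.sample_id, row.chrom))
        if not intervals:
            continue
        covered = 0
        for s, e in intervals:
            covered += max(0, min(e, row.end) - max(s, row.start))
        if covered / (row.end - row.start) > NORMAL_OVERLAP_THRESHOLD:
            keep_mask[i] = False
    return tumour_seg[keep_mask].reset_index(drop=True)


def call_gene_cna(
    seg: pd.DataFrame,
    model: pd.DataFrame,
    samples: list[str] | None = None,
    min_overlap_bp: int = 1,
    min_overlap_fraction: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-level amplification/deletion calls from filtered segments.

    A gene is amplified in a sample iff it overlaps (by at least
    ``min_overlap_bp``, half-open intersection, and at least
    ``min_overlap_fraction`` of the gene's length) a retained segment with
    mean > 0.3; deleted for mean < -0.3.  A gene hit by both signs in one
    sample is set false in both matrices (ambiguous call).
    """
    if samples is None:
        samples = sorted(set(seg["sample_id"]))
    genes = list(model["gene"])
    amp = pd.DataFrame(False, index=pd.Index(genes, name="gene"), columns=samples)
    dele = pd.DataFrame(False, index=pd.Index(genes, name="gene"), columns=samples)

    model_by_chrom = {chrom: sub for chrom, sub in model.groupby("chrom")}
    for row in seg.itertuples(index=False):
        if row.sample_id not in amp.columns:
            continue
        sub = model_by_chrom.get(row.chrom)
        if sub is None:
            continue
        ov = np.minimum(sub["end"].to_numpy(), row.end) - np.maximum(
            sub["start"].to_numpy(), row.start
        )
        lengths = (sub["end"] - sub["start"]).to_numpy()
        hit = (ov >= min_overlap_bp) & (ov >= min_overlap_fraction * lengths)
        if not hit.any():
            continue
        target = amp if row.segment_mean > SEGMENT_MEAN_THRESHOLD else dele
        target.loc[sub["gene"].to_numpy()[hit], row.sample_id] = True

    conflict = amp.to_numpy() & dele.to_numpy()
    if conflict.any():
        n = int(conflict.sum())
        logger.warning("%d ambiguous (gene, sample) amp+del call(s) set false in both", n)
        amp.values[conflict] = False
        dele.values[conflict] = False
    return amp, dele


def annotate_passengers(
    cohort: CancerCohort,
    alteration: str,
    p_cutoff: float = 0.05,
    fold_cutoff: float = 1.2,
) -> list[PassengerAnnotation]:
    """Classify each altered gene as passenger or concordant (driver-like).

    A deletion is non-passenger iff expression in deleted samples is lower
    (Welch t-test p < ``p_cutoff``) with anti-logged fold difference
    ``2**|d log2 mean| > fold_cutoff``; amplifications symmetric with
    higher expression.  Genes with < 2 samples on either side, or missing
    from the expression matrix, are passengers by convention.
    """
    if alteration not in ("amp", "del"):
        raise ValidationError(f"alteration must be 'amp' or 'del', got {alteration!r}")
    matrix = cohort.amp if alteration == "amp" else cohort.del_
    out: list[PassengerAnnotation] = []
    expr = cohort.expr
    for gene in matrix.index:
        altered = matrix.loc[gene].to_numpy()
        if gene not in expr.index:
            if altered.any():
                logger.info("%s: %s absent from expression; passenger by convention", cohort.cancer_type, gene)
            out.append(PassengerAnnotation(cohort.cancer_type, gene, alteration, True, 1.0, 1.0))
            continue
        x = expr.loc[gene].to_numpy(dtype=float)
        a, b = x[altered], x[~altered]
        if a.size < 2 or b.size < 2:
            out.append(PassengerAnnotation(cohort.cancer_type, gene, alteration, True, 1.0, 1.0))
            continue
        _, p = welch_t(a, b)
        dmean = float(a.mean() - b.mean())
        fold = float(2.0 ** abs(dmean))
        concordant = dmean > 0 if alteration == "amp" else dmean < 0
        is_passenger = not (p < p_cutoff and fold > fold_cutoff and concordant)
        out.append(
            PassengerAnnotation(cohort.cancer_type, gene, alteration, is_passenger, float(p), fold)
        )
    return out


def passenger_lookup(
    annotations: list[PassengerAnnotation],
) -> dict[tuple[str, str, str], PassengerAnnotation]:
    """Index annotations by (cancer_type, gene, alteration)."""
    return {(a.cancer_type, a.gene, a.alteration): a for a in annotations}
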