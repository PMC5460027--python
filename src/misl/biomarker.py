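"""Reverse MiSL: predictive genetic biomarkers for a drug.

Given a drug inhibiting gene ``Y``, the forward logic is run with roles
swapped: an alteration ``X`` (mutation or CNA) is a candidate biomarker of
sensitivity if ``X => not Y_del`` (HI-LO) or ``Y_amp => X`` (HI-HI) over
the cancers where ``Y``'s alteration is not a passenger — i.e. tumours
with ``X`` tend to retain or gain ``Y``, so inhibiting ``Y`` should be
selectively lethal in ``X``-altered cells.  Alterations on ``Y``'s own
chromosome are removed (they co-segregate with ``Y``'s copy number and are
likely artefactual), and ``Y`` must be overexpressed in ``X``-altered
samples of the cancer of interest.

Predictions are scored against cell-line pharmacology: predicted-sensitive
lines (harbouring >= 1 biomarker) are compared to truly sensitive lines
(first quartile of IC50 among tested lines) with a two-sided Fisher test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import welch_t
from .booleanize import CancerCohort, PassengerAnnotation
from .core import MislConfig, collect_passenger_annotations
from .errors import MislError, ValidationError
from .implications import (
    BooleanImplication,
    ImplicationKind,
    pair_statistics,
    parse_variable,
)

logger = logging.getLogger(__name__)


@dataclass
class BiomarkerPrediction:
    drug: str
    inhibited_gene: str
    biomarker: str  # variable id, e.g. "PIK3CA:mut" or "G0042:amp"
    cancer_type: str
    implication: BooleanImplication
    overexpression_p: float


@dataclass
class SensitivityEvaluation:
    target_family: str
    predicted_sensitive: set[str]
    truly_sensitive: set[str]
    overlap: int
    fisher_p: float


def _candidate_variables(cohorts: list[CancerCohort]) -> list[str]:
    vars_: set[str] = set()
    for c in cohorts:
        vars_.update(f"{g}:mut" for g in c.mut.index if ":" not in g)
        vars_.update(f"{g}:amp" for g in c.amp.index if ":" not in g)
        vars_.update(f"{g}:del" for g in c.del_.index if ":" not in g)
    return sorted(vars_)


def _pooled_rows(
    cohorts: list[CancerCohort], variables: list[str]
) -> np.ndarray:
    blocks = []
    for c in cohorts:
        block = np.zeros((len(variables), c.n_samples), dtype=bool)
        for i, var in enumerate(variables):
            gene, cls = parse_variable(var)
            m = c.alteration_matrix(cls)
            if gene in m.index:
                block[i] = m.loc[gene].to_numpy(dtype=bool)
        blocks.append(block)
    return np.concatenate(blocks, axis=1)


def predict_biomarkers(
    drug: str,
    drug_gene: pd.DataFrame,
    cohorts: list[CancerCohort],
    cfg: MislConfig | None = None,
    passenger_annotations: list[PassengerAnnotation] | None = None,
) -> list[BiomarkerPrediction]:
    """Alterations predicted to confer sensitivity to ``drug``.

    ``drug_gene`` is the interaction table (columns drug, gene,
    interaction); only ``inhibits`` rows define the drug's target set.
    """
    cfg = cfg or MislConfig()
    inhibited = sorted(
        drug_gene.loc[
            (drug_gene["drug"] == drug) & (drug_gene["interaction"] == "inhibits"), "gene"
        ]
    )
    if not inhibited:
        available = sorted(drug_gene["drug"].unique())
        raise MislError(f"drug {drug!r} has no inhibited genes; known drugs: {available}")
    if passenger_annotations is None:
        passenger_annotations = collect_passenger_annotations(cohorts, cfg)
    pann = {(a.cancer_type, a.gene, a.alteration): a for a in passenger_annotations}
    chrom = {}
    for c in cohorts:
        chrom.update(c.gene_chrom)

    predictions: list[BiomarkerPrediction] = []
    for y in inhibited:
        y_chrom = chrom.get(y)
        variables = [
            v
            for v in _candidate_variables(cohorts)
            if parse_variable(v)[0] != y
            and (y_chrom is None or chrom.get(parse_variable(v)[0]) != y_chrom)
        ]
        if not variables:
            continue
        hits: list[tuple[str, BooleanImplication]] = []
        for kind, y_class in ((ImplicationKind.HI_LO, "del"), (ImplicationKind.HI_HI, "amp")):
            contribs = [
                c
                for c in cohorts
                if len(c.alteration_matrix(y_class).index)
                and not pann.get(
                    (c.cancer_type, y, y_class),
                    PassengerAnnotation(c.cancer_type, y, y_class, True, 1.0, 1.0),
                ).is_passenger
            ]
            if not contribs:
                continue
            X = _pooled_rows(contribs, variables)
            y_vec = _pooled_rows(contribs, [f"{y}:{y_class}"])
            n_pool = y_vec.shape[1]
            if kind == ImplicationKind.HI_HI:
                k = n_pool if cfg.artificial_normal_k is None else cfg.artificial_normal_k
                Xp = np.concatenate([X, np.zeros((len(variables), k), dtype=bool)], axis=1)
                yp = np.concatenate([y_vec, np.zeros((1, k), dtype=bool)], axis=1)
                # Y_amp => X: Y amplification is the antecedent
                p, e, a = pair_statistics(yp, Xp, kind)
                p, e, a = p[0], e[0], a[0]
                n_used = n_pool + k
            else:
                # X => not Y_del
                p, e, a = pair_statistics(X, y_vec, kind)
                p, e, a = p[:, 0], e[:, 0], a[:, 0]
                n_used = n_pool
            sig = (p < cfg.cutoff_for(kind)) & (e < cfg.error_cutoff)
            for i in np.flatnonzero(sig):
                var = variables[i]
                if kind == ImplicationKind.HI_HI:
                    ante, cons = f"{y}:amp", var
                else:
                    ante, cons = var, f"{y}:del"
                hits.append(
                    (
                        var,
                        BooleanImplication(
                            antecedent=ante,
                            consequent=cons,
                            kind=kind,
                            fisher_p=float(p[i]),
                            error_rate=float(e[i]),
                            sparse_quadrant_count=int(a[i]),
                            n_samples=int(n_used),
                            cancer_types_used=[c.cancer_type for c in contribs],
                        ),
                    )
                )
        # final gate: Y overexpressed in X-altered samples, per cancer type
        for var, imp in hits:
            gene, cls = parse_variable(var)
            for c in cohorts:
                if y not in c.expr.index:
                    continue
                m = c.alteration_matrix(cls)
                if gene not in m.index:
                    continue
                altered = m.loc[gene].to_numpy(dtype=bool)
                x = c.expr.loc[y].to_numpy(dtype=float)
                a_, b_ = x[altered], x[~altered]
                if a_.size < 2 or b_.size < 2:
                    continue
                _, pv = welch_t(a_, b_)
                if pv < cfg.overexpr_p and a_.mean() > b_.mean():
                    predictions.append(
                        BiomarkerPrediction(
                            drug=drug,
                            inhibited_gene=y,
                            biomarker=var,
                            cancer_type=c.cancer_type,
                            implication=imp,
                            overexpression_p=float(pv),
                        )
                    )
    predictions.sort(
        key=lambda p: (p.inhibited_gene, p.implication.fisher_p, p.biomarker, p.cancer_type)
    )
    return predictions


def evaluate_sensitivity(
    predictions: list[BiomarkerPrediction],
    cell_line_alterations: pd.DataFrame,
    pharmacology: pd.DataFrame,
    drugs: list[str],
    target_family: str | None = None,
    tissues: list[str] | None = None,
) -> SensitivityEvaluation:
    """Overlap of predicted-sensitive and first-quartile-IC50 cell lines.

    ``cell_line_alterations`` is a Boolean variables x cell-lines matrix
    (rows named like biomarker variable ids).  Multiple ``drugs`` in one
    target family are pooled by per-line minimum IC50 over the family.
    ``tissues`` optionally restricts to tissue-matched lines.
    """
    from ._stats import cached_fisher_two_sided

    pharm = pharmacology[pharmacology["drug"].isin(drugs)]
    if tissues is not None:
        pharm = pharm[pharm["tissue"].isin(tissues)]
    if pharm.empty:
        raise MislError(f"no pharmacology rows for drugs {drugs}")
    ic50 = pharm.groupby("cell_line")["ic50"].min()
    if len(ic50) < 4:
        raise ValidationError("need >= 4 cell lines with IC50 for a quartile split")
    q1 = float(np.quantile(ic50.to_numpy(), 0.25))
    truly = set(ic50.index[ic50 <= q1])

    biomarkers = sorted({p.biomarker for p in predictions})
    present = [b for b in biomarkers if b in cell_line_alterations.index]
    tested = list(ic50.index)
    if present:
        cols = [l for l in tested if l in cell_line_alterations.columns]
        carrier = cell_line_alterations.loc[present, cols].to_numpy(dtype=bool).any(axis=0)
        predicted = {l for l, hit in zip(cols, carrier) if hit}
    else:
        predicted = set()

    n = len(tested)
    n11 = len(predicted & truly)
    n10 = len(predicted - truly)
    n01 = len(truly - predicted)
    n00 = n - n11 - n10 - n01
    p = cached_fisher_two_sided(n11, n10, n01, n00)
    return SensitivityEvaluation(
        target_family=target_family or "+".join(sorted(drugs)),
        predicted_sensitive=predicted,
        truly_sensitive=truly,
        overlap=n11,
        fisher_p=float(p),
    )
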