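"""The forward MiSL pipeline: from a mutation and a cancer of interest to
candidate synthetic-lethal partner genes.

The pipeline, for mutation ``X`` in cancer ``T``:

1. recurrence gate — keep cancers where ``X`` is mutated in >= 2.5% of
   samples;
2. deletion arm — HI-LO implications ``X => not B_del`` (mutual exclusion
   of ``X`` and partner deletion) over the pooled eligible cancers where
   ``B``'s deletion is not a copy-number passenger;
3. amplification arm — HI-HI implications ``B_amp => X`` (amplification
   preferentially in mutants) with artificial-normal augmentation, again
   restricted to non-passenger cancers;
4. overexpression gate — keep partners differentially overexpressed in
   ``X``-mutant versus wild-type samples of ``T`` (Welch t-test p < 0.05,
   higher mean in mutants).

Genes surviving every gate are the SL candidates of ``X`` in ``T``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import welch_t
from .booleanize import CancerCohort, PassengerAnnotation, annotate_passengers
from .errors import MislError, ValidationError
from .implications import BooleanImplication, ImplicationKind, parse_variable, scan_implications

logger = logging.getLogger(__name__)


@dataclass
class MislConfig:
    """Pipeline thresholds; defaults are the operating point of the method."""

    recurrence_fraction: float = 0.025
    fisher_cutoff: float = 0.05
    error_cutoff: float = 0.1
    passenger_fold: float = 1.2
    passenger_p: float = 0.05
    overexpr_p: float = 0.05
    artificial_normal_k: int | None = None  # None -> pooled sample count
    fdr_target: float = 0.05
    seed: int = 0
    per_type: bool = False
    exclude_same_chromosome: bool = False
    # per-kind cutoffs set by FDR calibration; None -> fisher_cutoff
    fisher_cutoff_hi_lo: float | None = None
    fisher_cutoff_hi_hi: float | None = None

    def cutoff_for(self, kind) -> float:
        from .implications import ImplicationKind

        if ImplicationKind(kind) == ImplicationKind.HI_LO:
            return self.fisher_cutoff_hi_lo or self.fisher_cutoff
        return self.fisher_cutoff_hi_hi or self.fisher_cutoff

    def __post_init__(self) -> None:
        if not 0 < self.recurrence_fraction < 1:
            raise ValidationError("recurrence_fraction must be in (0, 1)")
        for name in ("fisher_cutoff", "error_cutoff", "passenger_fold", "passenger_p", "overexpr_p", "fdr_target"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass
class SLCandidate:
    """A (mutation, partner, cancer) record with its full evidence trail."""

    mutation: str
    partner: str
    cancer_type: str
    arm: str  # "amplification" | "deletion"
    implication: BooleanImplication
    passenger_p: float
    passenger_fold: float
    overexpression_p: float
    overexpression_fold: float


def eligible_cancers(
    mutation: str, cohorts: list[CancerCohort], cfg: MislConfig | None = None
) -> list[str]:
    """Cancer types where the mutation is present in >= 2.5% of samples."""
    cfg = cfg or MislConfig()
    out = []
    for c in cohorts:
        if mutation in c.mut.index:
            frac = float(c.mut.loc[mutation].sum()) / c.n_samples
            if frac >= cfg.recurrence_fraction:
                out.append(c.cancer_type)
    return out


def _overexpression(
    coi: CancerCohort, mutation: str, partner: str, cfg: MislConfig
) -> tuple[float, float] | None:
    """(p, fold) if partner is overexpressed in mutants of the cancer of
    interest, else None."""
    if partner not in coi.expr.index or mutation not in coi.mut.index:
        return None
    mutated = coi.mut.loc[mutation].to_numpy(dtype=bool)
    x = coi.expr.loc[partner].to_numpy(dtype=float)
    a, b = x[mutated], x[~mutated]
    if a.size < 2 or b.size < 2:
        return None
    _, p = welch_t(a, b)
    dmean = float(a.mean() - b.mean())
    if p < cfg.overexpr_p and dmean > 0:
        return float(p), float(2.0 ** dmean)
    return None


def collect_passenger_annotations(
    cohorts: list[CancerCohort], cfg: MislConfig | None = None
) -> list[PassengerAnnotation]:
    """Passenger annotations for both alteration classes over all cohorts."""
    cfg = cfg or MislConfig()
    anns: list[PassengerAnnotation] = []
    for c in cohorts:
        for alt in ("amp", "del"):
            anns.extend(
                annotate_passengers(c, alt, p_cutoff=cfg.passenger_p, fold_cutoff=cfg.passenger_fold)
            )
    return anns


def calibrate_config(
    cohorts: list[CancerCohort],
    cfg: MislConfig | None = None,
    cutoff_grid: list[float] | None = None,
    n_permutations: int = 100,
    seed: int | None = None,
):
    """Return a config with per-kind Fisher cutoffs set by permutation FDR.

    Runs :func:`misl.implications.calibrate_fdr` for both implication
    kinds on the given cohorts and stores the chosen cutoffs; also returns
    the two calibration records for the run manifest.
    """
    from dataclasses import replace

    from .implications import calibrate_fdr

    cfg = cfg or MislConfig()
    grid = cutoff_grid or [0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05]
    seed = cfg.seed if seed is None else seed
    cal_lo = calibrate_fdr(
        cohorts, ImplicationKind.HI_LO, grid, n_permutations=n_permutations,
        seed=seed, error_cutoff=cfg.error_cutoff, fdr_target=cfg.fdr_target,
    )
    cal_hi = calibrate_fdr(
        cohorts, ImplicationKind.HI_HI, grid, n_permutations=n_permutations,
        seed=seed + 1, error_cutoff=cfg.error_cutoff, fdr_target=cfg.fdr_target,
    )
    out = replace(
        cfg, fisher_cutoff_hi_lo=cal_lo.chosen_cutoff, fisher_cutoff_hi_hi=cal_hi.chosen_cutoff
    )
    return out, {"hi_lo": cal_lo, "hi_hi": cal_hi}


def run_misl(
    mutation: str,
    cancer_of_interest: str,
    cohorts: list[CancerCohort],
    cfg: MislConfig | None = None,
    passenger_annotations: list[PassengerAnnotation] | None = None,
) -> list[SLCandidate]:
    """Candidate SL partners of ``mutation`` in ``cancer_of_interest``.

    ``passenger_annotations`` may be precomputed (e.g. shared across
    mutations); otherwise they are derived from the eligible cohorts'
    expression matrices.
    """
    cfg = cfg or MislConfig()
    by_name = {c.cancer_type: c for c in cohorts}
    if cancer_of_interest not in by_name:
        raise MislError(f"unknown cancer of interest {cancer_of_interest!r}")
    coi = by_name[cancer_of_interest]
    if coi.expr.empty:
        raise MislError(f"{cancer_of_interest} has no expression data")

    eligible = eligible_cancers(mutation, cohorts, cfg)
    if not eligible:
        logger.warning("%s not recurrent (>=%.1f%%) in any cohort", mutation, 100 * cfg.recurrence_fraction)
        return []
    elig_cohorts = [by_name[name] for name in eligible]
    if passenger_annotations is None:
        passenger_annotations = collect_passenger_annotations(elig_cohorts, cfg)
    pann = {(a.cancer_type, a.gene, a.alteration): a for a in passenger_annotations}

    anchor = f"{mutation}:mut"
    arms = [
        ("deletion", ImplicationKind.HI_LO, "del"),
        ("amplification", ImplicationKind.HI_HI, "amp"),
    ]
    candidates: list[SLCandidate] = []
    for arm_name, kind, alt in arms:
        imps = scan_implications(
            elig_cohorts,
            anchor,
            kind,
            passenger_filter=passenger_annotations,
            fisher_cutoff=cfg.cutoff_for(kind),
            error_cutoff=cfg.error_cutoff,
            artificial_normal_k=cfg.artificial_normal_k,
        )
        for imp in imps:
            partner_var = imp.antecedent if kind == ImplicationKind.HI_HI else imp.consequent
            partner, _ = parse_variable(partner_var)
            if cfg.exclude_same_chromosome:
                pc = _gene_chrom(cohorts, partner)
                mc = _gene_chrom(cohorts, mutation)
                if pc is not None and pc == mc:
                    continue
            over = _overexpression(coi, mutation, partner, cfg)
            if over is None:
                continue
            # strongest concordance evidence among contributing cancers
            anns = [
                pann[(ct, partner, alt)]
                for ct in imp.cancer_types_used
                if (ct, partner, alt) in pann
            ]
            best = min(anns, key=lambda a: a.p_value) if anns else None
            candidates.append(
                SLCandidate(
                    mutation=mutation,
                    partner=partner,
                    cancer_type=cancer_of_interest,
                    arm=arm_name,
                    implication=imp,
                    passenger_p=best.p_value if best else float("nan"),
                    passenger_fold=best.fold_difference if best else float("nan"),
                    overexpression_p=over[0],
                    overexpression_fold=over[1],
                )
            )
    candidates.sort(key=lambda c: (c.implication.fisher_p, c.partner, c.arm))
    return candidates


def _gene_chrom(cohorts: list[CancerCohort], gene: str) -> str | None:
    for c in cohorts:
        if gene in c.gene_chrom:
            return c.gene_chrom[gene]
    return None


def targetable_summary(
    candidates: dict[tuple[str, str], list[SLCandidate]],
    cohorts: list[CancerCohort],
    cfg: MislConfig | None = None,
) -> dict:
    """Summaries over completed runs keyed by (mutation, cancer_type).

    Returns per-cancer fractions of recurrent mutations that are targetable
    (>= 1 candidate) and of samples carrying >= 1 targetable mutation,
    per-mutation candidate counts, and the number of (mutation, partner)
    pairs shared by more than one cancer type.
    """
    cfg = cfg or MislConfig()
    by_name = {c.cancer_type: c for c in cohorts}
    per_cancer_rows = []
    for cancer, cohort in by_name.items():
        runs = {m: cands for (m, ct), cands in candidates.items() if ct == cancer}
        if not runs:
            continue
        targetable = {m for m, cands in runs.items() if cands}
        frac_mut = len(targetable) / len(runs)
        if targetable:
            rows = [m for m in targetable if m in cohort.mut.index]
            carrier = (
                cohort.mut.loc[rows].to_numpy(dtype=bool).any(axis=0)
                if rows
                else np.zeros(cohort.n_samples, dtype=bool)
            )
            frac_samples = float(carrier.mean())
        else:
            frac_samples = 0.0
        per_cancer_rows.append(
            {
                "cancer_type": cancer,
                "n_mutations_run": len(runs),
                "n_targetable": len(targetable),
                "fraction_targetable_mutations": frac_mut,
                "fraction_samples_targetable": frac_samples,
            }
        )
    per_mutation = pd.DataFrame(
        [
            {"mutation": m, "cancer_type": ct, "n_candidates": len(cands)}
            for (m, ct), cands in sorted(candidates.items())
        ]
    )
    pair_cancers: dict[tuple[str, str], set[str]] = {}
    for (m, ct), cands in candidates.items():
        for cand in cands:
            pair_cancers.setdefault((m, cand.partner), set()).add(ct)
    shared = sum(1 for cancers in pair_cancers.values() if len(cancers) > 1)
    return {
        "per_cancer": pd.DataFrame(per_cancer_rows),
        "per_mutation": per_mutation,
        "shared_pairs_across_cancers": shared,
    }
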