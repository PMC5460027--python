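"""Synthetic multi-cancer cohorts with planted synthetic-lethal structure.

The generator emulates exactly the statistical signals the miner assumes:

* background alterations are independent Bernoulli draws per gene and
  sample (mutations, amplifications, deletions);
* a planted HI-LO pair (X, B) makes deletions of B occur only in samples
  without mutation X (mutual exclusion; a configurable leak rate allows
  violations);
* a planted HI-HI pair (X, B) makes amplifications of B occur only inside
  X-mutant samples (subset structure);
* every non-passenger copy-number event shifts that gene's own log2
  expression by +/- ``effect_size``; designated passenger genes receive
  calls with no expression shift;
* planted partner genes are additionally overexpressed by ``effect_size``
  in X-mutant samples of the cancer of interest, feeding the final filter.

Default parameter values define the standard study conditions used by the
test-suite and the acceptance script: 3 cancers x 200 samples, 500 genes,
10 HI-LO + 10 HI-HI plants, 50 passengers, 1.0 log2 effect, 0.4 noise sd,
seed 7.  All randomness flows from one seed through per-artifact child
streams, so adding an artifact never perturbs existing ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .booleanize import CancerCohort
from .errors import ValidationError

_CHROMS = [f"chr{i}" for i in range(1, 23)]


@dataclass
class FixtureSpec:
    """Parameters of the synthetic pan-cancer cohort."""

    n_cancers: int = 3
    samples_per_cancer: int = 200
    n_genes: int = 500
    mutation_freq: float = 0.08
    amp_freq: float = 0.04
    del_freq: float = 0.04
    n_planted_hi_lo: int = 10
    n_planted_hi_hi: int = 10
    n_passengers: int = 50
    planted_mutation_freq: float = 0.30
    planted_partner_rate: float = 0.30
    passenger_rate: float = 0.15
    leak_rate: float = 0.0
    expression_noise_sd: float = 0.4
    effect_size: float = 1.0
    baseline_expression: float = 5.0
    overexpress_planted: bool = True
    cna_missing_cancers: tuple = ()
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("mutation_freq", "amp_freq", "del_freq", "planted_mutation_freq",
                     "planted_partner_rate", "passenger_rate"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0, 1)")
        if not 0 <= self.leak_rate < 1:
            raise ValidationError("leak_rate must be in [0, 1)")
        needed = 2 * (self.n_planted_hi_lo + self.n_planted_hi_hi) + self.n_passengers
        if needed > self.n_genes:
            raise ValidationError(
                f"spec needs {needed} special genes but only {self.n_genes} available"
            )


@dataclass
class SyntheticTruth:
    """The ground truth a fixture cohort was generated with."""

    planted_hi_lo: list[tuple[str, str]]
    planted_hi_hi: list[tuple[str, str]]
    passengers: list[tuple[str, str]]
    expression_effects: dict[str, float]
    cancer_of_interest: str
    seed: int
    generation_params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_hi_lo": self.planted_hi_lo,
                "planted_hi_hi": self.planted_hi_hi,
                "passengers": self.passengers,
                "expression_effects": self.expression_effects,
                "cancer_of_interest": self.cancer_of_interest,
                "seed": self.seed,
                "generation_params": self.generation_params,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            planted_hi_lo=[tuple(p) for p in d["planted_hi_lo"]],
            planted_hi_hi=[tuple(p) for p in d["planted_hi_hi"]],
            passengers=[tuple(p) for p in d["passengers"]],
            expression_effects=d["expression_effects"],
            cancer_of_interest=d["cancer_of_interest"],
            seed=d["seed"],
            generation_params=d["generation_params"],
        )


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def gene_model_frame(spec: FixtureSpec) -> pd.DataFrame:
    """Deterministic BED-style gene model: non-overlapping 5 kb genes."""
    genes = _gene_names(spec.n_genes)
    rows = []
    for i, g in enumerate(genes):
        chrom = _CHROMS[i % len(_CHROMS)]
        start = (i // len(_CHROMS)) * 10_000
        rows.append({"gene": g, "chrom": chrom, "start": start, "end": start + 5_000})
    return pd.DataFrame(rows)


def generate_cohorts(spec: FixtureSpec | None = None) -> tuple[list[CancerCohort], SyntheticTruth]:
    """Generate the pan-cancer cohorts and their ground truth."""
    spec = spec or FixtureSpec()
    root = np.random.SeedSequence(spec.seed)
    role_rng = np.random.default_rng(root.spawn(1)[0])
    genes = _gene_names(spec.n_genes)
    model = gene_model_frame(spec)
    gene_chrom = dict(zip(model["gene"], model["chrom"]))

    perm = role_rng.permutation(spec.n_genes)
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = [genes[i] for i in perm[cursor : cursor + k]]
        cursor += k
        return out

    anchors_hl = take(spec.n_planted_hi_lo)
    partners_hl = take(spec.n_planted_hi_lo)
    anchors_hh = take(spec.n_planted_hi_hi)
    partners_hh = take(spec.n_planted_hi_hi)
    passenger_genes = take(spec.n_passengers)
    passengers = [
        (g, "del" if i % 2 == 0 else "amp") for i, g in enumerate(passenger_genes)
    ]
    passenger_alt = dict(passengers)
    planted_partner_set = set(partners_hl) | set(partners_hh)
    anchor_of_partner = {b: x for x, b in zip(anchors_hl, partners_hl)}
    anchor_of_partner.update({b: x for x, b in zip(anchors_hh, partners_hh)})

    cancer_names = [f"C{i + 1}" for i in range(spec.n_cancers)]
    coi = cancer_names[0]
    cohorts: list[CancerCohort] = []
    expression_effects: dict[str, float] = {}
    cancer_seeds = root.spawn(1 + spec.n_cancers)[1:]

    for cname, cseed in zip(cancer_names, cancer_seeds):
        rng = np.random.default_rng(cseed)
        ns = spec.samples_per_cancer
        samples = [f"{cname}_S{i + 1:03d}" for i in range(ns)]
        gidx = pd.Index(genes, name="gene")

        mut = rng.random((spec.n_genes, ns)) < spec.mutation_freq
        # conflict-free background CNAs from a single uniform draw
        u = rng.random((spec.n_genes, ns))
        amp = u < spec.amp_freq
        dele = (u >= spec.amp_freq) & (u < spec.amp_freq + spec.del_freq)

        pos = {g: i for i, g in enumerate(genes)}
        for x in anchors_hl + anchors_hh:
            mut[pos[x]] = rng.random(ns) < spec.planted_mutation_freq
        for x, b in zip(anchors_hl, partners_hl):
            x_mut = mut[pos[x]]
            draw = rng.random(ns)
            dele[pos[b]] = np.where(
                x_mut, draw < spec.leak_rate, draw < spec.planted_partner_rate
            )
            amp[pos[b]] = False
        for x, b in zip(anchors_hh, partners_hh):
            x_mut = mut[pos[x]]
            draw = rng.random(ns)
            amp[pos[b]] = np.where(
                x_mut, draw < spec.planted_partner_rate, draw < spec.leak_rate
            )
            dele[pos[b]] = False
        for g, alt in passengers:
            draw = rng.random(ns) < spec.passenger_rate
            if alt == "del":
                dele[pos[g]] = draw
                amp[pos[g]] = False
            else:
                amp[pos[g]] = draw
                dele[pos[g]] = False
        conflict = amp & dele
        amp[conflict] = False
        dele[conflict] = False

        expr = spec.baseline_expression + rng.normal(
            0.0, spec.expression_noise_sd, size=(spec.n_genes, ns)
        )
        # concordant dosage effect for every non-passenger CNA; for planted
        # partner genes the dosage signal lives only outside the cancer of
        # interest, so the final mutant-overexpression filter inside it is
        # fed exclusively by the overexpression program below and each
        # filter of the pipeline can be ablated independently
        for i, g in enumerate(genes):
            if g in passenger_alt:
                continue
            if g in planted_partner_set and cname == coi:
                continue
            shift = np.zeros(ns)
            shift[amp[i]] += spec.effect_size
            shift[dele[i]] -= spec.effect_size
            if shift.any():
                expr[i] += shift
                expression_effects[f"{g}:{cname}:cna"] = spec.effect_size
        if spec.overexpress_planted and cname == coi:
            for b in sorted(planted_partner_set):
                x_mut = mut[pos[anchor_of_partner[b]]]
                expr[pos[b], x_mut] += spec.effect_size
                expression_effects[f"{b}:{cname}:mutant_overexpression"] = spec.effect_size

        has_cna = cname not in spec.cna_missing_cancers
        cohorts.append(
            CancerCohort(
                cancer_type=cname,
                samples=samples,
                mut=pd.DataFrame(mut, index=gidx, columns=samples),
                amp=pd.DataFrame(amp, index=gidx, columns=samples)
                if has_cna
                else pd.DataFrame(index=pd.Index([], name="gene"), columns=samples),
                del_=pd.DataFrame(dele, index=gidx, columns=samples)
                if has_cna
                else pd.DataFrame(index=pd.Index([], name="gene"), columns=samples),
                expr=pd.DataFrame(expr, index=gidx, columns=samples),
                gene_chrom=gene_chrom,
            )
        )

    truth = SyntheticTruth(
        planted_hi_lo=list(zip(anchors_hl, partners_hl)),
        planted_hi_hi=list(zip(anchors_hh, partners_hh)),
        passengers=passengers,
        expression_effects=expression_effects,
        cancer_of_interest=coi,
        seed=spec.seed,
        generation_params=dataclasses.asdict(spec),
    )
    return cohorts, truth


@dataclass
class ScreenSpec:
    """Parameters of the synthetic dropout (barcode-count) screen."""

    constructs_per_gene: int = 5
    n_background_genes: int = 200
    baseline_mean_reads: float = 1000.0
    baseline_log_sd: float = 0.5
    depth: float = 0.4  # mean treated/baseline ratio of planted genes
    depth_sd: float = 0.05
    noise_sd: float = 0.1  # ratio sd of null genes around 1.0
    low_coverage_fraction: float = 0.05  # constructs seeded below the read floor


def generate_screen(truth: SyntheticTruth, spec: ScreenSpec | None = None) -> pd.DataFrame:
    """Barcode-count screen covering planted partner genes plus nulls.

    Planted genes' constructs drop to ``depth`` under treatment; null
    genes' ratios sit at 1.0 with multiplicative noise.  A small fraction
    of constructs is seeded below the 100-read baseline floor to exercise
    the filter.
    """
    spec = spec or ScreenSpec()
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 101]))
    planted = sorted({b for _, b in truth.planted_hi_lo + truth.planted_hi_hi})
    n_total = truth.generation_params.get("n_genes", 500)
    all_genes = _gene_names(n_total)
    special = set(planted)
    background = [g for g in all_genes if g not in special][: spec.n_background_genes]
    rows = []
    for gene in planted + background:
        is_planted = gene in special
        for j in range(spec.constructs_per_gene):
            if rng.random() < spec.low_coverage_fraction:
                baseline = float(rng.integers(5, 100))
            else:
                baseline = float(
                    np.exp(rng.normal(np.log(spec.baseline_mean_reads), spec.baseline_log_sd))
                )
            if is_planted:
                ratio = max(0.0, rng.normal(spec.depth, spec.depth_sd))
            else:
                ratio = max(0.0, rng.normal(1.0, spec.noise_sd))
            rows.append(
                {
                    "construct_id": f"{gene}_sh{j + 1}",
                    "gene": gene,
                    "baseline": round(baseline),
                    "treated": round(baseline * ratio),
                }
            )
    return pd.DataFrame(rows)


def generate_essentiality_screen(
    truth: SyntheticTruth,
    n_mutated_lines: int = 8,
    n_wildtype_lines: int = 8,
    n_background_genes: int = 400,
    constructs_per_gene: int = 5,
    effect: float = 1.0,
    effect_sd: float = 0.2,
    null_sd: float = 1.0,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Per-cell-line shRNA summary-score screen (Achilles-style).

    Planted partner genes score ``effect`` lower (more depleted) in
    mutated lines; everything else is exchangeable noise.  Returns the
    screen table plus the mutated / wild-type line lists.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 202]))
    planted = sorted({b for _, b in truth.planted_hi_lo + truth.planted_hi_hi})
    n_total = truth.generation_params.get("n_genes", 500)
    all_genes = _gene_names(n_total)
    background = [g for g in all_genes if g not in set(planted)][:n_background_genes]
    mut_lines = [f"LINE_M{i + 1:02d}" for i in range(n_mutated_lines)]
    wt_lines = [f"LINE_W{i + 1:02d}" for i in range(n_wildtype_lines)]
    rows = []
    for gene in planted + background:
        base = rng.normal(0.0, null_sd)
        for j in range(constructs_per_gene):
            wt = base + rng.normal(0.0, effect_sd, size=n_wildtype_lines)
            mu = base + rng.normal(0.0, effect_sd, size=n_mutated_lines)
            if gene in set(planted):
                mu = mu - rng.normal(effect, effect_sd / 4)
            row = {"construct_id": f"{gene}_sh{j + 1}", "gene": gene}
            row.update(dict(zip(mut_lines, np.round(mu, 6))))
            row.update(dict(zip(wt_lines, np.round(wt, 6))))
            rows.append(row)
    return pd.DataFrame(rows), mut_lines, wt_lines


@dataclass
class PharmacologySpec:
    """Parameters of the synthetic cell-line pharmacology panel."""

    n_lines: int = 24
    n_biomarker_lines: int = 6
    drug: str = "DRUG1"
    sensitive_ic50_mean: float = 1.0
    resistant_ic50_mean: float = 6.0
    ic50_log_sd: float = 0.2
    tissues: tuple = ("lung", "breast", "intestine")


def generate_pharmacology(
    truth: SyntheticTruth, spec: PharmacologySpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell-line IC50 table plus the matching Boolean alteration matrix.

    The biomarker is the mutation of the first planted HI-LO pair's anchor
    gene; lines carrying it draw IC50 from the sensitive (low-mean)
    distribution, the rest from the resistant one.
    """
    spec = spec or PharmacologySpec()
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 303]))
    anchor, _partner = truth.planted_hi_lo[0]
    biomarker = f"{anchor}:mut"
    lines = [f"CL{i + 1:02d}" for i in range(spec.n_lines)]
    carriers = set(lines[: spec.n_biomarker_lines])
    rows = []
    for i, line in enumerate(lines):
        mean = spec.sensitive_ic50_mean if line in carriers else spec.resistant_ic50_mean
        ic50 = float(np.exp(rng.normal(np.log(mean), spec.ic50_log_sd)))
        rows.append(
            {
                "cell_line": line,
                "tissue": spec.tissues[i % len(spec.tissues)],
                "drug": spec.drug,
                "ic50": round(ic50, 4),
            }
        )
    pharm = pd.DataFrame(rows)
    alt = pd.DataFrame(
        [[line in carriers for line in lines]],
        index=pd.Index([biomarker], name="variable"),
        columns=lines,
    )
    return pharm, alt


def cohort_to_raw(
    cohort: CancerCohort, model: pd.DataFrame, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Render a Boolean cohort back into raw-style input tables.

    Returns (mutation table, tumour segment table, expression matrix) such
    that reading them back through the io module and re-booleanizing
    reproduces the cohort's matrices (the gene model's genes do not
    overlap, so one segment per altered gene suffices).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    coords = model.set_index("gene")
    mut_rows = []
    types = ["missense", "nonsense", "frameshift", "splice_site"]
    for gene in cohort.mut.index:
        if ":" in gene:
            continue
        for sample in cohort.mut.columns[cohort.mut.loc[gene]]:
            mut_rows.append(
                {
                    "sample_id": sample,
                    "gene": gene,
                    "mutation_type": types[int(rng.integers(len(types)))],
                }
            )
    mut_table = pd.DataFrame(mut_rows, columns=["sample_id", "gene", "mutation_type"])

    seg_rows = []
    for matrix, mean in ((cohort.amp, 0.8), (cohort.del_, -0.8)):
        for gene in matrix.index:
            if gene not in coords.index:
                continue
            rec = coords.loc[gene]
            for sample in matrix.columns[matrix.loc[gene]]:
                seg_rows.append(
                    {
                        "sample_id": sample,
                        "chrom": rec["chrom"],
                        "start": int(rec["start"]),
                        "end": int(rec["end"]),
                        "n_markers": 20,
                        "segment_mean": mean,
                    }
                )
    seg_table = pd.DataFrame(
        seg_rows, columns=["sample_id", "chrom", "start", "end", "n_markers", "segment_mean"]
    )
    return mut_table, seg_table, cohort.expr.copy()
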