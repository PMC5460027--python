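"""Implication statistics against independent oracles.

The Fisher oracle enumerates the hypergeometric distribution directly; the
scan oracle is a scalar double loop over variable pairs.  Both are written
here, independently of the vectorised implementation they check.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from misl import (
    CancerCohort,
    ImplicationKind,
    augment_artificial_normals,
    contingency,
    error_rate,
    fisher_p,
    scan_implications,
)
from misl.errors import ValidationError
from misl.implications import ContingencyTable, pair_statistics


def fisher_oracle(n11, n10, n01, n00):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    n = n11 + n10 + n01 + n00
    r1, c1 = n11 + n10, n11 + n01
    if min(r1, c1, n - r1, n - c1) == 0:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = hypergeom.pmf(n11, n, c1, r1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def table_strategy(max_total=60):
    return st.tuples(
        st.integers(0, max_total // 4),
        st.integers(0, max_total // 4),
        st.integers(0, max_total // 4),
        st.integers(0, max_total // 4),
    ).filter(lambda t: sum(t) > 0)


class TestContingency:
    def test_counts(self):
        t = contingency([1, 1, 0], [1, 0, 0])
        assert (t.n11, t.n10, t.n01, t.n00) == (1, 1, 0, 1)

    def test_all_true(self):
        t = contingency([1] * 5, [1] * 5)
        assert (t.n11, t.n10, t.n01, t.n00) == (5, 0, 0, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            contingency([1, 0], [1])

    def test_independence_fixture_quadrants_near_quarter(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(4000) < 0.5, rng.random(4000) < 0.5
        t = contingency(a, b)
        for q in (t.n11, t.n10, t.n01, t.n00):
            assert abs(q - 1000) < 120


class TestFisher:
    @settings(max_examples=400, deadline=None, derandomize=True)
    @given(table_strategy())
    def test_matches_enumeration_oracle(self, t):
        assert fisher_p(ContingencyTable(*t)) == pytest.approx(fisher_oracle(*t), abs=1e-10)

    @pytest.mark.parametrize("t", [(5, 0, 5, 0), (0, 0, 3, 4), (1, 1, 1, 1)])
    def test_degenerate_and_balanced_tables_are_one(self, t):
        assert fisher_p(ContingencyTable(*t)) == 1.0

    def test_perfect_split(self):
        assert fisher_p(ContingencyTable(5, 0, 0, 5)) == pytest.approx(
            fisher_oracle(5, 0, 0, 5), abs=1e-12
        )


class TestErrorRate:
    def test_zero_iff_sparse_quadrant_empty(self):
        # HI-LO sparse quadrant is n11
        assert error_rate(ContingencyTable(0, 10, 10, 10), ImplicationKind.HI_LO) == 0.0
        assert error_rate(ContingencyTable(1, 10, 10, 10), ImplicationKind.HI_LO) > 0.0

    def test_symmetric_case_is_half(self):
        # a = r = c = 7 -> 0.5*(7/14 + 7/14) = 0.5
        assert error_rate(ContingencyTable(7, 7, 7, 0), ImplicationKind.HI_LO) == pytest.approx(0.5)

    def test_worked_arithmetic(self):
        # HI-LO: a=n11=2, r=n10=18, c=n01=38 -> 0.5*(2/20 + 2/40)
        t = ContingencyTable(2, 18, 38, 100)
        assert error_rate(t, ImplicationKind.HI_LO) == pytest.approx(0.075)

    def test_hi_hi_uses_other_quadrant(self):
        # HI-HI: a=n10=2, r=n11=18, c=n00=38
        t = ContingencyTable(18, 2, 5, 38)
        assert error_rate(t, ImplicationKind.HI_HI) == pytest.approx(0.075)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(table_strategy(40))
    def test_bounded_and_monotone_in_sparse_count(self, t):
        for kind in ImplicationKind:
            e = error_rate(ContingencyTable(*t), kind)
            assert 0.0 <= e <= 1.0
        # monotonicity in a with r,c fixed (HI-LO: a=n11, r=n10, c=n01)
        n11, n10, n01, n00 = t
        e1 = error_rate(ContingencyTable(n11, n10, n01, n00), ImplicationKind.HI_LO)
        e2 = error_rate(ContingencyTable(n11 + 1, n10, n01, n00), ImplicationKind.HI_LO)
        assert e2 >= e1


class TestArtificialNormals:
    def test_identity_at_zero_and_shape_at_k(self):
        m = pd.DataFrame(True, index=["a", "b", "c"], columns=["s1", "s2", "s3", "s4", "s5"])
        assert augment_artificial_normals(m, 0) is m
        out = augment_artificial_normals(m, 10)
        assert out.shape == (3, 15)
        assert not out.iloc[:, 5:].to_numpy().any()

    def test_near_ubiquitous_alteration_needs_augmentation(self):
        """An amplification present in ~every sample has a degenerate 2x2
        (Fisher p = 1); appending all-negative samples makes the HI-HI
        implication detectable."""
        n = 60
        amp = np.ones(n, dtype=bool)
        mut = np.ones(n, dtype=bool)
        t_plain = contingency(amp, mut)
        assert fisher_p(t_plain) == 1.0
        aug_amp = np.concatenate([amp, np.zeros(n, dtype=bool)])
        aug_mut = np.concatenate([mut, np.zeros(n, dtype=bool)])
        t_aug = contingency(aug_amp, aug_mut)
        assert fisher_p(t_aug) < 1e-6
        assert error_rate(t_aug, ImplicationKind.HI_HI) == 0.0


def random_cohort(rng, n_vars, n_samples):
    genes = pd.Index([f"G{i}" for i in range(n_vars)], name="gene")
    samples = [f"S{i}" for i in range(n_samples)]
    mut = pd.DataFrame(rng.random((n_vars, n_samples)) < 0.3, index=genes, columns=samples)
    u = rng.random((n_vars, n_samples))
    amp = pd.DataFrame(u < 0.15, index=genes, columns=samples)
    dele = pd.DataFrame((u >= 0.15) & (u < 0.30), index=genes, columns=samples)
    expr = pd.DataFrame(5.0, index=genes, columns=samples)
    return CancerCohort("T", samples, mut, amp, dele, expr)


def brute_force_scan(cohort, anchor_gene, kind, fisher_cutoff, error_cutoff):
    """Scalar double loop: contingency -> Fisher gate -> error gate."""
    hits = set()
    anchor = cohort.mut.loc[anchor_gene].to_numpy()
    partner_matrix = cohort.amp if kind == ImplicationKind.HI_HI else cohort.del_
    n = len(cohort.samples)
    for gene in partner_matrix.index:
        if gene == anchor_gene:
            continue
        partner = partner_matrix.loc[gene].to_numpy()
        if kind == ImplicationKind.HI_HI:
            a = np.concatenate([partner, np.zeros(n, dtype=bool)])
            b = np.concatenate([anchor, np.zeros(n, dtype=bool)])
        else:
            a, b = anchor, partner
        t = contingency(a, b)
        if fisher_oracle(t.n11, t.n10, t.n01, t.n00) < fisher_cutoff and (
            error_rate(t, kind) < error_cutoff
        ):
            hits.add(gene)
    return hits


class TestScan:
    @pytest.mark.parametrize("kind", list(ImplicationKind))
    def test_matches_brute_force_on_random_fixtures(self, kind):
        rng = np.random.default_rng(123 if kind == ImplicationKind.HI_LO else 321)
        for _ in range(60):
            cohort = random_cohort(rng, int(rng.integers(3, 20)), int(rng.integers(10, 100)))
            anchor_gene = str(cohort.mut.index[0])
            expected = brute_force_scan(cohort, anchor_gene, kind, 0.05, 0.1)
            got = scan_implications([cohort], f"{anchor_gene}:mut", kind)
            got_genes = {
                (i.antecedent if kind == ImplicationKind.HI_HI else i.consequent).split(":")[0]
                for i in got
            }
            assert got_genes == expected

    def test_anchor_never_partners_itself(self, small_fixture):
        cohorts, truth = small_fixture
        anchor, _ = truth.planted_hi_lo[0]
        for kind in ImplicationKind:
            for imp in scan_implications(cohorts, f"{anchor}:mut", kind):
                other = imp.consequent if kind == ImplicationKind.HI_LO else imp.antecedent
                assert other.split(":")[0] != anchor

    def test_absent_anchor_yields_empty(self, small_fixture):
        cohorts, _ = small_fixture
        assert scan_implications(cohorts, "NOSUCH:mut", ImplicationKind.HI_LO) == []

    def test_null_significant_fraction_bounded(self):
        """Independent Bernoulli pairs pass the double gate at well below
        the Fisher cutoff rate (the error gate only tightens it)."""
        rng = np.random.default_rng(7)
        n_pairs, n = 1000, 200
        A = rng.random((n_pairs, n)) < 0.3
        B = rng.random((n_pairs, n)) < 0.15
        p, e, _ = pair_statistics(A, B, ImplicationKind.HI_LO)
        sig = np.diag(p < 0.05) & np.diag(e < 0.1)
        assert sig.mean() <= 0.05

    def test_joint_permutation_leaves_statistics_unchanged(self):
        rng = np.random.default_rng(9)
        a = rng.random(120) < 0.4
        b = rng.random(120) < 0.2
        perm = rng.permutation(120)
        t1, t2 = contingency(a, b), contingency(a[perm], b[perm])
        assert t1 == t2
        assert fisher_p(t1) == fisher_p(t2)
        assert error_rate(t1, ImplicationKind.HI_LO) == error_rate(t2, ImplicationKind.HI_LO)

    def test_hi_lo_unaffected_by_augmentation_contract(self, small_fixture):
        """HI-LO scans never append artificial normals: passing an explicit
        k changes nothing for that kind."""
        cohorts, truth = small_fixture
        anchor, _ = truth.planted_hi_lo[0]
        base = scan_implications(cohorts, f"{anchor}:mut", ImplicationKind.HI_LO)
        with_k = scan_implications(
            cohorts, f"{anchor}:mut", ImplicationKind.HI_LO, artificial_normal_k=50
        )
        assert [(i.antecedent, i.consequent, i.fisher_p) for i in base] == [
            (i.antecedent, i.consequent, i.fisher_p) for i in with_k
        ]
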