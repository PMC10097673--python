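import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from micromr.instruments import (
    CohortAssociation,
    InstrumentError,
    PowerSpec,
    directional_consistency_filter,
    f_statistic,
    fixed_effects_meta,
    greedy_clump,
    lor_from_r2_liability,
    mr_power_binary,
    r2_continuous,
    r2_liability_from_lor,
    select_by_threshold,
)

from conftest import make_assoc


class TestSelectByThreshold:
    def test_strict_comparison(self):
        assocs = [make_assoc(variant_id="rs1", pvalue=1e-9),
                  make_assoc(variant_id="rs2", pvalue=1e-7)]
        inst = select_by_threshold(assocs, 2.5e-8)
        assert inst.variant_ids == ("rs1",)
        assert inst.k == 1

    def test_all_null_gives_empty(self):
        assocs = [make_assoc(variant_id=f"rs{i}", pvalue=0.5) for i in range(5)]
        assert select_by_threshold(assocs, 2.5e-8).k == 0

    def test_sorted_by_p_then_id(self):
        assocs = [make_assoc(variant_id="rsB", pvalue=1e-9),
                  make_assoc(variant_id="rsA", pvalue=1e-9),
                  make_assoc(variant_id="rsC", pvalue=1e-10)]
        inst = select_by_threshold(assocs, 1e-8)
        assert inst.variant_ids == ("rsC", "rsA", "rsB")

    def test_planted_signal_recovered(self, rng):
        # z = 7 signal among nulls: only the planted variant passes 2.5e-8
        assocs = []
        for i in range(100):
            z = 7.0 if i == 42 else rng.standard_normal()
            se = 0.02
            p = max(2 * stats.norm.sf(abs(z)), 5e-324)
            assocs.append(make_assoc(variant_id=f"rs{i}", beta=z * se, se=se, pvalue=p))
        inst = select_by_threshold(assocs, 2.5e-8)
        assert inst.variant_ids == ("rs42",)


class TestFixedEffectsMeta:
    def test_equal_weight_average(self):
        cohorts = [
            CohortAssociation("discovery", make_assoc(beta=0.2, se=0.1, pvalue=0.05)),
            CohortAssociation("replication_1", make_assoc(beta=0.2, se=0.1, pvalue=0.05)),
        ]
        meta, supported = fixed_effects_meta(cohorts)
        assert meta.beta == pytest.approx(0.2)
        assert meta.se == pytest.approx(0.1 / math.sqrt(2))
        assert supported is True

    def test_cancellation(self):
        cohorts = [
            CohortAssociation("discovery", make_assoc(beta=0.2, se=0.1, pvalue=0.05)),
            CohortAssociation("replication_1", make_assoc(beta=-0.2, se=0.1, pvalue=0.05)),
        ]
        meta, supported = fixed_effects_meta(cohorts)
        assert meta.beta == pytest.approx(0.0)
        assert supported is False

    def test_three_cohort_vs_oracle(self):
        betas = [0.15, 0.22, 0.08]
        ses = [0.05, 0.08, 0.11]
        cohorts = [
            CohortAssociation(cid, make_assoc(beta=b, se=s, pvalue=0.05))
            for cid, b, s in zip(["discovery", "replication_1", "replication_2"], betas, ses)
        ]
        meta, _ = fixed_effects_meta(cohorts)
        # independent brute-force weighted average
        w = [1 / s**2 for s in ses]
        oracle_beta = sum(wi * bi for wi, bi in zip(w, betas)) / sum(w)
        oracle_se = math.sqrt(1 / sum(w))
        assert meta.beta == pytest.approx(oracle_beta, abs=1e-12)
        assert meta.se == pytest.approx(oracle_se, abs=1e-12)

    def test_single_cohort_raises(self):
        with pytest.raises(InstrumentError):
            fixed_effects_meta([CohortAssociation("discovery", make_assoc())])

    @given(st.lists(st.tuples(st.floats(-1, 1), st.floats(0.01, 1)), min_size=2, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_meta_variance_never_exceeds_smallest(self, cohorts_data):
        cohorts = [
            CohortAssociation(f"c{i}", make_assoc(beta=b, se=s, pvalue=0.5))
            for i, (b, s) in enumerate(cohorts_data)
        ]
        meta, _ = fixed_effects_meta(cohorts)
        assert meta.se**2 <= min(s for _, s in cohorts_data) ** 2 + 1e-12


class TestDirectionalConsistency:
    @staticmethod
    def _cohorts(vid, betas, se=0.02):
        names = ["discovery", "replication_1", "replication_2"]
        return [
            CohortAssociation(
                n, make_assoc(variant_id=vid, beta=b, se=se,
                              pvalue=max(2 * stats.norm.sf(abs(b / se)), 5e-324))
            )
            for n, b in zip(names, betas)
        ]

    def test_consistent_kept(self):
        per = {"rs1": self._cohorts("rs1", [0.12, 0.10, 0.11])}
        assert directional_consistency_filter(per).variant_ids == ("rs1",)

    def test_sign_flip_excluded_despite_tiny_p(self):
        per = {"rs1": self._cohorts("rs1", [0.30, -0.05, 0.30])}
        assert directional_consistency_filter(per).variant_ids == ()

    def test_weak_meta_excluded(self):
        per = {"rs1": self._cohorts("rs1", [0.02, 0.02, 0.02])}
        assert directional_consistency_filter(per).variant_ids == ()

    def test_missing_cohort_excluded(self):
        per = {
            "rs1": self._cohorts("rs1", [0.12, 0.10, 0.11]),
            "rs2": self._cohorts("rs2", [0.12, 0.10, 0.11])[:2],
        }
        assert directional_consistency_filter(per).variant_ids == ("rs1",)

    def test_planted_variant_retained_when_powered(self):
        # shared true effect across 3 cohorts, meta z ~ 8: retained >= 95% of runs
        rng = np.random.default_rng(7)
        kept = 0
        n_rep = 100
        for _ in range(n_rep):
            betas = rng.normal(0.1, 0.0216, size=3)  # per-cohort z ~ 4.6
            per = {"rs1": self._cohorts("rs1", list(betas), se=0.0216)}
            kept += directional_consistency_filter(per).k == 1
        assert kept >= 95


class TestGreedyClump:
    def test_identity_ld_keeps_all(self):
        assocs = [make_assoc(variant_id=f"rs{i}", pvalue=10**-(i + 2)) for i in range(4)]
        inst = greedy_clump(assocs, np.eye(4))
        assert set(inst.variant_ids) == {f"rs{i}" for i in range(4)}

    def test_tight_ld_keeps_best_only(self):
        assocs = [
            make_assoc(variant_id=f"rs{i}", pvalue=10**-(i + 2), position=1000 + i)
            for i in range(4)
        ]
        ld = np.full((4, 4), np.sqrt(0.9))
        np.fill_diagonal(ld, 1.0)
        inst = greedy_clump(assocs, ld)
        assert inst.variant_ids == ("rs3",)  # smallest p

    def test_window_limits_exclusion(self):
        assocs = [
            make_assoc(variant_id="rs1", pvalue=1e-9, position=1),
            make_assoc(variant_id="rs2", pvalue=1e-8, position=20_000_001),
        ]
        ld = np.array([[1.0, 0.9], [0.9, 1.0]])
        inst = greedy_clump(assocs, ld)  # outside 10 Mb window: both kept
        assert set(inst.variant_ids) == {"rs1", "rs2"}

    def test_dimension_mismatch_raises(self):
        with pytest.raises(InstrumentError):
            greedy_clump([make_assoc()], np.eye(2))

    @staticmethod
    def _brute_force(assocs, ld, r2_threshold, window_bp):
        """Independent restatement of the greedy definition."""
        order = sorted(range(len(assocs)), key=lambda i: (assocs[i].pvalue, assocs[i].variant_id))
        kept = []
        for i in order:
            if all(
                ld[i, j] ** 2 <= r2_threshold
                or abs(assocs[i].position - assocs[j].position) > window_bp
                for j in kept
            ):
                kept.append(i)
        return {assocs[i].variant_id for i in kept}

    def test_five_variant_oracle(self, rng):
        for _ in range(20):
            n = 5
            a = rng.uniform(-1, 1, size=(n, n))
            ld = (a @ a.T) / n
            d = np.sqrt(np.diag(ld))
            ld = ld / np.outer(d, d)
            assocs = [
                make_assoc(variant_id=f"rs{i}", pvalue=float(rng.uniform(1e-10, 1e-2)),
                           position=int(rng.integers(1, 5_000_000)))
                for i in range(n)
            ]
            got = set(greedy_clump(assocs, ld, r2_threshold=0.1).variant_ids)
            assert got == self._brute_force(assocs, ld, 0.1, 10_000_000)

    def test_order_invariance(self, rng):
        n = 6
        ld = np.eye(n)
        ld[0, 1] = ld[1, 0] = 0.5
        assocs = [
            make_assoc(variant_id=f"rs{i}", pvalue=float(rng.uniform(1e-8, 1e-3)))
            for i in range(n)
        ]
        base = greedy_clump(assocs, ld, r2_threshold=0.1).variant_ids
        perm = list(rng.permutation(n))
        shuffled = [assocs[i] for i in perm]
        ld_perm = ld[np.ix_(perm, perm)]
        assert greedy_clump(shuffled, ld_perm, r2_threshold=0.1).variant_ids == base


class TestR2Continuous:
    def test_derived_example(self):
        # z = 5, n = 2223: z^2/(z^2 + n) = 25/2248
        assert r2_continuous(0.2, 0.04, 0.3, 2223) == pytest.approx(25 / 2248)

    def test_zero_beta(self):
        assert r2_continuous(0.0, 0.04, 0.3, 1000) == 0.0

    def test_large_se_limit(self):
        assert r2_continuous(0.2, 1e6, 0.3, 1000) == pytest.approx(0.0, abs=1e-9)

    def test_invalid_maf(self):
        with pytest.raises(InstrumentError):
            r2_continuous(0.2, 0.04, 0.0, 1000)

    @given(
        beta=st.floats(-2, 2),
        se=st.floats(0.001, 1),
        maf=st.floats(0.001, 0.5),
        n=st.integers(2, 10**6),
    )
    @settings(max_examples=300, deadline=None)
    def test_algebraic_identity(self, beta, se, maf, n):
        z = beta / se
        expected = z**2 / (z**2 + n)
        assert r2_continuous(beta, se, maf, n) == pytest.approx(expected, abs=1e-12)


class TestR2Liability:
    def test_null_effect(self):
        assert r2_liability_from_lor(0.0, 0.3, 0.5) == 0.0

    def test_simulation_oracle(self):
        """Threshold-liability generative oracle: a latent liability with a
        known genotype effect and logistic residuals is dichotomized at the
        prevalence threshold; the per-allele log-OR is estimated by logistic
        regression and the conversion must recover the liability-scale R2
        measured directly on the simulated liabilities, within 15%."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        n, eaf, prev = 200_000, 0.3, 0.5
        lor_target = 0.5
        g = rng.binomial(2, eaf, n).astype(float)
        liability = lor_target * g + rng.logistic(0, 1, n)
        thresh = np.quantile(liability, 1 - prev)
        y = (liability > thresh).astype(float)
        lor_hat = sm.Logit(y, sm.add_constant(g)).fit(disp=0).params[1]

        r2_oracle = np.corrcoef(g, liability)[0, 1] ** 2
        r2_est = r2_liability_from_lor(lor_hat, eaf, prev)
        assert r2_est == pytest.approx(r2_oracle, rel=0.15)

    def test_invalid_prevalence(self):
        with pytest.raises(InstrumentError):
            r2_liability_from_lor(0.5, 0.3, 1.5)

    def test_inverse_round_trip(self):
        for r2 in (0.001, 0.01, 0.05):
            lor = lor_from_r2_liability(r2, 0.25)
            assert r2_liability_from_lor(lor, 0.25, 0.5) == pytest.approx(r2, rel=1e-10)


class TestFStatistic:
    def test_direct_substitution(self):
        assert f_statistic(0.01, 3890, 1) == pytest.approx(0.01 * 3888 / 0.99)

    def test_zero_r2(self):
        assert f_statistic(0.0, 100) == 0.0

    def test_r2_one_raises(self):
        with pytest.raises(InstrumentError):
            f_statistic(1.0, 100)

    @given(z=st.floats(2, 10), n=st.integers(10_000, 10**6))
    @settings(max_examples=100, deadline=None)
    def test_f_approx_z2_when_n_large(self, z, n):
        # r2 = z^2/(z^2+n); for k=1 F should be within 0.2% of z^2 when n >> z^2
        r2 = z**2 / (z**2 + n)
        assert f_statistic(r2, n, 1) == pytest.approx(z**2, rel=0.002)


class TestPower:
    def test_printed_design(self):
        spec = PowerSpec(alpha=0.05, r2=0.01, odds_ratio=1.2,
                         n_case=55_168, n_control=65_160)
        assert mr_power_binary(spec) == pytest.approx(0.89, abs=0.02)

    def test_null_or(self):
        spec = PowerSpec(alpha=0.05, r2=0.01, odds_ratio=1.0,
                         n_case=1000, n_control=1000)
        assert mr_power_binary(spec) == pytest.approx(0.025, abs=1e-9)

    def test_monotone_in_r2(self):
        powers = [
            mr_power_binary(PowerSpec(0.05, r2, 1.2, 5000, 5000))
            for r2 in np.linspace(0.001, 0.05, 25)
        ]
        assert all(b > a for a, b in zip(powers, powers[1:]))

    @pytest.mark.parametrize("field,values", [
        ("n_case", [1000, 2000, 5000, 20000]),
        ("n_control", [1000, 2000, 5000, 20000]),
        ("odds_ratio", [1.05, 1.1, 1.3, 1.8]),
    ])
    def test_monotone_in_design(self, field, values):
        base = dict(alpha=0.05, r2=0.01, odds_ratio=1.2, n_case=3000, n_control=3000)
        powers = []
        for v in values:
            base2 = dict(base)
            base2[field] = v
            powers.append(mr_power_binary(PowerSpec(**base2)))
        assert powers == sorted(powers)
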