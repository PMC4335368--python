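"""t-tests against closed forms and permutation oracles, Bland-Altman,
cohort summaries and simulated observer repeatability."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from pntquant.exceptions import DegenerateStatisticsError, ValidationError
from pntquant.stats import (
    bland_altman,
    cohort_table,
    flow_concordance,
    independent_t,
    observer_repeatability,
    paired_t,
)


class TestPairedT:
    def test_identical_vectors(self):
        assert paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.raises(DegenerateStatisticsError):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_hand_computed_example(self):
        # d = {-1, 0, -1, -1}: mean -0.75, sd 0.5, t = -3, p = 2*sf(3, df=3)
        t, p = paired_t([1, 2, 3, 4], [2, 2, 4, 5])
        assert t == pytest.approx(-3.0)
        assert p == pytest.approx(2 * sps.t.sf(3.0, 3), rel=1e-12)

    def test_matches_exact_sign_flip_permutation(self, rng):
        x = rng.normal(0.6, 1.0, 10)
        y = rng.normal(0.0, 1.0, 10)
        t_obs, p_t = paired_t(x, y)
        d = x - y
        # exact enumeration of all 2^10 sign assignments
        stats = []
        for signs in itertools.product([-1.0, 1.0], repeat=d.size):
            ds = d * np.array(signs)
            sd = ds.std(ddof=1)
            stats.append(abs(ds.mean() / (sd / math.sqrt(d.size))) if sd > 0 else 0.0)
        p_perm = float(np.mean(np.asarray(stats) >= abs(t_obs) - 1e-12))
        assert p_t == pytest.approx(p_perm, abs=0.06)


class TestIndependentT:
    def test_identical_groups(self):
        assert independent_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_zero_variance_groups_degenerate(self):
        with pytest.raises(DegenerateStatisticsError):
            independent_t([0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0])

    def test_welch_closed_form(self):
        x = np.array([19.8, 20.4, 19.6, 17.8, 18.5, 18.9, 18.3, 18.9, 19.5, 22.0])
        y = np.array([28.2, 26.6, 20.1, 23.3, 25.2, 22.1, 17.7, 27.6, 20.6, 13.7])
        t, p = independent_t(x, y)
        # Welch statistic and Satterthwaite df computed explicitly
        v1, v2 = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        t_exp = (x.mean() - y.mean()) / math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (x.size - 1) + v2**2 / (y.size - 1))
        assert t == pytest.approx(t_exp, rel=1e-12)
        assert p == pytest.approx(2 * sps.t.sf(abs(t_exp), df), rel=1e-9)

    def test_matches_label_permutation(self, rng):
        x = rng.normal(1.0, 1.0, 8)
        y = rng.normal(0.0, 1.0, 8)
        t_obs, p_t = independent_t(x, y)
        pooled = np.concatenate([x, y])
        perm_rng = np.random.default_rng(99)
        stats = []
        for _ in range(20000):
            perm = perm_rng.permutation(pooled)
            stats.append(abs(independent_t(perm[:8], perm[8:])[0]))
        p_perm = float(np.mean(np.asarray(stats) >= abs(t_obs) - 1e-12))
        assert p_t == pytest.approx(p_perm, abs=0.06)


class TestBlandAltman:
    def test_identical_inputs_all_zero(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.mean_difference == 0.0
        assert res.coefficient_of_repeatability == 0.0
        assert (res.loa_lower, res.loa_upper) == (0.0, 0.0)

    def test_closed_form_example(self):
        res = bland_altman([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.mean_difference == pytest.approx(2.0)
        assert res.sd_difference == pytest.approx(1.0)
        assert res.loa_lower == pytest.approx(0.04)
        assert res.loa_upper == pytest.approx(3.96)
        assert res.coefficient_of_repeatability == pytest.approx(1.96)

    def test_large_normal_sample_coverage(self, rng):
        d = rng.normal(3.0, 2.0, 10_000)
        res = bland_altman(d, np.zeros_like(d))
        inside = np.mean((d >= res.loa_lower) & (d <= res.loa_upper))
        assert 0.93 <= inside <= 0.97

    def test_cr_invariant_under_shift(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        a = bland_altman(x, y)
        b = bland_altman(x + 17.3, y + 17.3)
        assert a.coefficient_of_repeatability == pytest.approx(b.coefficient_of_repeatability)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0], [2.0])


class TestCohortTable:
    def test_fabry_cohort_method_comparison(self, fabry_cohort_measured):
        summary = cohort_table(fabry_cohort_measured)
        table = summary.to_frame()
        assert summary.n_per_group == {"fabry": 20}
        # the P&T-inclusive method yields larger mass, smaller volumes
        assert table.loc["lvm", "fabry_minc_mean"] > table.loc["lvm", "fabry_mex_mean"]
        assert table.loc["lvedv", "fabry_mex_mean"] > table.loc["lvedv", "fabry_minc_mean"]
        assert table.loc["lvesv", "fabry_mex_mean"] > table.loc["lvesv", "fabry_minc_mean"]
        assert table.loc["lvef", "fabry_minc_mean"] > table.loc["lvef", "fabry_mex_mean"]
        for measure in ("lvedv", "lvesv", "lvm", "lvef"):
            assert table.loc[measure, "fabry_paired_p"] < 0.05

    def test_degenerate_when_methods_identical(self, fabry_cohort_measured):
        import copy

        clones = []
        for m in fabry_cohort_measured[:3]:
            clone = copy.copy(m)
            clone.mex = m.minc
            clones.append(clone)
        table = cohort_table(clones).to_frame()
        assert table["fabry_paired_p"].fillna(1.0).eq(1.0).all()

    def test_single_subject_rejected(self, fabry_cohort_measured):
        with pytest.raises(ValidationError):
            cohort_table(fabry_cohort_measured[:1])


class TestFlowConcordance:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            flow_concordance([], "minc")

    def test_minc_concordant_mex_overestimates(self, fabry_cohort_measured):
        mean_inc, sem_inc, _ = flow_concordance(fabry_cohort_measured, "minc")
        mean_ex, _, p_ex = flow_concordance(fabry_cohort_measured, "mex")
        assert abs(mean_inc) < 3.0
        assert mean_ex > 5.0
        assert p_ex < 0.05


class TestObserverRepeatability:
    def test_zero_perturbation_is_exact(self, small_cohort):
        results = observer_repeatability(
            small_cohort, perturbation_seed=1, noise_redraw=False, roi_rotation_deg=0.0
        )
        for res in results.values():
            assert res.mean_difference == 0.0
            assert res.coefficient_of_repeatability == 0.0

    def test_noise_redraw_unbiased_and_noise_scales_cr(self, small_cohort):
        results = observer_repeatability(small_cohort, perturbation_seed=5,
                                         roi_rotation_deg=0.0)
        for res in results.values():
            sem = res.sd_difference / math.sqrt(res.n) if res.sd_difference else 1.0
            assert abs(res.mean_difference) <= max(3 * sem, 3.0)

        import dataclasses

        from pntquant.phantom import SubjectRecord, build_phantom

        quiet = []
        for rec in small_cohort:
            spec = dataclasses.replace(rec.spec, noise_sd=5.0)
            cine, velocity, truth = build_phantom(spec, rec.seed)
            quiet.append(
                SubjectRecord(rec.subject_id, rec.group, rec.height, rec.weight,
                              cine, velocity, truth, spec=spec, seed=rec.seed)
            )
        noisy_cr = np.mean(
            [r.coefficient_of_repeatability for r in results.values()]
        )
        quiet_cr = np.mean(
            [
                r.coefficient_of_repeatability
                for r in observer_repeatability(quiet, perturbation_seed=5,
                                                roi_rotation_deg=0.0).values()
            ]
        )
        assert quiet_cr < noisy_cr

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            observer_repeatability([], 1)
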