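"""Differential-expression core: cpm, BCV estimation, exact test, DEG calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import prizeforest as pf
from prizeforest.degs import CountMatrix, DEGFilter, DispersionModel
from prizeforest.errors import EstimationError, InputError, UnsupportedDesignError

from conftest import bh_oracle


def conditional_oracle(y1: int, y2: int, dispersion: float) -> float:
    """Independent linear-space summation oracle for the exact test.

    P(y | s) ~ NB(y; mu, phi) * NB(s - y; mu, phi) with mu = s/2, evaluated
    with scipy pmf calls and normalized by the full sum; two-sided p collects
    all splits with probability <= observed (relative tie tolerance 1e-9).
    """
    s = y1 + y2
    if s == 0:
        return 1.0
    k = np.arange(s + 1)
    if dispersion == 0:
        w = stats.binom.pmf(k, s, 0.5)
    else:
        r = 1.0 / dispersion
        mu = s / 2.0
        p = r / (r + mu)
        half = stats.nbinom.pmf(k, r, p)
        w = half * half[::-1]
        w = w / w.sum()
    obs = w[y1]
    return float(min(1.0, w[w <= obs * (1 + 1e-9)].sum()))


class TestCpm:
    def test_zero_count_is_zero(self):
        assert pf.cpm(0, 1e6) == 0.0

    def test_filter_boundary_value(self):
        assert pf.cpm(5, 1e6) == pytest.approx(5.0)

    def test_hand_arithmetic(self):
        assert pf.cpm(123, 2e6) == pytest.approx(61.5)

    def test_zero_library_rejected(self):
        with pytest.raises(InputError):
            pf.cpm(10, 0)


class TestEstimateBcv:
    def test_zero_variation_hits_floor(self):
        counts = pd.DataFrame(
            {"control": [10000] * 20, "treated": [10000] * 20},
            index=[f"HK{i}" for i in range(20)],
        )
        cm = CountMatrix(counts, lib_sizes=pd.Series({"control": 2e5, "treated": 2e5}))
        model = pf.estimate_bcv(cm, counts.index)
        assert model.bcv == pytest.approx(0.01)

    def test_recovers_true_bcv_on_simulation(self):
        # parameter recovery across seeds: estimate within +/-0.02 of 0.045
        errors = []
        for seed in range(20):
            cfg = pf.SynthConfig(seed=seed, n_genes=2000, n_housekeeping=200,
                                 bcv_true=0.045, lib_size=1e7)
            cm, labels = pf.make_counts(cfg)
            hk = labels.index[(labels == "housekeeping").to_numpy()]
            errors.append(pf.estimate_bcv(cm, hk).bcv - 0.045)
        assert max(abs(e) for e in errors) <= 0.02

    def test_override_is_returned_verbatim(self):
        counts = pd.DataFrame({"a": [1], "b": [2]}, index=["g"])
        cm = CountMatrix(counts, lib_sizes=pd.Series({"a": 1e6, "b": 1e6}))
        model = pf.estimate_bcv(cm, ["g"], bcv_override=0.045)
        assert model.bcv == 0.045 and model.dispersion == 0.045**2

    def test_too_few_housekeeping_genes(self, planted_counts):
        cm, labels = planted_counts
        with pytest.raises(EstimationError):
            pf.estimate_bcv(cm, list(cm.gene_ids[:3]))


class TestExactTest:
    def test_balanced_split_is_certain(self):
        assert pf.exact_test(10, 10) == 1.0

    def test_dispersion_zero_equals_binomial_exact_test(self):
        for y1, y2 in [(20, 0), (15, 5), (30, 10), (100, 80), (7, 7)]:
            expected = stats.binomtest(y1, y1 + y2, 0.5).pvalue
            assert pf.exact_test(y1, y2) == pytest.approx(expected, abs=1e-8)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            s = int(rng.integers(1, 201))
            y1 = int(rng.integers(0, s + 1))
            disp = float(rng.choice([0.0, 0.002025, 0.01, 0.1]))
            got = pf.exact_test(y1, s - y1, dispersion=disp)
            want = conditional_oracle(y1, s - y1, disp)
            assert got == pytest.approx(want, abs=1e-10)

    def test_specific_overdispersed_case(self):
        got = pf.exact_test(40, 10, dispersion=0.002025)
        want = conditional_oracle(40, 10, 0.002025)
        assert got == pytest.approx(want, abs=1e-10)

    def test_library_equalization_scales_counts(self):
        # geometric-mean equalization: libs (2e6, 5e5) scale to 1e6, so
        # (40, 5) becomes the (20, 10) comparison at equal libraries
        p_equal = pf.exact_test(20, 10, 1e6, 1e6, 0.01)
        p_scaled = pf.exact_test(40, 5, 2e6, 5e5, 0.01)
        assert p_scaled == pytest.approx(p_equal, abs=1e-12)

    @given(st.integers(0, 80), st.integers(0, 80),
           st.floats(0, 0.3, allow_nan=False))
    @settings(max_examples=60, deadline=None)
    def test_symmetry_at_equal_libraries(self, y1, y2, disp):
        assert pf.exact_test(y1, y2, dispersion=disp) == pytest.approx(
            pf.exact_test(y2, y1, dispersion=disp), abs=1e-12
        )

    def test_monotone_in_imbalance_at_fixed_total(self):
        s = 60
        for disp in (0.0, 0.05):
            ps = [pf.exact_test(y, s - y, dispersion=disp) for y in range(s // 2, s + 1)]
            assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_negative_inputs_rejected(self):
        with pytest.raises(InputError):
            pf.exact_test(-1, 5)


class TestLogFoldChange:
    def test_equal_cpm_is_zero(self):
        assert pf.log_fold_change(12.0, 12.0) == pytest.approx(0.0)

    def test_fourfold_ratio_with_vanishing_prior(self):
        assert pf.log_fold_change(40.0, 10.0, prior=1e-9) == pytest.approx(2.0, abs=1e-6)

    def test_zero_numerator_with_unit_prior(self):
        assert pf.log_fold_change(0.0, 30.0, prior=1.0) == pytest.approx(
            math.log2(1 / 31)
        )


class TestBenjaminiHochberg:
    def test_matches_from_definition_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for n in (1, 5, 100, 1000):
            p = rng.uniform(size=n)
            got = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(got, bh_oracle(p), atol=1e-12)


class TestCallDegs:
    def test_planted_degs_recovered_with_few_false_calls(self, planted_counts):
        cm, labels = planted_counts
        table = pf.call_degs(cm, DispersionModel(bcv=0.045))
        called = set(table.loc[table["call"] != "ns", "gene_id"])
        de = set(labels.index[labels.isin(["de_up", "de_down"]).to_numpy()])
        assert len(called & de) >= 80
        false = called - de
        assert len(false) <= 0.01 * len(table)

    def test_identical_samples_yield_no_calls(self):
        counts = pd.DataFrame({"control": [100, 2000, 50], "treated": [100, 2000, 50]},
                              index=["a", "b", "c"])
        cm = CountMatrix(counts, lib_sizes=pd.Series({"control": 1e6, "treated": 1e6}))
        table = pf.call_degs(cm, DispersionModel(bcv=0.045))
        assert (table["call"] == "ns").all()
        assert (table["PValue"] == 1.0).all()

    def test_cpm_filter_excludes_low_genes_before_testing(self):
        counts = pd.DataFrame({"control": [3, 300], "treated": [4, 600]},
                              index=["low", "high"])
        cm = CountMatrix(counts, lib_sizes=pd.Series({"control": 1e6, "treated": 1e6}))
        table = pf.call_degs(cm, DispersionModel(bcv=0.045))
        assert list(table["gene_id"]) == ["high"]

    def test_more_than_two_samples_rejected(self):
        counts = pd.DataFrame({"a": [1], "b": [2], "c": [3]}, index=["g"])
        cm = CountMatrix(counts)
        with pytest.raises(UnsupportedDesignError):
            pf.call_degs(cm, DispersionModel(bcv=0.045))

    def test_sorted_by_abs_logfc_and_fdr_bounds_p(self, planted_counts):
        cm, _ = planted_counts
        table = pf.call_degs(cm, DispersionModel(bcv=0.045))
        assert (table["FDR"] >= table["PValue"] - 1e-12).all()
        abs_lfc = table["logFC"].abs().to_numpy()
        assert (np.diff(abs_lfc) <= 1e-12).all()
        up = table[table["call"] == "up"]
        down = table[table["call"] == "down"]
        assert (up["logFC"] >= 2.0).all() and (down["logFC"] <= -2.0).all()
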