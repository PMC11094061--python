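"""Two-segment breakpoint fitting, event testing and calling."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

import apashift as a
from apashift.coverage import ValidationError
from apashift.quant import (QC_LOW_COVERAGE, QC_NO_BREAKPOINT, QC_OK,
                            adjust_and_call)


def brute_force_fit(D, search_min=100):
    """Exhaustive breakpoint minimizer with closed-form segment means.

    Clamps negative short-isoform abundance to the flat fit; ties are
    broken toward the most distal breakpoint.
    """
    D = np.atleast_2d(np.asarray(D, float))
    L = D.shape[1]
    best_rss, best_b = None, None
    for b in range(search_min, L - search_min + 1):
        rss = 0.0
        for row in D:
            um, dm = row[:b].mean(), row[b:].mean()
            if um < dm:
                m = row.mean()
                rss += ((row - m) ** 2).sum()
            else:
                rss += ((row[:b] - um) ** 2).sum() + ((row[b:] - dm) ** 2).sum()
        if best_rss is None or rss <= best_rss:
            best_rss, best_b = rss, b
    pduis = []
    for row in D:
        um, dm = row[:best_b].mean(), row[best_b:].mean()
        if um < dm:
            w_l, w_s = row.mean(), 0.0
        else:
            w_l, w_s = dm, um - dm
        pduis.append(100.0 * w_l / (w_l + w_s) if w_l + w_s > 0 else np.nan)
    return best_b, np.array(pduis)


def fisher_two_sided_oracle(table):
    """Exact two-sided Fisher p by full enumeration with rational
    arithmetic: sum of hypergeometric point probabilities <= P(observed)."""
    (x, b), (c, d) = table
    r1, r2 = x + b, c + d
    c1 = x + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(k):
        return Fraction(comb(r1, k) * comb(r2, c1 - k), denom)

    p_obs = pmf(x)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = pmf(k)
        if p <= p_obs:
            total += p
    return float(total)


class TestFitTwoSegment:
    def test_flat_coverage_is_all_distal(self):
        fit = a.fit_two_segment(np.full((3, 1000), 50.0))
        assert np.allclose(fit.pdui, 100.0)
        assert np.allclose(fit.w_short, 0.0)

    def test_step_to_zero_is_all_proximal(self):
        row = np.where(np.arange(1000) < 200, 80.0, 0.0)
        fit = a.fit_two_segment(np.tile(row, (2, 1)))
        assert fit.breakpoint == 200
        assert np.allclose(fit.pdui, 0.0)
        assert fit.qc_flag == QC_OK

    def test_noiseless_mixture_recovers_breakpoint_and_pdui(self):
        row = np.where(np.arange(1200) < 300, 100.0, 40.0)
        fit = a.fit_two_segment(row[None, :])
        assert fit.breakpoint == 300
        assert abs(fit.pdui[0] - 40.0) < 1e-12
        bb, bp = brute_force_fit(row[None, :])
        assert fit.breakpoint == bb
        assert np.allclose(fit.pdui, bp, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_on_noisy_genes(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(400, 900))
        b_true = int(rng.integers(150, L - 150))
        pdui = rng.uniform(10, 90)
        lam = np.where(np.arange(L) < b_true, 30.0, 30.0 * pdui / 100)
        D = rng.poisson(lam, size=(4, L)).astype(float)
        fit = a.fit_two_segment(D)
        bb, bp = brute_force_fit(D)
        assert fit.breakpoint == bb
        assert np.allclose(fit.pdui, bp, atol=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        D = rng.poisson(np.where(np.arange(500) < 220, 40.0, 12.0),
                        size=(3, 500)).astype(float)
        f1 = a.fit_two_segment(D)
        f2 = a.fit_two_segment(D * 7.5)
        assert f1.breakpoint == f2.breakpoint
        assert np.allclose(f1.pdui, f2.pdui, atol=1e-9)

    def test_ties_resolve_to_most_distal_breakpoint(self):
        # integer flat coverage: every breakpoint fits exactly
        fit = a.fit_two_segment(np.full((1, 600), 10.0), search_min=100)
        assert fit.breakpoint == 500

    def test_low_coverage_flagged_and_not_fitted(self):
        fit = a.fit_two_segment(np.full((2, 400), 0.1), min_mean_depth=1.0)
        assert fit.qc_flag == QC_LOW_COVERAGE
        assert fit.breakpoint is None
        assert np.all(np.isnan(fit.pdui))

    def test_flat_gene_flagged_no_breakpoint(self):
        rng = np.random.default_rng(4)
        D = rng.poisson(30.0, size=(3, 600)).astype(float)
        fit = a.fit_two_segment(D)
        assert fit.qc_flag == QC_NO_BREAKPOINT

    def test_unequal_lengths_rejected(self):
        t1 = a.CoverageTrack("g", "s1", "c", 1, np.ones(300), normalized=True)
        t2 = a.CoverageTrack("g", "s2", "c", 2, np.ones(301), normalized=True)
        with pytest.raises(ValidationError, match="unequal"):
            a.fit_two_segment([t1, t2])

    def test_short_utr_rejected(self):
        with pytest.raises(ValidationError, match="search_min"):
            a.fit_two_segment(np.ones((1, 150)), search_min=100)


def gene_fits_frame(ref_pduis, stim_pduis, ref_tables=None, stim_tables=None):
    rows = []
    for i, p in enumerate(ref_pduis):
        w_l, w_s = (ref_tables[i] if ref_tables
                    else (p, 100 - p))
        rows.append(dict(condition="naive", pdui=p, w_long=w_l, w_short=w_s))
    for i, p in enumerate(stim_pduis):
        w_l, w_s = (stim_tables[i] if stim_tables
                    else (p, 100 - p))
        rows.append(dict(condition="stim", pdui=p, w_long=w_l, w_short=w_s))
    return pd.DataFrame(rows)


class TestTestEvent:
    def test_identical_groups_are_null(self):
        df = gene_fits_frame([50, 50, 50], [50, 50, 50])
        mref, mstim, dpdui, p = a.test_event(df, "naive", "stim")
        assert dpdui == 0.0
        assert p == 1.0

    def test_uniform_shift_reports_mean_difference(self):
        df = gene_fits_frame([80.0, 82.0, 78.0], [55.0, 57.0, 53.0])
        _, _, dpdui, _ = a.test_event(df, "naive", "stim")
        assert abs(dpdui - (-25.0)) < 1e-12

    def test_fisher_p_matches_enumeration_oracle(self):
        # pooled table: ref (90 long, 10 short) vs stim (40 long, 60 short)
        df = gene_fits_frame([90, 90], [40, 40],
                             ref_tables=[(45, 5), (45, 5)],
                             stim_tables=[(20, 30), (20, 30)])
        _, _, _, p = a.test_event(df, "naive", "stim")
        oracle = fisher_two_sided_oracle([[90, 10], [40, 60]])
        assert np.isclose(p, oracle, rtol=1e-8)

    def test_single_replicate_group_reports_p_one(self):
        df = gene_fits_frame([80.0], [50.0, 52.0])
        _, _, dpdui, p = a.test_event(df, "naive", "stim")
        assert p == 1.0
        assert abs(dpdui - (-29.0)) < 1e-12

    def test_empty_group_rejected(self):
        df = gene_fits_frame([80.0], [50.0])
        with pytest.raises(ValidationError, match="empty group"):
            a.test_event(df, "naive", "other")

    def test_welch_alternative_behaves_on_shifted_groups(self):
        df = gene_fits_frame([80.0, 81.0, 79.0], [50.0, 51.0, 49.0])
        _, _, _, p = a.test_event(df, "naive", "stim", method="welch")
        assert p < 0.01


class TestAdjustAndCall:
    def test_bh_with_equal_ps_is_identity(self):
        ev = pd.DataFrame({"gene_id": list("abc"), "comparison": "x",
                           "mean_pdui_ref": 80.0, "mean_pdui_stim": 50.0,
                           "dpdui": [-30.0] * 3, "p_raw": [0.01] * 3})
        out = adjust_and_call(ev)
        assert np.allclose(out["p_adj"], 0.01)
        assert list(out["call"]) == ["shortened"] * 3

    def test_between_band_is_indeterminate(self):
        ev = pd.DataFrame({"gene_id": ["a"], "comparison": "x",
                           "mean_pdui_ref": 60.0, "mean_pdui_stim": 45.0,
                           "dpdui": [-15.0], "p_raw": [0.2]})
        assert adjust_and_call(ev)["call"].iloc[0] == "indeterminate"

    def test_empty_batch_passes_through(self):
        out = adjust_and_call(pd.DataFrame(
            columns=["gene_id", "comparison", "mean_pdui_ref",
                     "mean_pdui_stim", "dpdui", "p_raw"]))
        assert len(out) == 0
        assert "call" in out.columns
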