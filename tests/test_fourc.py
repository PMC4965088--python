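"""In-silico digest, VST, loess background, residual p-values, BH and the
replicate-consensus interaction call."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from polydomain.core_io import GenomicInterval
from polydomain.fourc import (
    FourCProfile,
    RestrictionFragment,
    analyze_profile,
    bh_adjust,
    call_interactions,
    digest_sequence,
    estimate_dispersion,
    fit_background,
    loess_smooth,
    read_counts_tsv,
    residual_pvalues,
    vst_transform,
    write_counts_tsv,
)


class TestDigest:
    def test_no_sites_gives_single_fragment(self):
        frags = digest_sequence("ACGTACGT", "GAATTC")
        assert len(frags) == 1
        assert (frags[0].interval.start, frags[0].interval.end) == (0, 8)

    def test_ecori_cut_between_g_and_a(self):
        # G^AATTC sticky-end cut: offset 1 into the site
        frags = digest_sequence("AAGAATTCCCGAATTCTT", "GAATTC", cut_offset=1)
        bounds = [(f.interval.start, f.interval.end) for f in frags]
        assert bounds == [(0, 3), (3, 11), (11, 18)]

    def test_default_cut_at_site_start(self):
        frags = digest_sequence("AAGAATTCCCGAATTCTT", "GAATTC")
        bounds = [(f.interval.start, f.interval.end) for f in frags]
        assert bounds == [(0, 2), (2, 10), (10, 18)]

    def test_overlapping_site_occurrences_all_cut(self):
        frags = digest_sequence("AAAAA", "AAAA")
        bounds = [(f.interval.start, f.interval.end) for f in frags]
        # matches at 0 and 1; the cut at 0 is a no-op boundary
        assert bounds == [(0, 1), (1, 5)]

    def test_ambiguous_site_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            digest_sequence("ACGT", "GANTC")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=200),
           st.sampled_from(["GAATTC", "GATC", "AA"]))
    @settings(derandomize=True, max_examples=200)
    def test_fragments_tile_sequence(self, seq, site):
        frags = digest_sequence(seq, site)
        assert sum(f.interval.length_bp() for f in frags) == len(seq)
        assert frags[0].interval.start == 0
        for a, b in zip(frags, frags[1:]):
            assert a.interval.end == b.interval.start
        assert [f.index for f in frags] == list(range(len(frags)))


class TestVst:
    @pytest.mark.parametrize("alpha", [0.01, 0.1, 1.0])
    def test_zero_maps_to_zero_and_monotone(self, alpha):
        assert vst_transform(np.array([0]), alpha)[0] == 0.0
        g = vst_transform(np.arange(100), alpha)
        assert np.all(np.diff(g) > 0)

    @pytest.mark.parametrize("n", [1, 10, 100, 5000])
    @pytest.mark.parametrize("alpha", [0.05, 0.1, 0.5])
    def test_matches_integral_of_reciprocal_sd(self, n, alpha):
        # g(n) = integral_0^n dmu / sqrt(mu + alpha mu^2), evaluated numerically
        expected, err = integrate.quad(
            lambda mu: 1.0 / math.sqrt(mu + alpha * mu * mu), 0, n,
            epsabs=1e-13, epsrel=1e-13,
        )
        got = float(vst_transform(np.array([n]), alpha)[0])
        assert got == pytest.approx(expected, abs=max(1e-10, 10 * err))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            vst_transform(np.array([-1]), 0.1)

    def test_dispersion_estimate_recovers_simulated_alpha(self, rng):
        alpha = 0.2
        mu = rng.uniform(50, 500, size=4000)
        n = 1.0 / alpha
        counts = rng.negative_binomial(n, n / (n + mu), size=(4, 4000)).T
        est = estimate_dispersion(counts)
        assert est == pytest.approx(alpha, rel=0.3)

    def test_dispersion_fallback_for_single_replicate(self):
        assert estimate_dispersion(np.ones((10, 1))) == 0.1


def _fragments(n, size=100):
    return [
        RestrictionFragment(GenomicInterval("chr2R", i * size, (i + 1) * size), i)
        for i in range(n)
    ]


class TestLoessBackground:
    def test_exact_on_linear_data(self):
        frags = _fragments(50)
        mids = np.array([f.interval.midpoint() for f in frags])
        values = 0.01 * mids + 3.0
        fit = fit_background(frags, values, exclusion_window=None)
        np.testing.assert_allclose(fit, values, atol=1e-6)

    def test_constant_data_gives_constant_fit(self):
        frags = _fragments(30)
        fit = fit_background(frags, np.full(30, 7.0), exclusion_window=None)
        np.testing.assert_allclose(fit, 7.0, atol=1e-9)

    def test_excluded_fragments_still_receive_predictions(self):
        frags = _fragments(50)
        mids = np.array([f.interval.midpoint() for f in frags])
        values = 0.01 * mids + 3.0
        excl = GenomicInterval("chr2R", 2000, 3000)
        values_spiked = values.copy()
        inside = (mids >= 2000) & (mids < 3000)
        values_spiked[inside] += 100
        fit = fit_background(frags, values_spiked, exclusion_window=excl)
        assert np.all(np.isfinite(fit))
        # predictions inside the window ignore the spiked values
        np.testing.assert_allclose(fit[inside], values[inside], atol=1e-6)

    def test_spike_on_smooth_decay_leaves_positive_residual(self):
        frags = _fragments(200)
        mids = np.array([f.interval.midpoint() for f in frags])
        smooth = 100.0 / (1.0 + mids / 2000.0)
        values = smooth.copy()
        values[120] *= 3
        fit = fit_background(frags, values, exclusion_window=None, span=0.2)
        assert values[120] - fit[120] > 0.5 * (values[120] - smooth[120])
        assert abs(fit[120] - smooth[120]) < 0.3 * smooth[120]

    def test_too_few_points_rejected(self):
        frags = _fragments(8)
        with pytest.raises(ValueError, match="at least"):
            fit_background(frags, np.ones(8), exclusion_window=None)

    def test_loess_matches_statsmodels_lowess_interior(self):
        # independent cross-check of the local-linear tricube smoother
        from statsmodels.nonparametric.smoothers_lowess import lowess

        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(0, 100, 150))
        y = np.sin(x / 15.0) + rng.normal(0, 0.05, x.size)
        ours = loess_smooth(x, y, x, span=1.0 / 3)
        ref = lowess(y, x, frac=1.0 / 3, it=0, return_sorted=False)
        # boundary windows differ slightly between implementations
        interior = slice(20, -20)
        np.testing.assert_allclose(ours[interior], ref[interior], atol=0.02)


class TestResidualPvalues:
    def test_zero_residual_gives_half(self):
        r = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        p = residual_pvalues(r, np.zeros_like(r))
        assert p[2] == pytest.approx(0.5)

    def test_z_of_2326_gives_p_of_001(self):
        a = 1.0 / 1.4826  # residual spread chosen so the robust scale is 1
        r = np.array([-2.326348, -a, 0.0, a, 2.326348])
        p = residual_pvalues(r, np.zeros_like(r))
        assert p[-1] == pytest.approx(0.01, abs=1e-5)

    def test_affine_invariance(self, rng):
        values = rng.normal(10, 2, 200)
        fit = np.full(200, 10.0)
        p1 = residual_pvalues(values, fit)
        p2 = residual_pvalues(5.0 * values - 3.0, 5.0 * fit - 3.0)
        np.testing.assert_allclose(p1, p2, rtol=1e-10)

    def test_null_pvalues_approximately_uniform(self, rng):
        values = rng.normal(0, 1, 2000)
        p = residual_pvalues(values, np.zeros(2000))
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_degenerate_scale_rejected(self):
        with pytest.raises(ValueError, match="robust scale"):
            residual_pvalues(np.ones(5), np.ones(5))


def bh_oracle(p):
    """Step-up from the definition: find the largest k with p_(k) <= k q / n
    by scanning every candidate threshold."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    for rank_pos in range(n):
        i = order[rank_pos]
        best = 1.0
        for rank_pos2 in range(rank_pos, n):
            j = order[rank_pos2]
            best = min(best, p[j] * n / (rank_pos2 + 1))
        q[i] = best
    return q


class TestBhAdjust:
    def test_single_p_is_identity(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.03])), [0.03])

    def test_hand_worked_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.5]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_matches_statsmodels_and_definition_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            n = int(rng.integers(1, 60))
            p = rng.uniform(size=n)
            q = bh_adjust(p)
            np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
            np.testing.assert_allclose(
                q, multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    @settings(derandomize=True, max_examples=200)
    def test_order_preserving_and_bounded(self, p):
        p = np.asarray(p)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))


def _profile_with(p, q, excluded=False):
    frags = _fragments(3)
    prof = FourCProfile(
        bait=frags[0].interval,
        exclusion_window=(
            frags[1].interval if excluded
            else GenomicInterval("chrX", 0, 1)
        ),
        fragments=frags,
        counts=np.ones((3, 2), dtype=int),
    )
    prof.p = np.tile(np.asarray(p), (3, 1)).astype(float)
    prof.q = np.tile(np.asarray(q), (3, 1)).astype(float)
    return prof


class TestCallInteractions:
    @pytest.mark.parametrize(
        "p, q, expected",
        [
            ((0.005, 0.005), (0.05, 0.2), True),   # p both, q in one
            ((0.005, 0.02), (0.01, 0.01), False),  # p fails one replicate
            ((0.5, 0.5), (0.9, 0.9), False),
            ((0.005, 0.005), (0.2, 0.2), False),   # q fails both
        ],
    )
    def test_consensus_rule(self, p, q, expected):
        prof = call_interactions(_profile_with(p, q))
        assert bool(prof.significant[0]) is expected

    def test_exclusion_window_never_called(self):
        prof = call_interactions(_profile_with((0.001, 0.001), (0.01, 0.01),
                                               excluded=True))
        assert not prof.significant[1]
        assert prof.significant[0] and prof.significant[2]

    def test_requires_two_replicates(self):
        frags = _fragments(3)
        prof = FourCProfile(
            bait=frags[0].interval,
            exclusion_window=frags[0].interval,
            fragments=frags,
            counts=np.ones((3, 1), dtype=int),
        )
        prof.p = prof.q = np.ones((3, 1))
        with pytest.raises(ValueError, match="replicate"):
            call_interactions(prof)


class TestCountsTsvRoundtrip:
    def test_roundtrip(self, tmp_path):
        from polydomain.synthetic_data import SimConfig, simulate_4c

        prof, _ = simulate_4c(SimConfig(seed=3))
        path = tmp_path / "counts.tsv"
        write_counts_tsv(prof, path)
        back = read_counts_tsv(path, prof.bait, prof.exclusion_window)
        np.testing.assert_array_equal(back.counts, prof.counts)
        assert back.fragments[10].interval == prof.fragments[10].interval

    def test_analyze_requires_two_replicates(self):
        frags = _fragments(20)
        prof = FourCProfile(
            bait=frags[0].interval,
            exclusion_window=frags[0].interval,
            fragments=frags,
            counts=np.ones((20, 1), dtype=int),
        )
        with pytest.raises(ValueError, match="replicate"):
            analyze_profile(prof)
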