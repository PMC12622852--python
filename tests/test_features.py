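"""Feature-detector tests: stated examples, brute-force oracle equivalence on
random profiles, region additivity/conservation and the scar dose response."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from valkit import ScarParams, build_genome, simulate_specimen
from valkit.features import (
    FeatureConfig,
    assemble_features,
    breakpoints_per_arm,
    compute_gloh,
    feature_names,
    oscillation_features,
    segment_size_features,
)
from valkit.genome import MB
from valkit.simulate import PROFILE_COLUMNS, CopyNumberProfile

from .conftest import make_random_profile
from .oracles import (
    brute_breakpoints,
    brute_gloh,
    brute_oscillation_chains,
    brute_size_histogram,
)


def profile_from_states(genome, arm_states):
    """Build a profile with equal-width segments per arm from total/minor runs."""
    rows = []
    for arm in genome.arms:
        states = arm_states.get(arm.name, [(2, 1)])
        bounds = np.linspace(arm.start, arm.end, len(states) + 1).astype(int)
        for (t, m), s, e in zip(states, bounds[:-1], bounds[1:]):
            rows.append((arm.chrom, int(s), int(e), t, m))
    return CopyNumberProfile(pd.DataFrame(rows, columns=PROFILE_COLUMNS))


@pytest.fixture(scope="module")
def one_chrom():
    return build_genome(
        {"n_chromosomes": 1, "chromosome_length": 100 * MB, "centromere_fraction": 0.5}
    )


class TestBreakpoints:
    def test_single_segment_arm_has_none(self, one_chrom):
        p = profile_from_states(one_chrom, {})
        assert breakpoints_per_arm(p, one_chrom) == {"chr1p": 0, "chr1q": 0}

    def test_three_segment_arm_has_two(self, one_chrom):
        p = profile_from_states(one_chrom, {"chr1p": [(2, 1), (3, 1), (2, 1)]})
        assert breakpoints_per_arm(p, one_chrom)["chr1p"] == 2

    def test_copy_neutral_loh_counts_allele_specifically(self, one_chrom):
        p = profile_from_states(one_chrom, {"chr1q": [(2, 1), (2, 0), (2, 1)]})
        counts = breakpoints_per_arm(p, one_chrom)
        assert counts["chr1q"] == 2
        total_only = breakpoints_per_arm(p, one_chrom, allele_specific=False)
        assert total_only["chr1q"] == 0

    def test_matches_brute_force_on_random_profiles(self, small_genome):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = make_random_profile(small_genome, rng)
            for region in ("whole", "telomeric", "centromeric"):
                assert breakpoints_per_arm(p, small_genome, region) == brute_breakpoints(
                    p, small_genome, region
                )

    def test_region_additivity(self, small_genome):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = make_random_profile(small_genome, rng)
            whole = breakpoints_per_arm(p, small_genome, "whole")
            parts = [
                breakpoints_per_arm(p, small_genome, r)
                for r in ("telomeric", "centromeric", "interstitial")
            ]
            for arm in whole:
                assert whole[arm] == sum(part[arm] for part in parts)


class TestSegmentSizes:
    def test_arm_sized_segments_fall_in_top_bin(self):
        g = build_genome(
            {"n_chromosomes": 2, "chromosome_length": 200 * MB, "centromere_fraction": 0.5}
        )
        p = profile_from_states(g, {})  # one 100 Mb segment per arm
        out = segment_size_features(p, g)
        assert out["count_ge100mb"] == 4
        assert out["frac_ge100mb"] == pytest.approx(1.0)

    def test_empty_window_yields_zero_features(self, small_genome):
        cfg = FeatureConfig(f_tel=0.0)
        rng = np.random.default_rng(3)
        p = make_random_profile(small_genome, rng)
        out = segment_size_features(p, small_genome, "telomeric", cfg)
        assert all(v == 0 for v in out.values())

    def test_matches_brute_force_histogram(self, small_genome):
        rng = np.random.default_rng(4)
        labels = ["lt1mb", "1mb_3mb", "3mb_10mb", "10mb_30mb", "30mb_100mb", "ge100mb"]
        for _ in range(100):
            p = make_random_profile(small_genome, rng)
            for region in ("whole", "telomeric", "centromeric"):
                out = segment_size_features(p, small_genome, region)
                counts, _ = brute_size_histogram(p, small_genome, region)
                assert [out[f"count_{lab}"] for lab in labels] == counts

    def test_size_conservation_per_region(self, small_genome):
        """Clipped segment lengths sum to the region's total length."""
        rng = np.random.default_rng(5)
        cfg = FeatureConfig()
        for _ in range(50):
            p = make_random_profile(small_genome, rng)
            for region in ("whole", "telomeric", "centromeric"):
                _, lengths = brute_size_histogram(p, small_genome, region, cfg)
                out = segment_size_features(p, small_genome, region, cfg)
                region_total = sum(lengths)
                frac_sum = sum(out[k] for k in out if k.startswith("frac_"))
                if region_total:
                    assert frac_sum == pytest.approx(1.0)


class TestOscillation:
    def test_constant_genome_has_no_chains(self, one_chrom):
        p = profile_from_states(one_chrom, {})
        out = oscillation_features(p, one_chrom)
        assert all(v == 0 for v in out.values())

    def test_five_segment_alternation_is_one_chain(self, one_chrom):
        p = profile_from_states(
            one_chrom, {"chr1p": [(2, 1), (3, 1), (2, 1), (3, 1), (2, 1)]}
        )
        out = oscillation_features(p, one_chrom)
        assert out["chains_ge3"] == 1
        assert out["chains_ge5"] == 1
        assert out["max_chain"] == 5
        assert out["longest_chain_chr1"] == 5

    def test_staircase_run_yields_length_three_chain(self, one_chrom):
        p = profile_from_states(
            one_chrom, {"chr1p": [(2, 1), (3, 1), (4, 1), (3, 1), (2, 1)]}
        )
        out = oscillation_features(p, one_chrom)
        assert out["max_chain"] == 3
        assert out["max_chain"] == max(brute_oscillation_chains([2, 3, 4, 3, 2]))

    def test_matches_brute_force_enumeration(self):
        """Chain scan equals exhaustive sub-run enumeration on random runs."""
        rng = np.random.default_rng(6)
        for _ in range(300):
            values = rng.integers(1, 4, size=rng.integers(3, 25))
            from valkit.features import _alternating_chains

            scan = sorted(length for _, length in _alternating_chains(values))
            assert scan == brute_oscillation_chains(values)

    def test_random_profiles_match_oracle(self, small_genome):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = make_random_profile(small_genome, rng)
            out = oscillation_features(p, small_genome)
            lengths = []
            for arm in small_genome.arms:
                seg = p.segments
                sub = seg[
                    (seg["chrom"] == arm.chrom)
                    & (seg["start"] >= arm.start)
                    & (seg["end"] <= arm.end)
                ].sort_values("start")
                lengths += brute_oscillation_chains(sub["total_cn"].tolist())
            assert out["chains_ge3"] == len(lengths)
            assert out["segments_in_chains"] == sum(lengths)
            assert out["max_chain"] == (max(lengths) if lengths else 0)


class TestGloh:
    def test_fully_balanced_genome_is_zero(self, one_chrom):
        assert compute_gloh(profile_from_states(one_chrom, {}), one_chrom) == 0.0

    def test_half_genome_subarm_loh(self, one_chrom):
        # half of each arm LOH, split across sub-arm segments (< 90% of arm)
        states = [(2, 0), (2, 1), (3, 0), (2, 1)]
        p = profile_from_states(one_chrom, {"chr1p": states, "chr1q": states})
        assert compute_gloh(p, one_chrom) == pytest.approx(0.5)

    def test_whole_arm_event_excluded(self, one_chrom):
        p = profile_from_states(one_chrom, {"chr1p": [(2, 0)]})
        assert compute_gloh(p, one_chrom) == 0.0

    def test_matches_brute_force(self, small_genome):
        rng = np.random.default_rng(8)
        for _ in range(100):
            p = make_random_profile(small_genome, rng)
            assert compute_gloh(p, small_genome) == pytest.approx(
                brute_gloh(p, small_genome)
            )


class TestAssembledVector:
    def test_schema_length_at_least_100(self, genome, contrast_cohort):
        sid = next(iter(contrast_cohort["truth"]))
        fv = assemble_features(contrast_cohort["truth"][sid], genome)
        assert len(fv) == len(feature_names(genome)) >= 100

    def test_identical_profiles_identical_vectors(self, small_genome):
        rng = np.random.default_rng(9)
        p = make_random_profile(small_genome, rng)
        a = assemble_features(p, small_genome).values
        b = assemble_features(p.copy(), small_genome).values
        pd.testing.assert_series_equal(a, b)

    def test_chromosome_order_invariance(self, small_genome):
        rng = np.random.default_rng(10)
        p = make_random_profile(small_genome, rng)
        shuffled = CopyNumberProfile(
            p.segments.sample(frac=1.0, random_state=1).reset_index(drop=True)
        )
        pd.testing.assert_series_equal(
            assemble_features(p, small_genome).values,
            assemble_features(shuffled, small_genome).values,
        )

    def test_scar_dose_response(self, small_genome):
        """Mean breakpoint total rises strictly with the planted rate.

        Oscillation bursts and the short-segment companion mechanism are
        switched off so the sweep isolates the breakpoint-rate dial; both add
        rate-independent breakpoints that would only blur the dose response.
        """
        rates = [2.0, 5.0, 10.0, 16.0, 24.0]
        means = []
        rng = np.random.default_rng(11)
        for rate in rates:
            params = ScarParams(
                breakpoint_rate_pos=rate,
                oscillation_burst_rate_pos=0.0,
                short_segment_bias_pos=0.0,
                snp_density=0.05,
            )
            totals = [
                assemble_features(
                    simulate_specimen(
                        small_genome, "positive", params, 0.6,
                        int(rng.integers(2**31)),
                    ).profile,
                    small_genome,
                ).values["bp_whole_total"]
                for _ in range(50)
            ]
            means.append(np.mean(totals))
        assert all(a < b for a, b in zip(means, means[1:]))
        rho = ss.spearmanr(rates, means).statistic
        assert rho > 0.9
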