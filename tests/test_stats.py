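"""Estimator tests: Wilson intervals against independent oracles, the LoB/LoD
rules, concordance, precision and interference agreement formulas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from valkit.simulate import ReplicateRecord, SnpVafTable
from valkit.stats import (
    ContingencyTable,
    DilutionLevelSummary,
    adjusted_tp,
    concordance_ppa_npa,
    determine_lod,
    dilution_factor,
    interference_agreement,
    lob_fpr,
    majority_reference,
    repeatability,
    reproducibility,
    wilson_ci,
)

from .oracles import wilson_by_inversion


def rep(call="negative", qc=True, sid="S1", plate=1, k=1, interferent=None, **kw):
    return ReplicateRecord(
        replicate_id=f"{sid}-{plate}-{k}-{call}-{interferent}",
        specimen_id=sid,
        study="TEST",
        plate=plate,
        rep_k=k,
        qc_valid=qc,
        call=None if not qc else call,
        interferent=interferent,
        **kw,
    )


class TestWilson:
    @pytest.mark.parametrize(
        "x,n,lower,upper",
        [
            (20, 20, 0.8389, 1.0000),
            (35, 36, 0.8583, 0.9951),
            (90, 100, 0.8256, 0.9448),
            (119, 126, 0.8898, 0.9728),
        ],
    )
    def test_reference_values(self, x, n, lower, upper):
        ci = wilson_ci(x, n)
        assert ci.lower == pytest.approx(lower, abs=5e-5)
        assert ci.upper == pytest.approx(upper, abs=5e-5)

    def test_boundary_closed_forms(self):
        from scipy.stats import norm

        z = norm.ppf(0.975)
        assert wilson_ci(0, 17).lower == 0.0
        assert wilson_ci(17, 17).lower == pytest.approx(17 / (17 + z * z))
        assert wilson_ci(17, 17).upper == 1.0

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(n=st.integers(1, 500), frac=st.floats(0, 1))
    def test_equals_score_test_inversion(self, n, frac):
        x = min(n, int(round(frac * n)))
        ci = wilson_ci(x, n)
        lo, hi = wilson_by_inversion(x, n)
        assert ci.lower == pytest.approx(lo, abs=1e-9)
        assert ci.upper == pytest.approx(hi, abs=1e-9)

    def test_equals_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 1000))
            x = int(rng.integers(0, n + 1))
            ci = wilson_ci(x, n)
            lo, hi = proportion_confint(x, n, method="wilson")
            assert ci.lower == pytest.approx(lo, abs=1e-9)
            assert ci.upper == pytest.approx(hi, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilson_ci(1, 0)
        with pytest.raises(ValueError):
            wilson_ci(5, 4)


class TestLobFpr:
    def test_all_negative_sixty(self):
        fpr = lob_fpr([rep("negative") for _ in range(60)])
        assert (fpr.x, fpr.n) == (0, 60) and fpr.pct() == 0.00

    def test_one_in_ten(self):
        fpr = lob_fpr([rep("positive")] + [rep("negative")] * 9)
        assert fpr.estimate == pytest.approx(0.10)

    def test_validity_weighting(self):
        reps = [rep("positive")] * 5 + [rep(qc=False)] * 5
        fpr = lob_fpr(reps)
        assert (fpr.x, fpr.n) == (5, 5)

    def test_no_valid_replicates(self):
        with pytest.raises(ValueError):
            lob_fpr([rep(qc=False)])


def vaf_table(vafs, depth=500):
    n = len(vafs)
    return SnpVafTable(
        pd.DataFrame(
            {
                "chrom": ["chr1"] * n,
                "pos": np.arange(n),
                "vaf": vafs,
                "depth": depth,
                "het_in_normal": True,
            }
        )
    )


class TestDilutionFactor:
    def test_identity_on_identical_tables(self):
        t = vaf_table(np.concatenate([np.full(60, 0.8), np.full(60, 0.2)]))
        assert dilution_factor(t, t) == pytest.approx(1.0)

    def test_fully_diluted_to_half(self):
        u = vaf_table(np.concatenate([np.full(60, 0.8), np.full(60, 0.2)]))
        d = vaf_table(np.full(120, 0.5))
        assert dilution_factor(u, d) == 0.0

    def test_too_few_usable_snps(self):
        u = vaf_table(np.full(30, 0.8))
        with pytest.raises(ValueError, match="usable"):
            dilution_factor(u, u)

    def test_recovers_planted_dilution(self, genome, params):
        """Factor within ±0.05 of the planted mass fraction at depth 500."""
        from valkit import dilute_replicate, simulate_specimen
        from valkit.simulate import ScarParams

        p = ScarParams(snp_density=1.0, depth=500)  # ~2,200 SNPs
        sp = simulate_specimen(genome, "positive", p, 1.0, seed=7)
        for d in (0.2, 0.4, 0.7):
            r = dilute_replicate(sp, d, 11, genome=genome, params=p)
            assert dilution_factor(sp.vafs, r.observed_vafs) == pytest.approx(d, abs=0.05)


class TestAdjustedTp:
    def test_product_and_identities(self):
        assert adjusted_tp(0.6, 0.5) == pytest.approx(0.30)
        assert adjusted_tp(0.42, 1.0) == pytest.approx(0.42)
        assert adjusted_tp(0.42, 0.0) == 0.0

    def test_bounds(self):
        with pytest.raises(ValueError):
            adjusted_tp(1.2, 0.5)


def level(sid, lv, hits, n, adj):
    return DilutionLevelSummary(sid, lv, n, hits, wilson_ci(hits, n), adj)


class TestDetermineLod:
    def test_median_across_specimens(self):
        levels = [
            level("S1", 0.2, 20, 20, 0.2304),
            level("S2", 0.2, 18, 18, 0.2451),
            level("S3", 0.2, 15, 15, 0.1221),
        ]
        _, overall = determine_lod(levels)
        assert overall == pytest.approx(0.2304)

    def test_single_specimen(self):
        per, overall = determine_lod([level("S1", 0.3, 19, 19, 0.31)])
        assert overall == pytest.approx(0.31)
        assert per["S1"]["level"] == 0.3

    def test_perfect_hit_rates_select_lowest_level(self):
        levels = [level("S1", lv, 20, 20, lv + 0.03) for lv in (0.4, 0.3, 0.2)]
        per, overall = determine_lod(levels)
        assert per["S1"]["level"] == 0.2
        assert overall == pytest.approx(0.23)

    def test_threshold_monotonicity(self):
        """Raising the hit threshold never selects a more dilute level."""
        rng = np.random.default_rng(1)
        lvls = []
        for lv in (0.2, 0.25, 0.3, 0.35, 0.4):
            hits = int(rng.integers(14, 21))
            lvls.append(level("S1", lv, hits, 20, lv))
        chosen = []
        for thr in (0.7, 0.8, 0.9, 0.95, 1.0):
            try:
                per, _ = determine_lod(lvls, thr)
                chosen.append(per["S1"]["level"])
            except ValueError:
                chosen.append(np.inf)
        assert all(a <= b for a, b in zip(chosen, chosen[1:]))

    def test_no_passing_level(self):
        with pytest.raises(ValueError):
            determine_lod([level("S1", 0.2, 10, 20, 0.2)])


class TestConcordance:
    TABLE = ContingencyTable(a=90, b=7, c=10, d=119, unknown_pos=1, unknown_neg=2)

    def test_reference_table(self):
        ppa, npa = concordance_ppa_npa(self.TABLE)
        assert ppa.pct() == 90.00 and (ppa.x, ppa.n) == (90, 100)
        assert npa.pct() == 94.44 and (npa.x, npa.n) == (119, 126)

    def test_unknowns_in_npa_denominator(self):
        _, npa = concordance_ppa_npa(self.TABLE, include_unknown_in_npa=True)
        assert npa.pct() == 92.97 and npa.n == 128

    def test_perfect_table(self):
        ppa, npa = concordance_ppa_npa(ContingencyTable(10, 0, 0, 10))
        assert ppa.estimate == 1.0 and npa.estimate == 1.0

    def test_empty_margin(self):
        with pytest.raises(ValueError):
            concordance_ppa_npa(ContingencyTable(0, 5, 0, 5))


class TestMajorityReference:
    def test_unanimous(self):
        assert majority_reference(["positive"] * 36) == "positive"

    def test_exact_half_is_positive(self):
        assert majority_reference(["positive"] * 18 + ["negative"] * 18) == "positive"

    def test_just_under_half_is_negative(self):
        assert majority_reference(["positive"] * 17 + ["negative"] * 19) == "negative"

    def test_no_known_calls(self):
        with pytest.raises(ValueError):
            majority_reference(["unknown"])


def precision_cohort(discordant_specs=("S2",), n_plates=18):
    """22-specimen cohort, 2 reps per plate; listed specimens get one flip."""
    reps = []
    for i in range(22):
        sid = f"S{i + 1}"
        ref = "positive" if i < 11 else "negative"
        flip = "negative" if ref == "positive" else "positive"
        for p in range(1, n_plates + 1):
            for k in (1, 2):
                call = flip if (sid in discordant_specs and p == 1 and k == 1) else ref
                reps.append(rep(call, sid=sid, plate=p, k=k))
    return reps


class TestReproducibility:
    def test_single_discordance_per_pool(self):
        reps = precision_cohort(discordant_specs=("S2", "S12"))
        per, pooled = reproducibility(reps)
        assert per["S2"].x == 35 and per["S2"].n == 36
        assert per["S2"].pct() == 97.22
        assert pooled["positive"].x == 395 and pooled["positive"].n == 396
        assert pooled["negative"].x == 395 and pooled["negative"].n == 396

    def test_all_agreeing_specimen_is_100(self):
        per, _ = reproducibility(precision_cohort(discordant_specs=()))
        assert all(ci.estimate == 1.0 for ci in per.values())

    def test_invariant_to_order_and_invalid_insertion(self):
        reps = precision_cohort(discordant_specs=("S5",))
        _, pooled = reproducibility(reps)
        rng = np.random.default_rng(4)
        shuffled = list(rng.permutation(np.array(reps, dtype=object)))
        shuffled += [rep(qc=False, sid="S5", plate=99)]
        _, pooled2 = reproducibility(shuffled)
        assert pooled["positive"] == pooled2["positive"]
        assert pooled["negative"] == pooled2["negative"]


class TestRepeatability:
    def test_discordant_pairs_counted(self):
        reps = precision_cohort(discordant_specs=("S2", "S13", "S14"))
        r = repeatability(reps)
        assert (r.x, r.n) == (22 * 18 - 3, 22 * 18)

    def test_incomplete_pair_excluded(self):
        reps = [
            rep("positive", plate=1, k=1),
            rep("positive", plate=1, k=2),
            rep("positive", plate=2, k=1),
            rep(qc=False, plate=2, k=2),
        ]
        r = repeatability(reps)
        assert (r.x, r.n) == (1, 1)

    def test_all_pairs_agree(self):
        r = repeatability(precision_cohort(discordant_specs=()))
        assert r.estimate == 1.0

    def test_overloaded_run_rejected(self):
        reps = [rep("positive", plate=1, k=k) for k in (1, 2, 2)]
        with pytest.raises(ValueError, match="more than 2"):
            repeatability(reps)


class TestInterference:
    def _cohort(self):
        reps = []
        # specimen with controls: reference positive, one discordant spiked rep
        for i in range(4):
            reps.append(rep("positive", sid="I1", interferent="normal_control", plate=i))
        reps.append(rep("positive", sid="I1", interferent="melanin", plate=10))
        reps.append(rep("negative", sid="I1", interferent="melanin", plate=11))
        # necrosis-only specimen: no controls -> excluded from overall
        reps.append(rep("positive", sid="N1", interferent="necrotic", plate=1))
        reps.append(rep("negative", sid="N1", interferent="necrotic", plate=2))
        return reps

    def test_sample_level_agreement(self):
        rows, overall = interference_agreement(self._cohort())
        melanin = rows[(rows.specimen_id == "I1") & (rows.interferent == "melanin")]
        assert melanin["pct_agreement"].iloc[0] == 50.00
        necro = rows[rows.specimen_id == "N1"]
        # tie -> positive reference by the >= 50% rule, one of two agrees
        assert necro["pct_agreement"].iloc[0] == 50.00
        assert not necro["included_in_overall"].iloc[0]

    def test_overall_excludes_groups_without_controls(self):
        _, overall = interference_agreement(self._cohort())
        assert (overall.x, overall.n) == (5, 6)

    def test_all_agreeing_cohort_is_100(self):
        reps = [rep("positive", sid="I1", interferent="normal_control", plate=i) for i in range(2)]
        reps += [rep("positive", sid="I1", interferent="ethanol", plate=i + 10) for i in range(2)]
        _, overall = interference_agreement(reps)
        assert overall.estimate == 1.0 and overall.n == 4
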