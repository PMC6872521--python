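import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepsplice import (
    PSP_P1,
    SCS_P1,
    KineticFilterConfig,
    PsmFilterConfig,
    Substrate,
    UndefinedProfileError,
    compute_site_profile,
    filter_kinetics,
    filter_psms,
    fit_titration,
    summarize_products,
)

from conftest import make_product


def psm_row(spectrum, peptide, score, q=0.01, rank=1, category="non-spliced"):
    return {
        "spectrum_id": spectrum,
        "peptide": peptide,
        "category": category,
        "ion_score": score,
        "q_value": q,
        "rank": rank,
    }


class TestPsmFilter:
    def test_ion_score_below_cutoff_removed(self):
        psms = pd.DataFrame([psm_row("s1", "PEPTIDEK", 19.0)])
        assert filter_psms(psms).empty

    def test_q_value_above_cutoff_removed(self):
        psms = pd.DataFrame([psm_row("s1", "PEPTIDEK", 50.0, q=0.06)])
        assert filter_psms(psms).empty

    def test_passing_nonspliced_hit_accepted_without_delta_rule(self):
        psms = pd.DataFrame(
            [
                psm_row("s1", "PEPTIDEK", 50.0),
                psm_row("s1", "PEPTIDER", 49.0, rank=2),  # near-tie, but top is non-spliced
            ]
        )
        assert list(filter_psms(psms)["peptide"]) == ["PEPTIDEK"]

    @pytest.mark.parametrize(
        "alt_score,accepted",
        [(40.0, False), (30.0, True)],  # deltas 20% and 40% against the 30% rule
    )
    def test_spliced_top_hit_needs_delta_margin(self, alt_score, accepted):
        psms = pd.DataFrame(
            [
                psm_row("s1", "SPLICEDK", 50.0, category="cis-normal"),
                psm_row("s1", "LINEARPK", alt_score, rank=2, category="non-spliced"),
            ]
        )
        got = filter_psms(psms)
        assert (len(got) == 1) == accepted

    def test_delta_rule_also_against_alternative_spliced(self):
        psms = pd.DataFrame(
            [
                psm_row("s1", "SPLICEDK", 50.0, category="cis-normal"),
                psm_row("s1", "SPLICEDR", 45.0, rank=2, category="cis-reverse"),
            ]
        )
        assert filter_psms(psms).empty

    def test_spectrum_without_rank1_errors(self):
        psms = pd.DataFrame([psm_row("s1", "PEPTIDEK", 50.0, rank=2)])
        with pytest.raises(ValueError, match="rank-1"):
            filter_psms(psms)

    def test_monotone_in_ion_score_cutoff(self):
        rng = np.random.default_rng(0)
        rows = [
            psm_row(f"s{k}", f"PEP{k}K", float(rng.uniform(5, 60)), q=float(rng.uniform(0, 0.1)))
            for k in range(40)
        ]
        psms = pd.DataFrame(rows)
        previous = None
        for cutoff in (10.0, 20.0, 30.0, 40.0):
            got = set(filter_psms(psms, PsmFilterConfig(ion_score_min=cutoff))["peptide"])
            if previous is not None:
                assert got <= previous
            previous = got


def kin_rows(peptide, areas, bio=1, tech=1, times=None):
    times = times if times is not None else list(range(len(areas)))
    return pd.DataFrame(
        {
            "peptide": peptide,
            "bio_rep": bio,
            "tech_rep": tech,
            "time_h": [float(t) for t in times],
            "area": [float(a) for a in areas],
        }
    )


def replicated(peptide, areas, n_bio=2, n_tech=2):
    return pd.concat(
        [kin_rows(peptide, areas, bio=b, tech=t) for b in range(1, n_bio + 1) for t in range(1, n_tech + 1)],
        ignore_index=True,
    )


class TestKineticFilter:
    def test_clean_rising_series_kept(self):
        kept, reasons = filter_kinetics(replicated("GOODPEPK", [0, 100, 200, 300]))
        assert set(kept["peptide"]) == {"GOODPEPK"}
        assert reasons.empty

    def test_t0_signal_flags_synthesis_artifact(self):
        kept, reasons = filter_kinetics(replicated("ARTIFACTK", [200, 250, 300]))
        assert kept.empty
        assert list(reasons["reason"]) == ["synthesis artifact"]

    def test_alternating_peaks_rejected(self):
        kept, reasons = filter_kinetics(replicated("ALTK", [0, 100, 10, 120, 15]))
        assert kept.empty
        assert list(reasons["reason"]) == ["alternating"]

    def test_small_swings_not_alternating(self):
        kept, _ = filter_kinetics(replicated("WOBBLEK", [0, 100, 80, 120, 110]))
        assert set(kept["peptide"]) == {"WOBBLEK"}

    def test_single_biological_replicate_rejected(self):
        kept, reasons = filter_kinetics(replicated("LONELYK", [0, 100, 200], n_bio=1))
        assert kept.empty
        assert not reasons.empty

    def test_single_technical_replicate_not_detected(self):
        kept, reasons = filter_kinetics(replicated("THINK", [0, 100, 200], n_tech=1))
        assert kept.empty

    def test_two_point_minimum_enforced(self):
        with pytest.raises(ValueError):
            filter_kinetics(kin_rows("SHORTK", [100.0]))

    def test_thresholds_configurable(self):
        cfg = KineticFilterConfig(artifact_t0_fraction=0.9)
        kept, _ = filter_kinetics(replicated("ARTIFACTK", [200, 250, 300]), cfg)
        assert set(kept["peptide"]) == {"ARTIFACTK"}


class TestTitration:
    def test_exact_linear_data_recovered(self):
        curve = fit_titration([0, 5, 10], [0, 500, 1000])
        assert curve.slope == pytest.approx(100.0)
        assert curve.intercept == pytest.approx(0.0)
        assert curve.quantify(250.0) == pytest.approx(2.5)

    def test_zero_area_maps_to_zero_on_zero_intercept_curve(self):
        curve = fit_titration([0, 5, 10], [0, 500, 1000])
        assert curve.quantify(0.0) == 0.0

    def test_noisy_titration_recovers_slope_within_ten_percent(self):
        rng = np.random.default_rng(42)
        pmol = np.array([0.0, 1.25, 2.5, 5.0, 10.0])
        true_slope = 240.0
        area = true_slope * pmol * rng.lognormal(0.0, 0.05, size=pmol.size)
        curve = fit_titration(pmol, area)
        assert abs(curve.slope - true_slope) / true_slope < 0.10

    def test_quantify_inverts_prediction_exactly(self):
        curve = fit_titration([0, 2, 4, 8], [3, 203, 403, 803])
        for pmol in [0.0, 0.5, 3.7, 10.0]:
            area = curve.slope * pmol + curve.intercept
            assert curve.quantify(area) == pytest.approx(pmol, abs=1e-9)

    def test_nonpositive_slope_is_unusable(self):
        with pytest.raises(ValueError, match="slope"):
            fit_titration([0, 5, 10], [1000, 500, 0])

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            fit_titration([0, 10], [0, 1000])


class TestSiteProfiles:
    def test_single_product_gives_full_percentage_at_its_terminus(self, kras):
        prod = make_product("KLVVVGAVGV", kras.g12v, amount=3.0)  # C-term at 14
        profile = compute_site_profile([prod], SCS_P1, substrate=kras.g12v)
        assert profile.percent.loc[14] == pytest.approx(100.0)
        assert profile.total() == pytest.approx(100.0, abs=1e-9)

    def test_equal_amounts_split_fifty_fifty(self, kras):
        p1 = make_product(kras.g12v.segment(3, 10), kras.g12v, amount=2.0)  # C-term 10
        p2 = make_product(kras.g12v.segment(7, 14), kras.g12v, amount=2.0)  # C-term 14
        profile = compute_site_profile([p1, p2], SCS_P1, substrate=kras.g12v)
        assert profile.percent.loc[10] == pytest.approx(50.0)
        assert profile.percent.loc[14] == pytest.approx(50.0)

    def test_ambiguous_decompositions_split_equally(self, kras):
        # the spliced candidate has 3 equivalent splice sites (psp_p1 6, 7, 8)
        prod = make_product("KLVVGAVGV", kras.g12v, amount=3.0)
        profile = compute_site_profile([prod], PSP_P1, substrate=kras.g12v)
        for pos in (6, 7, 8):
            assert profile.percent.loc[pos] == pytest.approx(100.0 / 3)

    def test_psp_ignores_nonspliced_products(self, kras):
        ns = make_product("KLVVVGAVGV", kras.g12v, amount=10.0)
        sp = make_product("KLVVGAVGV", kras.g12v, amount=1.0)
        profile = compute_site_profile([ns, sp], PSP_P1, substrate=kras.g12v)
        assert profile.total() == pytest.approx(100.0, abs=1e-9)
        assert set(profile.percent[profile.percent > 0].index) == {6, 7, 8}

    def test_all_zero_amounts_flagged_undefined(self, kras):
        prod = make_product("KLVVVGAVGV", kras.g12v, amount=0.0)
        with pytest.raises(UndefinedProfileError):
            compute_site_profile([prod], SCS_P1, substrate=kras.g12v)

    @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=8), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_profiles_sum_to_one_hundred(self, amounts, seed):
        rng = np.random.default_rng(seed)
        sub = Substrate(id="s", sequence="ACDEFGHIKLMNPQRS")
        products = []
        for k, amt in enumerate(amounts):
            i = int(rng.integers(1, 8))
            j = int(rng.integers(i + 2, 17))
            products.append(make_product(sub.segment(i, j), sub, amount=amt))
        profile = compute_site_profile(products, SCS_P1, substrate=sub)
        assert profile.total() == pytest.approx(100.0, abs=1e-9)
        assert (profile.percent >= 0).all()


class TestSummary:
    def test_counts_and_percentages(self, kras):
        sub = kras.g12v
        trans_sub = Substrate(id="t", sequence="ACDEF")
        products = [
            make_product(sub.segment(3, 10), sub, amount=4.0),
            make_product(sub.segment(7, 14), sub, amount=2.0),
            make_product("KLVVGAVGV", sub, amount=1.0),
            make_product("ACDEFACDEF", trans_sub, amount=1.0),
        ]
        summary = summarize_products(products)
        by_cat = summary.by_category
        assert by_cat.loc["non-spliced", "count"] == 2
        assert by_cat.loc["cis-normal", "count"] == 1
        assert by_cat.loc["trans", "count"] == 1
        assert by_cat.loc["non-spliced", "percent"] == pytest.approx(50.0)
        assert by_cat.loc["cis-normal", "percent"] == pytest.approx(25.0)
        assert by_cat["percent"].sum() == pytest.approx(100.0, abs=1e-9)
        assert by_cat["abundance_percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_length_medians_reported_for_cis(self, kras):
        products = [make_product("KLVVGAVGV", kras.g12v, amount=1.0)]
        summary = summarize_products(products)
        assert summary.length_medians["sr1_length"] == pytest.approx(3.0)
        assert summary.length_medians["intervening_length"] == pytest.approx(1.0)

    def test_empty_set_yields_empty_summary(self):
        summary = summarize_products([])
        assert summary.by_category.empty
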