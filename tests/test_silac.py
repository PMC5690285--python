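"""SILAC ratio statistics: efficiency correction, stoichiometry, testing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from ptmstoich.silac import (
    SilacStoichiometry,
    correct_ratio,
    correct_ratios,
    filter_psms,
    fractional_heavy,
    infer_state_composition,
    infer_unmodified_percent,
    labeling_efficiency,
    mw_test,
    normalize_p62_ratios,
    percent_heavy,
    protein_normalizer,
    run_silac,
    theoretical_null,
)


def mannwhitney_pvalue_bruteforce(x, y):
    """Exact two-sided p by enumerating every split of the pooled sample."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)

    def u_stat(xs, ys):
        return sum(
            (xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys
        )

    center = n * m / 2.0
    dev_obs = abs(u_stat(x, y) - center)
    devs = []
    indices = range(n + m)
    for chosen in itertools.combinations(indices, n):
        chosen = set(chosen)
        xs = pooled[sorted(chosen)]
        ys = pooled[[i for i in indices if i not in chosen]]
        devs.append(abs(u_stat(xs, ys) - center))
    return float(np.mean(np.asarray(devs) >= dev_obs - 1e-12))


def _psm_row(**kw):
    row = dict(
        sequence="QPNSAIRK", protein="RPS23", p62_state="di",
        intensity_h=400.0, intensity_l=100.0, ratio_hl=4.0,
        quan_result_id="q", confidence=True, unique=True, sample="pair",
    )
    row.update(kw)
    return row


class TestFilterPsms:
    def test_flag_filter(self):
        df = pd.DataFrame([
            _psm_row(quan_result_id="a"),
            _psm_row(quan_result_id="b", confidence=False),
            _psm_row(quan_result_id="c", unique=False),
            _psm_row(quan_result_id="d"),
            _psm_row(quan_result_id="e"),
        ])
        assert len(filter_psms(df)) == 3

    def test_single_missing_channel_imputed_with_global_minimum(self):
        df = pd.DataFrame([
            _psm_row(quan_result_id="a", intensity_l=100.0, intensity_h=250.0),
            _psm_row(quan_result_id="b", intensity_l=180.0, intensity_h=300.0),
            _psm_row(quan_result_id="c", intensity_l=np.nan, intensity_h=400.0,
                     ratio_hl=np.nan),
        ])
        out = filter_psms(df).set_index("quan_result_id")
        assert out.loc["c", "intensity_l"] == 100.0
        assert out.loc["c", "ratio_hl"] == pytest.approx(4.0)
        assert bool(out.loc["c", "imputed"])

    def test_both_channels_missing_dropped(self):
        df = pd.DataFrame([
            _psm_row(quan_result_id="a"),
            _psm_row(quan_result_id="b", intensity_l=np.nan, intensity_h=np.nan,
                     ratio_hl=np.nan),
        ])
        assert list(filter_psms(df)["quan_result_id"]) == ["a"]

    def test_ratios_recomputed_after_imputation(self):
        df = pd.DataFrame([
            _psm_row(quan_result_id="a", intensity_h=300.0, intensity_l=100.0,
                     ratio_hl=999.0),
        ])
        assert filter_psms(df)["ratio_hl"].iloc[0] == pytest.approx(3.0)

    def test_empty_in_empty_out(self):
        df = pd.DataFrame(columns=list(_psm_row().keys()))
        assert filter_psms(df).empty


class TestLabelingEfficiency:
    def test_median_based_estimate(self):
        assert labeling_efficiency([9, 19, 39]).e == pytest.approx(0.95)

    def test_symmetric_case(self):
        assert labeling_efficiency([1]).e == pytest.approx(0.5)

    def test_perfect_labeling_limit(self):
        assert labeling_efficiency([1e9]).e == pytest.approx(1.0, abs=1e-8)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            labeling_efficiency([])

    def test_even_count_uses_interpolated_median(self):
        model = labeling_efficiency([1, 3])
        assert model.reference_median_ratio == pytest.approx(2.0)


class TestCorrectRatio:
    @pytest.mark.parametrize(
        "r, e, expected", [(3, 0.95, 3.75), (3, 1, 3), (1, 1, 1)]
    )
    def test_hand_computed(self, r, e, expected):
        assert correct_ratio(r, e) == pytest.approx(expected)

    def test_invalid_efficiency_rejected(self):
        for e in (0, -0.5, 1.5):
            with pytest.raises(ValueError):
                correct_ratio(1.0, e)

    def test_saturation_flagged(self):
        # r=39, e=0.95: x = 39/40/0.95 > 1
        with pytest.raises(ValueError, match="saturat"):
            correct_ratio(39, 0.95)
        values, n_sat = correct_ratios([3, 39], 0.95)
        assert n_sat == 1 and np.isnan(values[1])

    @given(
        r=st.floats(min_value=0.01, max_value=5.0),
        e=st.floats(min_value=0.8, max_value=1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_increasing_in_r_decreasing_in_e(self, r, e):
        base = correct_ratio(r, e, on_saturation="nan")
        up_r = correct_ratio(r * 1.1, e, on_saturation="nan")
        if not (np.isnan(base) or np.isnan(up_r)):
            assert up_r > base
        lower_e = correct_ratio(r, max(e - 0.05, 0.8), on_saturation="nan")
        if not (np.isnan(base) or np.isnan(lower_e)):
            assert lower_e >= base


class TestProteinNormalizer:
    @pytest.mark.parametrize(
        "ratios, e, expected",
        [([3, 3, 3], 1, 3), ([1, 3, 9], 1, 3), ([3], 0.95, 3.75)],
    )
    def test_median_of_corrected(self, ratios, e, expected):
        value, _ = protein_normalizer(ratios, e)
        assert value == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            protein_normalizer([], 1.0)


class TestNormalizeRatios:
    def test_division_by_state(self):
        out = normalize_p62_ratios({"di": [6, 9], "mono": [3]}, 3.0)
        assert list(out["di"]) == [2, 3]
        assert list(out["mono"]) == [1]

    def test_empty_group_stays_empty(self):
        assert normalize_p62_ratios({"di": []}, 3.0)["di"].size == 0

    def test_nonpositive_normalizer_rejected(self):
        with pytest.raises(ValueError):
            normalize_p62_ratios({"di": [1]}, 0.0)


class TestFractionalHeavy:
    @pytest.mark.parametrize("pn, e, expected", [(1, 1, 0.5), (3, 1, 0.75)])
    def test_hand_computed(self, pn, e, expected):
        assert fractional_heavy(pn, e) == pytest.approx(expected)

    def test_clamped_at_one(self):
        # raw value (1/0.95) * 99/100 = 1.0421...
        assert fractional_heavy(99, 0.95) == 1.0


class TestPercentHeavy:
    @pytest.mark.parametrize(
        "h, expected",
        [([0.75, 0.75, 0.75], (75, 25)), ([0.5], (50, 50)),
         ([0.999, 0.9995, 1.0], (99.95, 0.05))],
    )
    def test_median_times_100(self, h, expected):
        ph, pl = percent_heavy(h)
        assert (ph, pl) == pytest.approx(expected)
        assert ph + pl == pytest.approx(100.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percent_heavy([])


class TestTheoreticalNull:
    def test_perfect_signal_limit_gives_ratio_one(self):
        sn, log2_sn = theoretical_null([1e9], 1.0)
        assert sn[0] == pytest.approx(1.0, abs=1e-6)
        assert log2_sn[0] == pytest.approx(0.0, abs=1e-6)

    def test_unit_reference_ratio(self):
        # sa = 1 -> y = 1/2 -> sn = 0.25 / 0.75 = 1/3
        sn, _ = theoretical_null([1.0], 1.0)
        assert sn[0] == pytest.approx(1 / 3)

    def test_efficiency_correction_chained_first(self):
        # at e = 0.95, s = 3 corrects to sa = 3.75 before the null mapping
        sn, _ = theoretical_null([3.0], 0.95)
        y = 3.75 / 4.75
        assert sn[0] == pytest.approx((y / 2) / (1 - y / 2))


class TestMannWhitney:
    def test_identical_sets_not_significant(self):
        assert mw_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_fully_separated_sets(self):
        assert mw_test(list(range(10)), list(range(100, 110))) < 0.001

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            mw_test([], [1.0])

    @pytest.mark.parametrize("n, m", [(3, 3), (4, 5), (6, 2), (8, 8)])
    def test_agrees_with_bruteforce_enumeration(self, n, m, rng):
        for _ in range(3):
            x = rng.normal(0, 1, n)
            y = rng.normal(0.5, 1, m)
            assert mw_test(x, y) == pytest.approx(
                mannwhitney_pvalue_bruteforce(x, y), abs=1e-12
            )


class TestStateInference:
    @pytest.mark.parametrize(
        "ratio, expected", [(3.125, 32.0), (1, 100.0), (4, 25.0), (0.5, 100.0)]
    )
    def test_unmodified_percent(self, ratio, expected):
        assert infer_unmodified_percent(ratio) == pytest.approx(expected)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            infer_unmodified_percent(0)

    @pytest.mark.parametrize(
        "unmod, di, mono", [(32, 8, 60), (0, 100, 0), (100, 0, 0)]
    )
    def test_composition_by_conservation(self, unmod, di, mono):
        comp = infer_state_composition(unmod, di)
        assert comp.percent_mono == pytest.approx(mono)

    def test_inconsistent_pair_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            infer_state_composition(70, 40)

    @given(
        unmod=st.floats(min_value=0, max_value=100),
        di=st.floats(min_value=0, max_value=100),
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation_property(self, unmod, di):
        if unmod + di > 100:
            with pytest.raises(ValueError):
                infer_state_composition(unmod, di)
        else:
            comp = infer_state_composition(unmod, di)
            total = comp.percent_unmodified + comp.percent_mono + comp.percent_di
            assert total == pytest.approx(100.0)


def _pair_table(p62_ratios_by_state, normalizer_ratios):
    rows = []
    for state, ratios in p62_ratios_by_state.items():
        for i, r in enumerate(ratios):
            rows.append(_psm_row(
                p62_state=state, quan_result_id=f"{state}_{i}",
                intensity_l=100.0, intensity_h=100.0 * r, ratio_hl=r,
            ))
    for i, r in enumerate(normalizer_ratios):
        rows.append(_psm_row(
            sequence="AVGDEVLK", p62_state="na", quan_result_id=f"n_{i}",
            intensity_l=100.0, intensity_h=100.0 * r, ratio_hl=r,
        ))
    return pd.DataFrame(rows)


class TestRunSilac:
    def test_identity_chain(self):
        """With e = 1 and unit normalizer, %H of ratio r is 100 r/(1+r)."""
        table = _pair_table({"di": [3.0] * 5}, [1.0] * 5)
        result = run_silac(table, reference_ratios=[1e9] * 3)
        assert result.labeling.e == pytest.approx(1.0, abs=1e-8)
        assert result.states["di"].percent_heavy == pytest.approx(75.0, abs=1e-4)

    @given(r=st.floats(min_value=0.05, max_value=20.0))
    @settings(max_examples=25, deadline=None)
    def test_identity_chain_property(self, r):
        table = _pair_table({"di": [r] * 3}, [1.0] * 3)
        result = run_silac(table, reference_ratios=[1e12] * 3)
        assert result.states["di"].percent_heavy == pytest.approx(
            100 * r / (1 + r), rel=1e-6
        )

    def test_percent_heavy_monotone_in_ratios(self):
        lo = run_silac(_pair_table({"di": [2, 2, 2]}, [1.0] * 3), [1e9] * 3)
        hi = run_silac(_pair_table({"di": [2, 2, 5]}, [1.0] * 3), [1e9] * 3)
        assert hi.states["di"].percent_heavy >= lo.states["di"].percent_heavy

    def test_missing_reference_named(self):
        with pytest.raises(ValueError, match="reference"):
            run_silac(_pair_table({"di": [1.0]}, [1.0]), [])

    def test_missing_normalizer_named(self):
        table = _pair_table({"di": [1.0]}, [])
        with pytest.raises(ValueError, match="non-site"):
            run_silac(table, [19.0])

    def test_missing_site_psms_named(self):
        table = _pair_table({}, [1.0, 1.0])
        with pytest.raises(ValueError, match="P62"):
            run_silac(table, [19.0])

    def test_absent_state_flagged(self):
        result = run_silac(_pair_table({"di": [3.0] * 3}, [1.0] * 3), [19.0] * 3)
        assert result.states["mono"].absent
        assert result.states["mono"].n_psms == 0

    def test_result_carries_intermediates(self):
        result = run_silac(_pair_table({"di": [3.0] * 3}, [1.0] * 3), [19.0] * 3)
        di = result.states["di"]
        assert len(di.pn) == len(di.h_values) == 3
        assert result.null_log2_sn

    def test_estimator_is_cloneable(self):
        est = SilacStoichiometry(target_protein="XYZ")
        assert clone(est).get_params()["target_protein"] == "XYZ"

    def test_synthetic_recovery(self, silac_sim):
        table, truth, reference = silac_sim
        result = run_silac(table, reference)
        assert result.labeling.e == pytest.approx(truth["e_true"], abs=0.01)
        for state, true_ph in truth["percent_heavy"].items():
            est = result.states[state].percent_light
            assert est == pytest.approx(100 - true_ph, abs=2.0)
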