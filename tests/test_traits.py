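"""Trait construction: ECM, HPU, MeP, MeC, filters, ratios, residualization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methaherd.traits import (
    DataError,
    DesignError,
    TraitResidualizer,
    apply_editing_filters,
    build_trait_table,
    compute_ecm,
    compute_hpu,
    compute_mep,
    compute_ratio_traits,
    delta_bw,
    residualize,
    transform_mec,
)


class TestEcm:
    @pytest.mark.parametrize(
        "milk,fat,protein,expected",
        [
            (0.0, 0.0, 0.0, 0.0),
            (30.0, 1.2, 1.0, 29.84),  # 7.5 + 14.64 + 7.7
            (1.0, 0.0, 0.0, 0.25),
        ],
    )
    def test_values(self, milk, fat, protein, expected):
        assert compute_ecm(milk, fat, protein) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(DataError):
            compute_ecm(-1.0, 0.0, 0.0)


class TestHpu:
    def test_zero(self):
        assert compute_hpu(0.0, 0.0, 0.0) == pytest.approx(0.0)

    def test_hand_evaluation(self):
        # 5.6*600^0.75 + 22*30 + 1.6e-5*100^3 = 1354.93 W = 1.35493 HPU
        assert compute_hpu(600.0, 30.0, 100.0) == pytest.approx(1.35493, abs=2e-4)

    @given(
        bw=st.floats(100, 900),
        ecm=st.floats(0, 60),
        days=st.floats(0, 280),
    )
    @settings(max_examples=50, derandomize=True)
    def test_linearity_in_ecm(self, bw, ecm, days):
        base = compute_hpu(bw, ecm, days)
        doubled = compute_hpu(bw, 2 * ecm, days)
        assert doubled - base == pytest.approx(22.0 * ecm / 1000.0, rel=1e-9, abs=1e-12)


class TestMep:
    def test_zero_ratio(self):
        assert compute_mep(0.0, 5000.0, 1.3) == pytest.approx(0.0)

    def test_hand_evaluation(self):
        # ratio 0.08, HPU 1.3549: 0.08*4320*1.3549*0.668 = 312.8 g/d
        got = compute_mep(400.0, 5000.0, 1.3549)
        assert got == pytest.approx(312.8, abs=0.1)

    def test_monotone_in_ch4(self):
        ch4 = np.linspace(100, 900, 20)
        mep = compute_mep(ch4, 5000.0, 1.3)
        assert np.all(np.diff(mep) > 0)

    @given(
        ratio=st.floats(0.01, 0.2),
        hpu=st.floats(0.5, 2.5),
        alpha=st.floats(0.1, 5.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_linear_in_ratio_and_hpu(self, ratio, hpu, alpha):
        base = compute_mep(ratio * 5000.0, 5000.0, hpu)
        assert compute_mep(alpha * ratio * 5000.0, 5000.0, hpu) == pytest.approx(
            alpha * base, rel=1e-9
        )
        assert compute_mep(ratio * 5000.0, 5000.0, alpha * hpu) == pytest.approx(
            alpha * base, rel=1e-9
        )

    def test_zero_co2_rejected(self):
        with pytest.raises(DataError):
            compute_mep(400.0, 0.0, 1.3)


class TestMec:
    def test_log_points(self):
        assert transform_mec(1.0) == pytest.approx(0.0)
        assert transform_mec(np.e) == pytest.approx(100.0)

    def test_typical_ppm_in_observed_range(self):
        # 313 ppm -> 574.6, inside the observed MeC range 414.0-731.5
        got = float(transform_mec(313.0))
        assert got == pytest.approx(574.6, abs=0.1)
        assert 414.0 < got < 731.5

    def test_nonpositive_rejected(self):
        with pytest.raises(DataError):
            transform_mec(0.0)


class TestRatioTraits:
    def test_consistency_with_reported_means(self):
        # reported trait means: MeP 337.9, MeY 15.4, MeI 9.2
        mey, mei = compute_ratio_traits(337.9, 21.94, 36.7)
        assert float(mey) == pytest.approx(15.4, abs=0.05)
        assert float(mei) == pytest.approx(9.2, abs=0.05)

    def test_zero_mep(self):
        mey, mei = compute_ratio_traits(0.0, 20.0, 30.0)
        assert float(mey) == 0.0 and float(mei) == 0.0

    def test_zero_denominator_flagged_missing(self):
        mey, mei = compute_ratio_traits(
            np.array([300.0, 300.0]), np.array([0.0, 20.0]), np.array([30.0, 0.0])
        )
        assert np.isnan(mey[0]) and not np.isnan(mey[1])
        assert np.isnan(mei[1]) and not np.isnan(mei[0])


def _toy_records() -> pd.DataFrame:
    """Cow 1: 4 good weeks + 1 with 4 missing days; cow 2: 2 good weeks;
    cow 3: exactly 3 good weeks."""
    rows = []
    for cow, weeks in ((1, [7, 7, 5, 4, 3]), (2, [7, 7]), (3, [4, 4, 4])):
        for w, nd in enumerate(weeks, start=1):
            rows.append({"cow_id": cow, "week_index": w, "n_days_observed": nd})
    return pd.DataFrame(rows)


class TestEditingFilters:
    def test_week_and_cow_rules(self):
        out, report = apply_editing_filters(_toy_records())
        # cow 1 loses the 3-day week, keeps 4; cow 2 dropped entirely;
        # cow 3 with exactly 3 valid weeks retained
        assert report.n_input == 10
        assert report.n_removed_missing_days == 1
        assert report.n_removed_few_weeks == 2
        assert report.n_cows_removed == 1
        assert report.n_output == 7
        assert set(out["cow_id"]) == {1, 3}
        assert (out.groupby("cow_id").size() >= 3).all()

    def test_empty_input(self):
        out, report = apply_editing_filters(pd.DataFrame(columns=["cow_id", "week_index", "n_days_observed"]))
        assert len(out) == 0
        assert report.n_input == 0 and report.n_output == 0


class TestDeltaBw:
    def test_centered_difference(self):
        table = pd.DataFrame(
            {"cow_id": [1] * 4, "bw_kg": [600.0, 604.0, 610.0, 611.0]}
        )
        d = delta_bw(table).to_numpy()
        assert d[0] == pytest.approx(4.0)  # forward at start
        assert d[1] == pytest.approx(5.0)  # (610-600)/2
        assert d[2] == pytest.approx(3.5)  # (611-604)/2
        assert d[3] == pytest.approx(1.0)  # backward at end

    def test_single_record_is_missing(self):
        table = pd.DataFrame({"cow_id": [1], "bw_kg": [600.0]})
        assert np.isnan(delta_bw(table).iloc[0])


def _residual_table(n=400, seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "cow_id": np.repeat(np.arange(n // 4), 4),
            "eys_class": rng.choice(["a", "b", "c"], n),
            "lactation_week": rng.integers(1, 45, n),
            "parity": rng.choice(["1", "2", "3+"], n),
            "age_at_calving_months": rng.uniform(22, 60, n),
            "ecm": rng.normal(36, 6, n),
            "mbw": rng.normal(120, 8, n),
        }
    )


class TestResidualize:
    def test_ols_properties(self):
        table = _residual_table()
        rng = np.random.default_rng(1)
        table["mep"] = 300 + 4 * table["ecm"] + rng.normal(0, 40, len(table))
        r = residualize(table, "mep", ("ecm", "mbw"))
        assert np.mean(r) == pytest.approx(0.0, abs=1e-9)
        for col in ("ecm", "mbw", "age_at_calving_months"):
            assert float(r @ table[col]) == pytest.approx(0.0, abs=1e-6)

    def test_recovers_noise_when_trait_is_linear_in_ecm(self):
        table = _residual_table(seed=2)
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 10, len(table))
        table["mep"] = 5.0 * table["ecm"] + noise
        r = residualize(table, "mep", ("ecm", "mbw"))
        assert np.corrcoef(r, table["ecm"])[0, 1] ** 2 < 0.01
        # the fit also absorbs a little noise through the other columns
        assert np.corrcoef(r, noise)[0, 1] > 0.9

    def test_residuals_uncorrelated_with_covariates_on_fit_sample(self):
        table = _residual_table(seed=4)
        rng = np.random.default_rng(5)
        table["mep"] = 200 + 3 * table["ecm"] + 0.5 * table["mbw"] + rng.normal(
            0, 30, len(table)
        )
        r = residualize(table, "mep", ("ecm", "mbw"))
        for col in ("ecm", "mbw"):
            x = table[col] - table[col].mean()
            corr = float(x @ r) / np.sqrt(float(x @ x) * float(r @ r))
            assert abs(corr) < 1e-10

    def test_rank_deficiency_names_columns(self):
        table = _residual_table(seed=6)
        table["dup"] = table["ecm"]
        table["mep"] = table["ecm"] * 2
        with pytest.raises(DesignError, match="dup"):
            residualize(table, "mep", ("ecm", "dup"))

    def test_missing_inputs_propagate(self):
        table = _residual_table(seed=7)
        table["mep"] = 5.0 * table["ecm"]
        table.loc[3, "mep"] = np.nan
        table.loc[5, "ecm"] = np.nan
        r = TraitResidualizer(("ecm", "mbw")).fit_transform(table, table["mep"])
        assert np.isnan(r[3]) and np.isnan(r[5])
        assert np.isfinite(np.delete(r, [3, 5])).all()


class TestBuildTraitTable:
    def test_pipeline_round_trip(self, small_herd):
        _, herd, table = small_herd
        for trait in ("ecm", "mbw", "dmi", "mep"):
            assert np.allclose(
                table[trait].to_numpy(),
                herd.latent[trait].to_numpy(),
                rtol=1e-10,
                atol=1e-10,
            )

    def test_mec_consistent_with_ch4_stream(self, small_herd):
        _, herd, table = small_herd
        expected = 100.0 * np.log(herd.records["ch4_ppm"].to_numpy())
        assert np.allclose(table["mec"].to_numpy(), expected)
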