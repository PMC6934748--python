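"""Melt-curve simulation, normalization, peak calling, species assignment,
and the throughput report."""

import numpy as np
import pandas as pd
import pytest

from meltdiag import (
    ClassifierParams,
    ConfigError,
    InputError,
    MeltCurve,
    MeltSimParams,
    NormalizationError,
    SpeciesCall,
    ThermoConditions,
    call_species,
    classify_curves,
    default_grid,
    derivative_and_peak,
    normalize_curve,
    simulate_melt_curve,
    summarize_assay,
)

REFS = {"marginata": 79.4, "dolus": 77.0}
NOISELESS = MeltSimParams(sd_fluor=0.0, sd_tm_shift_C=0.0)


def _piecewise_normalized_curve():
    """Exactly-normalized synthetic curve: 1 before the melt, 0 after,
    linear drop in between."""
    t = default_grid()
    f = np.interp(t, [65.0, 74.0, 80.0, 85.0], [1.0, 1.0, 0.0, 0.0])
    return MeltCurve("syn", t, f)


class TestSimulateMeltCurve:
    @pytest.mark.parametrize("tm", [77.0, 79.4])
    def test_noiseless_peak_recovers_tm(self, cond, tm):
        curve = simulate_melt_curve(-450.0, tm, cond, NOISELESS)
        d = derivative_and_peak(normalize_curve(curve))
        assert d.peak_tm_C == pytest.approx(tm, abs=0.05)

    def test_zero_amplitude_classified_failed(self, cond):
        rng = np.random.default_rng(0)
        params = MeltSimParams(amplitude=0.0)
        curve = simulate_melt_curve(-450.0, 77.0, cond, params, rng)
        (call,) = classify_curves([curve], REFS)
        assert call.call == "failed"

    def test_reproducible_under_seed(self, cond):
        c1 = simulate_melt_curve(-450.0, 77.0, cond, rng=np.random.default_rng(3))
        c2 = simulate_melt_curve(-450.0, 77.0, cond, rng=np.random.default_rng(3))
        assert np.array_equal(c1.fluorescence, c2.fluorescence)

    def test_monte_carlo_peak_separation(self, cond):
        """Two amplicons 2.4 degC apart, jitter sd 0.15: the mean simulated
        peak separation over 100 replicates recovers 2.4 +/- 0.3."""
        rng = np.random.default_rng(11)
        params = MeltSimParams(sd_fluor=0.01, sd_tm_shift_C=0.15)
        seps = []
        for _ in range(100):
            hi = simulate_melt_curve(-450.0, 79.4, cond, params, rng)
            lo = simulate_melt_curve(-450.0, 77.0, cond, params, rng)
            p_hi = derivative_and_peak(normalize_curve(hi)).peak_tm_C
            p_lo = derivative_and_peak(normalize_curve(lo)).peak_tm_C
            seps.append(p_hi - p_lo)
        assert np.mean(seps) == pytest.approx(2.4, abs=0.3)


class TestNormalizeCurve:
    def test_idempotent_on_normalized_input(self):
        curve = _piecewise_normalized_curve()
        out = normalize_curve(curve)
        assert np.allclose(out.fluorescence, curve.fluorescence, atol=1e-9)

    def test_affine_invariance(self):
        curve = _piecewise_normalized_curve()
        scaled = MeltCurve("syn", curve.temps_C, 10.0 * curve.fluorescence + 100.0)
        assert np.allclose(
            normalize_curve(curve).fluorescence,
            normalize_curve(scaled).fluorescence,
            atol=1e-9,
        )

    def test_affine_invariance_random(self, cond):
        rng = np.random.default_rng(12)
        curve = simulate_melt_curve(-450.0, 78.0, cond, rng=rng)
        for _ in range(5):
            a = rng.uniform(0.1, 50.0)
            b = rng.uniform(-100.0, 100.0)
            scaled = MeltCurve("x", curve.temps_C, a * curve.fluorescence + b)
            assert np.allclose(
                normalize_curve(curve).fluorescence,
                normalize_curve(scaled).fluorescence,
                atol=1e-6,
            )

    def test_default_windows_pin_plateaus(self, cond):
        curve = simulate_melt_curve(-450.0, 77.0, cond, NOISELESS)
        out = normalize_curve(curve)
        t = out.temps_C
        assert out.fluorescence[(t >= 66) & (t <= 68)].mean() == pytest.approx(1.0, abs=0.01)
        assert out.fluorescence[(t >= 83) & (t <= 85)].mean() == pytest.approx(0.0, abs=0.01)

    def test_small_window_rejected(self):
        curve = _piecewise_normalized_curve()
        with pytest.raises(NormalizationError):
            normalize_curve(curve, pre_window=(66.0, 66.1))

    def test_output_clipped(self, cond):
        rng = np.random.default_rng(13)
        curve = simulate_melt_curve(-450.0, 77.0, cond, rng=rng)
        out = normalize_curve(curve)
        assert out.fluorescence.min() >= -0.05 and out.fluorescence.max() <= 1.05


class TestDerivativeAndPeak:
    def test_logistic_peak_position(self):
        t = default_grid()
        f = 1.0 / (1.0 + np.exp((t - 78.0) / 0.3))
        d = derivative_and_peak(MeltCurve("syn", t, f))
        assert d.peak_tm_C == pytest.approx(78.0, abs=0.05)

    @pytest.mark.parametrize("tm", np.arange(68.0, 82.5, 1.7))
    def test_unbiased_across_grid(self, tm):
        t = default_grid()
        f = 1.0 / (1.0 + np.exp((t - tm) / 0.4))
        d = derivative_and_peak(MeltCurve("syn", t, f))
        assert d.peak_tm_C == pytest.approx(tm, abs=0.05)

    def test_bimodal_returns_major_peak_records_secondary(self):
        t = default_grid()
        f = 0.6 / (1.0 + np.exp((t - 72.0) / 0.4)) + 1.0 / (
            1.0 + np.exp((t - 79.0) / 0.4)
        )
        d = derivative_and_peak(MeltCurve("syn", t, f))
        assert d.peak_tm_C == pytest.approx(79.0, abs=0.1)
        assert any(abs(p - 72.0) < 0.2 for p, _ in d.secondary_peaks)

    def test_flat_curve_flagged(self):
        t = default_grid()
        d = derivative_and_peak(MeltCurve("syn", t, np.full_like(t, 0.3)))
        assert d.flagged_low_signal and d.peak_tm_C is None
        assert d.peak_height == 0.0

    def test_even_window_rejected(self):
        curve = _piecewise_normalized_curve()
        with pytest.raises(InputError):
            derivative_and_peak(curve, smooth=(10, 3))


class TestCallSpecies:
    def _dcurve(self, peak, height=0.3):
        t = default_grid()
        return type(
            "D",
            (),
            {
                "specimen_id": "s1",
                "peak_tm_C": peak,
                "peak_height": height,
                "flagged_low_signal": False,
            },
        )()

    @pytest.mark.parametrize(
        "peak, expected",
        [
            (79.4, "marginata"),
            (77.0, "dolus"),
            (78.2, "ambiguous"),  # midpoint: outside tau of both
        ],
    )
    def test_examples(self, peak, expected):
        assert call_species(self._dcurve(peak), REFS).call == expected

    def test_low_height_fails(self):
        assert call_species(self._dcurve(79.4, height=0.01), REFS).call == "failed"

    def test_close_references_rejected(self):
        with pytest.raises(ConfigError):
            call_species(self._dcurve(79.4), {"a": 77.0, "b": 77.5})

    def test_single_reference_rejected(self):
        with pytest.raises(InputError):
            call_species(self._dcurve(79.4), {"a": 77.0})


def _make_calls_and_metadata(
    n=518, n_males=279, n_failed=9, n_discordant=30, species=("marginata", "dolus")
):
    """Synthetic call/metadata tables with exact counts: failures among males,
    discordant prior labels among successful males."""
    calls, meta = [], []
    sp_a, sp_b = species
    for i in range(n):
        sid = f"s{i:04d}"
        male = i < n_males
        true = sp_a if i % 2 == 0 else sp_b
        if male and i < n_failed:
            calls.append(SpeciesCall(sid, "failed", None, None))
            prior = true
        else:
            calls.append(SpeciesCall(sid, true, 79.4 if true == sp_a else 77.0, 2.0))
            prior = None
            if male:
                discordant = n_failed <= i < n_failed + n_discordant
                prior = (sp_b if true == sp_a else sp_a) if discordant else true
        meta.append(
            {
                "specimen_id": sid,
                "sex": "male" if male else "female",
                "prior_label": prior if male else None,
            }
        )
    return calls, pd.DataFrame(meta)


class TestSummarizeAssay:
    def test_throughput_percentages(self):
        """518 specimens, 9 male failures, 30 discordant male labels:
        1.7% overall / 3.2% male failures, 10.75% (10.8%) discordance."""
        calls, meta = _make_calls_and_metadata()
        rep = summarize_assay(calls, meta)
        total, male, female = (
            rep.group("total"),
            rep.group("male"),
            rep.group("female"),
        )
        assert total["n_samples"] == 518 and male["n_samples"] == 279
        assert total["n_failed"] == 9 and total["pct_failed_1dp"] == 1.7
        assert male["n_failed"] == 9 and male["pct_failed_1dp"] == 3.2
        assert female["n_failed"] == 0
        assert total["n_ambiguous"] == 0
        assert male["n_discordant"] == 30
        assert male["pct_discordant_2dp"] == 10.75
        assert male["pct_discordant_1dp"] == 10.8
        n_success = total["n_samples"] - total["n_failed"]
        assert n_success == 509

    def test_count_conservation(self):
        calls, meta = _make_calls_and_metadata()
        rep = summarize_assay(calls, meta)
        for name in ("total", "male", "female"):
            row = rep.group(name)
            assigned = sum(
                row[c] for c in rep.table.columns if c.startswith("n_assigned_")
            )
            assert row["n_failed"] + row["n_ambiguous"] + assigned == row["n_samples"]

    def test_count_conservation_random_cohorts(self):
        rng = np.random.default_rng(14)
        options = ["marginata", "dolus", "ambiguous", "failed"]
        for _ in range(10):
            n = int(rng.integers(1, 60))
            calls = [
                SpeciesCall(f"s{i}", str(rng.choice(options)), None, None)
                for i in range(n)
            ]
            meta = pd.DataFrame(
                {
                    "specimen_id": [f"s{i}" for i in range(n)],
                    "sex": rng.choice(["male", "female"], n),
                    "prior_label": rng.choice(["marginata", None], n),
                }
            )
            rep = summarize_assay(calls, meta)
            for name in ("total", "male", "female"):
                row = rep.group(name)
                assigned = sum(
                    row[c] for c in rep.table.columns if c.startswith("n_assigned_")
                )
                assert (
                    row["n_failed"] + row["n_ambiguous"] + assigned == row["n_samples"]
                )

    def test_zero_specimens(self):
        meta = pd.DataFrame(columns=["specimen_id", "sex", "prior_label"])
        rep = summarize_assay([], meta)
        assert rep.group("total")["n_samples"] == 0
        assert rep.group("total")["pct_failed_1dp"] == 0.0

    def test_report_text_renders(self):
        calls, meta = _make_calls_and_metadata(n=20, n_males=10, n_failed=1, n_discordant=2)
        text = summarize_assay(calls, meta).to_text()
        assert "failed" in text and "[male]" in text
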