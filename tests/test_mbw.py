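"""Breath segmentation and washout indices (FRC, LCI, Sn, Scond*, Sacin*)."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from cflung.mbw import (
    BreathTable,
    MbwAnalyzer,
    MbwIndices,
    WashoutTrace,
    average_replicates,
    compute_frc,
    compute_lci,
    compute_scond_sacin,
    phase3_normalized_slopes,
    segment_breaths,
)
from cflung.synthetic import (
    LungModelParams,
    simulate_washout,
    washout_concentration_series,
)


def square_wave_trace(n_breaths=15, period_s=4.0, amp=0.5, fs=50.0, noise_sd=0.0, seed=0):
    """Square-wave flow, inspiration first; constant N2 0.05 on expiration."""
    t = np.arange(0, n_breaths * period_s, 1.0 / fs)
    phase = (t % period_s) < period_s / 2
    flow = np.where(phase, -amp, amp)
    if noise_sd:
        flow = flow + np.random.default_rng(seed).normal(0, noise_sd, flow.shape)
    n2 = np.where(phase, 0.0, 0.05)
    return WashoutTrace(time_s=t, flow_L_per_s=flow, n2_frac=n2, sample_rate_hz=fs)


class TestSegmentBreaths:
    def test_square_wave_count_and_volumes(self):
        bt = segment_breaths(square_wave_trace())
        assert len(bt) == 15
        # 0.5 L/s for 2 s per phase; trapezoid loses less than one sample
        assert bt.df["v_exp"].to_numpy() == pytest.approx(np.full(15, 1.0), abs=0.02)
        assert bt.df["v_insp"].to_numpy() == pytest.approx(np.full(15, 1.0), abs=0.02)

    def test_noisy_square_wave_same_count(self):
        bt = segment_breaths(square_wave_trace(noise_sd=0.02, seed=4))
        assert len(bt) == 15

    def test_all_zero_flow_errors(self):
        tr = WashoutTrace(
            time_s=np.arange(100) / 10.0,
            flow_L_per_s=np.zeros(100),
            n2_frac=np.zeros(100),
            sample_rate_hz=10.0,
        )
        with pytest.raises(ValueError, match="no complete breath"):
            segment_breaths(tr)

    def test_cev_is_cumulative(self):
        bt = segment_breaths(square_wave_trace())
        assert np.allclose(np.diff(bt.df["cev"]), bt.df["v_exp"].iloc[1:])


class TestFrc:
    def test_single_compartment_recovery(self, single_comp_trace, analyzer):
        idx, _ = analyzer.analyze(single_comp_trace)
        assert idx.frc_L == pytest.approx(3.0, rel=0.01)

    def test_two_compartment_recovery(self, two_comp_trace, analyzer):
        idx, _ = analyzer.analyze(two_comp_trace)
        assert idx.frc_L == pytest.approx(3.0, rel=0.01)

    def test_recovery_across_parameter_grid(self):
        an = MbwAnalyzer()
        for frc in (2.5, 4.5):
            for vt in (0.8, 1.1):
                p = LungModelParams.two_compartment(
                    frc_total=frc, tidal_volume=vt, dead_space=0.15
                )
                idx, _ = an.analyze(simulate_washout(p))
                assert idx.frc_L == pytest.approx(frc, rel=0.01)

    def test_equal_concentrations_error(self, single_comp_trace):
        bt = segment_breaths(single_comp_trace)
        with pytest.raises(ValueError, match="c_start > c_end"):
            compute_frc(bt, c_start=0.5, c_end=0.5)


class TestLci:
    def test_closed_form_dilution_series(self, single_comp_trace, analyzer):
        # breath 13 first below 0.78/40; alveolar VT 1 L, FRC 3 L
        idx, _ = analyzer.analyze(single_comp_trace)
        assert idx.lci == pytest.approx(13.0 / 3.0, rel=0.01)

    def test_already_cleared_error(self):
        t = np.arange(0, 40, 0.02)
        phase = (t % 4.0) < 2.0
        flow = np.where(phase, -0.5, 0.5)
        n2 = np.where(phase, 0.0, 0.001)  # below 0.78/40 from the start
        tr = WashoutTrace(time_s=t, flow_L_per_s=flow, n2_frac=n2, sample_rate_hz=50.0)
        bt = segment_breaths(tr)
        with pytest.raises(ValueError, match="already cleared"):
            compute_lci(bt, frc_L=3.0, c_start=0.78)

    def test_threshold_never_reached_error(self):
        bt = segment_breaths(square_wave_trace())  # constant 0.05 > 0.78/40
        with pytest.raises(ValueError, match="never reached"):
            compute_lci(bt, frc_L=3.0, c_start=0.78)

    def test_interpolated_lci_is_smaller(self, single_comp_trace):
        an_i = MbwAnalyzer(interpolate_lci=True)
        an = MbwAnalyzer()
        lci_i = an_i.analyze(single_comp_trace)[0].lci
        lci = an.analyze(single_comp_trace)[0].lci
        assert lci_i < lci

    def test_monotone_in_ventilation_asymmetry(self):
        """More asymmetric specific ventilation never lowers LCI."""
        lcis = []
        for fast_frac in (0.5, 0.6, 0.7, 0.8):
            p = LungModelParams.two_compartment(
                fast_vent_fraction=fast_frac, dead_space=0.15
            )
            lcis.append(MbwAnalyzer().analyze(simulate_washout(p))[0].lci)
        assert np.all(np.diff(lcis) >= 0)


def _table(sn, to, v_exp=1.0):
    n = len(sn)
    df = pd.DataFrame(
        {
            "index": np.arange(n),
            "v_insp": np.ones(n) * v_exp,
            "v_exp": np.ones(n) * v_exp,
            "cev": np.cumsum(np.ones(n) * v_exp),
            "c_mean_exp": np.full(n, 0.1),
            "c_et": np.full(n, 0.1),
            "s3": np.asarray(sn) * 0.05,
            "sn": np.asarray(sn, dtype=float),
            "flagged": np.zeros(n, bool),
            "to": np.asarray(to, dtype=float),
        }
    )
    return BreathTable(df=df, expirograms=[(np.array([0.0]), np.array([0.0]))] * n)


class TestPhase3Slopes:
    def test_flat_expirogram_zero_slope(self):
        bt = segment_breaths(square_wave_trace())  # constant 0.05 plateau
        bt = phase3_normalized_slopes(bt)
        assert bt.df["s3"].to_numpy() == pytest.approx(np.zeros(15), abs=1e-12)
        assert bt.df["sn"].to_numpy() == pytest.approx(np.zeros(15), abs=1e-12)

    def test_linear_expirogram_exact(self):
        """Expirogram 0.05 + 0.01 v over 1 L: S3 = 0.01 /L and Sn divides
        by the window mean 0.05725 (window midpoint v = 0.725)."""
        t = np.arange(0, 4.0, 0.01)
        phase = t < 2.0
        flow = np.where(phase, -0.5, 0.5)
        v = np.clip((t - 2.0) * 0.5, 0, None)
        n2 = np.where(phase, 0.0, 0.05 + 0.01 * v)
        tr = WashoutTrace(time_s=t, flow_L_per_s=flow, n2_frac=n2, sample_rate_hz=100.0)
        bt = phase3_normalized_slopes(segment_breaths(tr))
        assert bt.df["s3"].iloc[0] == pytest.approx(0.0100, rel=1e-3)
        assert bt.df["sn"].iloc[0] == pytest.approx(0.0100 / 0.05725, rel=1e-2)

    def test_small_breaths_flagged(self):
        tr = square_wave_trace()
        bt = segment_breaths(tr)
        bt.df.loc[7, "v_exp"] = 0.2  # shrink one breath below half the median
        bt2 = phase3_normalized_slopes(bt)
        assert bt2.df["flagged"].iloc[7]
        assert np.isnan(bt2.df["sn"].iloc[7])

    def test_sn_matches_forward_model_oracle(self, two_comp_params, two_comp_trace):
        """Per-breath Sn equals the analytic expired-mixture slope of the
        compartmental model."""
        _, bt = MbwAnalyzer().analyze(two_comp_trace)
        state = washout_concentration_series(two_comp_params)
        p = two_comp_params
        vt_alv = p.tidal_volume - p.dead_space
        # window in alveolar fraction for the [50%, 95%] expired-volume window
        x_lo = (0.5 * p.tidal_volume - p.dead_space) / vt_alv
        x_hi = (0.95 * p.tidal_volume - p.dead_space) / vt_alv
        x_mid = (x_lo + x_hi) / 2.0
        mean_win = state["mean_alveolar"] + state["drift"] * (x_mid - 0.5)
        sn_oracle = state["s3"] / mean_win
        n = len(bt.df)
        assert bt.df["sn"].to_numpy() == pytest.approx(sn_oracle[:n], abs=2e-3)


class TestScondSacin:
    def test_constant_sn(self):
        bt = _table(sn=[0.10] * 8, to=np.linspace(0.5, 4.0, 8))
        fit = compute_scond_sacin(bt)
        assert fit.scond_star == 0.0
        assert fit.sacin_star == pytest.approx(0.10)
        assert fit.accepted

    def test_exact_line(self):
        to = np.linspace(0.5, 4.0, 10)
        bt = _table(sn=0.02 + 0.05 * to, to=to)
        fit = compute_scond_sacin(bt)
        assert fit.scond_star == pytest.approx(0.05, rel=1e-9)
        assert fit.fit_r2 == pytest.approx(1.0)
        assert fit.sacin_star == pytest.approx(0.02, rel=1e-6)

    def test_too_few_breaths_in_window(self):
        bt = _table(sn=[0.1, 0.2, 0.3], to=[0.5, 1.0, 4.0])
        with pytest.raises(ValueError, match=">= 3 usable breaths"):
            compute_scond_sacin(bt)

    def test_homogeneous_lung_null(self, single_comp_trace, analyzer):
        idx, _ = analyzer.analyze(single_comp_trace)
        assert abs(idx.scond_star) < 1e-6
        assert abs(idx.sacin_star) < 1e-6

    def test_heterogeneous_lung_positive_scond(self, two_comp_trace, analyzer):
        idx, _ = analyzer.analyze(two_comp_trace)
        assert idx.scond_star > 0.01
        assert idx.accepted

    def test_turnover_consistency(self, two_comp_trace, analyzer):
        idx, bt = analyzer.analyze(two_comp_trace)
        assert bt.df["to"].iloc[-1] == pytest.approx(
            bt.df["cev"].iloc[-1] / idx.frc_L, rel=1e-12
        )


class TestAverageReplicates:
    def _mk(self, scond, r2):
        return MbwIndices(
            frc_L=3.0, lci=6.0, scond_star=scond, sacin_star=0.1,
            fit_r2=r2, n_breaths=20, accepted=r2 > 0.5,
        )

    def test_identical_replicates(self):
        r = self._mk(0.05, 0.9)
        avg = average_replicates([r, r, r])
        assert avg.scond_star == pytest.approx(r.scond_star, rel=1e-12)
        assert avg.lci == pytest.approx(r.lci, rel=1e-12)

    def test_acceptance_rule_filters_scond(self):
        reps = [self._mk(0.04, 0.9), self._mk(0.06, 0.8), self._mk(0.50, 0.4)]
        avg = average_replicates(reps)
        assert avg.scond_star == pytest.approx(0.05)
        assert avg.lci == pytest.approx(6.0)  # LCI averages all replicates

    def test_no_accepted_errors(self):
        with pytest.raises(ValueError, match="zero accepted"):
            average_replicates([self._mk(0.1, 0.3)])

    def test_averaging_beats_single_replicates(self):
        """Noisy triplicate averages land closer to the true Scond* than a
        single replicate in most Monte-Carlo runs."""
        p0 = LungModelParams.two_compartment(dead_space=0.15)
        truth = MbwAnalyzer().analyze(simulate_washout(p0))[0].scond_star
        an = MbwAnalyzer()
        wins = 0
        n_runs = 60
        for i in range(n_runs):
            reps = []
            for j in range(3):
                p = LungModelParams.two_compartment(
                    dead_space=0.15, conc_noise_sd=0.004, seed=1000 + 3 * i + j
                )
                reps.append(an.analyze(simulate_washout(p))[0])
            avg_err = abs(average_replicates(reps).scond_star - truth)
            single_err = abs(reps[0].scond_star - truth)
            if avg_err <= single_err:
                wins += 1
        assert wins / n_runs >= 0.6
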