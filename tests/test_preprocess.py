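"""Preprocessing chain: SCI, OD, TDDR, Beer-Lambert, regression, filters, GLM."""

import numpy as np
import pytest
from scipy import signal as sps

from nirslat import (
    ChannelQuality,
    EventSchedule,
    Recording,
    bandpass,
    beer_lambert,
    build_design,
    compute_sci,
    glm_residualize,
    run_preprocessing,
    short_channel_regress,
    tddr,
    to_optical_density,
)
from nirslat.preprocess import EXTINCTION, _tddr_1d
from nirslat.recording import Event

FS = 7.8


def _two_wavelength_recording(series_by_channel, fs=FS, stage="intensity"):
    ids, bands, cols = [], [], []
    for cid, (a, b) in series_by_channel.items():
        ids += [cid, cid]
        bands += ["760", "850"]
        cols += [a, b]
    return Recording(np.column_stack(cols), fs, stage, ids, bands)


class TestSci:
    def test_shared_cardiac_gives_high_sci(self):
        t = np.arange(0, 360, 1 / FS)
        rng = np.random.default_rng(0)
        card = np.sin(2 * np.pi * 1.2 * t)
        rec = _two_wavelength_recording(
            {"S1-D1": (10 + card + 0.01 * rng.standard_normal(t.size),
                       12 + 1.3 * card + 0.01 * rng.standard_normal(t.size))}
        )
        assert compute_sci(rec).sci[0] > 0.95

    def test_independent_noise_gives_low_sci(self):
        rng = np.random.default_rng(1)
        n = int(360 * FS)
        rec = _two_wavelength_recording(
            {"S1-D1": (10 + 0.1 * rng.standard_normal(n), 10 + 0.1 * rng.standard_normal(n))}
        )
        assert abs(compute_sci(rec).sci[0]) < 0.2

    @pytest.mark.parametrize("sci,flagged", [(0.39, True), (0.41, False)])
    def test_threshold_is_strictly_below_0p4(self, sci, flagged):
        q = ChannelQuality(["c"], np.array([sci]))
        assert bool(q.flagged[0]) is flagged

    def test_single_wavelength_rejected(self):
        rec = Recording(np.random.default_rng(0).normal(10, 1, (3000, 1)) ** 2,
                        FS, "intensity", ["S1-D1"], ["760"])
        with pytest.raises(ValueError, match="both wavelengths"):
            compute_sci(rec)

    def test_short_recording_rejected(self):
        n = int(10 * FS)
        rng = np.random.default_rng(0)
        rec = _two_wavelength_recording({"S1-D1": (10 + rng.normal(0, 0.1, n), 10 + rng.normal(0, 0.1, n))})
        with pytest.raises(ValueError, match="cardiac cycles"):
            compute_sci(rec)


class TestOpticalDensity:
    def test_constant_intensity_gives_zero_od(self):
        rec = _two_wavelength_recording({"S1-D1": (np.full(100, 3.0), np.full(100, 5.0))})
        assert np.abs(to_optical_density(rec).data).max() == 0.0

    def test_gain_invariance(self):
        rng = np.random.default_rng(2)
        base = np.exp(rng.normal(0, 0.1, 100))
        a = _two_wavelength_recording({"S1-D1": (base, base)})
        b = _two_wavelength_recording({"S1-D1": (7.3 * base, 0.2 * base)})
        assert np.allclose(to_optical_density(a).data, to_optical_density(b).data, atol=1e-12)

    def test_exact_inverse_construction(self):
        x = np.sin(np.linspace(0, 6, 200)) * 0.1
        i = np.exp(-x)
        i = i / i.mean()  # mean exactly 1 so OD(t) = x(t) - log(mean exp(-x))
        rec = _two_wavelength_recording({"S1-D1": (i, i)})
        od = to_optical_density(rec).data[:, 0]
        assert np.allclose(od - od.mean(), x - x.mean(), atol=1e-12)

    def test_nonpositive_sample_names_channel_and_sample(self):
        bad = np.ones(50)
        bad[17] = -1.0
        rec = _two_wavelength_recording({"S9-D9": (np.ones(50), bad)})
        with pytest.raises(ValueError, match=r"S9-D9.*17"):
            to_optical_density(rec)


class TestTddr:
    def test_constant_signal_unchanged(self):
        x = np.full(2808, 3.7)
        assert np.abs(_tddr_1d(x, FS) - x).max() < 1e-9

    def test_step_artifact_reduced_90_percent(self):
        t = np.arange(0, 360, 1 / FS)
        clean = np.sin(2 * np.pi * 0.05 * t)
        step = 10 * clean.std()
        x = clean.copy()
        x[x.size // 2 :] += step
        resid = _tddr_1d(x, FS) - clean
        n = x.size
        residual_step = abs(np.mean(resid[int(0.7 * n) :]) - np.mean(resid[: int(0.3 * n)]))
        assert residual_step <= 0.1 * step

    def test_smooth_sinusoid_distortion_below_5_percent(self):
        t = np.arange(0, 360, 1 / FS)
        clean = np.sin(2 * np.pi * 0.05 * t)
        out = _tddr_1d(clean, FS)
        assert np.sqrt(np.mean((out - clean) ** 2)) < 0.05 * np.sqrt(np.mean(clean**2))

    def test_reduces_extreme_derivative_percentile_on_spikes(self):
        t = np.arange(0, 360, 1 / FS)
        rng = np.random.default_rng(1)
        clean = np.sin(2 * np.pi * 0.05 * t)
        x = clean.copy()
        for t0 in rng.uniform(10, 350, 5):
            x += 10 * clean.std() * rng.choice([-1, 1]) * np.exp(-np.abs(t - t0) / 0.15)
        out = _tddr_1d(x, FS)
        p = lambda v: np.percentile(np.abs(np.diff(v)), 99.9)
        assert p(out) < p(x)

    def test_continuous_variant_matches_reference_implementation(self):
        """inlier_preserving=False reproduces the published continuous
        reweighting (cross-checked against MNE's reference TDDR)."""
        mne = pytest.importorskip("mne.preprocessing.nirs._tddr")
        rng = np.random.default_rng(0)
        t = np.arange(0, 120, 1 / FS)
        x = np.sin(2 * np.pi * 0.05 * t) + 0.3 * rng.standard_normal(t.size)
        x[500:] += 2.0
        ours = _tddr_1d(x, FS, inlier_preserving=False)
        theirs = mne._TDDR(x.copy(), FS)
        # implementations differ only in the low/high split filter padding
        assert np.corrcoef(ours, theirs)[0, 1] > 0.99

    def test_too_short_run_rejected(self):
        rec = Recording(np.zeros((10, 1)), FS, "optical_density", ["S1-D1"], ["760"])
        with pytest.raises(ValueError, match="warm-up"):
            tddr(rec)


class TestBeerLambert:
    def test_zero_od_gives_zero_concentration(self, montage):
        rec = _two_wavelength_recording({montage.long_ids[0]: (np.zeros(50), np.zeros(50))},
                                        stage="optical_density")
        hb = beer_lambert(rec, montage)
        assert np.abs(hb.data).max() == 0.0

    def test_forward_inverse_round_trip(self, montage):
        rng = np.random.default_rng(3)
        cid = montage.long_ids[0]
        d_cm = montage[cid].separation * 100
        hbo, hbr = rng.normal(0, 1, 300), rng.normal(0, 0.3, 300)  # micromolar
        od = {}
        for wl in ("760", "850"):
            e = EXTINCTION[wl]
            od[wl] = d_cm * 6.0 * (e["HbO"] * hbo + e["HbR"] * hbr) * 1e-6
        rec = _two_wavelength_recording({cid: (od["760"], od["850"])}, stage="optical_density")
        hb = beer_lambert(rec, montage)
        assert np.abs(hb.column(cid, "HbO") - hbo).max() < 1e-9
        assert np.abs(hb.column(cid, "HbR") - hbr).max() < 1e-9

    def test_doubling_dpf_halves_concentrations(self, montage):
        rng = np.random.default_rng(4)
        cid = montage.long_ids[0]
        rec = _two_wavelength_recording({cid: (rng.normal(0, 0.01, 100), rng.normal(0, 0.01, 100))},
                                        stage="optical_density")
        one = beer_lambert(rec, montage, dpf={"760": 6.0, "850": 6.0})
        two = beer_lambert(rec, montage, dpf={"760": 12.0, "850": 12.0})
        assert np.allclose(two.data, one.data / 2.0, atol=1e-15)

    def test_singular_extinction_rejected(self, montage):
        cid = montage.long_ids[0]
        rec = _two_wavelength_recording({cid: (np.zeros(10), np.zeros(10))}, stage="optical_density")
        ext = {"760": {"HbO": 1.0, "HbR": 2.0}, "850": {"HbO": 2.0, "HbR": 4.0}}
        with pytest.raises(ValueError, match="singular"):
            beer_lambert(rec, montage, extinction=ext)


def _hb_recording(montage, series_by_channel, fs=FS):
    ids, bands, cols = [], [], []
    for cid, x in series_by_channel.items():
        ids.append(cid)
        bands.append("HbO")
        cols.append(x)
    return Recording(np.column_stack(cols), fs, "haemoglobin", ids, bands)


def _nearest_short(montage, cid):
    mid = montage[cid].midpoint
    return min(montage.short_ids, key=lambda s: float(np.linalg.norm(montage[s].midpoint - mid)))


class TestShortChannelRegression:
    def test_long_equal_to_short_gives_zero_residual(self, montage):
        rng = np.random.default_rng(5)
        cid = montage.long_ids[0]
        short = _nearest_short(montage, cid)
        x = rng.normal(0, 1, 400)
        rec = _hb_recording(montage, {cid: x, short: x})
        out = short_channel_regress(rec, montage)
        assert np.sqrt(np.mean(out.column(cid, "HbO") ** 2)) < 1e-9 * np.sqrt(np.mean(x**2))

    def test_orthogonal_long_passes_through_demeaned(self, montage):
        cid = montage.long_ids[0]
        short = _nearest_short(montage, cid)
        n = 400
        t = np.arange(n)
        a = np.sin(2 * np.pi * t / 50) + 2.0
        b = np.cos(2 * np.pi * t / 50)  # orthogonal over integer periods
        rec = _hb_recording(montage, {cid: a, short: b})
        out = short_channel_regress(rec, montage)
        assert np.allclose(out.column(cid, "HbO"), a - a.mean(), atol=1e-9)

    def test_residual_orthogonal_to_short_channel(self, montage):
        rng = np.random.default_rng(6)
        series = {cid: rng.normal(0, 1, 500) for cid in montage.long_ids[:4]}
        for s in montage.short_ids:
            series[s] = rng.normal(0, 1, 500)
        rec = _hb_recording(montage, series)
        out = short_channel_regress(rec, montage)
        for cid in montage.long_ids[:4]:
            short = _nearest_short(montage, cid)
            resid = out.column(cid, "HbO")
            reg = rec.column(short, "HbO")
            assert abs(np.corrcoef(resid, reg)[0, 1]) < 1e-10

    def test_all_shorts_flagged_passes_through_with_warning(self, montage):
        rng = np.random.default_rng(7)
        series = {montage.long_ids[0]: rng.normal(0, 1, 100)}
        rec = _hb_recording(montage, series)
        with pytest.warns(UserWarning, match="short channels"):
            out = short_channel_regress(rec, montage, flagged=list(montage.short_ids))
        assert np.array_equal(out.data, rec.data)


class TestBandpass:
    def _tone(self, freq, dur=600.0):
        t = np.arange(0, dur, 1 / FS)
        x = np.sin(2 * np.pi * freq * t)
        return Recording(x[:, None], FS, "haemoglobin", ["S1-D1"], ["HbO"]), x

    def test_passband_tone_preserved(self):
        rec, x = self._tone(0.1)
        out = bandpass(rec).data[:, 0]
        interior = slice(int(60 * FS), -int(60 * FS))
        assert np.abs(out[interior]).max() == pytest.approx(1.0, rel=0.02)

    def test_slow_drift_attenuated(self):
        rec, x = self._tone(0.005, dur=2000.0)
        out = bandpass(rec).data[:, 0]
        # steady-state response away from the filter's edge transients
        interior = slice(int(200 * FS), -int(200 * FS))
        assert np.abs(out[interior]).max() < 0.05

    def test_zero_phase(self):
        rec, x = self._tone(0.1)
        out = bandpass(rec).data[:, 0]
        lags = sps.correlation_lags(x.size, x.size)
        xc = sps.correlate(out - out.mean(), x - x.mean())
        assert lags[np.argmax(xc)] == 0

    def test_low_sampling_rate_rejected(self):
        rec = Recording(np.zeros((100, 1)), 0.5, "haemoglobin", ["c"], ["HbO"])
        with pytest.raises(ValueError, match="sampling rate"):
            bandpass(rec)


class TestGlm:
    def _evoked_recording(self, columns):
        ev = EventSchedule([Event(10, 15, "auditory"), Event(50, 15, "visual"),
                            Event(90, 15, "auditory"), Event(130, 15, "visual")])
        n = int(170 * FS)
        return Recording(np.column_stack(columns)[:n], FS, "haemoglobin",
                         [f"c{i}" for i in range(len(columns))],
                         ["HbO"] * len(columns), events=ev), n

    def test_design_column_fully_removed(self):
        rec, n = self._evoked_recording([np.zeros(2000)])
        design = build_design(n, FS, rec.events)
        rec = rec.with_data(design.matrix[:, [1]])
        out = glm_residualize(rec, design=design)
        assert np.sqrt(np.mean(out.data**2)) < 1e-9 * np.sqrt(np.mean(rec.data**2))

    def test_orthogonal_channel_demeaned_only(self):
        rng = np.random.default_rng(8)
        x = rng.normal(5, 1, 2000)
        rec, n = self._evoked_recording([x])
        design = build_design(n, FS, rec.events)
        X = design.matrix
        # orthogonalize against the task regressors first
        beta, *_ = np.linalg.lstsq(X, rec.data, rcond=None)
        orth = rec.data - X[:, 1:] @ beta[1:]
        out = glm_residualize(rec.with_data(orth), design=design)
        assert np.allclose(out.data, orth - orth.mean(axis=0), atol=1e-9)

    def test_residuals_orthogonal_to_all_regressors(self):
        rng = np.random.default_rng(9)
        rec, n = self._evoked_recording([rng.normal(0, 1, 2000) for _ in range(3)])
        design = build_design(n, FS, rec.events)
        out = glm_residualize(rec, design=design)
        X = design.matrix / np.linalg.norm(design.matrix, axis=0)
        resid = out.data / np.linalg.norm(out.data, axis=0)
        assert np.abs(X.T @ resid).max() < 1e-10

    def test_resting_run_is_demeaned_passthrough(self):
        rng = np.random.default_rng(10)
        x = rng.normal(3, 1, (500, 2))
        rec = Recording(x, FS, "haemoglobin", ["a", "b"], ["HbO", "HbO"])
        out = glm_residualize(rec)
        assert np.allclose(out.data, x - x.mean(axis=0), atol=1e-12)
        assert out.stage == "residual"

    def test_rank_deficient_design_rejected(self):
        from nirslat.preprocess import GLMDesign

        n = 100
        X = np.column_stack([np.ones(n), np.ones(n)])
        rec = Recording(np.zeros((n, 1)), FS, "haemoglobin", ["a"], ["HbO"])
        with pytest.raises(ValueError, match="rank"):
            glm_residualize(rec, design=GLMDesign(X, ["intercept", "dup"]))


class TestFullChain:
    def test_chain_recovers_injected_hbo(self, montage, noise_free_subject):
        out, quality = run_preprocessing(noise_free_subject.runs["rest"], montage)
        truth = noise_free_subject.truth
        for cid in out.unique_channels:
            r = np.corrcoef(out.column(cid, "HbO"),
                            truth.hbo["rest"][:, truth.long_ids.index(cid)])[0, 1]
            assert r > 0.99

    def test_output_restricted_to_unflagged_long_hbo(self, montage, noisy_subject):
        out, quality = run_preprocessing(noisy_subject.runs["rest"], montage)
        assert out.stage == "residual"
        assert set(out.bands) == {"HbO"}
        expected = [c for c in montage.long_ids if c not in quality.flagged_ids]
        assert out.unique_channels == expected

    def test_injected_bad_channels_are_exactly_the_dropped_ones(self, montage):
        from nirslat import SimulationConfig, SubjectMeta, simulate_subject

        cfg = SimulationConfig(seed=5, max_bad_channels=3)
        meta = SubjectMeta("s", "control", "none")
        for seed in range(20):
            sub = simulate_subject(cfg, montage, meta, seed=seed)
            if any(c in montage.long_ids for c in sub.truth.bad_channels):
                break
        out, quality = run_preprocessing(sub.runs["rest"], montage)
        assert set(quality.flagged_ids) == set(sub.truth.bad_channels)
        bad_long = [c for c in sub.truth.bad_channels if c in montage.long_ids]
        assert set(montage.long_ids) - set(out.unique_channels) == set(bad_long)

    def test_default_cohort_stays_below_eight_flags(self, montage):
        from nirslat import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(seed=3, n_control=2, n_unilateral_left=1,
                               n_unilateral_right=1, n_bilateral=2, n_trials_per_condition=2)
        for sub in simulate_cohort(cfg, montage):
            _, quality = run_preprocessing(sub.runs["rest"], montage)
            assert quality.n_flagged < 8
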