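"""Synthetic fNIRS study generator with known ground truth.

Generates complete cohorts of raw dual-wavelength intensity recordings whose
latent connectivity modules, hemispheric laterality regime, physiological
nuisance components and artifacts are all known, so that every pipeline
stage and the group-level laterality contrasts can be tested end to end.

Signal model, per channel and run:

1. latent neural HbO (micromolar): a shared-factor construction gives exact
   expected pairwise correlations -- within-module rho_in, between-module
   rho_out -- from band-limited (0.04-0.35 Hz) unit-variance noise;
2. evoked runs add a canonical-HRF-convolved boxcar response per condition,
   scaled by a region-specific amplitude;
3. HbR = hbr_scale * HbO + independent noise (HbR is carried only so the
   Beer-Lambert and SNIRF stages are exercised realistically);
4. haemoglobin maps to optical density through the forward modified
   Beer-Lambert relation, and OD to intensity as I = gain * exp(-dOD);
5. cardiac (~1.1-1.3 Hz), systemic (~0.1 Hz, shared between short and long
   channels), motion artifacts (spikes and baseline shifts at recorded
   onsets) and white measurement noise are added in the OD domain; channels
   in the bad-channel set lose their cardiac component, which is what the
   scalp-coupling index flags downstream.

Group structure: control and bilateral subjects carry interhemispheric
modules (|Nr-Nl|/Nt = 0 by construction); unilateral subjects carry
lateralized modules -- the tinnitus-side hemisphere split into three
single-hemisphere modules and the opposite hemisphere forming one -- giving
ground-truth Module Laterality 1 and Modified Module Laterality +/-0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy import signal as sps

from .montage import Montage, default_montage
from .preprocess import DEFAULT_DPF, EXTINCTION, canonical_hrf
from .recording import Event, EventSchedule, Recording, SubjectMeta, WAVELENGTHS

#: wavelength-specific scaling of the shared cardiac waveform
_CARDIAC_WL_SCALE = {"760": 0.8, "850": 1.2}


@dataclass
class SimulationConfig:
    """All knobs of the generator; one seed drives every random draw."""

    seed: int = 0
    fs: float = 7.8
    # cohort composition (defaults match the study's group sizes)
    n_control: int = 18
    n_unilateral_left: int = 11
    n_unilateral_right: int = 7
    n_bilateral: int = 26
    # protocol
    rest_duration_s: float = 360.0
    n_trials_per_condition: int = 10
    block_s: float = 15.0
    isi_choices_s: tuple = (20.0, 25.0)
    pre_s: float = 20.0
    post_s: float = 25.0
    # latent module structure
    rho_in: float = 0.7
    rho_out: float = 0.15
    latent_sd_um: float = 1.0
    # evoked responses (micromolar peak amplitude per region)
    evoked_amp_um: dict = field(
        default_factory=lambda: {
            "auditory": {"left-temporal": 0.8, "right-temporal": 0.8, "frontal": 0.2},
            "visual": {"occipital": 0.8},
        }
    )
    evoked_scale_tinnitus: float = 1.0  # optional response reduction in tinnitus
    # haemodynamics / physiology
    hbr_scale: float = -0.3
    hbr_noise_um: float = 0.1
    cardiac_freq_hz: tuple = (1.1, 1.3)
    cardiac_amp_od: float = 0.01
    systemic_freq_hz: float = 0.1
    systemic_amp_long_um: float = 0.5
    systemic_amp_short_um: float = 1.0
    short_noise_um: float = 0.2
    # artifacts and noise
    spike_rate_per_min: float = 0.5
    spike_amp_od: float = 0.05
    shift_rate_per_min: float = 0.2
    shift_amp_od: float = 0.05
    noise_od_sd: float = 5e-4
    max_bad_channels: int = 3
    bad_channel_noise_od: float = 0.01

    def __post_init__(self):
        if not (0.0 <= self.rho_out < self.rho_in < 1.0):
            raise ValueError("need 1 > rho_in > rho_out >= 0")
        if self.fs <= 2 * self.cardiac_freq_hz[1]:
            raise ValueError("sampling rate must exceed twice the cardiac frequency")

    def noise_free(self) -> "SimulationConfig":
        """Variant with artifacts, physiology and noise disabled (oracle)."""
        return dc_replace(
            self,
            hbr_noise_um=0.0,
            cardiac_amp_od=0.0,
            systemic_amp_long_um=0.0,
            systemic_amp_short_um=0.0,
            short_noise_um=0.0,
            spike_rate_per_min=0.0,
            shift_rate_per_min=0.0,
            noise_od_sd=0.0,
            max_bad_channels=0,
        )


@dataclass
class GroundTruth:
    """Oracle record for one simulated subject."""

    modules: dict[str, int]  # long-channel id -> latent module index
    regime: str  # "interhemispheric" | "lateralized-left" | "lateralized-right"
    expected_mml: float
    expected_ml: float
    hbo: dict[str, np.ndarray]  # run name -> time x long-channel latent HbO (uM), pre-evoked
    evoked: dict[str, np.ndarray]  # run name -> time x long-channel evoked HbO (uM)
    long_ids: list[str]
    bad_channels: list[str]
    artifact_onsets: dict[str, list[float]]  # run name -> onset seconds


@dataclass
class SimulatedSubject:
    meta: SubjectMeta
    runs: dict[str, Recording]  # "rest" and "evoked"
    truth: GroundTruth


def make_event_schedule(
    n_trials_per_condition: int,
    block_s: float = 15.0,
    isi_choices_s=(20.0, 25.0),
    seed: int = 0,
    pre_s: float = 20.0,
) -> EventSchedule:
    """Random interleaving of auditory/visual blocks, at most two of the
    same type in a row, with 20/25 s inter-stimulus intervals."""
    if n_trials_per_condition < 1:
        raise ValueError("n_trials_per_condition must be >= 1")
    rng = np.random.default_rng(seed)
    labels = ["auditory"] * n_trials_per_condition + ["visual"] * n_trials_per_condition
    for _ in range(100_000):
        perm = [labels[i] for i in rng.permutation(len(labels))]
        runs = 1
        ok = True
        for a, b in zip(perm, perm[1:]):
            runs = runs + 1 if a == b else 1
            if runs > 2:
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError("could not satisfy the <=2-in-a-row constraint")
    events = []
    t = pre_s
    for cond in perm:
        events.append(Event(t, block_s, cond))
        t += block_s + float(rng.choice(isi_choices_s))
    return EventSchedule(events)


def _layout_interhemispheric(montage: Montage) -> dict[str, int]:
    """Modules spanning hemispheres: one per region, temporal split
    anterior/posterior across both sides."""
    modules: dict[str, int] = {}
    temporal = []
    for cid in montage.long_ids:
        region = montage[cid].region
        if region == "frontal":
            modules[cid] = 0
        elif region == "occipital":
            modules[cid] = 1
        else:
            temporal.append(cid)
    for cid in temporal:
        modules[cid] = 2 if montage[cid].midpoint[1] < 0 else 3
    return modules


def _layout_lateralized(montage: Montage, side: str) -> dict[str, int]:
    """Tinnitus-side hemisphere split into three single-hemisphere modules
    (temporal / frontal / occipital); opposite hemisphere one module."""
    modules: dict[str, int] = {}
    for cid in montage.long_ids:
        ch = montage[cid]
        if ch.hemisphere != side:
            modules[cid] = 3
        elif "temporal" in ch.region:
            modules[cid] = 0
        elif ch.region == "frontal":
            modules[cid] = 1
        else:
            modules[cid] = 2
    return modules


def _expected_laterality(modules: dict[str, int], montage: Montage) -> tuple[float, float]:
    ml_vals, mml_vals = [], []
    for m in sorted(set(modules.values())):
        chans = [c for c, mm in modules.items() if mm == m]
        hemis = [montage.hemisphere(c) for c in chans]
        nr, nl, nt = hemis.count("right"), hemis.count("left"), len(hemis)
        ml_vals.append(abs(nr - nl) / nt)
        mml_vals.append((nr - nl) / nt)
    return float(np.mean(ml_vals)), float(np.mean(mml_vals))


def _band_noise(rng: np.random.Generator, n: int, fs: float, lo=0.04, hi=0.35) -> np.ndarray:
    """Unit-variance noise band-limited inside the analysis pass-band.

    Filters a longer white-noise stretch and keeps the interior, so the
    series carries no filter edge transients (which would read as
    motion-like derivative outliers downstream).
    """
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    trim = int(round(3.0 * fs / lo))
    x = sps.sosfiltfilt(sos, rng.standard_normal(n + 2 * trim))[trim : trim + n]
    return x / x.std()


def _latent_hbo(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    n: int,
    modules: dict[str, int],
    long_ids: list[str],
) -> np.ndarray:
    """Shared-factor construction: corr = rho_in within, rho_out between."""
    module_idx = sorted(set(modules.values()))
    g = _band_noise(rng, n, cfg.fs)
    a = np.sqrt(cfg.rho_out / cfg.rho_in)
    factors = {
        m: a * g + np.sqrt(1 - a**2) * _band_noise(rng, n, cfg.fs) for m in module_idx
    }
    out = np.empty((n, len(long_ids)))
    for j, cid in enumerate(long_ids):
        f = factors[modules[cid]]
        e = _band_noise(rng, n, cfg.fs)
        out[:, j] = cfg.latent_sd_um * (np.sqrt(cfg.rho_in) * f + np.sqrt(1 - cfg.rho_in) * e)
    return out


def _evoked_response(
    cfg: SimulationConfig,
    montage: Montage,
    long_ids: list[str],
    schedule: EventSchedule,
    n: int,
    scale: float,
) -> np.ndarray:
    h = canonical_hrf(cfg.fs)
    resp = np.zeros((n, len(long_ids)))
    for cond in schedule.conditions:
        box = np.zeros(n)
        for e in schedule.for_condition(cond):
            i0 = int(round(e.onset_s * cfg.fs))
            i1 = min(n, i0 + int(round(e.duration_s * cfg.fs)))
            box[i0:i1] = 1.0
        shape = np.convolve(box, h)[:n]
        peak = np.max(np.abs(shape))
        if peak > 0:
            shape = shape / peak  # amp is the peak block response in uM
        amps = cfg.evoked_amp_um.get(cond, {})
        for j, cid in enumerate(long_ids):
            amp = amps.get(montage[cid].region, 0.0)
            resp[:, j] += scale * amp * shape
    return resp


def _artifacts(
    cfg: SimulationConfig, rng: np.random.Generator, n: int, fs: float
) -> tuple[np.ndarray, list[float]]:
    """Spike + baseline-shift artifact series (OD units) and onset times."""
    out = np.zeros(n)
    onsets: list[float] = []
    dur_min = n / fs / 60.0
    t = np.arange(n) / fs
    for _ in range(rng.poisson(cfg.spike_rate_per_min * dur_min)):
        t0 = rng.uniform(0, n / fs)
        amp = rng.choice([-1, 1]) * cfg.spike_amp_od * rng.uniform(0.5, 1.5)
        out += amp * np.exp(-np.abs(t - t0) / 0.3)
        onsets.append(float(t0))
    for _ in range(rng.poisson(cfg.shift_rate_per_min * dur_min)):
        t0 = rng.uniform(0, n / fs)
        amp = rng.choice([-1, 1]) * cfg.shift_amp_od * rng.uniform(0.5, 1.5)
        out += amp * (t >= t0)
        onsets.append(float(t0))
    return out, sorted(onsets)


def simulate_subject(
    config: SimulationConfig,
    montage: Montage,
    meta: SubjectMeta,
    seed: int | None = None,
) -> SimulatedSubject:
    """Simulate the two runs (rest + evoked) of one subject at the raw
    intensity stage, returning the recordings and their ground truth."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    long_ids = montage.long_ids
    short_ids = montage.short_ids

    if meta.group == "unilateral":
        modules = _layout_lateralized(montage, meta.tinnitus_side)
        regime = f"lateralized-{meta.tinnitus_side}"
    else:
        modules = _layout_interhemispheric(montage)
        regime = "interhemispheric"
    exp_ml, exp_mml = _expected_laterality(modules, montage)

    n_bad = int(rng.integers(0, config.max_bad_channels + 1)) if config.max_bad_channels else 0
    bad = (
        [montage.channel_ids[i] for i in rng.choice(len(montage.channel_ids), n_bad, replace=False)]
        if n_bad
        else []
    )
    cardiac_f = rng.uniform(*config.cardiac_freq_hz)
    evoked_scale = config.evoked_scale_tinnitus if meta.group != "control" else 1.0

    schedule = make_event_schedule(
        config.n_trials_per_condition,
        config.block_s,
        config.isi_choices_s,
        seed=int(rng.integers(2**31)),
        pre_s=config.pre_s,
    )
    last = schedule.events[-1]
    evoked_dur = last.onset_s + last.duration_s + config.post_s

    runs: dict[str, Recording] = {}
    hbo_truth: dict[str, np.ndarray] = {}
    evoked_truth: dict[str, np.ndarray] = {}
    artifact_truth: dict[str, list[float]] = {}
    for run_name, duration, events in (
        ("rest", config.rest_duration_s, EventSchedule()),
        ("evoked", evoked_dur, schedule),
    ):
        n = int(round(duration * config.fs))
        hbo_long = _latent_hbo(config, rng, n, modules, long_ids)
        hbo_truth[run_name] = hbo_long.copy()
        if run_name == "evoked":
            resp = _evoked_response(config, montage, long_ids, events, n, evoked_scale)
            hbo_long = hbo_long + resp
        else:
            resp = np.zeros_like(hbo_long)
        evoked_truth[run_name] = resp

        t = np.arange(n) / config.fs
        systemic = _band_noise(rng, n, config.fs, 0.06, 0.14) if (
            config.systemic_amp_long_um or config.systemic_amp_short_um
        ) else np.zeros(n)

        hbo = {}
        hbr = {}
        for j, cid in enumerate(long_ids):
            hbo[cid] = hbo_long[:, j] + config.systemic_amp_long_um * systemic
        for cid in short_ids:
            idio = (
                config.short_noise_um * _band_noise(rng, n, config.fs)
                if config.short_noise_um
                else np.zeros(n)
            )
            hbo[cid] = config.systemic_amp_short_um * systemic + idio
        for cid in montage.channel_ids:
            noise = (
                config.hbr_noise_um * _band_noise(rng, n, config.fs)
                if config.hbr_noise_um
                else np.zeros(n)
            )
            hbr[cid] = config.hbr_scale * hbo[cid] + noise

        data_cols = []
        ids_cols = []
        bands_cols = []
        onsets_all: list[float] = []
        for cid in montage.channel_ids:
            d_cm = montage[cid].separation * 100.0
            is_bad = cid in bad
            art, onsets = (
                _artifacts(config, rng, n, config.fs)
                if not is_bad and (config.spike_rate_per_min or config.shift_rate_per_min)
                else (np.zeros(n), [])
            )
            onsets_all.extend(onsets)
            phase = rng.uniform(0, 2 * np.pi)
            cardiac = (
                np.zeros(n)
                if is_bad
                else config.cardiac_amp_od * np.sin(2 * np.pi * cardiac_f * t + phase)
            )
            for wl in WAVELENGTHS:
                ext = EXTINCTION[wl]
                if is_bad:
                    # decoupled optode: mostly independent instrument noise
                    od = config.bad_channel_noise_od * rng.standard_normal(n)
                else:
                    od = (
                        d_cm
                        * DEFAULT_DPF[wl]
                        * (ext["HbO"] * hbo[cid] + ext["HbR"] * hbr[cid])
                        * 1e-6
                    )
                    od = od + _CARDIAC_WL_SCALE[wl] * cardiac + art
                if config.noise_od_sd:
                    od = od + config.noise_od_sd * rng.standard_normal(n)
                gain = rng.uniform(0.5, 2.0)
                data_cols.append(gain * np.exp(-od))
                ids_cols.append(cid)
                bands_cols.append(wl)
        runs[run_name] = Recording(
            data=np.column_stack(data_cols),
            fs=config.fs,
            stage="intensity",
            channel_ids=ids_cols,
            bands=bands_cols,
            events=events,
            meta=meta,
            run_type="rest" if run_name == "rest" else "evoked",
        )
        artifact_truth[run_name] = sorted(onsets_all)

    truth = GroundTruth(
        modules=modules,
        regime=regime,
        expected_mml=exp_mml,
        expected_ml=exp_ml,
        hbo=hbo_truth,
        evoked=evoked_truth,
        long_ids=list(long_ids),
        bad_channels=bad,
        artifact_onsets=artifact_truth,
    )
    return SimulatedSubject(meta, runs, truth)


def _draw_meta(rng: np.random.Generator, subject_id: str, group: str, side: str) -> SubjectMeta:
    tinnitus = group != "control"
    hear_l = float(np.clip(rng.normal(26, 10), 0, 70))
    hear_r = float(np.clip(rng.normal(25, 10), 0, 70))
    return SubjectMeta(
        subject_id=subject_id,
        group=group,
        tinnitus_side=side,
        thi=float(np.clip(rng.normal(45, 25), 0, 100)) if tinnitus else 0.0,
        loudness=float(np.clip(rng.normal(6, 2.5), 0, 10)) if tinnitus else 0.0,
        annoyance=float(np.clip(rng.normal(5.5, 3), 0, 10)) if tinnitus else 0.0,
        duration_years=float(np.clip(rng.normal(12, 10), 0.1, 50)) if tinnitus else 0.0,
        device="sport2" if rng.uniform() < 0.15 else "scout",
        hearing_left_db=hear_l,
        hearing_right_db=hear_r,
    )


def simulate_cohort(config: SimulationConfig, montage: Montage | None = None) -> list[SimulatedSubject]:
    """Simulate the full cohort across groups; all randomness flows from
    ``config.seed``."""
    montage = montage or default_montage()
    spec: list[tuple[str, str]] = (
        [("control", "none")] * config.n_control
        + [("unilateral", "left")] * config.n_unilateral_left
        + [("unilateral", "right")] * config.n_unilateral_right
        + [("bilateral", "none")] * config.n_bilateral
    )
    ss = np.random.SeedSequence(config.seed)
    meta_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.generate_state(len(spec), dtype=np.uint32)
    out = []
    for i, ((group, side), child) in enumerate(zip(spec, child_seeds)):
        meta = _draw_meta(meta_rng, f"sub-{i + 1:03d}", group, side)
        out.append(simulate_subject(config, montage, meta, seed=int(child)))
    return out
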