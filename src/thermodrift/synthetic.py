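"""Synthetic behaviour sessions and calcium recordings with known ground truth.

Every downstream stage of the package is testable without any recorded data:
the behaviour generator is the generative twin of the decision model (visit
durations are first-passage times of the configured drift-diffusion process,
with genotype x chamber drift/noise cells and per-animal random effects),
and the calcium generator emulates a 3-day DRG culture recording (1-min
baseline, three ascending 25-s warm stimuli at 5-min intervals, optional
capsaicin and KCl epochs, neuropil contamination, bleaching and shot noise).

Default behaviour conditions
----------------------------
The within-trial diffusion coefficient is fixed at sigma = 1, so the scale
of (v, sv, a) is set by requiring sessions that look like real ones: visits
of tens of seconds and roughly 60-100 visits per 30-minute session.  With
the relative start fixed at z = 0.9 this gives a = 200 evidence units
(start-to-leave-bound distance 20) and wildtype drifts around 1 evidence/s.
The test chamber (warmer than the preferred 31 C) carries a higher drift
(leave sooner) and higher drift variability than the neutral chamber.

Visit boundaries are snapped to the 1 Hz analysis grid (the resolution of
the downstream position traces), perturbing a drawn passage time by at most
0.5 s on visits of ~10-30 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ddm
from .calcium import Epoch, FluorescenceSet, StimulusTrace
from .ddm import DDMParams, softplus, softplus_inv
from .trajectory import ANIMAL_KEYPOINTS, ChamberGeometry, KeypointTrack

__all__ = [
    "BehaviorSimConfig",
    "BehaviorSample",
    "gen_behavior_sessions",
    "gen_visits",
    "make_session_track",
    "design_table",
    "recovery_config",
    "CalciumSimConfig",
    "CalciumSample",
    "gen_calcium_dataset",
    "labelled_training_set",
    "write_behavior_sample",
    "write_calcium_hdf5",
]


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

#: genotype -> chamber -> (v, sv); the mutant differs from wildtype by a
#: +0.5 drift and +0.3 drift-variability offset in the test chamber
DEFAULT_GENOTYPES: dict[str, dict[str, tuple[float, float]]] = {
    "wildtype": {"neutral": (1.0, 0.30), "test": (1.3, 0.45)},
    "mutant": {"neutral": (1.0, 0.30), "test": (1.8, 0.75)},
}

# pixel frame used when rendering keypoint tracks
_PX_ORIGIN = (100.0, 100.0)
_PX_SPAN = (600.0, 400.0)
_TOP_LEVEL_NORM = 1.25  # cage-top reference points, in floor-corner units
_CLIMB_Y_NORM = 1.1  # injected climbing frames sit between corners and tops

_KP_OFFSETS_PX = {
    "snout": (20.0, 0.0),
    "right_ear": (8.0, 6.0),
    "left_ear": (8.0, -6.0),
    "body_centre": (0.0, 0.0),
    "tail_base": (-16.0, 0.0),
    "tail_tip": (-30.0, 0.0),
}


@dataclass(frozen=True)
class BehaviorSimConfig:
    """Conditions for simulated chamber-preference sessions."""

    genotypes: dict[str, dict[str, tuple[float, float]]] = field(default_factory=lambda: {g: dict(c) for g, c in DEFAULT_GENOTYPES.items()})
    n_animals_per_genotype: int = 20
    a: float = 200.0  # boundary separation, evidence
    z: float = 0.9  # relative start (near the leave bound)
    session_length: float = 1800.0  # s
    temp_combo: str = "31v34"
    geometry: ChamberGeometry = field(default_factory=ChamberGeometry)
    frame_rate: float = 20.0  # Hz of the rendered keypoint tracks
    keypoint_noise_sd: float = 0.005  # normalised cage units
    dropout_prob: float = 0.05  # fraction of animal-keypoint predictions lost
    climbing_frac: float = 0.0  # fraction of frames spent on the walls
    animal_sd_v: float = 0.10  # SD of per-animal drift intercepts
    animal_sd_eta: float = 0.10  # SD of per-animal effects on the pre-softplus sv scale
    sim_dt: float = 1e-3  # Euler-Maruyama step, s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.session_length <= 0:
            raise ValueError("session_length must be positive")
        if not (0 < self.z < 1):
            raise ValueError("z must lie in (0, 1)")
        if self.a <= 0:
            raise ValueError("a must be positive")
        if not (0 <= self.dropout_prob < 1):
            raise ValueError("dropout_prob must lie in [0, 1)")
        if not (0 <= self.climbing_frac <= 1):
            raise ValueError("climbing_frac must lie in [0, 1]")
        for g, chambers in self.genotypes.items():
            for c, (v, sv) in chambers.items():
                if sv < 0:
                    raise ValueError(f"sv must be >= 0 for {g}/{c}")


@dataclass
class BehaviorSample:
    """Generated sessions: visit-level ground truth and (optionally) tracks.

    ``visits`` has one row per generated visit with the observable columns
    (animal, genotype, temp_combo, chamber, start, end, duration, censored)
    plus ground-truth columns (drift, v_cell, sv_cell).  ``animal_effects``
    records each animal's random effects (u_v additive on drift; u_eta
    additive on the pre-softplus drift-variability scale).
    """

    visits: pd.DataFrame
    animal_effects: pd.DataFrame
    tracks: dict[str, KeypointTrack] | None
    config: BehaviorSimConfig


def _animal_visits(cfg: BehaviorSimConfig, genotype: str, animal: str, rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    u_v = rng.normal(0.0, cfg.animal_sd_v)
    u_eta = rng.normal(0.0, cfg.animal_sd_eta)
    L = float(cfg.session_length)
    chamber = "neutral" if rng.random() < 0.5 else "test"
    t = 0.0
    rows = []
    while t < L - 0.5:
        v_cell, sv_cell = cfg.genotypes[genotype][chamber]
        v_eff = v_cell + u_v
        sv_eff = float(softplus(softplus_inv(sv_cell) + u_eta)) if sv_cell > 0 else 0.0
        drift = rng.normal(v_eff, sv_eff)
        remaining = L - t
        s = ddm.simulate_fpt(DDMParams(v=drift, sv=0.0, a=cfg.a, z=cfg.z), n=1, dt=cfg.sim_dt, rng=rng, max_time=remaining)
        left = bool(s.absorbed[0] and s.upper[0])
        censored = not left
        dur = max(1.0, float(np.round(s.time[0]))) if left else remaining
        if t + dur >= L - 1e-9:  # leaving at (or beyond) session end is unobserved
            dur = L - t
            censored = True
        rows.append(
            {
                "animal": animal,
                "genotype": genotype,
                "temp_combo": cfg.temp_combo,
                "chamber": chamber,
                "start": t,
                "end": t + dur,
                "duration": dur,
                "censored": censored,
                "drift": drift,
                "v_cell": v_eff,
                "sv_cell": sv_eff,
            }
        )
        t += dur
        chamber = "test" if chamber == "neutral" else "neutral"
    eff = {"animal": animal, "genotype": genotype, "u_v": u_v, "u_eta": u_eta}
    return pd.DataFrame(rows), eff


def gen_visits(config: BehaviorSimConfig) -> BehaviorSample:
    """Generate visit sequences (no keypoint rendering)."""
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(config.genotypes) * config.n_animals_per_genotype)
    frames, effects = [], []
    i = 0
    for genotype in config.genotypes:
        for k in range(config.n_animals_per_genotype):
            rng = np.random.default_rng(children[i])
            i += 1
            vf, eff = _animal_visits(config, genotype, f"{genotype}_{k:02d}", rng)
            frames.append(vf)
            effects.append(eff)
    visits = pd.concat(frames, ignore_index=True)
    return BehaviorSample(visits=visits, animal_effects=pd.DataFrame(effects), tracks=None, config=config)


def _ou(rng: np.random.Generator, n: int, dt: float, tau: float, sd: float) -> np.ndarray:
    phi = np.exp(-dt / tau)
    eps = rng.standard_normal(n) * sd * np.sqrt(1 - phi**2)
    out = np.empty(n)
    acc = rng.normal(0.0, sd)
    for i in range(n):  # short scalar loop is fine at session sizes
        acc = phi * acc + eps[i]
        out[i] = acc
    return out


def make_session_track(visits: pd.DataFrame, config: BehaviorSimConfig, seed) -> KeypointTrack:
    """Render one session's visits as a keypoint track.

    The animal centroid wanders (Ornstein-Uhlenbeck) inside the occupied
    chamber; tunnel transit is instantaneous at the 1 Hz visit resolution.
    Six animal keypoints are placed at fixed body offsets with Gaussian
    jitter; an exact ``dropout_prob`` fraction of animal-keypoint
    predictions is corrupted and flagged with low likelihood, and an exact
    ``climbing_frac`` fraction of frames is lifted into the climbing band
    between the floor-corner and cage-top levels.
    """
    rng = np.random.default_rng(seed)
    geo = config.geometry
    fr = config.frame_rate
    n_frames = int(round(config.session_length * fr))
    second = np.minimum(np.floor(np.arange(n_frames) / fr).astype(int), int(config.session_length) - 1)

    cham_by_sec = np.empty(int(config.session_length), dtype=object)
    for _, row in visits.iterrows():
        cham_by_sec[int(row["start"]) : int(row["end"])] = row["chamber"]
    cham = cham_by_sec[second]

    ranges = {"neutral": geo.neutral_x, "test": geo.test_x}
    centers = {c: (lo + hi) / 2 for c, (lo, hi) in ranges.items()}
    cx = np.array([centers[c] for c in cham])
    lo = np.array([ranges[c][0] + 0.02 for c in cham])
    hi = np.array([ranges[c][1] - 0.02 for c in cham])
    x = np.clip(cx + _ou(rng, n_frames, 1 / fr, tau=2.0, sd=0.08), lo, hi)
    y = np.clip(0.5 + _ou(rng, n_frames, 1 / fr, tau=2.0, sd=0.12), 0.05, 0.95)

    if config.climbing_frac > 0:
        k = int(round(config.climbing_frac * n_frames))
        idx = rng.choice(n_frames, size=k, replace=False)
        y[idx] = _CLIMB_Y_NORM

    ox, oy = _PX_ORIGIN
    sx, sy = _PX_SPAN
    X = ox + sx * x
    Y = oy + sy * y

    cols = {}
    noise_px = config.keypoint_noise_sd * sx
    for kp, (dx, dy) in _KP_OFFSETS_PX.items():
        cols[(kp, "x")] = X + dx + rng.normal(0, noise_px, n_frames)
        cols[(kp, "y")] = Y + dy + rng.normal(0, noise_px, n_frames)
        cols[(kp, "likelihood")] = np.full(n_frames, 0.99)

    if config.dropout_prob > 0:
        total = n_frames * len(ANIMAL_KEYPOINTS)
        k = int(round(config.dropout_prob * total))
        flat = rng.choice(total, size=k, replace=False)
        for j, kp in enumerate(ANIMAL_KEYPOINTS):
            sel = flat[(flat % len(ANIMAL_KEYPOINTS)) == j] // len(ANIMAL_KEYPOINTS)
            cols[(kp, "likelihood")][sel] = 0.3
            cols[(kp, "x")][sel] = ox + sx * rng.random(sel.size)
            cols[(kp, "y")][sel] = oy + sy * rng.random(sel.size)

    corner_xy = {
        "corner_bl": (ox, oy),
        "corner_br": (ox + sx, oy),
        "corner_tl": (ox, oy + sy),
        "corner_tr": (ox + sx, oy + sy),
    }
    top_xy = {
        "top_bl": (ox, oy + sy * _TOP_LEVEL_NORM),
        "top_br": (ox + sx, oy + sy * _TOP_LEVEL_NORM),
        "top_tl": (ox + 0.02 * sx, oy + sy * _TOP_LEVEL_NORM),
        "top_tr": (ox + sx - 0.02 * sx, oy + sy * _TOP_LEVEL_NORM),
    }
    for kp, (px, py) in {**corner_xy, **top_xy}.items():
        cols[(kp, "x")] = px + rng.normal(0, 0.2, n_frames)
        cols[(kp, "y")] = py + rng.normal(0, 0.2, n_frames)
        cols[(kp, "likelihood")] = np.full(n_frames, 0.999)

    data = pd.DataFrame(cols, index=pd.RangeIndex(n_frames, name="frame")).sort_index(axis=1)
    return KeypointTrack(data=data, frame_rate=fr)


def gen_behavior_sessions(config: BehaviorSimConfig, make_tracks: bool = True) -> BehaviorSample:
    """Generate full sessions: visits, animal effects and keypoint tracks."""
    sample = gen_visits(config)
    if make_tracks:
        track_root = np.random.SeedSequence([config.seed, 1])
        animals = list(dict.fromkeys(sample.visits["animal"]))
        tracks = {}
        for child, animal in zip(track_root.spawn(len(animals)), animals):
            av = sample.visits[sample.visits["animal"] == animal]
            tracks[animal] = make_session_track(av, config, child)
        sample.tracks = tracks
    return sample


def design_table(sample: BehaviorSample) -> pd.DataFrame:
    """Observable visit table for hierarchical fitting (ground truth stripped)."""
    return sample.visits[["animal", "genotype", "temp_combo", "chamber", "duration", "censored"]].copy()


def recovery_config(seed: int = 0, n_animals: int = 20) -> BehaviorSimConfig:
    """The parameter-recovery condition: two genotypes whose test-chamber
    drift and drift variability differ by +0.5 and +0.3."""
    return BehaviorSimConfig(seed=seed, n_animals_per_genotype=n_animals)


def write_behavior_sample(sample: BehaviorSample, outdir) -> None:
    """Write visits/effects as tidy CSV and tracks as long CSV + HDF5 bundle."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sample.visits.to_csv(out / "visits_truth.csv", index=False)
    sample.animal_effects.to_csv(out / "animal_effects.csv", index=False)
    design_table(sample).to_csv(out / "visits.csv", index=False)
    if sample.tracks:
        h5path = out / "tracks.h5"
        if h5path.exists():
            h5path.unlink()
        for animal, track in sample.tracks.items():
            track.to_csv(out / f"track_{animal}.csv")
            track.to_hdf5(h5path, name=animal)


# ---------------------------------------------------------------------------
# calcium
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalciumSimConfig:
    """Conditions for simulated DRG calcium-imaging recordings.

    Defaults emulate a 3-day culture field of view: ~6% of cells are
    warm-sensitive responders (most with dynamic-phase onsets), three
    ascending warm stimuli of 25 s separated by 5-min recovery, a 1-min
    baseline, 70% neuropil contamination, slow bleaching and shot noise.
    The three plateau temperatures are free parameters of the protocol
    (ascending within the warm range below 43 C).
    """

    n_cells: int = 300
    frac_responders: float = 0.06
    frac_dynamic_onset: float = 0.70
    stimulus_plateaus: tuple[float, ...] = (34.0, 37.0, 40.0)
    base_temp: float = 32.0
    baseline_s: float = 60.0
    stimulus_s: float = 25.0
    isi_s: float = 300.0
    ramp_s: float = 8.0
    sample_rate: float = 10.0
    neuropil_gain: float = 0.7
    bleach_tau: float = 600.0
    bleach_amp: float = 0.15
    noise_sd: float = 2.0  # F units
    temp_noise_sd: float = 0.02  # degC on the thermocouple trace
    include_agonists: bool = True
    frac_capsaicin: float = 0.4
    frac_viable: float = 0.97
    amp_mean: float = 40.0  # F units; responder transient amplitude scale
    seed: int = 0

    def __post_init__(self) -> None:
        pl = self.stimulus_plateaus
        if any(b <= a for a, b in zip(pl, pl[1:])):
            raise ValueError("stimulus plateaus must be strictly ascending")
        for name in ("frac_responders", "frac_dynamic_onset", "frac_capsaicin", "frac_viable"):
            val = getattr(self, name)
            if not (0 <= val <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0 <= self.neuropil_gain < 1):
            raise ValueError("neuropil_gain must lie in [0, 1)")


@dataclass
class CalciumSample:
    """Generated recording with ground truth."""

    fset: FluorescenceSet
    truth: pd.DataFrame  # per cell: responder, onset_phase, rel_onset, capsaicin, viable
    clean_F: np.ndarray  # bleached cell fluorescence without neuropil or noise
    ramp_end_s: list[float]  # true end of each warm ramp (absolute s)
    config: CalciumSimConfig


def _transient_kernel(t: np.ndarray, rise_s: float = 1.0, decay_s: float = 8.0) -> np.ndarray:
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay_s) - np.exp(-np.maximum(t, 0) / rise_s), 0.0)
    peak = k.max()
    return k / peak if peak > 0 else k


def gen_calcium_dataset(config: CalciumSimConfig) -> CalciumSample:
    """Generate raw F / Fneu matrices, the stimulus trace and ground truth.

    Raw fluorescence composes cell signal, ``neuropil_gain`` times a shared
    neuropil trace, multiplicative bleaching and Gaussian noise; the
    returned neuropil matrix is the (noise-free) spatial-average
    contamination regressor.  Negative composed fluorescence is clipped at
    zero with a warning.
    """
    rng = np.random.default_rng(config.seed)
    c = config
    n_stim = len(c.stimulus_plateaus)
    starts = [c.baseline_s + i * (c.stimulus_s + c.isi_s) for i in range(n_stim)]
    epochs = [
        Epoch(
            label=f"warm{i + 1}",
            start=s,
            end=s + c.stimulus_s,
            kind="warm" if c.stimulus_plateaus[i] < 43.0 else "heat",
            plateau=c.stimulus_plateaus[i],
        )
        for i, s in enumerate(starts)
    ]
    t_cursor = starts[-1] + c.stimulus_s + c.isi_s
    if c.include_agonists:
        epochs.append(Epoch(label="capsaicin", start=t_cursor, end=t_cursor + c.stimulus_s, kind="capsaicin"))
        t_cursor += c.stimulus_s + c.isi_s
        epochs.append(Epoch(label="kcl", start=t_cursor, end=t_cursor + c.stimulus_s, kind="kcl"))
        t_cursor += c.stimulus_s + 60.0
    else:
        t_cursor += 60.0

    n_t = int(round(t_cursor * c.sample_rate))
    time = np.arange(n_t) / c.sample_rate

    # thermocouple trace: linear ramp to plateau, exponential relaxation
    temp = np.full(n_t, c.base_temp)
    for ep in epochs:
        if not ep.thermal:
            continue
        dT = ep.plateau - c.base_temp
        rel = time - ep.start
        ramp_shape = np.clip(rel / c.ramp_s, 0.0, 1.0)
        after = np.clip(time - ep.end, 0.0, None)
        contrib = dT * ramp_shape * np.exp(-after / 15.0)
        contrib[rel < 0] = 0.0
        temp += contrib
    temp_noisy = temp + rng.normal(0, c.temp_noise_sd, n_t)
    stim = StimulusTrace(time=time, temp=temp_noisy, sample_rate=c.sample_rate)

    # ground-truth labels
    n = c.n_cells
    responder = rng.random(n) < c.frac_responders
    dynamic = rng.random(n) < c.frac_dynamic_onset
    viable = rng.random(n) < c.frac_viable
    capsaicin = (rng.random(n) < c.frac_capsaicin) & viable
    responder &= viable
    rel_onset = np.where(
        dynamic,
        rng.uniform(1.0, c.ramp_s - 1.0, n),
        rng.uniform(c.ramp_s + 2.0, c.stimulus_s - 3.0, n),
    )

    base_f = np.clip(rng.normal(100.0, 10.0, n), 50.0, None)
    amp = np.exp(rng.normal(np.log(c.amp_mean), 0.3, n))
    bleach = (1.0 - c.bleach_amp) + c.bleach_amp * np.exp(-time / c.bleach_tau)

    signal = np.zeros((n, n_t))
    kern_t = time[: int(60 * c.sample_rate)]
    resp_idx = np.nonzero(responder)[0]
    for i in resp_idx:
        for j, ep in enumerate(epochs):
            if not ep.thermal:
                continue
            onset = ep.start + rel_onset[i]
            k = _transient_kernel(time - onset)
            signal[i] += amp[i] * (1.0 + 0.35 * j) * k
    if c.include_agonists:
        caps_ep = next(ep for ep in epochs if ep.kind == "capsaicin")
        kcl_ep = next(ep for ep in epochs if ep.kind == "kcl")
        for i in np.nonzero(capsaicin)[0]:
            signal[i] += amp[i] * 1.5 * _transient_kernel(time - (caps_ep.start + rng.uniform(1.0, 4.0)))
        for i in np.nonzero(viable)[0]:
            signal[i] += 150.0 * _transient_kernel(time - (kcl_ep.start + rng.uniform(0.5, 2.0)))

    # shared neuropil trace: slow wander plus a small stimulus-locked bleed
    slow = np.convolve(rng.normal(0, 1.0, n_t), np.ones(int(5 * c.sample_rate)) / (5 * c.sample_rate), mode="same")
    neu_shared = 30.0 + 3.0 * slow
    for ep in epochs:
        if ep.thermal:
            neu_shared += 3.0 * _transient_kernel(time - ep.start - c.ramp_s / 2)
    neu_base = np.clip(rng.normal(0.0, 2.0, n), -5.0, 5.0)
    Fneu = (neu_base[:, None] + neu_shared[None, :]) * bleach[None, :]

    clean_F = (base_f[:, None] + signal) * bleach[None, :]
    F = clean_F + c.neuropil_gain * Fneu + rng.normal(0, c.noise_sd, (n, n_t))
    n_neg = int((F < 0).sum())
    if n_neg:
        warnings.warn(f"clipped {n_neg} negative fluorescence samples at 0")
        F = np.clip(F, 0.0, None)

    fset = FluorescenceSet(F=F, Fneu=Fneu, sample_rate=c.sample_rate, stim=stim, epochs=epochs)
    truth = pd.DataFrame(
        {
            "cell": np.arange(n),
            "responder": responder,
            "onset_phase": np.where(dynamic, "dynamic", "static"),
            "rel_onset": rel_onset,
            "capsaicin": capsaicin,
            "viable": viable,
        }
    )
    ramp_ends = [ep.start + c.ramp_s for ep in epochs if ep.thermal]
    return CalciumSample(fset=fset, truth=truth, clean_F=clean_F, ramp_end_s=ramp_ends, config=c)


def labelled_training_set(
    n_traces: int = 1000,
    seed: int = 1,
    noise_sd: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Balanced labelled per-stimulus traces for classifier training.

    Mirrors the hand-labelling step on real data: a sample of traces across
    stimuli with known responder labels.  Returns (traces at 4 Hz covering
    [start - 10 s, end], labels, rate).
    """
    from .calcium import CLASSIFIER_RATE_HZ, dff, downsample

    cfg = CalciumSimConfig(
        n_cells=max(n_traces // 3 + 1, 10),
        frac_responders=0.5,
        include_agonists=False,
        seed=seed,
        **({"noise_sd": noise_sd} if noise_sd is not None else {}),
    )
    sample = gen_calcium_dataset(cfg)
    corr = sample.fset.F - cfg.neuropil_gain * sample.fset.Fneu
    by_epoch = dff(corr, cfg.sample_rate, "first-10-frames-per-stimulus", epochs=sample.fset.epochs)
    traces, labels = [], []
    for label, trace in by_epoch.items():
        traces.append(downsample(trace.data, trace.sample_rate, CLASSIFIER_RATE_HZ))
        labels.append(sample.truth["responder"].to_numpy())
    X = np.vstack(traces)[:n_traces]
    y = np.concatenate(labels)[:n_traces]
    return X, y, CLASSIFIER_RATE_HZ


def write_calcium_hdf5(sample: CalciumSample, path, metadata_csv=None) -> None:
    """Write the recording as an HDF5 bundle (F, Fneu, temperature, time)
    plus a metadata table."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("F", data=sample.fset.F)
        h5.create_dataset("Fneu", data=sample.fset.Fneu)
        h5.create_dataset("temperature", data=sample.fset.stim.temp)
        h5.create_dataset("time", data=sample.fset.stim.time)
        h5.attrs["sample_rate"] = sample.fset.sample_rate
        ep = sample.fset.epochs
        h5.attrs["epoch_labels"] = [e.label.encode() for e in ep]
        h5.create_dataset("epoch_start", data=[e.start for e in ep])
        h5.create_dataset("epoch_end", data=[e.end for e in ep])
        h5.attrs["epoch_kinds"] = [e.kind.encode() for e in ep]
        h5.create_dataset("epoch_plateau", data=[e.plateau if e.plateau is not None else np.nan for e in ep])
    if metadata_csv is not None:
        sample.truth.to_csv(metadata_csv, index=False)
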