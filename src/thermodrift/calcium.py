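"""Calcium-trace pipeline for cultured DRG sensory neurons.

Recordings deliver per-cell fluorescence F and surrounding-neuropil
fluorescence Fneu (cell x time), a thermocouple temperature trace, and the
stimulus schedule (three ascending warm stimuli, optionally a capsaicin and
a high-KCl epoch).  The pipeline is:

* ``neuropil_correct``   - F - r * Fneu (r = 0.7 by default)
* ``dff``                - dF/F0 with either the session convention (F0 =
                           mean of the first 10 s) or the per-stimulus
                           convention (F0 = mean of the first 10 frames of
                           each stimulus window); optional percentile
                           clipping at the 0.1 / 99.9 percentiles
* ``segment_phases``     - split each warm stimulus into its dynamic
                           (rising) and static (plateau) phase at the end of
                           the peak of the smoothed temperature change rate
* ``classify_responders``- deterministic feature-based time-series
                           classifier (trained on labelled traces) marking
                           responding cells per stimulus
* ``onset_time``         - first time a responder exceeds 10% of its
                           maximum dF/F0 within the stimulus
* ``heatmap_order``      - cells sorted by the earliest crossing of 10% of
                           their cumulative dF/F0
* ``fov_stats``          - per-field-of-view responder proportions and mean
                           dF/F0 AUC per stimulus

Warm-sensitive cells respond to stimuli below 43 C; cells responding only
at >= 43 C are heat responders.  Cells that respond to none of the applied
stimuli are excluded from all downstream tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import NotFittedError
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

__all__ = [
    "HEAT_THRESHOLD_C",
    "StimulusTrace",
    "Epoch",
    "FluorescenceSet",
    "DFFTrace",
    "PhaseSplit",
    "ResponderClassifier",
    "neuropil_correct",
    "dff",
    "segment_phases",
    "downsample",
    "trace_features",
    "train_responder_classifier",
    "classify_responders",
    "onset_time",
    "build_responder_table",
    "heatmap_order",
    "fov_stats",
    "FOVStats",
]

HEAT_THRESHOLD_C = 43.0  # warm (innocuous) below, heat at or above
DEFAULT_NEUROPIL_R = 0.7
DEFAULT_CLIP_PERCENTILES = (0.1, 99.9)
ONSET_FRACTION = 0.10  # onset = first crossing of 10% of the in-stimulus max
CLASSIFIER_RATE_HZ = 4.0  # per-stimulus traces are downsampled to 4 Hz


@dataclass
class StimulusTrace:
    """Bath temperature (degC) sampled over the recording."""

    time: np.ndarray
    temp: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        if len(self.time) != len(self.temp):
            raise ValueError("time and temp must be congruent")


@dataclass(frozen=True)
class Epoch:
    """One stimulus application window.

    ``kind`` is "warm" or "heat" for thermal stimuli (with their plateau
    temperature) and "capsaicin" / "kcl" for the agonist epochs used as
    TRPV1-positivity and viability gates.
    """

    label: str
    start: float
    end: float
    kind: str = "warm"
    plateau: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("epoch end must exceed start")

    @property
    def thermal(self) -> bool:
        return self.kind in ("warm", "heat")


@dataclass
class FluorescenceSet:
    """Raw cell and neuropil fluorescence aligned to the stimulus trace."""

    F: np.ndarray  # cell x time, a.u.
    Fneu: np.ndarray  # cell x time, a.u.
    sample_rate: float
    stim: StimulusTrace
    epochs: list[Epoch]

    def __post_init__(self) -> None:
        if self.F.shape != self.Fneu.shape:
            raise ValueError(f"F {self.F.shape} and Fneu {self.Fneu.shape} must be congruent")
        t_end = self.F.shape[1] / self.sample_rate
        for ep in self.epochs:
            if ep.start < 0 or ep.end > t_end + 1e-9:
                raise ValueError(f"epoch {ep.label} [{ep.start}, {ep.end}] outside recording of {t_end:.1f} s")

    @property
    def n_cells(self) -> int:
        return self.F.shape[0]


@dataclass
class DFFTrace:
    """dF/F0 matrix (cell x time) with its F0 convention and validity mask."""

    data: np.ndarray
    time: np.ndarray
    sample_rate: float
    convention: str  # "first-10-s" or "first-10-frames-per-stimulus"
    valid: np.ndarray  # bool per cell; False where F0 <= 0


@dataclass
class PhaseSplit:
    """Dynamic/static decomposition of one thermal stimulus epoch."""

    label: str
    epoch_start: float
    epoch_end: float
    boundary: float  # s; dynamic = [epoch_start, boundary), static = [boundary, epoch_end]

    def phase_of(self, t: float) -> str:
        return "dynamic" if t < self.boundary else "static"


def neuropil_correct(F: np.ndarray, Fneu: np.ndarray, r: float = DEFAULT_NEUROPIL_R) -> np.ndarray:
    """Subtract a fraction ``r`` of the neuropil trace from each cell trace."""
    if not (0 <= r < 1):
        raise ValueError("neuropil coefficient r must lie in [0, 1)")
    F = np.asarray(F, dtype=float)
    Fneu = np.asarray(Fneu, dtype=float)
    if F.shape != Fneu.shape:
        raise ValueError(f"shape mismatch: F {F.shape} vs Fneu {Fneu.shape}")
    return F - r * Fneu


def _clip_percentiles(data: np.ndarray, valid: np.ndarray, percentiles) -> np.ndarray:
    lo, hi = np.percentile(data[valid], list(percentiles))
    out = data.copy()
    out[valid] = np.clip(data[valid], lo, hi)
    return out


def dff(
    F: np.ndarray,
    sample_rate: float,
    convention: str = "first-10-s",
    epochs: list[Epoch] | None = None,
    baseline_s: float = 10.0,
    pre_s: float = 10.0,
    n_f0_frames: int = 10,
    clip_percentiles: tuple[float, float] | None = None,
):
    """Normalise fluorescence to dF/F0 = (F - F0) / F0.

    convention "first-10-s": one F0 per cell from the first ``baseline_s``
    seconds of the recording; returns a single :class:`DFFTrace`.

    convention "first-10-frames-per-stimulus": for each epoch a window
    [start - pre_s, end] is cut out and normalised to the mean of its first
    ``n_f0_frames`` frames; returns ``{epoch label: DFFTrace}``.

    Cells with F0 <= 0 are flagged invalid (``valid=False``, rows zeroed)
    and must be excluded downstream.  ``clip_percentiles=(0.1, 99.9)``
    applies the percentile clipping used for display.
    """
    F = np.asarray(F, dtype=float)
    time = np.arange(F.shape[1]) / sample_rate
    if convention == "first-10-s":
        n0 = max(int(round(baseline_s * sample_rate)), 1)
        if n0 > F.shape[1]:
            raise ValueError("baseline window extends past the recording")
        f0 = F[:, :n0].mean(axis=1, keepdims=True)
        valid = f0[:, 0] > 0
        data = np.zeros_like(F)
        data[valid] = (F[valid] - f0[valid]) / f0[valid]
        if clip_percentiles is not None:
            data = _clip_percentiles(data, valid, clip_percentiles)
        return DFFTrace(data=data, time=time, sample_rate=sample_rate, convention=convention, valid=valid)
    if convention == "first-10-frames-per-stimulus":
        if not epochs:
            raise ValueError("per-stimulus convention requires epochs")
        out: dict[str, DFFTrace] = {}
        for ep in epochs:
            i0 = max(int(round((ep.start - pre_s) * sample_rate)), 0)
            i1 = min(int(round(ep.end * sample_rate)), F.shape[1])
            seg = F[:, i0:i1]
            if seg.shape[1] < n_f0_frames:
                raise ValueError(f"epoch {ep.label} window too short for F0 estimation")
            f0 = seg[:, :n_f0_frames].mean(axis=1, keepdims=True)
            valid = f0[:, 0] > 0
            data = np.zeros_like(seg)
            data[valid] = (seg[valid] - f0[valid]) / f0[valid]
            if clip_percentiles is not None:
                data = _clip_percentiles(data, valid, clip_percentiles)
            out[ep.label] = DFFTrace(data=data, time=time[i0:i1], sample_rate=sample_rate, convention=convention, valid=valid)
        return out
    raise ValueError(f"unknown F0 convention: {convention!r}")


# ---------------------------------------------------------------------------
# stimulus phase segmentation
# ---------------------------------------------------------------------------


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    n = max(int(n), 1)
    kernel = np.ones(n) / n
    pad = np.concatenate([np.full(n // 2, x[0]), x, np.full(n - 1 - n // 2, x[-1])])
    return np.convolve(pad, kernel, mode="valid")


def segment_phases(
    stim: StimulusTrace,
    epochs: list[Epoch],
    smooth_s: float = 2.0,
    frac: float = 0.10,
) -> list[PhaseSplit]:
    """Split each thermal stimulus at the end of the peak of the smoothed
    temperature change rate.

    The temperature derivative is smoothed with a centred moving average of
    width ``smooth_s``; within each epoch the boundary is the first time
    after the rate peak at which the smoothed rate falls below ``frac`` of
    the peak.  The moving average delays that crossing by a known
    ``smooth_s * (1/2 - frac)`` for an ideal ramp-plateau stimulus, so the
    detector subtracts this filter delay; on a noiseless ramp the boundary
    therefore lands on the ramp end.
    """
    rate = np.gradient(np.asarray(stim.temp, dtype=float), 1.0 / stim.sample_rate)
    n_smooth = int(round(smooth_s * stim.sample_rate))
    srate = _moving_average(rate, n_smooth)
    t = np.asarray(stim.time, dtype=float)
    out = []
    for ep in epochs:
        if not ep.thermal:
            continue
        sel = (t >= ep.start) & (t <= ep.end)
        r = srate[sel]
        ts = t[sel]
        ipk = int(np.argmax(r))
        if r[ipk] <= 0:
            raise ValueError(f"no positive temperature-rate peak inside epoch {ep.label}")
        below = np.nonzero(r[ipk:] < frac * r[ipk])[0]
        crossing = ts[ipk + below[0]] if below.size else ep.end
        boundary = crossing - smooth_s * (0.5 - frac)
        boundary = float(np.clip(boundary, ep.start, ep.end))
        out.append(PhaseSplit(label=ep.label, epoch_start=ep.start, epoch_end=ep.end, boundary=boundary))
    return out


# ---------------------------------------------------------------------------
# responder classification
# ---------------------------------------------------------------------------


def downsample(data: np.ndarray, rate_in: float, rate_out: float = CLASSIFIER_RATE_HZ) -> np.ndarray:
    """Block-average along the last axis from ``rate_in`` to ``rate_out`` Hz."""
    step = int(round(rate_in / rate_out))
    if step <= 1:
        return np.asarray(data, dtype=float)
    n = (data.shape[-1] // step) * step
    return np.asarray(data, dtype=float)[..., :n].reshape(*data.shape[:-1], n // step, step).mean(axis=-1)


def _response_template(n: int, rate: float, rise_s: float = 1.0, decay_s: float = 8.0) -> np.ndarray:
    t = np.arange(n) / rate
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return k / k.max()


def trace_features(traces: np.ndarray, rate: float, pre_s: float = 10.0) -> np.ndarray:
    """Feature matrix for per-stimulus dF/F0 traces (cells x time at 4 Hz).

    Each trace covers [stimulus start - pre_s, stimulus end].  Features:
    peak and mean in-stimulus amplitude z-scored against the pre-stimulus
    baseline, signal-to-noise, correlation with a canonical transient
    template, and the late/early response balance.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n_pre = max(int(round(pre_s * rate)), 2)
    base = traces[:, :n_pre]
    stim = traces[:, n_pre:]
    mu = base.mean(axis=1)
    sd = base.std(axis=1) + 1e-3
    peak = stim.max(axis=1)
    mean = stim.mean(axis=1)
    tmpl = _response_template(stim.shape[1], rate)
    sc = stim - stim.mean(axis=1, keepdims=True)
    tc = tmpl - tmpl.mean()
    denom = np.sqrt((sc**2).sum(axis=1) * (tc**2).sum()) + 1e-12
    corr = (sc @ tc) / denom
    half = stim.shape[1] // 2
    balance = stim[:, half:].mean(axis=1) - stim[:, :half].mean(axis=1)
    return np.column_stack(
        [
            (peak - mu) / sd,
            (mean - mu) / sd,
            peak,
            mean - mu,
            corr,
            balance / sd,
        ]
    )


@dataclass
class ResponderClassifier:
    """Deterministic feature-based responder classifier.

    A logistic regression over :func:`trace_features`, trained on labelled
    per-stimulus traces; identical inputs give identical calls.
    """

    scaler: StandardScaler = field(default_factory=StandardScaler)
    model: LogisticRegression = field(default_factory=lambda: LogisticRegression(C=1.0, max_iter=2000))
    pre_s: float = 10.0
    fitted: bool = False

    def fit(self, traces: np.ndarray, labels: np.ndarray, rate: float = CLASSIFIER_RATE_HZ) -> "ResponderClassifier":
        X = self.scaler.fit_transform(trace_features(traces, rate, self.pre_s))
        self.model.fit(X, np.asarray(labels, dtype=int))
        self.fitted = True
        return self

    def predict(self, traces: np.ndarray, rate: float = CLASSIFIER_RATE_HZ) -> np.ndarray:
        if not self.fitted:
            raise NotFittedError("responder classifier must be trained before use")
        X = self.scaler.transform(trace_features(traces, rate, self.pre_s))
        return self.model.predict(X).astype(bool)


def train_responder_classifier(traces: np.ndarray, labels: np.ndarray, rate: float = CLASSIFIER_RATE_HZ) -> ResponderClassifier:
    """Train the responder classifier on labelled per-stimulus traces."""
    return ResponderClassifier().fit(traces, labels, rate)


def classify_responders(
    dff_by_epoch: dict[str, DFFTrace],
    epochs: list[Epoch],
    model: ResponderClassifier,
) -> pd.DataFrame:
    """Responder call per cell x thermal stimulus.

    Traces are downsampled to 4 Hz before classification.  Returns a tidy
    frame (cell, stimulus, responder); invalid cells are never positive.
    """
    if not isinstance(model, ResponderClassifier) or not model.fitted:
        raise NotFittedError("classify_responders requires a trained ResponderClassifier")
    by_label = {ep.label: ep for ep in epochs}
    rows = []
    for label, trace in dff_by_epoch.items():
        ep = by_label[label]
        if not ep.thermal:
            continue
        ds = downsample(trace.data, trace.sample_rate, CLASSIFIER_RATE_HZ)
        calls = model.predict(ds, CLASSIFIER_RATE_HZ) & trace.valid
        rows += [{"cell": i, "stimulus": label, "responder": bool(c)} for i, c in enumerate(calls)]
    return pd.DataFrame(rows)


def _agonist_response(trace: DFFTrace, z_thresh: float, pre_s: float = 10.0) -> np.ndarray:
    """Amplitude-based call for agonist (capsaicin / KCl) epochs."""
    n_pre = max(int(round(pre_s * trace.sample_rate)), 2)
    base = trace.data[:, :n_pre]
    resp = trace.data[:, n_pre:]
    z = (resp.max(axis=1) - base.mean(axis=1)) / (base.std(axis=1) + 1e-3)
    return (z > z_thresh) & trace.valid


# ---------------------------------------------------------------------------
# onset timing and tables
# ---------------------------------------------------------------------------


def onset_time(
    trace: np.ndarray,
    time: np.ndarray,
    epoch: Epoch,
    fraction: float = ONSET_FRACTION,
    smooth_s: float = 0.0,
) -> float:
    """First time within the stimulus at which dF/F0 exceeds ``fraction`` of
    its in-stimulus maximum.

    ``smooth_s`` applies a centred moving average before thresholding; on
    noisy traces this keeps the 10% threshold above the noise floor without
    shifting a clean step or ramp crossing by more than one sample.
    """
    trace = np.asarray(trace, dtype=float)
    time = np.asarray(time, dtype=float)
    if smooth_s > 0 and len(time) > 1:
        rate = 1.0 / float(np.median(np.diff(time)))
        trace = _moving_average(trace, int(round(smooth_s * rate)))
    sel = (time >= epoch.start) & (time <= epoch.end)
    seg = trace[sel]
    ts = time[sel]
    mx = seg.max()
    if mx <= 0:
        raise ValueError(f"non-positive maximum dF/F0 in epoch {epoch.label}; cell is not a responder")
    above = np.nonzero(seg > fraction * mx)[0]
    return float(ts[above[0]])


def build_responder_table(
    dff_by_epoch: dict[str, DFFTrace],
    epochs: list[Epoch],
    model: ResponderClassifier,
    phase_splits: list[PhaseSplit] | None = None,
    kcl_z: float = 5.0,
    capsaicin_z: float = 5.0,
) -> pd.DataFrame:
    """Per cell x stimulus responder table with onset times and phase labels.

    Thermal stimuli are called by the trained classifier; capsaicin and KCl
    epochs by a robust amplitude criterion (their responses are large).
    Cells that respond to none of the applied stimuli are excluded.  Columns:
    cell, stimulus, responder, onset, onset_phase, plus per-cell flags
    warm_sensitive, heat_responder, capsaicin, kcl_viable.
    """
    calls = classify_responders(dff_by_epoch, epochs, model)
    by_label = {ep.label: ep for ep in epochs}
    splits = {ps.label: ps for ps in (phase_splits or [])}
    n_cells = next(iter(dff_by_epoch.values())).data.shape[0]

    caps = np.zeros(n_cells, dtype=bool)
    kcl = np.zeros(n_cells, dtype=bool)
    for ep in epochs:
        if ep.kind == "capsaicin" and ep.label in dff_by_epoch:
            caps |= _agonist_response(dff_by_epoch[ep.label], capsaicin_z)
        elif ep.kind == "kcl" and ep.label in dff_by_epoch:
            kcl |= _agonist_response(dff_by_epoch[ep.label], kcl_z)

    warm = np.zeros(n_cells, dtype=bool)
    heat = np.zeros(n_cells, dtype=bool)
    for _, row in calls[calls["responder"]].iterrows():
        ep = by_label[row["stimulus"]]
        if ep.plateau is not None and ep.plateau < HEAT_THRESHOLD_C:
            warm[row["cell"]] = True
        else:
            heat[row["cell"]] = True

    # onsets on the 4 Hz per-stimulus traces (lightly smoothed): at full rate
    # the 10%-of-max threshold sits too close to the shot-noise floor
    ds_cache = {}
    for label, trace in dff_by_epoch.items():
        step = max(int(round(trace.sample_rate / CLASSIFIER_RATE_HZ)), 1)
        ds_cache[label] = (
            downsample(trace.data, trace.sample_rate, CLASSIFIER_RATE_HZ),
            downsample(trace.time, trace.sample_rate, CLASSIFIER_RATE_HZ),
        )
    onsets, phases = [], []
    for _, row in calls.iterrows():
        if not row["responder"]:
            onsets.append(np.nan)
            phases.append(None)
            continue
        ep = by_label[row["stimulus"]]
        data_ds, time_ds = ds_cache[row["stimulus"]]
        t_on = onset_time(data_ds[row["cell"]], time_ds, ep, smooth_s=0.75)
        onsets.append(t_on)
        phases.append(splits[ep.label].phase_of(t_on) if ep.label in splits else None)
    calls = calls.assign(onset=onsets, onset_phase=phases)
    calls["warm_sensitive"] = warm[calls["cell"]]
    calls["heat_responder"] = heat[calls["cell"]]
    calls["capsaicin"] = caps[calls["cell"]]
    calls["kcl_viable"] = kcl[calls["cell"]]
    responded_any = warm | heat | caps  # "did not respond to any applied stimulus" rule
    return calls[responded_any[calls["cell"]]].reset_index(drop=True)


def heatmap_order(session_dff: DFFTrace, fraction: float = 0.10) -> np.ndarray:
    """Cell ordering for heat maps: ascending first crossing of ``fraction``
    of each cell's cumulative dF/F0 (session convention); ties keep the
    original order and non-positive totals sort last."""
    data = session_dff.data
    csum = np.cumsum(data, axis=1)
    total = csum[:, -1]
    crossing = np.full(data.shape[0], np.inf)
    pos = total > 0
    idx = np.argmax(csum >= fraction * total[:, None], axis=1)
    crossing[pos] = idx[pos] / session_dff.sample_rate
    return np.argsort(crossing, kind="stable")


@dataclass
class FOVStats:
    """Field-of-view level summary."""

    n_viable: int
    prop_warm: float  # warm-sensitive cells / viable cells
    per_stimulus: pd.DataFrame  # stimulus, n_responders, proportion, mean_auc


def fov_stats(
    table: pd.DataFrame,
    n_viable: int,
    dff_by_epoch: dict[str, DFFTrace],
    epochs: list[Epoch],
) -> FOVStats:
    """Responder proportions (relative to KCl-viable cells) and mean
    trapezoidal AUC of dF/F0 over each stimulus epoch, averaged over that
    stimulus's responders."""
    if n_viable <= 0:
        raise ValueError("no viable cells in field of view")
    by_label = {ep.label: ep for ep in epochs}
    rows = []
    for label, trace in dff_by_epoch.items():
        ep = by_label[label]
        if not ep.thermal:
            continue
        resp = table[(table["stimulus"] == label) & table["responder"]]["cell"].to_numpy()
        sel = (trace.time >= ep.start) & (trace.time <= ep.end)
        if resp.size:
            auc = np.trapezoid(trace.data[resp][:, sel], dx=1.0 / trace.sample_rate, axis=1)
            mean_auc = float(auc.mean())
        else:
            mean_auc = np.nan
        rows.append(
            {
                "stimulus": label,
                "n_responders": int(resp.size),
                "proportion": resp.size / n_viable,
                "mean_auc": mean_auc,
            }
        )
    warm_cells = table[table["warm_sensitive"]]["cell"].unique()
    return FOVStats(n_viable=int(n_viable), prop_warm=len(warm_cells) / n_viable, per_stimulus=pd.DataFrame(rows))
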