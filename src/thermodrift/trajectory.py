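"""From keypoint tracks to chamber visits and descriptive behaviour statistics.

The chamber preference test (CPT) records a mouse moving between a neutral
and a test chamber connected by a tunnel, tracked as six animal keypoints
plus eight static cage reference points (four floor corners, four cage
tops).  This module reproduces the session-processing chain:

1. ``clean_track``      - censor low-likelihood predictions, interpolate,
                          reject sessions with too much missing data
2. ``qc_climbing``      - flag sessions spent mostly on the cage walls
3. ``to_position``      - centroid of ears / body centre / tail base,
                          normalised to the tracked floor corners,
                          downsampled to 1 Hz, first 30 min
4. ``segment_visits``   - chamber occupancy runs -> visits (last censored)
5. ``summarize_session``- preference per 3-min bin, rolling visit lengths
                          (3-min window, 1-min lag), crossing counts
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ANIMAL_KEYPOINTS",
    "POSITION_KEYPOINTS",
    "CORNER_KEYPOINTS",
    "TOP_KEYPOINTS",
    "ChamberGeometry",
    "KeypointTrack",
    "SessionRejected",
    "clean_track",
    "qc_climbing",
    "to_position",
    "segment_visits",
    "summarize_session",
    "SessionSummary",
]

ANIMAL_KEYPOINTS = ["snout", "right_ear", "left_ear", "body_centre", "tail_base", "tail_tip"]
#: the animal's position is the centroid of these four keypoints
POSITION_KEYPOINTS = ["right_ear", "left_ear", "body_centre", "tail_base"]
CORNER_KEYPOINTS = ["corner_bl", "corner_br", "corner_tl", "corner_tr"]
TOP_KEYPOINTS = ["top_bl", "top_br", "top_tl", "top_tr"]

DEFAULT_LIKELIHOOD_THRESH = 0.95
DEFAULT_MAX_MISSING_FRAC = 0.25
DEFAULT_CLIMBING_FRAC = 0.95
SESSION_LENGTH_S = 1800.0  # analysed portion of a session: first 30 minutes


class SessionRejected(Exception):
    """A session failed quality control; ``reason`` says why."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


@dataclass(frozen=True)
class ChamberGeometry:
    """Chamber and tunnel extents along the normalised cage x axis."""

    neutral_x: tuple[float, float] = (0.0, 0.45)
    tunnel_x: tuple[float, float] = (0.45, 0.55)
    test_x: tuple[float, float] = (0.55, 1.0)

    def chamber_of(self, x: np.ndarray) -> np.ndarray:
        """Label each x position as neutral / tunnel / test."""
        x = np.asarray(x, dtype=float)
        return np.where(x < self.tunnel_x[0], "neutral", np.where(x > self.tunnel_x[1], "test", "tunnel"))


@dataclass
class KeypointTrack:
    """Per-frame keypoint coordinates with prediction likelihoods.

    ``data`` has one row per frame and a (keypoint, field) column MultiIndex
    with fields x, y (pixels) and likelihood in [0, 1].
    """

    data: pd.DataFrame
    frame_rate: float

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        idx = np.asarray(self.data.index)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("frame index must be strictly increasing")
        lik = self.data.xs("likelihood", axis=1, level=1).to_numpy()
        finite = lik[np.isfinite(lik)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("likelihoods must lie in [0, 1]")

    @property
    def keypoints(self) -> list[str]:
        return list(self.data.columns.get_level_values(0).unique())

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    # -- IO: long delimited text (frame, keypoint, x, y, likelihood) and HDF5

    def to_long_frame(self) -> pd.DataFrame:
        long = self.data.stack(level=0, future_stack=True).reset_index()
        long.columns = ["frame", "keypoint"] + list(long.columns[2:])
        return long[["frame", "keypoint", "x", "y", "likelihood"]]

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_rate: float) -> "KeypointTrack":
        long = pd.read_csv(path)
        wide = long.pivot(index="frame", columns="keypoint", values=["x", "y", "likelihood"])
        wide.columns = pd.MultiIndex.from_tuples([(kp, f) for f, kp in wide.columns])
        return cls(data=wide.sort_index(axis=1), frame_rate=frame_rate)

    def to_hdf5(self, path, name: str = "track") -> None:
        with h5py.File(path, "a") as h5:
            if name in h5:
                del h5[name]
            grp = h5.create_group(name)
            grp.attrs["frame_rate"] = self.frame_rate
            grp.attrs["keypoints"] = [k.encode() for k in self.keypoints]
            for f in ("x", "y", "likelihood"):
                grp.create_dataset(f, data=self.data.xs(f, axis=1, level=1)[self.keypoints].to_numpy())
            grp.create_dataset("frame", data=np.asarray(self.data.index))

    @classmethod
    def from_hdf5(cls, path, name: str = "track") -> "KeypointTrack":
        with h5py.File(path, "r") as h5:
            grp = h5[name]
            kps = [k.decode() if isinstance(k, bytes) else str(k) for k in grp.attrs["keypoints"]]
            frames = grp["frame"][:]
            cols = {}
            for f in ("x", "y", "likelihood"):
                arr = grp[f][:]
                for j, kp in enumerate(kps):
                    cols[(kp, f)] = arr[:, j]
            data = pd.DataFrame(cols, index=pd.Index(frames, name="frame")).sort_index(axis=1)
            return cls(data=data, frame_rate=float(grp.attrs["frame_rate"]))


def _require_keypoints(track: KeypointTrack, needed: list[str], what: str) -> None:
    missing = [k for k in needed if k not in track.keypoints]
    if missing:
        raise ValueError(f"track is missing {what} keypoints: {missing}")


def clean_track(
    track: KeypointTrack,
    likelihood_thresh: float = DEFAULT_LIKELIHOOD_THRESH,
    max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC,
) -> KeypointTrack:
    """Censor sub-threshold predictions, interpolate, or reject the session.

    Predictions with likelihood < ``likelihood_thresh`` are set missing.  If
    the missing fraction over the animal keypoints exceeds
    ``max_missing_frac`` (strictly) the session is rejected; otherwise
    missing coordinates are linearly interpolated over the frame index
    (edges filled from the nearest valid frame).  A keypoint with no valid
    prediction at all is grounds for rejection, not interpolation.
    """
    if not (0 < likelihood_thresh < 1) or not (0 < max_missing_frac < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    _require_keypoints(track, ANIMAL_KEYPOINTS, "animal")
    lik = track.data.xs("likelihood", axis=1, level=1)
    bad = lik < likelihood_thresh
    missing_frac = float(bad[ANIMAL_KEYPOINTS].to_numpy().mean())
    if missing_frac > max_missing_frac:
        raise SessionRejected(f"missing fraction {missing_frac:.3f} > {max_missing_frac:g}")
    all_missing = [kp for kp in track.keypoints if bool(bad[kp].all())]
    if all_missing:
        raise SessionRejected(f"keypoints with no valid prediction: {all_missing}")
    data = track.data.copy()
    for kp in track.keypoints:
        mask = bad[kp].to_numpy()
        if not mask.any():
            continue
        for f in ("x", "y"):
            col = data[(kp, f)].to_numpy(dtype=float, copy=True)
            col[mask] = np.nan
            ser = pd.Series(col, index=data.index).interpolate(method="index")
            data[(kp, f)] = ser.ffill().bfill().to_numpy()
    return KeypointTrack(data=data, frame_rate=track.frame_rate)


def _centroid(track: KeypointTrack) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack([track.data[(kp, "x")].to_numpy(dtype=float) for kp in POSITION_KEYPOINTS])
    ys = np.stack([track.data[(kp, "y")].to_numpy(dtype=float) for kp in POSITION_KEYPOINTS])
    return xs.mean(axis=0), ys.mean(axis=0)


def _corner_frame(track: KeypointTrack):
    cx = np.stack([track.data[(kp, "x")].to_numpy(dtype=float) for kp in CORNER_KEYPOINTS])
    cy = np.stack([track.data[(kp, "y")].to_numpy(dtype=float) for kp in CORNER_KEYPOINTS])
    return cx.min(axis=0), cx.max(axis=0), cy.min(axis=0), cy.max(axis=0)


def qc_climbing(track: KeypointTrack, frac_thresh: float = DEFAULT_CLIMBING_FRAC) -> bool:
    """True iff the animal spent (strictly) more than ``frac_thresh`` of the
    frames between the lower (floor-corner) and upper (cage-top) levels,
    i.e. on the walls rather than on the floor."""
    _require_keypoints(track, CORNER_KEYPOINTS, "cage corner")
    _require_keypoints(track, TOP_KEYPOINTS, "cage top")
    _, _, y0, y1 = _corner_frame(track)
    _, cy = _centroid(track)
    ynorm = (cy - y0) / (y1 - y0)
    ty = np.stack([track.data[(kp, "y")].to_numpy(dtype=float) for kp in TOP_KEYPOINTS]).mean(axis=0)
    top_level = float(((ty - y0) / (y1 - y0)).mean())
    in_band = (ynorm > 1.0) & (ynorm <= top_level + 0.25)
    return bool(in_band.mean() > frac_thresh)


def to_position(track: KeypointTrack, session_length: float = SESSION_LENGTH_S) -> pd.DataFrame:
    """Cleaned track -> 1 Hz normalised position trace over the first 30 min.

    The centroid of ears, body centre and tail base is scaled per frame to
    the tracked floor-corner frame (cancelling camera or setup shifts),
    averaged within each second and truncated to ``session_length``.
    Shorter sessions are rejected.
    """
    _require_keypoints(track, POSITION_KEYPOINTS, "position")
    _require_keypoints(track, CORNER_KEYPOINTS, "cage corner")
    cx, cy = _centroid(track)
    x0, x1, y0, y1 = _corner_frame(track)
    xn = (cx - x0) / (x1 - x0)
    yn = (cy - y0) / (y1 - y0)
    second = np.floor(np.arange(track.n_frames) / track.frame_rate).astype(int)
    df = pd.DataFrame({"second": second, "x": xn, "y": yn}).groupby("second").mean()
    n_keep = int(round(session_length))
    if len(df) < n_keep:
        raise SessionRejected(f"session shorter than {session_length:g} s ({len(df)} s)")
    df = df.iloc[:n_keep]
    return pd.DataFrame({"time": df.index.to_numpy(dtype=float), "x": df["x"].to_numpy(), "y": df["y"].to_numpy()})


def segment_visits(pos: pd.DataFrame, geometry: ChamberGeometry = ChamberGeometry()) -> pd.DataFrame:
    """Chamber-occupancy runs -> visits.

    Tunnel samples are attached to the visit they interrupt (the preceding
    chamber; leading tunnel samples join the first chamber entered).  The
    final visit is censored by the session end.  Returns a frame with
    columns chamber, start, end, duration, censored; the number of completed
    chamber changes is stored in ``.attrs["crossings"]``.
    """
    x = pos["x"].to_numpy(dtype=float)
    t = pos["time"].to_numpy(dtype=float)
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    cham = geometry.chamber_of(x)
    in_tunnel = cham == "tunnel"
    if in_tunnel.all():
        warnings.warn("position trace never leaves the tunnel; no visits")
        out = pd.DataFrame(columns=["chamber", "start", "end", "duration", "censored"])
        out.attrs["crossings"] = 0
        return out
    lab = cham.copy()
    prev = lab[~in_tunnel][0]
    for i in range(lab.size):  # tunnel samples inherit the surrounding visit
        if in_tunnel[i]:
            lab[i] = prev
        else:
            prev = lab[i]
    change = np.nonzero(lab[1:] != lab[:-1])[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [lab.size]])
    visits = pd.DataFrame(
        {
            "chamber": lab[starts],
            "start": t[starts] - t[0],
            "end": t[ends - 1] - t[0] + dt,
        }
    )
    visits["duration"] = visits["end"] - visits["start"]
    visits["censored"] = False
    visits.loc[visits.index[-1], "censored"] = True
    visits.attrs["crossings"] = len(visits) - 1
    return visits


@dataclass
class SessionSummary:
    """Descriptive statistics for one session."""

    preference: pd.DataFrame  # per 3-min bin: bin_start, frac_test, frac_neutral
    rolling: pd.DataFrame  # per window: window_start, mean_visit_length, n_visits, crossings
    crossings: int
    qc: dict = field(default_factory=dict)


def _interval_overlap(starts, ends, lo, hi):
    return np.clip(np.minimum(ends, hi) - np.maximum(starts, lo), 0.0, None)


def summarize_session(
    visits: pd.DataFrame,
    session_length: float = SESSION_LENGTH_S,
    bin_s: float = 180.0,
    window_s: float = 180.0,
    lag_s: float = 60.0,
) -> SessionSummary:
    """Preference per 3-min bin, rolling visit-length means and crossings.

    Rolling windows are time-based: a window starting at ``w`` covers visits
    whose *start* lies in [w, w + window_s); consecutive windows are lagged
    by ``lag_s``.  Per-bin chamber occupancy fractions sum to 1 because
    tunnel time is attached to visits.
    """
    if len(visits) == 0:
        raise ValueError("cannot summarise an empty visit sequence")
    vs = visits["start"].to_numpy(dtype=float)
    ve = visits["end"].to_numpy(dtype=float)
    vd = visits["duration"].to_numpy(dtype=float)
    is_test = (visits["chamber"] == "test").to_numpy()

    edges = np.arange(0.0, session_length + bin_s / 2, bin_s)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        ov = _interval_overlap(vs, ve, lo, hi)
        rows.append(
            {
                "bin_start": lo,
                "frac_test": ov[is_test].sum() / (hi - lo),
                "frac_neutral": ov[~is_test].sum() / (hi - lo),
            }
        )
    pref = pd.DataFrame(rows)

    wstarts = np.arange(0.0, session_length - window_s + 1e-9, lag_s)
    rrows = []
    for w in wstarts:
        inw = (vs >= w) & (vs < w + window_s)
        cross_in = inw & (np.arange(len(visits)) >= 1)  # each visit after the first = one completed crossing
        rrows.append(
            {
                "window_start": w,
                "mean_visit_length": float(vd[inw].mean()) if inw.any() else np.nan,
                "n_visits": int(inw.sum()),
                "crossings": int(cross_in.sum()),
            }
        )
    rolling = pd.DataFrame(rrows)
    return SessionSummary(
        preference=pref,
        rolling=rolling,
        crossings=int(visits.attrs.get("crossings", len(visits) - 1)),
    )
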