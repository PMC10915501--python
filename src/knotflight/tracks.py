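"""Trajectory cleaning for reverse-GPS (time-of-arrival) tracking data.

High-throughput regional tracking systems localize tagged shorebirds every
few seconds to minutes, but individual fixes can be badly wrong when few
receivers contribute to a solution.  The standard cleaning recipe for such
data is applied here in a fixed order:

1. remove fixes implying unrealistic ground speeds (> 100 m/s for a red knot),
2. remove fixes whose reported positional standard deviation exceeds 150 m,
3. pass a running median (window of 5 fixes) over the coordinates.

A :class:`Track` is one tag's time-ordered sequence of localizations held in
a :class:`pandas.DataFrame` with columns ``t`` (UTC timestamps), ``x``, ``y``
(planar metres) and ``sd`` (horizontal positional standard deviation, metres).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "segment_speed",
    "filter_speed",
    "filter_sd",
    "median_smooth",
    "preprocess",
    "StageReport",
]

TRACK_COLUMNS = ["t", "x", "y", "sd"]


@dataclass
class Track:
    """One tag's ordered localizations.

    Invariants: single tag id, strictly increasing timestamps, no duplicate
    timestamps (resolved at ingest by keeping the lower-sd record).
    """

    tag_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"track {self.tag_id!r} missing columns {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def times(self) -> pd.Series:
        return self.df["t"]

    @property
    def xy(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)

    def with_df(self, df: pd.DataFrame) -> "Track":
        return Track(self.tag_id, df.reset_index(drop=True))

    @classmethod
    def from_arrays(cls, tag_id, t, x, y, sd) -> "Track":
        df = pd.DataFrame(
            {"t": pd.to_datetime(t, utc=True), "x": x, "y": y, "sd": sd}
        )
        if not df["t"].is_monotonic_increasing:
            df = df.sort_values("t", kind="stable")
        return cls(str(tag_id), df)

    def validate(self) -> None:
        t = self.df["t"]
        if len(t) > 1 and not (t.diff().dropna() > pd.Timedelta(0)).all():
            raise ValueError(
                f"track {self.tag_id!r}: timestamps not strictly increasing"
            )
        if (self.df["sd"] < 0).any():
            raise ValueError(f"track {self.tag_id!r}: negative positional sd")


def segment_speed(a, b) -> float:
    """Ground speed (m/s) between two localizations.

    ``a`` and ``b`` are mappings/rows with fields ``t``, ``x``, ``y``;
    ``b`` must be strictly later than ``a``.
    """
    dt = (pd.Timestamp(b["t"]) - pd.Timestamp(a["t"])).total_seconds()
    if dt <= 0:
        raise ValueError("segment_speed requires b.t > a.t")
    return float(np.hypot(b["x"] - a["x"], b["y"] - a["y"])) / dt


def _incoming_speeds(df: pd.DataFrame) -> np.ndarray:
    """Speed of each fix from its immediate predecessor; NaN for the first."""
    t = df["t"].to_numpy()
    dt = np.diff(t).astype("timedelta64[ns]").astype(float) / 1e9
    dist = np.hypot(np.diff(df["x"].to_numpy(dtype=float)),
                    np.diff(df["y"].to_numpy(dtype=float)))
    out = np.full(len(df), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[1:] = dist / dt
    return out


def filter_speed(track: Track, threshold: float = 100.0) -> Track:
    """Iteratively drop fixes whose incoming-segment speed exceeds ``threshold``.

    Each pass recomputes speeds from the current immediate predecessor and
    removes every violating fix (strict ``>``; exactly ``threshold`` is kept);
    passes repeat until stable.  The first fix is always retained, so the
    surviving sequence never contains a segment faster than ``threshold``.
    """
    df = track.df
    if len(df) == 0:
        return track
    while True:
        speeds = _incoming_speeds(df)
        bad = speeds > threshold
        if not bad.any():
            break
        df = df.loc[~bad]
    return track.with_df(df)


def filter_sd(track: Track, threshold: float = 150.0) -> Track:
    """Drop fixes with positional standard deviation strictly above ``threshold`` metres."""
    sd = track.df["sd"]
    if sd.isna().any():
        i = int(sd.isna().idxmax())
        raise ValueError(
            f"track {track.tag_id!r}: missing sd at row {i} "
            f"(t={track.df['t'].iloc[i]})"
        )
    return track.with_df(track.df.loc[sd <= threshold])


def median_smooth(track: Track, window: int = 5) -> Track:
    """Running median of x and y over a centred window of ``window`` fixes.

    Near the ends the window shrinks symmetrically (the first and last fix
    are untouched, the second and penultimate use a window of 3, ...), so
    track length, timestamps and sd are unchanged.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("median_smooth window must be odd and >= 3")
    df = track.df
    n = len(df)
    if n == 0:
        return track
    half = window // 2
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    xs = np.empty(n)
    ys = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        xs[i] = np.median(x[i - h:i + h + 1])
        ys[i] = np.median(y[i - h:i + h + 1])
    out = df.copy()
    out["x"] = xs
    out["y"] = ys
    return track.with_df(out)


@dataclass
class StageReport:
    """Per-stage removal accounting for one track."""

    tag_id: str
    n_input: int = 0
    n_speed_removed: int = 0
    n_sd_removed: int = 0
    n_output: int = 0

    def as_dict(self) -> dict:
        return {
            "tag_id": self.tag_id,
            "n_input": self.n_input,
            "n_speed_removed": self.n_speed_removed,
            "n_sd_removed": self.n_sd_removed,
            "n_output": self.n_output,
        }


def preprocess(
    track: Track,
    speed_threshold: float = 100.0,
    sd_threshold: float = 150.0,
    smooth_window: int = 5,
    report: StageReport | None = None,
) -> Track:
    """Full cleaning pipeline: speed filter, then sd filter, then median smoother."""
    if report is None:
        report = StageReport(track.tag_id)
    report.n_input = len(track)
    after_speed = filter_speed(track, speed_threshold)
    report.n_speed_removed = report.n_input - len(after_speed)
    after_sd = filter_sd(after_speed, sd_threshold)
    report.n_sd_removed = len(after_speed) - len(after_sd)
    smoothed = median_smooth(after_sd, smooth_window)
    report.n_output = len(smoothed)
    return smoothed
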