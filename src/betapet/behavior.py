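"""Freezing scoring from frame-wise activity traces.

Overhead-video tracking reduces each behavioral session to one activity
score per video frame (a pixel-change count).  Freezing — the rodent
defense response of immobility — is scored by thresholding those scores:
a frame is inactive when its score falls strictly below a user-set
threshold.  Percent freezing is the fraction of inactive frames per 10-s
bin, and a freezing bout is a maximal run of consecutive inactive frames
lasting at least 2 s.

The activity threshold has no canonical value; it depends on camera,
arena and lighting, and is therefore a required, documented parameter
(the package default of 10.0 score units is arbitrary and should be tuned
per experiment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Default activity threshold (score units). Arbitrary; tune per experiment.
DEFAULT_THRESHOLD = 10.0

#: Minimum immobility-run duration to count as a freezing bout, seconds.
MIN_BOUT_S = 2.0

#: Bin width for percent-freezing time courses, seconds.
BIN_S = 10.0


@dataclass
class ActivityTrace:
    """Frame-wise activity scores for one behavioral session."""

    times_s: np.ndarray
    scores: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.times_s.shape != self.scores.shape:
            raise ValueError("times and scores must have equal length")
        if self.times_s.size and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.scores < 0):
            raise ValueError("activity scores must be nonnegative")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be positive")

    @classmethod
    def from_csv(cls, path, frame_rate_hz: float | None = None) -> "ActivityTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        if frame_rate_hz is None:
            frame_rate_hz = 1.0 / float(np.median(np.diff(t)))
        return cls(t, df["activity_score"].to_numpy(float), frame_rate_hz)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times_s, "activity_score": self.scores}).to_csv(
            path, index=False
        )


@dataclass
class FreezingSeries:
    """Binary inactivity flags plus binned percent freezing for a session."""

    inactive: np.ndarray
    threshold_used: float
    frame_rate_hz: float
    times_s: np.ndarray
    binned_pct: pd.DataFrame | None = None
    session_pct: float | None = None


@dataclass
class Bout:
    """One freezing bout: a maximal immobility run of at least ``MIN_BOUT_S``."""

    start_s: float
    duration_s: float


@dataclass
class KsResult:
    """Two-sample Kolmogorov-Smirnov comparison of bout-duration samples."""

    D: float
    p_value: float
    n_a: int
    n_b: int


def binarize_activity(trace: ActivityTrace, threshold: float = DEFAULT_THRESHOLD) -> FreezingSeries:
    """Flag frames as inactive when their activity score is strictly below
    ``threshold``.

    The strict inequality means a zero threshold yields zero freezing — the
    safe degenerate case.  The threshold used is recorded in the output.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if trace.scores.size == 0:
        raise ValueError("empty activity trace")
    return FreezingSeries(
        inactive=(trace.scores < threshold),
        threshold_used=float(threshold),
        frame_rate_hz=trace.frame_rate_hz,
        times_s=trace.times_s,
    )


def percent_freezing(
    series: FreezingSeries,
    bin_s: float = BIN_S,
    window: tuple[float, float] | None = None,
) -> FreezingSeries:
    """Compute per-bin and session percent freezing.

    Frames are grouped into consecutive ``bin_s`` bins starting at the
    window start (default: trace start); each bin's value is
    ``100 * inactive frames / frames in bin``.  The session value is the
    unweighted mean over *complete* bins inside the window; a trailing
    partial bin is reported in the binned table (flagged ``complete=False``)
    but excluded from the session mean.
    """
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    t = series.times_s
    if window is None:
        lo, hi = float(t[0]), float(t[-1]) + 1.0 / series.frame_rate_hz
    else:
        lo, hi = float(window[0]), float(window[1])
        if lo >= hi:
            raise ValueError("window start must precede window end")
        if lo < t[0] - 1.0 / series.frame_rate_hz or lo > t[-1]:
            raise ValueError(f"window [{lo}, {hi}] lies outside the trace")
    in_win = (t >= lo) & (t < hi)
    if not in_win.any():
        raise ValueError(f"window [{lo}, {hi}] contains no frames")
    idx = np.floor((t[in_win] - lo) / bin_s).astype(int)
    flags = series.inactive[in_win]
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    frozen = np.bincount(idx, weights=flags.astype(float), minlength=n_bins)
    pct = 100.0 * frozen / counts
    # a bin is complete when it spans the full bin width inside the window
    bin_end = lo + (np.arange(n_bins) + 1) * bin_s
    complete = bin_end <= hi + 1e-9
    binned = pd.DataFrame(
        {
            "bin_start_s": lo + np.arange(n_bins) * bin_s,
            "pct_freezing": pct,
            "n_frames": counts,
            "complete": complete,
        }
    )
    session = float(pct[complete].mean()) if complete.any() else float("nan")
    return FreezingSeries(
        inactive=series.inactive,
        threshold_used=series.threshold_used,
        frame_rate_hz=series.frame_rate_hz,
        times_s=series.times_s,
        binned_pct=binned,
        session_pct=session,
    )


def detect_bouts(series: FreezingSeries, min_duration_s: float = MIN_BOUT_S) -> list[Bout]:
    """Detect freezing bouts from unbinned inactivity flags.

    Maximal runs of consecutive inactive frames are converted to
    ``(start, duration = run length / frame rate)``; runs with duration
    >= ``min_duration_s`` (boundary included) are kept.  No smoothing and
    no merging across single-frame activity blips is applied.
    """
    flags = series.inactive.astype(int)
    if flags.size == 0:
        return []
    edges = np.diff(np.concatenate(([0], flags, [0])))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    bouts = []
    for s, e in zip(starts, ends):
        duration = (e - s) / series.frame_rate_hz
        if duration >= min_duration_s:
            bouts.append(Bout(start_s=float(series.times_s[s]), duration_s=float(duration)))
    return bouts


def bout_table(bouts: list[Bout], subject: str = "", session: str = "") -> pd.DataFrame:
    """Tabulate bouts as (subject, session, start_s, duration_s)."""
    return pd.DataFrame(
        [(subject, session, b.start_s, b.duration_s) for b in bouts],
        columns=["subject", "session", "start_s", "duration_s"],
    )


def ks_two_sample(sample_a, sample_b) -> KsResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the exact sup-gap between the two empirical CDFs; the p-value uses
    the asymptotic two-sample Smirnov distribution, appropriate for the
    hundreds of bouts typical of pooled session data.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method="asymp")
    return KsResult(D=float(res.statistic), p_value=float(res.pvalue), n_a=a.size, n_b=b.size)
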