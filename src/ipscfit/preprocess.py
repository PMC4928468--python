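"""Event isolation from raw voltage-clamp sweeps.

Turns recorded current traces (pA, inward events negative) into isolated,
baseline-free single-event traces suitable for fitting:

1. baseline/holding-current removal, using the ~5 ms of quiescent signal
   immediately preceding the detected onset;
2. event detection by a moving-window rise statistic — a candidate event
   begins where the (smoothed) signal increases by more than 10% of the
   trace's global peak magnitude across the window;
3. clipping at the point where the current has decayed to 20% of its peak,
   to avoid contamination of the late decay by smaller events;
4. rejection of events whose retained post-peak segment is shorter than
   5 ms, or that overlap a second deflection before the 20%-decay point.

The pipeline is deterministic: identical input yields identical output.
Traces are stored as recorded; event traces carry positive magnitudes.
"""

from __future__ import annotations

import glob as _glob
import os
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy.signal import medfilt

__all__ = [
    "TraceMeta",
    "RawTrace",
    "EventStatus",
    "EventWindow",
    "EventTrace",
    "TooShortError",
    "remove_baseline",
    "detect_events",
    "clip_event",
    "preprocess_trace",
    "moving_window_samples",
    "read_trace_csv",
    "read_traces_long",
    "read_trace_dir",
    "write_trace_csv",
    "write_event_csv",
    "write_event_manifest",
]

#: default thresholds of the preprocessing pipeline
DETECT_FRACTION = 0.10     # moving-window change > 10% of global peak
CLIP_FRACTION = 0.20       # clip when decayed to 20% of event peak
MIN_POST_PEAK_MS = 5.0     # reject events shorter than this after the peak
BASELINE_WINDOW_MS = 5.0   # quiescent window used for baseline estimation


class TooShortError(ValueError):
    """Trace too short for the requested baseline window."""


@dataclass(frozen=True)
class TraceMeta:
    trace_id: str = ""
    experiment: str = ""
    cell: str = ""
    holding_mv: float = -70.0


@dataclass(frozen=True)
class RawTrace:
    """A recorded sweep: current samples (pA) at fixed interval ``dt`` (ms)."""

    samples: np.ndarray
    dt: float
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.dt <= 0.0:
            raise ValueError(f"dt must be > 0, got {self.dt!r}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt

    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.samples.size)


class EventStatus(str, Enum):
    ACCEPTED = "accepted"
    REJECTED_SHORT = "rejected_short"
    REJECTED_OVERLAP = "rejected_overlap"


@dataclass(frozen=True)
class EventWindow:
    """Candidate event region: [start, end) sample indices into the raw trace."""

    start: int
    end: int
    peak_index: int
    overlap: bool = False


@dataclass(frozen=True)
class EventTrace:
    """A clipped single event: baseline-subtracted current magnitudes (pA).

    ``peak_index``, ``onset_index`` and ``clip_index`` are relative to the
    event window; ``start_index`` locates the window in the raw trace.
    """

    samples: np.ndarray
    dt: float
    peak_index: int
    peak_amplitude: float
    onset_index: int
    clip_index: int
    status: EventStatus
    start_index: int = 0
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def accepted(self) -> bool:
        return self.status is EventStatus.ACCEPTED

    @property
    def onset_time(self) -> float:
        return self.onset_index * self.dt

    @property
    def clip_time(self) -> float:
        """Time from the event peak to the clip point (ms)."""
        return (self.clip_index - self.peak_index) * self.dt

    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.samples.size)


def _deflection_sign(samples: np.ndarray) -> float:
    """Sign of the dominant deflection (inward recordings give -1)."""
    i = int(np.argmax(np.abs(samples)))
    return -1.0 if samples[i] < 0 else 1.0


def moving_window_samples(dt: float, duration: float) -> int:
    """Width of the detection moving window, in samples.

    max(1 ms, 20*dt), capped at 5% of the trace duration: wide enough to span
    the fastest rise (tau_r >= 0.05 ms) while averaging the noise, adapted per
    trace so short sweeps are not swamped by the window.
    """
    w_ms = max(1.0, 20.0 * dt)
    w_ms = min(w_ms, 0.05 * duration) if 0.05 * duration >= dt else dt
    return max(2, int(round(w_ms / dt)))


def remove_baseline(trace: RawTrace,
                    window_ms: float = BASELINE_WINDOW_MS) -> RawTrace:
    """Subtract the holding/baseline current estimated before the event onset.

    The onset is the last pre-peak sample whose deviation from a first-pass
    baseline stays within 3x the baseline-noise SD; the baseline is then the
    mean of the ``window_ms`` immediately preceding it.
    """
    if window_ms <= 0.0:
        raise TooShortError(f"baseline window must be > 0 ms, got {window_ms!r}")
    n_win = int(round(window_ms / trace.dt))
    if n_win < 1 or trace.samples.size < n_win + 1:
        raise TooShortError(
            f"trace of {trace.samples.size} samples shorter than "
            f"{window_ms} ms baseline window"
        )
    s = trace.samples
    first = s[:n_win]
    coarse = float(np.mean(first))
    noise_sd = float(np.std(first))
    dev = s - coarse
    peak = int(np.argmax(np.abs(dev)))
    quiet = np.abs(dev[:peak]) <= 3.0 * noise_sd
    onset = int(np.nonzero(quiet)[0][-1]) + 1 if np.any(quiet) else n_win
    lo = max(0, onset - n_win)
    baseline = float(np.mean(s[lo:onset])) if onset > lo else coarse
    return replace(trace, samples=s - baseline)


def _active_runs(active: np.ndarray, gap: int) -> list[tuple[int, int]]:
    """Contiguous True runs of ``active``, merging runs separated by < gap."""
    idx = np.nonzero(active)[0]
    if idx.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        if i - prev >= gap:
            runs.append((start, prev + 1))
            start = int(i)
        prev = int(i)
    runs.append((start, prev + 1))
    return runs


def detect_events(trace: RawTrace,
                  detect_fraction: float = DETECT_FRACTION,
                  clip_fraction: float = CLIP_FRACTION) -> list[EventWindow]:
    """Locate candidate event windows on a baseline-removed trace.

    An event announces itself as a rise: a net increase of the smoothed
    current magnitude, across the moving window, exceeding
    ``detect_fraction`` of the trace's global peak magnitude (with a robust
    noise floor, so pure-noise traces yield no windows).  Each contiguous
    rising region starts one candidate window, which extends to the onset
    of the next rise or the end of the trace.  An event is flagged as
    overlapping when the next rise begins before the current event has
    decayed to ``clip_fraction`` of its peak.
    """
    m = trace.samples * _deflection_sign(trace.samples)
    n = m.size
    n_w = moving_window_samples(trace.dt, trace.duration)
    if n < 2 * n_w + 1:
        return []
    smooth = np.convolve(m, np.full(n_w, 1.0 / n_w), mode="valid")
    rise = smooth[n_w:] - smooth[:-n_w]  # net change across one window
    peak_mag = float(m.max())
    if peak_mag <= 0.0:
        return []
    # robust noise scale of the rise statistic (MAD), so that fluctuations
    # of the background alone never cross the threshold
    noise_sd = 1.4826 * float(np.median(np.abs(rise - np.median(rise))))
    threshold = max(detect_fraction * peak_mag, 5.0 * noise_sd)
    active = rise > threshold
    runs = _active_runs(active, gap=n_w)
    windows: list[EventWindow] = []
    for k, (rs, _re) in enumerate(runs):
        nxt = runs[k + 1][0] if k + 1 < len(runs) else n
        start = max(0, rs - n_w)
        seg_peak = rs + int(np.argmax(m[rs:nxt]))
        overlap = False
        if k + 1 < len(runs):
            # has the current event decayed to the clip level before the
            # next deflection begins?
            tail = m[seg_peak:nxt]
            overlap = not np.any(tail <= clip_fraction * m[seg_peak])
        windows.append(EventWindow(start=start, end=nxt,
                                   peak_index=seg_peak, overlap=overlap))
    return windows


def clip_event(trace: RawTrace, window: EventWindow,
               clip_fraction: float = CLIP_FRACTION,
               min_post_peak_ms: float = MIN_POST_PEAK_MS) -> EventTrace:
    """Cut an event at the 20%-of-peak decay point and assign its status.

    The clip criterion is evaluated on a 3-sample median-filtered copy so a
    single noise spike cannot clip the trace prematurely; the clip index maps
    back to the unfiltered samples.
    """
    sign = _deflection_sign(trace.samples)
    m = trace.samples[window.start:window.end] * sign
    med = medfilt(m, kernel_size=3)
    peak_rel = window.peak_index - window.start
    peak_amp = float(m[peak_rel])
    below = np.nonzero(med[peak_rel + 1:] <= clip_fraction * peak_amp)[0]
    clip_rel = (peak_rel + 1 + int(below[0])) if below.size else (m.size - 1)

    if window.overlap:
        status = EventStatus.REJECTED_OVERLAP
    elif (clip_rel - peak_rel) * trace.dt < min_post_peak_ms:
        status = EventStatus.REJECTED_SHORT
    else:
        status = EventStatus.ACCEPTED

    noise_sd = float(np.std(m[:max(2, peak_rel // 4)])) if peak_rel >= 2 else 0.0
    pre = med[:peak_rel]
    quiet = np.abs(pre) <= max(3.0 * noise_sd, 0.05 * peak_amp)
    onset_rel = int(np.nonzero(quiet)[0][-1]) + 1 if np.any(quiet) else 0

    return EventTrace(
        samples=m[:clip_rel + 1],
        dt=trace.dt,
        peak_index=peak_rel,
        peak_amplitude=peak_amp,
        onset_index=onset_rel,
        clip_index=clip_rel,
        status=status,
        start_index=window.start,
        meta=trace.meta,
    )


def preprocess_trace(trace: RawTrace,
                     baseline_window_ms: float = BASELINE_WINDOW_MS,
                     detect_fraction: float = DETECT_FRACTION,
                     clip_fraction: float = CLIP_FRACTION,
                     min_post_peak_ms: float = MIN_POST_PEAK_MS) -> list[EventTrace]:
    """Full pipeline: baseline removal, detection, clipping, status assignment."""
    flat = remove_baseline(trace, window_ms=baseline_window_ms)
    windows = detect_events(flat, detect_fraction=detect_fraction,
                            clip_fraction=clip_fraction)
    return [
        clip_event(flat, w, clip_fraction=clip_fraction,
                   min_post_peak_ms=min_post_peak_ms)
        for w in windows
    ]


# ---------------------------------------------------------------------------
# Delimited-text I/O

def _parse_header(path: str) -> tuple[dict[str, str], int]:
    header: dict[str, str] = {}
    n_skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_skip += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                header[key.strip()] = val.strip()
    return header, n_skip


def _meta_from_header(header: dict[str, str], fallback_id: str) -> TraceMeta:
    return TraceMeta(
        trace_id=header.get("trace", fallback_id),
        experiment=header.get("experiment", ""),
        cell=header.get("cell", ""),
        holding_mv=float(header.get("holding_mV", -70.0)),
    )


def read_trace_csv(path: str) -> RawTrace:
    """Read one sweep from a delimited-text file.

    Leading ``# key = value`` lines carry metadata (trace, experiment, cell,
    holding_mV, dt_ms).  The body is CSV with either (time, current) columns
    or a single current column with ``dt_ms`` given in the header.
    """
    header, n_skip = _parse_header(path)
    df = pd.read_csv(path, skiprows=n_skip, sep=None, engine="python")
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "time" in cols and "current" in cols:
        t = df["time"].to_numpy(float)
        cur = df["current"].to_numpy(float)
        dt = float(np.median(np.diff(t)))
    elif "current" in cols and "dt_ms" in header:
        cur = df["current"].to_numpy(float)
        dt = float(header["dt_ms"])
    elif len(cols) == 2:
        t = df.iloc[:, 0].to_numpy(float)
        cur = df.iloc[:, 1].to_numpy(float)
        dt = float(np.median(np.diff(t)))
    else:
        raise ValueError(f"{path}: expected (time, current) columns or "
                         "a current column with dt_ms in the header")
    fallback = os.path.splitext(os.path.basename(path))[0]
    return RawTrace(samples=cur, dt=dt, meta=_meta_from_header(header, fallback))


def read_traces_long(path: str,
                     manifest: str | None = None) -> list[RawTrace]:
    """Read a long-format file with columns (trace, time, current).

    An optional manifest TSV (columns: trace, experiment, cell, holding_mV)
    supplies per-trace metadata.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    meta_map: dict[str, TraceMeta] = {}
    if manifest is not None:
        man = pd.read_csv(manifest, sep="\t")
        man.columns = [c.strip().lower() for c in man.columns]
        for _, row in man.iterrows():
            tid = str(row["trace"])
            meta_map[tid] = TraceMeta(
                trace_id=tid,
                experiment=str(row.get("experiment", "")),
                cell=str(row.get("cell", "")),
                holding_mv=float(row.get("holding_mv", -70.0)),
            )
    traces = []
    for tid, sub in df.groupby("trace", sort=True):
        t = sub["time"].to_numpy(float)
        dt = float(np.median(np.diff(t)))
        meta = meta_map.get(str(tid), TraceMeta(trace_id=str(tid)))
        traces.append(RawTrace(samples=sub["current"].to_numpy(float),
                               dt=dt, meta=meta))
    return traces


def read_trace_dir(pattern: str) -> list[RawTrace]:
    """Read every per-sweep CSV matching a glob pattern, sorted by path."""
    return [read_trace_csv(p) for p in sorted(_glob.glob(pattern))]


def write_trace_csv(trace: RawTrace, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# trace = {trace.meta.trace_id}\n")
        fh.write(f"# experiment = {trace.meta.experiment}\n")
        fh.write(f"# cell = {trace.meta.cell}\n")
        fh.write(f"# holding_mV = {trace.meta.holding_mv:g}\n")
        fh.write(f"# dt_ms = {trace.dt:g}\n")
        fh.write("time,current\n")
        for t, c in zip(trace.times(), trace.samples):
            fh.write(f"{t:.6g},{c:.10g}\n")


def write_event_csv(event: EventTrace, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# trace = {event.meta.trace_id}\n")
        fh.write(f"# status = {event.status.value}\n")
        fh.write(f"# peak_pA = {event.peak_amplitude:.6g}\n")
        fh.write(f"# dt_ms = {event.dt:g}\n")
        fh.write("time,current\n")
        for t, c in zip(event.times(), event.samples):
            fh.write(f"{t:.6g},{c:.10g}\n")


def write_event_manifest(events: list[EventTrace], path: str) -> None:
    """TSV manifest: trace id, status, peak amplitude, clip time after peak."""
    with open(path, "w") as fh:
        fh.write("trace\tstatus\tpeak_pA\tclip_ms\n")
        for ev in events:
            fh.write(f"{ev.meta.trace_id}\t{ev.status.value}\t"
                     f"{ev.peak_amplitude:.6g}\t{ev.clip_time:.6g}\n")
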