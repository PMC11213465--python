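"""Ribo-Seq vs RNA-Seq time-course dynamics and footprint stall-site detection.

Peak timing of a ribosome-protected series is compared against the matched
total-RNA series (the lag in hours is the signature of translational
regulation decoupled from transcript abundance), and per-transcript
footprint coverage is scanned for local pile-ups — candidate ribosome
stalling sites — with a robust z-score against the local median/MAD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeCourse",
    "DynamicsCall",
    "CoverageTrack",
    "StallPeak",
    "normalize_counts",
    "timecourse_peak",
    "translational_shift",
    "stall_peak_detect",
    "read_timecourse_tsv",
    "read_bedgraph",
]

#: canonical label -> hours mapping for the hypertrophy time course
LABEL_HOURS = {"sham": 0.0, "3 h": 3.0, "2 d": 48.0, "2 w": 336.0, "4 w": 672.0}


@dataclass
class TimeCourse:
    """Ordered timepoints with replicate expression levels (CPM)."""

    series: str
    labels: list[str]
    hours: list[float]
    levels: list[list[float]]  # one replicate list per timepoint

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("a time course needs >= 2 timepoints")
        if len(self.labels) != len(self.hours) or len(self.labels) != len(self.levels):
            raise ValueError("labels, hours and levels must align")
        if any(b <= a for a, b in zip(self.hours, self.hours[1:])):
            raise ValueError("hours must be strictly increasing")
        if any(v < 0 for reps in self.levels for v in reps):
            raise ValueError("levels must be non-negative")

    def means(self) -> np.ndarray:
        return np.array([float(np.mean(reps)) for reps in self.levels])


@dataclass(frozen=True)
class DynamicsCall:
    ribo_peak_label: str
    ribo_peak_hours: float
    rna_peak_label: str
    rna_peak_hours: float

    @property
    def lag_hours(self) -> float:
        return self.ribo_peak_hours - self.rna_peak_hours


def normalize_counts(raw: float | np.ndarray, library_size: float) -> float | np.ndarray:
    """Counts-per-million: raw * 1e6 / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return np.asarray(raw, dtype=float) * 1e6 / library_size if isinstance(
        raw, (list, np.ndarray)
    ) else raw * 1e6 / library_size


def timecourse_peak(tc: TimeCourse) -> tuple[str, float]:
    """Peak timepoint (label, hours) = argmax of replicate means, ties to earliest."""
    means = tc.means()
    idx = int(np.argmax(means))  # argmax returns the first (earliest) maximum
    return tc.labels[idx], tc.hours[idx]


def translational_shift(ribo: TimeCourse, rna: TimeCourse) -> DynamicsCall:
    """Peak both series on a shared grid and report the ribo-minus-RNA lag."""
    if ribo.hours != rna.hours or ribo.labels != rna.labels:
        raise ValueError("time courses must share an identical timepoint grid")
    rl, rh = timecourse_peak(ribo)
    tl, th = timecourse_peak(rna)
    return DynamicsCall(rl, rh, tl, th)


@dataclass
class CoverageTrack:
    """Per-position ribosome-footprint counts along one transcript."""

    transcript_id: str
    counts: np.ndarray  # integer counts, position 0 = transcript 5' end
    start_codon: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not (0 <= self.start_codon < len(self.counts)):
            raise ValueError("start codon outside the track")


@dataclass(frozen=True)
class StallPeak:
    position: int
    z: float
    fold_over_median: float


def stall_peak_detect(
    track: CoverageTrack,
    flank: int = 25,
    z_min: float = 5.0,
    mad_floor: float = 1.0,
    merge_nt: int = 3,
    start_window_codons: int = 50,
) -> tuple[list[StallPeak], float]:
    """Call footprint pile-ups by robust z against the local median/MAD.

    For each position the background is the +/-flank window excluding the
    position itself (so a lone spike cannot inflate its own baseline):
    z = (count - median) / max(MAD, mad_floor).  Positions with z >= z_min
    are merged within ``merge_nt`` nt keeping the maximum.

    Also returns the start-proximal ratio: mean coverage over the first
    ``start_window_codons`` codons downstream of the start codon divided by
    the mean over the remainder of the track (NaN when the remainder has no
    coverage).
    """
    if flank < 5:
        raise ValueError("flank must be >= 5")
    if z_min <= 0:
        raise ValueError("z_min must be > 0")
    counts = track.counts.astype(float)
    n = len(counts)
    if n < 2 * flank + 1:
        raise ValueError("track shorter than 2*flank + 1")

    candidates: list[StallPeak] = []
    for i in range(n):
        lo, hi = max(0, i - flank), min(n, i + flank + 1)
        window = np.concatenate([counts[lo:i], counts[i + 1 : hi]])
        med = float(np.median(window))
        mad = float(np.median(np.abs(window - med)))
        z = (counts[i] - med) / max(mad, mad_floor)
        if z >= z_min:
            fold = counts[i] / med if med > 0 else float("inf")
            candidates.append(StallPeak(i, float(z), float(fold)))

    peaks: list[StallPeak] = []
    for pk in candidates:  # candidates are position-sorted
        if peaks and pk.position - peaks[-1].position <= merge_nt:
            if pk.z > peaks[-1].z:
                peaks[-1] = pk
        else:
            peaks.append(pk)

    w = 3 * start_window_codons
    prox = counts[track.start_codon : track.start_codon + w]
    rest = np.concatenate(
        [counts[: track.start_codon], counts[track.start_codon + w :]]
    )
    if rest.size == 0 or rest.mean() == 0 or prox.size == 0:
        ratio = float("nan")
    else:
        ratio = float(prox.mean() / rest.mean())
    return peaks, ratio


def read_timecourse_tsv(path, series: str) -> TimeCourse:
    """Load one series from a long TSV (series, timepoint_label, hours, replicate, level)."""
    df = pd.read_csv(path, sep="\t")
    df = df[df["series"] == series]
    if df.empty:
        raise ValueError(f"series {series!r} not found in {path}")
    grid = (
        df[["timepoint_label", "hours"]]
        .drop_duplicates()
        .sort_values("hours")
        .reset_index(drop=True)
    )
    levels = [
        df[df["timepoint_label"] == lbl].sort_values("replicate")["level"].tolist()
        for lbl in grid["timepoint_label"]
    ]
    return TimeCourse(series, grid["timepoint_label"].tolist(),
                      grid["hours"].astype(float).tolist(), levels)


def read_bedgraph(path, starts: dict[str, int]) -> list[CoverageTrack]:
    """Read transcript-relative bedGraph coverage into CoverageTracks.

    ``starts`` maps transcript_id -> start-codon offset.  Positions not
    covered by any interval default to 0.
    """
    per_tx: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            tx, s, e, v = line.split("\t")
            per_tx.setdefault(tx, []).append((int(s), int(e), float(v)))
    tracks = []
    for tx, ivals in per_tx.items():
        length = max(e for _, e, _ in ivals)
        arr = np.zeros(length)
        for s, e, v in ivals:
            arr[s:e] = v
        tracks.append(CoverageTrack(tx, arr.astype(int), starts[tx]))
    return tracks
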