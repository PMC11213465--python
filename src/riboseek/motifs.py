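"""Promoter-motif scanning in cross-species conserved windows.

A position weight matrix (PWM) is scanned over TSS-anchored promoter
sequences with log2-odds scoring against a background base composition.
P-values come from the exact null distribution of the score under the
background model: for narrow matrices the distribution is computed exactly
by sparse dynamic programming over per-position contributions; for wide
matrices the contributions are discretized (default bin 0.01 bits, error
bounded by width x bin) before the same DP.

Conserved promoter windows are detected by ungapped TSS-anchored sliding
identity, and same-named motif hits falling in the same conserved window in
both species are paired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}

# width at which the sparse exact DP gives way to binned DP (4^8 = 65536
# worst-case states is still cheap; beyond that the binned null is used)
_EXACT_WIDTH_MAX = 8
_DEFAULT_BIN = 0.01

__all__ = [
    "PWM",
    "MotifHit",
    "ConservedWindow",
    "ConservedSitePair",
    "build_pwm",
    "scan_sequence",
    "score_pvalue",
    "conserved_window_detect",
    "cross_species_site_pairs",
    "read_pwm",
    "write_hits_bed",
    "reverse_complement",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


@dataclass
class PWM:
    """Position probability matrix over A,C,G,T with a background model."""

    probabilities: np.ndarray  # shape (width, 4), rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    name: str = "motif"
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probabilities.ndim != 2 or self.probabilities.shape[1] != 4:
            raise ValueError("probabilities must have shape (width, 4)")
        if self.width == 0:
            raise ValueError("zero-width PWM")
        if not np.allclose(self.probabilities.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's probabilities must sum to 1")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")
        if (self.probabilities <= 0).any() or (self.background <= 0).any():
            raise ValueError("probabilities must be strictly positive")
        self._dist: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def width(self) -> int:
        return self.probabilities.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """Per-position log2(p / background) score contributions, shape (width, 4)."""
        return np.log2(self.probabilities / self.background[None, :])

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    # -- null distribution ------------------------------------------------

    def score_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """(scores ascending, survival) of the log-odds score under the background.

        survival[i] = P(score >= scores[i]) for a random width-w window drawn
        from the background model.
        """
        if self._dist is None:
            if self.width <= _EXACT_WIDTH_MAX:
                self._dist = _sparse_score_dist(self.log_odds, self.background)
            else:
                self._dist = _binned_score_dist(
                    self.log_odds, self.background, _DEFAULT_BIN
                )
        return self._dist


def _sparse_score_dist(
    lo: np.ndarray, bg: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    # dict-based DP over exact partial sums; keys rounded to 10 decimals to
    # merge float-identical paths
    dist: dict[float, float] = {0.0: 1.0}
    for pos in range(lo.shape[0]):
        nxt: dict[float, float] = {}
        for s, p in dist.items():
            for b in range(4):
                key = round(s + lo[pos, b], 10)
                nxt[key] = nxt.get(key, 0.0) + p * bg[b]
        dist = nxt
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    surv = probs[::-1].cumsum()[::-1]
    return scores, surv


def _binned_score_dist(
    lo: np.ndarray, bg: np.ndarray, bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    q = np.rint(lo / bin_width).astype(np.int64)  # (w, 4) integer bins
    cur = np.ones(1)
    offset = 0  # integer score of cur[0]
    for pos in range(q.shape[0]):
        shifts = q[pos]
        lo_s, hi_s = int(shifts.min()), int(shifts.max())
        nxt = np.zeros(len(cur) + hi_s - lo_s)
        for b in range(4):
            sh = int(shifts[b]) - lo_s
            nxt[sh : sh + len(cur)] += bg[b] * cur
        cur = nxt
        offset += lo_s
    scores = (np.arange(len(cur)) + offset) * bin_width
    surv = cur[::-1].cumsum()[::-1]
    keep = cur > 0
    return scores[keep], surv[keep]


def build_pwm(
    site_counts: np.ndarray,
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
    name: str = "motif",
) -> PWM:
    """Build a PWM from per-position nucleotide counts with pseudocounting.

    p(pos, b) = (count[pos, b] + pseudocount) / (sum(count[pos]) + 4 * pseudocount)
    """
    counts = np.asarray(site_counts, dtype=float)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] == 0:
        raise ValueError("site_counts must have shape (width, 4), width >= 1")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    probs = (counts + pseudocount) / (
        counts.sum(axis=1, keepdims=True) + 4.0 * pseudocount
    )
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PWM(probs, bg, name=name, pseudocount=pseudocount)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    motif: str
    start: int  # 0-based on the forward sequence
    end: int  # exclusive
    strand: str  # "+" or "-"
    score: float  # bits
    p_value: float


def score_pvalue(pwm: PWM, score: float) -> float:
    """P(random background window scores >= score); 1 below min, 0 above max."""
    scores, surv = pwm.score_distribution()
    idx = int(np.searchsorted(scores, score - 1e-9, side="left"))
    if idx >= len(scores):
        return 0.0
    return float(surv[idx])


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(arr.shape, -1, dtype=np.int64)
    for base, i in _CODE.items():
        code[arr == ord(base)] = i
    return code


def _scan_one_strand(pwm: PWM, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """(offsets, scores) for all valid (N-free) windows on the given sequence."""
    w = pwm.width
    code = _encode(seq)
    n = len(code) - w + 1
    if n <= 0:
        return np.empty(0, dtype=int), np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(code, w)
    valid = (windows >= 0).all(axis=1)
    lo = pwm.log_odds
    safe = np.where(windows >= 0, windows, 0)
    scores = lo[np.arange(w)[None, :], safe].sum(axis=1)
    offs = np.nonzero(valid)[0]
    return offs, scores[valid]


def scan_sequence(
    pwm: PWM,
    seq: str,
    p_threshold: float = 1e-4,
    strands: str = "both",
    sequence_id: str = "",
) -> list[MotifHit]:
    """Return motif hits with p-value <= p_threshold, sorted by position.

    Windows containing N are skipped.  Reverse-strand hits are scored on the
    reverse complement and reported in forward-sequence coordinates.  A
    sequence shorter than the matrix width yields an empty result.
    """
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must be in (0, 1]")
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    w = pwm.width
    hits: list[MotifHit] = []

    def emit(offsets: np.ndarray, scores: np.ndarray, strand: str, L: int) -> None:
        for off, sc in zip(offsets, scores):
            p = score_pvalue(pwm, float(sc))
            if p <= p_threshold:
                if strand == "+":
                    start = int(off)
                else:
                    start = L - int(off) - w
                hits.append(
                    MotifHit(sequence_id, pwm.name, start, start + w, strand,
                             float(sc), p)
                )

    offs, scores = _scan_one_strand(pwm, seq)
    emit(offs, scores, "+", len(seq))
    if strands == "both":
        offs_r, scores_r = _scan_one_strand(pwm, reverse_complement(seq))
        emit(offs_r, scores_r, "-", len(seq))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


@dataclass(frozen=True)
class ConservedWindow:
    """Ungapped TSS-anchored conserved region (same coordinates in both species)."""

    start: int  # 0-based, TSS-relative offset into both promoters
    end: int  # exclusive
    identity: float  # percent identity over [start, end)

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError("identity must be a percentage")
        if self.end <= self.start:
            raise ValueError("empty window")


@dataclass(frozen=True)
class ConservedSitePair:
    motif: str
    hit_a: MotifHit
    hit_b: MotifHit
    window: ConservedWindow


def conserved_window_detect(
    seq_a: str,
    seq_b: str,
    window_len: int = 50,
    identity_min: float = 70.0,
    length_tolerance: int = 0,
) -> list[ConservedWindow]:
    """Detect conserved promoter windows by sliding ungapped identity.

    Both promoters are TSS-anchored so the same offset is compared in each
    species.  All length-``window_len`` windows with percent identity >=
    ``identity_min`` are found and overlapping qualifying windows are merged
    into maximal runs; the reported identity is recomputed over the merged
    span.
    """
    if abs(len(seq_a) - len(seq_b)) > length_tolerance:
        raise ValueError("promoter length mismatch beyond tolerance")
    L = min(len(seq_a), len(seq_b))
    if window_len > L:
        raise ValueError("window_len exceeds promoter length")
    a = np.frombuffer(seq_a[:L].upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b[:L].upper().encode(), dtype=np.uint8)
    match = (a == b).astype(float)
    kernel = np.ones(window_len)
    ident = 100.0 * np.convolve(match, kernel, mode="valid") / window_len
    qualifying = np.nonzero(ident >= identity_min)[0]
    windows: list[ConservedWindow] = []
    if qualifying.size == 0:
        return windows
    run_start = int(qualifying[0])
    prev = run_start
    spans: list[tuple[int, int]] = []
    for off in qualifying[1:]:
        off = int(off)
        if off <= prev + window_len:  # overlapping qualifying windows merge
            prev = off
        else:
            spans.append((run_start, prev + window_len))
            run_start = prev = off
    spans.append((run_start, prev + window_len))
    for s, e in spans:
        pid = 100.0 * match[s:e].mean()
        windows.append(ConservedWindow(s, e, float(pid)))
    return windows


def cross_species_site_pairs(
    hits_a: list[MotifHit],
    hits_b: list[MotifHit],
    windows: list[ConservedWindow],
) -> list[ConservedSitePair]:
    """Pair same-named hits from two species inside shared conserved windows.

    A pair is emitted when both hits fall entirely inside the same conserved
    window and their TSS-relative intervals overlap by >= 1 nt.
    """
    pairs = []
    for win in windows:
        in_a = [h for h in hits_a if h.start >= win.start and h.end <= win.end]
        in_b = [h for h in hits_b if h.start >= win.start and h.end <= win.end]
        for ha in in_a:
            for hb in in_b:
                if ha.motif != hb.motif:
                    continue
                if min(ha.end, hb.end) - max(ha.start, hb.start) >= 1:
                    pairs.append(ConservedSitePair(ha.motif, ha, hb, win))
    return pairs


def read_pwm(path, name: str | None = None, background=None) -> PWM:
    """Read a whitespace-delimited probability matrix.

    Accepts width x 4 (positions in rows) or 4 x width layouts; the
    orientation is auto-detected from which axis sums to 1.  Lines starting
    with '#' or '>' are skipped ('>' lines may carry the motif name).
    """
    rows = []
    motif_name = name
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(("#", ">")):
                if line.startswith(">") and motif_name is None:
                    motif_name = line[1:].strip() or None
                continue
            rows.append([float(tok) for tok in line.split()])
    mat = np.array(rows, dtype=float)
    if mat.ndim != 2:
        raise ValueError("malformed PWM file")
    if mat.shape[1] == 4 and np.allclose(mat.sum(axis=1), 1.0, atol=1e-6):
        pass
    elif mat.shape[0] == 4 and np.allclose(mat.sum(axis=0), 1.0, atol=1e-6):
        mat = mat.T
    else:
        raise ValueError("cannot detect PWM orientation (no axis sums to 1)")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PWM(mat, bg, name=motif_name or "motif")


def write_hits_bed(hits: list[MotifHit], path) -> None:
    """Write hits as BED6 (score = bits x 100, truncated)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.start}\t{h.end}\t{h.motif}\t"
                f"{int(h.score * 100)}\t{h.strand}\n"
            )
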