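"""Windowed internal tetranucleotide-signature correlation analysis.

A genome fragment is cut into overlapping windows (default 300 bp, step
100 bp). For each window the observed counts of all 256 tetranucleotides
are compared with the expectation of a maximal-order Markov model built
from the window's own trinucleotide and dinucleotide counts,

    E[N(n1 n2 n3 n4)] = N(n1 n2 n3) * N(n2 n3 n4) / N(n2 n3),

with approximate variance

    var = E * (N(n2 n3) - N(n1 n2 n3)) * (N(n2 n3) - N(n2 n3 n4)) / N(n2 n3)^2,

and the deviations are expressed as z-scores Z = (N - E) / sqrt(var).
The Pearson correlation between two windows' 256-component z-score
vectors measures whether they share a genomic signature; the full
pairwise matrix exposes compositionally exogenous regions (e.g. laterally
transferred segments) as blocks of low correlation.

Two strand-handling modes are provided. ``per_window_rc`` (default)
counts each window together with its own reverse complement, the
standard strand-symmetric signature. ``whole_sequence_rc`` appends the
reverse complement of the whole sequence before windowing, reproducing
the literal extend-then-cut procedure of older scripts (every window
reappears mirrored, and windows may span the junction).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import FeatureInterval, SequenceRecord, reverse_complement

log = logging.getLogger(__name__)

EXTENSION_MODES = ("per_window_rc", "whole_sequence_rc")

#: Windows whose z-vector standard deviation falls below this are degenerate.
_DEGENERATE_STD = 1e-12

#: Default minimum number of flagged windows per called region.
DEFAULT_MIN_RUN = 8
#: Default maximum unflagged gap (windows) bridged within one region.
DEFAULT_MAX_GAP = 8
#: Default half-width (windows) of the moving-average score smoother.
DEFAULT_SMOOTH_HALFWIDTH = 2
#: Minimum two-level separation of window scores required before any
#: region is called under the automatic threshold (null guard).
DEFAULT_MIN_SEPARATION = 0.07

# base -> 2-bit code lookup; invalid/ambiguous bases map to -1 and any
# k-mer containing them is skipped.
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_KMER_ALPHABET = "ACGT"


def kmer_index(kmer: str) -> int:
    """Canonical index of a k-mer (A=0, C=1, G=2, T=3, big-endian)."""
    idx = 0
    for ch in kmer:
        idx = idx * 4 + _KMER_ALPHABET.index(ch)
    return idx


def kmer_string(index: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_KMER_ALPHABET[index % 4])
        index //= 4
    return "".join(reversed(out))


@dataclass(frozen=True)
class WindowSpec:
    """Windowing parameters.

    window_length
        Window size in bases (default 300).
    step
        Distance between consecutive window starts (default 100).
    extension_mode
        Strand handling; see module docstring.
    """

    window_length: int = 300
    step: int = 100
    extension_mode: str = "per_window_rc"

    def __post_init__(self) -> None:
        if self.window_length < 7:
            raise ValueError("window_length must be >= 7")
        if self.step < 1 or self.step > self.window_length:
            raise ValueError("require 1 <= step <= window_length")
        if self.extension_mode not in EXTENSION_MODES:
            raise ValueError(
                f"extension_mode must be one of {EXTENSION_MODES}, got {self.extension_mode!r}"
            )


@dataclass(frozen=True)
class Window:
    """One window; start/end are 1-based inclusive on the windowed text
    (the original sequence, or its reverse-complement extension in
    ``whole_sequence_rc`` mode)."""

    seq_id: str
    index: int
    start: int
    end: int
    sequence: str


@dataclass
class WindowSignature:
    """Observed k-mer counts, Markov expectations and z-scores for one window."""

    window: Window
    n4: np.ndarray
    n3: np.ndarray
    n2: np.ndarray
    expected: np.ndarray
    variance: np.ndarray
    z: np.ndarray


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise Pearson matrix over a fragment's windows.

    ``mean_r``/``sd_r`` summarise the strict upper triangle (diagonal
    excluded; sample SD). ``seq_length`` is the original sequence length,
    used to map window coordinates back from the extended text in
    ``whole_sequence_rc`` mode.
    """

    seq_id: str
    windows: list[Window]
    r: np.ndarray
    mean_r: float
    sd_r: float
    extension_mode: str
    seq_length: int
    signatures: list[WindowSignature] = field(default_factory=list, repr=False)


@dataclass(frozen=True)
class LowCorrelationRegion:
    """A run of windows whose mean correlation against the rest of the
    fragment falls below threshold; coordinates are on the original
    sequence, 1-based inclusive."""

    seq_id: str
    start: int
    end: int
    mean_r_inside: float
    mean_r_outside: float
    first_window: int
    last_window: int


def fragment_sequence(record: SequenceRecord, spec: WindowSpec) -> list[Window]:
    """Cut a sequence into overlapping windows from its beginning.

    Windows start at 1, 1+step, 1+2*step, ...; a trailing stretch shorter
    than one window is dropped. In ``whole_sequence_rc`` mode the windows
    tile the concatenation of the sequence and its reverse complement.
    """
    text = record.seq
    if spec.extension_mode == "whole_sequence_rc":
        text = text + reverse_complement(text)
    if len(text) < spec.window_length:
        raise ValueError(
            f"sequence {record.id!r} too short: {len(text)} bases after any "
            f"extension < window_length {spec.window_length}"
        )
    windows = []
    for index, start0 in enumerate(range(0, len(text) - spec.window_length + 1, spec.step)):
        windows.append(
            Window(
                seq_id=record.id,
                index=index,
                start=start0 + 1,
                end=start0 + spec.window_length,
                sequence=text[start0 : start0 + spec.window_length],
            )
        )
    return windows


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _count_single_strand(seq: str, k: int) -> np.ndarray:
    codes = _encode(seq)
    m = len(codes) - k + 1
    if m <= 0:
        return np.zeros(4**k, dtype=np.int64)
    idx = np.zeros(m, dtype=np.int64)
    ok = np.ones(m, dtype=bool)
    for j in range(k):
        c = codes[j : j + m]
        ok &= c >= 0
        idx = idx * 4 + np.where(c >= 0, c, 0)
    return np.bincount(idx[ok], minlength=4**k)


def count_kmers(seq: str, k: int, extension_mode: str | None = None) -> np.ndarray:
    """Count overlapping k-mers (stride 1) in canonical A<C<G<T order.

    In ``per_window_rc`` mode the sequence and its reverse complement are
    counted as two separate strands (no k-mer spans the junction) and the
    counts summed. k-mers containing ambiguous bases are skipped.
    """
    if k not in (2, 3, 4):
        raise ValueError(f"k must be 2, 3 or 4, got {k}")
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    counts = _count_single_strand(seq, k)
    if extension_mode == "per_window_rc":
        counts = counts + _count_single_strand(reverse_complement(seq), k)
    return counts


# index bookkeeping for the 256 tetranucleotides n1n2n3n4:
# leading trinucleotide n1n2n3 = t >> 2, trailing trinucleotide
# n2n3n4 = t & 63, core dinucleotide n2n3 = (t >> 2) & 15.
_T = np.arange(256)
_LEAD3 = _T >> 2
_TRAIL3 = _T & 63
_CORE2 = (_T >> 2) & 15


def expected_counts(n3: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """Maximal-order Markov expectation for all 256 tetranucleotides.

    E = N(n1n2n3) * N(n2n3n4) / N(n2n3); E = 0 where the core
    dinucleotide count is zero.
    """
    n3 = np.asarray(n3, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if n3.shape != (64,) or n2.shape != (16,):
        raise ValueError("expected 64 trinucleotide and 16 dinucleotide counts")
    core = n2[_CORE2]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(core > 0, n3[_LEAD3] * n3[_TRAIL3] / np.where(core > 0, core, 1.0), 0.0)
    return e


def z_scores(n4: np.ndarray, n3: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """z-score of each tetranucleotide count against its Markov expectation.

    Z = (N - E)/sqrt(var); Z = 0 wherever var = 0 or E = 0, keeping the
    vector finite and comparable across windows.
    """
    n4 = np.asarray(n4, dtype=float)
    e = expected_counts(n3, n2)
    n3 = np.asarray(n3, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    core = n2[_CORE2]
    safe_core = np.where(core > 0, core, 1.0)
    var = e * (core - n3[_LEAD3]) * (core - n3[_TRAIL3]) / safe_core**2
    ok = (var > 0) & (e > 0)
    z = np.zeros(256)
    z[ok] = (n4[ok] - e[ok]) / np.sqrt(var[ok])
    return z


def window_signature(window: Window, extension_mode: str = "per_window_rc") -> WindowSignature:
    """Compute counts, expectations and z-scores for one window.

    In ``whole_sequence_rc`` mode each window is counted single-strand
    (the reverse-complement copy already exists in the extended text).
    """
    mode = extension_mode if extension_mode == "per_window_rc" else None
    n4 = count_kmers(window.sequence, 4, mode)
    n3 = count_kmers(window.sequence, 3, mode)
    n2 = count_kmers(window.sequence, 2, mode)
    e = expected_counts(n3, n2)
    core = n2[_CORE2].astype(float)
    safe_core = np.where(core > 0, core, 1.0)
    var = e * (core - n3[_LEAD3]) * (core - n3[_TRAIL3]) / safe_core**2
    z = z_scores(n4, n3, n2)
    return WindowSignature(window=window, n4=n4, n3=n3, n2=n2, expected=e, variance=var, z=z)


def pearson(z1: np.ndarray, z2: np.ndarray) -> float:
    """Pearson product-moment correlation over the 256 components.

    A zero-variance (degenerate) vector correlates as 0 with a warning
    rather than propagating NaN.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    s1, s2 = z1.std(), z2.std()
    if s1 < _DEGENERATE_STD or s2 < _DEGENERATE_STD:
        warnings.warn("degenerate (zero-variance) z-vector; correlation set to 0")
        return 0.0
    c1 = z1 - z1.mean()
    c2 = z2 - z2.mean()
    return float(np.clip(np.dot(c1, c2) / (np.linalg.norm(c1) * np.linalg.norm(c2)), -1.0, 1.0))


def correlation_matrix(record: SequenceRecord, spec: WindowSpec | None = None) -> CorrelationMatrix:
    """Pairwise Pearson matrix of window z-score vectors for one fragment."""
    spec = spec or WindowSpec()
    windows = fragment_sequence(record, spec)
    if len(windows) < 2:
        raise ValueError(
            f"sequence {record.id!r} admits only {len(windows)} window(s); need >= 2"
        )
    sigs = [window_signature(w, spec.extension_mode) for w in windows]
    z = np.array([s.z for s in sigs])
    centred = z - z.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    degenerate = norms < _DEGENERATE_STD
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} degenerate window(s) in {record.id!r}; "
            "their correlations are set to 0"
        )
    safe = np.where(degenerate, 1.0, norms)
    unit = centred / safe[:, None]
    r = np.clip(unit @ unit.T, -1.0, 1.0)
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    iu = np.triu_indices(len(windows), k=1)
    off = r[iu]
    mean_r = float(off.mean())
    sd_r = float(off.std(ddof=1)) if off.size > 1 else 0.0
    return CorrelationMatrix(
        seq_id=record.id,
        windows=windows,
        r=r,
        mean_r=mean_r,
        sd_r=sd_r,
        extension_mode=spec.extension_mode,
        seq_length=len(record.seq),
        signatures=sigs,
    )


def _original_span(start: int, end: int, seq_length: int) -> tuple[int, int]:
    """Map a window span on the extended text back to original coordinates.

    In ``whole_sequence_rc`` mode positions beyond ``seq_length`` mirror
    back onto the original sequence; junction-spanning windows clamp at
    the 3' end.
    """
    L = seq_length
    if end <= L:
        return start, end
    if start > L:
        return 2 * L - end + 1, 2 * L - start + 1
    return min(start, 2 * L - end + 1), L


def window_scores(
    matrix: CorrelationMatrix, mask: list[FeatureInterval] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window mean correlation against all other unmasked windows.

    Returns ``(scores, masked)``; masked windows (those overlapping a
    mask interval on this sequence) have NaN scores and are excluded
    from everyone else's mean.
    """
    n = len(matrix.windows)
    masked = np.zeros(n, dtype=bool)
    if mask:
        relevant = [iv for iv in mask if iv.seq_id == matrix.seq_id]
        for i, w in enumerate(matrix.windows):
            s, e = _original_span(w.start, w.end, matrix.seq_length)
            if any(iv.overlaps(s, e) for iv in relevant):
                masked[i] = True
    if masked.all():
        raise ValueError(f"all windows of {matrix.seq_id!r} are masked")
    keep = ~masked
    n_keep = int(keep.sum())
    if n_keep < 2:
        raise ValueError(f"fewer than 2 unmasked windows in {matrix.seq_id!r}")
    scores = np.full(n, np.nan)
    # row sums over unmasked columns; subtract own diagonal (1.0)
    sums = matrix.r[:, keep].sum(axis=1)
    scores[keep] = (sums[keep] - 1.0) / (n_keep - 1)
    return scores, masked


def _smooth_scores(scores: np.ndarray, halfwidth: int) -> np.ndarray:
    """NaN-aware moving average of the per-window scores."""
    if halfwidth <= 0:
        return scores.copy()
    n = len(scores)
    out = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i - halfwidth), min(n, i + halfwidth + 1)
        chunk = scores[lo:hi]
        if np.isfinite(chunk).any():
            out[i] = np.nanmean(chunk)
    return out


def two_level_threshold(scores: np.ndarray) -> tuple[float, float]:
    """Two-means split of window scores.

    Returns ``(threshold, separation)`` where the threshold is the
    midpoint of the two cluster means at convergence and the separation
    is the distance between them. Used to place the flagging threshold
    between the background signature level and a putative low-
    correlation block without assuming absolute correlation levels.
    """
    x = scores[np.isfinite(scores)]
    if x.size < 2:
        raise ValueError("need at least 2 finite scores")
    t = float(np.median(x))
    for _ in range(100):
        lo, hi = x[x < t], x[x >= t]
        if lo.size == 0 or hi.size == 0:
            return t, 0.0
        new_t = (lo.mean() + hi.mean()) / 2.0
        if abs(new_t - t) < 1e-12:
            break
        t = new_t
    lo, hi = x[x < t], x[x >= t]
    sep = float(hi.mean() - lo.mean()) if lo.size and hi.size else 0.0
    return float(t), sep


def _refine_run(
    raw: np.ndarray, a: int, b: int, lo: int, hi: int, halfwidth: int = 15
) -> tuple[int, int]:
    """Refine region boundaries by a three-segment constant fit.

    Chooses the (start, end) pair near the coarse run [a, b] minimising
    the residual sum of squares of an outside/inside/outside piecewise-
    constant model of the raw scores over the context [lo, hi).
    """
    x = raw[lo:hi].copy()
    finite = np.isfinite(x)
    if not finite.all():
        x[~finite] = np.nanmedian(x)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i: int, j: int) -> float:
        if j <= i:
            return 0.0
        s = c1[j] - c1[i]
        return float(c2[j] - c2[i] - s * s / (j - i))

    best = np.inf
    ba, bb = a, b
    n = len(x)
    for aa in range(max(lo + 1, a - halfwidth), min(b, a + halfwidth) + 1):
        for bb_ in range(max(aa + 1, b - halfwidth), min(hi - 2, b + halfwidth) + 1):
            i, j = aa - lo, bb_ + 1 - lo
            v = sse(0, i) + sse(i, j) + sse(j, n)
            if v < best:
                best, ba, bb = v, aa, bb_
    return ba, bb


def call_low_correlation_regions(
    matrix: CorrelationMatrix,
    threshold: float | None = None,
    min_run: int = DEFAULT_MIN_RUN,
    mask: list[FeatureInterval] | None = None,
    *,
    max_gap: int = DEFAULT_MAX_GAP,
    smooth_halfwidth: int = DEFAULT_SMOOTH_HALFWIDTH,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    refine: bool = True,
) -> list[LowCorrelationRegion]:
    """Call compositionally exogenous regions from a correlation matrix.

    Each window is scored by its mean correlation against all other
    unmasked windows; scores are lightly smoothed and windows falling
    below ``threshold`` are flagged. Flagged windows separated by at
    most ``max_gap`` unflagged ones form a candidate region; regions
    containing at least ``min_run`` flagged windows are kept, their
    boundaries optionally sharpened by a piecewise-constant changepoint
    fit on the unsmoothed scores, and reported in original-sequence
    coordinates. Masked windows (e.g. rRNA) take no part in scoring or
    calling.

    With ``threshold=None`` the threshold is placed automatically
    between the two score levels found by a two-means split, and
    nothing is called when the two levels are closer than
    ``min_separation`` (the homogeneous-fragment guard).
    """
    if threshold is not None and not (-1.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (-1, 1), got {threshold}")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    scores, masked = window_scores(matrix, mask)
    keep = ~masked
    smoothed = _smooth_scores(np.where(keep, scores, np.nan), smooth_halfwidth)
    if threshold is None:
        threshold, separation = two_level_threshold(smoothed)
        if separation < min_separation:
            return []
    flagged_idx = np.where(keep & (smoothed < threshold))[0]
    if flagged_idx.size == 0:
        return []
    clusters: list[list[int]] = [[int(flagged_idx[0])]]
    for f in flagged_idx[1:]:
        if f - clusters[-1][-1] <= max_gap + 1:
            clusters[-1].append(int(f))
        else:
            clusters.append([int(f)])
    runs = [(c[0], c[-1]) for c in clusters if len(c) >= min_run]
    regions: list[LowCorrelationRegion] = []
    n = len(matrix.windows)
    for k, (a, b) in enumerate(runs):
        if refine:
            lo = runs[k - 1][1] + 1 if k > 0 else 0
            hi = runs[k + 1][0] if k + 1 < len(runs) else n
            a, b = _refine_run(np.where(keep, scores, np.nan), a, b, lo, hi)
        inside = keep.copy()
        inside[: a] = False
        inside[b + 1 :] = False
        outside = keep & ~inside
        start, _ = _original_span(
            matrix.windows[a].start, matrix.windows[a].end, matrix.seq_length
        )
        _, end = _original_span(
            matrix.windows[b].start, matrix.windows[b].end, matrix.seq_length
        )
        regions.append(
            LowCorrelationRegion(
                seq_id=matrix.seq_id,
                start=min(start, end),
                end=max(start, end),
                mean_r_inside=float(np.nanmean(scores[inside])) if inside.any() else float("nan"),
                mean_r_outside=float(np.nanmean(scores[outside])) if outside.any() else float("nan"),
                first_window=int(a),
                last_window=int(b),
            )
        )
    return regions
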