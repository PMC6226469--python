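"""Long-read validation of predicted chromosome-end extensions.

For a category-1 extension (one whose label sequence aligned to homologous
reference sequence elsewhere) a chimeric chromosome end is *predicted* by
concatenating the homologous origin segment, an estimated gap of N's, and the
reference terminal segment, all in tip-first orientation (the sequence starts
at the chromosome tip and reads inward).  Long reads spanning the terminus
are then compared against the prediction with an exact k-mer dotplot followed
by collinear chaining — a deliberately aligner-free formalisation of reading
a dotplot by eye.  The same self-dotplot machinery estimates tandem-repeat
unit length and copy number at termini extended by duplication of their own
terminal sequence (off-main-diagonal chain offsets are multiples of the unit
length; their approximate GCD is the unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import reverse_complement

from .terminus import TerminusCall

__all__ = [
    "PredictedExtension",
    "ChainedSegment",
    "TandemEstimate",
    "ValidationVerdict",
    "build_prediction",
    "kmer_dotplot",
    "chain_matches",
    "estimate_tandem",
    "validate_extension",
]


@dataclass
class PredictedExtension:
    """Predicted chimeric chromosome end, tip-first: origin segment + N-gap
    + reference terminal segment."""

    terminus: str
    sequence: str
    origin_len: int
    gap_len: int
    terminal_len: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert len(self.sequence) == self.origin_len + self.gap_len + self.terminal_len


@dataclass
class ChainedSegment:
    """A chained run of collinear k-mer matches."""

    x_start: int
    x_end: int
    y_start: int
    y_end: int
    orientation: str
    diagonal: float  # mean y-x (+) or y+x (-)
    n_points: int

    @property
    def length(self) -> int:
        return self.x_end - self.x_start


@dataclass
class TandemEstimate:
    unit_len: float
    copies: int
    support: int


@dataclass
class ValidationVerdict:
    confirmed: bool
    covered_fraction: float
    internal_deletion: bool
    largest_internal_gap: float


# ---------------------------------------------------------------------------
# prediction


def _tip_first_terminal(seq: str, arm: str, length: int) -> str:
    return reverse_complement(seq[-length:]) if arm == "q" else seq[:length]


def build_prediction(
    reference: Mapping[str, str],
    call: TerminusCall,
    gap_len: int | None = None,
    terminal_len: int = 100_000,
) -> PredictedExtension:
    """Predicted chimeric end for a category-1 call.

    The top origin's matched span is extracted from the reference in
    tip-first orientation relative to the target terminus and joined to the
    target's reference terminal segment with ``gap_len`` N's (default: the
    called extension length minus the origin span, floored at zero).
    """
    if call.category != 1 or not call.origins:
        raise ValueError(
            f"no predicted sequence for {call.chrom}{call.arm}: not a category-1 call"
        )
    origin = call.origins[0]
    lo, hi = int(origin.span[0]), int(np.ceil(origin.span[1]))
    seg = reference[origin.chrom][lo:hi]
    # Orient the origin segment tip-first.  The extension labels were aligned
    # reading junction -> tip, so '+' means the donor runs with increasing
    # reference coordinate in that reading and must be flipped to read
    # tip -> junction; '-' is already tip-first.  (For a p-arm donor this
    # reduces to keeping the forward strand, for a q-arm donor to flipping.)
    if origin.orientation == "+":
        seg = reverse_complement(seg)
    if gap_len is None:
        gap_len = max(0, int(round(call.extension_len)) - len(seg))
    term = _tip_first_terminal(reference[call.chrom], call.arm, terminal_len)
    return PredictedExtension(
        terminus=f"{call.chrom}{call.arm}",
        sequence=seg + "N" * gap_len + term,
        origin_len=len(seg),
        gap_len=gap_len,
        terminal_len=len(term),
        provenance={"origin": (origin.chrom, origin.arm, lo, hi, origin.orientation)},
    )


# ---------------------------------------------------------------------------
# dotplot + chaining


def kmer_dotplot(
    seq_x: str, seq_y: str, k: int = 16
) -> dict[str, np.ndarray]:
    """All exact shared k-mers between two sequences.

    Returns ``{'+': points, '-': points}`` where each points array has rows
    (x, y) of k-mer start coordinates; reverse-orientation matches use
    reverse-complement k-mers with y reported on forward coordinates.
    k-mers containing N are ignored.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    out = {"+": np.empty((0, 2), dtype=np.int64), "-": np.empty((0, 2), dtype=np.int64)}
    if len(seq_x) < k or len(seq_y) < k:
        return out
    index: dict[str, list[int]] = {}
    sx = seq_x.upper()
    for i in range(len(sx) - k + 1):
        km = sx[i : i + k]
        if "N" in km:
            continue
        index.setdefault(km, []).append(i)
    sy = seq_y.upper()
    fwd, rev = [], []
    for j in range(len(sy) - k + 1):
        km = sy[j : j + k]
        if "N" in km:
            continue
        for i in index.get(km, ()):
            fwd.append((i, j))
        for i in index.get(reverse_complement(km), ()):
            rev.append((i, j))
    if fwd:
        out["+"] = np.array(fwd, dtype=np.int64)
    if rev:
        out["-"] = np.array(rev, dtype=np.int64)
    return out


def chain_matches(
    points: Mapping[str, np.ndarray] | np.ndarray,
    max_gap: float = 500.0,
    min_len: float = 1000.0,
    band_tol: float = 50.0,
    k: int = 16,
) -> list[ChainedSegment]:
    """Greedy collinear chaining of dotplot points per diagonal band.

    Points are grouped by diagonal (y-x for '+', y+x for '-') with
    single-linkage tolerance ``band_tol`` (indel drift moves the diagonal
    gradually), then split where consecutive x-gaps exceed ``max_gap``.
    Segments shorter than ``min_len`` are dropped.
    """
    if isinstance(points, np.ndarray):
        points = {"+": points}
    segments: list[ChainedSegment] = []
    for orient, pts in points.items():
        if pts is None or len(pts) == 0:
            continue
        x, y = pts[:, 0].astype(float), pts[:, 1].astype(float)
        diag = y - x if orient == "+" else y + x
        order = np.lexsort((x, diag))
        x, y, diag = x[order], y[order], diag[order]
        # single-linkage diagonal bands
        new_band = np.concatenate([[True], np.diff(diag) > band_tol])
        band_id = np.cumsum(new_band)
        for b in np.unique(band_id):
            sel = band_id == b
            bx, by, bd = x[sel], y[sel], diag[sel]
            o2 = np.argsort(bx)
            bx, by, bd = bx[o2], by[o2], bd[o2]
            cut = np.concatenate([[True], np.diff(bx) > max_gap])
            seg_id = np.cumsum(cut)
            for s in np.unique(seg_id):
                ss = seg_id == s
                sx_, sy_, sd_ = bx[ss], by[ss], bd[ss]
                length = sx_.max() - sx_.min() + k
                if length < min_len:
                    continue
                segments.append(
                    ChainedSegment(
                        int(sx_.min()), int(sx_.max() + k),
                        int(sy_.min()), int(sy_.max() + k),
                        orient, float(sd_.mean()), int(ss.sum()),
                    )
                )
    segments.sort(key=lambda s: (-s.length, s.x_start))
    return segments


# ---------------------------------------------------------------------------
# tandem-repeat estimation


def _approx_gcd(offsets: Sequence[float], tol: float) -> float:
    """Greatest common approximate divisor of chain offsets (relative
    tolerance ``tol``); multiples of the tandem unit length reduce to it."""
    offs = sorted(float(o) for o in offsets)
    candidates = sorted({o for o in offs} | {abs(a - b) for a in offs for b in offs if abs(a - b) > tol * max(offs)})
    for g in candidates:
        if g <= 0:
            continue
        if all(abs(o / g - round(o / g)) * g <= tol * o for o in offs):
            # refine: average the per-offset unit estimates
            units = [o / round(o / g) for o in offs]
            return float(np.mean(units))
    return offs[0]


def estimate_tandem(
    read: str,
    window: int = 50_000,
    k: int = 16,
    max_gap: float = 500.0,
    min_len: float = 1000.0,
    band_tol: float = 50.0,
    gcd_tol: float = 0.05,
) -> TandemEstimate:
    """Tandem-repeat unit length and copy number in a read's terminal window.

    Self-dotplot of the last ``window`` bp (terminal reads carry the
    chromosome tip at their end); forward off-main-diagonal chain offsets are
    collected and their approximate GCD is the unit length; copies = 1 +
    round(max offset / unit).  A non-repetitive window yields copies 1.
    """
    win = read[-window:] if window < len(read) else read
    pts = kmer_dotplot(win, win, k)
    segs = chain_matches({"+": pts["+"]}, max_gap, min_len, band_tol, k)
    offsets = sorted(
        {abs(s.diagonal) for s in segs if abs(s.diagonal) > max(band_tol, k)}
    )
    # deduplicate offsets of the same repeat separation (upper/lower triangle)
    merged: list[float] = []
    for o in offsets:
        if merged and abs(o - merged[-1]) <= band_tol * 2:
            continue
        merged.append(o)
    if not merged:
        return TandemEstimate(unit_len=0.0, copies=1, support=0)
    unit = _approx_gcd(merged, gcd_tol)
    copies = 1 + int(round(max(merged) / unit))
    return TandemEstimate(unit_len=unit, copies=copies, support=len(merged))


# ---------------------------------------------------------------------------
# read-vs-prediction validation


def _union_length(intervals: list[tuple[float, float]]) -> float:
    total, last = 0.0, None
    for s, e in sorted(intervals):
        if last is None or s > last:
            total += e - s
            last = e
        elif e > last:
            total += e - last
            last = e
    return total


def validate_extension(
    read: str,
    prediction: PredictedExtension,
    min_extension_coverage: float = 0.5,
    k: int = 16,
    max_gap: float = 500.0,
    min_len: float = 1000.0,
    deletion_threshold: float = 5000.0,
) -> ValidationVerdict:
    """Does a long read support the predicted chimeric end?

    The read is chained against the prediction (both orientations); the
    covered fraction is chained bp within the origin (extension) part divided
    by the origin length.  Confirmed when the fraction reaches
    ``min_extension_coverage``.  An uncovered internal run longer than
    ``deletion_threshold`` inside the covered origin region is reported as an
    internal deletion (extension more complicated than a simple duplication).
    """
    pts = kmer_dotplot(prediction.sequence, read, k)
    segs = chain_matches(pts, max_gap, min_len, k=k)
    olen = prediction.origin_len
    covered = [
        (max(0.0, s.x_start), min(float(olen), s.x_end))
        for s in segs
        if s.x_start < olen and s.x_end > 0
    ]
    covered = [(s, e) for s, e in covered if e > s]
    frac = _union_length(covered) / olen if olen else 0.0
    internal = False
    largest = 0.0
    if covered:
        lo = min(s for s, _ in covered)
        hi = max(e for _, e in covered)
        merged: list[tuple[float, float]] = []
        for s, e in sorted(covered):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        for (s0, e0), (s1, e1) in zip(merged[:-1], merged[1:]):
            largest = max(largest, s1 - e0)
        internal = largest > deletion_threshold and lo < hi
    return ValidationVerdict(
        confirmed=frac >= min_extension_coverage,
        covered_fraction=frac,
        internal_deletion=internal,
        largest_internal_gap=largest,
    )
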