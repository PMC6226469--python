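"""Label-map primitives: in-silico digestion, label merging, spacing statistics,
and a CMAP-dialect reader/writer.

An optical ("Bionano-style") label map is the ordered list of nicking-enzyme
recognition-site positions on a molecule, contig or chromosome, together with
the molecule length.  It is the optical-mapping analogue of a sequence: all
downstream alignment and chromosome-end calling operates on label maps only.

Coordinates are 0-based internally.  The CMAP dialect on disk is 1-based, the
convention in the wild; conversion happens at the I/O boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import reverse_complement
from intervaltree import IntervalTree

__all__ = [
    "LabelMap",
    "LabelStats",
    "digest",
    "merge_labels",
    "interlabel_stats",
    "read_cmap",
    "write_cmap",
]

# IUPAC nucleotide codes expanded to character classes (exact match, no
# mismatches: degeneracy in the motif only).
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class CmapParseError(ValueError):
    """Malformed CMAP-dialect file; message carries the offending line number."""


@dataclass
class LabelMap:
    """Ordered label positions on one molecule.

    Parameters
    ----------
    id : str
        Map identifier (contig/chromosome name).
    length : float
        Molecule length in bp.
    labels : ndarray
        Strictly increasing label positions, 0-based bp.
    meta : dict
        Free-form provenance (source name, arm orientation flag, ...).
    """

    id: str
    length: float
    labels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        if self.labels.size:
            if self.labels.min() < 0 or self.labels.max() >= self.length:
                raise ValueError(
                    f"map {self.id!r}: labels must lie in [0, length)"
                )
            if np.any(np.diff(self.labels) <= 0):
                raise ValueError(f"map {self.id!r}: labels must be strictly increasing")

    @property
    def n_labels(self) -> int:
        return int(self.labels.size)

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, LabelMap):
            return NotImplemented
        return (
            self.id == other.id
            and self.length == other.length
            and self.labels.size == other.labels.size
            and bool(np.all(self.labels == other.labels))
        )


@dataclass
class LabelStats:
    """Adjacent-label spacing statistics, in kb (population SD)."""

    mean_interval: float
    sd_interval: float
    n_intervals: int
    excluded_gap_intervals: int


def _motif_pattern(motif: str) -> re.Pattern:
    parts = []
    for ch in motif.upper():
        if ch not in _IUPAC:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in motif {motif!r}")
        cls = _IUPAC[ch]
        parts.append(cls if len(cls) == 1 else f"[{cls}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=" + "".join(parts) + ")")


def digest(sequence: str, motif: str) -> np.ndarray:
    """Positions of every occurrence of ``motif`` or its reverse complement.

    Both strands are scanned; positions are the 0-based start of the site on
    the forward strand, sorted and deduplicated.  An empty sequence yields an
    empty array.
    """
    if len(motif) < 4:
        raise ValueError("motif must be at least 4 bp")
    fwd = _motif_pattern(motif)
    rev = _motif_pattern(reverse_complement(motif))
    seq = str(sequence).upper()
    hits = {m.start() for m in fwd.finditer(seq)}
    hits.update(m.start() for m in rev.finditer(seq))
    return np.array(sorted(hits), dtype=float)


def merge_labels(labels: Sequence[float], merge_distance: float = 450.0) -> np.ndarray:
    """Collapse transitive clusters of nearby labels to their centroid.

    Labels whose adjacent spacing is <= ``merge_distance`` form a chain and are
    replaced by the cluster centroid, rounded half-up to an integer bp.  The
    450 bp default reflects the pre-alignment merging applied to reference
    label maps before realignment.  Idempotent for any already-merged input.
    """
    arr = np.asarray(labels, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any(np.diff(arr) < 0):
        raise ValueError("labels must be sorted")
    out = []
    start = 0
    for i in range(1, arr.size + 1):
        if i == arr.size or arr[i] - arr[i - 1] > merge_distance:
            out.append(np.floor(arr[start:i].mean() + 0.5))
            start = i
    return np.array(out, dtype=float)


def interlabel_stats(
    labels: Sequence[float] | LabelMap,
    gap_intervals: Iterable[tuple[float, float]] = (),
) -> LabelStats:
    """Mean and population SD of adjacent-label distances, in kb.

    Any adjacent pair whose spanned interval intersects a gap interval
    (half-open ``[start, end)``, e.g. reference N-gaps from a BED file) is
    excluded, because spacings across unknown sequence are not informative.
    """
    if isinstance(labels, LabelMap):
        labels = labels.labels
    arr = np.asarray(labels, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 labels")
    tree = IntervalTree()
    for s, e in gap_intervals:
        if e > s:
            tree.addi(s, e)
    keep = []
    excluded = 0
    for a, b in zip(arr[:-1], arr[1:]):
        if tree.overlap(a, b):
            excluded += 1
        else:
            keep.append(b - a)
    if not keep:
        raise ValueError("no usable adjacent-label pairs after gap exclusion")
    d = np.array(keep) / 1000.0
    return LabelStats(
        mean_interval=float(d.mean()),
        sd_interval=float(d.std()),  # population SD, fixed for reproducibility
        n_intervals=len(keep),
        excluded_gap_intervals=excluded,
    )


# ---------------------------------------------------------------------------
# CMAP dialect
#
# Tab-separated, one row per label plus a terminal channel-0 row carrying the
# map length (so empty maps round-trip).  Positions on disk are 1-based.

_CMAP_HEADER = [
    "#\tCMAP dialect (teloforge)",
    "#h\tCMapId\tContigLength\tNumSites\tSiteID\tLabelChannel\tPosition",
    "#f\tstring\tfloat\tint\tint\tint\tfloat",
]


def write_cmap(maps: Iterable[LabelMap], path: str | Path) -> None:
    """Write label maps in the CMAP dialect (1-based positions, 0.1 bp grid)."""
    lines = list(_CMAP_HEADER)
    for m in maps:
        n = m.n_labels
        for i, pos in enumerate(m.labels, start=1):
            lines.append(
                f"{m.id}\t{m.length:.1f}\t{n}\t{i}\t1\t{pos + 1:.1f}"
            )
        # channel-0 end row: carries id/length even for label-free maps
        lines.append(f"{m.id}\t{m.length:.1f}\t{n}\t{n + 1}\t0\t{m.length:.1f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_cmap(path: str | Path) -> list[LabelMap]:
    """Read a CMAP-dialect file written by :func:`write_cmap`.

    Raises :class:`CmapParseError` naming the offending line for malformed
    rows or non-monotone positions.
    """
    maps: list[LabelMap] = []
    cur_id: str | None = None
    cur_len = 0.0
    cur_labels: list[float] = []

    def flush() -> None:
        nonlocal cur_id, cur_labels
        if cur_id is not None:
            maps.append(LabelMap(cur_id, cur_len, np.array(cur_labels)))
        cur_id, cur_labels = None, []

    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise CmapParseError(f"line {lineno}: expected 6 fields, got {len(fields)}")
        try:
            map_id, length, _nsites, _site, channel, pos = (
                fields[0], float(fields[1]), int(fields[2]), int(fields[3]),
                int(fields[4]), float(fields[5]),
            )
        except ValueError as exc:
            raise CmapParseError(f"line {lineno}: {exc}") from None
        if map_id != cur_id:
            flush()
            cur_id, cur_len = map_id, length
        if channel == 0:
            flush()
            continue
        pos0 = pos - 1.0  # back to 0-based
        if cur_labels and pos0 <= cur_labels[-1]:
            raise CmapParseError(f"line {lineno}: non-monotone position {pos}")
        cur_labels.append(pos0)
    flush()
    return maps
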