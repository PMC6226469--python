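"""Subtelomeric duplication-family detection, enrichment and dating.

From a BED-like table of segmental-duplication pairs (two genomic intervals
with high sequence identity per record), the base-pair copy number of a
position is the number of records overlapping it.  Maximal runs of copy
number >= 22 are high-copy regions; the duplication copies spanning such a
region, together with their homologous partners, form a duplication family.
Families with at least one member within 1 Mb of a chromosome end are
subtelomeric.  Pairwise divergence between copies (single-base differences,
indels ignored) divided by a fixed inter-copy substitution rate of 0.3% per
Myr (3% divergence per 10 Myr) dates each duplication.

The >=22 threshold is exposed as a parameter: the source material states the
cut both as "at least 22" and "greater than 22"; the inclusive reading is
the default.  Both sides of each pair count toward copy number, since the
database lists each duplication pair as an entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from Bio import Align

__all__ = [
    "SegDupPair",
    "CopyNumberProfile",
    "DupFamily",
    "AgeEstimate",
    "read_segdup_table",
    "copy_number_profile",
    "high_copy_regions",
    "family_members",
    "detect_families",
    "subtelomeric_filter",
    "enrichment_test",
    "pairwise_divergence",
    "align_copies",
    "date_duplication",
    "subtel_region",
    "exon_homology",
]


@dataclass(frozen=True)
class SegDupPair:
    """One duplication-database record: two intervals (0-based half-open)
    plus their sequence identity."""

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    identity: float

    def __post_init__(self) -> None:
        if self.start_a >= self.end_a or self.start_b >= self.end_b:
            raise ValueError("intervals must satisfy start < end")
        if not 0 < self.identity <= 1:
            raise ValueError("identity must be in (0, 1]")


@dataclass
class CopyNumberProfile:
    """Run-length encoded per-chromosome copy-number counts."""

    runs: dict[str, list[tuple[int, int, int]]]  # chrom -> [(start, end, count)]

    def at(self, chrom: str, pos: int) -> int:
        for s, e, c in self.runs.get(chrom, ()):
            if s <= pos < e:
                return c
        return 0


@dataclass
class DupFamily:
    core: tuple[str, int, int]
    members: list[tuple[str, int, int]]
    subtel_flags: list[bool] = field(default_factory=list)

    @property
    def core_length(self) -> int:
        return self.core[2] - self.core[1]

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def n_subtelomeric(self) -> int:
        return sum(self.subtel_flags)


@dataclass
class AgeEstimate:
    divergence: float  # percent
    rate: float        # percent divergence between copies per Myr
    age: float         # Myr


def read_segdup_table(source: str | Path | pd.DataFrame) -> list[SegDupPair]:
    """Load duplication pairs from a TSV (chromA startA endA chromB startB
    endB identity) or an equivalent DataFrame."""
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t")
    return [
        SegDupPair(r.chromA, int(r.startA), int(r.endA),
                   r.chromB, int(r.startB), int(r.endB), float(r.identity))
        for r in df.itertuples()
    ]


def copy_number_profile(
    pairs: Sequence[SegDupPair], chrom_lengths: Mapping[str, int]
) -> CopyNumberProfile:
    """Base-pair copy number as an RLE profile (endpoint sweep; matches
    per-base counting exactly).  Each record contributes +1 over both of its
    intervals."""
    deltas: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for p in pairs:
        for chrom, s, e in ((p.chrom_a, p.start_a, p.end_a), (p.chrom_b, p.start_b, p.end_b)):
            if chrom not in chrom_lengths:
                raise ValueError(f"interval on unknown chromosome {chrom!r}")
            if s < 0 or e > chrom_lengths[chrom]:
                raise ValueError(f"interval {chrom}:{s}-{e} beyond chromosome length")
            deltas[chrom].append((s, 1))
            deltas[chrom].append((e, -1))
    runs: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, L in chrom_lengths.items():
        evs = sorted(deltas[chrom])
        out: list[tuple[int, int, int]] = []
        cur, count = 0, 0
        for pos, d in evs + [(L, 0)]:
            if pos > cur:
                if out and out[-1][2] == count and out[-1][1] == cur:
                    out[-1] = (out[-1][0], pos, count)
                else:
                    out.append((cur, pos, count))
                cur = pos
            elif pos == cur:
                pass
            count += d
        if not out:
            out = [(0, L, 0)]
        runs[chrom] = out
    return CopyNumberProfile(runs)


def high_copy_regions(
    profile: CopyNumberProfile, min_cn: int = 22
) -> list[tuple[str, int, int]]:
    """Maximal runs with copy number >= ``min_cn``, ordered by bp length
    descending (ties by chromosome then start)."""
    regions = []
    for chrom, runs in profile.runs.items():
        cur: tuple[int, int] | None = None
        for s, e, c in runs:
            if c >= min_cn:
                # runs partition the chromosome, so an open region always
                # ends exactly where the next qualifying run starts
                cur = (cur[0], e) if cur else (s, e)
            else:
                if cur:
                    regions.append((chrom, cur[0], cur[1]))
                    cur = None
        if cur:
            regions.append((chrom, cur[0], cur[1]))
    regions.sort(key=lambda r: (-(r[2] - r[1]), r[0], r[1]))
    return regions


def _contains(chrom: str, s: int, e: int, region: tuple[str, int, int]) -> bool:
    rc, rs, re_ = region
    return chrom == rc and s <= rs and e >= re_


def family_members(
    region: tuple[str, int, int], pairs: Sequence[SegDupPair]
) -> list[tuple[str, int, int]]:
    """Duplication copies of the family seeded by a high-copy region.

    Every pair side whose interval spans the entire region is a family copy;
    it contributes both itself and its homologous partner (the same stretch
    of sequence at the partner locus), deduplicated by interval.  A copy
    overlapping the region only partially contributes nothing.
    """
    members: set[tuple[str, int, int]] = set()
    for p in pairs:
        a = (p.chrom_a, p.start_a, p.end_a)
        b = (p.chrom_b, p.start_b, p.end_b)
        if _contains(*a, region):
            members.add(a)
            members.add(b)
        if _contains(*b, region):
            members.add(a)
            members.add(b)
    return sorted(members)


def detect_families(
    pairs: Sequence[SegDupPair],
    chrom_lengths: Mapping[str, int],
    min_cn: int = 22,
) -> list[DupFamily]:
    """Profile -> high-copy regions -> span-members, collapsing regions that
    yield the same member set (each copy of a family seeds the same family).
    Families ordered by core length descending."""
    profile = copy_number_profile(pairs, chrom_lengths)
    seen: dict[tuple, DupFamily] = {}
    for region in high_copy_regions(profile, min_cn):
        members = family_members(region, pairs)
        if not members:
            continue
        key = tuple(members)
        if key not in seen:
            seen[key] = DupFamily(core=region, members=members)
    return sorted(seen.values(), key=lambda f: -f.core_length)


def subtelomeric_filter(
    families: Sequence[DupFamily],
    chrom_lengths: Mapping[str, int],
    window: int = 1_000_000,
) -> list[DupFamily]:
    """Flag members within ``window`` of a chromosome end (intersection
    rule: a member straddling the boundary is flagged) and drop families
    with no subtelomeric member."""
    kept = []
    for fam in families:
        flags = []
        for chrom, s, e in fam.members:
            L = chrom_lengths[chrom]
            flags.append(s < window or e > L - window)
        fam.subtel_flags = flags
        if any(flags):
            kept.append(fam)
    return kept


def enrichment_test(
    family: DupFamily, subtel_bp: int, genome_bp: int
) -> tuple[float, float]:
    """Subtelomeric enrichment of a family's copies.

    Under the null, each of the n copies lands subtelomerically with
    probability p0 = subtel_bp / genome_bp.  Returns (fold, p) with
    fold = (k/n)/p0 and p the one-sided exact binomial tail P(X >= k).
    """
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    n = family.n_members
    if n < 1:
        raise ValueError("family must have at least one member")
    k = family.n_subtelomeric
    p0 = subtel_bp / genome_bp
    fold = (k / n) / p0 if p0 > 0 else float("inf")
    p_value = float(sps.binom.sf(k - 1, n, p0)) if k > 0 else 1.0
    return fold, min(p_value, 1.0)


class AlignmentTooShortError(ValueError):
    """Aligned length below the family's size filter."""


def pairwise_divergence(
    aligned_a: str, aligned_b: str, min_aligned_bp: int = 0
) -> float:
    """Percent single-base difference between two aligned copies.

    Columns containing a gap in either sequence are ignored (insertions and
    deletions do not count).  Raises :class:`AlignmentTooShortError` when
    fewer than ``min_aligned_bp`` gap-free columns remain.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    a = np.frombuffer(aligned_a.upper().encode(), dtype="S1")
    b = np.frombuffer(aligned_b.upper().encode(), dtype="S1")
    keep = (a != b"-") & (b != b"-")
    n = int(keep.sum())
    if n < max(min_aligned_bp, 1):
        raise AlignmentTooShortError(
            f"{n} aligned columns < required {min_aligned_bp}"
        )
    mismatches = int((a[keep] != b[keep]).sum())
    return 100.0 * mismatches / n


def align_copies(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global alignment of two copies with match/mismatch/gap = 1/-1/-2,
    returned as gapped strings for :func:`pairwise_divergence`."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])


def date_duplication(divergence_pct: float, rate_pct_per_myr: float = 0.3) -> AgeEstimate:
    """Molecular-clock age: divergence divided by the inter-copy substitution
    rate (default 0.3 %/Myr, i.e. 3% divergence between copies per 10 Myr)."""
    if rate_pct_per_myr <= 0:
        raise ValueError("rate must be positive")
    if divergence_pct < 0:
        raise ValueError("divergence must be >= 0")
    return AgeEstimate(
        divergence=divergence_pct,
        rate=rate_pct_per_myr,
        age=divergence_pct / rate_pct_per_myr,
    )


def subtel_region(
    intervals: Sequence[tuple[float, float]]
) -> tuple[float, float] | None:
    """Longest contiguous duplication coverage starting at the terminus.

    ``intervals`` are duplication intervals in terminus-distal coordinates
    (0 = chromosome tip).  Touching or overlapping intervals merge; the
    maximal merged prefix beginning at 0 is the subtelomeric-duplication
    region.  None when no duplication touches the terminus.
    """
    if not intervals:
        return None
    merged: list[list[float]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    first = merged[0]
    if first[0] > 0:
        return None
    return (0.0, first[1])


def exon_homology(exon_a_len: int, aligned_len: int, identity: float) -> bool:
    """Exon A is homologous to exon B when >= 90% of A aligns at identity
    strictly greater than 95% (asymmetric in A)."""
    if exon_a_len <= 0 or aligned_len < 0:
        raise ValueError("lengths must be positive")
    return aligned_len / exon_a_len >= 0.90 and identity > 0.95
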