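"""Chromosome-end calling from label-map alignments.

A sample's terminus is represented by the contig whose alignment reaches the
most distal reference label with the highest score.  Relative to that
anchored alignment each terminus is called reference / extension / missing /
extension_and_missing against a length threshold equal to the mean
inter-label distance plus ``k`` standard deviations (k=3 by default; with the
real optical-map spacing of 8.2 +/- 8.3 kb this gives the 33.1 kb threshold).
Sub-threshold discrepancies are indistinguishable from label-resolution
noise.

Size definitions (flush-aware netting).  Let (i*, j*) be the most
terminus-distal matched (contig, reference) label pair, D_q the contig
distance from i* to the contig's distal end, D_r the reference distance from
j* to the chromosome end, and D_r' = D_r minus N-gap bp in that span.  A side
is *flush* when it has no unmatched labels distal of the matched pair.  When
at least one side is flush its label-free tail carries no evidence of
divergence and the tails net out:

    extension_len = max(0, D_q - D_r),  missing_len = max(0, D_r' - D_q)

so aligning a reference against itself yields exactly 0/0 at every terminus
and a pure planted event measures exactly its planted length.  When both
sides carry unmatched distal labels the ends are genuinely divergent and the
sizes are reported independently (extension_len = D_q, missing_len = D_r'),
supporting combined extension_and_missing calls.

Extensions are classified category 1 or 2 by realigning the extension label
subsequence genome-wide with multiple matches: category 1 when some
alignment covers at least half of the extension labels (origins recorded),
category 2 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignment import AlignmentParams, LabelAlignment, align
from .label_io import LabelMap, LabelStats

__all__ = [
    "ThresholdModel",
    "TerminusCall",
    "TrioCall",
    "Origin",
    "compute_threshold",
    "anchor_terminus",
    "call_terminus",
    "classify_extension",
    "trio_inheritance",
    "detect_diploid",
    "terminal_window_map",
]


@dataclass
class ThresholdModel:
    """Extension/missing length threshold: mean + k * SD of the inter-label
    distance, in kb (unrounded internally; report at 0.1 kb)."""

    mean_interval: float
    sd_interval: float
    k: float
    threshold: float

    @property
    def threshold_bp(self) -> float:
        return self.threshold * 1000.0

    @property
    def reported(self) -> float:
        return round(self.threshold, 1)


def compute_threshold(stats: LabelStats, k: float = 3.0) -> ThresholdModel:
    return ThresholdModel(
        mean_interval=stats.mean_interval,
        sd_interval=stats.sd_interval,
        k=k,
        threshold=stats.mean_interval + k * stats.sd_interval,
    )


@dataclass
class Origin:
    """Homologous source of an extension: donor chromosome/arm with the
    matched reference span, orientation and label coverage."""

    chrom: str
    arm: str
    span: tuple[float, float]
    orientation: str
    coverage: float
    score: float


@dataclass
class TerminusCall:
    sample: str
    chrom: str
    arm: str
    status: str = "excluded"
    extension_len: float = 0.0
    missing_len: float = 0.0
    category: int | None = None
    origins: list[Origin] = field(default_factory=list)
    anchor_contig: str | None = None
    anchor_score: float = 0.0
    flags: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


@dataclass
class TrioCall:
    chrom: str
    arm: str
    parent_of_origin: str = "neither"  # mother | father | both | neither
    diff_father: int | None = None
    diff_mother: int | None = None
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# arm geometry helpers


def _ref_distality(pos: float, arm: str, ref_len: float) -> float:
    """Distance of a reference position from the arm's terminus."""
    return ref_len - pos if arm == "q" else pos


def _contig_distal_is_high(arm: str, orientation: str) -> bool:
    """Which contig end points at the terminus under this alignment."""
    return (arm == "q") == (orientation == "+")


def _gap_overlap(gaps: Sequence[tuple[float, float]], lo: float, hi: float) -> float:
    return sum(max(0.0, min(e, hi) - max(s, lo)) for s, e in gaps)


# ---------------------------------------------------------------------------
# anchoring and calling


def alignment_is_confident(
    aln: LabelAlignment, min_pairs: int = 1, min_score_per_interval: float = 0.0
) -> bool:
    """Support filter for anchoring: enough matched labels and a mean score
    per matched interval high enough to exclude gappy paralogous chains."""
    if aln.n_pairs < min_pairs:
        return False
    return aln.score >= min_score_per_interval * max(1, aln.n_pairs - 1)


def anchor_terminus(
    alignments: Sequence[LabelAlignment],
    chrom: str,
    arm: str,
    ref_map: LabelMap,
    contig_maps: Mapping[str, LabelMap] | None = None,
    terminal_window: float = 1_000_000.0,
    min_pairs: int = 1,
    min_score_per_interval: float = 0.0,
) -> LabelAlignment | None:
    """Pick the contig alignment representing this terminus.

    Among alignments whose most distal matched reference label lies within
    ``terminal_window`` of the terminus: smallest distality wins, then
    highest score, then longer aligned reference span, then larger distal
    overhang (the longest allele dominates, as in real diploid assemblies),
    then contig id.  Returns None when no candidate exists.

    ``min_pairs`` and ``min_score_per_interval`` discard weakly supported
    candidates (short or gappy paralogous matches between subtelomeres,
    which chain sparse duplication-family labels at a low score per matched
    interval); together they stand in for the alignment significance cutoff
    of the commercial aligner.
    """
    ranked = []
    for a in alignments:
        if a.ref_id != chrom or not alignment_is_confident(
            a, min_pairs, min_score_per_interval
        ):
            continue
        dists = [
            _ref_distality(ref_map.labels[j], arm, ref_map.length)
            for j in a.ref_indices()
        ]
        d = min(dists)
        if d > terminal_window:
            continue
        span = abs(a.ref_span[1] - a.ref_span[0])
        overhang = 0.0
        if contig_maps is not None and a.query_id in contig_maps:
            cm = contig_maps[a.query_id]
            overhang = _distal_measures(a, cm, arm)[0]
        ranked.append((d, -a.score, -span, -overhang, a.query_id, a))
    if not ranked:
        return None
    ranked.sort(key=lambda t: t[:5])
    return ranked[0][5]


def _distal_measures(
    aln: LabelAlignment, contig: LabelMap, arm: str
) -> tuple[float, bool, int]:
    """(D_q, contig_flush, index of most distal matched contig label)."""
    qi = aln.query_indices()
    if _contig_distal_is_high(arm, aln.orientation):
        i_star = max(qi)
        d_q = contig.length - contig.labels[i_star]
        flush = i_star == contig.n_labels - 1
    else:
        i_star = min(qi)
        d_q = float(contig.labels[i_star])
        flush = i_star == 0
    return float(d_q), flush, i_star


def call_terminus(
    aln: LabelAlignment,
    contig: LabelMap,
    ref_map: LabelMap,
    arm: str,
    threshold_bp: float,
    ngaps: Sequence[tuple[float, float]] = (),
    sample: str = "",
) -> TerminusCall:
    """Call one terminus from its anchored alignment (see module docstring
    for the flush-aware size definitions)."""
    ri = aln.ref_indices()
    if arm == "q":
        j_star = max(ri)
        ref_flush = j_star == ref_map.n_labels - 1
        span = (float(ref_map.labels[j_star]), ref_map.length)
    else:
        j_star = min(ri)
        ref_flush = j_star == 0
        span = (0.0, float(ref_map.labels[j_star]))
    d_r_phys = span[1] - span[0]
    d_r_known = d_r_phys - _gap_overlap(ngaps, *span)

    d_q, contig_flush, i_star = _distal_measures(aln, contig, arm)

    if ref_flush or contig_flush:
        # at least one side has a label-free distal tail: tails correspond
        # up to exhaustion and net out (self-alignment gives exactly 0/0,
        # a pure planted event measures exactly its planted length)
        ext = max(0.0, d_q - d_r_phys)
        miss = max(0.0, d_r_known - d_q)
    else:
        # unmatched labels distal on both sides: genuinely divergent ends,
        # sizes reported independently (extension plus reference deletion)
        ext = d_q
        miss = d_r_known

    has_ext = ext > threshold_bp
    has_miss = miss > threshold_bp
    status = (
        "extension_and_missing" if has_ext and has_miss
        else "extension" if has_ext
        else "missing" if has_miss
        else "reference"
    )
    return TerminusCall(
        sample=sample,
        chrom=ref_map.id,
        arm=arm,
        status=status,
        extension_len=ext,
        missing_len=miss,
        anchor_contig=aln.query_id,
        anchor_score=aln.score,
        meta={
            "i_star": i_star,
            "j_star": j_star,
            "orientation": aln.orientation,
            "distal_high": _contig_distal_is_high(arm, aln.orientation),
        },
    )


def extension_label_map(call: TerminusCall, contig: LabelMap) -> LabelMap:
    """The extension label subsequence as a standalone map, re-based so the
    junction (most distal matched contig label) is the origin."""
    i_star = call.meta["i_star"]
    anchor = float(contig.labels[i_star])
    if call.meta["distal_high"]:
        labels = contig.labels[contig.labels > anchor] - anchor
        length = contig.length - anchor
    else:
        sel = contig.labels[contig.labels < anchor]
        labels = np.sort(anchor - sel)
        length = anchor + 1.0
    return LabelMap(f"{contig.id}_ext", float(length), labels)


def classify_extension(
    call: TerminusCall,
    contig: LabelMap,
    ref_maps: Sequence[LabelMap],
    params: AlignmentParams | None = None,
    min_coverage: float = 0.5,
    arm_window: float = 1_000_000.0,
) -> TerminusCall:
    """Assign category 1/2 by realigning the extension labels genome-wide.

    Category 1 when any multi-match alignment covers >= ``min_coverage`` of
    the extension labels; all qualifying origins are recorded (overlapping
    duplication copies can yield several).  Too few extension labels to
    align is category 2 with a 'too_few_labels' flag.
    """
    if "extension" not in call.status:
        return call
    params = params or AlignmentParams()
    ext_map = extension_label_map(call, contig)
    if ext_map.n_labels < params.min_labels:
        call.category = 2
        call.flags.append("too_few_labels")
        return call
    hits = align(ext_map, list(ref_maps), params)
    ref_lens = {m.id: m.length for m in ref_maps}
    origins = []
    for a in hits:
        cov = a.n_pairs / ext_map.n_labels
        if cov < min_coverage:
            continue
        lo, hi = min(a.ref_span), max(a.ref_span)
        L = ref_lens[a.ref_id]
        arm = "p" if hi <= arm_window else "q" if lo >= L - arm_window else "i"
        origins.append(Origin(a.ref_id, arm, (lo, hi), a.orientation, cov, a.score))
    call.origins = origins
    call.category = 1 if origins else 2
    return call


# ---------------------------------------------------------------------------
# trio inheritance and diploid termini


def terminal_window_map(
    contig: LabelMap, distal_high: bool, window: int = 10
) -> LabelMap:
    """The distal ``window`` labels in tip-first coordinates (distance from
    the contig's terminus-distal end, ascending)."""
    if distal_high:
        sel = contig.labels[-window:]
        labels = np.sort(contig.length - sel)
    else:
        sel = contig.labels[:window]
        labels = np.array(sel, dtype=float)
    length = float(labels[-1] + 1.0) if labels.size else 1.0
    return LabelMap(f"{contig.id}_tip", length, labels)


def _window_diff(
    a: LabelMap, b: LabelMap, params: AlignmentParams | None = None
) -> int:
    """Unmatched terminal labels on either side of the best alignment of two
    tip-first windows."""
    if a.n_labels == 0 and b.n_labels == 0:
        return 0
    if a.n_labels == 0 or b.n_labels == 0:
        return a.n_labels + b.n_labels
    params = params or AlignmentParams(min_labels=2, max_skip=10)
    try:
        hits = align(a, b, params)
    except ValueError:
        hits = []
    if not hits:
        return a.n_labels + b.n_labels
    best = hits[0]
    return (a.n_labels - best.n_pairs) + (b.n_labels - best.n_pairs)


def trio_inheritance(
    child: tuple[LabelMap, bool],
    father: tuple[LabelMap, bool] | None,
    mother: tuple[LabelMap, bool] | None,
    chrom: str = "",
    arm: str = "",
    tolerance: int = 1,
    window: int = 10,
    params: AlignmentParams | None = None,
) -> TrioCall:
    """Which parent the child's terminus was inherited from.

    Each argument is (anchored contig map, distal_high flag).  The child's
    terminal ``window`` labels are aligned to each parent's; a parent within
    ``tolerance`` unmatched terminal labels (default: no more than one label
    difference) is a possible origin; both within tolerance -> 'both'.
    """
    call = TrioCall(chrom=chrom, arm=arm)
    cw = terminal_window_map(child[0], child[1], window)
    diffs = {}
    for name, parent in (("father", father), ("mother", mother)):
        if parent is None:
            call.flags.append(f"missing_{name}")
            continue
        pw = terminal_window_map(parent[0], parent[1], window)
        diffs[name] = _window_diff(cw, pw, params)
    call.diff_father = diffs.get("father")
    call.diff_mother = diffs.get("mother")
    within = [n for n, d in diffs.items() if d <= tolerance]
    call.parent_of_origin = (
        "both" if len(within) == 2 else within[0] if within else "neither"
    )
    return call


def detect_diploid(
    contigs: Sequence[tuple[str, LabelMap, bool]],
    tolerance: int = 1,
    window: int = 10,
    params: AlignmentParams | None = None,
) -> list[list[str]]:
    """Group contigs anchored to one terminus into allele classes.

    Contigs whose terminal label windows differ by more than ``tolerance``
    labels are distinct alleles; two near-identical contigs collapse into
    one.  Returns a list of allele classes (lists of contig ids).
    """
    classes: list[tuple[LabelMap, list[str]]] = []
    for cid, cm, high in contigs:
        w = terminal_window_map(cm, high, window)
        for rep, ids in classes:
            if _window_diff(w, rep, params) <= tolerance:
                ids.append(cid)
                break
        else:
            classes.append((w, [cid]))
    return [ids for _, ids in classes]
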