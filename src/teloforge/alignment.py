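"""Dynamic-programming alignment of label maps under a sizing-error model.

An optical-map alignment pairs query labels with reference labels
monotonically; the quality of a matched pair of adjacent intervals is scored
by how similar their bp lengths are relative to the sizing error expected at
that scale.  The score of an alignment is

    sum over consecutive matched pairs of  m - (dq - dr)^2 / (2 sigma^2)
    - fp_penalty * (interior skipped query labels)
    - fn_penalty * (interior skipped reference labels)

with sigma^2 = sd_fixed^2 + (sr * dr)^2.  A single matched label contributes
zero intervals, hence ``min_labels`` defaults to 3 to suppress degenerate
hits.  In ``endoutlier`` mode unaligned terminal runs on the query are free
(the mode used to anchor terminal contigs, where the distal overhang is
exactly the signal); in ``fit`` mode terminal unmatched query labels pay
``fp_penalty`` each.  Terminal reference labels are never penalised: the
reference is much longer than the query.

This is an emulation of the commercial RefAlign likelihood, which is not
public; everything downstream depends only on the ranking of alignments.
``brute_force_align`` enumerates all monotone pairings on tiny instances and
is the independent oracle the DP is tested against.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .label_io import LabelMap

__all__ = [
    "AlignmentParams",
    "LabelAlignment",
    "interval_score",
    "align",
    "brute_force_align",
    "recompute_score",
    "write_xmap",
    "read_xmap",
]

_NEG = -1e18


@dataclass
class AlignmentParams:
    """Scoring and search parameters.

    ``max_skip`` mirrors the assembler's deltaX/deltaY (printed value 12);
    ``max_matches`` mirrors MultiMatches 5.  ``sf`` is carried for parity with
    the printed parameter string but does not enter the emulated score; the
    fixed sizing SD defaults to 1 kb because the printed ``-sd 0.0`` would make
    short intervals infinitely precise.
    """

    match_bonus: float = 3.0
    sd_fixed: float = 1000.0
    sr: float = 0.01
    sf: float = 0.20
    fp_penalty: float | None = None  # default match_bonus / 2
    fn_penalty: float | None = None
    max_skip: int = 12
    max_matches: int = 5
    min_labels: int = 3
    min_score: float = 0.0
    mode: str = "endoutlier"  # or "fit"

    def __post_init__(self) -> None:
        if self.fp_penalty is None:
            self.fp_penalty = self.match_bonus / 2.0
        if self.fn_penalty is None:
            self.fn_penalty = self.match_bonus / 2.0
        if self.max_skip < 1 or self.max_matches < 1:
            raise ValueError("max_skip and max_matches must be >= 1")
        if self.fp_penalty < 0 or self.fn_penalty < 0:
            raise ValueError("penalties must be >= 0")
        if self.mode not in ("endoutlier", "fit"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class LabelAlignment:
    """A monotone pairing of query labels to reference labels.

    ``pairs`` holds (query label index, reference label index) tuples in
    original query coordinates; for orientation '-' the query indices decrease
    while reference indices increase.
    """

    query_id: str
    ref_id: str
    orientation: str
    pairs: list[tuple[int, int]]
    score: float
    query_span: tuple[float, float] = (0.0, 0.0)
    ref_span: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def query_indices(self) -> list[int]:
        return [p[0] for p in self.pairs]

    def ref_indices(self) -> list[int]:
        return [p[1] for p in self.pairs]


def interval_score(q_len: float, r_len: float, params: AlignmentParams) -> float:
    """Likelihood-style score of a pair of matched label intervals.

    Maximal (= match_bonus) at q_len == r_len, strictly decreasing and
    symmetric in |q_len - r_len|.
    """
    if q_len <= 0 or r_len <= 0:
        raise ValueError("interval lengths must be positive")
    var = params.sd_fixed**2 + (params.sr * r_len) ** 2
    return params.match_bonus - (q_len - r_len) ** 2 / (2.0 * var)


def _chain_score(
    q: np.ndarray, r: np.ndarray, chain: Sequence[tuple[int, int]], params: AlignmentParams
) -> float:
    """Score a monotone chain of (query, ref) index pairs; shared by the DP
    result verification, the brute-force oracle and recompute_score."""
    s = 0.0
    for (i0, j0), (i1, j1) in zip(chain[:-1], chain[1:]):
        s += interval_score(q[i1] - q[i0], r[j1] - r[j0], params)
        s -= params.fp_penalty * (i1 - i0 - 1)
        s -= params.fn_penalty * (j1 - j0 - 1)
    if params.mode == "fit":
        s -= params.fp_penalty * (chain[0][0] + (len(q) - 1 - chain[-1][0]))
    return s


def _dp_one_orientation(q: np.ndarray, r: np.ndarray, params: AlignmentParams):
    """Fill the DP over (chain-length layer, query label, reference label).

    Layer l holds the best chain of exactly l+1 matched labels ending at each
    cell; the top layer saturates at ``min_labels`` (chains of at least that
    many labels), which keeps the optimisation exact under the minimum-label
    constraint: without the layers, an empty restart (score 0) would shadow
    any negative-scoring longer chain and the constrained optimum would be
    lost.  Returns (end_scores of the saturated layer, back-pointer arrays).
    """
    n, m = len(q), len(r)
    fp, fn, mb = params.fp_penalty, params.fn_penalty, params.match_bonus
    ks = params.max_skip
    L0 = max(1, params.min_labels)
    S = np.full((L0, n, m), _NEG)
    BA = np.zeros((L0, n, m), dtype=np.int16)  # 0 marks a chain start
    BB = np.zeros((L0, n, m), dtype=np.int16)
    BL = np.zeros((L0, n, m), dtype=np.int8)

    if params.mode == "fit":
        S[0] = np.repeat(-fp * np.arange(n, dtype=float)[:, None], m, axis=1)
    else:
        S[0] = 0.0

    # reference interval lengths and inverse variances per reference gap b
    rd = [None] * (ks + 1)
    inv2v = [None] * (ks + 1)
    for b in range(1, min(ks, m - 1) + 1):
        d = r[b:] - r[:-b]
        rd[b] = d
        inv2v[b] = 1.0 / (2.0 * (params.sd_fixed**2 + (params.sr * d) ** 2))

    sat = L0 - 1
    for i in range(1, n):
        for a in range(1, min(ks, i) + 1):
            qd = q[i] - q[i - a]
            gap_pen = fp * (a - 1)
            for b in range(1, min(ks, m - 1) + 1):
                step = (mb - (qd - rd[b]) ** 2 * inv2v[b]) - fn * (b - 1) - gap_pen
                # grow layer l from layer l-1, plus the saturated
                # self-transition that represents chains >= min_labels
                for l, pl in [(l, l - 1) for l in range(1, L0)] + [(sat, sat)]:
                    base = S[pl, i - a, : m - b]
                    cand = base + step
                    tgt = S[l, i, b:]
                    upd = cand > tgt
                    if np.any(upd):
                        tgt[upd] = cand[upd]
                        BA[l, i, b:][upd] = a
                        BB[l, i, b:][upd] = b
                        BL[l, i, b:][upd] = pl

    end = S[sat].copy()
    if params.mode == "fit":
        end -= fp * (n - 1 - np.arange(n, dtype=float))[:, None]
    return end, BA, BB, BL


def _traceback(
    i: int, j: int, BA: np.ndarray, BB: np.ndarray, BL: np.ndarray
) -> list[tuple[int, int]]:
    l = BA.shape[0] - 1
    chain = [(i, j)]
    while BA[l, i, j] != 0:
        a, b, pl = int(BA[l, i, j]), int(BB[l, i, j]), int(BL[l, i, j])
        i, j, l = i - a, j - b, pl
        chain.append((i, j))
    chain.reverse()
    return chain


def _candidates_one_ref(
    query: LabelMap, ref: LabelMap, params: AlignmentParams, top_cells: int = 64
):
    """Best chains against one reference map, both orientations."""
    out = []
    q_fwd = query.labels
    q_rev = (query.length - query.labels)[::-1]
    n = len(q_fwd)
    for orient, q in (("+", q_fwd), ("-", q_rev)):
        if len(q) == 0 or ref.n_labels == 0:
            continue
        end, BA, BB, BL = _dp_one_orientation(q, ref.labels, params)
        flat = end.ravel()
        order = np.argsort(flat)[::-1][:top_cells]
        for cell in order:
            sc = flat[cell]
            if sc < params.min_score or sc <= _NEG / 2:
                break
            i, j = divmod(int(cell), ref.n_labels)
            chain = _traceback(i, j, BA, BB, BL)
            if orient == "+":
                pairs = chain
                qspan = (float(q_fwd[chain[0][0]]), float(q_fwd[chain[-1][0]]))
            else:
                pairs = [(n - 1 - k, j2) for k, j2 in chain]
                qspan = (
                    float(q_fwd[pairs[-1][0]]),
                    float(q_fwd[pairs[0][0]]),
                )
            out.append(
                LabelAlignment(
                    query_id=query.id,
                    ref_id=ref.id,
                    orientation=orient,
                    pairs=pairs,
                    score=float(sc),
                    query_span=qspan,
                    ref_span=(
                        float(ref.labels[chain[0][1]]),
                        float(ref.labels[chain[-1][1]]),
                    ),
                )
            )
    out.sort(key=lambda a: (-a.score, a.ref_span[0], a.orientation))
    return out


def align(
    query: LabelMap,
    refs: LabelMap | Sequence[LabelMap],
    params: AlignmentParams | None = None,
) -> list[LabelAlignment]:
    """Align a query label map against one or more reference maps.

    Returns up to ``max_matches`` alignments per reference, ordered by score,
    each pairing at least ``min_labels`` labels.  Secondary matches sharing
    more than half of their matched reference labels with a better-scoring
    accepted match are suppressed.  An empty list (not an error) means nothing
    scored above ``min_score``.
    """
    params = params or AlignmentParams()
    if isinstance(refs, LabelMap):
        refs = [refs]
    if query.n_labels < params.min_labels:
        raise ValueError(
            f"query {query.id!r} has {query.n_labels} labels < min_labels={params.min_labels}"
        )
    results: list[LabelAlignment] = []
    for ref in refs:
        accepted: list[LabelAlignment] = []
        for cand in _candidates_one_ref(query, ref, params):
            if len(accepted) >= params.max_matches:
                break
            cset = set(cand.ref_indices())
            if any(
                len(cset & set(a.ref_indices())) > 0.5 * len(cset) for a in accepted
            ):
                continue
            accepted.append(cand)
        results.extend(accepted)
    results.sort(key=lambda a: -a.score)
    return results


def brute_force_align(
    query: LabelMap, ref: LabelMap, params: AlignmentParams | None = None
) -> LabelAlignment | None:
    """Exhaustive oracle: enumerate every monotone pairing on tiny maps.

    Scores each pairing with the same formula as :func:`align` (interior gaps
    bounded by ``max_skip``; terminal query runs free in endoutlier mode) and
    returns the maximum.  Instances above 10 labels on either side are
    refused.
    """
    params = params or AlignmentParams()
    if query.n_labels > 10 or ref.n_labels > 10:
        raise ValueError("brute_force_align is restricted to maps of <= 10 labels")
    n, m = query.n_labels, ref.n_labels
    q_fwd = query.labels
    q_rev = (query.length - query.labels)[::-1]
    best: LabelAlignment | None = None
    for orient, q in (("+", q_fwd), ("-", q_rev)):
        for k in range(max(1, params.min_labels), min(n, m) + 1):
            for qi in itertools.combinations(range(n), k):
                if any(b - a > params.max_skip for a, b in zip(qi[:-1], qi[1:])):
                    continue
                for ri in itertools.combinations(range(m), k):
                    if any(b - a > params.max_skip for a, b in zip(ri[:-1], ri[1:])):
                        continue
                    chain = list(zip(qi, ri))
                    sc = _chain_score(q, ref.labels, chain, params)
                    if best is None or sc > best.score:
                        if orient == "+":
                            pairs = chain
                        else:
                            pairs = [(n - 1 - i, j) for i, j in chain]
                        best = LabelAlignment(
                            query.id, ref.id, orient, pairs, sc
                        )
    return best


def recompute_score(
    alignment: LabelAlignment,
    query: LabelMap,
    ref: LabelMap,
    params: AlignmentParams,
) -> float:
    """Re-derive an alignment's score from its pairs (recomputability check)."""
    n = query.n_labels
    if alignment.orientation == "+":
        q = query.labels
        chain = alignment.pairs
    else:
        q = (query.length - query.labels)[::-1]
        chain = [(n - 1 - i, j) for i, j in alignment.pairs]
    return _chain_score(q, ref.labels, chain, params)


# ---------------------------------------------------------------------------
# XMAP dialect

_XMAP_HEADER = [
    "#\tXMAP dialect (teloforge)",
    "#h\tXmapEntryID\tQryContigID\tRefContigID\tOrientation\tScore\tQryStart\tQryEnd\tRefStart\tRefEnd\tAlignment",
]


def _pairs_to_str(pairs: Sequence[tuple[int, int]]) -> str:
    # (ref,qry) 1-based site ids, the wild XMAP convention
    return "".join(f"({j + 1},{i + 1})" for i, j in pairs)


_PAIR_RE = re.compile(r"\((\d+),(\d+)\)")


def write_xmap(alignments: Sequence[LabelAlignment], path: str | Path) -> None:
    lines = list(_XMAP_HEADER)
    for k, a in enumerate(alignments, start=1):
        lines.append(
            "\t".join(
                [
                    str(k), a.query_id, a.ref_id, a.orientation,
                    f"{a.score:.4f}",
                    f"{a.query_span[0]:.1f}", f"{a.query_span[1]:.1f}",
                    f"{a.ref_span[0]:.1f}", f"{a.ref_span[1]:.1f}",
                    _pairs_to_str(a.pairs),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_xmap(path: str | Path) -> list[LabelAlignment]:
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 10:
            raise ValueError(f"xmap line {lineno}: expected 10 fields")
        pairs = [(int(i) - 1, int(j) - 1) for j, i in _PAIR_RE.findall(fields[9])]
        out.append(
            LabelAlignment(
                query_id=fields[1],
                ref_id=fields[2],
                orientation=fields[3],
                pairs=pairs,
                score=float(fields[4]),
                query_span=(float(fields[5]), float(fields[6])),
                ref_span=(float(fields[7]), float(fields[8])),
            )
        )
    return out
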