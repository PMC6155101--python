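"""Validated strand/loop alternation.

Raw strand annotations (from SHEET records, STRIDE, or a user table) are
turned into an ordered alternation S_1, L_1, S_2, ..., L_{n-1}, S_n along
the chain.  Strand order is chain (sequence) order, because the joint
points follow the chain; spatial adjacency is never used.  Loops are the
residue-range complements between consecutive strands and may be empty
(adjacent strands with no intervening residue).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .errors import (
    AmbiguousBoundaryError,
    AnnotationError,
    MissingTerminusError,
    TooFewStrandsError,
)
from .io import CAlphaTrace, RawStrand, ResidueId

logger = logging.getLogger(__name__)

__all__ = ["SegmentAnnotation", "build_annotation", "apply_tm_boundaries"]

# (start, end) residue identifiers, inclusive; None for a zero-length loop
Range = tuple[ResidueId, ResidueId]


@dataclass(frozen=True)
class SegmentAnnotation:
    """Ordered beta-strands S_1..S_n and the implied loops L_1..L_{n-1}.

    ``strands[i]`` and ``loops[i]`` are inclusive residue-identifier
    ranges; ``loops[i]`` is ``None`` for a zero-residue turn.  Invariants:
    n >= 2, strands disjoint and in chain order, loop_i strictly between
    strand_i and strand_{i+1}.
    """

    strands: tuple[Range, ...]
    loops: tuple[Range | None, ...]

    @property
    def n_strands(self) -> int:
        return len(self.strands)

    def __post_init__(self) -> None:
        if len(self.strands) < 2:
            raise TooFewStrandsError(
                f"need at least 2 strands, got {len(self.strands)}"
            )
        if len(self.loops) != len(self.strands) - 1:
            raise AnnotationError(
                f"{len(self.strands)} strands require "
                f"{len(self.strands) - 1} loops, got {len(self.loops)}"
            )


def _strand_indices(
    strand: RawStrand, trace: CAlphaTrace, trim: bool
) -> tuple[int, int]:
    """Map a raw strand's terminal residue ids to trace indices.

    With ``trim`` enabled, a terminus whose C-alpha is unresolved is moved
    inward to the nearest resolved residue; otherwise it is a hard error,
    since a silently shifted joint would corrupt every downstream angle.
    """
    ids = trace.residue_ids
    try:
        i = trace.index_of(strand.start)
    except KeyError:
        if not trim:
            raise MissingTerminusError(
                f"strand start {strand.start} has no C-alpha in chain "
                f"{trace.chain_id}"
            ) from None
        candidates = [
            k for k, r in enumerate(ids)
            if (r.number, r.icode) > (strand.start.number, strand.start.icode)
        ]
        if not candidates:
            raise MissingTerminusError(
                f"cannot trim strand start {strand.start}: no resolved "
                f"residue follows it"
            ) from None
        i = min(candidates)
        logger.warning("trimmed strand start %s -> %s", strand.start, ids[i])
    try:
        j = trace.index_of(strand.end)
    except KeyError:
        if not trim:
            raise MissingTerminusError(
                f"strand end {strand.end} has no C-alpha in chain "
                f"{trace.chain_id}"
            ) from None
        candidates = [
            k for k, r in enumerate(ids)
            if (r.number, r.icode) < (strand.end.number, strand.end.icode)
        ]
        if not candidates:
            raise MissingTerminusError(
                f"cannot trim strand end {strand.end}: no resolved residue "
                f"precedes it"
            ) from None
        j = max(candidates)
        logger.warning("trimmed strand end %s -> %s", strand.end, ids[j])
    if j < i:
        raise AnnotationError(
            f"strand {strand.start}-{strand.end} is reversed in chain order"
        )
    return i, j


def build_annotation(
    strands: Sequence[RawStrand],
    trace: CAlphaTrace,
    merge_gap: int = 0,
    trim_to_resolved: bool = False,
) -> SegmentAnnotation:
    """Validate raw strands against a trace and derive the loop complement.

    With ``merge_gap >= 1``, strands separated by at most ``merge_gap``
    residues are merged into one (for SHEET-record input only when they
    share a sheet identifier; SHEET records routinely split one physical
    strand at a beta-bulge).  ``merge_gap=0`` disables merging, so that
    directly adjacent strands remain distinct with a zero-length loop.
    Overlap is always an error, as is ending up with fewer than two
    strands.
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be non-negative")
    if not strands:
        raise TooFewStrandsError("no strands supplied")

    indexed = sorted(
        (( *_strand_indices(s, trace, trim_to_resolved), s) for s in strands),
        key=lambda t: t[0],
    )
    merged: list[list] = [list(indexed[0])]
    for i, j, s in indexed[1:]:
        pi, pj, ps = merged[-1]
        gap = i - pj - 1
        if gap < 0:
            raise AnnotationError(
                f"strands {ps.start}-{ps.end} and {s.start}-{s.end} overlap"
            )
        same_sheet = (
            s.source != "sheet_record"
            or ps.source != "sheet_record"
            or s.sheet_id == ps.sheet_id
        )
        # merge_gap=0 disables merging entirely: directly adjacent strands
        # are a legal zero-length-loop alternation, not one split strand
        if merge_gap >= 1 and gap <= merge_gap and same_sheet:
            merged[-1][1] = j
        else:
            merged.append([i, j, s])

    if len(merged) < 2:
        raise TooFewStrandsError(
            f"only {len(merged)} strand(s) remain after merging"
        )

    ids = trace.residue_ids
    strand_ranges: list[Range] = [(ids[i], ids[j]) for i, j, _ in merged]
    loops: list[Range | None] = []
    for (_, j, _), (i2, _, _) in zip(merged, merged[1:]):
        if i2 - j - 1 > 0:
            loops.append((ids[j + 1], ids[i2 - 1]))
        else:
            loops.append(None)
    return SegmentAnnotation(tuple(strand_ranges), tuple(loops))


def apply_tm_boundaries(
    annotation: SegmentAnnotation,
    tm_ranges: Sequence[Range],
    trace: CAlphaTrace,
) -> SegmentAnnotation:
    """Replace each intersected strand by its intersection with a TM range.

    Emulates restricting full-length strands to their membrane-embedded
    portion (OPM-style boundaries).  Each TM range must intersect exactly
    one strand; strand count is unchanged and loops are re-derived.
    """
    spans = [
        (trace.index_of(a), trace.index_of(b)) for a, b in annotation.strands
    ]
    new_spans = list(spans)
    for ta, tb in tm_ranges:
        ti, tj = trace.index_of(ta), trace.index_of(tb)
        if tj < ti:
            raise AmbiguousBoundaryError(f"TM range {ta}-{tb} is reversed")
        hits = [
            k for k, (i, j) in enumerate(spans) if max(i, ti) <= min(j, tj)
        ]
        if len(hits) != 1:
            raise AmbiguousBoundaryError(
                f"TM range {ta}-{tb} intersects {len(hits)} strands "
                f"(expected exactly 1)"
            )
        k = hits[0]
        i, j = new_spans[k]
        new_spans[k] = (max(i, ti), min(j, tj))

    ids = trace.residue_ids
    strand_ranges = tuple((ids[i], ids[j]) for i, j in new_spans)
    loops: list[Range | None] = []
    for (_, j), (i2, _) in zip(new_spans, new_spans[1:]):
        loops.append((ids[j + 1], ids[i2 - 1]) if i2 - j - 1 > 0 else None)
    return SegmentAnnotation(strand_ranges, tuple(loops))
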