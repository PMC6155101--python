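"""Sign-pattern statistics over descriptor angle series.

Every angle is reduced to a sign (+ for [0, 180], - for (-180, 0)), and
consecutive same-type angles within one structure are read as sliding
windows: dyads (width 2), triads (width 3).  Gamma angles additionally get
a four-quadrant label, and dyads over quadrant labels resolve the twist
geometry more finely than bare signs.  Windows never cross structure
boundaries: group-level aggregation sums per-structure counts.

A uniformly (+,+) dyad table is the signature of a right-handed twist;
negating all angles (a mirror image) exchanges (+,+) with (-,-) and
(+,-) with (-,+).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptor import Descriptor
from .errors import ConfigError

__all__ = [
    "SIGNS",
    "QUADRANTS",
    "sign_of",
    "signs_of",
    "dyad_counts",
    "triad_counts",
    "quadrant_of",
    "quadrant_dyad_counts",
    "histogram",
    "Histogram",
    "PatternSummary",
    "GroupingScheme",
    "TM_SCHEME",
    "CYTO_SCHEME",
    "summarize",
    "aggregate",
]

SIGNS = ("+", "-")
QUADRANTS = ("+A", "+B", "-A", "-B")

DYAD_PATTERNS = tuple("".join(p) for p in product(SIGNS, repeat=2))
TRIAD_PATTERNS = tuple("".join(p) for p in product(SIGNS, repeat=3))
QUADRANT_DYAD_PATTERNS = tuple(product(QUADRANTS, repeat=2))


def sign_of(angle: float) -> str:
    """'+' for angles in [0, +180], '-' for (-180, 0).

    Zero is counted as positive, matching the convention that the
    clockwise class covers 0 to +180 degrees.
    """
    return "+" if angle >= 0 else "-"


def signs_of(angles: Iterable[float]) -> str:
    """Sign string of an angle sequence, e.g. ``"++-+"``."""
    return "".join(sign_of(a) for a in angles)


def dyad_counts(signs: str) -> dict[str, int]:
    """Counts of the 4 ordered sign pairs over a width-2 sliding window.

    The input must be the sign string of consecutive same-type angles of a
    single structure.  Strings shorter than 2 give all-zero counts.
    """
    c = Counter(signs[i : i + 2] for i in range(len(signs) - 1))
    return {p: c.get(p, 0) for p in DYAD_PATTERNS}


def triad_counts(signs: str) -> dict[str, int]:
    """Counts of the 8 ordered sign triples over a width-3 sliding window."""
    c = Counter(signs[i : i + 3] for i in range(len(signs) - 2))
    return {p: c.get(p, 0) for p in TRIAD_PATTERNS}


def quadrant_of(angle: float) -> str:
    """Quadrant label of an angle in (-180, +180].

    +A = [0, 90), +B = [90, 180], -A = [-90, 0), -B = (-180, -90).
    Boundaries are pinned left-closed (with +180 closing the top) so the
    classification is total.
    """
    if angle >= 90:
        return "+B"
    if angle >= 0:
        return "+A"
    if angle >= -90:
        return "-A"
    return "-B"


def quadrant_dyad_counts(
    gamma_angles: Sequence[float],
) -> dict[tuple[str, str], int]:
    """Counts of the 16 ordered quadrant pairs over consecutive gamma
    angles of one structure."""
    labels = [quadrant_of(a) for a in gamma_angles]
    c = Counter(zip(labels, labels[1:]))
    return {p: c.get(p, 0) for p in QUADRANT_DYAD_PATTERNS}


@dataclass(frozen=True)
class Histogram:
    """Fixed-width binned counts over [-180, 180)."""

    edges: np.ndarray  # length n_bins + 1
    counts: np.ndarray  # length n_bins, ints

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def histogram(angles: Sequence[float], bin_width: float = 10.0) -> Histogram:
    """Left-closed, right-open bins over [-180, 180); +180 is counted in
    the top bin.  ``bin_width`` must divide 360."""
    if bin_width <= 0 or abs(round(360.0 / bin_width) * bin_width - 360.0) > 1e-9:
        raise ConfigError(f"bin width {bin_width} does not divide 360")
    n_bins = int(round(360.0 / bin_width))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    a = np.asarray(list(angles), dtype=float)
    if a.size == 0:
        return Histogram(edges, np.zeros(n_bins, dtype=int))
    # fold the closed top boundary into the final bin
    a = np.where(a >= 180.0, np.nextafter(180.0, -np.inf), a)
    counts, _ = np.histogram(a, bins=edges)
    return Histogram(edges, counts.astype(int))


@dataclass
class PatternSummary:
    """All pattern statistics of one structure or one aggregated group."""

    beta_signs: list[str] = field(default_factory=list)  # one string per structure
    gamma_signs: list[str] = field(default_factory=list)
    dyad_counts_beta: dict[str, int] = field(
        default_factory=lambda: {p: 0 for p in DYAD_PATTERNS}
    )
    dyad_counts_gamma: dict[str, int] = field(
        default_factory=lambda: {p: 0 for p in DYAD_PATTERNS}
    )
    triad_counts_beta: dict[str, int] = field(
        default_factory=lambda: {p: 0 for p in TRIAD_PATTERNS}
    )
    triad_counts_gamma: dict[str, int] = field(
        default_factory=lambda: {p: 0 for p in TRIAD_PATTERNS}
    )
    quadrant_dyad_counts_gamma: dict[tuple[str, str], int] = field(
        default_factory=lambda: {p: 0 for p in QUADRANT_DYAD_PATTERNS}
    )
    beta_angles: list[float] = field(default_factory=list)
    gamma_angles: list[float] = field(default_factory=list)
    n_structures: int = 0

    def merge(self, other: "PatternSummary") -> None:
        self.beta_signs += other.beta_signs
        self.gamma_signs += other.gamma_signs
        for mine, theirs in (
            (self.dyad_counts_beta, other.dyad_counts_beta),
            (self.dyad_counts_gamma, other.dyad_counts_gamma),
            (self.triad_counts_beta, other.triad_counts_beta),
            (self.triad_counts_gamma, other.triad_counts_gamma),
            (self.quadrant_dyad_counts_gamma, other.quadrant_dyad_counts_gamma),
        ):
            for k, v in theirs.items():
                mine[k] += v
        self.beta_angles += other.beta_angles
        self.gamma_angles += other.gamma_angles
        self.n_structures += other.n_structures

    def beta_histogram(self, bin_width: float = 10.0) -> Histogram:
        return histogram(self.beta_angles, bin_width)

    def gamma_histogram(self, bin_width: float = 10.0) -> Histogram:
        return histogram(self.gamma_angles, bin_width)


def summarize(descriptor: Descriptor) -> PatternSummary:
    """Pattern statistics of a single structure."""
    beta = descriptor.beta
    gamma = descriptor.gamma
    bs, gs = signs_of(beta), signs_of(gamma)
    return PatternSummary(
        beta_signs=[bs],
        gamma_signs=[gs],
        dyad_counts_beta=dyad_counts(bs),
        dyad_counts_gamma=dyad_counts(gs),
        triad_counts_beta=triad_counts(bs),
        triad_counts_gamma=triad_counts(gs),
        quadrant_dyad_counts_gamma=quadrant_dyad_counts(gamma),
        beta_angles=list(map(float, beta)),
        gamma_angles=list(map(float, gamma)),
        n_structures=1,
    )


@dataclass(frozen=True)
class GroupingScheme:
    """Named, disjoint strand-count bins for size-group aggregation."""

    name: str
    bins: tuple[tuple[str, frozenset[int]], ...]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for label, counts in self.bins:
            if seen & counts:
                raise ConfigError(
                    f"grouping scheme {self.name!r}: bin {label!r} overlaps "
                    f"an earlier bin"
                )
            seen |= counts

    def label_for(self, n_strands: int) -> str | None:
        for label, counts in self.bins:
            if n_strands in counts:
                return label
        return None


#: membrane barrels: small (4-10 strands), medium (12-16), large (18-26)
TM_SCHEME = GroupingScheme(
    "tm",
    (
        ("4-10", frozenset(range(4, 11))),
        ("12-16", frozenset(range(12, 17))),
        ("18-26", frozenset(range(18, 27))),
    ),
)

#: cytoplasmic barrels: 4-6, 7-8 and 10-14 strands
CYTO_SCHEME = GroupingScheme(
    "cyto",
    (
        ("4-6", frozenset(range(4, 7))),
        ("7-8", frozenset(range(7, 9))),
        ("10-14", frozenset(range(10, 15))),
    ),
)


def position_table(
    descriptors: Mapping[str, Descriptor],
) -> pd.DataFrame:
    """Per-position angle table over a cohort: one row per angle with the
    structure label, position index i, angle type and value (the raw
    material of position- and strand-number-resolved scatter plots)."""
    rows = []
    for label, d in descriptors.items():
        for k, (lab, kind, v) in enumerate(zip(d.labels, d.types, d.values)):
            rows.append(
                {
                    "structure_id": label,
                    "n_strands": d.n_strands,
                    "angle_index": lab,
                    "position": k // 2 + 1,
                    "angle_type": kind,
                    "value_degrees": float(v),
                }
            )
    return pd.DataFrame(rows)


def aggregate(
    descriptors: Mapping[str, Descriptor],
    scheme: GroupingScheme,
) -> tuple[dict[str, PatternSummary], pd.DataFrame]:
    """Group structures by strand count and sum their pattern statistics.

    Returns ``(per-group summaries, per-position angle table)``.  Counts
    are summed per structure, never computed across concatenated sign
    strings, so no window spans two structures.  Structures falling
    outside all bins are logged and excluded from the group summaries
    (they still appear in the position table).
    """
    import logging

    groups: dict[str, PatternSummary] = {
        label: PatternSummary() for label, _ in scheme.bins
    }
    for label, d in descriptors.items():
        bin_label = scheme.label_for(d.n_strands)
        if bin_label is None:
            logging.getLogger(__name__).warning(
                "structure %s with %d strands falls outside scheme %r; "
                "excluded from group summaries",
                label, d.n_strands, scheme.name,
            )
            continue
        groups[bin_label].merge(summarize(d))
    return groups, position_table(descriptors)
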