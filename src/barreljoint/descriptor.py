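"""Joint extraction and the alternating beta/gamma torsion series.

A protein with n beta-strands yields 2n joint points: the C-alpha of the
first and last residue of each strand, in chain order (P_1 .. P_2n).
Sliding a window of four consecutive joints along this polyline gives
2n - 3 torsion angles.  Windows centred on a strand span
Strand-Loop-Strand and are the beta-type angles (n - 1 of them); windows
centred on a loop span Loop-Strand-Loop and are the gamma-type angles
(n - 2).  The series alternates: beta_1, gamma_1, beta_2, gamma_2, ...,
beta_{n-1}.

Geometric meaning: beta_i near 0 deg means strands S_i and S_{i+1} are
antiparallel, near +/-180 deg parallel; gamma_i near 0 deg means S_i and
S_{i+2} lie on the same side of S_{i+1}, near +/-180 deg on opposite
sides.  The sign is the standard right-handed torsion sense; a uniformly
positive series is a right-handed twist.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, MissingTerminusError
from .io import CAlphaTrace, ResidueId
from .segments import SegmentAnnotation

__all__ = [
    "JointSet",
    "Descriptor",
    "extract_joints",
    "signed_dihedral",
    "compute_descriptor",
    "expected_counts",
]

#: a cross product with norm below this (after normalizing the bond
#: vectors) is treated as collinear
COLLINEAR_TOL = 1e-9


@dataclass(frozen=True)
class JointSet:
    """The 2n joint points of an n-strand structure, in chain order.

    ``points[2i]`` is the first-residue C-alpha of strand S_{i+1} and
    ``points[2i+1]`` its last-residue C-alpha.
    """

    points: np.ndarray  # shape (2n, 3)
    residue_ids: tuple[ResidueId, ...]
    n_strands: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.shape != (2 * self.n_strands, 3):
            raise ValueError(
                f"{self.n_strands} strands require {2 * self.n_strands} "
                f"joint points, got shape {pts.shape}"
            )
        if len(self.residue_ids) != len(pts):
            raise ValueError("one residue identifier required per joint")


@dataclass(frozen=True)
class Descriptor:
    """The alternating torsion series of one structure.

    ``values[k]`` (k 0-based) is the torsion over joints P_{k+1}..P_{k+4};
    even k are beta-type, odd k gamma-type.  ``labels`` carries the
    conventional names ("beta1", "gamma1", "beta2", ...).
    """

    values: np.ndarray  # degrees, in (-180, 180]
    n_strands: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        expected = 2 * self.n_strands - 3
        if len(vals) != expected:
            raise ValueError(
                f"{self.n_strands} strands require {expected} angles, "
                f"got {len(vals)}"
            )

    @property
    def beta(self) -> np.ndarray:
        """Beta-type angles beta_1 .. beta_{n-1} (degrees)."""
        return self.values[0::2]

    @property
    def gamma(self) -> np.ndarray:
        """Gamma-type angles gamma_1 .. gamma_{n-2} (degrees)."""
        return self.values[1::2]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(
            f"beta{k // 2 + 1}" if k % 2 == 0 else f"gamma{k // 2 + 1}"
            for k in range(len(self.values))
        )

    @property
    def types(self) -> tuple[str, ...]:
        return tuple(
            "beta" if k % 2 == 0 else "gamma" for k in range(len(self.values))
        )


def expected_counts(n_strands: int) -> tuple[int, int]:
    """Number of beta- and gamma-type angles an n-strand structure carries.

    The 2n joints support 2n - 3 four-point windows, which alternate
    beta/gamma starting and ending on beta: n - 1 beta angles and n - 2
    gamma angles (0 for n = 2).
    """
    if n_strands < 2:
        raise ValueError(f"need at least 2 strands, got {n_strands}")
    return n_strands - 1, max(n_strands - 2, 0)


def extract_joints(
    trace: CAlphaTrace, annotation: SegmentAnnotation
) -> JointSet:
    """Project strand termini onto their C-alpha coordinates.

    Joint 2i-1 is the first-residue C-alpha of strand S_i, joint 2i its
    last-residue C-alpha, in chain order.
    """
    points: list[np.ndarray] = []
    resids: list[ResidueId] = []
    for start, end in annotation.strands:
        for rid in (start, end):
            try:
                idx = trace.index_of(rid)
            except KeyError:
                raise MissingTerminusError(
                    f"strand terminus {rid} has no C-alpha in chain "
                    f"{trace.chain_id}"
                ) from None
            points.append(trace.coords[idx])
            resids.append(rid)
    return JointSet(np.array(points), tuple(resids), annotation.n_strands)


def signed_dihedral(p1, p2, p3, p4) -> float:
    """Standard signed torsion angle of four points, in degrees.

    With bond vectors b1 = p2 - p1, b2 = p3 - p2, b3 = p4 - p3:

        angle = atan2(|b2| * b1 . (b2 x b3), (b1 x b2) . (b2 x b3))

    Positive is the right-handed (clockwise looking from p2 towards p3)
    rotation of p4 relative to p1.  The result lies in (-180, +180];
    exactly antiperiplanar geometries report +180.  Coincident or
    collinear points raise :class:`DegenerateGeometryError`.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2, n3 = (np.linalg.norm(b) for b in (b1, b2, b3))
    if min(n1, n2, n3) == 0.0:
        raise DegenerateGeometryError("coincident consecutive points")
    c12 = np.cross(b1 / n1, b2 / n2)
    c23 = np.cross(b2 / n2, b3 / n3)
    if np.linalg.norm(c12) < COLLINEAR_TOL or np.linalg.norm(c23) < COLLINEAR_TOL:
        raise DegenerateGeometryError("collinear bond-vector triple")
    y = n2 * np.dot(b1, np.cross(b2, b3))
    x = np.dot(np.cross(b1, b2), np.cross(b2, b3))
    angle = float(np.degrees(np.arctan2(y, x)))
    if angle <= -180.0:  # atan2 returns (-180, 180]; normalize -180 -> +180
        angle = 180.0
    return angle


def compute_descriptor(joints: JointSet, flip_sign: bool = False) -> Descriptor:
    """Slide a four-joint window along P_1..P_2n and collect the torsions.

    ``flip_sign`` negates every angle (mapping +180 to itself), for use
    when comparing against data produced under the opposite sign
    convention for "clockwise".
    """
    pts = joints.points
    values: list[float] = []
    for k in range(len(pts) - 3):
        try:
            a = signed_dihedral(pts[k], pts[k + 1], pts[k + 2], pts[k + 3])
        except DegenerateGeometryError as exc:
            kind = "beta" if k % 2 == 0 else "gamma"
            raise DegenerateGeometryError(
                f"degenerate quadruple at {kind}{k // 2 + 1} "
                f"(joints P{k + 1}..P{k + 4}): {exc}"
            ) from None
        if flip_sign:
            a = 180.0 if a == 180.0 else -a
        values.append(a)
    return Descriptor(np.array(values), joints.n_strands)


# ---------------------------------------------------------------------------
# tabular export

def descriptor_table(
    descriptor: Descriptor,
    joints: JointSet,
    structure_id: str = "",
    chain: str = "",
) -> pd.DataFrame:
    """One row per angle: index, type, value, and the four joint residues."""
    rows = []
    rid = joints.residue_ids
    for k, (label, kind, value) in enumerate(
        zip(descriptor.labels, descriptor.types, descriptor.values)
    ):
        rows.append(
            {
                "structure_id": structure_id,
                "chain": chain,
                "n_strands": descriptor.n_strands,
                "angle_index": label,
                "angle_type": kind,
                "value_degrees": value,
                "joint1": str(rid[k]),
                "joint2": str(rid[k + 1]),
                "joint3": str(rid[k + 2]),
                "joint4": str(rid[k + 3]),
            }
        )
    return pd.DataFrame(rows)


def write_descriptor(
    descriptor: Descriptor,
    joints: JointSet,
    out_dir: str | Path,
    structure_id: str,
    chain: str = "",
) -> tuple[Path, Path]:
    """Write the angle table as TSV plus a JSON mirror; returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = descriptor_table(descriptor, joints, structure_id, chain)
    tsv = out_dir / f"{structure_id}.angles.tsv"
    table.to_csv(tsv, sep="\t", index=False, float_format="%.6f")
    js = out_dir / f"{structure_id}.angles.json"
    js.write_text(
        json.dumps(
            {
                "structure_id": structure_id,
                "chain": chain,
                "n_strands": descriptor.n_strands,
                "angles": [
                    {
                        "index": lab,
                        "type": kind,
                        "value_degrees": round(float(v), 6),
                    }
                    for lab, kind, v in zip(
                        descriptor.labels, descriptor.types, descriptor.values
                    )
                ],
            },
            indent=2,
        )
    )
    return tsv, js
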