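"""Reading C-alpha traces and strand-boundary annotations.

The descriptor needs two things per structure: the ordered C-alpha trace of
one chain, and a list of beta-strand residue ranges.  Strand ranges can come
from PDB ``SHEET`` header records, from STRIDE output (``ASG`` lines with
secondary-structure code ``E``), or from a user-supplied tab-separated
segment table.  PDB parsing is delegated to :mod:`gemmi`; STRIDE output and
the segment table have no parser in the scientific Python stack, so small
dedicated readers live here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import gemmi
import numpy as np

from .errors import (
    MissingFileError,
    NoCAlphaError,
    ParseError,
    UnknownChainError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueId",
    "CAlphaTrace",
    "RawStrand",
    "read_calpha_trace",
    "read_sheet_strands",
    "read_stride_strands",
    "read_segment_table",
    "parse_residue_id",
]


class ResidueId(NamedTuple):
    """PDB residue identity: author residue number plus insertion code.

    The insertion code is ``""`` when absent.  Identity, not order: PDB
    numbering need not be monotone, so chain order always follows file
    order of the trace, never a numeric sort of these tuples.
    """

    number: int
    icode: str = ""

    def __str__(self) -> str:  # "52" or "52A"
        return f"{self.number}{self.icode}"


_RESID_RE = re.compile(r"^(-?\d+)([A-Za-z]?)$")


def parse_residue_id(text: str) -> ResidueId:
    """Parse ``"52"`` or ``"52A"`` into a :class:`ResidueId`."""
    m = _RESID_RE.match(text.strip())
    if m is None:
        raise ParseError(f"cannot parse residue identifier {text!r}")
    return ResidueId(int(m.group(1)), m.group(2))


@dataclass(frozen=True)
class CAlphaTrace:
    """Ordered C-alpha coordinates of one chain.

    ``residues[i]`` is ``(ResidueId, residue_name)`` and ``coords[i]`` the
    matching position in Angstrom.  Order is file order of the chain.
    """

    chain_id: str
    residues: tuple[tuple[ResidueId, str], ...]
    coords: np.ndarray  # shape (N, 3), float64

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.coords):
            raise ValueError("residues and coords must have equal length")
        ids = [r for r, _ in self.residues]
        if len(set(ids)) != len(ids):
            raise ValueError("residue identifiers must be unique in a trace")
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def residue_ids(self) -> tuple[ResidueId, ...]:
        return tuple(r for r, _ in self.residues)

    def index_of(self, resid: ResidueId) -> int:
        """Position of a residue in the trace (raises KeyError if absent)."""
        try:
            return self._index[resid]
        except AttributeError:
            object.__setattr__(
                self, "_index", {r: i for i, (r, _) in enumerate(self.residues)}
            )
            return self._index[resid]


@dataclass(frozen=True)
class RawStrand:
    """One beta-strand residue range as reported by an annotation source,
    before validation/merging."""

    start: ResidueId
    end: ResidueId
    sheet_id: str = ""
    source: str = "user_table"  # sheet_record | stride | user_table | tm_boundary
    chain_id: str = ""


def _open_structure(path: str | Path) -> gemmi.Structure:
    path = Path(path)
    if not path.is_file():
        raise MissingFileError(f"no such structure file: {path}")
    try:
        return gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path} as PDB/mmCIF: {exc}") from exc


def _pick_calpha(residue: gemmi.Residue) -> gemmi.Atom | None:
    """Select the C-alpha of a residue, resolving alternate locations by
    highest occupancy, ties broken by altloc identifier ascending."""
    cas = [a for a in residue if a.name == "CA"]
    if not cas:
        return None
    return min(cas, key=lambda a: (-a.occ, a.altloc))


def read_calpha_trace(
    path: str | Path, chain: str, model_index: int = 1
) -> CAlphaTrace:
    """Read the C-alpha trace of one chain from a PDB (or mmCIF) file.

    Residues without a C-alpha atom are skipped with a logged warning.
    ``model_index`` is 1-based; the default first model matches the
    single-conformer X-ray structures the descriptor is meant for.
    """
    st = _open_structure(path)
    if not 1 <= model_index <= len(st):
        raise ValueError(
            f"model_index {model_index} out of range (file has {len(st)} models)"
        )
    model = st[model_index - 1]
    chain_obj = model.find_chain(chain)
    if chain_obj is None:
        raise UnknownChainError(
            f"chain {chain!r} not in model {model_index} of {path} "
            f"(available: {[c.name for c in model]})"
        )
    residues: list[tuple[ResidueId, str]] = []
    coords: list[list[float]] = []
    for res in chain_obj:
        ca = _pick_calpha(res)
        rid = ResidueId(res.seqid.num, res.seqid.icode.strip())
        if ca is None:
            logger.warning(
                "%s chain %s: residue %s %s has no C-alpha, skipped",
                path, chain, res.name, rid,
            )
            continue
        residues.append((rid, res.name))
        coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
    if not residues:
        raise NoCAlphaError(f"chain {chain!r} of {path} contains no C-alpha atoms")
    return CAlphaTrace(chain, tuple(residues), np.array(coords))


def read_sheet_strands(path: str | Path, chain: str) -> list[RawStrand]:
    """Strand ranges from the ``SHEET`` records of a PDB header.

    Returns one :class:`RawStrand` per record on the requested chain, in
    record order, with the sheet identifier preserved.  An input without
    SHEET records yields an empty list and a warning, not an error: the
    caller may still supply STRIDE or table annotations.
    """
    st = _open_structure(path)
    strands: list[RawStrand] = []
    for sheet in st.sheets:
        for s in sheet.strands:
            if s.start.chain_name != chain:
                continue
            strands.append(
                RawStrand(
                    start=ResidueId(s.start.res_id.seqid.num,
                                    s.start.res_id.seqid.icode.strip()),
                    end=ResidueId(s.end.res_id.seqid.num,
                                  s.end.res_id.seqid.icode.strip()),
                    sheet_id=sheet.name,
                    source="sheet_record",
                    chain_id=chain,
                )
            )
    if not strands:
        logger.warning("%s: no SHEET records for chain %s", path, chain)
    return strands


def read_stride_strands(path: str | Path, chain: str) -> list[RawStrand]:
    """Strand ranges from STRIDE plain-text output.

    Contiguous runs of residues assigned the extended-strand state
    (one-letter code ``E`` in ``ASG`` lines) on the requested chain become
    strands, in chain order.
    """
    path = Path(path)
    if not path.is_file():
        raise MissingFileError(f"no such STRIDE file: {path}")
    strands: list[RawStrand] = []
    run: list[ResidueId] = []

    def close_run() -> None:
        if run:
            strands.append(
                RawStrand(run[0], run[-1], source="stride", chain_id=chain)
            )
            run.clear()

    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith("ASG"):
            continue
        fields = line.split()
        # ASG <resname> <chain> <pdb-resnum[icode]> <ordinal> <code> <name> ...
        if len(fields) < 6:
            raise ParseError(f"{path}:{lineno}: malformed ASG line: {line!r}")
        _, _resname, line_chain, pdb_num, _ordinal, code = fields[:6]
        try:
            rid = parse_residue_id(pdb_num)
        except ParseError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if line_chain != chain:
            close_run()
            continue
        if code.upper() == "E":
            run.append(rid)
        else:
            close_run()
    close_run()
    return strands


def read_segment_table(path: str | Path) -> list[RawStrand]:
    """Strand ranges from a tab-separated table with header
    ``chain<TAB>start<TAB>end`` and residue identifiers written as
    ``number[icode]`` (``52``, ``52A``)."""
    path = Path(path)
    if not path.is_file():
        raise MissingFileError(f"no such segment table: {path}")
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file (header row required)")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    if header[:3] != ["chain", "start", "end"]:
        raise ParseError(
            f"{path}:1: expected header 'chain\\tstart\\tend', got {lines[0]!r}"
        )
    strands: list[RawStrand] = []
    for rowno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{rowno}: expected 3 tab-separated fields")
        chain_id = fields[0].strip()
        try:
            start = parse_residue_id(fields[1])
            end = parse_residue_id(fields[2])
        except ParseError as exc:
            raise ParseError(f"{path}:{rowno}: {exc}") from exc
        if (end.number, end.icode) < (start.number, start.icode):
            raise ParseError(
                f"{path}:{rowno}: end {end} precedes start {start}"
            )
        strands.append(
            RawStrand(start, end, source="user_table", chain_id=chain_id)
        )
    return strands


def read_tm_ranges(path: str | Path) -> list[tuple[ResidueId, ResidueId]]:
    """Membrane-embedded segment boundaries from a TSV with header
    ``start<TAB>end`` (one row per TM segment, OPM-style)."""
    path = Path(path)
    if not path.is_file():
        raise MissingFileError(f"no such TM-range table: {path}")
    lines = path.read_text().splitlines()
    if not lines or [h.strip().lower() for h in lines[0].split("\t")][:2] != ["start", "end"]:
        raise ParseError(f"{path}: expected header 'start\\tend'")
    ranges = []
    for rowno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{rowno}: expected 2 tab-separated fields")
        ranges.append((parse_residue_id(fields[0]), parse_residue_id(fields[1])))
    return ranges
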