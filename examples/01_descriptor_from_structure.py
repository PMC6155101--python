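"""Compute the beta/gamma joint descriptor of a structure file.

Builds an 8-stranded right-handed barrel, writes it out as a plain PDB
with SHEET records, then runs the full reading pipeline: C-alpha trace ->
strand annotation -> joint points -> alternating torsion series.
"""

import tempfile
from pathlib import Path

from barreljoint import (
    build_annotation,
    compute_descriptor,
    extract_joints,
    generate_barrel,
    membrane_barrel_spec,
    read_calpha_trace,
    read_sheet_strands,
    write_pdb,
)

with tempfile.TemporaryDirectory() as td:
    trace, annotation = generate_barrel(membrane_barrel_spec(8))
    path = write_pdb(trace, annotation, Path(td) / "barrel8.pdb")

    trace = read_calpha_trace(path, chain="A")
    strands = read_sheet_strands(path, chain="A")
    annotation = build_annotation(strands, trace, merge_gap=0)
    joints = extract_joints(trace, annotation)
    descriptor = compute_descriptor(joints)

print(f"{annotation.n_strands} strands -> {len(joints.points)} joints "
      f"-> {len(descriptor.values)} angles")
for label, value in zip(descriptor.labels, descriptor.values):
    print(f"  {label:7s} {value:8.2f} deg")
print(
    "\nbeta near 0 deg: adjacent strands antiparallel; positive beta and\n"
    "gamma throughout: a right-handed twist, the membrane-barrel signature."
)
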