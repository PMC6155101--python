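"""Sign patterns separate right- from left-handed barrels.

A right-handed antiparallel barrel gives uniformly positive beta and
gamma angles, hence exclusively (+,+) dyads and gamma dyads in the
positive quadrants; its mirror image gives the exchanged tables.
"""

from barreljoint import (
    compute_descriptor,
    extract_joints,
    generate_barrel,
    membrane_barrel_spec,
    reflect,
    summarize,
)

trace, annotation = generate_barrel(membrane_barrel_spec(12))
right = summarize(compute_descriptor(extract_joints(trace, annotation)))
left = summarize(
    compute_descriptor(extract_joints(reflect(trace), annotation))
)

print("right-handed barrel (n=12)")
print("  beta signs :", right.beta_signs[0])
print("  gamma signs:", right.gamma_signs[0])
print("  beta dyads :", {k: v for k, v in right.dyad_counts_beta.items() if v})
print("  gamma quadrant dyads:",
      {"|".join(k): v
       for k, v in right.quadrant_dyad_counts_gamma.items() if v})
print("mirror image")
print("  beta dyads :", {k: v for k, v in left.dyad_counts_beta.items() if v})
print(
    "\n(+,+) dominance = right-handed twist; the mirror swaps it for (-,-)."
)
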