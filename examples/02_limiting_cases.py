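"""The exact geometric limiting cases that pin the angle semantics.

Flat (coplanar) sheets and a folded three-strand fixture realise the four
reference arrangements exactly: antiparallel vs parallel strand pairs for
beta, same-side vs opposite-side strand triples for gamma.
"""

from barreljoint import (
    compute_descriptor,
    extract_joints,
    generate_flat_sheet,
    generate_gamma_fixture,
)


def angles(pair):
    return compute_descriptor(extract_joints(*pair))


d = angles(generate_flat_sheet(4))
print("flat antiparallel sheet   beta =", d.beta, " gamma =", d.gamma)

d = angles(generate_flat_sheet(3, parallel=True))
print("flat parallel sheet       beta =", d.beta)

d = angles(generate_gamma_fixture(opposite_side=False))
print("S3 folded back (same side of S2 as S1)   gamma_1 =", d.gamma[0])

d = angles(generate_gamma_fixture(opposite_side=True))
print("S3 extending away (opposite side)        gamma_1 =", d.gamma[0])

print(
    "\nbeta: 0 = antiparallel pair, 180 = parallel pair.\n"
    "gamma: 0 = S_i and S_i+2 on the same side of S_i+1, 180 = opposite."
)
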