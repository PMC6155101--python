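"""Independent brute-force torsion oracle.

Deliberately built by a different construction than the library: project
the outer bonds onto the plane normal to the central bond and take the
signed angle between the projections.  Used only as a cross-check.
"""

import numpy as np


def torsion_oracle(p1, p2, p3, p4) -> float:
    """Signed torsion in degrees via explicit projection onto the plane
    perpendicular to the central bond."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    axis = p3 - p2
    n = axis / np.linalg.norm(axis)
    u = (p1 - p2) - np.dot(p1 - p2, n) * n
    v = (p4 - p3) - np.dot(p4 - p3, n) * n
    angle = np.degrees(np.arctan2(np.dot(n, np.cross(u, v)), np.dot(u, v)))
    if angle <= -180.0:
        angle = 180.0
    return float(angle)
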