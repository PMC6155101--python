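import numpy as np
import pytest
from _oracle import torsion_oracle

from barreljoint import (
    DegenerateGeometryError,
    JointSet,
    ResidueId,
    compute_descriptor,
    expected_counts,
    extract_joints,
    generate_barrel,
    membrane_barrel_spec,
    signed_dihedral,
)
from barreljoint.descriptor import descriptor_table

WORKED_QUADRUPLES = [
    # planar, p1/p4 on the same side: the antiparallel strand-pair case
    (((0, 0, 0), (0, 4, 0), (2, 4, 0), (2, 0, 0)), 0.0),
    # planar, opposite sides: the parallel strand-pair case
    (((0, 0, 0), (0, 4, 0), (2, 0, 0), (2, 4, 0)), 180.0),
    (((1, 0, 0), (0, 0, 0), (0, 0, 1), (0, 1, 1)), 90.0),
]


def random_quadruples(n, seed=0):
    rng = np.random.default_rng(seed)
    while n > 0:
        q = rng.normal(scale=5.0, size=(4, 3))
        b = np.diff(q, axis=0)
        crosses = [np.cross(b[0], b[1]), np.cross(b[1], b[2])]
        norms = [np.linalg.norm(x) for x in b]
        if min(norms) < 1e-3 or min(np.linalg.norm(c) for c in crosses) < 1e-3:
            continue
        yield q
        n -= 1


class TestSignedDihedral:
    @pytest.mark.parametrize("quad,expected", WORKED_QUADRUPLES)
    def test_worked_quadruples(self, quad, expected):
        assert signed_dihedral(*quad) == pytest.approx(expected, abs=1e-9)

    def test_matches_independent_oracle(self):
        for q in random_quadruples(10_000, seed=12345):
            a = signed_dihedral(*q)
            b = torsion_oracle(*q)
            assert abs(a - b) <= 1e-6 or abs(abs(a) + abs(b) - 360) <= 1e-6

    def test_reversal_symmetry(self):
        for q in random_quadruples(500, seed=7):
            assert signed_dihedral(*q) == pytest.approx(
                signed_dihedral(*q[::-1]), abs=1e-9
            )

    def test_range_and_top_boundary(self):
        for q in random_quadruples(500, seed=8):
            a = signed_dihedral(*q)
            assert -180.0 < a <= 180.0
        # exactly antiperiplanar reports +180, never -180
        assert signed_dihedral(
            (0, 0, 0), (0, 4, 0), (2, 0, 0), (2, 4, 0)
        ) == 180.0

    def test_coincident_points_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            signed_dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))

    def test_collinear_triple_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            signed_dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (2, 1, 0))


class TestDescriptorSeries:
    @pytest.mark.parametrize("n", [2, 4, 8, 12, 16, 22, 26])
    def test_count_law(self, n):
        trace, ann = generate_barrel(membrane_barrel_spec(n))
        d = compute_descriptor(extract_joints(trace, ann))
        nb, ng = expected_counts(n)
        assert len(d.values) == 2 * n - 3
        assert len(d.beta) == nb
        assert len(d.gamma) == ng

    def test_rigid_motion_invariance(self):
        trace, ann = generate_barrel(membrane_barrel_spec(8))
        joints = extract_joints(trace, ann)
        ref = compute_descriptor(joints).values

        rng = np.random.default_rng(3)
        # random rotation via QR with positive determinant
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = JointSet(
            joints.points @ q.T + rng.normal(scale=30.0, size=3),
            joints.residue_ids,
            joints.n_strands,
        )
        assert np.abs(compute_descriptor(moved).values - ref).max() <= 1e-9

    def test_mirror_antisymmetry(self):
        trace, ann = generate_barrel(membrane_barrel_spec(8))
        joints = extract_joints(trace, ann)
        ref = compute_descriptor(joints).values
        mirrored = JointSet(
            joints.points * np.array([1.0, 1.0, -1.0]),
            joints.residue_ids,
            joints.n_strands,
        )
        out = compute_descriptor(mirrored).values
        expected = np.where(ref == 180.0, 180.0, -ref)
        assert np.abs(out - expected).max() <= 1e-9

    def test_flip_sign_flag(self):
        trace, ann = generate_barrel(membrane_barrel_spec(8))
        joints = extract_joints(trace, ann)
        a = compute_descriptor(joints).values
        b = compute_descriptor(joints, flip_sign=True).values
        assert np.allclose(b, np.where(a == 180.0, 180.0, -a))

    def test_labels_alternate(self):
        trace, ann = generate_barrel(membrane_barrel_spec(4))
        d = compute_descriptor(extract_joints(trace, ann))
        assert d.labels == ("beta1", "gamma1", "beta2", "gamma2", "beta3")

    def test_degenerate_quadruple_names_angle(self):
        pts = np.array(
            [[0, 0, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0],
             [3, 1, 0], [3, 2, 0], [4, 2, 0], [4, 3, 0]],
            dtype=float,
        )
        joints = JointSet(pts, tuple(ResidueId(i + 1) for i in range(8)), 4)
        with pytest.raises(DegenerateGeometryError, match="beta1"):
            compute_descriptor(joints)


class TestExtractJoints:
    @pytest.mark.parametrize("n,expected", [(8, 16), (4, 8), (2, 4)])
    def test_two_joints_per_strand(self, n, expected):
        trace, ann = generate_barrel(membrane_barrel_spec(n))
        joints = extract_joints(trace, ann)
        assert len(joints.points) == expected
        # joints are exactly the strand-terminus coordinates, in chain order
        for i, (start, end) in enumerate(ann.strands):
            assert joints.residue_ids[2 * i] == start
            assert joints.residue_ids[2 * i + 1] == end
            np.testing.assert_array_equal(
                joints.points[2 * i], trace.coords[trace.index_of(start)]
            )


class TestExpectedCounts:
    @pytest.mark.parametrize(
        "n,expected", [(12, (11, 10)), (8, (7, 6)), (2, (1, 0)), (3, (2, 1))]
    )
    def test_values(self, n, expected):
        assert expected_counts(n) == expected

    def test_rejects_degenerate_strand_numbers(self):
        with pytest.raises(ValueError):
            expected_counts(1)


def test_descriptor_table_carries_joint_residues():
    trace, ann = generate_barrel(membrane_barrel_spec(4))
    joints = extract_joints(trace, ann)
    table = descriptor_table(
        compute_descriptor(joints), joints, "demo", "A"
    )
    assert list(table["angle_index"]) == [
        "beta1", "gamma1", "beta2", "gamma2", "beta3"
    ]
    assert table.loc[0, "joint1"] == str(joints.residue_ids[0])
    assert table.loc[4, "joint4"] == str(joints.residue_ids[7])
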