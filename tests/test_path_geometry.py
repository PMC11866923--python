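"""Path data model, superposition/MSD metric, PCVs and path conditioning."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from neqbind import (
    Frame,
    PathGeometryError,
    ReferencePath,
    consecutive_msds,
    lambda_heuristic,
    msd,
    pad_endpoints,
    pcv_s,
    pcv_z,
    reparametrize_equidistant,
    smooth_path,
    superpose,
)

RNG = np.random.Generator(np.random.Philox(np.random.SeedSequence(42)))


def random_frame(n_atoms: int, scale: float = 1.0) -> Frame:
    coords = RNG.normal(scale=scale, size=(n_atoms, 3))
    return Frame(coords, tuple(f"A{i}" for i in range(n_atoms)))


def atom_line_path(positions, lambda_val=None) -> ReferencePath:
    """Single-atom frames at 1-D positions along x (no alignment)."""
    frames = [Frame(np.array([[p, 0.0, 0.0]]), ("X",)) for p in positions]
    return ReferencePath(frames, align_idx=None, cv_idx=(0,), lambda_val=lambda_val)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def brute_force_min_rmsd(mobile: Frame, reference: Frame, idx) -> float:
    """Independent oracle: minimise RMSD over rotations by dense sampling
    of random quaternions followed by local refinement on the rotation
    vector. Never calls the Kabsch path under test."""
    idx = np.asarray(idx)
    a = mobile.coords[idx] - mobile.coords[idx].mean(axis=0)
    b = reference.coords[idx] - reference.coords[idx].mean(axis=0)

    def rmsd_of(rotvec):
        r = Rotation.from_rotvec(rotvec)
        return float(np.sqrt(np.mean(np.sum((r.apply(a) - b) ** 2, axis=1))))

    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(7)))
    candidates = Rotation.random(4000, random_state=rng).as_rotvec()
    scores = [rmsd_of(v) for v in candidates]
    best = candidates[np.argsort(scores)[:5]]
    refined = [
        minimize(rmsd_of, v, method="Nelder-Mead", options={"xatol": 1e-12, "fatol": 1e-14})
        for v in best
    ]
    return min(r.fun for r in refined)


class TestSuperpose:
    def test_identity(self):
        f = random_frame(6)
        moved, rmsd = superpose(f, f, range(6))
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(moved.coords, f.coords, atol=1e-12)

    def test_recovers_exact_rigid_motion(self):
        f = random_frame(8)
        rot = Rotation.from_euler("z", 90, degrees=True)
        g = Frame(rot.apply(f.coords) + np.array([1.0, -2.0, 0.5]), f.atom_ids)
        moved, rmsd = superpose(g, f, range(8))
        assert rmsd < 1e-10
        np.testing.assert_allclose(moved.coords, f.coords, atol=1e-9)

    def test_matches_brute_force_rotation_search(self):
        ref = random_frame(10)
        noisy = Frame(
            ref.coords + RNG.normal(scale=0.05, size=ref.coords.shape),
            ref.atom_ids,
        )
        rot = Rotation.from_euler("xyz", [30, -50, 110], degrees=True)
        mobile = Frame(rot.apply(noisy.coords) + 0.7, ref.atom_ids)
        _, rmsd = superpose(mobile, ref, range(10))
        oracle = brute_force_min_rmsd(mobile, ref, range(10))
        assert rmsd == pytest.approx(oracle, abs=1e-6)

    def test_no_reflection(self):
        # a chiral 4-atom set and its mirror image: an improper transform
        # would give rmsd 0, a proper rotation cannot
        coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        f = Frame(coords, ("a", "b", "c", "d"))
        mirror = Frame(coords * np.array([1, 1, -1.0]), f.atom_ids)
        _, rmsd = superpose(mirror, f, range(4))
        assert rmsd > 0.1

    @pytest.mark.parametrize(
        "coords",
        [
            np.array([[0, 0, 0], [1, 0, 0]], float),                 # too few
            np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float),      # collinear
        ],
    )
    def test_degenerate_alignment_rejected(self, coords):
        ids = tuple("abc"[: len(coords)])
        f = Frame(coords, ids)
        with pytest.raises(PathGeometryError):
            superpose(f, f, range(len(coords)))

    def test_round_trip_rmsd(self):
        a, b = random_frame(7), random_frame(7)
        b = Frame(b.coords, a.atom_ids)
        _, r_ab = superpose(a, b, range(7))
        _, r_ba = superpose(b, a, range(7))
        assert r_ab == pytest.approx(r_ba, abs=1e-9)


class TestMsd:
    def test_zero_for_identical(self):
        f = random_frame(5)
        assert msd(f, f, None, range(5)) == pytest.approx(0.0, abs=1e-14)

    def test_single_atom_displacement(self):
        a = Frame(np.zeros((1, 3)), ("X",))
        b = Frame(np.array([[0.3, 0.0, 0.0]]), ("X",))
        assert msd(a, b, None, (0,)) == pytest.approx(0.09, abs=1e-12)

    def test_symmetric_and_matches_direct_sum(self):
        a, b = random_frame(9), random_frame(9)
        b = Frame(b.coords, a.atom_ids)
        align = (0, 1, 2, 3)
        cv = (4, 5, 6, 7, 8)
        forward = msd(a, b, align, cv)
        backward = msd(b, a, align, cv)
        assert forward == pytest.approx(backward, abs=1e-10)
        # direct-sum oracle after an explicit superposition
        b_fit, _ = superpose(b, a, align)
        direct = np.mean(
            np.sum((a.coords[list(cv)] - b_fit.coords[list(cv)]) ** 2, axis=1)
        )
        assert forward == pytest.approx(direct, abs=1e-12)

    def test_empty_cv_rejected(self):
        f = random_frame(4)
        with pytest.raises(PathGeometryError):
            msd(f, f, None, ())


# ---------------------------------------------------------------------------
# Path collective variables
# ---------------------------------------------------------------------------

class TestPcv:
    def test_endpoints_dominant_regime(self):
        path = atom_line_path([0.0, 1.0, 2.0], lambda_val=100.0)
        assert pcv_s(path.frames[0], path) < 0.01
        assert pcv_s(path.frames[-1], path) > 0.99

    def test_symmetric_midpoint_is_half(self):
        path = atom_line_path([0.0, 1.0, 2.0], lambda_val=3.0)
        s = pcv_s(Frame(np.array([[1.0, 0, 0]]), ("X",)), path)
        assert s == pytest.approx(0.5, abs=1e-12)

    def test_z_zero_on_node(self):
        path = atom_line_path([0.0, 1.0], lambda_val=50.0)
        # on a node, min distance is 0; softmin correction ~ ln(2)/λ
        z = pcv_z(path.frames[0], path)
        assert abs(z) < np.log(2) / 50.0 + 1e-12

    def test_z_softmin_limit(self):
        h = 0.4
        query = Frame(np.array([[1.0, h, 0.0]]), ("X",))
        path = atom_line_path([0.0, 1.0, 2.0], lambda_val=200.0)
        # distances: 1+h², h², 1+h² → softmin → h² as λ grows
        assert pcv_z(query, path) == pytest.approx(h**2, abs=1e-3)

    def test_z_bounds_tighten_with_lambda(self):
        query = Frame(np.array([[0.7, 0.2, 0.0]]), ("X",))
        gaps = []
        for lam in (5.0, 50.0, 500.0):
            path = atom_line_path([0.0, 1.0, 2.0], lambda_val=lam)
            d_min = min(
                msd(query, node, None, (0,)) for node in path.frames
            )
            z = pcv_z(query, path)
            assert z <= d_min + 1e-12
            assert z >= d_min - np.log(3) / lam - 1e-12
            gaps.append(d_min - z)
        assert gaps[0] > gaps[1] > gaps[2]

    def test_s_monotone_along_node_sweep(self):
        path = atom_line_path(np.arange(8.0))
        path.lambda_val = lambda_heuristic(path)
        values = [pcv_s(f, path) for f in path.frames]
        assert np.all(np.diff(values) > 0)

    def test_rigid_motion_invariance(self):
        # 4 fixed "pocket" atoms (alignment set) + 3 "ligand" atoms that
        # translate along the path (CV set)
        pocket = RNG.normal(scale=0.8, size=(4, 3))
        ligand = RNG.normal(scale=0.2, size=(3, 3)) + np.array([1.0, 0, 0])
        ids = tuple(f"P{i}" for i in range(4)) + tuple(f"L{i}" for i in range(3))
        nodes = [
            Frame(np.vstack([pocket, ligand + np.array([0.5 * i, 0, 0])]), ids)
            for i in range(4)
        ]
        path = ReferencePath(nodes, align_idx=(0, 1, 2, 3), cv_idx=(4, 5, 6))
        path.lambda_val = lambda_heuristic(path)
        query = Frame(
            np.vstack([pocket, ligand + np.array([0.8, 0.1, -0.05])]), ids
        )
        s0, z0 = pcv_s(query, path), pcv_z(query, path)
        rot = Rotation.from_euler("xyz", [17.0, -123.0, 55.0], degrees=True)
        moved = Frame(rot.apply(query.coords) + np.array([3.0, -1.0, 2.0]),
                      query.atom_ids)
        assert pcv_s(moved, path) == pytest.approx(s0, abs=1e-8)
        assert pcv_z(moved, path) == pytest.approx(z0, abs=1e-8)

    def test_short_path_rejected(self):
        path = atom_line_path([0.0], lambda_val=1.0)
        with pytest.raises(PathGeometryError):
            pcv_s(path.frames[0], path)


class TestLambdaHeuristic:
    def test_uniform_gaps(self):
        # consecutive MSD 0.1 nm² → λ = 2.3/0.1 = 23
        step = np.sqrt(0.1)
        path = atom_line_path(np.arange(5) * step)
        assert lambda_heuristic(path) == pytest.approx(23.0, rel=1e-12)

    def test_mixed_gaps(self):
        # gaps {0.1, 0.3} nm² → mean 0.2 → λ = 11.5
        path = atom_line_path([0.0, np.sqrt(0.1), np.sqrt(0.1) + np.sqrt(0.3)])
        assert lambda_heuristic(path) == pytest.approx(11.5, rel=1e-12)

    def test_scaling_dimension(self):
        path = atom_line_path([0.0, 0.4, 0.9, 1.2])
        s = 2.5
        scaled = atom_line_path([0.0, 0.4 * s, 0.9 * s, 1.2 * s])
        assert lambda_heuristic(scaled) == pytest.approx(
            lambda_heuristic(path) / s**2, rel=1e-10
        )

    def test_duplicate_nodes_rejected(self):
        path = atom_line_path([0.0, 0.0, 1.0])
        with pytest.raises(PathGeometryError):
            lambda_heuristic(path)


# ---------------------------------------------------------------------------
# Path conditioning
# ---------------------------------------------------------------------------

class TestReparametrize:
    def test_closed_form_three_nodes(self):
        # nodes at 0, 1, 3 → equal spacing puts the middle node at 1.5
        path = atom_line_path([0.0, 1.0, 3.0])
        out = reparametrize_equidistant(path, n_out=3)
        xs = [f.coords[0, 0] for f in out.frames]
        np.testing.assert_allclose(xs, [0.0, 1.5, 3.0], atol=1e-9)
        np.testing.assert_allclose(consecutive_msds(out), [2.25, 2.25], atol=1e-9)

    def test_already_equidistant_unchanged(self):
        path = atom_line_path([0.0, 1.0, 2.0, 3.0])
        out = reparametrize_equidistant(path)
        np.testing.assert_array_equal(out.coords_array(), path.coords_array())
        assert out.meta["spread"] == pytest.approx(0.0, abs=1e-14)

    def test_spread_below_tol_oracle_recheck(self):
        rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(5)))
        xs = np.cumsum(rng.uniform(0.2, 1.5, size=9))
        path = atom_line_path(np.concatenate([[0.0], xs]))
        out = reparametrize_equidistant(path, n_out=12, tol=1e-4)
        gaps = consecutive_msds(out)  # independent direct recomputation
        assert gaps.std() / gaps.mean() < 1e-4
        assert out.meta["converged"]

    def test_endpoints_bitwise_and_length(self):
        rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(9)))
        frames = [random_frame(5)]
        for _ in range(6):
            frames.append(
                Frame(frames[-1].coords + rng.normal(0.3, 0.1, (5, 3)),
                      frames[0].atom_ids)
            )
        path = ReferencePath(frames, align_idx=None, cv_idx=tuple(range(5)))
        out = reparametrize_equidistant(path, tol=1e-3, max_iter=500)
        np.testing.assert_array_equal(out.frames[0].coords, path.frames[0].coords)
        np.testing.assert_array_equal(out.frames[-1].coords, path.frames[-1].coords)
        total = lambda p: np.sqrt(consecutive_msds(p)).sum()
        assert total(out) <= total(path) + 1e-6


class TestPadEndpoints:
    def test_zero_pad_identity(self):
        path = atom_line_path([0.0, 1.0])
        assert pad_endpoints(path, 0) is path

    def test_collinear_extrapolation(self):
        path = atom_line_path([0.0, 1.0, 2.0])
        out = pad_endpoints(path, 1)
        xs = [f.coords[0, 0] for f in out.frames]
        np.testing.assert_allclose(xs, [-1.0, 0.0, 1.0, 2.0, 3.0], atol=1e-12)

    def test_boundary_msd_matches_terminal_step(self):
        rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(13)))
        frames = [random_frame(4)]
        for _ in range(3):
            frames.append(
                Frame(frames[-1].coords + rng.normal(0.2, 0.05, (4, 3)),
                      frames[0].atom_ids)
            )
        path = ReferencePath(frames, align_idx=None, cv_idx=(0, 1, 2, 3))
        out = pad_endpoints(path, 2)
        gaps = consecutive_msds(out)
        assert gaps[0] == pytest.approx(gaps[2], abs=1e-9)   # front pads
        assert gaps[1] == pytest.approx(gaps[2], abs=1e-9)
        assert gaps[-1] == pytest.approx(gaps[-3], abs=1e-9)  # back pads

    def test_originals_index_shifted(self):
        path = atom_line_path([0.0, 1.0, 2.0])
        out = pad_endpoints(path, 2)
        for i, f in enumerate(path.frames):
            np.testing.assert_array_equal(out.frames[i + 2].coords, f.coords)


class TestSmoothPath:
    def test_window_one_identity(self):
        path = atom_line_path([0.0, 1.0, 0.0, 1.0])
        assert smooth_path(path, 1) is path

    def test_zigzag_shortened(self):
        path = atom_line_path([0.0, 1.0, 0.0, 1.0])
        out = smooth_path(path, 3)
        length = lambda p: np.sqrt(consecutive_msds(p)).sum()
        assert length(out) < length(path)
        # interior nodes pulled toward the local mean
        assert out.frames[1].coords[0, 0] == pytest.approx(1.0 / 3.0)

    def test_straight_line_unchanged(self):
        path = atom_line_path([0.0, 1.0, 2.0, 3.0])
        out = smooth_path(path, 3)
        np.testing.assert_allclose(
            out.coords_array(), path.coords_array(), atol=1e-12
        )

    def test_even_window_rejected(self):
        path = atom_line_path([0.0, 1.0, 2.0])
        with pytest.raises(PathGeometryError):
            smooth_path(path, 2)
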