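"""Molecular reference paths and path collective variables (PCVs).

A reference path is an ordered sequence of molecular configurations
(nodes) tracing a transition such as ligand unbinding. Two collective
variables are defined with respect to it:

* ``S(x)`` — progress along the path, normalised to [0, 1] with the first
  node mapping to 0 (bound state) and the last to 1 (unbound state);
* ``Z(x)`` — orthogonal deviation from the path, a softmin over the
  per-node mean square deviations, in nm².

Both are built from softmin-weighted distances ``d_i = MSD(x, x_i)`` with
smoothness parameter λ (nm⁻²):

    S(x) = Σᵢ (i−1)·e^(−λ dᵢ) / [(p−1)·Σᵢ e^(−λ dᵢ)]      (i = 1..p)
    Z(x) = −(1/λ)·ln Σᵢ e^(−λ dᵢ)

The distance metric is the mean square deviation after optimal rigid
superposition on a designated alignment atom set, so Z carries nm² and
matches wall thresholds specified in nm². Well-behaved PCVs require
consecutive path nodes equidistant in this metric, which
:func:`reparametrize_equidistant` enforces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation


class PathGeometryError(ValueError):
    """Raised for invalid frames, paths or degenerate alignments."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Frame:
    """One molecular configuration: atom positions in nm plus labels."""

    coords: np.ndarray  # (n_atoms, 3), nm
    atom_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "atom_ids", tuple(self.atom_ids))
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise PathGeometryError(
                f"coords must be (n_atoms>=1, 3), got shape {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise PathGeometryError("coords contain non-finite values")
        if len(self.atom_ids) != coords.shape[0]:
            raise PathGeometryError("atom_ids length does not match coords")
        if len(set(self.atom_ids)) != len(self.atom_ids):
            raise PathGeometryError("atom_ids must be unique")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class ReferencePath:
    """Ordered path nodes defining the PCV metric space.

    Parameters
    ----------
    frames : sequence of Frame
        Path nodes, length p >= 2 (a single node is tolerated only as an
        intermediate artefact; PCV evaluation requires p >= 2).
    align_idx : sequence of int or None
        Atom indices used for rigid superposition before the MSD
        (typically pocket heavy atoms). ``None`` means frames are already
        expressed in a common frame and no superposition is applied.
    cv_idx : sequence of int
        Atom indices entering the MSD (ligand, optionally pocket atoms).
    lambda_val : float or None
        Smoothness parameter λ in nm⁻²; set via :func:`lambda_heuristic`
        if not given.
    """

    frames: list[Frame]
    align_idx: tuple[int, ...] | None = None
    cv_idx: tuple[int, ...] | None = None
    lambda_val: float | None = None
    units: str = "nm"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = list(self.frames)
        if not self.frames:
            raise PathGeometryError("path needs at least one frame")
        ids = self.frames[0].atom_ids
        for i, f in enumerate(self.frames):
            if f.atom_ids != ids:
                raise PathGeometryError(f"frame {i} has mismatching atom_ids")
        n = self.frames[0].n_atoms
        if self.cv_idx is None:
            self.cv_idx = tuple(range(n))
        else:
            self.cv_idx = tuple(int(i) for i in self.cv_idx)
        if len(self.cv_idx) == 0:
            raise PathGeometryError("cv_idx must be non-empty")
        if self.align_idx is not None:
            self.align_idx = tuple(int(i) for i in self.align_idx)
            if len(self.align_idx) == 0:
                raise PathGeometryError("align_idx must be non-empty or None")
            if max(self.align_idx) >= n or min(self.align_idx) < 0:
                raise PathGeometryError("align_idx out of range")
        if max(self.cv_idx) >= n or min(self.cv_idx) < 0:
            raise PathGeometryError("cv_idx out of range")
        if self.lambda_val is not None and not self.lambda_val > 0:
            raise PathGeometryError("lambda_val must be positive")

    @property
    def n_nodes(self) -> int:
        return len(self.frames)

    def coords_array(self) -> np.ndarray:
        """Stacked node coordinates, shape (p, n_atoms, 3)."""
        return np.stack([f.coords for f in self.frames])

    def with_frames(self, frames: Sequence[Frame], **meta) -> "ReferencePath":
        new = replace(self, frames=list(frames))
        new.meta = {**self.meta, **meta}
        return new


# ---------------------------------------------------------------------------
# Superposition and the MSD metric
# ---------------------------------------------------------------------------

def superpose(
    mobile: Frame, reference: Frame, align_idx: Sequence[int]
) -> tuple[Frame, float]:
    """Rigidly superpose ``mobile`` onto ``reference`` (Kabsch).

    Rotation + translation only (no reflection), minimising the RMSD over
    ``align_idx``. The transform fitted on the alignment atoms is applied
    to *all* atoms of ``mobile``.

    Returns
    -------
    (transformed, rmsd)
        The transformed frame and the post-fit RMSD (nm) over align_idx.
    """
    idx = np.asarray(align_idx, dtype=int)
    if idx.size < 3:
        raise PathGeometryError(
            f"superposition needs >= 3 alignment atoms, got {idx.size}"
        )
    a = mobile.coords[idx]
    b = reference.coords[idx]
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    # collinear (or coincident) alignment sets leave the rotation about the
    # common axis undetermined
    if np.linalg.matrix_rank(a_c, tol=1e-9) < 2 or np.linalg.matrix_rank(b_c, tol=1e-9) < 2:
        raise PathGeometryError("alignment atoms are collinear/degenerate")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        rot, _ = Rotation.align_vectors(b_c, a_c)
    new_coords = rot.apply(mobile.coords - a.mean(axis=0)) + b.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((new_coords[idx] - b) ** 2, axis=1))))
    return Frame(new_coords, mobile.atom_ids), rmsd


def msd(
    a: Frame,
    b: Frame,
    align_idx: Sequence[int] | None,
    cv_idx: Sequence[int],
) -> float:
    """Mean square deviation (nm²) between two frames over ``cv_idx``.

    When ``align_idx`` is given, ``b`` is first optimally superposed onto
    ``a``; with ``align_idx=None`` the frames are compared as-is.
    """
    cv = np.asarray(cv_idx, dtype=int)
    if cv.size == 0:
        raise PathGeometryError("cv_idx must be non-empty")
    if align_idx is not None:
        b, _ = superpose(b, a, align_idx)
    diff = a.coords[cv] - b.coords[cv]
    return float(np.mean(np.sum(diff * diff, axis=1)))


def _node_distances(x: Frame, path: ReferencePath) -> np.ndarray:
    return np.array(
        [msd(x, node, path.align_idx, path.cv_idx) for node in path.frames]
    )


# ---------------------------------------------------------------------------
# Path collective variables
# ---------------------------------------------------------------------------

def pcv_s(x: Frame, path: ReferencePath) -> float:
    """Progress coordinate S(x) in [0, 1] along the reference path.

    Softmin-weighted average of the node indices; overflow-safe via
    exponent shifting by the smallest node distance.
    """
    p = path.n_nodes
    if p < 2:
        raise PathGeometryError("pcv_s needs a path with >= 2 nodes")
    if path.lambda_val is None:
        raise PathGeometryError("path.lambda_val is not set")
    d = _node_distances(x, path)
    w = np.exp(-path.lambda_val * (d - d.min()))
    i = np.arange(p, dtype=float)  # (i-1) with 1-based node numbering
    return float(np.sum(i * w) / ((p - 1) * np.sum(w)))


def pcv_z(x: Frame, path: ReferencePath) -> float:
    """Orthogonal deviation Z(x) from the path, nm².

    Z = −(1/λ)·ln Σᵢ e^(−λ dᵢ); a softmin of the node distances, so
    Z → minᵢ dᵢ as λ → ∞ and Z ≤ minᵢ dᵢ always.
    """
    if path.lambda_val is None:
        raise PathGeometryError("path.lambda_val is not set")
    lam = path.lambda_val
    d = _node_distances(x, path)
    m = d.min()
    return float(m - np.log(np.sum(np.exp(-lam * (d - m)))) / lam)


def consecutive_msds(path: ReferencePath) -> np.ndarray:
    """MSD between each pair of consecutive nodes, length p−1."""
    return np.array(
        [
            msd(path.frames[i], path.frames[i + 1], path.align_idx, path.cv_idx)
            for i in range(path.n_nodes - 1)
        ]
    )


#: Heuristic numerator for λ over the mean consecutive MSD.
LAMBDA_HEURISTIC_CONSTANT = 2.3


def lambda_heuristic(
    path: ReferencePath, constant: float = LAMBDA_HEURISTIC_CONSTANT
) -> float:
    """Smoothness parameter λ = c / mean(consecutive MSD), in nm⁻².

    The constant c = 2.3 gives node weights that decay appreciably over
    one inter-node spacing, which keeps the S(x) mapping smooth and close
    to linear; it can be overridden through ``constant``.
    """
    if path.n_nodes < 2:
        raise PathGeometryError("lambda heuristic needs >= 2 nodes")
    gaps = consecutive_msds(path)
    if np.any(gaps <= 0):
        raise PathGeometryError(
            "duplicate consecutive nodes (zero MSD); deduplicate the path first"
        )
    return float(constant / gaps.mean())


# ---------------------------------------------------------------------------
# Path conditioning: reparametrization, padding, smoothing
# ---------------------------------------------------------------------------

def _progressive_align(path: ReferencePath) -> np.ndarray:
    """Node coordinates with each frame superposed onto its predecessor.

    Removes rigid-body drift so that linear interpolation between nodes is
    meaningful. Identity when the path has no alignment set.
    """
    coords = path.coords_array().copy()
    if path.align_idx is None:
        return coords
    frames = [path.frames[0]]
    for f in path.frames[1:]:
        aligned, _ = superpose(f, frames[-1], path.align_idx)
        frames.append(aligned)
    return np.stack([f.coords for f in frames])


def reparametrize_equidistant(
    path: ReferencePath,
    n_out: int | None = None,
    tol: float = 1e-3,
    max_iter: int = 200,
) -> ReferencePath:
    """Redistribute nodes so consecutive MSDs are equal (string-method style).

    New nodes are placed by piecewise-linear interpolation in aligned
    coordinate space at uniform arc length (arc length measured as the
    root of the MSD metric), iterating until the coefficient of variation
    of consecutive MSDs drops below ``tol``. Endpoints are preserved
    bit-for-bit.

    The achieved spread and convergence flag are stored in the result's
    ``meta`` under ``"spread"`` and ``"converged"``; failure to converge
    warns and returns the best result.
    """
    if n_out is None:
        n_out = path.n_nodes
    if n_out < 2:
        raise PathGeometryError("n_out must be >= 2")
    if path.n_nodes < 2:
        raise PathGeometryError("cannot reparametrize a single-node path")

    coords = _progressive_align(path)
    end_lo, end_hi = coords[0].copy(), coords[-1].copy()
    first = path.frames[0]
    cv = np.asarray(path.cv_idx, dtype=int)

    def seg_lengths(c: np.ndarray) -> np.ndarray:
        d = c[1:, cv] - c[:-1, cv]
        return np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1))  # sqrt(MSD)

    spread = np.inf
    for _ in range(max_iter):
        L = seg_lengths(coords)
        if np.all(L == 0):
            raise PathGeometryError("degenerate path: all nodes coincide")
        msds = L**2
        mean = msds.mean()
        spread = float(msds.std() / mean) if mean > 0 else np.inf
        if spread < tol and coords.shape[0] == n_out:
            break
        arc = np.concatenate([[0.0], np.cumsum(L)])
        targets = np.linspace(0.0, arc[-1], n_out)
        flat = coords.reshape(coords.shape[0], -1)
        new = np.empty((n_out, flat.shape[1]))
        for j in range(flat.shape[1]):
            new[:, j] = np.interp(targets, arc, flat[:, j])
        coords = new.reshape(n_out, *coords.shape[1:])
        # pin endpoints exactly
        coords[0] = end_lo
        coords[-1] = end_hi
    else:
        L = seg_lengths(coords)
        msds = L**2
        spread = float(msds.std() / msds.mean())
        if spread >= tol:
            warnings.warn(
                f"equidistant reparametrization did not reach tol={tol} "
                f"(spread={spread:.3g}) in {max_iter} iterations",
                RuntimeWarning,
            )

    frames = [Frame(c, first.atom_ids) for c in coords]
    return path.with_frames(frames, spread=spread, converged=bool(spread < tol))


def pad_endpoints(path: ReferencePath, n_pad: int) -> ReferencePath:
    """Extend the path with ``n_pad`` fictitious nodes at each end.

    Padding nodes continue the terminal segment by linear extrapolation at
    the terminal step size. They are never visited during steering but
    soften the boundary behaviour of the PCVs (without them, S saturates
    and loses resolution near the first and last physical node). Original
    nodes are unchanged, shifted by ``n_pad`` indices.
    """
    if n_pad < 0:
        raise PathGeometryError("n_pad must be >= 0")
    if n_pad == 0:
        return path
    if path.n_nodes < 2:
        raise PathGeometryError("cannot pad a path with fewer than 2 nodes")
    coords = _progressive_align(path)
    first_dir = coords[0] - coords[1]
    last_dir = coords[-1] - coords[-2]
    pre = [coords[0] + j * first_dir for j in range(n_pad, 0, -1)]
    post = [coords[-1] + j * last_dir for j in range(1, n_pad + 1)]
    ids = path.frames[0].atom_ids
    frames = (
        [Frame(c, ids) for c in pre]
        + list(path.frames)
        + [Frame(c, ids) for c in post]
    )
    return path.with_frames(frames, n_pad=n_pad)


def smooth_path(path: ReferencePath, window: int) -> ReferencePath:
    """Coordinate-wise moving average along the node index, endpoints fixed.

    A light local smoother that reduces node-to-node jitter in a guess
    path before equidistant reparametrization. ``window`` must be odd;
    ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise PathGeometryError("window must be an odd integer >= 1")
    if window == 1:
        return path
    coords = path.coords_array()
    p = coords.shape[0]
    half = window // 2
    out = coords.copy()
    for i in range(1, p - 1):
        lo, hi = max(0, i - half), min(p, i + half + 1)
        out[i] = coords[lo:hi].mean(axis=0)
    ids = path.frames[0].atom_ids
    return path.with_frames([Frame(c, ids) for c in out], smoothed_window=window)
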