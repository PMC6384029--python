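"""Wedge-compensated rigid alignment and averaging of subtomograms.

Similarity is a constrained cross-correlation: a Pearson correlation of
Fourier coefficients restricted to the intersection of the two volumes'
sampled (non-wedge) Fourier regions, so the missing wedge neither inflates
nor deflates the score.  Alignment is a deterministic grid search over
rotations (translations solved per rotation by masked FFT cross-correlation)
followed by local simplex refinement.  Averaging applies inverse poses and
normalises per Fourier voxel by the accumulated wedge coverage; even/odd
record parity gives independent ("gold standard") half maps.

Euler angles are zyz intrinsic, in degrees; rotating a reference by
``(phi, theta, psi)`` predicts an observation with that pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .simulate import wedge_mask

__all__ = [
    "AlignmentParams",
    "WedgeMask",
    "rotate_zyz",
    "shift_volume",
    "constrained_cc",
    "align_to_reference",
    "average_subtomograms",
]


class AlignmentError(ValueError):
    pass


@dataclass
class AlignmentParams:
    """Pose of one subtomogram: zyz Euler angles (deg), shift (nm), score."""

    phi: float = 0.0
    theta: float = 0.0
    psi: float = 0.0
    dx: float = 0.0
    dy: float = 0.0
    dz: float = 0.0
    score: float = 0.0

    def __post_init__(self) -> None:
        self.phi %= 360.0
        self.theta %= 360.0
        self.psi %= 360.0
        if not -1.0 - 1e-9 <= self.score <= 1.0 + 1e-9:
            raise AlignmentError("score must lie in [-1, 1]")

    def rotation(self) -> Rotation:
        return Rotation.from_euler("ZYZ", [self.phi, self.theta, self.psi],
                                   degrees=True)


@dataclass
class WedgeMask:
    """Missing-wedge support mask that rotates with a volume's pose."""

    tilt_range_deg: float = 60.0
    rotation: Optional[Rotation] = None

    def mask(self, shape: Tuple[int, int, int]) -> np.ndarray:
        if self.rotation is None:
            return wedge_mask(shape, self.tilt_range_deg)
        return _rotated_wedge_mask(shape, self.tilt_range_deg, self.rotation)


def _rotated_wedge_mask(shape, tilt_range_deg, rotation: Rotation) -> np.ndarray:
    """Support mask of a volume whose content was rotated by ``rotation``."""
    nz, ny, nx = shape
    kz, ky, kx = np.meshgrid(
        np.fft.fftfreq(nz), np.fft.fftfreq(ny), np.fft.fftfreq(nx),
        indexing="ij",
    )
    # content rotated by Q has spectrum support Q(original support); test
    # whether Q^-1 k was sampled
    k = np.stack([kx.ravel(), ky.ravel(), kz.ravel()], axis=1)
    kp = rotation.inv().apply(k)
    ang = np.degrees(np.arctan2(np.abs(kp[:, 0]), np.abs(kp[:, 2])))
    mask = (ang <= tilt_range_deg).reshape(shape)
    mask[0, 0, 0] = True
    return mask


# --------------------------------------------------------------------------
# volume transforms
# --------------------------------------------------------------------------

def _zyz_matrix_xyz(phi: float, theta: float, psi: float) -> np.ndarray:
    return Rotation.from_euler("ZYZ", [phi, theta, psi], degrees=True).as_matrix()


def rotate_zyz(vol: np.ndarray, phi: float, theta: float = 0.0,
               psi: float = 0.0, order: int = 1) -> np.ndarray:
    """Rotate volume content by zyz-intrinsic Euler angles about the box
    centre ((N-1)/2), counterclockwise about +z viewed from +z.

    Linear interpolation by default.
    """
    R = _zyz_matrix_xyz(phi, theta, psi)
    # map (x,y,z) matrix into (z,y,x) index convention
    P = R[::-1, ::-1]
    Minv = P.T  # inverse mapping for affine_transform (R orthonormal)
    center = (np.array(vol.shape) - 1) / 2.0
    offset = center - Minv @ center
    return ndimage.affine_transform(vol, Minv, offset=offset, order=order,
                                    mode="constant", cval=0.0)


def shift_volume(vol: np.ndarray, dx: float, dy: float, dz: float) -> np.ndarray:
    """Translate content by (dx, dy, dz) voxels via Fourier phase shifts."""
    f = np.fft.fftn(vol)
    f = ndimage.fourier_shift(f, shift=(dz, dy, dx))
    return np.real(np.fft.ifftn(f))


# --------------------------------------------------------------------------
# constrained cross-correlation
# --------------------------------------------------------------------------

def _common_mask(shape, wedge_a: Optional[WedgeMask], wedge_b: Optional[WedgeMask]) -> np.ndarray:
    mask = np.ones(shape, dtype=bool)
    if wedge_a is not None:
        mask &= wedge_a.mask(shape)
    if wedge_b is not None:
        mask &= wedge_b.mask(shape)
    mask[0, 0, 0] = False  # exclude DC: mean-free correlation
    return mask


def constrained_cc(a: np.ndarray, b: np.ndarray,
                   wedge_a: Optional[WedgeMask] = None,
                   wedge_b: Optional[WedgeMask] = None) -> float:
    """Pearson correlation over the intersection of the two Fourier wedges.

    Invariant to global intensity scaling and offset of either input;
    cc(v, v) = 1 for any non-constant v.
    """
    if a.shape != b.shape:
        raise AlignmentError("volumes must share shape")
    mask = _common_mask(a.shape, wedge_a, wedge_b)
    if not mask.any():
        raise AlignmentError("empty wedge intersection")
    fa = np.fft.fftn(a)[mask]
    fb = np.fft.fftn(b)[mask]
    na = np.linalg.norm(fa)
    nb = np.linalg.norm(fb)
    if na == 0 or nb == 0:
        raise AlignmentError("degenerate (constant) volume")
    return float(np.real(np.vdot(fa, fb)) / (na * nb))


# --------------------------------------------------------------------------
# alignment
# --------------------------------------------------------------------------

@dataclass
class SearchGrid:
    """Rotational search grid (deg) and translation bound (voxels).

    ``phi`` is the major in-plane search; ``theta``/``psi`` default to an
    identity-only search (the filament prior constrains out-of-plane tilt).
    """

    phi: Sequence[float] = field(default_factory=lambda: np.arange(0.0, 360.0, 4.0))
    theta: Sequence[float] = (0.0,)
    psi: Sequence[float] = (0.0,)
    max_shift: float = 5.0

    def poses(self) -> Iterable[Tuple[float, float, float]]:
        for t in self.theta:
            for p in self.psi:
                for f in self.phi:
                    yield (float(f), float(t), float(p))


def _best_shift(sub_f: np.ndarray, ref_f: np.ndarray, mask: np.ndarray,
                max_shift: float) -> Tuple[Tuple[float, float, float], float]:
    """Translation maximising masked correlation, from the FFT correlation
    map (integer precision; sub-voxel left to refinement)."""
    num = np.real(np.fft.ifftn(sub_f * np.conj(ref_f) * mask))
    norm = (np.linalg.norm(sub_f[mask]) * np.linalg.norm(ref_f[mask]))
    if norm == 0:
        raise AlignmentError("degenerate (constant) volume")
    shape = num.shape
    grids = np.meshgrid(*[np.fft.fftfreq(n) * n for n in shape], indexing="ij")
    within = np.ones(shape, dtype=bool)
    for g in grids:
        within &= np.abs(g) <= max_shift
    num_masked = np.where(within, num, -np.inf)
    idx = np.unravel_index(np.argmax(num_masked), shape)
    dz, dy, dx = (float(g[idx]) for g in grids)
    score = num[idx] * num.size / norm
    return (dx, dy, dz), float(np.clip(score, -1.0, 1.0))


def align_to_reference(
    sub: np.ndarray,
    ref: np.ndarray,
    search_grid: Optional[SearchGrid] = None,
    wedge: Optional[WedgeMask] = None,
    refine: bool = True,
) -> AlignmentParams:
    """Find the pose of ``ref`` that best explains ``sub``.

    Grid search over rotations with per-rotation translation from the masked
    correlation map, then Nelder-Mead refinement of (phi, dx, dy, dz).  The
    returned pose maps the reference onto the subtomogram.
    """
    if search_grid is None:
        search_grid = SearchGrid()
    if sub.shape != ref.shape:
        raise AlignmentError("subtomogram and reference must share shape")
    if float(np.ptp(sub)) == 0.0:
        raise AlignmentError("degenerate (constant) subtomogram")
    mask = _common_mask(sub.shape, wedge, None)
    sub_f = np.fft.fftn(sub)
    best: Optional[AlignmentParams] = None
    for (phi, theta, psi) in search_grid.poses():
        rref = rotate_zyz(ref, phi, theta, psi)
        ref_f = np.fft.fftn(rref)
        (dx, dy, dz), score = _best_shift(sub_f, ref_f, mask, search_grid.max_shift)
        if best is None or score > best.score:
            best = AlignmentParams(phi, theta, psi, dx, dy, dz, score)
    assert best is not None

    if refine:
        def neg_cc(x):
            phi, dx, dy, dz = x
            r = rotate_zyz(ref, phi, best.theta, best.psi)
            r = shift_volume(r, dx, dy, dz)
            try:
                return -constrained_cc(sub, r, wedge, None)
            except AlignmentError:
                return 1.0

        x0 = np.array([best.phi, best.dx, best.dy, best.dz])
        res = optimize.minimize(
            neg_cc, x0, method="Nelder-Mead",
            options={"xatol": 0.05, "fatol": 1e-5, "maxiter": 120},
        )
        if -res.fun >= best.score:
            phi, dx, dy, dz = res.x
            best = AlignmentParams(phi, best.theta, best.psi,
                                   dx, dy, dz, float(np.clip(-res.fun, -1, 1)))
    return best


# --------------------------------------------------------------------------
# averaging
# --------------------------------------------------------------------------

def average_subtomograms(
    stack: np.ndarray,
    params: Sequence[AlignmentParams],
    wedges: Optional[Sequence[WedgeMask]] = None,
) -> Tuple[np.ndarray, Tuple[np.ndarray, np.ndarray]]:
    """Average a stack after undoing each pose; returns (full, (even, odd)).

    Each subtomogram is shifted by the negative of its shift, rotated back,
    and accumulated in Fourier space with its rotated wedge support; the sum
    is normalised per voxel by the wedge coverage.  Half maps are formed
    from even / odd record indices (independent "gold-standard" halves).
    """
    n = len(stack)
    if n < 2:
        raise AlignmentError("need at least 2 subtomograms to average")
    if len(params) != n:
        raise AlignmentError("one AlignmentParams per subtomogram required")
    if wedges is None:
        wedges = [WedgeMask(90.0)] * n
    shape = stack[0].shape
    num = [np.zeros(shape, dtype=complex) for _ in range(2)]
    den = [np.zeros(shape) for _ in range(2)]
    for i, (vol, p, w) in enumerate(zip(stack, params, wedges)):
        aligned = shift_volume(np.asarray(vol, dtype=float), -p.dx, -p.dy, -p.dz)
        aligned = rotate_zyz(aligned, -p.psi, -p.theta, -p.phi)
        rot = p.rotation().inv()
        base = Rotation.identity() if w.rotation is None else w.rotation
        wmask = WedgeMask(w.tilt_range_deg, rot * base).mask(shape)
        f = np.fft.fftn(aligned) * wmask
        half = i % 2
        num[half] += f
        den[half] += wmask
    halves = []
    for h in range(2):
        d = np.maximum(den[h], 1e-9)
        halves.append(np.real(np.fft.ifftn(num[h] / d)))
    d = np.maximum(den[0] + den[1], 1e-9)
    full = np.real(np.fft.ifftn((num[0] + num[1]) / d))
    return full, (halves[0], halves[1])
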