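"""Synthetic tomogram and subtomogram generation with ground truth.

Renders a :class:`~tripletomo.geometry.ProcentrioleModel` into density
volumes (protofilament walls as chains of Gaussian tubulin-monomer blobs
every 4 nm, decorations as blobs at their own 4 or 8 nm repeat), applies the
missing wedge of a limited-tilt (default ±60°) acquisition, and emulates
boxed triplet segments with additive Gaussian noise at a configurable SNR.

Assembly intermediates are emulated by rendering the B-tubule with only PFs
B1–B3 (outer A-B junction) or the C-tubule with only C1–C3 and C8–C10 (both
B-C junctions), placed at filament ends according to a positional mix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import DecorationSpec, ProcentrioleModel

__all__ = [
    "SimulationConfig",
    "IntermediateSpec",
    "render_model",
    "render_segment",
    "apply_missing_wedge",
    "wedge_mask",
    "simulate_subtomograms",
    "make_reference",
    "sample_tubule_lengths",
    "positional_class_from_extents",
    "GROUND_TRUTH_COLUMNS",
]

MONOMER_REPEAT_NM = 4.0          # axial tubulin monomer spacing
PF_SIGMA_NM = 1.2                # Gaussian width of the wall tube
WALL_SAMPLE_NM = 1.0             # axial sampling of the continuous wall
MONOMER_CONTRAST = 0.6           # depth of the 4 nm monomer modulation

B_PARTIAL_PFS = ("B1", "B2", "B3")
C_PARTIAL_PFS = ("C1", "C2", "C3", "C8", "C9", "C10")

POSITIONAL_LABELS = ("proximal_end", "distal_end", "nascent", "short", "mid")

GROUND_TRUTH_COLUMNS = [
    "filament_id", "seg_idx", "phi", "theta", "psi", "dx", "dy", "dz",
    "label", "pos_class", "s_nm",
    "a_start", "a_end", "b_start", "b_end", "c_start", "c_end",
]


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Acquisition and boxing parameters for the synthetic data.

    ``voxel_nm`` defaults to 1.0 (the acquisition pixel of 0.482 nm is also
    accepted); ``tilt_range_deg`` mirrors the ±60° collection; the segment
    length of 29 nm covers more than three repeats of the largest (8 nm)
    periodicity.  SNR is signal variance over noise variance inside a
    dilated signal mask.
    """

    voxel_nm: float = 1.0
    box: int = 48
    tilt_range_deg: float = 60.0
    snr: float = 0.5
    seed: int = 0
    segment_length_nm: float = 29.0
    segment_overlap_fraction: float = 0.0
    jitter_nm: float = 1.5

    def __post_init__(self) -> None:
        if self.voxel_nm <= 0:
            raise SimulationError("voxel_nm must be positive")
        if not 0 < self.tilt_range_deg <= 90:
            raise SimulationError("tilt_range_deg must be in (0, 90]")
        if self.snr <= 0:
            raise SimulationError("snr must be positive")
        if self.segment_length_nm < 3 * 8.0:
            raise SimulationError(
                "segment_length_nm must cover at least three 8 nm repeats"
            )
        if not 0 <= self.segment_overlap_fraction < 1:
            raise SimulationError("segment_overlap_fraction must be in [0, 1)")


@dataclass
class IntermediateSpec:
    """Mix of partially assembled tubules injected into the simulation.

    ``b_partial_fraction`` / ``c_partial_fraction``: probability that a
    filament carries an incomplete B- / C-tubule region.  ``placement_mix``:
    distribution over where that region sits (proximal end, distal end,
    nascent = whole tubule, short = tubule under 10 nm, mid).
    """

    b_partial_fraction: float = 0.0
    c_partial_fraction: float = 0.0
    placement_mix: Dict[str, float] = field(
        default_factory=lambda: {
            "proximal_end": 0.287, "distal_end": 0.255, "nascent": 0.338,
            "short": 0.070, "mid": 0.051,
        }
    )

    def __post_init__(self) -> None:
        for f in (self.b_partial_fraction, self.c_partial_fraction):
            if not 0 <= f <= 1:
                raise SimulationError("partial fractions must be in [0, 1]")
        tot = sum(self.placement_mix.values())
        # printed class percentages round to 100.1%; renormalise small drift
        if abs(tot - 1.0) > 5e-3:
            raise SimulationError("placement_mix must sum to 1")
        self.placement_mix = {k: v / tot for k, v in self.placement_mix.items()}
        for k in self.placement_mix:
            if k not in POSITIONAL_LABELS:
                raise SimulationError(f"unknown placement label {k!r}")


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _splat_gaussians(vol: np.ndarray, centers_vox: np.ndarray,
                     sigmas_vox: np.ndarray, weights: np.ndarray) -> None:
    """Accumulate isotropic Gaussian blobs into ``vol`` (indexed z, y, x)."""
    shape = vol.shape
    for (cz, cy, cx), sig, w in zip(centers_vox, sigmas_vox, weights):
        r = max(2, int(np.ceil(3.0 * sig)))
        z0, z1 = int(np.floor(cz)) - r, int(np.floor(cz)) + r + 1
        y0, y1 = int(np.floor(cy)) - r, int(np.floor(cy)) + r + 1
        x0, x1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r + 1
        z0c, y0c, x0c = max(z0, 0), max(y0, 0), max(x0, 0)
        z1c, y1c, x1c = min(z1, shape[0]), min(y1, shape[1]), min(x1, shape[2])
        if z0c >= z1c or y0c >= y1c or x0c >= x1c:
            continue
        zz = np.arange(z0c, z1c, dtype=float) - cz
        yy = np.arange(y0c, y1c, dtype=float) - cy
        xx = np.arange(x0c, x1c, dtype=float) - cx
        g = np.exp(
            -(zz[:, None, None] ** 2 + yy[None, :, None] ** 2
              + xx[None, None, :] ** 2) / (2.0 * sig * sig)
        )
        vol[z0c:z1c, y0c:y1c, x0c:x1c] += w * g


def _decoration_anchor_xy(model: ProcentrioleModel, dec: DecorationSpec) -> np.ndarray:
    """Blade-local anchor of a decoration: mean anchor-PF position pushed
    radially (outward from the tubule centre; negative offsets go luminal)."""
    pts = np.array([model.triplet.pf_position(pf) for pf in dec.anchor_pfs])
    anchor = pts.mean(axis=0)
    center = model.triplet.tubule_center(dec.anchor_pfs[0][0])
    outward = anchor - center
    n = np.linalg.norm(outward)
    if n > 0:
        anchor = anchor + dec.radial_offset_nm * outward / n
    return anchor


def _model_blobs(
    model: ProcentrioleModel,
    z_lo: float,
    z_hi: float,
    triplet_indices: Optional[List[int]] = None,
    pf_subset: Optional[Dict[str, Tuple[str, ...]]] = None,
    extents_override: Optional[Dict[str, Tuple[float, float]]] = None,
    include: str = "all",
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Blob centres (world nm, columns x/y/z), sigmas and weights.

    ``pf_subset`` maps tubule id -> tuple of PF ids to keep (incomplete
    tubules); ``include`` selects 'all', 'walls' or 'decorations'.
    """
    if triplet_indices is None:
        triplet_indices = list(range(1, model.n_fold + 1))
    xs: List[np.ndarray] = []
    sig: List[np.ndarray] = []
    wts: List[np.ndarray] = []
    for k in triplet_indices:
        extents = model.per_triplet_tubule_extents[k - 1]
        if extents_override is not None:
            extents = extents_override
        if include in ("all", "walls"):
            for tid in ("A", "B", "C"):
                ring = model.triplet.rings[tid]
                t0, t1 = extents[tid]
                lo, hi = max(t0, z_lo), min(t1, z_hi)
                if hi <= lo:
                    continue
                # continuous wall tube: dense axial sampling with a cosine
                # monomer modulation at the 4 nm tubulin repeat
                z0 = np.ceil(lo / WALL_SAMPLE_NM) * WALL_SAMPLE_NM
                zs = np.arange(z0, hi, WALL_SAMPLE_NM)
                if zs.size == 0:
                    continue
                center = model.triplet.tubule_center(tid)
                pf_xy = center + ring.pf_xy()
                keep = np.ones(ring.n_pf, dtype=bool)
                if pf_subset and tid in pf_subset:
                    keep[:] = False
                    for pf in pf_subset[tid]:
                        keep[int(pf[1:]) - 1] = True
                pf_xy = pf_xy[keep]
                for z in zs:
                    pivot, u, v = model.blade_frame(float(z), k)
                    pts = pivot + np.outer(pf_xy[:, 0], u) + np.outer(pf_xy[:, 1], v)
                    n = pts.shape[0]
                    w = 1.0 + MONOMER_CONTRAST * np.cos(
                        2 * np.pi * z / MONOMER_REPEAT_NM
                    )
                    xs.append(np.column_stack([pts, np.full(n, z)]))
                    sig.append(np.full(n, PF_SIGMA_NM))
                    wts.append(np.full(n, w * WALL_SAMPLE_NM / MONOMER_REPEAT_NM))
        if include in ("all", "decorations"):
            for dec in model.triplet.decorations:
                anchor_tid = dec.anchor_pfs[0][0]
                t0, t1 = extents[anchor_tid]
                lo, hi = max(t0, z_lo), min(t1, z_hi)
                if hi <= lo:
                    continue
                if pf_subset and anchor_tid in pf_subset:
                    if not all(pf in pf_subset[anchor_tid] for pf in dec.anchor_pfs
                               if pf[0] == anchor_tid):
                        continue
                z0 = np.ceil(lo / dec.periodicity_nm) * dec.periodicity_nm
                zs = np.arange(z0, hi, dec.periodicity_nm)
                if zs.size == 0:
                    continue
                axy = _decoration_anchor_xy(model, dec)
                for z in zs:
                    pivot, u, v = model.blade_frame(float(z), k)
                    pt = pivot + axy[0] * u + axy[1] * v
                    xs.append(np.array([[pt[0], pt[1], z]]))
                    sig.append(np.array([dec.blob_sigma_nm]))
                    wts.append(np.array([1.5]))
    if not xs:
        return (np.zeros((0, 3)), np.zeros(0), np.zeros(0))
    return np.vstack(xs), np.concatenate(sig), np.concatenate(wts)


def render_model(
    model: ProcentrioleModel,
    config: SimulationConfig,
    shape: Optional[Tuple[int, int, int]] = None,
    origin_nm: Optional[Tuple[float, float, float]] = None,
    include: str = "all",
    triplet_indices: Optional[List[int]] = None,
) -> np.ndarray:
    """Render the model into a density volume (indexed z, y, x; nonnegative).

    ``origin_nm`` is the world (x, y, z) position of voxel (0, 0, 0); by
    default the volume is centred on the cylinder axis and spans the model
    length axially.
    """
    if config.voxel_nm > MONOMER_REPEAT_NM:
        raise SimulationError(
            "voxel size coarser than the 4 nm monomer repeat cannot encode it"
        )
    if shape is None:
        r_max = (model.pivot_radius_nm
                 + np.abs(np.asarray(model.triplet.tubule_center("C"))).sum()
                 + 2 * model.triplet.rings["C"].radius_major + 10.0)
        nxy = int(np.ceil(2 * r_max / config.voxel_nm))
        nz = int(np.ceil(model.length_nm / config.voxel_nm)) + 8
        shape = (nz, nxy, nxy)
    if origin_nm is None:
        # axis at array centre (N-1)/2 so rotations about the grid centre
        # coincide with rotations about the cylinder axis
        origin_nm = (
            -(shape[2] - 1) * config.voxel_nm / 2.0,
            -(shape[1] - 1) * config.voxel_nm / 2.0,
            -4.0,
        )
    ox, oy, oz = origin_nm
    vol = np.zeros(shape, dtype=np.float64)
    z_lo = oz
    z_hi = oz + shape[0] * config.voxel_nm
    centers, sigmas, weights = _model_blobs(
        model, z_lo, z_hi, triplet_indices=triplet_indices, include=include
    )
    if centers.shape[0] == 0:
        return vol
    cv = np.column_stack([
        (centers[:, 2] - oz) / config.voxel_nm,
        (centers[:, 1] - oy) / config.voxel_nm,
        (centers[:, 0] - ox) / config.voxel_nm,
    ])
    _splat_gaussians(vol, cv, sigmas / config.voxel_nm, weights)
    return vol


def render_segment(
    model: ProcentrioleModel,
    triplet_index: int,
    z_center: float,
    config: SimulationConfig,
    pf_subset: Optional[Dict[str, Tuple[str, ...]]] = None,
    extents_override: Optional[Dict[str, Tuple[float, float]]] = None,
    shift_nm: Tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Render one boxed triplet segment, centred on the A-tubule at z_center.

    ``shift_nm`` displaces the structure inside the box (the recorded pose
    shift).  The segment spans ``segment_length_nm`` axially.
    """
    box = config.box
    # A-tubule centre at voxel (box-1)/2: the rotation centre of the box
    half_nm = (box - 1) * config.voxel_nm / 2.0
    a_xy = model.tubule_center_xy(z_center, triplet_index, "A")
    origin = (a_xy[0] - half_nm, a_xy[1] - half_nm, z_center - half_nm)
    seg = config.segment_length_nm / 2.0
    centers, sigmas, weights = _model_blobs(
        model, z_center - seg, z_center + seg,
        triplet_indices=[triplet_index], pf_subset=pf_subset,
        extents_override=extents_override,
    )
    vol = np.zeros((box, box, box), dtype=np.float64)
    if centers.shape[0] == 0:
        return vol
    dx, dy, dz = shift_nm
    cv = np.column_stack([
        (centers[:, 2] - origin[2] + dz) / config.voxel_nm,
        (centers[:, 1] - origin[1] + dy) / config.voxel_nm,
        (centers[:, 0] - origin[0] + dx) / config.voxel_nm,
    ])
    _splat_gaussians(vol, cv, sigmas / config.voxel_nm, weights)
    return vol


# --------------------------------------------------------------------------
# missing wedge
# --------------------------------------------------------------------------

def wedge_mask(shape: Tuple[int, int, int], tilt_range_deg: float) -> np.ndarray:
    """Boolean Fourier-space mask of the *sampled* region (True = kept).

    Coefficients whose direction in the kx–kz plane lies more than
    ``tilt_range_deg`` away from the kz axis are lost (the missing wedge);
    the tilt axis is y, so ky is unconstrained.  DC is always kept.
    """
    if tilt_range_deg <= 0:
        raise SimulationError("tilt_range_deg must be positive")
    nz, ny, nx = shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    kx = np.fft.fftfreq(nx)[None, None, :]
    ang = np.degrees(np.arctan2(np.abs(kx), np.abs(kz)))
    mask = np.broadcast_to(ang <= tilt_range_deg, shape).copy()
    mask[0, :, 0] = True  # kz = kx = 0 line (includes DC) is always measured
    return mask


def apply_missing_wedge(volume: np.ndarray, tilt_range_deg: float) -> np.ndarray:
    """Project a volume onto the sampled (non-wedge) Fourier region.

    Idempotent and real-valued (the mask is Hermitian-symmetric).  A tilt
    range of 90° is a no-op.
    """
    if volume.ndim != 3:
        raise SimulationError("expected a 3D volume")
    if tilt_range_deg >= 90:
        return volume.astype(np.float64, copy=True)
    mask = wedge_mask(volume.shape, tilt_range_deg)
    f = np.fft.fftn(volume)
    f[~mask] = 0.0
    return np.real(np.fft.ifftn(f))


# --------------------------------------------------------------------------
# tubule length sampling and intermediates
# --------------------------------------------------------------------------

def sample_tubule_lengths(
    rng: np.random.Generator,
    mean_sd_per_tubule: Dict[str, Tuple[float, float]],
    max_rejections: int = 1000,
) -> Dict[str, Tuple[float, float]]:
    """Draw nested tubule extents with truncated-normal lengths, A >= B >= C.

    B is placed uniformly inside A and C inside B ("attached to the middle
    at different heights").  Raises if the ordering cannot be satisfied.
    """
    for tid in ("A", "B", "C"):
        if mean_sd_per_tubule[tid][0] <= 0:
            raise SimulationError("tubule mean lengths must be positive")

    def draw(mean: float, sd: float) -> float:
        if sd == 0:
            return mean
        for _ in range(100):
            x = rng.normal(mean, sd)
            if x > 0:
                return x
        raise SimulationError("could not draw a positive length")

    for _ in range(max_rejections):
        la = draw(*mean_sd_per_tubule["A"])
        lb = draw(*mean_sd_per_tubule["B"])
        lc = draw(*mean_sd_per_tubule["C"])
        if la >= lb >= lc:
            b0 = la and float(rng.uniform(0, la - lb)) if la > lb else 0.0
            c0 = b0 + (float(rng.uniform(0, lb - lc)) if lb > lc else 0.0)
            return {"A": (0.0, la), "B": (b0, b0 + lb), "C": (c0, c0 + lc)}
    raise SimulationError(
        "infeasible tubule length ordering (A >= B >= C) after max rejections"
    )


def positional_class_from_extents(
    seg_z: float,
    tubule_extent: Tuple[float, float],
    nascent: bool,
    end_window_nm: float,
    short_threshold_nm: float = 10.0,
) -> str:
    """Map a segment to one of the five positional intermediate classes."""
    t0, t1 = tubule_extent
    if t1 - t0 < short_threshold_nm:
        return "short"
    if nascent:
        return "nascent"
    if seg_z <= t0 + end_window_nm:
        return "proximal_end"
    if seg_z >= t1 - end_window_nm:
        return "distal_end"
    return "mid"


# --------------------------------------------------------------------------
# subtomogram simulation
# --------------------------------------------------------------------------

def make_reference(
    model: ProcentrioleModel,
    config: SimulationConfig,
    pf_subset: Optional[Dict[str, Tuple[str, ...]]] = None,
    apply_wedge: bool = False,
) -> np.ndarray:
    """Canonical noise-free reference segment at pose (0, 0, 0).

    The model's triplet rendered with blade angle zero at the segment centre
    (blade orientation 180°, pointing radially inward).  The model's twist
    rate is retained inside the segment, so rotating the reference about z
    by a record's ``phi`` reproduces that record's orientation exactly,
    including the intra-segment twist (both are pieces of one helical
    lattice).
    """
    from dataclasses import replace as _replace
    from .geometry import TwistProfile
    lattice = 2.0 * MONOMER_REPEAT_NM
    z_ref = np.round(model.length_nm / 2.0 / lattice) * lattice
    rate = model.twist.rate_deg_per_nm
    ref_model = _replace(
        model,
        twist=TwistProfile(theta0_deg=-rate * z_ref, rate_deg_per_nm=rate),
        per_triplet_tubule_extents=None,
        mirrored=False,
    )
    vol = render_segment(ref_model, 1, z_ref, config, pf_subset=pf_subset)
    if apply_wedge:
        vol = apply_missing_wedge(vol, config.tilt_range_deg)
    return vol

def _noise_sigma(signal: np.ndarray, snr: float) -> float:
    """Noise SD giving the requested variance-ratio SNR inside a dilated
    signal mask (background-dominated boxes otherwise dilute the ratio)."""
    thresh = 0.05 * signal.max() if signal.max() > 0 else 0.0
    mask = signal > thresh
    if mask.sum() < 10:
        return float(np.sqrt(signal.var() / snr)) if signal.var() > 0 else 1.0
    mask = ndimage.binary_dilation(mask, iterations=2)
    var_sig = float(signal[mask].var())
    return float(np.sqrt(var_sig / snr))


def simulate_subtomograms(
    model: ProcentrioleModel,
    config: SimulationConfig,
    intermediates: Optional[IntermediateSpec] = None,
    n_filaments: Optional[int] = None,
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Simulate boxed triplet segments with ground-truth records.

    Each filament (triplet) is cut into consecutive segments along z; each
    segment is rendered in its own box centred on the A-tubule, wedge
    filtered and, for finite SNR, degraded with additive Gaussian noise.
    The true pose is the zyz-intrinsic rotation (here a pure phi rotation
    about z) that takes the canonical reference segment (see
    :func:`make_reference`) to the observation, plus the random sub-voxel
    shift: phi = triplet azimuth + local blade angle.

    Returns ``(stack, records)`` where records is a DataFrame with columns
    ``GROUND_TRUTH_COLUMNS``.  Identical seed => bit-identical stack.
    """
    rng = np.random.default_rng(config.seed)
    if intermediates is None:
        intermediates = IntermediateSpec()
    if n_filaments is None:
        n_filaments = model.n_fold
    if n_filaments == 0:
        warnings.warn("zero filaments requested: empty stack")
        return (np.zeros((0, config.box, config.box, config.box), np.float32),
                pd.DataFrame(columns=GROUND_TRUTH_COLUMNS))

    step = config.segment_length_nm * (1 - config.segment_overlap_fraction)
    end_window = config.segment_length_nm

    labels_mix = list(intermediates.placement_mix.keys())
    probs_mix = np.array([intermediates.placement_mix[k] for k in labels_mix])

    vols: List[np.ndarray] = []
    rows: List[dict] = []
    for f in range(n_filaments):
        k = (f % model.n_fold) + 1
        base_ext = {t: tuple(v) for t, v in
                    model.per_triplet_tubule_extents[k - 1].items()}
        ext = dict(base_ext)
        b_state: Optional[str] = None
        c_state: Optional[str] = None
        if rng.random() < intermediates.b_partial_fraction:
            b_state = labels_mix[rng.choice(len(labels_mix), p=probs_mix)]
            ext["B"] = _place_partial_region(ext["A"], ext["B"], b_state, rng,
                                             config.segment_length_nm)
        if rng.random() < intermediates.c_partial_fraction:
            c_state = labels_mix[rng.choice(len(labels_mix), p=probs_mix)]
            ext["C"] = _place_partial_region(
                _clip(ext["B"], ext["A"]), _clip(ext["C"], ext["B"]),
                c_state, rng, config.segment_length_nm)
        ext["B"] = _clip(ext["B"], ext["A"])
        ext["C"] = _clip(ext["C"], ext["B"])

        a0, a1 = ext["A"]
        z0 = a0 + config.segment_length_nm / 2.0
        n_seg = max(1, int(np.floor((a1 - a0 - config.segment_length_nm) / step)) + 1)
        lattice = 2.0 * MONOMER_REPEAT_NM  # largest axial repeat (8 nm)
        prev_zc = -np.inf
        for s in range(n_seg):
            # segment centres snap to the 8 nm lattice: alignment registers
            # particles onto the axial repeat, so ground-truth shifts stay
            # sub-repeat jitter rather than arbitrary lattice phases
            zc = np.round((z0 + s * step) / lattice) * lattice
            if zc + config.segment_length_nm / 2.0 > a1 + lattice / 2.0 + 1e-9:
                break
            if zc <= prev_zc:
                continue
            prev_zc = zc
            if not (0 <= zc <= model.length_nm):
                continue
            shift = tuple(rng.uniform(-config.jitter_nm, config.jitter_nm, 3))
            pf_subset: Optional[Dict[str, Tuple[str, ...]]] = None
            label = "complete"
            pos_class = ""
            seg_lo = zc - config.segment_length_nm / 2.0
            seg_hi = zc + config.segment_length_nm / 2.0
            if b_state is not None and _overlaps_partial(
                    (seg_lo, seg_hi), ext["B"], b_state, end_window):
                pf_subset = {"B": B_PARTIAL_PFS}
                label = "B-partial"
                pos_class = positional_class_from_extents(
                    zc, ext["B"], b_state == "nascent", end_window)
            elif c_state is not None and _overlaps_partial(
                    (seg_lo, seg_hi), ext["C"], c_state, end_window):
                pf_subset = {"C": C_PARTIAL_PFS}
                label = "C-partial"
                pos_class = positional_class_from_extents(
                    zc, ext["C"], c_state == "nascent", end_window)

            vol = render_segment(
                model, k, zc, config,
                pf_subset=pf_subset, extents_override=ext, shift_nm=shift,
            )
            vol = apply_missing_wedge(vol, config.tilt_range_deg)
            if np.isfinite(config.snr):
                sigma = _noise_sigma(vol, config.snr)
                vol = vol + rng.normal(0.0, sigma, vol.shape)
            phi = (model.blade_orientation_deg(zc, k) - 180.0) % 360.0
            rows.append({
                "filament_id": f, "seg_idx": s,
                "phi": phi, "theta": 0.0, "psi": 0.0,
                "dx": shift[0], "dy": shift[1], "dz": shift[2],
                "label": label, "pos_class": pos_class, "s_nm": zc,
                "a_start": ext["A"][0], "a_end": ext["A"][1],
                "b_start": ext["B"][0], "b_end": ext["B"][1],
                "c_start": ext["C"][0], "c_end": ext["C"][1],
            })
            vols.append(vol.astype(np.float32))
    stack = (np.stack(vols) if vols else
             np.zeros((0, config.box, config.box, config.box), np.float32))
    return stack, pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)


def _clip(inner: Tuple[float, float], outer: Tuple[float, float]) -> Tuple[float, float]:
    lo = min(max(inner[0], outer[0]), outer[1])
    hi = max(min(inner[1], outer[1]), lo)
    return (lo, hi)


def _place_partial_region(
    a_ext: Tuple[float, float],
    t_ext: Tuple[float, float],
    state: str,
    rng: np.random.Generator,
    seg_len: float,
) -> Tuple[float, float]:
    """Adjust a tubule extent so its incomplete region realises ``state``."""
    t0, t1 = t_ext
    if state == "short":
        lo = t0 + (t1 - t0 - 8.0) * rng.random() if t1 - t0 > 8.0 else t0
        return (lo, min(lo + 8.0, t1))
    return (t0, t1)


def _overlaps_partial(
    seg: Tuple[float, float],
    t_ext: Tuple[float, float],
    state: str,
    end_window: float,
) -> bool:
    """Does this segment fall in the incomplete region of the tubule?"""
    lo, hi = seg
    t0, t1 = t_ext
    zc = 0.5 * (lo + hi)
    if t1 <= t0:
        return False
    if state == "short":
        # a sub-10 nm tubule leaves every segment without a complete tubule
        return True
    if state == "nascent":
        return hi > t0 and lo < t1
    if state == "proximal_end":
        return t0 <= zc <= t0 + end_window
    if state == "distal_end":
        return t1 - end_window <= zc <= t1
    if state == "mid":
        return t0 + end_window < zc < t1 - end_window
    return False
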