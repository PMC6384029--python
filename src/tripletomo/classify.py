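"""Multi-reference classification and positional mapping of intermediates.

Heterogeneity (incomplete tubules, A-C linker conformers) is detected by a
wedge-aware, hard-assignment k-means: subtomograms are brought into the
reference frame with their refined poses, and iteratively assigned to the
class average with the highest constrained cross-correlation inside a focus
mask (B-tubule region, C-tubule + linker region, ...).  Assembly
intermediates are then mapped by longitudinal position into five classes:
proximal end, distal end, nascent (whole tubule incomplete), short (tubule
under 10 nm) and mid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .align import (
    AlignmentError,
    AlignmentParams,
    WedgeMask,
    constrained_cc,
    rotate_zyz,
    shift_volume,
)
from .simulate import apply_missing_wedge

__all__ = [
    "ClassModel",
    "classify_multireference",
    "map_positional_classes",
    "combined_intermediate_fraction",
    "reciprocal_acl_classification",
    "composite_linker_map",
]

POSITIONAL_LABELS = ("proximal_end", "distal_end", "nascent", "short", "mid")


class ClassificationError(ValueError):
    pass


@dataclass
class ClassModel:
    """K class averages with populations and the focus mask used."""

    averages: np.ndarray          # (K, nz, ny, nx)
    populations: np.ndarray       # (K,)
    focus_mask: Optional[np.ndarray]
    objective: float              # mean within-class constrained CC
    objective_history: Optional[list] = None

    @property
    def k(self) -> int:
        return len(self.averages)


def _pose_tuple(poses: Optional[pd.DataFrame], i: int) -> Tuple[float, float, float]:
    if poses is None:
        return (0.0, 0.0, 0.0)
    r = poses.iloc[i]
    return (float(r.phi), float(r.get("theta", 0.0)), float(r.get("psi", 0.0)))


def _aligned_stack(stack: np.ndarray, poses: Optional[pd.DataFrame],
                   tilt_range_deg: float) -> Tuple[np.ndarray, np.ndarray]:
    """Inverse-transform subtomograms into the reference frame.

    Returns the aligned Fourier-space stack and the per-record rotated wedge
    supports, ready for wedge-normalised class averaging.
    """
    fs = []
    supports = []
    for i in range(len(stack)):
        v = np.asarray(stack[i], dtype=float)
        phi, theta, psi = _pose_tuple(poses, i)
        if poses is not None:
            r = poses.iloc[i]
            v = shift_volume(v, -r.dx, -r.dy, -r.dz)
            v = rotate_zyz(v, -psi, -theta, -phi)
        rot = Rotation.from_euler("ZYZ", [phi, theta, psi], degrees=True).inv()
        fs.append(np.fft.fftn(v))
        supports.append(WedgeMask(tilt_range_deg, rot).mask(v.shape))
    return np.stack(fs), np.stack(supports)


def _wedge_normalised_average(fs: np.ndarray, supports: np.ndarray,
                              members: np.ndarray) -> np.ndarray:
    # each record's spectrum is masked by its rotated wedge support before
    # summation: interpolation leaks energy outside the support, which would
    # otherwise survive normalisation as structured artefacts
    num = (fs[members] * supports[members]).sum(axis=0)
    den = supports[members].sum(axis=0)
    return np.real(np.fft.ifftn(num / np.maximum(den, 1e-9)))


def classify_multireference(
    stack: np.ndarray,
    poses: Optional[pd.DataFrame],
    k: int,
    focus_mask: Optional[np.ndarray] = None,
    seed: int = 0,
    tilt_range_deg: float = 60.0,
    max_iter: int = 10,
) -> Tuple[ClassModel, np.ndarray]:
    """Wedge-aware correlation k-means into ``k`` classes.

    Class averages are wedge-normalised averages of the inverse-transformed
    members in the reference frame; each record is then scored against every
    class by rotating the (focus-masked) average forward into the record's
    own frame, applying the record's missing wedge and correlating there —
    so wedge anisotropy cancels instead of masquerading as heterogeneity.
    Iterates until assignments are stable or ``max_iter``; deterministic for
    a fixed seed; an emptied class is re-seeded from the worst-fitting
    member.
    """
    n = len(stack)
    if k < 2 and n != k:
        raise ClassificationError("need k >= 2")
    if k > n:
        raise ClassificationError("more classes than subtomograms")
    rng = np.random.default_rng(seed)
    fs, supports = _aligned_stack(stack, poses, tilt_range_deg)
    subs = [np.asarray(stack[i], dtype=float) for i in range(n)]
    global_avg = _wedge_normalised_average(fs, supports, np.ones(n, dtype=bool))

    def composites(avgs: np.ndarray) -> np.ndarray:
        # focused classification: classes share the global average outside
        # the focus mask, so the missing-wedge bleed of surrounding density
        # is identical across templates and cancels in the comparison
        if focus_mask is None:
            return avgs
        return global_avg[None] + focus_mask[None] * (avgs - global_avg[None])

    def _inner(a: np.ndarray, b: np.ndarray) -> float:
        return float((a - a.mean()).ravel() @ (b - b.mean()).ravel())

    def score_against(comps: np.ndarray, i: int) -> Tuple[int, float]:
        """Amplitude-calibrated least-squares class choice for one record.

        Estimates a per-record signal amplitude against the mean template,
        then minimises ||v/alpha - t_j||^2 — plain correlation argmax is
        biased towards lower-norm (emptier) templates when classes nest.
        Returns (best class, correlation with the best template).
        """
        phi, theta, psi = _pose_tuple(poses, i)
        ts = []
        for comp in comps:
            t = comp
            if poses is not None:
                r = poses.iloc[i]
                t = rotate_zyz(t, phi, theta, psi)
                t = shift_volume(t, r.dx, r.dy, r.dz)
            ts.append(apply_missing_wedge(t, tilt_range_deg))
        tmean = np.mean(ts, axis=0)
        v = subs[i]
        alpha = _inner(v, tmean) / max(_inner(tmean, tmean), 1e-12)
        alpha = max(alpha, 1e-12)
        ml = [2.0 * _inner(v, t) / alpha - _inner(t, t) for t in ts]
        best = int(np.argmax(ml))
        tb = ts[best]
        denom = np.sqrt(max(_inner(v, v), 1e-12) * max(_inner(tb, tb), 1e-12))
        return best, _inner(v, tb) / denom

    scores = np.zeros(n)
    history: list = []
    assign = _initial_assignment(
        stack, poses, k, focus_mask, global_avg, tilt_range_deg, rng)
    masked_fs = fs * supports
    for _ in range(max_iter):
        nums = np.stack([
            masked_fs[assign == j].sum(axis=0) if (assign == j).any()
            else masked_fs[int(rng.integers(0, n))]
            for j in range(k)
        ])
        dens = np.stack([
            supports[assign == j].sum(axis=0) if (assign == j).any()
            else supports[int(rng.integers(0, n))].astype(float)
            for j in range(k)
        ])
        new_assign = np.empty(n, dtype=int)
        for i in range(n):
            # leave-one-out: a record's own noise in its class average would
            # otherwise anchor it to its current class at the symmetric
            # (all-averages-equal) saddle point
            avgs_i = []
            for j in range(k):
                num, den = nums[j], dens[j]
                if assign[i] == j and (assign == j).sum() > 1:
                    num = num - masked_fs[i]
                    den = den - supports[i]
                avgs_i.append(np.real(np.fft.ifftn(num / np.maximum(den, 1e-9))))
            comps = composites(np.stack(avgs_i))
            new_assign[i], scores[i] = score_against(comps, i)
        for j in range(k):
            if not (new_assign == j).any():
                worst = int(np.argmin(scores))
                new_assign[worst] = j
                scores[worst] = 0.0
        history.append(float(scores.mean()))
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    avgs = np.stack([
        _wedge_normalised_average(fs, supports, assign == j) for j in range(k)
    ])
    pops = np.bincount(assign, minlength=k)
    return ClassModel(avgs, pops, focus_mask, float(scores.mean()), history), assign


def _safe_cc(a: np.ndarray, b: np.ndarray, wedge: WedgeMask) -> float:
    try:
        return constrained_cc(a, b, wedge, None)
    except AlignmentError:
        return -1.0


def _initial_assignment(stack, poses, k, focus_mask, global_avg,
                        tilt_range_deg, rng) -> np.ndarray:
    """Seed the class split.

    With a focus mask: a 1D k-means on each record's amplitude-calibrated
    focus-region occupancy (how much of the global average's focus density
    the record carries) — a coarse but label-relevant axis that the
    iterations then sharpen.  Without a mask: a seeded random split.
    """
    n = len(stack)
    if focus_mask is not None and n > k:
        def _inner(a, b):
            return float((a - a.mean()).ravel() @ (b - b.mean()).ravel())

        feats = np.empty(n)
        for i in range(n):
            t_full = global_avg
            t_foc = global_avg * focus_mask
            if poses is not None:
                r = poses.iloc[i]
                phi, theta, psi = _pose_tuple(poses, i)
                t_full = shift_volume(
                    rotate_zyz(t_full, phi, theta, psi), r.dx, r.dy, r.dz)
                t_foc = shift_volume(
                    rotate_zyz(t_foc, phi, theta, psi), r.dx, r.dy, r.dz)
            t_full = apply_missing_wedge(t_full, tilt_range_deg)
            t_foc = apply_missing_wedge(t_foc, tilt_range_deg)
            v = np.asarray(stack[i], dtype=float)
            alpha = max(_inner(v, t_full) / max(_inner(t_full, t_full), 1e-12),
                        1e-12)
            feats[i] = _inner(v, t_foc) / alpha / max(
                _inner(t_foc, t_foc), 1e-12)
        if np.unique(feats).size >= k:
            from sklearn.cluster import KMeans
            km = KMeans(k, n_init=10, random_state=int(rng.integers(2 ** 31)))
            return km.fit(feats[:, None]).labels_.astype(int)
    assign = rng.integers(0, k, size=n)
    assign[rng.permutation(n)[:k]] = np.arange(k)  # every class seeded
    return assign


def tubule_focus_mask(model, box: int, voxel_nm: float, tubule: str,
                      radius_nm: Optional[float] = None) -> np.ndarray:
    """Cylindrical focus mask over one tubule in the canonical frame.

    The canonical reference frame has the blade pointing radially inward
    (orientation 180°) with the A-tubule centre at the box centre; the mask
    is a z-spanning cylinder around the chosen tubule's centre.
    """
    ring = model.triplet.rings[tubule]
    if radius_nm is None:
        radius_nm = ring.radius_major + 3.0
    delta = np.asarray(model.triplet.tubule_center(tubule)) - np.asarray(
        model.triplet.tubule_center("A"))
    # canonical frame basis (blade orientation 180°): u = (-1, 0), v = (0, -1)
    cx, cy = -delta[0], -delta[1]
    c = (box - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(box), np.arange(box), indexing="ij")
    r2 = ((xx - c) * voxel_nm - cx) ** 2 + ((yy - c) * voxel_nm - cy) ** 2
    mask2d = (r2 <= radius_nm ** 2).astype(float)
    return np.broadcast_to(mask2d, (box, box, box)).copy()


# --------------------------------------------------------------------------
# positional mapping of intermediates
# --------------------------------------------------------------------------

def map_positional_classes(
    records: pd.DataFrame,
    tubule: str,
    incomplete: Sequence[bool],
    end_window_nm: float = 29.0,
    short_threshold_nm: float = 10.0,
) -> Tuple[pd.Series, dict]:
    """Assign intermediate segments to the five positional classes.

    ``records`` needs ``filament_id``, ``s_nm`` and the tubule extents
    (``b_start``/``b_end`` or ``c_start``/``c_end``); ``incomplete`` flags
    the segments classified as having a partial tubule.  Rules, applied to
    incomplete segments: *short* if the tubule extent is under
    ``short_threshold_nm``; *nascent* if every segment of that filament's
    tubule is incomplete; *proximal_end* / *distal_end* if the segment lies
    within ``end_window_nm`` of the tubule minimum / maximum z; otherwise
    *mid*.  Records with missing extents are labelled ``unknown`` and
    excluded from the fractions.

    Returns per-record labels (empty string for complete segments) and a
    summary with per-label counts and fractions plus the combined fraction
    of proximal + distal + nascent.
    """
    lo_col, hi_col = f"{tubule.lower()}_start", f"{tubule.lower()}_end"
    incomplete = np.asarray(incomplete, dtype=bool)
    if len(incomplete) != len(records):
        raise ClassificationError("one incompleteness flag per record required")
    # nascent at filament level: the entire tubule is incomplete
    nascent_fil = {
        fid: bool(incomplete[g_idx].all())
        for fid, g_idx in records.groupby("filament_id").indices.items()
    }
    labels = []
    for i, (_, r) in enumerate(records.iterrows()):
        if not incomplete[i]:
            labels.append("")
            continue
        lo, hi = r.get(lo_col, np.nan), r.get(hi_col, np.nan)
        if not (np.isfinite(lo) and np.isfinite(hi)):
            labels.append("unknown")
            continue
        if hi - lo < short_threshold_nm:
            labels.append("short")
        elif nascent_fil[r.filament_id]:
            labels.append("nascent")
        elif r.s_nm <= lo + end_window_nm:
            labels.append("proximal_end")
        elif r.s_nm >= hi - end_window_nm:
            labels.append("distal_end")
        else:
            labels.append("mid")
    labels = pd.Series(labels, index=records.index, name="pos_class")
    counted = labels[labels.isin(POSITIONAL_LABELS)]
    n_lab = len(counted)
    fractions = {
        lab: (counted == lab).sum() / n_lab if n_lab else 0.0
        for lab in POSITIONAL_LABELS
    }
    summary = {
        "n_intermediates": int(incomplete.sum()),
        "n_labelled": int(n_lab),
        "n_unknown": int((labels == "unknown").sum()),
        "counts": {lab: int((counted == lab).sum()) for lab in POSITIONAL_LABELS},
        "fractions": fractions,
        "combined_end_fraction": combined_intermediate_fraction(fractions),
    }
    return labels, summary


def combined_intermediate_fraction(fractions: Dict[str, float]) -> float:
    """Combined fraction of end-located intermediates:
    proximal_end + distal_end + nascent."""
    return float(
        fractions.get("proximal_end", 0.0)
        + fractions.get("distal_end", 0.0)
        + fractions.get("nascent", 0.0)
    )


# --------------------------------------------------------------------------
# A-C linker schemes
# --------------------------------------------------------------------------

def reciprocal_acl_classification(
    stack: np.ndarray,
    poses: Optional[pd.DataFrame],
    scheme: str,
    k: int,
    recenter_shift_vox: Tuple[float, float, float] = (0.0, 0.0, 0.0),
    focus_mask: Optional[np.ndarray] = None,
    seed: int = 0,
    tilt_range_deg: float = 60.0,
    min_population_fraction: float = 0.05,
) -> Tuple[ClassModel, np.ndarray, np.ndarray]:
    """Classify A-C linker conformers with the A- or C-tubule as reference.

    The alignment origin is re-centred on the chosen tubule (a pure shift in
    the reference frame, ``recenter_shift_vox`` in x, y, z), then classified
    within ``focus_mask`` (by default the half-box nearest the reference
    tubule).  Classes smaller than ``min_population_fraction`` of N are
    flagged excluded (the mask of kept classes is returned).
    """
    if scheme not in ("A_ref", "C_ref"):
        raise ClassificationError(f"unknown scheme {scheme!r}")
    n = len(stack)
    dx, dy, dz = recenter_shift_vox
    if any(abs(s) > 0 for s in recenter_shift_vox):
        stack = np.stack([
            shift_volume(np.asarray(v, float), -dx, -dy, -dz) for v in stack
        ])
    if focus_mask is None:
        nz, ny, nx = stack[0].shape
        focus_mask = np.zeros((nz, ny, nx))
        if scheme == "A_ref":
            focus_mask[:, :, : nx // 2] = 1.0
        else:
            focus_mask[:, :, nx // 2:] = 1.0
    model, assign = classify_multireference(
        stack, poses, k, focus_mask=focus_mask, seed=seed,
        tilt_range_deg=tilt_range_deg,
    )
    keep = model.populations >= min_population_fraction * n
    if not keep.any():
        raise ClassificationError("all classes below the population threshold")
    return model, assign, keep


def composite_linker_map(
    avg_a_side: np.ndarray,
    avg_c_side: np.ndarray,
    class_average_low: np.ndarray,
    max_shift_vox: float = 6.0,
    min_fit_score: float = 0.2,
) -> Tuple[np.ndarray, dict]:
    """Composite of the two half-linker averages docked into a low-resolution
    class average.

    Each detailed average is rigid-fit (translation search maximising
    constrained CC) into the class average; the composite is the voxel-wise
    maximum of the two fitted maps.  Refuses to composite if either fit
    score falls below ``min_fit_score``.
    """
    if not (avg_a_side.shape == avg_c_side.shape == class_average_low.shape):
        raise ClassificationError("maps must share voxel grid")
    fits = {}
    fitted = []
    for name, vol in (("A_side", avg_a_side), ("C_side", avg_c_side)):
        shift, score = _fit_by_shift(vol, class_average_low, max_shift_vox)
        if score < min_fit_score:
            raise ClassificationError(
                f"{name} fit score {score:.3f} below threshold: refusing composite"
            )
        fits[name] = {"shift_vox": shift, "score": score}
        fitted.append(shift_volume(vol, *shift))
    composite = np.maximum(fitted[0], fitted[1])
    return composite, fits


def _fit_by_shift(vol: np.ndarray, target: np.ndarray,
                  max_shift: float) -> Tuple[Tuple[float, float, float], float]:
    fv = np.fft.fftn(vol)
    ft = np.fft.fftn(target)
    mask = np.ones(vol.shape, dtype=bool)
    mask[0, 0, 0] = False
    num = np.real(np.fft.ifftn(ft * np.conj(fv)))
    grids = np.meshgrid(*[np.fft.fftfreq(n) * n for n in vol.shape], indexing="ij")
    within = np.ones(vol.shape, dtype=bool)
    for g in grids:
        within &= np.abs(g) <= max_shift
    idx = np.unravel_index(np.argmax(np.where(within, num, -np.inf)), vol.shape)
    dz, dy, dx = (float(g[idx]) for g in grids)
    denom = np.linalg.norm(fv[mask]) * np.linalg.norm(ft[mask])
    score = float(num[idx] * num.size / denom) if denom > 0 else 0.0
    return (dx, dy, dz), min(score, 1.0)
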