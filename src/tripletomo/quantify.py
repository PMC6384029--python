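"""Quantitative analysis: twist statistics, FSC resolution, periodicity,
MIP segmentation with molecular-weight estimation, tubule-length statistics.

Conventions: lengths nm, spatial frequency 1/nm, masses Da unless a display
unit is stated.  Protein density for volume-to-mass conversion is
0.849 Da/Å³.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PROTEIN_DENSITY_DA_PER_A3",
    "ClassCountTable",
    "TwistMeasurement",
    "FSCCurve",
    "MIPSegment",
    "LengthStats",
    "weighted_twist",
    "swing_range",
    "measure_twist",
    "mass_from_volume",
    "fsc",
    "resolution_at",
    "periodicity",
    "segment_mips",
    "measure_lengths",
]

PROTEIN_DENSITY_DA_PER_A3 = 0.849


class QuantifyError(ValueError):
    pass


# --------------------------------------------------------------------------
# twist statistics
# --------------------------------------------------------------------------

@dataclass
class ClassCountTable:
    """Per-class swing angles and per-point class counts.

    ``theta_deg[j]`` is the twist angle of conformational class j;
    ``counts[i, j]`` the number of subtomograms of class j at longitudinal
    sample point i.  The default longitudinal grid is six points over 90 nm.
    """

    theta_deg: np.ndarray
    counts: np.ndarray
    points_nm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.theta_deg = np.asarray(self.theta_deg, dtype=float)
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if self.points_nm is None:
            self.points_nm = np.linspace(0.0, 90.0, self.counts.shape[0])
        self.points_nm = np.asarray(self.points_nm, dtype=float)
        if self.counts.shape[1] != self.theta_deg.size:
            raise QuantifyError("counts must have one column per class angle")
        if self.counts.shape[0] != self.points_nm.size:
            raise QuantifyError("counts must have one row per sample point")
        if (self.counts < 0).any():
            raise QuantifyError("counts must be nonnegative")


@dataclass
class TwistMeasurement:
    table: ClassCountTable
    weighted_deg: np.ndarray
    swing_range_deg: float


def weighted_twist(table: ClassCountTable) -> np.ndarray:
    """Count-weighted mean swing angle at each longitudinal point:
    T_i = sum_j theta_j N_ij / sum_j N_ij.

    Errors on any point with all-zero counts.
    """
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        bad = np.flatnonzero(totals == 0)
        raise QuantifyError(f"all-zero counts at point(s) {bad.tolist()}")
    return table.counts @ table.theta_deg / totals


def swing_range(table: ClassCountTable) -> float:
    """Full range of the class angles: max(theta) - min(theta), degrees."""
    if table.theta_deg.size < 2:
        raise QuantifyError("swing range needs at least two classes")
    return float(table.theta_deg.max() - table.theta_deg.min())


def measure_twist(table: ClassCountTable) -> TwistMeasurement:
    return TwistMeasurement(table, weighted_twist(table), swing_range(table))


# --------------------------------------------------------------------------
# Fourier shell correlation
# --------------------------------------------------------------------------

@dataclass
class FSCCurve:
    """Shell-wise correlation between two half maps.

    ``freq_per_nm`` are shell-centre spatial frequencies from DC to Nyquist;
    ``correlation`` the normalised cross-correlation per shell.
    """

    freq_per_nm: np.ndarray
    correlation: np.ndarray
    voxel_nm: float
    threshold: float = 0.143


def fsc(half1: np.ndarray, half2: np.ndarray, voxel_nm: float = 1.0,
        shell_width: int = 1) -> FSCCurve:
    """Fourier shell correlation between two half maps.

    Shells are ``shell_width`` Fourier voxels wide; fsc(v, v) = 1 in every
    shell.  No masking or phase-randomisation correction is applied — this
    is the bare gold-standard curve.
    """
    if half1.shape != half2.shape:
        raise QuantifyError("half maps must share shape")
    n = half1.shape[0]
    f1 = np.fft.fftn(half1)
    f2 = np.fft.fftn(half2)
    grids = np.meshgrid(*[np.fft.fftfreq(s) * s for s in half1.shape],
                        indexing="ij")
    r = np.sqrt(sum(g ** 2 for g in grids))
    nshell = int(np.floor(n / 2 / shell_width)) + 1
    idx = np.minimum((r / shell_width).astype(int), nshell - 1)
    num = np.zeros(nshell, dtype=complex)
    d1 = np.zeros(nshell)
    d2 = np.zeros(nshell)
    np.add.at(num, idx.ravel(), (f1 * np.conj(f2)).ravel())
    np.add.at(d1, idx.ravel(), (np.abs(f1) ** 2).ravel())
    np.add.at(d2, idx.ravel(), (np.abs(f2) ** 2).ravel())
    denom = np.sqrt(d1 * d2)
    corr = np.where(denom > 0, np.real(num) / np.maximum(denom, 1e-300), 0.0)
    freqs = np.arange(nshell) * shell_width / (n * voxel_nm)
    return FSCCurve(freqs, corr, voxel_nm)


def resolution_at(curve: FSCCurve, threshold: float = 0.143) -> float:
    """Resolution (nm) at the first crossing below ``threshold``.

    Linearly interpolated between the shells flanking the crossing; returns
    ``inf``-free behaviour: if the curve never drops below threshold the
    Nyquist resolution is reported (the map is consistent to the sampling
    limit); NaN if it starts below threshold.
    """
    c = curve.correlation
    f = curve.freq_per_nm
    if c.size < 2 or c[0] < threshold:
        return float("nan")
    below = np.flatnonzero(c < threshold)
    below = below[below > 0]
    if below.size == 0:
        return float(1.0 / f[-1])
    j = int(below[0])
    f0, f1 = f[j - 1], f[j]
    c0, c1 = c[j - 1], c[j]
    fx = f0 + (c0 - threshold) / max(c0 - c1, 1e-12) * (f1 - f0)
    return float(1.0 / fx)


# --------------------------------------------------------------------------
# longitudinal periodicity
# --------------------------------------------------------------------------

def periodicity(volume: np.ndarray, axis_mask: Optional[np.ndarray] = None,
                voxel_nm: float = 1.0,
                period_range_nm: Tuple[float, float] = (2.0, 20.0)) -> float:
    """Dominant longitudinal repeat (nm) of masked density.

    The masked volume is averaged over x and y into a 1D axial profile; the
    dominant non-DC peak of its power spectrum within ``period_range_nm``
    (2–20 nm by default, avoiding box-length artefacts) is reported as a
    period in nm.
    """
    vol = np.asarray(volume, dtype=float)
    if axis_mask is not None:
        vol = vol * axis_mask
        weights = axis_mask.reshape(vol.shape[0], -1).sum(axis=1)
    else:
        weights = np.full(vol.shape[0], np.prod(vol.shape[1:]))
    profile = vol.reshape(vol.shape[0], -1).sum(axis=1)
    profile = np.where(weights > 0, profile / np.maximum(weights, 1), 0.0)
    if np.ptp(profile) == 0:
        raise QuantifyError("constant density: no periodicity")
    # crop to the masked span and taper: the finite extent of the structure
    # otherwise leaks broad low-frequency power into the period search
    nonzero = np.flatnonzero(weights > 0)
    if nonzero.size > 0:
        profile = profile[nonzero[0]:nonzero[-1] + 1]
    nz = profile.size
    if nz * voxel_nm < 4 * period_range_nm[0]:
        raise QuantifyError("masked column too short for the period search")
    profile = (profile - profile.mean()) * np.hanning(nz)
    # zero-pad for fine frequency sampling so the peak is not quantised to
    # the raw box-length grid
    npad = max(8 * nz, 1024)
    power = np.abs(np.fft.rfft(profile, n=npad)) ** 2
    freqs = np.fft.rfftfreq(npad, d=voxel_nm)  # 1/nm
    with np.errstate(divide="ignore"):
        periods = np.where(freqs > 0, 1.0 / np.maximum(freqs, 1e-12), np.inf)
    valid = (periods >= period_range_nm[0]) & (periods <= period_range_nm[1])
    if not valid.any():
        raise QuantifyError("no spectral sample in the period search range")
    j = int(np.flatnonzero(valid)[np.argmax(power[valid])])
    if power[j] <= 0:
        raise QuantifyError("no periodic signal in range")
    return float(periods[j])


# --------------------------------------------------------------------------
# MIP segmentation and molecular weight
# --------------------------------------------------------------------------

@dataclass
class MIPSegment:
    """One segmented non-tubulin density component."""

    name: str
    voxel_indices: np.ndarray       # (n, 3) z, y, x
    volume_a3: float
    mass_da: float

    @property
    def mass_kda(self) -> float:
        return self.mass_da / 1000.0


def mass_from_volume(volume_a3: float) -> float:
    """Molecular weight (Da) from a density volume (Å³) at protein density
    0.849 Da/Å³."""
    return PROTEIN_DENSITY_DA_PER_A3 * volume_a3


def segment_mips(
    average_map: np.ndarray,
    model_density: np.ndarray,
    voxel_nm: float,
    threshold_sigma: float = 3.0,
    min_voxels: int = 5,
    background_mask: Optional[np.ndarray] = None,
) -> List[MIPSegment]:
    """Segment non-tubulin densities from an average map.

    The tubule-model density is subtracted; the difference map is
    thresholded at background mean + ``threshold_sigma`` * SD (background =
    voxels outside a dilated model mask unless given explicitly); connected
    components (26-connectivity) of at least ``min_voxels`` voxels become
    segments with mass = 0.849 Da/Å³ × volume.
    """
    if average_map.shape != model_density.shape:
        raise QuantifyError("maps must be co-registered on one grid")
    diff = np.asarray(average_map, dtype=float) - np.asarray(model_density, float)
    if background_mask is None:
        model_mask = model_density > 0.1 * model_density.max() if \
            model_density.max() > 0 else np.zeros_like(model_density, bool)
        background_mask = ~ndimage.binary_dilation(model_mask, iterations=3)
    bg = diff[background_mask]
    if bg.size == 0:
        bg = diff.ravel()  # model fills the box: fall back to global stats
    thr = bg.mean() + threshold_sigma * bg.std()
    above = diff > thr
    labels, nlab = ndimage.label(above, structure=np.ones((3, 3, 3), int))
    voxel_vol_a3 = (voxel_nm * 10.0) ** 3
    segments: List[MIPSegment] = []
    for lab in range(1, nlab + 1):
        idx = np.argwhere(labels == lab)
        if len(idx) < min_voxels:
            continue
        vol_a3 = len(idx) * voxel_vol_a3
        segments.append(MIPSegment(
            name=f"MIP{len(segments) + 1}",
            voxel_indices=idx,
            volume_a3=vol_a3,
            mass_da=mass_from_volume(vol_a3),
        ))
    segments.sort(key=lambda s: -s.volume_a3)
    for i, s in enumerate(segments):
        s.name = f"MIP{i + 1}"
    return segments


# --------------------------------------------------------------------------
# tubule length statistics
# --------------------------------------------------------------------------

@dataclass
class LengthStats:
    """Per-tubule length statistics: mean, SD and number of measurements."""

    mean_nm: Dict[str, float]
    sd_nm: Dict[str, float]
    n: Dict[str, int]


def measure_lengths(
    volume: np.ndarray,
    traces: Sequence[dict],
    voxel_nm: float = 1.0,
    threshold_fraction: float = 0.1,
) -> Tuple[pd.DataFrame, LengthStats]:
    """Measure tubule extents along filament traces in a rendered volume.

    Each trace is a dict with ``tubule`` (A/B/C), ``filament_id`` and an
    (n, 3) array ``points_vox`` of (z, y, x) voxel positions along the
    filament axis.  The extent runs from the first to the last
    supra-threshold density sample along the trace (threshold =
    ``threshold_fraction`` × volume max); zero-density traces yield length 0
    with a warning flag.
    """
    thr = threshold_fraction * float(volume.max())
    rows = []
    for tr in traces:
        pts = np.asarray(tr["points_vox"])
        if ((pts < 0).any()
                or (pts >= np.asarray(volume.shape)[None, :]).any()):
            raise QuantifyError(
                f"trace for filament {tr.get('filament_id')} leaves the volume")
        dens = ndimage.map_coordinates(volume, pts.T.astype(float), order=1)
        above = np.flatnonzero(dens > thr)
        if above.size == 0:
            length = 0.0
            warn = True
        else:
            seg = pts[above[-1]] - pts[above[0]]
            length = float(np.linalg.norm(seg)) * voxel_nm
            warn = False
        rows.append({
            "filament_id": tr.get("filament_id", -1),
            "tubule": tr["tubule"],
            "length_nm": length,
            "zero_density": warn,
        })
    df = pd.DataFrame(rows)
    mean, sd, n = {}, {}, {}
    for tub, g in df.groupby("tubule"):
        mean[tub] = float(g.length_nm.mean())
        sd[tub] = float(g.length_nm.std(ddof=1)) if len(g) > 1 else 0.0
        n[tub] = int(len(g))
    return df, LengthStats(mean, sd, n)
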