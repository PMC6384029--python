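"""Robust filament-constrained regression of alignment parameters.

A microtubule triplet is a continuous filament, so the pose parameters of
consecutive subtomograms along it must vary smoothly with arc length.  Each
of the six pose parameters is regressed independently on arc length with a
RANSAC consensus fit (default: straight line, matching the progressive
longitudinal twist): random minimal subsets propose a polynomial, inliers
are counted within a per-parameter tolerance, and the best consensus model
(most inliers, ties broken by inlier RMS residual) is used to flag outlier
subtomograms and replace their values with the regression prediction.
Angles are unwrapped along the filament before fitting so 360° jumps do not
break the regression; inliers are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "RansacConfig",
    "RansacResult",
    "FilamentSeries",
    "ransac_fit",
    "constrain_all",
    "iterate_align_constrain",
]

ANGLE_PARAMS = ("phi", "theta", "psi")
SHIFT_PARAMS = ("dx", "dy", "dz")
POSE_PARAMS = ANGLE_PARAMS + SHIFT_PARAMS


class RansacError(ValueError):
    pass


@dataclass
class RansacConfig:
    """Hyper-parameters of the per-filament consensus fit.

    ``tolerance`` maps parameter name to inlier tolerance (degrees for
    angles, nm for shifts).
    """

    degree: int = 1
    n_iterations: int = 1000
    tolerance: Dict[str, float] = field(
        default_factory=lambda: {
            "phi": 2.0, "theta": 2.0, "psi": 2.0,
            "dx": 1.5, "dy": 1.5, "dz": 1.5,
        }
    )
    min_inlier_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise RansacError("degree must be >= 0")
        if not 0 < self.min_inlier_fraction <= 1:
            raise RansacError("min_inlier_fraction must be in (0, 1]")
        for k, v in self.tolerance.items():
            if v <= 0:
                raise RansacError(f"tolerance for {k!r} must be positive")


@dataclass
class FilamentSeries:
    """Ordered pose samples along one filament: arc positions s (nm) and a
    value per position for each pose parameter."""

    filament_id: int
    s: np.ndarray
    values: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if self.s.size < 1:
            raise RansacError("a filament series needs at least one position")
        if np.any(np.diff(self.s) <= 0):
            raise RansacError("arc positions must be strictly increasing")
        for k, v in self.values.items():
            self.values[k] = np.asarray(v, dtype=float)
            if self.values[k].shape != self.s.shape:
                raise RansacError(f"values[{k!r}] length mismatch")


@dataclass
class RansacResult:
    """Consensus fit of one filament: per-parameter coefficients (highest
    degree first, np.polyfit order), combined inlier mask, corrected values
    and per-position residuals.  ``status`` is 'ok', 'skipped' (too few
    points) or 'failed' (no admissible consensus)."""

    filament_id: int
    status: str
    coefficients: Dict[str, np.ndarray]
    inlier_mask: np.ndarray
    corrected: Dict[str, np.ndarray]
    residuals: Dict[str, np.ndarray]


def _unwrap_deg(a: np.ndarray) -> np.ndarray:
    return np.degrees(np.unwrap(np.radians(a)))


def _ransac_1d(
    s: np.ndarray,
    y: np.ndarray,
    degree: int,
    tol: float,
    n_iter: int,
    min_inliers: int,
    rng: np.random.Generator,
) -> Tuple[Optional[np.ndarray], np.ndarray]:
    """Best consensus polynomial for one parameter: (coeffs, inlier mask).

    All minimal-subset hypotheses are evaluated in one vectorised batch
    (Vandermonde solve); the winner (most inliers, then lowest inlier RMS)
    is refit on its full consensus set.
    """
    n = s.size
    m = degree + 1  # minimal subset size
    # sampled minimal subsets, vectorised over iterations
    idx = np.argsort(rng.random((n_iter, n)), axis=1)[:, :m]
    ss = s[idx]                                     # (n_iter, m)
    yy = y[idx]
    powers = np.arange(degree, -1, -1)
    V = ss[..., None] ** powers                     # (n_iter, m, m)
    ok = np.abs(np.linalg.det(V)) > 1e-12 if m > 1 else np.ones(n_iter, bool)
    coefs = np.zeros((n_iter, m))
    if ok.any():
        coefs[ok] = np.linalg.solve(V[ok], yy[ok][..., None])[..., 0]
    V_full = s[:, None] ** powers                   # (n, m)
    resid = y[None, :] - coefs @ V_full.T           # (n_iter, n)
    inl = np.abs(resid) <= tol
    counts = np.where(ok, inl.sum(axis=1), -1)
    admissible = counts >= max(m, min_inliers)
    if not admissible.any():
        return None, np.zeros(n, dtype=bool)
    with np.errstate(invalid="ignore"):
        rms = np.sqrt(
            np.sum(np.where(inl, resid, 0.0) ** 2, axis=1)
            / np.maximum(counts, 1)
        )
    order = np.where(admissible, counts, -1) * 1e6 - np.where(np.isfinite(rms), rms, 1e6)
    best = int(np.argmax(order))
    # refit on the winning consensus set
    coef = np.polyfit(s[inl[best]], y[inl[best]], degree)
    final_inl = np.abs(y - np.polyval(coef, s)) <= tol
    return coef, final_inl


def ransac_fit(series: FilamentSeries, config: RansacConfig) -> RansacResult:
    """Consensus-fit all pose parameters of one filament and correct outliers.

    A subtomogram is an outlier if any parameter rejects it; outlier values
    are replaced by the per-parameter model predictions, inliers are passed
    through untouched (bitwise).  Deterministic for a fixed config seed.
    """
    n = series.s.size
    if n < config.degree + 2:
        return RansacResult(
            series.filament_id, "skipped", {},
            np.ones(n, dtype=bool),
            {k: v.copy() for k, v in series.values.items()},
            {k: np.zeros(n) for k in series.values},
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, series.filament_id & 0x7FFFFFFF])
    )
    min_inliers = int(np.ceil(config.min_inlier_fraction * n))
    coefs: Dict[str, np.ndarray] = {}
    resids: Dict[str, np.ndarray] = {}
    masks: Dict[str, np.ndarray] = {}
    corrected: Dict[str, np.ndarray] = {}
    failed = False
    for name, raw in series.values.items():
        y = _unwrap_deg(raw) if name in ANGLE_PARAMS else raw.astype(float)
        tol = config.tolerance.get(name, 2.0)
        coef, inl = _ransac_1d(series.s, y, config.degree, tol,
                               config.n_iterations, min_inliers, rng)
        if coef is None:
            failed = True
            coefs[name] = np.array([])
            masks[name] = np.ones(n, dtype=bool)
            resids[name] = np.zeros(n)
            corrected[name] = raw.copy()
            continue
        pred = np.polyval(coef, series.s)
        resid = y - pred
        out = y.copy()
        out[~inl] = pred[~inl]
        if name in ANGLE_PARAMS:
            full = raw.astype(float).copy()
            full[~inl] = np.mod(pred[~inl], 360.0)
            out = full
        coefs[name] = coef
        masks[name] = inl
        resids[name] = resid
        corrected[name] = out
    if failed:
        return RansacResult(
            series.filament_id, "failed", coefs, np.ones(n, dtype=bool),
            {k: v.copy() for k, v in series.values.items()}, resids,
        )
    combined = np.ones(n, dtype=bool)
    for name in series.values:
        combined &= masks[name]
    # an outlier in any parameter gets all its outlying parameters corrected
    return RansacResult(series.filament_id, "ok", coefs, combined,
                        corrected, resids)


def _series_from_group(fid: int, g: pd.DataFrame) -> FilamentSeries:
    g = g.sort_values("s_nm")
    return FilamentSeries(
        filament_id=int(fid),
        s=g["s_nm"].to_numpy(),
        values={p: g[p].to_numpy() for p in POSE_PARAMS if p in g.columns},
    )


def constrain_all(
    poses: pd.DataFrame, config: RansacConfig
) -> Tuple[pd.DataFrame, dict]:
    """Apply the filament constraint to a full pose table.

    ``poses`` must carry ``filament_id``, ``s_nm`` and the pose columns;
    filaments are processed independently.  Returns the corrected table (row
    order preserved) and a report with per-filament outlier counts.
    """
    out = poses.copy()
    report: dict = {"filaments": {}, "n_records": int(len(poses))}
    total_out = 0
    for fid, g in poses.groupby("filament_id"):
        series = _series_from_group(fid, g)
        res = ransac_fit(series, config)
        order = g.sort_values("s_nm").index
        n_out = int((~res.inlier_mask).sum()) if res.status == "ok" else 0
        total_out += n_out
        report["filaments"][str(int(fid))] = {
            "status": res.status,
            "n_points": int(len(g)),
            "n_outliers": n_out,
            "outlier_fraction": n_out / len(g),
        }
        if res.status == "ok":
            for p in series.values:
                out.loc[order, p] = res.corrected[p]
    report["n_outliers"] = total_out
    report["outlier_fraction"] = total_out / max(len(poses), 1)
    return out, report


def iterate_align_constrain(
    stack: np.ndarray,
    ref: np.ndarray,
    poses: pd.DataFrame,
    align_fn,
    config: RansacConfig,
    n_rounds: int = 2,
    divergence_drop: float = 0.05,
) -> Tuple[pd.DataFrame, List[dict]]:
    """Alternate alignment and filament constraint for ``n_rounds``.

    ``align_fn(stack, ref, poses) -> poses`` performs one alignment pass
    (typically a prior-constrained grid search seeded from the current
    poses).  Stops early, reporting, if the mean alignment score drops by
    more than ``divergence_drop``.
    """
    if n_rounds < 1:
        raise RansacError("n_rounds must be >= 1")
    history: List[dict] = []
    prev_score = -np.inf
    for rnd in range(n_rounds):
        poses = align_fn(stack, ref, poses)
        score = float(poses["score"].mean()) if "score" in poses else np.nan
        poses, report = constrain_all(poses, config)
        history.append({"round": rnd, "mean_score": score, "report": report})
        if np.isfinite(prev_score) and score < prev_score - divergence_drop:
            history[-1]["diverged"] = True
            break
        prev_score = score
    return poses, history
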