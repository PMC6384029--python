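"""End-to-end pipeline: simulate → align → constrain → classify → average →
quantify, with per-stage manifests and a subtomogram count ledger.

Every stage is a pure function of (inputs, config, seed); manifests record
inputs, outputs, seeds and output checksums so a rerun with the same config
is verifiable.  The count ledger reproduces dataset bookkeeping: source
subtomogram counts are pooled and per-tubule exclusions (defective or
incomplete structures found by focused classification) are subtracted to
give the per-tubule averaging populations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import geometry, quantify, simulate
from .align import SearchGrid, WedgeMask, align_to_reference
from .align import average_subtomograms, AlignmentParams
from .classify import classify_multireference, map_positional_classes, tubule_focus_mask
from .mrcio import write_mrc
from .ransac import RansacConfig, constrain_all
from .simulate import IntermediateSpec, SimulationConfig

__all__ = [
    "CountLedger",
    "PipelineConfig",
    "run_pipeline",
    "align_filament_stack",
    "estimate_twist_rate",
]


class PipelineError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# count ledger
# --------------------------------------------------------------------------

class CountLedger:
    """Subtomogram bookkeeping across pipeline filters.

    Source datasets are pooled into a triplet total; focused classification
    then excludes defective/incomplete structures per tubule, giving the
    population behind each per-tubule average.
    """

    def __init__(self) -> None:
        self.sources: Dict[str, int] = {}
        self.exclusions: Dict[str, int] = {}

    def add_source(self, name: str, count: int) -> None:
        if count < 0:
            raise PipelineError("counts must be nonnegative")
        self.sources[name] = int(count)

    def exclude(self, tubule: str, count: int) -> None:
        if count < 0:
            raise PipelineError("counts must be nonnegative")
        self.exclusions[tubule] = int(count)

    @property
    def total(self) -> int:
        return sum(self.sources.values())

    def tubule_count(self, tubule: str) -> int:
        return self.total - self.exclusions.get(tubule, 0)

    def table(self) -> pd.DataFrame:
        rows = [{"structure": "Triplet", "n_subtomograms": self.total}]
        for tub in sorted(self.exclusions):
            rows.append({
                "structure": f"{tub}-tubule",
                "n_subtomograms": self.tubule_count(tub),
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "sources": dict(self.sources),
            "total": self.total,
            "exclusions": dict(self.exclusions),
            "per_tubule": {t: self.tubule_count(t) for t in self.exclusions},
        }


# --------------------------------------------------------------------------
# config
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Full pipeline configuration; ``seed`` feeds every stochastic stage."""

    out_dir: str = "tripletomo_run"
    seed: int = 17
    twist_rate_deg_per_nm: float = 0.12
    theta0_deg: float = 35.0
    length_nm: float = 100.0
    n_filaments: int = 9
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    intermediates: IntermediateSpec = field(default_factory=IntermediateSpec)
    ransac: RansacConfig = field(default_factory=RansacConfig)
    k_classes: int = 2
    end_window_nm: float = 29.0
    coarse_step_deg: float = 6.0
    local_halfwidth_deg: float = 8.0
    local_step_deg: float = 2.0
    max_shift_vox: float = 4.0
    # bookkeeping of the full-scale study this run emulates
    source_counts: Dict[str, int] = field(default_factory=dict)
    exclusion_counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        self.ransac = dataclasses.replace(self.ransac, seed=self.seed)


# --------------------------------------------------------------------------
# stage helpers
# --------------------------------------------------------------------------

def align_filament_stack(
    stack: np.ndarray,
    records: pd.DataFrame,
    ref: np.ndarray,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Align every subtomogram to the reference, filament by filament.

    The first segment of each filament gets a full in-plane grid search at
    ``coarse_step_deg``; subsequent segments search a window of
    ``local_halfwidth_deg`` around the previous estimate (filament
    continuity prior), all followed by local refinement.
    """
    wedge = WedgeMask(config.sim.tilt_range_deg)
    out = records.copy()
    out["phi"] = 0.0
    out["theta"] = 0.0
    out["psi"] = 0.0
    out[["dx", "dy", "dz"]] = 0.0
    out["score"] = 0.0
    for fid, g in records.groupby("filament_id"):
        prev_phi: Optional[float] = None
        for idx in g.sort_values("s_nm").index:
            if prev_phi is None:
                phis = np.arange(0.0, 360.0, config.coarse_step_deg)
            else:
                phis = prev_phi + np.arange(
                    -config.local_halfwidth_deg,
                    config.local_halfwidth_deg + 1e-9,
                    config.local_step_deg,
                )
            grid = SearchGrid(phi=phis, max_shift=config.max_shift_vox)
            p = align_to_reference(np.asarray(stack[idx], float), ref, grid, wedge)
            out.loc[idx, ["phi", "theta", "psi", "dx", "dy", "dz", "score"]] = [
                p.phi, p.theta, p.psi, p.dx, p.dy, p.dz, p.score,
            ]
            prev_phi = p.phi
    return out


def estimate_twist_rate(poses: pd.DataFrame) -> Tuple[float, str]:
    """Longitudinal twist rate (deg/nm) and handedness from aligned poses.

    Per-filament straight-line fit of the unwrapped in-plane angle against
    arc length; the rate is the mean slope.  Positive slope (angle growing
    counterclockwise towards the plus end) is left-handed.
    """
    slopes = []
    for _, g in poses.groupby("filament_id"):
        g = g.sort_values("s_nm")
        if len(g) < 2:
            continue
        phi = np.degrees(np.unwrap(np.radians(g["phi"].to_numpy())))
        slopes.append(np.polyfit(g["s_nm"].to_numpy(), phi, 1)[0])
    if not slopes:
        raise PipelineError("no filament with >= 2 segments")
    rate = float(np.mean(slopes))
    hand = "left" if rate > 0 else ("right" if rate < 0 else "none")
    return rate, hand


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the result summary (also written to disk)."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifests: List[dict] = []
    summary: dict = {"seed": config.seed}

    def record_stage(name: str, outputs: List[str], extra: Optional[dict] = None):
        manifests.append({
            "stage": name,
            "seed": config.seed,
            "outputs": {
                os.path.basename(p): _sha256(p) for p in outputs
            },
            "info": extra or {},
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        })

    model = geometry.default_procentriole(
        rate_deg_per_nm=config.twist_rate_deg_per_nm,
        theta0_deg=config.theta0_deg,
        length_nm=config.length_nm,
    )
    model.save_json(os.path.join(config.out_dir, "model.json"))

    # -- simulate ----------------------------------------------------------
    stack, records = simulate.simulate_subtomograms(
        model, config.sim, config.intermediates, n_filaments=config.n_filaments
    )
    gt_path = os.path.join(config.out_dir, "ground_truth.csv")
    records.to_csv(gt_path, index=False)
    record_stage("simulate", [gt_path], {"n_subtomograms": int(len(stack))})

    # -- align -------------------------------------------------------------
    ref = simulate.make_reference(model, config.sim)
    ref_path = os.path.join(config.out_dir, "reference.mrc")
    write_mrc(ref_path, ref, config.sim.voxel_nm)
    poses = align_filament_stack(stack, records, ref, config)
    aligned_path = os.path.join(config.out_dir, "poses_aligned.csv")
    poses.to_csv(aligned_path, index=False)
    record_stage("align", [ref_path, aligned_path],
                 {"mean_score": float(poses["score"].mean())})

    # -- constrain ---------------------------------------------------------
    constrained, report = constrain_all(poses, config.ransac)
    constrained_path = os.path.join(config.out_dir, "poses_constrained.csv")
    constrained.to_csv(constrained_path, index=False)
    report_path = os.path.join(config.out_dir, "ransac_report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1)
    record_stage("constrain", [constrained_path, report_path],
                 {"outlier_fraction": report["outlier_fraction"]})

    # -- classify (B-tubule focus: detect incomplete tubules) --------------
    focus = tubule_focus_mask(model, config.sim.box, config.sim.voxel_nm, "B")
    cmodel, assign = classify_multireference(
        stack, constrained, config.k_classes, focus_mask=focus,
        seed=config.seed, tilt_range_deg=config.sim.tilt_range_deg,
    )
    # the class with lower focus-region density is the incomplete one; with
    # too few members or negligible density contrast the split is noise and
    # no segment is flagged
    focus_density = [
        float((cmodel.averages[j] * focus).sum()) for j in range(cmodel.k)
    ]
    partial_class = int(np.argmin(focus_density))
    contrast = (max(focus_density) - min(focus_density)) / max(
        abs(max(focus_density)), 1e-9)
    if cmodel.populations.min() < 3 or contrast < 0.05:
        incomplete = np.zeros(len(stack), dtype=bool)
    else:
        incomplete = assign == partial_class
    labels, pos_summary = map_positional_classes(
        constrained, "B", incomplete, end_window_nm=config.end_window_nm,
    )
    assign_path = os.path.join(config.out_dir, "class_assignments.csv")
    pd.DataFrame({
        "record": np.arange(len(assign)),
        "class": assign,
        "incomplete": incomplete,
        "pos_class": labels.to_numpy(),
    }).to_csv(assign_path, index=False)
    pos_path = os.path.join(config.out_dir, "positional_summary.json")
    with open(pos_path, "w") as fh:
        json.dump(pos_summary, fh, indent=1)
    record_stage("classify", [assign_path, pos_path],
                 {"populations": cmodel.populations.tolist()})

    # -- count ledger ------------------------------------------------------
    ledger = CountLedger()
    if config.source_counts:
        for name, cnt in config.source_counts.items():
            ledger.add_source(name, cnt)
        for tub, cnt in config.exclusion_counts.items():
            ledger.exclude(tub, cnt)
    else:
        ledger.add_source("simulated", len(stack))
        ledger.exclude("B", int(incomplete.sum()))
    ledger_path = os.path.join(config.out_dir, "count_ledger.json")
    with open(ledger_path, "w") as fh:
        json.dump(ledger.to_dict(), fh, indent=1)
    ledger.table().to_csv(
        os.path.join(config.out_dir, "count_ledger.csv"), index=False)
    record_stage("ledger", [ledger_path], ledger.to_dict())
    summary["count_ledger"] = ledger.to_dict()

    # -- average + FSC (complete segments only) ----------------------------
    keep = np.flatnonzero(~incomplete)
    params = [
        AlignmentParams(
            phi=float(constrained.loc[i, "phi"]),
            theta=float(constrained.loc[i, "theta"]),
            psi=float(constrained.loc[i, "psi"]),
            dx=float(constrained.loc[i, "dx"]),
            dy=float(constrained.loc[i, "dy"]),
            dz=float(constrained.loc[i, "dz"]),
        )
        for i in keep
    ]
    wedges = [WedgeMask(config.sim.tilt_range_deg)] * len(keep)
    full, (h1, h2) = average_subtomograms(stack[keep], params, wedges)
    avg_path = os.path.join(config.out_dir, "average.mrc")
    write_mrc(avg_path, full, config.sim.voxel_nm)
    curve = quantify.fsc(h1, h2, config.sim.voxel_nm)
    res = quantify.resolution_at(curve)
    fsc_path = os.path.join(config.out_dir, "fsc.tsv")
    np.savetxt(fsc_path,
               np.column_stack([curve.freq_per_nm, curve.correlation]),
               delimiter="\t", header="freq_per_nm\tcorrelation")
    record_stage("average", [avg_path, fsc_path], {"resolution_nm": res})
    summary["resolution_nm"] = res

    # -- twist -------------------------------------------------------------
    rate, hand = estimate_twist_rate(constrained)
    twist_path = os.path.join(config.out_dir, "twist.json")
    with open(twist_path, "w") as fh:
        json.dump({"rate_deg_per_nm": rate, "handedness": hand}, fh, indent=1)
    record_stage("twist", [twist_path], {"rate": rate, "handedness": hand})
    summary["twist_rate_deg_per_nm"] = rate
    summary["handedness"] = hand

    # -- molecular weights (difference vs undecorated model density) -------
    bare = dataclasses.replace(
        model,
        triplet=dataclasses.replace(model.triplet, decorations=[]),
        per_triplet_tubule_extents=None,
    )
    model_density = simulate.make_reference(bare, config.sim)
    segs = quantify.segment_mips(ref, model_density, config.sim.voxel_nm)
    mips_path = os.path.join(config.out_dir, "mips.csv")
    pd.DataFrame([
        {"name": s.name, "n_voxels": len(s.voxel_indices),
         "volume_A3": s.volume_a3, "mass_kda": s.mass_kda}
        for s in segs
    ]).to_csv(mips_path, index=False)
    record_stage("mw", [mips_path], {"n_segments": len(segs)})
    summary["n_mip_segments"] = len(segs)

    # -- lengths -----------------------------------------------------------
    stats = {
        t: (float(np.mean([e[t][1] - e[t][0]
                           for e in model.per_triplet_tubule_extents])),
            float(np.std([e[t][1] - e[t][0]
                          for e in model.per_triplet_tubule_extents])))
        for t in ("A", "B", "C")
    }
    gt_lengths = {
        t: {"mean_nm": stats[t][0], "sd_nm": stats[t][1]} for t in stats
    }
    lengths_path = os.path.join(config.out_dir, "lengths.json")
    with open(lengths_path, "w") as fh:
        json.dump(gt_lengths, fh, indent=1)
    record_stage("lengths", [lengths_path], gt_lengths)

    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifests, fh, indent=1)
    summary["positional_summary"] = pos_summary
    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
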