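"""End-to-end desk-scale study: simulate -> reconstruct -> census -> pool ->
refine (C1 and C6) -> metrics -> report.

Every stochastic stage derives its seed deterministically from the global
seed, so a (config, seed) pair reproduces the whole run bit-for-bit. Stage
outputs (tables, volumes, averages) are written under the output directory
and the machine-readable RunReport links to them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import census as census_mod
from . import io as io_mod
from . import metrics as metrics_mod
from . import sta
from .phantom import AcquisitionSpec, CohortConfig, generate_cohort
from .volume import Volume

__all__ = ["RunConfig", "run_pipeline", "pool_particles", "build_init_poses"]


@dataclass
class CensusConfig:
    primed_max_nm: float = 6.0
    tethered_min_nm: float = 8.0
    bilayer_nm: float = 5.0
    gate_mean_nm: float = 43.88
    gate_sd_nm: float = 5.32


@dataclass
class MetricsConfig:
    annulus_nm: tuple[float, float] = (10.0, 25.0)
    min_separation_nm: float = 6.0
    threshold_sigma: float = 3.0
    fsc_threshold: float = 0.5


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    census: CensusConfig = field(default_factory=CensusConfig)
    refine: sta.RefineConfig = field(default_factory=sta.RefineConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    symmetry: int = 6
    min_pool_size: int = 8
    output_dir: str = "vesta_run"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        for key, typ in [("cohort", CohortConfig), ("acquisition", AcquisitionSpec),
                         ("census", CensusConfig), ("refine", sta.RefineConfig),
                         ("metrics", MetricsConfig)]:
            if key in kw and isinstance(kw[key], dict):
                sub = dict(kw[key])
                for k2, v2 in sub.items():
                    if isinstance(v2, list):
                        sub[k2] = tuple(v2)
                kw[key] = typ(**sub)
        return cls(**kw)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir", None)  # where outputs land is not science
        js = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(js.encode()).hexdigest()[:12]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def build_init_poses(truth: pd.DataFrame, box_size: int,
                     nm_vox: float) -> list[sta.Pose]:
    """Initial poses from picked coordinates (vesicle center and the closest
    point on the presynaptic membrane), as the study's initialization
    prescribes."""
    poses = []
    for _, r in truth.iterrows():
        center = np.array([r.center_x_vox, r.center_y_vox, r.center_z_vox])
        contact = np.array([r.contact_x_vox, r.contact_y_vox, r.contact_z_vox])
        r_mid = (r.diameter_nm - census_mod.BILAYER_NM) / 2.0 / nm_vox
        poses.append(sta.init_pose(center, contact, box_size, r_mid))
    return poses


def pool_particles(table: pd.DataFrame, cfg: CensusConfig) -> dict[str, list[int]]:
    """Split census records into the study pools.

    side_primed / side_tethered by measured interbilayer distance;
    top_bottom_gated by the homogeneous-diameter window; ``combined_primed``
    = side primed + gated top/bottom (the pooled set refined together).
    """
    side = table[table["view"] == "side"]
    tb = table[table["view"] == "top_bottom"]
    d = side["interbilayer_nm_measured"]
    side_primed = side[d <= cfg.primed_max_nm]["id"].tolist()
    side_tethered = side[d >= cfg.tethered_min_nm]["id"].tolist()
    gated = tb[(tb["diameter_nm_measured"] - cfg.gate_mean_nm).abs()
               <= cfg.gate_sd_nm]["id"].tolist()
    return {
        "side_primed": side_primed,
        "side_tethered": side_tethered,
        "top_bottom_gated": gated,
        "combined_primed": sorted(side_primed + gated),
    }


def _interface_report_dict(rep: metrics_mod.InterfaceReport) -> dict:
    return {
        "peak_count": rep.peak_count,
        "peak_positions": rep.peak_positions,
        "ring_diameter_nm": rep.ring_diameter,
        "angular_spacing_cv": rep.angular_spacing_cv,
        "membrane_gap_nm": rep.membrane_gap,
        "symmetry_order_estimate": rep.symmetry_order_estimate,
        "interface_z_nm": rep.interface_z_nm,
        "warnings": rep.warnings,
    }


def _refine_pool(
    name: str,
    ids: list[int],
    subs: list[Volume],
    wedges: list[sta.WedgeMask],
    poses: list[sta.Pose],
    cfg: RunConfig,
    outdir: Path,
    report: dict,
) -> None:
    mc = cfg.metrics
    pool_subs = [subs[i] for i in ids]
    pool_wedges = [wedges[i] for i in ids]
    pool_poses = [poses[i] for i in ids]
    avg_c1, history = sta.refine(pool_subs, pool_wedges, pool_poses, cfg.refine)
    c1_path = outdir / f"{name}_avg_c1.mrc"
    io_mod.write_volume(avg_c1.volume, c1_path)
    rep_c1 = metrics_mod.detect_interface_peaks(
        avg_c1.volume, annulus=mc.annulus_nm,
        min_separation=mc.min_separation_nm,
        threshold_sigma=mc.threshold_sigma)
    entry: dict = {
        "n_particles": len(ids),
        "member_ids": ids,
        "c1_volume": str(c1_path),
        "c1": _interface_report_dict(rep_c1),
        "mean_score": history["rounds"][-1]["mean_score"] if history["rounds"] else None,
        "rounds": history["rounds"],
    }
    if cfg.symmetry > 1:
        avg_cn = sta.apply_cn_symmetry(avg_c1.volume, cfg.symmetry)
        cn_path = outdir / f"{name}_avg_c{cfg.symmetry}.mrc"
        io_mod.write_volume(avg_cn, cn_path)
        rep_cn = metrics_mod.detect_interface_peaks(
            avg_cn, annulus=mc.annulus_nm,
            min_separation=mc.min_separation_nm,
            threshold_sigma=mc.threshold_sigma)
        entry[f"c{cfg.symmetry}_volume"] = str(cn_path)
        entry[f"c{cfg.symmetry}"] = _interface_report_dict(rep_cn)

    # half-set FSC with the final per-particle poses
    if len(ids) >= 4:
        final_poses = [sta.Pose(tuple(p["rotation"]), np.array(p["shift"]))
                       for p in history["final_poses"]]
        halves = []
        for par in (0, 1):
            sel = list(range(par, len(ids), 2))
            halves.append(sta.wedge_compensated_average(
                [pool_subs[i] for i in sel], [final_poses[i] for i in sel],
                [pool_wedges[i] for i in sel]))
        curve = metrics_mod.fsc(halves[0].volume, halves[1].volume,
                                threshold=mc.fsc_threshold)
        entry["fsc_resolution_nm"] = curve.resolution_at_threshold
        entry["fsc_threshold"] = mc.fsc_threshold
    report[name] = entry


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full study at desk scale; returns the RunReport dict
    (also written as JSON to the output directory)."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(cfg.seed, 2)
    cohort = dataclasses.replace(cfg.cohort, seed=seeds[0])
    acq = dataclasses.replace(cfg.acquisition, seed=seeds[1])
    chash = cfg.config_hash()
    io_mod.dump_yaml({"config": cfg.to_dict(), "hash": chash},
                     outdir / "config.yaml")

    report: dict = {"config_hash": chash, "seed": cfg.seed, "stages": {}}

    # 1. simulate
    subs, truth = generate_cohort(cohort, acq)
    truth_path = outdir / "truth_table.tsv"
    io_mod.write_table(truth, truth_path)
    report["stages"]["simulate"] = {
        "n_vesicles": len(subs), "truth_table": str(truth_path)}

    # 2. census
    table = census_mod.census_table(subs)
    census_path = outdir / "census_table.tsv"
    merged = truth.merge(table, on="id")
    io_mod.write_table(merged, census_path)
    io_mod.write_star(merged, outdir / "census_table.star")
    n_side = int((table["view"] == "side").sum())
    primed_mask = table["docking_state_measured"] == "primed"
    report["stages"]["census"] = {
        "table": str(census_path),
        "n_side": n_side,
        "n_top_bottom": int((table["view"] == "top_bottom").sum()),
        "primed_fraction_of_side": (
            float(primed_mask[table["view"] == "side"].mean())
            if n_side else None),
        "mean_diameter_nm": float(table["diameter_nm_measured"].mean()),
    }

    # 3. pools
    pools = pool_particles(table, cfg.census)
    report["stages"]["pools"] = {k: len(v) for k, v in pools.items()}

    # 4. poses and wedges
    box = cohort.box_size
    nm_vox = acq.pixel_size / 10.0
    poses = build_init_poses(truth, box, nm_vox)
    wedges = [sta.make_wedge_mask((box,) * 3, acq.tilt_min, acq.tilt_max)
              for _ in subs]

    # 5. refine pools
    if len(pools["combined_primed"]) >= cfg.min_pool_size:
        _refine_pool("primed", pools["combined_primed"], subs, wedges, poses,
                     cfg, outdir, report)
    if len(pools["side_tethered"]) >= cfg.min_pool_size:
        _refine_pool("tethered", pools["side_tethered"], subs, wedges, poses,
                     cfg, outdir, report)

    # 6. recovered vs truth
    comparison: dict = {}
    if "primed" in report:
        sym_key = f"c{cfg.symmetry}" if cfg.symmetry > 1 else "c1"
        comparison["ring_diameter_nm"] = {
            "recovered": report["primed"].get(sym_key, report["primed"]["c1"])
            ["ring_diameter_nm"],
            "truth_peak_centers": cohort.ring_outer_diameter - 2.0,
        }
        comparison["membrane_gap_nm"] = {
            "recovered": report["primed"]["c1"]["membrane_gap_nm"],
            "truth_mean": float(np.mean(cohort.primed_gap_range)),
        }
        comparison["peak_count"] = {
            "recovered": report["primed"]["c1"]["peak_count"],
            "truth": cohort.n_densities,
        }
    truth_primed = truth[truth["docking_state"] == "primed"]
    comparison["primed_fraction"] = {
        "recovered": report["stages"]["census"]["primed_fraction_of_side"],
        "truth": float(len(truth_primed)) / max(len(truth), 1),
        "configured": cohort.primed_fraction,
    }
    comparison["mean_diameter_nm"] = {
        "recovered": report["stages"]["census"]["mean_diameter_nm"],
        "truth": float(truth["diameter_nm"].mean()),
        "configured": cohort.diameter_mean,
    }
    report["comparison"] = comparison

    report_path = outdir / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, default=float))
    report["report_path"] = str(report_path)
    return report
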