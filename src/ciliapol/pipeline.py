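"""Config-driven end-to-end runs.

A run generates synthetic inputs for two conditions (a well-polarised
"control" and a dispersed "mutant"), analyses each with the four
quantification stages, compares the translational vector distributions
with the Watson U^2 test, and writes every table, figure and summary to
the output directory together with a report.  Identical config + seed
gives byte-identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, beat, circular, io, rotational, similarity, synthetic, translational
from .errors import PipelineError

__all__ = ["DEFAULT_CONFIG", "RunReport", "load_config", "config_hash", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "ciliapol_run",
    "conditions": {
        "control": {"kappa": 8.0},
        "mutant": {"kappa": 1.5},
    },
    "apical": {
        "n_cells": 60,
        "mean_area": 60.0,
        "area_cv": 0.15,
        "mu_deg": 0.0,
        "displacement_frac": 0.3,
        "pixel_size": 0.2,
    },
    "orientations": {"n_images": 10, "cilia_per_image": 12, "mu_deg": 0.0, "kappa": 20.0},
    "beat": {"freq_hz": 9.0, "fps": 60.0, "duration_s": 2.0, "noise_sd": 10.0,
             "amplitude": 100.0, "min_prominence": 0.2},
    "profiles": {
        "block_design": {"query": "dev", "CD11c": "dev", "PAM": "dev",
                         "DAM1": "disease", "DAM2": "disease", "Aged": "other"},
        "n_genes": 500, "block_size": 40, "effect": 5.0, "noise_sd": 1.0,
        "linkage": "average",
    },
    "analysis": {"bound_deg": 45.0, "min_cells": 30, "min_cilia": 100,
                 "epsilon_um": 0.1, "reference": "per_image_mean"},
    "watson": {"n_permutations": 999},
}


@dataclass
class RunReport:
    version: str
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"version": self.version, "config_hash": self.config_hash,
             "seed": self.seed, "stages": self.stages, "warnings": self.warnings},
            indent=2, sort_keys=True,
        ))


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file (and/or an override dict) onto the defaults."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise PipelineError(f"config file {path} must contain a mapping")
        config = _merge(config, loaded)
    if overrides:
        config = _merge(config, overrides)
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _warn(report: RunReport, stage: str, record: str, message: str) -> None:
    report.warnings.append({"stage": stage, "record": record, "message": message})


def run_pipeline(config: dict) -> RunReport:
    """Execute all stages; any stage error aborts with stage name and context."""
    seed = int(config["seed"])
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, config_hash=config_hash(config), seed=seed)
    sub = {name: s for name, s in zip(
        ["apical", "orientations", "beat", "profiles"],
        np.random.SeedSequence(seed).spawn(4),
    )}

    # --- translational stage: one apical map per condition, Watson between them
    stage = "translational"
    try:
        cfg = config["apical"]
        ana = config["analysis"]
        angles_by_condition: dict[str, np.ndarray] = {}
        summaries = {}
        for i, (cond, cond_cfg) in enumerate(sorted(config["conditions"].items())):
            cell_map, truth = synthetic.gen_apical_map(
                n_cells=cfg["n_cells"], mean_area=cfg["mean_area"], area_cv=cfg["area_cv"],
                mu=cfg["mu_deg"], kappa=cond_cfg["kappa"],
                displacement_frac=cfg["displacement_frac"], pixel_size=cfg["pixel_size"],
                seed=int(sub["apical"].generate_state(1)[0] % (2**31)) + i,
                image_id=cond,
            )
            io.write_cell_map(cell_map, out_dir / f"cell_map_{cond}.csv")
            truth.to_json(out_dir / f"truth_apical_{cond}.json")
            vectors, summary = translational.analyze_map(
                cell_map, reference=ana["reference"], bound_deg=ana["bound_deg"],
                epsilon_um=ana["epsilon_um"], min_cells=ana["min_cells"],
            )
            translational.plot_polar_histogram(summary, out_dir / f"polar_{cond}.png")
            angles_by_condition[cond] = np.array(
                [v.angle_deg for v in vectors if not v.degenerate]
            )
            for msg in summary.warnings:
                _warn(report, stage, cond, msg)
            if summary.n_degenerate:
                _warn(report, stage, cond, f"{summary.n_degenerate} degenerate vectors")
            summaries[cond] = {
                "fraction_within_bound": summary.fraction_within_bound,
                "bound_deg": summary.bound_deg,
                "mean_area_um2": summary.mean_area_um2,
                "sem_area_um2": summary.sem_area_um2,
                "n_cells": summary.n_cells,
            }
        report.stages[stage] = summaries
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    stage = "watson"
    try:
        conds = sorted(angles_by_condition)
        if len(conds) >= 2:
            a, b = conds[0], conds[1]
            result = circular.watson_u2(
                circular.AngularSample(angles_by_condition[a], label=a),
                circular.AngularSample(angles_by_condition[b], label=b),
                n_permutations=int(config["watson"]["n_permutations"]),
                seed=seed,
            )
            report.stages[stage] = {
                "comparison": [a, b], "u2": result.u2,
                "p_permutation": result.p_permutation,
                "n1": result.n1, "n2": result.n2,
            }
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    stage = "rotational"
    try:
        cfg = config["orientations"]
        samples, truth = synthetic.gen_orientation_field(
            n_images=cfg["n_images"], cilia_per_image=cfg["cilia_per_image"],
            mu=cfg["mu_deg"], kappa=cfg["kappa"],
            seed=int(sub["orientations"].generate_state(1)[0] % (2**31)),
        )
        io.write_angles(samples, out_dir / "orientations.csv")
        truth.to_json(out_dir / "truth_orientations.json")
        summary = rotational.summarize_rotational(
            samples, min_cilia=config["analysis"]["min_cilia"]
        )
        rotational.plot_deviation_histogram(summary, out_dir / "rotational_hist.png")
        for msg in summary.warnings:
            _warn(report, stage, "orientations", msg)
        report.stages[stage] = {
            "grand_mean_dev_deg": summary.grand_mean_dev_deg,
            "sem_dev_deg": summary.sem_dev_deg,
            "n_cilia": summary.n_cilia,
            "n_images": summary.n_images,
        }
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    stage = "beat"
    try:
        cfg = config["beat"]
        stack, truth = synthetic.gen_beat_recording(
            freq_hz=cfg["freq_hz"], fps=cfg["fps"], duration_s=cfg["duration_s"],
            amplitude=cfg["amplitude"], noise_sd=cfg["noise_sd"],
            seed=int(sub["beat"].generate_state(1)[0] % (2**31)),
        )
        roi_dict = truth.per_item[0]["roi"]
        roi = beat.LineROI(x0=roi_dict["x0"], y0=roi_dict["y0"],
                           x1=roi_dict["x1"], y1=roi_dict["y1"], roi_id=roi_dict["roi_id"])
        io.write_stack(stack, out_dir / "recording.tif", rois=[roi])
        truth.to_json(out_dir / "truth_beat.json")
        kymo = beat.extract_kymograph(stack, roi)
        estimate = beat.estimate_beat(kymo, min_prominence=cfg["min_prominence"])
        if estimate.flags:
            _warn(report, stage, roi.roi_id, f"flags: {sorted(estimate.flags)}")
        report.stages[stage] = {
            "freq_peaks_hz": estimate.freq_peaks_hz,
            "freq_spectral_hz": estimate.freq_spectral_hz,
            "n_peaks": estimate.n_peaks,
            "flags": sorted(estimate.flags),
        }
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    stage = "similarity"
    try:
        cfg = config["profiles"]
        pset, truth = synthetic.gen_population_profiles(
            block_design=cfg["block_design"], n_genes=cfg["n_genes"],
            block_size=cfg["block_size"], effect=cfg["effect"], noise_sd=cfg["noise_sd"],
            seed=int(sub["profiles"].generate_state(1)[0] % (2**31)),
        )
        io.write_profiles(pset, out_dir / "profiles.csv")
        truth.to_json(out_dir / "truth_profiles.json")
        result = similarity.similarity_matrix(pset, linkage=cfg["linkage"])
        io.write_similarity(result, out_dir / "similarity")
        similarity.plot_correlation_heatmap(result, out_dir / "correlation_heatmap.png")
        for pop in result.excluded:
            _warn(report, stage, pop, "excluded zero attribute vector")
        report.stages[stage] = {
            "cluster_order": result.cluster_order,
            "n_genes_used": result.n_genes_used,
            "max_offdiag_correlation": float(
                (result.correlation.to_numpy() - np.eye(len(result.labels))).max()
            ),
        }
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    (out_dir / "config.json").write_text(json.dumps(config, indent=2, sort_keys=True))
    report.to_json(out_dir / "report.json")
    return report
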