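"""Workflow orchestration: seeded, composable stages with disk artifacts.

Stages (in dependency order):

    generate-cohort -> align -> train-ssm -> {evaluate-ssm, power, sample}
    sample + align + generate-cohort -> morph -> simulate -> {uq, sensitivity}

Each stage reads its upstream artifacts from the output directory, writes
its own artifacts plus a manifest (config hash, seed, package version),
and is bitwise reproducible for a fixed configuration.  A flat artifact
store keeps the workflow self-contained and testable without a workflow
engine.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import AlignedCohort, SimilarityTransform, align_cohort
from .geometry import CorrespondedShape, VolumetricMesh
from .inp import export_inp
from .mechanics import LoadCase, MaterialSet, batch_simulate, results_to_frame
from .morphing import build_template, morph_to_surface, select_control_points
from .phantom import PhantomSpec, generate_cohort
from .sampling import PowerSpec, latin_hypercube, min_sample_size, weights_to_sd_units
from .sensitivity import ShapConfig, analyse
from .ssm import PointDistributionModel, evaluate
from .uq import bootstrap_ci, ci_vs_sample_size
from .io import load_model, save_model

STAGES = (
    "generate-cohort",
    "align",
    "train-ssm",
    "evaluate-ssm",
    "power",
    "sample",
    "morph",
    "simulate",
    "uq",
    "sensitivity",
)

_REQUIRES = {
    "generate-cohort": (),
    "align": ("generate-cohort",),
    "train-ssm": ("align",),
    "evaluate-ssm": ("align",),
    "power": ("train-ssm",),
    "sample": ("train-ssm",),
    "morph": ("generate-cohort", "align", "train-ssm", "sample"),
    "simulate": ("morph",),
    "uq": ("simulate",),
    "sensitivity": ("sample", "simulate"),
}

_SENTINELS = {
    "generate-cohort": "cohort.npz",
    "align": "aligned.npz",
    "train-ssm": "ssm.npz",
    "evaluate-ssm": "ssm_performance.json",
    "power": "power.json",
    "sample": "weights.csv",
    "morph": "morphed.npz",
    "simulate": "results.csv",
    "uq": "uq_curves.csv",
    "sensitivity": "sensitivity.json",
}


class MissingArtifactError(RuntimeError):
    """Raised when a stage's upstream artifacts are absent."""


@dataclass
class PipelineConfig:
    """Complete parameterisation of a pipeline run.

    The defaults are the full study settings: 500 synthetic subjects
    bounded at +-2 SD, 1000 TPS control points, 1000 bootstrap iterations,
    1024 SHAP coalitions, alpha = 0.05 and a 400 N axial load.
    """

    phantom: dict = field(default_factory=dict)
    alignment: dict = field(
        default_factory=lambda: {"with_scaling": True, "reference": 0, "iterative": False}
    )
    ssm: dict = field(
        default_factory=lambda: {
            "n_modes": None,
            "kaiser_factor": 0.7,
            "specificity_samples": 500,
        }
    )
    power: dict = field(
        default_factory=lambda: {
            "predictors": None,  # None -> retained mode count
            "rho2": 0.15,
            "alpha": 0.05,
            "power": 0.95,
            "model": "random",
        }
    )
    sampling: dict = field(
        default_factory=lambda: {
            "n_samples": 500,
            "sd_range": 2.0,
            "criterion": "correlation_min",
        }
    )
    morphing: dict = field(
        default_factory=lambda: {"n_control_points": 1000, "regularisation": 0.0}
    )
    mechanics: dict = field(
        default_factory=lambda: {"total_force": 400.0, "min_scaled_jacobian": 0.05}
    )
    uq: dict = field(
        default_factory=lambda: {"iterations": 1000, "level": 0.95, "sizes": None}
    )
    sensitivity: dict = field(
        default_factory=lambda: {"n_coalitions": 1024, "significance_level": 0.05}
    )
    seed: int = 0
    output_dir: str = "pipeline_out"
    write_meshes: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        config = cls()
        for key, value in raw.items():
            if not hasattr(config, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(config, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            else:
                setattr(config, key, value)
        return config

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage seed below 2**31 derived from the global seed."""
        tag = zlib.crc32(stage.encode()) & 0x7FFFFFFF
        ss = np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF, tag])
        return int(ss.generate_state(1)[0] % (2**31))


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_manifest(config: PipelineConfig, stage: str) -> None:
    out = _outdir(config)
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seed": config.stage_seed(stage),
        "version": __version__,
    }
    with open(out / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def _require(config: PipelineConfig, stage: str) -> None:
    out = _outdir(config)
    for upstream in _REQUIRES[stage]:
        if not (out / _SENTINELS[upstream]).exists():
            raise MissingArtifactError(
                f"stage '{stage}' needs artifacts from stage '{upstream}'; "
                f"run 'run-stage {upstream}' first"
            )


# ---------------------------------------------------------------------------
# artifact (de)serialisation helpers


def _save_cohort(out: Path, meshes: list, truth) -> None:
    ref = meshes[0]
    np.savez_compressed(
        out / "cohort.npz",
        nodes=np.stack([m.nodes for m in meshes]),
        hexahedra=ref.hexahedra,
        labels=ref.structure_label.astype(str),
        surface_index=ref.surface_index,
        subject_ids=np.array([m.subject_id for m in meshes]),
        latent_weights=truth.latent_weights,
        latent_sd=truth.latent_sd,
        surface_fields=truth.surface_fields,
    )
    ranking = {
        k: [int(i) for i in v] for k, v in truth.true_importance_ranking.items()
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "response_coefficients": truth.response_coefficients,
                "latent_jacobian": {
                    k: list(map(float, v)) for k, v in truth.latent_jacobian.items()
                },
                "true_importance_ranking": ranking,
                "feature_refs": truth.feature_refs,
                "seed": truth.seed,
            },
            fh,
            indent=1,
        )


def _load_cohort(out: Path):
    data = np.load(out / "cohort.npz", allow_pickle=False)
    meshes = [
        VolumetricMesh(
            nodes=data["nodes"][i],
            hexahedra=data["hexahedra"],
            structure_label=data["labels"].astype(object),
            surface_index=data["surface_index"],
            subject_id=str(data["subject_ids"][i]),
        )
        for i in range(data["nodes"].shape[0])
    ]
    return meshes, data


def _load_aligned(out: Path) -> AlignedCohort:
    data = np.load(out / "aligned.npz", allow_pickle=False)
    with open(out / "transforms.json") as fh:
        tr = json.load(fh)
    shapes = [
        CorrespondedShape(data["points"][i], str(data["subject_ids"][i]))
        for i in range(data["points"].shape[0])
    ]
    transforms = [SimilarityTransform.from_dict(d) for d in tr["transforms"]]
    return AlignedCohort(shapes=shapes, transforms=transforms,
                         reference_id=tr["reference_id"])


# ---------------------------------------------------------------------------
# stages


def stage_generate_cohort(config: PipelineConfig) -> None:
    out = _outdir(config)
    spec = PhantomSpec(seed=config.stage_seed("generate-cohort"), **config.phantom)
    shapes, meshes, truth = generate_cohort(spec)
    _save_cohort(out, meshes, truth)
    _write_manifest(config, "generate-cohort")


def stage_align(config: PipelineConfig) -> None:
    _require(config, "align")
    out = _outdir(config)
    meshes, _ = _load_cohort(out)
    shapes = [m.surface_shape() for m in meshes]
    cohort = align_cohort(shapes, **config.alignment)
    np.savez_compressed(
        out / "aligned.npz",
        points=np.stack([s.points for s in cohort.shapes]),
        subject_ids=np.array([s.subject_id for s in cohort.shapes]),
    )
    cohort.save_transforms(out / "transforms.json")
    _write_manifest(config, "align")


def stage_train_ssm(config: PipelineConfig) -> None:
    _require(config, "train-ssm")
    out = _outdir(config)
    cohort = _load_aligned(out)
    model = PointDistributionModel(
        n_modes=config.ssm.get("n_modes"),
        kaiser_factor=config.ssm.get("kaiser_factor", 0.7),
    ).fit(cohort)
    save_model(
        model,
        out / "ssm.npz",
        metadata={"config_hash": config.config_hash(), "retained": model.retained_},
    )
    summary = {
        "retained_modes": model.retained_,
        "total_modes": model.n_total_modes_,
        "lambda_bar": model.lambda_bar_,
        "kaiser_threshold": model.kaiser_threshold(config.ssm.get("kaiser_factor", 0.7)),
        "compactness_at_retained": model.compactness(model.retained_),
        "eigenvalues": list(map(float, model.eigenvalues_)),
    }
    with open(out / "ssm_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    _write_manifest(config, "train-ssm")


def stage_evaluate_ssm(config: PipelineConfig) -> None:
    _require(config, "evaluate-ssm")
    out = _outdir(config)
    cohort = _load_aligned(out)
    performance = evaluate(
        cohort,
        M=config.ssm.get("n_modes"),
        n_specificity_samples=config.ssm.get("specificity_samples", 500),
        seed=config.stage_seed("evaluate-ssm"),
    )
    with open(out / "ssm_performance.json", "w") as fh:
        json.dump(performance.to_dict(), fh, indent=1)
    _write_manifest(config, "evaluate-ssm")


def stage_power(config: PipelineConfig) -> None:
    _require(config, "power")
    out = _outdir(config)
    predictors = config.power.get("predictors")
    if predictors is None:
        model, _ = load_model(out / "ssm.npz")
        predictors = model.retained_
    spec = PowerSpec(
        predictors=predictors,
        rho2=config.power.get("rho2", 0.15),
        alpha=config.power.get("alpha", 0.05),
        power=config.power.get("power", 0.95),
    )
    n_min = min_sample_size(spec, model=config.power.get("model", "random"))
    with open(out / "power.json", "w") as fh:
        json.dump(
            {
                "predictors": spec.predictors,
                "rho2": spec.rho2,
                "alpha": spec.alpha,
                "power": spec.power,
                "model": config.power.get("model", "random"),
                "min_sample_size": n_min,
                "recommended_n": 2 * n_min,
            },
            fh,
            indent=1,
        )
    _write_manifest(config, "power")


def stage_sample(config: PipelineConfig) -> None:
    _require(config, "sample")
    out = _outdir(config)
    model, _ = load_model(out / "ssm.npz")
    w = latin_hypercube(
        n=config.sampling.get("n_samples", 500),
        model=model,
        sd_range=config.sampling.get("sd_range", 2.0),
        criterion=config.sampling.get("criterion", "correlation_min"),
        seed=config.stage_seed("sample"),
    )
    w.to_csv(out / "weights.csv")
    np.savez_compressed(
        out / "weights.npz",
        values=w.values,
        eigenvalues=w.eigenvalues,
        sd_range=w.sd_range,
        seed=w.seed,
    )
    _write_manifest(config, "sample")


def stage_morph(config: PipelineConfig) -> None:
    _require(config, "morph")
    out = _outdir(config)
    meshes, _ = _load_cohort(out)
    cohort = _load_aligned(out)
    model, _ = load_model(out / "ssm.npz")
    wdata = np.load(out / "weights.npz")
    template = build_template(meshes, cohort.transforms)
    control = select_control_points(
        p=len(template.surface_index),
        c=min(config.morphing.get("n_control_points", 1000),
              len(template.surface_index)),
        seed=config.stage_seed("morph"),
    )
    morphed_nodes, reports = [], []
    for i, w in enumerate(wdata["values"]):
        surface = model.reconstruct(w, subject_id=f"synthetic_{i:03d}")
        morphed, report = morph_to_surface(
            template,
            surface,
            control_indices=control,
            regularisation=config.morphing.get("regularisation", 0.0),
        )
        morphed_nodes.append(morphed.nodes)
        reports.append(
            {
                "subject_id": morphed.subject_id,
                "surface_rmse_mm": report.surface_rmse,
                "surface_max_error_mm": report.surface_max_error,
                "control_rmse_mm": report.control_rmse,
                "inverted_fraction": report.inverted_fraction,
            }
        )
    np.savez_compressed(
        out / "morphed.npz",
        nodes=np.stack(morphed_nodes),
        control_indices=control,
        template_nodes=template.nodes,
    )
    pd.DataFrame(reports).to_csv(out / "warp_report.csv", index=False)
    if config.write_meshes:
        from .io import write_vtk_unstructured

        export_inp(template, path=str(out / "template.inp"))
        write_vtk_unstructured(template, out / "template.vtk")
    _write_manifest(config, "morph")


def _load_morphed(config: PipelineConfig):
    out = _outdir(config)
    meshes, _ = _load_cohort(out)
    ref = meshes[0]
    data = np.load(out / "morphed.npz")
    return [
        ref.with_nodes(data["nodes"][i], subject_id=f"synthetic_{i:03d}")
        for i in range(data["nodes"].shape[0])
    ]


def stage_simulate(config: PipelineConfig) -> None:
    _require(config, "simulate")
    out = _outdir(config)
    morphed = _load_morphed(config)
    materials = MaterialSet.default()
    load = LoadCase(total_force=config.mechanics.get("total_force", 400.0))
    results = batch_simulate(
        morphed,
        materials,
        load,
        min_scaled_jacobian=config.mechanics.get("min_scaled_jacobian", 0.05),
    )
    frame = results_to_frame(results)
    frame.to_csv(out / "results.csv", index=False)
    _write_manifest(config, "simulate")


def stage_uq(config: PipelineConfig) -> None:
    _require(config, "uq")
    out = _outdir(config)
    frame = pd.read_csv(out / "results.csv")
    valid = frame[frame["valid"]]
    iterations = config.uq.get("iterations", 1000)
    level = config.uq.get("level", 0.95)
    sizes = config.uq.get("sizes")
    n = len(valid)
    if sizes is None:
        lo = min(10, n)
        sizes = sorted(set(np.geomspace(lo, n, 5).astype(int)))
    curves = []
    densities = {}
    for outcome in ("idp", "fcp"):
        values = valid[outcome].to_numpy()
        curve = ci_vs_sample_size(
            values, sizes, iterations=iterations, level=level,
            seed=config.stage_seed("uq"),
        )
        cf = curve.to_frame()
        cf.insert(0, "outcome", outcome)
        curves.append(cf)
        densities[outcome] = [
            None if d is None else {"grid": d[0].tolist(), "pdf": d[1].tolist()}
            for d in curve.densities
        ]
        mean, lo_ci, hi_ci = bootstrap_ci(
            values, iterations=iterations, level=level,
            seed=config.stage_seed("uq"),
        )
        densities[f"{outcome}_full_sample"] = {
            "mean": mean, "ci_low": lo_ci, "ci_high": hi_ci, "n": int(n),
        }
    pd.concat(curves, ignore_index=True).to_csv(out / "uq_curves.csv", index=False)
    with open(out / "uq_densities.json", "w") as fh:
        json.dump(densities, fh, indent=1)
    _write_manifest(config, "uq")


def stage_sensitivity(config: PipelineConfig) -> None:
    _require(config, "sensitivity")
    out = _outdir(config)
    frame = pd.read_csv(out / "results.csv")
    wdata = np.load(out / "weights.npz")
    from .sampling import WeightMatrix

    w = WeightMatrix(
        values=wdata["values"],
        sd_range=float(wdata["sd_range"]),
        seed=int(wdata["seed"]),
        eigenvalues=wdata["eigenvalues"],
    )
    weights_sd = weights_to_sd_units(w)
    report = analyse(
        weights_sd,
        frame[["idp", "fcp"]],
        valid=frame["valid"].to_numpy(),
        significance_level=config.sensitivity.get("significance_level", 0.05),
        shap_config=ShapConfig(
            n_coalitions=config.sensitivity.get("n_coalitions", 1024),
            seed=config.stage_seed("sensitivity"),
        ),
    )
    report.metadata["weight_units"] = "sd"
    report.correlations.to_csv(out / "correlations.csv", index=False)
    report.to_csv(out / "sensitivity.csv")
    report.to_json(out / "sensitivity.json")
    try:
        from .sensitivity import plot_contributions, plot_correlation_heatmap

        plot_correlation_heatmap(report, out / "correlations.png")
        plot_contributions(report, out / "contributions.png")
    except Exception:  # plotting must never fail the pipeline
        pass
    _write_manifest(config, "sensitivity")


_STAGE_FUNCS = {
    "generate-cohort": stage_generate_cohort,
    "align": stage_align,
    "train-ssm": stage_train_ssm,
    "evaluate-ssm": stage_evaluate_ssm,
    "power": stage_power,
    "sample": stage_sample,
    "morph": stage_morph,
    "simulate": stage_simulate,
    "uq": stage_uq,
    "sensitivity": stage_sensitivity,
}


def run_stage(name: str, config: PipelineConfig) -> None:
    """Run one named stage; raises MissingArtifactError if upstreams are absent."""
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    _STAGE_FUNCS[name](config)


def run_all(config: PipelineConfig) -> None:
    """Run the complete workflow in dependency order."""
    for name in STAGES:
        run_stage(name, config)
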