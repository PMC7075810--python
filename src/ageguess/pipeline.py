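"""High-level commands tying the modules into reproducible runs.

Each command reads plain-text inputs, executes one experiment, writes its
outputs into an output directory, and records a RunManifest (resolved
configuration, input digests, seed, output paths) so any run can be
audited and repeated byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
from contextlib import contextmanager
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from . import io as agio
from .datamodel import (
    MethylomeMatrix,
    SampleMetadata,
    ages_vector,
    align_samples,
    exclude_sex_chromosomes,
    median_impute,
)
from .errors import PipelineError, ValidationError
from .evaluation import (
    CrossGenderMatrix,
    cross_gender_evaluate,
    derive_seed,
    learning_curve,
    learning_curve_difference,
    mad,
    mse,
    r2,
    repeated_kfold_cv,
    rmse,
)
from .mic import MicConfig
from .regress import RegressionModel, RegressorConfig
from .selection import (
    AgeGuessConfig,
    AgeGuessResult,
    baseline_select,
    run_ageguess,
    write_traces,
)
from .simulate import SyntheticConfig, simulate_methylome

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    command: str
    config: dict
    seed: int
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    outputs: list[str] = field(default_factory=list)
    timestamp: str = ""
    status: str = "ok"

    def write(self, path: str | Path) -> None:
        self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S%z")
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True), "utf-8"
        )


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@contextmanager
def _manifest_guard(manifest: "RunManifest", outdir: Path):
    """Ensure the run manifest lands on disk whether the command succeeds
    or raises; a failed run records its error in the status field."""
    try:
        yield
    except Exception as exc:
        manifest.status = f"error: {exc}"
        outdir.mkdir(parents=True, exist_ok=True)
        manifest.write(outdir / "manifest.json")
        raise
    manifest.write(outdir / "manifest.json")


def _config_dict(obj: Any) -> dict:
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return dict(obj)


def load_dataset(
    matrix_path: str | Path,
    metadata_path: str | Path,
    annotation_path: str | Path | None = None,
    dialect: str = "plain_tsv",
):
    matrix = agio.read_beta_matrix(matrix_path, dialect)  # type: ignore[arg-type]
    metadata = agio.read_metadata(metadata_path)
    annotation = agio.read_annotation(annotation_path) if annotation_path else []
    return matrix, metadata, annotation


def cmd_simulate(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a synthetic dataset and write matrix/metadata/annotation/truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest("simulate", _config_dict(config), config.seed)
    with _manifest_guard(manifest, outdir):
        matrix, metadata, annotation, truth = simulate_methylome(config)
        paths = {
            "matrix": outdir / "matrix.tsv",
            "metadata": outdir / "metadata.csv",
            "annotation": outdir / "annotation.csv",
            "truth": outdir / "truth.json",
        }
        agio.write_beta_matrix(matrix, paths["matrix"])
        agio.write_metadata(metadata, paths["metadata"])
        agio.write_annotation(annotation, paths["annotation"])
        truth.to_json(paths["truth"])
        manifest.outputs = [str(p) for p in paths.values()]
    return paths


def cmd_select(
    matrix_path: str | Path,
    metadata_path: str | Path,
    annotation_path: str | Path,
    config: AgeGuessConfig,
    outdir: str | Path,
    dialect: str = "plain_tsv",
    plot: bool = False,
) -> AgeGuessResult:
    """Run the full three-step selection and write panel, traces, model, report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest("select", _config_dict(config), config.seed)
    with _manifest_guard(manifest, outdir):
        manifest.inputs = {
            str(matrix_path): _digest(matrix_path),
            str(metadata_path): _digest(metadata_path),
            str(annotation_path): _digest(annotation_path),
        }
        matrix, metadata, annotation = load_dataset(
            matrix_path, metadata_path, annotation_path, dialect
        )
        result = run_ageguess(matrix, metadata, annotation, config)

        agio.write_probe_list(result.selected_probes, outdir / "biomarkers.txt")
        write_traces([result.step2_trace, result.step3_trace], outdir / "traces.tsv")
        result.step1_ranking.to_tsv(outdir / "ranking.tsv")
        result.final_model.to_json(outdir / "model.json")
        result.final_report.to_json(outdir / "report.json")
        result.final_report.predictions_csv(outdir / "predictions.csv")
        outputs = [
            "biomarkers.txt", "traces.tsv", "ranking.tsv",
            "model.json", "report.json", "predictions.csv",
        ]
        if plot:
            _plot_traces(result, outdir / "traces.png")
            outputs.append("traces.png")
        manifest.outputs = [str(outdir / o) for o in outputs]
    return result


def _plot_traces(result: AgeGuessResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, trace, ylab in (
        (axes[0], result.step2_trace, "CV MAD (years)"),
        (axes[1], result.step3_trace, "EI"),
    ):
        xs = [r.n_features for r in trace.records]
        ys = [r.metric_value for r in trace.records]
        ax.plot(xs, ys, marker="o", ms=2)
        ax.invert_xaxis()
        ax.set_xlabel("features remaining")
        ax.set_ylabel(ylab)
        ax.set_title(trace.step)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cmd_evaluate(
    model_path: str | Path,
    matrix_path: str | Path,
    metadata_path: str | Path,
    outdir: str | Path,
    dialect: str = "plain_tsv",
) -> dict:
    """Apply a saved model to a dataset and report prediction metrics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest("evaluate", {"model": str(model_path)}, 0)
    with _manifest_guard(manifest, outdir):
        manifest.inputs = {
            str(model_path): _digest(model_path),
            str(matrix_path): _digest(matrix_path),
            str(metadata_path): _digest(metadata_path),
        }
        model = RegressionModel.from_json(Path(model_path))
        matrix = agio.read_beta_matrix(matrix_path, dialect)  # type: ignore[arg-type]
        metadata = agio.read_metadata(metadata_path)
        matrix, metadata = align_samples(matrix, metadata)
        sub = matrix.select_probes(model.probe_ids)
        X = median_impute(sub.values).T
        ages = ages_vector(metadata)
        pred = model.predict(X, probe_ids=model.probe_ids)
        report = {
            "mad": mad(ages, pred),
            "mse": mse(ages, pred),
            "rmse": rmse(ages, pred),
            "r2": r2(ages, pred),
            "n_features": len(model.probe_ids),
            "n_samples": int(ages.size),
        }
        (outdir / "evaluation.json").write_text(
            json.dumps(report, indent=1, sort_keys=True), "utf-8"
        )
        manifest.outputs = [str(outdir / "evaluation.json")]
    return report


def cmd_compare(
    matrix_path: str | Path,
    metadata_path: str | Path,
    annotation_path: str | Path,
    methods: Sequence[str],
    n_features: int,
    config: AgeGuessConfig,
    outdir: str | Path,
    dialect: str = "plain_tsv",
):
    """Baseline selectors head-to-head at a fixed panel size.

    Every method selects ``n_features`` probes and the panel is scored by
    the same repeated-CV protocol, mirroring the fairness rule of giving
    each selector the same model size.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        "compare",
        {**_config_dict(config), "methods": list(methods), "n_features": n_features},
        config.seed,
    )
    with _manifest_guard(manifest, outdir):
        manifest.inputs = {str(matrix_path): _digest(matrix_path)}
        matrix, metadata, annotation = load_dataset(
            matrix_path, metadata_path, annotation_path, dialect
        )
        matrix, metadata = align_samples(matrix, metadata)
        matrix = exclude_sex_chromosomes(matrix, annotation, config.unannotated_policy)
        ages = ages_vector(metadata)
        rows = []
        for method in methods:
            probes = baseline_select(matrix, ages, method, n_features, config)  # type: ignore[arg-type]
            report = repeated_kfold_cv(
                matrix,
                ages,
                probes,
                config.regressor,
                folds=config.cv_folds,
                repeats=config.report_repeats,
                seed=derive_seed(config.seed, 9),
            )
            rows.append(
                {
                    "method": method,
                    "n_features": n_features,
                    "mad": report.mad,
                    "rmse": report.rmse,
                    "r2": report.r2,
                    "ei": report.ei,
                }
            )
        table = pd.DataFrame(rows)
        table.to_csv(outdir / "comparison.tsv", sep="\t", index=False)
        manifest.outputs = [str(outdir / "comparison.tsv")]
    return table


def split_by_sex(
    matrix: MethylomeMatrix, metadata: Sequence[SampleMetadata]
) -> dict[str, tuple[MethylomeMatrix, list[SampleMetadata]]]:
    """Both/Male/Female sub-datasets; errors when a sex has < 2 samples."""
    out: dict[str, tuple[MethylomeMatrix, list[SampleMetadata]]] = {
        "Both": (matrix, list(metadata))
    }
    for name, sex in (("Male", "male"), ("Female", "female")):
        members = [m for m in metadata if m.sex == sex]
        if len(members) < 2:
            raise PipelineError(
                f"cannot build the {sex} dataset: only {len(members)} "
                f"{sex} sample(s) present"
            )
        sub = matrix.select_samples([m.sample_id for m in members])
        out[name] = (sub, members)
    return out


def biomarker_overlap(sets: Mapping[str, Sequence[str]]) -> dict[str, int]:
    """Exact Venn-region cardinalities for two or more named probe sets.

    Region keys join the member set names with ``&`` (elements in exactly
    those sets and no other); counts sum to the size of the union.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValidationError("need at least 2 sets")
    as_sets = {k: set(v) for k, v in sets.items()}
    universe = set().union(*as_sets.values())
    regions: dict[str, int] = {}
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set(universe)
            for c in combo:
                inside &= as_sets[c]
            for other in names:
                if other not in combo:
                    inside -= as_sets[other]
            regions["&".join(combo)] = len(inside)
    return regions


def cmd_gender(
    matrix_path: str | Path,
    metadata_path: str | Path,
    annotation_path: str | Path,
    config: AgeGuessConfig,
    outdir: str | Path,
    dialect: str = "plain_tsv",
) -> dict:
    """Gender-specific workflow: select per dataset, cross-validate across.

    Runs the identical selection configuration on the combined, male-only
    and female-only datasets, computes the 3x3 cross-gender MAD matrix and
    the Venn overlap of the three biomarker panels.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest("gender", _config_dict(config), config.seed)
    with _manifest_guard(manifest, outdir):
        manifest.inputs = {str(matrix_path): _digest(matrix_path)}
        matrix, metadata, annotation = load_dataset(
            matrix_path, metadata_path, annotation_path, dialect
        )
        matrix, metadata = align_samples(matrix, metadata)
        datasets = split_by_sex(matrix, metadata)

        biomarkers: dict[str, list[str]] = {}
        for name, (sub, meta) in datasets.items():
            result = run_ageguess(sub, meta, annotation, config)
            biomarkers[f"{name}Model"] = result.selected_probes
            agio.write_probe_list(
                result.selected_probes, outdir / f"biomarkers_{name.lower()}.txt"
            )

        ag_datasets = {}
        for name, (sub, meta) in datasets.items():
            clean = exclude_sex_chromosomes(sub, annotation, config.unannotated_policy)
            ag_datasets[name] = (clean, ages_vector(meta))
        cgm = cross_gender_evaluate(
            ag_datasets,
            biomarkers,
            config.regressor,
            folds=config.cv_folds,
            repeats=config.report_repeats,
            seed=derive_seed(config.seed, 10),
        )
        cgm.to_tsv(outdir / "cross_gender_mad.tsv")
        overlap = biomarker_overlap(biomarkers)
        (outdir / "overlap.json").write_text(
            json.dumps(overlap, indent=1, sort_keys=True), "utf-8"
        )
        manifest.outputs = [
            str(outdir / f)
            for f in (
                "biomarkers_both.txt",
                "biomarkers_male.txt",
                "biomarkers_female.txt",
                "cross_gender_mad.tsv",
                "overlap.json",
            )
        ]
    return {"biomarkers": biomarkers, "matrix": cgm, "overlap": overlap}


def cmd_learning_curve(
    matrix_path: str | Path,
    metadata_path: str | Path,
    probes_path: str | Path,
    outdir: str | Path,
    seed: int = 0,
    fractions: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0),
    test_fraction: float = 0.3,
    regressor: RegressorConfig | None = None,
    dialect: str = "plain_tsv",
):
    """Training-size experiment for SVR and ridge on a fixed probe panel."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        "learning-curve",
        {"fractions": list(fractions), "test_fraction": test_fraction},
        seed,
    )
    with _manifest_guard(manifest, outdir):
        manifest.inputs = {str(matrix_path): _digest(matrix_path)}
        matrix = agio.read_beta_matrix(matrix_path, dialect)  # type: ignore[arg-type]
        metadata = agio.read_metadata(metadata_path)
        matrix, metadata = align_samples(matrix, metadata)
        probes = agio.read_probe_list(probes_path)
        base = regressor or RegressorConfig()
        configs = {
            "svr": dataclasses.replace(base, kind="svr"),
            "ridge": dataclasses.replace(base, kind="ridge"),
        }
        table = learning_curve(
            matrix,
            ages_vector(metadata),
            probes,
            configs,
            fractions=fractions,
            test_fraction=test_fraction,
            seed=seed,
        )
        table.to_csv(outdir / "learning_curve.tsv", sep="\t", index=False)
        diff = learning_curve_difference(table)
        diff.to_csv(outdir / "learning_curve_diff.tsv", sep="\t", index=False)
        manifest.outputs = [
            str(outdir / "learning_curve.tsv"),
            str(outdir / "learning_curve_diff.tsv"),
        ]
    return table
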