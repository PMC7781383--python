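"""End-to-end pipeline runner with a reproducibility manifest.

A YAML config selects the stages to run (``simulate``, ``count``,
``select``, ``cq``, ``features``, ``train``, ``predict``, ``crossval``) and
their parameters; every stochastic stage draws from the single top-level
seed, so re-running an identical config reproduces identical outputs.  The
manifest records the config hash, seed, SHA-256 digests of every artifact
and the package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import FeatureStandardizer, build_features, cq_long_to_wide, fit_standardizer
from .ngs import count_frequencies, extract_random_regions, select_candidate_aptamers, top_n_matrix
from .prediction import classify, cross_validate, evaluate, roc
from .qpcr import call_cq_table
from .simulate import (
    SimulationConfig,
    cohort_to_frame,
    simulate_amplification_curves,
    simulate_cohort,
    simulate_selection_reads,
)
from .splsda import SparsePLSDA

__all__ = ["run_pipeline", "DEFAULT_STAGES"]

DEFAULT_STAGES = ["simulate", "cq", "features", "train", "predict", "crossval"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _labels_from_meta(meta: pd.DataFrame, threshold: float = 0.79) -> pd.Series:
    if "amyloid_class" in meta.columns:
        lab = meta.set_index("sample_id")["amyloid_class"]
    else:
        lab = (meta.set_index("sample_id")["suvr"] > threshold).map(
            {True: "pos", False: "neg"}
        )
    return lab


def save_model(path: Path, model: SparsePLSDA, standardizer: FeatureStandardizer):
    payload = {"model": model.to_dict(), "standardizer": standardizer.to_dict()}
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[SparsePLSDA, FeatureStandardizer]:
    payload = json.loads(Path(path).read_text())
    return (
        SparsePLSDA.from_dict(payload["model"]),
        FeatureStandardizer.from_dict(payload["standardizer"]),
    )


def predict_samples(
    model: SparsePLSDA,
    standardizer: FeatureStandardizer,
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Score and call samples from a raw (unstandardized) feature frame."""
    Z = standardizer.transform(features)
    scores = model.decision_function(Z)
    stats = {str(k): v for k, v in model.class_stats_.items()}
    rows = []
    for sid, score in zip(features.index, scores):
        out = classify(float(score), stats, sample_id=str(sid))
        rows.append(dataclasses.asdict(out))
    return pd.DataFrame(rows)


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None) -> dict:
    """Run the configured stages in order; return (and write) the manifest.

    Raises if a stage's upstream artifact is missing, naming the stage.
    """
    if isinstance(config, (str, Path)):
        cfg = yaml.safe_load(Path(config).read_text())
    else:
        cfg = dict(config)
    out = Path(out_dir or cfg.get("out_dir", "aptamarker_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = list(cfg.get("stages", DEFAULT_STAGES))
    threshold = float(cfg.get("class_threshold", 0.79))

    outputs: dict[str, Path] = {}
    state: dict = {}

    def need(artifact: str, stage: str):
        path = out / artifact
        if artifact not in outputs and not path.exists():
            raise FileNotFoundError(
                f"stage '{stage}' requires missing upstream artifact {artifact!r}"
            )
        return path

    for stage in stages:
        if stage == "simulate":
            sim_params = dict(cfg.get("simulate", {}))
            n_lib = int(sim_params.pop("n_selection_samples", 22))
            sim = SimulationConfig(**{**sim_params, "seed": seed})
            samples = simulate_cohort(sim)
            meta = cohort_to_frame(samples)
            meta.to_csv(out / "metadata.csv", index=False)
            curves, truth = simulate_amplification_curves(samples, sim)
            curves.to_csv(out / "curves.csv", index=False)
            truth["true_midpoints"].to_csv(out / "true_midpoints.csv", index=False)
            gt = {"informative_aptamers": truth["informative_aptamers"]}
            if "count" in stages or "select" in stages:
                by_class = {"neg": [], "pos": []}
                for s in samples:
                    by_class[s.amyloid_class].append(s)
                half = n_lib // 2
                if len(by_class["neg"]) < half or len(by_class["pos"]) < n_lib - half:
                    raise ValueError("cohort too small for the selection subset")
                subset = by_class["neg"][:half] + by_class["pos"][: n_lib - half]
                libs = simulate_selection_reads(subset, sim, out / "libraries")
                gt["enriched_sequences"] = libs.enriched_sequences
                state["libraries"] = libs
                state["selection_samples"] = subset
                for sid, p in libs.fastq_paths.items():
                    outputs[f"libraries/{sid}.fastq"] = p
            (out / "ground_truth.json").write_text(json.dumps(gt, indent=2))
            outputs |= {
                "metadata.csv": out / "metadata.csv",
                "curves.csv": out / "curves.csv",
                "true_midpoints.csv": out / "true_midpoints.csv",
                "ground_truth.json": out / "ground_truth.json",
            }

        elif stage == "count":
            ncfg = cfg.get("ngs", {})
            if "libraries" in state:
                paths = state["libraries"].fastq_paths
            else:
                lib_dir = Path(ncfg.get("fastq_dir", out / "libraries"))
                if not lib_dir.is_dir():
                    raise FileNotFoundError(
                        "stage 'count' requires FASTQ libraries "
                        f"(missing directory {lib_dir})"
                    )
                paths = {p.stem: p for p in sorted(lib_dir.glob("*.fastq"))}
            extracted, reports = {}, {}
            for sid, p in paths.items():
                seqs, rep = extract_random_regions(
                    p, max_mismatch=int(ncfg.get("max_mismatch", 0))
                )
                extracted[sid] = seqs
                reports[sid] = dataclasses.asdict(rep)
            matrix = top_n_matrix(
                count_frequencies(extracted), int(ncfg.get("top_n", 10_000))
            )
            state["count_matrix"] = matrix
            matrix.counts.T.to_csv(out / "counts.csv")  # sequences x samples
            (out / "extraction_report.json").write_text(json.dumps(reports, indent=2))
            outputs |= {
                "counts.csv": out / "counts.csv",
                "extraction_report.json": out / "extraction_report.json",
            }

        elif stage == "select":
            if "count_matrix" not in state:
                raise FileNotFoundError(
                    "stage 'select' requires the count matrix from stage 'count'"
                )
            matrix = state["count_matrix"]
            if "selection_samples" in state:
                labels = [s.amyloid_class for s in state["selection_samples"]]
            else:
                meta = pd.read_csv(need("metadata.csv", "select"))
                labels = (
                    _labels_from_meta(meta, threshold)
                    .reindex(matrix.sample_ids)
                    .tolist()
                )
            sel = select_candidate_aptamers(
                matrix,
                labels,
                target_perfect_cv=bool(
                    cfg.get("ngs", {}).get("target_perfect_cv", True)
                ),
                seed=seed,
            )
            (out / "selection.json").write_text(json.dumps(sel.to_dict(), indent=2))
            outputs["selection.json"] = out / "selection.json"

        elif stage == "cq":
            curves = pd.read_csv(need("curves.csv", "cq"))
            qcfg = cfg.get("cq", {})
            table = call_cq_table(
                curves,
                baseline_window=tuple(qcfg.get("baseline", (3, 10))),
                k=float(qcfg.get("k", 6.0)),
                integer_cq=bool(qcfg.get("integer_cq", False)),
            )
            table.to_csv(out / "cq.csv", index=False)
            outputs["cq.csv"] = out / "cq.csv"

        elif stage == "features":
            cq = pd.read_csv(need("cq.csv", "features"))
            fm = build_features(cq_long_to_wide(cq))
            fm.to_csv(out / "features.csv")
            outputs["features.csv"] = out / "features.csv"

        elif stage == "train":
            fm = pd.read_csv(need("features.csv", "train"), index_col=0)
            meta = pd.read_csv(need("metadata.csv", "train"))
            labels = _labels_from_meta(meta, threshold).reindex(fm.index)
            tcfg = cfg.get("train", {})
            exclude = list(tcfg.get("exclude", []))
            if exclude:
                fm = fm.drop(index=exclude)
                labels = labels.drop(index=exclude)
            n_test = int(tcfg.get("n_test", 15))
            rng = np.random.default_rng(seed)
            perm = rng.permutation(len(fm))
            te, tr = perm[:n_test], perm[n_test:]
            while (
                np.unique(labels.iloc[tr]).size < 2
                or np.unique(labels.iloc[te]).size < 2
            ):
                warnings.warn("single-class split; resampling", stacklevel=2)
                perm = rng.permutation(len(fm))
                te, tr = perm[:n_test], perm[n_test:]
            Ztr, std = fit_standardizer(fm.iloc[tr])
            model = SparsePLSDA(
                n_components=int(tcfg.get("n_components", 1)),
                keep_x=tcfg.get("keep_x"),
            ).fit(Ztr, labels.iloc[tr].to_numpy())
            cutoff = tcfg.get("loading_cutoff")
            if cutoff is not None:
                model = model.filter_by_loading(float(cutoff))
            save_model(out / "model.json", model, std)
            pd.Series(fm.index[te]).to_csv(
                out / "test_ids.csv", index=False, header=["sample_id"]
            )
            outputs |= {
                "model.json": out / "model.json",
                "test_ids.csv": out / "test_ids.csv",
            }

        elif stage == "predict":
            model, std = load_model(need("model.json", "predict"))
            fm = pd.read_csv(need("features.csv", "predict"), index_col=0)
            meta = pd.read_csv(need("metadata.csv", "predict"))
            test_ids_path = out / "test_ids.csv"
            if test_ids_path.exists():
                ids = pd.read_csv(test_ids_path)["sample_id"].astype(str)
                fm = fm.loc[ids]
            preds = predict_samples(model, std, fm)
            preds.to_csv(out / "predictions.csv", index=False)
            labels = _labels_from_meta(meta, threshold).reindex(fm.index)
            cm = evaluate(preds["call"].tolist(), labels.tolist())
            points, auc_value = roc(preds["score"].to_numpy(), labels.to_numpy())
            points.to_csv(out / "roc.csv", index=False)
            metrics = {
                "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
                "sensitivity": cm.sensitivity,
                "specificity": cm.specificity,
                "accuracy": cm.accuracy,
                "auc": auc_value,
            }
            (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
            outputs |= {
                "predictions.csv": out / "predictions.csv",
                "metrics.json": out / "metrics.json",
                "roc.csv": out / "roc.csv",
            }

        elif stage == "crossval":
            fm = pd.read_csv(need("features.csv", "crossval"), index_col=0)
            meta = pd.read_csv(need("metadata.csv", "crossval"))
            labels = _labels_from_meta(meta, threshold).reindex(fm.index)
            ccfg = cfg.get("crossval", {})
            report = cross_validate(
                fm,
                labels.to_numpy(),
                n_repeats=int(ccfg.get("n_repeats", 5)),
                n_train=int(ccfg.get("n_train", 54)),
                n_test=int(ccfg.get("n_test", 15)),
                keep_x=ccfg.get("keep_x"),
                seed=seed,
                exclude=ccfg.get("exclude", ()),
            )
            (out / "cv_report.json").write_text(json.dumps(report.to_dict(), indent=2))
            outputs["cv_report.json"] = out / "cv_report.json"

        else:
            raise ValueError(f"unknown stage {stage!r}")

    cfg_canonical = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_canonical.encode()).hexdigest(),
        "seed": seed,
        "stages": stages,
        "version": __version__,
        "outputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in sorted(outputs.items())
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
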