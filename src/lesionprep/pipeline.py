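"""End-to-end pipeline: phantom/ingest -> filter -> split -> select -> build
-> (external or synthetic detector) -> evaluate -> aggregate.

The detector itself is an interface boundary: the pipeline emits a prepared
train/test dataset and consumes detections — either a CSV produced by an
external model or the built-in synthetic detector run on phantom ground
truth.  Every stage logs its counts; a stage failure aborts the run naming
the stage, with partial outputs left in place for debugging.  Two runs with
the same config produce identical manifests and metrics.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml

from . import evaluation, ingest, partitioning, phantom, preprocess, selection

__all__ = ["PipelineError", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


@_stage("phantom")
def _make_phantom(cfg: dict, out: Path, seed: int) -> phantom.PhantomCohort:
    spec_kwargs = dict(cfg)
    spec_kwargs.setdefault("seed", seed)
    emit = spec_kwargs.pop("emit", "png")
    spec = phantom.PhantomSpec(**spec_kwargs)
    cohort = phantom.generate_cohort(spec, out / "phantom", emit=emit)
    logger.info("stage phantom: %d patients written", spec.n_patients)
    return cohort


@_stage("ingest")
def _ingest(annotation_csv, image_root, fs_regex):
    errors: list[ingest.LoadError] = []
    cases = ingest.load_cohort(
        annotation_csv, image_root,
        fat_suppression_regex=fs_regex, errors=errors,
    )
    cases = [ingest.filter_fat_suppressed(c) for c in cases]
    usable = [c for c in cases if c.usable]
    logger.info(
        "stage ingest: %d cases loaded, %d usable, %d load errors",
        len(cases), len(usable), len(errors),
    )
    return usable


@_stage("partition")
def _partition(patient_ids, cfg: dict, seed: int):
    """Return a list of (name, train_ids, test_ids) splits."""
    mode = cfg.get("mode", "fraction")
    if mode == "fraction":
        train, test = partitioning.split_patients(
            patient_ids, cfg.get("test_fraction", 0.2), seed
        )
        return None, [("split", train, test)]
    if mode == "folds":
        plan = partitioning.make_fold_plan(patient_ids, cfg.get("k", 10), seed)
        return plan, [
            (f"fold_{i:02d}", *partitioning.fold_split(plan, i))
            for i in range(plan.k)
        ]
    raise ValueError(f"unknown split mode {mode!r}")


def run_pipeline(config: dict | str | Path) -> Path:
    """Execute the configured pipeline; return the run directory.

    Config keys (YAML or dict): ``out_dir``; ``seed``; either ``phantom``
    (PhantomSpec fields) or ``cohort`` (``annotation_csv`` + ``image_root``);
    ``split`` (``mode`` fraction/folds, ``test_fraction`` or ``k``);
    ``funnel`` (``a``, ``b``); ``target_size``; ``export_images``; either
    ``detector`` (DetectorModel fields) or ``detections_csv``; ``eval``
    (``tp_iou_threshold``).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    truth: phantom.PhantomCohort | None = None
    if "phantom" in config:
        truth = _make_phantom(config["phantom"], out, seed)
        annotation_csv = truth.annotation_csv
        image_root = truth.root
    elif "cohort" in config:
        annotation_csv = config["cohort"]["annotation_csv"]
        image_root = config["cohort"]["image_root"]
    else:
        raise PipelineError("config", ValueError("need 'phantom' or 'cohort'"))

    fs_regex = config.get("fat_suppression_regex", ingest.DEFAULT_FS_REGEX)
    cohort = _ingest(annotation_csv, image_root, fs_regex)
    patient_ids = sorted(c.patient_id for c in cohort)
    by_id = {c.patient_id: c for c in cohort}

    plan, splits = _partition(patient_ids, config.get("split", {}), seed)
    if plan is not None:
        plan.to_csv(out / "fold_plan.csv")

    funnel_cfg = config.get("funnel", {})
    params = selection.FunnelParams(
        a=funnel_cfg.get("a", 0.75), b=funnel_cfg.get("b", 1.9625)
    )
    target_size = int(config.get("target_size", 448))
    export_images = bool(config.get("export_images", True))
    tp_thr = float(config.get("eval", {}).get("tp_iou_threshold", 0.0))

    det_all: dict[str, list[evaluation.Detection]] | None = None
    if "detections_csv" in config:
        det_all = evaluation.load_detections_csv(config["detections_csv"])

    per_fold_metrics: list[evaluation.CohortMetrics] = []
    for fold_index, (name, train_ids, test_ids) in enumerate(splits):
        fold_dir = out / name
        fold_dir.mkdir(exist_ok=True)

        try:
            selections = {
                pid: selection.select_training_slices(by_id[pid].annotation, params)
                for pid in train_ids
            }
        except Exception as exc:  # pragma: no cover - guarded inputs
            raise PipelineError("select", exc) from exc
        logger.info(
            "stage select [%s]: kept %d of %d tumor slices across %d train patients",
            name,
            sum(s.n_keep for s in selections.values()),
            sum(s.n_total for s in selections.values()),
            len(train_ids),
        )

        if export_images:
            try:
                preprocess.assemble_dataset(
                    cohort, (train_ids, test_ids), selections,
                    image_root, fold_dir / "dataset", target_size=target_size,
                )
            except Exception as exc:
                raise PipelineError("build", exc) from exc

        try:
            if det_all is not None:
                detections = det_all
            elif truth is not None:
                model = phantom.DetectorModel(**config.get("detector", {}))
                detections = phantom.generate_detections(
                    truth, model, seed=seed + 1000 + fold_index
                )
            else:
                raise ValueError(
                    "no detections available: configure 'detector' (phantom "
                    "runs) or 'detections_csv'"
                )
            evals = [
                evaluation.evaluate_patient(
                    pid, by_id[pid].annotation, detections.get(pid, []),
                    tp_iou_threshold=tp_thr,
                )
                for pid in test_ids
            ]
            metrics = evaluation.cohort_metrics(evals)
        except Exception as exc:
            raise PipelineError("evaluate", exc) from exc

        with open(fold_dir / "metrics.json", "w") as fh:
            json.dump(metrics.as_dict(), fh, indent=2)
        logger.info(
            "stage evaluate [%s]: accuracy %.2f%% (%d TP / %d FN)",
            name, metrics.accuracy_pct, metrics.tp_count, metrics.fn_count,
        )
        per_fold_metrics.append(metrics)

    if len(per_fold_metrics) >= 2:
        agg = evaluation.aggregate_folds(per_fold_metrics)
        with open(out / "aggregate.json", "w") as fh:
            json.dump(
                {k: {"mean": m, "std": s} for k, (m, s) in agg.items()},
                fh, indent=2,
            )
        logger.info(
            "aggregate: mean accuracy %.2f%% +/- %.2f%%",
            *agg["accuracy_pct"],
        )
    return out
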