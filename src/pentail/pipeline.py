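"""End-to-end orchestration: synth -> features -> sequences -> CV -> final model.

The final-model protocol mirrors the original study: the two outer test
pens are untouched by every fitting step (weights, balancing, early
stopping); one learning pen is held out as the validation set for early
stopping; the remaining learning pens, class-balanced by undersampling,
form the training set.  The outer evaluation reports the combined and
per-pen threshold sweeps plus the per-behaviour-category breakdown.

A run directory is reproducible from its frozen config: one master seed
fans out deterministically (via hashing) to fold assignment, synthesis,
undersampling and weight initialization.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from pentail import data_io, param_stats
from pentail.cv_grid import derive_seed, expand_grid, make_folds, run_grid
from pentail.errors import ConfigurationError, LeakageError
from pentail.evaluation import category_breakdown, threshold_sweep
from pentail.features import fit_transform_pipeline
from pentail.models import ModelSpec, balance_undersample, build_model, predict_proba, train
from pentail.sequences import build_sequences
from pentail.synthetic import SynthConfig, generate


def prepare_features(
    table: data_io.FrameTable,
    raw_features: dict[str, np.ndarray],
    n_pc: int | None,
    fit_pens: list[str] | None = None,
):
    """Fit the mask/PCA/min-max transform and apply it per pen.

    ``fit_pens=None`` reproduces the original protocol (fit on all pens
    including test pens); pass training pens only to avoid that leakage.
    Rows for excluded frames are dropped before fitting and transforming.
    """
    pens = table.pens
    retained = {p: raw_features[p][~table.pen(p, include_excluded=True)["excluded"].to_numpy()]
                for p in pens}
    fit_on = pens if fit_pens is None else [str(p) for p in fit_pens]
    stacked = np.vstack([retained[p] for p in fit_on])
    transform, _ = fit_transform_pipeline(stacked, n_pc=n_pc)
    return transform, {p: transform.apply(retained[p]) for p in pens}


def run_final(
    table: data_io.FrameTable,
    features: dict[str, np.ndarray],
    spec: ModelSpec,
    outer_test_pens: tuple[str, str],
    validation_pen: str,
    seed: int,
    fit_on_train: bool = False,
    max_epochs: int = 200,
) -> dict:
    """Train the final model on all learning pens and test on the outer pens.

    ``features`` are raw (untransformed) per-pen matrices; the transform
    for ``spec.n_pc`` is fitted here.  Raises :class:`LeakageError` if
    the outer test pens intersect the training or validation pens.
    """
    outer = tuple(str(p) for p in outer_test_pens)
    val_pen = str(validation_pen)
    train_pens = [p for p in table.pens if p not in outer and p != val_pen]
    if val_pen in outer:
        raise LeakageError("validation pen is an outer test pen")
    if not train_pens:
        raise ConfigurationError("no training pens left")

    fit_pens = train_pens + [val_pen] if fit_on_train else None
    transform, transformed = prepare_features(table, features, spec.n_pc, fit_pens)
    seqs = build_sequences(table, transformed, spec.n_obs)

    train_set = balance_undersample(seqs.for_pens(train_pens),
                                    derive_seed(seed, "balance"))
    val_set = seqs.for_pens([val_pen])
    if set(train_set.pens) & set(outer) or set(val_set.pens) & set(outer):
        raise LeakageError("outer test pen leaked into a training artifact")

    width = seqs.x.shape[2]
    model = build_model(spec, input_dim=width, seed=derive_seed(seed, "init"))
    model, log = train(model, train_set, val_set, spec,
                       derive_seed(seed, "train"), max_epochs=max_epochs)

    reports = {}
    test_sets = {pen: seqs.for_pens([pen]) for pen in outer}
    test_sets["combined"] = seqs.for_pens(outer)
    for name, subset in test_sets.items():
        probs = predict_proba(model, subset, spec.family)
        report = threshold_sweep(probs, subset.labels)
        report.category_table = category_breakdown(
            probs, subset.labels, subset.categories, 0.5
        )
        report.extras["n_sequences"] = len(subset)
        report.extras["n_positive"] = subset.n_positive
        reports[name] = report

    return {
        "spec": spec,
        "model": model,
        "train_log": log,
        "transform": transform,
        "reports": reports,
        "train_size": len(train_set),
        "val_size": len(val_set),
    }


class _RunLogger:
    def __init__(self, path: Path):
        self.path = path

    def log(self, stage: str, **fields) -> None:
        record = {"stage": stage, "time": time.time(), **fields}
        with self.path.open("a") as fh:
            fh.write(json.dumps(record) + "\n")


def run_all(config: dict, out_dir: str | Path, force: bool = False) -> Path:
    """Execute every stage from one config dict and return the run directory.

    Config keys (all optional, with demo-scale defaults): ``seed``,
    ``synth`` (SynthConfig overrides), ``n_pc``, ``grid`` (domains for a
    reduced CV grid), ``final`` (family/n_obs/... of the final model),
    ``fit_on_train``, ``max_epochs``.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} exists; pass force=True to overwrite")
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    logger = _RunLogger(out_dir / "run_log.jsonl")
    seed = int(config.get("seed", 0))

    # --- synth -------------------------------------------------------------
    t0 = time.time()
    synth_cfg = SynthConfig(**{"seed": derive_seed(seed, "synth"),
                               **config.get("synth", {})})
    table, features, event_log = generate(synth_cfg)
    data_io.save_manifest(table, out_dir / "manifest.csv")
    (out_dir / "event_log.json").write_text(json.dumps(event_log, indent=1))
    data_io.summarize(table).to_csv(out_dir / "summary.csv", index=False)
    logger.log("synth", seconds=time.time() - t0, config=asdict(synth_cfg))

    # --- folds -------------------------------------------------------------
    outer_test, folds = make_folds(table.pens, derive_seed(seed, "folds"))
    (out_dir / "folds.json").write_text(
        json.dumps({"outer_test": outer_test, "folds": [asdict(f) for f in folds]},
                   indent=1)
    )

    # --- features ----------------------------------------------------------
    t0 = time.time()
    grid_cfg = config.get("grid", {})
    npc_values = [v if v != "none" else None
                  for v in grid_cfg.get("n_pc", [config.get("n_pc", 16)])]
    fit_pens = None
    if config.get("fit_on_train"):
        fit_pens = [p for p in table.pens if p not in outer_test]
    features_by_npc = {}
    for n_pc in npc_values:
        transform, transformed = prepare_features(table, features, n_pc, fit_pens)
        features_by_npc[n_pc] = transformed
        transform.save(out_dir / f"transform_npc_{n_pc}")
    logger.log("features", seconds=time.time() - t0, n_pc=[str(v) for v in npc_values])

    # --- CV grid -----------------------------------------------------------
    t0 = time.time()
    max_epochs = int(config.get("max_epochs", 60))
    results = None
    if grid_cfg:
        specs = []
        for family in grid_cfg.get("families", ["lstm"]):
            specs += expand_grid(
                family,
                n_obs=grid_cfg.get("n_obs", [10]),
                n_pc=npc_values,
                n_layers=grid_cfg.get("n_layers", [1]),
                widths=grid_cfg.get("widths"),
                dropout=grid_cfg.get("dropout", [0.0]),
            )
        results = run_grid(table, features_by_npc, folds, specs,
                           derive_seed(seed, "grid"),
                           out_csv=out_dir / "cv_results.csv",
                           max_epochs=max_epochs)
        logger.log("cv", seconds=time.time() - t0, rows=len(results))

    # --- final model -------------------------------------------------------
    t0 = time.time()
    final_cfg = dict(config.get("final", {}))
    if not final_cfg and results is not None:
        ok = results[(results["status"] == "ok")
                     & (results["test_pen_id"] == "combined")]
        best = ok.loc[ok["btmma"].idxmax()]
        final_cfg = {
            "family": best["family"],
            "n_obs": int(best["n_obs"]),
            "n_pc": None if best["n_pc"] == "none" else int(best["n_pc"]),
            "n_layers": int(best["n_layers"]),
            "node_rule": best["node_rule"] if best["family"] == "lstm" else None,
            "first_filters": int(best["first_filters"])
            if best["family"] == "cnn" else None,
            "dropout": float(best["dropout"]),
        }
    final_cfg.setdefault("family", "lstm")
    final_cfg.setdefault("n_obs", 10)
    final_cfg.setdefault("n_pc", npc_values[0])
    final_cfg.setdefault("n_layers", 1)
    if final_cfg["family"] == "lstm":
        final_cfg.setdefault("node_rule", "sum")
    else:
        final_cfg.setdefault("first_filters", 8)
    spec = ModelSpec(**final_cfg)
    learning = [p for p in table.pens if p not in outer_test]
    rng = np.random.default_rng(derive_seed(seed, "final_val"))
    val_pen = learning[rng.integers(len(learning))]
    final = run_final(table, features, spec, outer_test, val_pen,
                      derive_seed(seed, "final"),
                      fit_on_train=bool(config.get("fit_on_train")),
                      max_epochs=max_epochs)
    for name, report in final["reports"].items():
        report.to_json(out_dir / f"final_eval_{name}.json")
        report.curve.to_csv(out_dir / f"final_curve_{name}.csv", index=False)
    logger.log("final", seconds=time.time() - t0,
               spec=spec.key(), val_pen=val_pen,
               btmma=final["reports"]["combined"].btmma)

    # --- hyperparameter analysis -------------------------------------------
    if results is not None:
        for family in results["family"].unique():
            sub = results[results["family"] == family]
            for metric in ("nmma", "btmma"):
                try:
                    fitted = param_stats.fit_lmem(sub, metric, family)
                except (ValueError, KeyError) as exc:
                    logger.log("analyze", family=family, metric=metric,
                               skipped=str(exc))
                    continue
                param_stats.anova(fitted).to_csv(
                    out_dir / f"anova_{family}_{metric}.csv", index=False
                )
        logger.log("analyze", done=True)

    return out_dir
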