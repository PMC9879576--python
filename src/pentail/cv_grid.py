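"""Pen-wise cross-validation folds and hyperparameter grid runs.

Pens are the statistical unit: two pens are reserved as the outer test
set, and the remaining eight learning pens are split into a 4-fold
scheme where each fold tests on a disjoint pair of pens, validates on
one randomly chosen pen of the remaining six (for early stopping) and
trains on the other five.  Every learning pen therefore serves as an
inner test pen exactly once, and within each fold train / validation /
test pens are mutually disjoint.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from pentail.data_io import FrameTable
from pentail.errors import ConfigurationError, LeakageError
from pentail.models import (
    FIRST_FILTER_CHOICES,
    NODE_RULES,
    ModelSpec,
    balance_undersample,
    build_model,
    predict_proba,
    train,
)
from pentail.sequences import SequenceSet, build_sequences
from pentail.evaluation import threshold_sweep

#: Faithful hyperparameter domains of the reference grid.
GRID_N_OBS = (10, 20, 30)
GRID_N_PC = (4, 8, 16, 32, 64, 128, 256, 512, None)  # None = no-PCA baseline
#: The reference CNN grid ran one fewer component level than the LSTM grid
#: (its ANOVA reports 7 rather than 8 degrees of freedom); which level was
#: omitted is not documented, so the default drops 512 and keeps the
#: no-PCA baseline needed for baseline contrasts.
GRID_N_PC_CNN = (4, 8, 16, 32, 64, 128, 256, None)
GRID_N_LAYERS = (1, 2, 3)
GRID_DROPOUT = (0.0, 0.1, 0.2)


@dataclass(frozen=True)
class FoldPlan:
    fold_id: int
    inner_test_pens: tuple[str, str]
    validation_pen: str
    inner_train_pens: tuple[str, ...]

    def check_disjoint(self) -> None:
        groups = [set(self.inner_test_pens), {self.validation_pen},
                  set(self.inner_train_pens)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise LeakageError(f"fold {self.fold_id}: pen groups overlap")


def make_folds(
    pens: Sequence[str], seed: int, ordered: bool = False
) -> tuple[tuple[str, str], list[FoldPlan]]:
    """Reserve 2 outer test pens and build 4 disjoint inner-test folds.

    With ``ordered=True`` the pens keep their given order (the first two
    become the outer test set and consecutive pairs the fold test sets),
    matching the published pen layout; the validation pen of each fold
    is still drawn at random from the fold's six non-test learning pens.
    Generalizes to other pen counts: half the learning pens (in pairs)
    form the folds.
    """
    pens = [str(p) for p in pens]
    if len(set(pens)) != len(pens):
        raise ConfigurationError("pen ids must be unique")
    if len(pens) < 4:
        raise ConfigurationError("need at least 4 pens (2 outer test + 2 learning)")
    rng = np.random.default_rng(seed)
    order = list(pens) if ordered else [pens[i] for i in rng.permutation(len(pens))]
    outer_test = (order[0], order[1])
    learning = order[2:]
    if len(learning) % 2:
        raise ConfigurationError("learning pens must pair up evenly")
    folds = []
    for fold_id, i in enumerate(range(0, len(learning), 2), start=1):
        test_pair = (learning[i], learning[i + 1])
        rest = [p for p in learning if p not in test_pair]
        val = rest[rng.integers(len(rest))]
        train_pens = tuple(p for p in rest if p != val)
        plan = FoldPlan(fold_id, test_pair, val, train_pens)
        plan.check_disjoint()
        folds.append(plan)
    return outer_test, folds


def expand_grid(
    family: str,
    n_obs: Iterable[int] = GRID_N_OBS,
    n_pc: Iterable[int | None] | None = None,
    n_layers: Iterable[int] = GRID_N_LAYERS,
    widths: Iterable | None = None,
    dropout: Iterable[float] = GRID_DROPOUT,
) -> list[ModelSpec]:
    """Cross product of parameter domains as a list of :class:`ModelSpec`."""
    if n_pc is None:
        n_pc = GRID_N_PC if family == "lstm" else GRID_N_PC_CNN
    if widths is None:
        widths = NODE_RULES if family == "lstm" else FIRST_FILTER_CHOICES
    specs = []
    for o, p, l, w, d in itertools.product(n_obs, n_pc, n_layers, widths, dropout):
        kwargs = {"node_rule": w} if family == "lstm" else {"first_filters": w}
        specs.append(ModelSpec(family=family, n_obs=o, n_pc=p, n_layers=l,
                               dropout=d, **kwargs))
    return specs


def derive_seed(master_seed: int, *parts) -> int:
    """Deterministic sub-seed (< 2^31) from the master seed and a key.

    Hash-based so that any subset of the grid reproduces identically
    regardless of execution order.
    """
    digest = hashlib.sha256(
        ("|".join([str(master_seed), *map(str, parts)])).encode()
    ).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _row(spec: ModelSpec, fold: FoldPlan, test_pen: str, report, seed: int) -> dict:
    return {
        "fold_id": fold.fold_id,
        "test_pen_id": test_pen,
        "family": spec.family,
        "n_obs": spec.n_obs,
        "n_pc": "none" if spec.n_pc is None else spec.n_pc,
        "n_layers": spec.n_layers,
        "node_rule": spec.node_rule,
        "first_filters": spec.first_filters,
        "dropout": spec.dropout,
        "nmma": report.nmma,
        "btmma": report.btmma,
        "best_threshold": report.best_threshold,
        "auc": report.auc,
        "seed": seed,
        "status": "ok",
        "spec_key": spec.key(),
    }


def run_grid(
    table: FrameTable,
    features_by_npc: dict[int | None, dict[str, np.ndarray]],
    folds: list[FoldPlan],
    specs: list[ModelSpec],
    master_seed: int,
    out_csv: str | Path | None = None,
    max_epochs: int = 200,
    sequence_cache: dict | None = None,
    on_row: Callable[[dict], None] | None = None,
) -> pd.DataFrame:
    """Train and evaluate every grid point on every fold.

    ``features_by_npc`` maps each requested ``n_pc`` (or ``None``) to
    transformed per-pen feature matrices.  Per test pen and per fold one
    result row is emitted, plus a ``combined`` row over the pen pair.
    When ``out_csv`` exists, rows already present are skipped and new
    rows appended, so an interrupted run resumes to an identical table.
    """
    out_csv = Path(out_csv) if out_csv is not None else None
    done: set[tuple[str, int]] = set()
    rows: list[dict] = []
    if out_csv is not None and out_csv.exists():
        prev = pd.read_csv(out_csv)
        rows = prev.to_dict(orient="records")
        done = {(r["spec_key"], r["fold_id"]) for r in rows}

    cache = {} if sequence_cache is None else sequence_cache

    def sequences_for(n_obs: int, n_pc) -> SequenceSet:
        key = (n_obs, n_pc)
        if key not in cache:
            cache[key] = build_sequences(table, features_by_npc[n_pc], n_obs)
        return cache[key]

    for spec in specs:
        if spec.n_pc not in features_by_npc:
            raise ConfigurationError(f"no features prepared for n_pc={spec.n_pc}")
        for fold in folds:
            if (spec.key(), fold.fold_id) in done:
                continue
            seed = derive_seed(master_seed, spec.key(), fold.fold_id)
            seqs = sequences_for(spec.n_obs, spec.n_pc)
            new_rows = []
            try:
                train_set = balance_undersample(
                    seqs.for_pens(fold.inner_train_pens), seed
                )
                val_set = seqs.for_pens([fold.validation_pen])
                width = seqs.x.shape[2]
                model = build_model(spec, input_dim=width, seed=seed)
                model, _ = train(model, train_set, val_set, spec, seed,
                                 max_epochs=max_epochs)
                eval_sets = [(pen, seqs.for_pens([pen]))
                             for pen in fold.inner_test_pens]
                eval_sets.append(("combined", seqs.for_pens(fold.inner_test_pens)))
                for name, subset in eval_sets:
                    report = threshold_sweep(
                        predict_proba(model, subset, spec.family), subset.labels
                    )
                    new_rows.append(_row(spec, fold, name, report, seed))
            except Exception as exc:  # noqa: BLE001 - row-level isolation
                new_rows = [
                    {
                        **{k: None for k in
                           ("nmma", "btmma", "best_threshold", "auc")},
                        "fold_id": fold.fold_id,
                        "test_pen_id": "combined",
                        "family": spec.family,
                        "n_obs": spec.n_obs,
                        "n_pc": "none" if spec.n_pc is None else spec.n_pc,
                        "n_layers": spec.n_layers,
                        "node_rule": spec.node_rule,
                        "first_filters": spec.first_filters,
                        "dropout": spec.dropout,
                        "seed": seed,
                        "status": f"failed: {exc}",
                        "spec_key": spec.key(),
                    }
                ]
            rows.extend(new_rows)
            if on_row is not None:
                for r in new_rows:
                    on_row(r)
            if out_csv is not None:
                pd.DataFrame(rows).to_csv(out_csv, index=False)
    return pd.DataFrame(rows)
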