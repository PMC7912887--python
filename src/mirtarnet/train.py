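"""Dataset splitting, training with early stopping, grid search and repeats.

The 64/16/20 train/validation/test split is stratified by label with
per-class rounding (test = round(0.2*N_c), val = round(0.16*N_c), remainder
to training).  Grid search scans learning rate x dropout x batch size and
ranks cells by validation accuracy with a deterministic tie-break; repeated
runs re-split the data with seeds derived from one master seed so every run
is reproducible.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .codec import LabeledPair, PairSchema, encode_dataset
from .metrics import MetricsReport, evaluate
from .model import ModelSpec, build_model
from .nn import Adam, Network

logger = logging.getLogger(__name__)


class TrainError(RuntimeError):
    pass


@dataclass(frozen=True)
class SplitSpec:
    train_frac: float = 0.64
    val_frac: float = 0.16
    test_frac: float = 0.20
    seed: int = 0

    def __post_init__(self):
        if not math.isclose(self.train_frac + self.val_frac + self.test_frac, 1.0):
            raise ValueError("split fractions must sum to 1")
        if min(self.train_frac, self.val_frac, self.test_frac) <= 0:
            raise ValueError("split fractions must be positive")


@dataclass(frozen=True)
class HyperGrid:
    learning_rates: tuple = (0.2, 0.1, 0.05, 0.01, 0.005, 0.001)
    dropout_rates: tuple = (0.1, 0.2, 0.3, 0.4, 0.5)
    batch_sizes: tuple = (10, 30, 50, 100, 200)
    max_epochs: int = 1000

    def cells(self):
        """Cartesian product, ordered for the deterministic tie-break."""
        return list(
            itertools.product(
                sorted(self.learning_rates),
                sorted(self.dropout_rates),
                sorted(self.batch_sizes),
            )
        )


@dataclass(frozen=True)
class EarlyStopRule:
    """Stop when validation accuracy fails to improve by min_delta within patience."""

    min_delta: float = 0.001
    patience: int = 100


@dataclass
class Splits:
    train: list[LabeledPair]
    val: list[LabeledPair]
    test: list[LabeledPair]


@dataclass
class RunRecord:
    split_seed: int
    init_seed: int
    learning_rate: float
    dropout_rate: float
    batch_size: int
    epochs_run: int
    best_val_accuracy: float
    history: list[dict] = field(default_factory=list)
    test_report: MetricsReport | None = None
    model_path: str | None = None


def split_sizes(n: int, spec: SplitSpec) -> tuple[int, int, int]:
    """(train, val, test) sizes under the round-based convention."""
    n_test = round(spec.test_frac * n)
    n_val = round(spec.val_frac * n)
    return n - n_val - n_test, n_val, n_test


def split_dataset(pairs: list[LabeledPair], spec: SplitSpec) -> Splits:
    """Label-stratified, seed-deterministic 64/16/20 partition."""
    if not pairs:
        raise TrainError("cannot split an empty dataset")
    rng = np.random.default_rng(spec.seed)
    buckets: dict[str, list[LabeledPair]] = {"train": [], "val": [], "test": []}
    for label in (0, 1):
        members = [p for p in pairs if p.label == label]
        if not members:
            continue
        order = rng.permutation(len(members))
        n_train, n_val, n_test = split_sizes(len(members), spec)
        if min(n_train, n_val, n_test) < 1:
            raise TrainError(
                f"class {label} with {len(members)} pairs yields an empty split"
            )
        shuffled = [members[i] for i in order]
        buckets["test"].extend(shuffled[:n_test])
        buckets["val"].extend(shuffled[n_test : n_test + n_val])
        buckets["train"].extend(shuffled[n_test + n_val :])
    return Splits(**buckets)


def _accuracy(net: Network, X: np.ndarray, y: np.ndarray) -> float:
    probs = net.predict(X)
    return float(np.mean((probs >= 0.5) == (y == 1)))


def train_once(
    net: Network,
    splits_xy: tuple,
    learning_rate: float,
    batch_size: int,
    rule: EarlyStopRule = EarlyStopRule(),
    max_epochs: int = 1000,
    dropout_rate: float = float("nan"),
    seed: int = 0,
    split_seed: int = 0,
    clipnorm: float | None = 5.0,
) -> RunRecord:
    """Mini-batch Adam training with early stopping and best-weights restore.

    ``splits_xy`` is ((X_train, y_train), (X_val, y_val)); test evaluation is
    the caller's job.  Raises :class:`~mirtarnet.nn.NonFiniteLossError` on a
    diverged run.
    """
    (X_tr, y_tr), (X_val, y_val) = splits_xy
    rng = np.random.default_rng(seed)
    opt = Adam(lr=learning_rate, clipnorm=clipnorm)
    record = RunRecord(
        split_seed=split_seed,
        init_seed=seed,
        learning_rate=learning_rate,
        dropout_rate=dropout_rate,
        batch_size=batch_size,
        epochs_run=0,
        best_val_accuracy=-np.inf,
    )
    best_weights = net.clone_weights()
    epochs_since_improvement = 0
    for epoch in range(max_epochs):
        order = rng.permutation(len(X_tr))
        losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            loss = net.train_batch(X_tr[idx], y_tr[idx], rng)
            losses.append(loss)
            if learning_rate > 0:
                opt.step(net)
        val_acc = _accuracy(net, X_val, y_val)
        record.epochs_run = epoch + 1
        record.history.append(
            {"epoch": epoch + 1, "train_loss": float(np.mean(losses)),
             "val_accuracy": val_acc}
        )
        if val_acc >= record.best_val_accuracy + rule.min_delta or (
            record.best_val_accuracy == -np.inf
        ):
            if val_acc > record.best_val_accuracy:
                record.best_val_accuracy = val_acc
                best_weights = net.clone_weights()
            epochs_since_improvement = 0
        else:
            if val_acc > record.best_val_accuracy:
                # improved, but by less than min_delta: keep the weights,
                # don't reset the patience clock
                record.best_val_accuracy = val_acc
                best_weights = net.clone_weights()
            epochs_since_improvement += 1
            if epochs_since_improvement >= rule.patience:
                break
    net.set_weights(best_weights)
    return record


def _encode_splits(splits: Splits, schema: PairSchema):
    return (
        encode_dataset(splits.train, schema),
        encode_dataset(splits.val, schema),
        encode_dataset(splits.test, schema),
    )


def run_cell(
    pairs_or_splits,
    schema: PairSchema,
    learning_rate: float,
    dropout_rate: float,
    batch_size: int,
    base_spec: ModelSpec | None = None,
    rule: EarlyStopRule = EarlyStopRule(),
    max_epochs: int = 1000,
    init_seed: int = 0,
    split_spec: SplitSpec | None = None,
    removed: frozenset = frozenset(),
) -> tuple[RunRecord, Network]:
    """Split (if needed), build a fresh model and train one hyperparameter cell."""
    if isinstance(pairs_or_splits, Splits):
        splits = pairs_or_splits
        split_seed = split_spec.seed if split_spec else -1
    else:
        split_spec = split_spec or SplitSpec()
        splits = split_dataset(pairs_or_splits, split_spec)
        split_seed = split_spec.seed
    (tr, val, test) = _encode_splits(splits, schema)
    spec = base_spec or ModelSpec.for_schema(schema)
    spec = replace(spec, dropout_rate=dropout_rate, input_len=schema.total_len)
    net = build_model(spec, rng=init_seed, removed=removed)
    record = train_once(
        net, (tr, val),
        learning_rate=learning_rate,
        batch_size=batch_size,
        rule=rule,
        max_epochs=max_epochs,
        dropout_rate=dropout_rate,
        seed=init_seed,
        split_seed=split_seed,
    )
    X_test, y_test = test
    record.test_report = evaluate(y_test, net.predict(X_test))
    return record, net


def grid_search(
    pairs: list[LabeledPair],
    grid: HyperGrid,
    split_spec: SplitSpec,
    schema: PairSchema,
    base_spec: ModelSpec | None = None,
    rule: EarlyStopRule = EarlyStopRule(),
    init_seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Train every grid cell on one shared split; return best cell + leaderboard.

    Best = highest validation accuracy; ties break to the lowest learning
    rate, then lowest dropout, then smallest batch (the cell iteration
    order).  A failed cell is recorded with its error, not fatal.
    """
    cells = grid.cells()
    if not cells:
        raise TrainError("empty hyperparameter grid")
    splits = split_dataset(pairs, split_spec)
    rows = []
    best = None
    for lr, dropout, batch in cells:
        try:
            record, _ = run_cell(
                splits, schema, lr, dropout, batch,
                base_spec=base_spec, rule=rule, max_epochs=grid.max_epochs,
                init_seed=init_seed, split_spec=split_spec,
            )
            row = {
                "learning_rate": lr, "dropout_rate": dropout, "batch_size": batch,
                "val_accuracy": record.best_val_accuracy,
                "test_accuracy": record.test_report.accuracy,
                "epochs_run": record.epochs_run, "error": "",
            }
            if best is None or row["val_accuracy"] > best["val_accuracy"]:
                best = row
        except Exception as exc:  # noqa: BLE001 - cell failures are data
            logger.warning("grid cell (%s, %s, %s) failed: %s", lr, dropout, batch, exc)
            row = {
                "learning_rate": lr, "dropout_rate": dropout, "batch_size": batch,
                "val_accuracy": float("nan"), "test_accuracy": float("nan"),
                "epochs_run": 0, "error": str(exc),
            }
        rows.append(row)
    leaderboard = pd.DataFrame(rows)
    if best is None:
        raise TrainError("every grid cell failed")
    return best, leaderboard


def repeated_runs(
    pairs: list[LabeledPair],
    schema: PairSchema,
    learning_rate: float,
    dropout_rate: float,
    batch_size: int,
    n_repeats: int = 30,
    master_seed: int = 0,
    base_spec: ModelSpec | None = None,
    rule: EarlyStopRule = EarlyStopRule(),
    max_epochs: int = 1000,
    removed: frozenset = frozenset(),
    split_seeds: list[int] | None = None,
) -> tuple[list[MetricsReport], list[RunRecord]]:
    """Retrain over n_repeats random re-splits; returns per-repeat test metrics."""
    if n_repeats < 2:
        raise TrainError("need at least 2 repeats")
    if split_seeds is None:
        ss = np.random.SeedSequence(master_seed)
        split_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_repeats)]
    elif len(split_seeds) != n_repeats:
        raise TrainError("split_seeds length must equal n_repeats")
    reports, records = [], []
    for rep, seed in enumerate(split_seeds):
        try:
            record, _ = run_cell(
                pairs, schema, learning_rate, dropout_rate, batch_size,
                base_spec=base_spec, rule=rule, max_epochs=max_epochs,
                init_seed=seed, split_spec=SplitSpec(seed=seed), removed=removed,
            )
        except Exception as exc:
            raise TrainError(f"repeat {rep} (seed {seed}) failed: {exc}") from exc
        reports.append(record.test_report)
        records.append(record)
    return reports, records


def compose_unified_dataset(
    deepmirtar_pairs: list[LabeledPair],
    miraw_pairs: list[LabeledPair],
    frac_dmt: float = 0.90,
    cap_ratio: int = 3,
    seed: int = 0,
) -> dict[str, list[LabeledPair]]:
    """Merge the two pools into one balanced training set plus leftovers.

    Per class, ``floor(frac_dmt * min(class counts))`` pairs are drawn from
    the first pool (the same number from each class keeps the draw balanced)
    and ``min(cap_ratio * that, available)`` from the second; undrawn pairs
    are returned as the two leftover test sets.
    """
    rng = np.random.default_rng(seed)
    by_class = lambda pairs, label: [p for p in pairs if p.label == label]  # noqa: E731
    dmt = {lab: by_class(deepmirtar_pairs, lab) for lab in (0, 1)}
    mrw = {lab: by_class(miraw_pairs, lab) for lab in (0, 1)}
    n_dmt = math.floor(frac_dmt * min(len(dmt[0]), len(dmt[1])))
    if n_dmt < 1:
        raise TrainError("frac_dmt draws no pairs from the first pool")
    combined: list[LabeledPair] = []
    dmt_left: list[LabeledPair] = []
    mrw_left: list[LabeledPair] = []
    for lab in (0, 1):
        order = rng.permutation(len(dmt[lab]))
        chosen = [dmt[lab][i] for i in order[:n_dmt]]
        dmt_left.extend(dmt[lab][i] for i in order[n_dmt:])
        n_mrw = min(cap_ratio * n_dmt, len(mrw[lab]))
        order = rng.permutation(len(mrw[lab]))
        combined.extend(chosen)
        combined.extend(mrw[lab][i] for i in order[:n_mrw])
        mrw_left.extend(mrw[lab][i] for i in order[n_mrw:])
    if not combined:
        raise TrainError("cap produced an empty combined dataset")
    logger.info(
        "unified dataset: %d combined, %d first-pool leftover, %d second-pool leftover",
        len(combined), len(dmt_left), len(mrw_left),
    )
    return {
        "mirtarraw": combined,
        "deepmirtar_left": dmt_left,
        "miraw_left": mrw_left,
    }
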