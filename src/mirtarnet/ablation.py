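"""Architecture ablations: remove components, retrain, compare accuracies.

Variants remove one component group at a time — the max-pooling layer, the
convolution together with the pooling, the recurrent layer, the hidden dense
layer, or every dropout site — while all remaining hyperparameters stay at
the base model's values.  Comparisons are seed-matched: every variant sees
the identical sequence of data re-splits, so accuracy deltas reflect the
architecture alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codec import LabeledPair, PairSchema
from .metrics import aggregate_reports
from .model import REMOVABLE, InvalidSpecError, ModelSpec, build_model
from .nn import Network
from .train import EarlyStopRule, repeated_runs

FULL_MODEL = "full"


@dataclass(frozen=True)
class VariantSpec:
    base: ModelSpec
    removed: frozenset[str] = frozenset()
    name: str = ""

    def __post_init__(self):
        bad = set(self.removed) - REMOVABLE
        if bad:
            raise InvalidSpecError(f"unknown removable components: {sorted(bad)}")
        if not self.name:
            label = "+".join(sorted(self.removed)) if self.removed else FULL_MODEL
            object.__setattr__(self, "name", f"no_{label}" if self.removed else label)


def build_variant(spec: VariantSpec, rng=None) -> Network:
    """Network identical to the base except for the removed components."""
    return build_model(spec.base, rng=rng, removed=spec.removed)


def standard_variants(base: ModelSpec) -> list[VariantSpec]:
    """The full model plus the five single-removal variants."""
    return [VariantSpec(base)] + [
        VariantSpec(base, frozenset({name}))
        for name in ("max_pool", "cnn_and_pool", "rnn", "dense_hidden", "dropouts")
    ]


def compare_variants(
    pairs: list[LabeledPair],
    schema: PairSchema,
    variants: list[VariantSpec],
    n_repeats: int = 5,
    learning_rate: float = 0.005,
    dropout_rate: float = 0.2,
    batch_size: int = 30,
    master_seed: int = 0,
    rule: EarlyStopRule = EarlyStopRule(),
    max_epochs: int = 1000,
) -> pd.DataFrame:
    """Repeated seed-matched training per variant; one row per variant.

    The same split seeds (derived from ``master_seed``) are reused for every
    variant, so ``delta_accuracy`` vs the full model isolates the
    architectural change.
    """
    if len(variants) < 2 or not any(not v.removed for v in variants):
        raise ValueError("need >= 2 variants including the full model")
    ss = np.random.SeedSequence(master_seed)
    split_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_repeats)]
    rows = []
    for variant in variants:
        reports, _ = repeated_runs(
            pairs, schema, learning_rate, dropout_rate, batch_size,
            n_repeats=n_repeats, base_spec=variant.base, rule=rule,
            max_epochs=max_epochs, removed=variant.removed,
            split_seeds=split_seeds,
        )
        agg = aggregate_reports(reports)
        net = build_variant(variant, rng=0)
        rows.append(
            {
                "variant": variant.name,
                "removed": "+".join(sorted(variant.removed)),
                "param_count": net.param_count(),
                "mean_accuracy": agg["accuracy"]["mean"],
                "ci_low": agg["accuracy"]["ci_low"],
                "ci_high": agg["accuracy"]["ci_high"],
                "accuracies": [r.accuracy for r in reports],
            }
        )
    table = pd.DataFrame(rows)
    full_acc = table.loc[table["removed"] == "", "mean_accuracy"].iloc[0]
    table["delta_accuracy"] = table["mean_accuracy"] - full_acc
    return table
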