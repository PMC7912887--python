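"""Shared helpers for training-based tests (kept small for speed)."""

import numpy as np

from mirtarnet.codec import MIRAW_SCHEMA
from mirtarnet.model import ConvLayerSpec, ModelSpec, PoolSpec, RecurrentLayerSpec
from mirtarnet.train import EarlyStopRule, SplitSpec, run_cell

FAST_RULE = EarlyStopRule(min_delta=0.001, patience=8)


def small_spec(input_len=MIRAW_SCHEMA.total_len, dropout=0.2):
    return ModelSpec(
        input_len=input_len,
        conv=ConvLayerSpec(n_kernels=32, kernel_size=8),
        pool=PoolSpec(2, 2),
        rnn=RecurrentLayerSpec(hidden_units=16),
        dense_hidden_units=8,
        dropout_rate=dropout,
    )


def quick_train(pairs, schema=MIRAW_SCHEMA, seed=0, max_epochs=20, lr=0.01,
                batch_size=30, spec=None):
    """Train the scaled-down model on a pair list; returns (record, net)."""
    return run_cell(
        pairs, schema,
        learning_rate=lr, dropout_rate=0.2, batch_size=batch_size,
        base_spec=spec or small_spec(input_len=schema.total_len),
        rule=FAST_RULE, max_epochs=max_epochs,
        init_seed=seed, split_spec=SplitSpec(seed=seed),
    )


def scan_model_spec():
    """Small spec with the tanh LSTM fallback (reliable on tiny datasets)."""
    from mirtarnet.model import RecurrentLayerSpec
    from dataclasses import replace

    return replace(
        small_spec(dropout=0.1),
        rnn=RecurrentLayerSpec(hidden_units=16, activation="tanh"),
    )


def train_scan_model(seed, n_per_class=300):
    """Single-miRNA motif-detector model for planted-site recovery tests.

    Returns (record, net, query_mirna).  Negatives keep the miRNA and use
    seed-free random sites so the trained probability is motif-driven.
    """
    from mirtarnet.synth import SynthConfig, as_labeled_pairs, generate_dataset

    cfg = SynthConfig(
        n_pos=n_per_class, n_neg=n_per_class, site_len=40, n_mirnas=1,
        seed_mode="canonical_2_7", negative_mode="random_site",
        rng_seed=100 + seed,
    )
    dataset = generate_dataset(cfg)
    record, net = run_cell(
        as_labeled_pairs(dataset), MIRAW_SCHEMA,
        learning_rate=0.005, dropout_rate=0.1, batch_size=30,
        base_spec=scan_model_spec(), rule=EarlyStopRule(patience=20),
        max_epochs=60, init_seed=seed, split_spec=SplitSpec(seed=seed),
    )
    query = next(sp.pair.mirna for sp in dataset if sp.pair.label == 1)
    return record, net, query


def recover_planted_site(seed, gene_len=500):
    """True when the top-probability window carries the planted seed motif."""
    import numpy as np

    from mirtarnet.scan import predict_sites, split_gene

    _, net, query = train_scan_model(seed)
    rng = np.random.default_rng(seed)
    gene, offset, motif = plant_gene(query, gene_len, rng)
    windows = split_gene(gene, 40, 20)
    calls = predict_sites(net, MIRAW_SCHEMA, query, windows, "gene")
    best = max(calls, key=lambda c: c.probability)
    return motif in best.sequence


def plant_gene(query, gene_len, rng, region=(2, 7)):
    """A synthetic gene whose ONLY seed-pairing segment is the planted one.

    Random backgrounds of a few hundred nt contain near-complements of a
    6-nt seed by chance; those are genuine (non-canonical) binding sites, so
    they are scrubbed here to make the planted window uniquely attractive.
    Returns (gene_residues, planted_offset, motif).
    """
    from mirtarnet.codec import RnaSequence
    from mirtarnet.synth import BASES, pairs_with, revcomp_rna

    start, end = region
    seeds = [query.residues[s - 1 : e] for s, e in ((2, 7), (3, 8))]
    motif = revcomp_rna(query.residues[start - 1 : end])
    k = len(motif)

    def mismatches(segment, seed):
        return sum(
            0 if pairs_with(seed[len(seed) - 1 - i], segment[i], gu_allowed=True)
            else 1
            for i in range(k)
        )

    gene = list("".join(rng.choice(list(BASES), size=gene_len)))
    offset = int(rng.integers(0, gene_len - k + 1))
    gene[offset : offset + k] = motif
    planted_span = set(range(offset, offset + k))
    for _ in range(200):  # scrub competing (near-)sites
        dirty = False
        for o in range(gene_len - k + 1):
            if o == offset:
                continue
            for seed in seeds:
                if mismatches(gene[o : o + k], seed) <= 1:
                    mutable = [p for p in range(o, o + k) if p not in planted_span]
                    if not mutable:
                        continue
                    p = int(rng.choice(mutable))
                    gene[p] = str(rng.choice([b for b in BASES if b != gene[p]]))
                    dirty = True
        if not dirty:
            break
    return RnaSequence("".join(gene)), offset, motif


def shuffle_labels(pairs, seed=0):
    """Label-permuted copy of a dataset (breaks any miRNA:site relation)."""
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    labels = np.array([p.label for p in pairs])
    perm = rng.permutation(len(labels))
    return [replace(p, label=int(labels[j])) for p, j in zip(pairs, perm)]
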