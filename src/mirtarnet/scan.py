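"""Windowed scanning of gene sequences for miRNA binding sites.

A gene is split into overlapping windows of the model's site-slot width,
each window is scored against the query miRNA, windows at or above the
probability threshold are positive site calls, and a gene is a called
target when it carries at least ``min_sites_per_gene`` positive sites.
Positive sites can be exported as FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .codec import (
    LabeledPair,
    Orientation,
    PairSchema,
    RnaSequence,
    encode_pair,
    pad_sequence,
)
from .io import write_fasta
from .nn import Network

import numpy as np


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class ScanConfig:
    site_prob_threshold: float = 0.5
    min_sites_per_gene: int = 1
    step: int | None = None  # None -> window_len // 2 (50% overlap)

    def __post_init__(self):
        if not 0.0 < self.site_prob_threshold <= 1.0:
            raise ScanError("site_prob_threshold must be in (0, 1]")
        if self.min_sites_per_gene < 1:
            raise ScanError("min_sites_per_gene must be >= 1")


@dataclass(frozen=True)
class Window:
    offset: int  # 0-based start on the gene
    sequence: str  # window_len residues (N-padded for short genes)


@dataclass(frozen=True)
class WindowCall:
    gene_id: str
    mirna_id: str
    offset: int
    sequence: str
    probability: float
    call: bool


@dataclass(frozen=True)
class GeneCall:
    gene_id: str
    mirna_id: str
    n_windows: int
    n_positive_sites: int
    is_target: bool


@dataclass
class ScanResult:
    windows: list[WindowCall] = field(default_factory=list)
    genes: list[GeneCall] = field(default_factory=list)


def split_gene(gene: RnaSequence, window_len: int, step: int) -> list[Window]:
    """Overlapping windows covering every base of the gene.

    Offsets run 0, step, 2*step, ...; when the last stride overshoots, a
    final window is anchored at ``len(gene) - window_len``.  A gene shorter
    than one window yields a single right-N-padded window at offset 0.
    """
    if len(gene.residues) == 0:
        raise ScanError("empty gene")
    if not 0 < step < window_len:
        raise ScanError(f"step must be in (0, window_len); got {step} vs {window_len}")
    seq = gene.residues
    if len(seq) <= window_len:
        padded = pad_sequence(gene, window_len)
        return [Window(0, padded.residues)]
    offsets = list(range(0, len(seq) - window_len + 1, step))
    if offsets[-1] + window_len < len(seq):
        offsets.append(len(seq) - window_len)
    return [Window(off, seq[off : off + window_len]) for off in offsets]


def predict_sites(
    net: Network,
    schema: PairSchema,
    mirna: RnaSequence,
    windows: list[Window],
    gene_id: str,
    mirna_id: str = "mirna",
    threshold: float = 0.5,
) -> list[WindowCall]:
    """Score each window once against the (5'->3') query miRNA."""
    if not windows:
        return []
    wlen = len(windows[0].sequence)
    if wlen != schema.site_slot_len:
        raise ScanError(
            f"window length {wlen} does not match the model's site slot "
            f"{schema.site_slot_len}"
        )
    X = np.stack(
        [
            encode_pair(
                LabeledPair(
                    mirna=mirna,
                    site=RnaSequence(w.sequence, Orientation.FIVE_TO_THREE),
                    label=0,
                    pair_id=f"{gene_id}@{w.offset}",
                ),
                schema,
            ).codes
            for w in windows
        ]
    )
    probs = net.predict(X)
    return [
        WindowCall(
            gene_id=gene_id,
            mirna_id=mirna_id,
            offset=w.offset,
            sequence=w.sequence,
            probability=float(p),
            call=bool(p >= threshold),
        )
        for w, p in zip(windows, probs)
    ]


def call_genes(window_calls: list[WindowCall], min_sites_per_gene: int = 1
               ) -> list[GeneCall]:
    """Per (gene, miRNA): target iff positive-window count >= min_sites_per_gene."""
    groups: dict[tuple[str, str], list[WindowCall]] = {}
    for wc in window_calls:
        groups.setdefault((wc.gene_id, wc.mirna_id), []).append(wc)
    out = []
    for (gene_id, mirna_id), calls in groups.items():
        n_pos = sum(1 for c in calls if c.call)
        out.append(
            GeneCall(
                gene_id=gene_id,
                mirna_id=mirna_id,
                n_windows=len(calls),
                n_positive_sites=n_pos,
                is_target=n_pos >= min_sites_per_gene,
            )
        )
    return out


def scan_genes(
    net: Network,
    schema: PairSchema,
    mirnas: list[tuple[str, str]],
    genes: list[tuple[str, str]],
    config: ScanConfig = ScanConfig(),
) -> ScanResult:
    """Scan every miRNA against every gene (both given as (id, 5'->3' seq))."""
    from .codec import normalize_sequence

    window_len = schema.site_slot_len
    step = config.step if config.step is not None else max(1, window_len // 2)
    result = ScanResult()
    for gene_id, gene_seq in genes:
        windows = split_gene(normalize_sequence(gene_seq), window_len, step)
        for mirna_id, mirna_seq in mirnas:
            calls = predict_sites(
                net, schema, normalize_sequence(mirna_seq), windows,
                gene_id=gene_id, mirna_id=mirna_id,
                threshold=config.site_prob_threshold,
            )
            result.windows.extend(calls)
    result.genes = call_genes(result.windows, config.min_sites_per_gene)
    return result


def write_site_fasta(result: ScanResult, path: str | Path) -> int:
    """One FASTA record per positive window; returns the record count.

    Headers are ``<gene_id>|<mirna_id>|offset=<n>|prob=<p>``.  Zero positive
    windows produce an empty (but valid) FASTA file.
    """
    records = [
        (
            f"{wc.gene_id}|{wc.mirna_id}|offset={wc.offset}|prob={wc.probability:.4f}",
            wc.sequence,
        )
        for wc in result.windows
        if wc.call
    ]
    try:
        write_fasta(records, path)
    except OSError as exc:
        raise ScanError(f"cannot write site FASTA to {path}: {exc}") from exc
    return len(records)


def write_scan_table(result: ScanResult, path: str | Path) -> None:
    """Delimited output with a per-window section and a per-gene section."""
    with open(path, "w") as fh:
        fh.write("# windows\ngene_id\tmirna_id\toffset\tprobability\tcall\n")
        for wc in result.windows:
            fh.write(
                f"{wc.gene_id}\t{wc.mirna_id}\t{wc.offset}\t"
                f"{wc.probability:.6f}\t{int(wc.call)}\n"
            )
        fh.write("# genes\ngene_id\tmirna_id\tn_windows\tn_positive_sites\tis_target\n")
        for gc in result.genes:
            fh.write(
                f"{gc.gene_id}\t{gc.mirna_id}\t{gc.n_windows}\t"
                f"{gc.n_positive_sites}\t{int(gc.is_target)}\n"
            )
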