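"""File readers/writers: FASTA sequences and delimited pair tables.

The pair-table format is a tab- or comma-separated file with the columns
``mirna_id``, ``mirna_seq``, ``site_seq`` and ``label`` (0/1).  Sequences are
normalized on load (case folding, T->U) and a note is logged once per file
when normalization changed anything.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codec import LabeledPair, normalize_sequence

logger = logging.getLogger(__name__)

PAIR_TABLE_COLUMNS = ["mirna_id", "mirna_seq", "site_seq", "label"]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(record_id, normalized_sequence)`` tuples."""
    records = []
    changed = False
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        seq = normalize_sequence(raw)
        changed = changed or seq.residues != raw
        records.append((rec.id, seq.residues))
    if changed:
        logger.info("normalized sequences (case/T->U) while reading %s", path)
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_pair_table(path: str | Path) -> list[LabeledPair]:
    """Load a delimited miRNA:site pair table into :class:`LabeledPair` objects."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in PAIR_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pair table {path} lacks columns: {missing}")
    pairs = []
    changed = False
    for row in df.itertuples(index=False):
        mirna = normalize_sequence(str(row.mirna_seq))
        site = normalize_sequence(str(row.site_seq))
        changed = changed or (
            mirna.residues != row.mirna_seq or site.residues != row.site_seq
        )
        pairs.append(
            LabeledPair(mirna=mirna, site=site, label=int(row.label),
                        pair_id=str(row.mirna_id))
        )
    if changed:
        logger.info("normalized sequences (case/T->U) while reading %s", path)
    return pairs


def write_pair_table(pairs: list[LabeledPair], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "mirna_id": [p.pair_id for p in pairs],
            "mirna_seq": [p.mirna.residues for p in pairs],
            "site_seq": [p.site.residues for p in pairs],
            "label": [p.label for p in pairs],
        }
    )
    df.to_csv(path, sep="\t", index=False)
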