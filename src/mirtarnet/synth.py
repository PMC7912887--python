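"""Synthetic miRNA:target-site datasets with planted seed complementarity.

Positives carry, at a random offset inside the site, the reverse Watson-Crick
complement of the miRNA seed region (positions 2-7 or 3-8, 1-based on the
5'->3' miRNA).  Non-canonical positives relax the pairing with G-U wobbles
and/or at most one bulged or mismatched nucleotide.  Negatives reuse a
positive-style site but shuffle the miRNA, so the pairing relation — not the
marginal composition — separates the classes.  Provenance recorded per pair
makes every planted structure independently verifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .codec import LabeledPair, Orientation, RnaSequence

BASES = "AUGC"
WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
#: x pairs y if y == WC[x], or (gu) x=G,y=U / x=U,y=G.
GU = {"G": "U", "U": "G"}

REGIONS = {"canonical_2_7": (2, 7), "canonical_3_8": (3, 8)}
MODES = ("canonical_2_7", "canonical_3_8", "noncanonical")


class SynthError(ValueError):
    pass


class HomopolymerError(SynthError):
    """A single-letter miRNA cannot be shuffled into a distinct sequence."""


@dataclass(frozen=True)
class SynthConfig:
    n_pos: int = 100
    n_neg: int = 100
    mirna_len_range: tuple[int, int] = (19, 26)
    site_len: int = 40
    #: None -> per-pair mixture from mode_weights; otherwise a single fixed mode.
    seed_mode: Optional[str] = None
    mode_weights: dict = field(
        default_factory=lambda: {
            "canonical_2_7": 0.35,
            "canonical_3_8": 0.35,
            "noncanonical": 0.30,
        }
    )
    gu_allowed: bool = True
    max_bulge_or_mismatch: int = 1
    #: Size of the recurring miRNA pool (mimics real mature-miRNA reuse);
    #: None draws a fresh miRNA for every pair.
    n_mirnas: Optional[int] = 16
    #: 'shuffle' permutes the miRNA (site kept); 'mismatch' swaps in a
    #: different pool miRNA whose seed does not pair the planted segment;
    #: 'random_site' keeps the miRNA and draws a seed-free random site,
    #: which trains a motif-driven site detector (used for gene scanning).
    negative_mode: str = "shuffle"
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_pos <= 0 or self.n_neg <= 0:
            raise SynthError("class counts must be positive")
        lo, hi = self.mirna_len_range
        if not (0 < lo <= hi):
            raise SynthError(f"bad miRNA length range {self.mirna_len_range}")
        if self.site_len < 10:
            raise SynthError("site too short to plant a seed with flanks")
        if self.seed_mode is not None and self.seed_mode not in MODES:
            raise SynthError(f"unknown seed_mode {self.seed_mode!r}")
        for m in self.mode_weights:
            if m not in MODES:
                raise SynthError(f"unknown mode {m!r} in mode_weights")
        if self.negative_mode not in ("shuffle", "mismatch", "random_site"):
            raise SynthError(f"unknown negative_mode {self.negative_mode!r}")
        if self.negative_mode == "mismatch" and (self.n_mirnas or 0) < 2:
            raise SynthError("mismatch negatives need a miRNA pool of >= 2")


@dataclass(frozen=True)
class SynthPair:
    pair: LabeledPair
    provenance: dict


def revcomp_rna(seq: str) -> str:
    return "".join(WC[c] for c in reversed(seq))


def pairs_with(mirna_base: str, site_base: str, gu_allowed: bool = True) -> bool:
    """True when the two bases can hybridize (WC, optionally G-U wobble)."""
    if WC[mirna_base] == site_base:
        return True
    return gu_allowed and GU.get(mirna_base) == site_base


def random_mirna(rng: np.random.Generator,
                 len_range: tuple[int, int] = (19, 26)) -> RnaSequence:
    """Uniform-composition miRNA with length drawn from ``len_range``."""
    length = int(rng.integers(len_range[0], len_range[1] + 1))
    residues = "".join(rng.choice(list(BASES), size=length))
    return RnaSequence(residues, Orientation.FIVE_TO_THREE)


def _random_flank(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n)) if n > 0 else ""


def _wobble(seed: str, planted: list[str], rng) -> list[int]:
    """Swap eligible planted positions to G-U wobble pairing; returns indices.

    planted[k] faces seed base seed[-1 - k] (the segment is reversed).
    """
    eligible = [k for k in range(len(planted)) if seed[len(seed) - 1 - k] in GU]
    if not eligible:
        return []
    n_swap = int(rng.integers(1, len(eligible) + 1))
    chosen = sorted(rng.choice(eligible, size=n_swap, replace=False).tolist())
    for k in chosen:
        planted[k] = GU[seed[len(seed) - 1 - k]]
    return chosen


def plant_site(
    mirna: RnaSequence,
    site_len: int,
    mode: str,
    rng: np.random.Generator,
    gu_allowed: bool = True,
    max_bulge_or_mismatch: int = 1,
) -> tuple[RnaSequence, dict]:
    """Build a site containing a seed-complementary segment; returns provenance."""
    if mode not in MODES:
        raise SynthError(f"unknown mode {mode!r}")
    if mode == "noncanonical":
        region_name = str(rng.choice(["canonical_2_7", "canonical_3_8"]))
    else:
        region_name = mode
    start, end = REGIONS[region_name]  # 1-based inclusive on the 5'->3' miRNA
    if len(mirna) < end:
        raise SynthError(f"miRNA of length {len(mirna)} lacks positions {start}-{end}")
    seed = mirna.residues[start - 1 : end]
    planted = list(revcomp_rna(seed))
    perturbation = None
    perturbed: list[int] = []

    if mode == "noncanonical":
        options = ["mismatch", "bulge"] if max_bulge_or_mismatch > 0 else []
        if gu_allowed:
            options.append("gu")
        if not options:
            raise SynthError("noncanonical mode with no perturbation allowed")
        perturbation = str(rng.choice(options))
        if perturbation == "gu":
            perturbed = _wobble(seed, planted, rng)
            if not perturbed:  # seed had no G/U to wobble
                perturbation = "mismatch"
        if perturbation == "mismatch":
            k = int(rng.integers(0, len(planted)))
            facing = seed[len(seed) - 1 - k]
            choices = [b for b in BASES if not pairs_with(facing, b, gu_allowed=True)]
            planted[k] = str(rng.choice(choices))
            perturbed = [k]
        elif perturbation == "bulge":
            k = int(rng.integers(1, len(planted)))  # interior insertion
            planted.insert(k, str(rng.choice(list(BASES))))
            perturbed = [k]

    segment = "".join(planted)
    if len(segment) > site_len:
        raise SynthError(
            f"site length {site_len} too short for a {len(segment)}-nt planted segment"
        )
    offset = int(rng.integers(0, site_len - len(segment) + 1))
    residues = (
        _random_flank(rng, offset)
        + segment
        + _random_flank(rng, site_len - offset - len(segment))
    )
    provenance = {
        "mode": mode,
        "region": region_name,
        "mirna_positions": (start, end),
        "offset": offset,
        "planted_seq": segment,
        "perturbation": perturbation,
        "perturbed_positions": perturbed,
    }
    return RnaSequence(residues, Orientation.FIVE_TO_THREE), provenance


def verify_planted(sp: SynthPair) -> bool:
    """Check the recorded planted structure against the actual sequences."""
    prov = sp.provenance
    mirna, site = sp.pair.mirna.residues, sp.pair.site.residues
    seg = prov["planted_seq"]
    off = prov["offset"]
    if site[off : off + len(seg)] != seg:
        return False
    start, end = prov["mirna_positions"]
    seed = mirna[start - 1 : end]
    if prov["mode"] != "noncanonical":
        return seg == revcomp_rna(seed)
    aligned = list(seg)
    if prov["perturbation"] == "bulge":
        if len(aligned) != len(seed) + 1:
            return False
        del aligned[prov["perturbed_positions"][0]]
    if len(aligned) != len(seed):
        return False
    bad = sum(
        0 if pairs_with(seed[len(seed) - 1 - k], aligned[k]) else 1
        for k in range(len(aligned))
    )
    return bad <= (0 if prov["perturbation"] in ("gu", "bulge") else 1)


def make_negative(positive: SynthPair, rng: np.random.Generator) -> SynthPair:
    """Shuffle the miRNA (site kept) to break the planted pairing relation."""
    if positive.pair.label != 1:
        raise SynthError("make_negative expects a positive pair")
    residues = positive.pair.mirna.residues
    if len(set(residues)) < 2:
        raise HomopolymerError(f"cannot shuffle homopolymer miRNA {residues!r}")
    arr = np.frombuffer(residues.encode(), dtype="S1")
    while True:
        perm = rng.permutation(len(arr))
        shuffled = b"".join(arr[perm]).decode()
        if shuffled != residues:
            break
    provenance = {
        **positive.provenance,
        "shuffle_permutation": perm.tolist(),
        "source_mirna": residues,
    }
    pair = LabeledPair(
        mirna=RnaSequence(shuffled, Orientation.FIVE_TO_THREE),
        site=positive.pair.site,
        label=0,
        pair_id=positive.pair.pair_id + "_shuf",
    )
    return SynthPair(pair, provenance)


def make_mismatch_negative(
    positive: SynthPair, pool: list[RnaSequence], rng: np.random.Generator
) -> SynthPair:
    """Swap in a different pool miRNA whose seed does not pair the site."""
    if positive.pair.label != 1:
        raise SynthError("make_mismatch_negative expects a positive pair")
    start, end = positive.provenance["mirna_positions"]
    seg = positive.provenance["planted_seq"]
    off = positive.provenance["offset"]
    candidates = [m for m in pool if m.residues != positive.pair.mirna.residues]
    order = rng.permutation(len(candidates))
    for i in order:
        other = candidates[i]
        if len(other) < end:
            continue
        seed = other.residues[start - 1 : end]
        aligned = seg if len(seg) == len(seed) else seg[: len(seed)]
        ok_pairs = sum(
            1 if pairs_with(seed[len(seed) - 1 - k], aligned[k]) else 0
            for k in range(len(aligned))
        )
        if ok_pairs <= len(aligned) - 2:  # clearly non-pairing substitute
            pair = LabeledPair(
                mirna=other,
                site=positive.pair.site,
                label=0,
                pair_id=positive.pair.pair_id + "_swap",
            )
            provenance = {
                **positive.provenance,
                "source_mirna": positive.pair.mirna.residues,
                "swap_offset": off,
            }
            return SynthPair(pair, provenance)
    raise SynthError("no pool miRNA with a non-pairing seed found")


def make_random_site_negative(
    positive: SynthPair, rng: np.random.Generator, max_tries: int = 100
) -> SynthPair:
    """Keep the miRNA, replace the site by one with no exact seed complement."""
    if positive.pair.label != 1:
        raise SynthError("make_random_site_negative expects a positive pair")
    mirna = positive.pair.mirna.residues
    site_len = len(positive.pair.site)
    motifs = [
        revcomp_rna(mirna[s - 1 : e]) for s, e in REGIONS.values() if len(mirna) >= e
    ]
    for _ in range(max_tries):
        site = _random_flank(rng, site_len)
        if not any(m in site for m in motifs):
            provenance = {**positive.provenance, "mode": "random_site",
                          "perturbation": None, "offset": -1, "planted_seq": ""}
            pair = LabeledPair(
                mirna=positive.pair.mirna,
                site=RnaSequence(site, Orientation.FIVE_TO_THREE),
                label=0,
                pair_id=positive.pair.pair_id + "_rand",
            )
            return SynthPair(pair, provenance)
    raise SynthError("could not draw a seed-free random site")


def generate_dataset(cfg: SynthConfig) -> list[SynthPair]:
    """n_pos positives + n_neg negatives, shuffled, seed-reproducible."""
    rng = np.random.default_rng(cfg.rng_seed)
    if cfg.seed_mode is not None:
        modes, weights = [cfg.seed_mode], np.array([1.0])
    else:
        modes = list(cfg.mode_weights)
        weights = np.array([cfg.mode_weights[m] for m in modes], dtype=float)
        weights = weights / weights.sum()
    pool = (
        [random_mirna(rng, cfg.mirna_len_range) for _ in range(cfg.n_mirnas)]
        if cfg.n_mirnas
        else None
    )

    def _positive(idx: int) -> SynthPair:
        mirna = pool[int(rng.integers(len(pool)))] if pool else random_mirna(
            rng, cfg.mirna_len_range
        )
        mode = str(rng.choice(modes, p=weights))
        site, prov = plant_site(
            mirna, cfg.site_len, mode, rng,
            gu_allowed=cfg.gu_allowed,
            max_bulge_or_mismatch=cfg.max_bulge_or_mismatch,
        )
        pair = LabeledPair(mirna=mirna, site=site, label=1, pair_id=f"syn_{idx:05d}")
        return SynthPair(pair, prov)

    positives = [_positive(i) for i in range(cfg.n_pos)]
    if cfg.negative_mode == "shuffle":
        negatives = [make_negative(_positive(cfg.n_pos + i), rng)
                     for i in range(cfg.n_neg)]
    elif cfg.negative_mode == "mismatch":
        negatives = [make_mismatch_negative(_positive(cfg.n_pos + i), pool, rng)
                     for i in range(cfg.n_neg)]
    else:
        negatives = [make_random_site_negative(_positive(cfg.n_pos + i), rng)
                     for i in range(cfg.n_neg)]
    dataset = positives + negatives
    order = rng.permutation(len(dataset))
    return [dataset[i] for i in order]


def as_labeled_pairs(dataset: list[SynthPair]) -> list[LabeledPair]:
    return [sp.pair for sp in dataset]
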