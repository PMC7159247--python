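"""Fragment sampling from reference sequence sets.

Training data consists of fixed-length fragments drawn from labeled
reference sequences.  Random sampling draws fragments with replacement,
uniformly over all possible fragment positions across the eligible
references (a reference is chosen with probability proportional to the
number of start positions it offers).  Tiling produces overlapping
fragments with stride L/2 that cover a reference end to end, used for
held-out evaluation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from plasq.fasta_io import SeqRecord

logger = logging.getLogger(__name__)

PLASMID = "plasmid"
CHROMOSOME = "chromosome"

# canonical training fragment lengths (bp) and the model dispatch they feed
TRAIN_LENGTHS = (1000, 10000, 100000, 500000)


@dataclass
class Fragment:
    """A fixed-length subsequence with provenance."""

    sequence: str
    label: str
    source_id: str
    start: int

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TrainingConfig:
    """Parameters of length-binned training.

    ``n_short`` fragments per class are drawn for the 1 kb and 10 kb bins;
    for the 100 kb and 500 kb bins the plasmid fragment count is derived
    from ``depth_long``-fold coverage of the sufficiently long plasmids,
    and the chromosome class is sampled to match it.
    """

    lengths: tuple[int, ...] = TRAIN_LENGTHS
    n_short: int = 90000
    depth_long: float = 5.0
    seed: int = 0
    k_min: int = 3
    k_max: int = 7
    reg_strength: float = 1.0
    max_ambiguous_frac: float = 0.5
    reference_weighting: str = "fragment"  # or "reference"


def _eligible(refs: Sequence[SeqRecord], L: int) -> list[SeqRecord]:
    return [r for r in refs if len(r) >= L]


def sample_fragments(
    refs: Sequence[SeqRecord],
    L: int,
    n: int,
    seed: int,
    label: str = PLASMID,
    weighting: str = "fragment",
    max_ambiguous_frac: float = 1.0,
) -> list[Fragment]:
    """Draw ``n`` fragments of length ``L`` i.i.d. with replacement.

    With ``weighting="fragment"`` (default) a reference is chosen with
    probability proportional to ``len - L + 1`` over references of length
    >= L, making the draw uniform over every possible fragment; with
    ``"reference"`` eligible references are chosen uniformly.  The start
    offset is uniform in ``[0, len - L]``.  Deterministic given ``seed``.

    Fragments whose ambiguous-character fraction exceeds
    ``max_ambiguous_frac`` are redrawn (bounded retries), keeping moderate
    runs of N while rejecting mostly-ambiguous fragments.
    """
    eligible = _eligible(refs, L)
    if not eligible:
        max_len = max((len(r) for r in refs), default=0)
        raise ValueError(
            f"no reference of length >= {L} (longest available: {max_len} bp)"
        )
    rng = np.random.default_rng(seed)
    if weighting == "fragment":
        weights = np.array([len(r) - L + 1 for r in eligible], dtype=np.float64)
    elif weighting == "reference":
        weights = np.ones(len(eligible), dtype=np.float64)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    p = weights / weights.sum()
    out: list[Fragment] = []
    attempts = 0
    max_attempts = 20 * n + 100
    while len(out) < n:
        want = n - len(out)
        idx = rng.choice(len(eligible), size=want, p=p)
        for i in idx:
            attempts += 1
            ref = eligible[i]
            start = int(rng.integers(0, len(ref) - L + 1))
            seq = ref.sequence[start : start + L]
            if max_ambiguous_frac < 1.0 and attempts <= max_attempts:
                n_ambig = sum(1 for c in seq if c not in "ACGT")
                if n_ambig / L > max_ambiguous_frac:
                    continue
            out.append(Fragment(sequence=seq, label=label, source_id=ref.id, start=start))
    return out


def depth_fragment_count(refs: Sequence[SeqRecord], L: int, depth: float) -> int:
    """Fragments of length ``L`` needed to cover eligible references.

    Returns ``ceil(depth * sum(len_i for len_i >= L) / L)``; 0 when no
    reference is at least L long.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    total = sum(len(r) for r in refs if len(r) >= L)
    if total == 0:
        return 0
    return math.ceil(depth * total / L)


def tile_fragments(refs: Sequence[SeqRecord], L: int, label: str = PLASMID) -> list[Fragment]:
    """Overlapping fragments of length ``L`` with stride L/2 covering each reference.

    Starts run 0, L/2, 2*(L/2), ... while ``start <= len - L``; a final
    end-anchored fragment at ``start = len - L`` is added when the strided
    walk does not already land there, so every base of each eligible
    reference is covered.  References shorter than L are skipped and the
    skip count logged.
    """
    stride = max(L // 2, 1)
    out: list[Fragment] = []
    skipped = 0
    for ref in refs:
        if len(ref) < L:
            skipped += 1
            continue
        last = len(ref) - L
        starts = list(range(0, last + 1, stride))
        if starts[-1] != last:
            starts.append(last)
        for s in starts:
            out.append(
                Fragment(sequence=ref.sequence[s : s + L], label=label, source_id=ref.id, start=s)
            )
    if skipped:
        logger.info("tile_fragments: skipped %d reference(s) shorter than %d bp", skipped, L)
    return out


def split_references(
    refs: Sequence[SeqRecord],
    holdout_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Partition references into (training, held-out) sets.

    The split is by reference, never by fragment, so no evaluation
    fragment shares a source sequence with training.  At least one
    reference is held out whenever ``holdout_fraction > 0`` and there are
    two or more references.
    """
    if not 0 <= holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in [0, 1)")
    refs = list(refs)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(refs))
    n_hold = int(round(holdout_fraction * len(refs)))
    if holdout_fraction > 0 and n_hold == 0 and len(refs) >= 2:
        n_hold = 1
    hold_idx = set(order[:n_hold].tolist())
    train = [refs[i] for i in range(len(refs)) if i not in hold_idx]
    hold = [refs[i] for i in range(len(refs)) if i in hold_idx]
    return train, hold


def write_fragment_manifest(fragments: Sequence[Fragment], path: str) -> None:
    """Audit TSV: source_id, start, length, label."""
    with open(path, "w") as fh:
        fh.write("source_id\tstart\tlength\tlabel\n")
        for f in fragments:
            fh.write(f"{f.source_id}\t{f.start}\t{len(f)}\t{f.label}\n")
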