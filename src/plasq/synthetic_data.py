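"""Synthetic reference sets and simulated communities.

Real plasmid/chromosome reference databases are large downloads; this
module generates compositionally distinct stand-ins so that training,
classification and evaluation run end to end on a desk machine.  Two
Markov sequence sources — one per class — are separated by a single
``divergence`` knob: at 0 the sources are identical (no signal, a null
benchmark), at 1 they differ in GC content (roughly 0.65 vs 0.35) and in
dinucleotide texture.

The community model mirrors how real metagenomes are skewed: genome
relative abundances are log-normal (normalized to sum to 1), and each
plasmid carries an integer copy number drawn from a geometric
distribution on {1, 2, ...} with success parameter p = min(1,
log10(L) / 7) for a plasmid of length L bp — long plasmids are almost
always single-copy while short ones can be multi-copy.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from plasq.fasta_io import SeqRecord
from plasq.training import CHROMOSOME, PLASMID, Fragment

_BASES = "ACGT"
# log-weight sign pattern pushing composition toward G+C
_GC_SIGN = np.array([-1.0, 1.0, 1.0, -1.0])  # A, C, G, T


@dataclass
class MarkovSource:
    """An order-m Markov chain over {A, C, G, T}.

    ``transition`` has shape (4**order, 4); row ``c`` is the distribution
    of the next base given the 2-bit-packed context ``c`` (for order 0 a
    single row: the base composition).
    """

    order: int
    transition: np.ndarray

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=np.float64)
        if self.order < 0:
            raise ValueError("order must be >= 0")
        expected = (4**self.order, 4)
        if self.transition.shape != expected:
            raise ValueError(
                f"transition table shape {self.transition.shape}, expected {expected}"
            )
        sums = self.transition.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each context's next-base probabilities must sum to 1")
        if (self.transition < 0).any():
            raise ValueError("transition probabilities must be non-negative")

    @classmethod
    def from_gc(cls, gc: float, order: int = 0) -> "MarkovSource":
        """I.i.d. source with the given GC fraction (AT and GC split evenly)."""
        if not 0 <= gc <= 1:
            raise ValueError("gc must be in [0, 1]")
        row = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        return cls(order=order, transition=np.tile(row, (4**order, 1)))


def class_source(label: str, divergence: float) -> MarkovSource:
    """The canonical order-1 source for one class at a given divergence.

    Log-weights combine a GC shift of +-0.31 * divergence (GC ~0.65 for
    plasmids, ~0.35 for chromosomes at divergence 1) with a fixed
    class-specific dinucleotide signature scaled by the same divergence.
    At divergence 0 both classes reduce to the uniform i.i.d. source.
    """
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must be in [0, 1]")
    if label == PLASMID:
        sign, sig_seed = 1.0, 101
    elif label == CHROMOSOME:
        sign, sig_seed = -1.0, 202
    else:
        raise ValueError(f"unknown class label {label!r}")
    signature = np.random.default_rng(sig_seed).standard_normal((4, 4))
    logw = (
        sign * 0.31 * divergence * _GC_SIGN[None, :]
        + 0.25 * divergence * signature
    )
    table = np.exp(logw)
    table /= table.sum(axis=1, keepdims=True)
    return MarkovSource(order=1, transition=table)


def generate_sequence(
    source: MarkovSource,
    length: int,
    seed: int,
    id: str = "seq",
) -> SeqRecord:
    """Sample a sequence of exactly ``length`` bases from the chain.

    The initial context is drawn uniformly.  Deterministic given ``seed``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(source.transition, axis=1)
    cum[:, -1] = 1.0  # guard against rounding
    u = rng.random(length)
    out = np.empty(length, dtype=np.uint8)
    n_ctx = source.transition.shape[0]
    ctx_mask = n_ctx - 1
    ctx = int(rng.integers(0, n_ctx))
    for i in range(length):
        row = cum[ctx]
        r = u[i]
        b = 0
        while row[b] < r:
            b += 1
        out[i] = b
        ctx = ((ctx << 2) | b) & ctx_mask
    seq = "".join(_BASES[b] for b in out)
    return SeqRecord(id=id, sequence=seq)


def _log_uniform_lengths(
    rng: np.random.Generator, n: int, lo: int, hi: int
) -> np.ndarray:
    if not (0 < lo <= hi):
        raise ValueError(f"invalid length range ({lo}, {hi})")
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=n)).astype(int)


def make_benchmark_refs(
    n_plasmid: int = 40,
    n_chrom: int = 10,
    plasmid_len_range: tuple[int, int] = (500, 54000),
    chrom_len_range: tuple[int, int] = (10000, 140000),
    divergence: float = 0.8,
    seed: int = 0,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Generate labeled plasmid and chromosome reference sets.

    Per-reference lengths are log-uniform in the given ranges.  The
    defaults echo real databases (plasmid median ~54 kb, chromosome
    median ~3.7 Mb) scaled down for desk use — plasmids 10x shorter,
    chromosomes 100x — preserving the property that chromosomes are far
    longer than plasmids while keeping the 10 kb model bin trainable.
    """
    rng = np.random.default_rng(seed)
    plas_src = class_source(PLASMID, divergence)
    chrom_src = class_source(CHROMOSOME, divergence)
    plasmids: list[SeqRecord] = []
    for i, L in enumerate(_log_uniform_lengths(rng, n_plasmid, *plasmid_len_range)):
        plasmids.append(
            generate_sequence(
                plas_src, int(L), seed=int(rng.integers(0, 2**31)), id=f"plasmid_{i:04d}"
            )
        )
    chroms: list[SeqRecord] = []
    for i, L in enumerate(_log_uniform_lengths(rng, n_chrom, *chrom_len_range)):
        chroms.append(
            generate_sequence(
                chrom_src, int(L), seed=int(rng.integers(0, 2**31)), id=f"chromosome_{i:04d}"
            )
        )
    return plasmids, chroms


def copy_number_p(length: int, log_base: float = 10.0) -> float:
    """Geometric success parameter for a plasmid of the given length.

    p = min(1, log10(L) / 7) by default; the expected copy number 1/p is
    therefore non-increasing in plasmid length and hits exactly 1 (p = 1)
    at 10 Mb.
    """
    if length < 1:
        raise ValueError("plasmid length must be >= 1")
    return min(1.0, math.log(max(length, 2), log_base) / 7)


@dataclass
class CommunityMember:
    chromosome: SeqRecord
    abundance: float
    plasmids: list[tuple[SeqRecord, int]] = field(default_factory=list)


@dataclass
class SimulatedCommunity:
    """Genomes with relative abundances and per-plasmid copy numbers."""

    members: list[CommunityMember]

    @property
    def abundances(self) -> np.ndarray:
        return np.array([m.abundance for m in self.members])

    def write_manifest(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("genome_id\tabundance\tplasmid_id\tlength\tcopy_number\n")
            for m in self.members:
                if not m.plasmids:
                    fh.write(f"{m.chromosome.id}\t{m.abundance:.6g}\t-\t-\t-\n")
                for p, c in m.plasmids:
                    fh.write(
                        f"{m.chromosome.id}\t{m.abundance:.6g}\t{p.id}\t{len(p)}\t{c}\n"
                    )


def simulate_community(
    chromosomes: Sequence[SeqRecord],
    plasmids: Sequence[SeqRecord],
    sigma: float = 1.0,
    seed: int = 0,
    copy_log_base: float = 10.0,
) -> SimulatedCommunity:
    """Assemble a community from reference sequences.

    Genome abundances are exp(N(0, sigma^2)) normalized to sum to 1.
    Each plasmid is attached to a uniformly random genome and draws a
    copy number from Geometric(p) on {1, 2, ...} with
    p = min(1, log10(L)/7).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not chromosomes:
        raise ValueError("community needs at least one genome")
    rng = np.random.default_rng(seed)
    raw = np.exp(rng.normal(0.0, sigma, size=len(chromosomes)))
    ab = raw / raw.sum()
    members = [
        CommunityMember(chromosome=c, abundance=float(a))
        for c, a in zip(chromosomes, ab)
    ]
    for p in plasmids:
        host = int(rng.integers(0, len(members)))
        prob = copy_number_p(len(p), log_base=copy_log_base)
        copies = int(rng.geometric(prob))
        members[host].plasmids.append((p, copies))
    return SimulatedCommunity(members=members)


def fragment_community(
    community: SimulatedCommunity,
    n_fragments: int = 2000,
    length_range: tuple[int, int] = (200, 50000),
    seed: int = 0,
) -> list[Fragment]:
    """Emit contig-like labeled fragments from a community.

    Expected per-source fragment counts are proportional to
    abundance x copy_number x source length (copy number 1 for
    chromosomes).  Fragment lengths are log-uniform in ``length_range``
    (clamped to the source length), skewing the output short the way
    assembled metagenome contigs are.  Labels carry the source class.
    """
    lo, hi = length_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    sources: list[tuple[SeqRecord, str, float]] = []
    for m in community.members:
        sources.append((m.chromosome, CHROMOSOME, m.abundance * len(m.chromosome)))
        for p, copies in m.plasmids:
            sources.append((p, PLASMID, m.abundance * copies * len(p)))
    weights = np.array([w for _, _, w in sources])
    counts = rng.multinomial(n_fragments, weights / weights.sum())
    out: list[Fragment] = []
    for (rec, label, _), cnt in zip(sources, counts):
        if cnt == 0:
            continue
        src_len = len(rec)
        f_lo = min(lo, src_len)
        f_hi = min(hi, src_len)
        lengths = np.exp(
            rng.uniform(math.log(f_lo), math.log(f_hi), size=cnt)
        ).astype(int)
        lengths = np.clip(lengths, 1, src_len)
        for L in lengths:
            start = int(rng.integers(0, src_len - int(L) + 1))
            out.append(
                Fragment(
                    sequence=rec.sequence[start : start + int(L)],
                    label=label,
                    source_id=rec.id,
                    start=start,
                )
            )
    return out


def default_community(seed: int = 0, sigma: float = 1.0) -> SimulatedCommunity:
    """A small community with realistic plasmid/chromosome imbalance.

    Ten chromosomes (10-140 kb) host fifteen plasmids (0.5-20 kb), so the
    plasmid fraction of community DNA stays well below the chromosomal
    fraction, as in real metagenomes.
    """
    plasmids, chroms = make_benchmark_refs(
        n_plasmid=15,
        n_chrom=10,
        plasmid_len_range=(500, 20000),
        chrom_len_range=(10000, 140000),
        divergence=0.8,
        seed=seed,
    )
    return simulate_community(chroms, plasmids, sigma=sigma, seed=seed + 1)
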