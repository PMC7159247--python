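"""FASTA input and tab-separated result output.

Sequences are stored uppercase; any character outside {A, C, G, T} is
treated as ambiguous downstream.  Records with empty sequences are skipped
with a warning rather than passed on, so every record reaching the
featurizer has at least one base.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)


@dataclass
class SeqRecord:
    """A named nucleotide sequence.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    ``description`` is the full header line without the leading ``>``.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.description:
            self.description = self.id

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord` in file order.

    Lowercase bases are uppercased.  Records with empty sequences are
    skipped with a logged warning.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the first non-blank line is not a FASTA header.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"FASTA file not found: {path}")
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: not FASTA-formatted "
                        f"(first non-blank line does not start with '>')"
                    )
                break
    records: list[SeqRecord] = []
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            logger.warning("skipping empty record %r in %s", rec.id, path)
            continue
        records.append(SeqRecord(id=rec.id, sequence=seq, description=rec.description))
    return records


def iter_fasta(path: str | os.PathLike) -> Iterator[SeqRecord]:
    """Streaming variant of :func:`read_fasta` (same skipping rules)."""
    yield from read_fasta(path)


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.description}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_results(
    results: Sequence,
    path: str | os.PathLike,
    header: bool = False,
) -> None:
    """Write per-sequence plasmid probabilities as a two-column TSV.

    One line per sequence, ``<id>\\t<probability>``, probability printed
    with 4 decimal places, in the given (input) order.  ``results`` may be
    ``ClassificationResult`` objects or plain ``(id, probability)`` pairs.
    """
    with open(path, "w") as fh:
        if header:
            fh.write("id\tprobability\n")
        for item in results:
            if hasattr(item, "probability"):
                seq_id, prob = item.id, item.probability
            else:
                seq_id, prob = item
            fh.write(f"{seq_id}\t{prob:.4f}\n")
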