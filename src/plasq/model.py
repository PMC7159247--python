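"""Length-binned logistic-regression classification.

Four binary logistic models are trained on canonical k-mer frequency
vectors of fragments of fixed lengths 1 kb, 10 kb, 100 kb and 500 kb.  A
query sequence is routed to the model whose training length is nearest to
the query length, equivalently into one of four half-open-left length
ranges: (0, 5.5 kb], (5.5 kb, 55 kb], (55 kb, 300 kb], (300 kb, inf).
The positive class is "plasmid"; a sequence is labeled plasmid when its
predicted plasmid probability exceeds the threshold (default 0.5; a
probability of exactly 0.5 is labeled chromosome).
"""

from __future__ import annotations

import io
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from plasq.fasta_io import SeqRecord
from plasq.kmer_features import KmerIndex, featurize_batch
from plasq.training import (
    CHROMOSOME,
    PLASMID,
    TRAIN_LENGTHS,
    TrainingConfig,
    depth_fragment_count,
    sample_fragments,
)

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1

#: dispatch cut points: midpoints of consecutive training lengths
BOUNDARIES = (5500, 55000, 300000)


def assign_length_bin(L: int) -> int:
    """Training length whose model handles a sequence of length ``L``.

    Returns 1000 for L <= 5500, 10000 for 5500 < L <= 55000, 100000 for
    55000 < L <= 300000, and 500000 beyond — i.e. the closest training
    length, with ties going to the smaller bin.
    """
    if L < 1:
        raise ValueError(f"sequence length must be >= 1, got {L}")
    for boundary, train_len in zip(BOUNDARIES, TRAIN_LENGTHS):
        if L <= boundary:
            return train_len
    return TRAIN_LENGTHS[-1]


@dataclass
class LogisticModel:
    """One trained binary classifier: p(plasmid | x) = sigmoid(w.x + b)."""

    w: np.ndarray
    b: float
    train_length: int
    index_signature: str

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = X @ self.w + self.b
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class LengthBinnedModel:
    """The full classifier: per-length models plus dispatch boundaries.

    ``models`` maps training length -> LogisticModel.  Bins may be absent
    when the training references offered no sufficiently long sequences of
    one class; dispatch then falls back to the nearest available bin with
    a smaller training length (or, failing that, the smallest available).
    """

    models: dict[int, LogisticModel]
    boundaries: tuple[int, ...] = BOUNDARIES
    k_min: int = 3
    k_max: int = 7

    @property
    def index_signature(self) -> str:
        return next(iter(self.models.values())).index_signature

    def resolve_bin(self, L: int) -> int:
        """Bin actually used for a sequence of length L, honoring fallback."""
        want = assign_length_bin(L)
        if want in self.models:
            return want
        smaller = [t for t in self.models if t < want]
        if smaller:
            return max(smaller)
        return min(self.models)


@dataclass
class ClassificationResult:
    """Per-sequence outcome, in input order."""

    id: str
    probability: float
    label: str
    bin: int
    length: int


def train_logistic(
    X: np.ndarray,
    y: np.ndarray,
    reg_strength: float = 1.0,
    train_length: int = 0,
    index_signature: str = "",
    tol: float = 1e-4,
) -> LogisticModel:
    """Fit an L2-regularized logistic regression (plasmid = 1).

    ``reg_strength`` is the conventional inverse regularization strength
    C.  The solver (lbfgs) is deterministic given a fixed data order.
    Raises ``ValueError`` when a class is missing from ``y``.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    for cls, name in ((1, PLASMID), (0, CHROMOSOME)):
        if cls not in classes:
            raise ValueError(f"training data contains no {name} (class {cls}) examples")
    clf = LogisticRegression(C=reg_strength, solver="lbfgs", tol=tol, max_iter=2000)
    clf.fit(X, y)
    return LogisticModel(
        w=clf.coef_.ravel().astype(np.float64),
        b=float(clf.intercept_[0]),
        train_length=train_length,
        index_signature=index_signature,
    )


def train_length_binned(
    plasmid_refs: Sequence[SeqRecord],
    chrom_refs: Sequence[SeqRecord],
    config: TrainingConfig | None = None,
    workers: int = 1,
) -> LengthBinnedModel:
    """Train one logistic model per training length.

    For the 1 kb and 10 kb bins, ``config.n_short`` fragments per class
    are sampled with replacement.  For the 100 kb and 500 kb bins the
    plasmid fragment count covers the sufficiently long plasmids to depth
    ``config.depth_long`` and the chromosome class is sampled to match,
    keeping the bins balanced.  A bin for which either class has no
    sufficiently long reference is omitted with a warning; dispatch falls
    back to the nearest smaller available bin.
    """
    if config is None:
        config = TrainingConfig()
    index = KmerIndex(config.k_min, config.k_max)
    models: dict[int, LogisticModel] = {}
    for bin_i, L in enumerate(config.lengths):
        plas_ok = any(len(r) >= L for r in plasmid_refs)
        chrom_ok = any(len(r) >= L for r in chrom_refs)
        if not (plas_ok and chrom_ok):
            missing = [
                name
                for ok, name in ((plas_ok, PLASMID), (chrom_ok, CHROMOSOME))
                if not ok
            ]
            logger.warning(
                "skipping %d bp bin: no sufficiently long %s reference(s)",
                L,
                " or ".join(missing),
            )
            continue
        if L in (100000, 500000):
            n = depth_fragment_count(plasmid_refs, L, config.depth_long)
        else:
            n = config.n_short
        if n < 1:
            logger.warning("skipping %d bp bin: zero fragments requested", L)
            continue
        frags_p = sample_fragments(
            plasmid_refs, L, n, seed=config.seed * 8 + 2 * bin_i, label=PLASMID,
            max_ambiguous_frac=config.max_ambiguous_frac,
            weighting=config.reference_weighting,
        )
        frags_c = sample_fragments(
            chrom_refs, L, n, seed=config.seed * 8 + 2 * bin_i + 1, label=CHROMOSOME,
            max_ambiguous_frac=config.max_ambiguous_frac,
            weighting=config.reference_weighting,
        )
        X = featurize_batch([f.sequence for f in frags_p + frags_c], index, workers=workers)
        y = np.concatenate([np.ones(len(frags_p)), np.zeros(len(frags_c))])
        logger.info("training %d bp bin on %d fragments per class", L, n)
        models[L] = train_logistic(
            X, y, reg_strength=config.reg_strength,
            train_length=L, index_signature=index.signature,
        )
    if not models:
        raise ValueError("no bin had sufficiently long references of both classes")
    return LengthBinnedModel(models=models, k_min=config.k_min, k_max=config.k_max)


def classify(
    seqs: Sequence[SeqRecord],
    model: LengthBinnedModel,
    workers: int = 1,
    threshold: float = 0.5,
) -> list[ClassificationResult]:
    """Classify sequences, preserving input order for any worker count.

    Each sequence is routed by :func:`assign_length_bin` (with fallback
    for missing bins), featurized, and scored by that bin's model.
    """
    index = KmerIndex(model.k_min, model.k_max)
    if index.signature != model.index_signature:
        raise ValueError(
            f"feature-layout mismatch: featurizer {index.signature!r} "
            f"vs model {model.index_signature!r}"
        )
    if not seqs:
        return []
    bins = [model.resolve_bin(len(s)) for s in seqs]
    probs = np.empty(len(seqs), dtype=np.float64)
    for train_len in sorted(set(bins)):
        idx = [i for i, b in enumerate(bins) if b == train_len]
        X = featurize_batch([seqs[i] for i in idx], index, workers=workers)
        probs[idx] = model.models[train_len].predict_proba(X)
    return [
        ClassificationResult(
            id=s.id,
            probability=float(probs[i]),
            label=PLASMID if probs[i] > threshold else CHROMOSOME,
            bin=bins[i],
            length=len(s),
        )
        for i, s in enumerate(seqs)
    ]


def save_model(model: LengthBinnedModel, path: str | os.PathLike) -> None:
    """Serialize a LengthBinnedModel to a single .npz archive."""
    meta = {
        "format_version": FORMAT_VERSION,
        "index_signature": model.index_signature,
        "k_min": model.k_min,
        "k_max": model.k_max,
        "boundaries": list(model.boundaries),
        "train_lengths": sorted(model.models),
    }
    arrays: dict[str, np.ndarray] = {
        "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    }
    for L, m in model.models.items():
        arrays[f"w_{L}"] = m.w
        arrays[f"b_{L}"] = np.array([m.b], dtype=np.float64)
    np.savez(path, **arrays)


def load_model(path: str | os.PathLike) -> LengthBinnedModel:
    """Load a model archive; exact round-trip of weights and layout.

    Raises ``ValueError`` on a truncated/corrupt file, an unknown format
    version, or a feature-layout signature this build cannot reproduce.
    """
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            arrays = {name: data[name] for name in data.files}
    except Exception as exc:  # truncated/corrupt archives fail in many ways
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if meta.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {meta.get('format_version')!r} "
            f"(this build reads version {FORMAT_VERSION})"
        )
    expected = KmerIndex(meta["k_min"], meta["k_max"]).signature
    if meta["index_signature"] != expected:
        raise ValueError(
            f"feature-layout mismatch: model {meta['index_signature']!r} "
            f"vs this build {expected!r}"
        )
    models = {
        int(L): LogisticModel(
            w=arrays[f"w_{L}"],
            b=float(arrays[f"b_{L}"][0]),
            train_length=int(L),
            index_signature=meta["index_signature"],
        )
        for L in meta["train_lengths"]
    }
    return LengthBinnedModel(
        models=models,
        boundaries=tuple(meta["boundaries"]),
        k_min=meta["k_min"],
        k_max=meta["k_max"],
    )
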