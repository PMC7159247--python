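"""Self-contained benchmark experiments on synthetic data.

Each function runs one study end to end — generate references, train,
classify held-out material, measure — and returns plain numbers.  They are
the package's reproducible substitute for database-scale benchmarks:
problem sizes are scaled to run on a single CPU in seconds while keeping
the qualitative behavior (separability, length dependence, class
imbalance) intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from plasq.evaluation import MetricReport, pr_curve, score
from plasq.fasta_io import SeqRecord
from plasq.kmer_features import KmerIndex, featurize_batch
from plasq.model import classify, train_length_binned, train_logistic
from plasq.synthetic_data import (
    class_source,
    fragment_community,
    generate_sequence,
    make_benchmark_refs,
    simulate_community,
)
from plasq.training import (
    CHROMOSOME,
    PLASMID,
    TrainingConfig,
    sample_fragments,
    split_references,
)


def _spawn_seeds(seed: int, n: int, tag: int = 0) -> np.ndarray:
    rng = np.random.default_rng([seed, tag])
    return rng.integers(0, 2**31, size=n)


def heldout_f1(
    seed: int = 0,
    divergence: float = 0.8,
    n_short: int = 500,
    n_eval: int = 300,
) -> MetricReport:
    """Train on synthetic references and score fragments from held-out ones.

    A quarter of each reference set is held out by reference before
    training.  Evaluation fragments of 1 kb (and 10 kb where the held-out
    sets allow) are sampled from the held-out references only, classified,
    and scored with plasmid as the positive class.
    """
    plasmids, chroms = make_benchmark_refs(divergence=divergence, seed=seed)
    train_p, hold_p = split_references(plasmids, 0.25, seed=seed + 1)
    train_c, hold_c = split_references(chroms, 0.25, seed=seed + 2)
    model = train_length_binned(
        train_p, train_c, TrainingConfig(n_short=n_short, seed=seed)
    )
    frags = []
    for i, L in enumerate((1000, 10000)):
        if not (any(len(r) >= L for r in hold_p) and any(len(r) >= L for r in hold_c)):
            continue
        frags += sample_fragments(hold_p, L, n_eval, seed=seed + 10 + i, label=PLASMID)
        frags += sample_fragments(hold_c, L, n_eval, seed=seed + 20 + i, label=CHROMOSOME)
    recs = [SeqRecord(id=f"f{i}", sequence=f.sequence) for i, f in enumerate(frags)]
    truth = {f"f{i}": f.label for i, f in enumerate(frags)}
    results = classify(recs, model)
    return score(results, truth)


@dataclass
class NullResult:
    accuracy: float
    mean_probability: float
    n_test: int


def null_symmetry(
    seed: int = 0,
    L: int = 1000,
    n_train: int = 400,
    n_test: int = 2000,
) -> NullResult:
    """Train and test with both classes drawn from one identical source.

    At zero divergence the class sources coincide, so every test fragment
    is an independent draw from the same distribution regardless of label;
    balanced accuracy can differ from 0.5 only by binomial noise, and the
    mean predicted plasmid probability should sit near 0.5.
    """
    src = class_source(PLASMID, 0.0)
    assert np.allclose(src.transition, class_source(CHROMOSOME, 0.0).transition)
    index = KmerIndex()
    train_seeds = _spawn_seeds(seed, 2 * n_train, tag=1)
    X_train = featurize_batch(
        [generate_sequence(src, L, seed=int(s)).sequence for s in train_seeds], index
    )
    y_train = np.concatenate([np.ones(n_train), np.zeros(n_train)])
    model = train_logistic(
        X_train, y_train, train_length=L, index_signature=index.signature
    )
    test_seeds = _spawn_seeds(seed, 2 * n_test, tag=2)
    X_test = featurize_batch(
        [generate_sequence(src, L, seed=int(s)).sequence for s in test_seeds], index
    )
    y_test = np.concatenate([np.ones(n_test), np.zeros(n_test)])
    probs = model.predict_proba(X_test)
    acc = float(((probs > 0.5).astype(int) == y_test).mean())
    return NullResult(
        accuracy=acc, mean_probability=float(probs.mean()), n_test=2 * n_test
    )


def length_trend(
    seed: int = 0,
    lengths: tuple[int, ...] = (200, 1000, 10000),
    divergence: float = 0.3,
    n_train: int = 400,
    n_test: int = 200,
) -> dict[int, float]:
    """Held-out F1 per fragment length on two moderately divergent sources.

    Longer fragments average away compositional noise, so F1 should rise
    with fragment length; a mild divergence keeps the short-fragment task
    genuinely hard so the trend is visible.
    """
    index = KmerIndex()
    src_p = class_source(PLASMID, divergence)
    src_c = class_source(CHROMOSOME, divergence)
    out: dict[int, float] = {}
    for li, L in enumerate(lengths):
        n = n_train + n_test
        seeds_p = _spawn_seeds(seed, n, tag=10 + li)
        seeds_c = _spawn_seeds(seed, n, tag=40 + li)
        X = featurize_batch(
            [generate_sequence(src_p, L, seed=int(s)).sequence for s in seeds_p]
            + [generate_sequence(src_c, L, seed=int(s)).sequence for s in seeds_c],
            index,
        )
        y = np.concatenate([np.ones(n), np.zeros(n)])
        tr = np.r_[0:n_train, n : n + n_train]
        te = np.r_[n_train:n, n + n_train : 2 * n]
        model = train_logistic(
            X[tr], y[tr], train_length=L, index_signature=index.signature
        )
        pred = (model.predict_proba(X[te]) > 0.5).astype(int)
        tp = int(((pred == 1) & (y[te] == 1)).sum())
        fp = int(((pred == 1) & (y[te] == 0)).sum())
        fn = int(((pred == 0) & (y[te] == 1)).sum())
        out[L] = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
    return out


@dataclass
class CommunityResult:
    pr_auc: float
    pr_baseline: float
    f1_1kb: float
    plasmid_fraction: float
    n_contigs: int


def community_benchmark(
    seed: int = 0,
    divergence: float = 0.8,
    n_short: int = 500,
    n_contigs: int = 1000,
) -> CommunityResult:
    """Train on references, classify contigs from a simulated community.

    The community is assembled from freshly generated references of the
    same class sources (log-normal abundances, geometric copy numbers), so
    no contig shares a source sequence with training.  Reports the
    precision-recall area over contig scores, the F1 of the 0.5 rule on
    contigs longer than 1 kb, and the plasmid fraction of the contigs.
    """
    plasmids, chroms = make_benchmark_refs(divergence=divergence, seed=seed)
    model = train_length_binned(
        plasmids, chroms, TrainingConfig(n_short=n_short, seed=seed)
    )
    ev_plasmids, ev_chroms = make_benchmark_refs(
        n_plasmid=15,
        n_chrom=10,
        plasmid_len_range=(500, 20000),
        chrom_len_range=(10000, 140000),
        divergence=divergence,
        seed=seed + 1000,
    )
    community = simulate_community(ev_chroms, ev_plasmids, seed=seed + 2000)
    frags = fragment_community(community, n_fragments=n_contigs, seed=seed + 3000)
    recs = [SeqRecord(id=f"ctg{i}", sequence=f.sequence) for i, f in enumerate(frags)]
    truth = {f"ctg{i}": f.label for i, f in enumerate(frags)}
    results = classify(recs, model)
    _, auc, baseline = pr_curve([(r.probability, truth[r.id]) for r in results])
    rep = score(results, truth, min_length=999)
    n_plasmid = sum(1 for f in frags if f.label == PLASMID)
    return CommunityResult(
        pr_auc=auc,
        pr_baseline=baseline,
        f1_1kb=rep.f1,
        plasmid_fraction=n_plasmid / len(frags),
        n_contigs=len(frags),
    )
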