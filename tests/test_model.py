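import logging

import numpy as np
import pytest

from plasq.fasta_io import SeqRecord
from plasq.kmer_features import KmerIndex, featurize_batch
from plasq.model import (
    LengthBinnedModel,
    assign_length_bin,
    classify,
    load_model,
    save_model,
    train_length_binned,
    train_logistic,
)
from plasq.synthetic_data import class_source, generate_sequence, make_benchmark_refs
from plasq.training import CHROMOSOME, PLASMID, TrainingConfig


# ------------------------------------------------------------------- dispatch


@pytest.mark.parametrize(
    "L,expected",
    [
        (1, 1000),
        (5500, 1000),
        (5501, 10000),
        (55000, 10000),
        (55001, 100000),
        (300000, 100000),
        (300001, 500000),
        (10**9, 500000),
    ],
)
def test_assign_length_bin_boundaries(L, expected):
    assert assign_length_bin(L) == expected


def test_assign_length_bin_rejects_nonpositive():
    with pytest.raises(ValueError):
        assign_length_bin(0)


def test_dispatch_is_nearest_training_length():
    """The half-open ranges are exactly 'closest of {1k,10k,100k,500k}'."""
    lengths = [1, 100, 3000, 5500, 5501, 30000, 55000, 55001, 200000, 300000, 300001, 10**6]
    for L in lengths:
        nearest = min((1000, 10000, 100000, 500000), key=lambda t: (abs(L - t), t))
        assert assign_length_bin(L) == nearest


# ----------------------------------------------------------- logistic training


def test_train_logistic_separable_toy():
    """Poly-A vs poly-C fragments are perfectly separable in k-mer space."""
    idx = KmerIndex(3, 4)
    rng = np.random.default_rng(0)
    seqs, labels = [], []
    for _ in range(30):
        seqs.append("A" * int(rng.integers(50, 150)))
        labels.append(1)
        seqs.append("C" * int(rng.integers(50, 150)))
        labels.append(0)
    X = featurize_batch(seqs, idx)
    y = np.array(labels)
    m = train_logistic(X, y, train_length=1000, index_signature=idx.signature)
    pred = (m.predict_proba(X) > 0.5).astype(int)
    assert (pred == y).all()


def test_train_logistic_single_class_errors():
    X = np.zeros((4, 3))
    with pytest.raises(ValueError, match="chromosome"):
        train_logistic(X, np.ones(4))
    with pytest.raises(ValueError, match="plasmid"):
        train_logistic(X, np.zeros(4))


def test_null_calibration_and_accuracy(null_stats):
    """On identically distributed classes the model cannot beat chance.

    Mean predicted probability stays near 0.5 and balanced held-out
    accuracy is within 3 sigma of the binomial null.
    """
    assert 0.4 <= null_stats.mean_probability <= 0.6
    three_sigma = 3 * np.sqrt(0.25 / null_stats.n_test)
    assert abs(null_stats.accuracy - 0.5) <= three_sigma


def test_markov_sources_strongly_separable():
    """GC 0.35 vs 0.65 order-1 sources: held-out F1 >= 0.95 at 1 kb."""
    idx = KmerIndex(3, 5)
    sp = class_source(PLASMID, 1.0)
    sc = class_source(CHROMOSOME, 1.0)
    n, L = 250, 1000
    seqs = [generate_sequence(sp, L, seed=i).sequence for i in range(n)]
    seqs += [generate_sequence(sc, L, seed=5000 + i).sequence for i in range(n)]
    X = featurize_batch(seqs, idx)
    y = np.concatenate([np.ones(n), np.zeros(n)])
    n_train = 200
    tr = np.r_[0:n_train, n : n + n_train]
    te = np.r_[n_train:n, n + n_train : 2 * n]
    m = train_logistic(X[tr], y[tr], train_length=L, index_signature=idx.signature)
    pred = (m.predict_proba(X[te]) > 0.5).astype(int)
    tp = ((pred == 1) & (y[te] == 1)).sum()
    fp = ((pred == 1) & (y[te] == 0)).sum()
    fn = ((pred == 0) & (y[te] == 1)).sum()
    f1 = 2 * tp / (2 * tp + fp + fn)
    assert f1 >= 0.95


# ------------------------------------------------------- length-binned training


def test_train_length_binned_skips_unreachable_bins(caplog, small_refs, trained_model):
    plasmids, chroms = small_refs
    # plasmids top out below 55 kb, so the 100k/500k bins cannot be trained
    assert max(len(r) for r in plasmids) < 100000
    assert sorted(trained_model.models) == [1000, 10000]


def test_train_length_binned_deterministic(tmp_path):
    plasmids, chroms = make_benchmark_refs(
        n_plasmid=6, n_chrom=2, plasmid_len_range=(1500, 4000),
        chrom_len_range=(5000, 8000), divergence=1.0, seed=3,
    )
    config = TrainingConfig(n_short=40, seed=5)
    m1 = train_length_binned(plasmids, chroms, config)
    m2 = train_length_binned(plasmids, chroms, config)
    p1, p2 = tmp_path / "m1.npz", tmp_path / "m2.npz"
    save_model(m1, p1)
    save_model(m2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_train_length_binned_all_bins_empty():
    tiny_p = [SeqRecord(id="p", sequence="ACGT" * 50)]
    tiny_c = [SeqRecord(id="c", sequence="TTTT" * 50)]
    config = TrainingConfig(lengths=(100000, 500000), n_short=10)
    with pytest.raises(ValueError):
        train_length_binned(tiny_p, tiny_c, config)


def test_missing_bin_fallback_resolution(trained_model):
    # 100k/500k bins absent: long queries fall back to the 10k model
    assert trained_model.resolve_bin(1000) == 1000
    assert trained_model.resolve_bin(70000) == 10000
    assert trained_model.resolve_bin(400000) == 10000


# ------------------------------------------------------------------ classify


def _query_records(small_refs, n=30):
    plasmids, chroms = small_refs
    rng = np.random.default_rng(12)
    recs = []
    for i in range(n):
        src = plasmids[i % len(plasmids)] if i % 2 == 0 else chroms[i % len(chroms)]
        L = int(rng.integers(300, min(len(src), 20000)))
        start = int(rng.integers(0, len(src) - L + 1))
        recs.append(SeqRecord(id=f"q{i}", sequence=src.sequence[start : start + L]))
    return recs


def test_classify_order_and_labels(small_refs, trained_model):
    recs = _query_records(small_refs)
    results = classify(recs, trained_model)
    assert [r.id for r in results] == [r.id for r in recs]
    for r in results:
        assert (r.label == PLASMID) == (r.probability > 0.5)
        assert r.length == len(dict((x.id, x) for x in recs)[r.id])


def test_classify_empty_input(trained_model):
    assert classify([], trained_model) == []


def test_classify_parallel_invariance(small_refs, trained_model):
    recs = _query_records(small_refs, n=60)
    serial = classify(recs, trained_model, workers=1)
    parallel = classify(recs, trained_model, workers=8)
    assert [(r.id, r.probability, r.label, r.bin) for r in serial] == [
        (r.id, r.probability, r.label, r.bin) for r in parallel
    ]


def test_classify_threshold_tie_is_chromosome(trained_model):
    # a probability of exactly 0.5 must not be labeled plasmid
    from plasq.model import ClassificationResult, LogisticModel

    idx = KmerIndex(trained_model.k_min, trained_model.k_max)
    zero = LengthBinnedModel(
        models={
            1000: LogisticModel(
                w=np.zeros(idx.D), b=0.0, train_length=1000,
                index_signature=idx.signature,
            )
        },
        k_min=trained_model.k_min,
        k_max=trained_model.k_max,
    )
    [res] = classify([SeqRecord(id="x", sequence="ACGT" * 100)], zero)
    assert res.probability == 0.5
    assert res.label == CHROMOSOME


# ------------------------------------------------------------- serialization


def test_save_load_round_trip(tmp_path, small_refs, trained_model):
    path = tmp_path / "model.npz"
    save_model(trained_model, path)
    loaded = load_model(path)
    recs = _query_records(small_refs)
    before = [(r.id, r.probability) for r in classify(recs, trained_model)]
    after = [(r.id, r.probability) for r in classify(recs, loaded)]
    assert before == after
    for L, m in trained_model.models.items():
        np.testing.assert_array_equal(m.w, loaded.models[L].w)
        assert m.b == loaded.models[L].b


def test_load_rejects_altered_signature(tmp_path, trained_model):
    path = tmp_path / "model.npz"
    save_model(trained_model, path)
    blob = path.read_bytes().replace(b"canonical-lex", b"scrambled-lex")
    path.write_bytes(blob)
    with pytest.raises(ValueError, match="signature|layout|read"):
        load_model(path)


def test_load_rejects_truncated_file(tmp_path, trained_model):
    path = tmp_path / "model.npz"
    save_model(trained_model, path)
    path.write_bytes(path.read_bytes()[: path.stat().st_size // 2])
    with pytest.raises(ValueError):
        load_model(path)


def test_classify_rejects_mismatched_featurizer(small_refs, trained_model):
    other = LengthBinnedModel(
        models=trained_model.models, k_min=3, k_max=5
    )
    with pytest.raises(ValueError, match="layout"):
        classify([SeqRecord(id="x", sequence="ACGT" * 10)], other)
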