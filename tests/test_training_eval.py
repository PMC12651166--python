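"""Pair-file I/O, stratified splits, metric oracles and the training loop."""

import numpy as np
import pytest

from dtifuse import (DataError, DTIModel, InteractionRecord, compute_metrics,
                     evaluate, read_pairs, run_ablation, split_dataset,
                     train, unseen_pair_split, write_pairs)


def _records(n, pos_fraction=0.5, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        recs.append(InteractionRecord(
            smiles=f"C{'C' * (i % 4)}O", sequence="ACDHKH"[:3 + i % 3],
            label=int(rng.random() < pos_fraction)))
    return recs


# -- pair-file I/O --------------------------------------------------------

def test_well_formed_file_reads_all_rows(tmp_path):
    path = tmp_path / "pairs.tsv"
    path.write_text("smiles\tsequence\tlabel\n"
                    "CCO\tACDH\t1\n"
                    "CNC\tMKWV\t0\n"
                    "CCN\tHKHA\t1\n")
    recs = read_pairs(path)
    assert len(recs) == 3
    assert recs[0].smiles == "CCO" and recs[0].label == 1


def test_headerless_and_comma_dialects(tmp_path):
    path = tmp_path / "pairs.csv"
    path.write_text("CCO,ACDH,1\nCNC,MKWV,0\n")
    recs = read_pairs(path)
    assert [r.label for r in recs] == [1, 0]


def test_bad_label_row_rejected_with_line_number(tmp_path, caplog):
    path = tmp_path / "pairs.tsv"
    path.write_text("smiles\tsequence\tlabel\n"
                    "CCO\tACDH\t1\n"
                    "CNC\tMKWV\t2\n"
                    "CCN\tHKHA\t0\n")
    with caplog.at_level("WARNING", logger="dtifuse"):
        recs = read_pairs(path)
    assert len(recs) == 2
    assert ":3:" in caplog.text and "2" in caplog.text


def test_missing_columns_error_lists_header(tmp_path):
    path = tmp_path / "pairs.tsv"
    path.write_text("smiles\tlabel\nCCO\t1\n")
    with pytest.raises(DataError, match="smiles"):
        read_pairs(path)


def test_write_read_roundtrip_is_lossless(tmp_path):
    recs = _records(17)
    path = tmp_path / "pairs.tsv"
    write_pairs(recs, path)
    back = read_pairs(path)
    assert [(r.smiles, r.sequence, r.label) for r in back] == \
        [(r.smiles, r.sequence, r.label) for r in recs]


# -- splits ----------------------------------------------------------------

def test_ten_records_split_8_1_1():
    recs = _records(10)
    tr, va, te = split_dataset(recs, (0.8, 0.1, 0.1), seed=0)
    assert (len(tr), len(va), len(te)) == (8, 1, 1)


def test_split_is_deterministic_disjoint_and_exhaustive():
    recs = _records(37)
    a = split_dataset(recs, (0.8, 0.1, 0.1), seed=5)
    b = split_dataset(recs, (0.8, 0.1, 0.1), seed=5)
    for pa, pb in zip(a, b):
        assert [(r.smiles, r.sequence) for r in pa] == \
            [(r.smiles, r.sequence) for r in pb]
    ids = [id(r) for part in a for r in part]
    assert len(ids) == len(set(ids)) == len(recs)


def test_split_stratification_within_one_record():
    recs = _records(120, pos_fraction=0.3, seed=3)
    global_ratio = np.mean([r.label for r in recs])
    for part, frac in zip(split_dataset(recs, (0.8, 0.1, 0.1), seed=1),
                          (0.8, 0.1, 0.1)):
        n_pos = sum(r.label for r in part)
        assert abs(n_pos - global_ratio * len(part)) <= 1.0


def test_empty_partition_is_an_error():
    with pytest.raises(DataError, match="empty"):
        split_dataset(_records(3), (0.8, 0.1, 0.1), seed=0)


def test_unseen_pair_split_withholds_the_fraction():
    recs = _records(50)
    rest, held = unseen_pair_split(recs, 0.1, seed=2)
    assert len(held) == 5 and len(rest) == 45
    assert {id(r) for r in held}.isdisjoint({id(r) for r in rest})


# -- metrics ---------------------------------------------------------------

def _auroc_oracle(y, p):
    pos = [pi for yi, pi in zip(y, p) if yi == 1]
    neg = [pi for yi, pi in zip(y, p) if yi == 0]
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0
               for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


def _auprc_oracle(y, p):
    # step integration of the precision-recall curve at each unique score
    order = np.argsort(-np.asarray(p), kind="stable")
    y = np.asarray(y)[order]
    p = np.asarray(p)[order]
    n_pos = y.sum()
    ap, tp, fp, prev_recall = 0.0, 0, 0, 0.0
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and p[j] == p[i]:
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


def _confusion_oracle(y, p, thr):
    tp = sum(1 for yi, pi in zip(y, p) if yi == 1 and pi >= thr)
    tn = sum(1 for yi, pi in zip(y, p) if yi == 0 and pi < thr)
    fp = sum(1 for yi, pi in zip(y, p) if yi == 0 and pi >= thr)
    fn = sum(1 for yi, pi in zip(y, p) if yi == 1 and pi < thr)
    acc = (tp + tn) / len(y)
    f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
    denom = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    mcc = ((tp * tn - fp * fn) / denom) if denom else 0.0
    return acc, f1, mcc


def test_perfect_separation_gives_unit_ranking_metrics():
    rep = compute_metrics([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
    assert rep.auroc == 1.0 and rep.auprc == 1.0


def test_three_of_four_concordant_pairs():
    rep = compute_metrics([1, 0, 1, 0], [0.9, 0.8, 0.2, 0.1])
    np.testing.assert_allclose(rep.auroc, 0.75)


def test_exact_predictions_max_thresholded_metrics():
    y = [1, 0, 1, 1, 0]
    rep = compute_metrics(y, [float(v) for v in y])
    assert rep.accuracy == rep.f1 == rep.mcc == 1.0


def test_single_class_ranking_metrics_undefined_not_zero():
    rep = compute_metrics([1, 1, 1], [0.2, 0.5, 0.9])
    assert rep.auroc is None and rep.auprc is None
    assert rep.accuracy > 0


@pytest.mark.parametrize("seed", range(8))
def test_metrics_match_bruteforce_oracles(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 201))
    y = rng.integers(0, 2, size=n)
    if y.sum() in (0, n):
        y[0] = 1 - y[0]
    # duplicated scores exercise tie handling
    p = rng.choice(np.round(rng.random(max(3, n // 3)), 3), size=n)
    rep = compute_metrics(y, p, threshold=0.5)
    np.testing.assert_allclose(rep.auroc, _auroc_oracle(y, p), atol=1e-12)
    np.testing.assert_allclose(rep.auprc, _auprc_oracle(y, p), atol=1e-12)
    acc, f1, mcc = _confusion_oracle(y, p, 0.5)
    np.testing.assert_allclose(rep.accuracy, acc, atol=1e-12)
    np.testing.assert_allclose(rep.f1, f1, atol=1e-12)
    np.testing.assert_allclose(rep.mcc, mcc, atol=1e-9)


# -- training loop ---------------------------------------------------------

def _tiny_dataset(n=32, seed=0):
    from dtifuse import generate_dataset
    records, rule = generate_dataset(n, seed=seed, n_drugs=12, n_proteins=12,
                                     length_range=(8, 12), atom_budget=14)
    return records


def test_two_epoch_smoke_run_writes_loadable_checkpoint(tiny_config, tmp_path):
    recs = _tiny_dataset(32)
    tr, va = recs[:24], recs[24:]
    model, history = train(tiny_config, tr, va)
    assert len(history) >= 1
    assert all(np.isfinite(h["train_loss"]) for h in history)
    path = tmp_path / "ckpt.npz"
    model.save(path)
    loaded = DTIModel.load(path)
    smiles = [r.smiles for r in va]
    seqs = [r.sequence for r in va]
    np.testing.assert_array_equal(model.predict_pairs(smiles, seqs),
                                  loaded.predict_pairs(smiles, seqs))


def test_identical_seeds_reproduce_identical_losses(tiny_config):
    recs = _tiny_dataset(32)
    tr, va = recs[:24], recs[24:]
    _, h1 = train(tiny_config, tr, va)
    _, h2 = train(tiny_config, tr, va)
    assert [h["train_loss"] for h in h1] == [h["train_loss"] for h in h2]


def test_reevaluation_reproduces_stored_validation_metrics(tiny_config,
                                                           tmp_path):
    recs = _tiny_dataset(32)
    tr, va = recs[:24], recs[24:]
    model, history = train(tiny_config, tr, va)
    best = max(history, key=lambda h: (h["valid_auroc"], -h["epoch"]))
    rep = evaluate(model, va)
    assert rep.auroc == best["valid_auroc"]
    path = tmp_path / "ckpt.npz"
    model.save(path)
    rep2 = evaluate(DTIModel.load(path), va)
    assert rep2.as_dict() == rep.as_dict()


def test_empty_training_set_rejected(tiny_config):
    with pytest.raises(DataError, match="empty"):
        train(tiny_config, [], _tiny_dataset(8))


def test_unknown_ablation_mode_rejected(tiny_config):
    with pytest.raises(Exception, match="ablation"):
        run_ablation("bogus", tiny_config, _tiny_dataset(32))


def test_single_mode_checkpoint_has_no_fusion_parameters(tiny_config):
    recs = _tiny_dataset(40)
    cfg = tiny_config.replace(ablation="single", max_epochs=1)
    report, model, _ = run_ablation("single", cfg, recs)
    assert not any("fusion" in k for k in model.state_dict())
    full = DTIModel(tiny_config)
    assert any("fusion" in k for k in full.state_dict())
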