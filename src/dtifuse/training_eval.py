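"""Dataset I/O, splits, training loop, metrics and ablation runner.

Pair files are delimited text (tab or comma) with columns
(SMILES, sequence, label); the dialect matches the common public DTI
benchmark exports.  Splitting is stratified by label and fully determined
by a seed.  The five evaluation metrics are AUROC, AUPRC, Accuracy,
F1 and MCC; the threshold-free pair are undefined (None) when only one
class is present, never silently 0.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.metrics import (accuracy_score, average_precision_score,
                             f1_score, matthews_corrcoef, roc_auc_score)

from ._autodiff import Adam
from .config import ModelConfig
from .mol_featurizer import GraphCache
from .model import DTIModel, featurize_batch

logger = logging.getLogger("dtifuse")


class DataError(ValueError):
    """Raised for malformed pair files or impossible splits."""


@dataclass
class InteractionRecord:
    smiles: str
    sequence: str
    label: int
    predicted_p: float | None = None

    def __post_init__(self):
        if not self.smiles or not self.sequence:
            raise DataError("smiles and sequence must be nonempty")
        if self.label not in (0, 1):
            raise DataError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class MetricReport:
    auroc: float | None
    auprc: float | None
    accuracy: float
    f1: float
    mcc: float
    threshold: float

    def as_dict(self) -> dict:
        return {"auroc": self.auroc, "auprc": self.auprc,
                "accuracy": self.accuracy, "f1": self.f1, "mcc": self.mcc,
                "threshold": self.threshold}


# ---------------------------------------------------------------------------
# pair-file I/O
# ---------------------------------------------------------------------------

_HEADER_HINTS = {"smiles", "sequence", "label", "protein", "target"}


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_pairs(path, dialect: str | None = None) -> list:
    """Read (SMILES, sequence, label) records from delimited text.

    The delimiter is sniffed unless given; a header row is auto-detected.
    Malformed rows are rejected with their line numbers logged; duplicate
    pairs are logged but kept.
    """
    records: list[InteractionRecord] = []
    seen = set()
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first:
            raise DataError(f"{path}: empty pair file")
        delim = dialect or _sniff_delimiter(first)
        cols = [c.strip().lower() for c in first.rstrip("\n").split(delim)]
        has_header = bool(_HEADER_HINTS & set(cols))
        if has_header:
            if len(cols) < 3:
                raise DataError(
                    f"{path}: expected 3 columns (SMILES, sequence, label); "
                    f"found header {cols}")
            lines = fh
            start_line = 2
        else:
            fh.seek(0)
            lines = fh
            start_line = 1
        reader = csv.reader(lines, delimiter=delim)
        for lineno, row in enumerate(reader, start=start_line):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                logger.warning("%s:%d: rejected row with %d fields",
                               path, lineno, len(row))
                continue
            smi, seq, lab = row[0].strip(), row[1].strip(), row[2].strip()
            if lab not in ("0", "1"):
                logger.warning("%s:%d: rejected row with bad label %r",
                               path, lineno, lab)
                continue
            try:
                rec = InteractionRecord(smiles=smi, sequence=seq,
                                        label=int(lab))
            except DataError as err:
                logger.warning("%s:%d: rejected row (%s)", path, lineno, err)
                continue
            key = (smi, seq)
            if key in seen:
                logger.info("%s:%d: duplicate pair %s", path, lineno, key)
            seen.add(key)
            records.append(rec)
    return records


def write_pairs(records, path, delimiter: str = "\t"):
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["smiles", "sequence", "label"])
        for r in records:
            writer.writerow([r.smiles, r.sequence, r.label])


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(records, fractions=(0.8, 0.1, 0.1), seed: int = 0) -> tuple:
    """Stratified, seed-deterministic (train, valid, test) split.

    Within each label class, indices are shuffled and allocated to the three
    partitions proportionally (largest-remainder rounding), so each split's
    class ratio stays within one record of the global ratio.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise DataError("split fractions must sum to 1")
    records = list(records)
    n = len(records)
    rng = np.random.default_rng(seed)
    parts = ([], [], [])
    for label in (0, 1):
        idx = [i for i, r in enumerate(records) if r.label == label]
        rng.shuffle(idx)
        quotas = [f * len(idx) for f in fractions]
        counts = [math.floor(q) for q in quotas]
        rema = sorted(range(3), key=lambda i: quotas[i] - counts[i],
                      reverse=True)
        for i in rema[:len(idx) - sum(counts)]:
            counts[i] += 1
        pos = 0
        for part, cnt in zip(parts, counts):
            part.extend(idx[pos:pos + cnt])
            pos += cnt
    out = tuple([records[i] for i in sorted(part)] for part in parts)
    if any(len(p) == 0 for p in out):
        raise DataError(
            f"split of {n} records with fractions {fractions} leaves an "
            "empty partition")
    return out


def unseen_pair_split(records, fraction: float, seed: int = 0) -> tuple:
    """Withhold a fraction of pairs never seen in training (generalization
    check); returns (rest, held_out)."""
    records = list(records)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(records))
    k = int(round(fraction * len(records)))
    held = sorted(idx[:k].tolist())
    rest = sorted(idx[k:].tolist())
    return [records[i] for i in rest], [records[i] for i in held]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_metrics(labels, probabilities,
                    threshold: float = 0.5) -> MetricReport:
    """The five evaluation metrics from one prediction vector.

    AUROC/AUPRC are threshold-free; Accuracy/F1/MCC use ``threshold``.
    With a single observed class the ranking metrics are undefined (None).
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must align")
    single_class = len(np.unique(y)) < 2
    auroc = None if single_class else float(roc_auc_score(y, p))
    auprc = None if single_class else float(average_precision_score(y, p))
    yhat = (p >= threshold).astype(int)
    return MetricReport(
        auroc=auroc, auprc=auprc,
        accuracy=float(accuracy_score(y, yhat)),
        f1=float(f1_score(y, yhat, zero_division=0)),
        mcc=float(matthews_corrcoef(y, yhat)),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _records_batch(config, records, cache):
    return featurize_batch(config, [r.smiles for r in records],
                           [r.sequence for r in records], cache)


def evaluate(model: DTIModel, records, cache: GraphCache | None = None,
             threshold: float | None = None) -> MetricReport:
    probs = model.predict_pairs([r.smiles for r in records],
                                [r.sequence for r in records],
                                batch_size=model.config.batch_size,
                                graph_cache=cache)
    for r, p in zip(records, probs):
        r.predicted_p = float(p)
    return compute_metrics([r.label for r in records], probs,
                           threshold=threshold if threshold is not None
                           else model.config.threshold)


def train(config: ModelConfig, train_records, valid_records,
          progress: bool = False) -> tuple:
    """Seeded end-to-end training with early stopping on validation AUROC.

    Returns ``(model, history)``; the model carries the best-validation
    parameters.  A non-finite loss aborts with a diagnostic.
    """
    if not train_records:
        raise DataError("empty training set")
    model = DTIModel(config)
    cache = GraphCache(config.n_atoms_max)
    params = model.parameters()
    opt = Adam(params.values(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7A]))

    # featurize once; index batches into the cached arrays
    full = _records_batch(config, train_records, cache)
    labels = np.array([r.label for r in train_records], dtype=np.float32)
    n = len(train_records)

    best_auroc, best_state, best_epoch = -np.inf, model.state_dict(), -1
    history = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            sel = order[lo:lo + config.batch_size]
            batch = {k: v[sel] for k, v in full.items()}
            loss = model.loss(batch, labels[sel], training=True)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        report = evaluate(model, valid_records, cache)
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                 **{f"valid_{k}": v for k, v in report.as_dict().items()}}
        history.append(entry)
        if progress:
            logger.info("epoch %d loss %.4f valid AUROC %s", epoch,
                        entry["train_loss"], report.auroc)
        auroc = -np.inf if report.auroc is None else report.auroc
        if auroc > best_auroc:
            best_auroc, best_state, best_epoch = auroc, model.state_dict(), epoch
        elif epoch - best_epoch >= config.patience:
            break
    model.load_state(best_state)
    return model, history


def run_ablation(mode: str, config: ModelConfig, records,
                 seed: int | None = None) -> tuple:
    """Train and evaluate one architecture variant on a shared split.

    ``mode`` is one of full/noco/single/nocross; the data handling (split,
    seed, featurization) is identical across modes so reports are
    comparable.  Returns ``(report, model, history)``.
    """
    cfg = config.replace(ablation=mode,
                         seed=config.seed if seed is None else seed)
    tr, va, te = split_dataset(records, cfg.split_fractions, seed=cfg.seed)
    model, history = train(cfg, tr, va)
    report = evaluate(model, te)
    return report, model, history


def repeat_compare(config_a: ModelConfig, config_b: ModelConfig, records,
                   seeds=(0, 1, 2, 3, 4), metric: str = "auroc") -> dict:
    """Paired comparison of two configurations across repeated seeded runs.

    Trains both configurations with identical splits per seed and applies a
    paired t-test to the chosen test metric.
    """
    scores_a, scores_b = [], []
    for seed in seeds:
        ra, *_ = run_ablation(config_a.ablation, config_a, records, seed=seed)
        rb, *_ = run_ablation(config_b.ablation, config_b, records, seed=seed)
        scores_a.append(getattr(ra, metric))
        scores_b.append(getattr(rb, metric))
    tstat, pvalue = stats.ttest_rel(scores_a, scores_b)
    return {"scores_a": scores_a, "scores_b": scores_b,
            "t_statistic": float(tstat), "p_value": float(pvalue)}
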