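"""Per-residue high-response regions from a trained model.

For one (drug, protein) pair, the forward pass is run and the protein-side
fused representation P_f (the residue states after absorbing drug
conditioning through cross-attention) is captured on the valid residues.
Within each response dimension, the top quantile of residue positions
(default 30%, ties broken toward the lower position index) is flagged as
high-response; a residue's intensity is the fraction of dimensions that
flag it.  Intensities export as delimited text and contiguous
high-intensity runs as BED intervals (0-based, half-open).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np

from .model import DTIModel, featurize_batch


@dataclass
class ResponseMap:
    sequence: str
    response: np.ndarray     # (L_valid, D) activations
    high_flags: np.ndarray   # (L_valid, D) bool
    intensity: np.ndarray    # (L_valid,) in [0, 1]
    quantile: float


def top_quantile_flags(response: np.ndarray, quantile: float) -> np.ndarray:
    """Flag the ceil(q * L) highest positions per dimension.

    Ties break toward the lower position index (stable descending sort).
    """
    L, D = response.shape
    k = math.ceil(quantile * L)
    flags = np.zeros((L, D), dtype=bool)
    for d in range(D):
        order = np.argsort(-response[:, d], kind="stable")
        flags[order[:k], d] = True
    return flags


def response_map(model: DTIModel, smiles: str, sequence: str,
                 quantile: float = 0.30,
                 source: str = "fused") -> ResponseMap:
    """Compute the high-response map of a protein under one drug.

    ``source`` selects the response tensor: ``"fused"`` uses P_f (the
    drug-conditioned residue states); ``"attention"`` uses the raw
    cross-attention output Z_P instead, for comparison.
    """
    cfg = model.config
    if len(sequence) > cfg.seq_len_max:
        raise ValueError(
            f"sequence of length {len(sequence)} exceeds the padded maximum "
            f"{cfg.seq_len_max}")
    if source not in ("fused", "attention"):
        raise ValueError(f"unknown response source {source!r}")
    batch = featurize_batch(cfg, [smiles], [sequence])
    out = model.forward(batch, capture=True)
    if source == "attention":
        if "z_p" not in out:
            raise ValueError(
                "attention response source requires the cross-attention "
                "stage (not available under the nocross ablation)")
        resp = out["z_p"].data[0]
    else:
        resp = out["p_f"].data[0]
    valid = batch["prot_mask"][0].astype(bool)
    resp = resp[valid]
    flags = top_quantile_flags(resp, quantile)
    intensity = flags.sum(axis=1) / flags.shape[1]
    return ResponseMap(sequence=sequence[:valid.sum()], response=resp,
                       high_flags=flags, intensity=intensity,
                       quantile=quantile)


def high_intensity_runs(intensity: np.ndarray, cutoff: float) -> list:
    """Contiguous runs of intensity >= cutoff as 0-based half-open spans."""
    runs, start = [], None
    for i, v in enumerate(intensity):
        if v >= cutoff and start is None:
            start = i
        elif v < cutoff and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(intensity)))
    return runs


def export_regions(rmap: ResponseMap, intensity_path, bed_path,
                   cutoff: float = 0.5, name: str = "protein"):
    """Write per-residue intensity (TSV) and high-intensity runs (BED)."""
    with open(intensity_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["position", "residue", "intensity"])
        for i, v in enumerate(rmap.intensity, start=1):
            writer.writerow([i, rmap.sequence[i - 1], f"{v:.6f}"])
    with open(bed_path, "w", newline="") as fh:
        for start, end in high_intensity_runs(rmap.intensity, cutoff):
            fh.write(f"{name}\t{start}\t{end}\n")


def read_regions(bed_path) -> list:
    """Read BED intervals back as (start, end) 0-based half-open pairs."""
    runs = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            _, start, end = line.split("\t")
            runs.append((int(start), int(end)))
    return runs
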