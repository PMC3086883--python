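"""Whole-sequence cleavage scanning: score every internal peptide bond with a
trained model, min-max normalize per sequence, and flag the top-scoring
fraction of bonds as predicted cleavage sites."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import AnnotatedSubstrate, Instance, extract_window
from .mkl_svm import MKLModel, decision_scores


@dataclass
class ScanResult:
    """Per-bond decision values for one sequence, with normalized scores and
    the set of bonds above the top-fraction threshold."""

    sequence_id: str
    bond_scores: np.ndarray          # raw decision values, bond i at [i-1]
    normalized_scores: np.ndarray    # min-max rescaled to [0, 1]
    threshold_value: float           # on the normalized scale
    above_threshold: list[int]       # 1-based bond indices


def normalize_scores(raw) -> np.ndarray:
    """Min-max rescaling to [0, 1] per sequence; a constant profile maps to
    all-0.5 (rank order is preserved)."""
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ValueError("need at least two scores to normalize")
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        return np.full_like(raw, 0.5)
    return (raw - lo) / (hi - lo)


def top_fraction_threshold(scores, fraction: float = 0.05):
    """Threshold separating the top ``fraction`` of scores.

    The threshold sits just below the k-th largest score, k =
    ceil(fraction * n) (so at least one bond always qualifies); indices are
    the positions strictly above it, which keeps every score tied with the
    k-th largest.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    k = max(1, math.ceil(fraction * n))
    cutoff = np.sort(scores)[::-1][k - 1]
    below = scores[scores < cutoff]
    threshold = float(below.max()) if below.size else float(cutoff - 1.0)
    indices = [int(i) for i in np.nonzero(scores > threshold)[0]]
    return threshold, indices


def scan(model: MKLModel, substrate: AnnotatedSubstrate,
         top_fraction: float = 0.05) -> ScanResult:
    """Score every internal bond of a substrate with the trained model.

    Windows are cut at the model's stored spec with terminal padding;
    annotations on the substrate are ignored (scan is prediction-only).
    """
    if model.configs is None:
        raise ValueError("model is not scoreable")
    for cfg in model.configs:
        try:
            substrate.track(cfg.track)
        except KeyError:
            raise ValueError(f"substrate lacks required track {cfg.track!r}")
    spec = model.stored_spec
    queries = [
        Instance(
            seq_window=extract_window(substrate, bond, spec, "sequence"),
            ss_window=extract_window(substrate, bond, spec, "ss"),
            sa_window=extract_window(substrate, bond, spec, "sa"),
            label=0, source_id=substrate.id, bond_index=bond,
        )
        for bond in range(1, len(substrate))
    ]
    raw = decision_scores(model, queries)
    norm = normalize_scores(raw)
    threshold, idx0 = top_fraction_threshold(norm, top_fraction)
    return ScanResult(
        sequence_id=substrate.id,
        bond_scores=raw,
        normalized_scores=norm,
        threshold_value=threshold,
        above_threshold=[i + 1 for i in idx0],
    )


def scan_table(result: ScanResult, substrate: AnnotatedSubstrate) -> pd.DataFrame:
    """Tidy per-bond table: id, bond, P1/P1' residues, raw and normalized
    scores, and the above-threshold flag."""
    above = set(result.above_threshold)
    rows = [{
        "sequence_id": result.sequence_id,
        "bond_index": bond,
        "P1_residue": substrate.residues[bond - 1],
        "P1prime_residue": substrate.residues[bond],
        "raw_score": result.bond_scores[bond - 1],
        "normalized_score": result.normalized_scores[bond - 1],
        "above_threshold": int(bond in above),
    } for bond in range(1, len(substrate))]
    return pd.DataFrame(rows)


def plot_scan(result: ScanResult, ax=None):
    """Normalized score vs bond position, with the top-fraction threshold."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    x = np.arange(1, len(result.normalized_scores) + 1)
    ax.plot(x, result.normalized_scores, lw=1.0, color="tab:green")
    ax.axhline(result.threshold_value, color="tab:blue", lw=0.8)
    ax.set_xlabel("bond position")
    ax.set_ylabel("normalized score")
    ax.set_title(result.sequence_id)
    return ax
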