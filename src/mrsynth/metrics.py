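"""Evaluation metrics for OOV detection, modeling, and prediction.

* Dice coefficient with a +1 denominator guard (2|A∧B| / (|A| + |B| + 1));
* fractional OOV remaining: sum|M - E|^2 / sum|E|^2 over the ground-truth
  echo range, reported as log10 with a floor at -12 for exact recovery
  (log10 = 0, i.e. M = 0, is the no-intervention baseline);
* fractional reduction in standard deviation: 1 - sigma(D - M)/sigma(D),
  with sigma the complex standard deviation over a caller-supplied window
  (the ground-truth-free in-vivo surrogate);
* detection confusion counts, where a prediction counts as "detected" iff
  its cluster-thresholded mask is nonempty;
* per-bin medians/IQRs over the eight echo-time bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TIME_BINS_MS",
    "EvaluationReport",
    "dice",
    "fractional_oov_remaining",
    "fractional_std_reduction",
    "detection_confusion",
    "assign_bin",
    "bin_report",
    "LOG10_FLOOR",
]

#: Echo-top time bins (ms); half-open [low, high) except the last (closed).
TIME_BINS_MS = (
    (10, 20),
    (20, 40),
    (40, 60),
    (60, 80),
    (80, 120),
    (120, 200),
    (200, 300),
    (300, 400),
)

LOG10_FLOOR = -12.0


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Overlap of two binary masks: 2|pred & truth| / (|pred| + |truth| + 1)."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    inter = int(np.sum(pred & truth))
    return 2.0 * inter / (int(pred.sum()) + int(truth.sum()) + 1)


def fractional_oov_remaining(
    model: np.ndarray,
    truth_echo: np.ndarray,
    truth_range: np.ndarray,
    return_log10: bool = False,
):
    """sum|M - E|^2 / sum|E|^2 over ``truth_range`` (bool mask or indices)."""
    m = np.asarray(model)[truth_range]
    e = np.asarray(truth_echo)[truth_range]
    if m.size == 0:
        raise ValueError("truth range is empty")
    denom = float(np.sum(np.abs(e) ** 2))
    if denom == 0.0:
        raise ValueError("ground-truth echo has zero energy in the range")
    frac = float(np.sum(np.abs(m - e) ** 2)) / denom
    if not return_log10:
        return frac
    log10 = LOG10_FLOOR if frac == 0.0 else max(np.log10(frac), LOG10_FLOOR)
    return frac, float(log10)


def fractional_std_reduction(data: np.ndarray, model: np.ndarray, window) -> float:
    """1 - sigma(D - M)/sigma(D) over ``window``.

    sigma is the complex standard deviation sqrt(E|x - mu|^2), which treats
    the real and imaginary parts jointly and is invariant under adding a
    (complex) constant to D and M together.
    """
    d = np.asarray(data)[window]
    m = np.asarray(model)[window]
    if d.size < 2:
        raise ValueError("window must contain at least 2 samples")

    def sigma(x):
        return float(np.std(x))

    sd = sigma(d)
    if sd == 0.0:
        raise ValueError("sigma(D) is zero; reduction undefined")
    return 1.0 - sigma(d - m) / sd


def detection_confusion(pred_masks, truth_labels) -> dict:
    """Confusion counts; a prediction is 'detected' iff its mask is nonempty.

    ``pred_masks`` are cluster-thresholded boolean masks (or anything with a
    truthy ``any()``); ``truth_labels`` are the ground-truth presence flags.
    """
    if len(pred_masks) != len(truth_labels):
        raise ValueError("prediction/label lengths differ")
    tp = fn = tn = fp = 0
    for mask, label in zip(pred_masks, truth_labels):
        detected = bool(np.any(mask))
        if label:
            tp += detected
            fn += not detected
        else:
            fp += detected
            tn += not detected
    n_pos, n_neg = tp + fn, tn + fp
    return {
        "tp": tp,
        "fn": fn,
        "tn": tn,
        "fp": fp,
        "detection_rate": tp / n_pos if n_pos else float("nan"),
        "false_positive_rate": fp / n_neg if n_neg else float("nan"),
    }


def assign_bin(tau_s: float) -> int:
    """Bin index (0-7) of an echo-top time in seconds."""
    tau_ms = tau_s * 1e3
    for i, (lo, hi) in enumerate(TIME_BINS_MS):
        last = i == len(TIME_BINS_MS) - 1
        if lo <= tau_ms < hi or (last and tau_ms == hi):
            return i
    raise ValueError(f"tau = {tau_ms:.3f} ms outside the 10-400 ms bins")


@dataclass
class EvaluationReport:
    """Per-example metrics plus per-bin aggregates."""

    per_example: pd.DataFrame
    per_bin: pd.DataFrame

    def to_csv(self, path) -> None:
        self.per_example.to_csv(path, index=False)


def bin_report(results: list[dict], tau_values) -> EvaluationReport:
    """Aggregate per-example metric dicts into per-bin medians and IQRs.

    ``results`` rows may carry any numeric fields (dice, log10_remaining,
    std_reduction, ...); each row is binned by its echo-top time.
    """
    rows = []
    for res, tau in zip(results, tau_values):
        row = dict(res)
        row["tau_s"] = float(tau)
        row["bin"] = assign_bin(tau)
        rows.append(row)
    per_example = pd.DataFrame(rows)
    metric_cols = [
        c for c in per_example.columns if c not in ("bin",) and np.issubdtype(per_example[c].dtype, np.number)
    ]
    agg_rows = []
    for i, (lo, hi) in enumerate(TIME_BINS_MS):
        sub = per_example[per_example["bin"] == i]
        row = {"bin": i, "lo_ms": lo, "hi_ms": hi, "n": len(sub)}
        for c in metric_cols:
            vals = sub[c].dropna()
            vals = vals[np.isfinite(vals)]
            row[f"{c}_median"] = float(vals.median()) if len(vals) else float("nan")
            row[f"{c}_iqr_lo"] = float(vals.quantile(0.25)) if len(vals) else float("nan")
            row[f"{c}_iqr_hi"] = float(vals.quantile(0.75)) if len(vals) else float("nan")
        agg_rows.append(row)
    return EvaluationReport(per_example=per_example, per_bin=pd.DataFrame(agg_rows))
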