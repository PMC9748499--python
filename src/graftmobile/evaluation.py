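"""Confusion metrics and benchmark sweeps over simulated cohorts."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .baselines import ThresholdConfig, classify_table_method_a, classify_table_method_b
from .inference import DEFAULT_LOG_BF_THRESHOLD, PriorHyperparameters, classify_heterograft
from .simulate import Cohort, SimulationConfig, simulate_cohort

__all__ = [
    "ConfusionTable",
    "confusion",
    "predict_cohort",
    "run_depth_sweep",
    "run_snp_sweep",
]

logger = logging.getLogger(__name__)

METHODS = ("bayes", "method_a", "method_b")


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tpr(self) -> float:
        """True positive rate; NaN (not 0) when there are no positives."""
        pos = self.tp + self.fn
        return self.tp / pos if pos > 0 else math.nan

    @property
    def fpr(self) -> float:
        neg = self.fp + self.tn
        return self.fp / neg if neg > 0 else math.nan

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total > 0 else math.nan

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def _as_positive(label) -> bool:
    if isinstance(label, (bool, np.bool_)):
        return bool(label)
    if isinstance(label, str):
        if label in ("mobile", "positive", "1", "true", "True"):
            return True
        if label in ("non-mobile", "negative", "0", "false", "False"):
            return False
        raise ValueError(f"unrecognised label {label!r}")
    return bool(label)


def _as_mapping(labels) -> dict:
    if isinstance(labels, pd.DataFrame):
        return dict(zip(labels["transcript_id"], labels["label"]))
    if isinstance(labels, pd.Series):
        return labels.to_dict()
    return dict(labels)


def confusion(true_labels, predicted_labels) -> ConfusionTable:
    """Confusion counts over matched transcript keys.

    Both arguments are mappings ``transcript_id -> label`` (or data frames
    with ``transcript_id``/``label`` columns). The key sets must coincide;
    any discrepancy is reported explicitly.
    """
    truth = _as_mapping(true_labels)
    pred = _as_mapping(predicted_labels)
    missing = sorted(set(truth) - set(pred))
    extra = sorted(set(pred) - set(truth))
    if missing or extra:
        raise ValueError(
            f"label key mismatch: missing from predictions {missing[:10]}, "
            f"unexpected in predictions {extra[:10]}"
        )
    tp = fp = tn = fn = 0
    for key, t in truth.items():
        t_pos = _as_positive(t)
        p_pos = _as_positive(pred[key])
        if t_pos and p_pos:
            tp += 1
        elif t_pos and not p_pos:
            fn += 1
        elif not t_pos and p_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# Cohort classification and sweeps
# ---------------------------------------------------------------------------


def predict_cohort(
    cohort: Cohort,
    method: str,
    *,
    threshold: float = DEFAULT_LOG_BF_THRESHOLD,
    threshold_config: ThresholdConfig | None = None,
    prior: PriorHyperparameters | None = None,
    two_rate: bool = True,
) -> pd.DataFrame:
    """Per-transcript labels for one cohort under the requested method."""
    if method == "bayes":
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            per_tx, _ = classify_heterograft(
                cohort.heterograft,
                cohort.homograft_local,
                cohort.homograft_distal if two_rate else None,
                prior=prior,
                threshold=threshold,
            )
        out = per_tx[["transcript_id", "label"]].copy()
        out["method"] = "bayes"
        return out
    if method == "method_a":
        return classify_table_method_a(cohort.heterograft, threshold_config)
    if method == "method_b":
        return classify_table_method_b(
            cohort.homograft_local, cohort.heterograft, threshold_config
        )
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def _metric_row(ct: ConfusionTable) -> dict:
    return {
        "tp": ct.tp,
        "fp": ct.fp,
        "tn": ct.tn,
        "fn": ct.fn,
        "tpr": ct.tpr,
        "fpr": ct.fpr,
        "accuracy": ct.accuracy,
    }


def run_depth_sweep(
    depths: Sequence[int],
    base_config: SimulationConfig,
    methods: Iterable[str] = METHODS,
    repetitions: int = 1,
    *,
    seed: int = 0,
    homograft_depth: int | None = None,
    threshold: float = DEFAULT_LOG_BF_THRESHOLD,
    threshold_config: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Accuracy of each method across heterograft read depths.

    For each depth, ``repetitions`` independent cohorts are simulated from
    seeds derived deterministically from ``seed`` and the grid index, every
    method is run on each cohort, and confusion counts are pooled across
    repetitions. ``homograft_depth=None`` ties the homograft depth to the
    heterograft depth; an integer fixes it. Failures at a grid point are
    logged and the sweep continues.
    """
    depths = list(depths)
    if not depths:
        raise ValueError("depth grid must be non-empty")
    methods = list(methods)
    rows = []
    for gi, depth in enumerate(depths):
        n_hom = depth if homograft_depth is None else homograft_depth
        totals = {m: ConfusionTable(0, 0, 0, 0) for m in methods}
        try:
            for rep in range(repetitions):
                cfg = base_config.replace(
                    heterograft_depth=int(depth),
                    homograft_depth=int(n_hom),
                    seed=int(np.random.SeedSequence((seed, gi, rep)).generate_state(1)[0]),
                )
                cohort = simulate_cohort(cfg)
                truth = cohort.labels
                for m in methods:
                    pred = predict_cohort(
                        cohort,
                        m,
                        threshold=threshold,
                        threshold_config=threshold_config,
                    )
                    totals[m] = totals[m] + confusion(truth, pred)
        except Exception:  # pragma: no cover - defensive, sweep continues
            logger.exception("depth sweep failed at N=%s; point skipped", depth)
            continue
        for m in methods:
            rows.append(
                {
                    "method": m,
                    "heterograft_depth": depth,
                    "homograft_depth": n_hom,
                    "mobile_reads": base_config.mobile_reads,
                    "error_rate": base_config.error_rate,
                    "repetitions": repetitions,
                    "seed": seed,
                    **_metric_row(totals[m]),
                }
            )
    return pd.DataFrame(rows)


def run_snp_sweep(
    snp_counts: Sequence[int],
    base_config: SimulationConfig,
    repetitions: int = 1,
    *,
    seed: int = 0,
    threshold: float = DEFAULT_LOG_BF_THRESHOLD,
) -> pd.DataFrame:
    """Bayes-classifier TPR/FPR versus the number of SNPs per transcript."""
    snp_counts = list(snp_counts)
    if not snp_counts or min(snp_counts) < 1:
        raise ValueError("snp_counts must be a non-empty list of integers >= 1")
    rows = []
    for gi, k in enumerate(snp_counts):
        total = ConfusionTable(0, 0, 0, 0)
        for rep in range(repetitions):
            cfg = base_config.replace(
                snps_per_transcript=int(k),
                seed=int(np.random.SeedSequence((seed, gi, rep)).generate_state(1)[0]),
            )
            cohort = simulate_cohort(cfg)
            pred = predict_cohort(cohort, "bayes", threshold=threshold)
            total = total + confusion(cohort.labels, pred)
        rows.append(
            {
                "method": "bayes",
                "n_snps": k,
                "heterograft_depth": base_config.heterograft_depth,
                "homograft_depth": base_config.homograft_depth,
                "mobile_reads": base_config.mobile_reads,
                "error_rate": base_config.error_rate,
                "repetitions": repetitions,
                "seed": seed,
                **_metric_row(total),
            }
        )
    return pd.DataFrame(rows)
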