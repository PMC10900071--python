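"""Score-based OOD evaluation: AUC, thresholds, summaries, FP-count analysis.

Scores live in a long-format pandas table with columns
``volume_id, group_label, score_name, score_value``; group labels are
``in_distribution``, ``near_ood:<subclass>`` or ``far_ood:<subclass>``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ThresholdPolicy", "score_table", "auc", "ood_decision",
    "summarise_by_class", "likelihood_vs_fp",
]

SCORE_COLUMNS = ["volume_id", "group_label", "score_name", "score_value"]


def score_table(rows: list[tuple]) -> pd.DataFrame:
    """Build a validated score table from (volume_id, group_label, name, value) rows."""
    df = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    dup = df.duplicated(subset=["volume_id", "score_name"])
    if dup.any():
        raise ValueError(f"duplicate (volume_id, score_name) pairs: "
                         f"{df.loc[dup, 'volume_id'].tolist()[:5]}")
    return df


def auc(in_scores, ood_scores, direction: str = "low_is_ood") -> float:
    """Probability a random in-distribution/OOD pair is correctly ordered.

    Mann-Whitney construction with ties counting one half. ``direction``
    says which tail marks OOD: ``low_is_ood`` for log-likelihoods,
    ``high_is_ood`` for reconstruction error.
    """
    a = np.asarray(in_scores, dtype=np.float64)
    b = np.asarray(ood_scores, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score lists must be nonempty")
    if direction not in ("low_is_ood", "high_is_ood"):
        raise ValueError(f"unknown direction {direction!r}")
    ranks = stats.rankdata(np.concatenate([a, b]))
    # P(in > ood) + 0.5 * P(in == ood)
    u = ranks[:a.size].sum() - a.size * (a.size + 1) / 2.0
    p_in_above = u / (a.size * b.size)
    return float(p_in_above if direction == "low_is_ood" else 1.0 - p_in_above)


@dataclass(frozen=True)
class ThresholdPolicy:
    """Either an absolute log-likelihood cut or a percentile of training scores."""

    kind: str           # 'absolute' | 'training_percentile'
    value: float

    def __post_init__(self):
        if self.kind not in ("absolute", "training_percentile"):
            raise ValueError("kind must be 'absolute' or 'training_percentile'")
        if self.kind == "training_percentile" and not 0.0 < self.value < 100.0:
            raise ValueError("percentile must lie in (0, 100)")


def ood_decision(logliks: dict[str, float], policy: ThresholdPolicy,
                 training_scores=None) -> dict[str, bool]:
    """One-sided rule: flag a volume OOD iff its log-likelihood < threshold."""
    if policy.kind == "training_percentile":
        if training_scores is None or len(training_scores) == 0:
            raise ValueError("percentile policy requires training scores")
        threshold = float(np.percentile(np.asarray(training_scores, dtype=np.float64),
                                        policy.value))
    else:
        threshold = float(policy.value)
    return {vid: bool(score < threshold) for vid, score in logliks.items()}


def summarise_by_class(scores: pd.DataFrame, score_name: str = "loglik",
                       direction: str = "low_is_ood") -> pd.DataFrame:
    """Per-class mean (sd) of one score plus AUC against the in-distribution group.

    By convention the in-distribution row reports AUC 0.5 (it cannot be
    separated from itself).
    """
    df = scores[scores["score_name"] == score_name]
    if "in_distribution" not in set(df["group_label"]):
        raise ValueError("no in_distribution group present")
    in_vals = df.loc[df["group_label"] == "in_distribution", "score_value"].to_numpy()
    rows = []
    for label, grp in df.groupby("group_label", sort=True):
        vals = grp["score_value"].to_numpy()
        a = 0.5 if label == "in_distribution" else auc(in_vals, vals, direction)
        rows.append({"group_label": label, "n": len(vals),
                     "mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                     "auc_vs_in_distribution": a})
    return pd.DataFrame(rows)


def likelihood_vs_fp(scores: pd.DataFrame, fp_counts: dict[str, int],
                     score_name: str = "loglik") -> tuple[pd.DataFrame, float, bool]:
    """Join per-volume log-likelihoods with FP lesion counts; Spearman rank rho.

    Returns (joined table, rho, defined). ``defined`` is False (rho = nan)
    when either variable is constant.
    """
    df = scores[scores["score_name"] == score_name]
    ids_scores = set(df["volume_id"])
    ids_fp = set(fp_counts)
    if ids_scores != ids_fp:
        raise ValueError(
            f"volume id mismatch; scores-only={sorted(ids_scores - ids_fp)[:5]}, "
            f"fp-only={sorted(ids_fp - ids_scores)[:5]}")
    joined = df[["volume_id", "group_label", "score_value"]].rename(
        columns={"score_value": "loglik"}).copy()
    joined["fp_count"] = joined["volume_id"].map(fp_counts)
    ll = joined["loglik"].to_numpy()
    fp = joined["fp_count"].to_numpy(dtype=np.float64)
    if np.all(ll == ll[0]) or np.all(fp == fp[0]):
        return joined, float("nan"), False
    rho = float(stats.spearmanr(ll, fp).statistic)
    return joined, rho, True
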