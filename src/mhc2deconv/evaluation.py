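"""Performance metrics and benchmark comparison.

Per-molecule (or per-sample) evaluation uses three metrics: AUC, AUC 0.1 (ROC
area integrated to a false-positive rate of 10%, normalized so a perfect
classifier scores 1) and PPV (fraction of true positives among the top-N
predictions, N = number of positives for the unit).  Method-vs-method
comparisons use one-tailed binomial sign tests excluding ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hla import locus_of

MIN_POSITIVES = 10


def auc(pos_scores, neg_scores) -> float | None:
    """ROC AUC as the Mann-Whitney statistic (ties count 1/2) over n_pos*n_neg."""
    pos = np.asarray(pos_scores, dtype=np.float64)
    neg = np.asarray(neg_scores, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        return None
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _roc_curve(pos: np.ndarray, neg: np.ndarray):
    """ROC staircase vertices at distinct thresholds (descending scores),
    starting from (0, 0)."""
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.argsort(-scores, kind="mergesort")
    scores, labels = scores[order], labels[order]
    distinct = np.nonzero(np.diff(scores))[0]
    idx = np.r_[distinct, scores.size - 1]
    tps = np.cumsum(labels)[idx]
    fps = np.cumsum(1 - labels)[idx]
    tpr = np.r_[0.0, tps / pos.size]
    fpr = np.r_[0.0, fps / neg.size]
    return fpr, tpr


def auc01(pos_scores, neg_scores, max_fpr: float = 0.1, normalize: bool = True) -> float | None:
    """Trapezoidal ROC area over FPR in [0, max_fpr]; divided by max_fpr when
    ``normalize`` so the perfect classifier scores 1."""
    pos = np.asarray(pos_scores, dtype=np.float64)
    neg = np.asarray(neg_scores, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        return None
    fpr, tpr = _roc_curve(pos, neg)
    if fpr[-1] > max_fpr:
        i = int(np.searchsorted(fpr, max_fpr, side="right"))
        # interpolate the staircase segment crossing max_fpr
        t = (max_fpr - fpr[i - 1]) / (fpr[i] - fpr[i - 1])
        tpr_cut = tpr[i - 1] + t * (tpr[i] - tpr[i - 1])
        fpr = np.r_[fpr[:i], max_fpr]
        tpr = np.r_[tpr[:i], tpr_cut]
    area = float(np.trapezoid(tpr, fpr))
    return area / max_fpr if normalize else area


def ppv(scores, labels, n_top: int | None = None) -> float | None:
    """Positive fraction among the top-N predictions (stable sort: ties keep
    input order).  N defaults to the number of positives."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    if n_pos == 0:
        return None
    n = n_top if n_top is not None else n_pos
    order = np.argsort(-scores, kind="stable")[:n]
    return float(np.mean(labels[order] == 1))


@dataclass
class MetricReport:
    unit: str
    n_pos: int
    n_neg: int
    auc: float | None
    auc01: float | None
    ppv: float | None


def evaluate_cv(
    annotations: pd.DataFrame,
    min_positives: int = MIN_POSITIVES,
    by: str = "molecule",
) -> pd.DataFrame:
    """Per-molecule (or per-sample) metrics from annotated cross-validation
    predictions.

    ``annotations`` needs columns ``score``, ``target`` and the grouping column
    (default ``molecule`` — positives and negatives are pooled by the molecule
    they were assigned to).  Units with fewer than ``min_positives`` positives,
    or without negatives, are excluded.
    """
    rows = []
    for unit, grp in annotations.groupby(by, sort=True):
        pos = grp.loc[grp["target"] == 1, "score"].to_numpy()
        neg = grp.loc[grp["target"] == 0, "score"].to_numpy()
        if pos.size < min_positives or neg.size == 0:
            continue
        rows.append(
            {
                by: unit,
                "n_pos": pos.size,
                "n_neg": neg.size,
                "auc": auc(pos, neg),
                "auc01": auc01(pos, neg),
                "ppv": ppv(
                    np.concatenate([pos, neg]),
                    np.r_[np.ones(pos.size), np.zeros(neg.size)],
                ),
            }
        )
    return pd.DataFrame(rows, columns=[by, "n_pos", "n_neg", "auc", "auc01", "ppv"])


def aggregate_by_locus(report: pd.DataFrame) -> pd.DataFrame:
    """Mean metrics over molecule subsets defined by locus."""
    rep = report.copy()
    rep["locus"] = rep["molecule"].map(locus_of)
    return rep.groupby("locus")[["auc", "auc01", "ppv"]].mean().reset_index()


def sign_test(wins: int, losses: int) -> float | None:
    """One-tailed binomial sign test excluding ties: P(X >= wins | n, 1/2).

    Returns None when there are no informative (non-tied) comparisons.
    """
    n = wins + losses
    if n == 0:
        return None
    return float(stats.binom.sf(wins - 1, n, 0.5))


def read_external_ranks(path) -> pd.DataFrame:
    """External predictor's per-peptide percentile ranks:
    ``peptide<TAB>sample<TAB>molecule<TAB>rank``."""
    df = pd.read_csv(path, sep="\t", header=None, names=["peptide", "sample_id", "molecule", "rank"])
    df["rank"] = df["rank"].astype(float)
    return df


def benchmark_compare(
    ours: pd.DataFrame,
    external: pd.DataFrame,
    metrics: tuple[str, ...] = ("auc", "auc01", "ppv"),
    key: str = "sample_id",
) -> dict:
    """Paired per-sample comparison of two per-sample metric tables.

    Both frames must carry the same ``key`` values (error lists missing keys).
    Returns per-metric wins/losses/ties (wins = ours strictly better) and the
    one-tailed sign-test p-value excluding ties.
    """
    ours_keys = set(ours[key])
    ext_keys = set(external[key])
    if ours_keys != ext_keys:
        missing = sorted(ours_keys ^ ext_keys)
        raise ValueError(f"mismatched {key} sets between methods: {missing}")
    merged = ours.merge(external, on=key, suffixes=("_ours", "_ext"))
    out = {"n": len(merged), "per_sample": merged, "tests": {}}
    for m in metrics:
        a, b = merged[f"{m}_ours"], merged[f"{m}_ext"]
        wins = int((a > b).sum())
        losses = int((a < b).sum())
        out["tests"][m] = {
            "wins": wins,
            "losses": losses,
            "ties": int((a == b).sum()),
            "p_value": sign_test(wins, losses),
        }
    return out
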