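"""Decision rules and error metrics for multiple hypothesis testing.

The classifier route rejects test i when p_hat_i > 1 - q, where q is the
FDR level to control.  The Benjamini-Hochberg step-up procedure on p-values
is the benchmark.  Observed error proportions (FPR: false rejections among
rejections; FNP: missed alternatives among non-rejections) and the
Mann-Whitney formulation of the ROC AUC quantify performance when ground
truth is known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata

__all__ = [
    "MHTResult",
    "decide",
    "benjamini_hochberg",
    "roc_auc",
    "error_rates",
    "write_results_tsv",
]


def decide(p_hat, q: float, ids=None) -> np.ndarray:
    """Ids (or indices) with p_hat > 1 - q; monotone in q by construction."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly between 0 and 1")
    p_hat = np.asarray(p_hat, float)
    idx = np.where(p_hat > 1.0 - q)[0]
    if ids is None:
        return idx
    return np.asarray(ids)[idx]


def benjamini_hochberg(pvalues, q: float = 0.05):
    """Step-up BH: adjusted_(i) = min_{j>=i} m p_(j)/j (capped at 1);
    reject every test with adjusted p <= q.  Returns (adjusted, rejected
    indices)."""
    pvalues = np.asarray(pvalues, float)
    if ((pvalues < 0) | (pvalues > 1)).any() or not np.isfinite(pvalues).all():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly between 0 and 1")
    m = len(pvalues)
    order = np.argsort(pvalues, kind="stable")
    ranked = pvalues[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    rejected = np.where(adjusted <= q)[0]
    return adjusted, rejected


def roc_auc(scores, labels, orientation: str = "greater") -> dict:
    """AUC by the rank (Mann-Whitney) formulation with midrank ties, plus the
    ROC polygon.  ``orientation='greater'`` means larger scores indicate the
    alternative (p-hat); ``'less'`` means smaller scores do (p-values)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if orientation not in ("greater", "less"):
        raise ValueError("orientation must be 'greater' or 'less'")
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    s = scores if orientation == "greater" else -scores
    ranks = rankdata(s)  # midranks
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1)
    # ROC polygon over descending score thresholds
    order = np.argsort(-s, kind="stable")
    lab = labels[order]
    tps = np.cumsum(lab)
    fps = np.cumsum(1 - lab)
    keep = np.r_[np.diff(s[order]) != 0, True]  # collapse tied thresholds
    roc = np.column_stack([np.r_[0.0, fps[keep] / n0], np.r_[0.0, tps[keep] / n1]])
    return {"auc": float(auc), "roc": roc}


def error_rates(rejected, labels, ids=None) -> dict:
    """Observed FPR and FNP of a rejection set.

    fpr = false rejections / rejections, fnp = missed alternatives /
    non-rejections; a ratio with empty denominator is 0.
    """
    labels = np.asarray(labels, int)
    m = len(labels)
    mask = np.zeros(m, bool)
    if ids is not None:
        lookup = {str(t): i for i, t in enumerate(np.asarray(ids, dtype=str))}
        for r in rejected:
            mask[lookup[str(r)]] = True
    else:
        mask[np.asarray(list(rejected), int)] = True
    n_rej = int(mask.sum())
    false_rej = int((mask & (labels == 0)).sum())
    missed = int((~mask & (labels == 1)).sum())
    n_nonrej = m - n_rej
    return {
        "fpr": false_rej / n_rej if n_rej else 0.0,
        "fnp": missed / n_nonrej if n_nonrej else 0.0,
    }


@dataclass
class MHTResult:
    """Per-test alternative probabilities, a decision set at level q, and
    (when ground truth is available) error metrics."""

    ids: np.ndarray
    p_hat: np.ndarray
    q: float
    rejected: np.ndarray = field(init=False)
    metrics: dict | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=str)
        self.p_hat = np.asarray(self.p_hat, float)
        self.rejected = decide(self.p_hat, self.q, ids=self.ids)

    def attach_metrics(self, labels) -> "MHTResult":
        labels = np.asarray(labels, int)
        self.metrics = dict(error_rates(self.rejected, labels, ids=self.ids))
        self.metrics.update(auc=roc_auc(self.p_hat, labels)["auc"])
        return self

    def to_frame(self) -> pd.DataFrame:
        rej = np.isin(self.ids, self.rejected).astype(int)
        return pd.DataFrame({"id": self.ids, "p_hat": self.p_hat, "rejected": rej})


def write_results_tsv(result: MHTResult, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(directory / "results.tsv", sep="\t", index=False)
    if result.metrics is not None:
        with open(directory / "metrics.yaml", "w") as fh:
            yaml.safe_dump({k: float(v) for k, v in result.metrics.items()}, fh)
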