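"""Unscaled Bayes factors and the ordered relative-evidence (W) sequence.

The two-sample normal testing problem compares, per test i,

    H0: mu_X = mu_Y        vs        H1: mu_X != mu_Y,

with a common unknown standard deviation sigma.  Under the objective improper
priors used here (flat on the common location, flat on the standardized mean
shift delta/sigma, right-invariant 1/sigma on the scale) the ratio of marginal
likelihoods has the closed form

    log B = 1/2 log(2 pi N / (n_x n_y)) + (N-1)/2 * log(1 + t^2 / (N-2)),

with N = n_x + n_y and t the pooled-variance two-sample t statistic.  B is
"unscaled": improper priors leave an arbitrary positive constant c undefined,
so individual magnitudes mean nothing, but the ordering of the B_i across a
battery of tests — and ratios B_i/B_j — are well defined.  All arithmetic is
carried in log space.

Sorting the m log-BFs ascending and taking first differences gives the
relative-evidence sequence W (W_1 is fixed to the sentinel value 1).  W is
invariant to the unknown constant c, and its level shifts at the boundary
between null-dominated and alternative-dominated positions, which is the
signal the convolutional classifier in :mod:`mhtcnn.classifier` is trained
to find.

P-values can enter the same pipeline through the universal lower bound on the
Bayes factor,  B >= [-e * p * ln(p)]^{-1}  for p < 1/e  (and 1 otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TestBattery",
    "EvidenceSpec",
    "EvidenceSequence",
    "unscaled_bf_normal",
    "unscaled_log_bf_battery",
    "bf_lower_bound",
    "build_w_sequence",
    "read_evidence_tsv",
    "write_evidence_tsv",
]

_PV_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TestBattery:
    """Raw per-test two-sample data, optionally with ground-truth labels.

    ``x`` and ``y`` are (m, n_x) and (m, n_y) arrays: row i holds the two
    samples of test i.  ``labels`` (0 = null, 1 = alternative) are known for
    simulated batteries and absent for real data.  ``meta`` records
    provenance (seed, scenario parameters).
    """

    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=str)
        self.x = np.atleast_2d(np.asarray(self.x, float))
        self.y = np.atleast_2d(np.asarray(self.y, float))
        m = len(self.ids)
        if self.x.shape[0] != m or self.y.shape[0] != m:
            raise ValueError("ids, x and y must agree on the number of tests")
        if self.x.shape[1] < 2 or self.y.shape[1] < 2:
            raise ValueError("every test needs n_x >= 2 and n_y >= 2 replicates")
        if len(np.unique(self.ids)) != m:
            raise ValueError("test ids must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, int)
            if self.labels.shape != (m,):
                raise ValueError("labels must have one entry per test")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be 0 or 1")

    @property
    def m(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class EvidenceSpec:
    """Which marginal-likelihood model turns raw samples into evidence.

    ``two_sample_normal_common_variance`` is the closed form documented in
    the module docstring; ``pvalue_lower_bound`` routes p-values through the
    -e p log p bound.  ``options['heteroskedastic']`` switches to a
    Behrens-Fisher variant evaluated by numerical integration (flat priors on
    both means, 1/sigma on each scale).
    """

    model: str = "two_sample_normal_common_variance"
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in ("two_sample_normal_common_variance", "pvalue_lower_bound"):
            raise ValueError(f"unknown evidence model {self.model!r}")


@dataclass
class EvidenceSequence:
    """Ascending-ordered log evidence with permutation bookkeeping.

    ``order[k]`` is the original index of the test at sorted position k, so
    ``vector_sorted = vector[order]`` and the inverse permutation restores
    original id order.  ``w`` holds the sentinel 1 at position 0 and the
    non-negative first differences of ``log_bf_sorted`` after it.
    """

    log_bf_sorted: np.ndarray
    order: np.ndarray
    w: np.ndarray
    ids_sorted: np.ndarray
    labels_sorted: np.ndarray | None = None

    @property
    def m(self) -> int:
        return len(self.w)

    def inverse_order(self) -> np.ndarray:
        inv = np.empty_like(self.order)
        inv[self.order] = np.arange(len(self.order))
        return inv

    def to_original_order(self, sorted_values: np.ndarray) -> np.ndarray:
        """Map a vector aligned to sorted positions back to original test order."""
        sorted_values = np.asarray(sorted_values)
        if sorted_values.shape[0] != self.m:
            raise ValueError("length mismatch with the evidence sequence")
        return sorted_values[self.inverse_order()]


# ---------------------------------------------------------------------------
# unscaled BF for the two-sample normal problem
# ---------------------------------------------------------------------------

def _log_bf_from_stats(t2: np.ndarray, nx: int, ny: int) -> np.ndarray:
    n_tot = nx + ny
    return 0.5 * np.log(2.0 * np.pi * n_tot / (nx * ny)) + \
        0.5 * (n_tot - 1) * np.log1p(t2 / (n_tot - 2))


def unscaled_bf_normal(x, y, spec: EvidenceSpec | None = None) -> float:
    """Log unscaled Bayes factor of H1 (different means) against H0.

    Strictly increasing in |t| (pooled two-sample t) at fixed sample sizes;
    its minimum over datasets with given sizes is attained at t = 0.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two replicates per sample")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input samples")
    if spec is not None and spec.options.get("heteroskedastic"):
        return _log_bf_behrens_fisher(x, y)
    nx, ny = len(x), len(y)
    ss = float(((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum())
    if ss == 0.0:
        raise ValueError("zero residual variability: all x and y values identical")
    t2 = (x.mean() - y.mean()) ** 2 / (ss / (nx + ny - 2) * (1 / nx + 1 / ny))
    return float(_log_bf_from_stats(np.asarray(t2), nx, ny))


def unscaled_log_bf_battery(battery: TestBattery, spec: EvidenceSpec | None = None) -> np.ndarray:
    """Vectorised log unscaled BFs for every test of a battery."""
    if spec is not None and spec.options.get("heteroskedastic"):
        return np.array([_log_bf_behrens_fisher(xi, yi)
                         for xi, yi in zip(battery.x, battery.y)])
    x, y = battery.x, battery.y
    nx, ny = x.shape[1], y.shape[1]
    ss = ((x - x.mean(1, keepdims=True)) ** 2).sum(1) + \
         ((y - y.mean(1, keepdims=True)) ** 2).sum(1)
    if (ss == 0).any():
        bad = battery.ids[np.where(ss == 0)[0][0]]
        raise ValueError(f"zero residual variability in test {bad!r}")
    t2 = (x.mean(1) - y.mean(1)) ** 2 / (ss / (nx + ny - 2) * (1 / nx + 1 / ny))
    return _log_bf_from_stats(t2, nx, ny)


def _log_bf_behrens_fisher(x: np.ndarray, y: np.ndarray, n_nodes: int = 120) -> float:
    """Heteroskedastic (Behrens-Fisher) unscaled log-BF by Gauss-Legendre
    quadrature, with flat priors on both means and 1/sigma on each scale.

    Under H1 the two populations decouple, so the numerator is a product of
    two 2D integrals; the denominator (common mean) is a 3D integral over
    (mu, log sigma_x, log sigma_y).
    """
    from scipy.special import logsumexp

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sd = np.concatenate([x, y]).std(ddof=1)
    if sd == 0:
        raise ValueError("zero residual variability: all x and y values identical")
    xu, wu = np.polynomial.legendre.leggauss(n_nodes)
    u = xu * 10.0
    lwu = np.log(wu * 10.0)
    z = xu * 9.0 + np.log(sd)
    lwz = np.log(wu * 9.0)
    sig = np.exp(z)

    def _pop_logml(v: np.ndarray) -> float:
        # int N(v | mu, s) dmu ds/s  via mu = vbar + s*u, s = e^z
        n = len(v)
        vc = (v - v.mean())[:, None, None]
        e = -0.5 * ((vc / sig[None, None, :] - u[:, None, None].transpose(1, 0, 2)) ** 2).sum(0)
        ln = -n / 2 * np.log(2 * np.pi * sig ** 2)[None, :] + e + lwu[:, None] + lwz[None, :] \
            + np.log(sig)[None, :]
        return float(logsumexp(ln))

    log_m1 = _pop_logml(x) + _pop_logml(y)

    # H0: common mean; mu = grand mean + sd*u
    g = np.concatenate([x, y]).mean()
    xc = (x - g)[:, None, None, None]
    yc = (y - g)[:, None, None, None]
    sx = sig[None, :, None]
    sy = sig[None, None, :]
    mu_off = (sd * u)[:, None, None]
    ex = -0.5 * ((xc - mu_off[None]) ** 2 / sx[None] ** 2).sum(0) - len(x) * np.log(sx[0] * np.sqrt(2 * np.pi))
    ey = -0.5 * ((yc - mu_off[None]) ** 2 / sy[None] ** 2).sum(0) - len(y) * np.log(sy[0] * np.sqrt(2 * np.pi))
    ln0 = ex + ey + np.log(sd) + lwu[:, None, None] + lwz[None, :, None] + lwz[None, None, :]
    log_m0 = float(logsumexp(ln0))
    return log_m1 - log_m0


# ---------------------------------------------------------------------------
# p-value calibration (lower bound on the Bayes factor)
# ---------------------------------------------------------------------------

def bf_lower_bound(pv, floor: float = _PV_FLOOR):
    """Lower bound on the Bayes factor implied by a p-value.

    ``[-e * pv * ln(pv)]^{-1}`` for pv < 1/e and 1 otherwise; continuous at
    pv = 1/e, non-increasing on (0, 1/e).  Non-positive p-values are clamped
    to ``floor`` with a warning (the bound diverges as pv -> 0).
    """
    scalar = np.isscalar(pv)
    pv = np.atleast_1d(np.asarray(pv, float))
    if (pv > 1).any():
        raise ValueError("p-values must not exceed 1")
    if not np.isfinite(pv).all():
        raise ValueError("non-finite p-values")
    if (pv <= 0).any():
        warnings.warn(
            f"non-positive p-values clamped to {floor:g}; the Bayes-factor "
            "lower bound diverges as pv -> 0", RuntimeWarning, stacklevel=2)
        pv = np.maximum(pv, floor)
    out = np.ones_like(pv)
    small = pv < np.exp(-1.0)
    out[small] = 1.0 / (-np.e * pv[small] * np.log(pv[small]))
    return float(out[0]) if scalar else out


def log_bf_lower_bound(pv, floor: float = _PV_FLOOR):
    """Log of :func:`bf_lower_bound`, computed without overflow."""
    scalar = np.isscalar(pv)
    pv = np.atleast_1d(np.asarray(pv, float))
    if (pv > 1).any():
        raise ValueError("p-values must not exceed 1")
    if not np.isfinite(pv).all():
        raise ValueError("non-finite p-values")
    if (pv <= 0).any():
        warnings.warn(
            f"non-positive p-values clamped to {floor:g}; the Bayes-factor "
            "lower bound diverges as pv -> 0", RuntimeWarning, stacklevel=2)
        pv = np.maximum(pv, floor)
    out = np.zeros_like(pv)
    small = pv < np.exp(-1.0)
    out[small] = -1.0 - np.log(pv[small]) - np.log(-np.log(pv[small]))
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# the W sequence
# ---------------------------------------------------------------------------

def build_w_sequence(log_bfs, ids=None, labels=None) -> EvidenceSequence:
    """Sort log-BFs ascending and form W = (1, diff(log_bf_sorted)).

    The sort is stable (ties keep original index order) so the result is
    deterministic.  Any constant added to all log-BFs — the unknown
    normalisation c of the improper priors — cancels in the differences.
    """
    log_bfs = np.asarray(log_bfs, float)
    m = len(log_bfs)
    if m < 2:
        raise ValueError("need at least two tests to build a W sequence")
    if ids is None:
        ids = np.array([str(i) for i in range(m)])
    ids = np.asarray(ids, dtype=str)
    if len(ids) != m:
        raise ValueError("ids and log_bfs must have the same length")
    if not np.isfinite(log_bfs).all():
        bad = ids[np.where(~np.isfinite(log_bfs))[0][0]]
        raise ValueError(f"non-finite log Bayes factor for test {bad!r}")
    order = np.argsort(log_bfs, kind="stable")
    lb = log_bfs[order]
    w = np.empty(m)
    w[0] = 1.0  # fixed sentinel, not data
    w[1:] = np.diff(lb)
    labels_sorted = None
    if labels is not None:
        labels = np.asarray(labels, int)
        if len(labels) != m:
            raise ValueError("labels and log_bfs must have the same length")
        labels_sorted = labels[order]
    return EvidenceSequence(log_bf_sorted=lb, order=order, w=w,
                            ids_sorted=ids[order], labels_sorted=labels_sorted)


def ordered_pvalue_sequence(pvalues, ids=None, labels=None) -> EvidenceSequence:
    """Descending-ordered p-values as an evidence sequence (weakest evidence
    first, matching the ascending-BF convention).  ``w`` holds the ordered
    p-values themselves; ``log_bf_sorted`` the matching lower-bound log-BFs.
    """
    pvalues = np.asarray(pvalues, float)
    m = len(pvalues)
    if m < 2:
        raise ValueError("need at least two tests")
    if ids is None:
        ids = np.array([str(i) for i in range(m)])
    ids = np.asarray(ids, dtype=str)
    order = np.argsort(-pvalues, kind="stable")
    labels_sorted = None if labels is None else np.asarray(labels, int)[order]
    return EvidenceSequence(
        log_bf_sorted=log_bf_lower_bound(np.maximum(pvalues[order], _PV_FLOOR)),
        order=order,
        w=pvalues[order],
        ids_sorted=ids[order],
        labels_sorted=labels_sorted,
    )


# ---------------------------------------------------------------------------
# evidence table I/O
# ---------------------------------------------------------------------------

def read_evidence_tsv(path) -> pd.DataFrame:
    """Read a per-test evidence table: column ``id`` plus exactly one of
    ``log_bf`` or ``pvalue`` (tab-separated, header required)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'id'")
    has = [c for c in ("log_bf", "pvalue") if c in df.columns]
    if len(has) != 1:
        raise ValueError(f"{path}: need exactly one of columns 'log_bf' or 'pvalue'")
    if df["id"].duplicated().any():
        raise ValueError(f"{path}: duplicate test ids")
    return df


def write_evidence_tsv(path, ids, log_bf=None, pvalue=None) -> None:
    if (log_bf is None) == (pvalue is None):
        raise ValueError("provide exactly one of log_bf or pvalue")
    col, vals = ("log_bf", log_bf) if log_bf is not None else ("pvalue", pvalue)
    pd.DataFrame({"id": np.asarray(ids, dtype=str), col: np.asarray(vals, float)}) \
        .to_csv(path, sep="\t", index=False)
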