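"""Seeded simulation of two-sample test batteries.

The canonical training battery — m = 10,000 independent tests with
n_x = n_y = 10 replicates, unit variances, 9,000 nulls (both means 0) and
1,000 alternatives (second-population mean 3) — is what the sequence
classifier is trained on once.  The scenario grid varies signal strength
(mu_alt in 1..4), sample size (n in 3..10), heteroskedasticity (sigma in
1..3), null proportion (0.9, 0.95, 0.99), battery size (1,000 or 10,000)
and dependence (independent tests, or blocks of 2/5/10 tests whose values
are correlated through a randomly drawn positive-semidefinite correlation
matrix with Uniform(-1,1) off-diagonal draws).

All generation is driven by ``numpy.random.Generator`` streams spawned from
the scenario seed, so identical configurations reproduce bitwise-identical
batteries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .bf import TestBattery

__all__ = [
    "ScenarioConfig",
    "CorrelationBlock",
    "make_training_battery",
    "generate_battery",
    "random_correlation_matrix",
    "welch_pvalues",
    "save_battery",
    "load_battery",
    "CANONICAL",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation grid, fully seeded."""

    m: int = 1000
    m0_frac: float = 0.9
    n: int = 10
    mu_alt: float = 3.0
    sigma_x: float = 1.0
    sigma_y: float = 1.0
    dependence: str = "independent"
    block_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("invalid ScenarioConfig.m: need m >= 2")
        if not 0.0 < self.m0_frac < 1.0:
            raise ValueError("invalid ScenarioConfig.m0_frac: need 0 < m0_frac < 1")
        if self.n < 2:
            raise ValueError("invalid ScenarioConfig.n: need n >= 2")
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("invalid ScenarioConfig.sigma_x/sigma_y: must be positive")
        if self.dependence not in ("independent", "block"):
            raise ValueError("invalid ScenarioConfig.dependence: "
                             "must be 'independent' or 'block'")
        if self.dependence == "block":
            if self.block_size is None or self.block_size < 2:
                raise ValueError("invalid ScenarioConfig.block_size: need >= 2 "
                                 "for block dependence")
        if self.m1 < 1:
            raise ValueError("invalid ScenarioConfig.m0_frac: no alternative tests "
                             f"at m={self.m}")

    @property
    def m1(self) -> int:
        """Number of alternative tests: m - round(m * m0_frac)."""
        return self.m - int(round(self.m * self.m0_frac))


#: Parameters of the canonical training battery.
CANONICAL = ScenarioConfig(m=10_000, m0_frac=0.9, n=10, mu_alt=3.0,
                           sigma_x=1.0, sigma_y=1.0, dependence="independent")


@dataclass
class CorrelationBlock:
    """A b x b correlation matrix: symmetric, unit diagonal, PSD."""

    size: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.shape != (self.size, self.size):
            raise ValueError("matrix shape must match size")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(self.matrix).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semidefinite")


def random_correlation_matrix(b: int, rng: np.random.Generator) -> CorrelationBlock:
    """Correlation matrix with iid Uniform(-1,1) off-diagonal draws.

    A raw draw is usually indefinite for b > 2; it is then projected to the
    nearest PSD matrix by clipping negative eigenvalues at zero and the
    diagonal is rescaled back to 1.
    """
    if b < 2:
        raise ValueError("need block size >= 2")
    r = np.zeros((b, b))
    iu = np.triu_indices(b, 1)
    r[iu] = rng.uniform(-1.0, 1.0, len(iu[0]))
    r = r + r.T + np.eye(b)
    evals, evecs = np.linalg.eigh(r)
    if evals.min() < 0:
        evals = np.clip(evals, 0.0, None)
        r = (evecs * evals) @ evecs.T
        d = np.sqrt(np.clip(np.diag(r), 1e-12, None))
        r = r / np.outer(d, d)
        r = (r + r.T) / 2.0
        np.fill_diagonal(r, 1.0)
    return CorrelationBlock(size=b, matrix=r)


def _psd_factor(block: CorrelationBlock) -> np.ndarray:
    """Factor A with A A' = R, valid for singular R (eigen square root)."""
    evals, evecs = np.linalg.eigh(block.matrix)
    return evecs * np.sqrt(np.clip(evals, 0.0, None))


def generate_battery(cfg: ScenarioConfig) -> TestBattery:
    """Generate a labelled battery for one scenario cell.

    The first m0 tests are null (both population means 0), the remaining m1
    alternatives shift only the second population's mean to ``mu_alt``.
    In block mode consecutive tests share a freshly drawn correlation matrix
    per block (one for x, an independent one for y); a trailing partial
    block is simply a smaller block.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    m, n = cfg.m, cfg.n
    labels = np.zeros(m, int)
    labels[m - cfg.m1:] = 1
    mu_y = cfg.mu_alt * labels

    if cfg.dependence == "independent":
        x = rng.normal(0.0, cfg.sigma_x, (m, n))
        y = rng.normal(0.0, cfg.sigma_y, (m, n)) + mu_y[:, None]
    else:
        x = np.empty((m, n))
        y = np.empty((m, n))
        for start in range(0, m, cfg.block_size):
            stop = min(start + cfg.block_size, m)
            b = stop - start
            if b == 1:
                x[start] = rng.normal(0.0, cfg.sigma_x, n)
                y[start] = rng.normal(0.0, cfg.sigma_y, n)
            else:
                ax = _psd_factor(random_correlation_matrix(b, rng))
                ay = _psd_factor(random_correlation_matrix(b, rng))
                x[start:stop] = cfg.sigma_x * (ax @ rng.normal(size=(b, n)))
                y[start:stop] = cfg.sigma_y * (ay @ rng.normal(size=(b, n)))
        y += mu_y[:, None]

    width = len(str(m - 1))
    ids = np.array([f"t{i:0{width}d}" for i in range(m)])
    return TestBattery(ids=ids, x=x, y=y, labels=labels,
                       meta={"scenario": asdict(cfg)})


def make_training_battery(seed: int) -> TestBattery:
    """The canonical battery the single classifier is trained on."""
    cfg = ScenarioConfig(**{**asdict(CANONICAL), "seed": seed})
    return generate_battery(cfg)


def welch_pvalues(battery: TestBattery) -> np.ndarray:
    """Two-sided p-values of the two-sample t-test with Welch's correction
    (Welch-Satterthwaite degrees of freedom), one per test."""
    res = sps.ttest_ind(battery.x, battery.y, axis=1, equal_var=False)
    return np.asarray(res.pvalue)


# ---------------------------------------------------------------------------
# two-file battery serialisation: battery.tsv (long) + meta.yaml
# ---------------------------------------------------------------------------

def save_battery(battery: TestBattery, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    m, nx = battery.x.shape
    ny = battery.y.shape[1]
    rows = {
        "id": np.concatenate([np.repeat(battery.ids, nx), np.repeat(battery.ids, ny)]),
        "arm": np.concatenate([np.full(m * nx, "x"), np.full(m * ny, "y")]),
        "replicate": np.concatenate([np.tile(np.arange(nx), m), np.tile(np.arange(ny), m)]),
        "value": np.concatenate([battery.x.ravel(), battery.y.ravel()]),
    }
    if battery.labels is not None:
        rows["label"] = np.concatenate([np.repeat(battery.labels, nx),
                                        np.repeat(battery.labels, ny)])
    pd.DataFrame(rows).to_csv(directory / "battery.tsv", sep="\t", index=False)
    with open(directory / "meta.yaml", "w") as fh:
        yaml.safe_dump(battery.meta, fh)


def load_battery(directory) -> TestBattery:
    directory = Path(directory)
    df = pd.read_csv(directory / "battery.tsv", sep="\t", dtype={"id": str})
    meta = {}
    meta_path = directory / "meta.yaml"
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    ids = df["id"].drop_duplicates().to_numpy()
    piv = {arm: df[df["arm"] == arm].pivot(index="id", columns="replicate",
                                           values="value").loc[ids]
           for arm in ("x", "y")}
    labels = None
    if "label" in df.columns:
        labels = df.drop_duplicates("id").set_index("id")["label"].loc[ids].to_numpy()
    return TestBattery(ids=ids, x=piv["x"].to_numpy(), y=piv["y"].to_numpy(),
                       labels=labels, meta=meta)
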