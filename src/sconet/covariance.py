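"""Structural covariance network construction from regional gray-matter
volumes: covariate residualization, group-wise Pearson correlation,
negative-edge zeroing, and sparsity-threshold binarization.

A structural covariance network treats brain regions as nodes and the
between-subject correlation of their (covariate-corrected) volumes as edge
weights.  Binarizing both groups' matrices at the same sparsity -- the
fraction of the N(N-1)/2 possible edges retained -- guarantees equal edge
counts, so topological differences are not density artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MorphometryTable",
    "CovarianceNetwork",
    "residualize",
    "covariance_matrix",
    "zero_negatives",
    "binarize_at_sparsity",
    "sparsity_grid",
    "CollinearCovariatesError",
]

COVARIATE_NAMES = ("age", "sex", "education", "tiv")


class CollinearCovariatesError(ValueError):
    """The covariate design matrix is rank deficient."""


@dataclass
class MorphometryTable:
    """Subject x region volume matrix with per-subject covariates and labels.

    ``volumes`` is (n_subjects, n_regions); ``covariates`` is a DataFrame
    indexed like ``subjects`` with columns age, sex, education, tiv; ``group``
    holds 'high' / 'low' / 'none' per subject.
    """

    subjects: list
    regions: list
    volumes: np.ndarray
    covariates: pd.DataFrame
    group: np.ndarray
    residualized: bool = False

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.group = np.asarray(self.group, dtype=object)
        n, p = self.volumes.shape
        if len(self.subjects) != n:
            raise ValueError("subject list does not match volume rows")
        if len(self.regions) != p:
            raise ValueError("region list does not match volume columns")
        if len(self.group) != n:
            raise ValueError("group labels do not match subjects")
        if not np.all(np.isfinite(self.volumes)):
            bad = np.argwhere(~np.isfinite(self.volumes))[0]
            raise ValueError(
                f"missing/non-finite volume at subject {self.subjects[bad[0]]}, "
                f"region {self.regions[bad[1]]}"
            )
        if len(set(self.subjects)) != n:
            seen, dup = set(), None
            for s in self.subjects:
                if s in seen:
                    dup = s
                    break
                seen.add(s)
            raise ValueError(f"duplicate subject_id: {dup}")
        if list(self.covariates.index) != list(self.subjects):
            self.covariates = self.covariates.loc[self.subjects]

    @property
    def n_subjects(self) -> int:
        return self.volumes.shape[0]

    @property
    def n_regions(self) -> int:
        return self.volumes.shape[1]

    def subset(self, mask: np.ndarray) -> "MorphometryTable":
        idx = np.flatnonzero(mask)
        return MorphometryTable(
            subjects=[self.subjects[i] for i in idx],
            regions=list(self.regions),
            volumes=self.volumes[idx],
            covariates=self.covariates.iloc[idx],
            group=self.group[idx],
            residualized=self.residualized,
        )


@dataclass
class CovarianceNetwork:
    """Weighted correlation network, optionally binarized at one sparsity."""

    labels: list
    weights: np.ndarray
    sparsity: float | None = None
    adjacency: np.ndarray | None = None
    n_zeroed_negative: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weight matrix must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        if self.adjacency is None:
            raise ValueError("network has not been binarized")
        return int(np.triu(self.adjacency, 1).sum())


def _design_matrix(cov: pd.DataFrame, names: list[str]) -> np.ndarray:
    missing = [c for c in names if c not in cov.columns]
    if missing:
        raise ValueError(f"missing covariate column(s): {missing}")
    X = np.column_stack([np.ones(len(cov))] + [cov[c].to_numpy(dtype=float) for c in names])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns that lie in the span of the others
        collinear = []
        for j, name in enumerate(names):
            others = np.delete(X, j + 1, axis=1)
            resid = X[:, j + 1] - others @ np.linalg.lstsq(others, X[:, j + 1], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[:, j + 1])):
                collinear.append(name)
        raise CollinearCovariatesError(
            f"covariate design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear column(s): {collinear or 'intercept-related'}"
        )
    return X


def residualize(
    table: MorphometryTable, covariate_names: list[str] | tuple[str, ...] = COVARIATE_NAMES
) -> MorphometryTable:
    """Replace each region's volumes with OLS residuals on the covariates.

    A single regression (intercept + named covariates) is fitted per region
    over the pooled cohort; residuals have mean zero and are orthogonal to
    every covariate.  Idempotent: residualizing a residualized table is a
    no-op up to floating point.
    """
    names = list(covariate_names)
    if table.n_subjects <= len(names) + 1:
        raise ValueError("need more subjects than covariates + intercept")
    X = _design_matrix(table.covariates, names)
    coef, *_ = np.linalg.lstsq(X, table.volumes, rcond=None)
    resid = table.volumes - X @ coef
    return replace(table, volumes=resid, residualized=True)


def covariance_matrix(table: MorphometryTable, group: str | None = None) -> CovarianceNetwork:
    """Pearson correlation matrix across one group's subjects (diagonal zeroed)."""
    sub = table if group is None else table.subset(table.group == group)
    if sub.n_subjects < 4:
        raise ValueError(
            f"group {group!r} has {sub.n_subjects} subjects; need at least 4 for correlation"
        )
    sd = sub.volumes.std(axis=0)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        raise ValueError(f"zero-variance region: {sub.regions[j]}")
    w = np.corrcoef(sub.volumes, rowvar=False)
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0
    return CovarianceNetwork(labels=list(sub.regions), weights=w, meta={"group": group, "n": sub.n_subjects})


def zero_negatives(network: CovarianceNetwork) -> CovarianceNetwork:
    """Zero out negative correlations; only positive weights count as candidate edges."""
    w = network.weights.copy()
    neg = w < 0
    n_zeroed = int(np.triu(neg, 1).sum())
    w[neg] = 0.0
    return CovarianceNetwork(
        labels=list(network.labels),
        weights=w,
        n_zeroed_negative=n_zeroed,
        meta=dict(network.meta),
    )


def binarize_at_sparsity(network: CovarianceNetwork, sparsity: float) -> CovarianceNetwork:
    """Keep exactly ``floor(sparsity * N(N-1)/2)`` strongest positive edges.

    Ties at the cutoff weight break deterministically by (weight descending,
    row index ascending, column index ascending), so repeated runs and the
    nestedness of edge sets across sparsities are exact.
    """
    if not 0.0 < sparsity <= 1.0:
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    n = network.n_nodes
    e_max = n * (n - 1) // 2
    n_edges = int(np.floor(sparsity * e_max + 1e-9))
    iu, ju = np.triu_indices(n, k=1)
    w = network.weights[iu, ju]
    pos = w > 0
    n_pos = int(pos.sum())
    if n_edges > n_pos:
        raise ValueError(
            f"requested {n_edges} edges but only {n_pos} positive weights exist; "
            f"maximum achievable sparsity is {n_pos / e_max:.4f}"
        )
    order = np.lexsort((ju, iu, -w))
    keep = order[:n_edges]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    return CovarianceNetwork(
        labels=list(network.labels),
        weights=network.weights,
        sparsity=sparsity,
        adjacency=adj,
        n_zeroed_negative=network.n_zeroed_negative,
        meta=dict(network.meta),
    )


def sparsity_grid(low: float = 0.25, high: float = 0.53, step: float = 0.01) -> list[float]:
    """Inclusive arithmetic grid of sparsity thresholds, rounded to the step precision."""
    if not (0.0 < low <= high <= 1.0) or step <= 0:
        raise ValueError(f"invalid sparsity grid ({low}, {high}, {step})")
    decimals = max(0, -int(np.floor(np.log10(step))) + 2)
    n = int(np.floor((high - low) / step + 1e-9)) + 1
    return [round(low + i * step, decimals) for i in range(n)]
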