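"""Regularized partial-correlation network estimation with EBIC selection.

The trails × indicators prevalence matrix is treated as observations of a
pairwise Markov random field for continuous data (a Gaussian graphical
model). The precision matrix Θ is estimated by the graphical lasso —
maximizing ``log det Θ − tr(SΘ) − λ·Σ_{i≠j}|θ_ij|`` over positive-definite
matrices, with the L1 penalty on off-diagonal entries only — via block
coordinate descent (one lasso regression per column, in the style of the
original glasso algorithm). Edge weights are partial correlations
``w_ij = −θ_ij/√(θ_ii·θ_jj)``.

λ is chosen on a log-spaced path by the extended Bayesian information
criterion, EBIC(λ) = −n·(log det Θ − tr(SΘ)) + E·log n + 4·E·γ·log p,
where E is the number of edges and γ ≥ 0 trades fit against sparsity
(γ = 0.5 by default). Node importance is summarized by strength
centrality, the per-node sum of absolute edge weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from trailmetrics.errors import ConvergenceError, ValidationError
from trailmetrics.travel_time import Duration

__all__ = [
    "INDICATOR_LABELS",
    "NetworkConfig",
    "NetworkModel",
    "CentralityResult",
    "build_prevalence_matrix",
    "correlation",
    "graphical_lasso",
    "ebic_score",
    "select_network",
    "strength",
    "fr_layout",
]

#: Fixed variable order of the prevalence matrix.
INDICATOR_LABELS = ("ES", "CG", "SG", "TD", "BOK", "TT", "ATT")

#: Rubric maxima used to express scores as prevalences.
DEFAULT_REFERENCES = {"ES": 26, "CG": 5, "SG": 6}


@dataclass(frozen=True)
class NetworkConfig:
    """Estimation settings: EBIC γ, the λ path, and solver tolerances."""

    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    correlation_method: str = "pearson"
    tol: float = 1e-6
    max_iter: int = 500
    ridge_eps: float = 1e-3

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValidationError("gamma must be >= 0")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValidationError("lambda_min_ratio must be in (0, 1)")
        if self.n_lambda < 1:
            raise ValidationError("n_lambda must be >= 1")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValidationError("correlation_method must be pearson or spearman")


@dataclass(frozen=True)
class NetworkModel:
    """Estimated partial-correlation network."""

    weights: np.ndarray  # symmetric p×p partial correlations, zero diagonal
    precision: np.ndarray
    labels: tuple[str, ...]
    lambda_: float
    ebic: float
    n: int

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def edge_list(self) -> list[tuple[str, str, float]]:
        p = len(self.labels)
        return [
            (self.labels[i], self.labels[j], float(self.weights[i, j]))
            for i in range(p)
            for j in range(i + 1, p)
            if self.weights[i, j] != 0
        ]


@dataclass(frozen=True)
class CentralityResult:
    """Raw and standardized strength centrality per node."""

    labels: tuple[str, ...]
    raw: np.ndarray
    standardized: np.ndarray | None


# ---------------------------------------------------------------------------
# Prevalence matrix
# ---------------------------------------------------------------------------


def build_prevalence_matrix(
    results: Mapping[str, Mapping[str, object]],
    references: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Assemble the trails × indicators prevalence matrix.

    ``results`` maps trail name to its indicator inputs: ``es``, ``cg``,
    ``sg`` (raw rubric scores), ``td_km`` and ``bok_km`` (measured and
    load-equivalent distances), ``tt`` (:class:`Duration`), and either
    ``att`` (a Duration, converted to a percent of ``tt``) or an explicit
    ``att_pct``. ES/CG/SG become percents of their rubric maxima; TD and
    TT are fixed at 100; BOK and ATT are percent increases.
    """
    refs = dict(DEFAULT_REFERENCES)
    if references:
        refs.update(references)
    rows = {}
    for trail, vals in results.items():
        def get(key: str) -> object:
            if key not in vals or vals[key] is None:
                raise ValidationError(
                    f"trail {trail!r}: missing indicator {key!r}"
                )
            return vals[key]

        td = float(get("td_km"))
        bok = float(get("bok_km"))
        if "att_pct" in vals and vals["att_pct"] is not None:
            att_pct = float(vals["att_pct"])
        else:
            att = get("att")
            tt = get("tt")
            if not isinstance(att, Duration) or not isinstance(tt, Duration):
                raise ValidationError(
                    f"trail {trail!r}: 'att' and 'tt' must be Durations"
                )
            att_pct = 100.0 * float(att.seconds) / float(tt.seconds)
        rows[trail] = {
            "ES": 100.0 * float(get("es")) / refs["ES"],
            "CG": 100.0 * float(get("cg")) / refs["CG"],
            "SG": 100.0 * float(get("sg")) / refs["SG"],
            "TD": 100.0,
            "BOK": 100.0 * (bok / td - 1.0),
            "TT": 100.0,
            "ATT": att_pct,
        }
    return pd.DataFrame.from_dict(rows, orient="index")[list(INDICATOR_LABELS)]


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------


def correlation(X: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Sample correlation matrix of the indicator columns.

    Constant columns carry no correlation information and are dropped
    with a warning.
    """
    if len(X) < 2:
        raise ValidationError("at least 2 observations are required")
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"dropping constant columns from correlation: {constant}",
            stacklevel=2,
        )
        X = X.drop(columns=constant)
    if X.shape[1] == 0:
        raise ValidationError("all columns are constant")
    return X.corr(method=method)


# ---------------------------------------------------------------------------
# Graphical lasso (block coordinate descent)
# ---------------------------------------------------------------------------


def _lasso_cd(
    V: np.ndarray, s: np.ndarray, lam: float, beta: np.ndarray, tol: float
) -> np.ndarray:
    """Coordinate descent for ½βᵀVβ − sᵀβ + λ‖β‖₁ (V positive definite)."""
    q = len(s)
    for _ in range(1000):
        max_delta = 0.0
        for j in range(q):
            r = s[j] - V[j] @ beta + V[j, j] * beta[j]
            new = np.sign(r) * max(abs(r) - lam, 0.0) / V[j, j]
            delta = abs(new - beta[j])
            if delta > max_delta:
                max_delta = delta
            beta[j] = new
        if max_delta < tol:
            break
    return beta


def _ensure_psd(S: np.ndarray, ridge_eps: float) -> np.ndarray:
    eigmin = float(np.linalg.eigvalsh(S).min())
    if eigmin < 1e-8:
        warnings.warn(
            f"correlation matrix is singular or indefinite (min eigenvalue "
            f"{eigmin:.2e}); applying ridge repair +{ridge_eps}·I",
            stacklevel=3,
        )
        S = S + ridge_eps * np.eye(S.shape[0])
    return S

def graphical_lasso(
    S: np.ndarray,
    lam: float,
    config: NetworkConfig | None = None,
    _warm_B: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """L1-penalized precision estimation; returns (Θ, partial correlations W).

    Solves max over positive-definite Θ of
    ``log det Θ − tr(SΘ) − λ·Σ_{i≠j}|θ_ij|`` (penalty on off-diagonal
    entries only) by block coordinate descent: each column update is a
    lasso regression on the current covariance estimate.
    """
    config = config or NetworkConfig()
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-10):
        raise ValidationError("S must be a symmetric square matrix")
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    S = _ensure_psd(S, config.ridge_eps)
    if p == 1:
        theta = np.array([[1.0 / S[0, 0]]])
        return theta, np.zeros((1, 1))

    W = S.copy()
    B = np.zeros((p - 1, p)) if _warm_B is None else _warm_B.copy()
    off_scale = np.abs(S - np.diag(np.diag(S))).mean() + 1e-12
    idx_cache = [np.array([i for i in range(p) if i != j]) for j in range(p)]
    for _ in range(config.max_iter):
        W_old = W.copy()
        for j in range(p):
            idx = idx_cache[j]
            V = W[np.ix_(idx, idx)]
            beta = _lasso_cd(V, S[idx, j], lam, B[:, j], config.tol)
            B[:, j] = beta
            w12 = V @ beta
            W[idx, j] = w12
            W[j, idx] = w12
        if np.abs(W - W_old).mean() <= config.tol * off_scale:
            break
    else:
        gap = _dual_gap(S, _recover_theta(S, W, B, idx_cache), lam)
        raise ConvergenceError(
            f"graphical lasso did not converge in {config.max_iter} "
            f"iterations (duality gap {gap:.3e})"
        )
    theta = _recover_theta(S, W, B, idx_cache)
    d = np.sqrt(np.diag(theta))
    W_pcor = -theta / np.outer(d, d)
    np.fill_diagonal(W_pcor, 0.0)
    # enforce exact zeros where the lasso zeroed the regression weights
    W_pcor[np.abs(theta) == 0.0] = 0.0
    return theta, W_pcor


def _recover_theta(
    S: np.ndarray, W: np.ndarray, B: np.ndarray, idx_cache: list[np.ndarray]
) -> np.ndarray:
    p = S.shape[0]
    theta = np.zeros((p, p))
    for j in range(p):
        idx = idx_cache[j]
        beta = B[:, j]
        theta_jj = 1.0 / (W[j, j] - W[idx, j] @ beta)
        theta[j, j] = theta_jj
        theta[idx, j] = np.where(beta == 0.0, 0.0, -beta * theta_jj)
    return (theta + theta.T) / 2.0


def _dual_gap(S: np.ndarray, theta: np.ndarray, lam: float) -> float:
    p = S.shape[0]
    off_l1 = np.abs(theta).sum() - np.abs(np.diag(theta)).sum()
    return float(np.sum(S * theta) - p + lam * off_l1)


# ---------------------------------------------------------------------------
# EBIC and model selection
# ---------------------------------------------------------------------------


def ebic_score(
    theta: np.ndarray,
    S: np.ndarray,
    n: int,
    n_edges: int,
    gamma: float,
    p: int,
) -> float:
    """Extended BIC of a fitted precision matrix.

    ``−2·(n/2)·(log det Θ − tr(SΘ)) + E·log n + 4·E·γ·log p``; with γ = 0
    this is the ordinary BIC penalty for E free edge parameters.
    """
    if n <= 0:
        raise ValidationError("sample size n must be > 0")
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise ValidationError("theta must be positive definite")
    loglik = (n / 2.0) * (logdet - float(np.sum(S * theta)))
    return -2.0 * loglik + n_edges * np.log(n) + 4.0 * n_edges * gamma * np.log(p)


def lambda_path(S: np.ndarray, config: NetworkConfig) -> np.ndarray:
    """Log-spaced λ path from λ_max (full shrinkage) down to its min ratio."""
    off = np.abs(S - np.diag(np.diag(S)))
    lam_max = float(off.max())
    if lam_max <= 0:
        lam_max = 1.0  # diagonal S: any positive λ gives the empty network
    return np.logspace(
        np.log10(lam_max), np.log10(lam_max * config.lambda_min_ratio), config.n_lambda
    )


def select_network(
    S: np.ndarray | pd.DataFrame,
    n: int,
    config: NetworkConfig | None = None,
) -> NetworkModel:
    """Fit the λ path and return the EBIC-minimizing network."""
    config = config or NetworkConfig()
    labels: tuple[str, ...]
    if isinstance(S, pd.DataFrame):
        labels = tuple(str(c) for c in S.columns)
        S = S.to_numpy(dtype=float)
    else:
        S = np.asarray(S, dtype=float)
        labels = tuple(f"V{i+1}" for i in range(S.shape[0]))
    p = S.shape[0]
    if n < p:
        warnings.warn(
            f"sample size n={n} is below the number of variables p={p}; the "
            "sample correlation matrix is singular and results are fragile",
            stacklevel=2,
        )
    S = _ensure_psd(S, config.ridge_eps)
    best: tuple[float, float, np.ndarray, np.ndarray] | None = None
    warm = None
    for lam in lambda_path(S, config):
        theta, w = graphical_lasso(S, float(lam), config, _warm_B=warm)
        warm = _betas_from_theta(theta)
        n_edges = int(np.count_nonzero(np.triu(w, k=1)))
        score = ebic_score(theta, S, n, n_edges, config.gamma, p)
        if best is None or score < best[0]:
            best = (score, float(lam), theta, w)
    assert best is not None
    score, lam, theta, w = best
    return NetworkModel(
        weights=w, precision=theta, labels=labels, lambda_=lam, ebic=score, n=n
    )


def _betas_from_theta(theta: np.ndarray) -> np.ndarray:
    p = theta.shape[0]
    B = np.zeros((p - 1, p))
    for j in range(p):
        idx = [i for i in range(p) if i != j]
        B[:, j] = -theta[idx, j] / theta[j, j]
    return B


# ---------------------------------------------------------------------------
# Centrality and layout
# ---------------------------------------------------------------------------


def strength(
    W: np.ndarray | NetworkModel, standardize: bool = True
) -> CentralityResult:
    """Strength centrality: sᵢ = Σⱼ |wᵢⱼ|, optionally z-standardized."""
    if isinstance(W, NetworkModel):
        labels, mat = W.labels, W.weights
    else:
        mat = np.asarray(W, dtype=float)
        labels = tuple(f"V{i+1}" for i in range(mat.shape[0]))
    p = mat.shape[0]
    raw = np.abs(mat).sum(axis=1)
    std = None
    if standardize:
        if p == 1:
            raise ValidationError("standardized strength is undefined for p = 1")
        sd = raw.std(ddof=1)
        std = np.zeros(p) if sd == 0 else (raw - raw.mean()) / sd
    return CentralityResult(labels=labels, raw=raw, standardized=std)


def fr_layout(
    W: np.ndarray | NetworkModel, seed: int = 0, iterations: int = 50
) -> dict[str, tuple[float, float]]:
    """Force-directed (Fruchterman–Reingold) node coordinates.

    Absolute edge weights act as attraction strengths; the layout is
    deterministic for a fixed seed.
    """
    import networkx as nx

    if isinstance(W, NetworkModel):
        labels, mat = W.labels, W.weights
    else:
        mat = np.asarray(W, dtype=float)
        labels = tuple(f"V{i+1}" for i in range(mat.shape[0]))
    p = mat.shape[0]
    if p == 1:
        return {labels[0]: (0.0, 0.0)}
    G = nx.Graph()
    G.add_nodes_from(labels)
    for i in range(p):
        for j in range(i + 1, p):
            if mat[i, j] != 0:
                G.add_edge(labels[i], labels[j], weight=abs(float(mat[i, j])))
    pos = nx.spring_layout(G, seed=seed, iterations=iterations, weight="weight")
    return {node: (float(xy[0]), float(xy[1])) for node, xy in pos.items()}
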