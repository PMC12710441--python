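"""Pagel's lambda on species-level model residuals.

Under Brownian motion on a rooted tree with branch lengths, a continuous
value at the tips is multivariate normal with covariance V where
V[i, j] is the shared root-to-MRCA path length of tips i and j and
V[i, i] the root-to-tip distance.  Pagel's lambda multiplies the
off-diagonal entries by lambda in [0, 1]; lambda = 0 removes all
phylogenetic covariance and lambda = 1 is plain Brownian motion.

``estimate_lambda`` maximizes the multivariate-normal likelihood over
lambda with the mean and overall scale profiled analytically (GLS mean,
ML variance), and tests lambda = 0 with a likelihood-ratio statistic
referred to the boundary-corrected 0.5*chi2(1) distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "phylo_vcv",
    "lambda_transform",
    "estimate_lambda",
    "simulate_brownian",
    "PhyloSignalResult",
]


@dataclass(frozen=True)
class PhyloSignalResult:
    lambda_hat: float
    loglik_at_hat: float
    loglik_at_zero: float
    lrt_p: float
    n_species: int


def phylo_vcv(tree: dendropy.Tree) -> pd.DataFrame:
    """Species x species Brownian covariance (shared branch lengths).

    Diagonal entries are root-to-tip distances; off-diagonals the depth of
    the most recent common ancestor.  Tip labels must be unique.
    """
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate tip labels in tree")
    idx = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    V = np.zeros((n, n))

    tree.calc_node_root_distances(return_leaf_distances_only=False)
    # each internal node's depth is the covariance of tip pairs whose MRCA it is
    leafsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            leafsets[id(node)] = [i]
            V[i, i] = node.root_distance
            continue
        depth = node.root_distance or 0.0
        child_sets = [leafsets.pop(id(ch)) for ch in node.child_nodes()]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    for j in child_sets[b]:
                        V[i, j] = V[j, i] = depth
        merged: list[int] = []
        for s in child_sets:
            merged.extend(s)
        leafsets[id(node)] = merged
    return pd.DataFrame(V, index=taxa, columns=taxa)


def lambda_transform(vcv: np.ndarray | pd.DataFrame, lam: float) -> np.ndarray:
    """Scale off-diagonal covariances by lambda (diagonal unchanged)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    V = np.asarray(vcv, dtype=float)
    out = V * lam
    np.fill_diagonal(out, np.diag(V))
    return out


def _profile_loglik(y: np.ndarray, V: np.ndarray, lam: float) -> float:
    """Log-likelihood at lambda with mean and scale profiled out."""
    n = len(y)
    Vl = lambda_transform(V, lam)
    Vl = Vl + (1e-10 * float(np.mean(np.diag(Vl)))) * np.eye(n)  # numerical ridge
    try:
        c, low = cho_factor(Vl)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(Vl)
        raise np.linalg.LinAlgError(
            f"singular lambda-transformed covariance (condition number {cond:.3g})"
        ) from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    one = np.ones(n)
    Vi1 = cho_solve((c, low), one)
    Viy = cho_solve((c, low), y)
    mu = float(one @ Viy) / float(one @ Vi1)
    r = y - mu
    Vir = Viy - mu * Vi1
    s2 = float(r @ Vir) / n
    if s2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2.0 * np.pi * s2) + logdet + n)


def estimate_lambda(
    residuals: pd.Series,
    tree: dendropy.Tree,
    *,
    xatol: float = 1e-4,
) -> PhyloSignalResult:
    """ML estimate of Pagel's lambda for species-indexed residuals.

    ``residuals`` is indexed by species id; tips absent from the residual
    index are pruned (and vice versa).  At least 4 shared species are
    required.  The estimate is invariant to shifting or positively scaling
    the residuals (mean and variance are profiled).
    """
    V_full = phylo_vcv(tree)
    common = [t for t in V_full.index if t in residuals.index]
    if len(common) < 4:
        raise ValueError(
            f"need >= 4 species shared between residuals and tree, got {len(common)}"
        )
    V = V_full.loc[common, common].to_numpy()
    y = residuals.loc[common].to_numpy(dtype=float)

    neg = lambda lam: -_profile_loglik(y, V, lam)  # noqa: E731
    res = optimize.minimize_scalar(
        neg, bounds=(0.0, 1.0), method="bounded", options={"xatol": xatol}
    )
    candidates = {float(res.x): -res.fun, 0.0: _profile_loglik(y, V, 0.0), 1.0: _profile_loglik(y, V, 1.0)}
    lam_hat, ll_hat = max(candidates.items(), key=lambda kv: kv[1])
    ll0 = candidates[0.0]
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    # boundary null: 50:50 mixture of point mass at 0 and chi2(1)
    lrt_p = 1.0 if lr <= 0 else 0.5 * float(stats.chi2.sf(lr, df=1))
    return PhyloSignalResult(
        lambda_hat=float(lam_hat),
        loglik_at_hat=float(ll_hat),
        loglik_at_zero=float(ll0),
        lrt_p=float(lrt_p),
        n_species=len(common),
    )


def simulate_brownian(
    tree: dendropy.Tree, rng: np.random.Generator, *, sigma: float = 1.0
) -> pd.Series:
    """Draw one Brownian-motion realization at the tips (lambda = 1)."""
    V = phylo_vcv(tree)
    L = np.linalg.cholesky(V.to_numpy() + 1e-12 * np.eye(len(V)))
    return pd.Series(sigma * (L @ rng.standard_normal(len(V))), index=V.index)
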