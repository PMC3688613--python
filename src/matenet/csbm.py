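"""Continuous (mixed-membership) stochastic block model with an
unconnected extremal node.

Each node i of an undirected, unweighted simple network carries a
membership vector u_i on the simplex over Q extremal hypothetical nodes
(EHNs).  Edges are independent Bernoulli draws with

    pi_ij = u_i' B u_j = sum_{q,l} u_iq B_ql u_jl,

where B is a symmetric Q x Q connectivity matrix with entries in [0, 1]
whose row/column 0 is identically zero: EHN 0 is a virtual node
connected to nothing, always present, which absorbs degree
heterogeneity (weakly connected nodes load on it).  Because pi_ij is a
convex combination of B entries it is automatically a probability.

Inference is maximum likelihood by alternating projected-gradient
ascent with backtracking line search (monotone in the log-likelihood),
restarted from several initializations; model choice across Q uses AIC
with k = n(Q-1) + (Q-1)Q/2 free parameters (simplex coordinates plus
the free symmetric block of B).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import networkx as nx
import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

logger = logging.getLogger("matenet.csbm")

DELTA = 1e-9  # probability clipping for the log-likelihood


@dataclasses.dataclass
class CSBMFit:
    Q: int
    ids: list
    U: np.ndarray  # (n, Q), rows on the simplex
    B: np.ndarray  # (Q, Q), symmetric, row/col 0 zero
    logL: float
    aic: float
    n_restarts_used: int
    best_restart_seed: int
    converged: bool
    n_iter: int
    trace: list[float] | None = None


@dataclasses.dataclass
class ModelScan:
    fits: dict[int, CSBMFit]
    ranking: list[int]  # Q values, best (lowest) AIC first
    selected_Q: int
    override_Q: int | None


def edge_probability(u_i: np.ndarray, u_j: np.ndarray, B: np.ndarray) -> float:
    """Bernoulli edge probability pi_ij = u_i' B u_j."""
    u_i = np.asarray(u_i, dtype=float)
    u_j = np.asarray(u_j, dtype=float)
    if u_i.shape != (B.shape[0],) or u_j.shape != (B.shape[1],):
        raise ValueError("membership/connectivity dimension mismatch")
    return float(u_i @ B @ u_j)


def _adjacency(network: nx.Graph, ids: list | None = None) -> tuple[list, np.ndarray]:
    if ids is None:
        ids = sorted(network.nodes())
    X = nx.to_numpy_array(network, nodelist=ids, dtype=float)
    X = (X > 0).astype(float)
    np.fill_diagonal(X, 0.0)
    return list(ids), X


def _loglik(Xu: np.ndarray, iu, U: np.ndarray, B: np.ndarray) -> float:
    P = (U @ B @ U.T)[iu]
    P = np.clip(P, DELTA, 1 - DELTA)
    return float(Xu @ np.log(P) + (1 - Xu) @ np.log1p(-P))


def log_likelihood(network: nx.Graph, U: np.ndarray, B: np.ndarray, ids: list | None = None) -> float:
    """Bernoulli log-likelihood over unordered node pairs.

    Node order follows ``ids`` (default: sorted node labels), which must
    match the row order of ``U``.
    """
    ids, X = _adjacency(network, ids)
    n = len(ids)
    if U.shape[0] != n:
        raise ValueError("U rows must match network nodes")
    iu = np.triu_indices(n, 1)
    return _loglik(X[iu], iu, U, B)


def project_simplex_rows(V: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, q = V.shape
    s = np.sort(V, axis=1)[:, ::-1]
    cs = np.cumsum(s, axis=1) - 1.0
    k = np.arange(1, q + 1)
    cond = s - cs / k > 0
    rho = q - 1 - np.argmax(cond[:, ::-1], axis=1)
    theta = cs[np.arange(n), rho] / (rho + 1)
    return np.maximum(V - theta[:, None], 0.0)


def _project_B(B: np.ndarray) -> np.ndarray:
    B = 0.5 * (B + B.T)
    B = np.clip(B, 0.0, 1.0)
    B[0, :] = 0.0
    B[:, 0] = 0.0
    return B


def _grad_matrix(X: np.ndarray, U: np.ndarray, B: np.ndarray) -> np.ndarray:
    P = U @ B @ U.T
    np.clip(P, DELTA, 1 - DELTA, out=P)
    G = X / P - (1 - X) / (1 - P)
    np.fill_diagonal(G, 0.0)
    return G


def _spectral_init(X: np.ndarray, Q: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Softened spectral split plus degree-driven EHN-0 loading."""
    n = X.shape[0]
    deg = X.sum(axis=1)
    dmax = max(deg.max(), 1.0)
    u0 = np.clip(1.0 - deg / dmax, 0.05, 0.9)
    U = np.zeros((n, Q))
    U[:, 0] = u0
    k = Q - 1
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        try:
            vals, vecs = eigh(X)
            top = vecs[:, np.argsort(vals)[::-1][:k]]
            labels = KMeans(n_clusters=k, n_init=4, random_state=int(rng.integers(2**31))).fit_predict(top)
        except Exception:  # pragma: no cover - degenerate spectra
            labels = rng.integers(0, k, size=n)
    rest = 1.0 - u0
    for c in range(k):
        share = np.where(labels == c, 0.85, 0.15 / max(k - 1, 1))
        U[:, 1 + c] = rest * share
    U = 0.9 * U + 0.1 * rng.dirichlet(np.ones(Q), size=n)
    U = project_simplex_rows(U)
    dens = X.sum() / max(n * (n - 1), 1)
    B = np.full((Q, Q), min(0.5 * dens * 8, 0.2))
    np.fill_diagonal(B, np.clip(8 * dens, 0.1, 0.9))
    return U, _project_B(B)


def _random_init(n: int, Q: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    U = rng.dirichlet(np.ones(Q) * 0.8, size=n)
    B = rng.uniform(0.02, 0.98, size=(Q, Q))
    return U, _project_B(B)


def _optimize(
    X: np.ndarray,
    Q: int,
    U: np.ndarray,
    B: np.ndarray,
    max_iter: int,
    tol: float,
    trace: bool,
) -> tuple[np.ndarray, np.ndarray, float, bool, int, list[float] | None]:
    n = X.shape[0]
    iu = np.triu_indices(n, 1)
    Xu = X[iu]
    L = _loglik(Xu, iu, U, B)
    history = [L] if trace else None
    sB, sU = 0.25, 0.25
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        L_prev = L
        # --- B step (log-likelihood is concave in B for fixed U)
        G = _grad_matrix(X, U, B)
        gB = 0.5 * (U.T @ G @ U)
        gB = 0.5 * (gB + gB.T)
        gB[0, :] = 0.0
        gB[:, 0] = 0.0
        gmax = np.abs(gB).max()
        if gmax > 0:
            dB = gB / gmax
            s = sB
            while s > 1e-14:
                Bn = _project_B(B + s * dB)
                Ln = _loglik(Xu, iu, U, Bn)
                if Ln > L:
                    B, L = Bn, Ln
                    sB = min(s * 2.0, 1.0)
                    break
                s *= 0.5
            else:
                sB = 0.25
        # --- U step (joint over rows, monotone via backtracking)
        G = _grad_matrix(X, U, B)
        gU = G @ (U @ B)
        gmax = np.abs(gU).max()
        if gmax > 0:
            dU = gU / gmax
            s = sU
            while s > 1e-14:
                Un = project_simplex_rows(U + s * dU)
                Ln = _loglik(Xu, iu, Un, B)
                if Ln > L:
                    U, L = Un, Ln
                    sU = min(s * 2.0, 1.0)
                    break
                s *= 0.5
            else:
                sU = 0.25
        if trace:
            history.append(L)
        if abs(L - L_prev) / (abs(L_prev) + 1.0) < tol:
            converged = True
            break
    return U, B, L, converged, it, history


def _rescale_ridge(U: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pin the likelihood-flat scale ridge.

    Because EHN 0 contributes nothing to edge probabilities, scaling a
    non-zero EHN's membership column by c (with the slack absorbed by the
    EHN-0 column) while dividing the corresponding B entries by c leaves
    every pi_ij unchanged.  The convention adopted is archetypal: each
    connected EHN is scaled so its best-represented node attains
    membership 1 (the extremal node is the tightest hull vertex), which
    makes B entries comparable across fits.  Scales are reduced when
    needed to keep rows on the simplex and B in [0, 1].
    """
    Q = B.shape[0]
    c = np.ones(Q)
    for q in range(1, Q):
        m = U[:, q].max()
        if m > 0:
            c[q] = 1.0 / m
    # c >= 1, so scaled B entries can only shrink; the binding constraint
    # is the simplex: sum of scaled non-zero entries <= 1 for every row
    s = (U[:, 1:] * c[1:]).sum(axis=1)
    smax = s.max() if s.size else 0.0
    if smax > 1.0:
        c[1:] /= smax
    Un = U.copy()
    Un[:, 1:] = U[:, 1:] * c[1:]
    Un[:, 0] = 1.0 - Un[:, 1:].sum(axis=1)
    Bn = B.copy()
    for q in range(1, Q):
        for l in range(1, Q):
            Bn[q, l] = B[q, l] / (c[q] * c[l])
    if Bn.max() > 1.0 or Un.min() < -1e-12:  # give up rather than perturb pi
        return U, B
    Un = np.clip(Un, 0.0, 1.0)
    return Un, _project_B(Bn)


def _canonicalize(U: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix EHN identifiability: EHN 0 is the zero row/column; the scale
    ridge is pinned archetypally; the remaining EHNs are sorted by
    descending within-EHN connectivity, ties broken by the first node's
    membership mass."""
    U, B = _rescale_ridge(U, B)
    Q = B.shape[0]
    rest = sorted(range(1, Q), key=lambda q: (-B[q, q], -U[0, q]))
    order = [0] + rest
    return U[:, order], B[np.ix_(order, order)]


def aic(fit: "CSBMFit", n: int) -> float:
    """AIC with k = n(Q-1) + (Q-1)Q/2 free parameters."""
    Q = fit.Q
    k = n * (Q - 1) + (Q - 1) * Q // 2
    return -2.0 * fit.logL + 2.0 * k


def fit_csbm(
    network: nx.Graph,
    Q: int,
    n_restarts: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int | None = None,
    ids: list | None = None,
    trace: bool = False,
) -> CSBMFit:
    """Maximum-likelihood fit of the model for a fixed number of EHNs.

    The best of ``n_restarts`` runs is returned: the first restart uses a
    softened spectral initialization, the rest are random Dirichlet /
    uniform draws.  Accepted iterations never decrease the
    log-likelihood; convergence is a relative log-likelihood change
    below ``tol``.
    """
    if Q < 2:
        raise ValueError("Q must be >= 2 (EHN 0 plus at least one connected EHN)")
    ids, X = _adjacency(network, ids)
    n = len(ids)
    if n < 2:
        raise ValueError("network needs at least 2 nodes")
    if Q > n:
        warnings.warn(f"Q={Q} exceeds the number of nodes ({n}); over-parameterized model")

    master = np.random.default_rng(seed)
    restart_seeds = master.integers(2**31, size=n_restarts)
    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(int(restart_seeds[r]))
        if r == 0:
            U0, B0 = _spectral_init(X, Q, rng)
        else:
            U0, B0 = _random_init(n, Q, rng)
        U, B, L, conv, it, hist = _optimize(X, Q, U0, B0, max_iter, tol, trace)
        if best is None or L > best[2]:
            best = (U, B, L, conv, it, hist, int(restart_seeds[r]))
    U, B, L, conv, it, hist, rseed = best
    U, B = _canonicalize(U, B)
    fit = CSBMFit(
        Q=Q,
        ids=ids,
        U=U,
        B=B,
        logL=L,
        aic=0.0,
        n_restarts_used=n_restarts,
        best_restart_seed=rseed,
        converged=conv,
        n_iter=it,
        trace=hist,
    )
    fit.aic = aic(fit, n)
    return fit


def scan_models(
    network: nx.Graph,
    Q_min: int = 2,
    Q_max: int = 4,
    override_Q: int | None = None,
    **fit_kwargs,
) -> ModelScan:
    """Fit a range of Q values, rank by AIC, and select.

    ``override_Q`` allows a manual choice (e.g. when the AIC-best model
    reflects sampling-design structure rather than biology); the AIC
    ranking is reported unchanged.
    """
    if not 2 <= Q_min <= Q_max:
        raise ValueError("need 2 <= Q_min <= Q_max")
    seed = fit_kwargs.pop("seed", None)
    master = np.random.default_rng(seed)
    fits = {}
    for Q in range(Q_min, Q_max + 1):
        fits[Q] = fit_csbm(network, Q, seed=int(master.integers(2**31)), **fit_kwargs)
    ranking = sorted(fits, key=lambda q: fits[q].aic)
    selected = override_Q if override_Q is not None else ranking[0]
    if override_Q is not None and override_Q not in fits:
        raise ValueError("override_Q outside the scanned range")
    return ModelScan(fits=fits, ranking=ranking, selected_Q=selected, override_Q=override_Q)


def connectivity_structure(fit: CSBMFit) -> dict:
    """Diagnose whether a fit is assortative (within-EHN connectivity
    dominates) or disassortative/bipartite (between-EHN dominates).

    A bipartite-dominant fit on a progeny-design mating network usually
    means the model latched onto the mother/father sampling roles rather
    than onto species structure; harvesting progeny from every adult
    removes that artifact.
    """
    Q = fit.Q
    diag = np.diag(fit.B)[1:]
    off = fit.B[1:, 1:].copy()
    np.fill_diagonal(off, 0.0)
    max_diag = float(diag.max()) if diag.size else 0.0
    max_off = float(off.max()) if off.size else 0.0
    return {
        "max_within": max_diag,
        "max_between": max_off,
        "assortative": max_diag >= max_off,
    }


def sample_network(
    ids: list,
    U: np.ndarray,
    B: np.ndarray,
    seed: int | None = None,
) -> nx.Graph:
    """Draw a network from the model (independent Bernoulli edges)."""
    rng = np.random.default_rng(seed)
    n = len(ids)
    P = U @ B @ U.T
    g = nx.Graph()
    g.add_nodes_from(ids)
    iu, ju = np.triu_indices(n, 1)
    draws = rng.random(iu.size) < P[iu, ju]
    for i, j in zip(iu[draws], ju[draws]):
        g.add_edge(ids[i], ids[j])
    return g
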