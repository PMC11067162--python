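"""Consensus NMF decomposition of malignant-cell expression into subtype programs.

Malignant ductal cells are decomposed into K non-negative expression
programs (spectra over genes, usages per cell). K is selected by a
consensus procedure: many seeded NMF restarts per candidate K, outlier
component filtering, clustering of pooled components, and a stability
(mean silhouette) vs reconstruction-error trade-off. Cells are assigned
to the program with the largest usage, and per-sample subtype
proportions are computed over malignant cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

_EPS = 1e-12
UNASSIGNED = -1


@dataclass
class ProgramModel:
    """Non-negative spectra (K x genes, rows unit L2 norm) and usages
    (cells x K, rows sum to 1), with preprocessing metadata."""

    spectra: np.ndarray
    usages: np.ndarray
    K: int
    gene_subset: np.ndarray | None = None
    reconstruction_error: float = np.nan
    error_trace: np.ndarray | None = None
    n_iter: int = 0


@dataclass
class ConsensusResult:
    stability: dict  # K -> mean silhouette of clustered components
    error: dict  # K -> consensus reconstruction error
    selected_K: int
    n_restarts: int
    flat_error_warning: bool = False


@dataclass
class SubtypeProportions:
    fractions: pd.DataFrame  # samples x K, rows sum to 1 (NaN rows = no malignant cells)
    counts: pd.DataFrame  # samples x K assigned-cell counts
    n_unassigned: int = 0


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_for_nmf(
    counts,
    n_top_genes: int = 2000,
    pseudocount: float = 1.0,
    target_sum: float = 1e4,
):
    """Library-size normalize per cell, pick the most variable genes, and
    scale each gene by its standard deviation.

    All-zero cells are dropped with a warning. If every gene has zero
    variance (e.g. identical cells), gene selection falls back to
    total-expression ranking. Returns ``(X_scaled, gene_idx, gene_sd)``
    where ``X_scaled = X_norm[:, gene_idx] / gene_sd`` — dividing by
    ``gene_sd`` inverts the scaling exactly.
    """
    X = counts.X if hasattr(counts, "X") else counts
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    if n_top_genes > X.shape[1]:
        raise ValueError("n_top_genes exceeds the number of genes")
    totals = X.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        logger.warning("dropping %d all-zero cells before NMF", int((~keep).sum()))
        X = X[keep]
        totals = totals[keep]
    norm = X / totals[:, None] * target_sum
    logn = np.log1p(norm / pseudocount)
    var = logn.var(axis=0)
    # float-tolerant zero-variance check: identical cells leave O(eps^2) noise
    if var.max() <= 1e-12 * max(float(np.mean(logn) ** 2), 1e-30):
        logger.warning("all genes have zero variance; ranking genes by total expression")
        rank = norm.sum(axis=0)
    else:
        rank = var
    gene_idx = np.sort(np.argsort(rank, kind="stable")[::-1][:n_top_genes])
    sub = norm[:, gene_idx]
    sd = sub.std(axis=0)
    sd[sd == 0] = 1.0
    return sub / sd, gene_idx, sd, keep


# ---------------------------------------------------------------------------
# NMF by multiplicative updates
# ---------------------------------------------------------------------------

def _mu_iterate(X, W, H, update_w=True):
    """One multiplicative-update sweep minimizing ||X - WH||_F^2."""
    H *= (W.T @ X) / (W.T @ W @ H + _EPS)
    if update_w:
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
    return W, H


def _normalize_model(W, H):
    """Spectra rows to unit L2 norm; usage rows to sum 1 (zero rows stay zero)."""
    norms = np.linalg.norm(H, axis=1)
    norms[norms == 0] = 1.0
    H = H / norms[:, None]
    W = W * norms[None, :]
    rowsum = W.sum(axis=1)
    rowsum[rowsum == 0] = 1.0
    return W / rowsum[:, None], H


def _nndsvd_init(X, K):
    """Boutsidis-Gallopoulos SVD-based non-negative init (zeros filled with
    the matrix mean); much faster MU convergence on near-low-rank inputs."""
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    W = np.zeros((X.shape[0], K))
    H = np.zeros((K, X.shape[1]))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0] = np.sqrt(S[0]) * np.abs(Vt[0])
    for j in range(1, K):
        u, v = U[:, j], Vt[j]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        if np.linalg.norm(up) * np.linalg.norm(vp) >= np.linalg.norm(un) * np.linalg.norm(vn):
            u_, v_ = up, vp
        else:
            u_, v_ = un, vn
        nu, nv = np.linalg.norm(u_), np.linalg.norm(v_)
        scale = np.sqrt(S[j] * nu * nv) if nu * nv > 0 else 0.0
        if nu > 0:
            W[:, j] = scale * u_ / nu
        if nv > 0:
            H[j] = scale * v_ / nv
    fill = X.mean()
    W[W <= 0] = fill
    H[H <= 0] = fill
    return W, H


def _anls_polish(X, W, H, sweeps: int):
    """Alternating exact NNLS sweeps; pulls an MU solution to a stationary
    point much faster than the multiplicative tail on small instances."""
    from scipy.optimize import nnls as _nnls

    for _ in range(sweeps):
        for j in range(X.shape[1]):
            H[:, j], _ = _nnls(W, X[:, j])
        for i in range(X.shape[0]):
            W[i], _ = _nnls(H.T, X[i])
    return W, H


def fit_nmf(
    X: np.ndarray,
    K: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
    record_trace: bool = False,
    init: str = "random",
    polish_sweeps: int = 0,
) -> ProgramModel:
    """Rank-K NMF of a non-negative matrix by multiplicative updates.

    Minimizes squared Frobenius reconstruction error; stops when the
    relative error change between sweeps drops below ``tol``. ``init`` is
    "random" (default; what the consensus restarts rely on) or "nndsvd".
    ``polish_sweeps`` optionally finishes with exact alternating-NNLS sweeps
    (small instances only: cost grows with the matrix dimensions).
    """
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("X must be non-negative")
    if not 2 <= K <= min(X.shape):
        raise ValueError(f"K={K} outside [2, min(X.shape)={min(X.shape)}]")
    if init == "nndsvd":
        W, H = _nndsvd_init(X, K)
    else:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x4E4D46]))
        scale = np.sqrt(X.mean() / K)
        W = scale * rng.random((X.shape[0], K)) + _EPS
        H = scale * rng.random((K, X.shape[1])) + _EPS
    norm_x = np.linalg.norm(X)
    prev = np.inf
    trace = []
    n_iter = 0
    for it in range(max_iter):
        W, H = _mu_iterate(X, W, H)
        err = np.linalg.norm(X - W @ H)
        if record_trace:
            trace.append(err)
        n_iter = it + 1
        if prev < np.inf and abs(prev - err) <= tol * max(prev, _EPS):
            prev = err
            break
        prev = err
    if polish_sweeps > 0:
        W, H = _anls_polish(X, W, H, polish_sweeps)
        prev = np.linalg.norm(X - W @ H)
    Wn, Hn = _normalize_model(W, H)
    rel = prev / max(norm_x, _EPS)
    return ProgramModel(
        spectra=Hn, usages=Wn, K=K, reconstruction_error=float(rel),
        error_trace=np.array(trace) if record_trace else None, n_iter=n_iter,
    )


def refit_usages(X: np.ndarray, spectra: np.ndarray, max_iter: int = 200, tol: float = 1e-6):
    """Fit usages against fixed spectra by W-only multiplicative updates."""
    X = np.asarray(X, dtype=float)
    H = np.asarray(spectra, dtype=float)
    rng = np.random.default_rng(0)
    W = np.full((X.shape[0], H.shape[0]), X.mean() / max(H.shape[0], 1)) + _EPS
    prev = np.inf
    for _ in range(max_iter):
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        err = np.linalg.norm(X - W @ H)
        if prev < np.inf and abs(prev - err) <= tol * max(prev, _EPS):
            break
        prev = err
    return W, prev


# ---------------------------------------------------------------------------
# consensus over restarts
# ---------------------------------------------------------------------------

def consensus_nmf(
    X: np.ndarray,
    K_range,
    n_restarts: int = 20,
    outlier_filter_quantile: float = 0.95,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
    error_tolerance: float = 1.1,
):
    """Consensus NMF: restarts per K, outlier filtering, component clustering.

    For each K the L2-normalized spectra from all restarts are pooled;
    components whose cosine distance to their nearest neighbour (from a
    different restart) exceeds the ``outlier_filter_quantile`` quantile are
    dropped; the rest are clustered into K groups (KMeans on the unit
    sphere) and the mean silhouette is the stability. Consensus spectra are
    cluster medians; usages are refit against them and the relative
    reconstruction error recorded. ``selected_K`` maximizes stability among
    K whose error is within ``error_tolerance`` times the minimum error.
    Returns ``(ConsensusResult, ProgramModel at selected_K)``.
    """
    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range must be non-empty")
    if n_restarts < 10:
        raise ValueError("need n_restarts >= 10 for a meaningful consensus")
    X = np.asarray(X, dtype=float)
    norm_x = np.linalg.norm(X)
    stability, error, consensus_spectra = {}, {}, {}
    ss = np.random.SeedSequence([seed, 0xC05])
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(K_range) * n_restarts)]
    flat_warning = False
    for ki, K in enumerate(K_range):
        pool = []
        restart_of = []
        for r in range(n_restarts):
            m = fit_nmf(X, K, seed=child_seeds[ki * n_restarts + r], max_iter=max_iter, tol=tol)
            pool.append(m.spectra)
            restart_of.extend([r] * K)
        comp = np.vstack(pool)  # (n_restarts*K) x genes, unit rows
        restart_of = np.asarray(restart_of)
        # cosine distance to nearest neighbour from a different restart
        sim = comp @ comp.T
        dist = 1.0 - sim
        for r in range(n_restarts):
            mask = restart_of == r
            dist[np.ix_(mask, mask)] = np.inf
        nn = dist.min(axis=1)
        keep = nn <= np.quantile(nn, outlier_filter_quantile)
        kept = comp[keep]
        km = KMeans(n_clusters=K, n_init=10, random_state=seed % (2**31)).fit(kept)
        labels = km.labels_
        if len(np.unique(labels)) < 2:
            stability[K] = 0.0
        else:
            stability[K] = float(silhouette_score(kept, labels))
        med = np.vstack([np.median(kept[labels == c], axis=0) for c in range(K)])
        med = np.maximum(med, 0.0)
        norms = np.linalg.norm(med, axis=1)
        norms[norms == 0] = 1.0
        med = med / norms[:, None]
        consensus_spectra[K] = med
        _, err = refit_usages(X, med)
        error[K] = float(err / max(norm_x, _EPS))
    errs = np.array([error[K] for K in K_range])
    if errs.max() - errs.min() < 1e-6 * max(errs.max(), 1.0):
        logger.warning("consensus reconstruction error is flat across K_range")
        flat_warning = True
    admissible = [K for K in K_range if error[K] <= error_tolerance * errs.min()]
    selected_K = max(admissible, key=lambda K: (stability[K], -K))
    W, err = refit_usages(X, consensus_spectra[selected_K])
    Wn, Hn = _normalize_model(W, consensus_spectra[selected_K].copy())
    model = ProgramModel(
        spectra=Hn, usages=Wn, K=selected_K,
        reconstruction_error=float(err / max(norm_x, _EPS)),
    )
    result = ConsensusResult(
        stability=stability, error=error, selected_K=selected_K,
        n_restarts=n_restarts, flat_error_warning=flat_warning,
    )
    return result, model


# ---------------------------------------------------------------------------
# assignment and proportions
# ---------------------------------------------------------------------------

def assign_subtype(usages: np.ndarray) -> np.ndarray:
    """Per-cell subtype label = argmax usage; ties break to the lowest
    program index; all-zero rows get the ``UNASSIGNED`` (-1) label."""
    usages = np.asarray(usages, dtype=float)
    labels = np.argmax(usages, axis=1)  # numpy argmax takes the first maximum
    zero = usages.sum(axis=1) == 0
    if zero.any():
        logger.warning("%d cells with all-zero usages left unassigned", int(zero.sum()))
        labels = labels.copy()
        labels[zero] = UNASSIGNED
    return labels


def subtype_proportions(labels, sample_ids, malignant_mask, K: int | None = None) -> SubtypeProportions:
    """Per-sample subtype fractions over malignant cells.

    Unassigned cells are excluded from the denominator; samples with no
    malignant cells get NaN fraction rows (missing, not zero).
    """
    labels = np.asarray(labels)
    sample_ids = np.asarray(sample_ids)
    malignant_mask = np.asarray(malignant_mask, dtype=bool)
    if K is None:
        K = int(labels[labels >= 0].max()) + 1 if (labels >= 0).any() else 0
    samples = pd.unique(sample_ids)
    counts = pd.DataFrame(0, index=samples, columns=range(K))
    fractions = pd.DataFrame(np.nan, index=samples, columns=range(K))
    n_unassigned = 0
    for s in samples:
        mask = (sample_ids == s) & malignant_mask
        if not mask.any():
            logger.warning("sample %s has no malignant cells; proportions missing", s)
            continue
        lab = labels[mask]
        n_unassigned += int((lab == UNASSIGNED).sum())
        lab = lab[lab != UNASSIGNED]
        if len(lab) == 0:
            continue
        c = np.bincount(lab, minlength=K)
        counts.loc[s] = c
        fractions.loc[s] = c / c.sum()
    return SubtypeProportions(fractions=fractions, counts=counts, n_unassigned=n_unassigned)


def match_programs(fitted_spectra: np.ndarray, true_spectra: np.ndarray):
    """Greedy-free optimal matching of fitted to true programs by cosine
    similarity (Hungarian assignment). Returns (mapping fitted->true,
    per-pair cosine similarities)."""
    from scipy.optimize import linear_sum_assignment

    A = np.asarray(fitted_spectra, dtype=float)
    B = np.asarray(true_spectra, dtype=float)
    An = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), _EPS)
    Bn = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), _EPS)
    sim = An @ Bn.T
    rows, cols = linear_sum_assignment(-sim)
    return dict(zip(rows, cols)), sim[rows, cols]
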