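"""Supervised integrated factor analysis (SIFA) for multi-block data.

The model couples K feature blocks X_1..X_K observed on the same n subjects
through two kinds of Gaussian latent factors:

- *common* (joint) scores ``U0`` (n x r0) loading on every block through
  block-specific loading matrices ``V0k`` (p_k x r0), and
- *individual* scores ``Uk`` (n x r_k) loading only on block k through
  ``Vk`` (p_k x r_k).

Both kinds of scores are linearly driven by subject covariates Y (n x q):

    U0 = Y B0 + F0,   Uk = Y Bk + Fk,
    X_k = U0 V0k' + Uk Vk' + E_k,

with independent Gaussian score noise F (diagonal variances tau) and
residuals E_k ~ N(0, sigma_k^2 I).  Estimation is by EM on the observed-data
Gaussian likelihood, evaluated with low-rank (Woodbury) identities so the
p x p covariance is never formed.

Identifiability ("SIFA-B" flavour, robust to unbalanced block dimensions):
after fitting, parameters are mapped to a canonical gauge — unit score-noise
variances, mutually orthogonal columns of the stacked joint loading matrix
and of each individual loading matrix, factors ordered by decreasing loading
norm, and each column's largest-magnitude element positive.  The map is
exactly likelihood-preserving.  The synthetic generator additionally makes
truths whose joint loadings have equal norm across blocks and are orthogonal
to the individual loadings within each block, which this gauge preserves.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .data_model import MultiModalDataset

logger = logging.getLogger(__name__)

_TAU_FLOOR = 1e-10
_SIGMA_FLOOR = 1e-12


class SIFAError(ValueError):
    pass


@dataclass(frozen=True)
class SIFARanks:
    """Number of common (``r0``) and per-block individual (``r``) factors."""

    r0: int
    r: tuple[int, ...]

    def __post_init__(self):
        if self.r0 < 0 or any(rk < 0 for rk in self.r):
            raise SIFAError("ranks must be nonnegative")

    @property
    def total(self) -> int:
        return self.r0 + sum(self.r)

    def validate(self, n: int, p: list[int]) -> None:
        if len(self.r) != len(p):
            raise SIFAError("one individual rank per block required")
        for rk, pk in zip(self.r, p):
            if self.r0 + rk >= min(n, pk):
                raise SIFAError(
                    f"rank constraint violated: r0+r_k={self.r0 + rk} "
                    f">= min(n, p_k)={min(n, pk)}"
                )
        # the all-zero combination is admitted: it is the isotropic-noise
        # null model that likelihood cross-validation compares against


@dataclass
class SIFAModel:
    """SIFA parameters.  Shapes: B0 (q,r0); Bk[k] (q,r_k); V0k[k] (p_k,r0);
    Vk[k] (p_k,r_k); tau0 (r0,); tauk[k] (r_k,); sigma2 (K,)."""

    B0: np.ndarray
    Bk: list[np.ndarray]
    V0k: list[np.ndarray]
    Vk: list[np.ndarray]
    tau0: np.ndarray
    tauk: list[np.ndarray]
    sigma2: np.ndarray

    @property
    def K(self) -> int:
        return len(self.V0k)

    @property
    def q(self) -> int:
        return self.B0.shape[0]

    @property
    def ranks(self) -> SIFARanks:
        return SIFARanks(self.V0k[0].shape[1], tuple(V.shape[1] for V in self.Vk))

    @property
    def p(self) -> list[int]:
        return [V.shape[0] for V in self.V0k]

    def copy(self) -> "SIFAModel":
        return SIFAModel(
            B0=self.B0.copy(),
            Bk=[b.copy() for b in self.Bk],
            V0k=[v.copy() for v in self.V0k],
            Vk=[v.copy() for v in self.Vk],
            tau0=self.tau0.copy(),
            tauk=[t.copy() for t in self.tauk],
            sigma2=self.sigma2.copy(),
        )

    def to_dict(self) -> dict:
        """Plain-list container for JSON serialization."""
        return {
            "B0": self.B0.tolist(),
            "Bk": [b.tolist() for b in self.Bk],
            "V0k": [v.tolist() for v in self.V0k],
            "Vk": [v.tolist() for v in self.Vk],
            "tau0": self.tau0.tolist(),
            "tauk": [t.tolist() for t in self.tauk],
            "sigma2": self.sigma2.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SIFAModel":
        return cls(
            B0=np.asarray(d["B0"], float),
            Bk=[np.asarray(b, float) for b in d["Bk"]],
            V0k=[np.asarray(v, float) for v in d["V0k"]],
            Vk=[np.asarray(v, float) for v in d["Vk"]],
            tau0=np.asarray(d["tau0"], float),
            tauk=[np.asarray(t, float) for t in d["tauk"]],
            sigma2=np.asarray(d["sigma2"], float),
        )


@dataclass
class SIFAFit:
    model: SIFAModel
    U0_hat: np.ndarray
    Uk_hat: list[np.ndarray]
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    posterior_cov: np.ndarray | None = None
    sparsity: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

def _layout(ranks: SIFARanks):
    """Column indices of each factor group in the combined score matrix."""
    joint = np.arange(ranks.r0)
    offs = ranks.r0
    blocks = []
    for rk in ranks.r:
        blocks.append(np.arange(offs, offs + rk))
        offs += rk
    return joint, blocks


def _assemble(model: SIFAModel):
    """Stack loadings into W (p x R), score-noise variances T (R,), and the
    per-feature residual variance d (p,)."""
    ranks = model.ranks
    p = model.p
    R = ranks.total
    W = np.zeros((sum(p), R))
    joint, blk_idx = _layout(ranks)
    row = 0
    for k, pk in enumerate(p):
        if ranks.r0:
            W[row : row + pk, joint] = model.V0k[k]
        if ranks.r[k]:
            W[row : row + pk, blk_idx[k]] = model.Vk[k]
        row += pk
    T = np.concatenate([model.tau0] + list(model.tauk)) if R else np.empty(0)
    d = np.concatenate(
        [np.full(pk, model.sigma2[k]) for k, pk in enumerate(p)]
    )
    B_all = (
        np.concatenate([model.B0] + list(model.Bk), axis=1)
        if R
        else np.empty((model.q, 0))
    )
    return W, T, d, B_all


def _moments(model: SIFAModel, X: np.ndarray, Y: np.ndarray):
    """Posterior score moments and observed-data log-likelihood.

    Returns (M, Sigma_u, loglik) where M (n,R) holds the per-subject
    posterior mean scores and Sigma_u (R,R) the (subject-independent)
    posterior covariance.
    """
    n, p = X.shape
    W, T, d, B_all = _assemble(model)
    R = W.shape[1]
    if np.any(model.sigma2 <= 0) or (R and np.any(T <= 0)):
        raise SIFAError("variances must be positive")
    mu_u = Y @ B_all  # (n, R); zero when q == 0
    Resid = X - mu_u @ W.T
    dinv_quad = (Resid**2 / d).sum()
    base = -0.5 * (n * p * np.log(2 * np.pi) + n * np.log(d).sum())
    if R == 0:
        return (
            np.empty((n, 0)),
            np.empty((0, 0)),
            base - 0.5 * dinv_quad,
        )
    A = W / d[:, None]  # D^{-1} W
    G = W.T @ A  # W' D^{-1} W
    P = np.diag(1.0 / T) + G  # posterior precision
    L = np.linalg.cholesky(P)
    Sigma_u = np.linalg.inv(P)
    Sigma_u = 0.5 * (Sigma_u + Sigma_u.T)
    RA = Resid @ A  # (n, R) = (x - W mu)' D^{-1} W
    M = mu_u + RA @ Sigma_u
    # log|Sigma| = log|D| + log|T| + log|P|
    logdet_extra = np.log(T).sum() + 2 * np.log(np.diag(L)).sum()
    # quadratic: r'D^{-1}r - (r'D^{-1}W) Sigma_u (W'D^{-1}r), summed over rows
    corr = np.einsum("ij,jk,ik->", RA, Sigma_u, RA)
    loglik = base - 0.5 * (n * logdet_extra + dinv_quad - corr)
    return M, Sigma_u, float(loglik)


def observed_loglik(model: SIFAModel, ds: MultiModalDataset) -> float:
    """Exact Gaussian log-likelihood of the concatenated features given the
    covariates, evaluated with Woodbury identities (cost O(n p R), never
    forming the p x p covariance)."""
    X = ds.concatenated()
    Y = ds.covariates.Y
    if X.shape[1] != sum(model.p):
        raise SIFAError("dataset dimensions do not match model")
    _, _, ll = _moments(model, X, Y)
    return ll


def posterior_scores(
    model: SIFAModel, ds: MultiModalDataset
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Posterior mean latent scores for (possibly unseen) subjects.

    New subjects must be standardized with the *training* standardization
    record; closed-form Gaussian conditioning, no refitting.
    """
    X = ds.concatenated()
    if X.shape[1] != sum(model.p):
        raise SIFAError("dataset dimensions do not match model")
    M, _, _ = _moments(model, X, ds.covariates.Y)
    joint, blk_idx = _layout(model.ranks)
    return M[:, joint], [M[:, idx] for idx in blk_idx]


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _initialize(
    X_blocks: list[np.ndarray], Y: np.ndarray, ranks: SIFARanks, rng, jitter: float
) -> SIFAModel:
    """SVD warm start: joint loadings from the concatenated blocks,
    individual loadings from per-block residual SVDs, B from least squares."""
    n = X_blocks[0].shape[0]
    q = Y.shape[1]
    Xc = np.hstack(X_blocks)
    r0 = ranks.r0
    if r0:
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        U0 = U[:, :r0] * np.sqrt(n)
        V0 = Vt[:r0].T * (s[:r0] / np.sqrt(n))
    else:
        U0 = np.empty((n, 0))
        V0 = np.empty((Xc.shape[1], 0))
    # split stacked joint loadings per block
    V0k, row = [], 0
    for Xk in X_blocks:
        pk = Xk.shape[1]
        V0k.append(V0[row : row + pk].copy())
        row += pk
    Vk_list, Uk_list = [], []
    for k, Xk in enumerate(X_blocks):
        rk = ranks.r[k]
        Rk = Xk - U0 @ V0k[k].T
        if rk:
            U, s, Vt = np.linalg.svd(Rk, full_matrices=False)
            Uk_list.append(U[:, :rk] * np.sqrt(n))
            Vk_list.append(Vt[:rk].T * (s[:rk] / np.sqrt(n)))
        else:
            Uk_list.append(np.empty((n, 0)))
            Vk_list.append(np.empty((Xk.shape[1], 0)))
    scores = np.hstack([U0] + Uk_list)
    if q:
        B_all, *_ = np.linalg.lstsq(Y, scores, rcond=None)
        resid_scores = scores - Y @ B_all
    else:
        B_all = np.empty((0, scores.shape[1]))
        resid_scores = scores
    tau_all = np.maximum(resid_scores.var(axis=0), 1e-2) if scores.size else np.empty(0)
    joint, blk_idx = _layout(ranks)
    sigma2 = np.empty(len(X_blocks))
    for k, Xk in enumerate(X_blocks):
        fit_k = U0 @ V0k[k].T + Uk_list[k] @ Vk_list[k].T
        sigma2[k] = max(np.mean((Xk - fit_k) ** 2), 1e-4)
    if jitter:
        V0k = [v + jitter * rng.standard_normal(v.shape) for v in V0k]
        Vk_list = [v + jitter * rng.standard_normal(v.shape) for v in Vk_list]
    return SIFAModel(
        B0=B_all[:, joint],
        Bk=[B_all[:, idx] for idx in blk_idx],
        V0k=V0k,
        Vk=Vk_list,
        tau0=tau_all[joint].copy(),
        tauk=[tau_all[idx].copy() for idx in blk_idx],
        sigma2=sigma2,
    )


def em_fit(
    ds: MultiModalDataset,
    ranks: SIFARanks,
    tol: float = 1e-7,
    max_iter: int = 500,
    seed: int | None = None,
    jitter: float = 0.0,
    init: SIFAModel | None = None,
    canonicalize: bool = True,
) -> SIFAFit:
    """Fit the SIFA model by EM.

    The E-step computes the joint Gaussian posterior of all latent scores in
    closed form; the M-step updates B (least squares of posterior score means
    on Y), the loadings (per-block least squares against posterior score
    moments), and the variances.  The observed-data log-likelihood is
    monotone non-decreasing across iterations.  ``seed`` only controls the
    optional initialization ``jitter``.
    """
    X_blocks = ds.matrices()
    Y = ds.covariates.Y
    n = X_blocks[0].shape[0]
    p = [Xk.shape[1] for Xk in X_blocks]
    ranks.validate(n, p)
    rng = np.random.default_rng(seed)
    model = init.copy() if init is not None else _initialize(
        X_blocks, Y, ranks, rng, jitter
    )
    X = np.hstack(X_blocks)
    joint, blk_idx = _layout(ranks)
    R = ranks.total
    q = Y.shape[1]
    trace = []
    converged = False
    M = np.empty((n, 0))
    Sigma_u = np.empty((0, 0))
    it = 0
    for it in range(1, max_iter + 1):
        M, Sigma_u, ll = _moments(model, X, Y)
        trace.append(ll)
        if len(trace) > 1:
            prev = trace[-2]
            if abs(ll - prev) / (1.0 + abs(prev)) < tol:
                converged = True
                break
        # ---- M-step ----
        S = M.T @ M + n * Sigma_u  # E[sum u u']
        if q:
            B_all, *_ = np.linalg.lstsq(Y, M, rcond=None)
            score_resid = M - Y @ B_all
        else:
            B_all = np.empty((0, R))
            score_resid = M
        tau_all = np.maximum(
            (score_resid**2).mean(axis=0) + np.diag(Sigma_u), _TAU_FLOOR
        )
        row = 0
        for k, Xk in enumerate(X_blocks):
            pk = p[k]
            sel = np.concatenate([joint, blk_idx[k]]).astype(int)
            if sel.size:
                S_sel = S[np.ix_(sel, sel)]
                C = Xk.T @ M[:, sel]  # (p_k, m)
                V_sel = np.linalg.solve(S_sel, C.T).T
                model.V0k[k] = V_sel[:, : ranks.r0]
                model.Vk[k] = V_sel[:, ranks.r0 :]
                rss = (
                    (Xk**2).sum()
                    - 2.0 * (V_sel * C).sum()
                    + np.einsum("ij,jk,ik->", V_sel, S_sel, V_sel)
                )
            else:
                rss = (Xk**2).sum()
            model.sigma2[k] = max(rss / (n * pk), _SIGMA_FLOOR)
            row += pk
        model.B0 = B_all[:, joint]
        model.Bk = [B_all[:, idx] for idx in blk_idx]
        model.tau0 = tau_all[joint].copy()
        model.tauk = [tau_all[idx].copy() for idx in blk_idx]
    if not converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations "
            f"(last rel. change {abs(trace[-1] - trace[-2]) / (1 + abs(trace[-2])):.2e})"
            if len(trace) > 1
            else "EM did not converge",
            RuntimeWarning,
        )
        M, Sigma_u, ll = _moments(model, X, Y)
        trace.append(ll)
    U0_hat = M[:, joint]
    Uk_hat = [M[:, idx] for idx in blk_idx]
    fit = SIFAFit(
        model=model,
        U0_hat=U0_hat,
        Uk_hat=Uk_hat,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
        posterior_cov=Sigma_u,
    )
    if canonicalize:
        fit = apply_identifiability_fit(fit, Y)
    return fit


# ---------------------------------------------------------------------------
# Identifiability
# ---------------------------------------------------------------------------

def _canon_group(V: np.ndarray, tau: np.ndarray, B: np.ndarray):
    """Canonicalize one factor group: absorb tau into the loadings, SVD to
    orthogonal columns with decreasing norms, fix signs.  Returns
    (V', tau'=1, B'); the fitted mean contribution Y B V' is unchanged."""
    r = V.shape[1]
    if r == 0:
        return V, tau, B
    sq = np.sqrt(tau)
    Vs = V * sq  # scale columns
    U, s, Vt = np.linalg.svd(Vs, full_matrices=False)
    if np.any(s < 1e-12):
        raise SIFAError("rank-deficient loading column (norm < 1e-12)")
    Q = Vt.T
    V_new = U * s
    B_new = (B / sq) @ Q if B.size else B.reshape(B.shape[0], r)
    # sign rule: largest-magnitude element of each column positive
    flip = np.ones(r)
    for j in range(r):
        i = int(np.argmax(np.abs(V_new[:, j])))
        if V_new[i, j] < 0:
            flip[j] = -1.0
    return V_new * flip, np.ones(r), B_new * flip


def apply_identifiability(model: SIFAModel) -> SIFAModel:
    """Map parameters to the canonical gauge, preserving the likelihood.

    Score-noise variances are absorbed into the loadings (tau -> 1); the
    stacked joint loading matrix and each block's individual loading matrix
    get mutually orthogonal columns ordered by decreasing norm; each column's
    largest-magnitude element is made positive.  Coefficients B are
    transformed so all fitted means are unchanged.
    """
    model = model.copy()
    r0 = model.ranks.r0
    if r0:
        V0 = np.vstack(model.V0k)
        V_new, tau_new, B_new = _canon_group(V0, model.tau0, model.B0)
        row = 0
        for k, pk in enumerate(model.p):
            model.V0k[k] = V_new[row : row + pk]
            row += pk
        model.tau0 = tau_new
        model.B0 = B_new
    for k in range(model.K):
        if model.ranks.r[k]:
            V_new, tau_new, B_new = _canon_group(
                model.Vk[k], model.tauk[k], model.Bk[k]
            )
            model.Vk[k] = V_new
            model.tauk[k] = tau_new
            model.Bk[k] = B_new
    return model


def apply_identifiability_fit(fit: SIFAFit, Y: np.ndarray) -> SIFAFit:
    """Canonicalize a fit, transforming the stored posterior scores with the
    same factor rotation so fitted reconstructions are unchanged."""
    old = fit.model
    new = apply_identifiability(old)
    maps = {}

    # scores transform as u' = Y B' + (u - Y B_old) @ M with
    # M = diag(1/sqrt(tau)) Q flip, recovered from the loading pair
    def _score_transform(key, U, B_old, B_new, tau, V_old_stk, V_new_stk):
        r = U.shape[1]
        if r == 0:
            maps[key] = np.empty((0, 0))
            return U
        sq = np.sqrt(tau)
        Qf, *_ = np.linalg.lstsq(V_old_stk * sq, V_new_stk, rcond=None)
        M = np.diag(1.0 / sq) @ Qf
        maps[key] = M
        noise = U - (Y @ B_old if B_old.size else 0.0)
        out = noise @ M
        if B_new.size:
            out = out + Y @ B_new
        return out

    U0 = _score_transform(
        "joint", fit.U0_hat, old.B0, new.B0, old.tau0,
        np.vstack(old.V0k) if old.ranks.r0 else np.empty((sum(old.p), 0)),
        np.vstack(new.V0k) if new.ranks.r0 else np.empty((sum(new.p), 0)),
    )
    Uk = [
        _score_transform(f"block{k}", fit.Uk_hat[k], old.Bk[k], new.Bk[k],
                         old.tauk[k], old.Vk[k], new.Vk[k])
        for k in range(old.K)
    ]
    post_cov = None
    if fit.posterior_cov is not None:
        from scipy.linalg import block_diag

        M_full = block_diag(*[maps["joint"]] +
                            [maps[f"block{k}"] for k in range(old.K)])
        post_cov = M_full.T @ fit.posterior_cov @ M_full
    return SIFAFit(
        model=new,
        U0_hat=U0,
        Uk_hat=Uk,
        loglik_trace=fit.loglik_trace,
        converged=fit.converged,
        n_iter=fit.n_iter,
        posterior_cov=post_cov,
        sparsity=dict(fit.sparsity),
    )


def validate_identifiability(
    model: SIFAModel, atol: float = 1e-8, strict: bool = False
) -> None:
    """Raise if the model is not in canonical gauge.

    ``strict`` additionally checks the structural conditions the synthetic
    truths satisfy: within each block the combined [V0k | Vk] columns are
    mutually orthogonal, and each joint factor has equal loading norm across
    blocks.
    """
    r0 = model.ranks.r0
    if r0 and not np.allclose(model.tau0, 1.0, atol=atol):
        raise SIFAError("joint score-noise variances not unit")
    for k in range(model.K):
        if model.ranks.r[k] and not np.allclose(model.tauk[k], 1.0, atol=atol):
            raise SIFAError("individual score-noise variances not unit")

    def _check_cols(V, label):
        r = V.shape[1]
        if r == 0:
            return
        G = V.T @ V
        off = G - np.diag(np.diag(G))
        if np.max(np.abs(off)) > atol * max(1.0, np.max(np.abs(G))):
            raise SIFAError(f"{label}: columns not orthogonal")
        norms = np.sqrt(np.diag(G))
        if np.any(np.diff(norms) > atol):
            raise SIFAError(f"{label}: columns not in decreasing-norm order")
        for j in range(r):
            i = int(np.argmax(np.abs(V[:, j])))
            if V[i, j] < 0:
                raise SIFAError(f"{label}: sign rule violated in column {j}")

    if r0:
        _check_cols(np.vstack(model.V0k), "stacked joint loadings")
    for k in range(model.K):
        _check_cols(model.Vk[k], f"individual loadings block {k}")
    if strict:
        for k in range(model.K):
            Vc = np.hstack([model.V0k[k], model.Vk[k]])
            G = Vc.T @ Vc
            off = G - np.diag(np.diag(G))
            if off.size and np.max(np.abs(off)) > atol * max(1.0, np.max(np.abs(G))):
                raise SIFAError(f"block {k}: [V0k | Vk] not mutually orthogonal")
        if r0 and model.K > 1:
            norms = np.array(
                [np.linalg.norm(model.V0k[k], axis=0) for k in range(model.K)]
            )
            if np.max(norms.max(axis=0) - norms.min(axis=0)) > 1e-6 * norms.max():
                raise SIFAError("joint loading norms unequal across blocks")


# ---------------------------------------------------------------------------
# Rank selection by likelihood cross-validation
# ---------------------------------------------------------------------------

def select_ranks_lcv(
    ds: MultiModalDataset,
    r0_grid=(0, 1, 2, 3),
    rk_grid=(0, 1, 2),
    n_folds: int = 5,
    seed: int = 0,
    max_grid: int = 200,
    em_kwargs: dict | None = None,
) -> tuple[SIFARanks, pd.DataFrame]:
    """Choose factor ranks by likelihood cross-validation.

    Subjects are split into ``n_folds`` folds (stratified by group when
    possible); each candidate rank combination is fitted on the training
    folds and scored by the mean held-out per-subject log-likelihood; the
    maximizing combination wins.  When the full grid exceeds ``max_grid``
    combinations a greedy search optimizes r0 first (individual ranks at the
    smallest candidate), then each block's rank in turn.
    """
    if n_folds < 2:
        raise SIFAError("n_folds must be >= 2")
    em_kwargs = dict(em_kwargs or {})
    em_kwargs.setdefault("tol", 1e-5)
    em_kwargs.setdefault("max_iter", 200)
    em_kwargs.setdefault("canonicalize", False)
    K = ds.n_blocks
    n = ds.n_subjects
    labels = ds.covariates.group_labels
    idx = np.arange(n)
    min_class = min(np.bincount(pd.factorize(labels)[0])) if n else 0
    if n_folds <= min_class:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = list(splitter.split(idx, labels))
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = list(splitter.split(idx))

    def score(ranks: SIFARanks) -> float | None:
        try:
            ranks.validate(min(len(tr) for tr, _ in folds), ds.block_dims)
        except SIFAError as exc:
            logger.info("skipping ranks %s: %s", ranks, exc)
            return None
        total = 0.0
        for tr, te in folds:
            with warnings.catch_warnings():
                # candidate fits routinely hit max_iter; LCV only ranks them
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = em_fit(ds.subset(tr), ranks, **em_kwargs)
            total += observed_loglik(fit.model, ds.subset(te))
        return total / n

    rows = []

    def record(ranks, val):
        rows.append({"r0": ranks.r0, **{f"r{k+1}": ranks.r[k] for k in range(K)},
                     "mean_heldout_loglik": val})

    full = [
        SIFARanks(r0, rk)
        for r0 in r0_grid
        for rk in itertools.product(rk_grid, repeat=K)
    ]
    if len(full) <= max_grid:
        candidates = full
        best, best_val = None, -np.inf
        for ranks in candidates:
            val = score(ranks)
            if val is None:
                continue
            record(ranks, val)
            if val > best_val:
                best, best_val = ranks, val
    else:  # greedy: r0 first, then each block
        rk_min = min(rk_grid)
        best_r0, best_val = r0_grid[0], -np.inf
        for r0 in r0_grid:
            ranks = SIFARanks(r0, (rk_min,) * K)
            val = score(ranks)
            if val is None:
                continue
            record(ranks, val)
            if val > best_val:
                best_r0, best_val = r0, val
        rk = [rk_min] * K
        for k in range(K):
            for cand in rk_grid:
                if cand == rk[k]:
                    continue
                trial = rk.copy()
                trial[k] = cand
                ranks = SIFARanks(best_r0, tuple(trial))
                val = score(ranks)
                if val is None:
                    continue
                record(ranks, val)
                if val > best_val:
                    rk, best_val = trial, val
        best = SIFARanks(best_r0, tuple(rk))
    if best is None:
        raise SIFAError("no admissible rank combination in the grid")
    table = pd.DataFrame(rows).sort_values(
        "mean_heldout_loglik", ascending=False, ignore_index=True
    )
    return best, table


# ---------------------------------------------------------------------------
# Sparsification
# ---------------------------------------------------------------------------

def _lasso_loadings(S, C, lam, V0):
    """Minimize 0.5*E||x_f - u'v_f||^2 + lam*||v_f||_1 for every feature f,
    by cyclic coordinate descent on the score Gram matrix S = E[sum u u'].
    ``C`` is (m, p) = E[U]' X; returns V (p, m)."""
    m = S.shape[0]
    V = V0.copy()
    diag = np.diag(S)
    for _ in range(200):
        V_old = V.copy()
        for j in range(m):
            # partial residual correlation for every feature at once
            c = C[j] - V @ S[j] + V[:, j] * diag[j]
            V[:, j] = np.sign(c) * np.maximum(np.abs(c) - lam, 0.0) / diag[j]
        if np.max(np.abs(V - V_old)) < 1e-10 * (1 + np.max(np.abs(V))):
            break
    return V


def sparsify_loadings(
    fit: SIFAFit,
    ds: MultiModalDataset,
    penalty: str | float = "cv",
    n_folds: int = 5,
    n_lambda: int = 12,
    seed: int = 0,
) -> SIFAFit:
    """L1-sparsify the loading matrices for feature selection.

    Holding the posterior scores fixed, each block's loadings are
    re-estimated by L1-penalized least squares of the data on the scores
    (cyclic soft-thresholding; exact soft-thresholding when scores are
    orthogonal).  With ``penalty="cv"`` the per-block lambda is chosen by
    ``n_folds``-fold cross-validated reconstruction error with the
    one-standard-error rule; a float ``penalty`` fixes lambda directly
    (0 leaves the loadings at their least-squares values, i.e. unchanged).
    """
    model = fit.model.copy()
    ranks = model.ranks
    n = ds.n_subjects
    scores = np.hstack([fit.U0_hat] + fit.Uk_hat)
    joint, blk_idx = _layout(ranks)
    Sigma_u = fit.posterior_cov
    rng = np.random.default_rng(seed)
    chosen = {}
    for k, Xk in enumerate(ds.matrices()):
        sel = np.concatenate([joint, blk_idx[k]]).astype(int)
        if not sel.size:
            continue
        M_sel = scores[:, sel]
        extra = n * Sigma_u[np.ix_(sel, sel)] if Sigma_u is not None else 0.0
        S = M_sel.T @ M_sel + extra
        C = M_sel.T @ Xk
        V_cur = np.hstack([model.V0k[k], model.Vk[k]])
        if penalty == "cv":
            lam_max = np.max(np.abs(C))
            grid = lam_max * np.logspace(0, -3, n_lambda)
            perm = rng.permutation(n)
            fold_ids = np.array_split(perm, n_folds)
            errs = np.zeros((n_folds, len(grid)))
            for f, te in enumerate(fold_ids):
                tr = np.setdiff1d(perm, te)
                M_tr, M_te = M_sel[tr], M_sel[te]
                S_tr = M_tr.T @ M_tr + (
                    len(tr) * Sigma_u[np.ix_(sel, sel)]
                    if Sigma_u is not None
                    else 0.0
                )
                C_tr = M_tr.T @ Xk[tr]
                V = V_cur
                for g, lam_g in enumerate(grid):
                    V = _lasso_loadings(S_tr, C_tr, lam_g, V)
                    errs[f, g] = ((Xk[te] - M_te @ V.T) ** 2).mean()
            mean_err = errs.mean(axis=0)
            se = errs.std(axis=0, ddof=1) / np.sqrt(n_folds)
            best = int(np.argmin(mean_err))
            # one-SE rule: the sparsest (largest) lambda within one SE
            ok = np.flatnonzero(mean_err <= mean_err[best] + se[best])
            lam = float(grid[ok.min()])
        else:
            lam = float(penalty)
        # lambda = 0 imposes no penalty: the loadings stay at their
        # (EM least-squares) values
        V_new = _lasso_loadings(S, C, lam, V_cur) if lam > 0 else V_cur
        dead = np.flatnonzero(np.all(V_new == 0.0, axis=0))
        if dead.size:
            warnings.warn(
                f"block {k}: lambda={lam:.3g} zeroed factor column(s) {dead.tolist()};"
                " retained with empty support",
                RuntimeWarning,
            )
        model.V0k[k] = V_new[:, : ranks.r0]
        model.Vk[k] = V_new[:, ranks.r0 :]
        chosen[k] = {
            "lambda": lam,
            "n_zero": int((V_new == 0.0).sum()),
            "n_total": int(V_new.size),
        }
    return SIFAFit(
        model=model,
        U0_hat=fit.U0_hat,
        Uk_hat=[u.copy() for u in fit.Uk_hat],
        loglik_trace=fit.loglik_trace,
        converged=fit.converged,
        n_iter=fit.n_iter,
        posterior_cov=fit.posterior_cov,
        sparsity=chosen,
    )


# ---------------------------------------------------------------------------
# Variance explained
# ---------------------------------------------------------------------------

def variance_explained(fit: SIFAFit, ds: MultiModalDataset) -> pd.DataFrame:
    """Percent variation captured per block by the common factors, the
    individual factors, and all latent factors together
    (||reconstruction||_F^2 / ||X_k||_F^2 x 100)."""
    rows = []
    for k, blk in enumerate(ds.blocks):
        Xk = blk.values
        total = (Xk**2).sum()
        J = fit.U0_hat @ fit.model.V0k[k].T
        A = fit.Uk_hat[k] @ fit.model.Vk[k].T
        rows.append(
            {
                "modality": blk.modality,
                "common_pct": 100.0 * (J**2).sum() / total,
                "individual_pct": 100.0 * (A**2).sum() / total,
                "all_latent_pct": 100.0 * ((J + A) ** 2).sum() / total,
            }
        )
    return pd.DataFrame(rows)
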