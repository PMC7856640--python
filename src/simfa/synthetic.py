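"""Synthetic multimodal datasets drawn from the exact SIFA generative model.

The generator emulates the study design at the feature-table level: K
modality blocks on n subjects, latent scores linearly driven by group, age,
sex and race, block-specific loadings and residual noise, and a demographics
table with the cohort's structure (healthy controls vs. two first-episode
psychosis subgroups, ages ~N(23, 4) truncated to [15, 35]).

Truth parameters are stored in the canonical identifiability gauge of
:mod:`simfa.sifa` (and additionally satisfy the stricter structural
conditions: per-block orthogonality of joint and individual loadings, equal
joint-loading norms across blocks), so recovery tests compare like with
like.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    CovariateDesign,
    DataModelError,
    FeatureBlock,
    MultiModalDataset,
    encode_covariates,
)
from .sifa import SIFAFit, SIFAModel, SIFARanks, apply_identifiability_fit

#: Cohort structure: 62 HC, 61 schizophrenia-spectrum FEP, 26 mood-disorder FEP.
DEFAULT_GROUP_PROPORTIONS = {"HC": 62 / 149, "S_FEP": 61 / 149, "M_FEP": 26 / 149}

_MODALITY_ORDER = ("volume", "FA", "MD", "rsfmri")


@dataclass
class SimulationConfig:
    """Generative settings.  Defaults mirror the study cohort (n=149, four
    blocks of 198/96/96/2415 features); tests shrink ``n``/``p`` for speed."""

    n: int = 149
    p: tuple[int, ...] = (198, 96, 96, 2415)
    r0: int = 2
    r: tuple[int, ...] = (1, 1, 1, 1)
    group_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROPORTIONS)
    )
    #: per-factor SD of the score noise F (1.0 = canonical gauge)
    score_noise_sd: float = 1.0
    #: per-block residual SD sigma_k (scalar broadcast to all blocks)
    resid_sd: float | tuple[float, ...] = 1.0
    #: fraction of exact zeros per loading column (disjoint-support scheme)
    loading_sparsity: float = 0.0
    #: per-feature signal-to-noise of the leading joint factor
    snr: float = 2.0
    #: geometric decay of loading norms across factors (for strict ordering)
    strength_decay: float = 0.8
    #: group-dummy coefficients on joint scores (S_FEP row scale)
    group_beta: float = 1.0
    #: group-dummy coefficients on individual scores (0 = signal joint-only)
    group_beta_indiv: float = 0.0
    #: age/sex/race coefficients on all scores
    nuisance_beta: float = 0.2
    #: explicit coefficient matrices (override the scalar fields when given)
    B0: np.ndarray | None = None
    Bk: list | None = None
    seed: int = 0

    @property
    def K(self) -> int:
        return len(self.p)

    def validate(self) -> None:
        if len(self.r) != self.K:
            raise DataModelError("one individual rank per block required")
        SIFARanks(self.r0, tuple(self.r)).validate(self.n, list(self.p))
        total = sum(self.group_proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise DataModelError("group proportions must sum to 1")
        if not 0.0 <= self.loading_sparsity < 1.0:
            raise DataModelError("loading_sparsity must be in [0, 1)")

    @property
    def resid_sd_per_block(self) -> np.ndarray:
        r = np.asarray(self.resid_sd, dtype=float)
        return np.broadcast_to(r, (self.K,)).copy()


@dataclass
class SyntheticTruth:
    """Ground truth: canonical model parameters, realized scores, demographics."""

    model: SIFAModel
    U0: np.ndarray
    Uk: list[np.ndarray]
    demographics: pd.DataFrame
    covariates: CovariateDesign


# ---------------------------------------------------------------------------
# Demographics
# ---------------------------------------------------------------------------

def simulate_demographics(config: SimulationConfig) -> pd.DataFrame:
    """Draw a subject covariate table (group, age, sex, race).

    Groups are multinomial with the configured proportions; age is
    Normal(23, 4) truncated to [15, 35] years; sex is Bernoulli (64% male)
    and race categorical, both matching the cohort's margins.  Deterministic
    under a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    groups = [g for g, w in config.group_proportions.items() if w > 0]
    weights = np.array([config.group_proportions[g] for g in groups])
    weights = weights / weights.sum()
    labels = rng.choice(groups, size=config.n, p=weights)
    counts = pd.Series(labels).value_counts()
    low = [g for g in groups if counts.get(g, 0) < 2]
    if low:
        raise DataModelError(
            f"groups {low} have fewer than 2 subjects; downstream two-sample "
            "tests need n >= 2 per group (increase n or adjust proportions)"
        )
    a, b = (15 - 23) / 4, (35 - 23) / 4
    age = stats.truncnorm.rvs(a, b, loc=23, scale=4, size=config.n, random_state=rng)
    sex = np.where(rng.random(config.n) < 0.64, "M", "F")
    race = rng.choice(
        ["aa", "c", "as", "h", "o"], size=config.n, p=[0.51, 0.38, 0.04, 0.04, 0.03]
    )
    return pd.DataFrame(
        {
            "subject_id": [f"sub{i:04d}" for i in range(config.n)],
            "group": labels,
            "age": np.round(age, 1),
            "sex": sex,
            "race": race,
        }
    )


# ---------------------------------------------------------------------------
# Loadings and coefficients
# ---------------------------------------------------------------------------

def _orthonormal_frame(pk: int, m: int, sparsity: float, rng) -> np.ndarray:
    """p_k x m matrix with orthonormal columns; when sparse, columns live on
    disjoint random supports, giving exact zeros *and* exact orthogonality."""
    if m == 0:
        return np.empty((pk, 0))
    if sparsity == 0.0:
        A = rng.standard_normal((pk, m))
        Q, _ = np.linalg.qr(A)
        return Q[:, :m]
    support = max(2, int(round((1.0 - sparsity) * pk)))
    support = min(support, pk // m)
    if support < 1:
        raise DataModelError(
            f"cannot place {m} disjoint sparse supports in {pk} features"
        )
    perm = rng.permutation(pk)
    Q = np.zeros((pk, m))
    for j in range(m):
        idx = perm[j * support : (j + 1) * support]
        v = rng.standard_normal(support)
        Q[idx, j] = v / np.linalg.norm(v)
    return Q


def _pair_names(p: int) -> list[str]:
    """First p canonical 'A__B' names from the smallest seed set covering p."""
    S = 2
    while S * (S - 1) // 2 < p:
        S += 1
    seeds = [f"r{i:03d}" for i in range(S)]
    return [f"{a}__{b}" for a, b in itertools.combinations(seeds, 2)][:p]


def _feature_names(modality: str, pk: int) -> list[str]:
    if modality == "rsfmri":
        return _pair_names(pk)
    prefix = {"volume": "vol", "FA": "fa", "MD": "md"}[modality]
    return [f"{prefix}_{i:04d}" for i in range(pk)]


def _build_coefficients(config: SimulationConfig, cov: CovariateDesign):
    """Coefficient matrices keyed to the encoded covariate columns.

    Group dummies drive the joint scores (decaying across factors, opposite
    pattern for the second group so the two subgroup contrasts pick out
    different factors); nuisance covariates get a uniform small effect.
    """
    q = cov.n_covariates
    decay = config.strength_decay
    if config.B0 is not None:
        B0 = np.asarray(config.B0, float)
        if B0.shape != (q, config.r0):
            raise DataModelError("B0 must be q x r0")
    else:
        B0 = np.full((q, config.r0), config.nuisance_beta)
        for i, name in enumerate(cov.column_names):
            if name == "group_S_FEP":
                B0[i] = [config.group_beta * decay**j for j in range(config.r0)]
            elif name == "group_M_FEP":
                B0[i] = [
                    config.group_beta * decay ** (config.r0 - 1 - j)
                    for j in range(config.r0)
                ]
    if config.Bk is not None:
        Bk = [np.asarray(b, float) for b in config.Bk]
    else:
        Bk = []
        for k in range(config.K):
            b = np.full((q, config.r[k]), config.nuisance_beta)
            for i, name in enumerate(cov.column_names):
                if name.startswith("group_"):
                    b[i] = config.group_beta_indiv
            Bk.append(b)
    return B0, Bk


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

def simulate_sifa_dataset(
    config: SimulationConfig,
) -> tuple[MultiModalDataset, SyntheticTruth]:
    """Draw (dataset, truth) from the SIFA generative model.

    Scores: U0 = Y B0 + F0 and Uk = Y Bk + Fk with iid Gaussian score noise;
    data: X_k = U0 V0k' + Uk Vk' + E_k with iid Normal(0, sigma_k^2)
    residuals.  Loading norms implement the configured per-feature SNR with
    equal joint norms across blocks; the returned truth is in canonical
    identifiability gauge.  Bitwise-reproducible under a fixed seed.
    """
    config.validate()
    demo = simulate_demographics(config)
    cov = encode_covariates(demo)
    rng = np.random.default_rng((config.seed, 1))
    B0, Bk = _build_coefficients(config, cov)
    Y = cov.Y
    n, K = config.n, config.K

    F0 = config.score_noise_sd * rng.standard_normal((n, config.r0))
    U0 = Y @ B0 + F0
    Uk = []
    for k in range(K):
        Fk = config.score_noise_sd * rng.standard_normal((n, config.r[k]))
        Uk.append(Y @ Bk[k] + Fk)

    sig = config.resid_sd_per_block
    p_total = float(np.sum(config.p))
    # equal-norm joint loadings: stacked column norm c_j sized so the leading
    # joint factor contributes ~snr units of variance per feature (relative
    # to unit residual variance); equal per-block norms c_j/sqrt(K)
    c = np.sqrt(config.snr * p_total) * config.strength_decay ** np.arange(config.r0)
    modalities = list(_MODALITY_ORDER[:K]) if K <= 4 else [
        f"block{k}" for k in range(K)
    ]
    blocks, V0k_list, Vk_list = [], [], []
    for k in range(K):
        pk = config.p[k]
        m = config.r0 + config.r[k]
        Q = _orthonormal_frame(pk, m, config.loading_sparsity, rng)
        V0k = Q[:, : config.r0] * (c / np.sqrt(K))
        # individual structure half as strong per feature as the joint signal
        d = (
            np.sqrt(0.5 * config.snr * pk)
            * config.strength_decay ** np.arange(config.r[k])
        )
        Vk = Q[:, config.r0 :] * d
        V0k_list.append(V0k)
        Vk_list.append(Vk)
        E = sig[k] * rng.standard_normal((n, pk))
        Xk = U0 @ V0k.T + Uk[k] @ Vk.T + E
        blocks.append(
            FeatureBlock(
                modality=modalities[k],
                values=Xk,
                feature_names=_feature_names(modalities[k], pk),
                subject_ids=demo["subject_id"].tolist(),
                standardized=True,
            )
        )
    model = SIFAModel(
        B0=B0,
        Bk=Bk,
        V0k=V0k_list,
        Vk=Vk_list,
        tau0=np.full(config.r0, config.score_noise_sd**2),
        tauk=[np.full(config.r[k], config.score_noise_sd**2) for k in range(K)],
        sigma2=sig**2,
    )
    U0_c, Uk_c = U0, Uk
    canon = model
    if config.score_noise_sd > 0 and (config.r0 + sum(config.r)) > 0:
        # express truth (parameters AND realized scores) in canonical gauge
        tmp = SIFAFit(model=model, U0_hat=U0, Uk_hat=Uk,
                      loglik_trace=np.empty(0), converged=True, n_iter=0)
        tmp = apply_identifiability_fit(tmp, Y)
        canon, U0_c, Uk_c = tmp.model, tmp.U0_hat, tmp.Uk_hat
    ds = MultiModalDataset(blocks, cov)
    truth = SyntheticTruth(
        model=canon, U0=U0_c, Uk=Uk_c, demographics=demo, covariates=cov
    )
    return ds, truth


def simulate_null_dataset(
    config: SimulationConfig,
) -> tuple[MultiModalDataset, SyntheticTruth]:
    """As :func:`simulate_sifa_dataset` but with every group-dummy row of the
    score coefficients forced to zero (other covariate effects retained) —
    the type-I-error harness for the whole downstream pipeline."""
    import copy

    config = copy.deepcopy(config)
    config.group_beta = 0.0
    config.group_beta_indiv = 0.0
    if config.B0 is not None or config.Bk is not None:
        raise DataModelError(
            "null simulation builds its own coefficients; unset B0/Bk"
        )
    return simulate_sifa_dataset(config)
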