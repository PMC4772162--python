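"""Presence-background species distribution models.

Maximum-entropy density estimation over grid cells, implemented directly
as its convex dual: an L1-penalized log-linear model contrasting presence
cells against background cells. For feature vector f(x) and coefficients
lambda, the model density over background cells is

    q(x) = exp(f(x) . lambda) / Z,   Z = sum_bg exp(f(x) . lambda)

and the fit minimizes the penalized negative log-likelihood

    -mean_presence f(x) . lambda + log Z + sum_j beta_j |lambda_j|.

Feature classes follow the sample-size rule used for sparse herbarium
data: linear features for 5-10 records, quadratic for 11-14, hinge for 15
or more. The per-feature penalty beta_j scales with the feature's sample
standard deviation over the presences and a tabulated sample-size-dependent
base multiplier (documented in ``DEFAULT_BETA_TABLE``).

Continuous [0,1] suitability uses the complementary log-log transform
``1 - exp(-exp(H) * q(x))`` with H the entropy of q over the background,
which maps the uniform density to 1 - 1/e; all thresholding rules
downstream are rank-based, so this monotone choice does not affect
presence/absence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from .core import EnvMatrix

logger = logging.getLogger(__name__)

__all__ = ["select_features", "build_features", "fit_sdm", "auc", "SDMFit",
           "FEATURE_CLASSES"]

FEATURE_CLASSES = ("linear", "quadratic", "hinge")

# Sample-size -> base regularization multiplier, interpolated linearly and
# held constant outside the tabulated range. Config artifact in the spirit
# of common MaxEnt defaults; not a parity claim with any particular build.
DEFAULT_BETA_TABLE = {
    "linear": [(10, 1.0), (30, 0.2), (100, 0.05)],
    "quadratic": [(10, 1.0), (30, 0.2), (100, 0.05)],
    "hinge": [(0, 0.5), (1000, 0.5)],
}

N_HINGE_KNOTS = 10  # per direction, so 20 thresholds per predictor


def select_features(n_records: int) -> str:
    """Sample-size rule mapping record counts to a feature class.

    5-10 records -> linear, 11-14 -> quadratic, >= 15 -> hinge. Species
    with fewer than 5 distinct presence cells should have been filtered
    upstream and raise an error here.
    """
    if n_records < 5:
        raise ValueError(f"n_records={n_records} < 5; species should have been filtered")
    if n_records <= 10:
        return "linear"
    if n_records <= 14:
        return "quadratic"
    return "hinge"


def _beta_base(feature_class: str, n_records: int) -> float:
    table = DEFAULT_BETA_TABLE[feature_class]
    ns = np.array([t[0] for t in table], dtype=float)
    vs = np.array([t[1] for t in table], dtype=float)
    return float(np.interp(n_records, ns, vs))


def build_features(env: EnvMatrix, feature_class: str,
                   ) -> tuple[np.ndarray, list[str]]:
    """Expand predictors into the feature matrix for one feature class.

    Predictors are z-scored over the full domain. Quadratic adds squared
    terms; hinge adds, per predictor, ``N_HINGE_KNOTS`` forward and as many
    reverse hinges with knots at equally spaced quantiles of the domain
    values. Zero-variance predictors are dropped with a warning.
    """
    if feature_class not in FEATURE_CLASSES:
        raise ValueError(f"unknown feature class {feature_class!r}")
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name in env.names:
        x = env[name]
        sd = x.std()
        if sd == 0:
            logger.warning("predictor %r has zero variance; dropped from features", name)
            continue
        z = (x - x.mean()) / sd
        cols.append(z)
        names.append(name)
        if feature_class == "quadratic":
            cols.append(z ** 2)
            names.append(f"{name}^2")
        elif feature_class == "hinge":
            qs = (np.arange(1, N_HINGE_KNOTS + 1)) / (N_HINGE_KNOTS + 1)
            knots = np.quantile(x, qs)
            xmin, xmax = x.min(), x.max()
            for t in knots:
                if xmax > t:
                    cols.append(np.clip((x - t) / (xmax - t), 0.0, 1.0))
                    names.append(f"hinge({name}>{t:.4g})")
                if t > xmin:
                    cols.append(np.clip((t - x) / (t - xmin), 0.0, 1.0))
                    names.append(f"hinge({name}<{t:.4g})")
    if not cols:
        raise ValueError("no usable (non-constant) predictors")
    return np.column_stack(cols), names


@dataclass
class SDMFit:
    """A fitted presence-background model for one species."""

    species_id: str
    feature_class: str
    coefficients: pd.Series
    suitability: np.ndarray  # per-cell, in [0, 1]
    train_auc: float
    n_records: int
    presences: frozenset[int]
    raw_density: np.ndarray  # q(x) over background cells, sums to 1

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.suitability)):
            raise ValueError("suitability must be finite everywhere")


def fit_sdm(presences, env: EnvMatrix, feature_class: str | None = None,
            regularization_multiplier: float = 1.0, seed: int = 0,
            species_id: str = "species", background=None) -> SDMFit:
    """Fit one maximum-entropy SDM.

    ``presences`` is a set of cell ids; the background defaults to every
    domain cell (the seed only matters when a random background subsample
    is requested via ``background='subsample:N'``). The fit is deterministic
    given its inputs.
    """
    pres = np.asarray(sorted(presences), dtype=int)
    if pres.size < 5:
        raise ValueError("need at least 5 presence cells")
    n_records = pres.size
    if feature_class is None:
        feature_class = select_features(n_records)
    F, names = build_features(env, feature_class)
    n_cells = F.shape[0]
    if background is None:
        bg_idx = np.arange(n_cells)
    elif isinstance(background, str) and background.startswith("subsample:"):
        n_bg = int(background.split(":")[1])
        rng = np.random.default_rng(seed)
        bg_idx = np.sort(rng.choice(n_cells, size=min(n_bg, n_cells), replace=False))
        bg_idx = np.union1d(bg_idx, pres)  # background must include presences
    else:
        bg_idx = np.asarray(sorted(background), dtype=int)
    Fb = F[bg_idx]
    # standardize features over the background for conditioning
    mu = Fb.mean(axis=0)
    sd = Fb.std(axis=0)
    keep = sd > 1e-12
    Fs = (F[:, keep] - mu[keep]) / sd[keep]
    Fb = Fs[bg_idx]
    Fp = Fs[pres]
    names = [n for n, k in zip(names, keep) if k]
    p = Fb.shape[1]
    fbar = Fp.mean(axis=0)
    base = _beta_base(feature_class, n_records)
    s_j = np.maximum(Fp.std(axis=0), 1.0 / np.sqrt(n_records))
    beta = regularization_multiplier * base * s_j / np.sqrt(n_records)

    def objective(theta: np.ndarray):
        # lam = theta_pos - theta_neg; penalty on theta_pos + theta_neg keeps
        # the objective smooth in theta and equals the L1 norm at any optimum
        lam = theta[:p] - theta[p:]
        eta = Fb @ lam
        lz = logsumexp(eta)
        w = np.exp(eta - lz)
        nll = -fbar @ lam + lz - np.log(len(bg_idx))
        grad_lam = -fbar + Fb.T @ w
        grad = np.concatenate([grad_lam + beta, -grad_lam + beta])
        return nll + beta @ (theta[:p] + theta[p:]), grad

    theta0 = np.zeros(2 * p)
    res = optimize.minimize(objective, theta0, jac=True, method="L-BFGS-B",
                            bounds=[(0, None)] * (2 * p),
                            options={"maxiter": 1000, "ftol": 1e-10,
                                     "gtol": 1e-6})
    if not res.success and res.status != 1:  # status 1 = maxiter
        raise RuntimeError(f"MaxEnt optimizer failed for {species_id}: {res.message}")
    lam = res.x[:p] - res.x[p:]
    eta_all = Fs @ lam
    lz = logsumexp(eta_all[bg_idx])
    q_bg = np.exp(eta_all[bg_idx] - lz)
    entropy = float(-(q_bg * np.log(np.maximum(q_bg, 1e-300))).sum())
    q_all = np.exp(eta_all - lz)
    suitability = 1.0 - np.exp(-np.exp(entropy) * q_all)
    fit_auc = auc(suitability, pres, bg_idx)
    return SDMFit(species_id=species_id, feature_class=feature_class,
                  coefficients=pd.Series(lam, index=names),
                  suitability=suitability, train_auc=fit_auc,
                  n_records=n_records, presences=frozenset(int(c) for c in pres),
                  raw_density=q_bg)


def auc(suitability: np.ndarray, presences, background) -> float:
    """Rank (Mann-Whitney) AUC of presences against background cells.

    The probability that a random presence cell outranks a random
    background cell in suitability, with ties counted half. Background may
    overlap the presences (pseudo-absence contract); constant suitability
    gives 0.5 by the tie convention.
    """
    pres = np.asarray(sorted(presences), dtype=int)
    bg = np.asarray(sorted(background), dtype=int)
    if pres.size == 0 or bg.size == 0:
        raise ValueError("presences and background must be non-empty")
    vals = np.concatenate([suitability[pres], suitability[bg]])
    ranks = rankdata(vals)
    u = ranks[:pres.size].sum() - pres.size * (pres.size + 1) / 2
    return float(u / (pres.size * bg.size))
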