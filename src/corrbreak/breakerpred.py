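"""Genomic classification of correlation-breaking genotypes.

A logistic GBLUP: binary breaker status is modelled with a logit link and a
genotype random effect u ~ N(0, K σ²_u), where K is a marker-based
relationship matrix.  Fitting uses penalised quasi-likelihood (PQL):
iteratively reweighted working variates z = η + (y − μ)/W are fed through
the mixed-model equations, with σ²_u re-estimated by univariate REML on the
working model at each outer iteration.  Out-of-sample genotypes are scored
through the conditional mean u_new = K_{new,train} K_{train,train}⁻¹ û.

Validation follows two schemes: leave-one-individual-out and
leave-one-family-out (all clones/sibs of a family held out together, the
stricter test when training data contain family structure).  Discrimination
is summarised by the rank-based (Mann–Whitney) AUC, and genotypes are
flagged as predicted breakers when their score strictly exceeds a chosen
percentile of all scores.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit

from .kinship import RelationshipMatrix, blend

_CLIP = 1e-6


@dataclass
class LogisticGBLUPFit:
    beta0: float
    u: pd.Series  # BLUP genetic effects by id
    sigma2_u: float
    fitted: pd.Series  # fitted probabilities by id
    iterations: int
    converged: bool


def _check_labels(labels: pd.Series) -> np.ndarray:
    y = np.asarray(labels, dtype=float)
    vals = set(np.unique(y))
    if not vals <= {0.0, 1.0}:
        raise ValueError(f"labels must be 0/1, got values {sorted(vals)[:5]}")
    if len(vals) < 2:
        raise ValueError("labels are constant; nothing to classify")
    return y


def _working_reml_sigma2(z, W, K, beta_resid_free: bool = True) -> float:
    """Univariate REML for sigma2_u in z = 1*b0 + u + e, Var(e)=W^-1."""
    n = len(z)
    ones = np.ones(n)
    Winv = 1.0 / W

    def negll(log_s2):
        s2 = np.exp(log_s2)
        V = s2 * K + np.diag(Winv)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        logdetV = 2.0 * np.sum(np.log(np.diag(L)))
        Vi_one = np.linalg.solve(V, ones)
        Vi_z = np.linalg.solve(V, z)
        xvx = ones @ Vi_one
        b0 = (ones @ Vi_z) / xvx
        r = z - b0
        Vi_r = Vi_z - b0 * Vi_one
        return 0.5 * (logdetV + np.log(xvx) + r @ Vi_r)

    res = minimize_scalar(negll, bounds=(np.log(1e-6), np.log(1e4)), method="bounded")
    return float(np.exp(res.x))


def fit_logistic_gblup(
    labels: pd.Series,
    K: RelationshipMatrix,
    sigma2_u: float | None = None,
    max_iterations: int = 50,
    tol: float = 1e-6,
    blend_weight: float = 0.99,
) -> LogisticGBLUPFit:
    """PQL fit of the logistic GBLUP.

    ``labels`` is a 0/1 Series indexed by genotype id; ids must all be
    present in ``K``.  Pass ``sigma2_u`` to fix the genetic variance
    (used during cross-validation); otherwise it is re-estimated by REML
    on the working variates at each outer iteration.
    """
    y = _check_labels(labels)
    ids = list(labels.index)
    Kb = blend(K.subset(ids), blend_weight).values
    Kinv = np.linalg.inv(Kb)
    n = len(y)
    ones = np.ones(n)

    pbar = np.clip(y.mean(), _CLIP, 1 - _CLIP)
    beta0 = float(np.log(pbar / (1 - pbar)))
    u = np.zeros(n)
    s2 = 0.5 if sigma2_u is None else float(sigma2_u)
    estimate_s2 = sigma2_u is None

    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        eta = beta0 + u
        mu = np.clip(expit(eta), _CLIP, 1 - _CLIP)
        W = mu * (1 - mu)
        z = eta + (y - mu) / W
        if estimate_s2:
            s2 = _working_reml_sigma2(z, W, Kb)
        # MME for z = 1*b0 + u + e with Var(u)=s2*K, Var(e)=W^-1
        C = np.empty((n + 1, n + 1))
        C[0, 0] = W.sum()
        C[0, 1:] = C[1:, 0] = W
        C[1:, 1:] = np.diag(W) + Kinv / s2
        rhs = np.concatenate([[W @ z], W * z])
        sol = np.linalg.solve(C, rhs)
        new_beta0, new_u = sol[0], sol[1:]
        delta = max(abs(new_beta0 - beta0), np.abs(new_u - u).max())
        beta0, u = float(new_beta0), new_u
        if delta < tol:
            converged = True
            break

    fitted = expit(beta0 + u)
    return LogisticGBLUPFit(
        beta0=beta0,
        u=pd.Series(u, index=ids),
        sigma2_u=s2,
        fitted=pd.Series(fitted, index=ids),
        iterations=it,
        converged=converged,
    )


def predict(
    fit: LogisticGBLUPFit, K: RelationshipMatrix, new_ids, blend_weight: float = 0.99
) -> pd.Series:
    """Probabilities for held-out genotypes via the conditional BLUP mean."""
    train_ids = list(fit.u.index)
    new_ids = list(new_ids)
    both = train_ids + new_ids
    Kb = blend(K.subset(both), blend_weight).values
    nt = len(train_ids)
    K_tt = Kb[:nt, :nt]
    K_nt = Kb[nt:, :nt]
    u_new = K_nt @ np.linalg.solve(K_tt, fit.u.to_numpy())
    return pd.Series(expit(fit.beta0 + u_new), index=new_ids)


def loo_predict(
    labels: pd.Series,
    K: RelationshipMatrix,
    families: pd.Series | None = None,
    scheme: str = "individual",
    blend_weight: float = 0.99,
    refit_variance: bool = False,
) -> pd.DataFrame:
    """Leave-one-out cross-validated breaker scores.

    ``scheme='individual'`` holds out one genotype at a time;
    ``scheme='family'`` holds out every member of one family at a time
    (requires ``families``, a Series of family ids aligned to ``labels``).
    σ²_u is estimated once on the full data and held fixed across folds
    unless ``refit_variance`` is set.
    """
    _check_labels(labels)
    if scheme not in ("individual", "family"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "family":
        if families is None:
            raise ValueError("family scheme needs a families Series")
        families = families.reindex(labels.index)
        if families.isna().any():
            raise ValueError("families missing for some labelled genotypes")

    full = fit_logistic_gblup(labels, K, blend_weight=blend_weight)
    s2 = None if refit_variance else full.sigma2_u

    if scheme == "individual":
        folds = [[i] for i in labels.index]
    else:
        folds = [list(grp.index) for _, grp in labels.groupby(families)]

    rows = []
    for held in folds:
        train = labels.drop(index=held)
        if train.nunique() < 2:
            raise ValueError("a fold left the training labels constant; too few cases")
        f = fit_logistic_gblup(train, K, sigma2_u=s2, blend_weight=blend_weight)
        # score with the full-data intercept: the fold intercept is a
        # deterministic function of the held-out labels (leave-one-out mean
        # leakage) and would anti-correlate scores with labels under a null
        f = replace(f, beta0=full.beta0)
        preds = predict(f, K, held, blend_weight=blend_weight)
        for i in held:
            rows.append(
                {
                    "id": i,
                    "family": None if families is None else families.loc[i],
                    "label": int(labels.loc[i]),
                    "score": float(preds.loc[i]),
                }
            )
    return pd.DataFrame(rows)


def auc(labels, scores) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must be aligned")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = pd.Series(s).rank(method="average").to_numpy()
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def classify_percentile(scores: pd.Series, percentile: float = 95.0) -> pd.DataFrame:
    """Flag genotypes whose score strictly exceeds the given percentile."""
    s = scores.astype(float)
    thr = float(np.percentile(s.to_numpy(), percentile))
    return pd.DataFrame(
        {"score": s, "predicted_breaker": s > thr, "threshold": thr}, index=s.index
    )
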