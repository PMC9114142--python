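"""Comparison of additive genetic variance-covariance (G) matrices.

Two complementary views of G-matrix similarity between populations:

* Krzanowski subspace similarity — the mean squared cosine between the
  leading principal axes of the two matrices,
  r_Krz = (1/k) Σᵢ Σⱼ cos²(Λᵢᴬ, Λⱼᴮ), with k = t/2 − 1 principal
  components for t traits (so k = 1 for the four-trait case, where the
  statistic reduces to the squared cosine between leading eigenvectors).

* Random skewers / selection response decomposition (SRD) — probe both
  matrices with random selection-gradient vectors β (uniform on the unit
  sphere), compare the response vectors Δz = Gβ, and decompose each trait's
  response into its covariance-term contributions (G_i1 β₁, …, G_it β_t);
  the per-trait SRD score is the mean correlation of these trait-specific
  vectors across skewers.  Similar matrices give SRD scores near 1 with
  small variance; diverging matrices give low scores and large variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SRDResult:
    trait_scores: np.ndarray  # mean correlation per trait
    trait_variances: np.ndarray  # across-skewer variance per trait
    overall_mean: float
    n_skewers: int


def _check_pair(A: np.ndarray, B: np.ndarray) -> int:
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("need two square matrices of equal dimension")
    return A.shape[0]


def _leading_axes(M: np.ndarray, k: int) -> np.ndarray:
    """Top-k eigenvectors, deterministically oriented and ordered.

    Ties in eigenvalues are broken by requiring the first nonzero loading of
    each vector to be positive (sign convention) after sorting by eigenvalue.
    """
    w, v = np.linalg.eigh(M)
    order = np.argsort(w)[::-1]
    v = v[:, order]
    for j in range(v.shape[1]):
        col = v[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            v[:, j] = -col
    return v[:, :k]


def krzanowski_k(n_traits: int) -> int:
    """Number of principal components entering the test: floor(t/2) - 1."""
    k = n_traits // 2 - 1
    if k < 1:
        raise ValueError(
            f"k = floor(t/2) - 1 = {k} < 1 for t = {n_traits} traits; "
            "the subspace comparison needs at least 4 traits"
        )
    return k


def krzanowski(A: np.ndarray, B: np.ndarray, k: int | None = None) -> float:
    """Krzanowski common-subspace similarity in [0, 1]; symmetric in (A, B)."""
    t = _check_pair(A, B)
    k = krzanowski_k(t) if k is None else k
    if k < 1 or k > t:
        raise ValueError(f"invalid number of principal components k={k}")
    Va = _leading_axes(np.asarray(A, float), k)
    Vb = _leading_axes(np.asarray(B, float), k)
    cos2 = (Va.T @ Vb) ** 2
    return float(cos2.sum() / k)


def _unit_sphere(t: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """n selection-gradient vectors uniform on the unit sphere in R^t."""
    b = rng.standard_normal((n, t))
    return b / np.linalg.norm(b, axis=1, keepdims=True)


def random_skewers(
    A: np.ndarray, B: np.ndarray, n_skewers: int = 1000, rng: np.random.Generator | None = None
) -> dict:
    """Correlations between the two matrices' responses to random gradients."""
    t = _check_pair(A, B)
    if not np.any(A) or not np.any(B):
        raise ValueError("zero matrix: response correlations undefined")
    rng = np.random.default_rng() if rng is None else rng
    betas = _unit_sphere(t, n_skewers, rng)
    dz_a = betas @ np.asarray(A, float).T
    dz_b = betas @ np.asarray(B, float).T
    za = dz_a - dz_a.mean(axis=1, keepdims=True)
    zb = dz_b - dz_b.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(za, axis=1) * np.linalg.norm(zb, axis=1)
    corrs = (za * zb).sum(axis=1) / denom
    return {"correlations": corrs, "mean": float(corrs.mean()), "n_skewers": n_skewers}


def srd(
    A: np.ndarray, B: np.ndarray, n_skewers: int = 1000, rng: np.random.Generator | None = None
) -> SRDResult:
    """Selection response decomposition score between two G matrices.

    For each skewer β and trait i, the trait-specific response vector is
    (G_i1 β₁, …, G_it β_t); its (Pearson) correlation between the two
    matrices is averaged over skewers.  A trait whose row is entirely zero
    in either matrix gets an undefined (NaN) score.
    """
    t = _check_pair(A, B)
    rng = np.random.default_rng() if rng is None else rng
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    betas = _unit_sphere(t, n_skewers, rng)
    scores = np.full(t, np.nan)
    variances = np.full(t, np.nan)
    for i in range(t):
        if not np.any(A[i]) or not np.any(B[i]):
            continue
        va = A[i][None, :] * betas  # (n_skewers, t) trait-specific vectors
        vb = B[i][None, :] * betas
        ca = va - va.mean(axis=1, keepdims=True)
        cb = vb - vb.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(ca, axis=1) * np.linalg.norm(cb, axis=1)
        ok = denom > 0
        corrs = np.full(n_skewers, np.nan)
        corrs[ok] = (ca[ok] * cb[ok]).sum(axis=1) / denom[ok]
        scores[i] = float(np.nanmean(corrs))
        variances[i] = float(np.nanvar(corrs))
    return SRDResult(
        trait_scores=scores,
        trait_variances=variances,
        overall_mean=float(np.nanmean(scores)),
        n_skewers=n_skewers,
    )
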