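"""Linkage disequilibrium: composite and relatedness-corrected r², decay
fitting, and tests of LD-pattern difference between populations.

Composite LD between two loci is the squared Pearson correlation of their
unphased dosage vectors.  Structured samples inflate this estimate, so a
relatedness-corrected variant replaces the ordinary centering and
cross-products with K⁻¹-weighted ones (K the marker-based relationship
matrix); with K = I the two estimators coincide exactly.

The decay trend is the Hill & Weir (1988) expectation

    E(r²) = (10+C) / ((2+C)(11+C)) · [1 + (3+C)(12+12C+C²) / (n(2+C)(11+C))]

with C = 4Nc the population recombination parameter.  A per-pair C is not
identifiable, so C is parameterised as β·d (β per bp, d the pair's physical
distance) and β fitted by nonlinear least squares.  The distance at which
the fitted curve drops to r² = 0.2 summarises how quickly LD erodes.

Equality of two populations' within-scaffold correlation matrices is tested
with the Jennrich (1970) chi-square test on scaffolds with at least three
overlapping polymorphic markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genio import GenotypeMatrix


@dataclass
class HillWeirFit:
    beta_per_bp: float  # C(d) = beta * d
    n: int  # sample size entering the expectation
    rss: float
    n_pairs: int


@dataclass
class JennrichResult:
    scaffold: str
    chi2: float
    df: int
    p_value: float
    n1: int
    n2: int


# ---------------------------------------------------------------------------
# pairwise estimators

def composite_r2(x_i: np.ndarray, x_j: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape or x_i.ndim != 1 or len(x_i) < 3:
        raise ValueError("need two aligned vectors of length >= 3")
    if np.ptp(x_i) == 0 or np.ptp(x_j) == 0:
        raise ValueError("constant dosage vector: r2 undefined")
    r = np.corrcoef(x_i, x_j)[0, 1]
    return float(r * r)


def _weighted_cov(X: np.ndarray, kinv: np.ndarray) -> np.ndarray:
    """K⁻¹-weighted covariance matrix of marker columns X (n x p)."""
    ones = np.ones(X.shape[0])
    kin1 = kinv @ ones
    wmean = (kin1 @ X) / (ones @ kin1)
    Xc = X - wmean[None, :]
    return Xc.T @ kinv @ Xc


def corrected_r2(x_i: np.ndarray, x_j: np.ndarray, kinv: np.ndarray) -> float:
    """Relatedness-corrected r² for one marker pair.

    ``kinv`` is the (blended) inverse relationship matrix aligned to the
    dosage vectors.  Both vectors are centered by the K⁻¹-weighted mean and
    the squared weighted cross-product is scaled by the weighted variances.
    """
    X = np.column_stack([np.asarray(x_i, float), np.asarray(x_j, float)])
    if kinv.shape != (X.shape[0], X.shape[0]):
        raise ValueError("kinship inverse does not match vector length")
    S = _weighted_cov(X, kinv)
    if S[0, 0] <= 0 or S[1, 1] <= 0:
        raise ValueError("zero weighted variance: corrected r2 undefined")
    return float(S[0, 1] ** 2 / (S[0, 0] * S[1, 1]))


# ---------------------------------------------------------------------------
# scaffold-level LD

def _polymorphic_hard_markers(g: GenotypeMatrix, marker_ids) -> list:
    """Markers with complete hard calls and non-constant dosages in this sample."""
    sub = g.subset_markers(marker_ids)
    mask = sub.hard_call_mask()
    keep = []
    for k, m in enumerate(sub.marker_ids):
        col = sub.dosages[mask[:, k], k]
        if len(col) == sub.n_individuals and np.ptp(col) > 0:
            keep.append(m)
    return keep


def scaffold_ld(
    g: GenotypeMatrix,
    min_snps: int = 3,
    kinv: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """All within-scaffold LD pairs for scaffolds with >= min_snps usable markers.

    Returns a pair table (marker_i, marker_j, scaffold, distance_bp, r2 and,
    when ``kinv`` is given, r2_corrected) and a dict scaffold -> (marker ids,
    signed correlation matrix) feeding the Jennrich test.  Markers that are
    monomorphic or incompletely called in this sample are dropped before the
    threshold is applied.
    """
    rows = []
    matrices: dict = {}
    for scaffold, grp in g.marker_map.groupby("scaffold", sort=True):
        usable = _polymorphic_hard_markers(g, list(grp.index))
        if len(usable) < min_snps:
            continue
        sub = g.subset_markers(usable)
        order = np.argsort(sub.marker_map["pos_bp"].to_numpy())
        sub = sub.subset_markers(sub.marker_ids[order])
        X = sub.dosages
        pos = sub.marker_map["pos_bp"].to_numpy()
        if kinv is not None:
            S = _weighted_cov(X, kinv)
        else:
            S = np.atleast_2d(np.cov(X, rowvar=False))
        d = np.sqrt(np.diag(S))
        corr = S / np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
        matrices[str(scaffold)] = (list(sub.marker_ids), corr)
        r2 = corr**2
        p = len(usable)
        for a in range(p):
            for b in range(a + 1, p):
                rows.append(
                    (
                        sub.marker_ids[a],
                        sub.marker_ids[b],
                        str(scaffold),
                        int(abs(pos[a] - pos[b])),
                        float(np.clip(r2[a, b], 0.0, 1.0)),
                    )
                )
    col = "r2_corrected" if kinv is not None else "r2"
    pairs = pd.DataFrame(
        rows, columns=["marker_i", "marker_j", "scaffold", "distance_bp", col]
    )
    return pairs, matrices


# ---------------------------------------------------------------------------
# Hill–Weir decay

def hill_weir_expectation(C, n: int):
    """Expected r² as a function of C = 4Nc and sample size n."""
    C = np.asarray(C, dtype=float)
    lead = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    corr = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (n * (2.0 + C) * (11.0 + C))
    out = lead * corr
    return float(out) if out.ndim == 0 else out


def fit_hill_weir(pairs: pd.DataFrame, n: int, use_corrected: bool = False) -> HillWeirFit:
    """Least-squares fit of the decay curve E(r²; C = β·d, n) to observed pairs.

    Multi-start over β ∈ {1e-5, 1e-4, 1e-3, 1e-2} per bp guards against the
    flat tail of the objective; the best converged candidate wins.
    """
    col = "r2_corrected" if use_corrected else "r2"
    d = pairs["distance_bp"].to_numpy(dtype=float)
    y = pairs[col].to_numpy(dtype=float)
    keep = d > 0
    d, y = d[keep], y[keep]
    if len(d) < 10:
        raise ValueError("need at least 10 pairs with positive distance")

    def resid(beta):
        return hill_weir_expectation(beta[0] * d, n) - y

    best = None
    for start in (1e-5, 1e-4, 1e-3, 1e-2):
        sol = optimize.least_squares(
            resid, x0=[start], bounds=([0.0], [np.inf]), ftol=1e-10, xtol=1e-12
        )
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[1] - 1e-14:
            best = (float(sol.x[0]), rss)
    return HillWeirFit(beta_per_bp=best[0], n=n, rss=best[1], n_pairs=len(d))


def decay_distance(
    fit: HillWeirFit, threshold: float = 0.2, max_distance_bp: float | None = None
) -> float | None:
    """Smallest distance at which the fitted curve drops to ``threshold``.

    Returns None ("not reached") when β = 0 or when the curve stays above the
    threshold out to ten times ``max_distance_bp`` (default 1e9 bp).
    """
    if fit.beta_per_bp <= 0:
        return None
    if hill_weir_expectation(0.0, fit.n) <= threshold:
        return 0.0
    upper = 10.0 * (max_distance_bp if max_distance_bp is not None else 1e8)
    if hill_weir_expectation(fit.beta_per_bp * upper, fit.n) > threshold:
        return None
    f = lambda d: hill_weir_expectation(fit.beta_per_bp * d, fit.n) - threshold
    return float(optimize.brentq(f, 0.0, upper, xtol=1e-6))


# ---------------------------------------------------------------------------
# Jennrich test

def jennrich(R1: np.ndarray, n1: int, R2: np.ndarray, n2: int, scaffold: str = "") -> JennrichResult:
    """Jennrich (1970) chi-square test of equality of two correlation matrices.

    c = n1 n2/(n1+n2); R̄ = (n1 R1 + n2 R2)/(n1+n2); Z = √c R̄⁻¹ (R1 − R2);
    χ² = ½ tr(Z²) − diag(Z)' S⁻¹ diag(Z) with S = I + R̄ ∘ R̄⁻¹;
    df = p(p−1)/2.
    """
    R1 = np.asarray(R1, float)
    R2 = np.asarray(R2, float)
    p = R1.shape[0]
    if R1.shape != (p, p) or R2.shape != (p, p) or p < 3:
        raise ValueError("need two square correlation matrices of dimension >= 3")
    n = n1 + n2
    c = n1 * n2 / n
    Rbar = (n1 * R1 + n2 * R2) / n
    try:
        Rbar_inv = np.linalg.inv(Rbar)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular pooled correlation matrix") from exc
    Z = np.sqrt(c) * Rbar_inv @ (R1 - R2)
    S = np.eye(p) + Rbar * Rbar_inv
    try:
        S_inv = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular S matrix in Jennrich test") from exc
    dz = np.diag(Z)
    chi2 = 0.5 * np.trace(Z @ Z) - dz @ S_inv @ dz
    chi2 = max(float(chi2), 0.0)
    df = p * (p - 1) // 2
    return JennrichResult(
        scaffold=scaffold,
        chi2=chi2,
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)),
        n1=n1,
        n2=n2,
    )


def compare_populations(
    g_a: GenotypeMatrix,
    g_b: GenotypeMatrix,
    min_overlap: int = 3,
    kinv_a: np.ndarray | None = None,
    kinv_b: np.ndarray | None = None,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> dict:
    """Per-scaffold Jennrich tests of LD-pattern difference between populations.

    Only scaffolds with at least ``min_overlap`` markers that are polymorphic
    and fully called in *both* samples enter.  The uncorrected variant uses
    ordinary signed correlations; when both kinship inverses are supplied a
    relatedness-corrected variant (K⁻¹-weighted covariances normalised to
    correlations) is run on the same scaffolds, giving paired p-value traces.
    Scaffolds where the test is numerically singular are flagged and excluded
    from the summary fractions.
    """
    variants = {"uncorrected": (None, None)}
    if kinv_a is not None and kinv_b is not None:
        variants["corrected"] = (kinv_a, kinv_b)

    per_variant: dict = {}
    shared_scaffolds = None
    for name, (ka, kb) in variants.items():
        _, mats_a = scaffold_ld(g_a, min_snps=1, kinv=ka)
        _, mats_b = scaffold_ld(g_b, min_snps=1, kinv=kb)
        per_variant[name] = (mats_a, mats_b)

    # overlap is defined on hard-called polymorphic markers, identical for
    # both variants (the correction changes values, not marker usability)
    mats_a0, mats_b0 = per_variant["uncorrected"]
    qualifying = {}
    for scaffold in sorted(set(mats_a0) & set(mats_b0)):
        ids_a, _ = mats_a0[scaffold]
        ids_b, _ = mats_b0[scaffold]
        overlap = [m for m in ids_a if m in set(ids_b)]
        if len(overlap) >= min_overlap:
            qualifying[scaffold] = overlap
    if not qualifying:
        raise ValueError("no scaffolds with sufficient marker overlap")

    results: dict = {name: [] for name in variants}
    failed: dict = {name: [] for name in variants}
    for name in variants:
        mats_a, mats_b = per_variant[name]
        for scaffold, overlap in qualifying.items():
            ids_a, Ra = mats_a[scaffold]
            ids_b, Rb = mats_b[scaffold]
            ia = [ids_a.index(m) for m in overlap]
            ib = [ids_b.index(m) for m in overlap]
            R1 = Ra[np.ix_(ia, ia)]
            R2 = Rb[np.ix_(ib, ib)]
            try:
                res = jennrich(R1, g_a.n_individuals, R2, g_b.n_individuals, scaffold)
            except ValueError:
                failed[name].append(scaffold)
                continue
            results[name].append(res)

    summary: dict = {"alpha": alpha, "n_scaffolds_tested": len(qualifying)}
    for name in variants:
        pvals = np.array([r.p_value for r in results[name]])
        if bh_correct and len(pvals):
            from statsmodels.stats.multitest import multipletests

            rej, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
            frac = float(rej.mean())
        else:
            frac = float((pvals < alpha).mean()) if len(pvals) else float("nan")
        summary[f"fraction_significant_{name}"] = frac
        summary[f"n_failed_{name}"] = len(failed[name])
    return {"results": results, "summary": summary, "failed": failed}


def significant_scaffolds(compare: dict, variant: str = "uncorrected", alpha: float | None = None) -> list:
    """Scaffold ids whose Jennrich p-value falls below alpha."""
    alpha = compare["summary"]["alpha"] if alpha is None else alpha
    return [r.scaffold for r in compare["results"][variant] if r.p_value < alpha]
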