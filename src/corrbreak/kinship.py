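"""Relationship matrices and heterozygosity statistics.

Implements the three relationship matrices used throughout the analysis —
the pedigree numerator relationship matrix A (Henderson's tabular method),
the VanRaden marker-based matrix G, and frequency-free identity-by-state
(IBS) sharing — plus observed/expected heterozygosity summaries with a
resampling t-test for comparing two populations, and the spectral
decomposition used to visualise population structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix


@dataclass
class RelationshipMatrix:
    ids: np.ndarray
    values: np.ndarray
    kind: str  # "A" | "G" | "IBS"

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix is not symmetric")

    def subset(self, ids) -> "RelationshipMatrix":
        idx = {i: k for k, i in enumerate(self.ids)}
        rows = np.array([idx[i] for i in ids], dtype=int)
        return RelationshipMatrix(
            ids=self.ids[rows], values=self.values[np.ix_(rows, rows)], kind=self.kind
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class HetSummary:
    ho_per_individual: pd.Series
    he_per_marker: pd.Series

    @property
    def mean_ho(self) -> float:
        return float(self.ho_per_individual.mean())

    @property
    def mean_he(self) -> float:
        return float(self.he_per_marker.mean())


@dataclass
class HetTestResult:
    statistic: float
    p_value: float
    means_a: np.ndarray
    means_b: np.ndarray
    kind: str  # "observed" | "expected"


def numerator_a(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Average numerator relationship matrix by the tabular method.

    ``pedigree`` has columns id, sire, dam; unknown parents are None/NaN.
    Rows are topologically sorted internally so parents precede offspring.
    A_ii = 1 + 0.5 * A(sire, dam); A_ij = 0.5 * (A(j, sire_i) + A(j, dam_i)).
    """
    ped = pedigree.copy()
    ped["sire"] = ped["sire"].where(pd.notna(ped["sire"]), None)
    ped["dam"] = ped["dam"].where(pd.notna(ped["dam"]), None)
    ids = list(ped["id"])
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in pedigree")
    parents = {r.id: (r.sire, r.dam) for r in ped.itertuples()}

    ordered: list = []
    state: dict = {}  # 0 = in progress, 1 = done

    def visit(i, stack=()):
        if i is None or i not in parents:
            return
        if state.get(i) == 1:
            return
        if state.get(i) == 0:
            raise ValueError(f"pedigree cycle involving {i!r}")
        state[i] = 0
        s, d = parents[i]
        visit(s)
        visit(d)
        state[i] = 1
        ordered.append(i)

    for i in ids:
        visit(i)

    n = len(ordered)
    pos = {i: k for k, i in enumerate(ordered)}
    A = np.zeros((n, n))
    for k, i in enumerate(ordered):
        s, d = parents[i]
        si = pos.get(s) if s is not None else None
        di = pos.get(d) if d is not None else None
        A[k, k] = 1.0 + 0.5 * (A[si, di] if si is not None and di is not None else 0.0)
        for j in range(k):
            a = 0.5 * (
                (A[j, si] if si is not None else 0.0)
                + (A[j, di] if di is not None else 0.0)
            )
            A[k, j] = A[j, k] = a
    # return in the original id order
    perm = np.array([pos[i] for i in ids], dtype=int)
    return RelationshipMatrix(
        ids=np.array(ids, dtype=object), values=A[np.ix_(perm, perm)], kind="A"
    )


def vanraden_g(g: GenotypeMatrix, freqs: np.ndarray | None = None) -> RelationshipMatrix:
    """VanRaden marker-based relationship matrix G = ZZ' / (2 Σ p_i(1-p_i)).

    Z = M - 2p column-wise.  Dosages must contain no missing values
    (impute first); monomorphic markers are rejected.  By default allele
    frequencies are computed from the sample itself (pooled across whatever
    individuals are present); pass ``freqs`` to use an external reference.
    """
    M = g.dosages
    if np.isnan(M).any():
        raise ValueError("missing dosages; impute before building G")
    p = np.asarray(freqs, dtype=float) if freqs is not None else M.mean(axis=0) / 2.0
    if ((p <= 0) | (p >= 1)).any():
        bad = g.marker_ids[(p <= 0) | (p >= 1)]
        raise ValueError(f"monomorphic markers (filter first): {list(bad[:5])}")
    Z = M - 2.0 * p[None, :]
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = Z @ Z.T / denom
    return RelationshipMatrix(ids=g.individual_ids.copy(), values=G, kind="G")


def blend(rel: RelationshipMatrix, weight: float = 0.99) -> RelationshipMatrix:
    """Shrink toward the identity: weight*K + (1-weight)*I.

    Clonal/full-sib data make marker-based G near-singular; a light blend is
    the standard remedy before inversion.
    """
    n = len(rel.ids)
    return RelationshipMatrix(
        ids=rel.ids.copy(),
        values=weight * rel.values + (1.0 - weight) * np.eye(n),
        kind=rel.kind,
    )


def blended_inverse(rel: RelationshipMatrix, weight: float = 0.99) -> np.ndarray:
    """Inverse of the identity-blended relationship matrix."""
    K = blend(rel, weight).values
    try:
        return np.linalg.inv(K)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological input
        raise ValueError("blended relationship matrix is singular") from exc


def ibs(g: GenotypeMatrix) -> RelationshipMatrix:
    """Identity-by-state sharing: mean over hard calls of 1 - |g_i - g_j| / 2."""
    mask = g.hard_call_mask()
    D = np.where(mask, g.dosages, 0.0)
    n = g.n_individuals
    vals = np.empty((n, n))
    maskf = mask.astype(float)
    # pairwise sums of |d_i - d_j| over jointly called markers, vectorised by row
    for i in range(n):
        joint = maskf * mask[i]  # (n, m) of joint-call indicators
        diffs = np.abs(D - D[i]) * joint
        counts = joint.sum(axis=1)
        with np.errstate(invalid="ignore"):
            vals[i] = 1.0 - diffs.sum(axis=1) / (2.0 * counts)
        vals[i, counts == 0] = np.nan
    np.fill_diagonal(vals, 1.0)
    vals = (vals + vals.T) / 2.0
    return RelationshipMatrix(ids=g.individual_ids.copy(), values=vals, kind="IBS")


def heterozygosity(g: GenotypeMatrix, marker_subset=None) -> HetSummary:
    """Observed (per individual) and expected (per marker) heterozygosity.

    Only hard calls enter Ho; He = 2p(1-p) from observed-call frequencies.
    ``marker_subset`` restricts to a marker id list (e.g. scaffolds flagged
    by the correlation-matrix test).
    """
    if marker_subset is not None:
        marker_subset = list(marker_subset)
        if len(marker_subset) == 0:
            raise ValueError("empty marker subset")
        g = g.subset_markers(marker_subset)
    mask = g.hard_call_mask()
    het = (g.dosages == 1.0) & mask
    ncalls = mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        ho = het.sum(axis=1) / ncalls
    p = g.allele_freqs()
    he = 2.0 * p * (1.0 - p)
    return HetSummary(
        ho_per_individual=pd.Series(ho, index=g.individual_ids),
        he_per_marker=pd.Series(he, index=g.marker_ids),
    )


def het_resample_test(
    pop_a: GenotypeMatrix,
    pop_b: GenotypeMatrix,
    n_ind: int = 100,
    reps: int = 100,
    rng: np.random.Generator | None = None,
    kind: str = "observed",
) -> HetTestResult:
    """Resampling t-test for a heterozygosity difference between populations.

    In each of ``reps`` replicates, ``n_ind`` individuals are drawn without
    replacement from each population and the replicate's mean observed (or
    expected) heterozygosity recorded; the two vectors of replicate means are
    compared with a Welch two-sample t-test.  Replicates are independent
    draws, so the replicate means are not independent observations — the
    procedure is implemented as specified and the caveat documented.
    """
    rng = np.random.default_rng() if rng is None else rng
    if reps < 2:
        raise ValueError("need at least 2 resampling replicates for a t-test")
    for name, pop in (("A", pop_a), ("B", pop_b)):
        if pop.n_individuals < n_ind:
            raise ValueError(
                f"population {name} has {pop.n_individuals} individuals < n_ind={n_ind}; "
                "lower n_ind"
            )

    def replicate_means(pop: GenotypeMatrix) -> np.ndarray:
        out = np.empty(reps)
        for r in range(reps):
            rows = rng.choice(pop.n_individuals, size=n_ind, replace=False)
            sub = pop.subset_individuals(pop.individual_ids[rows])
            summ = heterozygosity(sub)
            out[r] = summ.mean_ho if kind == "observed" else summ.mean_he
        return out

    means_a = replicate_means(pop_a)
    means_b = replicate_means(pop_b)
    t, p = stats.ttest_ind(means_a, means_b, equal_var=False)
    return HetTestResult(
        statistic=float(t), p_value=float(p), means_a=means_a, means_b=means_b, kind=kind
    )


def pca(rel: RelationshipMatrix, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-k spectral decomposition of a relationship matrix.

    Coordinates are eigenvector * sqrt(eigenvalue) (negative eigenvalues are
    clipped at zero for the scaling); eigenvalues returned non-increasing.
    """
    n = len(rel.ids)
    if k > n:
        raise ValueError(f"k={k} exceeds matrix dimension {n}")
    w, v = np.linalg.eigh(rel.values)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    coords = v[:, :k] * np.sqrt(np.clip(w[:k], 0.0, None))[None, :]
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=rel.ids, columns=cols), w


def write_relationship(rel: RelationshipMatrix, path) -> None:
    rel.to_frame().to_csv(path, sep="\t")


def read_relationship(path, kind: str) -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix(
        ids=df.index.to_numpy(dtype=object), values=df.to_numpy(), kind=kind
    )
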