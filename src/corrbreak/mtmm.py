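"""Multivariate linear mixed models by REML.

Fits trait-stacked mixed models of the form

    Y = Xβ + Z a + Z g + Z r + Z s(or b) + e

where each random term has covariance (Σ_term ⊗ K): an unstructured t×t
trait covariance matrix crossed with a relationship structure K — the
pedigree numerator matrix A or marker matrix G for the additive term,
identity for the non-additive (clone) and trial-design terms — and the
residual is (R₀ ⊗ I) over complete-case records.  Estimation maximises the
REML log-likelihood through the mixed-model equations: EM warm-up sweeps
followed by average-information (AI) Newton steps with step-halving and an
EM fallback, so the likelihood never decreases.  Trait covariance matrices
are kept positive semi-definite by spectral projection at every iterate.

Downstream quantities follow the quantitative-genetics conventions used for
clonally replicated trials: narrow-sense heritability h² = σ²_a/(σ²_a+σ²_e)
(non-additive and design variances deliberately excluded from the
denominator), genetic correlations r_g = σ_axy/√(σ²_ax σ²_ay), with
standard errors from the delta method on the inverse AI matrix, and BLUP
breeding values extracted from the converged equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .kinship import RelationshipMatrix, blend


class ConvergenceError(RuntimeError):
    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class RandomTerm:
    name: str
    column: str  # phenotype-table column holding the factor level
    relationship: RelationshipMatrix | None = None  # None -> identity


@dataclass
class ModelSpec:
    traits: list
    terms: list  # of RandomTerm; the additive term should come first

    def __post_init__(self):
        if not self.terms:
            raise ValueError("model needs at least one random term")


@dataclass
class VarianceComponents:
    components: dict  # term name -> t x t trait covariance
    residual: np.ndarray
    loglik: float
    ai_matrix: np.ndarray | None
    param_names: list
    traits: list
    n_records: int
    converged: bool
    blups: dict = field(default_factory=dict)  # term name -> DataFrame levels x traits
    fixed_effects: np.ndarray | None = None
    iterations: int = 0


@dataclass
class GeneticParams:
    h2: pd.DataFrame  # trait, estimate, se
    rg: pd.DataFrame  # trait_x, trait_y, estimate, se
    traits: list


def standardize_by_site(ph: pd.DataFrame, traits) -> pd.DataFrame:
    """Z-score each trait within each site; constant strata are an error."""
    out = ph.copy()
    for t in traits:
        for site, grp in ph.groupby("site"):
            sd = grp[t].std(ddof=0)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"trait {t} is constant at site {site}")
            out.loc[grp.index, t] = (grp[t] - grp[t].mean()) / sd
    return out


# ---------------------------------------------------------------------------
# internals


def _psd_project(
    S: np.ndarray, floor_scale: float = 1e-8, floor_abs: float = 0.0
) -> np.ndarray:
    """Nearest PSD matrix with floored eigenvalues.

    The floor is max(floor_scale * lambda_max, floor_abs).  Every iterate
    passes through this projection, so the likelihood can be evaluated with
    plain inverses/determinants of exactly the matrix used in the mixed-model
    equations — a hidden ridge applied only on one side would break the
    log|C| vs q log|Sigma| cancellation near a variance boundary and fake a
    likelihood increase.  ``floor_abs`` (set from the phenotypic scale during
    fitting) matters when an entire component collapses: a purely relative
    floor would leave Sigma^-1 unbounded and wreck the conditioning of the
    mixed-model equations.
    """
    w, v = np.linalg.eigh((S + S.T) / 2.0)
    floor = max(floor_scale * max(w.max(), 1e-12), floor_abs)
    w = np.clip(w, floor, None)
    return (v * w) @ v.T


def _safe_inv(S: np.ndarray) -> np.ndarray:
    return np.linalg.inv(_psd_project(S))


class _Workspace:
    """Design matrices and precomputed cross-products for one fit."""

    def __init__(self, spec: ModelSpec, ph: pd.DataFrame):
        traits = list(spec.traits)
        data = ph.dropna(subset=traits).reset_index(drop=True)
        if len(data) == 0:
            raise ValueError("no complete-case records")
        self.traits = traits
        self.t = len(traits)
        self.N = len(data)
        self.Y = data[traits].to_numpy(float)  # N x t
        self.term_names = [term.name for term in spec.terms]

        blocks = [np.ones((self.N, 1))]
        self.part_slices = [slice(0, 1)]  # fixed intercept first
        self.levels: dict = {}
        self.Kinv: dict = {}
        self.K: dict = {}
        self.logdetK: dict = {}
        start = 1
        for term in spec.terms:
            levels = pd.unique(data[term.column])
            if len(levels) < 2 and term.relationship is None:
                raise ValueError(
                    f"random term {term.name!r} has a single level and is not identifiable"
                )
            lut = {lv: i for i, lv in enumerate(levels)}
            Z = np.zeros((self.N, len(levels)))
            Z[np.arange(self.N), [lut[v] for v in data[term.column]]] = 1.0
            blocks.append(Z)
            self.part_slices.append(slice(start, start + len(levels)))
            start += len(levels)
            self.levels[term.name] = list(levels)
            if term.relationship is None:
                K = np.eye(len(levels))
                Kinv = K
                logdet = 0.0
            else:
                rel = term.relationship
                missing = set(levels) - set(rel.ids)
                if missing:
                    raise ValueError(
                        f"levels missing from {term.name} relationship: {sorted(missing)[:5]}"
                    )
                rel = rel.subset(levels)
                if rel.kind == "G":
                    rel = blend(rel, 0.99)
                K = rel.values
                sign, logdet = np.linalg.slogdet(K)
                if sign <= 0:
                    raise ValueError(f"relationship for {term.name} is not positive definite")
                Kinv = np.linalg.inv(K)
            self.K[term.name] = K
            self.Kinv[term.name] = Kinv
            self.logdetK[term.name] = logdet
        self.B = np.hstack(blocks)  # N x m0
        self.m0 = self.B.shape[1]
        self.T = self.B.T @ self.B
        self.Bty = self.B.T @ self.Y  # m0 x t
        self.yty = self.Y.T @ self.Y  # t x t

    def q(self, name: str) -> int:
        return len(self.levels[name])

    def term_slice(self, name: str) -> slice:
        return self.part_slices[1 + self.term_names.index(name)]

    def cols(self, trait_idx: int, sl: slice) -> np.ndarray:
        return np.arange(sl.start, sl.stop) + trait_idx * self.m0


def _assemble(ws: _Workspace, sigmas: dict, R0: np.ndarray):
    """MME coefficient matrix, rhs, and the penalty inverses used."""
    t, m0 = ws.t, ws.m0
    R0inv = _safe_inv(R0)
    C = np.kron(R0inv, ws.T)
    sig_inv = {}
    for name in ws.term_names:
        Sinv = _safe_inv(sigmas[name])
        sig_inv[name] = Sinv
        sl = ws.term_slice(name)
        Kinv = ws.Kinv[name]
        for i in range(t):
            rows = ws.cols(i, sl)
            for j in range(t):
                colsj = ws.cols(j, sl)
                C[np.ix_(rows, colsj)] += Sinv[i, j] * Kinv
    rhs = (ws.Bty @ R0inv).T.reshape(-1)  # trait-major stacking
    return C, rhs, R0inv, sig_inv


def _loglik(ws, sigmas, R0, C_factor, rhs, theta, R0inv):
    t, N = ws.t, ws.N
    logdetC = 2.0 * np.sum(np.log(np.diag(C_factor[0])))
    term = 0.0
    for name in ws.term_names:
        q = ws.q(name)
        sign, ld = np.linalg.slogdet(sigmas[name])
        term += q * ld + t * ws.logdetK[name]
    sign, ldR = np.linalg.slogdet(R0)
    yRy = float(np.sum(R0inv * ws.yty))
    quad = yRy - float(theta @ rhs)
    m2ll = logdetC + term + N * ldR + quad
    return -0.5 * m2ll


def reml_fit(
    spec: ModelSpec,
    ph: pd.DataFrame,
    em_iterations: int = 5,
    max_iterations: int = 500,
    tol: float = 1e-6,
    seed: int = 1,
    compute_ai: bool = True,
    verbose: bool = False,
) -> VarianceComponents:
    """REML estimation of all trait covariance matrices.

    EM warm-up sweeps are followed by AI Newton steps; an AI step that fails
    to improve the likelihood even after step-halving falls back to an EM
    sweep, which keeps the likelihood monotone.  Convergence is declared
    when the log-likelihood changes by less than ``tol``.
    """
    ws = _Workspace(spec, ph)
    t = ws.t
    rng = np.random.default_rng(seed)
    Sy = np.cov(ws.Y, rowvar=False).reshape(t, t)
    K = len(ws.term_names)
    jitter = 1e-3 * np.trace(Sy) / t
    floor_abs = 1e-6 * np.trace(Sy) / t  # keeps Sigma^-1 bounded at boundaries

    def proj(S):
        return _psd_project(S, floor_abs=floor_abs)

    sigmas = {
        name: proj(0.5 * Sy / K + jitter * np.diag(1.0 + 0.01 * rng.random(t)))
        for name in ws.term_names
    }
    R0 = proj(0.5 * Sy + jitter * np.eye(t))

    trace = []
    last_ll = -np.inf
    theta = None
    Cinv = None
    converged = False
    it = 0

    def solve_state(sigmas, R0):
        C, rhs, R0inv, sig_inv = _assemble(ws, sigmas, R0)
        factor = cho_factor(C, lower=True, check_finite=False)
        theta = cho_solve(factor, rhs, check_finite=False)
        ll = _loglik(ws, sigmas, R0, factor, rhs, theta, R0inv)
        return C, rhs, R0inv, sig_inv, factor, theta, ll

    def em_update(theta, Cinv, R0inv, sigmas):
        new_sig = {}
        for name in ws.term_names:
            q = ws.q(name)
            sl = ws.term_slice(name)
            Kinv = ws.Kinv[name]
            U = np.column_stack([theta[ws.cols(i, sl)] for i in range(t)])
            S = U.T @ Kinv @ U
            for i in range(t):
                ri = ws.cols(i, sl)
                for j in range(i, t):
                    rj = ws.cols(j, sl)
                    tr = float(np.sum(Kinv * Cinv[np.ix_(ri, rj)].T))
                    S[i, j] += tr
                    if i != j:
                        S[j, i] += tr
            new_sig[name] = proj(S / q)
        # residual
        theta_mat = theta.reshape(t, ws.m0)
        E = ws.Y - ws.B @ theta_mat.T  # N x t residuals
        S = E.T @ E
        for i in range(t):
            ri = ws.cols(i, slice(0, ws.m0))
            for j in range(i, t):
                rj = ws.cols(j, slice(0, ws.m0))
                tr = float(np.sum(ws.T * Cinv[np.ix_(ri, rj)].T))
                S[i, j] += tr
                if i != j:
                    S[j, i] += tr
        new_R0 = proj(S / ws.N)
        return new_sig, new_R0

    C, rhs, R0inv, sig_inv, factor, theta, ll = solve_state(sigmas, R0)
    trace.append(ll)

    vech_idx = [(a, b) for a in range(t) for b in range(a, t)]

    def param_vector(sigmas, R0):
        vals = []
        for name in ws.term_names:
            vals.extend(sigmas[name][a, b] for a, b in vech_idx)
        vals.extend(R0[a, b] for a, b in vech_idx)
        return np.array(vals)

    def from_vector(phi):
        nv = len(vech_idx)
        sig = {}
        for k, name in enumerate(ws.term_names):
            S = np.zeros((t, t))
            for l, (a, b) in enumerate(vech_idx):
                S[a, b] = S[b, a] = phi[k * nv + l]
            sig[name] = proj(S)
        S = np.zeros((t, t))
        for l, (a, b) in enumerate(vech_idx):
            S[a, b] = S[b, a] = phi[K * nv + l]
        return sig, proj(S)

    def grad_and_ai(theta, Cinv, R0inv, sig_inv, sigmas, R0):
        theta_mat = theta.reshape(t, ws.m0)
        E = ws.Y - ws.B @ theta_mat.T  # residuals N x t
        Py = E @ R0inv  # N x t, trait columns of P y

        grads = []
        fvecs = []  # each (N, t) working vector dV/dphi @ Py
        for name in ws.term_names:
            q = ws.q(name)
            sl = ws.term_slice(name)
            Kmat = ws.K[name]
            Kinv = ws.Kinv[name]
            Sinv = sig_inv[name]
            zsl = slice(sl.start, sl.stop)
            # w_c = Z' (Py)_c via B'Py rows of the term
            BtPy = ws.B.T @ Py  # m0 x t
            w = BtPy[zsl, :]  # q x t
            vtil = Kmat @ w  # q x t
            D = w.T @ vtil  # t x t data part
            H = np.empty((t, t))
            for a in range(t):
                ra = ws.cols(a, sl)
                for b in range(a, t):
                    rb = ws.cols(b, sl)
                    H[a, b] = H[b, a] = float(np.sum(Cinv[np.ix_(ra, rb)] * Kinv.T))
            Etr = q * Sinv - Sinv @ H @ Sinv
            Gamma = 0.5 * (D - Etr)
            Zblock = ws.B[:, zsl]
            for a, b in vech_idx:
                S = np.zeros((t, t))
                S[a, b] = S[b, a] = 1.0
                grads.append(float(np.sum(Gamma * S)))
                f = Zblock @ (vtil @ S)  # N x t
                fvecs.append(f)
        # residual block
        Uc = np.empty((t, t))
        for a in range(t):
            ra = ws.cols(a, slice(0, ws.m0))
            for b in range(a, t):
                rb = ws.cols(b, slice(0, ws.m0))
                Uc[a, b] = Uc[b, a] = float(np.sum(Cinv[np.ix_(ra, rb)] * ws.T.T))
        TrP = ws.N * R0inv - R0inv @ Uc @ R0inv
        DR = Py.T @ Py
        GammaR = 0.5 * (DR - TrP)
        for a, b in vech_idx:
            S = np.zeros((t, t))
            S[a, b] = S[b, a] = 1.0
            grads.append(float(np.sum(GammaR * S)))
            fvecs.append(Py @ S)
        grad = np.array(grads)

        npar = len(fvecs)
        ai = np.empty((npar, npar))
        avecs = []
        for f in fvecs:
            Btf = ws.B.T @ f  # m0 x t
            a_l = (Btf @ R0inv).T.reshape(-1)
            avecs.append(a_l)
        Cinv_a = [Cinv @ a for a in avecs]
        for l in range(npar):
            for m in range(l, npar):
                direct = float(np.sum((fvecs[l] @ R0inv) * fvecs[m]))
                corr = float(avecs[l] @ Cinv_a[m])
                ai[l, m] = ai[m, l] = 0.5 * (direct - corr)
        return grad, ai

    ai_matrix = None
    # noise-robust stopping: keep the best iterate seen and stop after
    # ``patience`` post-warm-up iterations without a > tol improvement on it
    patience = 5
    stall = 0
    best_ll = ll
    best_state = (sigmas, R0, C, rhs, R0inv, sig_inv, factor, theta, ll)

    def em_slack(l):
        return 1e-5 * max(1.0, abs(l))

    for it in range(1, max_iterations + 1):
        Cinv = cho_solve(factor, np.eye(C.shape[0]), check_finite=False)
        if it <= em_iterations:
            new_sig, new_R0 = em_update(theta, Cinv, R0inv, sigmas)
            Cn, rhsn, R0invn, sig_invn, factn, thetan, lln = solve_state(new_sig, new_R0)
            if lln < ll - em_slack(ll):
                raise AssertionError(
                    f"EM step decreased the REML log-likelihood: {ll:.6f} -> {lln:.6f}"
                )
            accepted = (new_sig, new_R0, Cn, rhsn, R0invn, sig_invn, factn, thetan, lln)
        else:
            grad, ai = grad_and_ai(theta, Cinv, R0inv, sig_inv, sigmas, R0)
            ai_matrix = ai
            phi = param_vector(sigmas, R0)
            try:
                ridge = 1e-8 * max(np.abs(np.diag(ai)).max(), 1.0)
                delta = np.linalg.solve(ai + ridge * np.eye(len(ai)), grad)
            except np.linalg.LinAlgError:
                delta = None
            accepted = None
            if delta is not None:
                step = 1.0
                for _ in range(8):
                    cand = from_vector(phi + step * delta)
                    try:
                        state = solve_state(*cand)
                    except np.linalg.LinAlgError:
                        step *= 0.5
                        continue
                    if state[-1] > ll:
                        accepted = (*cand, *state)
                        break
                    step *= 0.5
            if accepted is None:
                # EM fallback keeps the likelihood monotone
                new_sig, new_R0 = em_update(theta, Cinv, R0inv, sigmas)
                state = solve_state(new_sig, new_R0)
                if state[-1] < ll - em_slack(ll):
                    raise AssertionError(
                        f"EM step decreased the REML log-likelihood: {ll:.6f} -> {state[-1]:.6f}"
                    )
                accepted = (new_sig, new_R0, *state)
                # guarded over-relaxation: EM crawls geometrically along
                # boundary ridges (e.g. a structurally singular component),
                # so try longer steps along the EM direction and keep the
                # first one that beats the plain EM step
                phi_cur = param_vector(sigmas, R0)
                phi_em = param_vector(new_sig, new_R0)
                em_ll = state[-1]
                for kappa in (16.0, 8.0, 4.0, 2.0):
                    cand = from_vector(phi_cur + kappa * (phi_em - phi_cur))
                    try:
                        st = solve_state(*cand)
                    except np.linalg.LinAlgError:
                        continue
                    if st[-1] > em_ll:
                        accepted = (*cand, *st)
                        break
        sigmas, R0, C, rhs, R0inv, sig_inv, factor, theta, new_ll = accepted
        trace.append(new_ll)
        if verbose:
            print(f"iter {it}: logL = {new_ll:.6f}")
        if new_ll > best_ll:
            best_state = accepted
            improved = new_ll > best_ll + max(tol, 1e-7 * max(1.0, abs(new_ll)))
            best_ll = new_ll
        else:
            improved = False
        if it > em_iterations:
            stall = 0 if improved else stall + 1
            if stall >= patience:
                converged = True
                break
        ll = new_ll
    sigmas, R0, C, rhs, R0inv, sig_inv, factor, theta, ll = best_state
    if not converged:
        raise ConvergenceError(
            f"REML did not converge in {max_iterations} iterations "
            f"(last |dlogL| = {abs(trace[-1] - trace[-2]):.2e})",
            trace=trace,
        )

    if compute_ai:
        Cinv = cho_solve(factor, np.eye(C.shape[0]), check_finite=False)
        _, ai_matrix = grad_and_ai(theta, Cinv, R0inv, sig_inv, sigmas, R0)

    param_names = []
    for name in ws.term_names + ["residual"]:
        for a, b in vech_idx:
            param_names.append(f"{name}:{ws.traits[a]}:{ws.traits[b]}")

    blups = {}
    for name in ws.term_names:
        sl = ws.term_slice(name)
        U = np.column_stack([theta[ws.cols(i, sl)] for i in range(t)])
        blups[name] = pd.DataFrame(U, index=ws.levels[name], columns=ws.traits)
    fixed = np.array([theta[ws.cols(i, slice(0, 1))][0] for i in range(t)])

    return VarianceComponents(
        components={n: sigmas[n] for n in ws.term_names},
        residual=R0,
        loglik=float(ll),
        ai_matrix=ai_matrix,
        param_names=param_names,
        traits=ws.traits,
        n_records=ws.N,
        converged=True,
        blups=blups,
        fixed_effects=fixed,
        iterations=it,
    )


# ---------------------------------------------------------------------------
# derived genetic parameters


def _param_cov(vc: VarianceComponents) -> np.ndarray | None:
    if vc.ai_matrix is None:
        return None
    ai = vc.ai_matrix
    ridge = 1e-8 * max(np.abs(np.diag(ai)).max(), 1.0)
    try:
        return np.linalg.inv(ai + ridge * np.eye(len(ai)))
    except np.linalg.LinAlgError:
        return None


def _pidx(vc: VarianceComponents, term: str, a: int, b: int) -> int:
    lo, hi = min(a, b), max(a, b)
    name = f"{term}:{vc.traits[lo]}:{vc.traits[hi]}"
    return vc.param_names.index(name)


def genetic_params(vc: VarianceComponents, additive_term: str = "additive") -> GeneticParams:
    """Heritabilities and genetic correlations with delta-method SEs.

    h² uses the two-component denominator σ²_a + σ²_e; other fitted terms
    are excluded by definition.  SEs come from first-order propagation of
    the inverse AI matrix; pairs with vanishing additive variance get
    missing r_g.
    """
    t = len(vc.traits)
    Sa = vc.components[additive_term]
    R0 = vc.residual
    pcov = _param_cov(vc)

    h2_rows = []
    for i, trait in enumerate(vc.traits):
        va, ve = Sa[i, i], R0[i, i]
        h2 = va / (va + ve)
        se = np.nan
        if pcov is not None:
            ia = _pidx(vc, additive_term, i, i)
            ie = _pidx(vc, "residual", i, i)
            grad = np.zeros(len(vc.param_names))
            grad[ia] = ve / (va + ve) ** 2
            grad[ie] = -va / (va + ve) ** 2
            se = float(np.sqrt(max(grad @ pcov @ grad, 0.0)))
        h2_rows.append((trait, float(h2), se))

    rg_rows = []
    for i in range(t):
        for j in range(i + 1, t):
            vx, vy, cxy = Sa[i, i], Sa[j, j], Sa[i, j]
            if vx <= 1e-12 or vy <= 1e-12:
                rg_rows.append((vc.traits[i], vc.traits[j], np.nan, np.nan))
                continue
            rg = cxy / np.sqrt(vx * vy)
            se = np.nan
            if pcov is not None:
                grad = np.zeros(len(vc.param_names))
                grad[_pidx(vc, additive_term, i, j)] = 1.0 / np.sqrt(vx * vy)
                grad[_pidx(vc, additive_term, i, i)] = -cxy / (2.0 * vx ** 1.5 * np.sqrt(vy))
                grad[_pidx(vc, additive_term, j, j)] = -cxy / (2.0 * vy ** 1.5 * np.sqrt(vx))
                se = float(np.sqrt(max(grad @ pcov @ grad, 0.0)))
            rg_rows.append((vc.traits[i], vc.traits[j], float(rg), se))

    return GeneticParams(
        h2=pd.DataFrame(h2_rows, columns=["trait", "h2", "se"]),
        rg=pd.DataFrame(rg_rows, columns=["trait_x", "trait_y", "rg", "se"]),
        traits=vc.traits,
    )


def extract_ebv(vc: VarianceComponents, term: str = "additive") -> pd.DataFrame:
    """BLUP breeding values of the additive term (levels x traits)."""
    if term not in vc.blups:
        raise KeyError(f"no term {term!r} in fit (have {list(vc.blups)})")
    return vc.blups[term].copy()


def prediction_accuracy(ebv, gebv) -> float:
    """Pearson correlation between aligned EBV and GEBV vectors."""
    ebv = np.asarray(ebv, float)
    gebv = np.asarray(gebv, float)
    if ebv.shape != gebv.shape:
        raise ValueError("EBV vectors must be aligned")
    return float(np.corrcoef(ebv, gebv)[0, 1])


# ---------------------------------------------------------------------------
# model presets


def training_model(traits, relationship: RelationshipMatrix) -> ModelSpec:
    """Single-tree-plot trial: additive + non-additive + replicate + set-in-rep."""
    return ModelSpec(
        traits=list(traits),
        terms=[
            RandomTerm("additive", "genotype_id", relationship),
            RandomTerm("nonadditive", "genotype_id", None),
            RandomTerm("replicate", "rep_factor", None),
            RandomTerm("set_in_rep", "group_factor", None),
        ],
    )


def prediction_model(traits, relationship: RelationshipMatrix) -> ModelSpec:
    """Incomplete-block trial: additive + non-additive + replicate + block."""
    return ModelSpec(
        traits=list(traits),
        terms=[
            RandomTerm("additive", "genotype_id", relationship),
            RandomTerm("nonadditive", "genotype_id", None),
            RandomTerm("replicate", "rep_factor", None),
            RandomTerm("incomplete_block", "group_factor", None),
        ],
    )


def add_design_factors(ph: pd.DataFrame) -> pd.DataFrame:
    """Derive combined replicate and set/block factor columns."""
    out = ph.copy()
    out["rep_factor"] = out["site"].astype(str) + ":" + out["rep"].astype(str)
    out["group_factor"] = out["rep_factor"] + ":" + out["set_or_block"].astype(str)
    return out
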