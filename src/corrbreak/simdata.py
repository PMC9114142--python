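"""Synthetic breeding-study generator.

Emulates the population design the analysis assumes: a conifer breeding
program where two training cohorts descend from parents picked out of a
common base population by different strategies — one by tandem selection
(growth first, then wood density; its offspring are the "correlation
breakers") and one by growth-and-form selection only — plus an independent
factorial-mated prediction cohort.  Genomes are scaffold-structured SNP
panels; distance-dependent LD arises from finite-population random-mating
burn-in with Poisson crossovers, and the breaker cohort's faster LD decay is
produced by extra intermating generations with a recombination multiplier
on top of the tandem selection itself (the two knobs are independent).

Traits (BR9, ST9, DBH, WD) are driven by sparse QTL effects.  Three
designated "pleiotropic-region" scaffolds carry QTLs with antagonistic
effects on DBH and WD; tandem selection pushes their allele frequencies
toward intermediate values, which elevates heterozygosity in those regions
of the breaker cohort while directional selection plus drift depresses its
genome-wide heterozygosity — the genomic signature the prediction stage
exploits.  All variance components are solved analytically from the
heritability and genetic-correlation targets before any phenotype noise is
drawn; nothing is rescaled afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix

TRAITS = ("BR9", "ST9", "DBH", "WD")
POP1GF, POP1HD, POP2GF = "POP1GF", "POP1HD", "POP2GF"


@dataclass
class SimConfig:
    """Study-design and genetic-architecture parameters (desk-scale defaults)."""

    # genome
    n_founders: int = 80
    n_scaffolds: int = 60
    snps_per_scaffold: int = 6
    scaffold_length_bp: int = 10_000
    maf_range: tuple = (0.05, 0.5)
    n_burnin_generations: int = 30
    base_recomb_per_scaffold: float = 0.06  # expected crossovers per meiosis
    # architecture
    n_pleio_scaffolds: int = 3
    n_qtl_pleiotropic: int = 12
    n_qtl_linked_pairs: int = 6
    n_qtl_shared_brst: int = 10
    n_qtl_private_per_trait: int = 15
    qtl_effect_sd: float = 1.0
    target_rg_dbh_wd: float = -0.4
    target_rg_br_st: float = 0.7
    h2_targets: dict = field(
        default_factory=lambda: {"BR9": 0.2, "ST9": 0.15, "DBH": 0.3, "WD": 0.5}
    )
    # non-additive / design variance, as fractions of the (unit) additive variance
    nonadd_ratio: float = 0.3
    rep_ratio: float = 0.2
    set_ratio: float = 0.15
    site_sd: float = 0.5
    # selection and mating design
    tandem_selection: bool = True
    tandem_stage1_fraction: float = 0.5
    recomb_multiplier_breakers: float = 10.0
    breaker_generations: int = 6
    families_gf: int = 10
    families_hd: int = 6
    families_factorial: int = 12
    factorial_parents: int = 10
    clones_per_family: int = 6
    copies_per_clone: int = 3
    n_sites: int = 2  # sites for the prediction cohort
    n_reps: int = 3
    n_sets: int = 3  # sets per replicate (training trial)
    n_blocks: int = 3  # incomplete blocks per replicate (prediction trial)
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_founders": self.n_founders,
            "n_scaffolds": self.n_scaffolds,
            "snps_per_scaffold": self.snps_per_scaffold,
            "scaffold_length_bp": self.scaffold_length_bp,
            "families_gf": self.families_gf,
            "families_hd": self.families_hd,
            "families_factorial": self.families_factorial,
            "factorial_parents": self.factorial_parents,
            "clones_per_family": self.clones_per_family,
            "copies_per_clone": self.copies_per_clone,
            "n_sites": self.n_sites,
            "n_reps": self.n_reps,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        for t, h2 in self.h2_targets.items():
            if not (0 < h2 < 1):
                raise ValueError(f"h2 target for {t} must be in (0,1), got {h2}")
        for rg in (self.target_rg_dbh_wd, self.target_rg_br_st):
            if not (-1 < rg < 1):
                raise ValueError(f"target rg must be in (-1,1), got {rg}")
        if self.recomb_multiplier_breakers < 1:
            raise ValueError("recomb_multiplier_breakers must be >= 1")


@dataclass
class SimulatedStudy:
    genotypes: GenotypeMatrix  # all genotyped individuals, population-tagged
    pedigree: pd.DataFrame  # id, sire, dam (founders blank)
    phenotypes: pd.DataFrame
    breaker_labels: pd.Series  # training individuals only
    families: pd.Series  # genotype id -> family id
    qtl_truth: pd.DataFrame  # marker x trait additive effects (nonzero rows)
    true_breeding_values: pd.DataFrame  # genotype x trait
    realized_params: dict
    config: SimConfig

    def population(self, tag: str) -> GenotypeMatrix:
        return self.genotypes.by_population(tag)


# ---------------------------------------------------------------------------
# genome scaffolding and founders


def _scaffold_layout(config: SimConfig, rng: np.random.Generator):
    """Marker map plus per-scaffold slices and local positions."""
    markers, scaffolds, positions = [], [], []
    slices, local_pos = [], []
    start = 0
    for s in range(config.n_scaffolds):
        pos = np.sort(
            rng.choice(config.scaffold_length_bp, size=config.snps_per_scaffold, replace=False)
        )
        for j, p in enumerate(pos):
            markers.append(f"scf{s:03d}_m{j}")
            scaffolds.append(f"scf{s:03d}")
            positions.append(int(p))
        slices.append(slice(start, start + config.snps_per_scaffold))
        local_pos.append(pos.astype(float))
        start += config.snps_per_scaffold
    marker_map = pd.DataFrame(
        {"scaffold": scaffolds, "pos_bp": positions}, index=pd.Index(markers, name="marker")
    )
    return marker_map, slices, local_pos


def meiosis(
    parent_haps: np.ndarray,
    recomb_rates: np.ndarray,
    slices: list,
    local_pos: list,
    scaffold_length_bp: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete from a (2, m) pair of parental haplotypes.

    Crossover counts per scaffold are Poisson(rate) with uniform bp
    positions; the gamete alternates parental haplotypes at crossovers and
    scaffolds segregate independently.
    """
    recomb_rates = np.broadcast_to(np.asarray(recomb_rates, float), (len(slices),))
    if (recomb_rates < 0).any():
        raise ValueError("recombination rates must be >= 0")
    m = parent_haps.shape[1]
    gamete = np.empty(m, dtype=parent_haps.dtype)
    for s, sl in enumerate(slices):
        k = rng.poisson(recomb_rates[s])
        start = rng.integers(2)
        if k == 0:
            gamete[sl] = parent_haps[start, sl]
        else:
            bp = np.sort(rng.uniform(0, scaffold_length_bp, size=k))
            seg = np.searchsorted(bp, local_pos[s])
            which = (start + seg) % 2
            block = parent_haps[:, sl]
            gamete[sl] = np.where(which == 0, block[0], block[1])
    return gamete


def _gametes_batch(haps, parent_idx, rates, slices, local_pos, length, rng):
    """Vectorised gametes for many parents; loops only over recombinant scaffolds."""
    g = len(parent_idx)
    m = haps.shape[2]
    rates = np.broadcast_to(np.asarray(rates, float), (len(slices),))
    out = np.empty((g, m), dtype=haps.dtype)
    for s, sl in enumerate(slices):
        k = rng.poisson(rates[s], size=g)
        start = rng.integers(0, 2, size=g)
        block = haps[parent_idx][:, :, sl]  # (g, 2, width)
        out[:, sl] = np.where((start == 0)[:, None], block[:, 0], block[:, 1])
        for gi in np.flatnonzero(k > 0):
            bp = np.sort(rng.uniform(0, length, size=k[gi]))
            which = (start[gi] + np.searchsorted(bp, local_pos[s])) % 2
            out[gi, sl] = np.where(which == 0, block[gi, 0], block[gi, 1])
    return out


def _random_mating_generation(haps, rates, slices, local_pos, length, rng, n_out=None):
    n = haps.shape[0] if n_out is None else n_out
    pool = haps.shape[0]
    sires = rng.integers(0, pool, size=n)
    dams = (sires + 1 + rng.integers(0, pool - 1, size=n)) % pool  # no selfing
    g1 = _gametes_batch(haps, sires, rates, slices, local_pos, length, rng)
    g2 = _gametes_batch(haps, dams, rates, slices, local_pos, length, rng)
    return np.stack([g1, g2], axis=1)


def simulate_founders(config: SimConfig, rng: np.random.Generator):
    """Base-population haplotypes with distance-dependent LD.

    Haplotypes start in linkage equilibrium at allele frequencies drawn from
    ``maf_range`` and then pass through ``n_burnin_generations`` of
    finite-population random mating, which lets drift build LD that decays
    with physical distance — the regime the decay analysis assumes.
    """
    config.validate()
    lo, hi = config.maf_range
    if lo == hi == 0:
        raise ValueError("degenerate maf_range")
    marker_map, slices, local_pos = _scaffold_layout(config, rng)
    m = len(marker_map)
    p = rng.uniform(lo, hi, size=m)
    haps = (rng.random((config.n_founders, 2, m)) < p[None, None, :]).astype(np.uint8)
    rates = np.full(config.n_scaffolds, config.base_recomb_per_scaffold)
    for _ in range(config.n_burnin_generations):
        haps = _random_mating_generation(
            haps, rates, slices, local_pos, config.scaffold_length_bp, rng
        )
    return haps, marker_map, slices, local_pos


# ---------------------------------------------------------------------------
# selection and mating


def tandem_select(candidates, ebv_growth, ebv_density, n_stage1: int, n_final: int):
    """Two-stage parent selection: growth first, then density among survivors.

    Deterministic given inputs; ties broken by candidate id.
    """
    candidates = list(candidates)
    if not (0 < n_final <= n_stage1 <= len(candidates)):
        raise ValueError(
            f"need n_final <= n_stage1 <= n_candidates, got {n_final}, {n_stage1}, {len(candidates)}"
        )
    growth = dict(zip(candidates, ebv_growth))
    density = dict(zip(candidates, ebv_density))
    stage1 = sorted(candidates, key=lambda c: (-growth[c], c))[:n_stage1]
    return sorted(stage1, key=lambda c: (-density[c], c))[:n_final]


def mate(parents, design: str, n_families: int, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Full-sib family list (family_id, sire, dam) under the given mating design.

    ``single_pair`` uses each of 2*n_families distinct parents exactly once;
    ``factorial`` samples sire-dam combinations from the pool without
    repeating a pair.
    """
    parents = list(parents)
    rows = []
    if design == "single_pair":
        if len(parents) < 2 * n_families:
            raise ValueError(
                f"single-pair design needs {2 * n_families} parents, got {len(parents)}"
            )
        for f in range(n_families):
            rows.append((f"F{f:03d}", parents[2 * f], parents[2 * f + 1]))
    elif design == "factorial":
        if len(parents) < 2:
            raise ValueError("factorial design needs at least 2 parents")
        max_pairs = len(parents) * (len(parents) - 1) // 2
        if n_families > max_pairs:
            raise ValueError(f"cannot form {n_families} distinct pairs from {len(parents)} parents")
        rng = np.random.default_rng() if rng is None else rng
        seen = set()
        f = 0
        while f < n_families:
            i, j = rng.choice(len(parents), size=2, replace=False)
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            rows.append((f"F{f:03d}", parents[key[0]], parents[key[1]]))
            f += 1
    else:
        raise ValueError(f"unknown mating design {design!r}")
    return pd.DataFrame(rows, columns=["family_id", "sire", "dam"])


# ---------------------------------------------------------------------------
# QTL architecture


def _solve_pair(shared_a, shared_b, priv_a, priv_b, target, M0c):
    """Scale private-effect vectors so the realised TBV correlation between a
    trait pair equals ``target``, using the empirical dosage covariance of
    the base cohort (so linkage between QTLs is accounted for exactly)."""
    s_a = M0c @ shared_a
    s_b = M0c @ shared_b
    v1, v2 = s_a.var(), s_b.var()
    cov = float(np.cov(s_a, s_b)[0, 1])
    rho = cov / np.sqrt(v1 * v2)
    if target == 0 or np.sign(rho) != np.sign(target) or abs(rho) < abs(target):
        warnings.warn(
            f"shared-QTL correlation {rho:.2f} cannot reach target {target:.2f}; "
            "using shared effects only"
        )
        return shared_a + priv_a * 0.0, shared_b + priv_b * 0.0
    vpa = (M0c @ priv_a).var()
    vpb = (M0c @ priv_b).var()
    t_a = np.sqrt(v1 / v2) * cov / target
    t_b = np.sqrt(v2 / v1) * cov / target
    ca = np.sqrt(max(t_a - v1, 0.0) / vpa) if vpa > 0 else 0.0
    cb = np.sqrt(max(t_b - v2, 0.0) / vpb) if vpb > 0 else 0.0
    return shared_a + ca * priv_a, shared_b + cb * priv_b


def _build_effects(config: SimConfig, marker_map: pd.DataFrame, M0: np.ndarray, rng):
    """Per-marker effects for the four traits, unit TBV variance in the base cohort."""
    m = len(marker_map)
    scaffolds = marker_map["scaffold"].to_numpy()
    scaffold_ids = sorted(set(scaffolds))
    designated = scaffold_ids[: config.n_pleio_scaffolds]
    desig_idx = np.flatnonzero(np.isin(scaffolds, designated))
    other_idx = np.flatnonzero(~np.isin(scaffolds, designated))

    used = set()

    def draw(pool, n):
        free = [i for i in pool if i not in used]
        if len(free) < n:
            raise ValueError("not enough markers for the requested QTL architecture")
        pick = rng.choice(free, size=n, replace=False)
        used.update(int(i) for i in pick)
        return np.asarray(pick, dtype=int)

    sd = config.qtl_effect_sd
    beta = {t: np.zeros(m) for t in TRAITS}

    # antagonistic pleiotropic QTLs on the designated scaffolds
    pleio = draw(desig_idx, min(config.n_qtl_pleiotropic, len(desig_idx)))
    e = np.abs(rng.normal(0, sd, size=len(pleio)))
    shared_d = np.zeros(m)
    shared_w = np.zeros(m)
    shared_d[pleio] = e
    shared_w[pleio] = -e * np.abs(rng.normal(1.0, 0.2, size=len(pleio)))

    # linked antagonistic pairs on other scaffolds: adjacent markers, one per trait
    pair_scaffolds = rng.choice(
        sorted(set(scaffolds[other_idx])), size=min(config.n_qtl_linked_pairs, 1_000), replace=False
    ) if config.n_qtl_linked_pairs > 0 else []
    for scf in pair_scaffolds:
        idx = np.flatnonzero(scaffolds == scf)
        j = rng.integers(0, len(idx) - 1)
        a, b = int(idx[j]), int(idx[j + 1])
        if a in used or b in used:
            continue
        used.update((a, b))
        shared_d[a] = np.abs(rng.normal(0, sd))
        shared_w[b] = -np.abs(rng.normal(0, sd))

    priv_d = np.zeros(m)
    priv_w = np.zeros(m)
    priv_d[draw(other_idx, config.n_qtl_private_per_trait)] = rng.normal(
        0, sd, size=config.n_qtl_private_per_trait
    )
    priv_w[draw(other_idx, config.n_qtl_private_per_trait)] = rng.normal(
        0, sd, size=config.n_qtl_private_per_trait
    )

    M0c = M0 - M0.mean(axis=0)
    beta["DBH"], beta["WD"] = _solve_pair(
        shared_d, shared_w, priv_d, priv_w, config.target_rg_dbh_wd, M0c
    )

    # BR9/ST9: common QTL set plus trait-private QTLs
    shared_bs = np.zeros(m)
    shared_bs[draw(other_idx, config.n_qtl_shared_brst)] = rng.normal(
        0, sd, size=config.n_qtl_shared_brst
    )
    priv_b = np.zeros(m)
    priv_s = np.zeros(m)
    priv_b[draw(other_idx, config.n_qtl_private_per_trait)] = rng.normal(
        0, sd, size=config.n_qtl_private_per_trait
    )
    priv_s[draw(other_idx, config.n_qtl_private_per_trait)] = rng.normal(
        0, sd, size=config.n_qtl_private_per_trait
    )
    beta["BR9"], beta["ST9"] = _solve_pair(
        shared_bs, shared_bs.copy(), priv_b, priv_s, config.target_rg_br_st, M0c
    )

    # normalise each trait to unit additive variance in the base cohort
    for t in TRAITS:
        v = (M0c @ beta[t]).var()
        if v <= 0:
            raise ValueError(f"degenerate additive variance for {t}")
        beta[t] = beta[t] / np.sqrt(v)

    effects = np.column_stack([beta[t] for t in TRAITS])
    truth = pd.DataFrame(effects, index=marker_map.index, columns=list(TRAITS))
    truth = truth.loc[(truth != 0).any(axis=1)]
    return effects, truth, designated


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    tbv: pd.DataFrame,
    layout: pd.DataFrame,
    h2_targets: dict,
    variance_ratios: dict | None = None,
    site_sd: float = 0.5,
    rng: np.random.Generator | None = None,
    ordinal_traits=("BR9", "ST9"),
) -> pd.DataFrame:
    """Trait records for a trial layout.

    phenotype = site mean + additive score + clone non-additive deviation +
    replicate effect + set/block effect + residual.  Residual variance per
    trait is solved from its heritability target against the empirical
    additive variance of the phenotyped genotypes; non-additive and design
    variances are fixed fractions of that additive variance.  Ordinal traits
    are produced on the latent scale, then cut into nine equal-frequency
    bins.
    """
    rng = np.random.default_rng() if rng is None else rng
    ratios = {"nonadd": 0.3, "rep": 0.2, "set": 0.15}
    if variance_ratios:
        ratios.update(variance_ratios)
    traits = list(tbv.columns)
    out = layout.copy()
    genos = tbv.index.to_numpy()
    gidx = {g: i for i, g in enumerate(genos)}
    rows_g = np.array([gidx[g] for g in out["genotype_id"]])
    sites = sorted(out["site"].unique())
    reps = sorted(set(zip(out["site"], out["rep"])))
    blocks = sorted(set(zip(out["site"], out["rep"], out["set_or_block"])))

    for t in traits:
        h2 = h2_targets[t]
        if not (0 < h2 < 1):
            raise ValueError(f"unreachable heritability target {h2} for {t}")
        va = float(tbv[t].to_numpy().var())
        if va == 0:
            raise ValueError(f"zero additive variance among phenotyped genotypes for {t}")
        sigma_e = np.sqrt(va * (1 - h2) / h2)
        site_eff = {s: rng.normal(0, site_sd) for s in sites}
        nonadd = {g: rng.normal(0, np.sqrt(ratios["nonadd"] * va)) for g in genos}
        rep_eff = {r: rng.normal(0, np.sqrt(ratios["rep"] * va)) for r in reps}
        set_eff = {b: rng.normal(0, np.sqrt(ratios["set"] * va)) for b in blocks}
        y = (
            tbv[t].to_numpy()[rows_g]
            + np.array([site_eff[s] for s in out["site"]])
            + np.array([nonadd[g] for g in out["genotype_id"]])
            + np.array([rep_eff[r] for r in zip(out["site"], out["rep"])])
            + np.array([set_eff[b] for b in zip(out["site"], out["rep"], out["set_or_block"])])
            + rng.normal(0, sigma_e, size=len(out))
        )
        if t in ordinal_traits:
            edges = np.quantile(y, np.linspace(0, 1, 10)[1:-1])
            y = np.searchsorted(edges, y) + 1.0
        out[t] = y
    return out


def _trial_layout(genotypes, families: pd.Series, site_names, copies, n_reps, n_groups, group_label):
    """One record per (genotype, site, replicate-copy); groups nest in replicates."""
    fam_ids = sorted(set(families[g] for g in genotypes))
    fam_group = {f: k % n_groups for k, f in enumerate(fam_ids)}
    rows = []
    for site in site_names:
        for g in genotypes:
            for c in range(copies):
                rep = c % n_reps + 1
                rows.append(
                    (g, c + 1, site, rep, f"{group_label}{fam_group[families[g]]}")
                )
    return pd.DataFrame(
        rows, columns=["genotype_id", "ramet", "site", "rep", "set_or_block"]
    )


# ---------------------------------------------------------------------------
# full study


def generate_study(config: SimConfig) -> SimulatedStudy:
    """Simulate the full three-cohort study; reproducible from ``config.seed``."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
    rng_gen, rng_sel, rng_mate, rng_breed, rng_pheno, _ = rngs

    haps, marker_map, slices, local_pos = simulate_founders(config, rng_gen)
    length = config.scaffold_length_bp
    base_rates = np.full(config.n_scaffolds, config.base_recomb_per_scaffold)
    M0 = haps.sum(axis=1).astype(float)
    effects, truth, designated = _build_effects(config, marker_map, M0, rng_sel)

    # selection proxies: breeding-value estimates with accuracy set by h2
    tbv0 = (M0 - M0.mean(axis=0)) @ effects  # founders x traits
    founder_ids = [f"FND{i:03d}" for i in range(config.n_founders)]

    def noisy(col, h2):
        va = tbv0[:, col].var()
        return tbv0[:, col] + rng_sel.normal(0, np.sqrt(va * (1 - h2) / h2), size=len(tbv0))

    ebv_growth = noisy(TRAITS.index("DBH"), config.h2_targets["DBH"])
    ebv_density = noisy(TRAITS.index("WD"), config.h2_targets["WD"])
    growth_by_id = dict(zip(founder_ids, ebv_growth))
    density_by_id = dict(zip(founder_ids, ebv_density))

    n_gf_parents = 2 * config.families_gf
    n_hd_parents = 2 * config.families_hd
    gf_parents = tandem_select(founder_ids, ebv_growth, ebv_density, n_gf_parents, n_gf_parents)
    pop2_parents = tandem_select(
        founder_ids, ebv_growth, ebv_density, config.factorial_parents, config.factorial_parents
    )

    # the breaker pool: stage-1 (growth) survivors are intermated *before* the
    # stage-2 (density) cut, so recombination acts in a pool large enough that
    # it, not drift, dominates the LD dynamics
    fidx = {f: i for i, f in enumerate(founder_ids)}
    stage1_n = max(int(config.tandem_stage1_fraction * config.n_founders), n_hd_parents)
    if config.tandem_selection:
        stage1 = tandem_select(founder_ids, ebv_growth, ebv_density, stage1_n, stage1_n)
    else:
        stage1 = list(
            np.array(founder_ids)[rng_sel.choice(config.n_founders, stage1_n, replace=False)]
        )
    pool_haps = haps[[fidx[p] for p in stage1]]
    hd_rates = base_rates * config.recomb_multiplier_breakers
    for _ in range(config.breaker_generations):
        pool_haps = _random_mating_generation(
            pool_haps, hd_rates, slices, local_pos, length, rng_breed
        )
    pool_tbv = (pool_haps.sum(axis=1).astype(float) - M0.mean(axis=0)) @ effects
    wd_col = TRAITS.index("WD")
    va_wd = pool_tbv[:, wd_col].var()
    h2_wd = config.h2_targets["WD"]
    pool_density_ebv = pool_tbv[:, wd_col] + rng_sel.normal(
        0, np.sqrt(max(va_wd, 1e-12) * (1 - h2_wd) / h2_wd), size=len(pool_tbv)
    )
    if config.tandem_selection:
        picked = np.argsort(-pool_density_ebv)[:n_hd_parents]
    else:
        picked = rng_sel.choice(len(pool_tbv), n_hd_parents, replace=False)
    hd_haps = pool_haps[picked]
    hd_parent_ids = [f"HDP{i:03d}" for i in range(n_hd_parents)]

    fam_gf = mate(gf_parents, "single_pair", config.families_gf, rng_mate)
    fam_hd = mate(hd_parent_ids, "single_pair", config.families_hd, rng_mate)
    fam_p2 = mate(pop2_parents, "factorial", config.families_factorial, rng_mate)

    def breed(fams, parent_haps, parent_ids, rates, prefix, rng):
        pidx = {p: i for i, p in enumerate(parent_ids)}
        genos, fam_of, doses, ped_rows = [], {}, [], []
        for r in fams.itertuples():
            for c in range(config.clones_per_family):
                gid = f"{prefix}_{r.family_id}_c{c}"
                g1 = meiosis(parent_haps[pidx[r.sire]], rates, slices, local_pos, length, rng)
                g2 = meiosis(parent_haps[pidx[r.dam]], rates, slices, local_pos, length, rng)
                genos.append(gid)
                fam_of[gid] = f"{prefix}_{r.family_id}"
                doses.append(g1.astype(float) + g2)
                ped_rows.append((gid, r.sire, r.dam))
        return genos, fam_of, np.array(doses), ped_rows

    gf_haps = haps[[fidx[p] for p in gf_parents]]
    p2_haps = haps[[fidx[p] for p in pop2_parents]]
    genos_gf, fam_gf_map, dos_gf, ped_gf = breed(
        fam_gf, gf_haps, gf_parents, base_rates, POP1GF, rng_breed
    )
    genos_hd, fam_hd_map, dos_hd, ped_hd = breed(
        fam_hd, hd_haps, hd_parent_ids, hd_rates, POP1HD, rng_breed
    )
    genos_p2, fam_p2_map, dos_p2, ped_p2 = breed(
        fam_p2, p2_haps, pop2_parents, base_rates, POP2GF, rng_breed
    )

    all_ids = genos_gf + genos_hd + genos_p2
    pops = [POP1GF] * len(genos_gf) + [POP1HD] * len(genos_hd) + [POP2GF] * len(genos_p2)
    dosages = np.vstack([dos_gf, dos_hd, dos_p2])
    genotypes = GenotypeMatrix(
        individual_ids=np.array(all_ids, dtype=object),
        marker_ids=marker_map.index.to_numpy(dtype=object),
        dosages=dosages,
        marker_map=marker_map,
        population=np.array(pops, dtype=object),
    )

    parents_seen = sorted(
        {r[1] for r in ped_gf + ped_hd + ped_p2} | {r[2] for r in ped_gf + ped_hd + ped_p2}
    )
    pedigree = pd.DataFrame(
        [(p, None, None) for p in parents_seen] + ped_gf + ped_hd + ped_p2,
        columns=["id", "sire", "dam"],
    )
    families = pd.Series({**fam_gf_map, **fam_hd_map, **fam_p2_map}, name="family_id")

    tbv = pd.DataFrame(
        (dosages - M0.mean(axis=0)) @ effects, index=all_ids, columns=list(TRAITS)
    )
    site_names_p2 = [f"S{k + 2}" for k in range(config.n_sites)]
    layout_p1 = _trial_layout(
        genos_gf + genos_hd, families, ["S1"], config.copies_per_clone, config.n_reps,
        config.n_sets, "set",
    )
    layout_p2 = _trial_layout(
        genos_p2, families, site_names_p2, config.copies_per_clone, config.n_reps,
        config.n_blocks, "blk",
    )
    phenotypes = pd.concat(
        [
            simulate_phenotypes(
                tbv.loc[genos_gf + genos_hd], layout_p1, config.h2_targets,
                {"nonadd": config.nonadd_ratio, "rep": config.rep_ratio, "set": config.set_ratio},
                config.site_sd, rng_pheno,
            ),
            simulate_phenotypes(
                tbv.loc[genos_p2], layout_p2, config.h2_targets,
                {"nonadd": config.nonadd_ratio, "rep": config.rep_ratio, "set": config.set_ratio},
                config.site_sd, rng_pheno,
            ),
        ],
        ignore_index=True,
    )

    labels = pd.Series(
        [1 if p == POP1HD else 0 for g, p in zip(all_ids, pops) if p in (POP1GF, POP1HD)],
        index=[g for g, p in zip(all_ids, pops) if p in (POP1GF, POP1HD)],
        name="breaker",
    )

    def pop_rg(ids):
        sub = tbv.loc[ids]
        return float(np.corrcoef(sub["DBH"], sub["WD"])[0, 1])

    realized = {
        "rg_dbh_wd": {
            POP1GF: pop_rg(genos_gf), POP1HD: pop_rg(genos_hd), POP2GF: pop_rg(genos_p2)
        },
        "designated_scaffolds": list(designated),
        "parents": {
            POP1GF: gf_parents, POP1HD: hd_parent_ids, POP2GF: pop2_parents,
            "growth_ebv": growth_by_id, "density_ebv": density_by_id,
        },
    }
    return SimulatedStudy(
        genotypes=genotypes,
        pedigree=pedigree,
        phenotypes=phenotypes,
        breaker_labels=labels,
        families=families,
        qtl_truth=truth,
        true_breeding_values=tbv,
        realized_params=realized,
        config=config,
    )


def random_mating_cohort(config: SimConfig, n: int, rng: np.random.Generator):
    """Unselected random-mating offspring cohort plus the trait effects used.

    Convenience for calibration studies: returns (dosages (n x m), marker_map,
    effects (m x t)) drawn from a fresh base population under ``config``.
    """
    haps, marker_map, slices, local_pos = simulate_founders(config, rng)
    M0 = haps.sum(axis=1).astype(float)
    effects, _, _ = _build_effects(config, marker_map, M0, rng)
    off = _random_mating_generation(
        haps, np.full(config.n_scaffolds, config.base_recomb_per_scaffold),
        slices, local_pos, config.scaffold_length_bp, rng, n_out=n,
    )
    return off.sum(axis=1).astype(float), marker_map, effects
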