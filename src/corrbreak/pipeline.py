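"""End-to-end analysis pipeline.

Runs the full study on a simulated (or user-supplied) data set: genotype QC,
relationship matrices, heterozygosity contrasts, LD structure and decay with
and without relatedness correction, multivariate REML fits per population,
G-matrix comparison, and genomic breaker classification.  Writes a JSON
summary and a human-readable report into the output directory.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import breakerpred, gcompare, kinship, ldtools, mtmm
from .genio import GenotypeMatrix, maf_filter, mean_impute
from .simdata import POP1GF, POP1HD, POP2GF, TRAITS, SimConfig, generate_study


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "results"
    maf_threshold: float = 0.01
    ld_alpha: float = 0.05
    ld_r2_threshold: float = 0.2
    het_reps: int = 100
    het_n_ind: int | None = None  # default: min(cohort sizes) // 2, at least 10
    n_skewers: int = 1000
    em_iterations: int = 5
    max_iterations: int = 500
    classify_percentile: float = 95.0
    analysis_seed: int = 1
    make_plots: bool = False
    skip_reml: bool = False  # LD/het/prediction only (faster)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    return obj


def _ld_block(g_breaker, g_other, kinv_b, kinv_o, config, summary):
    """LD decay and Jennrich comparison between breaker and non-breaker cohorts."""
    out = {}
    cmp_res = ldtools.compare_populations(
        g_breaker,
        g_other,
        kinv_a=kinv_b,
        kinv_b=kinv_o,
        alpha=config.ld_alpha,
    )
    out["jennrich"] = cmp_res["summary"]
    out["significant_scaffolds_uncorrected"] = ldtools.significant_scaffolds(
        cmp_res, "uncorrected"
    )
    if "corrected" in cmp_res["results"]:
        out["significant_scaffolds_corrected"] = ldtools.significant_scaffolds(
            cmp_res, "corrected"
        )

    decay = {}
    for name, g, kinv in (
        ("breaker", g_breaker, kinv_b),
        ("non_breaker", g_other, kinv_o),
    ):
        pairs, _ = ldtools.scaffold_ld(g)
        fit = ldtools.fit_hill_weir(pairs, n=g.n_individuals)
        dist = ldtools.decay_distance(
            fit, config.ld_r2_threshold, max_distance_bp=config.sim.scaffold_length_bp
        )
        decay[name] = {
            "beta_per_bp": fit.beta_per_bp,
            "n_pairs": fit.n_pairs,
            "mean_r2": float(pairs["r2"].mean()),
            "decay_distance_bp": dist,
        }
        if kinv is not None:
            pairs_c, _ = ldtools.scaffold_ld(g, kinv=kinv)
            decay[name]["mean_r2_corrected"] = float(pairs_c["r2_corrected"].mean())
    out["decay"] = decay
    summary["ld"] = out
    return cmp_res


def run(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the summary dict (also written to disk)."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.analysis_seed)
    summary: dict = {"config": {"seed": config.sim.seed, "analysis_seed": config.analysis_seed}}

    study = generate_study(config.sim)
    g_all, qc = maf_filter(study.genotypes, config.maf_threshold)
    g_all = mean_impute(g_all)
    summary["qc"] = qc.to_dict()
    summary["cohort_sizes"] = {
        tag: int((study.genotypes.population == tag).sum())
        for tag in (POP1GF, POP1HD, POP2GF)
    }

    # --- cohorts -----------------------------------------------------------
    pop1_ids = [i for i, p in zip(g_all.individual_ids, g_all.population) if p != POP2GF]
    g_pop1 = g_all.subset_individuals(pop1_ids)
    g_pop2 = g_all.by_population(POP2GF)
    g_breaker = g_all.by_population(POP1HD)
    g_other = g_all.by_population(POP1GF)
    labels = study.breaker_labels.loc[pop1_ids]
    summary["training_breaker_share"] = float(labels.mean())

    # --- relationships -----------------------------------------------------
    def cohort_g(g: GenotypeMatrix) -> kinship.RelationshipMatrix:
        # markers can be monomorphic within a cohort even after global QC
        poly, _ = maf_filter(g, 0.0)
        return kinship.vanraden_g(poly)

    G1 = cohort_g(g_pop1)
    G2 = cohort_g(g_pop2)
    kinv_b = kinship.blended_inverse(cohort_g(g_breaker))
    kinv_o = kinship.blended_inverse(cohort_g(g_other))
    coords, eigvals = kinship.pca(G1, k=2)
    summary["pca_top_eigvals"] = [float(v) for v in eigvals[:5]]

    # --- heterozygosity ----------------------------------------------------
    n_ind = config.het_n_ind
    if n_ind is None:
        n_ind = max(10, min(g_breaker.n_individuals, g_other.n_individuals) // 2)
    het_test = kinship.het_resample_test(
        g_breaker, g_other, n_ind=n_ind, reps=config.het_reps, rng=rng
    )
    summary["heterozygosity"] = {
        "breaker_mean_ho": kinship.heterozygosity(g_breaker).mean_ho,
        "non_breaker_mean_ho": kinship.heterozygosity(g_other).mean_ho,
        "resample_t": het_test.statistic,
        "resample_p": het_test.p_value,
        "n_ind_resampled": n_ind,
    }

    # --- LD ----------------------------------------------------------------
    cmp_res = _ld_block(g_breaker, g_other, kinv_b, kinv_o, config, summary)
    sig_scaffolds = summary["ld"]["significant_scaffolds_uncorrected"]
    if sig_scaffolds:
        sig_markers = [
            m
            for m, s in zip(g_all.marker_ids, g_all.marker_map["scaffold"])
            if s in set(sig_scaffolds)
        ]
        summary["heterozygosity"]["sig_region_breaker_ho"] = kinship.heterozygosity(
            g_breaker, marker_subset=sig_markers
        ).mean_ho
        summary["heterozygosity"]["sig_region_non_breaker_ho"] = kinship.heterozygosity(
            g_other, marker_subset=sig_markers
        ).mean_ho

    # --- multivariate REML per population ----------------------------------
    if not config.skip_reml:
        ph = mtmm.add_design_factors(study.phenotypes)
        traits = list(TRAITS)
        ph = mtmm.standardize_by_site(ph, traits)
        ph1 = ph[ph["genotype_id"].isin(pop1_ids)]
        ph2 = ph[ph["genotype_id"].isin(g_pop2.individual_ids)]

        fits = {}
        for name, data, spec in (
            ("pop1", ph1, mtmm.training_model(traits, G1)),
            ("pop2", ph2, mtmm.prediction_model(traits, G2)),
        ):
            vc = mtmm.reml_fit(
                spec,
                data,
                em_iterations=config.em_iterations,
                max_iterations=config.max_iterations,
            )
            gp = mtmm.genetic_params(vc)
            fits[name] = vc
            summary[f"reml_{name}"] = {
                "loglik": vc.loglik,
                "iterations": vc.iterations,
                "h2": {r.trait: {"est": r.h2, "se": r.se} for r in gp.h2.itertuples()},
                "rg": {
                    f"{r.trait_x}:{r.trait_y}": {"est": r.rg, "se": r.se}
                    for r in gp.rg.itertuples()
                },
            }

        # --- G-matrix comparison ------------------------------------------
        Sa1 = fits["pop1"].components["additive"]
        Sa2 = fits["pop2"].components["additive"]
        sk = gcompare.random_skewers(Sa1, Sa2, config.n_skewers, rng)
        srd_res = gcompare.srd(Sa1, Sa2, config.n_skewers, rng)
        summary["gcompare"] = {
            "krzanowski": gcompare.krzanowski(Sa1, Sa2),
            "random_skewers_mean": sk["mean"],
            "srd_trait_scores": dict(zip(traits, srd_res.trait_scores)),
            "srd_overall_mean": srd_res.overall_mean,
        }

    # --- breaker prediction -------------------------------------------------
    loo_ind = breakerpred.loo_predict(labels, G1, scheme="individual")
    loo_fam = breakerpred.loo_predict(
        labels, G1, families=study.families, scheme="family"
    )
    auc_ind = breakerpred.auc(loo_ind["label"], loo_ind["score"])
    auc_fam = breakerpred.auc(loo_fam["label"], loo_fam["score"])
    full_fit = breakerpred.fit_logistic_gblup(labels, G1)
    pop2_scores = breakerpred.predict(full_fit, kinship.vanraden_g(g_all), list(g_pop2.individual_ids))
    all_scores = pd.concat([full_fit.fitted, pop2_scores])
    classified = breakerpred.classify_percentile(all_scores, config.classify_percentile)
    pop2_flagged = classified.loc[list(g_pop2.individual_ids), "predicted_breaker"]
    summary["prediction"] = {
        "auc_loo_individual": auc_ind,
        "auc_loo_family": auc_fam,
        "sigma2_u": full_fit.sigma2_u,
        "n_pop2_flagged": int(pop2_flagged.sum()),
        "pop2_flagged_ids": list(pop2_flagged.index[pop2_flagged]),
        "percentile": config.classify_percentile,
    }

    summary["runtime_seconds"] = round(time.time() - t0, 2)

    (out_dir / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2))
    _write_report(out_dir / "report.md", summary)
    if config.make_plots:
        _plots(out_dir, coords, labels, study, g_breaker, g_other)
    return summary


def _write_report(path: Path, s: dict) -> None:
    lines = ["# Correlation-breaker analysis report", ""]
    lines += [
        f"Cohort sizes: {s['cohort_sizes']}",
        f"Markers retained after QC: {s['qc']['n_retained']} of {s['qc']['n_input']}",
        f"Training breaker share: {s['training_breaker_share']:.3f}",
        "",
        "## Heterozygosity",
        f"Mean observed heterozygosity — breakers {s['heterozygosity']['breaker_mean_ho']:.4f}, "
        f"non-breakers {s['heterozygosity']['non_breaker_mean_ho']:.4f} "
        f"(resampling t = {s['heterozygosity']['resample_t']:.2f}, "
        f"p = {s['heterozygosity']['resample_p']:.3g})",
    ]
    if "sig_region_breaker_ho" in s["heterozygosity"]:
        lines.append(
            f"Flagged-scaffold Ho — breakers {s['heterozygosity']['sig_region_breaker_ho']:.4f}, "
            f"non-breakers {s['heterozygosity']['sig_region_non_breaker_ho']:.4f}"
        )
    ld = s["ld"]
    lines += [
        "",
        "## Linkage disequilibrium",
        f"Jennrich fraction significant (uncorrected): "
        f"{ld['jennrich']['fraction_significant_uncorrected']:.3f}",
    ]
    if "fraction_significant_corrected" in ld["jennrich"]:
        lines.append(
            f"Jennrich fraction significant (corrected): "
            f"{ld['jennrich']['fraction_significant_corrected']:.3f}"
        )
    for name, d in ld["decay"].items():
        dist = d["decay_distance_bp"]
        dist_txt = f"{dist:.0f} bp" if dist is not None else "not reached"
        lines.append(
            f"{name}: mean r2 = {d['mean_r2']:.3f}, decay to threshold at {dist_txt}"
        )
    for pop in ("pop1", "pop2"):
        key = f"reml_{pop}"
        if key not in s:
            continue
        lines += ["", f"## Genetic parameters ({pop})"]
        for t, v in s[key]["h2"].items():
            lines.append(f"h2({t}) = {v['est']:.3f} (SE {v['se']:.3f})")
        for pair, v in s[key]["rg"].items():
            lines.append(f"rg({pair}) = {v['est']:.3f} (SE {v['se']:.3f})")
    if "gcompare" in s:
        lines += [
            "",
            "## G-matrix comparison",
            f"Krzanowski similarity: {s['gcompare']['krzanowski']:.3f}",
            f"Random skewers mean correlation: {s['gcompare']['random_skewers_mean']:.3f}",
            f"SRD overall mean: {s['gcompare']['srd_overall_mean']:.3f}",
        ]
    p = s["prediction"]
    lines += [
        "",
        "## Breaker prediction",
        f"AUC (leave-one-individual-out): {p['auc_loo_individual']:.3f}",
        f"AUC (leave-one-family-out): {p['auc_loo_family']:.3f}",
        f"Prediction-population genotypes flagged above the "
        f"{p['percentile']:.0f}th percentile: {p['n_pop2_flagged']}",
        "",
    ]
    path.write_text("\n".join(lines))


def _plots(out_dir: Path, coords, labels, study, g_breaker, g_other) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    is_b = np.array([labels.get(i, 0) == 1 for i in coords.index], dtype=bool)
    ax.scatter(coords["PC1"][~is_b], coords["PC2"][~is_b], s=12, label="non-breaker")
    ax.scatter(coords["PC1"][is_b], coords["PC2"][is_b], s=12, label="breaker")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "pca.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, g in (("breaker", g_breaker), ("non-breaker", g_other)):
        pairs, _ = ldtools.scaffold_ld(g)
        ax.scatter(pairs["distance_bp"], pairs["r2"], s=4, alpha=0.3, label=name)
    ax.set_xlabel("distance (bp)")
    ax.set_ylabel("r2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "ld_decay.png", dpi=120)
    plt.close(fig)
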