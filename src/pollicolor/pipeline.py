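"""End-to-end pipeline: ingest -> preprocess -> PCA -> visual models ->
color stats -> trait fits -> ancestral states -> threshold MCMC -> color
vectors -> PGLS, with one tidy output per stage and a run manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .colorstats import GroupedLoci, boot_group_distance, permutation_test, summaries_to_frame
from .errors import ConfigError
from .pca import phylomorphospace, standardized_pca
from .phylo import (
    anc_ml,
    color_vector,
    fit_continuous,
    fit_mk,
    pgls_corr,
    stochastic_map,
    threshold_mcmc,
)
from .spectra import aggregate, bin_matrix, read_spectra, smooth, trim
from .trees import read_newick
from .vision import (
    NoiseModel,
    achromatic_contrast,
    fly_locus,
    load_illuminant,
    load_receptor_set,
    maxwell_locus,
    quantum_catch,
)

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "spectra": None,          # long CSV path, or None with synthetic: true
    "tree": None,             # newick path
    "metadata": None,         # CSV with species, mode, zone
    "synthetic": False,
    "span": 0.25,
    "n_bins": 10,
    "trim": [300.0, 700.0],
    "viewers": ["hawkmoth", "blowfly", "hoverfly"],
    "hawkmoth_illuminant": "sunset",
    "fly_illuminant": "D65",
    "weber": 0.1,
    "n_boot": 200,
    "n_perm": 1000,
    "mcmc_generations": 20000,
    "mcmc_burn_in": None,
    "seed": 0,
    "out": "pollicolor_out",
}

STAGES = [
    "ingest",
    "preprocess",
    "pca",
    "vismodel",
    "colstats",
    "trait_fits",
    "ancestral",
    "threshold",
    "color_vectors",
    "pgls",
]


def validate_config(cfg: dict) -> dict:
    merged = {**DEFAULT_CONFIG, **(cfg or {})}
    unknown = set(merged) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if not merged["synthetic"]:
        for key in ("spectra", "tree", "metadata"):
            if merged[key] is None:
                raise ConfigError(f"config missing required path: {key}")
            if not Path(merged[key]).exists():
                raise ConfigError(f"configured {key} file does not exist: {merged[key]}")
    return merged


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(cfg: dict):
    from .simulate import default_scenario

    if cfg["synthetic"]:
        scen = default_scenario(seed=cfg["seed"])
        coll = type(scen.corollas)(scen.corollas.spectra + scen.leaves.spectra)
        return coll, scen.tree, scen.metadata()
    coll = read_spectra(cfg["spectra"], layout="long")
    tree = read_newick(cfg["tree"])
    meta = pd.read_csv(cfg["metadata"])
    return coll, tree, meta


def run_pipeline(cfg: dict) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    cfg = validate_config(cfg)
    outdir = Path(cfg["out"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: v for k, v in cfg.items()},
        "config_hash": _config_hash(cfg),
        "seed": cfg["seed"],
        "version": __version__,
        "stages": {},
    }
    stage = "startup"
    try:
        # 1. ingest ---------------------------------------------------------
        stage = "ingest"
        coll, tree, meta = _load_inputs(cfg)
        raw_path = outdir / "spectra_raw.csv"
        coll.write_csv(raw_path)
        manifest["stages"]["ingest"] = {"output": raw_path.name, "n_spectra": len(coll)}

        # 2. preprocess -----------------------------------------------------
        stage = "preprocess"
        lo, hi = cfg["trim"]
        proc = coll.map(lambda s: smooth(trim(s, lo, hi), span=cfg["span"]))
        by_ind = aggregate(proc, level="individual")
        corollas = by_ind.subset(tissue="corolla")
        leaf_mean = aggregate(proc.subset(tissue="leaf"), level="species")
        # one common background: mean over species-level leaf means
        bkg_values = np.mean([s.reflectance for s in leaf_mean], axis=0)
        background = leaf_mean.spectra[0].with_values(bkg_values)
        proc_path = outdir / "spectra_processed.csv"
        corollas.write_csv(proc_path)
        manifest["stages"]["preprocess"] = {
            "output": proc_path.name,
            "n_corolla": len(corollas),
            "n_leaf_species": len(leaf_mean),
        }

        # 3. PCA + phylomorphospace ----------------------------------------
        stage = "pca"
        binned = bin_matrix(corollas, n_bins=cfg["n_bins"], lo=lo, hi=hi)
        pca = standardized_pca(binned)
        sp_of_row = [idx.split("|")[0] for idx in binned.index]
        scores12 = pca.scores[["PC1", "PC2"]].copy()
        scores12["species"] = sp_of_row
        species_scores = scores12.groupby("species").mean()
        # phylomorphospace uses plain species labels (morph-free)
        species_scores.index = [s.split(":")[0] for s in species_scores.index]
        species_scores = species_scores.groupby(level=0).mean()
        pms = phylomorphospace(tree, species_scores)
        pca.scores.to_csv(outdir / "pca_scores.csv")
        pca.loadings.to_csv(outdir / "pca_loadings.csv")
        pms_rows = pd.concat([pms.tip_coords, pms.node_coords])
        pms_rows.to_csv(outdir / "phylomorphospace.csv")
        manifest["stages"]["pca"] = {
            "output": "pca_scores.csv",
            "explained_pc1_pc2": float(pca.cumulative_variance(2)),
        }

        # 4. visual models --------------------------------------------------
        stage = "vismodel"
        grid = corollas.wavelengths
        noise = NoiseModel(weber=cfg["weber"])
        loci_by_viewer: dict[str, list] = {}
        for viewer in cfg["viewers"]:
            recs = load_receptor_set(viewer, grid=grid)
            illum_name = (
                cfg["hawkmoth_illuminant"] if viewer == "hawkmoth" else cfg["fly_illuminant"]
            )
            illum = load_illuminant(illum_name)
            loci = [quantum_catch(s, recs, illum, background) for s in corollas]
            loci_by_viewer[viewer] = loci
            rows = []
            if viewer == "hawkmoth":
                noise = NoiseModel(weber=cfg["weber"], densities=recs.densities)
                bkg_locus = quantum_catch(background, recs, illum, background)
                for lc in loci:
                    xy = maxwell_locus(lc)
                    ach = achromatic_contrast(lc, bkg_locus, noise)
                    rows.append(
                        {
                            "sample": lc.label, "species": lc.species,
                            "x": xy[0], "y": xy[1],
                            **{f"q_{nm}": qv for nm, qv in zip(lc.receptor_names, lc.q)},
                            "achromatic_michelson": ach["value"],
                        }
                    )
            else:
                for lc in loci:
                    cat, uv = fly_locus(lc)
                    rows.append(
                        {
                            "sample": lc.label, "species": lc.species,
                            "u": uv[0], "v": uv[1], "category": cat,
                        }
                    )
            pd.DataFrame(rows).to_csv(outdir / f"loci_{viewer}.csv", index=False)
        manifest["stages"]["vismodel"] = {
            "output": [f"loci_{v}.csv" for v in cfg["viewers"]],
            "n_loci": {v: len(l) for v, l in loci_by_viewer.items()},
        }

        # 5. color stats ----------------------------------------------------
        stage = "colstats"
        mode_of = dict(zip(meta["species"].astype(str), meta["mode"].astype(str)))
        summaries = []
        for viewer, metric in (("hawkmoth", "rnl"), ("blowfly", "fly_euclid")):
            if viewer not in loci_by_viewer:
                continue
            loci = loci_by_viewer[viewer]
            g = GroupedLoci(
                loci,
                labels={
                    "species": [lc.species for lc in loci],
                    "mode": [mode_of.get(lc.species, "unknown") for lc in loci],
                },
            )
            perms = permutation_test(
                g, "mode", metric=metric, n_perm=cfg["n_perm"], seed=cfg["seed"], noise=noise
            )
            for pair in perms:
                boot = boot_group_distance(
                    g, pair, "mode", metric=metric, n_boot=cfg["n_boot"],
                    seed=cfg["seed"], noise=noise,
                )
                boot.p_value = perms[pair].p_value
                boot.n_perm = cfg["n_perm"]
                summaries.append(boot)
        colstats = summaries_to_frame(summaries)
        colstats.insert(0, "viewer", ["hawkmoth" if s.metric == "rnl" else "blowfly" for s in summaries])
        colstats.to_csv(outdir / "colstats.csv", index=False)
        manifest["stages"]["colstats"] = {"output": "colstats.csv", "n_pairs": len(summaries)}

        # 6. continuous & discrete trait fits ------------------------------
        stage = "trait_fits"
        pc1 = {sp: float(species_scores.loc[sp, "PC1"]) for sp in tree.tip_labels}
        cont_fits = {m: fit_continuous(tree, pc1, model=m) for m in ("BM", "OU", "EB")}
        best_cont = min(cont_fits.values(), key=lambda f: f.AICc)
        modes_by_tip = {sp: mode_of.get(sp, "unknown") for sp in tree.tip_labels}
        mk_fits = {m: fit_mk(tree, modes_by_tip, model=m) for m in ("ER", "SYM", "ARD")}
        best_mk = min(mk_fits.values(), key=lambda f: f.AIC)
        fit_rows = [
            {"trait": "PC1", "model": m, "logLik": f.logLik, "criterion": f.AICc,
             "sigma2": f.sigma2, "alpha": f.alpha, "r": f.r}
            for m, f in cont_fits.items()
        ] + [
            {"trait": "mode", "model": m, "logLik": f.logLik, "criterion": f.AIC,
             "sigma2": None, "alpha": None, "r": None}
            for m, f in mk_fits.items()
        ]
        pd.DataFrame(fit_rows).to_csv(outdir / "trait_fits.csv", index=False)
        manifest["stages"]["trait_fits"] = {
            "output": "trait_fits.csv",
            "best_continuous": best_cont.model,
            "best_mk": best_mk.model,
        }

        # 7. ancestral states + stochastic mapping -------------------------
        stage = "ancestral"
        anc = anc_ml(tree, pc1)
        anc_df = pd.DataFrame(
            {
                "node": tree.tip_labels + [f"node{i}" for i in range(tree.n_tips, tree.n_nodes)],
                "PC1": anc,
            }
        )
        anc_df.to_csv(outdir / "ancestral_pc1.csv", index=False)
        ens = stochastic_map(tree, modes_by_tip, mk_fits["ER"], n_maps=100, seed=cfg["seed"])
        post = pd.DataFrame(
            ens.node_posterior,
            columns=list(ens.states),
            index=anc_df["node"],
        )
        post.to_csv(outdir / "simmap_posterior.csv")
        manifest["stages"]["ancestral"] = {
            "output": ["ancestral_pc1.csv", "simmap_posterior.csv"],
            "n_maps": ens.n_maps,
        }

        # 8. threshold MCMC -------------------------------------------------
        stage = "threshold"
        zone_of = dict(zip(meta["species"].astype(str), meta["zone"].astype(int)))
        zones = {sp: zone_of[sp] for sp in tree.tip_labels}
        thr = threshold_mcmc(
            tree, zones, generations=cfg["mcmc_generations"],
            burn_in=cfg["mcmc_burn_in"], seed=cfg["seed"],
        )
        thr_df = pd.DataFrame(
            {
                "node": anc_df["node"],
                "liability_mean": thr.liability_mean,
                **{
                    f"P_zone{c}": thr.node_category_posterior[:, ci]
                    for ci, c in enumerate(thr.categories)
                },
            }
        )
        thr_df.to_csv(outdir / "threshold_posterior.csv", index=False)
        manifest["stages"]["threshold"] = {
            "output": "threshold_posterior.csv",
            "generations": thr.generations,
        }

        # 9. color vectors --------------------------------------------------
        stage = "color_vectors"
        vec_rows = []
        vectors = {}
        for viewer in ("hawkmoth", "blowfly"):
            if viewer not in loci_by_viewer:
                continue
            per_species: dict[str, list] = {}
            for lc in loci_by_viewer[viewer]:
                per_species.setdefault(lc.species, []).append(lc)
            # species-level locus: mean adapted catches
            sp_loci = []
            for sp in tree.tip_labels:
                group = per_species[sp]
                qbar = np.mean([lc.q for lc in group], axis=0)
                proto = group[0]
                sp_loci.append(
                    type(proto)(
                        viewer=proto.viewer, receptor_names=proto.receptor_names,
                        Q=qbar, q=qbar, r=qbar / qbar.sum(), species=sp, individual="mean",
                    )
                )
            vec = color_vector(sp_loci, viewer)
            vectors[viewer] = {lbl.split(":")[0].split("|")[0]: v for lbl, v in vec.items()}
            vec_rows.extend(
                {"viewer": viewer, "species": sp, "pc1": val}
                for sp, val in vectors[viewer].items()
            )
        pd.DataFrame(vec_rows).to_csv(outdir / "color_vectors.csv", index=False)
        manifest["stages"]["color_vectors"] = {"output": "color_vectors.csv"}

        # 10. PGLS ----------------------------------------------------------
        stage = "pgls"
        liab = {sp: thr.liability_mean[i] for i, sp in enumerate(tree.tip_labels)}
        pgls_rows = []
        for viewer, vec in vectors.items():
            for model in ("BM", "OU"):
                fit = pgls_corr(
                    tree,
                    {sp: liab[sp] for sp in tree.tip_labels},
                    {sp: vec[sp] for sp in tree.tip_labels},
                    model=model,
                )
                pgls_rows.append(
                    {
                        "viewer": viewer, "model": model, "r": fit.r,
                        "slope": fit.slope, "logLik": fit.logLik, "AIC": fit.AIC,
                        "p_value": fit.p_value, "alpha": fit.alpha,
                    }
                )
        pd.DataFrame(pgls_rows).to_csv(outdir / "pgls.csv", index=False)
        manifest["stages"]["pgls"] = {"output": "pgls.csv", "n_fits": len(pgls_rows)}
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}\nerror={exc!r}\n")
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
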