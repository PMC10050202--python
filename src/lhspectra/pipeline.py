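"""End-to-end pipeline: inputs -> imputation -> pPCA -> TPD -> scenarios -> surfaces.

Orchestrates one reproducible run.  Inputs are either real files (Newick
tree, trait CSV with empty cells for gaps, metadata CSV) or a synthetic
configuration; all stage seeds derive deterministically from the master
seed, and every stage writes plain-text artifacts (CSV/YAML) plus a
manifest into the run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import impute as imp
from . import ppca as pp
from . import scenarios as sc
from . import surface as sf
from . import synthetic as syn
from . import tpd
from .phylo import fit_lambda, kruskal_missingness_test, phylo_vcv, read_newick, write_newick

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "load_inputs"]

HIGH_RISK = ("CR", "EN")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``tree_path``/``traits_path``/``meta_path`` (all three)
    or ``sim`` must be supplied.
    """

    tree_path: str | None = None
    traits_path: str | None = None
    meta_path: str | None = None
    sim: syn.SimConfig | None = None

    n_imputations: int = 40
    maxit: int = 15
    donors: int = 5
    n_eigenvectors: int | None = None      # default: min(15, n/10)

    cells_per_dim: int = 200
    threshold_q: float = 0.99
    pad: float = 3.0

    n_null_iter: int = 999
    seed: int = 0
    out_dir: str = "run"

    def __post_init__(self):
        has_paths = all(p is not None for p in (self.tree_path, self.traits_path, self.meta_path))
        some_paths = any(p is not None for p in (self.tree_path, self.traits_path, self.meta_path))
        if self.sim is not None and some_paths:
            raise ValueError("supply either file paths or a synthetic config, not both")
        if self.sim is None and not has_paths:
            raise ValueError("supply tree/traits/meta paths or a synthetic config")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from the master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _normalise(label: str) -> str:
    return str(label).strip().replace(" ", "_")


def load_inputs(config: RunConfig):
    """Load or simulate (tree, traits, meta), with aligned species labels.

    Labels are matched exactly after underscore/space normalisation;
    a mismatch between tree and tables raises, listing the offenders.
    """
    if config.sim is not None:
        tree, traits, meta, _ = syn.simulate_dataset(config.sim)
    else:
        tree = read_newick(config.tree_path)
        traits = pd.read_csv(config.traits_path, index_col=0)
        meta = pd.read_csv(config.meta_path, index_col=0)
    for lf in tree.leaf_node_iter():
        lf.taxon.label = _normalise(lf.taxon.label)
    traits.index = [_normalise(s) for s in traits.index]
    meta.index = [_normalise(s) for s in meta.index]
    tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = sorted((set(traits.index) | set(meta.index)) - tips)
    if missing:
        raise ValueError(f"species absent from the tree: {missing[:20]}")
    order = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon.label in traits.index]
    return tree, traits.loc[order], meta.loc[order]


def _timed(name, fn, *args, **kwargs):
    t0 = time.perf_counter()
    out = fn(*args, **kwargs)
    logger.info("stage %-12s %.1fs", name, time.perf_counter() - t0)
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute every analysis stage and write all artifacts.

    Returns the run directory.  Identical configurations (including the
    master seed) reproduce every numeric artifact bit-identically.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()

    # ---- inputs -----------------------------------------------------------
    tree, traits, meta = _timed("inputs", load_inputs, config)
    cov = phylo_vcv(tree).reorder(list(traits.index))
    write_newick(tree, out / "tree.nwk")
    traits.to_csv(out / "traits.csv")
    meta.to_csv(out / "meta.csv")
    n = len(traits)

    # missingness association check
    miss_counts = traits[list(syn.FOCAL_TRAITS) + ["incubation"]].isna().sum(axis=1)
    status_group = np.where(
        meta["iucn"].isin(["DD"]), "DD",
        np.where(meta["iucn"].isin(sc.THREATENED), "threatened", "not_threatened"),
    )
    if miss_counts.sum() > 0 and len(np.unique(status_group)) > 1:
        H, p_kw, df_kw = kruskal_missingness_test(miss_counts.to_numpy(), status_group)
    else:
        H = p_kw = np.nan
        df_kw = 0

    # ---- per-trait phylogenetic signal (observed data) --------------------
    def _signal():
        rows = {}
        Z = imp.to_model_scale(traits[list(syn.FOCAL_TRAITS)])
        for t in syn.FOCAL_TRAITS:
            y = Z[t].dropna()
            if len(y) < 4:
                continue
            sub = cov.reorder(list(y.index))
            fit = fit_lambda(y.to_numpy(), sub)
            rows[t] = {"lambda": fit.lambda_hat, "se": fit.se}
        return rows
    signal = _timed("signal", _signal)

    # ---- imputation -------------------------------------------------------
    k = config.n_eigenvectors or imp.default_n_eigenvectors(n)
    eig = imp.phylo_eigenvectors(cov, k)
    iset = _timed(
        "imputation", imp.build_imputation_set, traits,
        covariates=eig, n_datasets=config.n_imputations,
        maxit=config.maxit, donors=config.donors,
        seed=stage_seed(config.seed, "imputation"),
    )
    imp_dir = out / "imputations"
    imp_dir.mkdir(exist_ok=True)
    for i, ds in enumerate(iset.datasets, 1):
        ds.to_csv(imp_dir / f"imputed_{i:02d}.csv")
    with open(imp_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"n_datasets": iset.n_datasets, "m": iset.m,
                        "maxit": iset.maxit, "seeds": list(iset.seeds)}, fh)
    diag = imp.imputation_diagnostics(iset, traits)
    diag.to_csv(out / "imputation_diagnostics.csv")

    # ---- pPCA x n_imputations + pooling -----------------------------------
    lambdas = {t: v["lambda"] for t, v in signal.items() if np.isfinite(v["lambda"])}

    def _ppca_all():
        results = []
        for ds in iset.datasets:
            X = pp.preprocess_traits(ds, cov, lambdas=lambdas)
            results.append(pp.ppca_fit(X, cov))
        return results
    results = _timed("ppca", _ppca_all)
    pooled, space = pp.pool_imputations(results)
    rotated = pp.varimax_kaiser(results[0])
    pooled.scores.to_csv(out / "ppca_scores.csv")
    pooled.loadings.to_csv(out / "ppca_loadings.csv")
    space.to_csv(out / "functional_space.csv")
    with open(out / "ppca.yaml", "w") as fh:
        yaml.safe_dump({
            "lambda_hat": float(pooled.lambda_hat),
            "var_explained": [float(v) for v in pooled.var_explained],
            "n_retained_kaiser": int(rotated.n_retained),
        }, fh)

    # ---- TPD --------------------------------------------------------------
    def _tpd():
        bw = tpd.select_bandwidth(space)
        grid = tpd.build_grid(space, bw, cells_per_dim=config.cells_per_dim, pad=config.pad)
        dens = tpd.tpd_density(space, bw, grid)
        thr = tpd.hdr_threshold(dens, config.threshold_q)
        return bw, grid, dens, thr
    bw, grid, dens, thr = _timed("tpd", _tpd)
    sp_frac, area_frac = tpd.hotspot_summary(thr, space, q=0.5)
    contours = tpd.quantile_contours(dens, tpd.CONTOUR_QS)
    cont_rows = [
        {"q": q, "n_cells": int(m.sum()), "area": float(m.sum() * dens.cell_area)}
        for q, m in zip(tpd.CONTOUR_QS, contours)
    ]
    pd.DataFrame(cont_rows).to_csv(out / "contours.csv", index=False)
    with open(out / "tpd.yaml", "w") as fh:
        yaml.safe_dump({
            "cells_per_dim": config.cells_per_dim,
            "threshold_q": config.threshold_q,
            "bandwidth": [[float(v) for v in row] for row in bw.H],
            "richness": float(tpd.richness(thr)),
            "hotspot_species_fraction": float(sp_frac),
            "hotspot_area_fraction": float(area_frac),
        }, fh)

    # ---- extinction scenarios ---------------------------------------------
    scen = _timed(
        "scenarios", sc.run_all_scenarios, space, meta,
        n_iter=config.n_null_iter, q=config.threshold_q,
        cells_per_dim=config.cells_per_dim,
        seed=stage_seed(config.seed, "scenarios"), bw=bw,
    )
    scen.to_csv(out / "scenarios.csv", index=False)
    sc.continent_threat_ratios(meta).to_csv(out / "continent_threats.csv")

    # ---- risk surfaces ----------------------------------------------------
    def _surfaces():
        rows = []
        assessed = meta.index[meta["iucn"] != "DD"]
        labels = meta.loc[assessed, "iucn"].isin(HIGH_RISK).astype(int)
        models = {"high_risk": (space.loc[assessed], labels)}
        threat_pool = meta.index[meta[list(syn.THREAT_NAMES)].notna().all(axis=1)]
        for t in syn.THREAT_NAMES:
            models[t] = (space.loc[threat_pool], meta.loc[threat_pool, t].astype(int))
        for name, (spc, lab) in models.items():
            if lab.nunique() < 2:
                logger.warning("surface %s skipped: single-class labels", name)
                continue
            model = sf.fit_binomial_surface(spc, lab.to_numpy())
            pred = sf.predict_surface(model, grid)
            pred.to_csv(out / f"surface_{name}.csv", index=False)
            rows.append({"model": name, "edf": model.edf, "chi2": model.chi2,
                         "p_value": model.p_value})
        return pd.DataFrame(rows)
    surfaces = _timed("surfaces", _surfaces)
    surfaces.to_csv(out / "surface_tests.csv", index=False)

    # ---- manifest ---------------------------------------------------------
    cfg = asdict(config)
    if config.sim is not None:
        cfg["sim"] = asdict(config.sim)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_species": int(n),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in ("imputation", "scenarios")},
        "missingness_test": {"H": float(H) if np.isfinite(H) else None,
                             "p": float(p_kw) if np.isfinite(p_kw) else None,
                             "df": int(df_kw)},
        "phylo_signal": {t: {k2: float(v2) for k2, v2 in v.items()} for t, v in signal.items()},
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
        "elapsed_s": round(time.perf_counter() - t_start, 2),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    logger.info("pipeline finished in %.1fs", time.perf_counter() - t_start)
    return out
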