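"""End-to-end orchestration: filter → responses → signal suite → PMC → PGLS.

One :class:`RunConfig` drives the whole analysis of one major taxon.  Every
stochastic stage draws from a named substream of the master seed, so reruns
with the same config are byte-identical.  Per-family and per-variable
failures are isolated and reported in the result bundle rather than
aborting the run.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import alpha, beta, cooccur, data_model, evomodels, phylo, signal

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis", "prune_to_families"]

# which response variables carry an SE (weighting / Cohen's d applies)
SE_VARIABLES = {
    "peak": "peak_se",
    "slope_xy": "se_xy",
    "slope_z": "se_z",
    "slope_hab": "se_hab",
}
RAW_VARIABLES = ["edf_raw", "edf_corrected", "r2_xy", "r2_z", "r2_hab"]


@dataclass
class RunConfig:
    matrix_path: str
    taxonomy_path: str
    metadata_path: str
    tree_path: str  # newick, tips = families (superset allowed)
    traits_path: str | None = None
    outdir: str = "results"
    min_plots: int = 50
    min_species: int = 5
    alpha: float = 0.05
    n_perm_mrm: int = 999
    n_perm_signal: int = 1000
    n_sim_pmc: int = 1000
    seed: int = 0
    signal_variables: list[str] | None = None  # override PGLS variable choice

    def validate(self) -> None:
        for name in ("min_plots", "min_species", "n_perm_mrm", "n_perm_signal", "n_sim_pmc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.seed is None:
            raise ValueError("a master seed is mandatory")


def prune_to_families(tree, families: list[str]):
    """Restrict an ultrametric tree to a family subset.

    The pruned tree is rebuilt by UPGMA on the sub-patristic matrix, which
    reproduces the induced subtree exactly when the input is ultrametric.
    """
    pat = phylo.patristic_matrix(tree)
    keep = [f for f in families if f in pat.index]
    return phylo.upgma(pat.loc[keep, keep])


def run_full_analysis(config: RunConfig) -> dict:
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ["mrm", "k", "d", "pmc", "distreg"],
            np.random.SeedSequence(config.seed).spawn(5),
        )
    }
    bundle: dict = {"config": {k: v for k, v in asdict(config).items()}, "errors": {}}

    occ, meta = data_model.read_occurrence(
        config.matrix_path, config.taxonomy_path, config.metadata_path
    )
    tree = phylo.read_newick(config.tree_path)
    retained, flags = data_model.filter_families(occ, config.min_plots, config.min_species)
    features = data_model.higher_level_features(occ, retained)
    bundle["filter"] = flags.reset_index().to_dict(orient="records")
    if not retained:
        bundle["status"] = "no families retained"
        _write_bundle(bundle, config.outdir)
        return bundle

    # representativeness: are the retained (widespread) families phylogenetically
    # clustered with respect to the full family pool on the tree?
    tip_set = set(phylo.tip_labels(tree))
    pool = [f for f in flags.index if f in tip_set]
    widespread = {f: int(f in retained) for f in pool}
    try:
        if 0 < sum(widespread.values()) < len(pool):
            pool_tree = prune_to_families(tree, pool)
            dres = signal.d_statistic(
                widespread, pool_tree, n_perm=config.n_perm_signal, seed=streams["d"]
            )
            bundle["representativeness"] = dict(
                D=dres.d, p_random=dres.p_random, p_brownian=dres.p_brownian
            )
        else:
            bundle["representativeness"] = None
    except ValueError as exc:
        bundle["errors"]["representativeness"] = str(exc)

    analysis_fams = [f for f in retained if f in tip_set]
    fam_tree = prune_to_families(tree, analysis_fams)
    patristic = phylo.patristic_matrix(fam_tree)

    # ---- per-family diversity responses ---------------------------------
    rows = []
    for fam in analysis_fams:
        row: dict = {"family": fam}
        try:
            tab = alpha.family_presence_sites(occ, meta, fam)
            coords = alpha.screen_coordinates(
                tab["richness"], tab["x"], tab["y"], config.alpha
            )
            fit = alpha.fit_richness_gam(
                tab["richness"].to_numpy(), tab["elevation"].to_numpy(), coords
            )
            pk = alpha.estimate_peak(
                tab["richness"].to_numpy(), tab["elevation"].to_numpy(), coords
            )
            row.update(
                edf_raw=fit.edf,
                edf_corrected=alpha.corrected_edf(fit, config.alpha),
                smooth_p=fit.p_smooth,
                peak=pk.peak,
                peak_se=pk.se,
                peak_model=pk.model,
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            bundle["errors"][f"alpha:{fam}"] = str(exc)
        try:
            row.update(
                beta.turnover_responses(
                    occ,
                    meta,
                    fam,
                    n_perm=config.n_perm_mrm,
                    seed=int(streams["mrm"].integers(2**31)),
                    alpha=config.alpha,
                )
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            bundle["errors"][f"beta:{fam}"] = str(exc)
        rows.append(row)
    responses = pd.DataFrame(rows).set_index("family")
    responses.to_csv(os.path.join(config.outdir, "responses.csv"))
    bundle["responses"] = json.loads(responses.to_json(orient="index"))

    # ---- phylogenetic signal suite --------------------------------------
    sig_rows = []
    pmc_out = {}
    for var in list(SE_VARIABLES) + RAW_VARIABLES:
        if var not in responses.columns:
            continue
        vals = responses[var].dropna()
        fams = [f for f in vals.index]
        if len(fams) < 4 or np.ptp(vals.to_numpy()) == 0:
            continue
        se_col = SE_VARIABLES.get(var)
        ses = responses.loc[fams, se_col] if se_col else None
        sub_tree = prune_to_families(fam_tree, fams)
        entry = {"variable": var}
        try:
            kr = signal.blomberg_k(
                dict(vals), sub_tree,
                se=None if ses is None else dict(ses),
                n_perm=config.n_perm_signal, seed=streams["k"],
            )
            entry.update(K=kr.k, K_p=kr.p, K_used_se=kr.used_se)
        except (ValueError, np.linalg.LinAlgError) as exc:
            bundle["errors"][f"K:{var}"] = str(exc)
        try:
            kind = "cohens_d" if se_col else "raw_difference"
            eff = signal.effect_size_matrix(
                dict(vals), se=None if ses is None else dict(ses),
                kind=kind, labels=fams,
            )
            dr = signal.signal_distance_regression(
                eff, patristic.loc[fams, fams],
                n_perm=config.n_perm_mrm, seed=streams["distreg"], kind=kind,
            )
            entry.update(dist_slope=dr.slope, dist_r2=dr.r2, dist_p=dr.p, dist_kind=kind)
        except (ValueError, np.linalg.LinAlgError) as exc:
            bundle["errors"][f"distreg:{var}"] = str(exc)
        try:
            pr = evomodels.pmc_power(
                dict(vals), sub_tree,
                se=None if ses is None else dict(ses),
                n_sim=config.n_sim_pmc, seed=streams["pmc"],
            )
            pmc_out[var] = pr.summary()
        except (ValueError, np.linalg.LinAlgError) as exc:
            bundle["errors"][f"pmc:{var}"] = str(exc)
        sig_rows.append(entry)
    sig_tab = pd.DataFrame(sig_rows).set_index("variable") if sig_rows else pd.DataFrame()
    if len(sig_tab):
        sig_tab.to_csv(os.path.join(config.outdir, "signal.csv"))
        bundle["signal"] = json.loads(sig_tab.to_json(orient="index"))
    bundle["pmc"] = pmc_out

    # ---- co-existence ----------------------------------------------------
    try:
        cs = cooccur.family_cscore_matrix(occ, analysis_fams)
        csr = signal.signal_distance_regression(
            cs, patristic.loc[analysis_fams, analysis_fams],
            n_perm=config.n_perm_mrm, seed=streams["distreg"], kind="raw_difference",
        )
        cs.to_csv(os.path.join(config.outdir, "cscore.csv"))
        bundle["cscore_regression"] = dict(slope=csr.slope, r2=csr.r2, p=csr.p)
    except (ValueError, np.linalg.LinAlgError) as exc:
        bundle["errors"]["cscore"] = str(exc)

    # ---- PGLS on signal-bearing variables --------------------------------
    if config.traits_path is not None and len(sig_tab):
        from . import pgls as pgls_mod

        traits = pd.read_csv(config.traits_path, index_col=0)
        if config.signal_variables is not None:
            chosen = config.signal_variables
        else:
            chosen = [
                v
                for v in sig_tab.index
                if sig_tab.loc[v].get("K_p", 1) < config.alpha
                and sig_tab.loc[v].get("dist_p", 1) < config.alpha
            ]
        tables = {}
        for var in chosen:
            y = responses[var].dropna()
            fams = [f for f in y.index if f in traits.index]
            if len(fams) < 5:
                continue
            se_col = SE_VARIABLES.get(var)
            w = responses.loc[fams, se_col] ** 2 if se_col else None
            try:
                tab = pgls_mod.model_selection(
                    y.loc[fams],
                    traits.loc[fams],
                    tree=prune_to_families(fam_tree, fams),
                    weights=w,
                )
                tab.to_csv(os.path.join(config.outdir, f"pgls_{var}.csv"), index=False)
                tables[var] = json.loads(tab.to_json(orient="records"))
            except (ValueError, np.linalg.LinAlgError) as exc:
                bundle["errors"][f"pgls:{var}"] = str(exc)
        bundle["pgls"] = tables

    bundle["status"] = "ok"
    _write_bundle(bundle, config.outdir)
    return bundle


def _write_bundle(bundle: dict, outdir: str) -> None:
    with open(os.path.join(outdir, "results.json"), "w") as fh:
        json.dump(bundle, fh, indent=1, sort_keys=True, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
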