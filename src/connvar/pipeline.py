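"""End-to-end orchestration of the synthetic connectome study.

Stages run in dependency order — synthetic data, preprocessing, cohort
splitting/matching, kernel ridge prediction with Haufe patterns,
morphometric similarity with regional models, spin-test spatial statistics,
mediation, and PLS transcriptomics — each writing plain-text artifacts to
the output directory and an entry (output hashes, seed, timing) into a JSON
manifest. A single master seed is fanned out to stages through a documented
counter scheme (stage index appended to the seed sequence), so stages are
reproducible independently of each other.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import io as io_mod
from . import mediation as med_mod
from . import msn as msn_mod
from . import predict as pred_mod
from . import preprocess as prep_mod
from . import regional_models as reg_mod
from . import spatial as spat_mod
from . import synthdata as synth_mod
from . import transcriptome as tx_mod

__all__ = ["default_config", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed or a required upstream stage was toggled off."""


def default_config() -> dict[str, Any]:
    """Demo-scale configuration: end-to-end in minutes on one CPU."""
    return {
        "seed": 0,
        "outdir": "connvar_out",
        "synth": {
            "n_group_a": 24,
            "n_group_b": 96,
            "n_parcels": 60,
            "n_networks": 7,
            "n_runs": 2,
            "frames_per_run": 150,
        },
        "stages": {
            "predict": True,
            "msn": True,
            "spatial": True,
            "mediation": True,
            "pls": True,
        },
        "predict": {"n_replicates": 3, "n_perm": 49, "n_folds": 5},
        "mediation": {"factor": "education", "n_boot": 200},
        "pls": {"n_perm": 99, "n_boot": 100, "n_donors": 3, "donor_noise": 2.0},
        "save_timeseries": False,
    }


def _load_config(config) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    merged = default_config()
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key] = {**merged[key], **val}
        else:
            merged[key] = val
    return merged


def _stage_seed(master: int, index: int) -> int:
    return int(np.random.default_rng([master & 0x7FFFFFFF, index]).integers(2**31))


def run_pipeline(config: dict[str, Any] | str | Path) -> dict[str, Any]:
    """Run the configured stages; return the output manifest."""
    cfg = _load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])
    stages = cfg["stages"]
    manifest: dict[str, Any] = {"seed": master, "stages": {}}
    state: dict[str, Any] = {}

    def record(stage: str, t0: float, files: list[Path], **info) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "seed": _stage_seed(master, len(manifest["stages"])),
            "outputs": {str(f.name): io_mod.sha256_of(f) for f in files},
            **info,
        }

    def require(stage: str) -> None:
        if stage not in manifest["stages"]:
            raise PipelineError(f"stage requires {stage!r}, which did not run")

    try:
        # --- synthetic data -------------------------------------------------
        t0 = time.time()
        scfg = synth_mod.SynthConfig(**cfg["synth"], seed=master)
        geometry = synth_mod.make_geometry(scfg)
        cohort = synth_mod.generate_cohort(scfg)
        ts = synth_mod.generate_timeseries(cohort, geometry, scfg)
        delta, regional_effect = synth_mod.planted_connectivity_effect(geometry, scfg)
        files = [
            io_mod.write_table(cohort, outdir / "cohort.tsv"),
            io_mod.write_table(geometry.to_frame(), outdir / "geometry.tsv"),
            io_mod.write_provenance(outdir / "synth.provenance.json", master,
                                    config=cfg["synth"]),
        ]
        if cfg.get("save_timeseries"):
            for sid, runs in ts.items():
                files += io_mod.write_runs(runs, sid, outdir / "timeseries")
        state.update(geometry=geometry, cohort=cohort, scfg=scfg,
                     planted_edgewise=delta, planted_regional=regional_effect)
        record("synthdata", t0, files, n_subjects=len(cohort))

        # --- preprocessing: censor, GSR, RSFC, gradients --------------------
        t0 = time.time()
        conns, gradients, kept = [], [], []
        reference = None
        for sid, runs in ts.items():
            clean = []
            for run in runs:
                mask, valid = prep_mod.censor_frames(run.rms)
                if not valid:
                    continue
                run.censored = mask
                clean.append(prep_mod.regress_global_signal(run))
            if not clean:
                continue
            conn = prep_mod.compute_rsfc(clean)
            grad = prep_mod.principal_gradient(conn, reference=reference)
            if reference is None:
                reference = grad.values
            conns.append(conn.values)
            gradients.append(grad.values)
            kept.append(sid)
        cohort = cohort[cohort["subject_id"].isin(kept)].reset_index(drop=True)
        conn_stack = np.stack(conns)
        grad_stack = np.stack(gradients)
        features = np.stack([pred_mod.vectorize_conn(c) for c in conn_stack])
        group_diff = (
            conn_stack[cohort["group"].to_numpy() == 1].mean(axis=0)
            - conn_stack[cohort["group"].to_numpy() == 0].mean(axis=0)
        )
        files = [io_mod.write_matrix(group_diff, outdir / "group_mean_rsfc_diff.tsv")]
        state.update(cohort=cohort, features=features, conn_stack=conn_stack,
                     gradients=grad_stack)
        record("preprocess", t0, files, n_valid_subjects=len(kept))

        # --- prediction -----------------------------------------------------
        if stages.get("predict"):
            t0 = time.time()
            pcfg = cfg["predict"]
            id_to_row = {sid: i for i, sid in enumerate(cohort["subject_id"])}
            cov_cols = ["age", "sex", "rms", "icv", "education", "income"]
            cov = cohort[cov_cols].to_numpy(dtype=float)
            y = np.where(cohort["group"].to_numpy() == 1, 1.0, -1.0)
            accs, haufe_total, n_haufe = [], 0.0, 0
            first_engine, first_y, first_pairs = None, None, None
            for rep in range(pcfg["n_replicates"]):
                pairs, folds = cohort_mod.matched_classification_split(
                    cohort, pcfg["n_folds"], seed=_stage_seed(master, 100 + rep)
                )
                rows = np.array([id_to_row[s] for s in folds.index])
                engine = pred_mod.CVEngine(
                    features[rows], cov[rows], folds.to_numpy(), inner_seed=rep
                )
                res = engine.run(y[rows], pred_mod.DEFAULT_LAMBDA_GRID,
                                 "classification")
                accs.append(res.accuracy)
                for train, yhat in res.train_artifacts:
                    haufe_total = haufe_total + pred_mod.haufe_weights(
                        features[rows][train], yhat)
                    n_haufe += 1
                if rep == 0:
                    local = {r: i for i, r in enumerate(rows)}
                    first_engine, first_y = engine, y[rows]
                    first_pairs = [(local[id_to_row[a]], local[id_to_row[b]])
                                   for a, b in pairs.pairs]
            perm_p, _ = pred_mod.permutation_null(
                [first_engine], first_y, float(np.mean(accs)),
                task="classification", n_perm=pcfg["n_perm"],
                seed=_stage_seed(master, 200), pairs=first_pairs,
            )
            edgewise = pred_mod.devectorize_conn(
                haufe_total / n_haufe, state["geometry"].n_parcels)
            network_level, regional = pred_mod.aggregate_weights(
                edgewise, state["geometry"].network)
            files = [
                io_mod.write_matrix(edgewise, outdir / "haufe_edgewise.tsv"),
                io_mod.write_matrix(network_level, outdir / "haufe_network.tsv"),
                io_mod.write_table(
                    pd.DataFrame({"parcel_id": state["geometry"].parcel_id,
                                  "haufe_regional": regional}),
                    outdir / "haufe_regional.tsv"),
                io_mod.write_table(
                    pd.DataFrame({"replicate": np.arange(len(accs)),
                                  "accuracy": accs}),
                    outdir / "prediction_accuracy.tsv"),
            ]
            state.update(haufe_regional=regional, haufe_edgewise=edgewise)
            record("predict", t0, files,
                   mean_accuracy=float(np.mean(accs)), permutation_p=perm_p)

        # --- morphometric similarity + regional models ----------------------
        if stages.get("msn"):
            t0 = time.time()
            morph = synth_mod.generate_morphometry(cohort, state["geometry"],
                                                   state["scfg"])
            regional_maps = np.stack([
                msn_mod.regional_msn(msn_mod.build_msn(morph[sid]))
                for sid in cohort["subject_id"]
            ])
            design = reg_mod.build_design(cohort)
            weights = reg_mod.group_size_weights(cohort["group"].to_numpy())
            result = reg_mod.weighted_lrm(regional_maps, design, weights, "group")
            files = [io_mod.write_table(
                result.to_frame().assign(parcel_id=state["geometry"].parcel_id),
                outdir / "msn_group_tmap.tsv")]
            state.update(msn_tmap=result.t, msn_regional=regional_maps)
            record("msn", t0, files,
                   n_significant=int(result.significant.sum()))

        # --- spatial statistics ---------------------------------------------
        if stages.get("spatial"):
            require("predict")
            t0 = time.time()
            spins = spat_mod.spin_permutations(
                state["geometry"], cfg["pls"]["n_perm"],
                seed=_stage_seed(master, 300))
            spin_haufe = spat_mod.spin_test(
                state["haufe_regional"], state["planted_regional"],
                state["geometry"], permutations=spins)
            info = {"haufe_vs_planted_r": spin_haufe.observed_r,
                    "haufe_vs_planted_spin_p": spin_haufe.p}
            if "msn_tmap" in state:
                spin_msn = spat_mod.spin_test(
                    state["msn_tmap"], state["haufe_regional"],
                    state["geometry"], permutations=spins)
                info.update(msn_vs_haufe_r=spin_msn.observed_r,
                            msn_vs_haufe_spin_p=spin_msn.p)
            files = [io_mod.write_provenance(
                outdir / "spatial_stats.json", master, **info)]
            record("spatial", t0, files, **info)

        # --- mediation ------------------------------------------------------
        if stages.get("mediation"):
            t0 = time.time()
            mcfg = cfg["mediation"]
            factor = cohort[mcfg["factor"]].to_numpy(dtype=float)
            composite, selected = med_mod.brain_composite(
                state["gradients"], factor)
            model = med_mod.fit_path_model(
                cohort["group"].to_numpy(dtype=float), factor, composite,
                cohort[["age", "sex", "rms", "icv"]],
                n_boot=mcfg["n_boot"], seed=_stage_seed(master, 400))
            table = pd.DataFrame({
                "path": ["a", "b", "c_prime", "c_total", "indirect"],
                "estimate": [model.a, model.b, model.c_prime, model.c_total,
                             model.indirect],
                "boot_se": [model.boot_se[k] for k in
                            ("a", "b", "c_prime", "c_total", "indirect")],
            })
            files = [io_mod.write_table(table, outdir / "mediation_paths.tsv")]
            record("mediation", t0, files, indirect=model.indirect,
                   ci=list(model.ci_indirect),
                   significant=bool(model.significant_indirect))

        # --- transcriptomics -------------------------------------------------
        if stages.get("pls"):
            require("predict")
            t0 = time.time()
            xcfg = cfg["pls"]
            expr_res = synth_mod.generate_expression(
                state["geometry"], state["planted_regional"], state["scfg"],
                n_donors=xcfg["n_donors"], donor_noise=xcfg["donor_noise"])
            ds, retained = tx_mod.differential_stability(expr_res.by_donor)
            expr = expr_res.expression[retained]
            response = state["haufe_regional"]
            res = tx_mod.bootstrap_gene_z(
                expr, response, n_boot=xcfg["n_boot"],
                seed=_stage_seed(master, 500))
            p_spin = tx_mod.pls_significance(
                expr, response, state["geometry"], n_perm=xcfg["n_perm"],
                seed=_stage_seed(master, 501))
            gene_table = pd.DataFrame({
                "gene": res.gene_weights.index,
                "weight": res.gene_weights.to_numpy(),
                "boot_se": res.gene_se.to_numpy(),
                "Z": res.gene_z.to_numpy(),
            }).sort_values("Z", ascending=False)
            files = [io_mod.write_table(gene_table, outdir / "pls1_genes.tsv")]
            record("pls", t0, files,
                   variance_explained=res.variance_explained,
                   permutation_p=p_spin, n_retained=len(retained),
                   n_pos=len(res.pls1_pos), n_neg=len(res.pls1_neg))
    except PipelineError:
        raise
    except Exception as exc:
        stage = len(manifest["stages"])
        raise PipelineError(f"pipeline aborted after stage {stage}: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
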