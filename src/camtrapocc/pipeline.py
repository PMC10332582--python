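"""Config-driven end-to-end runs: histories -> covariate prep -> p-first
single-species selection -> GOF -> spatial diagnostics -> co-occurrence.

The run is a pure function of (config, seeds): reruns with the same config
are draw-identical, and every output file is listed in a manifest with its
SHA-256 hash so reruns can be verified.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cooccurrence import CoOccData, bootstrap_interaction_factors, enumerate_variants, fit_cooc
from .covariates import build_design, correlation_screen, pca_landscape, zscore
from .selection import aicc_table, gof_bootstrap, gof_posterior_predictive, p_first_selection
from .spatial import distance_correlogram, distance_matrix, inverse_distance_weights, morans_i, occupancy_residuals
from .survey import build_history, filter_independent, pool_guild, read_records, read_stations, summarize_survey

log = logging.getLogger(__name__)

REQUIRED_KEYS = ["records", "stations", "out_dir", "focal_species", "seed"]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serializable: {type(o)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def run_pipeline(config: dict) -> dict:
    """Run the full workflow; returns the manifest dict."""
    for key in REQUIRED_KEYS:
        if key not in config:
            raise KeyError(f"missing config key: {key!r}")
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stage = "ingest"
    outputs: list[Path] = []
    run_log = {"version": __version__, "seed": seed, "stages": []}

    try:
        stations = read_stations(config["stations"])
        records = read_records(config["records"], stations)
        if config.get("guild_map"):
            records = pool_guild(records, dict(config["guild_map"]))
        records = filter_independent(records)
        focal = config["focal_species"]
        pair_species = {a for a, _ in config.get("cooc_pairs", [])} | {
            b for _, b in config.get("cooc_pairs", [])}
        histories = {}
        for sp in sorted({focal} | pair_species):
            histories[sp] = build_history(records, stations, sp,
                                          occasion_days=config.get("occasion_days", 7))
            hp, ep = out / f"history_{sp}.csv", out / f"effort_{sp}.csv"
            histories[sp].to_csv(hp, ep)
            outputs += [hp, ep]
        summary = summarize_survey(histories, stations, records)
        summary.blocks.to_csv(out / "survey_blocks.csv", index=False)
        summary.detections.to_csv(out / "survey_detections.csv", index=False)
        outputs += [out / "survey_blocks.csv", out / "survey_detections.csv"]
        run_log["stages"].append("ingest")

        stage = "covariates"
        if config.get("covariates"):
            table = pd.read_csv(config["covariates"], dtype={"station_id": str})
            table = table.set_index("station_id").loc[
                histories[focal].station_ids].reset_index()
        else:
            table = stations[["station_id", "pir_delay_class", "block_id"]].copy()
        zcols = config.get("zscore_columns") or [
            c for c in table.columns
            if c != "station_id" and pd.api.types.is_numeric_dtype(table[c])]
        if zcols:
            table = zscore(table, zcols)
            screen = correlation_screen(table, columns=zcols)
            screen.to_csv(out / "correlation_screen.csv", index=False)
            outputs.append(out / "correlation_screen.csv")
        if config.get("pca_columns"):
            pca = pca_landscape(table, config["pca_columns"])
            pd.DataFrame({"eigenvalue": pca.eigenvalues}).to_csv(
                out / "pca_eigenvalues.csv", index=False)
            pd.DataFrame(pca.loadings, index=pca.metric_names).to_csv(
                out / "pca_loadings.csv")
            table["LS"] = pca.scores_all[:, 0]
            outputs += [out / "pca_eigenvalues.csv", out / "pca_loadings.csv"]
        table.to_csv(out / "covariates_prepared.csv", index=False)
        outputs.append(out / "covariates_prepared.csv")
        run_log["stages"].append("covariates")

        stage = "selection"
        engine = config.get("engine", "ml")
        mcmc = config.get("mcmc", {})
        sel = p_first_selection(histories[focal], table,
                                config.get("p_candidates", []),
                                config.get("psi_candidates", []),
                                engine=engine, seed=seed, **mcmc)
        sel.stage1.to_csv(out / "selection_stage1.csv", index=False)
        sel.stage2.to_csv(out / "selection_stage2.csv", index=False)
        _write_json(out / "final_fit.json", sel.final_fit.to_report())
        outputs += [out / "selection_stage1.csv", out / "selection_stage2.csv",
                    out / "final_fit.json"]
        run_log["stages"].append("selection")

        stage = "gof"
        gof_cfg = config.get("gof", {})
        if engine == "ml":
            gof = gof_bootstrap(sel.final_fit,
                                n_sims=gof_cfg.get("n_sims", 200), seed=seed)
        else:
            gof = gof_posterior_predictive(sel.final_fit,
                                           n_draws_used=gof_cfg.get("n_draws", 200),
                                           seed=seed)
        _write_json(out / "gof.json", gof.to_report())
        outputs.append(out / "gof.json")
        run_log["stages"].append("gof")

        stage = "spatial"
        resid = occupancy_residuals(sel.final_fit)
        st = stations.set_index("station_id").loc[histories[focal].station_ids]
        coords = st[["x", "y"]].to_numpy(dtype=float)
        csys = st["coord_system"].iloc[0]
        dist = distance_matrix(coords[:, 0], coords[:, 1], csys)
        moran = morans_i(resid, inverse_distance_weights(dist))
        _write_json(out / "moran.json", moran.__dict__)
        cgram = distance_correlogram(resid, coords, csys,
                                     n_perms=config.get("n_perms", 199), seed=seed)
        cgram.to_frame().to_csv(out / "correlogram.csv", index=False)
        outputs += [out / "moran.json", out / "correlogram.csv"]
        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            fig, ax = plt.subplots(figsize=(6, 4))
            ax.fill_between(cgram.bin_centers, cgram.env_lo, cgram.env_hi,
                            alpha=0.3, label="95% permutation envelope")
            ax.plot(cgram.bin_centers, cgram.I, "o-", label="Moran's I")
            ax.axhline(0, color="k", lw=0.5)
            ax.set_xlabel("distance (m)")
            ax.set_ylabel("Moran's I")
            ax.legend()
            fig.savefig(out / "correlogram.png", dpi=120)
            plt.close(fig)
            outputs.append(out / "correlogram.png")
        except Exception as exc:   # plotting must not kill an analysis run
            log.warning("correlogram plot failed: %s", exc)
        run_log["stages"].append("spatial")

        stage = "cooccurrence"
        if config.get("cooc_pairs"):
            cooc_rows = []
            for a_label, b_label in config["cooc_pairs"]:
                data = CoOccData(histories[a_label], histories[b_label])
                fits = [fit_cooc(data, s) for s in enumerate_variants()]
                tab = aicc_table(fits)
                tab.insert(0, "pair", f"{a_label}|{b_label}")
                cooc_rows.append(tab)
                best = max(fits, key=lambda f: -f.aicc)
                report = best.to_report()
                if config.get("cooc_bootstrap", 0):
                    report["interaction_bootstrap"] = bootstrap_interaction_factors(
                        best, n_boot=int(config["cooc_bootstrap"]), seed=seed)
                _write_json(out / f"cooc_{a_label}_{b_label}.json", report)
                outputs.append(out / f"cooc_{a_label}_{b_label}.json")
            pd.concat(cooc_rows).to_csv(out / "cooc_selection.csv", index=False)
            outputs.append(out / "cooc_selection.csv")
            run_log["stages"].append("cooccurrence")
        else:
            log.info("no co-occurrence pairs configured; stage skipped")
            run_log["stages"].append("cooccurrence:skipped")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": seed,
        "files": {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                  for p in outputs},
    }
    _write_json(out / "run_log.json", run_log)
    _write_json(out / "manifest.json", manifest)
    return manifest
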