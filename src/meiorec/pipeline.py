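"""End-to-end orchestration.

``run_all`` executes the full analysis from a :class:`RunConfig` — simulate
(optional) → track binning → Hi-C scores per stage → crossover map → site
definition → quartile partitions → enrichment → pileups → feature matrix →
PCA → forward-selected models → P(s)/loop lengths — and writes per-stage
TSVs plus one machine-readable ``results.json``.  A single global seed fans
out into named substreams (one per stochastic stage), so reruns with the
same config are bitwise identical and stages can be reproduced in
isolation.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binning, hic, model, profiles, recombination
from .binning import ACTIVE_STATES, CHROMHMM_STATES, BinnedTrack
from .simulate import SimConfig, write_simulation

logger = logging.getLogger("meiorec")


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    outdir: str = "meiorec_out"
    simulate: SimConfig | None = None
    inputs: dict | None = None          # paths: chromsizes, chromhmm, peaks, tracks, ...
    bin_size: int = 5000
    stages: tuple[str, ...] = ("ES", "zygonema", "pachynema")
    flank_bins_profile: int = 100       # +-500 kb at 5-kb bins
    flank_bins_matrix: int = 50
    n_boot: int = 1000
    alpha_model: float = 0.001
    alpha_enrich: float = 0.01
    insulation_window: int = 100_000
    compartment_chunk: int = 10_000_000
    n_components: int = 4
    write_contact_files: bool = False   # contact triplet TSVs are ~100 MB/stage
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "simulate"})
        if sim is not None:
            if "chrom_lengths" in sim:
                sim["chrom_lengths"] = tuple(sim["chrom_lengths"])
            if "compartment_strength" in sim:
                sim["compartment_strength"] = dict(sim["compartment_strength"])
            cfg.simulate = SimConfig(**sim)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg


def _stage_seed(seed: int, tag: str) -> int:
    return (int(seed) * 1_000_003 + zlib.crc32(tag.encode())) % (2**31 - 1)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return [None if (isinstance(x, float) and not np.isfinite(x)) else x
                for x in o.tolist()]
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _sanitize(obj):
    """Replace non-finite floats by None, recursively (JSON has no NaN)."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (float, np.floating)) and not np.isfinite(obj):
        return None
    return obj


def _model_dict(fit: model.ModelFit) -> dict:
    return {
        "response": fit.response,
        "selected": fit.selected,
        "coef": {k: round(v, 10) for k, v in fit.coef.items()},
        "t": {k: round(v, 6) for k, v in fit.tvalues.items()},
        "r2": round(fit.r2, 8),
        "naive_r2": round(fit.naive_r2, 8),
        "naive_predictors": fit.naive_predictors,
        "threshold": fit.threshold,
        "n_obs": fit.n_obs,
    }


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the report dict (also written to
    ``<outdir>/results.json``).  Stages whose inputs are absent are skipped
    and listed under ``skipped``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "skipped": []}

    # ------------------------------------------------------------------ inputs
    if config.simulate is not None:
        sim_cfg = config.simulate
        logger.info("simulating synthetic genome (seed %d)", sim_cfg.seed)
        sim = write_simulation(out / "sim", sim_cfg,
                               write_contacts=config.write_contact_files)
        bins = sim["bins"]
        chromhmm = sim["chromhmm"]
        prdm9_peaks, dmc1_peaks = sim["prdm9"], sim["dmc1"]
        signal_tracks = sim["tracks"]
        contact_matrices = sim["contacts"]
        crossovers = sim["crossovers"]
        truth = sim["truth"]
        stages = tuple(s for s in config.stages if s in contact_matrices)
    else:
        bins, chromhmm, prdm9_peaks, dmc1_peaks, signal_tracks, contact_matrices, \
            crossovers, truth = _load_inputs(config)
        stages = tuple(s for s in config.stages if s in contact_matrices)
    report["n_bins"] = bins.n_bins
    report["stages_run"] = list(stages)

    # -------------------------------------------------------------- bin tracks
    logger.info("binning tracks")
    state_tracks = binning.chromhmm_overlap_tracks(chromhmm, bins)
    tracks: dict[str, BinnedTrack] = dict(state_tracks)
    for name, bg in signal_tracks.items():
        tracks[name] = binning.map_bedgraph_to_bins(bg, bins, name=name)
    tracks["prdm9"] = binning.map_bedgraph_to_bins(
        prdm9_peaks[["chrom", "start", "end", "score"]], bins, name="prdm9"
    )
    tracks["dmc1"] = binning.map_bedgraph_to_bins(
        dmc1_peaks[["chrom", "start", "end", "score"]], bins, name="dmc1"
    )
    activity_ref = BinnedTrack(
        "activity_ref",
        np.sum([state_tracks[s].values for s in ACTIVE_STATES], axis=0),
    )

    # -------------------------------------------------------------- hic scores
    hic_tracks: dict[str, BinnedTrack] = {}
    if contact_matrices:
        for stage in stages:
            cm = contact_matrices[stage]
            logger.info("Hi-C scores: %s", stage)
            hic_tracks[f"cis_total_{stage}"] = hic.cis_total_ratio(cm)
            hic_tracks[f"compartment_{stage}"] = hic.fine_grain_compartment(
                cm, activity_ref, chunk_bp=config.compartment_chunk
            )
            hic_tracks[f"insulation_{stage}"] = hic.insulation_score(
                cm, window_bp=config.insulation_window
            )
            hic_tracks[f"fire_{stage}"] = hic.fire_score(cm)
        for name, tr in hic_tracks.items():
            binning.write_bedgraph(tr, bins, out / f"{name}.bedgraph")
        report["stages"]["hic_scores"] = {
            name: int(np.isfinite(tr.values).sum()) for name, tr in hic_tracks.items()
        }
        if truth is not None:
            rec = {}
            for stage in stages:
                v = hic_tracks[f"compartment_{stage}"].values
                ok = np.isfinite(v)
                rec[stage] = round(
                    float(np.corrcoef(v[ok], truth.comp_label[ok])[0, 1]), 6
                )
            report["stages"]["compartment_truth_r"] = rec
    else:
        report["skipped"].append("hic_scores")

    # ---------------------------------------------------------- crossover map
    xo_track = recombination.crossover_score_map(crossovers, bins)
    tracks["crossover"] = xo_track
    binning.write_bedgraph(xo_track, bins, out / "crossover_score.bedgraph")
    report["stages"]["crossover_map"] = {
        "n_crossovers": int(len(crossovers)),
        "nonzero_bins": int((xo_track.values > 0).sum()),
    }

    # ------------------------------------------------------------------- sites
    score_tracks = {
        "prdm9": tracks["prdm9"],
        "dmc1": tracks["dmc1"],
        "crossover": xo_track,
        **hic_tracks,
    }
    prdm9_sites = recombination.define_sites(prdm9_peaks, bins, score_tracks, label="PRDM9")
    dsb_sites = recombination.define_sites(dmc1_peaks, bins, score_tracks, label="DSB")
    joint_peaks = pd.concat([prdm9_peaks, dmc1_peaks], ignore_index=True)
    joint_sites = recombination.define_sites(joint_peaks, bins, score_tracks, label="joint")
    report["stages"]["sites"] = {
        "prdm9": len(prdm9_sites), "dsb": len(dsb_sites), "joint": len(joint_sites)
    }
    for ss in (prdm9_sites, dsb_sites, joint_sites):
        ss.table.to_csv(out / f"sites_{ss.label}.tsv", sep="\t", index=False)

    # -------------------------------------------------------------- partitions
    part_prdm9 = recombination.partition_quartiles(prdm9_sites, "dmc1")
    part_dsb = recombination.partition_quartiles(dsb_sites, "crossover")
    report["stages"]["partitions"] = {
        "prdm9_by_dmc1": {"top": len(part_prdm9.top), "bottom": len(part_prdm9.bottom)},
        "dsb_by_crossover": {"top": len(part_dsb.top), "bottom": len(part_dsb.bottom)},
    }

    # -------------------------------------------------------------- enrichment
    enrich_vars = {
        "prdm9": tracks["prdm9"], "dmc1": tracks["dmc1"], "crossover": xo_track,
        **{k: tracks[k] for k in signal_tracks},
    }
    enr = {}
    for pname, (part, sites) in {
        "prdm9_by_dmc1": (part_prdm9, prdm9_sites),
        "dsb_by_crossover": (part_dsb, dsb_sites),
    }.items():
        tbl = recombination.enrichment_summary(
            part, sites, enrich_vars, alpha=config.alpha_enrich
        )
        tbl.to_csv(out / f"enrichment_{pname}.tsv", sep="\t", index=False)
        enr[pname] = {
            r["variable"]: {"log_fold_top": round(r["log_fold_top"], 6),
                            "log_fold_bottom": round(r["log_fold_bottom"], 6),
                            "significant": bool(r["significant"])}
            for _, r in tbl.iterrows()
        }
    report["stages"]["enrichment"] = enr

    # ----------------------------------------------------------------- pileups
    if contact_matrices:
        pile = {}
        boot_seed = _stage_seed(config.seed, "pileup")
        top_sites = recombination.SiteSet(
            "top", prdm9_sites.table[np.isin(prdm9_sites.bin_ids, part_prdm9.top)]
        )
        bot_sites = recombination.SiteSet(
            "bottom", prdm9_sites.table[np.isin(prdm9_sites.bin_ids, part_prdm9.bottom)]
        )
        for stage in stages:
            for tr_name in (f"cis_total_{stage}", f"compartment_{stage}"):
                p_top = profiles.pileup_track(
                    hic_tracks[tr_name], top_sites, bins,
                    config.flank_bins_profile, config.n_boot, boot_seed,
                )
                p_bot = profiles.pileup_track(
                    hic_tracks[tr_name], bot_sites, bins,
                    config.flank_bins_profile, config.n_boot, boot_seed,
                )
                cmp = profiles.compare_profiles(p_top, p_bot, config.n_boot, boot_seed)
                pile[tr_name] = {
                    "top_center": round(float(p_top.mean[config.flank_bins_profile]), 6),
                    "bottom_center": round(float(p_bot.mean[config.flank_bins_profile]), 6),
                    "difference_center": round(float(cmp["at_center"]), 6),
                }
                _write_profile(out / f"profile_{tr_name}_top.tsv", p_top)
                _write_profile(out / f"profile_{tr_name}_bottom.tsv", p_bot)
            pm = profiles.pileup_matrix(
                contact_matrices[stage], top_sites, config.flank_bins_matrix
            )
            np.savetxt(out / f"pileup_matrix_{stage}_top.tsv", pm.mean, delimiter="\t")
            F = config.flank_bins_matrix
            center_block = pm.mean[F - 10 : F + 11, F - 10 : F + 11]
            pile[f"matrix_{stage}"] = {
                # the exact diagonal is undefined under O/E; summarise the
                # central +-50-kb block instead
                "center_mean_oe": round(float(np.nanmean(center_block)), 6),
                "n_sites": pm.n_sites,
            }
        report["stages"]["pileups"] = pile
    else:
        report["skipped"].append("pileups")

    # ----------------------------------------------------- features/PCA/models
    if contact_matrices:
        feature_vars = {**hic_tracks,
                        **{k: tracks[k] for k in signal_tracks},
                        **{s: tracks[s] for s in CHROMHMM_STATES}}
        fm = model.build_feature_matrix(joint_sites, feature_vars, bins)
        pca = model.run_pca(fm, n_components=config.n_components)
        loadings = pd.DataFrame(
            pca.loadings.T, index=fm.columns,
            columns=[f"PC{i+1}" for i in range(pca.loadings.shape[0])],
        )
        loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
        prdm9_mask = np.isin(fm.rows["bin_id"].to_numpy(), prdm9_sites.bin_ids) & np.isfinite(
            fm.rows["prdm9"].to_numpy(dtype=float)
        ) & np.isfinite(fm.rows["dmc1"].to_numpy(dtype=float))
        dsb_mask = np.isin(fm.rows["bin_id"].to_numpy(), dsb_sites.bin_ids) & np.isfinite(
            fm.rows["dmc1"].to_numpy(dtype=float)
        )
        fits = model.fit_recombination_models(
            fm, pca, prdm9_mask, dsb_mask, alpha_base=config.alpha_model
        )
        report["stages"]["pca"] = {
            "explained_variance_pct": [
                round(100 * float(x), 4) for x in pca.explained_variance_ratio
            ],
            "n_features": len(fm.columns),
            "n_rows": int(fm.X.shape[0]),
            "n_dropped_rows": fm.n_dropped_rows,
        }
        report["stages"]["models"] = {k: _model_dict(v) for k, v in fits.items()}
    else:
        report["skipped"].extend(["features", "pca", "models"])

    # ------------------------------------------------------- P(s)/loop lengths
    if contact_matrices:
        ref_stage = stages[0]
        comp_ref = hic_tracks[f"compartment_{ref_stage}"].values
        loops = {}
        for stage in stages:
            curves = hic.ps_curves_by_compartment(contact_matrices[stage], comp_ref)
            est = {m: hic.loop_length_estimate(c) for m, c in curves.items()}
            for m, c in curves.items():
                _write_ps(out / f"ps_{stage}_{m}.tsv", c)
            ratio = (
                round(est["B"] / est["A"], 4)
                if est.get("A") and est.get("B")
                else None
            )
            loops[stage] = {
                "loop_A_bp": est.get("A"), "loop_B_bp": est.get("B"),
                "ratio_B_over_A": ratio,
            }
        report["stages"]["loop_lengths"] = loops
    else:
        report["skipped"].append("loop_lengths")

    report = _sanitize(report)
    with open(out / "results.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default,
                  allow_nan=False)
        fh.write("\n")
    logger.info("wrote %s", out / "results.json")
    return report


def _write_profile(path, p: profiles.Profile):
    pd.DataFrame(
        {"offset": p.offsets, "mean": p.mean, "ci_lo": p.ci_lo, "ci_hi": p.ci_hi}
    ).to_csv(path, sep="\t", index=False)


def _write_ps(path, c: hic.PsCurve):
    pd.DataFrame(
        {"s_mid": c.s_mid, "P": c.p, "dlogP_dlogs": c.deriv, "n_pairs": c.n_pairs}
    ).to_csv(path, sep="\t", index=False)


def _load_inputs(config: RunConfig):
    """Read pipeline inputs from files (``config.inputs`` path mapping).

    Required keys: chromsizes, chromhmm, prdm9_peaks, dmc1_peaks, crossovers.
    Optional: tracks (name -> bedGraph path), contacts (stage -> [triplets,
    bin_sums]).  Absent optional inputs cause the dependent stages to be
    skipped.
    """
    from .contacts import ContactMatrix

    paths = config.inputs or {}
    required = ["chromsizes", "chromhmm", "prdm9_peaks", "dmc1_peaks", "crossovers"]
    missing = [k for k in required if k not in paths]
    if missing:
        raise ValueError(f"missing required inputs: {missing}")
    chromsizes = binning.read_chromsizes(paths["chromsizes"])
    bins = binning.make_bins(chromsizes, config.bin_size)
    chromhmm = binning.read_bed(paths["chromhmm"])
    prdm9 = binning.read_bed(paths["prdm9_peaks"])
    dmc1 = binning.read_bed(paths["dmc1_peaks"])
    crossovers = binning.read_bed(paths["crossovers"])
    signal_tracks = {
        name: binning.read_bedgraph(p) for name, p in paths.get("tracks", {}).items()
    }
    contact_matrices = {}
    for stage, (trip, sums) in paths.get("contacts", {}).items():
        contact_matrices[stage] = ContactMatrix.read(
            bins, trip, sums, balance=paths.get("balance", False)
        )
    return bins, chromhmm, prdm9, dmc1, signal_tracks, contact_matrices, crossovers, None
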