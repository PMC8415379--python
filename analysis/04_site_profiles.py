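#!/usr/bin/env python
"""Symmetric-averaged cis/total and compartment profiles around DSB-favored
versus disfavored PRDM9 sites, with bootstrap confidence intervals, plus the
O/E contact-map pileup.  Writes TSVs under results/profiles/."""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from meiorec import binning, hic, profiles
from meiorec.recombination import define_sites, partition_quartiles, SiteSet
from meiorec.simulate import (
    SimConfig,
    simulate_contacts,
    simulate_genome,
    simulate_peaks_and_tracks,
)

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "profiles"


def main():
    cfg = SimConfig(seed=0)
    bins, truth, chromhmm, _ = simulate_genome(cfg)
    prdm9, dmc1, _ = simulate_peaks_and_tracks(bins, truth, cfg)
    states = binning.chromhmm_overlap_tracks(chromhmm, bins)
    ref = binning.BinnedTrack(
        "ref", np.sum([states[s].values for s in binning.ACTIVE_STATES], axis=0)
    )
    dmc1_track = binning.BinnedTrack("dmc1", np.full(bins.n_bins, np.nan))
    dmc1_track.values[dmc1["bin_id"].to_numpy()] = dmc1["score"].to_numpy()
    sites = define_sites(prdm9, bins, {"dmc1": dmc1_track}, label="PRDM9")
    part = partition_quartiles(sites, "dmc1")
    top = SiteSet("top", sites.table[np.isin(sites.bin_ids, part.top)])
    bottom = SiteSet("bottom", sites.table[np.isin(sites.bin_ids, part.bottom)])

    OUT.mkdir(parents=True, exist_ok=True)
    for stage in ("zygonema", "pachynema"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = simulate_contacts(bins, truth, cfg, stage)
            tracks = {
                "cis_total": hic.cis_total_ratio(cm),
                "compartment": hic.fine_grain_compartment(cm, ref),
            }
            for name, tr in tracks.items():
                p_top = profiles.pileup_track(tr, top, bins, 100, 1000, 0)
                p_bot = profiles.pileup_track(tr, bottom, bins, 100, 1000, 0)
                cmp = profiles.compare_profiles(p_top, p_bot, 1000, 0)
                pd.DataFrame({
                    "offset": p_top.offsets,
                    "top": p_top.mean, "top_lo": p_top.ci_lo, "top_hi": p_top.ci_hi,
                    "bottom": p_bot.mean, "bottom_lo": p_bot.ci_lo,
                    "bottom_hi": p_bot.ci_hi,
                }).to_csv(OUT / f"profile_{name}_{stage}.tsv", sep="\t", index=False)
                lo, hi = cmp["center_ci"]
                print(f"{stage} {name}: top-bottom at site = "
                      f"{cmp['at_center']:+.4f} (95% CI {lo:+.4f}..{hi:+.4f})")
            pm = profiles.pileup_matrix(cm, top, flank_bins=50)
            np.savetxt(OUT / f"pileup_matrix_{stage}_top.tsv", pm.mean, delimiter="\t")
    print(f"profiles written to {OUT}")


if __name__ == "__main__":
    main()
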