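#!/usr/bin/env python
"""Crossover-score map, PRDM9/DSB site sets, quartile partitions and the
enrichment heat-map table (recombination activity vs chromatin variables).
Writes tables under results/recombination/."""

import warnings
from pathlib import Path

import numpy as np

from meiorec import binning
from meiorec.recombination import (
    crossover_score_map,
    define_sites,
    enrichment_summary,
    partition_quartiles,
)
from meiorec.simulate import (
    SimConfig,
    simulate_crossovers,
    simulate_genome,
    simulate_peaks_and_tracks,
)

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "recombination"


def main():
    cfg = SimConfig(seed=0)
    bins, truth, chromhmm, _ = simulate_genome(cfg)
    prdm9, dmc1, signal_tracks = simulate_peaks_and_tracks(bins, truth, cfg)
    crossovers = simulate_crossovers(bins, truth, dmc1, cfg)
    OUT.mkdir(parents=True, exist_ok=True)

    xo_track = crossover_score_map(crossovers, bins)
    print(f"crossover map: {int((xo_track.values > 0).sum())} nonzero bins, "
          f"median(nonzero) = {np.median(xo_track.values[xo_track.values > 0]):.3f}")

    score_tracks = {"crossover": xo_track}
    for name, peaks in [("prdm9", prdm9), ("dmc1", dmc1)]:
        v = np.full(bins.n_bins, np.nan)
        v[peaks["bin_id"].to_numpy()] = peaks["score"].to_numpy()
        score_tracks[name] = binning.BinnedTrack(name, v)

    prdm9_sites = define_sites(prdm9, bins, score_tracks, label="PRDM9")
    dsb_sites = define_sites(dmc1, bins, score_tracks, label="DSB")
    part_prdm9 = partition_quartiles(prdm9_sites, "dmc1")
    part_dsb = partition_quartiles(dsb_sites, "crossover")
    print(f"{len(prdm9_sites)} PRDM9 sites -> top/bottom {len(part_prdm9.top)} by DMC1")
    print(f"{len(dsb_sites)} DSB sites -> top/bottom {len(part_dsb.top)} by crossover")

    variables = dict(score_tracks)
    for name, bg in signal_tracks.items():
        variables[name] = binning.map_bedgraph_to_bins(bg, bins, name)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for label, (part, sites) in {
            "prdm9_by_dmc1": (part_prdm9, prdm9_sites),
            "dsb_by_crossover": (part_dsb, dsb_sites),
        }.items():
            tbl = enrichment_summary(part, sites, variables)
            tbl.to_csv(OUT / f"enrichment_{label}.tsv", sep="\t", index=False)
            sig = tbl[tbl["significant"]]["variable"].tolist()
            print(f"{label}: significant top-vs-bottom differences in {sig}")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
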