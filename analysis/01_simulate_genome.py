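#!/usr/bin/env python
"""Generate the default synthetic meiotic genome and write every pipeline
input (chrom sizes, ChromHMM BED, peak sets, signal bedGraphs, contact
triplets, crossovers) under results/sim/."""

from pathlib import Path

from meiorec.simulate import SimConfig, write_simulation

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main():
    cfg = SimConfig(seed=0)
    sim = write_simulation(OUT, cfg)
    truth = sim["truth"]
    frac_a = truth.comp_label.mean()
    print(f"genome: {len(cfg.chrom_lengths)} chromosomes, "
          f"{sim['bins'].n_bins} bins of {cfg.bin_size} bp")
    print(f"A-compartment fraction: {frac_a:.2f}")
    print(f"PRDM9 peaks: {len(sim['prdm9'])}  crossovers: {len(sim['crossovers'])}")
    for stage, cm in sim["contacts"].items():
        print(f"{stage}: {cm.cis_raw.sum() / 2:.3g} cis contacts, "
              f"{int(cm.valid.sum())} valid bins")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
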