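"""Synthetic meiotic genome generator.

Produces every input the analysis consumes — chromosome sizes, a seven-state
chromatin segmentation, binned contact matrices with per-bin trans totals,
ChIP-seq style peak sets and signal tracks, and crossover intervals — from a
small parametric model with known ground truth:

* alternating A/B compartment blocks (exponential lengths),
* power-law contact decay with a compartment-specific loop-size shoulder,
* cis/total fraction anti-correlated with compartment score,
* PRDM9 peaks split between compartments with log-normal scores; DSB (DMC1)
  scores biased toward the A compartment and gene-body chromatin,
* crossovers drawn at DSB peaks, penalised in gene bodies and near the
  (acrocentric) chromosome start, reported as variable-length resolution
  intervals.

Everything is deterministic given ``SimConfig.seed``; each generation step
draws from its own named substream so stages can be rerun in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.signal import fftconvolve

from .binning import (
    ACTIVE_STATES,
    CHROMHMM_STATES,
    GENE_BODY_STATES,
    BinTable,
    make_bins,
)
from .contacts import ContactMatrix

# Log-normal shoulder geometry (log10 units).  The shoulder multiplies the
# power-law decay by 1 + amp * exp(-(log10 s - mu)^2 / (2 sigma^2)) with
# mu = log10(L) + SHOULDER_SIGMA + SHOULDER_CENTER_SHIFT, placed so that the
# maximum of d log P / d log s falls at the nominal loop size L for the
# default amplitude (verified numerically; see docs/methods.md).
SHOULDER_SIGMA = 0.35
SHOULDER_CENTER_SHIFT = 0.075

#: Chromatin-state frequencies inside A and B compartment blocks, in
#: CHROMHMM_STATES order.  Active/gene-body states concentrate in A,
#: unmarked chromatin dominates B.
STATE_PROBS_A = np.array([0.06, 0.06, 0.10, 0.10, 0.28, 0.30, 0.10])
STATE_PROBS_B = np.array([0.01, 0.01, 0.04, 0.02, 0.06, 0.76, 0.10])


@dataclass
class SimConfig:
    """Parameters of the synthetic genome.

    Defaults define the reference study conditions: three 60-Mb chromosomes
    at 5-kb bins, 2-Mb mean compartment blocks, P(s) exponent -1 with loop
    shoulders at 0.7 Mb (A) and 2.1 Mb (B), and ~5e6 cis contacts per
    chromosome.
    """

    chrom_lengths: tuple[int, ...] = (60_000_000, 60_000_000, 60_000_000)
    bin_size: int = 5000
    compartment_block_mean: float = 2_000_000.0
    state_segment_mean: float = 25_000.0
    ps_exponent: float = -1.0
    loop_size_A: float = 700_000.0
    loop_size_B: float = 2_100_000.0
    shoulder_amp: float = 1.0
    compartment_strength: dict = field(
        default_factory=lambda: {"ES": 1.0, "zygonema": 0.6, "pachynema": 0.75}
    )
    cis_fraction_base: float = 0.80
    cis_fraction_delta: float = 0.05
    read_depth: float = 5e6
    n_prdm9_peaks: int = 3000
    prdm9_frac_A: float = 0.57
    dsb_bias_A: float = 2.0
    dsb_bias_genebody: float = 1.5
    dsb_noise_sd: float = 0.4
    n_crossovers: int = 2000
    xo_min_len: float = 5000.0
    xo_max_len: float = 200_000.0
    gene_body_penalty: float = 0.2
    prdm9_cis_dip: float = 0.0  # optional zygonema-specific cis/total dip at PRDM9 bins
    seed: int = 0

    def __post_init__(self):
        if self.bin_size <= 0 or any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths and bin_size must be positive")
        if any(l < self.bin_size for l in self.chrom_lengths):
            raise ValueError("chromosome shorter than one bin")
        if not 0 < self.cis_fraction_base < 1:
            raise ValueError("cis_fraction_base must be in (0,1)")
        if not 0 < self.prdm9_frac_A < 1:
            raise ValueError("prdm9_frac_A must be in (0,1)")

    @property
    def chromsizes(self) -> dict[str, int]:
        return {f"chr{i+1}": int(l) for i, l in enumerate(self.chrom_lengths)}


@dataclass
class GroundTruth:
    """Known generative state of a synthetic genome."""

    comp_label: np.ndarray          # 1 = A, 0 = B per bin
    state_label: np.ndarray         # index into CHROMHMM_STATES per bin
    true_loop_sizes: dict           # {"A": bp, "B": bp}
    prdm9_peaks: pd.DataFrame       # chrom,start,end,summit,bin_id,score
    crossover_sources: pd.DataFrame | None = None


def _rng(seed: int, *tags: str) -> np.random.Generator:
    """Named substream: deterministic child generator for one stage."""
    entropy = [int(seed)] + [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# genome: compartment blocks + chromatin-state segmentation


def _draw_blocks(rng, n_bins, mean_bins) -> np.ndarray:
    """Alternating 0/1 labels in exponential-length blocks (>= 1 bin)."""
    labels = np.empty(n_bins, dtype=np.int8)
    cur = int(rng.integers(2))
    pos = 0
    while pos < n_bins:
        ln = max(1, int(round(rng.exponential(mean_bins))))
        labels[pos : pos + ln] = cur
        cur = 1 - cur
        pos += ln
    return labels


def simulate_genome(config: SimConfig):
    """Generate bins, compartment/state ground truth and the ChromHMM BED.

    Returns ``(bins, truth, chromhmm_bed, chromsizes)``.  PRDM9 peak
    positions and true binding scores are drawn here (they are part of the
    genome's ground truth and are needed by the contact simulator for the
    optional local-dip effect); :func:`simulate_peaks_and_tracks`
    materialises them as BED/bedGraph outputs.
    """
    bins = make_bins(config.chromsizes, config.bin_size)
    g_rng = _rng(config.seed, "genome")
    comp = np.empty(bins.n_bins, dtype=np.int8)
    state = np.empty(bins.n_bins, dtype=np.int8)
    block_mean_bins = config.compartment_block_mean / config.bin_size
    seg_mean_bins = max(1.0, config.state_segment_mean / config.bin_size)
    for chrom in bins.chroms:
        sl = bins.chrom_slice(chrom)
        n = bins.chrom_nbins(chrom)
        comp[sl] = _draw_blocks(g_rng, n, block_mean_bins)
        # state segments: exponential lengths, state drawn conditional on the
        # compartment of the segment's first bin
        local_state = np.empty(n, dtype=np.int8)
        pos = 0
        comp_local = comp[sl]
        while pos < n:
            ln = max(1, int(round(g_rng.exponential(seg_mean_bins))))
            probs = STATE_PROBS_A if comp_local[pos] == 1 else STATE_PROBS_B
            local_state[pos : pos + ln] = g_rng.choice(len(CHROMHMM_STATES), p=probs)
            pos += ln
        state[sl] = local_state

    truth = GroundTruth(
        comp_label=comp,
        state_label=state,
        true_loop_sizes={"A": config.loop_size_A, "B": config.loop_size_B},
        prdm9_peaks=_draw_prdm9_peaks(config, bins, comp, g_rng),
    )
    chromhmm = _state_bed(bins, state)
    return bins, truth, chromhmm, config.chromsizes


def _state_bed(bins: BinTable, state: np.ndarray) -> pd.DataFrame:
    """Collapse per-bin state labels into a sorted BED4 segmentation."""
    rows = []
    frame = bins.to_frame()
    for chrom in bins.chroms:
        sl = bins.chrom_slice(chrom)
        st = state[sl]
        sub = frame.iloc[sl.start : sl.stop]
        change = np.flatnonzero(np.diff(st)) + 1
        seg_starts = np.concatenate([[0], change])
        seg_ends = np.concatenate([change, [len(st)]])
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": sub["start"].to_numpy()[seg_starts],
                    "end": sub["end"].to_numpy()[seg_ends - 1],
                    "state": [CHROMHMM_STATES[s] for s in st[seg_starts]],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _draw_prdm9_peaks(config, bins, comp, rng) -> pd.DataFrame:
    """Place PRDM9 peaks across compartments with log-normal true scores."""
    if config.n_prdm9_peaks > bins.n_bins:
        raise ValueError("n_prdm9_peaks exceeds number of bins")
    n_a = int(round(config.prdm9_frac_A * config.n_prdm9_peaks))
    n_b = config.n_prdm9_peaks - n_a
    a_bins = np.flatnonzero(comp == 1)
    b_bins = np.flatnonzero(comp == 0)
    n_a = min(n_a, len(a_bins))
    n_b = min(config.n_prdm9_peaks - n_a, len(b_bins))
    chosen = np.concatenate(
        [
            rng.choice(a_bins, size=n_a, replace=False),
            rng.choice(b_bins, size=n_b, replace=False),
        ]
    )
    chosen.sort()
    chroms = bins.chrom_of(chosen)
    bin_starts = bins.bin_start(chosen)
    widths = rng.integers(800, 1601, size=len(chosen))
    lengths = np.array([bins.chromsizes[c] for c in chroms])
    centers = bin_starts + rng.integers(0, config.bin_size, size=len(chosen))
    centers = np.minimum(centers, lengths - 1)
    starts = np.maximum(centers - widths // 2, 0)
    ends = np.minimum(centers + (widths + 1) // 2, lengths)
    score = rng.lognormal(mean=1.0, sigma=0.8, size=len(chosen))
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "summit": centers - starts,
            "bin_id": chosen,
            "score": score,
        }
    )


# ---------------------------------------------------------------------------
# contacts


def _shoulder(s: np.ndarray, loop_size: float, amp: float) -> np.ndarray:
    mu = np.log10(loop_size) + SHOULDER_SIGMA + SHOULDER_CENTER_SHIFT
    x = np.log10(s)
    return amp * np.exp(-((x - mu) ** 2) / (2 * SHOULDER_SIGMA**2))


def _lambda_tables(config: SimConfig, stage: str, n: int):
    """Unscaled expected contact per pair, per separation d and label combo.

    Returns array of shape (3, n): rows indexed by a_i + a_j
    (0 = BB, 1 = AB, 2 = AA), column d = separation in bins (d >= 1;
    column 0 unused).
    """
    if stage not in config.compartment_strength:
        raise ValueError(f"unknown stage {stage!r}; known: {list(config.compartment_strength)}")
    strength = config.compartment_strength[stage]
    d = np.arange(n, dtype=float)
    d[0] = np.nan
    s = d * config.bin_size
    base = s**config.ps_exponent
    loop_ab = np.sqrt(config.loop_size_A * config.loop_size_B)
    tab = np.empty((3, n))
    tab[0] = base * (1 + _shoulder(s, config.loop_size_B, config.shoulder_amp)) * (1 + strength)
    tab[1] = base * (1 + _shoulder(s, loop_ab, config.shoulder_amp))
    tab[2] = base * (1 + _shoulder(s, config.loop_size_A, config.shoulder_amp)) * (1 + strength)
    tab[:, 0] = 0.0
    return tab


def _combo_pair_counts(a: np.ndarray):
    """Number of (i, i+d) pairs whose labels sum to 0/1/2, for every d."""
    n = len(a)
    af = a.astype(float)
    bf = 1.0 - af
    auto_a = np.rint(fftconvolve(af, af[::-1])[n - 1 :]).astype(np.int64)
    auto_b = np.rint(fftconvolve(bf, bf[::-1])[n - 1 :]).astype(np.int64)
    total = n - np.arange(n)
    return np.stack([auto_b, total - auto_a - auto_b, auto_a])


def expected_matrix(config: SimConfig, comp_local: np.ndarray, stage: str,
                    depth: float | None = None, row_factor: np.ndarray | None = None):
    """Dense expected (pre-sampling) cis matrix for one chromosome.

    Intended for small test genomes; memory is O(n^2).
    """
    n = len(comp_local)
    tab = _lambda_tables(config, stage, n)
    counts = _combo_pair_counts(comp_local.astype(np.int8))
    unscaled_total = float(np.nansum(tab[:, 1:] * counts[:, 1:]))
    scale = 1.0 if depth is None else depth / unscaled_total
    m = np.zeros((n, n))
    a = comp_local.astype(np.int64)
    for d in range(1, n):
        combo = a[: n - d] + a[d:]
        lam = tab[combo, d] * scale
        if row_factor is not None:
            lam = lam * row_factor[: n - d] * row_factor[d:]
        idx = np.arange(n - d)
        m[idx, idx + d] = lam
        m[idx + d, idx] = lam
    return m


def simulate_contacts(
    bins: BinTable, truth: GroundTruth, config: SimConfig, stage: str
) -> ContactMatrix:
    """Poisson-sample a stage-specific contact map from the generative model.

    Expected cis contact between bins i, j at separation s is proportional to
    ``s^alpha * (1 + shoulder(s; L_combo)) * (1 + strength * same_label)``,
    scaled so each chromosome receives ``read_depth`` expected contacts.
    Per-bin trans totals are drawn so the expected cis/total fraction is
    ``cis_fraction_base`` minus ``cis_fraction_delta`` in A bins and plus
    ``cis_fraction_delta`` in B bins.
    """
    if config.read_depth <= 0:
        raise ValueError("read_depth must be positive")
    rng = _rng(config.seed, "contacts", stage)
    matrices = {}
    cis_raw = np.zeros(bins.n_bins)
    for chrom in bins.chroms:
        sl = bins.chrom_slice(chrom)
        a = truth.comp_label[sl].astype(np.int64)
        n = len(a)
        tab = _lambda_tables(config, stage, n)
        counts = _combo_pair_counts(a.astype(np.int8))
        scale = config.read_depth / float(np.nansum(tab[:, 1:] * counts[:, 1:]))
        row_factor = np.ones(n)
        if config.prdm9_cis_dip > 0 and stage == "zygonema":
            local_peaks = truth.prdm9_peaks["bin_id"].to_numpy()
            in_chrom = (local_peaks >= sl.start) & (local_peaks < sl.stop)
            row_factor[local_peaks[in_chrom] - sl.start] = 1.0 - config.prdm9_cis_dip
        thin = (row_factor < 1).any()
        rows, cols, data = [], [], []
        # Poisson sampling factorised per (separation, label-combo) class:
        # class totals are Poisson, positions within a class are uniform —
        # exactly equivalent to independent per-pair Poisson draws.
        for d in range(1, n):
            n_event = rng.poisson(tab[:, d] * scale * counts[:, d])
            if not n_event.any():
                continue
            combo = a[: n - d] + a[d:]
            for cls in np.flatnonzero(n_event):
                pos = np.flatnonzero(combo == cls)
                idx = pos[rng.integers(0, len(pos), n_event[cls])]
                if thin:
                    keep = rng.random(len(idx)) < row_factor[idx] * row_factor[idx + d]
                    idx = idx[keep]
                if idx.size:
                    uniq, cnt = np.unique(idx, return_counts=True)
                    rows.append(uniq)
                    cols.append(uniq + d)
                    data.append(cnt.astype(float))
        if rows:
            i = np.concatenate(rows)
            j = np.concatenate(cols)
            v = np.concatenate(data)
        else:
            i = j = np.array([], dtype=int)
            v = np.array([])
        m = sp.coo_matrix((v, (i, j)), shape=(n, n)).tocsr()
        m = m + m.T
        matrices[chrom] = m
        cis_raw[sl] = np.asarray(m.sum(axis=1)).ravel()

    frac = np.where(
        truth.comp_label == 1,
        config.cis_fraction_base - config.cis_fraction_delta,
        config.cis_fraction_base + config.cis_fraction_delta,
    )
    if config.prdm9_cis_dip > 0 and stage == "zygonema":
        frac = frac.copy()
        frac[truth.prdm9_peaks["bin_id"].to_numpy()] -= config.prdm9_cis_dip
    frac = np.clip(frac, 0.01, 0.99)
    # trans totals drawn conditionally on realised cis coverage so the
    # expected per-bin cis/total equals ``frac``
    trans_raw = rng.poisson(cis_raw * (1 - frac) / frac).astype(float)
    return ContactMatrix(bins, matrices, cis_raw, trans_raw, valid=cis_raw > 0)


# ---------------------------------------------------------------------------
# peaks, signal tracks, crossovers


def simulate_peaks_and_tracks(bins: BinTable, truth: GroundTruth, config: SimConfig):
    """Materialise PRDM9/DMC1 peak sets and cohesin/CTCF/RNAPII signal tracks.

    DMC1 (DSB) peaks reuse the PRDM9 locations; their scores are the PRDM9
    scores multiplied by ``dsb_bias_A`` in the A compartment, by
    ``dsb_bias_genebody`` in gene-body chromatin, and by log-normal noise
    (sd ``dsb_noise_sd``; set to 0 to disable).

    Returns ``(prdm9_peaks, dmc1_peaks, tracks)`` where the peak tables carry
    chrom/start/end/summit/bin_id/score and ``tracks`` maps
    cohesin/CTCF/RNAPII to genome-wide bedGraph DataFrames.
    """
    rng = _rng(config.seed, "peaks")
    prdm9 = truth.prdm9_peaks.copy()
    bin_ids = prdm9["bin_id"].to_numpy()
    in_a = truth.comp_label[bin_ids] == 1
    in_gb = np.isin(
        truth.state_label[bin_ids],
        [CHROMHMM_STATES.index(s) for s in GENE_BODY_STATES],
    )
    noise = (
        rng.lognormal(mean=0.0, sigma=config.dsb_noise_sd, size=len(prdm9))
        if config.dsb_noise_sd > 0
        else 1.0
    )
    dmc1 = prdm9.copy()
    dmc1["score"] = (
        prdm9["score"].to_numpy()
        * np.where(in_a, config.dsb_bias_A, 1.0)
        * np.where(in_gb, config.dsb_bias_genebody, 1.0)
        * noise
    )

    frame = bins.to_frame()
    state = truth.state_label
    active = np.isin(state, [CHROMHMM_STATES.index(s) for s in ACTIVE_STATES])
    promoter = np.isin(
        state, [CHROMHMM_STATES.index(s) for s in ("H3K4me3", "H3K4me1_3")]
    )
    genebody = np.isin(state, [CHROMHMM_STATES.index(s) for s in GENE_BODY_STATES])
    n = bins.n_bins

    def _bg(values):
        out = frame[["chrom", "start", "end"]].copy()
        out["score"] = values
        return out

    tracks = {
        "RNAPII": _bg(rng.lognormal(0, 0.3, n) * (1 + 2.0 * promoter + 1.5 * genebody)),
        "CTCF": _bg(rng.lognormal(0, 0.3, n) * (1 + 1.0 * active)),
        "cohesin": _bg(rng.lognormal(0, 0.3, n) * (1 + 2.5 * promoter + 0.5 * active)),
    }
    return prdm9, dmc1, tracks


def simulate_crossovers(
    bins: BinTable, truth: GroundTruth, dsb_peaks: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Draw crossover resolution intervals at DSB peaks.

    Source sites are sampled without replacement with weight proportional to
    DMC1 score, down-weighted by ``gene_body_penalty`` in gene-body chromatin
    and by a linear ramp rising from 0.5 at the chromosome start to 1.5 at
    the end (acrocentric pericentromeric depletion).  Each crossover is
    reported as an interval of log-uniform length containing its source.
    """
    if config.n_crossovers > len(dsb_peaks):
        raise ValueError("n_crossovers exceeds number of DSB peaks")
    rng = _rng(config.seed, "crossovers")
    bin_ids = dsb_peaks["bin_id"].to_numpy()
    in_gb = np.isin(
        truth.state_label[bin_ids],
        [CHROMHMM_STATES.index(s) for s in GENE_BODY_STATES],
    )
    starts = bins.bin_start(bin_ids)
    lengths = np.array([bins.chromsizes[c] for c in dsb_peaks["chrom"]])
    ramp = 0.5 + starts / lengths
    w = dsb_peaks["score"].to_numpy() * np.where(in_gb, config.gene_body_penalty, 1.0) * ramp
    if config.n_crossovers == 0:
        src = np.array([], dtype=int)
    else:
        if w.sum() <= 0:
            raise ValueError("all crossover weights are zero")
        src = rng.choice(len(dsb_peaks), size=config.n_crossovers, replace=False, p=w / w.sum())
    chosen = dsb_peaks.iloc[np.sort(src)]
    n = len(chosen)
    xo_len = np.exp(
        rng.uniform(np.log(config.xo_min_len), np.log(config.xo_max_len), size=n)
    ).astype(int)
    centers = chosen["start"].to_numpy() + chosen["summit"].to_numpy()
    offset = rng.integers(0, np.maximum(xo_len, 1))
    xo_start = centers - offset
    xo_end = xo_start + xo_len
    lens = np.array([bins.chromsizes[c] for c in chosen["chrom"]])
    xo_start = np.clip(xo_start, 0, None)
    xo_end = np.minimum(np.maximum(xo_end, xo_start + 1), lens)
    out = pd.DataFrame(
        {
            "chrom": chosen["chrom"].to_numpy(),
            "start": xo_start,
            "end": xo_end,
            "source_bin": chosen["bin_id"].to_numpy(),
        }
    )
    out = out.sort_values(["chrom", "start"], ignore_index=True)
    truth.crossover_sources = out[["chrom", "source_bin"]].copy()
    return out


# ---------------------------------------------------------------------------
# file output


def write_simulation(outdir, config: SimConfig, write_contacts: bool = True):
    """Run the full generator and write every input file the pipeline reads.

    Returns the in-memory objects as a dict for direct use.  Contact triplet
    TSVs are by far the largest outputs (~100 MB per stage at the default
    depth); pass ``write_contacts=False`` to keep matrices in memory only.
    """
    from pathlib import Path

    from .binning import write_chromsizes

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bins, truth, chromhmm, chromsizes = simulate_genome(config)
    write_chromsizes(chromsizes, out / "genome.chrom.sizes")
    chromhmm.to_csv(out / "chromhmm.bed", sep="\t", header=False, index=False)

    prdm9, dmc1, tracks = simulate_peaks_and_tracks(bins, truth, config)
    for name, peaks in [("prdm9", prdm9), ("dmc1", dmc1)]:
        tbl = peaks.copy()
        tbl["name"] = [f"{name}_{k}" for k in range(len(tbl))]
        tbl[["chrom", "start", "end", "name", "score", "summit"]].to_csv(
            out / f"{name}_peaks.bed", sep="\t", header=False, index=False
        )
        bg = peaks[["chrom", "start", "end", "score"]]
        bg.to_csv(out / f"{name}.bedgraph", sep="\t", header=False, index=False)
    for name, bg in tracks.items():
        bg.to_csv(out / f"{name}.bedgraph", sep="\t", header=False, index=False)

    contact_matrices = {}
    for stage in config.compartment_strength:
        cm = simulate_contacts(bins, truth, config, stage)
        if write_contacts:
            cm.write(out / f"contacts_{stage}.tsv", out / f"bin_sums_{stage}.tsv")
        contact_matrices[stage] = cm

    crossovers = simulate_crossovers(bins, truth, dmc1, config)
    with open(out / "crossovers.bed", "w") as fh:
        fh.write("#chrom\tstart\tend\n")
        crossovers[["chrom", "start", "end"]].to_csv(fh, sep="\t", header=False, index=False)

    return {
        "bins": bins,
        "truth": truth,
        "chromhmm": chromhmm,
        "prdm9": prdm9,
        "dmc1": dmc1,
        "tracks": tracks,
        "contacts": contact_matrices,
        "crossovers": crossovers,
    }
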