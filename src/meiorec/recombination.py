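"""Recombination-activity maps and site-level summaries.

Builds the crossover-score genetic map from resolution intervals (each
crossover distributes unit mass 1/k over the k bins it intersects, and the
map is normalized by the median over nonzero bins), defines binding-site
sets from ChIP-seq peak centers, partitions sites into top/bottom quartiles
by an activity score, and summarises chromatin variables per partition with
log fold enrichments over the genome median and Bonferroni-adjusted rank-sum
tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from .binning import CHROMHMM_STATES, BinnedTrack, BinTable


# ---------------------------------------------------------------------------
# crossover-score map


def crossover_score_map(
    crossovers: pd.DataFrame,
    bins: BinTable,
    weight: str = "bins",
    median_over: str = "nonzero",
) -> BinnedTrack:
    """Crossover likelihood score per bin.

    Raw score of a bin is the sum over intersecting crossovers of ``1/k``,
    where ``k`` is the number of bins the crossover intersects (so each
    crossover contributes total mass 1 and sharply resolved crossovers get
    prominence).  The final score divides by the median raw score.

    Parameters
    ----------
    weight : "bins" (default) or "bp" — whether ``k`` counts intersected bins
        or the crossover's bp length in bin-size units.
    median_over : "nonzero" (default) or "all" — which bins enter the
        normalizing median.  With sparse crossovers the all-bin median is 0
        and normalization is skipped with a warning.
    """
    values = np.zeros(bins.n_bins)
    if len(crossovers) == 0:
        warnings.warn("no crossovers supplied; returning all-zero map")
        return BinnedTrack(name="crossover_score", values=values, kind="score")
    bs = bins.bin_size
    for chrom, grp in crossovers.groupby("chrom", sort=False):
        off = bins.chrom_offset(chrom)
        start = grp["start"].to_numpy()
        end = grp["end"].to_numpy()
        first = start // bs
        last = (end - 1) // bs
        k_bins = (last - first + 1).astype(float)
        if weight == "bins":
            w = 1.0 / k_bins
        elif weight == "bp":
            w = bs / (end - start).astype(float)
        else:
            raise ValueError(f"unknown weight mode {weight!r}")
        counts = (last - first + 1).astype(np.int64)
        ids = off + np.repeat(first, counts) + _ragged_arange(counts)
        np.add.at(values, ids, np.repeat(w, counts))
    if median_over == "nonzero":
        denom = np.median(values[values > 0]) if (values > 0).any() else 0.0
    elif median_over == "all":
        denom = np.median(values)
    else:
        raise ValueError(f"unknown median_over mode {median_over!r}")
    if denom > 0:
        values = values / denom
    else:
        warnings.warn("normalizing median is zero; returning raw crossover mass")
    return BinnedTrack(name="crossover_score", values=values, kind="score")


def _ragged_arange(counts: np.ndarray) -> np.ndarray:
    total = int(counts.sum())
    if total == 0:
        return np.array([], dtype=np.int64)
    out = np.ones(total, dtype=np.int64)
    out[0] = 0
    ends = np.cumsum(counts)[:-1]
    out[ends[ends < total]] = -(counts[:-1][ends < total] - 1)
    return np.cumsum(out)


# ---------------------------------------------------------------------------
# sites


@dataclass
class SiteSet:
    """Binding sites as unique genomic bins with per-site scores.

    ``table`` is indexed by sorted unique ``bin_id`` and carries whatever
    score columns were attached (e.g. prdm9, dmc1, crossover, position).
    """

    label: str
    table: pd.DataFrame

    @property
    def bin_ids(self) -> np.ndarray:
        return self.table["bin_id"].to_numpy()

    def __len__(self):
        return len(self.table)


def define_sites(
    peaks: pd.DataFrame,
    bins: BinTable,
    score_tracks: dict[str, BinnedTrack] | None = None,
    label: str = "sites",
) -> SiteSet:
    """Sites = bins containing each peak's center.

    The center is the summit (``start + summit``) when a summit column is
    present and non-negative, else the interval midpoint ``floor((s+e)/2)``.
    Peaks whose centers fall in one bin collapse to a single site.  Scores
    are attached from ``score_tracks`` by bin; fractional chromosomal
    position (bin start / chromosome length, a proxy for centromere distance
    on acrocentric chromosomes) is always attached.
    """
    df = peaks.reset_index(drop=True)
    if "summit" in df.columns:
        summit = df["summit"].to_numpy()
        center = np.where(
            summit >= 0,
            df["start"].to_numpy() + summit,
            (df["start"].to_numpy() + df["end"].to_numpy()) // 2,
        )
    else:
        center = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    ids = np.concatenate(
        [
            bins.bin_id(chrom, center[df["chrom"].to_numpy() == chrom])
            for chrom in pd.unique(df["chrom"])
        ]
    )
    ids = np.unique(ids)
    table = pd.DataFrame({"bin_id": ids})
    starts = bins.bin_start(ids)
    chroms = bins.chrom_of(ids)
    lengths = np.array([bins.chromsizes[c] for c in chroms])
    table["chrom"] = chroms
    table["start"] = starts
    table["position"] = starts / lengths
    for name, track in (score_tracks or {}).items():
        table[name] = track.values[ids]
    return SiteSet(label=label, table=table)


# ---------------------------------------------------------------------------
# quartile partitioning


@dataclass
class Partition:
    """Top/bottom quartile bin ids under a ranking score."""

    ranking: str
    top: np.ndarray
    bottom: np.ndarray

    def __post_init__(self):
        if set(self.top) & set(self.bottom):
            raise ValueError("top and bottom quartiles overlap")


def partition_quartiles(sites: SiteSet, ranking: str) -> Partition:
    """Rank sites by ``ranking`` descending (ties broken by genomic
    coordinate ascending) and return the first and last ``floor(n/4)``."""
    tbl = sites.table
    if ranking not in tbl.columns:
        raise ValueError(f"no score column {ranking!r} on site set {sites.label!r}")
    scored = tbl[np.isfinite(tbl[ranking].to_numpy(dtype=float))]
    if len(scored) < 8:
        raise ValueError(f"only {len(scored)} scored sites; need at least 8")
    ordered = scored.sort_values(
        [ranking, "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    )
    q = len(ordered) // 4
    return Partition(
        ranking=ranking,
        top=ordered["bin_id"].to_numpy()[:q],
        bottom=ordered["bin_id"].to_numpy()[-q:],
    )


# ---------------------------------------------------------------------------
# enrichment summaries


def enrichment_summary(
    partition: Partition,
    sites: SiteSet,
    variables: dict[str, BinnedTrack],
    valid: np.ndarray | None = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Log fold enrichment of each variable per site group + top-vs-bottom test.

    For each variable and each group (all sites / top quartile / bottom
    quartile): ``log2(group mean / genome-wide median over valid bins)``.
    When the genome median is 0 the genome mean is used instead (flagged in
    the ``baseline`` column).  Top-vs-bottom difference is a two-sided
    Wilcoxon rank-sum test, Bonferroni-corrected over variables
    (``p_adj = min(1, m * p)``) and flagged at ``p_adj < alpha``.
    """
    m = len(variables)
    groups = {"all": sites.bin_ids, "top": partition.top, "bottom": partition.bottom}
    rows = []
    for name, track in variables.items():
        v = track.values
        genome = v[valid] if valid is not None else v
        genome = genome[np.isfinite(genome)]
        med = np.median(genome)
        baseline, base_value = ("median", med)
        if med == 0:
            baseline, base_value = ("mean", genome.mean())
        row = {"variable": name, "baseline": baseline}
        for gname, ids in groups.items():
            gv = v[ids]
            gv = gv[np.isfinite(gv)]
            mean = gv.mean() if gv.size else np.nan
            with np.errstate(invalid="ignore", divide="ignore"):
                lfe = np.log2(mean / base_value) if base_value != 0 else np.nan
            row[f"log_fold_{gname}"] = lfe if np.isfinite(lfe) else np.nan
        top_v = v[partition.top]
        bot_v = v[partition.bottom]
        top_v = top_v[np.isfinite(top_v)]
        bot_v = bot_v[np.isfinite(bot_v)]
        if top_v.size and bot_v.size:
            stat, p = ranksums(top_v, bot_v)
        else:
            stat, p = np.nan, np.nan
        p_adj = min(1.0, m * p) if np.isfinite(p) else np.nan
        row.update(
            {"stat": stat, "p": p, "p_adj": p_adj,
             "significant": bool(np.isfinite(p_adj) and p_adj < alpha)}
        )
        rows.append(row)
    return pd.DataFrame(rows)


def state_conditioned_scores(
    sites: SiteSet,
    chromhmm_tracks: dict[str, BinnedTrack],
    score: str,
    states: tuple[str, ...] = CHROMHMM_STATES,
) -> dict[str, np.ndarray]:
    """Score distributions of sites grouped by each site's plurality
    chromatin state (largest overlap fraction; ties resolve to the first
    state in the declared order; fully missing segmentation -> "unassigned")."""
    ids = sites.bin_ids
    overlaps = np.vstack([chromhmm_tracks[s].values[ids] for s in states])
    scores = sites.table[score].to_numpy(dtype=float)
    out: dict[str, list] = {s: [] for s in states}
    out["unassigned"] = []
    finite_any = np.isfinite(overlaps).any(axis=0)
    best = np.nanargmax(np.where(np.isfinite(overlaps), overlaps, -1.0), axis=0)
    for i in range(len(ids)):
        key = states[best[i]] if finite_any[i] else "unassigned"
        out[key].append(scores[i])
    return {k: np.array(v) for k, v in out.items()}
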