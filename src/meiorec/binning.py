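"""Genome tiling and interval-to-bin mapping.

Every dataset in the pipeline — ChIP-seq signal, peak sets, chromatin-state
segmentations, crossover intervals and Hi-C matrices — is projected onto a
single fixed-width tiling of the genome (5-kb bins by default).  This module
owns that tiling (:class:`BinTable`), the per-bin value container
(:class:`BinnedTrack`) and the three projection operations:

* bedGraph signal  -> per-bin **maximum** score (``signal_max``),
* BED features     -> per-bin **covered fraction** after merging (``coverage``),
* ChromHMM BED4    -> one covered-fraction track per chromatin state.

Coordinates are 0-based half-open throughout (BED convention).  Missing
signal is NaN, never 0; coverage of an absent feature is genuinely 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Chromatin-state labels of the seven-state mouse testis segmentation, in the
#: declared tie-break order.  Active states first, then unmarked/repressed.
CHROMHMM_STATES = (
    "H3K4me3",            # promoters
    "H3K4me1_3",          # promoters/enhancers
    "H3K4me1",            # enhancers
    "H3K4me1_H3K36me3",   # enhancers/gene bodies
    "H3K36me3",           # gene bodies
    "unmarked",
    "H3K27me3",           # repressed / polycomb
)

#: States used as the default "active chromatin" reference when orienting
#: compartment eigenvectors (promoter + gene-body flavoured states).
ACTIVE_STATES = ("H3K4me3", "H3K4me1_3", "H3K4me1_H3K36me3", "H3K36me3")

#: States counted as gene bodies when penalising crossover formation.
GENE_BODY_STATES = ("H3K36me3", "H3K4me1_H3K36me3")


class BinTable:
    """Ordered tiling of a genome into fixed-width bins with global indices.

    Parameters
    ----------
    chromsizes
        Mapping chromosome name -> length in bp, in the desired order.
    bin_size
        Bin width in bp; the last bin of each chromosome may be truncated.
    """

    def __init__(self, chromsizes: dict[str, int], bin_size: int):
        if bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {bin_size}")
        names = list(chromsizes)
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in chromsizes")
        for name, length in chromsizes.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {name}: {length}")
        self.chromsizes: dict[str, int] = {k: int(v) for k, v in chromsizes.items()}
        self.bin_size = int(bin_size)
        self._offsets: dict[str, int] = {}
        self._nbins: dict[str, int] = {}
        off = 0
        for name, length in self.chromsizes.items():
            n = -(-length // bin_size)  # ceil division
            self._offsets[name] = off
            self._nbins[name] = n
            off += n
        self.n_bins = off

    # -- structure -----------------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self.chromsizes)

    def chrom_offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def chrom_nbins(self, chrom: str) -> int:
        return self._nbins[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        off = self._offsets[chrom]
        return slice(off, off + self._nbins[chrom])

    def bin_id(self, chrom, pos):
        """Global bin index containing position(s) ``pos`` on ``chrom``."""
        pos = np.asarray(pos)
        length = self.chromsizes[chrom]
        if np.any(pos < 0) or np.any(pos >= length):
            raise ValueError(f"position out of bounds on {chrom} (length {length})")
        return self._offsets[chrom] + pos // self.bin_size

    def bin_start(self, bin_ids) -> np.ndarray:
        """Genomic start coordinate of each global bin id."""
        return (np.asarray(bin_ids) - self._chrom_offset_of(bin_ids)) * self.bin_size

    def chrom_of(self, bin_ids) -> np.ndarray:
        edges = np.array([self._offsets[c] for c in self.chroms] + [self.n_bins])
        idx = np.searchsorted(edges, np.asarray(bin_ids), side="right") - 1
        return np.array(self.chroms, dtype=object)[idx]

    def _chrom_offset_of(self, bin_ids) -> np.ndarray:
        edges = np.array([self._offsets[c] for c in self.chroms] + [self.n_bins])
        idx = np.searchsorted(edges, np.asarray(bin_ids), side="right") - 1
        return edges[idx]

    def to_frame(self) -> pd.DataFrame:
        """Bin table as a BED-like DataFrame (chrom, start, end, bin_id)."""
        rows = []
        for chrom, length in self.chromsizes.items():
            n = self._nbins[chrom]
            starts = np.arange(n) * self.bin_size
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        df = pd.concat(rows, ignore_index=True)
        df["bin_id"] = np.arange(len(df))
        return df

    def __eq__(self, other):
        return (
            isinstance(other, BinTable)
            and self.chromsizes == other.chromsizes
            and self.bin_size == other.bin_size
        )

    def __repr__(self):
        return (
            f"BinTable({len(self.chromsizes)} chroms, bin_size={self.bin_size}, "
            f"n_bins={self.n_bins})"
        )


@dataclass
class BinnedTrack:
    """One value per genomic bin for a named variable.

    ``kind`` is one of ``signal_max`` (per-bin maximum of a signal track),
    ``coverage`` (fraction of the bin covered, in [0, 1]), ``score`` (derived
    quantity) or ``state_overlap``.  NaN marks missing data.
    """

    name: str
    values: np.ndarray
    kind: str = "score"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind in ("coverage", "state_overlap"):
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
                raise ValueError(f"{self.kind} track '{self.name}' outside [0,1]")

    def __len__(self):
        return len(self.values)


@dataclass
class CrossoverEvent:
    """A single resolved crossover with its resolution interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty crossover interval {self.chrom}:{self.start}-{self.end}")


# ---------------------------------------------------------------------------
# tiling


def make_bins(chromsizes: dict[str, int], bin_size: int) -> BinTable:
    """Tile each chromosome with ``ceil(length / bin_size)`` fixed-width bins."""
    return BinTable(chromsizes, bin_size)


# ---------------------------------------------------------------------------
# interval -> bin projections


def _check_bounds(df: pd.DataFrame, bins: BinTable):
    for chrom, grp in df.groupby("chrom", sort=False):
        if chrom not in bins.chromsizes:
            raise ValueError(f"unknown chromosome {chrom!r}")
        length = bins.chromsizes[chrom]
        bad = grp[(grp["start"] < 0) | (grp["end"] > length) | (grp["end"] <= grp["start"])]
        if len(bad):
            row = bad.iloc[0]
            raise ValueError(
                f"interval {row['chrom']}:{row['start']}-{row['end']} outside "
                f"chromosome bounds (length {length}) or empty"
            )


def map_bedgraph_to_bins(track: pd.DataFrame, bins: BinTable, name: str = "signal") -> BinnedTrack:
    """Per-bin maximum score of a bedGraph track; bins untouched stay NaN.

    An interval crossing a bin boundary contributes its score to every bin it
    overlaps (half-open semantics: [4999, 5001) touches both flanking 5-kb
    bins).
    """
    df = track.reset_index(drop=True)
    _check_bounds(df, bins)
    values = np.full(bins.n_bins, np.nan)
    bs = bins.bin_size
    for chrom, grp in df.groupby("chrom", sort=False):
        off = bins.chrom_offset(chrom)
        start_bin = off + grp["start"].to_numpy() // bs
        end_bin = off + (grp["end"].to_numpy() - 1) // bs
        counts = end_bin - start_bin + 1
        bin_ids = np.repeat(start_bin, counts) + _ragged_arange(counts)
        scores = np.repeat(grp["score"].to_numpy(dtype=float), counts)
        # initialise touched bins to -inf so max-accumulation sees a floor,
        # while untouched bins keep NaN (missing, not zero)
        tgt = np.unique(bin_ids)
        values[tgt[np.isnan(values[tgt])]] = -np.inf
        np.maximum.at(values, bin_ids, scores)
    return BinnedTrack(name=name, values=values, kind="signal_max")


def _ragged_arange(counts: np.ndarray) -> np.ndarray:
    """Concatenate ``arange(c)`` for each c in counts."""
    total = int(counts.sum())
    out = np.ones(total, dtype=np.int64)
    out[0] = 0
    ends = np.cumsum(counts)[:-1]
    out[ends] = -(counts[:-1] - 1)
    return np.cumsum(out)


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping/touching half-open intervals (returns sorted, disjoint)."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    keep_s, keep_e = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] <= keep_e[-1]:
            keep_e[-1] = max(keep_e[-1], e[i])
        else:
            keep_s.append(s[i])
            keep_e.append(e[i])
    return np.array(keep_s), np.array(keep_e)


def map_bed_coverage_to_bins(
    features: pd.DataFrame, bins: BinTable, name: str = "coverage"
) -> BinnedTrack:
    """Fraction of each bin covered by the (merged) feature set."""
    df = features.reset_index(drop=True)
    _check_bounds(df, bins)
    covered = np.zeros(bins.n_bins)
    bs = bins.bin_size
    for chrom, grp in df.groupby("chrom", sort=False):
        off = bins.chrom_offset(chrom)
        s, e = merge_intervals(grp["start"].to_numpy(), grp["end"].to_numpy())
        start_bin = s // bs
        end_bin = (e - 1) // bs
        counts = end_bin - start_bin + 1
        bin_local = np.repeat(start_bin, counts) + _ragged_arange(counts)
        lo = np.maximum(np.repeat(s, counts), bin_local * bs)
        hi = np.minimum(np.repeat(e, counts), (bin_local + 1) * bs)
        np.add.at(covered, off + bin_local, hi - lo)
    widths = np.empty(bins.n_bins)
    for chrom in bins.chroms:
        sl = bins.chrom_slice(chrom)
        n = bins.chrom_nbins(chrom)
        w = np.full(n, bs, dtype=float)
        w[-1] = bins.chromsizes[chrom] - (n - 1) * bs
        widths[sl] = w
    return BinnedTrack(name=name, values=covered / widths, kind="coverage")


def chromhmm_overlap_tracks(
    segmentation: pd.DataFrame, bins: BinTable, states: tuple[str, ...] = CHROMHMM_STATES
) -> dict[str, BinnedTrack]:
    """Per-state covered fraction of each bin for a BED4 segmentation.

    For a genome-covering segmentation the per-bin fractions sum to 1 across
    states.
    """
    unknown = set(segmentation["state"]) - set(states)
    if unknown:
        raise ValueError(f"unknown ChromHMM state label(s): {sorted(unknown)}")
    out = {}
    for state in states:
        sub = segmentation[segmentation["state"] == state][["chrom", "start", "end"]]
        out[state] = map_bed_coverage_to_bins(sub, bins, name=state)
        out[state].kind = "state_overlap"
    return out


# ---------------------------------------------------------------------------
# readers / writers (plain-text genomic formats)


def read_chromsizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def write_chromsizes(chromsizes: dict[str, int], path):
    with open(path, "w") as fh:
        for name, length in chromsizes.items():
            fh.write(f"{name}\t{length}\n")


def read_bed(path) -> pd.DataFrame:
    """BED3+ / narrowPeak reader.

    Returns columns chrom, start, end and, when present, score (column 5 for
    BED6+/narrowPeak, column 4 for BED4 with a numeric 4th field) and summit
    (narrowPeak column 10, -1 meaning absent).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    ncol = df.shape[1]
    out = pd.DataFrame(
        {"chrom": df[0], "start": df[1].astype(int), "end": df[2].astype(int)}
    )
    if ncol >= 5:
        out["name"] = df[3]
        out["score"] = pd.to_numeric(df[4], errors="coerce")
    elif ncol == 4:
        as_num = pd.to_numeric(df[3], errors="coerce")
        if as_num.notna().all():
            out["score"] = as_num
        else:
            out["state"] = df[3].astype(str)
    if ncol >= 10:  # narrowPeak: col 7 = signalValue, col 10 = summit offset
        out["signal"] = pd.to_numeric(df[6], errors="coerce")
        out["summit"] = df[9].astype(int)
    return out


def write_bed(df: pd.DataFrame, path, extra_cols: list[str] | None = None):
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "score"],
        dtype={"chrom": str},
    )
    return df


def write_bedgraph(track: BinnedTrack, bins: BinTable, path):
    """Write a BinnedTrack as bedGraph, skipping NaN bins."""
    frame = bins.to_frame()
    frame["score"] = track.values
    frame = frame[np.isfinite(frame["score"])]
    frame[["chrom", "start", "end", "score"]].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph_track(path, bins: BinTable, name: str) -> BinnedTrack:
    """Read a bin-aligned bedGraph back into a BinnedTrack (round-trip of
    :func:`write_bedgraph`); non-aligned input goes through
    :func:`map_bedgraph_to_bins` instead."""
    df = read_bedgraph(path)
    values = np.full(bins.n_bins, np.nan)
    for chrom, grp in df.groupby("chrom", sort=False):
        ids = bins.bin_id(chrom, grp["start"].to_numpy())
        values[ids] = grp["score"].to_numpy()
    return BinnedTrack(name=name, values=values)
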