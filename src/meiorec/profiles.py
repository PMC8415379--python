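"""Site-centered average profiles and contact-map pileups.

Sites are unoriented, so every per-site window is averaged with its reversal
(symmetric averaging) before aggregation; profiles are therefore exactly
mirror-symmetric about the site.  Confidence intervals come from a seeded
1000-resample bootstrap over sites (percentile 2.5/97.5).  Contact pileups
are observed/expected-normalized per chromosome before averaging, so a
matrix equal to its own expected-by-distance profile piles up to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binning import BinnedTrack
from .contacts import ContactMatrix
from .recombination import SiteSet


@dataclass
class Profile:
    """Symmetric-averaged per-offset means with bootstrap CIs."""

    offsets: np.ndarray          # bp offsets, -flank..+flank in bin steps
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_sites: int
    n_dropped: int               # sites too close to a chromosome end
    site_windows: np.ndarray | None = None  # (n_sites, 2F+1), post-symmetrization


@dataclass
class PileupMatrix:
    """Mean O/E contact submatrix centered on sites."""

    offsets: np.ndarray
    mean: np.ndarray             # (2F+1, 2F+1)
    n_per_cell: np.ndarray
    n_sites: int
    n_skipped: int


def _site_windows(values: np.ndarray, sites: SiteSet, flank: int, bins):
    """Per-site windows of a global per-bin array, restricted to sites at
    least ``flank`` bins from both chromosome ends."""
    kept, windows = [], []
    for chrom in bins.chroms:
        sl = bins.chrom_slice(chrom)
        n = bins.chrom_nbins(chrom)
        local = sites.bin_ids[(sites.bin_ids >= sl.start) & (sites.bin_ids < sl.stop)] - sl.start
        ok = (local >= flank) & (local < n - flank)
        for b in local[ok]:
            windows.append(values[sl][b - flank : b + flank + 1])
        kept.append(ok.sum())
    dropped = len(sites) - int(sum(kept))
    if not windows:
        raise ValueError("no sites retained after flank filtering")
    return np.vstack(windows), dropped


def _boot_means(stack: np.ndarray, n_boot: int, rng) -> np.ndarray:
    """Bootstrap-resampled column nanmeans over rows (sites).

    Resampling is done with per-row multinomial weights (equivalent in
    distribution to index resampling) so memory stays O(n_boot * n).
    """
    n = stack.shape[0]
    weights = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot).astype(float)
    sums = weights @ np.nan_to_num(stack)
    cnts = weights @ np.isfinite(stack).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return sums / cnts


def _bootstrap_ci(stack: np.ndarray, n_boot: int, seed: int):
    """Percentile bootstrap CI over rows (sites) of the column nanmeans."""
    boots = _boot_means(stack, n_boot, np.random.default_rng(seed))
    return np.nanpercentile(boots, 2.5, axis=0), np.nanpercentile(boots, 97.5, axis=0)


def pileup_track(
    track: BinnedTrack,
    sites: SiteSet,
    bins,
    flank_bins: int,
    n_boot: int = 1000,
    seed: int = 0,
) -> Profile:
    """Symmetric-averaged profile of ``track`` around site centers.

    Each site's window is averaged with its own reversal before the
    across-site mean, so ``mean[k] == mean[-k]`` exactly.  Missing bins are
    ignored per offset.
    """
    stack, dropped = _site_windows(track.values, sites, flank_bins, bins)
    stack = 0.5 * (stack + stack[:, ::-1])
    mean = np.nanmean(stack, axis=0)
    lo, hi = _bootstrap_ci(stack, n_boot, seed)
    offsets = np.arange(-flank_bins, flank_bins + 1) * bins.bin_size
    return Profile(
        offsets=offsets,
        mean=mean,
        ci_lo=lo,
        ci_hi=hi,
        n_sites=stack.shape[0],
        n_dropped=dropped,
        site_windows=stack,
    )


def expected_by_distance(cm: ContactMatrix, chrom: str) -> np.ndarray:
    """Mean balanced contact per separation over valid pairs (length n)."""
    from .contacts import diagonal_sums

    sums, counts = diagonal_sums(cm.matrices[chrom], cm.chrom_valid(chrom))
    with np.errstate(invalid="ignore", divide="ignore"):
        exp = sums / counts
    exp[counts == 0] = np.nan
    return exp


def pileup_matrix(
    cm: ContactMatrix, sites: SiteSet, flank_bins: int
) -> PileupMatrix:
    """Mean observed/expected contact submatrix centered on sites.

    Per site: extract the (2F+1)^2 balanced cis submatrix, divide each cell
    by the chromosome's expected contact at that cell's separation,
    symmetrize (average with the 180-degree rotation), then average across
    sites ignoring masked cells.  Sites on masked bins or too close to a
    chromosome end are skipped and counted.
    """
    F = flank_bins
    size = 2 * F + 1
    acc = np.zeros((size, size))
    cnt = np.zeros((size, size), dtype=np.int64)
    n_used = 0
    n_skipped = 0
    bins = cm.bins
    for chrom in bins.chroms:
        sl = bins.chrom_slice(chrom)
        n = bins.chrom_nbins(chrom)
        local = sites.bin_ids[(sites.bin_ids >= sl.start) & (sites.bin_ids < sl.stop)] - sl.start
        if local.size == 0:
            continue
        valid = cm.chrom_valid(chrom)
        exp = expected_by_distance(cm, chrom)
        exp = np.where(exp > 0, exp, np.nan)  # zero-expected separations drop out
        m = cm.matrices[chrom]
        sep = np.abs(np.subtract.outer(np.arange(size), np.arange(size)))
        for b in local:
            if b < F or b >= n - F or not valid[b]:
                n_skipped += 1
                continue
            idx = np.arange(b - F, b + F + 1)
            sub = m[idx][:, idx].toarray()
            with np.errstate(invalid="ignore", divide="ignore"):
                oe = sub / exp[sep]
            vv = np.outer(valid[idx], valid[idx])
            oe[~vv] = np.nan
            oe = 0.5 * (oe + oe[::-1, ::-1])
            good = np.isfinite(oe)
            acc[good] += oe[good]
            cnt += good
            n_used += 1
    if n_used == 0:
        raise ValueError("no usable sites for matrix pileup")
    mean = np.full((size, size), np.nan)
    nz = cnt > 0
    mean[nz] = acc[nz] / cnt[nz]
    offsets = np.arange(-F, F + 1) * bins.bin_size
    return PileupMatrix(offsets=offsets, mean=mean, n_per_cell=cnt, n_sites=n_used,
                        n_skipped=n_skipped)


def compare_profiles(
    top: Profile, bottom: Profile, n_boot: int = 1000, seed: int = 0
) -> dict:
    """Per-offset difference of two profiles with a bootstrap CI.

    Both profiles must carry their per-site windows and share the same
    flank.  Summary reports the difference at offset 0 and the mean over
    |offset| <= 10 bins.
    """
    if top.offsets.shape != bottom.offsets.shape or (top.offsets != bottom.offsets).any():
        raise ValueError("profiles have mismatched flanks")
    if top.site_windows is None or bottom.site_windows is None:
        raise ValueError("profiles must retain per-site windows")
    diff = top.mean - bottom.mean
    rng = np.random.default_rng(seed)
    boots = _boot_means(top.site_windows, n_boot, rng) - _boot_means(
        bottom.site_windows, n_boot, rng
    )
    lo = np.nanpercentile(boots, 2.5, axis=0)
    hi = np.nanpercentile(boots, 97.5, axis=0)
    center = len(diff) // 2
    zoom = max(0, center - 10), min(len(diff), center + 11)
    return {
        "offsets": top.offsets,
        "difference": diff,
        "ci_lo": lo,
        "ci_hi": hi,
        "at_center": diff[center],
        "mean_within_10_bins": float(np.nanmean(diff[zoom[0] : zoom[1]])),
        "center_ci": (lo[center], hi[center]),
    }
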