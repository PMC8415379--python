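"""Hi-C derived genome-wide scores.

All metrics consume a :class:`~meiorec.contacts.ContactMatrix` and emit
:class:`~meiorec.binning.BinnedTrack`s (or :class:`PsCurve`s):

* **cis/total ratio** — per-bin fraction of contacts that are
  intra-chromosomal; low values mark spatially accessible chromatin.
* **fine-grain compartment score** — leading eigenvector of the
  observed/expected correlation structure computed in 10-Mb diagonal chunks,
  needed because meiotic maps lose long-range signal too quickly for
  whole-chromosome eigendecomposition.  Positive = A (active) by orientation
  against an activity reference track.
* **insulation score** — log2 ratio of contacts crossing each locus within a
  diamond window to the chromosome-wide mean; minima mark domain boundaries.
* **FIRE score** — z-scored near-range (15–200 kb) cis contact frequency, a
  reimplementation of the FIRE statistic as a normalized local-interaction
  score.
* **P(s) curves** with optional compartment masking, and **loop-length
  estimates** as the maxima of d log P / d log s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import eigsh

from .binning import BinnedTrack
from .contacts import ContactMatrix, band_diagonals, diagonal_sums


# ---------------------------------------------------------------------------
# cis/total


def cis_total_ratio(cm: ContactMatrix, aggregation_bp: int | None = None) -> BinnedTrack:
    """Per-bin cis/(cis+trans) contact fraction, optionally pooled over a
    sliding coarse window before taking the ratio."""
    cis = cm.cis_raw.copy()
    trans = cm.trans_raw.copy()
    if aggregation_bp is not None:
        half = max(1, int(aggregation_bp // cm.bins.bin_size)) // 2
        k = 2 * half + 1
        kernel = np.ones(k)
        for chrom in cm.bins.chroms:
            sl = cm.bins.chrom_slice(chrom)
            v = cm.valid[sl].astype(float)
            cis[sl] = np.convolve(cm.cis_raw[sl] * v, kernel, mode="same")
            trans[sl] = np.convolve(cm.trans_raw[sl] * v, kernel, mode="same")
    total = cis + trans
    values = np.full(cm.bins.n_bins, np.nan)
    ok = cm.valid & (total > 0)
    zero = cm.valid & (total == 0)
    if zero.any():
        warnings.warn(f"{zero.sum()} valid bins with zero total contacts; left missing")
    values[ok] = cis[ok] / total[ok]
    return BinnedTrack(name="cis_total", values=values, kind="score")


# ---------------------------------------------------------------------------
# fine-grain compartment eigenvectors


def _oe_normalize(m: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Divide each diagonal by its mean over valid entries (in place copy)."""
    n = m.shape[0]
    out = np.array(m, dtype=float)
    vv = np.outer(valid, valid)
    for d in range(n):
        idx = np.arange(n - d)
        vals = out[idx, idx + d]
        ok = vv[idx, idx + d]
        mu = vals[ok].mean() if ok.any() else np.nan
        if not np.isfinite(mu) or mu == 0:
            continue
        out[idx, idx + d] = vals / mu
        out[idx + d, idx] = out[idx, idx + d]
    return out


def _chunk_bounds(n: int, chunk_bins: int, min_bins: int) -> list[tuple[int, int]]:
    """Split ``n`` bins into chunks of ``chunk_bins``; a short tail chunk
    (< ``min_bins``) is merged into the previous one."""
    bounds = []
    start = 0
    while start < n:
        stop = min(start + chunk_bins, n)
        bounds.append((start, stop))
        start = stop
    if len(bounds) > 1 and bounds[-1][1] - bounds[-1][0] < min_bins:
        last = bounds.pop()
        prev = bounds.pop()
        bounds.append((prev[0], last[1]))
    return bounds


def fine_grain_compartment(
    cm: ContactMatrix,
    reference: BinnedTrack,
    chunk_bp: int = 10_000_000,
    min_chunk_bp: int = 2_000_000,
    min_valid_bins: int = 20,
    eig_bin_bp: int | None = 100_000,
    min_ev_fraction: float = 0.1,
) -> BinnedTrack:
    """Compartment score from per-chunk eigendecomposition.

    Each ``chunk_bp`` diagonal chunk of a chromosome's balanced cis matrix is
    aggregated to ``eig_bin_bp`` cells (per-pair counts at fine resolution
    are too sparse for a stable eigenvector; set ``eig_bin_bp=None`` to stay
    at matrix resolution), observed/expected-normalized, converted to a
    correlation matrix, and reduced to its leading eigenvector.  The
    eigenvector is scaled to unit variance, sign-oriented so its correlation
    with ``reference`` (an activity proxy such as active-state coverage) is
    non-negative, projected back onto the member bins, and the chunks are
    concatenated.

    Chunks whose leading eigenvalue explains less than ``min_ev_fraction``
    of the correlation-matrix trace show no checkerboard structure (e.g. a
    compartment-homogeneous region) and are reported missing.
    """
    if len(reference.values) != cm.bins.n_bins:
        raise ValueError("reference track not aligned with bins")
    score = np.full(cm.bins.n_bins, np.nan)
    chunk_bins = max(1, int(chunk_bp // cm.bins.bin_size))
    min_bins = max(1, int(min_chunk_bp // cm.bins.bin_size))
    factor = 1
    if eig_bin_bp is not None:
        factor = max(1, int(eig_bin_bp // cm.bins.bin_size))
    for chrom in cm.bins.chroms:
        sl = cm.bins.chrom_slice(chrom)
        mat = cm.matrices[chrom]
        valid = cm.chrom_valid(chrom)
        for lo, hi in _chunk_bounds(mat.shape[0], chunk_bins, min_bins):
            nf = hi - lo
            v = valid[lo:hi]
            if v.sum() < min_valid_bins:
                warnings.warn(
                    f"{chrom}:{lo}-{hi}: only {int(v.sum())} valid bins; compartment "
                    "score left missing"
                )
                continue
            sub = mat[lo:hi, lo:hi].toarray()
            sub[~v, :] = 0.0
            sub[:, ~v] = 0.0
            # aggregate fine bins into eigendecomposition cells
            nc = -(-nf // factor)
            group = np.arange(nf) // factor
            agg = np.zeros((nc, nf))
            agg[group, np.arange(nf)] = 1.0
            coarse = agg @ sub @ agg.T
            vc = (agg @ v.astype(float)) > 0
            oe = _oe_normalize(coarse, vc)[np.ix_(vc, vc)]
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(oe)
            corr[~np.isfinite(corr)] = 0.0
            eigval, ev = _leading_eigenvector(corr)
            if eigval / corr.shape[0] < min_ev_fraction:
                warnings.warn(
                    f"{chrom}:{lo}-{hi}: no compartment structure (leading "
                    f"eigenvalue fraction {eigval / corr.shape[0]:.3f}); missing"
                )
                continue
            sd = ev.std()
            if sd > 0:
                ev = ev / sd
            # orient against the reference aggregated to the same cells
            ref_fine = reference.values[sl][lo:hi]
            with np.errstate(invalid="ignore"):
                ref_coarse = np.array(
                    [np.nanmean(ref_fine[group == g]) for g in range(nc)]
                )[vc]
            ok = np.isfinite(ref_coarse)
            if ok.sum() >= 2 and np.std(ref_coarse[ok]) > 0 and np.std(ev[ok]) > 0:
                if np.corrcoef(ev[ok], ref_coarse[ok])[0, 1] < 0:
                    ev = -ev
            ev_full = np.full(nc, np.nan)
            ev_full[vc] = ev
            vals = ev_full[group]          # project back onto member bins
            vals[~v] = np.nan
            score[sl.start + lo : sl.start + hi] = vals
    return BinnedTrack(name="compartment", values=score, kind="score")


def _leading_eigenvector(corr: np.ndarray) -> tuple[float, np.ndarray]:
    """Largest eigenvalue and its eigenvector of a symmetric matrix."""
    n = corr.shape[0]
    if n <= 3:
        w, u = np.linalg.eigh(corr)
        return float(w[-1]), u[:, -1]
    # fixed non-constant start vector: deterministic, and never annihilated
    # by matrices whose row sums vanish (e.g. balanced two-group structure)
    v0 = np.random.default_rng(0).random(n) + 0.5
    w, u = eigsh(corr, k=1, which="LA", v0=v0)
    return float(w[0]), u[:, 0]


# ---------------------------------------------------------------------------
# insulation


def insulation_score(cm: ContactMatrix, window_bp: int = 100_000) -> BinnedTrack:
    """Diamond-window insulation: log2 of the mean contact in the
    ``window x window`` square spanning each bin's diagonal position, divided
    by the chromosome-wide mean of that statistic."""
    bs = cm.bins.bin_size
    if window_bp % bs:
        raise ValueError("window must be a multiple of the bin size")
    w = window_bp // bs
    values = np.full(cm.bins.n_bins, np.nan)
    for chrom in cm.bins.chroms:
        sl = cm.bins.chrom_slice(chrom)
        n = cm.bins.chrom_nbins(chrom)
        if n <= 2 * w:
            warnings.warn(f"window {window_bp} too large for {chrom}; all missing")
            continue
        valid = cm.chrom_valid(chrom).astype(float)
        band = band_diagonals(cm.matrices[chrom], 2 * w)
        sums = np.zeros(n)
        counts = np.zeros(n)
        for d in range(1, 2 * w):
            vals = band[d, : n - d] * valid[: n - d] * valid[d:]
            vcnt = valid[: n - d] * valid[d:]
            cs = np.concatenate([[0.0], np.cumsum(vals)])
            cc = np.concatenate([[0.0], np.cumsum(vcnt)])
            b = np.arange(w, n - w)
            lo = b - min(w, d)
            hi = b - max(0, d - w)  # exclusive upper index into i-range
            sums[w : n - w] += cs[hi] - cs[lo]
            counts[w : n - w] += cc[hi] - cc[lo]
        means = np.full(n, np.nan)
        interior = np.arange(w, n - w)
        ok = counts[interior] > 0
        means[interior[ok]] = sums[interior[ok]] / counts[interior[ok]]
        means[~cm.chrom_valid(chrom)] = np.nan
        gmean = np.nanmean(means)
        if np.isfinite(gmean) and gmean > 0:
            with np.errstate(invalid="ignore", divide="ignore"):
                values[sl] = np.log2(means / gmean)
            values[sl][np.isinf(values[sl])] = np.nan
    return BinnedTrack(name="insulation", values=values, kind="score")


# ---------------------------------------------------------------------------
# FIRE


def fire_score(
    cm: ContactMatrix, near_lo: int = 15_000, near_hi: int = 200_000
) -> BinnedTrack:
    """Near-range interaction z-score (FIRE-style).

    Per valid bin: total balanced cis contact with partners at separations in
    ``[near_lo, near_hi]``, divided by the number of valid partners in range
    (removing the end-of-chromosome and masked-neighbour bias), then z-scored
    per chromosome.
    """
    if near_lo >= near_hi:
        raise ValueError("near_lo must be < near_hi")
    bs = cm.bins.bin_size
    d_lo = max(1, -(-near_lo // bs))
    d_hi = max(d_lo, near_hi // bs)
    values = np.full(cm.bins.n_bins, np.nan)
    for chrom in cm.bins.chroms:
        sl = cm.bins.chrom_slice(chrom)
        n = cm.bins.chrom_nbins(chrom)
        valid = cm.chrom_valid(chrom).astype(float)
        band = band_diagonals(cm.matrices[chrom], d_hi)
        sums = np.zeros(n)
        counts = np.zeros(n)
        for d in range(d_lo, d_hi + 1):
            pair_v = valid[: n - d] * valid[d:]
            vals = band[d, : n - d] * pair_v
            sums[: n - d] += vals
            sums[d:] += vals
            counts[: n - d] += pair_v
            counts[d:] += pair_v
        ok = cm.chrom_valid(chrom) & (counts > 0)
        rate = np.full(n, np.nan)
        rate[ok] = sums[ok] / counts[ok]
        mu = np.nanmean(rate)
        sd = np.nanstd(rate)
        z = np.full(n, np.nan)
        if np.isfinite(mu):
            z[ok] = (rate[ok] - mu) / sd if sd > 0 else 0.0
        values[sl] = z
    return BinnedTrack(name="fire", values=values, kind="score")


# ---------------------------------------------------------------------------
# P(s) and loop lengths


@dataclass
class PsCurve:
    """Contact probability vs genomic separation on a log-spaced grid."""

    edges: np.ndarray      # distance-bin edges, bp, strictly increasing
    s_mid: np.ndarray      # geometric midpoints
    p: np.ndarray          # normalized mean contact per distance bin (NaN = missing)
    deriv: np.ndarray      # d log P / d log s on the smoothed curve
    n_pairs: np.ndarray    # valid bin-pair count per distance bin
    mask: str = "none"


def _nan_moving_average(x: np.ndarray, k: int) -> np.ndarray:
    """Centered moving average ignoring NaN."""
    half = k // 2
    out = np.full_like(x, np.nan)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        window = x[lo:hi]
        good = np.isfinite(window)
        if good.any():
            out[i] = window[good].mean()
    return out


def ps_curve(
    cm: ContactMatrix,
    mask: np.ndarray | None = None,
    mask_label: str = "none",
    log_ratio: float = 1.12,
    min_pairs: int = 100,
    smooth_bins: int = 5,
) -> PsCurve:
    """Genome-pooled contact probability versus separation.

    ``mask`` is an optional per-bin boolean (global indexing); a bin pair
    contributes only when both bins are valid and pass the mask.  Distance
    bins are log-spaced with edge ratio ``log_ratio``; bins with fewer than
    ``min_pairs`` kept pairs are missing.  P is normalized to 1 at the first
    populated distance bin.
    """
    bs = cm.bins.bin_size
    max_sep = max(cm.bins.chrom_nbins(c) for c in cm.bins.chroms)
    sums = np.zeros(max_sep)
    counts = np.zeros(max_sep, dtype=np.int64)
    for chrom in cm.bins.chroms:
        sl = cm.bins.chrom_slice(chrom)
        pm = None if mask is None else np.asarray(mask[sl], dtype=bool)
        s_c, n_c = diagonal_sums(cm.matrices[chrom], cm.chrom_valid(chrom), pm)
        sums[: len(s_c)] += s_c
        counts[: len(n_c)] += n_c

    edges = [bs]
    while edges[-1] < max_sep * bs:
        edges.append(edges[-1] * log_ratio)
    edges = np.array(edges)
    sep_bp = np.arange(max_sep, dtype=float) * bs  # separation d -> bp
    which = np.searchsorted(edges, sep_bp[1:], side="right") - 1
    nb = len(edges) - 1
    bin_sum = np.bincount(which, weights=sums[1:], minlength=nb)[:nb]
    bin_cnt = np.bincount(which, weights=counts[1:], minlength=nb)[:nb].astype(np.int64)
    p = np.full(nb, np.nan)
    ok = bin_cnt >= min_pairs
    p[ok] = bin_sum[ok] / bin_cnt[ok]
    if ok.any():
        first = np.flatnonzero(ok & (p > 0))
        if first.size:
            p = p / p[first[0]]
    s_mid = np.sqrt(edges[:-1] * edges[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log10(p)
    logp[~np.isfinite(logp)] = np.nan
    smoothed = _nan_moving_average(logp, smooth_bins)
    logs = np.log10(s_mid)
    deriv = np.full(nb, np.nan)
    for i in range(1, nb - 1):
        if np.isfinite(smoothed[i - 1]) and np.isfinite(smoothed[i + 1]):
            deriv[i] = (smoothed[i + 1] - smoothed[i - 1]) / (logs[i + 1] - logs[i - 1])
    return PsCurve(edges=edges, s_mid=s_mid, p=p, deriv=deriv, n_pairs=bin_cnt, mask=mask_label)


def loop_length_estimate(
    ps: PsCurve, search_range: tuple[float, float] = (100_000.0, 10_000_000.0)
) -> float | None:
    """Loop size as the distance of the largest interior local maximum of
    d log P / d log s inside ``search_range``; None when no local maximum
    exists (e.g. a pure power law)."""
    populated = np.isfinite(ps.p).sum()
    if populated < 10:
        warnings.warn(f"P(s) curve has only {populated} populated distance bins")
        return None
    d = ps.deriv
    best_s, best_v = None, -np.inf
    for i in range(1, len(d) - 1):
        if not (np.isfinite(d[i - 1]) and np.isfinite(d[i]) and np.isfinite(d[i + 1])):
            continue
        if not (search_range[0] <= ps.s_mid[i] <= search_range[1]):
            continue
        if d[i] > d[i - 1] and d[i] > d[i + 1]:
            # strict local maximum; ties between equal maxima resolve to the
            # smaller distance because only strictly larger values replace
            if d[i] > best_v:
                best_v = d[i]
                best_s = float(ps.s_mid[i])
    return best_s


def ps_curves_by_compartment(
    cm: ContactMatrix, compartment: np.ndarray, **kwargs
) -> dict[str, PsCurve]:
    """A-masked, B-masked and unmasked P(s) curves.

    ``compartment`` is per-bin: positive/True = A, non-positive/False = B;
    NaN bins are excluded from both masked curves.
    """
    comp = np.asarray(compartment, dtype=float)
    a_mask = comp > 0
    b_mask = np.isfinite(comp) & (comp <= 0)
    return {
        "A": ps_curve(cm, mask=a_mask, mask_label="A", **kwargs),
        "B": ps_curve(cm, mask=b_mask, mask_label="B", **kwargs),
        "none": ps_curve(cm, mask=None, mask_label="none", **kwargs),
    }
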