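"""Binned Hi-C contact container.

Cis contacts are held as one symmetric sparse matrix per chromosome over that
chromosome's bins; trans contacts are reduced to a per-bin total (the only
consumer is the cis/total ratio).  Matrices are assumed balanced on input; an
iterative-proportional balancing fallback is provided for raw counts.  Bins
with zero coverage (or that fail balancing) are masked and ignored by every
downstream metric.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .binning import BinTable


class ContactMatrix:
    """Per-chromosome balanced cis matrices + per-bin trans totals + mask.

    Attributes
    ----------
    bins : BinTable
    matrices : dict[str, scipy.sparse.csr_matrix]
        Symmetric balanced cis matrix per chromosome (local bin indexing).
    cis_raw, trans_raw : np.ndarray
        Raw per-bin cis row sums and trans totals (global bin indexing).
    valid : np.ndarray of bool
        Mask of usable bins (global indexing).
    """

    def __init__(self, bins: BinTable, matrices, cis_raw, trans_raw, valid=None):
        self.bins = bins
        self.matrices = {}
        for chrom, m in matrices.items():
            m = sp.csr_matrix(m)
            n = bins.chrom_nbins(chrom)
            if m.shape != (n, n):
                raise ValueError(f"matrix shape {m.shape} != bins for {chrom} ({n})")
            asym = abs(m - m.T)
            if asym.nnz and asym.max() > 1e-8 * max(m.max(), 1e-300):
                raise ValueError(f"cis matrix for {chrom} is not symmetric")
            self.matrices[chrom] = m
        self.cis_raw = np.asarray(cis_raw, dtype=float)
        self.trans_raw = np.asarray(trans_raw, dtype=float)
        if valid is None:
            valid = self.cis_raw + self.trans_raw > 0
        self.valid = np.asarray(valid, dtype=bool)
        for arr, label in [(self.cis_raw, "cis_raw"), (self.trans_raw, "trans_raw"),
                           (self.valid, "valid")]:
            if arr.shape != (bins.n_bins,):
                raise ValueError(f"{label} length {arr.shape} != n_bins {bins.n_bins}")
        if (self.cis_raw < 0).any() or (self.trans_raw < 0).any():
            raise ValueError("raw contact sums must be non-negative")

    def chrom_valid(self, chrom: str) -> np.ndarray:
        return self.valid[self.bins.chrom_slice(chrom)]

    def dense(self, chrom: str) -> np.ndarray:
        """Dense balanced cis matrix with masked rows/columns set to NaN."""
        m = self.matrices[chrom].toarray()
        bad = ~self.chrom_valid(chrom)
        m[bad, :] = np.nan
        m[:, bad] = np.nan
        return m

    # -- serialisation -------------------------------------------------------

    def to_triplets(self) -> pd.DataFrame:
        """Upper-triangle bin-pair triplets (global bin1_id <= bin2_id, value)."""
        frames = []
        for chrom, m in self.matrices.items():
            off = self.bins.chrom_offset(chrom)
            coo = sp.triu(m).tocoo()
            frames.append(
                pd.DataFrame(
                    {"bin1_id": off + coo.row, "bin2_id": off + coo.col, "count": coo.data}
                )
            )
        df = pd.concat(frames, ignore_index=True)
        return df.sort_values(["bin1_id", "bin2_id"], ignore_index=True)

    def write(self, triplets_path, bin_sums_path):
        self.to_triplets().to_csv(triplets_path, sep="\t", index=False)
        pd.DataFrame(
            {
                "bin_id": np.arange(self.bins.n_bins),
                "cis_raw": self.cis_raw,
                "trans_raw": self.trans_raw,
                "valid": self.valid.astype(int),
            }
        ).to_csv(bin_sums_path, sep="\t", index=False)

    @classmethod
    def from_triplets(
        cls,
        bins: BinTable,
        triplets: pd.DataFrame,
        trans_raw: np.ndarray | None = None,
        balance: bool = False,
    ) -> "ContactMatrix":
        """Build from upper-triangle triplets (global bin ids).

        Pairs crossing a chromosome boundary are rejected: trans contacts
        enter only via ``trans_raw`` per-bin totals.
        """
        b1 = triplets["bin1_id"].to_numpy()
        b2 = triplets["bin2_id"].to_numpy()
        val = triplets["count"].to_numpy(dtype=float)
        c1 = bins.chrom_of(b1)
        c2 = bins.chrom_of(b2)
        if (c1 != c2).any():
            raise ValueError("triplets contain inter-chromosomal pairs")
        matrices = {}
        cis_raw = np.zeros(bins.n_bins)
        for chrom in bins.chroms:
            sel = c1 == chrom
            off = bins.chrom_offset(chrom)
            n = bins.chrom_nbins(chrom)
            i = b1[sel] - off
            j = b2[sel] - off
            m = sp.coo_matrix((val[sel], (i, j)), shape=(n, n)).tocsr()
            m = m + sp.triu(m, k=1).T  # symmetrise from the upper triangle
            matrices[chrom] = m
            cis_raw[bins.chrom_slice(chrom)] = np.asarray(m.sum(axis=1)).ravel()
        if trans_raw is None:
            trans_raw = np.zeros(bins.n_bins)
        cm = cls(bins, matrices, cis_raw, trans_raw)
        if balance:
            cm = iterative_balance(cm)
        return cm

    @classmethod
    def read(cls, bins: BinTable, triplets_path, bin_sums_path, balance=False):
        trip = pd.read_csv(triplets_path, sep="\t")
        sums = pd.read_csv(bin_sums_path, sep="\t")
        cm = cls.from_triplets(bins, trip, sums["trans_raw"].to_numpy(), balance=balance)
        cm.valid &= sums["valid"].to_numpy().astype(bool)
        return cm


def iterative_balance(
    cm: ContactMatrix, n_iter: int = 50, tol: float = 1e-5, min_nnz: int = 1
) -> ContactMatrix:
    """Iterative-proportional (ICE-style) balancing of each cis matrix.

    Rescales rows/columns toward equal marginals; bins whose marginal is zero
    (fewer than ``min_nnz`` contacts) are masked.  Stops early once the
    variance of the nonzero marginals falls below ``tol``.
    """
    matrices = {}
    valid = cm.valid.copy()
    for chrom, m in cm.matrices.items():
        m = m.astype(float).tocsr(copy=True)
        sl = cm.bins.chrom_slice(chrom)
        marg = np.asarray(m.sum(axis=1)).ravel()
        good = marg >= min_nnz
        valid[sl] &= good
        d = sp.diags(np.where(good, 1.0, 0.0))
        m = d @ m @ d
        for _ in range(n_iter):
            marg = np.asarray(m.sum(axis=1)).ravel()
            nz = marg[good]
            if nz.size == 0 or np.var(nz / nz.mean()) < tol:
                break
            scale = np.where(good & (marg > 0), marg / nz.mean(), 1.0)
            inv = sp.diags(1.0 / np.sqrt(scale))
            m = inv @ m @ inv
        matrices[chrom] = m.tocsr()
    return ContactMatrix(cm.bins, matrices, cm.cis_raw, cm.trans_raw, valid)


def band_diagonals(m: sp.csr_matrix, max_sep: int) -> np.ndarray:
    """Band representation D[d, i] = M[i, i+d] for d in 0..max_sep.

    Out-of-range positions are zero.  Used for insulation and FIRE, which
    only touch near-diagonal contacts.
    """
    n = m.shape[0]
    band = np.zeros((max_sep + 1, n))
    coo = sp.triu(m).tocoo()
    sep = coo.col - coo.row
    keep = sep <= max_sep
    band[sep[keep], coo.row[keep]] = coo.data[keep]
    return band


def diagonal_sums(m: sp.csr_matrix, valid: np.ndarray, pair_mask: np.ndarray | None = None):
    """Per-separation contact sums and valid-pair counts for one chromosome.

    Parameters
    ----------
    valid : bool array over the chromosome's bins (balancing mask).
    pair_mask : optional extra bool array (e.g. a compartment label mask);
        a pair contributes only when both bins pass ``valid & pair_mask``.

    Returns
    -------
    sums, counts : arrays of length n (separation 0 .. n-1); ``counts`` counts
        all kept pairs including zero-contact ones.
    """
    from scipy.signal import fftconvolve

    n = m.shape[0]
    keep = valid.copy()
    if pair_mask is not None:
        keep &= pair_mask
    coo = sp.triu(m).tocoo()
    ok = keep[coo.row] & keep[coo.col]
    sep = (coo.col - coo.row)[ok]
    sums = np.bincount(sep, weights=coo.data[ok], minlength=n)
    ind = keep.astype(float)
    # autocorrelation: counts[d] = sum_i ind[i] * ind[i+d]
    corr = fftconvolve(ind, ind[::-1])
    counts = np.rint(corr[n - 1 :]).astype(np.int64)
    return sums, counts
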