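"""A/B compartment calling from cis maps, consensus voting, pair strata.

The caller follows the classic eigenvector pipeline: distance-expected o/e
on the cis map, Pearson correlation matrix over unmasked bins, PCA, then
sign-orientation of each eigenvector so GC-rich regions score positive.
The first eigenvector is used when it correlates with the per-bin ATAC
signal (PCC > 0.30, guarding against whole-arm "compartments"), otherwise
the second.  Per-donor calls are combined by majority vote: at least four
of five donors must agree, 3-to-2 splits become NA.

Calls are coded int8: +1 = A, -1 = B, 0 = NA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

A, B, NA = 1, -1, 0
_CODE2STR = {1: "A", -1: "B", 0: "NA"}

ATAC_PCC_THRESHOLD = 0.30
MIN_UNMASKED_BINS = 10


def _pcc(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class CompartmentTrack:
    eigenvectors: np.ndarray  # (4, n_bins), NaN at masked bins
    chosen: int               # index of the selected eigenvector
    calls: np.ndarray         # int8 per bin: +1 A, -1 B, 0 NA

    def calls_str(self) -> list[str]:
        return [_CODE2STR[int(c)] for c in self.calls]

    def to_bedgraph(self, chrom: str, resolution: int, path) -> None:
        ev = self.eigenvectors[self.chosen]
        rows = [
            (chrom, i * resolution, (i + 1) * resolution, v)
            for i, v in enumerate(ev)
            if np.isfinite(v)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    def to_bed(self, chrom: str, resolution: int, path) -> None:
        rows = [
            (chrom, i * resolution, (i + 1) * resolution, _CODE2STR[int(c)])
            for i, c in enumerate(self.calls)
            if c != NA
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def cis_oe(matrix: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Observed over distance expected; expected = mean count per diagonal
    over unmasked entries.  Zero-expected diagonals stay NaN."""
    n = matrix.shape[0]
    oe = np.full_like(matrix, np.nan, dtype=float)
    ok2d = ~mask[:, None] & ~mask[None, :]
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        sel = ok2d[i, j]
        if not sel.any():
            continue
        exp = matrix[i, j][sel].mean()
        if exp <= 0:
            continue
        vals = matrix[i, j] / exp
        oe[i[sel], j[sel]] = vals[sel]
        oe[j[sel], i[sel]] = vals[sel]
    return oe


def call_compartments(
    cis_matrix: np.ndarray,
    gc_per_bin: np.ndarray,
    atac_per_bin: np.ndarray,
    mask: np.ndarray | None = None,
) -> CompartmentTrack:
    """Eigenvector compartment calls for one chromosome (see module docs)."""
    n = cis_matrix.shape[0]
    if cis_matrix.shape != (n, n):
        raise ValueError("cis map must be square")
    if len(gc_per_bin) != n or len(atac_per_bin) != n:
        raise ValueError("gc/atac vectors must align with the bin grid")
    mask = np.zeros(n, dtype=bool) if mask is None else mask.copy()
    mask |= np.asarray(cis_matrix).sum(axis=1) == 0
    keep = np.nonzero(~mask)[0]
    if keep.size < MIN_UNMASKED_BINS:
        raise ValueError(f"only {keep.size} unmasked bins (<{MIN_UNMASKED_BINS})")

    oe = cis_oe(cis_matrix, mask)[np.ix_(keep, keep)]
    oe = np.nan_to_num(oe, nan=1.0)  # missing diagonals carry no signal
    corr = np.corrcoef(oe)
    corr = np.nan_to_num(corr)

    # PCA of the correlation matrix: top-4 eigenvectors of its covariance
    centered = corr - corr.mean(axis=0, keepdims=True)
    cov = centered @ centered.T / max(1, keep.size - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:4]
    top = evecs[:, order].T  # (4, n_keep)

    gc_k = np.asarray(gc_per_bin, dtype=float)[keep]
    atac_k = np.asarray(atac_per_bin, dtype=float)[keep]
    for v in top:  # orient: GC-rich regions positive
        if _pcc(v, gc_k) < 0:
            v *= -1.0

    pcc1 = _pcc(top[0], atac_k)
    pcc2 = _pcc(top[1], atac_k)
    if pcc1 > ATAC_PCC_THRESHOLD:
        chosen = 0
    elif pcc2 > ATAC_PCC_THRESHOLD:
        chosen = 1
    else:
        warnings.warn(
            "neither eigenvector passes the ATAC check; falling back to EV1"
        )
        chosen = 0

    eigenvectors = np.full((4, n), np.nan)
    eigenvectors[:, keep] = top
    calls = np.zeros(n, dtype=np.int8)
    ev = eigenvectors[chosen]
    calls[np.nan_to_num(ev) > 0] = A
    calls[np.nan_to_num(ev) < 0] = B
    calls[mask] = NA
    return CompartmentTrack(eigenvectors, chosen, calls)


@dataclass
class ConsensusCompartments:
    calls: np.ndarray        # int8 per bin
    votes_a: np.ndarray
    votes_b: np.ndarray

    def calls_str(self) -> list[str]:
        return [_CODE2STR[int(c)] for c in self.calls]


def consensus_vote(tracks: list[CompartmentTrack],
                   n_required: int = 5,
                   min_agree: int = 4) -> ConsensusCompartments:
    """Per-bin majority vote across donors; fewer than `min_agree` agreeing
    donors (including losses to NA donors) gives NA."""
    if len(tracks) != n_required:
        raise ValueError(f"expected {n_required} donor tracks, got {len(tracks)}")
    calls = np.stack([t.calls for t in tracks])  # (donors, bins)
    votes_a = (calls == A).sum(axis=0)
    votes_b = (calls == B).sum(axis=0)
    out = np.zeros(calls.shape[1], dtype=np.int8)
    out[votes_a >= min_agree] = A
    out[votes_b >= min_agree] = B
    return ConsensusCompartments(out, votes_a, votes_b)


def pair_stratum(call_a: int, call_b: int) -> str:
    """Symmetric stratum of a trans bin pair: AA, AB/BA, BB, or NA."""
    if call_a == NA or call_b == NA:
        return "NA"
    if call_a == A and call_b == A:
        return "AA"
    if call_a == B and call_b == B:
        return "BB"
    return "AB/BA"


def bed_to_bin_coverage(intervals, chrom: str, chrom_length: int,
                        resolution: int) -> np.ndarray:
    """Fraction of each bin covered by (merged) intervals on `chrom`.

    `intervals` is an iterable of (chrom, start, end).
    """
    nbins = -(-chrom_length // resolution)
    cov = np.zeros(nbins)
    ivs = sorted((s, e) for c, s, e in intervals if c == chrom)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    for s, e in merged:
        e = min(e, chrom_length)
        b0, b1 = s // resolution, (e - 1) // resolution
        for b in range(b0, b1 + 1):
            lo = max(s, b * resolution)
            hi = min(e, (b + 1) * resolution)
            cov[b] += hi - lo
    widths = np.full(nbins, resolution, dtype=float)
    widths[-1] = chrom_length - (nbins - 1) * resolution
    return cov / widths
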