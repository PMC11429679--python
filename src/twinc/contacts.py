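"""Replicate contact-map containers, readers, and trans normalization.

Contact maps live on a fixed genome-wide bin grid (default 100 kb).  Trans
maps are dense ``(nA, nB)`` count matrices per ordered chromosome pair
(chromA before chromB in grid order); cis maps are square symmetric.  Two
on-disk dialects are supported: a plain TSV
(``chromA  binA_start  chromB  binB_start  count``) and a minimal
cooler-style HDF5 container with ``bins`` and ``pixels`` tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BinGrid:
    """Fixed-resolution binning of a chromosome set with global bin indices."""

    resolution: int
    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    @classmethod
    def from_chromsizes(cls, chromsizes: dict[str, int], resolution: int) -> "BinGrid":
        return cls(resolution, tuple(chromsizes), tuple(chromsizes.values()))

    def n_bins(self, chrom: str) -> int:
        length = self.chrom_lengths[self.chrom_names.index(chrom)]
        return -(-length // self.resolution)

    @property
    def chrom_offsets(self) -> dict[str, int]:
        offs, pos = {}, 0
        for name in self.chrom_names:
            offs[name] = pos
            pos += self.n_bins(name)
        return offs

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_names)

    def global_index(self, chrom: str, start: int) -> int:
        return self.chrom_offsets[chrom] + start // self.resolution

    def bin_location(self, gidx: int) -> tuple[str, int]:
        for name in self.chrom_names:
            n = self.n_bins(name)
            if gidx < n:
                return name, gidx * self.resolution
            gidx -= n
        raise IndexError("global bin index out of range")

    def chrom_pairs(self) -> list[tuple[str, str]]:
        names = self.chrom_names
        return [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]


@dataclass
class TransContactMap:
    chromA: str
    chromB: str
    matrix: np.ndarray  # (nA, nB)

    def __post_init__(self) -> None:
        if self.chromA == self.chromB:
            raise ValueError("trans map requires two distinct chromosomes")


@dataclass
class CisContactMap:
    chrom: str
    matrix: np.ndarray  # (n, n) symmetric


@dataclass
class ContactData:
    """One replicate's maps on a shared grid."""

    grid: BinGrid
    trans: dict[tuple[str, str], TransContactMap] = field(default_factory=dict)
    cis: dict[str, CisContactMap] = field(default_factory=dict)

    def trans_matrix(self, chromA: str, chromB: str) -> np.ndarray:
        """Dense matrix for an ordered pair; missing pairs are all-zero."""
        key = (chromA, chromB)
        if key in self.trans:
            return self.trans[key].matrix
        return np.zeros((self.grid.n_bins(chromA), self.grid.n_bins(chromB)))


@dataclass
class ReplicateSet:
    """A donor group ("labels" or "predictions") of replicates on one grid."""

    grid: BinGrid
    replicates: dict[str, ContactData]
    group: str = "labels"

    def __post_init__(self) -> None:
        for rep in self.replicates.values():
            if rep.grid != self.grid:
                raise ValueError("all replicates must share one BinGrid")


# ---------------------------------------------------------------------------
# readers


def load_contacts_tsv(path, grid: BinGrid) -> ContactData:
    """Read the TSV dialect: chromA, binA_start, chromB, binB_start, count."""
    data = ContactData(grid)
    cols = ["chromA", "startA", "chromB", "startB", "count"]
    try:
        df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    except pd.errors.EmptyDataError:
        return data
    if df.empty:
        return data
    if (df["count"] < 0).any():
        raise ValueError("negative contact counts")
    for col in ("startA", "startB"):
        if (df[col] % grid.resolution != 0).any():
            raise ValueError(
                f"bin starts not aligned to resolution {grid.resolution}"
            )
    order = {c: i for i, c in enumerate(grid.chrom_names)}
    for (ca, cb), sub in df.groupby(["chromA", "chromB"]):
        ia = (sub["startA"] // grid.resolution).to_numpy()
        ib = (sub["startB"] // grid.resolution).to_numpy()
        cnt = sub["count"].to_numpy(dtype=float)
        if ca == cb:
            n = grid.n_bins(ca)
            m = np.zeros((n, n))
            np.add.at(m, (ia, ib), cnt)
            off_diag = ia != ib
            np.add.at(m, (ib[off_diag], ia[off_diag]), cnt[off_diag])
            if ca in data.cis:
                data.cis[ca].matrix += m
            else:
                data.cis[ca] = CisContactMap(ca, m)
        else:
            # store under grid (chromA < chromB) ordering
            if order[ca] > order[cb]:
                ca, cb, ia, ib = cb, ca, ib, ia
            key = (ca, cb)
            if key not in data.trans:
                data.trans[key] = TransContactMap(
                    ca, cb, np.zeros((grid.n_bins(ca), grid.n_bins(cb)))
                )
            np.add.at(data.trans[key].matrix, (ia, ib), cnt)
    return data


def load_contacts_cool(path, grid: BinGrid | None = None) -> ContactData:
    """Read a minimal cooler-style HDF5 container (bins + pixels tables).

    Pixels follow the upper-triangle convention on global bin ids.
    """
    with h5py.File(path, "r") as h5:
        chrom_names = [c.decode() if isinstance(c, bytes) else str(c)
                       for c in h5["chroms/name"][:]]
        chrom_lengths = h5["chroms/length"][:]
        resolution = int(h5.attrs["bin-size"])
        file_grid = BinGrid(resolution, tuple(chrom_names),
                            tuple(int(x) for x in chrom_lengths))
        if grid is not None and grid != file_grid:
            raise ValueError("container grid does not match requested grid")
        grid = file_grid
        bin_chrom = h5["bins/chrom"][:]
        bin_start = h5["bins/start"][:]
        b1 = h5["pixels/bin1_id"][:]
        b2 = h5["pixels/bin2_id"][:]
        cnt = h5["pixels/count"][:].astype(float)
    if (cnt < 0).any():
        raise ValueError("negative contact counts")
    rows = pd.DataFrame(
        {
            "chromA": [chrom_names[bin_chrom[i]] for i in b1],
            "startA": bin_start[b1],
            "chromB": [chrom_names[bin_chrom[i]] for i in b2],
            "startB": bin_start[b2],
            "count": cnt,
        }
    )
    data = ContactData(grid)
    import io

    buf = io.StringIO()
    rows.to_csv(buf, sep="\t", header=False, index=False)
    buf.seek(0)
    return load_contacts_tsv(buf, grid)


def load_contacts(path, grid: BinGrid, format: str = "tsv") -> ContactData:
    if format == "tsv":
        return load_contacts_tsv(path, grid)
    if format == "cool":
        return load_contacts_cool(path, grid)
    raise ValueError(f"unknown contact format {format!r}")


def write_contacts_tsv(data: ContactData, path) -> None:
    rows = []
    res = data.grid.resolution
    for (ca, cb), tmap in sorted(data.trans.items()):
        ia, ib = np.nonzero(tmap.matrix)
        for i, j in zip(ia, ib):
            rows.append((ca, i * res, cb, j * res, tmap.matrix[i, j]))
    for chrom, cmap in sorted(data.cis.items()):
        iu = np.triu_indices_from(cmap.matrix)
        for i, j in zip(*iu):
            if cmap.matrix[i, j]:
                rows.append((chrom, i * res, chrom, j * res, cmap.matrix[i, j]))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# aggregation and normalization


def sum_replicates(repset: ReplicateSet) -> ContactData:
    """Elementwise sum of all replicates' maps per chromosome pair."""
    if not repset.replicates:
        raise ValueError("need at least one replicate")
    out = ContactData(repset.grid)
    for rep in repset.replicates.values():
        for key, tmap in rep.trans.items():
            if key in out.trans:
                if out.trans[key].matrix.shape != tmap.matrix.shape:
                    raise ValueError("grid mismatch between replicates")
                out.trans[key].matrix += tmap.matrix
            else:
                out.trans[key] = TransContactMap(*key, tmap.matrix.copy())
        for chrom, cmap in rep.cis.items():
            if chrom in out.cis:
                out.cis[chrom].matrix += cmap.matrix
            else:
                out.cis[chrom] = CisContactMap(chrom, cmap.matrix.copy())
    return out


def trans_bin_coverage(summed: ContactData) -> np.ndarray:
    """Genome-wide trans coverage per global bin (row + column sums)."""
    grid = summed.grid
    offs = grid.chrom_offsets
    cov = np.zeros(grid.total_bins)
    for (ca, cb), tmap in summed.trans.items():
        cov[offs[ca] : offs[ca] + tmap.matrix.shape[0]] += tmap.matrix.sum(axis=1)
        cov[offs[cb] : offs[cb] + tmap.matrix.shape[1]] += tmap.matrix.sum(axis=0)
    return cov


def expected_trans_scalar(summed: ContactData) -> float:
    """Genome-wide mean trans count per bin pair (the constant expectation)."""
    tot = sum(t.matrix.sum() for t in summed.trans.values())
    cells = sum(t.matrix.size for t in summed.trans.values())
    if cells == 0:
        raise ValueError("no trans maps")
    return float(tot) / float(cells)


def quantile_bin_mask(
    coverage: np.ndarray, top_frac: float, bottom_frac: float
) -> np.ndarray:
    """Boolean mask of bins in the top/bottom coverage quantiles.

    Ranking uses (coverage, global bin index) so ties resolve
    deterministically: the bottom set takes the lowest indices, the top set
    the highest.
    """
    n = coverage.size
    n_top = int(np.floor(top_frac * n + 0.5))
    n_bot = int(np.floor(bottom_frac * n + 0.5))
    order = np.lexsort((np.arange(n), coverage))  # ascending, ties by index
    mask = np.zeros(n, dtype=bool)
    if n_bot:
        mask[order[:n_bot]] = True
    if n_top:
        mask[order[n - n_top :]] = True
    return mask


def oe_log_normalize_trans(
    tmap: TransContactMap,
    expected_scalar: float,
    bin_mask: np.ndarray | None = None,
    grid: BinGrid | None = None,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """ln((o + α) / (expected + α)) with masked bins and empty rows/cols NaN.

    `bin_mask` is the global excluded-bin mask (True = drop); empty rows and
    columns of the pair map are dropped after masking, mirroring the
    regression-data preparation.
    """
    if expected_scalar <= 0:
        raise ValueError("expected_scalar must be positive")
    o = tmap.matrix.astype(float).copy()
    valid = np.ones_like(o, dtype=bool)
    if bin_mask is not None:
        if grid is None:
            raise ValueError("grid required when bin_mask is given")
        offs = grid.chrom_offsets
        rows_bad = bin_mask[offs[tmap.chromA] : offs[tmap.chromA] + o.shape[0]]
        cols_bad = bin_mask[offs[tmap.chromB] : offs[tmap.chromB] + o.shape[1]]
        valid &= ~rows_bad[:, None]
        valid &= ~cols_bad[None, :]
    occ = np.where(valid, o, 0.0)
    row_keep = occ.sum(axis=1) > 0
    col_keep = occ.sum(axis=0) > 0
    valid &= row_keep[:, None] & col_keep[None, :]
    out = np.full_like(o, np.nan)
    out[valid] = np.log((o[valid] + pseudocount) / (expected_scalar + pseudocount))
    return out
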