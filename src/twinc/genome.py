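"""One-hot genome store and fixed-length window extraction.

The model consumes pairs of fixed-length genomic windows as one-hot matrices
(channel order A, C, G, T).  The whole genome is held as a single packed
``(total_bp, 4)`` uint8 array with a chromosome offset table, mirroring the
memory-map layout used for whole-genome training, so window extraction is a
cheap slice.  Ambiguous bases (N and any IUPAC code) map to the all-zero row,
which keeps GC statistics honest: a row sums to 1 iff the base was called.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pyfaidx import Fasta

CHANNELS = "ACGT"

# letter -> channel; everything else (N, IUPAC codes) stays at -1 -> zero row
_LUT = np.full(256, -1, dtype=np.int16)
for _i, _c in enumerate(CHANNELS):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i


def onehot_from_string(seq: str) -> np.ndarray:
    """Encode a nucleotide string as an (L, 4) uint8 one-hot array."""
    codes = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    out = np.zeros((len(seq), 4), dtype=np.uint8)
    called = codes >= 0
    out[np.nonzero(called)[0], codes[called]] = 1
    return out


def string_from_onehot(onehot: np.ndarray) -> str:
    """Decode (L, 4) one-hot rows back to letters; zero rows become N."""
    letters = np.array(list(CHANNELS + "N"))
    idx = np.where(onehot.sum(axis=1) == 0, 4, onehot.argmax(axis=1))
    return "".join(letters[idx])


@dataclass
class Window:
    """A fixed-length one-hot window fully contained in one chromosome."""

    chrom: str
    start: int
    length: int
    seq: np.ndarray  # (length, 4), read-only view

    def gc_fraction(self) -> float:
        return gc_fraction(self.seq)


def gc_fraction(onehot: np.ndarray) -> float:
    """(G + C) / called bases; 0.0 when the window has no called base."""
    called = onehot.sum()
    if called == 0:
        return 0.0
    gc = onehot[:, 1].sum() + onehot[:, 2].sum()  # C + G channels
    return float(gc) / float(called)


@dataclass
class GenomeStore:
    """Packed one-hot genome with per-chromosome offsets."""

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    onehot: np.ndarray  # (total_bp, 4) uint8
    chrom_offsets: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        offsets, pos = {}, 0
        for name in self.chrom_names:
            offsets[name] = pos
            pos += self.chrom_lengths[name]
        if pos != self.onehot.shape[0]:
            raise ValueError(
                f"one-hot rows ({self.onehot.shape[0]}) != total bp ({pos})"
            )
        self.chrom_offsets = offsets
        self.onehot.setflags(write=False)

    def fetch_window(self, chrom: str, start: int, length: int) -> Window:
        """Return the one-hot window [start, start+length) on `chrom`.

        Windows must lie fully inside the chromosome; there is no padding.
        """
        if chrom not in self.chrom_offsets:
            raise KeyError(f"unknown chromosome {chrom!r}")
        clen = self.chrom_lengths[chrom]
        if start < 0 or length <= 0 or start + length > clen:
            raise ValueError(
                f"window {chrom}:{start}-{start + length} outside chromosome "
                f"of length {clen}"
            )
        off = self.chrom_offsets[chrom]
        return Window(chrom, start, length, self.onehot[off + start : off + start + length])

    def gc_per_bin(self, chrom: str, resolution: int) -> np.ndarray:
        """GC fraction of called bases for each `resolution`-sized bin."""
        clen = self.chrom_lengths[chrom]
        off = self.chrom_offsets[chrom]
        nbins = -(-clen // resolution)
        out = np.zeros(nbins)
        for b in range(nbins):
            s, e = b * resolution, min((b + 1) * resolution, clen)
            out[b] = gc_fraction(self.onehot[off + s : off + e])
        return out

    # -- persistence: flat binary + JSON sidecar ---------------------------

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        np.save(str(prefix) + ".onehot.npy", self.onehot)
        sidecar = {
            "chrom_names": self.chrom_names,
            "chrom_lengths": self.chrom_lengths,
        }
        Path(str(prefix) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "GenomeStore":
        prefix = Path(prefix)
        sidecar = json.loads(Path(str(prefix) + ".json").read_text())
        onehot = np.load(str(prefix) + ".onehot.npy", mmap_mode="r")
        return cls(sidecar["chrom_names"], sidecar["chrom_lengths"], np.asarray(onehot))


def build_store(fasta_path: str | Path) -> GenomeStore:
    """Build a :class:`GenomeStore` from a (multi-record, wrapped) FASTA."""
    fa = Fasta(str(fasta_path), as_raw=True, read_ahead=None)
    names = list(fa.keys())
    if not names:
        raise ValueError(f"no sequences in {fasta_path}")
    if len(names) != len(set(names)):
        raise ValueError("duplicate chromosome names in FASTA")
    lengths = {n: len(fa[n]) for n in names}
    if any(l == 0 for l in lengths.values()):
        raise ValueError("empty sequence in FASTA")
    total = sum(lengths.values())
    onehot = np.empty((total, 4), dtype=np.uint8)
    pos = 0
    for n in names:
        seq = str(fa[n][:])
        onehot[pos : pos + lengths[n]] = onehot_from_string(seq)
        pos += lengths[n]
    fa.close()
    return GenomeStore(names, lengths, onehot)
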