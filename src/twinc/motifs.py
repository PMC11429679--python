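"""Position-weight-matrix scanning with exact null p-values.

Motifs are position probability matrices scored against a 0-order
background by the summed log-odds ``log2((p_b + c) / (bg_b + c))`` with
pseudocount ``c``.  Scores are discretized on a 1/1000-bit grid and the
null distribution of the total integer score — each position drawn iid
from the background — is built by exact dynamic programming (convolution
of per-position score distributions), giving the probability of a score
at least as large as the observed one.  Both strands are scanned by
default (reverse strand via the reverse-complement matrix); positions
containing an ambiguous base are skipped.

The MEME minimal text format is supported for motif exchange.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

SCORE_EPS = 1.0 / 1000.0  # bits per discretization step
UNIFORM_BG = np.full(4, 0.25)


@dataclass
class Motif:
    id: str
    ppm: np.ndarray               # (L, 4) rows sum to 1
    background: np.ndarray = None  # (4,)
    pseudocount: float = 0.001

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.background is None:
            self.background = UNIFORM_BG.copy()
        self.background = np.asarray(self.background, dtype=float)
        if self.ppm.ndim != 2 or self.ppm.shape[1] != 4 or len(self.ppm) < 4:
            raise ValueError("PPM must be (L, 4) with L >= 4")
        if not np.allclose(self.ppm.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PPM rows must sum to 1")
        if (self.background <= 0).any():
            raise ValueError("degenerate background with zero entry")

    def __len__(self) -> int:
        return len(self.ppm)

    def log_odds(self) -> np.ndarray:
        """(L, 4) log2 odds with pseudocount."""
        c = self.pseudocount
        return np.log2((self.ppm + c) / (self.background[None, :] + c))

    def int_scores(self) -> np.ndarray:
        """Discretized (L, 4) integer score table at 1/1000-bit granularity."""
        return np.round(self.log_odds() / SCORE_EPS).astype(np.int64)

    def reverse_complement(self) -> "Motif":
        return Motif(self.id, self.ppm[::-1, ::-1].copy(),
                     self.background[::-1].copy(), self.pseudocount)

    def information_content(self) -> float:
        p = np.clip(self.ppm, 1e-12, 1.0)
        return float((p * np.log2(p / self.background[None, :])).sum())


@dataclass
class MotifOccurrence:
    motif_id: str
    window_id: int | str
    offset: int
    strand: str
    score: float   # log-odds, bits
    pvalue: float
    length: int = 0


def consensus_motif(motif_id: str, consensus: str, strength: float = 0.97,
                    background: np.ndarray | None = None) -> Motif:
    """Near-deterministic PPM from a consensus string."""
    lut = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(consensus)
    ppm = np.full((L, 4), (1.0 - strength) / 3.0)
    for i, ch in enumerate(consensus.upper()):
        ppm[i, lut[ch]] = strength
    return Motif(motif_id, ppm, background)


def null_score_distribution(motif: Motif) -> tuple[np.ndarray, int]:
    """Exact pmf of the total integer score under the background.

    Returns (pmf, min_score): pmf[k] = P(S == min_score + k).
    """
    table = motif.int_scores()
    bg = motif.background
    pmf = np.array([1.0])
    lo = 0
    for pos in range(len(motif)):
        s = table[pos]
        smin, smax = int(s.min()), int(s.max())
        step = np.zeros(smax - smin + 1)
        for b in range(4):
            step[s[b] - smin] += bg[b]
        pmf = np.convolve(pmf, step)
        lo += smin
    return pmf, lo


def pvalue_lookup(motif: Motif) -> tuple[np.ndarray, int]:
    """Right-tail table: tail[k] = P(S >= min_score + k).  Memoized."""
    cached = getattr(motif, "_pv_cache", None)
    if cached is not None:
        return cached
    pmf, lo = null_score_distribution(motif)
    tail = np.cumsum(pmf[::-1])[::-1]
    motif._pv_cache = (tail, lo)
    return tail, lo


def _scan_one_strand(table: np.ndarray, codes: np.ndarray,
                     ambiguous: np.ndarray) -> np.ndarray:
    """Integer score per offset; NaN-like minimum where a window has an N."""
    L = len(table)
    n_off = len(codes) - L + 1
    if n_off <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)      # (n_off, L)
    amb = np.lib.stride_tricks.sliding_window_view(ambiguous, L).any(axis=1)
    scores = table[np.arange(L)[None, :], win].sum(axis=1)
    return scores, amb


def scan_pwm(motif: Motif, window, p_threshold: float = 1e-5,
             strands: str = "both", window_id: int | str = 0,
             offset_origin: int = 0) -> list[MotifOccurrence]:
    """Report motif occurrences with exact p-value <= threshold.

    `window` is a one-hot (L, 4) array or a nucleotide string.
    """
    from .genome import onehot_from_string

    if isinstance(window, str):
        window = onehot_from_string(window)
    if len(window) < len(motif):
        raise ValueError("window shorter than motif")
    codes = window.argmax(axis=1)
    ambiguous = window.sum(axis=1) == 0

    hits: list[MotifOccurrence] = []
    strand_list = {"forward": ["+"], "reverse": ["-"], "both": ["+", "-"]}[strands]
    for strand in strand_list:
        m = motif if strand == "+" else motif.reverse_complement()
        tail, lo = pvalue_lookup(m)
        table = m.int_scores()
        scores, amb = _scan_one_strand(table, codes, ambiguous)
        k = scores - lo
        pvals = np.where(
            k < 0, 1.0,
            np.where(k >= len(tail), 0.0, tail[np.clip(k, 0, len(tail) - 1)]),
        )
        for off in np.nonzero((pvals <= p_threshold) & ~amb)[0]:
            hits.append(MotifOccurrence(
                motif.id, window_id, offset_origin + int(off), strand,
                int(scores[off]) * SCORE_EPS, float(pvals[off]), len(motif)
            ))
    return hits


def shuffle_motif_columns(motif: Motif, rng: np.random.Generator) -> Motif:
    """Decoy motif: permute the position (column) order, contents intact."""
    if len(motif) < 2:
        raise ValueError("need at least two columns to shuffle")
    perm = rng.permutation(len(motif))
    return Motif(motif.id + "_decoy", motif.ppm[perm].copy(),
                 motif.background.copy(), motif.pseudocount)


# ---------------------------------------------------------------------------
# MEME minimal format


def read_meme(path) -> list[Motif]:
    text = open(path).read()
    bg = UNIFORM_BG.copy()
    m = re.search(
        r"Background letter frequencies.*?\nA\s+([\d.eE+-]+)\s+C\s+([\d.eE+-]+)"
        r"\s+G\s+([\d.eE+-]+)\s+T\s+([\d.eE+-]+)",
        text,
    )
    if m:
        bg = np.array([float(g) for g in m.groups()])
    motifs = []
    for block in re.finditer(
        r"MOTIF\s+(\S+)[^\n]*\nletter-probability matrix:[^\n]*\n((?:[\s\d.eE+-]+\n?)+)",
        text,
    ):
        name = block.group(1)
        rows = [
            [float(v) for v in line.split()]
            for line in block.group(2).strip().splitlines()
            if line.strip()
        ]
        motifs.append(Motif(name, np.array(rows), bg.copy()))
    return motifs


def write_meme(motifs: list[Motif], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = motifs[0].background if motifs else UNIFORM_BG
        fh.write("Background letter frequencies\n")
        fh.write("A %.5f C %.5f G %.5f T %.5f\n\n" % tuple(bg))
        for m in motifs:
            fh.write(f"MOTIF {m.id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(m)} "
                f"nsites= 20 E= 0\n"
            )
            for row in m.ppm:
                fh.write(" %.6f %.6f %.6f %.6f\n" % tuple(row))
            fh.write("\n")
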