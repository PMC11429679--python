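"""Model interrogation: substitution experiments, attribution, enrichment.

Four layers of interpretation for a trained contact network:

* ranked-set substitution — locus pairs are ranked by predicted score, the
  top 10% act as donors of accessible-peak sequence into recipients drawn
  from the next 30% (or the reverse, stripping peaks from the top set), and
  the score shift quantifies what accessible sequence contributes;
* Integrated Gradients — per-base attribution along the straight path from
  an all-zero baseline to the one-hot input, applied jointly to both
  windows, with the completeness identity (attributions sum to
  F(input) - F(baseline)) as the accuracy audit;
* motif enrichment — occurrences of each motif (and of a column-shuffled
  decoy) found in accessible peaks are assigned the median per-base
  importance over their span; a right-tailed Mann-Whitney U test per motif
  with Benjamini-Hochberg control across motifs flags enriched factors;
* G-quadruplex analysis — greedy non-overlapping matches of
  G{3,}N{1,7}G{3,}N{1,7}G{3,}N{1,7}G{3,} (and the C-run mirror on the
  reverse strand), compared between predicted contact and no-contact pairs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .genome import string_from_onehot
from .metrics import binary_metrics
from .motifs import Motif, MotifOccurrence, scan_pwm, shuffle_motif_columns

# ---------------------------------------------------------------------------
# ranked partition


@dataclass
class RankedPartition:
    """Locus pairs sorted by descending score; top 10% and next 30% subsets."""

    pairs: list[tuple]      # (chromA, startA, chromB, startB), ranked
    scores: np.ndarray      # aligned with `pairs`
    top: list[tuple]
    next_: list[tuple]

    top_frac: float = 0.10
    next_frac: float = 0.30


def rank_and_partition(pairs, scores, top_frac: float = 0.10,
                       next_frac: float = 0.30) -> RankedPartition:
    """Sort by descending score (ties by coordinates) and take floor-sized
    top and next subsets."""
    n = len(pairs)
    if n < 10:
        raise ValueError("need at least 10 pairs to partition")
    scores = np.asarray(scores, dtype=float)
    order = sorted(range(n), key=lambda k: (-scores[k], tuple(pairs[k])))
    ranked = [tuple(pairs[k]) for k in order]
    rscores = scores[order]
    n_top = int(np.floor(top_frac * n))
    n_next = int(np.floor(next_frac * n))
    return RankedPartition(
        ranked, rscores, ranked[:n_top], ranked[n_top : n_top + n_next],
        top_frac, next_frac,
    )


# ---------------------------------------------------------------------------
# peak substitution


def read_bed(path) -> list[tuple[str, int, int]]:
    """(chrom, start, end) tuples from a 3+ column BED file."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            out.append((chrom, int(start), int(end)))
    return out


def merge_intervals(intervals) -> list[tuple[int, int]]:
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def peaks_in_window(peaks, chrom: str, start: int, length: int
                    ) -> list[tuple[int, int]]:
    """Peak intervals intersected with a window, in window coordinates,
    merged where overlapping."""
    local = []
    for c, s, e in peaks:
        if c != chrom:
            continue
        lo, hi = max(s, start), min(e, start + length)
        if hi > lo:
            local.append((lo - start, hi - start))
    return merge_intervals(local)


def splice_intervals(source: np.ndarray, dest: np.ndarray,
                     intervals) -> np.ndarray:
    """Copy `source` bases into a copy of `dest` at the given offsets."""
    if source.shape != dest.shape:
        raise ValueError("windows must have equal shape")
    out = dest.copy()
    for s, e in merge_intervals(intervals):
        out[s:e] = source[s:e]
    return out


def substitute_peaks(donor_pair, recipient_pair, peaks, store, window_bp: int,
                     direction: str = "insert"):
    """Build the modified window pair for one substitution.

    `donor_pair`/`recipient_pair` are (chromA, startA, chromB, startB) from
    the top-10% and next-30% sets respectively.  Peaks are intersected with
    the *donor* (top-set) windows; direction "insert" copies donor bases
    into the recipient windows at those offsets, direction "strip" replaces
    the donor's peak bases with recipient bases at the same offsets.
    Returns (windowA, windowB, n_peak_bases).
    """
    if direction not in ("insert", "strip"):
        raise ValueError(f"unknown direction {direction!r}")
    dA = store.fetch_window(donor_pair[0], donor_pair[1], window_bp).seq
    dB = store.fetch_window(donor_pair[2], donor_pair[3], window_bp).seq
    rA = store.fetch_window(recipient_pair[0], recipient_pair[1], window_bp).seq
    rB = store.fetch_window(recipient_pair[2], recipient_pair[3], window_bp).seq
    ivA = peaks_in_window(peaks, donor_pair[0], donor_pair[1], window_bp)
    ivB = peaks_in_window(peaks, donor_pair[2], donor_pair[3], window_bp)
    n_bases = sum(e - s for s, e in ivA) + sum(e - s for s, e in ivB)
    if direction == "insert":
        outA = splice_intervals(dA, rA, ivA)
        outB = splice_intervals(dB, rB, ivB)
    else:
        outA = splice_intervals(rA, dA, ivA)
        outB = splice_intervals(rB, dB, ivB)
    return outA, outB, n_bases


def run_substitution_experiment(net, partition: RankedPartition, peaks, store,
                                n_samples: int, rng: np.random.Generator,
                                direction: str = "insert"):
    """Sampled donor/recipient substitutions; returns (table, summary)."""
    window_bp = net.config.window_bp
    rows = []
    donors = partition.top
    recipients = partition.next_
    order = rng.permutation(len(donors))[:n_samples]
    for di in order:
        donor = donors[di]
        recipient = recipients[rng.integers(0, len(recipients))]
        outA, outB, n_bases = substitute_peaks(
            donor, recipient, peaks, store, window_bp, direction
        )
        if n_bases == 0:
            continue  # donor carries no peak overlap; skip and log
        base_pair = recipient if direction == "insert" else donor
        bA = store.fetch_window(base_pair[0], base_pair[1], window_bp).seq
        bB = store.fetch_window(base_pair[2], base_pair[3], window_bp).seq
        before = net.forward_pair(bA, bB)
        after = net.forward_pair(outA, outB)
        rows.append(
            {"donor": donor, "recipient": recipient, "before": before,
             "after": after, "delta": after - before, "peak_bases": n_bases}
        )
    table = pd.DataFrame(rows)
    if len(table):
        summary = {
            "n": len(table),
            "fraction_increased": float((table["delta"] > 0).mean()),
            "mean_delta": float(table["delta"].mean()),
        }
    else:
        summary = {"n": 0, "fraction_increased": np.nan, "mean_delta": np.nan}
    return table, summary


# ---------------------------------------------------------------------------
# Integrated Gradients


@dataclass
class ImportanceTrack:
    """Per-base attribution over one window of a pair."""

    scores: np.ndarray  # (L,)
    pairing: str        # "A" or "B"


def integrated_gradients(net, windowA: np.ndarray, windowB: np.ndarray,
                         baseline: np.ndarray | None = None, steps: int = 128,
                         chunk: int = 64):
    """Midpoint-Riemann Integrated Gradients applied jointly to both inputs.

    For classification networks the attributed quantity F is the pre-sigmoid
    contact logit (piecewise linear in the input, so the path integral is
    numerically tight; the sigmoid is monotone and preserves importance
    ordering).  Networks without a logit surface are attributed on their
    plain output.  Returns (trackA, trackB, diagnostics); diagnostics holds
    the completeness residual |sum(attr) - (F(x) - F(baseline))|.
    """
    if steps < 16:
        raise ValueError("need at least 16 integration steps")
    fwd = getattr(net, "forward_logits", None)
    if fwd is None or getattr(net.config, "head", None) != "classification":
        fwd = net.forward_pairs
    xA = np.asarray(windowA, dtype=np.float32)
    xB = np.asarray(windowB, dtype=np.float32)
    bA = np.zeros_like(xA) if baseline is None else np.asarray(baseline, np.float32)
    bB = np.zeros_like(xB) if baseline is None else np.asarray(baseline, np.float32)

    gA = np.zeros_like(xA, dtype=np.float64)
    gB = np.zeros_like(xB, dtype=np.float64)
    ts = (np.arange(steps) + 0.5) / steps
    for s in range(0, steps, chunk):
        tchunk = ts[s : s + chunk]
        pA = bA[None] + tchunk[:, None, None] * (xA - bA)[None]
        pB = bB[None] + tchunk[:, None, None] * (xB - bB)[None]
        fwd(pA, pB, train=False)
        ga, gb = net.backward(np.ones(len(tchunk), dtype=np.float32))
        if not (np.isfinite(ga).all() and np.isfinite(gb).all()):
            raise FloatingPointError("non-finite gradients in attribution")
        gA += ga.sum(axis=0)
        gB += gb.sum(axis=0)
    attrA = (xA - bA) * (gA / steps)
    attrB = (xB - bB) * (gB / steps)

    if fwd is net.forward_pairs:
        f_x = float(np.asarray(fwd(xA[None], xB[None], train=False))[0])
        f_b = float(np.asarray(fwd(bA[None], bB[None], train=False))[0])
    else:
        f_x = float(fwd(xA[None], xB[None])[0])
        f_b = float(fwd(bA[None], bB[None])[0])
    total = float(attrA.sum() + attrB.sum())
    diagnostics = {
        "f_input": float(f_x),
        "f_baseline": float(f_b),
        "sum_attributions": total,
        "completeness_residual": abs(total - (float(f_x) - float(f_b))),
    }
    trackA = ImportanceTrack(attrA.sum(axis=1), "A")
    trackB = ImportanceTrack(attrB.sum(axis=1), "B")
    return trackA, trackB, diagnostics


# ---------------------------------------------------------------------------
# motif enrichment


@dataclass
class EnrichmentResult:
    motif_id: str
    u_stat: float
    p_raw: float
    p_adj: float
    n_real: int
    n_decoy: int
    enriched: bool
    tested: bool = True


def occurrence_importances(occurrences: list[MotifOccurrence],
                           tracks: dict) -> dict[str, list[float]]:
    """Median per-base importance over each occurrence span, keyed by motif.

    `tracks` maps window id to a per-base importance array.
    """
    out: dict[str, list[float]] = {}
    for occ in occurrences:
        track = tracks[occ.window_id]
        span = track[occ.offset : occ.offset + occ.length]
        out.setdefault(occ.motif_id, []).append(float(np.median(span)))
    return out


def motif_enrichment(real_occurrences: list[MotifOccurrence],
                     decoy_occurrences: list[MotifOccurrence],
                     tracks: dict, alpha: float = 0.01,
                     min_occurrences: int = 5) -> list[EnrichmentResult]:
    """Right-tailed U test per motif (real vs decoy median importances) with
    Benjamini-Hochberg control across tested motifs."""
    real = occurrence_importances(real_occurrences, tracks)
    decoy_raw = occurrence_importances(decoy_occurrences, tracks)
    # decoy ids carry the "_decoy" suffix from shuffle_motif_columns
    decoy = {k.removesuffix("_decoy"): v for k, v in decoy_raw.items()}

    tested, untested = [], []
    for motif_id in sorted(set(real) | set(decoy)):
        r = real.get(motif_id, [])
        d = decoy.get(motif_id, [])
        if len(r) < min_occurrences or len(d) < min_occurrences:
            untested.append(
                EnrichmentResult(motif_id, np.nan, np.nan, np.nan,
                                 len(r), len(d), False, tested=False)
            )
            continue
        # exact null distribution for small samples, else asymptotic
        method = "exact" if max(len(r), len(d)) <= 25 else "asymptotic"
        u, p = mannwhitneyu(r, d, alternative="greater", method=method)
        tested.append((motif_id, float(u), float(p), len(r), len(d)))

    results = list(untested)
    if tested:
        pvals = [t[2] for t in tested]
        reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        for (motif_id, u, p, nr, nd), rej, pa in zip(tested, reject, p_adj):
            results.append(
                EnrichmentResult(motif_id, u, p, float(pa), nr, nd, bool(rej))
            )
    return sorted(results, key=lambda r: r.motif_id)


def scan_peaks_for_motifs(motifs: list[Motif], windows: dict, peaks,
                          window_coords: dict, rng: np.random.Generator,
                          p_threshold: float = 1e-5,
                          whole_window: bool = False):
    """Scan real and column-shuffled decoy motifs over accessible intervals.

    `windows` maps window id -> one-hot array; `window_coords` maps window
    id -> (chrom, start).  Returns (real_occurrences, decoy_occurrences).
    """
    real: list[MotifOccurrence] = []
    decoy: list[MotifOccurrence] = []
    decoys = [shuffle_motif_columns(m, rng) for m in motifs]
    for wid, onehot in windows.items():
        chrom, start = window_coords[wid]
        if whole_window:
            ivs = [(0, len(onehot))]
        else:
            ivs = peaks_in_window(peaks, chrom, start, len(onehot))
        for s, e in ivs:
            seg = onehot[s:e]
            for m, dm in zip(motifs, decoys):
                if e - s < len(m):
                    continue
                real.extend(scan_pwm(m, seg, p_threshold, window_id=wid,
                                     offset_origin=s))
                decoy.extend(scan_pwm(dm, seg, p_threshold, window_id=wid,
                                      offset_origin=s))
    return real, decoy


# ---------------------------------------------------------------------------
# G-quadruplexes

G4_FORWARD = re.compile(r"(?:G{3,}[ACGTN]{1,7}){3}G{3,}")
G4_REVERSE = re.compile(r"(?:C{3,}[ACGTN]{1,7}){3}C{3,}")


def scan_g4(window, strands: str = "both") -> list[tuple[int, int, str]]:
    """Greedy non-overlapping matches of the G4 consensus
    G{3,}N{1,7}G{3,}N{1,7}G{3,}N{1,7}G{3,} (C-run mirror on the reverse
    strand).  Returns (start, end, strand) tuples."""
    if not isinstance(window, str):
        window = string_from_onehot(np.asarray(window))
    seq = window.upper()
    hits = []
    if strands in ("forward", "both"):
        hits += [(m.start(), m.end(), "+") for m in G4_FORWARD.finditer(seq)]
    if strands in ("reverse", "both"):
        hits += [(m.start(), m.end(), "-") for m in G4_REVERSE.finditer(seq)]
    return sorted(hits)


def g4_enrichment(scores: np.ndarray, g4_counts: np.ndarray,
                  threshold: float = 0.5) -> dict:
    """Contact (> threshold) vs no-contact G4-count comparison.

    Right-tailed Mann-Whitney U (contact counts larger) plus the AUROC of
    the counts against the binary contact grouping.
    """
    scores = np.asarray(scores, dtype=float)
    counts = np.asarray(g4_counts, dtype=float)
    contact = scores > threshold
    if contact.all() or (~contact).all():
        raise ValueError("both contact and no-contact groups must be non-empty")
    u, p = mannwhitneyu(counts[contact], counts[~contact],
                        alternative="greater")
    rep = binary_metrics(contact.astype(int), counts)
    return {
        "u_stat": float(u),
        "p_value": float(p),
        "auroc": rep.auroc,
        "n_contact": int(contact.sum()),
        "n_no_contact": int((~contact).sum()),
    }
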