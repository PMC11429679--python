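"""Synthetic genomes, replicate contact maps and ground truth.

The generator emulates, at desk scale, the data a replicate trans-contact
study provides: a small genome (default six 400 kb chromosomes) with
iid background sequence at human-like GC, accessible intervals carrying
planted motif instances, and replicate trans count maps driven by a known
logistic motif-pair contact rule

    p(contact) = logistic(b0 + b_motif * co_occurrence + b_gc * (gc - gc0)),

where co-occurrence means motif X in one window and motif Y in the other
(symmetric in window order).  The contact indicator is drawn once per pair
and shared by every replicate of both donor groups; replicates differ only
in Poisson read noise (rate lambda_plus for contacting pairs, lambda_minus
for background).  All randomness flows from the spec seed, so every
emitted artifact is byte-identical across runs.

What this emulates and what it does not: replicate consensus structure,
motif-driven specificity, Poisson sampling noise and GC composition are
present; distance decay, matrix-balancing artifacts and chromosome
territory statistics are not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .contacts import BinGrid, ContactData, ReplicateSet, TransContactMap
from .genome import GenomeStore, onehot_from_string
from .motifs import Motif, consensus_motif

BASES = np.array(list("ACGT"))


@dataclass
class SyntheticSpec:
    """Study conditions for the toy trans-contact world."""

    n_chroms: int = 6
    chrom_length: int = 400_000
    resolution: int = 5_000          # bin size == model window size
    background_gc: float = 0.41
    motif_x: str = "TGACGTCATC"
    motif_y: str = "AGGCATTCGA"
    motif_strength: float = 0.997  # planted instances are near consensus-exact
    motif_window_prob: float = 0.25  # windows designated to carry each motif
    instances_extra_mean: float = 4.0  # motif windows get 1 + Poisson(this)
    accessible_prob: float = 0.3     # peak rate in windows without motifs
    accessible_length: int = 500
    background_placement_rate: float = 0.0   # stray placements per non-peak bp
    beta0: float = -5.0
    beta_motif: float = 7.5
    beta_gc: float = 0.0
    n_replicates: int = 5
    lambda_plus: float = 6.0
    lambda_minus: float = 0.3
    replicate_depths: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.lambda_plus > self.lambda_minus >= 0:
            raise ValueError("require lambda_plus > lambda_minus >= 0")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def bins_per_chrom(self) -> int:
        return self.chrom_length // self.resolution

    def motifs(self) -> tuple[Motif, Motif]:
        bg = np.array([(1 - self.background_gc) / 2, self.background_gc / 2,
                       self.background_gc / 2, (1 - self.background_gc) / 2])
        return (
            consensus_motif("motif_x", self.motif_x, self.motif_strength, bg),
            consensus_motif("motif_y", self.motif_y, self.motif_strength, bg),
        )


@dataclass
class SyntheticTruth:
    """Ground truth the generator commits to."""

    spec: SyntheticSpec
    has_x: dict[str, np.ndarray] = field(default_factory=dict)   # per-bin bool
    has_y: dict[str, np.ndarray] = field(default_factory=dict)
    gc_per_bin: dict[str, np.ndarray] = field(default_factory=dict)
    motif_positions: list[tuple[str, int, str]] = field(default_factory=list)
    peaks: list[tuple[str, int, int]] = field(default_factory=list)
    contact_prob: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    contact: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def peaks_bed(self, path) -> None:
        with open(path, "w") as fh:
            for c, s, e in self.peaks:
                fh.write(f"{c}\t{s}\t{e}\n")

    def save_json(self, path) -> None:
        payload = {
            "spec": asdict(self.spec),
            "has_x": {c: v.astype(int).tolist() for c, v in self.has_x.items()},
            "has_y": {c: v.astype(int).tolist() for c, v in self.has_y.items()},
            "motif_positions": self.motif_positions,
            "peaks": self.peaks,
            "contact": {f"{a}|{b}": m.astype(int).tolist()
                        for (a, b), m in self.contact.items()},
        }
        Path(path).write_text(json.dumps(payload))


def _sample_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _sample_from_ppm(rng: np.random.Generator, motif: Motif) -> np.ndarray:
    return np.array([rng.choice(4, p=row) for row in motif.ppm])


def simulate_genome(spec: SyntheticSpec) -> tuple[GenomeStore, SyntheticTruth]:
    """Background sequence + accessible intervals + planted motif instances."""
    motif_x, motif_y = spec.motifs()
    if len(motif_x) > spec.resolution or len(motif_y) > spec.resolution:
        raise ValueError("motif longer than a window")
    rng = np.random.default_rng(spec.seed)
    truth = SyntheticTruth(spec)
    nb = spec.bins_per_chrom
    res = spec.resolution
    total = spec.n_chroms * spec.chrom_length
    onehot = np.empty((total, 4), dtype=np.uint8)
    lengths: dict[str, int] = {}
    pos0 = 0
    eye = np.eye(4, dtype=np.uint8)
    for chrom in spec.chrom_names:
        codes = _sample_background(rng, spec.chrom_length, spec.background_gc)
        truth.has_x[chrom] = np.zeros(nb, dtype=bool)
        truth.has_y[chrom] = np.zeros(nb, dtype=bool)
        for b in range(nb):
            wstart = b * res
            carry_x = rng.random() < spec.motif_window_prob
            carry_y = rng.random() < spec.motif_window_prob
            # motif-bearing windows always get an accessible peak; others may
            has_peak = carry_x or carry_y or rng.random() < spec.accessible_prob
            peak = None
            if has_peak:
                ps = wstart + int(rng.integers(0, res - spec.accessible_length))
                peak = (ps, ps + spec.accessible_length)
                truth.peaks.append((chrom, peak[0], peak[1]))
            occupied: list[tuple[int, int]] = []
            for motif, carry, flag in (
                (motif_x, carry_x, truth.has_x),
                (motif_y, carry_y, truth.has_y),
            ):
                n_inst = (1 + rng.poisson(spec.instances_extra_mean)) if carry else 0
                n_inst += rng.poisson(spec.background_placement_rate * res)
                L = len(motif)
                for _ in range(n_inst):
                    # rejection-sample a slot that overlaps no earlier instance
                    for _try in range(20):
                        if peak is not None and rng.random() < 0.95:
                            lo, hi = peak[0], peak[1] - L
                        else:
                            lo, hi = wstart, wstart + res - L
                        p = int(rng.integers(lo, hi))
                        if all(p + L <= s or p >= e for s, e in occupied):
                            break
                    else:
                        continue
                    occupied.append((p, p + L))
                    codes[p : p + L] = _sample_from_ppm(rng, motif)
                    truth.motif_positions.append((chrom, p, motif.id))
                    flag[chrom][b] = True
        onehot[pos0 : pos0 + spec.chrom_length] = eye[codes]
        lengths[chrom] = spec.chrom_length
        pos0 += spec.chrom_length
        gc = np.empty(nb)
        for b in range(nb):
            seg = codes[b * res : (b + 1) * res]
            gc[b] = np.isin(seg, (1, 2)).mean()
        truth.gc_per_bin[chrom] = gc
    store = GenomeStore(spec.chrom_names, lengths, onehot)
    return store, truth


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def draw_contact_truth(truth: SyntheticTruth) -> None:
    """Draw the pairwise contact indicator once (shared by all replicates)."""
    spec = truth.spec
    rng = np.random.default_rng(spec.seed + 1_000_003)
    names = spec.chrom_names
    for i, ca in enumerate(names):
        for cb in names[i + 1 :]:
            xa, ya = truth.has_x[ca], truth.has_y[ca]
            xb, yb = truth.has_x[cb], truth.has_y[cb]
            co = (xa[:, None] & yb[None, :]) | (ya[:, None] & xb[None, :])
            z = spec.beta0 + spec.beta_motif * co.astype(float)
            if spec.beta_gc:
                gbar = 0.5 * (
                    truth.gc_per_bin[ca][:, None] + truth.gc_per_bin[cb][None, :]
                )
                z = z + spec.beta_gc * (gbar - spec.background_gc)
            p = _logistic(z)
            truth.contact_prob[(ca, cb)] = p
            truth.contact[(ca, cb)] = rng.random(p.shape) < p


def simulate_contacts(truth: SyntheticTruth, spec: SyntheticSpec,
                      group: str = "labels", group_seed: int = 0) -> ReplicateSet:
    """Poisson replicate count maps for one donor group."""
    if not truth.contact:
        draw_contact_truth(truth)
    rng = np.random.default_rng(spec.seed + 7_000_003 + group_seed)
    grid = BinGrid.from_chromsizes(
        {c: spec.chrom_length for c in spec.chrom_names}, spec.resolution
    )
    depths = spec.replicate_depths or (1.0,) * spec.n_replicates
    reps: dict[str, ContactData] = {}
    for r in range(spec.n_replicates):
        data = ContactData(grid)
        for key, contact in truth.contact.items():
            lam = np.where(contact, spec.lambda_plus, spec.lambda_minus)
            counts = rng.poisson(lam * depths[r]).astype(float)
            data.trans[key] = TransContactMap(key[0], key[1], counts)
        reps[f"{group}_rep{r}"] = data
    return ReplicateSet(grid, reps, group=group)


def simulate_world(spec: SyntheticSpec):
    """Genome + truth + both donor groups in one call.

    Returns (store, truth, labels_group, predictions_group).
    """
    store, truth = simulate_genome(spec)
    draw_contact_truth(truth)
    labels_group = simulate_contacts(truth, spec, "labels", group_seed=0)
    predictions_group = simulate_contacts(truth, spec, "predictions", group_seed=1)
    return store, truth, labels_group, predictions_group


# ---------------------------------------------------------------------------
# compartment-structured cis maps


def simulate_compartment_chromosome(
    n_bins: int = 60,
    seed: int = 0,
    block_size: int = 6,
    within: float = 2.0,
    between: float = 0.5,
    depth: float = 40.0,
    gc_effect: float = 0.05,
    atac_effect: float = 0.25,
):
    """Checkerboard cis map with planted A/B two-coloring.

    Counts are Poisson around ``depth * decay(d) * (within|between)`` with a
    1/(1+d) distance decay; A bins get higher GC and ATAC signal.  Returns
    (cis_matrix, planted_labels(+1/-1), gc_per_bin, atac_per_bin).
    """
    rng = np.random.default_rng(seed)
    labels = np.ones(n_bins, dtype=np.int8)
    for b0 in range(0, n_bins, block_size):
        if (b0 // block_size) % 2 == 1:
            labels[b0 : b0 + block_size] = -1
    same = labels[:, None] == labels[None, :]
    d = np.abs(np.arange(n_bins)[:, None] - np.arange(n_bins)[None, :])
    decay = 1.0 / (1.0 + d)
    lam = depth * decay * np.where(same, within, between)
    upper = rng.poisson(np.triu(lam))
    cis = upper + np.triu(upper, 1).T
    gc = 0.41 + gc_effect * (labels == 1) + rng.normal(0, 0.01, n_bins)
    atac = np.clip(
        0.05 + atac_effect * (labels == 1) + rng.normal(0, 0.03, n_bins), 0, 1
    )
    return cis.astype(float), labels, gc, atac
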