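"""Replicate-consensus trans-contact labels, parameter sweep, and folds.

Positive labels are trans bin pairs seen with at least ``i`` counts in at
least ``m`` of the label-group replicates; negatives are pairs with at most
``j`` counts in at least ``n`` replicates, restricted to rows/columns of the
pair map that are non-empty in the summed label-group matrix.  Bins in the
extreme coverage quantiles (top 0.1%, bottom 1% by genome-wide trans
coverage) are excluded throughout, and the same mask carries over to the
prediction group.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import (
    BinGrid,
    ReplicateSet,
    quantile_bin_mask,
    sum_replicates,
    trans_bin_coverage,
)

DEFAULT_TOP_FRAC = 0.001
DEFAULT_BOTTOM_FRAC = 0.01

#: chromosomes excluded from fold construction by default
DEFAULT_EXCLUDE = ("chrY", "chrM", "chrMT")


@dataclass(frozen=True)
class LabelParams:
    """The five calling parameters (resolution plus i, m, j, n)."""

    resolution: int
    i: int  # min count supporting a positive observation
    m: int  # min replicates supporting a positive
    j: int  # max count for a negative observation
    n: int  # min replicates supporting a negative

    def validate(self, n_replicates: int) -> None:
        if not self.i > self.j >= 0:
            raise ValueError(f"require i > j >= 0, got i={self.i}, j={self.j}")
        if not (1 <= self.m <= n_replicates and 1 <= self.n <= n_replicates):
            raise ValueError("m and n must lie in [1, replicate count]")


@dataclass
class LabelSet:
    """Positive/negative global-bin-index pairs plus the excluded-bin mask."""

    positives: set[tuple[int, int]]
    negatives: set[tuple[int, int]]
    excluded: np.ndarray  # bool per global bin
    params: LabelParams
    grid: BinGrid = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, b in sorted(self.positives):
            rows.append((*self._loc(a), *self._loc(b), 1))
        for a, b in sorted(self.negatives):
            rows.append((*self._loc(a), *self._loc(b), 0))
        return pd.DataFrame(
            rows, columns=["chromA", "startA", "chromB", "startB", "label"]
        )

    def _loc(self, gidx: int) -> tuple[str, int]:
        return self.grid.bin_location(gidx)

    def save(self, tsv_path, meta_path=None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if meta_path is not None:
            meta = {
                "params": vars(self.params),
                "excluded_bins": np.nonzero(self.excluded)[0].tolist(),
            }
            with open(meta_path, "w") as fh:
                json.dump(meta, fh)


def coverage_mask(
    label_group: ReplicateSet,
    top_frac: float = DEFAULT_TOP_FRAC,
    bottom_frac: float = DEFAULT_BOTTOM_FRAC,
) -> np.ndarray:
    """Excluded-bin mask from the summed label-group trans coverage."""
    summed = sum_replicates(label_group)
    cov = trans_bin_coverage(summed)
    return quantile_bin_mask(cov, top_frac, bottom_frac)


def call_labels(
    label_group: ReplicateSet,
    params: LabelParams,
    mask: np.ndarray | None = None,
) -> LabelSet:
    """Apply the consensus thresholds to every trans pair on the grid."""
    grid = label_group.grid
    reps = list(label_group.replicates.values())
    params.validate(len(reps))
    if mask is None:
        mask = coverage_mask(label_group)
    summed = sum_replicates(label_group)
    offs = grid.chrom_offsets
    positives: set[tuple[int, int]] = set()
    negatives: set[tuple[int, int]] = set()
    for ca, cb in grid.chrom_pairs():
        stack = np.stack([r.trans_matrix(ca, cb) for r in reps])  # (R, nA, nB)
        okA = ~mask[offs[ca] : offs[ca] + stack.shape[1]]
        okB = ~mask[offs[cb] : offs[cb] + stack.shape[2]]
        unmasked = okA[:, None] & okB[None, :]

        pos = ((stack >= params.i).sum(axis=0) >= params.m) & unmasked

        ssum = summed.trans_matrix(ca, cb) * unmasked
        row_ok = ssum.sum(axis=1) > 0
        col_ok = ssum.sum(axis=0) > 0
        cand = row_ok[:, None] & col_ok[None, :] & unmasked
        neg = ((stack <= params.j).sum(axis=0) >= params.n) & cand & ~pos

        ga, gb = offs[ca], offs[cb]
        for ia, ib in zip(*np.nonzero(pos)):
            positives.add((ga + ia, gb + ib))
        for ia, ib in zip(*np.nonzero(neg)):
            negatives.add((ga + ia, gb + ib))
    return LabelSet(positives, negatives, mask, params, grid)


def sweep_label_params(
    label_group: ReplicateSet,
    prediction_group: ReplicateSet,
    candidates: list[LabelParams] | None = None,
    resolution: int | None = None,
) -> tuple[pd.DataFrame, LabelParams | None]:
    """Score each candidate parameter set by labeling group A and ranking with
    summed group-B counts; return the table and the argmax-AUROC candidate.

    Ties break toward fewer labeled pairs, then lexicographic (i, m, j, n).
    Candidates yielding an empty class are flagged (AUROC NaN) and skipped.
    """
    from .metrics import binary_metrics

    grid = label_group.grid
    if candidates is None:
        res = resolution or grid.resolution
        r = len(label_group.replicates)
        candidates = [
            LabelParams(res, i, m, j, n)
            for i, m, j, n in itertools.product(
                range(1, 5), range(2, min(5, r) + 1), range(0, 3), range(2, min(5, r) + 1)
            )
            if i > j
        ]
    mask = coverage_mask(label_group)
    pred_sum = sum_replicates(prediction_group)
    offs = grid.chrom_offsets
    reps = list(label_group.replicates.values())
    summed = sum_replicates(label_group)

    # precompute per-pair arrays once; candidates then reduce to thresholding
    pair_data = []
    for ca, cb in grid.chrom_pairs():
        stack = np.stack([r.trans_matrix(ca, cb) for r in reps])
        okA = ~mask[offs[ca] : offs[ca] + stack.shape[1]]
        okB = ~mask[offs[cb] : offs[cb] + stack.shape[2]]
        unmasked = okA[:, None] & okB[None, :]
        ssum = summed.trans_matrix(ca, cb) * unmasked
        cand = (ssum.sum(axis=1) > 0)[:, None] & (ssum.sum(axis=0) > 0)[None, :]
        pair_data.append((stack, unmasked, cand & unmasked,
                          pred_sum.trans_matrix(ca, cb)))

    rows = []
    best: tuple | None = None
    best_params: LabelParams | None = None
    for p in candidates:
        p.validate(len(reps))
        pos_scores, neg_scores = [], []
        for stack, unmasked, cand, pred in pair_data:
            pos = ((stack >= p.i).sum(axis=0) >= p.m) & unmasked
            neg = ((stack <= p.j).sum(axis=0) >= p.n) & cand & ~pos
            pos_scores.append(pred[pos])
            neg_scores.append(pred[neg])
        ps = np.concatenate(pos_scores)
        ns = np.concatenate(neg_scores)
        n_pos, n_neg = ps.size, ns.size
        if n_pos == 0 or n_neg == 0:
            rows.append((p.i, p.m, p.j, p.n, n_pos, n_neg, np.nan))
            continue
        y = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
        auroc = binary_metrics(y, np.concatenate([ps, ns])).auroc
        rows.append((p.i, p.m, p.j, p.n, n_pos, n_neg, auroc))
        key = (-auroc, n_pos + n_neg, (p.i, p.m, p.j, p.n))
        if best is None or key < best:
            best = key
            best_params = p
    table = pd.DataFrame(
        rows, columns=["i", "m", "j", "n", "n_pos", "n_neg", "auroc"]
    )
    return table, best_params


def reproducibility_point(
    labelsA: LabelSet, labelsB: LabelSet
) -> tuple[float, float]:
    """(TPR, FPR) of group-B labels scored against group-A labels.

    Restricted to pairs labeled by both groups: TPR over A-positives that B
    labeled at all, FPR over A-negatives that B labeled at all.
    """
    posA, negA = labelsA.positives, labelsA.negatives
    posB, negB = labelsB.positives, labelsB.negatives
    labeledB = posB | negB
    tp_den = len(posA & labeledB)
    fp_den = len(negA & labeledB)
    if tp_den == 0 or fp_den == 0:
        raise ValueError("no overlap between the two label sets")
    tpr = len(posA & posB) / tp_den
    fpr = len(negA & posB) / fp_den
    return tpr, fpr


@dataclass
class FoldSpec:
    fold: int
    train: list[str]
    validation: list[str]
    test: list[str]


def chrom_folds(
    chroms: list[str],
    k: int = 5,
    seed: int = 0,
    exclude: tuple[str, ...] = DEFAULT_EXCLUDE,
) -> list[FoldSpec]:
    """k chromosome-level folds with disjoint test sets (19/2/2 at 23 chroms).

    Test (and validation) set size is ``max(1, n // (2k))``; each chromosome
    appears in at most one test set, as far as divisibility allows.
    """
    chroms = [c for c in chroms if c not in exclude]
    n = len(chroms)
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} chromosomes for k={k}")
    s = max(1, n // (2 * k))
    rng = np.random.default_rng(seed)
    order = [chroms[i] for i in rng.permutation(n)]
    folds = []
    for f in range(k):
        test = order[f * s : (f + 1) * s]
        val = [order[(((f + 1) * s) + t) % n] for t in range(s)]
        val = [c for c in val if c not in test]
        while len(val) < s:  # wrapped into the test block; extend past it
            nxt = order[(((f + 1) * s) + len(val) + s) % n]
            if nxt not in test and nxt not in val:
                val.append(nxt)
        train = [c for c in order if c not in test and c not in val]
        folds.append(FoldSpec(f, sorted(train), sorted(val), sorted(test)))
    return folds


def pairs_within(label_set: LabelSet, chroms: list[str]) -> LabelSet:
    """Restrict a LabelSet to pairs whose both chromosomes are in `chroms`."""
    grid = label_set.grid
    keep = set(chroms)

    def ok(pair):
        return (
            grid.bin_location(pair[0])[0] in keep
            and grid.bin_location(pair[1])[0] in keep
        )

    return LabelSet(
        {p for p in label_set.positives if ok(p)},
        {p for p in label_set.negatives if ok(p)},
        label_set.excluded,
        label_set.params,
        grid,
    )
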