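"""Consensus label calling, parameter sweep, reproducibility, folds."""

import itertools

import numpy as np
import pytest

from twinc.contacts import BinGrid, ContactData, ReplicateSet, TransContactMap
from twinc.labels import (
    LabelParams,
    LabelSet,
    call_labels,
    chrom_folds,
    coverage_mask,
    reproducibility_point,
    sweep_label_params,
)

GRID3 = BinGrid.from_chromsizes(
    {"cA": 2_000_000, "cB": 2_000_000, "cC": 2_000_000}, 100_000
)  # 20 bins each


def make_repset(rng, n_reps=5, lam=1.0, grid=GRID3, group="labels"):
    reps = {}
    for r in range(n_reps):
        data = ContactData(grid)
        for ca, cb in grid.chrom_pairs():
            data.trans[(ca, cb)] = TransContactMap(
                ca, cb,
                rng.poisson(lam, (grid.n_bins(ca), grid.n_bins(cb))).astype(float),
            )
        reps[f"{group}{r}"] = data
    return ReplicateSet(grid, reps, group=group)


def oracle_labels(repset, params, mask):
    """Exhaustive per-cell re-derivation of the calling rule."""
    grid = repset.grid
    offs = grid.chrom_offsets
    reps = list(repset.replicates.values())
    pos, neg = set(), set()
    for ca, cb in grid.chrom_pairs():
        nA, nB = grid.n_bins(ca), grid.n_bins(cb)
        summed = np.zeros((nA, nB))
        for r in reps:
            summed += r.trans_matrix(ca, cb)
        for i in range(nA):
            for j in range(nB):
                if mask[offs[ca] + i] or mask[offs[cb] + j]:
                    continue
                counts = [r.trans_matrix(ca, cb)[i, j] for r in reps]
                is_pos = sum(c >= params.i for c in counts) >= params.m
                if is_pos:
                    pos.add((offs[ca] + i, offs[cb] + j))
                    continue
                row_vals = [
                    summed[i, jj] for jj in range(nB)
                    if not mask[offs[cb] + jj]
                ]
                col_vals = [
                    summed[ii, j] for ii in range(nA)
                    if not mask[offs[ca] + ii]
                ]
                if sum(row_vals) == 0 or sum(col_vals) == 0:
                    continue
                if sum(c <= params.j for c in counts) >= params.n:
                    neg.add((offs[ca] + i, offs[cb] + j))
    return pos, neg


class TestCoverageMask:
    def test_top_and_bottom_fractions(self):
        rng = np.random.default_rng(0)
        repset = make_repset(rng, lam=3.0)
        mask = coverage_mask(repset, top_frac=0.1, bottom_frac=0.2)
        # 60 bins -> 6 top + 12 bottom
        assert mask.sum() == 18

    def test_matches_sort_oracle(self):
        from twinc.contacts import sum_replicates, trans_bin_coverage

        rng = np.random.default_rng(1)
        repset = make_repset(rng, lam=5.0)
        cov = trans_bin_coverage(sum_replicates(repset))
        mask = coverage_mask(repset, top_frac=0.05, bottom_frac=0.1)
        order = sorted(range(cov.size), key=lambda b: (cov[b], b))
        expect = set(order[:6]) | set(order[-3:])
        assert set(np.nonzero(mask)[0]) == expect


class TestCallLabels:
    def test_forced_positive_and_negative_cells(self):
        grid = BinGrid.from_chromsizes({"cA": 300_000, "cB": 300_000}, 100_000)
        counts = [2, 2, 2, 0, 0]
        reps = {}
        for r, c in enumerate(counts):
            m = np.ones((3, 3))  # background keeps rows non-empty
            m[0, 0] = c
            m[1, 1] = [1, 1, 0, 0, 0][r]
            data = ContactData(grid)
            data.trans[("cA", "cB")] = TransContactMap("cA", "cB", m)
            reps[f"r{r}"] = data
        repset = ReplicateSet(grid, reps)
        mask = np.zeros(6, dtype=bool)
        ls = call_labels(repset, LabelParams(100_000, 2, 3, 1, 4), mask)
        assert (0, 3) in ls.positives       # counts (2,2,2,0,0), i=2, m=3
        assert (1, 4) in ls.negatives       # counts (1,1,0,0,0), j=1, n=4
        assert ls.positives.isdisjoint(ls.negatives)

    def test_replicate_order_invariance(self):
        rng = np.random.default_rng(2)
        repset = make_repset(rng)
        mask = np.zeros(GRID3.total_bins, dtype=bool)
        params = LabelParams(100_000, 2, 3, 1, 4)
        ls1 = call_labels(repset, params, mask)
        shuffled = ReplicateSet(
            GRID3, dict(reversed(list(repset.replicates.items())))
        )
        ls2 = call_labels(shuffled, params, mask)
        assert ls1.positives == ls2.positives and ls1.negatives == ls2.negatives

    def test_invalid_params_error(self):
        rng = np.random.default_rng(3)
        repset = make_repset(rng)
        with pytest.raises(ValueError):
            call_labels(repset, LabelParams(100_000, 1, 3, 1, 4))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        repset = make_repset(rng, lam=1.5)
        mask = coverage_mask(repset, top_frac=0.05, bottom_frac=0.05)
        for i, m, j, n in itertools.product((1, 2, 3), (2, 4), (0, 1), (2, 4)):
            if i <= j:
                continue
            params = LabelParams(100_000, i, m, j, n)
            ls = call_labels(repset, params, mask)
            opos, oneg = oracle_labels(repset, params, mask)
            assert ls.positives == opos
            assert ls.negatives == oneg

    def test_monotonicity_in_thresholds(self):
        rng = np.random.default_rng(9)
        repset = make_repset(rng, lam=2.0)
        mask = np.zeros(GRID3.total_bins, dtype=bool)
        base = call_labels(repset, LabelParams(100_000, 2, 3, 1, 4), mask)
        stricter_i = call_labels(repset, LabelParams(100_000, 3, 3, 1, 4), mask)
        stricter_m = call_labels(repset, LabelParams(100_000, 2, 4, 1, 4), mask)
        assert stricter_i.positives <= base.positives
        assert stricter_m.positives <= base.positives


class TestSweep:
    def test_identical_prediction_counts_give_auroc_one(self):
        rng = np.random.default_rng(4)
        lg = make_repset(rng, lam=1.0)
        # prediction group identical to label group -> perfect ranking
        pg = ReplicateSet(GRID3, dict(lg.replicates), group="predictions")
        table, best = sweep_label_params(
            lg, pg, candidates=[LabelParams(100_000, 2, 3, 0, 4)]
        )
        row = table.iloc[0]
        if row.n_pos > 0 and row.n_neg > 0:
            assert row.auroc > 0.95

    def test_shuffled_predictions_near_chance(self):
        rng = np.random.default_rng(5)
        grid = BinGrid.from_chromsizes(
            {"cA": 5_000_000, "cB": 5_000_000}, 100_000
        )
        lg = make_repset(rng, lam=1.0, grid=grid)
        pg = make_repset(rng, lam=1.0, grid=grid, group="predictions")
        table, _ = sweep_label_params(
            lg, pg, candidates=[LabelParams(100_000, 1, 2, 0, 4)]
        )
        row = table.iloc[0]
        assert row.n_pos + row.n_neg >= 2000
        assert abs(row.auroc - 0.5) < 0.05

    def test_degenerate_candidate_flagged(self):
        rng = np.random.default_rng(6)
        lg = make_repset(rng, lam=0.0)  # all-zero maps: no positives
        pg = make_repset(rng, lam=0.0, group="predictions")
        table, best = sweep_label_params(
            lg, pg, candidates=[LabelParams(100_000, 2, 3, 1, 4)]
        )
        assert np.isnan(table.iloc[0].auroc)
        assert best is None


class TestReproducibilityPoint:
    def _labelset(self, pos, neg):
        return LabelSet(set(pos), set(neg), np.zeros(4, bool),
                        LabelParams(100_000, 2, 3, 1, 4), None)

    def test_identical_groups(self):
        a = self._labelset({(0, 2), (1, 3)}, {(0, 3)})
        assert reproducibility_point(a, a) == (1.0, 0.0)

    def test_inverted_groups(self):
        a = self._labelset({(0, 2)}, {(1, 3)})
        b = self._labelset({(1, 3)}, {(0, 2)})
        assert reproducibility_point(a, b) == (0.0, 1.0)

    def test_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(7)
        pairs = [(i, j + 50) for i in range(30) for j in range(30)]
        arr = rng.random(len(pairs))
        posA = {p for p, u in zip(pairs, arr) if u < 0.3}
        negA = {p for p, u in zip(pairs, arr) if 0.3 <= u < 0.7}
        arr2 = rng.random(len(pairs))
        posB = {p for p, u in zip(pairs, arr2) if u < 0.4}
        negB = {p for p, u in zip(pairs, arr2) if 0.5 <= u < 0.9}
        a, b = self._labelset(posA, negA), self._labelset(posB, negB)
        tpr, fpr = reproducibility_point(a, b)
        labeledB = posB | negB
        assert tpr == pytest.approx(len(posA & posB) / len(posA & labeledB))
        assert fpr == pytest.approx(len(negA & posB) / len(negA & labeledB))

    def test_empty_denominator_errors(self):
        a = self._labelset({(0, 2)}, {(1, 3)})
        b = self._labelset(set(), set())
        with pytest.raises(ValueError):
            reproducibility_point(a, b)


class TestChromFolds:
    def test_23_chromosomes_five_folds(self):
        chroms = [f"chr{i}" for i in range(1, 23)] + ["chrX"]
        folds = chrom_folds(chroms, k=5, seed=0)
        tests = [set(f.test) for f in folds]
        assert all(len(t) == 2 for t in tests)
        assert all(len(f.validation) == 2 for f in folds)
        assert all(len(f.train) == 19 for f in folds)
        for a, b in itertools.combinations(tests, 2):
            assert not a & b

    def test_exclusion_list_applied(self):
        chroms = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY", "chrM"]
        folds = chrom_folds(chroms, k=5, seed=0)
        for f in folds:
            all_c = set(f.train) | set(f.validation) | set(f.test)
            assert "chrY" not in all_c and "chrM" not in all_c

    def test_toy_partition_sizes(self):
        folds = chrom_folds([f"c{i}" for i in range(6)], k=3, seed=1)
        for f in folds:
            assert (len(f.train), len(f.validation), len(f.test)) == (4, 1, 1)
            assert not set(f.train) & set(f.test)
            assert not set(f.validation) & set(f.test)
        tests = [set(f.test) for f in folds]
        for a, b in itertools.combinations(tests, 2):
            assert not a & b

    def test_deterministic_under_seed(self):
        chroms = [f"chr{i}" for i in range(1, 24)]
        f1 = chrom_folds(chroms, k=5, seed=42)
        f2 = chrom_folds(chroms, k=5, seed=42)
        assert [(f.train, f.validation, f.test) for f in f1] == [
            (f.train, f.validation, f.test) for f in f2
        ]

    def test_too_few_chromosomes_errors(self):
        with pytest.raises(ValueError):
            chrom_folds(["c1", "c2", "c3"], k=5, seed=0)
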