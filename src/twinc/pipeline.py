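"""End-to-end reproducible run: simulate -> label -> train -> evaluate.

A single YAML-derived dict drives the whole run; every stage seeds its own
randomness from the run seed and the outputs carry a metadata block with
the config hash, so re-running an identical config reproduces identical
deterministic artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .labels import LabelParams, call_labels, coverage_mask, pairs_within
from .metrics import binary_metrics, gc_baseline
from .model import TwinCConfig, build_model
from .synthetic import SyntheticSpec, simulate_world
from .training import TrainConfig, _pair_arrays, _score_pairs, train_classifier

#: the end-to-end demonstration uses sixteen 400 kb chromosomes (10/3/3
#: split): chromosome-disjoint train/validation/test trans pairs require at
#: least two chromosomes per set, and ~1000 distinct training windows are
#: what makes the planted motif rule learnable rather than memorizable
DEFAULT_SPLIT = {"train": 10, "validation": 3, "test": 3}


def run_pipeline(config: dict, outdir: Path) -> dict:
    """Run the synthetic end-to-end study; returns paths and metrics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    spec_overrides = dict(config.get("synthetic", {}))
    spec_overrides.setdefault("n_chroms", sum(DEFAULT_SPLIT.values()))
    spec = SyntheticSpec(seed=seed, **spec_overrides)

    lp = config.get("label_params", {})
    params = LabelParams(
        spec.resolution, lp.get("i", 2), lp.get("m", 3),
        lp.get("j", 1), lp.get("n", 4),
    )

    store, truth, label_group, prediction_group = simulate_world(spec)
    mask = coverage_mask(label_group)
    label_set = call_labels(label_group, params, mask)

    chroms = spec.chrom_names
    split = {**DEFAULT_SPLIT, **config.get("split", {})}
    n_tr = len(chroms) - split["validation"] - split["test"]
    train_chroms = chroms[:n_tr]
    val_chroms = chroms[n_tr : n_tr + split["validation"]]
    test_chroms = chroms[n_tr + split["validation"] :]

    labels_train = pairs_within(label_set, train_chroms)
    labels_val = pairs_within(label_set, val_chroms)
    labels_test = pairs_within(label_set, test_chroms)

    tc = config.get("train", {})
    train_config = TrainConfig(
        lr=tc.get("lr", 2.5e-3),
        seed=seed + 1,
        max_batches=tc.get("max_batches", 1400),
        eval_interval=tc.get("eval_interval", 200),
        val_subsample=tc.get("val_subsample", 256),
    )
    net = build_model(TwinCConfig.toy(), seed=seed + 2)
    _, history = train_classifier(net, store, labels_train, labels_val,
                                  train_config)

    pos, neg = _pair_arrays(labels_test)
    rng = np.random.default_rng(seed + 3)
    max_neg = int(config.get("max_test_negatives", 4000))
    if len(neg) > max_neg:
        neg = neg[rng.choice(len(neg), max_neg, replace=False)]
    pairs = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    scores = _score_pairs(net, store, label_set.grid, pairs,
                          net.config.window_bp)
    rep = binary_metrics(y, scores)

    coords = [
        label_set.grid.bin_location(a) + label_set.grid.bin_location(b)
        for a, b in pairs
    ]
    gc_rep = binary_metrics(
        y, gc_baseline(coords, store, net.config.window_bp)
    )

    metrics = {
        "test_auroc": rep.auroc,
        "test_average_precision": rep.average_precision,
        "gc_baseline_auroc": gc_rep.auroc,
        "n_test_pos": int(len(pos)),
        "n_test_neg": int(len(neg)),
    }

    blob = json.dumps(config, sort_keys=True, default=str)
    payload = {
        "metadata": {
            "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
            "seed": seed,
            "spec": asdict(spec),
            "split": {"train": train_chroms, "validation": val_chroms,
                      "test": test_chroms},
        },
        "metrics": metrics,
    }
    (outdir / "metrics.json").write_text(json.dumps(payload, indent=1))
    history.to_csv(outdir / "history.csv", index=False)
    net.save(outdir / "model.twinc")
    return {"metrics": metrics, "outdir": str(outdir), "net": net,
            "store": store, "truth": truth, "label_set": label_set,
            "test_pairs": pairs, "test_labels": y, "test_scores": scores}
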