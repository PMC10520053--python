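#!/usr/bin/env python
"""Full-scale accuracy-vs-model-size sweep (workstation/cluster scale).

Trains OReN and saccadic variants across a geometric progression of layer
widths, in the separate setup (one model per concept, default size 3840)
or the joint setup (one model over all concepts, default size 108,000),
and writes per-configuration accuracies and parameter counts to JSON.

This is deliberately heavy: a full separate sweep over all registered
concepts and widths is an overnight workstation run on CPU. Trim
--concepts / --widths / --size for anything smaller.

Usage:
    python scripts/full_sweep.py --arch saccadic --unit ssnu \
        --widths 16,32,64 --mode separate --size 3840 --seed 0 --out sweep.json
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--arch", choices=["oren", "saccadic"], required=True)
    parser.add_argument("--unit", choices=["snn", "ssnu", "ssnu-r", "lstm"],
                        default="ssnu")
    parser.add_argument("--widths", default="16,32,64,128,256",
                        help="comma-separated layer widths N")
    parser.add_argument("--mode", choices=["separate", "joint"], default="separate")
    parser.add_argument("--concepts", default=None,
                        help="comma-separated concept ids (default: all registered)")
    parser.add_argument("--size", type=int, default=None,
                        help="dataset size (default 3840 separate / 108000 joint)")
    parser.add_argument("--epochs", type=int, default=20)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--human-thresholds", type=Path, default=None,
                        help="JSON file mapping concept id -> accuracy threshold")
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()

    from oddity.harness import (TrainConfig, count_parameters, train_model,
                                train_separate)
    from oddity.riddlegen import DatasetConfig, build_dataset, default_registry

    concepts = (args.concepts.split(",") if args.concepts
                else sorted(default_registry()))
    size = args.size or (3840 if args.mode == "separate" else 108_000)
    thresholds = (json.loads(args.human_thresholds.read_text())
                  if args.human_thresholds else None)

    sweep = []
    for n in (int(w) for w in args.widths.split(",")):
        cfg = TrainConfig(arch=args.arch, unit=args.unit, n=n,
                          epochs=args.epochs, seed=args.seed)
        params = count_parameters(args.arch, n, unit=args.unit)
        print(f"=== {args.arch}/{args.unit} N={n} ({params:,} parameters)", flush=True)
        if args.mode == "separate":
            res = train_separate(concepts, cfg, size=size, data_seed=args.seed,
                                 human_thresholds=thresholds)
            entry = {
                "n": n, "parameters": params,
                "mean_test_accuracy": res["mean_test_accuracy"],
                "mean_epochs_to_human_level": res["mean_epochs_to_human_level"],
                "per_concept": {c: r["test_accuracy"]
                                for c, r in res["per_concept"].items()},
            }
        else:
            data = build_dataset(DatasetConfig(mode="joint",
                                               concepts=tuple(concepts),
                                               size=size, seed=args.seed))
            _, hist = train_model(cfg, data)
            entry = {"n": n, "parameters": params,
                     "test_accuracy": hist.test_accuracy[-1]}
        sweep.append(entry)
        args.out.write_text(json.dumps(sweep, indent=2))
        print(json.dumps(entry, indent=2), flush=True)


if __name__ == "__main__":
    main()
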