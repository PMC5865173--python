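#!/usr/bin/env python
"""Calibrate the morphology classification thresholds on the generator.

Sweeps the ramified solidity cut and the elongated eccentricity cut over
a grid, scoring agreement with the generator's ground-truth classes for
both packaged channel profiles, and prints the accuracy-maximizing pair.
The shipped defaults (s_ramified=0.75, e_elongated=0.90) come from this
sweep.

    python scripts/calibrate_morphology.py [--n 800] [--seed 0]
"""

import argparse

import numpy as np

import eaekit as ek


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n", type=int, default=800, help="masks per channel")
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    records, truth = [], []
    for i, (channel, cfg) in enumerate(ek.load_morphology_profiles().items()):
        masks = ek.simulate_cell_masks(cfg, args.n, seed=args.seed + i)
        for cell, cls, _ in masks:
            rec = ek.measure(cell)
            records.append([rec.solidity, rec.eccentricity])
            truth.append(cls)
    X = np.asarray(records)
    truth = np.asarray(truth)

    best = (0.0, None)
    for s_r in np.arange(0.60, 0.86, 0.025):
        for e_e in np.arange(0.80, 0.97, 0.02):
            pred = ek.MorphologyClassifier(s_ramified=s_r,
                                           e_elongated=e_e).predict(X)
            acc = float((pred == truth).mean())
            if acc > best[0]:
                best = (acc, (round(float(s_r), 3), round(float(e_e), 3)))
    acc, (s_r, e_e) = best
    print(f"best: s_ramified={s_r} e_elongated={e_e} accuracy={acc:.4f}")
    default = ek.MorphologyClassifier()
    acc_def = float((default.predict(X) == truth).mean())
    print(f"shipped defaults: s_ramified={default.s_ramified} "
          f"e_elongated={default.e_elongated} accuracy={acc_def:.4f}")


if __name__ == "__main__":
    main()
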