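#!/usr/bin/env python
"""Windowed diversity within and between taxa on the reference dataset.

Reproduces the windowed-divergence picture that motivates everything
downstream: within-taxon windows are uniformly low; admixed-vs-donor
windows are bimodal -- a low mode from introgressed tracts that coalesce
recently, and a high mode at the taxon divergence.
"""

import importlib
import os

import numpy as np

from selfmix.diversity import pairwise_pi, windowed_pi
from selfmix.synthetic_data import simulate_dataset

sim = importlib.import_module("01_simulate")


def main():
    ds = simulate_dataset(sim.CONFIG)
    os.makedirs(sim.RESULTS, exist_ok=True)

    pairs = {
        "recipient_within": ("recipient0", "recipient1"),
        "donor_within": ("donor0", "donor1"),
        "recipient_donor": ("recipient0", "donor0"),
        "admixed_donor": ("admixed0", "donor0"),
    }
    rows = []
    for label, (a, b) in pairs.items():
        genome = pairwise_pi(ds.panel, a, b)
        ws = [w for w in windowed_pi(ds.panel, a, b, window_bp=5_000,
                                     slide_bp=5_000, min_sites=100)
              if not w.insufficient]
        vals = np.array([w.pi for w in ws])
        low = float(np.mean(vals < 0.005))
        rows.append((label, a, b, genome.pi, len(ws), low))
        print(f"{label:18s} pi = {genome.pi:.4f}   "
              f"{100 * low:5.1f}% of 5 kb windows below 0.5%")

    with open(os.path.join(sim.RESULTS, "02_diversity.tsv"), "w") as fh:
        fh.write("comparison\ta\tb\tgenome_pi\tn_windows\tfrac_windows_below_005\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")

    # the admixed sample shows a bimodal divergence distribution: its
    # low-divergence window fraction approximates the admixture proportion
    admix_low = rows[-1][-1]
    print(f"\nlow-divergence window fraction for the admixed sample "
          f"({admix_low:.3f}) tracks the planted alpha = {sim.CONFIG.alpha}")


if __name__ == "__main__":
    main()
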