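#!/usr/bin/env python
"""Depth-dependent bias of pi and robustness of ANIr under rarefaction.

Simulates a deeply sequenced (~600X) 100-strain Q30 metagenome on a 100 kb
ancestor, subsamples it on the 1-90% fraction grid with replicates, and
tabulates the diversity ratio (subsample metric / full-data metric) for both
pi and ANIr, plus average absolute relative errors per depth bin.

Writes results/rarefaction_points.tsv and results/rarefaction_error_summary.tsv.
"""
import math
import sys
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

import microdepth as m
from microdepth.experiment import PAPER_FRACTIONS
from microdepth.rarefy import average_absolute_error

SEED = 2
GENOME_LENGTH = 100_000
READ_LENGTH = 150
DEPTH = 600
N_STRAINS = 100
REPLICATES = 3


def main() -> int:
    n_reads = math.ceil(DEPTH * GENOME_LENGTH / READ_LENGTH)
    anc = m.generate_ancestor(GENOME_LENGTH, 0.5, seed=SEED)
    sset = m.derive_strain_set(anc, N_STRAINS, (0.0, 0.0249), seed=SEED + 1)
    ab = m.sample_lognormal_abundances(N_STRAINS, 1.0, seed=SEED + 2)

    with tempfile.TemporaryDirectory() as tmp:
        sim = m.simulate_metagenome(sset, ab, n_reads, READ_LENGTH, m.Q30,
                                    seed=SEED + 3, out_prefix=Path(tmp) / "d")
        reads = m.load_alignments(sim.sam, anc)
    points = m.rarefaction_series(reads, anc, PAPER_FRACTIONS,
                                  replicates=REPLICATES, seed=SEED + 4)

    df = pd.DataFrame([vars(p) for p in points])
    summaries = []
    for metric in ("pi", "anir"):
        full = {"pi": df["pi"] / df["ratio_pi"],
                "anir": df["anir"] / df["ratio_anir"]}[metric]
        summ = average_absolute_error(list(zip(df[metric], full)),
                                      list(df["mean_depth"]))
        summ.insert(0, "metric", metric)
        summaries.append(summ)
    summary = pd.concat(summaries, ignore_index=True)

    out = Path(__file__).resolve().parents[1] / "results"
    out.mkdir(exist_ok=True)
    df.to_csv(out / "rarefaction_points.tsv", sep="\t", index=False)
    summary.to_csv(out / "rarefaction_error_summary.tsv", sep="\t",
                   index=False)

    for lo, hi, label in ((40, 70, "~50X"), (150, 250, "~200X")):
        sel = df[(df.mean_depth >= lo) & (df.mean_depth <= hi)]
        if len(sel):
            print(f"median pi ratio at {label} "
                  f"({sel.mean_depth.mean():.0f}X): "
                  f"{sel.ratio_pi.median():.4f}   "
                  f"ANIr ratio: {sel.ratio_anir.median():.6f}")
    print("\nPer-depth-bin average absolute relative errors (%):")
    print(summary.to_string(index=False))
    print("\nFinding: pi is underestimated at every subsampled depth and the "
          "ratio climbs toward (but never reaches) 1 with depth, while ANIr "
          "ratios stay ~1 with errors orders of magnitude smaller.")
    print(f"wrote {out / 'rarefaction_points.tsv'} and "
          f"{out / 'rarefaction_error_summary.tsv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
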