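#!/usr/bin/env python
"""Simulate the synthetic cohort every later analysis step consumes.

Three datasets are generated under scratch/cohort/ (BAM and FASTA artifacts
are large/binary, so they live outside results/):

  germline_panel/  3'-kit dataset, 12 germline variants spread from 10 to
                   1,800 nt from the 3' transcript end, one of them rescued
                   by an internal 10-A mispriming site; no mosaic variant.
  null_panel/      3'-kit dataset with 24 "null" variants no cell carries,
                   for false-positive measurement.
  mosaic_5p/ and mosaic_3p/
                   the same cell population carrying a mosaic variant
                   (5% of cells, all germ layers) 50 nt from the 5' cap,
                   captured with the 5' and the 3' chemistry respectively.

Truth summaries (cell counts, true mosaic fraction) go to results/.
"""

from pathlib import Path
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "scripts"))
from acceptance import PANEL_DISTANCES  # shared panel definition

from dropgeno.simulate import (
    DEFAULT_CELL_TYPES,
    ExpressionModel,
    PolyASpec,
    SimConfig,
    VariantPlacement,
    simulate_dataset,
)

SEED = 20260926
ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    n_genes = len(PANEL_DISTANCES)

    germline = SimConfig(
        n_cells=1500, n_genes=n_genes, seed=SEED, kit_end="three_prime",
        exon_layout=tuple((1200, 800) if g % 2 else (2000,) for g in range(n_genes)),
        variants=tuple(
            VariantPlacement(g, 2000 - 1 - d, "germline")
            for g, d in enumerate(PANEL_DISTANCES)
        ),
        internal_polyA=(PolyASpec(10, (2000 - 1 - 1500) + 40, 10),),
        mispriming_rate=0.08, error_rate=0.001, mosaic_fraction=0.0,
        nb_mean_range=(0.3, 4.0),
    )
    simulate_dataset(germline, SCRATCH / "germline_panel")

    null = SimConfig(
        n_cells=800, n_genes=n_genes, seed=SEED + 1, kit_end="three_prime",
        exon_layout=tuple((2000,) for _ in range(n_genes)),
        variants=tuple(
            VariantPlacement(g, 2000 - 1 - d - off, "null_set")
            for off in (0, 15) for g, d in enumerate(PANEL_DISTANCES)
        ),
        mispriming_rate=0.0, error_rate=0.001, mosaic_fraction=0.0,
        nb_mean_range=(0.3, 3.0),
    )
    simulate_dataset(null, SCRATCH / "null_panel")

    model = ExpressionModel.random(
        8, DEFAULT_CELL_TYPES, np.random.default_rng([SEED, 9]), mean_range=(0.5, 3.0)
    )
    means = np.array(model.means)
    means[0, :] = 2.5
    model = ExpressionModel(tuple(map(tuple, means)), model.dispersion)
    summaries = []
    # distinct seeds per kit: separate nuclei drawn from the same tissue model
    for kit, sub, seed in (("five_prime", "mosaic_5p", SEED + 2), ("three_prime", "mosaic_3p", SEED + 3)):
        cfg = SimConfig(
            n_cells=2000, n_genes=8, seed=seed, kit_end=kit,
            exon_layout=((1200, 1000),),
            variants=(VariantPlacement(0, 50, "somatic_candidate"),),
            mispriming_rate=0.0, error_rate=0.001, mosaic_fraction=0.05,
            expression_model=model,
        )
        paths = simulate_dataset(cfg, SCRATCH / sub)
        truth = pd.read_csv(Path(paths["truth"]) / "truth_cells.tsv", sep="\t")
        summaries.append(
            {
                "dataset": sub, "kit": kit, "n_cells": len(truth),
                "n_mutant_cells": int(truth["is_mutant"].sum()),
                "true_mosaic_fraction": round(truth["is_mutant"].mean(), 4),
            }
        )
    summary = pd.DataFrame(summaries)
    summary.to_csv(RESULTS / "cohort_truth_summary.tsv", sep="\t", index=False)
    print(f"simulated cohort under {SCRATCH}")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
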