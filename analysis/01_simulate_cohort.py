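"""Simulate a small two-group signet-ring-cell cohort to disk.

Generates 2 groups x 3 slides x 120 cells with an ellipticity-atypia
(EP SD) effect injected into the LN-positive group, writing instance
masks, ground truth and covariates under results/cohort/.  The full-size
demo cohort (2 x 10 x 500) is exercised in memory by 04; this small one
keeps the file-based walkthrough quick.
"""

from pathlib import Path

from ringmorph import cli

CONFIG = {
    "min_cells": 100,
    "outcome": "ln_status",
    "groups": [
        {
            "name": "ln_neg",
            "n_slides": 3,
            "cells_per_slide": 120,
            "image_shape": [1000, 1000],
            "dist": {"cell_area_mean": 2000, "cell_area_sd": 400,
                     "aspect_ratio_sd": 0.06},
            "slide_jitter": {"aspect_ratio_sd": 0.012},
            "covariates": {"site": "colorectum", "lesion_type": "primary",
                           "ln_status": 0, "t_stage": 2},
        },
        {
            "name": "ln_pos",
            "n_slides": 3,
            "cells_per_slide": 120,
            "image_shape": [1000, 1000],
            "dist": {"cell_area_mean": 2000, "cell_area_sd": 400,
                     "aspect_ratio_sd": 0.085},
            "slide_jitter": {"aspect_ratio_sd": 0.012},
            "covariates": {"site": "colorectum", "lesion_type": "primary",
                           "ln_status": 1, "t_stage": 3},
        },
    ],
}

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"

if __name__ == "__main__":
    covariates = cli.run_simulate(CONFIG, seed=7, outdir=OUT)
    print(f"wrote {len(covariates)} slides ({covariates['group'].value_counts().to_dict()})")
    print(f"masks, truth.csv and covariates.csv under {OUT}")
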