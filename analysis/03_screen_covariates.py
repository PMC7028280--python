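#!/usr/bin/env python
"""Apply the variable-exclusion filter to the simulated covariate database.

Drops covariates with no spatial variability (identical 10th and 90th
percentiles) or too few distinct values, mirroring the pre-modelling screen
applied to the raw geographic-variable database, and writes the exclusion
report.  Run 01_simulate_network.py first.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ieg.covariates import CovariateMatrix, filter_variables
from ieg.io_config import load_tables

DATA = Path("scratch/analysis_data")
RESULTS = Path("results")


def main() -> None:
    data, cm, report = load_tables(
        DATA / "sites.csv", DATA / "annual.csv", DATA / "covariates.csv",
        DATA / "categories.csv",
    )
    print("loaded:", report)

    # add two pathological columns of the kind the screen exists for
    values = np.column_stack([
        cm.values,
        np.full(len(cm.site_ids), 3.7),                      # constant
        (np.arange(len(cm.site_ids)) % 3).astype(float),     # 3 unique values
    ])
    cm_aug = CovariateMatrix(
        site_ids=cm.site_ids,
        variable_names=cm.variable_names + ["CONST", "FEWVALS"],
        categories={**cm.categories, "CONST": "position", "FEWVALS": "source"},
        values=values,
    )
    kept = filter_variables(cm_aug)
    RESULTS.mkdir(exist_ok=True)
    kept.exclusions.to_csv(RESULTS / "03_excluded_variables.csv", index=False)
    print(f"retained {len(kept.variable_names)} of {len(cm_aug.variable_names)} "
          f"variables; exclusions:")
    print(kept.exclusions.to_string(index=False))


if __name__ == "__main__":
    main()
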