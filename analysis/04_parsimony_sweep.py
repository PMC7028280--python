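#!/usr/bin/env python
"""The central experiment: model performance versus number of covariates.

Sweeps the number of forward-selected covariates offered to PLS (0 = ordinary
kriging, a parsimonious band, and the full set) under conventional and
spatially clustered 10-fold cross-validation on the simulated network, then
summarises the no / some / all triplets.  Run 01_simulate_network.py first.
"""

from pathlib import Path

from ieg.evaluation import make_folds_clustered, make_folds_conventional
from ieg.experiment import parsimony_sweep, summarize_bands
from ieg.io_config import load_tables

DATA = Path("scratch/analysis_data")
RESULTS = Path("results")
K_LIST = (0, 3, 5, 10, 20, 30, 60, "all")
SEED = 20260928


def main() -> None:
    data, _, _ = load_tables(
        DATA / "sites.csv", DATA / "annual.csv", DATA / "covariates.csv"
    )
    folds = {
        "conventional": make_folds_conventional(len(data.site_ids), 10, SEED),
        "clustered": make_folds_clustered(data.coords, 10, SEED),
    }
    table = parsimony_sweep(
        data, folds, k_list=K_LIST, checkpoint_dir="scratch/sweep_checkpoints"
    )
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "04_parsimony_table.csv", index=False)
    bands = summarize_bands(table)
    bands.to_csv(RESULTS / "04_band_summary.csv", index=False)

    print(table.to_string(index=False))
    print("\nno / 3-30 band median / all summaries:")
    print(bands.to_string(index=False))
    r2 = bands[(bands.statistic == "r2")].set_index("scheme")
    for scheme in ("conventional", "clustered"):
        z, b, a = r2.loc[scheme, ["zero", "band_3_30", "all"]]
        verdict = "band beats all" if b >= a else "all beats band"
        print(f"{scheme}: R2 zero={z:.2f} band={b:.2f} all={a:.2f} -> {verdict}")


if __name__ == "__main__":
    main()
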