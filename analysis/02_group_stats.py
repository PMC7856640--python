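"""Mass-univariate group comparisons on the simulated cohort.

Reads the feature tables written by 01_simulate.py, reproduces the cohort
demographics table (Welch t for age, Yates chi-square for sex), and runs
per-feature Welch t tests with BH-FDR within each modality for each group
contrast.  Writes tidy CSVs under results/analysis/.
"""

from pathlib import Path

import pandas as pd

from simfa.data_model import (
    MultiModalDataset,
    encode_covariates,
    read_covariate_table,
    read_feature_table,
)
from simfa.group_stats import demographics_table, group_difference_table

DATA = Path("results/analysis/data")
OUT = Path("results/analysis")
CONTRASTS = [("HC", "S_FEP"), ("HC", "M_FEP"), ("S_FEP", "M_FEP")]
MODALITIES = ("volume", "FA", "MD", "rsfmri")


def load_dataset() -> tuple[MultiModalDataset, pd.DataFrame]:
    demo = read_covariate_table(DATA / "covariates.csv")
    blocks = [
        # synthetic tables are already on a standardized (z-like) scale
        read_feature_table(DATA / f"features_{m}.csv", m, standardized=True)
        for m in MODALITIES
    ]
    return MultiModalDataset(blocks, encode_covariates(demo)), demo


def main() -> None:
    ds, demo = load_dataset()
    demo_tab = demographics_table(demo, CONTRASTS)
    demo_tab.to_csv(OUT / "table_demographics.csv", index=False,
                    float_format="%.4g")
    print("demographics tests (no group-matching violations expected):")
    print(demo_tab.round(3).to_string(index=False))

    frames = []
    for contrast in CONTRASTS:
        for m in MODALITIES:
            tab = group_difference_table(ds, contrast, m)
            t = tab.table
            n_rej = int(t["rejected"].sum())
            frames.append(
                t.assign(modality=m, contrast=f"{contrast[0]} vs {contrast[1]}")
            )
            print(
                f"{contrast[0]:>6} vs {contrast[1]:<6} {m:>7}: "
                f"{n_rej}/{len(t)} features pass FDR q<0.05"
            )
    pd.concat(frames, ignore_index=True).to_csv(
        OUT / "table_group_differences.csv", index=False, float_format="%.6g"
    )


if __name__ == "__main__":
    main()
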