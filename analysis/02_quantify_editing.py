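"""Quantify editing efficiencies and apply the informative-site filter.

Efficiency at a site is edited / (edited + unedited) base counts; cells
below 50 reads are missing.  A site is informative when its conversion is
canonical (C→T or G→A), fewer than 95% of observed genotype values sit at
exactly 0 or 1 (pooled over CK and DT), and fewer than 10% of cells are
missing.
"""

import argparse
from pathlib import Path

import pandas as pd

from medito.pipeline import run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/pipeline"))
    args = ap.parse_args()

    run_pipeline(None, args.out, seed=args.seed,
                 stages=["simulate", "quantify", "filter"], resume=True)
    info = pd.read_csv(args.out / "informative.tsv", sep="\t")
    print(f"informative sites: {int(info['informative'].sum())} / {len(info)}")
    failed = info.loc[~info["informative"], "reasons"].value_counts()
    if len(failed):
        print("exclusion reasons:")
        print(failed.to_string())
    eff = pd.read_csv(args.out / "editing_DT.tsv", sep="\t", index_col="genotype")
    print(f"DT matrix: {eff.shape[0]} genotypes x {eff.shape[1]} sites, "
          f"median efficiency {eff.stack().median():.2f}")


if __name__ == "__main__":
    main()
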