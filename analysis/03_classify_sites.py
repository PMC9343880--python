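"""Classify editing sites: drought response, ecotype differentiation,
alteration-ratio patterns, and codon consequences.

Drought response = paired t-test (CK vs DT per genotype); ecotype
differentiation = Welch t-test (upland vs lowland) in each condition;
patterns use the alteration ratio (E_d−E_w)/E_w at the ±0.2 bounds.
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
                 stages=["simulate", "quantify", "filter", "classify"], resume=True)
    cls = pd.read_csv(args.out / "classification.tsv", sep="\t")
    inf = cls[cls["informative"]]
    up = (inf["drought_responsive"] & (inf["drought_direction"] == "increase")).sum()
    down = (inf["drought_responsive"] & (inf["drought_direction"] == "decrease")).sum()
    ck = set(inf.loc[inf["ecotype_differentiated_CK"], "site_id"])
    dt = set(inf.loc[inf["ecotype_differentiated_DT"], "site_id"])
    print(f"drought-responsive: {up} increased, {down} decreased (of {len(inf)} informative)")
    print(f"ecotype-differentiated: {len(ck)} CK, {len(dt)} DT, {len(ck & dt)} common")
    nonsyn = inf[(inf["consequence"] == "nonsynonymous") & inf["site_id"].isin(ck | dt)]
    print(f"ecotype-differentiated nonsynonymous sites: {len(nonsyn)}")
    gp = pd.read_csv(args.out / "gene_patterns.tsv", sep="\t")
    stable = gp.nsmallest(3, "upregulated")["gene_id"].tolist()
    labile = gp.nlargest(3, "upregulated")["gene_id"].tolist()
    print(f"most stable genes (fewest upregulated combos): {stable}; most changeable: {labile}")


if __name__ == "__main__":
    main()
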