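"""Editing–phenotype correlation and the correlation structure among sites.

Significance of a site–trait correlation uses the dual criterion
|PCC| > 0.2 AND p < 0.05.  A gene's correlation with a trait is the site
record with the largest |PCC| (sign retained; ties broken toward the
positive value, then the lower gene position).  The structure analysis
labels every site pair adjacent / same-gene / unrelated and compares the
PCC distributions by two-sided Mann–Whitney tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import EditingMatrix, SitePanel

__all__ = [
    "site_trait_correlation",
    "gene_trait_correlation",
    "correlation_structure",
]

DEFAULT_PCC_THRESHOLD = 0.2
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_N = 20

#: agronomic traits measured after harvest; booting-stage editing vs these is
#: reported with a caveat note rather than dropped.
POST_HARVEST_TRAITS = {"PH", "NT", "NG", "100GW", "GY", "biomass", "HI", "fecundity"}


def site_trait_correlation(
    matrix: EditingMatrix,
    traits: pd.DataFrame,
    pcc_threshold: float = DEFAULT_PCC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    min_n: int = DEFAULT_MIN_N,
) -> pd.DataFrame:
    """Pearson r and two-sided p per site × trait, pairwise-complete.

    ``traits`` is genotype-indexed (one condition's slice) with one column
    per trait.  Site-trait pairs with fewer than ``min_n`` complete genotype
    pairs get NA records and are never significant.
    """
    traits = traits.reindex(matrix.genotypes)
    eff = matrix.efficiencies.to_numpy(dtype=float)
    rows = []
    for trait in traits.columns:
        y_all = traits[trait].to_numpy(dtype=float)
        for j, site in enumerate(matrix.site_ids):
            x = eff[:, j]
            ok = np.isfinite(x) & np.isfinite(y_all)
            n = int(ok.sum())
            if n < min_n or np.std(x[ok]) == 0 or np.std(y_all[ok]) == 0:
                r, p, sig = np.nan, np.nan, False
            else:
                r, p = stats.pearsonr(x[ok], y_all[ok])
                sig = bool(abs(r) > pcc_threshold and p < alpha)
            rows.append(
                {
                    "level": "site",
                    "id": site,
                    "trait": trait,
                    "condition": matrix.condition,
                    "pcc": r,
                    "p": p,
                    "n": n,
                    "significant": sig,
                    "caveat": (
                        "booting-stage editing vs post-harvest trait"
                        if trait in POST_HARVEST_TRAITS
                        else ""
                    ),
                }
            )
    return pd.DataFrame(rows)


def gene_trait_correlation(site_records: pd.DataFrame, panel: SitePanel) -> pd.DataFrame:
    """Aggregate site records to genes: sign-retained max-|PCC| per gene × trait.

    Ties on |PCC| prefer the positive value, then the lower gene position.
    Genes whose sites all have NA records yield NA rows.
    """
    info = panel.sites.set_index("site_id")[["gene_id", "gene_position"]]
    df = site_records.merge(info, left_on="id", right_index=True, how="left")
    rows = []
    for (gene, trait, cond), grp in df.groupby(["gene_id", "trait", "condition"], sort=True):
        valid = grp[np.isfinite(grp["pcc"])]
        if valid.empty:
            rows.append(
                {
                    "level": "gene",
                    "id": gene,
                    "trait": trait,
                    "condition": cond,
                    "pcc": np.nan,
                    "p": np.nan,
                    "n": 0,
                    "significant": False,
                    "best_site": None,
                }
            )
            continue
        best = valid.assign(_abs=valid["pcc"].abs()).sort_values(
            by=["_abs", "pcc", "gene_position"], ascending=[False, False, True]
        ).iloc[0]
        rows.append(
            {
                "level": "gene",
                "id": gene,
                "trait": trait,
                "condition": cond,
                "pcc": float(best["pcc"]),
                "p": float(best["p"]),
                "n": int(best["n"]),
                "significant": bool(best["significant"]),
                "best_site": best["id"],
            }
        )
    return pd.DataFrame(rows)


def correlation_structure(
    matrix: EditingMatrix,
    panel: SitePanel,
    min_periods: int = DEFAULT_MIN_N,
) -> dict:
    """Site-pair PCC distributions by relatedness, with Mann–Whitney tests.

    Pairs are labeled ``adjacent`` (consecutive panel sites of one gene),
    ``same_gene`` (same gene, non-adjacent) or ``unrelated`` (different
    genes).  Returns the three PCC arrays, their medians, and two-sided
    Mann–Whitney p-values for each group comparison (NaN when a group is
    empty or has a single pair and no counterpart).
    """
    if len(panel.genes) < 2:
        raise ValueError("structure analysis needs at least 2 genes")
    corr = matrix.efficiencies.corr(min_periods=min_periods)
    sites = panel.sites.reset_index(drop=True)
    order = {s: k for k, s in enumerate(sites["site_id"])}
    gene = sites.set_index("site_id")["gene_id"]
    # rank of each site within its gene, in panel (position) order
    rank = sites.groupby("gene_id").cumcount()
    rank.index = sites["site_id"]

    ids = [s for s in matrix.site_ids if s in order]
    groups: dict[str, list[float]] = {"adjacent": [], "same_gene": [], "unrelated": []}
    n = len(ids)
    cmat = corr.loc[ids, ids].to_numpy()
    for i in range(n):
        for j in range(i + 1, n):
            r = cmat[i, j]
            if not np.isfinite(r):
                continue
            si, sj = ids[i], ids[j]
            if gene[si] != gene[sj]:
                groups["unrelated"].append(r)
            elif abs(int(rank[si]) - int(rank[sj])) == 1:
                groups["adjacent"].append(r)
            else:
                groups["same_gene"].append(r)

    out: dict = {k: np.asarray(v) for k, v in groups.items()}
    for k in ("adjacent", "same_gene", "unrelated"):
        out[f"median_{k}"] = float(np.median(out[k])) if len(out[k]) else float("nan")
    for a, b in (("adjacent", "unrelated"), ("same_gene", "unrelated"), ("adjacent", "same_gene")):
        key = f"p_{a}_vs_{b}"
        if len(out[a]) and len(out[b]):
            out[key] = float(stats.mannwhitneyu(out[a], out[b], alternative="two-sided").pvalue)
        else:
            out[key] = float("nan")
    return out
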