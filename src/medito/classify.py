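"""Informative-site filtering, drought/ecotype tests, pattern calls, and
codon-consequence annotation.

The informative filter applies three criteria per site: (1) canonical C→T or
G→A conversion; (2) the fraction of observed genotype values lying at exactly
0 or exactly 1, pooled over CK and DT, is below 95%; (3) the fraction of
missing cells over all genotype × condition cells is below 10%.

Drought response is a two-sided paired t-test (CK vs DT per genotype);
ecotype differentiation is a two-sided Welch t-test (upland vs lowland)
within each condition.  Pattern calls use the alteration ratio
(E_d − E_w)/E_w with the ±0.2 bounds inclusive into "unchanged".
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .core import CANONICAL_EDITS, EditingMatrix, InsufficientDataError, SitePanel

__all__ = [
    "informative_filter",
    "classify_drought_response",
    "classify_pattern",
    "gene_pattern_summary",
    "ecotype_differentiation",
    "annotate_consequence",
]

DEFAULT_INVARIANT_FRACTION_MAX = 0.95
DEFAULT_MISSING_FRACTION_MAX = 0.10
DEFAULT_MIN_PAIRS = 10
DEFAULT_MIN_GROUP = 10
#: alteration-ratio category when E_w = 0: "upregulated" needs E_d >= this.
EW_ZERO_MIN_ED = 0.05


def _aligned(ck: EditingMatrix, dt: EditingMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    if list(ck.site_ids) != list(dt.site_ids):
        raise ValueError("CK and DT matrices must share the site panel")
    genos = [g for g in ck.genotypes if g in set(dt.genotypes)]
    if not genos:
        raise InsufficientDataError("no overlapping genotypes between CK and DT")
    return ck.efficiencies.loc[genos], dt.efficiencies.loc[genos]


def informative_filter(
    ck: EditingMatrix,
    dt: EditingMatrix,
    panel: SitePanel,
    invariant_fraction_max: float = DEFAULT_INVARIANT_FRACTION_MAX,
    missing_fraction_max: float = DEFAULT_MISSING_FRACTION_MAX,
    per_condition_invariant: bool = False,
) -> pd.DataFrame:
    """Per-site informative-filter report.

    Returns one row per panel site with columns ``canonical``,
    ``invariant_fraction``, ``missing_fraction``, ``informative`` and
    ``reasons`` (semicolon-joined failure labels, empty when informative).
    With ``per_condition_invariant`` the invariant criterion must fail in
    both conditions separately instead of pooled (the stricter pooled
    reading is the default).
    """
    if list(ck.site_ids) != list(dt.site_ids):
        raise ValueError("CK and DT matrices must share the site panel")
    if list(ck.site_ids) != panel.site_ids:
        raise ValueError("matrices and panel disagree on sites")
    pooled = pd.concat([ck.efficiencies, dt.efficiencies], axis=0)
    vals = pooled.to_numpy(dtype=float)
    observed = np.isfinite(vals)
    extreme = observed & ((vals == 0.0) | (vals == 1.0))
    with np.errstate(invalid="ignore"):
        if per_condition_invariant:
            fracs = []
            for m in (ck, dt):
                v = m.efficiencies.to_numpy(dtype=float)
                obs = np.isfinite(v)
                fracs.append(
                    np.where(obs.sum(0) > 0, (obs & ((v == 0) | (v == 1))).sum(0) / obs.sum(0), 0.0)
                )
            invariant_fraction = np.minimum(*fracs)
        else:
            n_obs = observed.sum(axis=0)
            invariant_fraction = np.where(n_obs > 0, extreme.sum(axis=0) / n_obs, 0.0)
    missing_fraction = 1.0 - observed.mean(axis=0)

    canonical = panel.sites["ref_base"].isin(CANONICAL_EDITS).to_numpy()
    reasons = []
    for i in range(len(canonical)):
        r = []
        if not canonical[i]:
            r.append("non-canonical")
        if invariant_fraction[i] >= invariant_fraction_max:
            r.append("invariant-fraction")
        if missing_fraction[i] >= missing_fraction_max:
            r.append("missingness")
        reasons.append(";".join(r))
    return pd.DataFrame(
        {
            "site_id": panel.site_ids,
            "gene_id": panel.sites["gene_id"].to_numpy(),
            "canonical": canonical,
            "invariant_fraction": invariant_fraction,
            "missing_fraction": missing_fraction,
            "informative": [r == "" for r in reasons],
            "reasons": reasons,
        }
    )


def classify_drought_response(
    ck: EditingMatrix,
    dt: EditingMatrix,
    alpha: float = 0.05,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> pd.DataFrame:
    """Paired t-test per site over genotypes present in both conditions.

    Pairs with either value missing are dropped.  Sites with fewer than
    ``min_pairs`` complete pairs or zero variance of differences get p = NA
    and are never flagged.  Direction is the sign of mean(DT − CK) when
    flagged.
    """
    e_ck, e_dt = _aligned(ck, dt)
    diffs = e_dt.to_numpy(dtype=float) - e_ck.to_numpy(dtype=float)
    rows = []
    for j, site in enumerate(e_ck.columns):
        d = diffs[:, j]
        d = d[np.isfinite(d)]
        n = d.size
        if n < min_pairs or np.allclose(d.std(ddof=0), 0.0):
            p, flag, direction = np.nan, False, "none"
        else:
            t, p = stats.ttest_1samp(d, 0.0)
            flag = bool(p < alpha)
            direction = ("increase" if d.mean() > 0 else "decrease") if flag else "none"
        rows.append(
            {
                "site_id": site,
                "n_pairs": n,
                "mean_delta": float(np.mean(d)) if n else np.nan,
                "drought_p": p,
                "drought_responsive": flag,
                "drought_direction": direction,
            }
        )
    return pd.DataFrame(rows)


def classify_pattern(ck: EditingMatrix, dt: EditingMatrix) -> pd.DataFrame:
    """Alteration-ratio pattern per genotype × site combination.

    ratio = (E_d − E_w)/E_w; "upregulated" if > 0.2, "downregulated" if
    < −0.2, otherwise "unchanged" (boundaries inclusive).  E_w = 0 makes the
    ratio undefined; such combinations are "upregulated" when E_d ≥ 0.05 and
    "unchanged" otherwise (ratio reported 0 when E_d = 0, NA otherwise).
    Combinations with either value missing are "undefined" (ratio NA).
    """
    e_ck, e_dt = _aligned(ck, dt)
    ew = e_ck.to_numpy(dtype=float)
    ed = e_dt.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (ed - ew) / ew
    missing = ~np.isfinite(ew) | ~np.isfinite(ed)
    zero_w = (ew == 0.0) & ~missing

    cat = np.full(ew.shape, "unchanged", dtype=object)
    cat[ratio > 0.2] = "upregulated"
    cat[ratio < -0.2] = "downregulated"
    cat[zero_w] = np.where(ed[zero_w] >= EW_ZERO_MIN_ED, "upregulated", "unchanged")
    ratio[zero_w & (ed == 0.0)] = 0.0
    ratio[zero_w & (ed != 0.0)] = np.nan
    cat[missing] = "undefined"
    ratio[missing] = np.nan

    n_geno, n_site = ew.shape
    return pd.DataFrame(
        {
            "genotype": np.repeat(e_ck.index.to_numpy(), n_site),
            "site_id": np.tile(e_ck.columns.to_numpy(), n_geno),
            "alteration_ratio": ratio.ravel(),
            "category": cat.ravel(),
        }
    )


def gene_pattern_summary(calls: pd.DataFrame, panel: SitePanel) -> pd.DataFrame:
    """Per-gene proportions of up/down/unchanged genotype-site combinations.

    Proportions are over non-undefined combinations and sum to 1 per gene;
    genes with no defined combinations get NA rows.
    """
    if calls.empty:
        raise ValueError("no pattern calls supplied")
    gene_of = panel.sites.set_index("site_id")["gene_id"]
    df = calls.assign(gene_id=calls["site_id"].map(gene_of))
    df = df[df["category"] != "undefined"]
    counts = (
        df.groupby(["gene_id", "category"]).size().unstack(fill_value=0)
        .reindex(columns=["upregulated", "downregulated", "unchanged"], fill_value=0)
    )
    counts = counts.reindex(panel.genes, fill_value=0)
    total = counts.sum(axis=1)
    props = counts.div(total.replace(0, np.nan), axis=0)
    empty = total == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} gene(s) have no defined genotype-site combinations",
            stacklevel=2,
        )
    props["n_combinations"] = total
    props.index.name = "gene_id"
    return props.reset_index()


def ecotype_differentiation(
    matrix: EditingMatrix,
    ecotypes: pd.Series,
    alpha: float = 0.05,
    min_group: int = DEFAULT_MIN_GROUP,
    groups: tuple[str, str] = ("upland", "lowland"),
) -> pd.DataFrame:
    """Welch t-test per site between two ecotypes within one condition.

    ``ecotypes`` maps genotype → ecotype label.  Sites with fewer than
    ``min_group`` non-missing values in either group get p = NA; if a group
    has no genotypes at all the call is an error.
    """
    eco = ecotypes.reindex(matrix.genotypes)
    mask_a = (eco == groups[0]).to_numpy()
    mask_b = (eco == groups[1]).to_numpy()
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise InsufficientDataError(f"both ecotype groups {groups} must be present")
    vals = matrix.efficiencies.to_numpy(dtype=float)
    rows = []
    for j, site in enumerate(matrix.site_ids):
        a = vals[mask_a, j]
        b = vals[mask_b, j]
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if len(a) < min_group or len(b) < min_group or (a.std() == 0 and b.std() == 0):
            p, flag = np.nan, False
        else:
            _, p = stats.ttest_ind(a, b, equal_var=False)
            flag = bool(p < alpha)
        rows.append(
            {
                "site_id": site,
                "condition": matrix.condition,
                "n_" + groups[0]: len(a),
                "n_" + groups[1]: len(b),
                "mean_" + groups[0]: a.mean() if len(a) else np.nan,
                "mean_" + groups[1]: b.mean() if len(b) else np.nan,
                "ecotype_p": p,
                "ecotype_differentiated": flag,
            }
        )
    return pd.DataFrame(rows)


def annotate_consequence(panel: SitePanel, table: int = 1) -> pd.DataFrame:
    """Codon-consequence annotation for every panel site.

    Builds the codon containing each site from the gene reference, applies
    the canonical substitution in place (C→T, or G→A for antisense-
    represented amplicons), translates both codons with the selected NCBI
    translation table (1 = standard, which plant mitochondria use) and
    compares amino acids.  Sites without codon coordinates are "noncoding".
    """
    if panel.sequences is None:
        raise ValueError("consequence annotation needs gene reference sequences on the panel")
    rows = []
    for _, site in panel.sites.iterrows():
        if pd.isna(site["codon_index"]):
            rows.append({"site_id": site["site_id"], "consequence": "noncoding", "aa_change": None})
            continue
        gene_seq = panel.sequences[site["gene_id"]]
        pos = int(site["gene_position"])
        ci = int(site["codon_index"])
        cp = int(site["codon_position"])
        if (pos + 2) // 3 != ci or (pos - 1) % 3 + 1 != cp:
            raise ValueError(f"codon frame inconsistent with position at {site['site_id']}")
        codon = gene_seq[(ci - 1) * 3 : ci * 3]
        if len(codon) < 3:
            raise ValueError(f"codon truncated at {site['site_id']}")
        ref = site["ref_base"]
        if codon[cp - 1] != ref:
            raise ValueError(
                f"panel ref_base {ref!r} does not match reference at {site['site_id']}"
            )
        edited = codon[: cp - 1] + CANONICAL_EDITS[ref] + codon[cp:]
        aa_ref = str(Seq(codon).translate(table=table))
        aa_alt = str(Seq(edited).translate(table=table))
        consequence = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
        rows.append(
            {
                "site_id": site["site_id"],
                "consequence": consequence,
                "aa_change": f"{aa_ref}{ci}{aa_alt}" if aa_ref != aa_alt else None,
            }
        )
    return pd.DataFrame(rows)
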