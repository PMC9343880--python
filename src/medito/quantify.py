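"""Per-site base counting and editing-efficiency estimation.

Input is either aligned amplicon reads (SAM/BAM, one file per sample) or a
pre-tabulated pileup TSV (columns ``sample_id, site_id, ref_count,
alt_count``).  At a C-site only C/T bases are counted (ref/edited); at a
G-site only G/A — everything else, and deletions, are excluded from both
numerator and denominator, matching the alt/(ref+alt) efficiency formula.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .core import CANONICAL_EDITS, EditingMatrix, InsufficientDataError, PanelError, SitePanel

__all__ = [
    "count_conversions",
    "count_conversions_sam",
    "read_pileup_tsv",
    "write_pileup_tsv",
    "editing_efficiency",
    "validate_against_clones",
]

PILEUP_COLUMNS = ["sample_id", "site_id", "ref_count", "alt_count"]

DEFAULT_MIN_BASEQ = 20
DEFAULT_MIN_MAPQ = 20
#: depth below which a genotype-site cell is reported missing.
DEFAULT_MIN_CALL_DEPTH = 50


def read_pileup_tsv(path) -> pd.DataFrame:
    """Read the pileup dialect; validates columns and non-negative counts."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pileup TSV is missing columns: {missing}")
    if (df[["ref_count", "alt_count"]] < 0).any().any():
        raise ValueError("pileup counts must be non-negative")
    return df[PILEUP_COLUMNS].copy()


def write_pileup_tsv(counts: pd.DataFrame, path) -> None:
    counts[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


def count_conversions_sam(
    path,
    panel: SitePanel,
    sample_id: str | None = None,
    min_baseq: int = DEFAULT_MIN_BASEQ,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> pd.DataFrame:
    """Count ref/edited bases at every panel site from one sample's alignments.

    Works on unindexed SAM as well as indexed BAM: reads are streamed and
    matched to panel sites on their reference via aligned pairs.  Reads below
    ``min_mapq`` and bases below ``min_baseq`` are excluded; bases other than
    the site's ref/edited pair are ignored.
    """
    sites = panel.sites
    by_ref: dict[str, pd.DataFrame] = {g: grp for g, grp in sites.groupby("gene_id", sort=False)}
    ref_n = {s: 0 for s in sites["site_id"]}
    alt_n = {s: 0 for s in sites["site_id"]}

    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(path), require_index=False) as af:
            references = set(af.references or ())
            unknown = set(by_ref) - references
            if references and unknown == set(by_ref):
                raise PanelError(
                    f"no panel gene matches the alignment references (e.g. {sorted(unknown)[:3]})"
                )
            for gene, grp in by_ref.items():
                if gene in references:
                    ref_len = af.get_reference_length(gene)
                    if int(grp["gene_position"].max()) > ref_len:
                        raise PanelError(f"site position beyond reference length for {gene!r}")
            for read in af:
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if read.mapping_quality < min_mapq:
                    continue
                grp = by_ref.get(read.reference_name)
                if grp is None:
                    continue
                lo, hi = read.reference_start, read.reference_end  # 0-based half-open
                span = grp[(grp["gene_position"] > lo) & (grp["gene_position"] <= hi)]
                if span.empty:
                    continue
                pairs = {
                    rpos: qpos
                    for qpos, rpos in read.get_aligned_pairs(matches_only=True)
                }
                seq = read.query_sequence
                quals = read.query_qualities
                for _, site in span.iterrows():
                    qpos = pairs.get(site["gene_position"] - 1)
                    if qpos is None:
                        continue  # deletion at the site
                    if quals is not None and quals[qpos] < min_baseq:
                        continue
                    base = seq[qpos].upper()
                    ref = site["ref_base"]
                    if base == ref:
                        ref_n[site["site_id"]] += 1
                    elif base == CANONICAL_EDITS.get(ref):
                        alt_n[site["site_id"]] += 1
    finally:
        pysam.set_verbosity(save)

    if sample_id is None:
        sample_id = str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "site_id": sites["site_id"],
            "ref_count": [ref_n[s] for s in sites["site_id"]],
            "alt_count": [alt_n[s] for s in sites["site_id"]],
        }
    )


def count_conversions(source, panel: SitePanel, **kwargs) -> pd.DataFrame:
    """Dispatch on input type: pileup TSV path/DataFrame or SAM/BAM path."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        if not set(PILEUP_COLUMNS) <= set(df.columns):
            raise ValueError("pileup DataFrame lacks the dialect columns")
        unknown = set(df["site_id"]) - set(panel.site_ids)
        if unknown:
            raise PanelError(f"pileup refers to sites absent from the panel: {sorted(unknown)[:3]}")
        return df[PILEUP_COLUMNS]
    s = str(source)
    if s.endswith((".sam", ".bam", ".cram")):
        return count_conversions_sam(source, panel, **kwargs)
    return count_conversions(read_pileup_tsv(source), panel)


def editing_efficiency(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    min_call_depth: int = DEFAULT_MIN_CALL_DEPTH,
) -> dict[str, EditingMatrix]:
    """Turn a count table into per-condition genotype × site editing matrices.

    efficiency = alt / (ref + alt); cells with depth < ``min_call_depth``
    (including zero coverage) become missing.  Exact 0 and exact 1 are
    preserved — the informative filter depends on them.
    """
    required = {"sample_id", "genotype", "condition"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata must carry columns {sorted(required)}")
    merged = counts.merge(meta[["sample_id", "genotype", "condition"]], on="sample_id", how="left")
    if merged["genotype"].isna().any():
        bad = merged.loc[merged["genotype"].isna(), "sample_id"].unique()[:3]
        raise ValueError(f"samples missing from metadata: {list(bad)}")
    merged["depth"] = merged["ref_count"] + merged["alt_count"]
    out: dict[str, EditingMatrix] = {}
    for cond, grp in merged.groupby("condition", sort=True):
        depth = grp.pivot_table(index="genotype", columns="site_id", values="depth", aggfunc="sum")
        alt = grp.pivot_table(index="genotype", columns="site_id", values="alt_count", aggfunc="sum")
        with np.errstate(invalid="ignore", divide="ignore"):
            eff = alt / depth
        eff = eff.where(depth >= min_call_depth)
        depth = depth.fillna(0).astype(int)
        # keep panel/sample order stable and deterministic
        site_order = counts["site_id"].drop_duplicates().tolist()
        geno_order = meta.loc[meta["condition"] == cond, "genotype"].drop_duplicates().tolist()
        eff = eff.reindex(index=geno_order, columns=site_order)
        depth = depth.reindex(index=geno_order, columns=site_order).fillna(0).astype(int)
        out[cond] = EditingMatrix(eff, depth, condition=str(cond))
    return out


def validate_against_clones(
    high_throughput: Mapping[str, float] | pd.Series,
    clones: pd.DataFrame,
) -> dict:
    """Pearson correlation between amplicon-seq and Sanger-clone estimates.

    ``clones`` needs columns ``site_id, edited_clones, total_clones``; the
    clone estimate is edited/total.  Requires at least 3 shared sites; a
    zero-variance vector yields PCC = NA with a warning.
    """
    ht = pd.Series(dict(high_throughput), dtype=float)
    cl = clones.set_index("site_id")
    shared = [s for s in cl.index if s in ht.index and np.isfinite(ht[s])]
    if len(shared) < 3:
        raise InsufficientDataError(
            f"clone validation needs >= 3 shared sites, got {len(shared)}"
        )
    clone_eff = (cl.loc[shared, "edited_clones"] / cl.loc[shared, "total_clones"]).astype(float)
    x = ht[shared].to_numpy()
    y = clone_eff.to_numpy()
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        warnings.warn("constant efficiency vector: clone-validation PCC undefined", stacklevel=2)
        return {"pcc": float("nan"), "p": float("nan"), "n": len(shared)}
    r, p = stats.pearsonr(x, y)
    return {"pcc": float(r), "p": float(p), "n": len(shared)}
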