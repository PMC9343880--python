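"""Differential-expression threshold rule and core-DEG classification.

These are pure rules applied to a supplied DE table (the model fitting that
produces log2FC and p is out of scope here): a gene is a DEG when
|log2FC| > 1 and p < 0.05 (strict inequalities); across the four mutant
lines of the two PPR knockouts, a core DEG is Type I when it is a DEG in
both mutant genes, else Type II when it is a DEG in at least one line and
|log2FC| > 2 in all four lines.  Type I takes precedence.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["flag_deg", "classify_core_degs"]

DEFAULT_FC_THRESHOLD = 1.0
DEFAULT_ALPHA = 0.05
CORE_FC_THRESHOLD = 2.0


def flag_deg(log2fc, p, fc_threshold: float = DEFAULT_FC_THRESHOLD, alpha: float = DEFAULT_ALPHA):
    """DEG flag: (|log2FC| > fc_threshold) AND (p < alpha), both strict.

    Vectorized; NA inputs propagate to NA flags (pandas nullable boolean
    for arrays, ``None`` for scalars).
    """
    lfc = np.asarray(log2fc, dtype=float)
    pv = np.asarray(p, dtype=float)
    scalar = lfc.ndim == 0
    lfc = np.atleast_1d(lfc)
    pv = np.atleast_1d(pv)
    na = ~np.isfinite(lfc) | ~np.isfinite(pv)
    with np.errstate(invalid="ignore"):
        flag = (np.abs(lfc) > fc_threshold) & (pv < alpha)
    out = pd.array(flag, dtype="boolean")
    out[na] = pd.NA
    if scalar:
        v = out[0]
        return None if v is pd.NA else bool(v)
    return out


def classify_core_degs(
    table: pd.DataFrame,
    line_to_gene: dict[str, str],
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    core_fc: float = CORE_FC_THRESHOLD,
    p_column: str = "p",
) -> pd.DataFrame:
    """Classify every gene as Type I / Type II / none across four mutant lines.

    ``table`` is long (gene, line, log2fc, p-ish column); ``line_to_gene``
    maps the four line names onto the two mutant genes.  Genes missing any
    line contrast are skipped with a warning.  ``p_column`` selects the
    p-value column ("p" raw by default; point it at an adjusted column for
    the FDR mode).
    """
    lines = sorted(line_to_gene)
    mutant_genes = sorted(set(line_to_gene.values()))
    if len(lines) != 4 or len(mutant_genes) != 2:
        raise ValueError("core-DEG classification expects 4 lines mapped to 2 mutant genes")

    lfc = table.pivot_table(index="gene", columns="line", values="log2fc", aggfunc="first")
    pv = table.pivot_table(index="gene", columns="line", values=p_column, aggfunc="first")
    incomplete = lfc[lines].isna().any(axis=1) | pv[lines].isna().any(axis=1) if set(
        lines
    ) <= set(lfc.columns) else pd.Series(True, index=lfc.index)
    missing_cols = [ln for ln in lines if ln not in lfc.columns]
    if missing_cols:
        raise ValueError(f"DE table lacks contrasts for lines: {missing_cols}")
    if incomplete.any():
        warnings.warn(
            f"skipping {int(incomplete.sum())} gene(s) missing a line contrast", stacklevel=2
        )
    genes = lfc.index[~incomplete]

    rows = []
    for g in genes:
        deg_by_line = {
            ln: bool(flag_deg(lfc.at[g, ln], pv.at[g, ln], fc_threshold, alpha)) for ln in lines
        }
        deg_by_mutant = {
            mg: any(deg_by_line[ln] for ln in lines if line_to_gene[ln] == mg)
            for mg in mutant_genes
        }
        if all(deg_by_mutant.values()):
            call = "TypeI"
        elif any(deg_by_line.values()) and all(abs(lfc.at[g, ln]) > core_fc for ln in lines):
            call = "TypeII"
        else:
            call = "none"
        rec = {
            "gene": g,
            "call": call,
            "deg_lines": ";".join(ln for ln in lines if deg_by_line[ln]),
        }
        for ln in lines:
            rec[f"log2fc_{ln}"] = float(lfc.at[g, ln])
        rows.append(rec)
    return pd.DataFrame(rows)
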