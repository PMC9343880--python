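"""Shared data containers for the mitochondrial RNA-editing pipeline.

Two objects travel through every stage:

* :class:`SitePanel` — the catalogue of candidate C-to-U editing sites on a
  set of mitochondrial gene references (1-based, gene-sense coordinates).
* :class:`EditingMatrix` — genotype × site editing efficiencies in [0, 1]
  for one field condition (CK = well-watered, DT = drought), with per-cell
  sequencing depth attached.  Missing cells are NaN.

Both round-trip through plain TSV ("NA" encodes missing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical reference → edited base pairs for C-to-U editing as observed in
#: cDNA: C→T on the sense strand, G→A when the amplicon reference is the
#: antisense representation.
CANONICAL_EDITS = {"C": "T", "G": "A"}

CONDITIONS = ("CK", "DT")

PANEL_COLUMNS = [
    "site_id",
    "gene_id",
    "gene_position",
    "ref_base",
    "codon_index",
    "codon_position",
    "display_name",
]


class PanelError(ValueError):
    """Raised when a site panel is internally inconsistent with its references."""


class InsufficientDataError(ValueError):
    """Raised when an operation has too few observations to be meaningful."""


@dataclass
class SitePanel:
    """Catalogue of candidate editing sites.

    Parameters
    ----------
    sites
        One row per site with columns ``site_id, gene_id, gene_position,
        ref_base, codon_index, codon_position, display_name``.  Codon fields
        are nullable (jointly absent for non-coding sites).
    sequences
        Optional gene-sense reference sequence per ``gene_id`` (plain str).
    """

    sites: pd.DataFrame
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.sites.columns]
        if missing:
            raise PanelError(f"panel is missing columns: {missing}")
        df = self.sites.reset_index(drop=True).copy()
        if df["site_id"].duplicated().any():
            raise PanelError("duplicate site_id in panel")
        if (df["gene_position"] < 1).any():
            raise PanelError("gene_position must be 1-based (>= 1)")
        bad = ~df["ref_base"].isin(CANONICAL_EDITS)
        if bad.any():
            # Non-canonical sites are representable (the informative filter
            # must be able to reject them) but worth flagging early.
            warnings.warn(
                f"{int(bad.sum())} panel site(s) have a non-canonical ref_base; "
                "they will fail the informative filter",
                stacklevel=2,
            )
        has_idx = df["codon_index"].notna()
        has_pos = df["codon_position"].notna()
        if (has_idx != has_pos).any():
            raise PanelError("codon_index and codon_position must be jointly present or absent")
        if self.sequences is not None:
            for gene, grp in df.groupby("gene_id", sort=False):
                if gene not in self.sequences:
                    raise PanelError(f"no reference sequence for gene {gene!r}")
                if int(grp["gene_position"].max()) > len(self.sequences[gene]):
                    raise PanelError(f"site position beyond reference length for gene {gene!r}")
        self.sites = df

    # -- convenience -------------------------------------------------------
    @property
    def site_ids(self) -> list[str]:
        return self.sites["site_id"].tolist()

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def genes(self) -> list[str]:
        return self.sites["gene_id"].drop_duplicates().tolist()

    def edited_base(self, site_id: str) -> str:
        ref = self.sites.set_index("site_id").at[site_id, "ref_base"]
        return CANONICAL_EDITS[ref]

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.sites.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path, sequences: dict[str, str] | None = None) -> "SitePanel":
        df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"ref_base": str})
        return cls(df, sequences=sequences)


def make_display_name(gene_id: str, gene_position: int) -> str:
    """The field-standard site label, e.g. ``rps4-926``."""
    return f"{gene_id}-{int(gene_position)}"


@dataclass
class EditingMatrix:
    """Genotype × site editing efficiencies for one condition.

    ``efficiencies`` and ``depth`` share index (genotypes) and columns
    (site ids).  A cell is missing (NaN) exactly when its depth fell below
    the caller's calling threshold (including depth 0).
    """

    efficiencies: pd.DataFrame
    depth: pd.DataFrame
    condition: str = "CK"

    def __post_init__(self) -> None:
        if not self.efficiencies.index.equals(self.depth.index) or not (
            self.efficiencies.columns.equals(self.depth.columns)
        ):
            raise ValueError("efficiency and depth frames must be aligned")
        vals = self.efficiencies.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0))
        if not ok.all():
            raise ValueError("editing efficiencies must lie in [0, 1] or be NaN")

    @property
    def genotypes(self) -> list[str]:
        return self.efficiencies.index.tolist()

    @property
    def site_ids(self) -> list[str]:
        return self.efficiencies.columns.tolist()

    def to_tsv(self, path, depth_path=None) -> None:
        self.efficiencies.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g", index_label="genotype")
        if depth_path is not None:
            self.depth.to_csv(depth_path, sep="\t", na_rep="NA", float_format="%.10g", index_label="genotype")

    @classmethod
    def from_tsv(cls, path, depth_path=None, condition: str = "CK") -> "EditingMatrix":
        eff = pd.read_csv(path, sep="\t", index_col="genotype", na_values=["NA"])
        if depth_path is not None:
            depth = pd.read_csv(depth_path, sep="\t", index_col="genotype", na_values=["NA"])
        else:
            depth = pd.DataFrame(np.nan, index=eff.index, columns=eff.columns)
        return cls(eff, depth, condition=condition)
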