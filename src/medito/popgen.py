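"""Per-gene nucleotide diversity, F_ST, outlier scanning and haplotype
grouping for inbred (haploid-coded) rice resequencing panels.

π is Nei's average pairwise difference per site, with the window length in
the denominator so values are comparable across genes; missing genotypes are
handled per-SNP by pairwise-complete allele counting.  F_ST defaults to the
Hudson estimator combined over the window as a ratio of averages; a
Weir–Cockerham variant (haploid analogue) is available behind a flag.
Outliers are genes above an empirical background quantile (the 95th
percentile by default), with a two-sample Kolmogorov–Smirnov comparison of
the focal gene set against the genomic background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import InsufficientDataError

__all__ = [
    "GenotypePanel",
    "HaplotypeReport",
    "nucleotide_diversity",
    "fst",
    "popgen_scan",
    "outlier_scan",
    "haplotype_grouping",
    "read_vcf",
    "write_vcf",
    "read_windows_bed",
    "write_windows_bed",
]


@dataclass
class GenotypePanel:
    """Haploid biallelic genotypes with population labels and gene windows.

    ``genotypes`` is accession × SNP, values 0/1/NaN (missing).  Windows are
    1-based closed intervals (BED input is converted on read).
    """

    genotypes: np.ndarray
    chrom: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    accessions: pd.DataFrame  # columns: accession, population
    windows: pd.DataFrame  # columns: gene_id, chrom, start, end

    def __post_init__(self) -> None:
        n_acc, n_snp = self.genotypes.shape
        if len(self.accessions) != n_acc:
            raise ValueError("accession table does not match genotype rows")
        for arr in (self.chrom, self.positions, self.ref, self.alt):
            if len(arr) != n_snp:
                raise ValueError("SNP annotation length does not match genotype columns")
        for c, grp in pd.DataFrame({"chrom": self.chrom, "pos": self.positions}).groupby("chrom"):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"SNP positions must be sorted within chromosome {c!r}")
        empty = [
            w.gene_id
            for w in self.windows.itertuples()
            if self._window_cols(w.gene_id).size == 0
        ]
        if empty:
            warnings.warn(f"empty gene windows: {empty[:5]}", stacklevel=2)

    def _window(self, gene_id: str):
        w = self.windows[self.windows["gene_id"] == gene_id]
        if w.empty:
            raise KeyError(f"unknown gene window {gene_id!r}")
        return w.iloc[0]

    def _window_cols(self, gene_id: str) -> np.ndarray:
        w = self._window(gene_id)
        return np.flatnonzero(
            (self.chrom == w["chrom"])
            & (self.positions >= int(w["start"]))
            & (self.positions <= int(w["end"]))
        )

    def window_length(self, gene_id: str) -> int:
        w = self._window(gene_id)
        return int(w["end"]) - int(w["start"]) + 1

    def population_rows(self, population: str | list[str]) -> np.ndarray:
        pops = [population] if isinstance(population, str) else list(population)
        return np.flatnonzero(self.accessions["population"].isin(pops).to_numpy())


@dataclass
class HaplotypeReport:
    gene_id: str
    table: pd.DataFrame  # haplotype, label, per-population counts, total
    dominant: dict[str, str]  # population -> label of most frequent haplotype
    n_complete: int
    n_dropped: int


# ---------------------------------------------------------------------------
# diversity and differentiation
# ---------------------------------------------------------------------------

def _pair_diff_per_snp(sub: np.ndarray) -> np.ndarray:
    """Expected pairwise difference per SNP, pairwise-complete, unbiased n/(n-1)."""
    obs = np.isfinite(sub)
    n = obs.sum(axis=0).astype(float)
    n1 = np.nansum(sub, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = 2.0 * n1 * (n - n1) / (n * (n - 1.0))
    contrib[n < 2] = 0.0
    return contrib


def nucleotide_diversity(panel: GenotypePanel, gene_id: str, population: str | list[str]) -> float:
    """Nei's π per site over one gene window for one population.

    Monomorphic (and SNP-free) positions enter through the window length in
    the denominator; SNPs with < 2 non-missing genotypes contribute 0.
    Returns NaN when the window has no SNPs or < 2 accessions with any data.
    """
    cols = panel._window_cols(gene_id)
    rows = panel.population_rows(population)
    if cols.size == 0:
        return float("nan")
    sub = panel.genotypes[np.ix_(rows, cols)]
    if np.isfinite(sub).any(axis=1).sum() < 2:
        return float("nan")
    return float(_pair_diff_per_snp(sub).sum() / panel.window_length(gene_id))


def _hudson_components(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    na = np.isfinite(a).sum(axis=0).astype(float)
    nb = np.isfinite(b).sum(axis=0).astype(float)
    pa = np.where(na > 0, np.nansum(a, axis=0) / np.maximum(na, 1), np.nan)
    pb = np.where(nb > 0, np.nansum(b, axis=0) / np.maximum(nb, 1), np.nan)
    ok = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
        den = pa * (1 - pb) + pb * (1 - pa)
    num = np.where(ok, num, 0.0)
    den = np.where(ok, den, 0.0)
    return num, den


def _wc_theta(a: np.ndarray, b: np.ndarray) -> float:
    """Weir–Cockerham θ for haploid samples, summed over SNPs."""
    na = np.isfinite(a).sum(axis=0).astype(float)
    nb = np.isfinite(b).sum(axis=0).astype(float)
    ok = (na >= 2) & (nb >= 2)
    pa = np.nansum(a, axis=0) / np.maximum(na, 1)
    pb = np.nansum(b, axis=0) / np.maximum(nb, 1)
    r = 2.0
    n_tot = na + nb
    nc = (n_tot - (na**2 + nb**2) / n_tot) / (r - 1)
    pbar = (na * pa + nb * pb) / n_tot
    msp = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / (r - 1)
    msg = (na * pa * (1 - pa) + nb * pb * (1 - pb)) / (n_tot - r)
    num = msp - msg
    den = msp + (nc - 1) * msg
    num = np.where(ok, num, 0.0)
    den = np.where(ok, den, 0.0)
    if den.sum() == 0.0:
        return float("nan")
    return float(num.sum() / den.sum())


def fst(
    panel: GenotypePanel,
    gene_id: str,
    pop_a: str | list[str],
    pop_b: str | list[str],
    estimator: str = "hudson",
) -> float:
    """Window F_ST between two populations (ratio of per-SNP averages).

    Unclamped: small negative values are legitimate sampling noise.  NaN for
    windows monomorphic across both populations or with < 2 accessions with
    data in either population.
    """
    cols = panel._window_cols(gene_id)
    rows_a = panel.population_rows(pop_a)
    rows_b = panel.population_rows(pop_b)
    if cols.size == 0:
        return float("nan")
    a = panel.genotypes[np.ix_(rows_a, cols)]
    b = panel.genotypes[np.ix_(rows_b, cols)]
    if np.isfinite(a).any(axis=1).sum() < 2 or np.isfinite(b).any(axis=1).sum() < 2:
        raise InsufficientDataError("both populations need >= 2 accessions with data")
    if estimator == "hudson":
        num, den = _hudson_components(a, b)
        if den.sum() == 0.0:
            return float("nan")
        return float(num.sum() / den.sum())
    if estimator == "weir-cockerham":
        return _wc_theta(a, b)
    raise ValueError(f"unknown F_ST estimator {estimator!r}")


def popgen_scan(
    panel: GenotypePanel,
    landrace_pops: tuple[str, str] = ("upland", "lowland"),
    wild_pop: str = "wild",
    estimator: str = "hudson",
) -> pd.DataFrame:
    """Per-gene π by population, π ratios, and the two F_ST contrasts.

    ``fst_UL`` contrasts the two landrace ecotypes; ``fst_CW`` contrasts the
    pooled landraces against wild rice.  Ratios are NA where the denominator
    π is 0.  The clamped-to-[0, 1] convenience columns sit next to the raw
    estimates.
    """
    up, low = landrace_pops
    has_wild = wild_pop in set(panel.accessions["population"])
    rows = []
    for gene in panel.windows["gene_id"]:
        pi_u = nucleotide_diversity(panel, gene, up)
        pi_l = nucleotide_diversity(panel, gene, low)
        pi_land = nucleotide_diversity(panel, gene, list(landrace_pops))
        rec = {
            "gene_id": gene,
            "pi_upland": pi_u,
            "pi_lowland": pi_l,
            "pi_landrace": pi_land,
            "pi_ratio_UL": pi_u / pi_l if pi_l and np.isfinite(pi_l) and pi_l > 0 else np.nan,
            "fst_UL": fst(panel, gene, up, low, estimator=estimator),
        }
        if has_wild:
            pi_w = nucleotide_diversity(panel, gene, wild_pop)
            rec["pi_wild"] = pi_w
            rec["pi_ratio_CW"] = (
                pi_land / pi_w if pi_w and np.isfinite(pi_w) and pi_w > 0 else np.nan
            )
            rec["fst_CW"] = fst(panel, gene, list(landrace_pops), wild_pop, estimator=estimator)
        rows.append(rec)
    df = pd.DataFrame(rows)
    for col in [c for c in ("fst_UL", "fst_CW") if c in df.columns]:
        df[col + "_clamped"] = df[col].clip(0.0, 1.0)
    return df


def outlier_scan(
    values: pd.Series,
    background: pd.Series,
    quantile: float = 0.95,
    min_background: int = 100,
) -> dict:
    """Flag genes whose statistic exceeds an empirical background quantile.

    ``threshold`` is the linear-interpolation quantile of the background;
    also reports a two-sample KS comparison of the focal values against the
    background distribution (the focal set is typically much smaller).
    """
    bg = background.dropna()
    if len(bg) < min_background:
        raise InsufficientDataError(
            f"background needs >= {min_background} genes, got {len(bg)}"
        )
    threshold = float(np.quantile(bg.to_numpy(), quantile))
    vals = values.dropna()
    flags = values > threshold
    flags[values.isna()] = False
    if len(vals):
        ks = stats.ks_2samp(vals.to_numpy(), bg.to_numpy())
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:
        ks_stat, ks_p = float("nan"), float("nan")
    return {
        "threshold": threshold,
        "quantile": quantile,
        "flags": flags,
        "n_outliers": int(flags.sum()),
        "ks_stat": ks_stat,
        "ks_p": ks_p,
    }


def haplotype_grouping(panel: GenotypePanel, gene_id: str, min_count: int = 2) -> HaplotypeReport:
    """Group accessions by exact SNP-string identity over one gene window.

    Accessions with any missing genotype in the window are dropped (exact
    grouping must not be contaminated by imputation).  Haplotypes with total
    count ≥ ``min_count`` are labeled Hap-1, Hap-2, … in descending total
    frequency (ties broken lexicographically for determinism); rarer ones
    are labeled "minor".
    """
    cols = panel._window_cols(gene_id)
    if cols.size == 0:
        raise InsufficientDataError(f"gene window {gene_id!r} holds no SNPs")
    sub = panel.genotypes[:, cols]
    complete = np.isfinite(sub).all(axis=1)
    if not complete.any():
        raise InsufficientDataError("no accession has complete data in the window")
    strings = ["".join(str(int(v)) for v in row) for row in sub[complete]]
    pops = panel.accessions.loc[complete, "population"].to_numpy()
    df = pd.DataFrame({"haplotype": strings, "population": pops})
    counts = df.groupby(["haplotype", "population"]).size().unstack(fill_value=0)
    counts["total"] = counts.sum(axis=1)
    counts = counts.sort_values(by=["total", "haplotype"], ascending=[False, True])
    labels = []
    k = 0
    for _, row in counts.iterrows():
        if row["total"] >= min_count:
            k += 1
            labels.append(f"Hap-{k}")
        else:
            labels.append("minor")
    counts.insert(0, "label", labels)
    dominant = {}
    for pop in panel.accessions["population"].unique():
        if pop in counts.columns and counts[pop].sum() > 0:
            dominant[pop] = counts.loc[counts[pop].idxmax(), "label"]
    table = counts.reset_index()
    return HaplotypeReport(
        gene_id=gene_id,
        table=table,
        dominant=dominant,
        n_complete=int(complete.sum()),
        n_dropped=int((~complete).sum()),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_vcf(panel: GenotypePanel, path) -> None:
    """Emit a minimal VCF v4.2 with homozygous diploid-coded haploid calls."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(panel.chrom):
            last = panel.positions[panel.chrom == c].max()
            fh.write(f"##contig=<ID={c},length={int(last) + 10000}>\n")
        samples = "\t".join(panel.accessions["accession"])
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        code = {0.0: "0/0", 1.0: "1/1"}
        for j in range(panel.genotypes.shape[1]):
            gts = "\t".join(
                code.get(panel.genotypes[i, j], "./.") for i in range(panel.genotypes.shape[0])
            )
            fh.write(
                f"{panel.chrom[j]}\t{int(panel.positions[j])}\tsnp{j + 1}\t"
                f"{panel.ref[j]}\t{panel.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path, populations: pd.DataFrame, windows: pd.DataFrame) -> GenotypePanel:
    """Load biallelic SNPs from a VCF into the haploid inbred-line convention.

    Homozygous ref/alt map to 0/1; heterozygous calls collapse to missing
    with a warning; multiallelic records are skipped with a log line.
    ``populations`` must carry columns ``accession, population`` covering the
    VCF samples.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_multi = n_het = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_multi += 1
            continue
        gt = var.gt_types.astype(float)  # 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        n_het += int((gt == 1).sum())
        g = np.where(gt == 0, 0.0, np.where(gt == 2, 1.0, np.nan))
        rows.append(g)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    vcf.close()
    if n_multi:
        warnings.warn(f"skipped {n_multi} non-biallelic-SNP record(s)", stacklevel=2)
    if n_het:
        warnings.warn(
            f"collapsed {n_het} heterozygous call(s) to missing (inbred-line convention)",
            stacklevel=2,
        )
    genotypes = np.vstack(rows).T if rows else np.empty((len(samples), 0))
    pop = populations.set_index("accession")["population"]
    missing = [s for s in samples if s not in pop.index]
    if missing:
        raise ValueError(f"samples without population labels: {missing[:5]}")
    accessions = pd.DataFrame({"accession": samples, "population": pop.reindex(samples).to_numpy()})
    return GenotypePanel(
        genotypes=genotypes,
        chrom=np.array(chroms, dtype=object),
        positions=np.array(poss, dtype=int),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        accessions=accessions,
        windows=windows.reset_index(drop=True),
    )


def write_windows_bed(windows: pd.DataFrame, path) -> None:
    """Write gene windows as BED (0-based half-open; internal is 1-based closed)."""
    out = windows.copy()
    out["bed_start"] = out["start"].astype(int) - 1
    out[["chrom", "bed_start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_windows_bed(path) -> pd.DataFrame:
    """Read gene windows from BED, converting to the 1-based closed convention."""
    bed = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "gene_id"])
    bed["chrom"] = bed["chrom"].astype(str)
    bed["start"] = bed["start"].astype(int) + 1
    return bed[["gene_id", "chrom", "start", "end"]]
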