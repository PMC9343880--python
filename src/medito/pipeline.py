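"""Pipeline orchestration: simulate → quantify → filter → classify →
correlate → popgen → deg-rules → report, under one flat typed config.

Every stage reads/writes plain TSV/FASTA/VCF/JSON under one output
directory and records itself in a run manifest with output checksums, so a
rerun with the same config and seed is byte-identical and partial runs can
resume from completed stages.  All randomness flows from the single seed.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats as _stats

from . import __version__
from .classify import (
    annotate_consequence,
    classify_drought_response,
    classify_pattern,
    ecotype_differentiation,
    gene_pattern_summary,
    informative_filter,
)
from .core import EditingMatrix, SitePanel
from .correlate import correlation_structure, gene_trait_correlation, site_trait_correlation
from .degrules import classify_core_degs
from .popgen import (
    haplotype_grouping,
    outlier_scan,
    popgen_scan,
    read_vcf,
    read_windows_bed,
    write_vcf,
    write_windows_bed,
)
from .quantify import editing_efficiency
from .simulate import (
    PopGenSimConfig,
    ShiftSpec,
    SimulationConfig,
    TraitEffect,
    simulate_counts,
    simulate_de_table,
    simulate_editing_truth,
    simulate_popgen_dataset,
    simulate_site_panel,
    simulate_traits,
)

STAGES = ["simulate", "quantify", "filter", "classify", "correlate", "popgen", "deg-rules", "report"]

_FLOAT_FMT = "%.10g"


class ConfigError(ValueError):
    """Raised before any stage runs when the config violates the schema."""


# (type, min, max) per dotted field; None bound = unconstrained.
_SCHEMA = {
    "simulate.n_upland": (int, 1, None),
    "simulate.n_lowland": (int, 1, None),
    "simulate.n_genes": (int, 1, None),
    "simulate.total_sites": (int, 1, None),
    "simulate.mean_depth": ((int, float), 1, None),
    "simulate.depth_dispersion": ((int, float), 1e-9, None),
    "simulate.missing_rate": ((int, float), 0.0, 1.0),
    "simulate.sequencing_error_rate": ((int, float), 0.0, 1.0),
    "simulate.genotype_sd": ((int, float), 0.0, None),
    "simulate.gene_factor_sd": ((int, float), 0.0, None),
    "simulate.global_factor_sd": ((int, float), 0.0, None),
    "quantify.min_call_depth": (int, 0, None),
    "filter.invariant_fraction_max": ((int, float), 0.0, 1.0),
    "filter.missing_fraction_max": ((int, float), 0.0, 1.0),
    "classify.alpha": ((int, float), 0.0, 1.0),
    "correlate.alpha": ((int, float), 0.0, 1.0),
    "correlate.pcc_threshold": ((int, float), 0.0, 1.0),
    "popgen.quantile": ((int, float), 0.0, 1.0),
    "popgen.n_background_genes": (int, 1, None),
    "deg.fc_threshold": ((int, float), 0.0, None),
    "deg.alpha": ((int, float), 0.0, 1.0),
}


def default_config() -> dict:
    """Study-scale default configuration (the synthetic cohort's conditions)."""
    return {
        "seed": 0,
        "simulate": {
            "n_upland": 64,
            "n_lowland": 60,
            "n_genes": 31,
            "total_sites": 426,
            "mean_depth": 550.0,
            "depth_dispersion": 8.0,
            "missing_rate": 0.02,
            "sequencing_error_rate": 0.001,
            "genotype_sd": 0.4,
            "gene_factor_sd": 0.3,
            "global_factor_sd": 0.25,
            "drought_shift": {"n_positive": 240, "positive": 0.4, "n_negative": 2, "negative": -0.4},
            "ecotype_shift": {"n_positive": 40, "positive": 0.35, "n_negative": 17, "negative": -0.35},
            "trait_effects": [
                {"trait": "RWC", "target_pcc": -0.35, "driver_sites": "global", "condition": "DT"}
            ],
        },
        "quantify": {"min_call_depth": 50},
        "filter": {"invariant_fraction_max": 0.95, "missing_fraction_max": 0.10},
        "classify": {"alpha": 0.05, "bh": False},
        "correlate": {"pcc_threshold": 0.2, "alpha": 0.05},
        "popgen": {
            "quantile": 0.95,
            "n_background_genes": 200,
            "estimator": "hudson",
            "focal_genes": {"PPR035": 0.74, "PPR406": 0.62},
        },
        "deg": {"fc_threshold": 1.0, "alpha": 0.05},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(cfg: dict) -> dict:
    """Merge over defaults and type/range-check; errors name the field."""
    merged = _merge(default_config(), cfg or {})
    for dotted, (types, lo, hi) in _SCHEMA.items():
        section, key = dotted.split(".")
        val = merged.get(section, {}).get(key)
        if val is None or isinstance(val, bool) or not isinstance(val, types):
            raise ConfigError(f"config field {dotted} must be of type {types}")
        if lo is not None and val < lo:
            raise ConfigError(f"config field {dotted} must be >= {lo}, got {val}")
        if hi is not None and val > hi:
            raise ConfigError(f"config field {dotted} must be <= {hi}, got {val}")
    return merged


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def build_sim_config(cfg: dict, seed: int) -> SimulationConfig:
    sim = cfg["simulate"]

    def shift(d):
        if isinstance(d, dict):
            return ShiftSpec(**d)
        return d

    effects = tuple(TraitEffect(**e) for e in sim.get("trait_effects", []))
    return SimulationConfig(
        n_upland=sim["n_upland"],
        n_lowland=sim["n_lowland"],
        n_genes=sim["n_genes"],
        total_sites=sim["total_sites"],
        mean_depth=float(sim["mean_depth"]),
        depth_dispersion=float(sim["depth_dispersion"]),
        missing_rate=float(sim["missing_rate"]),
        sequencing_error_rate=float(sim["sequencing_error_rate"]),
        genotype_sd=float(sim["genotype_sd"]),
        gene_factor_sd=float(sim["gene_factor_sd"]),
        global_factor_sd=float(sim["global_factor_sd"]),
        drought_shift=shift(sim.get("drought_shift", 0.0)),
        ecotype_shift=shift(sim.get("ecotype_shift", 0.0)),
        trait_effects=effects,
        seed=seed,
    )


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT, **kw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log(msg: str) -> None:
    print(f"[medito] {msg}", file=sys.stderr)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    sim_cfg = build_sim_config(cfg, seed)
    panel = simulate_site_panel(sim_cfg)
    truth = simulate_editing_truth(panel, sim_cfg)
    counts, meta = simulate_counts(truth, sim_cfg)
    traits = simulate_traits(truth, sim_cfg)

    panel.to_tsv(outdir / "panel.tsv")
    records = [
        SeqRecord(Seq(seq), id=gene, description="synthetic mitochondrial gene reference")
        for gene, seq in panel.sequences.items()
    ]
    SeqIO.write(records, str(outdir / "reference.fasta"), "fasta")
    _write_tsv(counts, outdir / "counts.tsv")
    _write_tsv(meta, outdir / "samples.tsv")
    _write_tsv(traits, outdir / "traits.tsv")
    for k, cond in enumerate(truth.conditions):
        truth.frame(cond).to_csv(
            outdir / f"truth_{cond}.tsv", sep="\t", float_format=_FLOAT_FMT, index_label="genotype"
        )
    pd.DataFrame(
        {
            "site_id": truth.site_ids,
            "drought_shift": truth.drought_shift,
            "ecotype_shift": truth.ecotype_shift,
        }
    ).pipe(_write_tsv, outdir / "truth_shifts.tsv")

    pg_cfg = PopGenSimConfig(
        n_upland=sim_cfg.n_upland,
        n_lowland=sim_cfg.n_lowland,
        n_background_genes=cfg["popgen"]["n_background_genes"],
        focal_genes=cfg["popgen"].get("focal_genes", {}),
        seed=seed,
    )
    gpanel = simulate_popgen_dataset(pg_cfg)
    write_vcf(gpanel, outdir / "popgen.vcf")
    write_windows_bed(gpanel.windows, outdir / "windows.bed")
    _write_tsv(gpanel.accessions, outdir / "populations.tsv")

    de_table, line_map = simulate_de_table(seed=seed)
    _write_tsv(de_table, outdir / "de_table.tsv")
    _write_tsv(
        pd.DataFrame({"line": list(line_map), "mutant_gene": list(line_map.values())}),
        outdir / "de_line_map.tsv",
    )
    _log(f"simulate: {panel.n_sites} sites / {len(panel.genes)} genes, "
         f"{len(sim_cfg.genotypes)} genotypes x 2 conditions")
    return [outdir / f for f in (
        "panel.tsv", "reference.fasta", "counts.tsv", "samples.tsv", "traits.tsv",
        "truth_CK.tsv", "truth_DT.tsv", "truth_shifts.tsv",
        "popgen.vcf", "windows.bed", "populations.tsv", "de_table.tsv", "de_line_map.tsv",
    )]


def _load_matrices(outdir: Path) -> dict[str, EditingMatrix]:
    return {
        cond: EditingMatrix.from_tsv(
            outdir / f"editing_{cond}.tsv", outdir / f"depth_{cond}.tsv", condition=cond
        )
        for cond in ("CK", "DT")
    }


def stage_quantify(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    counts = pd.read_csv(outdir / "counts.tsv", sep="\t")
    meta = pd.read_csv(outdir / "samples.tsv", sep="\t")
    matrices = editing_efficiency(counts, meta, min_call_depth=cfg["quantify"]["min_call_depth"])
    out = []
    for cond, mat in sorted(matrices.items()):
        mat.to_tsv(outdir / f"editing_{cond}.tsv", outdir / f"depth_{cond}.tsv")
        out += [outdir / f"editing_{cond}.tsv", outdir / f"depth_{cond}.tsv"]
        _log(f"quantify: {cond} matrix {mat.efficiencies.shape}, "
             f"mean depth {np.nanmean(mat.depth.to_numpy(dtype=float)):.0f}")
    return out


def stage_filter(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    panel = SitePanel.from_tsv(outdir / "panel.tsv")
    m = _load_matrices(outdir)
    report = informative_filter(
        m["CK"], m["DT"], panel,
        invariant_fraction_max=cfg["filter"]["invariant_fraction_max"],
        missing_fraction_max=cfg["filter"]["missing_fraction_max"],
    )
    _write_tsv(report, outdir / "informative.tsv")
    _log(f"filter: {int(report['informative'].sum())} / {len(report)} sites informative")
    return [outdir / "informative.tsv"]


def _bh(p: pd.Series) -> pd.Series:
    mask = p.notna()
    adj = p.copy()
    if mask.any():
        adj[mask] = _stats.false_discovery_control(p[mask].to_numpy(), method="bh")
    return adj


def stage_classify(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(outdir / "reference.fasta"), "fasta")}
    panel = SitePanel.from_tsv(outdir / "panel.tsv", sequences=sequences)
    info = pd.read_csv(outdir / "informative.tsv", sep="\t")
    keep = info.loc[info["informative"], "site_id"].tolist()
    m = _load_matrices(outdir)
    meta = pd.read_csv(outdir / "samples.tsv", sep="\t")
    eco = meta.drop_duplicates("genotype").set_index("genotype")["ecotype"]
    alpha = cfg["classify"]["alpha"]

    def restrict(mat: EditingMatrix) -> EditingMatrix:
        return EditingMatrix(mat.efficiencies[keep], mat.depth[keep], condition=mat.condition)

    ck, dt = restrict(m["CK"]), restrict(m["DT"])
    drought = classify_drought_response(ck, dt, alpha=alpha)
    eco_tests = {c: ecotype_differentiation(mat, eco, alpha=alpha) for c, mat in (("CK", ck), ("DT", dt))}
    if cfg["classify"].get("bh"):
        drought["drought_p"] = _bh(drought["drought_p"])
        drought["drought_responsive"] = (drought["drought_p"] < alpha).fillna(False)
        for t in eco_tests.values():
            t["ecotype_p"] = _bh(t["ecotype_p"])
            t["ecotype_differentiated"] = (t["ecotype_p"] < alpha).fillna(False)
    consequence = annotate_consequence(panel)

    cls = info[["site_id", "gene_id", "informative", "reasons"]].merge(
        drought, on="site_id", how="left"
    )
    for cond, t in eco_tests.items():
        cls = cls.merge(
            t[["site_id", "ecotype_p", "ecotype_differentiated"]].rename(
                columns={
                    "ecotype_p": f"ecotype_p_{cond}",
                    "ecotype_differentiated": f"ecotype_differentiated_{cond}",
                }
            ),
            on="site_id",
            how="left",
        )
    for c in [c for c in cls.columns if c.startswith(("drought_responsive", "ecotype_differentiated"))]:
        cls[c] = cls[c].fillna(False).astype(bool)
    cls.loc[~cls["informative"], "drought_direction"] = cls.loc[
        ~cls["informative"], "drought_direction"
    ].fillna("none")
    cls = cls.merge(consequence, on="site_id", how="left")

    patterns = classify_pattern(ck, dt)
    gene_patterns = gene_pattern_summary(patterns, panel)

    _write_tsv(cls, outdir / "classification.tsv")
    _write_tsv(patterns, outdir / "patterns.tsv")
    _write_tsv(gene_patterns, outdir / "gene_patterns.tsv")
    _log(
        "classify: "
        f"{int((cls['drought_responsive'] & (cls['drought_direction'] == 'increase')).sum())} up / "
        f"{int((cls['drought_responsive'] & (cls['drought_direction'] == 'decrease')).sum())} down "
        f"drought-responsive; ecotype CK "
        f"{int(cls['ecotype_differentiated_CK'].sum())}, DT {int(cls['ecotype_differentiated_DT'].sum())}"
    )
    return [outdir / "classification.tsv", outdir / "patterns.tsv", outdir / "gene_patterns.tsv"]


def stage_correlate(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    panel = SitePanel.from_tsv(outdir / "panel.tsv")
    info = pd.read_csv(outdir / "informative.tsv", sep="\t")
    keep = info.loc[info["informative"], "site_id"].tolist()
    m = _load_matrices(outdir)
    traits = pd.read_csv(outdir / "traits.tsv", sep="\t")
    out_paths = []
    structure = {}
    for cond in ("CK", "DT"):
        mat = m[cond]
        mat = EditingMatrix(mat.efficiencies[keep], mat.depth[keep], condition=cond)
        tr = traits[traits["condition"] == cond].set_index("genotype").drop(columns="condition")
        site_rec = site_trait_correlation(
            mat, tr,
            pcc_threshold=cfg["correlate"]["pcc_threshold"],
            alpha=cfg["correlate"]["alpha"],
        )
        gene_rec = gene_trait_correlation(site_rec, panel)
        _write_tsv(site_rec, outdir / f"correlations_{cond}.tsv")
        _write_tsv(gene_rec, outdir / f"gene_correlations_{cond}.tsv")
        out_paths += [outdir / f"correlations_{cond}.tsv", outdir / f"gene_correlations_{cond}.tsv"]
        sub_panel = SitePanel(panel.sites[panel.sites["site_id"].isin(keep)])
        s = correlation_structure(mat, sub_panel)
        structure[cond] = {
            k: v for k, v in s.items() if not isinstance(v, np.ndarray)
        } | {f"n_{g}": int(len(s[g])) for g in ("adjacent", "same_gene", "unrelated")}
        _log(f"correlate: {cond} significant site-trait records "
             f"{int(site_rec['significant'].sum())}")
    with open(outdir / "structure.json", "w") as fh:
        json.dump(structure, fh, indent=2, sort_keys=True, allow_nan=True)
    return out_paths + [outdir / "structure.json"]


def stage_popgen(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    pops = pd.read_csv(outdir / "populations.tsv", sep="\t")
    windows = read_windows_bed(outdir / "windows.bed")
    gpanel = read_vcf(outdir / "popgen.vcf", pops, windows)
    scan = popgen_scan(gpanel, estimator=cfg["popgen"].get("estimator", "hudson"))
    focal = sorted(cfg["popgen"].get("focal_genes", {}))
    background = scan[~scan["gene_id"].isin(focal)].set_index("gene_id")["fst_UL"]
    focal_vals = scan[scan["gene_id"].isin(focal)].set_index("gene_id")["fst_UL"]
    out = outlier_scan(scan.set_index("gene_id")["fst_UL"], background,
                       quantile=cfg["popgen"]["quantile"])
    scan["fst_outlier"] = out["flags"].reindex(scan["gene_id"]).to_numpy()
    _write_tsv(scan, outdir / "popgen_scan.tsv")
    summary = {
        "threshold": out["threshold"],
        "quantile": out["quantile"],
        "n_outliers": out["n_outliers"],
        "ks_p_focal_vs_background": (
            float(_stats.ks_2samp(focal_vals.to_numpy(), background.dropna().to_numpy()).pvalue)
            if len(focal_vals)
            else None
        ),
        "focal_fst_UL": {g: float(focal_vals.get(g, np.nan)) for g in focal},
    }
    paths = [outdir / "popgen_scan.tsv"]
    for gene in focal:
        rep = haplotype_grouping(gpanel, gene)
        _write_tsv(rep.table, outdir / f"haplotypes_{gene}.tsv")
        summary.setdefault("dominant_haplotypes", {})[gene] = rep.dominant
        paths.append(outdir / f"haplotypes_{gene}.tsv")
    with open(outdir / "popgen_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _log(f"popgen: threshold {out['threshold']:.3f}, {out['n_outliers']} outlier gene(s)")
    return paths + [outdir / "popgen_summary.json"]


def stage_deg_rules(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    table = pd.read_csv(outdir / "de_table.tsv", sep="\t")
    line_map = pd.read_csv(outdir / "de_line_map.tsv", sep="\t")
    mapping = dict(zip(line_map["line"], line_map["mutant_gene"]))
    calls = classify_core_degs(
        table, mapping, fc_threshold=cfg["deg"]["fc_threshold"], alpha=cfg["deg"]["alpha"]
    )
    _write_tsv(calls, outdir / "core_degs.tsv")
    n1 = int((calls["call"] == "TypeI").sum())
    n2 = int((calls["call"] == "TypeII").sum())
    _log(f"deg-rules: {n1} Type I + {n2} Type II core DEGs")
    return [outdir / "core_degs.tsv"]


def write_report(outdir: Path) -> Path:
    """Aggregate per-site outputs into report.json (always recomputable)."""
    report: dict = {}
    cls_path = outdir / "classification.tsv"
    if cls_path.exists():
        cls = pd.read_csv(cls_path, sep="\t")
        inf = cls[cls["informative"]]
        ck_set = set(inf.loc[inf["ecotype_differentiated_CK"], "site_id"])
        dt_set = set(inf.loc[inf["ecotype_differentiated_DT"], "site_id"])
        nonsyn = inf["consequence"] == "nonsynonymous"
        report["sites"] = {
            "total": int(len(cls)),
            "informative": int(cls["informative"].sum()),
            "drought_increase": int(
                (inf["drought_responsive"] & (inf["drought_direction"] == "increase")).sum()
            ),
            "drought_decrease": int(
                (inf["drought_responsive"] & (inf["drought_direction"] == "decrease")).sum()
            ),
            "ecotype_differentiated_CK": len(ck_set),
            "ecotype_differentiated_DT": len(dt_set),
            "ecotype_common": len(ck_set & dt_set),
            "nonsynonymous": int(nonsyn.sum()),
            "ecotype_differentiated_nonsynonymous": int(
                (nonsyn & inf["site_id"].isin(ck_set | dt_set)).sum()
            ),
        }
    pat_path = outdir / "patterns.tsv"
    if pat_path.exists():
        pat = pd.read_csv(pat_path, sep="\t")
        defined = pat[pat["category"] != "undefined"]
        share = defined["category"].value_counts(normalize=True)
        report["patterns"] = {
            k: float(share.get(k, 0.0)) for k in ("upregulated", "downregulated", "unchanged")
        }
    for cond in ("CK", "DT"):
        p = outdir / f"correlations_{cond}.tsv"
        if p.exists():
            rec = pd.read_csv(p, sep="\t")
            sig = rec[rec["significant"].fillna(False)]
            entry = {
                "significant_positive": int((sig["pcc"] > 0).sum()),
                "significant_negative": int((sig["pcc"] < 0).sum()),
            }
            if cond == "DT":
                rwc = sig[(sig["trait"] == "RWC") & (sig["pcc"] < 0)]
                entry["rwc_negative_sites"] = int(rwc["id"].nunique())
            report.setdefault("correlations", {})[cond] = entry
    pg = outdir / "popgen_summary.json"
    if pg.exists():
        report["popgen"] = json.loads(pg.read_text())
    degs = outdir / "core_degs.tsv"
    if degs.exists():
        calls = pd.read_csv(degs, sep="\t")
        report["core_degs"] = {
            "TypeI": int((calls["call"] == "TypeI").sum()),
            "TypeII": int((calls["call"] == "TypeII").sum()),
        }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    flat = []
    for section, vals in report.items():
        if isinstance(vals, dict):
            for k, v in vals.items():
                if isinstance(v, (int, float, str)):
                    flat.append({"section": section, "key": k, "value": v})
    _write_tsv(pd.DataFrame(flat), outdir / "summary.tsv")
    return outdir / "report.json"


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "quantify": stage_quantify,
    "filter": stage_filter,
    "classify": stage_classify,
    "correlate": stage_correlate,
    "popgen": stage_popgen,
    "deg-rules": stage_deg_rules,
}


def run_pipeline(
    cfg: dict | None,
    outdir,
    seed: int = 0,
    stages: list[str] | None = None,
    resume: bool = False,
) -> dict:
    """Run the requested stages in dependency order; returns the manifest.

    The manifest snapshots the config and seed, records per-stage status and
    output checksums, and is written to ``manifest.json``.  A failed stage
    marks later stages skipped.  With ``resume``, stages already marked ok
    (with outputs still present) are not rerun.
    """
    cfg = validate_config(cfg or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    todo = stages or STAGES
    unknown = set(todo) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")

    manifest_path = outdir / "manifest.json"
    prev = json.loads(manifest_path.read_text()) if (resume and manifest_path.exists()) else {}
    prev_stages = {s["name"]: s for s in prev.get("stages", [])}

    manifest = {
        "tool": "medito",
        "version": __version__,
        "seed": int(seed),
        "config": cfg,
        "stages": [],
    }
    failed = False
    for name in [s for s in STAGES if s in todo]:
        entry = {"name": name, "status": "pending", "outputs": {}}
        if failed:
            entry["status"] = "skipped"
            manifest["stages"].append(entry)
            continue
        old = prev_stages.get(name)
        if (
            resume
            and old
            and old.get("status") == "ok"
            and all((outdir / p).exists() for p in old.get("outputs", {}))
        ):
            entry = old
            manifest["stages"].append(entry)
            _log(f"{name}: resumed (outputs present)")
            continue
        try:
            if name == "report":
                paths = [write_report(outdir)]
            else:
                paths = _STAGE_FUNCS[name](cfg, outdir, seed)
            entry["outputs"] = {str(p.relative_to(outdir)): _sha256(p) for p in paths}
            entry["status"] = "ok"
        except Exception as exc:  # noqa: BLE001 - manifest must record the failure
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            failed = True
            _log(f"{name}: FAILED ({entry['error']})")
        manifest["stages"].append(entry)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
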