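"""Synthetic amplicon-editing datasets with known ground truth.

The generator emulates the structure of the rice landrace study the rest of
the package analyses: 64 upland + 60 lowland genotypes sampled in two field
conditions (CK = well-watered, DT = drought), a 426-site panel spread over 31
mitochondrial genes, targeted amplicon sequencing at mean depth > 500, and a
trait table with planted editing–phenotype correlations.  Every stochastic
quantity flows from the single config seed, so identical (config, seed)
yields byte-identical outputs.

Effect structure
----------------
True editing efficiencies live on the logit scale:

    logit(E[g, s, CK]) = logit(base_s) + jitter_{g,s} + factor_{g,gene(s)}
                         + global_g + upland_g * ecotype_shift_s
    logit(E[g, s, DT]) = logit(E[g, s, CK]) + drought_shift_s

so shifted efficiencies always stay inside (0, 1); sites can additionally be
planted at exactly 0 or 1 (always-/never-edited controls).  Observed counts
are Binomial(depth, p(1-e) + (1-p)e) at negative-binomial depth, with
cell-wise missingness (depth 0).
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core import CANONICAL_EDITS, SitePanel, make_display_name

__all__ = [
    "ShiftSpec",
    "TraitEffect",
    "SimulationConfig",
    "TrueEfficiencyTensor",
    "simulate_site_panel",
    "simulate_editing_truth",
    "simulate_counts",
    "simulate_traits",
    "resolve_trait_effects",
    "simulate_haplotype_panel",
    "PopGenSimConfig",
    "simulate_popgen_dataset",
    "simulate_de_table",
]

#: rice mitochondrial gene names used for synthetic panels (sense CDS labels).
RICE_MT_GENES = [
    "atp1", "atp4", "atp6", "atp8", "atp9",
    "ccmB", "ccmC", "ccmFc", "ccmFn", "cob",
    "cox1", "cox2", "cox3", "matR",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "nad7", "nad9",
    "orfX",
    "rpl2", "rpl5", "rpl16",
    "rps1", "rps2", "rps3", "rps4", "rps7", "rps13",
]

TRAITS = ["PH", "NT", "FLL", "FLW", "NG", "100GW", "GY", "biomass", "HI", "fecundity", "RWC"]

# (mean, sd) per trait in CK; DT applies a multiplicative drought penalty.
_TRAIT_BASE = {
    "PH": (112.0, 14.0),       # cm
    "NT": (9.5, 2.2),
    "FLL": (30.0, 5.0),        # cm
    "FLW": (1.6, 0.25),        # cm
    "NG": (1250.0, 320.0),
    "100GW": (2.6, 0.35),      # g
    "GY": (27.0, 8.0),         # g / plant
    "biomass": (62.0, 14.0),   # g / plant
    "HI": (0.46, 0.07),
    "fecundity": (0.86, 0.09),
    "RWC": (0.93, 0.03),
}
_DT_MEAN_SCALE = {
    "PH": 0.85, "NT": 0.80, "FLL": 0.95, "FLW": 0.90, "NG": 0.65,
    "100GW": 0.92, "GY": 0.55, "biomass": 0.75, "HI": 0.85,
    "fecundity": 0.80, "RWC": 0.63,
}
_DT_SD_SCALE = {"RWC": 3.0}  # drought spreads leaf water status far more than CK

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass(frozen=True)
class ShiftSpec:
    """Plant a logit-scale shift at a random subset of sites.

    ``n_positive`` sites get ``positive``, ``n_negative`` distinct sites get
    ``negative``; everything else is 0.  Site subsets are drawn from the
    config seed, so they are reproducible.  On panels smaller than
    ``n_positive + n_negative`` the counts are scaled down proportionally,
    so the planted landscape keeps its shape at reduced scale.
    """

    n_positive: int = 0
    positive: float = 0.0
    n_negative: int = 0
    negative: float = 0.0


@dataclass(frozen=True)
class TraitEffect:
    """Drive one trait from editing efficiencies at driver sites.

    ``driver_sites`` is either an explicit list of site ids / integer site
    indices, an int meaning "this many sites drawn at random", or the string
    ``"global"`` to drive on the genotype's overall editing level (mean over
    all sites — the observable analogue of the shared genotype factor).  The
    trait is built as r·Z + sqrt(1-r²)·ε with Z the standardized mean driver
    efficiency, so the population PCC equals ``target_pcc`` by construction.
    """

    trait: str
    target_pcc: float
    driver_sites: int | tuple | str = 1
    condition: str = "DT"

    def __post_init__(self):
        if not -1.0 < self.target_pcc < 1.0:
            raise ValueError(f"target_pcc must lie in (-1, 1), got {self.target_pcc}")
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")


@dataclass
class SimulationConfig:
    """Study-scale defaults for the synthetic amplicon experiment."""

    n_upland: int = 64
    n_lowland: int = 60
    n_genes: int = 31
    #: int (same for every gene), per-gene sequence, or None → ``total_sites``
    #: split as evenly as possible across genes.
    sites_per_gene: int | Sequence[int] | None = None
    total_sites: int = 426
    mean_depth: float = 550.0
    depth_dispersion: float = 8.0
    baseline_beta: tuple[float, float] = (2.0, 2.0)
    #: logit-scale site-specific genotype-to-genotype spread.
    genotype_sd: float = 0.4
    #: logit-scale shared per-gene regulator factor (same-gene sites correlate).
    gene_factor_sd: float = 0.3
    #: logit-scale genotype-level overall editing propensity (all sites).
    global_factor_sd: float = 0.25
    drought_shift: ShiftSpec | float | Sequence | Mapping = field(
        default_factory=lambda: ShiftSpec(240, 0.4, 2, -0.4)
    )
    ecotype_shift: ShiftSpec | float | Sequence | Mapping = field(
        default_factory=lambda: ShiftSpec(40, 0.35, 17, -0.35)
    )
    #: site ids or integer indices planted at exactly 1.0 / 0.0 everywhere.
    always_edited_sites: tuple = ()
    never_edited_sites: tuple = ()
    #: site → missing fraction; exactly ceil(rate * cells) cells are blanked.
    high_missing_sites: Mapping = field(default_factory=dict)
    missing_rate: float = 0.02
    sequencing_error_rate: float = 0.001
    trait_effects: tuple[TraitEffect, ...] = (TraitEffect("RWC", -0.35, "global", "DT"),)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_upland", "n_lowland", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("missing_rate", "sequencing_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        a, b = self.baseline_beta
        if a <= 0 or b <= 0:
            raise ValueError("baseline_beta parameters must be positive")
        if isinstance(self.sites_per_gene, int) and self.sites_per_gene < 1:
            raise ValueError("sites_per_gene must be >= 1")

    # per-gene site allocation, resolved once
    def site_allocation(self) -> list[int]:
        if self.sites_per_gene is None:
            base, extra = divmod(self.total_sites, self.n_genes)
            return [base + (1 if i < extra else 0) for i in range(self.n_genes)]
        if isinstance(self.sites_per_gene, int):
            return [self.sites_per_gene] * self.n_genes
        alloc = [int(s) for s in self.sites_per_gene]
        if len(alloc) != self.n_genes:
            raise ValueError("sites_per_gene list length must equal n_genes")
        if any(s < 1 for s in alloc):
            raise ValueError("sites_per_gene entries must be >= 1")
        return alloc

    @property
    def n_sites(self) -> int:
        return sum(self.site_allocation())

    @property
    def genotypes(self) -> list[str]:
        return [f"U{i:03d}" for i in range(1, self.n_upland + 1)] + [
            f"L{i:03d}" for i in range(1, self.n_lowland + 1)
        ]

    @property
    def ecotypes(self) -> np.ndarray:
        return np.array(["upland"] * self.n_upland + ["lowland"] * self.n_lowland)


@dataclass
class TrueEfficiencyTensor:
    """Ground-truth editing probabilities: genotype × site × condition."""

    values: np.ndarray  # (n_genotypes, n_sites, 2); axis 2 = (CK, DT)
    genotypes: list[str]
    ecotypes: np.ndarray
    site_ids: list[str]
    drought_shift: np.ndarray
    ecotype_shift: np.ndarray
    conditions: tuple[str, str] = ("CK", "DT")

    def __post_init__(self):
        if self.values.shape != (len(self.genotypes), len(self.site_ids), 2):
            raise ValueError("tensor dimensions inconsistent with metadata")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("true efficiencies must lie in [0, 1]")

    def frame(self, condition: str) -> pd.DataFrame:
        k = self.conditions.index(condition)
        return pd.DataFrame(self.values[:, :, k], index=self.genotypes, columns=self.site_ids)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, stream])


def _site_indices(sites, site_ids: list[str]) -> np.ndarray:
    """Resolve a mix of site ids and integer indices to integer positions."""
    lookup = {s: i for i, s in enumerate(site_ids)}
    out = []
    for s in sites:
        if isinstance(s, (int, np.integer)):
            out.append(int(s))
        else:
            out.append(lookup[s])
    return np.asarray(out, dtype=int)


def _resolve_shift(spec, n_sites: int, site_ids: list[str], rng: np.random.Generator) -> np.ndarray:
    arr = np.zeros(n_sites)
    if isinstance(spec, ShiftSpec):
        n_pos, n_neg = spec.n_positive, spec.n_negative
        k = n_pos + n_neg
        if k > n_sites:
            scale = n_sites / k
            n_pos = int(n_pos * scale)
            n_neg = int(n_neg * scale)
            k = n_pos + n_neg
        idx = rng.choice(n_sites, size=k, replace=False)
        arr[idx[:n_pos]] = spec.positive
        arr[idx[n_pos:]] = spec.negative
    elif isinstance(spec, Mapping):
        idx = _site_indices(list(spec.keys()), site_ids)
        arr[idx] = np.fromiter(spec.values(), dtype=float, count=len(idx))
    elif np.isscalar(spec):
        arr[:] = float(spec)
    else:
        vals = np.asarray(spec, dtype=float)
        if vals.shape != (n_sites,):
            raise ValueError("per-site shift array has wrong length")
        arr = vals
    return arr


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

def simulate_site_panel(config: SimulationConfig) -> SitePanel:
    """Generate gene references and a site panel over them.

    Sites sit on C (sense amplicons, ~80%) or G (antisense amplicons)
    positions of a synthetic CDS built from sense codons (ATG start, no
    internal stops), with 1-based strictly increasing positions per gene and
    codon frame derived from position.
    """
    rng = _rng(config.seed, 1)
    alloc = config.site_allocation()
    gene_names = list(RICE_MT_GENES[: config.n_genes])
    while len(gene_names) < config.n_genes:
        gene_names.append(f"orf{100 + len(gene_names)}")

    rows = []
    sequences: dict[str, str] = {}
    snv = 1
    for gene, n_sites_g in zip(gene_names, alloc):
        n_codons = 40 + 12 * n_sites_g
        codons = ["ATG"] + [
            _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons - 1)
        ]
        seq = "".join(codons)
        sequences[gene] = seq
        base_arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
        c_pos = np.flatnonzero(base_arr == "C") + 1  # 1-based
        g_pos = np.flatnonzero(base_arr == "G") + 1
        want_c = int(round(0.8 * n_sites_g))
        want_c = min(want_c, len(c_pos))
        want_g = n_sites_g - want_c
        if want_g > len(g_pos):  # pragma: no cover - sequences are long enough
            want_c, want_g = n_sites_g - len(g_pos), len(g_pos)
        chosen = np.concatenate(
            [
                rng.choice(c_pos, size=want_c, replace=False),
                rng.choice(g_pos, size=want_g, replace=False),
            ]
        )
        for pos in np.sort(chosen):
            pos = int(pos)
            rows.append(
                {
                    "site_id": f"SNV{snv:05d}",
                    "gene_id": gene,
                    "gene_position": pos,
                    "ref_base": seq[pos - 1],
                    "codon_index": (pos + 2) // 3,
                    "codon_position": (pos - 1) % 3 + 1,
                    "display_name": make_display_name(gene, pos),
                }
            )
            snv += 1
    df = pd.DataFrame(rows)
    return SitePanel(df, sequences=sequences)


# ---------------------------------------------------------------------------
# truth + counts
# ---------------------------------------------------------------------------

def simulate_editing_truth(panel: SitePanel, config: SimulationConfig) -> TrueEfficiencyTensor:
    """Draw ground-truth editing probabilities for every genotype/site/condition."""
    rng = _rng(config.seed, 2)
    site_ids = panel.site_ids
    n_sites = len(site_ids)
    genotypes = config.genotypes
    ecotypes = config.ecotypes
    n_geno = len(genotypes)

    base = rng.beta(*config.baseline_beta, size=n_sites)
    base = np.clip(base, 1e-4, 1 - 1e-4)
    drought = _resolve_shift(config.drought_shift, n_sites, site_ids, rng)
    ecotype = _resolve_shift(config.ecotype_shift, n_sites, site_ids, rng)
    jitter = rng.normal(0.0, config.genotype_sd, size=(n_geno, n_sites))

    l_ck = logit(base)[None, :] + jitter
    if config.gene_factor_sd > 0:
        gene_codes = pd.factorize(panel.sites["gene_id"])[0]
        factors = rng.normal(0.0, config.gene_factor_sd, size=(n_geno, gene_codes.max() + 1))
        l_ck = l_ck + factors[:, gene_codes]
    if config.global_factor_sd > 0:
        l_ck = l_ck + rng.normal(0.0, config.global_factor_sd, size=(n_geno, 1))
    is_up = (ecotypes == "upland").astype(float)
    l_ck = l_ck + is_up[:, None] * ecotype[None, :]

    values = np.empty((n_geno, n_sites, 2))
    values[:, :, 0] = expit(l_ck)
    values[:, :, 1] = expit(l_ck + drought[None, :])

    for idx, v in (
        (_site_indices(config.always_edited_sites, site_ids), 1.0),
        (_site_indices(config.never_edited_sites, site_ids), 0.0),
    ):
        if len(idx):
            values[:, idx, :] = v
            drought[idx] = 0.0
            ecotype[idx] = 0.0

    return TrueEfficiencyTensor(
        values=values,
        genotypes=genotypes,
        ecotypes=ecotypes,
        site_ids=site_ids,
        drought_shift=drought,
        ecotype_shift=ecotype,
    )


def simulate_counts(
    truth: TrueEfficiencyTensor, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-cell depths and edited-base counts.

    Returns ``(counts, metadata)``: counts in the pileup dialect
    (sample_id, site_id, ref_count, alt_count) and per-sample metadata
    (sample_id, genotype, ecotype, condition).  Missing cells carry depth 0.
    """
    rng = _rng(config.seed, 3)
    n_geno, n_sites, _ = truth.values.shape
    shape = (n_geno, n_sites, 2)

    k = config.depth_dispersion
    depth = rng.negative_binomial(k, k / (k + config.mean_depth), size=shape)
    e = config.sequencing_error_rate
    p_obs = truth.values * (1 - e) + (1 - truth.values) * e
    alt = rng.binomial(depth, p_obs)

    miss = rng.random(shape) < config.missing_rate
    if config.high_missing_sites:
        site_ids = truth.site_ids
        n_cells = n_geno * 2
        for site, rate in config.high_missing_sites.items():
            j = int(_site_indices([site], site_ids)[0])
            n_blank = math.ceil(float(rate) * n_cells)
            flat = rng.choice(n_cells, size=n_blank, replace=False)
            miss[flat % n_geno, j, flat // n_geno] = True
    depth = np.where(miss, 0, depth)
    alt = np.where(miss, 0, alt)
    ref = depth - alt

    frames = []
    for ci, cond in enumerate(truth.conditions):
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": np.repeat(
                        [f"{g}_{cond}" for g in truth.genotypes], n_sites
                    ),
                    "site_id": np.tile(truth.site_ids, n_geno),
                    "ref_count": ref[:, :, ci].ravel(),
                    "alt_count": alt[:, :, ci].ravel(),
                }
            )
        )
    counts = pd.concat(frames, ignore_index=True)
    meta = pd.DataFrame(
        {
            "sample_id": [f"{g}_{c}" for c in truth.conditions for g in truth.genotypes],
            "genotype": list(truth.genotypes) * 2,
            "ecotype": list(truth.ecotypes) * 2,
            "condition": ["CK"] * len(truth.genotypes) + ["DT"] * len(truth.genotypes),
        }
    )
    return counts, meta


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def resolve_trait_effects(config: SimulationConfig, site_ids: list[str]) -> list[dict]:
    """Concretize trait effects: random driver-site draws become explicit ids.

    Deterministic for a fixed config seed; used by both :func:`simulate_traits`
    and any caller that needs to know where correlations were planted.
    """
    rng = _rng(config.seed, 4)
    resolved = []
    for eff in config.trait_effects:
        if isinstance(eff.driver_sites, str):
            if eff.driver_sites != "global":
                raise ValueError(f"unknown driver spec {eff.driver_sites!r}")
            idx = np.arange(len(site_ids))
        elif isinstance(eff.driver_sites, (int, np.integer)):
            idx = np.sort(rng.choice(len(site_ids), size=int(eff.driver_sites), replace=False))
        else:
            idx = _site_indices(list(eff.driver_sites), site_ids)
        resolved.append(
            {
                "trait": eff.trait,
                "condition": eff.condition,
                "target_pcc": eff.target_pcc,
                "driver_sites": [site_ids[i] for i in idx],
            }
        )
    return resolved


def simulate_traits(truth: TrueEfficiencyTensor, config: SimulationConfig) -> pd.DataFrame:
    """Trait table: genotype × condition rows, one column per agronomic trait.

    Driven traits achieve their target population PCC against the mean true
    driver efficiency; all other traits are independent noise around
    field-realistic means (drought applies a multiplicative penalty).
    RWC is clipped to [0, 1].
    """
    effects = resolve_trait_effects(config, truth.site_ids)
    rng = _rng(config.seed, 5)
    n_geno = len(truth.genotypes)
    by_key = {(e["trait"], e["condition"]): e for e in effects}

    rows = []
    for ci, cond in enumerate(truth.conditions):
        data = {"genotype": truth.genotypes, "condition": cond}
        for trait in TRAITS:
            mean, sd = _TRAIT_BASE[trait]
            if cond == "DT":
                mean *= _DT_MEAN_SCALE[trait]
                sd *= _DT_SD_SCALE.get(trait, 1.0)
            noise = rng.normal(size=n_geno)
            eff = by_key.get((trait, cond))
            if eff is not None:
                idx = _site_indices(eff["driver_sites"], truth.site_ids)
                signal = truth.values[:, idx, ci].mean(axis=1)
                s = signal.std(ddof=0)
                z = (signal - signal.mean()) / s if s > 0 else np.zeros(n_geno)
                r = eff["target_pcc"]
                z = r * z + math.sqrt(1 - r * r) * noise
            else:
                z = noise
            vals = mean + sd * z
            if trait == "RWC":
                vals = np.clip(vals, 0.0, 1.0)
            data[trait] = vals
        rows.append(pd.DataFrame(data))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# popgen panels
# ---------------------------------------------------------------------------

def simulate_haplotype_panel(
    n_pop1: int,
    n_pop2: int,
    n_snps: int,
    divergence: float,
    seed: int,
    pop_names: tuple[str, str] = ("upland", "lowland"),
):
    """Haploid biallelic panel for two populations with tunable divergence.

    Per SNP an ancestral frequency p ~ U(0.05, 0.95) is drawn; population
    frequencies are p1 = (1-d)·p and p2 = (1-d)·p + d, so d = 0 gives shared
    frequencies and d = 1 fixed differences (F_ST = 1).
    """
    from .popgen import GenotypePanel  # local import to avoid a cycle

    if n_pop1 < 2 or n_pop2 < 2:
        raise ValueError("each population needs at least 2 accessions")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    rng = _rng(seed, 6)
    p = rng.uniform(0.05, 0.95, size=n_snps)
    p1 = (1 - divergence) * p
    p2 = (1 - divergence) * p + divergence
    g1 = (rng.random((n_pop1, n_snps)) < p1).astype(float)
    g2 = (rng.random((n_pop2, n_snps)) < p2).astype(float)
    genotypes = np.vstack([g1, g2])
    positions = np.arange(1, n_snps + 1) * 10
    accessions = pd.DataFrame(
        {
            "accession": [f"{pop_names[0][0].upper()}{i:03d}" for i in range(1, n_pop1 + 1)]
            + [f"{pop_names[1][0].upper()}{i:03d}" for i in range(1, n_pop2 + 1)],
            "population": [pop_names[0]] * n_pop1 + [pop_names[1]] * n_pop2,
        }
    )
    windows = pd.DataFrame(
        {"gene_id": ["sim"], "chrom": ["1"], "start": [1], "end": [int(positions[-1]) + 10]}
    )
    return GenotypePanel(
        genotypes=genotypes,
        chrom=np.array(["1"] * n_snps),
        positions=positions,
        ref=np.array(["A"] * n_snps),
        alt=np.array(["G"] * n_snps),
        accessions=accessions,
        windows=windows,
    )


@dataclass
class PopGenSimConfig:
    """Resequencing-panel emulation: landraces + wild rice, per-gene windows."""

    n_upland: int = 64
    n_lowland: int = 60
    n_wild: int = 45
    n_background_genes: int = 200
    snps_per_gene_mean: float = 18.0
    #: Beta(a, b) prior for background upland–lowland divergence (mean ≈ 0.12,
    #: 95th percentile ≈ 0.33 — a moderately differentiated genomic background).
    background_divergence_beta: tuple[float, float] = (0.8, 6.0)
    #: focal, highly ecotype-differentiated genes and their U–L divergence.
    focal_genes: Mapping[str, float] = field(
        default_factory=lambda: {"PPR035": 0.74, "PPR406": 0.62}
    )
    wild_divergence: float = 0.25
    missing_rate: float = 0.01
    window_bp: int = 4000  # the -2000..+2000 bp gene-region convention
    seed: int = 0


def simulate_popgen_dataset(config: PopGenSimConfig):
    """Genome-scale background + focal PPR genes, three populations.

    Background genes get small upland–lowland divergence; focal genes get the
    configured high divergence.  Wild rice drifts from the landrace pool by
    ``wild_divergence``.  Returns a :class:`~medito.popgen.GenotypePanel`.
    """
    from .popgen import GenotypePanel

    rng = _rng(config.seed, 7)
    genes = [f"gene{i:04d}" for i in range(1, config.n_background_genes + 1)]
    a, b = config.background_divergence_beta
    div_ul = {g: float(d) for g, d in zip(genes, rng.beta(a, b, size=len(genes)))}
    for g, d in config.focal_genes.items():
        genes.append(g)
        div_ul[g] = float(d)

    chrom_list, pos_list, gene_rows, geno_blocks = [], [], [], []
    offset = 0
    nU, nL, nW = config.n_upland, config.n_lowland, config.n_wild
    for gene in genes:
        m = max(4, int(rng.poisson(config.snps_per_gene_mean)))
        start = offset + 1
        end = offset + config.window_bp
        pos = np.sort(rng.choice(np.arange(start, end + 1), size=m, replace=False))
        d = div_ul[gene]
        p = rng.uniform(0.05, 0.95, size=m)
        edge = rng.integers(0, 2, size=m).astype(float)
        p_up = (1 - d) * p + d * edge
        p_low = (1 - d) * p + d * (1 - edge)
        dw = config.wild_divergence
        p_wild = (1 - dw) * p + dw * rng.uniform(0, 1, size=m)
        block = np.vstack(
            [
                (rng.random((nU, m)) < p_up).astype(float),
                (rng.random((nL, m)) < p_low).astype(float),
                (rng.random((nW, m)) < p_wild).astype(float),
            ]
        )
        miss = rng.random(block.shape) < config.missing_rate
        block[miss] = np.nan
        geno_blocks.append(block)
        chrom_list.extend(["1"] * m)
        pos_list.extend(pos.tolist())
        gene_rows.append({"gene_id": gene, "chrom": "1", "start": start, "end": end})
        offset = end + 1000

    genotypes = np.hstack(geno_blocks)
    n_snps = genotypes.shape[1]
    ref_alt = rng.integers(0, 4, size=(n_snps, 2))
    bases = np.array(list("ACGT"))
    ref = bases[ref_alt[:, 0]]
    alt = bases[(ref_alt[:, 0] + 1 + ref_alt[:, 1] % 3) % 4]
    accessions = pd.DataFrame(
        {
            "accession": [f"U{i:03d}" for i in range(1, nU + 1)]
            + [f"L{i:03d}" for i in range(1, nL + 1)]
            + [f"W{i:03d}" for i in range(1, nW + 1)],
            "population": ["upland"] * nU + ["lowland"] * nL + ["wild"] * nW,
        }
    )
    return GenotypePanel(
        genotypes=genotypes,
        chrom=np.array(chrom_list),
        positions=np.array(pos_list, dtype=int),
        ref=ref,
        alt=alt,
        accessions=accessions,
        windows=pd.DataFrame(gene_rows),
    )


# ---------------------------------------------------------------------------
# differential-expression table (input to the rule module)
# ---------------------------------------------------------------------------

def simulate_de_table(
    n_genes: int = 2000,
    n_type1: int = 90,
    n_type2: int = 35,
    n_single: int = 300,
    seed: int = 0,
    lines: tuple[str, ...] = ("ppr035-1", "ppr035-2", "ppr406-1", "ppr406-2"),
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Synthetic mutant-vs-WT differential-expression table for four lines.

    Plants ``n_type1`` genes as DEGs in lines of both mutant genes,
    ``n_type2`` genes as DEGs in one line with |log2FC| > 2 in all four, and
    ``n_single`` ordinary single-mutant DEGs; the rest are null.  Returns the
    long table (gene, line, log2fc, p) and the line → mutant-gene mapping.
    """
    rng = _rng(seed, 8)
    line_to_gene = {ln: ln.rsplit("-", 1)[0] for ln in lines}
    genes = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    lfc = rng.normal(0.0, 0.4, size=(n_genes, len(lines)))
    p = rng.uniform(0.0, 1.0, size=(n_genes, len(lines)))

    idx = rng.permutation(n_genes)
    t1 = idx[:n_type1]
    t2 = idx[n_type1 : n_type1 + n_type2]
    single = idx[n_type1 + n_type2 : n_type1 + n_type2 + n_single]

    sign = rng.choice([-1.0, 1.0], size=n_type1)
    lfc[t1, :] = sign[:, None] * rng.uniform(1.5, 4.0, size=(n_type1, len(lines)))
    p[t1, :] = rng.uniform(0.0, 0.04, size=(n_type1, len(lines)))

    sign2 = rng.choice([-1.0, 1.0], size=n_type2)
    lfc[t2, :] = sign2[:, None] * rng.uniform(2.2, 5.0, size=(n_type2, len(lines)))
    p[t2, :] = rng.uniform(0.2, 1.0, size=(n_type2, len(lines)))
    hot = rng.integers(0, len(lines), size=n_type2)
    p[t2, hot] = rng.uniform(0.0, 0.04, size=n_type2)

    hot1 = rng.integers(0, len(lines), size=n_single)
    lfc[single, hot1] = rng.choice([-1.0, 1.0], size=n_single) * rng.uniform(
        1.2, 1.9, size=n_single
    )
    p[single, hot1] = rng.uniform(0.0, 0.04, size=n_single)

    table = pd.DataFrame(
        {
            "gene": np.repeat(genes, len(lines)),
            "line": np.tile(lines, n_genes),
            "log2fc": lfc.ravel(),
            "p": p.ravel(),
        }
    )
    return table, line_to_gene
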