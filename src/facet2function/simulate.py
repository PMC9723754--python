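"""Synthetic datasets with the design and causal structure of a subtropical
tree-diversity experiment.

The generator emulates a forest biodiversity–ecosystem-functioning
platform: ~52 plots planted at tree species richness 1–24, ~150 soil
samples, each measured for soil chemistry (TOC, TN, TP, pH, humidity),
PLFA marker biomasses, bacterial and fungal ASV tables, carbon-cycling
gene abundances, a 14-substrate MicroResp CO2 profile and basal
respiration.

Generation happens in three layers:

1. *soil chemistry* — multivariate-normal latents mapped affinely onto
   realistic ranges (clipping events are negligible at the default
   scales, so the requested covariance is preserved);
2. *latent facets* — each microbial facet is a linear combination of its
   structural parents on standardized (unit-SD) scales plus Gaussian
   disturbance; disturbances of the seven exogenous facets are correlated
   according to the reported facet correlations, and disturbance SDs are
   auto-scaled so every facet has ~unit variance, making the generating
   coefficients directly comparable to fitted standardized estimates;
3. *observations* — Dirichlet-multinomial ASV counts whose realized
   Shannon diversity tracks the latent diversity facet, lognormal PLFA
   markers consistent with latent total biomass and B:F, lognormal gene
   abundances whose evenness tracks the latent FG-evenness facet, a CO2
   matrix whose computed SIR efficiency/range track their latents, and
   noisy positive respiration.

The ground-truth latent table is retained so recovery can be tested at
every stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import structure
from .indices import ALANINE, OXALIC

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: default correlations among soil-chemistry latents (toc, tn, tp, ph, humidity)
DEFAULT_SOIL_CORRELATION = pd.DataFrame(
    [
        [1.00, 0.70, 0.30, -0.20, 0.25],
        [0.70, 1.00, 0.35, -0.15, 0.20],
        [0.30, 0.35, 1.00, 0.10, 0.10],
        [-0.20, -0.15, 0.10, 1.00, -0.10],
        [0.25, 0.20, 0.10, -0.10, 1.00],
    ],
    index=structure.SOIL_VARIABLES,
    columns=structure.SOIL_VARIABLES,
)

#: observed-scale location and spread of the soil variables
SOIL_MEANS = {"toc": 20.0, "tn": 1.6, "tp": 0.45, "ph": 4.8, "humidity": 0.30}
SOIL_SCALES = {"toc": 5.0, "tn": 0.35, "tp": 0.10, "ph": 0.35, "humidity": 0.05}
SOIL_BOUNDS = {
    "toc": (0.5, None),
    "tn": (0.05, None),
    "tp": (0.02, None),
    "ph": (3.0, 9.0),
    "humidity": (0.02, 0.98),
}


@dataclass
class DesignConfig:
    """Experimental design: plots, richness gradient, sample allocation."""

    n_plots: int = 52
    richness_levels: tuple[int, ...] = (1, 2, 4, 8, 16, 24)
    n_samples: int = 150
    seed: int | None = None

    def validate(self) -> None:
        if self.n_plots <= 0 or self.n_samples <= 0:
            raise ValueError("n_plots and n_samples must be positive")
        if not self.richness_levels:
            raise ValueError("richness_levels must be non-empty")
        if any(r <= 0 for r in self.richness_levels):
            raise ValueError("richness levels must be positive integers")
        if self.n_samples < self.n_plots:
            raise ValueError("n_samples must be at least n_plots")


@dataclass
class GeneratorParams:
    """Structural coefficients, noise scales and observation parameters."""

    structural_coefficients: dict = field(
        default_factory=lambda: dict(structure.FULL_COEFFICIENTS)
    )
    facet_correlations: dict = field(
        default_factory=lambda: dict(structure.FACET_CORRELATIONS)
    )
    exogenous_covariance: pd.DataFrame | None = None  # default: DEFAULT_SOIL_CORRELATION
    noise_sd: dict = field(default_factory=dict)      # per-variable override; else auto
    log_tree_richness: bool = False

    # --- observation layer ---
    n_asv_bacteria: int = 2000
    n_asv_fungi: int = 800
    depth_bacteria: int = 28897
    depth_fungi: int = 16542
    depth_spread: tuple[float, float] = (1.02, 1.5)   # uniform factor on depth
    asv_base_sigma: float = 1.5          # lognormal spread of the taxon pool
    dirichlet_log_conc: float = 4.0      # mean log total Dirichlet concentration
    dirichlet_conc_slope: float = 0.8    # response of log-concentration to latent
    plfa_total_mean: float = 30.0        # nmol/g, geometric mean total biomass
    plfa_total_sigma: float = 0.35
    bf_ratio_mean: float = 7.0
    bf_ratio_sigma: float = 0.30
    plfa_marker_noise: float = 0.10
    active_mean: float = 3.0             # ug C/g, geometric mean
    active_sigma: float = 0.35
    active_noise: float = 0.05
    n_genes_other: int = 12
    gene_base_sigma: float = 0.8
    gene_cata_slope: float = 0.5
    gene_spread0: float = 0.8
    gene_spread_slope: float = 0.4
    gene_noise: float = 0.10
    co2_mean: float = 1.5                # ug CO2-C / g / h, geometric mean
    co2_activity_slope: float = 0.15
    co2_spread0: float = 0.8
    co2_spread_slope: float = 0.45
    co2_range_slope: float = 0.35
    co2_noise: float = 0.10
    resp_mean: float = 2.0
    resp_scale: float = 0.4
    resp_noise: float = 0.05

    def soil_covariance(self) -> pd.DataFrame:
        cov = (
            DEFAULT_SOIL_CORRELATION
            if self.exogenous_covariance is None
            else self.exogenous_covariance
        )
        arr = np.asarray(cov, dtype=float)
        if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T):
            raise ValueError("exogenous covariance must be square symmetric")
        try:
            np.linalg.cholesky(arr)
        except np.linalg.LinAlgError:
            raise ValueError("exogenous covariance is not positive definite")
        if isinstance(cov, pd.DataFrame):
            return cov.astype(float)
        return pd.DataFrame(
            arr, index=structure.SOIL_VARIABLES, columns=structure.SOIL_VARIABLES
        )


# PLFA marker panel: marker -> group, group -> kingdom
MARKER_GROUPS = {
    "i15:0": "gram_positive", "a15:0": "gram_positive", "i16:0": "gram_positive",
    "i17:0": "gram_positive",
    "16:1w7": "gram_negative", "cy17:0": "gram_negative", "cy19:0": "gram_negative",
    "10Me16:0": "actinobacteria", "10Me18:0": "actinobacteria",
    "18:2w6,9": "saprotrophic_fungi", "18:1w9": "saprotrophic_fungi",
    "16:1w5": "arbuscular_mycorrhizal_fungi",
    "16:0": "general", "18:0": "general",
}
GROUP_KINGDOM = {
    "gram_positive": "bacteria", "gram_negative": "bacteria",
    "actinobacteria": "bacteria",
    "saprotrophic_fungi": "fungi", "arbuscular_mycorrhizal_fungi": "fungi",
    "general": "other",
}
#: relative weight of each marker within its group
MARKER_WEIGHTS = {
    "i15:0": 0.35, "a15:0": 0.30, "i16:0": 0.20, "i17:0": 0.15,
    "16:1w7": 0.45, "cy17:0": 0.30, "cy19:0": 0.25,
    "10Me16:0": 0.6, "10Me18:0": 0.4,
    "18:2w6,9": 0.6, "18:1w9": 0.4,
    "16:1w5": 1.0,
    "16:0": 0.6, "18:0": 0.4,
}
#: fraction of total biomass in the unclassified "general" pool
OTHER_FRACTION = 0.10

#: carbon-catabolism gene panel (flagged) plus other-cycle genes
CATABOLIC_GENES = [
    "amyA", "apu", "sga", "abfA", "xylA", "manB", "cex", "cbhI", "bglX",
    "naglu", "chiA", "pelA", "lig", "mnp", "glx", "pox", "cdh", "exg",
]
OTHER_GENES = [
    "amoA", "nirK", "nirS", "nosZ", "nifH", "ureC", "phoD", "phoN",
    "pqqC", "mcrA", "pmoA", "dsrA",
]

#: MicroResp substrate panel: name -> (class, molecular weight, C oxidation state)
SUBSTRATES = {
    "glucose": ("saccharide", 180.2, 0.0),
    "fructose": ("saccharide", 180.2, 0.0),
    "galactose": ("saccharide", 180.2, 0.0),
    "arabinose": ("saccharide", 150.1, 0.0),
    "n-acetyl-glucosamine": ("saccharide", 221.2, -0.5),
    ALANINE: ("amino-acid", 89.1, -2.0),
    "arginine": ("amino-acid", 174.2, -1.0),
    "asparagine": ("amino-acid", 132.1, 0.5),
    "cysteine": ("amino-acid", 121.2, -0.7),
    "gamma-aminobutyric acid": ("amino-acid", 103.1, -1.6),
    "malic acid": ("carboxylic-acid", 134.1, 1.0),
    "citric acid": ("carboxylic-acid", 192.1, 1.0),
    "ascorbic acid": ("carboxylic-acid", 176.1, 0.7),
    OXALIC: ("carboxylic-acid", 90.0, 3.0),
}
#: fixed substrate loadings for the community-profile spread term; the two
#: range substrates carry no loading so the profile-evenness and response-
#: range observation channels stay separable
SUBSTRATE_LOADINGS = {
    "glucose": 0.55, "fructose": 0.40, "galactose": 0.15, "arabinose": -0.10,
    "n-acetyl-glucosamine": -0.35, ALANINE: 0.0, "arginine": -0.55,
    "asparagine": 0.05, "cysteine": -0.70, "gamma-aminobutyric acid": -0.20,
    "malic acid": 0.35, "citric acid": 0.60, "ascorbic acid": -0.15,
    OXALIC: 0.0,
}

LATENT_FACETS = structure.FACET_VARIABLES


@dataclass
class SyntheticDataset:
    """Design, ground truth and the full observation battery."""

    design: pd.DataFrame
    soil: pd.DataFrame
    latents: pd.DataFrame
    asv_bacteria: pd.DataFrame
    asv_fungi: pd.DataFrame
    plfa: pd.DataFrame
    genes: pd.DataFrame
    microresp: pd.DataFrame
    respiration: pd.Series
    active_biomass: pd.Series
    marker_groups: dict = field(default_factory=lambda: dict(MARKER_GROUPS))
    group_kingdom: dict = field(default_factory=lambda: dict(GROUP_KINGDOM))
    catabolic_genes: list = field(default_factory=lambda: list(CATABOLIC_GENES))
    substrate_meta: pd.DataFrame | None = None
    params_used: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Stage 1: design
# ---------------------------------------------------------------------------

def generate_design(
    config: DesignConfig, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Sample -> plot -> tree-richness mapping.

    Richness levels are spread over plots as evenly as the level count
    allows; samples are allocated to plots evenly with the remainder going
    to randomly chosen plots.
    """
    config.validate()
    rng = _rng(rng, config.seed)
    levels = sorted(config.richness_levels)
    plot_richness = np.array(
        [levels[i % len(levels)] for i in range(config.n_plots)]
    )
    rng.shuffle(plot_richness)

    base = config.n_samples // config.n_plots
    counts = np.full(config.n_plots, base)
    extra = config.n_samples - base * config.n_plots
    if extra:
        counts[rng.choice(config.n_plots, size=extra, replace=False)] += 1

    rows = []
    k = 1
    for p in range(config.n_plots):
        for _ in range(counts[p]):
            rows.append(
                {
                    "sample": f"S{k:03d}",
                    "plot": f"P{p + 1:02d}",
                    "tree_richness": int(plot_richness[p]),
                }
            )
            k += 1
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# Stage 2: soil chemistry
# ---------------------------------------------------------------------------

def generate_soil_chemistry(
    design: pd.DataFrame,
    params: GeneratorParams,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Per-sample TOC, TN, TP, pH and humidity.

    Latents are multivariate normal with the configured covariance and are
    mapped affinely to observation scales; values are clipped to physical
    ranges, but the default scales make clipping vanishingly rare so the
    empirical covariance converges to the specification.
    """
    rng = _rng(rng)
    cov = params.soil_covariance()
    names = list(cov.columns)
    n = len(design)
    z = rng.multivariate_normal(
        np.zeros(len(names)), np.asarray(cov, dtype=float), size=n,
        method="cholesky",
    )
    out = {}
    for j, v in enumerate(names):
        raw = SOIL_MEANS[v] + SOIL_SCALES[v] * z[:, j]
        lo, hi = SOIL_BOUNDS[v]
        out[v] = np.clip(raw, lo, hi)
    return pd.DataFrame(out, index=design.index)


# ---------------------------------------------------------------------------
# Stage 3: latent facets
# ---------------------------------------------------------------------------

#: variables allowed as structural sources besides facets
_DRIVER_SOURCES = set(structure.DRIVERS)
_NOISE_FLOOR = 0.05


def generate_facets(
    design: pd.DataFrame,
    soil: pd.DataFrame,
    params: GeneratorParams,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Ground-truth latent facet table on standardized (unit-SD) scales.

    Each facet is the linear combination of its structural parents plus a
    Gaussian disturbance; disturbances of the seven exogenous facets are
    drawn jointly with the configured correlations. Unless overridden in
    ``params.noise_sd``, disturbance SDs are chosen so each facet has
    approximately unit variance. The returned table also carries the
    standardized driver columns (tree_richness, humidity, cp_ratio).
    """
    rng = _rng(rng)
    coeffs = dict(params.structural_coefficients)
    _validate_structure(coeffs)
    n = len(design)

    z = {}
    richness = design["tree_richness"].to_numpy(dtype=float)
    if params.log_tree_richness:
        richness = np.log(richness)
    z["tree_richness"] = _unit(richness)
    z["humidity"] = _unit(soil["humidity"].to_numpy(dtype=float))
    z["cp_ratio"] = _unit(
        soil["toc"].to_numpy(dtype=float) / soil["tp"].to_numpy(dtype=float)
    )

    # correlated standard-normal disturbances for the seven facet variables
    exo = structure.EXOGENOUS_FACETS
    C = np.eye(len(exo))
    for (a, b), r in params.facet_correlations.items():
        i, j = exo.index(a), exo.index(b)
        C[i, j] = C[j, i] = r
    try:
        np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        raise ValueError("facet correlation matrix is not positive definite")
    U = rng.multivariate_normal(np.zeros(len(exo)), C, size=n, method="cholesky")
    disturbances = {v: U[:, i] for i, v in enumerate(exo)}
    for v in structure.PHYSIOLOGY + [structure.RESPONSE]:
        disturbances[v] = rng.standard_normal(n)

    order = _topological_order(coeffs)
    for v in order:
        parents = [(s, b) for (s, t), b in coeffs.items() if t == v]
        pred = np.zeros(n)
        for s, b in parents:
            pred += b * z[s]
        if v in params.noise_sd:
            sd = float(params.noise_sd[v])
            if sd < 0:
                raise ValueError(f"noise_sd[{v!r}] must be non-negative")
        else:
            sd = float(np.sqrt(max(1.0 - np.var(pred), _NOISE_FLOOR**2)))
        z[v] = pred + sd * disturbances[v]

    cols = LATENT_FACETS + structure.DRIVERS
    return pd.DataFrame({c: z[c] for c in cols}, index=design.index)


def _validate_structure(coeffs: Mapping[tuple[str, str], float]) -> None:
    facet_set = set(LATENT_FACETS)
    for (s, t), _ in coeffs.items():
        if t not in facet_set:
            raise ValueError(f"structural target {t!r} is not a facet variable")
        if s not in facet_set and s not in _DRIVER_SOURCES:
            raise ValueError(
                f"structural source {s!r} must be a facet, tree richness or a "
                "soil variable"
            )
    # acyclicity over facet-facet edges
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(facet_set)
    g.add_edges_from([(s, t) for s, t in coeffs if s in facet_set])
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("structural graph over facets contains a cycle")


def _topological_order(coeffs) -> list[str]:
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(LATENT_FACETS)
    g.add_edges_from(
        [(s, t) for s, t in coeffs if s in set(LATENT_FACETS)]
    )
    return [v for v in nx.topological_sort(g)]


# ---------------------------------------------------------------------------
# Stage 4: observations
# ---------------------------------------------------------------------------

def generate_observations(
    latents: pd.DataFrame,
    params: GeneratorParams,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Observation battery consistent with the latent facet table.

    Returns a dict with keys asv_bacteria, asv_fungi, plfa, genes,
    microresp, respiration, active_biomass, substrate_meta.
    """
    rng = _rng(rng)
    samples = latents.index
    n = len(samples)

    asv_bac = _community(
        latents["bac_div"].to_numpy(), params.n_asv_bacteria,
        params.depth_bacteria, params, rng, prefix="bASV",
    )
    asv_fun = _community(
        latents["fun_div"].to_numpy(), params.n_asv_fungi,
        params.depth_fungi, params, rng, prefix="fASV",
    )
    asv_bac.columns = samples
    asv_fun.columns = samples

    plfa = _plfa_markers(latents, params, rng)
    plfa.columns = samples

    genes = _gene_table(latents, params, rng)
    genes.columns = samples

    microresp = _microresp(latents, params, rng)
    microresp.columns = samples

    resp = np.maximum(
        params.resp_mean
        + params.resp_scale * latents["respiration"].to_numpy()
        + params.resp_noise * rng.standard_normal(n),
        1e-6,
    )
    respiration = pd.Series(resp, index=samples, name="respiration")

    active = np.exp(
        np.log(params.active_mean)
        + params.active_sigma * latents["active_biomass"].to_numpy()
        + params.active_noise * rng.standard_normal(n)
    )
    active_biomass = pd.Series(active, index=samples, name="active_biomass")

    substrate_meta = pd.DataFrame(
        [
            {"substrate": s, "class": c, "molecular_weight": mw,
             "c_oxidation_state": ox}
            for s, (c, mw, ox) in SUBSTRATES.items()
        ]
    ).set_index("substrate")

    return {
        "asv_bacteria": asv_bac,
        "asv_fungi": asv_fun,
        "plfa": plfa,
        "genes": genes,
        "microresp": microresp,
        "respiration": respiration,
        "active_biomass": active_biomass,
        "substrate_meta": substrate_meta,
    }


def _community(latent, pool, depth, params, rng, prefix):
    """Dirichlet-multinomial counts with evenness tied to the latent."""
    n = len(latent)
    base = np.exp(params.asv_base_sigma * rng.standard_normal(pool))
    base /= base.sum()
    log_conc = params.dirichlet_log_conc + params.dirichlet_conc_slope * latent
    counts = np.empty((pool, n), dtype=np.int64)
    depths = np.round(
        depth * rng.uniform(*params.depth_spread, size=n)
    ).astype(np.int64)
    for i in range(n):
        conc = np.exp(log_conc[i])
        p = rng.dirichlet(np.maximum(conc * base, 1e-10))
        counts[:, i] = rng.multinomial(depths[i], p)
    return pd.DataFrame(counts, index=[f"{prefix}{k + 1:05d}" for k in range(pool)])


def _plfa_markers(latents, params, rng):
    n = len(latents)
    total = np.exp(
        np.log(params.plfa_total_mean)
        + params.plfa_total_sigma * latents["total_biomass"].to_numpy()
    )
    ratio = np.exp(
        np.log(params.bf_ratio_mean)
        + params.bf_ratio_sigma * latents["bf_ratio"].to_numpy()
    )
    pool = {
        "bacteria": (1 - OTHER_FRACTION) * total * ratio / (1 + ratio),
        "fungi": (1 - OTHER_FRACTION) * total / (1 + ratio),
        "other": OTHER_FRACTION * total,
    }
    # split kingdom pools over groups, then groups over weighted markers
    group_share = {}
    for kingdom in ("bacteria", "fungi", "other"):
        groups = [g for g, k in GROUP_KINGDOM.items() if k == kingdom]
        w = np.array([
            sum(MARKER_WEIGHTS[m] for m, g in MARKER_GROUPS.items() if g == grp)
            for grp in groups
        ], dtype=float)
        w /= w.sum()
        for grp, wi in zip(groups, w):
            group_share[grp] = pool[kingdom] * wi
    rows = {}
    for m, grp in MARKER_GROUPS.items():
        within = MARKER_WEIGHTS[m] / sum(
            MARKER_WEIGHTS[mm] for mm, gg in MARKER_GROUPS.items() if gg == grp
        )
        noise = np.exp(
            params.plfa_marker_noise * rng.standard_normal(n)
            - params.plfa_marker_noise**2 / 2
        )
        rows[m] = group_share[grp] * within * noise
    return pd.DataFrame(rows).T


def _gene_table(latents, params, rng):
    genes = CATABOLIC_GENES + OTHER_GENES[: params.n_genes_other]
    m = len(genes)
    n = len(latents)
    base = np.log(1e7) + params.gene_base_sigma * rng.standard_normal(m)
    dev = rng.standard_normal(m)
    dev -= dev.mean()
    cata = latents["cata_score"].to_numpy()
    fg = latents["fg_evenness"].to_numpy()
    spread = params.gene_spread0 * np.exp(-params.gene_spread_slope * fg)
    flags = np.array([g in set(CATABOLIC_GENES) for g in genes])
    log_a = (
        base[:, None]
        + params.gene_cata_slope * flags[:, None] * cata[None, :]
        + dev[:, None] * spread[None, :]
        + params.gene_noise * rng.standard_normal((m, n))
    )
    return pd.DataFrame(np.exp(log_a), index=genes)


def _microresp(latents, params, rng):
    subs = list(SUBSTRATES)
    v = np.array([SUBSTRATE_LOADINGS[s] for s in subs])
    w = np.array([1.0 if s == OXALIC else -1.0 if s == ALANINE else 0.0 for s in subs])
    n = len(latents)
    activity = (
        np.log(params.co2_mean)
        + params.co2_activity_slope * latents["active_biomass"].to_numpy()
    )
    spread = params.co2_spread0 * np.exp(
        -params.co2_spread_slope * latents["sir_efficiency"].to_numpy()
    )
    rng_term = params.co2_range_slope * latents["sir_range"].to_numpy()
    log_r = (
        activity[None, :]
        + v[:, None] * spread[None, :]
        + w[:, None] * rng_term[None, :]
        + params.co2_noise * rng.standard_normal((len(subs), n))
    )
    return pd.DataFrame(np.exp(log_r), index=subs)


# ---------------------------------------------------------------------------
# One-call generation and IO
# ---------------------------------------------------------------------------

def simulate_dataset(
    config: DesignConfig | None = None,
    params: GeneratorParams | None = None,
    seed: int | None = None,
) -> SyntheticDataset:
    """Generate a complete synthetic dataset (design through observations)."""
    config = config or DesignConfig()
    params = params or GeneratorParams()
    rng = _rng(None, seed if seed is not None else config.seed)
    design = generate_design(config, rng)
    soil = generate_soil_chemistry(design, params, rng)
    latents = generate_facets(design, soil, params, rng)
    obs = generate_observations(latents, params, rng)
    return SyntheticDataset(
        design=design,
        soil=soil,
        latents=latents,
        substrate_meta=obs["substrate_meta"],
        asv_bacteria=obs["asv_bacteria"],
        asv_fungi=obs["asv_fungi"],
        plfa=obs["plfa"],
        genes=obs["genes"],
        microresp=obs["microresp"],
        respiration=obs["respiration"],
        active_biomass=obs["active_biomass"],
        params_used=_params_record(config, params, seed),
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write the battery as TSV tables plus a JSON ground-truth sidecar."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    kw = {"sep": "\t", "float_format": "%.10g"}
    ds.design.to_csv(out / "design.tsv", **kw)
    ds.soil.to_csv(out / "soil.tsv", **kw)
    ds.asv_bacteria.rename_axis("asv").to_csv(out / "asv_bacteria.tsv", **kw)
    ds.asv_fungi.rename_axis("asv").to_csv(out / "asv_fungi.tsv", **kw)
    ds.plfa.rename_axis("marker").to_csv(out / "plfa.tsv", **kw)
    ds.genes.rename_axis("gene").to_csv(out / "genes.tsv", **kw)
    ds.microresp.rename_axis("substrate").to_csv(out / "microresp.tsv", **kw)
    pd.DataFrame(
        {"respiration": ds.respiration, "active_biomass": ds.active_biomass}
    ).rename_axis("sample").to_csv(out / "respiration.tsv", **kw)
    ds.substrate_meta.to_csv(out / "substrate_metadata.tsv", **kw)
    pd.Series(ds.marker_groups, name="group").rename_axis("marker").to_csv(
        out / "marker_groups.tsv", sep="\t"
    )
    pd.Series(ds.group_kingdom, name="kingdom").rename_axis("group").to_csv(
        out / "group_kingdoms.tsv", sep="\t"
    )
    (out / "catabolic_genes.txt").write_text("\n".join(ds.catabolic_genes) + "\n")
    sidecar = {
        "latents": {
            c: [round(float(x), 10) for x in ds.latents[c]] for c in ds.latents
        },
        "samples": list(ds.latents.index),
        "catabolic_genes": ds.catabolic_genes,
        "params": ds.params_used,
    }
    (out / "ground_truth.json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True)
    )


def write_biom(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a community matrix in BIOM format (requires ``biom-format``)."""
    from biom.table import Table
    from biom.util import biom_open

    table = Table(
        counts.to_numpy(), list(counts.index), list(counts.columns)
    )
    with biom_open(str(path), "w") as fh:
        table.to_hdf5(fh, "facet2function")


def _params_record(config, params, seed) -> dict:
    rec = {
        "design": asdict(config),
        "seed": seed,
        "structural_coefficients": {
            f"{s}->{t}": v for (s, t), v in params.structural_coefficients.items()
        },
        "facet_correlations": {
            f"{a}~~{b}": v for (a, b), v in params.facet_correlations.items()
        },
        "log_tree_richness": params.log_tree_richness,
    }
    rec["design"]["richness_levels"] = list(config.richness_levels)
    return rec


def _unit(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if not sd > 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _rng(rng, seed=None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is not None:
        return np.random.default_rng(rng)
    return np.random.default_rng(seed)
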