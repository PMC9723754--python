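"""End-to-end analysis pipeline.

Runs simulate (or ingest) -> facet indices -> tree-richness effect models
-> facet correlations -> stepwise function models with variance
partitioning -> path models with effect decomposition, writing every stage
as machine-readable TSV/JSON into a report bundle. Identical seeds give
byte-identical bundles; a frozen copy of the resolved configuration is
written alongside the outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import structure
from .effects import LinearEffectModel, compare_functional_forms, StepwiseSelector
from .indices import compute_facets
from .sem import PathModel, decompose_effects, fit_indices, group_effect_summary
from .simulate import DesignConfig, GeneratorParams, simulate_dataset, write_dataset
from .standardize import TwoSDScaler
from .varpart import VariancePartitioner

logger = logging.getLogger(__name__)

_TSV = {"sep": "\t", "float_format": "%.10g"}

#: predictor groups for the function models and variance partitioning
FACET_GROUPS = {
    "biomass": ["total_biomass", "active_biomass"],
    "taxonomic_profile": ["bf_ratio", "bac_div", "fun_div"],
    "functional_profile": ["cata_score", "fg_evenness"],
}
FUNCTION_RESPONSES = ["sir_efficiency", "sir_range", "respiration"]

REQUIRED_INPUTS = [
    "design", "soil", "asv_bacteria", "asv_fungi", "plfa", "marker_groups",
    "group_kingdoms", "genes", "catabolic_genes", "microresp", "respiration",
]


@dataclass
class RunConfig:
    """Resolved configuration of a full analysis run."""

    mode: str = "synthetic"              # synthetic | files
    seed: int = 0
    outdir: str = "f2f_run"
    n_plots: int = 52
    n_samples: int = 150
    richness_levels: tuple[int, ...] = (1, 2, 4, 8, 16, 24)
    rarefy_depth_bacteria: int = 28897
    rarefy_depth_fungi: int = 16542
    gene_scaling: str = "minmax"
    alpha: float = 0.05
    with_active_biomass: bool = True     # robustness flag: False drops the column
    inputs: dict = field(default_factory=dict)   # files mode: name -> path
    stages: dict = field(default_factory=dict)   # stage -> bool toggles

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        if "richness_levels" in raw:
            cfg.richness_levels = tuple(raw["richness_levels"])
        return cfg

    def stage_enabled(self, name: str) -> bool:
        return bool(self.stages.get(name, True))


def run_full_analysis(config: RunConfig) -> Path:
    """Run every stage and return the report-bundle directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    frozen = dict(asdict(config))
    frozen["richness_levels"] = list(config.richness_levels)
    (out / "config.yaml").write_text(yaml.safe_dump(frozen, sort_keys=True))

    summary: list[str] = ["full analysis report", "====================", ""]

    # --- stage: data -------------------------------------------------------
    if config.mode == "synthetic":
        design_cfg = DesignConfig(
            n_plots=config.n_plots,
            n_samples=config.n_samples,
            richness_levels=tuple(config.richness_levels),
        )
        ds = simulate_dataset(design_cfg, GeneratorParams(), seed=config.seed)
        write_dataset(ds, out / "data")
        tables = {
            "design": ds.design, "soil": ds.soil,
            "asv_bacteria": ds.asv_bacteria, "asv_fungi": ds.asv_fungi,
            "plfa": ds.plfa, "genes": ds.genes, "microresp": ds.microresp,
            "respiration": ds.respiration, "active_biomass": ds.active_biomass,
        }
        marker_groups = ds.marker_groups
        group_kingdom = ds.group_kingdom
        catabolic = ds.catabolic_genes
        summary.append(
            f"synthetic dataset: {len(ds.design)} samples, "
            f"{ds.design['plot'].nunique()} plots, seed {config.seed}"
        )
    elif config.mode == "files":
        tables, marker_groups, group_kingdom, catabolic = _read_inputs(config)
        summary.append(f"file inputs: {len(tables['design'])} samples")
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    # --- stage: facet indices ---------------------------------------------
    facets = compute_facets(
        asv_bacteria=tables["asv_bacteria"],
        asv_fungi=tables["asv_fungi"],
        plfa=tables["plfa"],
        marker_groups=marker_groups,
        group_kingdom=group_kingdom,
        genes=tables["genes"],
        catabolic=catabolic,
        microresp=tables["microresp"],
        respiration=tables["respiration"],
        active_biomass=tables["active_biomass"],
        soil=tables["soil"],
        rarefy_depth_bacteria=config.rarefy_depth_bacteria,
        rarefy_depth_fungi=config.rarefy_depth_fungi,
        gene_scaling=config.gene_scaling,
        seed=config.seed,
    )
    if not config.with_active_biomass:
        facets = facets.drop(columns=["active_biomass"])
    facets.to_csv(out / "facets.tsv", **_TSV)
    summary.append(f"facet table: {facets.shape[0]} samples x {facets.shape[1]} indices")

    facet_cols = [c for c in structure.FACET_VARIABLES if c in facets.columns]
    richness = tables["design"]["tree_richness"].astype(float)

    # --- stage: tree-richness effects -------------------------------------
    if config.stage_enabled("tree_effects"):
        rows = []
        for facet in facet_cols:
            y = facets[facet]
            mask = y.notna()
            fit = LinearEffectModel().fit(
                pd.DataFrame({"tree_richness": richness[mask]}), y[mask]
            ).result_
            forms = compare_functional_forms(y[mask], richness[mask])
            rows.append(
                {
                    "facet": facet,
                    "estimate": fit.estimates["tree_richness"],
                    "se": fit.se["tree_richness"],
                    "p_value": fit.pvalues["tree_richness"],
                    "r2": fit.r2,
                    "chosen_form": forms.chosen,
                    "delta_aic_linear": forms.delta_aic["linear"],
                }
            )
        tree_effects = pd.DataFrame(rows).set_index("facet")
        tree_effects.to_csv(out / "tree_effects.tsv", **_TSV)
        sig = tree_effects[tree_effects.p_value < config.alpha].index.tolist()
        summary.append(f"tree-richness effects significant at {config.alpha}: {sig}")

    # --- stage: facet correlations ----------------------------------------
    if config.stage_enabled("correlations"):
        profile_cols = [
            c for c in FACET_GROUPS["biomass"] + FACET_GROUPS["taxonomic_profile"]
            + FACET_GROUPS["functional_profile"] if c in facets.columns
        ]
        r, p = correlation_matrix(facets[profile_cols])
        r.to_csv(out / "facet_correlations.tsv", **_TSV)
        p.to_csv(out / "facet_correlation_pvalues.tsv", **_TSV)

    # --- stage: function models + variance partitioning --------------------
    if config.stage_enabled("function_models"):
        fm_rows, vp_rows = [], []
        groups = {
            g: [c for c in cols if c in facets.columns]
            for g, cols in FACET_GROUPS.items()
        }
        predictors = [c for cols in groups.values() for c in cols]
        for response in FUNCTION_RESPONSES:
            sub = facets[predictors + [response]].dropna()
            sel = StepwiseSelector().fit(sub[predictors], sub[response])
            for term in sel.result_.estimates.index:
                if term == "const":
                    continue
                fm_rows.append(
                    {
                        "response": response,
                        "term": term,
                        "estimate": sel.result_.estimates[term],
                        "se": sel.result_.se[term],
                        "p_value": sel.result_.pvalues[term],
                        "adj_r2": sel.result_.adj_r2,
                    }
                )
            sel_groups = {
                g: [c for c in cols if c in sel.selected_]
                for g, cols in groups.items()
            }
            vp = VariancePartitioner(groups=sel_groups).fit(
                sub[sel.selected_] if sel.selected_ else sub[predictors],
                sub[response],
            )
            fr = vp.result_.fractions()
            fr.name = "fraction"
            fr = fr.rename_axis("component").reset_index()
            fr.insert(0, "response", response)
            vp_rows.append(fr)
        pd.DataFrame(fm_rows).to_csv(out / "function_models.tsv", index=False, **_TSV)
        pd.concat(vp_rows).to_csv(out / "varpart.tsv", index=False, **_TSV)

    # --- stage: path models -----------------------------------------------
    if config.stage_enabled("sem"):
        frame = facets[facet_cols].copy()
        frame["tree_richness"] = richness
        frame["humidity"] = tables["soil"]["humidity"]
        if "cp_ratio" not in frame.columns and "cp_ratio" in facets.columns:
            frame["cp_ratio"] = facets["cp_ratio"]
        sem_dir = out / "sem"
        sem_dir.mkdir(exist_ok=True)
        for label, text in (
            ("cascade", _model_text("cascade", config.with_active_biomass)),
            ("drivers", _model_text("drivers", config.with_active_biomass)),
        ):
            (sem_dir / f"{label}.model").write_text(text + "\n")
            model = PathModel(spec=text)
            cols = [v for v in model_variables(text) if v in frame.columns]
            data = frame[cols].dropna()
            scaled = pd.DataFrame(
                TwoSDScaler().fit_transform(data), index=data.index,
                columns=data.columns,
            )
            fit = model.fit(scaled).fit_
            fit.params.to_csv(sem_dir / f"{label}_paths.tsv", index=False, **_TSV)
            indices_ = fit_indices(fit)
            (sem_dir / f"{label}_fit.json").write_text(
                json.dumps(_jsonable(indices_ | {
                    "n": fit.n, "r2": fit.r2.round(6).to_dict()
                }), indent=1, sort_keys=True)
            )
            dec = decompose_effects(fit, alpha=config.alpha)
            dec.table.to_csv(sem_dir / f"{label}_effects.tsv", index=False, **_TSV)
            gs = group_effect_summary(dec, targets=["respiration"])
            gs.table.to_csv(
                sem_dir / f"{label}_group_effects.tsv", index=False, **_TSV
            )
            summary.append(
                f"SEM {label}: chi2={fit.chi2:.3f} df={fit.df} "
                f"RMSEA={fit.rmsea:.3f} CFI={fit.cfi:.3f} SRMR={fit.srmr:.3f} "
                f"acceptable={indices_['acceptable']}"
            )

    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    return out


def correlation_matrix(facets: pd.DataFrame):
    """Pairwise Pearson correlations with p-values.

    Uses pairwise-complete observations; cells with fewer than 3 complete
    pairs or a constant column are missing (logged).
    """
    cols = list(facets.columns)
    r = pd.DataFrame(np.nan, index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, a in enumerate(cols):
        r.loc[a, a], p.loc[a, a] = 1.0, 0.0
        for b in cols[i + 1:]:
            pair = facets[[a, b]].dropna()
            if len(pair) < 3:
                logger.warning("correlation %s~%s: fewer than 3 complete pairs", a, b)
                continue
            x, y = pair[a].to_numpy(), pair[b].to_numpy()
            if x.std() == 0 or y.std() == 0:
                logger.warning("correlation %s~%s: constant column", a, b)
                continue
            rr, pp = stats.pearsonr(x, y)
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    return r.rename_axis("facet"), p.rename_axis("facet")


def model_variables(text: str) -> list[str]:
    from .sem import parse_model

    return list(parse_model(text).variables)


def _model_text(which: str, with_active: bool) -> str:
    text = (
        structure.cascade_model_text()
        if which == "cascade"
        else structure.driver_model_text()
    )
    if with_active:
        return text
    lines = []
    for line in text.splitlines():
        if line.startswith("active_biomass ~") and "~~" not in line:
            continue
        if "~~" in line and "active_biomass" in line:
            continue
        if "~" in line and "~~" not in line:
            lhs, rhs = line.split("~", 1)
            terms = [t.strip() for t in rhs.split("+") if t.strip() != "active_biomass"]
            if not terms:
                continue
            line = f"{lhs.strip()} ~ " + " + ".join(terms)
        if line.startswith("group:"):
            line = " ".join(t for t in line.split() if t != "active_biomass")
        lines.append(line)
    return "\n".join(lines)


def _read_inputs(config: RunConfig):
    missing = [k for k in REQUIRED_INPUTS if k not in config.inputs]
    if missing:
        raise FileNotFoundError(f"files mode is missing input table(s): {missing}")
    paths = {k: Path(v) for k, v in config.inputs.items()}
    absent = [f"{k} ({v})" for k, v in paths.items() if not v.exists()]
    if absent:
        raise FileNotFoundError(f"input file(s) not found: {absent}")

    def tsv(name, index_col=0):
        return pd.read_csv(paths[name], sep="\t", index_col=index_col)

    tables = {
        "design": tsv("design"),
        "soil": tsv("soil"),
        "asv_bacteria": tsv("asv_bacteria"),
        "asv_fungi": tsv("asv_fungi"),
        "plfa": tsv("plfa"),
        "genes": tsv("genes"),
        "microresp": tsv("microresp"),
    }
    resp = tsv("respiration")
    tables["respiration"] = resp["respiration"]
    if "active_biomass" in config.inputs:
        tables["active_biomass"] = tsv("active_biomass").iloc[:, 0]
    else:
        tables["active_biomass"] = resp["active_biomass"]
    marker_groups = tsv("marker_groups")["group"].to_dict()
    group_kingdom = tsv("group_kingdoms")["kingdom"].to_dict()
    catabolic = [
        line.strip()
        for line in Path(paths["catabolic_genes"]).read_text().splitlines()
        if line.strip()
    ]
    return tables, marker_groups, group_kingdom, catabolic


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj
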