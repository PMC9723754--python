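"""Canonical structure of the tree-diversity / soil-microbiome study.

Variable names, facet groupings and the published standardized path
coefficients that serve both as generator defaults and as the worked
example for effect decomposition. Two model layouts are provided:

* the *facet cascade* model — microbial biomass, taxonomic and functional
  profiles (treated as correlated exogenous facets) drive physiological
  potential (SIR efficiency / SIR range), which in turn drives microbial
  respiration;
* the *driver* model — the cascade extended with tree species richness and
  soil-chemistry drivers (soil humidity, C:P ratio) acting on the facets
  and functions.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Variables and groups
# ---------------------------------------------------------------------------

BIOMASS_FACETS = ["total_biomass", "active_biomass"]
TAXONOMIC_FACETS = ["bf_ratio", "bac_div", "fun_div"]
FUNCTIONAL_FACETS = ["cata_score", "fg_evenness"]
EXOGENOUS_FACETS = BIOMASS_FACETS + TAXONOMIC_FACETS + FUNCTIONAL_FACETS
PHYSIOLOGY = ["sir_efficiency", "sir_range"]
RESPONSE = "respiration"
FACET_VARIABLES = EXOGENOUS_FACETS + PHYSIOLOGY + [RESPONSE]

DRIVERS = ["tree_richness", "humidity", "cp_ratio"]
SOIL_VARIABLES = ["toc", "tn", "tp", "ph", "humidity"]

GROUPS = {
    "biomass": BIOMASS_FACETS,
    "taxonomic_profile": TAXONOMIC_FACETS,
    "functional_profile": FUNCTIONAL_FACETS,
    "physiological_potential": PHYSIOLOGY,
    "respiration": [RESPONSE],
    "tree_diversity": ["tree_richness"],
    "soil_chemistry": ["humidity", "cp_ratio"],
}

#: group label per variable (inverse of GROUPS)
GROUP_OF = {v: g for g, vs in GROUPS.items() for v in vs}

# ---------------------------------------------------------------------------
# Published standardized path coefficients (defaults for the generator and
# inputs to the worked effect-arithmetic example)
# ---------------------------------------------------------------------------

#: facet cascade: (source, target) -> standardized coefficient
CASCADE_COEFFICIENTS = {
    ("total_biomass", "sir_efficiency"): 0.209,
    ("active_biomass", "sir_efficiency"): 0.258,
    ("fg_evenness", "sir_efficiency"): -0.179,
    ("active_biomass", "respiration"): 0.590,
    ("fun_div", "respiration"): 0.128,
    ("sir_efficiency", "respiration"): 0.176,
    ("sir_range", "respiration"): 0.213,
}

#: additional driver paths in the extended model
DRIVER_COEFFICIENTS = {
    ("tree_richness", "total_biomass"): 0.173,
    ("tree_richness", "bac_div"): 0.164,
    ("tree_richness", "sir_efficiency"): 0.152,
    ("humidity", "respiration"): 0.312,
    ("humidity", "total_biomass"): -0.234,
    ("cp_ratio", "sir_range"): 0.269,
}

FULL_COEFFICIENTS = {**CASCADE_COEFFICIENTS, **DRIVER_COEFFICIENTS}

#: reported Pearson correlations between exogenous facets; pairs the study
#: reports only qualitatively (B:F negatively related to biomass and fungal
#: diversity) carry a modest default of -0.25
FACET_CORRELATIONS = {
    ("total_biomass", "active_biomass"): 0.45,
    ("cata_score", "fg_evenness"): 0.57,
    ("active_biomass", "fun_div"): 0.20,
    ("total_biomass", "bf_ratio"): -0.25,
    ("fun_div", "bf_ratio"): -0.25,
}


def cascade_model_text() -> str:
    """Model declaration for the facet cascade (no external drivers).

    All seven facets are exogenous with free covariances; both physiology
    indices receive paths from every facet; respiration receives paths from
    every facet plus both physiology indices.
    """
    lines = [
        "sir_efficiency ~ " + " + ".join(EXOGENOUS_FACETS),
        "sir_range ~ " + " + ".join(EXOGENOUS_FACETS),
        "respiration ~ " + " + ".join(EXOGENOUS_FACETS + PHYSIOLOGY),
    ]
    for i, a in enumerate(EXOGENOUS_FACETS):
        for b in EXOGENOUS_FACETS[i + 1 :]:
            lines.append(f"{a} ~~ {b}")
    lines.append(_group_block())
    return "\n".join(lines)


def driver_model_text() -> str:
    """Model declaration for the extended model with external drivers."""
    lines = [f"{f} ~ " + " + ".join(DRIVERS) for f in EXOGENOUS_FACETS]
    lines += [
        "sir_efficiency ~ " + " + ".join(EXOGENOUS_FACETS + DRIVERS),
        "sir_range ~ " + " + ".join(EXOGENOUS_FACETS + DRIVERS),
        "respiration ~ " + " + ".join(EXOGENOUS_FACETS + PHYSIOLOGY + DRIVERS),
    ]
    for i, a in enumerate(EXOGENOUS_FACETS):
        for b in EXOGENOUS_FACETS[i + 1 :]:
            lines.append(f"{a} ~~ {b}")
    for i, a in enumerate(DRIVERS):
        for b in DRIVERS[i + 1 :]:
            lines.append(f"{a} ~~ {b}")
    lines.append(_group_block())
    return "\n".join(lines)


def _group_block() -> str:
    out = []
    for g, vs in GROUPS.items():
        members = [v for v in vs]
        out.append(f"group: {g} = " + " ".join(members))
    return "\n".join(out)
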