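"""Microbial facet indices computed from raw measurement tables.

Table conventions
-----------------
Community matrices (ASV tables), PLFA marker tables, gene-abundance tables
and substrate-respiration (MicroResp CO2) matrices are pandas DataFrames
with *features as rows* (taxa / markers / genes / substrates) and *samples
as columns*. All derived per-sample indices come back indexed by sample.

Indices
-------
* richness S, Shannon H (natural log), Pielou J = H/ln S, Simpson
  dominance G = sum p_i^2 on rarefied ASV tables;
* total microbial biomass and bacteria:fungi ratio from PLFA marker sums;
* carbon-catabolism gene score ("Cata", sum of per-gene scaled abundances)
  and functional-gene evenness (Pielou J of the raw gene vector);
* SIR efficiency (Pielou J of the 14-substrate CO2 profile) and SIR range
  (CO2 difference oxalic acid minus alanine);
* soil C:N and C:P ratios.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

OXALIC = "oxalic acid"
ALANINE = "alanine"


# ---------------------------------------------------------------------------
# Evenness / diversity primitives
# ---------------------------------------------------------------------------

def shannon(x) -> float:
    """Shannon entropy H = -sum p ln p over the positive entries of ``x``."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative abundances")
    total = arr.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def pielou(x) -> float:
    """Pielou evenness J = H / ln S; defined as 0 for a single class.

    The one-class case is the 0/0 limit (H = 0, ln S = 0) and is pinned to
    0 so that a one-hot vector scores 0 and a uniform vector scores 1.
    """
    arr = np.asarray(x, dtype=float)
    pos = arr[arr > 0]
    s = int(pos.size)
    if s <= 1:
        return 0.0
    if np.all(pos == pos[0]):
        return 1.0  # uniform vector is exactly even
    return shannon(arr) / np.log(s)


def diversity_indices(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness, Shannon, Pielou and Simpson-dominance indices.

    Parameters
    ----------
    counts : DataFrame, taxa x samples, non-negative.

    Returns
    -------
    DataFrame indexed by sample with columns ``S`` (richness), ``H``
    (Shannon, natural log), ``J`` (Pielou evenness) and ``G`` (dominance,
    computed as the Simpson concentration sum p_i^2).
    """
    _check_counts(counts)
    out = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy(dtype=float)
        total = col.sum()
        if total <= 0:
            raise ValueError(f"sample {sample!r} has zero total count")
        p = col[col > 0] / total
        h = float(-(p * np.log(p)).sum())
        s = int(p.size)
        out[sample] = {
            "S": s,
            "H": h,
            "J": 0.0 if s == 1 else h / np.log(s),
            "G": float((p**2).sum()),
        }
    return pd.DataFrame.from_dict(out, orient="index").rename_axis("sample")


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefy(
    counts: pd.DataFrame,
    depth: int,
    seed: int | np.random.Generator | None = None,
    on_small: str = "drop",
) -> pd.DataFrame:
    """Subsample each sample to ``depth`` reads without replacement.

    Each retained column sums exactly to ``depth``; the draw is
    multivariate-hypergeometric, i.e. reads are removed without
    replacement, so the expected retained count of a taxon is
    ``depth * count / total``.

    Parameters
    ----------
    counts : DataFrame, taxa x samples, non-negative integers.
    depth : int
        Target reads per sample; must be positive.
    seed : int, Generator or None
        Randomness source; fixed seed gives identical output.
    on_small : {"drop", "error"}
        Samples whose total is below ``depth`` are dropped with a warning
        (default) or raise.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be a positive integer")
    if on_small not in ("drop", "error"):
        raise ValueError("on_small must be 'drop' or 'error'")
    _check_counts(counts)
    rng = np.random.default_rng(seed)
    mat = counts.to_numpy()
    if not np.issubdtype(mat.dtype, np.integer):
        if not np.allclose(mat, np.round(mat)):
            raise ValueError("community matrix must hold integer counts")
        mat = np.round(mat).astype(np.int64)
    totals = mat.sum(axis=0)
    small = totals < depth
    if small.any():
        names = list(counts.columns[small])
        if on_small == "error":
            raise ValueError(f"samples below rarefaction depth {depth}: {names}")
        logger.warning(
            "dropping %d sample(s) below rarefaction depth %d: %s",
            len(names), depth, names,
        )
    kept = counts.columns[~small]
    out = np.empty((mat.shape[0], len(kept)), dtype=np.int64)
    for j, sample in enumerate(kept):
        col = mat[:, counts.columns.get_loc(sample)]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return pd.DataFrame(out, index=counts.index, columns=kept)


# ---------------------------------------------------------------------------
# PLFA biomass
# ---------------------------------------------------------------------------

def biomass_summary(
    plfa: pd.DataFrame,
    marker_groups: Mapping[str, str],
    group_kingdom: Mapping[str, str],
) -> pd.DataFrame:
    """Total microbial biomass and bacteria:fungi ratio from PLFA markers.

    Parameters
    ----------
    plfa : DataFrame, markers x samples, biomass in nmol per g dry soil.
    marker_groups : mapping marker -> microbial group.
    group_kingdom : mapping group -> {"bacteria", "fungi", "other"}.

    Returns
    -------
    DataFrame with columns ``total_biomass`` (sum over all groups) and
    ``bf_ratio`` (bacterial sum over fungal sum; missing where the fungal
    sum is zero).
    """
    if (plfa.to_numpy(dtype=float) < 0).any():
        raise ValueError("negative PLFA biomass")
    missing = [m for m in plfa.index if m not in marker_groups]
    if missing:
        raise ValueError(f"markers without group assignment: {missing}")
    kingdom = pd.Series(
        {m: group_kingdom[marker_groups[m]] for m in plfa.index}, name="kingdom"
    )
    total = plfa.sum(axis=0)
    bac = plfa.loc[kingdom == "bacteria"].sum(axis=0)
    fun = plfa.loc[kingdom == "fungi"].sum(axis=0)
    bf = bac / fun.where(fun > 0)
    n_missing = int(bf.isna().sum())
    if n_missing:
        logger.warning("B:F undefined (zero fungal biomass) in %d sample(s)", n_missing)
    return pd.DataFrame({"total_biomass": total, "bf_ratio": bf}).rename_axis("sample")


# ---------------------------------------------------------------------------
# Functional genes
# ---------------------------------------------------------------------------

def gene_scores(
    genes: pd.DataFrame,
    catabolic: Sequence[str],
    scaling: str = "minmax",
) -> pd.DataFrame:
    """Carbon-catabolism gene score and functional-gene evenness.

    Each gene row is scaled *across samples* (min-max to [0, 1] by default,
    z-score as an alternative); the Cata score is the per-sample sum of the
    scaled abundances of the catabolism-flagged genes. FG evenness is the
    Pielou evenness of the sample's raw gene-abundance vector and does not
    depend on the scaling choice.
    """
    if scaling not in ("minmax", "zscore"):
        raise ValueError("scaling must be 'minmax' or 'zscore'")
    if genes.shape[1] < 2:
        raise ValueError("gene scaling is across samples; need at least 2 samples")
    if (genes.to_numpy(dtype=float) < 0).any():
        raise ValueError("negative gene abundances")
    unknown = [g for g in catabolic if g not in genes.index]
    if unknown:
        raise ValueError(f"catabolic genes absent from table: {unknown}")

    if scaling == "minmax":
        lo = genes.min(axis=1)
        span = genes.max(axis=1) - lo
        flat = span <= 0
        if flat.any():
            logger.warning(
                "constant gene row(s) scaled to 0 under minmax: %s",
                list(genes.index[flat]),
            )
        scaled = genes.sub(lo, axis=0).div(span.where(~flat, 1.0), axis=0)
        scaled.loc[flat] = 0.0
    else:
        mu = genes.mean(axis=1)
        sd = genes.std(axis=1, ddof=1)
        flat = sd <= 0
        if flat.any():
            logger.warning(
                "constant gene row(s) scaled to 0 under zscore: %s",
                list(genes.index[flat]),
            )
        scaled = genes.sub(mu, axis=0).div(sd.where(~flat, 1.0), axis=0)
        scaled.loc[flat] = 0.0

    cata = scaled.loc[list(catabolic)].sum(axis=0)
    evenness = pd.Series(
        {
            s: (pielou(genes[s].to_numpy()) if genes[s].sum() > 0 else np.nan)
            for s in genes.columns
        }
    )
    if evenness.isna().any():
        logger.warning(
            "FG evenness missing for sample(s) with zero gene totals: %s",
            list(evenness.index[evenness.isna()]),
        )
    return pd.DataFrame(
        {"cata_score": cata, "fg_evenness": evenness}
    ).rename_axis("sample")


# ---------------------------------------------------------------------------
# MicroResp physiological potential
# ---------------------------------------------------------------------------

def sir_efficiency(resp: pd.DataFrame) -> pd.Series:
    """SIR efficiency: Pielou evenness of the per-sample CO2 profile.

    A sample whose total CO2 production is zero has no defined evenness and
    comes back missing.
    """
    if (resp.to_numpy(dtype=float) < 0).any():
        raise ValueError("negative CO2 production")
    out = {}
    for s in resp.columns:
        v = resp[s].to_numpy(dtype=float)
        out[s] = pielou(v) if v.sum() > 0 else np.nan
    return pd.Series(out, name="sir_efficiency").rename_axis("sample")


def sir_range(
    resp: pd.DataFrame, upper: str = OXALIC, lower: str = ALANINE
) -> pd.Series:
    """SIR response range: signed CO2 difference ``upper`` minus ``lower``.

    The defaults are oxalic acid and alanine, the substrates at the upper
    and lower extremes of carbon oxidation state.
    """
    for name in (upper, lower):
        if name not in resp.index:
            raise KeyError(f"substrate {name!r} not present in respiration matrix")
    out = resp.loc[upper] - resp.loc[lower]
    out.name = "sir_range"
    return out.rename_axis("sample")


def substrate_sensitivity(
    resp: pd.DataFrame,
    scheme: str = "leave-one-out",
    substrate_class: Mapping[str, str] | None = None,
    k: int | None = None,
    reps: int = 100,
    seed: int | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Sensitivity of the SIR indices to substrate selection.

    For each substrate subset, SIR efficiency (and, when both range
    substrates survive, SIR range) is recomputed and correlated across
    samples with the full-panel index.

    Parameters
    ----------
    scheme : {"leave-one-out", "class-balanced", "random"}
        leave-one-out drops one substrate at a time; class-balanced drops
        one substrate per chemical class at a time (requires
        ``substrate_class``); random draws ``reps`` subsets of size ``k``.
    method : {"pearson", "spearman"}

    Returns
    -------
    DataFrame with one row per subset: the dropped/kept substrates and the
    correlation of each recomputed index with its full-panel value.
    """
    subs = list(resp.index)
    if len(subs) < 2:
        raise ValueError("need at least 2 substrates")
    full_eff = sir_efficiency(resp)
    full_rng = (
        sir_range(resp) if OXALIC in resp.index and ALANINE in resp.index else None
    )

    if scheme == "leave-one-out":
        subsets = [(f"drop:{s}", [t for t in subs if t != s]) for s in subs]
    elif scheme == "class-balanced":
        if substrate_class is None:
            raise ValueError("class-balanced scheme requires substrate_class map")
        classes = sorted(set(substrate_class[s] for s in subs))
        combos = itertools.product(
            *[[s for s in subs if substrate_class[s] == c] for c in classes]
        )
        subsets = [
            ("drop:" + "+".join(drop), [t for t in subs if t not in drop])
            for drop in combos
        ]
    elif scheme == "random":
        if k is None or k < 2:
            raise ValueError("random scheme requires subset size k >= 2")
        rng = np.random.default_rng(seed)
        subsets = []
        for r in range(reps):
            keep = sorted(rng.choice(len(subs), size=k, replace=False))
            subsets.append((f"rep:{r}", [subs[i] for i in keep]))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    corr = {"pearson": stats.pearsonr, "spearman": stats.spearmanr}[method]
    rows = []
    for label, keep in subsets:
        if len(keep) < 2:
            raise ValueError("subset must retain at least 2 substrates")
        sub = resp.loc[keep]
        eff = sir_efficiency(sub)
        row = {
            "subset": label,
            "n_substrates": len(keep),
            "r_sir_efficiency": _safe_corr(corr, full_eff, eff),
        }
        if full_rng is not None and OXALIC in keep and ALANINE in keep:
            row["r_sir_range"] = _safe_corr(corr, full_rng, sir_range(sub))
        else:
            row["r_sir_range"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _safe_corr(corr, a: pd.Series, b: pd.Series) -> float:
    mask = a.notna() & b.notna()
    x, y = a[mask].to_numpy(), b[mask].to_numpy()
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        # identical profiles after subsetting: correlation degenerates
        return 1.0 if np.allclose(x - x.mean(), y - y.mean()) else np.nan
    return float(corr(x, y)[0])


# ---------------------------------------------------------------------------
# Soil stoichiometry
# ---------------------------------------------------------------------------

def soil_stoichiometry(toc, tn, tp) -> pd.DataFrame:
    """Elementwise C:N = TOC/TN and C:P = TOC/TP ratios.

    Zero or negative denominators give missing values (logged), never
    infinities.
    """
    toc = pd.Series(np.asarray(toc, dtype=float)) if not isinstance(toc, pd.Series) else toc
    tn = pd.Series(np.asarray(tn, dtype=float), index=toc.index) if not isinstance(tn, pd.Series) else tn
    tp = pd.Series(np.asarray(tp, dtype=float), index=toc.index) if not isinstance(tp, pd.Series) else tp
    cn = toc / tn.where(tn > 0)
    cp = toc / tp.where(tp > 0)
    n_bad = int(cn.isna().sum() + cp.isna().sum())
    if n_bad:
        logger.warning("non-positive TN/TP denominators in %d cell(s)", n_bad)
    return pd.DataFrame({"cn_ratio": cn, "cp_ratio": cp}).rename_axis("sample")


# ---------------------------------------------------------------------------
# Facet-table assembly
# ---------------------------------------------------------------------------

def compute_facets(
    *,
    asv_bacteria: pd.DataFrame,
    asv_fungi: pd.DataFrame,
    plfa: pd.DataFrame,
    marker_groups: Mapping[str, str],
    group_kingdom: Mapping[str, str],
    genes: pd.DataFrame,
    catabolic: Sequence[str],
    microresp: pd.DataFrame,
    respiration: pd.Series,
    active_biomass: pd.Series,
    soil: pd.DataFrame | None = None,
    rarefy_depth_bacteria: int | None = 28897,
    rarefy_depth_fungi: int | None = 16542,
    gene_scaling: str = "minmax",
    active_biomass_multiplier: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Assemble the per-sample facet table from the measurement battery.

    Bacterial and fungal ASV tables are rarefied (defaults 28,897 and
    16,542 reads) before Shannon diversity is computed; samples lost to
    rarefaction carry missing diversity values. Active biomass is taken as
    a measured column, optionally scaled by a fixed conversion multiplier.
    When ``soil`` (columns toc, tn, tp) is given, C:N and C:P are appended.
    """
    rng = np.random.default_rng(seed)
    parts = []

    bm = biomass_summary(plfa, marker_groups, group_kingdom)
    parts.append(bm)
    parts.append((active_biomass_multiplier * active_biomass).rename("active_biomass"))

    bac = rarefy(asv_bacteria, rarefy_depth_bacteria, rng) if rarefy_depth_bacteria else asv_bacteria
    fun = rarefy(asv_fungi, rarefy_depth_fungi, rng) if rarefy_depth_fungi else asv_fungi
    parts.append(diversity_indices(bac)["H"].rename("bac_div"))
    parts.append(diversity_indices(fun)["H"].rename("fun_div"))

    parts.append(gene_scores(genes, catabolic, scaling=gene_scaling))
    parts.append(sir_efficiency(microresp))
    parts.append(sir_range(microresp))
    parts.append(respiration.rename("respiration"))

    facets = pd.concat(parts, axis=1).rename_axis("sample")
    if soil is not None:
        facets = facets.join(soil_stoichiometry(soil["toc"], soil["tn"], soil["tp"]))
    order = [
        "total_biomass", "active_biomass", "bf_ratio", "bac_div", "fun_div",
        "cata_score", "fg_evenness", "sir_efficiency", "sir_range", "respiration",
    ]
    extra = [c for c in facets.columns if c not in order]
    return facets[order + extra]


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample identifiers")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts in community matrix")
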