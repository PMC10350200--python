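"""Cell-growth assay processing and the molecular predictors of prevalence.

Fibroblast cultures are imaged at two-hour intervals after DNA damage
(ionizing radiation at 0/0.4/2/10 Gy, or doxorubicin at 0/0.11/0.33/1 μM
with a DMSO vehicle control at dose 0). The damage-response statistic is the
area under the cell-count-over-time curve of treated cells divided by the
AUC of the untreated cells of the same species and agent, expressed as a
percent — 100% means the treatment did not slow proliferation at all.

Replicate curves are averaged pointwise on the shared time grid before the
AUC ratio is taken (for a shared grid this equals averaging per-replicate
AUCs). Apoptosis (Annexin V positive) counts, when present, are summarized
but not modeled. The percent-growth values, and published somatic mutation
rates (single base substitutions per genome per year), are regressed against
prevalence on a log10 scale through the weighted phylogenetic regression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .pgls import RegressionDesign, fit_pgls
from .phylo import normalize_label, prune_to_taxa, tip_labels

logger = logging.getLogger(__name__)

GROWTH_COLUMNS = ["species", "agent", "dose", "replicate", "time_h", "count"]


def auc(time_h, counts) -> float:
    """Trapezoidal area under a cell-count time series."""
    t = np.asarray(time_h, dtype=float)
    c = np.asarray(counts, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("cell counts must be non-negative")
    return float(np.trapezoid(c, t))


def mean_curve(df: pd.DataFrame) -> pd.DataFrame:
    """Average replicate curves pointwise on the common time grid."""
    out = (
        df.groupby("time_h", as_index=False)["count"].mean().sort_values("time_h")
    )
    return out


def percent_growth(treated: pd.DataFrame, untreated: pd.DataFrame) -> float:
    """100 · AUC(mean treated) / AUC(mean untreated) on a matched grid."""
    mt = mean_curve(treated)
    mu = mean_curve(untreated)
    if not np.array_equal(mt["time_h"].to_numpy(), mu["time_h"].to_numpy()):
        raise ValueError("treated and untreated curves must share a time grid")
    auc_u = auc(mu["time_h"], mu["count"])
    if auc_u == 0:
        raise ValueError("untreated AUC is zero")
    return 100.0 * auc(mt["time_h"], mt["count"]) / auc_u


def damage_response_table(growth: pd.DataFrame) -> pd.DataFrame:
    """Percent growth relative to untreated for every species/agent/dose > 0.

    ``growth`` is the long-format assay table (columns ``species, agent,
    dose, replicate, time_h, count``); dose 0 rows are the per-agent
    untreated baseline (DMSO vehicle for doxorubicin, 0 Gy for radiation).
    """
    missing = [c for c in GROWTH_COLUMNS if c not in growth.columns]
    if missing:
        raise ValueError(f"growth table missing columns: {missing}")
    rows = []
    for (species, agent), sub in growth.groupby(["species", "agent"]):
        base = sub[sub["dose"] == 0]
        if base.empty:
            logger.warning("no untreated baseline for %s / %s; skipped", species, agent)
            continue
        for dose, tr in sub[sub["dose"] > 0].groupby("dose"):
            rows.append(
                {
                    "species": species,
                    "agent": agent,
                    "dose": dose,
                    "percent_growth": percent_growth(tr, base),
                }
            )
    return pd.DataFrame(rows, columns=["species", "agent", "dose", "percent_growth"])


def summarize_apoptosis(growth: pd.DataFrame) -> pd.DataFrame:
    """Mean final-timepoint apoptosis-positive count per species/agent/dose."""
    if "apoptosis_count" not in growth.columns:
        return pd.DataFrame(columns=["species", "agent", "dose", "final_apoptosis"])
    t_end = growth.groupby(["species", "agent", "dose"])["time_h"].transform("max")
    final = growth[growth["time_h"] == t_end]
    out = (
        final.groupby(["species", "agent", "dose"], as_index=False)["apoptosis_count"]
        .mean()
        .rename(columns={"apoptosis_count": "final_apoptosis"})
    )
    return out


def _pgls_on_predictor(
    prev: pd.DataFrame,
    predictor: pd.Series,
    tree,
    response: str,
    label: str,
) -> dict | None:
    """One log10-predictor PGLS fit; None when overlap is insufficient."""
    merged = prev.assign(
        scientific_name=prev["scientific_name"].map(normalize_label)
    ).merge(
        predictor.rename("x").rename_axis("scientific_name").reset_index(),
        on="scientific_name",
    )
    merged = merged[(merged["x"] > 0) & merged[response].notna()]
    if len(merged) < 4:
        logger.warning("%s: only %d overlapping species; skipped", label, len(merged))
        return None
    pruned = prune_to_taxa(tree, merged["scientific_name"])
    in_tree = set(tip_labels(pruned))
    merged = merged[merged["scientific_name"].isin(in_tree)]
    if len(merged) < 4:
        logger.warning("%s: fewer than 4 species in tree; skipped", label)
        return None
    design = RegressionDesign(
        species=tuple(merged["scientific_name"]),
        y=merged[response].to_numpy(dtype=float),
        X=np.column_stack([np.ones(len(merged)), np.log10(merged["x"].to_numpy(float))]),
        coef_names=("intercept", "log10_x"),
        n_counts=merged["n"].to_numpy(dtype=float),
    )
    fit = fit_pgls(design, prune_to_taxa(tree, merged["scientific_name"]))
    return {
        "analysis": label,
        "response": response,
        "slope": fit.beta[1],
        "se": fit.se[1],
        "p": fit.pvalues[1],
        "lambda_hat": fit.lambda_hat,
        "r2": fit.r2,
        "n": fit.n_obs,
    }


def assay_regressions(
    responses: pd.DataFrame,
    prev: pd.DataFrame,
    tree,
    prevalence_responses=("p_neo", "p_mal"),
) -> pd.DataFrame:
    """PGLS of prevalence on log10 percent growth, per agent and dose."""
    rows = []
    for (agent, dose), sub in responses.groupby(["agent", "dose"]):
        pred = sub.set_index(sub["species"].map(normalize_label))["percent_growth"]
        for resp in prevalence_responses:
            row = _pgls_on_predictor(
                prev, pred, tree, resp, f"{resp}~log10_percent_growth[{agent}@{dose}]"
            )
            if row is not None:
                row["agent"] = agent
                row["dose"] = dose
                rows.append(row)
    return pd.DataFrame(rows)


def mutation_rate_regressions(
    rates: pd.DataFrame,
    prev: pd.DataFrame,
    tree,
    prevalence_responses=("p_neo", "p_mal"),
) -> pd.DataFrame:
    """PGLS of prevalence on log10 somatic mutation rate (SBS/genome/year)."""
    pred = rates.set_index(rates["species"].map(normalize_label))["rate"]
    rows = []
    for resp in prevalence_responses:
        row = _pgls_on_predictor(prev, pred, tree, resp, f"{resp}~log10_mutation_rate")
        if row is not None:
            rows.append(row)
    return pd.DataFrame(rows)
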