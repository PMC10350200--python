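"""End-to-end orchestration: ingest → prevalence → regressions → model fits.

A :class:`RunConfig` (YAML on disk) names every input; :func:`run_pipeline`
executes the stages in order, writes tidy CSV outputs with a provenance
header (config hash + stage) into the output directory, and echoes the
configuration verbatim so a run can be reproduced byte-for-byte from its
output directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import assays as assays_mod
from . import records as records_mod
from . import stats as stats_mod
from .evolve import compare_models
from .pgls import AnalysisSpec, default_analysis_suite, run_regression_suite
from .phylo import normalize_label, prune_to_taxa, read_newick_file, tip_labels, vcv
from .records import DiagnosisDictionary, ExclusionReport, NameMap

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and settings for one pipeline run."""

    records: str
    dictionary: str
    name_map: str
    life_history: str
    tree: str
    outdir: str
    growth: str | None = None
    mutation_rates: str | None = None
    min_n: int = 20
    fdr_q: float = 0.10
    seed: int = 0
    lifespan_col: str = "max_longevity_months"
    suite: list | None = None  # optional explicit analysis suite (list of dicts)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self) -> str:
        d = {k: v for k, v in self.__dict__.items()}
        return yaml.safe_dump(d, sort_keys=True)

    def input_paths(self) -> dict[str, str]:
        paths = {
            "records": self.records,
            "dictionary": self.dictionary,
            "name_map": self.name_map,
            "life_history": self.life_history,
            "tree": self.tree,
        }
        if self.growth:
            paths["growth"] = self.growth
        if self.mutation_rates:
            paths["mutation_rates"] = self.mutation_rates
        return paths


def _config_hash(config: RunConfig) -> str:
    """Hash of the analysis-relevant settings (the output location is not one)."""
    d = {k: v for k, v in config.__dict__.items() if k != "outdir"}
    return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, stage: str, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# oncophylo stage={stage} config={cfg_hash}\n")
        df.to_csv(fh, index=False)


def _parse_suite(raw: list | None) -> list[AnalysisSpec] | None:
    if raw is None:
        return None
    out = []
    for entry in raw:
        out.append(
            AnalysisSpec(
                name=entry["name"],
                response=entry["response"],
                predictors=tuple((p, t) for p, t in entry["predictors"]),
                subset=entry.get("subset"),
            )
        )
    return out


def summarize_species(prev: pd.DataFrame, top_k: int = 10) -> dict[str, pd.DataFrame]:
    """Clade-level summaries and ranked species tables.

    Returns clade mean/median/range of neoplasia and malignancy prevalence,
    the top-k and bottom-k species by neoplasia prevalence, and the ranking
    by proportion of neoplasms that are malignant. Ties in any ranking are
    broken alphabetically by scientific name.
    """
    clade = (
        prev.groupby("clade")
        .agg(
            n_species=("scientific_name", "size"),
            mean_p_neo=("p_neo", "mean"),
            median_p_neo=("p_neo", "median"),
            min_p_neo=("p_neo", "min"),
            max_p_neo=("p_neo", "max"),
            mean_p_mal=("p_mal", "mean"),
            median_p_mal=("p_mal", "median"),
            min_p_mal=("p_mal", "min"),
            max_p_mal=("p_mal", "max"),
        )
        .reset_index()
    )
    ranked = prev.sort_values(
        ["p_neo", "scientific_name"], ascending=[False, True], kind="mergesort"
    )
    cols = ["scientific_name", "clade", "n", "p_neo", "p_mal", "mal_fraction"]
    by_mal = prev.dropna(subset=["mal_fraction"]).sort_values(
        ["mal_fraction", "scientific_name"], ascending=[False, True], kind="mergesort"
    )
    return {
        "clade_summary": clade,
        "top_species": ranked.head(top_k)[cols].reset_index(drop=True),
        "bottom_species": ranked.tail(top_k)[cols][::-1].reset_index(drop=True),
        "malignant_fraction_ranking": by_mal[cols].reset_index(drop=True),
    }


def desk_summary(prev: pd.DataFrame) -> dict[str, float]:
    """Headline statistics of a species-prevalence table.

    Computes the totals a reader would check first against a published
    species table: record and species counts, median necropsies per species,
    grand and per-clade mean prevalences, and the correlation between benign
    and malignant prevalence across species.
    """
    out: dict[str, float] = {
        "total_records": float(prev["n"].sum()),
        "n_species": float(len(prev)),
        "median_necropsies": float(prev["n"].median()),
        "mean_p_neo": float(prev["p_neo"].mean()),
        "mean_p_mal": float(prev["p_mal"].mean()),
    }
    for clade, sub in prev.groupby("clade"):
        out[f"mean_p_neo_{clade}"] = float(sub["p_neo"].mean())
        out[f"mean_p_mal_{clade}"] = float(sub["p_mal"].mean())
    if len(prev) >= 3 and prev["p_ben"].std() > 0 and prev["p_mal"].std() > 0:
        res = stats_mod.pearson(prev["p_ben"], prev["p_mal"])
        out["benign_malignant_r"] = res.statistic
        out["benign_malignant_p"] = res.p
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the result tables keyed by stage.

    Stages: ingest (resolve, filter), prevalence, species summaries, clade
    statistics, the PGLS regression suite with FDR control, BM/OU/EB model
    comparison for both prevalences, and (when assay inputs are configured)
    the damage-response and mutation-rate regressions. Any missing input
    path aborts before any output is written.
    """
    missing = [p for p in config.input_paths().values() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input paths: {missing}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(config)
    (outdir / "config.yaml").write_text(config.to_yaml())

    results: dict = {}
    stage = "load"
    try:
        raw_records = records_mod.read_records_csv(config.records)
        dictionary = DiagnosisDictionary.from_csv(config.dictionary)
        name_map = NameMap.from_csv(config.name_map)
        life = pd.read_csv(config.life_history, comment="#")
        life["scientific_name"] = life["scientific_name"].map(normalize_label)
        tree = read_newick_file(config.tree)

        stage = "ingest"
        report = ExclusionReport(n_input=len(raw_records))
        resolved = records_mod.resolve_names(raw_records, name_map, report)
        kept = records_mod.filter_records(resolved, report)
        logger.info(
            "ingest: %d records in, %d after resolution, %d after filters",
            len(raw_records),
            len(resolved),
            len(kept),
        )

        stage = "prevalence"
        prev = records_mod.compute_prevalence(
            kept, dictionary, min_n=config.min_n, report=report
        )
        logger.info("prevalence: %d species with >= %d necropsies", len(prev), config.min_n)
        results["prevalence"] = prev
        results["exclusion_report"] = report
        _write_csv(prev, outdir / "species_prevalence.csv", stage, cfg_hash)
        (outdir / "exclusion_report.txt").write_text(report.to_text() + "\n")

        stage = "summaries"
        summaries = summarize_species(prev)
        results["summaries"] = summaries
        for name, df in summaries.items():
            _write_csv(df, outdir / f"{name}.csv", stage, cfg_hash)
        results["desk_summary"] = desk_summary(prev)
        (outdir / "desk_summary.json").write_text(
            json.dumps(results["desk_summary"], indent=1, sort_keys=True) + "\n"
        )

        stage = "clade_stats"
        test_rows = []
        groups_neo = [sub["p_neo"].to_numpy() for _, sub in prev.groupby("clade")]
        if len(groups_neo) >= 2:
            for col in ("p_neo", "p_mal"):
                groups = [sub[col].to_numpy() for _, sub in prev.groupby("clade")]
                res = stats_mod.kruskal_wallis(groups)
                test_rows.append(
                    {
                        "test": f"kruskal_wallis_{col}",
                        "statistic": res.statistic,
                        "p": res.p,
                        "groups": "|".join(sorted(prev["clade"].unique())),
                    }
                )
        age_tests, densities = stats_mod.scaled_age_comparison(
            kept, life, dictionary, lifespan_col=config.lifespan_col
        )
        for clade, res in age_tests.items():
            test_rows.append(
                {
                    "test": f"ks_scaled_age_{clade}",
                    "statistic": res.statistic,
                    "p": res.p,
                    "groups": f"neoplasia({res.n[0]})|non({res.n[1]})",
                }
            )
        stats_df = pd.DataFrame(test_rows)
        results["clade_stats"] = stats_df
        _write_csv(stats_df, outdir / "clade_stats.csv", stage, cfg_hash)
        if not densities.empty:
            _write_csv(densities, outdir / "scaled_age_density.csv", stage, cfg_hash)

        stage = "pgls"
        suite = _parse_suite(config.suite) or default_analysis_suite()
        pgls_df = run_regression_suite(prev, life, tree, suite=suite, fdr_q=config.fdr_q)
        results["pgls"] = pgls_df
        _write_csv(pgls_df, outdir / "pgls_results.csv", stage, cfg_hash)

        stage = "trait_evolution"
        evo_frames = []
        species_in_tree = set(tip_labels(tree))
        evo_prev = prev[prev["scientific_name"].map(normalize_label).isin(species_in_tree)]
        if len(evo_prev) >= 4:
            pruned = prune_to_taxa(tree, evo_prev["scientific_name"])
            cov = vcv(pruned)
            aligned = evo_prev.set_index(
                evo_prev["scientific_name"].map(normalize_label)
            ).loc[list(cov.taxa)]
            for col in ("p_neo", "p_mal"):
                cmp_df = compare_models(aligned[col].to_numpy(float), cov)
                cmp_df.insert(0, "trait", col)
                evo_frames.append(cmp_df)
        evo_df = (
            pd.concat(evo_frames, ignore_index=True) if evo_frames else pd.DataFrame()
        )
        results["trait_evolution"] = evo_df
        _write_csv(evo_df, outdir / "trait_evolution.csv", stage, cfg_hash)

        if config.growth or config.mutation_rates:
            stage = "assays"
            assay_frames = []
            if config.growth:
                growth = pd.read_csv(config.growth, comment="#")
                responses = assays_mod.damage_response_table(growth)
                results["damage_response"] = responses
                _write_csv(responses, outdir / "damage_response.csv", stage, cfg_hash)
                assay_frames.append(assays_mod.assay_regressions(responses, prev, tree))
            if config.mutation_rates:
                rates = pd.read_csv(config.mutation_rates, comment="#")
                assay_frames.append(
                    assays_mod.mutation_rate_regressions(rates, prev, tree)
                )
            assay_df = pd.concat(
                [f for f in assay_frames if not f.empty], ignore_index=True
            ) if any(not f.empty for f in assay_frames) else pd.DataFrame()
            results["assay_regressions"] = assay_df
            _write_csv(assay_df, outdir / "assay_regressions.csv", stage, cfg_hash)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return results
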