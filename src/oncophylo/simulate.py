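"""Synthetic study generator: every pipeline input with known ground truth.

The generator emulates the structure of a multi-institution necropsy study:
a dated ultrametric phylogeny (pure-birth), life-history traits evolved by
Brownian motion on a log10 scale, a latent per-species prevalence that is
linear in the life-history predictors with phylogenetically correlated
residuals at a chosen Pagel's λ, binomial necropsy sampling with realistic
per-species necropsy counts (median 35, minimum 20), record-level tables
contaminated with neonates, histologically unconfirmed diagnoses and
unresolvable common names (which the ingest filters must remove to recover
the truth), and per-species growth-curve and somatic-mutation-rate assays.

Everything is driven by one integer seed; a ground-truth manifest is emitted
next to the generated tables.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from .phylo import normalize_label, tree_height
from .records import (
    DiagnosisDictionary,
    NameMap,
    NecropsyRecord,
    write_records_csv,
)

BENIGN_TERMS = ("adenoma", "fibroma", "papilloma", "lipoma", "hemangioma")
MALIGNANT_TERMS = (
    "lymphoma",
    "carcinoma",
    "sarcoma",
    "adenocarcinoma",
    "melanoma",
)
NON_NEOPLASTIC_TERMS = ("hyperplasia", "granuloma", "abscess", "cyst")

RADIATION_DOSES = (0.0, 0.4, 2.0, 10.0)  # Gy
DOXORUBICIN_DOSES = (0.0, 0.11, 0.33, 1.0)  # uM


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated study design.

    292 species in three clades, necropsy counts log-normal with median 35
    and a floor of 20, a latent percent-scale prevalence with mean ≈ 9%
    driven by log10 adult weight (2.1%/log10 g) and log10 gestation time
    (−5.6%/log10 month) with phylogenetic residuals at λ = 0.46, a ~0.65
    mean malignant share among tumour-bearing animals, 15 assay species and
    9 mutation-rate species with a 47.26%/log10-rate coupling.
    """

    seed: int = 0
    n_species: int = 292
    birth_rate: float = 1.0
    clade_fractions: tuple[float, float, float] = (0.34, 0.50, 0.16)

    # latent prevalence model (percent scale)
    lambda_true: float = 0.46
    sigma2_phylo: float = 36.0
    beta_weight: float = 2.1  # % per log10 g
    beta_gestation: float = -5.6  # % per log10 month on the latent prevalence
    mean_prevalence: float = 9.07
    # additive clade effects (Mammalia, Sauropsida, Amphibia) recreating the
    # mammals >> sauropsids > amphibians gradient; weighted mean ~ 0
    clade_offsets: tuple[float, float, float] = (6.21, -2.67, -4.91)
    mal_share_mean: float = 0.65
    mal_share_conc: float = 10.0

    # necropsy counts
    necropsy_median: float = 35.0
    necropsy_sigma: float = 0.95
    necropsy_min: int = 20

    # record-level contamination (fractions of a species' record count)
    neonate_fraction: float = 0.05
    unconfirmed_fraction: float = 0.03
    unresolved_fraction: float = 0.02
    n_institutions: int = 99

    # lifespan-scaled age-at-death model (Beta shapes per arm, times age_scale)
    age_beta_non: tuple[float, float] = (2.0, 3.0)
    age_beta_neo: tuple[float, float] = (3.0, 2.0)
    age_scale: float = 1.5

    # diagnosis term pools (empty malignant pool => no malignancies generated)
    benign_terms: tuple[str, ...] = BENIGN_TERMS
    malignant_terms: tuple[str, ...] = MALIGNANT_TERMS
    non_neoplastic_terms: tuple[str, ...] = NON_NEOPLASTIC_TERMS

    # assays
    n_assay_species: int = 15
    n_mutation_species: int = 9
    mutation_slope: float = 47.26  # % prevalence per log10(SBS/genome/year)
    mutation_rate_center: float = 20.0  # SBS/genome/year at mean prevalence
    mutation_noise_sd: float = 0.02  # sd on log10 rate
    growth_suppression_log10: float = -0.45  # mean log10 growth ratio at max dose
    growth_suppression_sd: float = 0.15
    growth_noise_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if abs(sum(self.clade_fractions) - 1.0) > 1e-9:
            raise ValueError("clade_fractions must sum to 1")


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def simulate_tree(config: SimulationConfig) -> dendropy.Tree:
    """Pure-birth ultrametric tree with ``n_species`` tips.

    Terminal branches are extended by one exponential waiting time so the
    youngest cherry does not have zero-length tips, and the root stem is
    removed; tips are labeled Species_0001..Species_NNNN in leaf order.
    """
    pyrng = random.Random(int(_rng(config, 1).integers(2**31 - 1)))
    tree = birthdeath.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=0.0,
        num_extant_tips=config.n_species,
        rng=pyrng,
    )
    extra = pyrng.expovariate(config.birth_rate * config.n_species)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree.seed_node.edge.length = None
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"Species_{i + 1:04d}"
    return tree


def _simulate_bm(tree: dendropy.Tree, rng: np.random.Generator, rate: float = 1.0):
    """Brownian tip states (root state 0) by one preorder pass."""
    values: dict = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = 0.0
            continue
        length = node.edge.length or 0.0
        values[node] = values[node.parent_node] + rng.normal(
            0.0, np.sqrt(rate * length)
        )
    return np.array(
        [values[leaf] for leaf in tree.leaf_node_iter()]
    ), [normalize_label(leaf.taxon.label) for leaf in tree.leaf_node_iter()]


def simulate_species_data(
    config: SimulationConfig, tree: dendropy.Tree
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Life-history table, species-prevalence table and ground-truth manifest.

    Predictors evolve by BM on the log10 scale; the latent percent
    prevalence is η = Xβ + u with u ~ N(0, σ² C(λ)/h), clipped to [0, 100];
    counts are binomial draws k_neo ~ Bin(n_i, η_i/100) and
    k_mal ~ Bin(k_neo, malignant share).
    """
    rng = _rng(config, 2)
    h = tree_height(tree)
    species: list[str] = [normalize_label(l.taxon.label) for l in tree.leaf_node_iter()]
    n_sp = len(species)

    # clade assignment: contiguous blocks in leaf order approximate clades
    counts = np.floor(np.array(config.clade_fractions) * n_sp).astype(int)
    counts[0] += n_sp - counts.sum()
    clades = (
        ["Mammalia"] * counts[0] + ["Sauropsida"] * counts[1] + ["Amphibia"] * counts[2]
    )

    # correlated BM fields on log10 scale (weight-gestation correlation ~0.5)
    b_w, _ = _simulate_bm(tree, rng, rate=1.0 / h)
    b_g, _ = _simulate_bm(tree, rng, rate=1.0 / h)
    b_l, _ = _simulate_bm(tree, rng, rate=1.0 / h)
    x_weight = 3.0 + 1.2 * b_w
    x_gest = 0.5 + 0.4 * (0.5 * b_w + np.sqrt(1 - 0.25) * b_g)
    x_longev = 2.2 + 0.35 * (0.4 * b_w + np.sqrt(1 - 0.16) * b_l)

    life = pd.DataFrame(
        {
            "scientific_name": species,
            "clade": clades,
            "adult_weight_g": 10.0**x_weight,
            "max_longevity_months": 10.0**x_longev,
            "gestation_months": 10.0**x_gest,
            "litter_size": np.round(
                np.clip(rng.lognormal(0.7, 0.5, n_sp), 1.0, 15.0), 1
            ),
            "sexual_maturity_months": 10.0
            ** (x_longev - 1.0 + rng.normal(0, 0.2, n_sp)),
            "growth_rate": 10.0 ** rng.normal(-2.0, 0.4, n_sp),
            "metabolic_rate": np.where(
                np.array(clades) == "Mammalia",
                10.0 ** (0.7 * x_weight - 1.0 + rng.normal(0, 0.15, n_sp)),
                np.nan,
            ),
        }
    )

    # latent prevalence: linear in predictors + lambda-structured residual
    u_phylo, _ = _simulate_bm(tree, rng, rate=1.0 / h)
    u_iid = rng.normal(0.0, 1.0, n_sp)
    lam = config.lambda_true
    u = np.sqrt(config.sigma2_phylo) * (
        np.sqrt(lam) * u_phylo + np.sqrt(1.0 - lam) * u_iid
    )
    effect = config.beta_weight * (x_weight - x_weight.mean()) + (
        config.beta_gestation * (x_gest - x_gest.mean())
    )
    offset_by_clade = dict(
        zip(("Mammalia", "Sauropsida", "Amphibia"), config.clade_offsets)
    )
    clade_effect = np.array([offset_by_clade[c] for c in clades])
    eta = np.clip(config.mean_prevalence + clade_effect + effect + u, 0.0, 100.0)

    n_i = np.maximum(
        config.necropsy_min,
        np.round(
            rng.lognormal(np.log(config.necropsy_median), config.necropsy_sigma, n_sp)
        ).astype(int),
    )
    k_neo = rng.binomial(n_i, eta / 100.0)
    if config.malignant_terms:
        a = config.mal_share_mean * config.mal_share_conc
        b = (1.0 - config.mal_share_mean) * config.mal_share_conc
        mal_share = rng.beta(a, b, n_sp)
    else:
        mal_share = np.zeros(n_sp)
    k_mal = rng.binomial(k_neo, mal_share)

    prev = pd.DataFrame(
        {
            "scientific_name": species,
            "clade": clades,
            "n": n_i,
            "k_neo": k_neo,
            "k_mal": k_mal,
            "p_neo": 100.0 * k_neo / n_i,
            "p_mal": 100.0 * k_mal / n_i,
            "p_ben": 100.0 * k_neo / n_i - 100.0 * k_mal / n_i,
            "mal_fraction": np.where(k_neo > 0, k_mal / np.maximum(k_neo, 1), np.nan),
        }
    )

    truth = {
        "lambda_true": config.lambda_true,
        "sigma2_phylo": config.sigma2_phylo,
        "beta_weight": config.beta_weight,
        "beta_gestation": config.beta_gestation,
        "mean_prevalence": config.mean_prevalence,
        "latent_prevalence": dict(zip(species, eta.tolist())),
        "mal_share": dict(zip(species, mal_share.tolist())),
    }
    return life, prev, truth


def _common_name(scientific: str) -> str:
    return scientific.replace("Species ", "synthetic beast ")


def simulate_records(
    config: SimulationConfig, prev: pd.DataFrame, life: pd.DataFrame | None = None
) -> tuple[list[NecropsyRecord], NameMap, DiagnosisDictionary]:
    """Record-level table whose clean re-aggregation reproduces ``prev`` exactly.

    For each species, exactly ``k_mal`` records carry a malignant term,
    ``k_neo − k_mal`` a benign term and the rest none; some tumour-free
    records carry a non-neoplastic term (which classification must ignore).
    On top of the true records, contaminant rows are injected — neonates,
    unconfirmed histology with a tumour term, and unresolvable common names —
    that the ingest filters must remove.
    """
    rng = _rng(config, 3)
    if not config.benign_terms:
        raise ValueError("benign term pool must be non-empty")
    dictionary = DiagnosisDictionary(
        {
            **{t: "benign" for t in config.benign_terms},
            **{t: "malignant" for t in config.malignant_terms},
            **{t: "non_neoplastic" for t in config.non_neoplastic_terms},
        }
    )
    name_map = NameMap(
        {_common_name(s): s for s in prev["scientific_name"]}
    )
    lifespans = (
        dict(zip(life["scientific_name"], life["max_longevity_months"]))
        if life is not None
        else {}
    )

    records: list[NecropsyRecord] = []
    rid = 0

    def draw_age(species: str, has_neo: bool) -> float | None:
        ref = lifespans.get(species)
        if ref is None:
            return None
        shapes = config.age_beta_neo if has_neo else config.age_beta_non
        ratio = rng.beta(*shapes) * config.age_scale
        return float(max(ratio * ref, 0.1))

    for row in prev.itertuples(index=False):
        species = row.scientific_name
        common = _common_name(species)
        statuses = (
            ["malignant"] * int(row.k_mal)
            + ["benign"] * int(row.k_neo - row.k_mal)
            + ["none"] * int(row.n - row.k_neo)
        )
        rng.shuffle(statuses)
        for status in statuses:
            rid += 1
            if status == "malignant":
                terms: tuple[str, ...] = (str(rng.choice(config.malignant_terms)),)
                if rng.random() < 0.3:  # malignant + incidental benign lesion
                    terms = terms + (str(rng.choice(config.benign_terms)),)
            elif status == "benign":
                terms = (str(rng.choice(config.benign_terms)),)
            else:
                terms = ()
                if config.non_neoplastic_terms and rng.random() < 0.15:
                    terms = (str(rng.choice(config.non_neoplastic_terms)),)
            records.append(
                NecropsyRecord(
                    record_id=f"R{rid:06d}",
                    institution=f"Zoo_{rng.integers(config.n_institutions):02d}",
                    common_name=common,
                    clade=row.clade,
                    diagnosis_terms=terms,
                    age_at_death_months=draw_age(species, status != "none"),
                    histology_confirmed=True,
                    neonate=False,
                )
            )
        # contaminants (all must be excluded by the ingest filters)
        for _ in range(rng.binomial(row.n, config.neonate_fraction)):
            rid += 1
            records.append(
                NecropsyRecord(
                    record_id=f"R{rid:06d}",
                    institution=f"Zoo_{rng.integers(config.n_institutions):02d}",
                    common_name=common,
                    clade=row.clade,
                    diagnosis_terms=(),
                    age_at_death_months=0.5,
                    histology_confirmed=True,
                    neonate=True,
                )
            )
        for _ in range(rng.binomial(row.n, config.unconfirmed_fraction)):
            rid += 1
            records.append(
                NecropsyRecord(
                    record_id=f"R{rid:06d}",
                    institution=f"Zoo_{rng.integers(config.n_institutions):02d}",
                    common_name=common,
                    clade=row.clade,
                    diagnosis_terms=(
                        str(rng.choice(config.benign_terms + config.malignant_terms)),
                    ),
                    age_at_death_months=draw_age(species, True),
                    histology_confirmed=False,
                    neonate=False,
                )
            )
        for _ in range(rng.binomial(row.n, config.unresolved_fraction)):
            rid += 1
            records.append(
                NecropsyRecord(
                    record_id=f"R{rid:06d}",
                    institution=f"Zoo_{rng.integers(config.n_institutions):02d}",
                    common_name=f"mystery beast {rid}",
                    clade=row.clade,
                    diagnosis_terms=(),
                    age_at_death_months=None,
                    histology_confirmed=True,
                    neonate=False,
                )
            )

    order = rng.permutation(len(records))
    return [records[i] for i in order], name_map, dictionary


def _logistic(t: np.ndarray, n0: float, k: float, r: float) -> np.ndarray:
    return k / (1.0 + (k / n0 - 1.0) * np.exp(-r * t))


def simulate_assays(
    config: SimulationConfig, prev: pd.DataFrame, truth: dict
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Growth-curve and mutation-rate tables coupled to the latent prevalence.

    Growth: logistic curves (2 h sampling; 5 days for radiation, 3 days for
    doxorubicin) whose rate is suppressed multiplicatively with dose, plus
    log-normal measurement noise, in triplicate. Mutation rates: log10 rate
    linear in latent prevalence with slope 1/``mutation_slope`` so that the
    regression of prevalence on log10 rate recovers ``mutation_slope``.
    """
    rng = _rng(config, 4)
    eta = truth["latent_prevalence"]
    species_all = list(prev["scientific_name"])
    assay_species = species_all[: config.n_assay_species]
    mut_species = species_all[: config.n_mutation_species]

    rows = []
    for species in assay_species:
        r0 = rng.normal(0.06, 0.008)
        l_i = rng.normal(config.growth_suppression_log10, config.growth_suppression_sd)
        for agent, doses, days in (
            ("radiation", RADIATION_DOSES, 5),
            ("doxorubicin", DOXORUBICIN_DOSES, 3),
        ):
            t = np.arange(0.0, days * 24.0 + 1e-9, 2.0)
            dmax = max(doses)
            for dose in doses:
                # rate multiplier shrinking with dose toward 10**l_i at dmax
                mult = 10.0 ** (l_i * dose / dmax)
                for rep in (1, 2, 3):
                    counts = _logistic(t, 2000.0, 30000.0, r0 * mult)
                    noise = rng.lognormal(0.0, config.growth_noise_sd, len(t))
                    apo = counts * 0.02 * (1.0 + 3.0 * dose / dmax) * (t / t[-1])
                    for ti, ci, ai in zip(t, counts * noise, apo):
                        rows.append(
                            {
                                "species": species,
                                "agent": agent,
                                "dose": dose,
                                "replicate": rep,
                                "time_h": ti,
                                "count": ci,
                                "apoptosis_count": ai,
                            }
                        )
    growth = pd.DataFrame(rows)

    eta_bar = float(np.mean([eta[s] for s in species_all]))
    mut_rows = []
    for species in mut_species:
        log10_rate = (
            np.log10(config.mutation_rate_center)
            + (eta[species] - eta_bar) / config.mutation_slope
            + rng.normal(0.0, config.mutation_noise_sd)
        )
        mut_rows.append({"species": species, "rate": 10.0**log10_rate})
    rates = pd.DataFrame(mut_rows, columns=["species", "rate"])
    assay_truth = {
        "mutation_slope": config.mutation_slope,
        "assay_species": assay_species,
        "mutation_species": mut_species,
    }
    return growth, rates, assay_truth


def simulate_study(config: SimulationConfig):
    """Full synthetic study: tree, tables, records and assays plus the truth."""
    tree = simulate_tree(config)
    life, prev, truth = simulate_species_data(config, tree)
    records, name_map, dictionary = simulate_records(config, prev, life)
    growth, rates, assay_truth = simulate_assays(config, prev, truth)
    truth = {**truth, **assay_truth, "config": dataclasses.asdict(config)}
    return {
        "tree": tree,
        "life_history": life,
        "prevalence": prev,
        "records": records,
        "name_map": name_map,
        "dictionary": dictionary,
        "growth": growth,
        "mutation_rates": rates,
        "truth": truth,
    }


def write_study(study: dict, outdir) -> dict:
    """Write every generated input in the dialect the pipeline reads.

    Returns the path map; the ground-truth manifest lands in
    ``truth_manifest.json`` next to the tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": outdir / "tree.nwk",
        "life_history": outdir / "life_history.csv",
        "prevalence": outdir / "true_prevalence.csv",
        "records": outdir / "records.csv",
        "name_map": outdir / "name_map.csv",
        "dictionary": outdir / "diagnosis_dictionary.csv",
        "growth": outdir / "growth_curves.csv",
        "mutation_rates": outdir / "mutation_rates.csv",
        "truth": outdir / "truth_manifest.json",
    }
    study["tree"].write(path=str(paths["tree"]), schema="newick", suppress_rooting=True)
    study["life_history"].to_csv(paths["life_history"], index=False)
    study["prevalence"].to_csv(paths["prevalence"], index=False)
    write_records_csv(study["records"], paths["records"])
    study["name_map"].to_csv(paths["name_map"])
    study["dictionary"].to_csv(paths["dictionary"])
    study["growth"].to_csv(paths["growth"], index=False)
    study["mutation_rates"].to_csv(paths["mutation_rates"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(study["truth"], fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
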