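"""Phylogenetic GLS with sampling-error weighting and ML estimation of Pagel's λ.

The regression model for species-level prevalence is

    y = X β + ε,   ε ~ N(0, σ² C(λ) + c · diag(1/n_i))

where C is the Brownian covariance implied by the phylogeny, C(λ) scales its
off-diagonal by Pagel's λ, and the diagonal term carries the sampling error of
each species mean: a prevalence estimated from n_i necropsies has standard
error proportional to 1/√n_i, i.e. the species point is weighted by √n_i.
β is profiled analytically (the GLS estimator), σ² analytically given the
variance ratio g = c/σ², and g and λ numerically. λ is restricted to [0, 1].

Numerics: with D = diag(1/n_i), write V = σ² D^{1/2} (A(λ) + g I) D^{1/2}
where A(λ) = D^{-1/2} C(λ) D^{-1/2}. One symmetric eigendecomposition of A
per λ makes the inner profile over g an O(N·p) operation per evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .phylo import PhyloCovariance, normalize_label, prune_to_taxa, vcv

logger = logging.getLogger(__name__)

_LOG10_G_BOUNDS = (-8.0, 8.0)  # variance-ratio search window (C normalized to height 1)


@dataclass(frozen=True)
class RegressionDesign:
    """Aligned response, design matrix and necropsy counts for one analysis.

    ``X`` must contain the intercept column; rows of ``y``, ``X`` and
    ``n_counts`` follow ``species``, which must match the (pruned) tree.
    """

    species: tuple[str, ...]
    y: np.ndarray
    X: np.ndarray
    coef_names: tuple[str, ...]
    n_counts: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        X = np.asarray(self.X, dtype=float)
        n = np.asarray(self.n_counts, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0] or len(n) != len(y):
            raise ValueError("y, X and n_counts must have matching rows")
        if X.shape[1] != len(self.coef_names):
            raise ValueError("coef_names must match design columns")
        if np.any(~np.isfinite(y)) or np.any(~np.isfinite(X)):
            raise ValueError("design contains missing values; listwise-delete first")
        if np.any(n <= 0):
            raise ValueError("necropsy counts must be positive")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "n_counts", n)

    @property
    def n_obs(self) -> int:
        return len(self.y)


@dataclass
class PGLSFit:
    """Result of one weighted phylogenetic regression."""

    coef_names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    lambda_hat: float
    sigma2: float
    error_scale: float  # c in v_i = c / n_i
    loglik: float
    r2: float
    n_obs: int
    df_resid: int
    meta: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef_names,
                "estimate": self.beta,
                "se": self.se,
                "t": self.tvalues,
                "p": self.pvalues,
                "lambda_hat": self.lambda_hat,
                "r2": self.r2,
                "n": self.n_obs,
            }
        )


def mvn_gls_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> float:
    """Log-likelihood of y ~ N(Xβ̂, V) at the GLS β̂, with V fully fixed."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    V = np.asarray(V, float)
    n = len(y)
    L = np.linalg.cholesky(V)
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + rss)


class _ProfileWorkspace:
    """Per-design cache for profiling the likelihood over (λ, g)."""

    def __init__(self, design: RegressionDesign, C: np.ndarray):
        self.design = design
        cmax = float(np.max(np.diag(C)))
        if cmax <= 0:
            raise ValueError("covariance diagonal must be positive")
        self.cmax = cmax
        self.Cn = C / cmax
        self.diagCn = np.diag(self.Cn).copy()
        n = design.n_obs
        self.d = 1.0 / design.n_counts  # D diagonal
        self.sqrt_d = np.sqrt(self.d)
        self.logdet_D = float(np.sum(np.log(self.d)))
        self.Xs = design.X / self.sqrt_d[:, None]  # D^{-1/2} X
        self.ys = design.y / self.sqrt_d
        self.N = n
        self.p = design.X.shape[1]
        self._cache_lam: float | None = None
        self._cache = None

    def _eig(self, lam: float):
        if self._cache_lam == lam:
            return self._cache
        Clam = lam * self.Cn + (1.0 - lam) * np.diag(self.diagCn)
        A = Clam / np.outer(self.sqrt_d, self.sqrt_d)
        w, Q = np.linalg.eigh(A)
        w = np.maximum(w, 0.0)  # clip tiny negative eigenvalues
        Xt = Q.T @ self.Xs
        yt = Q.T @ self.ys
        ones_t = Q.T @ (np.ones(self.N) / self.sqrt_d)
        self._cache_lam = lam
        self._cache = (w, Xt, yt, ones_t)
        return self._cache

    def _gls_at(self, lam: float, g: float):
        """GLS quantities at fixed (λ, g); returns (loglik, beta, rss_w, XtWX, w+g)."""
        w, Xt, yt, _ = self._eig(lam)
        wg = w + g
        if np.any(wg <= 0):
            return -np.inf, None, np.nan, None, wg
        inv = 1.0 / wg
        XtW = Xt * inv[:, None]
        XtWX = XtW.T @ Xt
        XtWy = XtW.T @ yt
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("rank-deficient design") from exc
        resid = yt - Xt @ beta
        rss = float(np.sum(resid * resid * inv))
        if rss <= 0:
            return -np.inf, beta, rss, XtWX, wg
        sigma2 = rss / self.N
        logdet = float(np.sum(np.log(wg))) + self.logdet_D
        ll = -0.5 * (
            self.N * np.log(2.0 * np.pi * sigma2) + logdet + self.N
        )
        return ll, beta, rss, XtWX, wg

    def profile_g(self, lam: float) -> tuple[float, float]:
        """Maximize over g at fixed λ; returns (max loglik, ĝ)."""
        lo, hi = _LOG10_G_BOUNDS

        def neg(log10_g: float) -> float:
            return -self._gls_at(lam, 10.0 ** log10_g)[0]

        res = optimize.minimize_scalar(
            neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-7}
        )
        best_ll, best_g = -res.fun, 10.0 ** res.x
        for log10_g in (lo, hi):
            ll = -neg(log10_g)
            if ll > best_ll:
                best_ll, best_g = ll, 10.0 ** log10_g
        return best_ll, best_g


def gls_profile_loglik(
    design: RegressionDesign, cov: PhyloCovariance, lam: float
) -> float:
    """Profile log-likelihood at a fixed λ (β, σ² and the error scale profiled).

    The covariance is aligned to the design's species order before use.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    C = cov.aligned_to(design.species).matrix
    ws = _ProfileWorkspace(design, C)
    ll, _ = ws.profile_g(lam)
    if not np.isfinite(ll):
        raise FloatingPointError(f"non-finite profile likelihood at lambda={lam}")
    return ll


def fit_pgls(
    design: RegressionDesign,
    tree_or_cov,
    coarse_grid: int = 21,
    refine_xatol: float = 1e-5,
    lambda_fixed: float | None = None,
) -> PGLSFit:
    """Weighted phylogenetic regression with λ estimated by maximum likelihood.

    λ̂ is located on a coarse grid over [0, 1], refined by bounded scalar
    maximization around the grid optimum, with both endpoints evaluated
    explicitly; ``lambda_fixed`` skips the search and conditions on the given
    λ. Standard errors use the unbiased residual variance (df = N − rank(X));
    R² is 1 − RSS/TSS on V(λ̂)^{-1/2}-whitened data.
    """
    if isinstance(tree_or_cov, PhyloCovariance):
        cov = tree_or_cov
    else:
        cov = vcv(tree_or_cov)
    C = cov.aligned_to(design.species).matrix
    N, p = design.n_obs, design.X.shape[1]
    if np.linalg.matrix_rank(design.X) < p:
        raise np.linalg.LinAlgError("rank-deficient design")
    if N < p + 2:
        raise ValueError(f"need at least rank(X)+2 = {p + 2} species, got {N}")

    ws = _ProfileWorkspace(design, C)

    if lambda_fixed is not None:
        if not 0.0 <= lambda_fixed <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        loglik, lambda_hat = ws.profile_g(lambda_fixed)[0], float(lambda_fixed)
    else:
        grid = np.linspace(0.0, 1.0, coarse_grid)
        lls = np.empty_like(grid)
        for i, lam in enumerate(grid):
            lls[i], _ = ws.profile_g(lam)
        if np.any(~np.isfinite(lls)):
            bad = grid[~np.isfinite(lls)][0]
            raise FloatingPointError(f"non-finite profile likelihood at lambda={bad}")
        i_best = int(np.argmax(lls))
        step = grid[1] - grid[0]
        lo = max(0.0, grid[i_best] - step)
        hi = min(1.0, grid[i_best] + step)

        def neg(lam: float) -> float:
            return -ws.profile_g(lam)[0]

        res = optimize.minimize_scalar(
            neg, bounds=(lo, hi), method="bounded", options={"xatol": refine_xatol}
        )
        candidates = [
            (float(-res.fun), float(res.x)),
            (float(lls[i_best]), float(grid[i_best])),
        ]
        for lam_end in (0.0, 1.0):
            candidates.append((ws.profile_g(lam_end)[0], lam_end))
        loglik, lambda_hat = max(candidates, key=lambda c: c[0])

    _, g_hat = ws.profile_g(lambda_hat)
    ll, beta, rss_w, XtWX, wg = ws._gls_at(lambda_hat, g_hat)
    sigma2_ml = rss_w / N
    sigma2_unbiased = rss_w / (N - p)
    cov_beta = sigma2_unbiased * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df=N - p)

    # whitened R^2 against the GLS intercept-only model
    w_eig, Xt, yt, one_t = ws._eig(lambda_hat)
    inv = 1.0 / (w_eig + g_hat)
    mu0 = float((one_t * inv) @ yt) / float((one_t * inv) @ one_t)
    tss = float(np.sum((yt - one_t * mu0) ** 2 * inv))
    r2 = 1.0 - rss_w / tss if tss > 0 else np.nan

    return PGLSFit(
        coef_names=design.coef_names,
        beta=beta,
        se=se,
        tvalues=tvals,
        pvalues=pvals,
        lambda_hat=float(lambda_hat),
        sigma2=sigma2_ml / ws.cmax,
        error_scale=sigma2_ml * g_hat,
        loglik=float(ll),
        r2=float(r2),
        n_obs=N,
        df_resid=N - p,
        meta={"g_hat": g_hat},
    )


# ---------------------------------------------------------------------------
# Analysis suite


@dataclass(frozen=True)
class AnalysisSpec:
    """One regression of the analysis suite.

    ``predictors`` maps life-history columns to a transform, ``"log10"`` or
    ``"none"``; ``subset`` restricts to one clade (None = all species).
    """

    name: str
    response: str
    predictors: tuple[tuple[str, str], ...]
    subset: str | None = None


#: life-history predictors and their default transform
LIFE_HISTORY_PREDICTORS: tuple[tuple[str, str], ...] = (
    ("adult_weight_g", "log10"),
    ("max_longevity_months", "log10"),
    ("gestation_months", "log10"),
    ("litter_size", "none"),
    ("sexual_maturity_months", "log10"),
    ("growth_rate", "log10"),
    ("metabolic_rate", "log10"),
)


def default_analysis_suite() -> list[AnalysisSpec]:
    """The 28-regression suite: 21 univariate (7 life-history predictors ×
    3 responses), 4 mammal-only (gestation and litter size against neoplasia
    and malignancy), and 3 multivariate models combining adult weight,
    gestation and maximum longevity."""
    suite: list[AnalysisSpec] = []
    for col, tf in LIFE_HISTORY_PREDICTORS:
        for resp in ("p_neo", "p_mal", "mal_fraction"):
            suite.append(
                AnalysisSpec(
                    name=f"{resp}~{col}",
                    response=resp,
                    predictors=((col, tf),),
                )
            )
    for col, tf in (("gestation_months", "log10"), ("litter_size", "none")):
        for resp in ("p_neo", "p_mal"):
            suite.append(
                AnalysisSpec(
                    name=f"{resp}~{col}|Mammalia",
                    response=resp,
                    predictors=((col, tf),),
                    subset="Mammalia",
                )
            )
    suite.append(
        AnalysisSpec(
            name="p_neo~adult_weight_g+gestation_months",
            response="p_neo",
            predictors=(("adult_weight_g", "log10"), ("gestation_months", "log10")),
        )
    )
    suite.append(
        AnalysisSpec(
            name="p_mal~adult_weight_g+gestation_months",
            response="p_mal",
            predictors=(("adult_weight_g", "log10"), ("gestation_months", "none")),
        )
    )
    suite.append(
        AnalysisSpec(
            name="p_neo~adult_weight_g+max_longevity_months+gestation_months",
            response="p_neo",
            predictors=(
                ("adult_weight_g", "log10"),
                ("max_longevity_months", "log10"),
                ("gestation_months", "none"),
            ),
        )
    )
    assert len(suite) == 28
    return suite


def build_design(
    data: pd.DataFrame, spec: AnalysisSpec
) -> RegressionDesign | None:
    """Assemble a design from a merged prevalence + life-history table.

    Applies the clade subset, the per-predictor transform, and listwise
    deletion. Returns None when a predictor column is absent or entirely
    missing after subsetting (the caller reports the skip).
    """
    df = data if spec.subset is None else data[data["clade"] == spec.subset]
    cols = [c for c, _ in spec.predictors]
    for c in cols + [spec.response]:
        if c not in df.columns:
            logger.warning("analysis %s skipped: column %r absent", spec.name, c)
            return None
    sub = df[["scientific_name", "n", spec.response] + cols].dropna()
    if sub.empty:
        logger.warning("analysis %s skipped: no complete cases", spec.name)
        return None
    Xcols = [np.ones(len(sub))]
    names = ["intercept"]
    for c, tf in spec.predictors:
        v = sub[c].to_numpy(dtype=float)
        if tf == "log10":
            if np.any(v <= 0):
                keep = v > 0
                sub = sub[keep]
                Xcols = [x[keep] for x in Xcols]
                v = v[keep]
            v = np.log10(v)
            names.append(f"log10_{c}")
        else:
            names.append(c)
        Xcols.append(v)
    if sub.empty:
        return None
    return RegressionDesign(
        species=tuple(normalize_label(s) for s in sub["scientific_name"]),
        y=sub[spec.response].to_numpy(dtype=float),
        X=np.column_stack(Xcols),
        coef_names=tuple(names),
        n_counts=sub["n"].to_numpy(dtype=float),
    )


def run_regression_suite(
    prevalence: pd.DataFrame,
    life_history: pd.DataFrame,
    tree,
    suite: list[AnalysisSpec] | None = None,
    fdr_q: float = 0.10,
) -> pd.DataFrame:
    """Run the full regression suite and BH-adjust slope p-values.

    Returns a tidy table with one row per coefficient per analysis
    (estimate, SE, t, p, BH-adjusted p across all slope coefficients at the
    given q, λ̂, R², N). Analyses whose predictor is unavailable, or with too
    few complete cases, are skipped with a log message.
    """
    from .stats import bh_fdr  # local import to avoid a cycle

    if suite is None:
        suite = default_analysis_suite()
    life = life_history.drop(
        columns=[c for c in ("clade",) if c in life_history.columns]
    )
    merged = prevalence.merge(life, on="scientific_name", how="left")
    merged["scientific_name"] = merged["scientific_name"].map(normalize_label)

    rows = []
    for spec in suite:
        design = build_design(merged, spec)
        if design is None:
            continue
        if design.n_obs < design.X.shape[1] + 2:
            logger.warning(
                "analysis %s skipped: only %d complete cases", spec.name, design.n_obs
            )
            continue
        try:
            pruned = prune_to_taxa(tree, design.species)
        except ValueError:
            logger.warning("analysis %s skipped: no overlap with tree", spec.name)
            continue
        in_tree = set(
            normalize_label(l.taxon.label) for l in pruned.leaf_node_iter()
        )
        if len(in_tree) < len(design.species):
            keep = [i for i, s in enumerate(design.species) if s in in_tree]
            logger.info(
                "analysis %s: %d species missing from tree dropped",
                spec.name,
                design.n_obs - len(keep),
            )
            design = RegressionDesign(
                species=tuple(design.species[i] for i in keep),
                y=design.y[keep],
                X=design.X[keep],
                coef_names=design.coef_names,
                n_counts=design.n_counts[keep],
            )
            if design.n_obs < design.X.shape[1] + 2:
                continue
        fit = fit_pgls(design, pruned)
        for j, coef in enumerate(fit.coef_names):
            rows.append(
                {
                    "analysis": spec.name,
                    "response": spec.response,
                    "subset": spec.subset or "all",
                    "coef": coef,
                    "estimate": fit.beta[j],
                    "se": fit.se[j],
                    "t": fit.tvalues[j],
                    "p": fit.pvalues[j],
                    "lambda_hat": fit.lambda_hat,
                    "r2": fit.r2,
                    "loglik": fit.loglik,
                    "n": fit.n_obs,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    slope_mask = out["coef"] != "intercept"
    out["p_adj"] = np.nan
    out["reject_fdr"] = False
    if slope_mask.any():
        fdr = bh_fdr(out.loc[slope_mask, "p"].to_numpy(), q=fdr_q)
        out.loc[slope_mask, "p_adj"] = fdr.adjusted
        out.loc[slope_mask, "reject_fdr"] = fdr.reject
    return out
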