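"""Mixed-effect models of Procrustes FA scores against covariates.

The response is the per-individual Procrustes FA score; fixed effects come
from demography (age at death in years, sex with female reference, decade of
birth as a decade-index trend) plus exactly one hurricane-related term, and
the maternal lineage (matriline) always enters as a random intercept to
absorb relatedness.  Four standard model variants are provided:

1. all individuals, hurricane experienced yes/no;
2. never-exposed subset, no hurricane term;
3. all individuals, number of hurricanes (0/1/2, categorical);
4. exposed subset, developmental stage at hurricane (fetal/juvenile/adult,
   fetal reference).

Fitting is REML via :class:`statsmodels.regression.mixed_linear_model.MixedLM`.
Per-coefficient t tests use Satterthwaite-approximated denominator degrees
of freedom computed here from the REML variance-parameter curvature (the
delta method on the coefficient variance, with a numerical Hessian of the
restricted log-likelihood); when the matriline variance collapses to the
boundary the fit is clamped at zero and residual df are used, with a logged
note.  Post hoc pairwise contrasts of a factor are z tests on the fitted
coefficient covariance with Bonferroni-Holm stepdown over the contrast
family.  A simulation-based power analysis refits the model on data
regenerated from the fitted (or specified) variance components with a
percent change in mean FA injected into an exposure group.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

BOUNDARY_RATIO = 1e-8  # matriline/residual variance ratio treated as zero


# ---------------------------------------------------------------------------
# Model specification and design construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One mixed-model variant: fixed-effect terms, subset rule, references.

    ``fixed`` entries are drawn from {"age", "sex", "decade_of_birth",
    "hurricane_yn", "n_hurricanes", "age_at_hurricane"}; the random term is
    always a matriline intercept.  Reference levels: sex = F, decade trend
    anchored at 1950, n_hurricanes = 0, age_at_hurricane = fetal.
    """

    name: str
    fixed: tuple[str, ...]
    subset: str = "all"  # all | never_exposed | exposed

    def __post_init__(self) -> None:
        hurricane_terms = [
            t for t in self.fixed
            if t in ("hurricane_yn", "n_hurricanes", "age_at_hurricane")
        ]
        if len(hurricane_terms) > 1:
            raise ValueError("at most one hurricane-related fixed effect per model")
        if self.subset not in ("all", "never_exposed", "exposed"):
            raise ValueError(f"unknown subset rule {self.subset!r}")


MODEL_SUITE: tuple[ModelSpec, ...] = (
    ModelSpec("model1_all_hurricane_yn",
              ("age", "sex", "decade_of_birth", "hurricane_yn"), "all"),
    ModelSpec("model2_never_exposed",
              ("age", "sex", "decade_of_birth"), "never_exposed"),
    ModelSpec("model3_all_n_hurricanes",
              ("age", "sex", "decade_of_birth", "n_hurricanes"), "all"),
    ModelSpec("model4_exposed_age_at_hurricane",
              ("age", "sex", "decade_of_birth", "age_at_hurricane"), "exposed"),
)


def apply_subset(data: pd.DataFrame, subset: str) -> pd.DataFrame:
    if subset == "all":
        return data
    if subset == "never_exposed":
        return data[~data["hurricane_experienced"]].reset_index(drop=True)
    if subset == "exposed":
        return data[data["hurricane_experienced"]].reset_index(drop=True)
    raise ValueError(subset)


def build_design(data: pd.DataFrame, fixed: tuple[str, ...]) -> pd.DataFrame:
    """Fixed-effect design matrix with an intercept, treatment coding.

    Continuous: ``age`` (years), ``decade_of_birth`` (decades since 1950).
    Categorical terms get treatment dummies against their reference level; a
    categorical term with a single observed level raises a ``ValueError``
    naming the term.
    """
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(data))}
    for term in fixed:
        if term == "age":
            cols["age"] = data["age_at_death"].to_numpy(dtype=float)
        elif term == "decade_of_birth":
            cols["decade_of_birth"] = (
                (data["decade_of_birth"].to_numpy(dtype=float) - 1950.0) / 10.0
            )
        elif term == "sex":
            _check_levels(data["sex"], term)
            cols["sex[T.M]"] = (data["sex"] == "M").to_numpy(dtype=float)
        elif term == "hurricane_yn":
            _check_levels(data["hurricane_experienced"], term)
            cols["hurricane_yn[T.True]"] = data["hurricane_experienced"].to_numpy(dtype=float)
        elif term == "n_hurricanes":
            _check_levels(data["n_hurricanes"], term)
            for level in (1, 2):
                if (data["n_hurricanes"] == level).any():
                    cols[f"n_hurricanes[T.{level}]"] = (
                        (data["n_hurricanes"] == level).to_numpy(dtype=float)
                    )
        elif term == "age_at_hurricane":
            observed = data["age_at_hurricane"]
            _check_levels(observed, term)
            for level in ("juvenile", "adult"):
                if (observed == level).any():
                    cols[f"age_at_hurricane[T.{level}]"] = (
                        (observed == level).to_numpy(dtype=float)
                    )
        else:
            raise ValueError(f"unknown fixed-effect term {term!r}")
    design = pd.DataFrame(cols, index=data.index)
    if len(data) <= design.shape[1]:
        raise ValueError(
            f"{len(data)} observations cannot identify {design.shape[1]} "
            "fixed-effect parameters"
        )
    return design


def _check_levels(series: pd.Series, term: str) -> None:
    if series.nunique() < 2:
        raise ValueError(
            f"fixed effect {term!r} has a single observed level "
            f"({series.unique()[0]!r}) in this subset"
        )


# ---------------------------------------------------------------------------
# REML restricted likelihood for the random-intercept structure
# (used for Satterthwaite curvature; fitting itself is statsmodels MixedLM)
# ---------------------------------------------------------------------------

def _blocks(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    order = np.argsort(groups, kind="stable")
    Xs, ys, gs = X[order], y[order], groups[order]
    edges = np.flatnonzero(np.r_[True, gs[1:] != gs[:-1], True])
    return [(Xs[a:b], ys[a:b]) for a, b in zip(edges[:-1], edges[1:])]


def _gls_pieces(theta: np.ndarray, blocks) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Accumulate X'V^-1 X, X'V^-1 y, y'V^-1 y and log|V| (Woodbury per group)."""
    sb2, se2 = float(theta[0]), float(theta[1])
    k = blocks[0][0].shape[1]
    xtvx = np.zeros((k, k))
    xtvy = np.zeros(k)
    ytvy = 0.0
    logdet = 0.0
    for Xg, yg in blocks:
        ng = len(yg)
        denom = se2 + ng * sb2
        c = sb2 / (se2 * denom)
        sx = Xg.sum(axis=0)
        sy = yg.sum()
        xtvx += Xg.T @ Xg / se2 - c * np.outer(sx, sx)
        xtvy += Xg.T @ yg / se2 - c * sx * sy
        ytvy += yg @ yg / se2 - c * sy * sy
        logdet += (ng - 1) * np.log(se2) + np.log(denom)
    return xtvx, xtvy, ytvy, logdet


def reml_loglike(theta: np.ndarray, blocks) -> float:
    """Restricted log-likelihood (up to constant) at variance params (sb2, se2)."""
    if theta[0] < 0 or theta[1] <= 0:
        return -np.inf
    xtvx, xtvy, ytvy, logdet = _gls_pieces(theta, blocks)
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(xtvx, xtvy)
    quad = ytvy - beta @ xtvy
    return -0.5 * (logdet + logdet_x + quad)


def coef_variance(theta: np.ndarray, blocks, contrast: np.ndarray) -> float:
    xtvx, _, _, _ = _gls_pieces(theta, blocks)
    return float(contrast @ np.linalg.solve(xtvx, contrast))


def satterthwaite_df(
    theta: np.ndarray, blocks, contrast: np.ndarray, *, rel_step: float = 1e-4
) -> float:
    """Satterthwaite denominator df for a fixed-effect contrast.

    ``df = 2 f^2 / (g' A g)`` with ``f = c' Var(beta) c`` evaluated at the
    REML estimate, ``g`` its gradient in the variance parameters (finite
    differences) and ``A`` the inverse observed information of the restricted
    likelihood (finite-difference Hessian).
    """
    theta = np.asarray(theta, dtype=float)
    steps = np.maximum(np.abs(theta), 1e-3 * theta[1]) * rel_step

    def f(t):
        return coef_variance(t, blocks, contrast)

    grad = np.empty(2)
    for i in range(2):
        e = np.zeros(2)
        e[i] = steps[i]
        lo = theta - e
        if lo[0] < 0:  # one-sided at the boundary
            grad[i] = (f(theta + e) - f(theta)) / steps[i]
        else:
            grad[i] = (f(theta + e) - f(lo)) / (2 * steps[i])

    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(i, 2):
            ei, ej = np.zeros(2), np.zeros(2)
            ei[i], ej[j] = steps[i], steps[j]
            if (theta - ei - ej)[0] < 0:
                base = reml_loglike(theta, blocks)
                hess[i, j] = (
                    reml_loglike(theta + ei + ej, blocks)
                    - reml_loglike(theta + ei, blocks)
                    - reml_loglike(theta + ej, blocks)
                    + base
                ) / (steps[i] * steps[j])
            else:
                hess[i, j] = (
                    reml_loglike(theta + ei + ej, blocks)
                    - reml_loglike(theta + ei - ej, blocks)
                    - reml_loglike(theta - ei + ej, blocks)
                    + reml_loglike(theta - ei - ej, blocks)
                ) / (4 * steps[i] * steps[j])
            hess[j, i] = hess[i, j]
    info = -hess
    try:
        a = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return np.nan
    denom = float(grad @ a @ grad)
    if denom <= 0:
        return np.nan
    fval = f(theta)
    return max(1.0, 2.0 * fval * fval / denom)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class FAMixedModel:
    """Random-intercept mixed model for FA scores.

    Parameters
    ----------
    data
        Joined FA-score + metadata table (one row per individual) with at
        least ``fa_score``, ``matriline`` and the covariate columns.
    spec
        :class:`ModelSpec` naming the fixed effects and subset rule.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        if data["matriline"].nunique() < 2:
            raise ValueError("need at least 2 matrilines for a random intercept")
        if data[["fa_score", "age_at_death", "decade_of_birth"]].isna().any().any():
            raise ValueError("missing covariate or response values")
        self.spec = spec
        self.data = apply_subset(data, spec.subset)
        if self.data.empty:
            raise ValueError(f"subset {spec.subset!r} selects no individuals")
        self.design = build_design(self.data, spec.fixed)
        self.groups = self.data["matriline"].to_numpy()
        self.endog = self.data["fa_score"].to_numpy(dtype=float)

    def _exact_results(self, X: np.ndarray, beta: np.ndarray) -> "FAMixedResults":
        names = list(self.design.columns)
        n_obs, k = X.shape
        zeros = pd.Series(np.zeros(k), index=names)
        resid_df = float(n_obs - k)
        return FAMixedResults(
            model=self,
            params=pd.Series(beta, index=names),
            bse=zeros.copy(),
            df=pd.Series(np.full(k, resid_df), index=names),
            tvalues=pd.Series(np.where(beta != 0, np.inf, 0.0), index=names),
            pvalues=pd.Series(np.where(beta != 0, 0.0, 1.0), index=names),
            cov_params=pd.DataFrame(np.zeros((k, k)), index=names, columns=names),
            sigma_matriline2=0.0,
            sigma_resid2=0.0,
            reml_criterion=np.inf,
            n_obs=int(n_obs),
            n_groups=int(pd.unique(self.groups).size),
            boundary=True,
            df_method="residual",
            converged=True,
        )

    @classmethod
    def from_scores(
        cls, scores: pd.DataFrame, metadata: pd.DataFrame, spec: ModelSpec
    ) -> "FAMixedModel":
        merged = metadata.merge(scores[["specimen_id", "fa_score"]], on="specimen_id",
                                validate="one_to_one")
        return cls(merged, spec)

    def fit(self, df_method: str = "satterthwaite") -> "FAMixedResults":
        """REML fit; ``df_method`` is "satterthwaite" or "residual"."""
        if df_method not in ("satterthwaite", "residual"):
            raise ValueError(df_method)
        X = self.design.to_numpy(dtype=float)
        # FA scores are O(1e-2); fit on a standardized response for optimizer
        # health and convert the variance components back afterwards.
        y_scale = float(np.std(self.endog))
        if y_scale <= 0:
            raise ValueError("response has zero variance")
        # Degenerate noise-free case: the response is an exact linear function
        # of the design, REML has no interior optimum.  Return the exact
        # (OLS-interpolating) coefficients with zero variance components.
        ols_beta, *_ = np.linalg.lstsq(X, self.endog, rcond=None)
        resid_ss = float(((self.endog - X @ ols_beta) ** 2).sum())
        if resid_ss <= 1e-24 * float(self.endog @ self.endog):
            logger.info("%s: response is noise-free; exact interpolation",
                        self.spec.name)
            return self._exact_results(X, ols_beta)
        sm_model = MixedLM(self.endog / y_scale, X, groups=self.groups)
        sm_fit = None
        last_err: Exception | None = None
        for method in ("bfgs", "powell", "nm"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sm_fit = sm_model.fit(reml=True, method=method)
                if getattr(sm_fit, "converged", True):
                    break
            except (np.linalg.LinAlgError, ValueError) as err:
                last_err = err
        if sm_fit is None:
            raise RuntimeError(f"REML optimization failed: {last_err}")
        sigma_b2 = float(np.asarray(sm_fit.cov_re)[0, 0]) * y_scale**2
        sigma_e2 = float(sm_fit.scale) * y_scale**2
        boundary = sigma_b2 <= BOUNDARY_RATIO * sigma_e2
        if boundary:
            logger.info(
                "%s: matriline variance at boundary (%.3g); clamped to 0, "
                "using residual df", self.spec.name, sigma_b2,
            )
            sigma_b2 = 0.0
        theta = np.array([sigma_b2, sigma_e2])
        blocks = _blocks(X, self.endog, self.groups)
        xtvx, xtvy, _, _ = _gls_pieces(theta, blocks)
        cov_beta = np.linalg.inv(xtvx)
        params = np.linalg.solve(xtvx, xtvy)
        bse = np.sqrt(np.diag(cov_beta))
        names = list(self.design.columns)
        n_obs, k = X.shape
        resid_df = float(n_obs - k)
        dfs = np.empty(k)
        if df_method == "residual" or boundary:
            if df_method == "satterthwaite" and boundary:
                pass  # note already logged
            dfs[:] = resid_df
        else:
            for j in range(k):
                c = np.zeros(k)
                c[j] = 1.0
                d = satterthwaite_df(theta, blocks, c)
                dfs[j] = d if np.isfinite(d) else resid_df
        tvals = params / bse
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dfs)
        return FAMixedResults(
            model=self,
            params=pd.Series(params, index=names),
            bse=pd.Series(bse, index=names),
            df=pd.Series(dfs, index=names),
            tvalues=pd.Series(tvals, index=names),
            pvalues=pd.Series(pvals, index=names),
            cov_params=pd.DataFrame(cov_beta, index=names, columns=names),
            sigma_matriline2=sigma_b2,
            sigma_resid2=sigma_e2,
            reml_criterion=float(reml_loglike(theta, blocks)),
            n_obs=int(n_obs),
            n_groups=int(pd.unique(self.groups).size),
            boundary=boundary,
            df_method="residual" if (df_method == "residual" or boundary)
            else "satterthwaite",
            converged=bool(getattr(sm_fit, "converged", True)),
            _theta=theta,
            _blocks=blocks,
        )


@dataclass
class FAMixedResults:
    """REML estimates, Satterthwaite t tests and variance components."""

    model: FAMixedModel
    params: pd.Series
    bse: pd.Series
    df: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    sigma_matriline2: float
    sigma_resid2: float
    reml_criterion: float
    n_obs: int
    n_groups: int
    boundary: bool
    df_method: str
    converged: bool
    _theta: np.ndarray = field(repr=False, default=None)
    _blocks: list = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Estimate": self.params,
                "Standard error": self.bse,
                "df": self.df,
                "t-value": self.tvalues,
                "p-value": self.pvalues,
            }
        )

    def contrast(self, c: np.ndarray) -> tuple[float, float]:
        """Estimate and SE of a linear combination of fixed effects."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.params.to_numpy())
        se = float(np.sqrt(c @ self.cov_params.to_numpy() @ c))
        return est, se

    def wald_joint(self, term: str) -> tuple[float, int, float]:
        """Joint Wald chi-square test that all coefficients of a factor are 0."""
        idx = [i for i, n in enumerate(self.params.index) if n.startswith(f"{term}[")]
        if not idx:
            raise ValueError(f"factor {term!r} not in the fitted model")
        b = self.params.to_numpy()[idx]
        v = self.cov_params.to_numpy()[np.ix_(idx, idx)]
        w = float(b @ np.linalg.solve(v, b))
        dof = len(idx)
        return w, dof, float(stats.chi2.sf(w, dof))


def fit_lmm(
    scores: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    spec: ModelSpec | None = None,
    df_method: str = "satterthwaite",
) -> FAMixedResults:
    """Fit one mixed-model variant to a joined (or separate) score table."""
    spec = spec or MODEL_SUITE[0]
    if metadata is None:
        model = FAMixedModel(scores, spec)
    else:
        model = FAMixedModel.from_scores(scores, metadata, spec)
    return model.fit(df_method=df_method)


def run_model_suite(
    data: pd.DataFrame, df_method: str = "satterthwaite"
) -> dict[str, FAMixedResults]:
    """Fit the four standard model variants to a joined score table."""
    return {spec.name: fit_lmm(data, spec=spec, df_method=df_method)
            for spec in MODEL_SUITE}


# ---------------------------------------------------------------------------
# Post hoc contrasts
# ---------------------------------------------------------------------------

FACTOR_LEVELS = {
    "age_at_hurricane": ("fetal", "juvenile", "adult"),
    "n_hurricanes": ("0", "1", "2"),
}


def posthoc_holm(
    result: FAMixedResults, factor: str = "age_at_hurricane"
) -> pd.DataFrame:
    """All pairwise level contrasts of a fitted factor, Holm-adjusted.

    z statistics use the fitted coefficient covariance (the usual large-sample
    treatment of pairwise comparisons on mixed models); the Holm stepdown is
    applied over the full family of pairwise contrasts.
    """
    names = list(result.params.index)
    prefix = f"{factor}[T."
    level_cols = {n[len(prefix):-1]: i for i, n in enumerate(names)
                  if n.startswith(prefix)}
    if not level_cols:
        raise ValueError(f"factor {factor!r} not in the fitted model")
    reference = next(
        lv for lv in FACTOR_LEVELS.get(factor, ()) if lv not in level_cols
    ) if factor in FACTOR_LEVELS else "reference"
    levels = [reference] + list(level_cols)
    k = len(names)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        c = np.zeros(k)
        if a in level_cols:
            c[level_cols[a]] += 1.0
        if b in level_cols:
            c[level_cols[b]] -= 1.0
        est, se = result.contrast(c)
        z = est / se
        rows.append(
            {"contrast": f"{a} - {b}", "estimate": est, "std_error": se,
             "z_value": z, "raw_p": 2.0 * stats.norm.sf(abs(z))}
        )
    out = pd.DataFrame(rows)
    out["adjusted_p"] = holm_adjust(out["raw_p"].to_numpy())
    return out


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Bonferroni-Holm stepdown adjustment (delegates to statsmodels)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]


# ---------------------------------------------------------------------------
# Simulation-based power analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerResult:
    """Estimated power per effect size (% change in mean FA score)."""

    effect_grid: tuple[float, ...]
    power: tuple[float, ...]
    n_sims: int
    alpha: float
    seed: int
    target_term: str

    def to_dataframe(self) -> pd.DataFrame:
        se = [np.sqrt(p * (1 - p) / self.n_sims) for p in self.power]
        return pd.DataFrame(
            {"effect_pct": self.effect_grid, "power": self.power, "mc_se": se}
        )

    def smallest_detectable(self, target_power: float = 0.8) -> float | None:
        """Smallest grid effect size reaching the target power, if any."""
        for e, p in zip(self.effect_grid, self.power):
            if p >= target_power:
                return e
        return None


def power_simulation(
    metadata: pd.DataFrame,
    effect_grid=(0.0, 2.5, 5.0, 7.5, 10.0),
    n_sims: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    *,
    baseline_mean: float = 0.015,
    sigma_matriline: float = 0.001,
    sigma_residual: float = 0.004,
    spec: ModelSpec | None = None,
    target_term: str = "hurricane_yn[T.True]",
) -> PowerResult:
    """Estimate power to detect a % change in mean FA in the exposed group.

    For each effect size ``e`` (% of the baseline mean FA), scores are
    simulated over the supplied metadata from the variance components, with
    an additive offset ``e/100 * baseline_mean`` for the group the target
    term marks; the model is refit and the proportion of simulations with
    ``p < alpha`` for that term is recorded.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    spec = spec or MODEL_SUITE[0]
    factor_col = {
        "hurricane_yn[T.True]": metadata["hurricane_experienced"].to_numpy(dtype=float),
        "age_at_hurricane[T.juvenile]":
            (metadata["age_at_hurricane"] == "juvenile").to_numpy(dtype=float),
        "age_at_hurricane[T.adult]":
            (metadata["age_at_hurricane"] == "adult").to_numpy(dtype=float),
    }.get(target_term)
    if factor_col is None:
        raise ValueError(f"unsupported target term {target_term!r}")
    mats = sorted(metadata["matriline"].unique())
    root = np.random.SeedSequence(seed)
    powers = []
    for e_i, effect in enumerate(effect_grid):
        rng = np.random.default_rng(root.spawn(1)[0])
        hits = 0
        offset = effect / 100.0 * baseline_mean
        for _ in range(n_sims):
            b = dict(zip(mats, rng.normal(0.0, sigma_matriline, len(mats))))
            y = (
                baseline_mean
                + offset * factor_col
                + metadata["matriline"].map(b).to_numpy()
                + rng.normal(0.0, sigma_residual, len(metadata))
            )
            df = metadata.copy()
            df["fa_score"] = y
            res = fit_lmm(df, spec=spec)
            if res.pvalues[target_term] < alpha:
                hits += 1
        powers.append(hits / n_sims)
    return PowerResult(
        effect_grid=tuple(float(e) for e in effect_grid),
        power=tuple(powers),
        n_sims=n_sims,
        alpha=alpha,
        seed=seed,
        target_term=target_term,
    )
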