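"""Linear mixed models of early white-matter development.

The analysis proceeds in stages, all built on a single random-intercept
linear mixed model (LMM):

1. mean-bundle development — per bundle, bundle-mean R1 (or MD) against age
   in days with a random intercept per subject; the fitted slope is the
   bundle's development rate;
2. node-wise development — the same model fitted independently at each of
   the 100 nodes of each bundle, giving a development map (newborn value,
   slope, |x|/y/z node coordinates);
3. slope models over the development map (every 10th node for spatial
   independence, random intercept per bundle):

   * model 1 (speed-up):          slope ~ 1 + newborn + (1|bundle)
   * model 2 (spatial gradient):  slope ~ 1 + |x| + y + z
                                          + |x|*y + |x|*z + y*z + (1|bundle)
   * model 3 (combined):          union of the fixed terms,

   with a likelihood-ratio test (ML refits, df = 1) of model 3 against
   model 2.  Coordinates are z-scored (sample SD) before interactions are
   formed.

Estimation is REML for reported fits and ML for likelihood-ratio tests.
R^2 is marginal: the squared correlation between the fixed-effects-only
prediction and the response; the adjusted variant applies the standard
1 - (1 - R^2)(n - 1)/(n - p - 1) penalty.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "LMMResult", "LMMSpec", "LRTResult", "SlopeModelComparison", "TractLMM",
    "compare_random_slope", "correlate_across_bundles",
    "fit_lmm", "fit_mean_bundle_development", "fit_nodewise_development",
    "fit_slope_models", "refit_excluding_node_range", "simulate_slope_table",
    "subsample_every_kth", "zscore_coords",
]

SPATIAL_TERMS = ["zx", "zy", "zz", "zx_zy", "zx_zz", "zy_zz"]


@dataclasses.dataclass(frozen=True)
class LMMSpec:
    """Fixed/random structure of one LMM.

    ``fixed_terms`` are column names of the data frame (the intercept is
    always included and not listed); ``group`` is the random-intercept
    grouping column; ``random_slope`` adds a per-group random slope on
    ``random_slope_term``.
    """

    response: str
    fixed_terms: tuple[str, ...]
    group: str
    random_slope: bool = False
    random_slope_term: str = "age_days"

    def formula(self) -> str:
        rhs = " + ".join(("1",) + self.fixed_terms)
        re = (f"(1 + {self.random_slope_term}|{self.group})"
              if self.random_slope else f"(1|{self.group})")
        return f"{self.response} ~ {rhs} + {re}"


@dataclasses.dataclass
class LMMResult:
    """Estimates and diagnostics of a fitted LMM (one random intercept).

    ``beta``/``se``/``pvalue`` are indexed by term name ("Intercept"
    first).  ``loglik`` is the REML or ML log-likelihood according to
    ``reml``; likelihood-ratio tests must use ML fits.
    """

    spec: LMMSpec
    beta: pd.Series
    se: pd.Series
    pvalue: pd.Series
    var_random_intercept: float
    var_residual: float
    loglik: float
    n_obs: int
    n_groups: int
    r2_marginal: float
    r2_adjusted: float
    reml: bool
    converged: bool

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({"lower": self.beta - z * self.se,
                             "upper": self.beta + z * self.se})

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"Linear mixed model: {self.spec.formula()}",
            f"  estimator: {'REML' if self.reml else 'ML'}   "
            f"n_obs={self.n_obs}  n_groups={self.n_groups}  "
            f"loglik={self.loglik:.3f}",
            f"  var(random intercept)={self.var_random_intercept:.4g}  "
            f"var(residual)={self.var_residual:.4g}",
            f"  R2 (marginal)={self.r2_marginal:.3f}  "
            f"adjusted={self.r2_adjusted:.3f}",
            f"  {'term':<14}{'beta':>12}{'SE':>11}{'p':>10}"
            f"{'95% CI':>24}",
        ]
        for term in self.beta.index:
            lines.append(
                f"  {term:<14}{self.beta[term]:>12.4g}{self.se[term]:>11.3g}"
                f"{self.pvalue[term]:>10.3g}"
                f"   [{ci.loc[term, 'lower']:.4g}, {ci.loc[term, 'upper']:.4g}]"
            )
        return "\n".join(lines)


@dataclasses.dataclass
class LRTResult:
    statistic: float
    df: int
    pvalue: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha


class TractLMM:
    """Model object for a single random-intercept LMM on a long table."""

    def __init__(self, data: pd.DataFrame, spec: LMMSpec):
        cols = [spec.response, *spec.fixed_terms, spec.group]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"columns missing from data: {missing}")
        data = data.dropna(subset=[spec.response, *spec.fixed_terms])
        if data[spec.group].nunique() < 2:
            raise ValueError("need >= 2 groups for a random intercept")
        self.data = data.reset_index(drop=True)
        self.spec = spec

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       fixed_terms, group: str, **kw) -> "TractLMM":
        return cls(data, LMMSpec(response, tuple(fixed_terms), group, **kw))

    def fit(self, reml: bool = True) -> LMMResult:
        spec, df = self.spec, self.data
        y = df[spec.response].to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(len(df))] + [df[t].to_numpy(dtype=float)
                                  for t in spec.fixed_terms])
        names = ["Intercept", *spec.fixed_terms]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular fixed-effects design")
        groups = df[spec.group].to_numpy()
        exog_re = None
        if spec.random_slope:
            exog_re = np.column_stack(
                [np.ones(len(df)), df[spec.random_slope_term].to_numpy(float)])
        # Rescale the response to unit SD before optimisation: development
        # rates are ~1e-3 with residual variances ~1e-10, which makes the
        # raw profiled likelihood numerically singular.  Estimates, SEs and
        # variances transform back exactly; log-likelihoods get the exact
        # Jacobian correction so LRTs are unaffected.
        scale = float(np.std(y))
        if scale == 0:
            scale = 1.0
        model = MixedLM(y / scale, X, groups=groups, exog_re=exog_re)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            try:
                res = model.fit(reml=reml, method=["lbfgs", "bfgs", "cg"])
            except np.linalg.LinAlgError:
                res = model.fit(reml=reml, method="powell")
            fe, bse_fe = np.asarray(res.fe_params), np.asarray(res.bse_fe)
        n_eff = len(y) - (0 if not reml else X.shape[1])
        loglik = float(res.llf) - n_eff * np.log(scale)
        beta = pd.Series(fe * scale, index=names)
        se = pd.Series(bse_fe * scale, index=names)
        pval = pd.Series(2 * stats.norm.sf(np.abs(beta / se)), index=names)
        fixed_pred = X @ beta.to_numpy()
        if np.std(fixed_pred) > 0 and np.std(y) > 0:
            r2 = float(np.corrcoef(fixed_pred, y)[0, 1] ** 2)
        else:
            r2 = 0.0
        n, p = len(y), X.shape[1] - 1
        r2_adj = (1 - (1 - r2) * (n - 1) / (n - p - 1)) if n - p - 1 > 0 else np.nan
        return LMMResult(
            spec=spec, beta=beta, se=se, pvalue=pval,
            var_random_intercept=float(np.asarray(res.cov_re)[0, 0]) * scale**2,
            var_residual=float(res.scale) * scale**2,
            loglik=loglik, n_obs=n,
            n_groups=int(pd.Series(groups).nunique()),
            r2_marginal=r2, r2_adjusted=float(r2_adj),
            reml=reml, converged=bool(res.converged),
        )


def fit_lmm(table: pd.DataFrame, spec: LMMSpec, reml: bool = True) -> LMMResult:
    return TractLMM(table, spec).fit(reml=reml)


# ---------------------------------------------------------------------------
# stage 1: mean-bundle development

def _bundle_session_means(profile_table: pd.DataFrame, metric: str
                          ) -> pd.DataFrame:
    t = profile_table[profile_table["metric"] == metric]
    if t.empty:
        raise ValueError(f"no rows with metric {metric!r}")
    g = (t.dropna(subset=["value"])
          .groupby(["bundle", "subject", "age_days", "timepoint"], sort=True))
    return g["value"].mean().reset_index()


def fit_mean_bundle_development(profile_table: pd.DataFrame, metric: str
                                ) -> pd.DataFrame:
    """Per-bundle LMM of bundle-mean metric against age.

    Returns one row per bundle: slope (units/day), slope_se, intercept,
    newborn_mean and newborn_se (measured across newborn subjects),
    r2_adjusted, and the LMMResult object in the ``fit`` column.
    """
    means = _bundle_session_means(profile_table, metric)
    rows = []
    for bundle, sub in means.groupby("bundle", sort=True):
        if sub["timepoint"].nunique() < 2:
            raise ValueError(f"bundle {bundle}: >= 2 timepoints required")
        res = fit_lmm(sub, LMMSpec("value", ("age_days",), "subject"))
        nb = sub[sub["timepoint"] == "0m"]["value"]
        rows.append({
            "bundle": bundle,
            "slope": res.beta["age_days"], "slope_se": res.se["age_days"],
            "intercept": res.beta["Intercept"],
            "newborn_mean": nb.mean() if len(nb) else np.nan,
            "newborn_se": nb.sem() if len(nb) > 1 else np.nan,
            "r2_adjusted": res.r2_adjusted,
            "fit": res,
        })
    return pd.DataFrame(rows)


def compare_random_slope(table: pd.DataFrame, spec: LMMSpec) -> LRTResult:
    """LRT of random intercept + slope against random intercept only.

    Both models are ML-fitted; the reference distribution is chi-square
    with df = 2 (the extra slope variance and intercept-slope covariance).
    """
    base = fit_lmm(table, dataclasses.replace(spec, random_slope=False),
                   reml=False)
    full = fit_lmm(table, dataclasses.replace(spec, random_slope=True),
                   reml=False)
    stat = max(0.0, 2.0 * (full.loglik - base.loglik))
    df = 2
    p = 1.0 if stat == 0 else float(stats.chi2.sf(stat, df))
    return LRTResult(stat, df, p)


# ---------------------------------------------------------------------------
# stage 2: node-wise development map

def fit_nodewise_development(profile_table: pd.DataFrame, metric: str,
                             nodes: list[int] | None = None) -> pd.DataFrame:
    """One LMM per (bundle, node): metric ~ age with subject intercepts.

    Returns the development map: bundle, node, slope, slope_se,
    newborn_mean (mean across newborn subjects at that node) and the
    average newborn (|x|, y, z) node coordinates.  Nodes whose values are
    all missing are flagged (``missing`` = True), not fatal.
    """
    t = profile_table[profile_table["metric"] == metric]
    if t.empty:
        raise ValueError(f"no rows with metric {metric!r}")
    if nodes is not None:
        t = t[t["node"].isin(nodes)]
    from .profiles import node_coordinates_table
    coords = node_coordinates_table(t).set_index(["bundle", "node"])

    rows = []
    for (bundle, node), sub in t.groupby(["bundle", "node"], sort=True):
        sub = sub.dropna(subset=["value"])
        row = {"bundle": bundle, "node": int(node)}
        if (bundle, node) in coords.index:
            c = coords.loc[(bundle, node)]
            row.update(x_abs=c["x_abs"], y=c["y"], z=c["z"])
        else:
            row.update(x_abs=np.nan, y=np.nan, z=np.nan)
        nb = sub[sub["timepoint"] == "0m"]["value"]
        row["newborn_mean"] = nb.mean() if len(nb) else np.nan
        if sub.empty or sub["subject"].nunique() < 2:
            row.update(slope=np.nan, slope_se=np.nan, missing=True)
        else:
            res = fit_lmm(sub, LMMSpec("value", ("age_days",), "subject"))
            row.update(slope=res.beta["age_days"],
                       slope_se=res.se["age_days"], missing=False)
        rows.append(row)
    return pd.DataFrame(rows)


def subsample_every_kth(dev_map: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Keep nodes k, 2k, ... (1-based) of each bundle for spatial independence."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return dev_map.copy()
    return dev_map[dev_map["node"] % k == 0].reset_index(drop=True)


def zscore_coords(dev_map: pd.DataFrame) -> pd.DataFrame:
    """Standardise |x|, y, z (sample SD) and form interaction columns."""
    if len(dev_map) < 2:
        raise ValueError("need >= 2 rows to z-score coordinates")
    out = dev_map.copy()
    for col, zcol in (("x_abs", "zx"), ("y", "zy"), ("z", "zz")):
        v = out[col].to_numpy(dtype=float)
        sd = np.std(v, ddof=1)
        if sd == 0:
            raise ValueError(f"coordinate {col} has zero variance")
        out[zcol] = (v - v.mean()) / sd
    out["zx_zy"] = out["zx"] * out["zy"]
    out["zx_zz"] = out["zx"] * out["zz"]
    out["zy_zz"] = out["zy"] * out["zz"]
    return out


# ---------------------------------------------------------------------------
# stage 3: slope models

@dataclasses.dataclass
class SlopeModelComparison:
    """The three slope models and the model-3 vs model-2 LRT."""

    model1: LMMResult           # slope ~ newborn value
    model2: LMMResult           # slope ~ spatial coordinates
    model3: LMMResult           # combined
    lrt_3_vs_2: LRTResult

    def summary(self) -> str:
        parts = ["=== model 1: speed-up ===", self.model1.summary(),
                 "=== model 2: spatial gradients ===", self.model2.summary(),
                 "=== model 3: combined ===", self.model3.summary(),
                 f"LRT model 3 vs model 2: stat={self.lrt_3_vs_2.statistic:.3f}"
                 f" df={self.lrt_3_vs_2.df} p={self.lrt_3_vs_2.pvalue:.4g}"]
        return "\n".join(parts)


def fit_slope_models(dev_map_subsampled: pd.DataFrame,
                     newborn_col: str = "newborn_mean"
                     ) -> SlopeModelComparison:
    """Fit the three slope models on a (subsampled, z-scored) development map."""
    d = dev_map_subsampled
    if "zx" not in d.columns:
        d = zscore_coords(d)
    if d["bundle"].nunique() < 2:
        raise ValueError("need >= 2 bundles")
    d = d.dropna(subset=["slope", newborn_col, "x_abs", "y", "z"])
    if d.empty:
        raise ValueError("empty table after dropping missing rows")

    s1 = LMMSpec("slope", (newborn_col,), "bundle")
    s2 = LMMSpec("slope", tuple(SPATIAL_TERMS), "bundle")
    s3 = LMMSpec("slope", (newborn_col, *SPATIAL_TERMS), "bundle")
    m1 = fit_lmm(d, s1)
    m2 = fit_lmm(d, s2)
    m3 = fit_lmm(d, s3)
    # LRT needs ML fits; df = 1 extra fixed term in model 3
    m2_ml = fit_lmm(d, s2, reml=False)
    m3_ml = fit_lmm(d, s3, reml=False)
    stat = max(0.0, 2.0 * (m3_ml.loglik - m2_ml.loglik))
    p = 1.0 if stat == 0 else float(stats.chi2.sf(stat, 1))
    return SlopeModelComparison(m1, m2, m3, LRTResult(stat, 1, p))


def refit_excluding_node_range(dev_map: pd.DataFrame, k: int = 10,
                               exclude_first: int = 10,
                               exclude_last: int = 10,
                               n_nodes: int = 100) -> SlopeModelComparison:
    """Drop the end nodes (default first/last 10), subsample, refit models.

    Checks that the slope-model effects are not driven by nodes close to
    cortical gray matter at the bundle endpoints.
    """
    keep = dev_map[(dev_map["node"] > exclude_first)
                   & (dev_map["node"] <= n_nodes - exclude_last)]
    if keep.empty:
        raise ValueError("empty table: all nodes excluded")
    return fit_slope_models(zscore_coords(subsample_every_kth(keep, k)))


def correlate_across_bundles(xs, ys) -> tuple[float, float, float]:
    """Across-bundle OLS scatter (one point per bundle) -> (R^2, p, slope)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 3:
        raise ValueError("need >= 3 bundle pairs")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("constant input has no defined correlation")
    res = stats.linregress(xs, ys)
    return float(res.rvalue**2), float(res.pvalue), float(res.slope)


# ---------------------------------------------------------------------------
# synthetic slope tables (coefficient-recovery experiments)

def simulate_slope_table(coords: pd.DataFrame, betas: dict[str, float],
                         residual_sd: float, seed: int,
                         newborn_col: str = "newborn_mean") -> pd.DataFrame:
    """Generate node-level slopes from the slope-model formula.

    ``coords`` needs bundle, node, x_abs, y, z (and ``newborn_col`` when
    betas has a 'newborn' entry).  Recognised beta keys: intercept, zx, zy,
    zz, zx_zy, zx_zz, zy_zz, newborn.  Coordinates are z-scored before the
    linear predictor is formed; gaussian residual noise with SD
    ``residual_sd`` is added.  The returned table is ready for
    fit_slope_models.
    """
    d = zscore_coords(coords.copy())
    rng = np.random.default_rng(seed)
    slope = np.full(len(d), betas.get("intercept", 0.0), dtype=float)
    for term in SPATIAL_TERMS:
        slope += betas.get(term, 0.0) * d[term].to_numpy()
    if "newborn" in betas:
        slope += betas["newborn"] * d[newborn_col].to_numpy(dtype=float)
    slope += rng.normal(0.0, residual_sd, size=len(d))
    d["slope"] = slope
    d["slope_se"] = residual_sd
    return d
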