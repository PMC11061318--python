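"""Panel assembly, fixed-effects OLS and two-stage least squares.

The structural model links a city's daily median sentiment to its
extreme-temperature indices and weather controls,

    Sentiment_it = b0 + b1 EHT_it + b2 ELT_it + b'X_it + T_t + g_i + e_it ,

with city fixed effects g_i absorbing time-invariant city traits and a
time fixed effect T_t (day-of-week dummies by default, or the 24 solar
terms).  City fixed effects are absorbed by within-demeaning; the
within estimator equals explicit city-dummy OLS (Frisch-Waugh).
Standard errors are cluster-robust by city: the CR1 sandwich

    V = c (X'X)^{-1} [ sum_g X_g' u_g u_g' X_g ] (X'X)^{-1} ,
    c = G/(G-1) * (N-1)/(N-k) ,

where k counts slope columns plus absorbed fixed-effect levels, and
p-values use a t distribution with G-1 degrees of freedom.

Because extreme temperature on a given city-day may correlate with
unobserved local shocks (an urban heat island heating tempers and
temperatures alike), the endogenous indices can be instrumented by the
altitude-corrected neighbor means NEHT/NELT: stage one projects each
endogenous regressor on instruments plus all exogenous terms, stage two
replaces it with the fitted value, and the final clustered covariance
evaluates structural residuals at the *original* regressors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calendars import solar_terms_of

log = logging.getLogger("thermosent")

DEFAULT_CONTROLS = ["PM25", "WS", "P", "CCD"]


@dataclass
class PanelSpec:
    """One estimation specification (outcome, regressors, FE, IV)."""

    outcome: str = "sentiment"
    regressors: list[str] = field(default_factory=lambda: ["EHT", "ELT"])
    controls: list[str] = field(default_factory=lambda: list(DEFAULT_CONTROLS))
    interactions: list[tuple[str, str]] = field(default_factory=list)
    fe_city: bool = True
    fe_time: str = "dow"  # dow | solar | week_of_year | none
    cluster: str = "city_id"
    standardize: list[str] = field(default_factory=list)
    endogenous: list[str] = field(default_factory=list)
    instruments: list[str] = field(default_factory=list)

    def active_variables(self) -> list[str]:
        cols = [self.outcome, *self.regressors, *self.controls, *self.instruments]
        cols += [m for _, m in self.interactions]
        seen: list[str] = []
        for c in cols:
            if c not in seen:
                seen.append(c)
        return seen


@dataclass
class RegressionResult:
    terms: list[str]
    params: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    n: int
    n_clusters: int
    r2_within: float
    r2_overall: float
    fe_absorbed: int
    extra: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])

    def stderr(self, term: str) -> float:
        return float(self.se[self.terms.index(term)])

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        t = stats.t.ppf(0.5 + level / 2, df=self.n_clusters - 1)
        i = self.terms.index(term)
        return (float(self.params[i] - t * self.se[i]),
                float(self.params[i] + t * self.se[i]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "estimate": self.params,
            "se_cluster": self.se,
            "p_value": self.pvalues,
            "n": self.n,
            "r2_within": self.r2_within,
            "r2_overall": self.r2_overall,
            "n_clusters": self.n_clusters,
        })


@dataclass
class IVResult:
    second_stage: RegressionResult
    first_stage: dict[str, RegressionResult]
    diagnostics: dict

    def to_frame(self) -> pd.DataFrame:
        frames = [self.second_stage.to_frame().assign(stage="2")]
        for name, res in self.first_stage.items():
            frames.append(res.to_frame().assign(stage=f"1:{name}"))
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# panel assembly

def build_panel(weather: pd.DataFrame, indices: pd.DataFrame,
                sentiment: pd.DataFrame, instruments: pd.DataFrame | None = None,
                meta: pd.DataFrame | None = None,
                spec: PanelSpec | None = None) -> pd.DataFrame:
    """Inner-join the component tables into the estimation panel.

    Applies listwise deletion on the spec's active variables (with a
    per-variable missingness report in ``attrs["missingness"]``),
    z-scores the requested regressors over the retained sample (raw
    copies kept as ``<col>_raw``, scale in ``attrs["standardize_sd"]``),
    and derives day-of-week, weekend, and solar-term labels plus any
    interaction columns (standardized index x raw moderator).
    """
    spec = spec or PanelSpec()
    df = weather.merge(indices, on=["city_id", "date"], how="inner")
    df = df.merge(sentiment, on=["city_id", "date"], how="inner")
    if instruments is not None:
        df = df.merge(instruments, on=["city_id", "date"], how="inner")
    if meta is not None:
        df = df.merge(meta, on="city_id", how="left")

    dts = pd.DatetimeIndex(df["date"])
    df["dow"] = dts.dayofweek  # 0=Mon .. 6=Sun
    df["weekend"] = (df["dow"] >= 5).astype(int)
    df["week_of_year"] = dts.isocalendar().week.to_numpy().astype(int)
    df["solar_term"] = solar_terms_of(df["date"]).to_numpy()

    active = [c for c in spec.active_variables() if c in df.columns]
    absent = set(spec.active_variables()) - set(df.columns)
    if absent:
        raise KeyError(f"specification names absent columns: {sorted(absent)}")
    miss = df[active].isna().sum()
    before = len(df)
    df = df.dropna(subset=active).reset_index(drop=True)
    if df.empty:
        raise ValueError("panel is empty after join and listwise deletion")
    if before - len(df):
        log.info("listwise deletion dropped %d rows: %s", before - len(df),
                 {k: int(v) for k, v in miss.items() if v})

    sds: dict[str, float] = {}
    for col in spec.standardize:
        raw = df[col].to_numpy(dtype=float)
        sd = raw.std(ddof=1)
        if sd == 0:
            raise ValueError(f"cannot standardize constant column {col}")
        df[f"{col}_raw"] = raw
        df[col] = (raw - raw.mean()) / sd
        sds[col] = float(sd)

    for reg, mod in spec.interactions:
        df[f"{reg}x{mod}"] = df[reg] * df[mod]

    df.attrs["missingness"] = {k: int(v) for k, v in miss.items()}
    df.attrs["standardize_sd"] = sds
    df.attrs["n_dropped"] = before - len(df)
    return df


def _time_dummies(panel: pd.DataFrame, fe_time: str) -> pd.DataFrame:
    if fe_time == "none":
        return pd.DataFrame(index=panel.index)
    col = {"dow": "dow", "solar": "solar_term", "week_of_year": "week_of_year"}[fe_time]
    d = pd.get_dummies(panel[col].astype(int), prefix=col, drop_first=True)
    return d.astype(float)


def _design(panel: pd.DataFrame, spec: PanelSpec, extra_cols: list[str] | None = None,
            drop: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    drop = drop or []
    cols = [c for c in spec.regressors if c not in drop]
    cols += [f"{r}x{m}" for r, m in spec.interactions]
    cols += list(spec.controls)
    cols += extra_cols or []
    X = panel[cols].to_numpy(dtype=float)
    td = _time_dummies(panel, spec.fe_time)
    names = cols + list(td.columns)
    if len(td.columns):
        X = np.column_stack([X, td.to_numpy(dtype=float)])
    if not spec.fe_city:
        X = np.column_stack([X, np.ones(len(panel))])
        names = names + ["const"]
    return X, names


def _demean(M: np.ndarray, groups: np.ndarray, enabled: bool) -> np.ndarray:
    if not enabled:
        return M
    df = pd.DataFrame(M)
    return (df - df.groupby(groups).transform("mean")).to_numpy()


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.max() > 0 else 0
    bad = [names[i] for i in np.where(diag <= tol)[0]]
    if bad:
        raise np.linalg.LinAlgError(f"design matrix rank-deficient; collinear terms: {bad}")


def _cluster_cov(Xd: np.ndarray, u: np.ndarray, clusters: np.ndarray,
                 k: int) -> np.ndarray:
    """CR1 sandwich with the G/(G-1) * (N-1)/(N-k) small-sample factor."""
    n = len(u)
    XtX_inv = np.linalg.inv(Xd.T @ Xd)
    Xu = pd.DataFrame(Xd * u[:, None]).groupby(clusters).sum().to_numpy()
    meat = Xu.T @ Xu
    G = Xu.shape[0]
    c = G / (G - 1) * (n - 1) / (n - k)
    return c * XtX_inv @ meat @ XtX_inv


def fit_fe_ols(panel: pd.DataFrame, spec: PanelSpec | None = None) -> RegressionResult:
    """Within (fixed-effects) OLS with city-clustered CR1 standard errors.

    City effects are absorbed by demeaning; time effects enter as
    indicator columns.  ``r2_within`` is computed on the demeaned fit,
    ``r2_overall`` on the raw outcome.  Requires at least two clusters
    and a full-rank design after absorption.
    """
    spec = spec or PanelSpec()
    clusters = panel[spec.cluster].to_numpy()
    G = len(pd.unique(clusters))
    if G < 2:
        raise ValueError("need at least 2 clusters for clustered inference")

    y = panel[spec.outcome].to_numpy(dtype=float)
    X, names = _design(panel, spec)
    cities = panel["city_id"].to_numpy()
    n_fe = len(pd.unique(cities)) if spec.fe_city else 0
    Xd = _demean(X, cities, spec.fe_city)
    yd = _demean(y[:, None], cities, spec.fe_city)[:, 0]
    _check_rank(Xd, names)

    beta, *_ = np.linalg.lstsq(Xd, yd, rcond=None)
    u = yd - Xd @ beta
    n, k = len(y), X.shape[1] + n_fe
    cov = _cluster_cov(Xd, u, clusters, k)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(tstat), df=G - 1)

    ssr = float(u @ u)
    tss_w = float(yd @ yd)
    tss_o = float(((y - y.mean()) ** 2).sum())
    return RegressionResult(
        terms=names, params=beta, se=se, pvalues=pvals, n=n, n_clusters=G,
        r2_within=1 - ssr / tss_w if tss_w > 0 else np.nan,
        r2_overall=1 - ssr / tss_o if tss_o > 0 else np.nan,
        fe_absorbed=n_fe,
    )


def fit_2sls(panel: pd.DataFrame, spec: PanelSpec) -> IVResult:
    """Two-stage least squares with city-clustered CR1 standard errors.

    ``spec.endogenous`` (a subset of the regressors) are instrumented by
    ``spec.instruments``; all other regressors, interactions, controls
    and time dummies are exogenous and instrument themselves.  Final
    residuals are evaluated at the original endogenous regressors.
    """
    if not spec.endogenous:
        raise ValueError("no endogenous regressors declared")
    if len(spec.instruments) < len(spec.endogenous):
        raise ValueError(
            f"order condition violated: {len(spec.instruments)} instrument(s) "
            f"for {len(spec.endogenous)} endogenous regressor(s)")

    clusters = panel[spec.cluster].to_numpy()
    G = len(pd.unique(clusters))
    if G < 2:
        raise ValueError("need at least 2 clusters for clustered inference")
    cities = panel["city_id"].to_numpy()
    n_fe = len(pd.unique(cities)) if spec.fe_city else 0

    y = panel[spec.outcome].to_numpy(dtype=float)
    W, w_names = _design(panel, spec, drop=spec.endogenous)  # exogenous block
    E = panel[spec.endogenous].to_numpy(dtype=float)
    Zx = panel[spec.instruments].to_numpy(dtype=float)

    Wd = _demean(W, cities, spec.fe_city)
    Ed = _demean(E, cities, spec.fe_city)
    Zd = _demean(Zx, cities, spec.fe_city)
    yd = _demean(y[:, None], cities, spec.fe_city)[:, 0]

    Z = np.column_stack([Zd, Wd])
    z_names = list(spec.instruments) + w_names
    _check_rank(Z, z_names)
    n = len(y)
    k_first = Z.shape[1] + n_fe

    first: dict[str, RegressionResult] = {}
    Ehat = np.empty_like(Ed)
    for j, name in enumerate(spec.endogenous):
        g, *_ = np.linalg.lstsq(Z, Ed[:, j], rcond=None)
        Ehat[:, j] = Z @ g
        u1 = Ed[:, j] - Ehat[:, j]
        cov1 = _cluster_cov(Z, u1, clusters, k_first)
        se1 = np.sqrt(np.diag(cov1))
        t1 = np.where(se1 > 0, g / se1, 0.0)
        ssr1, tss1 = float(u1 @ u1), float(Ed[:, j] @ Ed[:, j])
        first[name] = RegressionResult(
            terms=z_names, params=g, se=se1,
            pvalues=2 * stats.t.sf(np.abs(t1), df=G - 1), n=n, n_clusters=G,
            r2_within=1 - ssr1 / tss1 if tss1 > 0 else np.nan,
            r2_overall=np.nan, fe_absorbed=n_fe,
        )

    Xd = np.column_stack([Ed, Wd])
    Xhat = np.column_stack([Ehat, Wd])
    x_names = list(spec.endogenous) + w_names
    beta = np.linalg.solve(Xhat.T @ Xhat, Xhat.T @ yd)
    u = yd - Xd @ beta  # structural residuals at the ORIGINAL regressors
    k = Xd.shape[1] + n_fe
    cov = _cluster_cov(Xhat, u, clusters, k)
    se = np.sqrt(np.diag(cov))
    tstat = np.where(se > 0, beta / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(tstat), df=G - 1)
    ssr = float(u @ u)
    tss_w = float(yd @ yd)
    tss_o = float(((y - y.mean()) ** 2).sum())
    second = RegressionResult(
        terms=x_names, params=beta, se=se, pvalues=pvals, n=n, n_clusters=G,
        r2_within=1 - ssr / tss_w if tss_w > 0 else np.nan,
        r2_overall=1 - ssr / tss_o if tss_o > 0 else np.nan,
        fe_absorbed=n_fe,
    )
    diag = iv_diagnostics(Ed, Zd, Wd, n_absorbed=n_fe,
                          endogenous=spec.endogenous)
    return IVResult(second_stage=second, first_stage=first, diagnostics=diag)


def iv_diagnostics(Ed: np.ndarray, Zd: np.ndarray, Wd: np.ndarray,
                   n_absorbed: int = 0, endogenous: list[str] | None = None) -> dict:
    """Instrument-strength and identification diagnostics.

    Computes, per endogenous regressor, the first-stage F statistic for
    the joint exclusion of the instruments; the Cragg-Donald
    minimum-eigenvalue statistic (weak instruments); and the Anderson
    canonical-correlation LM statistic with its chi-square p-value
    (under-identification).  All on variables partialled of the
    exogenous block and absorbed fixed effects.
    """
    n, m = Ed.shape
    q = Zd.shape[1]
    # partial out the exogenous block
    if Wd.shape[1]:
        Bz, *_ = np.linalg.lstsq(Wd, Zd, rcond=None)
        Be, *_ = np.linalg.lstsq(Wd, Ed, rcond=None)
        Zt = Zd - Wd @ Bz
        Et = Ed - Wd @ Be
    else:
        Zt, Et = Zd, Ed
    dof = n - Wd.shape[1] - q - n_absorbed

    f_stats = {}
    names = endogenous or [f"endog_{j}" for j in range(m)]
    for j, name in enumerate(names):
        e = Et[:, j]
        g, *_ = np.linalg.lstsq(Zt, e, rcond=None)
        ssr_u = float(((e - Zt @ g) ** 2).sum())
        ssr_r = float(e @ e)
        f_stats[name] = ((ssr_r - ssr_u) / q) / (ssr_u / dof)

    P = Zt @ np.linalg.lstsq(Zt, Et, rcond=None)[0]
    Gm = Et.T @ P
    H = Et.T @ Et - Gm
    eigs = np.sort(np.real(np.linalg.eigvals(np.linalg.solve(H, Gm))))
    cragg_donald = float(eigs[0] * dof / q)

    # canonical correlations: r^2 solve |E'P E - r^2 E'E| = 0
    r2 = np.sort(np.real(np.linalg.eigvals(np.linalg.solve(Et.T @ Et, Gm))))
    r2_min = float(np.clip(r2[0], 0.0, 1.0))
    anderson_lm = n * r2_min
    lm_df = q - m + 1
    return {
        "first_stage_F": f_stats,
        "cragg_donald": cragg_donald,
        "anderson_lm": float(anderson_lm),
        "anderson_lm_df": int(lm_df),
        "anderson_lm_pvalue": float(stats.chi2.sf(anderson_lm, lm_df)),
    }
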