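"""Data preparation for the co-exposure network.

The preparation chain mirrors standard practice for urinary biomarker
panels ahead of a Gaussian graphical model fit:

1. exclude biomarkers with too many values below the LOQ (default: more
   than 40% censored);
2. natural-log transform (urinary concentration distributions are
   right-skewed);
3. fill left-censored cells with their conditional truncated-normal
   mean given the sample's observed biomarkers (single conditional
   imputation, deterministic);
4. fill missing cells by linear-regression single imputation from the
   observed biomarkers;
5. winsorize robust outliers (median/MAD z beyond +-4);
6. standardize each biomarker to mean 0, SD 1;
7. regress out covariates (sex, age, BMI, smoking, education and
   log-creatinine for urine dilution) and re-standardize the residuals.

All steps are deterministic; the censored imputation optionally draws
from the truncated conditional instead (seeded) for sensitivity checks.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import LinearRegression

from .panel import ExposurePanel, validate_covariates

__all__ = [
    "filter_loq",
    "log_transform",
    "impute_censored",
    "impute_missing",
    "correct_outliers",
    "adjust_covariates",
    "standardize",
    "preprocess_pipeline",
]

#: consistency factor making the MAD estimate the SD under normality
_MAD_SCALE = 1.4826


def filter_loq(
    panel: ExposurePanel, max_censored_fraction: float = 0.40
) -> tuple[ExposurePanel, pd.DataFrame]:
    """Drop biomarkers whose censored fraction exceeds the cutoff.

    The fraction is computed over non-missing cells and a biomarker is
    excluded iff it is *strictly* greater than ``max_censored_fraction``
    (a biomarker at exactly the cutoff is kept).  Biomarkers with no
    data at all are excluded with reason ``"no data"``.

    Returns the filtered panel and an exclusion report with one row per
    biomarker (columns: ``censored_fraction``, ``excluded``, ``reason``).
    """
    n_obs = (~panel.missing).sum(axis=0)
    n_cens = (panel.censored & ~panel.missing).sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = n_cens / n_obs.replace(0, np.nan)
    rows = []
    for b in panel.biomarkers:
        if n_obs[b] == 0:
            rows.append((b, np.nan, True, "no data"))
        elif frac[b] > max_censored_fraction:
            rows.append((b, frac[b], True,
                         f"censored fraction {frac[b]:.3f} > {max_censored_fraction:.2f}"))
        else:
            rows.append((b, frac[b], False, ""))
    report = pd.DataFrame(
        rows, columns=["biomarker", "censored_fraction", "excluded", "reason"]
    ).set_index("biomarker")
    kept = [b for b in panel.biomarkers if not report.loc[b, "excluded"]]
    return panel.subset(kept), report


def log_transform(panel: ExposurePanel) -> ExposurePanel:
    """Natural-log transform values and LOQ thresholds."""
    if panel.scale != "raw":
        raise ValueError(f"panel is already on the {panel.scale} scale")
    vals = panel.values.to_numpy()
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive concentration at sample {panel.values.index[i]}, "
            f"biomarker {panel.biomarkers[j]}: {vals[i, j]}"
        )
    out = panel.copy()
    out.values = np.log(panel.values)
    out.loq = np.log(panel.loq)
    out.scale = "log"
    return out


# ---------------------------------------------------------------------------
# censored imputation
# ---------------------------------------------------------------------------

def _censored_normal_mle(obs: np.ndarray, n_cens: int, bound: float) -> tuple[float, float]:
    """ML estimate of (mu, sigma) for a normal sample with ``n_cens``
    observations left-censored at ``bound`` (Tobit likelihood)."""
    m0, s0 = obs.mean(), max(obs.std(ddof=1), 1e-6)
    if n_cens == 0:
        return m0, s0

    def nll(theta: np.ndarray) -> float:
        mu, log_sd = theta
        sd = np.exp(log_sd)
        ll = stats.norm.logpdf(obs, mu, sd).sum()
        ll += n_cens * stats.norm.logcdf(bound, mu, sd)
        return -ll

    res = optimize.minimize(nll, x0=np.array([m0, np.log(s0)]), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000})
    mu, log_sd = res.x
    return float(mu), float(np.exp(log_sd))


def _truncated_normal_mean(mu: float, sd: float, upper: float) -> float:
    """E[X | X < upper] for X ~ N(mu, sd^2)."""
    alpha = (upper - mu) / sd
    log_phi = stats.norm.logpdf(alpha)
    log_Phi = stats.norm.logcdf(alpha)
    ratio = np.exp(log_phi - log_Phi)
    val = mu - sd * ratio
    return float(min(val, upper))


def estimate_moments(
    panel: ExposurePanel, shrinkage: float = 0.1
) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Estimate per-biomarker means/SDs and a correlation matrix on the
    log scale, accounting for left-censoring.

    Means and SDs come from a per-column censored-normal ML fit;
    correlations from pairwise-complete observed cells, shrunk toward
    the identity and eigenvalue-clipped to keep the matrix usable for
    conditioning.
    """
    vals = panel.values.to_numpy(dtype=float)
    cens = panel.censored.to_numpy()
    miss = panel.missing.to_numpy()
    obs_mask = ~cens & ~miss
    p = vals.shape[1]
    mu = np.empty(p)
    sd = np.empty(p)
    for j in range(p):
        obs = vals[obs_mask[:, j], j]
        if len(obs) < 3:
            raise ValueError(
                f"biomarker {panel.biomarkers[j]} has fewer than 3 observed values"
            )
        mu[j], sd[j] = _censored_normal_mle(obs, int((cens[:, j] & ~miss[:, j]).sum()),
                                            float(panel.loq.iloc[j]))
    # pairwise-complete correlations of observed cells
    x = np.where(obs_mask, vals, np.nan)
    corr = pd.DataFrame(x).corr(min_periods=5).to_numpy()
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = (1.0 - shrinkage) * corr + shrinkage * np.eye(p)
    w, v = np.linalg.eigh(corr)
    if w.min() < 1e-6:
        w = np.clip(w, 1e-6, None)
        corr = v @ np.diag(w) @ v.T
        dd = np.sqrt(np.diag(corr))
        corr = corr / np.outer(dd, dd)
    names = panel.biomarkers
    return (pd.Series(mu, index=names), pd.Series(sd, index=names),
            pd.DataFrame(corr, index=names, columns=names))


def impute_censored(
    panel: ExposurePanel,
    params: tuple[pd.Series, pd.Series, pd.DataFrame] | None = None,
    random_draw: bool = False,
    seed: int | None = None,
    shrinkage: float = 0.1,
) -> ExposurePanel:
    """Fill left-censored cells on the log scale.

    Each censored cell is replaced by the mean of its conditional
    normal distribution given the sample's observed biomarkers,
    truncated above at log(LOQ) — or by a seeded draw from that
    truncated conditional when ``random_draw`` is set.  Imputed values
    never exceed log(LOQ).  ``params`` may supply known ``(mu, sd,
    corr)`` moments (e.g. from a generator); by default they are
    estimated from the panel via :func:`estimate_moments`.
    """
    if panel.scale != "log":
        raise ValueError("impute_censored expects a log-scale panel")
    out = panel.copy()
    cens = panel.censored.to_numpy()
    if not cens.any():
        return out
    if params is None:
        mu_s, sd_s, corr_df = estimate_moments(panel, shrinkage=shrinkage)
    else:
        mu_s, sd_s, corr_df = params
        mu_s = mu_s[panel.biomarkers]
        sd_s = sd_s[panel.biomarkers]
        corr_df = corr_df.loc[panel.biomarkers, panel.biomarkers]
    mu = mu_s.to_numpy(dtype=float)
    sd = sd_s.to_numpy(dtype=float)
    sigma = corr_df.to_numpy() * np.outer(sd, sd)
    vals = out.values.to_numpy(dtype=float)
    miss = panel.missing.to_numpy()
    loq = panel.loq.to_numpy(dtype=float)
    rng = np.random.default_rng(seed) if random_draw else None

    for i in range(vals.shape[0]):
        c_idx = np.flatnonzero(cens[i])
        if len(c_idx) == 0:
            continue
        o_idx = np.flatnonzero(~cens[i] & ~miss[i])
        for j in c_idx:
            if len(o_idx) > 0:
                s_oo = sigma[np.ix_(o_idx, o_idx)]
                s_jo = sigma[j, o_idx]
                try:
                    sol = np.linalg.solve(s_oo, s_jo)
                except np.linalg.LinAlgError:
                    sol, *_ = np.linalg.lstsq(s_oo, s_jo, rcond=None)
                    warnings.warn(
                        f"singular conditioning covariance for biomarker "
                        f"{panel.biomarkers[j]}; using least-squares pseudo-solution",
                        stacklevel=2,
                    )
                m = mu[j] + sol @ (vals[i, o_idx] - mu[o_idx])
                v = sigma[j, j] - sol @ s_jo
                s = float(np.sqrt(max(v, 1e-12)))
            else:  # nothing observed for this sample: marginal truncated mean
                m, s = mu[j], sd[j]
            bound = loq[j]
            if random_draw:
                a = -np.inf
                b = (bound - m) / s
                vals[i, j] = stats.truncnorm.rvs(a, b, loc=m, scale=s, random_state=rng)
            else:
                vals[i, j] = _truncated_normal_mean(m, s, bound)

    out.values = pd.DataFrame(vals, index=panel.values.index, columns=panel.biomarkers)
    return out


def impute_missing(panel: ExposurePanel) -> ExposurePanel:
    """Fill missing cells by linear-regression single imputation.

    Deterministic iterated regression imputation (the ``norm.predict``
    flavour): each incomplete biomarker is regressed on the others over
    complete rows and missing cells are replaced by the fitted values.
    Censored cells must already be filled.
    """
    if panel.scale != "log":
        raise ValueError("impute_missing expects a log-scale panel")
    out = panel.copy()
    miss = panel.missing.to_numpy()
    if not miss.any():
        return out
    all_missing = miss.all(axis=1)
    if all_missing.any():
        i = int(np.flatnonzero(all_missing)[0])
        raise ValueError(f"sample {panel.values.index[i]} has all biomarkers missing")
    x = out.values.to_numpy(dtype=float).copy()
    x[miss] = np.nan
    imputer = IterativeImputer(
        estimator=LinearRegression(),
        sample_posterior=False,
        max_iter=15,
        tol=1e-8,
        initial_strategy="mean",
        random_state=0,
    )
    filled = imputer.fit_transform(x)
    if filled.shape[1] != x.shape[1]:  # imputer drops all-NaN columns
        raise ValueError("a biomarker has no observed values at all; exclude it first")
    out.values = pd.DataFrame(filled, index=panel.values.index, columns=panel.biomarkers)
    out.missing = pd.DataFrame(
        np.zeros_like(miss, dtype=bool), index=panel.values.index, columns=panel.biomarkers
    )
    return out


def correct_outliers(
    panel: ExposurePanel, z_cut: float = 4.0
) -> tuple[ExposurePanel, pd.Series]:
    """Winsorize values whose robust z-score exceeds ``+-z_cut``.

    The robust z uses the per-biomarker median and the MAD scaled to be
    consistent with the SD under normality.  Biomarkers with MAD = 0
    are skipped with a warning.  Returns the corrected panel and the
    per-biomarker count of clipped cells.
    """
    out = panel.copy()
    vals = out.values.to_numpy(dtype=float)
    counts = pd.Series(0, index=panel.biomarkers, name="n_winsorized")
    for j, b in enumerate(panel.biomarkers):
        col = vals[:, j]
        ok = ~np.isnan(col)
        med = np.median(col[ok])
        mad = np.median(np.abs(col[ok] - med)) * _MAD_SCALE
        if mad == 0:
            warnings.warn(f"MAD is zero for biomarker {b}; outlier correction skipped",
                          stacklevel=2)
            continue
        lo, hi = med - z_cut * mad, med + z_cut * mad
        clipped = ok & ((col < lo) | (col > hi))
        vals[:, j] = np.clip(col, lo, hi)
        counts[b] = int(clipped.sum())
    out.values = pd.DataFrame(vals, index=panel.values.index, columns=panel.biomarkers)
    return out, counts


def _design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    """Intercept + one-hot categoricals + age + BMI + log(creatinine)."""
    cols = [np.ones(len(covariates))]
    for cat in ("sex", "smoking", "education"):
        dummies = pd.get_dummies(covariates[cat].astype(str), drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
    cols.append(covariates["age"].to_numpy(dtype=float))
    cols.append(covariates["bmi"].to_numpy(dtype=float))
    cols.append(np.log(covariates["creatinine"].to_numpy(dtype=float)))
    return np.column_stack(cols)


def adjust_covariates(panel: ExposurePanel, covariates: pd.DataFrame) -> ExposurePanel:
    """Replace each biomarker by its OLS residuals on the covariates.

    The design holds an intercept, one-hot sex/smoking/education, age,
    BMI and log(creatinine) — the latter removes shared urinary
    dilution, which would otherwise inflate all pairwise dependencies.
    Residuals are exactly orthogonal to every design column; collinear
    designs are handled by the minimum-norm least-squares solution
    (with a warning).
    """
    validate_covariates(covariates, panel.n_samples)
    X = _design_matrix(covariates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            f"covariate design is rank deficient ({rank} < {X.shape[1]}); "
            "redundant columns contribute nothing",
            stacklevel=2,
        )
    out = panel.copy()
    Y = out.values.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("adjust_covariates requires a fully imputed panel")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    out.values = pd.DataFrame(Y - X @ beta, index=panel.values.index,
                              columns=panel.biomarkers)
    return out


def standardize(panel: ExposurePanel, ddof: int = 1) -> ExposurePanel:
    """Scale each biomarker to mean 0, SD 1 (sample SD by default)."""
    out = panel.copy()
    vals = out.values.to_numpy(dtype=float)
    mean = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0, ddof=ddof)
    zero = sd == 0
    if zero.any():
        b = panel.biomarkers[int(np.flatnonzero(zero)[0])]
        raise ValueError(f"biomarker {b} has zero variance; cannot standardize")
    out.values = pd.DataFrame((vals - mean) / sd, index=panel.values.index,
                              columns=panel.biomarkers)
    out.scale = "standardized"
    return out


def preprocess_pipeline(
    panel: ExposurePanel,
    covariates: pd.DataFrame | None = None,
    max_censored_fraction: float = 0.40,
    z_cut: float = 4.0,
    censored_params: tuple | None = None,
    random_draw: bool = False,
    seed: int | None = None,
) -> tuple[ExposurePanel, dict]:
    """Run the full preparation chain; returns the network-ready panel
    and a report dict (exclusions, winsorized counts).

    Order: LOQ filter -> log -> censored imputation -> missing
    imputation -> outlier winsorization -> standardize -> covariate
    adjustment (skipped when ``covariates`` is None) -> re-standardize.
    """
    kept, exclusions = filter_loq(panel, max_censored_fraction)
    logged = log_transform(kept)
    filled = impute_censored(logged, params=censored_params,
                             random_draw=random_draw, seed=seed)
    complete = impute_missing(filled)
    corrected, n_winsorized = correct_outliers(complete, z_cut=z_cut)
    standardized = standardize(corrected)
    if covariates is not None:
        adjusted = adjust_covariates(standardized, covariates)
        standardized = standardize(adjusted)
    report = {
        "exclusions": exclusions,
        "n_winsorized": n_winsorized,
        "kept_biomarkers": standardized.biomarkers,
    }
    return standardized, report
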