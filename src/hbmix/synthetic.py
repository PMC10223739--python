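"""Synthetic urinary biomarker panels with planted co-occurrence structure.

Population human-biomonitoring datasets of the kind this package
analyses are individual-level health data and generally cannot be
shared.  This module generates panels that emulate their salient
features so the whole pipeline is testable end to end:

* log-normal marginal concentrations (urinary biomarker distributions
  are right-skewed, hence the pipeline's natural-log transform);
* a block-structured Gaussian copula on the log scale — biomarkers
  within a planted block share partial correlations of magnitude
  ``rho``, between-block partial correlations are exactly zero.  The
  blocks are the ground-truth "communities" the network stage should
  recover;
* covariate effects (sex, age, BMI, smoking, education) as additive
  shifts on the log scale;
* shared urinary dilution: creatinine is log-normal and enters every
  biomarker multiplicatively;
* left-censoring at a per-biomarker LOQ placed at a configurable
  quantile of the realized distribution;
* sporadic missingness, either cell-wise or as whole biomarker columns
  missing for a subset of samples.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import ExposurePanel

__all__ = ["GeneratorConfig", "PlantedTruth", "plant_precision", "generate_panel"]


@dataclasses.dataclass
class PlantedTruth:
    """Ground truth behind a generated panel.

    Attributes
    ----------
    community_of : dict
        Biomarker id -> block label (``"C1"``, ``"C2"``, ...) or None
        for singletons.
    precision : DataFrame
        The planted p x p precision matrix (unit diagonal).  Off-block
        entries are exactly zero.
    loq : Series or None
        Per-biomarker LOQ on the concentration scale (set by
        :func:`generate_panel`).
    true_values : DataFrame or None
        The uncensored latent concentrations (set by
        :func:`generate_panel`); used by imputation-quality checks.
    """

    community_of: dict[str, str | None]
    precision: pd.DataFrame
    loq: pd.Series | None = None
    true_values: pd.DataFrame | None = None

    @property
    def partial_correlation(self) -> pd.DataFrame:
        K = self.precision.to_numpy()
        d = np.sqrt(np.diag(K))
        P = -K / np.outer(d, d)
        np.fill_diagonal(P, 1.0)
        return pd.DataFrame(P, index=self.precision.index, columns=self.precision.columns)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "community_of": self.community_of,
            "biomarkers": list(self.precision.columns),
            "precision": self.precision.to_numpy().tolist(),
            "loq": None if self.loq is None else self.loq.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclasses.dataclass
class GeneratorConfig:
    """Study-like defaults: 515 samples, 51 biomarkers, blocks of 3-6.

    ``blocks`` lists planted community sizes; biomarkers beyond
    ``sum(blocks)`` are singletons with no community.  ``rho`` is the
    within-block partial-correlation magnitude.  ``censoring_quantile``
    places the per-biomarker LOQ at that quantile of the realized
    concentrations (scalar or one value per biomarker).
    ``covariate_effects`` maps covariate name to a slope on the log
    scale applied to every biomarker.  ``creatinine_exponent`` is the
    shared dilution exponent (1 = concentrations fully proportional to
    creatinine).
    """

    n_samples: int = 515
    n_biomarkers: int = 51
    blocks: tuple[int, ...] = (6, 5, 4, 4, 3, 3, 3, 3)
    rho: float = 0.3
    sign: str = "auto"
    log_mean: float | np.ndarray | None = None
    log_sd: float | np.ndarray = 1.0
    censoring_quantile: float | np.ndarray = 0.10
    missing_rate: float = 0.02
    missing_mode: str = "cell"  # "cell" or "column"
    column_missing_fraction: float = 0.5
    covariate_effects: dict[str, float] | None = None
    creatinine_exponent: float = 1.0
    biomarker_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.biomarker_names is not None:
            self.biomarker_names = tuple(self.biomarker_names)
            if len(self.biomarker_names) != self.n_biomarkers:
                raise ValueError(
                    f"{len(self.biomarker_names)} biomarker names for "
                    f"{self.n_biomarkers} biomarkers"
                )
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie in (0, 1)")
        if sum(self.blocks) > self.n_biomarkers:
            raise ValueError(
                f"block sizes sum to {sum(self.blocks)} > {self.n_biomarkers} biomarkers"
            )
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        q = np.atleast_1d(np.asarray(self.censoring_quantile, dtype=float))
        if ((q < 0) | (q >= 1)).any():
            raise ValueError("censoring_quantile must lie in [0, 1)")
        if self.missing_mode not in ("cell", "column"):
            raise ValueError("missing_mode must be 'cell' or 'column'")


def _biomarker_names(p: int) -> list[str]:
    return [f"B{i + 1:02d}" for i in range(p)]


def plant_precision(
    blocks: list[int] | tuple[int, ...],
    rho: float,
    p: int,
    sign: str = "auto",
) -> PlantedTruth:
    """Build a block-diagonal precision matrix with planted communities.

    Within each block every pairwise partial correlation has magnitude
    ``rho``; between blocks (and for singletons) partial correlations
    are exactly zero.  The matrix has unit diagonal.

    An equi-partial-correlation block of size k with all pairs equal to
    +rho is positive definite only when ``rho < 1/(k-1)`` (and no
    diagonal rescaling can fix that).  The ``sign`` policy handles
    this: ``"positive"`` demands +rho and raises when infeasible,
    ``"negative"`` plants -rho (feasible for any block size and
    ``rho < 1``), and the default ``"auto"`` uses +rho where feasible
    and falls back to -rho per block.  Graph structure — the object the
    network stage estimates — is the same either way.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must lie in (0, 1)")
    blocks = list(blocks)
    if any(b < 1 for b in blocks):
        raise ValueError("block sizes must be >= 1")
    if sum(blocks) > p:
        raise ValueError(f"block sizes sum to {sum(blocks)} > p = {p}")
    if sign not in ("auto", "positive", "negative"):
        raise ValueError("sign must be 'auto', 'positive' or 'negative'")

    K = np.eye(p)
    names = _biomarker_names(p)
    community_of: dict[str, str | None] = {b: None for b in names}
    start = 0
    for label_i, k in enumerate(blocks, start=1):
        feasible_positive = rho < 1.0 / (k - 1) if k > 1 else True
        if sign == "positive" and not feasible_positive:
            raise ValueError(
                f"rho = {rho} with all-positive partial correlations is not positive "
                f"definite for block size {k} (requires rho < {1.0 / (k - 1):.4g}); "
                "use sign='auto' or 'negative'"
            )
        use_positive = feasible_positive if sign == "auto" else (sign == "positive")
        off = -rho if use_positive else rho  # precision off-diagonal
        block = np.full((k, k), off)
        np.fill_diagonal(block, 1.0)
        K[start:start + k, start:start + k] = block
        for name in names[start:start + k]:
            community_of[name] = f"C{label_i}"
        start += k

    eigvals = np.linalg.eigvalsh(K)
    if eigvals.min() <= 0:
        raise ValueError(
            f"planted precision is not positive definite (min eigenvalue {eigvals.min():.3g})"
        )
    precision = pd.DataFrame(K, index=names, columns=names)
    return PlantedTruth(community_of=community_of, precision=precision)


def _generate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Covariates resembling a children/adolescent survey population."""
    sex = rng.choice(["f", "m"], size=n)
    age = rng.integers(3, 18, size=n).astype(float)  # years, 3-17
    bmi = np.clip(rng.normal(18.5, 3.0, size=n), 12.0, None)  # kg/m2
    smoking = rng.choice(["no", "yes"], size=n, p=[0.92, 0.08])
    education = rng.choice(["low", "medium", "high"], size=n, p=[0.25, 0.5, 0.25])
    # first-morning-void creatinine, g/L: geometric mean ~1, GSD ~e^0.5
    creatinine = np.exp(rng.normal(0.0, 0.5, size=n))
    return pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "smoking": smoking,
            "education": education,
            "creatinine": creatinine,
        },
        index=pd.RangeIndex(n, name="sample"),
    )


def generate_panel(
    config: GeneratorConfig,
    seed: int | None = None,
) -> tuple[ExposurePanel, pd.DataFrame, PlantedTruth]:
    """Draw a synthetic panel, covariate table and its planted truth.

    Concentrations are ``exp(log_mean + log_sd * z + covariate effects
    + creatinine_exponent * log(creatinine))`` where ``z`` is a unit-
    variance Gaussian field with the planted block precision.  Cells
    whose latent concentration falls below the per-biomarker LOQ are
    flagged censored and stored at the LOQ; missing cells are NaN.
    Identical seeds give identical output.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, p = config.n_samples, config.n_biomarkers
    truth = plant_precision(config.blocks, config.rho, p, config.sign)
    if config.biomarker_names is not None:
        rename = dict(zip(truth.precision.columns, config.biomarker_names))
        truth.precision = truth.precision.rename(index=rename, columns=rename)
        truth.community_of = {rename[b]: c for b, c in truth.community_of.items()}
    names = list(truth.precision.columns)

    sigma = np.linalg.inv(truth.precision.to_numpy())
    # rescale to unit marginal variance; diagonal scaling preserves the
    # partial-correlation pattern
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, p)) @ chol.T

    covariates = _generate_covariates(n, rng)

    if config.log_mean is None:
        log_mean = np.linspace(np.log(0.2), np.log(20.0), p)
    else:
        log_mean = np.broadcast_to(np.asarray(config.log_mean, dtype=float), (p,)).copy()
    log_sd = np.broadcast_to(np.asarray(config.log_sd, dtype=float), (p,)).copy()

    log_conc = log_mean + log_sd * z
    effects = config.covariate_effects or {}
    for cov, beta in effects.items():
        col = covariates[cov]
        if col.dtype.kind in "if":
            x = col.to_numpy(dtype=float)
            x = x - x.mean()
        else:  # binary/categorical: indicator of the non-reference level
            levels = sorted(col.unique())
            x = (col == levels[-1]).to_numpy(dtype=float)
            x = x - x.mean()
        log_conc += beta * x[:, None]
    log_conc += config.creatinine_exponent * np.log(covariates["creatinine"].to_numpy())[:, None]

    true_values = np.exp(log_conc)

    q = np.broadcast_to(np.atleast_1d(np.asarray(config.censoring_quantile, dtype=float)), (p,))
    loq = np.empty(p)
    for j in range(p):
        if q[j] <= 0:
            loq[j] = true_values[:, j].min() / 10.0  # nothing censored
        else:
            loq[j] = np.quantile(true_values[:, j], q[j])
    censored = true_values < loq

    missing = np.zeros((n, p), dtype=bool)
    if config.missing_rate > 0:
        if config.missing_mode == "cell":
            missing = rng.random((n, p)) < config.missing_rate
        else:
            n_cols = int(round(config.missing_rate * p))
            cols = rng.choice(p, size=n_cols, replace=False)
            for j in cols:
                rows = rng.random(n) < config.column_missing_fraction
                missing[rows, j] = True
    censored = censored & ~missing

    values = true_values.copy()
    values[censored] = np.broadcast_to(loq, (n, p))[censored]
    values[missing] = np.nan

    index = covariates.index
    meta = pd.DataFrame(
        {"community": [truth.community_of[b] for b in names]}, index=pd.Index(names, name="biomarker")
    )
    panel = ExposurePanel(
        values=pd.DataFrame(values, index=index, columns=names),
        loq=pd.Series(loq, index=names, name="loq"),
        censored=pd.DataFrame(censored, index=index, columns=names),
        missing=pd.DataFrame(missing, index=index, columns=names),
        meta=meta,
        scale="raw",
    )
    truth.loq = panel.loq.copy()
    truth.true_values = pd.DataFrame(true_values, index=index, columns=names)
    return panel, covariates, truth


def write_dataset(
    panel: ExposurePanel,
    covariates: pd.DataFrame,
    truth: PlantedTruth,
    out_dir: str | Path,
) -> None:
    """Write panel CSVs, the covariate CSV and the planted truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel.to_dir(out)
    covariates.to_csv(out / "covariates.csv", index_label="sample")
    truth.to_json(out / "planted_truth.json")
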