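"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest

from hbmix import GeneratorConfig, generate_panel, load_database
from hbmix.panel import ExposurePanel


def admm_glasso(S, lam, rho=1.0, n_iter=50_000, tol=1e-13):
    """Independent penalized-likelihood optimizer for the graphical lasso.

    ADMM splitting: the smooth log-det subproblem is solved exactly by
    eigendecomposition, the L1 subproblem by off-diagonal soft
    thresholding.  Entirely separate from the coordinate-descent /
    LARS algorithms inside the package.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    Z = np.eye(p)
    U = np.zeros((p, p))
    for _ in range(n_iter):
        w, V = np.linalg.eigh(rho * (Z - U) - S)
        xi = (w + np.sqrt(w**2 + 4 * rho)) / (2 * rho)
        X = V @ (xi[:, None] * V.T)
        A = X + U
        Zn = np.sign(A) * np.maximum(np.abs(A) - lam / rho, 0.0)
        np.fill_diagonal(Zn, np.diag(A))
        r = np.linalg.norm(X - Zn)
        s = rho * np.linalg.norm(Zn - Z)
        U = U + X - Zn
        Z = Zn
        if r < tol and s < tol:
            break
    return Z


def random_correlation(p, rng, n_factor=2):
    """A random well-conditioned correlation matrix."""
    B = rng.standard_normal((p, n_factor * p))
    return np.corrcoef(B)


def truth_labels(truth, nodes):
    """Integer community labels from a PlantedTruth (singletons unique)."""
    seen = {}
    out, nxt = [], -1
    for b in nodes:
        c = truth.community_of[b]
        if c is None:
            out.append(nxt)
            nxt -= 1
        else:
            out.append(seen.setdefault(c, len(seen)))
    return np.array(out)


def make_panel(values, loq=None, censored=None, missing=None, scale="raw"):
    """Build an ExposurePanel from a plain array with sensible defaults."""
    values = pd.DataFrame(np.asarray(values, dtype=float))
    values.columns = [f"B{j + 1:02d}" for j in range(values.shape[1])]
    n, p = values.shape
    if loq is None:
        loq = pd.Series(np.full(p, 1e-12 if scale == "raw" else -np.inf),
                        index=values.columns)
        if scale == "raw":
            smallest = np.nanmin(values.to_numpy())
            loq[:] = smallest / 10.0 if smallest > 0 else 1e-12
    else:
        loq = pd.Series(np.broadcast_to(np.asarray(loq, dtype=float), (p,)),
                        index=values.columns)
    if censored is None:
        censored = np.zeros((n, p), dtype=bool)
    if missing is None:
        missing = np.zeros((n, p), dtype=bool)
    return ExposurePanel(
        values=values,
        loq=loq,
        censored=pd.DataFrame(np.asarray(censored, bool), columns=values.columns),
        missing=pd.DataFrame(np.asarray(missing, bool), columns=values.columns),
        scale=scale,
    )


@pytest.fixture(scope="session")
def db():
    return load_database()


@pytest.fixture(scope="session")
def small_dataset():
    """A small generated dataset shared across tests (read-only)."""
    cfg = GeneratorConfig(n_samples=250, n_biomarkers=20, blocks=(4, 3, 3),
                          rho=0.35, censoring_quantile=0.1, missing_rate=0.02,
                          seed=11)
    return generate_panel(cfg)
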