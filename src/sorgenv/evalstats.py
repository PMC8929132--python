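"""Model-evaluation statistics for the envirotyping pipeline.

Three groups of tools:

* :func:`agreement` — simulated-vs-observed agreement metrics (RMSE, NRMSE,
  Nash–Sutcliffe efficiency, Pearson correlation).
* :func:`variance_components` — REML variance components for observed yield
  under the random-effects model ``y = μ + site + ECG(site) + residual``,
  quantifying how much yield variance the environment classification
  captures.
* :func:`impute_gaps` / :func:`ecg_biplot` — low-rank completion of the
  unbalanced hybrid × environment yield matrix followed by a centered
  singular-value-decomposition biplot of hybrids against the four
  environment categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AgreementReport",
    "VarianceDecomposition",
    "BiplotResult",
    "agreement",
    "variance_components",
    "impute_gaps",
    "ecg_biplot",
]


@dataclass
class AgreementReport:
    """Agreement between simulated and observed series.

    ``nrmse`` is the RMSE expressed as a percentage of the observed mean
    (reported as NaN and flagged when that mean is 0); ``nse`` is the
    Nash–Sutcliffe efficiency, 1 for a perfect model and 0 for a model no
    better than predicting the observed mean.
    """

    rmse: float
    nrmse: float
    nse: float
    pearson_r: float
    n: int
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "nrmse": self.nrmse,
            "nse": self.nse,
            "pearson_r": self.pearson_r,
            "n": self.n,
            "flags": list(self.flags),
        }


def agreement(observed, simulated) -> AgreementReport:
    """Compute RMSE, NRMSE (% of observed mean), NSE and Pearson r."""
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape or obs.ndim != 1:
        raise ValueError("observed and simulated must be 1-D series of equal length")
    if obs.size < 2:
        raise ValueError("need at least two pairs")
    if np.isnan(obs).any() or np.isnan(sim).any():
        raise ValueError("missing pairs are not allowed")

    flags: list[str] = []
    err = sim - obs
    rmse = float(np.sqrt(np.mean(err**2)))
    obs_mean = obs.mean()
    if obs_mean == 0:
        nrmse = float("nan")
        flags.append("nrmse undefined: observed mean is zero")
    else:
        nrmse = float(100.0 * rmse / obs_mean)
    ss_obs = float(((obs - obs_mean) ** 2).sum())
    if ss_obs == 0:
        nse = float("nan")
        flags.append("nse undefined: observed series has zero variance")
        pearson_r = float("nan")
        flags.append("pearson undefined: observed series has zero variance")
    else:
        nse = float(1.0 - (err**2).sum() / ss_obs)
        if np.std(sim) == 0:
            pearson_r = float("nan")
            flags.append("pearson undefined: simulated series has zero variance")
        else:
            pearson_r = float(np.corrcoef(obs, sim)[0, 1])
    return AgreementReport(rmse=rmse, nrmse=nrmse, nse=nse, pearson_r=pearson_r, n=obs.size, flags=flags)


@dataclass
class VarianceDecomposition:
    """Variance-component estimates and their shares of the total."""

    components: dict
    percentages: dict
    method: str
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "components": dict(self.components),
            "percentages": dict(self.percentages),
            "method": self.method,
            "flags": list(self.flags),
        }


def variance_components(
    table: pd.DataFrame,
    response: str = "yield_kg_ha",
    site_col: str = "site",
    ecg_col: str = "ecg",
    include_hybrid: bool = False,
    hybrid_col: str = "hybrid",
) -> VarianceDecomposition:
    """REML variance components for ``y = μ + site + ECG(site) + residual``.

    Site and the environment category nested in site enter as random
    effects; hybrid is excluded by default and available through
    ``include_hybrid`` as an additional (within-site) variance component.
    Estimates are non-negative by construction (REML boundary at 0);
    percentages of the summed components are reported alongside.
    """
    for col in (response, site_col, ecg_col):
        if col not in table.columns:
            raise KeyError(f"missing column {col!r}")
    data = table.dropna(subset=[response]).copy()
    if data[site_col].nunique() < 2:
        raise ValueError("need at least two sites")
    flags: list[str] = []
    if (data.groupby(site_col)[ecg_col].nunique() < 2).all():
        flags.append("nested ECG component inestimable: every site has a single ECG level")

    y = data[response].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        comps = {"site": 0.0, "ecg_within_site": 0.0, "residual": 0.0}
        if include_hybrid:
            comps["hybrid"] = 0.0
        flags.append("degenerate response: total variance is zero")
        pct = {k: 0.0 for k in comps}
        pct["residual"] = 100.0
        return VarianceDecomposition(comps, pct, "degenerate", flags)

    vc_formula = {"ecg": f"0 + C({ecg_col})"}
    if include_hybrid:
        vc_formula["hybrid"] = f"0 + C({hybrid_col})"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            f"{response} ~ 1",
            groups=site_col,
            re_formula="1",
            vc_formula=vc_formula,
            data=data,
        )
        result = model.fit(reml=True)

    comps = {
        "site": max(float(result.cov_re.iloc[0, 0]), 0.0),
        "ecg_within_site": 0.0,
        "residual": max(float(result.scale), 0.0),
    }
    vc_names = list(model.exog_vc.names)
    for name, est in zip(vc_names, result.vcomp):
        key = "ecg_within_site" if name == "ecg" else name
        comps[key] = max(float(est), 0.0)
    if not result.converged:
        flags.append("REML did not report convergence")

    total = sum(comps.values())
    pct = {k: 100.0 * v / total for k, v in comps.items()}
    return VarianceDecomposition(comps, pct, "REML (MixedLM)", flags)


def impute_gaps(
    matrix: pd.DataFrame | np.ndarray,
    rank: int = 2,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[pd.DataFrame | np.ndarray, dict]:
    """Fill missing cells of a genotype × environment table by iterative SVD.

    Missing cells are initialized with column means, then refined by
    repeating {column-center, rank-``rank`` singular decomposition, rebuild,
    overwrite only the missing cells} until the largest absolute change in
    an imputed cell drops below ``tol``.  Observed cells are never modified.
    Returns the completed matrix and an info dict with the iteration count,
    convergence flag and last delta.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    X = X.copy()
    mask = np.isnan(X)
    if rank >= min(X.shape):
        raise ValueError("rank must be smaller than both matrix dimensions")
    if not mask.any():
        info = {"n_iter": 0, "converged": True, "last_delta": 0.0}
        return (matrix.copy() if is_frame else X), info
    if mask.all(axis=1).any() or mask.all(axis=0).any():
        raise ValueError("every row and column needs at least one observed cell")

    col_means = np.nanmean(np.where(mask, np.nan, X), axis=0)
    X[mask] = np.take(col_means, np.where(mask)[1])

    delta = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        center = X.mean(axis=0)
        Xc = X - center
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        approx = (U[:, :rank] * s[:rank]) @ Vt[:rank] + center
        delta = float(np.abs(approx[mask] - X[mask]).max())
        X[mask] = approx[mask]
        if delta < tol:
            break
    converged = delta < tol
    info = {"n_iter": n_iter, "converged": converged, "last_delta": delta}
    if not converged:
        warnings.warn(
            f"gap imputation did not converge in {max_iter} iterations "
            f"(last delta {delta:.3e})",
            RuntimeWarning,
        )
    if is_frame:
        out = pd.DataFrame(X, index=matrix.index, columns=matrix.columns)
        return out, info
    return X, info


@dataclass
class BiplotResult:
    """Two-component biplot of hybrids (scores) against environment
    categories (loadings) from a column-centered singular decomposition."""

    scores: pd.DataFrame  # hybrids × (PC1, PC2)
    loadings: pd.DataFrame  # categories × (PC1, PC2)
    pc_variance_fractions: np.ndarray  # all PCs, non-increasing, sums to 1
    singular_values: np.ndarray

    def loading_angle(self, a: str, b: str) -> float:
        """Angle (degrees) between two category loading vectors in the
        2-PC plane — ~180° for negatively correlated categories, ~90° for
        uncorrelated ones."""
        va = self.loadings.loc[a].to_numpy()
        vb = self.loadings.loc[b].to_numpy()
        cosine = float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))
        return float(np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0))))


def ecg_biplot(means: pd.DataFrame) -> BiplotResult:
    """Biplot of a completed hybrid × environment-category mean-yield table.

    Columns are centered (removing the per-category mean across hybrids)
    and decomposed; hybrid scores are ``U·S`` and category loadings the
    right singular vectors, both restricted to the first two components.
    """
    if means.isna().any().any():
        raise ValueError("means table must be complete; impute gaps first")
    if means.shape[0] < 3:
        raise ValueError("need at least three hybrids")
    X = means.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if (s > 1e-12).sum() < 2:
        raise ValueError("centered matrix has rank < 2; biplot undefined")
    fractions = s**2 / (s**2).sum()
    scores = pd.DataFrame(
        U[:, :2] * s[:2], index=means.index, columns=["PC1", "PC2"]
    )
    loadings = pd.DataFrame(Vt[:2].T, index=means.columns, columns=["PC1", "PC2"])
    return BiplotResult(
        scores=scores,
        loadings=loadings,
        pc_variance_fractions=fractions,
        singular_values=s,
    )
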