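"""Phenotype preparation: normality transform, covariate adjustment, h2.

The test ranks trait values, so the preparation pipeline matters only
through the ranks it produces; the fixed order is transform (rank-based
inverse normal, applied when a normality check fails or on request),
then covariate adjustment by ordinary least squares, then testing.
Stratified analyses are independent runs on subsets sharing the
pedigree.

Narrow-sense heritability enters only through the null simulation.  It
can be supplied directly or estimated here by maximum likelihood under
the standard polygenic covariance sigma^2 * (2*Phi*h2 + (1-h2)*I),
profiled over sigma^2 and a GLS mean in the eigenbasis of 2*Phi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import KinshipMatrix

__all__ = [
    "PhenotypeTable",
    "read_phenotypes",
    "inverse_normal_transform",
    "needs_transform",
    "adjust_covariates",
    "HeritabilityEstimate",
    "H2Estimator",
    "estimate_h2",
    "prepare_trait",
    "PrepReport",
]


def read_phenotypes(
    path: str | Path,
    na_values: Sequence[str] = ("NA", "nan", ""),
    id_column: str = "id",
) -> pd.DataFrame:
    """Read a phenotype TSV (header row, one id column) indexed by id."""
    df = pd.read_csv(path, sep="\t", na_values=list(na_values), comment="#")
    if id_column not in df.columns:
        raise ValueError(f"phenotype table has no {id_column!r} column")
    df[id_column] = df[id_column].astype(str)
    if df[id_column].duplicated().any():
        dups = df[id_column][df[id_column].duplicated()].tolist()
        raise ValueError(f"duplicate ids in phenotype table: {dups[:5]}")
    return df.set_index(id_column)


# alias: a phenotype table is a DataFrame indexed by individual id with
# trait and covariate columns
PhenotypeTable = pd.DataFrame


def inverse_normal_transform(values: pd.Series) -> pd.Series:
    """Rank-based inverse normal transform with the Blom offset.

    Non-missing value with (average, tie-sharing) rank r among n maps to
    Phi^-1((r - 3/8) / (n + 1/4)); missing values stay missing.  Output
    depends on input only through ranks.
    """
    x = values.dropna()
    if x.nunique() < 2:
        raise ValueError(
            f"trait {values.name!r} is constant; inverse normal transform undefined"
        )
    ranks = stats.rankdata(x.to_numpy(), method="average")
    z = stats.norm.ppf((ranks - 0.375) / (len(x) + 0.25))
    out = pd.Series(np.nan, index=values.index, name=values.name, dtype=float)
    out.loc[x.index] = z
    return out


def needs_transform(values: pd.Series, p_threshold: float = 0.01) -> bool:
    """Normality check deciding whether to transform ("when necessary").

    Shapiro-Wilk on the non-missing values (subsampled to 4,999 for
    large n, where the test is effectively exact anyway); returns True
    when normality is rejected at ``p_threshold``.
    """
    x = values.dropna().to_numpy()
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    if len(x) > 4999:
        rng = np.random.default_rng(0)
        x = rng.choice(x, size=4999, replace=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bool(stats.shapiro(x).pvalue < p_threshold)


def adjust_covariates(values: pd.Series, covariates: pd.DataFrame) -> pd.Series:
    """Residualize a trait on an intercept plus covariates (OLS).

    Categorical covariates are expanded to indicator contrasts (first
    level dropped).  Residuals are re-standardized to unit variance.
    A rank-deficient design or an (essentially) perfectly predicted
    trait is an error naming the offending columns.
    """
    x = values.dropna()
    cov = covariates.loc[x.index]
    if cov.isna().any().any():
        bad = cov.columns[cov.isna().any()].tolist()
        raise ValueError(f"missing covariate values for columns {bad}")
    design = pd.get_dummies(cov, drop_first=True, dtype=float)
    design.insert(0, "(intercept)", 1.0)
    X = design.to_numpy()
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR: columns beyond the numerical rank are the collinear ones
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True, mode="economic")
        collinear = [design.columns[j] for j in sorted(piv[rank:])]
        raise ValueError(f"collinear covariate columns: {collinear}")
    beta, *_ = np.linalg.lstsq(X, x.to_numpy(), rcond=None)
    resid = x.to_numpy() - X @ beta
    sd = resid.std(ddof=1)
    if sd < 1e-10 * max(1.0, float(np.abs(x).max())):
        raise ValueError(
            f"trait {values.name!r} is an exact linear function of the "
            "covariates; residuals are degenerate"
        )
    out = pd.Series(np.nan, index=values.index, name=values.name, dtype=float)
    out.loc[x.index] = resid / sd
    return out


# ---------------------------------------------------------------------------
# Heritability
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityEstimate:
    h2_hat: float
    sigma2_hat: float
    loglik_profile: pd.DataFrame  # columns h2, loglik
    ci: tuple[float, float]  # profile-likelihood 95% interval

    def __repr__(self) -> str:
        return (
            f"HeritabilityEstimate(h2_hat={self.h2_hat:.3f}, "
            f"ci=({self.ci[0]:.3f}, {self.ci[1]:.3f}))"
        )


class H2Estimator:
    """Polygenic-model ML heritability, reusing one eigendecomposition.

    The covariance model is sigma^2 * (2*Phi*h2 + (1-h2)*I).  With
    2*Phi = U diag(lam) U', the likelihood at any h2 needs only the
    rotated data U'y: the expensive eigendecomposition is done once per
    kinship matrix, so many traits (or simulation replicates) on the
    same subjects are cheap.
    """

    H2_MAX = 0.99

    def __init__(self, K: KinshipMatrix, ids: Sequence[str] | None = None):
        self.ids = list(ids) if ids is not None else list(K.ids)
        idx = K.indices(self.ids)
        rel = 2.0 * K.phi[np.ix_(idx, idx)]
        if not (rel - np.diag(np.diag(rel)) > 0).any():
            raise ValueError(
                "no related pairs among the phenotyped subjects; "
                "heritability is unidentifiable"
            )
        self.lam, self.U = np.linalg.eigh(rel)

    def _profile_loglik(self, z: np.ndarray, u1: np.ndarray, h2: float):
        """Log-likelihood at h2 with sigma^2 and the GLS mean profiled out."""
        d = h2 * self.lam + (1.0 - h2)
        mu = (u1 * z / d).sum() / (u1 * u1 / d).sum()
        resid = z - mu * u1
        n = len(z)
        sigma2 = float((resid**2 / d).sum() / n)
        return (
            -0.5 * (n * np.log(2.0 * np.pi * sigma2) + np.log(d).sum() + n),
            sigma2,
        )

    def estimate(self, values: pd.Series, grid_points: int = 99) -> HeritabilityEstimate:
        x = values.reindex(self.ids)
        if x.isna().any():
            raise ValueError(
                "missing trait values among estimator subjects; build the "
                "estimator on the non-missing ids"
            )
        if x.nunique() < 2:
            raise ValueError(f"trait {values.name!r} is constant")
        z = self.U.T @ x.to_numpy()
        u1 = self.U.T @ np.ones(len(x))
        grid = np.linspace(0.0, self.H2_MAX, grid_points)
        lls = np.array([self._profile_loglik(z, u1, h)[0] for h in grid])
        j = int(np.argmax(lls))
        # golden-section refinement inside the bracketing grid cells
        from scipy.optimize import minimize_scalar

        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda h: -self._profile_loglik(z, u1, h)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-5},
        )
        h2_hat = float(np.clip(res.x, 0.0, self.H2_MAX))
        ll_max, sigma2_hat = self._profile_loglik(z, u1, h2_hat)
        # profile-likelihood 95% CI: drop of chi2_1(0.95)/2 = 1.9207
        cutoff = ll_max - 1.9207
        inside = grid[lls >= cutoff]
        ci = (
            (float(inside.min()), float(min(inside.max(), self.H2_MAX)))
            if len(inside)
            else (h2_hat, h2_hat)
        )
        profile = pd.DataFrame({"h2": grid, "loglik": lls})
        return HeritabilityEstimate(
            h2_hat=h2_hat, sigma2_hat=sigma2_hat, loglik_profile=profile, ci=ci
        )


def estimate_h2(values: pd.Series, K: KinshipMatrix) -> HeritabilityEstimate:
    """ML narrow-sense heritability of one trait (see :class:`H2Estimator`).

    The subject set is the trait's non-missing ids; at least one related
    phenotyped pair is required for identifiability.
    """
    x = values.dropna()
    return H2Estimator(K, ids=list(x.index)).estimate(x)


# ---------------------------------------------------------------------------
# Per-trait preparation pipeline
# ---------------------------------------------------------------------------

@dataclass
class PrepReport:
    """What was done to one trait before testing."""

    trait: str
    n_used: int
    transformed: bool
    covariates: list[str]
    h2: float
    h2_source: str  # "user" or "estimated"
    stratum: str | None = None


def prepare_trait(
    table: PhenotypeTable,
    trait: str,
    covariates: Sequence[str] = (),
    force_transform: bool = False,
    transform_p: float = 0.01,
    min_n: int = 50,
) -> tuple[pd.Series, PrepReport]:
    """Transform-then-adjust one trait column; returns values and a report.

    The heritability fields of the report are filled in by the caller
    (user override or :func:`estimate_h2` on the prepared values).
    """
    if trait not in table.columns:
        raise KeyError(f"trait {trait!r} not in phenotype table")
    values = pd.to_numeric(table[trait], errors="coerce")
    n = int(values.notna().sum())
    if n < min_n:
        raise ValueError(
            f"trait {trait!r} has {n} non-missing values, below the floor {min_n}"
        )
    transformed = force_transform or needs_transform(values, transform_p)
    if transformed:
        values = inverse_normal_transform(values)
    if covariates:
        missing_cols = [c for c in covariates if c not in table.columns]
        if missing_cols:
            raise KeyError(f"covariate columns not in table: {missing_cols}")
        cov = table[list(covariates)]
        usable = values.notna() & cov.notna().all(axis=1)
        adjusted = adjust_covariates(values[usable], cov.loc[usable])
        values = adjusted.reindex(values.index)
    report = PrepReport(
        trait=trait,
        n_used=int(values.notna().sum()),
        transformed=transformed,
        covariates=list(covariates),
        h2=float("nan"),
        h2_source="unset",
    )
    return values, report
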