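"""Model-ready design matrix construction.

The propensity and outcome models share one design: every covariate effect
is allowed to vary with age by interacting the covariate with a 3-column
age B-spline basis (so the fitted coefficient of each covariate is itself a
smooth function of age).  Upstream of that expansion, rare comorbidity
(phecode) count features are removed, missing labs are mean-imputed, and
the comorbidity counts are summarized by their first three principal
components.

The basis uses 3 equally spaced knots spanning the central age range
(5th-95th percentile) with boundary clamping, which yields exactly three
basis columns satisfying a partition of unity; the full design is then the
3 basis columns plus the 3 x p interaction columns, for 3(1+p) columns
total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from drclaims.exceptions import ConfigError, DataError

__all__ = [
    "filter_rare_features",
    "impute_labs_mean",
    "comorbidity_pca",
    "AgeSplineBasis",
    "age_spline_basis",
    "DesignMatrix",
    "build_design_matrix",
]


def filter_rare_features(
    counts: pd.DataFrame, threshold: float = 0.05
) -> tuple[pd.DataFrame, list[str]]:
    """Drop count features present in fewer than ``threshold`` of patients.

    Prevalence = fraction of patients with a count > 0; features with
    prevalence *strictly below* the threshold are dropped (a feature at
    exactly the threshold is retained).  Returns the filtered table and the
    list of dropped feature names.
    """
    if counts.shape[0] == 0:
        raise DataError("cannot compute feature prevalence on an empty cohort")
    if (counts.to_numpy() < 0).any():
        raise DataError("phecode counts must be non-negative")
    prevalence = (counts > 0).mean(axis=0)
    dropped = list(prevalence.index[prevalence < threshold])
    return counts.drop(columns=dropped), dropped


def impute_labs_mean(
    labs: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace missing lab values by the observed column mean.

    Returns the completed table and a report with the per-column missing
    fraction and imputed mean.  A fully missing column is an error: there
    is no mean to impute from.
    """
    out = labs.copy()
    rows = []
    for col in labs.columns:
        missing = labs[col].isna()
        if missing.all():
            raise DataError(f"lab column '{col}' has no observed values to impute from")
        mean = labs[col].mean()
        out[col] = labs[col].fillna(mean)
        rows.append(
            {"lab": col, "missing_fraction": float(missing.mean()),
             "imputed_mean": float(mean)}
        )
    return out, pd.DataFrame(rows)


def comorbidity_pca(
    counts: pd.DataFrame, n_components: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leading principal-component scores of the comorbidity counts.

    Columns are centered and scaled to unit variance (correlation PCA;
    count scales differ by orders of magnitude), constant columns are
    scaled by 1.  Sign convention: within each component the
    largest-magnitude loading is positive.  Returns
    ``(scores, loadings)``; scores are row-aligned with ``counts``.
    """
    if counts.shape[1] < n_components:
        raise DataError(
            f"need >= {n_components} features after filtering, "
            f"got {counts.shape[1]}; request fewer components"
        )
    if counts.shape[0] < n_components + 1:
        raise DataError("need more patients than components")
    x = counts.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    x = x / np.where(sd > 0, sd, 1.0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if (s[:n_components] > 1e-12).sum() < n_components:
        rank = int((s > 1e-12).sum())
        # rank-deficient: keep orthogonal zero scores for missing directions
        if rank == 0:
            raise DataError("comorbidity matrix has rank 0; cannot run PCA")
    scores = u[:, :n_components] * s[:n_components]
    load = vt[:n_components].T
    flip = np.sign(load[np.abs(load).argmax(axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    load = load * flip
    cols = [f"pc{k + 1}" for k in range(n_components)]
    return (
        pd.DataFrame(scores, columns=cols, index=counts.index),
        pd.DataFrame(load, columns=cols, index=counts.columns),
    )


@dataclass
class AgeSplineBasis:
    """A fitted age B-spline basis, reusable on new data.

    ``knots`` are the distinct break points (equally spaced over the
    5th-95th age percentiles of the fitting data); evaluation clamps ages
    to the knot range so out-of-domain ages take the boundary basis values.
    """

    knots: np.ndarray
    degree: int

    @property
    def n_basis(self) -> int:
        return len(self.knots) + self.degree - 1

    def __call__(self, age: np.ndarray) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        if not np.all(np.isfinite(age)):
            raise DataError("ages must be finite")
        lo, hi = self.knots[0], self.knots[-1]
        x = np.clip(age, lo, hi)
        # nudge the right boundary inside so the last basis evaluates to 1
        x = np.minimum(x, hi - 1e-9 * max(1.0, abs(hi)))
        t = np.concatenate(
            [np.repeat(self.knots[0], self.degree), self.knots,
             np.repeat(self.knots[-1], self.degree)]
        )
        return BSpline.design_matrix(x, t, self.degree).toarray()

    def column_names(self) -> list[str]:
        return [f"age_b{k + 1}" for k in range(self.n_basis)]


def age_spline_basis(
    age: np.ndarray, n_knots: int = 3, degree: int = 1
) -> tuple[np.ndarray, AgeSplineBasis]:
    """Fit and evaluate the age basis: ``n_knots`` equally spaced knots over
    the 5th-95th percentile of ``age``, clamped B-spline of ``degree``.

    The default (3 knots, degree 1) gives exactly 3 basis columns — the
    three "age basis variables" whose interactions produce age-varying
    coefficient estimates — and satisfies the partition of unity.
    """
    age = np.asarray(age, dtype=float)
    if not np.all(np.isfinite(age)):
        raise DataError("ages must be finite")
    lo, hi = np.percentile(age, [5, 95])
    if hi - lo < 1e-8:
        raise DataError("age vector is (nearly) constant; cannot place knots")
    if n_knots < 2:
        raise ConfigError("need at least 2 knots")
    basis = AgeSplineBasis(knots=np.linspace(lo, hi, n_knots), degree=degree)
    return basis(age), basis


@dataclass
class DesignMatrix:
    """Expanded covariate matrix shared by the PS and outcome models.

    ``X`` holds the 3 age-basis columns followed by basis-by-covariate
    interaction columns (named ``<covariate>:age_b<k>``).  ``meta`` records,
    per source covariate, the standardization statistics used (continuous
    covariates are standardized to mean 0, SD 1 on the fitting cohort;
    binary covariates are left on their natural scale for interpretable
    balance diagnostics).  ``transform`` re-applies the fitted expansion to
    new rows using the stored statistics.
    """

    X: pd.DataFrame
    basis: AgeSplineBasis
    covariates: list[str]
    standardize: dict = field(default_factory=dict)
    basis_columns: list[str] = field(default_factory=list)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def transform(self, covariate_df: pd.DataFrame, age: np.ndarray) -> pd.DataFrame:
        b = self.basis(age)
        blocks = {name: b[:, k] for k, name in enumerate(self.basis_columns)}
        for cov in self.covariates:
            x = covariate_df[cov].to_numpy(dtype=float)
            if cov in self.standardize:
                mu, sd = self.standardize[cov]
                x = (x - mu) / sd
            for k, bname in enumerate(self.basis_columns):
                blocks[f"{cov}:{bname}"] = b[:, k] * x
        out = pd.DataFrame(blocks, index=covariate_df.index)
        return out[[c for c in self.columns]]


def build_design_matrix(
    covariate_df: pd.DataFrame,
    age: np.ndarray,
    *,
    binary_tol: int = 2,
    n_knots: int = 3,
    degree: int = 1,
) -> DesignMatrix:
    """Build the shared design: age basis + basis-by-covariate interactions.

    ``covariate_df`` holds the non-age covariates (demographics, labs,
    medication counts, comorbidity PCs, ...), one row per patient, already
    imputed.  Continuous covariates (more than ``binary_tol`` distinct
    values) are standardized on this cohort and the statistics stored for
    reuse at prediction time.  Covariates that are constant (so their
    interaction columns are constant multiples of the basis, or all zero)
    are dropped with a warning.
    """
    if len(covariate_df) != len(np.asarray(age)):
        raise DataError("covariate table and age vector are not row-aligned")
    if covariate_df.isna().any().any():
        raise DataError("covariates contain missing values; impute first")

    b, basis = age_spline_basis(age, n_knots=n_knots, degree=degree)
    basis_cols = basis.column_names()

    keep: list[str] = []
    standardize: dict = {}
    for cov in covariate_df.columns:
        x = covariate_df[cov].to_numpy(dtype=float)
        uniq = np.unique(x)
        if uniq.size < 2:
            warnings.warn(
                f"covariate '{cov}' is constant; its interaction columns are "
                "dropped", stacklevel=2,
            )
            continue
        keep.append(cov)
        if uniq.size > binary_tol:
            mu, sd = float(x.mean()), float(x.std(ddof=0))
            standardize[cov] = (mu, sd if sd > 0 else 1.0)

    dm = DesignMatrix(
        X=pd.DataFrame(index=covariate_df.index),
        basis=basis,
        covariates=keep,
        standardize=standardize,
        basis_columns=basis_cols,
    )
    blocks = {name: b[:, k] for k, name in enumerate(basis_cols)}
    for cov in keep:
        x = covariate_df[cov].to_numpy(dtype=float)
        if cov in standardize:
            mu, sd = standardize[cov]
            x = (x - mu) / sd
        for k, bname in enumerate(basis_cols):
            blocks[f"{cov}:{bname}"] = b[:, k] * x
    dm.X = pd.DataFrame(blocks, index=covariate_df.index)
    return dm
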