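"""Feature harmonization across reconstruction kernels.

Radiomic features shift in location and spread with the reconstruction
kernel (or scanner manufacturer).  This module implements:

* residual-based outlier screening — each feature is residualized in
  three univariable OLS models (on age, BMI and smoking pack-years) and
  a scan is flagged if any residual falls outside
  ``median ± iqr_multiplier × IQR`` of that residual vector;
* parametric empirical-Bayes ComBat: per feature, batch location and
  scale are estimated in standardized space, shrunk toward normal /
  inverse-gamma priors shared across features, and inverted out, while
  the effects of designated protected covariates are estimated jointly
  and re-added so their associations survive harmonization;
* a two-sample Kolmogorov–Smirnov assessment of residual batch
  differences per feature.

The ComBat estimator follows the standard parametric algorithm (as in
the sva / neuroCombat reference implementations): least-squares grand
and covariate effects, pooled-variance standardization, and iterated
conditional posterior means for the batch parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES


@dataclass
class HarmonizationConfig:
    iqr_multiplier: float = 2.5
    residual_covariates: tuple[str, ...] = ("age", "bmi", "pack_years")
    protected_variables: tuple[str, ...] = (
        "sex",
        "lungrads_group",
        "smoking_status",
        "age",
        "bmi",
        "pack_years",
    )
    drop_outliers: bool = True
    eb_tolerance: float = 1e-4
    ks_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.iqr_multiplier <= 0:
            raise ValueError("iqr_multiplier must be positive")
        if not 0 < self.ks_alpha < 1:
            raise ValueError("ks_alpha must be in (0, 1)")


@dataclass
class OutlierFlags:
    """Per-scan outlier flags with their triggering (feature, covariate) pairs."""

    flagged: pd.Series  # bool, indexed like the feature matrix
    triggers: list[tuple[object, str, str]] = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())


def feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in FEATURE_NAMES if c in df.columns]


def flag_outliers(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    config: HarmonizationConfig | None = None,
) -> OutlierFlags:
    """Residual-outlier screening over all (feature, covariate) pairs.

    ``features`` rows and ``covariates`` rows must align 1:1.  For each
    feature f and each covariate c, f is regressed on c (univariable
    OLS, pooled over the dataset); scan i is flagged if any residual
    lies outside ``median ± m·IQR`` of that residual vector.  A constant
    covariate degenerates to intercept-only regression (residuals are
    the centered feature values).
    """
    if config is None:
        config = HarmonizationConfig()
    cols = feature_columns(features)
    if len(features) != len(covariates):
        raise ValueError("features and covariates must have the same number of rows")
    flagged = pd.Series(False, index=features.index)
    triggers: list[tuple[object, str, str]] = []
    for cov in config.residual_covariates:
        if cov not in covariates.columns:
            raise ValueError(f"missing residual covariate {cov!r}")
        x = covariates[cov].to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(x), x])
        if np.ptp(x) == 0:
            X = X[:, :1]
        for f in cols:
            y = features[f].to_numpy(dtype=float)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            med = np.median(r)
            q75, q25 = np.percentile(r, [75, 25])
            half = config.iqr_multiplier * (q75 - q25)
            # guard against flagging pure floating-point noise when the
            # residual vector is (numerically) constant
            atol = 1e-8 * max(1.0, float(np.abs(y).max()))
            out = (r < med - half - atol) | (r > med + half + atol)
            if out.any():
                flagged.iloc[np.nonzero(out)[0]] = True
                for i in np.nonzero(out)[0]:
                    triggers.append((features.index[i], f, cov))
    return OutlierFlags(flagged=flagged, triggers=triggers)


def build_protected_design(
    covariates: pd.DataFrame,
    protected: tuple[str, ...],
) -> pd.DataFrame:
    """Reference-coded design matrix (no intercept) of protected covariates.

    Numeric covariates enter as-is; categorical ones as drop-first
    indicator columns.
    """
    parts = []
    for name in protected:
        if name not in covariates.columns:
            continue
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float).rename(name))
        else:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True).astype(float)
            parts.append(dummies)
    if not parts:
        return pd.DataFrame(index=covariates.index)
    return pd.concat(parts, axis=1)


def _aprior(delta_hat: np.ndarray) -> float:
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(
    z_batch: np.ndarray,
    g_hat: np.ndarray,
    d_hat: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    conv: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterated conditional posterior means for one batch (all features)."""
    n = z_batch.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((z_batch - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old)),
            np.max(np.abs(d_new - d_old) / np.abs(d_old)),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


class CombatHarmonizer(TransformerMixin, BaseEstimator):
    """Parametric empirical-Bayes ComBat as a scikit-learn transformer.

    Parameters
    ----------
    eb_tolerance : float
        Convergence tolerance of the iterated EB posterior solver.
    parametric : bool
        Only the parametric prior family is implemented; kept as a
        parameter for interface clarity.

    Fitted attributes
    -----------------
    batches_ : list of batch labels
    gamma_star_, delta_star_ : (n_batches, n_features) EB location/scale
    grand_mean_, var_pooled_ : per-feature standardization parameters
    beta_covariates_ : protected-covariate coefficients per feature
    """

    def __init__(self, eb_tolerance: float = 1e-4, parametric: bool = True) -> None:
        self.eb_tolerance = eb_tolerance
        self.parametric = parametric

    def fit(
        self,
        X: np.ndarray,
        y=None,
        *,
        batch: np.ndarray,
        design: np.ndarray | None = None,
    ) -> "CombatHarmonizer":
        """Estimate standardization and per-batch EB parameters.

        ``X`` is (n_samples, n_features); ``batch`` a label per sample;
        ``design`` the optional (n_samples, n_covariates) protected-
        covariate matrix (no intercept).
        """
        X = np.asarray(X, dtype=float)
        batch = np.asarray(batch)
        n, p = X.shape
        if batch.shape[0] != n:
            raise ValueError("batch must have one label per sample")
        self.batches_ = [b for b in pd.unique(batch)]
        counts = {b: int((batch == b).sum()) for b in self.batches_}
        for b, c in counts.items():
            if c < 2:
                raise ValueError(f"batch {b!r} has a single scan; ComBat requires >= 2")
        onehot = np.column_stack([(batch == b).astype(float) for b in self.batches_])
        if design is None:
            design = np.empty((n, 0))
        design = np.asarray(design, dtype=float)
        D = np.column_stack([onehot, design])
        rank = np.linalg.matrix_rank(D)
        if rank < D.shape[1]:
            aliased = []
            base = onehot
            r0 = np.linalg.matrix_rank(base)
            for j in range(design.shape[1]):
                r1 = np.linalg.matrix_rank(np.column_stack([base, design[:, j]]))
                if r1 == r0:
                    aliased.append(j)
                else:
                    base = np.column_stack([base, design[:, j]])
                    r0 = r1
            raise ValueError(f"rank-deficient design; aliased covariate columns: {aliased}")

        n_batch = len(self.batches_)
        B_hat, *_ = np.linalg.lstsq(D, X, rcond=None)
        props = np.array([counts[b] / n for b in self.batches_])
        self.grand_mean_ = props @ B_hat[:n_batch]
        resid = X - D @ B_hat
        self.var_pooled_ = (resid**2).mean(axis=0)
        self.var_pooled_ = np.where(self.var_pooled_ <= 0, 1e-12, self.var_pooled_)
        self.beta_covariates_ = B_hat[n_batch:]

        stand_mean = self.grand_mean_[None, :] + design @ self.beta_covariates_
        Z = (X - stand_mean) / np.sqrt(self.var_pooled_)[None, :]

        gamma_hat = np.vstack([Z[batch == b].mean(axis=0) for b in self.batches_])
        delta_hat = np.vstack([Z[batch == b].var(axis=0, ddof=1) for b in self.batches_])
        if len(self.batches_) == 1:
            # nothing to harmonize: identity adjustment by construction
            self.gamma_star_ = np.zeros_like(gamma_hat)
            self.delta_star_ = np.ones_like(delta_hat)
            self.gamma_hat_ = gamma_hat
            self.delta_hat_ = delta_hat
            self.n_features_in_ = p
            return self
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for i, b in enumerate(self.batches_):
            g_bar = gamma_hat[i].mean()
            t2 = gamma_hat[i].var(ddof=1)
            a = _aprior(delta_hat[i])
            bp = _bprior(delta_hat[i])
            gamma_star[i], delta_star[i] = _it_sol(
                Z[batch == b], gamma_hat[i], delta_hat[i], g_bar, t2, a, bp, self.eb_tolerance
            )
        self.gamma_star_ = gamma_star
        self.delta_star_ = delta_star
        self.gamma_hat_ = gamma_hat
        self.delta_hat_ = delta_hat
        self.n_features_in_ = p
        return self

    def transform(
        self,
        X: np.ndarray,
        *,
        batch: np.ndarray,
        design: np.ndarray | None = None,
    ) -> np.ndarray:
        """Remove batch location/scale; re-add grand and protected effects."""
        check_is_fitted(self, "gamma_star_")
        X = np.asarray(X, dtype=float)
        batch = np.asarray(batch)
        n, p = X.shape
        if p != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        unseen = [b for b in pd.unique(batch) if b not in self.batches_]
        if unseen:
            raise ValueError(f"unseen batch labels: {unseen}")
        if design is None:
            design = np.empty((n, 0))
        design = np.asarray(design, dtype=float)
        stand_mean = self.grand_mean_[None, :] + design @ self.beta_covariates_
        Z = (X - stand_mean) / np.sqrt(self.var_pooled_)[None, :]
        out = np.empty_like(Z)
        for i, b in enumerate(self.batches_):
            sel = batch == b
            if not sel.any():
                continue
            out[sel] = (Z[sel] - self.gamma_star_[i][None, :]) / np.sqrt(self.delta_star_[i])[None, :]
        out = out * np.sqrt(self.var_pooled_)[None, :] + stand_mean
        return out

    def fit_transform(self, X, y=None, **kwargs):  # noqa: D102 — sklearn signature
        return self.fit(X, y, **kwargs).transform(X, batch=kwargs["batch"], design=kwargs.get("design"))


def combat_fit(
    features: pd.DataFrame,
    batch_col: str = "batch",
    covariates: pd.DataFrame | None = None,
    config: HarmonizationConfig | None = None,
) -> tuple[CombatHarmonizer, pd.DataFrame | None]:
    """Fit ComBat on a feature table; returns (model, protected design)."""
    if config is None:
        config = HarmonizationConfig()
    cols = feature_columns(features)
    design = None
    if covariates is not None:
        design = build_protected_design(covariates, config.protected_variables)
    model = CombatHarmonizer(eb_tolerance=config.eb_tolerance)
    model.fit(
        features[cols].to_numpy(float),
        batch=features[batch_col].to_numpy(),
        design=None if design is None else design.to_numpy(float),
    )
    return model, design


def combat_apply(
    model: CombatHarmonizer,
    features: pd.DataFrame,
    batch_col: str = "batch",
    design: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply a fitted ComBat model; non-feature columns pass through."""
    cols = feature_columns(features)
    out = features.copy()
    out[cols] = model.transform(
        features[cols].to_numpy(float),
        batch=features[batch_col].to_numpy(),
        design=None if design is None else design.to_numpy(float),
    )
    return out


def ks_batch_assessment(
    features: pd.DataFrame,
    batch_col: str = "batch",
    config: HarmonizationConfig | None = None,
    method: str = "asymp",
) -> pd.DataFrame:
    """Two-sample KS test per feature between exactly two batches.

    Returns a DataFrame with columns ``feature, D, p, significant``;
    ``method`` may be "asymp" (default), "exact" or "auto".
    """
    if config is None:
        config = HarmonizationConfig()
    labels = pd.unique(features[batch_col])
    if len(labels) != 2:
        raise ValueError(f"KS assessment requires exactly 2 batches, got {list(labels)}")
    a = features[features[batch_col] == labels[0]]
    b = features[features[batch_col] == labels[1]]
    rows = []
    for f in feature_columns(features):
        res = stats.ks_2samp(a[f].to_numpy(float), b[f].to_numpy(float), method=method)
        rows.append({"feature": f, "D": res.statistic, "p": res.pvalue,
                     "significant": res.pvalue < config.ks_alpha})
    return pd.DataFrame(rows)
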