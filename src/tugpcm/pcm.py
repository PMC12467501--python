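"""Principal-component models with Varimax rotation and variable selection.

The modelling object follows the Model/Results convention: a
:class:`PrincipalComponentModel` is built from a subjects x variables
DataFrame; :meth:`~PrincipalComponentModel.fit` returns
:class:`PCMResults`, which carries the rotated loadings, eigenvalues,
per-component explained variance, communalities, the sampling-adequacy
statistics and the variable-removal log, and offers ``summary()``,
``scores()`` and ``plot_loadings()``.

Method
------
PCA is performed on the correlation matrix so every variable contributes
equally.  Suitability is screened with the Kaiser-Meyer-Olkin (KMO)
measure (> 0.5 required) and Bartlett's test of sphericity (p < 0.05).
Components with eigenvalue strictly greater than 1 are retained and rotated
with a Kaiser-row-normalized Varimax rotation.  Variables with a rotated
loading above 0.8 on some component are marked "retained"; while any
retained variable has a communality below 0.800, the single variable with
the lowest communality is removed and the model refitted.  Per-phase models
are built on each phase's 30 variables; a task-level model pools the
variables retained across phases.  Component scores use the regression
(Thompson) method on the rotated solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as sps

from .features import phase_columns

__all__ = [
    "AdequacyError",
    "PCMConfig",
    "PrincipalComponentModel",
    "PCMResults",
    "kmo_statistic",
    "bartlett_sphericity",
    "pca_correlation",
    "varimax_rotate",
    "fit_phase_pcm",
    "build_tug_pcm",
    "total_explained_variance",
    "compute_scores",
    "tucker_congruence",
]


class AdequacyError(RuntimeError):
    """The data failed the KMO / Bartlett suitability screen."""


@dataclass(frozen=True)
class PCMConfig:
    loading_threshold: float = 0.8
    communality_threshold: float = 0.800
    kmo_min: float = 0.5
    alpha: float = 0.05  # Bartlett significance requirement
    check_adequacy: bool = True
    max_varimax_iter: int = 100
    varimax_tol: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("loading_threshold", "communality_threshold", "kmo_min"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _correlation_matrix(data: pd.DataFrame) -> np.ndarray:
    sds = data.std(ddof=1)
    constant = sds.index[sds == 0].tolist()
    if constant:
        raise ValueError(
            f"constant (zero-variance) variable(s): {constant}; "
            "correlation-matrix PCA is undefined for them"
        )
    return np.corrcoef(data.to_numpy(dtype=float), rowvar=False)


def kmo_statistic(corr: np.ndarray) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r^2 / (sum r^2 + sum q^2) over off-diagonal elements, where q
    are the anti-image partial correlations obtained from the inverse of the
    correlation matrix: q_jk = −inv_jk / sqrt(inv_jj inv_kk).
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    if corr.shape != (p, p) or p < 2:
        raise ValueError("need a square correlation matrix with p >= 2")
    try:
        inv = sla.inv(corr)
    except sla.LinAlgError as exc:
        raise ValueError(
            "correlation matrix is singular; reduce the variable set before "
            "computing KMO"
        ) from exc
    if not np.all(np.isfinite(inv)) or np.linalg.cond(corr) > 1e12:
        raise ValueError(
            "correlation matrix is numerically singular; reduce the variable "
            "set before computing KMO"
        )
    d = np.sqrt(np.abs(np.diag(inv)))
    partial = -inv / np.outer(d, d)
    off = ~np.eye(p, dtype=bool)
    r2 = float((corr[off] ** 2).sum())
    q2 = float((partial[off] ** 2).sum())
    if r2 + q2 == 0.0:
        warnings.warn("KMO undefined: no off-diagonal correlation", stacklevel=2)
        return float("nan")
    return r2 / (r2 + q2)


def bartlett_sphericity(corr: np.ndarray, n_subjects: int) -> tuple:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = −(n − 1 − (2p + 5)/6) ln det R, df = p(p−1)/2.
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    if n_subjects <= p:
        raise ValueError("Bartlett's test needs more subjects than variables")
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0:
        raise ValueError("non-positive determinant: correlation matrix invalid")
    chi2 = -(n_subjects - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return float(chi2), int(df), float(sps.chi2.sf(chi2, df))


def pca_correlation(data: pd.DataFrame) -> tuple:
    """Eigendecomposition of the correlation matrix.

    Returns (eigenvalues desc, loadings) with loadings = eigenvectors scaled
    by sqrt(eigenvalues) over *all* components; retention is the caller's
    concern.
    """
    if data.shape[1] < 2:
        raise ValueError("PCA needs at least 2 variables")
    if data.shape[0] <= 2:
        raise ValueError("PCA needs more than 2 subjects")
    corr = _correlation_matrix(data)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    loadings = eigvec[:, order] * np.sqrt(eigval)
    return eigval, loadings


def varimax_rotate(loadings: np.ndarray, normalize: bool = True,
                   tol: float = 1e-6, max_iter: int = 100) -> np.ndarray:
    """Orthogonal Varimax rotation with Kaiser row normalization.

    Maximizes the varimax criterion (variance of squared loadings within
    each column); communalities — row sums of squares — are preserved.
    A single-component matrix is returned unchanged with a warning.
    """
    L = np.asarray(loadings, dtype=float)
    if L.ndim != 2:
        raise ValueError("loadings must be a 2-D array")
    p, k = L.shape
    if k < 2:
        warnings.warn("varimax is a no-op for a single component", stacklevel=2)
        return L.copy()
    h = np.sqrt((L**2).sum(axis=1))
    if normalize:
        safe = np.where(h > 0, h, 1.0)
        X = L / safe[:, None]
    else:
        X = L.copy()
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = X @ R
        tmp = X.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(tmp)
        R = u @ vt
        d_new = s.sum()
        if d_new < d * (1.0 + tol):
            break
        d = d_new
    out = X @ R
    # pairwise polish: the SVD iteration can stall just short of a local
    # optimum; planar sweeps finish the climb
    p_, _ = out.shape
    for _ in range(50):
        improved = False
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = out[:, i], out[:, j]
                u = x**2 - y**2
                v = 2.0 * x * y
                num = 2.0 * (p_ * (u * v).sum() - u.sum() * v.sum())
                den = p_ * (u**2 - v**2).sum() - (u.sum() ** 2 - v.sum() ** 2)
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) > 1e-9:
                    c, sn = np.cos(phi), np.sin(phi)
                    out[:, i], out[:, j] = c * x + sn * y, -sn * x + c * y
                    improved = True
        if not improved:
            break
    if normalize:
        out = out * safe[:, None]
    return out


def _order_and_sign(rotated: np.ndarray) -> np.ndarray:
    """Order components by explained variance (SS loadings) descending and
    make each component's largest-magnitude loading positive."""
    ss = (rotated**2).sum(axis=0)
    order = np.argsort(ss)[::-1]
    out = rotated[:, order]
    for j in range(out.shape[1]):
        i = np.argmax(np.abs(out[:, j]))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


@dataclass
class PCMResults:
    """Fitted principal-component model.

    Attributes
    ----------
    rotated_loadings : DataFrame, variables x components (pc1, pc2, ...)
    eigenvalues : ndarray, all correlation-matrix eigenvalues (descending)
    explained_variance_pct : ndarray, per retained component after rotation
    communalities : Series per variable (row sums of squared loadings)
    kmo, bartlett : adequacy statistics of the final variable set
    retained_variables : variables with |loading| > threshold somewhere
    excluded_low_communality : removal log, in removal order
    """

    model: "PrincipalComponentModel"
    rotated_loadings: pd.DataFrame
    eigenvalues: np.ndarray
    explained_variance_pct: np.ndarray
    communalities: pd.Series
    kmo: float
    bartlett: tuple
    n_subjects: int
    retained_variables: list
    excluded_low_communality: list = field(default_factory=list)
    _score_weights: pd.DataFrame | None = None
    _standardize: tuple | None = None

    @property
    def variable_names(self) -> list:
        return list(self.rotated_loadings.index)

    @property
    def n_components(self) -> int:
        return self.rotated_loadings.shape[1]

    @property
    def total_explained_variance(self) -> float:
        """Sum of the retained components' explained-variance percentages."""
        return float(np.sum(self.explained_variance_pct))

    def scores(self, data: pd.DataFrame | None = None) -> pd.DataFrame:
        """Regression-method component scores (standardized projection).

        With no argument, scores of the fitted sample are returned; their
        per-component mean is zero by construction.
        """
        if data is None:
            data = self.model.data
        missing = [v for v in self.variable_names if v not in data.columns]
        if missing:
            raise ValueError(f"missing model variable(s): {missing}")
        mu, sd = self._standardize
        z = (data[self.variable_names] - mu) / sd
        return z @ self._score_weights

    def summary(self) -> str:
        chi2, df, p = self.bartlett
        lines = [
            "Principal Component Model (correlation matrix, Varimax rotation)",
            "=" * 66,
            f"Subjects: {self.n_subjects}    Variables: {len(self.variable_names)}"
            f"    Components (eigenvalue > 1): {self.n_components}",
            f"KMO: {self.kmo:.3f}    Bartlett: chi2({df}) = {chi2:.2f}, p = {p:.3g}",
            f"Total explained variance: {self.total_explained_variance:.2f}%",
            "",
            "Explained variance per component (%):",
            "  " + "  ".join(
                f"pc{j + 1}: {v:.2f}" for j, v in enumerate(self.explained_variance_pct)
            ),
            "",
            f"Variables with |loading| > {self.model.config.loading_threshold}: "
            f"{len(self.retained_variables)}",
        ]
        if self.excluded_low_communality:
            lines.append(
                "Removed for low communality (in order): "
                + ", ".join(self.excluded_low_communality)
            )
        loading_df = self.rotated_loadings.round(3)
        lines += ["", "Rotated loadings:", loading_df.to_string()]
        return "\n".join(lines)

    def plot_loadings(self, ax=None):
        """Heatmap of the rotated loading matrix (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(
                figsize=(1.0 + 0.45 * self.n_components,
                         1.0 + 0.22 * len(self.variable_names))
            )
        im = ax.imshow(
            self.rotated_loadings.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r",
            aspect="auto",
        )
        ax.set_xticks(range(self.n_components),
                      labels=self.rotated_loadings.columns)
        ax.set_yticks(range(len(self.variable_names)),
                      labels=self.variable_names, fontsize=7)
        ax.figure.colorbar(im, ax=ax, label="loading")
        return ax

    def to_dict(self) -> dict:
        chi2, df, p = self.bartlett
        return {
            "variables": self.variable_names,
            "components": list(self.rotated_loadings.columns),
            "rotated_loadings": self.rotated_loadings.to_numpy().tolist(),
            "eigenvalues": np.asarray(self.eigenvalues).tolist(),
            "explained_variance_pct": np.asarray(
                self.explained_variance_pct
            ).tolist(),
            "communalities": self.communalities.to_dict(),
            "kmo": None if np.isnan(self.kmo) else self.kmo,
            "bartlett": {"chi2": chi2, "df": df, "p": p},
            "n_subjects": self.n_subjects,
            "retained_variables": self.retained_variables,
            "excluded_low_communality": self.excluded_low_communality,
        }


class PrincipalComponentModel:
    """Correlation-matrix PCA with Varimax rotation and variable selection.

    Parameters
    ----------
    data : DataFrame
        Subjects x variables; index identifies subjects.
    config : PCMConfig
        Thresholds (loading 0.8, communality 0.800, KMO > 0.5, Bartlett
        alpha 0.05) and rotation controls.
    """

    def __init__(self, data: pd.DataFrame, config: PCMConfig = PCMConfig()):
        if data.columns.duplicated().any():
            raise ValueError("duplicate variable names")
        self.data = data.astype(float)
        self.config = config

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, columns=None, **kwargs):
        cfg = PCMConfig(**kwargs) if kwargs else PCMConfig()
        return cls(data[list(columns)] if columns is not None else data, cfg)

    # -- single fit ---------------------------------------------------------

    def _fit_once(self, data: pd.DataFrame, check_adequacy: bool | None = None
                  ) -> PCMResults:
        cfg = self.config
        gate = cfg.check_adequacy if check_adequacy is None else check_adequacy
        n = data.shape[0]
        corr = _correlation_matrix(data)
        try:
            kmo = kmo_statistic(corr)
            bart = bartlett_sphericity(corr, n)
        except ValueError:
            if gate:
                raise
            # pooled fits with many variables relative to subjects can have a
            # (near-)singular correlation matrix; report NaN adequacy there
            warnings.warn(
                "adequacy statistics unavailable (singular correlation matrix "
                "or n <= p); reporting NaN", stacklevel=2,
            )
            p_ = corr.shape[0]
            kmo = float("nan")
            bart = (float("nan"), p_ * (p_ - 1) // 2, float("nan"))
        if gate:
            if not kmo > cfg.kmo_min:
                raise AdequacyError(
                    f"KMO {kmo:.3f} does not exceed {cfg.kmo_min} "
                    f"(Bartlett chi2={bart[0]:.1f}, p={bart[2]:.3g})"
                )
            if not bart[2] < cfg.alpha:
                raise AdequacyError(
                    f"Bartlett's sphericity not significant "
                    f"(p={bart[2]:.3g}, KMO={kmo:.3f})"
                )
        eigval, loadings = pca_correlation(data)
        n_keep = int(np.sum(eigval > 1.0))  # strictly greater than 1
        n_keep = max(n_keep, 1)
        kept = loadings[:, :n_keep]
        if n_keep >= 2:
            rotated = varimax_rotate(
                kept, tol=cfg.varimax_tol, max_iter=cfg.max_varimax_iter
            )
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rotated = varimax_rotate(kept)
        rotated = _order_and_sign(rotated)
        p = data.shape[1]
        explained = 100.0 * (rotated**2).sum(axis=0) / p
        communality = pd.Series((rotated**2).sum(axis=1), index=data.columns)
        comp_names = [f"pc{j + 1}" for j in range(n_keep)]
        loading_df = pd.DataFrame(rotated, index=data.columns, columns=comp_names)
        retained = loading_df.index[
            (loading_df.abs() > cfg.loading_threshold).any(axis=1)
        ].tolist()
        # regression (Thompson) score weights on the rotated solution;
        # pseudo-inverse covers the (near-)singular pooled case
        try:
            w = sla.solve(corr, rotated, assume_a="sym")
        except sla.LinAlgError:
            w = np.linalg.pinv(corr) @ rotated
        weights = pd.DataFrame(w, index=data.columns, columns=comp_names)
        res = PCMResults(
            model=self,
            rotated_loadings=loading_df,
            eigenvalues=eigval,
            explained_variance_pct=explained,
            communalities=communality,
            kmo=kmo,
            bartlett=bart,
            n_subjects=n,
            retained_variables=retained,
        )
        res._score_weights = weights
        res._standardize = (data.mean(), data.std(ddof=1))
        return res

    def fit(self, prune: bool = False) -> PCMResults:
        """Fit the model; with ``prune=True`` run the communality-exclusion
        loop (remove the lowest-communality variable and refit while any
        |loading| > threshold variable has communality below threshold).

        The adequacy screen gates the initial fit only; refits inside the
        exclusion loop are not re-gated (the final model still reports its
        own KMO and Bartlett statistics).
        """
        data = self.data
        removed = []
        first = True
        while True:
            res = self._fit_once(data, check_adequacy=None if first else False)
            first = False
            if not prune:
                break
            low = res.communalities.loc[res.retained_variables]
            offending = low.index[low < self.config.communality_threshold]
            if offending.empty or data.shape[1] <= 2:
                break
            # the exclusion pool is the high-loading set itself: variables
            # that load strongly but whose variance the retained components
            # explain poorly are the ones dropped, one at a time
            worst = low.loc[offending].idxmin()
            removed.append(worst)
            data = data.drop(columns=[worst])
        res.excluded_low_communality = removed
        return res


# ---------------------------------------------------------------------------
# task-level conveniences mirroring the published procedure


def fit_phase_pcm(feature_table: pd.DataFrame, phase: str,
                  config: PCMConfig = PCMConfig()) -> PCMResults:
    """Fit the PCM of one TUG phase (its 30 variables), with the adequacy
    screen and the communality-exclusion loop."""
    cols = [c for c in phase_columns(phase) if c in feature_table.columns]
    if not cols:
        raise ValueError(f"feature table has no columns for phase {phase!r}")
    model = PrincipalComponentModel(feature_table[cols], config)
    return model.fit(prune=True)


def build_tug_pcm(feature_table: pd.DataFrame, retained_variables,
                  config: PCMConfig = PCMConfig()) -> PCMResults:
    """Fit the task-level PCM on the variables retained across phase models.

    The pooled fit keeps the eigenvalue > 1 retention and loading flags but
    does not re-run the communality pruning; adequacy statistics are
    computed and reported, not gated (whether the pooled model re-screens
    adequacy is a procedural choice; see the methods note).
    """
    retained_variables = list(retained_variables)
    if not retained_variables:
        raise ValueError("no retained variables to pool")
    missing = [v for v in retained_variables if v not in feature_table.columns]
    if missing:
        raise ValueError(f"missing retained variable(s): {missing}")
    cfg = PCMConfig(
        loading_threshold=config.loading_threshold,
        communality_threshold=config.communality_threshold,
        kmo_min=config.kmo_min,
        alpha=config.alpha,
        check_adequacy=False,
        max_varimax_iter=config.max_varimax_iter,
        varimax_tol=config.varimax_tol,
    )
    model = PrincipalComponentModel(feature_table[retained_variables], cfg)
    return model.fit(prune=False)


def total_explained_variance(result_or_pct) -> float:
    """Total explained variance (%) of a fitted model, or of a sequence of
    per-component percentages."""
    if isinstance(result_or_pct, PCMResults):
        return result_or_pct.total_explained_variance
    return float(np.sum(np.asarray(result_or_pct, dtype=float)))


def compute_scores(results: PCMResults, feature_table: pd.DataFrame | None = None
                   ) -> pd.DataFrame:
    """Component scores; see :meth:`PCMResults.scores`."""
    return results.scores(feature_table)


def tucker_congruence(x: np.ndarray, y: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    if denom == 0:
        return float("nan")
    return float(np.abs((x * y).sum()) / denom)
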