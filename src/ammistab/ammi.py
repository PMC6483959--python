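"""Additive Main effects and Multiplicative Interaction (AMMI) model.

The AMMI model for a balanced genotype x environment table of cell means
``y_ge`` combines a two-way fixed-effects ANOVA for the main effects with a
principal-component (SVD) decomposition of the interaction residual:

    y_ge = mu + alpha_g + beta_e + sum_n lambda_n * gamma_gn * delta_en + Q_ge

where ``mu`` is the grand mean, ``alpha_g`` / ``beta_e`` the zero-sum
genotype / environment main effects, ``lambda_n`` the singular values of the
doubly-centered interaction matrix, ``gamma_gn`` / ``delta_en`` unit-norm
genotype / environment eigenvectors, and ``Q_ge`` the residual beyond the
``N`` retained axes.  Scores are reported with symmetric scaling
(``sqrt(lambda_n) * gamma_gn`` and ``sqrt(lambda_n) * delta_en``), so each
axis's genotype and environment score vectors both have squared norm
``lambda_n`` and the per-axis interaction sum of squares on the
replicate-total scale is ``r * lambda_n**2``.

Axis significance uses Gollob's approximate F-test with
``df_n = G + E - 1 - 2n`` against a replicate-level error mean square.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .ge_data import GEMatrix, ReplicateTable

__all__ = [
    "AMMI",
    "center_interaction",
    "ammi_decompose",
    "anova_from_means",
    "anova_two_way",
    "gollob_axis_tests",
    "biplot_coordinates",
    "gollob_df",
]


def _as_matrix(X, replicates: Optional[int] = None) -> GEMatrix:
    if isinstance(X, GEMatrix):
        if replicates is not None and replicates != X.replicates:
            return GEMatrix(X.values, X.genotype_ids, X.environment_ids, replicates)
        return X
    if isinstance(X, pd.DataFrame):
        return GEMatrix.from_frame(X, replicates=replicates or 1)
    X = np.asarray(X, dtype=float)
    G, E = X.shape
    return GEMatrix(
        X,
        tuple(f"G{i + 1}" for i in range(G)),
        tuple(f"E{j + 1}" for j in range(E)),
        replicates=replicates or 1,
    )


def center_interaction(ge: GEMatrix | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Doubly-centered interaction matrix Z_ge = y_ge - y_g. - y_.e + y_..

    Every row and column of the result sums to zero; its squared Frobenius
    norm times the replicate count is the interaction sum of squares.
    """
    ge = _as_matrix(ge)
    Y = ge.values
    return Y - Y.mean(axis=1, keepdims=True) - Y.mean(axis=0, keepdims=True) + Y.mean()


def gollob_df(G: int, E: int, n: int) -> int:
    """Gollob degrees of freedom for interaction axis ``n`` (1-based)."""
    return G + E - 1 - 2 * n


class AMMI(BaseEstimator):
    """AMMI decomposition of a balanced genotype x environment trial.

    A decomposition estimator in the scikit-learn idiom: ``fit`` takes a
    ``(G, E)`` table of cell means (a :class:`~ammistab.ge_data.GEMatrix`,
    DataFrame, or array), estimates the additive main effects, and extracts
    the multiplicative interaction axes by SVD of the doubly-centered
    residual.

    Parameters
    ----------
    n_components : int or "auto", default "auto"
        Number of interaction axes N retained in the adjusted model.  With
        ``"auto"``: all axes whose Gollob test is significant at ``alpha``
        when an error mean square is available, else 2 (the biplot minimum).
    replicates : int, optional
        Override for the replicate count behind each cell mean.
    error_ms, error_df : float, int, optional
        Replicate-level error mean square and its degrees of freedom, used
        for Gollob axis tests (and automatic axis selection).
    alpha : float, default 0.05
        Significance level for automatic axis retention.

    Attributes
    ----------
    grand_mean_ : float
    genotype_effects_, environment_effects_ : ndarray
        Zero-sum main effects alpha_g and beta_e.
    singular_values_ : ndarray, shape (M,)
        lambda_n on the cell-means scale, descending; M = min(G-1, E-1).
    genotype_scores_, environment_scores_ : ndarray
        Symmetrically scaled IPCA scores, shapes (G, M) and (E, M).
    axis_ss_ : ndarray
        Per-axis interaction SS on the replicate-total scale, r*lambda_n**2.
    axis_df_ : ndarray
        Gollob degrees of freedom per axis.
    axis_pct_ : ndarray
        Percentage of the interaction SS captured by each axis.
    n_components_ : int
        Number of retained axes N.
    residual_ : ndarray
        Q_ge for the retained N (zero matrix when N = M).
    """

    def __init__(
        self,
        n_components: int | str = "auto",
        replicates: Optional[int] = None,
        error_ms: Optional[float] = None,
        error_df: Optional[int] = None,
        alpha: float = 0.05,
    ):
        self.n_components = n_components
        self.replicates = replicates
        self.error_ms = error_ms
        self.error_df = error_df
        self.alpha = alpha

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y=None) -> "AMMI":
        ge = _as_matrix(X, self.replicates)
        Y = ge.values
        G, E = Y.shape
        r = ge.replicates
        self.genotype_ids_ = list(ge.genotype_ids)
        self.environment_ids_ = list(ge.environment_ids)
        self.replicates_ = r
        self.grand_mean_ = float(Y.mean())
        self.genotype_effects_ = Y.mean(axis=1) - self.grand_mean_
        self.environment_effects_ = Y.mean(axis=0) - self.grand_mean_

        Z = center_interaction(ge)
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        M = min(G - 1, E - 1)
        U, s, Vt = U[:, :M], s[:M], Vt[:M]
        self._order_and_sign(U, s, Vt)

        # a purely additive table leaves only floating-point residue in Z;
        # treat it as exactly zero interaction
        tiny = 1e-12 * max(1.0, float(np.abs(Y).max()) ** 2)
        degenerate = float((s**2).sum()) <= tiny
        if degenerate:
            s = np.zeros_like(s)

        root = np.sqrt(s)
        self.singular_values_ = s
        self.genotype_scores_ = U * root
        self.environment_scores_ = Vt.T * root
        self.axis_ss_ = r * s**2
        self.axis_df_ = np.array([gollob_df(G, E, n) for n in range(1, M + 1)])
        ss_ge = float(self.axis_ss_.sum())
        if not degenerate:
            self.axis_pct_ = 100.0 * self.axis_ss_ / ss_ge
        else:
            warnings.warn(
                "interaction sum of squares is zero; axis percentages undefined",
                RuntimeWarning,
                stacklevel=2,
            )
            self.axis_pct_ = np.zeros(M)
        self.interaction_ss_ = ss_ge
        self.n_components_ = self._select_axes(M)
        N = self.n_components_
        self.residual_ = Z - (self.genotype_scores_[:, :N] @ self.environment_scores_[:, :N].T)
        return self

    def _order_and_sign(self, U: np.ndarray, s: np.ndarray, Vt: np.ndarray) -> None:
        """Deterministic axis order and signs, in place.

        numpy returns singular values descending already; exact ties are
        broken by the sign of the first environment loading, then original
        order.  Per axis, signs are flipped so the environment score of
        largest magnitude is positive (scores enter ASV only through their
        magnitudes, so this is cosmetic but makes output reproducible).
        """
        order = sorted(range(len(s)), key=lambda n: (-s[n], -np.sign(Vt[n, 0]), n))
        s[:] = s[order]
        U[:] = U[:, order]
        Vt[:] = Vt[order]
        for n in range(len(s)):
            j = int(np.argmax(np.abs(Vt[n])))
            if Vt[n, j] < 0:
                Vt[n] *= -1.0
                U[:, n] *= -1.0

    def _select_axes(self, M: int) -> int:
        if self.n_components == "auto":
            if self.error_ms is not None and self.error_df is not None:
                table = gollob_axis_tests(self, self.error_ms, self.error_df, n_axes=M)
                p = table["p_value"].to_numpy()[:M]
                return max(int((p < self.alpha).sum()), 1)
            return min(2, M)
        n = int(self.n_components)
        if not 1 <= n <= M:
            raise ValueError(f"n_components must be in [1, {M}], got {n}")
        return n

    # -- derived quantities ----------------------------------------------
    def fitted_values(self, n_components: Optional[int] = None) -> np.ndarray:
        """Model-fitted cell means with the first ``n_components`` axes.

        With all M axes this reconstructs the observed table exactly.
        """
        check_is_fitted(self, "grand_mean_")
        N = len(self.singular_values_) if n_components is None else n_components
        bilinear = self.genotype_scores_[:, :N] @ self.environment_scores_[:, :N].T
        return (
            self.grand_mean_
            + self.genotype_effects_[:, None]
            + self.environment_effects_[None, :]
            + bilinear
        )

    def transform(self, X) -> np.ndarray:
        """Project genotype rows observed in the fitted environments.

        Rows are centered against their own mean and the fitted environment
        effects, then projected on the environment eigenvectors; training
        rows map to ``genotype_scores_``.
        """
        check_is_fitted(self, "grand_mean_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.environment_ids_):
            raise ValueError(
                f"expected {len(self.environment_ids_)} environment columns"
            )
        Z = X - X.mean(axis=1, keepdims=True) - self.environment_effects_[None, :]
        root = np.sqrt(self.singular_values_)
        delta = self.environment_scores_ / np.where(root > 0, root, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = Z @ delta / np.where(root > 0, root, np.inf)
        return scores

    def score_table(self) -> pd.DataFrame:
        """Genotype and environment IPCA scores as a tidy frame."""
        check_is_fitted(self, "grand_mean_")
        M = len(self.singular_values_)
        cols = [f"IPCA{n}" for n in range(1, M + 1)]
        gen = pd.DataFrame(self.genotype_scores_, index=self.genotype_ids_, columns=cols)
        env = pd.DataFrame(
            self.environment_scores_, index=self.environment_ids_, columns=cols
        )
        gen.insert(0, "entity_type", "genotype")
        env.insert(0, "entity_type", "environment")
        return pd.concat([gen, env])


def ammi_decompose(
    ge: GEMatrix | pd.DataFrame | np.ndarray,
    n_components: int | str = "auto",
    **kwargs,
) -> AMMI:
    """Fit an :class:`AMMI` model; thin functional wrapper."""
    return AMMI(n_components=n_components, **kwargs).fit(ge)


# ---------------------------------------------------------------------------
# ANOVA tables

_ANOVA_COLS = ["source", "df", "ss", "ms", "f_statistic", "p_value", "pct_explained"]


def _anova_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=_ANOVA_COLS)


def anova_from_means(
    ge: GEMatrix | pd.DataFrame | np.ndarray,
    error_ms: Optional[float] = None,
    error_df: Optional[int] = None,
) -> pd.DataFrame:
    """Two-way ANOVA main-effect/interaction partition from cell means.

    Sums of squares are on the replicate-total scale (means-scale SS times
    ``r``).  F statistics and p-values are filled in only when an external
    error mean square (with its df) is supplied.
    """
    if (error_ms is None) != (error_df is None):
        raise ValueError("error_ms and error_df must be supplied together")
    ge = _as_matrix(ge)
    Y, r = ge.values, ge.replicates
    G, E = Y.shape
    gm = Y.mean()
    ss_g = r * E * ((Y.mean(axis=1) - gm) ** 2).sum()
    ss_e = r * G * ((Y.mean(axis=0) - gm) ** 2).sum()
    ss_ge = r * (center_interaction(ge) ** 2).sum()
    rows = [
        {"source": "Genotypes", "df": G - 1, "ss": ss_g},
        {"source": "Environments", "df": E - 1, "ss": ss_e},
        {"source": "Interactions", "df": (G - 1) * (E - 1), "ss": ss_ge},
    ]
    if error_ms is not None:
        rows.append(
            {"source": "Error", "df": error_df, "ss": error_ms * error_df}
        )
    total_ss = sum(row["ss"] for row in rows)
    for row in rows:
        row["ms"] = row["ss"] / row["df"] if row["df"] > 0 else np.nan
        row["pct_explained"] = 100.0 * row["ss"] / total_ss if total_ss > 0 else np.nan
        if error_ms is not None and row["source"] != "Error" and error_ms > 0:
            row["f_statistic"] = row["ms"] / error_ms
            row["p_value"] = stats.f.sf(row["f_statistic"], row["df"], error_df)
    return _anova_frame(rows)


def anova_two_way(rep: ReplicateTable) -> pd.DataFrame:
    """Replicate-level two-way fixed-effects ANOVA of a balanced trial.

    Requires r >= 2 so a within-cell error stratum exists; F-statistics test
    each source against the pooled error mean square.
    """
    r = rep.n_replicates
    if r < 2:
        raise ValueError(
            "replicate-level ANOVA needs r >= 2; with a single observation "
            "per cell use anova_from_means with an external error term"
        )
    ge = rep.to_matrix()
    G, E = ge.values.shape
    obs = rep.records["value"].to_numpy(dtype=float)
    cell_means = (
        rep.records.groupby(["genotype", "environment"])["value"].transform("mean")
    ).to_numpy(dtype=float)
    ss_error = float(((obs - cell_means) ** 2).sum())
    df_error = G * E * (r - 1)
    error_ms = ss_error / df_error
    table = anova_from_means(ge, error_ms=error_ms, error_df=df_error)
    return table


def gollob_axis_tests(
    model: AMMI,
    error_ms: float,
    error_df: int,
    n_axes: Optional[int] = None,
) -> pd.DataFrame:
    """Gollob F-tests for the interaction principal component axes.

    Axis ``n`` carries ``G + E - 1 - 2n`` degrees of freedom; the leftover
    interaction SS beyond the tested axes forms a residual row.  Percentages
    are of the interaction SS.
    """
    check_is_fitted(model, "axis_ss_")
    if error_ms <= 0:
        raise ValueError("error_ms must be positive")
    M = len(model.axis_ss_)
    if n_axes is None:
        n_axes = model.n_components_
    if not 1 <= n_axes <= M:
        raise ValueError(f"n_axes must be in [1, {M}], got {n_axes}")
    ss_ge = model.interaction_ss_
    rows = []
    for n in range(n_axes):
        df_n = int(model.axis_df_[n])
        ss_n = float(model.axis_ss_[n])
        ms_n = ss_n / df_n
        rows.append(
            {
                "source": f"IPCA{n + 1}",
                "df": df_n,
                "ss": ss_n,
                "ms": ms_n,
                "f_statistic": ms_n / error_ms,
                "p_value": stats.f.sf(ms_n / error_ms, df_n, error_df),
                "pct_explained": 100.0 * ss_n / ss_ge if ss_ge > 0 else np.nan,
            }
        )
    df_resid = (
        (len(model.genotype_ids_) - 1) * (len(model.environment_ids_) - 1)
        - int(model.axis_df_[:n_axes].sum())
    )
    ss_resid = ss_ge - float(model.axis_ss_[:n_axes].sum())
    if df_resid > 0:
        ms_resid = ss_resid / df_resid
        rows.append(
            {
                "source": "Residuals",
                "df": df_resid,
                "ss": ss_resid,
                "ms": ms_resid,
                "f_statistic": ms_resid / error_ms,
                "p_value": stats.f.sf(ms_resid / error_ms, df_resid, error_df),
                "pct_explained": 100.0 * ss_resid / ss_ge if ss_ge > 0 else np.nan,
            }
        )
    return _anova_frame(rows)


def biplot_coordinates(
    model: AMMI,
    ge: GEMatrix | pd.DataFrame | np.ndarray,
    kind: str = "ammi2",
) -> pd.DataFrame:
    """Coordinates for the two standard AMMI biplots.

    ``"ammi1"`` plots entity mean (x) against IPCA1 score (y);
    ``"ammi2"`` plots IPCA1 (x) against IPCA2 (y).  The grand mean is
    attached as frame metadata (``.attrs["grand_mean"]``) for the AMMI1
    reference line.
    """
    check_is_fitted(model, "grand_mean_")
    ge = _as_matrix(ge)
    if kind not in ("ammi1", "ammi2"):
        raise ValueError("kind must be 'ammi1' or 'ammi2'")
    if kind == "ammi2" and len(model.singular_values_) < 2:
        raise ValueError("ammi2 biplot needs at least two interaction axes")
    labels = list(model.genotype_ids_) + list(model.environment_ids_)
    entity = ["genotype"] * len(model.genotype_ids_) + ["environment"] * len(
        model.environment_ids_
    )
    ipca1 = np.concatenate(
        [model.genotype_scores_[:, 0], model.environment_scores_[:, 0]]
    )
    if kind == "ammi1":
        x = np.concatenate(
            [ge.values.mean(axis=1), ge.values.mean(axis=0)]
        )
        y = ipca1
    else:
        x = ipca1
        y = np.concatenate(
            [model.genotype_scores_[:, 1], model.environment_scores_[:, 1]]
        )
    out = pd.DataFrame(
        {"label": labels, "entity_type": entity, "x": x, "y": y}
    )
    out.attrs["grand_mean"] = model.grand_mean_
    out.attrs["kind"] = kind
    return out
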