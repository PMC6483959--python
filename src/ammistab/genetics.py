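"""Additive and epistatic gene-effect estimation from doubled-haploid lines.

In a doubled-haploid (DH) population every locus is homozygous, so line
means carry additive and additive-by-additive (epistatic) effects but no
dominance.  The quantile method identifies *extreme* line groups — lines
below the ``q_low`` (default 0.03) or above the ``q_high`` (default 0.97)
empirical quantile of the line-mean distribution — which in theory
accumulate only trait-decreasing / only trait-increasing alleles.  From the
group means ``L_min``, ``L_max`` and the whole-population mean ``L``:

    a_DH  = (L_max - L_min) / 2          total additive effect
    aa_DH = (L_max + L_min) / 2 - L      total epistatic effect

and from the better- and lower-scoring parent means ``P1 >= P2``:

    a_Parents = (P1 - P2) / 2.

Each effect is a single-degree-of-freedom linear contrast of line means;
given a replicate-level error mean square ``MS_e``, the test statistic is
``F = MS_effect / MS_e`` on (1, error_df) degrees of freedom, where
``MS_effect = estimate^2 * m / sum(c^2)`` with contrast coefficients ``c``
and ``m`` observations behind each line mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .ge_data import GEMatrix, GenotypeMeta

__all__ = [
    "ExtremeGroups",
    "extreme_lines",
    "additive_effect_dh",
    "epistasis_effect_dh",
    "additive_effect_parents",
    "contrast_f_test",
    "QuantileGeneticEffects",
    "genetic_effects_grid",
    "significance_stars",
]


@dataclass(frozen=True)
class ExtremeGroups:
    """Minimal / maximal DH-line groups from the quantile method."""

    minimal_lines: tuple[str, ...]
    maximal_lines: tuple[str, ...]
    q_low: float = 0.03
    q_high: float = 0.97

    def __post_init__(self) -> None:
        if not self.minimal_lines or not self.maximal_lines:
            raise ValueError("extreme groups must be nonempty")
        if set(self.minimal_lines) & set(self.maximal_lines):
            raise ValueError(
                "minimal and maximal groups overlap; widen the quantile gap "
                f"(q_low={self.q_low}, q_high={self.q_high}) or check for a "
                "degenerate (near-constant) trait distribution"
            )


def _as_series(line_means) -> pd.Series:
    s = pd.Series(line_means, dtype=float)
    if s.index.inferred_type in ("integer", "range"):
        s.index = [f"L{i}" for i in s.index]
    return s


def extreme_lines(line_means, q_low: float = 0.03, q_high: float = 0.97) -> ExtremeGroups:
    """Identify minimal/maximal DH lines by the empirical quantile method.

    Quantiles use linear interpolation of order statistics (numpy default).
    The global minimum / maximum line is always included, so both groups are
    nonempty even when the quantile falls below every observation.
    """
    if not 0 < q_low < q_high < 1:
        raise ValueError("require 0 < q_low < q_high < 1")
    s = _as_series(line_means)
    if len(s) < 3:
        raise ValueError("need at least 3 DH lines")
    lo, hi = np.quantile(s.to_numpy(), [q_low, q_high])
    minimal = set(s.index[s <= lo]) | {s.idxmin()}
    maximal = set(s.index[s >= hi]) | {s.idxmax()}
    return ExtremeGroups(
        tuple(sorted(minimal)), tuple(sorted(maximal)), q_low, q_high
    )


def additive_effect_dh(groups: ExtremeGroups, line_means) -> float:
    """Total additive effect: half the maximal-minus-minimal group mean gap."""
    s = _as_series(line_means)
    return 0.5 * float(
        s[list(groups.maximal_lines)].mean() - s[list(groups.minimal_lines)].mean()
    )


def epistasis_effect_dh(groups: ExtremeGroups, line_means) -> float:
    """Total additive-by-additive effect: extreme-group midpoint minus L-bar.

    ``line_means`` must cover *all* DH lines of the subset under analysis
    (its mean is the population mean L-bar).
    """
    s = _as_series(line_means)
    mid = 0.5 * (
        s[list(groups.maximal_lines)].mean() + s[list(groups.minimal_lines)].mean()
    )
    return float(mid - s.mean())


def additive_effect_parents(p1_mean: float, p2_mean: float) -> float:
    """Half the better-minus-lower parent difference (nonnegative)."""
    return 0.5 * abs(float(p1_mean) - float(p2_mean))


def contrast_f_test(
    estimate: float,
    coef_sq_sum: float,
    error_ms: float,
    error_df: int,
    n_obs_per_mean: int,
) -> tuple[float, float, float]:
    """F-test of a single-df contrast of line means against an error MS.

    Parameters
    ----------
    estimate
        The contrast value ``c' ybar``.
    coef_sq_sum
        ``sum(c_i^2)`` over the contrast coefficients.
    error_ms, error_df
        Replicate-level error mean square and its degrees of freedom.
    n_obs_per_mean
        Observations behind each line mean (``r`` per environment, ``r*E``
        for a cross-environment mean).

    Returns
    -------
    (ms, f, p)
    """
    if error_ms <= 0 or error_df < 1:
        raise ValueError("need a positive error_ms with error_df >= 1")
    ms = estimate**2 * n_obs_per_mean / coef_sq_sum
    f = ms / error_ms
    return ms, f, float(stats.f.sf(f, 1, error_df))


def _additive_coef_sq(n_min: int, n_max: int) -> float:
    return 0.25 / n_min + 0.25 / n_max


def _epistasis_coef_sq(n_min: int, n_max: int, n_all: int) -> float:
    # coefficients: 1/(2 n_max) - 1/n on max lines, 1/(2 n_min) - 1/n on min
    # lines, -1/n elsewhere
    n = n_all
    c_max = 0.5 / n_max - 1.0 / n
    c_min = 0.5 / n_min - 1.0 / n
    c_rest = -1.0 / n
    return n_max * c_max**2 + n_min * c_min**2 + (n - n_max - n_min) * c_rest**2


class QuantileGeneticEffects(BaseEstimator):
    """Quantile-method estimator of total additive and epistatic effects.

    ``fit`` takes the DH line means of one analysis context (a single
    environment or the cross-environment means) and estimates ``a_DH`` and
    ``aa_DH``; with an error mean square it also computes the contrast
    F-tests.

    Parameters
    ----------
    q_low, q_high : float
        Empirical quantiles bounding the minimal / maximal groups.
    error_ms, error_df : float, int, optional
        Replicate-level error mean square and df for the F-tests.
    n_obs_per_mean : int, default 1
        Observations averaged into each line mean (r, or r*E for a
        cross-environment mean).

    Attributes
    ----------
    groups_ : ExtremeGroups
    a_dh_, aa_dh_ : float
    l_min_mean_, l_max_mean_, l_mean_ : float
    f_a_, p_a_, f_aa_, p_aa_ : float (nan without an error term)
    """

    def __init__(
        self,
        q_low: float = 0.03,
        q_high: float = 0.97,
        error_ms: Optional[float] = None,
        error_df: Optional[int] = None,
        n_obs_per_mean: int = 1,
    ):
        self.q_low = q_low
        self.q_high = q_high
        self.error_ms = error_ms
        self.error_df = error_df
        self.n_obs_per_mean = n_obs_per_mean

    def fit(self, X, y=None) -> "QuantileGeneticEffects":
        s = _as_series(X)
        groups = extreme_lines(s, self.q_low, self.q_high)
        self.line_ids_ = list(s.index)
        self.groups_ = groups
        self.l_min_mean_ = float(s[list(groups.minimal_lines)].mean())
        self.l_max_mean_ = float(s[list(groups.maximal_lines)].mean())
        self.l_mean_ = float(s.mean())
        self.a_dh_ = additive_effect_dh(groups, s)
        self.aa_dh_ = epistasis_effect_dh(groups, s)
        n_min, n_max = len(groups.minimal_lines), len(groups.maximal_lines)
        self.ms_a_ = self.f_a_ = self.p_a_ = np.nan
        self.ms_aa_ = self.f_aa_ = self.p_aa_ = np.nan
        if self.error_ms is not None and self.error_df is not None:
            self.ms_a_, self.f_a_, self.p_a_ = contrast_f_test(
                self.a_dh_,
                _additive_coef_sq(n_min, n_max),
                self.error_ms,
                self.error_df,
                self.n_obs_per_mean,
            )
            self.ms_aa_, self.f_aa_, self.p_aa_ = contrast_f_test(
                self.aa_dh_,
                _epistasis_coef_sq(n_min, n_max, len(s)),
                self.error_ms,
                self.error_df,
                self.n_obs_per_mean,
            )
        return self

    def predict(self, X=None) -> dict:
        """Return the fitted effect estimates as a plain dict."""
        check_is_fitted(self, "a_dh_")
        return {
            "a_dh": self.a_dh_,
            "aa_dh": self.aa_dh_,
            "L_min_mean": self.l_min_mean_,
            "L_max_mean": self.l_max_mean_,
            "L_mean": self.l_mean_,
        }


def significance_stars(p: float) -> str:
    """Field convention: * P<0.05, ** P<0.01, *** P<0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def genetic_effects_grid(
    ge: GEMatrix,
    meta: Sequence[GenotypeMeta],
    q_low: float = 0.03,
    q_high: float = 0.97,
    error_ms: Optional[float] = None,
    error_df: Optional[int] = None,
) -> pd.DataFrame:
    """Full gene-effect grid: per environment and cross-environment mean.

    Rows are (parameter, subset): ``a_parents`` over the two parents, and
    ``a_dh`` / ``aa_dh`` for all DH lines and for each seed-type subset
    present.  Extremes are re-identified *within* each subset; parents are
    excluded from all DH groups.  With an error term, companion ``*_p``
    and ``*_stars`` columns are added.
    """
    meta_by_id = {m.genotype_id: m for m in meta}
    unknown = [g for g in ge.genotype_ids if g not in meta_by_id]
    if unknown:
        raise ValueError(f"genotypes without metadata: {unknown}")
    parents = [g for g in ge.genotype_ids if meta_by_id[g].role == "parent"]
    if len(parents) != 2:
        raise ValueError(
            f"parental estimates need exactly two parents, found {len(parents)}"
        )
    frame = ge.to_frame()
    frame["Mean"] = frame.mean(axis=1)
    contexts = list(ge.environment_ids) + ["Mean"]
    dh_ids = [g for g in ge.genotype_ids if meta_by_id[g].role == "dh_line"]
    subsets = {"all": dh_ids}
    for st in ("hulled", "hull_less"):
        ids = [g for g in dh_ids if meta_by_id[g].seed_type == st]
        if ids:
            subsets[st] = ids

    have_error = error_ms is not None and error_df is not None
    r = ge.replicates
    rows: dict[tuple[str, str], dict] = {}

    def put(key: tuple[str, str], ctx: str, value: float, p: float = np.nan) -> None:
        row = rows.setdefault(key, {})
        row[ctx] = value
        if have_error:
            row[f"{ctx}_p"] = p
            row[f"{ctx}_stars"] = significance_stars(p)

    for ctx in contexts:
        m = r * ge.n_environments if ctx == "Mean" else r
        p1, p2 = frame.loc[parents[0], ctx], frame.loc[parents[1], ctx]
        a_par = additive_effect_parents(p1, p2)
        p_val = np.nan
        if have_error:
            _, _, p_val = contrast_f_test(a_par, 0.5, error_ms, error_df, m)
        put(("a_parents", "parents"), ctx, a_par, p_val)
        for name, ids in subsets.items():
            est = QuantileGeneticEffects(
                q_low,
                q_high,
                error_ms=error_ms if have_error else None,
                error_df=error_df if have_error else None,
                n_obs_per_mean=m,
            ).fit(frame.loc[ids, ctx])
            put(("a_dh", name), ctx, est.a_dh_, est.p_a_)
            put(("aa_dh", name), ctx, est.aa_dh_, est.p_aa_)

    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["parameter", "subset"])
    order = [("a_parents", "parents")]
    for name in subsets:
        order += [("a_dh", name), ("aa_dh", name)]
    return out.loc[order]
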