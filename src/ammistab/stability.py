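"""AMMI stability value (ASV) and genotype selection index (GSI).

ASV (Purchase's statistic) is a genotype's weighted distance from the origin
of the IPCA1 x IPCA2 score plane,

    ASV = sqrt( (SS_IPCA1/SS_IPCA2 * IPCA1)^2 + IPCA2^2 ),

with the first-axis score weighted by the ratio of the first two axes'
interaction sums of squares to compensate for its larger share.  Small ASV
means a stable genotype.  GSI adds the genotype's rank by trait mean
(1 = highest) to its rank by ASV (1 = most stable); small GSI flags
genotypes that are both high-performing and stable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.utils.validation import check_is_fitted

from .ammi import AMMI
from .ge_data import GEMatrix

__all__ = ["asv", "stability_report"]


def asv(
    ipca1,
    ipca2,
    ss_ipca1: float,
    ss_ipca2: float,
):
    """AMMI stability value from first- and second-axis scores.

    ``ss_ipca1`` / ``ss_ipca2`` may be on any common scale (the ratio is
    what enters); both scores may be scalars or arrays.  Invariant to the
    signs of both scores.
    """
    if ss_ipca2 <= 0:
        raise ZeroDivisionError(
            "SS_IPCA2 must be positive: with a rank-1 interaction the ASV "
            "weight is undefined (every genotype's IPCA2 score is zero)"
        )
    w = ss_ipca1 / ss_ipca2
    out = np.sqrt((w * np.asarray(ipca1)) ** 2 + np.asarray(ipca2) ** 2)
    return float(out) if out.ndim == 0 else out


def stability_report(model: AMMI, ge: GEMatrix | pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Per-genotype mean, IPCA scores, ASV, ranks, and GSI.

    Ranks: ``rank_mean`` (RY) descends from the highest mean,
    ``rank_asv`` (RASV) ascends from the smallest ASV; ties receive average
    ranks, so GSI can be non-integer under ties.  Rows are sorted by GSI
    ascending (best first).
    """
    check_is_fitted(model, "genotype_scores_")
    if len(model.singular_values_) < 2:
        raise ValueError("stability report needs at least two interaction axes")
    if not isinstance(ge, GEMatrix):
        ge = GEMatrix.from_frame(pd.DataFrame(ge)) if not isinstance(ge, pd.DataFrame) else GEMatrix.from_frame(ge)
    means = ge.genotype_means().reindex(model.genotype_ids_)
    scores1 = model.genotype_scores_[:, 0]
    scores2 = model.genotype_scores_[:, 1]
    stab = asv(scores1, scores2, model.axis_ss_[0], model.axis_ss_[1])
    report = pd.DataFrame(
        {
            "mean": means.to_numpy(),
            "ipca1": scores1,
            "ipca2": scores2,
            "asv": stab,
        },
        index=pd.Index(model.genotype_ids_, name="genotype"),
    )
    report["rank_mean"] = report["mean"].rank(ascending=False, method="average")
    report["rank_asv"] = report["asv"].rank(ascending=True, method="average")
    report["gsi"] = report["rank_mean"] + report["rank_asv"]
    return report.sort_values(["gsi", "rank_mean"], kind="mergesort")
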