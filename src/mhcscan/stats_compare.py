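"""Comparative statistics over the 34-species locus-count table.

Wraps the standard rank-based machinery (scipy.stats) behind the small set
of statistics the locus-count comparison needs: product-moment and rank
correlations, group medians, the two-group Mann-Whitney test reported as a
tie-corrected Kruskal-Wallis chi-square (the convention of the JMP output
the published values follow), and the matched-pairs signed-rank statistic
in JMP's form: zero differences keep their ranks (Pratt) and the reported
S is half the sum of signed ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .model import SpeciesLocusRecord


@dataclass
class ComparisonResult:
    statistic_name: str
    value: float
    n: int
    p_value: Optional[float] = None
    group_summaries: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"{self.statistic_name}: statistic is not finite")


def _pairwise_complete(x: Sequence, y: Sequence) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray([np.nan if v is None else v for v in x], dtype=float)
    y = np.asarray([np.nan if v is None else v for v in y], dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    return x[mask], y[mask]


def pearson(x: Sequence, y: Sequence, name: str = "pearson_r") -> ComparisonResult:
    """Product-moment correlation; two-sided p from the t distribution (n-2 df).

    Missing values are dropped pairwise, never imputed.
    """
    xv, yv = _pairwise_complete(x, y)
    if len(xv) < 3:
        raise ValueError("pearson requires at least 3 complete pairs")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    r, p = sps.pearsonr(xv, yv)
    return ComparisonResult(name, float(r), len(xv), float(p))


def spearman(x: Sequence, y: Sequence, name: str = "spearman_rho") -> ComparisonResult:
    """Rank correlation: Pearson on mean-ranked data (ties share mean rank)."""
    xv, yv = _pairwise_complete(x, y)
    if len(xv) < 3:
        raise ValueError("spearman requires at least 3 complete pairs")
    rho, p = sps.spearmanr(xv, yv)
    return ComparisonResult(name, float(rho), len(xv), float(p))


def median_by_group(values: Sequence, groups: Sequence,
                    name: str = "median") -> ComparisonResult:
    """Per-group medians (midpoint of the two central order statistics)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    meds = {}
    for g in dict.fromkeys(groups.tolist()):  # preserve first-seen order
        meds[g] = float(np.median(values[groups == g]))
    overall = float(np.median(values))
    return ComparisonResult(name, overall, len(values), None, group_summaries=meds)


def rank_sum_chisq(values: Sequence, groups: Sequence,
                   name: str = "mann_whitney_chisq") -> ComparisonResult:
    """Two-group Mann-Whitney reported as tie-corrected chi-square (df = 1).

    This is the Kruskal-Wallis H statistic on two groups, which is how the
    published chi-square values are parameterised.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(dict.fromkeys(groups.tolist()))
    if len(levels) != 2:
        raise ValueError("rank_sum_chisq requires exactly two groups")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(values) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(a, b)
    return ComparisonResult(name, float(h), len(values), float(p),
                            group_summaries={str(levels[0]): float(np.median(a)),
                                             str(levels[1]): float(np.median(b))})


def signed_rank(x: Sequence, y: Sequence, name: str = "wilcoxon_signed_rank",
                ) -> ComparisonResult:
    """Matched-pairs signed-rank statistic, JMP convention.

    Differences (x - y) are ranked by absolute value with zeros kept in the
    ranking (Pratt); zeros contribute no signed rank.  The reported S is
    (sum of positive signed ranks - sum of negative signed ranks) / 2,
    which equals n(n+1)/4 when every difference is positive and 0 when all
    differences are zero.  The plain positive-rank sum W+ over nonzero
    differences and an exact/normal p-value from the standard zero-dropped
    test are reported alongside.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = x - y
    if np.all(d == 0):
        return ComparisonResult(name, 0.0, len(d), 1.0,
                                group_summaries={"w_plus": 0.0, "n_nonzero": 0})
    ranks = sps.rankdata(np.abs(d))
    s = float((ranks[d > 0].sum() - ranks[d < 0].sum()) / 2.0)
    nz = d[d != 0]
    ranks_nz = sps.rankdata(np.abs(nz))
    w_plus = float(ranks_nz[nz > 0].sum())
    try:
        p = float(sps.wilcoxon(nz, correction=False, mode="auto").pvalue)
    except ValueError:
        p = None
    return ComparisonResult(name, s, len(d), p,
                            group_summaries={"w_plus": w_plus, "n_nonzero": int(len(nz))})


# ---------------------------------------------------------------------------
# the full battery over the species table
# ---------------------------------------------------------------------------

def _drop_largest_disagreements(records: Sequence[SpeciesLocusRecord],
                                n_drop: int = 2) -> list[SpeciesLocusRecord]:
    """Drop the species whose published/predicted class II counts disagree most."""
    with_pub = [r for r in records if r.published_II is not None]
    ranked = sorted(with_pub, key=lambda r: -abs(r.published_II - r.predicted_II))
    dropped = {r.species for r in ranked[:n_drop]}
    return [r for r in with_pub if r.species not in dropped]


def accuracy_report(records: Sequence[SpeciesLocusRecord],
                    predicted: Optional[dict[str, tuple[float, float]]] = None,
                    ) -> list[ComparisonResult]:
    """The full published-versus-predicted battery over the species table.

    ``predicted`` optionally maps species -> (class I count, class II count)
    from a fresh pipeline run, substituting the table's predictions so a new
    run can be compared against the published analysis.
    """
    recs = list(records)
    if predicted is not None:
        subbed = []
        for r in recs:
            if r.species in predicted:
                vals = tuple(predicted[r.species])
                pred_i, pred_ii = vals[0], vals[1]
                stop_i, stop_ii = (vals[2], vals[3]) if len(vals) == 4 else (0.0, 0.0)
                r = SpeciesLocusRecord(
                    species=r.species, order_name=r.order_name,
                    is_passerine=r.is_passerine,
                    predicted_I=pred_i, predicted_II=pred_ii,
                    published_I=r.published_I, published_II=r.published_II,
                    stop_I=stop_i, stop_II=stop_ii,
                )
            subbed.append(r)
        recs = subbed

    out: list[ComparisonResult] = []
    pub_II = [r.published_II for r in recs]
    pred_II = [r.predicted_II for r in recs]
    out.append(pearson(pub_II, pred_II, "classII_published_vs_predicted_r"))

    inliers = _drop_largest_disagreements(recs)
    out.append(pearson([r.published_II for r in inliers],
                       [r.predicted_II for r in inliers],
                       "classII_published_vs_predicted_r_excl_outliers"))

    out.append(pearson(pub_II, [r.predicted_II - r.stop_II for r in recs],
                       "classII_published_vs_predicted_nostop_r"))

    out.append(pearson([r.published_I for r in recs],
                       [r.predicted_I for r in recs],
                       "classI_published_vs_predicted_r"))

    out.append(spearman([r.predicted_I for r in recs],
                        [r.predicted_II for r in recs],
                        "classI_vs_classII_spearman_rho"))

    grp = ["passerine" if r.is_passerine else "nonpasserine" for r in recs]
    out.append(median_by_group([r.predicted_I for r in recs], grp,
                               "classI_median"))
    out.append(median_by_group([r.predicted_II for r in recs], grp,
                               "classII_median"))
    out.append(rank_sum_chisq([r.predicted_I for r in recs], grp,
                              "classI_passerine_chisq"))
    out.append(rank_sum_chisq([r.predicted_II for r in recs], grp,
                              "classII_passerine_chisq"))
    out.append(rank_sum_chisq([r.predicted_I - r.stop_I for r in recs], grp,
                              "classI_passerine_chisq_nostop"))
    out.append(rank_sum_chisq([r.predicted_II - r.stop_II for r in recs], grp,
                              "classII_passerine_chisq_nostop"))
    out.append(signed_rank([r.predicted_II for r in recs],
                           [r.predicted_I for r in recs],
                           "classII_vs_classI_signed_rank"))
    out.append(signed_rank([r.predicted_II - r.stop_II for r in recs],
                           [r.predicted_I - r.stop_I for r in recs],
                           "classII_vs_classI_signed_rank_nostop"))
    return out
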