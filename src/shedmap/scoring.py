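"""Turnover scores, tip scores and group summaries.

The turnover score of a cell or pixel is the residual-weighted expression
sum

    score(obs) = sum_i residual_i * expression_i(obs)

where ``expression`` is sum-normalized over exactly the residual table's
included gene set, so every defined score is a convex combination of the
residuals and is bounded by [min residual, max residual]. Observations
detecting zero panel genes get an undefined (NaN) score — 0 is a
meaningful score value and must not alias missingness.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import NormalizedMatrix, ParameterError, ValidationError
from .residuals import ResidualTable, refit_excluding

DEFAULT_MIN_GROUP_SIZE = 15


@dataclass
class ScoreTable:
    """Per-observation turnover scores.

    ``table`` is indexed by observation with columns ``turnover_score``
    (NaN when undefined), ``n_panel_genes_detected`` and ``weight_mass``
    (the fraction of the observation's normalized expression carried by
    panel genes before renormalization); ``tip_score`` is optional.
    """

    table: pd.DataFrame
    residual_table_id: str = "all"
    exclusion_id: str | None = None

    @property
    def scores(self) -> pd.Series:
        return self.table["turnover_score"]

    def defined(self) -> pd.Series:
        s = self.scores
        return s[s.notna()]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")


def _score_against(nm: NormalizedMatrix, rt: ResidualTable) -> pd.DataFrame:
    panel = rt.included_genes
    if set(nm.normalization_genes) != set(panel):
        raise ValidationError(
            "expression matrix is not normalized over the residual table's "
            f"included gene set ({len(nm.normalization_genes)} vs "
            f"{len(panel)} genes); renormalize before scoring")
    weights = nm.values.loc[panel]
    resid = rt.residuals.loc[panel].to_numpy()
    scores = pd.Series(resid @ weights.to_numpy(), index=nm.obs)
    detected = (weights > 0).sum(axis=0)
    scores[detected == 0] = np.nan
    mass = weights.sum(axis=0)  # 1.0 unless flagged
    return pd.DataFrame({
        "turnover_score": scores,
        "n_panel_genes_detected": detected.astype(int),
        "weight_mass": mass,
    })


def turnover_score(nm: NormalizedMatrix, rt: ResidualTable) -> ScoreTable:
    """Residual-weighted expression score for every observation."""
    return ScoreTable(_score_against(nm, rt), residual_table_id=rt.gene_subset)


def turnover_score_excluding(nm: NormalizedMatrix, rt: ResidualTable,
                             exclusion_set: Sequence[str],
                             refit: bool = True) -> ScoreTable:
    """Turnover score with a gene set (e.g. apoptosis genes) excluded.

    The excluded genes are removed from the residual table, the regression
    is refit on the remaining genes (``refit=False`` keeps the original
    residuals, for sensitivity analysis), expression is renormalized over
    the remaining genes, and scores recomputed. The unexcluded score is
    retained alongside for comparison.
    """
    excl = pd.Index(pd.unique(pd.Index(list(exclusion_set))))
    baseline = _score_against(nm, rt)
    if len(excl) == 0:
        out = baseline.copy()
        out["turnover_score_full"] = baseline["turnover_score"]
        return ScoreTable(out, rt.gene_subset, exclusion_id="none")
    if refit:
        rt2 = refit_excluding(rt, excl)
    else:
        remaining = rt.table.index.difference(excl, sort=False)
        sub = rt.table.loc[remaining]
        if int(sub["included"].sum()) < 3:
            raise ParameterError("exclusion set leaves fewer than 3 genes")
        rt2 = ResidualTable(table=sub, slope=rt.slope,
                            intercept=rt.intercept, pseudo=rt.pseudo,
                            n_genes=int(sub["included"].sum()),
                            pearson_r=rt.pearson_r,
                            gene_subset=rt.gene_subset,
                            refit_of="no-refit-exclusion")
    nm2 = nm.renormalize(rt2.included_genes)
    out = _score_against(nm2, rt2)
    out["turnover_score_full"] = baseline["turnover_score"]
    return ScoreTable(out, rt.gene_subset,
                      exclusion_id=f"excl[{len(excl)}]")


def tip_score(expr: NormalizedMatrix, tip_markers: Sequence[str],
              bottom_markers: Sequence[str]) -> pd.Series:
    """Zonation coordinate in [0, 1]: sum(tip) / (sum(tip) + sum(bottom)).

    Undefined (NaN) when an observation expresses neither marker set.
    """
    tip = pd.Index(pd.unique(pd.Index(list(tip_markers))))
    bottom = pd.Index(pd.unique(pd.Index(list(bottom_markers))))
    overlap = tip.intersection(bottom)
    if len(overlap):
        raise ParameterError(
            f"tip and bottom marker lists overlap: {list(overlap[:5])}")
    tip = tip.intersection(expr.genes)
    bottom = bottom.intersection(expr.genes)
    if len(tip) == 0 or len(bottom) == 0:
        raise ParameterError("tip or bottom marker list empty after "
                             "resolving against the matrix genes")
    tip_sum = expr.values.loc[tip].sum(axis=0)
    bot_sum = expr.values.loc[bottom].sum(axis=0)
    denom = tip_sum + bot_sum
    with np.errstate(invalid="ignore"):
        score = tip_sum / denom.replace(0, np.nan)
    score.name = "tip_score"
    return score


def group_score_summary(st: ScoreTable, labels: pd.Series,
                        min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
                        ) -> pd.DataFrame:
    """Box-plot style five-number summary of scores per group.

    Median, Q1/Q3 (linear interpolation between order statistics), whisker
    bounds at the most extreme scores within 1.5 IQR of the box, and n.
    Groups smaller than ``min_group_size`` are kept but flagged.
    """
    scores = st.defined()
    labels = labels.reindex(scores.index)
    if labels.isna().any():
        missing = scores.index[labels.isna()]
        raise ParameterError(
            f"labels missing for scored observations: {list(missing[:5])}")
    rows = []
    for g, vals in scores.groupby(labels, observed=True):
        v = vals.to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        in_lo = v[v >= q1 - 1.5 * iqr]
        in_hi = v[v <= q3 + 1.5 * iqr]
        rows.append({
            "group": g, "n": len(v), "median": med, "q1": q1, "q3": q3,
            "iqr": iqr,
            "whisker_lo": in_lo.min() if len(in_lo) else np.nan,
            "whisker_hi": in_hi.max() if len(in_hi) else np.nan,
            "small_group": len(v) < min_group_size,
        })
    return pd.DataFrame(rows).set_index("group")
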