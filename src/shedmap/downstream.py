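"""Downstream analyses: inter-crypt gating, score splits, differential
expression, and the spatial microenvironment (neighborhood) comparison.

Conventions locked here:

* the per-gene test is a two-sided Mann–Whitney rank-sum on sum-normalized
  expression (Welch t on log values available via ``test="welch_log"``);
* fold change is pseudocounted on both group means and evaluated
  symmetrically, max(FC, 1/FC), so depletion can be significant too;
* "up to 70 µm" is inclusive (Euclidean, center to center);
* pixels within the radius of both the high and the low focal set go to
  the high side by default (``both_policy="closest"`` assigns by nearest
  focal pixel instead);
* quantile splits use rank order with deterministic ties broken by
  observation id, so a 33% split of 100 observations is exactly 33.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .core_data import (CountMatrix, NormalizedMatrix, ParameterError,
                        ValidationError, sum_normalize)
from .scoring import ScoreTable

logger = logging.getLogger("shedmap")

DEFAULT_Q_THRESHOLD = 0.05
DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_EXPR_FLOOR = 1e-5
DEFAULT_DE_PSEUDO = 1e-5
DEFAULT_RADIUS_UM = 70.0
DEFAULT_HIGH_FRACTION = 0.02
DEFAULT_NEIGHBORHOOD_MIN_UMI = 100
DEFAULT_POS_GATE = 1e-3
DEFAULT_NEG_GATE = 1e-3
DEFAULT_AQP8_PIXEL_GATE = 2e-3


# ---------------------------------------------------------------------------
# Gating
# ---------------------------------------------------------------------------

def gate_intercrypt_cells(nm: NormalizedMatrix,
                          pos_markers: Sequence[str] = ("AQP8", "GUCA2B"),
                          pos_threshold: float = DEFAULT_POS_GATE,
                          neg_marker: str = "ZG16",
                          neg_threshold: float = DEFAULT_NEG_GATE,
                          ) -> pd.Index:
    """Cells with every positive marker strictly above ``pos_threshold``
    and the negative (goblet) marker strictly below ``neg_threshold``."""
    for g in (*pos_markers, neg_marker):
        if g not in nm.genes:
            raise ParameterError(f"marker gene {g!r} not in matrix")
    keep = pd.Series(True, index=nm.obs)
    for g in pos_markers:
        keep &= nm.values.loc[g] > pos_threshold
    keep &= nm.values.loc[neg_marker] < neg_threshold
    keep &= ~nm.obs.isin(nm.flagged)
    return nm.obs[keep]


def gate_intercrypt_pixels(cluster_labels: pd.Series,
                           intercrypt_cluster,
                           mucosa_mask: Sequence[str],
                           aqp8_expr: pd.Series,
                           aqp8_threshold: float = DEFAULT_AQP8_PIXEL_GATE,
                           ) -> pd.Index:
    """Pixels in (inter-crypt cluster ∩ mucosa) refined by AQP8 expression.

    Cluster labels are consumed as input (e.g. exported from an external
    clustering), never computed here. The AQP8 refinement is inclusive
    (>= threshold).
    """
    mucosa = pd.Index(mucosa_mask)
    in_cluster = cluster_labels.index[cluster_labels == intercrypt_cluster]
    candidates = in_cluster.intersection(mucosa)
    if len(candidates) == 0:
        raise ParameterError("inter-crypt cluster and mucosa mask do not "
                             "intersect")
    expr = aqp8_expr.reindex(candidates)
    if expr.isna().any():
        raise ParameterError("AQP8 expression missing for candidate pixels")
    return candidates[expr >= aqp8_threshold]


# ---------------------------------------------------------------------------
# Score splits
# ---------------------------------------------------------------------------

def split_by_score(st: ScoreTable, high_fraction: float,
                   low_fraction: float | None = None,
                   mode: str = "quantile",
                   keep_ties: bool = False) -> tuple[pd.Index, pd.Index]:
    """Split scored observations into high- and low-score sets.

    ``mode="quantile"``: high = top ``high_fraction`` by score, low =
    bottom ``low_fraction`` (e.g. the tertile comparison, 0.33/0.33).
    ``mode="rest"``: high = top ``high_fraction``, low = everything else
    (the 2%/98% design). Ranks break ties by observation id for
    determinism; ``keep_ties=True`` instead includes every observation
    tied with the boundary score.
    """
    scores = st.defined()
    if len(scores) < 2:
        raise ParameterError("need at least 2 defined scores to split")
    if low_fraction is None:
        low_fraction = 1.0 - high_fraction if mode == "rest" else high_fraction
    if mode == "quantile" and high_fraction + low_fraction > 1 + 1e-12:
        raise ParameterError("high_fraction + low_fraction exceeds 1")
    if scores.nunique() == 1:
        logger.warning("split_by_score: all %d scores identical; split is "
                       "arbitrary", len(scores))
    # stable sort over an id-sorted series => ties broken by observation id
    order = scores.loc[sorted(scores.index)].sort_values(
        kind="mergesort", ascending=False)
    n = len(order)
    n_high = int(np.floor(n * high_fraction))
    if keep_ties and n_high > 0:
        cut = order.iloc[n_high - 1]
        n_high = int((order >= cut).sum())
    high = pd.Index(order.index[:n_high])
    if mode == "rest":
        low = pd.Index(order.index[n_high:])
    elif mode == "quantile":
        n_low = int(np.floor(n * low_fraction))
        if keep_ties and n_low > 0:
            cut = order.iloc[n - n_low]
            n_low = int((order <= cut).sum())
        low = pd.Index(order.index[n - n_low:]) if n_low else pd.Index([])
    else:
        raise ParameterError("mode must be 'quantile' or 'rest'")
    logger.info("split_by_score: %d high / %d low of %d", len(high),
                len(low), n)
    return high, low


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

@dataclass
class DeTable:
    """Per-gene two-group comparison, MA-plot ready."""

    table: pd.DataFrame
    params: dict

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def benjamini_hochberg(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ParameterError("p-values outside [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(nm: NormalizedMatrix, group_a: Sequence[str],
                            group_b: Sequence[str],
                            q_threshold: float = DEFAULT_Q_THRESHOLD,
                            fc_threshold: float = DEFAULT_FC_THRESHOLD,
                            expr_floor: float = DEFAULT_EXPR_FLOOR,
                            pseudo: float = DEFAULT_DE_PSEUDO,
                            test: str = "ranksum") -> DeTable:
    """Two-group, per-gene differential expression with BH correction.

    Genes are tested when the larger of the two group means exceeds
    ``expr_floor`` (strict, per "maximal expression above 1e-5"); BH runs
    across tested genes only. Significance requires q < ``q_threshold``
    and a symmetric fold change max(FC, 1/FC) >= ``fc_threshold``.
    """
    a = pd.Index(group_a)
    b = pd.Index(group_b)
    if len(a.intersection(b)):
        raise ParameterError("groups overlap")
    if len(a) < 3 or len(b) < 3:
        raise ParameterError("each group needs >= 3 observations")
    for idx, name in ((a, "A"), (b, "B")):
        missing = idx.difference(nm.obs)
        if len(missing):
            raise ParameterError(
                f"group {name} has unknown observations: {list(missing[:5])}")
    va = nm.values[a].to_numpy(float)
    vb = nm.values[b].to_numpy(float)
    mean_a = va.mean(axis=1)
    mean_b = vb.mean(axis=1)
    fc = (mean_a + pseudo) / (mean_b + pseudo)
    sym_fc = np.maximum(fc, 1.0 / fc)
    m_value = np.log2(fc)
    a_value = 0.5 * (np.log10(mean_a + pseudo) + np.log10(mean_b + pseudo))

    tested = np.maximum(mean_a, mean_b) > expr_floor
    if not tested.any():
        raise ParameterError("no genes above the expression floor")

    pvals = np.full(len(nm.genes), np.nan)
    if test == "ranksum":
        res = stats.mannwhitneyu(va[tested], vb[tested], axis=1,
                                 alternative="two-sided")
        pvals[tested] = res.pvalue
    elif test == "welch_log":
        la = np.log10(va[tested] + pseudo)
        lb = np.log10(vb[tested] + pseudo)
        res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
        pvals[tested] = res.pvalue
    else:
        raise ParameterError("test must be 'ranksum' or 'welch_log'")

    qvals = np.full_like(pvals, np.nan)
    qvals[tested] = benjamini_hochberg(pvals[tested])
    significant = tested & (qvals < q_threshold) & (sym_fc >= fc_threshold)

    table = pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b, "A": a_value, "M": m_value,
        "fold_change": fc, "p_value": pvals, "q_value": qvals,
        "tested": tested, "significant": significant,
    }, index=nm.genes)
    return DeTable(table, params={
        "q_threshold": q_threshold, "fc_threshold": fc_threshold,
        "expr_floor": expr_floor, "pseudo": pseudo, "test": test,
        "n_a": len(a), "n_b": len(b)})


# ---------------------------------------------------------------------------
# Spatial neighborhoods
# ---------------------------------------------------------------------------

@dataclass
class SpatialNeighborhood:
    """Bookkeeping for a high-vs-low focal-pixel neighborhood comparison."""

    high_focal: pd.Index
    low_focal: pd.Index
    high_neighbors: pd.Index
    low_neighbors: pd.Index
    radius_um: float
    both_policy: str


def _coords(meta: pd.DataFrame, obs: pd.Index) -> np.ndarray:
    for c in ("x_um", "y_um"):
        if c not in meta.columns:
            raise ValidationError("pixel coordinates (x_um/y_um, in "
                                  "micrometres) are required")
    xy = meta.loc[obs, ["x_um", "y_um"]].to_numpy(float)
    if not np.all(np.isfinite(xy)):
        raise ValidationError("non-finite pixel coordinates")
    return xy


def neighborhood_de(grid: CountMatrix, st: ScoreTable,
                    compartment_mask: Sequence[str],
                    radius_um: float = DEFAULT_RADIUS_UM,
                    high_fraction: float = DEFAULT_HIGH_FRACTION,
                    min_umi: int = DEFAULT_NEIGHBORHOOD_MIN_UMI,
                    both_policy: str = "high",
                    **de_params) -> tuple[DeTable, SpatialNeighborhood]:
    """Differential expression around high- vs low-turnover focal pixels.

    1. Focal (scored) pixels are split into the top ``high_fraction`` and
       the remaining fraction by turnover score.
    2. Compartment pixels (e.g. lamina propria) with totals strictly above
       ``min_umi`` whose centers lie within ``radius_um`` (inclusive) of a
       high (resp. low) focal pixel form the two neighbor sets; pixels near
       both sides follow ``both_policy`` ("high" or "closest").
    3. The two neighbor sets are compared by
       :func:`differential_expression` on expression sum-normalized over
       all grid genes.
    """
    high, low = split_by_score(st, high_fraction, mode="rest")
    mask = pd.Index(compartment_mask).intersection(grid.obs)
    candidates = mask[grid.totals().loc[mask] > min_umi]
    if len(candidates) == 0:
        raise ParameterError("no compartment pixels above the UMI floor")

    cand_xy = _coords(grid.obs_meta, candidates)
    tree = cKDTree(cand_xy)
    # inclusive radius: pad by a relative epsilon against FP wobble at the
    # exact boundary
    r = radius_um * (1 + 1e-12)

    def hits(focal: pd.Index) -> np.ndarray:
        if len(focal) == 0:
            return np.zeros(len(candidates), dtype=bool)
        fxy = _coords(grid.obs_meta, focal)
        idx = tree.query_ball_point(fxy, r)
        out = np.zeros(len(candidates), dtype=bool)
        for lst in idx:
            out[lst] = True
        return out

    near_high = hits(high)
    near_low = hits(low)
    both = near_high & near_low
    if both.any():
        if both_policy == "high":
            near_low &= ~both
        elif both_policy == "closest":
            fxy_h = _coords(grid.obs_meta, high)
            fxy_l = _coords(grid.obs_meta, low)
            th, tl = cKDTree(fxy_h), cKDTree(fxy_l)
            dh, _ = th.query(cand_xy[both])
            dl, _ = tl.query(cand_xy[both])
            to_high = dh <= dl
            bidx = np.where(both)[0]
            near_low[bidx[to_high]] = False
            near_high[bidx[~to_high]] = False
        else:
            raise ParameterError("both_policy must be 'high' or 'closest'")

    high_nb = candidates[near_high]
    low_nb = candidates[near_low]
    if len(high_nb) == 0 or len(low_nb) == 0:
        raise ParameterError(
            f"no neighbors within {radius_um} um on one side "
            f"(high: {len(high_nb)}, low: {len(low_nb)})")
    nb = SpatialNeighborhood(high, low, high_nb, low_nb, radius_um,
                             both_policy)
    union = high_nb.union(low_nb, sort=False)
    nm = sum_normalize(grid.subset_obs(union), "all")
    de = differential_expression(nm, high_nb, low_nb, **de_params)
    return de, nb
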