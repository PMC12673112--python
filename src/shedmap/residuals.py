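"""Per-gene shedding residuals from the wash ~ biopsy regression.

The central statistic: for each gene, the median sum-normalized expression
is computed across wash samples and across biopsy samples (median on the
linear scale), a pseudocount is added, and log10 wash is regressed on
log10 biopsy by ordinary least squares with an intercept:

    y_i = log10(median_wash_i + pseudo)
    x_i = log10(median_biopsy_i + pseudo)
    residual_i = y_i - (intercept + slope * x_i)

Positive residuals mark genes overrepresented among shed cells (washes),
negative residuals genes overrepresented in the tissue. The regression
direction (wash on y) is fixed, not configurable, because flipping it
flips every residual sign.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import NormalizedMatrix, ParameterError, ValidationError

DEFAULT_PSEUDO = 1e-5


@dataclass
class ResidualTable:
    """Per-gene residuals plus the fitted regression.

    ``table`` is indexed by gene with columns ``residual``, ``log10_wash``,
    ``log10_biopsy`` and ``included``; excluded genes keep their log values
    but have NaN residuals. Fit-level metadata lives on the dataclass.
    """

    table: pd.DataFrame
    slope: float
    intercept: float
    pseudo: float
    n_genes: int
    pearson_r: float
    gene_subset: str = "all"
    refit_of: str | None = None

    @property
    def included_genes(self) -> pd.Index:
        return self.table.index[self.table["included"]]

    @property
    def residuals(self) -> pd.Series:
        """Residuals of included genes."""
        return self.table.loc[self.table["included"], "residual"]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")
        meta = {
            "slope": self.slope, "intercept": self.intercept,
            "pseudo": self.pseudo, "n_genes": self.n_genes,
            "pearson_r": self.pearson_r, "gene_subset": self.gene_subset,
            "refit_of": self.refit_of,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResidualTable":
        table = pd.read_csv(path, sep="\t", index_col=0)
        table["included"] = table["included"].astype(bool)
        meta = json.loads(Path(str(path) + ".json").read_text())
        return cls(table=table, **meta)


def aggregate_group_median(nm: NormalizedMatrix,
                           group: Sequence[str]) -> pd.Series:
    """Per-gene median of normalized expression across ``group`` samples.

    The median is taken on the linear scale; the pseudocount and log10 are
    applied later, by the regression.
    """
    group = list(group)
    if len(group) == 0:
        raise ParameterError("empty sample group")
    flagged = set(nm.flagged) & set(group)
    if flagged:
        raise ParameterError(
            f"group contains flagged (zero-total) observations: "
            f"{sorted(flagged)[:5]}")
    missing = pd.Index(group).difference(nm.obs)
    if len(missing):
        raise ParameterError(f"unknown observations: {list(missing[:5])}")
    return nm.values[group].median(axis=1)


def fit_shedding_regression(wash_median: pd.Series,
                            biopsy_median: pd.Series,
                            pseudo: float = DEFAULT_PSEUDO,
                            gene_subset: Sequence[str] | str = "all",
                            min_median: float | None = None,
                            ) -> ResidualTable:
    """OLS fit of log10(wash + pseudo) on log10(biopsy + pseudo).

    Parameters
    ----------
    wash_median, biopsy_median
        Per-gene median normalized expression, aligned on the same gene
        index.
    pseudo
        Pseudocount added to both medians before log10; the published
        default is 1e-5 on sum-normalized fractions.
    gene_subset
        Restrict the fit to these genes ("all" = every aligned gene).
    min_median
        Optional inclusion floor: keep genes whose larger median exceeds
        this value. Default (None) keeps genes with a nonzero median in at
        least one fraction.
    """
    if pseudo <= 0:
        raise ParameterError("pseudo must be > 0")
    if not wash_median.index.equals(biopsy_median.index):
        raise ParameterError("wash and biopsy medians must share one gene "
                             "index")
    if isinstance(gene_subset, str):
        if gene_subset != "all":
            raise ParameterError("gene_subset must be 'all' or a gene list")
        genes = wash_median.index
        subset_label = "all"
    else:
        genes = pd.Index(gene_subset)
        missing = genes.difference(wash_median.index)
        if len(missing):
            raise ParameterError(
                f"gene_subset not in the median vectors: {list(missing[:5])}")
        subset_label = f"panel[{len(genes)}]"

    w = wash_median.loc[genes].astype(float)
    b = biopsy_median.loc[genes].astype(float)
    if (w < 0).any() or (b < 0).any():
        raise ValidationError("negative median expression")

    larger = np.maximum(w, b)
    included = larger > (min_median if min_median is not None else 0.0)

    y = np.log10(w + pseudo)
    x = np.log10(b + pseudo)
    return _ols_residual_table(x, y, included, pseudo, subset_label)


def _ols_residual_table(x: pd.Series, y: pd.Series, included: pd.Series,
                        pseudo: float, subset_label: str,
                        refit_of: str | None = None) -> ResidualTable:
    n = int(included.sum())
    if n < 3:
        raise ParameterError(f"only {n} genes available for the regression "
                             "(need >= 3)")
    xi = x[included].to_numpy()
    yi = y[included].to_numpy()
    if np.ptp(xi) == 0:
        raise ValidationError("zero variance in biopsy log expression; "
                              "slope undefined")
    design = np.column_stack([np.ones_like(xi), xi])
    (intercept, slope), *_ = np.linalg.lstsq(design, yi, rcond=None)
    fitted = intercept + slope * x
    residual = (y - fitted).where(included)
    r = float(np.corrcoef(xi, yi)[0, 1])
    table = pd.DataFrame({
        "residual": residual,
        "log10_wash": y,
        "log10_biopsy": x,
        "included": included,
    })
    return ResidualTable(table=table, slope=float(slope),
                         intercept=float(intercept), pseudo=pseudo,
                         n_genes=n, pearson_r=r, gene_subset=subset_label,
                         refit_of=refit_of)


def _refit_on(rt: ResidualTable, genes: pd.Index, label: str,
              refit_of: str) -> ResidualTable:
    sub = rt.table.loc[genes]
    included = sub["included"].copy()
    return _ols_residual_table(sub["log10_biopsy"], sub["log10_wash"],
                               included, rt.pseudo, label, refit_of=refit_of)


def restrict_residuals(rt: ResidualTable,
                       panel: Sequence[str]) -> ResidualTable:
    """Refit the regression de novo on the panel genes.

    Equivalent to running :func:`fit_shedding_regression` directly on the
    overlap of the panel with the fitted genes; the residuals are *not*
    simply subset, because slope and intercept change with the gene set.
    """
    panel_idx = pd.Index(pd.unique(pd.Index(panel)))
    overlap = rt.table.index.intersection(panel_idx)
    n_inc = int(rt.table.loc[overlap, "included"].sum())
    if n_inc < 3:
        raise ParameterError(
            f"panel overlaps only {n_inc} included genes (need >= 3)")
    return _refit_on(rt, overlap, f"panel[{len(overlap)}]",
                     refit_of=rt.gene_subset)


def refit_excluding(rt: ResidualTable,
                    exclusion_set: Sequence[str]) -> ResidualTable:
    """Refit the regression after removing ``exclusion_set`` genes."""
    excl = pd.Index(pd.unique(pd.Index(list(exclusion_set))))
    remaining = rt.table.index.difference(excl, sort=False)
    n_inc = int(rt.table.loc[remaining, "included"].sum())
    if n_inc < 3:
        raise ParameterError(
            "exclusion set removes all but "
            f"{n_inc} included genes (need >= 3)")
    return _refit_on(rt, remaining, f"excl[{len(excl)}]",
                     refit_of=rt.gene_subset)
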