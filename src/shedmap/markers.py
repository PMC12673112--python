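"""Marker-panel selection and panel-representation summaries.

A gene enters an organ (or cell-type) panel when its mean sum-normalized
expression in the target group clears ``min_expression`` and its
pseudocounted fold change over the strongest competitor group clears
``min_fold_change``:

    (target_mean + pseudo) / (max_other_mean + pseudo) >= min_fold_change

The off-target aggregation defaults to the maximum over other groups (the
strictest notion of specificity) with the mean available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import NormalizedMatrix, ParameterError

DEFAULT_MIN_EXPRESSION = 1e-5
DEFAULT_MIN_FOLD_CHANGE = 1.5
DEFAULT_PSEUDO = 1e-5
DEFAULT_MIN_CELLS_PER_TYPE = 300


@dataclass
class MarkerPanel:
    """A named gene panel with per-gene selection statistics."""

    name: str
    genes: list[str]
    stats: pd.DataFrame  # index gene: target_mean, max_offtarget_mean, fold_change
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def to_tsv(self, path: str | Path) -> None:
        self.stats.assign(panel=self.name).to_csv(path, sep="\t")


def _group_means(nm: NormalizedMatrix, labels: pd.Series) -> pd.DataFrame:
    labels = labels.reindex(nm.obs)
    usable = nm.obs.difference(nm.flagged)
    vals = nm.values[usable]
    return vals.T.groupby(labels.loc[usable], observed=True).mean().T


def select_specific_genes(reference: NormalizedMatrix,
                          labels: pd.Series,
                          target_group: str,
                          min_expression: float = DEFAULT_MIN_EXPRESSION,
                          min_fold_change: float = DEFAULT_MIN_FOLD_CHANGE,
                          pseudo: float = DEFAULT_PSEUDO,
                          offtarget_agg: str = "max") -> MarkerPanel:
    """Genes specifically expressed in ``target_group`` of a reference."""
    means = _group_means(reference, labels)
    if means.shape[1] < 2:
        raise ParameterError("reference must contain at least 2 groups")
    if target_group not in means.columns:
        raise ParameterError(f"target group {target_group!r} not present")
    target = means[target_group]
    others = means.drop(columns=[target_group])
    if offtarget_agg == "max":
        off = others.max(axis=1)
    elif offtarget_agg == "mean":
        off = others.mean(axis=1)
    else:
        raise ParameterError("offtarget_agg must be 'max' or 'mean'")
    fc = (target + pseudo) / (off + pseudo)
    keep = (target >= min_expression) & (fc >= min_fold_change)
    stats = pd.DataFrame({
        "target_mean": target, "max_offtarget_mean": off, "fold_change": fc,
    })[keep].sort_index()
    return MarkerPanel(
        name=str(target_group),
        genes=list(stats.index),
        stats=stats,
        params={"min_expression": min_expression,
                "min_fold_change": min_fold_change, "pseudo": pseudo,
                "offtarget_agg": offtarget_agg},
    )


def select_celltype_markers(sc_reference: NormalizedMatrix,
                            celltype_labels: pd.Series,
                            min_cells_per_type: int = DEFAULT_MIN_CELLS_PER_TYPE,
                            exceptions: Sequence[str] = (),
                            min_expression: float = DEFAULT_MIN_EXPRESSION,
                            min_fold_change: float = DEFAULT_MIN_FOLD_CHANGE,
                            pseudo: float = DEFAULT_PSEUDO,
                            offtarget_agg: str = "max",
                            ) -> dict[str, MarkerPanel]:
    """Per-cell-type marker panels from a labelled single-cell reference.

    Cell types with fewer than ``min_cells_per_type`` cells are dropped
    before selection unless listed in ``exceptions`` (rare lineages such as
    enteroendocrine cells).
    """
    labels = celltype_labels.reindex(sc_reference.obs)
    counts = labels.value_counts()
    retained = [t for t in counts.index
                if counts[t] >= min_cells_per_type or t in set(exceptions)]
    if not retained:
        raise ParameterError("no cell types retained after the size filter")
    mask = labels.isin(retained)
    sub = NormalizedMatrix(sc_reference.values.loc[:, mask.to_numpy()],
                           sc_reference.normalization_genes,
                           sc_reference.flagged.intersection(
                               sc_reference.obs[mask]),
                           sc_reference.obs_meta.loc[mask.to_numpy()])
    out: dict[str, MarkerPanel] = {}
    for t in retained:
        out[t] = select_specific_genes(
            sub, labels[mask], t, min_expression=min_expression,
            min_fold_change=min_fold_change, pseudo=pseudo,
            offtarget_agg=offtarget_agg)
    return out


def panel_representation(nm: NormalizedMatrix,
                         panels: Mapping[str, MarkerPanel] | Sequence[MarkerPanel],
                         class_labels: pd.Series) -> pd.DataFrame:
    """Mean and SEM of log10 normalized expression of panel genes per class.

    For each panel x sample class: panel genes with nonzero mean expression
    in at least one compared class are eligible; within a class, log10 is
    taken over that class's positive gene means (genes at exactly zero in a
    class cannot be logged and are dropped from that class's summary, with
    ``n_nonzero`` reporting how many genes contributed). SEM is the sample
    standard deviation over genes divided by sqrt(n).
    """
    if not isinstance(panels, Mapping):
        panels = {p.name: p for p in panels}
    class_labels = class_labels.reindex(nm.obs)
    class_means = _group_means(nm, class_labels)
    rows = []
    for pname, panel in panels.items():
        resolved = pd.Index(panel.genes).intersection(nm.genes)
        if len(resolved) == 0:
            rows.append({"panel": pname, "class": None, "n_nonzero": 0,
                         "mean_log10": np.nan, "sem_log10": np.nan,
                         "flag": "no_resolvable_genes"})
            continue
        sub = class_means.loc[resolved]
        eligible = sub.index[(sub > 0).any(axis=1)]
        for cls in class_means.columns:
            vals = sub.loc[eligible, cls]
            pos = vals[vals > 0]
            logs = np.log10(pos.to_numpy())
            n = len(logs)
            rows.append({
                "panel": pname, "class": cls, "n_nonzero": n,
                "mean_log10": logs.mean() if n else np.nan,
                "sem_log10": (logs.std(ddof=1) / np.sqrt(n)) if n > 1
                             else (0.0 if n == 1 else np.nan),
                "flag": "",
            })
    return pd.DataFrame(rows)
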