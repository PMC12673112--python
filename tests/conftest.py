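import numpy as np
import pandas as pd
import pytest

import shedmap as sm


@pytest.fixture
def toy_counts():
    """3 genes x 2 samples with column sums (8, 9)."""
    return pd.DataFrame([[5, 0], [3, 2], [0, 7]],
                        index=["g1", "g2", "g3"], columns=["s1", "s2"])


@pytest.fixture(scope="session")
def zonated_pipeline():
    """One full synthetic run: truth, bulks, cells, residuals, scores.

    Session-scoped; shedding gradient 2, 3000 cells, 3+3 bulk samples at
    1e6 reads.
    """
    truth = sm.make_zonated_truth(seed=11)
    bulk = sm.simulate_wash_biopsy(truth, seed=12)
    cells = sm.simulate_cells(truth, n_cells=3000, seed=13)
    nm = sm.sum_normalize(bulk, "all")
    roles = bulk.obs_meta["role"]
    wash = sm.aggregate_group_median(nm, bulk.obs[roles == "wash"])
    biopsy = sm.aggregate_group_median(nm, bulk.obs[roles == "biopsy"])
    rt = sm.fit_shedding_regression(wash, biopsy)
    cell_nm = sm.sum_normalize(cells, rt.included_genes)
    st = sm.turnover_score(cell_nm, rt)
    return {"truth": truth, "bulk": bulk, "cells": cells, "rt": rt,
            "cell_nm": cell_nm, "scores": st,
            "wash": wash, "biopsy": biopsy}


def ols_normal_equations(x, y):
    """Independent closed-form OLS oracle: slope, intercept, residuals."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xbar, ybar = x.mean(), y.mean()
    slope = np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2)
    intercept = ybar - slope * xbar
    return slope, intercept, y - (intercept + slope * x)


def bh_stepup(p):
    """Textbook Benjamini-Hochberg step-up oracle."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj
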