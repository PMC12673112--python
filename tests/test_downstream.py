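import numpy as np
import pandas as pd
import pytest
from scipy import stats

import shedmap as sm
from shedmap.core_data import ParameterError

from conftest import bh_stepup


def normalized(counts: dict[str, list[float]], genes):
    vals = pd.DataFrame(counts, index=genes)
    return sm.sum_normalize(sm.CountMatrix(vals), "all")


def score_table(scores: dict[str, float]):
    return sm.ScoreTable(pd.DataFrame({
        "turnover_score": pd.Series(scores),
        "n_panel_genes_detected": 1, "weight_mass": 1.0}))


class TestGateIntercryptCells:
    genes = ["AQP8", "GUCA2B", "ZG16", "other"]

    def nm(self, cells):
        scale = 10**6
        vals = pd.DataFrame(
            {c: [round(a * scale), round(g * scale), round(z * scale),
                 scale - round((a + g + z) * scale)]
             for c, (a, g, z) in cells.items()}, index=self.genes)
        return sm.sum_normalize(sm.CountMatrix(vals), "all")

    def test_positive_and_negative_gates(self):
        nm = self.nm({
            "keep": (2e-3, 1.5e-3, 0.0),
            "aqp8_at_threshold": (1e-3, 1.5e-3, 0.0),  # strict "above"
            "goblet": (2e-3, 1.5e-3, 5e-3),            # ZG16 veto
            "guca2b_low": (2e-3, 5e-4, 0.0),
        })
        kept = sm.gate_intercrypt_cells(nm)
        assert list(kept) == ["keep"]

    def test_zg16_boundary_is_strict(self):
        nm = self.nm({"c": (2e-3, 2e-3, 1e-3)})
        assert len(sm.gate_intercrypt_cells(nm)) == 0

    def test_missing_marker_named(self):
        nm = normalized({"c": [1, 1]}, ["AQP8", "GUCA2B"])
        with pytest.raises(ParameterError, match="ZG16"):
            sm.gate_intercrypt_cells(nm)


class TestGateIntercryptPixels:
    def test_intersection_mask_and_inclusive_refinement(self):
        labels = pd.Series({"p1": 3, "p2": 3, "p3": 1, "p4": 3})
        mucosa = ["p1", "p2", "p3"]  # p4 outside the mucosa
        aqp8 = pd.Series({"p1": 2e-3, "p2": 1.9e-3, "p3": 5e-3,
                          "p4": 5e-3})
        kept = sm.gate_intercrypt_pixels(labels, 3, mucosa, aqp8)
        # p1 kept at exactly 2e-3 (inclusive), p2 below, p3 wrong cluster
        assert list(kept) == ["p1"]

    def test_empty_intersection_errors(self):
        labels = pd.Series({"p1": 1})
        with pytest.raises(ParameterError, match="intersect"):
            sm.gate_intercrypt_pixels(labels, 2, ["p9"],
                                      pd.Series({"p1": 1.0}))


class TestSplitByScore:
    def test_tertile_split_counts(self):
        st = score_table({f"c{i:03d}": float(i) for i in range(100)})
        high, low = sm.split_by_score(st, 0.33, 0.33)
        assert len(high) == 33 and len(low) == 33
        assert len(set(high) & set(low)) == 0
        assert min(st.scores[high]) > max(st.scores[low])

    def test_rest_mode_two_percent(self):
        st = score_table({f"c{i:03d}": float(i) for i in range(100)})
        high, low = sm.split_by_score(st, 0.02, mode="rest")
        assert len(high) == 2 and len(low) == 98
        assert set(high) == {"c099", "c098"}

    def test_all_ties_warns_but_splits_deterministically(self, caplog):
        st = score_table({f"c{i}": 1.0 for i in range(10)})
        with caplog.at_level("WARNING", logger="shedmap"):
            high1, _ = sm.split_by_score(st, 0.2, mode="rest")
            high2, _ = sm.split_by_score(st, 0.2, mode="rest")
        assert "identical" in caplog.text
        assert list(high1) == list(high2)

    def test_keep_ties_mode_includes_boundary(self):
        st = score_table({"a": 3.0, "b": 2.0, "c": 2.0, "d": 2.0,
                          "e": 1.0})
        high, _ = sm.split_by_score(st, 0.4, mode="rest", keep_ties=True)
        assert set(high) == {"a", "b", "c", "d"}

    def test_too_few_scores_error(self):
        st = score_table({"a": 1.0})
        with pytest.raises(ParameterError):
            sm.split_by_score(st, 0.5, 0.5)


class TestBenjaminiHochberg:
    def test_hand_cases(self):
        assert sm.benjamini_hochberg([0.03]) == pytest.approx([0.03])
        q = sm.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        q = sm.benjamini_hochberg([0.2, 0.2, 0.2])
        assert np.allclose(q, [0.2, 0.2, 0.2])

    def test_matches_textbook_stepup_including_ties(self):
        rng = np.random.default_rng(31)
        for _ in range(500):
            n = int(rng.integers(1, 40))
            p = rng.uniform(size=n)
            if rng.random() < 0.5:
                p = np.round(p, 2)  # force ties
            # equal to floating-point rounding: the two implementations
            # evaluate p*m/rank in different legal orders
            assert np.allclose(sm.benjamini_hochberg(p), bh_stepup(p),
                               rtol=1e-12, atol=0)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(32)
        p = rng.uniform(size=200)
        q = sm.benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ParameterError):
            sm.benjamini_hochberg([0.5, 1.5])


class TestDifferentialExpression:
    @staticmethod
    def two_group_nm(n_genes=50, n_per_group=10, seed=0, shift_first=1.0):
        rng = np.random.default_rng(seed)
        prog = rng.dirichlet(np.ones(n_genes) * 5)
        prog_b = prog.copy()
        prog_b[0] /= shift_first
        prog_b /= prog_b.sum()
        counts = np.column_stack(
            [rng.multinomial(2000, prog) for _ in range(n_per_group)]
            + [rng.multinomial(2000, prog_b) for _ in range(n_per_group)])
        genes = [f"g{i}" for i in range(n_genes)]
        cols = [f"c{i}" for i in range(2 * n_per_group)]
        nm = sm.sum_normalize(sm.CountMatrix(
            pd.DataFrame(counts, index=genes, columns=cols)), "all")
        return nm, cols[:n_per_group], cols[n_per_group:]

    def test_identical_gene_not_significant(self):
        nm, a, b = self.two_group_nm(seed=1)
        de = sm.differential_expression(nm, a, b)
        flat = de.table[np.isclose(de.table["fold_change"], 1.0, atol=0.05)]
        assert not flat["significant"].any()

    def test_spiked_gene_detected_and_fc_matches_hand_formula(self):
        nm, a, b = self.two_group_nm(seed=2, shift_first=4.0,
                                     n_per_group=20)
        de = sm.differential_expression(nm, a, b)
        row = de.table.loc["g0"]
        assert row["significant"]
        mean_a = nm.values.loc["g0", a].mean()
        mean_b = nm.values.loc["g0", b].mean()
        assert row["fold_change"] == pytest.approx(
            (mean_a + 1e-5) / (mean_b + 1e-5))
        assert row["M"] == pytest.approx(np.log2(row["fold_change"]))

    def test_depleted_gene_can_be_significant(self):
        nm, a, b = self.two_group_nm(seed=3, shift_first=0.2,
                                     n_per_group=20)
        de = sm.differential_expression(nm, a, b)
        row = de.table.loc["g0"]
        assert row["fold_change"] < 1 and row["significant"]

    def test_expr_floor_excludes_genes_from_testing(self):
        nm, a, b = self.two_group_nm(seed=4)
        floor = float(np.median(
            np.maximum(nm.values[a].mean(axis=1),
                       nm.values[b].mean(axis=1))))
        de = sm.differential_expression(nm, a, b, expr_floor=floor)
        sub = de.table[~de.table["tested"]]
        assert len(sub) > 0
        assert sub["p_value"].isna().all()
        assert not sub["significant"].any()
        with pytest.raises(ParameterError, match="floor"):
            sm.differential_expression(nm, a, b, expr_floor=1.0)

    def test_group_contracts(self):
        nm, a, b = self.two_group_nm()
        with pytest.raises(ParameterError, match="overlap"):
            sm.differential_expression(nm, a, a)
        with pytest.raises(ParameterError, match=">= 3"):
            sm.differential_expression(nm, a[:2], b)

    def test_welch_alternative_agrees_on_strong_signal(self):
        nm, a, b = self.two_group_nm(seed=5, shift_first=5.0,
                                     n_per_group=20)
        de_w = sm.differential_expression(nm, a, b, test="welch_log")
        assert de_w.table.loc["g0", "significant"]

    def test_null_permutation_calibration(self):
        # continuous null data: p-values approximately uniform, and the
        # BH+FC gate yields no discoveries
        rng = np.random.default_rng(41)
        n_genes, n = 400, 30
        raw = rng.gamma(2.0, 1.0, size=(n_genes, 2 * n)) + 1e-3
        genes = [f"g{i}" for i in range(n_genes)]
        cols = [f"c{i}" for i in range(2 * n)]
        nm = sm.sum_normalize(sm.CountMatrix(
            pd.DataFrame(raw, index=genes, columns=cols)), "all")
        perm = rng.permutation(cols)
        de = sm.differential_expression(nm, list(perm[:n]), list(perm[n:]),
                                        fc_threshold=1.0)
        p = de.table["p_value"].dropna()
        frac = (p < 0.05).mean()
        assert abs(frac - 0.05) < 0.04
        assert (de.table["q_value"].dropna() < 0.05).sum() == 0


class TestNeighborhoodDe:
    @staticmethod
    def lattice_grid(seed=0, side=14, pitch=8.0):
        """Random-count pixel lattice with a known focal score pattern."""
        rng = np.random.default_rng(seed)
        rows, cols = np.meshgrid(np.arange(side), np.arange(side),
                                 indexing="ij")
        idx = pd.Index([f"p{r:02d}_{c:02d}" for r, c in
                        zip(rows.ravel(), cols.ravel())])
        meta = pd.DataFrame({
            "role": "pixel",
            "x_um": cols.ravel() * pitch, "y_um": rows.ravel() * pitch,
        }, index=idx)
        genes = [f"g{i}" for i in range(30)]
        vals = pd.DataFrame(
            rng.poisson(20, size=(30, len(idx))), index=genes,
            columns=idx)
        return sm.CountMatrix(vals, meta)

    def test_exact_boundary_inclusive(self):
        # high focal pixel at origin with candidates at exactly 70 um and
        # at 70.1 um; a low focal pixel far away with its own candidates
        meta = pd.DataFrame({
            "role": "pixel",
            "x_um": [0.0, 70.0, 70.1, 10.0, 20.0,
                     1000.0, 1010.0, 1020.0, 1030.0],
            "y_um": 0.0,
        }, index=["focal_hi", "at70", "beyond", "near1", "near2",
                  "focal_lo", "lo1", "lo2", "lo3"])
        genes = [f"g{i}" for i in range(5)]
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.poisson(100, size=(5, 9)), index=genes,
                            columns=meta.index)
        grid = sm.CountMatrix(vals, meta)
        st = score_table({"focal_hi": 1.0, "focal_lo": 0.0})
        candidates = ["at70", "beyond", "near1", "near2",
                      "lo1", "lo2", "lo3"]
        de, nb = sm.neighborhood_de(grid, st, candidates, radius_um=70.0,
                                    high_fraction=0.5, min_umi=0)
        assert set(nb.high_neighbors) == {"at70", "near1", "near2"}
        assert set(nb.low_neighbors) == {"lo1", "lo2", "lo3"}
        assert "beyond" not in set(nb.high_neighbors) | \
            set(nb.low_neighbors)

    def test_neighbor_sets_match_brute_force(self):
        grid = self.lattice_grid(seed=2)
        rng = np.random.default_rng(3)
        focal = list(rng.choice(grid.obs, size=40, replace=False))
        rest = grid.obs.difference(focal, sort=False)
        scores = score_table(dict(zip(
            focal, rng.normal(size=len(focal)))))
        de, nb = sm.neighborhood_de(grid, scores, rest, radius_um=20.0,
                                    high_fraction=0.2, min_umi=0)
        high, low = sm.split_by_score(scores, 0.2, mode="rest")
        xy = grid.obs_meta[["x_um", "y_um"]]

        def brute(focal_set):
            out = set()
            for p in rest:
                for f in focal_set:
                    d = np.hypot(xy.loc[p, "x_um"] - xy.loc[f, "x_um"],
                                 xy.loc[p, "y_um"] - xy.loc[f, "y_um"])
                    if d <= 20.0:
                        out.add(p)
                        break
            return out

        bh, bl = brute(high), brute(low)
        assert set(nb.high_neighbors) == bh
        assert set(nb.low_neighbors) == bl - bh  # both -> high policy

    def test_closest_policy_reassigns_shared_pixels(self):
        grid = self.lattice_grid(seed=4)
        rng = np.random.default_rng(5)
        focal = list(grid.obs[:30])
        rest = grid.obs.difference(focal, sort=False)
        scores = score_table(dict(zip(focal,
                                      rng.normal(size=len(focal)))))
        _, nb_high = sm.neighborhood_de(grid, scores, rest,
                                        radius_um=40.0, high_fraction=0.2,
                                        min_umi=0, both_policy="high")
        _, nb_close = sm.neighborhood_de(grid, scores, rest,
                                         radius_um=40.0, high_fraction=0.2,
                                         min_umi=0, both_policy="closest")
        union_h = set(nb_high.high_neighbors) | set(nb_high.low_neighbors)
        union_c = set(nb_close.high_neighbors) | set(nb_close.low_neighbors)
        assert union_h == union_c
        assert set(nb_close.high_neighbors) <= set(nb_high.high_neighbors)

    def test_mirror_symmetry(self):
        # focal pixels mirrored about the lattice's vertical axis produce
        # mirror-image neighbor sets
        grid = self.lattice_grid(seed=6, side=10)
        def mirror(name):
            r, c = name[1:].split("_")
            return f"p{r}_{9 - int(c):02d}"
        focal = ["p02_01", "p07_03"]
        focal_m = [mirror(f) for f in focal]
        rest = grid.obs.difference(focal + focal_m, sort=False)
        s1 = score_table({focal[0]: 1.0, focal[1]: 0.0})
        s2 = score_table({focal_m[0]: 1.0, focal_m[1]: 0.0})
        _, nb1 = sm.neighborhood_de(grid, s1, rest, radius_um=25.0,
                                    high_fraction=0.5, min_umi=0)
        _, nb2 = sm.neighborhood_de(grid, s2, rest, radius_um=25.0,
                                    high_fraction=0.5, min_umi=0)
        assert {mirror(p) for p in nb1.high_neighbors} == \
            set(nb2.high_neighbors)
        assert {mirror(p) for p in nb1.low_neighbors} == \
            set(nb2.low_neighbors)

    def test_min_umi_floor_and_no_neighbor_error(self):
        grid = self.lattice_grid(seed=7)
        focal = list(grid.obs[:4])
        rest = grid.obs.difference(focal, sort=False)
        scores = score_table({f: float(i) for i, f in enumerate(focal)})
        with pytest.raises(ParameterError, match="UMI floor"):
            sm.neighborhood_de(grid, scores, rest, min_umi=10**9)
        with pytest.raises(ParameterError, match="no neighbors"):
            sm.neighborhood_de(grid, scores, rest, radius_um=1.0,
                               high_fraction=0.25, min_umi=0)
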