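"""Marker-panel clustering, subpopulations, phase calls, 2C cells, mRNA content."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import cellvar as cv
from cellvar.populations import linkage_to_newick, spearman_cell_distance


@pytest.fixture(scope="module")
def serum_view(full_normalized, full_dataset):
    obs, counts, norm, adj = full_normalized
    cells = obs.index[obs["condition"] == "serum"]
    return obs.loc[cells], adj[cells], full_dataset.uns["gene_sets"]


class TestMarkerPanelCluster:
    def test_two_planted_groups_recovered(self):
        rng = np.random.default_rng(20)
        genes = [f"g{i}" for i in range(20)]
        base = rng.uniform(3, 6, 20)
        shift = np.where(np.arange(20) < 10, 1.0, -1.0)
        cols = {}
        truth = []
        for i in range(200):
            grp = i % 2
            prof = base + shift * (1 if grp else -1) + rng.normal(0, 0.7, 20)
            cols[f"c{i}"] = np.exp2(prof)
            truth.append(grp)
        values = pd.DataFrame(cols, index=genes)
        res = cv.marker_panel_cluster(values, genes, k=2)
        assert adjusted_rand_score(truth, res.cell_labels) > 0.9

    def test_k_equals_n_cells(self):
        rng = np.random.default_rng(21)
        values = pd.DataFrame(rng.gamma(3, 10, size=(8, 6)))
        res = cv.marker_panel_cluster(values, list(values.index), k=6)
        assert res.cell_labels.nunique() == 6

    def test_duplicate_cell_zero_distance(self):
        rng = np.random.default_rng(22)
        values = pd.DataFrame(rng.gamma(3, 10, size=(10, 5)))
        values[5] = values[0]
        res = cv.marker_panel_cluster(values, list(values.index), k=2)
        assert abs(res.distance.loc[0, 5]) < 1e-12
        assert res.cell_labels[0] == res.cell_labels[5]

    def test_missing_panel_genes_listed(self):
        values = pd.DataFrame(np.ones((6, 25)), index=[f"g{i}" for i in range(6)])
        with pytest.raises(ValueError, match="gX"):
            cv.marker_panel_cluster(values, [f"g{i}" for i in range(5)] + ["gX"], k=2)

    def test_invariant_to_cell_order(self):
        rng = np.random.default_rng(23)
        values = pd.DataFrame(
            rng.gamma(3, 10, size=(12, 30)), columns=[f"c{i}" for i in range(30)]
        )
        res = cv.marker_panel_cluster(values, list(values.index), k=3)
        perm = rng.permutation(30)
        res2 = cv.marker_panel_cluster(values.iloc[:, perm], list(values.index), k=3)
        labels2 = res2.cell_labels[values.columns]
        assert adjusted_rand_score(res.cell_labels, labels2) == 1.0


class TestSerumSubpopulations:
    def test_planted_structure_recovered(self, serum_view):
        obs, values, sets = serum_view
        labels, table = cv.delineate_serum_subpopulations(
            values, sets["pluripotency_panel"], sets["differentiation_panel"]
        )
        assert adjusted_rand_score(obs["subpopulation"], labels) > 0.9
        props = table["proportion"]
        for name, planted in [("committed", 0.15), ("intermediate", 0.17), ("ground", 0.68)]:
            assert abs(props[name] - planted) <= 0.05
        assert (
            table.loc["committed", "pluripotency_score"]
            < table.loc["ground", "pluripotency_score"]
        )

    def test_committed_lose_pluripotency_markers(self, serum_view):
        obs, values, sets = serum_view
        oct4_like = sets["pluripotency_panel"][0]
        committed = obs.index[obs["subpopulation"] == "committed"]
        ground = obs.index[obs["subpopulation"] == "ground"]
        p = stats.mannwhitneyu(
            values.loc[oct4_like, committed],
            values.loc[oct4_like, ground],
            alternative="less",
        ).pvalue
        assert p < 0.01

    def test_conflicting_score_ordering_raises_ambiguity(self):
        """Three clear clusters where the lowest-pluripotency cluster is
        NOT the highest-differentiation one: the committed label cannot
        be assigned and the score table is surfaced in the error."""
        rng = np.random.default_rng(24)
        genes = [f"g{i}" for i in range(12)]
        pluri, diff = genes[:6], genes[6:]
        profiles = {
            "low_both": {g: 1.0 for g in pluri} | {g: 1.0 for g in diff},
            "high_both": {g: 7.0 for g in pluri} | {g: 7.0 for g in diff},
            "mid_both": {g: 4.0 for g in pluri} | {g: 4.0 for g in diff},
        }
        cols = {}
        for i in range(120):
            grp = list(profiles)[i % 3]
            prof = np.array([profiles[grp][g] for g in genes])
            cols[f"c{i}"] = np.exp2(prof + rng.normal(0, 0.3, 12))
        values = pd.DataFrame(cols, index=genes)
        with pytest.raises(ValueError, match="ambiguous|no cut"):
            cv.delineate_serum_subpopulations(values, pluri, diff)


class TestPhaseAssignment:
    def test_dominant_markers_win(self):
        g1s, g2m = [f"a{i}" for i in range(5)], [f"b{i}" for i in range(5)]
        mat = np.zeros((10, 12))
        mat[5:, :6] = 50.0  # first 6 cells express only G2M markers
        mat[:5, 6:] = 50.0
        values = pd.DataFrame(mat, index=g1s + g2m)
        table, _ = cv.assign_phase(values, g1s, g2m)
        assert (table["phase"][:6] == "G2M").all()
        assert (table["phase"][6:] == "G1S").all()

    def test_swap_symmetry(self, full_normalized, full_dataset):
        obs, _, _, adj = full_normalized
        sets = full_dataset.uns["gene_sets"]
        t1, _ = cv.assign_phase(adj, sets["G1S_markers"], sets["G2M_markers"])
        t2, _ = cv.assign_phase(adj, sets["G2M_markers"], sets["G1S_markers"])
        swapped = t2["phase"].map({"G1S": "G2M", "G2M": "G1S"})
        # ties break toward the first set, so equality holds off ties
        ties = t1["score_g1s"] == t1["score_g2m"]
        assert (t1["phase"][~ties] == swapped[~ties]).all()

    def test_fractions_sum_to_one_and_recover_planting(self, full_normalized, full_dataset):
        obs, _, _, adj = full_normalized
        sets = full_dataset.uns["gene_sets"]
        _, fr = cv.assign_phase(
            adj, sets["G1S_markers"], sets["G2M_markers"], conditions=obs["condition"]
        )
        assert np.allclose(fr.sum(axis=1), 1.0)
        assert abs(fr.loc["2i", "G2M"] - 0.60) <= 0.05
        assert abs(fr.loc["a2i", "G2M"] - 0.35) <= 0.05

    def test_empty_marker_set_rejected(self):
        values = pd.DataFrame(np.ones((4, 10)), index=list("abcd"))
        with pytest.raises(ValueError, match="empty"):
            cv.assign_phase(values, ["x", "y"], list("ab"))


class Test2CDetection:
    def test_planted_cells_found(self, full_normalized, full_dataset):
        obs, _, norm, _ = full_normalized
        sets = full_dataset.uns["gene_sets"]
        cells = obs.index[obs["condition"] == "2i"]
        endog = norm.loc[~full_dataset.var["is_spike"].values]
        flags, evidence = cv.detect_2c_cells(
            endog[cells], sets["2C_markers"], mervl_gene="MERVL-reporter"
        )
        truth = obs.loc[cells, "is_2c"]
        tp = int((flags & truth).sum())
        precision = tp / max(int(flags.sum()), 1)
        recall = tp / int(truth.sum())
        assert precision >= 0.9 and recall >= 0.9
        assert evidence["fold"][0] >= 10

    def test_no_planted_cells_no_flags(self, full_normalized, full_dataset):
        obs, _, norm, _ = full_normalized
        sets = full_dataset.uns["gene_sets"]
        cells = obs.index[obs["condition"] == "a2i"]
        endog = norm.loc[~full_dataset.var["is_spike"].values]
        flags, _ = cv.detect_2c_cells(
            endog[cells], sets["2C_markers"], mervl_gene="MERVL-reporter"
        )
        assert int(flags.sum()) == 0

    def test_unreachable_threshold_flags_nothing(self, full_normalized, full_dataset):
        obs, _, norm, _ = full_normalized
        sets = full_dataset.uns["gene_sets"]
        cells = obs.index[obs["condition"] == "2i"]
        endog = norm.loc[~full_dataset.var["is_spike"].values]
        flags, _ = cv.detect_2c_cells(
            endog[cells], sets["2C_markers"], mervl_gene="MERVL-reporter",
            fold_threshold=np.inf,
        )
        assert int(flags.sum()) == 0

    def test_missing_mervl_warns(self, full_normalized, full_dataset):
        obs, _, norm, _ = full_normalized
        sets = full_dataset.uns["gene_sets"]
        cells = obs.index[obs["condition"] == "2i"]
        endog = norm.loc[~full_dataset.var["is_spike"].values]
        with pytest.warns(UserWarning, match="absent"):
            cv.detect_2c_cells(endog[cells], sets["2C_markers"], mervl_gene="NotAGene")


class Test2CDifferentialExpression:
    def test_directional_recovery(self, full_normalized, full_dataset):
        obs, _, norm, _ = full_normalized
        cells = obs.index[obs["condition"] == "2i"]
        endog = norm.loc[~full_dataset.var["is_spike"].values, cells]
        flags = obs.loc[cells, "is_2c"]
        n_up, n_down, _ = cv.count_2c_de_direction(flags, endog)
        # planted: markers and MERVL up in 2C cells, nothing planted down
        assert n_up > n_down
        assert n_up >= 10

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(25)
        values = pd.DataFrame(
            rng.poisson(20, size=(300, 100)).astype(float),
            columns=[f"c{i}" for i in range(100)],
        )
        flags = pd.Series(False, index=values.columns)
        flags.iloc[:10] = True
        n_up, n_down, table = cv.count_2c_de_direction(flags, values)
        assert (n_up + n_down) <= 0.05 * len(table)

    def test_degenerate_flag_sets_rejected(self):
        values = pd.DataFrame(np.ones((5, 10)), columns=[f"c{i}" for i in range(10)])
        all_true = pd.Series(True, index=values.columns)
        with pytest.raises(ValueError, match="reference"):
            cv.count_2c_de_direction(all_true, values)
        two = pd.Series([True, True] + [False] * 8, index=values.columns)
        with pytest.raises(ValueError, match=">= 3"):
            cv.count_2c_de_direction(two, values)


class TestMRNAContent:
    def test_ratio_arithmetic(self):
        counts = pd.DataFrame(
            {"c1": [900, 100], "c2": [450, 100]}, index=["g1", "spike1"]
        )
        mask = pd.Series([False, True], index=counts.index)
        table, _ = cv.mrna_content(counts, mask)
        assert table.loc["c1", "ratio"] == 9.0
        assert table.loc["c2", "ratio"] == 4.5

    def test_doubling_endogenous_doubles_ratio(self):
        rng = np.random.default_rng(26)
        counts = pd.DataFrame(
            rng.poisson(50, size=(20, 8)), index=[f"g{i}" for i in range(20)]
        )
        mask = pd.Series([i >= 15 for i in range(20)], index=counts.index)
        t1, _ = cv.mrna_content(counts, mask)
        doubled = counts.copy()
        doubled.loc[~mask] *= 2
        t2, _ = cv.mrna_content(doubled, mask)
        assert np.allclose(t2["ratio"], 2 * t1["ratio"])

    def test_zero_spike_cell_flagged_and_excluded(self):
        counts = pd.DataFrame(
            {"c1": [900, 100], "c2": [450, 0]}, index=["g1", "spike1"]
        )
        mask = pd.Series([False, True], index=counts.index)
        table, _ = cv.mrna_content(counts, mask)
        assert not table.loc["c2", "defined"]
        assert np.isnan(table.loc["c2", "ratio"])

    def test_planted_content_difference_recovered(self):
        from conftest import single_condition_config

        cfg = single_condition_config(n_genes=600, n_cells=400, seed=30)
        cfg.conditions = ("lo", "hi")
        cfg.n_cells_per_condition = {"lo": 200, "hi": 200}
        cfg.n_batches_per_condition = {"lo": 1, "hi": 1}
        cfg.subpop_spec = {c: [cv.SubpopSpec("ground", 1.0)] for c in ("lo", "hi")}
        cfg.g2m_fraction = {"lo": 0.5, "hi": 0.5}
        cfg.content_by_condition = {"hi": 2.0}
        cfg.content_g2m_factor = 1.0
        cfg.batch_location_sd = cfg.batch_gene_location_sd = cfg.batch_scale_sd = 0.0
        ds = cv.simulate_dataset(cfg)
        counts = cv.counts_frame(ds)
        table, comp = cv.mrna_content(
            counts, ds.var["is_spike"], groups=ds.obs[["condition"]]
        )
        row = comp.iloc[0]
        observed = max(row["median_a"], row["median_b"]) / min(row["median_a"], row["median_b"])
        assert abs(observed - 2.0) <= 0.2
        assert row["p"] < 1e-6

    def test_ratio_stable_under_uniform_thinning(self):
        from conftest import single_condition_config

        cfg = single_condition_config(n_genes=600, n_cells=200, seed=31)
        ds = cv.simulate_dataset(cfg)
        counts = cv.counts_frame(ds)
        rng = np.random.default_rng(0)
        thinned = pd.DataFrame(
            rng.binomial(counts.values.astype(int), 0.5),
            index=counts.index,
            columns=counts.columns,
        )
        t1, _ = cv.mrna_content(counts, ds.var["is_spike"])
        t2, _ = cv.mrna_content(thinned, ds.var["is_spike"])
        assert abs(t2["ratio"].median() / t1["ratio"].median() - 1) < 0.05


def test_newick_rendering_round_trips_leaf_names():
    rng = np.random.default_rng(27)
    values = pd.DataFrame(
        rng.gamma(3, 10, size=(8, 6)), columns=[f"cell{i}" for i in range(6)]
    )
    res = cv.marker_panel_cluster(values, list(values.index), k=2)
    text = linkage_to_newick(res.linkage_tree, list(values.columns))
    assert text.endswith(";") and text.count("(") == text.count(")")
    for name in values.columns:
        assert name in text


def test_spearman_distance_properties():
    rng = np.random.default_rng(28)
    logv = pd.DataFrame(rng.normal(size=(15, 10)))
    d = spearman_cell_distance(logv)
    assert np.allclose(d.values, d.values.T)
    assert np.allclose(np.diag(d.values), 0.0)
    assert ((d.values >= 0) & (d.values <= 2)).all()
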