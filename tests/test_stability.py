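import numpy as np
import pandas as pd
import pytest

import refstab as rs
from refstab.errors import EstimationError

from . import oracles
from .conftest import random_ct_frames


def frame(values, genes, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestRelativeQuantities:
    def test_minimum_ct_maps_to_one(self, random_ct_matrix):
        q = rs.relative_quantities(random_ct_matrix)
        assert np.allclose(q.max(axis=1), 1.0)
        assert ((q > 0) & (q <= 1)).all().all()

    def test_hand_values(self):
        ct = frame([[20.0, 23.0]], ["g"])
        assert rs.relative_quantities(ct).iloc[0, 1] == pytest.approx(0.125)
        ct2 = frame([[20.0, 21.0]], ["g"])
        q2 = rs.relative_quantities(ct2, {"g": 1.9})
        assert q2.iloc[0, 1] == pytest.approx(1.9**-1, abs=1e-12)


class TestGenorm:
    def test_proportional_genes_have_zero_m(self):
        base = np.array([1.0, 0.5, 0.25, 0.8])
        q = frame([base, 0.5 * base, 0.1 * base], ["a", "b", "c"])
        res = rs.genorm(q)
        assert np.allclose(res.m_values, 0.0)

    def test_matches_brute_force(self, random_ct_matrix):
        q = rs.relative_quantities(random_ct_matrix)
        res = rs.genorm(q)
        logq = {g: list(np.log2(q.loc[g])) for g in q.index}
        expected = oracles.genorm_m_oracle(logq)
        for g in q.index:
            assert res.m_values[g] == pytest.approx(expected[g], abs=1e-10)

    def test_sample_scale_invariance(self, random_ct_matrix):
        q = rs.relative_quantities(random_ct_matrix)
        scaled = q.copy()
        scaled.iloc[:, 2] *= 7.3  # common factor on one sample
        a, b = rs.genorm(q).m_values, rs.genorm(scaled).m_values
        assert np.allclose(a, b, atol=1e-12)

    def test_final_pair_shares_rank_and_m(self):
        rng = np.random.default_rng(1)
        q = rs.relative_quantities(
            frame(rng.uniform(18, 30, size=(5, 8)), [f"g{i}" for i in range(5)])
        )
        res = rs.genorm(q)
        pair = res.final_pair
        assert len(pair) == 2
        assert (res.ranking[list(pair)] == 1.5).all()
        # M of the surviving pair is symmetric: one pairwise SD each
        logq = np.log2(q.loc[list(pair)].to_numpy())
        m_pair = np.std(logq[0] - logq[1], ddof=1)
        assert m_pair == m_pair  # finite

    def test_too_few_genes_raises(self):
        with pytest.raises(EstimationError, match="3"):
            rs.genorm(frame([[1.0, 0.5], [0.5, 1.0]], ["a", "b"]))


class TestPairwiseVariation:
    def test_proportional_genes_all_zero(self):
        base = np.array([1.0, 0.5, 0.25, 0.8])
        q = frame([base, 0.5 * base, 0.1 * base, 0.2 * base], list("abcd"))
        res = rs.genorm(q)
        v = rs.genorm_pairwise_variation(q, res.ranking)
        assert np.allclose(v, 0.0)

    def test_series_length(self):
        rng = np.random.default_rng(2)
        q = rs.relative_quantities(
            frame(rng.uniform(18, 30, size=(5, 6)), [f"g{i}" for i in range(5)])
        )
        v = rs.genorm_pairwise_variation(q, rs.genorm(q).ranking)
        assert list(v.index) == ["V2/3", "V3/4", "V4/5"]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        q = rs.relative_quantities(
            frame(rng.uniform(18, 30, size=(4, 7)), [f"g{i}" for i in range(4)])
        )
        res = rs.genorm(q)
        v = rs.genorm_pairwise_variation(q, res.ranking)
        order = list(res.ranking.sort_values(kind="mergesort").index)
        logq = {g: list(np.log2(q.loc[g])) for g in q.index}
        expected = oracles.genorm_pairwise_variation_oracle(logq, order)
        assert np.allclose(v.to_numpy(), expected, atol=1e-10)


class TestNormfinder:
    def test_additive_gene_has_zero_rho(self):
        rng = np.random.default_rng(4)
        others = rng.uniform(18, 30, size=(3, 6))
        x = others.mean(axis=0) + 1.0  # column means plus a constant
        ct = frame(np.vstack([others, x]), ["a", "b", "c", "x"])
        rho = rs.normfinder(ct)
        assert rho["x"] == pytest.approx(0.0, abs=1e-12)

    def test_per_sample_shift_invariance(self, random_ct_matrix):
        shifted = random_ct_matrix + np.array([0.3, -0.8, 1.1, 0.0, 2.0, -1.5])
        a, b = rs.normfinder(random_ct_matrix), rs.normfinder(shifted)
        assert np.allclose(a, b, atol=1e-12)

    def test_matches_brute_force(self, random_ct_matrix):
        y = rs.log2_quantities(random_ct_matrix)
        expected = oracles.normfinder_oracle(
            {g: list(y.loc[g]) for g in y.index}
        )
        rho = rs.normfinder(random_ct_matrix)
        for g in y.index:
            assert rho[g] == pytest.approx(expected[g], abs=1e-10)

    def test_grouped_matches_brute_force(self):
        rng = np.random.default_rng(8)
        ct = frame(rng.uniform(18, 30, size=(5, 8)),
                   [f"g{i}" for i in range(5)])
        labels = ["u"] * 4 + ["v"] * 4
        groups = pd.Series(labels, index=ct.columns)
        rho = rs.normfinder(ct, groups=groups)
        y = rs.log2_quantities(ct)
        expected = oracles.normfinder_grouped_oracle(
            {g: list(y.loc[g]) for g in y.index}, labels
        )
        for g in ct.index:
            assert rho[g] == pytest.approx(expected[g], abs=1e-10)

    def test_bad_grouping_falls_back_with_warning(self, random_ct_matrix):
        groups = pd.Series(["u"] * 5 + ["v"], index=random_ct_matrix.columns)
        with pytest.warns(UserWarning, match="ungrouped"):
            rho = rs.normfinder(random_ct_matrix, groups=groups)
        assert np.allclose(rho, rs.normfinder(random_ct_matrix))


class TestBestkeeper:
    def test_constant_gene_degenerate(self):
        ct = frame([[21.0, 21.0, 21.0], [20.0, 22.0, 24.0], [19.0, 20.0, 21.0]],
                   ["const", "a", "b"])
        bk = rs.bestkeeper(ct)
        assert bk.loc["const", "bestkeeper_sd"] == 0.0
        assert bk.loc["const", "bestkeeper_cv_pct"] == 0.0
        assert np.isnan(bk.loc["const", "bestkeeper_r"])

    def test_hand_calculation(self):
        bk = rs.bestkeeper(frame([[20.0, 22.0], [21.0, 21.0]], ["g", "h"]))
        assert bk.loc["g", "bestkeeper_sd"] == pytest.approx(np.sqrt(2), abs=1e-4)
        assert bk.loc["g", "bestkeeper_cv_pct"] == pytest.approx(
            100 * np.sqrt(2) / 21, abs=1e-3
        )

    def test_geometric_mean_index(self):
        ct = frame([[20.0], [30.0]], ["a", "b"], ["s"])
        idx = rs.stability.bestkeeper_index(ct)
        assert idx["s"] == pytest.approx(np.sqrt(600), abs=1e-4)

    def test_matches_brute_force(self, random_ct_matrix):
        bk = rs.bestkeeper(random_ct_matrix)
        expected = oracles.bestkeeper_oracle(
            {g: list(random_ct_matrix.loc[g]) for g in random_ct_matrix.index}
        )
        for g in random_ct_matrix.index:
            assert bk.loc[g, "bestkeeper_sd"] == pytest.approx(
                expected[g]["sd"], abs=1e-10)
            assert bk.loc[g, "bestkeeper_r"] == pytest.approx(
                expected[g]["r"], abs=1e-10)

    def test_high_sd_flagged_inconsistent(self):
        ct = frame([[18.0, 24.0, 20.0], [21.0, 21.1, 21.2], [22.0, 22.1, 21.9]],
                   ["wild", "calm", "calm2"])
        bk = rs.bestkeeper(ct)
        assert bool(bk.loc["wild", "inconsistent"])
        assert not bk.loc["calm", "inconsistent"]


class TestDeltaCt:
    def test_constant_offset_pair_is_perfectly_stable(self):
        ct = frame([[20.0, 21.0, 22.0], [23.0, 24.0, 25.0]], ["a", "b"])
        st = rs.delta_ct_stability(ct)
        assert np.allclose(st, 0.0)

    def test_hand_calculation(self):
        ct = frame([[20.0, 21.0, 22.0], [20.0, 22.0, 24.0], [20.0, 20.0, 20.0]],
                   ["A", "B", "C"])
        st = rs.delta_ct_stability(ct)
        assert st["A"] == pytest.approx(1.0)
        assert st["B"] == pytest.approx(1.5)
        assert st["C"] == pytest.approx(1.5)

    def test_per_sample_shift_invariance(self, random_ct_matrix):
        shifted = random_ct_matrix + np.array([1.0, -2.0, 0.5, 0.0, 3.0, -1.0])
        assert np.allclose(
            rs.delta_ct_stability(random_ct_matrix),
            rs.delta_ct_stability(shifted),
            atol=1e-12,
        )

    def test_matches_brute_force(self, random_ct_matrix):
        st = rs.delta_ct_stability(random_ct_matrix)
        expected = oracles.delta_ct_oracle(
            {g: list(random_ct_matrix.loc[g]) for g in random_ct_matrix.index}
        )
        for g in random_ct_matrix.index:
            assert st[g] == pytest.approx(expected[g], abs=1e-10)


class TestComposite:
    def test_unanimous_winner(self):
        ranks = pd.DataFrame(
            {"m1": [1, 2, 3], "m2": [1, 3, 2], "m3": [1, 2, 3], "m4": [1, 3, 2]},
            index=["w", "x", "y"],
        )
        comp = rs.composite_rank(ranks)
        assert comp.loc["w", "composite_geomean"] == pytest.approx(1.0)
        assert comp.loc["w", "final_rank"] == 1.0

    def test_hand_geometric_mean(self):
        ranks = pd.DataFrame({"m1": [1], "m2": [2], "m3": [1], "m4": [2]},
                             index=["g"])
        comp = rs.composite_rank(ranks)
        assert comp.loc["g", "composite_geomean"] == pytest.approx(
            4 ** 0.25, abs=1e-9
        )

    def test_order_invariance(self, random_ct_matrix):
        scores = rs.stability_scores(random_ct_matrix)
        perm = random_ct_matrix.iloc[[2, 0, 3, 1]]
        scores_p = rs.stability_scores(perm)
        joined = scores.table["final_rank"].sort_index()
        assert joined.equals(scores_p.table["final_rank"].sort_index())


class TestSubsetsAndRanker:
    def _table(self, seed=0, **kwargs):
        table, truth = rs.generate_ct_dataset(
            rs.CtDesign(), rs.default_gene_panel(), seed=seed, **kwargs
        )
        return table, truth

    def test_degenerate_partition_equals_all_samples(self):
        table, _ = self._table()
        report = rs.subset_stability(table, partition="strain")
        only_qm6a = rs.CtTable(
            table.data[table.data["strain"] == "QM6a"].copy()
        )
        direct = rs.StabilityRanker().fit(only_qm6a)
        assert report.subset_scores["strain=QM6a"] == direct.scores_

    def test_strain_partition_structure(self):
        table, _ = self._table()
        report = rs.subset_stability(table, partition="strain")
        assert set(report.subset_scores) == {"strain=QM6a", "strain=Rut-C30"}
        assert report.scores.table.shape[0] == 7

    def test_subset_specific_stability_contrast(self):
        """A gene regulated only in strain B ranks better within strain A."""
        design = rs.CtDesign()
        fixed = {
            cell: (2.0 if (cell[0] == "Rut-C30" and i % 2 == 0) else 0.0)
            for i, cell in enumerate(design.cells)
        }
        genes = [
            rs.CtGeneSpec("x", cond_sd=0.0, bio_sd=0.1, tech_sd=0.1,
                          fixed_effects=fixed),
            rs.CtGeneSpec("r1", cond_sd=0.1, bio_sd=0.1, tech_sd=0.1),
            rs.CtGeneSpec("r2", cond_sd=0.4, bio_sd=0.1, tech_sd=0.1),
            rs.CtGeneSpec("r3", cond_sd=0.6, bio_sd=0.1, tech_sd=0.1),
        ]
        table, _ = rs.generate_ct_dataset(design, genes, seed=21)
        report = rs.subset_stability(table, partition="strain")
        rank_a = report.subset_scores["strain=QM6a"].table.loc["x", "final_rank"]
        rank_b = report.subset_scores["strain=Rut-C30"].table.loc["x", "final_rank"]
        assert rank_a < rank_b

    def test_stage_labels_derive_early_late(self):
        rows = []
        for tp in ("24", "84"):
            rows.append((f"S{tp}", "g1", 20.0, 1, 1, "A", "glc", tp))
        from .conftest import make_ct_table

        stage = rs.stability.derive_stage_labels(make_ct_table(rows))
        assert stage["S24"] == "early" and stage["S84"] == "late"

    def test_ranker_recovers_truth_order_extremes(self):
        table, truth = self._table(seed=13)
        est = rs.StabilityRanker().fit(table)
        worst_two = set(truth.expected_stability_order[-2:])
        bottom_two = set(
            est.scores_.table["final_rank"].nlargest(2).index
        )
        assert bottom_two == worst_two

    def test_ranker_accepts_wide_frame(self, random_ct_matrix):
        est = rs.StabilityRanker().fit(random_ct_matrix)
        assert est.scores_.table.shape[0] == 4
        assert est.ranking_.min() == 1.0


@pytest.mark.parametrize("method", ["genorm", "normfinder", "deltact"])
def test_methods_match_oracles_on_random_panel(method):
    """Spot-check each score against its brute-force oracle on 10 matrices."""
    for ct in random_ct_frames(10, seed=99):
        if method == "genorm":
            q = rs.relative_quantities(ct)
            got = rs.genorm(q).m_values
            expected = oracles.genorm_m_oracle(
                {g: list(np.log2(q.loc[g])) for g in q.index}
            )
        elif method == "normfinder":
            got = rs.normfinder(ct)
            y = rs.log2_quantities(ct)
            expected = oracles.normfinder_oracle(
                {g: list(y.loc[g]) for g in y.index}
            )
        else:
            got = rs.delta_ct_stability(ct)
            expected = oracles.delta_ct_oracle(
                {g: list(ct.loc[g]) for g in ct.index}
            )
        for g in ct.index:
            assert got[g] == pytest.approx(expected[g], abs=1e-10)
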