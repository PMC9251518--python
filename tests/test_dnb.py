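import numpy as np
import pandas as pd
import pytest

from tipnet.dnb import (
    StageView,
    candidate_groups,
    composite_index,
    select_dnb,
    stage_views,
    tipping_stage,
)

from conftest import make_expression, oracle_composite_index


def view_from_rows(rows, stage="S"):
    rows = np.asarray(rows, dtype=float)
    genes = [f"g{i}" for i in range(rows.shape[0])]
    return StageView(
        stage, pd.DataFrame(rows, index=genes,
                            columns=[f"s{j}" for j in range(rows.shape[1])])
    )


class TestCompositeIndex:
    def test_hand_example(self):
        view = view_from_rows([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]])
        ci = composite_index(view, {"g0", "g1"})
        assert ci.sd_d == pytest.approx(np.sqrt(5 / 3), rel=1e-12)
        assert ci.pcc_d == pytest.approx(1.0)
        assert ci.pcc_o == pytest.approx(1.0)
        assert ci.ci == pytest.approx(np.sqrt(5 / 3), rel=1e-12)

    def test_constant_group_degenerate(self):
        view = view_from_rows([[2, 2, 2, 2], [3, 3, 3, 3], [1, 2, 3, 4]])
        with pytest.warns(UserWarning):
            ci = composite_index(view, {"g0", "g1"})
        assert ci.sd_d == 0.0 and ci.ci == 0.0 and ci.degenerate

    def test_zero_pcc_o_flagged_infinite(self):
        view = view_from_rows([[1, 2, 3, 4], [1, 2, 3, 4], [5, 5, 5, 5]])
        with pytest.warns(UserWarning):
            ci = composite_index(view, {"g0", "g1"})
        assert ci.infinite and np.isinf(ci.ci)

    def test_duplicating_group_gene_keeps_means(self):
        rng = np.random.default_rng(0)
        rows = rng.standard_normal((4, 8))
        base = composite_index(view_from_rows(rows), {"g0", "g1"})
        dup = np.vstack([rows[:2], rows[:2], rows[2:]])
        doubled = composite_index(view_from_rows(dup), {"g0", "g1", "g2", "g3"})
        assert doubled.sd_d == pytest.approx(base.sd_d, rel=1e-12)
        # every duplicated pair correlates at exactly 1 except self-copies
        assert doubled.pcc_o == pytest.approx(base.pcc_o, rel=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for n_group in (2, 4, 8):
            rows = rng.gamma(2, 3, (n_group + 5, 9))
            view = view_from_rows(rows)
            group = {f"g{i}" for i in range(n_group)}
            ci = composite_index(view, group)
            mask = np.array([g in group for g in view.values.index])
            sd, pd_, po, ref = oracle_composite_index(rows, mask)
            assert ci.sd_d == pytest.approx(sd, abs=1e-12)
            assert ci.pcc_d == pytest.approx(pd_, abs=1e-12)
            assert ci.pcc_o == pytest.approx(po, abs=1e-12)
            assert ci.ci == pytest.approx(ref, abs=1e-12)

    def test_invariances(self):
        rng = np.random.default_rng(2)
        rows = rng.standard_normal((6, 10))
        group = {"g0", "g1", "g2"}
        base = composite_index(view_from_rows(rows), group)
        # per-gene mean shifts
        shifted = rows + rng.standard_normal((6, 1))
        assert composite_index(view_from_rows(shifted), group).ci == pytest.approx(
            base.ci, rel=1e-12
        )
        # sample reordering
        perm = rng.permutation(10)
        assert composite_index(view_from_rows(rows[:, perm]), group).ci == (
            pytest.approx(base.ci, rel=1e-12)
        )
        # common multiplicative factor on group genes scales CI through sd_d
        scaled = rows.copy()
        scaled[:3] *= 3.0
        assert composite_index(view_from_rows(scaled), group).ci == pytest.approx(
            3 * base.ci, rel=1e-12
        )

    def test_group_must_leave_outsiders(self):
        view = view_from_rows(np.random.default_rng(3).random((3, 6)))
        with pytest.raises(ValueError, match="non-member"):
            composite_index(view, {"g0", "g1", "g2"})


class TestCandidateGroups:
    def _two_stage_views(self, rng, n_genes=12, block=None, n_samples=8):
        blocks = []
        for stage in ("A", "B"):
            x = rng.standard_normal((n_genes, n_samples))
            if block and stage == "B":
                f = rng.standard_normal(n_samples)
                for i in block:
                    x[i] = 0.9 * f + 0.2 * rng.standard_normal(n_samples)
            blocks.append(view_from_rows(x, stage))
        return blocks

    def test_planted_block_found(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            views = self._two_stage_views(rng, block=[0, 1, 2, 3, 4])
            cands = candidate_groups(views, min_size=5, cut_height=0.5)
            planted = {f"g{i}" for i in range(5)}
            if any(len(set(m) & planted) >= 4 for _, m in cands):
                hits += 1
        assert hits >= 18  # >=90% of 20 seeds

    def test_independent_genes_yield_nothing(self):
        quiet = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            views = self._two_stage_views(rng, block=None)
            cands = candidate_groups(views, min_size=5, cut_height=0.5)
            quiet += not cands
        assert quiet >= 15

    def test_min_size_above_gene_count_empty(self):
        rng = np.random.default_rng(4)
        views = self._two_stage_views(rng)
        with pytest.warns(UserWarning, match="no candidate"):
            assert candidate_groups(views, min_size=50) == []

    def test_needs_two_stages(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="2 stages"):
            candidate_groups([view_from_rows(rng.random((6, 8)))])


class TestTippingStage:
    def test_argmax(self):
        tip, flags = tipping_stage(
            {"NCA": 1.0, "IML": 5.0, "AMI": 2.0}, ["NCA", "IML", "AMI"]
        )
        assert tip == "IML" and not flags["tie"]

    def test_all_equal_degenerate(self):
        tip, flags = tipping_stage(
            {"NCA": 0.0, "IML": 0.0, "AMI": 0.0}, ["NCA", "IML", "AMI"]
        )
        assert tip == "NCA" and flags["tie"] and flags["degenerate"]

    def test_tie_goes_to_earliest(self):
        tip, flags = tipping_stage(
            {"NCA": 3.0, "IML": 3.0, "AMI": 1.0}, ["NCA", "IML", "AMI"]
        )
        assert tip == "NCA" and flags["tie"] and not flags["degenerate"]


class TestSelectDnb:
    def test_deterministic(self, small_study):
        from tipnet.expression import filter_expressed

        expr = filter_expressed(small_study.expression, 8)
        r1 = select_dnb(expr, min_size=10, log2=True)
        r2 = select_dnb(expr, min_size=10, log2=True)
        assert r1.dnb_genes == r2.dnb_genes
        assert r1.tipping_stage == r2.tipping_stage
        assert r1.ci_profile() == r2.ci_profile()

    def test_recovers_planted_group(self, small_study):
        """Smoke-level recovery on one study: the winner substantially
        overlaps the planted group and the tipping stage is right (the
        recovery *rate* over many seeds is asserted in the acceptance
        suite)."""
        from tipnet.expression import filter_expressed

        expr = filter_expressed(small_study.expression, 8)
        res = select_dnb(expr, min_size=10, log2=True)
        truth = small_study.truth.dnb_genes
        jac = len(res.dnb_genes & truth) / len(res.dnb_genes | truth)
        assert jac >= 1 / 3
        assert res.tipping_stage == expr.stage_order[small_study.truth.tipping_stage]

    def test_audit_covers_every_candidate(self, small_study):
        from tipnet.expression import filter_expressed

        expr = filter_expressed(small_study.expression, 8)
        res = select_dnb(expr, min_size=10, log2=True)
        assert res.candidates_audit
        assert all(
            set(a) >= {"origin_stage", "size", "score", "ci"}
            for a in res.candidates_audit
        )

    def test_monotone_in_planted_inflation(self):
        """Raising the planted SD inflation does not lower the median CI at
        the planted stage (paired seeds)."""
        from tipnet.expression import filter_expressed
        from tipnet.simulate import SimulationConfig, simulate_study

        def tip_ci(seed, inflation):
            cfg = SimulationConfig(
                n_genes=80, module_sizes=[25], module_trait_loadings=[0.5],
                dnb_size=12, dnb_sd_inflation=inflation, seed=seed,
            )
            study = simulate_study(cfg)
            expr = filter_expressed(study.expression, 8)
            views = stage_views(expr, log2=True)
            tip = expr.stage_order[study.truth.tipping_stage]
            view = next(v for v in views if v.stage == tip)
            return composite_index(view, study.truth.dnb_genes).ci

        lo = np.median([tip_ci(s, 1.5) for s in range(20)])
        hi = np.median([tip_ci(s, 3.0) for s in range(20)])
        assert hi >= lo
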