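"""Screen orchestration, gene classification and candidate-set algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rfgsea import (
    GeneSet,
    ScreenConfig,
    SimulationParams,
    assemble_candidates,
    screen_all,
    screen_gene,
    simulate_study,
)
from rfgsea.rf import RFConfig
from rfgsea.screen import GeneScreenRecord, _child_seeds, _classify_mse

FAST = ScreenConfig(rf=RFConfig(n_trees=30, seed=0), n_perm=150, root_seed=0)


@pytest.fixture(scope="module")
def tiny_study():
    return simulate_study(
        SimulationParams(
            n_genes=30, n_samples=50, module_size=10, prior_true=7,
            prior_decoys=3, seed=3,
        )
    )


class TestClassification:
    @pytest.mark.parametrize(
        "es,p,expected",
        [
            (0.8, 0.01, "POSITIVE"),
            (-0.8, 0.01, "NEGATIVE"),
            (0.8, 0.20, "NONE"),
            (-0.8, 0.05, "NONE"),  # p == alpha is not < alpha
            (0.0, 0.001, "NONE"),
        ],
    )
    def test_mse_class_rule(self, es, p, expected):
        assert _classify_mse(es, p, alpha=0.05) == expected


class TestScreenGene:
    def test_module_gene_flagged_positive(self, tiny_study):
        gene = sorted(tiny_study.module_genes)[0]
        rec = screen_gene(tiny_study.matrix, gene, tiny_study.prior, FAST)
        assert rec.mse_class == "POSITIVE"

    def test_negative_class_when_prior_anchors_bottom(self):
        """A target driven only by non-prior genes, with the prior genes
        pure noise, enriches the prior at the bottom of the ranking."""
        rng = np.random.default_rng(0)
        n_s = 60
        drivers = rng.normal(size=(6, n_s))
        y = drivers.sum(axis=0) + rng.normal(0, 0.3, n_s)
        noise = rng.normal(size=(10, n_s))
        genes = ("T",) + tuple(f"D{i}" for i in range(6)) + tuple(
            f"P{i}" for i in range(10)
        )
        import rfgsea

        m = rfgsea.ExpressionMatrix(
            genes, tuple(f"S{j}" for j in range(n_s)), np.vstack([y, drivers, noise])
        )
        prior = GeneSet("p", tuple(f"P{i}" for i in range(10)))
        rec = screen_gene(m, "T", prior, FAST)
        assert rec.es_mse < 0
        assert rec.mse_class in ("NEGATIVE", "NONE")
        # with the bottom-anchored ranking, significance implies NEGATIVE
        if rec.p_mse < FAST.alpha:
            assert rec.mse_class == "NEGATIVE"


class TestScreenAll:
    def test_one_record_per_eligible_gene(self, tiny_study):
        table = screen_all(tiny_study.matrix, tiny_study.prior, FAST)
        assert len(table) == tiny_study.matrix.n_genes
        assert list(table["gene"]) == list(tiny_study.matrix.gene_ids)

    def test_constant_gene_skipped_with_log(self, tiny_study, caplog):
        vals = tiny_study.matrix.values.copy()
        vals[4] = 7.0
        import rfgsea

        m = rfgsea.ExpressionMatrix(
            tiny_study.matrix.gene_ids, tiny_study.matrix.sample_ids, vals
        )
        with caplog.at_level("WARNING", logger="rfgsea"):
            table = screen_all(m, tiny_study.prior, FAST)
        assert len(table) == m.n_genes - 1
        skipped = m.gene_ids[4]
        assert skipped not in set(table["gene"])
        assert sum(skipped in r.message for r in caplog.records) == 1

    def test_worker_count_does_not_change_results(self, tiny_study):
        sub = ScreenConfig(
            rf=RFConfig(n_trees=20, seed=0), n_perm=120, root_seed=1,
            target_genes=tuple(tiny_study.matrix.gene_ids[:6]),
        )
        serial = screen_all(tiny_study.matrix, tiny_study.prior, sub)
        from dataclasses import replace

        parallel = screen_all(
            tiny_study.matrix, tiny_study.prior, replace(sub, workers=2)
        )
        pd.testing.assert_frame_equal(serial, parallel)

    def test_checkpoint_resume_skips_finished_genes(self, tiny_study, tmp_path):
        ckpt = tmp_path / "screen.ckpt"
        cfg = ScreenConfig(
            rf=RFConfig(n_trees=20, seed=0), n_perm=120, root_seed=2,
            target_genes=tuple(tiny_study.matrix.gene_ids[:4]),
        )
        first = screen_all(tiny_study.matrix, tiny_study.prior, cfg, checkpoint=ckpt)
        assert ckpt.exists()
        resumed = screen_all(tiny_study.matrix, tiny_study.prior, cfg, checkpoint=ckpt)
        pd.testing.assert_frame_equal(first, resumed)

    def test_per_gene_seeds_independent_of_target_subset(self, tiny_study):
        full = screen_all(tiny_study.matrix, tiny_study.prior, FAST)
        from dataclasses import replace

        sub = screen_all(
            tiny_study.matrix,
            tiny_study.prior,
            replace(FAST, target_genes=tuple(tiny_study.matrix.gene_ids[5:8])),
        )
        merged = full[full["gene"].isin(sub["gene"])].reset_index(drop=True)
        # BH columns differ (different families); raw columns must agree
        raw = ["gene", "es_mse", "p_mse", "es_purity", "p_purity"]
        pd.testing.assert_frame_equal(merged[raw], sub[raw].reset_index(drop=True))

    def test_child_seeds_stable_and_distinct(self):
        a = _child_seeds(17, "TP53")
        assert a == _child_seeds(17, "TP53")
        assert a != _child_seeds(17, "KRAS")
        assert a != _child_seeds(18, "TP53")
        assert all(0 <= s < 2**31 for s in a)


def record(gene, mse_class="NONE", purity=False):
    return GeneScreenRecord(
        gene=gene, es_mse=0.5 if mse_class == "POSITIVE" else -0.5,
        p_mse=0.01 if mse_class != "NONE" else 0.5,
        es_purity=0.4, p_purity=0.01 if purity else 0.9,
        mse_class=mse_class, purity_hit=purity,
    )


class TestAssemble:
    def test_hand_worked_set_algebra(self):
        records = [
            record("A", "POSITIVE"),
            record("B", "POSITIVE", purity=True),
            record("C", "NEGATIVE", purity=True),
            record("D"),
        ]
        sets = assemble_candidates(records, degs=["B", "C", "D"])
        assert sets.final == {"B"}
        assert "C" not in sets.final
        assert sets.mse_negative == {"C"}

    def test_empty_degs_empty_final(self):
        sets = assemble_candidates([record("A", "POSITIVE", purity=True)], degs=[])
        assert sets.final == frozenset()

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["POSITIVE", "NEGATIVE", "NONE"]),
                st.booleans(),
                st.booleans(),
            ),
            min_size=1,
            max_size=25,
        )
    )
    def test_invariants_hold_on_fuzzed_tables(self, rows):
        records = [
            record(f"G{i}", mse_class, purity)
            for i, (mse_class, purity, _) in enumerate(rows)
        ]
        degs = [f"G{i}" for i, (_, _, in_degs) in enumerate(rows) if in_degs]
        sets = assemble_candidates(records, degs)
        assert not sets.mse_positive & sets.mse_negative
        assert sets.final == sets.mse_positive & sets.purity & sets.degs
        assert not sets.final & sets.mse_negative
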