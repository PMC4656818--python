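"""Tests for the synthetic-data generators and their planted-truth contracts."""

import numpy as np
import pandas as pd
import pytest

from omicompare.microarray_de import IntensityMatrix
from omicompare.simulate import (
    simulate_expression_study,
    simulate_itraq_experiment,
    simulate_literature_corpus,
    simulate_pathway_annotation,
)


class TestExpressionStudy:
    def test_zero_de_fraction_plants_nothing(self):
        _, _, truth = simulate_expression_study(n_genes=50, de_fraction=0.0, seed=1)
        assert truth.de_genes == {}

    def test_same_seed_reproduces_matrices_exactly(self):
        c1, k1, t1 = simulate_expression_study(n_genes=40, seed=7)
        c2, k2, t2 = simulate_expression_study(n_genes=40, seed=7)
        assert c1.values.equals(c2.values)
        assert k1.values.equals(k2.values)
        assert t1.de_genes == t2.de_genes

    def test_different_seeds_differ(self):
        c1, _, _ = simulate_expression_study(n_genes=40, seed=1)
        c2, _, _ = simulate_expression_study(n_genes=40, seed=2)
        assert not c1.values.equals(c2.values)

    def test_planted_count_and_polarity_split(self):
        _, _, truth = simulate_expression_study(n_genes=100, de_fraction=0.05, seed=3)
        polarities = [p for p, _ in truth.de_genes.values()]
        assert len(polarities) == 5
        assert polarities.count(+1) == 3  # ties go to up
        assert polarities.count(-1) == 2

    def test_intensities_strictly_positive(self):
        control, case, _ = simulate_expression_study(n_genes=30, seed=4)
        assert (control.values.to_numpy() > 0).all()
        assert (case.values.to_numpy() > 0).all()

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            simulate_expression_study(n_genes=5)
        with pytest.raises(ValueError):
            simulate_expression_study(n_replicates=1)
        with pytest.raises(ValueError):
            simulate_expression_study(de_fraction=1.0)

    def test_metadata_carries_genotype_and_tissue(self):
        control, case, _ = simulate_expression_study(n_genes=20, seed=5, tissue="cortex")
        assert (control.sample_meta["genotype"] == "control").all()
        assert (case.sample_meta["genotype"] == "case").all()
        assert (case.sample_meta["tissue"] == "cortex").all()


class TestItraqExperiment:
    def test_noiseless_null_gives_exact_unit_ratios(self):
        table, truth = simulate_itraq_experiment(
            n_proteins=10, control_cv=0.0, diff_fraction=0.0, fold=1.0, seed=1
        )
        assert truth.diff_proteins == {}
        assert np.allclose(table["i114"], table["i115"])
        assert np.allclose(table["i114"] / table["i115"], 1.0)
        ctrl_mean = (table["i114"] + table["i115"]) / 2
        assert np.allclose(table["i116"] / ctrl_mean, 1.0)

    def test_same_seed_identical_tables(self):
        t1, _ = simulate_itraq_experiment(n_proteins=20, seed=9)
        t2, _ = simulate_itraq_experiment(n_proteins=20, seed=9)
        assert t1.equals(t2)

    def test_planted_fold_shows_in_case_channels(self):
        table, truth = simulate_itraq_experiment(
            n_proteins=10, control_cv=0.0, diff_fraction=0.3, fold=2.0, seed=2
        )
        planted = set(truth.diff_proteins)
        assert len(planted) == 3
        sub = table[table["protein_id"].isin(planted)]
        ctrl = (sub["i114"] + sub["i115"]) / 2
        assert np.allclose(sub["i116"] / ctrl, 2.0)

    def test_custom_protein_ids_and_pinned_planted(self):
        ids = ["Stxbp1", "Rock2", "Agk"]
        table, truth = simulate_itraq_experiment(protein_ids=ids, planted=["Agk"], seed=3)
        assert set(table["protein_id"]) == set(ids)
        assert set(truth.diff_proteins) == {"Agk"}

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            simulate_itraq_experiment(peptides_per_protein=0)
        with pytest.raises(ValueError):
            simulate_itraq_experiment(fold=0.0)
        with pytest.raises(ValueError):
            simulate_itraq_experiment(protein_ids=["A"], planted=["B"])


class TestPathwayAnnotation:
    universe = [f"g{i}" for i in range(200)]

    def test_planted_pathway_attains_R_above_one(self):
        de = self.universe[:20]
        coll, truth = simulate_pathway_annotation(
            n_pathways=10, universe=self.universe, planted={"pw01"}, de_genes=de,
            enrichment_factor=5.0, seed=1,
        )
        from omicompare.enrichment import hypergeometric_enrichment

        rec = hypergeometric_enrichment(de, coll, min_members=0)
        assert rec.loc["pw01", "R"] > 1

    def test_empty_de_genes_gives_all_zero_overlap(self):
        coll, _ = simulate_pathway_annotation(
            n_pathways=5, universe=self.universe, planted=set(), de_genes=[], seed=2
        )
        assert all(len(m & set()) == 0 for m in coll.pathways.values())

    def test_unknown_planted_id_rejected(self):
        with pytest.raises(ValueError, match="planted"):
            simulate_pathway_annotation(
                n_pathways=3, universe=self.universe, planted={"pw99"}, de_genes=[], seed=3
            )

    def test_determinism(self):
        kw = dict(n_pathways=6, universe=self.universe, planted={"pw02"}, de_genes=self.universe[:10], seed=5)
        c1, _ = simulate_pathway_annotation(**kw)
        c2, _ = simulate_pathway_annotation(**kw)
        assert c1.pathways == c2.pathways

    def test_null_factor_keeps_false_positive_rate_nominal(self):
        # enrichment_factor = 1: pathways draw uniformly, so the fraction of
        # pathways flagged at p < 0.05 stays near or below the nominal rate
        from omicompare.enrichment import hypergeometric_enrichment

        de = self.universe[:30]
        n_sig = n_tot = 0
        for seed in range(15):
            coll, _ = simulate_pathway_annotation(
                n_pathways=20, universe=self.universe, planted=set(), de_genes=de,
                enrichment_factor=1.0, seed=seed,
            )
            rec = hypergeometric_enrichment(de, coll, min_members=0)
            n_sig += int(rec["significant"].sum())
            n_tot += len(rec)
        rate = n_sig / n_tot
        # binomial slack: 3 SE above the nominal 0.05
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_tot)


class TestLiteratureCorpus:
    genes = [f"gene{i}" for i in range(15)]

    def test_explicit_link_puts_keyword_in_document(self):
        corpus, truth = simulate_literature_corpus(
            self.genes, ["autism"], {("gene2", "autism"): "explicit"}, seed=1
        )
        assert "autism" in corpus.documents["gene2"].split()
        assert truth.keyword_links == {("gene2", "autism"): "explicit"}

    def test_implicit_link_shares_context_but_not_keyword(self):
        corpus, _ = simulate_literature_corpus(
            self.genes, ["autism"], {("gene2", "autism"): "implicit"}, seed=2
        )
        tokens = set(corpus.documents["gene2"].split())
        assert "autism" not in tokens
        assert any(t.startswith("autismctx") for t in tokens)

    def test_unlinked_genes_share_no_keyword_vocabulary(self):
        corpus, _ = simulate_literature_corpus(
            self.genes, ["autism"], {("gene2", "autism"): "explicit"}, seed=3
        )
        unlinked = set(corpus.documents["gene5"].split())
        assert not any(t == "autism" or t.startswith("autismctx") for t in unlinked)

    def test_unknown_link_references_rejected(self):
        with pytest.raises(ValueError, match="unknown gene"):
            simulate_literature_corpus(self.genes, ["autism"], {("nope", "autism"): "explicit"})
        with pytest.raises(ValueError, match="unknown keyword"):
            simulate_literature_corpus(self.genes, ["autism"], {("gene1", "adhd"): "explicit"})

    def test_determinism(self):
        links = {("gene1", "autism"): "explicit"}
        c1, _ = simulate_literature_corpus(self.genes, ["autism"], links, seed=4)
        c2, _ = simulate_literature_corpus(self.genes, ["autism"], links, seed=4)
        assert c1.documents == c2.documents


class TestTruthRecovery:
    """End-to-end: generators feed the analysis stages and truth comes back."""

    def test_downstream_de_calling_recovers_planted_genes(self):
        from omicompare.microarray_de import ZRatioModel

        control, case, truth = simulate_expression_study(
            n_genes=1000, n_replicates=3, de_fraction=0.05, effect=3.0, seed=11
        )
        res = ZRatioModel(IntensityMatrix.concat([control, case])).fit()
        planted_up = {g for g, (p, _) in truth.de_genes.items() if p > 0}
        planted_down = {g for g, (p, _) in truth.de_genes.items() if p < 0}
        planted = planted_up | planted_down
        tp = len(set(res.up) & planted_up) + len(set(res.down) & planted_down)
        fp = len((set(res.up) | set(res.down)) - planted)
        sensitivity = tp / len(planted)
        specificity = 1 - fp / (1000 - len(planted))
        assert sensitivity > 0.9
        assert specificity > 0.9

    def test_sensitivity_monotone_in_effect_up_to_saturation(self):
        from omicompare.microarray_de import ZRatioModel

        pooled = []
        for effect in (0.5, 1.0, 2.0, 3.0):
            tp = total = 0
            for seed in range(3):
                control, case, truth = simulate_expression_study(
                    n_genes=500, de_fraction=0.05, effect=effect, seed=seed
                )
                res = ZRatioModel(IntensityMatrix.concat([control, case])).fit()
                pu = {g for g, (p, _) in truth.de_genes.items() if p > 0}
                pd_ = {g for g, (p, _) in truth.de_genes.items() if p < 0}
                tp += len(set(res.up) & pu) + len(set(res.down) & pd_)
                total += len(truth.de_genes)
            pooled.append(tp / total)
        # non-decreasing up to a small saturation tolerance: at very large
        # planted effects the case-column SD inflates and sensitivity plateaus
        assert all(b >= a - 0.02 for a, b in zip(pooled, pooled[1:]))

    def test_itraq_caller_recovers_planted_proteins(self):
        from omicompare.itraq import ReporterQuant

        table, truth = simulate_itraq_experiment(
            n_proteins=200, control_cv=0.05, diff_fraction=0.1, fold=1.5, seed=21
        )
        res = ReporterQuant(table).fit()
        planted = set(truth.diff_proteins)
        assert len(set(res.up) & planted) / len(planted) >= 0.95
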