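"""Quasibinomial inference: fit, BH, conservative averaging, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poeseq import (
    SimConfig,
    bh_adjust,
    classify_gene,
    conservative_proportion,
    fit_gene,
    make_design,
    run_poe,
    simulate_allelic_counts,
)
from poeseq.counts import gene_level_counts, substitute_paternal_zero
from poeseq.poe import effects_design_matrix

from _irls_oracle import irls_quasibinomial


@pytest.fixture(scope="module")
def rep_design():
    d = make_design(SimConfig(seed=0))
    return d[d["status"] == "reproductive"].reset_index(drop=True)


class TestFitGene:
    def test_balanced_counts_give_zero_intercept_p_one(self):
        d = pd.DataFrame({"x": [1] * 4})
        fit = fit_gene([10, 20, 30, 40], [10, 20, 30, 40], d, factors=())
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-10)
        assert fit.p_intercept == 1.0

    def test_intercept_only_equals_pooled_logit(self):
        m = np.array([90, 85, 92, 88])
        p = np.array([10, 15, 8, 12])
        d = pd.DataFrame({"x": [1] * 4})
        fit = fit_gene(m, p, d, factors=())
        assert fit.beta[0] == pytest.approx(float(np.log(m.sum() / p.sum())), abs=1e-8)

    def test_matches_independent_irls(self, rep_design, rng):
        X, _ = effects_design_matrix(rep_design, ("direction", "family"))
        for _ in range(20):
            n = rng.integers(20, 200, size=len(rep_design))
            y = rng.binomial(n, rng.uniform(0.2, 0.8))
            fit = fit_gene(y, n - y, rep_design, ("direction", "family"))
            beta, se, disp, p = irls_quasibinomial(y, n, X)
            np.testing.assert_allclose(fit.beta, beta, atol=1e-8)
            assert fit.dispersion == pytest.approx(disp, abs=1e-8)
            assert fit.p_intercept == pytest.approx(p[0], abs=1e-6)

    def test_saturated_design_rejected(self):
        d = pd.DataFrame({"f": ["a", "b"]})
        with pytest.raises(ValueError, match="saturated"):
            fit_gene([5, 6], [5, 6], d, factors=("f",))

    def test_too_few_positive_libraries_rejected(self):
        d = pd.DataFrame({"x": [1] * 4})
        with pytest.raises(ValueError, match="positive totals"):
            fit_gene([5, 0, 0, 0], [5, 0, 0, 0], d, factors=())

    def test_large_count_agreement_with_binomial_z(self, rep_design, rng):
        """At dispersion ~1 and large counts, the t test approximates the
        standard binomial GLM z test."""
        import statsmodels.api as sm

        n = np.full(len(rep_design), 5000)
        y = rng.binomial(n, 0.52)
        fit = fit_gene(y, n - y, rep_design, ("direction",))
        X, _ = effects_design_matrix(rep_design, ("direction",))
        res = sm.GLM(np.column_stack([y, n - y]), X,
                     family=sm.families.Binomial()).fit()
        assert fit.p_intercept == pytest.approx(float(res.pvalues[0]), rel=0.3)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_q_at_least_p_and_bounded(self, pvals):
        q = bh_adjust(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        assert np.all(q <= 1.0)


class TestConservativeProportion:
    def _table(self, design, props, depth=100):
        rows = []
        for lib, prop in zip(design["library_id"], props):
            m = int(round(depth * prop))
            rows.append({"library_id": lib, "maternal": m, "paternal": depth - m})
        return pd.DataFrame(rows)

    def test_constant_proportion_preserved(self, rep_design):
        tab = self._table(rep_design, [0.7] * len(rep_design))
        grand, per_colony, per_direction = conservative_proportion(tab, rep_design)
        assert grand == pytest.approx(0.7)
        assert all(v == pytest.approx(0.7) for v in per_colony.values())

    def test_equal_colony_weighting(self, rep_design):
        colonies = sorted(rep_design["colony"].unique())
        props = [
            0.9 if c != colonies[-1] else 0.5
            for c in rep_design["colony"]
        ]
        grand, per_colony, _ = conservative_proportion(
            self._table(rep_design, props, depth=1000), rep_design
        )
        assert grand == pytest.approx(0.8, abs=1e-3)

    def test_unbalanced_matches_nested_oracle(self, rep_design, rng):
        tab = self._table(rep_design, rng.uniform(0.2, 0.8, len(rep_design)))
        # drop a third of the libraries to unbalance the nesting
        tab = tab.sample(frac=0.67, random_state=5).reset_index(drop=True)
        grand, _, _ = conservative_proportion(tab, rep_design)
        meta = rep_design.set_index("library_id")
        d = tab.join(meta, on="library_id")
        d["prop"] = d["maternal"] / (d["maternal"] + d["paternal"])
        # independent nested group-by average
        oracle = (
            d.groupby(["colony", "worker_type", "tissue"])["prop"].mean()
            .groupby(["colony", "worker_type"]).mean()
            .groupby("colony").mean().mean()
        )
        assert grand == pytest.approx(float(oracle), abs=1e-12)
        assert grand != pytest.approx(float(d["prop"].mean()), abs=1e-6)

    def test_empty_colony_raises(self, rep_design):
        one_colony = rep_design["colony"].iloc[0]
        tab = self._table(rep_design, [0.6] * len(rep_design))
        tab = tab[
            ~tab["library_id"].isin(
                rep_design.loc[rep_design["colony"] == one_colony, "library_id"]
            )
        ]
        with pytest.raises(ValueError, match="no allelic data"):
            conservative_proportion(tab, rep_design)


class TestClassifyGene:
    COLONIES_HI = {"A-initial": 0.7, "A-reciprocal": 0.65, "B-initial": 0.6,
                   "B-reciprocal": 0.62}
    DIRS_HI = {"initial": 0.65, "reciprocal": 0.64}

    def test_significant_high_proportion_is_maternal(self):
        label = classify_gene(0.04, 0.65, self.COLONIES_HI, self.DIRS_HI)
        assert label == "MATERNAL"

    def test_proportion_gate_blocks_weak_bias(self):
        label = classify_gene(0.04, 0.55, self.COLONIES_HI, self.DIRS_HI)
        assert label == "BIALLELIC"

    def test_nonsignificant_is_biallelic(self):
        label = classify_gene(0.2, 0.9, self.COLONIES_HI, self.DIRS_HI)
        assert label == "BIALLELIC"

    def test_colony_inconsistency_blocks_parent_call(self):
        colonies = dict(self.COLONIES_HI, **{"B-reciprocal": 0.45})
        label = classify_gene(0.01, 0.65, colonies, self.DIRS_HI)
        assert label == "BIALLELIC"

    def test_direction_flip_is_lineage_never_parent(self):
        colonies = {"A-initial": 0.8, "B-initial": 0.8,
                    "A-reciprocal": 0.2, "B-reciprocal": 0.2}
        dirs = {"initial": 0.8, "reciprocal": 0.2}
        label = classify_gene(0.01, 0.5, colonies, dirs)
        assert label == "LINEAGE_A"
        dirs_b = {"initial": 0.2, "reciprocal": 0.8}
        assert classify_gene(0.01, 0.5, colonies, dirs_b) == "LINEAGE_B"

    def test_paternal_mirror(self):
        colonies = {k: 1 - v for k, v in self.COLONIES_HI.items()}
        dirs = {k: 1 - v for k, v in self.DIRS_HI.items()}
        assert classify_gene(0.04, 0.35, colonies, dirs) == "PATERNAL"


@pytest.fixture(scope="module")
def experiment():
    cfg = SimConfig(n_genes=40, seed=17)
    design = make_design(cfg)
    snp_table, truth = simulate_allelic_counts(cfg, design)
    gene_table = substitute_paternal_zero(gene_level_counts(snp_table))
    return cfg, design, gene_table, truth


class TestRunPoe:
    def test_recovered_labels_match_truth(self, experiment):
        cfg, design, gene_table, truth = experiment
        report = run_poe(gene_table, design, status="reproductive")
        merged = report.merge(truth, on="gene_id")
        parents = merged[merged["true_class"].isin(["MATERNAL", "PATERNAL"])]
        assert (parents["label"] == parents["true_class"]).mean() >= 0.75
        lineage = merged[merged["true_class"].str.startswith("LINEAGE")]
        assert not lineage["label"].isin(["MATERNAL", "PATERNAL"]).any()

    def test_label_symmetry_under_column_swap(self, experiment):
        cfg, design, gene_table, truth = experiment
        swapped = gene_table.rename(
            columns={"maternal": "paternal", "paternal": "maternal"}
        )
        fwd = run_poe(gene_table, design, status="sterile").set_index("gene_id")
        rev = run_poe(swapped, design, status="sterile").set_index("gene_id")
        flip = {"MATERNAL": "PATERNAL", "PATERNAL": "MATERNAL",
                "LINEAGE_A": "LINEAGE_B", "LINEAGE_B": "LINEAGE_A",
                "BIALLELIC": "BIALLELIC"}
        for gene in fwd.index:
            assert rev.loc[gene, "label"] == flip[fwd.loc[gene, "label"]]
            assert rev.loc[gene, "q"] == pytest.approx(fwd.loc[gene, "q"], abs=1e-6)

    def test_joint_status_fit_runs(self, experiment):
        cfg, design, gene_table, truth = experiment
        report = run_poe(gene_table, design, status="both")
        assert len(report) > 0
        assert {"beta0", "q", "label"} <= set(report.columns)

    def test_invalid_status_rejected(self, experiment):
        cfg, design, gene_table, _ = experiment
        with pytest.raises(ValueError):
            run_poe(gene_table, design, status="all")

    def test_null_pvalues_roughly_uniform(self):
        """Intercept p-values under the null are approximately uniform."""
        cfg = SimConfig(
            n_genes=200, frac_maternal=0, frac_paternal=0, frac_lineage=0,
            mean_allelic_depth=50, overdispersion_rho=0.05, seed=23,
        )
        design = make_design(cfg)
        snp_table, _ = simulate_allelic_counts(cfg, design)
        gene_table = substitute_paternal_zero(gene_level_counts(snp_table))
        report = run_poe(gene_table, design, status="reproductive")
        frac = float((report["p"] < 0.05).mean())
        assert 0.0 <= frac <= 0.10
        assert not report["label"].isin(["MATERNAL", "PATERNAL"]).any() or \
            report["label"].isin(["MATERNAL", "PATERNAL"]).mean() <= 0.01
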