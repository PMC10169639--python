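import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_annotation, make_beta
from demkin.datamodel import ExpressionMatrix, PairedDesign
from demkin.integrate import (
    AntiCorrelationScreen,
    GeneRegionBeta,
    collapse_probes_by_iqr,
    fisher_z_p,
    gene_region_beta,
    paired_deg,
)
from oracles import spearman_oracle


def _design(n):
    return PairedDesign(
        patients=tuple(f"P{i}" for i in range(n)),
        t1_samples=tuple(f"t1_{i}" for i in range(n)),
        t0_samples=tuple(f"t0_{i}" for i in range(n)),
    )


def _expr(values, probes, samples):
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples))


class TestProbeCollapse:
    def test_keeps_highest_iqr_probe(self):
        expr = _expr(
            [[1.0, 5.0, 9.0], [4.0, 5.0, 6.0]], ["probeA", "probeB"], ["s1", "s2", "s3"]
        )
        out = collapse_probes_by_iqr(expr, {"probeA": "G1", "probeB": "G1"})
        np.testing.assert_allclose(out.data.loc["G1"], [1.0, 5.0, 9.0])

    def test_single_probe_gene_passes_through(self):
        expr = _expr([[2.0, 3.0]], ["probeA"], ["s1", "s2"])
        out = collapse_probes_by_iqr(expr, {"probeA": "G1"})
        np.testing.assert_allclose(out.data.loc["G1"], [2.0, 3.0])

    def test_iqr_tie_breaks_to_smallest_probe_id(self):
        expr = _expr(
            [[1.0, 2.0], [11.0, 12.0]], ["probeB", "probeA"], ["s1", "s2"]
        )
        out = collapse_probes_by_iqr(expr, {"probeA": "G1", "probeB": "G1"})
        # equal IQR (both 0.5): probeA wins lexicographically
        np.testing.assert_allclose(out.data.loc["G1"], [11.0, 12.0])

    def test_matches_brute_force_argmax(self):
        rng = np.random.default_rng(3)
        probes = [f"pr{i:03d}" for i in range(60)]
        genes = {p: f"G{int(rng.integers(0, 15)):02d}" for p in probes}
        vals = rng.normal(size=(60, 7))
        out = collapse_probes_by_iqr(_expr(vals, probes, [f"s{j}" for j in range(7)]), genes)
        iqr = {p: np.percentile(vals[i], 75) - np.percentile(vals[i], 25)
               for i, p in enumerate(probes)}
        for gene in set(genes.values()):
            members = sorted(p for p in probes if genes[p] == gene)
            best = min(members, key=lambda p: (-iqr[p], p))
            np.testing.assert_allclose(out.data.loc[gene], vals[probes.index(best)])

    def test_unmapped_probes_dropped(self):
        expr = _expr([[1.0, 2.0], [3.0, 4.0]], ["pa", "pb"], ["s1", "s2"])
        out = collapse_probes_by_iqr(expr, {"pa": "G1"})
        assert list(out.data.index) == ["G1"]

    def test_empty_mapping_rejected(self):
        expr = _expr([[1.0]], ["pa"], ["s1"])
        with pytest.raises(ValueError):
            collapse_probes_by_iqr(expr, {})


class TestPairedDEG:
    def test_identical_timepoints_give_zero_fold_change(self):
        design = _design(4)
        base = np.random.default_rng(0).normal(7, 1, size=(30, 4))
        expr = _expr(
            np.hstack([base, base]),
            [f"G{i}" for i in range(30)],
            list(design.t1_samples) + list(design.t0_samples),
        )
        deg = paired_deg(expr, design)
        assert np.allclose(deg.log2fc.to_numpy(), 0.0)
        assert deg.significant_genes() == set()

    def test_planted_induced_gene_is_significant(self):
        rng = np.random.default_rng(1)
        n = 23
        design = _design(n)
        base = rng.normal(7, 1, size=(200, n))
        fc = rng.normal(0, 0.1, size=(200, n))
        fc[0] += 1.0  # induced gene: +1 log2 in all patients
        expr = _expr(
            np.hstack([base + fc, base]),
            [f"G{i}" for i in range(200)],
            list(design.t1_samples) + list(design.t0_samples),
        )
        deg = paired_deg(expr, design)
        assert "G0" in deg.significant_genes()
        assert deg.table.loc["G0", "mean_log2fc"] == pytest.approx(1.0, abs=0.1)

    def test_null_pvalues_pass_ks_uniformity(self):
        rng = np.random.default_rng(2)
        n = 10
        design = _design(n)
        base = rng.normal(7, 1, size=(2000, n))
        noise = rng.normal(0, 0.3, size=(2000, n))
        expr = _expr(
            np.hstack([base + noise, base]),
            [f"G{i}" for i in range(2000)],
            list(design.t1_samples) + list(design.t0_samples),
        )
        deg = paired_deg(expr, design)
        d = stats.kstest(deg.table["p"].to_numpy(), "uniform").statistic
        assert d < 0.05


class TestGeneRegionBeta:
    def _annot(self):
        return make_annotation(
            {
                "c1": {"nearest_gene": "G1",
                       "region_categories": frozenset({"TSS200"})},
                "c2": {"nearest_gene": "G1",
                       "region_categories": frozenset({"TSS1500"})},
                "c3": {"nearest_gene": "G2",
                       "region_categories": frozenset({"Body"})},
                "c4": {"nearest_gene": "G2",
                       "region_categories": frozenset({"5UTR", "1stExon"})},
            }
        )

    def test_promoter_mean(self):
        beta = make_beta([[0.8], [0.6], [0.4], [0.2]],
                         cpgs=["c1", "c2", "c3", "c4"], samples=["s"])
        rb = gene_region_beta(beta, self._annot())
        assert rb.promoter.loc["G1", "s"] == pytest.approx(0.7)

    def test_gene_without_region_is_absent_not_zero(self):
        beta = make_beta([[0.8], [0.6], [0.4], [0.2]],
                         cpgs=["c1", "c2", "c3", "c4"], samples=["s"])
        rb = gene_region_beta(beta, self._annot())
        assert np.isnan(rb.body.loc["G1", "s"])
        assert rb.n_cpgs.loc["G1", "body"] == 0

    def test_dual_category_cpg_counts_in_both_regions(self):
        beta = make_beta([[0.8], [0.6], [0.4], [0.2]],
                         cpgs=["c1", "c2", "c3", "c4"], samples=["s"])
        rb = gene_region_beta(beta, self._annot())
        # c4 is 5UTR (promoter) and 1stExon (body)
        assert rb.promoter.loc["G2", "s"] == pytest.approx(0.2)
        assert rb.body.loc["G2", "s"] == pytest.approx(0.3)

    def test_matches_brute_force_group_by(self):
        rng = np.random.default_rng(4)
        cpgs = [f"c{i}" for i in range(50)]
        cats = [frozenset({"TSS200"}), frozenset({"Body"}), frozenset({"intergenic"})]
        rows = {
            c: {
                "nearest_gene": f"G{int(rng.integers(0, 8))}",
                "region_categories": cats[int(rng.integers(0, 3))],
            }
            for c in cpgs
        }
        annot = make_annotation(rows)
        vals = rng.random((50, 3))
        beta = make_beta(vals, cpgs=cpgs, samples=["s0", "s1", "s2"])
        rb = gene_region_beta(beta, annot)
        for gene in rb.promoter.index:
            members = [i for i, c in enumerate(cpgs)
                       if rows[c]["nearest_gene"] == gene
                       and "TSS200" in rows[c]["region_categories"]]
            if members:
                np.testing.assert_allclose(
                    rb.promoter.loc[gene].to_numpy(), vals[members].mean(axis=0)
                )


class TestAntiCorrelationScreen:
    def _screen(self, x_rows, y_rows, n=None):
        """x_rows/y_rows: gene -> per-patient log2FC / promoter delta beta."""
        n = n or len(next(iter(x_rows.values())))
        design = _design(n)
        genes = sorted(x_rows)
        prom_t0 = pd.DataFrame(0.8, index=genes, columns=list(design.t0_samples))
        prom_t1 = pd.DataFrame(
            {s: [0.8 + y_rows[g][k] for g in genes]
             for k, s in enumerate(design.t1_samples)},
            index=genes,
        )
        promoter = pd.concat([prom_t1, prom_t0], axis=1)
        body = pd.DataFrame(np.nan, index=genes, columns=promoter.columns)
        rb = GeneRegionBeta(promoter=promoter, body=body,
                            n_cpgs=pd.DataFrame({"promoter": 1, "body": 0}, index=genes))
        fc = pd.DataFrame(
            {p: [x_rows[g][k] for g in genes] for k, p in enumerate(design.patients)},
            index=genes,
        )
        return AntiCorrelationScreen(rb, fc, design).fit()

    def test_perfect_anticorrelation_called(self):
        res = self._screen(
            {"G1": [1, 2, 3, 4, 5]}, {"G1": [-0.1, -0.2, -0.3, -0.4, -0.5]}
        )
        row = res.table.iloc[0]
        assert row["rho"] == pytest.approx(-1.0)
        assert row["p"] < 0.05
        assert bool(row["anti_correlated_call"])

    def test_positive_correlation_never_called(self):
        res = self._screen(
            {"G1": [1, 2, 3, 4, 5]}, {"G1": [0.1, 0.2, 0.3, 0.4, 0.5]}
        )
        row = res.table.iloc[0]
        assert row["rho"] == pytest.approx(1.0)
        assert not bool(row["anti_correlated_call"])

    def test_zero_variance_flagged_not_called(self):
        res = self._screen({"G1": [1, 1, 1, 1, 1]}, {"G1": [-0.1, -0.2, -0.3, -0.4, -0.5]})
        row = res.table.iloc[0]
        assert bool(row["undefined"])
        assert not bool(row["anti_correlated_call"])

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            self._screen({"G1": [1, 2, 3]}, {"G1": [-0.1, -0.2, -0.3]}, n=3)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=8).tolist()
        y = rng.normal(scale=0.1, size=8).tolist()
        base = self._screen({"G1": x}, {"G1": y}).table.iloc[0]
        warped = self._screen({"G1": [np.exp(v) for v in x]}, {"G1": y}).table.iloc[0]
        assert warped["rho"] == pytest.approx(base["rho"], abs=1e-12)
        assert warped["p"] == pytest.approx(base["p"], abs=1e-12)

    def test_spearman_matches_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            n = int(rng.integers(3, 11))
            x = rng.integers(0, 5, size=n).astype(float)  # heavy ties
            y = rng.integers(0, 5, size=n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            got = float(stats.spearmanr(x, y).statistic)
            assert got == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_null_calibration_of_call_rate(self):
        rng = np.random.default_rng(7)
        n_genes, n = 800, 10
        x_rows = {f"G{i}": rng.normal(size=n).tolist() for i in range(n_genes)}
        y_rows = {f"G{i}": rng.normal(scale=0.05, size=n).tolist() for i in range(n_genes)}
        res = self._screen(x_rows, y_rows)
        rate = res.table["anti_correlated_call"].mean()
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_genes)

    def test_fisher_z_alternatives(self):
        p_less = fisher_z_p(-0.8, 10, "less")
        p_greater = fisher_z_p(-0.8, 10, "greater")
        p_two = fisher_z_p(-0.8, 10, "two-sided")
        assert p_less < 0.05 < p_greater
        assert p_two == pytest.approx(2 * p_less, rel=1e-9)
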