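"""Library statistics: normalization, (partial) correlations, codon screens."""

import numpy as np
import pytest
from scipy import stats

import ribotai as rt

from conftest import make_gene


def make_record(vid, codons, abundance, od, folding=None):
    return rt.LibraryRecord(
        variant_id=vid,
        seq=rt.CodingSequence(id=vid, codons=tuple(codons)),
        protein_abundance=abundance,
        od=od,
        folding_energy=folding,
    )


class TestPerCellAbundance:
    def test_division_by_od(self):
        rec = make_record("v", ["AAA"], 100.0, 2.0)
        assert rt.per_cell_abundance(rec) == pytest.approx(50.0)

    def test_zero_abundance_allowed(self):
        rec = make_record("v", ["AAA"], 0.0, 1.7)
        assert rt.per_cell_abundance(rec) == 0.0

    def test_vector_matches_elementwise_loop(self, default_lib):
        values = [rt.per_cell_abundance(r) for r in default_lib[:10]]
        for rec, value in zip(default_lib[:10], values):
            assert value == pytest.approx(rec.protein_abundance / rec.od)

    def test_non_positive_od_rejected_at_construction(self):
        with pytest.raises(ValueError, match="OD"):
            make_record("v", ["AAA"], 1.0, 0.0)

    def test_homogeneity_scaling_abundance_scales_output(self, default_lib):
        rec = default_lib[0]
        scaled = rt.LibraryRecord(
            variant_id=rec.variant_id, seq=rec.seq,
            protein_abundance=rec.protein_abundance * 3.0, od=rec.od,
        )
        assert rt.per_cell_abundance(scaled) == pytest.approx(
            3.0 * rt.per_cell_abundance(rec)
        )


class TestCorrelate:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = rt.correlate(x, 2 * x + 1, "pearson")
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 1e-12

    def test_monotone_decreasing_spearman(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        res = rt.correlate(x, -np.exp(x), "spearman")
        assert res.r == pytest.approx(-1.0)

    def test_eight_point_textbook_formula(self):
        x = np.array([2.0, 4.0, 5.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0, 8.0, 7.0])
        # direct product-moment formula as the oracle
        r_oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        res = rt.correlate(x, y, "pearson")
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.n_obs == 8

    def test_constant_vector_flagged_undefined_not_raised(self):
        res = rt.correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.undefined and np.isnan(res.r)

    def test_affine_invariance_of_both_methods(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        for method in ("pearson", "spearman"):
            base = rt.correlate(x, y, method)
            shifted = rt.correlate(3.0 * x + 2.0, 0.5 * y - 7.0, method)
            assert shifted.r == pytest.approx(base.r, abs=1e-12)
            sym = rt.correlate(y, x, method)
            assert sym.r == pytest.approx(base.r, abs=1e-12)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            rt.correlate([1.0, 2.0], [1.0, 2.0])


class TestPartialCorrelate:
    def test_reduces_to_raw_when_control_uncorrelated(self):
        # with r_xz = r_yz = 0 exactly, the formula collapses to r_xy
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([2.0, -1.0, 1.5, -2.0, 1.0, -0.5])
        z = np.array([1.0, 1.0, -1.0, -1.0, 0.0, 0.0])
        y = y - y.mean()
        y = y - (y @ z) / (z @ z) * z  # orthogonalize y against z
        assert abs(rt.correlate(x, z).r) < 1e-12
        assert abs(rt.correlate(y, z).r) < 1e-12
        assert rt.partial_correlate(x, y, z).r == pytest.approx(
            rt.correlate(x, y).r, abs=1e-12
        )

    def test_degenerate_control_flagged_undefined(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        res = rt.partial_correlate(x, y, x)
        assert res.undefined

    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            x, y, z = rng.normal(size=(3, 50))
            res = rt.partial_correlate(x, y, z)
            # classical equivalence: correlate OLS residuals of x~z and y~z
            def residuals(v):
                beta = np.polyfit(z, v, 1)
                return v - np.polyval(beta, z)
            oracle = stats.pearsonr(residuals(x), residuals(y)).statistic
            assert res.r == pytest.approx(oracle, abs=1e-10)

    def test_matches_independent_partial_correlation_package(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        x, y, z = rng.normal(size=(3, 40))
        df = pd.DataFrame(dict(x=x, y=y, z=z))
        for method in ("pearson", "spearman"):
            expected = pingouin.partial_corr(df, x="x", y="y", covar="z", method=method)
            p_col = [c for c in expected.columns if c.lower().startswith("p")][0]
            res = rt.partial_correlate(x, y, z, method)
            assert res.r == pytest.approx(float(expected["r"].iloc[0]), abs=1e-9)
            assert res.p_value == pytest.approx(float(expected[p_col].iloc[0]), abs=1e-9)


class TestAnalyzeBottleneckVsExpression:
    def test_recovers_planted_signs(self, default_lib, weights):
        analysis = rt.analyze_bottleneck_vs_expression(default_lib, weights)
        assert analysis.get("relative_location", "pearson").r < 0
        assert analysis.get("relative_location", "spearman").r < 0
        assert analysis.get("relative_strength", "pearson", subset="band").r > 0

    def test_recovered_r_near_analytic_target(self, default_lib, weights):
        # compare the pipeline's Pearson r on log per-cell abundance with the
        # analytic value implied by the generator's realized design and noise
        model = rt.EffectModel()
        analysis = rt.analyze_bottleneck_vs_expression(
            default_lib, weights, log_abundance=True
        )
        t = analysis.variant_table
        loc = t["relative_location"].to_numpy()
        strength = t["relative_strength"].to_numpy()
        folding = t["folding_energy"].to_numpy()
        proximal = loc <= model.proximal_cutoff
        mu = (
            model.beta_location * loc
            + model.beta_strength_proximal * (strength - model.strength_reference) * proximal
            + model.beta_folding * folding
        )
        target = (
            np.cov(loc, mu)[0, 1]
            / loc.std(ddof=1)
            / np.sqrt(mu.var(ddof=1) + model.noise_sd_abundance**2)
        )
        observed = analysis.get("relative_location", "pearson").r
        assert observed == pytest.approx(target, abs=0.15)

    def test_pure_folding_confound_has_null_partial_correlation(self, weights):
        # abundance is a deterministic function of folding energy only
        rng = np.random.default_rng(3)
        spec = rt.LibrarySpec(n_variants=60, seed=3)
        variants = rt.generate_library(spec, weights)
        folding = rng.normal(-8, 2, size=60)
        records = [
            rt.LibraryRecord(
                variant_id=v.id, seq=v,
                protein_abundance=float(np.exp(0.3 * f + 5.0)),
                od=1.0, folding_energy=float(f),
            )
            for v, f in zip(variants, folding)
        ]
        analysis = rt.analyze_bottleneck_vs_expression(records, weights)
        partial = analysis.get(
            "relative_location", "pearson", controlled="folding_energy"
        )
        assert abs(partial.r) < 0.12

    def test_duplicated_library_preserves_correlations(self, default_lib, weights):
        once = rt.analyze_bottleneck_vs_expression(default_lib, weights)
        twice = rt.analyze_bottleneck_vs_expression(
            list(default_lib) + list(default_lib), weights
        )
        assert twice.get("relative_location", "pearson").r == pytest.approx(
            once.get("relative_location", "pearson").r, abs=1e-12
        )

    def test_narrow_band_skipped_with_warning(self, default_lib, weights):
        with pytest.warns(UserWarning, match="skipped"):
            analysis = rt.analyze_bottleneck_vs_expression(
                default_lib, weights, location_band=(0.9999, 1.0)
            )
        assert not (analysis.correlations["subset"] == "band").any()


class TestCodonFitnessScan:
    def test_constant_codon_classified_constant(self, default_lib):
        report = rt.codon_fitness_scan(default_lib)
        # single-codon amino acids never vary in a synonymous library
        assert report.classes["AUG"] == "constant"
        assert report.classes["UGG"] == "constant"

    def test_planted_penalty_codons_flagged_negative(self, default_lib):
        report = rt.codon_fitness_scan(default_lib)
        assert report.classes["UCA"] == "negative"
        assert report.classes["CAU"] == "negative"
        assert report.alpha_corrected == pytest.approx(0.05 / 61)

    def test_counts_partition_gene_length(self, default_lib):
        counts = rt.codon_count_matrix(default_lib)
        lengths = np.array([r.seq.length_l for r in default_lib])
        assert (counts.sum(axis=1).to_numpy() == lengths).all()

    def test_shuffled_od_rarely_significant(self, default_lib):
        # permutation null: with OD decoupled from sequence, ~nothing should
        # pass the Bonferroni threshold
        rng = np.random.default_rng(17)
        ods = np.array([r.od for r in default_lib])
        n_tests = n_significant = 0
        for _ in range(20):
            perm = rng.permutation(ods)
            shuffled = [
                rt.LibraryRecord(
                    variant_id=r.variant_id, seq=r.seq,
                    protein_abundance=r.protein_abundance, od=float(o),
                )
                for r, o in zip(default_lib, perm)
            ]
            report = rt.codon_fitness_scan(shuffled)
            tested = report.table[report.table["class"] != "constant"]
            n_tests += len(tested)
            n_significant += tested["class"].isin(["negative", "positive"]).sum()
        assert n_significant / n_tests < 0.05


class TestRankFitnessCodons:
    def test_planted_penalties_rank_first_and_second(self, default_lib):
        report = rt.rank_fitness_codons(default_lib)
        assert set(report.ranked_codons[:2]) == {"UCA", "CAU"}
        # single-codon amino acids are excluded before step 1
        assert "AUG" in report.excluded_constant

    def test_passenger_codon_collapses_under_control(self, weights):
        # passenger: perfectly tracks a planted penalty codon, so controlling
        # for the penalty explains its OD association away
        rng = np.random.default_rng(23)
        spec = rt.LibrarySpec(n_variants=120, seed=23)
        variants = rt.generate_library(spec, weights)
        records = []
        for v in variants:
            uca = v.codons.count("UCA")
            cau = v.codons.count("CAU")
            od = 1.5 - 0.06 * uca - 0.05 * cau + rng.normal(0, 0.05)
            records.append(
                rt.LibraryRecord(
                    variant_id=v.id, seq=v, protein_abundance=1.0, od=float(max(od, 0.05)),
                )
            )
        report = rt.rank_fitness_codons(records)
        assert set(report.ranked_codons[:2]) == {"UCA", "CAU"}
        table = report.table.set_index("codon")
        # AGC tracks CAU only through the His synonym split; GCU-family
        # passengers (any codon anti-correlated with a penalty codon through
        # the synonymous draw) must sit far below the planted pair
        third = table["min_abs_partial_r"].iloc[2]
        assert table["min_abs_partial_r"].iloc[1] > 3 * third

    def test_partial_matrix_matches_residual_oracle(self, default_lib):
        report = rt.rank_fitness_codons(default_lib)
        counts = rt.codon_count_matrix(default_lib)
        od = np.array([r.od for r in default_lib], dtype=float)
        kept = list(report.partial_matrix.index)
        rng = np.random.default_rng(1)
        pairs = [(kept[i], kept[j]) for i, j in
                 zip(rng.integers(0, len(kept), 5), rng.integers(0, len(kept), 5)) if i != j]
        for ci, cj in pairs:
            x = counts[ci].to_numpy(dtype=float)
            z = counts[cj].to_numpy(dtype=float)
            def residuals(v):
                beta = np.polyfit(z, v, 1)
                return v - np.polyval(beta, z)
            oracle = stats.pearsonr(residuals(x), residuals(od)).statistic
            assert report.partial_matrix.loc[ci, cj] == pytest.approx(oracle, abs=1e-10)

    def test_single_negative_codon_falls_back_to_raw_r(self):
        # 6 variants, one varying codon (GCU count) anti-correlated with OD
        rng = np.random.default_rng(9)
        records = []
        for i in range(6):
            codons = ["GCU"] * (i + 1) + ["AAA"] * (8 - i)
            records.append(
                rt.LibraryRecord(
                    variant_id=f"v{i}",
                    seq=rt.CodingSequence(id=f"v{i}", codons=tuple(codons)),
                    protein_abundance=1.0,
                    od=float(2.0 - 0.1 * i + 1e-3 * rng.normal()),
                )
            )
        report = rt.rank_fitness_codons(records)
        # GCU and AAA counts are perfectly anti-correlated; AAA's raw r is
        # positive so only GCU survives step 1 and keeps |raw r| as its score
        assert report.ranked_codons == ["GCU"]
        row = report.table.iloc[0]
        assert row["min_abs_partial_r"] == pytest.approx(abs(row["raw_r"]))
        assert row["controlling_codon"] is None
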