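import numpy as np
import pandas as pd
import pytest

from titrabench.annotation import generate_annotation
from titrabench.design import canonical_design
from titrabench.foldchange import (
    FoldChangeTable,
    absolute_fold_change,
    average_abs_fc,
    build_fold_change_table,
    fc_compression,
    fc_enhancement,
    fc_titration_fidelity,
)
from titrabench.matrix import ExpressionMatrix
from titrabench.preprocess import collapse_replicates
from titrabench.simulate import (
    PlatformSpec,
    generate_expression,
    generate_platform_probes,
    make_truth,
)

CONTRASTS = ("AG1BM4", "AG1BM16", "AG1BM64", "BMO")
FRACTIONS = {"AG1BM4": 0.75, "AG1BM16": 0.9375, "AG1BM64": 0.984375, "BMO": 1.0}


def _table(ratios: dict) -> FoldChangeTable:
    return FoldChangeTable(
        platform="p", contrasts=CONTRASTS,
        ratio=pd.DataFrame(ratios, columns=list(CONTRASTS)),
        contrast_fraction=FRACTIONS,
    )


class TestAbsoluteFoldChange:
    @pytest.mark.parametrize("ratio, expected", [(2, 2), (0.25, 4), (1, 1), (1.5, 1.5)])
    def test_values(self, ratio, expected):
        assert absolute_fold_change(ratio) == expected

    def test_reciprocal_symmetry(self):
        for r in (0.1, 0.5, 2.0, 7.3):
            assert absolute_fold_change(r) == pytest.approx(absolute_fold_change(1 / r))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            absolute_fold_change(0.0)


class TestAverageAbsFc:
    def test_all_ones(self):
        t = _table({c: [1.0, 1.0] for c in CONTRASTS})
        per, overall = average_abs_fc(t)
        assert overall == 1.0 and (per == 1.0).all()

    def test_single_gene_is_identity(self):
        t = _table({c: [v] for c, v in zip(CONTRASTS, [1.5, 2.0, 0.25, 3.0])})
        per, overall = average_abs_fc(t)
        assert list(per) == [1.5, 2.0, 4.0, 3.0]
        assert overall == pytest.approx(np.mean([1.5, 2.0, 4.0, 3.0]))

    def test_five_gene_toy_matches_mean_oracle(self):
        rng = np.random.default_rng(0)
        ratios = {c: rng.lognormal(size=5) for c in CONTRASTS}
        t = _table(ratios)
        per, overall = average_abs_fc(t)
        expect_per = {
            c: np.mean([r if r >= 1 else 1 / r for r in ratios[c]]) for c in CONTRASTS
        }
        for c in CONTRASTS:
            assert per[c] == pytest.approx(expect_per[c])
        assert overall == pytest.approx(np.mean(list(expect_per.values())))

    def test_empty_subset_errors(self):
        t = _table({c: [1.0] for c in CONTRASTS})
        with pytest.raises(ValueError, match="subset"):
            average_abs_fc(t, gene_subset=["nope"])


class TestFcTitrationFidelity:
    def test_increasing_counts_and_constant_excluded(self):
        t = _table({
            "AG1BM4": [1.1, 2.0], "AG1BM16": [1.5, 2.0],
            "AG1BM64": [2.2, 2.0], "BMO": [3.0, 2.0],
        })
        corr, frac = fc_titration_fidelity(t)
        assert corr.iloc[0] > 0.5
        assert np.isnan(corr.iloc[1])
        assert frac == 1.0  # constant gene excluded from denominator

    def test_anticorrelated_gene_does_not_count(self):
        t = _table({
            "AG1BM4": [3.0], "AG1BM16": [2.2], "AG1BM64": [1.5], "BMO": [1.1],
        })
        _, frac = fc_titration_fidelity(t)
        assert frac == 0.0  # one-sided rule: r must exceed +0.5

    def test_matches_brute_force_on_simulation(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        ratios = {c: rng.lognormal(0.3, 0.4, size=40) for c in CONTRASTS}
        t = _table(ratios)
        corr, frac = fc_titration_fidelity(t)
        x = [FRACTIONS[c] for c in CONTRASTS]
        abs_fc = np.array(
            [[r if r >= 1 else 1 / r for r in ratios[c]] for c in CONTRASTS]
        ).T
        expected = [stats.pearsonr(x, row).statistic for row in abs_fc]
        assert np.allclose(corr.to_numpy(), expected)
        assert frac == pytest.approx(np.mean(np.array(expected) > 0.5))


class TestFcEnhancement:
    def test_equal_values(self):
        assert fc_enhancement(5.0, 5.0) == 0.0

    def test_simple_arithmetic(self):
        assert fc_enhancement(5.0, 6.0) == pytest.approx(20.0)

    def test_worked_example_rounds_to_64(self):
        assert round(fc_enhancement(5.42, 8.88)) == 64

    def test_nonpositive_baseline(self):
        with pytest.raises(ValueError):
            fc_enhancement(0.0, 1.0)


class TestFcCompression:
    def test_identity_gives_zero(self):
        x = np.linspace(-3, 3, 20)
        fit = fc_compression(x, x)
        assert fit["slope"] == pytest.approx(1.0)
        assert abs(fit["compression_percent"]) < 1e-9
        assert fit["r_squared"] == pytest.approx(1.0)

    def test_half_slope_gives_fifty_percent(self):
        x = np.linspace(-3, 3, 20)
        fit = fc_compression(x, 0.5 * x)
        assert fit["compression_percent"] == pytest.approx(50.0)

    def test_recovers_planted_exponent(self):
        """Platform with power-law exponent c on abundance shows log2
        ratios scaled by c, so the fit recovers c as the slope."""
        ann = generate_annotation(400, seed=41)
        specs = [PlatformSpec("ref"), PlatformSpec("cmp")]
        design = canonical_design({"ref": 2, "cmp": 2})
        truth = make_truth(
            ann, specs, seed=41, noise_gene_fraction=0.0,
            compression={"ref": 1.0, "cmp": 0.6},
            noise_scale={"ref": 0.05, "cmp": 0.05},
            background={"ref": 0.0, "cmp": 0.0},
        )
        probes = {s.name: generate_platform_probes(ann, s, seed=41) for s in specs}
        mats = generate_expression(ann, probes, design, truth, specs)
        l2 = {}
        for name in ("ref", "cmp"):
            coll = collapse_replicates(mats[name].non_control(), design)
            l2[name] = np.log2(coll.data["BMO"] / coll.data["AGO"])
        fit = fc_compression(l2["ref"].to_numpy(), l2["cmp"].to_numpy())
        assert fit["slope"] == pytest.approx(0.6, abs=0.05)

    def test_guards(self):
        with pytest.raises(ValueError, match="3 finite"):
            fc_compression([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero variance"):
            fc_compression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBuildFoldChangeTable:
    def _collapsed(self, design, values):
        df = pd.DataFrame(values, columns=list(design.samples))
        df.index = [f"g{i}" for i in range(len(df))]
        return ExpressionMatrix(data=df, kind="cpm", platform="p")

    def test_flat_gene_has_unit_ratios(self, design):
        m = self._collapsed(design, np.full((3, 5), 4.0))
        t = build_fold_change_table(m, design)
        assert (t.ratio.to_numpy() == 1.0).all()
        assert (t.abs_fc.to_numpy() == 1.0).all()

    def test_hand_computed_ratios(self, design):
        m = self._collapsed(design, [[2.0, 4.0, 1.0, 8.0, 6.0]])
        t = build_fold_change_table(m, design)
        assert list(t.ratio.loc["g0"]) == [2.0, 0.5, 4.0, 3.0]
        assert list(t.abs_fc.loc["g0"]) == [2.0, 2.0, 4.0, 3.0]
        assert np.allclose(t.log2_ratio.loc["g0"], np.log2([2.0, 0.5, 4.0, 3.0]))

    def test_detected_only_filters(self, design):
        m = self._collapsed(design, np.full((3, 5), 2.0))
        det = pd.Series([True, False, True], index=m.data.index)
        t = build_fold_change_table(m, design, detected=det)
        assert set(t.ratio.index) == {"g0", "g2"}
        t_all = build_fold_change_table(
            m, design, detected=pd.Series(True, index=m.data.index)
        )
        assert len(t_all.ratio) == 3

    def test_missing_reference_errors(self, design):
        df = pd.DataFrame({"BMO": [1.0]}, index=["g0"])
        m = ExpressionMatrix(data=df, kind="cpm")
        with pytest.raises(ValueError, match="reference sample"):
            build_fold_change_table(m, design)


class TestPatternRestrictionDirection:
    def test_clean_features_show_larger_fold_change(self, design):
        """Features mixing isoforms dilute fold-change toward 1; restricting
        summaries to clean (single-pattern) features raises the overall
        average absolute fold-change."""
        from titrabench.preprocess import summarize_to_level

        rng = np.random.default_rng(9)
        n_genes = 30
        rows, index, grouping_all, grouping_clean = {}, [], {}, {}
        fracs = [design.bmo_fraction[s] for s in design.samples]
        for g in range(n_genes):
            ea, eb = rng.lognormal(3, 1), rng.lognormal(3, 1)
            # one clean feature, two isoform-diluted ones (the majority,
            # as off-pattern probes typically are)
            for kind, dilute in (("clean", 0.0), ("dirty1", 0.7), ("dirty2", 0.8)):
                fid = f"g{g}_{kind}"
                index.append(fid)
                grouping_all[fid] = f"g{g}"
                if kind == "clean":
                    grouping_clean[fid] = f"g{g}"
                vals = []
                for f in fracs:
                    ab = f * eb + (1 - f) * ea
                    # dirty features carry a constant off-target component
                    vals.append((1 - dilute) * ab + dilute * (ea + eb) / 2)
                rows[fid] = vals
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(design.samples))
        m = ExpressionMatrix(data=df, kind="signal", platform="p")
        overalls = {}
        for name, grouping in (("all", grouping_all), ("clean", grouping_clean)):
            summarized = summarize_to_level(m, pd.Series(grouping))
            linear = summarized.with_data(np.exp2(summarized.data) - 1, kind="cpm")
            table = build_fold_change_table(linear, design)
            _, overalls[name] = average_abs_fc(table)
        assert overalls["clean"] > overalls["all"]
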