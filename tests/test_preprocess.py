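import numpy as np
import pandas as pd
import pytest

from screenbias.datamodel import CountMatrix, GeneSets, GuideMap, ScreenMatrix
from screenbias.preprocess import (
    QCThresholds,
    collapse_to_genes,
    compute_lfc,
    compute_replicate_lfc,
    filter_guides,
    filter_replicates,
    scale_profiles,
)


def _guidemap(rows):
    df = pd.DataFrame(rows)
    return GuideMap(df.set_index("guide_id"))


class TestGuideFilter:
    @pytest.mark.parametrize(
        "flag",
        [
            "multi_align_same_gene",
            "multi_align_multi_gene",
            "no_alignment",
            "intergenic_only",
            "sole_passing_guide",
        ],
    )
    def test_each_disqualifying_flag_removes_the_guide(self, flag):
        gm = _guidemap(
            [
                {"guide_id": "bad", "gene": "A", "chromosome": "1", "position": 1,
                 "qc_flags": frozenset({flag})},
                {"guide_id": "good", "gene": "A", "chromosome": "1", "position": 2,
                 "qc_flags": frozenset()},
            ]
        )
        filtered, report = filter_guides(gm)
        assert list(filtered.guides) == ["good"]
        assert report.removed_guides["guide_id"].tolist() == ["bad"]
        assert flag in report.removed_guides["reasons"].iloc[0]

    def test_empty_surviving_set_is_a_hard_error(self):
        gm = _guidemap(
            [{"guide_id": "g", "gene": "A", "chromosome": "1", "position": 1,
              "qc_flags": frozenset({"no_alignment"})}]
        )
        with pytest.raises(ValueError, match="no guides survive"):
            filter_guides(gm)


def _counts(values: dict, plasmids=("pDNA",), rep_model=None):
    df = pd.DataFrame(values)
    roles = {c: ("plasmid" if c in plasmids else "replicate") for c in df.columns}
    if rep_model is None:
        rep_model = {c: c.split("_")[0] for c in df.columns if roles[c] == "replicate"}
    return CountMatrix(df, roles, rep_model)


class TestComputeLfc:
    def test_matches_hand_evaluated_formula(self):
        # totals 1e6 in both samples; plasmid 100 reads, screen 25 reads
        counts = _counts(
            {
                "pDNA": [100.0, 1_000_000 - 100],
                "M1_r1": [25.0, 1_000_000 - 25],
            }
        )
        lfc = compute_lfc(counts)
        expected = np.log2(26 / 1_000_001) - np.log2(101 / 1_000_001)
        assert lfc.values.loc[0, "M1"] == pytest.approx(expected)
        assert expected == pytest.approx(-1.9577, abs=1e-3)

    def test_equal_normalized_counts_give_zero(self):
        counts = _counts({"pDNA": [50.0, 50.0], "M1_r1": [50.0, 50.0]})
        assert np.allclose(compute_lfc(counts).values.to_numpy(), 0.0)

    def test_replicates_are_averaged_per_model(self):
        # engineer two replicates whose guide LFCs are exactly -1 and -3
        counts = _counts(
            {
                "pDNA": [4.0, 1.0],
                "M1_r1": [1.5, 1.0],  # with pc=1: log2(2.5/5) - log2(5/5)... see pc=0
                "M1_r2": [1.5, 1.0],
            }
        )
        rep = compute_replicate_lfc(counts, pseudocount=0)
        model = compute_lfc(counts, pseudocount=0)
        assert np.allclose(
            model.values["M1"].to_numpy(),
            rep[["M1_r1", "M1_r2"]].mean(axis=1).to_numpy(),
        )

    def test_zero_total_sample_reports_its_name(self):
        counts = _counts({"pDNA": [1.0], "M1_r1": [0.0]})
        with pytest.raises(ValueError, match="M1_r1"):
            compute_lfc(counts)

    def test_uniform_rescaling_invariance_with_zero_pseudocount(self):
        rng = np.random.default_rng(3)
        base = rng.integers(10, 1000, size=(20, 3)).astype(float)
        counts = _counts(
            {"pDNA": base[:, 0], "M1_r1": base[:, 1], "M2_r1": base[:, 2]}
        )
        scaled = _counts(
            {"pDNA": base[:, 0], "M1_r1": base[:, 1] * 7, "M2_r1": base[:, 2]}
        )
        a = compute_lfc(counts, pseudocount=0).values
        b = compute_lfc(scaled, pseudocount=0).values
        assert np.allclose(a.to_numpy(), b.to_numpy())


class TestCollapse:
    def _screen(self, data, guides):
        return ScreenMatrix(
            pd.DataFrame(data, index=guides, columns=["M1"]), level="guide"
        )

    def test_median_collapse_odd_even_single(self):
        gm = _guidemap(
            [
                {"guide_id": f"g{i}", "gene": gene, "chromosome": "1",
                 "position": i + 1, "qc_flags": frozenset()}
                for i, gene in enumerate(["A", "A", "A", "B", "B", "C"])
            ]
        )
        guide_lfc = self._screen([-1.0, -2.0, -4.0, -1.0, -3.0, -5.0],
                                 [f"g{i}" for i in range(6)])
        genes = collapse_to_genes(guide_lfc, gm)
        assert genes.values.loc["A", "M1"] == -2.0  # median of {-1,-2,-4}
        assert genes.values.loc["B", "M1"] == -2.0  # midpoint of {-1,-3}
        assert genes.values.loc["C", "M1"] == -5.0  # single guide passes through

    def test_commutes_with_monotone_guide_relabeling(self):
        # collapse depends on guide values, not guide identities
        gm1 = _guidemap(
            [{"guide_id": f"g{i}", "gene": "A", "chromosome": "1",
              "position": i + 1, "qc_flags": frozenset()} for i in range(4)]
        )
        vals = [-0.5, -1.5, -2.5, -3.0]
        a = collapse_to_genes(self._screen(vals, [f"g{i}" for i in range(4)]), gm1)
        b = collapse_to_genes(self._screen(vals[::-1], [f"g{i}" for i in range(4)]), gm1)
        assert a.values.loc["A", "M1"] == b.values.loc["A", "M1"]


class TestScaleProfiles:
    def _matrix(self, rng, ess, ness, n_other=50):
        genes = ess + ness + [f"X{i}" for i in range(n_other)]
        data = rng.normal(0, 1, (len(genes), 3))
        return ScreenMatrix(pd.DataFrame(data, index=genes, columns=list("ABC")))

    def test_post_medians_are_exactly_minus_one_and_zero(self):
        rng = np.random.default_rng(0)
        ess = [f"E{i}" for i in range(11)]
        ness = [f"N{i}" for i in range(11)]
        m = self._matrix(rng, ess, ness)
        sets = GeneSets(frozenset(ess), frozenset(ness))
        scaled = scale_profiles(m, sets)
        assert scaled.scale_tag == "scaled"
        assert np.allclose(scaled.values.loc[ess].median(axis=0), -1.0)
        assert np.allclose(scaled.values.loc[ness].median(axis=0), 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        ess = [f"E{i}" for i in range(5)]
        ness = [f"N{i}" for i in range(5)]
        sets = GeneSets(frozenset(ess), frozenset(ness))
        once = scale_profiles(self._matrix(rng, ess, ness), sets)
        twice = scale_profiles(once, sets)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy())

    def test_known_affine_solution_halves_values(self):
        genes = ["E1", "N1", "X"]
        m = ScreenMatrix(pd.DataFrame({"M": [-2.0, 0.0, 3.0]}, index=genes))
        scaled = scale_profiles(m, GeneSets(frozenset(["E1"]), frozenset(["N1"])))
        assert np.allclose(scaled.values["M"].to_numpy(), [-1.0, 0.0, 1.5])

    def test_degenerate_screen_is_an_error(self):
        m = ScreenMatrix(pd.DataFrame({"M": [1.0, 1.0]}, index=["E1", "N1"]))
        with pytest.raises(ValueError, match="degenerate"):
            scale_profiles(m, GeneSets(frozenset(["E1"]), frozenset(["N1"])))


class TestReplicateFilter:
    def _setup(self):
        rng = np.random.default_rng(5)
        genes = [f"E{i}" for i in range(10)] + [f"N{i}" for i in range(10)]
        sets = GeneSets(frozenset(g for g in genes if g.startswith("E")),
                        frozenset(g for g in genes if g.startswith("N")))
        # good replicates: essentials strongly depleted -> very negative NNMD
        good = np.r_[rng.normal(-3, 0.05, 10), rng.normal(0, 0.05, 10)]
        reps = {
            "A_r1": good + rng.normal(0, 0.01, 20),
            "A_r2": good + rng.normal(0, 0.01, 20),
            "A_bad_nnmd": rng.normal(0, 0.05, 20),  # no control separation
            "B_r1": good + rng.normal(0, 0.01, 20),
            "B_r2": good + rng.normal(0, 0.01, 20),
            "B_anticorr": -good,  # fails sibling correlation
            "C_r1": good + rng.normal(0, 0.01, 20),  # single-replicate model
        }
        preview = ScreenMatrix(pd.DataFrame(reps, index=genes))
        counts = pd.DataFrame(
            {name: np.full(20, 500.0) for name in ["pDNA", *reps]}, index=genes
        )
        counts["A_r2"] = 150.0  # mean reads below threshold
        cm = CountMatrix(
            counts,
            {c: ("plasmid" if c == "pDNA" else "replicate") for c in counts.columns},
            {c: c.split("_")[0] for c in counts.columns if c != "pDNA"},
        )
        return cm, preview, sets, genes

    def test_each_criterion_flags_the_right_replicate(self):
        cm, preview, sets, genes = self._setup()
        filtered, report = filter_replicates(
            cm, preview, sets, high_variance_genes=genes
        )
        removed = report.removed_replicates.set_index("replicate")
        assert removed.loc["A_r2", "mean_reads"]
        assert removed.loc["A_bad_nnmd", "nnmd"]
        assert removed.loc["B_anticorr", "correlation"]
        # A_bad_nnmd is anticorrelated with nothing, but its flat controls fail NNMD
        assert set(filtered.replicate_samples) >= {"A_r1", "B_r1", "B_r2", "C_r1"}
        assert {"A_r2", "A_bad_nnmd", "B_anticorr"}.isdisjoint(
            filtered.replicate_samples
        )

    def test_passing_replicate_with_good_values_is_retained(self):
        cm, preview, sets, genes = self._setup()
        filtered, _ = filter_replicates(cm, preview, sets, high_variance_genes=genes)
        assert "A_r1" in filtered.replicate_samples

    def test_single_replicate_model_skips_correlation(self):
        cm, preview, sets, genes = self._setup()
        _, report = filter_replicates(cm, preview, sets, high_variance_genes=genes)
        assert any("single replicate" in n for n in report.notes)

    def test_custom_thresholds_respected(self):
        cm, preview, sets, genes = self._setup()
        lax = QCThresholds(
            min_mean_reads=0, min_replicate_correlation=-2, max_nnmd=1e6
        )
        filtered, report = filter_replicates(
            cm, preview, sets, high_variance_genes=genes, thresholds=lax
        )
        assert report.removed_replicates.empty
        assert set(filtered.replicate_samples) == set(cm.replicate_samples)


def test_guide_and_replicate_filters_commute(counts_bundle):
    from screenbias.preprocess import compute_replicate_lfc

    gm = counts_bundle.guidemap
    counts = counts_bundle.counts
    rep_gene = collapse_to_genes(
        ScreenMatrix(compute_replicate_lfc(counts), level="guide"), gm
    )
    sets = counts_bundle.gene_sets

    g_first, _ = filter_guides(gm)
    c_after_g, _ = filter_replicates(counts, rep_gene, sets)

    c_first, _ = filter_replicates(counts, rep_gene, sets)
    g_after_c, _ = filter_guides(gm)

    assert g_first.table.index.equals(g_after_c.table.index)
    assert list(c_after_g.values.columns) == list(c_first.values.columns)


def test_end_to_end_preprocessing_recovers_simulated_lfc(counts_bundle):
    """Counts -> LFC -> gene collapse tracks the simulated gene-level truth."""
    gm, _ = filter_guides(counts_bundle.guidemap)
    guide_lfc = compute_lfc(counts_bundle.counts)
    gene_lfc = collapse_to_genes(guide_lfc, gm)
    common = gene_lfc.values.index.intersection(counts_bundle.screen.values.index)
    a = gene_lfc.values.loc[common].to_numpy().ravel()
    b = counts_bundle.screen.values.loc[common].to_numpy().ravel()
    assert np.corrcoef(a, b)[0, 1] > 0.9
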