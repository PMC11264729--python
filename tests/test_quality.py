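import numpy as np
import pandas as pd
import pytest

from screenbias.datamodel import CFECatalog, GeneSets, OmicsProfiles, ScreenMatrix
from screenbias.quality import (
    bh_adjust,
    biomarker_scan,
    nnmd,
    oncogene_addiction_auroc,
    recall_at_fdr,
    screen_roc,
)


def _sets(ess, ness):
    return GeneSets(frozenset(ess), frozenset(ness))


def _series(pairs):
    return pd.Series(dict(pairs))


class TestScreenRoc:
    def test_concordant_pair_example(self):
        lfc = _series([("E1", -3.0), ("E2", -1.0), ("N1", -2.0), ("N2", 0.0), ("N3", 1.0)])
        auroc, _ = screen_roc(lfc, _sets(["E1", "E2"], ["N1", "N2", "N3"]))
        assert auroc == pytest.approx(5 / 6)

    def test_perfect_and_reversed_separation(self):
        lfc = _series([("E1", -3.0), ("E2", -2.0), ("N1", 0.0), ("N2", 1.0)])
        sets = _sets(["E1", "E2"], ["N1", "N2"])
        assert screen_roc(lfc, sets)[0] == 1.0
        assert screen_roc(-lfc, sets)[0] == 0.0

    def test_auroc_equals_bruteforce_concordance(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n_e, n_n = rng.integers(5, 100), rng.integers(5, 100)
            ess = [f"E{i}" for i in range(n_e)]
            ness = [f"N{i}" for i in range(n_n)]
            lfc = pd.Series(
                rng.permutation(np.linspace(-3, 3, n_e + n_n)),  # tie-free
                index=ess + ness,
            )
            auroc, _ = screen_roc(lfc, _sets(ess, ness))
            concordant = np.mean(
                [[lfc[e] < lfc[n] for n in ness] for e in ess]
            )
            assert auroc == pytest.approx(concordant)

    def test_empty_control_set_is_an_error(self):
        lfc = _series([("E1", -1.0), ("N1", 0.0)])
        with pytest.raises(ValueError, match="control set"):
            screen_roc(lfc, _sets(["E1"], ["ABSENT"]))


class TestNnmd:
    def test_hand_example_with_unscaled_mad(self):
        value = nnmd([-2.2, -2.0, -1.8], [0.1, -0.1, 0.0])
        assert value == pytest.approx(-20.0)

    def test_identical_distributions_give_zero(self):
        x = [0.5, -0.5, 0.1, -0.1]
        assert nnmd(x, x) == 0.0

    def test_translation_invariance_and_shift_response(self):
        rng = np.random.default_rng(1)
        e = rng.normal(-2, 0.3, 50)
        n = rng.normal(0, 0.3, 50)
        base = nnmd(e, n)
        assert nnmd(e + 1.3, n + 1.3) == pytest.approx(base)
        # moving E down by delta changes NNMD by exactly -delta / MAD(N)
        mad = np.median(np.abs(n - np.median(n)))
        assert nnmd(e - 0.7, n) == pytest.approx(base - 0.7 / mad)

    def test_scaled_mad_variant(self):
        e, n = [-2.2, -2.0, -1.8], [0.1, -0.1, 0.0]
        assert nnmd(e, n, scaled_mad=True) == pytest.approx(-20.0 / 1.4826, rel=1e-3)

    def test_zero_mad_is_an_error(self):
        with pytest.raises(ValueError, match="MAD"):
            nnmd([-1.0], [0.0, 0.0, 0.0])


class TestRecallAtFdr:
    def test_eight_gene_ranked_example(self):
        # ranked labels E,E,N,E,N,E,N,N: PPV never reaches 0.95 after k=2
        lfc = _series(
            [("E1", -4.0), ("E2", -3.5), ("N1", -3.0), ("E3", -2.5),
             ("N2", -2.0), ("E4", -1.5), ("N3", -1.0), ("N4", -0.5)]
        )
        result = recall_at_fdr(lfc, _sets(["E1", "E2", "E3", "E4"],
                                          ["N1", "N2", "N3", "N4"]))
        assert result.k_star == 2
        assert result.lfc_star == -3.5
        assert result.recalls["essential"] == 0.5
        assert result.recalls["nonessential"] == 0.0

    def test_perfect_separation(self):
        lfc = _series([("E1", -3.0), ("E2", -2.0), ("N1", 0.0), ("N2", 1.0)])
        result = recall_at_fdr(lfc, _sets(["E1", "E2"], ["N1", "N2"]))
        assert result.recalls["essential"] == 1.0
        assert result.recalls["nonessential"] == 0.0

    def test_monotone_in_ppv_threshold(self):
        rng = np.random.default_rng(2)
        ess = [f"E{i}" for i in range(30)]
        ness = [f"N{i}" for i in range(30)]
        lfc = pd.Series(
            np.r_[rng.normal(-1, 0.5, 30), rng.normal(0, 0.5, 30)], index=ess + ness
        )
        sets = _sets(ess, ness)
        previous = None
        for threshold in (0.99, 0.95, 0.9, 0.8, 0.5):
            recalls = recall_at_fdr(lfc, sets, ppv_threshold=threshold).recalls
            if previous is not None:
                for name in recalls:
                    assert recalls[name] >= previous[name]
            previous = recalls

    def test_unreachable_ppv_flags_and_zeroes(self):
        lfc = _series([("E1", 0.0), ("N1", -1.0), ("N2", -2.0), ("N3", -3.0)])
        result = recall_at_fdr(lfc, _sets(["E1"], ["N1", "N2", "N3"]))
        assert result.flagged and result.k_star is None
        assert set(result.recalls.values()) == {0.0}

    def test_target_set_disjoint_from_hits_scores_zero(self):
        lfc = _series(
            [("E1", -3.0), ("E2", -2.5), ("N1", 0.0), ("G1", 5.0), ("G2", 6.0)]
        )
        result = recall_at_fdr(
            lfc, _sets(["E1", "E2"], ["N1"]), {"extra": frozenset(["G1", "G2"])}
        )
        assert result.recalls["extra"] == 0.0


class TestOncogeneAddiction:
    def _fixture(self, pos_scores, neg_scores):
        models = [f"M{i}" for i in range(len(pos_scores) + len(neg_scores))]
        scores = list(pos_scores) + list(neg_scores)
        scaled = ScreenMatrix(
            pd.DataFrame([scores], index=["ONC"], columns=models), scale_tag="scaled"
        )
        mutation = pd.DataFrame(
            [[1] * len(pos_scores) + [0] * len(neg_scores)], index=["ONC"],
            columns=models,
        )
        omics = OmicsProfiles(
            pd.DataFrame([[2] * len(models)], index=["ONC"], columns=models),
            pd.DataFrame([[0.1] * len(models)], index=["ONC"], columns=models),
        )
        return scaled, omics, mutation

    def test_pooled_concordance_example(self):
        scaled, omics, mutation = self._fixture([-1.5, -0.1], [-0.2, 0.0, 0.1])
        value = oncogene_addiction_auroc(scaled, omics, ["ONC"], mutation)
        assert value == pytest.approx(5 / 6)

    def test_fully_separated_pools(self):
        scaled, omics, mutation = self._fixture([-2.0, -1.5], [0.0, 0.5])
        assert oncogene_addiction_auroc(scaled, omics, ["ONC"], mutation) == 1.0

    def test_requires_scaled_matrix(self):
        scaled, omics, mutation = self._fixture([-1.0], [0.0])
        raw = ScreenMatrix(scaled.values, scale_tag="raw")
        with pytest.raises(ValueError, match="scaled"):
            oncogene_addiction_auroc(raw, omics, ["ONC"], mutation)

    def test_permuted_labels_give_half_on_average(self):
        rng = np.random.default_rng(3)
        values = []
        for _ in range(20):
            scores = rng.normal(size=40)
            scaled, omics, mutation = self._fixture(scores[:15], scores[15:])
            values.append(oncogene_addiction_auroc(scaled, omics, ["ONC"], mutation))
        assert np.mean(values) == pytest.approx(0.5, abs=0.03)

    def test_oncogene_without_both_controls_dropped(self):
        scaled, omics, mutation = self._fixture([-1.0, -0.5], [0.0])
        mutation.loc["ONC"] = 1  # no negatives anywhere
        with pytest.raises(ValueError, match="pool"):
            oncogene_addiction_auroc(scaled, omics, ["ONC"], mutation)


def _catalog(models, tissue_labels, events):
    tissue = pd.Series(tissue_labels, index=models)
    tp53 = pd.Series(["wild_type"] * len(models), index=models)
    return CFECatalog(pd.DataFrame(events, columns=models), tissue, tp53)


class TestBiomarkerScan:
    def test_strong_group_difference_matches_pooled_t(self):
        models = [f"M{i}" for i in range(6)]
        lfc = ScreenMatrix(
            pd.DataFrame(
                [[-1.0, -1.1, -0.9, 0.0, 0.1, -0.1]], index=["SSD1"], columns=models
            )
        )
        cfe = _catalog(models, ["lung"] * 6,
                       {m: [1 if i < 3 else 0] for i, m in enumerate(models)})
        cfe.events.index = ["CFE1"]
        result = biomarker_scan(lfc, cfe, ["SSD1"], min_group=3)
        assert result.n_tests == 1
        row = result.tests.iloc[0]
        assert row["t"] == pytest.approx(-12.2474, abs=1e-3)
        assert row["fdr"] < 0.05

    def test_groups_below_minimum_are_not_tested(self):
        models = [f"M{i}" for i in range(6)]
        lfc = ScreenMatrix(
            pd.DataFrame([np.zeros(6)], index=["SSD1"], columns=models)
        )
        cfe = _catalog(models, ["lung"] * 6,
                       {m: [1 if i < 2 else 0] for i, m in enumerate(models)})
        with pytest.warns(UserWarning, match="no testable"):
            result = biomarker_scan(lfc, cfe, ["SSD1"], min_group=3)
        assert result.n_tests == 0 and result.hits.empty

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(4)
        models = [f"M{i}" for i in range(20)]
        lfc = ScreenMatrix(
            pd.DataFrame(rng.normal(0, 0.2, (5, 20)),
                         index=[f"SSD{i}" for i in range(5)], columns=models)
        )
        cfe = _catalog(models, ["lung"] * 20,
                       {m: [i % 2] for i, m in enumerate(models)})
        result = biomarker_scan(lfc, cfe, [f"SSD{i}" for i in range(5)])
        assert result.hits.empty

    def test_scan_is_tissue_stratified(self, default_bundle):
        result = biomarker_scan(
            default_bundle.screen, default_bundle.cfe,
            default_bundle.gene_sets.ssd_genes,
        )
        if not result.tests.empty:
            sizes = result.tests[["n_with_event", "n_without_event"]]
            assert (sizes >= 3).all().all()
            assert (result.tests["fdr"] >= result.tests["p"] - 1e-12).all()


def test_bh_on_uniform_null_controls_empirical_fdr():
    """Mean false-discovery proportion over seeded uniform-null scans <= 0.07."""
    rng = np.random.default_rng(12345)
    fdp = []
    for _ in range(200):
        p = rng.uniform(size=10_000)
        rejected = bh_adjust(p) < 0.05
        fdp.append(1.0 if rejected.any() else 0.0)  # every rejection is false
    assert np.mean(fdp) <= 0.07
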