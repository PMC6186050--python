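import numpy as np
import pytest

from speciescadd import evaluation, training
from speciescadd.core import SpeciesCaddError, Variant
from speciescadd.evaluation import UndefinedAUCError


def pairwise_auc(scores, labels):
    """Exhaustive Mann-Whitney oracle: P(s+ > s-) + 0.5 P(s+ = s-)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert evaluation.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_partial_overlap(self):
        # pos {0.8, 0.4}, neg {0.6, 0.2}: 3 of 4 pairs concordant
        assert evaluation.roc_auc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_tie_convention(self):
        assert evaluation.roc_auc([0.5, 0.5], [1, 0]) == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedAUCError):
            evaluation.roc_auc([0.1, 0.2], [1, 1])

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            assert evaluation.roc_auc(scores, labels) == pytest.approx(
                pairwise_auc(scores.tolist(), labels.tolist()), abs=1e-12
            )

    def test_complement_identity_without_ties(self, rng):
        scores = rng.permutation(40) / 40.0
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        assert evaluation.roc_auc(scores, labels) + evaluation.roc_auc(
            -scores, labels
        ) == pytest.approx(1.0)


def flagged_variant(i, consequence=None, transcribed=False, translated=False):
    return Variant(
        "c1", 2 * i, "A", "T",
        consequence=consequence, transcribed=transcribed, translated=translated,
    )


class TestStratifiedReport:
    def test_subset_membership(self):
        variants = [
            flagged_variant(0, "missense", True, True),
            flagged_variant(1, "intergenic", False, False),
            flagged_variant(2, "intron", True, False),
            flagged_variant(3, "synonymous", True, True),
        ]
        labels = np.array([1, 0, 1, 0])
        scores = np.array([0.9, 0.1, 0.8, 0.2])
        report = evaluation.stratified_report(scores, variants, labels)
        counts = {
            sid: (r.n_pos + r.n_neg) for sid, r in report.subsets.items()
        }
        # missense variant: I, III, V, VII; intergenic: I, II; intron: I, III, IV
        assert counts == {"I": 4, "II": 1, "III": 3, "IV": 1, "V": 2, "VI": 1, "VII": 1}
        # single-class subsets are undefined, never zero
        assert report.subsets["II"].auc is None
        assert report.subsets["I"].auc == 1.0

    def test_partition_identities_on_random_flags(self, rng):
        consequences = ["intergenic", "intron", "synonymous", "missense", "UTR"]
        variants = []
        for i in range(300):
            c = consequences[int(rng.integers(0, len(consequences)))]
            translated = c in ("synonymous", "missense")
            transcribed = translated or c in ("intron", "UTR")
            variants.append(flagged_variant(i, c, transcribed, translated))
        labels = rng.integers(0, 2, size=300)
        labels[:2] = [0, 1]
        scores = rng.normal(size=300)
        report = evaluation.stratified_report(scores, variants, labels)
        n = lambda s: report.subsets[s].n_pos + report.subsets[s].n_neg
        assert n("II") + n("III") == n("I")
        assert n("IV") + n("V") == n("III")
        assert n("VI") + n("VII") <= n("V")

    def test_label_permutation_control(self, rng):
        variants = [flagged_variant(i, "intergenic") for i in range(5000)]
        scores = rng.normal(size=5000)
        labels = rng.permutation(np.repeat([0, 1], 2500))
        report = evaluation.stratified_report(scores, variants, labels)
        assert 0.45 <= report.subsets["I"].auc <= 0.55


def candidate(i, consequence, af):
    return Variant(
        "c1", 2 * i, "A", "T", consequence=consequence, af=af,
        transcribed=consequence != "intergenic",
        translated=consequence in ("missense", "synonymous", "stop_gained"),
    )


class TestMatchNegatives:
    def make_pool(self):
        pool = []
        i = 0
        for csq, n, af in [
            ("missense", 30, 0.95), ("stop_gained", 10, 0.95),
            ("synonymous", 30, 0.95), ("intron", 30, 0.95),
            ("missense", 20, 0.85),  # below the AF filter
        ]:
            for _ in range(n):
                pool.append(candidate(i, csq, af))
                i += 1
        return pool

    def test_exact_stratum_matching(self):
        positives = [
            candidate(1000, "missense", None),
            candidate(1001, "missense", None),
            candidate(1002, "synonymous", None),
            candidate(1003, "intron", None),
        ]
        negatives = evaluation.match_negatives(positives, self.make_pool(), seed=3)
        assert len(negatives) == 4
        strata = [evaluation._stratum(v) for v in negatives]
        assert strata.count("non_synonymous") == 2
        assert strata.count("synonymous") == 1
        assert strata.count("other") == 1

    def test_af_filter_absolute(self):
        positives = [candidate(1000, "missense", None) for _ in range(25)]
        positives = [
            Variant("c1", 5000 + 2 * i, "A", "T", consequence="missense",
                    transcribed=True, translated=True)
            for i in range(25)
        ]
        negatives = evaluation.match_negatives(positives, self.make_pool(), seed=1)
        assert all(v.af >= 0.9 for v in negatives)

    def test_determinism(self):
        positives = [candidate(1000 + i, "synonymous", None) for i in range(5)]
        a = evaluation.match_negatives(positives, self.make_pool(), seed=11)
        b = evaluation.match_negatives(positives, self.make_pool(), seed=11)
        assert [(v.contig, v.pos) for v in a] == [(v.contig, v.pos) for v in b]

    def test_shortfall_names_stratum(self):
        positives = [candidate(1000 + i, "synonymous", None) for i in range(100)]
        with pytest.raises(SpeciesCaddError, match="synonymous"):
            evaluation.match_negatives(positives, self.make_pool(), seed=0)


def toy_model(names, betas):
    return training.TrainedModel(
        feature_names=list(names),
        betas=np.asarray(betas, float),
        intercept=0.0,
        scale_factors=np.ones(len(names)),
    )


class TestWeightRankCorrelation:
    def test_self_comparison(self):
        m = toy_model("abcde", [0.5, -1.0, 2.0, 0.1, -0.3])
        rho, n = evaluation.weight_rank_correlation(m, m)
        assert rho == pytest.approx(1.0)
        assert n == 5

    def test_reversed_order(self):
        a = toy_model("abcd", [4.0, 3.0, 2.0, 1.0])
        b = toy_model("abcd", [1.0, -2.0, 3.0, -4.0])
        rho, _ = evaluation.weight_rank_correlation(a, b)
        assert rho == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        a = toy_model("abcde", [0.9, -0.1, 0.5, 2.0, -1.2])
        b = toy_model("abcde", [1.1, 0.4, -0.2, 0.6, 0.3])
        rho, n = evaluation.weight_rank_correlation(a, b)
        # direct Spearman from rank definitions (no ties here)
        from scipy.stats import rankdata

        ra = rankdata([abs(x) for x in a.betas])
        rb = rankdata([abs(x) for x in b.betas])
        expected = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)
        assert n == 5

    def test_zero_weights_excluded(self):
        a = toy_model("abcde", [1.0, 0.0, 2.0, 3.0, 4.0])
        b = toy_model("abcde", [1.0, 5.0, 2.0, 3.0, 0.0])
        _, n = evaluation.weight_rank_correlation(a, b)
        assert n == 3

    def test_too_few_common_rejected(self):
        a = toy_model("ab", [1.0, 2.0])
        b = toy_model("ab", [1.0, 2.0])
        with pytest.raises(SpeciesCaddError, match="need >= 3"):
            evaluation.weight_rank_correlation(a, b)


class TestCrossSpeciesScore:
    def _matrix(self, rng, names, n=10):
        from speciescadd.features import FeatureColumn, FeatureMatrix

        variants = [Variant("c1", 2 * i, "A", "T") for i in range(n)]
        cols = [
            FeatureColumn(name, frozenset({"conservation"}), rng.normal(size=n),
                          np.zeros(n, dtype=bool))
            for name in names
        ]
        return FeatureMatrix(variants, cols)

    def test_identity_map_equals_plain_score(self, rng):
        m = self._matrix(rng, ["a", "b", "c"])
        model = toy_model("abc", [1.0, -1.0, 0.5])
        np.testing.assert_allclose(
            evaluation.cross_species_score(model, m), training.score(model, m)
        )

    def test_dropping_zero_beta_feature_is_noop(self, rng):
        m = self._matrix(rng, ["a", "b"])
        model = toy_model("abc", [1.0, -1.0, 0.0])
        scores = evaluation.cross_species_score(
            model, m, name_map={"a": "a", "b": "b"}, allow_drop=True
        )
        full = self._matrix(rng, ["c"])  # placeholder, not used
        np.testing.assert_allclose(
            scores,
            m.column("a").values * 1.0 - m.column("b").values,
        )

    def test_dropped_nonzero_feature_shifts_by_its_contribution(self, rng):
        m = self._matrix(rng, ["a", "b", "c"])
        model = toy_model("abc", [1.0, -1.0, 2.0])
        full = evaluation.cross_species_score(model, m)
        reduced = evaluation.cross_species_score(
            model, m, name_map={"a": "a", "b": "b"}, allow_drop=True
        )
        np.testing.assert_allclose(full - reduced, 2.0 * m.column("c").values)

    def test_unmapped_feature_rejected_without_flag(self, rng):
        m = self._matrix(rng, ["a"])
        model = toy_model("ab", [1.0, 1.0])
        with pytest.raises(SpeciesCaddError, match="b"):
            evaluation.cross_species_score(model, m, name_map={"a": "a"})
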