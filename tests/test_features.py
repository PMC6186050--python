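import numpy as np
import pandas as pd
import pytest

from speciescadd import features
from speciescadd.core import GenomeSequence, SpeciesCaddError, Track, Variant
from speciescadd.features import FeatureColumn, FeatureMatrix
from speciescadd.io_formats import ALL_5MERS


def genome(seq: str) -> GenomeSequence:
    return GenomeSequence({"c1": seq})


def var(pos, ref="A", alt="T", **kw) -> Variant:
    return Variant("c1", pos, ref, alt, **kw)


class TestGcContent:
    def test_extremes(self):
        assert features.gc_content(genome("GCGCGC"), var(2, ref="G", alt="A"), 2) == 1.0
        assert features.gc_content(genome("ATATAT"), var(2, ref="A", alt="G"), 2) == 0.0

    def test_direct_count(self):
        # effective 10-base window with 4 G/C
        g = genome("GCGCAAAAAT")
        assert features.gc_content(g, var(0, ref="G", alt="A"), 9) == pytest.approx(0.4)

    def test_n_excluded_from_denominator(self):
        g = genome("GNNNA")
        assert features.gc_content(g, Variant("c1", 2, "A", "T"), 2) == pytest.approx(0.5)

    def test_all_n_window_missing(self):
        g = genome("NNNNN")
        assert features.gc_content(g, Variant("c1", 2, "A", "T"), 1) is None

    def test_matches_brute_force(self, rng):
        bases = np.array(list("ACGTN"))
        seq = "".join(bases[rng.integers(0, 5, size=400)])
        g = genome(seq)
        for _ in range(50):
            pos = int(rng.integers(0, 400))
            hw = int(rng.integers(1, 120))
            got = features.gc_content(g, Variant("c1", pos, "A", "T"), hw)
            window = seq[max(0, pos - hw) : pos + hw + 1]
            known = [b for b in window if b != "N"]
            expected = (
                None if not known else sum(b in "GC" for b in known) / len(known)
            )
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected)


class TestShapeDelta:
    @pytest.fixture()
    def table(self):
        return pd.DataFrame(
            {"MGW": np.zeros(1024)}, index=pd.Index(ALL_5MERS, name="kmer")
        ).assign(MGW=lambda df: np.arange(1024.0))

    def test_direct_subtraction(self):
        table = pd.DataFrame({"MGW": np.zeros(1024)}, index=pd.Index(ALL_5MERS, name="kmer"))
        table.loc["AACGT", "MGW"] = 1.5
        table.loc["AATGT", "MGW"] = 2.0
        g = genome("AACGTAA")
        out = features.shape_delta(g, Variant("c1", 2, "C", "T"), table)
        assert out["MGW"] == pytest.approx(0.5)

    def test_edge_positions_missing(self, table):
        g = genome("ACGTACGT")
        for pos, ref in [(0, "A"), (1, "C"), (6, "G"), (7, "T")]:
            alt = "G" if ref != "G" else "A"
            out = features.shape_delta(g, Variant("c1", pos, ref, alt), table)
            assert out["MGW"] is None

    def test_n_in_kmer_missing(self, table):
        g = genome("ANCGT")
        assert features.shape_delta(g, Variant("c1", 2, "C", "T"), table)["MGW"] is None

    def test_antisymmetry(self, rng, table):
        """delta(a->b) computed on the mutated genome equals -delta(b->a)."""
        bases = "ACGT"
        for _ in range(40):
            kmer_idx = int(rng.integers(0, 1024))
            ref5 = ALL_5MERS[kmer_idx]
            alt_base = bases[(bases.index(ref5[2]) + int(rng.integers(1, 4))) % 4]
            g_fwd = genome(ref5)
            fwd = features.shape_delta(
                g_fwd, Variant("c1", 2, ref5[2], alt_base), table
            )["MGW"]
            alt5 = ref5[:2] + alt_base + ref5[3:]
            back = features.shape_delta(
                genome(alt5), Variant("c1", 2, alt_base, ref5[2]), table
            )["MGW"]
            assert fwd == pytest.approx(-back, abs=1e-12)

    def test_reference_allele_mismatch_rejected(self, table):
        g = genome("AACGTAA")
        with pytest.raises(SpeciesCaddError, match="mismatch"):
            features.shape_delta(g, Variant("c1", 2, "G", "T"), table)


class TestTrackLookup:
    def test_score_interval_and_missing(self):
        score = Track.per_base("cons", [("c1", 0, 10, 0.7)])
        assert features.track_lookup(score, var(5)) == pytest.approx(0.7)
        assert features.track_lookup(score, var(10)) is None
        peaks = Track.intervals("peaks", [("c1", 3, 6)])
        assert features.track_lookup(peaks, var(4)) == 1.0
        assert features.track_lookup(peaks, var(6)) == 0.0


class TestEncodeConsequences:
    def csq(self, rows):
        return pd.DataFrame(
            rows,
            columns=["contig", "pos", "ref", "alt", "consequence", "transcribed", "translated"],
        )

    def test_one_hot_and_flags(self):
        variants = [var(4, "A", "T"), var(9, "C", "G")]
        table = self.csq([("c1", 4, "A", "T", "missense", True, True)])
        cols = features.encode_consequences(table, variants)
        by_name = {c.name: c for c in cols}
        assert by_name["csq_missense"].values.tolist() == [1.0, 0.0]
        assert by_name["csq_missense"].tags == frozenset({"vep", "coding"})
        assert by_name["csq_intron"].tags == frozenset({"vep"})
        assert variants[0].transcribed and variants[0].translated
        # absent variant: all-zero encoding, untranscribed
        assert variants[1].transcribed is False
        assert all(c.values[1] == 0.0 for c in cols)

    def test_duplicate_key_rejected(self):
        table = self.csq(
            [
                ("c1", 4, "A", "T", "intron", True, False),
                ("c1", 4, "A", "T", "missense", True, True),
            ]
        )
        with pytest.raises(SpeciesCaddError, match="duplicate"):
            features.encode_consequences(table, [var(4, "A", "T")])

    def test_unknown_term_rejected(self):
        table = self.csq([("c1", 4, "A", "T", "frameshift", True, True)])
        with pytest.raises(SpeciesCaddError, match="frameshift"):
            features.encode_consequences(table, [var(4, "A", "T")])


def matrix_from(columns, n=None):
    n = n if n is not None else len(columns[0].values)
    variants = [Variant("c1", 2 * i, "A", "T") for i in range(n)]
    return FeatureMatrix(variants, columns)


def col(name, tags, values, missing=None):
    values = np.asarray(values, dtype=float)
    missing = (
        np.zeros(len(values), dtype=bool) if missing is None else np.asarray(missing)
    )
    return FeatureColumn(name, frozenset(tags), values, missing)


class TestCompositeFeatures:
    def test_definition_and_missing_propagation(self):
        m = matrix_from(
            [
                col("GERPN", {"conservation"}, [2.0, 2.0, 2.0], [False, False, True]),
                col("csq_intron", {"vep"}, [1.0, 0.0, 1.0]),
            ]
        )
        out = features.composite_features(m, [("intron", "GERPN")])
        assert len(out) == 1
        c = out[0]
        assert c.name == "GERPN_x_intron"
        assert c.tags == frozenset({"composite", "conservation"})
        assert c.values[0] == 2.0  # active one-hot carries the value
        assert c.values[1] == 0.0  # inactive -> 0
        assert c.missing_mask.tolist() == [False, False, True]

    def test_name_collision_rejected(self):
        m = matrix_from(
            [
                col("GERPN", {"conservation"}, [2.0]),
                col("csq_intron", {"vep"}, [1.0]),
                col("GERPN_x_intron", {"composite"}, [0.0]),
            ]
        )
        with pytest.raises(SpeciesCaddError, match="collision"):
            features.composite_features(m, [("intron", "GERPN")])


class TestApplyTier:
    @pytest.fixture()
    def tagged_matrix(self):
        return matrix_from(
            [
                col("phastcons", {"conservation"}, [0.1]),
                col("GC", {"sequence"}, [0.4]),
                col("csq_missense", {"vep", "coding"}, [1.0]),
                col("csq_intron", {"vep"}, [0.0]),
                col("sift", {"coding"}, [0.2]),
                col("h3k4me3", {"epigenetic"}, [1.0]),
                col("strain_af", {"species_specific"}, [0.9]),
                col("phastcons_x_intron", {"composite", "conservation"}, [0.0]),
            ]
        )

    @pytest.mark.parametrize(
        "tier, expected",
        [
            (
                "all",
                {"phastcons", "GC", "csq_missense", "csq_intron", "sift",
                 "h3k4me3", "strain_af", "phastcons_x_intron"},
            ),
            (
                "no_epi",
                {"phastcons", "GC", "csq_missense", "csq_intron", "sift",
                 "phastcons_x_intron"},
            ),
            (
                "cons_vep",
                {"phastcons", "GC", "csq_missense", "csq_intron", "phastcons_x_intron"},
            ),
            ("seq_only", {"phastcons", "GC"}),
        ],
    )
    def test_survival_by_tier(self, tagged_matrix, tier, expected):
        assert set(features.apply_tier(tagged_matrix, tier).names()) == expected

    def test_idempotent_and_monotone(self, tagged_matrix):
        chain = ["seq_only", "cons_vep", "no_epi", "all"]
        kept = {}
        for tier in chain:
            out = features.apply_tier(tagged_matrix, tier)
            again = features.apply_tier(out, tier)
            assert out.names() == again.names()
            kept[tier] = set(out.names())
        assert kept["seq_only"] <= kept["cons_vep"] <= kept["no_epi"] <= kept["all"]


class TestImputeMissing:
    def test_indicator_added_and_values_zero_filled(self):
        m = matrix_from([col("x", {"sequence"}, [1.0, 0.0], [False, True])])
        out = features.impute_missing(m)
        assert out.names() == ["x", "x__missing"]
        np.testing.assert_array_equal(out.column("x").values, [1.0, 0.0])
        np.testing.assert_array_equal(out.column("x__missing").values, [0.0, 1.0])
        assert not out.has_missing()

    def test_clean_column_untouched(self):
        m = matrix_from([col("x", {"sequence"}, [1.0, 2.0])])
        out = features.impute_missing(m)
        assert out.names() == ["x"]

    def test_growth_equals_missing_columns(self, rng):
        cols = []
        n_with_missing = 0
        for j in range(8):
            miss = rng.random(10) < 0.3 * (j % 2)
            n_with_missing += int(miss.any())
            cols.append(col(f"f{j}", {"sequence"}, rng.normal(size=10), miss))
        before = matrix_from(cols)
        out = features.impute_missing(before)
        assert len(out.columns) == len(cols) + n_with_missing
        for c in cols:  # non-missing values unchanged
            np.testing.assert_array_equal(
                out.column(c.name).values[~c.missing_mask], c.values[~c.missing_mask]
            )


class TestBuildFeatureMatrix:
    def test_end_to_end_assembly(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=500)])
        g = genome(seq)
        variants = []
        for pos in range(10, 400, 40):
            ref_b = seq[pos]
            alt_b = "ACGT"[("ACGT".index(ref_b) + 1) % 4]
            variants.append(Variant("c1", pos, ref_b, alt_b, label="derived"))
        track = Track.per_base(
            "cons", [("c1", v.pos, v.pos + 1, float(i)) for i, v in enumerate(variants)]
        )
        csq = pd.DataFrame(
            [
                ("c1", v.pos, v.ref_allele, v.alt_allele, "missense", True, True)
                for v in variants[:3]
            ],
            columns=["contig", "pos", "ref", "alt", "consequence", "transcribed", "translated"],
        )
        shape = pd.DataFrame(
            {"MGW": np.arange(1024.0)}, index=pd.Index(ALL_5MERS, name="kmer")
        )
        cfg = features.FeatureConfig(composite_spec=[("missense", "cons")])
        m = features.build_feature_matrix(
            g, variants, [(track, {"conservation"})], csq, shape, cfg
        )
        assert "GC" in m.names()
        assert "shape_MGW" in m.names()
        assert "cons_x_missense" in m.names()
        assert not m.has_missing()
        assert m.column("cons").values.tolist() == list(range(len(variants)))
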