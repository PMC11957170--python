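import math

import pytest
from hypothesis import given, settings, strategies as st

from penbayes import variant_data as vd
from penbayes.variant_data import (HeterozygoteCounts, VariantTable,
                                   encode_clinvar, evidence_weight,
                                   merge_counts, observed_penetrance,
                                   parse_variant_id)
from conftest import make_record


class TestParseVariantId:
    @pytest.mark.parametrize("text,expected", [
        ("p.R420W", (420, "R", "W")),
        ("R420W", (420, "R", "W")),
        ("p.Arg420Trp", (420, "R", "W")),
        ("p.V186M", (186, "V", "M")),
    ])
    def test_dialects(self, text, expected):
        assert parse_variant_id(text) == expected

    @pytest.mark.parametrize("bad", ["420", "p.R420", "X999Z", "p.R420X"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(ValueError):
            parse_variant_id(bad)


class TestObservedPenetrance:
    @pytest.mark.parametrize("aff,unaff,expected", [
        (14, 10, 14 / 24),
        (0, 5, 0.0),
        (1, 22, 1 / 23),
        (5, 0, 1.0),
    ])
    def test_fraction_affected(self, aff, unaff, expected):
        assert observed_penetrance(HeterozygoteCounts(aff, unaff)) == \
            pytest.approx(expected)

    def test_zero_total_raises(self):
        with pytest.raises(vd.UndefinedPenetranceError):
            observed_penetrance(HeterozygoteCounts(0, 0))

    @given(aff=st.integers(0, 1000), unaff=st.integers(0, 1000))
    def test_bounds_and_unity(self, aff, unaff):
        if aff + unaff == 0:
            return
        p = observed_penetrance(HeterozygoteCounts(aff, unaff))
        assert 0.0 <= p <= 1.0
        assert (p == 1.0) == (unaff == 0 and aff > 0)


class TestEvidenceWeight:
    def test_printed_form_values(self):
        assert evidence_weight(1) == pytest.approx(1 - 1 / 1.01)   # 0.009901
        assert evidence_weight(100) == pytest.approx(1 - 1 / 100.01)

    def test_limit_approaches_one(self):
        assert evidence_weight(10**6) == pytest.approx(1.0, abs=1e-5)

    def test_soft_form(self):
        assert evidence_weight(1, form="soft") == pytest.approx(1 - 1 / 1.01)
        assert evidence_weight(100, form="soft") == pytest.approx(0.5)

    @given(n=st.integers(1, 10**6))
    def test_monotone_and_bounded(self, n):
        w = evidence_weight(n)
        assert 0.0 <= w < 1.0
        assert evidence_weight(n + 1) > w

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            evidence_weight(0)


class TestEncodeClinvar:
    @pytest.mark.parametrize("label,expected", [
        ("Pathogenic", 1.0),
        ("Likely pathogenic", 1.0),
        ("P/LP", 1.0),
        ("Uncertain significance", 0.0),
        ("VUS", 0.0),
        ("Likely benign", 0.0),
        ("Benign", 0.0),
        ("absent", None),
    ])
    def test_encoding(self, label, expected):
        assert encode_clinvar(label) == expected

    def test_unrecognized_lists_accepted(self):
        with pytest.raises(ValueError, match="accepted labels"):
            encode_clinvar("conflicting interpretations!!")


class TestReadCountTable:
    def test_single_hgvs_row(self, tmp_path):
        f = tmp_path / "c.csv"
        f.write_text("variant,affected,unaffected\np.R420W,14,10\n")
        table = vd.read_count_table(f)
        rec = table[(420, "R", "W")]
        assert rec.counts == HeterozygoteCounts(14, 10)

    def test_header_only_is_empty(self, tmp_path):
        f = tmp_path / "c.csv"
        f.write_text("variant,affected,unaffected\n")
        assert len(vd.read_count_table(f)) == 0

    def test_bad_count_names_row(self, tmp_path):
        f = tmp_path / "c.csv"
        f.write_text("variant,affected,unaffected\np.R420W,3,abc\n")
        with pytest.raises(ValueError, match="row 1"):
            vd.read_count_table(f)

    def test_missing_columns(self, tmp_path):
        f = tmp_path / "c.csv"
        f.write_text("foo,bar\n1,2\n")
        with pytest.raises(vd.FormatError):
            vd.read_count_table(f)

    def test_positional_columns_and_tsv(self, tmp_path):
        f = tmp_path / "c.tsv"
        f.write_text("position\tref\talt\taffected\tunaffected\n"
                     "420\tR\tW\t2\t1\n")
        table = vd.read_count_table(f)
        assert table[(420, "R", "W")].counts.total == 3

    def test_duplicate_rows_summed(self, tmp_path):
        f = tmp_path / "c.csv"
        f.write_text("variant,affected,unaffected\np.R420W,1,0\np.R420W,3,2\n")
        assert vd.read_count_table(f)[(420, "R", "W")].counts == \
            HeterozygoteCounts(4, 2)


class TestReadPopulationTable:
    def _write(self, tmp_path, rows):
        f = tmp_path / "pop.csv"
        f.write_text("variant,af,allele_count\n" + "\n".join(rows) + "\n")
        return f

    def test_af_filter_and_mapping(self, tmp_path):
        f = self._write(tmp_path, ["p.R420W,0.05,100", "p.V186M,5e-6,3"])
        table = vd.read_population_table(f, af_threshold=1e-4)
        assert (420, "R", "W") not in table
        rec = table[(186, "V", "M")]
        assert rec.counts == HeterozygoteCounts(0, 3)

    def test_vacuous_threshold_keeps_all(self, tmp_path):
        f = self._write(tmp_path, ["p.R420W,0.05,100", "p.V186M,5e-6,3"])
        assert len(vd.read_population_table(f, af_threshold=1.0)) == 2

    def test_negative_frequency(self, tmp_path):
        f = self._write(tmp_path, ["p.R420W,-0.1,2"])
        with pytest.raises(ValueError, match="negative"):
            vd.read_population_table(f)


class TestMergeCounts:
    def test_counts_summed(self):
        cur = VariantTable([make_record(10, "A", "T", 2, 1)])
        pop = VariantTable([make_record(10, "A", "T", 0, 5)])
        assert merge_counts(cur, pop)[(10, "A", "T")].counts == \
            HeterozygoteCounts(2, 6)

    def test_population_only_passthrough(self):
        pop = VariantTable([make_record(7, "G", "S", 0, 9)])
        merged = merge_counts(VariantTable(), pop)
        assert merged[(7, "G", "S")].counts == HeterozygoteCounts(0, 9)

    def test_conflicting_reference_residue(self):
        cur = VariantTable([make_record(10, "A", "T", 1, 0)])
        pop = VariantTable([make_record(10, "G", "T", 0, 1)])
        with pytest.raises(ValueError, match="conflicting"):
            merge_counts(cur, pop)

    @given(st.data())
    @settings(max_examples=25, deadline=None)
    def test_commutative_over_random_tables(self, data):
        def table(prefix):
            n = data.draw(st.integers(0, 5))
            recs = []
            for i in range(n):
                pos = data.draw(st.integers(1, 8))
                recs.append(make_record(pos, "A", "T",
                                        data.draw(st.integers(0, 5)),
                                        data.draw(st.integers(0, 5))))
            return VariantTable(recs)

        t1, t2 = table("a"), table("b")
        ab = {r.key: (r.counts.affected, r.counts.unaffected)
              for r in merge_counts(t1, t2)}
        ba = {r.key: (r.counts.affected, r.counts.unaffected)
              for r in merge_counts(t2, t1)}
        assert ab == ba


class TestRoundTrip:
    def test_write_read_counts_exact(self, tmp_path, small_table):
        path = tmp_path / "table.csv"
        vd.write_table(small_table, path)
        back = vd.read_table(path)
        assert sorted(back.keys()) == sorted(small_table.keys())
        for key in small_table.keys():
            assert back[key].counts == small_table[key].counts

    def test_finalize_drops_empty_and_weights(self):
        t = VariantTable([make_record(1, "A", "T", 0, 0),
                          make_record(2, "A", "T", 1, 1)])
        final = t.finalize()
        assert len(final) == 1
        assert final[(2, "A", "T")].weight == \
            pytest.approx(evidence_weight(2))
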