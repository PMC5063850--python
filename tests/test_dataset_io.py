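"""Findings grammar, dataset readers/writers, and fixture integrity."""
import pytest

from carcwoe.dataset import (
    Dataset,
    DatasetError,
    DuplicateIdError,
    Finding,
    SchemaError,
    format_finding_list,
    parse_finding_list,
    read_dataset,
    write_dataset,
)
from carcwoe.simulate import SimulationConfig, generate
from carcwoe.vocab import CATEGORIES, UnknownTokenError


class TestFindingsGrammar:
    @pytest.mark.parametrize(
        "cell,with_morph,expected",
        [
            ("tes tu; li ad; li ac", True,
             (Finding("tes", "tu"), Finding("li", "ad"), Finding("li", "ac"))),
            ("–", True, ()),
            ("-", False, ()),
            ("", False, ()),
            ("li; thyr", False, (Finding("li"), Finding("thyr"))),
            # organ codes may contain a space; the split is on the LAST space
            ("soft t sar", True, (Finding("soft t", "sar"),)),
            ("bo most", True, (Finding("bo", "most"),)),
            # duplicates and order preserved (lossless transcription)
            ("stom; ut; stom", False,
             (Finding("stom"), Finding("ut"), Finding("stom"))),
            # trailing separator tolerated
            ("tes ad;", True, (Finding("tes", "ad"),)),
        ],
    )
    def test_parse(self, cell, with_morph, expected):
        assert parse_finding_list(cell, with_morph) == expected

    def test_unresolvable_token_names_row_and_token(self, kb):
        with pytest.raises(UnknownTokenError, match=r"xx.*row 7"):
            parse_finding_list("xx ad", True, kb.vocab, row_id=7)

    def test_bare_tumor_token_rejected(self):
        with pytest.raises(DatasetError, match="morphology"):
            parse_finding_list("li", True)

    def test_format_inverts_parse(self):
        cell = "tes tu; li ad; li ac"
        assert format_finding_list(parse_finding_list(cell, True)) == cell


class TestFixtureIntegrity:
    def test_row_count_and_ids(self, fixture_ds):
        assert len(fixture_ds) == 289
        ids = [rec.compound_id for rec in fixture_ds]
        assert sorted(ids) == list(range(1, 290))

    def test_published_categories_in_enum(self, fixture_ds):
        for rec in fixture_ds:
            assert rec.cat_his_published in CATEGORIES
            assert rec.cat_ph_published in CATEGORIES
            assert rec.cat_final_published in CATEGORIES

    def test_tumor_findings_always_carry_morphology(self, fixture_ds):
        for rec in fixture_ds:
            assert all(f.morphology is not None for f in rec.tumor_findings)
            for f in (rec.weight_findings + rec.hypertrophy_findings
                      + rec.hyperplasia_findings):
                assert f.morphology is None

    def test_peroxisome_flag_only_on_fibrates(self, fixture_ds):
        flagged = {r.compound_id for r in fixture_ds if r.peroxisome_proliferator}
        assert flagged == {
            r.compound_id for r in fixture_ds if r.pharm_class_id == "MB, fibrates"
        }


class TestRoundTrip:
    def test_fixture_round_trips_exactly(self, fixture_ds, kb, tmp_path):
        path = tmp_path / "roundtrip.csv"
        write_dataset(fixture_ds, path)
        again = read_dataset(path, kb.vocab)
        assert again.records == fixture_ds.records

    def test_empty_dataset_writes_header_only(self, tmp_path, kb):
        path = tmp_path / "empty.csv"
        write_dataset(Dataset(), path)
        assert path.read_text().count("\n") == 1
        with pytest.warns(UserWarning, match="empty"):
            again = read_dataset(path, kb.vocab)
        assert len(again) == 0

    def test_synthetic_dataset_row_count(self, tmp_path, kb):
        ds = generate(SimulationConfig(n_classes=10, class_size_min=5,
                                       class_size_max=5, seed=3))
        assert len(ds) == 50
        path = tmp_path / "synthetic.csv"
        write_dataset(ds, path)
        assert path.read_text().count("\n") == 51  # header + 50 data rows

    @pytest.mark.parametrize("seed", [0, 1, 17, 202])
    def test_generated_datasets_round_trip(self, seed, kb, tmp_path):
        """Write/read identity over arbitrary generated datasets."""
        ds = generate(SimulationConfig(n_classes=25, seed=seed))
        path = tmp_path / f"sim{seed}.csv"
        write_dataset(ds, path)
        assert read_dataset(path, kb.vocab).records == ds.records


class TestReaderErrors:
    def test_duplicate_id(self, tmp_path, kb, fixture_ds):
        ds = Dataset(records=[fixture_ds.records[4], fixture_ds.records[4]])
        path = tmp_path / "dup.csv"
        write_dataset(ds, path)
        with pytest.raises(DuplicateIdError, match=str(ds.records[0].compound_id)):
            read_dataset(path, kb.vocab)

    def test_schema_mismatch(self, tmp_path, kb):
        path = tmp_path / "bad.csv"
        path.write_text("compound_id,notes\n1,hello\n", encoding="utf-8")
        with pytest.raises(SchemaError):
            read_dataset(path, kb.vocab)

    def test_unknown_token_carries_row_id(self, tmp_path, kb):
        header = ("compound_id,mode_of_action,therapeutic_area,pharm_class_id,"
                  "single_in_class,peroxisome_proliferator,weight_findings,"
                  "hypertrophy_findings,hyperplasia_findings,tumor_findings,"
                  "cat_his_published,cat_ph_published,cat_final_published\n")
        path = tmp_path / "tok.csv"
        path.write_text(header + '5,"X, thing",ZZ,x,false,false,,,,"qq ad",,,\n',
                        encoding="utf-8")
        with pytest.raises(UnknownTokenError, match=r"qq.*row 5"):
            read_dataset(path, kb.vocab)
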