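import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ageguess.datamodel import (
    MethylomeMatrix,
    align_samples,
    exclude_sex_chromosomes,
    median_impute,
    normalize_chromosome,
)
from ageguess.errors import (
    AlignmentError,
    AnnotationError,
    FormatError,
    RangeError,
    ValidationError,
)
from ageguess.io import (
    read_annotation,
    read_beta_matrix,
    read_metadata,
    write_beta_matrix,
)


class TestBetaMatrixIO:
    def test_round_trip_identity(self, tiny_matrix, tmp_path):
        path = tmp_path / "m.tsv"
        write_beta_matrix(tiny_matrix, path)
        back = read_beta_matrix(path)
        assert back == tiny_matrix

    @settings(max_examples=25, deadline=None)
    @given(data=st.data())
    def test_round_trip_random_matrices(self, data):
        """Write-then-read reproduces ids and float values bit-exactly."""
        import tempfile

        n_probes = data.draw(st.integers(0, 6))
        n_samples = data.draw(st.integers(1, 5))
        vals = np.array(
            [
                [
                    data.draw(
                        st.one_of(
                            st.just(np.nan),
                            st.floats(0, 1, allow_nan=False),
                        )
                    )
                    for _ in range(n_samples)
                ]
                for _ in range(n_probes)
            ]
        ).reshape(n_probes, n_samples)
        m = MethylomeMatrix(
            [f"cg{i}" for i in range(n_probes)],
            [f"s{j}" for j in range(n_samples)],
            vals,
        )
        with tempfile.TemporaryDirectory() as d:
            path = f"{d}/m.tsv"
            write_beta_matrix(m, path)
            assert read_beta_matrix(path) == m

    def test_empty_matrix_writes_header_only(self, tmp_path):
        m = MethylomeMatrix([], ["s1", "s2"], np.empty((0, 2)))
        path = tmp_path / "empty.tsv"
        write_beta_matrix(m, path)
        assert path.read_text().splitlines() == ["probe_id\ts1\ts2"]
        assert read_beta_matrix(path) == m

    def test_missing_value_written_as_canonical_token(self, tiny_matrix, tmp_path):
        path = tmp_path / "m.tsv"
        write_beta_matrix(tiny_matrix, path)
        row = path.read_text().splitlines()[2].split("\t")
        assert row[0] == "cg02" and row[2] == "NA"

    def test_out_of_range_value_is_cited(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("probe_id\ta\tb\ncg1\t0.5\t1.2\n")
        with pytest.raises(RangeError, match="1.2"):
            read_beta_matrix(path)

    def test_ragged_row_reports_line_number(self, tmp_path):
        path = tmp_path / "ragged.tsv"
        path.write_text("probe_id\ta\tb\ncg1\t0.5\t0.6\ncg2\t0.5\n")
        with pytest.raises(FormatError, match="line 3"):
            read_beta_matrix(path)

    def test_duplicate_probe_id_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("probe_id\ta\ncg1\t0.5\ncg1\t0.6\n")
        with pytest.raises(ValidationError, match="cg1"):
            read_beta_matrix(path)

    def test_geo_dialect_matches_plain_parse(self, tmp_path):
        body = "ID_REF\ts1\ts2\ts3\n" + "".join(
            f"cg{i}\t0.{i}\t0.{i + 1}\tNA\n" for i in range(1, 6)
        )
        plain = tmp_path / "plain.tsv"
        plain.write_text(body)
        geo = tmp_path / "geo.txt"
        geo.write_text(
            "!Series_title\t\"x\"\n!Series_platform\t\"GPL13534\"\n"
            "!Sample_count\t3\n!extra\tline\n"
            "!series_matrix_table_begin\n" + body + "!series_matrix_table_end\n"
        )
        a = read_beta_matrix(plain, "plain_tsv")
        b = read_beta_matrix(geo, "geo_series_matrix")
        assert a == b
        assert b.values.shape == (5, 3)

    def test_geo_missing_sentinels_is_format_error(self, tmp_path):
        path = tmp_path / "nosent.txt"
        path.write_text("!Series_title\nID\ts1\ncg1\t0.5\n")
        with pytest.raises(FormatError, match="sentinel"):
            read_beta_matrix(path, "geo_series_matrix")


class TestMetadataAnnotation:
    def test_basic_parse_and_sex_normalisation(self, tmp_path):
        path = tmp_path / "meta.csv"
        path.write_text("sample_id,age,sex\ns1,34,F\ns2,60.5,male\n")
        records = read_metadata(path)
        assert records[0].sample_id == "s1"
        assert records[0].age == 34.0
        assert records[0].sex == "female"
        assert records[1].sex == "male"

    def test_non_positive_age_rejected(self, tmp_path):
        path = tmp_path / "meta.csv"
        path.write_text("sample_id,age,sex\ns2,-1,M\n")
        with pytest.raises(ValidationError):
            read_metadata(path)

    def test_unknown_sex_maps_to_unknown_with_warning(self, tmp_path, caplog):
        path = tmp_path / "meta.csv"
        path.write_text("sample_id,age,sex\ns3,60,xx\n")
        with caplog.at_level(logging.WARNING, logger="ageguess.io"):
            records = read_metadata(path)
        assert records[0].sex == "unknown"
        assert sum("unrecognised sex" in r.message for r in caplog.records) == 1

    def test_annotation_parse(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text("probe_id,chromosome,gene\ncg1,chrX,\ncg2,7,TP53\n")
        records = read_annotation(path)
        assert records[0].gene is None
        assert records[1].gene == "TP53"
        assert normalize_chromosome(records[0].chromosome) == "X"


class TestAlignSamples:
    def test_intersection_in_matrix_order(self, tiny_matrix, tiny_metadata):
        meta = [m for m in tiny_metadata if m.sample_id != "s1"]
        aligned, out_meta = align_samples(tiny_matrix, meta)
        assert aligned.sample_ids == ["s2", "s3"]
        assert [m.sample_id for m in out_meta] == ["s2", "s3"]

    def test_identity_when_ids_match(self, tiny_matrix, tiny_metadata):
        aligned, out_meta = align_samples(tiny_matrix, tiny_metadata)
        assert aligned == tiny_matrix
        assert [m.sample_id for m in out_meta] == tiny_matrix.sample_ids

    def test_disjoint_ids_error(self, tiny_matrix, tiny_metadata):
        meta = [type(m)("other_" + m.sample_id, m.age, m.sex) for m in tiny_metadata]
        with pytest.raises(AlignmentError):
            align_samples(tiny_matrix, meta)


class TestSexChromosomeExclusion:
    def test_xy_probes_removed_in_order(self, tiny_matrix, tiny_annotation):
        out = exclude_sex_chromosomes(tiny_matrix, tiny_annotation)
        assert out.probe_ids == ["cg01", "cg03"]

    def test_all_autosomal_is_identity(self, tiny_matrix, tiny_annotation):
        autosomal = [type(a)(a.probe_id, "5", a.gene) for a in tiny_annotation]
        assert exclude_sex_chromosomes(tiny_matrix, autosomal) == tiny_matrix

    def test_idempotent(self, tiny_matrix, tiny_annotation):
        once = exclude_sex_chromosomes(tiny_matrix, tiny_annotation)
        twice = exclude_sex_chromosomes(once, tiny_annotation)
        assert once == twice

    def test_unannotated_probe_dropped_with_warning(self, tiny_matrix, tiny_annotation, caplog):
        partial = tiny_annotation[:2]  # cg03 missing
        with caplog.at_level(logging.WARNING, logger="ageguess.datamodel"):
            out = exclude_sex_chromosomes(tiny_matrix, partial)
        assert out.probe_ids == ["cg01"]
        assert any("unannotated" in r.message for r in caplog.records)

    def test_unannotated_keep_and_error_policies(self, tiny_matrix, tiny_annotation):
        partial = tiny_annotation[:2]
        kept = exclude_sex_chromosomes(tiny_matrix, partial, unannotated="keep")
        assert kept.probe_ids == ["cg01", "cg03"]
        with pytest.raises(AnnotationError, match="cg03"):
            exclude_sex_chromosomes(tiny_matrix, partial, unannotated="error")


class TestInvariantsAndImputation:
    def test_range_validation_with_clamp_tolerance(self):
        vals = np.array([[1.0 + 5e-10, -5e-10]])
        m = MethylomeMatrix(["cg1"], ["a", "b"], vals)
        assert m.values[0, 0] == 1.0 and m.values[0, 1] == 0.0
        with pytest.raises(RangeError):
            MethylomeMatrix(["cg1"], ["a", "b"], np.array([[0.5, 1.01]]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            MethylomeMatrix(["cg1", "cg2"], ["a"], np.zeros((1, 1)))

    def test_median_impute_uses_training_medians(self):
        vals = np.array([[0.1, np.nan, 0.3], [np.nan, np.nan, np.nan]])
        out = median_impute(vals)
        assert out[0, 1] == pytest.approx(0.2)
        assert np.all(out[1] == 0.5)  # all-missing probe -> midpoint
        given_med = median_impute(vals, medians=np.array([0.7, 0.7]))
        assert given_med[0, 1] == 0.7
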