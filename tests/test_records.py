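"""Record data model, CSV I/O, intake recalculation, filtering, phases."""

import numpy as np
import pytest

from nutrireq import (
    FlockWeekRecord,
    RangeFilterConfig,
    assign_phase,
    compute_intakes,
    filter_records,
    read_records,
    write_records,
)
from nutrireq.exceptions import SchemaError, ValidationError
from nutrireq.records import rejection_frame, stratify_by_phase

VALID_CSV = """flock_id,age_weeks,me_intake,dlys_intake,dmet_intake,dthr_intake,chicks_per_hen_week
f1,28,450,0.95,0.63,0.77,3.1
f2,40,455,1.02,0.66,0.80,4.2
f3,55,448,0.88,0.58,0.69,3.5
"""


def _write(tmp_path, text, name="data.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadWrite:
    def test_valid_csv_reads_three_clean_records(self, tmp_path):
        records = read_records(_write(tmp_path, VALID_CSV), "intakes")
        assert len(records) == 3
        assert all(not r.quality_flags for r in records)
        assert records[0].me_intake == 450.0
        assert records[2].chicks_per_hen_week == 3.5

    def test_empty_response_cell_is_flagged_missing(self, tmp_path):
        text = VALID_CSV.replace("f2,40,455,1.02,0.66,0.80,4.2",
                                 "f2,40,455,1.02,0.66,0.80,")
        records = read_records(_write(tmp_path, text), "intakes")
        assert records[1].chicks_per_hen_week is None
        assert "missing:chicks_per_hen_week" in records[1].quality_flags

    def test_missing_required_column_names_the_column(self, tmp_path):
        text = VALID_CSV.replace("age_weeks,", "").replace("f1,28", "f1").replace(
            "f2,40", "f2").replace("f3,55", "f3")
        with pytest.raises(SchemaError, match="age_weeks"):
            read_records(_write(tmp_path, text), "intakes")

    def test_non_numeric_cell_raises_instead_of_coercing(self, tmp_path):
        text = VALID_CSV.replace("0.95", "high")
        with pytest.raises(SchemaError, match="high"):
            read_records(_write(tmp_path, text), "intakes")

    def test_round_trip_preserves_fields(self, tmp_path):
        records = read_records(_write(tmp_path, VALID_CSV), "intakes")
        out = tmp_path / "out.csv"
        write_records(records, out, "intakes")
        back = read_records(out, "intakes")
        assert back == records


class TestComputeIntakes:
    def test_digestible_lysine_arithmetic(self):
        rec = FlockWeekRecord("f", 30, feed_intake=160.0, lys_conc=0.65,
                              dig_lys=0.85)
        out = compute_intakes(rec)
        assert out.dlys_intake == pytest.approx(0.884)

    def test_me_intake_arithmetic(self):
        rec = FlockWeekRecord("f", 30, feed_intake=160.0, me_conc=2800.0)
        out = compute_intakes(rec)
        assert out.me_intake == pytest.approx(448.0)

    def test_missing_digestibility_leaves_intake_missing_with_flag(self):
        rec = FlockWeekRecord("f", 30, feed_intake=160.0, met_conc=0.45)
        out = compute_intakes(rec)
        assert out.dmet_intake is None
        assert "missing:dig_met" in out.quality_flags

    def test_precomputed_intake_preserved_without_overwrite(self):
        rec = FlockWeekRecord("f", 30, feed_intake=160.0, me_conc=2800.0,
                              me_intake=500.0)
        assert compute_intakes(rec).me_intake == 500.0
        assert compute_intakes(rec, overwrite=True).me_intake == pytest.approx(448.0)

    def test_negative_input_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            FlockWeekRecord("f", 30, feed_intake=-1.0)
        with pytest.raises(ValidationError):
            FlockWeekRecord("f", 30, dig_lys=1.2)


class TestPhases:
    @pytest.mark.parametrize(
        "age,label",
        [(26, "early"), (32, "early"), (33, "mid"), (50, "mid"),
         (51, "late"), (62, "late")],
    )
    def test_boundary_ages(self, age, label):
        assert assign_phase(age) == label

    @pytest.mark.parametrize("age", [25, 63, 0])
    def test_out_of_range_age_errors(self, age):
        with pytest.raises(ValidationError):
            assign_phase(age)

    def test_phase_labels_partition_the_age_window(self):
        labels = [assign_phase(a) for a in range(26, 63)]
        assert set(labels) == {"early", "mid", "late"}
        # each age maps to exactly one label and blocks are contiguous
        assert labels == sorted(labels, key=["early", "mid", "late"].index)

    def test_stratify_groups_by_age(self):
        recs = [FlockWeekRecord("f", a) for a in (26, 40, 60, 33)]
        groups = stratify_by_phase(recs)
        assert [r.age_weeks for r in groups["early"]] == [26]
        assert [r.age_weeks for r in groups["mid"]] == [40, 33]
        assert [r.age_weeks for r in groups["late"]] == [60]


class TestFiltering:
    def test_out_of_range_age_rejected_with_reason(self):
        recs = [FlockWeekRecord("f", 70, chicks_per_hen_week=3.0)]
        config = RangeFilterConfig(bounds={"age_weeks": (26, 62)})
        kept, rejected = filter_records(recs, config)
        assert not kept
        assert rejected[0].reasons == ["range:age_weeks"]

    def test_clean_records_all_kept_unchanged(self):
        recs = [FlockWeekRecord("f", 30, chicks_per_hen_week=3.0,
                                me_intake=450.0) for _ in range(5)]
        config = RangeFilterConfig(bounds={"me_intake": (200, 700)})
        kept, rejected = filter_records(recs, config)
        assert len(kept) == 5 and not rejected
        assert all(r.me_intake == 450.0 for r in kept)

    def test_iqr_fence_rejects_single_extreme_response(self, rng):
        # 100 clustered responses plus one extreme; the Tukey fence
        # (computed independently here) isolates exactly that record.
        values = rng.normal(4.0, 0.2, size=100)
        values[17] = 9.0
        q1, q3 = np.quantile(np.sort(values), [0.25, 0.75])
        fence_hi = q3 + 1.5 * (q3 - q1)
        assert values[17] > fence_hi
        assert np.sum(values > fence_hi) == 1
        recs = [FlockWeekRecord("f", 40, chicks_per_hen_week=float(v))
                for v in values]
        config = RangeFilterConfig(
            iqr_variables=("chicks_per_hen_week",), iqr_reject=True
        )
        kept, rejected = filter_records(recs, config)
        assert len(kept) == 99
        assert rejected[0].reasons == ["iqr:chicks_per_hen_week"]

    def test_iqr_flag_only_by_default(self, rng):
        values = rng.normal(4.0, 0.2, size=50)
        values[3] = 9.0
        recs = [FlockWeekRecord("f", 40, chicks_per_hen_week=float(v))
                for v in values]
        config = RangeFilterConfig(iqr_variables=("chicks_per_hen_week",))
        kept, rejected = filter_records(recs, config)
        assert len(kept) == 50 and not rejected
        assert "iqr:chicks_per_hen_week" in kept[3].quality_flags

    def test_missing_required_field_rejected(self):
        recs = [FlockWeekRecord("f", 30)]
        kept, rejected = filter_records(recs, RangeFilterConfig())
        assert rejected and "missing:chicks_per_hen_week" in rejected[0].reasons

    def test_rejection_frame_has_reason_column(self):
        recs = [FlockWeekRecord("f", 70, chicks_per_hen_week=3.0)]
        _, rejected = filter_records(
            recs, RangeFilterConfig(bounds={"age_weeks": (26, 62)})
        )
        frame = rejection_frame(rejected, "intakes")
        assert list(frame["reject_reason"]) == ["range:age_weeks"]
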