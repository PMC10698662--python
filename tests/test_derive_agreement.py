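import itertools
import math
from datetime import date

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sleepagree.core_time import ClockTime
from sleepagree.derive_agreement import (
    AgreementStats,
    DerivationError,
    GroupKey,
    age_decade,
    agreement_stats,
    bland_altman_points,
    bmi_class,
    classify_participant,
    derive_night,
    participant_means,
    psqi_group,
    qos_is_good,
    stratified_agreement,
)
from sleepagree.qc_match import select_analysis_set, validate_and_match
from sleepagree.records_io import ParticipantProfile, PsqiRecord
from sleepagree.synthetic_cohort import CohortParams, generate_cohort

from conftest import make_chat, make_fitbit


class TestDeriveNight:
    def test_arithmetic_example(self):
        fb = make_fitbit(start="00:20:00", end="07:28:00", minutes_awake=58)
        ch = make_chat(bed="00:15", asleep="00:30", wake="07:20", ast_minutes=390)
        (m,) = validate_and_match([fb], [ch])
        n = derive_night(m)
        assert n.chat_tst == 24600
        assert n.fitbit_tst == 25680
        assert n.fitbit_ast == 22200
        assert n.diff_tst == 25680 - 24600
        assert n.diff_ast == 22200 - 390 * 60
        assert n.diff_onset == -600  # device onset 10 min earlier

    def test_zero_waso_identity(self):
        fb = make_fitbit(start="23:40:00", end="07:05:00", minutes_awake=0)
        ch = make_chat()
        (m,) = validate_and_match([fb], [ch])
        n = derive_night(m)
        assert n.fitbit_ast == n.fitbit_tst

    def test_rejects_invalid_night(self):
        fb = make_fitbit()
        ch = make_chat(bed="23:00", asleep="22:30")
        (m,) = validate_and_match([fb], [ch])
        with pytest.raises(DerivationError):
            derive_night(m)

    def test_ledger_oracle_on_synthetic_nights(self):
        data = generate_cohort(CohortParams(n_participants=15, rng_seed=21))
        frame = data.ledger.frame.set_index(["participant_id", "sleep_date"])
        matched = [m for m in validate_and_match(data.fitbit, data.chat)
                   if m.qc_status == "valid"]
        assert len(matched) >= 200
        for m in matched[:200]:
            n = derive_night(m)
            row = frame.loc[(m.participant_id, m.sleep_date.isoformat())]
            dev_ast = row["true_tst_sec"] - row["fitbit_waso_min"] * 60
            assert n.diff_ast == dev_ast - row["chat_ast_min"] * 60
            span = (row["chat_wake_sec"] - row["chat_asleep_sec"]) % 86400
            assert n.chat_tst == span


class TestAgreementStats:
    def test_printed_loa_pairs_within_tolerance(self):
        # mean -8.65 min with 58.1-min half width
        st_ = AgreementStats.from_summary(543, -519.0, 58.1 * 60 / 1.96)
        assert abs(st_.loa_low / 60 - (-66.8)) <= 0.1
        assert abs(st_.loa_high / 60 - 49.5) <= 0.1

    def test_all_zero_diffs(self):
        st_ = agreement_stats([0.0] * 5)
        assert st_.mean_diff == 0 and st_.loa_low == 0 and st_.loa_high == 0
        assert math.isnan(st_.p_paired_t)

    def test_n_below_2_errors(self):
        with pytest.raises(ValueError):
            agreement_stats([1.0])

    def test_half_width_exact(self):
        st_ = agreement_stats([1.0, 2.0, 3.0, 10.0])
        assert st_.half_width == pytest.approx(1.96 * st_.sd_diff)
        assert st_.loa_low <= st_.mean_diff <= st_.loa_high

    def test_permutation_oracle_small_sample(self):
        diffs = np.array([12.0, -5.0, 20.0, 3.0, -8.0, 15.0, 7.0, -2.0])
        st_ = agreement_stats(diffs)
        # exact sign-flip null, all 2^8 patterns
        obs = abs(diffs.mean())
        count = sum(abs((diffs * np.array(signs)).mean()) >= obs - 1e-12
                    for signs in itertools.product([1, -1], repeat=8))
        p_perm = count / 2 ** 8
        assert p_perm == 0.203125
        assert st_.p_paired_t == pytest.approx(0.18100633037031053)
        assert abs(st_.p_paired_t - p_perm) < 0.05

    @given(st.lists(st.floats(-5000, 5000), min_size=3, max_size=30),
           st.floats(-3000, 3000))
    def test_shift_equivariance(self, diffs, c):
        base = agreement_stats(diffs)
        shifted = agreement_stats([d + c for d in diffs])
        assert shifted.mean_diff == pytest.approx(base.mean_diff + c, abs=1e-6)
        assert shifted.sd_diff == pytest.approx(base.sd_diff, abs=1e-6)
        assert shifted.loa_low == pytest.approx(base.loa_low + c, abs=1e-6)
        assert shifted.loa_high == pytest.approx(base.loa_high + c, abs=1e-6)


class TestClassification:
    @pytest.mark.parametrize("score,group", [(0, "good"), (5, "good"), (6, "poor"),
                                             (21, "poor"), (None, "unclassified")])
    def test_psqi_group(self, score, group):
        assert psqi_group(score) == group

    @pytest.mark.parametrize("bmi,cls", [
        (17.0, "underweight"), (18.5, "normal"), (22.9, "normal"),
        (23.0, "preobese"), (24.9, "preobese"), (25.0, "obesity_1"),
        (29.9, "obesity_1"), (30.0, "obesity_2"), (41.0, "obesity_2"),
    ])
    def test_bmi_class_bounds(self, bmi, cls):
        assert bmi_class(bmi) == cls

    def test_bmi_invalid(self):
        with pytest.raises(ValueError):
            bmi_class(0.0)

    @pytest.mark.parametrize("age,decade", [(30, "30s"), (39, "30s"), (45, "40s"), (59, "50s")])
    def test_age_decade(self, age, decade):
        assert age_decade(age) == decade

    def test_age_invalid(self):
        with pytest.raises(ValueError):
            age_decade(500)

    @pytest.mark.parametrize("qos,good", [("very_good", True), ("quite_good", True),
                                          ("quite_poor", False), ("very_poor", False)])
    def test_qos(self, qos, good):
        assert qos_is_good(qos) is good

    def test_classify_participant(self):
        prof = ParticipantProfile("P1", "women", 44, 22.1)
        psqi = PsqiRecord("P1", ClockTime.from_hms(23, 0), 15, ClockTime.from_hms(7, 0), 7.0, 4)
        labels = classify_participant(prof, psqi)
        assert labels == {"psqi": "good", "gender": "women", "age": "40s", "bmi": "normal"}
        assert classify_participant(prof, None)["psqi"] == "unclassified"


def _analysis_inputs(params):
    data = generate_cohort(params)
    matched = validate_and_match(data.fitbit, data.chat)
    aset = select_analysis_set(matched, fitbit_records=data.fitbit)
    return data, aset


class TestStratifiedAgreement:
    def test_identical_diff_lists_identical_stats(self):
        diffs = [10.0, -20.0, 5.0, 40.0]
        assert agreement_stats(diffs) == agreement_stats(list(diffs))

    def test_qos_bias_recovery(self):
        params = CohortParams(
            n_participants=120, nights_per_participant=14, rng_seed=31,
            report_bias_good_min=19.0, report_bias_poor_min=0.0,
            report_bias_sd_min=90 / 1.96, participant_bias_sd_min=0.0,
        )
        data, aset = _analysis_inputs(params)
        stats_map = stratified_agreement(aset, data.profiles, data.psqi,
                                         variable="ast", axes=("qos",))
        good = stats_map[GroupKey("qos", "good")]
        poor = stats_map[GroupKey("qos", "poor")]
        for st_, bias in ((good, -19.0), (poor, 0.0)):
            ci = 1.96 * st_.sd_diff / math.sqrt(st_.n)
            assert abs(st_.mean_diff / 60 - bias) < ci / 60 + 2.0

    def test_union_count_conservation(self):
        params = CohortParams(n_participants=25, rng_seed=41)
        data, aset = _analysis_inputs(params)
        stats_map = stratified_agreement(aset, data.profiles, data.psqi,
                                         variable="ast", axes=("qos",))
        n_total = sum(st_.n for st_ in stats_map.values() if st_ is not None)
        assert n_total == sum(len(v) for v in aset.participants.values())

    def test_participant_axes_partition_included_set(self):
        params = CohortParams(n_participants=25, rng_seed=43)
        data, aset = _analysis_inputs(params)
        stats_map = stratified_agreement(aset, data.profiles, data.psqi, variable="tst")
        for axis in ("psqi", "gender", "age", "bmi"):
            n_axis = sum((st_.n if st_ is not None else 1)
                         for k, st_ in stats_map.items() if k.axis == axis)
            assert n_axis == aset.n_included

    def test_small_stratum_reports_none(self):
        params = CohortParams(n_participants=25, rng_seed=47)
        data, aset = _analysis_inputs(params)
        # force one participant into a singleton BMI stratum
        profiles = [p if i else ParticipantProfile(p.participant_id, p.gender, p.age_years, 17.0)
                    for i, p in enumerate(data.profiles)]
        stats_map = stratified_agreement(aset, profiles, data.psqi, variable="ast", axes=("bmi",))
        assert stats_map.get(GroupKey("bmi", "underweight")) is None


class TestParticipantMeansAndPoints:
    def test_participant_means_linearity(self):
        params = CohortParams(n_participants=10, rng_seed=51)
        data, aset = _analysis_inputs(params)
        from sleepagree.derive_agreement import nights_by_participant
        for pid, nights in nights_by_participant(aset).items():
            pm = participant_means(pid, nights)
            # TST diff mean = offset diff mean - onset diff mean (same nights)
            assert pm.mean_diffs["tst"] == pytest.approx(
                pm.mean_diffs["offset"] - pm.mean_diffs["onset"], abs=1e-6)
            assert pm.n_nights == len(nights)

    def test_bland_altman_axes(self):
        fb = make_fitbit(start="00:20:00", end="07:28:00", minutes_awake=58)
        ch = make_chat(bed="00:15", asleep="00:30", wake="07:20", ast_minutes=390)
        (m,) = validate_and_match([fb], [ch])
        n = derive_night(m)
        ((x, y),) = bland_altman_points([n], "ast")
        assert x == n.fitbit_ast
        assert y == n.diff_ast
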