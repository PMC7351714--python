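"""Window extraction: interval rules, guard margins, quality filtering."""

import numpy as np
import pytest

from ahecast.annotation import AHEEvent, annotate_record
from ahecast.records import Cohort
from ahecast.synthetic import GeneratorConfig, generate_cohort
from ahecast.windowing import (
    SampleWindow,
    build_dataset,
    extract_negative_windows,
    extract_positive_windows,
    quality_filter,
)

from conftest import make_record


def event(onset, end):
    return AHEEvent(onset_index=onset, end_index=end, drop_fraction_at_onset=0.25)


@pytest.fixture
def long_record():
    return make_record(np.full(500, 90.0), patient_id="pw")


class TestPositiveWindows:
    def test_window_interval_arithmetic(self, long_record):
        windows = extract_positive_windows(long_record, [event(200, 230)], 30, 10)
        assert len(windows) == 1
        assert windows[0].start_index == 160
        assert windows[0].features_raw.shape == (30, 3)
        assert windows[0].label == 1

    def test_window_before_record_start_is_dropped(self, long_record):
        assert extract_positive_windows(long_record, [event(50, 70)], 30, 30) == []

    def test_two_hour_buffer_after_prior_event(self, long_record):
        events = [event(250, 300), event(400, 430)]
        windows = extract_positive_windows(long_record, events, 60, 10)
        # second window [330, 390) starts before 300 + 120 = 420: dropped
        assert [w.start_index for w in windows] == [180]

    def test_gap_controls_window_placement(self, long_record):
        for gap in (10, 20, 30):
            (w,) = extract_positive_windows(long_record, [event(300, 330)], 60, gap)
            assert w.start_index + 60 + gap == 300

    def test_off_grid_lengths_rejected(self, long_record):
        with pytest.raises(ValueError):
            extract_positive_windows(long_record, [], 25, 10)
        with pytest.raises(ValueError):
            extract_positive_windows(long_record, [], 30, 15)


class TestNegativeWindows:
    def test_event_free_record_packs_at_stride(self, long_record):
        windows = extract_negative_windows(long_record, [], 60)
        assert [w.start_index for w in windows] == [0, 60, 120, 180, 240, 300, 360, 420]

    def test_record_fully_covered_by_event_has_no_negatives(self, long_record):
        assert extract_negative_windows(long_record, [event(0, 500)], 60) == []

    def test_guard_regions_respected_around_event(self, long_record):
        windows = extract_negative_windows(long_record, [event(240, 260)], 60)
        starts = [w.start_index for w in windows]
        # no window may intersect the event's guarded zone [120, 380)
        for s in starts:
            assert s + 60 <= 120 or s >= 380
        # greedy packing before and after, verified exhaustively
        assert starts == [0, 60, 380, 440]

    def test_windows_never_overlap(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(240, 900))
            record = make_record(np.full(n, 90.0))
            events = []
            if rng.random() < 0.8:
                o = int(rng.integers(60, n - 30))
                events.append(event(o, min(n, o + 20)))
            windows = extract_negative_windows(record, events, 30)
            spans = sorted((w.start_index, w.start_index + 30) for w in windows)
            for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
                assert a_hi <= b_lo


class TestQualityFilter:
    def _window(self, raw):
        return SampleWindow(
            patient_id="p",
            start_index=0,
            obs_length=raw.shape[0],
            gap_length=10,
            label=0,
            features_raw=raw,
        )

    def test_clean_window_kept(self):
        raw = np.tile([90.0, 80.0, 97.0], (60, 1))
        assert quality_filter(self._window(raw))

    def test_over_ten_percent_erroneous_rejected(self):
        raw = np.tile([90.0, 80.0, 97.0], (60, 1))
        raw.flat[: 19 * 3 : 3] = np.nan  # 19 of 180 samples = 10.6%
        flat = raw.reshape(-1)
        flat[np.arange(19)] = np.nan
        assert not quality_filter(self._window(flat.reshape(60, 3)))

    def test_exactly_ten_percent_kept(self):
        raw = np.tile([90.0, 80.0, 97.0], (60, 1))
        flat = raw.reshape(-1)
        flat[np.arange(18)] = np.nan  # exactly 10%
        assert quality_filter(self._window(flat.reshape(60, 3)))

    def test_out_of_range_counts_as_erroneous(self):
        raw = np.tile([90.0, 80.0, 97.0], (60, 1))
        flat = raw.reshape(-1)
        flat[np.arange(19)] = 250.0
        assert not quality_filter(self._window(flat.reshape(60, 3)))


class TestBuildDataset:
    def _cohort(self, seed=0, n=20, prevalence=0.5):
        return generate_cohort(
            GeneratorConfig(
                n_patients=n,
                ahe_prevalence=prevalence,
                seed=seed,
                missing_rate=0.0,
                artifact_rate=0.0,
                noise_sd=(1.0, 2.0, 0.5),
            )
        )

    def test_eventless_cohort_is_all_negative(self):
        cohort = self._cohort(prevalence=0.0)
        events = {r.patient_id: [] for r in cohort.records}
        ds = build_dataset(cohort, events, 60, 10)
        assert len(ds) > 0
        assert ds.n_pos == 0

    def test_positive_count_matches_detected_planted_events(self):
        cohort = self._cohort(seed=4)
        events = {r.patient_id: annotate_record(r) for r in cohort.records}
        ds = build_dataset(cohort, events, 30, 10)
        eligible = 0
        for record in cohort.records:
            for e in events[record.patient_id]:
                if e.onset_index - 10 - 30 >= 0:
                    eligible += 1
        assert ds.n_pos == eligible
        assert ds.n_pos == len({e.patient_id for e in cohort.planted_events})

    def test_negatives_are_gap_independent(self):
        cohort = self._cohort(seed=6)
        events = {r.patient_id: annotate_record(r) for r in cohort.records}
        a = build_dataset(cohort, events, 30, 10)
        b = build_dataset(cohort, events, 30, 60)
        neg_a = {(p, s) for p, s, y in zip(a.patient_ids, a.start_indices, a.y) if y == 0}
        neg_b = {(p, s) for p, s, y in zip(b.patient_ids, b.start_indices, b.y) if y == 0}
        assert neg_a == neg_b

    def test_processed_features_are_normalized_and_complete(self):
        cohort = generate_cohort(
            GeneratorConfig(n_patients=10, ahe_prevalence=0.5, seed=8)
        )
        events = {r.patient_id: annotate_record(r) for r in cohort.records}
        ds = build_dataset(cohort, events, 60, 10)
        assert not np.any(np.isnan(ds.X))
        assert ds.X.min() >= 0.0 and ds.X.max() <= 1.0
        assert set(np.unique(ds.mask)) <= {0.0, 1.0}

    def test_guard_region_invariant_on_generated_cohorts(self):
        for seed in range(5):
            cohort = self._cohort(seed=seed, n=10)
            events = {r.patient_id: annotate_record(r) for r in cohort.records}
            ds = build_dataset(cohort, events, 60, 10)
            lengths = {r.patient_id: r.length for r in cohort.records}
            for pid, start, label in zip(ds.patient_ids, ds.start_indices, ds.y):
                if label == 1:
                    continue
                for e in events[str(pid)]:
                    end = e.end_index if e.end_index is not None else lengths[str(pid)]
                    assert not (e.onset_index < start + 60 + 120 and end > start - 120)
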