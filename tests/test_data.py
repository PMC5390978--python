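import io

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from dispersalkit.data import (
    CaptureRecord,
    ReleaseEvent,
    aggregate_by_ring,
    build_trap_layout,
    load_fixture,
    read_captures_csv,
    read_releases_csv,
    read_traps_csv,
    ring_summary_frame,
    table1_release_events,
    write_captures_csv,
    write_releases_csv,
    write_traps_csv,
)

EXPECTED_COUNTS = {
    "D170": {40: 6, 80: 12, 160: 24, 320: 48, 640: 40, 960: 40},
    "D200": {40: 24, 80: 24, 160: 24, 320: 48, 640: 40, 960: 40},
}


def _release(rid=1, n_flew=1000, design="D170", retained=True, experience="experienced"):
    return ReleaseEvent(
        release_id=rid,
        date=pd.Timestamp("2014-02-03").date(),
        experience=experience,
        n_placed=2 * n_flew,
        n_flew=n_flew,
        storage_days_min=1,
        storage_days_max=3,
        design_id=design,
        retained=retained,
    )


class TestTrapLayout:
    @pytest.mark.parametrize("design,total", [("D170", 170), ("D200", 200)])
    def test_ring_counts(self, design, total):
        layout = build_trap_layout(design)
        assert len(layout) == total
        assert layout.ring_counts == EXPECTED_COUNTS[design]

    def test_ring_trap_distances_match_nominal(self):
        for design in ("D170", "D200"):
            for trap in build_trap_layout(design).traps:
                tol = 20.0 if trap.ring_m in (640, 960) else 1.0
                assert abs(trap.distance - trap.ring_m) <= tol

    def test_inner_ring_spacing_d200(self):
        # 24 equidistant traps on the 40 m circle sit ~10.4 m apart (chord)
        layout = build_trap_layout("D200")
        pts = np.array([[t.x, t.y] for t in layout.traps if t.ring_m == 40])
        expected = 2 * 40 * np.sin(np.pi / 24)
        assert pdist(pts).min() == pytest.approx(expected, abs=0.1)

    def test_cluster_structure(self):
        layout = build_trap_layout("D170")
        for ring in (640, 960):
            pts = np.array([[t.x, t.y] for t in layout.traps if t.ring_m == ring])
            assert len(pts) == 40
            # within a cluster consecutive traps sit 40 m apart
            for c in range(8):
                cluster = pts[5 * c : 5 * (c + 1)]
                gaps = np.linalg.norm(np.diff(cluster, axis=0), axis=1)
                assert np.allclose(gaps, 40.0, atol=0.5)

    def test_determinism_byte_identical_export(self, tmp_path):
        exports = []
        for _ in range(2):
            buf = io.StringIO()
            build_trap_layout("D200").to_frame().to_csv(buf, index=False)
            exports.append(buf.getvalue())
        assert exports[0] == exports[1]

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError, match="unknown design_id"):
            build_trap_layout("D999")


class TestAggregateByRing:
    def test_empty_captures_give_zero_rows(self):
        layout = build_trap_layout("D170")
        rows = aggregate_by_ring([], layout, [_release(n_flew=875)])
        assert len(rows) == 6
        assert all(r.n_recaptured == 0 and r.pr_percent == 0.0 for r in rows)

    def test_per_trap_percentage_arithmetic(self):
        layout = build_trap_layout("D170")
        caps = [
            CaptureRecord(1, "D170-40-01", 1, n_male=1),
            CaptureRecord(1, "D170-40-03", 1, n_female=1),
        ]
        rows = aggregate_by_ring(caps, layout, [_release(n_flew=1000)])
        ring40 = next(r for r in rows if r.ring_m == 40)
        # 2 captures over 6 traps x 1000 flyers
        assert ring40.pr_percent == pytest.approx(100 * 2 / (6 * 1000))
        assert (ring40.n_male, ring40.n_female) == (1, 1)

    def test_count_conservation_and_exclusion_of_discarded(self):
        layout = build_trap_layout("D170")
        rels = [_release(1), _release(2, retained=False)]
        caps = [
            CaptureRecord(1, "D170-80-01", 3, n_male=3),
            CaptureRecord(1, "D170-960-05", 2, n_female=2),
            CaptureRecord(2, "D170-40-01", 7, n_male=7),  # discarded release
        ]
        rows = aggregate_by_ring(caps, layout, rels)
        assert {r.release_id for r in rows} == {1}
        assert sum(r.n_recaptured for r in rows) == 5

    def test_unresolvable_ids_raise(self):
        layout = build_trap_layout("D170")
        with pytest.raises(KeyError, match="nope"):
            aggregate_by_ring([CaptureRecord(1, "nope", 1, n_male=1)], layout, [_release(1)])
        with pytest.raises(ValueError, match="99"):
            aggregate_by_ring(
                [CaptureRecord(99, "D170-40-01", 1, n_male=1)], layout, [_release(1)]
            )


class TestFixtures:
    def test_release_table_aggregates(self):
        df = load_fixture("table1_releases")
        assert len(df) == 15
        kept = df[df.retained == 1]
        assert int(kept.n_flew.sum()) == 9209
        assert int(kept.n_recaptured.sum()) == 96
        assert not df[df.release_id.isin([6, 10, 12])].retained.any()

    def test_diffusion_param_table_best_row(self):
        df = load_fixture("table3_diffusion_params")
        best = df[(df.model == "heterogeneous") & (df.variance == "power")]
        got = dict(zip(best.param, best.estimate))
        assert got == {"A1_prime": 3.2, "B1": 21.6, "A2_prime": 0.04, "B2": 1022}

    def test_design_fixtures_and_unknown_name(self):
        assert len(load_fixture("design_D170")) == 170
        with pytest.raises(ValueError, match="unknown fixture"):
            load_fixture("table9")

    def test_release_events_validate(self):
        events = table1_release_events()
        assert len(events) == 15
        assert sum(e.n_flew for e in events if e.retained) == 9209


class TestCsvRoundTrips:
    def test_traps(self, tmp_path):
        layout = build_trap_layout("D200")
        p = tmp_path / "traps.csv"
        write_traps_csv(layout, p)
        assert read_traps_csv(p) == layout

    def test_releases(self, tmp_path):
        rels = [_release(1), _release(2, design="D200", retained=False, experience="naive")]
        p = tmp_path / "releases.csv"
        write_releases_csv(rels, p)
        assert read_releases_csv(p) == rels

    def test_captures(self, tmp_path):
        caps = [CaptureRecord(1, "D170-40-01", 3, 1, 1, 1)]
        p = tmp_path / "captures.csv"
        write_captures_csv(caps, p)
        assert read_captures_csv(p) == caps


class TestRecordValidation:
    def test_sex_counts_must_sum(self):
        with pytest.raises(ValueError, match="n_marked"):
            CaptureRecord(1, "t", 3, n_male=1, n_female=1)

    def test_flew_cannot_exceed_placed(self):
        with pytest.raises(ValueError, match="n_flew"):
            _release(n_flew=10).__class__(
                **{**_release().__dict__, "n_placed": 5, "n_flew": 10}
            )

    def test_ring_summary_frame_columns(self):
        layout = build_trap_layout("D170")
        rows = aggregate_by_ring([], layout, [_release()])
        df = ring_summary_frame(rows)
        assert list(df.columns) == [
            "release_id", "ring_m", "n_traps", "n_recaptured",
            "n_flew", "n_male", "n_female", "pr_percent",
        ]
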