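"""Trail domain types, route-table and GPX ingestion, profile segmentation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trailmetrics.errors import FormatError, ValidationError
from trailmetrics.trail_model import (
    Direction,
    RouteSegment,
    TrailProfile,
    Waypoint,
    read_gpx,
    read_segment_table,
    segment_profile,
    write_segment_table,
)
from trailmetrics.synthetic import SynthConfig, synth_gpx, synth_trail


def make_profile(deltas, step_km=0.1, speed=2.0):
    alt = 100.0
    segs = []
    for k, d in enumerate(deltas, start=1):
        direction = (
            Direction.UPHILL if d > 0 else Direction.DOWNHILL if d < 0 else Direction.FLAT
        )
        segs.append(
            RouteSegment(f"Route {k}", step_km, alt, alt + d, speed, direction)
        )
        alt += d
    return TrailProfile("toy", tuple(segs))


class TestTypes:
    def test_total_distance_is_sum_of_segments(self):
        p = make_profile([5, -3, 2])
        assert p.total_distance_km == pytest.approx(0.3, abs=1e-9)
        assert p.ascent_m == 7 and p.descent_m == 3

    def test_direction_must_match_altitude_change(self):
        with pytest.raises(ValidationError):
            RouteSegment("r", 0.1, 100, 90, 2, Direction.UPHILL)
        with pytest.raises(ValidationError):
            RouteSegment("r", 0.1, 100, 110, 2, Direction.DOWNHILL)
        with pytest.raises(ValidationError):
            RouteSegment("r", 0.1, 100, 110, 2, Direction.FLAT)

    def test_segments_must_chain_altitudes(self):
        a = RouteSegment("a", 0.1, 100, 110, 2, Direction.UPHILL)
        b = RouteSegment("b", 0.1, 200, 190, 2, Direction.DOWNHILL)
        with pytest.raises(ValidationError):
            TrailProfile("bad", (a, b))

    def test_waypoint_rejects_negative_distance(self):
        with pytest.raises(ValidationError):
            Waypoint(-0.1, 100)


class TestSegmentTable:
    def test_sitio_fundao_total(self, sitio_fundao):
        assert sitio_fundao.total_distance_km == pytest.approx(1.7)
        assert len(sitio_fundao.segments) == 10

    def test_two_row_additivity(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text(
            "route,altitude_end_m,distance_km,speed_kmh,direction\n"
            "start,100,0,,\nA,110,0.3,4,uphill\nB,105,0.7,4,downhill\n"
        )
        p = read_segment_table(f)
        assert p.total_distance_km == pytest.approx(1.0)

    def test_missing_column_names_it(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text("route,altitude_end_m,speed_kmh,direction\nstart,100,,\n")
        with pytest.raises(FormatError, match="distance_km"):
            read_segment_table(f)

    def test_empty_data_section_rejected(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text("route,altitude_end_m,distance_km,speed_kmh,direction\n")
        with pytest.raises(ValidationError):
            read_segment_table(f)

    def test_negative_distance_rejected(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text(
            "route,altitude_end_m,distance_km,speed_kmh,direction\n"
            "start,100,0,,\nA,110,-0.3,4,uphill\n"
        )
        with pytest.raises(ValidationError):
            read_segment_table(f)

    @pytest.mark.parametrize("fixture", ["sitio_fundao", "pontal", "missao_velha"])
    def test_write_read_round_trip(self, fixture, request, tmp_path):
        profile = request.getfixturevalue(fixture)
        out = tmp_path / "rt.csv"
        write_segment_table(profile, out)
        again = read_segment_table(out, name=profile.name)
        assert again == profile


class TestGpx:
    def test_two_points(self, tmp_path):
        gpx = tmp_path / "t.gpx"
        # ~1 km east along the equator: 1 km / (R) rad of longitude
        dlon = math.degrees(1.0 / 6371.0088)
        gpx.write_text(
            '<?xml version="1.0"?><gpx version="1.1" '
            'xmlns="http://www.topografix.com/GPX/1/1"><trk><trkseg>'
            f'<trkpt lat="0" lon="0"><ele>100</ele></trkpt>'
            f'<trkpt lat="0" lon="{dlon}"><ele>110</ele></trkpt>'
            "</trkseg></trk></gpx>"
        )
        wps = read_gpx(gpx)
        assert wps[0].cumulative_distance_km == 0.0
        assert wps[0].altitude_m == 100
        assert wps[1].cumulative_distance_km == pytest.approx(1.0, rel=1e-6)
        assert wps[1].altitude_m == 110

    def test_single_point(self, tmp_path):
        gpx = tmp_path / "t.gpx"
        gpx.write_text(
            '<gpx version="1.1"><trk><trkseg>'
            '<trkpt lat="0" lon="0"><ele>5</ele></trkpt>'
            "</trkseg></trk></gpx>"
        )
        wps = read_gpx(gpx)
        assert len(wps) == 1 and wps[0].cumulative_distance_km == 0.0

    def test_missing_elevation_is_an_error(self, tmp_path):
        gpx = tmp_path / "t.gpx"
        gpx.write_text(
            '<gpx version="1.1"><trk><trkseg>'
            '<trkpt lat="0" lon="0"/></trkseg></trk></gpx>'
        )
        with pytest.raises(FormatError, match="elevation"):
            read_gpx(gpx)

    def test_synthetic_track_arc_length(self, tmp_path):
        text, true_km = synth_gpx(SynthConfig(seed=7), n_points=100)
        gpx = tmp_path / "s.gpx"
        gpx.write_text(text)
        wps = read_gpx(gpx)
        assert len(wps) == 100
        assert wps[-1].cumulative_distance_km == pytest.approx(true_km, rel=1e-3)


class TestSegmentProfile:
    def test_monotone_ascent_is_one_segment(self):
        wps = [Waypoint(0.1 * i, 100 + 5 * i) for i in range(10)]
        p = segment_profile(wps, min_elev_change_m=0)
        assert len(p.segments) == 1
        assert p.segments[0].direction is Direction.UPHILL

    def test_v_profile_is_down_then_up(self):
        wps = [Waypoint(0, 100), Waypoint(0.5, 50), Waypoint(1.0, 120)]
        p = segment_profile(wps, min_elev_change_m=0)
        assert [s.direction for s in p.segments] == [Direction.DOWNHILL, Direction.UPHILL]

    def test_small_runs_merge_into_neighbour(self):
        # 10 m up, 0.5 m down blip, 10 m up -> one uphill segment at 1 m threshold
        wps = [
            Waypoint(0.0, 100),
            Waypoint(0.3, 110),
            Waypoint(0.4, 109.5),
            Waypoint(0.7, 119.5),
        ]
        p = segment_profile(wps, min_elev_change_m=1.0)
        assert len(p.segments) == 1
        assert p.segments[0].direction is Direction.UPHILL
        assert p.total_distance_km == pytest.approx(0.7)

    def test_fewer_than_two_waypoints_rejected(self):
        with pytest.raises(ValidationError):
            segment_profile([Waypoint(0, 100)])

    def test_recovers_generator_breakpoints(self):
        cfg = SynthConfig(seed=3, n_routes=6, alternate_signs=True)
        profile, wps, truth = synth_trail(cfg)
        seg = segment_profile(wps, min_elev_change_m=0, surface_speed_kmh=2.0)
        assert len(seg.segments) == truth.n_segments == 6
        assert [1 if s.direction is Direction.UPHILL else -1 for s in seg.segments] == list(
            truth.segment_signs
        )
        assert seg.total_distance_km == pytest.approx(truth.total_km, rel=1e-9)

    @given(
        alts=st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=30),
        thresh=st.floats(0, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_distance_conservation(self, alts, thresh):
        """Segment distances always sum to the track length."""
        wps = [Waypoint(0.05 * i, 100 + a) for i, a in enumerate(alts)]
        try:
            p = segment_profile(wps, min_elev_change_m=thresh)
        except ValidationError:
            return  # zero-length degenerate track
        assert p.total_distance_km == pytest.approx(
            wps[-1].cumulative_distance_km, abs=1e-9
        )
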