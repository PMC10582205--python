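"""organizer: segmentation state machine, side assignment, folder layout."""

import filecmp
from pathlib import Path

import pytest

from embryosort.detector import BoundingBox, Detection, FrameDetections
from embryosort.organizer import (
    FolderLayout,
    OrganizerState,
    assign_sides,
    crop_and_save,
    organize,
    patient_id,
    segment_stream,
)


def _stream(counts):
    """Detection stream with `counts[i]` dummy detections at frame i."""
    out = []
    for i, c in enumerate(counts):
        dets = [
            Detection(BoundingBox(10 + 100 * j, 10, 60 + 100 * j, 60), 0.9)
            for j in range(c)
        ]
        out.append(FrameDetections(frame_index=i, detections=dets))
    return out


class TestSegmentStream:
    def test_hand_traced_state_machine(self):
        counts = [0, 0, 2, 2, 2, 0, 0, 0, 2, 2, 0]
        segs = segment_stream(_stream(counts), gap_frames=2, min_len_frames=2)
        assert [(s.first_frame, s.last_frame) for s in segs] == [(2, 4), (8, 9)]
        assert [s.drop_index for s in segs] == [1, 2]

    def test_all_empty_yields_no_segments(self):
        assert segment_stream(_stream([0] * 12), 2, 2) == []

    def test_uninterrupted_detections_yield_one_segment(self):
        segs = segment_stream(_stream([2] * 20), 5, 5)
        assert [(s.first_frame, s.last_frame) for s in segs] == [(0, 19)]

    def test_short_segments_discarded_without_consuming_index(self):
        # a 1-frame blip, then a real segment: survivor must be drop 1
        counts = [0, 2, 0, 0, 0, 2, 2, 2, 2, 2, 0]
        segs = segment_stream(_stream(counts), gap_frames=2, min_len_frames=3)
        assert [(s.drop_index, s.first_frame, s.last_frame) for s in segs] == [
            (1, 5, 9)
        ]

    def test_gap_shorter_than_hysteresis_does_not_split(self):
        counts = [2, 2, 0, 0, 2, 2]
        segs = segment_stream(_stream(counts), gap_frames=3, min_len_frames=2)
        assert [(s.first_frame, s.last_frame) for s in segs] == [(0, 5)]

    def test_empty_stream_is_not_an_error(self):
        assert segment_stream([], 2, 2) == []

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            segment_stream(_stream([1]), gap_frames=0, min_len_frames=1)


def _det(xc, yc=50.0, conf=0.9, size=40.0):
    return Detection(
        BoundingBox(xc - size / 2, yc - size / 2, xc + size / 2, yc + size / 2), conf
    )


class TestAssignSides:
    def test_smaller_x_center_goes_left(self):
        state = OrganizerState()
        got = assign_sides([_det(300), _det(100)], state)
        assert got[1].box.x_center == 100 and got[2].box.x_center == 300

    def test_three_detections_drop_lowest_confidence(self):
        state = OrganizerState()
        got = assign_sides(
            [_det(100, conf=0.9), _det(300, conf=0.8), _det(200, conf=0.3)], state
        )
        assert got[1].box.x_center == 100 and got[2].box.x_center == 300

    def test_x_tie_broken_by_smaller_y(self):
        state = OrganizerState()
        got = assign_sides([_det(100, yc=90), _det(100, yc=30)], state)
        assert got[1].box.y_center == 30 and got[2].box.y_center == 90

    def test_lone_detection_follows_nearest_history_mean(self):
        state = OrganizerState(left_history=[105.0], right_history=[290.0])
        got = assign_sides([_det(110)], state)
        assert list(got) == [1]
        got = assign_sides([_det(260)], state)
        assert list(got) == [2]

    def test_lone_detection_without_history_defaults_left(self):
        got = assign_sides([_det(400)], OrganizerState())
        assert list(got) == [1]

    def test_history_updated_with_assignments(self):
        state = OrganizerState()
        assign_sides([_det(100), _det(300)], state)
        assert state.left_history == [100.0] and state.right_history == [300.0]

    def test_empty_detections_is_contract_violation(self):
        with pytest.raises(ValueError):
            assign_sides([], OrganizerState())


class TestFolderLayout:
    def test_rendered_path_matches_convention(self, tmp_path):
        layout = FolderLayout(day=3, patient_id=patient_id(3, 1), medium_index=1, embryo_index=1)
        assert layout.path() == Path("Day_3/D3_001/Medium_01/Embryo_01")

    def test_patient_id_zero_padding(self):
        assert patient_id(5, 12) == "D5_012"

    @pytest.mark.parametrize("kwargs", [
        {"day": 4, "patient_id": "D4_001", "medium_index": 1, "embryo_index": 1},
        {"day": 3, "patient_id": "D3_001", "medium_index": 0, "embryo_index": 1},
        {"day": 3, "patient_id": "D3_001", "medium_index": 1, "embryo_index": 3},
    ])
    def test_invalid_layouts_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FolderLayout(**kwargs)


class TestCropAndSave:
    def test_crop_geometry_and_naming(self, tmp_path, mini_video):
        frames, _ = mini_video
        layout = FolderLayout(3, "D3_001", 1, 1)
        det = _det(50, 50, size=20)
        path = crop_and_save(frames[0], det, layout, seq=1, root=tmp_path)
        assert path == tmp_path / "Day_3/D3_001/Medium_01/Embryo_01/image_01.jpg"
        from PIL import Image

        assert Image.open(path).size == (20, 20)

    def test_box_past_edge_is_clamped(self, tmp_path, mini_video):
        frames, _ = mini_video
        w = frames[0].width
        det = Detection(BoundingBox(w - 10, 10, w + 30, 50), 0.9)
        path = crop_and_save(frames[0], det, FolderLayout(3, "D3_001", 1, 2), 1, tmp_path)
        from PIL import Image

        assert Image.open(path).size == (10, 40)

    def test_zero_area_crop_skipped_with_warning(self, tmp_path, mini_video, caplog):
        frames, _ = mini_video
        h = frames[0].height
        det = Detection(BoundingBox(10, h + 5, 50, h + 45), 0.9)
        with caplog.at_level("WARNING"):
            out = crop_and_save(frames[0], det, FolderLayout(3, "D3_001", 1, 1), 1, tmp_path)
        assert out is None
        assert not (tmp_path / "Day_3").exists()


class TestOrganize:
    def test_three_drop_video_yields_six_embryo_folders(self, tmp_path, three_drop_video):
        frames, manifest = three_drop_video
        report = organize(
            frames, manifest.to_detections(), day=3, patient="D3_001",
            out_root=tmp_path, target_fps=manifest.fps,
        )
        assert len(report.segments) == 3
        folders = sorted(tmp_path.glob("Day_3/D3_001/Medium_*/Embryo_*"))
        assert len(folders) == 6
        assert report.n_folders == 6
        media = sorted({f.parent.name for f in folders})
        assert media == ["Medium_01", "Medium_02", "Medium_03"]

    def test_no_detections_yields_empty_report(self, tmp_path, mini_video):
        frames, _ = mini_video
        empty = [FrameDetections(frame_index=f.index) for f in frames]
        report = organize(frames, empty, 3, "D3_001", tmp_path)
        assert report.segments == [] and report.total_crops == 0
        assert not any(tmp_path.iterdir())

    def test_one_drop_two_embryos_two_folders(self, tmp_path, mini_video):
        frames, manifest = mini_video
        report = organize(
            frames, manifest.to_detections(), 3, "D3_001", tmp_path,
            target_fps=manifest.fps,
        )
        folders = sorted(tmp_path.glob("Day_3/D3_001/Medium_01/Embryo_*"))
        assert [f.name for f in folders] == ["Embryo_01", "Embryo_02"]

    def test_left_folder_sources_left_of_right(self, tmp_path, mini_video):
        frames, manifest = mini_video
        organize(frames, manifest.to_detections(), 3, "D3_001", tmp_path,
                 target_fps=manifest.fps)
        for mf in manifest.frames:
            if mf.phase == "clear":
                xs = {b["side"]: (b["box"][0] + b["box"][2]) / 2 for b in mf.boxes}
                assert xs["left"] < xs["right"]

    def test_crop_numbering_gapless_per_folder(self, tmp_path, mini_video):
        frames, manifest = mini_video
        report = organize(frames, manifest.to_detections(), 3, "D3_001", tmp_path,
                          target_fps=manifest.fps)
        for folder, count in report.crops_per_folder.items():
            names = sorted(p.name for p in (tmp_path / folder).glob("*.jpg"))
            assert names == [f"image_{i:02d}.jpg" for i in range(1, count + 1)]

    def test_rerun_is_byte_identical(self, tmp_path, mini_video):
        frames, manifest = mini_video
        outs = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            organize(frames, manifest.to_detections(), 3, "D3_001", out,
                     target_fps=manifest.fps)
            outs.append(out)
        files_a = sorted(p.relative_to(outs[0]) for p in outs[0].rglob("*.jpg"))
        files_b = sorted(p.relative_to(outs[1]) for p in outs[1].rglob("*.jpg"))
        assert files_a == files_b
        for rel in files_a:
            assert filecmp.cmp(outs[0] / rel, outs[1] / rel, shallow=False)

    def test_segments_match_manifest_clear_phases(self, tmp_path, three_drop_video):
        frames, manifest = three_drop_video
        gap = 5
        report = organize(
            frames, manifest.to_detections(include_ramp=False), 3, "D3_001",
            tmp_path, gap_frames=gap, target_fps=manifest.fps,
        )
        bounds = manifest.clear_phase_bounds()
        assert len(report.segments) == len(bounds) == 3
        for seg, (first, last) in zip(report.segments, bounds):
            assert abs(seg.first_frame - first) <= gap
            assert abs(seg.last_frame - last) <= gap
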