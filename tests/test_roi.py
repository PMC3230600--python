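"""ROI model: ImageJ binary codec, JSON sidecar, rasterization, pairing."""

import math
import struct
import zipfile

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nemaquant import (Roi, RoiSet, pair_background, read_imagej_roi,
                       read_roi_archive, roi_centroid, roi_mask,
                       roi_set_from_json, roi_set_to_json, write_imagej_roi,
                       write_roi_archive)
from nemaquant.roi import (PairingError, RoiFormatError,
                           UnsupportedShapeError, classify_roi_name)

from conftest import brute_force_mask


def encode_imagej_rect(top, left, bottom, right, roi_type=1):
    """Independent ImageJ .roi writer following the published big-endian
    layout: 'Iout' magic, version short, type byte, bbox shorts at 8-15."""
    buf = bytearray(64)
    buf[0:4] = b"Iout"
    struct.pack_into(">h", buf, 4, 218)
    buf[6] = roi_type
    struct.pack_into(">4h", buf, 8, top, left, bottom, right)
    return bytes(buf)


def encode_imagej_polygon(vertices):
    xs = [x for x, _ in vertices]
    ys = [y for _, y in vertices]
    left, top = min(xs), min(ys)
    buf = bytearray(64)
    buf[0:4] = b"Iout"
    struct.pack_into(">h", buf, 4, 218)
    buf[6] = 0
    struct.pack_into(">4h", buf, 8, top, left, max(ys), max(xs))
    struct.pack_into(">h", buf, 16, len(xs))
    body = struct.pack(f">{len(xs)}h", *(x - left for x in xs))
    body += struct.pack(f">{len(ys)}h", *(y - top for y in ys))
    return bytes(buf) + body


class TestImageJCodec:
    def test_rectangle_decodes_bounding_box(self):
        raw = encode_imagej_rect(top=10, left=20, bottom=30, right=60)
        roi = read_imagej_roi(raw)
        assert roi.shape_kind == "rectangle"
        assert roi.vertices == [(20.0, 10.0), (60.0, 30.0)]

    def test_polygon_decodes_absolute_vertices(self):
        verts = [(5, 7), (25, 9), (14, 31)]
        roi = read_imagej_roi(encode_imagej_polygon(verts))
        assert roi.shape_kind == "polygon"
        assert roi.vertices == [(float(x), float(y)) for x, y in verts]

    def test_oval_type_code(self):
        roi = read_imagej_roi(encode_imagej_rect(0, 0, 10, 10, roi_type=2))
        assert roi.shape_kind == "oval"

    def test_bad_magic_rejected(self):
        raw = b"Xout" + encode_imagej_rect(1, 1, 5, 5)[4:]
        with pytest.raises(RoiFormatError, match="Iout"):
            read_imagej_roi(raw)

    def test_unsupported_type_names_code(self):
        raw = encode_imagej_rect(0, 0, 5, 5, roi_type=3)  # line
        with pytest.raises(UnsupportedShapeError, match="3"):
            read_imagej_roi(raw)

    @settings(derandomize=True, max_examples=50)
    @given(st.data())
    def test_write_read_identity(self, data):
        kind = data.draw(st.sampled_from(["rectangle", "oval", "polygon",
                                          "freehand"]))
        if kind in ("rectangle", "oval"):
            x1 = data.draw(st.integers(0, 200))
            y1 = data.draw(st.integers(0, 200))
            w = data.draw(st.integers(1, 100))
            h = data.draw(st.integers(1, 100))
            verts = [(x1, y1), (x1 + w, y1 + h)]
        else:
            n = data.draw(st.integers(3, 12))
            verts = [(data.draw(st.integers(0, 500)),
                      data.draw(st.integers(0, 500))) for _ in range(n)]
        roi = Roi("r", "other", kind, verts)
        back = read_imagej_roi(write_imagej_roi(roi), name="r")
        assert back.shape_kind == kind
        assert back.vertices == roi.vertices


class TestArchive:
    def test_zip_roundtrip_maps_tissues(self, tmp_path):
        rs = RoiSet([
            Roi("intestine", "intestine", "rectangle", [(0, 0), (10, 10)]),
            Roi("bg1", "background", "oval", [(20, 20), (30, 30)]),
        ], image_ref="img1")
        path = tmp_path / "img1_rois.zip"
        write_roi_archive(rs, path)
        back = read_roi_archive(path)
        assert {r.tissue for r in back} == {"intestine", "background"}
        assert {r.name for r in back} == {"intestine", "bg1"}

    def test_single_roi_file(self, tmp_path):
        roi = Roi("pharynx", "pharynx", "oval", [(1, 1), (9, 9)])
        path = tmp_path / "pharynx.roi"
        path.write_bytes(write_imagej_roi(roi))
        rs = read_roi_archive(path)
        assert len(rs) == 1 and rs.rois[0].tissue == "pharynx"

    def test_non_roi_entry_skipped(self, tmp_path, caplog):
        path = tmp_path / "mixed.zip"
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("bg.roi", write_imagej_roi(
                Roi("bg", "background", "rectangle", [(0, 0), (5, 5)])))
            zf.writestr("notes.txt", "not a roi")
        rs = read_roi_archive(path)
        assert len(rs) == 1

    def test_empty_archive_errors(self, tmp_path):
        path = tmp_path / "empty.zip"
        with zipfile.ZipFile(path, "w"):
            pass
        with pytest.raises(RoiFormatError, match="no ROI"):
            read_roi_archive(path)


class TestJsonSidecar:
    def test_roundtrip_identity(self):
        rs = RoiSet([
            Roi("intestine", "intestine", "polygon", [(0, 0), (9, 2), (4, 8)]),
            Roi("bg", "background", "oval", [(12, 12), (20, 18)]),
        ], image_ref="sec1")
        back = roi_set_from_json(roi_set_to_json(rs))
        assert back.image_ref == "sec1"
        for a, b in zip(rs, back):
            assert (a.name, a.tissue, a.shape_kind, a.vertices) == \
                   (b.name, b.tissue, b.shape_kind, b.vertices)

    def test_missing_tissue_names_roi(self):
        text = ('{"image_ref": "x", "rois": [{"name": "oops", '
                '"shape_kind": "rectangle", "vertices": [[0,0],[5,5]]}]}')
        with pytest.raises(RoiFormatError, match="oops"):
            roi_set_from_json(text)

    def test_empty_set_valid(self):
        assert len(roi_set_from_json('{"image_ref": "x", "rois": []}')) == 0


class TestMask:
    def test_half_open_rectangle_area(self):
        roi = Roi("r", "other", "rectangle", [(2, 2), (5, 4)])
        assert roi_mask(roi, 10, 10).sum() == 6  # 3 columns x 2 rows

    def test_triangle_matches_brute_force(self, triangle_roi):
        mask = roi_mask(triangle_roi, 10, 10)
        oracle = brute_force_mask(triangle_roi, 10, 10)
        assert np.array_equal(mask, oracle)

    def test_full_image_oval_area_is_quarter_pi(self):
        roi = Roi("o", "other", "oval", [(0, 0), (200, 200)])
        frac = roi_mask(roi, 200, 200).sum() / (200 * 200)
        assert frac == pytest.approx(math.pi / 4, rel=0.02)

    @settings(derandomize=True, max_examples=30)
    @given(st.data())
    def test_random_shapes_match_brute_force(self, data):
        kind = data.draw(st.sampled_from(["rectangle", "oval", "polygon"]))
        if kind == "polygon":
            n = data.draw(st.integers(3, 8))
            verts = [(data.draw(st.integers(0, 40)),
                      data.draw(st.integers(0, 40))) for _ in range(n)]
        else:
            x1 = data.draw(st.integers(0, 30))
            y1 = data.draw(st.integers(0, 30))
            verts = [(x1, y1), (x1 + data.draw(st.integers(1, 30)),
                                y1 + data.draw(st.integers(1, 30)))]
        roi = Roi("r", "other", kind, verts)
        assert np.array_equal(roi_mask(roi, 48, 48),
                              brute_force_mask(roi, 48, 48))


class TestCentroid:
    def test_rectangle_centroid_half_open(self):
        roi = Roi("r", "other", "rectangle", [(0, 0), (10, 10)])
        assert roi_centroid(roi) == (4.5, 4.5)

    def test_single_pixel(self):
        roi = Roi("r", "other", "rectangle", [(3, 7), (4, 8)])
        assert roi_centroid(roi) == (3.0, 7.0)

    def test_degenerate_polygon_falls_back_to_vertex_mean(self):
        # collinear vertices: empty mask
        roi = Roi("r", "other", "polygon", [(0, 0), (4, 4), (8, 8)])
        cx, cy = roi_centroid(roi)
        assert (cx, cy) == (4.0, 4.0)


class TestPairing:
    @staticmethod
    def _pt_roi(name, tissue, x, y):
        return Roi(name, tissue, "rectangle", [(x, y), (x + 1, y + 1)])

    def test_distance_tie_breaks_by_list_order(self):
        tissue = self._pt_roi("t", "intestine", 0, 0)
        bg_a = self._pt_roi("a", "background", 5, 0)
        bg_b = self._pt_roi("b", "background", 3, 4)
        pairs = pair_background([tissue], [bg_a, bg_b])
        assert pairs[0].background_roi.name == "a"
        assert pairs[0].distance == pytest.approx(5.0)

    def test_single_pair(self):
        t = self._pt_roi("t", "pharynx", 2, 2)
        b = self._pt_roi("b", "background", 9, 9)
        pairs = pair_background([t], [b])
        assert pairs[0].background_roi.name == "b"

    def test_no_background_instructs_annotation(self):
        with pytest.raises(PairingError, match="background"):
            pair_background([self._pt_roi("t", "intestine", 0, 0)], [])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        tissues = [self._pt_roi(f"t{i}", "intestine",
                                int(rng.integers(0, 100)),
                                int(rng.integers(0, 100)))
                   for i in range(10)]
        bgs = [self._pt_roi(f"b{i}", "background",
                            int(rng.integers(0, 100)),
                            int(rng.integers(0, 100)))
               for i in range(4)]
        pairs = pair_background(tissues, bgs)
        for t, p in zip(tissues, pairs):
            cx, cy = roi_centroid(t)
            dists = [math.hypot(cx - roi_centroid(b)[0],
                                cy - roi_centroid(b)[1]) for b in bgs]
            assert p.background_roi.name == bgs[int(np.argmin(dists))].name

    def test_translation_invariance(self):
        rng = np.random.default_rng(42)
        coords = rng.integers(0, 80, size=(8, 2))
        tissues = [self._pt_roi(f"t{i}", "intestine", int(x), int(y))
                   for i, (x, y) in enumerate(coords[:5])]
        bgs = [self._pt_roi(f"b{i}", "background", int(x), int(y))
               for i, (x, y) in enumerate(coords[5:])]
        base = [p.background_roi.name for p in pair_background(tissues, bgs)]
        dx, dy = 13, 29
        tissues2 = [self._pt_roi(r.name, "intestine",
                                 int(r.vertices[0][0] + dx),
                                 int(r.vertices[0][1] + dy)) for r in tissues]
        bgs2 = [self._pt_roi(r.name, "background",
                             int(r.vertices[0][0] + dx),
                             int(r.vertices[0][1] + dy)) for r in bgs]
        shifted = [p.background_roi.name for p in pair_background(tissues2, bgs2)]
        assert base == shifted


def test_tissue_vocabulary_prefix_match():
    assert classify_roi_name("Intestine_2") == "intestine"
    assert classify_roi_name("bg1") == "background"
    assert classify_roi_name("BODY_wall") == "body_wall"
    assert classify_roi_name("gonad_proximal") == "germline_proximal"
    assert classify_roi_name("mystery") == "other"


def test_invariants_rejected():
    with pytest.raises(ValueError):
        Roi("r", "other", "polygon", [(0, 0), (1, 1)])  # too few vertices
    with pytest.raises(ValueError):
        Roi("r", "other", "rectangle", [(5, 5), (2, 2)])  # inverted corners
    with pytest.raises(ValueError):
        Roi("r", "other", "rectangle", [(-1, 0), (5, 5)])  # negative coord
    with pytest.raises(ValueError):
        RoiSet([Roi("a", "other", "oval", [(0, 0), (2, 2)]),
                Roi("a", "other", "oval", [(3, 3), (5, 5)])])  # dup names
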