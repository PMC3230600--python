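"""Regions of interest: data model, ImageJ .roi binary I/O, JSON sidecars,
rasterization, and tissue-to-background pairing.

Coordinate convention: 0-based, x rightward, y downward, pixel centers at
integer coordinates.  Rectangles and ovals are stored as two bounding-box
corners and rasterized half-open ([x1, x2) x [y1, y2)) so that areas add up
without double counting.  Polygons and freehand outlines use the even-odd
(ray-crossing) rule on pixel centers.
"""

from __future__ import annotations

import io
import json
import logging
import math
import struct
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

TISSUES = (
    "intestine",
    "body_wall",
    "pharynx",
    "head",
    "germline_distal",
    "germline_proximal",
    "embryo",
    "background",
    "other",
)

SHAPE_KINDS = ("polygon", "rectangle", "oval", "freehand")

# ImageJ ROI type codes (byte 6 of the header).
_IJ_POLYGON = 0
_IJ_RECT = 1
_IJ_OVAL = 2
_IJ_FREEHAND = 7
_IJ_TYPE_TO_KIND = {
    _IJ_POLYGON: "polygon",
    _IJ_RECT: "rectangle",
    _IJ_OVAL: "oval",
    _IJ_FREEHAND: "freehand",
}
_KIND_TO_IJ_TYPE = {v: k for k, v in _IJ_TYPE_TO_KIND.items()}

# Case-insensitive name prefixes used to infer the tissue class of an ROI
# from its file name when no explicit label is available.
_TISSUE_PREFIXES = (
    ("background", "background"),
    ("bg", "background"),
    ("intestine", "intestine"),
    ("body", "body_wall"),
    ("pharynx", "pharynx"),
    ("head", "head"),
    ("gonad_distal", "germline_distal"),
    ("gonad_proximal", "germline_proximal"),
    ("germline_distal", "germline_distal"),
    ("germline_proximal", "germline_proximal"),
    ("germ", "germline_distal"),
    ("embryo", "embryo"),
)


class RoiFormatError(ValueError):
    """Malformed or unrecognized ROI data."""


class UnsupportedShapeError(RoiFormatError):
    """ImageJ ROI type code outside the supported area shapes."""


class PairingError(ValueError):
    """Tissue/background pairing cannot be formed."""


def classify_roi_name(name: str) -> str:
    """Map an ROI name onto the tissue vocabulary by case-insensitive
    prefix match; unmatched names fall back to ``other``."""
    low = name.lower()
    for prefix, tissue in _TISSUE_PREFIXES:
        if low.startswith(prefix):
            return tissue
    return "other"


@dataclass
class Roi:
    """A labeled planar annotation on a micrograph.

    ``vertices`` are absolute pixel coordinates; rectangles and ovals carry
    exactly the two bounding-box corners (x1, y1), (x2, y2) with x1 < x2 and
    y1 < y2.
    """

    name: str
    tissue: str
    shape_kind: str
    vertices: list[tuple[float, float]]
    source: str = "json"

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.shape_kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape_kind {self.shape_kind!r}")
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]
        for x, y in self.vertices:
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"roi {self.name!r}: non-finite vertex")
            if x < 0 or y < 0:
                raise ValueError(f"roi {self.name!r}: negative coordinate")
        if self.shape_kind in ("polygon", "freehand"):
            if len(self.vertices) < 3:
                raise ValueError(f"roi {self.name!r}: polygon needs >= 3 vertices")
        else:
            if len(self.vertices) != 2:
                raise ValueError(f"roi {self.name!r}: box shape needs 2 corners")
            (x1, y1), (x2, y2) = self.vertices
            if not (x1 < x2 and y1 < y2):
                raise ValueError(f"roi {self.name!r}: corners must satisfy x1<x2, y1<y2")

    def mask(self, width: int, height: int) -> np.ndarray:
        return roi_mask(self, width, height)

    def centroid(self) -> tuple[float, float]:
        return roi_centroid(self)


@dataclass
class RoiSet:
    """All ROIs annotating one micrograph."""

    rois: list[Roi] = field(default_factory=list)
    image_ref: str = ""

    def __post_init__(self) -> None:
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            raise ValueError("roi names must be unique within a set")

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def by_tissue(self, tissue: str) -> list[Roi]:
        return [r for r in self.rois if r.tissue == tissue]

    @property
    def tissue_rois(self) -> list[Roi]:
        return [r for r in self.rois if r.tissue != "background"]

    @property
    def background_rois(self) -> list[Roi]:
        return self.by_tissue("background")


@dataclass
class RoiPairing:
    """A tissue ROI paired with its geometrically closest background ROI."""

    tissue_roi: Roi
    background_roi: Roi
    distance: float

    def __post_init__(self) -> None:
        if self.background_roi.tissue != "background":
            raise ValueError("background_roi must have tissue 'background'")
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


# ---------------------------------------------------------------------------
# ImageJ .roi binary format (big-endian, 64-byte header, "Iout" magic)
# ---------------------------------------------------------------------------

def read_imagej_roi(raw: bytes, name: str = "", tissue: str | None = None) -> Roi:
    """Decode one ImageJ ``.roi`` record into a :class:`Roi`.

    Supports the area shapes the analysis needs: polygon (0), rectangle (1),
    oval (2) and freehand (7).  Lines, points and composite shapes are
    rejected with :class:`UnsupportedShapeError`.
    """
    if len(raw) < 64:
        raise RoiFormatError("ROI record shorter than the 64-byte header")
    if raw[0:4] != b"Iout":
        raise RoiFormatError(f"missing 'Iout' magic (got {raw[0:4]!r})")
    roi_type = raw[6]
    top, left, bottom, right = struct.unpack(">4h", raw[8:16])
    n_coords = struct.unpack(">h", raw[16:18])[0]

    if roi_type not in _IJ_TYPE_TO_KIND:
        raise UnsupportedShapeError(
            f"unsupported ImageJ ROI type code {roi_type} "
            f"(supported: {sorted(_IJ_TYPE_TO_KIND)})"
        )
    kind = _IJ_TYPE_TO_KIND[roi_type]

    if kind in ("rectangle", "oval"):
        vertices = [(float(left), float(top)), (float(right), float(bottom))]
    else:
        if n_coords < 3:
            raise RoiFormatError(f"polygon ROI with {n_coords} coordinates")
        need = 64 + 4 * n_coords
        if len(raw) < need:
            raise RoiFormatError("truncated polygon coordinate block")
        xs = struct.unpack(f">{n_coords}h", raw[64 : 64 + 2 * n_coords])
        ys = struct.unpack(
            f">{n_coords}h", raw[64 + 2 * n_coords : 64 + 4 * n_coords]
        )
        vertices = [(float(left + x), float(top + y)) for x, y in zip(xs, ys)]

    if tissue is None:
        tissue = classify_roi_name(name) if name else "other"
    return Roi(name=name, tissue=tissue, shape_kind=kind, vertices=vertices,
               source="imagej")


def write_imagej_roi(roi: Roi) -> bytes:
    """Encode a :class:`Roi` as an ImageJ ``.roi`` record (inverse of
    :func:`read_imagej_roi` for the supported shapes; coordinates are
    rounded to integers as the classic format stores shorts)."""
    header = bytearray(64)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, 228)  # version, as written by ImageJ 1.x
    header[6] = _KIND_TO_IJ_TYPE[roi.shape_kind]

    if roi.shape_kind in ("rectangle", "oval"):
        (x1, y1), (x2, y2) = roi.vertices
        struct.pack_into(">4h", header, 8,
                         round(y1), round(x1), round(y2), round(x2))
        return bytes(header)

    xs = [round(x) for x, _ in roi.vertices]
    ys = [round(y) for _, y in roi.vertices]
    left, top = min(xs), min(ys)
    struct.pack_into(">4h", header, 8, top, left, max(ys), max(xs))
    struct.pack_into(">h", header, 16, len(xs))
    body = struct.pack(f">{len(xs)}h", *(x - left for x in xs))
    body += struct.pack(f">{len(ys)}h", *(y - top for y in ys))
    return bytes(header) + body


def read_roi_archive(path: str | Path) -> RoiSet:
    """Read a ``.zip`` archive of ``.roi`` entries (or one bare ``.roi``
    file) into a :class:`RoiSet`.  ROI names come from entry filename stems
    and are mapped onto the tissue vocabulary by prefix."""
    path = Path(path)
    rois: list[Roi] = []
    if zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            for entry in zf.namelist():
                if not entry.lower().endswith(".roi"):
                    logger.warning("skipping non-roi archive entry %r", entry)
                    continue
                stem = Path(entry).stem
                rois.append(read_imagej_roi(zf.read(entry), name=stem))
    elif path.suffix.lower() == ".roi":
        rois.append(read_imagej_roi(path.read_bytes(), name=path.stem))
    else:
        raise RoiFormatError(f"{path} is neither a zip archive nor a .roi file")
    if not rois:
        raise RoiFormatError(f"no ROI entries found in {path}")
    return RoiSet(rois=rois, image_ref=path.stem.removesuffix("_rois"))


def write_roi_archive(roi_set: RoiSet, path: str | Path) -> None:
    """Write a RoiSet as a zip of ImageJ ``.roi`` entries."""
    with zipfile.ZipFile(path, "w") as zf:
        for roi in roi_set:
            zf.writestr(f"{roi.name}.roi", write_imagej_roi(roi))


# ---------------------------------------------------------------------------
# JSON sidecar (ground-truth dialect for synthetic data)
# ---------------------------------------------------------------------------

def roi_set_to_json(roi_set: RoiSet) -> str:
    payload = {
        "image_ref": roi_set.image_ref,
        "rois": [
            {
                "name": r.name,
                "tissue": r.tissue,
                "shape_kind": r.shape_kind,
                "vertices": [[x, y] for x, y in r.vertices],
            }
            for r in roi_set
        ],
    }
    return json.dumps(payload, indent=1)


def roi_set_from_json(text: str) -> RoiSet:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise RoiFormatError(
            f"malformed ROI JSON at line {exc.lineno}: {exc.msg}"
        ) from exc
    rois = []
    for entry in payload.get("rois", []):
        for key in ("name", "tissue", "shape_kind", "vertices"):
            if key not in entry:
                raise RoiFormatError(
                    f"roi {entry.get('name', '<unnamed>')!r} missing field {key!r}"
                )
        rois.append(
            Roi(
                name=entry["name"],
                tissue=entry["tissue"],
                shape_kind=entry["shape_kind"],
                vertices=[tuple(v) for v in entry["vertices"]],
                source="json",
            )
        )
    return RoiSet(rois=rois, image_ref=payload.get("image_ref", ""))


# ---------------------------------------------------------------------------
# Rasterization and geometry
# ---------------------------------------------------------------------------

def roi_mask(roi: Roi, width: int, height: int) -> np.ndarray:
    """Boolean (height, width) mask: True where the pixel center lies inside
    the shape.  Fully off-image ROIs yield an empty mask with a warning."""
    if width < 1 or height < 1:
        raise ValueError("mask dimensions must be >= 1")
    yy, xx = np.mgrid[0:height, 0:width]
    if roi.shape_kind == "rectangle":
        (x1, y1), (x2, y2) = roi.vertices
        mask = (xx >= x1) & (xx < x2) & (yy >= y1) & (yy < y2)
    elif roi.shape_kind == "oval":
        (x1, y1), (x2, y2) = roi.vertices
        a = (x2 - x1) / 2.0
        b = (y2 - y1) / 2.0
        # center of the half-open pixel span [x1, x2)
        cx = x1 + a - 0.5
        cy = y1 + b - 0.5
        mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    else:
        mask = _polygon_mask(roi.vertices, xx, yy)
    if not mask.any():
        logger.warning("roi %r rasterizes to an empty mask on %dx%d",
                       roi.name, width, height)
    return mask


def _polygon_mask(vertices: Sequence[tuple[float, float]],
                  xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    """Even-odd (ray crossing) point-in-polygon test, vectorized over the
    pixel-center grid."""
    inside = np.zeros(xx.shape, dtype=bool)
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        crosses = (y1 > yy) != (y2 > yy)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = (x2 - x1) * (yy - y1) / (y2 - y1) + x1
        inside ^= crosses & (xx < x_at)
    return inside


def roi_centroid(roi: Roi) -> tuple[float, float]:
    """Arithmetic mean of mask pixel centers; falls back to the vertex mean
    when the mask is empty (degenerate or off-image shapes)."""
    xs = [v[0] for v in roi.vertices]
    ys = [v[1] for v in roi.vertices]
    w = int(math.ceil(max(xs))) + 2
    h = int(math.ceil(max(ys))) + 2
    mask = roi_mask(roi, w, h)
    if not mask.any():
        logger.warning("roi %r: empty mask, centroid falls back to vertex mean",
                       roi.name)
        return (float(np.mean(xs)), float(np.mean(ys)))
    yy, xx = np.nonzero(mask)
    return (float(xx.mean()), float(yy.mean()))


def pair_background(tissue_rois: Iterable[Roi],
                    background_rois: Sequence[Roi]) -> list[RoiPairing]:
    """Pair every tissue ROI with the background ROI minimizing centroid
    Euclidean distance.  Ties break by background list order (first wins); a
    background ROI may serve multiple tissue ROIs."""
    background_rois = list(background_rois)
    if not background_rois:
        raise PairingError(
            "no background ROI available; annotate a comprehensive, mostly "
            "circular and representative local background area next to each "
            "section"
        )
    bg_centroids = [roi_centroid(b) for b in background_rois]
    pairings = []
    for t in tissue_rois:
        cx, cy = roi_centroid(t)
        best_i, best_d = 0, math.inf
        for i, (bx, by) in enumerate(bg_centroids):
            d = math.hypot(cx - bx, cy - by)
            if d < best_d:
                best_i, best_d = i, d
        pairings.append(RoiPairing(t, background_rois[best_i], best_d))
    return pairings
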