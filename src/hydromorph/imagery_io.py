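"""Raster, mask and point-table I/O with an explicit geo-coordinate contract.

Supported formats
-----------------
* GeoTIFF (via :mod:`tifffile`, ModelPixelScale/ModelTiepoint tags)
* PNG or plain TIFF accompanied by an ESRI world file (``.pgw``/``.tfw``/``.wld``)
* CSV for control-point pairs and ground-truth points
* GeoJSON polygons for channel-boundary masks (rasterised centre-in-polygon)
* classified maps as single-band GeoTIFF plus a two-column CSV legend sidecar

All world coordinates are planar metres; see :class:`hydromorph.geo.GeoTransform`
for the pixel-centre convention.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .classes import UNCLASSIFIED, FeatureClass, parse_class
from .geo import GeoTransform
from .rasters import ClassifiedMap, RGBImage

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922

WORLD_FILE_SUFFIXES = (".wld", ".tfw", ".pgw", ".jgw")


class MissingGeoreferenceError(ValueError):
    """Raised when a raster has neither embedded geotags nor a world file."""


class FormatError(ValueError):
    """Raised for rasters or tables that violate the documented format."""


@dataclass(frozen=True)
class ControlPointPair:
    """Surveyed vs image-derived planimetric position of one marker.

    ``role`` is "GCP" for points used in georeferencing and "XP" for
    independent check points.
    """

    id: str
    role: str
    x_ref: float
    y_ref: float
    x_img: float
    y_img: float

    def __post_init__(self) -> None:
        if self.role not in ("GCP", "XP"):
            raise ValueError(f"role must be GCP or XP, got {self.role!r}")
        for v in (self.x_ref, self.y_ref, self.x_img, self.y_img):
            if not np.isfinite(v):
                raise ValueError(f"non-finite coordinate in control point {self.id!r}")


@dataclass(frozen=True)
class GroundTruthPoint:
    """A visually classified grid point (planar metres + truth class)."""

    easting: float
    northing: float
    truth_class: FeatureClass


# ---------------------------------------------------------------------------
# world files


def _world_file_for(path: Path) -> Path | None:
    for suffix in (path.suffix[:2] + path.suffix[-1] + "w" if len(path.suffix) == 4 else "",
                   *WORLD_FILE_SUFFIXES):
        if not suffix:
            continue
        cand = path.with_suffix(suffix)
        if cand.exists():
            return cand
    return None


def read_world_file(path: Path) -> GeoTransform:
    """Parse a 6-line ESRI world file into a :class:`GeoTransform`."""
    vals = [float(line.strip()) for line in Path(path).read_text().split()[:6]]
    if len(vals) != 6:
        raise FormatError(f"world file {path} must have 6 numeric lines")
    a, d, b, e, c, f = vals
    if d != 0 or b != 0:
        raise FormatError("rotated world files are not supported")
    if a <= 0 or e >= 0 or abs(a) != abs(e):
        raise FormatError("world file must describe square north-up pixels")
    # C, F are the CENTRE of the top-left pixel
    return GeoTransform(origin_easting=c - a / 2.0, origin_northing=f + a / 2.0, gsd=a)


def write_world_file(path: Path, transform: GeoTransform) -> None:
    g = transform.gsd
    cx = transform.origin_easting + g / 2.0
    cy = transform.origin_northing - g / 2.0
    Path(path).write_text(f"{g:.12g}\n0.0\n0.0\n{-g:.12g}\n{cx:.12f}\n{cy:.12f}\n")


# ---------------------------------------------------------------------------
# geotiff tags


def _geotags(transform: GeoTransform) -> list:
    g = transform.gsd
    return [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (g, g, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, transform.origin_easting, transform.origin_northing, 0.0)),
    ]


def _transform_from_tiff(page) -> GeoTransform | None:
    tags = page.tags
    if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
        return None
    sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
    tp = tags[_TAG_MODEL_TIEPOINT].value
    i, j, _, x, y, _ = tp[:6]
    if abs(sx - sy) > 1e-12:
        raise FormatError("non-square pixels are not supported")
    # tie point gives world coords of raster point (j=row, i=col) outer corner
    return GeoTransform(origin_easting=x - i * sx, origin_northing=y + j * sy, gsd=sx)


# ---------------------------------------------------------------------------
# orthoimagery


def read_orthoimage(path: str | Path) -> RGBImage:
    """Read a georeferenced RGB orthoimage.

    GeoTIFF transforms are read from embedded tags; other rasters need a
    sibling world file. An alpha channel, if present, is folded into
    ``valid_mask`` (alpha 0 = invalid).

    Raises
    ------
    MissingGeoreferenceError
        If neither embedded tags nor a world file provide a transform.
    FormatError
        For non-image or single-band (greyscale) inputs.
    """
    path = Path(path)
    transform = None
    if path.suffix.lower() in (".tif", ".tiff"):
        try:
            with tifffile.TiffFile(path) as tf:
                page = tf.pages[0]
                data = page.asarray()
                transform = _transform_from_tiff(page)
        except (tifffile.TiffFileError, OSError) as exc:
            raise FormatError(f"{path} is not a readable TIFF: {exc}") from exc
    else:
        try:
            data = np.asarray(Image.open(path))
        except Exception as exc:  # Pillow raises UnidentifiedImageError/OSError
            raise FormatError(f"{path} is not a readable image: {exc}") from exc

    if transform is None:
        wf = _world_file_for(path)
        if wf is None:
            raise MissingGeoreferenceError(
                f"{path} has no embedded georeference and no world file "
                f"({'/'.join(WORLD_FILE_SUFFIXES)})"
            )
        transform = read_world_file(wf)

    if data.ndim != 3 or data.shape[2] not in (3, 4):
        raise FormatError(
            f"{path}: expected 3-band RGB (optionally +alpha), got shape {data.shape}"
        )
    mask = None
    if data.shape[2] == 4:
        mask = data[:, :, 3] > 0
        data = data[:, :, :3]
    pixels = np.clip(data, 0, 255).astype(np.uint8)
    return RGBImage(pixels=pixels, transform=transform, valid_mask=mask)


def write_orthoimage(image: RGBImage, path: str | Path) -> None:
    """Write an RGB(A) GeoTIFF (alpha carries the valid mask when not full)."""
    path = Path(path)
    data = image.pixels
    if not image.valid_mask.all():
        alpha = np.where(image.valid_mask, 255, 0).astype(np.uint8)
        data = np.dstack([data, alpha])
    tifffile.imwrite(path, data, photometric="rgb", extratags=_geotags(image.transform))


# ---------------------------------------------------------------------------
# classified maps + legend


def legend_path_for(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + "_legend.csv")


def write_classified_map(cmap: ClassifiedMap, path: str | Path) -> None:
    """Write a single-band uint16 GeoTIFF of class codes plus a legend sidecar.

    The legend (``<stem>_legend.csv``) lists every code present in the map,
    including 0 for unclassified/nodata pixels.
    """
    path = Path(path)
    labels = cmap.labels.astype(np.uint16)
    tifffile.imwrite(path, labels, photometric="minisblack",
                     extratags=_geotags(cmap.transform))
    codes = sorted(int(c) for c in np.unique(labels))
    with open(legend_path_for(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "name"])
        for code in codes:
            name = "unclassified" if code == UNCLASSIFIED else FeatureClass(code).name.lower()
            writer.writerow([code, name])


def read_classified_map(path: str | Path) -> ClassifiedMap:
    """Read a classified map written by :func:`write_classified_map`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        labels = page.asarray()
        transform = _transform_from_tiff(page)
    if transform is None:
        wf = _world_file_for(path)
        if wf is None:
            raise MissingGeoreferenceError(f"{path} has no georeference")
        transform = read_world_file(wf)
    labels = labels.astype(np.int32)
    return ClassifiedMap(labels=labels, transform=transform,
                         valid_mask=labels != UNCLASSIFIED)


def read_legend(path: str | Path) -> dict[int, str]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        return {int(row["code"]): row["name"] for row in reader}


# ---------------------------------------------------------------------------
# boundary masks


def read_boundary_mask(path: str | Path, transform: GeoTransform | None = None,
                       shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a channel-boundary mask from a raster or a GeoJSON polygon.

    Raster masks (single-band, nonzero = inside) are returned as-is. GeoJSON
    polygons are rasterised onto the grid given by ``transform``/``shape``
    with a centre-in-polygon test.
    """
    path = Path(path)
    if path.suffix.lower() in (".json", ".geojson"):
        if transform is None or shape is None:
            raise ValueError("rasterising a polygon boundary needs transform and shape")
        return _rasterise_geojson(path, transform, shape)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = np.asarray(Image.open(path))
    if data.ndim != 2:
        raise FormatError(f"boundary raster {path} must be single-band")
    return data.astype(bool)


def _rasterise_geojson(path: Path, transform: GeoTransform,
                       shape: tuple[int, int]) -> np.ndarray:
    import shapely
    from shapely.geometry import shape as shp_shape

    gj = json.loads(Path(path).read_text())
    if gj.get("type") == "FeatureCollection":
        geoms = [shp_shape(f["geometry"]) for f in gj["features"]]
    elif gj.get("type") == "Feature":
        geoms = [shp_shape(gj["geometry"])]
    else:
        geoms = [shp_shape(gj)]
    geom = shapely.unary_union(geoms)
    h, w = shape
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    xs, ys = transform.world_of(rows.ravel(), cols.ravel())
    inside = shapely.contains_xy(geom, xs, ys)
    return inside.reshape(h, w)


# ---------------------------------------------------------------------------
# point tables


def read_control_points(path: str | Path) -> list[ControlPointPair]:
    """Read control-point pairs from CSV (header: id,role,x_ref,y_ref,x_img,y_img)."""
    pairs: list[ControlPointPair] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "role", "x_ref", "y_ref", "x_img", "y_img"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(
                f"{path}: header must contain {sorted(required)}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                coords = {k: float(row[k]) for k in ("x_ref", "y_ref", "x_img", "y_img")}
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}, row {lineno}: malformed numeric field "
                                  f"({exc})") from exc
            try:
                pairs.append(ControlPointPair(id=row["id"], role=row["role"], **coords))
            except ValueError as exc:
                raise FormatError(f"{path}, row {lineno}: {exc}") from exc
    return pairs


def write_control_points(pairs: list[ControlPointPair], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "role", "x_ref", "y_ref", "x_img", "y_img"])
        for p in pairs:
            writer.writerow([p.id, p.role, repr(p.x_ref), repr(p.y_ref),
                             repr(p.x_img), repr(p.y_img)])


def read_truth_points(path: str | Path) -> list[GroundTruthPoint]:
    """Read ground-truth points from CSV (header: easting,northing,truth_class)."""
    points: list[GroundTruthPoint] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"easting", "northing", "truth_class"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"{path}: header must contain {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                e, n = float(row["easting"]), float(row["northing"])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}, row {lineno}: malformed numeric field") from exc
            try:
                cls = parse_class(row["truth_class"])
            except ValueError as exc:
                raise FormatError(f"{path}, row {lineno}: {exc}") from exc
            points.append(GroundTruthPoint(easting=e, northing=n, truth_class=cls))
    return points


def write_truth_points(points: list[GroundTruthPoint], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["easting", "northing", "truth_class"])
        for p in points:
            writer.writerow([repr(p.easting), repr(p.northing),
                             p.truth_class.name.lower()])
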