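"""Minimal multi-band GeoTIFF I/O built on tifffile.

Rasters are stored north-up with a simple affine transform
``x = x0 + col * px``, ``y = y0 - row * py`` where ``(x0, y0)`` is the
*top-left corner* of the top-left pixel.  Band names, the transform and
the NoData value are carried in a JSON payload in the ImageDescription
tag alongside the standard GeoTIFF ModelPixelScale/ModelTiepoint tags,
so files round-trip exactly through :func:`write_geotiff` /
:func:`read_geotiff`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

# GeoTIFF tag ids
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


@dataclass
class RasterStack:
    """A stack of co-registered single-band rasters sharing one grid.

    Parameters
    ----------
    data
        Array of shape ``(n_bands, rows, cols)``.
    band_names
        One name per band.
    origin
        ``(x0, y0)`` world coordinates of the top-left corner.
    pixel_size
        Pixel edge length in metres (square pixels).
    nodata
        Value marking invalid pixels on disk.
    mask
        Boolean ``(rows, cols)`` array, ``True`` where pixels are invalid.
    """

    data: np.ndarray
    band_names: list[str]
    origin: tuple[float, float] = (0.0, 0.0)
    pixel_size: float = 30.0
    nodata: float = DEFAULT_NODATA
    mask: np.ndarray | None = None
    crs: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("data must have shape (n_bands, rows, cols)")
        if len(self.band_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.band_names)} band names for {self.data.shape[0]} bands"
            )
        if self.mask is None:
            self.mask = np.zeros(self.grid_shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid_shape:
                raise ValueError("mask shape does not match grid shape")

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def band(self, name: str) -> np.ndarray:
        return self.data[self.band_names.index(name)]

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """World x/y coordinates of pixel centres, each ``(rows, cols)``."""
        rows, cols = self.grid_shape
        x0, y0 = self.origin
        x = x0 + (np.arange(cols) + 0.5) * self.pixel_size
        y = y0 - (np.arange(rows) + 0.5) * self.pixel_size
        return np.broadcast_to(x, (rows, cols)).copy(), np.broadcast_to(
            y[:, None], (rows, cols)
        ).copy()


def write_geotiff(path, stack: RasterStack, dtype: str = "float32") -> None:
    """Write a :class:`RasterStack` as a multi-page GeoTIFF."""
    data = stack.data.astype(dtype).copy()
    if stack.mask is not None and stack.mask.any():
        data[:, stack.mask] = stack.nodata
    meta = {
        "band_names": list(stack.band_names),
        "origin": [float(stack.origin[0]), float(stack.origin[1])],
        "pixel_size": float(stack.pixel_size),
        "nodata": float(stack.nodata),
        "crs": stack.crs,
    }
    x0, y0 = stack.origin
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (stack.pixel_size, stack.pixel_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_GDAL_NODATA, "s", 0, str(stack.nodata)),
    ]
    tifffile.imwrite(
        str(path),
        data,
        photometric="minisblack",
        description=json.dumps(meta, sort_keys=True),
        extratags=extratags,
    )


def read_geotiff(path) -> RasterStack:
    """Read a GeoTIFF written by :func:`write_geotiff`."""
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        page = tif.pages[0]
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, ValueError):
                meta = {}
        scale_tag = page.tags.get(_MODEL_PIXEL_SCALE)
        tie_tag = page.tags.get(_MODEL_TIEPOINT)
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    n_bands = data.shape[0]
    band_names = meta.get("band_names") or [f"band_{i + 1}" for i in range(n_bands)]
    nodata = float(meta.get("nodata", DEFAULT_NODATA))
    if meta.get("origin") is not None:
        origin = (float(meta["origin"][0]), float(meta["origin"][1]))
    elif tie_tag is not None:
        origin = (float(tie_tag.value[3]), float(tie_tag.value[4]))
    else:
        origin = (0.0, 0.0)
    if meta.get("pixel_size") is not None:
        pixel_size = float(meta["pixel_size"])
    elif scale_tag is not None:
        pixel_size = float(scale_tag.value[0])
    else:
        pixel_size = 30.0
    mask = np.all(data == nodata, axis=0) | np.all(np.isnan(data), axis=0)
    data = data.copy()
    data[:, mask] = 0.0
    return RasterStack(
        data=data,
        band_names=list(band_names),
        origin=origin,
        pixel_size=pixel_size,
        nodata=nodata,
        mask=mask,
        crs=meta.get("crs"),
    )
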