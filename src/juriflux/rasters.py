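"""Raster bundle container and plain-TIFF I/O.

All layers of a jurisdiction share one grid (rows x cols) and one pixel
size in metres; pixel area is (pixel size)^2 with no projection
correction, matching a 30 m equal-area working grid. Rasters are written
as single-band TIFFs via :mod:`tifffile`, with grid geometry kept in a
sidecar ``grid.json``.

Loss-year band convention (bit-exact): 0 = no loss; 1..tp = year index
within the reference period in which the pixel lost forest. The gain
band is binary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["RasterBundle", "pixel_area_ha"]

M2_PER_HA = 10_000.0


def pixel_area_ha(pixel_size_m: float) -> float:
    """Area of one square pixel in hectares."""
    return (pixel_size_m ** 2) / M2_PER_HA


@dataclass
class RasterBundle:
    """Aligned raster layers for one jurisdiction.

    Layers (all ``rows x cols``):

    - ``loss_year``  int, 0 = no loss, 1..tp = loss-year index
    - ``gain``       uint8 binary
    - ``canopy2000`` uint8 binary (forested in year 2000)
    - ``stratum``    int biomass-stratum id, 0 = non-forest / unassigned
    - ``disturbance`` int code, see ``disturbance_codes``
    - ``zone``       int code, see ``zone_codes``
    - ``permit``     int code, see ``permit_codes``
    - ``concession`` uint8 binary (licensed logging concession)
    - ``wetland``    int code: 0 none, 1 peat, 2 mangrove
    """

    pixel_size_m: float
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    codes: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate_alignment()

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.layers.values()))
        return first.shape

    @property
    def pixel_area_ha(self) -> float:
        return pixel_area_ha(self.pixel_size_m)

    def validate_alignment(self) -> None:
        shapes = {name: arr.shape for name, arr in self.layers.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"misaligned raster grids: {shapes}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def area_ha(self, mask: np.ndarray) -> float:
        """Total area of True pixels in ha."""
        return float(np.count_nonzero(mask)) * self.pixel_area_ha

    # -- persistence -----------------------------------------------------

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self.layers.items():
            tifffile.imwrite(directory / f"{name}.tif", np.ascontiguousarray(arr))
        meta = {
            "pixel_size_m": self.pixel_size_m,
            "layers": sorted(self.layers),
            "codes": self.codes,
        }
        (directory / "grid.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def read(cls, directory: str | Path) -> "RasterBundle":
        directory = Path(directory)
        meta = json.loads((directory / "grid.json").read_text())
        layers = {
            name: tifffile.imread(directory / f"{name}.tif")
            for name in meta["layers"]
        }
        return cls(pixel_size_m=meta["pixel_size_m"], layers=layers,
                   codes={k: dict(v) for k, v in meta.get("codes", {}).items()})
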