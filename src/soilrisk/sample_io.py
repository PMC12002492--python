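"""Reading, validation and writing of soil-survey sample tables.

A sample table holds one row per sampling site: a unique site id, projected
planar coordinates in meters, and total concentrations (mg/kg) of the measured
elements.  Concentrations below the analytical detection limit are stored as 0
and flagged as non-detects, matching how XRF survey tables report them.

Two on-disk dialects are supported and round-trip exactly: a wide CSV
(``site_id,x,y,<element>...``) and GeoJSON Point features carrying the same
properties.  The reference registry (MPC, background, detection limit, hazard
class per element) travels as a small CSV.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ElementReference",
    "SampleTable",
    "ValidationReport",
    "read_sample_table",
    "write_sample_table",
    "read_reference_table",
    "write_reference_table",
    "validate_dataset",
]

_COORD_COLUMNS = ("x", "y")


class FormatError(ValueError):
    """Raised when an input file does not have the expected structure."""


@dataclass(frozen=True)
class ElementReference:
    """Regulatory and background reference values for one element.

    ``background_is_mpc`` marks elements absent from the background soil, for
    which the MPC stands in as background (so CF and HQ coincide).
    """

    element: str
    mpc: float
    background: float
    background_is_mpc: bool = False
    detection_limit: float = 0.0
    hazard_class: int = 3

    def __post_init__(self):
        if not self.mpc > 0:
            raise ValueError(f"{self.element}: MPC must be positive, got {self.mpc}")
        if not self.background > 0:
            raise ValueError(f"{self.element}: background must be positive")
        if self.hazard_class not in (1, 2, 3):
            raise ValueError(f"{self.element}: hazard class must be 1, 2 or 3")


@dataclass
class SampleTable:
    """Per-site concentrations with projected planar coordinates.

    ``frame`` is indexed by site id with columns ``x``, ``y`` and one column
    per element, in a stable element order used by every downstream table.
    """

    frame: pd.DataFrame
    elements: list[str]

    def __post_init__(self):
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate site ids: {dupes}")
        conc = self.frame[self.elements].to_numpy(dtype=float)
        if (conc < 0).any():
            raise ValueError("negative concentrations are not allowed")
        _check_projected(self.frame["x"].to_numpy(), self.frame["y"].to_numpy())

    @property
    def n_sites(self) -> int:
        return len(self.frame)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def site_ids(self) -> list:
        return self.frame.index.tolist()

    @property
    def coords(self) -> np.ndarray:
        return self.frame[["x", "y"]].to_numpy(dtype=float)

    @property
    def conc(self) -> pd.DataFrame:
        """Concentration block (sites × elements, mg/kg)."""
        return self.frame[self.elements]

    @property
    def detected(self) -> pd.DataFrame:
        """Detection flags; a stored 0 means below the detection limit."""
        return self.frame[self.elements] > 0

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        x, y = self.frame["x"], self.frame["y"]
        return float(x.min()), float(y.min()), float(x.max()), float(y.max())


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    n_sites: int = 0
    n_elements: int = 0

    @property
    def ok(self) -> bool:
        return not self.errors


def _check_projected(x: np.ndarray, y: np.ndarray) -> None:
    # Geographic coordinates would make cell areas non-metric; refuse them.
    if len(x) >= 2 and np.all(np.abs(x) <= 180) and np.all(np.abs(y) <= 90):
        raise ValueError(
            "coordinates look geographic (lon/lat); project to a metric CRS "
            "(planar meters) before loading"
        )


def read_sample_table(path: str | Path, dialect: str = "csv") -> SampleTable:
    """Read a sample table from CSV or GeoJSON.

    Zeros are non-detects by convention; element order follows column order
    (CSV) or the property order of the first feature (GeoJSON).
    """
    path = Path(path)
    if dialect == "csv":
        frame = pd.read_csv(path)
        _require_columns(frame, path)
        frame = frame.set_index("site_id")
    elif dialect == "geojson":
        with open(path) as fh:
            collection = json.load(fh)
        rows = []
        for feat in collection.get("features", []):
            props = dict(feat["properties"])
            gx, gy = feat["geometry"]["coordinates"]
            rows.append({"site_id": props.pop("site_id"), "x": gx, "y": gy, **props})
        if not rows:
            raise FormatError(f"{path}: no Point features found")
        frame = pd.DataFrame(rows).set_index("site_id")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    elements = [c for c in frame.columns if c not in _COORD_COLUMNS]
    if not elements:
        raise FormatError(f"{path}: no element columns found")
    frame[elements] = frame[elements].astype(float)
    return SampleTable(frame=frame, elements=elements)


def _require_columns(frame: pd.DataFrame, path: Path) -> None:
    missing = [c for c in ("site_id", "x", "y") if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def write_sample_table(table: SampleTable, path: str | Path, dialect: str = "csv") -> None:
    """Write a sample table; output is accepted bit-exactly by the reader."""
    path = Path(path)
    if dialect == "csv":
        table.frame.reset_index().to_csv(path, index=False)
    elif dialect == "geojson":
        features = []
        for site_id, row in table.frame.iterrows():
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [row["x"], row["y"]]},
                    "properties": {"site_id": site_id, **{el: row[el] for el in table.elements}},
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_reference_table(path: str | Path) -> dict[str, ElementReference]:
    """Read the per-element reference registry CSV.

    Columns: ``element,mpc,background,detection_limit,hazard_class``; an empty
    background cell means the element was absent from background soil and the
    MPC is substituted (``background_is_mpc``).
    """
    frame = pd.read_csv(path)
    if frame.empty:
        raise FormatError(f"{path}: reference table is empty")
    if "element" not in frame.columns or "mpc" not in frame.columns:
        raise FormatError(f"{path}: reference table needs 'element' and 'mpc' columns")
    registry: dict[str, ElementReference] = {}
    for _, row in frame.iterrows():
        background = row.get("background", math.nan)
        background_is_mpc = pd.isna(background)
        registry[row["element"]] = ElementReference(
            element=row["element"],
            mpc=float(row["mpc"]),
            background=float(row["mpc"]) if background_is_mpc else float(background),
            background_is_mpc=bool(background_is_mpc),
            detection_limit=float(row.get("detection_limit", 0.0) or 0.0),
            hazard_class=int(row.get("hazard_class", 3)),
        )
    return registry


def write_reference_table(registry: dict[str, ElementReference], path: str | Path) -> None:
    rows = []
    for ref in registry.values():
        rows.append(
            {
                "element": ref.element,
                "mpc": ref.mpc,
                "background": "" if ref.background_is_mpc else ref.background,
                "detection_limit": ref.detection_limit,
                "hazard_class": ref.hazard_class,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def validate_dataset(
    table: SampleTable,
    registry: dict[str, ElementReference],
    bbox: tuple[float, float, float, float] | None = None,
) -> ValidationReport:
    """Cross-check a sample table against the reference registry.

    Errors block the pipeline (element without reference values); warnings do
    not (sites outside the configured bounding box).
    """
    report = ValidationReport(n_sites=table.n_sites, n_elements=table.n_elements)
    for el in table.elements:
        if el not in registry:
            report.errors.append(f"element {el!r} has no reference entry")
    if bbox is not None:
        xmin, ymin, xmax, ymax = bbox
        for site_id, row in table.frame.iterrows():
            if not (xmin <= row["x"] <= xmax and ymin <= row["y"] <= ymax):
                report.warnings.append(f"site {site_id!r} lies outside the configured bbox")
    return report
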