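"""Slide geometry, spot roles, and grid-indexed quantification-table I/O.

An RPPA slide is a grid of subgrids (one subgrid per print pin). Every
printed spot is addressed by four 1-based indices — subgrid row/column and
spot row/column within the subgrid — matching the Main Row / Main Col /
Sub Row / Sub Col vocabulary of MicroVigene quantification tables.

The default layout reproduces a common production design: 12 x 4 subgrids
of 11 x 11 spots (132 x 44 = 5808 spots). Each subgrid carries 22 samples
and 2 positive-control sets, each printed as a 5-step 1:2 serial dilution,
plus a single protein-free buffer spot serving as negative control.
Positive-control sets occupy fixed positions in every subgrid so their
anchors form a regular lattice across the slide.
"""

from __future__ import annotations

import enum
import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import IO, Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("rppanorm")

__all__ = [
    "SpotRole",
    "GridCoord",
    "SlideLayout",
    "Slide",
    "FormatError",
    "LayoutError",
    "build_default_layout",
    "build_layout",
    "absolute_position",
    "read_quantification",
    "write_slide",
    "read_layout",
    "write_layout",
    "MICROVIGENE_COLUMNS",
]


class FormatError(ValueError):
    """A quantification table violates the expected tabular contract."""


class LayoutError(ValueError):
    """A layout declaration is internally inconsistent."""


class SpotRole(str, enum.Enum):
    SAMPLE = "sample"
    POSITIVE_CONTROL = "positive_control"
    NEGATIVE_CONTROL = "negative_control"


#: Default (MicroVigene-style) column names for the tab-separated spot table.
MICROVIGENE_COLUMNS: Mapping[str, str] = {
    "subgrid_row": "Main Row",
    "subgrid_col": "Main Col",
    "spot_row": "Sub Row",
    "spot_col": "Sub Col",
    "sample_id": "Sample",
    "dilution_step": "Dilution",
    "intensity": "Signal",
    "corrected": "Corrected",
    "cf": "CF",
    "valid": "Valid",
}

_GRID_KEYS = ("subgrid_row", "subgrid_col", "spot_row", "spot_col")


@dataclass(frozen=True)
class GridCoord:
    """1-based grid address of one spot: subgrid indices + indices within."""

    subgrid_row: int
    subgrid_col: int
    spot_row: int
    spot_col: int


@dataclass
class SlideLayout:
    """Geometric contract of a slide plus the role of every coordinate.

    Parameters
    ----------
    n_subgrid_rows, n_subgrid_cols
        Subgrid grid dimensions (12 x 4 by default).
    subgrid_height, subgrid_width
        Spots per subgrid along each axis (11 x 11 by default).
    n_dilutions
        Steps per dilution series (5 by default; step 1 is undiluted).
    dilution_factor
        Per-step dilution ratio in (0, 1); 0.5 means 1:2 serial dilutions.
    samples_per_subgrid
        Distinct samples whose full series fits in one subgrid (22).
    n_control_sets
        Positive-control dilution sets per subgrid (2).
    control_row
        Within-subgrid row holding the control sets and the buffer spot.
    """

    n_subgrid_rows: int = 12
    n_subgrid_cols: int = 4
    subgrid_height: int = 11
    subgrid_width: int = 11
    n_dilutions: int = 5
    dilution_factor: float = 0.5
    samples_per_subgrid: int = 22
    n_control_sets: int = 2
    control_row: int = 11
    table: pd.DataFrame = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.dilution_factor < 1.0:
            raise LayoutError("dilution_factor must lie in (0, 1)")
        sample_slots = (self.subgrid_height - 1) * self.subgrid_width
        if self.samples_per_subgrid * self.n_dilutions != sample_slots:
            raise LayoutError(
                f"samples_per_subgrid * n_dilutions must fill the "
                f"{sample_slots} non-control spots of each subgrid"
            )
        if self.n_control_sets * self.n_dilutions + 1 != self.subgrid_width:
            raise LayoutError(
                "control row must hold exactly the control sets plus one buffer spot"
            )
        if not 1 <= self.control_row <= self.subgrid_height:
            raise LayoutError("control_row outside the subgrid")
        if self.table is None:
            object.__setattr__(self, "table", _build_role_table(self))

    # -- derived geometry ------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.n_subgrid_rows * self.subgrid_height

    @property
    def n_cols(self) -> int:
        return self.n_subgrid_cols * self.subgrid_width

    @property
    def n_spots(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_subgrids(self) -> int:
        return self.n_subgrid_rows * self.n_subgrid_cols

    @property
    def n_control_sets_total(self) -> int:
        return self.n_subgrids * self.n_control_sets

    def params(self) -> dict:
        return {
            "n_subgrid_rows": self.n_subgrid_rows,
            "n_subgrid_cols": self.n_subgrid_cols,
            "subgrid_height": self.subgrid_height,
            "subgrid_width": self.subgrid_width,
            "n_dilutions": self.n_dilutions,
            "dilution_factor": self.dilution_factor,
            "samples_per_subgrid": self.samples_per_subgrid,
            "n_control_sets": self.n_control_sets,
            "control_row": self.control_row,
        }


def _build_role_table(layout: SlideLayout) -> pd.DataFrame:
    """Materialize the role map: one row per coordinate, row-major order.

    Within each subgrid, every row except ``control_row`` is filled with
    sample dilution series laid out contiguously in row-major order; the
    control row carries the positive-control runs followed by the buffer.
    """
    h, w = layout.subgrid_height, layout.subgrid_width
    nd = layout.n_dilutions
    records = []
    for sgr in range(1, layout.n_subgrid_rows + 1):
        for sgc in range(1, layout.n_subgrid_cols + 1):
            subgrid_index = (sgr - 1) * layout.n_subgrid_cols + (sgc - 1)
            slot = 0  # running row-major index over non-control positions
            for r in range(1, h + 1):
                for c in range(1, w + 1):
                    if r == layout.control_row:
                        run = (c - 1) // nd
                        if run < layout.n_control_sets:
                            role = SpotRole.POSITIVE_CONTROL
                            sample_id = f"PC_r{sgr:02d}c{sgc}s{run + 1}"
                            dilution = (c - 1) % nd + 1
                        else:
                            role = SpotRole.NEGATIVE_CONTROL
                            sample_id = f"BUF_r{sgr:02d}c{sgc}"
                            dilution = 0
                    else:
                        sample = subgrid_index * layout.samples_per_subgrid + slot // nd
                        role = SpotRole.SAMPLE
                        sample_id = f"S{sample + 1:04d}"
                        dilution = slot % nd + 1
                        slot += 1
                    records.append(
                        (sgr, sgc, r, c,
                         (sgr - 1) * h + r, (sgc - 1) * w + c,
                         role.value, sample_id, dilution)
                    )
    df = pd.DataFrame.from_records(
        records,
        columns=["subgrid_row", "subgrid_col", "spot_row", "spot_col",
                 "row", "col", "role", "sample_id", "dilution_step"],
    )
    df["dilution_step"] = df["dilution_step"].astype("int64")
    return df


def build_layout(**params) -> SlideLayout:
    """Construct a layout from explicit geometry parameters."""
    return SlideLayout(**params)


def build_default_layout() -> SlideLayout:
    """The default 132 x 44 production layout.

    48 subgrids of 121 spots: per subgrid 22 samples and 2 positive-control
    sets in 5 half-dilutions each, plus one buffer spot — 5808 spots in
    total, of which 480 are positive controls (96 sets) and 48 negatives.
    """
    return SlideLayout()


def absolute_position(coord: GridCoord, layout: SlideLayout) -> tuple[int, int]:
    """Map a four-index grid coordinate to absolute (row, col) on the slide.

    The map is bijective: for the default layout it covers 1..132 x 1..44.
    """
    if not (1 <= coord.subgrid_row <= layout.n_subgrid_rows
            and 1 <= coord.subgrid_col <= layout.n_subgrid_cols
            and 1 <= coord.spot_row <= layout.subgrid_height
            and 1 <= coord.spot_col <= layout.subgrid_width):
        raise LayoutError(f"coordinate {coord} outside layout bounds")
    row = (coord.subgrid_row - 1) * layout.subgrid_height + coord.spot_row
    col = (coord.subgrid_col - 1) * layout.subgrid_width + coord.spot_col
    return row, col


@dataclass
class Slide:
    """A fully populated slide: layout, per-spot measurements, metadata.

    ``spots`` holds one row per layout coordinate (layout order) with the
    role map columns plus ``intensity`` (raw signal, arbitrary units) and
    ``valid`` (False for missing/flagged spots; such spots are excluded
    from anchor selection and QC but still receive a correction factor).
    """

    layout: SlideLayout
    spots: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.spots) != self.layout.n_spots:
            raise LayoutError(
                f"slide has {len(self.spots)} spots; layout requires "
                f"{self.layout.n_spots}"
            )
        if (self.spots["intensity"] < 0).any():
            raise FormatError("negative intensities are not allowed")

    @classmethod
    def from_intensities(
        cls,
        layout: SlideLayout,
        intensities: np.ndarray,
        valid: Optional[np.ndarray] = None,
        metadata: Optional[dict] = None,
    ) -> "Slide":
        """Build a slide from an intensity vector in layout (row-major) order."""
        df = layout.table.copy()
        df["intensity"] = np.asarray(intensities, dtype=float)
        df["valid"] = True if valid is None else np.asarray(valid, dtype=bool)
        return cls(layout=layout, spots=df, metadata=metadata or {})


def read_quantification(
    source: Union[str, IO[str]],
    layout: SlideLayout,
    column_map: Optional[Mapping[str, str]] = None,
    metadata: Optional[dict] = None,
) -> Slide:
    """Read a tab-separated spot quantification table into a Slide.

    The table must name the four grid-index columns and a signal column
    (MicroVigene names by default; override via ``column_map``). Roles,
    sample identities and dilution steps are taken from the layout's role
    map. Records missing from the table become invalid spots with zero
    intensity (logged); duplicated or out-of-bounds coordinates and
    non-numeric intensities are format errors.
    """
    cols = dict(MICROVIGENE_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(source, sep="\t", comment="#")

    needed = [cols[k] for k in _GRID_KEYS] + [cols["intensity"]]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    rename = {cols[k]: k for k in _GRID_KEYS}
    rename[cols["intensity"]] = "intensity"
    if cols["corrected"] in df.columns:
        rename[cols["corrected"]] = "corrected"
    if cols["valid"] in df.columns:
        rename[cols["valid"]] = "valid"
    df = df.rename(columns=rename)

    for key in _GRID_KEYS:
        try:
            df[key] = df[key].astype("int64")
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-integer value in column {cols[key]}") from exc
    bad = pd.to_numeric(df["intensity"], errors="coerce").isna() & df["intensity"].notna()
    if bad.any() or df["intensity"].isna().any():
        rows = df.index[bad | df["intensity"].isna()].tolist()
        raise FormatError(f"non-numeric intensity at table row(s) {rows[:5]}")
    df["intensity"] = df["intensity"].astype(float)

    oob = (
        (df["subgrid_row"] < 1) | (df["subgrid_row"] > layout.n_subgrid_rows)
        | (df["subgrid_col"] < 1) | (df["subgrid_col"] > layout.n_subgrid_cols)
        | (df["spot_row"] < 1) | (df["spot_row"] > layout.subgrid_height)
        | (df["spot_col"] < 1) | (df["spot_col"] > layout.subgrid_width)
    )
    if oob.any():
        first = df.loc[oob.idxmax(), list(_GRID_KEYS)].tolist()
        raise FormatError(f"coordinate {tuple(first)} outside layout bounds")
    dup = df.duplicated(subset=list(_GRID_KEYS))
    if dup.any():
        first = df.loc[dup.idxmax(), list(_GRID_KEYS)].tolist()
        raise FormatError(f"duplicate coordinate {tuple(first)}")

    keep = ["intensity"] + (["corrected"] if "corrected" in df.columns else []) \
        + (["valid"] if "valid" in df.columns else [])
    merged = layout.table.merge(
        df[list(_GRID_KEYS) + keep], on=list(_GRID_KEYS), how="left"
    )
    absent = merged["intensity"].isna()
    if absent.any():
        n = int(absent.sum())
        logger.warning("%d spot(s) missing from table; marked invalid", n)
        warnings.warn(f"{n} spot(s) missing from quantification table", stacklevel=2)
    if "valid" in merged.columns:
        merged["valid"] = merged["valid"].fillna(False).astype(bool) & ~absent
    else:
        merged["valid"] = ~absent
    merged["intensity"] = merged["intensity"].fillna(0.0)
    return Slide(layout=layout, spots=merged, metadata=metadata or {})


def write_slide(
    slide: Slide,
    target: Union[str, IO[str], None] = None,
    corrected: Optional[np.ndarray] = None,
    cf: Optional[np.ndarray] = None,
    header_comments: Optional[list[str]] = None,
    column_map: Optional[Mapping[str, str]] = None,
) -> Optional[str]:
    """Write a slide as a tab-separated spot table.

    Round-trips through :func:`read_quantification` up to float formatting.
    ``corrected`` and ``cf``, if given, must cover every spot and are
    written as extra columns alongside the raw signal. Returns the table
    text when ``target`` is None.
    """
    cols = dict(MICROVIGENE_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = slide.spots.copy()
    out = pd.DataFrame({
        cols["subgrid_row"]: df["subgrid_row"],
        cols["subgrid_col"]: df["subgrid_col"],
        cols["spot_row"]: df["spot_row"],
        cols["spot_col"]: df["spot_col"],
        cols["sample_id"]: df["sample_id"],
        cols["dilution_step"]: df["dilution_step"],
        cols["intensity"]: df["intensity"],
        cols["valid"]: df["valid"].astype(int),
    })
    for name, values in (("corrected", corrected), ("cf", cf)):
        if values is not None:
            values = np.asarray(values, dtype=float)
            if len(values) != len(df):
                raise LayoutError(f"{name} does not cover every spot")
            out[cols[name]] = values
        elif name in df.columns:
            out[cols[name]] = df[name]

    buf = io.StringIO()
    for line in header_comments or []:
        buf.write(f"# {line}\n")
    for key, value in slide.metadata.items():
        buf.write(f"# {key}: {'' if value is None else value}\n")
    out.to_csv(buf, sep="\t", index=False, float_format="%.10g")
    text = buf.getvalue()
    if target is None:
        return text
    if isinstance(target, str):
        with open(target, "w") as fh:
            fh.write(text)
    else:
        target.write(text)
    return None


def write_layout(layout: SlideLayout, target: Union[str, IO[str], None] = None) -> Optional[str]:
    """Serialize a layout declaration as YAML (geometry parameters only)."""
    text = yaml.safe_dump(layout.params(), sort_keys=False)
    if target is None:
        return text
    if isinstance(target, str):
        with open(target, "w") as fh:
            fh.write(text)
    else:
        target.write(text)
    return None


def read_layout(source: Union[str, IO[str]]) -> SlideLayout:
    """Load a layout declaration from a YAML file or stream."""
    if isinstance(source, str):
        with open(source) as fh:
            params = yaml.safe_load(fh)
    else:
        params = yaml.safe_load(source)
    if not isinstance(params, dict):
        raise LayoutError("layout file must contain a mapping of parameters")
    known = set(SlideLayout().params())
    unknown = set(params) - known
    if unknown:
        raise LayoutError(f"unknown layout parameter(s): {sorted(unknown)}")
    return SlideLayout(**params)
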