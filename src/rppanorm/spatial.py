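"""Correction-factor surfaces from positive-control anchors.

The measurement model is multiplicative: the measured intensity at a spot
is the true intensity times a spatially varying correction factor,

    I(x, y) = CF(x, y) * I'(x, y),        CF(x, y) = PCI(x, y) / <PCI>,

where PCI is the local positive-control intensity and <PCI> the mean
positive-control intensity across the slide. CF > 1 marks regions biased
high. Because sample locations do not carry positive controls, pseudo
positive-control intensities PCI*(x, y) are interpolated from anchors —
one representative spot per positive-control set — and the corrected
intensity is I' = I / CF.

Anchors are registered onto a regular rectangular lattice (one lattice row
per subgrid row, one lattice column per control set column); lattice-line
coordinates are the mean absolute positions of the line's anchors, so the
small positional jitter of a per-set median spot cannot break the
rectangularity that bilinear interpolation requires. Spots outside the
anchor hull take the value of the nearest covered location (per-axis clamp
onto the lattice rectangle).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.interpolate import RectBivariateSpline, RegularGridInterpolator

from .layout import Slide, SpotRole

logger = logging.getLogger("rppanorm")

__all__ = [
    "Anchor",
    "AnchorLattice",
    "CorrectionSurface",
    "NormalizedSlide",
    "ExteriorQueryError",
    "AnchorSelectionError",
    "select_anchors",
    "compute_reference",
    "assemble_lattice",
    "bilinear_interpolate",
    "extrapolate_nearest",
    "build_surface",
    "spline_surface",
    "apply_correction",
    "normalize_slide",
    "DEFAULT_CLAMP",
]

DEFAULT_CLAMP = (0.1, 10.0)


class ExteriorQueryError(ValueError):
    """A query point lies outside the anchor lattice's covered rectangle."""


class AnchorSelectionError(ValueError):
    """A positive-control set yields no usable anchor."""


@dataclass(frozen=True)
class Anchor:
    """One interpolation knot: a positive-control spot's position + intensity.

    ``lattice_row``/``lattice_col`` index the anchor's line in the regular
    anchor lattice (subgrid row; control-set column across the slide).
    """

    row: int
    col: int
    pci: float
    set_id: str
    lattice_row: int
    lattice_col: int


def select_anchors(slide: Slide, policy: str = "median") -> list[Anchor]:
    """Choose one anchor per positive-control dilution set.

    policy "median" (default): the set's anchor is the valid spot whose
    intensity is the set median — the dilution most likely to sit in the
    assay's linear range — at that spot's own position; for an even number
    of valid spots the lower median is taken (a real spot with a real
    position). policy "fixed:k" instead takes dilution step k of every set.

    Raises :class:`AnchorSelectionError` naming the set if any set has no
    valid spot with positive intensity.
    """
    fixed_step: Optional[int] = None
    if policy.startswith("fixed:"):
        fixed_step = int(policy.split(":", 1)[1])
    elif policy != "median":
        raise ValueError(f"unknown anchor policy {policy!r}")

    layout = slide.layout
    pc = slide.spots[slide.spots["role"] == SpotRole.POSITIVE_CONTROL.value]
    anchors: list[Anchor] = []
    for set_id, grp in pc.groupby("sample_id", sort=True):
        usable = grp[grp["valid"] & (grp["intensity"] > 0)]
        if usable.empty:
            raise AnchorSelectionError(
                f"positive-control set {set_id!r} has no valid spot with "
                f"positive intensity"
            )
        if fixed_step is not None:
            hit = usable[usable["dilution_step"] == fixed_step]
            if hit.empty:
                raise AnchorSelectionError(
                    f"positive-control set {set_id!r} has no valid spot at "
                    f"dilution step {fixed_step}"
                )
            spot = hit.iloc[0]
        else:
            ordered = usable.sort_values("intensity", kind="mergesort")
            spot = ordered.iloc[(len(ordered) - 1) // 2]  # lower median
        sgr, sgc = int(spot["subgrid_row"]), int(spot["subgrid_col"])
        # control sets run left-to-right within the control row; recover the
        # set index from the spot column so the lattice column is global
        set_index = (int(spot["spot_col"]) - 1) // layout.n_dilutions
        anchors.append(
            Anchor(
                row=int(spot["row"]),
                col=int(spot["col"]),
                pci=float(spot["intensity"]),
                set_id=str(set_id),
                lattice_row=sgr,
                lattice_col=(sgc - 1) * layout.n_control_sets + set_index + 1,
            )
        )
    return anchors


def compute_reference(anchors: Sequence[Anchor]) -> float:
    """Reference intensity <PCI>: the arithmetic mean of anchor intensities."""
    if len(anchors) == 0:
        raise AnchorSelectionError("cannot compute a reference from zero anchors")
    return float(np.mean([a.pci for a in anchors]))


@dataclass
class AnchorLattice:
    """Anchors registered on a regular rectangular grid.

    ``rows``/``cols`` are strictly increasing lattice-line coordinates in
    absolute spot-index space (means of the member anchors' positions);
    ``values`` is the (n_rows, n_cols) array of anchor intensities.
    """

    rows: np.ndarray
    cols: np.ndarray
    values: np.ndarray

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (float(self.rows[0]), float(self.rows[-1]),
                float(self.cols[0]), float(self.cols[-1]))

    def contains(self, row, col) -> np.ndarray:
        r0, r1, c0, c1 = self.bounds
        return (np.asarray(row) >= r0) & (np.asarray(row) <= r1) \
            & (np.asarray(col) >= c0) & (np.asarray(col) <= c1)


def assemble_lattice(anchors: Sequence[Anchor]) -> AnchorLattice:
    """Arrange anchors into the regular lattice bilinear interpolation needs.

    Each lattice line's coordinate is the mean absolute position of its
    anchors, absorbing within-set median-position jitter without breaking
    the grid. Requires a complete rectangular complement of anchors.
    """
    lr = sorted({a.lattice_row for a in anchors})
    lc = sorted({a.lattice_col for a in anchors})
    if len(lr) * len(lc) != len(anchors):
        raise AnchorSelectionError(
            f"anchors do not form a complete {len(lr)} x {len(lc)} lattice"
        )
    ri = {v: i for i, v in enumerate(lr)}
    ci = {v: i for i, v in enumerate(lc)}
    values = np.full((len(lr), len(lc)), np.nan)
    row_pos = np.zeros((len(lr), len(lc)))
    col_pos = np.zeros((len(lr), len(lc)))
    for a in anchors:
        i, j = ri[a.lattice_row], ci[a.lattice_col]
        if not np.isnan(values[i, j]):
            raise AnchorSelectionError("two anchors share one lattice cell")
        values[i, j] = a.pci
        row_pos[i, j] = a.row
        col_pos[i, j] = a.col
    rows = row_pos.mean(axis=1)
    cols = col_pos.mean(axis=0)
    if not (np.all(np.diff(rows) > 0) and np.all(np.diff(cols) > 0)):
        raise AnchorSelectionError("lattice line coordinates are not increasing")
    return AnchorLattice(rows=rows, cols=cols, values=values)


def bilinear_interpolate(
    lattice: AnchorLattice,
    row: Union[float, np.ndarray],
    col: Union[float, np.ndarray],
) -> np.ndarray:
    """Evaluate the bilinear pseudo-PCI surface at interior points.

    Standard bilinear blend within each axis-aligned cell of four anchors:
    linear in row at fixed column and vice versa, exact at the corners, and
    bounded by the four corner values. Raises :class:`ExteriorQueryError`
    for any point outside the covered rectangle (resolved by
    :func:`extrapolate_nearest`).
    """
    row = np.asarray(row, dtype=float)
    col = np.asarray(col, dtype=float)
    if not np.all(lattice.contains(row, col)):
        raise ExteriorQueryError("query outside the anchor lattice")
    scalar = row.ndim == 0 and col.ndim == 0
    interp = RegularGridInterpolator(
        (lattice.rows, lattice.cols), lattice.values, method="linear",
        bounds_error=True,
    )
    out = interp(np.stack([np.atleast_1d(row), np.atleast_1d(col)], axis=-1))
    return float(out[0]) if scalar else out


def extrapolate_nearest(
    lattice: AnchorLattice,
    row: Union[float, np.ndarray],
    col: Union[float, np.ndarray],
    method: str = "bilinear",
) -> np.ndarray:
    """Pseudo-PCI for points outside (or inside) the anchor hull.

    Each query is moved to the nearest covered location under Euclidean
    distance in spot-index space — for an axis-aligned rectangle this is
    the per-axis clamp, which is unique — and the surface is evaluated
    there. At covered positions this coincides with plain interpolation.
    """
    row = np.clip(np.asarray(row, dtype=float), lattice.rows[0], lattice.rows[-1])
    col = np.clip(np.asarray(col, dtype=float), lattice.cols[0], lattice.cols[-1])
    if method == "bilinear":
        return bilinear_interpolate(lattice, row, col)
    if method == "spline":
        return _spline_evaluate(lattice, row, col)
    raise ValueError(f"unknown interpolation method {method!r}")


def _spline_evaluate(lattice: AnchorLattice, row: np.ndarray, col: np.ndarray) -> np.ndarray:
    """Interpolating bicubic tensor spline through the anchor lattice."""
    spline = RectBivariateSpline(
        lattice.rows, lattice.cols, lattice.values, kx=3, ky=3, s=0
    )
    out = spline.ev(np.atleast_1d(row), np.atleast_1d(col))
    scalar = np.ndim(row) == 0 and np.ndim(col) == 0
    return float(out[0]) if scalar else out


@dataclass
class CorrectionSurface:
    """Per-spot correction factors CF = PCI*/<PCI>, clamped.

    ``pseudo_pci`` and ``cf`` are aligned with the slide's spot table
    (layout order). ``cf`` is clamped into ``clamp_bounds``; ``cf_raw``
    keeps the unclamped ratio and ``n_clamped`` counts clamp events.
    """

    cf: np.ndarray
    pseudo_pci: np.ndarray
    reference: float
    method: str
    clamp_bounds: tuple[float, float]
    anchors: list[Anchor] = field(repr=False)
    lattice: AnchorLattice = field(repr=False)
    cf_raw: np.ndarray = field(repr=False)
    n_clamped: int = 0


@dataclass
class NormalizedSlide:
    """A slide plus its spatially corrected intensities I' = I / CF."""

    slide: Slide
    corrected: np.ndarray
    surface: CorrectionSurface

    def to_slide(self) -> Slide:
        """Slide whose spot table carries the corrected and CF columns."""
        df = self.slide.spots.copy()
        df["corrected"] = self.corrected
        df["cf"] = self.surface.cf
        return Slide(layout=self.slide.layout, spots=df,
                     metadata=dict(self.slide.metadata))


def build_surface(
    slide: Slide,
    policy: str = "median",
    method: str = "bilinear",
    clamp_bounds: tuple[float, float] = DEFAULT_CLAMP,
) -> CorrectionSurface:
    """Compose anchor selection, lattice assembly, interpolation and clamping.

    Interior spots take the bilinear (or bicubic-spline) pseudo-PCI of
    their surrounding anchors; exterior spots the nearest covered value.
    CF = PCI*/<PCI> is clamped into ``clamp_bounds`` (a dead region on a
    slide would otherwise explode corrected intensities); clamp events are
    logged. Every spot — valid or not — receives a correction factor.
    """
    if method not in ("bilinear", "spline"):
        raise ValueError(f"unknown interpolation method {method!r}")
    anchors = select_anchors(slide, policy=policy)
    lattice = assemble_lattice(anchors)
    reference = compute_reference(anchors)

    use = method
    if method == "spline" and (len(lattice.rows) < 4 or len(lattice.cols) < 4):
        warnings.warn(
            "anchor lattice too small for a bicubic spline; falling back to "
            "bilinear interpolation", stacklevel=2,
        )
        logger.warning("spline requested on a %dx%d lattice; using bilinear",
                       len(lattice.rows), len(lattice.cols))
        use = "bilinear"

    rows = slide.spots["row"].to_numpy(dtype=float)
    cols = slide.spots["col"].to_numpy(dtype=float)
    pseudo = extrapolate_nearest(lattice, rows, cols, method=use)
    cf_raw = pseudo / reference
    lo, hi = clamp_bounds
    if not 0 < lo < hi:
        raise ValueError("clamp bounds must satisfy 0 < low < high")
    cf = np.clip(cf_raw, lo, hi)
    n_clamped = int(np.sum((cf_raw < lo) | (cf_raw > hi)))
    if n_clamped:
        logger.warning("clamped %d correction factor(s) into [%g, %g]",
                       n_clamped, lo, hi)
    return CorrectionSurface(
        cf=cf, pseudo_pci=pseudo, reference=reference, method=use,
        clamp_bounds=(lo, hi), anchors=anchors, lattice=lattice,
        cf_raw=cf_raw, n_clamped=n_clamped,
    )


def spline_surface(
    slide: Slide,
    policy: str = "median",
    clamp_bounds: tuple[float, float] = DEFAULT_CLAMP,
) -> CorrectionSurface:
    """Bicubic-spline variant of :func:`build_surface`.

    Falls back to bilinear (with a warning) when the lattice has fewer
    than 4 distinct rows or columns, where cubic pieces are unsupported.
    """
    return build_surface(slide, policy=policy, method="spline",
                         clamp_bounds=clamp_bounds)


def apply_correction(slide: Slide, surface: CorrectionSurface) -> NormalizedSlide:
    """Divide every spot's intensity by its correction factor.

    Invalid spots are corrected too (they keep their flag); raw
    intensities are preserved on the slide.
    """
    if len(surface.cf) != len(slide.spots):
        raise ValueError("correction surface does not cover every spot")
    if not np.all(np.isfinite(surface.cf)) or np.any(surface.cf <= 0):
        raise ValueError("correction factors must be finite and positive")
    corrected = slide.spots["intensity"].to_numpy(dtype=float) / surface.cf
    return NormalizedSlide(slide=slide, corrected=corrected, surface=surface)


def normalize_slide(
    slide: Slide,
    policy: str = "median",
    method: str = "bilinear",
    clamp_bounds: tuple[float, float] = DEFAULT_CLAMP,
) -> NormalizedSlide:
    """One-call spatial normalization: build the surface and apply it."""
    return apply_correction(slide, build_surface(
        slide, policy=policy, method=method, clamp_bounds=clamp_bounds))
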