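"""Synthetic RPPA slides with known ground truth.

The simulator emulates the production slide design — serially half-diluted
samples, positive-control dilution sets shared across the slide, one buffer
spot per subgrid — under a known multiplicative spatial bias field and
multiplicative lognormal measurement noise:

    measured = true_intensity * bias(row, col) * exp(N(0, sigma_log)).

Because signal generation in the assay is proportional (reporter deposition
scales with bound antibody), both bias and noise are modelled as
multiplicative, which composes cleanly with the correction-factor model.
Every simulated slide ships with a :class:`TruthRecord` storing the exact
true intensities, bias values and noise multipliers, so bias-removal claims
are testable spot by spot. Bias fields are normalized to unit mean (smooth
fields over the slide grid; cell-wise bilinear fields over their defining
lattice nodes) so the simulated reference intensity is unbiased.

Not modelled: antibody cross-reactivity, signal saturation, spot morphology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .layout import Slide, SlideLayout, SpotRole, build_default_layout

__all__ = [
    "BiasField",
    "SimulationConfig",
    "TruthRecord",
    "constant_field",
    "linear_gradient",
    "radial_gaussian",
    "low_freq_sinusoid",
    "cellwise_bilinear",
    "make_bias_field",
    "anchor_node_positions",
    "simulate_slide",
    "simulate_replicate_study",
    "simulate_duplicate_pair",
]


# ---------------------------------------------------------------------------
# bias fields
# ---------------------------------------------------------------------------

@dataclass
class BiasField:
    """A positive multiplicative field over the slide's absolute grid.

    ``grid`` holds the field value at every (row, col); ``evaluate``
    indexes it for 1-based positions. Cell-wise bilinear fields also carry
    their defining lattice (``node_rows``, ``node_cols``, ``node_values``).
    """

    kind: str
    params: dict
    grid: np.ndarray
    node_rows: Optional[np.ndarray] = None
    node_cols: Optional[np.ndarray] = None
    node_values: Optional[np.ndarray] = None

    def evaluate(self, rows, cols) -> np.ndarray:
        return self.grid[np.asarray(rows) - 1, np.asarray(cols) - 1]

    @property
    def slide_mean(self) -> float:
        return float(self.grid.mean())


def _positions(layout: SlideLayout) -> tuple[np.ndarray, np.ndarray]:
    r = np.arange(1, layout.n_rows + 1, dtype=float)
    c = np.arange(1, layout.n_cols + 1, dtype=float)
    return np.meshgrid(r, c, indexing="ij")


def constant_field(layout: SlideLayout) -> BiasField:
    """No spatial bias: the field is identically 1."""
    return BiasField("constant", {},
                     np.ones((layout.n_rows, layout.n_cols)))


def linear_gradient(
    layout: SlideLayout,
    amplitude: float = 0.3,
    direction: tuple[float, float] = (0.0, 1.0),
) -> BiasField:
    """Linear ramp 1 + amplitude * t, t in [-1, 1] along ``direction``.

    t is the projection of the spot position onto the direction vector,
    rescaled so the field spans [1-a, 1+a]. A linear field's mean over the
    full grid is its value at the grid centre, so the mean is exactly 1.
    """
    if not 0 <= amplitude < 1:
        raise ValueError("amplitude must lie in [0, 1)")
    rr, cc = _positions(layout)
    proj = direction[0] * rr + direction[1] * cc
    lo, hi = proj.min(), proj.max()
    if hi == lo:
        raise ValueError("degenerate gradient direction")
    t = 2.0 * (proj - lo) / (hi - lo) - 1.0
    return BiasField("linear_gradient",
                     {"amplitude": amplitude, "direction": tuple(direction)},
                     1.0 + amplitude * t)


def radial_gaussian(
    layout: SlideLayout,
    amplitude: float = 0.3,
    centre: Optional[tuple[float, float]] = None,
    sigma: Optional[float] = None,
) -> BiasField:
    """Gaussian bump 1 + amplitude * exp(-d^2 / 2 sigma^2), unit-mean scaled."""
    if not 0 <= amplitude < 1:
        raise ValueError("amplitude must lie in [0, 1)")
    rr, cc = _positions(layout)
    if centre is None:
        centre = ((layout.n_rows + 1) / 2, (layout.n_cols + 1) / 2)
    if sigma is None:
        sigma = min(layout.n_rows, layout.n_cols) / 3.0
    d2 = (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2
    raw = 1.0 + amplitude * np.exp(-d2 / (2.0 * sigma**2))
    grid = raw / raw.mean()
    return BiasField("radial_gaussian",
                     {"amplitude": amplitude, "centre": centre, "sigma": sigma},
                     grid)


def low_freq_sinusoid(
    layout: SlideLayout,
    amplitude: float = 0.3,
    periods: tuple[float, float] = (1.0, 1.0),
    phase: tuple[float, float] = (0.7, 0.3),
) -> BiasField:
    """Smooth low-frequency undulation: 1 + a sin(.) sin(.), unit-mean scaled.

    One period along each axis by default — the gentle tilt/edge pattern
    uneven reagent exposure produces, varying slowly relative to the
    11-spot subgrid pitch so it is well captured by the anchor lattice.
    """
    if not 0 <= amplitude < 1:
        raise ValueError("amplitude must lie in [0, 1)")
    rr, cc = _positions(layout)
    raw = 1.0 + amplitude * (
        np.sin(2 * np.pi * periods[0] * (rr - 1) / (layout.n_rows - 1) + phase[0])
        * np.sin(2 * np.pi * periods[1] * (cc - 1) / (layout.n_cols - 1) + phase[1])
    )
    grid = raw / raw.mean()
    return BiasField("low_freq_sinusoid",
                     {"amplitude": amplitude, "periods": tuple(periods),
                      "phase": tuple(phase)},
                     grid)


def anchor_node_positions(layout: SlideLayout) -> tuple[np.ndarray, np.ndarray]:
    """Absolute positions of the default (median-dilution) anchor lattice.

    One node row per subgrid row (the control row) and one node column per
    control set, at the middle dilution of its 5-spot run — where the
    median-of-set anchor of a clean monotone dilution series sits.
    """
    mid = (layout.n_dilutions + 1) // 2
    rows = np.array([
        (sgr - 1) * layout.subgrid_height + layout.control_row
        for sgr in range(1, layout.n_subgrid_rows + 1)
    ], dtype=float)
    cols = np.array([
        (sgc - 1) * layout.subgrid_width + k * layout.n_dilutions + mid
        for sgc in range(1, layout.n_subgrid_cols + 1)
        for k in range(layout.n_control_sets)
    ], dtype=float)
    return rows, cols


def _bilinear_closed_form(
    node_rows: np.ndarray, node_cols: np.ndarray, node_values: np.ndarray,
    rows: np.ndarray, cols: np.ndarray,
) -> np.ndarray:
    """Direct four-corner bilinear blend with per-axis clamping outside."""
    r = np.clip(np.asarray(rows, dtype=float), node_rows[0], node_rows[-1])
    c = np.clip(np.asarray(cols, dtype=float), node_cols[0], node_cols[-1])
    i = np.clip(np.searchsorted(node_rows, r, side="right") - 1,
                0, len(node_rows) - 2)
    j = np.clip(np.searchsorted(node_cols, c, side="right") - 1,
                0, len(node_cols) - 2)
    t = (r - node_rows[i]) / (node_rows[i + 1] - node_rows[i])
    u = (c - node_cols[j]) / (node_cols[j + 1] - node_cols[j])
    return ((1 - t) * (1 - u) * node_values[i, j]
            + (1 - t) * u * node_values[i, j + 1]
            + t * (1 - u) * node_values[i + 1, j]
            + t * u * node_values[i + 1, j + 1])


def cellwise_bilinear(
    layout: SlideLayout,
    amplitude: float = 0.3,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> BiasField:
    """Bias that is exactly bilinear within every anchor cell.

    Node values are drawn uniformly in [1-a, 1+a] at the default anchor
    lattice positions and normalized to unit node mean, making the
    bilinear normalizer's recovery exact (the acceptance backbone); the
    field is constant beyond the lattice hull (per-axis clamp), matching
    the normalizer's nearest-covered-point exterior rule.
    """
    if not 0 <= amplitude < 1:
        raise ValueError("amplitude must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    node_rows, node_cols = anchor_node_positions(layout)
    values = rng.uniform(1.0 - amplitude, 1.0 + amplitude,
                         size=(len(node_rows), len(node_cols)))
    values /= values.mean()
    rr, cc = _positions(layout)
    grid = _bilinear_closed_form(node_rows, node_cols, values, rr, cc)
    return BiasField("cellwise_bilinear", {"amplitude": amplitude},
                     grid, node_rows=node_rows, node_cols=node_cols,
                     node_values=values)


_FIELD_FACTORIES = {
    "constant": constant_field,
    "linear_gradient": linear_gradient,
    "radial_gaussian": radial_gaussian,
    "low_freq_sinusoid": low_freq_sinusoid,
    "cellwise_bilinear": cellwise_bilinear,
}


def make_bias_field(kind: str, layout: SlideLayout, **params) -> BiasField:
    """Factory by field name: constant, linear_gradient, radial_gaussian,
    low_freq_sinusoid, or cellwise_bilinear."""
    try:
        factory = _FIELD_FACTORIES[kind]
    except KeyError:
        raise ValueError(f"unknown bias field kind {kind!r}") from None
    return factory(layout, **params)


# ---------------------------------------------------------------------------
# slide simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for one simulated slide.

    Defaults model a production slide: positive-control top level 10000
    signal units; sample top levels lognormal around 5000 with wide
    (sdlog = 1) biological spread; buffer background 200; 5% multiplicative
    measurement noise (sigma on the log scale); bias amplitude as carried
    by ``bias``. Identical config + seed reproduces a slide bit for bit.
    """

    layout: SlideLayout = field(default_factory=build_default_layout)
    control_level: float = 10000.0
    sample_meanlog: float = math.log(5000.0)
    sample_sdlog: float = 1.0
    noise_sigma_log: float = 0.05
    background_level: float = 200.0
    bias: Optional[BiasField] = None

    def __post_init__(self) -> None:
        if self.control_level <= 0 or self.background_level < 0:
            raise ValueError("control_level must be positive and "
                             "background_level non-negative")
        if self.noise_sigma_log < 0:
            raise ValueError("noise_sigma_log must be non-negative")
        if self.bias is None:
            self.bias = constant_field(self.layout)
        if self.bias.grid.shape != (self.layout.n_rows, self.layout.n_cols):
            raise ValueError("bias field does not match the layout grid")


@dataclass
class TruthRecord:
    """Exact per-spot ground truth of a simulated slide (layout order)."""

    true_intensity: np.ndarray
    bias: np.ndarray
    noise: np.ndarray
    config: SimulationConfig


def _true_intensities(
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_levels: Optional[dict[str, float]] = None,
) -> np.ndarray:
    """Noise- and bias-free intensity of every spot.

    Dilution step d carries level * dilution_factor^(d-1); positive
    controls share one top level, samples draw independent lognormal top
    levels (unless supplied), buffers sit at the background level.
    """
    table = config.layout.table
    dil = config.layout.dilution_factor ** (
        table["dilution_step"].to_numpy() - 1).clip(min=0)
    role = table["role"].to_numpy()
    truth = np.empty(len(table))

    if sample_levels is None:
        ids = sorted(table.loc[role == SpotRole.SAMPLE.value, "sample_id"].unique())
        draws = rng.lognormal(config.sample_meanlog, config.sample_sdlog,
                              size=len(ids))
        sample_levels = dict(zip(ids, draws))
    level = table["sample_id"].map(sample_levels).to_numpy(dtype=float)

    is_sample = role == SpotRole.SAMPLE.value
    is_pc = role == SpotRole.POSITIVE_CONTROL.value
    is_neg = role == SpotRole.NEGATIVE_CONTROL.value
    truth[is_sample] = level[is_sample] * dil[is_sample]
    truth[is_pc] = config.control_level * dil[is_pc]
    truth[is_neg] = config.background_level
    return truth


def _measure(
    config: SimulationConfig, truth: np.ndarray, rng: np.random.Generator,
    bias: Optional[BiasField] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    bias = config.bias if bias is None else bias
    table = config.layout.table
    b = bias.evaluate(table["row"].to_numpy(), table["col"].to_numpy())
    noise = np.exp(rng.normal(0.0, config.noise_sigma_log, size=len(truth))) \
        if config.noise_sigma_log > 0 else np.ones(len(truth))
    return truth * b * noise, b, noise


def simulate_slide(
    config: SimulationConfig,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    metadata: Optional[dict] = None,
) -> tuple[Slide, TruthRecord]:
    """Draw one slide: truth, then measured = truth * bias * noise."""
    if rng is None:
        rng = np.random.default_rng(seed)
    truth = _true_intensities(config, rng)
    measured, b, noise = _measure(config, truth, rng)
    slide = Slide.from_intensities(config.layout, measured,
                                   metadata=metadata or {"slide_id": "sim"})
    return slide, TruthRecord(true_intensity=truth, bias=b, noise=noise,
                              config=config)


def simulate_replicate_study(
    config: SimulationConfig,
    n_conditions: int = 100,
    n_bio_replicates: int = 3,
    replicate_cv: float = 0.10,
    seed: Optional[int] = None,
) -> tuple[Slide, TruthRecord, dict[str, str]]:
    """One slide carrying a biological-replicate study plus grouping map.

    ``n_conditions`` experimental conditions are printed in
    ``n_bio_replicates`` biological replicates each (3 by default,
    mirroring a triplicated drug-perturbation design). Replicates of one
    condition share a lognormal condition mean and scatter around it with
    lognormal dispersion whose CV equals ``replicate_cv``; replicate spots
    are scattered over the slide at random so spatial bias shows up as
    excess replicate variance. Remaining sample slots carry independent
    singleton samples. Returns (slide, truth, {sample_id: condition}).
    """
    layout = config.layout
    n_slots = layout.n_subgrids * layout.samples_per_subgrid
    needed = n_conditions * n_bio_replicates
    if needed > n_slots:
        raise ValueError(
            f"{needed} replicate slots requested but the layout has {n_slots}")
    rng = np.random.default_rng(seed)

    ids = sorted(
        layout.table.loc[layout.table["role"] == SpotRole.SAMPLE.value,
                         "sample_id"].unique()
    )
    assignment = rng.permutation(ids)
    sigma_rep = math.sqrt(math.log(1.0 + replicate_cv**2))
    cond_means = rng.lognormal(config.sample_meanlog, config.sample_sdlog,
                               size=n_conditions)
    sample_levels: dict[str, float] = {}
    grouping: dict[str, str] = {}
    for k in range(n_conditions):
        for r in range(n_bio_replicates):
            sid = assignment[k * n_bio_replicates + r]
            factor = math.exp(rng.normal(0.0, sigma_rep)) if sigma_rep > 0 else 1.0
            sample_levels[sid] = cond_means[k] * factor
            grouping[sid] = f"cond_{k + 1:03d}"
    for sid in assignment[needed:]:
        sample_levels[sid] = float(
            rng.lognormal(config.sample_meanlog, config.sample_sdlog))

    truth = _true_intensities(config, rng, sample_levels=sample_levels)
    measured, b, noise = _measure(config, truth, rng)
    slide = Slide.from_intensities(layout, measured,
                                   metadata={"slide_id": "sim_replicate_study"})
    record = TruthRecord(true_intensity=truth, bias=b, noise=noise,
                         config=config)
    return slide, record, grouping


def simulate_duplicate_pair(
    config: SimulationConfig,
    bias_second: Optional[BiasField] = None,
    seed: Optional[int] = None,
) -> tuple[tuple[Slide, TruthRecord], tuple[Slide, TruthRecord]]:
    """Two slides printed with the same samples at equivalent locations.

    The truth is drawn once; each slide gets its own bias field
    (``config.bias`` and ``bias_second``, defaulting to the first) and an
    independent noise draw — the duplicate-slide design used to measure
    inter-slide reproducibility.
    """
    ss = np.random.SeedSequence(seed)
    rng_truth, rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(3))
    truth = _true_intensities(config, rng_truth)
    pair = []
    for rng, bias, tag in ((rng_a, config.bias, "A"),
                           (rng_b, bias_second or config.bias, "B")):
        measured, b, noise = _measure(config, truth, rng, bias=bias)
        slide = Slide.from_intensities(config.layout, measured,
                                       metadata={"slide_id": f"sim_dup_{tag}"})
        pair.append((slide, TruthRecord(true_intensity=truth, bias=b,
                                        noise=noise, config=config)))
    return pair[0], pair[1]
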