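import numpy as np
import pytest

from rppanorm import Slide, SlideLayout, build_default_layout


@pytest.fixture(scope="session")
def default_layout() -> SlideLayout:
    return build_default_layout()


@pytest.fixture(scope="session")
def toy_layout() -> SlideLayout:
    """3 x 3 subgrids of 6 x 6 spots with one control set per subgrid.

    Yields a 3 x 3 anchor lattice (rows 6/12/18, cols 3/9/15 under the
    fixed middle-dilution policy) — small enough for exhaustive oracles.
    """
    return SlideLayout(
        n_subgrid_rows=3, n_subgrid_cols=3,
        subgrid_height=6, subgrid_width=6,
        n_dilutions=5, samples_per_subgrid=6,
        n_control_sets=1, control_row=6,
    )


def make_slide(layout: SlideLayout, intensities=None, rng=None) -> Slide:
    """Slide with given (or seeded lognormal) intensities in layout order."""
    if intensities is None:
        rng = rng or np.random.default_rng(0)
        intensities = rng.lognormal(mean=8.0, sigma=0.5, size=layout.n_spots)
    return Slide.from_intensities(layout, np.asarray(intensities, dtype=float))


@pytest.fixture()
def uniform_slide(default_layout) -> Slide:
    """Every spot at the same positive intensity."""
    return make_slide(default_layout,
                      np.full(default_layout.n_spots, 1000.0))
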