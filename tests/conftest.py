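import numpy as np
import pytest

from biospot.imaging import GridModel, PadLayout


@pytest.fixture
def small_layout():
    """3x4 lattice, pitch 20 px, spot radius 4 px."""
    return PadLayout(n_rows=3, n_cols=4, pitch=20.0, spot_radius=4.0)


@pytest.fixture
def grid_10x10():
    """10x10 lattice used by most densitometry fixtures."""
    return PadLayout(n_rows=10, n_cols=10, pitch=16.0, spot_radius=4.0)


def axis_aligned_grid(layout: PadLayout, origin=(20.0, 20.0)) -> GridModel:
    """Exact unrotated GridModel for a layout (test helper)."""
    return GridModel(
        origin=np.asarray(origin, dtype=float),
        row_step=np.array([0.0, layout.pitch]),
        col_step=np.array([layout.pitch, 0.0]),
    )


def spanning_active_mask(rng: np.random.Generator, n_rows: int, n_cols: int,
                         p_active: float) -> np.ndarray:
    """Random active mask guaranteed to touch every row and column.

    Mirrors the real assay, where baseline bioreporter luminescence
    makes every row/column visible; keeps the lattice-window placement
    identifiable.
    """
    while True:
        mask = rng.random((n_rows, n_cols)) < p_active
        if mask.any(axis=1).all() and mask.any(axis=0).all():
            return mask
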