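import numpy as np
import pytest

from ctoam.projection import Densitogram


def make_densitogram(values, surface_mask=None, pixel_size=1.0, view="proximal",
                     subject=None, timepoint=None):
    """Construct a densitogram directly from a 2D array, for unit tests."""
    values = np.asarray(values, dtype=float)
    if surface_mask is None:
        surface_mask = np.isfinite(values)
    out = np.where(surface_mask, values, np.nan)
    return Densitogram(
        values_hu=out,
        surface_mask=np.asarray(surface_mask, dtype=bool),
        pixel_size=pixel_size,
        view_name=view,
        mip_depth=1.5,
        u0=0.0,
        v0=0.0,
        subject_id=subject,
        timepoint=timepoint,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def quiet_spec():
    """Compact noise-free synthetic spec shared by deterministic tests."""
    from dataclasses import replace

    from ctoam.synthetic import compact_spec

    return replace(compact_spec(), noise_sd=0.0)
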