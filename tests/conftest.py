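"""Shared fixtures: coarse flow solves reused across test modules."""
import numpy as np
import pytest

import stenoflow as sf

#: Grid spacing used for shared test solves (m); coarse enough to keep the
#: direct solves fast, fine enough for <1% Poiseuille accuracy.
DX_TEST = 2e-6
Q_PRP = 2.4e-9
W_EXP = 480e-6
W_SLAB = 50e-6


@pytest.fixture(scope="session")
def straight_geometry():
    return sf.ChamberGeometry.straight(channel_width=W_EXP, length=60e-6)


@pytest.fixture(scope="session")
def straight_flow(straight_geometry):
    """Plane-Poiseuille reference: straight channel, experimental width."""
    mask = sf.rasterize(straight_geometry, DX_TEST)
    return sf.solve_flow(mask, sf.PRP, Q_PRP, width=W_EXP)


@pytest.fixture(scope="session")
def slab_geometry():
    """Full-length straight slab at the periodic simulation width (50 um)."""
    return sf.ChamberGeometry.straight(channel_width=W_SLAB)


@pytest.fixture(scope="session")
def slab_flow(slab_geometry):
    mask = sf.rasterize(slab_geometry, DX_TEST)
    q = Q_PRP * W_SLAB / W_EXP  # equal mean velocity in the periodic slab
    return sf.solve_flow(mask, sf.PRP, q, width=W_SLAB)


@pytest.fixture(scope="session")
def vr_geometry():
    return sf.build_van_rooij_geometry()


@pytest.fixture(scope="session")
def vr_flow(vr_geometry):
    """Stenotic chamber solve at the PRP flow rate (coarse grid)."""
    mask = sf.rasterize(vr_geometry, DX_TEST)
    return sf.solve_flow(mask, sf.PRP, Q_PRP, width=W_EXP)
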