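"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from flashmap.geometry import build_geometry, place_binding_sites
from flashmap.simulate import (
    DriftTrajectory,
    ImagingParams,
    events_to_localizations,
    simulate_rounds,
)
from flashmap.tables import LocalizationTable


TWO_LAYER_GEOMETRY = {
    "preset": "two_layer",
    "delta": 60.0,
    "ribbon_length": 4000.0,
    "site_density_per_um": 200.0,
}

# photons_per_frame chosen so a one-frame event has sigma_loc = 130/sqrt(676) ~ 5 nm
TWO_LAYER_IMAGING = dict(
    n_rounds=2, frames_per_round=3000, photons_per_frame=676.0,
    mean_dark_frames=500.0, mean_bright_frames=3.0,
)


@pytest.fixture(scope="session")
def two_layer_sim():
    """A dense two-layer simulation (no drift) shared by registration and
    proximity tests: sites, events, imaging params and the list-mode table."""
    rng = np.random.default_rng(20240901)
    geometry = build_geometry(TWO_LAYER_GEOMETRY)
    sites = place_binding_sites(geometry, 1.0, 0.0, rng)
    params = ImagingParams(**TWO_LAYER_IMAGING)
    events = simulate_rounds(sites, params, rng)
    table = events_to_localizations(
        events, sites, DriftTrajectory.zero(params.n_frames_total), params, rng
    )
    return {
        "geometry": geometry,
        "sites": sites,
        "params": params,
        "events": events,
        "table": table,
    }


@pytest.fixture()
def toy_table():
    """A tiny hand-written localization table."""
    df = pd.DataFrame(
        {
            "frame": [0, 1, 2, 0, 5],
            "round": [0, 0, 0, 1, 1],
            "x": [100.0, 102.0, 101.0, 500.0, 504.0],
            "y": [200.0, 201.0, 199.0, 600.0, 601.0],
            "photons": [1000.0, 800.0, 900.0, 1200.0, 700.0],
            "loc_precision": [5.0, 6.0, 5.5, 4.0, 7.0],
            "species": [0, 0, 0, 1, 1],
        }
    )
    return LocalizationTable(df=df, pixel_size=108.0)
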