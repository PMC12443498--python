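import numpy as np
import pandas as pd
import pytest

from riversdm.config import RunConfig
from riversdm.network import StreamNetwork, StreamSegment, compute_strahler_orders
from riversdm.pipeline import run_pipeline


def build_network(segment_specs, grid_shape=(40, 40), cell_size_km=1.0):
    """Hand-build a network from (id, cells, downstream_id) triples."""
    segments = []
    down_of = {}
    for seg_id, cells, downstream_id in segment_specs:
        segments.append(
            StreamSegment(id=seg_id, upstream_ids=[], cells=list(cells), downstream_id=downstream_id)
        )
        down_of[seg_id] = downstream_id
    by_id = {s.id: s for s in segments}
    for seg_id, downstream_id in down_of.items():
        if downstream_id is not None:
            by_id[downstream_id].upstream_ids.append(seg_id)
    net = StreamNetwork.from_segments(segments, grid_shape, cell_size_km)
    return compute_strahler_orders(net)


@pytest.fixture
def y_network():
    """Two order-1 headwaters joining into one downstream segment."""
    return build_network(
        [
            (0, [(0, 0), (1, 1)], 2),
            (1, [(0, 4), (1, 3)], 2),
            (2, [(2, 2), (3, 2), (4, 2)], None),
        ]
    )


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """The default synthetic study, run once end to end and shared.

    Returns (config, outdir) with every pipeline artifact written.
    """
    outdir = tmp_path_factory.mktemp("default_study")
    cfg = RunConfig(seed=0)
    run_pipeline(cfg, outdir)
    return cfg, outdir


def load_sites(outdir) -> pd.DataFrame:
    return pd.read_csv(outdir / "sites.csv")


def load_grid(outdir, name) -> np.ndarray:
    from riversdm.grids import read_ascii_grid

    grid, _ = read_ascii_grid(outdir / name)
    return grid
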