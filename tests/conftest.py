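import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from retcomm.io_formats import ExpressionAtlas
from retcomm.profiles import CellTypeProfile
from retcomm.synthetic import default_design, simulate_experiment


def make_atlas(counts, genes, cell_types, timepoints_per_cell, subclasses=None,
               declared=("control", "12h", "24h", "48h")):
    """Hand-build a small atlas from a dense array."""
    counts = np.asarray(counts)
    n_cells = counts.shape[1]
    subclasses = subclasses or [None] * n_cells
    cells = pd.DataFrame({
        "barcode": [f"bc{i:04d}" for i in range(n_cells)],
        "cell_type": cell_types,
        "subclass": subclasses,
        "survival_class": [None] * n_cells,
        "timepoint": timepoints_per_cell,
        "sample": ["s1"] * n_cells,
    })
    return ExpressionAtlas(counts=sp.csr_matrix(counts), genes=list(genes), cells=cells,
                           timepoints=tuple(declared))


def make_profile(group, timepoint, mean, detection=None, n_cells=10):
    """Profile from plain dicts; detection defaults to 1 for nonzero means."""
    mean = pd.Series(mean, dtype=float)
    if detection is None:
        detection = (mean > 0).astype(float)
    else:
        detection = pd.Series(detection, dtype=float).reindex(mean.index).fillna(0.0)
    return CellTypeProfile(group=group, timepoint=timepoint, mean_expr=mean,
                           detection_rate=detection, n_cells=n_cells)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated experiment reused by read-only tests."""
    design = default_design(n_cell_types=4, n_high=2, n_low=2, n_genes=80,
                            cells_per_group=80, n_planted=2, n_decoys=4,
                            n_loops=1, seed=11)
    atlas, truth = simulate_experiment(design)
    return design, atlas, truth
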