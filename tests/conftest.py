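import numpy as np
import pandas as pd
import pytest

from slscreen.screen import PlateGeometry, ScreenDataset


def make_dataset(values_by_replicate, geometry=None, roles=None):
    """Build a one-plate ScreenDataset from {(genotype, rep): 2-D array}.

    ``roles`` is an optional matrix of role strings (default all library);
    reagents are named g_{row}_{col} so the map is shared across replicates.
    """
    rows = []
    geometry = geometry or PlateGeometry(*next(iter(values_by_replicate.values())).shape)
    for (genotype, rep), mat in values_by_replicate.items():
        mat = np.asarray(mat, dtype=float)
        for i in range(mat.shape[0]):
            for j in range(mat.shape[1]):
                role = roles[i][j] if roles is not None else "library"
                rows.append(
                    {
                        "plate": "P1",
                        "row": i + 1,
                        "col": j + 1,
                        "reagent": "" if role == "empty" else f"g_{i + 1}_{j + 1}",
                        "role": role,
                        "genotype": genotype,
                        "replicate": rep,
                        "readout": mat[i, j],
                    }
                )
    return ScreenDataset(pd.DataFrame(rows), geometry)


@pytest.fixture
def rng():
    return np.random.default_rng(20241105)
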