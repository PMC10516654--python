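import numpy as np
import pandas as pd
import pytest

from mrpr.hdx import PEPTIDE_COLUMNS


def make_peptide_rows(
    peptides,
    timepoints=(10.0,),
    replicates=(1,),
    protease="pepsin",
    **overrides,
):
    """Build a peptide table from (peptide_id, start, end, uptake) tuples.

    Quality columns default to values that pass every filter; override
    per-column via keyword (scalar applied to all rows).
    """
    rows = []
    for pid, start, end, uptake in peptides:
        for t in timepoints:
            for rep in replicates:
                row = {
                    "peptide_id": pid,
                    "sequence": "A" * (end - start + 1),
                    "start": start,
                    "end": end,
                    "protease": protease,
                    "replicate": rep,
                    "timepoint": t,
                    "uptake": uptake,
                    "intensity": 50_000.0,
                    "n_products": 4,
                    "mass_error": 2.0,
                    "rt_delta": 0.1,
                    "n_nondeut_ids": 3,
                }
                row.update(overrides)
                rows.append(row)
    return pd.DataFrame(rows, columns=PEPTIDE_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
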