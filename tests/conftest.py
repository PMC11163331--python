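"""Shared fixtures: one noise-free synthetic run processed end-to-end.

The run is generated once per session; several integration and acceptance
tests read from it, so its configuration is the reference condition:
20 specimens + 3 water controls (one per role), zero sequencing error,
zero chimeras.
"""

import numpy as np
import pandas as pd
import pytest

import symbiomark as sm


@pytest.fixture(scope="session")
def noise_free_cfg():
    return sm.default_config(
        n_specimens=20, n_controls=1, seed=11, error_rate=0.0, chimera_rate=0.0,
        reads_mean={"COI": 3000, "16S-V1V2": 1500, "16S-V4": 3000},
    )


@pytest.fixture(scope="session")
def noise_free_run(tmp_path_factory, noise_free_cfg):
    run_dir = tmp_path_factory.mktemp("noise_free_run")
    truth = sm.simulate_run(noise_free_cfg, run_dir)
    result = sm.run_pipeline(run_dir)
    return {"cfg": noise_free_cfg, "dir": run_dir, "truth": truth, "result": result}


def make_table(counts: dict, taxonomy: dict | None = None, marker="16S-V4", level="zOTU"):
    """Small hand-built FeatureTable: counts maps feature -> {sample: n}."""
    df = pd.DataFrame(counts).T.fillna(0).astype(int)
    taxonomy = taxonomy or {}
    meta = pd.DataFrame(
        {
            "sequence": ["" for _ in df.index],
            "taxonomy": [taxonomy.get(f, "") for f in df.index],
            "total_abundance": df.sum(axis=1).to_numpy(),
        },
        index=df.index,
    )
    return sm.FeatureTable(marker, level, df, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
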