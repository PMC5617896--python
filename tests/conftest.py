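"""Shared fixtures: small hand-built matrices and one synthetic pipeline run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from facreg import pipeline
from facreg.core import CountMatrix, Design


def make_design(
    genotypes=("ref", "G"), timepoints=("2h",), replicates=2, library_size=1e6
) -> Design:
    rows = []
    for g in genotypes:
        for tp in timepoints:
            for r in range(1, replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{g}_{tp}_r{r}",
                        "genotype": g,
                        "timepoint": tp,
                        "replicate": r,
                        "library_size": library_size,
                    }
                )
    return Design(pd.DataFrame(rows))


def make_counts(values, lengths=None, **design_kw) -> CountMatrix:
    """CountMatrix from a genes x samples array."""
    values = np.asarray(values)
    design = make_design(**design_kw)
    genes = [f"g{i}" for i in range(values.shape[0])]
    if lengths is None:
        lengths = [1000] * values.shape[0]
    return CountMatrix(
        pd.DataFrame(values, index=genes, columns=design.sample_ids),
        pd.Series(lengths, index=genes),
        design,
    )


@pytest.fixture(scope="session")
def synthetic_run(tmp_path_factory):
    """One full synthetic pipeline run (300 genes, fixed seed), reused widely."""
    outdir = tmp_path_factory.mktemp("synth")
    cfg = pipeline.simulate_inputs(outdir, n_genes=300, seed=11)
    summary = pipeline.run_pipeline(cfg)
    return cfg, summary
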