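import numpy as np
import pandas as pd
import pytest

from her2scape.cohort_io import CopyNumberTable, GeneAnnotation
from her2scape.synthetic_cohort import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-size cohort at the default (noisy) study conditions."""
    return generate_cohort(SimulationConfig(n_tumors=300, n_normals=40), seed=7)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Zero-noise cohort: planted events are recoverable exactly."""
    cfg = SimulationConfig(n_tumors=300, n_normals=40, noise_sd=0.0)
    return generate_cohort(cfg, seed=11)


def make_genes(rows):
    """Helper: gene annotation from (gene_id, chrom, arm, start, end) tuples."""
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "arm", "start", "end"])
    df["symbol"] = df["gene_id"]
    return GeneAnnotation(df.set_index("gene_id"))


def make_cn(values: dict, ploidy=None, samples=None):
    """Helper: CopyNumberTable from {gene: [values per sample]}.

    ``ploidy`` may be a list (aligned to sample order) or a dict by sample.
    """
    df = pd.DataFrame(values).T
    df.columns = samples if samples is not None else [f"S{i}" for i in range(df.shape[1])]
    pl = None
    if ploidy is not None:
        if isinstance(ploidy, dict):
            pl = pd.Series(ploidy, dtype=float)
        else:
            pl = pd.Series(list(ploidy), index=df.columns, dtype=float)
    return CopyNumberTable(values=df.astype(float), ploidy=pl)
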