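import warnings

import numpy as np
import pandas as pd
import pytest

import ptaging as pt
from ptaging.preprocess import preprocess_layer
from ptaging.report import _coefficient_stack
from ptaging.types import Layer, OmicsMatrix, SampleMeta


def make_matrix(values, layer=Layer.PROTEIN_TOTAL, ages=(6, 12, 24), reps=None, genes=None):
    """Build an OmicsMatrix from a 2-D array; columns cycle age-major."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if reps is None:
        reps = -(-n_samples // len(ages))  # ceil; trailing ages may be short
    samples = []
    for age in ages:
        for r in range(1, reps + 1):
            an = f"A{age}m_{r}"
            samples.append(SampleMeta(f"{layer.value}:{an}", an, age, layer))
    samples = samples[:n_samples]
    genes = genes or [f"g{i}" for i in range(n_genes)]
    df = pd.DataFrame(values, index=genes, columns=[s.sample_id for s in samples])
    return OmicsMatrix(df, samples)


@pytest.fixture(scope="session")
def small_cohort():
    """Default planted-phenotype cohort at reduced size."""
    cfg = pt.default_config(n_genes=600, set_size=40, seed=11)
    return pt.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_stack(small_cohort):
    """Preprocessed layers and the three coefficient tables for the small cohort."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = {}
        for lay, m in small_cohort.matrices.items():
            thr = 0.12 if lay.is_count else 0.4
            norm[lay], _ = preprocess_layer(
                m, contaminants=pt.default_contaminants(), stderr_threshold=thr
            )
        coeffs = _coefficient_stack(norm, small_cohort.matrices)
    return {"normalized": norm, "coeffs": coeffs}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
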