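import numpy as np
import pandas as pd
import pytest

from vdindex.io import CountMatrix, GeneAnnotation, load_vitdpas_table1
from vdindex.pipeline import RunConfig, run_pipeline
from vdindex.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def table1():
    return load_vitdpas_table1()


@pytest.fixture(scope="session")
def small_config():
    """Fast cohort: full participant count, reduced gene panel."""
    return SimulationConfig(n_genes=800, n_targets=80, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    counts, cohort, ann, truth = small_cohort
    result = run_pipeline(counts, cohort, ann, config=RunConfig(seed=11))
    return result, truth


def toy_counts(values: np.ndarray, n_pairs: int, gene_ids=None) -> CountMatrix:
    """Wrap a genes x (2*n_pairs) array as a paired CountMatrix."""
    g = values.shape[0]
    gene_ids = gene_ids or [f"g{i}" for i in range(g)]
    sample_ids, rows = [], []
    for p in range(n_pairs):
        for tp in ("d0", "d1"):
            sid = f"s{p}_{tp}"
            sample_ids.append(sid)
            rows.append({"sample_id": sid, "participant_id": f"p{p}", "timepoint": tp})
    counts = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    counts.index.name = "gene_id"
    return CountMatrix(counts=counts, sample_map=pd.DataFrame(rows).set_index("sample_id"))


def coding_annotation(gene_ids) -> GeneAnnotation:
    return GeneAnnotation(
        pd.DataFrame(
            {
                "symbol": list(gene_ids),
                "biotype": "protein_coding",
                "has_position": True,
            },
            index=pd.Index(list(gene_ids), name="gene_id"),
        )
    )
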