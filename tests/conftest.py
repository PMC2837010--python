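import numpy as np
import pandas as pd
import pytest

from srcprog.containers import ExpressionMatrix, ProbeLevelMatrix, TumorCohort


def make_plm(probeset_probes: dict[str, np.ndarray], conditions: list[str] | None = None,
             temperatures: list[str] | None = None) -> ProbeLevelMatrix:
    """Build a ProbeLevelMatrix from {probeset: (n_probes, n_arrays) array}."""
    blocks, tuples = [], []
    for ps, arr in probeset_probes.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        blocks.append(arr)
        tuples.extend((ps, i) for i in range(arr.shape[0]))
    mat = np.vstack(blocks)
    n_arrays = mat.shape[1]
    array_ids = [f"a{j}" for j in range(n_arrays)]
    conditions = conditions or ["c0"] * n_arrays
    temperatures = temperatures or ["41.5"] * n_arrays
    intensities = pd.DataFrame(
        mat,
        index=pd.MultiIndex.from_tuples(tuples, names=["probeset_id", "probe_index"]),
        columns=array_ids,
    )
    samples = pd.DataFrame(
        {"condition": conditions, "temperature": temperatures, "replicate": range(1, n_arrays + 1)},
        index=pd.Index(array_ids, name="array_id"),
    )
    return ProbeLevelMatrix(intensities, samples)


def make_expression(values: np.ndarray, conditions: list[str],
                    feature_prefix: str = "f") -> ExpressionMatrix:
    """Linear-scale expression matrix with condition metadata."""
    values = np.asarray(values, dtype=float)
    sample_ids = [f"s{j}" for j in range(values.shape[1])]
    samples = pd.DataFrame(
        {"condition": conditions, "temperature": ["41.5"] * len(conditions), "replicate": 1},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    df = pd.DataFrame(
        values, index=[f"{feature_prefix}{i}" for i in range(values.shape[0])], columns=sample_ids
    )
    return ExpressionMatrix(df, samples)


def make_cohort(expression: np.ndarray, times, events, gene_ids=None, tumor_ids=None) -> TumorCohort:
    expression = np.atleast_2d(np.asarray(expression, dtype=float))
    n_genes, n_tumors = expression.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    tumor_ids = tumor_ids or [f"t{j:03d}" for j in range(n_tumors)]
    expr = pd.DataFrame(expression, index=gene_ids, columns=tumor_ids)
    surv = pd.DataFrame(
        {"time": np.asarray(times, float), "event": np.asarray(events, int)},
        index=pd.Index(tumor_ids, name="tumor_id"),
    )
    return TumorCohort(expr, surv)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
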