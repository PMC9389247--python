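"""Shared fixtures: expensive preset-scale objects are session-scoped so
the acceptance-style tests reuse one simulation / one RFE run."""

import warnings

import numpy as np
import pytest

import embrisk
from embrisk import preprocess, scoring, svm


def _prepare(preset: str, seed: int):
    scenario = embrisk.preset_scenario(preset).replace(seed=seed)
    counts, truth = embrisk.simulate_counts(scenario)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        keep = preprocess.mad_filter(preprocess.compute_qc(counts))
    expr = preprocess.normalize_log(counts.subset_cells(keep))
    sets = embrisk.make_gene_sets(scenario)
    return {
        "scenario": scenario,
        "counts": counts,
        "truth": truth,
        "keep": keep,
        "expr": expr,
        "sets": sets,
        "program": truth.program_of_cell[keep],
    }


@pytest.fixture(scope="session")
def mf_prepared():
    return _prepare("mf_default", seed=101)


@pytest.fixture(scope="session")
def il_prepared():
    return _prepare("il_default", seed=202)


@pytest.fixture(scope="session")
def panel_data() -> svm.LabeledDataset:
    """Two-class table whose packaged 13-gene panel drives separation."""
    scenario = embrisk.preset_scenario("panel_default")
    counts, truth = embrisk.simulate_counts(scenario)
    expr = preprocess.normalize_log(counts)
    return svm.LabeledDataset(expr.values, truth.embolic_label, expr.gene_names)


@pytest.fixture(scope="session")
def panel_rfe(panel_data):
    """The full SVM-RFE run over the ten-value penalty grid (slow)."""
    return svm.svm_rfe(panel_data, seed=0)


def make_panel_testset(seed: int) -> svm.LabeledDataset:
    scenario = embrisk.preset_scenario("panel_default").replace(seed=seed)
    counts, truth = embrisk.simulate_counts(scenario)
    expr = preprocess.normalize_log(counts)
    return svm.LabeledDataset(expr.values, truth.embolic_label, expr.gene_names)


@pytest.fixture(scope="session")
def tiny_counts():
    """A 3-cell x 3-gene count matrix with one mitochondrial gene."""
    import scipy.sparse as sp

    from embrisk.io import CountMatrix

    return CountMatrix(
        values=sp.csr_matrix(np.array([[2, 0, 3], [1, 1, 0], [0, 4, 4]])),
        barcodes=["c1", "c2", "c3"],
        gene_ids=["g1", "g2", "g3"],
        gene_names=["MT-A", "B", "C"],
        mito_mask=[True, False, False],
    )
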