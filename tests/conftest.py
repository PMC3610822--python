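import numpy as np
import pandas as pd
import pytest

from gdref import datasets, diffexp, probes, simulate


@pytest.fixture(scope="session")
def tables():
    return datasets.load_paper_tables()


@pytest.fixture(scope="session")
def null_dataset():
    """200 genes, no effects, noise 0.3 — shared across calibration tests."""
    config = simulate.SimulationConfig(
        n_genes=200, probes_per_gene=3, noise_sd=0.3, seed=11
    )
    return config, *simulate.generate_array_dataset(config)


@pytest.fixture(scope="session")
def null_results(null_dataset):
    _, scans, annotations, _ = null_dataset
    matrix = probes.build_matrix(scans, annotations, probes.assign_weights(annotations))
    genes = diffexp.summarize_genes(matrix, annotations)
    design = diffexp.DesignInfo.from_labels(genes.values.columns)
    fit = diffexp.fit_gene_model(genes, design)
    return diffexp.moderate_statistics(fit)


def make_annotations(n_valid, n_crosshyb=0, n_intergenic=0):
    """Hand-built probe annotation table used by several unit tests."""
    rows = []
    i = 0
    for _ in range(n_valid):
        i += 1
        rows.append({"probe_id": f"P{i:06d}", "class": probes.VALID,
                     "gene_ids": f"G{i:06d}"})
    for _ in range(n_crosshyb):
        i += 1
        rows.append({"probe_id": f"P{i:06d}", "class": probes.CROSSHYB,
                     "gene_ids": f"G{i:06d};G{i + 1:06d}"})
    for _ in range(n_intergenic):
        i += 1
        rows.append({"probe_id": f"P{i:06d}", "class": probes.INTERGENIC,
                     "gene_ids": ""})
    return pd.DataFrame(rows)


def matrix_from_values(values: dict, weights=None):
    df = pd.DataFrame(values)
    w = pd.Series(weights, index=df.index) if weights is not None else None
    return probes.ExpressionMatrix(df, w)


def rng(seed=0):
    return np.random.default_rng(seed)
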