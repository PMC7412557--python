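"""Shared fixtures: a small simulated data set and the default-scale run.

The session-scoped fixtures exist because the full default simulation
(2,000 genes, 27 samples) plus its network is expensive; every test that
needs the default-scale objects shares one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aphidnet import (
    ExpressionMatrix,
    filter_expressed,
    generate_annotations,
    generate_design,
    generate_expression,
    generate_metabolites,
    normalize,
)

#: Seed for the shared default-scale simulation; fixed so stochastic
#: recovery checks are reproducible.
DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def design():
    return generate_design()


@pytest.fixture(scope="session")
def small_sim(design):
    """A fast small simulation: 6 modules x 30 genes + 120 background."""
    counts, truth = generate_expression(
        design=design,
        n_genes_per_module=30,
        n_background=120,
        n_hubs_per_module=2,
        seed=7,
    )
    return counts, truth


@pytest.fixture(scope="session")
def default_sim(design):
    """The default-scale simulation used by the recovery checks."""
    counts, truth = generate_expression(design=design, seed=DEFAULT_SEED)
    annotation = generate_annotations(truth, seed=DEFAULT_SEED + 1)
    metabolites = generate_metabolites(
        design=design,
        pathway_ids=sorted(annotation.pathways),
        truth=truth,
        seed=DEFAULT_SEED + 2,
    )
    return counts, truth, annotation, metabolites


@pytest.fixture(scope="session")
def default_network(default_sim, design):
    """Normalized matrix, expressed set, network, and modules at defaults."""
    from aphidnet import build_network, detect_modules

    counts, truth, annotation, metabolites = default_sim
    norm = normalize(counts)
    expressed = filter_expressed(norm)
    data = norm.data.loc[expressed]
    net = build_network(data)
    assignment = detect_modules(net.tom, data)
    return {
        "norm": norm,
        "expressed": expressed,
        "data": data,
        "network": net,
        "assignment": assignment,
    }


@pytest.fixture()
def tiny_matrix():
    """A 4-gene, 6-sample deterministic matrix for arithmetic checks."""
    data = pd.DataFrame(
        np.array(
            [
                [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
                [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
                [0.0, 1.0, 0.0, 2.0, 1.0, 0.0],
            ]
        ),
        index=["gA", "gB", "gC", "gD"],
        columns=[f"s{i}" for i in range(6)],
    )
    return ExpressionMatrix(data=data, scale="log2norm")
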