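import numpy as np
import pandas as pd
import pytest

from earmir.data_io import TargetPredictionTable
from earmir.synthetic_data import PlantedFamily, SyntheticConfig, generate_study
from earmir.target_enrichment import build_graph


@pytest.fixture(scope="session")
def null_study():
    """A complete study with no planted regulation."""
    return generate_study(SyntheticConfig(seed=101))


@pytest.fixture(scope="session")
def protein_only_study():
    """Three families planted with translational (protein-only) suppression."""
    cfg = SyntheticConfig(
        planted_families=(
            PlantedFamily("FAM001", "protein_only", 0.3, 0.4),
            PlantedFamily("FAM002", "protein_only", 0.3, 0.4),
            PlantedFamily("FAM003", "protein_only", 0.3, 0.4),
        ),
        seed=7,
    )
    return generate_study(cfg)


def random_toy_graph(rng, n_edges):
    """A small random weighted bipartite prediction graph for oracle tests."""
    fams = [f"F{i}" for i in range(int(rng.integers(2, 5)))]
    genes = [f"G{i}" for i in range(int(rng.integers(3, 7)))]
    pairs = set()
    while len(pairs) < n_edges:
        pairs.add((str(rng.choice(fams)), str(rng.choice(genes))))
        if len(pairs) == len(fams) * len(genes):
            break
    # sort before drawing weights: set order is hash-randomized per process
    rows = [(f, g, -round(float(rng.uniform(0.05, 0.5)), 3), True) for f, g in sorted(pairs)]
    df = pd.DataFrame(
        rows, columns=["family_id", "gene_id", "site_context_score", "conserved"]
    )
    return build_graph(TargetPredictionTable(df), genes, conserved_only=True), genes


@pytest.fixture
def toy_graph_factory():
    return random_toy_graph
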