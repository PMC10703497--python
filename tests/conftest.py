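import numpy as np
import pandas as pd
import pytest

from celltics.hierarchy import load_pathway_hierarchy
from celltics.model import CellTICS
from celltics.preprocess import normalize_counts, split_train_test
from celltics.simdata import SimConfig, simulate_dataset, write_toy_hierarchy


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """Default synthetic dataset, its toy hierarchy and a 75/25 split."""
    cfg = SimConfig(seed=1)
    matrix, annotation, truth = simulate_dataset(cfg)
    norm = normalize_counts(matrix)
    rel, ann = write_toy_hierarchy(cfg, tmp_path_factory.mktemp("toy"))
    tree = load_pathway_hierarchy(rel, ann, "R-TOY")
    train, train_annot, test, test_annot = split_train_test(norm, annotation, 0.75, seed=1)
    return {
        "cfg": cfg, "counts": matrix, "norm": norm, "annotation": annotation,
        "truth": truth, "tree": tree, "relations": rel, "annotations": ann,
        "train": train, "train_annot": train_annot,
        "test": test, "test_annot": test_annot,
    }


@pytest.fixture(scope="session")
def fitted(sim_bundle):
    """A fully trained two-stage model on the default synthetic data."""
    model = CellTICS(sim_bundle["train"], sim_bundle["train_annot"],
                     sim_bundle["tree"], n_levels=2)
    return model.fit(seed=1)


@pytest.fixture
def toy_tree_files(tmp_path):
    """Hand-written 2-level hierarchy: root->{P1,P2}, P1->{P3}, plus genes."""
    rel = tmp_path / "rel.tsv"
    rel.write_text("R-TST-P1\tR-TST-P3\n")
    ann = tmp_path / "ann.tsv"
    ann.write_text(
        "gA\tR-TST-P3\n"
        "gB\tR-TST-P3\n"
        "gC\tR-TST-P2\n"
        "gD\tR-TST-P1\n"
    )
    return str(rel), str(ann)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
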