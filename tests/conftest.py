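import networkx as nx
import numpy as np
import pandas as pd
import pytest

from decidiff.formats import Annotation, ExpressionMatrix, Ontology
from decidiff.synthetic_data import (SimulationConfig, simulate_bulk,
                                     simulate_cells, simulate_ontology)


@pytest.fixture(scope="session")
def sim_default():
    """Full default-size zero-noise synthetic study, generated once.

    Read-only: tests must not mutate the returned objects.
    """
    cfg = SimulationConfig(seed=7)
    matrix, design, truth = simulate_bulk(cfg)
    cells, truth = simulate_cells(cfg, truth)
    ontology, annotation, groups, truth = simulate_ontology(cfg, truth)
    return {
        "config": cfg,
        "matrix": matrix,
        "design": design,
        "cells": cells,
        "ontology": ontology,
        "annotation": annotation,
        "groups": groups,
        "truth": truth,
    }


def small_config(**overrides) -> SimulationConfig:
    """A scaled-down simulation (2000 genes, ~100 DEGs per stimulus)."""
    defaults = dict(
        n_genes=2000,
        planted_up={"cAMP": 110, "cAMP+MPA": 120, "MPA": 90, "E2+MPA": 85},
        planted_down={"cAMP": 130, "cAMP+MPA": 140, "MPA": 95, "E2+MPA": 90},
        common_up=30, common_down=60,
        camp_pair_up=60, camp_pair_down=20,
        mpa_triple_up=15, mpa_pair_up=15, mpa_pair_down=15,
        n_cells_proliferative=25, n_cells_secretory=20,
        invivo_up=200, invivo_down=250,
        genes_per_term=5, background_per_term=3,
        seed=11,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture()
def diamond_ontology():
    """R <- A, B; C is_a both A and B; D is_a C; E is_a B."""
    g = nx.DiGraph()
    for term, name in [("R", "root process"), ("A", "branch a"),
                       ("B", "branch b"), ("C", "diamond bottom"),
                       ("D", "leaf under c"), ("E", "leaf under b")]:
        g.add_node(term, name=name, namespace="biological_process")
    g.add_edges_from([("A", "R"), ("B", "R"), ("C", "A"), ("C", "B"),
                      ("D", "C"), ("E", "B")])
    return Ontology(g)


@pytest.fixture()
def diamond_annotation(diamond_ontology):
    genes = [f"g{i}" for i in range(1, 11)]
    direct = {
        "g1": frozenset({"D"}), "g2": frozenset({"D"}),
        "g3": frozenset({"C"}), "g4": frozenset({"E"}),
        "g5": frozenset({"E"}), "g6": frozenset({"A"}),
        "g7": frozenset({"B"}), "g8": frozenset({"R"}),
        "g9": frozenset({"R"}), "g10": frozenset({"R"}),
    }
    return Annotation(direct, frozenset(genes))


@pytest.fixture()
def tiny_matrix():
    data = pd.DataFrame(
        [[1.0, 2.0], [0.0, 3.5], [10.0, 10.0]],
        index=["ACTB", "GAPDH", "FOXO1"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(data)


def random_distance_table(n: int, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    points = rng.normal(size=(n, 3))
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    labels = [f"s{i}" for i in range(n)]
    return pd.DataFrame(d, index=labels, columns=labels)
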