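"""Shared helpers: random catalogs and random weighted networks."""

from __future__ import annotations

import random

import networkx as nx
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def random_weighted_net(seed: int, n: int = 20, p: float = 0.3,
                        max_w: int = 50) -> nx.Graph:
    """Erdős–Rényi topology with uniform integer weights in 1..max_w."""
    rng = random.Random(seed)
    g = nx.gnp_random_graph(n, p, seed=seed)
    for u, v in g.edges:
        g[u][v]["weight"] = rng.randint(1, max_w)
    return g


def random_catalog(seed: int, n_traits: int = 20, n_genes: int = 30,
                   n_pathways: int = 15):
    """Small random (trait→gene, gene→pathway) row lists, duplicates allowed."""
    rng = random.Random(seed)
    tg = [(f"T{rng.randrange(n_traits)}", f"G{rng.randrange(n_genes)}")
          for _ in range(3 * n_traits)]
    gp = [(f"G{rng.randrange(n_genes)}", f"P{rng.randrange(n_pathways)}")
          for _ in range(3 * n_genes)]
    return tg, gp


@pytest.fixture
def tmp_tsv(tmp_path):
    """Write rows to a TSV file under tmp_path and return its path."""
    def write(rows, name="table.tsv"):
        path = tmp_path / name
        path.write_text("".join("\t".join(r) + "\n" for r in rows))
        return path
    return write
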