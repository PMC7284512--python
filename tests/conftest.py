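import numpy as np
import pytest

from liriopogon import synthetic_data as sd
from liriopogon.panel import load_default_panel
from liriopogon.seqio import SeqRecord


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def reference_set(panel):
    """(rbcl_by_haplotype, clade_models) built with a fixed seed."""
    return sd.make_reference_set(panel, seed=11)


@pytest.fixture(scope="session")
def its_reference(panel):
    return SeqRecord(id="ITS_reference", seq=panel.references["ITS"])


@pytest.fixture(scope="session")
def rbcl_reference(panel):
    return SeqRecord(id="rbcL_reference", seq=panel.references["rbcL"])


@pytest.fixture(scope="session")
def collection_run(tmp_path_factory):
    """One full-pipeline run on the packaged reconstruction (bootstrap 100).

    Session-scoped: the acceptance tally tests all read from this run.
    """
    from liriopogon import cli

    tmp = tmp_path_factory.mktemp("collection")
    cfg = sd.GeneratorConfig(seed=20)
    sim_dir = cli.run_simulate(cfg, tmp / "sim", collection=True)
    report = cli.run_verify(
        cli.RunConfig(
            rbcl_fasta=sim_dir / "rbcl.fasta",
            its_fasta=sim_dir / "its.fasta",
            its_references=sim_dir / "its_references.fasta",
            manifest=sim_dir / "manifest.tsv",
            out_dir=tmp / "verify",
            bootstrap=100,
            seed=20,
        )
    )
    return {"report": report, "sim_dir": sim_dir, "out_dir": tmp / "verify"}


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random unrooted binary tree -> (names, path-length distance matrix).

    Built by sequential leaf attachment; used as the additivity oracle for NJ.
    """
    names = [f"t{i}" for i in range(n_taxa)]
    # edges as dict node -> list of (node, length); internal nodes get negative ids
    edges: dict[int, list[tuple[int, float]]] = {0: [], 1: []}
    next_internal = -1

    def add_edge(a, b, w):
        edges.setdefault(a, []).append((b, w))
        edges.setdefault(b, []).append((a, w))

    def drop_edge(a, b):
        edges[a] = [(x, w) for x, w in edges[a] if x != b]
        edges[b] = [(x, w) for x, w in edges[b] if x != a]

    add_edge(0, 1, float(rng.uniform(0.05, 1.0)))
    for leaf in range(2, n_taxa):
        # pick a random existing edge and subdivide it
        all_edges = [(a, b, w) for a in edges for b, w in edges[a] if a < b]
        a, b, w = all_edges[rng.integers(len(all_edges))]
        mid = next_internal
        next_internal -= 1
        drop_edge(a, b)
        split = float(rng.uniform(0.2, 0.8))
        add_edge(a, mid, w * split)
        add_edge(mid, b, w * (1 - split))
        add_edge(mid, leaf, float(rng.uniform(0.05, 1.0)))

    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        dist = {i: 0.0}
        stack = [i]
        while stack:
            cur = stack.pop()
            for nxt, w in edges[cur]:
                if nxt not in dist:
                    dist[nxt] = dist[cur] + w
                    stack.append(nxt)
        for j in range(n_taxa):
            D[i, j] = dist[j]
    return names, D
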