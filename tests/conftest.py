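"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest
from skbio import TreeNode

from snptrace import simdata
from snptrace.io_formats import PopulationMap, VariantTable


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def make_vt(genotypes, samples=None, contig="chr1", pos=None, ref=None,
            alt=None, info=None) -> VariantTable:
    """Build a VariantTable from per-site genotype strings.

    ``genotypes`` is a list of sites, each a list of per-sample strings like
    "0/0", "0/1", "./." (or "1/2" for multiallelic sites).
    """
    n_sites = len(genotypes)
    n_samples = len(genotypes[0]) if n_sites else 0
    samples = samples or [f"s{i + 1}" for i in range(n_samples)]
    g = np.full((n_sites, n_samples, 2), -1, dtype=np.int8)
    for i, row in enumerate(genotypes):
        for j, cell in enumerate(row):
            a, b = cell.replace("|", "/").split("/")
            g[i, j, 0] = -1 if a == "." else int(a)
            g[i, j, 1] = -1 if b == "." else int(b)
    pos = np.array(pos if pos is not None else range(10, 10 * n_sites + 1, 10),
                   dtype=np.int64)
    ref = np.array(ref if ref is not None else ["A"] * n_sites, dtype=object)
    alt = alt if alt is not None else [("C",)] * n_sites
    return VariantTable(
        samples=samples,
        contig=np.array([contig] * n_sites, dtype=object),
        pos=pos, ref=ref, alt=list(alt), genotypes=g,
        info={k: np.asarray(v, dtype=float) for k, v in (info or {}).items()},
    )


def random_vt(rng: np.random.Generator, n_samples: int, n_sites: int,
              missing_rate: float = 0.1) -> VariantTable:
    g = rng.integers(0, 2, size=(n_sites, n_samples, 2)).astype(np.int8)
    miss = rng.random((n_sites, n_samples)) < missing_rate
    g[miss] = -1
    return VariantTable(
        samples=[f"s{i}" for i in range(n_samples)],
        contig=np.array(["chr1"] * n_sites, dtype=object),
        pos=np.arange(1, n_sites + 1, dtype=np.int64) * 5,
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=[("G",)] * n_sites,
        genotypes=g,
        info={},
    )


def random_popmap(rng: np.random.Generator, samples: list[str],
                  n_pops: int) -> PopulationMap:
    """Random assignment guaranteeing every population non-empty."""
    labels = [f"P{k}" for k in range(n_pops)]
    assign = {s: labels[i % n_pops] for i, s in enumerate(samples)}
    extra = rng.integers(0, n_pops, size=len(samples))
    for i, s in enumerate(samples[n_pops:], start=n_pops):
        assign[s] = labels[extra[i]]
    return PopulationMap(assign)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def haf_oracle(vt: VariantTable, pm: PopulationMap, pop: str, i: int,
               code: int) -> float:
    """Loop-based HAF: homozygous carriers over genotyped members."""
    cols = [k for k, s in enumerate(vt.samples) if pm.assignments[s] == pop]
    hom = n = 0
    for c in cols:
        a, b = int(vt.genotypes[i, c, 0]), int(vt.genotypes[i, c, 1])
        if a < 0 or b < 0:
            continue
        n += 1
        if a == b == code:
            hom += 1
    return hom / n if n else float("nan")


def diagnostic_oracle(vt: VariantTable, pm: PopulationMap, t: float):
    """Brute-force enumeration of all (site, focal pop, allele) triples."""
    hits = set()
    pops = pm.populations
    for i in range(vt.n_sites):
        if len(vt.alt[i]) != 1:
            continue
        hafs = {p: (haf_oracle(vt, pm, p, i, 0), haf_oracle(vt, pm, p, i, 1))
                for p in pops}
        if any(np.isnan(h[0]) for h in hafs.values()):
            continue
        for focal in pops:
            for a_code in (0, 1):
                b_code = 1 - a_code
                if hafs[focal][a_code] >= t and all(
                        hafs[q][b_code] >= t for q in pops if q != focal):
                    hits.add((str(vt.contig[i]), int(vt.pos[i]), focal,
                              a_code))
    return hits


def random_binary_tree(rng: np.random.Generator, leaves: list[str]) -> TreeNode:
    """Random unrooted binary topology via sequential random joins."""
    nodes = [TreeNode(name=l) for l in leaves]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(children=[nodes.pop(j), nodes.pop(i)])
        nodes.append(parent)
    return TreeNode(children=nodes)


def rf_oracle(t1: TreeNode, t2: TreeNode) -> int:
    """Bipartition enumeration by graph edge removal (networkx connectivity),
    independent of the package's tip-traversal implementation."""

    def splits(tree: TreeNode) -> set:
        g = nx.Graph()
        ids = {}
        for k, node in enumerate(tree.traverse(include_self=True)):
            ids[id(node)] = k
            g.add_node(k)
        for node in tree.traverse(include_self=False):
            g.add_edge(ids[id(node)], ids[id(node.parent)])
        leaves = {ids[id(t)]: t.name for t in tree.tips()}
        all_leaves = frozenset(leaves.values())
        out = set()
        for e in list(g.edges()):
            h = g.copy()
            h.remove_edge(*e)
            comp = nx.node_connected_component(h, e[0])
            side = frozenset(n for k, n in leaves.items() if k in comp)
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(frozenset((side, all_leaves - side)))
        return out

    return len(splits(t1) ^ splits(t2))


def brute_force_mst_weight(dist: dict[tuple[int, int], int], n: int) -> int:
    """Minimum spanning weight by enumerating all spanning trees (n <= 8)."""
    edges = list(dist.items())
    best = None
    for combo in itertools.combinations(edges, n - 1):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(e for e, _ in combo)
        if nx.is_connected(g):
            w = sum(w for _, w in combo)
            best = w if best is None else min(best, w)
    return best


# ---------------------------------------------------------------------------
# Session fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_scenario():
    return simdata.simulate_scenario(simdata.SimConfig(seed=11))


@pytest.fixture(scope="session")
def scenario_paths(default_scenario, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("scenario")
    return simdata.write_scenario(default_scenario, outdir)
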