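"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (exhaustive enumeration, hand
formulas) and share no code with the implementation paths they check.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from chemophylo.ancestral_reconstruction import Phylogeny, _Index, mk_transition
from chemophylo.spectra_io import Spectrum


# ---------------------------------------------------------------------------
# Spectrum generation
# ---------------------------------------------------------------------------

def random_spectrum(rng: np.random.Generator, feature_id: str = "s",
                    n_peaks: int | None = None, precursor: float | None = None,
                    mode: str = "positive") -> Spectrum:
    n = int(n_peaks if n_peaks is not None else rng.integers(2, 9))
    prec = float(precursor if precursor is not None else rng.uniform(300, 900))
    mz = np.sort(rng.uniform(50, prec - 20, n))
    inten = rng.lognormal(0.0, 1.0, n)
    return Spectrum(feature_id, prec, rt=float(rng.uniform(0, 10)), mode=mode,
                    peaks=np.column_stack([mz, inten]))


def related_spectrum_pair(rng: np.random.Generator,
                          n_shared: int = 4) -> tuple[Spectrum, Spectrum]:
    """A pair with engineered direct and shifted peak matches, so the
    assignment problem is non-trivial."""
    a = random_spectrum(rng, "a", n_peaks=int(rng.integers(4, 9)))
    delta = float(rng.uniform(-80, 80))
    b_peaks = []
    for mz, inten in a.peaks[:n_shared]:
        if rng.random() < 0.5:
            b_peaks.append((mz + rng.normal(0, 0.005), rng.lognormal(0, 1)))
        else:
            b_peaks.append((mz - delta + rng.normal(0, 0.005), rng.lognormal(0, 1)))
    for _ in range(int(rng.integers(0, 4))):
        b_peaks.append((rng.uniform(50, a.precursor_mz), rng.lognormal(0, 1)))
    b_peaks = [(abs(mz) + 1.0, i) for mz, i in b_peaks]
    b = Spectrum("b", a.precursor_mz + delta, mode="positive", peaks=b_peaks)
    return a, b


# ---------------------------------------------------------------------------
# Modified-cosine oracle: exhaustive one-to-one assignment over candidates
# ---------------------------------------------------------------------------

def oracle_modified_cosine(a: Spectrum, b: Spectrum, fragment_tol: float = 0.02
                           ) -> tuple[float, int]:
    """Best score over every one-to-one subset of candidate peak pairs,
    by recursive enumeration (no assignment solver involved)."""
    if len(a.peaks) == 0 or len(b.peaks) == 0:
        return 0.0, 0
    wa = np.sqrt(a.intensity)
    wa = wa / np.linalg.norm(wa)
    wb = np.sqrt(b.intensity)
    wb = wb / np.linalg.norm(wb)
    shift = a.precursor_mz - b.precursor_mz
    cand = [(i, j, wa[i] * wb[j])
            for i in range(len(wa)) for j in range(len(wb))
            if abs(a.mz[i] - b.mz[j]) <= fragment_tol
            or abs(a.mz[i] - (b.mz[j] + shift)) <= fragment_tol]

    best = {"score": 0.0, "n": 0}

    def recurse(k: int, used_a: frozenset, used_b: frozenset,
                score: float, n: int) -> None:
        if score > best["score"] + 1e-15 or (
                abs(score - best["score"]) <= 1e-15 and n > best["n"]):
            best["score"], best["n"] = score, n
        for t in range(k, len(cand)):
            i, j, w = cand[t]
            if i in used_a or j in used_b:
                continue
            recurse(t + 1, used_a | {i}, used_b | {j}, score + w, n + 1)

    recurse(0, frozenset(), frozenset(), 0.0, 0)
    return min(best["score"], 1.0), best["n"]


# ---------------------------------------------------------------------------
# Mk-model oracles: brute-force enumeration over internal labelings
# ---------------------------------------------------------------------------

def random_phylogeny(rng: np.random.Generator, n_tips: int,
                     min_len: float = 0.05, max_len: float = 2.0) -> Phylogeny:
    """Random rooted binary tree by successive random joins."""
    tree = dendropy.Tree()
    nodes = []
    for i in range(n_tips):
        nd = dendropy.Node()
        nd.taxon = tree.taxon_namespace.new_taxon(label=f"t{i}")
        nd.edge.length = float(rng.uniform(min_len, max_len))
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b, a = nodes.pop(j), nodes.pop(i)
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(min_len, max_len))
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    nodes[0].edge.length = None
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return Phylogeny(tree)


def oracle_mk_loglik(phylo: Phylogeny, states: dict[str, int], q: float) -> float:
    """Sum over all internal-node labelings of the joint probability."""
    idx = _Index(phylo.tree)
    internal = [i for i in range(len(idx.nodes)) if idx.children[i]]
    tip = {i: states[idx.nodes[i].taxon.label]
           for i in range(len(idx.nodes)) if not idx.children[i]}
    total = 0.0
    for combo in itertools.product([0, 1], repeat=len(internal)):
        lab = dict(tip)
        lab.update(dict(zip(internal, combo)))
        p = 0.5
        for i in range(len(idx.nodes) - 1):
            p *= mk_transition(q, idx.length[i])[lab[idx.parent[i]], lab[i]]
        total += p
    return float(np.log(total))


def oracle_mk_marginal(phylo: Phylogeny, states: dict[str, int], q: float,
                       node_name: str) -> float:
    """P(node = 1 | tips) by enumeration."""
    idx = _Index(phylo.tree)
    names = [nd.taxon.label if nd.is_leaf() else f"node{i}"
             for i, nd in enumerate(idx.nodes)]
    internal = [i for i in range(len(idx.nodes)) if idx.children[i]]
    tip = {i: states[names[i]] for i in range(len(idx.nodes))
           if not idx.children[i]}
    target = names.index(node_name)
    num = {0: 0.0, 1: 0.0}
    for combo in itertools.product([0, 1], repeat=len(internal)):
        lab = dict(tip)
        lab.update(dict(zip(internal, combo)))
        p = 0.5
        for i in range(len(idx.nodes) - 1):
            p *= mk_transition(q, idx.length[i])[lab[idx.parent[i]], lab[i]]
        num[lab[target]] += p
    return num[1] / (num[0] + num[1])


def phylogeny_from_newick(nwk: str, clades: dict | None = None) -> Phylogeny:
    tree = dendropy.Tree.get(data=nwk, schema="newick",
                             preserve_underscores=True, rooting="force-rooted")
    return Phylogeny(tree, {k: frozenset(v) for k, v in (clades or {}).items()})


# ---------------------------------------------------------------------------
# Benjamini-Hochberg oracle: literal step-up definition
# ---------------------------------------------------------------------------

def oracle_bh(pvals: np.ndarray) -> np.ndarray:
    """adj_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj_sorted[rank - 1] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_dataset():
    from chemophylo.synthetic_data import SimulationConfig, simulate_dataset
    cfg = SimulationConfig(seed=42, n_genera=10, species_per_genus=2,
                           n_compound_families=6, n_characters=12)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_table():
    """3 features x 4 samples with simple metadata."""
    from chemophylo.spectra_io import FeatureTable
    areas = pd.DataFrame(
        [[10.0, 0.0, 5.0, 1.0],
         [2.0, 4.0, 0.0, 3.0],
         [1.0, 1.0, 1.0, 1.0]],
        index=["f1", "f2", "f3"], columns=["s1", "s2", "s3", "s4"])
    meta = pd.DataFrame({"mz": [100.0, 200.0, 300.0], "rt": [1.0, 2.0, 3.0]},
                        index=areas.index)
    table = FeatureTable(areas, meta)
    sample_meta = pd.DataFrame(
        {"species": ["sp1", "sp1", "sp2", "sp2"],
         "genus": ["G1", "G1", "G2", "G2"],
         "clade": ["A", "A", "B", "B"],
         "solvent": ["hydroethanolic"] * 4,
         "mode": ["positive"] * 4},
        index=areas.columns)
    sample_meta.index.name = "sample_id"
    return table, sample_meta
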