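"""Mk-model maximum-likelihood ancestral state reconstruction.

Binary chemical-class characters evolve on a rooted phylogeny under the
one-rate symmetric Markov model (Mk1): transitions 0<->1 occur at a single
rate ``q``, giving along a branch of length ``t``

    P(same)  = 1/2 + 1/2 * exp(-2 q t)
    P(change) = 1/2 - 1/2 * exp(-2 q t)

with a uniform root prior.  Likelihoods come from Felsenstein's pruning
algorithm (vectorized over characters, with per-node scaling); the rate is
fitted per character by bounded 1-D optimization; per-node marginal state
probabilities come from the standard two-pass (up/down) computation.  MAP
node labelings yield gain/loss counts, from which each named clade is
classified as carrying the character state as a synapomorphy (single
origin on the clade stem), a homoplasy (stem change plus additional
origins elsewhere), or as uninformative.

A Fitch parsimony labeling is available as an alternative optimization for
comparison with parsimony-style visualizations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .character_coding import CharacterMatrix

logger = logging.getLogger("chemophylo")

MIN_BRANCH = 1e-8
Q_BOUNDS = (1e-8, 200.0)

CALLS = ("synapomorphy_present", "synapomorphy_absent",
         "homoplasy_present", "homoplasy_absent", "uninformative")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

@dataclass
class Phylogeny:
    """Rooted tree with genus-labeled tips and named (monophyletic) clades."""

    tree: dendropy.Tree
    clades: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label if leaf.taxon else None
                  for leaf in self.tree.leaf_node_iter()]
        if any(lab is None for lab in labels):
            raise ValueError("tree has unlabeled tips")
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels are not unique")
        self._tips = set(labels)
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                if node.edge.length is None or node.edge.length <= 0:
                    logger.warning("replacing zero/None branch length with %g",
                                   MIN_BRANCH)
                    node.edge.length = MIN_BRANCH
        self.clades = {name: frozenset(tips)
                       for name, tips in self.clades.items()}
        for name, tips in self.clades.items():
            self.check_monophyletic(tips, name)

    @property
    def tip_labels(self) -> set[str]:
        return set(self._tips)

    def check_monophyletic(self, tips: frozenset[str], name: str = "") -> dendropy.Node:
        missing = tips - self._tips
        if missing:
            raise ValueError(f"clade {name!r}: tips not in tree: {sorted(missing)}")
        mrca = self.tree.mrca(taxa=[t for t in self.tree.taxon_namespace
                                    if t.label in tips])
        under = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        if under != set(tips):
            raise ValueError(f"clade {name!r} is not monophyletic "
                             f"(MRCA also spans {sorted(under - set(tips))})")
        return mrca

    def pruned_to(self, genera: list[str]) -> "Phylogeny":
        """Restrict the tree to the sampled genera, dropping clades that
        lose monophyly or fall below two tips."""
        keep = set(genera) & self._tips
        if len(keep) < 2:
            raise ValueError("fewer than 2 sampled genera on the tree")
        taxa = [t for t in self.tree.taxon_namespace if t.label in keep]
        sub = self.tree.extract_tree_with_taxa(taxa=taxa)
        sub.is_rooted = True
        new_clades = {}
        for name, tips in self.clades.items():
            inter = frozenset(tips & keep)
            if len(inter) < 1:
                continue
            try:
                Phylogeny(sub.clone(depth=1), {name: inter})
                new_clades[name] = inter
            except ValueError:
                logger.warning("clade %s lost monophyly after pruning", name)
        return Phylogeny(sub, new_clades)

    def write(self, path: str | Path) -> None:
        self.tree.write(path=str(path), schema="newick", suppress_rooting=True,
                        real_value_format_specifier=".10f")


def read_newick(path: str | Path,
                clades: dict[str, set[str]] | None = None) -> Phylogeny:
    """Parse a rooted newick tree with branch lengths (zero-length branches
    are replaced by a small epsilon with a warning)."""
    from dendropy.dataio.newickreader import NewickReader
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True,
                                 rooting="force-rooted")
    except NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"tip labels are not unique in {path}: {exc}") from exc
    return Phylogeny(tree, {k: frozenset(v) for k, v in (clades or {}).items()})


# ---------------------------------------------------------------------------
# Mk model
# ---------------------------------------------------------------------------

def mk_transition(q: float, t: float) -> np.ndarray:
    """2x2 transition matrix of the symmetric binary Mk model."""
    if q <= 0 or t < 0:
        raise ValueError("require q > 0 and t >= 0")
    e = np.exp(-2.0 * q * t)
    same, diff = 0.5 + 0.5 * e, 0.5 - 0.5 * e
    return np.array([[same, diff], [diff, same]])


class _Index:
    """Postorder array representation of a tree for vectorized pruning."""

    def __init__(self, tree: dendropy.Tree):
        self.nodes = list(tree.postorder_node_iter())
        self.idx = {id(n): i for i, n in enumerate(self.nodes)}
        self.parent = np.full(len(self.nodes), -1, dtype=int)
        self.length = np.zeros(len(self.nodes))
        self.children: list[list[int]] = [[] for _ in self.nodes]
        self.tip_index: dict[str, int] = {}
        for i, n in enumerate(self.nodes):
            if n.parent_node is not None:
                self.parent[i] = self.idx[id(n.parent_node)]
                self.children[self.parent[i]].append(i)
                self.length[i] = n.edge.length
            if n.is_leaf():
                self.tip_index[n.taxon.label] = i
        self.root = len(self.nodes) - 1
        self.n_tips = len(self.tip_index)
        self._tip_order = sorted(self.tip_index, key=lambda lab: self.tip_index[lab])
        self._tip_pos = {self.tip_index[lab]: k
                         for k, lab in enumerate(self._tip_order)}

    def states_array(self, states: dict[str, int] | pd.Series | np.ndarray,
                     chars_by_row: bool = False) -> np.ndarray:
        """(n_chars, n_tips_in_index_order) int array from tip states."""
        if isinstance(states, pd.Series):
            states = states.to_dict()
        if isinstance(states, dict):
            missing = set(self.tip_index) - set(states)
            if missing:
                raise ValueError(f"missing tip states: {sorted(missing)}")
            return np.array([[int(states[lab]) for lab in self.tip_order]])
        arr = np.asarray(states, dtype=int)
        return arr if chars_by_row else arr[None, :]

    @property
    def tip_order(self) -> list[str]:
        return list(self._tip_order)


def _partials(index: _Index, tip_states: np.ndarray, q: float
              ) -> tuple[np.ndarray, np.ndarray]:
    """Up-pass partial likelihoods.

    Returns (partials[n_nodes, n_chars, 2], log-scaling[n_chars]); partials
    are rescaled per node so the log-likelihood is
    log(0.5 * sum_s partial_root(s)) + scale.
    """
    n_nodes, n_chars = len(index.nodes), tip_states.shape[0]
    part = np.zeros((n_nodes, n_chars, 2))
    scale = np.zeros(n_chars)
    for i, node in enumerate(index.nodes):
        if not index.children[i]:
            tip_col = tip_states[:, _tip_pos(index, i)]
            part[i, np.arange(n_chars), tip_col] = 1.0
        else:
            acc = np.ones((n_chars, 2))
            for c in index.children[i]:
                p = mk_transition(q, index.length[c])
                acc *= part[c] @ p.T
            mx = acc.max(axis=1)
            mx[mx == 0] = 1.0
            part[i] = acc / mx[:, None]
            scale += np.log(mx)
    return part, scale


def _tip_pos(index: _Index, node_i: int) -> int:
    # position of tip node_i within the tip ordering used by states arrays
    return index._tip_pos[node_i]


def character_log_likelihood(phylo: Phylogeny, states, q: float) -> float:
    """Felsenstein pruning log-likelihood of one character (uniform root
    prior); equals brute-force enumeration over internal labelings."""
    index = _Index(phylo.tree)
    arr = index.states_array(states)
    return float(_loglik_from_index(index, arr, q)[0])


def _loglik_from_index(index: _Index, tip_states: np.ndarray, q: float) -> np.ndarray:
    part, scale = _partials(index, tip_states, q)
    root_l = 0.5 * part[index.root].sum(axis=1)
    return np.log(root_l) + scale


@dataclass
class RateFit:
    q_hat: float
    log_likelihood: float
    at_boundary: bool = False


def estimate_rate(phylo: Phylogeny, matrix: CharacterMatrix | pd.Series,
                  per_character: bool = True,
                  q_bounds: tuple[float, float] = Q_BOUNDS) -> list[RateFit] | RateFit:
    """ML estimate of the Mk1 rate.

    ``per_character=True`` fits one rate per character (the behavior of
    single-character reconstructions); otherwise a single rate is fitted to
    the summed log-likelihood of all characters.  Constant characters carry
    no rate information and are returned pinned at the lower bound with
    ``at_boundary=True``.
    """
    if isinstance(matrix, CharacterMatrix):
        df = matrix.states.T          # characters x genera
    elif isinstance(matrix, pd.Series):
        df = matrix.to_frame().T      # single character
    else:
        df = pd.DataFrame(matrix)     # characters x genera already
    index = _Index(phylo.tree)
    cols = index.tip_order
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"characters missing tip states: {sorted(missing)}")
    arr = df[cols].to_numpy(dtype=int)

    def fit(rows: np.ndarray) -> RateFit:
        variable = np.ptp(rows, axis=1).max() > 0
        if not variable:
            ll = float(_loglik_from_index(index, rows, q_bounds[0]).sum())
            return RateFit(q_bounds[0], ll, at_boundary=True)

        def nll(q: float) -> float:
            return -float(_loglik_from_index(index, rows, q).sum())

        # the log-likelihood flattens at high rates, so bracket the optimum
        # on a log-spaced grid first, then refine with bounded minimization
        grid = np.geomspace(q_bounds[0], q_bounds[1], 40)
        vals = np.array([nll(q) for q in grid])
        k = int(np.argmin(vals))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        if not res.success:  # pragma: no cover
            raise RuntimeError(f"rate optimization failed in ({lo}, {hi}): {res}")
        q_hat, best = float(res.x), float(res.fun)
        if vals[k] < best:  # grid point beat the refinement (flat region)
            q_hat, best = float(grid[k]), float(vals[k])
        at_bound = (q_hat <= q_bounds[0] * 1.01) or (q_hat >= q_bounds[1] * 0.99)
        return RateFit(q_hat, -best, at_boundary=at_bound)

    if per_character:
        fits = [fit(arr[i:i + 1]) for i in range(arr.shape[0])]
        return fits[0] if isinstance(matrix, pd.Series) else fits
    return fit(arr)


def marginal_asr(phylo: Phylogeny, states, q: float
                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-node marginal state probabilities and MAP states for one
    character.

    Two-pass computation: the up pass collects subtree partials, the down
    pass propagates the likelihood of the rest of the tree; marginals are
    their normalized product.  MAP ties at exactly 0.5 resolve to state 0
    with a logged flag.  Internal nodes are named ``node<i>`` in postorder;
    tips keep their labels.
    """
    if q <= 0:
        raise ValueError("q must be > 0")
    index = _Index(phylo.tree)
    arr = index.states_array(states)
    part, _ = _partials(index, arr, q)
    n_nodes, n_chars = len(index.nodes), arr.shape[0]

    down = np.zeros((n_nodes, n_chars, 2))
    down[index.root] = 0.5
    # messages from child subtrees into the parent, reused for siblings
    child_msg = np.zeros((n_nodes, n_chars, 2))  # indexed by child
    for i in reversed(range(n_nodes)):           # preorder
        for c in index.children[i]:
            child_msg[c] = part[c] @ mk_transition(q, index.length[c]).T
        for c in index.children[i]:
            sib = np.ones((n_chars, 2))
            for b in index.children[i]:
                if b != c:
                    sib *= child_msg[b]
            down[c] = (down[i] * sib) @ mk_transition(q, index.length[c])

    post = part * down
    norm = post.sum(axis=2, keepdims=True)
    norm[norm == 0] = 1.0
    post = post / norm

    names = [n.taxon.label if n.is_leaf() else f"node{i}"
             for i, n in enumerate(index.nodes)]
    probs = pd.DataFrame(post[:, 0, :], index=names, columns=[0, 1])
    p1 = probs[1].to_numpy()
    ties = np.isclose(p1, 0.5, rtol=0.0, atol=1e-12)
    if ties.any():
        logger.info("marginal_asr: %d MAP ties resolved to state 0", ties.sum())
    map_states = pd.Series(np.where(p1 > 0.5, 1, 0), index=names, name="map")
    return probs, map_states


def joint_map_states(phylo: Phylogeny, states, q: float) -> pd.Series:
    """Jointly most probable ancestral labeling (max-product analogue of the
    pruning algorithm, i.e. Pupko-style joint reconstruction).

    Unlike taking the per-node argmax of the marginals -- which can yield a
    history that is not internally consistent -- this maximizes the
    probability of the complete labeling, so origin counts read off it
    correspond to an actual evolutionary scenario.  Ties resolve to state 0.
    """
    if q <= 0:
        raise ValueError("q must be > 0")
    index = _Index(phylo.tree)
    arr = index.states_array(states)[0]
    n_nodes = len(index.nodes)
    # best[i][s] = max log-prob of subtree below i given node i in state s
    best = np.full((n_nodes, 2), -np.inf)
    choice = np.zeros((n_nodes, 2), dtype=int)  # child state given parent state
    for i in range(n_nodes):
        if not index.children[i]:
            best[i, arr[_tip_pos(index, i)]] = 0.0
        else:
            best[i] = 0.0
            for c in index.children[i]:
                logp = np.log(mk_transition(q, index.length[c]))
                # for each state of i, best contribution of child c
                contrib = logp + best[c][None, :]
                # ties: prefer child state 0 (argmax returns first maximum)
                pick = np.argmax(contrib, axis=1)
                best[i] += contrib[np.arange(2), pick]
                choice[c] = pick
    names = [n.taxon.label if n.is_leaf() else f"node{i}"
             for i, n in enumerate(index.nodes)]
    out = np.zeros(n_nodes, dtype=int)
    root_scores = best[index.root] + np.log(0.5)
    out[index.root] = 0 if root_scores[0] >= root_scores[1] else 1
    for i in reversed(range(n_nodes - 1)):  # parents before children
        out[i] = choice[i, out[index.parent[i]]]
    return pd.Series(out, index=names, name="joint_map")


def count_origins(phylo: Phylogeny, node_states: pd.Series) -> tuple[int, int]:
    """Gains (0->1) and losses (1->0) along edges of a fully labeled tree."""
    index = _Index(phylo.tree)
    names = [n.taxon.label if n.is_leaf() else f"node{i}"
             for i, n in enumerate(index.nodes)]
    gains = losses = 0
    for i, n in enumerate(index.nodes):
        p = index.parent[i]
        if p < 0:
            continue
        s_child, s_parent = int(node_states[names[i]]), int(node_states[names[p]])
        if s_parent == 0 and s_child == 1:
            gains += 1
        elif s_parent == 1 and s_child == 0:
            losses += 1
    return gains, losses


def fitch_states(phylo: Phylogeny, states) -> pd.Series:
    """Fitch parsimony labeling (binary characters).

    Bottom-up state sets; top-down resolution keeps the parent's state when
    it is in the child's set (root ambiguity resolves to state 0, the same
    deterministic tie rule as the MAP labeling).
    """
    index = _Index(phylo.tree)
    arr = index.states_array(states)[0]
    sets: list[set[int]] = [set() for _ in index.nodes]
    for i, node in enumerate(index.nodes):
        if not index.children[i]:
            sets[i] = {int(arr[_tip_pos(index, i)])}
        else:
            inter = set.intersection(*(sets[c] for c in index.children[i]))
            sets[i] = inter or set.union(*(sets[c] for c in index.children[i]))
    names = [n.taxon.label if n.is_leaf() else f"node{i}"
             for i, n in enumerate(index.nodes)]
    out = {}
    out[names[index.root]] = min(sets[index.root])
    for i in reversed(range(len(index.nodes) - 1)):
        p = index.parent[i]
        parent_state = out[names[p]]
        out[names[i]] = parent_state if parent_state in sets[i] else min(sets[i])
    return pd.Series(out, name="fitch")


def classify_character(phylo: Phylogeny, clade: str | frozenset[str],
                       tip_states, map_states: pd.Series,
                       gains: int, losses: int) -> str:
    """Synapomorphy / homoplasy call for one character on one clade.

    Let ``s`` be the state shared by every clade tip (a polymorphic clade
    is uninformative).  If the clade's MRCA reconstructs to ``s``, its
    parent to the opposite state (a stem change), and ``s`` arises exactly
    once on the whole tree, the character is a synapomorphy of the clade;
    with a stem change but multiple origins it is a homoplasy; anything
    else is uninformative.
    """
    tips = phylo.clades[clade] if isinstance(clade, str) else frozenset(clade)
    name = clade if isinstance(clade, str) else ""
    mrca = phylo.check_monophyletic(tips, name)
    if isinstance(tip_states, dict):
        tip_states = pd.Series(tip_states)
    vals = {int(tip_states[t]) for t in tips}
    if len(vals) != 1:
        return "uninformative"
    s = vals.pop()
    if mrca.parent_node is None:
        return "uninformative"  # clade spans the whole tree: no stem to change on

    index = _Index(phylo.tree)
    names = {id(n): (n.taxon.label if n.is_leaf() else f"node{i}")
             for i, n in enumerate(index.nodes)}
    mrca_state = int(map_states[names[id(mrca)]])
    parent_state = int(map_states[names[id(mrca.parent_node)]])
    if mrca_state != s or parent_state != 1 - s:
        return "uninformative"
    origins = gains if s == 1 else losses
    kind = "present" if s == 1 else "absent"
    if origins == 1:
        return f"synapomorphy_{kind}"
    if origins > 1:
        return f"homoplasy_{kind}"
    return "uninformative"


# ---------------------------------------------------------------------------
# Per-matrix driver
# ---------------------------------------------------------------------------

@dataclass
class ASRResult:
    character: str
    q_hat: float
    log_likelihood: float
    at_boundary: bool
    marginals: pd.DataFrame
    map_states: pd.Series
    gains: int
    losses: int
    clade_calls: dict[str, str]
    ubiquitous: bool
    provenance: str | None = None


def run_asr(phylo: Phylogeny, matrix: CharacterMatrix,
            per_character: bool = True,
            method: str = "fitch") -> tuple[list[ASRResult], pd.DataFrame]:
    """Reconstruct every character and classify every named clade.

    The tree is pruned to the matrix's genera first.  Rates are fitted and
    marginal state probabilities computed by maximum likelihood for every
    character; the node labeling used to count gains/losses and classify
    clades comes from ``method``: ``'fitch'`` (default) uses the parsimony
    labeling in the fast-optimization style that favors homoplasies, while
    ``'ml'`` uses the jointly most probable labeling under the fitted rate.
    Characters present in (or absent from) every genus receive no clade
    calls and are listed as ubiquitous/absent in the report.

    Returns the per-character results and a per-clade report table with
    the classes present / absent and their calls.
    """
    if method not in ("ml", "fitch"):
        raise ValueError(f"unknown method {method!r}")
    missing = set(matrix.genera) - phylo.tip_labels
    if missing:
        raise ValueError(f"matrix genera not on tree: {sorted(missing)}")
    sub = phylo.pruned_to(matrix.genera)
    fits = estimate_rate(sub, matrix, per_character=per_character)
    if not per_character:
        fits = [fits] * len(matrix.characters)

    results: list[ASRResult] = []
    for char, fit in zip(matrix.characters, fits):
        tip_states = matrix.states[char]
        q_eff = max(fit.q_hat, Q_BOUNDS[0])
        marg, _ = marginal_asr(sub, tip_states, q_eff)
        if method == "fitch":
            map_states = fitch_states(sub, tip_states)
        else:
            # joint (not per-node marginal) MAP: a consistent history whose
            # edge changes are countable as gains/losses
            map_states = joint_map_states(sub, tip_states, q_eff)
        gains, losses = count_origins(sub, map_states)
        calls = {}
        ubiq = bool((tip_states == 1).all())
        if not ubiq and not bool((tip_states == 0).all()):
            for cname in sub.clades:
                calls[cname] = classify_character(sub, cname, tip_states,
                                                 map_states, gains, losses)
        prov = None
        if matrix.provenance is not None and char in matrix.provenance.index:
            prov = matrix.provenance[char]
        results.append(ASRResult(char, fit.q_hat, fit.log_likelihood,
                                 fit.at_boundary, marg, map_states,
                                 gains, losses, calls, ubiq, prov))

    rows = []
    for cname in sub.clades:
        present, absent = [], []
        for r in results:
            call = r.clade_calls.get(cname, "uninformative")
            tag = f" ({r.provenance})" if r.provenance else ""
            star = "*" if call.startswith("synapomorphy") else ""
            if call.endswith("present"):
                present.append(r.character + tag + star)
            elif call.endswith("absent"):
                absent.append(r.character + tag + star)
        rows.append({"clade": cname,
                     "classes_present": "; ".join(sorted(present)) or "-",
                     "classes_absent": "; ".join(sorted(absent)) or "-"})
    report = pd.DataFrame(rows, columns=["clade", "classes_present",
                                         "classes_absent"])
    report.attrs["ubiquitous"] = sorted(r.character for r in results if r.ubiquitous)
    return results, report
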