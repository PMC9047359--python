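"""Feature-based molecular networking.

Nodes are LC-MS features (MS/MS spectra); an undirected edge is admitted
when the modified cosine exceeds ``min_cosine`` (strictly) with at least
``min_matched_peaks`` aligned fragments.  Connected components are the
molecular families.  Node attributes summarize per-clade relative
abundances (the pie charts of the original visualizations) and total peak
area (node size).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .spectra_io import FeatureTable, Spectrum
from .spectral_similarity import SimilarityParams, clean_spectrum, modified_cosine

logger = logging.getLogger("chemophylo")


@dataclass
class LibraryHit:
    feature_id: str
    library_compound_id: str
    score: float
    n_matched: int
    annotation: dict | None = None


def pairwise_scores(spectra: list[Spectrum],
                    params: SimilarityParams | None = None,
                    clean: bool = True) -> list[tuple[str, str, float, int]]:
    """Score all unordered spectrum pairs; emit only pairs passing both the
    cosine and matched-peak thresholds.

    ``clean`` applies the precursor-removal and window filters first (set
    False if the spectra are already filtered).
    """
    p = params or SimilarityParams()
    specs = [clean_spectrum(s, p) for s in spectra] if clean else list(spectra)
    specs.sort(key=lambda s: s.feature_id)  # input-order invariance
    edges = []
    for a, b in itertools.combinations(specs, 2):
        score, n = modified_cosine(a, b, p)
        if score > p.min_cosine and n >= p.min_matched_peaks:
            edges.append((a.feature_id, b.feature_id, score, n))
    return edges


def build_network(scores: list[tuple[str, str, float, int]],
                  table: FeatureTable,
                  meta: pd.DataFrame,
                  params: SimilarityParams | None = None,
                  spectra: list[Spectrum] | None = None,
                  library_hits: list[LibraryHit] | None = None,
                  blank_fraction: float | None = None,
                  top_k_neighbors: int | None = None,
                  max_component_size: int | None = None) -> nx.Graph:
    """Assemble the molecular network graph.

    Every feature in ``table`` becomes a node (isolated features stay as
    singletons).  Node attributes: ``precursor_mz``, ``rt``, ``node_size``
    (summed area over samples), ``clade_abundance`` (per-clade share of the
    summed area, JSON-encoded; all-zero features are flagged ``zero_area``)
    and ``annotation`` from the library search.

    ``blank_fraction`` optionally drops features whose mean area across
    blank samples (metadata clade == "blank") is at least that fraction of
    their mean area across real samples.

    ``top_k_neighbors`` and ``max_component_size`` enable the GNPS-style
    optional pruning steps (both off by default): an edge survives topK
    pruning only if it ranks among the K best-scoring edges of *both*
    endpoints, and oversized components are split by dropping their
    weakest edges.
    """
    g = nx.Graph()
    by_id = {s.feature_id: s for s in (spectra or [])}
    hits = {h.feature_id: h for h in (library_hits or [])}

    samples = [s for s in table.sample_ids if s in meta.index]
    clades = meta.loc[samples, "clade"]
    blank_samples = [s for s in samples if clades[s] == "blank"]
    real_samples = [s for s in samples if clades[s] != "blank"]

    drop: set[str] = set()
    if blank_fraction is not None and blank_samples:
        blank_mean = table.areas[blank_samples].mean(axis=1)
        real_mean = table.areas[real_samples].mean(axis=1)
        drop = set(table.areas.index[(blank_mean >= blank_fraction * real_mean)
                                     & (real_mean > 0)])
        if drop:
            logger.info("blank filter removed %d features", len(drop))

    for fid in table.feature_ids:
        if fid in drop:
            continue
        row = table.areas.loc[fid, real_samples]
        total = float(row.sum())
        pie: dict[str, float] = {}
        if total > 0:
            shares = row.groupby(clades[real_samples]).sum() / total
            pie = {str(c): float(v) for c, v in shares.items() if v > 0}
        spec = by_id.get(fid)
        hit = hits.get(fid)
        g.add_node(
            fid,
            precursor_mz=float(spec.precursor_mz) if spec is not None
            else float(table.feature_meta.loc[fid, "mz"]),
            rt=float(table.feature_meta.loc[fid, "rt"]),
            node_size=total,
            zero_area=total == 0,
            clade_abundance=json.dumps(pie, sort_keys=True),
            annotation=json.dumps(hit.annotation, sort_keys=True) if hit else "",
        )

    for u, v, score, n in scores:
        if u == v:
            continue
        if u not in g or v not in g:
            if u in drop or v in drop:
                continue
            raise ValueError(f"edge ({u}, {v}) references a feature missing "
                             f"from the table")
        g.add_edge(u, v, cosine=float(score), n_matched=int(n))

    if top_k_neighbors is not None:
        top = {}
        for node in g.nodes:
            ranked = sorted(g.edges(node, data="cosine"),
                            key=lambda e: (-e[2], e[0], e[1]))
            top[node] = {frozenset(e[:2]) for e in ranked[:top_k_neighbors]}
        # an edge survives only if it ranks in the top K of both endpoints
        for u, v in [e for e in g.edges
                     if frozenset(e) not in top[e[0]] & top[e[1]]]:
            g.remove_edge(u, v)
    if max_component_size is not None:
        todo = [set(c) for c in nx.connected_components(g)]
        while todo:
            comp = todo.pop()
            if len(comp) <= max_component_size:
                continue
            u, v, _ = min(g.subgraph(comp).edges(data="cosine"),
                          key=lambda e: (e[2], e[0], e[1]))
            g.remove_edge(u, v)
            todo.extend(set(c)
                        for c in nx.connected_components(g.subgraph(comp)))
    return g


def components(net: nx.Graph) -> list[set[str]]:
    """Molecular families: connected components, largest first."""
    return sorted(nx.connected_components(net), key=lambda c: (-len(c), min(c)))


def library_search(spectra: list[Spectrum], library: list[Spectrum],
                   params: SimilarityParams | None = None,
                   clean: bool = True) -> list[LibraryHit]:
    """Annotate queries against a reference library.

    For each query, candidates are library spectra whose precursor m/z
    agrees within ``precursor_tol``; the best hit passing the cosine and
    matched-peak thresholds is kept (ties: higher matched-peak count, then
    library order).
    """
    p = params or SimilarityParams()
    queries = [clean_spectrum(s, p) for s in spectra] if clean else spectra
    lib = [clean_spectrum(s, p) for s in library] if clean else library
    hits: list[LibraryHit] = []
    for orig, q in zip(spectra, queries):
        best: tuple[float, int, int] | None = None  # (score, n, -index)
        best_entry = None
        for idx, entry in enumerate(lib):
            if abs(q.precursor_mz - entry.precursor_mz) > p.precursor_tol:
                continue
            score, n = modified_cosine(q, entry, p)
            if score > p.min_cosine and n >= p.min_matched_peaks:
                key = (score, n, -idx)
                if best is None or key > best:
                    best, best_entry = key, (entry, library[idx])
        if best is not None:
            entry, orig_entry = best_entry
            hits.append(LibraryHit(orig.feature_id, entry.feature_id,
                                   best[0], best[1], orig_entry.annotation))
    return hits


def extraction_overlap(tables: dict[str, FeatureTable]) -> pd.DataFrame:
    """Venn counts of features detected (area > 0 in >= 1 sample) under each
    extraction solvent, for tables sharing a feature alignment.

    Returns one row per region (each solvent alone and each pairwise
    intersection) with counts and percentage of the union.
    """
    detected = {name: set(t.areas.index[(t.areas > 0).any(axis=1)])
                for name, t in tables.items()}
    union: set[str] = set().union(*detected.values()) if detected else set()
    total = len(union)
    rows = []
    names = sorted(detected)
    for a, b in itertools.combinations(names, 2):
        shared = detected[a] & detected[b]
        only_a = detected[a] - detected[b]
        only_b = detected[b] - detected[a]
        denom = len(detected[a] | detected[b])
        for label, s in ((f"{a}&{b}", shared), (f"{a}_only", only_a),
                         (f"{b}_only", only_b)):
            rows.append({"region": label, "count": len(s),
                         "percent": 100.0 * len(s) / denom if denom else 0.0})
    if len(names) == 1:
        rows.append({"region": names[0], "count": total, "percent": 100.0})
    out = pd.DataFrame(rows)
    out.attrs["n_union"] = total
    return out


def write_network(net: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Export the network as GraphML or a TSV edge list (both round-trip
    through :func:`read_network`)."""
    if fmt == "graphml":
        nx.write_graphml(net, str(path))
    elif fmt == "edge_tsv":
        rows = [{"source": u, "target": v,
                 "cosine": d["cosine"], "n_matched": d["n_matched"]}
                for u, v, d in net.edges(data=True)]
        df = pd.DataFrame(rows, columns=["source", "target", "cosine", "n_matched"])
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_network(path: str | Path, fmt: str = "graphml") -> nx.Graph:
    if fmt == "graphml":
        return nx.read_graphml(str(path))
    if fmt == "edge_tsv":
        g = nx.Graph()
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        for _, row in df.iterrows():
            g.add_edge(row["source"], row["target"],
                       cosine=float(row["cosine"]), n_matched=int(row["n_matched"]))
        return g
    raise ValueError(f"unknown format {fmt!r}")
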