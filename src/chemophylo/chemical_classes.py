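"""Chemical hierarchy and clade-level class enrichment.

Features carry an in-silico chemical taxonomy (superclass / class /
subclass) and a binary molecular fingerprint.  The hierarchy step clusters
fingerprints by Euclidean distance into a rooted tree and prunes leaves
without a superclass assignment.  Enrichment sums relative abundances per
class, applies the arcsine-square-root transform, tests clade effects by
one-way ANOVA with Benjamini-Hochberg adjustment across classes, follows
up with Tukey HSD pairwise contrasts, and reports log2 fold changes of the
untransformed clade means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist
from scipy.stats import f_oneway
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .spectra_io import FeatureTable

logger = logging.getLogger("chemophylo")

LEVELS = ("superclass", "class", "subclass")


@dataclass
class ClassificationTable:
    """Per-feature chemical taxonomy plus binary fingerprint vectors.

    ``labels``: DataFrame indexed by feature id with superclass/class/
    subclass columns (None/NaN where unclassified; a non-null subclass
    implies non-null class implies non-null superclass).  ``fingerprints``:
    DataFrame of uniform-length binary vectors, same index.
    """

    labels: pd.DataFrame
    fingerprints: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in LEVELS if c not in self.labels.columns]
        if missing:
            raise ValueError(f"classification table missing columns: {missing}")
        self.labels.index = self.labels.index.map(str)
        lab = self.labels
        bad_sub = lab["subclass"].notna() & lab["class"].isna()
        bad_cls = lab["class"].notna() & lab["superclass"].isna()
        if bad_sub.any() or bad_cls.any():
            raise ValueError("classification levels must be hierarchical "
                             "(subclass => class => superclass)")
        if self.fingerprints is not None:
            self.fingerprints.index = self.fingerprints.index.map(str)
            fp = self.fingerprints.to_numpy()
            if not np.isin(fp, (0, 1)).all():
                raise ValueError("fingerprints must be binary 0/1 vectors")

    def class_of(self, level: str = "class") -> pd.Series:
        return self.labels[level]


def build_chemistry_tree(cls: ClassificationTable,
                         method: str = "average") -> dendropy.Tree:
    """Hierarchically cluster fingerprint vectors into a rooted tree.

    Euclidean pairwise distances between the binary fingerprints,
    agglomerated with the chosen linkage (average by default; ward and
    complete are accepted), leaf labels = feature ids.  Branch lengths are
    merge-height differences, so root-to-leaf paths equal half the merge
    heights.
    """
    if cls.fingerprints is None or len(cls.fingerprints) < 2:
        raise ValueError("need >= 2 features with fingerprints")
    # canonical ordering makes the tree invariant to input order
    fps = cls.fingerprints.sort_index()
    ids = list(fps.index)
    x = fps.to_numpy(dtype=float)
    d = pdist(x, metric="euclidean")
    if np.all(d == 0):
        logger.warning("all fingerprints identical: star-like tree")
    z = linkage(d, method=method)
    root, nodes = to_tree(z, rd=True)

    tree = dendropy.Tree()
    taxa = tree.taxon_namespace

    def convert(scnode, parent_height: float) -> dendropy.Node:
        node = dendropy.Node()
        node.edge.length = max(parent_height - scnode.dist, 0.0)
        if scnode.is_leaf():
            node.taxon = taxa.new_taxon(label=ids[scnode.id])
        else:
            node.add_child(convert(scnode.left, scnode.dist))
            node.add_child(convert(scnode.right, scnode.dist))
        return node

    seed = convert(root, root.dist)
    seed.edge.length = None
    tree.seed_node = seed
    tree.is_rooted = True
    return tree


def prune_to_superclass(tree: dendropy.Tree,
                        cls: ClassificationTable) -> dendropy.Tree:
    """Remove leaves without a superclass-level classification.

    Unary internal nodes left behind are contracted with branch lengths
    summed, so path lengths between surviving leaves are preserved.
    """
    classified = set(cls.labels.index[cls.labels["superclass"].notna()])
    keep = [t for t in tree.taxon_namespace
            if t.label in classified and tree.find_node_with_taxon_label(t.label)]
    if not keep:
        raise ValueError("pruning removed every leaf")
    pruned = tree.extract_tree_with_taxa(taxa=keep,
                                         suppress_unifurcations=True)
    pruned.is_rooted = True
    return pruned


def class_abundance_table(table: FeatureTable, cls: ClassificationTable,
                          level: str = "class") -> pd.DataFrame:
    """Per-sample relative abundance summed by chemical class.

    Each sample's class value is the summed area of that class's features
    divided by the sample's total area over all features, so values lie in
    [0, 1] and sum to at most 1 (the unclassified remainder is dropped).
    """
    totals = table.areas.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"zero-total sample(s): {zero}")
    labels = cls.labels[level].reindex(table.areas.index)
    grouped = table.areas.groupby(labels, dropna=True).sum()
    rel = (grouped / totals).T  # samples x classes
    rel.columns.name = level
    return rel


@dataclass
class EnrichmentResult:
    anova: pd.DataFrame          # class, F, p, p_adj, note
    tukey: pd.DataFrame          # class, clade1, clade2, tukey_p
    log2fc: pd.DataFrame         # class, clade1, clade2, log2fc
    heatmap: pd.DataFrame        # significant classes x clades (mean rel abund)
    alpha: float = 0.05
    clade_means: pd.DataFrame | None = None


def enrichment_anova(abund: pd.DataFrame, meta: pd.DataFrame,
                     clades_tested: list[str] | None = None,
                     alpha: float = 0.05) -> EnrichmentResult:
    """Test each chemical class for differential enrichment across clades.

    Values are arcsine-square-root transformed (y = arcsin(sqrt(p)));
    a one-way ANOVA per class across clades, BH adjustment across classes,
    Tukey HSD pairwise contrasts on the transformed values, and log2 fold
    changes of the untransformed clade means.  Classes constant across all
    samples cannot be tested and are skipped with a note.
    """
    if ((abund.to_numpy() < -1e-12) | (abund.to_numpy() > 1 + 1e-12)).any():
        raise ValueError("abundances must be relative (in [0, 1])")
    clades = meta.loc[abund.index, "clade"]
    if clades_tested is not None:
        keep = clades.isin(clades_tested)
        abund, clades = abund.loc[keep], clades[keep]
    groups = sorted(clades.unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 clades to test")
    sizes = clades.value_counts()
    small = sizes.index[sizes < 2].tolist()
    if small:
        raise ValueError(f"clades with < 2 samples: {small}")

    y = np.arcsin(np.sqrt(np.clip(abund.to_numpy(dtype=float), 0.0, 1.0)))
    y = pd.DataFrame(y, index=abund.index, columns=abund.columns)

    rows, tukey_rows, fc_rows = [], [], []
    means = abund.groupby(clades).mean().reindex(groups)
    for cname in abund.columns:
        vec = y[cname]
        if np.ptp(vec.to_numpy()) == 0:
            rows.append({"class": cname, "F": np.nan, "p": np.nan,
                         "note": "constant; skipped"})
            continue
        per_clade = [vec[clades == g].to_numpy() for g in groups]
        f, p = f_oneway(*per_clade)
        rows.append({"class": cname, "F": float(f), "p": float(p), "note": ""})
        tuk = pairwise_tukeyhsd(vec.to_numpy(), clades.to_numpy())
        res = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
        for _, r in res.iterrows():
            tukey_rows.append({"class": cname, "clade1": str(r["group1"]),
                               "clade2": str(r["group2"]),
                               "tukey_p": float(r["p-adj"])})
        for i, g1 in enumerate(groups):
            for g2 in groups[i + 1:]:
                with np.errstate(divide="ignore", invalid="ignore"):
                    fc = float(np.log2(means.loc[g1, cname] / means.loc[g2, cname]))
                fc_rows.append({"class": cname, "clade1": g1, "clade2": g2,
                                "log2fc": fc})

    anova = pd.DataFrame(rows, columns=["class", "F", "p", "note"])
    tested = anova["p"].notna()
    anova["p_adj"] = np.nan
    if tested.any():
        anova.loc[tested, "p_adj"] = multipletests(
            anova.loc[tested, "p"], method="fdr_bh")[1]
    anova = anova[["class", "F", "p", "p_adj", "note"]]

    sig = anova.loc[anova["p_adj"] < alpha, "class"].tolist()
    heatmap = means[sig].T if sig else pd.DataFrame(columns=groups)
    return EnrichmentResult(
        anova=anova,
        tukey=pd.DataFrame(tukey_rows, columns=["class", "clade1", "clade2",
                                                "tukey_p"]),
        log2fc=pd.DataFrame(fc_rows, columns=["class", "clade1", "clade2",
                                              "log2fc"]),
        heatmap=heatmap,
        alpha=alpha,
        clade_means=means,
    )


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True, real_value_format_specifier=".10f")


def read_classification_table(path) -> ClassificationTable:
    """Read the TSV written by :func:`write_classification_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str}).set_index("feature_id")
    fp_cols = [c for c in df.columns if c.startswith("fp_")]
    labels = df[[c for c in LEVELS]]
    fps = df[fp_cols].astype(int) if fp_cols else None
    if fps is not None:
        fps.columns = range(len(fp_cols))
    return ClassificationTable(labels, fps)


def write_classification_table(cls: ClassificationTable, path) -> None:
    out = cls.labels.copy()
    if cls.fingerprints is not None:
        fp = cls.fingerprints.copy()
        fp.columns = [f"fp_{i}" for i in range(fp.shape[1])]
        out = pd.concat([out, fp.reindex(out.index)], axis=1)
    out.to_csv(path, sep="\t", index_label="feature_id")
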