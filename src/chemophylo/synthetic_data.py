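"""Ground-truthed synthetic inputs for the whole pipeline.

The generator emulates the statistical structure the analysis assumes,
without modeling instrument physics:

* compound families: a base spectrum plus derivatives whose precursor and
  higher-mass fragments shift by glycosidic neutral losses (hexoside
  162.053, deoxyhexoside 146.058, pentoside 132.042, water 18.011 Da), so
  molecular networking recovers the families by construction;
* clade-structured feature tables: lognormal peak areas with Bernoulli
  dropout, one chemical class planted per clade (nonzero areas only in
  that clade's samples) and the remaining classes spread across clades;
* solvent complementarity: per-feature detection patterns across the two
  extraction solvents drawn with the shared / hydroethanolic-only /
  ethyl-acetate-only proportions reported for each ionization mode
  (74/21/5 % positive, 59/36/5 % negative);
* binary characters evolved forward under the one-rate Mk model on a
  pure-birth tree (root age normalized to 1), with true node states and
  origin counts recorded.

Everything is a pure function of (config, seed): one integer seed drives a
hierarchical RNG stream per artifact, so stages reproduce byte-identically
even when re-run alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .ancestral_reconstruction import Phylogeny, _Index, count_origins
from .character_coding import CharacterMatrix, write_characters_tsv
from .chemical_classes import ClassificationTable, write_classification_table
from .spectra_io import (FeatureTable, NEGATIVE, POSITIVE, Spectrum,
                         write_feature_table, write_metadata, write_mgf)

DEFAULT_CLASSES = (
    "Flavonoids", "Triterpenoids", "Quinic acids and derivatives",
    "Ecdysteroids", "Iridoids", "Isoquinoline alkaloids",
    "Furofuranoid lignans", "Polyamines",
)

SUPERCLASS_OF = {
    "Flavonoids": "Phenylpropanoids and polyketides",
    "Triterpenoids": "Lipids and lipid-like molecules",
    "Quinic acids and derivatives": "Organic oxygen compounds",
    "Ecdysteroids": "Lipids and lipid-like molecules",
    "Iridoids": "Lipids and lipid-like molecules",
    "Isoquinoline alkaloids": "Organoheterocyclic compounds",
    "Furofuranoid lignans": "Phenylpropanoids and polyketides",
    "Polyamines": "Organic nitrogen compounds",
}

#: per-mode feature detection pattern across extraction solvents:
#: (shared, hydroethanolic-only, ethyl-acetate-only) proportions
SOLVENT_PATTERN = {POSITIVE: (0.74, 0.21, 0.05),
                   NEGATIVE: (0.59, 0.36, 0.05)}

HYDRO, ETOAC = "hydroethanolic", "ethyl_acetate"


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genera: int = 16
    species_per_genus: int = 2
    n_clades: int = 4
    clades: dict[str, set[str]] | None = None  # explicit tip partitions
    n_compound_families: int = 8
    members_per_family: int = 4
    peaks_per_spectrum: int = 8
    neutral_losses: tuple[float, ...] = (162.053, 146.058, 132.042, 18.011)
    class_labels: tuple[str, ...] = DEFAULT_CLASSES
    planted_class_by_clade: dict[str, str] | None = None
    abundance_lognormal: tuple[float, float] = (10.0, 1.0)
    dropout_prob: float = 0.1
    mk_rate: float = 0.5
    #: sd of the per-feature lognormal factor applied to ethyl-acetate
    #: sample areas (extraction-dependent relative abundance)
    solvent_effect_sigma: float = 0.8
    tree_model: str = "pure_birth"
    n_characters: int = 50
    modes: tuple[str, ...] = (POSITIVE, NEGATIVE)
    fingerprint_length: int = 64
    fingerprint_noise: float = 0.03
    unclassified_prob: float = 0.1

    def __post_init__(self) -> None:
        for p in (self.dropout_prob, self.fingerprint_noise, self.unclassified_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.mk_rate <= 0:
            raise ValueError("mk_rate must be > 0")
        if self.tree_model != "pure_birth":
            raise ValueError(f"unknown tree model {self.tree_model!r}")
        if self.peaks_per_spectrum < 4:
            raise ValueError("peaks_per_spectrum must be >= 4 to satisfy the "
                             "matched-peak floor")
        if self.clades is not None:
            tips = [t for s in self.clades.values() for t in s]
            if len(tips) != len(set(tips)):
                raise ValueError("explicit clades must be disjoint")

    def genus_names(self) -> list[str]:
        return [f"G{i:02d}" for i in range(1, self.n_genera + 1)]


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """One child RNG stream per artifact (stage-level reproducibility)."""
    names = ("tree", "families", "table", "characters", "fingerprints", "library")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

def _yule_tree(rng: np.random.Generator, tips: list[str]) -> dendropy.Tree:
    """Pure-birth tree: exponential waiting times between speciations,
    random lineage splits, made ultrametric with root age 1."""
    n = len(tips)
    tree = dendropy.Tree()
    tree.is_rooted = True
    # active lineages and their birth times
    active = [(tree.seed_node, 0.0)]
    now = 0.0
    while len(active) < n:
        now += rng.exponential(1.0 / len(active))
        i = rng.integers(len(active))
        node, _ = active.pop(i)
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        # record birth time on the child for later length assignment
        for child in (left, right):
            child.birth = now
        if node is not tree.seed_node:
            node.edge.length = now - node.birth
        else:
            node.birth = 0.0
            node.edge.length = None
        active.append((left, now))
        active.append((right, now))
    now += rng.exponential(1.0 / len(active))
    order = rng.permutation(len(tips))
    for (node, _), k in zip(active, order):
        node.edge.length = now - node.birth
        node.taxon = tree.taxon_namespace.new_taxon(label=tips[k])
    # normalize root age (root-to-tip depth; the tree is ultrametric) to 1
    leaf = next(tree.leaf_node_iter())
    depth = 0.0
    node = leaf
    while node.parent_node is not None:
        depth += node.edge.length
        node = node.parent_node
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length /= depth
    return tree


def _derive_clades(tree: dendropy.Tree, k: int) -> dict[str, set[str]]:
    """Split the tree into k monophyletic tip groups by repeatedly breaking
    the largest group at its subtree root."""
    groups = [tree.seed_node]
    while len(groups) < k:
        groups.sort(key=lambda nd: -len(nd.leaf_nodes()))
        big = groups.pop(0)
        kids = big.child_nodes()
        if len(kids) < 2:  # cannot split a tip further
            groups.append(big)
            break
        groups = kids + groups
    named = sorted(groups, key=lambda nd: min(l.taxon.label for l in nd.leaf_nodes()))
    return {chr(ord("A") + i): {l.taxon.label for l in nd.leaf_nodes()}
            for i, nd in enumerate(named)}


def simulate_tree(cfg: SimulationConfig,
                  rng: np.random.Generator | None = None,
                  max_resample: int = 200) -> Phylogeny:
    """Pure-birth phylogeny over the configured genera, ultrametric with
    root age 1, with named clades attached to MRCA tip sets.

    Explicit clade partitions are honored by resampling until each is
    monophyletic (up to ``max_resample`` draws); otherwise ``n_clades``
    monophyletic groups are carved from the drawn tree.
    """
    if cfg.n_genera < 2:
        raise ValueError("need at least 2 genera")
    rng = rng if rng is not None else _streams(cfg.seed)["tree"]
    tips = cfg.genus_names()
    for _ in range(max_resample):
        tree = _yule_tree(rng, tips)
        if cfg.clades is None:
            clades = _derive_clades(tree, cfg.n_clades)
            return Phylogeny(tree, {k: frozenset(v) for k, v in clades.items()})
        try:
            return Phylogeny(tree, {k: frozenset(v)
                                    for k, v in cfg.clades.items()})
        except ValueError:
            continue
    raise ValueError(f"no tree with monophyletic clades in {max_resample} draws")


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def _draw_peaks(rng: np.random.Generator, n: int, max_mz: float,
                min_gap: float = 20.0) -> np.ndarray:
    for _ in range(200):
        mz = np.sort(rng.uniform(50.0, max_mz, n))
        if n < 2 or np.diff(mz).min() >= min_gap:
            break
    else:
        mz = np.linspace(50.0, max_mz, n)  # deterministic fallback
    inten = rng.lognormal(0.0, 1.0, n)
    inten *= 100.0 / inten.max()
    return np.column_stack([mz, inten])


def _classes_for_mode(cfg: SimulationConfig, mode: str,
                      planted: dict[str, str]) -> list[str]:
    """Planted classes ionize in both modes; the rest alternate, giving the
    partially overlapping per-mode class inventories."""
    out = []
    planted_set = set(planted.values())
    for i, c in enumerate(cfg.class_labels):
        if c in planted_set:
            out.append(c)
        elif (i % 2 == 0 and mode == POSITIVE) or (i % 2 == 1 and mode == NEGATIVE):
            out.append(c)
    return out


def default_planted(cfg: SimulationConfig, clade_names: list[str]) -> dict[str, str]:
    if cfg.planted_class_by_clade is not None:
        return dict(cfg.planted_class_by_clade)
    return {clade: cfg.class_labels[i % len(cfg.class_labels)]
            for i, clade in enumerate(sorted(clade_names))}


def simulate_compound_families(cfg: SimulationConfig, mode: str = POSITIVE,
                               rng: np.random.Generator | None = None,
                               planted: dict[str, str] | None = None
                               ) -> tuple[list[Spectrum], dict[str, str], dict[str, str]]:
    """Spectra for ``n_compound_families`` families in one ionization mode.

    Each family is a base spectrum plus derivatives whose precursor and
    upper-mass fragments are shifted by cumulative neutral losses; within a
    family every fragment aligns either directly or via the precursor-mass
    difference, so the modified cosine is ~1 with >= 4 matched peaks, while
    between families chance alignments are negligible.

    Returns (spectra, family_of_feature, class_of_feature).
    """
    rng = rng if rng is not None else _streams(cfg.seed)["families"]
    planted = planted if planted is not None else {}
    classes = _classes_for_mode(cfg, mode, planted)
    spectra: list[Spectrum] = []
    family_of: dict[str, str] = {}
    class_of: dict[str, str] = {}
    for fam in range(cfg.n_compound_families):
        cls = classes[fam % len(classes)]
        base_prec = rng.uniform(350.0, 800.0)
        base_peaks = _draw_peaks(rng, cfg.peaks_per_spectrum, base_prec - 30.0)
        losses = rng.choice(cfg.neutral_losses, size=cfg.members_per_family - 1)
        fam_name = f"{mode[:3]}_fam{fam:02d}"
        shift = 0.0
        for m in range(cfg.members_per_family):
            fid = f"{fam_name}_m{m}"
            peaks = base_peaks.copy()
            if m > 0:
                shift += float(losses[m - 1])
                upper = peaks[:, 0] >= np.median(peaks[:, 0])
                peaks[upper, 0] += shift
            rt = float(rng.uniform(0.5, 8.0))
            spectra.append(Spectrum(fid, base_prec + shift, rt=rt, mode=mode,
                                    peaks=peaks))
            family_of[fid] = fam_name
            class_of[fid] = cls
    return spectra, family_of, class_of


# ---------------------------------------------------------------------------
# Feature table + metadata
# ---------------------------------------------------------------------------

def build_metadata(cfg: SimulationConfig, clades: dict[str, frozenset[str]],
                   mode: str) -> pd.DataFrame:
    clade_of = {g: c for c, tips in clades.items() for g in tips}
    rows = {}
    for genus in cfg.genus_names():
        for sp in range(1, cfg.species_per_genus + 1):
            species = f"{genus}_sp{sp}"
            for solvent, tag in ((HYDRO, "he"), (ETOAC, "ea")):
                sid = f"{species}_{tag}_{mode[:3]}"
                rows[sid] = {"species": species, "genus": genus,
                             "clade": clade_of[genus], "solvent": solvent,
                             "mode": mode}
    meta = pd.DataFrame.from_dict(rows, orient="index")
    meta.index.name = "sample_id"
    return meta


def simulate_feature_table(cfg: SimulationConfig, spectra: list[Spectrum],
                           class_of: dict[str, str],
                           clades: dict[str, frozenset[str]],
                           planted: dict[str, str],
                           rng: np.random.Generator | None = None
                           ) -> tuple[FeatureTable, pd.DataFrame]:
    """Peak-area table and sample metadata for one ionization mode.

    Areas are lognormal with Bernoulli dropout; features of a clade's
    planted class have nonzero areas only in that clade's samples; the
    per-feature solvent detection pattern follows the configured per-mode
    shared / hydro-only / EtOAc-only proportions.
    """
    mode = spectra[0].mode if spectra else POSITIVE
    rng = rng if rng is not None else _streams(cfg.seed)["table"]
    meta = build_metadata(cfg, clades, mode)
    mu, sigma = cfg.abundance_lognormal
    planted_clade_of_class = {v: k for k, v in planted.items()}

    fids = [s.feature_id for s in spectra]
    patterns = rng.choice(3, size=len(fids), p=SOLVENT_PATTERN[mode])
    areas = np.zeros((len(fids), len(meta)))
    sample_clade = meta["clade"].to_numpy()
    sample_solvent = meta["solvent"].to_numpy()
    for i, fid in enumerate(fids):
        cls = class_of.get(fid)
        clade_limit = planted_clade_of_class.get(cls)
        ok_clade = np.ones(len(meta), dtype=bool) if clade_limit is None \
            else sample_clade == clade_limit
        if clade_limit is not None:
            # planted features must reach the hydroethanolic subset the
            # downstream analyses use: redraw shared vs hydro-only with the
            # mode's proportions renormalized over those two patterns
            p_shared, p_hydro, _ = SOLVENT_PATTERN[mode]
            patterns[i] = 0 if rng.random() < p_shared / (p_shared + p_hydro) \
                else 1
        if patterns[i] == 0:
            ok_solv = np.ones(len(meta), dtype=bool)
        elif patterns[i] == 1:
            ok_solv = sample_solvent == HYDRO
        else:
            ok_solv = sample_solvent == ETOAC
        ok = ok_clade & ok_solv
        vals = rng.lognormal(mu, sigma, ok.sum())
        if cfg.solvent_effect_sigma > 0:
            factor = rng.lognormal(0.0, cfg.solvent_effect_sigma)
            vals = np.where(sample_solvent[ok] == ETOAC, vals * factor, vals)
        if cfg.dropout_prob > 0:
            drop = rng.random(ok.sum()) < cfg.dropout_prob
            # keep at least one detection so the feature exists in the table
            if drop.all():
                drop[rng.integers(len(drop))] = False
            vals = np.where(drop, 0.0, vals)
        areas[i, ok] = vals

    table = FeatureTable(
        pd.DataFrame(areas, index=fids, columns=meta.index),
        pd.DataFrame({"mz": [s.precursor_mz for s in spectra],
                      "rt": [s.rt for s in spectra]}, index=fids))
    return table, meta


# ---------------------------------------------------------------------------
# Mk characters
# ---------------------------------------------------------------------------

def simulate_characters_mk(phylo: Phylogeny, q: float, n_characters: int,
                           rng: np.random.Generator | int | None = None
                           ) -> tuple[CharacterMatrix, pd.DataFrame, pd.Series]:
    """Forward-simulate binary characters under the Mk1 model.

    The root state is uniform on {0, 1}; along a branch of length t the
    state flips with probability 1/2 - 1/2 exp(-2qt).  Returns the tip
    matrix, all true node states (named as in the reconstruction:
    tip labels and ``node<i>`` in postorder), and per-character true origin
    (gain) counts.
    """
    if q <= 0:
        raise ValueError("q must be > 0")
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    index = _Index(phylo.tree)
    names = [n.taxon.label if n.is_leaf() else f"node{i}"
             for i, n in enumerate(index.nodes)]
    n_nodes = len(index.nodes)
    states = np.zeros((n_characters, n_nodes), dtype=int)
    states[:, index.root] = rng.integers(0, 2, n_characters)
    for i in reversed(range(n_nodes - 1)):  # parents before children
        p = index.parent[i]
        flip_prob = 0.5 - 0.5 * np.exp(-2.0 * q * index.length[i])
        flips = rng.random(n_characters) < flip_prob
        states[:, i] = np.where(flips, 1 - states[:, p], states[:, p])

    node_states = pd.DataFrame(states.T, index=names,
                               columns=[f"char{j:03d}" for j in range(n_characters)])
    tips = index.tip_order
    matrix = CharacterMatrix(node_states.loc[tips].copy())
    origins = {}
    for char in node_states.columns:
        gains, _ = count_origins(phylo, node_states[char])
        origins[char] = gains
    return matrix, node_states, pd.Series(origins, name="true_gains")


# ---------------------------------------------------------------------------
# Fingerprints / classification
# ---------------------------------------------------------------------------

def simulate_classification(cfg: SimulationConfig, class_of: dict[str, str],
                            rng: np.random.Generator | None = None
                            ) -> ClassificationTable:
    """Binary fingerprints and taxonomy labels standing in for in-silico
    structure classification.

    Each class gets a random prototype fingerprint; features inherit it
    with small bit-flip noise, so fingerprint clustering groups features by
    class.  A configurable fraction of features is left unclassified (null
    superclass) to exercise tree pruning.
    """
    rng = rng if rng is not None else _streams(cfg.seed)["fingerprints"]
    protos = {c: rng.integers(0, 2, cfg.fingerprint_length)
              for c in cfg.class_labels}
    rows, fps = {}, {}
    for fid in sorted(class_of):
        cls = class_of[fid]
        flips = rng.random(cfg.fingerprint_length) < cfg.fingerprint_noise
        fps[fid] = np.where(flips, 1 - protos[cls], protos[cls])
        if rng.random() < cfg.unclassified_prob:
            rows[fid] = {"superclass": None, "class": None, "subclass": None}
        else:
            rows[fid] = {"superclass": SUPERCLASS_OF.get(cls, f"Superclass of {cls}"),
                         "class": cls, "subclass": f"{cls} subclass"}
    labels = pd.DataFrame.from_dict(rows, orient="index")
    fingerprints = pd.DataFrame.from_dict(fps, orient="index")
    return ClassificationTable(labels, fingerprints)


def simulate_library(cfg: SimulationConfig, spectra: list[Spectrum],
                     family_of: dict[str, str], class_of: dict[str, str]
                     ) -> list[Spectrum]:
    """Reference spectral library: one annotated copy of each family's base
    spectrum (exact spectral match for the corresponding features)."""
    library = []
    for s in spectra:
        if s.feature_id.endswith("_m0"):
            fam = family_of[s.feature_id]
            library.append(Spectrum(
                f"lib_{fam}", s.precursor_mz, s.rt, s.charge, s.mode, s.peaks,
                annotation={"compound": f"compound_{fam}",
                            "class": class_of[s.feature_id]}))
    return library


# ---------------------------------------------------------------------------
# Whole-dataset driver
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    family_of_feature: dict[str, str]
    class_of_feature: dict[str, str]
    planted_class_by_clade: dict[str, str]
    mk_matrix: CharacterMatrix
    true_node_states: pd.DataFrame
    true_origin_counts: pd.Series


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    tree: Phylogeny
    spectra: dict[str, list[Spectrum]]
    tables: dict[str, FeatureTable]
    metadata: pd.DataFrame
    library: dict[str, list[Spectrum]]
    classification: dict[str, ClassificationTable]
    truth: GroundTruth


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate the full set of pipeline inputs plus ground truth."""
    streams = _streams(cfg.seed)
    tree = simulate_tree(cfg, streams["tree"])
    planted = default_planted(cfg, list(tree.clades))

    spectra, tables, library, classification = {}, {}, {}, {}
    family_of: dict[str, str] = {}
    class_of: dict[str, str] = {}
    metas = []
    for mode in cfg.modes:
        specs, fam, cls = simulate_compound_families(
            cfg, mode, streams["families"], planted)
        table, meta = simulate_feature_table(
            cfg, specs, cls, tree.clades, planted, streams["table"])
        spectra[mode] = specs
        tables[mode] = table
        metas.append(meta)
        library[mode] = simulate_library(cfg, specs, fam, cls)
        classification[mode] = simulate_classification(cfg, cls,
                                                       streams["fingerprints"])
        family_of.update(fam)
        class_of.update(cls)

    mk_matrix, node_states, origins = simulate_characters_mk(
        tree, cfg.mk_rate, cfg.n_characters, streams["characters"])
    truth = GroundTruth(family_of, class_of, planted, mk_matrix,
                        node_states, origins)
    return SyntheticDataset(cfg, tree, spectra, tables,
                            pd.concat(metas), library, classification, truth)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write every artifact as plain text files; returns path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for mode, specs in ds.spectra.items():
        p = out / f"spectra_{mode}.mgf"
        write_mgf(specs, p)
        paths[f"mgf_{mode}"] = str(p)
        p = out / f"library_{mode}.mgf"
        write_mgf(ds.library[mode], p)
        paths[f"library_{mode}"] = str(p)
        p = out / f"features_{mode}.csv"
        write_feature_table(ds.tables[mode], p)
        paths[f"features_{mode}"] = str(p)
        p = out / f"classification_{mode}.tsv"
        write_classification_table(ds.classification[mode], p)
        paths[f"classification_{mode}"] = str(p)
    p = out / "metadata.tsv"
    write_metadata(ds.metadata, p)
    paths["metadata"] = str(p)
    p = out / "tree.nwk"
    ds.tree.write(p)
    paths["tree"] = str(p)
    p = out / "clades.json"
    p.write_text(json.dumps({k: sorted(v) for k, v in ds.tree.clades.items()},
                            indent=1, sort_keys=True))
    paths["clades"] = str(p)
    p = out / "mk_characters.tsv"
    write_characters_tsv(ds.truth.mk_matrix, p)
    paths["mk_characters"] = str(p)
    p = out / "ground_truth.json"
    p.write_text(json.dumps({
        "family_of_feature": ds.truth.family_of_feature,
        "class_of_feature": ds.truth.class_of_feature,
        "planted_class_by_clade": ds.truth.planted_class_by_clade,
        "true_origin_counts": ds.truth.true_origin_counts.to_dict(),
    }, indent=1, sort_keys=True))
    paths["ground_truth"] = str(p)
    return paths
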