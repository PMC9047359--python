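"""End-to-end orchestration: ingest -> network -> ordination -> enrichment
-> character coding -> ancestral reconstruction.

A single YAML-able config drives the run; every stage writes plain-text
artifacts into the output directory and a machine-readable manifest records
the config hash, seeds and per-stage row counts.  Stages can be skipped
individually; a stage failure aborts the run with the stage name, leaving a
``manifest.partial.json`` marker.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestral_reconstruction as asr
from . import character_coding as coding
from . import chemical_classes as chem
from . import molecular_networking as net
from . import multivariate_stats as stats
from . import spectra_io as io
from .spectral_similarity import SimilarityParams
from .synthetic_data import ETOAC, HYDRO

logger = logging.getLogger("chemophylo")

ALL_STAGES = ("ingest", "network", "ordinate", "enrich",
              "code_characters", "asr")


@dataclass
class PipelineConfig:
    """Validated configuration of a full run.

    ``mgf``, ``features``, ``library`` and ``classification`` map ionization
    mode -> file path; ``library`` and ``classification`` are optional per
    mode (stages degrade gracefully without them).
    """

    outdir: str
    metadata: str
    mgf: dict[str, str] = field(default_factory=dict)
    features: dict[str, str] = field(default_factory=dict)
    library: dict[str, str] = field(default_factory=dict)
    classification: dict[str, str] = field(default_factory=dict)
    tree: str | None = None
    clades_file: str | None = None
    dialect: str = "plain"
    similarity: SimilarityParams = field(default_factory=SimilarityParams)
    clades_tested: list[str] | None = None
    # optional network pruning (off by default)
    blank_fraction: float | None = None
    top_k_neighbors: int | None = None
    max_component_size: int | None = None
    alpha: float = 0.05
    min_abundance: float = 0.0
    genus_threshold: float = 0.0
    n_permutations: int = 999
    seed: int = 0
    skip: list[str] = field(default_factory=list)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("similarity", {})
        cfg = cls(**raw)
        if isinstance(sim, dict):
            cfg.similarity = SimilarityParams(**sim)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        unknown = set(self.skip) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages in skip: {sorted(unknown)}")
        if not self.mgf or not self.features:
            raise ValueError("config needs at least one mode's mgf and features")
        if set(self.mgf) != set(self.features):
            raise ValueError("mgf and features must cover the same modes")
        for group in (self.mgf, self.features, self.library,
                      self.classification):
            for mode, path in group.items():
                if not Path(path).exists():
                    raise FileNotFoundError(f"{mode}: {path}")
        if not Path(self.metadata).exists():
            raise FileNotFoundError(self.metadata)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def config_hash(self) -> str:
        as_dict = dataclasses.asdict(self)
        blob = json.dumps(as_dict, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all configured stages; returns the manifest dict."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "chemophylo",
        "version": _pkg_version("chemophylo"),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }
    state: dict = {}
    stages = [(name, globals()[f"_stage_{name}"]) for name in ALL_STAGES
              if name not in cfg.skip]
    partial = out / "manifest.partial.json"
    for name, fn in stages:
        try:
            counts = fn(cfg, state, out)
        except Exception as exc:
            partial.write_text(json.dumps(manifest, indent=1, default=str))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = counts
        logger.info("stage %s done: %s", name, counts)
    partial.unlink(missing_ok=True)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    return manifest


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_ingest(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    meta = io.read_metadata(cfg.metadata)
    spectra, tables = {}, {}
    counts = {}
    for mode in sorted(cfg.mgf):
        specs = io.read_mgf(cfg.mgf[mode], mode=mode)
        table = io.read_feature_table(cfg.features[mode], dialect=cfg.dialect)
        io.validate_metadata(meta, table)
        table = io.filter_features_with_ms2(table, specs)
        spectra[mode], tables[mode] = specs, table
        counts[mode] = {"spectra": len(specs), "features": table.shape[0],
                        "samples": table.shape[1]}
    state.update(meta=meta, spectra=spectra, tables=tables)
    return counts


def _hydro_table(cfg: PipelineConfig, state: dict, mode: str) -> io.FeatureTable:
    meta = state["meta"]
    hydro = [s for s in state["tables"][mode].sample_ids
             if meta.loc[s, "solvent"] == HYDRO]
    return state["tables"][mode].subset_samples(hydro)


def _stage_network(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    counts = {}
    state["networks"], state["hits"] = {}, {}
    for mode, specs in state["spectra"].items():
        # networking runs on the hydroethanolic-extract features
        table = _hydro_table(cfg, state, mode)
        specs_in = [s for s in specs if s.feature_id in set(table.feature_ids)]
        scores = net.pairwise_scores(specs_in, cfg.similarity)
        hits = []
        if mode in cfg.library:
            library = io.read_mgf(cfg.library[mode], mode=mode)
            hits = net.library_search(specs_in, library, cfg.similarity)
        g = net.build_network(scores, table, state["meta"], cfg.similarity,
                              spectra=specs_in, library_hits=hits,
                              blank_fraction=cfg.blank_fraction,
                              top_k_neighbors=cfg.top_k_neighbors,
                              max_component_size=cfg.max_component_size)
        net.write_network(g, out / f"network_{mode}.graphml", "graphml")
        net.write_network(g, out / f"network_{mode}_edges.tsv", "edge_tsv")
        state["networks"][mode] = g
        state["hits"][mode] = hits
        counts[mode] = {"nodes": g.number_of_nodes(),
                        "edges": g.number_of_edges(),
                        "components": len(net.components(g)),
                        "library_hits": len(hits)}
    overlap = net.extraction_overlap(
        {f"{mode}:{solv}": state["tables"][mode].subset_samples(
            [s for s in state["tables"][mode].sample_ids
             if state["meta"].loc[s, "solvent"] == solv])
         for mode in state["tables"] for solv in (HYDRO, ETOAC)})
    overlap.to_csv(out / "extraction_overlap.tsv", sep="\t", index=False)
    state["overlap"] = overlap
    return counts


def _stage_ordinate(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    meta = state["meta"]
    counts = {}
    state["groups"] = {}
    rng = np.random.default_rng(cfg.seed)
    for mode, table in state["tables"].items():
        dm = stats.bray_curtis(table)
        solvents = meta.loc[table.sample_ids, "solvent"]
        res = stats.permanova(dm, solvents, cfg.n_permutations,
                              seed=int(rng.integers(2**31)))
        counts[mode] = {"solvent_permanova_F": round(res.pseudo_F, 4),
                        "solvent_permanova_p": res.p_value}
        for solv in (HYDRO, ETOAC):
            sub = table.subset_samples(
                [s for s in table.sample_ids if solvents[s] == solv])
            dms = stats.canberra(sub)
            coords = stats.pcoa(dms)
            coords.coordinates.iloc[:, :3].to_csv(
                out / f"pcoa_{mode}_{solv}.tsv", sep="\t")
            clades = meta.loc[sub.sample_ids, "clade"]
            pres = stats.permanova(dms, clades, cfg.n_permutations,
                                   seed=int(rng.integers(2**31)))
            counts[f"{mode}:{solv}"] = {
                "clade_permanova_F": round(pres.pseudo_F, 4),
                "clade_permanova_p": pres.p_value}
            if solv == HYDRO:
                state["groups"][mode] = stats.cluster_two_groups(dms)
    with open(out / "permanova.json", "w") as fh:
        json.dump(counts, fh, indent=1)
    return counts


def _stage_enrich(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    counts = {}
    state["abundance"], state["enrichment"] = {}, {}
    for mode, table in state["tables"].items():
        if mode not in cfg.classification:
            continue
        cls = chem.read_classification_table(cfg.classification[mode])
        hydro = _hydro_table(cfg, state, mode)
        abund = chem.class_abundance_table(hydro, cls)
        result = chem.enrichment_anova(abund, state["meta"],
                                       cfg.clades_tested, cfg.alpha)
        abund.to_csv(out / f"class_abundance_{mode}.tsv", sep="\t")
        result.anova.to_csv(out / f"enrichment_{mode}.tsv", sep="\t",
                            index=False)
        result.heatmap.to_csv(out / f"enrichment_heatmap_{mode}.tsv", sep="\t")
        if cls.fingerprints is not None and len(cls.fingerprints) >= 2:
            tree = chem.build_chemistry_tree(cls)
            tree = chem.prune_to_superclass(tree, cls)
            chem.write_newick(tree, out / f"chemistry_tree_{mode}.nwk")
        state["abundance"][mode] = abund
        state["enrichment"][mode] = result
        sig = result.anova["p_adj"] < cfg.alpha
        counts[mode] = {"classes": int(abund.shape[1]),
                        "significant": int(sig.sum())}
    return counts


def _stage_code_characters(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    matrices = {}
    for mode, abund in state.get("abundance", {}).items():
        presence = coding.binarize_classes(abund, state["meta"],
                                           cfg.min_abundance)
        matrices[mode] = coding.summarize_to_genus(presence, state["meta"],
                                                   cfg.genus_threshold)
    if not matrices:
        raise ValueError("no class abundances available (enrich stage "
                         "skipped or no classification tables)")
    if len(matrices) == 2:
        pos, neg = matrices.get("positive"), matrices.get("negative")
        merged = coding.merge_modes(pos, neg)
    else:
        merged = next(iter(matrices.values()))
    coding.write_characters_tsv(merged, out / "characters.tsv")
    coding.write_characters_nexus(merged, out / "characters.nex")
    state["characters"] = merged
    return {"genera": len(merged.genera), "characters": len(merged.characters)}


def _stage_asr(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    if cfg.tree is None:
        raise ValueError("asr stage requires a tree")
    clades = {}
    if cfg.clades_file:
        clades = {k: set(v)
                  for k, v in json.loads(Path(cfg.clades_file).read_text()).items()}
    phylo = asr.read_newick(cfg.tree, clades)
    matrix = state["characters"]
    results, report = asr.run_asr(phylo, matrix)
    report.to_csv(out / "asr_report.tsv", sep="\t", index=False)
    rows = [{"character": r.character, "q_hat": r.q_hat,
             "log_likelihood": r.log_likelihood, "gains": r.gains,
             "losses": r.losses, "ubiquitous": r.ubiquitous,
             **{f"call_{c}": call for c, call in r.clade_calls.items()}}
            for r in results]
    pd.DataFrame(rows).to_csv(out / "asr_characters.tsv", sep="\t", index=False)
    (out / "asr_ubiquitous.json").write_text(
        json.dumps(report.attrs["ubiquitous"], indent=1))
    state["asr"] = (results, report)
    n_synapo = sum(1 for r in results
                   for c in r.clade_calls.values() if c.startswith("synapomorphy"))
    n_homo = sum(1 for r in results
                 for c in r.clade_calls.values() if c.startswith("homoplasy"))
    return {"characters": len(results),
            "ubiquitous": len(report.attrs["ubiquitous"]),
            "synapomorphy_calls": n_synapo, "homoplasy_calls": n_homo}
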