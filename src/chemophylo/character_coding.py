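"""Binary character coding of chemical classes for phylogenetic analysis.

Class detections are binarized per species, summarized to the genus level
by an arithmetic mean over the genus's species (state 1 when the mean
exceeds a threshold, default 0: presence in any sampled species), and the
two ionization modes are merged by logical OR with per-character provenance
("pos" / "neg" / "both").
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("chemophylo")


@dataclass
class CharacterMatrix:
    """Genera x characters binary presence/absence matrix."""

    states: pd.DataFrame  # index genera, columns character names, values {0,1}
    provenance: pd.Series | None = None  # per character: pos / neg / both

    def __post_init__(self) -> None:
        vals = self.states.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("character states must be binary 0/1")
        if self.states.index.has_duplicates:
            raise ValueError("duplicate genus names")
        if self.states.columns.has_duplicates:
            raise ValueError("duplicate character names")
        self.states = self.states.astype(int)

    @property
    def genera(self) -> list[str]:
        return list(self.states.index)

    @property
    def characters(self) -> list[str]:
        return list(self.states.columns)


def binarize_classes(abund: pd.DataFrame, meta: pd.DataFrame,
                     min_abundance: float = 0.0) -> pd.DataFrame:
    """Species x class presence: 1 iff the class's relative abundance
    strictly exceeds ``min_abundance`` in at least one sample of the
    species."""
    if (abund.to_numpy() < 0).any():
        raise ValueError("abundances must be >= 0")
    species = meta.loc[abund.index, "species"]
    present = (abund > min_abundance).groupby(species).any()
    return present.astype(int)


def summarize_to_genus(species_presence: pd.DataFrame, meta: pd.DataFrame,
                       threshold: float = 0.0) -> CharacterMatrix:
    """Genus x class states from the arithmetic mean of species presences.

    State 1 iff mean > ``threshold`` (strict); the default 0 codes a genus
    present whenever any sampled species is.
    """
    sp_to_genus = (meta.reset_index()[["species", "genus"]]
                   .drop_duplicates().set_index("species")["genus"])
    unmapped = [s for s in species_presence.index if s not in sp_to_genus.index]
    if unmapped:
        raise ValueError(f"species without genus mapping: {unmapped}")
    genus = sp_to_genus.reindex(species_presence.index)
    means = species_presence.groupby(genus).mean()
    if (means.index.value_counts() == 0).any():  # pragma: no cover
        raise ValueError("genus with zero species")
    return CharacterMatrix((means > threshold).astype(int))


def merge_modes(pos: CharacterMatrix, neg: CharacterMatrix) -> CharacterMatrix:
    """Merge the two ionization modes' matrices by logical OR.

    Characters absent from one mode count as 0 there; provenance records
    which mode(s) detected each character ("pos", "neg", or "both").
    Commutative and idempotent.
    """
    if set(pos.genera) != set(neg.genera):
        diff = sorted(set(pos.genera) ^ set(neg.genera))
        raise ValueError(f"genus sets differ between modes: {diff}")
    genera = pos.genera
    chars = sorted(set(pos.characters) | set(neg.characters))
    p = pos.states.reindex(index=genera, columns=chars, fill_value=0)
    n = neg.states.reindex(index=genera, columns=chars, fill_value=0)
    merged = ((p + n) > 0).astype(int)
    prov = {}
    for c in chars:
        in_pos, in_neg = p[c].any(), n[c].any()
        prov[c] = "both" if (in_pos and in_neg) else ("pos" if in_pos else "neg")
    return CharacterMatrix(merged, pd.Series(prov, name="provenance"))


def profile_character(groups: pd.Series, meta: pd.DataFrame,
                      name: str = "chemical_profile") -> CharacterMatrix:
    """Code the two-group PCoA chemical-profile split as one binary
    character at the genus level.

    A genus takes the majority group of its samples (group "B" coded 1);
    ties go to the group of its lexicographically first sample, with a
    logged flag.
    """
    genus = meta.loc[groups.index, "genus"]
    states = {}
    for g, idx in groups.groupby(genus).groups.items():
        labels = groups.loc[sorted(idx)]
        counts = labels.value_counts()
        if len(counts) == 2 and counts.iloc[0] == counts.iloc[1]:
            choice = labels.iloc[0]
            logger.warning("profile_character: tie for genus %s -> %s", g, choice)
        else:
            choice = counts.idxmax()
        states[g] = 1 if choice == "B" else 0
    df = pd.DataFrame({name: states})
    df.index.name = "genus"
    return CharacterMatrix(df.sort_index())


# ---------------------------------------------------------------------------
# File formats: TSV and a NEXUS characters block (Mesquite-compatible)
# ---------------------------------------------------------------------------

def write_characters_tsv(matrix: CharacterMatrix, path: str | Path) -> None:
    out = matrix.states.copy()
    out.to_csv(path, sep="\t", index_label="genus")
    if matrix.provenance is not None:
        prov_path = Path(path).with_suffix(".provenance.tsv")
        matrix.provenance.rename("provenance").rename_axis("character").to_csv(
            prov_path, sep="\t")


def read_characters_tsv(path: str | Path) -> CharacterMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"genus": str}).set_index("genus")
    prov_path = Path(path).with_suffix(".provenance.tsv")
    prov = None
    if prov_path.exists():
        prov = pd.read_csv(prov_path, sep="\t", dtype=str).set_index(
            "character")["provenance"]
    return CharacterMatrix(df, prov)


def write_characters_nexus(matrix: CharacterMatrix, path: str | Path) -> None:
    """Write the matrix as a NEXUS file with TAXA and CHARACTERS blocks."""
    genera = matrix.genera
    chars = matrix.characters
    lines = ["#NEXUS", "", "BEGIN TAXA;",
             f"    DIMENSIONS NTAX={len(genera)};",
             "    TAXLABELS " + " ".join(_nexus_quote(g) for g in genera) + ";",
             "END;", "", "BEGIN CHARACTERS;",
             f"    DIMENSIONS NCHAR={len(chars)};",
             '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;',
             "    CHARSTATELABELS",
             ",\n".join(f"        {i + 1} {_nexus_quote(c)}"
                        for i, c in enumerate(chars)) + ";",
             "    MATRIX"]
    width = max(len(g) for g in genera) + 2
    for g in genera:
        row = "".join(str(v) for v in matrix.states.loc[g])
        lines.append(f"        {_nexus_quote(g):<{width}} {row}")
    lines += ["    ;", "END;", ""]
    Path(path).write_text("\n".join(lines))


def _nexus_quote(label: str) -> str:
    if re.search(r"[\s()\[\]{}/\\,;:=*'\"`+<>-]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_characters_nexus(path: str | Path) -> CharacterMatrix:
    """Read a NEXUS standard characters block written by
    :func:`write_characters_nexus`."""
    text = Path(path).read_text()
    labels = re.search(r"CHARSTATELABELS(.*?);", text, re.S | re.I)
    chars = []
    if labels:
        for item in labels.group(1).split(","):
            item = item.strip()
            if not item:
                continue
            m = re.match(r"\d+\s+(.*)", item, re.S)
            chars.append(_nexus_unquote(m.group(1).strip()))
    matrix_m = re.search(r"MATRIX(.*?);", text, re.S | re.I)
    if not matrix_m:
        raise ValueError(f"{path}: no MATRIX block")
    rows = {}
    for line in matrix_m.group(1).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("'"):
            m = re.match(r"'((?:[^']|'')*)'\s+([01?\-]+)", line)
            name, states = _nexus_unquote("'" + m.group(1) + "'"), m.group(2)
        else:
            name, states = line.split(None, 1)
            states = states.strip()
        rows[name] = [int(c) for c in states]
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=chars or None)
    df.index.name = "genus"
    return CharacterMatrix(df)


def _nexus_unquote(label: str) -> str:
    if label.startswith("'") and label.endswith("'"):
        return label[1:-1].replace("''", "'")
    return label
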