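"""Readers and writers for the formats the pipeline touches.

Trees are Newick (via dendropy, treated as rooted as written, underscores
preserved); presence/detection matrices are tab-separated with the dialect
``1`` = present/detected, ``0`` = absent/undetected, ``NA`` = unknown;
gene sets are one identifier per line; trait tables are two-column TSV
(species, ``H`` or ``NH``).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

GENOME = "genome"
TRANSCRIPTOME = "transcriptome"

HOST = "host"
NON_HOST = "non-host"

_TRAIT_CODES = {"H": HOST, "NH": NON_HOST, HOST: HOST, NON_HOST: NON_HOST}


class FormatError(ValueError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def read_newick(text: str) -> dendropy.Tree:
    """Parse a single rooted Newick statement into a dendropy tree.

    Underscores in tip labels are preserved verbatim.  Raises
    :class:`FormatError` on unbalanced parentheses, duplicate tip labels
    or empty labels, naming the offending label where possible.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise FormatError("newick statement must end with ';'")
    if text.count("(") != text.count(")"):
        raise FormatError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'"
        )
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"newick parse error: {exc}") from exc
    labels = [leaf.taxon.label if leaf.taxon else "" for leaf in tree.leaf_node_iter()]
    if any(not lab for lab in labels):
        raise FormatError("empty tip label in newick input")
    dupes = {lab for lab in labels if labels.count(lab) > 1}
    if dupes:
        raise FormatError(f"duplicate tip labels: {sorted(dupes)}")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


@dataclass
class GeneFamilyTree:
    """A gene family tree whose tips are genes annotated with species.

    ``species_map`` sends each gene id (tip label) to its species id.  By
    default the species id is the suffix after the last underscore of the
    tip label, e.g. ``g17_athaliana`` -> species ``athaliana``.
    """

    tree: dendropy.Tree
    species_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = tip_labels(self.tree)
        if not self.species_map:
            self.species_map = {lab: split_gene_label(lab)[1] for lab in labels}
        missing = [lab for lab in labels if lab not in self.species_map]
        if missing:
            raise FormatError(f"tips without species annotation: {missing}")

    def species_of(self, gene_id: str) -> str:
        return self.species_map[gene_id]


def split_gene_label(label: str, delimiter: str = "_") -> tuple[str, str]:
    """Split ``geneid_speciesid`` on the last delimiter occurrence."""
    if delimiter not in label:
        raise FormatError(f"tip label {label!r} has no {delimiter!r} species suffix")
    gene, _, species = label.rpartition(delimiter)
    if not gene or not species:
        raise FormatError(f"tip label {label!r} splits into an empty part")
    return gene, species


def read_gene_family_tree(
    text: str, species_map: Mapping[str, str] | None = None
) -> GeneFamilyTree:
    return GeneFamilyTree(read_newick(text), dict(species_map or {}))


# ---------------------------------------------------------------------------
# Presence matrices
# ---------------------------------------------------------------------------


@dataclass
class PresenceMatrix:
    """Ternary gene/OG x species presence states with data-source tags.

    ``data`` is a float frame: 1.0 = present, 0.0 = absent, NaN = unknown.
    ``source`` tags each species column as genome- or transcriptome-derived.
    """

    data: pd.DataFrame
    source: dict[str, str]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate row (gene/OG) identifiers")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate species identifiers")
        missing = [s for s in self.data.columns if s not in self.source]
        if missing:
            raise FormatError(f"species without a data-source tag: {missing}")
        bad = {v for v in self.source.values()} - {GENOME, TRANSCRIPTOME}
        if bad:
            raise FormatError(f"unknown data-source tags: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    def is_present(self, gene: str, species: str) -> bool:
        return self.data.at[gene, species] == 1.0

    def is_absent(self, gene: str, species: str) -> bool:
        return self.data.at[gene, species] == 0.0

    def is_unknown(self, gene: str, species: str) -> bool:
        return bool(np.isnan(self.data.at[gene, species]))


def _parse_cells(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(np.nan, index=df.index, columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        for i, row in enumerate(df.index):
            tok = str(df.iat[i, j]).strip()
            if tok == "1":
                out.iat[i, j] = 1.0
            elif tok == "0":
                out.iat[i, j] = 0.0
            elif tok in ("NA", "nan"):
                out.iat[i, j] = np.nan
            else:
                raise FormatError(
                    f"unknown cell token {tok!r} at row {row!r}, column {col!r}"
                )
    return out


def read_presence_matrix(
    path_or_buf, source_map: Mapping[str, str]
) -> PresenceMatrix:
    """Read a TSV presence matrix (first column row ids, header species ids)."""
    raw = pd.read_csv(
        path_or_buf, sep="\t", header=None, dtype=str, keep_default_na=False
    )
    header = [str(v) for v in raw.iloc[0, 1:]]
    if len(header) != len(set(header)):
        raise FormatError("duplicate species identifiers in header")
    df = raw.iloc[1:].set_index(raw.columns[0])
    df.index = [str(v) for v in df.index]
    df.columns = header
    if df.index.has_duplicates:
        raise FormatError("duplicate gene/OG identifiers")
    if df.shape[0] == 0:
        raise FormatError("no rows in presence matrix")
    return PresenceMatrix(_parse_cells(df), {s: source_map[s] for s in df.columns})


def write_presence_matrix(matrix: PresenceMatrix, path_or_buf) -> None:
    enc = matrix.data.map(
        lambda v: "NA" if np.isnan(v) else ("1" if v == 1.0 else "0")
    )
    enc.to_csv(path_or_buf, sep="\t", index_label="id")


# ---------------------------------------------------------------------------
# Gene sets and trait tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("gene set must have a non-empty name")


def read_gene_set(path_or_buf, name: str | None = None) -> GeneSet:
    """One identifier per line; ``#`` comments and blank lines are skipped.

    An empty file yields an empty set with a warning rather than an error.
    """
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
        set_name = name or "gene_set"
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
        set_name = name or str(path_or_buf)
    members = {
        ln.strip() for ln in lines if ln.strip() and not ln.lstrip().startswith("#")
    }
    if not members:
        warnings.warn(f"gene set {set_name!r} is empty", stacklevel=2)
    return GeneSet(set_name, frozenset(members))


def write_gene_set(gene_set: GeneSet, path) -> None:
    with open(path, "w") as fh:
        for member in sorted(gene_set.members):
            fh.write(member + "\n")


def read_trait_table(path_or_buf) -> dict[str, str]:
    """Two-column TSV: species id, then ``H``/``NH`` (or host/non-host)."""
    df = pd.read_csv(
        path_or_buf, sep="\t", header=None, names=["species", "trait"], dtype=str
    )
    if df["species"].duplicated().any():
        dup = df["species"][df["species"].duplicated()].tolist()
        raise FormatError(f"duplicate species in trait table: {dup}")
    traits: dict[str, str] = {}
    for _, row in df.iterrows():
        code = str(row["trait"]).strip()
        if code not in _TRAIT_CODES:
            raise FormatError(f"unknown trait value {code!r} for {row['species']!r}")
        traits[str(row["species"]).strip()] = _TRAIT_CODES[code]
    return traits


def write_trait_table(traits: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for sp in traits:
            fh.write(f"{sp}\t{'H' if traits[sp] == HOST else 'NH'}\n")


def presence_matrix_from_text(text: str, source_map: Mapping[str, str]) -> PresenceMatrix:
    return read_presence_matrix(io.StringIO(text), source_map)
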