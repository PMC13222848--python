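"""Karyotype tables, phylogenies, and the join between them.

Input data are (a) a delimited table of per-species karyotype records —
haploid autosome count plus sex-chromosome system — and (b) one or more
rooted trees with branch lengths in units of 10^8 years.  Species may carry
several conflicting records; downstream inference resolves each tip to a
single state per run by a uniform random draw.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed vocabulary of supported sex-chromosome systems.
SCS_VOCABULARY = ("XY", "XO", "neoXY")

# Accepted spellings, lower-cased with separators stripped.  "xyp" is the
# distance-pairing punctiform-y variant of a plain XY system.
_SCS_ALIASES = {
    "xy": "XY",
    "xyp": "XY",
    "xo": "XO",
    "x0": "XO",
    "neoxy": "neoXY",
}

_COLUMN_ALIASES = {
    "species": {"species", "taxon", "name", "tip"},
    "haploid_autosomes": {
        "haploid_autosomes",
        "haploid_autosome_number",
        "autosomes",
        "autosome_number",
        "k",
    },
    "scs": {"scs", "sex_chromosome_system", "system", "sex_system"},
}


class KaryotypeFormatError(ValueError):
    """Malformed karyotype table (missing columns, bad header)."""


class KaryotypeValidationError(ValueError):
    """A row violates a record invariant; message names the row."""


class TreeFormatError(ValueError):
    """Unparseable tree input or a tree violating a structural invariant."""


def normalize_scs(label: str) -> str:
    """Map a free-text sex-chromosome-system label onto the closed vocabulary.

    Raises ``KaryotypeValidationError`` for anything outside it (multi-sex
    systems such as X1X2Y are unsupported by design).
    """
    key = re.sub(r"[\s_\-+]", "", str(label)).lower()
    try:
        return _SCS_ALIASES[key]
    except KeyError:
        raise KaryotypeValidationError(
            f"unsupported sex-chromosome system {label!r}; "
            f"expected one of {SCS_VOCABULARY}"
        ) from None


def normalize_species(name: str) -> str:
    """Canonical species key: trimmed, internal whitespace collapsed to '_'."""
    return re.sub(r"\s+", "_", str(name).strip())


@dataclass(frozen=True)
class KaryotypeRecord:
    """One published karyotype for one species."""

    species: str
    haploid_autosomes: int
    scs: str
    source: str | None = None

    def __post_init__(self) -> None:
        if not str(self.species).strip():
            raise KaryotypeValidationError("species name must be non-empty")
        if self.scs not in SCS_VOCABULARY:
            raise KaryotypeValidationError(
                f"scs {self.scs!r} not in {SCS_VOCABULARY}"
            )
        if not isinstance(self.haploid_autosomes, (int, np.integer)):
            raise KaryotypeValidationError(
                f"haploid_autosomes must be an integer, got "
                f"{self.haploid_autosomes!r}"
            )
        if self.haploid_autosomes < 1:
            raise KaryotypeValidationError(
                f"haploid_autosomes must be >= 1, got {self.haploid_autosomes}"
            )


class Phylogeny:
    """A rooted tree with branch lengths (1 unit = 10^8 years).

    Thin wrapper around :class:`dendropy.Tree` that enforces unique tip
    labels and the presence of branch lengths, and exposes the handful of
    operations the pipeline needs (pruning, depth, ultrametricity check).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeFormatError(f"duplicate tip labels: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise TreeFormatError("tree has edges without branch lengths")
            if edge.length < 0:
                raise TreeFormatError(f"negative branch length {edge.length}")

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [
            normalize_species(leaf.taxon.label)
            for leaf in self._tree.leaf_node_iter()
        ]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def total_length(self) -> float:
        return sum(
            e.length
            for e in self._tree.preorder_edge_iter()
            if e.length is not None and e.head_node is not self._tree.seed_node
        )

    @property
    def depth(self) -> float:
        """Maximum root-to-tip distance."""
        return max(self._tip_depths())

    def _tip_depths(self) -> list[float]:
        self._tree.calc_node_root_distances(
            return_leaf_distances_only=True
        )
        return [leaf.root_distance for leaf in self._tree.leaf_node_iter()]

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        depths = self._tip_depths()
        return (max(depths) - min(depths)) <= tol * max(max(depths), 1.0)

    def prune_to(self, labels: Iterable[str]) -> "Phylogeny":
        """Return a copy restricted to the given tip labels."""
        keep = {normalize_species(x) for x in labels}
        clone = self._tree.clone(depth=1)
        taxa = [
            leaf.taxon
            for leaf in clone.leaf_node_iter()
            if normalize_species(leaf.taxon.label) in keep
        ]
        if not taxa:
            raise TreeFormatError("pruning would remove every tip")
        clone.retain_taxa(taxa)
        return Phylogeny(clone)

    def scaled(self, factor: float) -> "Phylogeny":
        """Return a copy with every branch length multiplied by ``factor``."""
        clone = self._tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
        return Phylogeny(clone)

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips}, depth={self.depth:.4g})"


@dataclass
class MatchedDataset:
    """A phylogeny joined with per-tip karyotype records.

    Every retained tip carries at least one record; tips without records
    have been pruned (and logged), records without tips dropped.
    """

    phylogeny: Phylogeny
    records_by_tip: dict[str, list[KaryotypeRecord]]
    pruned_tips: list[str] = field(default_factory=list)
    unmatched_species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        tips = set(self.phylogeny.tip_labels)
        if tips != set(self.records_by_tip):
            missing = tips - set(self.records_by_tip)
            extra = set(self.records_by_tip) - tips
            raise ValueError(
                f"tip/record mismatch: tips without records {sorted(missing)}, "
                f"records without tips {sorted(extra)}"
            )
        for tip, recs in self.records_by_tip.items():
            if not recs:
                raise ValueError(f"tip {tip!r} has no karyotype records")

    @property
    def n_tips(self) -> int:
        return self.phylogeny.n_tips

    @property
    def multi_record_tips(self) -> list[str]:
        return [t for t, r in self.records_by_tip.items() if len(r) > 1]


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    lowered = {c.strip().lower(): c for c in columns}
    for canonical, aliases in _COLUMN_ALIASES.items():
        hit = [orig for low, orig in lowered.items() if low in aliases]
        if not hit:
            raise KaryotypeFormatError(
                f"missing required column {canonical!r} "
                f"(accepted aliases: {sorted(aliases)})"
            )
        mapping[canonical] = hit[0]
    return mapping


def read_karyotype_table(
    path: str | Path | io.IOBase, *, delimiter: str | None = None
) -> list[KaryotypeRecord]:
    """Read a delimited karyotype table into validated records.

    The table needs columns for species, haploid autosome number, and
    sex-chromosome system (case-insensitive aliases accepted).  Duplicate
    species are allowed — they represent conflicting published records for
    the same tip.  The delimiter is sniffed unless given explicitly.
    """
    if isinstance(path, (str, Path)) and not Path(path).exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            engine="python" if delimiter is None else "c",
            dtype=str,
            comment="#",
        )
    except pd.errors.EmptyDataError:
        raise KaryotypeFormatError("karyotype table is empty (no header)")
    cols = _resolve_columns(list(df.columns))
    if df.empty:
        logger.warning("karyotype table %s has a header but no rows", path)
        return []
    has_source = any(c.strip().lower() == "source" for c in df.columns)
    source_col = next(
        (c for c in df.columns if c.strip().lower() == "source"), None
    )
    records: list[KaryotypeRecord] = []
    for i, row in df.iterrows():
        rowno = int(i) + 2  # 1-based, counting the header line
        raw_count = row[cols["haploid_autosomes"]]
        try:
            count = int(str(raw_count).strip())
            if float(str(raw_count).strip()) != count:
                raise ValueError
        except (TypeError, ValueError):
            raise KaryotypeValidationError(
                f"row {rowno}: haploid autosome count {raw_count!r} "
                "is not an integer"
            ) from None
        try:
            scs = normalize_scs(row[cols["scs"]])
            rec = KaryotypeRecord(
                species=normalize_species(row[cols["species"]]),
                haploid_autosomes=count,
                scs=scs,
                source=(str(row[source_col]) if has_source else None),
            )
        except KaryotypeValidationError as exc:
            raise KaryotypeValidationError(f"row {rowno}: {exc}") from None
        records.append(rec)
    return records


def write_karyotype_table(
    records: Sequence[KaryotypeRecord], path: str | Path
) -> None:
    """Write records as CSV; exact round-trip partner of
    :func:`read_karyotype_table`."""
    df = pd.DataFrame(
        {
            "species": [r.species for r in records],
            "haploid_autosomes": [r.haploid_autosomes for r in records],
            "scs": [r.scs for r in records],
        }
    )
    if any(r.source for r in records):
        df["source"] = [r.source or "" for r in records]
    df.to_csv(path, index=False)


def read_trees(path: str | Path) -> list[Phylogeny]:
    """Read all trees from a Newick or Nexus file (schema auto-detected)."""
    path = Path(path)
    text = path.read_text()
    schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        tree_list = dendropy.TreeList.get(data=text, schema=schema)
    except Exception as exc:
        raise TreeFormatError(f"could not parse {path} as {schema}: {exc}")
    trees: list[Phylogeny] = []
    for i, t in enumerate(tree_list):
        try:
            trees.append(Phylogeny(t))
        except TreeFormatError as exc:
            raise TreeFormatError(f"tree {i}: {exc}") from None
    if not trees:
        raise TreeFormatError(f"no trees found in {path}")
    logger.info("read %d tree(s) from %s", len(trees), path)
    return trees


def match_tips(
    trees: Sequence[Phylogeny], records: Sequence[KaryotypeRecord]
) -> list[MatchedDataset]:
    """Join each tree with the karyotype records, pruning uncovered tips.

    Species names match exactly after whitespace/underscore normalization.
    A tree sharing no taxa with the records is a hard error.
    """
    if not trees or not records:
        raise ValueError("match_tips requires non-empty trees and records")
    by_species: dict[str, list[KaryotypeRecord]] = {}
    for rec in records:
        by_species.setdefault(normalize_species(rec.species), []).append(rec)

    out: list[MatchedDataset] = []
    for i, tree in enumerate(trees):
        tips = tree.tip_labels
        matched = [t for t in tips if t in by_species]
        if not matched:
            raise ValueError(
                f"tree {i}: no overlap between tip labels and record species"
            )
        pruned = sorted(set(tips) - set(matched))
        unmatched = sorted(set(by_species) - set(tips))
        if pruned:
            logger.info(
                "tree %d: pruned %d tip(s) without karyotype records: %s",
                i,
                len(pruned),
                ", ".join(pruned),
            )
        if unmatched:
            logger.debug(
                "tree %d: %d record species not on the tree",
                i,
                len(unmatched),
            )
        phylo = tree if not pruned else tree.prune_to(matched)
        out.append(
            MatchedDataset(
                phylogeny=phylo,
                records_by_tip={t: list(by_species[t]) for t in matched},
                pruned_tips=pruned,
                unmatched_species=unmatched,
            )
        )
    return out


def resolve_tip_states(
    dataset: MatchedDataset, rng_seed: int | np.random.Generator
) -> dict[str, tuple[int, str]]:
    """Pick one (count, scs) per tip, uniformly among that tip's records.

    Tips with several conflicting records are resolved by an independent
    uniform draw per tip; the draw is reproducible under the seed.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    resolved: dict[str, tuple[int, str]] = {}
    for tip in sorted(dataset.records_by_tip):
        recs = dataset.records_by_tip[tip]
        rec = recs[0] if len(recs) == 1 else recs[int(rng.integers(len(recs)))]
        resolved[tip] = (rec.haploid_autosomes, rec.scs)
    return resolved
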