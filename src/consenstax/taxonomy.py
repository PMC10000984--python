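"""NCBI-style taxonomy: taxdump parsing, lineages, LCA and fractional consensus.

The taxonomy is a rooted tree of taxid nodes (the root is its own parent).
Three queries drive the rest of the toolkit:

* ``lineage`` — the root-to-node path;
* ``lca`` — the deepest node shared by every lineage of a taxid set;
* ``consensus`` — the deepest node whose subtree covers at least a fraction
  ``level`` of a vote list.  With ``level > 0.5`` at most one child can
  qualify at each depth, so the result is unique; ``level == 1.0``
  degenerates to the LCA.

Merged taxids (merged.dmp) are remapped silently with a log record; unknown
(deleted) taxids raise :class:`UnknownTaxidError`.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "TaxNode",
    "Taxonomy",
    "TaxonomyError",
    "TaxdumpParseError",
    "TaxonomyIntegrityError",
    "UnknownTaxidError",
    "load_taxdump",
]


class TaxonomyError(Exception):
    """Base class for taxonomy errors."""


class TaxdumpParseError(TaxonomyError):
    """A dmp file line did not follow the NCBI dialect."""


class TaxonomyIntegrityError(TaxonomyError):
    """The node table violates the tree invariants."""


class UnknownTaxidError(TaxonomyError, KeyError):
    """A taxid resolves to neither a node nor a merged record."""


@dataclass(frozen=True)
class TaxNode:
    """One node of the taxonomy tree.

    The root is encoded NCBI-style as its own parent.  ``rank`` is a free
    label ("species", "genus", "no rank", ...); "no rank" nodes stay in
    lineages and are simply skipped by rank-based queries.
    """

    taxid: int
    parent: int
    rank: str
    name: str


# NCBI dmp dialect: fields separated by "\t|\t", lines terminated by "\t|".
_FIELD_SEP = "\t|\t"


def _parse_dmp_line(line: str, path: str, lineno: int, min_fields: int) -> list[str]:
    raw = line.rstrip("\n")
    if raw.endswith("\t|"):
        raw = raw[: -len("\t|")]
    fields = raw.split(_FIELD_SEP)
    if len(fields) < min_fields:
        raise TaxdumpParseError(
            f"{path}:{lineno}: expected at least {min_fields} fields, got {len(fields)}"
        )
    return fields


class Taxonomy:
    """A validated taxid tree supporting lineage, LCA and consensus queries."""

    def __init__(
        self,
        nodes: Mapping[int, TaxNode],
        merged: Mapping[int, int] | None = None,
    ) -> None:
        self.nodes: dict[int, TaxNode] = dict(nodes)
        self.merged: dict[int, int] = dict(merged or {})
        self._validate()
        self._depth_cache: dict[int, int] = {}

    # -- construction / validation ------------------------------------

    def _validate(self) -> None:
        roots = [n.taxid for n in self.nodes.values() if n.parent == n.taxid]
        if len(roots) != 1:
            raise TaxonomyIntegrityError(
                f"expected exactly one root, found {len(roots)}: {roots[:5]}"
            )
        self._root = roots[0]
        for node in self.nodes.values():
            if node.parent not in self.nodes:
                raise TaxonomyIntegrityError(
                    f"taxid {node.taxid} has unresolvable parent {node.parent}"
                )
        for old, new in self.merged.items():
            if new not in self.nodes:
                raise TaxonomyIntegrityError(
                    f"merged taxid {old} points to unknown taxid {new}"
                )
        # no cycles: every parent walk must hit the root in < |nodes| steps
        n = len(self.nodes)
        for taxid in self.nodes:
            cur, steps = taxid, 0
            while cur != self._root:
                cur = self.nodes[cur].parent
                steps += 1
                if steps >= n:
                    raise TaxonomyIntegrityError(f"cycle detected at taxid {taxid}")

    @property
    def root(self) -> TaxNode:
        return self.nodes[self._root]

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes or taxid in self.merged

    # -- lookups -------------------------------------------------------

    def resolve(self, taxid: int) -> int:
        """Canonical taxid: remap merged ids (logged), raise on unknown."""
        if taxid in self.nodes:
            return taxid
        if taxid in self.merged:
            new = self.merged[taxid]
            logger.info("taxid %d merged into %d", taxid, new)
            return new
        raise UnknownTaxidError(taxid)

    def __getitem__(self, taxid: int) -> TaxNode:
        return self.nodes[self.resolve(taxid)]

    def name(self, taxid: int) -> str:
        return self[taxid].name

    def rank(self, taxid: int) -> str:
        return self[taxid].rank

    def parent(self, taxid: int) -> TaxNode:
        return self.nodes[self[taxid].parent]

    def children(self, taxid: int) -> list[int]:
        taxid = self.resolve(taxid)
        return [
            n.taxid
            for n in self.nodes.values()
            if n.parent == taxid and n.taxid != taxid
        ]

    # -- tree queries ---------------------------------------------------

    def lineage(self, taxid: int) -> list[TaxNode]:
        """Root-to-node path, both endpoints included."""
        cur = self.resolve(taxid)
        path = [self.nodes[cur]]
        while cur != self._root:
            cur = self.nodes[cur].parent
            path.append(self.nodes[cur])
        path.reverse()
        return path

    def depth(self, taxid: int) -> int:
        """Number of edges from the root (root has depth 0)."""
        taxid = self.resolve(taxid)
        if taxid not in self._depth_cache:
            self._depth_cache[taxid] = len(self.lineage(taxid)) - 1
        return self._depth_cache[taxid]

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """The lineage node carrying ``rank``, or None if the lineage skips it."""
        for node in self.lineage(taxid):
            if node.rank == rank:
                return node.taxid
        return None

    def lca(self, taxids: Sequence[int]) -> int:
        """Last common ancestor: deepest node on every input lineage."""
        if not taxids:
            raise ValueError("lca() requires a non-empty taxid list")
        lineages = [self.lineage(t) for t in taxids]
        shortest = min(len(l) for l in lineages)
        last = lineages[0][0].taxid
        for i in range(shortest):
            tid = lineages[0][i].taxid
            if all(l[i].taxid == tid for l in lineages[1:]):
                last = tid
            else:
                break
        return last

    def consensus(self, taxids: Sequence[int], level: float) -> int:
        """Deepest node covered by at least ``level`` of the vote lineages.

        Votes count with multiplicity; dereplication to unique taxa is the
        caller's concern.  ``level`` must lie in (0.5, 1.0]: the strict
        majority guarantees that at most one child qualifies per depth, so
        the qualifying nodes form a root chain and the deepest is unique.
        """
        if not taxids:
            raise ValueError("consensus() requires a non-empty taxid list")
        if not 0.5 < level <= 1.0:
            raise ValueError(f"consensus level must be in (0.5, 1.0], got {level}")
        n = len(taxids)
        cover: Counter[int] = Counter()
        for t in taxids:
            for node in self.lineage(t):
                cover[node.taxid] += 1
        # descend from the root through the unique qualifying child
        cur = self._root
        child_of: dict[int, list[int]] = {}
        for tid in cover:
            p = self.nodes[tid].parent
            if p != tid:
                child_of.setdefault(p, []).append(tid)
        while True:
            nxt = [
                c for c in child_of.get(cur, []) if cover[c] / n >= level
            ]
            if not nxt:
                return cur
            # level > 0.5 makes a second qualifying sibling impossible
            cur = nxt[0]


def _read_nodes(nodes_path: Path) -> dict[int, tuple[int, str]]:
    out: dict[int, tuple[int, str]] = {}
    with open(nodes_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _parse_dmp_line(line, str(nodes_path), lineno, 3)
            try:
                taxid, parent = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise TaxdumpParseError(
                    f"{nodes_path}:{lineno}: non-integer taxid field"
                ) from exc
            out[taxid] = (parent, fields[2].strip())
    return out


def _read_names(names_path: Path) -> dict[int, str]:
    out: dict[int, str] = {}
    with open(names_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _parse_dmp_line(line, str(names_path), lineno, 4)
            if fields[3].strip() != "scientific name":
                continue  # other name classes ignored
            try:
                taxid = int(fields[0])
            except ValueError as exc:
                raise TaxdumpParseError(
                    f"{names_path}:{lineno}: non-integer taxid field"
                ) from exc
            out[taxid] = fields[1].strip()
    return out


def _read_merged(merged_path: Path) -> dict[int, int]:
    out: dict[int, int] = {}
    with open(merged_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _parse_dmp_line(line, str(merged_path), lineno, 2)
            try:
                out[int(fields[0])] = int(fields[1])
            except ValueError as exc:
                raise TaxdumpParseError(
                    f"{merged_path}:{lineno}: non-integer taxid field"
                ) from exc
    return out


def load_taxdump(
    nodes_path: str | Path,
    names_path: str | Path,
    merged_path: str | Path | None = None,
) -> Taxonomy:
    """Load nodes.dmp / names.dmp (and optionally merged.dmp) into a Taxonomy.

    Files follow the NCBI dmp dialect: fields separated by ``\\t|\\t``,
    lines terminated by ``\\t|``.  Only "scientific name" entries of the
    names file are used; nodes without one get an empty name.
    """
    nodes_raw = _read_nodes(Path(nodes_path))
    names = _read_names(Path(names_path))
    merged = _read_merged(Path(merged_path)) if merged_path else {}
    nodes = {
        taxid: TaxNode(taxid, parent, rank, names.get(taxid, ""))
        for taxid, (parent, rank) in nodes_raw.items()
    }
    return Taxonomy(nodes, merged)
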