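"""Rank-labelled viral taxonomy: a forest of order→family→genus→species chains.

The tree supports the ancestor queries used by lowest-common-ancestor (LCA)
read assignment and by rank roll-up when building taxon-by-sample tables, and
renders lineage strings in the ``o__X;f__Y;g__Z;s__W`` dialect, where an
undetermined name appears as e.g. ``g__u`` and an unnamed one as ``g__n``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .constants import (
    RANK_INDEX,
    RANK_PREFIX,
    RANKS,
    SUBJECT_CLASSES,
    UNDETERMINED_NAME,
    UNNAMED_NAME,
)
from .errors import TaxonomyError, UnknownSubjectError


@dataclass(frozen=True, slots=True)
class TaxonNode:
    """One taxon: id, display name, rank, and parent (``None`` for roots)."""

    taxon_id: str
    name: str
    rank: str
    parent_id: Optional[str]

    @property
    def undetermined(self) -> bool:
        return self.name == UNDETERMINED_NAME

    @property
    def unnamed(self) -> bool:
        return self.name == UNNAMED_NAME


class TaxonomyTree:
    """A validated forest of rank-ordered taxa plus a subject→taxon map.

    Parameters
    ----------
    nodes
        Iterable of :class:`TaxonNode`. Parent links must form a forest in
        which each child's rank is exactly one step deeper than its parent's
        (order→family→genus→species).
    subject_map
        Mapping ``subject_id -> (taxon_id, subject_class)`` linking reference
        sequences to taxa, with the reference class (prophage, bacteriophage,
        eukaryotic_virus, or bacterial) used downstream for partitioning.
    """

    def __init__(
        self,
        nodes: Iterable[TaxonNode],
        subject_map: Optional[Mapping[str, tuple[str, str]]] = None,
    ) -> None:
        self.nodes: dict[str, TaxonNode] = {}
        for node in nodes:
            if node.taxon_id in self.nodes:
                raise TaxonomyError(f"duplicate taxon_id {node.taxon_id!r}")
            if node.rank not in RANKS:
                raise TaxonomyError(
                    f"taxon {node.taxon_id!r} has unknown rank {node.rank!r}"
                )
            self.nodes[node.taxon_id] = node
        self._validate_structure()
        self.subject_map: dict[str, tuple[str, str]] = {}
        for subject_id, (taxon_id, subject_class) in (subject_map or {}).items():
            if taxon_id not in self.nodes:
                raise TaxonomyError(
                    f"subject {subject_id!r} mapped to absent taxon {taxon_id!r}"
                )
            if subject_class not in SUBJECT_CLASSES:
                raise TaxonomyError(
                    f"subject {subject_id!r} has unknown class {subject_class!r}"
                )
            self.subject_map[subject_id] = (taxon_id, subject_class)
        self._depth_cache: dict[str, int] = {}

    def _validate_structure(self) -> None:
        for node in self.nodes.values():
            if node.parent_id is None:
                continue
            if node.parent_id == node.taxon_id:
                raise TaxonomyError(f"taxon {node.taxon_id!r} is its own parent")
            parent = self.nodes.get(node.parent_id)
            if parent is None:
                raise TaxonomyError(
                    f"taxon {node.taxon_id!r} has missing parent {node.parent_id!r}"
                )
            if RANK_INDEX[node.rank] != RANK_INDEX[parent.rank] + 1:
                raise TaxonomyError(
                    f"taxon {node.taxon_id!r} ({node.rank}) cannot descend from "
                    f"{parent.taxon_id!r} ({parent.rank})"
                )
        # Cycle check: walk each node to a root, bounded by the rank chain the
        # rank-order check already enforces, but keep an explicit guard.
        for start in self.nodes:
            seen = set()
            current: Optional[str] = start
            while current is not None:
                if current in seen:
                    raise TaxonomyError(f"cycle detected at taxon {current!r}")
                seen.add(current)
                current = self.nodes[current].parent_id

    # -- queries -----------------------------------------------------------

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def rank_of(self, taxon_id: str) -> str:
        return self._node(taxon_id).rank

    def _node(self, taxon_id: str) -> TaxonNode:
        try:
            return self.nodes[taxon_id]
        except KeyError:
            raise TaxonomyError(f"unknown taxon {taxon_id!r}") from None

    def ancestors(self, taxon_id: str) -> list[str]:
        """Taxon ids from ``taxon_id`` itself up to its root, in that order."""
        path = []
        current: Optional[str] = taxon_id
        while current is not None:
            node = self._node(current)
            path.append(current)
            current = node.parent_id
        return path

    def depth(self, taxon_id: str) -> int:
        """Edges between ``taxon_id`` and its root (root depth is 0)."""
        cached = self._depth_cache.get(taxon_id)
        if cached is None:
            cached = len(self.ancestors(taxon_id)) - 1
            self._depth_cache[taxon_id] = cached
        return cached

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> Optional[str]:
        """The ancestor-or-self of ``taxon_id`` at ``rank``, or ``None`` if the
        taxon is resolved shallower than ``rank``."""
        if rank not in RANKS:
            raise TaxonomyError(f"unknown rank {rank!r}")
        for ancestor in self.ancestors(taxon_id):
            if self.nodes[ancestor].rank == rank:
                return ancestor
        return None

    def lca(self, taxon_ids: Iterable[str]) -> Optional[str]:
        """Deepest node ancestral to (or equal to) every given taxon.

        Returns ``None`` when the taxa share no ancestor (different roots of
        the forest), which downstream becomes an UNDETERMINED assignment.
        """
        ids = list(taxon_ids)
        if not ids:
            raise TaxonomyError("lca of an empty taxon set is undefined")
        common = set(self.ancestors(ids[0]))
        for taxon_id in ids[1:]:
            common &= set(self.ancestors(taxon_id))
            if not common:
                return None
        return max(common, key=self.depth)

    def taxon_for_subject(self, subject_id: str) -> str:
        try:
            return self.subject_map[subject_id][0]
        except KeyError:
            raise UnknownSubjectError(f"unknown subject {subject_id!r}") from None

    def class_of_subject(self, subject_id: str) -> str:
        try:
            return self.subject_map[subject_id][1]
        except KeyError:
            raise UnknownSubjectError(f"unknown subject {subject_id!r}") from None

    # -- rendering ---------------------------------------------------------

    def lineage_label(self, taxon_id: str) -> str:
        """Semicolon-joined rank-prefixed lineage from root down to the taxon,
        e.g. ``o__Caudovirales;f__Siphoviridae;g__u;s__Streptococcus phage X``.
        """
        parts = []
        for ancestor in reversed(self.ancestors(taxon_id)):
            node = self.nodes[ancestor]
            if node.undetermined:
                name = "u"
            elif node.unnamed:
                name = "n"
            else:
                name = node.name
            parts.append(RANK_PREFIX[node.rank] + name)
        return ";".join(parts)

    def species_ids(self) -> list[str]:
        return [t for t, n in self.nodes.items() if n.rank == "species"]
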