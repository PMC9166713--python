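"""Glycan structures, condensed-notation parsing and binding-motif mining.

A glycan is modelled as a rooted tree of monosaccharide residues.  The root
is the reducing end; edges point from a child residue toward the residue it
is glycosidically linked to, and carry the anomeric configuration (``a``,
``b`` or ``?`` when unknown) together with the two linkage carbons.  The
text dialect is the familiar condensed linear notation, e.g.::

    Galb1-3GlcNAcb1-2Mana1-3Man
    Mana1-3(Mana1-6)Manb1-4GlcNAc-Sp12

The rightmost residue (before an optional ``-SpN`` spacer) is the root, and
a parenthesized branch attaches to the residue immediately to its right.

A binding motif is itself a small glycan tree.  ``contains_motif`` decides
sub-tree embedding (residue codes, substituents, anomeric configuration and
both linkage carbons must all agree; an edge whose anomeric configuration is
unknown in the *data* matches any motif configuration).  ``mine_motifs``
enumerates every connected sub-glycan of a set of array binders, scores each
candidate by the contrast between its frequency among binders and among
non-binders, and reports the maximal motifs per score tier.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

__all__ = [
    "MONOSACCHARIDES",
    "GlycanParseError",
    "Residue",
    "Linkage",
    "GlycanStructure",
    "GlycanMotif",
    "parse_glycan",
    "contains_motif",
    "enumerate_subglycans",
    "mine_motifs",
]

#: Recognised monosaccharide codes.  Longest-match tokenization, so codes
#: that are prefixes of other codes (Glc / GlcA / GlcNAc) are safe.
MONOSACCHARIDES: tuple[str, ...] = (
    "GlcNAc",
    "GalNAc",
    "Neu5Ac",
    "Neu5Gc",
    "GlcA",
    "IdoA",
    "Glc",
    "Gal",
    "Man",
    "Fuc",
    "Xyl",
    "Rha",
    "Ara",
    "Kdn",
)

_CODES_BY_LENGTH = tuple(sorted(MONOSACCHARIDES, key=len, reverse=True))
_SUBSTITUENT_RE = re.compile(r"\d[SP]")
_LINK_RE = re.compile(r"([ab?])(\d)-(\d)")
_SPACER_RE = re.compile(r"-Sp\d+$")


class GlycanParseError(ValueError):
    """Raised when a condensed glycan string cannot be parsed."""


@dataclass(frozen=True)
class Residue:
    """A monosaccharide, optionally decorated (e.g. sulfation ``6S``)."""

    code: str
    substituents: tuple[str, ...] = ()

    def __str__(self) -> str:
        return self.code + "".join(self.substituents)


@dataclass(frozen=True)
class Linkage:
    """Glycosidic linkage from a child residue to its parent."""

    anomeric: str  # 'a', 'b' or '?' (unknown)
    child_carbon: int
    parent_carbon: int

    def __str__(self) -> str:
        return f"{self.anomeric}{self.child_carbon}-{self.parent_carbon}"


class GlycanStructure:
    """Rooted tree of monosaccharide residues.

    Parameters
    ----------
    nodes:
        Mapping of node id to :class:`Residue`.
    parents:
        Mapping of child node id to ``(parent_id, Linkage)``; the root has
        no entry.
    root_id:
        Id of the reducing-end residue.

    Equality and hashing use the canonical serialization, so structures are
    compared up to node renumbering.
    """

    __slots__ = ("nodes", "parents", "root_id", "_children", "_canonical")

    def __init__(
        self,
        nodes: dict[int, Residue],
        parents: dict[int, tuple[int, Linkage]],
        root_id: int,
    ) -> None:
        if not nodes:
            raise ValueError("a glycan must contain at least one residue")
        if root_id not in nodes:
            raise ValueError("root_id not among nodes")
        if root_id in parents:
            raise ValueError("root must not have a parent")
        if set(parents) != set(nodes) - {root_id}:
            raise ValueError("every non-root node needs exactly one parent")
        children: dict[int, list[tuple[int, Linkage]]] = {nid: [] for nid in nodes}
        for child, (parent, link) in parents.items():
            if parent not in nodes:
                raise ValueError(f"parent {parent} of node {child} unknown")
            children[parent].append((child, link))
        # reachability from root; with unique parents this certifies a tree
        seen = {root_id}
        stack = [root_id]
        while stack:
            for child, _ in children[stack.pop()]:
                if child in seen:
                    raise ValueError("cycle detected")
                seen.add(child)
                stack.append(child)
        if seen != set(nodes):
            raise ValueError("nodes unreachable from root")
        self.nodes = dict(nodes)
        self.parents = dict(parents)
        self.root_id = root_id
        self._children = children
        self._canonical: str | None = None

    # -- basic queries ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def children(self, node_id: int) -> list[tuple[int, Linkage]]:
        return list(self._children[node_id])

    @property
    def edges(self) -> list[tuple[int, int, Linkage]]:
        """``(child, parent, linkage)`` triples."""
        return [(c, p, l) for c, (p, l) in self.parents.items()]

    # -- canonical form ---------------------------------------------------

    def serialize(self) -> str:
        """Canonical condensed-notation text.

        Children of a node are ordered by (parent carbon, child residue
        code, anomeric, child carbon, serialized subtree); the first child
        is written inline as the backbone, the rest in parentheses.  The
        result round-trips through :func:`parse_glycan`.
        """
        if self._canonical is None:
            memo: dict[int, str] = {}

            def ser(nid: int) -> str:
                if nid in memo:
                    return memo[nid]
                kids = sorted(
                    self._children[nid],
                    key=lambda cl: (
                        cl[1].parent_carbon,
                        self.nodes[cl[0]].code,
                        cl[1].anomeric,
                        cl[1].child_carbon,
                        ser(cl[0]),
                    ),
                )
                parts: list[str] = []
                for k, (child, link) in enumerate(kids):
                    piece = ser(child) + str(link)
                    parts.append(piece if k == 0 else f"({piece})")
                parts.append(str(self.nodes[nid]))
                memo[nid] = "".join(parts)
                return memo[nid]

            self._canonical = ser(self.root_id)
        return self._canonical

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlycanStructure):
            return NotImplemented
        return self.serialize() == other.serialize()

    def __hash__(self) -> int:
        return hash(self.serialize())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GlycanStructure({self.serialize()!r})"


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _tokenize(text: str) -> list[tuple]:
    tokens: list[tuple] = []
    pos = 0
    n = len(text)
    while pos < n:
        c = text[pos]
        if c == "(":
            tokens.append(("LPAR", pos))
            pos += 1
            continue
        if c == ")":
            tokens.append(("RPAR", pos))
            pos += 1
            continue
        m = _LINK_RE.match(text, pos)
        if m:
            tokens.append(
                ("LINK", pos, Linkage(m.group(1), int(m.group(2)), int(m.group(3))))
            )
            pos = m.end()
            continue
        if c in "ab?" and pos + 1 < n and text[pos + 1].isdigit():
            raise GlycanParseError(
                f"malformed linkage at position {pos}: expected e.g. 'b1-3'"
            )
        for code in _CODES_BY_LENGTH:
            if text.startswith(code, pos):
                pos += len(code)
                subs = []
                while True:
                    sm = _SUBSTITUENT_RE.match(text, pos)
                    if sm is None:
                        break
                    subs.append(sm.group(0))
                    pos = sm.end()
                tokens.append(("RES", pos, Residue(code, tuple(sorted(subs)))))
                break
        else:
            bad = re.match(r"[A-Za-z0-9?]+", text[pos:])
            token = bad.group(0) if bad else text[pos]
            raise GlycanParseError(
                f"unknown monosaccharide or malformed token {token!r} at position {pos}"
            )
    return tokens


def parse_glycan(text: str) -> GlycanStructure:
    """Parse a condensed glycan string into a :class:`GlycanStructure`.

    The rightmost residue is the root (reducing end).  A trailing spacer
    suffix such as ``-Sp12`` is stripped.  Unknown residue codes, unbalanced
    parentheses and malformed linkages raise :class:`GlycanParseError`.
    """
    if not isinstance(text, str) or not text.strip():
        raise GlycanParseError("empty glycan string")
    text = _SPACER_RE.sub("", text.strip())
    tokens = _tokenize(text)

    nodes: dict[int, Residue] = {}
    parents: dict[int, tuple[int, Linkage]] = {}
    counter = itertools.count()

    def parse_chain(pos: int, in_branch: bool) -> tuple[int, Linkage | None, int]:
        """Parse a chain; return (chain root id, trailing link or None, new pos)."""
        pending: list[tuple[int, Linkage]] = []
        while pos < len(tokens):
            kind = tokens[pos][0]
            if kind == "LPAR":
                child, link, pos = parse_chain(pos + 1, in_branch=True)
                assert link is not None
                pending.append((child, link))
            elif kind == "RES":
                nid = next(counter)
                nodes[nid] = tokens[pos][2]
                for c, l in pending:
                    parents[c] = (nid, l)
                pending = []
                pos += 1
                if pos < len(tokens) and tokens[pos][0] == "LINK":
                    link = tokens[pos][2]
                    pos += 1
                    if in_branch and pos < len(tokens) and tokens[pos][0] == "RPAR":
                        return nid, link, pos + 1
                    pending = [(nid, link)]
                else:
                    if in_branch:
                        if pos >= len(tokens):
                            raise GlycanParseError(
                                "unbalanced '(': branch never closed"
                            )
                        raise GlycanParseError(
                            "branch must end with a linkage before ')' near "
                            f"position {tokens[pos][1]}"
                        )
                    if pos < len(tokens):
                        raise GlycanParseError(
                            f"unexpected trailing token at position {tokens[pos][1]}"
                        )
                    return nid, None, pos
            elif kind == "RPAR":
                raise GlycanParseError(
                    f"unbalanced ')' at position {tokens[pos][1]}"
                )
            else:  # LINK with no residue before it
                raise GlycanParseError(
                    f"malformed linkage placement at position {tokens[pos][1]}"
                )
        if in_branch:
            raise GlycanParseError("unbalanced '(': branch never closed")
        raise GlycanParseError("glycan string ends without a root residue")

    root_id, _, _ = parse_chain(0, in_branch=False)
    return GlycanStructure(nodes, parents, root_id)


# ---------------------------------------------------------------------------
# sub-tree embedding
# ---------------------------------------------------------------------------


def _edges_match(data_link: Linkage, motif_link: Linkage) -> bool:
    if data_link.child_carbon != motif_link.child_carbon:
        return False
    if data_link.parent_carbon != motif_link.parent_carbon:
        return False
    # an under-specified array structure ('?') matches any motif configuration
    return data_link.anomeric == motif_link.anomeric or data_link.anomeric == "?"


def contains_motif(glycan: GlycanStructure, motif: GlycanStructure) -> bool:
    """True iff *motif* embeds injectively somewhere inside *glycan*.

    The embedding must preserve residue codes and substituents, parent/child
    relations, anomeric configuration and both carbon positions of every
    motif edge.  The motif root may map to any glycan node (unanchored
    matching).
    """
    memo: dict[tuple[int, int], bool] = {}

    def embed(gid: int, mid: int) -> bool:
        key = (gid, mid)
        if key in memo:
            return memo[key]
        ok = False
        if glycan.nodes[gid] == motif.nodes[mid]:
            mkids = motif.children(mid)
            if not mkids:
                ok = True
            else:
                gkids = glycan.children(gid)
                if len(gkids) >= len(mkids):
                    def assign(k: int, used: int) -> bool:
                        if k == len(mkids):
                            return True
                        mc, ml = mkids[k]
                        for idx, (gc, gl) in enumerate(gkids):
                            if used & (1 << idx):
                                continue
                            if _edges_match(gl, ml) and embed(gc, mc):
                                if assign(k + 1, used | (1 << idx)):
                                    return True
                        return False

                    ok = assign(0, 0)
        memo[key] = ok
        return ok

    return any(embed(gid, motif.root_id) for gid in glycan.nodes)


# ---------------------------------------------------------------------------
# connected sub-glycan enumeration and motif mining
# ---------------------------------------------------------------------------


def _extract(glycan: GlycanStructure, node_set: frozenset[int], root: int) -> GlycanStructure:
    nodes = {nid: glycan.nodes[nid] for nid in node_set}
    parents = {
        nid: glycan.parents[nid]
        for nid in node_set
        if nid != root and glycan.parents[nid][0] in node_set
    }
    return GlycanStructure(nodes, parents, root)


def enumerate_subglycans(
    glycan: GlycanStructure, max_size: int
) -> dict[str, GlycanStructure]:
    """All connected sub-glycans of *glycan* with at most *max_size* nodes.

    Keys are canonical serializations; each sub-glycan keeps the residue and
    linkage labels of its parent structure.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")

    def connected_sets(v: int, budget: int) -> list[frozenset[int]]:
        opts: list[frozenset[int]] = [frozenset([v])]
        for child, _ in glycan.children(v):
            extended: list[frozenset[int]] = []
            for s in opts:
                extended.append(s)
                room = budget - len(s)
                if room > 0:
                    for t in connected_sets(child, room):
                        if len(s) + len(t) <= budget:
                            extended.append(s | t)
            opts = extended
        return opts

    out: dict[str, GlycanStructure] = {}
    for v in glycan.nodes:
        for node_set in connected_sets(v, max_size):
            sub = _extract(glycan, node_set, v)
            out.setdefault(sub.serialize(), sub)
    return out


@dataclass(frozen=True)
class GlycanMotif:
    """A candidate conserved binding determinant.

    ``score = binder_coverage - nonbinder_frequency``: a transparent
    contrast between how often the sub-glycan occurs among bound versus
    unbound glycans.
    """

    pattern: GlycanStructure
    binder_coverage: float
    nonbinder_frequency: float
    score: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "score", self.binder_coverage - self.nonbinder_frequency
        )


def mine_motifs(
    binders: list[GlycanStructure] | set[GlycanStructure],
    nonbinders: list[GlycanStructure] | set[GlycanStructure],
    max_size: int,
) -> list[GlycanMotif]:
    """Mine conserved sub-glycan motifs separating binders from non-binders.

    Enumerates every connected sub-glycan (up to *max_size* nodes) occurring
    in at least one binder, computes exact occurrence fractions with
    :func:`contains_motif`, and returns motifs sorted by (score desc, size
    desc, canonical text asc).  Within the ranking, a motif is dropped when
    a strict super-motif scores at least as well, so only maximal motifs per
    score tier are reported.
    """
    binders = sorted(set(binders), key=GlycanStructure.serialize)
    nonbinders = sorted(set(nonbinders), key=GlycanStructure.serialize)
    if not binders:
        raise ValueError("binder set must be non-empty")
    if max_size < 1:
        raise ValueError("max_size must be >= 1")

    candidates: dict[str, GlycanStructure] = {}
    for g in binders:
        candidates.update(enumerate_subglycans(g, max_size))

    motifs: list[GlycanMotif] = []
    for sub in candidates.values():
        cov = sum(contains_motif(g, sub) for g in binders) / len(binders)
        freq = (
            sum(contains_motif(g, sub) for g in nonbinders) / len(nonbinders)
            if nonbinders
            else 0.0
        )
        motifs.append(GlycanMotif(sub, cov, freq))

    motifs.sort(key=lambda m: (-m.score, -len(m.pattern), m.pattern.serialize()))

    kept: list[GlycanMotif] = []
    for m in motifs:
        dominated = any(
            other.score >= m.score
            and len(other.pattern) > len(m.pattern)
            and contains_motif(other.pattern, m.pattern)
            for other in motifs
            if other is not m
        )
        if not dominated:
            kept.append(m)
    return kept
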