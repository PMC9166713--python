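"""Independent oracles used to cross-check the implementation.

Each oracle follows a different algorithmic route from the code it checks:
exhaustive enumeration, brute-force recursion, or a literal step-by-step
transcription of a stated rule.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np

from lectiscope.glycan import GlycanStructure
from lectiscope.identity import global_align_identity


# ---------------------------------------------------------------------------
# alignment score by exhaustive recursion (tiny sequences only)
# ---------------------------------------------------------------------------


def brute_force_best_score(a, b, sub, aa_index, gap_open, gap_extend):
    """Maximum global alignment score over all alignments, by recursion.

    States: 0 = coming from a pairing/start, 1 = extending a gap in `a`,
    2 = extending a gap in `b`.
    """
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i, j, state):
        if i == len(a) and j == len(b):
            return 0.0
        best = -float("inf")
        if i < len(a) and j < len(b):
            best = max(best, sub[aa_index[a[i]], aa_index[b[j]]] + rec(i + 1, j + 1, 0))
        if j < len(b):  # gap in a
            cost = gap_extend if state == 1 else gap_open
            best = max(best, -cost + rec(i, j + 1, 1))
        if i < len(a):  # gap in b
            cost = gap_extend if state == 2 else gap_open
            best = max(best, -cost + rec(i + 1, j, 2))
        return best

    return rec(0, 0, 0)


# ---------------------------------------------------------------------------
# greedy clustering, transcribed step by step from the stated rule
# ---------------------------------------------------------------------------


def greedy_cluster_oracle(sequences, threshold):
    """Literal transcription of the ordered greedy centroid rule."""
    ordered = sorted(sequences, key=lambda it: (-len(it[1]), it[0]))
    centroids = []  # (accession, sequence)
    members = {}  # centroid accession -> [member accessions]
    for acc, seq in ordered:
        best = None
        best_identity = None
        for cacc, cseq in centroids:  # creation order; strict > keeps earliest tie
            ident = global_align_identity(seq, cseq).identity
            if best_identity is None or ident > best_identity:
                best, best_identity = cacc, ident
        if best is not None and best_identity >= threshold:
            members[best].append(acc)
        else:
            centroids.append((acc, seq))
            members[acc] = [acc]
    return {c: tuple(m) for c, m in members.items()}


# ---------------------------------------------------------------------------
# rarefaction by exhaustive subset enumeration
# ---------------------------------------------------------------------------


def exhaustive_rarefaction(block: np.ndarray, n: int) -> float:
    """Average richness over all n-sample subsets of a Boolean matrix."""
    N = block.shape[1]
    total = Fraction(0)
    count = 0
    for subset in itertools.combinations(range(N), n):
        total += int(block[:, list(subset)].any(axis=1).sum())
        count += 1
    return float(Fraction(total, count))


# ---------------------------------------------------------------------------
# sub-tree embedding by exhaustive injective mapping
# ---------------------------------------------------------------------------


def _link_ok(data_link, motif_link):
    return (
        data_link.child_carbon == motif_link.child_carbon
        and data_link.parent_carbon == motif_link.parent_carbon
        and (data_link.anomeric == motif_link.anomeric or data_link.anomeric == "?")
    )


def embeds_brute_force(glycan: GlycanStructure, motif: GlycanStructure) -> bool:
    """Check embedding by trying every injective node mapping."""
    m_nodes = list(motif.nodes)
    g_nodes = list(glycan.nodes)
    for image in itertools.permutations(g_nodes, len(m_nodes)):
        mapping = dict(zip(m_nodes, image))
        ok = True
        for mid in m_nodes:
            if glycan.nodes[mapping[mid]] != motif.nodes[mid]:
                ok = False
                break
        if not ok:
            continue
        for child, (parent, mlink) in motif.parents.items():
            gchild = mapping[child]
            if gchild not in glycan.parents:
                ok = False
                break
            gparent, glink = glycan.parents[gchild]
            if gparent != mapping[parent] or not _link_ok(glink, mlink):
                ok = False
                break
        if ok:
            return True
    return False


# ---------------------------------------------------------------------------
# connected sub-tree enumeration by subset filtering
# ---------------------------------------------------------------------------


def connected_subtrees_brute_force(glycan: GlycanStructure, max_size: int):
    """All connected sub-glycans via brute-force subset filtering."""
    out = {}
    node_list = list(glycan.nodes)
    for size in range(1, min(max_size, len(node_list)) + 1):
        for subset in itertools.combinations(node_list, size):
            chosen = set(subset)
            # connected iff exactly one chosen node lacks a chosen parent
            roots = [
                nid
                for nid in chosen
                if nid == glycan.root_id or glycan.parents[nid][0] not in chosen
            ]
            if len(roots) != 1:
                continue
            root = roots[0]
            nodes = {nid: glycan.nodes[nid] for nid in chosen}
            parents = {
                nid: glycan.parents[nid] for nid in chosen if nid != root
            }
            sub = GlycanStructure(nodes, parents, root)
            out.setdefault(sub.serialize(), sub)
    return out


def mine_motifs_oracle(binders, nonbinders, max_size):
    """Brute-force motif mining with the same scoring/maximality contract."""
    binders = sorted(set(binders), key=GlycanStructure.serialize)
    nonbinders = sorted(set(nonbinders), key=GlycanStructure.serialize)
    candidates = {}
    for g in binders:
        candidates.update(connected_subtrees_brute_force(g, max_size))
    scored = []
    for ser, sub in candidates.items():
        cov = sum(embeds_brute_force(g, sub) for g in binders) / len(binders)
        freq = (
            sum(embeds_brute_force(g, sub) for g in nonbinders) / len(nonbinders)
            if nonbinders
            else 0.0
        )
        scored.append((ser, sub, cov, freq, cov - freq))
    scored.sort(key=lambda t: (-t[4], -len(t[1]), t[0]))
    kept = []
    for ser, sub, cov, freq, score in scored:
        dominated = any(
            o_score >= score and len(o_sub) > len(sub)
            and embeds_brute_force(o_sub, sub)
            for o_ser, o_sub, _, _, o_score in scored
            if o_ser != ser
        )
        if not dominated:
            kept.append((ser, cov, freq))
    return kept


# ---------------------------------------------------------------------------
# random glycan trees for property tests
# ---------------------------------------------------------------------------

_RESIDUES = ("Gal", "Glc", "Man", "GlcNAc", "Fuc")


def random_tree(rng: np.random.Generator, n_nodes: int) -> GlycanStructure:
    """Random labelled rooted tree; independent of the package generators."""
    from lectiscope.glycan import Linkage, Residue

    nodes = {0: Residue(_RESIDUES[int(rng.integers(len(_RESIDUES)))])}
    parents = {}
    used = {0: set()}
    for nid in range(1, n_nodes):
        while True:
            parent = int(rng.integers(nid))
            free = [c for c in (2, 3, 4, 6) if c not in used[parent]]
            if free:
                break
        carbon = free[int(rng.integers(len(free)))]
        anomeric = ("a", "b", "?")[int(rng.integers(3))]
        nodes[nid] = Residue(_RESIDUES[int(rng.integers(len(_RESIDUES)))])
        parents[nid] = (parent, Linkage(anomeric, 1, carbon))
        used[parent].add(carbon)
        used[nid] = set()
    return GlycanStructure(nodes, parents, 0)


def random_subtree(rng: np.random.Generator, glycan: GlycanStructure,
                   max_size: int) -> GlycanStructure:
    """Uniformly pick one connected sub-glycan (for monotonicity tests)."""
    subs = list(connected_subtrees_brute_force(glycan, max_size).values())
    return subs[int(rng.integers(len(subs)))]
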