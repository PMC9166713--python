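"""Global alignment identity, greedy centroid clustering, reference matching.

Percent identity is computed from a Needleman-Wunsch/Gotoh global alignment
with affine gaps (BLOSUM62, gap open 11, gap extend 1 by default — the
scoring a BLASTP user would expect).  Identity is defined as matches divided
by *all* alignment columns, terminal gap columns included; this is the
single unambiguous definition used throughout the package, so identity is 1
exactly when the two sequences are identical and ``columns >= max(len(a),
len(b))`` always holds.

Alignment statistics are made symmetric by construction: the pair is put
into a canonical order before the dynamic program runs, and the reported
quantities (matches, columns, aligned pairs, score) do not depend on the
argument order.  Traceback ties prefer a residue pairing over a gap in the
first sequence over a gap in the second, making repeated runs bit-identical.

Two thresholds with different boundary semantics coexist deliberately:
clustering admits a member at identity >= threshold (sequences "clustered at
90% identity"), while matching a query against a reference set requires
identity strictly > threshold (a match "at > 90% identity").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

__all__ = [
    "AlignmentScoring",
    "AlignmentResult",
    "Cluster",
    "ClusterSet",
    "Match",
    "global_align_identity",
    "greedy_cluster",
    "match_to_set",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM62.alphabet)
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}
_SUB = np.asarray(_BLOSUM62, dtype=np.float64)
#: residues accepted in input sequences (20 canonical + X for unknown)
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_NEG = -1e30


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution matrix and affine gap penalties.

    ``gap_open`` is the cost of the first residue of a gap and
    ``gap_extend`` the cost of each further residue.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def substitution(self) -> np.ndarray:
        if self.matrix == "BLOSUM62":
            return _SUB
        return np.asarray(substitution_matrices.load(self.matrix), dtype=np.float64)


DEFAULT_SCORING = AlignmentScoring()


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of one global alignment."""

    matches: int
    columns: int
    score: float
    aligned_pairs: int
    identity: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "identity", self.matches / self.columns)


@njit(cache=True)
def _gotoh(xi, yi, sub, gap_open, gap_extend):  # pragma: no cover - numba
    n = xi.shape[0]
    m = yi.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in x (consumes y)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in y (consumes x)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        X[0, j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        Y[i, 0] = -(gap_open + (i - 1) * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = best + sub[xi[i - 1], yi[j - 1]]
            X[i, j] = max(M[i, j - 1] - gap_open,
                          max(X[i, j - 1] - gap_extend, Y[i, j - 1] - gap_open))
            Y[i, j] = max(M[i - 1, j] - gap_open,
                          max(X[i - 1, j] - gap_open, Y[i - 1, j] - gap_extend))
    return M, X, Y


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(f"invalid amino-acid residue(s): {sorted(bad)}")
    return np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))


def global_align_identity(
    a: str, b: str, scoring: AlignmentScoring = DEFAULT_SCORING
) -> AlignmentResult:
    """Globally align two amino-acid sequences and report identity.

    Raises ``ValueError`` on an empty sequence or an unrecognized residue.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    # canonical argument order makes every reported statistic symmetric
    if (len(a), a) > (len(b), b):
        a, b = b, a
    xi, yi = _encode(a), _encode(b)
    sub = scoring.substitution()
    go, ge = float(scoring.gap_open), float(scoring.gap_extend)
    M, X, Y = _gotoh(xi, yi, sub, go, ge)

    i, j = len(a), len(b)
    end_vals = (M[i, j], X[i, j], Y[i, j])
    score = max(end_vals)
    state = int(np.argmax(np.array(end_vals) == score))  # 0=M, 1=X, 2=Y

    matches = columns = pairs = 0
    while i > 0 or j > 0:
        if state == 0:  # residue pairing
            columns += 1
            pairs += 1
            if xi[i - 1] == yi[j - 1]:
                matches += 1
            target = M[i, j] - sub[xi[i - 1], yi[j - 1]]
            i -= 1
            j -= 1
            if M[i, j] == target:
                state = 0
            elif X[i, j] == target:
                state = 1
            else:
                state = 2
        elif state == 1:  # gap in first sequence, consumes b_j
            columns += 1
            v = X[i, j]
            j -= 1
            if M[i, j] - go == v:
                state = 0
            elif X[i, j] - ge == v:
                state = 1
            else:
                state = 2
        else:  # gap in second sequence, consumes a_i
            columns += 1
            v = Y[i, j]
            i -= 1
            if M[i, j] - go == v:
                state = 0
            elif X[i, j] - go == v:
                state = 1
            else:
                state = 2
    return AlignmentResult(matches=matches, columns=columns, score=float(score),
                           aligned_pairs=pairs)


def _identity_upper_bound(a: str, b: str) -> float:
    """matches <= min length and columns >= max length, so identity can
    never exceed this ratio; used to skip hopeless alignments."""
    la, lb = len(a), len(b)
    return min(la, lb) / max(la, lb)


# ---------------------------------------------------------------------------
# greedy centroid clustering
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    centroid: str
    members: list[str]          # includes the centroid, in join order
    identities: dict[str, float]  # member accession -> identity to centroid


@dataclass
class ClusterSet:
    """Partition of input sequences into centroid-defined clusters."""

    clusters: list[Cluster]
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def assignment(self) -> dict[str, str]:
        """Member accession -> centroid accession."""
        return {m: c.centroid for c in self.clusters for m in c.members}


def greedy_cluster(
    sequences: list[tuple[str, str]],
    threshold: float = 0.90,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> ClusterSet:
    """USEARCH-style greedy centroid clustering at an identity threshold.

    Sequences are processed by (length desc, accession asc).  The first
    becomes a centroid; each later sequence joins the best-identity centroid
    with identity >= *threshold* (ties go to the earliest-created centroid),
    otherwise it founds a new cluster.  Every member therefore sits at
    identity >= threshold from its centroid and the clusters partition the
    input.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    seen: set[str] = set()
    for acc, _ in sequences:
        if acc in seen:
            raise ValueError(f"duplicate accession {acc!r}")
        seen.add(acc)
    ordered = sorted(sequences, key=lambda it: (-len(it[1]), it[0]))
    clusters: list[Cluster] = []
    centroid_seqs: list[str] = []
    for acc, seq in ordered:
        best_idx = -1
        best_identity = -1.0
        for idx, cseq in enumerate(centroid_seqs):
            if seq == cseq:
                ident = 1.0
            elif _identity_upper_bound(seq, cseq) < threshold:
                continue
            else:
                ident = global_align_identity(seq, cseq, scoring).identity
            if ident > best_identity:
                best_identity = ident
                best_idx = idx
        if best_idx >= 0 and best_identity >= threshold:
            clusters[best_idx].members.append(acc)
            clusters[best_idx].identities[acc] = best_identity
        else:
            clusters.append(Cluster(centroid=acc, members=[acc], identities={acc: 1.0}))
            centroid_seqs.append(seq)
    return ClusterSet(clusters=clusters, threshold=threshold)


# ---------------------------------------------------------------------------
# matching a query against a reference set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Match:
    accession: str
    identity: float
    coverage: float


def match_to_set(
    query: str,
    references: list[tuple[str, str]],
    threshold: float = 0.90,
    min_coverage: float = 0.8,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    first_only: bool = False,
) -> list[Match]:
    """References matching *query* at identity strictly above *threshold*.

    Coverage is the fraction of query residues paired with a reference
    residue in the global alignment and must reach *min_coverage*.  Matches
    are returned sorted by identity descending (ties by accession).  With
    ``first_only`` the scan stops at the first match — a fast path for
    presence/absence calls.
    """
    if not query:
        raise ValueError("empty query sequence")
    if not references:
        raise ValueError("empty reference set")
    out: list[Match] = []
    lq = len(query)
    for acc, seq in references:
        if seq == query:
            out.append(Match(acc, 1.0, 1.0))
            if first_only:
                return out
            continue
        if _identity_upper_bound(query, seq) <= threshold:
            continue
        if min(lq, len(seq)) / lq < min_coverage:
            continue
        res = global_align_identity(query, seq, scoring)
        coverage = res.aligned_pairs / lq
        if res.identity > threshold and coverage >= min_coverage:
            out.append(Match(acc, res.identity, coverage))
            if first_only:
                return out
    out.sort(key=lambda m: (-m.identity, m.accession))
    return out
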