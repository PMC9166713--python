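"""Presence/absence matrix, prevalence, body-site overlap and rarefaction.

Each metagenomic sample contributes a gene catalog (predicted protein
sequences).  A lectin is *present* in a sample when at least one catalog
gene matches it above the identity threshold (strictly, per the matching
rule in :mod:`lectiscope.identity`).  Presence calls are summarized into a
Boolean lectin x sample matrix from which every downstream statistic is
derived: per-site richness, mean lectins per person (one sample = one
person), cross-site overlap/Venn regions, the most prevalent lectins per
site, and analytic sample-based rarefaction curves.

Rarefaction is incidence-based: with ``N`` samples at a site and lectin
``i`` present in ``N_i`` of them, the expected richness among ``n`` randomly
drawn samples is

    S(n) = sum_i [ 1 - C(N - N_i, n) / C(N, n) ]

evaluated in exact rational arithmetic (``C`` is the binomial coefficient,
zero when ``n > N - N_i``).  S is monotone non-decreasing and concave,
S(1) is the mean per-sample richness and S(N) the observed site richness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .identity import AlignmentScoring, DEFAULT_SCORING, match_to_set

__all__ = [
    "GeneCatalog",
    "PresenceMatrix",
    "RarefactionCurve",
    "build_presence_matrix",
    "prevalence_summary",
    "site_overlap",
    "top_prevalent",
    "rarefaction_curve",
    "read_manifest",
]


@dataclass(frozen=True)
class GeneCatalog:
    """Predicted protein-coding genes of one metagenomic sample."""

    sample_id: str
    body_site: str
    genes: tuple[tuple[str, str], ...]  # (gene_id, amino-acid sequence)


@dataclass
class PresenceMatrix:
    """Boolean lectin x sample incidence plus the sample -> site map."""

    data: pd.DataFrame  # bool; index = lectin accessions, columns = sample ids
    site_map: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.data.columns) - set(self.site_map)
        if missing:
            raise ValueError(f"samples without a body site: {sorted(missing)}")

    @property
    def lectins(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def sites(self) -> list[str]:
        return sorted({self.site_map[s] for s in self.data.columns})

    def site_samples(self, site: str) -> list[str]:
        return [s for s in self.data.columns if self.site_map[s] == site]


@dataclass
class RarefactionCurve:
    """Expected lectin richness versus number of samples at one body site."""

    body_site: str
    n_samples: int
    incidence: dict[str, int]  # lectin -> number of site samples containing it
    points: np.ndarray  # points[k] = S(k + 1) for k in 0..N-1
    sd: np.ndarray | None = None  # optional resampling SDs, same shape

    def expected_richness(self, n: int) -> float:
        if not 1 <= n <= self.n_samples:
            raise ValueError(f"n must lie in 1..{self.n_samples}")
        return float(self.points[n - 1])


def read_manifest(path) -> list[tuple[str, str, str]]:
    """Manifest TSV (sample_id, body_site, fasta_path) -> list of rows."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"sample_id", "body_site", "fasta_path"}
    if not needed <= set(df.columns):
        raise ValueError(f"manifest must contain columns {sorted(needed)}")
    return [(r.sample_id, r.body_site, r.fasta_path) for r in df.itertuples(index=False)]


def build_presence_matrix(
    lectins: list[tuple[str, str]],
    catalogs: list[GeneCatalog],
    threshold: float = 0.90,
    min_coverage: float = 0.8,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> PresenceMatrix:
    """Summarize lectin-versus-catalog matches into a Boolean matrix.

    Cell (i, s) is true iff some gene of sample ``s`` matches lectin ``i``
    at identity strictly above *threshold* with sufficient query coverage.
    An empty catalog yields an all-false column; duplicate sample ids are an
    error.  The result does not depend on gene or sample order.
    """
    if not lectins or not catalogs:
        raise ValueError("need at least one lectin and one catalog")
    sample_ids = [c.sample_id for c in catalogs]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id in catalogs")
    accs = [acc for acc, _ in lectins]
    if len(set(accs)) != len(accs):
        raise ValueError("duplicate lectin accession")
    data = pd.DataFrame(False, index=accs, columns=sample_ids, dtype=bool)
    for cat in catalogs:
        if not cat.genes:
            continue
        genes = list(cat.genes)
        for acc, seq in lectins:
            hit = match_to_set(
                seq, genes, threshold, min_coverage, scoring, first_only=True
            )
            if hit:
                data.loc[acc, cat.sample_id] = True
    site_map = {c.sample_id: c.body_site for c in catalogs}
    return PresenceMatrix(data=data, site_map=site_map)


def prevalence_summary(matrix: PresenceMatrix) -> dict[str, dict]:
    """Per-site richness, mean lectins per person and per-lectin counts."""
    out: dict[str, dict] = {}
    for site in matrix.sites():
        cols = matrix.site_samples(site)
        block = matrix.data[cols]
        per_lectin = block.sum(axis=1)
        out[site] = {
            "n_samples": len(cols),
            "richness": int((per_lectin > 0).sum()),
            "mean_per_sample": float(block.sum(axis=0).mean()),
            "per_lectin_counts": {
                acc: int(n) for acc, n in per_lectin.items() if n > 0
            },
        }
    return out


def site_overlap(matrix: PresenceMatrix) -> dict:
    """Cross-site sharing statistics.

    A lectin's site set is the set of body sites with at least one positive
    sample.  The shared fraction is the proportion of observed lectins found
    in two or more sites; a site's specific fraction is the proportion of
    its lectins found in that site only.  For up to six sites the exact Venn
    region counts are included; beyond that only the pairwise table is.
    """
    sites = matrix.sites()
    if not sites:
        raise ValueError("matrix has no sites")
    site_sets: dict[str, tuple[str, ...]] = {}
    for acc in matrix.lectins:
        row = matrix.data.loc[acc]
        present = tuple(
            sorted({matrix.site_map[s] for s in matrix.samples if row[s]})
        )
        if present:
            site_sets[acc] = present
    observed = list(site_sets)
    n_observed = len(observed)
    shared = [acc for acc in observed if len(site_sets[acc]) >= 2]
    specific_fraction: dict[str, float] = {}
    for site in sites:
        site_lectins = [acc for acc in observed if site in site_sets[acc]]
        only_here = [acc for acc in site_lectins if site_sets[acc] == (site,)]
        specific_fraction[site] = (
            len(only_here) / len(site_lectins) if site_lectins else 0.0
        )
    pairwise = {
        f"{a}&{b}": sum(
            1 for acc in observed if a in site_sets[acc] and b in site_sets[acc]
        )
        for i, a in enumerate(sites)
        for b in sites[i + 1:]
    }
    result = {
        "site_sets": {acc: list(site_sets[acc]) for acc in sorted(site_sets)},
        "n_observed": n_observed,
        "shared_fraction": len(shared) / n_observed if n_observed else 0.0,
        "site_specific_fraction": specific_fraction,
        "pairwise_counts": pairwise,
    }
    if len(sites) <= 6:
        venn: dict[str, int] = {}
        from itertools import combinations

        for k in range(1, len(sites) + 1):
            for combo in combinations(sites, k):
                venn["&".join(combo)] = sum(
                    1 for acc in observed if site_sets[acc] == combo
                )
        result["venn_counts"] = venn
    return result


def top_prevalent(
    matrix: PresenceMatrix, site: str, fraction: float = 0.1
) -> list[str]:
    """The most prevalent lectins at a site (e.g. the top 10%).

    Lectins present at the site are ranked by within-site sample count
    (ties broken by accession) and the top ``ceil(fraction * richness)``
    are returned.  A site with no observed lectin yields an empty list.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    cols = matrix.site_samples(site)
    if not cols:
        raise ValueError(f"site {site!r} has no samples")
    counts = matrix.data[cols].sum(axis=1)
    present = [(acc, int(n)) for acc, n in counts.items() if n > 0]
    if not present:
        return []
    present.sort(key=lambda it: (-it[1], it[0]))
    k = math.ceil(fraction * len(present))
    return [acc for acc, _ in present[:k]]


def rarefaction_curve(
    matrix: PresenceMatrix,
    site: str,
    resample: int = 0,
    seed: int | None = None,
) -> RarefactionCurve:
    """Analytic sample-based rarefaction curve for one body site.

    ``resample > 0`` additionally estimates standard deviations by drawing
    that many random sample subsets per point (seeded, reproducible); the
    expectation itself always comes from the exact formula.
    """
    cols = matrix.site_samples(site)
    if not cols:
        raise ValueError(f"site {site!r} has no samples")
    N = len(cols)
    counts = matrix.data[cols].sum(axis=1)
    incidence = {acc: int(n) for acc, n in counts.items() if n > 0}
    points = np.empty(N, dtype=float)
    denom_cache = {n: math.comb(N, n) for n in range(1, N + 1)}
    for n in range(1, N + 1):
        total = Fraction(0)
        for n_i in incidence.values():
            absent = math.comb(N - n_i, n) if n <= N - n_i else 0
            total += 1 - Fraction(absent, denom_cache[n])
        points[n - 1] = float(total)
    sd = None
    if resample > 0:
        rng = np.random.default_rng(seed)
        incid = np.array(list(incidence.values()))
        block = matrix.data[cols].to_numpy()
        block = block[block.sum(axis=1) > 0]
        sd = np.zeros(N, dtype=float)
        for n in range(1, N + 1):
            richness = np.empty(resample, dtype=float)
            for r in range(resample):
                chosen = rng.choice(N, size=n, replace=False)
                richness[r] = (block[:, chosen].any(axis=1)).sum()
            sd[n - 1] = richness.std(ddof=1) if resample > 1 else 0.0
        del incid
    return RarefactionCurve(
        body_site=site, n_samples=N, incidence=incidence, points=points, sd=sd
    )
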