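"""Seeded synthetic datasets with planted ground truth for every stage.

These generators emulate the statistical shape of the pipeline's real
inputs — a domain-annotated protein universe with decoys, sequence families
at controlled divergence, per-body-site gene catalogs with planted
per-lectin inclusion probabilities, and a glycan-array library in which the
binders share a planted motif — while recording exactly what was planted so
downstream results can be checked against the truth.

Every generator is a pure function of (config, seed): one
``numpy.random.Generator`` is created per dataset and consumed in a fixed
documented order, so identical calls are byte-identical and adding records
never perturbs earlier draws.

Divergence convention: ``within_divergence`` is the expected *pairwise*
divergence between two family members.  Each member therefore carries
``round(L * within_divergence / 2)`` substitutions relative to the common
ancestor, at positions drawn without replacement, so two members differ at
no more than ``within_divergence`` of their sites.  This keeps identity
guarantees exact: at 5% divergence every member aligns to every other at
>= 95% identity, safely above a 90% clustering threshold.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .array import ArrayRecord
from .glycan import GlycanStructure, Linkage, Residue, contains_motif, parse_glycan
from .mining import (
    DEFAULT_EXCLUSION_KEYWORDS,
    DomainAnnotation,
    ProteinRecord,
)
from .prevalence import GeneCatalog

__all__ = [
    "AA20",
    "GroundTruth",
    "UniverseConfig",
    "FamilyConfig",
    "SiteSpec",
    "CatalogConfig",
    "ArrayConfig",
    "gen_protein_universe",
    "gen_sequence_families",
    "gen_catalogs",
    "gen_glycan_array",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# domain pools; categories are fixed by the emitted domain table.  The CBM
# pool matches the packaged default CBM list so the default filter config
# recognizes every planted carbohydrate-binding domain.
CBM_POOL = ("IPR033803", "IPR024361")
SECONDARY_POOL = ("IPR003961", "IPR011990", "IPR013783", "IPR036465")
CATALYTIC_POOL = ("IPR017853", "IPR000322")

CLEAN_DESCRIPTIONS = (
    "uncharacterized protein",
    "hypothetical protein",
    "protein of unknown function DUF1735",
)

#: decoy classes in the order their violated rule is reported
DECOY_CLASSES = ("no_cbm", "catalytic", "keyword", "reviewed")


@dataclass
class GroundTruth:
    """Planted labels for one synthetic dataset.

    Only the fields relevant to the generating function are populated.
    """

    labels: dict[str, tuple[bool, str | None]] | None = None  # accession -> (accept, reason)
    families: dict[str, str] | None = None  # accession -> family id
    presence: dict[str, dict[str, bool]] | None = None  # lectin -> sample -> bool
    site_map: dict[str, str] | None = None
    binders: dict[str, bool] | None = None  # glycan_id -> is binder
    planted_motif: str | None = None  # canonical serialization

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {k: v for k, v in asdict(self).items() if v is not None},
                fh,
                indent=2,
                sort_keys=True,
            )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute exactly round(len * rate) positions (no indels)."""
    n_sub = round(len(seq) * rate)
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = [a for a in AA20 if a != chars[pos]]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# protein universe
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UniverseConfig:
    n_true_lectins: int = 100
    n_decoys: int = 100
    #: fractions of decoys violating, respectively, the no-CBM, catalytic,
    #: keyword and reviewed rules
    decoy_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    domain_length: tuple[int, int] = (40, 120)
    linker_length: tuple[int, int] = (5, 30)


def _allocate(n: int, fractions: tuple[float, ...]) -> list[int]:
    total = sum(fractions)
    if total > 1.0 + 1e-9:
        raise ValueError("decoy mix fractions sum to more than 1")
    if any(f < 0 for f in fractions):
        raise ValueError("decoy mix fractions must be non-negative")
    if total == 0:
        if n > 0:
            raise ValueError("cannot allocate decoys with all-zero mix")
        return [0] * len(fractions)
    shares = [n * f / total for f in fractions]
    counts = [int(s) for s in shares]
    remainders = sorted(
        range(len(shares)), key=lambda i: (shares[i] - counts[i], -i), reverse=True
    )
    for i in remainders[: n - sum(counts)]:
        counts[i] += 1
    return counts


def _build_record(
    rng: np.random.Generator,
    accession: str,
    domain_ids: list[str],
    categories: dict[str, str],
    reviewed: bool,
    description: str,
    config: UniverseConfig,
) -> ProteinRecord:
    lo_d, hi_d = config.domain_length
    lo_l, hi_l = config.linker_length
    domains = []
    pos = int(rng.integers(lo_l, hi_l + 1))
    for dom in domain_ids:
        length = int(rng.integers(lo_d, hi_d + 1))
        domains.append(
            DomainAnnotation(dom, pos + 1, pos + length, categories[dom])
        )
        pos += length + int(rng.integers(lo_l, hi_l + 1))
    seq = _random_seq(rng, pos)
    return ProteinRecord(accession, seq, tuple(domains), reviewed, description)


def gen_protein_universe(
    config: UniverseConfig, seed: int
) -> tuple[list[ProteinRecord], dict[str, str], GroundTruth]:
    """Annotated protein universe with planted lectins and decoys.

    True lectins carry >= 1 CBM, no catalytic domain, a clean description
    and ``reviewed=False``.  Each decoy violates exactly one rule according
    to the configured mix.  Returns (records, domain table, ground truth);
    draw order is: true lectins in accession order, then decoys class by
    class in the ``DECOY_CLASSES`` order.
    """
    rng = np.random.default_rng(seed)
    categories = {
        **{d: "carbohydrate_binding" for d in CBM_POOL},
        **{d: "other" for d in SECONDARY_POOL},
        **{d: "catalytic" for d in CATALYTIC_POOL},
    }
    records: list[ProteinRecord] = []
    labels: dict[str, tuple[bool, str | None]] = {}

    def pick(pool, k):
        return [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]

    for i in range(config.n_true_lectins):
        acc = f"LEC{i + 1:05d}"
        doms = pick(CBM_POOL, int(rng.integers(1, 3)))
        doms += pick(SECONDARY_POOL, int(rng.integers(0, 3)))
        rng.shuffle(doms)
        desc = CLEAN_DESCRIPTIONS[int(rng.integers(len(CLEAN_DESCRIPTIONS)))]
        records.append(
            _build_record(rng, acc, doms, categories, False, desc, config)
        )
        labels[acc] = (True, None)

    counts = _allocate(config.n_decoys, config.decoy_mix)
    class_counts = dict(zip(DECOY_CLASSES, counts))
    idx = 0
    for cls in DECOY_CLASSES:
        for _ in range(class_counts[cls]):
            idx += 1
            acc = f"DEC{idx:05d}"
            reviewed = False
            desc = CLEAN_DESCRIPTIONS[int(rng.integers(len(CLEAN_DESCRIPTIONS)))]
            if cls == "no_cbm":
                doms = pick(SECONDARY_POOL, int(rng.integers(1, 3)))
            elif cls == "catalytic":
                doms = pick(CBM_POOL, 1) + pick(CATALYTIC_POOL, 1)
                rng.shuffle(doms)
            elif cls == "keyword":
                doms = pick(CBM_POOL, 1)
                kw = DEFAULT_EXCLUSION_KEYWORDS[
                    int(rng.integers(len(DEFAULT_EXCLUSION_KEYWORDS)))
                ]
                desc = f"putative {kw.lower()} protein"
            else:  # reviewed
                doms = pick(CBM_POOL, 1)
                reviewed = True
            records.append(
                _build_record(rng, acc, doms, categories, reviewed, desc, config)
            )
            labels[acc] = (False, cls)

    truth = GroundTruth(labels=labels)
    return records, categories, truth


# ---------------------------------------------------------------------------
# sequence families
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilyConfig:
    n_families: int = 5
    family_size: int = 6
    #: expected pairwise divergence between two members of a family
    within_divergence: float = 0.05
    ancestor_length: tuple[int, int] = (100, 140)


def gen_sequence_families(
    config: FamilyConfig, seed: int
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Families of related sequences at controlled divergence.

    Each family is an independent random ancestor; each member carries
    exactly ``round(L * within_divergence / 2)`` substitutions from it.
    Draw order: per family, ancestor length, ancestor sequence, then the
    members in order.
    """
    if not 0.0 <= config.within_divergence < 1.0:
        raise ValueError("within_divergence must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    sequences: list[tuple[str, str]] = []
    families: dict[str, str] = {}
    lo, hi = config.ancestor_length
    for f in range(config.n_families):
        fam_id = f"fam{f + 1:02d}"
        length = int(rng.integers(lo, hi + 1))
        ancestor = _random_seq(rng, length)
        for m in range(config.family_size):
            acc = f"{fam_id}_m{m + 1:02d}"
            seq = _mutate(rng, ancestor, config.within_divergence / 2)
            sequences.append((acc, seq))
            families[acc] = fam_id
    return sequences, GroundTruth(families=families)


# ---------------------------------------------------------------------------
# gene catalogs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteSpec:
    name: str
    n_samples: int
    #: probability each lectin is carried by a sample at this site; either a
    #: single float for all lectins or a per-accession mapping
    p_inclusion: float | dict[str, float] = 0.5

    def probability(self, accession: str) -> float:
        if isinstance(self.p_inclusion, dict):
            return self.p_inclusion[accession]
        return self.p_inclusion


#: the five body sites surveyed for lectin prevalence
DEFAULT_SITES = (
    SiteSpec("stool", 20, 0.5),
    SiteSpec("buccal_mucosa", 20, 0.3),
    SiteSpec("supragingival_plaque", 20, 0.3),
    SiteSpec("tongue_dorsum", 20, 0.3),
    SiteSpec("posterior_fornix", 20, 0.1),
)


@dataclass(frozen=True)
class CatalogConfig:
    sites: tuple[SiteSpec, ...] = DEFAULT_SITES
    #: per-copy divergence of a planted lectin gene (0 = exact copies)
    mutation_divergence: float = 0.0
    n_background: int = 2
    background_length: tuple[int, int] = (40, 200)


def gen_catalogs(
    config: CatalogConfig,
    lectins: list[tuple[str, str]],
    seed: int,
) -> tuple[list[GeneCatalog], GroundTruth]:
    """Per-sample gene catalogs with planted lectin prevalence.

    Draw order per sample: one inclusion Bernoulli per lectin (in input
    order), then mutation draws for included lectins, then background gene
    lengths and sequences.
    """
    if not lectins:
        raise ValueError("lectin set must be non-empty")
    rng = np.random.default_rng(seed)
    catalogs: list[GeneCatalog] = []
    presence: dict[str, dict[str, bool]] = {acc: {} for acc, _ in lectins}
    site_map: dict[str, str] = {}
    lo, hi = config.background_length
    for site in config.sites:
        for s in range(site.n_samples):
            sample_id = f"{site.name}_s{s + 1:03d}"
            site_map[sample_id] = site.name
            genes: list[tuple[str, str]] = []
            included = [
                rng.random() < site.probability(acc) for acc, _ in lectins
            ]
            for (acc, seq), inc in zip(lectins, included):
                presence[acc][sample_id] = bool(inc)
                if inc:
                    copy = (
                        _mutate(rng, seq, config.mutation_divergence)
                        if config.mutation_divergence > 0
                        else seq
                    )
                    genes.append((f"{sample_id}|{acc}", copy))
            for k in range(config.n_background):
                length = int(rng.integers(lo, hi + 1))
                genes.append((f"{sample_id}|bg{k + 1}", _random_seq(rng, length)))
            catalogs.append(GeneCatalog(sample_id, site.name, tuple(genes)))
    return catalogs, GroundTruth(presence=presence, site_map=site_map)


# ---------------------------------------------------------------------------
# glycan array
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArrayConfig:
    n_binders: int = 12
    n_nonbinders: int = 12
    planted_motif: str = "Galb1-3GlcNAcb1-2Mana1-3Man"
    protein_id: str = "CBM5"
    concentration: str = "5 ug/ml"
    n_replicates: int = 6
    binder_mean: float = 20000.0
    nonbinder_mean: float = 200.0
    noise_sd: float = 500.0
    outlier_prob: float = 0.1
    outlier_scale: float = 5.0


_CONTEXT_RESIDUES = ("Gal", "Glc", "Man", "GlcNAc", "GalNAc", "Fuc", "Xyl")
_PARENT_CARBONS = (2, 3, 4, 6)


class _TreeBuilder:
    """Incremental rooted-tree construction with one linkage per carbon."""

    def __init__(self) -> None:
        self.nodes: dict[int, Residue] = {}
        self.parents: dict[int, tuple[int, Linkage]] = {}
        self.used: dict[int, set[int]] = {}
        self.root_id: int | None = None
        self._next = 0

    def _new_id(self) -> int:
        nid = self._next
        self._next += 1
        return nid

    def add_root(self, residue: Residue) -> int:
        assert self.root_id is None
        nid = self._new_id()
        self.nodes[nid] = residue
        self.used[nid] = set()
        self.root_id = nid
        return nid

    def free_carbons(self, nid: int) -> list[int]:
        return [c for c in _PARENT_CARBONS if c not in self.used[nid]]

    def attachable(self) -> list[int]:
        return [nid for nid in self.nodes if self.free_carbons(nid)]

    def add_child(self, parent: int, residue: Residue, anomeric: str,
                  parent_carbon: int) -> int:
        nid = self._new_id()
        self.nodes[nid] = residue
        self.used[nid] = set()
        child_carbon = 2 if residue.code == "Neu5Ac" else 1
        self.parents[nid] = (parent, Linkage(anomeric, child_carbon, parent_carbon))
        self.used[parent].add(parent_carbon)
        return nid

    def add_subtree(self, parent: int | None, sub: GlycanStructure,
                    anomeric: str | None, parent_carbon: int | None) -> None:
        """Graft *sub* (its whole tree) below *parent*; None = make it root."""
        mapping: dict[int, int] = {}
        order = [sub.root_id]
        pos = 0
        while pos < len(order):
            order.extend(c for c, _ in sub.children(order[pos]))
            pos += 1
        for old in order:
            nid = self._new_id()
            mapping[old] = nid
            self.nodes[nid] = sub.nodes[old]
            self.used[nid] = set()
        for child, (p, link) in sub.parents.items():
            self.parents[mapping[child]] = (mapping[p], link)
            self.used[mapping[p]].add(link.parent_carbon)
        if parent is None:
            assert self.root_id is None
            self.root_id = mapping[sub.root_id]
        else:
            rid = mapping[sub.root_id]
            child_carbon = 2 if sub.nodes[sub.root_id].code == "Neu5Ac" else 1
            self.parents[rid] = (
                parent,
                Linkage(anomeric, child_carbon, parent_carbon),
            )
            self.used[parent].add(parent_carbon)

    def to_structure(self) -> GlycanStructure:
        assert self.root_id is not None
        return GlycanStructure(self.nodes, self.parents, self.root_id)


def _random_residue(rng: np.random.Generator) -> Residue:
    return Residue(_CONTEXT_RESIDUES[int(rng.integers(len(_CONTEXT_RESIDUES)))])


def _random_tree(rng: np.random.Generator, n_nodes: int) -> GlycanStructure:
    tb = _TreeBuilder()
    tb.add_root(_random_residue(rng))
    for _ in range(n_nodes - 1):
        candidates = tb.attachable()
        parent = candidates[int(rng.integers(len(candidates)))]
        carbons = tb.free_carbons(parent)
        carbon = carbons[int(rng.integers(len(carbons)))]
        anomeric = "ab"[int(rng.integers(2))]
        tb.add_child(parent, _random_residue(rng), anomeric, carbon)
    return tb.to_structure()


def _binder_glycan(rng: np.random.Generator, motif: GlycanStructure) -> GlycanStructure:
    """Motif grafted into random context (always contains the motif)."""
    if rng.random() < 0.5:
        # motif hangs off a random context tree
        context = _random_tree(rng, int(rng.integers(1, 4)))
        tb = _TreeBuilder()
        tb.add_subtree(None, context, None, None)
        candidates = tb.attachable()
        parent = candidates[int(rng.integers(len(candidates)))]
        carbons = tb.free_carbons(parent)
        carbon = carbons[int(rng.integers(len(carbons)))]
        anomeric = "ab"[int(rng.integers(2))]
        tb.add_subtree(parent, motif, anomeric, carbon)
    else:
        # motif is the backbone, decorated with random extra residues
        tb = _TreeBuilder()
        tb.add_subtree(None, motif, None, None)
        for _ in range(int(rng.integers(0, 3))):
            candidates = tb.attachable()
            parent = candidates[int(rng.integers(len(candidates)))]
            carbons = tb.free_carbons(parent)
            carbon = carbons[int(rng.integers(len(carbons)))]
            anomeric = "ab"[int(rng.integers(2))]
            tb.add_child(parent, _random_residue(rng), anomeric, carbon)
    return tb.to_structure()


def gen_glycan_array(
    config: ArrayConfig, seed: int
) -> tuple[list[ArrayRecord], GroundTruth]:
    """Glycan-array screen with a planted conserved binding motif.

    Binders embed the planted motif in random tree context; non-binders are
    random trees verified at generation time not to contain it.  Replicate
    RFUs are the class mean plus Gaussian noise, with occasional outlier
    replicates (scaled by ``outlier_scale``) to exercise trimming.  Draw
    order: binder structures, non-binder structures, then replicate values
    glycan by glycan.
    """
    if not 0 < config.n_binders:
        raise ValueError("need at least one binder")
    motif = parse_glycan(config.planted_motif)  # raises on an unparseable motif
    rng = np.random.default_rng(seed)

    structures: list[tuple[str, GlycanStructure, bool]] = []
    for i in range(config.n_binders):
        g = _binder_glycan(rng, motif)
        assert contains_motif(g, motif)
        structures.append((f"G{i + 1:04d}", g, True))
    made = 0
    attempts = 0
    while made < config.n_nonbinders:
        attempts += 1
        if attempts > 1000 * config.n_nonbinders:
            raise RuntimeError("could not generate motif-free non-binders")
        g = _random_tree(rng, int(rng.integers(3, 7)))
        if contains_motif(g, motif):
            continue
        made += 1
        structures.append((f"G{config.n_binders + made:04d}", g, False))

    records: list[ArrayRecord] = []
    binder_labels: dict[str, bool] = {}
    for gid, structure, is_binder in structures:
        mean = config.binder_mean if is_binder else config.nonbinder_mean
        reps = []
        for _ in range(config.n_replicates):
            value = mean
            if config.noise_sd > 0:
                value += rng.normal(0.0, config.noise_sd)
            if config.outlier_prob > 0 and rng.random() < config.outlier_prob:
                value = mean * config.outlier_scale * (1 if rng.random() < 0.5 else -1)
            reps.append(float(value))
        records.append(
            ArrayRecord(
                glycan_id=gid,
                structure=structure,
                protein_id=config.protein_id,
                concentration=config.concentration,
                replicate_rfus=tuple(reps),
            )
        )
        binder_labels[gid] = is_binder
    truth = GroundTruth(binders=binder_labels, planted_motif=motif.serialize())
    return records, truth
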