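"""Candidate lectin mining from domain-annotated protein records.

A candidate microbial lectin is an unreviewed protein that carries at least
one carbohydrate-binding module (CBM) domain, no catalytic domain, and whose
free-text description does not name a function already understood
(transport, cell structure, adhesion, ...).  Domain categories come from an
explicit domain table — never guessed from the identifier — and the
description screen uses a fixed keyword list applied case-insensitively to
whole tokens, so "Fim" rejects "fim protein" but not "fimbriae" (which is
excluded by its own keyword).

The module also derives N-to-C domain architectures, summary statistics
(sequences / architectures / distinct CBM and secondary domains) and the
CBM x secondary-domain co-occurrence matrix used to survey architectural
diversity.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

__all__ = [
    "DEFAULT_EXCLUSION_KEYWORDS",
    "DEFAULT_CBM_DOMAINS",
    "DomainAnnotation",
    "ProteinRecord",
    "FilterConfig",
    "Decision",
    "classify_record",
    "derive_architecture",
    "summarize_candidates",
    "cooccurrence_matrix",
    "read_annotations",
    "read_domain_table",
    "read_protein_fasta",
]

#: Keywords that flag a protein as having a known, non-lectin function
#: (carbohydrate transport, cell structure, adhesion, ...).
DEFAULT_EXCLUSION_KEYWORDS: tuple[str, ...] = (
    "TonB", "Transport", "Channel", "Porin", "OmpA", "Anchor", "Receptor",
    "Dockerin", "Cohesin", "Flagella", "Lamin", "Lipoprotein", "Secretion",
    "RagB", "SusD", "ScaA", "ScaB", "Scaffoldin", "Septum", "Spore", "SusE",
    "Wall", "Fimbrial", "Fim", "FimH", "Adhesin", "PapG", "Membrane",
    "Fimbriae", "Adhesion",
)

#: Small packaged default CBM list; real analyses should supply the full
#: curated set of carbohydrate-binding InterPro identifiers.
DEFAULT_CBM_DOMAINS: frozenset[str] = frozenset({"IPR033803", "IPR024361"})

DOMAIN_CATEGORIES = ("carbohydrate_binding", "catalytic", "other")

_SEQ_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


@dataclass(frozen=True)
class DomainAnnotation:
    """One annotated domain interval (1-based, inclusive)."""

    domain_id: str
    start: int
    end: int
    category: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.domain_id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"{self.domain_id}: positions are 1-based")
        if self.category not in DOMAIN_CATEGORIES:
            raise ValueError(
                f"{self.domain_id}: unknown category {self.category!r}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """Protein sequence plus its ordered domain annotations."""

    accession: str
    sequence: str
    domains: tuple[DomainAnnotation, ...]
    reviewed: bool
    description: str = ""

    def __post_init__(self) -> None:
        if not _SEQ_RE.match(self.sequence.upper()):
            raise ValueError(
                f"{self.accession}: sequence must be non-empty over the "
                "20-letter alphabet plus X"
            )
        for d in self.domains:
            if d.end > len(self.sequence):
                raise ValueError(
                    f"{self.accession}: domain {d.domain_id} interval "
                    f"[{d.start}, {d.end}] exceeds sequence length "
                    f"{len(self.sequence)}"
                )


@dataclass(frozen=True)
class FilterConfig:
    """Rules defining a candidate lectin."""

    cbm_domain_ids: frozenset[str] = DEFAULT_CBM_DOMAINS
    exclusion_keywords: tuple[str, ...] = DEFAULT_EXCLUSION_KEYWORDS
    require_unreviewed: bool = True
    keyword_case_sensitive: bool = False

    def __post_init__(self) -> None:
        if not self.cbm_domain_ids:
            raise ValueError("cbm_domain_ids must be non-empty")


@dataclass(frozen=True)
class Decision:
    accepted: bool
    reason: str | None = None  # first failing rule: no_cbm | catalytic | keyword | reviewed


def _keyword_hit(description: str, config: FilterConfig) -> str | None:
    tokens = _TOKEN_RE.findall(description)
    if config.keyword_case_sensitive:
        token_set = set(tokens)
        for kw in config.exclusion_keywords:
            if kw in token_set:
                return kw
    else:
        token_set = {t.lower() for t in tokens}
        for kw in config.exclusion_keywords:
            if kw.lower() in token_set:
                return kw
    return None


def classify_record(record: ProteinRecord, config: FilterConfig) -> Decision:
    """Accept or reject a protein as a candidate lectin.

    Accept iff it has >= 1 CBM domain, no catalytic domain, a description
    free of exclusion keywords, and (by default) is not a reviewed entry.
    A rejection reports the *first* failing rule in the fixed order
    no_cbm, catalytic, keyword, reviewed.
    """
    if not any(d.domain_id in config.cbm_domain_ids for d in record.domains):
        return Decision(False, "no_cbm")
    if any(d.category == "catalytic" for d in record.domains):
        return Decision(False, "catalytic")
    if _keyword_hit(record.description, config) is not None:
        return Decision(False, "keyword")
    if config.require_unreviewed and record.reviewed:
        return Decision(False, "reviewed")
    return Decision(True)


def derive_architecture(record: ProteinRecord) -> tuple[str, ...]:
    """N-to-C ordered tuple of domain ids.

    Domains are ordered by (start asc, end asc, domain_id asc); repeated
    copies of the same domain are kept.  Inter-domain spacing and exact
    coordinates are deliberately ignored: an architecture is just the
    ordered domain string.
    """
    ordered = sorted(record.domains, key=lambda d: (d.start, d.end, d.domain_id))
    return tuple(d.domain_id for d in ordered)


def summarize_candidates(
    candidates: list[ProteinRecord], config: FilterConfig
) -> dict[str, int]:
    """Counts of sequences, distinct architectures, CBM and secondary domains."""
    architectures = {derive_architecture(r) for r in candidates}
    cbm_ids: set[str] = set()
    secondary_ids: set[str] = set()
    for r in candidates:
        for d in r.domains:
            if d.domain_id in config.cbm_domain_ids:
                cbm_ids.add(d.domain_id)
            else:
                secondary_ids.add(d.domain_id)
    return {
        "n_sequences": len(candidates),
        "n_architectures": len(architectures),
        "n_cbm_domains": len(cbm_ids),
        "n_secondary_domains": len(secondary_ids),
    }


def cooccurrence_matrix(
    candidates: list[ProteinRecord], config: FilterConfig
) -> tuple[pd.DataFrame, pd.Series]:
    """CBM x secondary-domain co-occurrence counts plus per-domain totals.

    Each record increments a (CBM id, secondary id) cell once per distinct
    pair it contains, regardless of domain copy number.  Totals count the
    records containing each domain at least once.  Only CBM x non-CBM pairs
    are counted.
    """
    cbm_ids: set[str] = set()
    sec_ids: set[str] = set()
    pair_counts: dict[tuple[str, str], int] = {}
    totals: dict[str, int] = {}
    for r in candidates:
        present = {d.domain_id for d in r.domains}
        r_cbm = sorted(present & config.cbm_domain_ids)
        r_sec = sorted(present - config.cbm_domain_ids)
        cbm_ids.update(r_cbm)
        sec_ids.update(r_sec)
        for dom in present:
            totals[dom] = totals.get(dom, 0) + 1
        for c in r_cbm:
            for s in r_sec:
                pair_counts[(c, s)] = pair_counts.get((c, s), 0) + 1
    matrix = pd.DataFrame(
        0, index=sorted(cbm_ids), columns=sorted(sec_ids), dtype=int
    )
    for (c, s), n in pair_counts.items():
        matrix.loc[c, s] = n
    totals_series = pd.Series(totals, dtype=int).sort_index()
    return matrix, totals_series


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def read_domain_table(path) -> dict[str, str]:
    """Domain table TSV (domain_id, category, name) -> {domain_id: category}."""
    table: dict[str, str] = {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"domain_id", "category"} <= set(df.columns):
        raise ValueError("domain table needs domain_id and category columns")
    for row in df.itertuples(index=False):
        if row.category not in DOMAIN_CATEGORIES:
            raise ValueError(f"{row.domain_id}: unknown category {row.category!r}")
        table[row.domain_id] = row.category
    return table


def read_protein_fasta(path) -> dict[str, str]:
    """FASTA keyed by accession (the record id)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_annotations(
    path, sequences: dict[str, str], domain_table: dict[str, str] | None = None
) -> list[ProteinRecord]:
    """Read the annotation TSV and join it with sequences.

    Columns: accession, reviewed, description, domain_id, start, end,
    category — one row per domain; a protein without domains has a single
    row with empty domain fields.  When *domain_table* is given, it
    overrides the per-row category (the table is the authority).
    """
    rows: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        needed = {"accession", "reviewed", "description", "domain_id", "start", "end"}
        if reader.fieldnames is None or not needed <= set(reader.fieldnames):
            raise ValueError(f"annotation TSV must contain columns {sorted(needed)}")
        for row in reader:
            acc = row["accession"]
            entry = rows.setdefault(
                acc,
                {
                    "reviewed": row["reviewed"].strip().lower() in ("true", "1", "yes"),
                    "description": row["description"],
                    "domains": [],
                },
            )
            if row["domain_id"]:
                if domain_table is not None:
                    if row["domain_id"] not in domain_table:
                        raise ValueError(
                            f"domain {row['domain_id']} absent from domain table"
                        )
                    category = domain_table[row["domain_id"]]
                else:
                    category = row.get("category", "") or "other"
                entry["domains"].append(
                    DomainAnnotation(
                        domain_id=row["domain_id"],
                        start=int(row["start"]),
                        end=int(row["end"]),
                        category=category,
                    )
                )
    records = []
    for acc in sorted(rows):
        if acc not in sequences:
            raise ValueError(f"annotated accession {acc} missing from FASTA")
        entry = rows[acc]
        records.append(
            ProteinRecord(
                accession=acc,
                sequence=sequences[acc],
                domains=tuple(entry["domains"]),
                reviewed=entry["reviewed"],
                description=entry["description"],
            )
        )
    return records
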