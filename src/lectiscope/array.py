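"""Glycan-array processing: replicate aggregation, normalization, binder calls.

Array data arrive as one row per (glycan, protein, concentration) with at
least three replicate relative-fluorescence-unit (RFU) measurements.  RFUs
are background-subtracted and may be negative.  Replicates are aggregated by
dropping exactly one maximum and one minimum occurrence and averaging the
rest (the standard trimmed mean used for six-replicate glycan microarray
screens).  Aggregated values are normalized to the top glycan binder, which
is set to 1, after clipping negatives to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .glycan import GlycanStructure, mine_motifs, parse_glycan

__all__ = [
    "ArrayRecord",
    "BindingProfile",
    "aggregate_replicates",
    "normalize_profile",
    "call_binders",
    "read_array_csv",
    "build_profile",
    "analyze_array",
]


@dataclass(frozen=True)
class ArrayRecord:
    """One glycan spot on the array for one protein/concentration."""

    glycan_id: str
    structure: GlycanStructure
    protein_id: str
    concentration: str
    replicate_rfus: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.replicate_rfus) < 3:
            raise ValueError(
                f"{self.glycan_id}: need at least 3 replicate RFUs, "
                f"got {len(self.replicate_rfus)}"
            )
        if not all(math.isfinite(v) for v in self.replicate_rfus):
            raise ValueError(f"{self.glycan_id}: non-finite replicate RFU")


@dataclass(frozen=True)
class BindingProfile:
    """Aggregated, normalized and thresholded binding of one screen."""

    protein_id: str
    concentration: str
    aggregated: dict[str, float]
    normalized: dict[str, float]
    binders: frozenset[str]
    threshold: float


def aggregate_replicates(rfus: list[float] | tuple[float, ...]) -> float:
    """Trimmed mean: drop one maximum and one minimum, average the rest.

    With six replicates this is the mean of the remaining four.  Exactly one
    occurrence of the extreme value is removed even when extremes are tied.
    Fewer than three values is an error (trimming would leave nothing).
    """
    vals = list(rfus)
    if len(vals) < 3:
        raise ValueError("need at least 3 replicates to trim and average")
    vals.remove(max(vals))
    vals.remove(min(vals))
    return sum(vals) / len(vals)


def normalize_profile(aggregated: dict[str, float]) -> dict[str, float]:
    """Scale aggregated RFUs to the top binder (set to 1).

    Negative aggregated values are clipped to zero before division.  An
    empty map, or one with no positive value, has no binder to anchor the
    scale and raises ``ValueError``.
    """
    if not aggregated:
        raise ValueError("empty profile: nothing to normalize")
    top = max(aggregated.values())
    if top <= 0:
        raise ValueError("no positive aggregated RFU: no top binder to anchor")
    return {gid: max(v, 0.0) / top for gid, v in aggregated.items()}


def call_binders(normalized: dict[str, float], threshold: float = 0.1) -> set[str]:
    """Glycans whose normalized score reaches *threshold* (0..1)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return {gid for gid, score in normalized.items() if score >= threshold}


def read_array_csv(path) -> list[ArrayRecord]:
    """Read an array CSV with columns glycan_id, structure, protein_id,
    concentration, rep1..repN (N >= 3; extra rep columns allowed)."""
    df = pd.read_csv(
        path,
        dtype={"glycan_id": str, "protein_id": str},
        float_precision="round_trip",
    )
    required = {"glycan_id", "structure", "protein_id", "concentration"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"array CSV missing columns: {sorted(missing)}")
    rep_cols = sorted(
        (c for c in df.columns if c.startswith("rep") and c[3:].isdigit()),
        key=lambda c: int(c[3:]),
    )
    if len(rep_cols) < 3:
        raise ValueError("array CSV needs at least 3 rep columns")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            ArrayRecord(
                glycan_id=str(d["glycan_id"]),
                structure=parse_glycan(str(d["structure"])),
                protein_id=str(d["protein_id"]),
                concentration=str(d["concentration"]),
                replicate_rfus=tuple(float(d[c]) for c in rep_cols),
            )
        )
    return records


def build_profile(records: list[ArrayRecord], threshold: float = 0.1) -> BindingProfile:
    """Aggregate, normalize and call binders for one protein/concentration."""
    if not records:
        raise ValueError("no array records")
    keys = {(r.protein_id, r.concentration) for r in records}
    if len(keys) != 1:
        raise ValueError(
            "records mix proteins or concentrations; group before profiling"
        )
    protein_id, concentration = next(iter(keys))
    aggregated = {r.glycan_id: aggregate_replicates(r.replicate_rfus) for r in records}
    normalized = normalize_profile(aggregated)
    binders = call_binders(normalized, threshold)
    return BindingProfile(
        protein_id, concentration, aggregated, normalized, frozenset(binders), threshold
    )


def analyze_array(
    records: list[ArrayRecord],
    threshold: float = 0.1,
    max_motif_size: int = 4,
    top_motifs: int = 20,
) -> dict:
    """Full array analysis for every (protein, concentration) group.

    Returns a JSON-serializable report with, per group, the per-glycan
    profile, the binder calls, and the ranked conserved motifs mined from
    the binder/non-binder split.
    """
    report: dict = {"groups": {}}
    by_group: dict[tuple[str, str], list[ArrayRecord]] = {}
    for r in records:
        by_group.setdefault((r.protein_id, r.concentration), []).append(r)
    for (protein_id, conc) in sorted(by_group):
        group = by_group[(protein_id, conc)]
        profile = build_profile(group, threshold)
        structures = {r.glycan_id: r.structure for r in group}
        binder_structs = [structures[g] for g in sorted(profile.binders)]
        nonbinder_structs = [
            structures[g] for g in sorted(set(structures) - profile.binders)
        ]
        motifs = mine_motifs(binder_structs, nonbinder_structs, max_motif_size)
        report["groups"][f"{protein_id}@{conc}"] = {
            "protein_id": protein_id,
            "concentration": conc,
            "threshold": threshold,
            "profile": {
                gid: {
                    "aggregated_rfu": profile.aggregated[gid],
                    "normalized_score": profile.normalized[gid],
                    "binder": gid in profile.binders,
                }
                for gid in sorted(profile.aggregated)
            },
            "binders": sorted(profile.binders),
            "motifs": [
                {
                    "pattern": m.pattern.serialize(),
                    "size": len(m.pattern),
                    "binder_coverage": m.binder_coverage,
                    "nonbinder_frequency": m.nonbinder_frequency,
                    "score": m.score,
                }
                for m in motifs[:top_motifs]
            ],
        }
    return report
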