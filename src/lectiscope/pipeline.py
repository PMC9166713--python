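"""End-to-end discovery pipeline: mine -> cluster -> prevalence -> motifs.

The pipeline composes the per-stage modules into one deterministic run:
candidate lectins are filtered from the annotated universe, deduplicated by
greedy centroid clustering, matched against per-sample gene catalogs to
build the presence matrix, summarized into prevalence / overlap /
rarefaction statistics and the domain co-occurrence matrix, and, when array
data are supplied, the glycan screen is profiled and mined for motifs.
Stages whose inputs are absent are skipped and flagged in the report.
"""

from __future__ import annotations

from dataclasses import dataclass

from .array import ArrayRecord, analyze_array
from .identity import AlignmentScoring, DEFAULT_SCORING, greedy_cluster
from .mining import (
    FilterConfig,
    ProteinRecord,
    classify_record,
    cooccurrence_matrix,
    summarize_candidates,
)
from .prevalence import (
    GeneCatalog,
    build_presence_matrix,
    prevalence_summary,
    rarefaction_curve,
    site_overlap,
    top_prevalent,
)

__all__ = ["PipelineConfig", "PipelineError", "run_discovery_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    cluster_threshold: float = 0.90   # inclusive: clustered *at* 90% identity
    match_threshold: float = 0.90     # strict: catalog match at > 90% identity
    min_coverage: float = 0.8
    binder_threshold: float = 0.1
    max_motif_size: int = 4
    top_fraction: float = 0.1
    scoring: AlignmentScoring = DEFAULT_SCORING


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_discovery_pipeline(
    universe: list[ProteinRecord] | None = None,
    catalogs: list[GeneCatalog] | None = None,
    array_records: list[ArrayRecord] | None = None,
    config: PipelineConfig | None = None,
    filter_config: FilterConfig | None = None,
) -> dict:
    """Run every enabled stage and return one JSON-serializable report.

    The report (and any files written from it) is fully deterministic for a
    fixed input and configuration.  Also returns intermediate objects under
    the ``"_objects"`` key for programmatic use; strip it before dumping.
    """
    config = config or PipelineConfig()
    filter_config = filter_config or FilterConfig()
    report: dict = {
        "config": {
            "cluster_threshold": config.cluster_threshold,
            "match_threshold": config.match_threshold,
            "min_coverage": config.min_coverage,
            "binder_threshold": config.binder_threshold,
            "max_motif_size": config.max_motif_size,
            "top_fraction": config.top_fraction,
        },
        "stages": {},
    }
    objects: dict = {}

    candidates: list[ProteinRecord] = []
    if universe is not None:
        try:
            decisions = {r.accession: classify_record(r, filter_config) for r in universe}
            candidates = [r for r in universe if decisions[r.accession].accepted]
            reject_counts: dict[str, int] = {}
            for d in decisions.values():
                if not d.accepted:
                    reject_counts[d.reason] = reject_counts.get(d.reason, 0) + 1
            summary = summarize_candidates(candidates, filter_config)
            matrix, totals = cooccurrence_matrix(candidates, filter_config)
            report["mining"] = {
                "n_input": len(universe),
                "n_accepted": len(candidates),
                "reject_counts": dict(sorted(reject_counts.items())),
                "summary": summary,
                "cooccurrence": {
                    "pairs": [
                        [c, s, int(matrix.loc[c, s])]
                        for c in matrix.index
                        for s in matrix.columns
                        if matrix.loc[c, s] > 0
                    ],
                    "totals": {dom: int(n) for dom, n in totals.items()},
                },
            }
            objects["decisions"] = decisions
            objects["candidates"] = candidates
            report["stages"]["mining"] = "ok"
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError("mining", exc) from exc
    else:
        report["stages"]["mining"] = "skipped"

    lectins: list[tuple[str, str]] = []
    if candidates:
        try:
            clusters = greedy_cluster(
                [(r.accession, r.sequence) for r in candidates],
                config.cluster_threshold,
                config.scoring,
            )
            lectins = []
            seq_by_acc = {r.accession: r.sequence for r in candidates}
            for cluster in clusters.clusters:
                lectins.append((cluster.centroid, seq_by_acc[cluster.centroid]))
            report["clustering"] = {
                "threshold": config.cluster_threshold,
                "n_input": len(candidates),
                "n_clusters": clusters.n_clusters,
                "cluster_sizes": sorted(
                    (len(c.members) for c in clusters.clusters), reverse=True
                ),
            }
            objects["clusters"] = clusters
            objects["lectins"] = lectins
            report["stages"]["clustering"] = "ok"
        except Exception as exc:
            raise PipelineError("clustering", exc) from exc
    else:
        report["stages"]["clustering"] = "skipped"

    if catalogs and lectins:
        try:
            matrix = build_presence_matrix(
                lectins,
                catalogs,
                config.match_threshold,
                config.min_coverage,
                config.scoring,
            )
            prevalence = prevalence_summary(matrix)
            overlap = site_overlap(matrix)
            curves = [rarefaction_curve(matrix, site) for site in matrix.sites()]
            report["prevalence"] = prevalence
            report["overlap"] = overlap
            report["top_prevalent"] = {
                site: top_prevalent(matrix, site, config.top_fraction)
                for site in matrix.sites()
            }
            report["rarefaction"] = {
                c.body_site: [[n + 1, float(v)] for n, v in enumerate(c.points)]
                for c in curves
            }
            objects["presence"] = matrix
            objects["rarefaction"] = curves
            report["stages"]["prevalence"] = "ok"
        except Exception as exc:
            raise PipelineError("prevalence", exc) from exc
    else:
        report["stages"]["prevalence"] = "skipped"

    if array_records:
        try:
            report["array"] = analyze_array(
                array_records, config.binder_threshold, config.max_motif_size
            )
            report["stages"]["array"] = "ok"
        except Exception as exc:
            raise PipelineError("array", exc) from exc
    else:
        report["stages"]["array"] = "skipped"

    report["_objects"] = objects
    return report
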