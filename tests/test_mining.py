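"""Candidate-lectin filtering, architectures and co-occurrence."""

import itertools

import pytest

from lectiscope.io import write_annotations, write_domain_table, write_fasta
from lectiscope.mining import (
    DEFAULT_EXCLUSION_KEYWORDS,
    DomainAnnotation,
    FilterConfig,
    ProteinRecord,
    classify_record,
    cooccurrence_matrix,
    derive_architecture,
    read_annotations,
    read_domain_table,
    read_protein_fasta,
    summarize_candidates,
)

CBM = "IPR033803"
CBM2 = "IPR024361"
FN3 = "IPR003961"
GH = "IPR017853"

CONFIG = FilterConfig(cbm_domain_ids=frozenset({CBM, CBM2}))


def record(
    domains,
    reviewed=False,
    description="uncharacterized protein",
    accession="P1",
    length=1000,
):
    return ProteinRecord(
        accession=accession,
        sequence="A" * length,
        domains=tuple(domains),
        reviewed=reviewed,
        description=description,
    )


def dom(domain_id, start, end, category="other"):
    return DomainAnnotation(domain_id, start, end, category)


class TestClassify:
    def test_fn3_plus_cbm_accepted(self):
        # the archetypal two-domain lectin architecture: Fn3 then CBM
        r = record([dom(FN3, 30, 120), dom(CBM, 700, 950, "carbohydrate_binding")])
        assert classify_record(r, CONFIG).accepted

    def test_catalytic_domain_rejected(self):
        r = record([dom(CBM, 1, 100, "carbohydrate_binding"), dom(GH, 200, 400, "catalytic")])
        assert classify_record(r, CONFIG) .reason == "catalytic"

    def test_keyword_rejected(self):
        r = record([dom(CBM, 1, 100, "carbohydrate_binding")],
                   description="putative fimbrial protein")
        assert classify_record(r, CONFIG).reason == "keyword"

    def test_reviewed_rejected(self):
        r = record([dom(CBM, 1, 100, "carbohydrate_binding")], reviewed=True)
        assert classify_record(r, CONFIG).reason == "reviewed"
        relaxed = FilterConfig(
            cbm_domain_ids=frozenset({CBM}), require_unreviewed=False
        )
        assert classify_record(r, relaxed).accepted

    def test_keyword_matching_is_whole_token_case_insensitive(self):
        base = [dom(CBM, 1, 100, "carbohydrate_binding")]
        # 'Fim' must not fire inside a longer word
        ok = record(base, description="fimbr-related uncharacterized protein")
        assert classify_record(ok, CONFIG).accepted
        hit = record(base, description="FIM protein homolog")
        assert classify_record(hit, CONFIG).reason == "keyword"
        # 'Fimbriae' fires through its own keyword, not through 'Fim'
        hit2 = record(base, description="involved in fimbriae assembly")
        assert classify_record(hit2, CONFIG).reason == "keyword"

    def test_case_sensitive_mode(self):
        strict = FilterConfig(
            cbm_domain_ids=frozenset({CBM}), keyword_case_sensitive=True
        )
        base = [dom(CBM, 1, 100, "carbohydrate_binding")]
        assert classify_record(
            record(base, description="fim protein"), strict
        ).accepted
        assert classify_record(
            record(base, description="Fim protein"), strict
        ).reason == "keyword"

    def test_first_failing_reason_over_all_rule_combinations(self):
        # enumerate all 2^4 violation patterns; the reported reason must be
        # the first violated rule in the fixed order
        order = ["no_cbm", "catalytic", "keyword", "reviewed"]
        for no_cbm, catalytic, keyword, reviewed in itertools.product(
            [False, True], repeat=4
        ):
            domains = [] if no_cbm else [dom(CBM, 1, 100, "carbohydrate_binding")]
            if catalytic:
                domains.append(dom(GH, 200, 300, "catalytic"))
            description = "putative membrane protein" if keyword else "unknown"
            r = record(domains, reviewed=reviewed, description=description)
            decision = classify_record(r, CONFIG)
            violated = [
                reason
                for reason, flag in zip(order, [no_cbm, catalytic, keyword, reviewed])
                if flag
            ]
            if violated:
                assert decision.reason == violated[0]
            else:
                assert decision.accepted

    def test_default_keyword_list_is_the_curated_exclusion_set(self):
        assert "SusD" in DEFAULT_EXCLUSION_KEYWORDS
        assert len(DEFAULT_EXCLUSION_KEYWORDS) == 30


class TestArchitecture:
    def test_nc_order(self):
        r = record([dom(CBM, 700, 950, "carbohydrate_binding"), dom(FN3, 30, 120)])
        assert derive_architecture(r) == (FN3, CBM)

    def test_empty(self):
        assert derive_architecture(record([])) == ()

    def test_tie_break_on_equal_start(self):
        r = record([dom("IPR_B", 10, 50), dom("IPR_A", 10, 40)])
        assert derive_architecture(r) == ("IPR_A", "IPR_B")

    def test_duplicate_domains_kept(self):
        r = record([dom(CBM, 1, 50, "carbohydrate_binding"),
                    dom(CBM, 100, 150, "carbohydrate_binding")])
        assert derive_architecture(r) == (CBM, CBM)


class TestSummaries:
    def test_shared_architecture(self):
        recs = [
            record([dom(CBM, 1, 50, "carbohydrate_binding"), dom(FN3, 60, 100)],
                   accession="P1"),
            record([dom(CBM, 1, 50, "carbohydrate_binding"), dom(FN3, 60, 100)],
                   accession="P2"),
        ]
        assert summarize_candidates(recs, CONFIG) == {
            "n_sequences": 2,
            "n_architectures": 1,
            "n_cbm_domains": 1,
            "n_secondary_domains": 1,
        }

    def test_empty(self):
        assert summarize_candidates([], CONFIG) == {
            "n_sequences": 0,
            "n_architectures": 0,
            "n_cbm_domains": 0,
            "n_secondary_domains": 0,
        }

    def test_distinct_architectures(self):
        recs = [
            record([dom(CBM, 1, 50, "carbohydrate_binding")], accession="P1"),
            record([dom(CBM, 1, 50, "carbohydrate_binding"), dom(FN3, 60, 100)],
                   accession="P2"),
            record([dom(CBM2, 1, 50, "carbohydrate_binding"), dom(FN3, 60, 100)],
                   accession="P3"),
        ]
        assert summarize_candidates(recs, CONFIG) == {
            "n_sequences": 3,
            "n_architectures": 3,
            "n_cbm_domains": 2,
            "n_secondary_domains": 1,
        }

    def test_invariant_to_record_order(self):
        recs = [
            record([dom(CBM, 1, 50, "carbohydrate_binding")], accession="P1"),
            record([dom(CBM2, 1, 50, "carbohydrate_binding"), dom(FN3, 60, 100)],
                   accession="P2"),
        ]
        assert summarize_candidates(recs, CONFIG) == summarize_candidates(
            recs[::-1], CONFIG
        )


class TestCooccurrence:
    def test_pairs_counted_once_per_record(self):
        r = record(
            [
                dom(CBM, 1, 50, "carbohydrate_binding"),
                dom(FN3, 60, 100),
                dom("IPR_Q", 120, 160),
            ]
        )
        matrix, totals = cooccurrence_matrix([r], CONFIG)
        assert matrix.loc[CBM, FN3] == 1 and matrix.loc[CBM, "IPR_Q"] == 1
        assert totals[CBM] == 1 and totals[FN3] == 1

    def test_cbm_only_record_contributes_total_no_pairs(self):
        r = record([dom(CBM, 1, 50, "carbohydrate_binding")])
        matrix, totals = cooccurrence_matrix([r], CONFIG)
        assert matrix.size == 0 and totals[CBM] == 1

    def test_counts_add_across_records(self):
        recs = [
            record([dom(CBM, 1, 50, "carbohydrate_binding"), dom(FN3, 60, 100)],
                   accession="P1"),
            record([dom(CBM, 1, 50, "carbohydrate_binding"), dom(FN3, 60, 100)],
                   accession="P2"),
        ]
        matrix, totals = cooccurrence_matrix(recs, CONFIG)
        assert matrix.loc[CBM, FN3] == 2
        assert (matrix.to_numpy() >= 0).all()

    def test_copy_number_ignored(self):
        r = record(
            [
                dom(CBM, 1, 50, "carbohydrate_binding"),
                dom(FN3, 60, 100),
                dom(FN3, 120, 180),
            ]
        )
        matrix, _ = cooccurrence_matrix([r], CONFIG)
        assert matrix.loc[CBM, FN3] == 1


class TestValidation:
    def test_domain_interval_must_fit_sequence(self):
        with pytest.raises(ValueError):
            record([dom(CBM, 1, 2000, "carbohydrate_binding")], length=100)

    def test_bad_interval_and_category(self):
        with pytest.raises(ValueError):
            DomainAnnotation(CBM, 50, 10, "other")
        with pytest.raises(ValueError):
            DomainAnnotation(CBM, 1, 10, "mystery")


def test_annotation_tsv_roundtrip(tmp_path):
    recs = [
        record([dom(FN3, 30, 120), dom(CBM, 200, 400, "carbohydrate_binding")],
               accession="P1", length=500),
        record([], accession="P2", description="no domains at all", length=50),
    ]
    fasta = tmp_path / "prot.fa"
    ann = tmp_path / "ann.tsv"
    table_path = tmp_path / "dom.tsv"
    write_fasta([(r.accession, r.sequence) for r in recs], fasta)
    write_annotations(recs, ann)
    write_domain_table(
        {FN3: "other", CBM: "carbohydrate_binding"}, table_path
    )
    table = read_domain_table(table_path)
    back = read_annotations(ann, read_protein_fasta(fasta), table)
    assert [(r.accession, r.domains, r.reviewed, r.description) for r in back] == [
        (r.accession, r.domains, r.reviewed, r.description) for r in recs
    ]
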