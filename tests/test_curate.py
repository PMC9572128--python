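"""Curation: adduct normalization, merge/deduplication, replicate statistics."""

import math

import pytest

from ccsfp.curate import (
    Adduct,
    AdductClass,
    CuratedDataset,
    Platform,
    RawCCSEntry,
    filter_adducts,
    merge_and_deduplicate,
    normalize_adduct,
    replicate_report_dataframe,
    replicate_stats,
)


def entry(smiles, adduct="[M+H]+", ccs=120.0, library="libA", source_id="x"):
    return RawCCSEntry(
        source_id=source_id, smiles=smiles, adduct_raw=adduct, ccs=ccs, library=library
    )


class TestNormalizeAdduct:
    @pytest.mark.parametrize(
        "raw, kind",
        [
            ("[M+H]+", AdductClass.M_PLUS_H),
            ("M+H", AdductClass.M_PLUS_H),
            ("[M + H]+", AdductClass.M_PLUS_H),
            ("(M+H)+", AdductClass.M_PLUS_H),
            ("[M-H]-", AdductClass.M_MINUS_H),
            ("M-H", AdductClass.M_MINUS_H),
            ("[M − H]−", AdductClass.M_MINUS_H),  # unicode minus
            ("[M]+.", AdductClass.M_RADICAL),
            ("[M].", AdductClass.M_RADICAL),
            ("[M]+•", AdductClass.M_RADICAL),
        ],
    )
    def test_dialects(self, raw, kind):
        assert normalize_adduct(raw).kind is kind

    def test_unknown_adducts_preserved_as_other(self):
        adduct = normalize_adduct("[M+Na]+")
        assert adduct.kind is AdductClass.OTHER
        assert adduct.label == "[M+Na]+"

    def test_empty_label_rejected_with_row(self):
        with pytest.raises(ValueError, match="row 17"):
            normalize_adduct("  ", row=17)


class TestMergeAndDeduplicate:
    def test_exact_triple_duplicate_collapsed_across_libraries(self):
        libs = [[entry("CCO", library="libA")], [entry("CCO", library="libB")]]
        ds = merge_and_deduplicate(libs)
        assert len(ds) == 1
        assert ds.records[0].library == "libA"  # first-library precedence

    def test_differing_ccs_values_all_retained(self):
        libs = [[entry("CCO", ccs=120.0), entry("CCO", ccs=123.0)]]
        assert len(merge_and_deduplicate(libs)) == 2

    def test_counting_with_one_duplicate(self):
        lib_a = [entry("CCO"), entry("CCC"), entry("CCN")]
        lib_b = [entry("CCO"), entry("CCCl")]
        assert len(merge_and_deduplicate([lib_a, lib_b])) == 4

    def test_canonicalization_unifies_smiles_dialects(self):
        libs = [[entry("OCC"), entry("C(C)O")]]  # both ethanol
        assert len(merge_and_deduplicate(libs)) == 1

    def test_ccs_precision_controls_duplicate_matching(self):
        libs = [[entry("CCO", ccs=120.04), entry("CCO", ccs=120.01)]]
        assert len(merge_and_deduplicate(libs, ccs_precision=1)) == 1
        assert len(merge_and_deduplicate(libs, ccs_precision=2)) == 2

    def test_unparseable_smiles_excluded_and_logged(self):
        libs = [[entry("not_a_smiles", source_id="bad1"), entry("CCO")]]
        ds = merge_and_deduplicate(libs)
        assert len(ds) == 1
        assert ds.provenance["n_parse_failures"] == 1
        assert ds.provenance["parse_failures"][0]["source_id"] == "bad1"

    def test_idempotent_on_own_output(self):
        libs = [
            [entry("CCO"), entry("CCO", ccs=123.0), entry("CCC")],
            [entry("CCO"), entry("c1ccccc1", adduct="[M+Na]+")],
        ]
        first = merge_and_deduplicate(libs)
        again = merge_and_deduplicate(
            [
                [
                    RawCCSEntry(r.source_id or "", r.canonical_smiles, r.adduct.display, r.ccs, r.library)
                    for r in first.records
                ]
            ]
        )
        assert {(r.canonical_smiles, r.adduct.key(), r.ccs) for r in again.records} == {
            (r.canonical_smiles, r.adduct.key(), r.ccs) for r in first.records
        }

    def test_record_count_bounded_by_input(self):
        libs = [[entry("CCO"), entry("CCC")], [entry("CCN")]]
        ds = merge_and_deduplicate(libs)
        assert len(ds) == 3  # equality iff no duplicates, no parse failures


class TestFilterAdducts:
    def test_sodiated_removed_protonated_kept(self):
        ds = merge_and_deduplicate(
            [[entry("CCO"), entry("CCC"), entry("CCN", adduct="[M+Na]+")]]
        )
        filtered = filter_adducts(ds)
        assert len(filtered) == 2
        assert all(r.adduct.kind is AdductClass.M_PLUS_H for r in filtered.records)
        assert filtered.provenance["n_adducts_removed"] == 1

    def test_per_adduct_counts_preserved(self):
        ds = merge_and_deduplicate(
            [
                [
                    entry("CCO"),
                    entry("CCC", adduct="[M-H]-"),
                    entry("CCN", adduct="[M]+."),
                    entry("CCS", adduct="[M+K]+"),
                ]
            ]
        )
        filtered = filter_adducts(ds)
        kinds = [r.adduct.kind for r in filtered.records]
        assert sorted(k.value for k in kinds) == ["M_MINUS_H", "M_PLUS_H", "M_RADICAL"]

    def test_empty_result_is_legal(self):
        ds = merge_and_deduplicate([[entry("CCO", adduct="[M+Na]+")]])
        assert len(filter_adducts(ds)) == 0


class TestReplicateStats:
    def test_sample_standard_deviation_arithmetic(self):
        ds = merge_and_deduplicate([[entry("CCO", ccs=100.0), entry("CCO", ccs=120.0)]])
        stats, summary = replicate_stats(ds)
        (s,) = stats
        assert s.n == 2
        assert s.mean_ccs == pytest.approx(110.0)
        assert s.sd_ccs == pytest.approx(14.1421, abs=1e-4)
        assert s.rsd_pct == pytest.approx(12.856, abs=1e-3)
        assert summary["median_rsd_pct"] == pytest.approx(12.856, abs=1e-3)

    def test_identical_replicates_have_zero_rsd(self):
        # distinct raw CCS that round to the same value survive dedup only if
        # they differ at the curation precision
        ds = merge_and_deduplicate(
            [[entry("CCO", ccs=150.0), entry("CCO", ccs=150.0, library="libB")]]
        )
        # exact duplicates collapse; force two records via different precision
        assert len(ds) == 1
        ds2 = CuratedDataset(records=ds.records * 2, provenance={})
        stats, _ = replicate_stats(ds2)
        assert stats[0].rsd_pct == 0.0

    def test_singletons_skipped_and_flagging(self):
        ds = merge_and_deduplicate(
            [
                [
                    entry("CCO", ccs=100.0),
                    entry("CCO", ccs=130.0),
                    entry("CCC", ccs=200.0),
                ]
            ]
        )
        stats, summary = replicate_stats(ds, flag_threshold_pct=10.0)
        assert len(stats) == 1
        assert len(summary["flagged"]) == 1  # rsd ~18% > 10%
        report = replicate_report_dataframe(stats)
        assert bool(report["flagged"].iloc[0])

    def test_order_invariance(self):
        lib = [entry("CCO", ccs=c) for c in (100.0, 110.0, 125.0)]
        a = replicate_stats(merge_and_deduplicate([lib]))[0]
        b = replicate_stats(merge_and_deduplicate([lib[::-1]]))[0]
        assert [(s.canonical_smiles, s.n, s.mean_ccs, s.sd_ccs) for s in a] == [
            (s.canonical_smiles, s.n, s.mean_ccs, s.sd_ccs) for s in b
        ]


def test_invalid_entries_rejected():
    with pytest.raises(ValueError, match="positive"):
        RawCCSEntry("x", "CCO", "[M+H]+", -5.0, "libA")
    with pytest.raises(ValueError, match="library"):
        RawCCSEntry("x", "CCO", "[M+H]+", 120.0, "")


def test_platform_parsing_defaults_to_unknown():
    assert Platform.parse("dtim") is Platform.DTIM
    assert Platform.parse("weird") is Platform.UNKNOWN
    assert Platform.parse(None) is Platform.UNKNOWN
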