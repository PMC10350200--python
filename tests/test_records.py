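"""Necropsy record classification, filtering and prevalence arithmetic."""

import numpy as np
import pandas as pd
import pytest

from oncophylo.records import (
    DiagnosisDictionary,
    ExclusionReport,
    NameMap,
    classify_record,
    compute_prevalence,
    filter_records,
    read_records_csv,
    resolve_names,
    write_records_csv,
)

from conftest import make_record


@pytest.mark.parametrize(
    "terms, expected",
    [
        (["lymphoma"], "malignant"),
        ([], "none"),
        (["adenoma", "hyperplasia"], "benign"),
        (["adenoma", "lymphoma"], "malignant"),  # malignant outranks benign
        (["hyperplasia"], "none"),  # non-neoplastic terms are ignored
        (["Lymphoma "], "malignant"),  # case/whitespace-folded match
    ],
)
def test_classify_record(toy_dictionary, terms, expected):
    rec = make_record(1, terms=terms)
    assert classify_record(rec, toy_dictionary) == expected


def test_unmapped_term_raises(toy_dictionary):
    rec = make_record(1, terms=["osteoma"])
    with pytest.raises(KeyError):
        classify_record(rec, toy_dictionary)


def test_dictionary_rejects_conflicts_and_empty():
    with pytest.raises(ValueError):
        DiagnosisDictionary({})
    with pytest.raises(ValueError):
        DiagnosisDictionary({"adenoma": "benign", "ADENOMA": "malignant"})
    with pytest.raises(ValueError):
        DiagnosisDictionary({"adenoma": "weird"})


def test_filter_records_keeps_order_and_counts():
    # 10 rows: 3 neonates, 2 tumour terms without histology -> 5 retained
    records = (
        [make_record(i, neonate=True) for i in range(3)]
        + [
            make_record(3 + i, terms=["adenoma"], histology_confirmed=False)
            for i in range(2)
        ]
        + [make_record(5 + i, terms=["lymphoma"]) for i in range(2)]
        + [make_record(7 + i) for i in range(3)]
    )
    report = ExclusionReport(n_input=len(records))
    kept = filter_records(records, report)
    assert [r.record_id for r in kept] == [f"R{i:04d}" for i in range(5, 10)]
    assert report.n_neonate == 3
    assert report.n_unconfirmed_histology == 2


def test_filter_keeps_tumour_free_unconfirmed_records():
    # nothing to confirm histologically when no neoplasm was suspected
    rec = make_record(1, terms=[], histology_confirmed=False)
    assert filter_records([rec]) == [rec]


def test_resolve_names_case_insensitive_and_reports_misses(toy_name_map):
    records = [
        make_record(1, common="Virginia Opossum"),
        make_record(2, common="virginia opossum"),
        make_record(3, common="mystery beast"),
    ]
    report = ExclusionReport()
    out = resolve_names(records, toy_name_map, report)
    assert [r.scientific_name for r in out] == ["Didelphis virginiana"] * 2
    assert report.n_unresolved_name == 1
    assert report.unresolved_names == {"mystery beast": 1}


def _ferret_records(n, k_neo, k_mal, start=0):
    recs = []
    for i in range(n):
        if i < k_mal:
            terms = ["lymphoma"]
        elif i < k_neo:
            terms = ["adenoma"]
        else:
            terms = []
        recs.append(
            make_record(start + i, terms=terms, scientific_name="Mustela putorius")
        )
    return recs


def test_compute_prevalence_arithmetic(toy_dictionary):
    prev = compute_prevalence(_ferret_records(20, 5, 2), toy_dictionary, min_n=20)
    row = prev.iloc[0]
    assert row["n"] == 20 and row["k_neo"] == 5 and row["k_mal"] == 2
    assert row["p_neo"] == 25.0
    assert row["p_mal"] == 10.0
    assert row["p_ben"] == 15.0
    assert row["mal_fraction"] == pytest.approx(0.4)


def test_compute_prevalence_zero_and_empty(toy_dictionary):
    prev = compute_prevalence(_ferret_records(30, 0, 0), toy_dictionary)
    assert prev.iloc[0]["p_neo"] == 0.0
    assert compute_prevalence([], toy_dictionary).empty


def test_prevalence_percent_identity_and_ordering_invariance(toy_dictionary, rng):
    records = _ferret_records(40, 13, 7)
    prev = compute_prevalence(records, toy_dictionary)
    shuffled = [records[i] for i in rng.permutation(len(records))]
    prev2 = compute_prevalence(shuffled, toy_dictionary)
    pd.testing.assert_frame_equal(prev, prev2)
    assert np.all(prev["p_ben"] + prev["p_mal"] == prev["p_neo"])


def test_min_n_filter_is_monotone(toy_dictionary):
    records = _ferret_records(25, 4, 1) + [
        make_record(100 + i, terms=[], scientific_name="Didelphis virginiana")
        for i in range(15)
    ]
    species = {
        m: set(compute_prevalence(records, toy_dictionary, min_n=m)["scientific_name"])
        for m in (10, 20, 30)
    }
    assert species[30] <= species[20] <= species[10]
    assert species[10] == {"Didelphis virginiana", "Mustela putorius"}
    assert species[20] == {"Mustela putorius"}


def test_unmapped_terms_excluded_with_report(toy_dictionary):
    records = _ferret_records(20, 2, 1) + [
        make_record(200, terms=["osteoma"], scientific_name="Mustela putorius")
    ]
    report = ExclusionReport()
    prev = compute_prevalence(records, toy_dictionary, min_n=20, report=report)
    assert prev.iloc[0]["n"] == 20  # excluded from the denominator too
    assert report.n_unmapped_term == 1
    assert report.unmapped_terms == {"osteoma": 1}


def test_removing_malignant_terms_zeroes_malignancy(toy_dictionary):
    records = _ferret_records(20, 6, 3)
    benign_only = toy_dictionary.without_class("malignant")
    report = ExclusionReport()
    prev = compute_prevalence(records, benign_only, min_n=1, report=report)
    # malignant records become unmapped and drop out, so no malignancies remain
    assert np.all(prev["p_mal"] == 0)
    assert report.n_unmapped_term == 3


def test_records_csv_round_trip(tmp_path, small_study):
    path = tmp_path / "records.csv"
    write_records_csv(small_study["records"], path)
    back = read_records_csv(path)
    assert back == small_study["records"]


def test_name_map_csv_round_trip(tmp_path, toy_name_map):
    path = tmp_path / "map.csv"
    toy_name_map.to_csv(path)
    back = NameMap.from_csv(path)
    assert back.lookup("Domestic Ferret") == "Mustela putorius"


# ------------------------------------------------------ property test

from hypothesis import given, settings
from hypothesis import strategies as st


@given(st.data())
@settings(deadline=None, max_examples=40, derandomize=True)
def test_prevalence_count_invariants_property(toy_dictionary, data):
    n = data.draw(st.integers(min_value=1, max_value=60))
    k_neo = data.draw(st.integers(min_value=0, max_value=n))
    k_mal = data.draw(st.integers(min_value=0, max_value=k_neo))
    prev = compute_prevalence(_ferret_records(n, k_neo, k_mal), toy_dictionary, min_n=1)
    row = prev.iloc[0]
    assert 0 <= row["p_mal"] <= row["p_neo"] <= 100
    # exact on integer counts; floating point leaves at most one ulp
    from fractions import Fraction

    assert Fraction(100 * (k_neo - k_mal), n) + Fraction(100 * k_mal, n) == Fraction(
        100 * k_neo, n
    )
    assert row["p_ben"] + row["p_mal"] == pytest.approx(row["p_neo"], abs=1e-10)
    assert row["k_mal"] <= row["k_neo"] <= row["n"]
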