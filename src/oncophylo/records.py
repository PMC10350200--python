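"""Record-level necropsy data: parsing, diagnosis classification, filtering,
and per-species prevalence.

The sampling unit is a necropsied animal. Each record carries the diagnosis
terms found at necropsy (possibly none), a histology-confirmation flag and a
neonate flag. A terminology dictionary maps diagnosis terms to ``benign``,
``malignant`` or ``non_neoplastic``; prevalence is computed per animal, so an
animal with several neoplasms counts once toward neoplasia prevalence and once
toward malignancy prevalence if any lesion is malignant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CLADES = ("Mammalia", "Sauropsida", "Amphibia")

#: diagnosis classes in increasing severity order
CLASS_NONE = "none"
CLASS_BENIGN = "benign"
CLASS_MALIGNANT = "malignant"
CLASS_NON_NEOPLASTIC = "non_neoplastic"

_DICT_CLASSES = frozenset({CLASS_BENIGN, CLASS_MALIGNANT, CLASS_NON_NEOPLASTIC})


def _norm_term(term: str) -> str:
    """Case-fold and collapse internal whitespace."""
    return " ".join(term.strip().casefold().split())


@dataclass(frozen=True)
class NecropsyRecord:
    """One animal's necropsy outcome."""

    record_id: str
    institution: str
    common_name: str
    clade: str
    diagnosis_terms: tuple[str, ...] = ()
    scientific_name: str | None = None
    age_at_death_months: float | None = None
    histology_confirmed: bool = True
    neonate: bool = False

    def __post_init__(self) -> None:
        if self.clade not in CLADES:
            raise ValueError(f"unknown clade {self.clade!r}; expected one of {CLADES}")
        if self.age_at_death_months is not None and self.age_at_death_months < 0:
            raise ValueError("age_at_death_months must be >= 0")


class DiagnosisDictionary:
    """Terminology dictionary mapping diagnosis terms to benign/malignant.

    Matching is exact on the case-folded, whitespace-normalized term; there is
    deliberately no stemming or fuzzy matching so that every classification is
    auditable against the dictionary file.
    """

    def __init__(self, mapping: Mapping[str, str]):
        if not mapping:
            raise ValueError("diagnosis dictionary must be non-empty")
        self._map: dict[str, str] = {}
        for term, cls in mapping.items():
            key = _norm_term(term)
            if cls not in _DICT_CLASSES:
                raise ValueError(f"term {term!r} has invalid class {cls!r}")
            if key in self._map and self._map[key] != cls:
                raise ValueError(f"term {term!r} maps to two classes")
            self._map[key] = cls

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, term: str) -> bool:
        return _norm_term(term) in self._map

    def lookup(self, term: str) -> str | None:
        return self._map.get(_norm_term(term))

    def terms(self, cls: str | None = None) -> list[str]:
        if cls is None:
            return sorted(self._map)
        return sorted(t for t, c in self._map.items() if c == cls)

    def without_class(self, cls: str) -> "DiagnosisDictionary":
        """Copy of the dictionary with every term of one class removed."""
        kept = {t: c for t, c in self._map.items() if c != cls}
        return DiagnosisDictionary(kept)

    @classmethod
    def from_csv(cls, path) -> "DiagnosisDictionary":
        df = pd.read_csv(path, comment="#")
        term_col, class_col = df.columns[:2]
        return cls(dict(zip(df[term_col].astype(str), df[class_col].astype(str))))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"term": sorted(self._map), "class": [self._map[t] for t in sorted(self._map)]}
        ).to_csv(path, index=False)


class NameMap:
    """Static common-name -> scientific-name table (case-insensitive lookup)."""

    def __init__(self, mapping: Mapping[str, str]):
        self._map = {_norm_term(k): str(v) for k, v in mapping.items()}

    def __len__(self) -> int:
        return len(self._map)

    def lookup(self, common_name: str) -> str | None:
        return self._map.get(_norm_term(common_name))

    @classmethod
    def from_csv(cls, path) -> "NameMap":
        df = pd.read_csv(path, comment="#")
        c1, c2 = df.columns[:2]
        return cls(dict(zip(df[c1].astype(str), df[c2].astype(str))))

    def to_csv(self, path) -> None:
        items = sorted(self._map.items())
        pd.DataFrame(items, columns=["common_name", "scientific_name"]).to_csv(
            path, index=False
        )


@dataclass
class ExclusionReport:
    """Book-keeping for records removed between raw input and prevalence.

    Nothing is dropped silently: every exclusion increments a counter here and
    is echoed through :mod:`logging`.
    """

    n_input: int = 0
    n_neonate: int = 0
    n_unconfirmed_histology: int = 0
    n_unresolved_name: int = 0
    n_unmapped_term: int = 0
    unresolved_names: dict[str, int] = field(default_factory=dict)
    unmapped_terms: dict[str, int] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [
            "exclusion report",
            f"  records in:               {self.n_input}",
            f"  neonates excluded:        {self.n_neonate}",
            f"  histology unconfirmed:    {self.n_unconfirmed_histology}",
            f"  unresolved common names:  {self.n_unresolved_name}",
            f"  unmapped diagnosis terms: {self.n_unmapped_term}",
        ]
        for name, k in sorted(self.unresolved_names.items()):
            lines.append(f"    unresolved name: {name!r} x{k}")
        for term, k in sorted(self.unmapped_terms.items()):
            lines.append(f"    unmapped term: {term!r} x{k}")
        return "\n".join(lines)


def classify_record(record: NecropsyRecord, dictionary: DiagnosisDictionary) -> str:
    """Classify one record as ``none``, ``benign`` or ``malignant``.

    Malignant wins over benign when both are present; terms mapping to
    ``non_neoplastic`` are ignored. A term absent from the dictionary raises
    :class:`KeyError` — callers aggregate these into the exclusion report
    rather than treating the record as tumour-free.
    """
    if len(dictionary) == 0:  # pragma: no cover - constructor forbids this
        raise ValueError("diagnosis dictionary must be non-empty")
    best = CLASS_NONE
    for term in record.diagnosis_terms:
        cls = dictionary.lookup(term)
        if cls is None:
            raise KeyError(term)
        if cls == CLASS_MALIGNANT:
            return CLASS_MALIGNANT
        if cls == CLASS_BENIGN:
            best = CLASS_BENIGN
    return best


def filter_records(
    records: Sequence[NecropsyRecord], report: ExclusionReport | None = None
) -> list[NecropsyRecord]:
    """Apply the record-level inclusion filters, preserving order.

    Neonates are excluded outright (to avoid the bias from high neonatal
    mortality); records reporting a suspect neoplasm that was never examined
    histologically are excluded. Records with no diagnosis terms are kept
    regardless of the histology flag — there was nothing to confirm.
    """
    out: list[NecropsyRecord] = []
    for rec in records:
        if rec.neonate:
            if report is not None:
                report.n_neonate += 1
            continue
        if rec.diagnosis_terms and not rec.histology_confirmed:
            if report is not None:
                report.n_unconfirmed_histology += 1
            continue
        out.append(rec)
    return out


def resolve_names(
    records: Sequence[NecropsyRecord],
    name_map: NameMap,
    report: ExclusionReport | None = None,
) -> list[NecropsyRecord]:
    """Fill ``scientific_name`` from the common-name table.

    Records whose common name has no mapping (and no pre-resolved scientific
    name) are dropped from the returned list and tallied in the report.
    """
    out: list[NecropsyRecord] = []
    for rec in records:
        if rec.scientific_name:
            out.append(rec)
            continue
        sci = name_map.lookup(rec.common_name)
        if sci is None:
            if report is not None:
                report.n_unresolved_name += 1
                report.unresolved_names[rec.common_name] = (
                    report.unresolved_names.get(rec.common_name, 0) + 1
                )
            logger.warning("unresolved common name: %r", rec.common_name)
            continue
        out.append(replace(rec, scientific_name=sci))
    return out


def compute_prevalence(
    records: Sequence[NecropsyRecord],
    dictionary: DiagnosisDictionary,
    min_n: int = 20,
    report: ExclusionReport | None = None,
) -> pd.DataFrame:
    """Per-species neoplasia and malignancy prevalence.

    Parameters
    ----------
    records
        Filtered, name-resolved records.
    dictionary
        Terminology dictionary used to classify each record.
    min_n
        Minimum necropsy count for a species to enter the table (default 20).
    report
        Optional exclusion report; records containing a diagnosis term absent
        from the dictionary are excluded from both numerator and denominator
        and tallied here.

    Returns
    -------
    DataFrame with one row per retained species and columns
    ``scientific_name, clade, n, k_neo, k_mal, p_neo, p_mal, p_ben,
    mal_fraction`` — prevalences on the percent scale, ``mal_fraction`` the
    proportion of tumour-bearing animals whose worst lesion is malignant
    (NaN when ``k_neo`` is zero).
    """
    counts: dict[str, dict] = {}
    for rec in records:
        if not rec.scientific_name:
            continue
        try:
            cls = classify_record(rec, dictionary)
        except KeyError as exc:
            term = exc.args[0]
            if report is not None:
                report.n_unmapped_term += 1
                report.unmapped_terms[term] = report.unmapped_terms.get(term, 0) + 1
            logger.warning(
                "record %s excluded: unmapped diagnosis term %r", rec.record_id, term
            )
            continue
        entry = counts.setdefault(
            rec.scientific_name, {"clade": rec.clade, "n": 0, "k_neo": 0, "k_mal": 0}
        )
        entry["n"] += 1
        if cls in (CLASS_BENIGN, CLASS_MALIGNANT):
            entry["k_neo"] += 1
        if cls == CLASS_MALIGNANT:
            entry["k_mal"] += 1

    rows = []
    for name in sorted(counts):
        e = counts[name]
        if e["n"] < min_n:
            continue
        n, k_neo, k_mal = e["n"], e["k_neo"], e["k_mal"]
        p_neo = 100.0 * k_neo / n
        p_mal = 100.0 * k_mal / n
        rows.append(
            {
                "scientific_name": name,
                "clade": e["clade"],
                "n": n,
                "k_neo": k_neo,
                "k_mal": k_mal,
                "p_neo": p_neo,
                "p_mal": p_mal,
                # defined as the difference so p_ben + p_mal == p_neo exactly
                "p_ben": p_neo - p_mal,
                "mal_fraction": (k_mal / k_neo) if k_neo > 0 else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "scientific_name",
            "clade",
            "n",
            "k_neo",
            "k_mal",
            "p_neo",
            "p_mal",
            "p_ben",
            "mal_fraction",
        ],
    )


# ---------------------------------------------------------------------------
# CSV interchange

RECORD_COLUMNS = [
    "record_id",
    "institution",
    "common_name",
    "scientific_name",
    "clade",
    "age_at_death_months",
    "diagnosis_terms",
    "histology_confirmed",
    "neonate",
]


def read_records_csv(path) -> list[NecropsyRecord]:
    """Read a record-level table; ``diagnosis_terms`` is semicolon-delimited."""
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records CSV missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        terms = tuple(t.strip() for t in row.diagnosis_terms.split(";") if t.strip())
        age = float(row.age_at_death_months) if row.age_at_death_months else None
        out.append(
            NecropsyRecord(
                record_id=row.record_id,
                institution=row.institution,
                common_name=row.common_name,
                scientific_name=row.scientific_name or None,
                clade=row.clade,
                age_at_death_months=age,
                diagnosis_terms=terms,
                histology_confirmed=_parse_bool(row.histology_confirmed),
                neonate=_parse_bool(row.neonate),
            )
        )
    return out


def write_records_csv(records: Iterable[NecropsyRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "record_id": r.record_id,
                "institution": r.institution,
                "common_name": r.common_name,
                "scientific_name": r.scientific_name or "",
                "clade": r.clade,
                "age_at_death_months": (
                    "" if r.age_at_death_months is None else r.age_at_death_months
                ),
                "diagnosis_terms": ";".join(r.diagnosis_terms),
                "histology_confirmed": r.histology_confirmed,
                "neonate": r.neonate,
            }
        )
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def _parse_bool(value: str) -> bool:
    v = str(value).strip().casefold()
    if v in {"true", "1", "yes", "t"}:
        return True
    if v in {"false", "0", "no", "f", ""}:
        return False
    raise ValueError(f"cannot parse boolean {value!r}")
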