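"""IEDB B-cell assay curation pipeline.

Takes an IEDB "full" CSV export of B-cell assay records and reproduces
the curation steps that isolate quantitative dose-response data on
antibody-mediated biological effects:

1. restrict to the antibody-dependent biological-activity assay types
   (the 14 method/technique categories of the B-cell assay tree);
2. keep only records whose "Quantitative measurement" field holds a
   numeric point estimate — drop empty values and drop bounds flagged by
   an inequality symbol in "Measurement Inequality";
3. convert the percentage measurements to effect quotients q, compute the
   binary Shannon entropy of each, and rank by decreasing q;
4. tabulate positive/negative record counts per assay type.

Column headers drift between IEDB export versions, so every logical field
is resolved through a user-overridable column map (YAML-friendly dict);
the defaults are the field names of the classic full-format export.  Both
the plain single-header dialect and the two-row grouped-header dialect
are read transparently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .errors import SchemaError, UnitError
from .informativeness import EffectObservation, percent_to_quotient, shannon_entropy

__all__ = [
    "AssayRecord",
    "CurationReport",
    "SummaryTable",
    "DEFAULT_COLUMN_MAP",
    "BIOLOGICAL_ACTIVITY_ASSAY_TYPES",
    "read_iedb_csv",
    "filter_biological_activity",
    "select_quantitative",
    "annotate_effects",
    "summarize_counts",
    "curate",
]

#: Logical field -> header text in the classic IEDB full-format export.
DEFAULT_COLUMN_MAP: Dict[str, str] = {
    "bcell_id": "BCell ID",
    "epitope_id": "Epitope ID",
    "pubmed_id": "PubMed ID",
    "epitope_type": "Type",
    "immunogen_epitope_relation": "1st Immunogen Epitope Relation",
    "method_technique": "Method/Technique",
    "qualitative_measure": "Qualitative Measure",
    "quantitative_measurement": "Quantitative measurement",
    "measurement_inequality": "Measurement Inequality",
    "assay_type_units": "Assay Type Units",
}

#: The 14 antibody-dependent biological-activity assay types.
BIOLOGICAL_ACTIVITY_ASSAY_TYPES: Tuple[str, ...] = (
    "Ab-dependent Phagocytosis/opsonization",
    "Antibody-dependent cellular cytotoxicity",
    "Complement-dependent cytotoxicity",
    "Enhancement/activation of antigen activity",
    "Exacerbation of disease after treatment",
    "Hypersensitivity",
    "Ig-mediated histamine release",
    "Induction of tolerance",
    "Inhibition of Ab biological activity",
    "Neutralization/inhibition of antigen activity",
    "Protection after challenge",
    "Protection from fertility",
    "Reduction of disease after treatment",
    "Survival after challenge",
)

#: Assay types whose readout is an inhibition percentage.
_INHIBITION_TYPES = frozenset({"neutralization/inhibition of antigen activity"})
#: Assay types whose readout is a survival/protection percentage.
_SURVIVAL_TYPES = frozenset({"survival after challenge", "protection after challenge"})

_INEQUALITY_SYMBOLS = ("<", ">", "≤", "≥", "<=", ">=")


def _norm(text: str) -> str:
    """Case-fold and collapse internal whitespace for tolerant matching."""
    return re.sub(r"\s+", " ", str(text).strip()).lower()


@dataclass
class AssayRecord:
    """One IEDB B-cell assay record (one CSV row)."""

    bcell_id: str
    epitope_id: str = ""
    pubmed_id: str = ""
    epitope_type: str = ""
    immunogen_epitope_relation: str = ""
    method_technique: str = ""
    qualitative_measure: str = ""
    quantitative_measurement: str = ""
    measurement_inequality: str = ""
    assay_type_units: str = ""
    extras: Dict[str, str] = field(default_factory=dict)


@dataclass
class SummaryTable:
    """Per-assay-type record counts with positive/negative split.

    ``rows`` maps the canonical method/technique name to a dict with keys
    ``total``, ``positive``, ``negative``; qualitative values that map to
    neither polarity are tallied in ``unclassified`` (kept out of the
    positive/negative sums so each row still satisfies
    total = positive + negative + unclassified).
    """

    rows: Dict[str, Dict[str, int]] = field(default_factory=dict)

    @property
    def grand_total(self) -> int:
        return sum(r["total"] for r in self.rows.values())

    @property
    def grand_positive(self) -> int:
        return sum(r["positive"] for r in self.rows.values())

    @property
    def grand_negative(self) -> int:
        return sum(r["negative"] for r in self.rows.values())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {"method_technique": k, **v}
                for k, v in sorted(self.rows.items())
            ],
            columns=["method_technique", "total", "positive", "negative", "unclassified"],
        )
        return df


@dataclass
class CurationReport:
    """Tallies and products of a full curation run."""

    n_input: int
    n_scope_excluded: int
    n_excluded_assay_type: int
    n_excluded_empty: int
    n_excluded_inequality: int
    n_excluded_nonnumeric: int
    n_quantitative: int
    records: List[EffectObservation] = field(default_factory=list)
    quantitative_records: List[AssayRecord] = field(default_factory=list)
    counts: Optional[SummaryTable] = None

    def tallies(self) -> Dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_scope_excluded": self.n_scope_excluded,
            "n_excluded_assay_type": self.n_excluded_assay_type,
            "n_excluded_empty": self.n_excluded_empty,
            "n_excluded_inequality": self.n_excluded_inequality,
            "n_excluded_nonnumeric": self.n_excluded_nonnumeric,
            "n_quantitative": self.n_quantitative,
        }


def _resolve_columns(
    columns: Sequence[str], column_map: Mapping[str, str]
) -> Optional[Dict[str, str]]:
    """Map logical fields to actual headers, or None if any is missing."""
    normed = {_norm(c): c for c in columns}
    resolved = {}
    for logical, header in column_map.items():
        actual = normed.get(_norm(header))
        if actual is None:
            return None
        resolved[logical] = actual
    return resolved


def read_iedb_csv(
    path, column_map: Optional[Mapping[str, str]] = None
) -> List[AssayRecord]:
    """Read an IEDB full-format B-cell CSV into assay records.

    ``column_map`` overrides entries of :data:`DEFAULT_COLUMN_MAP`
    (logical field name -> header text).  Exports with a two-row grouped
    header (group labels above field names) are detected and read from
    their second header row.  Unknown extra columns are preserved in each
    record's ``extras``.

    Raises :class:`SchemaError` listing the unresolved fields if required
    columns are missing, or on malformed CSV (with the offending line).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    def _read(skiprows: int) -> pd.DataFrame:
        return pd.read_csv(
            path,
            dtype=str,
            keep_default_na=False,
            skiprows=skiprows,
            skipinitialspace=True,
        )

    try:
        df = _read(0)
    except pd.errors.ParserError as exc:
        raise SchemaError(f"malformed CSV: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise SchemaError("empty CSV file") from exc

    resolved = _resolve_columns(df.columns, cmap)
    if resolved is None and len(df) > 0:
        # two-row grouped-header dialect: field names live on the 2nd row
        if hasattr(path, "seek"):
            path.seek(0)
        try:
            df2 = _read(1)
        except (pd.errors.ParserError, pd.errors.EmptyDataError):
            df2 = None
        if df2 is not None:
            resolved2 = _resolve_columns(df2.columns, cmap)
            if resolved2 is not None:
                df, resolved = df2, resolved2
    if resolved is None:
        missing = [
            f"{logical} ({header!r})"
            for logical, header in cmap.items()
            if _resolve_columns(df.columns, {logical: header}) is None
        ]
        raise SchemaError("missing required columns: " + ", ".join(missing))

    known = set(resolved.values())
    records: List[AssayRecord] = []
    seen_ids = set()
    for i, row in df.iterrows():
        fields = {logical: str(row[actual]).strip() for logical, actual in resolved.items()}
        extras = {c: str(row[c]) for c in df.columns if c not in known}
        rec = AssayRecord(extras=extras, **fields)
        if not rec.bcell_id:
            raise SchemaError(f"row {i + 2}: empty bcell_id")
        if rec.bcell_id in seen_ids:
            raise SchemaError(f"row {i + 2}: duplicate bcell_id {rec.bcell_id!r}")
        seen_ids.add(rec.bcell_id)
        records.append(rec)
    return records


def filter_scope(
    records: Sequence[AssayRecord],
    epitope_type: str = "Linear peptide",
    immunogen_epitope_relation: str = "Epitope",
) -> Tuple[List[AssayRecord], List[AssayRecord]]:
    """Optional pre-filter to the linear-peptide / epitope-immunogen scope.

    Records with a blank value in either field pass (the export may simply
    omit them).  Returns (kept, excluded).
    """
    kept, excluded = [], []
    for rec in records:
        type_ok = (not rec.epitope_type) or _norm(rec.epitope_type) == _norm(epitope_type)
        rel_ok = (not rec.immunogen_epitope_relation) or _norm(
            rec.immunogen_epitope_relation
        ) == _norm(immunogen_epitope_relation)
        (kept if type_ok and rel_ok else excluded).append(rec)
    return kept, excluded


def filter_biological_activity(
    records: Sequence[AssayRecord],
    assay_types: Sequence[str] = BIOLOGICAL_ACTIVITY_ASSAY_TYPES,
) -> Tuple[List[AssayRecord], List[AssayRecord]]:
    """Partition records into biological-activity assays vs everything else.

    Matching on method/technique is case-insensitive after whitespace
    normalization.  Returns (kept, excluded).
    """
    allowed = {_norm(t) for t in assay_types}
    kept, excluded = [], []
    for rec in records:
        (kept if _norm(rec.method_technique) in allowed else excluded).append(rec)
    return kept, excluded


def select_quantitative(
    records: Sequence[AssayRecord],
) -> Tuple[List[AssayRecord], Dict[str, List[AssayRecord]]]:
    """Keep records carrying a numeric point-estimate measurement.

    Excluded, under separate tallies: records with an empty
    "Quantitative measurement"; records whose "Measurement Inequality"
    holds an inequality symbol (the value is a bound, not a point
    estimate); records with a non-numeric non-empty measurement (warned).

    Returns (kept, {"empty": [...], "inequality": [...], "nonnumeric": [...]}).
    """
    import warnings

    kept: List[AssayRecord] = []
    excluded: Dict[str, List[AssayRecord]] = {"empty": [], "inequality": [], "nonnumeric": []}
    for rec in records:
        meas = rec.quantitative_measurement.strip()
        ineq = rec.measurement_inequality.strip()
        if ineq:
            if ineq not in _INEQUALITY_SYMBOLS:
                warnings.warn(
                    f"record {rec.bcell_id}: unrecognized inequality {ineq!r}; "
                    "excluding as a bound",
                    stacklevel=2,
                )
            excluded["inequality"].append(rec)
            continue
        if not meas:
            excluded["empty"].append(rec)
            continue
        try:
            float(meas.rstrip("%").strip())
        except ValueError:
            warnings.warn(
                f"record {rec.bcell_id}: non-numeric measurement {meas!r} excluded",
                stacklevel=2,
            )
            excluded["nonnumeric"].append(rec)
            continue
        kept.append(rec)
    return kept, excluded


def assay_category(method_technique: str) -> str:
    """Map a method/technique name to {inhibition, survival, other}."""
    m = _norm(method_technique)
    if m in _INHIBITION_TYPES:
        return "inhibition"
    if m in _SURVIVAL_TYPES:
        return "survival"
    return "other"


def annotate_effects(
    records: Sequence[AssayRecord], *, strict_units: bool = True
) -> List[EffectObservation]:
    """Convert percentage measurements to ranked effect observations.

    Each record's measurement (a percentage) becomes the quotient
    q = value/100, annotated with its binary Shannon entropy in bits and
    an assay category.  The returned list is ranked by decreasing q, ties
    broken by ascending bcell_id so the ranking is deterministic.

    Under strict units (default) the "Assay Type Units" string must
    contain a percent sign; with ``strict_units=False`` records with blank
    units but a measurement in [0, 100] are accepted with a warning.
    """
    import warnings

    obs: List[EffectObservation] = []
    for rec in records:
        units = rec.assay_type_units.strip()
        value_text = rec.quantitative_measurement
        if "%" not in units:
            if strict_units or units:
                raise UnitError(
                    f"record {rec.bcell_id}: units {units!r} not recognized "
                    "as a percentage"
                )
            warnings.warn(
                f"record {rec.bcell_id}: blank units, assuming percentage",
                stacklevel=2,
            )
        q = percent_to_quotient(value_text)
        obs.append(
            EffectObservation(
                q=q,
                entropy=float(shannon_entropy(q)),
                assay_category=assay_category(rec.method_technique),
                source_id=rec.bcell_id,
            )
        )
    obs.sort(key=lambda o: (-o.q, str(o.source_id)))
    return obs


_POSITIVE_PREFIX = "positive"
_NEGATIVE_PREFIX = "negative"


def summarize_counts(records: Sequence[AssayRecord]) -> SummaryTable:
    """Per-assay-type totals with a positive/negative split.

    Qualitative variants ("Positive-High", "Positive-Low",
    "Positive-Intermediate", ...) fold into Positive, and likewise for
    Negative.  Anything else is warned about and tallied as unclassified,
    outside the positive/negative sums.
    """
    import warnings

    canonical = {_norm(t): t for t in BIOLOGICAL_ACTIVITY_ASSAY_TYPES}
    table = SummaryTable()
    for rec in records:
        name = canonical.get(_norm(rec.method_technique), rec.method_technique)
        row = table.rows.setdefault(
            name, {"total": 0, "positive": 0, "negative": 0, "unclassified": 0}
        )
        row["total"] += 1
        qual = _norm(rec.qualitative_measure)
        if qual.startswith(_POSITIVE_PREFIX):
            row["positive"] += 1
        elif qual.startswith(_NEGATIVE_PREFIX):
            row["negative"] += 1
        else:
            warnings.warn(
                f"record {rec.bcell_id}: unmappable qualitative value "
                f"{rec.qualitative_measure!r}",
                stacklevel=2,
            )
            row["unclassified"] += 1
    return table


def curate(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    *,
    apply_scope_filter: bool = False,
    strict_units: bool = True,
) -> CurationReport:
    """Run the full curation pipeline on an IEDB B-cell CSV export.

    Read -> (optional scope pre-filter) -> biological-activity assay-type
    restriction -> quantitative point-estimate selection -> percent-to-q
    conversion with entropy annotation and decreasing-q ranking.  The
    positive/negative summary table is computed over all
    biological-activity records (quantitative or not), mirroring how the
    assay-type breakdown is reported for a full retrieval.

    The report's tallies partition the input exactly:
    n_input = n_scope_excluded + n_excluded_assay_type + n_excluded_empty
    + n_excluded_inequality + n_excluded_nonnumeric + n_quantitative.
    """
    records = read_iedb_csv(path, column_map)
    n_input = len(records)
    if apply_scope_filter:
        records, scope_excluded = filter_scope(records)
    else:
        scope_excluded = []
    bio, non_bio = filter_biological_activity(records)
    quant, excl = select_quantitative(bio)
    observations = annotate_effects(quant, strict_units=strict_units)
    counts = summarize_counts(bio)
    return CurationReport(
        n_input=n_input,
        n_scope_excluded=len(scope_excluded),
        n_excluded_assay_type=len(non_bio),
        n_excluded_empty=len(excl["empty"]),
        n_excluded_inequality=len(excl["inequality"]),
        n_excluded_nonnumeric=len(excl["nonnumeric"]),
        n_quantitative=len(quant),
        records=observations,
        quantitative_records=list(quant),
        counts=counts,
    )


_QUANT_COLUMNS = [
    "rank",
    "bcell_id",
    "epitope_id",
    "pubmed_id",
    "method_technique",
    "assay_category",
    "q",
    "entropy_bits",
]


def quantitative_frame(report: CurationReport) -> pd.DataFrame:
    """Ranked quantitative records as a DataFrame ready for CSV output."""
    by_id = {r.bcell_id: r for r in report.quantitative_records}
    rows = []
    for i, o in enumerate(report.records):
        rec = by_id.get(o.source_id)
        rows.append(
            {
                "rank": i + 1,
                "bcell_id": o.source_id,
                "epitope_id": rec.epitope_id if rec else "",
                "pubmed_id": rec.pubmed_id if rec else "",
                "method_technique": rec.method_technique if rec else "",
                "assay_category": o.assay_category,
                "q": o.q,
                "entropy_bits": o.entropy,
            }
        )
    return pd.DataFrame(rows, columns=_QUANT_COLUMNS)
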