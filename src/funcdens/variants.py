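"""Variant functional-measurement tables: parsing, WT normalization,
cell-system selection, and replicate aggregation.

Electrophysiology reports are heterogeneous: each publication measures a
mutant channel alongside its own wild-type control, in some expression
system, for one or more gating parameters.  The pipeline here reduces that
to a single wild-type-referenced value per (gene, position, substitution,
parameter):

1. every report is normalized to the same-publication WT — ratio parameters
   (currents, time constants) become percent of WT, voltage-dependence
   parameters become mV shifts;
2. for each variant/parameter, only reports from the highest-preference
   cell system present are kept (falling back to everything else when no
   preferred system was used);
3. remaining replicate reports are averaged (unweighted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PARAMETERS",
    "RATIO_PARAMETERS",
    "SHIFT_PARAMETERS",
    "VariantMeasurement",
    "NormalizedVariant",
    "VariantTable",
    "SchemaError",
    "NormalizationError",
    "read_variant_table",
    "normalize_to_wt",
    "select_cell_system",
    "aggregate_replicates",
    "process_variant_table",
    "variant_key",
]

#: Functional parameters with a defined WT-normalization rule.
RATIO_PARAMETERS = frozenset(
    {"peak_current", "late_current", "recovery_inact", "tau_act", "tau_deact"}
)
SHIFT_PARAMETERS = frozenset({"v_half_act", "v_half_inact"})
PARAMETERS = tuple(sorted(RATIO_PARAMETERS | SHIFT_PARAMETERS))

REQUIRED_COLUMNS = (
    "gene",
    "seq_position",
    "ref_aa",
    "alt_aa",
    "parameter",
    "mutant_value",
    "wt_value",
    "cell_system",
    "source_id",
)

#: Optional column marking the expression protocol; used by the
#: homomeric-only filter (heteromeric/heterozygous rows dropped by default).
EXPRESSION_COLUMN = "expression_mode"


class SchemaError(ValueError):
    """The variant table is missing a required column."""


class NormalizationError(ValueError):
    """A measurement cannot be normalized (e.g. WT value of zero in ratio mode)."""


@dataclass(frozen=True)
class VariantMeasurement:
    """One raw functional report for one variant and one parameter."""

    gene: str
    seq_position: int
    ref_aa: str
    alt_aa: str
    parameter: str
    mutant_value: float
    wt_value: float
    cell_system: str
    source_id: str
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"{self.gene} {self.seq_position}: ref_aa == alt_aa ({self.ref_aa})")
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")


@dataclass(frozen=True)
class NormalizedVariant:
    """WT-referenced functional perturbation Δfunction for one variant.

    ``delta_function`` is percent-of-WT for ratio parameters (WT = 100) and
    a shift in mV for voltage-dependence parameters (WT = 0).
    """

    gene: str
    seq_position: int
    ref_aa: str
    alt_aa: str
    parameter: str
    delta_function: float
    n_reports: int = 1
    cell_system_used: str = ""
    extra: dict = field(default_factory=dict, compare=False)

def variant_key(v) -> tuple:
    """Aggregation key: one record per (gene, position, alt_aa, parameter)."""
    return (v.gene, int(v.seq_position), v.alt_aa, v.parameter)


@dataclass
class VariantTable:
    """Parsed variant table: typed records plus pass-through predictor columns."""

    records: list[VariantMeasurement]
    predictor_columns: list[str]
    rejected: list[tuple[int, str]]  # (row number, reason)


def read_variant_table(path: str | Path, sep: str | None = None) -> VariantTable:
    """Read a delimited variant measurement table.

    Unknown numeric columns are carried through on each record's ``extra``
    dict and registered as candidate predictors.  Rows with an unknown
    parameter or unparseable numerics are rejected with row-level
    diagnostics rather than aborting the parse.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    extra_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS and c != EXPRESSION_COLUMN]

    records: list[VariantMeasurement] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            extra = {}
            for c in extra_cols:
                raw = row[c]
                extra[c] = float(raw) if raw not in ("", "NA", "nan") else np.nan
            if EXPRESSION_COLUMN in df.columns:
                extra[EXPRESSION_COLUMN] = row[EXPRESSION_COLUMN]
            rec = VariantMeasurement(
                gene=row["gene"],
                seq_position=int(row["seq_position"]),
                ref_aa=row["ref_aa"],
                alt_aa=row["alt_aa"],
                parameter=row["parameter"],
                mutant_value=float(row["mutant_value"]),
                wt_value=float(row["wt_value"]),
                cell_system=row["cell_system"],
                source_id=row["source_id"],
                extra=extra,
            )
        except (ValueError, KeyError) as exc:
            rejected.append((i, str(exc)))
            logger.warning("%s row %d rejected: %s", path.name, i, exc)
            continue
        records.append(rec)
    return VariantTable(records=records, predictor_columns=extra_cols, rejected=rejected)


def normalize_to_wt(m: VariantMeasurement) -> NormalizedVariant:
    """Normalize one report to its same-publication wild-type.

    Ratio parameters: 100 × mutant/WT (percent of WT).
    Shift parameters: mutant − WT (mV).
    """
    if m.parameter in RATIO_PARAMETERS:
        if m.wt_value == 0:
            raise NormalizationError(
                f"{m.gene} {m.ref_aa}{m.seq_position}{m.alt_aa} {m.parameter}: WT value is zero"
            )
        delta = 100.0 * m.mutant_value / m.wt_value
    else:
        delta = m.mutant_value - m.wt_value
    return NormalizedVariant(
        gene=m.gene,
        seq_position=m.seq_position,
        ref_aa=m.ref_aa,
        alt_aa=m.alt_aa,
        parameter=m.parameter,
        delta_function=delta,
        n_reports=1,
        cell_system_used=m.cell_system,
        extra=dict(m.extra),
    )


def select_cell_system(records: Sequence, preference: Sequence[str]) -> list:
    """Keep, per (variant, parameter), only the highest-preference cell system.

    When none of the preferred systems was used for a variant, all of its
    records are kept — preference applies only "when available".
    """
    if not preference:
        raise ValueError("preference list must be nonempty")
    for r in records:
        if not hasattr(r, "cell_system"):
            # aggregated records no longer carry a raw cell system: selection
            # must happen before replicate averaging, never after
            raise TypeError(
                "select_cell_system requires raw (pre-aggregation) measurement records"
            )
    rank = {sys: i for i, sys in enumerate(preference)}
    groups: dict[tuple, list] = {}
    for r in records:
        groups.setdefault(variant_key(r), []).append(r)
    kept: list = []
    for recs in groups.values():
        ranks = [rank.get(r.cell_system, len(preference)) for r in recs]
        best = min(ranks)
        if best < len(preference):
            kept.extend(r for r, k in zip(recs, ranks) if k == best)
        else:
            kept.extend(recs)
    return kept


def aggregate_replicates(records: Sequence[NormalizedVariant]) -> list[NormalizedVariant]:
    """Average replicate WT-normalized reports per variant and parameter.

    The mean is unweighted; records must already be cell-system-filtered.
    Pass-through predictor values take the first non-missing report.
    """
    groups: dict[tuple, list[NormalizedVariant]] = {}
    for r in records:
        groups.setdefault(variant_key(r), []).append(r)
    out: list[NormalizedVariant] = []
    for key, recs in groups.items():
        delta = float(np.mean([r.delta_function for r in recs]))
        systems = sorted({r.cell_system_used for r in recs})
        extra: dict = {}
        for r in recs:
            for k, v in r.extra.items():
                if k not in extra or (isinstance(extra[k], float) and np.isnan(extra[k])):
                    extra[k] = v
        out.append(
            NormalizedVariant(
                gene=key[0],
                seq_position=key[1],
                ref_aa=recs[0].ref_aa,
                alt_aa=key[2],
                parameter=key[3],
                delta_function=delta,
                n_reports=sum(r.n_reports for r in recs),
                cell_system_used=";".join(systems),
                extra=extra,
            )
        )
    out.sort(key=variant_key)
    return out


DEFAULT_CELL_PREFERENCE: dict[str, tuple[str, ...]] = {
    "SCN5A": ("HEK293",),
    "KCNQ1": ("CHO",),
}


def process_variant_table(
    records: Iterable[VariantMeasurement],
    cell_preference: Sequence[str] | dict[str, Sequence[str]] | None = None,
    homomeric_only: bool = True,
) -> list[NormalizedVariant]:
    """Full reduction: filter → cell-system selection → normalize → average.

    The stage order is fixed: cell-system selection must precede replicate
    averaging (averaging across systems and then selecting would change the
    result).  ``cell_preference`` may be one list for all genes or a mapping
    gene → preference list; genes without an entry fall back to the
    defaults for SCN5A/KCNQ1 and otherwise to no preference.
    """
    records = list(records)
    if homomeric_only:
        n0 = len(records)
        records = [
            r for r in records
            if r.extra.get(EXPRESSION_COLUMN, "homomeric") in ("", "homomeric")
        ]
        if len(records) != n0:
            logger.info("dropped %d heteromeric/heterozygous records", n0 - len(records))

    by_gene: dict[str, list[VariantMeasurement]] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)

    normalized: list[NormalizedVariant] = []
    for gene, recs in by_gene.items():
        if isinstance(cell_preference, dict):
            pref = cell_preference.get(gene) or DEFAULT_CELL_PREFERENCE.get(gene)
        elif cell_preference is not None:
            pref = cell_preference
        else:
            pref = DEFAULT_CELL_PREFERENCE.get(gene)
        if pref:
            recs = select_cell_system(recs, list(pref))
        for r in recs:
            try:
                normalized.append(normalize_to_wt(r))
            except NormalizationError as exc:
                logger.warning("skipping record: %s", exc)
    return aggregate_replicates(normalized)


def to_frame(variants: Sequence[NormalizedVariant]) -> pd.DataFrame:
    """Aggregated variants as a DataFrame (the canonical exchange table)."""
    rows = []
    for v in variants:
        row = {
            "gene": v.gene,
            "seq_position": v.seq_position,
            "ref_aa": v.ref_aa,
            "alt_aa": v.alt_aa,
            "parameter": v.parameter,
            "delta_function": v.delta_function,
            "n_reports": v.n_reports,
            "cell_system_used": v.cell_system_used,
        }
        row.update({k: val for k, val in v.extra.items() if k != EXPRESSION_COLUMN})
        rows.append(row)
    return pd.DataFrame(rows)
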