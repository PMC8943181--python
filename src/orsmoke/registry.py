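"""Harmful-VOC compound panel: identities, hazard classes and exposure limits.

The packaged registry transcribes the 32-compound panel of irritating, toxic,
carcinogenic and/or mutagenic VOCs observed in operating-room air during
electrocautery use, together with the OSHA/NIOSH permissible exposure limits
and the average/maximum concentrations reported for measurements at surgeon
level without smoke evacuation.  Rows covering several isobaric compounds
(which proton-transfer-reaction MS cannot separate) are kept as a single
record named by the slash-joined label, carrying every CAS number; the
molecular formula and weight are those of the first-listed compound.

Two limit cells (methanol, ethanol) are printed on a doubtful unit scale in
the source table; they are transcribed verbatim in ppb and carry
``limit_suspect=True`` so that downstream exceedance screens can report them
separately instead of silently trusting them.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import pandas as pd

from .errors import FormatError, ParameterError, ValidationError

__all__ = [
    "HAZARD_FLAGS",
    "CompoundRecord",
    "CompoundTable",
    "load_registry",
    "write_registry",
    "protonated_mass",
    "applicable_limit",
    "PRINTED_AVG_TOTAL_PPB",
    "PRINTED_MAX_TOTAL_PPB",
]

#: Hazard vocabulary used by the panel.
HAZARD_FLAGS = frozenset(
    {
        "carcinogenic",
        "mutagenic",
        "teratogenic",
        "acute_toxic",
        "corrosive",
        "irritant",
        "odor",
    }
)

#: Totals printed in the source panel for the average and maximum columns.
#: The maximum column actually sums to 9991.01 ppb; the printed 8991 cannot be
#: reconciled with the column and both values are reported side by side.
PRINTED_AVG_TOTAL_PPB = 272.69
PRINTED_MAX_TOTAL_PPB = 8991.0

# Monoisotopic masses (u) of the elements admissible in panel formulas.
_MONOISOTOPIC = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "S": 31.97207100,
    "F": 18.99840322,
    "Cl": 34.96885268,
}

#: Mass of a proton (u); PTR ionization adds one to each neutral molecule.
PROTON_MASS = 1.00727646688

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

_REQUIRED_COLUMNS = [
    "name",
    "cas",
    "formula",
    "mw_g_mol",
    "hazards",
    "limit_osha_ppb",
    "limit_niosh_ppb",
    "limit_suspect",
    "avg_ppb_paper",
    "max_ppb_paper",
]


def protonated_mass(formula: str) -> float:
    """Exact mass (Th) of the protonated molecule ``[M+H]+``.

    PTR-MS detects VOCs after proton transfer from H3O+, so the observed m/z
    of a singly charged ion is the monoisotopic neutral mass plus one proton.

    Parameters
    ----------
    formula:
        Molecular formula using the elements C, H, N, O, S, F, Cl
        (e.g. ``"C2H4O"`` for acetaldehyde).
    """
    if not formula:
        raise ParameterError("empty molecular formula")
    mass = 0.0
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ParameterError(f"cannot parse formula {formula!r} at position {pos}")
        symbol, count = match.group(1), match.group(2)
        if symbol not in _MONOISOTOPIC:
            raise ParameterError(f"unknown element {symbol!r} in formula {formula!r}")
        mass += _MONOISOTOPIC[symbol] * (int(count) if count else 1)
        pos = match.end()
    if pos != len(formula):
        raise ParameterError(f"cannot parse formula {formula!r} at position {pos}")
    return mass + PROTON_MASS


@dataclass(frozen=True)
class CompoundRecord:
    """One harmful-panel entry: identity, hazard classes and limits.

    Concentrations and limits are ppb by volume.  ``limit_osha_ppb`` /
    ``limit_niosh_ppb`` are ``None`` when the source table lists no limit;
    limits printed without an agency attribution are stored in the OSHA slot.
    """

    name: str
    cas_numbers: tuple[str, ...]
    formula: str
    molecular_weight: float
    hazard_flags: frozenset[str]
    limit_osha_ppb: float | None = None
    limit_niosh_ppb: float | None = None
    limit_suspect: bool = False
    avg_ppb_paper: float = 0.0
    max_ppb_paper: float = 0.0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("compound name must be non-empty")
        if self.molecular_weight <= 0:
            raise ValidationError(f"{self.name}: molecular weight must be > 0")
        if not self.hazard_flags:
            raise ValidationError(f"{self.name}: hazard_flags must be non-empty")
        unknown = set(self.hazard_flags) - HAZARD_FLAGS
        if unknown:
            raise ValidationError(f"{self.name}: unknown hazard flags {sorted(unknown)}")
        for label, limit in (("OSHA", self.limit_osha_ppb), ("NIOSH", self.limit_niosh_ppb)):
            if limit is not None and limit <= 0:
                raise ValidationError(f"{self.name}: {label} limit must be > 0 when present")
        if self.avg_ppb_paper > self.max_ppb_paper:
            raise ValidationError(
                f"{self.name}: average concentration exceeds maximum "
                f"({self.avg_ppb_paper} > {self.max_ppb_paper})"
            )


def applicable_limit(record: CompoundRecord) -> float | None:
    """The governing permissible exposure limit for a compound, in ppb.

    Returns the more stringent (smaller) of the OSHA and NIOSH limits when
    both are listed, the single listed limit otherwise, and ``None``
    ("unassessed") when the panel lists neither.
    """
    limits = [x for x in (record.limit_osha_ppb, record.limit_niosh_ppb) if x is not None]
    return min(limits) if limits else None


@dataclass
class CompoundTable:
    """Ordered collection of :class:`CompoundRecord` with unique names."""

    records: list[CompoundRecord] = field(default_factory=list)
    version: str = "table1-v1"

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate compound names: {dupes}")
        self._by_name = {r.name: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> CompoundRecord:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Registry as a DataFrame in the on-disk column layout."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "name": r.name,
                    "cas": ";".join(r.cas_numbers),
                    "formula": r.formula,
                    "mw_g_mol": r.molecular_weight,
                    "hazards": ";".join(sorted(r.hazard_flags)),
                    "limit_osha_ppb": r.limit_osha_ppb,
                    "limit_niosh_ppb": r.limit_niosh_ppb,
                    "limit_suspect": r.limit_suspect,
                    "avg_ppb_paper": r.avg_ppb_paper,
                    "max_ppb_paper": r.max_ppb_paper,
                }
            )
        return pd.DataFrame(rows, columns=_REQUIRED_COLUMNS)


def _parse_optional_float(cell: object, row: int, column: str) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return None
    try:
        return float(str(cell).replace(",", ""))
    except ValueError as exc:
        raise FormatError(f"row {row}: column {column!r} is not numeric: {cell!r}") from exc


def load_registry(path: str | Path = "packaged") -> CompoundTable:
    """Load a compound registry from delimited text.

    ``path="packaged"`` loads the built-in 32-compound harmful panel.
    Malformed rows are rejected with their (1-based, header-excluded) row
    number; a file with errors yields no partial table.
    """
    if path == "packaged":
        source = resources.files("orsmoke").joinpath("data/harmful_panel.csv")
        with resources.as_file(source) as p:
            return load_registry(p)
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: not a registry file ({exc})") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")

    records: list[CompoundRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row_dict = dict(zip(frame.columns, row))
        try:
            suspect_raw = row_dict["limit_suspect"].strip().lower()
            if suspect_raw not in {"", "true", "false"}:
                raise FormatError(f"row {i}: limit_suspect must be true/false")
            avg = _parse_optional_float(row_dict["avg_ppb_paper"], i, "avg_ppb_paper")
            mx = _parse_optional_float(row_dict["max_ppb_paper"], i, "max_ppb_paper")
            mw = _parse_optional_float(row_dict["mw_g_mol"], i, "mw_g_mol")
            if avg is None or mx is None or mw is None:
                raise FormatError(f"row {i}: mw_g_mol/avg/max concentrations are required")
            records.append(
                CompoundRecord(
                    name=row_dict["name"],
                    cas_numbers=tuple(x for x in row_dict["cas"].split(";") if x),
                    formula=row_dict["formula"],
                    molecular_weight=mw,
                    hazard_flags=frozenset(x for x in row_dict["hazards"].split(";") if x),
                    limit_osha_ppb=_parse_optional_float(row_dict["limit_osha_ppb"], i, "limit_osha_ppb"),
                    limit_niosh_ppb=_parse_optional_float(row_dict["limit_niosh_ppb"], i, "limit_niosh_ppb"),
                    limit_suspect=suspect_raw == "true",
                    avg_ppb_paper=avg,
                    max_ppb_paper=mx,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return CompoundTable(records=records)


def write_registry(table: CompoundTable, path: str | Path) -> None:
    """Write a registry in the same delimited layout :func:`load_registry` reads."""
    frame = table.to_frame()
    frame["limit_suspect"] = frame["limit_suspect"].map({True: "true", False: "false"})
    frame.to_csv(path, index=False)
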