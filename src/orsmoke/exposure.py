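"""Inhaled dose, breath uptake, exposure-limit screening, cigarette equivalence.

Concentrations in ppb by volume convert to mass via the ideal gas law: at
temperature ``T`` and pressure ``P`` one mole of air occupies ``R·T/P``
litres (24.47 L/mol at the 25 °C / 101.325 kPa defaults), so

    µg/m³ = ppb × MW / Vm            (MW g/mol, Vm L/mol)

and the mass inhaled over an operation at minute ventilation ``V̇`` (L/min)
for ``D`` minutes is

    dose = ppb × 10⁻⁹ × V̇·D / Vm × MW × 10⁶  µg.

Breath uptake is the inhale-minus-exhale concentration difference, absolute
and as a fraction of the inhaled mean.  The exceedance screen compares
per-compound maxima against the governing (most stringent) OSHA/NIOSH limit
using a strict inequality; compounds whose transcribed limit is flagged
suspect are reported in a dedicated section rather than silently trusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

from .errors import ParameterError
from .registry import CompoundRecord, CompoundTable, applicable_limit
from .signal import IonTimeSeries, OperationSummary

__all__ = [
    "GAS_CONSTANT_L_KPA",
    "ExposureParams",
    "ExposureDose",
    "UptakeResult",
    "ExceedanceRow",
    "ExceedanceReport",
    "ppb_to_mass_conc",
    "mass_conc_to_ppb",
    "inhaled_dose",
    "uptake_fraction",
    "cigarette_equivalents",
    "load_cigarette_reference",
    "compute_doses",
    "exceedance_report",
]

#: Molar gas constant in L·kPa/(mol·K).
GAS_CONSTANT_L_KPA = 8.31446261815324


@dataclass(frozen=True)
class ExposureParams:
    """Breathing and gas-state assumptions for dose calculations.

    Defaults follow the campaign's assumptions: minute ventilation 5 L/min
    over a 120 min operation, ideal gas at 25 °C and 101.325 kPa.
    """

    minute_ventilation_l: float = 5.0
    duration_min: float = 120.0
    temperature_k: float = 298.15
    pressure_kpa: float = 101.325

    def __post_init__(self) -> None:
        for nm in ("minute_ventilation_l", "duration_min", "temperature_k", "pressure_kpa"):
            if getattr(self, nm) < 0 or (nm in ("temperature_k", "pressure_kpa") and getattr(self, nm) <= 0):
                raise ParameterError(f"{nm} must be positive")

    @property
    def molar_volume_l(self) -> float:
        """Ideal-gas molar volume R·T/P in L/mol."""
        return GAS_CONSTANT_L_KPA * self.temperature_k / self.pressure_kpa


def ppb_to_mass_conc(ppb: float, mw: float, params: ExposureParams | None = None) -> float:
    """Convert a ppb-by-volume concentration to µg/m³ (ideal gas)."""
    if mw <= 0:
        raise ParameterError(f"molecular weight must be > 0, got {mw}")
    if ppb < 0:
        raise ParameterError(f"concentration must be >= 0, got {ppb}")
    params = params or ExposureParams()
    return ppb * mw / params.molar_volume_l


def mass_conc_to_ppb(ug_m3: float, mw: float, params: ExposureParams | None = None) -> float:
    """Inverse of :func:`ppb_to_mass_conc`."""
    if mw <= 0:
        raise ParameterError(f"molecular weight must be > 0, got {mw}")
    params = params or ExposureParams()
    return ug_m3 * params.molar_volume_l / mw


def inhaled_dose(mean_ppb: float, mw: float, params: ExposureParams | None = None) -> float:
    """Mass of a compound inhaled over one operation, in µg.

    ``mean_ppb`` is the mean breath-inlet concentration; the air volume
    breathed is minute ventilation × duration, converted to moles with the
    ideal-gas molar volume.
    """
    if mean_ppb < 0:
        raise ParameterError(f"mean_ppb must be >= 0, got {mean_ppb}")
    if mw <= 0:
        raise ParameterError(f"molecular weight must be > 0, got {mw}")
    params = params or ExposureParams()
    moles_air = params.minute_ventilation_l * params.duration_min / params.molar_volume_l
    return mean_ppb * 1e-9 * moles_air * mw * 1e6


@dataclass(frozen=True)
class UptakeResult:
    """Breath uptake of one compound: absolute and fractional."""

    compound: str
    uptake_ppb: float
    uptake_fraction: float | None
    clipped: bool = False


def uptake_fraction(inhale: IonTimeSeries, exhale: IonTimeSeries, compound: str) -> UptakeResult:
    """Uptake of a compound from paired inhale/exhale breath series.

    ``uptake_ppb`` is the difference of the operation-segment means;
    ``uptake_fraction`` divides by the inhaled mean and is clipped to
    ``[0, 1]`` (noise can push the raw ratio outside), with ``clipped``
    recording whether clipping occurred.  The fraction is undefined
    (``None``) when the inhaled mean is not positive.
    """
    for series in (inhale, exhale):
        if compound not in series.data.columns:
            raise KeyError(f"{series.op_id}: no channel {compound!r}")
    mean_in = float(inhale.segment("operation")[compound].mean())
    mean_ex = float(exhale.segment("operation")[compound].mean())
    uptake_ppb = mean_in - mean_ex
    if mean_in <= 0:
        return UptakeResult(compound, uptake_ppb, None)
    raw = uptake_ppb / mean_in
    frac = min(max(raw, 0.0), 1.0)
    return UptakeResult(compound, uptake_ppb, frac, clipped=frac != raw)


def load_cigarette_reference() -> dict[str, float]:
    """Per-cigarette emitted mass (µg) for compounds with published values."""
    source = resources.files("orsmoke").joinpath("data/cigarette_reference.csv")
    with resources.as_file(source) as path:
        frame = pd.read_csv(path)
    return dict(zip(frame["compound"], frame["ug_per_cigarette"].astype(float)))


def cigarette_equivalents(
    dose_ug: float,
    compound: str,
    reference: Mapping[str, float] | None = None,
) -> float | None:
    """Dose expressed as a number of cigarettes, or ``None`` without a reference."""
    if dose_ug < 0:
        raise ParameterError(f"dose must be >= 0, got {dose_ug}")
    reference = load_cigarette_reference() if reference is None else reference
    if compound not in reference:
        return None
    return dose_ug / reference[compound]


@dataclass(frozen=True)
class ExposureDose:
    """Inhaled mass and uptake results for one compound."""

    compound: str
    mean_ppb: float
    inhaled_mass_ug: float
    cigarette_equivalents: float | None = None
    uptake_fraction: float | None = None
    uptake_ppb: float | None = None


def compute_doses(
    mean_ppb: Mapping[str, float],
    registry: CompoundTable,
    params: ExposureParams | None = None,
    uptake: Mapping[str, UptakeResult] | None = None,
    reference: Mapping[str, float] | None = None,
) -> list[ExposureDose]:
    """Inhaled dose per compound from mean breath-inlet concentrations."""
    params = params or ExposureParams()
    reference = load_cigarette_reference() if reference is None else reference
    doses = []
    for name, ppb in mean_ppb.items():
        record = registry[name]
        dose = inhaled_dose(max(ppb, 0.0), record.molecular_weight, params)
        up = uptake.get(name) if uptake else None
        doses.append(
            ExposureDose(
                compound=name,
                mean_ppb=float(ppb),
                inhaled_mass_ug=dose,
                cigarette_equivalents=cigarette_equivalents(dose, name, reference),
                uptake_fraction=None if up is None else up.uptake_fraction,
                uptake_ppb=None if up is None else up.uptake_ppb,
            )
        )
    return doses


def doses_to_frame(doses: list[ExposureDose]) -> pd.DataFrame:
    return pd.DataFrame([d.__dict__ for d in doses])


@dataclass(frozen=True)
class ExceedanceRow:
    """Screening result for one compound."""

    compound: str
    max_ppb: float
    limit_ppb: float | None
    exceeds: bool
    limit_suspect: bool


@dataclass
class ExceedanceReport:
    """Exposure-limit screen over a panel of per-compound maxima."""

    rows: list[ExceedanceRow]

    @property
    def flagged(self) -> list[str]:
        return [r.compound for r in self.rows if r.exceeds]

    @property
    def suspect(self) -> list[ExceedanceRow]:
        return [r for r in self.rows if r.limit_suspect]

    @property
    def unassessed(self) -> list[str]:
        return [r.compound for r in self.rows if r.limit_ppb is None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def render_text(self) -> str:
        lines = ["Exposure-limit exceedance screen", "=" * 32, ""]
        lines.append(f"{'compound':<48}{'max (ppb)':>12}{'limit (ppb)':>14}  status")
        for r in self.rows:
            limit = "unassessed" if r.limit_ppb is None else f"{r.limit_ppb:g}"
            status = "EXCEEDS" if r.exceeds else ("-" if r.limit_ppb is not None else "no limit")
            if r.limit_suspect:
                status += " (suspect limit)"
            lines.append(f"{r.compound:<48}{r.max_ppb:>12.2f}{limit:>14}  {status}")
        lines.append("")
        lines.append(f"Compounds exceeding their governing limit: {', '.join(self.flagged) or 'none'}")
        if self.unassessed:
            lines.append(
                "No OSHA/NIOSH limit is assigned for: " + ", ".join(self.unassessed)
            )
        if self.suspect:
            lines.append("")
            lines.append("Suspect limits")
            lines.append("-" * 14)
            for r in self.suspect:
                lines.append(f"  {r.compound}: transcribed limit {r.limit_ppb:g} ppb")
            lines.append(
                "  These limit cells are printed on a doubtful unit scale in the source\n"
                "  panel (conventional NIOSH limits for methanol and ethanol are stated\n"
                "  in ppm, i.e. 1000x larger than a ppb reading). They were transcribed\n"
                "  verbatim in ppb rather than rescaled by guesswork, so exceedance\n"
                "  decisions against them are unreliable in both directions; note that\n"
                "  methanol has been reported among the compounds exceeding occupational\n"
                "  limits in OR smoke measurements even though it is not flagged here."
            )
        return "\n".join(lines) + "\n"


def exceedance_report(
    maxima: Mapping[str, float] | OperationSummary,
    registry: CompoundTable,
) -> ExceedanceReport:
    """Screen per-compound maxima against permissible exposure limits.

    A compound is flagged iff a limit exists and its maximum strictly
    exceeds the governing (minimum) OSHA/NIOSH limit; compounds without a
    limit are listed as unassessed and never flagged.
    """
    if isinstance(maxima, OperationSummary):
        maxima = maxima.channel_stats["max_ppb"].to_dict()
    rows = []
    for name, mx in maxima.items():
        record: CompoundRecord = registry[name]
        limit = applicable_limit(record)
        rows.append(
            ExceedanceRow(
                compound=name,
                max_ppb=float(mx),
                limit_ppb=limit,
                exceeds=limit is not None and mx > limit,
                limit_suspect=record.limit_suspect,
            )
        )
    return ExceedanceReport(rows=rows)
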