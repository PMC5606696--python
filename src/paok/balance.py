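"""Per-cycle phosphate and COD mass balances for a down-flow hanging sponge
(DHS) enrichment reactor.

Each 12-h cycle has an aerobic phase (phosphate-containing feed trickling at
a constant flow; uptake = flow * duration * concentration drop) and an
anaerobic phase (the column filled with a fixed volume of organic substrate;
release = end-of-phase P mass minus the P mass carried over in the liquid the
sponge retained at the phase switch).  Specific rates normalize the per-cycle
amounts to sponge volume and phase duration (mg P cm^-3 h^-1).

Negative balances (e.g. apparent release during the aerobic phase) are
flagged and returned as computed, never clipped — they usually indicate a
measurement problem worth seeing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

__all__ = [
    "CycleRecord",
    "CycleBalance",
    "Measured",
    "aerobic_uptake",
    "anaerobic_release",
    "cod_consumed",
    "specific_rates",
    "cycle_balance",
]


class Measured(NamedTuple):
    """A computed amount plus any quality flags raised while computing it."""

    value: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CycleRecord:
    """One sampled reactor cycle.

    Volumes in litres, flows in L d^-1, concentrations in mg L^-1, durations
    in hours, sponge volume in cm^3.  Defaults reflect a bench DHS unit:
    3.24 L d^-1 aerobic flow over 9 h, a 70-mL anaerobic fill held 3 h,
    200 mg COD L^-1 anaerobic substrate and a 6-cm^3 sponge string.
    ``retained_liquid_volume`` is the liquid held in the sponge at the
    aerobic-to-anaerobic switch; when unmeasured (None) it defaults to the
    sponge pore volume, i.e. the sponge volume itself (the open-pore foam
    holds roughly its own volume of liquid).
    """

    run_id: str
    day: float
    aerobic_influent_p: float
    aerobic_effluent_p: float
    anaerobic_end_p: float
    anaerobic_end_cod: float
    aerobic_flow: float = 3.24
    aerobic_hours: float = 9.0
    anaerobic_hours: float = 3.0
    anaerobic_fill_volume: float = 0.070
    anaerobic_influent_cod: float = 200.0
    sponge_volume: float = 6.0
    retained_liquid_volume: Optional[float] = None

    def __post_init__(self) -> None:
        for name in (
            "aerobic_flow",
            "aerobic_hours",
            "anaerobic_hours",
            "anaerobic_fill_volume",
            "sponge_volume",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "aerobic_influent_p",
            "aerobic_effluent_p",
            "anaerobic_end_p",
            "anaerobic_end_cod",
            "anaerobic_influent_cod",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.retained_liquid_volume is not None and self.retained_liquid_volume < 0:
            raise ValueError("retained_liquid_volume must be >= 0")

    @property
    def retained_volume_l(self) -> float:
        if self.retained_liquid_volume is not None:
            return self.retained_liquid_volume
        return self.sponge_volume / 1000.0  # cm^3 -> L


@dataclass(frozen=True)
class CycleBalance:
    """Mass balances and sponge-normalized specific rates for one cycle."""

    run_id: str
    day: float
    p_uptake_mg: float
    p_release_mg: float
    cod_consumed_mg: float
    cod_fraction_remaining: Optional[float]
    specific_uptake: float
    specific_release: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def aerobic_uptake(record: CycleRecord) -> Measured:
    """Phosphate taken up over the aerobic phase, mg P per cycle.

    flow (L d^-1) * duration (d) * (influent - effluent) (mg L^-1).
    """
    delta = record.aerobic_influent_p - record.aerobic_effluent_p
    amount = record.aerobic_flow * (record.aerobic_hours / 24.0) * delta
    flags = ("release-during-aerobic",) if amount < 0 else ()
    return Measured(amount, flags)


def anaerobic_release(record: CycleRecord) -> Measured:
    """Phosphate released over the anaerobic phase, mg P per cycle.

    End-of-phase P mass in the fill volume, corrected for the P already
    present in the liquid the sponge carried over from the aerobic phase:

        fill_volume * end_P  -  retained_volume * aerobic_effluent_P
    """
    carried = record.retained_volume_l * record.aerobic_effluent_p
    amount = record.anaerobic_fill_volume * record.anaerobic_end_p - carried
    flags = ("negative-release",) if amount < 0 else ()
    return Measured(amount, flags)


def cod_consumed(record: CycleRecord) -> tuple[Measured, Optional[float]]:
    """COD consumed during the anaerobic phase and the fraction remaining.

    Returns ``(Measured(mg COD per cycle), end/influent)``; the fraction is
    ``None`` (flagged) when the influent COD is zero.
    """
    consumed = record.anaerobic_fill_volume * (
        record.anaerobic_influent_cod - record.anaerobic_end_cod
    )
    flags: tuple[str, ...] = ()
    if consumed < 0:
        flags += ("cod-produced",)
    if record.anaerobic_influent_cod == 0:
        return Measured(consumed, flags + ("zero-influent-cod",)), None
    return Measured(consumed, flags), record.anaerobic_end_cod / record.anaerobic_influent_cod


def specific_rates(amount_mg: float, sponge_volume_cm3: float, phase_hours: float) -> float:
    """Normalize a per-cycle amount to sponge volume and phase duration.

    Returns mg P cm^-3 h^-1; negative amounts pass through as negative rates.
    """
    if sponge_volume_cm3 <= 0:
        raise ValueError("sponge_volume must be > 0")
    if phase_hours <= 0:
        raise ValueError("phase duration must be > 0")
    return amount_mg / (sponge_volume_cm3 * phase_hours)


def cycle_balance(record: CycleRecord) -> CycleBalance:
    """Full uptake/release/COD balance with specific rates for one record."""
    uptake = aerobic_uptake(record)
    release = anaerobic_release(record)
    cod, fraction = cod_consumed(record)
    return CycleBalance(
        run_id=record.run_id,
        day=record.day,
        p_uptake_mg=uptake.value,
        p_release_mg=release.value,
        cod_consumed_mg=cod.value,
        cod_fraction_remaining=fraction,
        specific_uptake=specific_rates(
            uptake.value, record.sponge_volume, record.aerobic_hours
        ),
        specific_release=specific_rates(
            release.value, record.sponge_volume, record.anaerobic_hours
        ),
        flags=uptake.flags + release.flags + cod.flags,
    )
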