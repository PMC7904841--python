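"""Dilution-adjusted quantitation for the QUANTUM BLUE sCAL lateral-flow test.

The reader reports the calprotectin concentration of the *diluted* specimen on
the cassette; its native quantitation window is 50-1000 ng/ml.  Effective
specimen concentrations are obtained by multiplying the cassette reading by
the dilution fold, so the effective measuring range scales with dilution:
500-10,000 ng/ml at the recommended 1:10 serum dilution, 2000-40,000 ng/ml at
the 1:40 saliva dilution, and up to 100,000 ng/ml after the 1:100 re-test.

All dilution scaling is explicit in this module; censored results carry the
violated limit plus a status flag, never a bare number.  Values exactly equal
to a limit count as within range (the re-test rule fires only *above* the
upper limit).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = [
    "RangeStatus",
    "DilutionProtocol",
    "AssayResult",
    "DEFAULT_PROTOCOL",
    "quantitation_range",
    "effective_concentration",
    "measure_saliva_with_retest",
]


class RangeStatus(str, Enum):
    WITHIN_RANGE = "within_range"
    BELOW_LLOQ = "below_lloq"
    ABOVE_ULOQ = "above_uloq"


@dataclass(frozen=True)
class DilutionProtocol:
    """Cassette quantitation limits (ng/ml of diluted specimen) and the
    dilution folds of the clinic workflow."""

    cassette_lloq: float = 50.0
    cassette_uloq: float = 1000.0
    serum_dilution: int = 10
    saliva_dilution: int = 40
    saliva_retest_dilution: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.cassette_lloq < self.cassette_uloq:
            raise ValueError("need 0 < cassette_lloq < cassette_uloq")
        for name in ("serum_dilution", "saliva_dilution", "saliva_retest_dilution"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.saliva_retest_dilution > self.saliva_dilution:
            raise ValueError("saliva_retest_dilution must exceed saliva_dilution")


DEFAULT_PROTOCOL = DilutionProtocol()


@dataclass(frozen=True)
class AssayResult:
    """A dilution-adjusted quantitation with censoring status.

    When ``status`` is ``within_range``, ``effective_conc`` lies inside the
    effective quantitation range at ``dilution_used``; otherwise it equals the
    violated effective limit.
    """

    effective_conc: float
    status: RangeStatus
    dilution_used: int

    def to_dict(self) -> dict:
        return {
            "effective_conc": self.effective_conc,
            "status": self.status.value,
            "dilution_used": self.dilution_used,
        }


def quantitation_range(
    dilution: float, protocol: DilutionProtocol = DEFAULT_PROTOCOL
) -> tuple[float, float]:
    """Effective (LLOQ, ULOQ) of the assay at a given dilution fold.

    >>> quantitation_range(10)
    (500.0, 10000.0)
    """
    if dilution <= 0:
        raise ValueError(f"dilution fold must be positive, got {dilution}")
    return (protocol.cassette_lloq * dilution, protocol.cassette_uloq * dilution)


def effective_concentration(cassette_reading: float, dilution: float) -> float:
    """Specimen concentration implied by a cassette reading at a dilution fold."""
    if cassette_reading < 0:
        raise ValueError(f"cassette reading must be >= 0, got {cassette_reading}")
    if dilution <= 0:
        raise ValueError(f"dilution fold must be positive, got {dilution}")
    return cassette_reading * dilution


def measure_saliva_with_retest(
    true_conc: float, protocol: DilutionProtocol = DEFAULT_PROTOCOL
) -> AssayResult:
    """Deterministic saliva workflow: measure at the 1:40 dilution; if the
    cassette reads above its upper limit, re-measure at 1:100; if still above,
    censor at the re-test ceiling.  Below the cassette lower limit at 1:40,
    censor at the 1:40 floor.  Measurement noise is the cohort generator's
    job, not this function's."""
    if true_conc < 0:
        raise ValueError(f"concentration must be >= 0, got {true_conc}")

    d1 = protocol.saliva_dilution
    reading1 = true_conc / d1
    if reading1 > protocol.cassette_uloq:
        d2 = protocol.saliva_retest_dilution
        reading2 = true_conc / d2
        if reading2 > protocol.cassette_uloq:
            return AssayResult(
                effective_conc=effective_concentration(protocol.cassette_uloq, d2),
                status=RangeStatus.ABOVE_ULOQ,
                dilution_used=d2,
            )
        return AssayResult(
            effective_conc=effective_concentration(reading2, d2),
            status=RangeStatus.WITHIN_RANGE,
            dilution_used=d2,
        )
    if reading1 < protocol.cassette_lloq:
        return AssayResult(
            effective_conc=effective_concentration(protocol.cassette_lloq, d1),
            status=RangeStatus.BELOW_LLOQ,
            dilution_used=d1,
        )
    return AssayResult(
        effective_conc=effective_concentration(reading1, d1),
        status=RangeStatus.WITHIN_RANGE,
        dilution_used=d1,
    )
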