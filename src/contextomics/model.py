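"""Shared domain types for the contextual-proteomics pipeline.

The atomic quantification input is a :class:`PeptideMeasurement` — one
endogenous/reference (spiked heavy standard) intensity pair together with
the known spike amount in attomoles.  Sample bookkeeping lives in
:class:`SampleMeta`; protein-complex composition, with integer subunit
multiplicities and the receptor homo-oligomer assumption, in
:class:`ComplexDefinition`.

Units: amounts are attomoles (amol, 1e-18 mol) throughout; conversion to
molecule counts happens only at the copies-per-cell boundary
(:mod:`contextomics.context`).  Time points are minutes; fraction and
replicate indices are 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple


class ContextomicsError(Exception):
    """Base class for all package errors."""


class FormatError(ContextomicsError):
    """A file does not conform to the documented table/config schema."""


class ValidationError(ContextomicsError):
    """A record violates a domain invariant."""


class ConfigError(ContextomicsError):
    """A configuration file is structurally valid but semantically wrong."""


class QuantificationError(ContextomicsError):
    """A measurement cannot be converted into an absolute amount."""


class InsufficientDataError(ContextomicsError):
    """Too few usable data points for the requested fit or test."""


def _check_finite_nonneg(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise ValidationError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class PeptideMeasurement:
    """One endogenous/reference intensity pair with its spike amount.

    ``spike_amount`` is the amount (amol) of the stable-isotope-labeled
    reference peptide present in the matrix at the spike point.
    """

    sample_id: str
    protein_id: str
    peptide_sequence: str
    charge: int
    endogenous_intensity: float
    reference_intensity: float
    spike_amount: float

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValidationError(f"charge must be >= 1, got {self.charge}")
        _check_finite_nonneg("endogenous_intensity", self.endogenous_intensity)
        _check_finite_nonneg("reference_intensity", self.reference_intensity)
        _check_finite_nonneg("spike_amount", self.spike_amount)


SAMPLE_TYPES = ("lysate", "affinity_purification", "bnpage_fraction")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample bookkeeping.

    ``cell_equivalents`` is the number of cells represented by the peptide
    matrix *at the spike point*; every amount-to-copies conversion divides
    by this value.  For lysate rulers the reference peptides are spiked
    right after lysis, for affinity purifications into the final peptide
    matrix — carrying the spike-point denominator in the metadata makes the
    two conventions explicit and uniform.
    """

    sample_id: str
    sample_type: str
    timepoint: float
    replicate: int
    cell_equivalents: float
    injected_fraction: float
    treatment: Optional[str] = None
    fraction_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValidationError(
                f"sample_type must be one of {SAMPLE_TYPES}, got {self.sample_type!r}"
            )
        if self.timepoint < 0:
            raise ValidationError(f"timepoint must be >= 0, got {self.timepoint}")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        if self.cell_equivalents <= 0:
            raise ValidationError(
                f"cell_equivalents must be > 0, got {self.cell_equivalents}"
            )
        if not (0 < self.injected_fraction <= 1):
            raise ValidationError(
                f"injected_fraction must be in (0, 1], got {self.injected_fraction}"
            )
        has_fraction = self.fraction_index is not None
        is_gel = self.sample_type == "bnpage_fraction"
        if has_fraction != is_gel:
            raise ValidationError(
                "fraction_index must be present iff sample_type is bnpage_fraction"
            )
        if has_fraction and self.fraction_index < 1:  # type: ignore[operator]
            raise ValidationError("fraction_index is 1-based and must be >= 1")


@dataclass(frozen=True)
class ComplexDefinition:
    """A named complex with integer member multiplicities.

    ``receptor_flag`` marks the complex holding the receptor itself;
    ``receptor_oligomer`` is the literature-derived homo-oligomer count of
    the receptor (3 for a trimeric TNF-family receptor).  Multiplicities
    are taken as given, never inferred.
    """

    complex_name: str
    members: Tuple[Tuple[str, int], ...]
    reference_policy: str = "most_abundant"
    receptor_flag: bool = False
    receptor_oligomer: int = 3

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"complex {self.complex_name!r} has no members")
        for pid, mult in self.members:
            if mult < 1:
                raise ValidationError(
                    f"multiplicity of {pid} in {self.complex_name} must be >= 1"
                )
        seen = set()
        for pid, _ in self.members:
            if pid in seen:
                raise ValidationError(
                    f"duplicate member {pid} in complex {self.complex_name}"
                )
            seen.add(pid)
        if self.receptor_oligomer < 1:
            raise ValidationError("receptor_oligomer must be >= 1")
        if not (
            self.reference_policy == "most_abundant"
            or self.reference_policy.startswith("fixed:")
        ):
            raise ValidationError(
                f"reference_policy must be 'most_abundant' or 'fixed:<protein_id>', "
                f"got {self.reference_policy!r}"
            )

    @property
    def member_ids(self) -> Tuple[str, ...]:
        return tuple(pid for pid, _ in self.members)

    @property
    def multiplicities(self) -> dict:
        return {pid: mult for pid, mult in self.members}


def receptor_complex(complexes) -> ComplexDefinition:
    """Return the unique receptor-flagged complex, or raise ConfigError."""
    flagged = [c for c in complexes if c.receptor_flag]
    if len(flagged) != 1:
        raise ConfigError(
            f"exactly one complex must carry receptor_flag, found {len(flagged)}"
        )
    return flagged[0]


@dataclass(frozen=True)
class ProteinAmount:
    """Absolute amount (amol) of one protein in one sample."""

    sample_id: str
    protein_id: str
    amount: float
    cv: float
    n_peptides: int

    def __post_init__(self) -> None:
        _check_finite_nonneg("amount", self.amount)
        _check_finite_nonneg("cv", self.cv)
        if self.n_peptides < 1:
            raise ValidationError(f"n_peptides must be >= 1, got {self.n_peptides}")


@dataclass(frozen=True)
class MonomerInfo:
    """Monomer molecular weight (kDa) and optional sequence of a protein."""

    protein_id: str
    monomer_mw: float
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.monomer_mw > 0 and math.isfinite(self.monomer_mw)):
            raise ValidationError(f"monomer_mw must be > 0, got {self.monomer_mw}")
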