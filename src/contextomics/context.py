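"""Cellular-context calculations: copies per cell, resource allocation,
and signalosome mass.

Absolute amounts (amol) become molecule counts via Avogadro's number and
copies per cell via the number of cell equivalents the sample represents
at the spike point.  A well-measured calibrant protein (the receptor,
whose copy number is determined directly from lysates) acts as a ruler to
translate the amounts of every other protein onto the copies-per-cell
scale from the same experiment.

Resource allocation compares, per protein, the copies available in the
cell with the copies required to supply at least one complete complex per
trimeric receptor; proteins below that requirement are limiting for
signalosome formation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

from .model import ComplexDefinition, ValidationError

log = logging.getLogger(__name__)

#: 2019 SI exact value, mol^-1
AVOGADRO = 6.02214076e23

AMOL_TO_MOL = 1e-18


@dataclass(frozen=True)
class CellContext:
    """Cell-level bookkeeping used to convert amounts to copies."""

    mass_per_cell_pg: float
    cells_processed: float
    injected_fraction: float
    calibrant_protein: str
    calibrant_copies_per_cell: float

    def __post_init__(self) -> None:
        if self.mass_per_cell_pg <= 0 or self.cells_processed <= 0:
            raise ValidationError("mass_per_cell_pg and cells_processed must be > 0")
        if not (0 < self.injected_fraction <= 1):
            raise ValidationError("injected_fraction must be in (0, 1]")
        if self.calibrant_copies_per_cell <= 0:
            raise ValidationError("calibrant_copies_per_cell must be > 0")


@dataclass(frozen=True)
class AllocationRecord:
    """Available vs required vs recovered copies for one protein."""

    protein_id: str
    copies_available: float
    copies_required: float
    copies_recovered: Optional[float]
    limiting: bool


@dataclass(frozen=True)
class MassEstimate:
    """Average molecules and summed molecular weight per receptor unit."""

    timepoint: float
    molecules_per_receptor: Mapping[str, float]
    total_molecules: float
    total_mw_mda: float
    per: str = "trimer"
    majority_mass_contributor: Optional[str] = None


def protein_mass_per_cell(total_mass_mg: float, cell_count: float) -> float:
    """Average protein content per cell in pg, from a bulk measurement."""
    if total_mass_mg <= 0 or cell_count <= 0:
        raise ValidationError("total_mass_mg and cell_count must be > 0")
    return total_mass_mg * 1e9 / cell_count


def cell_equivalents(protein_mass_ug: float, mass_per_cell_pg: float) -> float:
    """Number of cells represented by a given protein mass."""
    if protein_mass_ug <= 0 or mass_per_cell_pg <= 0:
        raise ValidationError("protein_mass_ug and mass_per_cell_pg must be > 0")
    return protein_mass_ug * 1e6 / mass_per_cell_pg


def injected_cell_equivalents(cells: float, injected_fraction: float) -> float:
    if cells <= 0:
        raise ValidationError("cell equivalents must be > 0")
    if not (0 < injected_fraction <= 1):
        raise ValidationError("injected_fraction must be in (0, 1]")
    return cells * injected_fraction


def amount_to_molecules(amount_mol: float) -> float:
    """Molecule count of an amount in mol (1 zmol is about 600 molecules)."""
    if amount_mol < 0:
        raise ValidationError("amount must be >= 0")
    return amount_mol * AVOGADRO


def copies_per_cell(amount_amol: float, cell_equivalents_at_spike: float) -> float:
    """Copies per cell from an absolute amount (amol) and the spike-point
    cell-equivalent count of the sample."""
    if cell_equivalents_at_spike <= 0:
        raise ValidationError("cell_equivalents_at_spike must be > 0")
    return amount_to_molecules(amount_amol * AMOL_TO_MOL) / cell_equivalents_at_spike


def translate_copies_via_calibrant(
    calibrant_copies_per_cell: float,
    protein_amount: float,
    calibrant_amount: float,
) -> float:
    """Scale a protein's amount to copies per cell using the calibrant's
    known copy number and its amount from the same experiment."""
    if calibrant_amount <= 0:
        raise ValidationError("calibrant_amount must be > 0")
    return calibrant_copies_per_cell * protein_amount / calibrant_amount


def complexes_per_cell(
    copies: Mapping[str, float], complex_def: ComplexDefinition
) -> float:
    """Complete complexes a cell can assemble: min over members of
    copies / multiplicity.  An absent member means zero complexes."""
    counts = []
    for pid, mult in complex_def.members:
        if pid not in copies:
            log.warning(
                "complex %s: member %s has no copy estimate; 0 complexes",
                complex_def.complex_name,
                pid,
            )
            return 0.0
        counts.append(copies[pid] / mult)
    return min(counts)


def copies_required_for_isostoichiometry(
    complex_def: ComplexDefinition,
    receptor_copies_per_cell: float,
    receptor_oligomer: int = 3,
) -> Dict[str, float]:
    """Copies of each member needed for one complete complex per trimeric
    (or ``receptor_oligomer``-meric) receptor unit."""
    if receptor_copies_per_cell <= 0:
        raise ValidationError("receptor_copies_per_cell must be > 0")
    if receptor_oligomer < 1:
        raise ValidationError("receptor_oligomer must be >= 1")
    receptor_units = receptor_copies_per_cell / receptor_oligomer
    return {pid: mult * receptor_units for pid, mult in complex_def.members}


def limiting_components(
    copies_available: Mapping[str, float],
    copies_required: Mapping[str, float],
    copies_recovered: Optional[Mapping[str, float]] = None,
) -> List[AllocationRecord]:
    """Per-protein allocation records, sorted by available/required ascending.

    A protein is limiting iff strictly fewer copies are available than
    required; exact equality means exactly sufficient.
    """
    if set(copies_available) != set(copies_required):
        only_a = set(copies_available) - set(copies_required)
        only_r = set(copies_required) - set(copies_available)
        raise ValidationError(
            f"protein sets differ: only-available={sorted(only_a)}, "
            f"only-required={sorted(only_r)}"
        )
    records = []
    for pid in copies_available:
        avail = copies_available[pid]
        req = copies_required[pid]
        records.append(
            AllocationRecord(
                protein_id=pid,
                copies_available=avail,
                copies_required=req,
                copies_recovered=(
                    copies_recovered.get(pid) if copies_recovered is not None else None
                ),
                limiting=avail < req,
            )
        )
    records.sort(
        key=lambda r: (
            r.copies_available / r.copies_required
            if r.copies_required > 0
            else float("inf"),
            r.protein_id,
        )
    )
    return records


def recovered_copies(
    ap_amount_amol: float,
    ap_cell_equivalents: float,
    copies_available: Optional[float] = None,
) -> Tuple[float, Optional[float]]:
    """Copies per (starting) cell recovered in an affinity purification,
    and the recovery yield when the available copy number is supplied."""
    if ap_cell_equivalents <= 0:
        raise ValidationError("ap_cell_equivalents must be > 0")
    recovered = copies_per_cell(ap_amount_amol, ap_cell_equivalents)
    yield_fraction = None
    if copies_available is not None and copies_available > 0:
        yield_fraction = recovered / copies_available
    return recovered, yield_fraction


def signalosome_mass(
    bound_amounts: Mapping[str, float],
    receptor_amount: float,
    receptor_id: str,
    monomer_mw: Mapping[str, float],
    timepoint: float = 0.0,
    receptor_oligomer: int = 3,
    per: str = "trimer",
    ubiquitin_id: str = "UBIQ",
) -> MassEstimate:
    """Average molecules and summed MW associated with one receptor unit.

    ``per="trimer"`` expresses molecule counts per oligomeric receptor
    unit (the receptor contributes ``receptor_oligomer`` copies of itself);
    ``per="monomer"`` per receptor monomer.  The MW sum includes the
    receptor's own mass.  When one protein contributes more than half of
    the total mass (in practice conjugated ubiquitin), it is flagged as
    the majority mass contributor.
    """
    if receptor_amount <= 0:
        raise ValidationError("receptor_amount must be > 0")
    if per not in ("trimer", "monomer"):
        raise ValidationError("per must be 'trimer' or 'monomer'")
    missing = [
        pid
        for pid in list(bound_amounts) + [receptor_id]
        if pid not in monomer_mw
    ]
    if missing:
        raise ValidationError(f"missing monomer MW for: {sorted(set(missing))}")
    unit = receptor_amount / receptor_oligomer if per == "trimer" else receptor_amount
    molecules: Dict[str, float] = {
        receptor_id: receptor_oligomer if per == "trimer" else 1.0
    }
    for pid, amount in bound_amounts.items():
        if pid == receptor_id:
            continue
        molecules[pid] = amount / unit
    total_molecules = sum(molecules.values())
    masses = {pid: n * monomer_mw[pid] for pid, n in molecules.items()}
    total_kda = sum(masses.values())
    majority = None
    for pid, mass in masses.items():
        if total_kda > 0 and mass > 0.5 * total_kda:
            majority = pid
    if majority == ubiquitin_id:
        log.info("ubiquitin contributes the majority of the signalosome mass")
    return MassEstimate(
        timepoint=timepoint,
        molecules_per_receptor=molecules,
        total_molecules=total_molecules,
        total_mw_mda=total_kda / 1000.0,
        per=per,
        majority_mass_contributor=majority,
    )
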