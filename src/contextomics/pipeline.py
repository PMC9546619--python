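"""End-to-end composition of the pipeline stages.

quantify -> copies per cell (lysate ruler) -> stoichiometry -> cellular
context (allocation, recovery, signalosome mass).  Each helper consumes
and produces the same objects the TSV formats carry, so the CLI stages
compose without manual editing.
"""

from __future__ import annotations

import statistics
from collections import defaultdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from . import context as ctx
from . import stoich
from .model import ComplexDefinition, ProteinAmount, SampleMeta, ValidationError, receptor_complex
from .quant import quantify_table


def amounts_by_sample(
    amounts: Iterable[ProteinAmount],
) -> Dict[str, Dict[str, float]]:
    out: Dict[str, Dict[str, float]] = defaultdict(dict)
    for a in amounts:
        out[a.sample_id][a.protein_id] = a.amount
    return dict(out)


def lysate_copies_per_cell(
    amounts: Iterable[ProteinAmount],
    samples: Mapping[str, SampleMeta],
    calibrant_id: Optional[str] = None,
) -> Dict[str, float]:
    """Copies per cell of every protein, averaged over lysate samples.

    Each sample's amounts are divided by its spike-point cell equivalents.
    When a calibrant is given, its copies are computed directly and every
    other protein is translated through the calibrant's amount in the same
    sample; with the spike-point convention the two routes agree exactly.
    """
    per_protein: Dict[str, List[float]] = defaultdict(list)
    for sample_id, sample_amounts in amounts_by_sample(amounts).items():
        meta = samples[sample_id]
        if meta.sample_type != "lysate":
            continue
        if calibrant_id is not None:
            if calibrant_id not in sample_amounts:
                raise ValidationError(
                    f"calibrant {calibrant_id} not quantified in {sample_id}"
                )
            calibrant_copies = ctx.copies_per_cell(
                sample_amounts[calibrant_id], meta.cell_equivalents
            )
            for pid, amount in sample_amounts.items():
                per_protein[pid].append(
                    ctx.translate_copies_via_calibrant(
                        calibrant_copies, amount, sample_amounts[calibrant_id]
                    )
                )
        else:
            for pid, amount in sample_amounts.items():
                per_protein[pid].append(
                    ctx.copies_per_cell(amount, meta.cell_equivalents)
                )
    if not per_protein:
        raise ValidationError("no lysate samples found")
    return {pid: statistics.fmean(vals) for pid, vals in per_protein.items()}


def ap_bound_per_receptor_unit(
    amounts: Iterable[ProteinAmount],
    samples: Mapping[str, SampleMeta],
    receptor_id: str,
    receptor_oligomer: int = 3,
) -> Dict[float, Dict[str, float]]:
    """Copies bound per oligomeric receptor unit, per timepoint.

    Replicate samples of a timepoint are averaged after dividing each
    protein's amount by the receptor's amount in the same sample (so the
    capture efficiency cancels sample by sample).
    """
    per_tp: Dict[float, Dict[str, List[float]]] = defaultdict(lambda: defaultdict(list))
    for sample_id, sample_amounts in amounts_by_sample(amounts).items():
        meta = samples[sample_id]
        if meta.sample_type != "affinity_purification":
            continue
        receptor_amount = sample_amounts.get(receptor_id, 0.0)
        if receptor_amount <= 0:
            raise ValidationError(
                f"receptor {receptor_id} not quantified in AP sample {sample_id}"
            )
        unit_amount = receptor_amount / receptor_oligomer
        for pid, amount in sample_amounts.items():
            per_tp[meta.timepoint][pid].append(amount / unit_amount)
    return {
        t: {pid: statistics.fmean(vals) for pid, vals in prot.items()}
        for t, prot in per_tp.items()
    }


def ap_recovered_copies(
    amounts: Iterable[ProteinAmount],
    samples: Mapping[str, SampleMeta],
    timepoint: float,
) -> Dict[str, float]:
    """Copies per starting cell recovered in the AP at one timepoint,
    averaged over replicates."""
    per_protein: Dict[str, List[float]] = defaultdict(list)
    for sample_id, sample_amounts in amounts_by_sample(amounts).items():
        meta = samples[sample_id]
        if meta.sample_type != "affinity_purification" or meta.timepoint != timepoint:
            continue
        for pid, amount in sample_amounts.items():
            recovered, _ = ctx.recovered_copies(amount, meta.cell_equivalents)
            per_protein[pid].append(recovered)
    return {pid: statistics.fmean(vals) for pid, vals in per_protein.items()}


def allocation_analysis(
    copies: Mapping[str, float],
    complexes: Sequence[ComplexDefinition],
    recovered: Optional[Mapping[str, float]] = None,
) -> List[ctx.AllocationRecord]:
    """Allocation records for every complex member: available vs required
    (one complete complex per oligomeric receptor unit) vs recovered."""
    receptor = receptor_complex(complexes)
    receptor_id = receptor.member_ids[0]
    if receptor_id not in copies:
        raise ValidationError(f"no copy estimate for receptor {receptor_id}")
    required: Dict[str, float] = {}
    for cdef in complexes:
        if cdef.receptor_flag:
            continue
        required.update(
            ctx.copies_required_for_isostoichiometry(
                cdef, copies[receptor_id], receptor.receptor_oligomer
            )
        )
    available = {pid: copies.get(pid, 0.0) for pid in required}
    return ctx.limiting_components(available, required, recovered)


def stoichiometry_by_timepoint(
    bound: Mapping[float, Mapping[str, float]],
    complexes: Sequence[ComplexDefinition],
    source: str = "aqua",
) -> List[stoich.StoichiometryEstimate]:
    """Relative stoichiometry of each complex at each timepoint where at
    least one member carries signal."""
    estimates = []
    for t in sorted(bound):
        for cdef in complexes:
            amounts = {
                pid: bound[t][pid] for pid in cdef.member_ids if pid in bound[t]
            }
            if not amounts or all(v == 0 for v in amounts.values()):
                continue
            estimates.append(
                stoich.relative_stoichiometry(
                    cdef, amounts, timepoint=t, source=source
                )
            )
    return estimates


def recruitment_profiles(
    amounts: Iterable[ProteinAmount],
    samples: Mapping[str, SampleMeta],
    receptor_id: str,
) -> List[stoich.RecruitmentProfile]:
    """Receptor- and max-normalized recruitment profiles from AP samples.

    Replicates are averaged per timepoint before normalization.
    """
    per_tp: Dict[float, Dict[str, List[float]]] = defaultdict(lambda: defaultdict(list))
    for sample_id, sample_amounts in amounts_by_sample(amounts).items():
        meta = samples[sample_id]
        if meta.sample_type != "affinity_purification":
            continue
        for pid, amount in sample_amounts.items():
            per_tp[meta.timepoint][pid].append(amount)
    timepoints = sorted(per_tp)
    mean_amounts = {
        t: {pid: statistics.fmean(vals) for pid, vals in per_tp[t].items()}
        for t in timepoints
    }
    proteins: List[str] = []
    for t in timepoints:
        for pid in mean_amounts[t]:
            if pid not in proteins:
                proteins.append(pid)
    receptor_series = [mean_amounts[t].get(receptor_id, 0.0) for t in timepoints]
    profiles = []
    for pid in proteins:
        series = [mean_amounts[t].get(pid, 0.0) for t in timepoints]
        profiles.append(
            stoich.normalize_timecourse(pid, timepoints, series, receptor_series)
        )
    return profiles


def quantify_and_contextualize(
    lysate_measurements,
    lysate_samples: Mapping[str, SampleMeta],
    ap_measurements,
    ap_samples: Mapping[str, SampleMeta],
    complexes: Sequence[ComplexDefinition],
    monomer_mw: Mapping[str, float],
    peak_timepoint: float = 10.0,
    aggregate: str = "mean",
) -> dict:
    """Run quantify -> stoich -> context on peptide tables and return the
    stage outputs in one dictionary."""
    receptor = receptor_complex(complexes)
    receptor_id = receptor.member_ids[0]
    lysate_amounts = quantify_table(lysate_measurements, method=aggregate)
    ap_amounts = quantify_table(ap_measurements, method=aggregate)
    copies = lysate_copies_per_cell(lysate_amounts, lysate_samples, calibrant_id=receptor_id)
    bound = ap_bound_per_receptor_unit(
        ap_amounts, ap_samples, receptor_id, receptor.receptor_oligomer
    )
    recovered = ap_recovered_copies(ap_amounts, ap_samples, peak_timepoint)
    allocation = allocation_analysis(copies, complexes, recovered)
    estimates = stoichiometry_by_timepoint(bound, complexes)
    mass_estimates = []
    for t in sorted(bound):
        bound_amounts = {
            pid: v for pid, v in bound[t].items() if pid != receptor_id and v > 0
        }
        known = {pid: v for pid, v in bound_amounts.items() if pid in monomer_mw}
        mass_estimates.append(
            ctx.signalosome_mass(
                known,
                receptor_amount=float(receptor.receptor_oligomer),
                receptor_id=receptor_id,
                monomer_mw=monomer_mw,
                timepoint=t,
                receptor_oligomer=receptor.receptor_oligomer,
                per="trimer",
            )
        )
    profiles = recruitment_profiles(ap_amounts, ap_samples, receptor_id)
    return {
        "lysate_amounts": lysate_amounts,
        "ap_amounts": ap_amounts,
        "copies_per_cell": copies,
        "bound_per_receptor_unit": bound,
        "recovered_copies": recovered,
        "allocation": allocation,
        "stoichiometry": estimates,
        "mass_estimates": mass_estimates,
        "recruitment_profiles": profiles,
    }
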