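"""Synthetic ground truth and simulated measurements.

The generator produces a known cellular state — copies per cell of every
monitored protein, complex definitions with integer multiplicities, and
receptor-recruitment kinetics — and simulates from it the three
measurement designs the analysis consumes:

* lysate quantification with a five-level reference-peptide spike ladder,
* time-resolved affinity-purification quantification with a four-level
  ladder, where the amount of each protein bound to the receptor follows
  saturating recruitment kinetics peaking at 10 minutes,
* native-gel migration profiles, well-trapped without deubiquitinase
  treatment and a periodic ladder of peaks with it.

The noise model is multiplicative lognormal on intensities with a shared
per-peptide response factor: the factor multiplies the endogenous and the
reference channel identically and cancels in their ratio, which is
exactly the cancellation the spike-in design relies on.  The per-channel
lognormal sigma is set so the CV of the endogenous/reference ratio equals
``noise_cv``.  True amounts below the detection limit are censored (the
row is omitted, not zero-filled).

Default parameter values encode the emulated cellular state: a receptor
at about 2.5e4 copies per cell, member copy numbers in the 1e3-1e6 range,
a deubiquitinase-module member held below its isostoichiometry
requirement, substoichiometric accessory factors, and heavily
super-stoichiometric conjugated ubiquitin.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .context import AVOGADRO, copies_required_for_isostoichiometry
from .model import (
    ComplexDefinition,
    ConfigError,
    PeptideMeasurement,
    SampleMeta,
    ValidationError,
    receptor_complex,
)

# ---------------------------------------------------------------------------
# Default cellular state

DEFAULT_COMPLEXES: Tuple[ComplexDefinition, ...] = (
    ComplexDefinition(
        "receptor", (("TNFR1", 3),), receptor_flag=True, receptor_oligomer=3
    ),
    ComplexDefinition(
        "core", (("TRADD", 3), ("RIPK1", 3), ("TRAF2", 3), ("BIRC2", 1))
    ),
    ComplexDefinition("lubac", (("HOIP", 1), ("HOIL1", 2), ("SHARPIN", 2))),
    ComplexDefinition("cyld_spata2", (("CYLD", 2), ("SPATA2", 2))),
    ComplexDefinition("ikk", (("NEMO", 2), ("IKKA", 1), ("IKKB", 1))),
    ComplexDefinition("tab_tak1", (("TAB1", 2), ("TAB2", 2), ("TAK1", 1))),
    ComplexDefinition("tbk1_module", (("TANK", 2), ("TBK1", 2))),
)

#: copies per cell of the emulated steady state
DEFAULT_COPIES_PER_CELL: Dict[str, float] = {
    "TNFR1": 25_000.0,
    "TRADD": 120_000.0,
    "RIPK1": 90_000.0,
    "TRAF2": 200_000.0,
    "BIRC2": 60_000.0,
    "HOIP": 50_000.0,
    "HOIL1": 70_000.0,
    "SHARPIN": 150_000.0,
    "CYLD": 12_000.0,
    "SPATA2": 6_000.0,
    "NEMO": 300_000.0,
    "IKKA": 150_000.0,
    "IKKB": 250_000.0,
    "TAB1": 80_000.0,
    "TAB2": 40_000.0,
    "TAK1": 100_000.0,
    "TANK": 50_000.0,
    "TBK1": 60_000.0,
    "UBIQ": 50_000_000.0,
    "WHIP": 40_000.0,
    "UBASH3B": 20_000.0,
    "A20": 30_000.0,
    "TAX1BP1": 25_000.0,
}

#: monomer molecular weights, kDa
DEFAULT_MONOMER_MW: Dict[str, float] = {
    "TNFR1": 50.0,
    "TRADD": 34.0,
    "RIPK1": 76.0,
    "TRAF2": 56.0,
    "BIRC2": 70.0,
    "HOIP": 120.0,
    "HOIL1": 58.0,
    "SHARPIN": 40.0,
    "CYLD": 107.0,
    "SPATA2": 58.0,
    "NEMO": 48.0,
    "IKKA": 85.0,
    "IKKB": 87.0,
    "TAB1": 55.0,
    "TAB2": 76.0,
    "TAK1": 67.0,
    "TANK": 50.0,
    "TBK1": 84.0,
    "UBIQ": 8.5,
    "WHIP": 72.0,
    "UBASH3B": 75.0,
    "A20": 90.0,
    "TAX1BP1": 90.0,
}

#: occupancy of each complex per trimeric receptor unit at peak recruitment
DEFAULT_OCCUPANCY: Dict[str, float] = {
    "core": 0.8,
    "lubac": 0.5,
    "cyld_spata2": 0.11,
    "ikk": 0.9,
    "tab_tak1": 0.4,
    "tbk1_module": 0.3,
}

#: accessory (non-structural) factors: copies bound per trimer at peak
DEFAULT_ASSOCIATED_BOUND: Dict[str, float] = {
    "WHIP": 0.06,
    "UBASH3B": 0.05,
    "A20": 0.08,
    "TAX1BP1": 0.04,
}

DEFAULT_UBIQUITIN_PER_RECEPTOR = 550.0

DEFAULT_TIMEPOINTS = (0.0, 5.0, 10.0, 15.0)

# lysate ruler design: 100 ug digested at 230 pg/cell, 0.7% injected
LYSATE_MASS_PER_CELL_PG = 230.0
LYSATE_PROTEIN_UG = 100.0
LYSATE_CELL_EQUIVALENTS = LYSATE_PROTEIN_UG * 1e6 / LYSATE_MASS_PER_CELL_PG
LYSATE_INJECTED_FRACTION = 0.007

# affinity-purification design: 2% of 1.2e8 starting cells processed
AP_STARTING_CELLS = 1.2e8
AP_PROCESSED_FRACTION = 0.02
AP_PROCESSED_CELLS = AP_STARTING_CELLS * AP_PROCESSED_FRACTION
AP_INJECTED_FRACTION = 0.1

SPIKE_MIN_AMOL = 16.0
SPIKE_MAX_AMOL = 160_000.0


@dataclass(frozen=True)
class RecruitmentParams:
    """Saturating recruitment with lag, peak time, and post-peak decay."""

    lag: float = 0.0
    rate: float = 0.4
    peak_time: float = 10.0
    decay: float = 0.05

    def fraction(self, t: float) -> float:
        """Recruitment level in [0, 1]; maximal at ``peak_time``."""
        if t < 0:
            raise ValidationError("timepoint must be >= 0")
        if t <= self.lag:
            return 0.0
        if t <= self.peak_time:
            num = 1.0 - math.exp(-self.rate * (t - self.lag))
            den = 1.0 - math.exp(-self.rate * (self.peak_time - self.lag))
            return num / den
        return math.exp(-self.decay * (t - self.peak_time))


DEFAULT_RECRUITMENT: Dict[str, RecruitmentParams] = {
    "core": RecruitmentParams(lag=0.0, rate=0.5),
    "lubac": RecruitmentParams(lag=1.0, rate=0.4),
    "cyld_spata2": RecruitmentParams(lag=2.0, rate=0.35),
    "ikk": RecruitmentParams(lag=1.0, rate=0.4),
    "tab_tak1": RecruitmentParams(lag=1.0, rate=0.45),
    "tbk1_module": RecruitmentParams(lag=2.0, rate=0.3),
    "ubiquitin": RecruitmentParams(lag=0.0, rate=0.25),
    "associated": RecruitmentParams(lag=2.0, rate=0.3),
}


@dataclass(frozen=True)
class GroundTruth:
    """The simulated cellular state every downstream stage is tested against."""

    seed: int
    copies_per_cell: Mapping[str, float]
    complexes: Tuple[ComplexDefinition, ...]
    occupancy: Mapping[str, float]
    recruitment_params: Mapping[str, RecruitmentParams]
    associated_bound: Mapping[str, float]
    ubiquitin_id: str
    ubiquitin_per_receptor: float
    monomer_mw: Mapping[str, float]
    timepoints: Tuple[float, ...]
    noise_cv: float
    response_factor_sigma: float
    lod_amol: float
    bound_per_receptor: Mapping[Tuple[str, float], float] = field(default_factory=dict)

    @property
    def receptor(self) -> ComplexDefinition:
        return receptor_complex(self.complexes)

    @property
    def receptor_id(self) -> str:
        return self.receptor.member_ids[0]

    @property
    def receptor_oligomer(self) -> int:
        return self.receptor.receptor_oligomer

    @property
    def receptor_units_per_cell(self) -> float:
        """Oligomeric (trimeric) receptor units per cell."""
        return self.copies_per_cell[self.receptor_id] / self.receptor_oligomer

    def protein_ids(self) -> List[str]:
        return list(self.copies_per_cell.keys())

    def member_ids(self) -> List[str]:
        out: List[str] = []
        for c in self.complexes:
            for pid in c.member_ids:
                if pid not in out:
                    out.append(pid)
        return out

    def complex_of(self, protein_id: str) -> Optional[ComplexDefinition]:
        for c in self.complexes:
            if protein_id in c.member_ids:
                return c
        return None

    def bound_at(self, protein_id: str, t: float) -> float:
        """Copies of a protein bound per oligomeric receptor unit at time t."""
        if t < 0:
            raise ValidationError("timepoint must be >= 0")
        if protein_id == self.receptor_id:
            return float(self.receptor_oligomer)
        if protein_id == self.ubiquitin_id:
            return self.ubiquitin_per_receptor * self.recruitment_params[
                "ubiquitin"
            ].fraction(t)
        if protein_id in self.associated_bound:
            return self.associated_bound[protein_id] * self.recruitment_params[
                "associated"
            ].fraction(t)
        cdef = self.complex_of(protein_id)
        if cdef is None:
            return 0.0
        params = self.recruitment_params[cdef.complex_name]
        occupancy = self.occupancy.get(cdef.complex_name, 0.0)
        return cdef.multiplicities[protein_id] * occupancy * params.fraction(t)

    def true_limiting_set(self) -> set:
        """Complex members whose copies fall below the isostoichiometry
        requirement implied by the true receptor copy number."""
        receptor_copies = self.copies_per_cell[self.receptor_id]
        limiting = set()
        for cdef in self.complexes:
            if cdef.receptor_flag:
                continue
            required = copies_required_for_isostoichiometry(
                cdef, receptor_copies, self.receptor_oligomer
            )
            for pid, req in required.items():
                if self.copies_per_cell.get(pid, 0.0) < req:
                    limiting.add(pid)
        return limiting


def generate_truth(config: Optional[Mapping] = None, seed: int = 0) -> GroundTruth:
    """Build a ground-truth cellular state; deterministic for a given seed.

    ``config`` may override ``complexes``, fix ``copies_per_cell`` exactly,
    supply a ``copies_range`` (log-uniform sampling bounds for proteins
    without fixed copies), and set ``occupancy``, ``noise_cv``,
    ``response_factor_sigma``, ``lod_amol``, ``timepoints``,
    ``ubiquitin_per_receptor``, and ``monomer_mw``.
    """
    config = dict(config or {})
    complexes = tuple(config.get("complexes", DEFAULT_COMPLEXES))
    receptor = receptor_complex(complexes)  # raises unless exactly one

    copies = dict(config.get("copies_per_cell", DEFAULT_COPIES_PER_CELL))
    if receptor.member_ids[0] not in copies:
        raise ConfigError(
            f"receptor {receptor.member_ids[0]} has no copies_per_cell entry"
        )
    rng = np.random.default_rng(seed)
    lo, hi = config.get("copies_range", (1e3, 1e6))
    if lo > hi:
        raise ConfigError(f"copies_range min {lo} > max {hi}")
    for cdef in complexes:
        for pid in cdef.member_ids:
            if pid not in copies:
                copies[pid] = float(
                    10 ** rng.uniform(math.log10(lo), math.log10(hi))
                )
    for value in copies.values():
        if value <= 0:
            raise ConfigError("copies_per_cell values must be > 0")

    recruitment = dict(DEFAULT_RECRUITMENT)
    recruitment.update(config.get("recruitment_params", {}))
    occupancy = dict(DEFAULT_OCCUPANCY)
    occupancy.update(config.get("occupancy", {}))
    timepoints = tuple(float(t) for t in config.get("timepoints", DEFAULT_TIMEPOINTS))
    truth = GroundTruth(
        seed=seed,
        copies_per_cell=copies,
        complexes=complexes,
        occupancy=occupancy,
        recruitment_params=recruitment,
        associated_bound=dict(
            config.get("associated_bound", DEFAULT_ASSOCIATED_BOUND)
        ),
        ubiquitin_id=config.get("ubiquitin_id", "UBIQ"),
        ubiquitin_per_receptor=float(
            config.get("ubiquitin_per_receptor", DEFAULT_UBIQUITIN_PER_RECEPTOR)
        ),
        monomer_mw=dict(config.get("monomer_mw", DEFAULT_MONOMER_MW)),
        timepoints=timepoints,
        noise_cv=float(config.get("noise_cv", 0.2)),
        response_factor_sigma=float(config.get("response_factor_sigma", 1.0)),
        lod_amol=float(config.get("lod_amol", 0.01)),
    )
    if truth.noise_cv < 0 or truth.lod_amol < 0:
        raise ConfigError("noise_cv and lod_amol must be >= 0")
    bound = {
        (pid, t): truth.bound_at(pid, t)
        for pid in truth.protein_ids()
        for t in timepoints
    }
    return GroundTruth(**{**asdict_shallow(truth), "bound_per_receptor": bound})


def asdict_shallow(truth: GroundTruth) -> dict:
    """Field dict of a GroundTruth without deep-copying nested dataclasses."""
    return {
        name: getattr(truth, name) for name in truth.__dataclass_fields__
    }


# ---------------------------------------------------------------------------
# Peptide-level simulation


def spike_ladder(levels: int) -> np.ndarray:
    """Geometric spike ladder spanning the design range [16, 160000] amol."""
    if levels < 2:
        raise ValidationError("need at least 2 spike levels")
    return np.geomspace(SPIKE_MIN_AMOL, SPIKE_MAX_AMOL, num=levels)


def _nearest_spike(true_amount: float, ladder: np.ndarray) -> float:
    """Spike level closest to the true amount in log space (the design
    matches reference to endogenous concentration)."""
    if true_amount <= ladder[0]:
        return float(ladder[0])
    return float(ladder[np.argmin(np.abs(np.log(ladder) - np.log(true_amount)))])


def _peptide_sequences(truth: GroundTruth, peptides_per_protein: int) -> Dict[str, List[str]]:
    """Deterministic synthetic tryptic peptide sequences per protein.

    Derived from the truth seed so lysate and AP simulations share the
    same peptide identities.
    """
    rng = np.random.default_rng(truth.seed + 104729)
    alphabet = np.array(list("ACDEFGHILMNQSTVWY"))  # no K/R/P inside
    out: Dict[str, List[str]] = {}
    for pid in truth.protein_ids():
        seqs = []
        for _ in range(peptides_per_protein):
            length = int(rng.integers(8, 14))
            body = "".join(rng.choice(alphabet, size=length))
            seqs.append(body + "K")
        out[pid] = seqs
    return out


def _channel_sigma(noise_cv: float) -> float:
    """Per-channel lognormal sigma so the two-channel ratio CV equals
    noise_cv: the ratio's log-sd is sqrt(2) sigma and the CV of a
    lognormal with log-sd s is sqrt(exp(s^2) - 1)."""
    return math.sqrt(math.log(1.0 + noise_cv**2) / 2.0)


def _simulate_rows(
    rng: np.random.Generator,
    sample_id: str,
    true_amounts: Mapping[str, float],
    sequences: Mapping[str, List[str]],
    response_factors: Mapping[str, float],
    ladder: np.ndarray,
    noise_cv: float,
    lod_amol: float,
) -> List[PeptideMeasurement]:
    sigma = _channel_sigma(noise_cv)
    rows: List[PeptideMeasurement] = []
    for pid, amount in true_amounts.items():
        if amount < lod_amol:
            continue  # censored: below detection limit
        spike = _nearest_spike(amount, ladder)
        for seq in sequences[pid]:
            rf = response_factors[seq]
            eps_endo = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            eps_ref = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            rows.append(
                PeptideMeasurement(
                    sample_id=sample_id,
                    protein_id=pid,
                    peptide_sequence=seq,
                    charge=2,
                    endogenous_intensity=rf * amount * math.exp(eps_endo),
                    reference_intensity=rf * spike * math.exp(eps_ref),
                    spike_amount=spike,
                )
            )
    return rows


def lysate_true_amounts(truth: GroundTruth, cell_equivalents: float) -> Dict[str, float]:
    """True amount (amol) of each protein in a lysate digest representing
    the given number of cell equivalents."""
    return {
        pid: copies * cell_equivalents / AVOGADRO * 1e18
        for pid, copies in truth.copies_per_cell.items()
    }


def ap_true_amounts(
    truth: GroundTruth, t: float, processed_cells: float
) -> Dict[str, float]:
    """True amount (amol) of each protein captured on the receptor at time
    t across the processed cells."""
    units = truth.receptor_units_per_cell * processed_cells
    return {
        pid: truth.bound_at(pid, t) * units / AVOGADRO * 1e18
        for pid in truth.protein_ids()
    }


def simulate_lysate_quant(
    truth: GroundTruth,
    n_replicates: int = 3,
    peptides_per_protein: int = 3,
    spike_levels: int = 5,
    timepoints: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> Tuple[List[PeptideMeasurement], List[SampleMeta]]:
    """Simulate the lysate quantification design: ``n_replicates`` lysates
    per timepoint, a five-level spike ladder, spike point right after
    lysis (cell equivalents of the digested material)."""
    if peptides_per_protein < 1:
        raise ValidationError("peptides_per_protein must be >= 1")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    timepoints = tuple(timepoints if timepoints is not None else truth.timepoints)
    rng = np.random.default_rng(seed)
    sequences = _peptide_sequences(truth, peptides_per_protein)
    response_factors = {
        seq: float(np.exp(rng.normal(0.0, truth.response_factor_sigma)))
        if truth.response_factor_sigma > 0
        else 1.0
        for seqs in sequences.values()
        for seq in seqs
    }
    ladder = spike_ladder(spike_levels)
    true_amounts = lysate_true_amounts(truth, LYSATE_CELL_EQUIVALENTS)
    rows: List[PeptideMeasurement] = []
    samples: List[SampleMeta] = []
    for t in timepoints:
        for rep in range(1, n_replicates + 1):
            sample_id = f"lysate_t{t:g}_r{rep}"
            samples.append(
                SampleMeta(
                    sample_id=sample_id,
                    sample_type="lysate",
                    timepoint=t,
                    replicate=rep,
                    cell_equivalents=LYSATE_CELL_EQUIVALENTS,
                    injected_fraction=LYSATE_INJECTED_FRACTION,
                )
            )
            rows.extend(
                _simulate_rows(
                    rng,
                    sample_id,
                    true_amounts,
                    sequences,
                    response_factors,
                    ladder,
                    truth.noise_cv,
                    truth.lod_amol,
                )
            )
    return rows, samples


def simulate_ap_quant(
    truth: GroundTruth,
    timepoints: Optional[Sequence[float]] = None,
    processed_cells: float = AP_PROCESSED_CELLS,
    injected_fraction: float = AP_INJECTED_FRACTION,
    n_replicates: int = 3,
    peptides_per_protein: int = 3,
    spike_levels: int = 4,
    seed: int = 0,
) -> Tuple[List[PeptideMeasurement], List[SampleMeta]]:
    """Simulate the time-resolved affinity-purification design.

    The amount of each protein in the purified material is its bound
    copies per receptor unit times the receptor units captured from the
    processed cells; at t=0 only the receptor itself carries signal.
    The spike point is the final peptide matrix, so the spike-point cell
    equivalents equal the processed cells.
    """
    timepoints = tuple(timepoints if timepoints is not None else truth.timepoints)
    if any(t < 0 for t in timepoints):
        raise ValidationError("timepoints must be >= 0")
    if 0.0 not in timepoints:
        raise ValidationError("timepoints must include 0 (unstimulated reference)")
    if processed_cells <= 0:
        raise ValidationError("processed_cells must be > 0")
    rng = np.random.default_rng(seed)
    sequences = _peptide_sequences(truth, peptides_per_protein)
    response_factors = {
        seq: float(np.exp(rng.normal(0.0, truth.response_factor_sigma)))
        if truth.response_factor_sigma > 0
        else 1.0
        for seqs in sequences.values()
        for seq in seqs
    }
    ladder = spike_ladder(spike_levels)
    rows: List[PeptideMeasurement] = []
    samples: List[SampleMeta] = []
    for t in timepoints:
        true_amounts = ap_true_amounts(truth, t, processed_cells)
        for rep in range(1, n_replicates + 1):
            sample_id = f"ap_t{t:g}_r{rep}"
            samples.append(
                SampleMeta(
                    sample_id=sample_id,
                    sample_type="affinity_purification",
                    timepoint=t,
                    replicate=rep,
                    cell_equivalents=processed_cells,
                    injected_fraction=injected_fraction,
                )
            )
            rows.extend(
                _simulate_rows(
                    rng,
                    sample_id,
                    true_amounts,
                    sequences,
                    response_factors,
                    ladder,
                    truth.noise_cv,
                    truth.lod_amol,
                )
            )
    return rows, samples


def simulate_bnpage_profiles(
    truth: GroundTruth,
    n_fractions: int = 70,
    period: int = 10,
    well_fractions: int = 3,
    noise_floor: float = 0.01,
    peak_sigma: float = 1.2,
    peak_decay: float = 0.75,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate native-gel migration profiles for both conditions.

    minusDUB: the intact assembly stays trapped in the well, so each
    protein's signal piles into fractions 1..well_fractions (all of it at
    zero noise).  plusDUB: a ladder of Gaussian peaks at
    period, 2*period, ... with geometrically decaying heights — regularly
    spaced peaks with constant successive intensity ratios — plus an
    additive uniform noise floor in both conditions.

    Returns a long-format table (protein_id, condition, fraction_index,
    intensity).
    """
    if not (2 <= period < n_fractions):
        raise ValidationError("period must satisfy 2 <= period < n_fractions")
    if well_fractions < 1 or well_fractions >= n_fractions:
        raise ValidationError("well_fractions must be in [1, n_fractions)")
    rng = np.random.default_rng(seed)
    x = np.arange(1, n_fractions + 1, dtype=float)
    well_weights = 0.5 ** np.arange(well_fractions)
    centers = np.arange(period, n_fractions - 2 * int(peak_sigma), period)
    rows = []
    for pid in truth.protein_ids():
        amplitude = float(np.exp(rng.normal(0.0, 0.5)))
        minus = np.zeros(n_fractions)
        minus[:well_fractions] = amplitude * well_weights
        plus = np.zeros(n_fractions)
        for k, center in enumerate(centers):
            plus += (
                amplitude
                * peak_decay**k
                * np.exp(-((x - center) ** 2) / (2 * peak_sigma**2))
            )
        if noise_floor > 0:
            minus = minus + noise_floor * amplitude * rng.uniform(size=n_fractions)
            plus = plus + noise_floor * amplitude * rng.uniform(size=n_fractions)
        for cond, vec in (("minusDUB", minus), ("plusDUB", plus)):
            for i, v in enumerate(vec, start=1):
                rows.append(
                    {
                        "protein_id": pid,
                        "condition": cond,
                        "fraction_index": i,
                        "intensity": float(v),
                    }
                )
    return pd.DataFrame(rows, columns=["protein_id", "condition", "fraction_index", "intensity"])


# ---------------------------------------------------------------------------
# Ground-truth serialization (JSON, for test oracles and the CLI)


def truth_to_json(truth: GroundTruth, path: str) -> None:
    doc = {
        "seed": truth.seed,
        "copies_per_cell": dict(truth.copies_per_cell),
        "complexes": [
            {
                "name": c.complex_name,
                "receptor": c.receptor_flag,
                "receptor_oligomer": c.receptor_oligomer,
                "reference_policy": c.reference_policy,
                "members": [[pid, mult] for pid, mult in c.members],
            }
            for c in truth.complexes
        ],
        "occupancy": dict(truth.occupancy),
        "recruitment_params": {
            name: asdict(params) for name, params in truth.recruitment_params.items()
        },
        "associated_bound": dict(truth.associated_bound),
        "ubiquitin_id": truth.ubiquitin_id,
        "ubiquitin_per_receptor": truth.ubiquitin_per_receptor,
        "monomer_mw": dict(truth.monomer_mw),
        "timepoints": list(truth.timepoints),
        "noise_cv": truth.noise_cv,
        "response_factor_sigma": truth.response_factor_sigma,
        "lod_amol": truth.lod_amol,
        "bound_per_receptor": [
            [pid, t, v] for (pid, t), v in truth.bound_per_receptor.items()
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def truth_from_json(path: str) -> GroundTruth:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    complexes = tuple(
        ComplexDefinition(
            complex_name=c["name"],
            members=tuple((pid, int(mult)) for pid, mult in c["members"]),
            reference_policy=c["reference_policy"],
            receptor_flag=c["receptor"],
            receptor_oligomer=int(c["receptor_oligomer"]),
        )
        for c in doc["complexes"]
    )
    return GroundTruth(
        seed=int(doc["seed"]),
        copies_per_cell=doc["copies_per_cell"],
        complexes=complexes,
        occupancy=doc["occupancy"],
        recruitment_params={
            name: RecruitmentParams(**params)
            for name, params in doc["recruitment_params"].items()
        },
        associated_bound=doc["associated_bound"],
        ubiquitin_id=doc["ubiquitin_id"],
        ubiquitin_per_receptor=doc["ubiquitin_per_receptor"],
        monomer_mw=doc["monomer_mw"],
        timepoints=tuple(doc["timepoints"]),
        noise_cv=doc["noise_cv"],
        response_factor_sigma=doc["response_factor_sigma"],
        lod_amol=doc["lod_amol"],
        bound_per_receptor={
            (pid, float(t)): v for pid, t, v in doc["bound_per_receptor"]
        },
    )
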