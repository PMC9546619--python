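"""Complex stoichiometry inference and recruitment time-course analysis.

Relative stoichiometry is the ratio of each member's absolute amount to
the most abundant member (or a fixed reference).  Integer stoichiometry
models are found by exhaustive enumeration over bounded base vectors,
optionally extended by one additive "excess" vector — the partial-complex
isoform pattern in which surplus copies of some subunits ride along with a
core isostoichiometric complex.  Fits are scored by root-mean-square error
in log2 space, so a 2x and a 0.5x discrepancy weigh equally.
"""

from __future__ import annotations

import functools
import itertools
import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .model import ComplexDefinition, InsufficientDataError, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StoichiometryEstimate:
    complex_name: str
    timepoint: Optional[float]
    reference_member: str
    ratios: Mapping[str, float]
    source: str = "aqua"
    missing_members: Tuple[str, ...] = ()


@dataclass(frozen=True)
class IntegerModel:
    """One candidate integer stoichiometry: base + optional excess vector."""

    members: Tuple[str, ...]
    base: Tuple[int, ...]
    excess: Optional[Tuple[int, ...]]
    predicted_ratios: Tuple[float, ...]
    fit_error: float

    @property
    def total_copies(self) -> int:
        return sum(self.base) + (sum(self.excess) if self.excess else 0)

    @property
    def composition(self) -> Tuple[int, ...]:
        if self.excess is None:
            return self.base
        return tuple(b + e for b, e in zip(self.base, self.excess))

    def as_dicts(self) -> Tuple[Dict[str, int], Optional[Dict[str, int]]]:
        base = dict(zip(self.members, self.base))
        excess = dict(zip(self.members, self.excess)) if self.excess else None
        return base, excess


@dataclass(frozen=True)
class RecruitmentProfile:
    """Receptor-normalized, max-normalized recruitment time course."""

    protein_id: str
    timepoints: Tuple[float, ...]
    values: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.values):
            raise ValidationError("timepoints and values differ in length")


@dataclass(frozen=True)
class BoundFraction:
    fraction: float
    over_unity: bool


def relative_stoichiometry(
    complex_def: ComplexDefinition,
    amounts: Mapping[str, float],
    timepoint: Optional[float] = None,
    source: str = "aqua",
    policy: Optional[str] = None,
) -> StoichiometryEstimate:
    """Member amounts relative to the reference member.

    Under the ``most_abundant`` policy the reference is the member with the
    largest amount (ties broken by member order in the definition); under
    ``fixed:<protein_id>`` it is that member.  Members absent from
    ``amounts`` are reported in ``missing_members`` with no ratio.
    """
    policy = policy or complex_def.reference_policy
    present = [
        (pid, amounts[pid]) for pid in complex_def.member_ids if pid in amounts
    ]
    missing = tuple(pid for pid in complex_def.member_ids if pid not in amounts)
    if not present or all(a == 0 for _, a in present):
        raise InsufficientDataError(
            f"all member amounts of {complex_def.complex_name} are zero or missing"
        )
    if policy == "most_abundant":
        reference = max(present, key=lambda t: t[1])[0]
    else:
        reference = policy.split(":", 1)[1]
        if reference not in dict(present):
            raise InsufficientDataError(
                f"fixed reference {reference} has no amount in "
                f"{complex_def.complex_name}"
            )
    ref_amount = dict(present)[reference]
    if ref_amount <= 0:
        raise InsufficientDataError(
            f"reference member {reference} has amount 0 in {complex_def.complex_name}"
        )
    ratios = {pid: amount / ref_amount for pid, amount in present}
    return StoichiometryEstimate(
        complex_name=complex_def.complex_name,
        timepoint=timepoint,
        reference_member=reference,
        ratios=ratios,
        source=source,
        missing_members=missing,
    )


def _gcd_reduced(vec: Tuple[int, ...]) -> bool:
    return math.gcd(*vec) == 1


def enumerate_candidates(
    n_members: int, max_copies: int = 4, allow_excess: bool = True
) -> List[Tuple[Tuple[int, ...], Optional[Tuple[int, ...]]]]:
    """All (base, excess) candidates of the bounded search space.

    Base vectors have every entry in 1..max_copies and gcd 1; excess
    vectors (when allowed) have entries in 0..max_copies and are not all
    zero.  The space is small by construction so enumeration is exhaustive.
    """
    if max_copies < 1:
        raise ValueError("max_copies must be >= 1")
    bases = [
        vec
        for vec in itertools.product(range(1, max_copies + 1), repeat=n_members)
        if _gcd_reduced(vec)
    ]
    candidates: List[Tuple[Tuple[int, ...], Optional[Tuple[int, ...]]]] = [
        (base, None) for base in bases
    ]
    if allow_excess:
        excesses = [
            vec
            for vec in itertools.product(range(0, max_copies + 1), repeat=n_members)
            if any(vec)
        ]
        candidates.extend(itertools.product(bases, excesses))
    return candidates


@functools.lru_cache(maxsize=16)
def _candidate_arrays(
    n_members: int, max_copies: int, allow_excess: bool
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized candidate set: base matrix, excess matrix (-1 marks "no
    excess vector"), log2 of the max-normalized composition, total copies."""
    candidates = enumerate_candidates(n_members, max_copies, allow_excess)
    base = np.array([b for b, _ in candidates], dtype=np.int64)
    excess = np.array(
        [e if e is not None else (-1,) * n_members for _, e in candidates],
        dtype=np.int64,
    )
    comp = base + np.where(excess >= 0, excess, 0)
    pred_log = np.log2(comp / comp.max(axis=1, keepdims=True))
    copies = comp.sum(axis=1)
    return base, excess, pred_log, copies


def fit_integer_stoichiometry(
    observed_ratios: Mapping[str, float],
    max_copies: int = 4,
    allow_excess: bool = True,
    top: Optional[int] = 10,
) -> List[IntegerModel]:
    """Rank integer stoichiometry models against observed member ratios.

    Predicted ratios are the (base + excess) composition normalized to its
    maximum; the fit error is the RMS log2 difference to the observed
    ratios (also max-normalized).  Ranking: fit error, then total copy
    number (parsimony), then lexicographic order of (base, excess) —
    fully deterministic.  Distinct decompositions can predict identical
    ratios; callers comparing models should compare predicted ratios.
    """
    members = tuple(observed_ratios.keys())
    if len(members) < 2:
        raise InsufficientDataError("need at least 2 members with ratios")
    if max_copies < 1:
        raise ValueError("max_copies must be >= 1")
    obs = np.array([observed_ratios[m] for m in members], dtype=float)
    if not np.all(np.isfinite(obs)) or np.any(obs <= 0):
        raise ValidationError("observed ratios must be finite and > 0")
    obs_log = np.log2(obs / obs.max())
    base, excess, pred_log, copies = _candidate_arrays(
        len(members), max_copies, allow_excess
    )
    errors = np.sqrt(np.mean((pred_log - obs_log) ** 2, axis=1))
    # lexsort: last key is primary — error, then parsimony, then (base, excess)
    flat = np.hstack([base, np.where(excess >= 0, excess, 0)])
    keys = [flat[:, j] for j in range(flat.shape[1] - 1, -1, -1)]
    order = np.lexsort(keys + [copies, errors])
    if top is not None:
        order = order[:top]
    models = []
    for i in order:
        has_excess = excess[i, 0] >= 0
        models.append(
            IntegerModel(
                members=members,
                base=tuple(int(v) for v in base[i]),
                excess=tuple(int(v) for v in excess[i]) if has_excess else None,
                predicted_ratios=tuple(np.exp2(pred_log[i])),
                fit_error=float(errors[i]),
            )
        )
    return models


def occupancy_fraction(
    bait_amount: float, interactor_amount: float, interactor_multiplicity: int = 1
) -> float:
    """Fraction of bait molecules occupied by an interactor.

    Values above 1 are legitimate (super-stoichiometric binding, e.g.
    ubiquitin chains) and returned as-is.
    """
    if bait_amount <= 0:
        raise ValidationError("bait_amount must be > 0")
    if interactor_multiplicity < 1:
        raise ValidationError("interactor_multiplicity must be >= 1")
    return (interactor_amount / interactor_multiplicity) / bait_amount


def complex_bound_fraction(
    carrier_complexes: float, cargo_complexes: float
) -> BoundFraction:
    """Fraction of carrier complexes that have a cargo complex bound."""
    if carrier_complexes <= 0:
        raise ValidationError("carrier_complexes must be > 0")
    fraction = cargo_complexes / carrier_complexes
    return BoundFraction(fraction=fraction, over_unity=fraction > 1.0)


def normalize_timecourse(
    protein_id: str,
    timepoints: Sequence[float],
    amounts: Sequence[float],
    receptor_amounts: Sequence[float],
) -> RecruitmentProfile:
    """Divide a time course by the receptor's, then by its own maximum.

    An all-zero analyte yields a flat-zero profile with a warning instead
    of dividing by a zero maximum.
    """
    if not (len(timepoints) == len(amounts) == len(receptor_amounts)):
        raise ValidationError("timepoint grids differ between analyte and receptor")
    amounts = np.asarray(amounts, dtype=float)
    receptor = np.asarray(receptor_amounts, dtype=float)
    if np.all(amounts == 0):
        log.warning("analyte %s is zero at every timepoint", protein_id)
        return RecruitmentProfile(
            protein_id=protein_id,
            timepoints=tuple(timepoints),
            values=(0.0,) * len(timepoints),
        )
    if np.any((amounts > 0) & (receptor <= 0)):
        raise ValidationError(
            f"receptor amount is 0 at a timepoint where {protein_id} is nonzero"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(receptor > 0, amounts / np.where(receptor > 0, receptor, 1), 0.0)
    values = ratios / ratios.max()
    return RecruitmentProfile(
        protein_id=protein_id, timepoints=tuple(timepoints), values=tuple(values)
    )


def cluster_profiles(
    profiles: Sequence[RecruitmentProfile], k: int = 3
) -> Dict[str, int]:
    """Group recruitment profiles by shape.

    Agglomerative hierarchical clustering with 1 - Pearson correlation as
    the distance and average linkage, cut to ``k`` clusters.  Profiles with
    zero variance have no defined correlation and are placed in singleton
    clusters (labels above ``k``) with a warning.  Labels are 1-based and
    deterministic given the input order.
    """
    if len(profiles) < k:
        raise InsufficientDataError(f"need at least k={k} profiles")
    grids = {p.timepoints for p in profiles}
    if len(grids) != 1:
        raise ValidationError("profiles are not on identical timepoint grids")
    matrix = np.array([p.values for p in profiles], dtype=float)
    variable = np.std(matrix, axis=1) > 0
    labels: Dict[str, int] = {}
    idx_variable = np.flatnonzero(variable)
    if idx_variable.size >= 2 and idx_variable.size >= k:
        dist = pdist(matrix[idx_variable], metric="correlation")
        link = hierarchy.linkage(dist, method="average")
        cut = hierarchy.fcluster(link, t=k, criterion="maxclust")
        for pos, i in enumerate(idx_variable):
            labels[profiles[i].protein_id] = int(cut[pos])
    else:
        for n, i in enumerate(idx_variable, start=1):
            labels[profiles[i].protein_id] = n
    next_label = max(labels.values(), default=0) + 1
    for i in np.flatnonzero(~variable):
        log.warning(
            "profile %s has zero variance; assigned singleton cluster",
            profiles[i].protein_id,
        )
        labels[profiles[i].protein_id] = next_label
        next_label += 1
    return labels
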