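"""Absolute protein quantification from spiked-reference peptide tables.

The core estimator is the AQUA ratio: the endogenous/reference intensity
ratio of a peptide, multiplied by the known spike amount, gives the
endogenous amount directly.  Peptide-specific response factors (ionization
efficiency, "flyability") multiply both channels identically and cancel in
the ratio, which is what makes the method absolute.

Per-protein amounts are the arithmetic mean of per-peptide amounts
(charge states of the same peptide are averaged first so multiply-observed
peptides are not over-weighted); the median is available for outlier-prone
peptide sets.  iBAQ (summed intensity over the number of observable fully
tryptic peptides) provides an orthogonal, label-free relative-molar scale.
"""

from __future__ import annotations

import logging
import statistics
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from pyteomics import parser as pyt_parser
from scipy import stats

from .model import (
    InsufficientDataError,
    PeptideMeasurement,
    ProteinAmount,
    QuantificationError,
    ValidationError,
)

log = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# K/R cleavage, blocked by a following proline; no missed cleavages.
TRYPSIN_RULE = r"[KR](?!P)"


@dataclass(frozen=True)
class DilutionSeries:
    """A peptide's dilution ladder: (injected amount amol, intensity) points."""

    peptide_sequence: str
    points: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValidationError("a dilution series needs at least 3 points")
        amounts = [a for a, _ in self.points]
        if any(b <= a for a, b in zip(amounts, amounts[1:])):
            raise ValidationError("dilution amounts must be strictly increasing")
        if any(i < 0 for _, i in self.points):
            raise ValidationError("intensities must be >= 0")


@dataclass(frozen=True)
class IbaqRecord:
    protein_id: str
    summed_intensity: float
    observable_peptides: int
    ibaq: float


@dataclass(frozen=True)
class LinearityFit:
    slope: float
    intercept: float
    r_squared: float
    n_excluded: int


def quantify_peptide_amount(m: PeptideMeasurement) -> float:
    """Endogenous amount (amol) of one peptide measurement.

    amount = (endogenous / reference) x spike_amount.
    """
    if m.reference_intensity <= 0:
        raise QuantificationError(
            f"reference intensity <= 0 for {m.sample_id}/{m.protein_id}/"
            f"{m.peptide_sequence}/+{m.charge}"
        )
    if m.spike_amount <= 0:
        raise QuantificationError(
            f"spike amount <= 0 for {m.sample_id}/{m.protein_id}/"
            f"{m.peptide_sequence}/+{m.charge}"
        )
    return (m.endogenous_intensity / m.reference_intensity) * m.spike_amount


def aggregate_protein_amount(
    peptide_amounts: Sequence[float],
    sample_id: str = "",
    protein_id: str = "",
    method: str = "mean",
) -> ProteinAmount:
    """Aggregate per-peptide amounts into one protein amount.

    The CV is the sample standard deviation (n-1 denominator) over the
    mean; it is 0 for a single peptide and reported as 0 when the mean is 0.
    """
    if not peptide_amounts:
        raise InsufficientDataError("no peptide-level amounts to aggregate")
    n = len(peptide_amounts)
    mean = statistics.fmean(peptide_amounts)
    if method == "mean":
        amount = mean
    elif method == "median":
        amount = statistics.median(peptide_amounts)
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    if n > 1 and mean > 0:
        cv = statistics.stdev(peptide_amounts) / mean
    else:
        cv = 0.0
    return ProteinAmount(
        sample_id=sample_id, protein_id=protein_id, amount=amount, cv=cv, n_peptides=n
    )


def quantify_table(
    measurements: Iterable[PeptideMeasurement], method: str = "mean"
) -> List[ProteinAmount]:
    """Per-(sample, protein) absolute amounts from a peptide table.

    Charge states of the same peptide are averaged first; rows with zero
    reference intensity are dropped with a warning (no ratio exists); rows
    with zero endogenous intensity contribute an amount of 0.
    """
    per_peptide: Dict[Tuple[str, str, str], List[float]] = defaultdict(list)
    order: List[Tuple[str, str]] = []
    seen = set()
    for m in measurements:
        if m.reference_intensity <= 0 or m.spike_amount <= 0:
            log.warning(
                "dropping row with unusable reference channel: %s/%s/%s",
                m.sample_id,
                m.protein_id,
                m.peptide_sequence,
            )
            continue
        key = (m.sample_id, m.protein_id)
        if key not in seen:
            seen.add(key)
            order.append(key)
        per_peptide[(m.sample_id, m.protein_id, m.peptide_sequence)].append(
            quantify_peptide_amount(m)
        )
    per_protein: Dict[Tuple[str, str], List[float]] = defaultdict(list)
    for (sample_id, protein_id, _), amounts in per_peptide.items():
        per_protein[(sample_id, protein_id)].append(statistics.fmean(amounts))
    return [
        aggregate_protein_amount(per_protein[key], key[0], key[1], method=method)
        for key in order
    ]


def digest_peptides(sequence: str) -> List[str]:
    """Fully tryptic peptides (0 missed cleavages) of a protein sequence."""
    sequence = sequence.upper()
    bad = set(sequence) - AMINO_ACIDS
    if not sequence or bad:
        raise ValidationError(
            f"sequence contains non-amino-acid characters: {sorted(bad)!r}"
        )
    return list(
        pyt_parser.cleave(sequence, TRYPSIN_RULE, missed_cleavages=0, regex=True)
    )


def count_observable_peptides(
    sequence: str, min_len: int = 7, max_len: int = 30
) -> int:
    """Number of distinct fully tryptic peptides with length in [min_len, max_len].

    This is the iBAQ denominator: trypsin cleaves C-terminal to K/R unless
    followed by P, with no missed cleavages.
    """
    return sum(min_len <= len(p) <= max_len for p in set(digest_peptides(sequence)))


def ibaq_abundance(summed_intensity: float, observable_peptides: int) -> IbaqRecord:
    if observable_peptides < 1:
        raise QuantificationError("observable_peptides must be >= 1")
    if summed_intensity < 0:
        raise ValidationError("summed_intensity must be >= 0")
    return IbaqRecord(
        protein_id="",
        summed_intensity=summed_intensity,
        observable_peptides=observable_peptides,
        ibaq=summed_intensity / observable_peptides,
    )


def ibaq_table(
    measurements: Iterable[PeptideMeasurement],
    sequences: Mapping[str, str],
    min_len: int = 7,
    max_len: int = 30,
) -> List[IbaqRecord]:
    """iBAQ per protein from endogenous intensities and protein sequences.

    Proteins with no observable peptides (or no sequence) are excluded with
    a logged warning rather than raising: the rest of the table is fine.
    """
    summed: Dict[str, float] = defaultdict(float)
    order: List[str] = []
    for m in measurements:
        if m.protein_id not in summed:
            order.append(m.protein_id)
        summed[m.protein_id] += m.endogenous_intensity
    records = []
    for pid in order:
        seq = sequences.get(pid)
        if seq is None:
            log.warning("iBAQ: no sequence for %s, protein excluded", pid)
            continue
        n_obs = count_observable_peptides(seq, min_len=min_len, max_len=max_len)
        if n_obs == 0:
            log.warning("iBAQ: %s has no observable peptides, protein excluded", pid)
            continue
        records.append(
            IbaqRecord(
                protein_id=pid,
                summed_intensity=summed[pid],
                observable_peptides=n_obs,
                ibaq=summed[pid] / n_obs,
            )
        )
    return records


def fit_linearity(series: DilutionSeries) -> LinearityFit:
    """OLS of log10(intensity) on log10(amount) over a dilution ladder.

    Zero-intensity points cannot enter log space; they are excluded and
    counted in ``n_excluded``.
    """
    usable = [(a, i) for a, i in series.points if i > 0]
    n_excluded = len(series.points) - len(usable)
    if len(usable) < 3:
        raise InsufficientDataError(
            f"only {len(usable)} usable points after excluding zero intensities"
        )
    x = np.log10([a for a, _ in usable])
    y = np.log10([i for _, i in usable])
    if np.allclose(y, y[0]):
        # constant intensity: slope 0, undefined correlation treated as exact
        return LinearityFit(0.0, float(y[0]), 1.0, n_excluded)
    res = stats.linregress(x, y)
    return LinearityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_excluded=n_excluded,
    )
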