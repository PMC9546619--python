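"""Blue-native PAGE migration-profile analysis.

Intact assemblies too large for the gel stay trapped in the well, piling
signal into the first fractions; deubiquitinase treatment disassembles
ubiquitin-dependent super-complexes into subcomplexes that migrate as a
ladder of regularly spaced peaks.  This module normalizes per-fraction
intensity profiles, locates the first relative minimum used as a
normalization anchor, quantifies the early-to-late signal shift between
conditions with a paired one-sided Wilcoxon signed-rank test, detects
peaks and their periodicity, and computes comigration correlations.

Fraction indices are 1-based throughout, matching gel-slice numbering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .model import ContextomicsError, InsufficientDataError, ValidationError

log = logging.getLogger(__name__)


class NoMinimumError(ContextomicsError):
    """The profile has no relative minimum (monotone shape)."""


@dataclass(frozen=True)
class BNPAGEProfile:
    """Per-fraction intensities of one protein in one condition."""

    protein_id: str
    condition: str
    intensities: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.intensities) < 10:
            raise ValidationError("a gel profile needs at least 10 fractions")
        if any(v < 0 or not np.isfinite(v) for v in self.intensities):
            raise ValidationError("intensities must be finite and >= 0")

    def replace(self, intensities: Sequence[float]) -> "BNPAGEProfile":
        return BNPAGEProfile(self.protein_id, self.condition, tuple(intensities))


@dataclass(frozen=True)
class PeakSet:
    """Detected peaks of one profile with spacing statistics."""

    protein_id: str
    peak_indices: Tuple[int, ...]
    spacings: Tuple[int, ...]
    spacing_mean: Optional[float]
    spacing_cv: Optional[float]
    peak_intensity_ratios: Tuple[float, ...]


@dataclass(frozen=True)
class ShiftResult:
    """Early-fraction signal shares per protein and the paired shift test."""

    early_cutoff: int
    shares_minus: Mapping[str, float]
    shares_plus: Mapping[str, float]
    differences: Mapping[str, float]
    p_value: Optional[float]


def profiles_from_table(df: pd.DataFrame) -> Dict[Tuple[str, str], BNPAGEProfile]:
    """Build profiles from a long table (protein_id, condition,
    fraction_index, intensity); missing fractions are zero-filled."""
    out: Dict[Tuple[str, str], BNPAGEProfile] = {}
    n_fractions = int(df["fraction_index"].max())
    for (pid, cond), grp in df.groupby(["protein_id", "condition"], sort=False):
        vec = np.zeros(n_fractions)
        vec[grp["fraction_index"].to_numpy() - 1] = grp["intensity"].to_numpy()
        out[(pid, cond)] = BNPAGEProfile(pid, cond, tuple(vec))
    return out


def normalize_profile_max(profile: BNPAGEProfile) -> BNPAGEProfile:
    """Scale so the maximum intensity is 1."""
    peak = max(profile.intensities)
    if peak <= 0:
        raise ValidationError(f"profile {profile.protein_id} is all zero")
    return profile.replace([v / peak for v in profile.intensities])


def normalize_profile_to_fraction(
    profile: BNPAGEProfile, fraction_index: int
) -> BNPAGEProfile:
    """Scale so the intensity at the given 1-based fraction is 1."""
    if not (1 <= fraction_index <= len(profile.intensities)):
        raise ValidationError(f"fraction_index {fraction_index} out of range")
    anchor = profile.intensities[fraction_index - 1]
    if anchor <= 0:
        raise ValidationError(
            f"profile {profile.protein_id}: zero intensity at anchor fraction "
            f"{fraction_index}"
        )
    return profile.replace([v / anchor for v in profile.intensities])


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks at the edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd integer")
    half = window // 2
    out = np.empty_like(values, dtype=float)
    for i in range(len(values)):
        lo = max(0, i - half)
        hi = min(len(values), i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def find_first_relative_minimum(
    profile: BNPAGEProfile, smoothing_window: int = 3
) -> int:
    """First relative minimum (1-based fraction index) after smoothing.

    Returns the smallest interior index i with smoothed[i] < smoothed[i-1]
    and smoothed[i] <= smoothed[i+1]; a plateau resolves to its earliest
    index.  Monotone profiles have no relative minimum and raise
    :class:`NoMinimumError`.
    """
    values = np.asarray(profile.intensities, dtype=float)
    if len(values) < 3:
        raise ValidationError("profile too short for minimum detection")
    smoothed = _smooth(values, smoothing_window)
    for i in range(1, len(smoothed) - 1):
        if smoothed[i] < smoothed[i - 1] and smoothed[i] <= smoothed[i + 1]:
            return i + 1
    raise NoMinimumError(
        f"profile {profile.protein_id} has no relative minimum"
    )


def early_share(profile: BNPAGEProfile, early_cutoff: int) -> float:
    """Fraction of total signal in fractions 1..early_cutoff."""
    total = sum(profile.intensities)
    if total <= 0:
        raise ValidationError(f"profile {profile.protein_id} is all zero")
    return sum(profile.intensities[:early_cutoff]) / total


def early_late_shift(
    profiles_minus: Mapping[str, BNPAGEProfile],
    profiles_plus: Mapping[str, BNPAGEProfile],
    early_cutoff: int = 5,
    min_proteins: int = 5,
) -> ShiftResult:
    """Early-fraction signal shares in both conditions and the paired
    one-sided Wilcoxon signed-rank test of share(minus) > share(plus).

    Proteins quantified in only one condition are excluded from the test
    (their shares are still computable via :func:`early_share`).  With
    fewer than ``min_proteins`` matched proteins the test is skipped with
    a warning and the p-value reported absent.  Identical shares in both
    conditions mean no shift; the p-value is then 1.
    """
    matched = [pid for pid in profiles_minus if pid in profiles_plus]
    if not matched:
        raise InsufficientDataError("no proteins present in both conditions")
    shares_minus = {p: early_share(profiles_minus[p], early_cutoff) for p in matched}
    shares_plus = {p: early_share(profiles_plus[p], early_cutoff) for p in matched}
    differences = {p: shares_minus[p] - shares_plus[p] for p in matched}
    p_value: Optional[float] = None
    diffs = np.array([differences[p] for p in matched])
    if len(matched) < min_proteins:
        log.warning(
            "only %d matched proteins (< %d): shift test skipped",
            len(matched),
            min_proteins,
        )
    elif np.all(diffs == 0):
        p_value = 1.0
    else:
        res = stats.wilcoxon(diffs, alternative="greater", method="exact")
        p_value = float(res.pvalue)
    return ShiftResult(
        early_cutoff=early_cutoff,
        shares_minus=shares_minus,
        shares_plus=shares_plus,
        differences=differences,
        p_value=p_value,
    )


def detect_peaks_and_periodicity(
    profile: BNPAGEProfile,
    min_prominence_fraction: float = 0.1,
    exclude_well: int = 0,
) -> PeakSet:
    """Local maxima with prominence >= a fraction of the profile maximum,
    with spacing statistics and successive peak-height ratios.

    ``exclude_well`` drops peaks within the first n fractions (the well
    region, where trapped material accumulates).  No qualifying peaks is
    a valid outcome (empty PeakSet), not an error.
    """
    values = np.asarray(profile.intensities, dtype=float)
    prominence = min_prominence_fraction * values.max() if values.max() > 0 else None
    if prominence is None or prominence == 0:
        peaks = np.array([], dtype=int)
    else:
        peaks, _ = sps.find_peaks(values, prominence=prominence)
    indices = tuple(int(i) + 1 for i in peaks if int(i) + 1 > exclude_well)
    spacings = tuple(b - a for a, b in zip(indices, indices[1:]))
    if spacings:
        spacing_mean = float(np.mean(spacings))
        spacing_cv = (
            float(np.std(spacings, ddof=1) / spacing_mean)
            if len(spacings) > 1 and spacing_mean > 0
            else 0.0
        )
    else:
        spacing_mean = None
        spacing_cv = None
    heights = [values[i - 1] for i in indices]
    ratios = tuple(
        float(b / a) if a > 0 else float("inf") for a, b in zip(heights, heights[1:])
    )
    return PeakSet(
        protein_id=profile.protein_id,
        peak_indices=indices,
        spacings=spacings,
        spacing_mean=spacing_mean,
        spacing_cv=spacing_cv,
        peak_intensity_ratios=ratios,
    )


def comigration_matrix(profiles: Sequence[BNPAGEProfile]) -> pd.DataFrame:
    """Pairwise Pearson correlation of profiles on identical fraction grids.

    Zero-variance profiles have undefined correlations, reported as NaN
    with a warning.
    """
    if len(profiles) < 2:
        raise InsufficientDataError("need at least 2 profiles")
    lengths = {len(p.intensities) for p in profiles}
    if len(lengths) != 1:
        raise ValidationError("profiles are not on identical fraction grids")
    ids = [p.protein_id for p in profiles]
    matrix = np.array([p.intensities for p in profiles], dtype=float)
    flat = np.std(matrix, axis=1) == 0
    for pid in np.array(ids)[flat]:
        log.warning("profile %s has zero variance; correlations undefined", pid)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(matrix)
    corr[flat, :] = np.nan
    corr[:, flat] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=ids, columns=ids)
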