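"""MELD exception points for hepatocellular carcinoma candidates.

HCC candidates often have preserved liver function, so a laboratory MELD
underestimates their waitlist risk relative to access. The remedy implemented
here awards extra points by survival equivalence: for each HCC MELD band
[a, b] at or below the ceiling of 20, compare the waitlist survival of HCC
patients in that band with non-HCC patients in the offset band [a + d, b + d]
(clipped at 40) for candidate offsets d, and select the offset whose log-rank
p-value is maximal among those with p >= alpha — i.e. the upward shift that
makes the two groups statistically indistinguishable. If no offset reaches
alpha the maximal-p offset is reported flagged as non-equivalent. Above the
ceiling the presence of HCC is taken not to affect waitlist survival and no
points are added.

Comparisons use the full follow-up log-rank; Kaplan-Meier summaries at the
configured horizon (default 90 days) are attached for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidInputError
from .registry import PatientRecord, compute_meld, derive_outcome
from .survival import LogRankResult, km_fit, logrank_arrays

__all__ = [
    "BandComparison",
    "ExceptionEntry",
    "ExceptionTable",
    "KONOS_EXCEPTION_TABLE",
    "compare_bands",
    "find_exception_points",
    "apply_exception",
    "HCCExceptionModel",
    "HCCExceptionResults",
]

DEFAULT_HCC_BANDS: tuple[tuple[int, int], ...] = ((6, 13), (14, 20))
EXCEPTION_CEILING = 20


@dataclass(frozen=True)
class BandComparison:
    """Log-rank comparison of an HCC band against a non-HCC band."""

    hcc_band: tuple[int, int]
    non_hcc_band: tuple[int, int]
    logrank: LogRankResult
    horizon_days: float
    survival_hcc: float
    survival_non_hcc: float
    n_hcc: int
    n_non_hcc: int


@dataclass(frozen=True)
class ExceptionEntry:
    hcc_band: tuple[int, int]
    added_points: int
    p_value: float
    equivalent: bool  # False when no offset reached alpha (best offset reported anyway)


@dataclass(frozen=True)
class ExceptionTable:
    """Map from HCC MELD band to additional allocation points (ceiling MELD 20)."""

    entries: tuple[ExceptionEntry, ...]
    ceiling: int = EXCEPTION_CEILING

    def __post_init__(self) -> None:
        seen: list[tuple[int, int]] = []
        for e in self.entries:
            lo, hi = e.hcc_band
            if e.added_points < 0:
                raise InvalidInputError("added_points must be >= 0")
            if hi > self.ceiling or lo < 6:
                raise InvalidInputError(f"band {e.hcc_band} outside [6, {self.ceiling}]")
            for lo2, hi2 in seen:
                if lo <= hi2 and lo2 <= hi:
                    raise InvalidInputError("exception bands must be disjoint")
            seen.append((lo, hi))

    def points_for(self, meld: int) -> int:
        for e in self.entries:
            if e.hcc_band[0] <= meld <= e.hcc_band[1]:
                return e.added_points
        return 0


#: The table adopted by the Korean network: +4 points below MELD 14, +5 for 14-20.
KONOS_EXCEPTION_TABLE = ExceptionTable(
    entries=(
        ExceptionEntry(hcc_band=(6, 13), added_points=4, p_value=float("nan"), equivalent=True),
        ExceptionEntry(hcc_band=(14, 20), added_points=5, p_value=float("nan"), equivalent=True),
    )
)


def _cohort_arrays(records: Sequence[PatientRecord]):
    meld = np.array([compute_meld(r.labs).score for r in records], dtype=int)
    outcomes = [derive_outcome(r) for r in records]
    time = np.array([o.time_days for o in outcomes], dtype=float)
    event = np.array([o.event for o in outcomes], dtype=bool)
    hcc = np.array([r.hcc for r in records], dtype=bool)
    return meld, time, event, hcc


def _band_mask(meld: np.ndarray, band: tuple[int, int]) -> np.ndarray:
    return (meld >= band[0]) & (meld <= band[1])


def compare_bands(
    records: Sequence[PatientRecord],
    hcc_band: tuple[int, int],
    non_hcc_band: tuple[int, int],
    horizon_days: float = 90.0,
) -> BandComparison:
    """Two-group log-rank of HCC patients in ``hcc_band`` vs non-HCC in ``non_hcc_band``."""
    meld, time, event, hcc = _cohort_arrays(records)
    m_hcc = hcc & _band_mask(meld, hcc_band)
    m_non = (~hcc) & _band_mask(meld, non_hcc_band)
    if not m_hcc.any() or not m_non.any():
        raise DegenerateInputError(
            f"empty comparison group: HCC {hcc_band} (n={int(m_hcc.sum())}), "
            f"non-HCC {non_hcc_band} (n={int(m_non.sum())})"
        )
    sel = m_hcc | m_non
    group = m_non[sel].astype(int)  # 0 = HCC band, 1 = non-HCC band
    res = logrank_arrays(time[sel], event[sel], group, 2)
    surv_hcc = km_fit(list(zip(time[m_hcc], event[m_hcc]))).survival_at(horizon_days)
    surv_non = km_fit(list(zip(time[m_non], event[m_non]))).survival_at(horizon_days)
    return BandComparison(
        hcc_band=tuple(hcc_band),
        non_hcc_band=tuple(non_hcc_band),
        logrank=res,
        horizon_days=horizon_days,
        survival_hcc=surv_hcc,
        survival_non_hcc=surv_non,
        n_hcc=int(m_hcc.sum()),
        n_non_hcc=int(m_non.sum()),
    )


def find_exception_points(
    records: Sequence[PatientRecord],
    hcc_bands: Sequence[tuple[int, int]] = DEFAULT_HCC_BANDS,
    candidate_offsets: Sequence[int] = tuple(range(11)),
    alpha: float = 0.05,
    horizon_days: float = 90.0,
) -> ExceptionTable:
    """Derive additional points per HCC band by survival equivalence.

    For each band, evaluates every candidate offset and keeps the offset with
    the largest log-rank p among those with p >= alpha (falling back to the
    overall max-p offset, flagged non-equivalent, when none passes).
    """
    entries = []
    for band in hcc_bands:
        if band[1] > EXCEPTION_CEILING:
            raise InvalidInputError(f"HCC band {band} exceeds the MELD {EXCEPTION_CEILING} ceiling")
        evaluated: list[tuple[int, float]] = []
        for delta in candidate_offsets:
            if delta < 0:
                raise InvalidInputError("offsets must be non-negative")
            target = (min(band[0] + delta, 40), min(band[1] + delta, 40))
            try:
                comp = compare_bands(records, band, target, horizon_days)
            except DegenerateInputError:
                continue
            evaluated.append((delta, comp.logrank.p_value))
        if not evaluated:
            raise DegenerateInputError(f"no candidate offset yields data for HCC band {band}")
        passing = [(d, p) for d, p in evaluated if p >= alpha]
        pool = passing if passing else evaluated
        best_delta, best_p = max(pool, key=lambda dp: (dp[1], -dp[0]))
        entries.append(
            ExceptionEntry(
                hcc_band=tuple(band),
                added_points=best_delta,
                p_value=best_p,
                equivalent=bool(passing),
            )
        )
    return ExceptionTable(entries=tuple(entries))


def apply_exception(meld: int, hcc: bool, table: ExceptionTable = KONOS_EXCEPTION_TABLE) -> int:
    """Allocation MELD after exception points (capped at 40); non-HCC unchanged."""
    if not 6 <= meld <= 40:
        raise InvalidInputError(f"meld must be in [6, 40], got {meld}")
    if not hcc:
        return meld
    return min(meld + table.points_for(meld), 40)


# ---------------------------------------------------------------------------
# Model / results presentation
# ---------------------------------------------------------------------------

class HCCExceptionModel:
    """Survival-equivalence model for HCC exception points.

    Fits the offset search on a cohort of records; the results object carries
    the derived :class:`ExceptionTable` plus every band comparison evaluated.
    """

    def __init__(
        self,
        records: Sequence[PatientRecord],
        hcc_bands: Sequence[tuple[int, int]] = DEFAULT_HCC_BANDS,
        candidate_offsets: Sequence[int] = tuple(range(11)),
        alpha: float = 0.05,
        horizon_days: float = 90.0,
    ):
        self.records = list(records)
        self.hcc_bands = tuple(tuple(b) for b in hcc_bands)
        self.candidate_offsets = tuple(candidate_offsets)
        self.alpha = alpha
        self.horizon_days = horizon_days

    def fit(self) -> "HCCExceptionResults":
        comparisons: dict[tuple[int, int], list[BandComparison]] = {}
        for band in self.hcc_bands:
            rows = []
            for delta in self.candidate_offsets:
                target = (min(band[0] + delta, 40), min(band[1] + delta, 40))
                try:
                    rows.append(compare_bands(self.records, band, target, self.horizon_days))
                except DegenerateInputError:
                    continue
            comparisons[band] = rows
        table = find_exception_points(
            self.records, self.hcc_bands, self.candidate_offsets, self.alpha, self.horizon_days
        )
        return HCCExceptionResults(model=self, table=table, comparisons=comparisons)


@dataclass
class HCCExceptionResults:
    model: HCCExceptionModel
    table: ExceptionTable
    comparisons: dict[tuple[int, int], list[BandComparison]]

    def comparison_frame(self) -> pd.DataFrame:
        rows = []
        for band, comps in self.comparisons.items():
            for c in comps:
                rows.append(
                    {
                        "hcc_band": f"{band[0]}-{band[1]}",
                        "offset": c.non_hcc_band[0] - band[0],
                        "non_hcc_band": f"{c.non_hcc_band[0]}-{c.non_hcc_band[1]}",
                        "n_hcc": c.n_hcc,
                        "n_non_hcc": c.n_non_hcc,
                        "logrank_p": c.logrank.p_value,
                        "surv_hcc": c.survival_hcc,
                        "surv_non_hcc": c.survival_non_hcc,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "HCC MELD exception points (survival equivalence search)",
            f"alpha = {self.model.alpha}, horizon = {self.model.horizon_days:g} days, "
            f"offsets = {self.model.candidate_offsets[0]}..{self.model.candidate_offsets[-1]}",
            "",
        ]
        for e in self.table.entries:
            flag = "" if e.equivalent else "  [no offset reached alpha]"
            lines.append(
                f"HCC MELD {e.hcc_band[0]}-{e.hcc_band[1]}: +{e.added_points} points "
                f"(log-rank p = {e.p_value:.3f}){flag}"
            )
        frame = self.comparison_frame()
        if not frame.empty:
            lines.append("")
            lines.append(frame.round(4).to_string(index=False))
        return "\n".join(lines)
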