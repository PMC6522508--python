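"""Donor-organ priority ranking under two allocation systems.

``meld`` system — the staged broader-sharing scheme adopted in Korea: a
single combined regional+national tier for status 1, then MELD 38-40 shared
regionally-then-nationally per exact score, then alternating regional /
national tiers for MELD 31-37, 21-30 and <=20. Within a tier candidates are
ordered by allocation MELD (laboratory MELD plus any HCC exception points)
descending, then waiting time descending.

``ctp_status`` system — the previous CTP-based scheme: urgency status
(1 > 2A > 2B > 3) with waiting time as tie-break; status 1/2A candidates
reach donors nationally during their first ``national_window_days`` days
after registration, all others only regionally. Out-of-region candidates who
cannot receive the offer are kept at the bottom of the returned ranking
(flagged ineligible) so the output is always a permutation of the
blood-compatible input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import InvalidInputError
from .hcc_exception import ExceptionTable, KONOS_EXCEPTION_TABLE, apply_exception
from .registry import PatientRecord, classify_status, compute_meld

__all__ = [
    "DonorOffer",
    "AllocationTier",
    "RankedCandidate",
    "assign_tier",
    "rank_waitlist",
    "blood_compatible",
    "TIER_LABELS",
]

#: donor blood type -> recipient blood types that may receive the organ
_BLOOD_COMPAT = {
    "O": {"O", "A", "B", "AB"},
    "A": {"A", "AB"},
    "B": {"B", "AB"},
    "AB": {"AB"},
}

TIER_LABELS = {
    1: "Combined regional and national status 1",
    2: "Regional/national MELD 38-40 (per score, regional first)",
    3: "Regional MELD 31-37",
    4: "National MELD 31-37",
    5: "Regional MELD 21-30",
    6: "National MELD 21-30",
    7: "Regional MELD <=20",
    8: "National MELD <=20",
}


@dataclass(frozen=True)
class DonorOffer:
    """A deceased-donor liver offer."""

    donor_region: int
    blood_type: str
    offer_date: str | None = None

    def __post_init__(self) -> None:
        if self.donor_region not in (1, 2, 3):
            raise InvalidInputError(f"donor_region must be 1, 2 or 3, got {self.donor_region!r}")
        if self.blood_type not in _BLOOD_COMPAT:
            raise InvalidInputError(f"unknown blood type {self.blood_type!r}")


@dataclass(frozen=True)
class AllocationTier:
    """Ordered rank (1 = highest priority) in the staged sharing scheme."""

    rank: int
    label: str


def blood_compatible(donor_type: str, recipient_type: str) -> bool:
    return recipient_type in _BLOOD_COMPAT[donor_type]


def assign_tier(
    status: str, allocation_meld: int, candidate_region: int, donor_region: int
) -> AllocationTier:
    """Tier in the staged broader-sharing scheme.

    Status 1 shares nationally in a single top tier. MELD 38-40 forms one
    regional+national tier (sub-ordering per exact score is handled by
    :func:`rank_waitlist`). Lower bands alternate regional before national.
    """
    if candidate_region not in (1, 2, 3) or donor_region not in (1, 2, 3):
        raise InvalidInputError("regions must be 1, 2 or 3")
    if not 6 <= allocation_meld <= 40:
        raise InvalidInputError(f"allocation_meld must be in [6, 40], got {allocation_meld}")
    if status == "1":
        rank = 1
    elif allocation_meld >= 38:
        rank = 2
    else:
        regional = candidate_region == donor_region
        if allocation_meld >= 31:
            rank = 3 if regional else 4
        elif allocation_meld >= 21:
            rank = 5 if regional else 6
        else:
            rank = 7 if regional else 8
    return AllocationTier(rank=rank, label=TIER_LABELS[rank])


@dataclass(frozen=True)
class RankedCandidate:
    """One line of a ranked match run."""

    position: int
    id: str
    tier: AllocationTier | None
    status: str
    allocation_meld: int
    lab_meld: int
    waiting_days: float
    region: int
    eligible: bool


_STATUS_URGENCY = {"1": 0, "2A": 1, "2B": 2, "3": 3, "unlisted": 4}


def rank_waitlist(
    offer: DonorOffer,
    candidates: Sequence[PatientRecord],
    exception_table: ExceptionTable = KONOS_EXCEPTION_TABLE,
    system: str = "meld",
    national_window_days: float = 14.0,
) -> list[RankedCandidate]:
    """Rank blood-compatible candidates for a donor offer.

    Returns a permutation of the compatibility-filtered candidates under a
    total, input-order-independent key (final tie-break on candidate id).
    Waiting time is taken as ``follow_up_days`` (days on the list at offer).
    """
    if system not in ("meld", "ctp_status"):
        raise InvalidInputError(f"unknown system {system!r}")
    if not candidates:
        return []
    rows = []
    for rec in candidates:
        if not blood_compatible(offer.blood_type, rec.blood_type):
            continue
        status = classify_status(rec.status_criteria)
        lab_meld = compute_meld(rec.labs).score
        alloc_meld = apply_exception(lab_meld, rec.hcc, exception_table)
        waiting = rec.follow_up_days
        if system == "meld":
            tier = assign_tier(status, alloc_meld, rec.region, offer.donor_region)
            regional = rec.region == offer.donor_region
            # tier 2 shares per exact score, regional leg before national
            sub = (-alloc_meld, 0 if regional else 1) if tier.rank == 2 else (0, 0)
            key = (tier.rank, *sub, -alloc_meld, -waiting, rec.id)
            eligible = True
        else:
            regional = rec.region == offer.donor_region
            national_reach = status in ("1", "2A") and waiting <= national_window_days
            eligible = regional or national_reach
            tier = None
            key = (0 if eligible else 1, _STATUS_URGENCY[status], -waiting, rec.id)
        rows.append((key, rec, status, tier, alloc_meld, lab_meld, waiting, eligible))
    rows.sort(key=lambda r: r[0])
    return [
        RankedCandidate(
            position=i + 1,
            id=rec.id,
            tier=tier,
            status=status,
            allocation_meld=alloc_meld,
            lab_meld=lab_meld,
            waiting_days=waiting,
            region=rec.region,
            eligible=eligible,
        )
        for i, (key, rec, status, tier, alloc_meld, lab_meld, waiting, eligible) in enumerate(rows)
    ]
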