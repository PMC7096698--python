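"""Semi-quantitative small-vessel-disease (SVD) rating schemas and burden score.

Four marker classes are encoded:

* **WMH** — Fazekas ratings, periventricular (PVH) and deep (DWMH), each 0–3
  (0 absent; 1 caps/pencil-thin lining or punctate foci; 2 smooth halo or
  beginning confluence; 3 irregular signal extending into deep WM or large
  confluent areas).
* **EPVS** — enlarged perivascular spaces, 5-point grades in the centrum
  semiovale (CSO) and basal ganglia (BG): 0 none, 1 = 1–10, 2 = 11–20,
  3 = 21–40, 4 = >40; dichotomous presence in the midbrain.
* **Microbleeds** — definite-microbleed counts, classified deep vs lobar
  ("possible" microbleeds are retained for audit only, never analysed).
* **Lacunes** — counts deep vs lobar, with candidates admitted only at
  diameters of 3–15 mm inclusive (below 3 mm risks confusion with EPVS,
  above 15 mm with non-SVD lesions).

The total SVD burden score awards one point per marker class present:
WMH (PVH grade 3 and/or DWMH grade >= 2), EPVS (BG grade >= 2, i.e. more
than 10), >= 1 lacune, >= 1 microbleed.  Missing modalities (e.g. no SWI
scan, hence no microbleed data) are encoded as ``None`` and propagate to a
missing burden score rather than counting as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .exceptions import RatingValidationError

LACUNE_MIN_DIAMETER_MM = 3.0
LACUNE_MAX_DIAMETER_MM = 15.0

#: Upper count edge (inclusive) of each EPVS grade above 0.
_EPVS_BIN_UPPER = (0, 10, 20, 40)


@dataclass
class SvdRatings:
    """One subject's semi-quantitative SVD ratings.

    ``None`` marks a missing modality, not an absent finding.
    """

    fazekas_pvh: int | None = None
    fazekas_dwmh: int | None = None
    epvs_cso: int | None = None
    epvs_bg: int | None = None
    epvs_midbrain: int | None = None
    microbleeds_lobar: int | None = None
    microbleeds_deep: int | None = None
    lacunes_lobar: int | None = None
    lacunes_deep: int | None = None
    possible_microbleeds: int = field(default=0)  # audit only, never analysed

    @property
    def microbleeds_total(self) -> int | None:
        if self.microbleeds_lobar is None or self.microbleeds_deep is None:
            return None
        return self.microbleeds_lobar + self.microbleeds_deep

    @property
    def lacunes_total(self) -> int | None:
        if self.lacunes_lobar is None or self.lacunes_deep is None:
            return None
        return self.lacunes_lobar + self.lacunes_deep


#: field -> (lo, hi) inclusive allowed range; counts are unbounded above.
_ORDINAL_RANGES = {
    "fazekas_pvh": (0, 3),
    "fazekas_dwmh": (0, 3),
    "epvs_cso": (0, 4),
    "epvs_bg": (0, 4),
    "epvs_midbrain": (0, 1),
}
_COUNT_FIELDS = (
    "microbleeds_lobar",
    "microbleeds_deep",
    "lacunes_lobar",
    "lacunes_deep",
    "possible_microbleeds",
)


def validate_ratings(record: SvdRatings) -> SvdRatings:
    """Validate every populated field against its scale; return the record.

    Raises :class:`RatingValidationError` naming the offending field and its
    allowed range.  ``None`` (missing modality) always passes.
    """
    for name, (lo, hi) in _ORDINAL_RANGES.items():
        value = getattr(record, name)
        if value is None:
            continue
        if value != int(value) or not lo <= value <= hi:
            raise RatingValidationError(
                f"{name}={value!r} outside allowed range {lo}..{hi}"
            )
    for name in _COUNT_FIELDS:
        value = getattr(record, name)
        if value is None:
            continue
        if value != int(value) or value < 0:
            raise RatingValidationError(
                f"{name}={value!r} must be a nonnegative integer"
            )
    return record


def epvs_grade_from_count(count: int) -> int:
    """Map a raw EPVS count to its 5-point grade (0 none ... 4 over 40)."""
    if count != int(count) or count < 0:
        raise RatingValidationError(f"EPVS count {count!r} must be a nonnegative integer")
    for grade, upper in enumerate(_EPVS_BIN_UPPER):
        if count <= upper:
            return grade
    return 4


@dataclass
class LacuneCandidate:
    """A candidate lacune: diameter in mm and deep/lobar location."""

    diameter_mm: float
    location: str  # "deep" | "lobar"

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise RatingValidationError(
                f"lacune diameter must be positive, got {self.diameter_mm}"
            )
        if self.location not in ("deep", "lobar"):
            raise RatingValidationError(
                f"lacune location must be 'deep' or 'lobar', got {self.location!r}"
            )


def filter_lacunes(candidates: Iterable[LacuneCandidate]) -> dict[str, int]:
    """Count candidates whose diameter lies in [3, 15] mm, per location.

    Bounds are inclusive; returns ``{"deep": n, "lobar": n}``.
    """
    counts = {"deep": 0, "lobar": 0}
    for cand in candidates:
        if LACUNE_MIN_DIAMETER_MM <= cand.diameter_mm <= LACUNE_MAX_DIAMETER_MM:
            counts[cand.location] += 1
    return counts


def svd_burden_score(ratings: SvdRatings) -> int | None:
    """Total SVD burden 0–4: one point per marker class present.

    Points: WMH if ``fazekas_pvh == 3`` or ``fazekas_dwmh >= 2``; EPVS if
    ``epvs_bg >= 2``; lacunes if any lacune; microbleeds if any microbleed.
    Returns ``None`` when any needed field is missing.
    """
    validate_ratings(ratings)
    mb_total = ratings.microbleeds_total
    lac_total = ratings.lacunes_total
    needed = (
        ratings.fazekas_pvh,
        ratings.fazekas_dwmh,
        ratings.epvs_bg,
        mb_total,
        lac_total,
    )
    if any(v is None for v in needed):
        return None
    score = 0
    score += int(ratings.fazekas_pvh == 3 or ratings.fazekas_dwmh >= 2)
    score += int(ratings.epvs_bg >= 2)
    score += int(lac_total >= 1)
    score += int(mb_total >= 1)
    return score


def ratings_from_row(row) -> SvdRatings:
    """Build :class:`SvdRatings` from a mapping/Series with schema columns.

    Missing keys and NaN/None values become ``None``.
    """
    def get(key):
        try:
            v = row[key]
        except (KeyError, IndexError):
            return None
        if v is None:
            return None
        try:
            if v != v:  # NaN
                return None
        except Exception:
            pass
        return int(v)

    return validate_ratings(
        SvdRatings(
            fazekas_pvh=get("fazekas_pvh"),
            fazekas_dwmh=get("fazekas_dwmh"),
            epvs_cso=get("epvs_cso"),
            epvs_bg=get("epvs_bg"),
            epvs_midbrain=get("epvs_midbrain"),
            microbleeds_lobar=get("microbleeds_lobar"),
            microbleeds_deep=get("microbleeds_deep"),
            lacunes_lobar=get("lacunes_lobar"),
            lacunes_deep=get("lacunes_deep"),
            possible_microbleeds=get("possible_microbleeds") or 0,
        )
    )
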