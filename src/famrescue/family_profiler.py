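"""Per-family domain-plDDT histograms, peak detection and bimodality flagging.

A protein family whose members split into a high-confidence mode (mean domain
plDDT >= 70) and a medium/low-confidence mode is a candidate for template
rescue: the confident members can serve as structural templates for the rest.
This module builds the 100-bin max-normalized histogram of member domain
plDDTs, finds its peaks under height and distance constraints, classifies the
peaks, and ranks candidate families by how balanced their low/high split is.

Candidate peaks come from :func:`scipy.signal.find_peaks` (local maxima above
a minimum height; plateaus resolve to their midpoint bin, left bin on
even-width plateaus).  The minimum-distance filter is applied here with a
fully deterministic greedy rule -- accept candidates in order of descending
height, ties to the lower bin index, discarding anything closer than the
minimum distance to an accepted peak -- because the reference routine leaves
the order of equal-height candidates unspecified.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .exceptions import ValidationError

__all__ = [
    "Peak",
    "PeakParams",
    "FamilyProfile",
    "build_histogram",
    "detect_peaks",
    "classify_peak",
    "is_rescuable_bimodal",
    "rank_families",
    "build_profile",
    "profiles_to_json",
    "profiles_from_json",
]

logger = logging.getLogger(__name__)

# peak classes on the plDDT scale: low < 50 <= medium < 70 <= high
LOW_MEDIUM_BOUNDARY = 50.0
CONFIDENCE_THRESHOLD = 70.0


@dataclass(frozen=True)
class Peak:
    """A retained histogram peak.

    ``bin_index`` is 1-based in [1, 100]; ``plddt_value`` is the bin center
    (bin k covers [k-1, k) on the plDDT axis, so its center is k - 0.5).
    """

    bin_index: int
    height: float
    plddt_value: float
    peak_class: str


@dataclass(frozen=True)
class PeakParams:
    """Peak-detection constraints on the max-normalized histogram."""

    min_height: float = 0.03
    min_distance: int = 19
    n_bins: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.min_height <= 1):
            raise ValidationError("min_height must be in (0, 1]")
        if self.min_distance < 1:
            raise ValidationError("min_distance must be >= 1")


@dataclass
class FamilyProfile:
    """A family's member plDDTs with the derived histogram and peaks."""

    family_id: str
    member_plddts: dict[str, float]
    histogram: np.ndarray = field(default=None)  # type: ignore[assignment]
    peaks: list[Peak] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.member_plddts)


def build_histogram(
    values: Sequence[float], n_bins: int = 100
) -> np.ndarray:
    """Bin values on [0, 100] into ``n_bins`` equal bins, normalized so max == 1.

    Bin k (1-based) covers [(k-1)*100/n, k*100/n), with the last bin closed on
    the right so 100.0 is counted.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot build a histogram from no values")
    if values.min() < 0 or values.max() > 100:
        raise ValidationError("plDDT values must lie in [0, 100]")
    counts, _ = np.histogram(values, bins=n_bins, range=(0.0, 100.0))
    return counts / counts.max()


def detect_peaks(
    histogram: Sequence[float], params: PeakParams = PeakParams()
) -> list[Peak]:
    """Find local maxima meeting the height and minimum-distance constraints.

    Candidates below ``min_height`` are dropped; remaining candidates are
    accepted greedily in order of descending height, discarding any candidate
    closer than ``min_distance`` bins to an already-accepted one.  Result is
    sorted by bin index.
    """
    hist = np.asarray(histogram, dtype=float)
    n = len(hist)
    bin_width = 100.0 / n
    candidates, _ = find_peaks(hist, height=params.min_height)
    order = sorted(candidates, key=lambda i: (-hist[i], i))
    accepted: list[int] = []
    for c in order:
        if all(abs(int(c) - a) >= params.min_distance for a in accepted):
            accepted.append(int(c))
    peaks = [
        Peak(
            bin_index=int(i) + 1,
            height=float(hist[i]),
            plddt_value=(int(i) + 0.5) * bin_width,
            peak_class=classify_peak((int(i) + 0.5) * bin_width),
        )
        for i in accepted
    ]
    return sorted(peaks, key=lambda p: p.bin_index)


def classify_peak(plddt_value: float) -> str:
    """Classify a plDDT value: low (<50), medium (50 to <70), or high (>=70)."""
    if not (0 <= plddt_value <= 100):
        raise ValidationError(f"plDDT value {plddt_value} outside [0, 100]")
    if plddt_value < LOW_MEDIUM_BOUNDARY:
        return "low"
    if plddt_value < CONFIDENCE_THRESHOLD:
        return "medium"
    return "high"


def is_rescuable_bimodal(
    profile: FamilyProfile, min_members: int = 100
) -> bool:
    """A family is rescuable when it is big enough and bimodal across 70.

    Requires at least ``min_members`` members, one peak in the high class and
    one in the low or medium class.
    """
    if profile.n_members < min_members:
        return False
    classes = {p.peak_class for p in profile.peaks}
    return "high" in classes and bool(classes & {"low", "medium"})


def balance_score(profile: FamilyProfile) -> float:
    """|n_below70 - n_at_or_above70| / n_total over member plDDTs (0 = balanced)."""
    vals = np.fromiter(profile.member_plddts.values(), dtype=float)
    n_high = int((vals >= CONFIDENCE_THRESHOLD).sum())
    n_low = vals.size - n_high
    return abs(n_low - n_high) / vals.size


def rank_families(
    profiles: Sequence[FamilyProfile], k: int
) -> list[str]:
    """Return the ``k`` family ids with the most balanced low/high split.

    Ascending by balance score; ties broken by larger member count, then
    lexicographic family id.
    """
    if k > len(profiles):
        logger.warning(
            "requested top %d families but only %d are available", k, len(profiles)
        )
    ranked = sorted(
        profiles,
        key=lambda p: (balance_score(p), -p.n_members, p.family_id),
    )
    return [p.family_id for p in ranked[:k]]


def build_profile(
    family_id: str,
    member_plddts: Mapping[str, float],
    params: PeakParams = PeakParams(),
) -> FamilyProfile:
    """Histogram the member plDDTs and detect peaks in one step."""
    profile = FamilyProfile(family_id=family_id, member_plddts=dict(member_plddts))
    profile.histogram = build_histogram(
        list(profile.member_plddts.values()), params.n_bins
    )
    profile.peaks = detect_peaks(profile.histogram, params)
    return profile


def profiles_to_json(
    profiles: Iterable[FamilyProfile], path: str | Path
) -> Path:
    payload = [
        {
            "family_id": p.family_id,
            "member_plddts": p.member_plddts,
            "histogram": [float(h) for h in p.histogram],
            "peaks": [
                {
                    "bin_index": pk.bin_index,
                    "height": pk.height,
                    "plddt_value": pk.plddt_value,
                    "peak_class": pk.peak_class,
                }
                for pk in p.peaks
            ],
        }
        for p in profiles
    ]
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def profiles_from_json(path: str | Path) -> list[FamilyProfile]:
    payload = json.loads(Path(path).read_text())
    profiles = []
    for entry in payload:
        profiles.append(
            FamilyProfile(
                family_id=entry["family_id"],
                member_plddts=dict(entry["member_plddts"]),
                histogram=np.asarray(entry["histogram"], dtype=float),
                peaks=[Peak(**pk) for pk in entry["peaks"]],
            )
        )
    return profiles
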