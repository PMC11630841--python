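"""Stratified cohort selection for remodelling.

From each chosen family, up to ``per_stratum`` proteins are drawn from each of
three confidence strata of domain plDDT: low (<70), medium (70 to <90) and
high (>=90).  Complete proteins are prioritized over fragments; within a
priority class the draw is a seeded uniform sample.  A deficit in one stratum
is not transferred to another, so a family contributes at most
``3 * per_stratum`` proteins.

Note the strata here (70/90 boundaries) intentionally differ from the peak
classes used for family selection (50/70 boundaries): the former describe the
remodelling cohort, the latter the family-level bimodality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = ["CohortEntry", "assign_stratum", "select_cohort", "STRATA"]

logger = logging.getLogger(__name__)

STRATA = ("low", "medium", "high")
_LOW_BOUNDARY = 70.0
_HIGH_BOUNDARY = 90.0


@dataclass(frozen=True)
class CohortEntry:
    """One selected protein with its stratum at selection time."""

    protein_id: str
    family_id: str
    stratum: str
    domain_plddt: float
    is_fragment: bool


def assign_stratum(domain_plddt: float) -> str:
    """Stratum of a domain plDDT: low (<70), medium (70 to <90), high (>=90)."""
    if not (0 <= domain_plddt <= 100):
        raise ValidationError(f"plDDT value {domain_plddt} outside [0, 100]")
    if domain_plddt < _LOW_BOUNDARY:
        return "low"
    if domain_plddt < _HIGH_BOUNDARY:
        return "medium"
    return "high"


def select_cohort(
    members: Sequence[tuple[str, float, bool]],
    family_id: str,
    per_stratum: int = 10,
    seed: int = 0,
) -> list[CohortEntry]:
    """Select up to ``per_stratum`` members per stratum, fragments last.

    ``members`` are (protein_id, domain_plddt, is_fragment) tuples.  Within
    each stratum, non-fragments are exhausted before any fragment is chosen;
    within a priority class the choice is a uniform draw seeded by ``seed``.
    Output order is stratum (low, medium, high), then protein id.
    """
    if per_stratum < 1:
        raise ValidationError("per_stratum must be >= 1")
    if not members:
        logger.warning("family %s: empty member list, empty cohort", family_id)
        return []
    rng = np.random.default_rng(seed)
    selected: list[CohortEntry] = []
    by_stratum: dict[str, list[tuple[str, float, bool]]] = {s: [] for s in STRATA}
    for pid, plddt, frag in members:
        by_stratum[assign_stratum(plddt)].append((pid, plddt, frag))
    for stratum in STRATA:
        pool = by_stratum[stratum]
        complete = sorted(m for m in pool if not m[2])
        fragments = sorted(m for m in pool if m[2])
        chosen: list[tuple[str, float, bool]] = []
        for priority_class in (complete, fragments):
            need = per_stratum - len(chosen)
            if need <= 0:
                break
            if len(priority_class) <= need:
                chosen.extend(priority_class)
            else:
                picks = rng.choice(len(priority_class), size=need, replace=False)
                chosen.extend(priority_class[i] for i in sorted(picks))
        for pid, plddt, frag in sorted(chosen):
            selected.append(
                CohortEntry(
                    protein_id=pid,
                    family_id=family_id,
                    stratum=stratum,
                    domain_plddt=plddt,
                    is_fragment=frag,
                )
            )
    return selected
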