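"""Template-rescue orchestration: banks, prediction modes, best pick.

The rescue strategy re-predicts each cohort protein in two template modes --
templates plus the MSA, and templates plus the single sequence (MSA disabled)
-- using within-family high-confidence models (mean plDDT >= 70) as templates.
The "best pick" is whichever template mode gives the higher mean plDDT.  A
protein is *rescued* when its baseline (no-template) mean plDDT was below the
confidence threshold 70 and the best pick reaches it.

Predictions go through a pluggable backend satisfying
:class:`PredictionBackend`; the package ships a stochastic mock backend (in
:mod:`famrescue.synthetic`) and a command-template adapter for an external
predictor (in :mod:`famrescue.backends`).  The neural network itself is out of
scope here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from . import align as _align
from .cohort import CohortEntry
from .exceptions import BackendContractError, ValidationError
from .model_io import StructureModel

__all__ = [
    "MODES",
    "CONFIDENCE_THRESHOLD",
    "PredictionRequest",
    "PredictionResult",
    "PredictionBackend",
    "TemplateBank",
    "RescueRecord",
    "RescueConfig",
    "build_template_bank",
    "best_pick",
    "run_rescue",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

MODES = ("no_template_msa", "template_msa", "template_single")
CONFIDENCE_THRESHOLD = 70.0


@dataclass(frozen=True)
class PredictionRequest:
    """One prediction job handed to a backend."""

    protein_id: str
    sequence: str
    mode: str
    templates: tuple[StructureModel, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"unknown prediction mode {self.mode!r}")
        if self.mode == "no_template_msa" and self.templates:
            raise ValidationError("no_template_msa requests must carry no templates")

    @property
    def msa_enabled(self) -> bool:
        return self.mode != "template_single"


@dataclass(frozen=True)
class PredictionResult:
    """A backend's answer: the model plus its mean and domain plDDT."""

    protein_id: str
    mode: str
    model: StructureModel
    mean_plddt: float
    domain_plddt: float

    def __post_init__(self) -> None:
        if not math.isclose(
            self.mean_plddt, float(np.mean(self.model.plddt)), abs_tol=1e-6
        ):
            raise ValidationError(
                f"{self.protein_id}: mean_plddt inconsistent with model.plddt"
            )


@runtime_checkable
class PredictionBackend(Protocol):
    """Contract for prediction engines (mock or external command)."""

    def predict(self, request: PredictionRequest) -> PredictionResult:
        ...


@dataclass
class TemplateBank:
    """The within-family models confident enough to serve as templates."""

    family_id: str
    templates: list[StructureModel]
    min_plddt: float = CONFIDENCE_THRESHOLD

    def __post_init__(self) -> None:
        for t in self.templates:
            if t.mean_plddt < self.min_plddt:
                raise ValidationError(
                    f"template {t.protein_id} has mean plDDT "
                    f"{t.mean_plddt:.2f} < {self.min_plddt}"
                )

    def __len__(self) -> int:
        return len(self.templates)


@dataclass
class RescueRecord:
    """Per-protein outcome across the three prediction modes."""

    protein_id: str
    family_id: str
    stratum: str
    baseline_plddt: float
    template_msa_plddt: float
    template_single_plddt: float
    best_pick_plddt: float
    best_pick_mode: str
    rescued: bool
    closest_template_id: str
    closest_template_identity_pct: float
    baseline_domain_plddt: float = math.nan
    template_msa_domain_plddt: float = math.nan
    template_single_domain_plddt: float = math.nan


@dataclass(frozen=True)
class RescueConfig:
    """Knobs of the rescue stage.

    ``max_templates`` caps how many highest-plDDT templates are passed per
    request (common predictor limit).  ``exclude_self_template`` drops a
    protein's own first-round model from its template set; the default keeps
    it, mirroring the positive-control behaviour where a confident protein is
    remodelled with itself as template.  ``rescue_threshold`` is the mean
    plDDT a best pick must reach (inclusive) to count as rescued.
    """

    min_template_plddt: float = CONFIDENCE_THRESHOLD
    rescue_threshold: float = CONFIDENCE_THRESHOLD
    max_templates: int = 4
    exclude_self_template: bool = False


def build_template_bank(
    results: Sequence[PredictionResult],
    family_id: str,
    min_plddt: float = CONFIDENCE_THRESHOLD,
) -> TemplateBank:
    """Keep the baseline models with mean plDDT >= ``min_plddt`` (inclusive).

    ``results`` must all come from the no-template baseline run.  The bank is
    sorted by descending mean plDDT (ties by protein id for determinism).
    """
    for r in results:
        if r.mode != "no_template_msa":
            raise ValidationError(
                f"template bank must be built from baseline runs, got {r.mode}"
            )
    qualifying = [r.model for r in results if r.mean_plddt >= min_plddt]
    qualifying.sort(key=lambda m: (-m.mean_plddt, m.protein_id))
    if not qualifying:
        logger.warning("family %s: no model reaches plDDT %.0f; empty bank",
                       family_id, min_plddt)
    return TemplateBank(family_id=family_id, templates=qualifying,
                        min_plddt=min_plddt)


def best_pick(
    template_msa_plddt: float, template_single_plddt: float
) -> tuple[str, float]:
    """Higher-plDDT template mode; ties go to the lower-variance MSA mode."""
    if template_single_plddt > template_msa_plddt:
        return "template_single", template_single_plddt
    return "template_msa", template_msa_plddt


def _select_templates(
    bank: TemplateBank, protein_id: str, config: RescueConfig
) -> tuple[StructureModel, ...]:
    pool = bank.templates
    if config.exclude_self_template:
        pool = [t for t in pool if t.protein_id != protein_id]
    return tuple(pool[: config.max_templates])


def run_rescue(
    entry: CohortEntry,
    sequence: str,
    bank: TemplateBank,
    backend: PredictionBackend,
    seed: int = 0,
    baseline: PredictionResult | None = None,
    config: RescueConfig = RescueConfig(),
) -> RescueRecord:
    """Run the three prediction modes for one protein and classify the outcome.

    A cached ``baseline`` result (from the template-bank stage) is reused when
    given, mirroring the single initial no-template run of the pipeline.  A
    backend failure in one mode leaves that field NaN; the rescued flag is
    computed only when both the baseline and the best pick are determinable.
    """
    if len(bank) == 0:
        raise ValidationError(f"family {entry.family_id}: empty template bank")

    def _predict(mode: str, templates: tuple[StructureModel, ...]) -> PredictionResult | None:
        try:
            return backend.predict(
                PredictionRequest(
                    protein_id=entry.protein_id,
                    sequence=sequence,
                    mode=mode,
                    templates=templates,
                    seed=seed,
                )
            )
        except BackendContractError:
            raise
        except Exception:
            logger.exception(
                "backend failed for %s in mode %s", entry.protein_id, mode
            )
            return None

    templates = _select_templates(bank, entry.protein_id, config)
    if not templates:
        raise ValidationError(
            f"{entry.protein_id}: no templates left after self-exclusion"
        )

    if baseline is None:
        baseline = _predict("no_template_msa", ())
    res_msa = _predict("template_msa", templates)
    res_single = _predict("template_single", templates)

    closest_id, closest_identity = _align.closest_template_identity(
        sequence, [(t.protein_id, t.sequence) for t in templates]
    )

    base = baseline.mean_plddt if baseline else math.nan
    msa = res_msa.mean_plddt if res_msa else math.nan
    single = res_single.mean_plddt if res_single else math.nan

    if not math.isnan(msa) and not math.isnan(single):
        mode, best = best_pick(msa, single)
    elif not math.isnan(msa):
        mode, best = "template_msa", msa
    elif not math.isnan(single):
        mode, best = "template_single", single
    else:
        mode, best = "", math.nan

    rescued = (
        not math.isnan(base)
        and not math.isnan(best)
        and base < CONFIDENCE_THRESHOLD
        and best >= config.rescue_threshold
    )
    return RescueRecord(
        protein_id=entry.protein_id,
        family_id=entry.family_id,
        stratum=entry.stratum,
        baseline_plddt=base,
        template_msa_plddt=msa,
        template_single_plddt=single,
        best_pick_plddt=best,
        best_pick_mode=mode,
        rescued=rescued,
        closest_template_id=closest_id,
        closest_template_identity_pct=closest_identity,
        baseline_domain_plddt=baseline.domain_plddt if baseline else math.nan,
        template_msa_domain_plddt=res_msa.domain_plddt if res_msa else math.nan,
        template_single_domain_plddt=res_single.domain_plddt if res_single else math.nan,
    )


_REPORT_COLUMNS = [
    "protein_id",
    "family_id",
    "stratum",
    "baseline_plddt",
    "template_msa_plddt",
    "template_single_plddt",
    "best_pick_plddt",
    "best_pick_mode",
    "rescued",
    "closest_template_id",
    "closest_template_identity_pct",
    "baseline_domain_plddt",
    "template_msa_domain_plddt",
    "template_single_domain_plddt",
]


def records_to_frame(records: Sequence[RescueRecord]) -> pd.DataFrame:
    """Rescue records as a report table with a stable column order."""
    df = pd.DataFrame([vars(r) for r in records], columns=_REPORT_COLUMNS)
    return df.sort_values(["family_id", "protein_id"]).reset_index(drop=True)
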