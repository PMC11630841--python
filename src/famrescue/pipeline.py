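"""End-to-end orchestration: profiles -> cohort -> bank -> rescue -> report.

This wires the stages together the way the rescue study runs them: profile
every family's domain plDDTs, keep the rescuable bimodal families (optionally
the k most balanced), select a stratified cohort per family, run the baseline
predictions once, build the template bank from the confident baselines, then
re-predict each cohort protein in both template modes and classify rescues.

The backend is pluggable; with the mock backend the whole pipeline runs in
seconds and is fully deterministic in (config, seed).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortEntry, select_cohort
from .family_profiler import (
    FamilyProfile,
    PeakParams,
    build_profile,
    is_rescuable_bimodal,
    rank_families,
)
from .model_io import DomainAnnotation, StructureModel, mean_plddt
from .rescue import (
    PredictionBackend,
    PredictionRequest,
    RescueConfig,
    RescueRecord,
    build_template_bank,
    records_to_frame,
    run_rescue,
)

__all__ = ["PipelineConfig", "run_pipeline", "profile_families", "write_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Top-level pipeline parameters."""

    peak_params: PeakParams = PeakParams()
    min_members: int = 100
    top_k_families: int | None = None
    per_stratum: int = 10
    rescue: RescueConfig = RescueConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config file; unset keys keep their defaults.

        Recognized sections: top-level ``min_members``, ``top_k_families``,
        ``per_stratum``; ``peaks`` (min_height, min_distance, n_bins);
        ``rescue`` (min_template_plddt, rescue_threshold, max_templates,
        exclude_self_template).
        """
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            peak_params=PeakParams(**raw.get("peaks", {})),
            min_members=raw.get("min_members", 100),
            top_k_families=raw.get("top_k_families"),
            per_stratum=raw.get("per_stratum", 10),
            rescue=RescueConfig(**raw.get("rescue", {})),
        )


def profile_families(
    models_by_family: Mapping[str, Sequence[StructureModel]],
    annotations: Sequence[DomainAnnotation],
    params: PeakParams = PeakParams(),
) -> list[FamilyProfile]:
    """Build a peak-annotated profile of domain mean plDDTs per family."""
    spans = {a.protein_id: a.span for a in annotations}
    profiles = []
    for family_id in sorted(models_by_family):
        member_plddts = {
            m.protein_id: mean_plddt(m, spans[m.protein_id])
            for m in models_by_family[family_id]
            if m.protein_id in spans
        }
        if member_plddts:
            profiles.append(build_profile(family_id, member_plddts, params))
    return profiles


def _entry_seed(master_seed: int, protein_id: str) -> int:
    return int(
        np.random.SeedSequence(
            (master_seed, zlib.crc32(protein_id.encode()))
        ).generate_state(1)[0]
        % (2**31)
    )


def run_pipeline(
    models_by_family: Mapping[str, Sequence[StructureModel]],
    annotations: Sequence[DomainAnnotation],
    backend: PredictionBackend,
    seed: int = 0,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[list[RescueRecord], list[FamilyProfile]]:
    """Run the full rescue study; returns rescue records and family profiles."""
    ann_by_id = {a.protein_id: a for a in annotations}
    profiles = profile_families(models_by_family, annotations, config.peak_params)
    rescuable = [
        p for p in profiles if is_rescuable_bimodal(p, config.min_members)
    ]
    if config.top_k_families is not None:
        keep = set(rank_families(rescuable, config.top_k_families))
        rescuable = [p for p in rescuable if p.family_id in keep]
    logger.info("%d / %d families are rescuable-bimodal", len(rescuable), len(profiles))

    records: list[RescueRecord] = []
    for profile in rescuable:
        family_id = profile.family_id
        members = [
            (pid, plddt, ann_by_id[pid].is_fragment)
            for pid, plddt in profile.member_plddts.items()
        ]
        cohort = select_cohort(
            members, family_id, per_stratum=config.per_stratum, seed=seed
        )
        if not cohort:
            continue
        model_by_id = {m.protein_id: m for m in models_by_family[family_id]}
        baselines = {}
        for entry in cohort:
            req = PredictionRequest(
                protein_id=entry.protein_id,
                sequence=model_by_id[entry.protein_id].sequence,
                mode="no_template_msa",
                seed=_entry_seed(seed, entry.protein_id),
            )
            baselines[entry.protein_id] = backend.predict(req)
        bank = build_template_bank(
            list(baselines.values()), family_id,
            min_plddt=config.rescue.min_template_plddt,
        )
        if len(bank) == 0:
            logger.warning("family %s skipped: empty template bank", family_id)
            continue
        for entry in cohort:
            records.append(
                run_rescue(
                    entry,
                    sequence=model_by_id[entry.protein_id].sequence,
                    bank=bank,
                    backend=backend,
                    seed=_entry_seed(seed, entry.protein_id),
                    baseline=baselines[entry.protein_id],
                    config=config.rescue,
                )
            )
    return records, profiles


def write_report(records: Sequence[RescueRecord], path: str | Path) -> Path:
    """Write the rescue records as the final CSV report (deterministic bytes)."""
    df = records_to_frame(records)
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")
    return path
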