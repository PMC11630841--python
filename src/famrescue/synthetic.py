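"""Synthetic protein families and a stochastic mock prediction backend.

Every pipeline stage is exercisable at desk scale without structure-prediction
hardware: :func:`generate_family` emits families of homologous sequences whose
member mean plDDTs follow a two-component truncated-Gaussian mixture on
[0, 100] (emulating the bimodal confidence distributions seen across real
protein families), and :class:`MockBackend` answers prediction requests with a
plDDT response model in which the improvement grows linearly with the identity
to the closest template.

The response model is a test harness, not a scientific claim.  It encodes the
qualitative behaviour of template-based re-prediction: gains increase with
template identity; below an identity floor the single-sequence mode degrades
confidence while the MSA mode merely stops improving; the single-sequence mode
is higher-variance than the MSA mode, and the MSA mode occasionally ignores
the templates altogether.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .align import closest_template_identity
from .exceptions import BackendContractError, ValidationError
from .model_io import DomainAnnotation, StructureModel
from .rescue import PredictionRequest, PredictionResult

__all__ = [
    "FamilySpec",
    "MockResponseSpec",
    "MockBackend",
    "generate_family",
    "generate_study",
]

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic family.

    ``mixture`` holds two (mean, sd, weight) components of the member mean
    domain plDDT distribution, truncated to [0, 100].  ``identity_decay`` is
    the maximum per-site mutation rate applied to the family consensus; a
    member's actual rate scales with how low its plDDT is, so low-confidence
    members are also the most diverged -- which is what makes template
    identity informative downstream.
    """

    family_id: str
    n_members: int = 150
    consensus: str | None = None
    seq_length: int = 80
    domain_span: tuple[int, int] = (11, 70)
    mixture: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (45.0, 2.0, 0.5),
        (88.0, 2.0, 0.5),
    )
    identity_decay: float = 0.8
    fragment_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        w = self.mixture[0][2] + self.mixture[1][2]
        if abs(w - 1.0) > 1e-9:
            raise ValidationError("mixture weights must sum to 1")
        for mean, sd, weight in self.mixture:
            if not (0 <= mean <= 100) or sd <= 0 or weight < 0:
                raise ValidationError("invalid mixture component")
        if not (0 <= self.identity_decay <= 1):
            raise ValidationError("identity_decay must be in [0, 1]")
        if not (0 <= self.fragment_fraction <= 1):
            raise ValidationError("fragment_fraction must be in [0, 1]")
        if self.n_members < 1:
            raise ValidationError("n_members must be >= 1")
        length = len(self.consensus) if self.consensus else self.seq_length
        start, end = self.domain_span
        if not (1 <= start <= end <= length):
            raise ValidationError("domain_span out of sequence bounds")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    a, b = (0.0 - mean) / sd, (100.0 - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _helix_trace(n: int) -> np.ndarray:
    """Idealized alpha-helix Calpha trace: 2.3 A radius, 1.5 A rise, 100 deg turn."""
    t = np.arange(n)
    angle = np.deg2rad(100.0) * t
    return np.column_stack(
        [2.3 * np.cos(angle), 2.3 * np.sin(angle), 1.5 * t]
    )


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, window: int = 7) -> np.ndarray:
    raw = rng.normal(0.0, sd, size=n + window - 1)
    kernel = np.ones(window) / window
    return np.convolve(raw, kernel, mode="valid")


def _mutate(
    rng: np.random.Generator, consensus: np.ndarray, rate: float
) -> tuple[str, float]:
    """Mutate each site with probability ``rate``; returns (sequence, % identity)."""
    mask = rng.random(consensus.size) < rate
    seq = consensus.copy()
    for i in np.flatnonzero(mask):
        choices = _AMINO_ACIDS[_AMINO_ACIDS != consensus[i]]
        seq[i] = rng.choice(choices)
    identity = 100.0 * (1.0 - mask.mean())
    return "".join(seq), identity


def generate_family(
    spec: FamilySpec,
) -> tuple[list[StructureModel], list[DomainAnnotation], pd.DataFrame]:
    """Generate one synthetic family.

    Returns the member models (with per-residue plDDT profiles and a helix-like
    Calpha trace), their domain annotations, and a bookkeeping ("truth") table
    recording each member's mixture component, target mean, realized domain
    plDDT, mutation rate and planted identity to the consensus.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.consensus is not None:
        consensus = np.array(list(spec.consensus))
    else:
        consensus = rng.choice(_AMINO_ACIDS, size=spec.seq_length)
    length = consensus.size
    start, end = spec.domain_span
    dom = slice(start - 1, end)
    weights = [spec.mixture[0][2], spec.mixture[1][2]]
    coords = _helix_trace(length)

    models: list[StructureModel] = []
    annotations: list[DomainAnnotation] = []
    truth_rows: list[dict] = []
    for i in range(spec.n_members):
        pid = f"{spec.family_id}_m{i:04d}"
        component = int(rng.choice(2, p=weights))
        mean, sd, _ = spec.mixture[component]
        target = _truncated_normal(rng, mean, sd)
        # divergence scales with lack of confidence: low-plDDT members drift
        rate = spec.identity_decay * (1.0 - target / 100.0) * rng.uniform(0.5, 1.5)
        rate = float(np.clip(rate, 0.0, 0.95))
        sequence, planted_identity = _mutate(rng, consensus, rate)
        is_fragment = bool(rng.random() < spec.fragment_fraction)

        profile = np.full(length, target)
        profile += _smooth_noise(rng, length, sd=6.0)
        # residues outside the domain are less constrained: extra noise and sag
        outside = np.ones(length, dtype=bool)
        outside[dom] = False
        profile[outside] += rng.uniform(-12.0, 0.0) + _smooth_noise(
            rng, int(outside.sum()), sd=4.0
        )
        # re-center the domain on the drawn target mean
        profile[dom] += target - profile[dom].mean()
        profile = np.clip(profile, 0.0, 100.0)

        model = StructureModel(
            protein_id=pid,
            sequence=sequence,
            plddt=profile,
            ca_coords=coords.copy(),
        )
        models.append(model)
        annotations.append(
            DomainAnnotation(
                protein_id=pid,
                family_id=spec.family_id,
                start=start,
                end=end,
                is_fragment=is_fragment,
                sequence=sequence,
            )
        )
        truth_rows.append(
            {
                "protein_id": pid,
                "family_id": spec.family_id,
                "component": component,
                "target_mean_plddt": target,
                "mean_plddt": float(profile.mean()),
                "domain_plddt": float(profile[dom].mean()),
                "mutation_rate": rate,
                "planted_identity_pct": planted_identity,
                "is_fragment": is_fragment,
            }
        )
    return models, annotations, pd.DataFrame(truth_rows)


def generate_study(
    n_families: int = 10,
    members_per_family: int = 30,
    seed: int = 0,
    **spec_overrides,
) -> tuple[
    dict[str, list[StructureModel]],
    list[DomainAnnotation],
    pd.DataFrame,
]:
    """Generate a multi-family study with per-family seeds spawned from ``seed``."""
    child_seeds = np.random.SeedSequence(seed).generate_state(n_families)
    models_by_family: dict[str, list[StructureModel]] = {}
    annotations: list[DomainAnnotation] = []
    truths: list[pd.DataFrame] = []
    for i in range(n_families):
        spec = FamilySpec(
            family_id=f"FAM{i:03d}",
            n_members=members_per_family,
            seed=int(child_seeds[i] % (2**31)),
            **spec_overrides,
        )
        models, anns, truth = generate_family(spec)
        models_by_family[spec.family_id] = models
        annotations.extend(anns)
        truths.append(truth)
    return models_by_family, annotations, pd.concat(truths, ignore_index=True)


@dataclass(frozen=True)
class MockResponseSpec:
    """Stochastic plDDT response of the mock backend.

    The expected gain in template modes is linear in the identity to the
    closest template: ``gain_at_full_identity * (identity - identity_floor) /
    (100 - identity_floor)``.  Below ``identity_floor`` (percent) the
    single-sequence response goes negative (a too-distant template actively
    misleads the prediction) while the MSA response is floored at zero.  The
    MSA response is further scaled by ``msa_scale`` (templates contribute less
    when an MSA is present) and with probability ``msa_ignore_prob`` the MSA
    run ignores the templates entirely (zero expected gain).  Mode noise is
    Gaussian with ``sd_single >= sd_msa``: single-sequence predictions are the
    more volatile.
    """

    gain_at_full_identity: float = 40.0
    identity_floor: float = 30.0
    sd_single: float = 12.0
    sd_msa: float = 6.0
    msa_scale: float = 0.4
    msa_ignore_prob: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_single < self.sd_msa:
            raise ValidationError("sd_single must be >= sd_msa")
        if not (0 <= self.identity_floor < 100):
            raise ValidationError("identity_floor must be in [0, 100)")
        if not (0 <= self.msa_ignore_prob <= 1):
            raise ValidationError("msa_ignore_prob must be in [0, 1]")


_MODE_INDEX = {"no_template_msa": 0, "template_msa": 1, "template_single": 2}


class MockBackend:
    """Prediction backend that replays generated baselines and simulates rescue.

    The backend is deterministic per (request seed, protein id, mode): repeated
    identical requests return identical results regardless of call order.
    """

    def __init__(
        self,
        models: Mapping[str, StructureModel] | Sequence[StructureModel],
        domain_spans: Mapping[str, tuple[int, int]],
        response: MockResponseSpec = MockResponseSpec(),
    ) -> None:
        if not isinstance(models, Mapping):
            models = {m.protein_id: m for m in models}
        self._models = dict(models)
        self._spans = dict(domain_spans)
        self.response = response

    def _rng(self, request: PredictionRequest) -> np.random.Generator:
        entropy = (
            self.response.seed,
            request.seed,
            zlib.crc32(request.protein_id.encode()),
            _MODE_INDEX[request.mode],
        )
        return np.random.default_rng(np.random.SeedSequence(entropy))

    def _result(
        self, request: PredictionRequest, plddt: np.ndarray
    ) -> PredictionResult:
        base = self._models[request.protein_id]
        model = StructureModel(
            protein_id=request.protein_id,
            sequence=base.sequence,
            plddt=plddt,
            ca_coords=None if base.ca_coords is None else base.ca_coords.copy(),
        )
        start, end = self._spans[request.protein_id]
        return PredictionResult(
            protein_id=request.protein_id,
            mode=request.mode,
            model=model,
            mean_plddt=float(plddt.mean()),
            domain_plddt=float(plddt[start - 1 : end].mean()),
        )

    def expected_delta(self, identity_pct: float, mode: str) -> float:
        """Noise-free expected mean-plDDT change for a template mode."""
        r = self.response
        frac = (identity_pct - r.identity_floor) / (100.0 - r.identity_floor)
        if mode == "template_single":
            return r.gain_at_full_identity * frac
        return max(r.msa_scale * r.gain_at_full_identity * frac, 0.0)

    def predict(self, request: PredictionRequest) -> PredictionResult:
        if request.protein_id not in self._models:
            raise BackendContractError(f"unknown protein {request.protein_id}")
        baseline = self._models[request.protein_id].plddt
        if request.mode == "no_template_msa":
            return self._result(request, baseline.copy())
        if not request.templates:
            raise BackendContractError(
                f"{request.mode} request for {request.protein_id} has no templates"
            )
        rng = self._rng(request)
        _, identity = closest_template_identity(
            request.sequence,
            [(t.protein_id, t.sequence) for t in request.templates],
        )
        delta = self.expected_delta(identity, request.mode)
        if request.mode == "template_msa" and rng.random() < self.response.msa_ignore_prob:
            delta = 0.0
        sd = (
            self.response.sd_single
            if request.mode == "template_single"
            else self.response.sd_msa
        )
        if sd > 0:
            delta += rng.normal(0.0, sd)
        plddt = np.clip(baseline + delta, 0.0, 100.0)
        return self._result(request, plddt)
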