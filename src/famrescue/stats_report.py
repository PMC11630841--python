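"""Summary statistics over rescue records and the final report.

The headline questions after a rescue run are paired: did the template modes
raise the mean plDDT of the low-confidence proteins over their no-template
baselines, and does the gain track the identity to the closest template?
Accordingly the module wraps the paired one-sided Wilcoxon signed-rank test
and the Pearson correlation (both via scipy.stats), and aggregates rescue
records into a :class:`SummaryStats` with per-mode delta means/SDs, rescue
counts, the Wilcoxon comparisons and the identity-vs-delta correlations.

All deltas are computed on the low-baseline subset (baseline mean plDDT < 70),
the set the rescue strategy targets; whole-protein means are the primary
metric with domain-restricted deltas carried alongside.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .exceptions import DegenerateDataError, ValidationError
from .rescue import CONFIDENCE_THRESHOLD, RescueRecord, records_to_frame

__all__ = [
    "SummaryStats",
    "paired_wilcoxon_one_sided",
    "pearson",
    "summarize",
    "summary_to_json",
    "write_figure_tables",
]

_EXACT_MAX_N = 25


def paired_wilcoxon_one_sided(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "greater",
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test of ``y`` against ``x``.

    ``alternative='greater'`` tests whether y tends to exceed x.  Zero
    differences are dropped; ties in |d| get midranks.  The exact null
    distribution is used for n <= 25 nonzero differences, otherwise the
    normal approximation with continuity correction.
    """
    if alternative not in ("greater", "less"):
        raise ValidationError("alternative must be 'greater' or 'less'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired samples must have equal length")
    d = y - x
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateDataError("all paired differences are zero")
    if d.size < 5:
        raise DegenerateDataError(
            f"only {d.size} nonzero differences; need at least 5"
        )
    method = "exact" if d.size <= _EXACT_MAX_N else "approx"
    res = _sps.wilcoxon(
        d, alternative=alternative, correction=True, method=method,
        zero_method="wilcox",
    )
    return float(res.statistic), float(res.pvalue)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in one of the samples")
    res = _sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class SummaryStats:
    """Aggregated rescue-run statistics (deltas over the low-baseline subset)."""

    n_total: int
    n_low_baseline: int
    n_rescued: int
    mean_delta: dict[str, float]
    sd_delta: dict[str, float]
    wilcoxon: dict[str, tuple[float, float]]
    pearson: dict[str, tuple[float, float]]

    @property
    def rescue_rate(self) -> float:
        if self.n_low_baseline == 0:
            return math.nan
        return self.n_rescued / self.n_low_baseline


def _safe_wilcoxon(x: np.ndarray, y: np.ndarray, alternative: str) -> tuple[float, float]:
    """Wilcoxon that reports (0.0, 1.0) -- no evidence -- on degenerate input."""
    try:
        return paired_wilcoxon_one_sided(x, y, alternative)
    except DegenerateDataError:
        return 0.0, 1.0


def summarize(records: Sequence[RescueRecord]) -> SummaryStats:
    """Aggregate rescue records into counts, per-mode deltas and tests.

    Wilcoxon comparisons (one-sided, greater): each template mode and the best
    pick against the baseline, and template_single against template_msa.
    Pearson: closest-template identity against the per-protein delta for each
    template mode.  All restricted to the low-baseline subset.
    """
    if not records:
        raise ValidationError("no records to summarize")
    df = records_to_frame(records)
    low = df[df["baseline_plddt"] < CONFIDENCE_THRESHOLD].dropna(
        subset=["template_msa_plddt", "template_single_plddt"]
    )
    n_low = len(low)
    deltas = {
        "template_msa": (low["template_msa_plddt"] - low["baseline_plddt"]).to_numpy(),
        "template_single": (low["template_single_plddt"] - low["baseline_plddt"]).to_numpy(),
        "best_pick": (low["best_pick_plddt"] - low["baseline_plddt"]).to_numpy(),
    }
    mean_delta = {k: float(v.mean()) if v.size else math.nan for k, v in deltas.items()}
    sd_delta = {k: float(v.std(ddof=1)) if v.size > 1 else math.nan for k, v in deltas.items()}

    wilcoxon: dict[str, tuple[float, float]] = {}
    pearson_map: dict[str, tuple[float, float]] = {}
    if n_low:
        base = low["baseline_plddt"].to_numpy()
        wilcoxon["template_msa_vs_baseline"] = _safe_wilcoxon(
            base, low["template_msa_plddt"].to_numpy(), "greater"
        )
        wilcoxon["template_single_vs_baseline"] = _safe_wilcoxon(
            base, low["template_single_plddt"].to_numpy(), "greater"
        )
        wilcoxon["best_pick_vs_baseline"] = _safe_wilcoxon(
            base, low["best_pick_plddt"].to_numpy(), "greater"
        )
        wilcoxon["template_single_vs_template_msa"] = _safe_wilcoxon(
            low["template_msa_plddt"].to_numpy(),
            low["template_single_plddt"].to_numpy(),
            "greater",
        )
        identity = low["closest_template_identity_pct"].to_numpy()
        for mode in ("template_msa", "template_single"):
            try:
                pearson_map[f"identity_vs_delta_{mode}"] = pearson(
                    identity, deltas[mode]
                )
            except DegenerateDataError:
                pearson_map[f"identity_vs_delta_{mode}"] = (math.nan, math.nan)

    return SummaryStats(
        n_total=len(df),
        n_low_baseline=n_low,
        n_rescued=int(df["rescued"].sum()),
        mean_delta=mean_delta,
        sd_delta=sd_delta,
        wilcoxon=wilcoxon,
        pearson=pearson_map,
    )


def summary_to_json(summary: SummaryStats, path: str | Path) -> Path:
    payload = {
        "n_total": summary.n_total,
        "n_low_baseline": summary.n_low_baseline,
        "n_rescued": summary.n_rescued,
        "rescue_rate": summary.rescue_rate,
        "mean_delta": summary.mean_delta,
        "sd_delta": summary.sd_delta,
        "wilcoxon": {
            k: {"statistic": s, "one_sided_p": p}
            for k, (s, p) in summary.wilcoxon.items()
        },
        "pearson": {
            k: {"r": r, "p": p} for k, (r, p) in summary.pearson.items()
        },
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def write_figure_tables(
    records: Sequence[RescueRecord], out_dir: str | Path
) -> dict[str, Path]:
    """Per-figure CSVs: per-mode plDDTs, baseline-vs-best scatter, identity-vs-delta."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = records_to_frame(records)
    paths: dict[str, Path] = {}

    modes = df.melt(
        id_vars=["protein_id", "family_id", "stratum"],
        value_vars=["baseline_plddt", "template_msa_plddt", "template_single_plddt",
                    "best_pick_plddt"],
        var_name="mode",
        value_name="mean_plddt",
    )
    paths["modes"] = out_dir / "fig_modes.csv"
    modes.to_csv(paths["modes"], index=False)

    scatter = df[
        ["protein_id", "family_id", "stratum", "baseline_plddt",
         "best_pick_plddt", "best_pick_mode", "rescued"]
    ]
    paths["scatter"] = out_dir / "fig_scatter.csv"
    scatter.to_csv(paths["scatter"], index=False)

    low = df[df["baseline_plddt"] < CONFIDENCE_THRESHOLD].copy()
    low["delta_template_msa"] = low["template_msa_plddt"] - low["baseline_plddt"]
    low["delta_template_single"] = low["template_single_plddt"] - low["baseline_plddt"]
    identity = low[
        ["protein_id", "family_id", "closest_template_id",
         "closest_template_identity_pct", "delta_template_msa",
         "delta_template_single"]
    ]
    paths["identity"] = out_dir / "fig_identity.csv"
    identity.to_csv(paths["identity"], index=False)
    return paths
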