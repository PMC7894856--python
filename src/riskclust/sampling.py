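"""Risk-stratified disjoint subsampling.

Draws ``n_sets`` pairwise-disjoint subsamples of equal size from the
high-risk population, stratifying the risk percentile in fixed-width
increments so each sample's risk distribution mirrors the population's.
One set is the validation set (final clustering); the rest are training
sets (hyperparameter tuning).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AllocationError, ConfigurationError

HIGH_RISK_THRESHOLD = 75


@dataclass(frozen=True)
class SamplePlan:
    n_sets: int = 11
    set_size: int = 10_000
    stratum_width: int = 5
    high_risk_threshold: int = HIGH_RISK_THRESHOLD
    validation_index: int = 0  # which drawn set is the validation set
    seed: int = 0

    def __post_init__(self):
        if self.n_sets < 1 or self.set_size < 1:
            raise ConfigurationError("n_sets and set_size must be positive")
        if self.stratum_width < 1:
            raise ConfigurationError("stratum_width must be positive")
        if not 0 <= self.validation_index < self.n_sets:
            raise ConfigurationError("validation_index out of range")

    def strata_edges(self) -> list[tuple[int, int]]:
        """Half-open strata [lo, lo+width), with the top percentile folded
        into the last stratum."""
        edges = []
        lo = self.high_risk_threshold
        while lo < 100:
            hi = min(lo + self.stratum_width, 100)
            edges.append((lo, hi))
            lo = hi
        return edges


@dataclass
class SampleSet:
    role: str  # "train" | "validation"
    patient_ids: list[str]
    stratum_counts: dict[str, int] = field(default_factory=dict)


def largest_remainder_allocation(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing exactly to ``total`` with minimal
    distortion of the target proportions (largest-remainder rule; ties go
    to the earlier stratum)."""
    quotas = proportions * total
    base = np.floor(quotas).astype(int)
    remainder = total - base.sum()
    frac = quotas - base
    order = np.lexsort((np.arange(len(frac)), -frac))
    alloc = base.copy()
    alloc[order[:remainder]] += 1
    return alloc


def stratified_sample(
    population: pd.DataFrame, plan: SamplePlan
) -> list[SampleSet]:
    """Draw the plan's disjoint sets from ``population`` (columns:
    patient_id, risk_percentile), jointly without replacement.

    Per set, each stratum receives round(set_size x population stratum
    proportion) patients via the largest-remainder rule.
    """
    required = {"patient_id", "risk_percentile"}
    if not required <= set(population.columns):
        raise ConfigurationError(f"population must have columns {sorted(required)}")
    pct = population["risk_percentile"].to_numpy()
    if (pct < plan.high_risk_threshold).any():
        raise ConfigurationError(
            "population contains percentiles below the high-risk threshold"
        )
    n_pop = len(population)
    if plan.n_sets * plan.set_size > n_pop:
        raise ConfigurationError(
            f"population of {n_pop} cannot supply {plan.n_sets} x {plan.set_size}"
        )
    edges = plan.strata_edges()
    stratum_of = np.minimum(
        (pct - plan.high_risk_threshold) // plan.stratum_width, len(edges) - 1
    ).astype(int)
    counts = np.bincount(stratum_of, minlength=len(edges))
    proportions = counts / n_pop
    alloc = largest_remainder_allocation(proportions, plan.set_size)
    for s, (lo, hi) in enumerate(edges):
        if alloc[s] * plan.n_sets > counts[s]:
            raise AllocationError(
                f"stratum [{lo},{hi}) holds {counts[s]} patients but "
                f"{alloc[s]} x {plan.n_sets} are required"
            )
    rng = np.random.default_rng(plan.seed)
    ids = population["patient_id"].to_numpy()
    sets: list[list[str]] = [[] for _ in range(plan.n_sets)]
    stratum_counts: list[dict[str, int]] = [dict() for _ in range(plan.n_sets)]
    for s, (lo, hi) in enumerate(edges):
        members = ids[stratum_of == s]
        shuffled = members[rng.permutation(len(members))]
        for k in range(plan.n_sets):
            chunk = shuffled[k * alloc[s] : (k + 1) * alloc[s]]
            sets[k].extend(chunk.tolist())
            stratum_counts[k][f"[{lo},{hi})"] = int(alloc[s])
    return [
        SampleSet(
            role="validation" if k == plan.validation_index else "train",
            patient_ids=sets[k],
            stratum_counts=stratum_counts[k],
        )
        for k in range(plan.n_sets)
    ]


def write_samples(sets: list[SampleSet], plan: SamplePlan, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"plan": plan.__dict__, "sets": []}
    for k, s in enumerate(sets):
        path = outdir / f"set_{k:02d}.tsv"
        pd.Series(s.patient_ids, name="patient_id").to_csv(path, sep="\t", index=False)
        manifest["sets"].append(
            {"index": k, "role": s.role, "file": path.name,
             "stratum_counts": s.stratum_counts}
        )
    out = outdir / "sample_manifest.json"
    out.write_text(json.dumps(manifest, indent=1))
    return out
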