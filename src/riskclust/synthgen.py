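"""Synthetic high-risk cohort generator with planted subgroup structure.

Emulates the feature table of a high-risk (risk percentile >= 75) primary
care cohort: ~119 mixed-type variables over seven domains, repeated
lab/vital measurements, pharmacy fill histories, missing data, and two-year
outcomes. A :class:`PlantedStructure` plants known subgroups (each defined
by a signature of shifted features and an outcome model) on top of a common
baseline, plus a background fraction of patients who receive only small
idiosyncratic perturbations and therefore resist clustering. Ground truth
is carried alongside the data so every downstream stage (feature
engineering, embedding, clustering, profiling, reporting) can be validated
without access to any restricted real-world source.

Baseline marginals are deliberately simple: binary flags are Bernoulli(p)
with p drawn once per feature from [0.02, 0.35] (diagnosis/insurance-style
flags in real high-risk cohorts are mostly uncommon), continuous features
are standard normal before signature shifts, counts are Poisson. Effect
sizes are expressed in standardized units for continuous/count features
and as prevalence shifts for binary ones; members of a subgroup are more
homogeneous on their signature's continuous features than the cohort at
large (``PlantedStructure.signature_sd``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import FeatureDef, default_catalog, CATEGORY_BY_DOMAIN
from .errors import ConfigurationError

#: Reserved true_label value for unplanted (background) patients.
BACKGROUND_LABEL = -1

#: Day-index window covered by one calendar year of feature data.
DEFAULT_WINDOW = (0, 364)

#: Risk-percentile threshold defining the high-risk cohort.
HIGH_RISK_THRESHOLD = 75

OUTCOME_COLUMNS = (
    "died_2y",
    "any_hospitalization_2y",
    "inpatient_days_2y",
    "any_ed_2y",
    "ed_visits_2y",
)

META_COLUMNS = ("risk_percentile", "true_label") + OUTCOME_COLUMNS

#: medication class -> prescription flag column used to decide who fills.
CLASS_FLAGS = {
    "antihypertensive": "antihypertensive_use",
    "statin": "statin_use",
    "glucose_lowering": "glucose_lowering_use",
}

DEFAULT_CLASSES = tuple(CLASS_FLAGS)


@dataclass(frozen=True)
class Signature:
    """One shifted feature in a subgroup's signature.

    ``effect`` is a standardized mean shift for continuous/count features
    and a prevalence shift (added to the baseline Bernoulli p, then clipped
    to [0.01, 0.99]) for binary features.
    """

    feature: str
    domain: str
    effect: float


@dataclass(frozen=True)
class OutcomeModel:
    mortality_2y: float
    mean_inpatient_days: float
    mean_ed_visits: float


@dataclass(frozen=True)
class SubgroupSpec:
    name: str
    size: int
    signature: tuple[Signature, ...]
    outcomes: OutcomeModel
    adherence: float | None = None  # target PDC; None -> baseline behaviour

    @property
    def category(self) -> str:
        """Majority domain of the signature, collapsed onto the
        comorbidity / sociodemographic / psychobehavioral taxonomy."""
        cats = [CATEGORY_BY_DOMAIN[s.domain] for s in self.signature]
        uniq, counts = np.unique(cats, return_counts=True)
        return str(uniq[np.argmax(counts)])


@dataclass(frozen=True)
class PlantedStructure:
    subgroups: tuple[SubgroupSpec, ...]
    background_fraction: float
    seed: int
    background_outcomes: OutcomeModel = OutcomeModel(0.10, 2.5, 1.3)
    #: residual SD of a continuous signature feature within its subgroup,
    #: relative to the baseline SD of 1. Members of a phenotype are more
    #: homogeneous on its defining variables than the cohort at large.
    signature_sd: float = 0.6

    def __post_init__(self):
        if not 0 <= self.background_fraction < 1:
            raise ConfigurationError("background_fraction must be in [0, 1)")
        if any(g.size <= 0 for g in self.subgroups):
            raise ConfigurationError("subgroup sizes must be positive")

    @property
    def n_subgroups(self) -> int:
        return len(self.subgroups)

    @property
    def subgroup_sizes(self) -> list[int]:
        return [g.size for g in self.subgroups]

    @property
    def signature_features(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.subgroups:
            for s in g.signature:
                seen.setdefault(s.feature, None)
        return list(seen)


@dataclass
class CohortTable:
    """Feature table plus ground truth.

    ``data`` is indexed by patient_id and holds the drawn feature columns
    (in dictionary order) followed by risk_percentile, true_label and the
    two-year outcome columns. ``pre_mask`` retains pre-masking feature
    values after missingness injection, for imputation oracles.
    """

    data: pd.DataFrame
    dictionary: list[FeatureDef]
    structure: PlantedStructure
    pre_mask: pd.DataFrame | None = None

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.dictionary if not f.derived]

    @property
    def n(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class FillHistory:
    """Pharmacy fill history of one patient for one medication class."""

    patient_id: str
    medication_class: str
    fills: tuple[tuple[int, int], ...]  # (start day, days supplied)
    window: tuple[int, int] = DEFAULT_WINDOW

    def __post_init__(self):
        lo, hi = self.window
        if hi < lo:
            raise ConfigurationError("empty observation window")
        for start, supply in self.fills:
            if supply < 1:
                raise ConfigurationError("days supplied must be >= 1")
            if start + supply <= lo or start > hi:
                raise ConfigurationError("fill outside observation window")


@dataclass(frozen=True)
class RepeatedMeasureSeries:
    patient_id: str
    variable: str
    observations: tuple[tuple[int, float], ...]  # (day, value)

    def __post_init__(self):
        if not self.observations:
            raise ConfigurationError("series must contain >= 1 observation")


# ---------------------------------------------------------------------------
# canonical planted structure


def _sig(feature: str, effect: float, by_name=None) -> Signature:
    from .catalog import catalog_by_name

    by_name = by_name or catalog_by_name()
    return Signature(feature, by_name[feature].domain, effect)


def demo_structure(
    n_total: int = 3000,
    n_subgroups: int = 12,
    background_fraction: float = 0.25,
    seed: int = 0,
) -> PlantedStructure:
    """Canonical 12-subgroup structure echoing the taxonomy of published
    high-risk-cohort phenotypes: mostly comorbidity-defined subgroups plus
    subgroups defined purely by sociodemographic or psychobehavioral
    signatures, with outcome models spanning low- to very-high-mortality
    phenotypes.
    """
    from .catalog import catalog_by_name

    bn = catalog_by_name()

    def S(feature, effect):
        return _sig(feature, effect, bn)

    # Distinct clinical phenotypes touch many of the 119 variables at once
    # (a defining flag plus its downstream labs, pharmacy and utilization
    # footprint), so each signature spans ~10-18 features with strong,
    # near-deterministic shifts on the defining flags.
    templates = [
        (
            "insulin_dependent_diabetes",
            600,
            (
                S("diabetes_complicated", 0.85),
                S("diabetes_uncomplicated", 0.60),
                S("insulin_use", 0.90),
                S("glucose_lowering_use", 0.80),
                S("hemoglobin_a1c", 4.0),
                S("glucose", 3.5),
                S("bmi", 2.0),
                S("egfr", -2.0),
                S("n_primary_care_visits", 2.5),
                S("antihypertensive_use", 0.50),
                S("hdl_cholesterol", -1.5),
                S("obesity", 0.50),
                S("peripheral_vascular_disease", 0.50),
                S("hypertension_uncomplicated", 0.50),
                S("triglycerides", 2.0),
                S("statin_use", 0.50),
                S("n_active_medications", 2.0),
            ),
            OutcomeModel(0.12, 4.0, 1.5),
            None,
        ),
        (
            "chronic_renal_disease",
            350,
            (
                S("renal_failure", 0.90),
                S("creatinine", 4.0),
                S("egfr", -4.0),
                S("bun", 3.5),
                S("potassium", 2.5),
                S("hemoglobin", -2.5),
                S("fluid_electrolyte_disorder", 0.70),
                S("hypertension_complicated", 0.70),
                S("n_specialty_visits", 2.5),
                S("albumin", -1.5),
                S("deficiency_anemia", 0.60),
                S("bicarbonate", -2.0),
                S("n_active_medications", 2.0),
            ),
            OutcomeModel(0.20, 8.0, 2.0),
            None,
        ),
        (
            "polysubstance_opioid",
            280,
            (
                S("opioid_use_disorder", 0.90),
                S("drug_abuse", 0.85),
                S("alcohol_abuse", 0.60),
                S("suicide_attempt_history", 0.45),
                S("n_psychiatry_visits", 3.0),
                S("n_substance_use_visits", 3.5),
                S("n_detox_admissions", 2.0),
                S("smoking_current", 0.60),
                S("sedative_use_disorder", 0.45),
                S("depression", 0.40),
            ),
            OutcomeModel(0.05, 5.0, 3.5),
            0.45,
        ),
        (
            "chronic_liver_disease",
            220,
            (
                S("liver_disease", 0.90),
                S("alt", 3.5),
                S("ast", 3.5),
                S("total_bilirubin", 3.5),
                S("albumin", -3.0),
                S("platelet_count", -3.0),
                S("coagulopathy", 0.70),
                S("fluid_electrolyte_disorder", 0.60),
                S("alkaline_phosphatase", 2.5),
                S("triglycerides", 1.5),
                S("alcohol_abuse", 0.50),
                S("wbc_count", 1.5),
            ),
            OutcomeModel(0.22, 9.0, 2.2),
            None,
        ),
        (
            "medicaid_low_income",
            180,
            (
                S("medicaid", 0.90),
                S("low_income_pension", 0.85),
                S("copay_exempt", 0.80),
                S("income_proxy", -3.5),
                S("homeless_history", 0.70),
                S("married", -0.45),
                S("lives_alone", 0.50),
                S("distance_to_care_miles", -3.0),
                S("rural_residence", -0.40),
                S("va_priority_high", 0.60),
                S("medicare", -0.45),
                S("age", -2.5),
                S("service_connected_50plus", -0.40),
                S("race_black", 0.35),
            ),
            OutcomeModel(0.08, 3.0, 2.0),
            0.60,
        ),
        (
            "chf_cardiac",
            150,
            (
                S("chf", 0.90),
                S("cardiac_arrhythmia", 0.80),
                S("valvular_disease", 0.60),
                S("anticoagulant_use", 0.80),
                S("n_inpatient_days_prior", 3.5),
                S("systolic_bp", -2.5),
                S("any_inpatient_prior", 0.60),
                S("peripheral_vascular_disease", 0.60),
                S("pulse", 2.0),
                S("n_general_medicine_admits", 3.0),
                S("weight_change", 2.0),
                S("bun", 1.5),
                S("n_ed_visits_prior", 2.0),
                S("hypertension_complicated", 0.50),
            ),
            OutcomeModel(0.25, 10.0, 2.5),
            None,
        ),
        (
            "psychoses_no_substance",
            130,
            (
                S("psychoses", 0.90),
                S("bipolar_disorder", 0.70),
                S("n_psychiatry_visits", 4.0),
                S("n_mental_health_visits", 3.0),
                S("antipsychotic_use", 0.80),
                S("n_no_show_appointments", 2.0),
                S("smoking_current", 0.50),
                S("anxiety_disorder", 0.60),
                S("depression", 0.65),
                S("suicide_attempt_history", 0.50),
                S("ptsd", 0.45),
            ),
            OutcomeModel(0.04, 4.0, 2.5),
            0.55,
        ),
        (
            "female_predominant",
            110,
            (
                S("female", 0.92),
                S("age", -3.5),
                S("years_enrolled", -3.0),
                S("married", 0.55),
                S("medicare", -0.50),
                S("va_priority_high", -0.45),
                S("service_connected_50plus", 0.55),
                S("rural_residence", -0.35),
                S("distance_to_care_miles", -2.0),
                S("race_other", 0.35),
                S("lives_alone", -0.25),
            ),
            OutcomeModel(0.01, 1.5, 1.2),
            None,
        ),
        (
            "amphetamine_predominant",
            90,
            (
                S("amphetamine_use", 0.92),
                S("cocaine_use", 0.70),
                S("drug_abuse", 0.80),
                S("ptsd", 0.55),
                S("suicide_attempt_history", 0.40),
                S("n_substance_use_visits", 2.5),
                S("n_detox_admissions", 3.0),
                S("smoking_current", 0.65),
            ),
            OutcomeModel(0.06, 8.0, 4.3),
            0.35,
        ),
        (
            "copd_pulmonary",
            70,
            (
                S("chronic_pulmonary_disease", 0.90),
                S("respiratory_rate", 3.0),
                S("hemoglobin", 1.5),
                S("any_inpatient_prior", 0.55),
                S("smoking_current", 0.65),
                S("wbc_count", 1.5),
                S("n_ed_visits_prior", 2.5),
                S("bicarbonate", 2.0),
                S("pulse", 1.5),
                S("sedative_rx", 0.40),
                S("n_general_medicine_admits", 2.0),
            ),
            OutcomeModel(0.18, 7.0, 2.5),
            None,
        ),
        (
            "metastatic_cancer",
            40,
            (
                S("metastatic_cancer", 0.92),
                S("solid_tumor_without_metastasis", 0.60),
                S("weight_loss", 0.75),
                S("albumin", -2.5),
                S("n_specialty_visits", 3.5),
                S("hemoglobin", -2.5),
                S("wbc_count", 1.5),
                S("deficiency_anemia", 0.60),
                S("pain_score", 2.5),
                S("any_inpatient_prior", 0.60),
                S("n_active_medications", 1.5),
            ),
            OutcomeModel(0.40, 12.0, 2.0),
            None,
        ),
        (
            "home_based_care",
            30,
            (
                S("n_home_based_care_visits", 4.5),
                S("n_telephone_encounters", 3.5),
                S("paralysis", 0.70),
                S("age", 2.5),
                S("any_nursing_home", 0.75),
                S("other_neurological_disorder", 0.70),
                S("n_primary_care_visits", 2.0),
                S("days_since_last_visit", -1.5),
                S("weight_change", -2.0),
                S("pain_score", 1.5),
            ),
            OutcomeModel(0.45, 6.0, 1.5),
            None,
        ),
    ]
    if not 1 <= n_subgroups <= len(templates):
        raise ConfigurationError(f"n_subgroups must be in 1..{len(templates)}")
    templates = templates[:n_subgroups]
    base_sizes = np.array([t[1] for t in templates], dtype=float)
    planted_total = n_total - int(round(background_fraction * n_total))
    sizes = np.floor(base_sizes / base_sizes.sum() * planted_total).astype(int)
    sizes = np.maximum(sizes, 10)
    # largest-remainder style fix-up so sizes sum exactly to planted_total
    sizes[0] += planted_total - sizes.sum()
    subgroups = tuple(
        SubgroupSpec(name, int(sz), sig, out, adh)
        for (name, _, sig, out, adh), sz in zip(templates, sizes)
    )
    return PlantedStructure(subgroups, background_fraction, seed)


# ---------------------------------------------------------------------------
# cohort generation


def _select_catalog(structure: PlantedStructure, n_features: int | None) -> list[FeatureDef]:
    cat = default_catalog()
    by_name = {f.name: f for f in cat}
    for feat in structure.signature_features:
        if feat not in by_name:
            raise ConfigurationError(f"signature feature {feat!r} not in the data dictionary")
        if by_name[feat].derived:
            raise ConfigurationError(
                f"signature feature {feat!r} is derived; plant adherence effects "
                "via SubgroupSpec.adherence instead"
            )
    if n_features is None or n_features >= len(cat):
        return cat
    required = set(structure.signature_features)
    if n_features < len(required) + 10:
        raise ConfigurationError(
            "n_features must cover all signature features plus >= 10 nuisance features"
        )
    keep: list[FeatureDef] = [f for f in cat if f.name in required or f.derived]
    for f in cat:
        if len(keep) >= n_features:
            break
        if f.name not in required and not f.derived:
            keep.append(f)
    order = {f.name: i for i, f in enumerate(cat)}
    keep.sort(key=lambda f: order[f.name])
    return keep


def generate_cohort(
    structure: PlantedStructure,
    n_total: int,
    n_features: int | None = None,
    seed: int | None = None,
) -> CohortTable:
    """Draw a cohort of ``n_total`` patients with the planted structure.

    Subgroup members have their signature features shifted by the stated
    effect sizes relative to a common baseline; background patients receive
    small per-patient perturbations (|effect| <= 0.5 on a handful of
    signature features) so that some genuinely resist clustering. Every row
    records its true label and outcomes drawn from the subgroup's outcome
    model. Deterministic given (structure, seed).
    """
    if seed is None:
        seed = structure.seed
    sizes = structure.subgroup_sizes
    if n_total < sum(sizes):
        raise ConfigurationError(
            f"n_total={n_total} smaller than the planted sizes (sum={sum(sizes)})"
        )
    catalog = _select_catalog(structure, n_features)
    drawn = [f for f in catalog if not f.derived]
    rng = np.random.default_rng(seed)

    n_background = n_total - sum(sizes)
    labels = np.concatenate(
        [np.full(sz, k) for k, sz in enumerate(sizes)]
        + [np.full(n_background, BACKGROUND_LABEL)]
    ).astype(int)
    labels = labels[rng.permutation(n_total)]
    patient_ids = [f"P{i:06d}" for i in range(1, n_total + 1)]

    # per-cell effect matrices (standardized shift / prevalence shift);
    # planted subgroup effects are kept apart from the background's
    # idiosyncratic perturbations so member coherence applies only to
    # true members
    sub_effects: dict[str, np.ndarray] = {}
    bg_effects: dict[str, np.ndarray] = {}

    def eff(store: dict[str, np.ndarray], feature: str) -> np.ndarray:
        if feature not in store:
            store[feature] = np.zeros(n_total)
        return store[feature]

    for k, g in enumerate(structure.subgroups):
        members = labels == k
        for s in g.signature:
            eff(sub_effects, s.feature)[members] += s.effect

    # background patients get small idiosyncratic perturbations on a random
    # handful of signature features, so some genuinely resist clustering
    sig_features = structure.signature_features
    bg_rows = np.flatnonzero(labels == BACKGROUND_LABEL)
    if sig_features:
        hi = min(6, len(sig_features))
        for i in bg_rows:
            k = int(rng.integers(2, hi + 1))
            chosen = rng.choice(len(sig_features), size=k, replace=False)
            for j in chosen:
                eff(bg_effects, sig_features[j])[i] += rng.uniform(-0.5, 0.5)

    # baseline parameters drawn once per feature, in dictionary order
    columns: dict[str, np.ndarray] = {}
    latent: dict[str, np.ndarray] = {}
    baseline_p: dict[str, float] = {}
    baseline_lam: dict[str, float] = {}
    for f in drawn:
        if f.kind == "binary":
            # flag prevalences emulate a real high-risk cohort's baseline
            # table: diagnosis/insurance-style flags are mostly uncommon
            baseline_p[f.name] = float(rng.uniform(0.02, 0.35))
        elif f.kind == "count":
            baseline_lam[f.name] = float(rng.uniform(0.5, 5.0))

    from .catalog import CORRELATED_PAIRS

    corr_dep = {dep: (parent, r) for dep, parent, r in CORRELATED_PAIRS}

    for f in drawn:
        if f.kind == "continuous":
            latent[f.name] = rng.standard_normal(n_total)
    zero = np.zeros(n_total)
    for f in drawn:
        if f.kind != "continuous":
            continue
        z = latent[f.name]
        if f.name in corr_dep:
            parent, r = corr_dep[f.name]
            if parent in latent:
                z = r * latent[parent] + np.sqrt(1 - r * r) * z
        se = sub_effects.get(f.name, zero)
        shifted = se != 0
        if shifted.any():
            z = np.where(shifted, z * structure.signature_sd, z)
        columns[f.name] = z + se + bg_effects.get(f.name, zero)

    for f in drawn:
        if f.kind == "binary":
            shift = sub_effects.get(f.name, zero) + bg_effects.get(f.name, zero)
            p = np.clip(baseline_p[f.name] + shift, 0.01, 0.99)
            columns[f.name] = (rng.random(n_total) < p).astype(float)
        elif f.kind == "count":
            lam0 = baseline_lam[f.name]
            shift = sub_effects.get(f.name, zero) + bg_effects.get(f.name, zero)
            lam = np.maximum(lam0 + shift * np.sqrt(lam0), 0.05)
            columns[f.name] = rng.poisson(lam).astype(float)

    # the comorbidity burden score is the sum of the flags, not a free draw
    flag_cols = [
        f.name for f in drawn if f.domain == "comorbidity" and f.kind == "binary"
    ]
    if "elixhauser_count" in columns and flag_cols:
        columns["elixhauser_count"] = np.sum(
            [columns[c] for c in flag_cols], axis=0
        ).astype(float)

    # outcomes per subgroup outcome model
    mort = np.empty(n_total)
    days_mean = np.empty(n_total)
    ed_mean = np.empty(n_total)
    for k, g in enumerate(structure.subgroups):
        m = labels == k
        mort[m] = g.outcomes.mortality_2y
        days_mean[m] = g.outcomes.mean_inpatient_days
        ed_mean[m] = g.outcomes.mean_ed_visits
    bg = labels == BACKGROUND_LABEL
    mort[bg] = structure.background_outcomes.mortality_2y
    days_mean[bg] = structure.background_outcomes.mean_inpatient_days
    ed_mean[bg] = structure.background_outcomes.mean_ed_visits

    died = rng.random(n_total) < mort
    inpatient_days = rng.poisson(days_mean)
    ed_visits = rng.poisson(ed_mean)

    # risk percentile: monotone in latent severity, truncated at 75
    severity = rng.standard_normal(n_total) + 3.0 * mort
    ranks = np.argsort(np.argsort(severity, kind="stable"), kind="stable")
    percentile = HIGH_RISK_THRESHOLD + np.floor(
        (100 - HIGH_RISK_THRESHOLD) * ranks / n_total
    ).astype(int)

    frame = {f.name: columns[f.name] for f in drawn}
    frame["risk_percentile"] = percentile
    frame["true_label"] = labels
    frame["died_2y"] = died.astype(int)
    frame["any_hospitalization_2y"] = (inpatient_days > 0).astype(int)
    frame["inpatient_days_2y"] = inpatient_days
    frame["any_ed_2y"] = (ed_visits > 0).astype(int)
    frame["ed_visits_2y"] = ed_visits
    df = pd.DataFrame(frame, index=pd.Index(patient_ids, name="patient_id"))
    return CohortTable(df, catalog, structure)


# ---------------------------------------------------------------------------
# missingness injection


def inject_missingness(
    table: CohortTable,
    per_domain_rates: Mapping[str, float],
    mechanism: str = "MCAR",
    seed: int = 0,
    conditioning: str = "n_primary_care_visits",
) -> CohortTable:
    """Mask feature cells at the given per-domain rates.

    Under ``MCAR`` each targeted cell is masked independently at its
    domain's rate. Under ``MAR_on_utilization`` the per-patient masking
    probability decreases monotonically with the (fully observed)
    conditioning utilization variable: patients seen less often have more
    gaps in their record. Pre-mask values are retained on the returned
    table for imputation oracles.
    """
    for dom, rate in per_domain_rates.items():
        if not 0 <= rate <= 1:
            raise ConfigurationError(f"rate {rate} for domain {dom!r} outside [0, 1]")
    if mechanism not in ("MCAR", "MAR_on_utilization"):
        raise ConfigurationError(f"unknown mechanism {mechanism!r}")
    data = table.data.copy()
    feature_names = table.feature_names
    pre_mask = data[feature_names].copy()
    rng = np.random.default_rng(seed)
    n = len(data)

    if mechanism == "MAR_on_utilization":
        if conditioning not in data.columns:
            raise ConfigurationError(f"conditioning variable {conditioning!r} absent")
        cond_dom = {f.name: f.domain for f in table.dictionary}.get(conditioning)
        if per_domain_rates.get(cond_dom, 0.0) > 0:
            raise ConfigurationError(
                "MAR conditioning variable must stay fully observed; "
                f"its domain {cond_dom!r} has a nonzero rate"
            )
        z = data[conditioning].to_numpy(dtype=float)
        sd = z.std()
        z = (z - z.mean()) / (sd if sd > 0 else 1.0)
        w = np.exp(-z)  # monotone decreasing in the conditioning variable
        w = w / w.mean()

    by_name = {f.name: f for f in table.dictionary}
    for name in feature_names:
        rate = per_domain_rates.get(by_name[name].domain, 0.0)
        if rate <= 0:
            continue
        if name == conditioning and mechanism == "MAR_on_utilization":
            continue
        if mechanism == "MCAR":
            p = np.full(n, rate)
        else:
            p = np.clip(rate * w, 0.0, 0.98)
        mask = rng.random(n) < p
        if mask.any():
            col = data[name].astype(float)
            col[mask] = np.nan
            data[name] = col
    return CohortTable(data, table.dictionary, table.structure, pre_mask=pre_mask)


# ---------------------------------------------------------------------------
# repeated measures


def generate_repeated_measures(
    table: CohortTable,
    seed: int = 0,
    mean_extra_obs: float = 2.0,
    noise_sd: float = 0.3,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Emit repeated lab/vital observations around each patient's central
    value (long frame: patient_id, variable, day, value). Patients whose
    cell was masked by :func:`inject_missingness` get no series."""
    rng = np.random.default_rng(seed)
    lo, hi = window
    rows_pid: list[np.ndarray] = []
    rows_var: list[str] = []
    frames = []
    pids = table.data.index.to_numpy()
    for f in table.dictionary:
        if not f.repeated or f.derived:
            continue
        truth = table.data[f.name].to_numpy(dtype=float)
        observed = ~np.isnan(truth)
        idx = np.flatnonzero(observed)
        n_obs = 1 + rng.poisson(mean_extra_obs, size=idx.size)
        rep_pid = np.repeat(pids[idx], n_obs)
        rep_truth = np.repeat(truth[idx], n_obs)
        total = int(n_obs.sum())
        days = rng.integers(lo, hi + 1, size=total)
        values = rep_truth + rng.normal(0.0, noise_sd, size=total)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": rep_pid,
                    "variable": f.name,
                    "day": days,
                    "value": values,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["patient_id", "variable", "day", "value"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["variable", "patient_id", "day"], kind="stable").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# pharmacy fill histories


def _simulate_fills(
    rng: np.random.Generator,
    target: float,
    window: tuple[int, int],
    supply_choices: Sequence[int] = (30, 90),
    supply_probs: Sequence[float] = (0.7, 0.3),
    overlap_prob: float = 0.15,
) -> list[tuple[int, int]]:
    lo, hi = window
    length = hi - lo + 1
    if target <= 0:
        return []
    if target >= 1:
        fills = []
        s = lo
        while s <= hi:
            fills.append((s, 30))
            s += 30
        return fills
    mean_supply = float(np.dot(supply_choices, supply_probs))
    mean_overlap = 3.0  # E[U(1, 5)]
    # gap multiplier solving target = E[covered] / E[cycle] (renewal-reward)
    c = (mean_supply - overlap_prob * mean_overlap) * (1 - target) / (
        target * (1 - overlap_prob) * mean_supply
    )
    fills = []
    s = lo + int(rng.integers(0, 6))
    while s <= hi:
        supply = int(rng.choice(supply_choices, p=supply_probs))
        fills.append((s, supply))
        if rng.random() < overlap_prob:
            delay = -rng.uniform(1.0, min(5.0, supply / 2))
        else:
            delay = supply * c * rng.uniform(0.5, 1.5)
        s = s + supply + int(round(delay))
    return fills


def generate_fill_histories(
    table: CohortTable,
    classes: Sequence[str] = DEFAULT_CLASSES,
    adherence_targets: float | Mapping[int, float] | None = None,
    seed: int = 0,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Simulate pharmacy fills so each prescribed patient's day-level
    coverage approximates a target PDC.

    ``adherence_targets`` is either a single target for every patient, or a
    mapping from true_label to target (unmapped labels fall back to the
    baseline behaviour: patient-level targets around 0.77, the typical mean
    adherence of high-risk cohorts). Gaps and overlapping early refills
    both occur with positive probability. Returns a long frame
    (patient_id, medication_class, start_day, days_supplied).
    """
    if not classes:
        raise ConfigurationError("empty medication class list")
    for cls in classes:
        if cls not in CLASS_FLAGS:
            raise ConfigurationError(f"unknown medication class {cls!r}")
        if CLASS_FLAGS[cls] not in table.data.columns:
            raise ConfigurationError(f"flag column for class {cls!r} absent from table")
    if isinstance(adherence_targets, Mapping):
        for t in adherence_targets.values():
            if not 0 <= t <= 1:
                raise ConfigurationError("adherence targets must lie in [0, 1]")
    elif adherence_targets is not None and not 0 <= adherence_targets <= 1:
        raise ConfigurationError("adherence targets must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    labels = table.data["true_label"].to_numpy()
    n = len(table.data)

    # resolve per-patient targets (deterministic order: patients x draw)
    targets = np.empty(n)
    for i in range(n):
        if adherence_targets is None:
            base = 0.77
            jitter = True
        elif isinstance(adherence_targets, Mapping):
            base = adherence_targets.get(int(labels[i]), 0.77)
            jitter = 0 < base < 1
        else:
            base = float(adherence_targets)
            jitter = 0 < base < 1
        if jitter:
            targets[i] = float(np.clip(base + rng.normal(0.0, 0.08), 0.02, 0.98))
        else:
            targets[i] = base

    records = []
    pids = table.data.index.to_numpy()
    for cls in classes:
        flags = table.data[CLASS_FLAGS[cls]].to_numpy(dtype=float)
        for i in range(n):
            if not flags[i] == 1.0:
                continue
            for start, supply in _simulate_fills(rng, targets[i], window):
                records.append((pids[i], cls, start, supply))
    return pd.DataFrame(
        records, columns=["patient_id", "medication_class", "start_day", "days_supplied"]
    )


# ---------------------------------------------------------------------------
# IO


def write_cohort(
    table: CohortTable,
    outdir: str | Path,
    measures: pd.DataFrame | None = None,
    fills: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the cohort CSV (repeated-measure variables excluded: those are
    delivered through the repeated-measures TSV), the JSON data dictionary,
    the ground-truth JSON, and optional fills / measures TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    repeated = {f.name for f in table.dictionary if f.repeated}
    cohort_cols = [
        c for c in table.data.columns if c not in repeated and c != "true_label"
    ]
    paths["cohort"] = outdir / "cohort.csv"
    table.data[cohort_cols].to_csv(paths["cohort"])

    paths["dictionary"] = outdir / "data_dictionary.json"
    paths["dictionary"].write_text(
        json.dumps([asdict(f) for f in table.dictionary], indent=1)
    )

    paths["ground_truth"] = outdir / "ground_truth.json"
    truth = {
        "seed": table.structure.seed,
        "background_label": BACKGROUND_LABEL,
        "background_fraction": table.structure.background_fraction,
        "subgroups": [
            {
                "index": k,
                "name": g.name,
                "size": g.size,
                "category": g.category,
                "signature": [asdict(s) for s in g.signature],
                "outcomes": asdict(g.outcomes),
                "adherence": g.adherence,
            }
            for k, g in enumerate(table.structure.subgroups)
        ],
        "true_labels": {
            pid: int(lab) for pid, lab in table.data["true_label"].items()
        },
    }
    paths["ground_truth"].write_text(json.dumps(truth, indent=1))

    if measures is not None:
        paths["measures"] = outdir / "repeated_measures.tsv"
        measures.to_csv(paths["measures"], sep="\t", index=False)
    if fills is not None:
        paths["fills"] = outdir / "fills.tsv"
        fills.to_csv(paths["fills"], sep="\t", index=False)
    return paths
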