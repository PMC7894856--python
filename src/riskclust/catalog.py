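"""Default variable catalog for synthetic high-risk cohorts.

The catalog mirrors the kind of post-ETL feature table a clinical data
warehouse extract yields for a high-risk primary-care population: 119
variables spread over seven domains (sociodemographic/insurance,
comorbidity flags, pharmacy incl. medication adherence, vital signs,
laboratories, prior utilization, psychobehavioral). Comorbidity and
psychobehavioral variables are binary diagnosis-style flags, utilization
variables are visit/day counts, labs and vitals are continuous and carry
repeated measurements, and the adherence variables are derived downstream
from pharmacy fill histories rather than drawn directly.
"""

from __future__ import annotations

from dataclasses import dataclass

DOMAINS = (
    "sociodemographic",
    "comorbidity",
    "pharmacy",
    "vitals",
    "labs",
    "utilization",
    "psychobehavioral",
)

#: Collapse the seven feature domains onto the three subgroup categories
#: used when labelling clusters (clinical/comorbidity-driven vs
#: sociodemographic vs psychobehavioral).
CATEGORY_BY_DOMAIN = {
    "sociodemographic": "sociodemographic",
    "psychobehavioral": "psychobehavioral",
    "comorbidity": "comorbidity",
    "pharmacy": "comorbidity",
    "vitals": "comorbidity",
    "labs": "comorbidity",
    "utilization": "comorbidity",
}

KINDS = ("binary", "count", "continuous", "categorical")


@dataclass(frozen=True)
class FeatureDef:
    """One entry of the data dictionary.

    ``derived`` marks variables computed by the feature-engineering stage
    (e.g. adherence from fill histories) instead of being drawn directly;
    ``repeated`` marks variables observed as repeated measurements that are
    median-aggregated downstream.
    """

    name: str
    domain: str
    kind: str
    derived: bool = False
    repeated: bool = False

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r} for {self.name!r}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r} for {self.name!r}")


def _b(name: str, domain: str) -> FeatureDef:
    return FeatureDef(name, domain, "binary")


def _c(name: str, domain: str) -> FeatureDef:
    return FeatureDef(name, domain, "count")


def _cont(name: str, domain: str, repeated: bool = False) -> FeatureDef:
    return FeatureDef(name, domain, "continuous", repeated=repeated)


_SOCIODEMOGRAPHIC = [
    _cont("age", "sociodemographic"),
    _b("female", "sociodemographic"),
    _b("race_black", "sociodemographic"),
    _b("race_hispanic", "sociodemographic"),
    _b("race_other", "sociodemographic"),
    _b("medicaid", "sociodemographic"),
    _b("medicare", "sociodemographic"),
    _b("married", "sociodemographic"),
    _b("lives_alone", "sociodemographic"),
    _b("rural_residence", "sociodemographic"),
    _b("homeless_history", "sociodemographic"),
    _b("va_priority_high", "sociodemographic"),
    _b("service_connected_50plus", "sociodemographic"),
    _b("low_income_pension", "sociodemographic"),
    _b("copay_exempt", "sociodemographic"),
    _cont("income_proxy", "sociodemographic"),
    _cont("years_enrolled", "sociodemographic"),
    _cont("distance_to_care_miles", "sociodemographic"),
]

_COMORBIDITY_FLAGS = [
    "chf",
    "cardiac_arrhythmia",
    "valvular_disease",
    "pulmonary_circulation_disorder",
    "peripheral_vascular_disease",
    "hypertension_uncomplicated",
    "hypertension_complicated",
    "paralysis",
    "other_neurological_disorder",
    "chronic_pulmonary_disease",
    "diabetes_uncomplicated",
    "diabetes_complicated",
    "hypothyroidism",
    "renal_failure",
    "liver_disease",
    "peptic_ulcer_disease",
    "hiv_aids",
    "lymphoma",
    "metastatic_cancer",
    "solid_tumor_without_metastasis",
    "rheumatoid_arthritis",
    "coagulopathy",
    "obesity",
    "weight_loss",
    "fluid_electrolyte_disorder",
    "blood_loss_anemia",
    "deficiency_anemia",
    "ischemic_heart_disease",
    "post_surgical_infection",
]

_COMORBIDITY = [_b(n, "comorbidity") for n in _COMORBIDITY_FLAGS] + [
    _c("elixhauser_count", "comorbidity")
]

_PHARMACY = [
    _b("antidepressant_use", "pharmacy"),
    _b("antihypertensive_use", "pharmacy"),
    _b("glucose_lowering_use", "pharmacy"),
    _b("statin_use", "pharmacy"),
    _b("anticoagulant_use", "pharmacy"),
    _b("opioid_rx", "pharmacy"),
    _b("sedative_rx", "pharmacy"),
    _b("antipsychotic_use", "pharmacy"),
    _b("insulin_use", "pharmacy"),
    _c("n_active_medications", "pharmacy"),
    FeatureDef("adherence_weighted", "pharmacy", "continuous", derived=True),
    FeatureDef("adherence_antihypertensive", "pharmacy", "continuous", derived=True),
    FeatureDef("adherence_statin", "pharmacy", "continuous", derived=True),
    FeatureDef("adherence_glucose_lowering", "pharmacy", "continuous", derived=True),
]

_VITALS = [
    _cont("systolic_bp", "vitals", repeated=True),
    _cont("diastolic_bp", "vitals", repeated=True),
    _cont("pulse", "vitals", repeated=True),
    _cont("respiratory_rate", "vitals", repeated=True),
    _cont("bmi", "vitals", repeated=True),
    _cont("pain_score", "vitals", repeated=True),
    _cont("weight_change", "vitals", repeated=True),
]

_LAB_NAMES = [
    "albumin",
    "creatinine",
    "egfr",
    "hemoglobin_a1c",
    "hemoglobin",
    "hematocrit",
    "wbc_count",
    "platelet_count",
    "sodium",
    "potassium",
    "bicarbonate",
    "bun",
    "glucose",
    "alt",
    "ast",
    "total_bilirubin",
    "alkaline_phosphatase",
    "hdl_cholesterol",
    "triglycerides",
]

_LABS = [_cont(n, "labs", repeated=True) for n in _LAB_NAMES]

_UTILIZATION = [
    _b("any_outpatient_visit", "utilization"),
    _b("any_ed_prior", "utilization"),
    _b("any_inpatient_prior", "utilization"),
    _b("any_nursing_home", "utilization"),
    _c("n_primary_care_visits", "utilization"),
    _c("n_specialty_visits", "utilization"),
    _c("n_ed_visits_prior", "utilization"),
    _c("n_inpatient_days_prior", "utilization"),
    _c("n_general_medicine_admits", "utilization"),
    _c("n_surgical_admits", "utilization"),
    _c("n_home_based_care_visits", "utilization"),
    _c("n_telephone_encounters", "utilization"),
    _c("n_mental_health_visits", "utilization"),
    _c("n_no_show_appointments", "utilization"),
    _c("days_since_last_visit", "utilization"),
]

_PSYCHOBEHAVIORAL = [
    _b("depression", "psychobehavioral"),
    _b("psychoses", "psychobehavioral"),
    _b("ptsd", "psychobehavioral"),
    _b("anxiety_disorder", "psychobehavioral"),
    _b("bipolar_disorder", "psychobehavioral"),
    _b("alcohol_abuse", "psychobehavioral"),
    _b("drug_abuse", "psychobehavioral"),
    _b("opioid_use_disorder", "psychobehavioral"),
    _b("amphetamine_use", "psychobehavioral"),
    _b("cocaine_use", "psychobehavioral"),
    _b("sedative_use_disorder", "psychobehavioral"),
    _b("smoking_current", "psychobehavioral"),
    _b("suicide_attempt_history", "psychobehavioral"),
    _c("n_psychiatry_visits", "psychobehavioral"),
    _c("n_substance_use_visits", "psychobehavioral"),
    _c("n_detox_admissions", "psychobehavioral"),
]

#: (dependent, parent, correlation) pairs imposed on the continuous baseline
#: so the correlation-pruning stage has physiologically plausible work
#: (hematocrit tracks hemoglobin, eGFR is inversely tied to creatinine, ...).
CORRELATED_PAIRS = [
    ("hematocrit", "hemoglobin", 0.95),
    ("egfr", "creatinine", -0.90),
    ("ast", "alt", 0.88),
]


def default_catalog() -> list[FeatureDef]:
    """The 119-variable dictionary used by the synthetic cohort generator."""
    cat = (
        _SOCIODEMOGRAPHIC
        + _COMORBIDITY
        + _PHARMACY
        + _VITALS
        + _LABS
        + _UTILIZATION
        + _PSYCHOBEHAVIORAL
    )
    names = [f.name for f in cat]
    assert len(names) == len(set(names)) == 119
    return cat


def catalog_by_name(catalog: list[FeatureDef] | None = None) -> dict[str, FeatureDef]:
    return {f.name: f for f in (catalog or default_catalog())}
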