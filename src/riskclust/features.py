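"""Feature engineering: raw cohort inputs -> standardized analysis matrix.

The fixed pipeline order is: median aggregation of repeated measurements ->
PDC adherence derivation -> low-variance filter -> correlation pruning ->
missingness-count feature -> single chained-equations (FCS) imputation ->
standardization. Every applied transform is recorded in the provenance
list, and pruning decisions are recorded in a :class:`PruningReport`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import FeatureDef
from .errors import ConfigurationError, InputError, PipelineError
from .synthgen import CLASS_FLAGS, DEFAULT_WINDOW, FillHistory, RepeatedMeasureSeries

MISSINGNESS_FEATURE = "n_missing_variables"


# ---------------------------------------------------------------------------
# median aggregation of repeated measurements


def aggregate_medians(
    series: pd.DataFrame | Sequence[RepeatedMeasureSeries],
) -> pd.DataFrame:
    """Collapse repeated observations to one median per (patient, variable).

    Accepts either the long measurements frame (patient_id, variable, day,
    value) or a list of :class:`RepeatedMeasureSeries`. Patients with no
    series for a variable simply get no cell (NaN after reindexing).
    """
    if not isinstance(series, pd.DataFrame):
        rows = [
            (s.patient_id, s.variable, day, value)
            for s in series
            for day, value in s.observations
        ]
        series = pd.DataFrame(rows, columns=["patient_id", "variable", "day", "value"])
    if series.empty:
        return pd.DataFrame()
    wide = series.groupby(["patient_id", "variable"])["value"].median().unstack()
    wide.columns.name = None
    return wide


# ---------------------------------------------------------------------------
# proportion of days covered


def covered_days(fills: Sequence[tuple[int, int]], window: tuple[int, int]) -> set[int]:
    lo, hi = window
    days: set[int] = set()
    for start, supply in fills:
        days.update(range(max(start, lo), min(start + supply - 1, hi) + 1))
    return days


def compute_pdc(history: FillHistory) -> float:
    """PDC = |union of covered days within the window| / window length.

    Overlapping fills never double-count (set union).
    """
    lo, hi = history.window
    length = hi - lo + 1
    if length <= 0:
        raise InputError("observation window has length 0")
    return len(covered_days(history.fills, history.window)) / length


def weighted_adherence(
    per_class_pdc: Mapping[str, float],
    weights: Mapping[str, float] | None = None,
) -> float:
    """Combine per-class PDCs into a single adherence value.

    Default weights are days-of-therapy per class (more prescribed days
    contribute more); pass equal weights for an unweighted mean. Classes
    with zero total weight across the board collapse to 0 (prescribed but
    never filled).
    """
    if not per_class_pdc:
        raise InputError("no per-class PDC values")
    if weights is None:
        weights = {c: 1.0 for c in per_class_pdc}
    total = sum(weights.get(c, 0.0) for c in per_class_pdc)
    if total <= 0:
        return 0.0
    return sum(per_class_pdc[c] * weights.get(c, 0.0) for c in per_class_pdc) / total


def pdc_features(
    fills: pd.DataFrame,
    cohort: pd.DataFrame,
    classes: Sequence[str] = tuple(CLASS_FLAGS),
    window: tuple[int, int] = DEFAULT_WINDOW,
    weighting: str = "days_supplied",
) -> pd.DataFrame:
    """Per-patient per-class PDC plus weighted adherence.

    A patient prescribed a class (per its flag column) with no fills gets
    PDC 0 for that class; a patient prescribed nothing in any class gets
    the missing marker, not 0.
    """
    lo, hi = window
    if hi - lo + 1 <= 0:
        raise InputError("observation window has length 0")
    if weighting not in ("days_supplied", "unweighted"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    index = cohort.index
    out = pd.DataFrame(index=index)
    weights = pd.DataFrame(0.0, index=index, columns=list(classes))
    by_pair = (
        fills.groupby(["patient_id", "medication_class"])
        if len(fills)
        else None
    )
    grouped: dict[tuple[str, str], pd.DataFrame] = (
        {k: g for k, g in by_pair} if by_pair is not None else {}
    )
    for cls in classes:
        flag = CLASS_FLAGS.get(cls)
        if flag is None or flag not in cohort.columns:
            raise ConfigurationError(f"no prescription flag for class {cls!r}")
        prescribed = cohort[flag] == 1
        col = np.full(len(index), np.nan)
        wcol = np.zeros(len(index))
        for i, pid in enumerate(index):
            if not prescribed.iloc[i]:
                continue
            g = grouped.get((pid, cls))
            if g is None:
                col[i] = 0.0
                continue
            pairs = list(zip(g["start_day"].astype(int), g["days_supplied"].astype(int)))
            col[i] = len(covered_days(pairs, window)) / (hi - lo + 1)
            wcol[i] = float(g["days_supplied"].sum())
        out[f"adherence_{cls}"] = col
        weights[cls] = wcol

    pdc_cols = [f"adherence_{cls}" for cls in classes]
    pdcs = out[pdc_cols].to_numpy()
    if weighting == "days_supplied":
        w = weights.to_numpy()
    else:
        w = (~np.isnan(pdcs)).astype(float)
    w = np.where(np.isnan(pdcs), 0.0, w)
    wsum = w.sum(axis=1)
    any_prescribed = (~np.isnan(pdcs)).any(axis=1)
    weighted = np.full(len(index), np.nan)
    nz = wsum > 0
    weighted[nz] = (np.nan_to_num(pdcs) * w)[nz].sum(axis=1) / wsum[nz]
    # prescribed somewhere but zero days of therapy anywhere -> 0.0
    weighted[any_prescribed & ~nz] = 0.0
    out["adherence_weighted"] = weighted
    return out


# ---------------------------------------------------------------------------
# pruning


@dataclass
class PruningReport:
    n_original: int
    removed_low_variance: list[tuple[str, float]] = field(default_factory=list)
    removed_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    n_retained: int = 0

    def to_dict(self) -> dict:
        return {
            "n_original": self.n_original,
            "removed_low_variance": [
                {"variable": v, "variance": var} for v, var in self.removed_low_variance
            ],
            "removed_correlated": [
                {"dropped": d, "kept": k, "r": r} for d, k, r in self.removed_correlated
            ],
            "n_retained": self.n_retained,
        }


def low_variance_filter(
    matrix: pd.DataFrame, min_variance: float = 0.0099
) -> tuple[pd.DataFrame, list[tuple[str, float]]]:
    """Drop columns whose observed-value variance falls below the cutoff.

    For binary columns the population variance equals p(1-p), so the
    default cutoff of 0.0099 drops flags with prevalence below 1% or above
    99% (the usual near-zero-variance convention).
    """
    if matrix.shape[1] < 1:
        raise InputError("matrix has no columns")
    dropped: list[tuple[str, float]] = []
    keep: list[str] = []
    for col in matrix.columns:
        vals = matrix[col].dropna().to_numpy(dtype=float)
        var = float(np.var(vals)) if vals.size else 0.0
        if var < min_variance:
            dropped.append((col, var))
        else:
            keep.append(col)
    if not keep:
        raise PipelineError(f"all {matrix.shape[1]} columns dropped by variance filter")
    return matrix[keep], dropped


def correlation_prune(
    matrix: pd.DataFrame, r_max: float = 0.80
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Greedy pairwise-correlation pruning.

    While any retained pair has |Pearson r| > r_max (computed on
    pairwise-complete observations), the member of the worst pair with the
    larger mean absolute correlation to all other retained columns is
    dropped; ties drop the later column in the fixed column order.
    """
    cols = list(matrix.columns)
    if len(cols) < 2:
        return matrix, []
    corr = matrix.corr(min_periods=2).to_numpy(dtype=float)
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr, nan=0.0)
    acorr = np.abs(corr)
    active = np.ones(len(cols), dtype=bool)
    removed: list[tuple[str, str, float]] = []
    while True:
        sub = np.where(np.outer(active, active), acorr, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= r_max:
            break
        i, j = min(i, j), max(i, j)
        others = active.copy()
        mean_i = sub[i, others].mean()
        mean_j = sub[j, others].mean()
        if mean_i > mean_j:
            drop, keep = i, j
        elif mean_j > mean_i:
            drop, keep = j, i
        else:  # tie: drop the later column
            drop, keep = j, i
        removed.append((cols[drop], cols[keep], float(corr[drop, keep])))
        active[drop] = False
    retained = [c for c, a in zip(cols, active) if a]
    return matrix[retained], removed


# ---------------------------------------------------------------------------
# missingness count


def missingness_count(matrix: pd.DataFrame) -> pd.Series:
    """Per-patient count of missing cells among the retained analysis
    variables (run after pruning, before imputation)."""
    return matrix.isna().sum(axis=1).astype(int).rename(MISSINGNESS_FEATURE)


# ---------------------------------------------------------------------------
# FCS imputation


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _logistic_irls(
    X: np.ndarray, y: np.ndarray, ridge: float = 1e-3, max_iter: int = 25, tol: float = 1e-8
) -> np.ndarray:
    """Ridge-stabilized iteratively reweighted least squares for a logistic
    model with intercept (the ridge keeps separation from diverging)."""
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    pen = ridge * np.eye(p + 1)
    pen[0, 0] = 0.0
    for _ in range(max_iter):
        eta = A @ beta
        mu = np.clip(_sigmoid(eta), 1e-8, 1 - 1e-8)
        w = mu * (1 - mu)
        grad = A.T @ (y - mu) - pen @ beta
        hess = (A * w[:, None]).T @ A + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def impute_fcs(
    matrix: pd.DataFrame,
    kinds: Mapping[str, str],
    n_cycles: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Single chained-equations imputation (one completed data set).

    Missing cells are initialized by draws from each column's observed
    values; then for ``n_cycles`` sweeps each incomplete variable is
    regressed on all others using the currently completed data (linear
    model with residual noise for continuous/count variables, logistic with
    Bernoulli draws for binary ones) and its missing cells are replaced.
    Observed cells are never altered. Deterministic given ``seed``.
    """
    if n_cycles < 1:
        raise ConfigurationError("n_cycles must be >= 1")
    mask = matrix.isna()
    if not mask.to_numpy().any():
        return matrix.copy()
    fully_missing = [c for c in matrix.columns if mask[c].all()]
    if fully_missing:
        raise InputError(f"column(s) fully missing: {fully_missing}")

    rng = np.random.default_rng(seed)
    cols = list(matrix.columns)
    X = matrix.to_numpy(dtype=float).copy()
    M = mask.to_numpy()
    incomplete = [j for j, c in enumerate(cols) if M[:, j].any()]

    # initialization: draws from the observed marginal
    for j in incomplete:
        obs = X[~M[:, j], j]
        X[M[:, j], j] = rng.choice(obs, size=int(M[:, j].sum()), replace=True)

    for _ in range(n_cycles):
        for j in incomplete:
            mis = M[:, j]
            obs = ~mis
            others = [k for k in range(len(cols)) if k != j]
            Z = X[:, others]
            y = X[:, j]
            kind = kinds.get(cols[j], "continuous")
            if kind == "binary":
                y_obs = y[obs]
                if y_obs.min() == y_obs.max():
                    X[mis, j] = y_obs[0]
                    continue
                beta = _logistic_irls(Z[obs], y_obs)
                p_mis = _sigmoid(
                    np.column_stack([np.ones(int(mis.sum())), Z[mis]]) @ beta
                )
                X[mis, j] = (rng.random(int(mis.sum())) < p_mis).astype(float)
            else:
                A_obs = np.column_stack([np.ones(int(obs.sum())), Z[obs]])
                coef, *_ = np.linalg.lstsq(A_obs, y[obs], rcond=None)
                resid = y[obs] - A_obs @ coef
                sd = float(resid.std())
                A_mis = np.column_stack([np.ones(int(mis.sum())), Z[mis]])
                pred = A_mis @ coef + rng.normal(0.0, sd, size=int(mis.sum()))
                if kind == "count":
                    pred = np.maximum(np.round(pred), 0.0)
                X[mis, j] = pred
    out = pd.DataFrame(X, index=matrix.index, columns=matrix.columns)
    out[~mask] = matrix[~mask]  # observed cells bit-exact
    return out


# ---------------------------------------------------------------------------
# standardization


@dataclass
class Standardizer:
    means: pd.Series
    sds: pd.Series

    def apply(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return (matrix[self.means.index] - self.means) / self.sds


def standardize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, Standardizer]:
    """Fit-once z-scoring: every column (binary ones included, so ridge
    coefficients are comparable across types) is centered and scaled by the
    fitting-set mean and population SD."""
    means = matrix.mean()
    sds = pd.Series(
        np.std(matrix.to_numpy(dtype=float), axis=0), index=matrix.columns
    )
    zero = sds[sds == 0].index.tolist()
    if zero:
        raise PipelineError(f"zero-variance column(s) reached standardize: {zero}")
    tf = Standardizer(means, sds)
    return tf.apply(matrix), tf


# ---------------------------------------------------------------------------
# end-to-end feature engineering


@dataclass
class FeatureMatrix:
    """Analysis-ready matrix plus metadata.

    ``values`` is the standardized complete matrix (patients x retained
    variables); ``domains`` maps each retained variable to its domain tag;
    ``provenance`` is the ordered list of applied transforms.
    """

    values: pd.DataFrame
    domains: dict[str, str]
    kinds: dict[str, str]
    standardizer: Standardizer
    report: PruningReport
    provenance: list[dict] = field(default_factory=list)


def assemble_matrix(
    cohort: pd.DataFrame,
    dictionary: Sequence[FeatureDef],
    measures: pd.DataFrame | None = None,
    fills: pd.DataFrame | None = None,
    classes: Sequence[str] = tuple(CLASS_FLAGS),
    window: tuple[int, int] = DEFAULT_WINDOW,
    weighting: str = "days_supplied",
) -> pd.DataFrame:
    """Combine direct cohort columns, median-aggregated repeated
    measurements and fill-derived adherence into one raw feature matrix
    with NaN as the missing marker, columns in dictionary order."""
    medians = aggregate_medians(measures) if measures is not None else pd.DataFrame()
    if not medians.empty:
        medians = medians.reindex(cohort.index)
    adherence = (
        pdc_features(fills, cohort, classes, window, weighting)
        if fills is not None
        else pd.DataFrame(index=cohort.index)
    )
    pieces: dict[str, pd.Series | float] = {}
    for f in dictionary:
        if f.derived:
            if f.name in adherence.columns:
                pieces[f.name] = adherence[f.name]
        elif f.repeated:
            pieces[f.name] = (
                medians[f.name] if f.name in medians.columns else np.nan
            )
        elif f.name in cohort.columns:
            pieces[f.name] = cohort[f.name].astype(float)
    return pd.DataFrame(pieces, index=cohort.index)


def build_features(
    cohort: pd.DataFrame,
    dictionary: Sequence[FeatureDef],
    measures: pd.DataFrame | None = None,
    fills: pd.DataFrame | None = None,
    *,
    min_variance: float = 0.0099,
    r_max: float = 0.80,
    n_cycles: int = 10,
    seed: int = 0,
    classes: Sequence[str] = tuple(CLASS_FLAGS),
    window: tuple[int, int] = DEFAULT_WINDOW,
    weighting: str = "days_supplied",
) -> FeatureMatrix:
    """Run the full fixed-order feature pipeline on raw cohort inputs."""
    provenance: list[dict] = []
    raw = assemble_matrix(cohort, dictionary, measures, fills, classes, window, weighting)
    provenance.append(
        {"step": "assemble", "n_variables": raw.shape[1], "weighting": weighting}
    )

    report = PruningReport(n_original=raw.shape[1])
    pruned, lowvar = low_variance_filter(raw, min_variance)
    report.removed_low_variance = lowvar
    provenance.append(
        {"step": "low_variance_filter", "min_variance": min_variance,
         "removed": [v for v, _ in lowvar]}
    )

    pruned, corr_removed = correlation_prune(pruned, r_max)
    report.removed_correlated = corr_removed
    report.n_retained = pruned.shape[1]
    provenance.append(
        {"step": "correlation_prune", "r_max": r_max,
         "removed": [d for d, _, _ in corr_removed]}
    )

    with_count = pruned.copy()
    with_count[MISSINGNESS_FEATURE] = missingness_count(pruned)
    provenance.append({"step": "missingness_count", "feature": MISSINGNESS_FEATURE})

    kinds = {f.name: f.kind for f in dictionary}
    kinds[MISSINGNESS_FEATURE] = "count"
    complete = impute_fcs(with_count, kinds, n_cycles=n_cycles, seed=seed)
    provenance.append({"step": "impute_fcs", "n_cycles": n_cycles, "seed": seed})

    # a constant missingness count (e.g. fully observed input) cannot be
    # standardized; drop it rather than fail
    const = [c for c in complete.columns if complete[c].nunique() <= 1]
    if const:
        complete = complete.drop(columns=const)
        provenance.append({"step": "drop_constant_post_impute", "removed": const})

    z, tf = standardize(complete)
    provenance.append({"step": "standardize", "n_variables": z.shape[1]})

    domains = {f.name: f.domain for f in dictionary}
    domains[MISSINGNESS_FEATURE] = "utilization"
    return FeatureMatrix(
        values=z,
        domains={c: domains.get(c, "utilization") for c in z.columns},
        kinds={c: kinds.get(c, "continuous") for c in z.columns},
        standardizer=tf,
        report=report,
        provenance=provenance,
    )


def write_features(fm: FeatureMatrix, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "analysis_matrix.csv",
        "report": outdir / "feature_report.json",
    }
    fm.values.to_csv(paths["matrix"])
    paths["report"].write_text(
        json.dumps(
            {
                "pruning": fm.report.to_dict(),
                "provenance": fm.provenance,
                "domains": fm.domains,
            },
            indent=1,
        )
    )
    return paths
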