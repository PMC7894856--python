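"""Per-cluster outcome summaries and the cohort baseline table.

Noise/outlier patients are first-class: every summary carries a dedicated
noise row (never silently merged or dropped) plus an overall row.
Percentages and means are reported to one decimal in the formatted
variants; machine-readable outputs keep full precision.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import FeatureDef
from .clustering import NOISE
from .errors import InputError

OUTCOME_FIELDS = [
    "died_2y",
    "any_hospitalization_2y",
    "inpatient_days_2y",
    "any_ed_2y",
    "ed_visits_2y",
]


def summarize_outcomes(
    labels: pd.Series, outcomes: pd.DataFrame
) -> pd.DataFrame:
    """Exact group-by outcome aggregation per cluster, plus noise and
    overall rows.

    ``labels`` is indexed by patient_id with the reserved noise label;
    ``outcomes`` must cover every labeled patient and may also carry
    ``risk_percentile``.
    """
    missing = labels.index.difference(outcomes.index)
    if len(missing):
        raise InputError(f"patient(s) with label but no outcomes: {list(missing)[:5]}")
    for col in OUTCOME_FIELDS:
        if col not in outcomes.columns:
            raise InputError(f"outcome column {col!r} absent")
    joined = outcomes.loc[labels.index].copy()
    joined["_cluster"] = labels.to_numpy()

    def one_row(sub: pd.DataFrame, name) -> dict:
        n = len(sub)
        row = {"cluster": name, "n": n}
        if n == 0:
            row.update(
                {
                    "mortality_pct": np.nan,
                    "any_hospitalization_pct": np.nan,
                    "mean_inpatient_days": np.nan,
                    "any_ed_pct": np.nan,
                    "mean_ed_visits": np.nan,
                    "mean_risk_percentile": np.nan,
                }
            )
            return row
        row["mortality_pct"] = 100.0 * sub["died_2y"].mean()
        row["any_hospitalization_pct"] = 100.0 * sub["any_hospitalization_2y"].mean()
        row["mean_inpatient_days"] = float(sub["inpatient_days_2y"].mean())
        row["any_ed_pct"] = 100.0 * sub["any_ed_2y"].mean()
        row["mean_ed_visits"] = float(sub["ed_visits_2y"].mean())
        row["mean_risk_percentile"] = (
            float(sub["risk_percentile"].mean())
            if "risk_percentile" in sub.columns
            else np.nan
        )
        return row

    rows = []
    cluster_ids = sorted(int(u) for u in labels.unique() if u != NOISE)
    for cid in cluster_ids:
        rows.append(one_row(joined[joined["_cluster"] == cid], cid))
    rows.append(one_row(joined[joined["_cluster"] == NOISE], "noise"))
    rows.append(one_row(joined, "overall"))
    return pd.DataFrame(rows)


def format_outcome_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """One-decimal presentation of the machine summary."""
    out = summary.copy()
    for col in out.columns:
        if col.endswith("_pct") or col.startswith("mean_"):
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.1f}"
            )
    return out


def baseline_table(
    cohort: pd.DataFrame, dictionary: Sequence[FeatureDef] | Mapping[str, str]
) -> pd.DataFrame:
    """Descriptive cohort table: mean (SD) for continuous/count variables,
    n (%) for binary ones, over whatever variables exist in the input."""
    if len(cohort) == 0:
        raise InputError("empty cohort")
    if not isinstance(dictionary, Mapping):
        kinds = {f.name: f.kind for f in dictionary}
    else:
        kinds = dict(dictionary)
    rows = []
    for name, kind in kinds.items():
        if name not in cohort.columns:
            continue
        vals = cohort[name].dropna()
        if kind == "binary":
            n1 = int((vals == 1).sum())
            pct = 100.0 * n1 / len(vals) if len(vals) else np.nan
            rows.append(
                {
                    "variable": name,
                    "kind": kind,
                    "summary": f"{n1} ({pct:.1f})",
                    "value": n1,
                    "spread": pct,
                }
            )
        else:
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
            rows.append(
                {
                    "variable": name,
                    "kind": kind,
                    "summary": f"{mean:.2f} ({sd:.2f})",
                    "value": mean,
                    "spread": sd,
                }
            )
    return pd.DataFrame(rows)
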