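"""Discriminative cluster characterization via one-versus-rest ridge.

Each cluster is described by ridge regressions of a binary membership
indicator (this cluster = 1, any other cluster = 0; noise excluded from
both classes) on the standardized analysis variables, fit over a grid of
100 penalty values. The 100 coefficient vectors are averaged element-wise
and normalized to unit maximum absolute value; per-variable importance is
the cross-cluster range (max - min) of those normalized coefficients, and
the 20 largest ranges are flagged for plotting. An automated label
suggestion reports each cluster's top-5 variables with sign and domain and
the majority domain collapsed onto the comorbidity / sociodemographic /
psychobehavioral taxonomy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .catalog import CATEGORY_BY_DOMAIN
from .clustering import NOISE
from .errors import InputError


def default_penalty_grid(
    n: int = 100, lo: float = 1e-4, hi: float = 1e4
) -> np.ndarray:
    """100 log-spaced ridge penalties."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


@dataclass
class ClusterProfile:
    cluster_id: int
    variables: list[str]
    coefficients: np.ndarray  # grid-averaged, normalized to unit max-abs
    penalty_grid: np.ndarray
    n_members: int

    def top(self, k: int = 5) -> list[tuple[str, float]]:
        idx = np.argsort(-np.abs(self.coefficients), kind="stable")[:k]
        return [(self.variables[i], float(self.coefficients[i])) for i in idx]


# ---------------------------------------------------------------------------
# ridge


def fit_ridge(
    X: np.ndarray, y: np.ndarray, lam: float
) -> tuple[np.ndarray, float]:
    """Linear-probability ridge with unpenalized intercept.

    Minimizes ||y - b0 - X beta||^2 + lam ||beta||^2; solved in closed
    form on column-centered data.
    """
    if lam <= 0:
        raise InputError("penalty must be positive")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise InputError("y must contain both classes")
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    p = X.shape[1]
    beta = linalg.solve(
        Xc.T @ Xc + lam * np.eye(p), Xc.T @ yc, assume_a="pos"
    )
    intercept = float(ym - xm @ beta)
    return beta, intercept


def _ridge_path(X: np.ndarray, y: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """All grid solutions at once via one SVD of the centered design."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    uty = U.T @ yc
    # beta(lam) = V diag(s / (s^2 + lam)) U^T yc
    shrink = s[:, None] / (s[:, None] ** 2 + grid[None, :])
    return Vt.T @ (shrink * uty[:, None])  # p x n_grid


def profile_cluster(
    X: pd.DataFrame,
    labels: np.ndarray,
    cluster_id: int,
    grid: np.ndarray | None = None,
) -> ClusterProfile:
    """Fit the 100-penalty one-vs-rest ridge family for one cluster and
    return its averaged, max-abs-normalized coefficient vector."""
    if grid is None:
        grid = default_penalty_grid()
    grid = np.asarray(grid, dtype=float)
    if len(grid) != 100:
        warnings.warn(
            f"penalty grid has {len(grid)} values (100 is conventional)",
            stacklevel=2,
        )
    labels = np.asarray(labels)
    clustered = labels != NOISE
    y = (labels[clustered] == cluster_id).astype(float)
    if y.sum() == 0:
        raise InputError(f"cluster {cluster_id} is empty")
    if y.sum() == y.size:
        raise InputError("one-vs-rest needs at least one non-member cluster point")
    Xm = X.to_numpy(dtype=float)[clustered]
    path = _ridge_path(Xm, y, grid)  # p x n_grid
    avg = path.mean(axis=1)
    max_abs = np.max(np.abs(avg))
    if max_abs > 0:
        avg = avg / max_abs
    return ClusterProfile(
        cluster_id=int(cluster_id),
        variables=list(X.columns),
        coefficients=avg,
        penalty_grid=grid,
        n_members=int(y.sum()),
    )


def profile_all_clusters(
    X: pd.DataFrame, labels: np.ndarray, grid: np.ndarray | None = None
) -> list[ClusterProfile]:
    ids = sorted(int(u) for u in np.unique(labels) if u != NOISE)
    return [profile_cluster(X, labels, cid, grid) for cid in ids]


# ---------------------------------------------------------------------------
# importance and label evidence


def importance_ranges(profiles: Sequence[ClusterProfile]) -> pd.DataFrame:
    """Per-variable cross-cluster range of the normalized coefficients,
    ranked descending with the top-20 flagged (ties keep the fixed
    variable order)."""
    if len(profiles) < 2:
        raise InputError("importance ranges need >= 2 cluster profiles")
    variables = profiles[0].variables
    coef = np.column_stack([p.coefficients for p in profiles])
    ranges = coef.max(axis=1) - coef.min(axis=1)
    order = np.argsort(-ranges, kind="stable")
    rank = np.empty(len(variables), dtype=int)
    rank[order] = np.arange(1, len(variables) + 1)
    n_flag = min(20, len(variables))
    table = pd.DataFrame(
        {
            "variable": variables,
            "range": ranges,
            "rank": rank,
            "top20": rank <= n_flag,
        }
    )
    return table.sort_values("rank", kind="stable").reset_index(drop=True)


def suggest_labels(
    profiles: Sequence[ClusterProfile],
    domains: Mapping[str, str],
    top_k: int = 5,
) -> list[dict]:
    """Per-cluster ordered label evidence: the top-k variables by absolute
    normalized coefficient with sign and domain tag, plus the majority
    domain mapped onto the subgroup category taxonomy. Domain ties are all
    reported rather than silently broken."""
    out = []
    for prof in profiles:
        top = prof.top(top_k)
        evidence = [
            {
                "variable": v,
                "coefficient": c,
                "sign": "+" if c >= 0 else "-",
                "domain": domains.get(v, "unknown"),
            }
            for v, c in top
        ]
        doms = [e["domain"] for e in evidence]
        uniq, counts = np.unique(doms, return_counts=True)
        winners = sorted(str(u) for u, c in zip(uniq, counts) if c == counts.max())
        categories = sorted(
            {CATEGORY_BY_DOMAIN.get(w, "comorbidity") for w in winners}
        )
        out.append(
            {
                "cluster": prof.cluster_id,
                "n_members": prof.n_members,
                "top_variables": evidence,
                "majority_domains": winners,
                "suggested_category": categories[0] if len(categories) == 1 else categories,
            }
        )
    return out


# ---------------------------------------------------------------------------
# IO


def write_profiles(
    profiles: Sequence[ClusterProfile],
    importance: pd.DataFrame,
    evidence: list[dict],
    outdir: str | Path,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in profiles:
        for v, c in zip(p.variables, p.coefficients):
            rows.append({"cluster": p.cluster_id, "variable": v, "coefficient": c})
    pd.DataFrame(rows).to_csv(outdir / "cluster_profiles.tsv", sep="\t", index=False)
    importance.to_csv(outdir / "importance.tsv", sep="\t", index=False)
    (outdir / "label_evidence.json").write_text(json.dumps(evidence, indent=1))
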