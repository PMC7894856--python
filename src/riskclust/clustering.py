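"""From-scratch OPTICS on the 2-D embedding.

Produces the reachability ordering (core distance = distance to the
min_pts-th nearest neighbour, the point itself included; points processed
through a priority queue keyed by smallest reachability with index
tie-breaks), extracts flat cluster labels either by a global reachability
cut (equivalent to DBSCAN's core-point partition at that radius) or by
xi-steep up/down area extraction, and tunes (min_pts, extraction) over the
training sets with a silhouette-with-noise-penalty criterion. Points in no
cluster keep the reserved noise label -1.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, InputError
from .metrics import mean_silhouette

NOISE = -1

UNDEFINED = np.inf  # marker for undefined core/reachability distances


@dataclass(frozen=True)
class OpticsConfig:
    """min_pts counts the point itself; eps may be infinite. Exactly one of
    ``xi`` (steep-area extraction), ``cut`` (absolute reachability
    threshold) or ``cut_quantile`` (threshold at a quantile of the finite
    reachabilities, scale-free across data sets) selects the extraction."""

    min_pts: int = 25
    eps: float = math.inf
    xi: float | None = 0.05
    cut: float | None = None
    cut_quantile: float | None = None

    def __post_init__(self):
        if self.min_pts < 2:
            raise ConfigurationError("min_pts must be >= 2")
        chosen = [v is not None for v in (self.xi, self.cut, self.cut_quantile)]
        if sum(chosen) != 1:
            raise ConfigurationError(
                "exactly one of xi / cut / cut_quantile must be set"
            )
        if self.xi is not None and not 0 < self.xi < 1:
            raise ConfigurationError("xi must lie in (0, 1)")
        if self.cut is not None and self.cut > self.eps:
            raise ConfigurationError("cut threshold must be <= eps")
        if self.cut_quantile is not None and not 0 < self.cut_quantile < 1:
            raise ConfigurationError("cut_quantile must lie in (0, 1)")

    def describe(self) -> str:
        if self.xi is not None:
            ex = f"xi={self.xi}"
        elif self.cut is not None:
            ex = f"cut={self.cut}"
        else:
            ex = f"cut_quantile={self.cut_quantile}"
        return f"min_pts={self.min_pts}, {ex}"


@dataclass
class ReachabilityResult:
    order: np.ndarray  # processing order (permutation of point indices)
    core_distance: np.ndarray  # per point; UNDEFINED if not a core point
    reachability: np.ndarray  # per point; UNDEFINED for component starts
    labels: np.ndarray | None  # cluster index per point, NOISE reserved
    config: OpticsConfig
    predecessor: np.ndarray | None = None  # point that set each reachability

    @property
    def ordered_reachability(self) -> np.ndarray:
        return self.reachability[self.order]

    def noise_fraction(self) -> float:
        if self.labels is None:
            raise InputError("labels not extracted yet")
        return float(np.mean(self.labels == NOISE))


# ---------------------------------------------------------------------------
# ordering


def optics_order(points: np.ndarray, config: OpticsConfig) -> ReachabilityResult:
    """Standard OPTICS ordering; deterministic for a fixed point order
    (priority ties broken by point index)."""
    X = np.asarray(points, dtype=float)
    n = X.shape[0]
    if n < config.min_pts:
        raise InputError(f"n={n} smaller than min_pts={config.min_pts}")
    if not np.isfinite(X).all():
        raise InputError("coordinates must be finite")
    D = cdist(X, X)
    eps = config.eps
    k = config.min_pts

    # core distance: distance to the k-th nearest neighbour incl. self
    part = np.partition(D, k - 1, axis=1)
    core = part[:, k - 1].copy()
    if math.isfinite(eps):
        within = (D <= eps).sum(axis=1)
        core[within < k] = UNDEFINED

    reach = np.full(n, UNDEFINED)
    pred = np.full(n, -1, dtype=int)
    processed = np.zeros(n, dtype=bool)
    order: list[int] = []
    heap: list[tuple[float, int]] = []

    def expand(p: int) -> None:
        if not math.isfinite(core[p]):
            return
        if math.isfinite(eps):
            neigh = np.flatnonzero((D[p] <= eps) & ~processed)
        else:
            neigh = np.flatnonzero(~processed)
        new_reach = np.maximum(core[p], D[p, neigh])
        for o, r in zip(neigh, new_reach):
            if r < reach[o]:
                reach[o] = r
                pred[o] = p
                heapq.heappush(heap, (r, int(o)))

    for start in range(n):
        if processed[start]:
            continue
        processed[start] = True
        order.append(start)
        expand(start)
        while heap:
            r, q = heapq.heappop(heap)
            if processed[q] or r > reach[q]:
                continue
            processed[q] = True
            order.append(q)
            expand(q)
    return ReachabilityResult(
        order=np.array(order, dtype=int),
        core_distance=core,
        reachability=reach,
        labels=None,
        config=config,
        predecessor=pred,
    )


# ---------------------------------------------------------------------------
# extraction


def _cut_labels(result: ReachabilityResult, eps_prime: float) -> np.ndarray:
    n = len(result.order)
    labels = np.full(n, NOISE, dtype=int)
    current = NOISE
    next_label = 0
    for p in result.order:
        r = result.reachability[p]
        if r <= eps_prime:
            if current == NOISE:  # defensive: should follow a cluster start
                current = next_label
                next_label += 1
            labels[p] = current
        elif result.core_distance[p] <= eps_prime:
            current = next_label
            next_label += 1
            labels[p] = current
        else:
            labels[p] = NOISE
            current = NOISE
    return labels


def _extend_area(
    steep: np.ndarray, opposite: np.ndarray, start: int, min_pts: int
) -> int:
    """Maximal xi-steep area from ``start``: may contain at most min_pts
    consecutive non-steep points and no point moving in the opposite
    direction; returns the inclusive end index."""
    n = len(steep)
    end = start
    bad = 0
    j = start
    while j < n:
        if steep[j]:
            end = j
            bad = 0
        elif not opposite[j]:
            bad += 1
            if bad > min_pts:
                break
        else:
            break
        j += 1
    return end


def _trim_predecessor(
    R: np.ndarray, pred_plot: np.ndarray, order: np.ndarray, s: int, e: int
) -> tuple[int | None, int | None]:
    """Shrink the cluster end until its reachability is anchored inside the
    cluster (predecessor correction for spurious boundary points)."""
    while s < e:
        if R[s] > R[e]:
            return s, e
        if pred_plot[e] in order[s:e]:
            return s, e
        e -= 1
    return None, None


def _xi_intervals(
    r: np.ndarray,
    xi: float,
    min_pts: int,
    pred_plot: np.ndarray | None = None,
    order: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """xi-steep up/down cluster extraction over the ordered reachability
    profile (inf marks undefined reachability); returns (start, end)
    intervals in ordering positions, smaller (nested) clusters first."""
    n = len(r)
    R = np.append(r, np.inf)  # sentinel so trailing clusters can close
    ixi = 1.0 - xi
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = R[:-1] / R[1:]
        steep_up = ratio <= ixi
        steep_down = ratio >= 1.0 / ixi
        going_up = ratio < 1.0
        going_down = ratio > 1.0
    # inf/inf transitions are not boundaries
    both_inf = np.isinf(R[:-1]) & np.isinf(R[1:])
    steep_up[both_inf] = False
    steep_down[both_inf] = False

    sdas: list[dict] = []
    clusters: list[tuple[int, int]] = []
    mib = 0.0
    index = 0
    for i in np.flatnonzero(steep_up | steep_down):
        if i < index:
            continue
        mib = max(mib, float(np.max(R[index : i + 1])))
        if math.isinf(mib):
            sdas = []
        else:
            sdas = [d for d in sdas if R[d["start"]] * ixi >= mib]
            for d in sdas:
                d["mib"] = max(d["mib"], mib)
        if steep_down[i]:
            end = _extend_area(steep_down, going_up, i, min_pts)
            sdas.append({"start": int(i), "end": int(end), "mib": 0.0})
            index = end + 1
            mib = float(R[index])
        else:
            u_start, u_end = int(i), _extend_area(steep_up, going_down, i, min_pts)
            index = u_end + 1
            mib = float(R[index])
            found: list[tuple[int, int]] = []
            for d in sdas:
                s, e = d["start"], u_end
                if R[e + 1] * ixi < d["mib"]:  # in-between max too high
                    continue
                d_max = R[d["start"]]
                if d_max * ixi >= R[e + 1]:
                    # left edge higher: move the start right, down to the
                    # level of the cluster end
                    while R[s + 1] > R[e + 1] and s < d["end"]:
                        s += 1
                elif R[e + 1] * ixi >= d_max:
                    # right edge higher: move the end left, down to the
                    # level of the cluster start
                    while R[e - 1] > d_max and e > u_start:
                        e -= 1
                if pred_plot is not None and order is not None:
                    s, e = _trim_predecessor(R, pred_plot, order, s, e)
                    if s is None:
                        continue
                if e - s + 1 < min_pts:
                    continue
                if s > d["end"] or e < u_start:
                    continue
                found.append((int(s), int(e)))
            found.reverse()  # innermost steep-down area first
            clusters.extend(found)
    return clusters


def extract_clusters(
    result: ReachabilityResult, config: OpticsConfig | None = None
) -> np.ndarray:
    """Flat cluster labels from the reachability profile.

    Cut mode walks the ordering with a global threshold; xi mode extracts
    steep-area clusters (nested clusters flattened by letting smaller,
    more specific clusters override containing ones). Clusters smaller
    than min_pts dissolve to noise.
    """
    config = config or result.config
    if config is None:
        raise ConfigurationError("extraction config absent")
    n = len(result.order)
    if config.xi is None:
        # cut mode: exact DBSCAN extraction at eps'; every cluster is
        # seeded by a core point, so its eps'-neighbourhood holds >=
        # min_pts density-reachable points by construction
        if config.cut is not None:
            eps_prime = config.cut
        else:
            finite = result.reachability[np.isfinite(result.reachability)]
            if finite.size == 0:
                return np.full(n, NOISE, dtype=int)
            eps_prime = float(np.quantile(finite, config.cut_quantile))
        labels = _cut_labels(result, eps_prime)
    else:
        r = result.ordered_reachability
        if not np.isfinite(r).any():
            return np.full(n, NOISE, dtype=int)
        pred_plot = (
            result.predecessor[result.order]
            if result.predecessor is not None
            else None
        )
        intervals = _xi_intervals(
            r, config.xi, config.min_pts, pred_plot, result.order
        )
        # flatten the nested hierarchy: each point goes to its smallest
        # enclosing extracted cluster (larger clusters are painted first,
        # nested ones overwrite inside). Near-root intervals spanning most
        # of the ordering describe the whole data set, not a subgroup, and
        # are not painted; undersized clusters were already dropped.
        max_span = int(0.75 * n)
        kept = [iv for iv in intervals if iv[1] - iv[0] + 1 <= max_span]
        plot_labels = np.full(n, NOISE, dtype=int)
        kept.sort(key=lambda iv: iv[1] - iv[0], reverse=True)
        for lab_id, (s, e) in enumerate(kept):
            plot_labels[s : e + 1] = lab_id
        labels = np.full(n, NOISE, dtype=int)
        labels[result.order] = plot_labels
    # relabel compactly in order of first appearance along the ordering
    out = np.full(n, NOISE, dtype=int)
    next_id = 0
    seen: dict[int, int] = {}
    for p in result.order:
        lab = labels[p]
        if lab == NOISE:
            continue
        if lab not in seen:
            seen[lab] = next_id
            next_id += 1
        out[p] = seen[lab]
    return out


def cluster_embedding(points: np.ndarray, config: OpticsConfig) -> ReachabilityResult:
    result = optics_order(points, config)
    result.labels = extract_clusters(result, config)
    return result


# ---------------------------------------------------------------------------
# hyperparameter tuning


def default_grid(n: int | None = None) -> list[OpticsConfig]:
    """Candidate grid searched by the tuner.

    min_pts scales with the set size (about 1-2.5% of n, floored at 5), in
    the same spirit as using ~0.25% of a very large set: a fixed absolute
    min_pts makes no sense across set sizes. Falls back to (5, 10, 15, 25)
    when n is unknown.
    """
    if n is None:
        min_pts_values: tuple[int, ...] = (5, 10, 15, 25)
    else:
        raw = {max(5, int(round(f * n))) for f in (0.010, 0.017, 0.025)}
        min_pts_values = tuple(sorted(raw))
    grid: list[OpticsConfig] = []
    for min_pts in min_pts_values:
        for xi in (0.03, 0.05):
            grid.append(OpticsConfig(min_pts=min_pts, xi=xi))
        for q in (0.65, 0.70, 0.75, 0.85):
            grid.append(OpticsConfig(min_pts=min_pts, xi=None, cut_quantile=q))
    return grid


def tune_hyperparameters(
    train_embeddings: Sequence[np.ndarray],
    grid: Sequence[OpticsConfig] | None = None,
    noise_target: float = 0.25,
    noise_penalty: float = 0.5,
) -> tuple[OpticsConfig, pd.DataFrame]:
    """Score every candidate on every training set and return the argmax.

    Per set the score is the mean silhouette of clustered points minus
    ``noise_penalty`` x |noise fraction - noise_target|; a candidate's
    overall score is the median across sets. Candidates that cluster
    nothing anywhere score -inf. Deterministic; ties keep grid order.
    """
    if grid is None:
        grid = default_grid()
    if len(grid) < 1:
        raise ConfigurationError("empty candidate grid")
    if len(train_embeddings) < 2:
        raise ConfigurationError("tuning requires >= 2 training sets")
    rows = []
    best_idx, best_score = None, -math.inf
    for gi, cand in enumerate(grid):
        set_scores = []
        any_clustered = False
        for si, pts in enumerate(train_embeddings):
            pts = np.asarray(pts, dtype=float)
            try:
                res = cluster_embedding(pts, cand)
            except InputError:
                set_scores.append(-math.inf)
                continue
            labels = res.labels
            clustered = labels != NOISE
            noise_frac = 1.0 - clustered.mean()
            n_clusters = len(np.unique(labels[clustered]))
            if n_clusters == 0:
                set_scores.append(-math.inf)
                continue
            any_clustered = True
            if n_clusters >= 2:
                sil = mean_silhouette(pts[clustered], labels[clustered])
            else:
                sil = 0.0  # a single cluster carries no separation signal
            set_scores.append(sil - noise_penalty * abs(noise_frac - noise_target))
        score = -math.inf if not any_clustered else float(np.median(set_scores))
        rows.append(
            {
                "candidate": cand.describe(),
                "min_pts": cand.min_pts,
                "xi": cand.xi,
                "cut_quantile": cand.cut_quantile,
                "score": score,
                "set_scores": set_scores,
            }
        )
        if score > best_score:
            best_score, best_idx = score, gi
    if best_idx is None or not math.isfinite(best_score):
        raise ConfigurationError("every candidate failed to cluster anything")
    return grid[best_idx], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IO


def write_clustering(
    result: ReachabilityResult,
    patient_ids: Sequence[str],
    outdir: str | Path,
    name: str = "clusters",
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = np.asarray(patient_ids)
    pos = np.arange(len(result.order))
    reach_df = pd.DataFrame(
        {
            "order_position": pos,
            "patient_id": ids[result.order],
            "reachability": result.ordered_reachability,
            "core_distance": result.core_distance[result.order],
        }
    )
    reach_df.to_csv(outdir / f"{name}_reachability.tsv", sep="\t", index=False)
    labels = result.labels
    lab_df = pd.DataFrame(
        {
            "patient_id": ids,
            "cluster": ["noise" if l == NOISE else str(l) for l in labels],
        }
    )
    lab_df.to_csv(outdir / f"{name}_labels.tsv", sep="\t", index=False)
    meta = {"config": asdict(result.config), "noise_fraction": result.noise_fraction()}
    meta["config"]["eps"] = None if math.isinf(result.config.eps) else result.config.eps
    (outdir / f"{name}_meta.json").write_text(json.dumps(meta, indent=1))
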