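"""Population metrics and rank-based treatment comparisons.

The quantities measured here are the ones the study design turns on: what
fraction of the living population has ever executed the programmed-cell-death
instruction, what fraction merely carries it, how many neighbours a
cell-death event touches on each side of the kin boundary, and how many
beneficiaries are "cheaters" (kin with no PCD instruction of their own).
Treatment endpoints are compared with the Mann-Whitney rank-sum test.

Missing values are explicit NaNs, never silent zeros: an empty population or
an event-free window yields NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import UsageError
from .world import PCDEvent, World  # noqa: F401  (PCDEvent re-exported here)

#: Largest per-group size at which the exact enumeration test is used.
EXACT_MAX_N = 8


@dataclass(frozen=True)
class EndpointSummary:
    """Per-replicate endpoint of one treatment run."""

    treatment: str
    replicate: int
    seed: int
    pct_attempting_pcd: float
    carrier_pct: float
    n_events: int
    mean_kin_affected: float
    mean_nonkin_affected: float
    mean_cheater_kin: float
    extinct: bool


# ---------------------------------------------------------------------------
# population-level metrics
# ---------------------------------------------------------------------------

def pct_attempting_pcd(world: World, window: int = 1) -> float:
    """Percentage of living organisms that have ever executed PCD.

    Primary reading of "% of the population performing programmed cell
    death": lifetime-attempt prevalence among the living, averaged over the
    trailing ``window`` sampled updates of the world's time series (per-update
    incidence is emitted alongside in the time series as
    ``pcd_incidence_pct``). With no recorded time series the instantaneous
    prevalence is returned. Empty population -> NaN.
    """
    if window < 1:
        raise UsageError(f"window must be >= 1, got {window}")
    if world.time_series:
        vals = [row["pct_attempting_pcd"] for row in world.time_series[-window:]]
        arr = np.asarray(vals, dtype=float)
        return float(np.nan) if np.all(np.isnan(arr)) else float(np.nanmean(arr))
    if world.population == 0:
        return float("nan")
    return 100.0 * float(np.mean(world.pcd_attempts[world.alive] >= 1))


def carrier_pct(world: World) -> float:
    """Percentage of living organisms whose genome contains a PCD site."""
    if world.population == 0:
        return float("nan")
    from .genome import PCD as _PCD
    return 100.0 * float(np.mean((world.genomes[world.alive] == _PCD).any(axis=1)))


def _window_events(events: Iterable[PCDEvent],
                   window: tuple[int, int] | None) -> list[PCDEvent]:
    if window is None:
        return list(events)
    lo, hi = window
    return [e for e in events if lo <= e.update <= hi]


def mean_affected_per_event(events: Iterable[PCDEvent],
                            window: tuple[int, int] | None = None,
                            side: str = "kin") -> float:
    """Mean number of kin (or nonkin) in the radius per cell-death event.

    ``window`` is an inclusive ``(first_update, last_update)`` interval, or
    None for all events. An empty window returns NaN (a flagged missing
    value), never 0.
    """
    if side not in ("kin", "nonkin"):
        raise UsageError(f"side must be 'kin' or 'nonkin', got {side!r}")
    evs = _window_events(events, window)
    if not evs:
        return float("nan")
    key = "n_kin_affected" if side == "kin" else "n_nonkin_affected"
    return float(np.mean([getattr(e, key) for e in evs]))


def mean_cheater_kin_per_event(events: Iterable[PCDEvent],
                               window: tuple[int, int] | None = None) -> float:
    """Mean number of kin lacking the PCD instruction per event (NaN if none)."""
    evs = _window_events(events, window)
    if not evs:
        return float("nan")
    return float(np.mean([e.n_cheater_kin for e in evs]))


def endpoint_from_timeseries(ts: pd.DataFrame, window: int) -> dict:
    """Trailing-window endpoint values recomputed from a saved time series."""
    tail = ts.tail(window)
    return {
        "pct_attempting_pcd": float(tail["pct_attempting_pcd"].mean()),
        "carrier_pct": float(tail["carrier_pct"].mean()),
    }


# ---------------------------------------------------------------------------
# rank-sum comparisons
# ---------------------------------------------------------------------------

class RankSumResult(NamedTuple):
    statistic: float  # Mann-Whitney U of the first sample
    pvalue: float
    degenerate: bool
    method: str  # "exact" or "asymptotic"


def _u_statistic(xs: np.ndarray, ys: np.ndarray) -> float:
    """U of xs over ys: pairwise wins plus half-credit for ties."""
    u = 0.0
    for x in xs:
        u += float(np.sum(x > ys)) + 0.5 * float(np.sum(x == ys))
    return u


def rank_sum_test(xs: Sequence[float], ys: Sequence[float],
                  alternative: str = "two-sided") -> RankSumResult:
    """Mann-Whitney rank-sum test between two endpoint samples.

    For both sample sizes <= 8 the p-value comes from exact enumeration of
    all label assignments of the pooled values (ties handled by the
    enumeration itself); larger samples use the tie-corrected normal
    approximation. If every value in both samples is identical the comparison
    is degenerate and p = 1 is returned with the flag set.
    ``U_xy + U_yx == n*m`` always holds.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise UsageError(f"unknown alternative {alternative!r}")
    xs = np.asarray(list(xs), dtype=float)
    ys = np.asarray(list(ys), dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise UsageError("both samples must be non-empty")
    n, m = xs.size, ys.size
    u_obs = _u_statistic(xs, ys)
    pooled = np.concatenate([xs, ys])
    if np.all(pooled == pooled[0]):
        return RankSumResult(u_obs, 1.0, True, "degenerate")
    if n <= EXACT_MAX_N and m <= EXACT_MAX_N:
        center = n * m / 2.0
        dev = abs(u_obs - center)
        hits = 0
        total = 0
        eps = 1e-9
        for combo in combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(combo)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if alternative == "two-sided":
                if abs(u - center) >= dev - eps:
                    hits += 1
            elif alternative == "greater":
                if u >= u_obs - eps:
                    hits += 1
            else:
                if u <= u_obs + eps:
                    hits += 1
        return RankSumResult(u_obs, hits / total, False, "exact")
    res = _sps.mannwhitneyu(xs, ys, alternative=alternative, method="asymptotic")
    return RankSumResult(float(res.statistic), float(res.pvalue), False, "asymptotic")


def summarize_grid(endpoints: pd.DataFrame,
                   pairs: Sequence[tuple[str, str]] | None = None,
                   metric: str = "pct_attempting_pcd",
                   alternative: str = "two-sided",
                   out_path=None) -> pd.DataFrame:
    """Pairwise rank-sum comparisons between treatment groups.

    ``endpoints`` is the replicate-level table produced by
    :func:`unicell.experiments.run_grid` (columns ``treatment`` and the chosen
    ``metric``). ``pairs`` lists ``(group_a, group_b)`` treatment names; by
    default every treatment named ``X`` with an ``X-control`` sibling is
    compared against its control. No multiple-testing correction is applied.
    """
    names = set(endpoints["treatment"].unique())
    if pairs is None:
        pairs = [(t, f"{t}-control") for t in sorted(names)
                 if f"{t}-control" in names and not t.endswith("-control")]
    rows = []
    for a, b in pairs:
        for g in (a, b):
            if g not in names:
                raise UsageError(f"pair ({a}, {b}): group {g!r} missing from endpoint table")
        va = endpoints.loc[endpoints["treatment"] == a, metric].to_numpy(dtype=float)
        vb = endpoints.loc[endpoints["treatment"] == b, metric].to_numpy(dtype=float)
        va = va[~np.isnan(va)]
        vb = vb[~np.isnan(vb)]
        res = rank_sum_test(va, vb, alternative=alternative)
        rows.append({
            "pair": f"{a} vs {b}", "group_a": a, "group_b": b,
            "mean_a": float(np.mean(va)), "mean_b": float(np.mean(vb)),
            "U": res.statistic, "p": res.pvalue,
            "n_a": int(va.size), "n_b": int(vb.size),
        })
    table = pd.DataFrame(rows, columns=["pair", "group_a", "group_b", "mean_a",
                                        "mean_b", "U", "p", "n_a", "n_b"])
    if out_path is not None:
        table.to_csv(out_path, index=False)
    return table
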