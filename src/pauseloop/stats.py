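"""Rank-based two-sample comparisons for the experiment's group contrasts.

The headline analysis compares each kinematic metric between the
forward-stimulus and backward-stimulus groups, within each gating condition,
with the Mann-Whitney U test.  At the experiment's sample sizes (n = 15 per
group) an exact test is feasible, so the p-value policy is:

* ``exact``        — full enumeration of all C(n_a + n_b, n_a) label
  assignments when ``n_a + n_b <= 14`` (ties handled via midranks);
* ``permutation``  — seeded Monte-Carlo over label permutations
  (default 100 000) when ``14 < n_a + n_b <= 40`` or ties are present;
* ``normal_approx``— tie-corrected normal approximation with continuity
  correction otherwise.

Two-sided p-values are twice the smaller tail, capped at 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, MissingCellError

__all__ = [
    "GroupComparison",
    "mann_whitney_u",
    "compare_all",
    "DEFAULT_METRICS",
    "write_comparisons",
]

DEFAULT_METRICS = (
    "walking_fraction",
    "mean_pause_duration",
    "total_side_motion",
    "total_distance",
)

_EXACT_MAX = 14
_PERM_MAX = 40
_DEFAULT_N_PERM = 100_000
_EPS = 1e-9


@dataclass(frozen=True)
class GroupComparison:
    """One metric x condition contrast between the two stimulus directions."""

    metric: str
    condition: str
    n_forward: int
    n_backward: int
    U: float
    p_two_sided: float
    method: str  # 'exact' | 'permutation' | 'normal_approx'

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "condition": self.condition,
            "n_fwd": self.n_forward,
            "n_bwd": self.n_backward,
            "U": self.U,
            "p": self.p_two_sided,
            "method": self.method,
        }


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample ``a``: #{a_i > b_j} + 0.5 #{a_i == b_j}."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _u_from_ranksum(rank_sum: float, n_a: int) -> float:
    return rank_sum - n_a * (n_a + 1) / 2.0


def _two_sided(p_le: float, p_ge: float) -> float:
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _exact_p(pooled_ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Exact two-sided p by enumerating every assignment of group labels."""
    n = pooled_ranks.size
    count_le = 0
    count_ge = 0
    total = 0
    for combo in itertools.combinations(range(n), n_a):
        u = _u_from_ranksum(pooled_ranks[list(combo)].sum(), n_a)
        if u <= u_obs + _EPS:
            count_le += 1
        if u >= u_obs - _EPS:
            count_ge += 1
        total += 1
    return _two_sided(count_le / total, count_ge / total)


def _permutation_p(
    pooled_ranks: np.ndarray,
    n_a: int,
    u_obs: float,
    rng: np.random.Generator,
    n_perm: int,
) -> float:
    """Seeded Monte-Carlo permutation p with the add-one correction."""
    n = pooled_ranks.size
    # each row: ranks of a random size-n_a subset, via argsort of uniforms
    order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_a]
    u = _u_from_ranksum(pooled_ranks[order].sum(axis=1), n_a)
    p_le = (1 + np.count_nonzero(u <= u_obs + _EPS)) / (n_perm + 1)
    p_ge = (1 + np.count_nonzero(u >= u_obs - _EPS)) / (n_perm + 1)
    return _two_sided(p_le, p_ge)


def _normal_p(pooled: np.ndarray, n_a: int, n_b: int, u_obs: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    *,
    metric: str = "",
    condition: str = "",
    rng: Optional[np.random.Generator] = None,
    n_perm: int = _DEFAULT_N_PERM,
) -> GroupComparison:
    """Two-sided Mann-Whitney U test of ``a`` (forward) vs ``b`` (backward).

    The reported ``U`` counts pairs where ``a`` exceeds ``b`` (ties count
    half); the p-value method follows the exact/permutation/normal policy
    described in the module docstring and is recorded in the result.
    ``rng`` seeds the Monte-Carlo branch (unseeded default otherwise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    u_obs = _u_statistic(a, b)

    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    has_ties = np.unique(pooled).size < n

    if n <= _EXACT_MAX:
        p = _exact_p(ranks, n_a, u_obs)
        method = "exact"
    elif n <= _PERM_MAX or has_ties:
        if rng is None:
            rng = np.random.default_rng()
        p = _permutation_p(ranks, n_a, u_obs, rng, n_perm)
        method = "permutation"
    else:
        p = _normal_p(pooled, n_a, n_b, u_obs)
        method = "normal_approx"

    return GroupComparison(
        metric=metric,
        condition=condition,
        n_forward=n_a,
        n_backward=n_b,
        U=u_obs,
        p_two_sided=p,
        method=method,
    )


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (optional family-wise correction)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def compare_all(
    trials: pd.DataFrame,
    metrics: Sequence[str] = DEFAULT_METRICS,
    *,
    rng: Optional[np.random.Generator] = None,
    n_perm: int = _DEFAULT_N_PERM,
    holm: bool = False,
) -> pd.DataFrame:
    """Forward-vs-backward contrasts for every metric x condition cell.

    ``trials`` holds one row per subject trial with at least ``condition``,
    ``direction`` and the metric columns.  Raises
    :class:`~pauseloop.errors.MissingCellError` if any condition lacks one of
    the two direction groups.
    """
    required = {"condition", "direction"}
    if not required.issubset(trials.columns):
        raise InsufficientDataError(
            f"trial table needs columns {sorted(required)}"
        )
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    conditions = list(dict.fromkeys(trials["condition"]))
    for metric in metrics:
        for cond in conditions:
            sub = trials[trials["condition"] == cond]
            fwd = sub.loc[sub["direction"] == "FORWARD", metric].to_numpy(float)
            bwd = sub.loc[sub["direction"] == "BACKWARD", metric].to_numpy(float)
            if fwd.size == 0:
                raise MissingCellError(metric, cond, "FORWARD")
            if bwd.size == 0:
                raise MissingCellError(metric, cond, "BACKWARD")
            rows.append(
                mann_whitney_u(
                    fwd,
                    bwd,
                    metric=metric,
                    condition=cond,
                    rng=rng,
                    n_perm=n_perm,
                ).to_dict()
            )
    out = pd.DataFrame(rows)
    if holm:
        out["p_holm"] = holm_adjust(out["p"].to_numpy())
    return out


def write_comparisons(comparisons: pd.DataFrame, path) -> None:
    """CSV writer: metric, condition, n_fwd, n_bwd, U, p, method."""
    comparisons.to_csv(path, index=False)
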