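"""Independent reference implementations used to validate the package.

These deliberately avoid the package's code paths: the transport oracle
solves the optimal-transport linear program directly, the rank-sum oracle
enumerates subsets, and the window-score oracle re-derives the YCAY pattern
rules recursively from the published table.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog


def lp_wasserstein(x, y, p: float = 1.0) -> float:
    """p-Wasserstein distance via the transport LP on the full coupling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    cost = np.abs(x[:, None] - y[None, :]) ** p
    # constraints: row sums = 1/n, column sums = 1/m
    a_eq = []
    b_eq = []
    for i in range(n):
        row = np.zeros((n, m))
        row[i, :] = 1.0
        a_eq.append(row.ravel())
        b_eq.append(1.0 / n)
    for j in range(m):
        col = np.zeros((n, m))
        col[:, j] = 1.0
        a_eq.append(col.ravel())
        b_eq.append(1.0 / m)
    res = linprog(cost.ravel(), A_eq=np.array(a_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    assert res.success
    return float(res.fun) ** (1.0 / p)


def enumerate_ranksum_p(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all C(N, n_x) assignments.

    Uses midranks for ties and the central two-sided rule
    min(1, 2 * min(P(S <= s), P(S >= s))).
    """
    from scipy.stats import rankdata

    x = list(x)
    y = list(y)
    pooled = np.array(x + y, dtype=float)
    ranks = rankdata(pooled)
    n_x = len(x)
    s_obs = ranks[:n_x].sum()
    sums = [sum(combo) for combo in itertools.combinations(ranks, n_x)]
    total = len(sums)
    p_le = sum(1 for s in sums if s <= s_obs + 1e-9) / total
    p_ge = sum(1 for s in sums if s >= s_obs - 1e-9) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def _find_ycay(seq: str) -> list[int]:
    """Greedy non-overlapping YCAY matcher written with explicit char checks."""
    s = seq.upper().replace("T", "U")
    py = {"C", "U"}
    sites = []
    i = 0
    while i + 4 <= len(s):
        if s[i] in py and s[i + 1] == "C" and s[i + 2] == "A" and s[i + 3] in py:
            sites.append(i)
            i += 4
        else:
            i += 1
    return sites


def _score_gaps_recursive(gaps: list[int]) -> int:
    """Recursive statement of the published pattern table.

    A gap >= 7 isolates the current motif (score 0 for it).  With two
    following gaps both <= 6 a triple is scored 8 (both <= 2), 4 (mixed) or,
    for the unpublished (3-6, 3-6) layout, as its leading pair (1).
    Otherwise the leading pair scores 2 (gap <= 2) or 1 (gap 3-6).
    """
    if not gaps:
        return 0
    g1 = gaps[0]
    if g1 >= 7:
        return _score_gaps_recursive(gaps[1:])
    if len(gaps) >= 2 and gaps[1] <= 6:
        g2 = gaps[1]
        if g1 <= 2 and g2 <= 2:
            return 8 + _score_gaps_recursive(gaps[3:])
        if (g1 <= 2) != (g2 <= 2):
            return 4 + _score_gaps_recursive(gaps[3:])
        return 1 + _score_gaps_recursive(gaps[2:])
    pair = 2 if g1 <= 2 else 1
    return pair + _score_gaps_recursive(gaps[2:])


def window_score(seq45: str) -> int:
    """Reference raw window score (45-nt window)."""
    sites = _find_ycay(seq45)
    if len(sites) < 2:
        return 0
    gaps = [sites[k + 1] - sites[k] - 4 for k in range(len(sites) - 1)]
    return _score_gaps_recursive(gaps)


def ks_statistic_on_ranks(n: int, hit_positions: set[int]) -> float:
    """Classic two-sample KS running statistic on a ranked list (signed)."""
    n_hit = len(hit_positions)
    best = 0.0
    running = 0.0
    for i in range(n):
        if i in hit_positions:
            running += 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


def make_window(gaps: tuple[int, ...], motif: str = "UCAU", pad: str = "A", length: int = 45) -> str:
    """Build a window holding one planted YCAY arrangement, padded to length."""
    core = motif + "".join(pad * g + motif for g in gaps)
    if len(core) > length:
        raise ValueError("arrangement does not fit the window")
    return core + pad * (length - len(core))
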