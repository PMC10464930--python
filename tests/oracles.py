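"""Independent brute-force reference implementations used as test oracles.

These deliberately re-derive each quantity from its written definition
with the plainest possible code (loops, BFS, pair counting), sharing no
code path with the package implementation.
"""

from __future__ import annotations

import statistics
from collections import deque

import numpy as np


def dscore_bruteforce(trials, recode=(300.0, 3000.0), drop_above=10_000.0,
                      penalty=600.0) -> float:
    """Improved-algorithm D from a trial frame, written longhand.

    Order: drop latencies above ``drop_above``; replace error latencies by
    their block's mean correct latency + ``penalty``; recode to the bounds;
    pool practice+test per condition; D = (mean life - mean death) /
    inclusive SD of all retained paired-block latencies.
    """
    rows = [
        dict(block=r.block_index, cond=r.condition, lat=float(r.latency_ms),
             ok=bool(r.correct))
        for r in trials.itertuples()
        if r.condition in ("death_congruent", "life_congruent")
    ]
    rows = [r for r in rows if r["lat"] <= drop_above]
    block_means = {}
    for b in {r["block"] for r in rows}:
        good = [r["lat"] for r in rows if r["block"] == b and r["ok"]]
        allv = [r["lat"] for r in rows if r["block"] == b]
        block_means[b] = statistics.fmean(good if good else allv)
    lats = []
    for r in rows:
        lat = r["lat"] if r["ok"] else block_means[r["block"]] + penalty
        if recode is not None:
            lat = min(max(lat, recode[0]), recode[1])
        lats.append((r["cond"], lat))
    death = [v for c, v in lats if c == "death_congruent"]
    life = [v for c, v in lats if c == "life_congruent"]
    pooled = death + life
    sd = statistics.stdev(pooled)
    return (statistics.fmean(life) - statistics.fmean(death)) / sd


def clusters_bruteforce(F, threshold, neighbor_pairs):
    """Connected components of suprathreshold cells by BFS.

    Connectivity: same channel and |dt| = 1, or neighboring channels and
    the same timepoint. Returns a list of (frozenset of cells, mass).
    """
    F = np.asarray(F)
    n_ch, n_t = F.shape
    neigh = {c: set() for c in range(n_ch)}
    for a, b in neighbor_pairs:
        neigh[a].add(b)
        neigh[b].add(a)
    cells = {(c, t) for c in range(n_ch) for t in range(n_t) if F[c, t] > threshold}
    seen = set()
    out = []
    for start in sorted(cells):
        if start in seen:
            continue
        comp = set()
        queue = deque([start])
        seen.add(start)
        while queue:
            c, t = queue.popleft()
            comp.add((c, t))
            candidates = [(c, t - 1), (c, t + 1)] + [(c2, t) for c2 in neigh[c]]
            for cell in candidates:
                if cell in cells and cell not in seen:
                    seen.add(cell)
                    queue.append(cell)
        out.append((frozenset(comp), float(sum(F[c, t] for c, t in comp))))
    return out


def auc_pair_counting(case_scores, control_scores) -> float:
    """AUC as the fraction of concordant case/control pairs (ties = 1/2)."""
    wins = 0.0
    total = 0
    for s in case_scores:
        for c in control_scores:
            total += 1
            if s > c:
                wins += 1.0
            elif s == c:
                wins += 0.5
    return wins / total


def ols_normal_equations(X, y):
    """Betas via the textbook normal equations (X'X)^-1 X'y."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    return np.linalg.solve(X.T @ X, X.T @ y)
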