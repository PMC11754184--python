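"""Independent brute-force reference implementations used only by tests.

Everything here is written straight from the defining formulas with
plain Python loops, deliberately sharing no code with the package, so
agreement between the two routes is meaningful.
"""

from __future__ import annotations

import math

from scipy.stats import chi2, norm


def oracle_hedges_g(case, control):
    n1, n2 = len(case), len(control)
    m1 = sum(case) / n1
    m2 = sum(control) / n2
    ss1 = sum((x - m1) ** 2 for x in case)
    ss2 = sum((x - m2) ** 2 for x in control)
    sp = math.sqrt((ss1 + ss2) / (n1 + n2 - 2))
    j = 1 - 3 / (4 * (n1 + n2 - 2) - 1)
    g = j * (m1 - m2) / sp
    v = (n1 + n2) / (n1 * n2) + g * g / (2 * (n1 + n2))
    p = 2 * norm.sf(abs(g) / math.sqrt(v))
    return g, v, p


def oracle_dersimonian_laird(g, v):
    k = len(g)
    if k == 1:
        return g[0], math.sqrt(v[0]), 0.0, 0.0
    w = [1 / vi for vi in v]
    g_fixed = sum(wi * gi for wi, gi in zip(w, g)) / sum(w)
    q = sum(wi * (gi - g_fixed) ** 2 for wi, gi in zip(w, g))
    c = sum(w) - sum(wi * wi for wi in w) / sum(w)
    tau2 = max(0.0, (q - (k - 1)) / c)
    ws = [1 / (vi + tau2) for vi in v]
    mu = sum(wi * gi for wi, gi in zip(ws, g)) / sum(ws)
    se = 1 / math.sqrt(sum(ws))
    return mu, se, tau2, q


def oracle_fisher(p_values):
    stat = -2 * sum(math.log(max(p, 1e-300)) for p in p_values)
    return stat, chi2.sf(stat, 2 * len(p_values))


def oracle_bh(p_values):
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        val = min(prev, p_values[i] * m / rank)
        q[i] = min(val, 1.0)
        prev = val
    return q


def oracle_auc_pairs(case, control):
    """All-pairs counting AUC with half credit for ties."""
    wins = 0.0
    for x in case:
        for y in control:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (len(case) * len(control))


def oracle_trapezoid(points):
    area = 0.0
    for (x0, y0), (x1, y1) in zip(points[:-1], points[1:]):
        area += (x1 - x0) * (y0 + y1) / 2
    return area


def oracle_delong_variance(case, control):
    """Placement-value DeLong variance computed with explicit loops."""
    n1, n0 = len(case), len(control)
    v10 = []
    for x in case:
        s = sum(1.0 if x > y else (0.5 if x == y else 0.0) for y in control)
        v10.append(s / n0)
    v01 = []
    for y in control:
        s = sum(1.0 if x > y else (0.5 if x == y else 0.0) for x in case)
        v01.append(s / n1)
    auc = sum(v10) / n1
    s10 = sum((v - auc) ** 2 for v in v10) / (n1 - 1)
    s01 = sum((v - auc) ** 2 for v in v01) / (n0 - 1)
    return auc, s10 / n1 + s01 / n0


def _oracle_score(rows, up, down, j):
    """Meta-score of sample j from per-gene value rows (dicts gene -> list)."""
    up_vals = [rows[g][j] for g in up if g in rows]
    down_vals = [rows[g][j] for g in down if g in rows]
    score = 0.0
    if up_vals:
        score += sum(up_vals) / len(up_vals)
    if down_vals:
        score -= sum(down_vals) / len(down_vals)
    return score


def oracle_weighted_auc(cohorts, up, down):
    """cohorts: list of (rows, case_flags) with rows gene -> list of values."""
    num = 0.0
    den = 0
    for rows, case_flags in cohorts:
        n = len(case_flags)
        scores = [_oracle_score(rows, up, down, j) for j in range(n)]
        case = [s for s, f in zip(scores, case_flags) if f]
        control = [s for s, f in zip(scores, case_flags) if not f]
        num += n * oracle_auc_pairs(case, control)
        den += n
    return num / den


def oracle_greedy(cohorts, candidates, forward_threshold=0.0, backward_threshold=0.0):
    """Step-by-step exhaustive greedy search; returns the full trace.

    candidates: list of (gene, direction, effect). Each step evaluates
    every remaining candidate (or removable gene) exhaustively with the
    all-pairs AUC oracle. Tie-break: highest weighted AUC, then largest
    |effect|, then gene symbol.
    """
    up, down = [], []
    remaining = list(candidates)
    effects = {g: e for g, _, e in candidates}
    trace = []
    current = None
    while remaining:
        evals = []
        for gene, direction, effect in remaining:
            t_up = up + [gene] if direction == "up" else up
            t_down = down + [gene] if direction == "down" else down
            evals.append((oracle_weighted_auc(cohorts, t_up, t_down), gene, direction, effect))
        evals.sort(key=lambda t: (-t[0], -abs(t[3]), t[1]))
        wauc, gene, direction, effect = evals[0]
        if current is not None and wauc - current <= forward_threshold:
            break
        (up if direction == "up" else down).append(gene)
        remaining = [c for c in remaining if c[0] != gene]
        current = wauc
        trace.append(("add", gene, wauc))
    while len(up) + len(down) > 1:
        evals = []
        for direction, genes in (("up", up), ("down", down)):
            for gene in genes:
                t_up = [g for g in up if g != gene] if direction == "up" else up
                t_down = [g for g in down if g != gene] if direction == "down" else down
                evals.append((oracle_weighted_auc(cohorts, t_up, t_down), gene, direction))
        # removal ties drop the weakest effect, keeping strong genes
        evals.sort(key=lambda t: (-t[0], abs(effects.get(t[1], 0.0)), t[1]))
        wauc, gene, direction = evals[0]
        if current - wauc > backward_threshold:
            break
        (up if direction == "up" else down).remove(gene)
        current = wauc
        trace.append(("remove", gene, wauc))
    return up, down, trace
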