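"""Independent straight-line reimplementations used as test oracles.

Everything here is deliberately written as plain scalar loops (bisection
instead of Newton, per-feature arithmetic instead of array programs) so that
agreement with the package is evidence of correctness rather than shared
code paths.
"""

from __future__ import annotations

import itertools
import math

from scipy import special, stats


def reference_moderated(values_a, values_b):
    """Loop-based moderated t: returns (t_list, p_list, d0, s0sq).

    values_a/values_b: list (per feature) of lists of observations.
    """
    F = len(values_a)
    n1, n2 = len(values_a[0]), len(values_b[0])
    d = n1 + n2 - 2
    deltas, s2s = [], []
    for i in range(F):
        ma = sum(values_a[i]) / n1
        mb = sum(values_b[i]) / n2
        ss = sum((x - ma) ** 2 for x in values_a[i]) + sum((x - mb) ** 2 for x in values_b[i])
        deltas.append(ma - mb)
        s2s.append(ss / d)

    es = [math.log(v) - special.digamma(d / 2) + math.log(d / 2) for v in s2s if v > 0]
    mean_e = sum(es) / len(es)
    var_e = sum((e - mean_e) ** 2 for e in es) / (len(es) - 1)
    evar = var_e - float(special.polygamma(1, d / 2))
    if evar > 0:
        # geometric bisection of the (monotone decreasing) trigamma function
        lo, hi = 1e-9, 1e9
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if float(special.polygamma(1, mid)) > evar:
                lo = mid
            else:
                hi = mid
        half_d0 = math.sqrt(lo * hi)
        d0 = 2.0 * half_d0
        s0sq = math.exp(mean_e + float(special.digamma(half_d0)) - math.log(half_d0))
    else:
        d0 = math.inf
        s0sq = math.exp(mean_e)

    ts, ps = [], []
    for i in range(F):
        if math.isinf(d0):
            spost = s0sq
        else:
            spost = (d0 * s0sq + d * s2s[i]) / (d0 + d)
        se2 = spost * (1.0 / n1 + 1.0 / n2)
        if se2 > 0:
            t = deltas[i] / math.sqrt(se2)
        else:
            t = 0.0 if deltas[i] == 0 else math.copysign(math.inf, deltas[i])
        if math.isinf(t):
            p = 0.0
        elif math.isinf(d0):
            p = 2.0 * float(stats.norm.sf(abs(t)))
        else:
            p = 2.0 * float(stats.t.sf(abs(t), d + d0))
        ts.append(t)
        ps.append(min(max(p, 0.0), 1.0))
    return ts, ps, d0, s0sq


def exhaustive_sampling_p(values, idx_a, idx_b):
    """Exact pooled permutation p by enumerating every per-column permutation.

    ``values`` is a list of per-feature rows.  Within each group, each sample
    column's values are permuted across features independently; all
    per-feature null p-values over the full product of column permutations
    form the pool.  Returns the list of exact sampling p values.
    """
    F = len(values)
    _, obs_p, _, _ = reference_moderated(
        [[values[i][j] for j in idx_a] for i in range(F)],
        [[values[i][j] for j in idx_b] for i in range(F)],
    )

    perms = list(itertools.permutations(range(F)))
    null_pool = []
    # per-column permutation choices for each group, as a cross product
    per_col_choices = [perms] * (len(idx_a) + len(idx_b))
    for combo in itertools.product(*per_col_choices):
        cols = list(idx_a) + list(idx_b)
        permuted = [[0.0] * len(cols) for _ in range(F)]
        for cpos, (col, perm) in enumerate(zip(cols, combo)):
            for i in range(F):
                permuted[perm[i]][cpos] = values[i][col]
        a = [row[: len(idx_a)] for row in permuted]
        b = [row[len(idx_a):] for row in permuted]
        _, ps, _, _ = reference_moderated(a, b)
        null_pool.extend(ps)

    total = len(null_pool)
    return [sum(1 for q in null_pool if q <= p) / total for p in obs_p], obs_p
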