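"""Numerical core: empirical-Bayes moderated t and pooled permutation p.

The moderated t-statistic replaces each feature's pooled two-sample variance
``s2`` with a posterior value shrunk toward a prior ``s0sq`` estimated across
all features,

    s2_post = (d0 * s0sq + d * s2) / (d0 + d),

where ``d`` is the per-feature residual degrees of freedom and ``d0`` the
prior degrees of freedom.  Under the working model ``s2 ~ s0sq * F(d, d0)``,
so ``log s2`` has closed-form mean and variance in terms of digamma and
trigamma functions; (d0, s0sq) are recovered by method of moments on
``log s2`` (Newton inversion of the trigamma function).  The resulting
t-statistic is referred to a t distribution with ``d + d0`` degrees of
freedom — with 2 replicates per group this roughly triples the effective
degrees of freedom and is what makes the design testable at all.

All kernels accept leading batch dimensions so that thousands of permutation
replicates are processed as one array program.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

__all__ = [
    "trigamma_inverse",
    "fit_variance_prior",
    "moderated_stats",
    "pooled_permutation_p",
]


def trigamma_inverse(y):
    """Solve trigamma(x) = y for x > 0, elementwise (Newton iteration).

    Monotone decreasing map; for very large y the solution approaches 1/sqrt(y)
    and for very small y it approaches 1/y, which seed the iteration bounds.
    """
    y = np.asarray(y, dtype=float)
    out = np.full(y.shape, np.nan)
    small = y < 1e-6
    large = y > 1e7
    out[small] = 1.0 / y[small]
    out[large] = 1.0 / np.sqrt(y[large])
    mid = ~(small | large) & np.isfinite(y)
    if np.any(mid):
        ym = y[mid]
        x = 0.5 + 1.0 / ym
        for _ in range(50):
            tri = special.polygamma(1, x)
            dif = tri * (1.0 - tri / ym) / special.polygamma(2, x)
            x = x + dif
            if np.max(np.abs(dif / x)) < 1e-10:
                break
        out[mid] = x
    return out if out.ndim else float(out)


def fit_variance_prior(s2, d):
    """Method-of-moments fit of (d0, s0sq) from per-feature variances.

    Parameters
    ----------
    s2 : array (..., F)
        Pooled residual variances; zero-variance features are excluded from
        the moment equations (they carry no scale information).
    d : int
        Residual degrees of freedom shared by all features.

    Returns
    -------
    d0, s0sq : arrays with shape (...) — ``d0`` may be ``inf`` when the
        observed spread of ``log s2`` is at or below its sampling floor,
        meaning complete shrinkage to the common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    with np.errstate(divide="ignore"):
        z = np.where(s2 > 0, np.log(np.where(s2 > 0, s2, 1.0)), np.nan)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    n_ok = np.sum(np.isfinite(e), axis=-1)
    n_ok_safe = np.maximum(n_ok, 1)
    mean_e = np.nansum(np.where(np.isfinite(e), e, 0.0), axis=-1) / n_ok_safe
    dev = np.where(np.isfinite(e), e - mean_e[..., None], 0.0)
    denom = np.maximum(n_ok - 1, 1)
    var_e = np.sum(dev * dev, axis=-1) / denom
    evar = var_e - special.polygamma(1, d / 2.0)

    d0 = np.where(evar > 0, 2.0 * trigamma_inverse(np.where(evar > 0, evar, 1.0)), np.inf)
    finite = np.isfinite(d0)
    corr = np.zeros_like(mean_e)
    if np.any(finite):
        half = np.where(finite, d0 / 2.0, 1.0)
        corr = np.where(finite, special.digamma(half) - np.log(half), 0.0)
    with np.errstate(over="ignore"):
        s0sq = np.exp(mean_e + corr)
    s0sq = np.where(n_ok == 0, 0.0, s0sq)
    d0 = np.where(n_ok == 0, np.inf, d0)
    if s2.ndim == 1:
        return float(d0), float(s0sq)
    return d0, s0sq


def moderated_stats(a, b, d0=None, s0sq=None):
    """Two-group moderated-t statistics, vectorized over leading axes.

    Parameters
    ----------
    a, b : arrays (..., F, n1) and (..., F, n2)
        Observations per feature for the case (a) and control (b) group.
    d0, s0sq : optional
        Prior degrees of freedom / prior variance.  When omitted both are
        estimated by :func:`fit_variance_prior`; passing ``d0=0`` yields the
        ordinary pooled-variance Student t.

    Returns
    -------
    dict with per-feature arrays ``delta`` (mean_a - mean_b), ``s2``,
    ``s2_post``, ``t``, ``p`` and scalars/batched ``d``, ``d0``, ``s0sq``,
    ``df_total``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.shape[-1], b.shape[-1]
    d = n1 + n2 - 2
    if d < 1:
        raise ValueError("need at least 2 samples in one group (residual df >= 1)")
    mean_a = a.mean(axis=-1)
    mean_b = b.mean(axis=-1)
    delta = mean_a - mean_b
    ss = np.sum((a - mean_a[..., None]) ** 2, axis=-1) + np.sum(
        (b - mean_b[..., None]) ** 2, axis=-1
    )
    s2 = ss / d

    if d0 is None:
        d0, s0sq_est = fit_variance_prior(s2, d)
        if s0sq is None:
            s0sq = s0sq_est
    elif s0sq is None:
        if np.all(np.asarray(d0) == 0):
            s0sq = np.zeros(np.shape(s2)[:-1]) if s2.ndim > 1 else 0.0
        else:
            raise ValueError("s0sq must be supplied when d0 is forced nonzero")

    d0_arr = np.asarray(d0, dtype=float)[..., None] if np.ndim(d0) else np.asarray(d0, dtype=float)
    s0_arr = np.asarray(s0sq, dtype=float)[..., None] if np.ndim(s0sq) else np.asarray(s0sq, dtype=float)
    with np.errstate(invalid="ignore"):
        s2_post = np.where(
            np.isinf(d0_arr) * np.ones_like(s2, dtype=bool),
            s0_arr * np.ones_like(s2),
            (d0_arr * s0_arr + d * s2) / (d0_arr + d),
        )

    se2 = s2_post * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(se2)
        # 0/0 (no signal, no variance) is a null result; x/0 is infinite evidence
        t = np.where(se2 > 0, t, np.where(delta == 0, 0.0, np.sign(delta) * np.inf))

    df_total = d + np.asarray(d0, dtype=float)
    df_b = np.broadcast_to(
        df_total[..., None] if np.ndim(df_total) else df_total, t.shape
    )
    with np.errstate(invalid="ignore"):
        p = np.where(
            np.isinf(df_b),
            2.0 * stats.norm.sf(np.abs(t)),
            2.0 * stats.t.sf(np.abs(t), np.where(np.isinf(df_b), 1.0, df_b)),
        )
    p = np.where(np.isinf(t), 0.0, p)
    p = np.clip(p, 0.0, 1.0)
    return {
        "mean_a": mean_a,
        "mean_b": mean_b,
        "delta": delta,
        "s2": s2,
        "d": d,
        "d0": d0,
        "s0sq": s0sq,
        "s2_post": s2_post,
        "t": t,
        "df_total": df_total,
        "p": p,
    }


def pooled_permutation_p(
    values,
    idx_a,
    idx_b,
    B: int,
    rng: np.random.Generator,
    smoothing: bool = False,
    chunk: int = 500,
):
    """Permutation "sampling p" with a null pooled across features.

    For each of ``B`` replicates the values are permuted across features
    independently within every sample column of each group — abundance labels
    are broken while per-sample loading effects are preserved — and the full
    moderated-t p-value is recomputed for every feature.  All ``B * F`` null
    p-values form one pool; the sampling p of feature ``f`` is the fraction
    of the pool at or below its observed p-value.  With ``smoothing`` the
    (b+1)/(B+1)-style estimate is returned so that 0 is unattainable.

    Parameters
    ----------
    values : array (F, n)
        Feature x sample matrix (raw Ct or delta-Ct).
    idx_a, idx_b : integer arrays
        Column indices of the case and control samples.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if rng is None:
        raise ValueError("a seeded numpy Generator is required (reproducibility contract)")
    values = np.asarray(values, dtype=float)
    idx_a = np.asarray(idx_a, dtype=int)
    idx_b = np.asarray(idx_b, dtype=int)
    obs_p = moderated_stats(values[:, idx_a], values[:, idx_b])["p"]

    F = values.shape[0]
    counts = np.zeros(F, dtype=np.int64)
    total = 0
    sub_a = values[:, idx_a]
    sub_b = values[:, idx_b]
    done = 0
    while done < B:
        bsz = min(chunk, B - done)
        perm_a = np.broadcast_to(sub_a, (bsz,) + sub_a.shape).copy()
        perm_b = np.broadcast_to(sub_b, (bsz,) + sub_b.shape).copy()
        rng.permuted(perm_a, axis=1, out=perm_a)
        rng.permuted(perm_b, axis=1, out=perm_b)
        null_p = moderated_stats(perm_a, perm_b)["p"]
        pool = np.sort(null_p.ravel())
        counts += np.searchsorted(pool, obs_p, side="right")
        total += pool.size
        done += bsz
    if smoothing:
        return (counts + 1.0) / (total + 1.0)
    return counts / float(total)
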