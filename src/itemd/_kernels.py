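"""Compiled inner-loop kernels for the sift.

The inner sift (extrema detection, mirrored natural-spline envelopes,
envelope-mean subtraction) runs hundreds of times per IMF extraction,
so it is implemented as a single numba kernel.  A pure-numpy fallback
is used when numba is unavailable; both paths implement identical
arithmetic (natural cubic splines through plateau-midpoint extrema,
two extrema mirrored about each signal end).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba present in supported envs
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _extrema_kernel(x):
    """Interior maxima/minima with plateau midpoints (compiled)."""
    n = x.size
    starts = np.empty(n, np.int64)
    m = 1
    starts[0] = 0
    for i in range(1, n):
        if x[i] != x[i - 1]:
            starts[m] = i
            m += 1
    maxl = np.empty(m, np.int64)
    maxv = np.empty(m)
    minl = np.empty(m, np.int64)
    minv = np.empty(m)
    nmax = 0
    nmin = 0
    for j in range(1, m - 1):
        a = x[starts[j - 1]]
        b = x[starts[j]]
        c = x[starts[j + 1]]
        if b > a and b > c:
            maxl[nmax] = (starts[j] + starts[j + 1] - 1) // 2
            maxv[nmax] = b
            nmax += 1
        elif b < a and b < c:
            minl[nmin] = (starts[j] + starts[j + 1] - 1) // 2
            minv[nmin] = b
            nmin += 1
    return maxl[:nmax], maxv[:nmax], minl[:nmin], minv[:nmin]


@njit(cache=True)
def _natural_envelope(locs, vals, n):
    """Natural cubic spline through extrema, two mirrored per edge."""
    m0 = locs.size
    nm = 2 if m0 >= 2 else m0
    total = m0 + 2 * nm
    xs = np.empty(total)
    ys = np.empty(total)
    for k in range(nm):
        xs[k] = -float(locs[nm - 1 - k])
        ys[k] = vals[nm - 1 - k]
    for k in range(m0):
        xs[nm + k] = float(locs[k])
        ys[nm + k] = vals[k]
    for k in range(nm):
        xs[nm + m0 + k] = float(2 * (n - 1) - locs[m0 - 1 - k])
        ys[nm + m0 + k] = vals[m0 - 1 - k]
    # drop coincident knots (mirror of an extremum sitting on the edge)
    fx = np.empty(total)
    fy = np.empty(total)
    c = 0
    for k in range(total):
        if c == 0 or xs[k] > fx[c - 1]:
            fx[c] = xs[k]
            fy[c] = ys[k]
            c += 1
    m = c
    out = np.empty(n)
    if m == 1:
        for t in range(n):
            out[t] = fy[0]
        return out
    if m == 2:
        slope = (fy[1] - fy[0]) / (fx[1] - fx[0])
        for t in range(n):
            out[t] = fy[0] + slope * (t - fx[0])
        return out

    h = np.empty(m - 1)
    for k in range(m - 1):
        h[k] = fx[k + 1] - fx[k]
    # Thomas algorithm for interior second derivatives, natural ends
    M = np.zeros(m)
    cp = np.zeros(m)
    dp = np.zeros(m)
    beta = 2.0 * (h[0] + h[1])
    cp[1] = h[1] / beta
    dp[1] = 6.0 * ((fy[2] - fy[1]) / h[1] - (fy[1] - fy[0]) / h[0]) / beta
    for k in range(2, m - 1):
        rhs = 6.0 * ((fy[k + 1] - fy[k]) / h[k] - (fy[k] - fy[k - 1]) / h[k - 1])
        beta = 2.0 * (h[k - 1] + h[k]) - h[k - 1] * cp[k - 1]
        cp[k] = h[k] / beta
        dp[k] = (rhs - h[k - 1] * dp[k - 1]) / beta
    for k in range(m - 2, 0, -1):
        M[k] = dp[k] - cp[k] * M[k + 1]

    seg = 0
    for t in range(n):
        tf = float(t)
        while seg < m - 2 and fx[seg + 1] < tf:
            seg += 1
        hk = fx[seg + 1] - fx[seg]
        a = (fx[seg + 1] - tf) / hk
        b = (tf - fx[seg]) / hk
        out[t] = (
            a * fy[seg]
            + b * fy[seg + 1]
            + ((a * a * a - a) * M[seg] + (b * b * b - b) * M[seg + 1]) * hk * hk / 6.0
        )
    return out


@njit(cache=True)
def _sift_kernel(x, threshold, max_inner):
    """Inner sift: subtract envelope means until the Cauchy criterion.

    Returns the proto-IMF and the number of completed subtractions
    (0 means the input had too few extrema to sift at all).
    """
    n = x.size
    h = x.copy()
    done = 0
    for _ in range(max_inner):
        maxl, maxv, minl, minv = _extrema_kernel(h)
        if maxl.size < 2 or minl.size < 2:
            return h, done
        upper = _natural_envelope(maxl, maxv, n)
        lower = _natural_envelope(minl, minv, n)
        num = 0.0
        den = 0.0
        for i in range(n):
            mean_i = 0.5 * (upper[i] + lower[i])
            num += mean_i * mean_i
            den += h[i] * h[i]
            h[i] -= mean_i
        done += 1
        sd = num / den if den > 0.0 else 0.0
        if sd < threshold:
            break
    return h, done
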