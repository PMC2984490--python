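"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's own search code: they enumerate every
legal assignment explicitly and evaluate densities through scipy, so that
agreement with the fast implementations is an informative check.
"""
import itertools
import math

import numpy as np
from scipy.stats import multivariate_normal, norm


def gaussian_bruteforce(mu, sd, rho, latencies):
    """Exhaustive argmax of the summed Gaussian prior densities.

    Every (p1, p2, p3) assignment to candidates or the empty designation is
    scored: a candidate scores its prior pdf (0 if below rho), the empty
    designation scores rho; non-empty picks must be strictly increasing.
    Ties prefer earlier latencies (missing sorts last), then fewer missing.
    """
    lat = list(latencies)
    n = len(lat)
    best_key, best = None, None
    for pick in itertools.product(range(-1, n), repeat=3):
        vals = [None if k == -1 else lat[k] for k in pick]
        present = [v for v in vals if v is not None]
        if any(b <= a for a, b in zip(present, present[1:])):
            continue
        J = 0.0
        for i, k in enumerate(pick):
            if k == -1:
                J += rho[i]
            else:
                p = norm.pdf(lat[k], loc=mu[i], scale=sd[i])
                J += p if p >= rho[i] else 0.0
        lex = tuple(math.inf if v is None else v for v in vals)
        key = (-J, lex, sum(v is None for v in vals))
        if best_key is None or key < best_key:
            best_key, best = key, tuple(vals)
    return best


def _mixture_pdf(weights, means, covs, dims, pts):
    pts = np.atleast_2d(pts)
    out = np.zeros(pts.shape[0])
    for w, m, c in zip(weights, means, covs):
        sub_m = np.asarray(m)[list(dims)]
        sub_c = np.asarray(c)[np.ix_(dims, dims)]
        out += w * multivariate_normal.pdf(pts, mean=sub_m, cov=sub_c,
                                           allow_singular=True)
    return out


def gmm_bruteforce(weights, means, covs, tau3, tau2, latencies):
    """Three-stage hierarchical mixture recognition by full enumeration."""
    lat = list(latencies)
    n = len(lat)

    if n >= 3:
        best, best_d = None, -np.inf
        for i, j, k in itertools.combinations(range(n), 3):
            d = _mixture_pdf(weights, means, covs, (0, 1, 2),
                             [[lat[i], lat[j], lat[k]]])[0]
            if d > best_d:
                best, best_d = (lat[i], lat[j], lat[k]), d
        if best_d >= tau3:
            return best

    if n >= 2:
        best, best_d, best_dims = None, -np.inf, None
        for dims in ((0, 1), (0, 2), (1, 2)):
            for i, j in itertools.combinations(range(n), 2):
                d = _mixture_pdf(weights, means, covs, dims,
                                 [[lat[i], lat[j]]])[0]
                if d > best_d:
                    best, best_d, best_dims = (lat[i], lat[j]), d, dims
        if best_d >= tau2:
            out = [None, None, None]
            out[best_dims[0]], out[best_dims[1]] = best
            return tuple(out)

    if n >= 1:
        best_peak, best_j, best_d = None, None, -np.inf
        for peak in range(3):
            for j in range(n):
                d = _mixture_pdf(weights, means, covs, (peak,), [[lat[j]]])[0]
                if d > best_d:
                    best_peak, best_j, best_d = peak, j, d
        out = [None, None, None]
        out[best_peak] = lat[best_j]
        return tuple(out)

    return (None, None, None)


def lexmin_assignment(yhat, latencies, delta):
    """Full one-to-one assignment minimising the sorted distance sequence.

    Enumerates every injective map from peaks to candidates (a peak may also
    stay unassigned, but only when no remaining candidate is within delta);
    among maps that assign the maximum possible number of peaks, the one
    whose sorted distance tuple is lexicographically smallest wins.
    """
    lat = list(latencies)
    n = len(lat)
    best_key, best = None, None
    for pick in itertools.product(range(-1, n), repeat=3):
        used = [k for k in pick if k >= 0]
        if len(used) != len(set(used)):
            continue
        dists = sorted(abs(yhat[i] - lat[k])
                       for i, k in enumerate(pick) if k >= 0)
        if any(d > delta for d in dists):
            continue
        key = (-len(dists), tuple(dists))
        if best_key is None or key < best_key:
            best_key = key
            best = tuple(None if k == -1 else lat[k] for k in pick)
    return best


def recount_confusion(truths, preds):
    """Independent per-peak confusion recount (explicit if-chains)."""
    out = {p: {"TP": 0, "FP": 0, "TN": 0, "FN": 0} for p in ("p1", "p2", "p3")}
    for t, p in zip(truths, preds):
        for i, name in enumerate(("p1", "p2", "p3")):
            y, yhat = t[i], p[i]
            if y is None and yhat is None:
                out[name]["TN"] += 1
            elif y is None:
                out[name]["FP"] += 1
            elif yhat is not None and yhat == y:
                out[name]["TP"] += 1
            else:
                out[name]["FN"] += 1
    return out
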