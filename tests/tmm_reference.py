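"""Brute-force reference implementation of TMM factor estimation.

Deliberately written with plain Python loops and explicit arithmetic,
independent of getmm.normalize, to serve as an oracle: (a) reference
column by upper-quartile closeness, (b) per-gene M/A/variance over genes
positive in both columns, (c) rank-based double trim, (d) precision-
weighted mean of surviving M values, (e) geometric-mean-1 rescaling.
"""

import math


def _quantile_type7(values, p):
    xs = sorted(values)
    h = (len(xs) - 1) * p
    lo = math.floor(h)
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def _average_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _pair_factor(col, lib, ref, lib_ref, logratio_trim, abs_trim, weighted):
    m_vals, a_vals, variances = [], [], []
    for y_k, y_r in zip(col, ref):
        if y_k > 0 and y_r > 0:
            pk, pr = y_k / lib, y_r / lib_ref
            m_vals.append(math.log2(pk / pr))
            a_vals.append(0.5 * math.log2(pk * pr))
            variances.append((lib - y_k) / (lib * y_k) + (lib_ref - y_r) / (lib_ref * y_r))
    n = len(m_vals)
    if n == 0:
        return 1.0
    lo_l = math.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * abs_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = _average_ranks(m_vals)
    rank_a = _average_ranks(a_vals)
    kept = [
        i
        for i in range(n)
        if lo_l <= rank_m[i] <= hi_l and lo_s <= rank_a[i] <= hi_s
    ]
    if not kept or max(abs(m_vals[i]) for i in kept) < 1e-6:
        return 1.0
    if weighted:
        num = sum(m_vals[i] / variances[i] for i in kept)
        den = sum(1.0 / variances[i] for i in kept)
    else:
        num = sum(m_vals[i] for i in kept)
        den = len(kept)
    f = num / den
    if not math.isfinite(f):
        return 1.0
    return 2.0**f


def tmm_factors_bruteforce(
    columns,
    ref_index=None,
    logratio_trim=0.30,
    abs_trim=0.05,
    weighted=True,
):
    """Factors for a list of sample columns (each a list of gene values)."""
    libs = [sum(col) for col in columns]
    if ref_index is None:
        uq = [_quantile_type7(col, 0.75) / lib for col, lib in zip(columns, libs)]
        mean_uq = sum(uq) / len(uq)
        best, ref_index = None, 0
        for i, q in enumerate(uq):
            dist = abs(q - mean_uq)
            if best is None or dist < best:
                best, ref_index = dist, i
    ref, lib_ref = columns[ref_index], libs[ref_index]
    factors = [
        _pair_factor(col, lib, ref, lib_ref, logratio_trim, abs_trim, weighted)
        for col, lib in zip(columns, libs)
    ]
    log_mean = sum(math.log(f) for f in factors) / len(factors)
    return [f / math.exp(log_mean) for f in factors]
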