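"""Independent straight-line reimplementations used as oracles.

These deliberately avoid the package's vectorized code paths: plain Python
loops, sorted-list order statistics, and explicit per-element arithmetic.
"""

import math


def rank_percentile(values, q):
    v = sorted(values)
    idx = min(max(math.ceil(q * len(v)), 1), len(v)) - 1
    return v[idx]


def reactivity_oracle(stops_t, stops_c, bg_c, s=0.25, q_hi=0.95, q_lo=0.05, pseudo=1e-6):
    """Element-by-element reactivity transform on raw counts.

    Returns a list of floats with None for missing bases (zero raw control
    coverage).
    """
    n = len(stops_t)
    f_rt = rank_percentile(stops_t, q_hi)
    f_rc = rank_percentile(stops_c, q_hi)
    f_bc = rank_percentile(bg_c, q_hi)
    r_t = [x / f_rt if f_rt else x for x in stops_t]
    r_c = [x / f_rc if f_rc else x for x in stops_c]
    b_c = [x / f_bc if f_bc else x for x in bg_c]
    es = []
    for i in range(n):
        if bg_c[i] == 0:
            es.append(None)
        else:
            es.append((r_t[i] - s * r_c[i]) / max(b_c[i], pseudo))
    finite = [e for e in es if e is not None]
    lo = rank_percentile(finite, q_lo)
    hi = rank_percentile(finite, q_hi)
    out = []
    for e in es:
        if e is None:
            out.append(None)
        elif hi == lo:
            out.append(0.0)
        else:
            out.append(max(0.0, min(1.0, (e - lo) / (hi - lo))))
    return out


def strucdiff_oracle(es_ref, es_alt):
    """Naive O(N*w) sliding-window mean of absolute differences (width 5).

    None marks missing output (incomplete neighbourhood or a missing input
    base anywhere in it).
    """
    n = len(es_ref)
    out = [None] * n
    for i in range(2, n - 2):
        total = 0.0
        ok = True
        for k in range(i - 2, i + 3):
            a, b = es_ref[k], es_alt[k]
            if a is None or b is None or a != a or b != b:
                ok = False
                break
            total += abs(b - a)
        if ok:
            out[i] = total / 5.0
    return out


def auc_oracle(scores_pos, scores_neg):
    """All-pairs Mann-Whitney AUC with half-credit ties."""
    wins = 0.0
    for p in scores_pos:
        for q in scores_neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(scores_pos) * len(scores_neg))
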