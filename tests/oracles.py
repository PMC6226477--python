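"""Independent brute-force oracles used to freeze expected test values.

These deliberately avoid the implementation's minimal-end dynamic program:
the motif oracle enumerates *every* achievable decomposition end by plain
recursion and applies the leftmost-shortest non-overlap policy on the full
end sets; the regression and t-test oracles are textbook closed forms.
"""

from __future__ import annotations

import math


def _g_run(seq: str, pos: int) -> int:
    m = 0
    while pos + m < len(seq) and seq[pos + m] == "G":
        m += 1
    return m


def _all_ends(seq, pos, tracts_left, g, lmin, lmax, cache):
    """Every end position of ``tracts_left`` tracts starting exactly at pos."""
    key = (pos, tracts_left)
    if key in cache:
        return cache[key]
    out: set[int] = set()
    run = _g_run(seq, pos)
    if run >= g:
        for t in range(g, run + 1):
            if tracts_left == 1:
                out.add(pos + t)
            else:
                for loop in range(lmin, lmax + 1):
                    nxt = pos + t + loop
                    if nxt < len(seq):
                        out |= _all_ends(seq, nxt, tracts_left - 1, g, lmin, lmax, cache)
    cache[key] = out
    return out


def brute_force_hits(sequence: str, g: int, lmin: int, lmax: int, n_tracts: int = 4):
    """Leftmost-shortest non-overlapping (start, end) pairs by full enumeration."""
    seq = sequence.upper().replace("U", "T")
    min_len = n_tracts * g + (n_tracts - 1) * lmin
    cache: dict = {}
    hits = []
    i = 0
    while i <= len(seq) - min_len:
        ends = _all_ends(seq, i, n_tracts, g, lmin, lmax, cache)
        if ends:
            end = min(ends)
            hits.append((i, end))
            i = end
        else:
            i += 1
    return hits


def brute_force_count(sequence: str, g: int, lmin: int, lmax: int, n_tracts: int = 4) -> int:
    return len(brute_force_hits(sequence, g, lmin, lmax, n_tracts))


def ols_oracle(x, y):
    """Closed-form simple OLS: slope, intercept, Pearson r, two-sided slope p."""
    from scipy.stats import t as t_dist

    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    syy = sum((yi - my) ** 2 for yi in y)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    slope = sxy / sxx
    intercept = my - slope * mx
    r = sxy / math.sqrt(sxx * syy)
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = 2 * t_dist.sf(abs(t), n - 2)
    return slope, intercept, r, p


def ttest_oracle(a, b):
    """Textbook two-sample equal-variance t statistic and two-tailed p."""
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * t_dist.sf(abs(t), na + nb - 2)
    return t, p


def random_sequence(rng, length: int, g_fraction: float) -> str:
    """Random test sequence with the requested guanine fraction."""
    rest = (1.0 - g_fraction) / 3.0
    return "".join(
        rng.choice(["A", "C", "G", "T"], size=length, p=[rest, rest, g_fraction, rest])
    )
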