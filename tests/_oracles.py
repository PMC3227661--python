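"""Independent brute-force oracles shared by the unit and acceptance suites.

Each oracle re-derives an expected result with the most literal method
available (position-by-position scans, outward searches, direct finite
summation, naive set algebra) and stays independent of the library code it
checks.
"""

import math

import numpy as np

from tagomics import MLUI_MOTIF, NLAIII_MOTIF, revcomp


def naive_find(seq: str, motif: str) -> list[int]:
    """Quadratic position-by-position motif scan."""
    return [i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif]


def naive_mmsdk(seq: str) -> list[tuple]:
    """Per-MluI-cut outward scan for the nearest NlaIII cut or obstacle.

    Returns (start, end, side, has_internal_nla, tag18|None) per fragment.
    """
    msites = naive_find(seq, MLUI_MOTIF)
    cuts = [s + 1 for s in msites]
    out = []
    for i, cut in enumerate(cuts):
        lo = cuts[i - 1] if i > 0 else 0
        hi = cuts[i + 1] if i + 1 < len(cuts) else len(seq)
        u = None
        for g in range(cut - 4, lo - 1, -1):
            if g >= 0 and seq[g : g + 4] == NLAIII_MOTIF and g >= lo:
                u = g + 4
                break
        if u is not None and u < cut:
            tag = seq[u : u + 18] if cut - u >= 18 else None
            out.append((u, cut, "upstream", True, tag))
        elif u is None and lo < cut:
            out.append((lo, cut, "upstream", False, None))
        d = None
        for g in range(cut, hi - 3):
            if seq[g : g + 4] == NLAIII_MOTIF and g + 4 <= hi and g + 4 > cut:
                d = g + 4
                break
        if d is not None:
            tag = revcomp(seq[d - 4 - 18 : d - 4]) if d - 4 - cut >= 18 else None
            out.append((cut, d, "downstream", True, tag))
        elif cut < hi:
            out.append((cut, hi, "downstream", False, None))
    return out


def ac_oracle(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided conditional Poisson p-value by direct summation (1e-15 tail),
    in the same canonical orientation (condition on the smaller count)."""
    if (y, n2) < (x, n1):
        x, y, n1, n2 = y, x, n2, n1
    r = n2 / n1
    terms = [1.0 / (1 + r) ** (x + 1)]
    k = 0
    while terms[-1] > 1e-18 or k < y + 5:
        terms.append(terms[-1] * r * (x + k + 1) / ((k + 1) * (1 + r)))
        k += 1
        if k > 200_000:  # pragma: no cover
            break
    lower = sum(terms[: y + 1])
    upper = sum(terms[y:])
    return min(1.0, 2.0 * min(lower, upper))


def bh_oracle(p):
    """Textbook step-up: adj_(i) = min_{j>=i}(p_(j) m / j), capped, input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def hypergeom_oracle(N: int, K: int, n: int, k: int) -> float:
    """Right tail of the hypergeometric law by direct finite summation."""
    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
    return min(1.0, total)


def consensus_oracle(pred_sets, exp_sets, min_pred: int = 2) -> set:
    """Naive set algebra: >=min_pred prediction votes, intersected with the
    union of the experimental sets."""
    from collections import Counter

    votes = Counter()
    for s in pred_sets:
        for pair in set(s):
            votes[pair] += 1
    a = {p for p, c in votes.items() if c >= min_pred}
    b = set().union(*[set(s) for s in exp_sets]) if exp_sets else set()
    return a & b
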