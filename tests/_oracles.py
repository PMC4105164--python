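"""Independent brute-force oracles used by the test suite.

These deliberately avoid the seeded/vectorised strategies of the package:
repeats are found by scanning every diagonal window, inverted repeats by an
all-diagonal longest-run scan, and alignment scores by exhaustive recursion
over edit paths.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from plastcomp._dna import revcomp
from plastcomp.alignment import Scoring
from plastcomp.repeats import _allowed, _transform_b


def brute_repeats(seq, min_len=30, max_mismatch=3, max_len=5000, cap=150):
    """Every maximal valid repeat window, by exhaustive diagonal scan."""
    n = len(seq)
    hits = set()
    for rtype in ("direct", "reverse", "palindromic"):
        b = _transform_b(seq, rtype)
        for d in range(-(n - 1), n):
            lo, hi = max(0, d), min(n, n + d)
            if hi - lo < min_len:
                continue
            pos = np.arange(lo, hi)
            mm = np.array(
                [seq[p] != b[p - d] or seq[p] == "N" for p in pos]
            )
            ps = np.concatenate([[0], np.cumsum(mm)])
            m = hi - lo
            for L in range(min_len, min(cap, m) + 1):
                starts = np.arange(0, m - L + 1)
                h = ps[starts + L] - ps[starts]
                ok = h <= _allowed(L, max_mismatch)
                for s0 in starts[ok]:
                    hh = int(h[s0])
                    ext = False
                    if s0 - 1 >= 0:
                        if int(ps[s0 + L] - ps[s0 - 1]) <= _allowed(
                            L + 1, max_mismatch
                        ):
                            ext = True
                    if not ext and s0 + L + 1 <= m:
                        if int(ps[s0 + L + 1] - ps[s0]) <= _allowed(
                            L + 1, max_mismatch
                        ):
                            ext = True
                    if ext or L > max_len:
                        continue
                    p = lo + int(s0)
                    if rtype == "direct":
                        if d == 0:
                            continue
                        p1, p2 = p, p - d
                    else:
                        p1, p2 = p, n - (p - d) - L
                    p1, p2 = min(p1, p2), max(p1, p2)
                    if p2 < p1 + L:
                        continue
                    hits.add((rtype, p1, p2, L, hh))
    final = []
    for h in sorted(hits, key=lambda t: (-t[3], t[1], t[2])):
        t, p1, p2, L, mmc = h
        contained = any(
            k[0] == t and k[1] <= p1 and p1 + L <= k[1] + k[3]
            and k[2] <= p2 and p2 + L <= k[2] + k[3]
            for k in final
        )
        if not contained:
            final.append(h)
    return set(final)


def brute_longest_inverted_pair(seq: str, min_len: int):
    """Longest pair of disjoint exactly reverse-complementary circular
    segments, by scanning every diagonal of the doubled sequence."""
    n = len(seq)
    d2 = seq + seq
    r2 = revcomp(d2)
    best = set()
    best_len = 0
    for diag in range(-2 * n + 1, 2 * n):
        lo, hi = max(0, diag), min(2 * n, 2 * n + diag)
        run = 0
        for p in range(lo, hi):
            if d2[p] == r2[p - diag]:
                run += 1
            else:
                run = 0
                continue
            L = min(run, n)
            if L < min_len:
                continue
            start = p - run + 1 if run <= n else p - n + 1
            i = start % n
            j = (2 * n - (start - diag) - L) % n
            gap1 = (j - (i + L)) % n
            gap2 = (i - (j + L)) % n
            if 2 * L <= n and gap1 + gap2 == n - 2 * L:
                key = tuple(sorted([(i, L), (j, L)]))
                if L > best_len:
                    best, best_len = {key}, L
                elif L == best_len:
                    best.add(key)
    return best_len, best


def brute_align_score(a: str, b: str, sc: Scoring | None = None) -> int:
    """Optimal global affine-gap score by exhaustive recursion (tiny inputs)."""
    sc = sc or Scoring()

    @lru_cache(maxsize=None)
    def f(i: int, j: int, state: int) -> int:
        if i == len(a) and j == len(b):
            return 0
        best = -(10 ** 9)
        if i < len(a) and j < len(b):
            s = sc.match if a[i] == b[j] else sc.mismatch
            best = max(best, s + f(i + 1, j + 1, 0))
        if i < len(a):
            cost = sc.gap_extend if state == 1 else sc.gap_open
            best = max(best, cost + f(i + 1, j, 1))
        if j < len(b):
            cost = sc.gap_extend if state == 2 else sc.gap_open
            best = max(best, cost + f(i, j + 1, 2))
        return best

    return f(0, 0, 0)


def score_alignment_rows(r1: str, r2: str, sc: Scoring | None = None) -> int:
    """Re-score a finished pairwise alignment under the affine model."""
    sc = sc or Scoring()
    s, st = 0, 0
    for c1, c2 in zip(r1, r2):
        if c1 != "-" and c2 != "-":
            s += sc.match if c1 == c2 else sc.mismatch
            st = 0
        elif c2 == "-":
            s += sc.gap_extend if st == 1 else sc.gap_open
            st = 1
        else:
            s += sc.gap_extend if st == 2 else sc.gap_open
            st = 2
    return s


def plant_repeat_pair(rng, n, specs):
    """Random sequence with planted repeat pairs; returns (seq, truth)."""
    s = list(rng.choice(list("ACGT"), n))
    truth = []
    for kind, L, mm in specs:
        x = "".join(rng.choice(list("ACGT"), L))
        if kind == "palindromic":
            y = list(revcomp(x))
        elif kind == "reverse":
            y = list(x[::-1])
        else:
            y = list(x)
        for p in rng.choice(L, size=mm, replace=False):
            y[p] = rng.choice([c for c in "ACGT" if c != y[p]])
        p1 = int(rng.integers(0, n // 2 - L))
        p2 = int(rng.integers(n // 2, n - L))
        s[p1 : p1 + L] = x
        s[p2 : p2 + L] = "".join(y)
        truth.append((kind, p1, p2, L, mm))
    return "".join(s), truth
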