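"""Independent brute-force oracles used by the tests.

Everything here is written with plain Python loops and lists, deliberately
avoiding the numpy code paths of the package, so the two implementations can
only agree by computing the same quantity.
"""
from __future__ import annotations

_ALN = (0, 7, 8)  # M, =, X
_QONLY = (1, 4)  # I, S
_RONLY = (2, 3)  # D, N


def brute_pileup(reads, ref_length):
    """Per-position A/C/G/T counts via pure loops."""
    counts = [[0, 0, 0, 0] for _ in range(ref_length)]
    for r in reads:
        q, p = 0, r.ref_start
        for op, ln in r.cigartuples:
            if op in _ALN:
                for k in range(ln):
                    b = "ACGT".find(r.sequence[q + k])
                    if b >= 0:
                        counts[p + k][b] += 1
                q += ln
                p += ln
            elif op in _QONLY:
                q += ln
            elif op in _RONLY:
                p += ln
    return counts


def brute_site_pi(column):
    depth = sum(column)
    return 1.0 - sum((c / depth) ** 2 for c in column)


def brute_profile(reads, ref, min_cov=5):
    """(pi, anir, mean_depth, breadth, n_sites) via pure loops."""
    counts = brute_pileup(reads, ref.length)
    pis = [brute_site_pi(col) for col in counts if sum(col) >= min_cov]
    pi = sum(pis) / len(pis) if pis else float("nan")
    anir = 100.0 * sum(r.identity for r in reads) / len(reads)
    total = sum(sum(col) for col in counts)
    covered = sum(1 for col in counts if sum(col) > 0)
    return (pi, anir, total / ref.length, 100.0 * covered / ref.length,
            len(pis))


def brute_mismatch_count(a, b):
    """Hamming distance between two equal-length sequences."""
    assert len(a) == len(b)
    return sum(1 for x, y in zip(a, b) if x != y)


def brute_depth_category(depth):
    if depth < 10:
        return "<10X"
    if depth < 50:
        return "10-50X"
    if depth < 200:
        return "50-200X"
    return ">200X"
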