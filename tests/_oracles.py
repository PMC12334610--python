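"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a route disjoint from the package's
implementation: explicit CIGAR expansion, full hypergeometric enumeration,
and unrestricted haplotype enumeration.
"""

from __future__ import annotations

import itertools

from scipy.stats import hypergeom

# BAM op codes: M I D N S H P = X
_CONSUMES_QUERY = {0, 1, 4, 7, 8}
_CONSUMES_REF = {0, 2, 3, 7, 8}
_ALIGNED = {0, 7, 8}


def expand_cigar(
    ref_start: int, cigartuples: list[tuple[int, int]]
) -> dict[int, int | None]:
    """Explicit per-base reference -> query-offset map of an alignment.

    Aligned reference positions map to their query offset; positions under
    a deletion or reference skip map to None. Soft/hard clips and
    insertions consume no reference and never appear as keys.
    """
    mapping: dict[int, int | None] = {}
    ref, query = ref_start, 0
    for op, length in cigartuples:
        for _ in range(length):
            if op in _ALIGNED:
                mapping[ref] = query
                ref += 1
                query += 1
            elif op in _CONSUMES_REF:  # D, N
                mapping[ref] = None
                ref += 1
            elif op in _CONSUMES_QUERY:  # I, S
                query += 1
            # H, P: neither
    return mapping


def introns_by_expansion(
    ref_start: int, cigartuples: list[tuple[int, int]], min_intron: int
) -> list[tuple[int, int]]:
    """Intron intervals recovered from the expanded map: maximal runs of
    reference positions deleted by an N operation."""
    introns = []
    ref = ref_start
    for op, length in cigartuples:
        if op == 3 and length >= min_intron:
            introns.append((ref, ref + length))
        if op in _CONSUMES_REF:
            ref += length
    # cross-check against the expanded map: every intronic position is None
    mapping = expand_cigar(ref_start, cigartuples)
    for s, e in introns:
        assert all(mapping[p] is None for p in range(s, e))
    return introns


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact p by full enumeration of tables at fixed margins.

    Sums hypergeometric point probabilities not exceeding the observed
    table's, with a 1e-9 relative tolerance for algebraic pmf ties.
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    support = range(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    pmf = {k: hypergeom.pmf(k, n, row1, col1) for k in support}
    observed = pmf[a]
    return float(sum(p for p in pmf.values() if p <= observed * (1 + 1e-9)))


def exhaustive_mec_cost(matrix: dict[str, list[int | None]], n_sites: int) -> int:
    """Minimum MEC cost over ALL 2^S haplotype vectors (no label fixing)."""
    best = None
    for hap in itertools.product((0, 1), repeat=n_sites):
        comp = tuple(1 - h for h in hap)
        cost = 0
        for calls in matrix.values():
            d1 = sum(
                1 for c, h in zip(calls, hap) if c is not None and c != h
            )
            d2 = sum(
                1 for c, h in zip(calls, comp) if c is not None and c != h
            )
            cost += min(d1, d2)
        if best is None or cost < best:
            best = cost
    assert best is not None
    return best
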