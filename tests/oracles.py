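"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: per-offset character comparison for scanning, full
outcome enumeration for the binomial tail, and subset enumeration for
cluster calling.  These never share code with the package internals.
"""

from math import comb

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def rc(word: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(word))


def _matches(fragment: str, word: str) -> bool:
    return all(b in "ACGT" and b in IUPAC[c] for b, c in zip(fragment, word))


def _match_mask(fragment: str, word: str) -> list[bool]:
    return [b in "ACGT" and b in IUPAC[c] for b, c in zip(fragment, word)]


def _longest_run(mask: list[bool]) -> int:
    best = run = 0
    for ok in mask:
        run = run + 1 if ok else 0
        best = max(best, run)
    return best


def brute_force_exact(sequence: str, origin: int, motif: str) -> set:
    """All (start, strand) exact matches on both strands, independently per
    strand; palindromes collapse to '+' as the scanner's contract states."""
    L = len(motif)
    rcm = rc(motif)
    hits = set()
    for i in range(len(sequence) - L + 1):
        fragment = sequence[i:i + L]
        if _matches(fragment, motif):
            hits.add((origin + i, "+"))
        if _matches(fragment, rcm):
            if motif == rcm:
                hits.add((origin + i, "+"))
            else:
                hits.add((origin + i, "-"))
    return hits


def brute_force_near(
    sequence: str, origin: int, motif: str, min_consecutive: int | None = None
) -> set:
    """All (start, strand) windows whose match mask to the motif (or its
    reverse complement) carries a run of >= min_consecutive identities but is
    not an exact match."""
    L = len(motif)
    if min_consecutive is None:
        min_consecutive = L - 1
    rcm = rc(motif)
    hits = set()
    for i in range(len(sequence) - L + 1):
        fragment = sequence[i:i + L]
        for word, strand in ((motif, "+"), (rcm, "-")):
            mask = _match_mask(fragment, word)
            if all(mask):
                continue  # exact, not near
            if _longest_run(mask) >= min_consecutive:
                if motif == rcm:
                    hits.add((origin + i, "+"))
                else:
                    hits.add((origin + i, strand))
    return hits


def binomial_upper_tail(observed: int, n: int, p: float) -> float:
    """P[X >= observed] by full enumeration of the n-trial binomial."""
    return sum(
        comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(observed, n + 1)
    )


def brute_force_clusters(
    starts: list[int], window_bp: int, min_sites: int
) -> set[frozenset]:
    """All maximal qualifying subsets of hit start positions, by subset
    enumeration (feasible for small n only)."""
    n = len(starts)
    qualifying = []
    for mask in range(1, 2 ** n):
        subset = [starts[i] for i in range(n) if mask >> i & 1]
        subset.sort()
        if len(subset) < min_sites:
            continue
        if all(b - a <= window_bp for a, b in zip(subset, subset[1:])):
            qualifying.append(frozenset(i for i in range(n) if mask >> i & 1))
    maximal = set()
    for idx in qualifying:
        # maximal: adding any other hit must break the gap rule
        extendable = False
        for other in range(n):
            if other in idx:
                continue
            combined = sorted(starts[i] for i in idx | {other})
            if all(b - a <= window_bp for a, b in zip(combined, combined[1:])):
                extendable = True
                break
        if not extendable:
            maximal.add(frozenset(starts[i] for i in idx))
    return maximal
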