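"""Independent brute-force oracles used by the tests.

These deliberately re-derive results by exhaustive means (full dynamic
programming with complete co-optimal backtracking, naive per-position
scanning) and share no code path with the package implementations they
check, beyond the public left-normalization convention.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Seq import Seq

MATCH = 1.0
MISMATCH = -1.0
GAP_OPEN = -5.0  # cost of the first gapped position
GAP_EXTEND = -1.0

NEG = float("-inf")


def optimal_alignments(ref: str, query: str, cap: int = 500):
    """Enumerate all co-optimal global alignments under affine-gap scoring.

    Returns a list of op lists; ops are ('M', i, j) for an aligned pair,
    ('D', i) for a deleted ref base, ('I', i, j) for query base j inserted
    before ref offset i. Intended for toy sequences (<= ~40 bp).
    """
    n, m = len(ref), len(query)

    @lru_cache(maxsize=None)
    def score(i: int, j: int, state: str) -> float:
        # best score of aligning ref[:i] with query[:j], ending in state
        if i == 0 and j == 0:
            return 0.0 if state == "M" else NEG
        best = NEG
        if state == "M" and i > 0 and j > 0:
            s = MATCH if ref[i - 1] == query[j - 1] else MISMATCH
            best = max(score(i - 1, j - 1, st) for st in "MDI") + s
        elif state == "D" and i > 0:
            best = max(
                score(i - 1, j, "M") + GAP_OPEN,
                score(i - 1, j, "D") + GAP_EXTEND,
                score(i - 1, j, "I") + GAP_OPEN,
            )
        elif state == "I" and j > 0:
            best = max(
                score(i, j - 1, "M") + GAP_OPEN,
                score(i, j - 1, "I") + GAP_EXTEND,
                score(i, j - 1, "D") + GAP_OPEN,
            )
        return best

    final = max(score(n, m, st) for st in "MDI")
    results: list[list[tuple]] = []

    def backtrack(i: int, j: int, state: str, tail: list[tuple]) -> None:
        if len(results) >= cap:
            return
        if i == 0 and j == 0:
            if state == "M":
                results.append(list(reversed(tail)))
            return
        target = score(i, j, state)
        if target == NEG:
            return
        if state == "M" and i > 0 and j > 0:
            s = MATCH if ref[i - 1] == query[j - 1] else MISMATCH
            for prev in "MDI":
                if score(i - 1, j - 1, prev) + s == target:
                    backtrack(i - 1, j - 1, prev, tail + [("M", i - 1, j - 1)])
        elif state == "D" and i > 0:
            for prev, cost in (("M", GAP_OPEN), ("D", GAP_EXTEND), ("I", GAP_OPEN)):
                if score(i - 1, j, prev) + cost == target:
                    backtrack(i - 1, j, prev, tail + [("D", i - 1)])
        elif state == "I" and j > 0:
            for prev, cost in (("M", GAP_OPEN), ("I", GAP_EXTEND), ("D", GAP_OPEN)):
                if score(i, j - 1, prev) + cost == target:
                    backtrack(i, j - 1, prev, tail + [("I", i, j - 1)])

    for st in "MDI":
        if score(n, m, st) == final:
            backtrack(n, m, st, [])
    return results


def raw_diffs_from_ops(ref: str, query: str, ops) -> tuple[tuple, ...]:
    """Convert an op list into left-normalized raw diffs.

    Diffs are ('substitution', offset, ref_base, alt_base),
    ('deletion', offset, deleted_seq) and ('insertion', offset, inserted_seq),
    with indels shifted to their leftmost equivalent reference placement.
    """
    from becall.alleles import left_normalize_deletion, left_normalize_insertion

    diffs: list[tuple] = []
    run_kind = None
    run_start = None
    run_seq = ""

    def flush() -> None:
        nonlocal run_kind, run_start, run_seq
        if run_kind == "D":
            off = left_normalize_deletion(ref, run_start, len(run_seq))
            diffs.append(("deletion", off, ref[off : off + len(run_seq)]))
        elif run_kind == "I":
            off, seq = left_normalize_insertion(ref, run_start, run_seq)
            diffs.append(("insertion", min(off, len(ref) - 1), seq))
        run_kind = run_start = None
        run_seq = ""

    for op in ops:
        if op[0] == "M":
            flush()
            _, i, j = op
            if ref[i] != query[j]:
                diffs.append(("substitution", i, ref[i], query[j]))
        elif op[0] == "D":
            if run_kind != "D":
                flush()
                run_kind, run_start = "D", op[1]
            run_seq += ref[op[1]]
        else:  # I
            if run_kind != "I":
                flush()
                run_kind, run_start = "I", op[1]
            run_seq += query[op[2]]
    flush()
    return tuple(sorted(diffs, key=lambda d: d[1]))


def oracle_diff_sets(ref: str, query: str) -> set[tuple]:
    """Left-normalized diff tuples of every co-optimal alignment."""
    return {raw_diffs_from_ops(ref, query, ops) for ops in optimal_alignments(ref, query)}


def brute_scan(genome: str, spacer: str, max_mm: int = 5, seed_len: int = 10):
    """Naive full-genome guide-site scan on both strands.

    Returns {(start, strand): (mismatches, rule)} where start is the 0-based
    plus-strand coordinate of the leftmost protospacer base.
    """
    L = len(spacer)
    seed = spacer[-seed_len:]
    hits: dict[tuple[int, str], tuple[int, str]] = {}
    for strand in "+-":
        s = genome if strand == "+" else str(Seq(genome).reverse_complement())
        for i in range(len(s) - L - 2):
            pam = s[i + L : i + L + 3]
            if len(pam) < 3 or pam[1:] != "GG":
                continue
            window = s[i : i + L]
            mm = sum(a != b for a, b in zip(window, spacer))
            if mm <= max_mm:
                rule = "full_mismatch_budget"
            elif window[-seed_len:] == seed:
                rule = "seed_10nt"
            else:
                continue
            start = i if strand == "+" else len(s) - i - L
            hits[(start, strand)] = (mm, rule)
    return hits


def chi2_closed_form(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square on a 2x2 table via the textbook closed form."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    return n * (a * d - b * c) ** 2 / denom
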