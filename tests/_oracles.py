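"""Independent brute-force oracles used by the tests.

These deliberately share no code with the package: the Smith-Waterman
oracle is a plain three-state Gotoh dynamic program over explicit Python
loops, and the pangenome oracle enumerates every ordered genome draw.
"""

from itertools import product

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score_oracle(query: str, subject: str, gap_open: int = 11,
                    gap_extend: int = 1) -> float:
    """Optimal local alignment score, affine gaps costing open + k*extend."""
    m, n = len(query), len(subject)
    neg = float("-inf")
    best = 0.0
    # H: best ending in a match/mismatch; E: gap in subject axis; F: in query.
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[neg] * (n + 1) for _ in range(m + 1)]
    F = [[neg] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend,
                          H[i][j - 1] - gap_open - gap_extend)
            F[i][j] = max(F[i - 1][j] - gap_extend,
                          H[i - 1][j] - gap_open - gap_extend)
            sub = _BLOSUM62[query[i - 1], subject[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def enumerate_accumulation_means(cluster_sets: dict[str, set[str]]):
    """Exact per-k mean core/pan sizes over all N^N ordered draws."""
    genomes = sorted(cluster_sets)
    n = len(genomes)
    core_totals = [0.0] * n
    pan_totals = [0.0] * n
    draws = 0
    for order in product(genomes, repeat=n):
        draws += 1
        core, pan = None, set()
        for k, genome in enumerate(order):
            sets = cluster_sets[genome]
            core = set(sets) if core is None else core & sets
            pan = pan | sets
            core_totals[k] += len(core)
            pan_totals[k] += len(pan)
    return ([c / draws for c in core_totals], [p / draws for p in pan_totals])
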