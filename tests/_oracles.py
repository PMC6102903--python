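"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: the Smith–Waterman oracle
is a full-matrix Gotoh DP with traceback, the ORF oracle is a separately
written six-frame scanner built on Biopython translation, and the vote oracle
is an exhaustive tally. They provide the second route of every dual-route
check.
"""

from __future__ import annotations

from Bio.Seq import Seq

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def smith_waterman(a: str, b: str, match: int = 1, mismatch: int = -1,
                   gap_open: int = -5, gap_extend: int = -2):
    """Optimal local alignment score of a vs b (gap of length L costs
    open + (L−1)·extend) plus one optimal path as aligned (i, j) pairs
    (0-based positions into a and b). Full O(nm) Gotoh DP, no heuristics."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    best, best_cell = 0.0, None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = max(H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1])
            H[i][j] = max(0.0, diag + s)
            if H[i][j] > best:
                best, best_cell = H[i][j], (i, j)
    if best_cell is None:
        return 0.0, []
    # traceback through states from the best H cell
    pairs = []
    i, j = best_cell
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] == 0:
                break
            pairs.append((i - 1, j - 1))
            s = match if a[i - 1] == b[j - 1] else mismatch
            prev = H[i][j] - s
            if H[i - 1][j - 1] == prev:
                state = "H"
            elif E[i - 1][j - 1] == prev:
                state = "E"
            else:
                state = "F"
            i, j = i - 1, j - 1
        elif state == "E":
            if E[i][j] == H[i][j - 1] + gap_open:
                state = "H"
            j -= 1
        else:
            if F[i][j] == H[i - 1][j] + gap_open:
                state = "H"
            i -= 1
    pairs.reverse()
    return best, pairs


def path_has_exact_seed(a: str, b: str, pairs, k: int) -> bool:
    """True if the alignment path contains k consecutive diagonal match
    columns — i.e. an exact k-mer shared by a and b lies on the path."""
    run = 0
    prev = None
    for i, j in pairs:
        contiguous = prev is not None and i == prev[0] + 1 and j == prev[1] + 1
        if a[i] == b[j]:
            run = run + 1 if contiguous and run > 0 else 1
        else:
            run = 0
        if run >= k:
            return True
        prev = (i, j)
    return False


START = {"ATG", "GTG", "TTG"}
STOP = {"TAA", "TAG", "TGA"}


def six_frame_orfs_oracle(seq: str, min_len_aa: int = 60):
    """Independent stop-to-stop six-frame ORF scan; returns a set of
    (start, end, strand) tuples in forward-strand 0-based half-open
    coordinates, end inclusive of the stop codon."""
    seq = seq.upper()
    n = len(seq)
    found = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            codons = [s[i:i + 3] for i in range(frame, n - 2, 3)]
            seg_begin = 0  # codon index after previous stop
            for ci, codon in enumerate(codons):
                if codon in STOP:
                    for cj in range(seg_begin, ci):
                        if codons[cj] in START:
                            aa_len = ci - cj  # codons excluding stop
                            if aa_len >= min_len_aa:
                                lo = frame + cj * 3
                                hi = frame + (ci + 1) * 3
                                if strand == "-":
                                    lo, hi = n - hi, n - lo
                                found.add((lo, hi, strand))
                            break
                    seg_begin = ci + 1
    return found


def translate_oracle(nt: str) -> str:
    """Biopython translation (independent of the package's codon table)."""
    return str(Seq(nt).translate())


def majority_vote_oracle(labels, scores):
    """Exhaustive vote tally: winner = most votes, ties by summed score,
    then lexicographic label. ``labels`` may contain None (unclassified)."""
    votes, total = {}, {}
    for lab, sc in zip(labels, scores):
        if lab is None:
            continue
        votes[lab] = votes.get(lab, 0) + 1
        total[lab] = total.get(lab, 0.0) + sc
    if not votes:
        return None, {}
    winner = sorted(votes, key=lambda l: (-votes[l], -total[l], l))[0]
    return winner, votes
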