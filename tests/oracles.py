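"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle re-derives the quantity by naive enumeration, sharing no code
with the implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math

STOPS = {"TAA", "TAG", "TGA"}

_CODE = {}


def _genetic_code():
    # build the standard code from Biopython once, for the NG86 oracles
    global _CODE
    if not _CODE:
        from Bio.Seq import Seq

        for c in ("".join(t) for t in itertools.product("ACGT", repeat=3)):
            _CODE[c] = str(Seq(c).translate())
    return _CODE


# ---------------------------------------------------------------------------
# ORF oracle: naive six-frame stop-split scanner


def orf_scan_bruteforce(contig_id: str, seq: str, min_len_nt: int, require_both_stops: bool = False):
    """Return {(contig, start, end, strand, frame, aa)} of stop-flanked runs."""
    from Bio.Seq import Seq

    out = set()
    L = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else str(Seq(seq).reverse_complement())
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, L - 2, 3)]
            # split the codon string on stop codons, keeping indices
            runs = []
            cur = []
            start_idx = 0
            for idx, c in enumerate(codons):
                if c in STOPS:
                    if cur:
                        runs.append((start_idx, cur))
                    cur = []
                    start_idx = idx + 1
                else:
                    cur.append(c)
            if cur:
                runs.append((start_idx, cur))
            for start_idx, cs in runs:
                if 3 * len(cs) < min_len_nt:
                    continue
                if require_both_stops:
                    left_ok = start_idx > 0 and codons[start_idx - 1] in STOPS
                    right_ok = start_idx + len(cs) < len(codons) and codons[
                        start_idx + len(cs)
                    ] in STOPS
                    if not (left_ok and right_ok):
                        continue
                off_s = frame + 3 * start_idx
                off_e = off_s + 3 * len(cs) - 1
                if strand == "+":
                    g_start, g_end = off_s + 1, off_e + 1
                else:
                    g_start, g_end = L - off_e, L - off_s
                aa = str(Seq("".join(cs)).translate())
                out.add((contig_id, g_start, g_end, strand, frame, aa))
    return out


# ---------------------------------------------------------------------------
# local Viterbi oracle: exhaustive enumeration of all legal state paths


def viterbi_bruteforce(profile, seq: str) -> float:
    """Maximal local alignment score by enumerating every legal state path.

    A path enters at any match state (cost log2(1/M)), moves between
    consecutive match states either directly, via >= 1 insert emissions,
    or via a chain of delete states, and exits from any match state for
    free. Match states emit log-odds bits, inserts emit 0 bits.
    Exponential; only usable for tiny profiles and peptides.
    """
    M = profile.M
    em = profile._em_bits
    t = profile._t_bits
    enc = [profile_aa_index(a) for a in seq]
    L = len(seq)
    entry = -math.log2(M)
    best = -math.inf

    def from_match(i, j, score):
        # in M_j having consumed i residues (seq[i-1] was emitted by M_j)
        nonlocal best
        best = max(best, score)
        if j == M - 1:
            return
        # M_j -> M_{j+1}
        if i < L:
            from_match(i + 1, j + 1, score + t["MM"][j] + em[j + 1, enc[i]])
        # M_j -> I_j (k >= 1 insert emissions) -> M_{j+1}
        for k in range(1, L - i):
            cost = score + t["MI"][j] + (k - 1) * t["II"][j]
            from_match(i + k + 1, j + 1, cost + t["IM"][j] + em[j + 1, enc[i + k]])
        # M_j -> D_{j+1} .. D_{n-1} -> M_n for n >= j+2
        if i < L:
            for n in range(j + 2, M):
                cost = score + t["MD"][j]
                for d in range(j + 1, n - 1):
                    cost += t["DD"][d]
                cost += t["DM"][n - 1]
                from_match(i + 1, n, cost + em[n, enc[i]])

    for i0 in range(L):
        for j0 in range(M):
            from_match(i0 + 1, j0, entry + em[j0, enc[i0]])
    return best


def profile_aa_index(a: str) -> int:
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    return alphabet.index(a) if a in alphabet else 20


# ---------------------------------------------------------------------------
# NG86 oracles: single-mutant and pathway enumeration


def count_sites_bruteforce(codon: str) -> tuple[float, float]:
    code = _genetic_code()
    s = 0.0
    for pos in range(3):
        syn = stops = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOPS:
                stops += 1
            elif code[mut] == code[codon]:
                syn += 1
        if 3 - stops > 0:
            s += syn / (3 - stops)
    return s, 3.0 - s


def count_differences_bruteforce(a: str, b: str) -> tuple[float, float]:
    code = _genetic_code()
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    valid, everything = [], []
    for order in itertools.permutations(diff):
        cur, syn, non, bad = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                bad = True
                non += 1
            elif code[nxt] == code[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        everything.append((syn, non))
        if not bad:
            valid.append((syn, non))
    pool = valid or everything
    return (
        sum(p[0] for p in pool) / len(pool),
        sum(p[1] for p in pool) / len(pool),
    )


# ---------------------------------------------------------------------------
# local alignment oracle: enumerate all affine-gap local alignments


def sw_bruteforce(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> float:
    """Optimal local affine-gap alignment score by exhaustive recursion.

    gap_open is the cost of a gap's first position (BLAST open+extend);
    alignments must start and end with an aligned (match) column.
    """
    best = 0.0

    def go(i, j, state, score):
        nonlocal best
        if state == "M":
            best = max(best, score)
        if i >= len(a) or j >= len(b):
            if state != "M":
                return
        if i < len(a) and j < len(b):
            go(i + 1, j + 1, "M", score + matrix[a[i]][b[j]])
        if i < len(a):
            cost = gap_extend if state == "X" else gap_open
            go(i + 1, j, "X", score - cost)
        if j < len(b):
            cost = gap_extend if state == "Y" else gap_open
            go(i, j + 1, "Y", score - cost)

    for i0 in range(len(a)):
        for j0 in range(len(b)):
            go(i0 + 1, j0 + 1, "M", matrix[a[i0]][b[j0]])
    return best
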