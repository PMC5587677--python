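"""Independent brute-force oracles used only by the tests.

Each function re-derives a quantity from first principles with naive
enumeration, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math
from functools import lru_cache

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_longest_orf(seq: str) -> int:
    """Longest ATG..stop (stop included) or ATG..end ORF over 6 frames, nt."""
    best = 0
    for s in (seq, revcomp(seq)):
        n = len(s)
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, n - 2, 3)]
            for ci, codon in enumerate(codons):
                if codon != "ATG":
                    continue
                length = 0
                for cj in range(ci, len(codons)):
                    c = codons[cj]
                    if "N" in c:
                        length += 3
                        continue
                    length += 3
                    if c in ("TAA", "TAG", "TGA") and cj > ci:
                        break
                else:
                    best = max(best, length)
                    continue
                best = max(best, length)
    return best


def brute_orfs_ge(seq: str, min_nt: int) -> list[int]:
    """Maximal ORF lengths >= min_nt over 6 frames, derived by cutting each
    frame at its stop codons and taking the first ATG of every segment."""
    out = []
    for s in (seq, revcomp(seq)):
        n = len(s)
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, n - 2, 3)]
            segments = []
            current = []
            for c in codons:
                current.append(c)
                if "N" not in c and c in ("TAA", "TAG", "TGA"):
                    segments.append((current, True))
                    current = []
            if current:
                segments.append((current, False))
            for seg, _stopped in segments:
                for k, c in enumerate(seg):
                    if c == "ATG":
                        length = 3 * (len(seg) - k)
                        if length >= min_nt:
                            out.append(length)
                        break
    return out


def smith_waterman(a: str, b: str, match=1, mismatch=-1, gap=-2) -> int:
    """Full DP local-alignment best score, linear gaps."""
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            v = max(0, prev[j - 1] + sub, prev[j] + gap, cur[j - 1] + gap)
            cur[j] = v
            if v > best:
                best = v
        prev = cur
    return best


def binom_exact_two_sided(k: int, n: int, p: float) -> float:
    """Two-sided exact p by direct pmf enumeration with math.comb."""
    pmf = [math.comb(n, x) * p**x * (1 - p) ** (n - x) for x in range(n + 1)]
    obs = pmf[k]
    return sum(q for q in pmf if q <= obs * (1 + 1e-9))


def max_pairs_enumeration(seq: str) -> int:
    """Max base pairs over ALL non-crossing structures (min loop 3) by
    exhaustive recursion; AU/GC/GU pairs, T==U."""
    s = seq.upper().replace("U", "T")
    pairs = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if j - i < 4:
            return 0
        best = rec(i, j - 1)  # j unpaired
        for k in range(i, j - 3):
            if (s[k], s[j]) in pairs:
                best = max(best, rec(i, k - 1) + 1 + rec(k + 1, j - 1) if k > i
                           else 1 + rec(k + 1, j - 1))
        return best

    out = rec(0, len(s) - 1)
    rec.cache_clear()
    return out


def brute_target_expectation(mature_dna: str, target: str,
                             seed=(2, 13), mismatch=1.0, wobble=0.5, bulge=2.0):
    """Best expectation over all windows and single-bulge placements,
    computed with plain loops from the scoring rules."""
    L = len(mature_dna)

    def col_pen(m_base, t_base):
        if _COMP[m_base] == t_base:
            return 0.0
        if (m_base == "G" and t_base == "T") or (m_base == "T" and t_base == "G"):
            return wobble
        return mismatch

    def weight(i):
        return 2.0 if seed[0] <= i <= seed[1] else 1.0

    def score_ungapped(site):
        total = 0.0
        for i in range(1, L + 1):  # miRNA position, 5'->3'
            t_base = site[L - i]
            total += col_pen(mature_dna[i - 1], t_base) * weight(i)
        return total

    def score_target_bulge(site):  # len L+1, one site base unpaired
        best = None
        for g in range(1, L):
            total = bulge * weight(L - g)
            for q in range(L):
                t_base = site[q] if q < g else site[q + 1]
                i = L - q
                total += col_pen(mature_dna[i - 1], t_base) * weight(i)
            if best is None or total < best:
                best = total
        return best

    def score_mirna_bulge(site):  # len L-1, one miRNA base unpaired
        best = None
        for g in range(1, L - 1):
            total = bulge * weight(L - g)
            for q in range(L):
                if q == g:
                    continue
                t_base = site[q] if q < g else site[q - 1]
                i = L - q
                total += col_pen(mature_dna[i - 1], t_base) * weight(i)
            if best is None or total < best:
                best = total
        return best

    best = None
    for w in range(len(target) + 1):
        for sl, fn in ((L, score_ungapped), (L + 1, score_target_bulge),
                       (L - 1, score_mirna_bulge)):
            if w + sl <= len(target):
                sc = fn(target[w : w + sl])
                if sc is not None and (best is None or sc < best):
                    best = sc
    return best


def mimicry_triples_oracle(hits) -> set[tuple[str, str, str]]:
    """Set-intersection reconstruction of mimicry triples from a hit table.

    ``hits`` is an iterable of (mirna, target_id, target_class).
    """
    lnc: dict[str, set[str]] = {}
    mrna: dict[str, set[str]] = {}
    for mir, tid, cls in hits:
        (lnc if cls == "lncRNA" else mrna).setdefault(mir, set()).add(tid)
    triples = set()
    for mir in set(lnc) & set(mrna):
        for l in lnc[mir]:
            for m in mrna[mir]:
                triples.add((l, mir, m))
    return triples


def n50_oracle(lengths) -> int:
    """Sort-based N50: walk from the longest until half the total is covered."""
    ls = sorted(lengths, reverse=True)
    half = sum(ls) / 2
    acc = 0
    for L in ls:
        acc += L
        if acc >= half:
            return L
    raise ValueError("empty")
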