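"""miRNA precursor identification, target prediction and mimicry networks.

Homology-based miRNA discovery in an assembled transcriptome: mature miRNA
matching with up to two substitutions, hairpin validation by base-pair
maximization folding (Nussinov-style dynamic programme with a minimum loop
of 3 and AU/GC/GU pairs), a psRNATarget-like expectation score for
miRNA-target duplexes, and construction of the typed lncRNA-miRNA-mRNA
graph in which lncRNAs sharing a miRNA with mRNA targets are flagged as
candidate target mimics.

The energy proxy is -(3*GC + 2*AU + 1*GU) over the paired bases; the
MFEI-like ratio divides the per-100-nt energy proxy by the window's GC
percentage. Constants are package choices calibrated on the synthetic
generator, not literature thermodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

# Target-scoring scheme (fixed, documented):
MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
BULGE_PENALTY = 2.0
SEED_RANGE = (2, 13)  # miRNA positions (1-based, from the 5' end) with doubled penalties
DEFAULT_EXPECTATION_CUTOFF = 3.0
DEFAULT_MAX_MISMATCH = 2
DEFAULT_FLANK = 200
DEFAULT_MIN_PAIRED_FRACTION = 0.6
# calibrated on the generator's planted hairpins (see docs/methods.md)
DEFAULT_MAX_MFEI = -0.7

_RNA2DNA = str.maketrans("Uu", "TT")


@dataclass(frozen=True)
class MatureMiRNA:
    name: str
    sequence: str  # RNA alphabet
    family: str = ""

    def __post_init__(self):
        if set(self.sequence) - set("ACGU"):
            raise ValueError(f"{self.name}: mature sequence must be RNA (ACGU)")
        if not 18 <= len(self.sequence) <= 24:
            raise ValueError(f"{self.name}: mature length outside 18-24 nt")

    @property
    def dna(self) -> str:
        return self.sequence.translate(_RNA2DNA)


@dataclass(frozen=True)
class MatureHit:
    transcript_id: str
    mature_name: str
    start: int  # 0-based half-open on the transcript sense strand
    end: int
    mismatches: int


@dataclass
class PrecursorCall:
    transcript_id: str
    mature_name: str
    mature_start: int
    mature_end: int
    mismatches: int
    structure: str
    window_start: int
    window_end: int
    mature_paired_fraction: float
    energy_proxy: float
    mfei_proxy: float
    arm: str
    valid: bool
    truncated: bool = False


@dataclass(frozen=True)
class TargetHit:
    mirna_name: str
    target_id: str
    target_class: str  # coding | lncRNA
    expectation: float
    site_start: int
    site_end: int
    inhibition: str  # cleavage | translation


# ---------------------------------------------------------------------------
# Mature matching
# ---------------------------------------------------------------------------

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.array([_ENC.get(b, 4) for b in seq], dtype=np.int8)


def match_mature(
    transcripts: dict[str, str],
    mature_set: dict[str, str],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> list[MatureHit]:
    """All sense-strand windows within Hamming distance ``max_mismatch`` of
    a mature sequence (U and T equivalent; no indels)."""
    hits = []
    enc_matures = {name: _encode(seq) for name, seq in mature_set.items()}
    for tid, seq in transcripts.items():
        enc = _encode(seq)
        for name, m in enc_matures.items():
            L = m.size
            if enc.size < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(enc, L)
            mism = (windows != m[None, :]).sum(axis=1)
            for w in np.flatnonzero(mism <= max_mismatch):
                hits.append(MatureHit(tid, name, int(w), int(w) + L, int(mism[w])))
    return hits


# ---------------------------------------------------------------------------
# Base-pair maximization folding
# ---------------------------------------------------------------------------

MIN_LOOP = 3


@njit(cache=True)
def _nussinov_dp(codes):  # pragma: no cover - exercised via fold_hairpin
    n = codes.size
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]
            if dp[i, j - 1] > best:
                best = dp[i, j - 1]
            a, b = codes[i], codes[j]
            # AU: {0,3}; GC: {1,2}; GU: {2,3}; N (4) never pairs
            pairable = a < 4 and b < 4 and (a + b == 3 or a + b == 5)
            if pairable and dp[i + 1, j - 1] + 1 > best:
                best = dp[i + 1, j - 1] + 1
            for k in range(i + 1, j):
                v = dp[i, k] + dp[k + 1, j]
                if v > best:
                    best = v
            dp[i, j] = best
    return dp


def _pairable(a: int, b: int) -> bool:
    pairs = {(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)}
    return (a, b) in pairs


def fold_hairpin(window_sequence: str) -> tuple[str, int, float]:
    """Fold a window by base-pair maximization.

    Returns (dot-bracket structure, pair count, energy proxy). The
    traceback resolves ties by preferring the pairing that closes the
    outermost ends, then leaving the 5' base unpaired, then the 3' base,
    then the smallest bifurcation point.
    """
    seq = window_sequence.upper().translate(_RNA2DNA)
    n = len(seq)
    if n == 0:
        raise ValueError("empty window")
    codes = _encode(seq)
    dp = _nussinov_dp(codes)
    structure = ["."] * n
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        target = dp[i, j]
        if target == 0:
            continue
        if _pairable(codes[i], codes[j]) and dp[i + 1, j - 1] + 1 == target:
            pairs.append((i, j))
            structure[i], structure[j] = "(", ")"
            stack.append((i + 1, j - 1))
        elif dp[i + 1, j] == target:
            stack.append((i + 1, j))
        elif dp[i, j - 1] == target:
            stack.append((i, j - 1))
        else:
            for k in range(i + 1, j):
                if dp[i, k] + dp[k + 1, j] == target:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    gc = au = gu = 0
    for i, j in pairs:
        a, b = codes[i], codes[j]
        key = (min(a, b), max(a, b))
        if key == (1, 2):
            gc += 1
        elif key == (0, 3):
            au += 1
        else:
            gu += 1
    energy = -(3.0 * gc + 2.0 * au + 1.0 * gu)
    return "".join(structure), len(pairs), energy


def _terminal_loops(structure: str, min_stem: int = 3) -> list[tuple[int, int]]:
    """Half-open spans of hairpin (terminal) loops.

    A terminal loop is the unpaired stretch enclosed by an innermost pair
    whose closing helix stacks at least ``min_stem`` consecutive pairs:
    single-pair closures are artifacts of base-pair maximization, not
    apical loops of a real stem.
    """
    pair_of = {}
    stack = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            pair_of[stack.pop()] = i
    pairs = set(pair_of.items())
    loops = []
    for i, j in pair_of.items():
        if not all(structure[k] == "." for k in range(i + 1, j)):
            continue
        depth = 0
        while (i - depth, j + depth) in pairs:
            depth += 1
        if depth >= min_stem:
            loops.append((i + 1, j))
    return sorted(loops)


def validate_precursor(
    transcript_seq: str,
    hit: MatureHit,
    flank: int = DEFAULT_FLANK,
    min_paired_fraction: float = DEFAULT_MIN_PAIRED_FRACTION,
    max_mfei: float = DEFAULT_MAX_MFEI,
) -> PrecursorCall:
    """Fold mature +- flank and apply the hairpin criteria.

    Valid iff the mature lies entirely on one arm (no mature base inside a
    terminal loop), at least ``min_paired_fraction`` of its bases are
    paired, and the MFEI-like ratio is at most ``max_mfei``. Windows
    truncated by the transcript ends are folded as-is and flagged.
    """
    n = len(transcript_seq)
    ws = max(0, hit.start - flank)
    we = min(n, hit.end + flank)
    if we - ws < 10:
        raise ValueError("precursor window shorter than 10 nt")
    truncated = (hit.start - flank < 0) or (hit.end + flank > n)
    window = transcript_seq[ws:we]
    structure, pair_count, energy = fold_hairpin(window)
    m0, m1 = hit.start - ws, hit.end - ws
    mature_struct = structure[m0:m1]
    paired_frac = sum(ch != "." for ch in mature_struct) / max(m1 - m0, 1)
    loops = _terminal_loops(structure)
    in_loop = any(ls < m1 and m0 < le for ls, le in loops)
    gc_pct = 100.0 * (window.count("G") + window.count("C")) / len(window)
    mfei = (energy / len(window) * 100.0) / gc_pct if gc_pct > 0 else 0.0
    mid = (m0 + m1) / 2
    if loops:
        # nearest terminal loop decides the arm
        loop_mid = min((abs((ls + le) / 2 - mid), (ls + le) / 2) for ls, le in loops)[1]
        arm = "5p" if mid <= loop_mid else "3p"
    else:
        arm = "5p"
    valid = (paired_frac >= min_paired_fraction) and not in_loop and (mfei <= max_mfei)
    return PrecursorCall(
        transcript_id=hit.transcript_id, mature_name=hit.mature_name,
        mature_start=hit.start, mature_end=hit.end, mismatches=hit.mismatches,
        structure=structure, window_start=ws, window_end=we,
        mature_paired_fraction=paired_frac, energy_proxy=energy,
        mfei_proxy=mfei, arm=arm, valid=valid, truncated=truncated,
    )


def find_precursors(
    transcripts: dict[str, str],
    mature_set: dict[str, str],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    flank: int = DEFAULT_FLANK,
    **validate_kwargs,
) -> list[PrecursorCall]:
    """match_mature then validate_precursor; best call per (transcript, mature)."""
    calls: dict[tuple[str, str], PrecursorCall] = {}
    for hit in match_mature(transcripts, mature_set, max_mismatch=max_mismatch):
        call = validate_precursor(transcripts[hit.transcript_id], hit,
                                  flank=flank, **validate_kwargs)
        key = (hit.transcript_id, hit.mature_name)
        prev = calls.get(key)
        rank = (call.valid, call.mature_paired_fraction, -call.mismatches)
        if prev is None or rank > (prev.valid, prev.mature_paired_fraction, -prev.mismatches):
            calls[key] = call
    return list(calls.values())


# ---------------------------------------------------------------------------
# Target prediction (psRNATarget-like expectation scoring)
# ---------------------------------------------------------------------------

def _weight_vector(L: int) -> np.ndarray:
    """Per-miRNA-position penalty multiplier indexed by site offset q,
    where q = L - i for miRNA position i (antiparallel duplex)."""
    w = np.ones(L)
    for q in range(L):
        i = L - q
        if SEED_RANGE[0] <= i <= SEED_RANGE[1]:
            w[q] = 2.0
    return w


def _penalty_lut() -> np.ndarray:
    """pen[mature_base, target_base] in {0, 0.5, 1} (codes A,C,G,T)."""
    comp = {0: 3, 1: 2, 2: 1, 3: 0}
    pen = np.full((4, 4), MISMATCH_PENALTY)
    for m in range(4):
        pen[m, comp[m]] = 0.0
    pen[2, 3] = WOBBLE_PENALTY  # mature G : target T(U)
    pen[3, 2] = WOBBLE_PENALTY  # mature U : target G
    return pen


_PEN = _penalty_lut()


def _bulge_weight(g: int, L: int) -> float:
    """Bulge multiplier: doubled when it interrupts the seed region."""
    i = L - g
    return 2.0 if SEED_RANGE[0] <= i <= SEED_RANGE[1] else 1.0


def score_site(mature_dna: str, site: str) -> float | None:
    """Expectation of one duplex: ungapped if len(site)==L, one target
    bulge if L+1, one miRNA bulge if L-1. None if lengths are impossible."""
    L = len(mature_dna)
    mr = _encode(mature_dna[::-1])
    t = _encode(site)
    if (t >= 4).any() or (mr >= 4).any():
        return None
    w = _weight_vector(L)
    if len(site) == L:
        return float((_PEN[mr, t] * w).sum())
    if len(site) == L + 1:
        best = None
        for g in range(1, L):
            pen = (_PEN[mr[:g], t[:g]] * w[:g]).sum() \
                + BULGE_PENALTY * _bulge_weight(g, L) \
                + (_PEN[mr[g:], t[g + 1:]] * w[g:]).sum()
            if best is None or pen < best:
                best = pen
        return float(best)
    if len(site) == L - 1:
        best = None
        for g in range(1, L - 1):
            pen = (_PEN[mr[:g], t[:g]] * w[:g]).sum() \
                + BULGE_PENALTY * _bulge_weight(g, L) \
                + (_PEN[mr[g + 1:], t[g:]] * w[g + 1:]).sum()
            if best is None or pen < best:
                best = pen
        return float(best)
    return None


def _best_site_for_pair(mr, t, w, L):
    """Vectorized best (expectation, start, end) over all windows and
    single-bulge placements for one mature/target pair."""
    n = t.size
    results = []
    if n >= L:
        win = np.lib.stride_tricks.sliding_window_view(t, L)
        pen = _PEN[mr[None, :], win] * w[None, :]
        scores = pen.sum(axis=1)
        b = int(np.argmin(scores))
        results.append((float(scores[b]), b, b + L))
    if n >= L + 1:
        win = np.lib.stride_tricks.sliding_window_view(t, L + 1)
        pen_l = _PEN[mr[None, :], win[:, :L]] * w[None, :]   # target base q aligned
        pen_r = _PEN[mr[None, :], win[:, 1:]] * w[None, :]   # shifted past the bulge
        cum_l = np.cumsum(pen_l, axis=1)
        tot_r = pen_r.sum(axis=1)
        cum_r = np.cumsum(pen_r, axis=1)
        best = None
        for g in range(1, L):
            s = cum_l[:, g - 1] + BULGE_PENALTY * _bulge_weight(g, L) + (tot_r - cum_r[:, g - 1])
            b = int(np.argmin(s))
            if best is None or s[b] < best[0]:
                best = (float(s[b]), b, b + L + 1)
        results.append(best)
    if n >= L - 1:
        win = np.lib.stride_tricks.sliding_window_view(t, L - 1)
        pen_l = _PEN[mr[:-1][None, :], win] * w[:-1][None, :]
        pen_r = _PEN[mr[1:][None, :], win] * w[1:][None, :]
        cum_l = np.cumsum(pen_l, axis=1)
        tot_r = pen_r.sum(axis=1)
        cum_r = np.cumsum(pen_r, axis=1)
        best = None
        for g in range(1, L - 1):
            s = cum_l[:, g - 1] + BULGE_PENALTY * _bulge_weight(g, L) + (tot_r - cum_r[:, g - 1])
            b = int(np.argmin(s))
            if best is None or s[b] < best[0]:
                best = (float(s[b]), b, b + L - 1)
        results.append(best)
    return min(results) if results else None


def predict_targets(
    mature_set: dict[str, str],
    targets: dict[str, str],
    target_classes: pd.Series | dict | None = None,
    cutoff: float = DEFAULT_EXPECTATION_CUTOFF,
) -> list[TargetHit]:
    """Best target site per (miRNA, transcript) with expectation <= cutoff.

    The expectation sums mismatch (1.0), G:U wobble (0.5) and single-nt
    bulge (2.0) penalties over the duplex, doubled at miRNA positions 2-13;
    at most one bulge (in either strand) is allowed. Inhibition is
    'translation' when a full mismatch sits at miRNA position 10 or 11,
    'cleavage' otherwise.
    """
    target_classes = target_classes if target_classes is not None else {}
    hits = []
    for name, mat in mature_set.items():
        mdna = mat.translate(_RNA2DNA)
        L = len(mdna)
        mr = _encode(mdna[::-1])
        w = _weight_vector(L)
        for tid, tseq in targets.items():
            t = _encode(tseq)
            if (t >= 4).any():
                t = t.copy()
                t[t >= 4] = 0  # N treated as A (scores as mismatch against most bases)
            found = _best_site_for_pair(mr, t, w, L)
            if found is None or found[0] > cutoff:
                continue
            exp, s, e = found
            site = tseq[s:e]
            inhibition = _inhibition(mdna, site)
            cls = target_classes.get(tid, "coding") if hasattr(target_classes, "get") \
                else target_classes[tid]
            hits.append(TargetHit(name, tid, cls, exp, s, e, inhibition))
    return hits


def _inhibition(mature_dna: str, site: str) -> str:
    """Cleavage unless a mismatch falls at miRNA position 10 or 11."""
    L = len(mature_dna)
    mr = _encode(mature_dna[::-1])
    t = _encode(site)
    if len(site) == L:
        offsets = range(L)
        tmap = lambda q: t[q]
    elif len(site) == L + 1:
        # locate the best bulge placement again to know the pairing register
        best_g, best_pen = 1, np.inf
        w = _weight_vector(L)
        for g in range(1, L):
            pen = (_PEN[mr[:g], t[:g]] * w[:g]).sum() \
                + BULGE_PENALTY * _bulge_weight(g, L) \
                + (_PEN[mr[g:], t[g + 1:]] * w[g:]).sum()
            if pen < best_pen:
                best_g, best_pen = g, pen
        offsets = range(L)
        tmap = lambda q: t[q] if q < best_g else t[q + 1]
    elif len(site) == L - 1:
        best_g, best_pen = 1, np.inf
        w = _weight_vector(L)
        for g in range(1, L - 1):
            pen = (_PEN[mr[:g], t[:g]] * w[:g]).sum() \
                + BULGE_PENALTY * _bulge_weight(g, L) \
                + (_PEN[mr[g + 1:], t[g:]] * w[g + 1:]).sum()
            if pen < best_pen:
                best_g, best_pen = g, pen
        offsets = [q for q in range(L) if q != best_g]
        tmap = lambda q: t[q] if q < best_g else t[q - 1]
    else:
        return "cleavage"
    for q in offsets:
        i = L - q  # miRNA position
        if i in (10, 11) and _PEN[mr[q], tmap(q)] == MISMATCH_PENALTY:
            return "translation"
    return "cleavage"


# ---------------------------------------------------------------------------
# Regulatory network
# ---------------------------------------------------------------------------

def build_network(
    target_hits: list[TargetHit],
    precursor_calls: list[PrecursorCall] | None = None,
    de_status: pd.Series | dict | None = None,
):
    """Typed lncRNA-miRNA-mRNA graph with DE coloring and mimicry triples.

    Nodes carry ``kind`` (miRNA/lncRNA/mRNA), ``de_status`` and ``color``
    (red=up, green=down, grey otherwise). Every (lncRNA, miRNA, mRNA)
    triple in which the miRNA targets both partners is a candidate target
    mimic. Returns (graph, mimicry_triples, stress_responsive_pairs).
    """
    import networkx as nx

    if de_status is None:
        de_status = {}
    get_de = de_status.get
    g = nx.DiGraph()

    def color(status):
        return {"up": "red", "down": "green"}.get(status, "grey")

    for hit in target_hits:
        if hit.target_class not in ("coding", "lncRNA"):
            raise ValueError(f"target {hit.target_id}: unknown class {hit.target_class}")
        g.add_node(hit.mirna_name, kind="miRNA", de_status="ns", color="grey")
        kind = "mRNA" if hit.target_class == "coding" else "lncRNA"
        st = get_de(hit.target_id, "ns")
        g.add_node(hit.target_id, kind=kind, de_status=st, color=color(st))
        g.add_edge(hit.mirna_name, hit.target_id,
                   expectation=hit.expectation, inhibition=hit.inhibition)
    for call in precursor_calls or ():
        if call.valid and call.transcript_id in g:
            g.nodes[call.transcript_id]["precursor_of"] = call.mature_name

    triples = []
    for mir in [n for n, d in g.nodes(data=True) if d["kind"] == "miRNA"]:
        lncs = [t for t in g.successors(mir) if g.nodes[t]["kind"] == "lncRNA"]
        mrnas = [t for t in g.successors(mir) if g.nodes[t]["kind"] == "mRNA"]
        for l in lncs:
            for m in mrnas:
                triples.append((l, mir, m))
    pairs = [
        (mir, t)
        for mir, t in g.edges
        if g.nodes[t]["kind"] == "lncRNA" and g.nodes[t]["de_status"] in ("up", "down")
    ]
    return g, triples, pairs


def export_network(g, triples, prefix) -> None:
    """GraphML plus plain edge-list TSV and node-attribute sidecar."""
    import networkx as nx

    nx.write_graphml(g, f"{prefix}.graphml")
    with open(f"{prefix}.edges.tsv", "w") as fh:
        fh.write("source\ttarget\texpectation\tinhibition\n")
        for u, v, d in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['expectation']}\t{d['inhibition']}\n")
    with open(f"{prefix}.nodes.tsv", "w") as fh:
        fh.write("node\tkind\tde_status\tcolor\n")
        for n, d in sorted(g.nodes(data=True)):
            fh.write(f"{n}\t{d['kind']}\t{d['de_status']}\t{d['color']}\n")
    with open(f"{prefix}.mimicry.tsv", "w") as fh:
        fh.write("lncRNA\tmiRNA\tmRNA\n")
        for l, mir, m in sorted(triples):
            fh.write(f"{l}\t{mir}\t{m}\n")


def read_mature_fasta(path) -> dict[str, str]:
    """miRBase-style mature FASTA; T converted to U."""
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper().replace("T", "U")
    return out
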