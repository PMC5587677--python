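"""Coding/lncRNA classification cascade.

Implements the filtering cascade used for lncRNA discovery in de novo
transcriptome assemblies: structural-RNA contaminant exclusion, repeat
masking, the 240-nt functional-ORF rule, an ab initio coding-potential vote
(hexamer bias scorer), homology screening against reference sequence sets,
and the final four-way decision
{contaminant, coding, lncRNA, ambiguous}.

A transcript is called coding only when ORF, ab initio and homology evidence
all agree; it is called lncRNA only when all three are negative and the
transcript is longer than 200 nt. Mixed evidence yields ``ambiguous``.

Coordinates are 0-based half-open throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ._tables import hexamer_table

MIN_LNCRNA_LEN = 200
DEFAULT_MIN_ORF_NT = 240

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Transcript:
    """An assembled transcript with its assembly identifiers."""

    id: str
    sequence: str
    gene_id: str = ""
    isoform_index: int = 1
    samples: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError(f"{self.id}: alphabet outside ACGTN")


@dataclass(frozen=True)
class OrfHit:
    """An open reading frame located on the forward-strand coordinate system.

    ``start``/``end`` are 0-based half-open forward-strand coordinates;
    the stop codon, when present, is included in the span and length.
    """

    strand: str
    frame: int
    start: int
    end: int
    has_start: bool
    has_stop: bool

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    database: str
    percent_identity: float
    alignment_length: int
    raw_score: float
    approx_evalue: float


@dataclass
class EvidenceRecord:
    transcript_id: str
    length: int
    contaminant: bool = False
    contaminant_source: str = ""
    unscreenable: bool = False
    orf_pass: bool | None = None
    abinitio_votes: dict[str, bool] = field(default_factory=dict)
    homology_pass: bool | None = None
    best_hit: HomologyHit | None = None
    final_class: str = ""

    @property
    def abinitio_pass(self) -> bool:
        """Any-one-positive rule over the ab initio predictor panel."""
        return any(self.abinitio_votes.values())


# ---------------------------------------------------------------------------
# Local alignment (shared by contaminant screen, homology search, and the
# cross-genotype comparison in `express`).
# ---------------------------------------------------------------------------

def _nucl_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


def _prot_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


# Karlin-Altschul constants for the advisory E-value, E = K*m*n*exp(-lambda*S).
# Fixed, not fitted; the identity/length thresholds dominate all decisions.
_KA = {"nucl": (0.625, 0.41), "prot": (0.267, 0.041)}  # (lambda, K)


def _best_local(aligner, query: str, subject: str):
    """Best local alignment score plus identity/length of one optimal trace."""
    alignments = aligner.align(query, subject)
    score = alignments.score
    if score <= 0:
        return 0.0, 0.0, 0
    aln = alignments[0]
    counts = aln.counts()
    ncols = counts.identities + counts.mismatches + counts.gaps
    pident = 100.0 * counts.identities / ncols if ncols else 0.0
    return score, pident, ncols


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1) if "N" not in seq[i : i + k]}


def homology_search(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    mode: str = "nucl",
    min_identity: float = 95.0,
    min_length: int = 30,
    max_evalue: float = 1e-5,
    database: str = "db",
    both_strands: bool = True,
    prefilter_k: int | None = None,
) -> dict[str, HomologyHit]:
    """Best passing hit per query under optimal local alignment.

    Scoring is match +1 / mismatch -1 / gap -2 for ``mode='nucl'`` and
    BLOSUM62 with gap open -11 / extend -1 for ``mode='prot'``. The E-value
    is the Karlin-Altschul form with fixed constants and is advisory; the
    identity and length thresholds carry the decisions.

    By default every query/subject pair is aligned exactly (equivalent to
    the full Smith-Waterman matrix). ``prefilter_k`` switches on a
    seed-and-extend shortcut for large sets: only pairs sharing an exact
    k-mer (either strand for nucleotides) are aligned, which cannot create
    spurious hits but may miss weak ones well below the identity cut-offs.
    """
    if mode not in ("nucl", "prot"):
        raise ValueError(f"unknown mode {mode!r}")
    aligner = _nucl_aligner() if mode == "nucl" else _prot_aligner()
    lam, K = _KA[mode]
    total_subject = sum(len(s) for s in subjects.values())

    seed_index: dict[str, set[str]] | None = None
    if prefilter_k:
        seed_index = {}
        for sid, sseq in subjects.items():
            for kmer in _kmer_set(sseq, prefilter_k):
                seed_index.setdefault(kmer, set()).add(sid)

    hits: dict[str, HomologyHit] = {}
    for qid, qseq in queries.items():
        strands = [qseq]
        if mode == "nucl" and both_strands:
            strands.append(reverse_complement(qseq))
        if seed_index is None:
            candidates = set(subjects)
        else:
            candidates = set()
            for qs in strands:
                for kmer in _kmer_set(qs, prefilter_k):
                    candidates |= seed_index.get(kmer, set())
        best = None
        for sid in candidates:
            sseq = subjects[sid]
            if not sseq:
                continue
            for qs in strands:
                score, pident, ncols = _best_local(aligner, qs, sseq)
                if best is None or score > best[0]:
                    best = (score, pident, ncols, sid)
        if best is None:
            continue
        score, pident, ncols, sid = best
        evalue = K * len(qseq) * max(total_subject, 1) * float(np.exp(-lam * score))
        if pident >= min_identity and ncols >= min_length and evalue <= max_evalue:
            hits[qid] = HomologyHit(qid, sid, database, pident, ncols, score, evalue)
    return hits


def screen_contaminants(
    transcripts: Sequence[Transcript],
    contaminant_db: Mapping[str, str],
    min_identity: float = 95.0,
    min_length: int = 30,
    max_evalue: float = 1e-5,
    prefilter_k: int | None = None,
) -> dict[str, EvidenceRecord]:
    """Flag transcripts matching structural-RNA references.

    A transcript is a contaminant iff some local alignment to a database
    sequence reaches ``min_identity`` percent identity over at least
    ``min_length`` columns. Transcripts that are >50% N are marked
    unscreenable rather than contaminant.
    """
    if not contaminant_db:
        raise ValueError("contaminant database is empty")
    records: dict[str, EvidenceRecord] = {}
    screenable = {}
    for t in transcripts:
        rec = EvidenceRecord(t.id, len(t.sequence))
        if t.sequence.count("N") > len(t.sequence) / 2:
            rec.unscreenable = True
        else:
            screenable[t.id] = t.sequence
        records[t.id] = rec
    hits = homology_search(
        screenable, dict(contaminant_db), mode="nucl",
        min_identity=min_identity, min_length=min_length,
        max_evalue=max_evalue, database="contaminant", prefilter_k=prefilter_k,
    )
    for qid, hit in hits.items():
        records[qid].contaminant = True
        records[qid].contaminant_source = hit.subject_id
    return records


# ---------------------------------------------------------------------------
# Repeat masking
# ---------------------------------------------------------------------------

def mask_repeats(
    sequence: str,
    repeat_library: Mapping[str, str],
    k: int = 15,
    min_extend_identity: float = 0.90,
) -> str:
    """Mask library-derived repeats with N.

    Exact k-mer seeds shared with the library (either strand) are extended
    outward while running identity against the library context stays at or
    above ``min_extend_identity``; covered positions become N. Idempotent:
    N never matches a seed.
    """
    if not repeat_library:
        return sequence
    seeds: dict[str, list[tuple[str, int]]] = {}
    lib = {}
    for name, rseq in repeat_library.items():
        for tag, s in ((name, rseq), (name + "/rc", reverse_complement(rseq))):
            lib[tag] = s
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                if "N" not in kmer:
                    seeds.setdefault(kmer, []).append((tag, i))
    n = len(sequence)
    mask = np.zeros(n, dtype=bool)
    for i in range(n - k + 1):
        kmer = sequence[i : i + k]
        if "N" in kmer or kmer not in seeds:
            continue
        for tag, j in seeds[kmer]:
            ref = lib[tag]
            lo_q, lo_r = i, j
            matches, cols = k, k
            while lo_q > 0 and lo_r > 0:
                cols += 1
                matches += sequence[lo_q - 1] == ref[lo_r - 1]
                if matches / cols < min_extend_identity:
                    cols -= 1
                    break
                lo_q -= 1
                lo_r -= 1
            hi_q, hi_r = i + k, j + k
            while hi_q < n and hi_r < len(ref):
                cols += 1
                matches += sequence[hi_q] == ref[hi_r]
                if matches / cols < min_extend_identity:
                    break
                hi_q += 1
                hi_r += 1
            mask[lo_q:hi_q] = True
    if not mask.any():
        return sequence
    out = np.frombuffer(sequence.encode(), dtype="S1").copy()
    out[mask] = b"N"
    return out.tobytes().decode()


# ---------------------------------------------------------------------------
# ORF detection
# ---------------------------------------------------------------------------

def find_orfs(
    sequence: str,
    min_len_nt: int = DEFAULT_MIN_ORF_NT,
    require_start: bool = True,
) -> list[OrfHit]:
    """Scan all six frames for start-to-stop ORFs.

    An ORF runs from ATG to the next in-frame stop (stop included in the
    length) or to the end of the sequence (``has_stop=False``). Only
    maximal ORFs are reported: the first ATG of each stop-to-stop segment
    opens the ORF and nested downstream starts are not re-reported. Codons
    containing N never act as start or stop. Returns every ORF of at least
    ``min_len_nt`` plus the longest ORF overall (so the longest is always
    reported even when nothing reaches the cut-off). ``require_start=False``
    switches to stop-to-stop open segments.
    """
    n = len(sequence)
    hits: list[OrfHit] = []
    longest: OrfHit | None = None

    def emit(strand, frame, s_local, e_local, has_start, has_stop, seqlen):
        nonlocal longest
        if strand == "+":
            start, end = s_local, e_local
        else:  # map local coords on the reverse strand to forward coords
            start, end = seqlen - e_local, seqlen - s_local
        hit = OrfHit(strand, frame, start, end, has_start, has_stop)
        if hit.length_nt >= min_len_nt:
            hits.append(hit)
        if longest is None or hit.length_nt > longest.length_nt:
            longest = hit

    for strand in "+-":
        seq = sequence if strand == "+" else reverse_complement(sequence)
        for frame in range(3):
            orf_start = None
            i = frame
            while i + 3 <= n:
                codon = seq[i : i + 3]
                if "N" in codon:
                    i += 3
                    continue
                is_stop = codon in ("TAA", "TAG", "TGA")
                if orf_start is None:
                    if (codon == "ATG") if require_start else (not is_stop):
                        orf_start = i
                        if is_stop:  # unreachable for require_start
                            orf_start = None
                elif is_stop:
                    emit(strand, frame, orf_start, i + 3, require_start, True, n)
                    orf_start = None
                i += 3
            if orf_start is not None:
                end = orf_start + 3 * ((n - orf_start) // 3)
                emit(strand, frame, orf_start, end, require_start, False, n)

    if longest is not None and longest.length_nt < min_len_nt:
        hits.append(longest)
    hits.sort(key=lambda h: (-h.length_nt, h.start, h.strand))
    return hits


def longest_orf(sequence: str, require_start: bool = True) -> OrfHit | None:
    hits = find_orfs(sequence, min_len_nt=0, require_start=require_start)
    return hits[0] if hits else None


def orf_sequence(sequence: str, orf: OrfHit) -> str:
    """The ORF's nucleotides in reading orientation (5'->3' of its strand)."""
    sub = sequence[orf.start : orf.end]
    return sub if orf.strand == "+" else reverse_complement(sub)


# ---------------------------------------------------------------------------
# Ab initio coding potential (hexamer-bias scorer)
# ---------------------------------------------------------------------------

_B2I = {"A": 0, "C": 1, "G": 2, "T": 3}


def _hexamer_codes(seq: str, step: int = 3) -> np.ndarray:
    codes = []
    for i in range(0, len(seq) - 5, step):
        h = seq[i : i + 6]
        code = 0
        ok = True
        for b in h:
            v = _B2I.get(b)
            if v is None:
                ok = False
                break
            code = code * 4 + v
        if ok:
            codes.append(code)
    return np.asarray(codes, dtype=np.intp)


def coding_potential_score(
    sequence: str,
    table: np.ndarray | None = None,
    coverage_weight: float = 0.2,
) -> tuple[float, bool]:
    """Hexamer-bias coding potential over the longest ORF.

    The score is the mean in-frame hexamer log-likelihood ratio (coding
    codon-pair model vs uniform background) over the longest ORF, taking
    the better of the two strands, plus ``coverage_weight`` times the
    fraction of the transcript covered by that ORF. Vote is ``score > 0``.
    Sequences shorter than 6 nt, or with no ORF, score 0 / False.
    """
    if table is None:
        table = hexamer_table()
    if len(sequence) < 6:
        return 0.0, False
    if not np.any(table):
        return 0.0, False
    orf = longest_orf(sequence)  # six-frame scan, so both strands are covered
    if orf is None:
        return 0.0, False
    orf_seq = orf_sequence(sequence, orf)
    if orf.has_stop:
        orf_seq = orf_seq[:-3]  # score sense codons only
    codes = _hexamer_codes(orf_seq, step=3)
    if codes.size == 0:
        return 0.0, False
    mean_llr = float(table[codes].mean())
    score = mean_llr + coverage_weight * orf.length_nt / len(sequence)
    return score, score > 0


# ---------------------------------------------------------------------------
# Final decision
# ---------------------------------------------------------------------------

def decide_class(record: EvidenceRecord) -> str:
    """Four-way decision from the evidence flags.

    contaminant if flagged; coding iff ORF, ab initio and homology all
    positive; lncRNA iff all three negative and length > 200 nt; anything
    else is ambiguous.
    """
    if record.contaminant:
        return "contaminant"
    for name, val in (("orf_pass", record.orf_pass), ("homology_pass", record.homology_pass)):
        if val is None:
            raise ValueError(f"{record.transcript_id}: missing evidence field {name}")
    if not record.abinitio_votes:
        raise ValueError(f"{record.transcript_id}: missing evidence field abinitio_votes")
    orf, ab, hom = record.orf_pass, record.abinitio_pass, record.homology_pass
    if orf and ab and hom:
        return "coding"
    if not orf and not ab and not hom and record.length > MIN_LNCRNA_LEN:
        return "lncRNA"
    return "ambiguous"


def classify_transcripts(
    transcripts: Sequence[Transcript],
    contaminant_db: Mapping[str, str],
    protein_db: Mapping[str, str],
    repeat_library: Mapping[str, str] | None = None,
    hexamer: np.ndarray | None = None,
    min_orf_nt: int = DEFAULT_MIN_ORF_NT,
    contaminant_min_identity: float = 95.0,
    contaminant_min_length: int = 30,
    protein_min_identity: float = 80.0,
    protein_min_length: int = 30,
    max_evalue: float = 1e-5,
    extra_scorers: Iterable | None = None,
    contaminant_prefilter_k: int | None = 12,
    protein_prefilter_k: int | None = 6,
) -> dict[str, EvidenceRecord]:
    """Run the full cascade and fill in ``final_class`` for every transcript.

    The ab initio panel is the bundled hexamer scorer plus any
    ``extra_scorers`` (callables sequence -> (score, vote)); the panel
    passes when at least one member votes coding. The homology criterion is
    a protein-level screen of the translated longest ORF.
    """
    if hexamer is None:
        hexamer = hexamer_table()
    records = screen_contaminants(
        transcripts, contaminant_db,
        min_identity=contaminant_min_identity, min_length=contaminant_min_length,
        max_evalue=max_evalue, prefilter_k=contaminant_prefilter_k,
    )
    repeat_library = repeat_library or {}
    peptides: dict[str, str] = {}
    for t in transcripts:
        rec = records[t.id]
        if rec.contaminant:
            rec.final_class = "contaminant"
            continue
        masked = mask_repeats(t.sequence, repeat_library)
        orfs = find_orfs(masked, min_len_nt=min_orf_nt)
        rec.orf_pass = any(o.length_nt >= min_orf_nt for o in orfs)
        score, vote = coding_potential_score(masked, hexamer)
        rec.abinitio_votes["hexamer"] = vote
        for scorer in extra_scorers or ():
            rec.abinitio_votes[getattr(scorer, "__name__", "extra")] = scorer(masked)[1]
        orf = longest_orf(masked)
        if orf is not None and orf.length_nt >= 30:
            pep = str(Seq(orf_sequence(masked, orf)).translate()).rstrip("*")
            if pep and "*" not in pep:
                peptides[t.id] = pep
    hits = homology_search(
        peptides, dict(protein_db), mode="prot",
        min_identity=protein_min_identity, min_length=protein_min_length,
        max_evalue=max_evalue, database="protein", prefilter_k=protein_prefilter_k,
    )
    for t in transcripts:
        rec = records[t.id]
        if rec.final_class == "contaminant":
            continue
        rec.homology_pass = t.id in hits
        rec.best_hit = hits.get(t.id)
        rec.final_class = decide_class(rec)
    return records
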