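"""Seeded synthetic benchmark generator.

Emulates the inputs of a de novo wheat root transcriptome study so every
downstream stage (classification cascade, differential expression, miRNA
network, splicing) can be verified against planted ground truth without any
external download:

* coding transcripts carrying one long start-to-stop ORF written with a
  GC-biased codon model (wheat-like wobble-position bias);
* lncRNAs of 201-~2,900 nt with GC held near 44% and no ORF reaching the
  240-nt coding cut-off on either strand;
* contaminants as high-identity mutated copies of bundled synthetic
  rRNA/tRNA-like fixtures;
* two-condition negative-binomial count matrices with symmetric planted
  fold changes;
* miRNA precursor hairpins (mature arm with 0-2 substitutions opposite a
  near-reverse-complement arm) planted into lncRNAs;
* a toy A/B sub-genome with paired isoforms realizing planted
  alternative-splicing events.

Randomness uses one seed per run; each generation stage draws from its own
child stream (``default_rng([seed, stage])``, stages numbered in the order
the functions appear below) so enlarging one transcript class never
reshuffles another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify as _cls
from ._tables import CONTAMINANT_FIXTURES, codon_weights, SENSE_CODONS
from .classify import Transcript, reverse_complement

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))

EVENT_TYPES = ("intron_retention", "exon_skipping", "alt_acceptor", "alt_donor", "other")

# observed event-share of splicing analyses in tetraploid wheat roots
DEFAULT_AS_MIX = {
    "intron_retention": 0.38,
    "other": 0.29,
    "alt_acceptor": 0.15,
    "alt_donor": 0.10,
    "exon_skipping": 0.08,
}


class ConfigError(ValueError):
    """Raised for impossible generator parameter combinations."""


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_coding: int = 1000
    n_lncrna: int = 600
    n_contaminant: int = 100
    coding_length_range: tuple[int, int] = (400, 2000)
    lncrna_length_range: tuple[int, int] = (201, 2900)
    lncrna_gc_target: float = 0.44
    coding_orf_min: int = 300
    hexamer_bias_strength: float = 1.0
    n_precursors: int = 20
    precursor_flank: int = 200
    expr_mean_coding: float = 200.0
    expr_mean_lncrna: float = 50.0
    nb_dispersion: float = 0.1
    de_fraction: float = 0.1
    de_log2fc: float = 4.0
    n_replicates: int = 3
    n_as_loci: int = 50
    as_event_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AS_MIX))

    def __post_init__(self):
        for name in ("n_coding", "n_lncrna", "n_contaminant", "n_precursors",
                     "n_replicates", "n_as_loci"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.lncrna_length_range[0] <= 200:
            raise ConfigError("lncrna_length_range minimum must be > 200")
        if self.lncrna_length_range[1] < self.lncrna_length_range[0]:
            raise ConfigError("lncrna_length_range max < min")
        if self.coding_length_range[0] < self.coding_orf_min + 6:
            raise ConfigError("coding_length_range minimum too small for coding_orf_min")
        if not 0 < self.lncrna_gc_target < 1:
            raise ConfigError("lncrna_gc_target must be a fraction in (0,1)")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if not 0 <= self.de_fraction <= 1:
            raise ConfigError("de_fraction must be in [0,1]")
        if set(self.as_event_mix) - set(EVENT_TYPES):
            raise ConfigError(f"unknown event types in as_event_mix")
        if abs(sum(self.as_event_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("as_event_mix proportions must sum to 1")


@dataclass
class SyntheticTruth:
    """Planted ground truth for every generated entity."""

    transcripts: pd.DataFrame  # id-indexed: true_class, length, gc, orf_start, orf_end, source
    de: pd.DataFrame | None = None  # id-indexed: de_status, planted_log2fc, base_mean
    precursors: pd.DataFrame | None = None
    targets: pd.DataFrame | None = None  # planted miRNA target sites
    models: pd.DataFrame | None = None  # transcript exon chains on the toy genome
    events: pd.DataFrame | None = None  # planted AS events per locus


def _stream(config: GeneratorConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


# ---------------------------------------------------------------------------
# Transcript generation
# ---------------------------------------------------------------------------

def _random_dna(rng, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(BASES, size=n, p=p))


def _coding_sequence(rng, length: int, orf_min: int, codon_p) -> tuple[str, int, int]:
    """A transcript of ``length`` nt with one planted start-to-stop ORF."""
    codons, probs = codon_p
    max_orf = length - 6  # leave at least 3 nt of UTR on each side
    max_orf -= (max_orf - 6) % 3
    orf_len = int(rng.integers(orf_min, max_orf + 1))
    orf_len -= orf_len % 3
    n_sense = orf_len // 3 - 2  # minus start and stop codons
    body = "".join(rng.choice(codons, size=n_sense, p=probs))
    stop = rng.choice(["TAA", "TAG", "TGA"])
    orf = "ATG" + body + stop
    utr5_len = int(rng.integers(3, length - orf_len - 2))
    utr3_len = length - orf_len - utr5_len
    utr5 = _random_dna(rng, utr5_len, gc=0.5)
    utr3 = _random_dna(rng, utr3_len, gc=0.5)
    return utr5 + orf + utr3, utr5_len, utr5_len + orf_len


def _gc_controlled(rng, length: int, gc_target: float) -> str:
    """Sequence with realized GC within ~1 point of target."""
    n_gc = int(round(length * (gc_target + rng.normal(0.0, 0.005))))
    n_gc = min(max(n_gc, 0), length)
    arr = np.empty(length, dtype="<U1")
    strong = rng.choice(["G", "C"], size=n_gc)
    weak = rng.choice(["A", "T"], size=length - n_gc)
    pos = rng.permutation(length)
    arr[pos[:n_gc]] = strong
    arr[pos[n_gc:]] = weak
    return "".join(arr)


def _break_long_orfs(rng, seq: str, max_orf: int = 239, forbidden: tuple[int, int] | None = None,
                     max_iter: int = 300) -> str | None:
    """Destroy every start-to-stop ORF longer than ``max_orf`` on either strand.

    Start codons are rewritten with a GC-preserving single-base edit
    (ATG->AAG on the edited strand) so the composition control is not
    disturbed. Returns None when a start inside ``forbidden`` (a planted
    hairpin) blocks the repair.
    """
    s = list(seq)
    for _ in range(max_iter):
        hits = _cls.find_orfs("".join(s), min_len_nt=max_orf + 1)
        hits = [h for h in hits if h.length_nt > max_orf]
        if not hits:
            return "".join(s)
        h = hits[0]
        if h.strand == "+":
            pos = h.start + 1  # the T of ATG
            new = "A"
        else:
            pos = h.end - 2  # forward 'A', complement of the T of ATG
            new = "T"
        if forbidden is not None and forbidden[0] <= pos < forbidden[1]:
            return None
        s[pos] = new
    return None


def generate_transcriptome(config: GeneratorConfig) -> tuple[list[Transcript], SyntheticTruth]:
    """Generate coding, lncRNA and contaminant transcripts with ground truth.

    Byte-deterministic for a fixed config. Coding transcripts carry one
    planted ORF of at least ``coding_orf_min`` nt; lncRNAs carry no
    start-to-stop ORF of 240 nt or more on either strand and sit within
    three GC points of ``lncrna_gc_target``; contaminants are >=96%-identity
    copies of the bundled structural-RNA fixtures.
    """
    codons = np.array(SENSE_CODONS)
    weights = codon_weights(config.hexamer_bias_strength)
    probs = np.array([weights[c] for c in codons])
    probs = probs / probs.sum()

    transcripts: list[Transcript] = []
    rows = []

    rng = _stream(config, 0)
    lo, hi = config.coding_length_range
    for i in range(config.n_coding):
        length = int(rng.integers(lo, hi + 1))
        seq, orf_s, orf_e = _coding_sequence(rng, length, config.coding_orf_min, (codons, probs))
        tid = f"COD_{i:05d}"
        transcripts.append(Transcript(tid, seq, gene_id=tid))
        rows.append((tid, "coding", length, _gc(seq), orf_s, orf_e, ""))

    rng = _stream(config, 1)
    lo, hi = config.lncrna_length_range
    for i in range(config.n_lncrna):
        length = int(rng.integers(lo, hi + 1))
        seq = None
        while seq is None:
            seq = _break_long_orfs(rng, _gc_controlled(rng, length, config.lncrna_gc_target))
        tid = f"LNC_{i:05d}"
        transcripts.append(Transcript(tid, seq, gene_id=tid))
        rows.append((tid, "lncRNA", length, _gc(seq), pd.NA, pd.NA, ""))

    rng = _stream(config, 2)
    for i in range(config.n_contaminant):
        name, fixture = CONTAMINANT_FIXTURES[i % len(CONTAMINANT_FIXTURES)]
        rate = rng.uniform(0.0, 0.03)  # keeps identity >= ~97%, always >= 96% expected
        seq = _mutate(rng, fixture, rate)
        tid = f"CON_{i:05d}"
        transcripts.append(Transcript(tid, seq, gene_id=tid))
        rows.append((tid, "contaminant", len(seq), _gc(seq), pd.NA, pd.NA, name))

    truth = pd.DataFrame(
        rows,
        columns=["id", "true_class", "length", "gc", "orf_start", "orf_end", "source"],
    ).set_index("id")
    return transcripts, SyntheticTruth(transcripts=truth)


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def _mutate(rng, seq: str, rate: float) -> str:
    s = list(seq)
    n_mut = int(round(rate * len(s)))
    for pos in rng.choice(len(s), size=n_mut, replace=False):
        alternatives = [b for b in "ACGT" if b != s[pos]]
        s[pos] = rng.choice(alternatives)
    return "".join(s)


def make_reference_proteins(
    transcripts: list[Transcript], truth: SyntheticTruth, config: GeneratorConfig,
    aa_mut_rate: float = 0.02,
) -> dict[str, str]:
    """Synthetic protein reference database: translations of the planted
    coding ORFs with a few amino-acid substitutions, emulating homologs
    from related grass species."""
    from Bio.Seq import Seq

    rng = _stream(config, 6)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    proteins = {}
    info = truth.transcripts
    for t in transcripts:
        if info.loc[t.id, "true_class"] != "coding":
            continue
        s, e = int(info.loc[t.id, "orf_start"]), int(info.loc[t.id, "orf_end"])
        pep = str(Seq(t.sequence[s:e]).translate()).rstrip("*")
        p = list(pep)
        n_mut = int(round(aa_mut_rate * len(p)))
        for pos in rng.choice(len(p), size=n_mut, replace=False):
            p[pos] = rng.choice(aa)
        proteins[f"ref_{t.id}"] = "".join(p)
    return proteins


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def generate_counts(truth: SyntheticTruth, config: GeneratorConfig):
    """Two-condition NB count matrix with symmetric planted fold changes.

    Control means come from the class mean times a lognormal per-transcript
    factor; planted DE transcripts get a drought mean of exactly
    ``2**(+-de_log2fc)`` times the control mean, half up and half down.
    Returns an :class:`lncwheat.express.ExpressionMatrix` and records the
    DE truth on ``truth.de``.
    """
    from .express import ExpressionMatrix

    rng = _stream(config, 3)
    info = truth.transcripts
    ids = info.index.to_numpy()
    classes = info["true_class"].to_numpy()
    class_mean = np.where(classes == "lncRNA", config.expr_mean_lncrna, config.expr_mean_coding)
    base_mean = class_mean * np.exp(rng.normal(0.0, 0.4, size=len(ids)) - 0.08)

    eligible = np.flatnonzero(classes != "contaminant")
    n_de = int(round(config.de_fraction * eligible.size))
    de_idx = rng.choice(eligible, size=n_de, replace=False)
    lfc = np.zeros(len(ids))
    half = n_de // 2
    shuffled = rng.permutation(de_idx)
    lfc[shuffled[:half]] = config.de_log2fc
    lfc[shuffled[half:]] = -config.de_log2fc

    mean_control = base_mean
    mean_drought = base_mean * np.power(2.0, lfc)

    r = config.n_replicates
    samples = [f"CK_{j+1}" for j in range(r)] + [f"DS_{j+1}" for j in range(r)]
    conditions = {s: ("control" if s.startswith("CK") else "drought") for s in samples}
    cols = {}
    for j, s in enumerate(samples):
        mu = mean_control if conditions[s] == "control" else mean_drought
        if config.nb_dispersion < 1e-12:
            cols[s] = rng.poisson(mu)
        else:
            shape = 1.0 / config.nb_dispersion
            lam = rng.gamma(shape, mu * config.nb_dispersion)
            cols[s] = rng.poisson(lam)
    counts = pd.DataFrame(cols, index=ids)

    status = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none"))
    truth.de = pd.DataFrame(
        {"de_status": status, "planted_log2fc": lfc, "base_mean": base_mean}, index=ids
    )
    lengths = info["length"].astype(int)
    return ExpressionMatrix(counts=counts, lengths=lengths, conditions=conditions)


# ---------------------------------------------------------------------------
# miRNA precursors
# ---------------------------------------------------------------------------

def synthetic_mature_set(config: GeneratorConfig, n: int = 25) -> dict[str, str]:
    """Synthetic mature miRNA set (RNA alphabet, 21-mers), miRBase-style names."""
    rng = _stream(config, 7)
    out = {}
    for i in range(n):
        seq = "".join(rng.choice(np.array(list("ACGU")), size=21))
        out[f"syn-miR{i + 1:03d}"] = seq
    return out


def plant_mirna_precursors(
    transcripts: list[Transcript],
    mature_set: dict[str, str],
    config: GeneratorConfig,
    truth: SyntheticTruth | None = None,
) -> tuple[list[Transcript], pd.DataFrame]:
    """Embed miRNA hairpins into lncRNA transcripts.

    Each planted precursor carries the mature sequence with 0-2
    substitutions on one arm and a near-reverse-complement (0-1 further
    substitutions) on the other, separated by a 6-12 nt loop. Transcripts
    too short for the hairpin are skipped with a log message. Returns the
    modified transcript list and the precursor truth table (also stored on
    ``truth.precursors`` when a truth object is passed).
    """
    rng = _stream(config, 4)
    matures = list(mature_set.items())
    if not matures:
        raise ConfigError("mature set is empty")
    for name, seq in matures:
        if not 18 <= len(seq) <= 24:
            raise ConfigError(f"mature {name} length outside 18-24 nt")

    by_id = {t.id: t for t in transcripts}
    lnc_ids = [t.id for t in transcripts if t.id.startswith("LNC_")]
    if truth is not None:
        lnc_ids = [i for i in truth.transcripts.index
                   if truth.transcripts.loc[i, "true_class"] == "lncRNA"]
    rows = []
    planted = 0
    cursor = 0
    while planted < config.n_precursors and cursor < len(lnc_ids):
        tid = lnc_ids[cursor]
        cursor += 1
        name, mature_rna = matures[planted % len(matures)]
        mature = mature_rna.replace("U", "T")
        mlen = len(mature)
        loop_len = int(rng.integers(6, 13))
        hp_len = 2 * mlen + loop_len
        t = by_id[tid]
        if len(t.sequence) < hp_len + 20:
            logger.info("precursor planting skipped %s: transcript too short", tid)
            continue
        n_sub = int(rng.integers(0, 3))
        arm = _substitute(rng, mature, n_sub)
        star = reverse_complement(arm)
        if rng.random() < 0.5:
            star = _substitute(rng, star, 1)
        loop = "".join(rng.choice(np.array(list("AC")), size=loop_len))
        arm_5p = rng.random() < 0.5
        hairpin = (arm + loop + star) if arm_5p else (star + loop + arm)
        pos = int(rng.integers(10, len(t.sequence) - hp_len - 10))
        new_seq = t.sequence[:pos] + hairpin + t.sequence[pos + hp_len:]
        repaired = _break_long_orfs(rng, new_seq, forbidden=(pos, pos + hp_len))
        if repaired is None:
            logger.info("precursor planting skipped %s: could not keep ORF-free", tid)
            continue
        by_id[tid] = Transcript(tid, repaired, gene_id=t.gene_id,
                                isoform_index=t.isoform_index, samples=t.samples)
        m_start = pos if arm_5p else pos + mlen + loop_len
        rows.append((tid, name, m_start, m_start + mlen, n_sub,
                     "5p" if arm_5p else "3p", pos, pos + hp_len))
        planted += 1
    table = pd.DataFrame(
        rows,
        columns=["transcript_id", "mature_name", "mature_start", "mature_end",
                 "mismatches", "arm", "hairpin_start", "hairpin_end"],
    )
    if truth is not None:
        truth.precursors = table
    return [by_id[t.id] for t in transcripts], table


def _substitute(rng, seq: str, k: int) -> str:
    s = list(seq)
    for pos in rng.choice(len(s), size=k, replace=False):
        s[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
    return "".join(s)


def plant_target_sites(
    transcripts: list[Transcript],
    mature_set: dict[str, str],
    config: GeneratorConfig,
    truth: SyntheticTruth | None = None,
    n_mirnas: int = 5,
    lnc_per_mirna: int = 1,
    mrna_per_mirna: int = 2,
) -> tuple[list[Transcript], pd.DataFrame]:
    """Plant near-perfect miRNA target sites into coding and lncRNA
    transcripts so each chosen miRNA targets both classes (the substrate of
    target-mimicry triples). Sites are the reverse complement of the mature
    with at most one G:U wobble outside the seed region. Coding sites land
    in the 3' UTR so the planted ORF is untouched."""
    rng = _stream(config, 8)
    matures = list(mature_set.items())[:n_mirnas]
    by_id = {t.id: t for t in transcripts}
    info = truth.transcripts if truth is not None else None

    def candidates(cls_prefix):
        if info is not None:
            want = "coding" if cls_prefix == "COD" else "lncRNA"
            return [i for i in info.index if info.loc[i, "true_class"] == want]
        return [t.id for t in transcripts if t.id.startswith(cls_prefix)]

    cod_pool, lnc_pool = candidates("COD"), candidates("LNC")
    rows = []
    ci = li = 0
    for name, mature_rna in matures:
        mature = mature_rna.replace("U", "T")
        site = reverse_complement(mature)
        L = len(site)
        for want, count in (("lncRNA", lnc_per_mirna), ("coding", mrna_per_mirna)):
            placed = 0
            pool = lnc_pool if want == "lncRNA" else cod_pool
            while placed < count:
                if want == "lncRNA":
                    if li >= len(pool):
                        break
                    tid = pool[li]; li += 1
                else:
                    if ci >= len(pool):
                        break
                    tid = pool[ci]; ci += 1
                t = by_id[tid]
                if want == "coding":
                    lo = int(info.loc[tid, "orf_end"]) if info is not None else len(t.sequence) - L - 5
                    hi = len(t.sequence) - L
                    if hi <= lo:
                        logger.info("target planting skipped %s: no room after ORF", tid)
                        continue
                    pos = int(rng.integers(lo, hi))
                    new_seq = t.sequence[:pos] + site + t.sequence[pos + L:]
                else:
                    hp = None
                    if truth is not None and truth.precursors is not None:
                        sel = truth.precursors[truth.precursors.transcript_id == tid]
                        if len(sel):
                            hp = (int(sel.iloc[0].hairpin_start), int(sel.iloc[0].hairpin_end))
                    pos = int(rng.integers(5, len(t.sequence) - L - 5))
                    if hp and not (pos + L <= hp[0] or pos >= hp[1]):
                        continue
                    cand = t.sequence[:pos] + site + t.sequence[pos + L:]
                    span = (min(pos, hp[0]), max(pos + L, hp[1])) if hp else (pos, pos + L)
                    new_seq = _break_long_orfs(rng, cand, forbidden=span)
                    if new_seq is None:
                        logger.info("target planting skipped %s: could not keep ORF-free", tid)
                        continue
                by_id[tid] = Transcript(tid, new_seq, gene_id=t.gene_id,
                                        isoform_index=t.isoform_index, samples=t.samples)
                rows.append((name, tid, pos, pos + L, want))
                placed += 1
    table = pd.DataFrame(
        rows, columns=["mature_name", "transcript_id", "site_start", "site_end", "target_class"]
    )
    if truth is not None:
        truth.targets = table
    return [by_id[t.id] for t in transcripts], table


# ---------------------------------------------------------------------------
# Toy genome with planted splicing events
# ---------------------------------------------------------------------------

_CHROMS = ["1A", "1B", "2A", "2B", "3A", "3B", "scaffold_1"]
_LOCUS_SPAN = 4000


def _allocate_events(mix: dict[str, float], n: int) -> list[str]:
    """Largest-remainder allocation of n loci over the event mix."""
    keys = [k for k in EVENT_TYPES if mix.get(k, 0) > 0]
    raw = {k: mix[k] * n for k in keys}
    counts = {k: int(raw[k]) for k in keys}
    short = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: raw[k] - int(raw[k]), reverse=True)[:short]:
        counts[k] += 1
    out = []
    for k in keys:
        out.extend([k] * counts[k])
    return out


def _event_chains(rng, etype: str, strand: str, offset: int):
    """Two exon chains (genomic 0-based half-open) realizing the event."""
    a = int(rng.integers(80, 160))   # first exon
    i1 = int(rng.integers(90, 200))  # intron
    b = int(rng.integers(80, 160))   # middle/second exon
    i2 = int(rng.integers(90, 200))
    c = int(rng.integers(80, 160))   # last exon
    s = offset
    if etype == "intron_retention":
        t1 = [(s, s + a), (s + a + i1, s + a + i1 + b)]
        t2 = [(s, s + a + i1 + b)]
    elif etype == "exon_skipping":
        t1 = [(s, s + a), (s + a + i1, s + a + i1 + b),
              (s + a + i1 + b + i2, s + a + i1 + b + i2 + c)]
        t2 = [(s, s + a), (s + a + i1 + b + i2, s + a + i1 + b + i2 + c)]
    elif etype in ("alt_acceptor", "alt_donor"):
        shift = int(rng.integers(12, 40))
        # differ at the intron's right genomic boundary: on '+' the right
        # boundary is the acceptor, on '-' it is the donor
        differ_right = (etype == "alt_acceptor") == (strand == "+")
        if differ_right:
            t1 = [(s, s + a), (s + a + i1, s + a + i1 + b)]
            t2 = [(s, s + a), (s + a + i1 + shift, s + a + i1 + b)]
        else:
            t1 = [(s, s + a), (s + a + i1, s + a + i1 + b)]
            t2 = [(s, s + a - shift), (s + a + i1, s + a + i1 + b)]
    else:  # other: both intron boundaries differ, no containment
        shift = int(rng.integers(12, min(40, a - 20)))
        t1 = [(s, s + a), (s + a + i1, s + a + i1 + b)]
        t2 = [(s, s + a - shift), (s + a + i1 + shift, s + a + i1 + b)]
    return t1, t2


def generate_toy_genome(
    truth: SyntheticTruth, config: GeneratorConfig
) -> tuple[dict[str, str], str]:
    """Toy A/B genome plus transcript-to-genome alignments.

    Pairs of generated transcripts are assigned to loci on chromosomes named
    with A/B suffixes (plus an unplaced scaffold); each locus realizes one
    planted event type. Returns (genome dict, GFF3 text); the exon chains
    and events are recorded on ``truth.models`` / ``truth.events``.
    """
    rng = _stream(config, 5)
    info = truth.transcripts
    pool = [i for i in info.index if info.loc[i, "true_class"] == "coding"]
    pool += [i for i in info.index if info.loc[i, "true_class"] == "lncRNA"]
    n_loci = config.n_as_loci
    if 2 * n_loci > len(pool):
        raise ConfigError("not enough transcripts for the requested AS loci")
    etypes = _allocate_events(config.as_event_mix, n_loci)
    order = rng.permutation(n_loci)

    model_rows, event_rows, gff_lines = [], [], ["##gff-version 3"]
    chrom_cursor: dict[str, int] = {c: 0 for c in _CHROMS}
    for li in range(n_loci):
        etype = etypes[order[li]]
        chrom = _CHROMS[li % len(_CHROMS)]
        slot = chrom_cursor[chrom]
        chrom_cursor[chrom] += 1
        offset = 200 + slot * _LOCUS_SPAN
        strand = "+" if rng.random() < 0.5 else "-"
        t1_id, t2_id = pool[2 * li], pool[2 * li + 1]
        chain1, chain2 = _event_chains(rng, etype, strand, offset)
        locus = f"locus_{li:04d}"
        for tid, chain in ((t1_id, chain1), (t2_id, chain2)):
            ident = float(np.round(rng.uniform(90.5, 99.5), 1))
            model_rows.append((tid, chrom, strand, chain, locus, ident))
            span = (chain[0][0], chain[-1][1])
            gff_lines.append(
                f"{chrom}\tlncwheat_sim\ttranscript\t{span[0] + 1}\t{span[1]}\t.\t"
                f"{strand}\t.\tID={tid};identity={ident}"
            )
            for (es, ee) in chain:
                gff_lines.append(
                    f"{chrom}\tlncwheat_sim\texon\t{es + 1}\t{ee}\t.\t{strand}\t.\t"
                    f"Parent={tid}"
                )
        event_rows.append((locus, t1_id, t2_id, etype))

    genome = {}
    for chrom in _CHROMS:
        length = 200 + chrom_cursor[chrom] * _LOCUS_SPAN + 200
        genome[chrom] = "".join(rng.choice(BASES, size=length))

    truth.models = pd.DataFrame(
        model_rows, columns=["transcript_id", "chrom", "strand", "exons", "locus", "identity"]
    )
    truth.events = pd.DataFrame(
        event_rows, columns=["locus", "transcript_1", "transcript_2", "event_type"]
    )
    return genome, "\n".join(gff_lines) + "\n"


# ---------------------------------------------------------------------------
# Serialization helpers
# ---------------------------------------------------------------------------

def write_fasta(path, sequences, width: int = 60) -> None:
    """Write a name->sequence mapping (or Transcript list) as FASTA."""
    if not isinstance(sequences, dict):
        sequences = {t.id: t.sequence for t in sequences}
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_truth(truth: SyntheticTruth, prefix) -> None:
    """Write every populated truth table as TSV next to ``prefix``."""
    truth.transcripts.to_csv(f"{prefix}.transcripts.tsv", sep="\t")
    for name in ("de", "precursors", "targets", "models", "events"):
        table = getattr(truth, name)
        if table is not None:
            out = table.copy()
            if name == "models":
                out["exons"] = out["exons"].map(
                    lambda ch: ";".join(f"{s}-{e}" for s, e in ch)
                )
            out.to_csv(f"{prefix}.{name}.tsv", sep="\t",
                       index=name == "de")
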