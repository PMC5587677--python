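"""Transcript-to-genome alignment models and alternative-splicing events.

Consumes transcript alignments (GFF3/GTF exon features, 1-based inclusive)
produced by a spliced aligner, groups overlapping models into loci, tallies
the A/B sub-genome assignment of tetraploid wheat chromosomes, counts
single- vs multi-exon transcripts per class, and classifies pairwise
alternative-splicing events by intron-chain comparison:

* intron retention: an intron of one transcript lies entirely within an
  exon of the other;
* exon skipping: an internal exon of one lies entirely within an intron of
  the other while both flanking introns' outer boundaries match;
* alternative donor / acceptor: two introns share one boundary and differ
  at the other, with donor = intron 5' boundary and acceptor = intron 3'
  boundary in transcription orientation;
* other: any remaining intron-chain difference within the shared span.

Events are de-duplicated per locus on (type, coordinates), and the rules
are applied with precedence IR > ES > Alt > other so that, for instance, a
skipped exon is not additionally reported as an alternative-acceptor pair.
Internal coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

EVENT_TYPES = ("intron_retention", "exon_skipping", "alt_acceptor", "alt_donor", "other")


@dataclass
class TranscriptModel:
    transcript_id: str
    chrom: str
    strand: str  # + - or .
    exons: list[tuple[int, int]]  # sorted, disjoint, 0-based half-open
    identity: float | None = None
    locus: str | None = None

    def __post_init__(self):
        self.exons = sorted(tuple(e) for e in self.exons)
        last = None
        for s, e in self.exons:
            if e - s < 1:
                raise ValueError(f"{self.transcript_id}: empty exon [{s},{e})")
            if last is not None and s < last:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            last = e

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[k][1], self.exons[k + 1][0]) for k in range(len(self.exons) - 1)]


@dataclass(frozen=True)
class SpliceEvent:
    locus: str
    transcript_1: str
    transcript_2: str
    type: str
    start: int
    end: int


class GffError(ValueError):
    pass


def load_alignments(gff_path, min_identity: float = 90.0) -> list[TranscriptModel]:
    """Build transcript models from a GFF3/GTF alignment file.

    Exon features are grouped per parent/transcript id; models whose
    ``identity`` attribute (when present) falls below ``min_identity`` are
    dropped. Distinct model ids (e.g. one per alignment path) yield
    separate models, so a transcript aligned at several loci keeps one
    model per locus. Missing-strand models are kept with strand '.'.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(gff_path), ":memory:", merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # re-raise with a parse-oriented message
        raise GffError(f"failed to parse {gff_path}: {exc}") from exc

    groups: dict[str, dict] = {}
    identities: dict[str, float] = {}
    for feat in db.all_features():
        ftype = feat.featuretype.lower()
        if ftype == "exon":
            parents = feat.attributes.get("Parent") or feat.attributes.get("transcript_id")
            if not parents:
                raise GffError(f"exon without Parent/transcript_id at line: {feat}")
            if feat.end < feat.start:
                raise GffError(f"malformed exon coordinates: {feat}")
            for pid in parents:
                g = groups.setdefault(pid, {"chrom": feat.seqid, "strand": feat.strand or ".",
                                            "exons": []})
                g["exons"].append((feat.start - 1, feat.end))  # to 0-based half-open
        else:
            ident = feat.attributes.get("identity")
            if ident:
                identities[feat.id] = float(ident[0])

    models = []
    for pid, g in groups.items():
        ident = identities.get(pid)
        if ident is not None and ident < min_identity:
            continue
        models.append(TranscriptModel(pid, g["chrom"], g["strand"] or ".",
                                      g["exons"], identity=ident))
    return models


# ---------------------------------------------------------------------------
# Loci and per-class tallies
# ---------------------------------------------------------------------------

def _strand_compatible(a: str, b: str) -> bool:
    return a == b or a == "." or b == "."


def assign_loci(models: list[TranscriptModel], prefix: str = "locus") -> list[TranscriptModel]:
    """Group models into loci: connected components of exon-overlap on the
    same chromosome and compatible strand. Mutates ``locus`` in place."""
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    counter = 0
    for chrom in sorted(by_chrom):
        ms = sorted(by_chrom[chrom], key=lambda m: m.span)
        parent = list(range(len(ms)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in combinations(range(len(ms)), 2):
            if not _strand_compatible(ms[i].strand, ms[j].strand):
                continue
            if any(s1 < e2 and s2 < e1
                   for (s1, e1) in ms[i].exons for (s2, e2) in ms[j].exons):
                parent[find(i)] = find(j)
        comp_ids: dict[int, str] = {}
        for k, m in enumerate(ms):
            root = find(k)
            if root not in comp_ids:
                comp_ids[root] = f"{prefix}_{counter:05d}"
                counter += 1
            m.locus = comp_ids[root]
    return models


def assign_subgenome(models: list[TranscriptModel],
                     classes: pd.Series | dict | None = None) -> pd.DataFrame:
    """A/B/unplaced tallies per transcript class, plus per-chromosome counts.

    Chromosome names ending in A or B map to the corresponding sub-genome;
    anything else (scaffolds) is unplaced.
    """
    classes = classes if classes is not None else {}
    rows = []
    for m in models:
        sub = m.chrom[-1] if m.chrom[-1] in "AB" and not m.chrom.startswith("scaffold") else "unplaced"
        cls = classes.get(m.transcript_id, "unknown") if hasattr(classes, "get") else "unknown"
        rows.append((m.transcript_id, m.chrom, sub, cls))
    df = pd.DataFrame(rows, columns=["transcript_id", "chrom", "subgenome", "class"])
    return df


def exon_stats(models: list[TranscriptModel],
               classes: pd.Series | dict | None = None) -> pd.DataFrame:
    """Single/multi-exon counts per class.

    A transcript with models at several loci is counted once with its
    maximum exon count; a ``both_forms`` flag marks transcripts with both
    single- and multi-exon models.
    """
    classes = classes if classes is not None else {}
    per_transcript: dict[str, list[int]] = {}
    for m in models:
        per_transcript.setdefault(m.transcript_id, []).append(len(m.exons))
    rows = []
    for tid, counts in per_transcript.items():
        cls = classes.get(tid, "unknown") if hasattr(classes, "get") else "unknown"
        rows.append({
            "transcript_id": tid,
            "class": cls,
            "max_exons": max(counts),
            "single_exon": max(counts) == 1,
            "both_forms": min(counts) == 1 < max(counts),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pairwise event classification
# ---------------------------------------------------------------------------

def _within(inner: tuple[int, int], outer: tuple[int, int]) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def _pair_events(m1: TranscriptModel, m2: TranscriptModel) -> list[tuple[str, int, int]]:
    """Events between two models of one locus, with IR > ES > Alt > other
    precedence; introns explained by a higher rule are consumed."""
    shared = (max(m1.span[0], m2.span[0]), min(m1.span[1], m2.span[1]))
    if shared[0] >= shared[1]:
        return []

    def introns_in(m):
        return [iv for iv in m.introns if _within(iv, shared)]

    i1, i2 = introns_in(m1), introns_in(m2)
    if not i1 and not i2:
        return []
    events: list[tuple[str, int, int]] = []
    used1: set[tuple[int, int]] = set()
    used2: set[tuple[int, int]] = set()

    # intron retention
    for a, b, used in ((m1, m2, used1), (m2, m1, used2)):
        for iv in introns_in(a):
            if any(_within(iv, ex) for ex in b.exons):
                events.append(("intron_retention", iv[0], iv[1]))
                used.add(iv)

    # exon skipping: internal exon of one inside an intron of the other,
    # flanking introns' outer boundaries matching that intron's boundaries
    for a, b, used_a, used_b in ((m1, m2, used1, used2), (m2, m1, used2, used1)):
        a_introns = a.introns
        for k in range(1, len(a.exons) - 1):
            ex = a.exons[k]
            if not _within(ex, shared):
                continue
            left, right = a_introns[k - 1], a_introns[k]
            for iv in introns_in(b):
                if _within(ex, iv) and left[0] == iv[0] and right[1] == iv[1]:
                    events.append(("exon_skipping", ex[0], ex[1]))
                    used_b.add(iv)
                    used_a.add(left)
                    used_a.add(right)

    # alternative donor / acceptor on remaining introns
    stranded = m1.strand in "+-" and m2.strand in "+-"
    for iv1 in i1:
        if iv1 in used1:
            continue
        for iv2 in i2:
            if iv2 in used2 or iv1 == iv2:
                continue
            share_left, share_right = iv1[0] == iv2[0], iv1[1] == iv2[1]
            if share_left == share_right:
                continue
            if not stranded:
                continue
            strand = m1.strand if m1.strand in "+-" else m2.strand
            lo = min(iv1[0], iv2[0])
            hi = max(iv1[1], iv2[1])
            if share_left:  # differ at the right genomic boundary
                etype = "alt_acceptor" if strand == "+" else "alt_donor"
            else:  # differ at the left genomic boundary
                etype = "alt_donor" if strand == "+" else "alt_acceptor"
            events.append((etype, lo, hi))
            used1.add(iv1)
            used2.add(iv2)

    if not events and sorted(i1) != sorted(i2):
        events.append(("other", shared[0], shared[1]))
    return events


def classify_events(models: list[TranscriptModel]) -> list[SpliceEvent]:
    """All pairwise events per locus, de-duplicated on (type, coords).

    Models must carry locus assignments (see :func:`assign_loci`); loci are
    inferred on the fly when absent.
    """
    if any(m.locus is None for m in models):
        assign_loci(models)
    by_locus: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_locus.setdefault(m.locus, []).append(m)
    out: list[SpliceEvent] = []
    for locus in sorted(by_locus):
        seen: set[tuple[str, int, int]] = set()
        ms = sorted(by_locus[locus], key=lambda m: m.transcript_id)
        for m1, m2 in combinations(ms, 2):
            for etype, s, e in _pair_events(m1, m2):
                key = (etype, s, e)
                if key in seen:
                    continue
                seen.add(key)
                out.append(SpliceEvent(locus, m1.transcript_id, m2.transcript_id,
                                       etype, s, e))
    return out


def event_summary(events: list[SpliceEvent]) -> pd.Series:
    counts = pd.Series(0, index=list(EVENT_TYPES), dtype=int)
    for ev in events:
        counts[ev.type] += 1
    return counts
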