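"""Haplotype calling from long-read CRISPR amplicons.

The workflow mirrors amplicon practice for CCS-like reads:

1. :func:`discover_spacers` — find approximate repeat occurrences in a seed
   read set and extract the inter-repeat segments as candidate spacers,
   clustered at an identity threshold (a repeat-anchored seed-spacer
   detector).
2. :func:`map_spacers` — fuzzily map primers and every catalog spacer onto
   each read and assign exactly one QC category.
3. :func:`call_haplotypes` — turn PASS reads into ordered spacer-ID arrays
   and aggregate per-sample counts, with per-category QC bookkeeping.
4. :func:`extract_putative_new_spacers` — pull candidate regions (with their
   bordering repeats) out of irregularly spaced reads so discovery can be
   re-run on them.

Edit thresholds are Levenshtein (substitutions + indels): CCS errors are
indel-rich, so a pure-mismatch count would miss real occurrences. The
default budget of 5 edits corresponds to ~85 % identity on a typical spacer.
"""

from __future__ import annotations

import enum
from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .arrays import CrisprArray, Spacer, SpacerCatalog
from .errors import EmptySample, NoRepeatFound
from .matching import Occurrence, best_occurrence, find_occurrences, identity, revcomp

DEFAULT_MAX_EDITS = 5
DEFAULT_MIN_LEN = 33  # approximate size of a single spacer
DEFAULT_SPACING_TOL = 5  # slack on the repeat-length gap between spacer hits
DEFAULT_IDENTITY = 0.85


class QCCategory(enum.Enum):
    PASS = "PASS"
    MISSING_PRIMER = "MISSING_PRIMER"
    TOO_SHORT = "TOO_SHORT"
    MIXED_ORIENTATION = "MIXED_ORIENTATION"
    MISORDERED = "MISORDERED"
    IRREGULAR_SPACING = "IRREGULAR_SPACING"


#: Precedence in which categories are assigned (first failure wins).
QC_PRECEDENCE = [
    QCCategory.MISSING_PRIMER,
    QCCategory.TOO_SHORT,
    QCCategory.MIXED_ORIENTATION,
    QCCategory.MISORDERED,
    QCCategory.IRREGULAR_SPACING,
    QCCategory.PASS,
]


@dataclass(frozen=True)
class SpacerHit:
    """One spacer occurrence on the (orientation-normalized) insert."""

    spacer_id: int
    start: int
    end: int
    dist: int
    strand: str  # '+' catalog orientation, '-' reverse complement


@dataclass
class ReadQC:
    """QC classification of one read plus everything needed downstream."""

    read_id: str
    category: QCCategory
    matches: list[SpacerHit] = field(default_factory=list)
    sequence: str = ""  # orientation-normalized full read
    insert_start: int = 0  # insert = sequence[insert_start:insert_end]
    insert_end: int = 0

    @property
    def array(self) -> CrisprArray | None:
        if self.category is not QCCategory.PASS:
            return None
        return CrisprArray(h.spacer_id for h in self.matches)


# ---------------------------------------------------------------------------
# Spacer discovery
# ---------------------------------------------------------------------------

def discover_spacers(
    reads: Iterable[SeqRecord | str],
    repeat: str,
    max_repeat_edits: int = DEFAULT_MAX_EDITS,
    min_len: int = 20,
    max_len: int = 60,
    identity_threshold: float = DEFAULT_IDENTITY,
    min_count: int = 1,
    start_id: int = 1,
) -> SpacerCatalog:
    """Repeat-anchored seed-spacer discovery.

    Approximate repeat occurrences are located on both strands of every
    read (the strand with more occurrences wins); segments between
    consecutive occurrences whose length falls in ``[min_len, max_len]``
    become candidate spacers. Candidates are clustered greedily at
    ``identity_threshold`` and each cluster is represented by its most
    frequent sequence (ties broken lexicographically). Fresh integer IDs
    are assigned in cluster-creation order.

    Raises
    ------
    NoRepeatFound
        If no read contains the repeat within ``max_repeat_edits``.
    """
    if len(repeat) < 20:
        raise ValueError("repeat must be at least 20 nt")
    segments: list[str] = []
    any_repeat = False
    n_reads = 0
    for rec in reads:
        n_reads += 1
        seq = str(rec.seq) if isinstance(rec, SeqRecord) else str(rec)
        seq = seq.upper()
        occ_f = find_occurrences(repeat, seq, max_repeat_edits)
        occ_r = find_occurrences(repeat, revcomp(seq), max_repeat_edits)
        if len(occ_r) > len(occ_f):
            seq, occ = revcomp(seq), occ_r
        else:
            occ = occ_f
        if occ:
            any_repeat = True
        for prev, nxt in zip(occ, occ[1:]):
            seg = seq[prev.end : nxt.start]
            if min_len <= len(seg) <= max_len:
                segments.append(seg)
    if n_reads == 0:
        raise ValueError("no reads supplied")
    if not any_repeat:
        raise NoRepeatFound(
            f"no read contains the repeat within {max_repeat_edits} edits"
        )

    clusters: list[Counter[str]] = []
    reps: list[str] = []
    for seg in segments:
        best_i, best_ident = -1, identity_threshold
        for i, rep in enumerate(reps):
            ident = identity(seg, rep)
            if ident >= best_ident:
                best_i, best_ident = i, ident
        if best_i >= 0:
            clusters[best_i][seg] += 1
        else:
            clusters.append(Counter([seg]))
            reps.append(seg)

    spacers = []
    next_id = start_id
    for cluster in clusters:
        if sum(cluster.values()) < min_count:
            continue
        top = max(cluster.items(), key=lambda kv: (kv[1], [-ord(c) for c in kv[0]]))
        spacers.append(Spacer(id=next_id, sequence=top[0]))
        next_id += 1
    return SpacerCatalog(spacers, repeat)


def augment_catalog(
    catalog: SpacerCatalog,
    candidates: SpacerCatalog,
    identity_threshold: float = DEFAULT_IDENTITY,
) -> tuple[SpacerCatalog, list[Spacer]]:
    """Merge re-discovered candidate spacers into an existing catalog.

    A candidate matching an existing spacer at or above the identity
    threshold is redundant; one whose *best* match sits slightly below the
    threshold (within 0.15) is a degraded rediscovery of a known spacer
    and is discarded rather than added (it would shadow the established
    spacer in fuzzy mapping). Candidates below that band are admitted as
    genuinely new — unrelated sequences of this length typically align at
    ~0.5-0.6 identity, well under it.

    Returns the (possibly extended) catalog and the discarded candidates.
    """
    new_spacers = list(catalog.spacers)
    next_id = max((s.id for s in catalog.spacers), default=0) + 1
    discarded: list[Spacer] = []
    for cand in candidates:
        idents = [identity(cand.sequence, s.sequence) for s in catalog.spacers]
        best = max(idents, default=0.0)
        if best >= identity_threshold:
            continue  # already known
        if best >= identity_threshold - 0.15:
            discarded.append(cand)  # degraded copy of a known spacer
            continue
        new_spacers.append(Spacer(id=next_id, sequence=cand.sequence))
        next_id += 1
    return (
        SpacerCatalog(
            new_spacers,
            catalog.repeat_sequence,
            reference_order=catalog.reference_order,
        ),
        discarded,
    )


# ---------------------------------------------------------------------------
# Read classification
# ---------------------------------------------------------------------------

def _is_subsequence(seq: list[int], reference: tuple[int, ...]) -> bool:
    it = iter(reference)
    return all(x in it for x in seq)


def map_spacers(
    read: str | SeqRecord,
    catalog: SpacerCatalog,
    primers: tuple[str, str],
    max_edits: int = DEFAULT_MAX_EDITS,
    min_len: int = DEFAULT_MIN_LEN,
    spacing_tol: int = DEFAULT_SPACING_TOL,
    read_id: str = "",
) -> ReadQC:
    """Classify one read and report its ordered spacer hits.

    The read is first orientation-normalized so the forward primer sits at
    the leader end (if the primers are found on the reverse strand the read
    is reverse-complemented). Exactly one QC category is then assigned, by
    precedence MISSING_PRIMER > TOO_SHORT > MIXED_ORIENTATION > MISORDERED >
    IRREGULAR_SPACING > PASS:

    * MISSING_PRIMER — either primer absent within ``max_edits``;
    * TOO_SHORT — insert between the primers shorter than ``min_len``;
    * MIXED_ORIENTATION — spacer hits on both strands;
    * MISORDERED — a spacer hit twice, or hit order inconsistent with the
      catalog's reference spacer order (when one is defined);
    * IRREGULAR_SPACING — a gap between consecutive hits (or between a
      primer and its flanking hit) differing from the repeat length by more
      than ``spacing_tol``, i.e. a putative un-catalogued spacer; a read
      whose insert carries no catalog spacer at all is flagged the same way;
    * PASS — everything consistent; ``matches`` holds the leader-to-trailer
      spacer hits.
    """
    if isinstance(read, SeqRecord):
        read_id = read_id or read.id
        read = str(read.seq)
    seq = read.upper()
    fwd, rev = primers[0].upper(), primers[1].upper()

    def primer_pair(s: str) -> tuple[Occurrence | None, Occurrence | None]:
        return (
            best_occurrence(fwd, s, max_edits),
            best_occurrence(revcomp(rev), s, max_edits),
        )

    hits_f = primer_pair(seq)
    hits_r = primer_pair(revcomp(seq))
    score_f = sum(h is not None for h in hits_f)
    score_r = sum(h is not None for h in hits_r)
    if score_r > score_f:
        seq = revcomp(seq)
        p_fwd, p_rev = hits_r
    else:
        p_fwd, p_rev = hits_f

    qc = ReadQC(read_id=read_id, category=QCCategory.PASS, sequence=seq)
    if p_fwd is None or p_rev is None or p_rev.start < p_fwd.end:
        qc.category = QCCategory.MISSING_PRIMER
        return qc
    qc.insert_start, qc.insert_end = p_fwd.end, p_rev.start
    insert = seq[qc.insert_start : qc.insert_end]

    if len(insert) < min_len:
        qc.category = QCCategory.TOO_SHORT
        return qc

    # collect candidate hits of every spacer on both strands of the insert,
    # then resolve overlaps greedily by (edit distance, position, id)
    candidates: list[SpacerHit] = []
    for sp in catalog:
        for strand, pat in (("+", sp.sequence), ("-", revcomp(sp.sequence))):
            for occ in find_occurrences(pat, insert, max_edits):
                candidates.append(
                    SpacerHit(sp.id, occ.start, occ.end, occ.dist, strand)
                )
    chosen: list[SpacerHit] = []
    for hit in sorted(candidates, key=lambda h: (h.dist, h.start, h.spacer_id)):
        if all(hit.end <= c.start or hit.start >= c.end for c in chosen):
            chosen.append(hit)
    chosen.sort(key=lambda h: h.start)
    qc.matches = chosen

    if chosen and len({h.strand for h in chosen}) > 1:
        qc.category = QCCategory.MIXED_ORIENTATION
        return qc

    ids = [h.spacer_id for h in chosen]
    if len(set(ids)) != len(ids) or (
        catalog.reference_order is not None
        and not _is_subsequence(ids, catalog.reference_order)
    ):
        qc.category = QCCategory.MISORDERED
        return qc

    rlen = len(catalog.repeat_sequence)
    bounds = [0] + [x for h in chosen for x in (h.start, h.end)] + [len(insert)]
    gaps = [bounds[i + 1] - bounds[i] for i in range(0, len(bounds) - 1, 2)]
    if not chosen or any(abs(g - rlen) > spacing_tol for g in gaps):
        qc.category = QCCategory.IRREGULAR_SPACING
        return qc

    return qc


# ---------------------------------------------------------------------------
# Haplotype calling
# ---------------------------------------------------------------------------

@dataclass
class QCSummary:
    """Per-sample QC category counts and fractions."""

    counts: pd.DataFrame  # index: sample, columns: category names

    @property
    def fractions(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample_id")


def call_haplotypes(
    reads_by_sample: Mapping[str, Iterable[SeqRecord | str]],
    catalog: SpacerCatalog,
    primers: tuple[str, str],
    max_edits: int = DEFAULT_MAX_EDITS,
    min_len: int = DEFAULT_MIN_LEN,
    spacing_tol: int = DEFAULT_SPACING_TOL,
    keep_flagged: bool = False,
) -> tuple[dict[str, dict[CrisprArray, int]], QCSummary] | tuple[
    dict[str, dict[CrisprArray, int]], QCSummary, dict[str, list[ReadQC]]
]:
    """Call per-sample haplotype read counts from raw amplicon reads.

    Every read receives exactly one QC category; PASS reads become
    :class:`CrisprArray` haplotypes whose per-sample counts are aggregated.

    Raises
    ------
    EmptySample
        If any sample yields zero PASS reads.

    With ``keep_flagged=True`` additionally returns the
    IRREGULAR_SPACING-flagged :class:`ReadQC` objects per sample, for
    :func:`extract_putative_new_spacers`.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    table: dict[str, dict[CrisprArray, int]] = {}
    rows: dict[str, Counter[str]] = {}
    flagged: dict[str, list[ReadQC]] = {}
    for sample, reads in reads_by_sample.items():
        counts: Counter[CrisprArray] = Counter()
        cat_counts: Counter[str] = Counter({c.value: 0 for c in QCCategory})
        flagged[sample] = []
        for i, read in enumerate(reads):
            rid = read.id if isinstance(read, SeqRecord) else f"{sample}/{i}"
            qc = map_spacers(
                read, catalog, primers, max_edits, min_len, spacing_tol, read_id=rid
            )
            cat_counts[qc.category.value] += 1
            if qc.category is QCCategory.PASS:
                counts[qc.array] += 1
            elif qc.category is QCCategory.IRREGULAR_SPACING:
                flagged[sample].append(qc)
        if not counts:
            raise EmptySample(
                f"sample {sample!r} yielded no PASS reads "
                f"(categories: {dict(cat_counts)})"
            )
        table[sample] = dict(counts)
        rows[sample] = cat_counts
    summary = QCSummary(
        counts=pd.DataFrame.from_dict(rows, orient="index")
        .fillna(0)
        .astype(int)
        .reindex(columns=[c.value for c in QCCategory])
        .sort_index()
    )
    if keep_flagged:
        return table, summary, flagged
    return table, summary


def extract_putative_new_spacers(
    flagged: Iterable[ReadQC],
    repeat_length: int | None = None,
    spacing_tol: int = DEFAULT_SPACING_TOL,
) -> list[SeqRecord]:
    """Candidate novel-spacer regions from irregularly spaced reads.

    For every irregular gap — between consecutive spacer hits, or between a
    primer and its flanking hit — the subsequence between the bounding
    regular hits is returned *including* the bordering repeats, so that
    re-running :func:`discover_spacers` on the output can recover the novel
    spacer. When ``repeat_length`` is given, only the gaps that actually
    deviate from it by more than ``spacing_tol`` are extracted; otherwise
    every inter-hit region is returned. Reads not flagged
    IRREGULAR_SPACING are ignored.
    """
    out: list[SeqRecord] = []
    for qc in flagged:
        if qc.category is not QCCategory.IRREGULAR_SPACING:
            continue
        insert = qc.sequence[qc.insert_start : qc.insert_end]
        anchors = [0] + [x for h in qc.matches for x in (h.start, h.end)]
        anchors.append(len(insert))
        k = 0
        for lo, hi in zip(anchors[::2], anchors[1::2]):
            region = insert[lo:hi]
            if repeat_length is not None and abs(len(region) - repeat_length) <= spacing_tol:
                continue
            if region:
                rec = SeqRecord(
                    Seq(region),
                    id=f"{qc.read_id}/candidate{k}",
                    description="",
                )
                rec.letter_annotations["phred_quality"] = [40] * len(region)
                out.append(rec)
                k += 1
    return out
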