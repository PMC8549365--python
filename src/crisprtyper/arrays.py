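"""Core domain types: spacers, spacer catalogs and CRISPR arrays.

A CRISPR array is stored as an ordered sequence of integer spacer IDs,
position 0 being the leader (5') end where new spacers are inserted and the
last position the trailer end. Pairwise comparison of two arrays partitions
their spacers into three classes that the spacer-loss likelihood consumes:

* ``shared``          -- retained in both lineages since their common ancestor;
* ``internal_unique`` -- present in one array only, at or trailer-ward of the
  leader-most shared spacer (ancestral spacers lost by the other lineage);
* ``leader_unique``   -- present in one array only, leader-ward of every
  shared spacer (candidate post-divergence insertions).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import edlib

from .errors import CollinearityError

_DNA = set("ACGT")

#: Reserved FASTA record id for the repeat sequence in a catalog file.
REPEAT_RECORD_ID = "REPEAT"


@dataclass(frozen=True)
class Spacer:
    """A unique spacer sequence with its integer catalog label."""

    id: int
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("spacer sequence must be non-empty")
        if set(self.sequence) - _DNA:
            raise ValueError(
                f"spacer {self.id}: sequence must be uppercase A/C/G/T, "
                f"got {self.sequence!r}"
            )


class SpacerCatalog:
    """An ordered collection of spacers plus the repeat that separates them.

    Parameters
    ----------
    spacers:
        Spacers in catalog order. IDs must be unique and sequences mutually
        distinguishable: any two spacers closer than ``min_separation``
        Levenshtein edits would be uncallable as distinct under fuzzy
        matching, so such a catalog is rejected.
    repeat_sequence:
        The conserved direct repeat (>= 20 nt).
    reference_order:
        Optional spacer-ID order of the ancestral array (leader->trailer).
        When present, read classification can check that mapped spacers
        appear in an order consistent with it.
    """

    def __init__(
        self,
        spacers: Iterable[Spacer],
        repeat_sequence: str,
        *,
        reference_order: Sequence[int] | None = None,
        min_separation: int = 6,
    ) -> None:
        self.spacers: list[Spacer] = list(spacers)
        self.repeat_sequence = repeat_sequence
        self.reference_order = tuple(reference_order) if reference_order else None
        if len(repeat_sequence) < 20:
            raise ValueError("repeat sequence must be at least 20 nt")
        ids = [s.id for s in self.spacers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate spacer ids in catalog")
        self._by_id: dict[int, Spacer] = {s.id: s for s in self.spacers}
        for i, a in enumerate(self.spacers):
            for b in self.spacers[i + 1 :]:
                d = edlib.align(a.sequence, b.sequence, mode="NW")["editDistance"]
                if d < min_separation:
                    raise ValueError(
                        f"spacers {a.id} and {b.id} are within {d} edits of "
                        f"each other (< {min_separation}); they cannot be "
                        "called as distinct under fuzzy matching"
                    )

    def __len__(self) -> int:
        return len(self.spacers)

    def __iter__(self):
        return iter(self.spacers)

    def __getitem__(self, spacer_id: int) -> Spacer:
        return self._by_id[spacer_id]

    def __contains__(self, spacer_id: int) -> bool:
        return spacer_id in self._by_id

    @property
    def ids(self) -> list[int]:
        return [s.id for s in self.spacers]


@dataclass(frozen=True)
class CrisprArray:
    """Ordered spacer IDs of one haplotype, leader (5') end first."""

    spacer_ids: tuple[int, ...]

    def __init__(self, spacer_ids: Iterable[int]) -> None:
        object.__setattr__(self, "spacer_ids", tuple(spacer_ids))
        if not self.spacer_ids:
            raise ValueError("array must contain at least one spacer")
        if len(set(self.spacer_ids)) != len(self.spacer_ids):
            raise ValueError(
                f"duplicated spacer id in array {self.spacer_ids}; the model "
                "has no duplication process"
            )

    def __len__(self) -> int:
        return len(self.spacer_ids)

    def __iter__(self):
        return iter(self.spacer_ids)

    def __str__(self) -> str:
        return ",".join(str(i) for i in self.spacer_ids)

    def is_subsequence_of(self, other: "CrisprArray") -> bool:
        """True if this array can arise from ``other`` by deletions only."""
        it = iter(other.spacer_ids)
        return all(sid in it for sid in self.spacer_ids)


@dataclass(frozen=True)
class PairAlignment:
    """Partition of two arrays' spacers into shared / unique classes."""

    shared: tuple[int, ...]
    internal_unique_a: int = 0
    internal_unique_b: int = 0
    leader_unique_a: int = 0
    leader_unique_b: int = 0

    @property
    def n_shared(self) -> int:
        return len(self.shared)


def align_pair(a: CrisprArray, b: CrisprArray) -> PairAlignment:
    """Partition the spacers of two arrays by shared-spacer collinearity.

    Raises
    ------
    CollinearityError
        If the spacers common to both arrays do not occur in the same
        relative order, which no ordered insertion/deletion history can
        produce.
    """
    set_b = set(b.spacer_ids)
    set_a = set(a.spacer_ids)
    shared_in_a = [s for s in a.spacer_ids if s in set_b]
    shared_in_b = [s for s in b.spacer_ids if s in set_a]
    if shared_in_a != shared_in_b:
        raise CollinearityError(
            f"shared spacers are order-discordant: {shared_in_a} in A vs "
            f"{shared_in_b} in B"
        )
    shared = tuple(shared_in_a)

    def _split(arr: CrisprArray) -> tuple[int, int]:
        if not shared:
            # with no anchor the leader/internal boundary is undefined; all
            # unique spacers are counted as internal
            return len(arr), 0
        first_shared = arr.spacer_ids.index(shared[0])
        leader = first_shared  # unique spacers leader-ward of all shared
        internal = len(arr) - len(shared) - leader
        return internal, leader

    int_a, lead_a = _split(a)
    int_b, lead_b = _split(b)
    return PairAlignment(
        shared=shared,
        internal_unique_a=int_a,
        internal_unique_b=int_b,
        leader_unique_a=lead_a,
        leader_unique_b=lead_b,
    )


@dataclass
class NestedDeletionReport:
    """Which arrays are pure-deletion derivatives of the longest array."""

    longest: CrisprArray
    nested: dict[CrisprArray, bool] = field(default_factory=dict)

    @property
    def all_nested(self) -> bool:
        return all(self.nested.values())

    @property
    def fraction_nested(self) -> float:
        return sum(self.nested.values()) / len(self.nested)


def validate_nested_deletion_set(
    arrays: Iterable[CrisprArray],
    reference: CrisprArray | None = None,
) -> NestedDeletionReport:
    """Check whether every array is an ordered subsequence of the longest.

    The longest array is taken as the most ancestral state; ties are broken
    by lexicographic spacer-ID order for determinism. When the ancestral
    array is known independently (e.g. simulated truth) pass it as
    ``reference``. Report-only: arrays that are not nested are flagged,
    never rejected.
    """
    arrs = list(arrays)
    if not arrs:
        raise ValueError("need at least one array")
    longest = reference if reference is not None else max(
        arrs, key=lambda a: (len(a), tuple(-i for i in a.spacer_ids))
    )
    report = NestedDeletionReport(longest=longest)
    for arr in arrs:
        report.nested[arr] = arr.is_subsequence_of(longest)
    return report


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def write_catalog_fasta(catalog: SpacerCatalog, path: str | Path) -> None:
    """Write a catalog as FASTA: integer spacer ids + a REPEAT record."""
    with open(path, "w") as fh:
        fh.write(f">{REPEAT_RECORD_ID}\n{catalog.repeat_sequence}\n")
        for sp in catalog:
            fh.write(f">{sp.id}\n{sp.sequence}\n")


def read_catalog_fasta(path: str | Path, **kwargs) -> SpacerCatalog:
    from Bio import SeqIO

    repeat = None
    spacers = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id == REPEAT_RECORD_ID:
            repeat = str(rec.seq).upper()
        else:
            spacers.append(Spacer(id=int(rec.id), sequence=str(rec.seq).upper()))
    if repeat is None:
        raise ValueError(f"{path}: no {REPEAT_RECORD_ID} record")
    return SpacerCatalog(spacers, repeat, **kwargs)


def write_haplotype_tsv(
    table: Mapping[str, Mapping[CrisprArray, int]],
    path: str | Path,
) -> None:
    """Write per-sample haplotype counts as TSV.

    Columns: sample_id, haplotype_id, spacer_ids (comma-joined,
    leader->trailer), read_count. Haplotype ids are assigned H1..Hn over the
    distinct arrays in order of decreasing total count (ties by spacer ids).
    """
    totals: dict[CrisprArray, int] = {}
    for counts in table.values():
        for arr, n in counts.items():
            totals[arr] = totals.get(arr, 0) + n
    ordered = sorted(totals, key=lambda a: (-totals[a], a.spacer_ids))
    hap_id = {arr: f"H{i + 1}" for i, arr in enumerate(ordered)}
    with open(path, "w") as fh:
        fh.write("sample_id\thaplotype_id\tspacer_ids\tread_count\n")
        for sample in sorted(table):
            for arr, n in sorted(
                table[sample].items(), key=lambda kv: (-kv[1], kv[0].spacer_ids)
            ):
                fh.write(f"{sample}\t{hap_id[arr]}\t{arr}\t{n}\n")


def read_haplotype_tsv(
    path: str | Path,
) -> tuple[dict[str, dict[CrisprArray, int]], dict[str, CrisprArray]]:
    """Read the TSV dialect written by :func:`write_haplotype_tsv`.

    Returns (per-sample counts, haplotype_id -> array mapping).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "haplotype_id": str})
    table: dict[str, dict[CrisprArray, int]] = {}
    haps: dict[str, CrisprArray] = {}
    for row in df.itertuples(index=False):
        arr = CrisprArray(int(x) for x in str(row.spacer_ids).split(","))
        haps[row.haplotype_id] = arr
        table.setdefault(row.sample_id, {})[arr] = int(row.read_count)
    return table, haps
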