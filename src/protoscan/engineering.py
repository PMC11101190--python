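"""Apply mutation records to an ancestral genome and track coordinates.

This module plays the role that ``gdtools APPLY`` plus aligner-based
re-mapping play in real resequencing workflows: given the list of mutations
carried by an evolved clone, it reconstructs the evolved genome sequence and
an *exact* ancestral<->evolved coordinate correspondence, so downstream
interval analysis never depends on approximate alignment.

Supported record types are SNP, DEL, INS and MOB (new insertion of a mobile
element with a target-site duplication).  AMP/INV and other GenomeDiff types
are rejected loudly.  Mutations must be mutually non-overlapping on the
ancestral genome; clone mutation lists from reconciled resequencing
pipelines satisfy this.

Coordinate conventions: GenomeDiff files are 1-based (breseq convention);
everything in memory is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .genome import GenomeRecord, reverse_complement

SUPPORTED_TYPES = ("SNP", "DEL", "INS", "MOB")

#: default target-site duplication for IS150-class elements (bp)
DEFAULT_TSD = 3

GENOMEDIFF_HEADER = "#=GENOME_DIFF simplified-1"


class GenomeDiffError(ValueError):
    """Malformed mutation record or file."""


class MutationConflictError(ValueError):
    """Mutations overlap on the ancestral genome."""


@dataclass(frozen=True)
class MutationRecord:
    """One GenomeDiff-style event in ancestral coordinates (1-based position)."""

    id: str
    type: str
    position: int
    new_base: str | None = None          # SNP
    size: int | None = None              # DEL
    sequence: str | None = None          # INS
    element: str | None = None           # MOB
    element_length: int | None = None    # MOB
    strand: str | None = None            # MOB insertion orientation
    duplication_size: int = DEFAULT_TSD  # MOB target-site duplication

    def __post_init__(self) -> None:
        if self.type not in SUPPORTED_TYPES:
            raise GenomeDiffError(f"unsupported mutation type {self.type!r} (record {self.id})")
        if self.position < 1:
            raise GenomeDiffError(f"position must be 1-based positive (record {self.id})")
        if self.type == "SNP" and not self.new_base:
            raise GenomeDiffError(f"SNP record {self.id} lacks new_base")
        if self.type == "DEL" and (self.size is None or self.size < 1):
            raise GenomeDiffError(f"DEL record {self.id} needs size >= 1")
        if self.type == "INS" and not self.sequence:
            raise GenomeDiffError(f"INS record {self.id} lacks inserted sequence")
        if self.type == "MOB":
            if not self.element or self.element_length is None or self.element_length < 1:
                raise GenomeDiffError(f"MOB record {self.id} needs element name and length >= 1")
            if self.strand not in ("+", "-"):
                raise GenomeDiffError(f"MOB record {self.id} needs strand +/-")
            if self.duplication_size < 0:
                raise GenomeDiffError(f"MOB record {self.id} has negative duplication size")

    # ---------------------------------------------------------------- spans

    def footprint(self) -> tuple[int, int]:
        """Ancestral bases altered/claimed by this event (0-based half-open).

        INS inserts *after* ``position`` (breseq dialect) and claims no
        ancestral base beyond the anchor; MOB claims its target-site
        duplication, which starts at ``position``.
        """
        p0 = self.position - 1
        if self.type == "SNP":
            return (p0, p0 + 1)
        if self.type == "DEL":
            return (p0, p0 + self.size)
        if self.type == "INS":
            return (p0 + 1, p0 + 1)  # zero-width anchor after position
        # MOB: duplicated target bases
        return (p0, p0 + self.duplication_size)

    def size_change(self) -> int:
        """Net evolved-minus-ancestral length change."""
        if self.type == "SNP":
            return 0
        if self.type == "DEL":
            return -self.size
        if self.type == "INS":
            return len(self.sequence)
        return self.element_length + self.duplication_size

    @property
    def is_small_indel(self) -> bool:
        return (self.type == "INS") or (self.type == "DEL" and self.size <= 10)


# --------------------------------------------------------------------- I/O


def parse_genomediff(path: str | Path) -> tuple[list[MutationRecord], int]:
    """Parse the simplified GenomeDiff dialect.

    Returns ``(records, skipped)`` where ``skipped`` counts unknown record
    types that were reported and ignored.
    """
    records: list[MutationRecord] = []
    skipped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise GenomeDiffError(f"line {lineno}: expected at least 3 columns")
            mtype, mid, pos_s = cols[0], cols[1], cols[2]
            if mtype not in SUPPORTED_TYPES:
                skipped += 1
                continue
            try:
                position = int(pos_s)
            except ValueError as exc:
                raise GenomeDiffError(f"line {lineno}: malformed coordinate {pos_s!r}") from exc
            if position < 1:
                raise GenomeDiffError(f"line {lineno}: coordinate must be >= 1")
            try:
                if mtype == "SNP":
                    rec = MutationRecord(id=mid, type="SNP", position=position, new_base=cols[3])
                elif mtype == "DEL":
                    size = int(cols[3])
                    if size < 1:
                        raise GenomeDiffError(f"line {lineno}: negative or zero DEL size")
                    rec = MutationRecord(id=mid, type="DEL", position=position, size=size)
                elif mtype == "INS":
                    rec = MutationRecord(id=mid, type="INS", position=position, sequence=cols[3])
                else:  # MOB
                    rec = MutationRecord(
                        id=mid,
                        type="MOB",
                        position=position,
                        element=cols[3],
                        element_length=int(cols[4]),
                        strand=cols[5],
                        duplication_size=int(cols[6]) if len(cols) > 6 else DEFAULT_TSD,
                    )
            except (IndexError, ValueError) as exc:
                if isinstance(exc, GenomeDiffError):
                    raise
                raise GenomeDiffError(f"line {lineno}: malformed record: {exc}") from exc
            records.append(rec)
    return records, skipped


def write_genomediff(records: list[MutationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(GENOMEDIFF_HEADER + "\n")
        for r in records:
            if r.type == "SNP":
                fh.write(f"SNP\t{r.id}\t{r.position}\t{r.new_base}\n")
            elif r.type == "DEL":
                fh.write(f"DEL\t{r.id}\t{r.position}\t{r.size}\n")
            elif r.type == "INS":
                fh.write(f"INS\t{r.id}\t{r.position}\t{r.sequence}\n")
            else:
                fh.write(
                    f"MOB\t{r.id}\t{r.position}\t{r.element}\t{r.element_length}"
                    f"\t{r.strand}\t{r.duplication_size}\n"
                )


# ----------------------------------------------------------- coordinate map


@dataclass(frozen=True)
class Segment:
    """One ancestral<->evolved correspondence.

    ``kind`` is one of ``mapped`` (1:1, possibly substituted), ``deleted``
    (ancestral-only) or ``inserted`` (evolved-only material).
    """

    anc_start: int
    anc_end: int
    evo_start: int
    evo_end: int
    kind: str


@dataclass(frozen=True)
class LiftResult:
    start: int | None
    end: int | None
    status: str               # clean | contains-indel | deleted | partial
    indel: int = 0            # largest net inserted/deleted span inside the interval


@dataclass
class CoordinateMap:
    """Ordered ancestral<->evolved interval correspondences for one clone."""

    segments: list[Segment]
    anc_length: int
    evo_length: int
    mutations: list[MutationRecord] = field(default_factory=list)

    # -------------------------------------------------------------- queries

    def _check(self, start: int, end: int) -> None:
        if not (0 <= start <= end <= self.anc_length):
            raise ValueError(
                f"interval [{start}, {end}) outside ancestral genome of length {self.anc_length}"
            )

    def lift_interval(self, start: int, end: int) -> LiftResult:
        """Map an ancestral interval to the evolved genome.

        ``clean`` iff no mutation intersects the interval; ``contains-indel``
        reports the largest net inserted/deleted span among intersecting
        events; ``deleted`` iff every base of the interval was removed;
        ``partial`` if the interval straddles a deletion boundary such that
        only some bases survive (also carries the indel size).
        """
        self._check(start, end)
        evo_lo: int | None = None
        evo_hi: int | None = None
        surviving = 0
        for seg in self.segments:
            if seg.kind == "inserted":
                continue
            lo = max(seg.anc_start, start)
            hi = min(seg.anc_end, end)
            if lo >= hi:
                continue
            if seg.kind == "mapped":
                e_lo = seg.evo_start + (lo - seg.anc_start)
                e_hi = seg.evo_start + (hi - seg.anc_start)
                evo_lo = e_lo if evo_lo is None else min(evo_lo, e_lo)
                evo_hi = e_hi if evo_hi is None else max(evo_hi, e_hi)
                surviving += hi - lo
        # classify against the mutation list
        indel = 0
        touched = False
        for m in self.mutations:
            f_lo, f_hi = m.footprint()
            if f_lo == f_hi:  # zero-width INS anchor: intersects if inside (start, end)
                inside = start < f_lo < end
            else:
                inside = max(f_lo, start) < min(f_hi, end)
            if inside:
                touched = True
                indel = max(indel, abs(m.size_change()))
        if surviving == 0:
            return LiftResult(None, None, "deleted", indel)
        if not touched:
            return LiftResult(evo_lo, evo_hi, "clean", 0)
        if surviving < end - start:
            return LiftResult(evo_lo, evo_hi, "partial", indel)
        return LiftResult(evo_lo, evo_hi, "contains-indel", indel)

    def lift_back(self, start: int, end: int) -> LiftResult:
        """Map an evolved interval back to ancestral coordinates."""
        if not (0 <= start <= end <= self.evo_length):
            raise ValueError(
                f"interval [{start}, {end}) outside evolved genome of length {self.evo_length}"
            )
        anc_lo: int | None = None
        anc_hi: int | None = None
        surviving = 0
        inserted = 0
        for seg in self.segments:
            if seg.kind == "deleted":
                continue
            lo = max(seg.evo_start, start)
            hi = min(seg.evo_end, end)
            if lo >= hi:
                continue
            if seg.kind == "mapped":
                a_lo = seg.anc_start + (lo - seg.evo_start)
                a_hi = seg.anc_start + (hi - seg.evo_start)
                anc_lo = a_lo if anc_lo is None else min(anc_lo, a_lo)
                anc_hi = a_hi if anc_hi is None else max(anc_hi, a_hi)
                surviving += hi - lo
            else:
                inserted += hi - lo
        if surviving == 0:
            return LiftResult(None, None, "deleted", inserted)
        if inserted == 0 and surviving == end - start:
            return LiftResult(anc_lo, anc_hi, "clean", 0)
        return LiftResult(anc_lo, anc_hi, "contains-indel", inserted)


def identity_map(length: int) -> CoordinateMap:
    return CoordinateMap(
        segments=[Segment(0, length, 0, length, "mapped")], anc_length=length, evo_length=length
    )


# ------------------------------------------------------------- application


def _oriented_element(seq: str, strand: str) -> str:
    return seq if strand == "+" else reverse_complement(seq)


def apply_mutations(
    genome: GenomeRecord,
    mutations: list[MutationRecord],
    element_sequences: dict[str, str] | None = None,
) -> tuple[str, CoordinateMap]:
    """Build the evolved sequence and its coordinate map.

    Mutations must be mutually non-overlapping; overlaps raise
    :class:`MutationConflictError` listing the offending ids.  MOB records
    need their element sequence in ``element_sequences``.
    """
    L = genome.length
    element_sequences = element_sequences or {}

    for m in mutations:
        lo, hi = m.footprint()
        if not (0 <= lo <= hi <= L) or m.position > L:
            raise ValueError(f"mutation {m.id} position {m.position} out of range (genome {L} bp)")
        if m.type == "DEL" and m.size >= L:
            raise ValueError(f"mutation {m.id} would delete the entire genome")

    ordered = sorted(mutations, key=lambda m: m.footprint())
    for a, b in zip(ordered, ordered[1:]):
        a_lo, a_hi = a.footprint()
        b_lo, b_hi = b.footprint()
        # zero-width INS anchors may coincide with interval ends but not interiors
        if max(a_lo, b_lo) < min(a_hi, b_hi) or (b_lo == b_hi and a_lo < b_lo < a_hi):
            raise MutationConflictError(f"mutations overlap on ancestral genome: {a.id}, {b.id}")

    seq_parts: list[str] = []
    segments: list[Segment] = []
    anc_cursor = 0
    evo_cursor = 0

    def emit_mapped(upto: int) -> None:
        nonlocal anc_cursor, evo_cursor
        if upto > anc_cursor:
            seq_parts.append(genome.sequence[anc_cursor:upto])
            n = upto - anc_cursor
            segments.append(Segment(anc_cursor, upto, evo_cursor, evo_cursor + n, "mapped"))
            anc_cursor = upto
            evo_cursor += n

    for m in ordered:
        p0 = m.position - 1
        if m.type == "SNP":
            emit_mapped(p0)
            seq_parts.append(m.new_base)
            segments.append(Segment(p0, p0 + 1, evo_cursor, evo_cursor + 1, "mapped"))
            anc_cursor = p0 + 1
            evo_cursor += 1
        elif m.type == "DEL":
            emit_mapped(p0)
            segments.append(Segment(p0, p0 + m.size, evo_cursor, evo_cursor, "deleted"))
            anc_cursor = p0 + m.size
        elif m.type == "INS":
            emit_mapped(p0 + 1)  # inserts after position
            ins = m.sequence
            seq_parts.append(ins)
            segments.append(
                Segment(anc_cursor, anc_cursor, evo_cursor, evo_cursor + len(ins), "inserted")
            )
            evo_cursor += len(ins)
        else:  # MOB
            dup = m.duplication_size
            emit_mapped(p0 + dup)  # target site (first copy of the duplication)
            try:
                elem = element_sequences[m.element]
            except KeyError as exc:
                raise KeyError(f"no sequence provided for element {m.element!r}") from exc
            if len(elem) != m.element_length:
                raise ValueError(
                    f"element {m.element!r} sequence length {len(elem)} != declared "
                    f"{m.element_length} (record {m.id})"
                )
            ins = _oriented_element(elem, m.strand) + genome.sequence[p0 : p0 + dup]
            seq_parts.append(ins)
            segments.append(
                Segment(anc_cursor, anc_cursor, evo_cursor, evo_cursor + len(ins), "inserted")
            )
            evo_cursor += len(ins)

    emit_mapped(L)
    evolved = "".join(seq_parts)
    cmap = CoordinateMap(
        segments=segments, anc_length=L, evo_length=len(evolved), mutations=list(mutations)
    )
    expected = L + sum(m.size_change() for m in mutations)
    assert cmap.evo_length == expected, "length bookkeeping violated"
    return evolved, cmap
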