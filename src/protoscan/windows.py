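"""Fixed-width strand-aware genome windows: partition, filter, categorize.

The ancestral genome is tiled into fixed-width windows on both strands
(step defaults to the window size, i.e. non-overlapping tiling — the only
reading consistent with ~18.7k windows of 400 bp over a 4.6-Mb genome on
both strands).  Windows are then screened against every evolved clone's
coordinate map and against repeat/IS annotations, and the survivors are
categorized as annotated / antisense / intergenic with a gene-adjacency
flag for the non-genic classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .engineering import CoordinateMap, LiftResult
from .genome import Feature, GENIC_KINDS, REPEAT_KINDS, STRANDS

CATEGORIES = ("annotated", "antisense", "intergenic")

#: same-strand gene overlap (bp) beyond which a window counts as annotated;
#: the rule is strict (> OVERLAP_BP), ties go non-genic
OVERLAP_BP = 10
#: net indel size (bp) beyond which a window is dropped in a clone (strict >)
MAX_INDEL_BP = 10
UPSTREAM_BP = 300
DOWNSTREAM_BP = 100


@dataclass
class Window:
    """One fixed-width strand-aware interval on the ancestral genome."""

    id: str
    start: int
    end: int
    strand: str
    category: str | None = None
    gene_adjacent: bool | None = None
    lifted: dict[str, LiftResult] = field(default_factory=dict)
    drop_reason: str | None = None
    drop_clone: str | None = None

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def dropped(self) -> bool:
        return self.drop_reason is not None


@dataclass
class WindowSet:
    windows: list[Window]
    window_size: int
    genome_id: str = "ancestor"
    step: int | None = None

    def __iter__(self):
        return iter(self.windows)

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def surviving(self) -> list[Window]:
        return [w for w in self.windows if not w.dropped]

    def tallies(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for w in self.surviving:
            if w.category is not None:
                out[w.category] += 1
        return out

    def write_tsv(self, path) -> None:
        cols = "chrom start end window_id score strand category gene_adjacent drop_reason".split()
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for w in self.windows:
                fh.write(
                    f"{self.genome_id}\t{w.start}\t{w.end}\t{w.id}\t0\t{w.strand}"
                    f"\t{w.category or '.'}\t{'' if w.gene_adjacent is None else int(w.gene_adjacent)}"
                    f"\t{w.drop_reason or '.'}\n"
                )


def partition_windows(
    genome_length: int, window_size: int = 400, step: int | None = None, genome_id: str = "ancestor"
) -> WindowSet:
    """Tile both strands with windows of ``window_size``.

    The terminal partial window is dropped, so each strand carries
    ``floor((L - window_size) / step) + 1`` windows (``= floor(L/size)``
    for the default tiling step).
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if window_size > genome_length:
        raise ValueError(
            f"window_size {window_size} exceeds genome length {genome_length}"
        )
    step = step or window_size
    starts = range(0, genome_length - window_size + 1, step)
    windows = [
        Window(id=f"w{strand}{i:06d}", start=s, end=s + window_size, strand=strand)
        for strand in STRANDS
        for i, s in enumerate(starts)
    ]
    return WindowSet(windows=windows, window_size=window_size, genome_id=genome_id, step=step)


def filter_windows(
    windows: WindowSet,
    clone_maps: dict[str, CoordinateMap],
    annotations: list[Feature] | None = None,
    max_indel: int = MAX_INDEL_BP,
) -> WindowSet:
    """Apply the retention filters against every clone.

    A window is dropped if, in any clone, it is deleted or carries a net
    indel > ``max_indel`` bp, or if it overlaps an annotated IS/repeat
    region by >= 1 bp on either strand.  Survivors carry lifted coordinates
    for every clone.  The multi-mapping filter of aligner-based workflows
    is a no-op under exact liftover (duplications are unsupported) and is
    intentionally absent.
    """
    repeats = [f for f in (annotations or []) if f.kind in REPEAT_KINDS]
    for w in windows:
        w.drop_reason = None
        w.drop_clone = None
        w.lifted = {}
        hit = next((r for r in repeats if r.overlap(w.start, w.end) >= 1), None)
        if hit is not None:
            w.drop_reason = "repeat-overlap"
            continue
        for clone, cmap in clone_maps.items():
            res = cmap.lift_interval(w.start, w.end)
            w.lifted[clone] = res
            if res.status == "deleted":
                w.drop_reason = "deleted"
                w.drop_clone = clone
                break
            if res.indel > max_indel:
                w.drop_reason = f"indel>{max_indel}bp"
                w.drop_clone = clone
                break
    return windows


def _flanks(gene: Feature, upstream: int, downstream: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """(upstream flank, downstream flank) intervals for a gene, strand-aware."""
    if gene.strand == "+":
        return (gene.start - upstream, gene.start), (gene.end, gene.end + downstream)
    return (gene.end, gene.end + upstream), (gene.start - downstream, gene.start)


def categorize_windows(
    windows: WindowSet,
    annotations: list[Feature],
    overlap_bp: int = OVERLAP_BP,
    upstream: int = UPSTREAM_BP,
    downstream: int = DOWNSTREAM_BP,
) -> WindowSet:
    """Assign each window exactly one of annotated / antisense / intergenic.

    ``annotated``: same-strand overlap > ``overlap_bp`` with any annotated
    gene (coding, RNA or pseudogene); ``antisense``: >= 1 bp opposite-strand
    overlap with a protein-coding gene; else ``intergenic``.  Non-genic
    windows additionally get ``gene_adjacent`` if they touch the 300-bp
    upstream or 100-bp downstream flank of a same-strand annotated gene.
    Gene extents are the coding sequence as annotated.
    """
    genes = [f for f in annotations if f.kind in GENIC_KINDS]
    coding = [f for f in annotations if f.kind == "gene"]
    for f in annotations:
        if f.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {f.strand!r}")
    for w in windows:
        same = [g for g in genes if g.strand == w.strand]
        if any(g.overlap(w.start, w.end) > overlap_bp for g in same):
            w.category = "annotated"
            w.gene_adjacent = None
            continue
        if any(g.overlap(w.start, w.end) >= 1 for g in coding if g.strand != w.strand):
            w.category = "antisense"
        else:
            w.category = "intergenic"
        adj = False
        for g in same:
            for lo, hi in _flanks(g, upstream, downstream):
                lo = max(lo, 0)
                if lo < hi and min(w.end, hi) - max(w.start, lo) >= 1:
                    adj = True
        w.gene_adjacent = adj
    return windows
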