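"""The proto-gene detection cascade.

A proto-gene here is a previously silent region that gained transcription
immediately downstream of a new mutation.  The cascade, run per evolved
clone: extract 100- and 200-bp regions downstream of every mutation (both
strands, except mobile-element insertions whose outward promoter fixes the
strand) -> drop regions with >10-bp same-strand overlap with annotated
genes/RNA genes/pseudogenes/repeats -> NB Wald test against the ancestor on
the combined regions+genes transcriptome -> deduplicate -> require
ancestral silence (quantitative coverage rule) -> require absence of
expression across an external condition library -> classify the causal
mutation -> scan the surrounding sequence for ORFs.

Each candidate carries its full filter trail; an excluded candidate names
exactly one deciding filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .diffexp import DEResults, NBWaldDE
from .engineering import CoordinateMap, MutationRecord
from .genome import Feature, GENIC_KINDS, GenomeRecord, REPEAT_KINDS, reverse_complement
from .quantify import CountMatrix

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

CAUSE_IS_PROMOTER = "promoter in insertion sequence"
CAUSE_TRANSLOCATION = "translocation to existing promoter"
CAUSE_UNKNOWN = "point mutation or small indel (promoter status unknown)"
CAUSE_LARGE_DEL_NO_PROMOTER = "large deletion (no upstream promoter identified)"


@dataclass
class DetectionParams:
    """Tunable thresholds of the cascade (defaults follow the study design)."""

    alpha: float = 0.05                 # BH-adjusted Wald threshold, transcription
    q_threshold: float = 0.01           # differential-translation q threshold
    lengths: tuple[int, ...] = (100, 200)
    overlap_bp: int = 10                # strict > rule for same-strand overlaps
    min_reads_condition: int = 3        # "seen" if >= this in any condition
    silent_frac: float = 0.1            # t_silent = max(frac x median coverage, floor)
    expr_frac: float = 1.0              # t_expr = max(frac x median coverage, floor)
    coverage_floor: float = 1.0         # reads per base
    run_len: int = 25                   # contiguous covered run that voids silence (bp)
    run_cov: int = 3                    # coverage depth defining such a run
    min_count: int = 2                  # DE low-count skip threshold
    require_both_lengths: bool = False  # strict mode: 100- and 200-bp must both be significant
    large_del_threshold: int = 1000     # bp; deletions at least this size can translocate
    promoter_search_bp: int = 500       # upstream scan for a promoter-bearing gene
    orf_min_len: int = 30               # strictly > this many bp
    orf_upstream: int = 200
    orf_downstream: int = 500


@dataclass
class CandidateRegion:
    """One mutation-downstream region with its filter trail."""

    mutation_id: str
    clone: str
    strand: str
    length: int
    evo_start: int
    evo_end: int
    anc_start: int | None = None
    anc_end: int | None = None
    truncated: bool = False
    trail: list[tuple[str, str, str]] = field(default_factory=list)
    excluded_by: str | None = None
    significant: bool | None = None
    log2fc: float | None = None
    padj: float | None = None
    silence: str | None = None
    condition: str | None = None

    @property
    def feature_id(self) -> str:
        return f"{self.mutation_id}|{self.strand}|{self.length}"

    @property
    def excluded(self) -> bool:
        return self.excluded_by is not None

    def record(self, stage: str, verdict: str, detail: str = "") -> None:
        self.trail.append((stage, verdict, detail))
        if verdict == "excluded" and self.excluded_by is None:
            self.excluded_by = stage


# ------------------------------------------------------------- extraction


def _evo_point(cmap: CoordinateMap, anc_pos: int) -> int:
    """Evolved coordinate of the first surviving base at/after ``anc_pos``."""
    if anc_pos >= cmap.anc_length:
        return cmap.evo_length
    res = cmap.lift_interval(anc_pos, anc_pos + 1)
    if res.start is not None:
        return res.start
    # base deleted: walk right to the junction
    for seg in cmap.segments:
        if seg.kind == "mapped" and seg.anc_start >= anc_pos:
            return seg.evo_start
    return cmap.evo_length


def _mutation_anchors(m: MutationRecord, cmap: CoordinateMap) -> dict[str, int]:
    """Evolved-genome anchor point(s) for downstream extraction.

    The anchor is the first base after the mutation's footprint in the
    evolved genome, per strand (reading direction).  MOB events anchor only
    on the promoter-bearing side of the inserted element.
    """
    p0 = m.position - 1
    if m.type == "MOB":
        dup = m.duplication_size
        # ancestral base p0+dup is the first one mapped after the inserted
        # material (element + second duplication copy)
        ins_end = _evo_point(cmap, p0 + dup)
        ins_start = ins_end - (m.element_length + dup)
        if m.strand == "+":
            return {"+": ins_end}
        return {"-": ins_start}
    lo, hi = m.footprint()
    if m.type == "INS":
        # ancestral base p0+1 maps to just after the inserted bases;
        # ancestral base p0 maps to just before them
        return {"+": _evo_point(cmap, p0 + 1), "-": _evo_point(cmap, p0) + 1}
    # SNP / DEL: plus-strand anchor after the footprint, minus before it
    return {"+": _evo_point(cmap, hi), "-": _evo_point(cmap, lo)}


def extract_downstream_regions(
    mutations: list[MutationRecord],
    cmap: CoordinateMap,
    lengths: tuple[int, ...] = (100, 200),
    clone: str = "evolved",
) -> list[CandidateRegion]:
    """100-/200-bp regions immediately downstream of each mutation.

    Non-MOB mutations yield regions on both strands; MOB insertions only on
    the strand read outward from the element's promoter-bearing end.
    Regions running off a genome end are truncated and flagged.
    """
    regions: list[CandidateRegion] = []
    for m in mutations:
        anchors = _mutation_anchors(m, cmap)
        for strand, anchor in anchors.items():
            for length in lengths:
                if strand == "+":
                    start, end = anchor, anchor + length
                else:
                    start, end = anchor - length, anchor
                t_start, t_end = max(0, start), min(cmap.evo_length, end)
                truncated = (t_start, t_end) != (start, end)
                if t_start >= t_end:
                    continue
                reg = CandidateRegion(
                    mutation_id=m.id,
                    clone=clone,
                    strand=strand,
                    length=length,
                    evo_start=t_start,
                    evo_end=t_end,
                    truncated=truncated,
                )
                back = cmap.lift_back(t_start, t_end)
                reg.anc_start, reg.anc_end = back.start, back.end
                reg.record("extracted", "ok", "truncated" if truncated else "")
                regions.append(reg)
    return regions


# ---------------------------------------------------------------- filters


def filter_candidate_overlaps(
    regions: list[CandidateRegion],
    annotations: list[Feature],
    overlap_bp: int = 10,
) -> list[CandidateRegion]:
    """Exclude regions with >``overlap_bp`` same-strand overlap with any
    annotated gene, RNA gene, pseudogene or repeat (ancestral coordinates).
    """
    listed = [f for f in annotations if f.kind in (GENIC_KINDS | REPEAT_KINDS)]
    for reg in regions:
        if reg.excluded:
            continue
        if reg.anc_start is None:
            reg.record("overlap-filter", "ok", "no ancestral coordinates")
            continue
        hit = next(
            (
                f
                for f in listed
                if f.strand == reg.strand and f.overlap(reg.anc_start, reg.anc_end) > overlap_bp
            ),
            None,
        )
        if hit is not None:
            ov = hit.overlap(reg.anc_start, reg.anc_end)
            reg.record("overlap-filter", "excluded", f"{ov} bp same-strand with {hit.name}")
        else:
            reg.record("overlap-filter", "ok")
    return regions


def dedup_regions(
    regions: list[CandidateRegion], annotations: list[Feature]
) -> list[CandidateRegion]:
    """Post-test deduplication.

    Regions with identical evolved coordinates and strand (adjacent
    mutations counted twice) keep only the first in genome order; regions
    overlapping a repeat on the opposite strand are excluded.
    """
    repeats = [f for f in annotations if f.kind in REPEAT_KINDS]
    seen: dict[tuple, str] = {}
    for reg in sorted(
        (r for r in regions if not r.excluded),
        key=lambda r: (r.anc_start if r.anc_start is not None else r.evo_start, r.strand),
    ):
        key = (reg.evo_start, reg.evo_end, reg.strand)
        if key in seen:
            reg.record("dedup", "excluded", f"duplicate of {seen[key]}")
            continue
        seen[key] = reg.feature_id
        if reg.anc_start is not None:
            hit = next(
                (
                    f
                    for f in repeats
                    if f.strand != reg.strand and f.overlap(reg.anc_start, reg.anc_end) >= 1
                ),
                None,
            )
            if hit is not None:
                reg.record("dedup", "excluded", f"opposite-strand repeat {hit.name}")
                continue
        reg.record("dedup", "ok")
    return regions


# ---------------------------------------------------------------- testing


def test_candidates(
    regions: list[CandidateRegion],
    counts: CountMatrix,
    groups: pd.Series,
    reference: str = "ancestor",
    params: DetectionParams | None = None,
) -> DEResults:
    """NB Wald test on the combined regions+genes transcriptome.

    ``counts`` must cover every surviving region's ``feature_id`` plus the
    annotated genes (one normalization universe).  A region is significant
    iff padj < alpha AND log2FC > 0 (increases only).
    """
    params = params or DetectionParams()
    missing = [r.feature_id for r in regions if not r.excluded and r.feature_id not in counts.features]
    if missing:
        raise KeyError(f"count matrix lacks candidate features: {missing[:5]} ...")
    res = NBWaldDE(
        counts, groups, reference=reference, min_count=params.min_count, alpha=params.alpha
    ).fit()
    t = res.table
    for reg in regions:
        if reg.excluded:
            continue
        row = t.loc[reg.feature_id]
        reg.log2fc = float(row["log2FoldChange"]) if pd.notna(row["log2FoldChange"]) else None
        reg.padj = float(row["padj"]) if pd.notna(row["padj"]) else None
        reg.significant = bool(
            row["status"] == "tested"
            and pd.notna(row["padj"])
            and row["padj"] < params.alpha
            and row["log2FoldChange"] > 0
        )
        reg.record(
            "de-test",
            "significant" if reg.significant else "not-significant",
            f"padj={reg.padj}, log2FC={reg.log2fc}",
        )
    return res


# ------------------------------------------------------ ancestral coverage


@dataclass
class CoverageTracks:
    """Per-base, per-replicate, strand-aware coverage on one genome."""

    plus: np.ndarray   # (replicates, L)
    minus: np.ndarray  # (replicates, L)

    def __post_init__(self) -> None:
        self.plus = np.atleast_2d(np.asarray(self.plus, dtype=float))
        self.minus = np.atleast_2d(np.asarray(self.minus, dtype=float))
        self._medians: dict[str, np.ndarray] | None = None

    def strand(self, strand: str) -> np.ndarray:
        return self.plus if strand == "+" else self.minus

    def medians(self, strand: str) -> np.ndarray:
        """Genome-wide per-base median coverage, per replicate."""
        if self._medians is None:
            self._medians = {
                "+": np.median(self.plus, axis=1),
                "-": np.median(self.minus, axis=1),
            }
        return self._medians[strand]

    def write_bedgraph(self, path, strand: str, replicate: int = 0, chrom: str = "ancestor") -> None:
        cov = self.strand(strand)[replicate]
        edges = np.flatnonzero(np.diff(cov)) + 1
        starts = np.r_[0, edges]
        ends = np.r_[edges, len(cov)]
        with open(path, "w") as fh:
            for s, e in zip(starts, ends):
                if cov[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{cov[s]:g}\n")


def _longest_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.r_[False, mask, False].astype(int)
    edges = np.diff(padded)
    return int((np.flatnonzero(edges == -1) - np.flatnonzero(edges == 1)).max())


def ancestral_silence_check(
    region: CandidateRegion,
    coverage: CoverageTracks,
    params: DetectionParams | None = None,
) -> str:
    """Quantitative stand-in for visual inspection of coverage plots.

    silent: in ALL ancestral replicates, mean per-base coverage over the
    region is below ``max(silent_frac x genome-wide median, coverage_floor)``
    AND no contiguous run of >= ``run_len`` bp reaches ``run_cov`` reads.
    expressed: mean coverage >= ``max(expr_frac x median, coverage_floor)``
    in any replicate.  Otherwise ambiguous.
    """
    params = params or DetectionParams()
    if region.anc_start is None or region.anc_end is None:
        raise ValueError(f"region {region.feature_id} has no ancestral coordinates")
    tracks = coverage.strand(region.strand)
    meds = coverage.medians(region.strand)
    sub = tracks[:, region.anc_start : region.anc_end]
    if sub.shape[1] == 0:
        raise ValueError(f"missing coverage for region {region.feature_id}")
    means = sub.mean(axis=1)
    t_silent = np.maximum(params.silent_frac * meds, params.coverage_floor)
    t_expr = np.maximum(params.expr_frac * meds, params.coverage_floor)
    runs = np.array([_longest_run(rep >= params.run_cov) for rep in sub])
    if (means < t_silent).all() and (runs < params.run_len).all():
        return "silent"
    if (means >= t_expr).any():
        return "expressed"
    return "ambiguous"


def cross_condition_filter(
    region: CandidateRegion,
    condition_counts: CountMatrix,
    params: DetectionParams | None = None,
) -> str:
    """``seen`` iff the region has >= ``min_reads_condition`` reads in at
    least one external condition (per-condition rule, no pooling)."""
    params = params or DetectionParams()
    if region.feature_id not in condition_counts.features:
        raise KeyError(f"no condition counts for {region.feature_id}")
    row = condition_counts.counts.loc[region.feature_id]
    return "seen" if (row >= params.min_reads_condition).any() else "unseen"


# ----------------------------------------------------------------- causes


def classify_cause(
    mutation: MutationRecord,
    genome: GenomeRecord,
    region_strand: str,
    params: DetectionParams | None = None,
) -> str:
    """Assign the route by which transcription was gained."""
    params = params or DetectionParams()
    if mutation.type == "MOB":
        return CAUSE_IS_PROMOTER
    if mutation.type == "DEL" and mutation.size >= params.large_del_threshold:
        p0 = mutation.position - 1
        if region_strand == "+":
            lo, hi = p0 - params.promoter_search_bp, p0
            found = any(
                g.strand == "+" and lo <= g.end <= hi for g in genome.genes
            )
        else:
            lo, hi = p0 + mutation.size, p0 + mutation.size + params.promoter_search_bp
            found = any(
                g.strand == "-" and lo <= g.start <= hi for g in genome.genes
            )
        return CAUSE_TRANSLOCATION if found else CAUSE_LARGE_DEL_NO_PROMOTER
    return CAUSE_UNKNOWN


# ------------------------------------------------------------------- ORFs


@dataclass(frozen=True)
class Orf:
    start: int   # 0-based offset in the scanned sequence
    end: int     # half-open, includes the stop codon
    frame: int

    @property
    def length(self) -> int:
        return self.end - self.start


def find_orfs(sequence: str, min_len: int = 30) -> list[Orf]:
    """Maximal ORFs (first start codon after the previous in-frame stop to
    the stop codon, inclusive), in all three frames of the given strand.

    Start codons: ATG/GTG/TTG; reported lengths include the stop codon and
    must be strictly greater than ``min_len`` bp.
    """
    seq = sequence.upper()
    orfs: list[Orf] = []
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if start is not None and (i + 3 - start) > min_len:
                    orfs.append(Orf(start=start, end=i + 3, frame=frame))
                start = None
            elif start is None and codon in START_CODONS:
                start = i
    return sorted(orfs, key=lambda o: (o.start, o.end))


def orfs_for_candidate(
    mutation_anchor: int,
    evolved_sequence: str,
    strand: str,
    params: DetectionParams | None = None,
) -> list[Orf]:
    """ORF scan from ``orf_upstream`` bp before the mutation anchor to
    ``orf_downstream`` bp after it, on the transcribed strand.

    ORFs lying entirely upstream of the anchor (not spanning the mutation)
    are discarded.  Offsets are in scanned-window coordinates, 5'->3' on the
    transcribed strand with the anchor at ``orf_upstream``.
    """
    params = params or DetectionParams()
    L = len(evolved_sequence)
    if strand == "+":
        lo = max(0, mutation_anchor - params.orf_upstream)
        hi = min(L, mutation_anchor + params.orf_downstream)
        window = evolved_sequence[lo:hi]
        anchor_off = mutation_anchor - lo
    else:
        lo = max(0, mutation_anchor - params.orf_downstream)
        hi = min(L, mutation_anchor + params.orf_upstream)
        window = reverse_complement(evolved_sequence[lo:hi])
        anchor_off = hi - mutation_anchor
    return [o for o in find_orfs(window, params.orf_min_len) if o.end > anchor_off]


# ---------------------------------------------------------------- cascade


@dataclass
class ProtoGeneResults:
    """Report plus per-candidate filter trail for one detection run."""

    report: pd.DataFrame
    trail: pd.DataFrame
    regions: list[CandidateRegion]
    de: DEResults
    candidates: pd.DataFrame
    ribo_report: pd.DataFrame | None = None

    @property
    def proto_genes(self) -> pd.DataFrame:
        return self.report

    def summary(self) -> str:
        n_regions = len(self.regions)
        n_sig = sum(bool(r.significant) for r in self.regions)
        lines = [
            "Proto-gene detection",
            f"  candidate regions extracted: {n_regions}",
            f"  regions with significant transcription increase: {n_sig}",
            f"  proto-genes reported: {len(self.report)}",
        ]
        if len(self.report):
            by_cause = self.report["cause"].value_counts()
            for cause, n in by_cause.items():
                lines.append(f"    {cause}: {n}")
        return "\n".join(lines)


class ProtoGeneDetection:
    """Model object for the detection cascade on one evolved clone.

    Parameters
    ----------
    genome : GenomeRecord
        The ancestral genome with annotations.
    mutations : list of MutationRecord
        The clone's mutation list (ancestral coordinates).
    coord_map : CoordinateMap
        Output of :func:`protoscan.engineering.apply_mutations`.
    counts : CountMatrix
        RNA counts over the combined regions+genes transcriptome; sample
        columns labelled by ``groups``.
    groups : mapping sample -> {"ancestor", "evolved"}
    evolved_sequence : str
        The clone's genome sequence (for the ORF scan).
    condition_counts : CountMatrix, optional
        Ancestor-genotype counts across external conditions.
    ancestral_coverage : CoverageTracks, optional
        Ancestral per-base RNA coverage for the silence rule.
    ribo_counts : CountMatrix, optional
        Ribosome-profiling counts; runs the same cascade for translation.
    """

    def __init__(
        self,
        genome: GenomeRecord,
        mutations: list[MutationRecord],
        coord_map: CoordinateMap,
        counts: CountMatrix,
        groups,
        evolved_sequence: str | None = None,
        condition_counts: CountMatrix | None = None,
        ancestral_coverage: CoverageTracks | None = None,
        ribo_counts: CountMatrix | None = None,
        clone: str = "evolved",
        params: DetectionParams | None = None,
    ) -> None:
        self.genome = genome
        self.mutations = {m.id: m for m in mutations}
        self.coord_map = coord_map
        self.counts = counts
        self.groups = pd.Series(groups)
        self.evolved_sequence = evolved_sequence
        self.condition_counts = condition_counts
        self.ancestral_coverage = ancestral_coverage
        self.ribo_counts = ribo_counts
        self.clone = clone
        self.params = params or DetectionParams()

    @classmethod
    def from_scenario(cls, scenario, params: DetectionParams | None = None) -> "ProtoGeneDetection":
        return cls(
            genome=scenario.genome,
            mutations=scenario.mutations,
            coord_map=scenario.coord_map,
            counts=scenario.rna_counts,
            groups=scenario.groups,
            evolved_sequence=scenario.evolved_sequence,
            condition_counts=scenario.condition_counts,
            ancestral_coverage=scenario.ancestral_coverage,
            ribo_counts=scenario.ribo_counts,
            clone=scenario.clone,
            params=params,
        )

    # ---------------------------------------------------------------- fit

    def fit(self) -> ProtoGeneResults:
        params = self.params
        muts = list(self.mutations.values())
        regions = extract_downstream_regions(muts, self.coord_map, params.lengths, self.clone)
        filter_candidate_overlaps(regions, self.genome.features, params.overlap_bp)
        de = test_candidates(regions, self.counts, self.groups, params=params)
        dedup_regions(regions, self.genome.features)

        ribo_sig: dict[str, bool] = {}
        if self.ribo_counts is not None:
            ribo_regions = [replace(r, trail=list(r.trail)) for r in regions]
            ribo_groups = (
                self.ribo_counts.samples["group"]
                if self.ribo_counts.samples is not None
                else self.groups
            )
            test_candidates(ribo_regions, self.ribo_counts, ribo_groups, params=params)
            ribo_sig = {r.feature_id: bool(r.significant) for r in ribo_regions}

        rows = []
        cand_rows = []
        by_unit: dict[tuple[str, str], list[CandidateRegion]] = {}
        for r in regions:
            by_unit.setdefault((r.mutation_id, r.strand), []).append(r)

        for (mid, strand), unit in sorted(
            by_unit.items(), key=lambda kv: self.mutations[kv[0][0]].position
        ):
            m = self.mutations[mid]
            live = [r for r in unit if not r.excluded]
            sig = [r for r in live if r.significant]
            if params.require_both_lengths and len(sig) < len(params.lengths):
                sig = []
            status, reason = "candidate", ""
            rep: CandidateRegion | None = None
            if not live:
                status, reason = "excluded", unit[0].excluded_by or "overlap-filter"
            elif not sig:
                status, reason = "excluded", "not-significant"
            else:
                # representative region: the 200-bp variant when significant,
                # else the significant 100-bp one
                rep = max(sig, key=lambda r: r.length)
                if self.ancestral_coverage is not None:
                    verdict = ancestral_silence_check(rep, self.ancestral_coverage, params)
                    for r in sig:
                        r.silence = verdict
                        r.record("silence-check", verdict)
                    if verdict != "silent":
                        status, reason = "excluded", f"ancestral-{verdict}"
                if status == "candidate" and self.condition_counts is not None:
                    verdict = cross_condition_filter(rep, self.condition_counts, params)
                    for r in sig:
                        r.condition = verdict
                        r.record("condition-screen", verdict)
                    if verdict == "seen":
                        status, reason = "excluded", "seen in condition library"

            cand_rows.append(
                {
                    "mutation_id": mid,
                    "strand": strand,
                    "mutation_type": m.type,
                    "position": m.position,
                    "n_regions": len(unit),
                    "n_significant": len(sig),
                    "status": "proto-gene" if status == "candidate" and sig else status,
                    "reason": reason,
                }
            )
            if status != "candidate" or not sig:
                continue

            cause = classify_cause(m, self.genome, strand, params)
            longest = None
            if self.evolved_sequence is not None:
                anchor = rep.evo_start if strand == "+" else rep.evo_end
                orfs = orfs_for_candidate(anchor, self.evolved_sequence, strand, params)
                longest = max((o.length for o in orfs), default=0)
            rows.append(
                {
                    "proto_gene_id": f"{self.clone}_{mid}_{m.type}",
                    "clone": self.clone,
                    "start_position_ancestral": m.position,
                    "mutation_type": m.type,
                    "strand": strand,
                    "cause": cause,
                    "log2FC": rep.log2fc,
                    "padj": rep.padj,
                    "orf_longest_bp": longest,
                    "novel_translation": ribo_sig.get(rep.feature_id, False),
                    "k12_catalog_verdict": pd.NA,  # user-supplied external screen
                }
            )

        report = pd.DataFrame(
            rows,
            columns=[
                "proto_gene_id",
                "clone",
                "start_position_ancestral",
                "mutation_type",
                "strand",
                "cause",
                "log2FC",
                "padj",
                "orf_longest_bp",
                "novel_translation",
                "k12_catalog_verdict",
            ],
        )
        trail = pd.DataFrame(
            [
                {
                    "feature_id": r.feature_id,
                    "stage": stage,
                    "verdict": verdict,
                    "detail": detail,
                }
                for r in regions
                for stage, verdict, detail in r.trail
            ]
        )
        candidates = pd.DataFrame(cand_rows)
        ribo_report = None
        if ribo_sig:
            ribo_report = pd.DataFrame(
                [
                    {"feature_id": fid, "ribo_significant": sig_}
                    for fid, sig_ in sorted(ribo_sig.items())
                ]
            )
        return ProtoGeneResults(
            report=report,
            trail=trail,
            regions=regions,
            de=de,
            candidates=candidates,
            ribo_report=ribo_report,
        )


# ----------------------------------------------------------------- survey


def survey_is_downstream(
    element: str,
    results: ProtoGeneResults,
    mutations: list[MutationRecord],
    coverage: CoverageTracks | None = None,
    params: DetectionParams | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Survey every insertion of ``element``: downstream DE verdict and
    ancestral-silence verdict, with summary counts."""
    params = params or DetectionParams()
    mob_ids = {m.id for m in mutations if m.type == "MOB" and m.element == element}
    rows = []
    for r in results.regions:
        if r.mutation_id not in mob_ids or r.length != max(params.lengths):
            continue
        silence = r.silence
        if silence is None and coverage is not None and r.anc_start is not None:
            silence = ancestral_silence_check(r, coverage, params)
        rows.append(
            {
                "mutation_id": r.mutation_id,
                "strand": r.strand,
                "significant": bool(r.significant),
                "silence": silence,
            }
        )
    table = pd.DataFrame(rows, columns=["mutation_id", "strand", "significant", "silence"])
    summary = {
        "total": len(table),
        "significant": int(table["significant"].sum()) if len(table) else 0,
        "significant_and_silent": int(
            ((table["significant"]) & (table["silence"] == "silent")).sum()
        )
        if len(table)
        else 0,
    }
    return table, summary


def run_detection(config, params: DetectionParams | None = None) -> ProtoGeneResults:
    """Simulate a synthetic scenario from ``config`` and run the cascade."""
    from .simulate import simulate_scenario

    scenario = simulate_scenario(config)
    return ProtoGeneDetection.from_scenario(scenario, params=params).fit()
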