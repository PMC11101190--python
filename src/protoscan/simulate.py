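"""Synthetic study generator: genome, mutations, expression, counts.

Emulates the data structure of a long-term bacterial evolution experiment
at desk scale so that every pipeline stage can be tested against planted
ground truth: a ~50-kb ancestral genome densely annotated with genes and
small intergenic gaps, a mutation spectrum dominated by SNPs and small
indels (95.7% by default) with rarer IS-element insertions and large
deletions, NB-distributed replicated RNA-seq/Ribo-seq counts with high
genic and near-zero non-genic expression, and a configurable number of
planted proto-gene events in which the region downstream of a mutation
gains strong transcription in the evolved clone.

Random streams are split per stage from the master seed, so changing one
stage's parameters does not perturb the draws of another.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detect import (
    CandidateRegion,
    CoverageTracks,
    extract_downstream_regions,
    filter_candidate_overlaps,
)
from .engineering import (
    CoordinateMap,
    MutationRecord,
    apply_mutations,
)
from .genome import Feature, GenomeRecord, REPEAT_KINDS
from .quantify import CountMatrix

MUTATION_CLASSES = ("snp", "small_indel", "mob", "large_del")

IS_ELEMENT = "IS150"
BASES = np.array(list("ACGT"))


class PlacementError(RuntimeError):
    """Requested annotations or mutations cannot be placed."""


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic scenario.

    Defaults mirror the emulated experiment: a 50-kb genome, 100 mutations
    with 95.7% SNP/small-indel mass, a 1,443-bp IS element, 5 planted
    proto-genes at 50-fold gain, 2 replicates per group, and a 34-condition
    external expression library with one condition-expressed plant.
    """

    genome_length: int = 50_000
    gene_count: int = 40
    gene_length_range: tuple[int, int] = (300, 900)
    intergenic_gap_range: tuple[int, int] = (50, 400)
    mutation_count: int = 100
    class_weights: dict[str, float] = field(
        default_factory=lambda: {
            "snp": 0.80,
            "small_indel": 0.157,
            "mob": 0.03,
            "large_del": 0.013,
        }
    )
    is_element_length: int = 1443
    large_del_range: tuple[int, int] = (1000, 4000)
    planted_protogene_count: int = 5
    planted_fold_change: float = 50.0
    planted_translated_count: int = 1
    baseline_genic_tpm: float = 100.0
    baseline_nongenic_tpm: float = 0.01
    genic_tpm_sigma: float = 0.5          # lognormal spread of genic expression
    region_te_factor: float = 0.2         # Ribo/RNA ratio for non-genic regions
    dispersion: float = 0.1               # NB2 alpha
    library_size: int = 1_200_000
    condition_library_size: int = 75_000
    read_length: int = 28
    replicates: int = 2
    condition_count: int = 34
    condition_expressed_count: int = 1
    condition_expressed_reads: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_weights must sum to 1 (got {total})")
        if unknown := set(self.class_weights) - set(MUTATION_CLASSES):
            raise ValueError(f"unknown mutation classes: {sorted(unknown)}")
        if self.planted_protogene_count > self.mutation_count:
            raise ValueError("planted_protogene_count exceeds mutation_count")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per group")
        if self.planted_fold_change < 1:
            raise ValueError("planted_fold_change must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k in ("gene_length_range", "intergenic_gap_range", "large_del_range"):
            d[k] = list(d[k])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("gene_length_range", "intergenic_gap_range", "large_del_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ["genome", "elements", "mutations", "model", "plant", "rna", "ribo", "conditions", "coverage"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


# ---------------------------------------------------------------- ancestor


def generate_ancestor(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenomeRecord:
    """Random ancestral genome with non-overlapping same-strand genes on
    both strands, at least one annotated repeat region, and small
    intergenic gaps.  Deterministic for a fixed seed."""
    rng = rng if rng is not None else _streams(config.seed)["genome"]
    L = config.genome_length
    lo_g, hi_g = config.gene_length_range
    if L < 10 * hi_g:
        raise PlacementError(f"genome_length {L} < 10 x max gene length {hi_g}")
    lo_gap, hi_gap = config.intergenic_gap_range

    feats: list[Feature] = []
    gaps: list[tuple[int, int]] = []
    cursor = int(rng.integers(lo_gap, hi_gap + 1))
    gaps.append((0, cursor))
    for i in range(config.gene_count):
        glen = int(rng.integers(lo_g, hi_g + 1))
        if cursor + glen > L:
            raise PlacementError(
                f"cannot place gene {i + 1}/{config.gene_count}: "
                f"{L - cursor} bp left, {glen} bp needed"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        feats.append(Feature(name=f"gene_{i:04d}", start=cursor, end=cursor + glen, strand=strand))
        cursor += glen
        gap = int(rng.integers(lo_gap, hi_gap + 1))
        gaps.append((cursor, min(cursor + gap, L)))
        cursor += gap
    if cursor < L:
        gaps[-1] = (gaps[-1][0], L)

    # repeat annotations inside the widest intergenic gaps
    wide = sorted((g for g in gaps if g[1] - g[0] >= 200), key=lambda g: g[0])
    chosen = [wide[k] for k in sorted(rng.choice(len(wide), size=min(2, len(wide)), replace=False))] if wide else []
    if not chosen:
        widest = max(gaps, key=lambda g: g[1] - g[0])
        if widest[1] - widest[0] < 20:
            raise PlacementError("no intergenic gap can host a repeat annotation")
        chosen = [widest]
    for j, (gs, ge) in enumerate(chosen):
        rlen = min(150, ge - gs - 10)
        strand = "+" if rng.random() < 0.5 else "-"
        feats.append(
            Feature(name=f"rep_{j:02d}", start=gs + 5, end=gs + 5 + rlen, strand=strand, kind="repeat")
        )

    seq = _random_seq(rng, L)
    return GenomeRecord(name=f"ancestor_seed{config.seed}", sequence=seq, features=feats)


def element_library(config: SimulationConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    rng = rng if rng is not None else _streams(config.seed)["elements"]
    return {IS_ELEMENT: _random_seq(rng, config.is_element_length)}


# --------------------------------------------------------------- mutations


def sample_mutations(
    genome: GenomeRecord,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[MutationRecord]:
    """Draw ``mutation_count`` mutually non-overlapping mutations with the
    configured class spectrum (positions uniform over the genome)."""
    rng = rng if rng is not None else _streams(config.seed)["mutations"]
    L = genome.length
    classes = [c for c in MUTATION_CLASSES if config.class_weights.get(c, 0) > 0]
    weights = np.array([config.class_weights[c] for c in classes])
    draws = rng.choice(len(classes), size=config.mutation_count, p=weights)
    # place large-footprint events first so they can still find room
    rank = {"large_del": 0, "mob": 1, "small_indel": 2, "snp": 3}
    order = sorted(range(len(draws)), key=lambda i: (rank[classes[draws[i]]], i))

    occupied: list[tuple[int, int]] = []

    def place(span: int, max_start: int, cls: str) -> int:
        for _ in range(1000):
            p0 = int(rng.integers(0, max_start + 1))
            if all(p0 + span <= s or p0 >= e for s, e in occupied):
                occupied.append((p0, p0 + span))
                return p0
        raise PlacementError(f"zero placeable positions for mutation class {cls!r}")

    records: list[MutationRecord] = []
    for i in order:
        cls = classes[draws[i]]
        mid = f"m{i:03d}"
        if cls == "snp":
            p0 = place(1, L - 1, cls)
            ref = genome.sequence[p0]
            new = str(rng.choice([b for b in "ACGT" if b != ref]))
            records.append(MutationRecord(id=mid, type="SNP", position=p0 + 1, new_base=new))
        elif cls == "small_indel":
            if rng.random() < 0.5:
                size = int(rng.integers(1, 11))
                p0 = place(size, L - size, cls)
                records.append(MutationRecord(id=mid, type="DEL", position=p0 + 1, size=size))
            else:
                seq = _random_seq(rng, int(rng.integers(1, 11)))
                p0 = place(1, L - 2, cls)
                records.append(MutationRecord(id=mid, type="INS", position=p0 + 1, sequence=seq))
        elif cls == "mob":
            dup = 3
            p0 = place(dup, L - dup - 1, cls)
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(
                MutationRecord(
                    id=mid,
                    type="MOB",
                    position=p0 + 1,
                    element=IS_ELEMENT,
                    element_length=config.is_element_length,
                    strand=strand,
                    duplication_size=dup,
                )
            )
        else:  # large_del
            lo, hi = config.large_del_range
            size = int(rng.integers(lo, hi + 1))
            size = min(size, L // 2)  # never delete the entire genome
            p0 = place(size, L - size, cls)
            records.append(MutationRecord(id=mid, type="DEL", position=p0 + 1, size=size))
    return records


# -------------------------------------------------------- expression model


@dataclass
class ExpressionModel:
    """Per-feature mean TPM per sample group, strand-aware, with a
    translation-efficiency factor linking Ribo-seq to RNA-seq means."""

    features: pd.DataFrame   # index feature_id: start, end, strand, length, kind, eligible
    rna: pd.DataFrame        # feature x group mean TPM
    te_factor: pd.Series     # Ribo mean = RNA mean x factor
    ribo: pd.DataFrame | None = None  # explicit Ribo means (overrides te_factor)

    def __post_init__(self) -> None:
        if (self.rna.to_numpy() < 0).any():
            raise ValueError("expression means must be >= 0")
        if self.ribo is None:
            self.ribo = self.rna.mul(self.te_factor, axis=0)

    def copy(self) -> "ExpressionModel":
        return ExpressionModel(
            features=self.features.copy(),
            rna=self.rna.copy(),
            te_factor=self.te_factor.copy(),
            ribo=self.ribo.copy(),
        )


def _region_eligible(reg: CandidateRegion, annotations: list[Feature]) -> bool:
    if reg.excluded or reg.truncated or reg.anc_start is None:
        return False
    repeats = [f for f in annotations if f.kind in REPEAT_KINDS]
    return not any(
        f.strand != reg.strand and f.overlap(reg.anc_start, reg.anc_end) >= 1 for f in repeats
    )


def build_expression_model(
    genome: GenomeRecord,
    regions: list[CandidateRegion],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ExpressionModel:
    """Baseline means: genic features around ``baseline_genic_tpm`` with
    lognormal spread, candidate regions at the near-zero non-genic
    baseline, identical in ancestor and evolved groups."""
    rng = rng if rng is not None else _streams(config.seed)["model"]
    rows = []
    means = []
    te = []
    for g in genome.genes:
        tpm = config.baseline_genic_tpm * rng.lognormal(0.0, config.genic_tpm_sigma)
        rows.append((g.name, g.start, g.end, g.strand, g.length, "gene", False))
        means.append(tpm)
        te.append(1.0)
    for reg in regions:
        rows.append(
            (
                reg.feature_id,
                reg.anc_start if reg.anc_start is not None else -1,
                reg.anc_end if reg.anc_end is not None else -1,
                reg.strand,
                reg.evo_end - reg.evo_start,
                "region",
                _region_eligible(reg, genome.features),
            )
        )
        means.append(config.baseline_nongenic_tpm)
        te.append(config.region_te_factor)
    features = pd.DataFrame(
        rows, columns=["feature_id", "start", "end", "strand", "length", "kind", "eligible"]
    ).set_index("feature_id")
    if features.index.duplicated().any():
        raise ValueError("duplicate feature ids in expression model")
    rna = pd.DataFrame({"ancestor": means, "evolved": means}, index=features.index, dtype=float)
    te_factor = pd.Series(te, index=features.index, dtype=float)
    return ExpressionModel(features=features, rna=rna, te_factor=te_factor)


def plant_protogenes(
    mutations: list[MutationRecord],
    model: ExpressionModel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionModel, pd.DataFrame]:
    """Raise the evolved-group mean of eligible downstream regions by
    ``planted_fold_change`` for ``planted_protogene_count`` mutations.

    Mutations with an eligible (non-genic, non-repeat, untruncated) silent
    downstream region are candidates; IS insertions are planted
    preferentially, then large deletions, mirroring the dominance of
    promoter recruitment among observed causes.  For MOB events only the
    promoter-side strand exists, so only that strand is raised.  Returns
    the updated model plus a truth table (one row per planted event).
    """
    rng = rng if rng is not None else _streams(config.seed)["plant"]
    model = model.copy()
    feats = model.features
    by_mut: dict[str, dict[str, list[str]]] = {}
    for fid, row in feats[feats["kind"] == "region"].iterrows():
        mid, strand, _ = fid.split("|")
        if row["eligible"]:
            by_mut.setdefault(mid, {}).setdefault(strand, []).append(fid)
    # a plantable unit needs every extraction length eligible on one strand
    n_lengths = 2
    plantable: dict[str, list[str]] = {}
    mut_order = {m.id: m for m in mutations}
    for mid, strands in by_mut.items():
        ok = [s for s, fids in strands.items() if len(fids) >= n_lengths]
        if ok:
            plantable[mid] = sorted(ok)
    eligible_muts = sorted(plantable)
    if len(eligible_muts) < config.planted_protogene_count:
        raise PlacementError(
            f"only {len(eligible_muts)} mutations have an eligible silent downstream "
            f"region; {config.planted_protogene_count} plants requested"
        )

    def cls_rank(mid: str) -> int:
        m = mut_order[mid]
        if m.type == "MOB":
            return 0
        if m.type == "DEL" and m.size >= 1000:
            return 1
        return 2

    ranked = sorted(eligible_muts, key=lambda mid: (cls_rank(mid), rng.random()))
    chosen = ranked[: config.planted_protogene_count]

    truth_rows = []
    for k, mid in enumerate(chosen):
        strands = plantable[mid]
        strand = strands[int(rng.integers(0, len(strands)))]
        fids = by_mut[mid][strand]
        translated = k < config.planted_translated_count
        for fid in fids:
            anc = model.rna.loc[fid, "ancestor"]
            model.rna.loc[fid, "evolved"] = config.planted_fold_change * anc
            if translated:
                model.ribo.loc[fid, "evolved"] = (
                    model.te_factor.loc[fid] * model.rna.loc[fid, "evolved"]
                )
            # non-translated plants keep their ancestral Ribo mean (gain in
            # transcription only), so the translation cascade stays quiet
        rep = max(fids, key=lambda f: int(f.split("|")[2]))
        truth_rows.append(
            {
                "mutation_id": mid,
                "mutation_type": mut_order[mid].type,
                "strand": strand,
                "anc_start": int(feats.loc[rep, "start"]),
                "anc_end": int(feats.loc[rep, "end"]),
                "fold": config.planted_fold_change,
                "translated": translated,
                "condition_expressed": False,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "mutation_id",
            "mutation_type",
            "strand",
            "anc_start",
            "anc_end",
            "fold",
            "translated",
            "condition_expressed",
        ],
    )
    return model, truth


# ------------------------------------------------------------------ counts


def _expected_counts(tpm: pd.Series, lengths: pd.Series, library_size: int) -> np.ndarray:
    mass = tpm.to_numpy() * lengths.to_numpy()
    total = mass.sum()
    if total == 0:
        return np.zeros(len(tpm))
    return library_size * mass / total


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion == 0:
        out[pos] = rng.poisson(mean[pos])
    else:
        n = 1.0 / dispersion
        out[pos] = rng.negative_binomial(n, n / (n + mean[pos]))
    return out


def simulate_counts(
    model: ExpressionModel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    assay: str = "rna",
    groups: tuple[str, ...] = ("ancestor", "evolved"),
) -> CountMatrix:
    """Replicated NB counts from group mean TPMs.

    Expected reads for a feature are its TPM x length share of the library;
    counts are NB2 with the configured dispersion (Poisson in the
    dispersion -> 0 limit)."""
    rng = rng if rng is not None else _streams(config.seed)[assay]
    means = model.rna if assay == "rna" else model.ribo
    lengths = model.features["length"]
    cols = {}
    meta = []
    for group in groups:
        mu = _expected_counts(means[group], lengths, config.library_size)
        for r in range(1, config.replicates + 1):
            name = f"{group}_{assay}_r{r}"
            cols[name] = _nb_draw(rng, mu, config.dispersion)
            meta.append((name, group, assay, r))
    counts = pd.DataFrame(cols, index=means.index)
    samples = pd.DataFrame(meta, columns=["sample", "group", "assay", "replicate"]).set_index(
        "sample"
    )
    return CountMatrix(counts=counts, lengths=lengths.astype(int), samples=samples)


def simulate_condition_library(
    model: ExpressionModel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    condition_expressed: dict[str, int] | None = None,
) -> CountMatrix:
    """Ancestor-genotype counts across ``condition_count`` external
    conditions (one sample per condition).

    ``condition_expressed`` maps feature ids to the condition index in
    which they are expressed at ``condition_expressed_reads`` mean reads,
    exercising the cross-condition exclusion filter."""
    if config.condition_count < 1:
        raise ValueError("condition_count must be >= 1")
    rng = rng if rng is not None else _streams(config.seed)["conditions"]
    condition_expressed = condition_expressed or {}
    lengths = model.features["length"]
    base_mu = _expected_counts(model.rna["ancestor"], lengths, config.condition_library_size)
    cols = {}
    for c in range(config.condition_count):
        mu = base_mu.copy()
        for fid, ci in condition_expressed.items():
            if ci == c:
                mu[model.features.index.get_loc(fid)] = config.condition_expressed_reads
        cols[f"cond_{c + 1:02d}"] = _nb_draw(rng, mu, config.dispersion)
    counts = pd.DataFrame(cols, index=model.features.index)
    return CountMatrix(counts=counts, lengths=lengths.astype(int))


def counts_to_coverage(
    counts: pd.Series,
    features: pd.DataFrame,
    genome_length: int,
    read_length: int,
    rng: np.random.Generator,
) -> CoverageTracks:
    """Spread one sample's per-feature read counts into per-base coverage
    on the ancestral genome (uniform read starts within each feature).

    Total coverage mass equals the total placed read-bases."""
    # difference arrays (length L+1): cumulative sum yields coverage
    plus = np.zeros(genome_length + 1)
    minus = np.zeros(genome_length + 1)
    for fid, row in features.iterrows():
        c = int(counts.loc[fid])
        if c == 0 or row["start"] < 0:
            continue
        start, end, strand = int(row["start"]), int(row["end"]), row["strand"]
        span = end - start
        rl = min(read_length, span)
        max_start = end - rl
        starts = rng.integers(start, max_start + 1, size=c) if max_start > start else np.full(c, start)
        track = plus if strand == "+" else minus
        np.add.at(track, starts, 1.0)
        np.add.at(track, starts + rl, -1.0)
    return CoverageTracks(
        plus=np.cumsum(plus)[None, :genome_length],
        minus=np.cumsum(minus)[None, :genome_length],
    )


def simulate_ancestral_coverage(
    rna_counts: CountMatrix,
    model: ExpressionModel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> CoverageTracks:
    """Per-replicate ancestral coverage tracks consistent with the
    ancestor-group RNA counts."""
    rng = rng if rng is not None else _streams(config.seed)["coverage"]
    anc_cols = [c for c in rna_counts.counts.columns if c.startswith("ancestor_")]
    feats = model.features
    genes = feats[feats["kind"] == "gene"]
    # candidate regions overlap and nest each other; coverage must come from
    # one read population, so merge region intervals into union loci and
    # place background reads once per locus at the ancestral baseline level
    mass = float((model.rna["ancestor"] * feats["length"]).sum())
    loci_rows = []
    for strand in ("+", "-"):
        sel = feats[(feats["kind"] == "region") & (feats["strand"] == strand) & (feats["start"] >= 0)]
        last_s = last_e = None
        for s, e in sorted(zip(sel["start"], sel["end"])):
            if last_e is not None and s <= last_e:
                last_e = max(last_e, e)
            else:
                if last_e is not None:
                    loci_rows.append((last_s, last_e, strand))
                last_s, last_e = s, e
        if last_e is not None:
            loci_rows.append((last_s, last_e, strand))
    loci = pd.DataFrame(loci_rows, columns=["start", "end", "strand"])
    loci.index = [f"locus_{i}" for i in range(len(loci))]
    loci["length"] = loci["end"] - loci["start"]
    locus_mu = (
        config.library_size * config.baseline_nongenic_tpm * loci["length"].to_numpy() / mass
        if mass > 0
        else np.zeros(len(loci))
    )

    cov_feats = pd.concat([genes[["start", "end", "strand", "length"]], loci])
    plus, minus = [], []
    for col in anc_cols:
        counts = pd.concat(
            [
                rna_counts.counts.loc[genes.index, col],
                pd.Series(_nb_draw(rng, locus_mu, config.dispersion), index=loci.index),
            ]
        )
        tr = counts_to_coverage(
            counts, cov_feats, config.genome_length, config.read_length, rng
        )
        plus.append(tr.plus[0])
        minus.append(tr.minus[0])
    return CoverageTracks(plus=np.vstack(plus), minus=np.vstack(minus))


# ---------------------------------------------------------------- scenario


@dataclass
class Scenario:
    """Everything a detection run needs, plus the planted ground truth."""

    config: SimulationConfig
    genome: GenomeRecord
    element_sequences: dict[str, str]
    mutations: list[MutationRecord]
    evolved_sequence: str
    coord_map: CoordinateMap
    regions: list[CandidateRegion]
    model: ExpressionModel
    truth: pd.DataFrame
    rna_counts: CountMatrix
    ribo_counts: CountMatrix
    condition_counts: CountMatrix
    ancestral_coverage: CoverageTracks
    clone: str = "evolved"

    @property
    def groups(self) -> pd.Series:
        return self.rna_counts.samples["group"]


def simulate_scenario(config: SimulationConfig) -> Scenario:
    """Generate one full synthetic study from a config (deterministic)."""
    rngs = _streams(config.seed)
    genome = generate_ancestor(config, rngs["genome"])
    elements = element_library(config, rngs["elements"])
    mutations = sample_mutations(genome, config, rngs["mutations"])
    evolved, cmap = apply_mutations(genome, mutations, elements)
    regions = extract_downstream_regions(mutations, cmap)
    filter_candidate_overlaps(regions, genome.features)
    model = build_expression_model(genome, regions, config, rngs["model"])
    model, truth = plant_protogenes(mutations, model, config, rngs["plant"])

    cond_expressed: dict[str, int] = {}
    if config.condition_expressed_count > 0 and len(truth):
        k = min(config.condition_expressed_count, len(truth))
        picks = rngs["conditions"].choice(len(truth), size=k, replace=False)
        for i in picks:
            row = truth.iloc[i]
            truth.loc[truth.index[i], "condition_expressed"] = True
            ci = int(rngs["conditions"].integers(0, config.condition_count))
            for fid in model.features.index:
                if fid.startswith(f"{row.mutation_id}|{row.strand}|"):
                    cond_expressed[fid] = ci

    rna = simulate_counts(model, config, rngs["rna"], assay="rna")
    ribo = simulate_counts(model, config, rngs["ribo"], assay="ribo")
    cond = simulate_condition_library(model, config, rngs["conditions"], cond_expressed)
    coverage = simulate_ancestral_coverage(rna, model, config, rngs["coverage"])
    return Scenario(
        config=config,
        genome=genome,
        element_sequences=elements,
        mutations=mutations,
        evolved_sequence=evolved,
        coord_map=cmap,
        regions=regions,
        model=model,
        truth=truth,
        rna_counts=rna,
        ribo_counts=ribo,
        condition_counts=cond,
        ancestral_coverage=coverage,
    )
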