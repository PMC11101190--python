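"""Read counting with nonunique-all semantics and NRC/TPM normalization.

Counting follows htseq-count's ``nonunique-all`` mode: a read interval
increments *every* same-strand feature it overlaps by >= 1 bp, so reads
spanning feature junctions contribute to all of them.  Expression units are
NRC (read count / feature length in bp) and TPM (NRC / sum of NRC x 1e6);
the normalization universe is whatever feature set the matrix was built
over, and different universes are never mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

TPM_SCALE = 1_000_000


@dataclass
class CountMatrix:
    """Features x samples non-negative integer read counts."""

    counts: pd.DataFrame                     # features x samples
    lengths: pd.Series                       # bp per feature
    samples: pd.DataFrame | None = None      # sample metadata (group/assay/replicate)
    unassigned: pd.Series | None = None      # reads overlapping no feature, per sample

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("missing feature lengths")
        if (self.lengths <= 0).any():
            raise ValueError("feature lengths must be >= 1")

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    def subset(self, feature_ids) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.loc[feature_ids].copy(),
            lengths=self.lengths.loc[feature_ids].copy(),
            samples=self.samples,
        )

    def write_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def read_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        lengths = df.pop("length")
        return cls(counts=df.astype(int), lengths=lengths)


def count_reads(
    features,
    reads: dict[str, list[tuple[int, int, str]]],
    genome_length: int | None = None,
    samples: pd.DataFrame | None = None,
) -> CountMatrix:
    """Count strand-aware read intervals into features (nonunique-all).

    ``features`` is an iterable of objects with ``name/start/end/strand``
    attributes (or ``id`` instead of ``name``); ``reads`` maps sample id to
    a list of ``(start, end, strand)`` intervals in the same coordinate
    system as the features.
    """
    feats = list(features)
    ids = [getattr(f, "name", None) or getattr(f, "id") for f in feats]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate feature ids")
    trees = {"+": IntervalTree(), "-": IntervalTree()}
    for idx, f in enumerate(feats):
        trees[f.strand].addi(f.start, f.end, idx)

    mat = np.zeros((len(feats), len(reads)), dtype=np.int64)
    unassigned = {}
    for j, (sample, intervals) in enumerate(reads.items()):
        miss = 0
        for start, end, strand in intervals:
            if genome_length is not None and not (0 <= start < end <= genome_length):
                raise ValueError(
                    f"read [{start}, {end}) in sample {sample!r} outside genome "
                    f"of length {genome_length}"
                )
            hits = trees[strand].overlap(start, end)
            if not hits:
                miss += 1
                continue
            for h in hits:
                mat[h.data, j] += 1
        unassigned[sample] = miss

    counts = pd.DataFrame(mat, index=pd.Index(ids, name="feature_id"), columns=list(reads))
    lengths = pd.Series([f.end - f.start for f in feats], index=counts.index)
    return CountMatrix(
        counts=counts, lengths=lengths, samples=samples, unassigned=pd.Series(unassigned)
    )


def compute_nrc(cm: CountMatrix) -> pd.DataFrame:
    """Normalized read count: count per feature / feature length (bp)."""
    return cm.counts.div(cm.lengths, axis=0)


def compute_tpm(nrc: pd.DataFrame) -> pd.DataFrame:
    """TPM = NRC / sum(NRC) x 1e6 per sample; all-zero columns stay zero."""
    colsum = nrc.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        import warnings

        warnings.warn(f"all-zero sample columns left at zero: {list(colsum.index[zero])}")
    safe = colsum.replace(0, np.nan)
    return nrc.div(safe, axis=1).fillna(0.0) * TPM_SCALE


def tpm_from_counts(cm: CountMatrix) -> pd.DataFrame:
    return compute_tpm(compute_nrc(cm))


def mean_tpm(tpm: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Average replicate columns within each sample group."""
    groups = pd.Series(groups).reindex(tpm.columns)
    if groups.isna().any():
        raise ValueError("every sample column needs a group label")
    return tpm.T.groupby(groups).mean().T


def tally_expressed_windows(
    tpm: pd.DataFrame,
    categories: pd.Series,
    cutoffs: list[float],
    gene_adjacent: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-sample, per-category counts of windows with TPM strictly above
    each cutoff (exact-boundary values are excluded).

    ``categories`` (and optionally ``gene_adjacent``) are indexed by window
    id, aligned with the TPM rows.
    """
    categories = categories.reindex(tpm.index)
    rows = []
    for cutoff in cutoffs:
        passed = tpm > cutoff
        for sample in tpm.columns:
            hit = passed[sample]
            for cat, members in categories.groupby(categories):
                idx = members.index
                if gene_adjacent is not None and cat != "annotated":
                    adj = gene_adjacent.reindex(idx).fillna(False).astype(bool)
                    rows.append((sample, cutoff, cat, "gene_adjacent", int(hit[idx[adj]].sum())))
                    rows.append((sample, cutoff, cat, "isolated", int(hit[idx[~adj]].sum())))
                else:
                    rows.append((sample, cutoff, cat, "all", int(hit[idx].sum())))
    return pd.DataFrame(rows, columns=["sample", "cutoff", "category", "adjacency", "count"])
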