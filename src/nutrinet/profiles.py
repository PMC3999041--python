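"""Feature-by-sample tables: hit filtering, normalization, ranking, clustering.

A :class:`FeatureTable` holds one feature kind (genus, phylum, COG, CAZyme
family or virulence factor) as a features x samples matrix and tracks its
processing state: raw ``counts``, ``normalized`` (reads assigned to the
feature divided by the *total* sequenced reads of the sample, so column
sums stay below one) or ``ranked`` (each feature's abundances replaced by
their average ranks across samples, ascending).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

__all__ = [
    "KINDS",
    "STATES",
    "FeatureTable",
    "HitThresholds",
    "PatternGroups",
    "filter_hits",
    "normalize_abundance",
    "rank_normalize",
    "core_features",
    "cluster_abundance_patterns",
    "group_cumulative_abundance",
]

KINDS = ("taxon-genus", "taxon-phylum", "cog", "cazyme", "vf")
STATES = ("counts", "normalized", "ranked")

HIT_COLUMNS = ("read_id", "sample_id", "feature_id", "identity_pct", "coverage_pct")


@dataclass
class FeatureTable:
    """Features x samples matrix with a feature-kind label and a state tag."""

    data: pd.DataFrame  # index = feature ids, columns = sample ids
    kind: str
    state: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}; expected one of {KINDS}")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        values = self.data.to_numpy(float)
        if values.size and np.nanmin(values) < 0:
            raise ValueError("feature tables cannot contain negative values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def row(self, feature_id: str) -> np.ndarray:
        return self.data.loc[feature_id].to_numpy(float)

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[:, list(sample_ids)].copy(), self.kind, self.state)

    def subset_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(feature_ids)].copy(), self.kind, self.state)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, kind: str, state: str = "counts") -> "FeatureTable":
        data = pd.read_csv(path, sep="\t", index_col=0)
        data.index = data.index.astype(str)
        return cls(data, kind, state)


@dataclass(frozen=True)
class HitThresholds:
    """Strict lower bounds on per-read alignment quality.

    A hit survives only if identity, query coverage and (when a length
    threshold is set) alignment length each strictly exceed their bound.
    """

    min_identity_pct: float
    min_query_coverage_pct: float
    min_alignment_length_bp: int | None = None

    def __post_init__(self) -> None:
        for pct in (self.min_identity_pct, self.min_query_coverage_pct):
            if not (0 < pct <= 100):
                raise ValueError("percentage thresholds must lie in (0, 100]")

    @classmethod
    def taxa(cls) -> "HitThresholds":
        """Defaults for read-to-genome taxonomic hits: >65% id, >70% cov, >75 bp."""
        return cls(65.0, 70.0, 75)

    @classmethod
    def eggnog(cls) -> "HitThresholds":
        """Defaults for read-to-eggNOG functional hits: >65% id, >90% cov."""
        return cls(65.0, 90.0, None)


def filter_hits(hits: pd.DataFrame, thresholds: HitThresholds) -> pd.DataFrame:
    """Count reads passing the thresholds per (feature, sample).

    ``hits`` needs columns read_id, sample_id, feature_id, identity_pct,
    coverage_pct and — when an alignment-length threshold is set —
    alignment_length. All comparisons are strict ``>``.
    Returns a features x samples count table (all observed samples kept,
    features without passing reads dropped).
    """
    required = list(HIT_COLUMNS)
    if thresholds.min_alignment_length_bp is not None:
        required.append("alignment_length")
    missing = set(required) - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")

    mask = (hits["identity_pct"] > thresholds.min_identity_pct) & (
        hits["coverage_pct"] > thresholds.min_query_coverage_pct
    )
    if thresholds.min_alignment_length_bp is not None:
        mask &= hits["alignment_length"] > thresholds.min_alignment_length_bp
    passing = hits.loc[mask]
    counts = (
        passing.pivot_table(
            index="feature_id", columns="sample_id", values="read_id",
            aggfunc="count", fill_value=0,
        )
        .astype(int)
    )
    # retain every sample seen in the input, even if nothing passed there
    all_samples = pd.Index(sorted(hits["sample_id"].astype(str).unique()), name="sample_id")
    counts.columns = counts.columns.astype(str)
    counts = counts.reindex(columns=all_samples, fill_value=0)
    counts.index = counts.index.astype(str)
    return counts.sort_index()


def normalize_abundance(table: FeatureTable, total_reads: pd.Series) -> FeatureTable:
    """Divide each sample's counts by that sample's *total* sequenced reads.

    The denominator is the whole-metagenome read count, not the number of
    assigned reads, so columns sum to the assignment rate (< 1).
    """
    if table.state != "counts":
        raise ValueError(f"expected a counts table, got state {table.state!r}")
    totals = pd.Series(total_reads).astype(float)
    missing = set(table.sample_ids) - set(totals.index)
    if missing:
        raise ValueError(f"no total read count for samples: {sorted(missing)}")
    totals = totals.loc[table.sample_ids]
    if (totals <= 0).any():
        raise ValueError("total read counts must be strictly positive")
    data = table.data.div(totals, axis=1)
    return FeatureTable(data, table.kind, "normalized")


def rank_normalize(table: FeatureTable) -> FeatureTable:
    """Rank each feature's abundances across samples, ascending, ties averaged."""
    if table.state != "normalized":
        raise ValueError(f"expected a normalized table, got state {table.state!r}")
    ranks = rankdata(table.values, axis=1, method="average")
    data = pd.DataFrame(ranks, index=table.data.index, columns=table.data.columns)
    return FeatureTable(data, table.kind, "ranked")


def core_features(
    table: FeatureTable,
    min_abundance: float = 0.01,
    min_prevalence: float = 0.5,
) -> list[str]:
    """Features whose normalized abundance strictly exceeds ``min_abundance``
    in at least ``ceil(min_prevalence * n_samples)`` samples."""
    if table.state != "normalized":
        raise ValueError(f"expected a normalized table, got state {table.state!r}")
    needed = math.ceil(min_prevalence * table.n_samples)
    hits = (table.values > min_abundance).sum(axis=1)
    return [f for f, h in zip(table.feature_ids, hits) if h >= needed]


@dataclass
class PatternGroups:
    """Feature -> group label mapping from abundance-pattern clustering."""

    labels: dict[str, str]
    linkage_matrix: np.ndarray = field(repr=False, default=None)
    n_groups: int = 0

    def members(self, label: str) -> list[str]:
        return sorted(f for f, g in self.labels.items() if g == label)

    def group_names(self) -> list[str]:
        return sorted(set(self.labels.values()), key=lambda g: (len(g), g))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_id": list(self.labels), "group": list(self.labels.values())}
        )


def _spearman_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise Spearman correlation between rows; constant rows correlate 0."""
    ranks = rankdata(values, axis=1, method="average")
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms == 0
    norms[constant] = 1.0
    unit = centered / norms[:, None]
    rho = unit @ unit.T
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def cluster_abundance_patterns(table: FeatureTable, n_groups: int) -> PatternGroups:
    """Group features with similar abundance patterns across samples.

    Agglomerative clustering with distance ``1 - Spearman`` between feature
    rows and average linkage, cut into ``n_groups`` flat groups. Group
    labels G1..Gk are assigned in order of each group's alphabetically
    first member, so the labelling is deterministic. Constant features get
    zero correlation with everything (distance 1).
    """
    n_features = len(table.feature_ids)
    if n_groups < 1 or n_groups > n_features:
        raise ValueError(f"n_groups must be in [1, {n_features}], got {n_groups}")
    rho = _spearman_matrix(table.values)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    raw = fcluster(Z, t=n_groups, criterion="maxclust")
    # relabel deterministically: order groups by their alphabetically first member
    features = table.feature_ids
    first_member = {}
    for f, g in sorted(zip(features, raw), key=lambda fg: fg[0]):
        first_member.setdefault(g, f)
    order = sorted(first_member, key=first_member.get)
    rename = {g: f"G{i + 1}" for i, g in enumerate(order)}
    labels = {f: rename[g] for f, g in zip(features, raw)}
    return PatternGroups(labels=labels, linkage_matrix=Z, n_groups=len(order))


def group_cumulative_abundance(
    table: FeatureTable, groups: PatternGroups, members
) -> pd.Series:
    """Per-sample sum of all features carrying the given group label(s)."""
    if isinstance(members, str):
        members = [members]
    members = list(members)
    known = set(groups.labels.values())
    unknown = set(members) - known
    if unknown:
        raise KeyError(f"unknown group labels: {sorted(unknown)}")
    feats = [f for f in table.feature_ids if groups.labels.get(f) in set(members)]
    if not feats:
        raise ValueError(f"no features in table belong to groups {members}")
    return table.data.loc[feats].sum(axis=0)
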