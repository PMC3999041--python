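"""Feature-gradient associations with ReBoot significance, power and group tests.

Relative abundances are compositional: closing each sample to its library
size induces spurious negative correlations that naive tests misread. The
ReBoot procedure guards against this by comparing a bootstrap distribution
of the observed Spearman correlation against a permutation null in which
the permuted profile is pushed back through the closure (each sample's
composition is renormalized after the permutation), so that purely
compositional coupling is present in the null as well.

The ReBoot score is ``z = (mean_bootstrap - mean_null) / sd_null`` with a
two-sided p-value from the standard normal tail, matching the convention
that |z| > 1.97 corresponds to p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import norm, rankdata, studentized_range
from statsmodels.stats.multitest import multipletests

from .profiles import FeatureTable

__all__ = [
    "RebootParams",
    "AssociationResult",
    "GroupComparisonResult",
    "TukeyPair",
    "DegenerateNullError",
    "spearman_rho",
    "reboot_significance",
    "correlation_power",
    "associate_with_index",
    "association_frame",
    "group_compare",
    "comparison_frame",
    "bh_fdr",
    "classify_pc_nc",
    "category_composition",
]


class DegenerateNullError(RuntimeError):
    """Raised when the ReBoot permutation null has zero spread."""


@dataclass(frozen=True)
class RebootParams:
    """Resampling sizes and seed for the ReBoot procedure."""

    n_permutations: int = 1000
    n_bootstraps: int = 1000
    seed: int = 0
    z_threshold: float = 1.97

    def __post_init__(self) -> None:
        if self.n_permutations < 1 or self.n_bootstraps < 1:
            raise ValueError("resample counts must be positive")
        if self.n_permutations < 100 or self.n_bootstraps < 100:
            warnings.warn(
                "fewer than 100 permutations/bootstraps is unreliable for inference",
                stacklevel=2,
            )


@dataclass
class AssociationResult:
    """One feature's correlation with the nutritional index."""

    feature_id: str
    rho: float
    reboot_z: float
    p_value: float
    power: float
    direction: str  # positive | negative | none


@dataclass
class TukeyPair:
    group_a: str
    group_b: str
    q_statistic: float
    p_value: float
    significant: bool


@dataclass
class GroupComparisonResult:
    """ANOVA / Kruskal-Wallis comparison of one feature across classes."""

    feature_id: str
    anova_F: float
    anova_p: float
    kw_H: float
    kw_p: float
    eta_squared: float
    anova_q: float = np.nan
    kw_q: float = np.nan
    tukey_pairs: list[TukeyPair] = field(default_factory=list)

    @property
    def q_bh(self) -> float:
        """Headline BH-adjusted p (parametric family)."""
        return self.anova_q


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (average-rank ties; Pearson on ranks).

    Constant input yields NaN with a warning rather than an exception.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("Spearman correlation undefined for constant input", stacklevel=2)
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def correlation_power(rho: float, n: int, alpha: float = 0.05) -> float:
    """Two-sided power of a correlation test via the Fisher arctanh transform.

    With ``z' = atanh(|rho|)`` and noncentrality ``delta = z' * sqrt(n-3)``,
    power = Phi(delta - z_crit) + Phi(-delta - z_crit). |rho| = 1 gives
    power 1 by convention; rho = 0 recovers alpha.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    r = abs(float(rho))
    if r >= 1.0:
        return 1.0
    delta = np.arctanh(r) * np.sqrt(n - 3)
    z_crit = norm.ppf(1 - alpha / 2)
    return float(norm.cdf(delta - z_crit) + norm.cdf(-delta - z_crit))


# ---------------------------------------------------------------------------
# ReBoot internals (shared with networks.build_network)


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return rankdata(a, axis=-1, method="average")


def _pearson_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two broadcastable stacks of vectors."""
    A = A - A.mean(axis=-1, keepdims=True)
    B = B - B.mean(axis=-1, keepdims=True)
    num = (A * B).sum(axis=-1)
    den = np.sqrt((A * A).sum(axis=-1) * (B * B).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return out


def _composition_matrix(composition) -> tuple[np.ndarray, list[str]]:
    if isinstance(composition, FeatureTable):
        return composition.values, composition.feature_ids
    if isinstance(composition, pd.DataFrame):
        return composition.to_numpy(float), [str(i) for i in composition.index]
    raise TypeError("composition must be a FeatureTable or DataFrame")


def _null_stats_vs_target(
    comp: np.ndarray,
    a_idx: int,
    target: np.ndarray | None,
    b_idx: int | None,
    perms: np.ndarray,
) -> np.ndarray:
    """Null Spearman correlations: permute row ``a_idx``, renormalize, correlate.

    After permuting the focal row, every sample's column is rescaled so its
    sum returns to the pre-permutation value (closure restored). The
    correlation partner is either an external gradient (``target``) or the
    renormalized row ``b_idx``.
    """
    a = comp[a_idx]
    col_sums = comp.sum(axis=0)
    a_perm = a[perms]  # (P, n)
    new_sums = (col_sums - a)[None, :] + a_perm
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = np.where(new_sums > 0, col_sums / new_sums, 0.0)
    a_renorm = a_perm * factor
    if target is not None:
        return _pearson_rows(_rank_rows(a_renorm), _rank_rows(np.asarray(target, float)))
    b_renorm = comp[b_idx][None, :] * factor
    return _pearson_rows(_rank_rows(a_renorm), _rank_rows(b_renorm))


def _bootstrap_mean_rho(x: np.ndarray, y: np.ndarray, idx: np.ndarray) -> float:
    """Mean bootstrap Spearman: rank once on the observed sample, then
    resample the rank pairs (avoids tie-induced attenuation from re-ranking
    duplicated observations)."""
    rx, ry = _rank_rows(x), _rank_rows(y)
    rho = _pearson_rows(rx[idx], ry[idx])
    return float(np.nanmean(rho))


def _z_to_p(z: float) -> float:
    return float(2.0 * norm.sf(abs(z)))


def reboot_significance(
    feature_a: str,
    feature_b_or_index,
    composition,
    params: RebootParams | None = None,
) -> tuple[float, float]:
    """ReBoot z-score and two-sided p for one association.

    ``feature_a`` names a row of ``composition`` (a normalized feature
    table). The partner is either another feature id or a per-sample
    gradient vector (e.g. the cumulative nutritional index). Deterministic
    for a fixed ``params.seed``.
    """
    params = params or RebootParams()
    comp, feature_ids = _composition_matrix(composition)
    try:
        a_idx = feature_ids.index(feature_a)
    except ValueError:
        raise KeyError(f"feature {feature_a!r} not in composition") from None

    n = comp.shape[1]
    if np.ptp(comp[a_idx]) == 0:
        raise DegenerateNullError(
            f"feature {feature_a!r} is constant; permutation null is degenerate"
        )
    if isinstance(feature_b_or_index, str):
        try:
            b_idx = feature_ids.index(feature_b_or_index)
        except ValueError:
            raise KeyError(f"feature {feature_b_or_index!r} not in composition") from None
        target = None
        y = comp[b_idx]
    else:
        b_idx = None
        target = np.asarray(feature_b_or_index, float)
        if target.shape != (n,):
            raise ValueError("index vector length must match the number of samples")
        y = target

    rng = np.random.default_rng(np.random.SeedSequence([params.seed, a_idx]))
    boot_idx = rng.integers(0, n, size=(params.n_bootstraps, n))
    mean_boot = _bootstrap_mean_rho(comp[a_idx], y, boot_idx)

    perms = np.argsort(rng.random((params.n_permutations, n)), axis=1)
    rho_null = _null_stats_vs_target(comp, a_idx, target, b_idx, perms)
    mean_null = float(np.nanmean(rho_null))
    sd_null = float(np.nanstd(rho_null, ddof=1))
    if not np.isfinite(sd_null) or sd_null == 0:
        raise DegenerateNullError(
            f"permutation null for {feature_a!r} has zero spread; "
            "feature is (nearly) constant"
        )
    z = (mean_boot - mean_null) / sd_null
    return float(z), _z_to_p(z)


def associate_with_index(
    table: FeatureTable,
    index: pd.Series,
    composition: FeatureTable,
    params: RebootParams | None = None,
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Correlate every feature with the nutritional index, ReBoot-validated.

    ``table`` supplies the abundances used for the Spearman estimate
    (ranked or normalized — the estimate is rank-invariant), while
    ``composition`` is the normalized table whose closure the ReBoot null
    must respect. Constant features are skipped with a warning.
    """
    params = params or RebootParams()
    idx = pd.Series(index).astype(float)
    missing = set(table.sample_ids) - set(idx.index)
    if missing:
        raise ValueError(f"index missing samples: {sorted(missing)}")
    target = idx.loc[table.sample_ids].to_numpy()

    results: list[AssociationResult] = []
    n = table.n_samples
    for feature in table.feature_ids:
        row = table.row(feature)
        if np.ptp(row) == 0:
            warnings.warn(
                f"skipping constant feature {feature!r} in association analysis",
                stacklevel=2,
            )
            continue
        rho = spearman_rho(row, target)
        z, p = reboot_significance(feature, target, composition, params)
        power = correlation_power(rho, n, alpha)
        if p < alpha:
            direction = "positive" if rho > 0 else "negative"
        else:
            direction = "none"
        results.append(AssociationResult(feature, rho, z, p, power, direction))
    return results


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "rho": r.rho,
                "reboot_z": r.reboot_z,
                "p_value": r.p_value,
                "power": r.power,
                "direction": r.direction,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Group comparisons


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving.

    NaN entries propagate as NaN and are excluded from the correction.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    valid = np.isfinite(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan, dtype=float)
    if valid.sum():
        out[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return out


def _eta_squared(groups: list[np.ndarray]) -> float:
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_total = float(((allv - grand) ** 2).sum())
    if ss_total == 0:
        return 0.0
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    return ss_between / ss_total


def _tukey_kramer(groups: dict[str, np.ndarray], alpha: float = 0.05) -> list[TukeyPair]:
    """All-pairs Tukey-Kramer comparisons with unequal-n standard errors.

    q = |mean_i - mean_j| / sqrt(MS_within / 2 * (1/n_i + 1/n_j)), compared
    against the studentized range with df = N - k.
    """
    names = sorted(groups)
    k = len(names)
    N = sum(len(g) for g in groups.values())
    df = N - k
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups.values())
    ms_within = ss_within / df if df > 0 else np.nan
    pairs: list[TukeyPair] = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[names[i]], groups[names[j]]
            if ms_within > 0:
                se = np.sqrt(ms_within / 2.0 * (1.0 / len(gi) + 1.0 / len(gj)))
                q = abs(gi.mean() - gj.mean()) / se
                p = float(studentized_range.sf(q, k, df))
            elif gi.mean() == gj.mean():
                q, p = 0.0, 1.0
            else:
                q, p = np.inf, 0.0
            pairs.append(TukeyPair(names[i], names[j], float(q), p, p < alpha))
    return pairs


def group_compare(
    table: FeatureTable,
    classes: pd.Series,
    alpha: float = 0.05,
) -> list[GroupComparisonResult]:
    """Compare each feature across nutrition classes (AH/BL/SM).

    Runs one-way ANOVA (with eta-squared effect size and Tukey-Kramer
    post-hoc pairs) and the tie-corrected Kruskal-Wallis H test, then
    applies BH-FDR across features separately within each test family.
    Features facing a class with fewer than 2 samples are skipped with a
    warning.
    """
    cls = pd.Series(classes).astype(str)
    missing = set(table.sample_ids) - set(cls.index)
    if missing:
        raise ValueError(f"classes missing samples: {sorted(missing)}")
    cls = cls.loc[table.sample_ids]
    names = sorted(cls.unique())
    if len(names) < 2:
        raise ValueError("need at least two classes to compare")
    masks = {name: (cls == name).to_numpy() for name in names}
    small = [name for name, m in masks.items() if m.sum() < 2]
    if small:
        warnings.warn(
            f"classes with <2 samples ({small}); group comparison skipped",
            stacklevel=2,
        )
        return []

    results: list[GroupComparisonResult] = []
    for feature in table.feature_ids:
        row = table.row(feature)
        groups = {name: row[m] for name, m in masks.items()}
        values = list(groups.values())
        if np.ptp(row) == 0:
            f_stat, f_p, h_stat, h_p = 0.0, 1.0, 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f_stat, f_p = stats.f_oneway(*values)
                try:
                    h_stat, h_p = stats.kruskal(*values)
                except ValueError:  # all values identical across groups
                    h_stat, h_p = 0.0, 1.0
            if not np.isfinite(f_stat):
                f_stat, f_p = 0.0, 1.0
        results.append(
            GroupComparisonResult(
                feature_id=feature,
                anova_F=float(f_stat),
                anova_p=float(f_p),
                kw_H=float(h_stat),
                kw_p=float(h_p),
                eta_squared=_eta_squared(values),
                tukey_pairs=_tukey_kramer(groups, alpha),
            )
        )

    anova_q = bh_fdr([r.anova_p for r in results])
    kw_q = bh_fdr([r.kw_p for r in results])
    for r, qa, qk in zip(results, anova_q, kw_q):
        r.anova_q = float(qa)
        r.kw_q = float(qk)
    return results


def comparison_frame(results: list[GroupComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "anova_F": r.anova_F,
                "anova_p": r.anova_p,
                "anova_q": r.anova_q,
                "kw_H": r.kw_H,
                "kw_p": r.kw_p,
                "kw_q": r.kw_q,
                "eta_squared": r.eta_squared,
            }
            for r in results
        ]
    )


def classify_pc_nc(
    results: list[AssociationResult], z_threshold: float = 1.97
) -> tuple[list[str], list[str]]:
    """Split features into positively (z > t) and negatively (z < -t)
    correlated sets by their ReBoot z-score."""
    pc = sorted(r.feature_id for r in results if r.reboot_z > z_threshold)
    nc = sorted(r.feature_id for r in results if r.reboot_z < -z_threshold)
    return pc, nc


def category_composition(features, category_map: dict) -> dict[str, float]:
    """Percentage of features per higher-level category (sums to 100).

    Features absent from the map fall into an ``unknown`` bucket; an empty
    feature set yields an empty result with a warning.
    """
    features = list(features)
    if not features:
        warnings.warn("empty feature set; no category composition", stacklevel=2)
        return {}
    counts: dict[str, int] = {}
    for f in features:
        cat = category_map.get(f, "unknown")
        counts[cat] = counts.get(cat, 0) + 1
    total = len(features)
    return {cat: 100.0 * c / total for cat, c in sorted(counts.items())}
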