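"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a 20-child gut-metagenome cohort along a nutrition
gradient: cumulative nutritional indices spread over roughly -11.6 to
-2.2, a dominant Prevotella-like genus, planted gradient-positive (G1-like,
commensal) and gradient-negative (G4-like, pathogen-like) taxa, neutral
taxa, hub taxa whose co-occurrence coupling strengthens as nutrition
falls, compositional closure at realistic library sizes and
Dirichlet-multinomial count noise. Ground-truth roles are carried
alongside the tables so downstream detection can be scored.

Model: each taxon has a latent Gaussian log-abundance
``base + direction * effect_size * u + loading * hub_factor + noise``,
where ``u`` is the sample's position along the index range rescaled to
[-1/2, +1/2]. Latents are mapped to proportions per sample by
exponentiate-and-normalize (softmax closure) and to counts by a
Dirichlet-multinomial at the sample's library size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .nutrition import GrowthReference, classify_nutrition, toy_growth_reference
from .profiles import FeatureTable, HitThresholds

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "HitTableFixture",
    "generate_cohort",
    "generate_anthropometrics",
    "generate_hit_table",
]

#: fraction of reads assignable at genus level; total sequenced reads are
#: library_size / assignment_rate so normalized column sums stay below 1
GENUS_ASSIGNMENT_RATE = 0.36

#: COG functional category names used for the synthetic category map
COG_CATEGORIES = (
    "Energy production and conversion",
    "Amino acid transport and metabolism",
    "Carbohydrate transport and metabolism",
    "Lipid transport and metabolism",
    "Cell motility",
    "Intracellular trafficking and secretion",
    "Inorganic ion transport and metabolism",
    "Secondary metabolites biosynthesis",
    "Function unknown",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort generator.

    ``effect_size`` is the change in latent log-abundance of a planted
    gradient taxon across the *full* index range (the gradient coordinate
    is the cumulative index rescaled to a unit interval), so the
    proportions of planted taxa swing by about ``exp(effect_size)``-fold
    from one end of the gradient to the other. ``hub_coupling_slope``
    scales the loading of the shared hub factor, which rises linearly
    from 0 at the healthy end to the slope value at the malnourished end.
    """

    n_samples: int = 20
    index_range: tuple[float, float] = (-11.58, -2.18)
    n_g1_taxa: int = 5
    n_g4_taxa: int = 5
    n_neutral_taxa: int = 13
    n_hubs: int = 2
    hub_size: int = 5
    effect_size: float = 2.0
    dominant_fraction: float = 0.35
    hub_coupling_slope: float = 2.0
    library_size_range: tuple[int, int] = (100_000, 200_000)
    overdispersion: float = 100.0
    latent_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be at least 4")
        lo, hi = self.index_range
        if not lo < hi:
            raise ValueError("index_range must satisfy low < high")
        for name in ("n_g1_taxa", "n_g4_taxa", "n_neutral_taxa", "n_hubs", "hub_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not (0 < self.dominant_fraction < 1):
            raise ValueError("dominant_fraction must lie in (0, 1)")
        if self.hub_coupling_slope < 0:
            raise ValueError("hub_coupling_slope must be non-negative")
        llo, lhi = self.library_size_range
        if llo <= 0 or lhi < llo:
            raise ValueError("library_size_range must be positive with low <= high")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")
        if self.latent_sd <= 0:
            raise ValueError("latent_sd must be positive")


@dataclass
class SyntheticCohort:
    """Generated cohort: metadata, genus counts, functional tables, truth."""

    metadata: pd.DataFrame
    genus_counts: FeatureTable
    functional_tables: dict[str, FeatureTable]
    truth: pd.DataFrame  # columns: feature_id, kind, role, hub
    cog_categories: dict[str, str]
    config: SyntheticConfig

    def features_with_role(self, role: str, kind: str = "taxon-genus") -> list[str]:
        mask = (self.truth["role"] == role) & (self.truth["kind"] == kind)
        return sorted(self.truth.loc[mask, "feature_id"])

    def write(self, out_dir) -> None:
        """Write metadata, counts, truth and the COG category map as TSV."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        self.genus_counts.to_tsv(out / "genus_counts.tsv")
        for kind, table in self.functional_tables.items():
            table.to_tsv(out / f"{kind}_counts.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"feature_id": list(self.cog_categories),
             "category": list(self.cog_categories.values())}
        ).to_csv(out / "cog_categories.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# anthropometrics


def generate_anthropometrics(
    metadata_skeleton: pd.DataFrame,
    reference: GrowthReference | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate heights and weights whose z-scores hit per-sample targets.

    The skeleton needs sample_id, age_months and sex. Height is obtained
    by inverting the LMS height-for-age transform at the target
    ``z_height_age``; weight by inverting weight-for-height at the
    generated height. Because one height and one weight determine all
    three scores, weight-for-age is implied rather than free: when a
    ``target_index`` column is present, the weight-for-height target is
    solved numerically so the three scores sum to the target cumulative
    index exactly; otherwise ``z_weight_height`` targets are used (drawn
    from N(-2, 1.5) if absent, alongside z_height_age).

    Recomputing the scores from the generated measurements reproduces the
    stored z-scores to floating-point accuracy (round-trip property).
    """
    reference = reference or toy_growth_reference()
    rng = np.random.default_rng(seed)
    required = {"sample_id", "age_months", "sex"}
    missing = required - set(metadata_skeleton.columns)
    if missing:
        raise ValueError(f"skeleton missing columns: {sorted(missing)}")

    skel = metadata_skeleton.copy()
    n = len(skel)
    if "z_height_age" not in skel.columns:
        if "target_index" in skel.columns:
            # stunting tracks overall status: centre z1 near a third of the target
            centre = skel["target_index"].to_numpy(float) / 3.0
            skel["z_height_age"] = (centre + rng.normal(0.0, 0.7, n)).clip(-4.5, 2.5)
        else:
            skel["z_height_age"] = rng.normal(-2.0, 1.5, n).clip(-4.5, 2.5)
    if "target_index" not in skel.columns and "z_weight_height" not in skel.columns:
        skel["z_weight_height"] = rng.normal(-2.0, 1.5, n).clip(-4.5, 2.5)

    rows = []
    for row in skel.itertuples(index=False):
        z1 = float(row.z_height_age)
        height = reference.measurement_for_z(row.sex, "height-for-age", row.age_months, z1)

        def scores_for(z3: float) -> tuple[float, float, float]:
            weight = reference.measurement_for_z(row.sex, "weight-for-height", height, z3)
            z2 = reference.z_score(row.sex, "weight-for-age", row.age_months, weight)
            return weight, z2, z3

        if hasattr(row, "target_index"):
            target = float(row.target_index)

            def gap(z3: float) -> float:
                _, z2, _ = scores_for(z3)
                return z1 + z2 + z3 - target

            lo, hi = -8.0, 8.0
            while gap(lo) > 0 and lo > -24.0:
                lo -= 4.0
            while gap(hi) < 0 and hi < 24.0:
                hi += 4.0
            z3 = brentq(gap, lo, hi, xtol=1e-12)
        else:
            z3 = float(row.z_weight_height)
        weight, z2, z3 = scores_for(z3)
        # store scores recomputed from the rounded-free measurements
        z1_back = reference.z_score(row.sex, "height-for-age", row.age_months, height)
        z3_back = reference.z_score(row.sex, "weight-for-height", height, weight)
        cum = z1_back + z2 + z3_back
        rows.append(
            {
                "sample_id": row.sample_id,
                "age_months": float(row.age_months),
                "sex": row.sex,
                "height_cm": height,
                "weight_kg": weight,
                "z_height_age": z1_back,
                "z_weight_age": z2,
                "z_weight_height": z3_back,
                "cumulative_index": cum,
                "nutrition_class": classify_nutrition(cum),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# latent abundance model


def _feature_roster(config: SyntheticConfig) -> pd.DataFrame:
    rows = [{"feature_id": "Prevotella_like", "role": "dominant", "hub": ""}]
    for i in range(config.n_g1_taxa):
        rows.append({"feature_id": f"g1_taxon_{i + 1:02d}", "role": "gradient-positive", "hub": ""})
    for i in range(config.n_g4_taxa):
        rows.append({"feature_id": f"g4_taxon_{i + 1:02d}", "role": "gradient-negative", "hub": ""})
    for h in range(config.n_hubs):
        for i in range(config.hub_size):
            rows.append(
                {"feature_id": f"hub{h + 1}_taxon_{i + 1:02d}", "role": "hub-member",
                 "hub": f"hub{h + 1}"}
            )
    for i in range(config.n_neutral_taxa):
        rows.append({"feature_id": f"neutral_taxon_{i + 1:02d}", "role": "neutral", "hub": ""})
    return pd.DataFrame(rows)


def _latent_counts(
    roster: pd.DataFrame,
    u: np.ndarray,
    library_sizes: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
    dominant_row: str | None = "Prevotella_like",
) -> np.ndarray:
    """Counts (features x samples) from the latent Gaussian closure model."""
    F, n = len(roster), len(u)
    base = rng.normal(0.0, 1.0, F)
    if dominant_row is not None:
        dom = roster.index[roster["feature_id"] == dominant_row]
        if len(dom):
            others = np.exp(np.delete(base, dom[0])).sum()
            d = config.dominant_fraction
            base[dom[0]] = np.log(d / (1.0 - d) * others)

    direction = np.zeros(F)
    direction[(roster["role"] == "gradient-positive").to_numpy()] = 1.0
    direction[(roster["role"] == "gradient-negative").to_numpy()] = -1.0

    latent = base[:, None] + direction[:, None] * config.effect_size * u[None, :]

    u_high = 0.5  # top of the rescaled gradient
    loading = config.hub_coupling_slope * (u_high - u)  # (n,), >= 0
    for hub in sorted(set(roster["hub"]) - {""}):
        members = (roster["hub"] == hub).to_numpy()
        factor = rng.normal(0.0, 1.0, n)
        # subtract the log-normal mean so the hub factor plants co-occurrence
        # without shifting expected abundance along the gradient
        latent[members] += (loading * factor - loading**2 / 2.0)[None, :]

    latent += rng.normal(0.0, config.latent_sd, (F, n))

    props = np.exp(latent - latent.max(axis=0, keepdims=True))
    props /= props.sum(axis=0, keepdims=True)

    counts = np.zeros((F, n), dtype=np.int64)
    for s in range(n):
        conc = props[:, s] * (library_sizes[s] / config.overdispersion)
        q = rng.dirichlet(np.maximum(conc, 1e-12))
        counts[:, s] = rng.multinomial(library_sizes[s], q)
    return counts


# roster sizes for the functional stand-in tables (positive, negative, neutral)
_FUNCTIONAL_LAYOUT = {
    "cog": (8, 8, 24),
    "cazyme": (6, 0, 14),
    "vf": (0, 4, 6),
}


def _functional_roster(kind: str, layout: tuple[int, int, int]) -> pd.DataFrame:
    n_pos, n_neg, n_neu = layout
    rows = []
    for i in range(n_pos):
        rows.append({"feature_id": f"{kind}_pos_{i + 1:03d}", "role": "gradient-positive", "hub": ""})
    for i in range(n_neg):
        rows.append({"feature_id": f"{kind}_neg_{i + 1:03d}", "role": "gradient-negative", "hub": ""})
    for i in range(n_neu):
        rows.append({"feature_id": f"{kind}_neutral_{i + 1:03d}", "role": "neutral", "hub": ""})
    return pd.DataFrame(rows)


def generate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort. Deterministic for a fixed seed."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0F0]))

    lo, hi = config.index_range
    n = config.n_samples
    indices = rng.uniform(lo, hi, n)
    u = (indices - (lo + hi) / 2.0) / (hi - lo)  # in [-1/2, 1/2]

    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    skeleton = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age_months": np.round(rng.uniform(12.0, 59.0, n), 1),
            "sex": rng.choice(["M", "F"], n),
            "target_index": indices,
        }
    )
    anthro_seed = int(rng.integers(0, 2**31 - 1))
    metadata = generate_anthropometrics(skeleton, toy_growth_reference(), seed=anthro_seed)

    llo, lhi = config.library_size_range
    library_sizes = rng.integers(llo, lhi + 1, n)
    metadata["total_reads"] = np.round(library_sizes / GENUS_ASSIGNMENT_RATE).astype(int)
    metadata["library_size"] = library_sizes

    roster = _feature_roster(config)
    counts = _latent_counts(roster, u, library_sizes, config, rng)
    genus_counts = FeatureTable(
        pd.DataFrame(counts, index=roster["feature_id"].tolist(), columns=sample_ids),
        kind="taxon-genus",
        state="counts",
    )

    truth_frames = [roster.assign(kind="taxon-genus")]
    functional_tables: dict[str, FeatureTable] = {}
    for kind, layout in _FUNCTIONAL_LAYOUT.items():
        froster = _functional_roster(kind, layout)
        fcounts = _latent_counts(froster, u, library_sizes, config, rng, dominant_row=None)
        functional_tables[kind] = FeatureTable(
            pd.DataFrame(fcounts, index=froster["feature_id"].tolist(), columns=sample_ids),
            kind=kind,
            state="counts",
        )
        truth_frames.append(froster.assign(kind=kind))

    truth = pd.concat(truth_frames, ignore_index=True)[["feature_id", "kind", "role", "hub"]]

    cog_ids = functional_tables["cog"].feature_ids
    cats = rng.choice(len(COG_CATEGORIES), len(cog_ids))
    cog_categories = {f: COG_CATEGORIES[c] for f, c in zip(cog_ids, cats)}

    return SyntheticCohort(
        metadata=metadata,
        genus_counts=genus_counts,
        functional_tables=functional_tables,
        truth=truth,
        cog_categories=cog_categories,
        config=config,
    )


# ---------------------------------------------------------------------------
# hit-table fixture


@dataclass
class HitTableFixture:
    """Read-level hit table with pass/fail truth recorded at generation."""

    hits: pd.DataFrame
    thresholds: HitThresholds
    n_passing: int
    passing_per_cell: pd.DataFrame  # features x samples truth counts


def generate_hit_table(
    cohort: SyntheticCohort,
    thresholds: HitThresholds | None = None,
    seed: int = 0,
    n_rows: int = 400,
    pass_fraction: float = 0.5,
) -> HitTableFixture:
    """Emit read-level hits straddling the filtering thresholds.

    Each row is pre-decided to pass or fail: passing rows draw every
    alignment statistic strictly above its threshold, failing rows draw at
    least one statistic at or below it. The pass/fail truth counts are
    recorded at generation, independent of any filtering code.
    """
    thresholds = thresholds or HitThresholds.taxa()
    rng = np.random.default_rng(seed)
    features = cohort.genus_counts.feature_ids
    samples = cohort.genus_counts.sample_ids

    t_id = thresholds.min_identity_pct
    t_cov = thresholds.min_query_coverage_pct
    t_len = thresholds.min_alignment_length_bp

    rows = []
    cell_counts = pd.DataFrame(0, index=features, columns=samples)
    for k in range(n_rows):
        feature = features[rng.integers(len(features))]
        sample = samples[rng.integers(len(samples))]
        should_pass = rng.random() < pass_fraction
        if should_pass:
            ident = rng.uniform(t_id + 0.5, 100.0)
            cov = rng.uniform(t_cov + 0.5, 100.0)
            alen = int(rng.integers((t_len or 0) + 1, 400))
        else:
            # fail on at least one statistic; others drawn freely
            which = rng.integers(3 if t_len is not None else 2)
            ident = rng.uniform(30.0, t_id) if which == 0 else rng.uniform(t_id + 0.5, 100.0)
            cov = rng.uniform(30.0, t_cov) if which == 1 else rng.uniform(t_cov + 0.5, 100.0)
            if t_len is not None:
                alen = int(rng.integers(20, t_len + 1)) if which == 2 else int(
                    rng.integers(t_len + 1, 400)
                )
            else:
                alen = int(rng.integers(20, 400))
        rows.append(
            {
                "read_id": f"read_{k:05d}",
                "sample_id": sample,
                "feature_id": feature,
                "identity_pct": round(float(ident), 2),
                "coverage_pct": round(float(cov), 2),
                "alignment_length": alen,
            }
        )
        # re-evaluate the drawn values against the strict rule: rounding may
        # not cross a threshold because passing draws sit >= 0.5 above it
        passes = rows[-1]["identity_pct"] > t_id and rows[-1]["coverage_pct"] > t_cov
        if t_len is not None:
            passes = passes and alen > t_len
        if passes:
            cell_counts.loc[feature, sample] += 1

    hits = pd.DataFrame(rows)
    return HitTableFixture(
        hits=hits,
        thresholds=thresholds,
        n_passing=int(cell_counts.to_numpy().sum()),
        passing_per_cell=cell_counts,
    )
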