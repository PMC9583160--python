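"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates the study design the analysis targets: a few dozen
soil metagenomes annotated at KO level with positive Estimated Copy values,
a metadata table of biogeochemical covariates with planted linear
correlations to chosen gene metrics, planted categorical association rules
between covariate bins and operon presence, and planar coordinates with a
smooth spatial gradient. It is a structural emulator for exercising every
pipeline stage end-to-end — not a statistical twin of any real dataset.

Model
-----
* Per KO ``k`` and sample: detection ~ Bernoulli(prevalence_k); detected KOs
  get ``1 + NegBin`` distinct GeneIDs; each GeneID's Estimated Copy is
  log-normal.
* A covariate targeting metric ``m`` (richness or abundance of one KO) is
  built by a Gaussian copula: the metric's normal scores are mixed with
  independent noise at weight rho, then shifted/scaled to the covariate's
  output units. The realized sample correlation is recorded in the truth
  record.
* A planted rule ``{var in category} => {Protein Present/Absent}`` is
  enforced after covariate generation: for each sample in the antecedent
  category (empirical-quantile bins, matching the miner's discretization)
  the operon's KO records are completed or deleted with the stated
  obedience probability.
* Coordinates are a jittered cluster layout; spatial covariates decay as a
  Gaussian bump around a field center.

Everything is driven by one integer seed; the same config and seed give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .catalog import GeneCatalog, load_catalog
from .rules import discretize

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateSpec:
    """One synthetic biogeochemical covariate.

    ``target_metric``/``target_ko`` select the gene statistic the covariate
    is correlated with (``rho``); with ``target_ko=None`` the covariate is
    independent noise, and ``spatial=True`` instead follows the config's
    spatial gradient. ``mean``/``sd`` set the output units.
    """

    name: str
    mean: float
    sd: float
    rho: float = 0.0
    target_metric: str = "richness"  # "richness" | "abundance"
    target_ko: str | None = None
    spatial: bool = False


@dataclass(frozen=True)
class PlantedRule:
    """A deterministic-ish implication planted into the dataset.

    ``variable``/``category`` form the antecedent item (3-bin labels
    ``<30%``/``30-70%``/``>70%`` or 2-bin ``<50%``/``>50%``); the consequent
    is presence (or absence) of a catalog protein's full operon. Obedience
    is the per-sample probability that the consequent is enforced.
    """

    variable: str
    category: str
    protein: str
    present: bool = True
    obedience: float = 1.0


def _default_covariates() -> tuple[CovariateSpec, ...]:
    # Emulates the study's covariate families: alkaline pH negatively
    # coupled to denitrification-gene richness, water/nitrogen positively
    # coupled, a biomass field on a spatial gradient, independent carbon.
    return (
        CovariateSpec("pH", mean=8.6, sd=0.5, rho=-0.6,
                      target_metric="richness", target_ko="K00368"),
        CovariateSpec("soil_water_pct", mean=8.0, sd=3.0, rho=0.6,
                      target_metric="richness", target_ko="K00376"),
        CovariateSpec("nitrogen_pct", mean=0.08, sd=0.03, rho=0.5,
                      target_metric="abundance", target_ko="K02588"),
        CovariateSpec("carbon_pct", mean=0.4, sd=0.15),
        CovariateSpec("biomass", mean=5.0, sd=2.0, spatial=True),
        CovariateSpec("taxa_richness", mean=120.0, sd=40.0, rho=0.5,
                      target_metric="richness", target_ko="K00372"),
    )


def _default_rules() -> tuple[PlantedRule, ...]:
    return (PlantedRule("soil_water_pct", ">70%", "NosZ", present=True,
                        obedience=1.0),)


@dataclass
class SimulationConfig:
    """Full parameterization of one synthetic dataset (32 samples default)."""

    n_samples: int = 32
    seed: int = 0
    mean_richness: float = 3.0  # mean GeneIDs per detected (sample, KO)
    dispersion: float = 2.0  # negative-binomial size parameter
    copy_mu: float = 0.0  # log-normal log-mean of Estimated Copy
    copy_sigma: float = 0.5
    prevalence: dict[str, float] = field(default_factory=dict)  # per-KO detection prob
    covariates: tuple[CovariateSpec, ...] = field(default_factory=_default_covariates)
    planted_rules: tuple[PlantedRule, ...] = field(default_factory=_default_rules)
    n_clusters: int = 4  # sampling-site clusters
    region_size: float = 10_000.0  # meters
    cluster_sd: float = 600.0  # jitter around cluster centers
    gradient_length: float = 3_000.0  # decay length of the spatial bump

    def validate(self) -> None:
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples")
        for c in self.covariates:
            if not -1.0 <= c.rho <= 1.0:
                raise ValueError(f"covariate {c.name}: |rho| must be <= 1")
            if c.target_metric not in ("richness", "abundance"):
                raise ValueError(f"covariate {c.name}: bad target metric")
        for r in self.planted_rules:
            if not 0.0 <= r.obedience <= 1.0:
                raise ValueError(f"rule on {r.protein}: obedience must be in [0,1]")
        for p in self.prevalence.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("prevalence must be in [0,1]")


def default_prevalence(catalog: GeneCatalog) -> dict[str, float]:
    """Per-KO detection probabilities spanning ubiquitous to rare.

    Evenly spaced over [0.15, 1.0] in catalog order so that both the
    always-present and the seldom-seen code paths are exercised.
    """
    kos = catalog.kos
    grid = np.linspace(1.0, 0.15, len(kos))
    return {ko: float(p) for ko, p in zip(kos, grid)}


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _normal_scores(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform (average ranks for ties).

    Tied values (e.g. the zero block of an undetected KO) share one score so
    that the planted correlation is not diluted by arbitrary tie ordering.
    """
    from scipy import stats

    v = np.asarray(values, dtype=float)
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf(ranks / (len(v) + 1))


def _metric_vector(
    records: pd.DataFrame, samples: Sequence[str], ko: str, metric: str
) -> np.ndarray:
    sub = records[records["ko"] == ko]
    if metric == "richness":
        agg = sub.groupby("sample_id")["gene_id"].count()
    else:
        agg = sub.groupby("sample_id")["estimated_copy"].sum()
    return agg.reindex(samples).fillna(0.0).to_numpy(dtype=float)


def generate(
    config: SimulationConfig | None = None,
    catalog: GeneCatalog | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate one synthetic dataset.

    Returns
    -------
    records:
        Long gene-record table ``sample_id, gene_id, ko, estimated_copy``.
    env:
        Sample-indexed metadata with ``x``, ``y`` and every covariate.
    truth:
        YAML-serializable record of every planted parameter plus realized
        correlations/prevalences — sufficient to recompute each expected
        statistic without re-sampling.
    """
    config = config or SimulationConfig()
    config.validate()
    catalog = catalog or load_catalog()
    rng = np.random.default_rng(config.seed)
    samples = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    prevalence = dict(config.prevalence) or default_prevalence(catalog)
    unknown = set(prevalence) - set(catalog.kos)
    if unknown:
        raise ValueError(f"prevalence given for non-catalog KOs: {sorted(unknown)}")

    # --- coordinates: jittered cluster layout ------------------------------
    centers = rng.uniform(0.15, 0.85, size=(config.n_clusters, 2)) * config.region_size
    assignment = rng.integers(0, config.n_clusters, size=config.n_samples)
    coords = centers[assignment] + rng.normal(
        scale=config.cluster_sd, size=(config.n_samples, 2)
    )
    field_center = centers[0]

    # --- gene records -------------------------------------------------------
    nb_p = config.dispersion / (config.dispersion + (config.mean_richness - 1.0))
    rows: list[tuple[str, str, str, float]] = []
    counters = {s: 0 for s in samples}

    def add_record(sample: str, ko: str) -> None:
        counters[sample] += 1
        copy = float(rng.lognormal(config.copy_mu, config.copy_sigma))
        rows.append((sample, f"{sample}_g{counters[sample]:04d}", ko, copy))

    for ko in catalog.kos:
        p_k = prevalence.get(ko, 0.5)
        detected = rng.random(config.n_samples) < p_k
        n_extra = rng.negative_binomial(config.dispersion, nb_p, size=config.n_samples)
        for s_idx, sample in enumerate(samples):
            if not detected[s_idx]:
                continue
            for _ in range(1 + int(n_extra[s_idx])):
                add_record(sample, ko)

    records = pd.DataFrame(
        rows, columns=["sample_id", "gene_id", "ko", "estimated_copy"]
    )

    # --- covariates ---------------------------------------------------------
    env = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    env["x"] = coords[:, 0]
    env["y"] = coords[:, 1]
    realized: dict[str, float] = {}
    for spec in config.covariates:
        if spec.spatial:
            d2 = ((coords - field_center) ** 2).sum(axis=1)
            bump = np.exp(-d2 / (2.0 * config.gradient_length**2))
            z = (bump - bump.mean()) / (bump.std() or 1.0)
            z = 0.9 * z + np.sqrt(1 - 0.9**2) * rng.standard_normal(config.n_samples)
        elif spec.target_ko is not None:
            m = _metric_vector(records, samples, spec.target_ko, spec.target_metric)
            zm = _normal_scores(m)
            eps = rng.standard_normal(config.n_samples)
            z = spec.rho * zm + np.sqrt(1.0 - spec.rho**2) * eps
        else:
            z = rng.standard_normal(config.n_samples)
        env[spec.name] = spec.mean + spec.sd * z

    # --- planted rules ------------------------------------------------------
    rule_truth = []
    for rule in config.planted_rules:
        scheme = 2 if rule.category in ("<50%", ">50%") else 3
        disc = discretize(env[rule.variable], scheme)
        in_category = disc.categories == rule.category
        kos = sorted(catalog.members_of_protein(rule.protein))
        enforced = []
        for sample, hit in in_category.items():
            if not hit:
                continue
            if rng.random() >= rule.obedience:
                continue
            enforced.append(sample)
            have = {r[2] for r in rows if r[0] == sample}
            if rule.present:
                for ko in kos:
                    if ko not in have:
                        add_record(sample, ko)
            else:
                rows = [
                    r for r in rows if not (r[0] == sample and r[2] in kos)
                ]
        rule_truth.append(
            {
                "variable": rule.variable,
                "category": rule.category,
                "protein": rule.protein,
                "present": rule.present,
                "obedience": rule.obedience,
                "n_antecedent": int(in_category.sum()),
                "enforced_samples": enforced,
            }
        )

    records = pd.DataFrame(
        rows, columns=["sample_id", "gene_id", "ko", "estimated_copy"]
    )
    records = records.sort_values(["sample_id", "gene_id"]).reset_index(drop=True)

    for spec in config.covariates:
        if spec.target_ko is not None and not spec.spatial:
            m = _metric_vector(records, samples, spec.target_ko, spec.target_metric)
            if np.ptp(m) > 0:
                realized[spec.name] = float(np.corrcoef(env[spec.name], m)[0, 1])

    realized_prev = {
        ko: float((records["ko"] == ko).groupby(records["sample_id"]).any()
                  .reindex(samples).fillna(False).mean())
        for ko in catalog.kos
    }
    truth = {
        "config": {
            **{k: v for k, v in asdict(config).items()
               if k not in ("covariates", "planted_rules")},
            "covariates": [asdict(c) for c in config.covariates],
            "planted_rules": [asdict(r) for r in config.planted_rules],
        },
        "prevalence_planted": {k: float(v) for k, v in prevalence.items()},
        "prevalence_realized": realized_prev,
        "realized_correlations": realized,
        "rules": rule_truth,
        "field_center": [float(field_center[0]), float(field_center[1])],
    }
    return records, env, truth


def write_dataset(
    records: pd.DataFrame,
    env: pd.DataFrame,
    truth: dict,
    outdir: str | Path,
) -> Path:
    """Write a dataset in the pipeline's input layout.

    Per-sample gene-record TSVs plus ``manifest.csv``, ``env.csv`` and
    ``truth.yaml`` under ``outdir``. Byte-identical for identical inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for sample_id, sub in records.groupby("sample_id", sort=True):
        fname = f"records_{sample_id}.tsv"
        sub[["gene_id", "ko", "estimated_copy"]].to_csv(
            outdir / fname, sep="\t", index=False
        )
        manifest_rows.append((sample_id, fname))
    pd.DataFrame(manifest_rows, columns=["sample_id", "path"]).to_csv(
        outdir / "manifest.csv", index=False
    )
    env.reset_index().to_csv(outdir / "env.csv", index=False)
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
    return outdir


# ---------------------------------------------------------------------------
# Bundled micro-fixture
# ---------------------------------------------------------------------------

_FIXTURE_KOS = ("K00368", "K00376", "K10535", "K02586", "K02591", "K02588")

_FIXTURE_RECORDS = [
    # sample, gene_id, ko, estimated_copy
    ("S1", "g1", "K00368", 1.0), ("S1", "g2", "K00368", 2.5),
    ("S1", "g3", "K00368", 3.0), ("S1", "g4", "K00376", 4.0),
    ("S1", "g5", "K02586", 1.0), ("S1", "g6", "K02591", 1.0),
    ("S1", "g7", "K02588", 2.0),
    ("S2", "g1", "K00368", 2.0), ("S2", "g2", "K02588", 1.5),
    ("S3", "g1", "K00368", 1.0), ("S3", "g2", "K00368", 1.0),
    ("S3", "g3", "K10535", 0.5),
    ("S4", "g1", "K00368", 3.0), ("S4", "g2", "K00376", 1.0),
    ("S4", "g3", "K00376", 2.0),
    ("S5", "g1", "K00368", 1.0), ("S5", "g2", "K02586", 1.0),
    ("S5", "g3", "K02591", 1.0),
    ("S6", "g1", "K00368", 2.0), ("S6", "g2", "K00376", 1.0),
    ("S6", "g3", "K02586", 1.0), ("S6", "g4", "K02591", 2.0),
    ("S6", "g5", "K02588", 1.0),
    ("S7", "g1", "K10535", 1.0), ("S7", "g2", "K10535", 1.0),
    ("S8", "g1", "K00368", 1.0),
]

_FIXTURE_ENV = {
    "sample_id": ["S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8"],
    "x": [0.0, 2.0, 4.0, 1.0, 3.0, 0.0, 4.0, 2.0],
    "y": [0.0, 0.0, 1.0, 2.0, 3.0, 4.0, 4.0, 5.0],
    "pH": [9.0, 8.5, 8.2, 8.8, 7.9, 8.0, 9.5, 7.6],
    "soil_water_pct": [2.0, 5.0, 8.0, 3.0, 9.0, 10.0, 1.0, 12.0],
}


def fixture_small() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic 8-sample, 6-KO micro-dataset with hand-checkable metrics.

    Covers a multi-gene operon (NifDKH: complete in S1 and S6, partial in
    S2 and S5), single-KO proteins (NirK, NosZ, Hao), zero rows, and an
    n=1 undefined variance. Used in documentation examples and as a golden
    fixture in tests.
    """
    records = pd.DataFrame(
        _FIXTURE_RECORDS, columns=["sample_id", "gene_id", "ko", "estimated_copy"]
    )
    env = pd.DataFrame(_FIXTURE_ENV).set_index("sample_id")
    return records, env
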