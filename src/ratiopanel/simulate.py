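"""Seeded synthetic cohorts with planted differential ratio structure.

The generator emulates the study design the pipeline targets: a training
cohort of plasma samples in three groups (LAC = lung adenocarcinoma,
BENIGN = non-neoplastic lung lesion, CONTROL = high-risk healthy), an
independent validation cohort, pooled-sample sequencing counts for
discovery, and per-individual triplicate qPCR CT values.

Generative model (all on the log2 scale):

* species baseline abundance ``b_s ~ Normal(baseline_log2_mean,
  baseline_log2_sd)``, shared between cohorts;
* per-sample true expression ``e_si = b_s + effect_s(group_i) +
  Normal(0, biological_sd)``, where ``effect_s`` is the planted shift on
  the numerator species of each planted pair in its affected groups;
* CT per technical replicate ``CT = ct_intercept - ct_slope * e_si +
  Normal(0, ct_replicate_sd)``, replicates collapsed by mean. With the
  default slope of 1 cycle per doubling (100% amplification efficiency),
  the pair dCT equals the pair's log2 expression ratio in expectation;
* pooled counts: a pool's relative abundance is the mean of its members'
  linear-scale expression, normalized; reads are drawn multinomially with
  ``library_size`` trials.

Planting a shift on one member makes every pair containing that member
differential; pairs of two unaffected species are exact nulls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError
from .io import (
    CountMatrix,
    CtMatrix,
    validate_annotations,
    validate_metadata,
)
from .ratios import pair_id

# group sizes of the emulated training / validation cohorts
TRAINING_SIZES = {"LAC": 50, "BENIGN": 35, "CONTROL": 29}
VALIDATION_SIZES = {"LAC": 44, "BENIGN": 32, "CONTROL": 51}

# observed small ncRNA class composition (415 species overall)
DEFAULT_CLASS_COUNTS = {
    "mature_miRNA": 310,
    "pre_miRNA": 32,
    "tRNA": 47,
    "snoRNA": 19,
    "rRNA": 3,
    "scRNA": 4,
}


@dataclass(frozen=True)
class PlantedPair:
    """Ground-truth differential pair: numerator species gets the shift."""

    species_a: int
    species_b: int
    effect_log2: float
    affected_groups: tuple[str, ...] = ("LAC", "BENIGN")


def _default_planted() -> tuple[PlantedPair, ...]:
    # seven panel-1-like pairs (up in LAC+BENIGN) and five panel-2-like
    # pairs (up in LAC only), with effects spanning the reported range
    p1 = [1.73, 1.61, 2.31, 3.31, 3.37, 2.19, 2.89]
    p2 = [0.93, 1.35, 1.40, 0.96, 0.94]
    pairs = []
    idx = 0
    for e in p1:
        pairs.append(PlantedPair(idx, idx + 1, e, ("LAC", "BENIGN")))
        idx += 2
    for e in p2:
        pairs.append(PlantedPair(idx, idx + 1, e, ("LAC",)))
        idx += 2
    return tuple(pairs)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic study; defaults mirror the emulated design."""

    n_species: int = 415
    n_per_group: dict = field(default_factory=lambda: dict(TRAINING_SIZES))
    n_per_group_validation: dict = field(
        default_factory=lambda: dict(VALIDATION_SIZES)
    )
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    planted_pairs: tuple[PlantedPair, ...] = field(default_factory=_default_planted)
    biological_sd: float = 0.5
    ct_intercept: float = 36.0
    ct_slope: float = 1.0
    ct_replicate_sd: float = 0.25
    replicates: int = 3
    pools_per_group: int = 2
    library_size: int = 20_000_000
    class_counts: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ConfigError("n_species must be >= 2")
        if self.library_size <= 0:
            raise ConfigError("library_size must be > 0")
        if self.biological_sd < 0 or self.ct_replicate_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        for p in self.planted_pairs:
            if not np.isfinite(p.effect_log2):
                raise ConfigError("planted effect sizes must be finite")
            if p.species_a == p.species_b:
                raise ConfigError("planted pair members must be distinct")
            if not (0 <= p.species_a < self.n_species
                    and 0 <= p.species_b < self.n_species):
                raise ConfigError(
                    f"planted species index out of range: "
                    f"({p.species_a}, {p.species_b}) with n_species={self.n_species}"
                )
            bad = set(p.affected_groups) - set(TRAINING_SIZES)
            if bad:
                raise ConfigError(f"unknown affected group(s): {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "SimulationConfig":
        doc = dict(doc)
        if "planted_pairs" in doc:
            doc["planted_pairs"] = tuple(
                PlantedPair(
                    species_a=int(p["species_a"]),
                    species_b=int(p["species_b"]),
                    effect_log2=float(p["effect_log2"]),
                    affected_groups=tuple(p.get("affected_groups", ("LAC", "BENIGN"))),
                )
                for p in doc["planted_pairs"]
            )
        return cls(**doc)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def species_table(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic species ids and classes for a configuration.

    Classes are assigned in proportion to ``class_counts``, except that the
    species used by planted pairs are forced to mature miRNA so they are
    never excluded from pair enumeration.
    """
    counts = dict(config.class_counts)
    total = sum(counts.values())
    classes = []
    for cls_name, cnt in counts.items():
        n = round(cnt / total * config.n_species)
        classes.extend([cls_name] * n)
    classes = classes[: config.n_species]
    while len(classes) < config.n_species:
        classes.append("mature_miRNA")
    planted_idx = {i for p in config.planted_pairs for i in (p.species_a, p.species_b)}
    # stable shuffle so excluded classes are not clustered at the end
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    order = rng.permutation(config.n_species)
    classes = [classes[i] for i in order]
    for i in planted_idx:
        classes[i] = "mature_miRNA"
    ids = [f"sim-{classes[i][:3]}-{i:04d}" for i in range(config.n_species)]
    return validate_annotations(
        pd.DataFrame({"species_id": ids, "rna_class": classes})
    )


def _baselines(config: SimulationConfig) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    return rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, config.n_species
    )


def _group_effects(config: SimulationConfig) -> dict[str, np.ndarray]:
    eff = {g: np.zeros(config.n_species) for g in TRAINING_SIZES}
    for p in config.planted_pairs:
        for g in p.affected_groups:
            eff[g][p.species_a] += p.effect_log2
    return eff


@dataclass(frozen=True)
class CohortSim:
    """One simulated cohort: CT data, metadata, and the generative truth."""

    ct: CtMatrix
    ct_replicates: pd.DataFrame
    metadata: pd.DataFrame
    expression: pd.DataFrame  # species × samples, true log2 expression
    truth: pd.DataFrame


def truth_table(config: SimulationConfig) -> pd.DataFrame:
    ids = species_table(config)["species_id"].to_numpy()
    rows = [
        {
            "pair_id": pair_id(ids[p.species_a], ids[p.species_b]),
            "species_a": ids[p.species_a],
            "species_b": ids[p.species_b],
            "effect_log2": p.effect_log2,
            "affected_groups": "+".join(p.affected_groups),
        }
        for p in config.planted_pairs
    ]
    return pd.DataFrame(
        rows,
        columns=["pair_id", "species_a", "species_b", "effect_log2", "affected_groups"],
    )


def simulate_cohort(config: SimulationConfig, cohort: str = "training") -> CohortSim:
    """Simulate per-individual true expression and triplicate CT values."""
    if cohort not in ("training", "validation"):
        raise ConfigError(f"unknown cohort {cohort!r}")
    sizes = config.n_per_group if cohort == "training" else config.n_per_group_validation
    tag = {"training": "tr", "validation": "va"}[cohort]
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 303 if cohort == "training" else 404])
    )
    base = _baselines(config)
    effects = _group_effects(config)
    ids = species_table(config)["species_id"].to_numpy()

    cols, groups = [], []
    expr_cols = []
    for g in ("LAC", "BENIGN", "CONTROL"):
        n = int(sizes.get(g, 0))
        for i in range(n):
            sid = f"{tag}_{g}_{i + 1:03d}"
            e = base + effects[g] + rng.normal(0.0, config.biological_sd, config.n_species)
            cols.append(sid)
            groups.append(g)
            expr_cols.append(e)
    expression = pd.DataFrame(
        np.column_stack(expr_cols), index=ids, columns=cols
    )

    ct_true = config.ct_intercept - config.ct_slope * expression
    rep_frames = {}
    for r in range(1, config.replicates + 1):
        noise = rng.normal(0.0, config.ct_replicate_sd, ct_true.shape)
        rep = ct_true + noise
        for j, sid in enumerate(cols):
            rep_frames[f"{sid}_r{r}"] = rep.iloc[:, j]
    # interleave replicate columns per sample for the on-disk layout
    ordered = [f"{sid}_r{r}" for sid in cols for r in range(1, config.replicates + 1)]
    ct_replicates = pd.DataFrame(rep_frames)[ordered]
    blocks = ct_replicates.to_numpy().reshape(len(ids), len(cols), config.replicates)
    ct = pd.DataFrame(blocks.mean(axis=2), index=ids, columns=cols)

    metadata = validate_metadata(
        pd.DataFrame({"sample_id": cols, "group": groups, "cohort": cohort})
    )
    return CohortSim(
        ct=CtMatrix(ct, replicate_count=config.replicates),
        ct_replicates=ct_replicates,
        metadata=metadata,
        expression=expression,
        truth=truth_table(config),
    )


def default_pool_spec(metadata: pd.DataFrame, pools_per_group: int = 2):
    """Split each group's samples into roughly equal pools (by sample order)."""
    spec = []
    for g in ("LAC", "BENIGN", "CONTROL"):
        members = metadata.loc[metadata["group"] == g, "sample_id"].tolist()
        if not members:
            continue
        chunks = np.array_split(np.asarray(members, dtype=object), pools_per_group)
        for k, chunk in enumerate(chunks, start=1):
            spec.append((g, f"pool_{g}_{k}", list(chunk)))
    return spec


def pool_samples(
    expression: pd.DataFrame,
    pool_spec,
    library_size: int,
    seed: int = 0,
) -> CountMatrix:
    """Multinomial sequencing counts of pooled samples.

    Pooling averages the members' *linear-scale* expression (equal plasma
    volume per individual), normalizes to relative abundance, and draws
    ``library_size`` reads multinomially per pool, so each pool's column
    sum equals ``library_size`` exactly.
    """
    if library_size <= 0:
        raise ConfigError("library_size must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    linear = np.exp2(expression)
    cols = {}
    for item in pool_spec:
        group, name, members = item
        if len(members) == 0:
            raise ConfigError(f"empty pool {name!r}")
        missing = [m for m in members if m not in linear.columns]
        if missing:
            raise ConfigError(f"pool {name!r} references unknown sample(s) {missing[:5]}")
        mean_linear = linear[list(members)].mean(axis=1).to_numpy()
        p = mean_linear / mean_linear.sum()
        cols[name] = rng.multinomial(library_size, p)
    counts = pd.DataFrame(cols, index=expression.index, dtype=np.int64)
    return CountMatrix(counts)


@dataclass(frozen=True)
class SyntheticStudy:
    """A complete two-cohort study: counts, CT matrices, metadata, truth."""

    annotations: pd.DataFrame
    counts: CountMatrix
    training: CohortSim
    validation: CohortSim

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.concat(
            [self.training.metadata, self.validation.metadata], ignore_index=True
        )

    @property
    def truth(self) -> pd.DataFrame:
        return self.training.truth


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Simulate both cohorts plus pooled-sequencing counts of the training one."""
    training = simulate_cohort(config, "training")
    validation = simulate_cohort(config, "validation")
    spec = default_pool_spec(training.metadata, config.pools_per_group)
    counts = pool_samples(
        training.expression, spec, config.library_size, seed=config.seed
    )
    return SyntheticStudy(
        annotations=species_table(config),
        counts=counts,
        training=training,
        validation=validation,
    )


def write_study(study: SyntheticStudy, out_dir) -> dict[str, str]:
    """Write the study as the pipeline's plain-text input artifacts."""
    from pathlib import Path

    from .io import write_annotations, write_count_matrix, write_metadata

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotations": out / "annotations.tsv",
        "counts": out / "counts.tsv",
        "ct_training": out / "ct_training.tsv",
        "ct_validation": out / "ct_validation.tsv",
        "metadata": out / "metadata.csv",
        "truth": out / "truth.tsv",
    }
    write_annotations(study.annotations, paths["annotations"])
    write_count_matrix(study.counts, paths["counts"])
    study.training.ct_replicates.to_csv(
        paths["ct_training"], sep="\t", index_label="species_id", na_rep="NA"
    )
    study.validation.ct_replicates.to_csv(
        paths["ct_validation"], sep="\t", index_label="species_id", na_rep="NA"
    )
    write_metadata(study.metadata, paths["metadata"])
    study.truth.to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
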