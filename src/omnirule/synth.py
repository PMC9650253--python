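"""Seeded synthetic multiomics datasets with known ground truth.

No raw data accompany the fish study this pipeline is modelled on, so
every downstream method is exercised on synthetic data that emulates
the statistical structure the analysis assumes:

* muscle-metabolite ("NMR") and gut-microbiota ("taxa") composition
  tables drawn from cluster-specific Dirichlet concentration vectors
  (gamma draws, column-normalised) — the simplest generative model
  that satisfies the simplex constraint of composition ratios;
* planted cluster structure: each cluster inflates the concentration
  of its own small set of discriminative features by a factor
  ``1 + separation``;
* strain-stratified phenotypes (length, weight, cutting-strength A/B,
  lipid, collagen) with per-strain mean shifts, so within-strain
  ranking is meaningful;
* categorical metadata (species, habitat, habitat name, water type)
  sampled per strain;
* optional planted metadata->feature association rules, enforced by
  resampling the target feature's within-sample rank tier with a
  configured conditional probability;
* an optional "extreme" sample concentrating nearly all microbiota
  mass on two taxa, to exercise the outlier-omission path.

Everything is a pure function of (config, seed): identical inputs give
bit-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlantedRule",
    "SynthConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "generate_two_group_tables",
]

SPECIES = (
    "O_mykiss",
    "O_masou",
    "O_nerka",
    "O_kisutch",
    "S_malma",
    "S_leucomaenis",
    "S_trutta",
)
HABITATS = ("river", "lake_or_pond", "sea")
SPOTS = {
    "river": ("chitose_river", "yoshida_river", "kushiro_river"),
    "lake_or_pond": ("lake_chuzenji", "lake_towada", "ashinoko_pond"),
    "sea": ("sanriku_coast", "uchiura_bay"),
}
PHENO_VARS = ("length", "weight", "A", "B", "lipid", "collagen")
_PHENO_BASE = {
    "length": (30.0, 3.0),  # cm: (grand mean, within-strain sd)
    "weight": (400.0, 50.0),  # g
    "A": (5.0, 0.8),  # cutting-strength log-fit slope (N)
    "B": (2.0, 0.5),  # cutting-strength log-fit intercept (N)
    "lipid": (8.0, 1.5),  # % wet weight
    "collagen": (1.5, 0.3),  # % wet weight
}


@dataclass(frozen=True)
class PlantedRule:
    """A planted metadata -> feature-tier association.

    When a sample carries metadata item ``item`` (e.g.
    ``"habitat=lake_or_pond"``), the feature ``feature`` of table
    ``omic`` is forced into (direction High) or out of the top rank
    quarter of that sample with conditional probability ``prob``;
    for Low, the bottom quarter.
    """

    item: str
    feature: str
    direction: str = "High"
    prob: float = 0.9
    omic: str = "nmr"

    def __post_init__(self) -> None:
        if self.direction not in ("High", "Low"):
            raise ValueError(f"direction must be High|Low, got {self.direction!r}")
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError(f"prob must be in [0, 1], got {self.prob}")
        if self.omic not in ("nmr", "taxa"):
            raise ValueError(f"omic must be nmr|taxa, got {self.omic!r}")
        if "=" not in self.item:
            raise ValueError(f"item must look like 'key=value', got {self.item!r}")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults mirror the modelled study's dimensions: 233 metabolite
    regions of interest, 21 taxonomic groups, ~120 fish spread over
    several strains.  ``separation`` scales cluster-mean offsets
    (0 = no cluster signal); ``noise_sd`` is the sd of per-sample
    log-normal jitter on the Dirichlet concentrations;
    ``concentration`` scales all concentrations (higher = tighter
    compositions; the default gives a ~15% within-cluster CV per
    feature).  ``cluster_weights`` sets relative cluster sizes; by
    default one cluster dominates with ~65% of the samples and the
    rest split the remainder evenly, emulating the strongly
    unbalanced group sizes seen in real cohorts.
    """

    n_samples: int = 120
    n_nmr_features: int = 233
    n_taxa: int = 21
    k_clusters: int = 3
    separation: float = 8.0
    n_strains: int = 7
    planted_rules: tuple[PlantedRule, ...] = ()
    noise_sd: float = 0.1
    seed: int = 0
    concentration: float = 50.0
    cluster_weights: tuple[float, ...] | None = None
    n_discriminative: int = 5
    n_discriminative_taxa: int = 2
    extreme_sample: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_rules", tuple(self.planted_rules))
        if self.cluster_weights is not None:
            object.__setattr__(self, "cluster_weights", tuple(self.cluster_weights))
        for fld in ("n_samples", "n_nmr_features", "n_taxa", "k_clusters",
                    "n_strains", "n_discriminative", "n_discriminative_taxa"):
            v = getattr(self, fld)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{fld} must be a positive integer, got {v!r}")
        if self.n_samples < self.k_clusters * 4:
            raise ValueError(
                "n_samples must be >= 4 * k_clusters "
                f"(got n_samples={self.n_samples}, k_clusters={self.k_clusters})"
            )
        if self.separation < 0:
            raise ValueError(f"separation must be >= 0, got {self.separation}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.concentration <= 0:
            raise ValueError(f"concentration must be > 0, got {self.concentration}")
        if self.cluster_weights is not None:
            if len(self.cluster_weights) != self.k_clusters:
                raise ValueError("cluster_weights must have k_clusters entries")
            if any(w <= 0 for w in self.cluster_weights):
                raise ValueError("cluster_weights must be positive")
        if self.k_clusters * self.n_discriminative > self.n_nmr_features:
            raise ValueError("n_discriminative too large for n_nmr_features")
        if self.k_clusters * self.n_discriminative_taxa > self.n_taxa:
            raise ValueError("n_discriminative_taxa too large for n_taxa")
        if self.n_strains > len(SPECIES):
            raise ValueError(f"n_strains must be <= {len(SPECIES)}")


@dataclass(frozen=True)
class GroundTruth:
    cluster_labels: pd.Series  # 1..k per sample
    discriminative_features: dict[str, tuple[str, ...]]
    planted_rules: tuple[PlantedRule, ...]


@dataclass(frozen=True)
class SyntheticDataset:
    """All tables share one sample index; compositions column-sum to 1."""

    nmr: pd.DataFrame  # features x samples
    taxa: pd.DataFrame  # features x samples
    phenotypes: pd.DataFrame  # samples x variables
    metadata: pd.DataFrame  # samples x categorical items (incl. strain)
    truth: GroundTruth

    def equals(self, other: "SyntheticDataset") -> bool:
        return (
            self.nmr.equals(other.nmr)
            and self.taxa.equals(other.taxa)
            and self.phenotypes.equals(other.phenotypes)
            and self.metadata.equals(other.metadata)
            and self.truth.cluster_labels.equals(other.truth.cluster_labels)
            and self.truth.discriminative_features
            == other.truth.discriminative_features
            and self.truth.planted_rules == other.truth.planted_rules
        )


def _balanced_labels(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.resize(np.arange(1, k + 1), n)
    rng.shuffle(labels)
    return labels


def _cluster_labels(
    n: int, k: int, weights: tuple[float, ...] | None, rng: np.random.Generator
) -> np.ndarray:
    """Cluster sizes from weights (default: one dominant cluster with
    ~65% of samples and the rest spread evenly — the unbalanced shape
    real cohorts of this kind report — each cluster at least 4
    samples)."""
    if weights is None:
        weights = (0.35 / max(k - 1, 1),) * (k - 1) + (0.65,) if k > 1 else (1.0,)
    w = np.asarray(weights, dtype=float)
    counts = np.maximum(np.floor(w / w.sum() * n).astype(int), 4)
    while counts.sum() > n:  # trim the largest until counts fit
        counts[np.argmax(counts)] -= 1
    counts[np.argmax(counts)] += n - counts.sum()
    labels = np.repeat(np.arange(1, k + 1), counts)
    rng.shuffle(labels)
    return labels


def _compositions(
    n_features: int,
    labels: np.ndarray,
    k: int,
    n_disc: int,
    separation: float,
    noise_sd: float,
    concentration: float,
    rng: np.random.Generator,
    prefix: str,
) -> tuple[np.ndarray, list[str], list[str]]:
    feature_ids = [f"{prefix}{i + 1}" for i in range(n_features)]
    base_alpha = rng.uniform(0.5, 1.5, size=n_features) * concentration
    disc_idx = rng.choice(n_features, size=k * n_disc, replace=False)
    cluster_alpha = np.tile(base_alpha, (k, 1))
    for c in range(k):
        block = disc_idx[c * n_disc : (c + 1) * n_disc]
        cluster_alpha[c, block] *= 1.0 + separation
    n = len(labels)
    vals = np.empty((n_features, n))
    for j in range(n):
        alpha = cluster_alpha[labels[j] - 1]
        if noise_sd > 0:
            alpha = alpha * np.exp(rng.normal(0.0, noise_sd, size=n_features))
        draw = rng.gamma(shape=alpha, scale=1.0)
        vals[:, j] = draw / draw.sum()
    disc_ids = [feature_ids[i] for i in np.sort(disc_idx)]
    return vals, feature_ids, disc_ids


def _force_rank_tier(
    column: np.ndarray,
    feat_idx: int,
    direction: str,
    in_tier: bool,
    rng: np.random.Generator,
) -> None:
    """Resample one feature's value so its within-sample rank lands in
    (or out of) the top/bottom quarter; column is renormalised in place."""
    n = len(column)
    q = n // 4
    others = np.delete(column, feat_idx)
    desc = np.sort(others)[::-1]  # length n-1
    if direction == "High":
        ranks = np.arange(1, q + 1) if in_tier else np.arange(q + 1, n + 1)
    else:
        ranks = np.arange(n - q + 1, n + 1) if in_tier else np.arange(1, n - q + 1)
    r = int(rng.choice(ranks))
    # value with exactly r-1 of the others above it
    upper = desc[r - 2] if r >= 2 else desc[0] * 1.5 + 1e-12
    lower = desc[r - 1] if r <= n - 1 else 0.0
    column[feat_idx] = rng.uniform(lower, upper)
    column /= column.sum()


def _apply_planted_rules(
    tables: dict[str, pd.DataFrame],
    metadata: pd.DataFrame,
    rules: Sequence[PlantedRule],
    rng: np.random.Generator,
) -> None:
    for rule in rules:
        key, _, value = rule.item.partition("=")
        if key not in metadata.columns:
            raise ValueError(f"planted rule item key {key!r} not in metadata")
        table = tables[rule.omic]
        if rule.feature not in table.index:
            raise ValueError(
                f"planted rule feature {rule.feature!r} not in {rule.omic} table"
            )
        feat_idx = table.index.get_loc(rule.feature)
        carriers = metadata[key].astype(str) == value
        for sample in metadata.index[carriers]:
            col = table[sample].to_numpy()
            in_tier = rng.uniform() < rule.prob
            _force_rank_tier(col, feat_idx, rule.direction, in_tier, rng)
            table[sample] = col


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Generate a full synthetic study from a validated config.

    Deterministic: the same config (including its seed) always yields
    bit-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"fish{i + 1:03d}" for i in range(n)]

    labels = _cluster_labels(n, config.k_clusters, config.cluster_weights, rng)

    nmr_vals, nmr_ids, nmr_disc = _compositions(
        config.n_nmr_features, labels, config.k_clusters, config.n_discriminative,
        config.separation, config.noise_sd, config.concentration, rng, prefix="ROI.",
    )
    taxa_vals, taxa_ids, taxa_disc = _compositions(
        config.n_taxa, labels, config.k_clusters, config.n_discriminative_taxa,
        config.separation, config.noise_sd, config.concentration, rng, prefix="taxon.",
    )
    nmr = pd.DataFrame(nmr_vals, index=nmr_ids, columns=sample_ids)
    taxa = pd.DataFrame(taxa_vals, index=taxa_ids, columns=sample_ids)

    # strains and per-strain metadata
    strains = np.array(SPECIES[: config.n_strains])
    strain_of = strains[_balanced_labels(n, config.n_strains, rng) - 1]
    habitat_pref = {s: rng.dirichlet(np.ones(len(HABITATS)) * 2.0) for s in strains}
    habitat = np.array(
        [HABITATS[rng.choice(len(HABITATS), p=habitat_pref[s])] for s in strain_of]
    )
    spot = np.array([SPOTS[h][rng.integers(len(SPOTS[h]))] for h in habitat])
    water = np.where(habitat == "sea", "salt", "fresh")
    metadata = pd.DataFrame(
        {
            "species": strain_of,
            "strain": strain_of,
            "habitat": habitat,
            "habitat_name": spot,
            "water": water,
        },
        index=sample_ids,
    )

    # strain-stratified phenotypes
    pheno = pd.DataFrame(index=sample_ids, columns=list(PHENO_VARS), dtype=float)
    strain_shift = {
        s: {v: rng.normal(0.0, sd) for v, (_, sd) in _PHENO_BASE.items()}
        for s in strains
    }
    for v, (mean, sd) in _PHENO_BASE.items():
        shifts = np.array([strain_shift[s][v] for s in strain_of])
        pheno[v] = mean + shifts + rng.normal(0.0, sd, size=n)

    _apply_planted_rules({"nmr": nmr, "taxa": taxa}, metadata, config.planted_rules, rng)

    if config.extreme_sample:
        # last sample: nearly all microbiota mass on two taxa
        col = np.full(config.n_taxa, 1e-4)
        col[0], col[1] = 0.9, 0.095
        taxa.iloc[:, -1] = col / col.sum()

    truth = GroundTruth(
        cluster_labels=pd.Series(labels, index=sample_ids, name="cluster"),
        discriminative_features={"nmr": tuple(nmr_disc), "taxa": tuple(taxa_disc)},
        planted_rules=config.planted_rules,
    )
    return SyntheticDataset(nmr=nmr, taxa=taxa, phenotypes=pheno,
                            metadata=metadata, truth=truth)


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> list[Path]:
    """Write a dataset as CSV tables plus a JSON ground-truth sidecar.

    Omics tables keep features as rows and samples as columns;
    phenotype and metadata tables have samples as rows.  The directory
    is created if needed; the written files round-trip through
    :func:`read_dataset` to an equal dataset.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in [("nmr", ds.nmr), ("taxa", ds.taxa),
                     ("phenotypes", ds.phenotypes), ("metadata", ds.metadata)]:
        p = out / f"{name}.csv"
        df.to_csv(p)
        paths.append(p)
    truth = {
        "cluster_labels": {
            str(k): int(v) for k, v in ds.truth.cluster_labels.items()
        },
        "discriminative_features": {
            k: list(v) for k, v in ds.truth.discriminative_features.items()
        },
        "planted_rules": [asdict(r) for r in ds.truth.planted_rules],
    }
    p = out / "truth.json"
    p.write_text(json.dumps(truth, indent=2))
    paths.append(p)
    return paths


def read_dataset(in_dir: str | Path) -> SyntheticDataset:
    """Read back a dataset written by :func:`write_dataset`."""
    d = Path(in_dir)
    rt = dict(index_col=0, float_precision="round_trip")
    nmr = pd.read_csv(d / "nmr.csv", **rt)
    taxa = pd.read_csv(d / "taxa.csv", **rt)
    pheno = pd.read_csv(d / "phenotypes.csv", **rt)
    meta = pd.read_csv(d / "metadata.csv", index_col=0)
    raw = json.loads((d / "truth.json").read_text())
    labels = pd.Series(
        {k: int(v) for k, v in raw["cluster_labels"].items()}, name="cluster"
    )
    labels.index = labels.index.astype(str)
    truth = GroundTruth(
        cluster_labels=labels,
        discriminative_features={
            k: tuple(v) for k, v in raw["discriminative_features"].items()
        },
        planted_rules=tuple(PlantedRule(**r) for r in raw["planted_rules"]),
    )
    return SyntheticDataset(nmr=nmr, taxa=taxa, phenotypes=pheno,
                            metadata=meta, truth=truth)


def generate_two_group_tables(
    n_a: int,
    n_b: int,
    n_features: int = 40,
    seed: int = 0,
    marker_feature: str | None = "marker",
    marker_share: tuple[float, float] = (0.2, 0.4),
    noise_sd: float = 0.1,
    concentration: float = 50.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two composition tables for a two-group classification benchmark.

    Both groups are drawn from the same tight Dirichlet baseline
    (``concentration`` as in :class:`SynthConfig`).  If
    ``marker_feature`` is given, group A additionally carries that
    feature with a dominant share drawn from ``marker_share`` while
    group B has it at exactly zero — a disjoint-support marker, the
    idealised analogue of a highly abundant clade-specific metabolite,
    that a classifier should separate perfectly and rank first in
    importance.  With ``marker_feature=None`` the two groups are
    exchangeable and classification accuracy should sit at chance.
    """
    if n_a < 4 or n_b < 4:
        raise ValueError("each group needs at least 4 samples")
    rng = np.random.default_rng(seed)
    base_alpha = rng.uniform(0.5, 1.5, size=n_features) * concentration
    feature_ids = [f"ROI.{i + 1}" for i in range(n_features)]

    def draw(n: int, prefix: str) -> pd.DataFrame:
        cols = {}
        for j in range(n):
            alpha = base_alpha * np.exp(rng.normal(0, noise_sd, n_features))
            v = rng.gamma(alpha)
            cols[f"{prefix}{j + 1:03d}"] = v / v.sum()
        return pd.DataFrame(cols, index=feature_ids)

    table_a = draw(n_a, "a")
    table_b = draw(n_b, "b")
    if marker_feature is not None:
        share = rng.uniform(*marker_share, size=n_a)
        table_a = table_a.mul(1.0 - share, axis=1)
        table_a.loc[marker_feature] = share
        table_b.loc[marker_feature] = 0.0
    return table_a, table_b
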