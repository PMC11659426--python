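"""Synthetic survey generator with known ground truth.

Emulates the statistical shape of a small subsurface-sediment
microbiome survey: ~10 geolocated samples, thousands of sparse,
heavy-tailed taxa, and a gene-group (functional) table that stays
nearly constant across samples because taxa within a functional group
are interchangeable (functional redundancy).

The generating model assigns every taxon to a functional group.  Each
group carries a lognormal "mass" that is the same in every sample;
within a group, taxa split the mass according to lognormal base shares.
Three switches perturb this neutral baseline:

* ``segregation`` s in (0, 1]: each group is split into two factions;
  in each sample one faction (chosen by a fair coin) holds the group's
  mass, and each member joins the hosting pattern with probability s
  (otherwise it is present independently with probability 1/2).
  Within-group co-presence is thereby depressed relative to
  independence while every taxon keeps an informative occupancy
  (~half the samples), so presence-based tests retain power; group
  masses stay fixed, the signature of stable function with variable
  taxonomy.  For s < 0, whole groups drop out of samples together,
  enhancing co-presence (aggregation).  s = 0 is neutral: no occupancy
  structure at all, and read placement is exchangeable with the
  co-occurrence null models, so their p-values calibrate.
* ``distance_decay`` (per km): taxon log-abundances acquire a spatially
  correlated Gaussian field with correlation exp(-lambda * distance),
  producing distance-decay of community similarity.
* ``env_effects``: per-covariate linear effects on taxon
  log-abundances, giving |delta covariate| real predictive power for
  pairwise dissimilarity.

Reads are then drawn multinomially per sample at lognormally
heterogeneous depths.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dissimilarity import geographic_distances
from .table import (
    RANKS,
    CommunityTable,
    FunctionalProfile,
    TaxonomyMap,
    read_table,
    read_taxonomy,
    to_proportions,
    write_table,
    write_taxonomy,
)

__all__ = ["GeneratorConfig", "SyntheticDataset", "generate",
           "write_dataset", "load_dataset"]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic survey.

    Defaults mirror the scale of the emulated study: 10 samples,
    2000 taxa, ~5412 reads per sample (54116 reads over 10 samples),
    100 functional groups of 20 taxa each, and a coordinate box along
    the Oregon coast spanning a few hundred km.
    """

    n_samples: int = 10
    n_taxa: int = 2000
    reads_per_sample: int = 5412
    depth_sigma: float = 0.3  # lognormal spread of per-sample depths
    abundance_sigma: float = 2.0  # log-sd of within-group taxon shares
    group_sigma: float = 1.0  # log-sd of functional-group masses
    n_functional_groups: int = 100
    segregation: float = 0.0  # s in [-1, 1]
    distance_decay: float = 0.0  # lambda, per km
    decay_sigma: float = 1.0  # amplitude of the spatial field
    env_effects: dict = field(default_factory=dict)
    n_env_variables: int = 5
    frac_unclassified_genus: float = 0.1
    lat_range: tuple = (42.0, 46.3)
    lon_range: tuple = (-124.2, -123.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.segregation <= 1.0:
            raise ValueError("segregation must lie in [-1, 1]")
        for name in ("n_samples", "n_taxa", "reads_per_sample",
                     "n_functional_groups"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_functional_groups > self.n_taxa:
            raise ValueError("more functional groups than taxa")

    @property
    def redundancy(self) -> int:
        """Approximate number of taxa per functional group."""
        return self.n_taxa // self.n_functional_groups


@dataclass
class SyntheticDataset:
    table: CommunityTable  # counts
    taxonomy: TaxonomyMap
    coordinates: dict  # sample_id -> (lat, lon)
    environment: pd.DataFrame  # samples x covariates
    functional: FunctionalProfile
    taxon_groups: dict  # taxon_id -> group_id
    config: GeneratorConfig


def _balanced_taxonomy(
    n_taxa: int, frac_unclassified: float, rng: np.random.Generator
) -> TaxonomyMap:
    """Random balanced hierarchy so collapsing is exercised at every rank."""
    n_genera = max(1, n_taxa // 5)
    lineages = {}
    unclassified = rng.random(n_taxa) < frac_unclassified
    for i in range(n_taxa):
        g = i % n_genera
        fam = g // 4
        order = fam // 2
        cls = order // 2
        phy = cls // 2
        dom = phy // 4
        lin = (
            f"d{dom}",
            f"p{phy}",
            f"c{cls}",
            f"o{order}",
            f"f{fam}",
            None if unclassified[i] else f"g{g}",
        )
        lineages[f"T{i + 1:05d}"] = lin
    return TaxonomyMap(lineages)


def generate(cfg: GeneratorConfig) -> SyntheticDataset:
    """Draw one synthetic dataset from the generating model."""
    rng = np.random.default_rng(cfg.seed)
    M, n = cfg.n_taxa, cfg.n_samples
    taxon_ids = [f"T{i + 1:05d}" for i in range(M)]
    sample_ids = [f"S{j + 1:02d}" for j in range(n)]

    lat = rng.uniform(*cfg.lat_range, size=n)
    lon = rng.uniform(*cfg.lon_range, size=n)
    coords = {sid: (float(a), float(b)) for sid, a, b in zip(sample_ids, lat, lon)}

    env = pd.DataFrame(
        rng.standard_normal((n, cfg.n_env_variables)),
        index=sample_ids,
        columns=[f"env_{k + 1}" for k in range(cfg.n_env_variables)],
    )

    groups = np.arange(M) % cfg.n_functional_groups
    group_ids = [f"G{g + 1:04d}" for g in range(cfg.n_functional_groups)]
    taxon_groups = {tid: group_ids[g] for tid, g in zip(taxon_ids, groups)}

    group_mass = rng.lognormal(0.0, cfg.group_sigma, size=cfg.n_functional_groups)
    shares = rng.lognormal(0.0, cfg.abundance_sigma, size=M)

    # within-group per-sample shares; faction alternation for s > 0
    s = cfg.segregation
    W = np.empty((M, n))
    for g in range(cfg.n_functional_groups):
        members = np.flatnonzero(groups == g)
        u = shares[members]
        m = len(members)
        if s > 0 and m >= 2:
            # alternate faction labels through the group so both factions
            # are nonempty; each sample hosts one faction
            faction = np.arange(m) % 2
            hosting = rng.integers(0, 2, size=n)
            follow = rng.random((m, n)) < s
            coin = rng.random((m, n)) < 0.5
            present = np.where(follow,
                               faction[:, None] == hosting[None, :], coin)
            # guarantee the group keeps its mass in every sample
            empty = ~present.any(axis=0)
            if empty.any():
                present[0, empty] = True
            masked = u[:, None] * present
            W[members] = group_mass[g] * masked / masked.sum(axis=0)
        else:
            base = u / u.sum()
            W[members] = group_mass[g] * base[:, None]
        if s < 0:
            # aggregation: whole group drops out of some samples together
            off = rng.random(n) < 0.5 * (-s)
            W[np.ix_(members, np.flatnonzero(off))] = 0.0

    if cfg.distance_decay > 0:
        geo = geographic_distances(coords).reorder(sample_ids)
        cov = np.exp(-cfg.distance_decay * geo.values)
        L = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
        fields = rng.standard_normal((M, n)) @ L.T
        W *= np.exp(cfg.decay_sigma * fields)

    for name, effect in cfg.env_effects.items():
        if name not in env.columns:
            raise ValueError(f"unknown environmental variable {name!r}")
        beta = rng.standard_normal(M)
        z = env[name].to_numpy()
        W *= np.exp(effect * np.outer(beta, z))

    depths = np.maximum(
        1,
        np.round(
            rng.lognormal(
                np.log(cfg.reads_per_sample) - cfg.depth_sigma**2 / 2,
                cfg.depth_sigma,
                size=n,
            )
        ).astype(np.int64),
    )
    counts = np.zeros((M, n), dtype=np.int64)
    for j in range(n):
        w = W[:, j]
        if w.sum() == 0:
            raise ValueError("a sample ended up with zero total intensity")
        counts[:, j] = rng.multinomial(depths[j], w / w.sum())

    table = CommunityTable(
        pd.DataFrame(counts, index=taxon_ids, columns=sample_ids), mode="counts"
    )
    taxonomy = _balanced_taxonomy(M, cfg.frac_unclassified_genus, rng)

    props, _ = to_proportions(table)
    fp = (
        props.data.groupby(pd.Series(taxon_groups), sort=True).sum()
        .reindex(group_ids).fillna(0.0)
    )
    colsums = fp.to_numpy().sum(axis=0)
    fp = fp / np.where(colsums == 0, 1.0, colsums)
    functional = FunctionalProfile(fp)

    return SyntheticDataset(
        table=table,
        taxonomy=taxonomy,
        coordinates=coords,
        environment=env,
        functional=functional,
        taxon_groups=taxon_groups,
        config=cfg,
    )


def write_dataset(d: SyntheticDataset, directory) -> dict[str, Path]:
    """Write the dataset as the TSV/JSON formats the analysis consumes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "community": directory / "community.tsv",
        "taxonomy": directory / "taxonomy.tsv",
        "metadata": directory / "metadata.tsv",
        "gene_groups": directory / "gene_groups.tsv",
        "taxon_groups": directory / "taxon_groups.tsv",
        "params": directory / "params.json",
    }
    write_table(d.table, paths["community"])
    write_taxonomy(d.taxonomy, paths["taxonomy"])
    meta = pd.DataFrame(
        {
            "latitude_deg": [d.coordinates[s][0] for s in d.table.sample_ids],
            "longitude_deg": [d.coordinates[s][1] for s in d.table.sample_ids],
        },
        index=d.table.sample_ids,
    )
    meta = pd.concat([meta, d.environment.loc[d.table.sample_ids]], axis=1)
    meta.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    d.functional.data.to_csv(paths["gene_groups"], sep="\t",
                             index_label="group_id")
    pd.Series(d.taxon_groups, name="group_id").to_csv(
        paths["taxon_groups"], sep="\t", index_label="taxon_id"
    )
    with open(paths["params"], "w") as fh:
        json.dump(dataclasses.asdict(d.config), fh, indent=2, sort_keys=True)
    return paths


def load_dataset(directory) -> SyntheticDataset:
    """Read back a dataset previously written by :func:`write_dataset`."""
    directory = Path(directory)
    with open(directory / "params.json") as fh:
        raw = json.load(fh)
    raw["lat_range"] = tuple(raw["lat_range"])
    raw["lon_range"] = tuple(raw["lon_range"])
    cfg = GeneratorConfig(**raw)
    table = read_table(directory / "community.tsv")
    taxonomy = read_taxonomy(directory / "taxonomy.tsv")
    meta = pd.read_csv(directory / "metadata.tsv", sep="\t", index_col=0)
    coords = {
        str(s): (float(meta.loc[s, "latitude_deg"]),
                 float(meta.loc[s, "longitude_deg"]))
        for s in meta.index
    }
    env = meta.drop(columns=["latitude_deg", "longitude_deg"])
    fp = FunctionalProfile(
        pd.read_csv(directory / "gene_groups.tsv", sep="\t", index_col=0)
    )
    tg = pd.read_csv(directory / "taxon_groups.tsv", sep="\t", index_col=0)
    taxon_groups = {str(k): str(v) for k, v in tg["group_id"].items()}
    return SyntheticDataset(
        table=table,
        taxonomy=taxonomy,
        coordinates=coords,
        environment=env,
        functional=fp,
        taxon_groups=taxon_groups,
        config=cfg,
    )
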