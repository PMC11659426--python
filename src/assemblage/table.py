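"""Taxa-by-sample tables: I/O, normalization, taxonomic collapsing and
gene-group proportion aggregation.

The central container is :class:`CommunityTable`, a labeled nonnegative
matrix with taxa as rows and samples as columns, carried either as raw
read counts or as per-sample proportions (each nonzero column summing
to 1).  All downstream statistics (dissimilarities, null models,
variability profiles) consume this container or the binary
:class:`PresenceAbsenceMatrix` derived from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "CommunityTable",
    "TaxonomyMap",
    "PresenceAbsenceMatrix",
    "FunctionalProfile",
    "TableError",
    "read_table",
    "write_table",
    "to_proportions",
    "to_presence_absence",
    "collapse_to_level",
    "aggregate_functional_profile",
    "read_taxonomy",
    "write_taxonomy",
]

#: Ordered taxonomic ranks, coarsest first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

PROPORTION_TOL = 1e-9


class TableError(ValueError):
    """Raised for malformed tables: duplicate labels, negative or
    non-numeric cells, unknown ranks, or inconsistent mappings."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    for lab in labels:
        seen[lab] = seen.get(lab, 0) + 1
    dups = [lab for lab, k in seen.items() if k > 1]
    if dups:
        raise TableError(f"duplicate {what} labels: {dups[:5]}")


@dataclass
class CommunityTable:
    """Taxa × samples matrix of counts or proportions.

    Parameters
    ----------
    data
        DataFrame with taxon IDs as the index and sample IDs as columns.
        Entries must be nonnegative; in ``"proportions"`` mode every
        column with any nonzero entry must sum to 1 within ``1e-9``.
    mode
        ``"counts"`` or ``"proportions"``.
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "proportions"):
            raise TableError(f"unknown mode {self.mode!r}")
        _check_unique(list(self.data.index), "taxon")
        _check_unique(list(self.data.columns), "sample")
        values = self.data.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            i, j = np.argwhere(values < 0)[0]
            raise TableError(
                f"negative entry at taxon {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )
        if self.mode == "proportions":
            sums = values.sum(axis=0)
            bad = np.flatnonzero((sums > 0) & (np.abs(sums - 1.0) > PROPORTION_TOL))
            if bad.size:
                raise TableError(
                    f"proportions column {self.data.columns[bad[0]]!r} "
                    f"sums to {sums[bad[0]]!r}, expected 1"
                )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def drop_empty_taxa(self) -> tuple["CommunityTable", int]:
        """Remove all-zero rows; returns (table, number dropped)."""
        keep = self.data.sum(axis=1) > 0
        dropped = int((~keep).sum())
        return CommunityTable(self.data.loc[keep].copy(), self.mode), dropped


@dataclass
class TaxonomyMap:
    """Mapping from taxon ID to a ranked lineage (domain .. genus).

    Lineage entries may be ``None`` meaning "unclassified at this rank";
    classification must not resume below a missing rank.
    """

    lineages: dict[str, tuple[str | None, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, lin in self.lineages.items():
            if len(lin) != len(RANKS):
                raise TableError(
                    f"lineage for {tid!r} has {len(lin)} ranks, expected {len(RANKS)}"
                )

    def __getitem__(self, taxon_id: str) -> tuple[str | None, ...]:
        return self.lineages[taxon_id]

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.lineages

    def prefix(self, taxon_id: str, level: str) -> tuple[str | None, ...]:
        depth = RANKS.index(level) + 1
        return self.lineages[taxon_id][:depth]


@dataclass
class PresenceAbsenceMatrix:
    """Binary taxa × samples occurrence matrix.

    ``occupancy`` (row sums) is the number of samples containing each
    taxon; ``richness`` (column sums) the number of taxa per sample.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise TableError("presence-absence entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        if self.values.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise TableError("matrix shape does not match labels")

    @property
    def occupancy(self) -> np.ndarray:
        """Per-taxon number of occupied samples (N_i)."""
        return self.values.sum(axis=1).astype(int)

    @property
    def richness(self) -> np.ndarray:
        """Per-sample number of present taxa."""
        return self.values.sum(axis=0).astype(int)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class FunctionalProfile:
    """Gene-group × samples proportion matrix; each column sums to 1."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "group")
        _check_unique(list(self.data.columns), "sample")
        values = self.data.to_numpy(dtype=float)
        if values.size and values.min() < 0:
            raise TableError("negative proportion in functional profile")
        sums = values.sum(axis=0)
        bad = np.flatnonzero((sums > 0) & (np.abs(sums - 1.0) > PROPORTION_TOL))
        if bad.size:
            raise TableError(
                f"functional profile column {self.data.columns[bad[0]]!r} "
                "does not sum to 1"
            )

    @property
    def group_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# I/O

def read_table(path, format: str = "tsv") -> CommunityTable:
    """Read a taxa-by-sample count table.

    ``tsv``: tab-separated, first column taxon IDs, header row sample
    IDs, '.' decimal, no quoting.  ``biom-like-json``: minimal BIOM v1
    JSON with ``rows``/``columns``/``data`` (dense or sparse).
    Row/column order of the input is preserved.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        _check_unique(list(df.index), "taxon")
        _check_unique(list(df.columns), "sample")
        numeric = df.apply(pd.to_numeric, errors="coerce")
        if numeric.isna().any().any():
            i, j = np.argwhere(numeric.isna().to_numpy())[0]
            raise TableError(
                f"non-numeric cell at taxon {df.index[i]!r}, "
                f"sample {df.columns[j]!r}: {df.iloc[i, j]!r}"
            )
        if (numeric.to_numpy() < 0).any():
            i, j = np.argwhere(numeric.to_numpy() < 0)[0]
            raise TableError(
                f"negative cell at taxon {df.index[i]!r}, "
                f"sample {df.columns[j]!r}: {df.iloc[i, j]!r}"
            )
        return CommunityTable(numeric, mode="counts")
    if format == "biom-like-json":
        with open(path) as fh:
            doc = json.load(fh)
        rows = [r["id"] for r in doc["rows"]]
        cols = [c["id"] for c in doc["columns"]]
        mat = np.zeros((len(rows), len(cols)))
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[int(i), int(j)] = v
        else:
            mat[:] = np.asarray(doc["data"], dtype=float)
        return CommunityTable(pd.DataFrame(mat, index=rows, columns=cols),
                              mode="counts")
    raise TableError(f"unknown table format {format!r}")


def write_table(t: CommunityTable, path) -> None:
    """Write a table as TSV; counts are written as integers."""
    df = t.data
    if t.mode == "counts":
        values = df.to_numpy(dtype=float)
        if np.allclose(values, np.round(values)):
            df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="taxon_id")


def read_taxonomy(path) -> TaxonomyMap:
    """Read a taxonomy TSV: taxon_id, domain..genus; empty = unclassified."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    lineages = {}
    for tid, row in df.iterrows():
        lin = tuple((v if v != "" else None) for v in row.tolist()[: len(RANKS)])
        lin = lin + (None,) * (len(RANKS) - len(lin))
        lineages[str(tid)] = lin
    return TaxonomyMap(lineages)


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    rows = {tid: [v if v is not None else "" for v in lin]
            for tid, lin in tax.lineages.items()}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    df.to_csv(path, sep="\t", index_label="taxon_id")


# ---------------------------------------------------------------------------
# Transformations

def to_proportions(t: CommunityTable) -> tuple[CommunityTable, list[str]]:
    """Normalize each sample (column) to sum 1.

    All-zero columns are left untouched and returned as the second
    element.  Idempotent: proportions in, proportions out.
    """
    values = t.values
    sums = values.sum(axis=0)
    zero_cols = [t.sample_ids[j] for j in np.flatnonzero(sums == 0)]
    safe = np.where(sums == 0, 1.0, sums)
    out = values / safe
    return (
        CommunityTable(
            pd.DataFrame(out, index=t.taxon_ids, columns=t.sample_ids),
            mode="proportions",
        ),
        zero_cols,
    )


def to_presence_absence(t: CommunityTable, threshold: float = 1) -> PresenceAbsenceMatrix:
    """Binarize: entry 1 iff value >= threshold.

    For counts the default threshold of one read means "detected at
    all"; proportions tables require a strictly positive threshold.
    """
    if t.mode == "proportions" and threshold <= 0:
        raise TableError("proportions mode requires a strictly positive threshold")
    if threshold <= 0:
        raise TableError("threshold must be positive")
    binary = (t.values >= threshold).astype(np.int8)
    return PresenceAbsenceMatrix(t.taxon_ids, t.sample_ids, binary)


def collapse_to_level(
    t: CommunityTable, tax: TaxonomyMap, level: str
) -> CommunityTable:
    """Sum rows sharing the same lineage prefix up to ``level``.

    Taxa unclassified at ``level`` are pooled by their deepest classified
    prefix into distinct ``unclassified-<prefix>`` rows, so per-sample
    totals are conserved exactly.
    """
    if level not in RANKS:
        raise TableError(f"unknown rank {level!r}; expected one of {RANKS}")
    missing = [tid for tid in t.taxon_ids if tid not in tax]
    if missing:
        raise TableError(f"taxa missing from taxonomy: {missing[:5]}")
    depth = RANKS.index(level) + 1
    labels = []
    for tid in t.taxon_ids:
        prefix = tax.lineages[tid][:depth]
        if all(v is not None for v in prefix):
            labels.append(";".join(prefix))
        else:
            known = []
            for v in prefix:
                if v is None:
                    break
                known.append(v)
            labels.append("unclassified-" + ";".join(known))
    grouped = t.data.groupby(np.asarray(labels), sort=False).sum()
    return CommunityTable(grouped, mode=t.mode)


def aggregate_functional_profile(
    contig_coverage: pd.DataFrame,
    pcg_to_contig: Mapping[str, str],
    pcg_to_groups: Mapping[str, Iterable[str]],
    exclude_groups: Iterable[str] = (),
    exclude_before_renormalization: bool = True,
) -> FunctionalProfile:
    """Aggregate contig coverages into gene-group proportions.

    Per sample: contig coverages are normalized to proportions, each
    protein-coding gene (PCG) inherits its host contig's proportion,
    PCG values are renormalized to sum 1, each group's proportion is the
    sum of its member PCGs' proportions, and finally group proportions
    are renormalized to sum 1 over the retained groups.

    ``exclude_groups`` removes non-functional catch-all categories;
    ``exclude_before_renormalization`` controls whether removal happens
    before or after the final normalization (the result is identical
    either way up to scaling, but both orders are supported).
    """
    exclude = set(exclude_groups)
    contigs = list(contig_coverage.index)
    missing = [p for p, c in pcg_to_contig.items() if c not in set(contigs)]
    if missing:
        raise TableError(
            f"PCGs reference contigs absent from the coverage table: {missing[:5]}"
        )
    cov = contig_coverage.to_numpy(dtype=float)
    if cov.size and cov.min() < 0:
        raise TableError("negative contig coverage")
    sums = cov.sum(axis=0)
    contig_prop = cov / np.where(sums == 0, 1.0, sums)
    contig_idx = {c: i for i, c in enumerate(contigs)}

    pcg_ids = list(pcg_to_contig)
    pcg_prop = np.stack([contig_prop[contig_idx[pcg_to_contig[p]]] for p in pcg_ids])
    pcg_sums = pcg_prop.sum(axis=0)
    pcg_prop = pcg_prop / np.where(pcg_sums == 0, 1.0, pcg_sums)

    group_ids: list[str] = []
    for p in pcg_ids:
        for g in pcg_to_groups.get(p, ()):
            if g not in group_ids:
                group_ids.append(g)
    if exclude_before_renormalization:
        group_ids = [g for g in group_ids if g not in exclude]
    group_mat = np.zeros((len(group_ids), contig_coverage.shape[1]))
    gidx = {g: i for i, g in enumerate(group_ids)}
    for pi, p in enumerate(pcg_ids):
        for g in pcg_to_groups.get(p, ()):
            if g in gidx:
                group_mat[gidx[g]] += pcg_prop[pi]
    gsums = group_mat.sum(axis=0)
    group_mat = group_mat / np.where(gsums == 0, 1.0, gsums)
    if not exclude_before_renormalization and exclude:
        keep = [i for i, g in enumerate(group_ids) if g not in exclude]
        group_ids = [group_ids[i] for i in keep]
        group_mat = group_mat[keep]
        gsums = group_mat.sum(axis=0)
        group_mat = group_mat / np.where(gsums == 0, 1.0, gsums)
    df = pd.DataFrame(group_mat, index=group_ids,
                      columns=list(contig_coverage.columns))
    return FunctionalProfile(df)
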