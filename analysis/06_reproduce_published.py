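"""Reproduce the deposited survey's headline numbers from its published
supplementary tables, if you have downloaded them.

This script expects two locally supplied TSV files (not redistributed
here) converted from the published supplementary data:

* ``--taxa``: taxa-by-sample read-count table (ASV or OTU level),
  first column taxon IDs, header row sample IDs;
* ``--metadata``: sample metadata with columns sample_id,
  latitude_deg, longitude_deg (plus any numeric covariates);
* optionally ``--taxonomy``: taxon_id + domain..genus columns, to also
  run the phylum-level Hellinger Mantel test.

It then recomputes the core-biome curve (average per-sample richness,
taxa shared by two random samples and by all samples, and the derived
percentage drops) and, with taxonomy, the phylum-level Hellinger
Mantel correlation against geographic distance.
"""

import argparse
import sys

import pandas as pd

from assemblage.dissimilarity import geographic_distances, pairwise_dissimilarity
from assemblage.mantel import mantel_test
from assemblage.table import (
    collapse_to_level,
    read_table,
    read_taxonomy,
    to_presence_absence,
)
from assemblage.variability import core_biome_curve


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--taxa", required=True, help="taxa x samples TSV")
    ap.add_argument("--metadata", required=True, help="sample metadata TSV")
    ap.add_argument("--taxonomy", default=None)
    ap.add_argument("--permutations", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    table, dropped = read_table(args.taxa).drop_empty_taxa()
    print(f"{table.shape[0]} taxa x {table.shape[1]} samples "
          f"({dropped} all-zero rows dropped)")

    pa = to_presence_absence(table)
    curve = core_biome_curve(pa, method="exact")
    drop2 = 100 * (1 - curve[1] / curve[0])
    print(f"average per-sample richness: {curve[0]:.1f}")
    print(f"shared by two random samples: {curve[1]:.1f} (down {drop2:.1f}%)")
    print(f"shared by all {pa.n_samples} samples: {curve[-1]:.0f}")

    if args.taxonomy is None:
        print("no taxonomy given; skipping the phylum-level Mantel test")
        return
    meta = pd.read_csv(args.metadata, sep="\t", index_col=0)
    if not {"latitude_deg", "longitude_deg"} <= set(meta.columns):
        sys.exit("metadata must have latitude_deg and longitude_deg columns")
    coords = {str(s): (float(meta.loc[s, "latitude_deg"]),
                       float(meta.loc[s, "longitude_deg"]))
              for s in meta.index}
    tax = read_taxonomy(args.taxonomy)
    phylum = collapse_to_level(table, tax, "phylum").drop_empty_taxa()[0]
    dm = pairwise_dissimilarity(phylum, "hellinger")
    res = mantel_test(dm, geographic_distances(coords),
                      n_perm=args.permutations, seed=args.seed)
    print(f"phylum-level Hellinger Mantel: rho = {res.rho:.2f}, "
          f"one-sided p = {res.p_one_sided:.3f}")


if __name__ == "__main__":
    main()
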