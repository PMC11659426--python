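"""Null-model tests of taxon co-distributions at every taxonomic
level: the checkerboard co-occurrence (CC) score against the
fixed-fixed (SIM9) swap null on presence/absence, and the Morisita
(MA) score against the IT abundance null on read counts.  In the
segregated synthetic survey both observed scores should fall below
their null means at the fine levels, with significantly low one-sided
p-values — the statistical fingerprint of competitive exclusion.
"""

import argparse
from pathlib import Path

import pandas as pd

from assemblage.nullmodels import bonferroni_threshold, null_test
from assemblage.simulate import load_dataset
from assemblage.table import collapse_to_level, to_presence_absence

LEVELS = ["asv", "genus", "family", "order", "class", "phylum"]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results")
    ap.add_argument("--n-null", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    dataset = load_dataset(args.data)
    table, _ = dataset.table.drop_empty_taxa()

    rows = []
    for level in LEVELS:
        lvl = (table if level == "asv"
               else collapse_to_level(table, dataset.taxonomy, level))
        lvl, _ = lvl.drop_empty_taxa()
        row = {"level": level, "n_taxa": lvl.shape[0]}
        try:
            cc = null_test("cc", to_presence_absence(lvl), "sim9",
                           n_null=args.n_null, seed=args.seed)
            row.update(cc_observed=cc.observed, cc_null_mean=cc.null_mean,
                       cc_p_low=cc.p_low)
        except Exception as exc:  # degenerate at coarse levels
            row["cc_note"] = str(exc)
        try:
            ma = null_test("ma", lvl, "it", n_null=args.n_null,
                           seed=args.seed)
            row.update(ma_observed=ma.observed, ma_null_mean=ma.null_mean,
                       ma_p_low=ma.p_low)
        except Exception as exc:
            row["ma_note"] = str(exc)
        rows.append(row)

    df = pd.DataFrame(rows)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "nullmodels.tsv", sep="\t", index=False)

    thr = bonferroni_threshold(0.05, len(LEVELS))
    print(df.to_string(index=False))
    for score in ("cc", "ma"):
        col = f"{score}_p_low"
        if col in df:
            n = int((df[col] < thr).sum())
            print(f"{score.upper()}: {n}/{df[col].notna().sum()} levels "
                  f"significantly low after Bonferroni (p < {thr:.4f})")


if __name__ == "__main__":
    main()
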