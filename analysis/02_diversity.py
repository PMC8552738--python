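"""Alpha and beta diversity of the simulated communities.

Rarefies every sample to a common depth, computes Chao1/Shannon with a
Kruskal-Wallis test across caves, ordinates Bray-Curtis dissimilarities by
PCoA, and clusters samples by UPGMA (newick written for tree viewers).
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from cavenet import diversity, tables


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--depth", type=int, default=8000)
    parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/diversity"))
    args = parser.parse_args()

    table = tables.read_feature_table(args.data_dir / "table.tsv")
    metadata = tables.read_metadata(args.data_dir / "metadata.tsv")
    rare = tables.rarefy(table, args.depth, args.seed, drop_small=True)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    alpha = diversity.alpha_diversity_table(rare)
    alpha.to_csv(args.out_dir / "alpha_diversity.tsv", sep="\t")
    print(f"alpha diversity over {rare.n_samples} samples rarefied to {args.depth}:")
    print(alpha.describe().loc[["mean", "min", "max"]].round(2).to_string())

    caves = metadata.df.loc[rare.sample_ids, "cave"].to_numpy()
    for index in ("chao1", "shannon"):
        h, p = diversity.kruskal_wallis(alpha[index].to_numpy(), caves)
        print(f"Kruskal-Wallis across caves, {index}: H={h:.3f}, p={p:.3g}")

    bc = diversity.bray_curtis(rare)
    res = diversity.pcoa(bc)
    res.to_frame().to_csv(args.out_dir / "pcoa_coordinates.tsv", sep="\t")
    pd.DataFrame(
        {"eigenvalue": res.eigenvalues, "explained_pct": res.explained}
    ).to_csv(args.out_dir / "pcoa_eigen.tsv", sep="\t", index_label="axis")
    print(
        f"PCoA: PCo1 {res.explained[0]:.2f}% and PCo2 {res.explained[1]:.2f}% "
        "of positive-eigenvalue variance"
    )

    tree = diversity.upgma(bc)
    (args.out_dir / "upgma.nwk").write_text(tree.to_newick() + "\n")
    print(f"wrote diversity tables and UPGMA newick to {args.out_dir}")


if __name__ == "__main__":
    sys.exit(main())
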