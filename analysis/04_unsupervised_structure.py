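"""Unsupervised sample structure on the top-variance features.

Complete-linkage hierarchical clustering (Euclidean distance, top-50
variance features) with a two-cluster Fisher exact test against disease
status, plus PCA of the same submatrix.
"""
from pathlib import Path

from mirblood.io import read_annotation_csv, read_expression_tsv, write_json
from mirblood.unsupervised import (
    hierarchical_cluster,
    pca,
    select_top_variance,
    two_cut_fisher,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    m = read_expression_tsv(ROOT / "expression.tsv")
    ann = read_annotation_csv(ROOT / "cohort" / "annotation.csv")

    top = select_top_variance(m, 50)
    tree = hierarchical_cluster(top)
    (ROOT / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
    result = two_cut_fisher(tree, ann)
    pc = pca(top, n_components=2)
    pc.scores.to_csv(ROOT / "pca_scores.tsv", sep="\t", index_label="sample_id")
    write_json(
        {"fisher_p": result.fisher_p, "contingency": result.table.tolist(),
         "explained_fraction": pc.explained_fraction.tolist()},
        ROOT / "two_cut_fisher.json",
    )
    print(f"two-cluster cut contingency (rows clusters, cols control/melanoma):\n"
          f"{result.table}")
    print(f"two-tailed Fisher exact p = {result.fisher_p:.3g}")
    print(f"PC1+PC2 explained variance: {pc.explained_fraction.sum():.2f} "
          f"({pc.explained_fraction[0]:.2f} + {pc.explained_fraction[1]:.2f})")


if __name__ == "__main__":
    main()
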