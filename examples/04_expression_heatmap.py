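"""Preprocess tissue expression counts into a heatmap-ready matrix.

Counts are CPM-normalized, averaged per tissue, log2-transformed and
mean-centered per gene, then genes and tissues are Ward-clustered.
Marker genes simulated with a 50-fold boost in one tissue should peak
there after preprocessing.
"""

from flaxscreen import (
    ExpressionConfig,
    cluster_heatmap,
    cpm_normalize,
    flag_low_expression,
    heatmap_matrix,
    simulate_expression,
)

tissues = ["root", "stem", "leaf", "flower", "capsule"]
matrix, truth = simulate_expression(120, tissues, samples_per_tissue=3)
print(f"counts: {matrix.counts.shape[0]} genes x {matrix.counts.shape[1]} samples "
      f"({len(tissues)} tissues)")

cpm = cpm_normalize(matrix)
low = flag_low_expression(cpm)  # CPM < 10 in every sample
print(f"low-expressed genes (CPM < 10 everywhere): {int(low.sum())}")

mat = heatmap_matrix(matrix, ExpressionConfig(aggregate="tissue_mean"))
trees, ordered = cluster_heatmap(mat, axis="both")
print(f"heatmap matrix {ordered.shape}; tissue leaf order:", list(ordered.columns))

markers = truth[truth.marker_tissue != ""]
hits = sum(mat.loc[m.gene_id].idxmax() == m.marker_tissue
           for m in markers.itertuples())
print(f"marker genes peaking in their designated tissue: {hits}/{len(markers)}")
# centered values are log2 fold changes relative to the gene's mean
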