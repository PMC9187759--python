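"""Three-step array normalization: log2, median-centering, unit magnitude.

Each sample column is (1) floored and log2-transformed, (2) centered at
its own median, and (3) scaled so its sum of squares equals one. The
procedure matches the normalization used to train the EMT scorer, so new
cohorts scored with frozen parameters remain comparable with the
training data. Centering and magnitude normalization are per array (per
sample column), over all genes — the signature genes are inspected only
afterwards, by `normalization_report`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import ExpressionMatrix, GeneSet

__all__ = ["normalize_expression", "normalization_report"]


def normalize_expression(
    m: ExpressionMatrix, floor: float = 1.0
) -> ExpressionMatrix:
    """Apply log2 -> per-column median centering -> unit sum of squares.

    Values below `floor` are raised to it before the log so near-zero
    summarized intensities do not explode. Requires a raw-stage matrix
    (never re-applies to already-normalized data) and at least two genes
    per array. A column that is constant after centering has zero
    magnitude and is an error.
    """
    m.require_stage("raw", "normalize_expression")
    if floor <= 0:
        raise ValueError("floor must be positive")
    if m.n_genes < 2:
        raise ValueError("need at least 2 genes per array to normalize")
    vals = m.values.to_numpy(dtype=float)
    vals = np.log2(np.maximum(vals, floor))
    vals = vals - np.median(vals, axis=0, keepdims=True)
    ssq = np.sum(vals**2, axis=0)
    zero = ssq <= 0
    if zero.any():
        bad = [m.sample_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"zero magnitude after centering for samples {bad[:5]}")
    vals = vals / np.sqrt(ssq)[None, :]
    out = pd.DataFrame(vals, index=m.values.index, columns=m.values.columns)
    return m.with_values(out, stage="normalized")


def normalization_report(
    m_ref: ExpressionMatrix, m_new: ExpressionMatrix, genes: GeneSet
) -> dict:
    """Compare per-gene normalized-expression distributions across datasets.

    For each signature gene present in both matrices, report the median,
    quartiles and range in each dataset plus a two-sample KS statistic
    over samples. Genes absent from either matrix are listed under
    ``missing``, never dropped silently. Used to confirm that two
    independently normalized cohorts are on a comparable scale before a
    frozen scorer is applied to the new one.
    """
    m_ref.require_stage("normalized", "normalization_report")
    m_new.require_stage("normalized", "normalization_report")
    ref_idx, new_idx = set(m_ref.values.index), set(m_new.values.index)
    shared = [g for g in genes.genes if g in ref_idx and g in new_idx]
    missing = [g for g in genes.genes if g not in ref_idx or g not in new_idx]
    if not shared:
        raise ValueError(f"no genes of set {genes.name!r} shared by both matrices")
    rows = []
    for g in shared:
        x = m_ref.values.loc[g].to_numpy(dtype=float)
        y = m_new.values.loc[g].to_numpy(dtype=float)
        ks = sps.ks_2samp(x, y, method="asymp")
        rows.append(
            {
                "gene": g,
                "ref_median": float(np.median(x)),
                "ref_q1": float(np.percentile(x, 25)),
                "ref_q3": float(np.percentile(x, 75)),
                "ref_min": float(x.min()),
                "ref_max": float(x.max()),
                "new_median": float(np.median(y)),
                "new_q1": float(np.percentile(y, 25)),
                "new_q3": float(np.percentile(y, 75)),
                "new_min": float(y.min()),
                "new_max": float(y.max()),
                "ks_statistic": float(ks.statistic),
                "ks_pvalue": float(ks.pvalue),
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    return {"table": table, "missing": missing, "gene_set": genes.name}
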