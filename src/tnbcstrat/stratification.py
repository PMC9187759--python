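"""EMT risk-group construction from a per-sample EMT score.

The pipeline treats the EMT score as a pluggable input: the preferred
route loads precomputed integer scores from a two-column TSV (the
Boolean-network scorer that produces them is external to this package
and is deliberately not reimplemented). For end-to-end testing without
that input, a clearly labelled surrogate scorer is provided: the
rank-normalized mean of a mesenchymal marker set minus that of an
epithelial marker set, discretized to a small non-negative integer
scale. The surrogate is monotone in mesenchymal-versus-epithelial
balance by construction; it stands in for the real scorer only in
synthetic tests and is tagged "surrogate" in its provenance.

Risk groups are built by sorting samples ascending by (score, sample id)
and cutting into 2 or 3 contiguous near-equal blocks — a median split
for two groups.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import ExpressionMatrix, GeneSet, GroupAssignment, ScoreVector

__all__ = ["split_by_score", "surrogate_emt_score", "EMT_LABELS"]

EMT_LABELS = {2: ("low", "high"), 3: ("low", "med", "high")}


def split_by_score(s: ScoreVector, n_groups: int = 2) -> GroupAssignment:
    """Sort ascending by (score, sample id) and split into equal blocks.

    The remainder of n // n_groups goes to the lowest blocks. Equal
    scores straddling a boundary stay split deterministically by id
    order; each boundary score is recorded in the assignment parameters
    and flagged "tied" when the neighboring block shares it.
    """
    if n_groups not in EMT_LABELS:
        raise ValueError(f"n_groups must be in {sorted(EMT_LABELS)}, got {n_groups}")
    n = len(s)
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} samples, got {n}")
    order = (
        pd.DataFrame({"score": s.values, "id": s.values.index.astype(str)})
        .sort_values(["score", "id"], ascending=[True, True], kind="stable")
    )
    base, rem = divmod(n, n_groups)
    sizes = [base + (1 if i < rem else 0) for i in range(n_groups)]
    labels_order = EMT_LABELS[n_groups]
    labels = {}
    boundaries = []
    start = 0
    for size, lab in zip(sizes, labels_order):
        block = order.index[start : start + size]
        for sid in block:
            labels[sid] = lab
        if start + size < n:
            b_last = float(order["score"].iloc[start + size - 1])
            b_next = float(order["score"].iloc[start + size])
            boundaries.append(
                {"below": lab, "value": b_last, "tied": b_last == b_next}
            )
        start += size
    return GroupAssignment(
        name="emt_risk",
        labels=pd.Series(labels).loc[s.values.index],
        label_set=labels_order,
        params={
            "n_groups": n_groups,
            "sizes": sizes,
            "boundaries": boundaries,
            "tie_rule": "ascending sample id",
        },
    )


def surrogate_emt_score(
    m: ExpressionMatrix, e_set: GeneSet, m_set: GeneSet, n_levels: int = 11
) -> ScoreVector:
    """Rank-based mesenchymal-minus-epithelial surrogate EMT score.

    Per sample: rank-normalize (to [0, 1]) the mean expression of the
    mesenchymal set and of the epithelial set across the cohort, take
    the difference, and discretize the [-1, 1] range into `n_levels`
    integer levels 0..n_levels-1. Higher = more mesenchymal.
    """
    m.require_stage("normalized", "surrogate_emt_score")
    e_present = e_set.present_in(m)
    m_present = m_set.present_in(m)
    if not e_present or not m_present:
        missing = e_set.name if not e_present else m_set.name
        raise ValueError(f"gene set {missing!r} fully absent from matrix")
    if set(e_present) == set(m_present):
        warnings.warn("epithelial and mesenchymal sets identical; scores degenerate")
    e_mean = m.values.loc[e_present].mean(axis=0).to_numpy()
    m_mean = m.values.loc[m_present].mean(axis=0).to_numpy()
    n = m.n_samples
    # rank-normalize to [0, 1]; average ranks keep ties symmetric
    e_rank = (sps.rankdata(e_mean) - 1) / max(n - 1, 1)
    m_rank = (sps.rankdata(m_mean) - 1) / max(n - 1, 1)
    diff = m_rank - e_rank  # in [-1, 1]
    levels = np.rint((diff + 1.0) / 2.0 * (n_levels - 1)).astype(int)
    return ScoreVector(
        name="emt_surrogate",
        values=pd.Series(levels.astype(float), index=m.sample_ids),
        provenance={
            "kind": "surrogate",
            "e_set": e_set.name,
            "m_set": m_set.name,
            "n_levels": n_levels,
            "definition": "rank(mean M-set) - rank(mean E-set), discretized",
        },
    )
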