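"""Metasignature scoring and immune-microenvironment group construction.

A metasignature score is the mean normalized expression over a named
gene set (Immune/CDSig1, Fibrosis/CDSig3, Cholesterol/EDSig2,
Interferon/EDSig5). Two group constructions are provided:

* Immune/Fibrosis: samples in the top 60% by immune score form the
  "Immune high/Fibrosis low" candidates and samples in the top 40% by
  fibrosis score form the "Immune low/Fibrosis high" candidates; samples
  satisfying both criteria are labelled Intermediate (samples satisfying
  neither criterion also land in Intermediate — the conservative,
  deterministic bucket).
* Cholesterol/Interferon: the Immune-high group is split in half by the
  composite rank of (interferon - cholesterol), so each refined group
  holds exactly 50% of the subset.

Both constructions are rank-based: quantiles are type-1 empirical with
ties broken by ascending sample id, so group counts hit round(n * frac)
exactly and assignments are invariant under any strictly increasing
transform of the scores.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSet, GroupAssignment, ScoreVector

__all__ = [
    "score_gene_set",
    "classify_immune_fibrosis",
    "classify_chol_ifn",
    "IHFL",
    "ILFH",
    "INTERMEDIATE",
    "CHOL_LOW_IFN_HIGH",
    "CHOL_HIGH_IFN_LOW",
]

IHFL = "ImmuneHigh_FibrosisLow"
ILFH = "ImmuneLow_FibrosisHigh"
INTERMEDIATE = "Intermediate"
CHOL_LOW_IFN_HIGH = "CholLow_IFNhigh"
CHOL_HIGH_IFN_LOW = "CholHigh_IFNlow"


def score_gene_set(m: ExpressionMatrix, gs: GeneSet) -> ScoreVector:
    """Per-sample mean of normalized expression over the set's present genes."""
    m.require_stage("normalized", "score_gene_set")
    present = gs.present_in(m)
    if not present:
        raise ValueError(f"no genes of set {gs.name!r} present in matrix")
    coverage = len(present) / len(gs)
    if coverage < 0.5:
        warnings.warn(
            f"gene set {gs.name!r}: only {len(present)}/{len(gs)} genes present"
        )
    vals = m.values.loc[present].mean(axis=0)
    return ScoreVector(
        name=gs.name,
        values=vals,
        provenance={
            "gene_set": gs.name,
            "n_genes": len(present),
            "coverage": coverage,
            "stage": m.stage,
            "statistic": "mean",
        },
    )


def _top_fraction(score: ScoreVector, frac: float) -> set[str]:
    """Ids of the round(n*frac) highest-scoring samples.

    Ties broken by ascending sample id: among equal scores the
    lexicographically earlier id is ranked higher, so counts are exact.
    """
    s = score.values
    if s.nunique() == 1:
        raise ValueError(
            f"score {score.name!r} is constant; quantile groups undefined"
        )
    k = int(round(len(s) * frac))
    order = (
        pd.DataFrame({"score": s, "id": s.index.astype(str)})
        .sort_values(["score", "id"], ascending=[False, True], kind="stable")
    )
    return set(order.index[:k])


def classify_immune_fibrosis(
    immune: ScoreVector,
    fibrosis: ScoreVector,
    frac_ihfl: float = 0.6,
    frac_ilfh: float = 0.4,
) -> GroupAssignment:
    """Top-60% immune / top-40% fibrosis group construction.

    Dual members and neither-members are labelled Intermediate.
    """
    if list(immune.values.index) != list(fibrosis.values.index):
        if set(immune.values.index) != set(fibrosis.values.index):
            raise ValueError("immune and fibrosis scores cover different samples")
        fibrosis = ScoreVector(
            fibrosis.name, fibrosis.values.loc[immune.values.index],
            fibrosis.provenance,
        )
    imm_high = _top_fraction(immune, frac_ihfl)
    fib_high = _top_fraction(fibrosis, frac_ilfh)
    labels = {}
    for sid in immune.values.index:
        in_i, in_f = sid in imm_high, sid in fib_high
        if in_i and not in_f:
            labels[sid] = IHFL
        elif in_f and not in_i:
            labels[sid] = ILFH
        else:
            labels[sid] = INTERMEDIATE
    return GroupAssignment(
        name="immune_fibrosis",
        labels=pd.Series(labels).loc[immune.values.index],
        label_set=(IHFL, ILFH, INTERMEDIATE),
        params={
            "frac_ihfl": frac_ihfl,
            "frac_ilfh": frac_ilfh,
            "n_immune_high": len(imm_high),
            "n_fibrosis_high": len(fib_high),
            "tie_rule": "ascending sample id",
        },
    )


def classify_chol_ifn(
    chol: ScoreVector, ifn: ScoreVector, subset: list[str]
) -> GroupAssignment:
    """50/50 refinement of a subset by the (interferon - cholesterol) rank.

    Top half (extra sample on odd n) -> cholesterol-low / interferon-high.
    A single composite rank is used because two independent median splits
    cannot guarantee exactly half the samples per group.
    """
    subset = list(subset)
    if len(subset) < 2:
        raise ValueError("subset must contain at least 2 samples")
    missing = [s for s in subset if s not in chol.values.index or s not in ifn.values.index]
    if missing:
        raise ValueError(f"scores missing for subset samples {missing[:5]}")
    composite = ifn.values.loc[subset] - chol.values.loc[subset]
    order = (
        pd.DataFrame({"c": composite, "id": composite.index.astype(str)})
        .sort_values(["c", "id"], ascending=[False, True], kind="stable")
    )
    n_top = (len(subset) + 1) // 2
    top = set(order.index[:n_top])
    labels = pd.Series(
        {sid: (CHOL_LOW_IFN_HIGH if sid in top else CHOL_HIGH_IFN_LOW) for sid in subset}
    ).loc[subset]
    return GroupAssignment(
        name="chol_ifn",
        labels=labels,
        label_set=(CHOL_LOW_IFN_HIGH, CHOL_HIGH_IFN_LOW),
        params={
            "n_top": n_top,
            "composite": "ifn - chol",
            "tie_rule": "ascending sample id",
        },
    )
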