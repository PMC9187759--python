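"""Pathway Deregulation Scores (PDS) with reference-mean zero anchoring.

The PDS of a sample for a pathway is its arc-length position along a
principal curve fitted in the subspace of that pathway's genes. The zero
of the scale is placed at the mean arc-length position of a declared
reference group (rather than at an end of the curve), which shifts every
score by the same constant and makes the scale robust to variability
among reference samples: PDS differences between samples are unaffected
by the anchor choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSet, ScoreVector
from .principal_curve import PrincipalCurve, fit_principal_curve

__all__ = ["compute_pds", "PDSResult"]


@dataclass
class PDSResult:
    """Per-sample PDS for one pathway, plus the fitted curve.

    The reference group's mean PDS is zero by construction; the sign is
    oriented so the median PDS of non-reference samples is >= 0.
    """

    pathway: str
    scores: ScoreVector
    anchor: float
    reference_ids: tuple[str, ...]
    curve: PrincipalCurve
    genes_used: tuple[str, ...]
    genes_dropped: tuple[str, ...] = ()

    def reference_mean(self) -> float:
        if not self.reference_ids:
            return float(self.scores.values.mean())
        return float(self.scores.values.loc[list(self.reference_ids)].mean())


def compute_pds(
    m: ExpressionMatrix,
    gs: GeneSet,
    reference_ids: list[str] | None = None,
    span: float = 0.3,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> PDSResult:
    """Fit a principal curve in the pathway subspace and score samples.

    Steps: restrict to the pathway's genes, standardize each gene to
    zero mean / unit variance across samples, fit the curve, then anchor
    the arc-length parameters at the reference samples' mean position.
    Genes with zero variance are dropped with a warning. With no
    reference ids, the all-sample mean anchors the scale (degraded mode,
    warned).
    """
    m.require_stage("normalized", "compute_pds")
    if m.n_samples < 5:
        raise ValueError("need at least 5 samples for a principal curve")
    present = gs.present_in(m)
    if len(present) < 2:
        raise ValueError(
            f"gene set {gs.name!r}: {len(present)} genes present, need >= 2"
        )
    sub = m.values.loc[present]  # genes x samples
    sd = sub.std(axis=1, ddof=0)
    # constant rows can carry float-noise std ~1e-16; treat those as zero
    zero_var = sd <= 1e-12 * sub.abs().max(axis=1).clip(lower=1.0)
    dropped = tuple(sub.index[zero_var])
    if dropped:
        warnings.warn(f"dropping zero-variance genes {list(dropped)[:5]}")
        sub = sub.loc[~zero_var]
    if sub.shape[0] < 2:
        raise ValueError(f"gene set {gs.name!r}: fewer than 2 variable genes")
    z = (sub.sub(sub.mean(axis=1), axis=0)).div(sub.std(axis=1, ddof=0), axis=0)
    points = z.to_numpy().T  # samples x genes

    curve = fit_principal_curve(points, span=span, tol=tol, max_iter=max_iter)

    sample_ids = list(m.sample_ids)
    lam = pd.Series(curve.lambdas, index=sample_ids)
    reference_ids = list(reference_ids or [])
    unknown = [r for r in reference_ids if r not in lam.index]
    if unknown:
        raise ValueError(f"reference ids not in matrix: {unknown[:5]}")
    if reference_ids:
        anchor = float(lam.loc[reference_ids].mean())
        non_ref = lam.index.difference(reference_ids)
    else:
        warnings.warn("no reference samples given; anchoring at the cohort mean")
        anchor = float(lam.mean())
        non_ref = lam.index
    pds = lam - anchor
    orient_on = pds.loc[non_ref] if len(non_ref) else pds
    sign = -1.0 if float(orient_on.median()) < 0 else 1.0
    pds = sign * pds

    scores = ScoreVector(
        name=f"PDS:{gs.name}",
        values=pds,
        provenance={
            "pathway": gs.name,
            "n_genes": int(sub.shape[0]),
            "reference_ids": reference_ids,
            "anchor": anchor,
            "sign": sign,
            "converged": curve.converged,
        },
    )
    return PDSResult(
        pathway=gs.name,
        scores=scores,
        anchor=anchor,
        reference_ids=tuple(reference_ids),
        curve=curve,
        genes_used=tuple(sub.index),
        genes_dropped=dropped,
    )
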