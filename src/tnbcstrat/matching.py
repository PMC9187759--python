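"""Cross-dataset sample matching by transcriptome correlation.

When the same tumors appear in two expression datasets without a shared
identifier, the matching sample pair is recoverable because a sample's
correlation with its own duplicate is far larger than with any other
sample. The match is accepted only when that correlation exceeds the
runner-up by a margin (reliability), and is then verified against
clinical fields (age, tumor size); samples whose clinical data disagree
are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import ClinicalTable, ExpressionMatrix

__all__ = ["cross_correlate", "match_samples", "verify_clinical", "MatchResult"]


@dataclass
class MatchResult:
    """Per-query match table plus the parameters that produced it.

    Columns: best_match, best_correlation, second_best_correlation,
    margin, reliable, collision, clinical_ok (True/False/NaN), excluded,
    exclusion_reason.
    """

    table: pd.DataFrame
    params: dict = field(default_factory=dict)

    def matched_pairs(self) -> list[tuple[str, str]]:
        """(query, target) pairs that survived every filter."""
        ok = self.table[~self.table["excluded"] & self.table["best_match"].notna()]
        return list(zip(ok.index, ok["best_match"]))

    def excluded_ids(self) -> list[str]:
        return list(self.table.index[self.table["excluded"]])


def cross_correlate(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    method: str = "pearson",
    min_shared_genes: int = 30,
) -> pd.DataFrame:
    """Correlation of every sample of `a` against every sample of `b`.

    Computed over the shared-gene intersection only (kept in `a`'s gene
    order, so the table is invariant under any common reordering of the
    two matrices). Zero-variance samples get a missing row/column with a
    warning rather than a spurious correlation.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    shared = [g for g in a.values.index if g in set(b.values.index)]
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} shared genes; need >= {min_shared_genes}"
        )
    xa = a.values.loc[shared].to_numpy(dtype=float)
    xb = b.values.loc[shared].to_numpy(dtype=float)
    if method == "spearman":
        xa = sps.rankdata(xa, axis=0)
        xb = sps.rankdata(xb, axis=0)
    sa = xa.std(axis=0)
    sb = xb.std(axis=0)
    za = (xa - xa.mean(axis=0)) / np.where(sa > 0, sa, 1.0)
    zb = (xb - xb.mean(axis=0)) / np.where(sb > 0, sb, 1.0)
    corr = za.T @ zb / len(shared)
    corr[sa == 0, :] = np.nan
    corr[:, sb == 0] = np.nan
    if (sa == 0).any() or (sb == 0).any():
        import warnings

        warnings.warn("zero-variance sample(s) over shared genes; set to missing")
    table = pd.DataFrame(corr, index=a.sample_ids, columns=b.sample_ids)
    table.attrs["n_shared_genes"] = len(shared)
    table.attrs["method"] = method
    return table


def match_samples(corr_table: pd.DataFrame, margin_min: float = 0.10) -> MatchResult:
    """Best one-directional match per query with a reliability margin.

    A query is reliable iff (best - second best) correlation >= `margin_min`.
    Several queries matching the same target are flagged as collisions
    but not auto-excluded.
    """
    if not 0 <= margin_min <= 2:
        raise ValueError("margin_min must be in [0, 2]")
    rows = []
    for q in corr_table.index:
        r = corr_table.loc[q]
        valid = r.dropna()
        if valid.empty:
            rows.append(
                dict(
                    query=q, best_match=None, best_correlation=np.nan,
                    second_best_correlation=np.nan, margin=np.nan,
                    reliable=False, excluded=True, exclusion_reason="unmatched",
                )
            )
            continue
        order = valid.sort_values(ascending=False, kind="stable")
        best, best_r = order.index[0], float(order.iloc[0])
        second_r = float(order.iloc[1]) if len(order) > 1 else -np.inf
        margin = best_r - second_r
        reliable = margin >= margin_min
        rows.append(
            dict(
                query=q, best_match=best, best_correlation=best_r,
                second_best_correlation=second_r, margin=margin,
                reliable=reliable, excluded=not reliable,
                exclusion_reason=None if reliable else "low margin",
            )
        )
    table = pd.DataFrame(rows).set_index("query")
    counts = table["best_match"].value_counts()
    collided = set(counts.index[counts > 1])
    table["collision"] = table["best_match"].isin(collided)
    table["clinical_ok"] = pd.Series(pd.NA, index=table.index, dtype=object)
    return MatchResult(
        table=table,
        params={
            "margin_min": margin_min,
            "method": corr_table.attrs.get("method"),
            "n_shared_genes": corr_table.attrs.get("n_shared_genes"),
        },
    )


def verify_clinical(
    matches: MatchResult,
    clin_a: ClinicalTable,
    clin_b: ClinicalTable,
    age_tol: float = 1.0,
    size_tol_rel: float = 0.10,
) -> MatchResult:
    """Check each matched pair's age and tumor size for agreement.

    clinical_ok is True iff all non-missing paired fields agree
    (|delta age| <= age_tol years, relative size difference <= size_tol_rel);
    missing on either side means the field is skipped, and a pair with no
    comparable field gets clinical_ok = missing, not False. A pair whose
    clinical data disagree is excluded.
    """
    table = matches.table.copy()
    for q in table.index:
        t = table.at[q, "best_match"]
        if t is None or q not in clin_a.data.index or t not in clin_b.data.index:
            continue
        ra, rb = clin_a.data.loc[q], clin_b.data.loc[t]
        checks = []
        if pd.notna(ra["age"]) and pd.notna(rb["age"]):
            checks.append(abs(ra["age"] - rb["age"]) <= age_tol)
        if pd.notna(ra["tumor_size"]) and pd.notna(rb["tumor_size"]):
            denom = max(abs(ra["tumor_size"]), abs(rb["tumor_size"]), 1e-12)
            checks.append(
                abs(ra["tumor_size"] - rb["tumor_size"]) / denom <= size_tol_rel
            )
        if not checks:
            continue  # clinical_ok stays missing
        ok = all(checks)
        table.at[q, "clinical_ok"] = ok
        if not ok:
            table.at[q, "excluded"] = True
            table.at[q, "exclusion_reason"] = "clinical disagreement"
    params = dict(matches.params, age_tol=age_tol, size_tol_rel=size_tol_rel)
    return MatchResult(table=table, params=params)
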