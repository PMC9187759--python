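"""End-to-end comparison of EMT-score and immune-microenvironment groups.

`run_comparison` executes the full linear pipeline from one
configuration mapping: normalize -> (optional cross-dataset match) ->
metasignature scores -> group construction -> PDS -> statistics, and
writes every table it produces to an output directory. The report
answers the study's central question at cohort scale: are the groups
selected by the EMT score related to the immune-microenvironment
stratification, as measured by correlation tests, per-group KS tests
and Kaplan-Meier curves?

Config layout (YAML/dict; all blocks optional except `seed`)::

    seed: 1
    synthetic:            # generate the cohort (omit to load files)
      n_samples: 200
      noise_sd: 0.5
      emt_immune_loading: 0.0
    inputs:               # real-data mode: user-supplied files
      expression: path.tsv
      dialect: tsv        # or series_matrix
      clinical: path.csv
    matching:
      enabled: true       # synthetic mode: build a noisy duplicate
      noise_sd: 0.3
      n_corrupt: 4
      margin_min: 0.10
    emt:
      score_file: path.tsv   # precomputed integer EMT scores
      surrogate: true        # or use the labelled surrogate scorer
      n_groups: 2
    metasignatures:
      frac_ihfl: 0.6
      frac_ilfh: 0.4
    pds:
      span: 0.3
      gene_sets: [immune, fibrosis, cholesterol, interferon]
    normalization:
      floor: 1.0
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import ClinicalTable, ExpressionMatrix, GroupAssignment, ScoreVector
from .io import (
    read_clinical,
    read_expression,
    read_gmt,
    read_score,
    write_expression,
    write_score,
)
from .matching import cross_correlate, match_samples, verify_clinical
from .metasignatures import (
    IHFL,
    ILFH,
    classify_chol_ifn,
    classify_immune_fibrosis,
    score_gene_set,
)
from .normalization import normalize_expression
from .pds import compute_pds
from .stats import correlation_matrix, kaplan_meier, ks_two_sample, logrank_test
from .stratification import split_by_score, surrogate_emt_score
from .synthetic import cohort_gene_sets, generate_cohort, generate_duplicate

logger = logging.getLogger("tnbcstrat")

__all__ = ["run_comparison", "crosstab_groups", "ComparisonReport"]


@dataclass
class ComparisonReport:
    """All artifacts of one pipeline run, in memory and on disk."""

    config: dict
    scores: dict[str, ScoreVector] = field(default_factory=dict)
    groups: dict[str, GroupAssignment] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    out_dir: Path | None = None


def crosstab_groups(a: GroupAssignment, b: GroupAssignment) -> pd.DataFrame:
    """Contingency table of two group assignments over shared samples.

    Row/column margins are appended; samples present in only one
    assignment are counted in the table's ``unshared`` attr.
    """
    shared = a.labels.index.intersection(b.labels.index)
    if len(shared) == 0:
        raise ValueError("no shared samples between assignments")
    tab = pd.crosstab(a.labels.loc[shared], b.labels.loc[shared], margins=True)
    tab.index.name = a.name
    tab.columns.name = b.name
    tab.attrs["unshared"] = int(
        len(a.labels.index.symmetric_difference(b.labels.index))
    )
    return tab


def _load_inputs(config: dict):
    """Return (matrix_raw, clinical, truth_or_None, gene_sets, duplicate_or_None)."""
    seed = int(config["seed"])
    if "synthetic" in config or "inputs" not in config:
        syn = dict(config.get("synthetic", {}))
        syn.setdefault("seed", seed)
        matrix, clinical, truth = generate_cohort(**syn)
        gene_sets = cohort_gene_sets(syn.get("block_sizes"))
        dup = None
        mcfg = config.get("matching", {})
        if mcfg.get("enabled"):
            dup = generate_duplicate(
                matrix,
                clinical,
                noise_sd=float(mcfg.get("noise_sd", 0.3)),
                permute_seed=seed + 1,
                n_corrupt=int(mcfg.get("n_corrupt", 0)),
            )
        return matrix, clinical, truth, gene_sets, dup
    inputs = config["inputs"]
    matrix = read_expression(
        inputs["expression"], dialect=inputs.get("dialect", "tsv")
    )
    clinical = (
        read_clinical(inputs["clinical"], inputs.get("clinical_columns"))
        if "clinical" in inputs
        else ClinicalTable(pd.DataFrame(index=pd.Index(matrix.sample_ids)))
    )
    gene_sets = read_gmt(inputs["gene_sets"])
    return matrix, clinical, None, gene_sets, None


def run_comparison(config: dict, out_dir: str | Path) -> ComparisonReport:
    """Run the full comparison pipeline and write a report directory."""
    if "seed" not in config:
        raise ValueError("config must declare a seed")
    emt_cfg = dict(config.get("emt", {}))
    if "score_file" in emt_cfg and not Path(emt_cfg["score_file"]).exists():
        raise ValueError(f"EMT score file not found: {emt_cfg['score_file']}")
    if "score_file" not in emt_cfg and not emt_cfg.get("surrogate", True):
        raise ValueError(
            "config.emt must give a score_file or enable the surrogate scorer"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = ComparisonReport(config=config, out_dir=out)

    matrix, clinical, truth, gene_sets, dup = _load_inputs(config)
    logger.info("inputs: %d genes x %d samples", matrix.n_genes, matrix.n_samples)

    floor = float(config.get("normalization", {}).get("floor", 1.0))
    norm = normalize_expression(matrix, floor=floor)
    write_expression(norm, out / "normalized.tsv")
    logger.info("normalized with floor=%s", floor)

    if dup is not None:
        mcfg = config.get("matching", {})
        dup_norm = normalize_expression(dup.matrix, floor=floor)
        corr = cross_correlate(norm, dup_norm)
        matches = match_samples(corr, margin_min=float(mcfg.get("margin_min", 0.10)))
        matches = verify_clinical(
            matches,
            clinical,
            dup.clinical,
            age_tol=float(mcfg.get("age_tol", 1.0)),
            size_tol_rel=float(mcfg.get("size_tol", 0.10)),
        )
        report.tables["matches"] = matches.table
        matches.table.to_csv(out / "matches.tsv", sep="\t")
        n_correct = sum(
            dup.mapping.get(t) == q for q, t in matches.matched_pairs()
        )
        report.summary["matching"] = {
            "n_matched": len(matches.matched_pairs()),
            "n_excluded": len(matches.excluded_ids()),
            "n_correct": n_correct,
            "excluded_ids": matches.excluded_ids(),
        }
        logger.info("matching: %s", report.summary["matching"])

    meta_cfg = config.get("metasignatures", {})
    meta_names = ("immune", "fibrosis", "cholesterol", "interferon")
    for name in meta_names:
        gs = gene_sets[meta_cfg.get(name, name)]
        sv = score_gene_set(norm, gs)
        report.scores[name] = sv
        write_score(sv, out / f"score_{name}.tsv")

    if "score_file" in emt_cfg:
        emt_score = read_score(emt_cfg["score_file"], name="emt")
    else:
        emt_score = surrogate_emt_score(
            norm,
            gene_sets[emt_cfg.get("e_set", "emt_e")],
            gene_sets[emt_cfg.get("m_set", "emt_m")],
        )
    report.scores["emt"] = emt_score
    write_score(emt_score, out / "score_emt.tsv")

    emt_groups = split_by_score(emt_score, n_groups=int(emt_cfg.get("n_groups", 2)))
    report.groups["emt"] = emt_groups
    if_groups = classify_immune_fibrosis(
        report.scores["immune"],
        report.scores["fibrosis"],
        frac_ihfl=float(meta_cfg.get("frac_ihfl", 0.6)),
        frac_ilfh=float(meta_cfg.get("frac_ilfh", 0.4)),
    )
    report.groups["immune_fibrosis"] = if_groups
    ihfl_members = if_groups.members(IHFL)
    if len(ihfl_members) >= 2:
        report.groups["chol_ifn"] = classify_chol_ifn(
            report.scores["cholesterol"], report.scores["interferon"], ihfl_members
        )
    for name, g in report.groups.items():
        g.labels.to_csv(out / f"groups_{name}.tsv", sep="\t", header=False)
    report.tables["crosstab_emt_vs_if"] = crosstab_groups(
        emt_groups, if_groups
    )

    pds_cfg = config.get("pds", {})
    # reference group: the lowest-EMT-score decile (declared fallback when no
    # normal/adjacent samples exist)
    n_ref = max(2, int(np.ceil(0.1 * len(emt_score))))
    ref_ids = (
        emt_score.values.sort_values(kind="stable").index[:n_ref].tolist()
    )
    for name in pds_cfg.get("gene_sets", list(meta_names)):
        res = compute_pds(
            norm,
            gene_sets[name],
            reference_ids=ref_ids,
            span=float(pds_cfg.get("span", 0.3)),
            tol=float(pds_cfg.get("tol", 1e-4)),
        )
        report.scores[f"pds_{name}"] = res.scores
        write_score(res.scores, out / f"pds_{name}.tsv")

    corr_scores = [v for k, v in report.scores.items() if k != "emt"]
    corr_tab = correlation_matrix(corr_scores, emt_score)
    report.tables["emt_correlations"] = corr_tab
    corr_tab.to_csv(out / "emt_correlations.tsv", sep="\t")

    ks_rows = []
    for label_a, label_b in [(IHFL, ILFH)]:
        a_ids, b_ids = if_groups.members(label_a), if_groups.members(label_b)
        if a_ids and b_ids:
            res = ks_two_sample(
                emt_score.values.loc[a_ids], emt_score.values.loc[b_ids]
            )
            ks_rows.append(
                {
                    "group_a": label_a, "group_b": label_b,
                    "statistic": res.statistic, "pvalue": res.pvalue,
                    "significant": res.significant,
                }
            )
    report.tables["group_ks"] = pd.DataFrame(ks_rows)
    report.tables["group_ks"].to_csv(out / "group_ks.tsv", sep="\t", index=False)

    surv = clinical.survival()
    if len(surv):
        km_frames, lr = _survival_by_group(surv, emt_groups)
        for lab, frame in km_frames.items():
            frame.to_csv(out / f"km_emt_{lab}.csv", index=False)
            report.tables[f"km_emt_{lab}"] = frame
        if lr is not None:
            report.summary["logrank_emt"] = {
                "statistic": lr.statistic, "pvalue": lr.pvalue,
                "significant": lr.significant,
            }

    report.summary["version"] = __version__
    report.summary["config"] = _jsonable(config)
    report.summary["n_samples"] = matrix.n_samples
    report.summary["n_genes"] = matrix.n_genes
    report.summary["correlations"] = {
        str(k): {"r": _f(v["r"]), "pvalue": _f(v["pvalue"]),
                 "significant": bool(v["significant"])}
        for k, v in corr_tab.iterrows()
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(report.summary, fh, indent=2, default=str)
    logger.info("report written to %s", out)
    return report


def _survival_by_group(surv: pd.DataFrame, groups: GroupAssignment):
    km_frames = {}
    arms = {}
    for lab in groups.label_set:
        ids = [s for s in groups.members(lab) if s in surv.index]
        if not ids:
            continue
        sub = surv.loc[ids]
        curve = kaplan_meier(sub["followup_time"], sub["event"])
        km_frames[lab] = curve.as_frame()
        arms[lab] = sub
    lr = None
    if "low" in arms and "high" in arms:
        lr = logrank_test(
            arms["low"]["followup_time"], arms["low"]["event"],
            arms["high"]["followup_time"], arms["high"]["event"],
        )
    return km_frames, lr


def _f(x) -> float | None:
    return None if pd.isna(x) else float(x)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
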