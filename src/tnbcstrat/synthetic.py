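"""Synthetic TNBC-like cohorts with planted, recoverable structure.

The generator emulates the statistical skeleton the analysis assumes,
not real microarray noise: a latent EMT axis that drives an
epithelial/mesenchymal marker-gene block and the survival hazard, four
metasignature gene blocks (immune, fibrosis, cholesterol, interferon)
driven by partially correlated latents, three tissue compartments
ordered bulk > stroma > epithelium on the EMT latent, and a noisy
column-permuted duplicate dataset with matched clinical fields for the
cross-dataset matching stage.

Expression is generated as exp2(baseline + latent loadings + Gaussian
noise), so taking log2 recovers the linear latent model exactly and the
three-step normalization behaves as it would on summarized microarray
intensities. Every latent is stored alongside the cohort (`CohortTruth`)
so planted correlations can be recomputed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, ExpressionMatrix, GeneSet, GeneSetCollection

__all__ = [
    "generate_cohort",
    "generate_duplicate",
    "cohort_gene_sets",
    "CohortTruth",
    "DuplicateResult",
    "DEFAULT_BLOCK_SIZES",
]

DEFAULT_BLOCK_SIZES = {
    "immune": 30,
    "fibrosis": 30,
    "cholesterol": 30,
    "interferon": 30,
    "emt_e": 30,
    "emt_m": 30,
}

_BLOCK_PREFIX = {
    "immune": "IMM",
    "fibrosis": "FIB",
    "cholesterol": "CHO",
    "interferon": "IFN",
    "emt_e": "EMTE",
    "emt_m": "EMTM",
}

COMPARTMENTS = ("bulk", "stroma", "epithelium")


@dataclass
class CohortTruth:
    """Planted latent values and generator parameters for one cohort."""

    table: pd.DataFrame  # per sample: latents, compartment, hazard multiplier
    params: dict = field(default_factory=dict)

    def latent(self, name: str) -> pd.Series:
        return self.table[f"{name}_latent"]


@dataclass
class DuplicateResult:
    """Noisy permuted duplicate of a cohort plus the planted answers."""

    matrix: ExpressionMatrix
    clinical: ClinicalTable
    mapping: dict[str, str]            # duplicate id -> source id
    corrupted_dup_ids: tuple[str, ...]
    corrupted_source_ids: tuple[str, ...]


def cohort_gene_sets(block_sizes: dict[str, int] | None = None) -> GeneSetCollection:
    """Gene sets naming each planted block, matching `generate_cohort`."""
    sizes = dict(DEFAULT_BLOCK_SIZES, **(block_sizes or {}))
    sets = [
        GeneSet(
            name=block,
            genes=tuple(f"{_BLOCK_PREFIX[block]}{i:04d}" for i in range(sizes[block])),
        )
        for block in DEFAULT_BLOCK_SIZES
    ]
    return GeneSetCollection(sets=sets)


def generate_cohort(
    n_samples: int = 200,
    n_background_genes: int = 400,
    block_sizes: dict[str, int] | None = None,
    effect_size: float = 1.0,
    noise_sd: float = 0.5,
    compartment_shift: float = 1.0,
    hazard_ratio_per_emt_unit: float = 2.0,
    emt_immune_loading: float = 0.0,
    fibrosis_immune_loading: float = -0.5,
    chol_immune_loading: float = -0.3,
    ifn_immune_loading: float = 0.3,
    baseline_log2: float = 7.0,
    base_hazard: float = np.log(2) / 60.0,
    censor_fraction: float = 0.3,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, ClinicalTable, CohortTruth]:
    """Generate one cohort: raw expression, clinical table, planted truth.

    Latents are standard normal. The fibrosis, cholesterol and
    interferon latents are built as loading * immune + sqrt(1-loading^2)
    * residual, so their marginals stay standard normal; the EMT latent
    is independent of immune by default (`emt_immune_loading` plants a
    dependence). Compartments shift the EMT latent by +shift (bulk), 0
    (stroma), -shift (epithelium). Survival times are exponential with
    hazard base_hazard * HR^(standardized EMT latent); censoring is an
    independent exponential tuned to `censor_fraction` at the baseline
    hazard. Expression is exp2-linear in the latents so log2 recovers
    the model exactly at noise_sd = 0.
    """
    if seed is None:
        raise ValueError("seed is required")
    sizes = dict(DEFAULT_BLOCK_SIZES, **(block_sizes or {}))
    if min(sizes.values()) < 1 or n_samples < 1 or n_background_genes < 0:
        raise ValueError("all sizes must be >= 1 (background genes >= 0)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    compartment = np.array(
        [COMPARTMENTS[i % len(COMPARTMENTS)] for i in range(n_samples)]
    )
    shift_of = {"bulk": compartment_shift, "stroma": 0.0, "epithelium": -compartment_shift}
    shift = np.array([shift_of[c] for c in compartment])

    immune = rng.standard_normal(n_samples)

    def _mix(loading: float) -> np.ndarray:
        resid = rng.standard_normal(n_samples)
        return loading * immune + np.sqrt(max(1.0 - loading**2, 0.0)) * resid

    emt = _mix(emt_immune_loading) + shift
    fibrosis = _mix(fibrosis_immune_loading)
    cholesterol = _mix(chol_immune_loading)
    interferon = _mix(ifn_immune_loading)

    latent_of = {
        "immune": immune,
        "fibrosis": fibrosis,
        "cholesterol": cholesterol,
        "interferon": interferon,
        "emt_e": -emt,  # epithelial markers fall as EMT rises
        "emt_m": emt,
    }
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    for block in DEFAULT_BLOCK_SIZES:
        lat = latent_of[block]
        for i in range(sizes[block]):
            gene_ids.append(f"{_BLOCK_PREFIX[block]}{i:04d}")
            rows.append(baseline_log2 + effect_size * lat)
    for i in range(n_background_genes):
        gene_ids.append(f"BG{i:04d}")
        rows.append(np.full(n_samples, baseline_log2))
    log2_expr = np.vstack(rows)
    if noise_sd > 0:
        log2_expr = log2_expr + rng.normal(0.0, noise_sd, size=log2_expr.shape)
    values = pd.DataFrame(np.exp2(log2_expr), index=gene_ids, columns=sample_ids)
    matrix = ExpressionMatrix(values, stage="raw")

    # survival: exponential with log-hazard linear in the standardized EMT latent
    z = (emt - emt.mean()) / (emt.std() if emt.std() > 0 else 1.0)
    hazard = base_hazard * hazard_ratio_per_emt_unit**z
    event_time = rng.exponential(1.0 / hazard)
    if censor_fraction > 0:
        censor_rate = base_hazard * censor_fraction / (1.0 - censor_fraction)
        censor_time = rng.exponential(1.0 / censor_rate, size=n_samples)
    else:
        censor_time = np.full(n_samples, np.inf)
    followup = np.minimum(event_time, censor_time)
    event = event_time <= censor_time

    age = np.clip(np.round(rng.normal(58.0, 10.0, n_samples)), 30, 90)
    tumor_size = np.round(rng.lognormal(0.7, 0.4, n_samples), 2)
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "age": age,
                "tumor_size": tumor_size,
                "followup_time": followup,
                "event": event.astype(float),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = CohortTruth(
        table=pd.DataFrame(
            {
                "emt_latent": emt,
                "immune_latent": immune,
                "fibrosis_latent": fibrosis,
                "cholesterol_latent": cholesterol,
                "interferon_latent": interferon,
                "compartment": compartment,
                "hazard_multiplier": hazard / base_hazard,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
        params={
            "n_samples": n_samples,
            "n_background_genes": n_background_genes,
            "block_sizes": sizes,
            "effect_size": effect_size,
            "noise_sd": noise_sd,
            "compartment_shift": compartment_shift,
            "hazard_ratio_per_emt_unit": hazard_ratio_per_emt_unit,
            "emt_immune_loading": emt_immune_loading,
            "fibrosis_immune_loading": fibrosis_immune_loading,
            "chol_immune_loading": chol_immune_loading,
            "ifn_immune_loading": ifn_immune_loading,
            "seed": seed,
        },
    )
    return matrix, clinical, truth


def generate_duplicate(
    m: ExpressionMatrix,
    clin: ClinicalTable,
    noise_sd: float = 0.3,
    permute_seed: int | None = None,
    n_corrupt: int = 0,
) -> DuplicateResult:
    """Column-permuted noisy duplicate with matched clinical fields.

    Noise is added on the log2 scale so it is comparable with the
    generator's. `n_corrupt` duplicated samples get scrambled age and
    tumor size, emulating matches that clinical verification must
    reject.
    """
    if permute_seed is None:
        raise ValueError("permute_seed is required")
    if n_corrupt > m.n_samples:
        raise ValueError("n_corrupt exceeds the number of samples")
    rng = np.random.default_rng(permute_seed)
    perm = rng.permutation(m.n_samples)
    src_ids = [m.sample_ids[j] for j in perm]
    dup_ids = [f"D{i:04d}" for i in range(m.n_samples)]
    log2_vals = np.log2(np.maximum(m.values.to_numpy(dtype=float)[:, perm], 1e-12))
    if noise_sd > 0:
        log2_vals = log2_vals + rng.normal(0.0, noise_sd, size=log2_vals.shape)
    dup_matrix = ExpressionMatrix(
        pd.DataFrame(np.exp2(log2_vals), index=m.gene_ids, columns=dup_ids),
        stage="raw",
    )
    dup_clin = clin.data.loc[src_ids].copy()
    dup_clin.index = pd.Index(dup_ids, name="sample_id")
    corrupt_pos = rng.choice(m.n_samples, size=n_corrupt, replace=False)
    corrupted_dup = tuple(dup_ids[i] for i in sorted(corrupt_pos))
    corrupted_src = tuple(src_ids[i] for i in sorted(corrupt_pos))
    for i in corrupt_pos:
        dup_clin.iloc[i, dup_clin.columns.get_loc("age")] = (
            dup_clin.iloc[i]["age"] + 25.0
        )
        dup_clin.iloc[i, dup_clin.columns.get_loc("tumor_size")] = (
            dup_clin.iloc[i]["tumor_size"] * 3.0
        )
    return DuplicateResult(
        matrix=dup_matrix,
        clinical=ClinicalTable(dup_clin),
        mapping=dict(zip(dup_ids, src_ids)),
        corrupted_dup_ids=corrupted_dup,
        corrupted_source_ids=corrupted_src,
    )
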