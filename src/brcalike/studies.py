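"""Reusable simulation studies exercising the full analysis chain.

These functions generate synthetic cohorts under stated conditions, run the
fitting / embedding / resampling stages, and measure operating
characteristics (floor p-value reporting, type-I error, power, recovery
rates).  They are shared between the test suite and the acceptance script
so both report the same computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import build_aberration_groups, load_aberration_events
from .embedding import embed_profiles
from .features import call_hypermethylation, call_low_expression, summarize_gene_methylation
from .resampling import empirical_p, group_median_distance, permutation_null, run_comparison_suite
from .signatures import fit_cohort_weights
from .synthetic import CohortConfig, GroupSpec, generate_cohort

# Replicate-cohort conditions: cohort scale and BRCA group sizes mirror the
# study population (~1000 patients; 22 germline carriers per BRCA gene); the
# candidate group carries delta on the HRD-like signature with 500 mutations
# per tumor (the regime in which mixture weights are recoverable).
POWER_COHORT = dict(
    n_patients=1000,
    n_signatures=27,
    n_genes_expression=60,
    mutations_per_tumor=500,
)


def _replicate_config(delta: float, n_group: int, seed: int) -> CohortConfig:
    # BRCA-like reference structure mirrors the study population: 22 germline
    # carriers per BRCA gene plus somatic mutations, deletions and
    # hypermethylation events totalling ~125 reference members, all sharing
    # the HRD-like enrichment; plus the enriched candidate group and a null
    # comparison group.
    return CohortConfig(
        group_specs=(
            GroupSpec("BRCA1", "germline_mutation", 22, delta, 0),
            GroupSpec("BRCA2", "germline_mutation", 22, delta, 0),
            GroupSpec("BRCA1", "somatic_mutation", 14, delta, 0),
            GroupSpec("BRCA1", "hypermethylation", 36, delta, 0),
            GroupSpec("BRCA2", "somatic_mutation", 12, delta, 0),
            GroupSpec("BRCA2", "homozygous_deletion", 19, delta, 0),
            GroupSpec("BARD1", "somatic_mutation", n_group, delta, 1),
            GroupSpec("ATM", "somatic_mutation", 15, 0.0, 2),
        ),
        seed=seed,
        **POWER_COHORT,
    )


def replicate_group_test(
    delta: float, n_group: int, B: int, seed: int
) -> tuple[float, float]:
    """One replicate: cohort -> weights -> MDS -> suite; returns the candidate
    group's (raw, Holm-adjusted) p for its between-vs-reference test."""
    cohort = generate_cohort(_replicate_config(delta, n_group, seed))
    weights, _ = fit_cohort_weights(cohort.spectra, cohort.signatures)
    emb = embed_profiles(weights.drop(columns=["residual"]))
    events = load_aberration_events(cohort.aberrations)
    groups = build_aberration_groups(events, ["BARD1", "ATM"])
    reference = next(g for g in groups if g.label == "BRCA-like")
    # the suite tests the single enriched candidate group between-vs-reference
    # (the null ATM group stays in the cohort as background)
    tested = [g for g in groups if g.label == "BARD1:somatic_mutation"]
    results, _ = run_comparison_suite(
        emb, tested, reference=reference, B=B, seed=seed, include_within=False
    )
    r = next(x for x in results if x.label == "BARD1:somatic_mutation vs BRCA-like")
    return r.p_raw, r.p_holm


def power_study(
    n_replicates: int = 50,
    delta: float = 0.6,
    n_group: int = 20,
    B: int = 5_000,
    seed: int = 0,
) -> float:
    """Fraction of replicate cohorts whose enriched group reaches Holm p <= 0.05."""
    base = int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**31)
    hits = 0
    for rep in range(n_replicates):
        _, p_holm = replicate_group_test(delta, n_group, B, (base + rep) % 2**31)
        if p_holm <= 0.05:
            hits += 1
    return hits / n_replicates


def type1_study(
    n_tests: int = 400,
    n_cohorts: int = 40,
    n_patients: int = 150,
    group_size: int = 10,
    B: int = 1_000,
    seed: int = 0,
) -> np.ndarray:
    """Raw within-group p-values for random groups drawn from null cohorts.

    Cohorts carry no enrichment (all deltas zero), so the tested groups are
    exchangeable with the background and the raw p-values should be uniform.
    """
    ss = np.random.SeedSequence(seed)
    p_values = []
    per_cohort = int(np.ceil(n_tests / n_cohorts))
    for cohort_seed in ss.spawn(n_cohorts):
        rng = np.random.default_rng(cohort_seed)
        cfg = CohortConfig(
            n_patients=n_patients,
            n_signatures=10,
            n_genes_expression=20,
            mutations_per_tumor=200,
            seed=int(rng.integers(2**31)),
        )
        cohort = generate_cohort(cfg)
        weights, _ = fit_cohort_weights(cohort.spectra, cohort.signatures)
        emb = embed_profiles(weights.drop(columns=["residual"]))
        for _ in range(per_cohort):
            if len(p_values) >= n_tests:
                break
            members = rng.choice(emb.n, size=group_size, replace=False)
            obs = group_median_distance(emb.coords, members)
            null = permutation_null(emb, group_size, "within", B=B, seed=rng)
            p, _ = empirical_p(obs, null, B)
            p_values.append(p)
    return np.asarray(p_values)


def floor_p_configuration(
    n_background: int = 980, n_group: int = 20, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """A 2-D configuration whose designated group is maximally tight.

    Background samples scatter with unit spread; the group's members are
    coincident, so the observed median pairwise distance (zero) falls below
    every permuted median with overwhelming probability.
    """
    rng = np.random.default_rng(seed)
    coords = np.vstack(
        [rng.normal(size=(n_background, 2)), np.tile(rng.normal(size=2), (n_group, 1))]
    )
    members = np.arange(n_background, n_background + n_group)
    return coords, members


@dataclass
class OutlierRecovery:
    sensitivity: float
    false_positive_rate: float
    n_injected: int
    n_flagged: int


def hypermethylation_recovery(
    n_genes: int = 20,
    n_patients: int = 1000,
    n_injected_per_gene: int = 5,
    rate: float = 20.0,
    seed: int = 0,
) -> OutlierRecovery:
    """Recovery of injected high-beta outliers on the synthetic cohort tables.

    Builds a cohort whose hypermethylation groups inject betas in [0.5, 0.9]
    over the truncated-exponential background, summarizes probes to gene
    level and runs the detector; aggregates over genes.
    """
    specs = tuple(
        GroupSpec(f"GM{i:02d}", "hypermethylation", n_injected_per_gene, 0.0, 0)
        for i in range(n_genes)
    )
    cfg = CohortConfig(
        n_patients=n_patients,
        n_signatures=4,
        n_genes_expression=n_genes + 5,
        group_specs=specs,
        beta_background_rate=rate,
        mutations_per_tumor=50,
        seed=seed,
    )
    cohort = generate_cohort(cfg)
    gm = summarize_gene_methylation(cohort.methylation_probes)
    events = call_hypermethylation(gm.betas)
    truth = set(cohort.ground_truth.hypermethylation)
    called = {(e.patient_id, e.gene) for e in events}
    # restrict to the genes that actually carry injections
    inj_genes = {g for (_, g) in truth}
    called = {(p, g) for (p, g) in called if g in inj_genes}
    tp = len(called & truth)
    fp = len(called - truth)
    n_negatives = len(inj_genes) * n_patients - len(truth)
    return OutlierRecovery(
        sensitivity=tp / len(truth),
        false_positive_rate=fp / n_negatives,
        n_injected=len(truth),
        n_flagged=len(called),
    )


def low_expression_recovery(
    n_genes: int = 10, n_samples: int = 1000, seed: int = 0
) -> tuple[float, int]:
    """Injected near-zero expressors: sensitivity and clean-gene false flags.

    Half the genes get one sample knocked down to ``exp(-10)`` over a
    lognormal background; the other half are clean.  Returns the fraction of
    injected samples flagged and the number of flags on clean genes.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    rows = {}
    truth = []
    for g in range(n_genes):
        vals = np.exp(rng.normal(5.0, 1.0, n_samples))
        if g < n_genes // 2:
            j = int(rng.integers(n_samples))
            vals[j] = np.exp(-10.0)
            truth.append((f"G{g:03d}", samples[j]))
        rows[f"G{g:03d}"] = vals
    expr = pd.DataFrame(rows, index=samples).T
    flags = call_low_expression(expr)
    called = set(map(tuple, flags.to_numpy()))
    tp = len(called & set(truth))
    clean_genes = {f"G{g:03d}" for g in range(n_genes // 2, n_genes)}
    fp_clean = sum(1 for (g, _) in called if g in clean_genes)
    return tp / len(truth), fp_clean
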