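"""Synthetic cohort generation with the statistical structure the analysis assumes.

A cohort emulates a breast-cancer study population: each tumor carries a
non-negative mixture over K mutational signatures (one designated "HRD-like"
signature is enriched by an additive effect ``delta`` in designated
aberration groups, mimicking homologous-recombination deficiency), a
96-channel spectrum drawn multinomially from that mixture, a
cluster-structured gene-expression profile (Gaussian clusters in a latent
space, mimicking intrinsic-subtype structure), promoter-methylation beta
values with a low truncated-exponential background and injected high-beta
outliers, and binary clinical indicators whose log-odds are linear in each
patient's (ground-truth) distance to the BRCA-like reference group.  Every
injected effect is recorded as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError
from .signatures import CHANNELS

HRD_SIGNATURE_INDEX = 0  # the designated HRD-like signature row


@dataclass(frozen=True)
class GroupSpec:
    """One injected aberration group."""

    gene: str
    event_type: str
    size: int
    delta: float = 0.0  # additive enrichment of the HRD-like weight, in [0, 1]
    expression_cluster: int = 0


@dataclass
class CohortConfig:
    n_patients: int = 1000
    n_signatures: int = 27
    n_genes_expression: int = 200
    n_probes_per_gene: int = 5
    group_specs: tuple[GroupSpec, ...] = ()
    # negative-binomial mutation counts per tumor (mean / dispersion r);
    # a fixed count can be forced with mutations_per_tumor
    mutation_mean: float = 100.0
    mutation_dispersion: float = 1.0
    mutations_per_tumor: int | None = None
    beta_background_rate: float = 20.0
    outlier_beta_range: tuple[float, float] = (0.5, 0.9)
    n_expression_clusters: int = 5
    expression_cluster_sep: float = 3.0
    latent_dim: int = 50
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_patients": self.n_patients,
            "n_signatures": self.n_signatures,
            "n_genes_expression": self.n_genes_expression,
            "n_probes_per_gene": self.n_probes_per_gene,
            "n_expression_clusters": self.n_expression_clusters,
            "latent_dim": self.latent_dim,
        }
        for name, v in counts.items():
            if v < 1:
                raise InvalidConfigError(f"{name} must be positive, got {v}")
        if self.n_signatures < 2:
            raise InvalidConfigError("need at least 2 signatures")
        if sum(g.size for g in self.group_specs) > self.n_patients:
            raise InvalidConfigError("group sizes exceed the cohort size")
        for g in self.group_specs:
            if not 0.0 <= g.delta <= 1.0:
                raise InvalidConfigError(f"delta must lie in [0,1], got {g.delta}")
            if g.size < 1:
                raise InvalidConfigError("group sizes must be positive")
        if self.beta_background_rate <= 0:
            raise InvalidConfigError("beta_background_rate must be positive")
        lo, hi = self.outlier_beta_range
        if not 0.0 <= lo < hi <= 1.0:
            raise InvalidConfigError("outlier_beta_range must be an interval in [0,1]")
        if self.mutation_mean <= 0 or self.mutation_dispersion <= 0:
            raise InvalidConfigError("mutation count parameters must be positive")


@dataclass
class GroundTruth:
    true_weights: pd.DataFrame  # patients x K
    mutation_counts: pd.Series
    group_members: dict[str, list[str]]
    hypermethylation: list[tuple[str, str]]  # (patient, gene)
    low_expression: list[tuple[str, str]]  # (patient, gene)
    expression_clusters: pd.Series
    clinical_coefficients: dict[str, float]
    hrd_index: int = HRD_SIGNATURE_INDEX


@dataclass
class SyntheticCohort:
    config: CohortConfig
    patients: list[str]
    signatures: pd.DataFrame  # K x 96
    aberrations: pd.DataFrame
    spectra: pd.DataFrame  # patients x 96
    expression: pd.DataFrame  # genes x patients
    methylation_probes: pd.DataFrame
    clinical: pd.DataFrame
    ground_truth: GroundTruth

    def write(self, out_dir: str | Path) -> dict[str, str]:
        """Write the cohort tables as TSV files; returns the path map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        tables = {
            "aberrations.tsv": self.aberrations,
            "spectra.tsv": self.spectra,
            "signatures.tsv": self.signatures,
            "expression.tsv": self.expression,
            "methylation_probes.tsv": self.methylation_probes,
            "clinical.tsv": self.clinical,
        }
        index_tables = {"spectra.tsv", "signatures.tsv", "expression.tsv", "clinical.tsv"}
        for name, df in tables.items():
            p = out / name
            df.to_csv(p, sep="\t", index=name in index_tables)
            paths[name] = str(p)
        gt_rows = []
        for (pat, gene) in self.ground_truth.hypermethylation:
            gt_rows.append({"kind": "hypermethylation", "patient_id": pat, "gene": gene, "value": ""})
        for (pat, gene) in self.ground_truth.low_expression:
            gt_rows.append({"kind": "low_expression", "patient_id": pat, "gene": gene, "value": ""})
        for label, members in self.ground_truth.group_members.items():
            for pat in members:
                gt_rows.append({"kind": "group", "patient_id": pat, "gene": label, "value": ""})
        hrd = self.ground_truth.true_weights.iloc[:, self.ground_truth.hrd_index]
        for pat, w in hrd.items():
            gt_rows.append({"kind": "true_hrd_weight", "patient_id": pat, "gene": "", "value": f"{w:.6g}"})
        p = out / "ground_truth.tsv"
        pd.DataFrame(gt_rows).to_csv(p, sep="\t", index=False)
        paths["ground_truth.tsv"] = str(p)
        return paths


def generate_signature_matrix(
    k: int,
    channels: int = 96,
    seed: int | np.random.Generator = 0,
    max_cosine: float = 0.99,
) -> np.ndarray:
    """Row-stochastic k x channels matrix of sparse, pairwise-distinct signatures.

    Rows are drawn from a sparse Dirichlet (concentration 0.1) to mimic the
    peaked shape of real mutational signatures; rows with cosine similarity
    >= ``max_cosine`` to an earlier row are redrawn.
    """
    if k < 2:
        raise InvalidConfigError(f"need at least 2 signatures, got k={k}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    attempts = 0
    while len(rows) < k:
        cand = rng.dirichlet(np.full(channels, 0.1))
        ok = True
        cn = cand / np.linalg.norm(cand)
        for r in rows:
            if float(cn @ (r / np.linalg.norm(r))) >= max_cosine:
                ok = False
                break
        if ok:
            rows.append(cand)
        attempts += 1
        if attempts > 100 * k:
            raise InvalidConfigError("could not draw pairwise-distinct signatures")
    S = np.vstack(rows)
    return S / S.sum(axis=1, keepdims=True)


def generate_spectra(
    weights: np.ndarray,
    signatures: np.ndarray,
    n_mutations: int | np.ndarray,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Multinomial spectra of given sizes from mixture distributions w'S."""
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    S = np.asarray(signatures, dtype=float)
    if np.any(W < 0):
        raise InvalidInputError("signature weights must be non-negative")
    if not np.allclose(W.sum(axis=1), 1.0, atol=1e-8):
        raise InvalidInputError("signature weights must lie on the simplex")
    counts = np.broadcast_to(np.asarray(n_mutations, dtype=np.int64), (W.shape[0],))
    if np.any(counts < 1):
        raise InvalidInputError("n_mutations must be at least 1 per tumor")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = W @ S
    probs = probs / probs.sum(axis=1, keepdims=True)
    out = np.empty((W.shape[0], S.shape[1]), dtype=np.int64)
    for i in range(W.shape[0]):
        out[i] = rng.multinomial(int(counts[i]), probs[i])
    return out


def _truncated_exponential(rng: np.random.Generator, rate: float, size) -> np.ndarray:
    """Exponential(rate) truncated to [0, 1] via inverse-CDF sampling."""
    u = rng.random(size)
    return -np.log1p(-u * (1.0 - np.exp(-rate))) / rate


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort with recorded ground truth."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (
        s_sig, s_w, s_counts, s_spec, s_expr, s_meth, s_clin,
    ) = (np.random.default_rng(c) for c in ss.spawn(7))

    n = config.n_patients
    K = config.n_signatures
    patients = [f"P{i:04d}" for i in range(n)]

    sig = generate_signature_matrix(K, seed=s_sig)
    sig_names = [f"S{j + 1}" for j in range(K)]
    signatures = pd.DataFrame(sig, index=pd.Index(sig_names, name="signature"), columns=list(CHANNELS))

    # --- group memberships: disjoint consecutive blocks ---
    group_members: dict[str, list[str]] = {}
    member_delta = np.zeros(n)
    member_cluster = np.full(n, -1, dtype=int)
    cursor = 0
    for spec in config.group_specs:
        block = patients[cursor : cursor + spec.size]
        cursor += spec.size
        group_members[f"{spec.gene}:{spec.event_type}"] = list(block)
        idx = [patients.index(p) for p in block]
        member_delta[idx] = np.maximum(member_delta[idx], spec.delta)
        member_cluster[idx] = spec.expression_cluster

    # --- true signature weights: Dirichlet(1) background + HRD enrichment ---
    W = s_w.dirichlet(np.ones(K), size=n)
    W[:, HRD_SIGNATURE_INDEX] += member_delta
    W = W / W.sum(axis=1, keepdims=True)
    true_weights = pd.DataFrame(W, index=pd.Index(patients, name="patient"), columns=sig_names)

    # --- mutation counts and spectra ---
    if config.mutations_per_tumor is not None:
        counts = np.full(n, int(config.mutations_per_tumor), dtype=np.int64)
    else:
        r = config.mutation_dispersion
        p_nb = r / (r + config.mutation_mean)
        counts = s_counts.negative_binomial(r, p_nb, size=n).astype(np.int64)
        counts = np.maximum(counts, 1)
    spectra = pd.DataFrame(
        generate_spectra(W, sig, counts, seed=s_spec),
        index=pd.Index(patients, name="tumor"),
        columns=list(CHANNELS),
    )

    # --- aberration table ---
    ab_rows = []
    for spec in config.group_specs:
        for pat in group_members[f"{spec.gene}:{spec.event_type}"]:
            ab_rows.append(
                {
                    "patient_id": pat,
                    "gene": spec.gene,
                    "event_type": spec.event_type,
                    "classification": "pathogenic",
                    "loh": "",
                }
            )
    aberrations = pd.DataFrame(
        ab_rows, columns=["patient_id", "gene", "event_type", "classification", "loh"]
    )

    # --- expression: Gaussian clusters in a latent space, lognormal scale ---
    panel_genes = sorted({s.gene for s in config.group_specs} | {"BRCA1", "BRCA2"})
    n_filler = max(config.n_genes_expression - len(panel_genes), 0)
    genes = panel_genes + [f"GF{i:04d}" for i in range(n_filler)]
    L = config.latent_dim
    centers = s_expr.normal(0.0, config.expression_cluster_sep, size=(config.n_expression_clusters, L))
    clusters = np.where(
        member_cluster >= 0,
        member_cluster % config.n_expression_clusters,
        s_expr.integers(0, config.n_expression_clusters, size=n),
    )
    latent = centers[clusters] + s_expr.normal(0.0, 1.0, size=(n, L))
    loading = s_expr.normal(0.0, 1.0 / np.sqrt(L), size=(L, len(genes)))
    log_expr = 5.0 + latent @ loading + s_expr.normal(0.0, 0.3, size=(n, len(genes)))
    expr = np.exp(log_expr).T  # genes x patients
    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=patients)

    # --- low-expression injection: silencing events knock down the gene ---
    low_expression: list[tuple[str, str]] = []
    for spec in config.group_specs:
        if spec.event_type in ("hypermethylation", "homozygous_deletion"):
            for pat in group_members[f"{spec.gene}:{spec.event_type}"]:
                expression.loc[spec.gene, pat] *= 1e-4
                low_expression.append((pat, spec.gene))

    # --- methylation probes ---
    meth_rows = []
    hypermeth: list[tuple[str, str]] = []
    hyper_by_gene: dict[str, list[str]] = {}
    for spec in config.group_specs:
        if spec.event_type == "hypermethylation":
            members = group_members[f"{spec.gene}:{spec.event_type}"]
            hyper_by_gene.setdefault(spec.gene, []).extend(members)
            hypermeth.extend((pat, spec.gene) for pat in members)
    lo, hi = config.outlier_beta_range
    for gene in panel_genes:
        for j in range(config.n_probes_per_gene):
            dist = 50 + 100 * j  # 50, 150, 250 in-window; 350+ outside
            betas = _truncated_exponential(s_meth, config.beta_background_rate, n)
            if dist <= 300 and gene in hyper_by_gene:
                for pat in hyper_by_gene[gene]:
                    betas[patients.index(pat)] = lo + (hi - lo) * s_meth.random()
            row = {"probe_id": f"cg_{gene}_{j}", "gene": gene, "tss_distance": dist}
            row.update({pat: betas[i] for i, pat in enumerate(patients)})
            meth_rows.append(row)
    methylation = pd.DataFrame(meth_rows)

    # --- clinical indicators: log-odds linear in distance to reference ---
    ref_members = sorted(
        {
            pat
            for spec in config.group_specs
            if spec.gene in ("BRCA1", "BRCA2")
            for pat in group_members[f"{spec.gene}:{spec.event_type}"]
        }
    )
    if len(ref_members) >= 2:
        ref_idx = [patients.index(p) for p in ref_members]
        diffs = W[:, None, :] - W[ref_idx][None, :, :]
        dmat = np.sqrt((diffs**2).sum(axis=-1))
        d = np.empty(n)
        for i in range(n):
            row = dmat[i]
            if i in ref_idx:
                row = np.delete(row, ref_idx.index(i))
            d[i] = np.median(row)
        z = (d - d.mean()) / d.std()
    else:
        hrdw = W[:, HRD_SIGNATURE_INDEX]
        z = -(hrdw - hrdw.mean()) / hrdw.std()
    coefs = {"indicator_pos": 2.0, "indicator_neg": -2.0, "indicator_null": 0.0}
    clin = {}
    for name, beta in coefs.items():
        prob = 1.0 / (1.0 + np.exp(-(beta * z)))
        clin[name] = (s_clin.random(n) < prob).astype(int)
    clinical = pd.DataFrame(clin, index=pd.Index(patients, name="patient"))

    ground_truth = GroundTruth(
        true_weights=true_weights,
        mutation_counts=pd.Series(counts, index=patients, name="n_mutations"),
        group_members=group_members,
        hypermethylation=hypermeth,
        low_expression=low_expression,
        expression_clusters=pd.Series(clusters, index=patients, name="cluster"),
        clinical_coefficients=coefs,
    )
    return SyntheticCohort(
        config=config,
        patients=patients,
        signatures=signatures,
        aberrations=aberrations,
        spectra=spectra,
        expression=expression,
        methylation_probes=methylation,
        clinical=clinical,
        ground_truth=ground_truth,
    )
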