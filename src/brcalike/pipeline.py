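"""End-to-end pipeline orchestration with explicit configuration.

All tabular I/O is tab-separated UTF-8 with a single header row; missing
values are empty fields; sample identifiers are opaque strings.  Every
output file carries leading ``#`` comment lines recording the package
version, the seed and a hash of the configuration, and readers skip such
lines.  Stage order: catalog -> feature calls -> signature fit -> embed ->
compare -> downstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .catalog import build_aberration_groups, load_aberration_events
from .downstream import correlation_screen, crossval_logistic, distance_to_reference
from .embedding import Embedding, embed_profiles
from .errors import InvalidConfigError, StratificationError
from .features import call_hypermethylation, call_low_expression, summarize_gene_methylation
from .resampling import comparison_frame, run_comparison_suite
from .signatures import fit_cohort_weights

logger = logging.getLogger(__name__)

STAGES = ("catalog", "features", "signatures", "embed", "compare", "downstream")


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config_hash: str | None = None,
    index: bool = True,
) -> None:
    """Write a TSV with a provenance header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# brcalike {__version__}")
        if seed is not None:
            fh.write(f" seed={seed}")
        if config_hash is not None:
            fh.write(f" config={config_hash}")
        fh.write("\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


@dataclass
class PipelineConfig:
    out_dir: str
    aberrations: str | None = None
    spectra: str | None = None
    signatures: str | None = None
    expression: str | None = None
    methylation_probes: str | None = None
    clinical: str | None = None
    stages: tuple[str, ...] = STAGES
    B: int = 100_000
    seed: int = 0
    gene_panel: tuple[str, ...] = ()
    tss_window: int = 300
    include_within: bool = True
    signature_cutoff: float = 0.06
    min_mutations: int = 10
    expression_log_transform: bool = True
    holm_family: str = "all-aberration-types"
    classifier_folds: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "gene_panel" in raw:
            raw["gene_panel"] = tuple(raw["gene_panel"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    _STAGE_INPUTS = {
        "catalog": ("aberrations",),
        "features": ("methylation_probes", "expression"),
        "signatures": ("spectra", "signatures"),
        "embed": (),
        "compare": (),
        "downstream": ("clinical",),
    }

    def validate(self) -> None:
        for stage in self.stages:
            if stage not in STAGES:
                raise InvalidConfigError(f"unknown stage {stage!r}")
            for attr in self._STAGE_INPUTS[stage]:
                p = getattr(self, attr)
                if p is None:
                    raise InvalidConfigError(f"stage {stage!r} requires input {attr!r}")
                if not Path(p).exists():
                    raise InvalidConfigError(f"input file not found: {p}")
        if self.B < 1:
            raise InvalidConfigError("B must be positive")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) a run manifest."""
    config.validate()  # fail fast, before any computation
    chash = config.config_hash()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": chash,
        "stages": list(config.stages),
        "artifacts": {},
        "warnings": [],
        "status": "ok",
    }

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        p = out / name
        write_tsv(df, p, seed=config.seed, config_hash=chash, index=index)
        manifest["artifacts"][name] = str(p)
        logger.info("stage output %s: %d rows", name, len(df))

    events = []
    groups = []
    reference = None
    try:
        if "catalog" in config.stages:
            ab = read_tsv(config.aberrations)
            events = load_aberration_events(ab)

        if "features" in config.stages:
            probes = read_tsv(config.methylation_probes)
            gm = summarize_gene_methylation(probes, window=config.tss_window)
            manifest["warnings"] += [
                f"gene {g} dropped: no probes near TSS" for g in gm.dropped_genes
            ]
            hyper = call_hypermethylation(gm.betas)
            emit(
                "hypermethylation_events.tsv",
                pd.DataFrame(
                    [
                        {"patient_id": e.patient_id, "gene": e.gene, "event_type": e.event_type}
                        for e in hyper
                    ],
                    columns=["patient_id", "gene", "event_type"],
                ),
            )
            existing = {(e.patient_id, e.gene, e.event_type) for e in events}
            events += [
                e
                for e in hyper
                if (e.patient_id, e.gene, e.event_type) not in existing
            ]
            expr = read_tsv(config.expression, index_col=0)
            low = call_low_expression(expr)
            emit("low_expression_flags.tsv", low)

        weights = None
        if "signatures" in config.stages:
            spectra = read_tsv(config.spectra, index_col=0)
            sig = read_tsv(config.signatures, index_col=0)
            weights, skipped = fit_cohort_weights(
                spectra, sig, cutoff=config.signature_cutoff, min_mutations=config.min_mutations
            )
            manifest["warnings"] += [f"tumor {t} skipped: too few mutations" for t in skipped]
            emit("signature_weights.tsv", weights, index=True)

        emb_sig: Embedding | None = None
        if "embed" in config.stages:
            if weights is None:
                raise InvalidConfigError("embed stage requires the signatures stage")
            emb_sig = embed_profiles(weights.drop(columns=["residual"]), dims=2)
            df = emb_sig.to_frame()
            df["eigenvalue1"] = emb_sig.eigenvalues[0]
            df["eigenvalue2"] = emb_sig.eigenvalues[1]
            emit("embedding_signatures.tsv", df, index=True)
            if config.expression is not None:
                expr = read_tsv(config.expression, index_col=0)
                emb_expr = embed_profiles(
                    expr.T, dims=2, log_transform=config.expression_log_transform
                )
                df = emb_expr.to_frame()
                df["eigenvalue1"] = emb_expr.eigenvalues[0]
                df["eigenvalue2"] = emb_expr.eigenvalues[1]
                emit("embedding_expression.tsv", df, index=True)

        if "compare" in config.stages:
            if emb_sig is None:
                raise InvalidConfigError("compare stage requires the embed stage")
            panel = list(config.gene_panel) or sorted({e.gene for e in events})
            all_groups = build_aberration_groups(events, panel)
            reference = next(g for g in all_groups if g.label == "BRCA-like")
            embedded = set(emb_sig.sample_ids)
            groups = []
            for g in all_groups:
                if g.label == "BRCA-like":
                    continue
                members = frozenset(m for m in g.members if m in embedded)
                if members:
                    groups.append(
                        type(g)(label=g.label, gene=g.gene, event_types=g.event_types, members=members)
                    )
            ref_members = frozenset(m for m in reference.members if m in embedded)
            reference = type(reference)(
                label=reference.label,
                gene=reference.gene,
                event_types=reference.event_types,
                members=ref_members,
            )
            results, skipped_cmp = run_comparison_suite(
                emb_sig,
                groups,
                reference=reference if len(reference.members) >= 1 else None,
                B=config.B,
                seed=config.seed,
                include_within=config.include_within,
                family=config.holm_family,
            )
            manifest["warnings"] += skipped_cmp
            emit("comparisons.tsv", comparison_frame(results))

        if "downstream" in config.stages:
            if emb_sig is None or reference is None or len(reference.members) < 2:
                raise InvalidConfigError(
                    "downstream stage requires the compare stage and a reference of >= 2 members"
                )
            dist = distance_to_reference(emb_sig, set(reference.members))
            emit("reference_distances.tsv", dist.to_frame(), index=True)
            clinical = read_tsv(config.clinical, index_col=0)
            clinical.index = clinical.index.map(str)
            screen = correlation_screen(dist, clinical, add_bh=True)
            emit("correlations.tsv", screen)
            labels = pd.Series(
                [1 if s in reference.members else 0 for s in emb_sig.sample_ids],
                index=emb_sig.sample_ids,
            )
            try:
                report = crossval_logistic(
                    emb_sig, labels, folds=config.classifier_folds, seed=config.seed
                )
                emit(
                    "classifier_report.tsv",
                    pd.DataFrame(
                        [
                            {
                                "target": report.target,
                                "folds": report.folds,
                                "seed": report.seed,
                                "sensitivity": report.sensitivity,
                                "specificity": report.specificity,
                                "auroc": report.auroc,
                                "fold_class_weights": ";".join(
                                    f"{w:.4g}" for w in report.class_weights
                                ),
                            }
                        ]
                    ),
                )
            except StratificationError as exc:
                manifest["warnings"].append(f"classifier skipped: {exc}")
    except Exception:
        manifest["status"] = "failed"
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
        raise

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["artifacts"]["manifest.json"] = str(out / "manifest.json")
    return manifest
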