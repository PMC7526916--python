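"""Aberration events, somatic-variant filtering and patient-group construction.

"Aberration" covers four event types on a gene: germline mutation, somatic
mutation, homozygous deletion (GISTIC call of -2) and promoter
hypermethylation.  Somatic variants are excluded when any of four criteria
holds — synonymous consequence, LOW/MODIFIER predicted effect, concordant
benign SIFT + PolyPhen predictions, or population allele frequency above 1% —
and BRCA1/BRCA2 somatic variants are additionally retained only when their
clinical classification is pathogenic, likely pathogenic or VUS.  Germline
events enter the catalog only when classified pathogenic or likely
pathogenic.  Loss-of-heterozygosity flags are carried as annotations and
never alter group membership.

Patient groups are built per gene and event type, together with a per-gene
"any" group (the union across event types) and a BRCA-like reference group
(all patients with any aberration type in BRCA1 or BRCA2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

EVENT_TYPES = (
    "germline_mutation",
    "somatic_mutation",
    "homozygous_deletion",
    "hypermethylation",
)

VARIANT_CLASSES = ("synonymous", "missense", "nonsense", "frameshift", "splice", "other")
SEVERITIES = ("HIGH", "MODERATE", "LOW", "MODIFIER")
SIFT_CALLS = ("deleterious", "tolerated")
POLYPHEN_CALLS = ("damaging", "benign")
CLASSIFICATIONS = (
    "pathogenic",
    "likely-pathogenic",
    "VUS",
    "likely-benign",
    "benign",
    "unclassified",
)

GERMLINE_INCLUDED_CLASSES = ("pathogenic", "likely-pathogenic")
BRCA_GENES = ("BRCA1", "BRCA2")
BRCA_KEPT_CLASSES = ("pathogenic", "likely-pathogenic", "VUS")

#: exclusion reason codes, in check order
REASON_SYNONYMOUS = "synonymous"
REASON_LOW_IMPACT = "low_impact"
REASON_PREDICTED_BENIGN = "predicted_benign"
REASON_COMMON = "common"
REASON_BRCA_CLASSIFICATION = "brca_not_pathogenic_or_vus"


@dataclass(frozen=True)
class VariantAnnotation:
    patient_id: str
    gene: str
    variant_class: str
    severity: str
    sift: str | None = None
    polyphen: str | None = None
    population_frequency: float | None = None
    classification: str = "unclassified"

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValidationError(f"unknown variant class {self.variant_class!r}")
        if self.severity not in SEVERITIES:
            raise ValidationError(f"unknown severity {self.severity!r}")
        if self.sift is not None and self.sift not in SIFT_CALLS:
            raise ValidationError(f"unknown SIFT call {self.sift!r}")
        if self.polyphen is not None and self.polyphen not in POLYPHEN_CALLS:
            raise ValidationError(f"unknown PolyPhen call {self.polyphen!r}")
        if self.population_frequency is not None and not (
            0.0 <= self.population_frequency <= 1.0
        ):
            raise ValidationError(
                f"allele frequency outside [0,1]: {self.population_frequency}"
            )
        if self.classification not in CLASSIFICATIONS:
            raise ValidationError(f"unknown classification {self.classification!r}")


@dataclass(frozen=True)
class AberrationEvent:
    patient_id: str
    gene: str
    event_type: str
    loh: bool | None = None  # None = unknown; descriptive annotation only

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.event_type!r}")


@dataclass(frozen=True)
class GroupDefinition:
    label: str
    gene: str  # gene symbol or reference tag
    event_types: tuple[str, ...]
    members: frozenset[str] = field(default_factory=frozenset)

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass
class FilterResult:
    kept: list[VariantAnnotation]
    excluded: list[tuple[VariantAnnotation, tuple[str, ...]]]

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def exclusion_reasons(v: VariantAnnotation, frequency_cutoff: float = 0.01) -> tuple[str, ...]:
    """All exclusion criteria a somatic variant triggers, in check order.

    The four criteria form a union: any one of them excludes the variant.
    """
    reasons = []
    if v.variant_class == "synonymous":
        reasons.append(REASON_SYNONYMOUS)
    if v.severity in ("LOW", "MODIFIER"):
        reasons.append(REASON_LOW_IMPACT)
    if v.sift == "tolerated" and v.polyphen == "benign":
        reasons.append(REASON_PREDICTED_BENIGN)
    if v.population_frequency is not None and v.population_frequency > frequency_cutoff:
        reasons.append(REASON_COMMON)
    if v.gene in BRCA_GENES and v.classification not in BRCA_KEPT_CLASSES:
        reasons.append(REASON_BRCA_CLASSIFICATION)
    return tuple(reasons)


def variants_from_table(table: pd.DataFrame) -> list[VariantAnnotation]:
    """Build annotations from a TSV-style frame; empty cells become missing."""

    def _opt(row, col):
        v = row.get(col)
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
            return None
        return v

    out = []
    for _, row in table.iterrows():
        freq = _opt(row, "population_frequency")
        out.append(
            VariantAnnotation(
                patient_id=str(row["patient_id"]),
                gene=str(row["gene"]),
                variant_class=str(row["variant_class"]),
                severity=str(row["severity"]),
                sift=_opt(row, "sift"),
                polyphen=_opt(row, "polyphen"),
                population_frequency=float(freq) if freq is not None else None,
                classification=str(_opt(row, "classification") or "unclassified"),
            )
        )
    return out


def toy_variant_table() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The packaged 20-row worked example and its hand-derived partition."""
    from importlib.resources import files

    data = files("brcalike") / "data"
    variants = pd.read_csv(str(data / "toy_variants.tsv"), sep="\t")
    expected = pd.read_csv(
        str(data / "toy_variants_expected.tsv"), sep="\t", keep_default_na=False
    )
    return variants, expected


def filter_somatic_variants(
    variants: list[VariantAnnotation], frequency_cutoff: float = 0.01
) -> FilterResult:
    """Partition somatic variants into kept and excluded, with reason codes."""
    kept, excluded = [], []
    for v in variants:
        reasons = exclusion_reasons(v, frequency_cutoff)
        if reasons:
            excluded.append((v, reasons))
        else:
            kept.append(v)
    return FilterResult(kept=kept, excluded=excluded)


def call_homozygous_deletions(cnv: pd.DataFrame) -> list[AberrationEvent]:
    """One homozygous-deletion event per (gene, sample) cell equal to -2.

    ``cnv`` is genes x samples with discrete GISTIC calls in {-2,...,2}.
    """
    values = cnv.to_numpy()
    valid = np.isin(values[~pd.isna(values)], (-2, -1, 0, 1, 2))
    if not valid.all():
        raise ValidationError("CNV calls must lie in the GISTIC set {-2,...,2}")
    genes_idx, sample_idx = np.nonzero(values == -2)
    return [
        AberrationEvent(
            patient_id=str(cnv.columns[j]),
            gene=str(cnv.index[i]),
            event_type="homozygous_deletion",
        )
        for i, j in zip(genes_idx, sample_idx)
    ]


def load_aberration_events(table: pd.DataFrame) -> list[AberrationEvent]:
    """Build events from an aberration table, gating germline rows by pathogenicity.

    Expected columns: ``patient_id``, ``gene``, ``event_type``; optional
    ``classification`` (germline rows are included only when pathogenic or
    likely pathogenic) and ``loh`` (true/false/empty).
    """
    events: list[AberrationEvent] = []
    seen: set[tuple[str, str, str]] = set()
    for _, row in table.iterrows():
        etype = str(row["event_type"])
        if etype not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {etype!r}")
        if etype == "germline_mutation":
            cls = str(row.get("classification", "pathogenic") or "pathogenic")
            if cls not in GERMLINE_INCLUDED_CLASSES:
                continue
        loh_raw = row.get("loh", None)
        loh = None
        if isinstance(loh_raw, str) and loh_raw.strip():
            loh = loh_raw.strip().lower() in ("true", "1", "yes")
        elif isinstance(loh_raw, (bool, np.bool_)):
            loh = bool(loh_raw)
        key = (str(row["patient_id"]), str(row["gene"]), etype)
        if key in seen:
            continue
        seen.add(key)
        events.append(
            AberrationEvent(patient_id=key[0], gene=key[1], event_type=etype, loh=loh)
        )
    return events


def build_aberration_groups(
    events: list[AberrationEvent],
    gene_panel: list[str],
    reference_genes: tuple[str, ...] = BRCA_GENES,
    reference_label: str = "BRCA-like",
) -> list[GroupDefinition]:
    """Per-gene per-type groups, per-gene "any" groups and the reference group.

    The reference group is the union of patients with any event type in the
    reference genes.  Genes without events produce no groups.
    """
    if not gene_panel:
        raise ValidationError("gene panel must not be empty")
    by_gene_type: dict[tuple[str, str], set[str]] = {}
    by_gene: dict[str, set[str]] = {}
    for e in events:
        by_gene_type.setdefault((e.gene, e.event_type), set()).add(e.patient_id)
        by_gene.setdefault(e.gene, set()).add(e.patient_id)
    groups: list[GroupDefinition] = []
    for gene in gene_panel:
        for etype in EVENT_TYPES:
            members = by_gene_type.get((gene, etype))
            if members:
                groups.append(
                    GroupDefinition(
                        label=f"{gene}:{etype}",
                        gene=gene,
                        event_types=(etype,),
                        members=frozenset(members),
                    )
                )
        if gene in by_gene:
            groups.append(
                GroupDefinition(
                    label=f"{gene}:any",
                    gene=gene,
                    event_types=EVENT_TYPES,
                    members=frozenset(by_gene[gene]),
                )
            )
    reference_members: set[str] = set()
    for gene in reference_genes:
        reference_members |= by_gene.get(gene, set())
    groups.append(
        GroupDefinition(
            label=reference_label,
            gene="|".join(reference_genes),
            event_types=EVENT_TYPES,
            members=frozenset(reference_members),
        )
    )
    return groups


def exclude_overlap(
    g1: GroupDefinition, g2: GroupDefinition
) -> tuple[GroupDefinition, GroupDefinition]:
    """Remove patients present in both groups from both groups."""
    shared = g1.members & g2.members
    return (
        replace(g1, members=g1.members - shared),
        replace(g2, members=g2.members - shared),
    )
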