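"""Median-pairwise-distance permutation tests with Holm correction.

The homogeneity of a patient group in an embedded profile space is measured
by the median of all pairwise Euclidean distances among its members; the
similarity of two disjoint groups by the median over all cross pairs.  A
permutation null is built by repeatedly drawing random groups of the same
sizes (uniformly, without replacement) from the embedded cohort and
recomputing the statistic.  Small observed medians indicate unusually tight
or mutually similar groups, so the one-sided empirical p-value is the
proportion of null statistics less than or equal to the observed value,
floored at ``1/B`` (a ``(b+1)/(B+1)`` convention is available by flag).
Families of empirical p-values are adjusted by Holm's step-down method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from statsmodels.stats.multitest import multipletests

from .catalog import GroupDefinition, exclude_overlap
from .embedding import Embedding
from .errors import InvalidInputError, UndefinedStatisticError, ValidationError


def group_median_distance(coords: np.ndarray, members: np.ndarray) -> float:
    """Median over all C(n,2) pairwise distances among ``members`` rows."""
    idx = np.asarray(members, dtype=np.intp)
    if idx.size < 2:
        raise UndefinedStatisticError("median pairwise distance needs >= 2 members")
    return float(np.median(pdist(coords[idx])))


def cross_group_median_distance(
    coords: np.ndarray, g1: np.ndarray, g2: np.ndarray
) -> float:
    """Median over all |g1| x |g2| cross-pair distances (disjoint groups)."""
    a = np.asarray(g1, dtype=np.intp)
    b = np.asarray(g2, dtype=np.intp)
    if a.size == 0 or b.size == 0:
        raise UndefinedStatisticError("both groups must be non-empty")
    if np.intersect1d(a, b).size:
        raise ValidationError("groups must be disjoint; apply overlap exclusion first")
    return float(np.median(cdist(coords[a], coords[b])))


def union_median_distance(coords: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> float:
    """Median pairwise distance over the union of two groups (alternate reading)."""
    idx = np.union1d(np.asarray(g1, np.intp), np.asarray(g2, np.intp))
    return group_median_distance(coords, idx)


def _median_sqrt(d2: np.ndarray) -> np.ndarray:
    """Row-wise median of sqrt(d2) taking sqrt only at the central order stats."""
    m, npairs = d2.shape
    mid = npairs // 2
    if npairs % 2:
        part = np.partition(d2, mid, axis=1)
        return np.sqrt(part[:, mid])
    part = np.partition(d2, [mid - 1, mid], axis=1)
    return 0.5 * (np.sqrt(part[:, mid - 1]) + np.sqrt(part[:, mid]))


def _null_medians_batch(
    pts: np.ndarray, k1: int, k2: int | None
) -> np.ndarray:
    """Median statistics for a batch of drawn coordinate sets (B, k, 2)."""
    if k2 is None:
        dx = pts[:, :, None, 0] - pts[:, None, :, 0]
        dy = pts[:, :, None, 1] - pts[:, None, :, 1]
        dx *= dx
        dy *= dy
        dx += dy
        iu = np.triu_indices(pts.shape[1], 1)
        return _median_sqrt(dx[:, iu[0], iu[1]])
    a, b = pts[:, :k1, :], pts[:, k1:, :]
    dx = a[:, :, None, 0] - b[:, None, :, 0]
    dy = a[:, :, None, 1] - b[:, None, :, 1]
    dx *= dx
    dy *= dy
    dx += dy  # (B, k1, k2) squared cross distances
    return _median_sqrt(dx.reshape(dx.shape[0], -1))


def permutation_null(
    embedding: Embedding | np.ndarray,
    group_sizes: int | tuple[int, int],
    statistic: str = "within",
    B: int = 100_000,
    eligible: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    batch_size: int = 2_000,
) -> np.ndarray:
    """Draw ``B`` null median statistics by randomizing patient identifiers.

    Each iteration samples the required group sizes uniformly without
    replacement from ``eligible`` (all embedded samples by default); for the
    ``between`` statistic the two groups come from one disjoint draw.
    """
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding, float)
    if statistic not in ("within", "between"):
        raise InvalidInputError(f"unknown statistic {statistic!r}")
    if statistic == "within":
        if isinstance(group_sizes, tuple):
            (k1,) = group_sizes
        else:
            k1 = int(group_sizes)
        k2 = None
        ktot = k1
        if k1 < 2:
            raise UndefinedStatisticError("within statistic needs group size >= 2")
    else:
        k1, k2 = (int(s) for s in group_sizes)
        if k1 < 1 or k2 < 1:
            raise UndefinedStatisticError("between statistic needs non-empty groups")
        ktot = k1 + k2
    elig = (
        np.arange(coords.shape[0], dtype=np.intp)
        if eligible is None
        else np.asarray(eligible, dtype=np.intp)
    )
    n_elig = elig.size
    if ktot > n_elig:
        raise InvalidInputError(
            f"cannot draw {ktot} samples from {n_elig} eligible patients"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty(B, dtype=float)
    done = 0
    while done < B:
        m = min(batch_size, B - done)
        keys = rng.random((m, n_elig))
        # row-wise uniform random ordered subsets of the eligible pool: take
        # the ktot smallest keys per row (a uniform subset), then order them
        # by key, which is a uniform ordering conditional on the subset
        if ktot < n_elig:
            idx = np.argpartition(keys, ktot, axis=1)[:, :ktot]
        else:
            idx = np.broadcast_to(np.arange(n_elig), (m, n_elig)).copy()
        subkeys = np.take_along_axis(keys, idx, axis=1)
        order = np.take_along_axis(idx, np.argsort(subkeys, axis=1), axis=1)
        pts = coords[elig[order]]
        out[done : done + m] = _null_medians_batch(pts, k1, k2)
        done += m
    return out


def empirical_p(
    observed: float, null: np.ndarray, B: int | None = None, convention: str = "floor"
) -> tuple[float, int]:
    """One-sided empirical p (small statistic = significant) and exceedance count.

    ``convention='floor'`` reports ``max(b, 1)/B`` (the reporting floor is 1/B);
    ``'add-one'`` reports ``(b + 1)/(B + 1)``.
    """
    null = np.asarray(null, dtype=float)
    B = null.size if B is None else int(B)
    if B < 1 or null.size != B:
        raise InvalidInputError("null vector length must equal B >= 1")
    b = int(np.count_nonzero(null <= observed))
    if convention == "floor":
        p = max(b, 1) / B
    elif convention == "add-one":
        p = (b + 1) / (B + 1)
    else:
        raise InvalidInputError(f"unknown convention {convention!r}")
    return p, b


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment, returned in the original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass
class ComparisonResult:
    """One permutation comparison with its provenance."""

    label: str
    statistic: str  # 'within' or 'between'
    n1: int
    n2: int | None
    observed: float
    B: int
    b: int
    p_raw: float
    p_holm: float = float("nan")
    family: str = "default"
    seed: int = 0
    n_excluded_overlap: int = 0


def comparison_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tabular summary of a comparison suite."""
    return pd.DataFrame(
        {
            "comparison": [r.label for r in results],
            "statistic": [r.statistic for r in results],
            "n1": [r.n1 for r in results],
            "n2": [r.n2 if r.n2 is not None else "" for r in results],
            "observed_median": [r.observed for r in results],
            "B": [r.B for r in results],
            "b": [r.b for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_holm": [r.p_holm for r in results],
            "family": [r.family for r in results],
            "seed": [r.seed for r in results],
            "n_excluded_overlap": [r.n_excluded_overlap for r in results],
        }
    )


def run_comparison_suite(
    embedding: Embedding,
    groups: list[GroupDefinition],
    reference: GroupDefinition | None = None,
    B: int = 100_000,
    seed: int = 0,
    include_within: bool = False,
    family: str = "default",
    convention: str = "floor",
    union_statistic: bool = False,
) -> tuple[list[ComparisonResult], list[str]]:
    """Run between-vs-reference (and optionally within) tests for each group.

    Overlap with the reference group is excluded from both sides before the
    between statistic; groups emptied by the exclusion (or too small for the
    within statistic) are skipped and reported.  All raw p-values are
    adjusted together as one Holm family.
    """
    results: list[ComparisonResult] = []
    skipped: list[str] = []
    ss = np.random.SeedSequence(seed)
    coords = embedding.coords
    all_idx = np.arange(embedding.n, dtype=np.intp)
    for group in groups:
        child_rng = np.random.default_rng(ss.spawn(1)[0])
        if reference is not None:
            g_ex, ref_ex = exclude_overlap(group, reference)
            n_removed = len(group.members) - len(g_ex.members)
            if not g_ex.members or not ref_ex.members:
                skipped.append(f"{group.label}: empty after overlap exclusion")
            else:
                gi = embedding.index_of(sorted(g_ex.members))
                ri = embedding.index_of(sorted(ref_ex.members))
                if union_statistic:
                    obs = union_median_distance(coords, gi, ri)
                else:
                    obs = cross_group_median_distance(coords, gi, ri)
                null = permutation_null(
                    embedding,
                    (gi.size, ri.size),
                    statistic="between",
                    B=B,
                    eligible=all_idx,
                    seed=child_rng,
                )
                p, b = empirical_p(obs, null, B, convention=convention)
                results.append(
                    ComparisonResult(
                        label=f"{group.label} vs {reference.label}",
                        statistic="between",
                        n1=gi.size,
                        n2=ri.size,
                        observed=obs,
                        B=B,
                        b=b,
                        p_raw=p,
                        family=family,
                        seed=seed,
                        n_excluded_overlap=n_removed,
                    )
                )
        if include_within or reference is None:
            if len(group.members) < 2:
                skipped.append(f"{group.label}: fewer than 2 members for within test")
                continue
            gi = embedding.index_of(sorted(group.members))
            obs = group_median_distance(coords, gi)
            null = permutation_null(
                embedding,
                gi.size,
                statistic="within",
                B=B,
                eligible=all_idx,
                seed=child_rng,
            )
            p, b = empirical_p(obs, null, B, convention=convention)
            results.append(
                ComparisonResult(
                    label=f"{group.label} within",
                    statistic="within",
                    n1=gi.size,
                    n2=None,
                    observed=obs,
                    B=B,
                    b=b,
                    p_raw=p,
                    family=family,
                    seed=seed,
                )
            )
    if results:
        adj = holm_adjust(np.array([r.p_raw for r in results]))
        for r, a in zip(results, adj):
            r.p_holm = float(a)
    return results, skipped
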