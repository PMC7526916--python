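"""Pairwise Euclidean distances and classical (Torgerson) multidimensional scaling.

Classical MDS double-centers the squared-distance matrix,

    B = -1/2 * J D^2 J,      J = I - 11'/n,

takes the leading eigenpairs of ``B`` and scales each eigenvector by the
square root of its eigenvalue.  For configurations whose intrinsic dimension
is at most the target dimension the original distances are reproduced
exactly.  The eigenvector sign ambiguity is resolved canonically: each axis
is flipped so that the sample with the largest absolute coordinate on that
axis has a positive coordinate (ties broken by the smallest index), which
makes the embedding invariant under reordering of the input samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import InvalidInputError, ValidationError


def pairwise_euclidean(profiles: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix between the rows of ``profiles``."""
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InvalidInputError("need a 2-D array with at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValidationError("profiles contain missing or non-finite values")
    return squareform(pdist(X, metric="euclidean"))


@dataclass
class Embedding:
    """A low-dimensional configuration of samples with MDS diagnostics."""

    sample_ids: list[str]
    coords: np.ndarray  # (n, dims)
    eigenvalues: np.ndarray  # (dims,), descending
    captured_fraction: float  # of total positive eigenvalue mass

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise ValidationError(f"samples not embedded: {missing[:5]}")
        return np.asarray([lookup[s] for s in ids], dtype=np.intp)

    def to_frame(self) -> pd.DataFrame:
        dims = self.coords.shape[1]
        df = pd.DataFrame(
            self.coords,
            index=pd.Index(self.sample_ids, name="sample"),
            columns=[f"dim{i + 1}" for i in range(dims)],
        )
        return df


def classical_mds(
    distances: np.ndarray,
    dims: int = 2,
    sample_ids: Sequence[str] | None = None,
) -> Embedding:
    """Embed a symmetric distance matrix into ``dims`` dimensions.

    Negative eigenvalues among the leading ``dims`` produce zeroed
    coordinate axes with a warning.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    n = D.shape[0]
    if n < 2:
        raise InvalidInputError("need at least 2 samples")
    if dims < 1:
        raise InvalidInputError("dims must be positive")
    D2 = D**2
    # double centering without forming J explicitly
    row_mean = D2.mean(axis=1, keepdims=True)
    col_mean = D2.mean(axis=0, keepdims=True)
    B = -0.5 * (D2 - row_mean - col_mean + D2.mean())
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # numerical rank cutoff: eigenvalues within machine noise of zero are
    # treated as exactly zero (degenerate axes give zero coordinates)
    tol = np.finfo(float).eps * n * max(float(eigval.max()), 0.0)
    eigval = np.where(np.abs(eigval) <= tol, 0.0, eigval)
    top_val = eigval[:dims]
    top_vec = eigvec[:, :dims]
    coords = np.zeros((n, dims))
    for j in range(dims):
        if top_val[j] > 0:
            coords[:, j] = top_vec[:, j] * np.sqrt(top_val[j])
        elif top_val[j] < 0:
            warnings.warn(
                f"axis {j + 1}: negative eigenvalue {top_val[j]:.3g}; coordinates zeroed",
                stacklevel=2,
            )
    # canonical orientation: dominant sample on each axis points positive
    for j in range(dims):
        col = coords[:, j]
        if col.any():
            i_star = int(np.argmax(np.abs(col)))
            if col[i_star] < 0:
                coords[:, j] = -col
    positive_mass = float(eigval[eigval > 0].sum())
    captured = float(top_val[top_val > 0].sum()) / positive_mass if positive_mass > 0 else 0.0
    ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValidationError("sample_ids length does not match distance matrix")
    return Embedding(
        sample_ids=ids,
        coords=coords,
        eigenvalues=top_val.copy(),
        captured_fraction=captured,
    )


def embed_profiles(
    profiles: pd.DataFrame,
    dims: int = 2,
    log_transform: bool = False,
) -> Embedding:
    """Distance + classical MDS convenience over a (samples x features) frame.

    ``log_transform`` applies ``log2(x + 1)`` first (the expression-profile
    preprocessing default); signature-weight profiles are embedded raw.
    """
    X = profiles.to_numpy(dtype=float)
    if log_transform:
        if np.any(X < 0):
            raise ValidationError("log transform requires non-negative values")
        X = np.log2(X + 1.0)
    D = pairwise_euclidean(X)
    return classical_mds(D, dims=dims, sample_ids=[str(s) for s in profiles.index])
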