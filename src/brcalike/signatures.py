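"""Trinucleotide mutation spectra and non-negative signature-weight fitting.

A tumor's somatic single-nucleotide variants are summarized as counts over
the 96 canonical substitution-in-context channels: the six pyrimidine-strand
substitutions (C>A, C>G, C>T, T>A, T>C, T>G) crossed with the four possible
5' and 3' flanking bases.  Purine-reference variants are reverse-complemented
onto the pyrimidine strand before channel assignment.

A normalized spectrum ``f`` is decomposed over a row-stochastic signature
matrix ``S`` (K signatures x 96 channels) by non-negative least squares,

    minimize || f - w' S ||_2   subject to  w >= 0,

after which weights below a cutoff are zeroed and the survivors rescaled to
the pre-cutoff total mass.  The unexplained residual fraction ``1 - sum(w)``
(before the cutoff bookkeeping) is reported alongside the weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import DataIntegrityError, FitError, InvalidInputError

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

#: the 96 channels in canonical COSMIC order: substitution-major, then
#: 5' flanking base, then 3' flanking base, each in alphabetical order
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def channel_of(ref: str, alt: str, context: str) -> str:
    """Map a single-base substitution with its 3-mer context to a channel.

    ``context`` is the reference 3-mer centered on the variant site.  Purine
    references are folded onto the pyrimidine strand.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise InvalidInputError(f"not a single-base substitution: {ref}>{alt}")
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise InvalidInputError(f"non-ACGT allele: {ref}>{alt}")
    if len(context) != 3 or any(b not in _COMPLEMENT for b in context):
        raise InvalidInputError(f"bad trinucleotide context {context!r}")
    if context[1] != ref:
        raise DataIntegrityError(
            f"context middle base {context[1]} does not match ref allele {ref}"
        )
    if ref in ("G", "A"):
        context = reverse_complement(context)
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


@dataclass
class SpectrumResult:
    """A 96-channel spectrum plus a tally of skipped non-SNV records."""

    counts: np.ndarray  # shape (96,), int
    n_skipped: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_series(self, name: str | None = None) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS), name=name)


def build_mutation_spectrum(
    snvs: Iterable[tuple[str, int, str, str]],
    context_provider: Callable[[str, int], str],
) -> SpectrumResult:
    """Accumulate SNVs ``(chrom, position, ref, alt)`` into a 96-channel spectrum.

    ``context_provider(chrom, position)`` must return the reference 3-mer
    centered on the (1-based) position.  Records whose ref or alt is not a
    single base, or whose alleles are equal, are skipped and counted; a
    context whose middle base disagrees with the ref allele raises
    :class:`DataIntegrityError`.
    """
    counts = np.zeros(96, dtype=np.int64)
    skipped = 0
    for chrom, pos, ref, alt in snvs:
        if len(ref) != 1 or len(alt) != 1 or ref == alt or "-" in (ref, alt):
            skipped += 1
            continue
        context = context_provider(chrom, pos)
        counts[_CHANNEL_INDEX[channel_of(ref, alt, context)]] += 1
    return SpectrumResult(counts=counts, n_skipped=skipped)


@dataclass
class SignatureWeights:
    """Per-tumor non-negative signature weights with residual bookkeeping."""

    weights: np.ndarray  # shape (K,)
    residual: float  # 1 - sum(raw weights), before the cutoff step
    tumor_id: str | None = None

    def to_series(self, names: Sequence[str] | None = None) -> pd.Series:
        idx = list(names) if names is not None else list(range(len(self.weights)))
        s = pd.Series(self.weights, index=idx, name=self.tumor_id)
        s["residual"] = self.residual
        return s


def _validate_signature_matrix(signatures: np.ndarray) -> np.ndarray:
    S = np.asarray(signatures, dtype=float)
    if S.ndim != 2 or S.shape[1] != 96:
        raise InvalidInputError(f"signature matrix must be K x 96, got {S.shape}")
    if np.any(S < 0):
        raise InvalidInputError("signature matrix has negative entries")
    if not np.allclose(S.sum(axis=1), 1.0, atol=1e-6):
        raise InvalidInputError("signature rows must sum to 1")
    return S


def fit_signature_weights(
    spectrum: np.ndarray,
    signatures: np.ndarray,
    cutoff: float = 0.06,
    min_mutations: int = 10,
    tumor_id: str | None = None,
) -> SignatureWeights:
    """Fit non-negative signature weights to one spectrum.

    The spectrum is normalized to channel frequencies and decomposed by NNLS
    over the signature rows; weights below ``cutoff`` are zeroed and the
    surviving weights rescaled so their sum equals the pre-cutoff total.
    Tumors with fewer than ``min_mutations`` mutations are refused.
    """
    c = np.asarray(spectrum, dtype=float).ravel()
    if c.size != 96 or np.any(c < 0):
        raise InvalidInputError("spectrum must be 96 non-negative counts")
    S = _validate_signature_matrix(signatures)
    total = c.sum()
    if total < min_mutations:
        raise FitError(
            f"spectrum has {total:.0f} mutations, fewer than min_mutations={min_mutations}"
        )
    f = c / total
    w_raw, _ = nnls(S.T, f)
    residual = 1.0 - float(w_raw.sum())
    mass = float(w_raw.sum())
    w = np.where(w_raw >= cutoff, w_raw, 0.0)
    kept = float(w.sum())
    if kept > 0 and kept < mass:
        w = w * (mass / kept)
    return SignatureWeights(weights=w, residual=residual, tumor_id=tumor_id)


def fit_cohort_weights(
    spectra: pd.DataFrame,
    signatures: pd.DataFrame,
    cutoff: float = 0.06,
    min_mutations: int = 10,
) -> tuple[pd.DataFrame, list[str]]:
    """Fit weights for every tumor in a (tumors x 96) spectra table.

    Returns a (tumors x K+1) frame with one column per signature plus a
    ``residual`` column, and the list of tumors skipped for having too few
    mutations.
    """
    if list(spectra.columns) != list(CHANNELS):
        spectra = spectra.loc[:, list(CHANNELS)]
    S = _validate_signature_matrix(signatures.to_numpy())
    rows, skipped = [], []
    for tumor, row in spectra.iterrows():
        try:
            fit = fit_signature_weights(
                row.to_numpy(), S, cutoff=cutoff, min_mutations=min_mutations,
                tumor_id=str(tumor),
            )
        except FitError:
            skipped.append(str(tumor))
            continue
        rows.append(fit.to_series(names=list(signatures.index)))
    out = pd.DataFrame(rows)
    out.index.name = spectra.index.name or "tumor"
    return out, skipped
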