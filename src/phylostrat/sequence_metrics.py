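"""Per-sequence protein property metrics.

Implements the hydrophobicity +/-1 encoding, the normalized index of
dispersion psi (hydrophobic clustering), fractional amino-acid composition,
mean intrinsic-disorder aggregation with optional sub-ranges, the
cysteine-excision transform, and a simple smoothing-based disorder surrogate
for use when no external per-residue predictor output is available.

The clustering statistic compares the variance of +/-1 hydrophobicity block
sums (blocks of ``s`` consecutive residues, default 6) against its
expectation under random arrangement of the same composition, so that
psi = 1 for randomly arranged sequences, psi > 1 for sequences whose
hydrophobic residues clump together, and psi < 1 for over-dispersed ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "HYDROPHOBIC",
    "STANDARD_AA",
    "HydrophobicityEncoding",
    "ClusteringResult",
    "CompositionVector",
    "DisorderProfile",
    "hydrophobicity_encode",
    "clustering_index",
    "psi_from_signs",
    "composition",
    "mean_disorder",
    "excise_cysteine",
    "surrogate_disorder",
]

#: The 20 standard amino acids, alphabetical one-letter order.
STANDARD_AA = tuple("ACDEFGHIKLMNPQRSTVWY")

#: The six most hydrophobic residues, scored +1.
HYDROPHOBIC = frozenset("LIVFMW")

# Ambiguity / rare codes: B ~ D or N (-1), J ~ I or L (+1), Z ~ E or Q (-1),
# U selenocysteine (-1), O pyrrolysine (-1).  X (unknown) is scored -1 for
# clustering but excluded from composition.
_SCORE: dict[str, int] = {aa: (1 if aa in HYDROPHOBIC else -1) for aa in STANDARD_AA}
_SCORE.update({"B": -1, "J": 1, "Z": -1, "U": -1, "O": -1, "X": -1})


@dataclass(frozen=True)
class HydrophobicityEncoding:
    """A sequence together with its +/-1 hydrophobicity scores."""

    residues: str
    scores: np.ndarray  # int8, values in {+1, -1}

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.residues)


@dataclass(frozen=True)
class ClusteringResult:
    """Normalized index of dispersion for one sequence.

    ``psi`` is the mean of the per-frame indices ``per_frame_psi``; it is
    ``None`` when the statistic is undefined (sequence too short, or some
    frame has all residues of one sign so the normalizer vanishes).
    """

    psi: float | None
    per_frame_psi: tuple[float, ...]
    n_frames: int
    block_size: int
    truncated_length: int
    per_frame_totals: tuple[int, ...]
    per_frame_normalizers: tuple[float, ...]
    defined: bool
    reason: str | None = None


@dataclass(frozen=True)
class CompositionVector:
    """Fractions of the 20 standard amino acids (sum to 1)."""

    fractions: Mapping[str, float]
    length_used: int

    def as_array(self) -> np.ndarray:
        return np.array([self.fractions[aa] for aa in STANDARD_AA])


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue disorder scores in [0, 1] for one sequence."""

    scores: np.ndarray
    source: str = "external"


def hydrophobicity_encode(sequence: str) -> HydrophobicityEncoding:
    """Encode a protein sequence as +/-1 hydrophobicity scores.

    L, I, V, F, M, W (and J) score +1; all other standard residues and the
    ambiguity/rare codes B, Z, U, O, X score -1.

    Raises
    ------
    ValueError
        If the sequence is empty or contains a letter outside the 20
        standard codes plus B, J, Z, U, O, X (position reported 1-based).
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    scores = np.empty(len(seq), dtype=np.int8)
    for i, aa in enumerate(seq):
        try:
            scores[i] = _SCORE[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}") from None
    return HydrophobicityEncoding(residues=seq, scores=scores)


def psi_from_signs(scores: np.ndarray, block_size: int = 6) -> ClusteringResult:
    """Clustering index from a +/-1 score vector (see :func:`clustering_index`)."""
    s = int(block_size)
    scores = np.asarray(scores, dtype=np.int64)
    L = scores.size
    if s < 1:
        raise ValueError("block_size must be >= 1")
    if L < 2 * s:
        return ClusteringResult(
            psi=None, per_frame_psi=(), n_frames=0, block_size=s,
            truncated_length=0, per_frame_totals=(), per_frame_normalizers=(),
            defined=False, reason="too short",
        )
    N = s * (L // s)
    p = max(1, L % s)
    psis: list[float] = []
    totals: list[int] = []
    normalizers: list[float] = []
    defined = True
    reason = None
    for f in range(p):
        window = scores[f : f + N]
        sigma = window.reshape(N // s, s).sum(axis=1)
        M = int(sigma.sum())
        totals.append(M)
        if abs(M) == N:
            # All residues share one sign: the random-arrangement variance
            # is zero and the index is undefined.
            defined = False
            reason = "single-sign frame"
            normalizers.append(0.0)
            continue
        K = s * (N * N - M * M) / (N * N - N) * (1.0 - s / N)
        normalizers.append(K)
        dev = sigma - s * M / N
        psis.append(float((s / N) * np.sum(dev * dev) / K))
    if not defined:
        return ClusteringResult(
            psi=None, per_frame_psi=tuple(psis), n_frames=p, block_size=s,
            truncated_length=N, per_frame_totals=tuple(totals),
            per_frame_normalizers=tuple(normalizers), defined=False, reason=reason,
        )
    return ClusteringResult(
        psi=float(np.mean(psis)), per_frame_psi=tuple(psis), n_frames=p,
        block_size=s, truncated_length=N, per_frame_totals=tuple(totals),
        per_frame_normalizers=tuple(normalizers), defined=True,
    )


def clustering_index(sequence: str, block_size: int = 6) -> ClusteringResult:
    """Normalized index of dispersion of hydrophobic residues.

    The sequence is encoded +/-1, then for each frame ``f`` (start offsets
    ``0..p-1`` with ``p = max(1, L mod s)``) the first ``N = s*floor(L/s)``
    residues are split into blocks of ``s``; the squared deviations of the
    block sums from their mean are normalized by the without-replacement
    sampling variance ``K = s*(N^2 - M^2)/(N^2 - N)*(1 - s/N)`` so that a
    random arrangement has expectation 1.  Frames are averaged.

    Sequences shorter than ``2*s`` or with any single-sign frame yield an
    undefined result (``defined=False``) rather than an arbitrary number.
    """
    enc = hydrophobicity_encode(sequence)
    return psi_from_signs(enc.scores, block_size=block_size)


def composition(sequence: str) -> CompositionVector:
    """Fractional amino-acid composition over the 20 standard residues.

    Non-standard letters (B, J, Z, U, O, X) are excluded from both the
    numerator and the denominator.

    Raises
    ------
    ValueError
        If the sequence is empty or contains no standard residue.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    counts = {aa: 0 for aa in STANDARD_AA}
    n = 0
    for aa in seq:
        if aa in counts:
            counts[aa] += 1
            n += 1
        elif aa not in _SCORE:
            raise ValueError(f"unknown residue {aa!r}")
    if n == 0:
        raise ValueError("sequence has no standard residues; composition undefined")
    return CompositionVector(
        fractions={aa: counts[aa] / n for aa in STANDARD_AA}, length_used=n
    )


def mean_disorder(
    profile: DisorderProfile, residue_range: tuple[int, int] | None = None
) -> float:
    """Mean per-residue disorder, optionally over a 1-based inclusive range."""
    scores = np.asarray(profile.scores, dtype=float)
    if residue_range is None:
        sub = scores
    else:
        start, end = residue_range
        if not (1 <= start <= end <= scores.size):
            raise ValueError(
                f"range [{start}, {end}] outside profile of length {scores.size}"
            )
        sub = scores[start - 1 : end]
    if sub.size == 0:
        raise ValueError("empty range")
    return float(sub.mean())


def excise_cysteine(sequence: str) -> tuple[str, bool]:
    """Remove all cysteine residues, preserving order.

    Returns ``(excised_sequence, is_empty)``; the flag marks the degenerate
    all-cysteine case.
    """
    out = sequence.upper().replace("C", "")
    return out, len(out) == 0


def surrogate_disorder(
    sequence: str,
    propensity_table: Mapping[str, float] | Sequence[float],
    window: int = 7,
) -> DisorderProfile:
    """Smoothing-based per-residue disorder profile.

    Each residue's score is the centered moving average (over ``window``
    positions, shrinking at the edges) of per-residue disorder propensities,
    supplied either as a per-letter table or as a precomputed per-position
    vector.  This is a deliberately simple stand-in profile generator for
    pipelines that do not ship an external predictor's output.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if isinstance(propensity_table, Mapping):
        vals = np.array([propensity_table[aa] for aa in sequence.upper()], dtype=float)
    else:
        vals = np.asarray(propensity_table, dtype=float)
        if vals.size != len(sequence):
            raise ValueError("propensity vector length does not match sequence")
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("propensities must lie in [0, 1]")
    half = window // 2
    n = vals.size
    cum = np.concatenate([[0.0], np.cumsum(vals)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    scores = (cum[hi + 1] - cum[lo]) / (hi - lo + 1)
    return DisorderProfile(scores=scores, source="surrogate")
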