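"""Transmembrane status from externally supplied helix predictions.

The pipeline never runs a helix predictor itself; it consumes TMHMM-style
interval tables.  A gene is transmembrane when the union of its predicted
helices covers strictly more than 18 residues.  A pfam instance is
transmembrane when some single helix overlaps it by at least half the pfam
length, or the pfam overlaps at least half of that helix.  Both 50% tests
use exact integer arithmetic on residue counts so the boundary is unambiguous.
Downstream analyses keep the TM and non-TM partitions separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = ["HelixAnnotation", "gene_tm_status", "pfam_tm_status", "GENE_TM_THRESHOLD"]

#: A gene is TM iff its merged helices cover strictly more residues than this.
GENE_TM_THRESHOLD = 18


@dataclass(frozen=True)
class HelixAnnotation:
    """Predicted transmembrane helices for one gene.

    Intervals are 1-based inclusive residue ranges; they may overlap and are
    merged before residue counting.  ``gene_length`` (optional) enables
    bounds checking.
    """

    gene_id: str
    intervals: tuple[tuple[int, int], ...]
    gene_length: int | None = None

    def __post_init__(self):
        for start, end in self.intervals:
            if start < 1 or end < start:
                raise ValueError(
                    f"gene {self.gene_id}: invalid helix interval [{start}, {end}]"
                )
            if self.gene_length is not None and end > self.gene_length:
                raise ValueError(
                    f"gene {self.gene_id}: helix [{start}, {end}] exceeds "
                    f"gene length {self.gene_length}"
                )

    def merged(self) -> list[tuple[int, int]]:
        if not self.intervals:
            return []
        ivs = sorted(self.intervals)
        out = [ivs[0]]
        for start, end in ivs[1:]:
            if start <= out[-1][1] + 1:
                out[-1] = (out[-1][0], max(out[-1][1], end))
            else:
                out.append((start, end))
        return out

    def covered_residues(self) -> int:
        return sum(end - start + 1 for start, end in self.merged())


def gene_tm_status(helices: HelixAnnotation) -> bool:
    """True iff merged helices cover more than 18 residues (strictly)."""
    return helices.covered_residues() > GENE_TM_THRESHOLD


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def pfam_tm_status(
    pfam_interval: tuple[int, int], helices: HelixAnnotation
) -> bool:
    """True iff some helix overlaps >= 50% of the pfam, or vice versa.

    Evaluated per helix (not pooled across helices), with the ratio test done
    as ``2 * overlap >= length`` in integers.
    """
    start, end = pfam_interval
    if start < 1 or end < start:
        raise ValueError(f"invalid pfam interval [{start}, {end}]")
    pfam_len = end - start + 1
    # predicted helices are evaluated one at a time, as annotated
    for helix in helices.intervals:
        ov = _overlap(pfam_interval, helix)
        if ov == 0:
            continue
        helix_len = helix[1] - helix[0] + 1
        if 2 * ov >= pfam_len or 2 * ov >= helix_len:
            return True
    return False
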