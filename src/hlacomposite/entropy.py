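"""Positional sequence diversity of HLA alignments via Shannon entropy.

Each alignment column is scored with 2-bit Shannon entropy over the
nucleotide frequencies of A, C, G, T. Gap characters are excluded — the
published HLA reference alleles often cover only partial exon sequence,
so a gap is missing data, not a fifth symbol. N and other IUPAC
ambiguity codes are likewise excluded. A rolling mean (default 100 bp)
smooths the per-column profile for plotting against gene coordinates;
window edges use shrunken partial windows so the profile keeps the
alignment's length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["EntropyProfile", "column_entropy", "profile_alignment"]

_NUCLEOTIDES = "ACGT"


@dataclass(frozen=True)
class EntropyProfile:
    """Per-column and rolling-mean entropy (bits) for one alignment."""

    locus: str
    per_position: np.ndarray
    rolling: np.ndarray
    window: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: 1-based position, raw and rolling entropy."""
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.per_position) + 1),
                "entropy": self.per_position,
                "rolling_entropy": self.rolling,
            }
        )


def column_entropy(column: Iterable[str]) -> float:
    """Shannon entropy (bits) of one alignment column.

    Only A/C/G/T count toward the frequencies; gaps, N, and other
    ambiguity codes are dropped. A column with no informative characters
    has no defined entropy and returns NaN so callers can flag it rather
    than mistake it for a conserved (0-bit) position.
    """
    counts = np.zeros(4)
    for ch in column:
        idx = _NUCLEOTIDES.find(ch.upper())
        if idx >= 0:
            counts[idx] += 1
    total = counts.sum()
    if total == 0:
        return float("nan")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _sequences(msa) -> list[str]:
    """Accept a Biopython alignment, SeqRecords, or plain strings."""
    seqs = []
    for rec in msa:
        seq = getattr(rec, "seq", rec)
        seqs.append(str(seq))
    return seqs


def profile_alignment(
    msa, window: int = 100, *, locus: str = "", center: bool = True
) -> EntropyProfile:
    """Entropy profile of a multiple sequence alignment.

    Parameters
    ----------
    msa
        Aligned sequences: a ``Bio.Align.MultipleSeqAlignment``, an
        iterable of ``SeqRecord``, or plain strings. At least two
        sequences of equal length are required.
    window
        Rolling-mean width in alignment positions. ``window=1`` returns
        the raw profile. The mean is centered by default (configurable),
        with partial windows at the edges; all-gap (NaN) columns are
        skipped within each window.
    """
    seqs = _sequences(msa)
    if len(seqs) < 2:
        raise ValueError("alignment must contain at least two sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    if window < 1:
        raise ValueError("window must be >= 1")
    ncol = lengths.pop()
    per_position = np.array(
        [column_entropy(s[i] for s in seqs) for i in range(ncol)]
    )
    rolling = (
        pd.Series(per_position)
        .rolling(window, center=center, min_periods=1)
        .mean()
        .to_numpy()
    )
    return EntropyProfile(
        locus=locus, per_position=per_position, rolling=rolling, window=window
    )
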