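"""Column trimming: gappyout-style removal of poorly aligned columns and the
complete-deletion matrix used for tree building.

``trim_gappyout`` offers two modes.  ``fixed`` drops every column whose gap
fraction exceeds a threshold (default 0.2) — simple and reproducible.
``auto`` selects the cut from the data: the distinct per-column gap scores
(1 − gap fraction) are sorted ascending, paired with the fraction of columns
that a cut at each score would remove, and the cut is placed at the largest
increase between consecutive slopes of that curve (the "elbow").  Columns
whose gap score falls strictly below the cut are removed.  Ambiguity codes
are not gaps and never count against a column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dielscan.io import Alignment, GAP


class TrimError(ValueError):
    """Raised when a trimming rule would remove every column."""


@dataclass(frozen=True)
class TrimResult:
    """Trimmed alignment plus the map back to original column coordinates."""

    trimmed: Alignment
    kept_columns: tuple[int, ...]
    gap_fraction: tuple[float, ...]

    def row_ungapped_lengths(self) -> dict[str, int]:
        """Per-sequence length after trimming, gaps excluded."""
        return {r.id: len(r.ungapped) for r in self.trimmed.records}

    def write_column_map(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("trimmed_index\toriginal_index\n")
            for t, o in enumerate(self.kept_columns):
                fh.write(f"{t}\t{o}\n")


def column_gap_fraction(alignment: Alignment) -> np.ndarray:
    """Fraction of rows that are '-' at each column (ambiguity codes are not gaps)."""
    arr = alignment.to_array()
    return (arr == GAP).mean(axis=0)


def _auto_cut_score(gap_fraction: np.ndarray) -> float:
    """Gap score below which columns are removed, by the slope-elbow rule."""
    scores = 1.0 - np.asarray(gap_fraction, dtype=float)
    distinct = np.unique(scores)  # ascending
    k = len(distinct)
    if k == 1:
        return distinct[0]  # removal is strict-below: identity
    # x: fraction of columns removed by cutting at this score; y: the score
    x = np.array([(scores < s).mean() for s in distinct])
    y = distinct
    slopes = np.diff(y) / np.diff(x)
    if k == 2:
        return distinct[1]
    jumps = np.diff(slopes)  # slope increase between consecutive segments
    cut_idx = int(np.argmax(jumps)) + 1  # first maximum wins
    return distinct[cut_idx]


def trim_gappyout(alignment: Alignment, mode: str = "fixed", g_max: float = 0.2) -> TrimResult:
    """Remove gap-rich columns.

    Parameters
    ----------
    mode : {'fixed', 'auto'}
        ``fixed`` removes columns with gap fraction > ``g_max``; ``auto``
        derives the cut from the gap-score curve (see module docstring).
    """
    if mode not in ("fixed", "auto"):
        raise ValueError(f"unknown trim mode {mode!r}")
    gf = column_gap_fraction(alignment)
    if mode == "fixed":
        keep = gf <= g_max
    else:
        cut = _auto_cut_score(gf)
        keep = (1.0 - gf) >= cut
    kept = tuple(int(i) for i in np.flatnonzero(keep))
    if not kept:
        raise TrimError(f"trim_gappyout(mode={mode!r}, g_max={g_max}) removed every column")
    return TrimResult(
        trimmed=alignment.take_columns(kept),
        kept_columns=kept,
        gap_fraction=tuple(float(v) for v in gf),
    )


def complete_deletion(alignment: Alignment) -> tuple[Alignment, tuple[int, ...]]:
    """Keep only columns where every row is an unambiguous A/C/G/T base.

    This is the site filter applied before distance and likelihood
    computations: any gap, ambiguity code or missing character disqualifies
    the whole column.
    """
    arr = alignment.to_array()
    ok = np.isin(arr, list("ACGT")).all(axis=0)
    kept = tuple(int(i) for i in np.flatnonzero(ok))
    if not kept:
        raise TrimError("complete deletion removed every column")
    return alignment.take_columns(kept), kept
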