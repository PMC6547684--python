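"""Position-wise residue enrichment between positive and negative windows.

For every window offset and amino acid, the count of that residue at
that offset in the foreground (positive) fragments is tested against the
background (negative) frequency with a two-sided exact binomial test.
Pad positions are excluded from both numerator and denominator.  Cells
with p below the significance threshold are flagged over- or
under-represented according to the sign of the log-odds; this is a
two-sample sequence-logo style analysis, reported as a table rather
than a graphic.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import AMINO_ACIDS, PAD, PeptideFragment

__all__ = ["position_enrichment", "render_text_logo"]

#: Pseudocount added per residue when forming background frequencies, so
#: that unseen background residues do not yield p = 0 exactly.
_PSEUDO = 0.5


def _position_counts(fragments: Sequence[PeptideFragment]) -> tuple[np.ndarray, np.ndarray]:
    """(width x 20) residue counts and per-position non-pad totals."""
    width = fragments[0].width
    counts = np.zeros((width, 20), dtype=int)
    totals = np.zeros(width, dtype=int)
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for f in fragments:
        if f.width != width:
            raise ValueError("fragments have mismatched window widths")
        for i, c in enumerate(f.window):
            if c != PAD:
                counts[i, aa_index[c]] += 1
                totals[i] += 1
    return counts, totals


def position_enrichment(
    positives: Sequence[PeptideFragment],
    negatives: Sequence[PeptideFragment],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-(offset, residue) enrichment table.

    Columns: offset, residue, fg_count, fg_total, bg_count, bg_total,
    log_odds (base 2, pseudocounted), p_value (two-sided exact
    binomial), direction in {over, under, none}.
    """
    if not positives or not negatives:
        raise ValueError("both fragment sets must be non-empty")
    if positives[0].width != negatives[0].width:
        raise ValueError(
            f"window width mismatch: {positives[0].width} vs {negatives[0].width}"
        )
    fg_counts, fg_totals = _position_counts(positives)
    bg_counts, bg_totals = _position_counts(negatives)
    width = positives[0].width
    hw = positives[0].half_width
    rows = []
    for i in range(width):
        offset = i - hw
        for j, aa in enumerate(AMINO_ACIDS):
            fg, fg_n = int(fg_counts[i, j]), int(fg_totals[i])
            bg, bg_n = int(bg_counts[i, j]), int(bg_totals[i])
            p_bg = (bg + _PSEUDO) / (bg_n + 20 * _PSEUDO)
            if fg_n > 0:
                p_value = float(
                    stats.binomtest(fg, fg_n, p_bg, alternative="two-sided").pvalue
                )
                p_fg = (fg + _PSEUDO) / (fg_n + 20 * _PSEUDO)
                log_odds = float(np.log2(p_fg / p_bg))
            else:
                p_value, log_odds = 1.0, 0.0
            if p_value < alpha and log_odds > 0:
                direction = "over"
            elif p_value < alpha and log_odds < 0:
                direction = "under"
            else:
                direction = "none"
            rows.append((offset, aa, fg, fg_n, bg, bg_n, log_odds, p_value, direction))
    return pd.DataFrame(
        rows,
        columns=[
            "offset",
            "residue",
            "fg_count",
            "fg_total",
            "bg_count",
            "bg_total",
            "log_odds",
            "p_value",
            "direction",
        ],
    )


def render_text_logo(table: pd.DataFrame, max_residues: int = 3) -> str:
    """Compact text rendering: significant residues per offset."""
    lines = []
    for offset, group in table.groupby("offset"):
        over = group[group["direction"] == "over"].nsmallest(max_residues, "p_value")
        under = group[group["direction"] == "under"].nsmallest(max_residues, "p_value")
        over_s = ",".join(over["residue"]) or "-"
        under_s = ",".join(under["residue"]) or "-"
        lines.append(f"{offset:+3d}  over: {over_s:<12} under: {under_s}")
    return "\n".join(lines)
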