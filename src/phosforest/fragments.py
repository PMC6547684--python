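"""Peptide-window extraction around candidate phosphosites.

A candidate site is a serine or threonine residue in a protein sequence.
Each site is represented as a fixed-width window of ``2*half_width + 1``
residues centered on the S/T, padded with ``'X'`` where the window runs
past a protein terminus.  Positions are 1-based throughout.

Non-standard residue letters (B, J, O, U, Z and literal X) are mapped to
the pad symbol ``'X'`` on input and carry no information in any encoder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical 20 amino-acid alphabet (PSI-BLAST column order is defined in
#: :mod:`phosforest.profiles`; here alphabetical order is used for encoders).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Pad / unknown-residue symbol.
PAD = "X"

_NONSTANDARD = set("BJOUZX")


def sanitize_sequence(sequence: str) -> str:
    """Uppercase a protein sequence and map non-standard letters to 'X'."""
    seq = sequence.upper()
    return "".join(PAD if c in _NONSTANDARD or c not in AMINO_ACIDS else c for c in seq)


@dataclass(frozen=True)
class PeptideFragment:
    """A fixed-width peptide window centered on an S/T residue.

    Attributes
    ----------
    protein_id : str
        Identifier of the source protein.
    center_pos : int
        1-based position of the central residue in the source protein.
    residue : str
        The central residue, ``'S'`` or ``'T'``.
    window : str
        Window string of length ``2 * half_width + 1`` over the 20
        amino-acid letters plus the pad symbol ``'X'``.
    label : int or None
        ``+1`` (phosphosite), ``-1`` (non-phosphosite) or ``None`` when
        the fragment is an unlabeled prediction candidate.
    half_width : int
        Number of residues on each side of the center.
    """

    protein_id: str
    center_pos: int
    residue: str
    window: str
    label: int | None
    half_width: int

    def __post_init__(self) -> None:
        w = 2 * self.half_width + 1
        if len(self.window) != w:
            raise ValueError(
                f"window length {len(self.window)} != 2*{self.half_width}+1"
            )
        if self.residue not in ("S", "T"):
            raise ValueError(f"central residue must be S or T, got {self.residue!r}")
        if self.window[self.half_width] != self.residue:
            raise ValueError("window center does not match the declared residue")
        if self.label not in (1, -1, None):
            raise ValueError(f"label must be +1, -1 or None, got {self.label!r}")
        # pads may only form contiguous runs at the two ends
        core = self.window.strip(PAD)
        if PAD in core:
            raise ValueError("pad symbols inside the window interior")

    @property
    def width(self) -> int:
        return 2 * self.half_width + 1

    def offsets(self) -> range:
        """Window offsets relative to the center, -half_width..+half_width."""
        return range(-self.half_width, self.half_width + 1)

    def is_pad(self, i: int) -> bool:
        """True when window index ``i`` (0-based) is a pad position."""
        return self.window[i] == PAD


def extract_window(
    sequence: str,
    pos: int,
    half_width: int,
    *,
    protein_id: str = "",
    label: int | None = None,
) -> PeptideFragment:
    """Extract the ``2*half_width+1``-residue window centered at ``pos``.

    ``pos`` is 1-based and must hold an S or T.  Window positions that
    fall outside the protein are filled with the pad symbol ``'X'``.
    """
    if not 1 <= pos <= len(sequence):
        raise IndexError(f"position {pos} out of range 1..{len(sequence)}")
    seq = sanitize_sequence(sequence)
    center = seq[pos - 1]
    if center not in ("S", "T"):
        raise ValueError(
            f"residue at position {pos} is {sequence[pos - 1]!r}, not S or T"
        )
    lo = pos - 1 - half_width
    hi = pos - 1 + half_width + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(seq))
    window = PAD * left_pad + seq[max(lo, 0) : min(hi, len(seq))] + PAD * right_pad
    return PeptideFragment(
        protein_id=protein_id,
        center_pos=pos,
        residue=center,
        window=window,
        label=label,
        half_width=half_width,
    )


def scan_st_sites(sequence: str) -> list[int]:
    """Return every 1-based position of an S or T residue, ascending."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    return [i + 1 for i, c in enumerate(seq) if c in ("S", "T")]


def balance_negatives(
    positives: Sequence[PeptideFragment],
    negatives: Sequence[PeptideFragment],
    ratio: float = 2.0,
    seed: int = 0,
) -> list[PeptideFragment]:
    """Subsample negatives to ``floor(ratio * n_pos)`` and append to positives.

    Sampling is uniform without replacement and deterministic under
    ``seed``.  If fewer negatives are available than requested, all are
    kept and a warning is logged.
    """
    if len(positives) == 0:
        raise ValueError("positive set is empty")
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    n_wanted = int(np.floor(ratio * len(positives)))
    rng = np.random.default_rng(seed)
    if n_wanted >= len(negatives):
        if n_wanted > len(negatives):
            logger.warning(
                "requested %d negatives but only %d available; keeping all",
                n_wanted,
                len(negatives),
            )
        chosen = list(negatives)
    else:
        idx = rng.choice(len(negatives), size=n_wanted, replace=False)
        chosen = [negatives[i] for i in sorted(idx)]
    return list(positives) + chosen


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly line-wrapped, multi-record) FASTA into {id: sequence}."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


SITE_COLUMNS = ["protein_id", "position", "label"]


def read_site_table(path) -> pd.DataFrame:
    """Read a 3-column site TSV: protein_id, 1-based position, label (+1/-1)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site table {path} missing columns {sorted(missing)}")
    df = df[SITE_COLUMNS].copy()
    df["position"] = df["position"].astype(int)
    df["label"] = df["label"].astype(int)
    bad = ~df["label"].isin([1, -1])
    if bad.any():
        raise ValueError(f"site table labels must be +1/-1; bad rows: {bad.sum()}")
    return df


def write_site_table(df: pd.DataFrame, path) -> None:
    df[SITE_COLUMNS].to_csv(path, sep="\t", index=False)


def extract_fragments(
    sequences: Mapping[str, str],
    sites: pd.DataFrame,
    half_width: int = 10,
) -> list[PeptideFragment]:
    """Extract a labeled fragment per site-table row.

    Raises if a row names an unknown protein, an out-of-range position or
    a non-S/T residue.
    """
    out = []
    for row in sites.itertuples(index=False):
        if row.protein_id not in sequences:
            raise KeyError(f"protein {row.protein_id!r} not found in FASTA input")
        out.append(
            extract_window(
                sequences[row.protein_id],
                int(row.position),
                half_width,
                protein_id=row.protein_id,
                label=int(row.label),
            )
        )
    return out


FRAGMENT_COLUMNS = ["protein_id", "position", "residue", "window", "label"]


def fragments_to_frame(fragments: Iterable[PeptideFragment]) -> pd.DataFrame:
    rows = [
        (f.protein_id, f.center_pos, f.residue, f.window, 0 if f.label is None else f.label)
        for f in fragments
    ]
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def write_fragments(fragments: Iterable[PeptideFragment], path) -> None:
    fragments_to_frame(fragments).to_csv(path, sep="\t", index=False)


def read_fragments(path) -> list[PeptideFragment]:
    df = pd.read_csv(path, sep="\t")
    frags = []
    for row in df.itertuples(index=False):
        window = str(row.window)
        frags.append(
            PeptideFragment(
                protein_id=str(row.protein_id),
                center_pos=int(row.position),
                residue=str(row.residue),
                window=window,
                label=None if int(row.label) == 0 else int(row.label),
                half_width=len(window) // 2,
            )
        )
    return frags
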