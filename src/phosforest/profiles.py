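"""Per-protein PSSM and predicted-structure profiles.

PSSMs are read from the PSI-BLAST ASCII dialect (``-out_ascii_pssm``):
a couple of header lines, then one row per residue holding the residue
index, the residue letter, 20 log-odds integers, 20 weighted-percentage
columns and two trailing floats.  Only the log-odds block is kept.

Structural profiles carry, per residue, solvent accessible surface area,
the four backbone torsion angles (phi, psi, theta, tau) and three
secondary-structure probabilities (helix, strand, coil), as emitted by
per-residue structure predictors; they are stored as 9-column TSV
(``idx ASA phi psi theta tau pH pE pC``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: PSI-BLAST PSSM column order.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

STRUCT_COLUMNS = ["ASA", "phi", "psi", "theta", "tau", "pH", "pE", "pC"]


@dataclass
class PSSMProfile:
    """Log-odds substitution profile over a full protein.

    ``scores`` has shape (L, 20) with columns in PSI-BLAST order
    ``A R N D C Q E G H I L K M F P S T W Y V``.
    """

    protein_id: str
    scores: np.ndarray
    residues: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(f"PSSM scores must be (L, 20), got {self.scores.shape}")
        if self.residues and len(self.residues) != len(self.scores):
            raise ValueError("residue string length does not match row count")

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass
class StructProfile:
    """Per-residue structural profile: (L, 8) array, columns STRUCT_COLUMNS."""

    protein_id: str
    rows: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[1] != 8:
            raise ValueError(f"struct profile must be (L, 8), got {self.rows.shape}")
        probs = self.rows[:, 5:8]
        if ((probs < 0) | (probs > 1)).any():
            bad = int(np.argmax(((probs < 0) | (probs > 1)).any(axis=1)))
            raise ValueError(
                f"secondary-structure probability outside [0,1] at residue {bad + 1}"
            )

    def __len__(self) -> int:
        return self.rows.shape[0]


class ProfileParseError(ValueError):
    """Malformed profile file; carries the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def read_pssm(path) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM; keeps only the 20 log-odds columns."""
    path = Path(path)
    scores: list[list[float]] = []
    residues: list[str] = []
    expected_idx = 1
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            continue
        # data rows start with the running residue index
        if not tokens[0].isdigit():
            continue
        if int(tokens[0]) != expected_idx:
            continue  # e.g. stray numeric header; data rows are sequential
        if len(tokens) < 22:
            raise ProfileParseError(
                path, lineno, f"expected >=22 tokens on a PSSM row, got {len(tokens)}"
            )
        residue = tokens[1]
        if len(residue) != 1 or not residue.isalpha():
            raise ProfileParseError(path, lineno, f"bad residue field {residue!r}")
        try:
            row = [float(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise ProfileParseError(path, lineno, f"non-numeric log-odds: {exc}")
        scores.append(row)
        residues.append(residue.upper())
        expected_idx += 1
    if not scores:
        raise ProfileParseError(path, len(lines), "no PSSM data rows found")
    return PSSMProfile(
        protein_id=path.stem, scores=np.array(scores), residues="".join(residues)
    )


def write_pssm(profile: PSSMProfile, path) -> None:
    """Serialize in the PSI-BLAST ASCII dialect that :func:`read_pssm` accepts.

    The percentage block is emitted as zeros (it is never read back).
    """
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n"
        )
        fh.write(" " * 11 + "  ".join(PSSM_ALPHABET) + "   " + "  ".join(PSSM_ALPHABET) + "\n")
        residues = profile.residues or "A" * len(profile)
        for i, row in enumerate(profile.scores, start=1):
            ints = " ".join(f"{int(round(v)):3d}" for v in row)
            pcts = " ".join("  0" for _ in row)
            fh.write(f"{i:5d} {residues[i - 1]}  {ints}  {pcts}  0.00 0.00\n")


def read_struct_profile(path) -> StructProfile:
    """Read a 9-column structural-profile TSV (idx + 8 feature columns)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = {"idx", *STRUCT_COLUMNS} - set(df.columns)
    if missing:
        raise ProfileParseError(path, 1, f"missing columns {sorted(missing)}")
    rows = df[STRUCT_COLUMNS].to_numpy(dtype=float)
    try:
        return StructProfile(protein_id=path.stem.replace(".struct", ""), rows=rows)
    except ValueError as exc:
        raise ProfileParseError(path, -1, str(exc))


def write_struct_profile(profile: StructProfile, path) -> None:
    df = pd.DataFrame(profile.rows, columns=STRUCT_COLUMNS)
    df.insert(0, "idx", np.arange(1, len(profile) + 1))
    df.to_csv(path, sep="\t", index=False)


def window_profile(profile: PSSMProfile | StructProfile, pos: int, half_width: int) -> np.ndarray:
    """Slice profile rows for the window centered at 1-based ``pos``.

    Returns a ``(2*half_width+1, n_cols)`` array; rows that fall outside
    the protein are all-zero, mirroring the pad convention of the
    sequence window.
    """
    mat = profile.scores if isinstance(profile, PSSMProfile) else profile.rows
    length = mat.shape[0]
    if not 1 <= pos <= length:
        raise IndexError(f"position {pos} out of range 1..{length}")
    width = 2 * half_width + 1
    out = np.zeros((width, mat.shape[1]), dtype=float)
    lo = pos - 1 - half_width
    for w in range(width):
        src = lo + w
        if 0 <= src < length:
            out[w] = mat[src]
    return out


def load_profile_dir(
    directory, suffix: str, reader
) -> dict[str, PSSMProfile | StructProfile]:
    """Load every ``<protein_id><suffix>`` file in a directory."""
    directory = Path(directory)
    out = {}
    for path in sorted(directory.glob(f"*{suffix}")):
        prof = reader(path)
        pid = path.name[: -len(suffix)]
        prof.protein_id = pid
        out[pid] = prof
    return out


def load_pssm_dir(directory) -> dict[str, PSSMProfile]:
    return load_profile_dir(directory, ".pssm", read_pssm)


def load_struct_dir(directory) -> dict[str, StructProfile]:
    return load_profile_dir(directory, ".struct.tsv", read_struct_profile)


def require_profiles(
    fragments, profiles: Mapping[str, PSSMProfile | StructProfile], kind: str
) -> None:
    """Raise with the full missing-protein list if any fragment lacks a profile."""
    missing = sorted({f.protein_id for f in fragments} - set(profiles))
    if missing:
        raise KeyError(f"missing {kind} profiles for proteins: {', '.join(missing)}")
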