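"""Synthetic benchmark data with the statistical structure the pipeline assumes.

Each generated "protein" is a single window-width peptide whose center
alternates between S and T.  Positive fragments draw basic residues at
characteristic flanking offsets (lysine and arginine enrichment around
the phosphosite, the hallmark pattern of microbial pS/pT neighborhoods);
negatives are pure background.  Matching per-protein PSSM and
structural-profile files can be emitted so every encoder and the full
train/predict path run without external tools.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fragments import AMINO_ACIDS, PeptideFragment, extract_window, write_fasta, write_site_table
from .model import Dataset
from .profiles import (
    PSSM_ALPHABET,
    PSSMProfile,
    StructProfile,
    write_pssm,
    write_struct_profile,
)

#: Default K/R flanking enrichment in positives: lysine immediately
#: around the site, arginine further out.
DEFAULT_MOTIF: tuple[tuple[int, str, float], ...] = (
    (-3, "K", 0.55),
    (-2, "K", 0.55),
    (-1, "K", 0.55),
    (+1, "K", 0.55),
    (+2, "K", 0.55),
    (-6, "R", 0.45),
    (-4, "R", 0.45),
    (+4, "R", 0.45),
)


@dataclass
class SynthConfig:
    """Generator settings.

    n_pos / n_neg default to a 2:1 negative:positive class ratio.
    ``motif`` lists (offset, residue, probability) enrichment rules
    applied to positives only; ``background`` is a length-20 probability
    vector over the amino acids (uniform when omitted).  ``pssm_bonus``
    and ``pssm_noise`` shape the synthetic log-odds: the observed
    residue's column gets +bonus, every column gets N(0, noise) noise.
    """

    n_pos: int = 200
    n_neg: int = 400
    window: int = 21
    motif: tuple[tuple[int, str, float], ...] = DEFAULT_MOTIF
    background: np.ndarray | None = None
    pssm_bonus: float = 7.0
    pssm_noise: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        hw = self.window // 2
        for off, res, prob in self.motif:
            if not -hw <= off <= hw or off == 0:
                raise ValueError(f"motif offset {off} outside non-center +/-{hw}")
            if res not in AMINO_ACIDS:
                raise ValueError(f"motif residue {res!r} not a standard amino acid")
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"motif probability {prob} outside [0,1]")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0):
                raise ValueError("background must be 20 probabilities summing to 1")
            self.background = bg

    @property
    def half_width(self) -> int:
        return self.window // 2


def _background(config: SynthConfig) -> np.ndarray:
    if config.background is not None:
        return config.background
    return np.full(20, 1.0 / 20.0)


def _sample_window(rng: np.random.Generator, config: SynthConfig, positive: bool, center: str) -> str:
    bg = _background(config)
    hw = config.half_width
    letters = [AMINO_ACIDS[i] for i in rng.choice(20, size=config.window, p=bg)]
    letters[hw] = center
    if positive:
        for off, res, prob in config.motif:
            if rng.random() < prob:
                letters[hw + off] = res
    return "".join(letters)


def generate_fragments(
    config: SynthConfig,
) -> tuple[list[PeptideFragment], dict[str, str], pd.DataFrame]:
    """Labeled fragments plus their FASTA sequences and site table.

    Each fragment is its own window-length protein with the candidate
    site at the central position; centers alternate S and T within each
    class.
    """
    rng = np.random.default_rng(config.seed)
    sequences: dict[str, str] = {}
    rows = []
    fragments: list[PeptideFragment] = []
    specs = [("pos", 1, config.n_pos), ("neg", -1, config.n_neg)]
    for prefix, label, count in specs:
        for i in range(count):
            center = "S" if i % 2 == 0 else "T"
            pid = f"{prefix}{i + 1:05d}"
            seq = _sample_window(rng, config, positive=(label == 1), center=center)
            sequences[pid] = seq
            pos = config.half_width + 1
            rows.append((pid, pos, label))
            fragments.append(
                extract_window(seq, pos, config.half_width, protein_id=pid, label=label)
            )
    sites = pd.DataFrame(rows, columns=["protein_id", "position", "label"])
    return fragments, sequences, sites


def generate_pssm(
    protein: str, config: SynthConfig, protein_id: str = "", rng: np.random.Generator | None = None
) -> PSSMProfile:
    """Synthetic log-odds: +bonus for the observed residue plus seeded noise."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    scores = rng.normal(0.0, config.pssm_noise, size=(len(protein), 20))
    for i, c in enumerate(protein):
        if c in PSSM_ALPHABET:
            scores[i, PSSM_ALPHABET.index(c)] += config.pssm_bonus
    scores = np.clip(np.round(scores), -12, 12)
    return PSSMProfile(protein_id=protein_id, scores=scores, residues=protein)


def generate_struct_profile(
    protein: str, config: SynthConfig, protein_id: str = "", rng: np.random.Generator | None = None
) -> StructProfile:
    """Synthetic structural profile: non-negative ASA, torsions, SS simplex."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = len(protein)
    asa = np.abs(rng.normal(60.0, 20.0, size=n))
    angles = rng.uniform(-180.0, 180.0, size=(n, 4))
    ss = rng.dirichlet(np.ones(3), size=n)
    rows = np.column_stack([asa, angles, ss])
    return StructProfile(protein_id=protein_id, rows=rows)


def generate_dataset(config: SynthConfig, outdir=None, with_profiles: bool = True) -> Dataset:
    """Full synthetic dataset; optionally written to ``outdir`` as plain files.

    Writes ``sequences.fasta``, ``sites.tsv`` and, when profiles are
    requested, one ``<id>.pssm`` and ``<id>.struct.tsv`` per protein
    under ``pssm/`` and ``struct/``.
    """
    _, sequences, sites = generate_fragments(config)
    pssm: dict[str, PSSMProfile] = {}
    struct: dict[str, StructProfile] = {}
    if with_profiles:
        rng = np.random.default_rng(config.seed + 1)
        for pid, seq in sequences.items():
            pssm[pid] = generate_pssm(seq, config, pid, rng)
            struct[pid] = generate_struct_profile(seq, config, pid, rng)
    dataset = Dataset(sequences=sequences, sites=sites, pssm=pssm, struct=struct)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(sequences, outdir / "sequences.fasta")
        write_site_table(sites, outdir / "sites.tsv")
        if with_profiles:
            (outdir / "pssm").mkdir(exist_ok=True)
            (outdir / "struct").mkdir(exist_ok=True)
            for pid in sequences:
                write_pssm(pssm[pid], outdir / "pssm" / f"{pid}.pssm")
                write_struct_profile(struct[pid], outdir / "struct" / f"{pid}.struct.tsv")
    return dataset
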