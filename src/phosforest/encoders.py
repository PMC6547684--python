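"""Feature encodings for S/T-centered peptide windows.

Seven encodings turn a window of width W = 2*half_width + 1 (21 by
default) into a fixed-length numeric vector:

========  ====================================================  dim (W=21)
AAC       amino-acid composition of the window                          20
AFC       k-spaced amino-acid pair composition (k = 0..4) over
          the 21-symbol alphabet (20 AA + pad 'X')                   2,205
BE        per-position one-hot (binary) encoding                       420
AIP       per-position physicochemical indices (15 scales)             315
SSF       per-position predicted structural features (8)               168
PSSM      per-position substitution log-odds (20)                      420
PKA       k-spaced pair composition of the logistic-rescaled
          PSSM window (k = 0..4)                                     2,000
========  ====================================================  ==========

The combined encoding concatenates AFC, AIP, BE and PKA in that fixed
order (4,940 features at W=21).  Pad positions contribute zeros to every
per-position encoding; in AFC the pad participates as its own symbol.

Encoders follow the scikit-learn transformer protocol: ``transform``
accepts a sequence of :class:`~phosforest.fragments.PeptideFragment` and
returns an ``(n, d)`` float array; ``get_feature_names_out`` names the
columns (e.g. ``BE|pos=-3|K``, ``PKA|k=2|K_R``) so that downstream
feature selection stays interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .fragments import AMINO_ACIDS, PAD, PeptideFragment
from .profiles import (
    PSSM_ALPHABET,
    PSSMProfile,
    STRUCT_COLUMNS,
    StructProfile,
    window_profile,
)

#: AFC alphabet: 20 amino acids plus the pad symbol.
AFC_ALPHABET = AMINO_ACIDS + PAD

DEFAULT_K_VALUES = (0, 1, 2, 3, 4)


@dataclass
class FeatureVector:
    """Named numeric features from one encoder applied to one fragment."""

    names: list[str]
    values: np.ndarray
    encoder_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names are not unique")

    def __len__(self) -> int:
        return len(self.values)


def load_aaindex() -> pd.DataFrame:
    """Load the bundled 15 x 20 physicochemical index table.

    The shipped table (`data/aaindex15_synthetic.tsv`) is a synthetic
    stand-in carrying the 15 published index identifiers with
    best-effort reconstructions of the corresponding scales; values are
    z-scored across the 20 amino acids before use, so only relative
    ordering and spread matter downstream.
    """
    with resources.files("phosforest.data").joinpath(
        "aaindex15_synthetic.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df = df.rename(columns={"#index": "index"}).set_index("index")
    if df.shape != (15, 20):
        raise ValueError(f"AAindex table must be 15x20, got {df.shape}")
    if df.isna().any().any():
        raise ValueError("AAindex table has missing entries")
    return df.astype(float)


def standardize_aaindex(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each index across the 20 amino acids."""
    mean = table.mean(axis=1)
    std = table.std(axis=1, ddof=0)
    return table.sub(mean, axis=0).div(std, axis=0)


def _offsets(half_width: int) -> list[int]:
    return list(range(-half_width, half_width + 1))


def _offset_tag(off: int) -> str:
    return f"{off:+d}" if off else "0"


# ---------------------------------------------------------------------------
# per-fragment encoding functions (the canonical definitions)


def encode_aac(fragment: PeptideFragment) -> FeatureVector:
    """Amino-acid composition: count of each AA over non-pad positions."""
    non_pad = [c for c in fragment.window if c != PAD]
    if not non_pad:
        raise ValueError("cannot compute composition of an all-pad fragment")
    counts = np.array([non_pad.count(a) for a in AMINO_ACIDS], dtype=float)
    return FeatureVector(
        names=[f"AAC|{a}" for a in AMINO_ACIDS],
        values=counts / len(non_pad),
        encoder_tag="AAC",
    )


def _afc_names(k_values: Sequence[int]) -> list[str]:
    return [
        f"AFC|k={k}|{a}_{b}" for k in k_values for a in AFC_ALPHABET for b in AFC_ALPHABET
    ]


def encode_afc(
    fragment: PeptideFragment, k_values: Sequence[int] = DEFAULT_K_VALUES
) -> FeatureVector:
    """k-spaced pair composition over the 21-symbol alphabet.

    For spacing k, the pair (a, b) counts positions i where window[i] = a
    and window[i + k + 1] = b, normalized by the number of such pairs,
    W - k - 1.
    """
    w = fragment.window
    width = len(w)
    idx = {c: i for i, c in enumerate(AFC_ALPHABET)}
    blocks = []
    for k in k_values:
        if k >= width - 1:
            raise ValueError(f"k={k} too large for window of width {width}")
        counts = np.zeros((21, 21))
        for i in range(width - k - 1):
            counts[idx[w[i]], idx[w[i + k + 1]]] += 1
        blocks.append(counts.ravel() / (width - k - 1))
    return FeatureVector(
        names=_afc_names(k_values),
        values=np.concatenate(blocks),
        encoder_tag="AFC",
    )


def encode_be(fragment: PeptideFragment) -> FeatureVector:
    """Per-position one-hot encoding; pad positions give all-zero blocks."""
    hw = fragment.half_width
    names, values = [], np.zeros(20 * fragment.width)
    for j, (off, c) in enumerate(zip(_offsets(hw), fragment.window)):
        names.extend(f"BE|pos={_offset_tag(off)}|{a}" for a in AMINO_ACIDS)
        if c != PAD:
            values[20 * j + AMINO_ACIDS.index(c)] = 1.0
    return FeatureVector(names=names, values=values, encoder_tag="BE")


def encode_aip(
    fragment: PeptideFragment, table: pd.DataFrame | None = None
) -> FeatureVector:
    """Per-position physicochemical index values (standardized); pads -> 0."""
    if table is None:
        table = standardize_aaindex(load_aaindex())
    index_ids = list(table.index)
    hw = fragment.half_width
    names, values = [], np.zeros(len(index_ids) * fragment.width)
    n_idx = len(index_ids)
    for j, (off, c) in enumerate(zip(_offsets(hw), fragment.window)):
        names.extend(f"AIP|pos={_offset_tag(off)}|{ix}" for ix in index_ids)
        if c != PAD:
            if c not in table.columns:
                raise KeyError(f"residue {c!r} missing from the index table")
            values[n_idx * j : n_idx * (j + 1)] = table[c].to_numpy()
    return FeatureVector(names=names, values=values, encoder_tag="AIP")


def encode_ssf(fragment: PeptideFragment, profile: StructProfile) -> FeatureVector:
    """Windowed structural profile, flattened position-major; pad rows zero."""
    mat = window_profile(profile, fragment.center_pos, fragment.half_width)
    names = [
        f"SSF|pos={_offset_tag(off)}|{col}"
        for off in _offsets(fragment.half_width)
        for col in STRUCT_COLUMNS
    ]
    return FeatureVector(names=names, values=mat.ravel(), encoder_tag="SSF")


def encode_pssm(fragment: PeptideFragment, profile: PSSMProfile) -> FeatureVector:
    """Windowed PSSM log-odds, flattened position-major; pad rows zero."""
    mat = window_profile(profile, fragment.center_pos, fragment.half_width)
    names = [
        f"PSSM|pos={_offset_tag(off)}|{a}"
        for off in _offsets(fragment.half_width)
        for a in PSSM_ALPHABET
    ]
    return FeatureVector(names=names, values=mat.ravel(), encoder_tag="PSSM")


def _pka_names(k_values: Sequence[int]) -> list[str]:
    return [
        f"PKA|k={k}|{a}_{b}" for k in k_values for a in PSSM_ALPHABET for b in PSSM_ALPHABET
    ]


def _windowed_logistic_pssm(fragment: PeptideFragment, profile: PSSMProfile) -> np.ndarray:
    """Logistic-rescaled PSSM window with pad rows forced to exactly 0."""
    mat = window_profile(profile, fragment.center_pos, fragment.half_width)
    rescaled = 1.0 / (1.0 + np.exp(-mat))
    length = len(profile)
    lo = fragment.center_pos - 1 - fragment.half_width
    for w in range(fragment.width):
        src = lo + w
        if not 0 <= src < length:
            rescaled[w] = 0.0
    return rescaled


def encode_pka(
    fragment: PeptideFragment,
    profile: PSSMProfile,
    k_values: Sequence[int] = DEFAULT_K_VALUES,
) -> FeatureVector:
    """Profile-based k-spaced pair composition.

    The windowed PSSM is passed through the logistic function
    ``1 / (1 + e^{-x})`` (pad rows stay 0); the (a, b) feature at
    spacing k is ``sum_i P'[i, a] * P'[i+k+1, b] / (W - k - 1)``.
    """
    p = _windowed_logistic_pssm(fragment, profile)
    width = fragment.width
    blocks = []
    for k in k_values:
        if k >= width - 1:
            raise ValueError(f"k={k} too large for window of width {width}")
        pair = p[: width - k - 1].T @ p[k + 1 :]
        blocks.append(pair.ravel() / (width - k - 1))
    return FeatureVector(
        names=_pka_names(k_values), values=np.concatenate(blocks), encoder_tag="PKA"
    )


def encode_combined(
    fragment: PeptideFragment,
    pssm_profile: PSSMProfile,
    k_values: Sequence[int] = DEFAULT_K_VALUES,
    aaindex: pd.DataFrame | None = None,
) -> FeatureVector:
    """Concatenate AFC, AIP, BE and PKA (in that fixed order)."""
    parts = [
        encode_afc(fragment, k_values),
        encode_aip(fragment, aaindex),
        encode_be(fragment),
        encode_pka(fragment, pssm_profile, k_values),
    ]
    return FeatureVector(
        names=[n for p in parts for n in p.names],
        values=np.concatenate([p.values for p in parts]),
        encoder_tag="COMBINED",
    )


# ---------------------------------------------------------------------------
# scikit-learn transformers


class FragmentEncoder(TransformerMixin, BaseEstimator):
    """Base transformer: X is a sequence of PeptideFragment objects."""

    def fit(self, X, y=None):
        self.feature_names_out_ = np.asarray(
            self._encode_one(X[0]).names if len(X) else [], dtype=object
        )
        return self

    def transform(self, X) -> np.ndarray:
        if not len(X):
            return np.empty((0, 0))
        vecs = [self._encode_one(f) for f in X]
        return np.vstack([v.values for v in vecs])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return self.feature_names_out_

    def _encode_one(self, fragment: PeptideFragment) -> FeatureVector:  # pragma: no cover
        raise NotImplementedError


class AACEncoder(FragmentEncoder):
    """Amino-acid composition (20 features)."""

    def _encode_one(self, fragment):
        return encode_aac(fragment)


class AFCEncoder(FragmentEncoder):
    """k-spaced amino-acid pair composition (2,205 features by default)."""

    def __init__(self, k_values: tuple[int, ...] = DEFAULT_K_VALUES):
        self.k_values = k_values

    def _encode_one(self, fragment):
        return encode_afc(fragment, self.k_values)


class BinaryEncoder(FragmentEncoder):
    """Per-position one-hot encoding (20 x W features)."""

    def _encode_one(self, fragment):
        return encode_be(fragment)


class AAIndexEncoder(FragmentEncoder):
    """Per-position physicochemical-index encoding (15 x W features)."""

    def __init__(self, table: pd.DataFrame | None = None):
        self.table = table

    def fit(self, X, y=None):
        raw = self.table if self.table is not None else load_aaindex()
        self.table_ = standardize_aaindex(raw)
        return super().fit(X, y)

    def _encode_one(self, fragment):
        table = getattr(self, "table_", None)
        if table is None:
            table = standardize_aaindex(
                self.table if self.table is not None else load_aaindex()
            )
        return encode_aip(fragment, table)


class _ProfileEncoder(FragmentEncoder):
    """Shared lookup machinery for profile-backed encoders."""

    def __init__(self, profiles: Mapping[str, object] | None = None):
        self.profiles = profiles

    def _profile_for(self, fragment):
        if self.profiles is None or fragment.protein_id not in self.profiles:
            raise KeyError(
                f"no profile available for protein {fragment.protein_id!r}"
            )
        return self.profiles[fragment.protein_id]


class StructEncoder(_ProfileEncoder):
    """Per-position structural-feature encoding (8 x W features)."""

    def _encode_one(self, fragment):
        return encode_ssf(fragment, self._profile_for(fragment))


class PSSMEncoder(_ProfileEncoder):
    """Per-position PSSM log-odds encoding (20 x W features)."""

    def _encode_one(self, fragment):
        return encode_pssm(fragment, self._profile_for(fragment))


class PKAEncoder(_ProfileEncoder):
    """Profile-based k-spaced pair composition (2,000 features by default)."""

    def __init__(
        self,
        profiles: Mapping[str, PSSMProfile] | None = None,
        k_values: tuple[int, ...] = DEFAULT_K_VALUES,
    ):
        super().__init__(profiles)
        self.k_values = k_values

    def _encode_one(self, fragment):
        return encode_pka(fragment, self._profile_for(fragment), self.k_values)


class CombinedEncoder(_ProfileEncoder):
    """AFC + AIP + BE + PKA concatenation (4,940 features at W=21)."""

    def __init__(
        self,
        profiles: Mapping[str, PSSMProfile] | None = None,
        k_values: tuple[int, ...] = DEFAULT_K_VALUES,
        aaindex: pd.DataFrame | None = None,
    ):
        super().__init__(profiles)
        self.k_values = k_values
        self.aaindex = aaindex

    def _encode_one(self, fragment):
        table = None
        if self.aaindex is not None:
            table = standardize_aaindex(self.aaindex)
        return encode_combined(
            fragment, self._profile_for(fragment), self.k_values, table
        )


ENCODER_TAGS = ("aac", "afc", "be", "aip", "ssf", "pssm", "pka", "combined")


def make_encoder(
    tag: str,
    pssm_profiles: Mapping[str, PSSMProfile] | None = None,
    struct_profiles: Mapping[str, StructProfile] | None = None,
    k_values: tuple[int, ...] = DEFAULT_K_VALUES,
) -> FragmentEncoder:
    """Factory mapping an encoder tag to a ready transformer."""
    tag = tag.lower()
    if tag == "aac":
        return AACEncoder()
    if tag == "afc":
        return AFCEncoder(k_values)
    if tag == "be":
        return BinaryEncoder()
    if tag == "aip":
        return AAIndexEncoder()
    if tag == "ssf":
        return StructEncoder(struct_profiles)
    if tag == "pssm":
        return PSSMEncoder(pssm_profiles)
    if tag == "pka":
        return PKAEncoder(pssm_profiles, k_values)
    if tag == "combined":
        return CombinedEncoder(pssm_profiles, k_values)
    raise ValueError(f"unknown encoder {tag!r}; choose from {ENCODER_TAGS}")


def encode_fragments(
    fragments: Sequence[PeptideFragment], encoder: FragmentEncoder
) -> pd.DataFrame:
    """Encode fragments into a named-column DataFrame (the feature matrix)."""
    encoder.fit(fragments)
    X = encoder.transform(fragments)
    return pd.DataFrame(X, columns=list(encoder.get_feature_names_out()))


META_COLUMNS = ["protein_id", "position", "label"]


def write_feature_matrix(matrix: pd.DataFrame, fragments, path) -> None:
    """Export a feature matrix as TSV with leading metadata columns."""
    meta = pd.DataFrame(
        {
            "protein_id": [f.protein_id for f in fragments],
            "position": [f.center_pos for f in fragments],
            "label": [0 if f.label is None else f.label for f in fragments],
        }
    )
    pd.concat([meta, matrix.reset_index(drop=True)], axis=1).to_csv(
        path, sep="\t", index=False
    )


def read_feature_matrix(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a feature-matrix TSV; returns (metadata, features)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature matrix missing metadata columns {sorted(missing)}")
    return df[META_COLUMNS], df.drop(columns=META_COLUMNS)
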