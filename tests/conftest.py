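import numpy as np
import pytest

from phosforest.fragments import AMINO_ACIDS, PeptideFragment, extract_window
from phosforest.model import encode_with_tags
from phosforest.synthetic import SynthConfig, generate_dataset


def random_fragment(rng: np.random.Generator, half_width: int = 10) -> PeptideFragment:
    """A random valid fragment, occasionally terminal (padded)."""
    width = 2 * half_width + 1
    protein_len = int(rng.integers(width // 2, 3 * width))
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=protein_len))
    pos = int(rng.integers(1, protein_len + 1))
    seq = seq[: pos - 1] + ("S" if rng.random() < 0.5 else "T") + seq[pos:]
    label = 1 if rng.random() < 0.5 else -1
    return extract_window(seq, pos, half_width, protein_id="rand", label=label)


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic dataset with profiles (90 fragments)."""
    return generate_dataset(SynthConfig(n_pos=30, n_neg=60, seed=7))


@pytest.fixture(scope="session")
def benchmark():
    """The 600-fragment planted-motif benchmark with its combined encoding."""
    from phosforest.fragments import extract_fragments

    config = SynthConfig(seed=11)  # defaults: 200 pos, 400 neg, window 21
    dataset = generate_dataset(config)
    frags = extract_fragments(dataset.sequences, dataset.sites, config.half_width)
    X = encode_with_tags(frags, ["combined"], dataset.pssm, dataset.struct)
    y = np.array([f.label for f in frags])
    return {"config": config, "dataset": dataset, "fragments": frags, "X": X, "y": y}
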