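import numpy as np
import pytest

import ubimdd as u


@pytest.fixture(scope="session")
def benchmark():
    """One seeded two-motif benchmark replicate (positives, negatives, hidden)."""
    return u.benchmark_dataset(n_positives=400, seed=1234)


@pytest.fixture(scope="session")
def small_positives():
    """120 planted-motif positives for cheap model-level tests."""
    positives, _ = u.generate_fragments(
        u.two_motif_specs(), n_total=120, seed=99, label=u.POSITIVE
    )
    return positives


@pytest.fixture(scope="session")
def small_negatives():
    negatives, _ = u.generate_fragments(
        [u.MotifSpec(weight=1.0)], n_total=250, seed=100, label=u.NEGATIVE
    )
    return negatives


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_fragment_set(rng, size, n=6, label=u.POSITIVE, pad_fraction=0.0):
    """Uniform-background fragments, optionally with terminal pads."""
    frags = []
    length = 2 * n + 1
    for i in range(size):
        codes = rng.integers(0, 20, size=length)
        window = list("".join(u.AMINO_ACIDS[c] for c in codes))
        window[n] = "K"
        if pad_fraction and rng.random() < pad_fraction:
            pl = int(rng.integers(0, n + 1))
            pr = int(rng.integers(0, n + 1))
            window[:pl] = "-" * pl
            window[length - pr:] = "-" * pr
        frags.append(
            u.Fragment(
                window="".join(window),
                n=n,
                label=label,
                protein_id=f"r{i}",
                site_position=n + 1,
            )
        )
    return u.FragmentSet(frags)
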