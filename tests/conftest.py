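import numpy as np
import pytest

from retescan.sd_energy import default_energy_model
from retescan.synthetic import generate_genome

_TERMINAL = {"AU", "UA", "GU", "UG"}


def brute_force_delta_g(window: str, anti_sd: str, model) -> float:
    """Independent duplex-energy oracle: enumerate every helix placement.

    For every (window position, anti-SD position, helix length) triple the
    pairs are checked one by one and the energy summed explicitly; no run
    decomposition or dynamic programming is shared with the implementation.
    """
    best = 0.0
    lw, la = len(window), len(anti_sd)
    for i in range(lw):
        for j in range(la):
            for length in range(2, min(lw - i, j + 1) + 1):
                pairs = [window[i + k] + anti_sd[j - k]
                         for k in range(length)]
                if not all(p in model.valid_pairs for p in pairs):
                    continue
                e = model.init_penalty
                for p, q in zip(pairs, pairs[1:]):
                    e += model.stack_table[(p, q)]
                for p in (pairs[0], pairs[-1]):
                    if p in _TERMINAL:
                        e += model.terminal_au_penalty
                best = min(best, e)
    return best


@pytest.fixture(scope="session")
def model():
    return default_energy_model()


@pytest.fixture(scope="session")
def small_genome():
    """A 150-gene planted genome shared across test modules."""
    return generate_genome(n_genes=150, seed=42)


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGU"[i] for i in rng.integers(4, size=length))
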