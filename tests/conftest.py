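import numpy as np
import pytest

from metalbind import AnnotatedChain, SynthSpec, generate, make_fragments
from metalbind.alphabets import AA21


@pytest.fixture(scope="session")
def planted_chains():
    """A moderately sized planted dataset shared by model-level tests."""
    spec = SynthSpec(n_chains=25, min_length=100, max_length=160, prevalence=0.03, seed=11)
    chains, truth = generate(spec)
    return chains, truth


@pytest.fixture()
def toy_chain():
    return AnnotatedChain("toy", "ACDEFGHIK", frozenset({3, 5}))


@pytest.fixture()
def random_fragments():
    """1,000 random L=9 fragments (some containing X) for oracle checks."""
    rng = np.random.default_rng(42)
    symbols = list(AA21)
    probs = np.full(21, 0.9 / 20)
    probs[-1] = 0.1  # X appears often enough to exercise the skip rules
    frags = []
    for k in range(1000):
        residues = "".join(rng.choice(symbols, size=9, p=probs))
        # keep the centre a real residue, as windowing guarantees
        mid = list(residues)
        if mid[4] == "X":
            mid[4] = "A"
        residues = "".join(mid)
        frags.append(_fragment(residues, label=bool(k % 7 == 0)))
    return frags


def _fragment(residues, label=False):
    from metalbind import Fragment

    L = len(residues)
    return Fragment(
        chain_id="r",
        center_position=1,
        residues=residues,
        ss_window="C" * L,
        rsa_window="b" * L,
        label=label,
    )


@pytest.fixture()
def make_fragment():
    return _fragment
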