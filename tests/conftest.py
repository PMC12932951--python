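import numpy as np
import pytest

from syntaxner.corpus import Sentence, Token


def random_tree(rng: np.random.Generator, n: int) -> list[int]:
    """Random labeled rooted tree as a head vector (not necessarily projective).

    Nodes are attached one at a time, each to a uniformly chosen already-placed
    node, over a random placement order — guarantees a single root and
    acyclicity without biasing toward any shape.
    """
    order = rng.permutation(n) + 1
    heads = [0] * (n + 1)  # 1-based; heads[0] unused
    placed = [int(order[0])]
    heads[placed[0]] = 0
    for v in order[1:]:
        heads[int(v)] = int(rng.choice(placed))
        placed.append(int(v))
    return heads[1:]


DEPRELS = ["nsubj", "obj", "pobj", "compound", "amod", "det", "prep", "punct"]


def random_parsed_sentence(rng: np.random.Generator, n: int) -> Sentence:
    heads = random_tree(rng, n)
    toks = [Token(index=i, form=f"w{i}", head=h,
                  deprel="root" if h == 0 else DEPRELS[int(rng.integers(len(DEPRELS)))])
            for i, h in enumerate(heads, start=1)]
    return Sentence(toks)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
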