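import pytest

from compalign import ReactionNetwork, toy_instance


@pytest.fixture
def toy():
    """Worked-example networks P (5 reactions), P-bar (4) and similarities."""
    return toy_instance()


@pytest.fixture
def path4():
    return ReactionNetwork(edges=[("a", "b"), ("b", "c"), ("c", "d")], level=0)


def make_path(n: int, prefix: str = "p") -> ReactionNetwork:
    ids = [f"{prefix}{i}" for i in range(n)]
    return ReactionNetwork(
        edges=[(ids[i], ids[i + 1]) for i in range(n - 1)], level=0
    )
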