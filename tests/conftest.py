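import random

import pytest

import potionsim as ps


@pytest.fixture(scope="session")
def table() -> ps.RecipeTable:
    return ps.default_recipe_table()


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(12345)


@pytest.fixture(scope="session")
def toy_network():
    return ps.make_fixture("toy_network")


def write_recipe_csv(path, rows, header=True):
    """Write a recipe CSV from (product, trajectory, tier, iscore, tscore, ingredients) tuples."""
    lines = []
    if header:
        lines.append("product,trajectory,tier,innovation_score,tier_score,ingredients")
    for r in rows:
        lines.append(",".join(str(v) for v in r))
    path.write_text("\n".join(lines) + "\n")
    return path


CANONICAL_ROWS = [
    ("a1", "basic_a", 0, 6, 0, ""),
    ("a2", "basic_a", 0, 8, 0, ""),
    ("a3", "basic_a", 0, 10, 0, ""),
    ("b1", "basic_b", 0, 6, 0, ""),
    ("b2", "basic_b", 0, 8, 0, ""),
    ("b3", "basic_b", 0, 10, 0, ""),
    ("1a", "a", 1, 48, 48, "a1;a2;a3"),
    ("1b", "b", 1, 48, 48, "b1;b2;b3"),
    ("2a", "a", 2, 109, 109, "1a;a1;a2"),
    ("2b", "b", 2, 109, 109, "1b;b1;b2"),
    ("3a", "a", 3, 188, 188, "2a;a2;a3"),
    ("3b", "b", 3, 188, 188, "2b;b2;b3"),
    ("x", "crossover", 4, 358, 358, "3a;3b;a3"),
]
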