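"""Items, trajectories and the recipe table of the Potions Task.

The task is a cumulative-innovation game: starting from six basic
ingredients (three per trajectory), unordered triads of items combine into
higher-tier items along two path-dependent trajectories (A and B).  The
single tier-4 item -- the *crossover* -- requires the terminal (tier-3)
items of both trajectories, so it can only be reached by a population that
explores both paths.  Everything in this module is deterministic and
RNG-free; the stochastic dynamics live in :mod:`potionsim.engine`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Trajectory",
    "Item",
    "RecipeTable",
    "RecipeError",
    "RecipeParseError",
    "RecipeValidationError",
    "load_recipe_table",
    "default_recipe_table",
    "validate_recipe_table",
    "lookup_combination",
    "initial_inventory",
    "TIER_SCORES",
    "CROSSOVER_SCORE",
]

#: Agent score awarded by the highest-tier item held: tiers 1-4.
TIER_SCORES: dict[int, float] = {0: 0.0, 1: 48.0, 2: 109.0, 3: 188.0, 4: 358.0}

#: Score of the tier-4 crossover item; reaching it ends a run.
CROSSOVER_SCORE: float = 358.0


class Trajectory(str, Enum):
    """Which discovery line an item belongs to."""

    BASIC_A = "basic_a"
    BASIC_B = "basic_b"
    A = "a"
    B = "b"
    CROSSOVER = "crossover"


@dataclass(frozen=True)
class Item:
    """A potion: immutable, identified by name.

    ``innovation_score`` is the selection weight used when agents choose
    which items to combine; ``tier_score`` is the score an agent earns for
    holding the item (0 for basics, then 48/109/188/358).  ``rank`` is the
    item's level in the task and equals its tier; it is carried as metadata
    and used only by the rank-based Gini variant.
    """

    name: str
    trajectory: Trajectory
    tier: int
    innovation_score: float
    tier_score: float

    @property
    def rank(self) -> int:
        return self.tier


class RecipeError(ValueError):
    """Base class for recipe-table problems."""


class RecipeParseError(RecipeError):
    """A recipe file could not be parsed; the message names the line."""


class RecipeValidationError(RecipeError):
    """A parsed table violates the task's structural invariants."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid recipe table:\n" + "\n".join(f"- {v}" for v in violations)
        )


class RecipeTable:
    """The valid-combination table: unordered name-triads -> product items.

    ``items`` maps every item name to its :class:`Item`; ``recipes`` maps a
    ``frozenset`` of three ingredient names to the product's name.
    """

    def __init__(
        self,
        items: Mapping[str, Item],
        recipes: Mapping[frozenset, str],
    ) -> None:
        self.items: dict[str, Item] = dict(items)
        self.recipes: dict[frozenset, str] = {
            frozenset(k): v for k, v in recipes.items()
        }

    def lookup(self, triad: Iterable[str]) -> Item | None:
        """Return the product of ``triad`` or ``None`` if it is invalid.

        A triad with fewer than three distinct names is invalid (recipes
        are unordered sets of three distinct items).
        """
        key = frozenset(triad)
        if len(key) != 3:
            return None
        name = self.recipes.get(key)
        return self.items[name] if name is not None else None

    def basics(self) -> list[Item]:
        """The tier-0 items, sorted by name."""
        return sorted(
            (it for it in self.items.values() if it.tier == 0),
            key=lambda it: it.name,
        )

    @property
    def crossover_item(self) -> Item:
        (item,) = [it for it in self.items.values() if it.tier == 4]
        return item

    def closure(self) -> set[str]:
        """Names reachable from the basics by repeated combination.

        Brute-force fixed point over all 3-subsets of the reachable set;
        tables are tiny (~14 items) so this is cheap.
        """
        from itertools import combinations

        reached = {it.name for it in self.basics()}
        grew = True
        while grew:
            grew = False
            for triad in combinations(sorted(reached), 3):
                prod = self.lookup(triad)
                if prod is not None and prod.name not in reached:
                    reached.add(prod.name)
                    grew = True
        return reached

    def __repr__(self) -> str:  # pragma: no cover
        return f"RecipeTable({len(self.items)} items, {len(self.recipes)} recipes)"


_COLUMNS = ("product", "trajectory", "tier", "innovation_score", "tier_score", "ingredients")


def _parse_row(row: Mapping[str, str], where: str) -> tuple[Item, frozenset | None]:
    try:
        name = row["product"].strip()
        traj = Trajectory(row["trajectory"].strip().lower())
        tier = int(row["tier"])
        innovation = float(row["innovation_score"])
        tier_score = float(row["tier_score"])
        raw = (row.get("ingredients") or "").strip()
    except (KeyError, ValueError) as exc:
        raise RecipeParseError(f"{where}: malformed row ({exc})") from exc
    if not name:
        raise RecipeParseError(f"{where}: empty product name")
    if innovation <= 0:
        raise RecipeParseError(f"{where}: innovation_score must be positive")
    ingredients: frozenset | None = None
    if raw:
        parts = [p.strip() for p in raw.replace(",", ";").split(";") if p.strip()]
        if len(parts) != 3 or len(set(parts)) != 3:
            raise RecipeParseError(
                f"{where}: ingredients must list exactly 3 distinct names, got {parts!r}"
            )
        ingredients = frozenset(parts)
    elif tier != 0:
        raise RecipeParseError(f"{where}: non-basic item {name!r} needs ingredients")
    return Item(name, traj, tier, innovation, tier_score), ingredients


def load_recipe_table(path: str | Path) -> RecipeTable:
    """Load and validate a recipe table from a CSV or YAML file.

    CSV columns (or YAML mapping keys): ``product``, ``trajectory``,
    ``tier``, ``innovation_score``, ``tier_score``, ``ingredients`` (three
    names separated by ``;``, empty for basics).  Lines starting with ``#``
    are comments.  Raises :class:`RecipeParseError` on malformed input and
    :class:`RecipeValidationError` if the parsed table violates the task's
    structure.
    """
    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        rows = _read_yaml_rows(path)
    else:
        rows = _read_csv_rows(path)
    if not rows:
        raise RecipeParseError(f"{path}: no recipe rows found")

    items: dict[str, Item] = {}
    recipes: dict[frozenset, str] = {}
    violations: list[str] = []
    for where, row in rows:
        item, ingredients = _parse_row(row, where)
        if item.name in items:
            violations.append(f"duplicate product {item.name!r} ({where})")
            continue
        items[item.name] = item
        if ingredients is not None:
            if ingredients in recipes:
                violations.append(
                    f"duplicate triad {sorted(ingredients)} ({where})"
                )
                continue
            recipes[ingredients] = item.name

    table = RecipeTable(items, recipes)
    violations.extend(validate_recipe_table(table))
    if violations:
        raise RecipeValidationError(violations)
    return table


def _read_csv_rows(path: Path) -> list[tuple[str, dict]]:
    rows: list[tuple[str, dict]] = []
    with open(path, newline="") as fh:
        lines = [
            (i + 1, line)
            for i, line in enumerate(fh)
            if line.strip() and not line.lstrip().startswith("#")
        ]
    if not lines:
        return []
    header = [c.strip() for c in next(csv.reader([lines[0][1]]))]
    missing = set(_COLUMNS) - set(header)
    if missing:
        raise RecipeParseError(f"{path}: missing columns {sorted(missing)}")
    for lineno, line in lines[1:]:
        (values,) = csv.reader([line])
        if len(values) != len(header):
            raise RecipeParseError(f"{path}:{lineno}: expected {len(header)} fields")
        rows.append((f"{path}:{lineno}", dict(zip(header, values))))
    return rows


def _read_yaml_rows(path: Path) -> list[tuple[str, dict]]:
    import yaml

    data = yaml.safe_load(path.read_text())
    if not isinstance(data, list):
        raise RecipeParseError(f"{path}: expected a YAML list of recipe mappings")
    return [
        (f"{path}[{i}]", {k: str(v) if v is not None else "" for k, v in row.items()})
        for i, row in enumerate(data)
    ]


def default_recipe_table() -> RecipeTable:
    """The bundled (structural fallback) recipe table."""
    ref = resources.files("potionsim.data") / "recipes_fallback.csv"
    with resources.as_file(ref) as path:
        return load_recipe_table(path)


def validate_recipe_table(table: RecipeTable) -> list[str]:
    """Check the task's structural invariants; return a list of violations.

    An empty list means the table is a well-formed Potions Task: six basics
    (three per trajectory, scores 6/8/10), one item per trajectory-tier for
    tiers 1-3 with the tier ladder 48/109/188, a single tier-4 crossover of
    score 358 whose recipe joins both tier-3 terminals, path dependency
    (every tier-k recipe, k in {2,3}, contains its own trajectory's
    tier-(k-1) item), every item the product of exactly one recipe, and
    full reachability from the basics.
    """
    v: list[str] = []
    items = table.items

    basics = [it for it in items.values() if it.tier == 0]
    for traj, basic_traj in ((Trajectory.A, Trajectory.BASIC_A), (Trajectory.B, Trajectory.BASIC_B)):
        group = sorted(it.innovation_score for it in basics if it.trajectory == basic_traj)
        if group != [6, 8, 10]:
            v.append(
                f"trajectory {traj.value!r} needs exactly three basics with "
                f"innovation scores 6/8/10, found {group}"
            )
    if any(it.tier_score != 0 for it in basics):
        v.append("basics must have tier_score 0")

    # tier ladder: one item per (trajectory, tier) for tiers 1-3
    for traj in (Trajectory.A, Trajectory.B):
        for tier in (1, 2, 3):
            found = [it for it in items.values() if it.trajectory == traj and it.tier == tier]
            if len(found) != 1:
                v.append(f"expected exactly one tier-{tier} item on trajectory {traj.value!r}")
            elif found[0].tier_score != TIER_SCORES[tier]:
                v.append(
                    f"{found[0].name!r}: tier-{tier} score must be {TIER_SCORES[tier]}"
                )

    cross = [it for it in items.values() if it.tier == 4]
    if len(cross) != 1:
        v.append("expected exactly one tier-4 (crossover) item")
    else:
        c = cross[0]
        if c.trajectory is not Trajectory.CROSSOVER:
            v.append(f"tier-4 item {c.name!r} must be on the crossover trajectory")
        if c.tier_score != TIER_SCORES[4]:
            v.append(f"tier-4 score must be {TIER_SCORES[4]}")

    stray = [it.name for it in items.values() if it.tier not in (0, 1, 2, 3, 4)]
    if stray:
        v.append(f"items with tier outside 0-4: {stray}")

    # recipe structure
    produced: dict[str, int] = {}
    basic_names = {it.name for it in basics}
    all_basic_recipes = []
    for triad, product in table.recipes.items():
        produced[product] = produced.get(product, 0) + 1
        unknown = [n for n in triad if n not in items]
        if unknown:
            v.append(f"recipe for {product!r} uses undefined ingredients {unknown}")
            continue
        if triad <= basic_names:
            all_basic_recipes.append((triad, product))
        prod_item = items.get(product)
        if prod_item is None:
            v.append(f"recipe produces undefined item {product!r}")
            continue
        if prod_item.tier in (2, 3):
            prev = [
                it.name
                for it in items.values()
                if it.trajectory == prod_item.trajectory and it.tier == prod_item.tier - 1
            ]
            if not any(p in triad for p in prev):
                v.append(
                    f"tier-{prod_item.tier} recipe for {product!r} must contain the "
                    f"tier-{prod_item.tier - 1} item of its trajectory"
                )
        if prod_item.tier == 4:
            terminals = {it.name for it in items.values() if it.tier == 3}
            if not terminals <= triad:
                v.append("crossover recipe must contain both tier-3 terminal items")

    if len(all_basic_recipes) != 2:
        v.append(
            f"expected exactly two all-basic recipes, found {len(all_basic_recipes)}"
        )

    for it in items.values():
        if it.tier == 0:
            if produced.get(it.name):
                v.append(f"basic {it.name!r} must not be the product of a recipe")
        elif produced.get(it.name, 0) != 1:
            v.append(
                f"{it.name!r} must be the product of exactly one recipe, "
                f"found {produced.get(it.name, 0)}"
            )

    if not v:
        reached = table.closure()
        missing = sorted(set(items) - reached)
        if missing:
            v.append(f"items unreachable from the basics: {missing}")
    return v


def lookup_combination(table: RecipeTable, triad: Iterable[str]) -> Item | None:
    """Functional alias for :meth:`RecipeTable.lookup`."""
    return table.lookup(triad)


def initial_inventory(table: RecipeTable) -> set[Item]:
    """The six basic items every agent starts with (a fresh set per call)."""
    basics = table.basics()
    if len(basics) != 6:
        raise RecipeValidationError(
            [f"initial inventory needs exactly 6 basics, table has {len(basics)}"]
        )
    return set(basics)
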