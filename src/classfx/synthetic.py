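"""Synthetic drug-AE association tables with known planted class effects.

The generator emulates the statistical shape of a curated package-insert
master table: a universe of drug ingredients partitioned (with optional
overlap) into classification-scheme classes, each ingredient marketed as
one or more products, a rooted AE hierarchy, sparse background
ingredient-AE associations, and a set of *planted* class effects in which
every member of a chosen class is associated with a chosen leaf AE.

Defaults mirror the scale of a real cardiovascular-drug curation: 194
ingredients in 36 classes, 736 leaf AEs in a depth-3 hierarchy, 1-3
products per ingredient, and a background association probability of 0.04
(about 30 AEs per ingredient — the order of magnitude of a package
insert's adverse-reaction list).

Background associations are drawn at the ingredient level and then attached
to one randomly chosen product of that ingredient, matching the direction
of the product->ingredient collapse rule.  Planted effects are placed at
leaf AEs so that detection at ancestor AE classes exercises upward
propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np

from .class_effects import Cutoffs, detect_class_effects
from .data_io import AssociationRecord, AssociationTable
from .hierarchy import Hierarchy

__all__ = [
    "SyntheticConfig",
    "GeneratedStudy",
    "OperatingCharacteristics",
    "default_class_sizes",
    "generate",
    "estimate_operating_characteristics",
]

AE_ROOT = "AE:ROOT"
CLASS_ROOT = "CLS:ROOT"


def default_class_sizes(n_ingredients: int = 194, n_classes: int = 36) -> list[int]:
    """As-even-as-possible class sizes covering the ingredient universe."""
    base = n_ingredients // n_classes
    extra = n_ingredients - base * n_classes
    return [base + 1] * extra + [base] * (n_classes - extra)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic association table.

    ``planted_effects`` lists ``(class_index, leaf_ae_index)`` pairs; every
    member of that class becomes associated with that leaf AE through at
    least one of its products.  All remaining (ingredient, leaf AE) pairs
    are associated independently with probability ``p_bg``.
    """

    n_ingredients: int = 194
    n_products_per_ingredient: int | tuple[int, int] = (1, 3)
    class_sizes: tuple[int, ...] = tuple(default_class_sizes())
    overlap_fraction: float = 0.0
    ae_hierarchy_depth: int = 3
    n_leaf_aes: int = 736
    p_bg: float = 0.04
    planted_effects: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_bg <= 1.0:
            raise ValueError("p_bg must lie in [0, 1]")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.ae_hierarchy_depth < 2:
            raise ValueError("ae_hierarchy_depth must be >= 2")
        if any(s < 1 for s in self.class_sizes):
            raise ValueError("class sizes must be >= 1")
        n_fresh = sum(self.class_sizes) - self.n_overlap_slots
        if n_fresh < self.n_ingredients:
            raise ValueError(
                "class sizes too small to cover every ingredient at this "
                f"overlap fraction (fresh slots {n_fresh} < {self.n_ingredients})"
            )
        for ci, ai in self.planted_effects:
            if not 0 <= ci < len(self.class_sizes):
                raise ValueError(f"planted class index out of range: {ci}")
            if not 0 <= ai < self.n_leaf_aes:
                raise ValueError(f"planted leaf AE index out of range: {ai}")

    @property
    def n_overlap_slots(self) -> int:
        return math.floor(sum(self.class_sizes) * self.overlap_fraction)


class GeneratedStudy(NamedTuple):
    table: AssociationTable
    class_hierarchy: Hierarchy
    ae_hierarchy: Hierarchy
    planted: set[tuple[str, str]]  # (class_id, leaf AE id) ground truth


def _ae_hierarchy(n_leaves: int, depth: int) -> tuple[Hierarchy, list[str]]:
    """Balanced-ish rooted tree of the requested depth with n_leaves leaves.

    Intermediate level sizes interpolate geometrically between 1 and
    n_leaves; parents are assigned round-robin, so the layout is
    deterministic.
    """
    levels: list[list[str]] = [[AE_ROOT]]
    for lvl in range(1, depth):
        n = max(2, round(n_leaves ** (lvl / depth)))
        n = min(n, n_leaves)
        levels.append([f"AE:M{lvl}_{i:04d}" for i in range(n)])
    leaves = [f"AE:L{i:04d}" for i in range(n_leaves)]
    levels.append(leaves)
    edges = []
    for upper, lower in zip(levels, levels[1:]):
        for j, node in enumerate(lower):
            edges.append((node, upper[j % len(upper)]))
    labels = {AE_ROOT: "adverse event"}
    labels.update({t: f"ae {t.split(':', 1)[1]}" for lvl in levels[1:] for t in lvl})
    return Hierarchy.from_edges(edges, labels=labels), leaves


def _assign_classes(
    cfg: SyntheticConfig, ingredients: list[str], rng: np.random.Generator
) -> dict[str, list[str]]:
    """Deal ingredients into classes; duplicate slots create overlap."""
    n_classes = len(cfg.class_sizes)
    class_ids = [f"CLS:{i:03d}" for i in range(n_classes)]
    members: dict[str, list[str]] = {c: [] for c in class_ids}
    # duplicate (overlap) slots are spread across classes round-robin
    dup_slots = [0] * n_classes
    for k in range(cfg.n_overlap_slots):
        dup_slots[k % n_classes] += 1
    fresh_slots = [s - d for s, d in zip(cfg.class_sizes, dup_slots)]
    if any(f < 0 for f in fresh_slots):
        raise ValueError("overlap_fraction too large for the smallest class")
    shuffled = [ingredients[i] for i in rng.permutation(len(ingredients))]
    # fill fresh slots by cycling the shuffled universe: every ingredient is
    # covered at least once because sum(fresh_slots) >= n_ingredients
    pos = 0
    for cid, n_fresh in zip(class_ids, fresh_slots):
        for _ in range(n_fresh):
            members[cid].append(shuffled[pos % len(shuffled)])
            pos += 1
    for cid, n_dup in zip(class_ids, dup_slots):
        have = set(members[cid])
        candidates = [i for i in ingredients if i not in have]
        if candidates:
            picks = rng.choice(len(candidates), size=min(n_dup, len(candidates)),
                               replace=False)
            members[cid].extend(candidates[int(p)] for p in sorted(picks))
    # dedupe within a class (cycling can revisit an ingredient)
    return {c: sorted(set(m)) for c, m in members.items()}


def generate(cfg: SyntheticConfig, seed: int | None = None) -> GeneratedStudy:
    """Draw one synthetic study; identical config and seed give identical output.

    Returns the association table, the class and AE hierarchies, and the
    planted ground truth as ``(class_id, leaf_ae_id)`` pairs.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ingredients = [f"ING:{i:04d}" for i in range(cfg.n_ingredients)]
    class_of = _assign_classes(cfg, ingredients, rng)

    class_edges = [(cid, CLASS_ROOT) for cid in class_of]
    for cid, mem in class_of.items():
        class_edges.extend((ing, cid) for ing in mem)
    class_h = Hierarchy.from_edges(class_edges)

    ae_h, leaves = _ae_hierarchy(cfg.n_leaf_aes, cfg.ae_hierarchy_depth)

    npp = cfg.n_products_per_ingredient
    if isinstance(npp, tuple):
        counts = rng.integers(npp[0], npp[1] + 1, size=cfg.n_ingredients)
    else:
        counts = np.full(cfg.n_ingredients, int(npp))
    products = {
        ing: [f"P:{ing.split(':')[1]}_{j}" for j in range(int(counts[i]))]
        for i, ing in enumerate(ingredients)
    }

    # ingredient-level draw, then attach each association to one product
    assoc: dict[str, set[int]] = {ing: set() for ing in ingredients}
    if cfg.p_bg > 0:
        draws = rng.random((cfg.n_ingredients, cfg.n_leaf_aes)) < cfg.p_bg
        for i, ing in enumerate(ingredients):
            assoc[ing].update(np.flatnonzero(draws[i]).tolist())
    planted: set[tuple[str, str]] = set()
    class_ids = sorted(class_of)
    for ci, ai in cfg.planted_effects:
        cid = class_ids[ci]
        planted.add((cid, leaves[ai]))
        for ing in class_of[cid]:
            assoc[ing].add(ai)

    records = []
    for ing in ingredients:
        prods = products[ing]
        for ai in sorted(assoc[ing]):
            prod = prods[int(rng.integers(len(prods)))]
            ae = leaves[ai]
            records.append(
                AssociationRecord(
                    product_id=prod,
                    product_name_en=f"product {prod.split(':')[1]}",
                    ingredient_ids=(ing,),
                    ae_term_en=f"ae L{ai:04d}",
                    ae_id=ae,
                )
            )
    table = AssociationTable(records=records)
    return GeneratedStudy(table, class_h, ae_h, planted)


class OperatingCharacteristics(NamedTuple):
    recovery_rate: float
    recovery_se: float
    false_positive_rate: float
    false_positive_se: float
    n_planted_scored: int
    n_null_scored: int


def estimate_operating_characteristics(
    cfg: SyntheticConfig,
    n_reps: int,
    cutoffs: Cutoffs = Cutoffs(),
    ae_ids: Sequence[str] | None = None,
) -> OperatingCharacteristics:
    """Monte-Carlo recovery and false-positive rates of the detection filter.

    Each replicate regenerates a study (seeds derived from ``cfg.seed``),
    runs :func:`detect_class_effects` over every class against the scored
    AEs (all leaf AEs unless ``ae_ids`` is given), and tallies planted pairs
    recovered and non-planted pairs flagged significant.  Standard errors
    are binomial over the pooled pair counts.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n_rec = n_planted = n_fp = n_null = 0
    for rep in range(n_reps):
        rep_seed = (cfg.seed * 100003 + rep) % (2**31)
        study = generate(cfg, seed=rep_seed)
        class_ids = sorted(study.class_hierarchy.children(CLASS_ROOT))
        scored_aes = (
            list(ae_ids) if ae_ids is not None else sorted(study.ae_hierarchy.leaves)
        )
        results = detect_class_effects(
            study.table,
            study.class_hierarchy,
            study.ae_hierarchy,
            class_ids,
            scored_aes,
            cutoffs=cutoffs,
        )
        for r in results:
            if (r.class_id, r.ae_id) in study.planted:
                n_planted += 1
                n_rec += r.significant
            else:
                n_null += 1
                n_fp += r.significant
    rec = n_rec / n_planted if n_planted else float("nan")
    fp = n_fp / n_null if n_null else float("nan")
    rec_se = math.sqrt(rec * (1 - rec) / n_planted) if n_planted else float("nan")
    fp_se = math.sqrt(fp * (1 - fp) / n_null) if n_null else float("nan")
    return OperatingCharacteristics(rec, rec_se, fp, fp_se, n_planted, n_null)


def with_seed(cfg: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of ``cfg`` with a different seed."""
    return replace(cfg, seed=seed)
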