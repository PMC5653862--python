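"""Drug class-effect statistics over an ingredient universe.

The unit of counting is the drug *ingredient*, not the marketed product: an
ingredient is associated with an adverse event (AE) as soon as at least one
product containing it reports that AE.  For a drug class (a member set of
ingredients resolved from a classification hierarchy) and an AE, four
quantities are computed:

* **PCR** — proportional class-level ratio, the fraction of class members
  associated with the AE; ``PCR = 1`` is the operational definition of a
  class effect (every ingredient in the class carries the AE).
* **C-PRR** — class-level proportional reporting ratio over a 2x2
  contingency table of in-class / out-of-class vs with-AE / without-AE
  ingredient counts: ``(a/(a+c)) / (b/(b+d))``.
* **C-chi2** — Pearson chi-squared on the same 2x2 table (optionally with
  Yates continuity correction).
* A minimum-ingredient filter, the class-level analogue of minimal
  case-report filtering.

A (class, AE) pair is declared a statistically significant class effect
when all four criteria hold: PCR = 1, C-PRR >= 2, chi2 > 4 and class size
>= 3 (the customary disproportionality cutoffs).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .data_io import AssociationTable
from .hierarchy import Hierarchy, class_members, propagate_ae

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "Cutoffs",
    "ClassEffectResult",
    "collapse_to_ingredients",
    "pcr",
    "contingency",
    "c_prr",
    "c_chi2",
    "detect_class_effects",
    "rank_top_aes",
    "results_to_frame",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 ingredient-count table for one (drug class, AE) pair.

    ``a``: in-class with the AE; ``b``: out-of-class with the AE;
    ``c``: in-class without the AE; ``d``: out-of-class without the AE.
    ``a + c`` is the class size and ``a + b + c + d`` the universe size.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in contingency table: {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class Cutoffs:
    """Significance filter settings (defaults are the customary cutoffs)."""

    c_prr_min: float = 2.0
    chi2_min: float = 4.0
    min_ingredients: int = 3
    yates: bool = False

    def __post_init__(self) -> None:
        if self.c_prr_min <= 0 or self.chi2_min <= 0 or self.min_ingredients <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass(frozen=True)
class ClassEffectResult:
    """One scored (class, AE) pair with statistics and filter flags."""

    class_id: str
    ae_id: str
    table: ContingencyTable
    pcr: float
    c_prr: float
    chi2: float
    passes_pcr: bool
    passes_cprr: bool
    passes_chi2: bool
    passes_min_n: bool
    zero_background: bool = False

    @property
    def n_with_ae(self) -> int:
        return self.table.a

    @property
    def class_size(self) -> int:
        return self.table.a + self.table.c

    @property
    def significant(self) -> bool:
        return (
            self.passes_pcr
            and self.passes_cprr
            and self.passes_chi2
            and self.passes_min_n
        )


def collapse_to_ingredients(
    table: AssociationTable, universe: Iterable[str] | None = None
) -> dict[str, set[str]]:
    """Product-level records -> ingredient -> AE-id set.

    An ingredient carries an AE iff at least one product containing it does;
    multi-ingredient products fan the AE out to every ingredient.  Pass
    ``universe`` to include ingredients with no recorded AEs (they appear
    with an empty set); the default universe is the table's own.
    """
    out: dict[str, set[str]] = {
        i: set() for i in (table.ingredient_universe if universe is None else universe)
    }
    for r in table.records:
        for ingredient in r.ingredient_ids:
            out.setdefault(ingredient, set()).add(r.ae_key)
    return out


def pcr(members: set[str], ae_positive: set[str]) -> float:
    """Proportional class-level ratio: |members with AE| / |members|."""
    if not members:
        raise ValueError("PCR undefined for an empty class")
    if not ae_positive <= members:
        raise ValueError("ae_positive must be a subset of members")
    return len(ae_positive) / len(members)


def contingency(
    members: set[str], universe: set[str], ae_positive_universe: set[str]
) -> ContingencyTable:
    """Count the 2x2 cells for one class against the ingredient universe."""
    if not members <= universe:
        raise ValueError("members must be a subset of the universe")
    if not ae_positive_universe <= universe:
        raise ValueError("ae_positive_universe must be a subset of the universe")
    a = len(members & ae_positive_universe)
    b = len(ae_positive_universe - members)
    c = len(members - ae_positive_universe)
    d = len(universe) - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def c_prr(t: ContingencyTable) -> float:
    """Class-level proportional reporting ratio ``(a/(a+c)) / (b/(b+d))``.

    Returns 0 when no class member has the AE, and ``inf`` when the AE has
    no out-of-class background (``b = 0`` with ``a > 0``): the
    disproportionality is maximal but degenerate, so consumers should also
    inspect the zero-background flag carried by detection results.
    """
    if t.a + t.c == 0:
        raise ValueError("C-PRR undefined: empty class (a + c = 0)")
    if t.b + t.d == 0:
        raise ValueError("C-PRR undefined: empty background (b + d = 0)")
    if t.a == 0:
        return 0.0
    if t.b == 0:
        return math.inf
    return (t.a / (t.a + t.c)) / (t.b / (t.b + t.d))


def c_chi2(t: ContingencyTable, correction: bool = False) -> float:
    """Pearson chi-squared on the 2x2 table.

    Closed form ``N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``; with
    ``correction`` the Yates continuity correction shrinks ``|ad - bc|`` by
    ``N/2`` (floored at zero).  A table with any zero marginal carries no
    information and returns 0.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        logger.debug("degenerate contingency table (zero marginal): %s", t)
        return 0.0
    diff = abs(a * d - b * c)
    if correction:
        diff = max(diff - n / 2, 0.0)
    return n * diff * diff / denom


def detect_class_effects(
    table: AssociationTable,
    class_h: Hierarchy,
    ae_h: Hierarchy,
    class_ids: Sequence[str],
    ae_ids: Sequence[str],
    cutoffs: Cutoffs = Cutoffs(),
    universe: set[str] | None = None,
) -> list[ClassEffectResult]:
    """Score every (class, AE) pair and apply the significance filter.

    The background ``universe`` defaults to every ingredient mapped into the
    classification scheme under analysis — the leaf terms of ``class_h``
    (minus its roots) — which is the denominator the ``b``/``d`` cells are
    counted against.  Ingredients in the scheme but absent from the table
    count as AE-free background.  Pass ``universe`` explicitly to pin a
    different background.

    AE associations are propagated upward through ``ae_h`` first, so
    ``ae_ids`` may name terms at any hierarchy level.  Records whose AE id
    does not resolve in ``ae_h`` are excluded from this analysis (their
    count is logged).  Results are sorted by ``(class_id, ae_id)``.
    """
    if not class_ids:
        return []
    assoc = collapse_to_ingredients(table)
    known = ae_h.nodes
    n_dropped = sum(len(aes - known) for aes in assoc.values())
    if n_dropped:
        logger.info(
            "excluding %d ingredient-AE associations not resolvable in the AE hierarchy",
            n_dropped,
        )
    assoc = {i: aes & known for i, aes in assoc.items()}
    propagated = propagate_ae(assoc, ae_h)

    if universe is None:
        # leaf terms of the scheme are its ingredients; a childless class
        # node being scored is not an ingredient, so exclude the class ids
        universe = class_h.leaves - class_h.roots - set(class_ids)
    members_by_class: dict[str, set[str]] = {}
    for cid in class_ids:
        members = class_members(class_h, cid, universe)
        if not members:
            logger.warning("class %s has no mapped ingredients; dropped", cid)
            continue
        members_by_class[cid] = members

    unique_aes = sorted(set(ae_ids))
    unknown = [ae for ae in unique_aes if ae not in known]
    if unknown:
        raise KeyError(f"AE id(s) not in the AE hierarchy: {unknown}")
    positives = {
        ae: {i for i in universe if ae in propagated.get(i, ())} for ae in unique_aes
    }

    results: list[ClassEffectResult] = []
    for cid in sorted(members_by_class):
        members = members_by_class[cid]
        for ae_id in unique_aes:
            positive = positives[ae_id]
            t = contingency(members, universe, positive)
            score = pcr(members, members & positive)
            prr = c_prr(t) if t.b + t.d > 0 else math.nan
            chi2 = c_chi2(t, correction=cutoffs.yates)
            results.append(
                ClassEffectResult(
                    class_id=cid,
                    ae_id=ae_id,
                    table=t,
                    pcr=score,
                    c_prr=prr,
                    chi2=chi2,
                    passes_pcr=score == 1.0,
                    passes_cprr=prr >= cutoffs.c_prr_min,
                    passes_chi2=chi2 > cutoffs.chi2_min,
                    passes_min_n=(t.a + t.c) >= cutoffs.min_ingredients,
                    zero_background=t.b == 0 and t.a > 0,
                )
            )
    return results


def rank_top_aes(
    table: AssociationTable, k: int, level: str = "ingredient"
) -> list[tuple[str, int]]:
    """Top-k AEs by number of distinct drugs carrying them.

    ``level`` selects the counting unit: marketed products or collapsed
    ingredients.  Ties break lexicographically on the AE identifier.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if level not in ("product", "ingredient"):
        raise ValueError(f"unknown level: {level!r}")
    carriers: dict[str, set[str]] = {}
    for r in table.records:
        units = [r.product_id] if level == "product" else list(r.ingredient_ids)
        carriers.setdefault(r.ae_key, set()).update(units)
    ranked = sorted(carriers.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [(ae, len(units)) for ae, units in ranked[:k]]


def results_to_frame(
    results: Iterable[ClassEffectResult],
    class_labels: Mapping[str, str] | None = None,
    ae_labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Results as a tidy table (one row per scored pair).

    Includes an ``n_pairs_tested`` column so downstream users can apply
    their own multiplicity adjustment; the filter itself applies none.
    """
    results = list(results)
    class_labels = class_labels or {}
    ae_labels = ae_labels or {}
    rows = [
        {
            "class_id": r.class_id,
            "class_label": class_labels.get(r.class_id, r.class_id),
            "ae_id": r.ae_id,
            "ae_label": ae_labels.get(r.ae_id, r.ae_id),
            "ingredient_no": r.class_size,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "pcr": r.pcr,
            "c_prr": r.c_prr,
            "chi2": r.chi2,
            "passes_pcr": r.passes_pcr,
            "passes_cprr": r.passes_cprr,
            "passes_chi2": r.passes_chi2,
            "passes_min_n": r.passes_min_n,
            "zero_background": r.zero_background,
            "significant": r.significant,
            "n_pairs_tested": len(results),
        }
        for r in results
    ]
    return pd.DataFrame(rows)
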