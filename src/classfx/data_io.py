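"""Readers and writers for the association master table and hierarchy files.

Canonical dialects (UTF-8, tab-separated, diffable):

* **Master table TSV** — one (product, AE) pair per row, columns
  ``product_id, product_name_cn, product_name_en, ingredient_ids,
  moa_class_ids, ae_term_cn, ae_term_en, ae_id``.  List-valued cells
  (``ingredient_ids``, ``moa_class_ids``) use ``|`` as internal separator.
* **Hierarchy TSV** — columns ``child_id, parent_id``; optional labels TSV
  with columns ``id, label_en, label_cn``.
* **OBO subset** — flat OBO files (``[Term]`` stanzas with ``id``, ``name``
  and ``is_a`` tags) are accepted as an alternative hierarchy source.

Spreadsheet ingestion is deliberately kept out of the statistics path: an
Excel master file is converted once to the canonical TSV and analysed from
there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import obonet
import pandas as pd

from .hierarchy import Hierarchy

logger = logging.getLogger(__name__)

MASTER_COLUMNS = (
    "product_id",
    "product_name_cn",
    "product_name_en",
    "ingredient_ids",
    "moa_class_ids",
    "ae_term_cn",
    "ae_term_en",
    "ae_id",
)
#: Columns that must be non-empty on every row.
MANDATORY_COLUMNS = ("product_id", "ae_term_en")

LIST_SEP = "|"

__all__ = [
    "AssociationRecord",
    "AssociationTable",
    "LoadError",
    "load_association_table",
    "write_association_table",
    "load_hierarchy",
    "write_hierarchy",
    "MASTER_COLUMNS",
]


class LoadError(ValueError):
    """Structured load failure: names the offending column, row or byte."""


@dataclass(frozen=True)
class AssociationRecord:
    """One product-level drug <-> adverse-event association.

    ``ae_id`` resolves in the AE hierarchy when present; records without an
    ``ae_id`` still count toward product/AE-term tallies but are excluded
    from hierarchy-propagated statistics.
    """

    product_id: str
    ae_term_en: str
    product_name_cn: str = ""
    product_name_en: str = ""
    ingredient_ids: tuple[str, ...] = ()
    moa_class_ids: tuple[str, ...] = ()
    ae_term_cn: str = ""
    ae_id: str = ""

    def __post_init__(self) -> None:
        if not self.product_id:
            raise ValueError("product_id must be non-empty")
        if not self.ae_term_en:
            raise ValueError("ae_term_en must be non-empty")

    @property
    def ae_key(self) -> str:
        """Identifier used for de-duplication and counting: the ontology id
        when mapped, otherwise the English term."""
        return self.ae_id or self.ae_term_en


@dataclass
class AssociationTable:
    """The master-file image: a set of product-level association records."""

    records: list[AssociationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = _dedupe(self.records)

    @property
    def product_universe(self) -> set[str]:
        return {r.product_id for r in self.records}

    @property
    def ingredient_universe(self) -> set[str]:
        return {i for r in self.records for i in r.ingredient_ids}

    @property
    def moa_universe(self) -> set[str]:
        return {m for r in self.records for m in r.moa_class_ids}

    def ae_terms_en(self) -> set[str]:
        return {r.ae_term_en for r in self.records}

    def ae_terms_cn(self) -> set[str]:
        return {r.ae_term_cn for r in self.records if r.ae_term_cn}

    def ae_ids(self) -> set[str]:
        return {r.ae_id for r in self.records if r.ae_id}

    def summary(self) -> dict[str, int]:
        """Load-report counts: records, products, ingredients, distinct AE
        terms (EN/CN) and how many records lack an ontology AE id."""
        return {
            "n_records": len(self.records),
            "n_products": len(self.product_universe),
            "n_ingredients": len(self.ingredient_universe),
            "n_ae_terms_en": len(self.ae_terms_en()),
            "n_ae_terms_cn": len(self.ae_terms_cn()),
            "n_ae_ids": len(self.ae_ids()),
            "n_records_unmapped_ae": sum(1 for r in self.records if not r.ae_id),
        }


def _dedupe(records: Iterable[AssociationRecord]) -> list[AssociationRecord]:
    """Collapse duplicate (product, AE) pairs, keeping first occurrence."""
    seen: set[tuple[str, str]] = set()
    out: list[AssociationRecord] = []
    for r in records:
        key = (r.product_id, r.ae_key)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def _split_list(cell: str) -> tuple[str, ...]:
    return tuple(x for x in str(cell).split(LIST_SEP) if x) if cell else ()


def load_association_table(path: str | Path) -> AssociationTable:
    """Read a canonical master-table TSV.

    Duplicate (product, AE) rows collapse to one record; a load report is
    emitted at INFO level.  Missing mandatory columns, malformed rows and
    non-UTF-8 bytes raise :class:`LoadError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
        )
    except UnicodeDecodeError as exc:
        raise LoadError(f"{path}: not valid UTF-8 ({exc})") from exc
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    for col in MASTER_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            records.append(
                AssociationRecord(
                    product_id=row.product_id,
                    product_name_cn=row.product_name_cn,
                    product_name_en=row.product_name_en,
                    ingredient_ids=_split_list(row.ingredient_ids),
                    moa_class_ids=_split_list(row.moa_class_ids),
                    ae_term_cn=row.ae_term_cn,
                    ae_term_en=row.ae_term_en,
                    ae_id=row.ae_id,
                )
            )
        except ValueError as exc:
            raise LoadError(f"{path}: malformed row {i}: {exc}") from exc
    table = AssociationTable(records=records)
    logger.info("loaded %s: %s", path, table.summary())
    return table


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    """Write the canonical TSV; ``load(write(t))`` is record-set identical."""
    rows = [
        {
            "product_id": r.product_id,
            "product_name_cn": r.product_name_cn,
            "product_name_en": r.product_name_en,
            "ingredient_ids": LIST_SEP.join(r.ingredient_ids),
            "moa_class_ids": LIST_SEP.join(r.moa_class_ids),
            "ae_term_cn": r.ae_term_cn,
            "ae_term_en": r.ae_term_en,
            "ae_id": r.ae_id,
        }
        for r in table.records
    ]
    pd.DataFrame(rows, columns=list(MASTER_COLUMNS)).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


def _load_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise LoadError(f"{path}: labels file must have an 'id' column")
    col = "label_en" if "label_en" in df.columns else df.columns[1]
    return dict(zip(df["id"], df[col]))


def load_hierarchy(
    path: str | Path,
    format: str = "edge-list",
    labels_path: str | Path | None = None,
) -> Hierarchy:
    """Read a hierarchy as an edge-list TSV or a flat OBO subset.

    Both formats yield the same rooted DAG for equivalent content; cycles
    and dangling ids raise :class:`~classfx.hierarchy.HierarchyError`.
    """
    path = Path(path)
    labels = _load_labels(labels_path) if labels_path else {}
    if format == "edge-list":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for col in ("child_id", "parent_id"):
            if col not in df.columns:
                raise LoadError(f"{path}: missing column {col!r}")
        edges = list(zip(df["child_id"], df["parent_id"]))
        return Hierarchy.from_edges(edges, labels=labels)
    if format == "obo-subset":
        graph = obonet.read_obo(path)
        edges = [
            (child, parent)
            for child, parent, key in graph.edges(keys=True)
            if key == "is_a"
        ]
        obo_labels = {
            n: data["name"] for n, data in graph.nodes(data=True) if "name" in data
        }
        obo_labels.update(labels)
        return Hierarchy.from_edges(edges, nodes=graph.nodes, labels=obo_labels)
    raise ValueError(f"unknown hierarchy format: {format!r}")


def write_hierarchy(h: Hierarchy, path: str | Path) -> None:
    edges = sorted(h.edges)
    pd.DataFrame(edges, columns=["child_id", "parent_id"]).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )
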