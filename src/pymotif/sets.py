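"""Set-level interactome analyses.

Exclusive (UpSet-semantics) intersection counts over ligase interactomes,
the multi-ligase sharing fraction, phospho-annotation classification of
non-PY interactors (both pT and pS / exactly one kind / none), and
functional-category fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import pandas as pd

MAX_SETS = 12


@dataclass
class MembershipTable:
    """Ligase -> interactor membership: per protein, the sets it belongs to."""

    set_names: tuple
    memberships: dict

    def __post_init__(self) -> None:
        if not self.set_names:
            raise ValueError("membership table needs >= 1 set")
        if len(set(self.set_names)) != len(self.set_names):
            raise ValueError("duplicate set names")
        universe = frozenset(self.set_names)
        for pid, member_of in self.memberships.items():
            member_of = frozenset(member_of)
            if not member_of:
                raise ValueError(f"protein {pid!r} belongs to no set")
            if not member_of <= universe:
                raise ValueError(
                    f"protein {pid!r} names unknown set(s) {sorted(member_of - universe)}"
                )
            self.memberships[pid] = member_of


@dataclass
class IntersectionReport:
    """Exclusive intersection counts for every nonempty subset of sets.

    ``exclusive_counts`` maps a tuple of set names (in ``set_names`` order)
    to the number of proteins whose membership equals exactly that subset;
    zero-count combinations are included. Counts sum to ``union_size``.
    """

    set_names: tuple
    exclusive_counts: dict
    union_size: int
    fraction_multi: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sets": "&".join(combo), "degree": len(combo), "exclusive_count": n}
            for combo, n in self.exclusive_counts.items()
        ]
        return pd.DataFrame(rows, columns=["sets", "degree", "exclusive_count"])


def exclusive_intersections(table: MembershipTable) -> IntersectionReport:
    """Exact exclusive counts for all 2^k - 1 set combinations (k <= 12)."""
    k = len(table.set_names)
    if k > MAX_SETS:
        raise ValueError(
            f"{k} sets would need {2**k - 1} combinations; limit is {MAX_SETS} sets"
        )
    order = {name: i for i, name in enumerate(table.set_names)}
    counts = {}
    for r in range(1, k + 1):
        for combo in combinations(table.set_names, r):
            counts[combo] = 0
    n_multi = 0
    for member_of in table.memberships.values():
        combo = tuple(sorted(member_of, key=order.__getitem__))
        counts[combo] += 1
        if len(combo) >= 2:
            n_multi += 1
    union_size = len(table.memberships)
    return IntersectionReport(
        set_names=table.set_names,
        exclusive_counts=counts,
        union_size=union_size,
        fraction_multi=(n_multi / union_size) if union_size else 0.0,
    )


@dataclass(frozen=True)
class PhosphoAnnotation:
    """Per-protein counts of annotated phospho-threonine / -serine sites."""

    sites: dict

    def counts(self, protein_id: str) -> tuple:
        """(n_pT, n_pS); proteins absent from the table count as (0, 0)."""
        return self.sites.get(protein_id, (0, 0))


@dataclass(frozen=True)
class PhosphoSummary:
    """Classification of an id set by phospho-site annotation.

    ``n_both``: >= 1 pT site AND >= 1 pS site; ``n_either``: exactly one of
    the two kinds present; ``n_none``: neither (including ids absent from
    the annotation table). ``pct_any`` is 100 * (both + either) / total,
    reported to 1 decimal.
    """

    n_total: int
    n_both: int
    n_either: int
    n_none: int
    pct_any: float
    per_protein: pd.DataFrame = field(repr=False, compare=False, default=None)


def phospho_classify(annotations: PhosphoAnnotation, protein_ids: Iterable[str]) -> PhosphoSummary:
    """Classify each id as both / either / none from its pT and pS counts."""
    protein_ids = list(dict.fromkeys(protein_ids))
    if not protein_ids:
        raise ValueError("phospho_classify requires a non-empty id set")
    rows = []
    for pid in protein_ids:
        pt, ps = annotations.counts(pid)
        if pt > 0 and ps > 0:
            cls = "both"
        elif pt > 0 or ps > 0:
            cls = "either"
        else:
            cls = "none"
        rows.append({"protein_id": pid, "n_pt": pt, "n_ps": ps, "class": cls})
    table = pd.DataFrame(rows)
    n_both = int((table["class"] == "both").sum())
    n_either = int((table["class"] == "either").sum())
    n_total = len(protein_ids)
    return PhosphoSummary(
        n_total=n_total,
        n_both=n_both,
        n_either=n_either,
        n_none=n_total - n_both - n_either,
        pct_any=round(100.0 * (n_both + n_either) / n_total, 1),
        per_protein=table,
    )


@dataclass(frozen=True)
class FunctionalSummary:
    """Fraction of an id set falling in a functional category (2-decimal %)."""

    n_set: int
    n_in_category: int
    pct: float


def functional_fraction(protein_ids: Iterable[str], category_members: Iterable[str]) -> FunctionalSummary:
    """Percent of ``protein_ids`` that are members of the category."""
    ids = set(protein_ids)
    if not ids:
        raise ValueError("functional_fraction requires a non-empty id set")
    n_in = len(ids & set(category_members))
    return FunctionalSummary(
        n_set=len(ids),
        n_in_category=n_in,
        pct=round(100.0 * n_in / len(ids), 2),
    )
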