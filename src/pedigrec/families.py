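"""Extraction of analyzable three-generation families.

A family is one (offspring, donor parent) pair in which the offspring,
the donor and at least one of the donor's parents are genotyped, so the
donor's haplotypes can be phased and the transmitted haplotype traced.
An offspring contributes up to two families (one per parent): the unit
of analysis is the meiosis, not the animal.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Cohort


@dataclass(frozen=True)
class FamilyRecord:
    offspring: str
    donor: str
    donor_sex: str            # 'M' (sire meiosis) or 'F' (dam meiosis)
    grandparents: tuple       # genotyped parents of the donor
    breed: str
    offspring_typed: int
    donor_typed: int
    min_typed: int            # density of the pair = min of the two

    def density_class(self, threshold: int) -> str:
        return "ge" if self.min_typed >= threshold else "lt"

    @property
    def meiosis_id(self) -> str:
        return f"{self.donor}>{self.offspring}"


def _check_acyclic(ped: pd.DataFrame) -> None:
    """Iterative DFS over child -> parent links; name any cycle found."""
    parents = {}
    for aid, row in ped.iterrows():
        parents[aid] = [p for p in (row["sire"], row["dam"])
                        if p != "0" and p in ped.index]
    WHITE, GREY, BLACK = 0, 1, 2
    color = {a: WHITE for a in parents}
    for root in parents:
        if color[root] != WHITE:
            continue
        stack = [(root, iter(parents[root]))]
        color[root] = GREY
        path = [root]
        while stack:
            node, it = stack[-1]
            for nxt in it:
                if color[nxt] == GREY:
                    i = path.index(nxt)
                    cyc = " -> ".join(path[i:] + [nxt])
                    raise ValueError(f"pedigree contains a cycle: {cyc}")
                if color[nxt] == WHITE:
                    color[nxt] = GREY
                    path.append(nxt)
                    stack.append((nxt, iter(parents[nxt])))
                    break
            else:
                color[node] = BLACK
                path.pop()
                stack.pop()


def extract_families(cohort: Cohort, density_threshold: int):
    """Enumerate three-generation families and the Table-1-style summary.

    Returns ``(families, summary)`` where ``summary`` counts families by
    breed x donor sex x density class (columns ``male_lt``, ``male_ge``,
    ``female_lt``, ``female_ge``), with a total column, the percentage
    of the grand total per breed, and a ``TOTAL`` row.
    """
    ped = cohort.ped
    _check_acyclic(ped)
    typed = {a: int(t) for a, t in zip(cohort.ids, cohort.typed_counts)}

    fams = []
    for off in cohort.ids:
        row = ped.loc[off]
        for role, donor in (("M", row["sire"]), ("F", row["dam"])):
            if donor == "0" or donor not in typed:
                continue
            drow = ped.loc[donor]
            gps = tuple(g for g in (drow["sire"], drow["dam"])
                        if g != "0" and g in typed)
            if not gps:
                continue
            fams.append(FamilyRecord(
                offspring=off,
                donor=donor,
                donor_sex=role,
                grandparents=gps,
                breed=str(row["breed"]),
                offspring_typed=typed[off],
                donor_typed=typed[donor],
                min_typed=min(typed[off], typed[donor]),
            ))

    summary = summarize_families(fams, density_threshold)
    return fams, summary


def summarize_families(fams, density_threshold: int) -> pd.DataFrame:
    cells = {}
    for f in fams:
        sex = "male" if f.donor_sex == "M" else "female"
        key = (f.breed, f"{sex}_{f.density_class(density_threshold)}")
        cells[key] = cells.get(key, 0) + 1
    breeds = sorted({b for b, _ in cells})
    cols = ["male_lt", "male_ge", "female_lt", "female_ge"]
    data = {b: [cells.get((b, c), 0) for c in cols] for b in breeds}
    summary = pd.DataFrame.from_dict(data, orient="index", columns=cols)
    summary.index.name = "breed"
    return attach_totals(summary)


def attach_totals(summary: pd.DataFrame) -> pd.DataFrame:
    """Add the total column, grand-total row and percentage-of-total column.

    Usable directly on externally supplied count tables (the breed total
    must equal the sum of its four sex x density cells by construction).
    """
    out = summary.copy()
    out["total"] = out.sum(axis=1)
    grand = int(out["total"].sum())
    out["pct"] = 100.0 * out["total"] / grand if grand else 0.0
    total_row = out.sum(axis=0)
    total_row.name = "TOTAL"
    return pd.concat([out, total_row.to_frame().T])
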