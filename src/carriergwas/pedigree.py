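"""Pedigree data model, kinship, and pedigree-based cohort classification.

The central objects here support a carrier-augmented association design for a
recessive disease in a closed breeding population: unaffected dogs that occupy
pedigree positions which force or strongly suggest heterozygosity for a
recessive risk allele (parents or offspring of affected dogs, or repeated
(great-)grandparents of affected dogs) are labelled *carriers* and given an
intermediate phenotype code, while relatives whose carrier status is ambiguous
are excluded from the analysis altogether.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "PedigreeError",
    "StatusAssignment",
    "build_pedigree",
    "additive_relationship",
    "relation_category",
    "classify_cohort",
    "common_ancestors",
]

MALE = "M"
FEMALE = "F"


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate id, sex conflict)."""


@dataclass
class Pedigree:
    """A validated set of (id, sire, dam, sex, year) records.

    Unknown parents are ``None``. Sex is ``"M"``/``"F"`` or ``None``; birth
    year is an int or ``None``. Construct through :func:`build_pedigree`,
    which checks acyclicity, id uniqueness and sex consistency.
    """

    records: pd.DataFrame  # columns: id, sire, dam, sex, year

    def __post_init__(self) -> None:
        self._sire = dict(zip(self.records["id"], self.records["sire"]))
        self._dam = dict(zip(self.records["id"], self.records["dam"]))
        self._sex = dict(zip(self.records["id"], self.records["sex"]))
        self._year = dict(zip(self.records["id"], self.records["year"]))

    @property
    def ids(self) -> list[str]:
        return list(self.records["id"])

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, iid: str) -> bool:
        return iid in self._sire

    def sire(self, iid: str) -> str | None:
        return self._sire[iid]

    def dam(self, iid: str) -> str | None:
        return self._dam[iid]

    def sex(self, iid: str) -> str | None:
        return self._sex[iid]

    def year(self, iid: str) -> int | None:
        return self._year[iid]

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        return self._sire[iid], self._dam[iid]

    def is_founder(self, iid: str) -> bool:
        return self._sire[iid] is None and self._dam[iid] is None

    def offspring(self, iid: str) -> list[str]:
        rec = self.records
        mask = (rec["sire"] == iid) | (rec["dam"] == iid)
        return list(rec.loc[mask, "id"])

    def ancestors(self, iid: str, max_generations: int | None = None) -> set[str]:
        """Strict ancestor closure of ``iid``, optionally depth-truncated."""
        out: set[str] = set()
        frontier = [iid]
        depth = 0
        while frontier and (max_generations is None or depth < max_generations):
            nxt = []
            for x in frontier:
                for p in self.parents(x):
                    if p is not None and p not in out:
                        out.add(p)
                        nxt.append(p)
            frontier = nxt
            depth += 1
        return out

    def descendants(self, iid: str) -> set[str]:
        out: set[str] = set()
        frontier = [iid]
        while frontier:
            nxt = []
            for x in frontier:
                for c in self.offspring(x):
                    if c not in out:
                        out.add(c)
                        nxt.append(c)
            frontier = nxt
        return out


def _norm(value) -> str | None:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    s = str(value).strip()
    return s if s not in ("", "0", "nan", "None") else None


def build_pedigree(records: Iterable[Mapping] | pd.DataFrame) -> Pedigree:
    """Validate raw pedigree records and return a :class:`Pedigree`.

    Raises :class:`PedigreeError` for duplicate ids, parent-offspring cycles,
    or sex conflicts (an id used as sire but recorded/used as female, etc.).
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records))
    rec = records.copy()
    for col, default in (("sire", None), ("dam", None), ("sex", None), ("year", None)):
        if col not in rec.columns:
            rec[col] = default
    rec["id"] = rec["id"].map(str)
    rec["sire"] = rec["sire"].map(_norm)
    rec["dam"] = rec["dam"].map(_norm)
    rec["sex"] = rec["sex"].map(lambda v: _norm(v))
    rec["year"] = rec["year"].map(lambda v: None if _norm(v) is None else int(float(v)))

    dup = rec["id"][rec["id"].duplicated()].tolist()
    if dup:
        raise PedigreeError(f"duplicate pedigree ids: {sorted(set(dup))}")

    known = set(rec["id"])
    # Parents referenced but not listed become implicit founders.
    implicit = []
    for col, sex in (("sire", MALE), ("dam", FEMALE)):
        for p in rec[col].dropna().unique():
            if p not in known:
                implicit.append({"id": p, "sire": None, "dam": None, "sex": sex, "year": None})
                known.add(p)
    if implicit:
        rec = pd.concat([rec, pd.DataFrame(implicit)], ignore_index=True)

    # Sex consistency: usage as sire/dam must agree with declared sex.
    declared = dict(zip(rec["id"], rec["sex"]))
    for col, sex, word in (("sire", MALE, "male"), ("dam", FEMALE, "female")):
        for p in rec[col].dropna().unique():
            d = declared.get(p)
            if d is not None and d != sex:
                raise PedigreeError(f"sex conflict: {p} used as {col} but recorded as {d!r}")
            declared[p] = sex
    rec["sex"] = rec["id"].map(declared)

    g = nx.DiGraph()
    g.add_nodes_from(rec["id"])
    for _, row in rec.iterrows():
        for p in (row["sire"], row["dam"]):
            if p is not None:
                g.add_edge(p, row["id"])
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
        raise PedigreeError(f"pedigree contains a cycle: {path}")

    rec = rec[["id", "sire", "dam", "sex", "year"]].reset_index(drop=True)
    return Pedigree(rec)


def _ancestor_closure(ped: Pedigree, subset: Sequence[str], max_generations: int) -> list[str]:
    """Subset plus its ancestors to ``max_generations``, parents-first order."""
    keep: set[str] = set(subset)
    for iid in subset:
        keep |= ped.ancestors(iid, max_generations=max_generations)
    # Topological order (parents before offspring) restricted to `keep`;
    # a parent outside `keep` is treated as unknown.
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(x: str) -> None:
        stack = [(x, False)]
        while stack:
            node, done = stack.pop()
            if done:
                state[node] = 2
                order.append(node)
                continue
            if state.get(node):
                continue
            state[node] = 1
            stack.append((node, True))
            for p in ped.parents(node):
                if p is not None and p in keep and not state.get(p):
                    stack.append((p, False))

    for iid in keep:
        visit(iid)
    return order


def additive_relationship(
    ped: Pedigree,
    subset: Sequence[str] | None = None,
    max_generations: int = 15,
) -> pd.DataFrame:
    """Numerator relationship matrix A by the recursive tabular method.

    The computation runs over the ancestor closure of ``subset`` truncated at
    ``max_generations``; ancestors beyond the truncation horizon are treated
    as unknown unrelated founders. Kinship is A/2 and the diagonal is 1 + F
    with F the inbreeding coefficient.
    """
    if max_generations < 1:
        raise ValueError("max_generations must be >= 1")
    if subset is None:
        subset = ped.ids
    subset = [str(s) for s in subset]
    missing = [s for s in subset if s not in ped]
    if missing:
        raise KeyError(f"ids not in pedigree: {missing}")

    order = _ancestor_closure(ped, subset, max_generations)
    idx = {iid: i for i, iid in enumerate(order)}
    keep = set(order)
    n = len(order)
    a = np.zeros((n, n))
    for j, iid in enumerate(order):
        s, d = ped.parents(iid)
        si = idx[s] if (s in keep and s is not None) else None
        di = idx[d] if (d in keep and d is not None) else None
        # Cross terms with all previously tabulated individuals.
        if si is not None or di is not None:
            row = np.zeros(j)
            if si is not None:
                row += a[si, :j]
            if di is not None:
                row += a[di, :j]
            a[j, :j] = a[:j, j] = 0.5 * row
        a[j, j] = 1.0 + (0.5 * a[si, di] if (si is not None and di is not None) else 0.0)
    sel = [idx[s] for s in subset]
    return pd.DataFrame(a[np.ix_(sel, sel)], index=subset, columns=subset)


def relation_category(ped: Pedigree, a: str, b: str) -> set[str]:
    """All pedigree relationship categories of ``a`` viewed from ``a`` toward ``b``.

    Categories: parent, offspring, full-sib, half-sib, grandparent,
    great-grandparent, grandchild, avuncular (a is a full or half sibling of a
    parent of b). A pair can satisfy several categories at once.
    """
    for x in (a, b):
        if x not in ped:
            raise KeyError(f"id not in pedigree: {x}")
    if a == b:
        raise ValueError("relation_category requires two distinct individuals")
    out: set[str] = set()
    sb, db = ped.parents(b)
    sa, da = ped.parents(a)
    if a in (sb, db):
        out.add("parent")
    if b in (sa, da):
        out.add("offspring")

    def parents_of(x: str | None) -> tuple[str | None, str | None]:
        return ped.parents(x) if x is not None else (None, None)

    pa = {p for p in (sa, da) if p is not None}
    pb = {p for p in (sb, db) if p is not None}
    shared = pa & pb
    if pa and pb and "parent" not in out and "offspring" not in out:
        if len(shared) == 2:
            out.add("full-sib")
        elif len(shared) == 1:
            out.add("half-sib")

    grandparents_b = {g for p in pb for g in parents_of(p) if g is not None}
    if a in grandparents_b:
        out.add("grandparent")
    ggparents_b = {g for gp in grandparents_b for g in parents_of(gp) if g is not None}
    if a in ggparents_b:
        out.add("great-grandparent")
    grandparents_a = {g for p in pa for g in parents_of(p) if g is not None}
    if b in grandparents_a:
        out.add("grandchild")
    # Avuncular: a is a (half-)sibling of a parent of b.
    for p in pb:
        if p == a:
            continue
        pp = {x for x in parents_of(p) if x is not None}
        if pa and pp and (pa & pp) and p not in (sa, da) and a not in parents_of(p):
            out.add("avuncular")
    return out


@dataclass
class StatusAssignment:
    """Per-individual cohort status with phenotype codes and exclusion reasons.

    ``status`` maps each genotyped id to one of case / carrier / control /
    excluded_relative / excluded_diagnosis. ``y`` is the quantitative code
    (2 case, 1 carrier, 0 control), defined only for retained dogs;
    ``binary`` is 1 for cases and 0 for controls with carriers absent.
    """

    status: dict[str, str]
    y: dict[str, int]
    binary: dict[str, int]
    reason: dict[str, str] = field(default_factory=dict)

    def ids_with(self, *statuses: str) -> list[str]:
        return [i for i, s in self.status.items() if s in statuses]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.status.values():
            out[s] = out.get(s, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for iid in sorted(self.status):
            rows.append(
                {
                    "id": iid,
                    "status": self.status[iid],
                    "y": self.y.get(iid, ""),
                    "reason": self.reason.get(iid, ""),
                }
            )
        return pd.DataFrame(rows, columns=["id", "status", "y", "reason"])


def classify_cohort(
    ped: Pedigree,
    case_ids: Sequence[str],
    genotyped_ids: Sequence[str],
    diagnoses: Mapping[str, str] | None = None,
    pihat: pd.DataFrame | None = None,
    pihat_cutoff: float = 0.25,
    exclude_t_cell: bool = True,
) -> StatusAssignment:
    """Assign case / carrier / control / excluded status to genotyped dogs.

    Rule order (carrier rules take precedence over exclusion rules):

    1. cases with an ambiguous diagnosis (``diagnoses[id] == "ambiguous"``)
       are dropped as ``excluded_diagnosis``;
    2. optionally, T-cell cases (``diagnoses[id] == "T"``) are dropped the
       same way;
    3. remaining confirmed cases are ``case``;
    4. genotyped non-cases that are a parent of >=1 case, an offspring of
       >=1 case, or a grandparent/great-grandparent of >=2 cases are
       ``carrier``;
    5. remaining dogs that are a sibling/half-sibling, grandchild, or
       aunt/uncle of a case, a (great-)grandparent of exactly one case, or
       that have PIHAT > ``pihat_cutoff`` with any genotyped case, are
       ``excluded_relative``;
    6. everything else is ``control``.

    Ungenotyped cases still drive rules 4–5 (carrier positions are defined by
    the full pedigree, not just the genotyped cohort) but do not appear in
    the output.
    """
    diagnoses = dict(diagnoses or {})
    case_ids = [str(c) for c in case_ids]
    genotyped = [str(g) for g in genotyped_ids]
    genoset = set(genotyped)

    status: dict[str, str] = {}
    reason: dict[str, str] = {}

    active_cases: list[str] = []
    for c in case_ids:
        dx = diagnoses.get(c, "confirmed")
        if dx == "ambiguous":
            if c in genoset:
                status[c] = "excluded_diagnosis"
                reason[c] = "ambiguous diagnosis (stage-V lymphoma vs ALL)"
            continue
        if exclude_t_cell and dx == "T":
            if c in genoset:
                status[c] = "excluded_diagnosis"
                reason[c] = "T-cell immunophenotype"
            continue
        active_cases.append(c)

    for c in active_cases:
        if c in genoset:
            status[c] = "case"

    ped_cases = [c for c in active_cases if c in ped]

    def case_relation_counts(iid: str) -> dict[str, int]:
        counts = {k: 0 for k in ("parent", "offspring", "grandparent", "great-grandparent",
                                 "full-sib", "half-sib", "grandchild", "avuncular")}
        for c in ped_cases:
            if c == iid:
                continue
            try:
                cats = relation_category(ped, iid, c)
            except KeyError:
                continue
            for k in counts:
                if k in cats:
                    counts[k] += 1
        return counts

    pihat_max: dict[str, float] = {}
    if pihat is not None and len(pihat):
        geno_cases = {c for c in active_cases if c in genoset}
        for _, row in pihat.iterrows():
            i, j, ph = str(row["ID1"]), str(row["ID2"]), float(row["PI_HAT"])
            for x, other in ((i, j), (j, i)):
                if other in geno_cases and x not in geno_cases:
                    pihat_max[x] = max(pihat_max.get(x, 0.0), ph)

    for iid in genotyped:
        if iid in status:
            continue
        counts = case_relation_counts(iid) if iid in ped else None
        if counts is not None:
            if counts["parent"] >= 1 or counts["offspring"] >= 1:
                status[iid] = "carrier"
                which = "parent" if counts["parent"] else "offspring"
                reason[iid] = f"{which} of a case"
                continue
            n_gp = counts["grandparent"] + counts["great-grandparent"]
            if n_gp >= 2:
                status[iid] = "carrier"
                reason[iid] = "(great-)grandparent of >=2 cases"
                continue
            if counts["full-sib"] or counts["half-sib"]:
                status[iid] = "excluded_relative"
                reason[iid] = "sibling of a case"
                continue
            if counts["grandchild"]:
                status[iid] = "excluded_relative"
                reason[iid] = "grandchild of a case"
                continue
            if counts["avuncular"]:
                status[iid] = "excluded_relative"
                reason[iid] = "aunt/uncle of a case"
                continue
            if n_gp == 1:
                status[iid] = "excluded_relative"
                reason[iid] = "(great-)grandparent of exactly one case"
                continue
        if pihat_max.get(iid, 0.0) > pihat_cutoff:
            status[iid] = "excluded_relative"
            reason[iid] = f"pihat {pihat_max[iid]:.3f} > {pihat_cutoff} with a case"
            continue
        status[iid] = "control"

    y = {i: {"case": 2, "carrier": 1, "control": 0}[s] for i, s in status.items()
         if s in ("case", "carrier", "control")}
    binary = {i: (1 if s == "case" else 0) for i, s in status.items()
              if s in ("case", "control")}
    return StatusAssignment(status=status, y=y, binary=binary, reason=reason)


def common_ancestors(
    ped: Pedigree,
    case_ids: Sequence[str],
    max_generations: int | None = None,
) -> pd.DataFrame:
    """Ancestors shared by every listed case, ranked for reporting.

    Returns a DataFrame (ancestor id, birth year, total path length across
    cases, number of listed cases descending from the ancestor), sorted by
    birth year (oldest first, unknown years last), then minimum total path
    length, then id. Empty if the cases share no ancestor.
    """
    case_ids = [str(c) for c in case_ids if str(c) in ped]
    if len(case_ids) < 2:
        raise ValueError("need >=2 cases with pedigree links")
    closures = [ped.ancestors(c, max_generations=max_generations) for c in case_ids]
    shared = set.intersection(*closures)
    if not shared:
        return pd.DataFrame(columns=["id", "year", "total_path_length", "n_cases_descended"])

    # Generation distance from each case up to each shared ancestor (BFS).
    def depths(c: str) -> dict[str, int]:
        d = {c: 0}
        frontier = [c]
        while frontier:
            nxt = []
            for x in frontier:
                for p in ped.parents(x):
                    if p is not None and p not in d:
                        d[p] = d[x] + 1
                        nxt.append(p)
            frontier = nxt
        return d

    per_case = [depths(c) for c in case_ids]
    rows = []
    for anc in shared:
        total = sum(d[anc] for d in per_case)
        rows.append(
            {
                "id": anc,
                "year": ped.year(anc),
                "total_path_length": total,
                "n_cases_descended": len(case_ids),
            }
        )
    out = pd.DataFrame(rows)
    out["_year"] = out["year"].map(lambda v: np.inf if v is None else v)
    out = out.sort_values(["_year", "total_path_length", "id"]).drop(columns="_year")
    return out.reset_index(drop=True)
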