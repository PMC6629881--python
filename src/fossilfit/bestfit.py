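"""Best-fit placement of a partially observed fossil in trait-range tables.

The rule: a fossil is attributed to the extant group(s) — tribes, then
genera within candidate tribes — whose pooled per-group character ranges are
compatible with *every one* of the fossil's observed characters (a "100%
fit"). Compatibility is set intersection: an observed value or interval fits
a reference range iff they overlap. Traits the reference table does not
record for a group are "unknown" and excluded from both numerator and
denominator; a group compared on zero traits is "indeterminate", never a
candidate.

Reference ranges are pooled over all modern species of a group, so a state
that occurs in only a minority of species still belongs to the group's set
(presence suffices for fit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "TraitRange",
    "GroupProfile",
    "ReferenceTraitTable",
    "FossilObservation",
    "FitReport",
    "overlaps",
    "fit_report",
    "hierarchical_assign",
    "comparison_table",
    "read_reference_table",
    "write_reference_table",
    "read_fossil_observation",
]

FIT, NO_FIT, PARTIAL, UNKNOWN = "fit", "no-fit", "partial", "unknown"


@dataclass(frozen=True)
class TraitRange:
    """A group's pooled range for one trait.

    kind: ``interval`` (integer lo..hi), ``int_set`` (explicit integer set)
    or ``cat_set`` (categorical value set). ``partial`` marks ranges whose
    fit should be displayed as "(+)" — compatible but with a caveat.
    """

    kind: str
    lo: float | None = None
    hi: float | None = None
    members: frozenset = frozenset()
    provenance: str = ""
    partial: bool = False

    def __post_init__(self) -> None:
        if self.kind == "interval":
            if self.lo is None or self.hi is None or self.lo > self.hi:
                raise ValueError(f"interval needs lo <= hi, got {self.lo}..{self.hi}")
        elif self.kind in ("int_set", "cat_set"):
            if not self.members:
                raise ValueError(f"{self.kind} needs non-empty members")
        else:
            raise ValueError(f"unknown trait kind {self.kind!r}")

    @classmethod
    def interval(cls, lo, hi, provenance="", partial=False) -> "TraitRange":
        return cls("interval", lo=lo, hi=hi, provenance=provenance, partial=partial)

    @classmethod
    def int_set(cls, members, provenance="", partial=False) -> "TraitRange":
        return cls("int_set", members=frozenset(members), provenance=provenance, partial=partial)

    @classmethod
    def cat_set(cls, members, provenance="", partial=False) -> "TraitRange":
        return cls("cat_set", members=frozenset(members), provenance=provenance, partial=partial)


@dataclass
class GroupProfile:
    name: str
    n_species: int = 0
    traits: dict = field(default_factory=dict)  # trait name -> TraitRange


@dataclass
class ReferenceTraitTable:
    """Per-group trait ranges at one taxonomic level (tribe or genus)."""

    level: str  # "tribe" | "genus"
    groups: list  # of GroupProfile

    def __post_init__(self) -> None:
        if self.level not in ("tribe", "genus"):
            raise ValueError("level must be 'tribe' or 'genus'")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")

    @property
    def vocabulary(self) -> set:
        vocab = set()
        for g in self.groups:
            vocab |= set(g.traits)
        return vocab

    def group(self, name: str) -> GroupProfile:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)


@dataclass
class FossilObservation:
    """Observed trait values of the query taxon; unobserved traits absent.

    Values may be scalars, ``(lo, hi)`` intervals, or categorical strings /
    sets of strings.
    """

    traits: dict

    def validate_against(self, table: ReferenceTraitTable) -> None:
        unknown = set(self.traits) - table.vocabulary
        if unknown:
            raise ValueError(
                f"observed trait(s) {sorted(unknown)} absent from reference vocabulary"
            )


def _as_interval(value):
    if isinstance(value, tuple) and len(value) == 2:
        lo, hi = value
    else:
        lo = hi = value
    if lo > hi:
        raise ValueError(f"observed interval {value} has lo > hi")
    return lo, hi


def overlaps(obs, ref: TraitRange, trait: str = "") -> str:
    """``fit``/``partial`` iff the observation intersects the reference range."""
    label = f" for trait {trait!r}" if trait else ""
    if ref.kind == "cat_set":
        if isinstance(obs, (int, float, tuple)):
            raise TypeError(f"categorical reference vs numeric observation{label}")
        obs_set = {obs} if isinstance(obs, str) else set(obs)
        hit = bool(obs_set & ref.members)
    else:
        if isinstance(obs, str) or (
            isinstance(obs, (set, frozenset)) and any(isinstance(x, str) for x in obs)
        ):
            raise TypeError(f"numeric reference vs categorical observation{label}")
        lo, hi = _as_interval(obs)
        if ref.kind == "interval":
            hit = lo <= ref.hi and hi >= ref.lo
        else:  # int_set
            hit = any(lo <= m <= hi for m in ref.members)
    if not hit:
        return NO_FIT
    return PARTIAL if ref.partial else FIT


@dataclass
class GroupVerdict:
    name: str
    per_trait: dict  # trait -> fit | partial | no-fit | unknown
    n_observed_compared: int
    fit_fraction: float | None  # None when indeterminate

    @property
    def indeterminate(self) -> bool:
        return self.n_observed_compared == 0

    @property
    def is_candidate(self) -> bool:
        return not self.indeterminate and self.fit_fraction == 1.0


@dataclass
class FitReport:
    level: str
    verdicts: list  # of GroupVerdict

    @property
    def candidates(self) -> list:
        return [v.name for v in self.verdicts if v.is_candidate]

    def verdict(self, name: str) -> GroupVerdict:
        for v in self.verdicts:
            if v.name == name:
                return v
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.verdicts:
            row = {"group": v.name, "n_compared": v.n_observed_compared,
                   "fit_fraction": v.fit_fraction,
                   "candidate": v.is_candidate}
            row.update(v.per_trait)
            rows.append(row)
        return pd.DataFrame(rows)


def fit_report(fossil: FossilObservation, table: ReferenceTraitTable) -> FitReport:
    """Score the fossil against every group; candidates fit on all compared traits."""
    if not table.groups:
        raise ValueError("empty reference table")
    fossil.validate_against(table)
    verdicts = []
    for group in table.groups:
        per_trait, n_cmp, n_fit = {}, 0, 0
        for trait, obs in fossil.traits.items():
            ref = group.traits.get(trait)
            if ref is None:
                per_trait[trait] = UNKNOWN
                continue
            verdict = overlaps(obs, ref, trait=trait)
            per_trait[trait] = verdict
            n_cmp += 1
            if verdict in (FIT, PARTIAL):
                n_fit += 1
        verdicts.append(
            GroupVerdict(
                name=group.name,
                per_trait=per_trait,
                n_observed_compared=n_cmp,
                fit_fraction=(n_fit / n_cmp) if n_cmp else None,
            )
        )
    return FitReport(level=table.level, verdicts=verdicts)


@dataclass
class HierarchicalAssignment:
    tribe_report: FitReport
    tribe_candidates: list
    genus_reports: dict  # tribe -> FitReport
    genus_candidates: dict  # tribe -> list of genera (or None = unresolved)

    @property
    def unresolved_tribes(self) -> list:
        return [t for t, g in self.genus_candidates.items() if g is None]


def hierarchical_assign(
    fossil: FossilObservation,
    tribe_table: ReferenceTraitTable,
    genus_tables: dict | None = None,
) -> HierarchicalAssignment:
    """Tribe-level best fit, then genus-level within each candidate tribe.

    A candidate tribe without a genus table is reported as unresolved below
    tribe level rather than erroring.
    """
    genus_tables = genus_tables or {}
    tribe_report = fit_report(fossil, tribe_table)
    genus_reports, genus_candidates = {}, {}
    for tribe in tribe_report.candidates:
        table = genus_tables.get(tribe)
        if table is None:
            genus_candidates[tribe] = None
            continue
        # only the traits present in this table's vocabulary are comparable
        sub = FossilObservation(
            {k: v for k, v in fossil.traits.items() if k in table.vocabulary}
        )
        rep = fit_report(sub, table) if sub.traits else FitReport(table.level, [])
        genus_reports[tribe] = rep
        genus_candidates[tribe] = rep.candidates
    return HierarchicalAssignment(
        tribe_report=tribe_report,
        tribe_candidates=tribe_report.candidates,
        genus_reports=genus_reports,
        genus_candidates=genus_candidates,
    )


_SYMBOL = {FIT: "+", PARTIAL: "(+)", NO_FIT: "-", UNKNOWN: "?"}


def comparison_table(
    fossil: FossilObservation, named_groups: list, table: ReferenceTraitTable
) -> pd.DataFrame:
    """Character-by-character +/−/(+)/? grid for the fossil vs named groups."""
    for name in named_groups:
        table.group(name)  # raises KeyError if absent
    report = fit_report(fossil, table)
    traits = list(fossil.traits)
    data = {"trait": traits}
    for name in named_groups:
        v = report.verdict(name)
        data[name] = [_SYMBOL[v.per_trait[t]] for t in traits]
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Delimited I/O
# ---------------------------------------------------------------------------
# Reference table TSV header:
#   level  group  n_species  trait  kind  lo  hi  members  partial  provenance
# 'members' is comma-separated; 'kind' in {interval, int_set, cat_set}.

def read_reference_table(path) -> ReferenceTraitTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    levels = set(df["level"])
    if len(levels) != 1:
        raise ValueError(f"reference table mixes levels: {sorted(levels)}")
    groups: dict = {}
    for _, row in df.iterrows():
        g = groups.setdefault(
            row["group"],
            GroupProfile(name=row["group"], n_species=int(row["n_species"] or 0)),
        )
        kind = row["kind"]
        partial = row.get("partial", "") in ("1", "true", "True", "yes")
        prov = row.get("provenance", "")
        if kind == "interval":
            tr = TraitRange.interval(float(row["lo"]), float(row["hi"]), prov, partial)
        elif kind == "int_set":
            members = [int(x) for x in row["members"].split(",") if x != ""]
            tr = TraitRange.int_set(members, prov, partial)
        elif kind == "cat_set":
            members = [x.strip() for x in row["members"].split(",") if x.strip()]
            tr = TraitRange.cat_set(members, prov, partial)
        elif kind in ("", "unknown"):
            continue  # explicit unknown entry
        else:
            raise ValueError(f"unknown trait kind {kind!r} for trait {row['trait']!r}")
        g.traits[row["trait"]] = tr
    return ReferenceTraitTable(level=levels.pop(), groups=list(groups.values()))


def write_reference_table(table: ReferenceTraitTable, path) -> None:
    rows = []
    for g in table.groups:
        for trait, tr in g.traits.items():
            rows.append(
                {
                    "level": table.level,
                    "group": g.name,
                    "n_species": g.n_species,
                    "trait": trait,
                    "kind": tr.kind,
                    "lo": "" if tr.lo is None else tr.lo,
                    "hi": "" if tr.hi is None else tr.hi,
                    "members": ",".join(str(m) for m in sorted(tr.members)),
                    "partial": int(tr.partial),
                    "provenance": tr.provenance,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fossil_observation(path) -> FossilObservation:
    """TSV with columns trait, kind, lo, hi, members (same dialect as above)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    traits: dict = {}
    for _, row in df.iterrows():
        kind = row["kind"]
        if kind == "interval":
            lo, hi = float(row["lo"]), float(row["hi"])
            traits[row["trait"]] = lo if lo == hi else (lo, hi)
        elif kind == "int_set":
            members = [int(x) for x in row["members"].split(",") if x != ""]
            traits[row["trait"]] = members[0] if len(members) == 1 else (
                min(members), max(members))
        elif kind == "cat_set":
            members = {x.strip() for x in row["members"].split(",") if x.strip()}
            traits[row["trait"]] = next(iter(members)) if len(members) == 1 else members
        else:
            raise ValueError(f"unknown kind {kind!r} for trait {row['trait']!r}")
    return FossilObservation(traits=traits)
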