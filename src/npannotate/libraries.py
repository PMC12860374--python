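"""Predictive candidate libraries: known compounds, "A + nB" combinations,
and diagnostic-ion / neutral-loss signature libraries.

Three kinds of knowledge base drive annotation:

* a **known-compound library** (name, formula, structural class) expanded to
  precursor m/z values over a configurable adduct set;
* a **combinatorial library** built by attaching 0..n_max group fragments
  (sugars, acyls, methyls, ...) to each parent compound, covering plausible
  but unreported derivatives;
* a **signature library** of class-specific diagnostic MS2 ions and neutral
  losses used for in-source-fragment exclusion and class assignment.

All three persist as small CSV files; curated defaults ship with the package
under ``npannotate/data``.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations, combinations_with_replacement
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .chem import (
    ATOMIC_MASS,
    COMBINATORIAL_ADDUCTS,
    NEGATIVE_ADDUCTS,
    POSITIVE_ADDUCTS,
    AdductSpec,
    Formula,
    adduct_mz,
    get_adduct,
    parse_formula,
    round_mass,
)

log = logging.getLogger(__name__)

#: Controlled vocabulary of structural classes.
COMPOUND_CLASSES = frozenset(
    {
        "flavonol",
        "phenolic acid",
        "lignan",
        "phospholipid",
        "resin glycoside",
        "alkaloid",
        "oligosaccharide",
        "fatty acid",
        "other",
    }
)

DEFAULT_MASS_RANGE = (50.0, 1500.0)  # Da, mirrors the acquisition range


@dataclass(frozen=True)
class CompoundRecord:
    """A known compound: name, neutral formula and structural class."""

    name: str
    formula: Formula
    compound_class: str
    source: str = ""
    is_standard: bool = False

    def __post_init__(self) -> None:
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValueError(
                f"unknown compound class {self.compound_class!r} for {self.name!r}"
            )
        if not self.formula:
            raise ValueError(f"empty formula for compound {self.name!r}")


@dataclass(frozen=True)
class GroupFragment:
    """A substituent added by the "A + nB" algorithm.

    ``delta`` is the net formula change on attachment (the dehydrated
    residue, e.g. hexosyl C6H10O5, not the free sugar).
    """

    name: str
    delta: Formula
    classes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.delta.mass <= 0:
            raise ValueError(f"group {self.name!r} must have positive mass delta")
        unknown = self.classes - COMPOUND_CLASSES
        if unknown:
            raise ValueError(f"group {self.name!r}: unknown classes {sorted(unknown)}")

    def applies_to(self, compound_class: str) -> bool:
        return not self.classes or compound_class in self.classes


@dataclass(frozen=True)
class CandidateRecord:
    """A parent plus a multiset of attached groups, with precursor m/z values."""

    parent: str
    groups: tuple[str, ...]  # sorted group names, with repetition
    formula: Formula
    compound_class: str
    mz: dict[str, float] = field(default_factory=dict)  # adduct name -> m/z
    is_standard: bool = False

    @property
    def name(self) -> str:
        if not self.groups:
            return self.parent
        parts = []
        seen: dict[str, int] = {}
        for g in self.groups:
            seen[g] = seen.get(g, 0) + 1
        for g in sorted(seen):
            n = seen[g]
            parts.append(f"+{n}{g}" if n > 1 else f"+{g}")
        return self.parent + "".join(parts)

    def __hash__(self) -> int:
        return hash((self.parent, self.groups))


@dataclass
class CombinatorialConfig:
    """Settings for the "A + nB" generator."""

    n_max: int = 5
    repetition: bool = True
    adducts: Sequence[str] = COMBINATORIAL_ADDUCTS
    mass_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_max < 0:
            raise ValueError("n_max must be >= 0")


# ---------------------------------------------------------------------------
# compound library

def _read_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def load_compound_library(path: str | Path) -> list[CompoundRecord]:
    """Read a compound CSV (columns: name, formula, class[, source, standard])."""
    df = _read_csv(path)
    required = {"name", "formula", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"compound CSV {path}: missing columns {sorted(missing)}")
    records: list[CompoundRecord] = []
    seen: set[tuple[str, str]] = set()
    for d in df.to_dict("records"):
        name = str(d["name"]).strip()
        formula = parse_formula(str(d["formula"]))
        key = (name, str(formula))
        if key in seen:
            log.warning("duplicate compound row dropped: %s (%s)", name, formula)
            continue
        seen.add(key)
        source = d.get("source", "")
        standard = d.get("standard", 0)
        records.append(
            CompoundRecord(
                name=name,
                formula=formula,
                compound_class=str(d["class"]).strip(),
                source="" if pd.isna(source) else str(source),
                is_standard=bool(int(0 if pd.isna(standard) else standard)),
            )
        )
    return records


def load_group_library(path: str | Path) -> list[GroupFragment]:
    """Read a group-fragment CSV (columns: name, formula, classes).

    ``classes`` is a ``;``-separated list; empty means the group attaches to
    any parent class.
    """
    df = _read_csv(path)
    missing = {"name", "formula"} - set(df.columns)
    if missing:
        raise ValueError(f"group CSV {path}: missing columns {sorted(missing)}")
    groups = []
    for d in df.to_dict("records"):
        raw = d.get("classes", "")
        if raw is None or pd.isna(raw):
            raw = ""
        classes = frozenset(c.strip() for c in str(raw).split(";") if c.strip())
        groups.append(
            GroupFragment(
                name=str(d["name"]).strip(),
                delta=parse_formula(str(d["formula"])),
                classes=classes,
            )
        )
    return groups


# ---------------------------------------------------------------------------
# precursor index

class PrecursorIndex:
    """Sorted m/z index over (candidate, adduct) entries with window queries."""

    def __init__(self, entries: Iterable[tuple[float, object, str]]):
        # entries: (mz, record, adduct name)
        self._entries = sorted(entries, key=lambda e: (e[0], getattr(e[1], "name", ""), e[2]))
        self._mz = [e[0] for e in self._entries]

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def query(self, mz: float, tol: float) -> list[tuple[float, object, str]]:
        """All entries with |entry.mz - mz| <= tol, in library order."""
        lo = bisect.bisect_left(self._mz, mz - tol)
        hi = bisect.bisect_right(self._mz, mz + tol)
        return self._entries[lo:hi]


def expand_precursors(
    records: Sequence[CompoundRecord | CandidateRecord],
    adducts: Sequence[str] | None = None,
    polarity: str | None = None,
) -> PrecursorIndex:
    """One index entry per (record, adduct).

    When ``adducts`` is None the full five-adduct set is used, optionally
    restricted to one polarity.
    """
    if adducts is None:
        adducts = POSITIVE_ADDUCTS + NEGATIVE_ADDUCTS
    specs = [get_adduct(a) for a in adducts]
    if polarity is not None:
        specs = [s for s in specs if s.polarity == polarity]
    entries = []
    for rec in records:
        for spec in specs:
            entries.append((adduct_mz(rec.formula, spec), rec, spec.name))
    return PrecursorIndex(entries)


# ---------------------------------------------------------------------------
# "A + nB" combinatorial generator

def count_combinations(p: int, g: int, n_max: int, repetition: bool = True) -> int:
    """Closed-form size of the combinatorial library.

    With repetition: ``p * sum_{i=0..n_max} C(g+i-1, i)``; without:
    ``p * sum_{i=0..min(n_max,g)} C(g, i)``.
    """
    if min(p, g, n_max) < 0:
        raise ValueError("arguments must be non-negative")
    if repetition:
        # i = 0 contributes the bare parent even when there are no groups
        total = 1 + sum(math.comb(g + i - 1, i) for i in range(1, n_max + 1))
    else:
        total = sum(math.comb(g, i) for i in range(min(n_max, g) + 1))
    return p * total


def generate_combinations(
    parents: Sequence[CompoundRecord],
    groups: Sequence[GroupFragment],
    cfg: CombinatorialConfig | None = None,
) -> list[CandidateRecord]:
    """Enumerate parent + 0..n_max group-fragment multisets.

    Groups attach only to parents of a compatible class.  Output order is
    deterministic: parents in input order, then multiset size, then
    lexicographic group-name order.
    """
    cfg = cfg or CombinatorialConfig()
    chooser = combinations_with_replacement if cfg.repetition else combinations
    out: list[CandidateRecord] = []
    for parent in parents:
        usable = sorted(
            (g for g in groups if g.applies_to(parent.compound_class)),
            key=lambda g: g.name,
        )
        for size in range(cfg.n_max + 1):
            for combo in chooser(usable, size):
                formula = parent.formula
                for g in combo:
                    formula = formula + g.delta
                if cfg.mass_range is not None:
                    lo, hi = cfg.mass_range
                    if not (lo <= formula.mass <= hi):
                        continue
                mz = {a: adduct_mz(formula, a) for a in cfg.adducts}
                out.append(
                    CandidateRecord(
                        parent=parent.name,
                        groups=tuple(g.name for g in combo),
                        formula=formula,
                        compound_class=parent.compound_class,
                        mz=mz,
                        is_standard=parent.is_standard and not combo,
                    )
                )
    return out


def write_candidates_csv(candidates: Sequence[CandidateRecord], path: str | Path) -> None:
    """Export candidates with one m/z column per adduct."""
    adduct_names: list[str] = []
    for c in candidates:
        for a in c.mz:
            if a not in adduct_names:
                adduct_names.append(a)
    rows = []
    for c in candidates:
        row = {
            "name": c.name,
            "parent": c.parent,
            "groups": ";".join(c.groups),
            "formula": str(c.formula),
            "class": c.compound_class,
            "neutral_mass": round_mass(c.formula.mass),
        }
        for a in adduct_names:
            row[f"mz {a}"] = round_mass(c.mz[a]) if a in c.mz else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# signature library

@dataclass(frozen=True)
class SignatureEntry:
    """One diagnostic ion or neutral loss.

    For a diagnostic ion ``mass`` is the ion m/z ([M-H]- or [M+H]+ of the
    stated neutral formula, per polarity); for a neutral loss it is the plain
    monoisotopic mass of the lost moiety.
    """

    name: str
    kind: str  # "diagnostic" | "neutral_loss"
    polarity: str  # "positive" | "negative" | "both"
    mass: float
    compound_class: str
    formula: Formula | None = None

    def matches_polarity(self, polarity: str) -> bool:
        return self.polarity == "both" or self.polarity == polarity


class SignatureLibrary:
    """Class-tagged diagnostic ions and neutral losses."""

    def __init__(self, entries: Iterable[SignatureEntry]):
        self.entries = list(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def diagnostics(self, polarity: str | None = None) -> list[SignatureEntry]:
        return [
            e
            for e in self.entries
            if e.kind == "diagnostic" and (polarity is None or e.matches_polarity(polarity))
        ]

    def neutral_losses(self, polarity: str | None = None) -> list[SignatureEntry]:
        return [
            e
            for e in self.entries
            if e.kind == "neutral_loss" and (polarity is None or e.matches_polarity(polarity))
        ]

    def loss_masses(self) -> list[SignatureEntry]:
        """All neutral-loss entries regardless of polarity tag.

        A neutral loss carries no charge, so in-source Δmass matching
        consults every entry; polarity tags only gate MS2 class scoring.
        """
        return [e for e in self.entries if e.kind == "neutral_loss"]

    def classes(self) -> set[str]:
        return {e.compound_class for e in self.entries}


_H = ATOMIC_MASS["H"]


def _resolve_signature_mass(kind: str, polarity: str, formula: Formula) -> float:
    if kind == "neutral_loss":
        return formula.mass
    if polarity == "negative":
        return formula.mass - _H
    if polarity == "positive":
        return formula.mass + _H
    raise ValueError("a diagnostic ion with a formula needs an explicit polarity")


def load_signature_library(path: str | Path, max_discrepancy_mda: float = 0.5) -> SignatureLibrary:
    """Read a signature CSV (name, kind, polarity, formula, exact_mass, class).

    Either ``formula`` or ``exact_mass`` must be present; when both are
    given the recomputed mass must agree with ``exact_mass`` within
    ``max_discrepancy_mda`` mDa.
    """
    df = _read_csv(path)
    required = {"name", "kind", "polarity", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"signature CSV {path}: missing columns {sorted(missing)}")
    entries = []
    for i, d in enumerate(df.to_dict("records")):
        name = str(d["name"]).strip()
        kind = str(d["kind"]).strip()
        if kind not in ("diagnostic", "neutral_loss"):
            raise ValueError(f"{path} row {i}: kind must be diagnostic|neutral_loss")
        polarity = str(d["polarity"]).strip()
        if polarity not in ("positive", "negative", "both"):
            raise ValueError(f"{path} row {i}: bad polarity {polarity!r}")
        cls = str(d["class"]).strip()
        if cls not in COMPOUND_CLASSES:
            raise ValueError(f"{path} row {i}: unknown class {cls!r}")
        raw_formula = d.get("formula")
        raw_mass = d.get("exact_mass")
        formula = None
        if raw_formula is not None and not pd.isna(raw_formula) and str(raw_formula).strip():
            formula = parse_formula(str(raw_formula))
        stated = None
        if raw_mass is not None and not pd.isna(raw_mass) and str(raw_mass).strip() != "":
            stated = float(raw_mass)
        if formula is None and stated is None:
            raise ValueError(f"{path} row {i} ({name}): needs formula or exact_mass")
        if formula is not None:
            mass = _resolve_signature_mass(kind, polarity, formula)
            if stated is not None and abs(mass - stated) * 1e3 > max_discrepancy_mda:
                raise ValueError(
                    f"{path} row {i} ({name}): formula mass {mass:.4f} disagrees "
                    f"with exact_mass {stated:.4f} by more than "
                    f"{max_discrepancy_mda} mDa"
                )
        else:
            mass = stated  # type: ignore[assignment]
        entries.append(SignatureEntry(name, kind, polarity, mass, cls, formula))
    return SignatureLibrary(entries)


# ---------------------------------------------------------------------------
# packaged defaults

def packaged_data_path(filename: str) -> Path:
    """Path of a CSV shipped under ``npannotate/data``."""
    return Path(resources.files("npannotate").joinpath("data", filename))  # type: ignore[arg-type]


def default_compound_library() -> list[CompoundRecord]:
    return load_compound_library(packaged_data_path("compounds.csv"))


def default_group_library() -> list[GroupFragment]:
    return load_group_library(packaged_data_path("groups.csv"))


def default_signature_library() -> SignatureLibrary:
    return load_signature_library(packaged_data_path("signatures.csv"))


def default_prototypes() -> list[CompoundRecord]:
    return load_compound_library(packaged_data_path("prototypes.csv"))
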