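"""Prototype / phase I-II metabolite annotation of screened markers.

Exogenous markers surviving the chemometric screen are matched against a
combinatorial library of representative absorbed compounds (prototypes)
transformed by common metabolic reactions: reduction/desaturation (+/-2H),
oxidation (+O), (de)methylation (+/-CH2), hydration, sulfation (+SO3,
+79.9568 Da) and glucuronidation (+GluA, +176.0321 Da) -- the dominant
phase II conjugations of dietary phenolics and flavonols -- plus
glucosidation (+Glc).  MS2 confirmation looks for the prototype core ion
among the fragments or a neutral loss equal to the conjugate mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Sequence

import pandas as pd

from .chem import (
    COMBINATORIAL_ADDUCTS,
    Formula,
    FormulaError,
    MassError,
    adduct_mz,
    get_adduct,
    mass_error,
    parse_formula,
)
from .feature_io import DEFAULT_MZ_TOL, Feature, top_k_fragments
from .libraries import CompoundRecord, PrecursorIndex, _read_csv

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReactionSpec:
    """A metabolic transformation as a signed formula change."""

    name: str
    plus: Formula
    minus: Formula
    phase: str  # "I" | "II"
    max_multiplicity: int = 3

    @property
    def delta_mass(self) -> float:
        return self.plus.mass - self.minus.mass

    def apply(self, f: Formula, times: int = 1) -> Formula:
        """Apply the reaction ``times`` times; FormulaError if counts go negative."""
        return (f + self.plus * times) - self.minus * times


def load_reaction_library(path: str | Path) -> list[ReactionSpec]:
    """Read a reaction CSV (name, plus, minus, phase, max_multiplicity)."""
    df = _read_csv(path)
    out = []
    for d in df.to_dict("records"):
        plus = d.get("plus", "")
        minus = d.get("minus", "")
        out.append(
            ReactionSpec(
                name=str(d["name"]).strip(),
                plus=parse_formula(str(plus)) if plus and not pd.isna(plus) else Formula(),
                minus=parse_formula(str(minus)) if minus and not pd.isna(minus) else Formula(),
                phase=str(d["phase"]).strip(),
                max_multiplicity=int(d.get("max_multiplicity", 3)),
            )
        )
    return out


def default_reactions() -> list[ReactionSpec]:
    path = Path(resources.files("npannotate").joinpath("data", "reactions.csv"))  # type: ignore[arg-type]
    return load_reaction_library(path)


@dataclass(frozen=True)
class MetaboliteCandidate:
    """A prototype plus a reaction multiset, with precursor m/z per adduct."""

    prototype: CompoundRecord
    reactions: tuple[str, ...]  # sorted reaction names, with repetition
    formula: Formula
    mz: dict[str, float] = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return len(self.reactions)

    @property
    def name(self) -> str:
        """Display name, e.g. ``Quercetin+2GluA`` or ``Caffeic acid+CH2+SO3``."""
        if not self.reactions:
            return self.prototype.name
        counts: dict[str, int] = {}
        for r in self.reactions:
            counts[r] = counts.get(r, 0) + 1
        parts = []
        for r in sorted(counts):
            n = counts[r]
            sign, base = r[0], r[1:]
            parts.append(f"{sign}{n}{base}" if n > 1 else r)
        return self.prototype.name + "".join(parts)

    def __hash__(self) -> int:
        return hash((self.prototype.name, self.reactions))

    # duck-typing used by Ms1Hit consumers
    @property
    def compound_class(self) -> str:
        return self.prototype.compound_class

    @property
    def is_standard(self) -> bool:
        return False


def build_metabolite_library(
    prototypes: Sequence[CompoundRecord],
    reactions: Sequence[ReactionSpec] | None = None,
    max_steps: int = 3,
    adducts: Sequence[str] = COMBINATORIAL_ADDUCTS,
) -> list[MetaboliteCandidate]:
    """Enumerate all reaction multisets of 0..max_steps on each prototype.

    Per-reaction multiplicity caps are respected; transformations that
    would drive an element count negative are skipped with a debug log.
    Size-0 multisets are the prototypes themselves.
    """
    if max_steps < 0:
        raise ValueError("max_steps must be >= 0")
    reactions = default_reactions() if reactions is None else list(reactions)
    rxn_by_name = {r.name: r for r in reactions}
    out: list[MetaboliteCandidate] = []
    for proto in prototypes:
        for size in range(max_steps + 1):
            for combo in combinations_with_replacement(sorted(rxn_by_name), size):
                counts: dict[str, int] = {}
                for name in combo:
                    counts[name] = counts.get(name, 0) + 1
                if any(n > rxn_by_name[r].max_multiplicity for r, n in counts.items()):
                    continue
                formula = proto.formula
                try:
                    for name, n in counts.items():
                        formula = rxn_by_name[name].apply(formula, n)
                except FormulaError:
                    log.debug("skipping %s %s: negative element count",
                              proto.name, combo)
                    continue
                mz = {a: adduct_mz(formula, a) for a in adducts}
                out.append(
                    MetaboliteCandidate(
                        prototype=proto,
                        reactions=tuple(combo),
                        formula=formula,
                        mz=mz,
                    )
                )
    return out


def metabolite_index(lib: Sequence[MetaboliteCandidate]) -> PrecursorIndex:
    entries = []
    for cand in lib:
        for adduct, mz in cand.mz.items():
            entries.append((mz, cand, adduct))
    return PrecursorIndex(entries)


@dataclass(frozen=True)
class MetaboliteAnnotation:
    """A screened marker matched to prototype+reaction candidates."""

    feature_id: str
    candidate: MetaboliteCandidate
    adduct: str
    error: MassError
    core_ion_seen: bool
    conjugate_loss_seen: bool
    source: str = ""  # plasma | urine | ""

    @property
    def ms2_confirmed(self) -> bool:
        return self.core_ion_seen or self.conjugate_loss_seen


def annotate_markers(
    markers: Sequence[Feature],
    lib: Sequence[MetaboliteCandidate],
    mz_tol: float = DEFAULT_MZ_TOL,
    sources: dict[str, str] | None = None,
    top_k: int = 20,
) -> list[MetaboliteAnnotation]:
    """Match marker features against the metabolite library.

    Candidates for one marker are ranked by (reaction steps, |mDa|), so an
    exact prototype match outranks a round-trip like +2H-2H.  MS2
    confirmation checks for the prototype core ion (prototype m/z under the
    matched adduct) among the fragments, or a fragment/precursor neutral
    loss equal to the total conjugate mass shift.
    """
    index = metabolite_index(lib)
    sources = sources or {}
    out: list[MetaboliteAnnotation] = []
    for f in markers:
        matches = []
        for mz, cand, adduct in index.query(f.mz, mz_tol):
            if get_adduct(adduct).polarity != f.polarity:
                continue
            matches.append((cand, adduct, mz))
        ranked = sorted(
            matches,
            key=lambda m: (m[0].n_steps, abs(f.mz - m[2]), m[0].name, m[1]),
        )
        for cand, adduct, mz in ranked:
            core_seen = False
            loss_seen = False
            if f.ms2 is not None and len(f.ms2) > 0:
                trimmed = top_k_fragments(f.ms2, top_k) if len(f.ms2) > top_k else f.ms2
                core_mz = cand.prototype and adduct_mz(cand.prototype.formula, adduct)
                core_seen = any(abs(p.mz - core_mz) <= mz_tol for p in trimmed.peaks)
                shift = cand.formula.mass - cand.prototype.formula.mass
                if shift > mz_tol:
                    loss_seen = any(
                        abs((f.mz - p.mz) - shift) <= mz_tol for p in trimmed.peaks
                    )
            out.append(
                MetaboliteAnnotation(
                    feature_id=f.id,
                    candidate=cand,
                    adduct=adduct,
                    error=mass_error(f.mz, mz),
                    core_ion_seen=core_seen,
                    conjugate_loss_seen=loss_seen,
                    source=sources.get(f.id, ""),
                )
            )
    return out


def best_annotations(
    annotations: Sequence[MetaboliteAnnotation],
    prefer_confirmed: bool = False,
) -> list[MetaboliteAnnotation]:
    """Best annotation per feature (annotate_markers preserves rank).

    With ``prefer_confirmed`` an MS2-confirmed candidate outranks an
    unconfirmed one regardless of step count -- fragment evidence for the
    prototype core resolves precursor-mass ties that a 0.02 Da window
    cannot.  Default keeps the pure (steps, |mDa|) order.
    """
    grouped: dict[str, list[MetaboliteAnnotation]] = {}
    order: list[str] = []
    for a in annotations:
        if a.feature_id not in grouped:
            order.append(a.feature_id)
        grouped.setdefault(a.feature_id, []).append(a)
    out = []
    for fid in order:
        cands = grouped[fid]
        if prefer_confirmed:
            confirmed = [a for a in cands if a.ms2_confirmed]
            out.append(confirmed[0] if confirmed else cands[0])
        else:
            out.append(cands[0])
    return out


def summarize_absorption(annotations: Sequence[MetaboliteAnnotation]) -> pd.DataFrame:
    """Per-prototype counts of prototype vs metabolite features and sources.

    Duplicate feature ids collapse to their first (best-ranked) annotation.
    """
    rows = {}
    for a in best_annotations(annotations):
        proto = a.candidate.prototype.name
        row = rows.setdefault(
            proto,
            {"prototype": proto, "n_prototype": 0, "n_metabolite": 0,
             "plasma": 0, "urine": 0},
        )
        if a.candidate.n_steps == 0:
            row["n_prototype"] += 1
        else:
            row["n_metabolite"] += 1
        if a.source in ("plasma", "urine"):
            row[a.source] += 1
    return pd.DataFrame(
        sorted(rows.values(), key=lambda r: r["prototype"]),
        columns=["prototype", "n_prototype", "n_metabolite", "plasma", "urine"],
    )


def annotation_table(annotations: Sequence[MetaboliteAnnotation]) -> pd.DataFrame:
    from .chem import round_mass

    rows = []
    for a in best_annotations(annotations):
        rows.append(
            {
                "id": a.feature_id,
                "identification": a.candidate.name,
                "formula": str(a.candidate.formula),
                "selected_ion": a.adduct,
                "calculated": round_mass(a.candidate.mz[a.adduct]),
                "mda": round(a.error.mda, 2),
                "class": a.candidate.compound_class,
                "steps": a.candidate.n_steps,
                "ms2_confirmed": a.ms2_confirmed,
                "source": a.source,
            }
        )
    return pd.DataFrame(rows)
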