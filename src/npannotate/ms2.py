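"""MS2-level annotation: neutral-loss extraction, signature matching,
class assignment and final identification records.

Class assignment is evidence counting: each matched diagnostic ion and each
matched class-specific neutral loss contributes one point to its class; the
winning class needs at least one diagnostic ion or two neutral losses, and
ties are reported as ambiguous.  Entries of class "other" (generic losses
such as H2O) never score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .feature_io import (
    DEFAULT_MZ_TOL,
    FeatureTable,
    Ms2Spectrum,
    top_k_fragments,
)
from .libraries import SignatureEntry, SignatureLibrary
from .ms1 import Ms1Hit, hits_by_feature

TOP_K = 20


@dataclass(frozen=True)
class SignatureMatch:
    entry: SignatureEntry
    observed: float  # peak m/z or loss mass (Da)
    mda: float


@dataclass
class SignatureMatches:
    """Diagnostic-ion and neutral-loss matches for one spectrum."""

    diagnostic: list[SignatureMatch] = field(default_factory=list)
    losses: list[SignatureMatch] = field(default_factory=list)

    def tallies(self) -> dict[str, dict[str, int]]:
        """Per-class counts of diagnostic and loss matches ("other" excluded)."""
        out: dict[str, dict[str, int]] = {}
        for kind, matches in (("diagnostic", self.diagnostic), ("loss", self.losses)):
            for m in matches:
                cls = m.entry.compound_class
                if cls == "other":
                    continue
                out.setdefault(cls, {"diagnostic": 0, "loss": 0})[kind] += 1
        return out


def spectrum_neutral_losses(
    s: Ms2Spectrum,
    top_k: int = TOP_K,
    mz_tol: float = DEFAULT_MZ_TOL,
    include_fragment_pairs: bool = True,
) -> list[float]:
    """Neutral-loss set of a spectrum (sorted, deduplicated within tolerance).

    Losses are precursor minus each of the ``top_k`` strongest fragments
    (positive values only) plus, by default, all fragment-fragment
    differences -- sequential eliminations show up between fragments, not
    only against the precursor.
    """
    trimmed = top_k_fragments(s, top_k) if len(s) > top_k else s
    mzs = [p.mz for p in trimmed.peaks]
    losses = [s.precursor_mz - m for m in mzs if s.precursor_mz - m > mz_tol]
    if include_fragment_pairs:
        for i in range(len(mzs)):
            for j in range(i + 1, len(mzs)):
                d = mzs[j] - mzs[i]
                if d > mz_tol:
                    losses.append(d)
    losses.sort()
    dedup: list[float] = []
    for x in losses:
        if not dedup or x - dedup[-1] > mz_tol:
            dedup.append(x)
    return dedup


def match_signatures(
    s: Ms2Spectrum,
    lib: SignatureLibrary,
    mz_tol: float = DEFAULT_MZ_TOL,
    top_k: int = TOP_K,
    include_fragment_pairs: bool = True,
) -> SignatureMatches:
    """Match diagnostics against the top-k peaks and losses against the loss set."""
    trimmed = top_k_fragments(s, top_k) if len(s) > top_k else s
    result = SignatureMatches()
    for entry in lib.diagnostics(s.polarity):
        for p in trimmed.peaks:
            err = p.mz - entry.mass
            if abs(err) <= mz_tol:
                result.diagnostic.append(SignatureMatch(entry, p.mz, err * 1e3))
    loss_set = spectrum_neutral_losses(
        s, top_k=top_k, mz_tol=mz_tol, include_fragment_pairs=include_fragment_pairs
    )
    for entry in lib.neutral_losses(s.polarity):
        for loss in loss_set:
            err = loss - entry.mass
            if abs(err) <= mz_tol:
                result.losses.append(SignatureMatch(entry, loss, err * 1e3))
    return result


def classify(matches: SignatureMatches) -> tuple[str | None, int]:
    """Assign a structural class from signature evidence.

    Score per class = diagnostic matches + neutral-loss matches.  The
    winner needs >= 1 diagnostic match or >= 2 class-specific losses; a tie
    between top classes returns ``("ambiguous", score)``; no evidence
    returns ``(None, 0)``.
    """
    tallies = matches.tallies()
    eligible = {
        cls: c["diagnostic"] + c["loss"]
        for cls, c in tallies.items()
        if c["diagnostic"] >= 1 or c["loss"] >= 2
    }
    if not eligible:
        return None, 0
    best = max(eligible.values())
    winners = [cls for cls, s in eligible.items() if s == best]
    if len(winners) > 1:
        return "ambiguous", best
    return winners[0], best


#: confidence tiers, strongest first
TIERS = ("standard-confirmed", "class+formula", "formula-only", "unassigned")


@dataclass
class AnnotationResult:
    feature_id: str
    mz: float
    rt: float
    candidates: list[Ms1Hit]
    assigned_class: str | None
    class_score: int
    tier: str
    matches: SignatureMatches | None

    @property
    def best(self) -> Ms1Hit | None:
        return self.candidates[0] if self.candidates else None


def annotate(
    table: FeatureTable,
    hits: Sequence[Ms1Hit],
    lib: SignatureLibrary,
    mz_tol: float = DEFAULT_MZ_TOL,
    top_k: int = TOP_K,
) -> list[AnnotationResult]:
    """Join MS1 hits with MS2 signature evidence per feature.

    When a class is assigned and at least one candidate belongs to it, the
    candidate list is filtered to that class.  In-source-flagged features
    are excluded.  Output is ordered by feature id.
    """
    by_feature = hits_by_feature(list(hits))
    results = []
    for f in sorted(table, key=lambda f: f.id):
        if f.is_in_source_fragment:
            continue
        cands = by_feature.get(f.id, [])
        matches = None
        cls: str | None = None
        score = 0
        if f.ms2 is not None and len(f.ms2) > 0:
            matches = match_signatures(f.ms2, lib, mz_tol=mz_tol, top_k=top_k)
            cls, score = classify(matches)
        if cls not in (None, "ambiguous"):
            filtered = [
                h for h in cands
                if getattr(h.candidate, "compound_class", None) == cls
            ]
            if filtered:
                cands = filtered
        if cands and cls not in (None, "ambiguous"):
            tier = (
                "standard-confirmed"
                if getattr(cands[0].candidate, "is_standard", False)
                else "class+formula"
            )
        elif cands:
            tier = "formula-only"
        else:
            tier = "unassigned"
        results.append(
            AnnotationResult(
                feature_id=f.id,
                mz=f.mz,
                rt=f.rt,
                candidates=cands,
                assigned_class=cls,
                class_score=score,
                tier=tier,
                matches=matches,
            )
        )
    return results


def annotation_table(results: Sequence[AnnotationResult]):
    """Flatten annotation results to a DataFrame (one row per feature)."""
    import pandas as pd

    rows = []
    for r in results:
        best = r.best
        rows.append(
            {
                "id": r.feature_id,
                "mz": r.mz,
                "rt": r.rt,
                "name": getattr(best.candidate, "name", "") if best else "",
                "formula": str(getattr(best.candidate, "formula", "")) if best else "",
                "adduct": best.adduct if best else "",
                "mda": round(best.error.mda, 2) if best else "",
                "class": r.assigned_class or "",
                "tier": r.tier,
                "n_diagnostic": len(r.matches.diagnostic) if r.matches else 0,
                "n_losses": len(r.matches.losses) if r.matches else 0,
            }
        )
    return pd.DataFrame(rows)
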