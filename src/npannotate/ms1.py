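"""MS1-level annotation: precursor matching against candidate libraries,
in-source-fragment exclusion, and adduct grouping.

In-source fragmentation produces fragment ions that co-elute with their
intact precursor and masquerade as independent features.  A feature is
flagged when a higher-m/z feature at the same retention time differs from it
by a known neutral-loss mass; flagged features are excluded from candidate
matching (but kept for networking, where their spectra remain informative).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx

from .chem import get_adduct, mass_error, MassError
from .feature_io import DEFAULT_MZ_TOL, DEFAULT_RT_TOL, Feature, FeatureTable
from .libraries import PrecursorIndex, SignatureLibrary


@dataclass(frozen=True)
class InSourceFlag:
    """A feature explained as the in-source fragment of a co-eluting parent."""

    fragment_id: str
    parent_id: str
    loss_name: str
    delta_mass: float  # observed parent - fragment (Da)
    delta_mass_error: float  # observed - library loss (Da)
    delta_rt: float  # |RT difference| (min)


@dataclass(frozen=True)
class Ms1Hit:
    """A candidate whose precursor m/z matches a feature within tolerance."""

    feature_id: str
    candidate: object  # CompoundRecord or CandidateRecord
    adduct: str
    theoretical_mz: float
    error: MassError


#: Fixed window for the adduct-delta exemption below.  Kept independent of
#: ``mz_tol`` so that enlarging the matching tolerance never shrinks the
#: flag set.
_ADDUCT_EXEMPT_TOL = 0.01


def flag_in_source_fragments(
    table: FeatureTable,
    signatures: SignatureLibrary,
    rt_tol: float = DEFAULT_RT_TOL,
    mz_tol: float = DEFAULT_MZ_TOL,
    exempt_adduct_deltas: bool = True,
    min_loss_mass: float = 40.0,
) -> list[InSourceFlag]:
    """Flag co-eluting lower-m/z features explained by a neutral loss.

    For every ordered co-eluting pair (high, low) whose m/z difference
    matches any neutral-loss entry within ``mz_tol``, the low feature is
    flagged.  Chains are safe: a flagged fragment may itself spawn flags,
    and the reported parent is the chain's highest co-eluting unflagged
    feature.  The result is independent of feature order, and enlarging
    either tolerance can only enlarge the flag set.

    Two adducts of one molecule also co-elute at a fixed m/z spacing, and
    two of those spacings collide with real neutral-loss masses
    ([M+HCOO]- vs [M-H]- equals a formic-acid loss; [M+NH4]+ vs [M+H]+
    equals an ammonia loss).  With ``exempt_adduct_deltas`` (default) a
    pair whose spacing sits within ``0.01`` Da of an inter-adduct delta is
    left to adduct grouping instead of being flagged.

    Only losses of at least ``min_loss_mass`` (default 40 Da) are consulted:
    in-source cleavage sheds whole residues (sugars, acyls, conjugates),
    while small MS2-only eliminations (CH2, NH3, H2O, CO) would make any
    pair of co-eluting features look related.
    """
    losses = [e for e in signatures.loss_masses() if e.mass >= min_loss_mass]
    exempt = (
        list(_inter_adduct_deltas(table.polarity).values())
        if exempt_adduct_deltas
        else []
    )
    feats = sorted(table, key=lambda f: (-f.mz, f.id))
    root: dict[str, str] = {}
    flags: dict[str, InSourceFlag] = {}
    for hi, lo in itertools.combinations(feats, 2):
        # feats is sorted descending, so hi.mz >= lo.mz
        if abs(hi.rt - lo.rt) > rt_tol:
            continue
        delta = hi.mz - lo.mz
        if delta <= 0:
            continue
        if any(abs(delta - d) <= _ADDUCT_EXEMPT_TOL for d in exempt):
            continue
        matched = None
        for entry in losses:
            err = delta - entry.mass
            if abs(err) <= mz_tol:
                if matched is None or abs(err) < abs(matched[1]):
                    matched = (entry, err)
        if matched is None:
            continue
        parent = root.get(hi.id, hi.id)
        entry, err = matched
        flag = InSourceFlag(
            fragment_id=lo.id,
            parent_id=parent,
            loss_name=entry.name,
            delta_mass=delta,
            delta_mass_error=err,
            delta_rt=abs(hi.rt - lo.rt),
        )
        # keep the first (highest-parent) explanation for each fragment
        if lo.id not in flags:
            flags[lo.id] = flag
            root[lo.id] = parent
    return [flags[f.id] for f in feats if f.id in flags]


def apply_flags(table: FeatureTable, flags: list[InSourceFlag]) -> FeatureTable:
    """Return a copy of the table with ``is_in_source_fragment`` set."""
    flagged = {f.fragment_id for f in flags}
    from dataclasses import replace

    features = [
        replace(f, is_in_source_fragment=(f.id in flagged)) for f in table
    ]
    return FeatureTable(features, table.polarity, table.provenance)


def match_precursors(
    table: FeatureTable,
    index: PrecursorIndex,
    mz_tol: float = DEFAULT_MZ_TOL,
    skip_flagged: bool = True,
) -> list[Ms1Hit]:
    """All library candidates within tolerance of each feature.

    Hits for one feature are ranked by |mDa| (ties keep library order).
    Features flagged as in-source fragments are skipped when
    ``skip_flagged`` is set.
    """
    hits: list[Ms1Hit] = []
    for f in table:
        if skip_flagged and f.is_in_source_fragment:
            continue
        matches = index.query(f.mz, mz_tol)
        scored = sorted(
            (
                Ms1Hit(
                    feature_id=f.id,
                    candidate=rec,
                    adduct=adduct,
                    theoretical_mz=mz,
                    error=mass_error(f.mz, mz),
                )
                for mz, rec, adduct in matches
            ),
            key=lambda h: abs(h.error.mda),
        )
        hits.extend(scored)
    return hits


def hits_by_feature(hits: list[Ms1Hit]) -> dict[str, list[Ms1Hit]]:
    out: dict[str, list[Ms1Hit]] = {}
    for h in hits:
        out.setdefault(h.feature_id, []).append(h)
    return out


#: m/z differences between co-eluting adducts of one neutral molecule.
def _inter_adduct_deltas(polarity: str) -> dict[str, float]:
    from .chem import ADDUCTS

    specs = [a for a in ADDUCTS.values() if a.polarity == polarity]
    deltas = {}
    for a, b in itertools.combinations(specs, 2):
        d = abs(a.delta - b.delta)
        deltas[f"{a.name}/{b.name}"] = d
    return deltas


def group_adducts(
    table: FeatureTable,
    rt_tol: float = DEFAULT_RT_TOL,
    mz_tol: float = DEFAULT_MZ_TOL,
) -> list[list[str]]:
    """Group co-eluting features whose m/z differences are inter-adduct deltas.

    Returns connected components (lists of feature ids, sorted); singletons
    included.  Each group supports one neutral-mass hypothesis.
    """
    deltas = _inter_adduct_deltas(table.polarity)
    g = nx.Graph()
    g.add_nodes_from(f.id for f in table)
    for a, b in itertools.combinations(table, 2):
        if abs(a.rt - b.rt) > rt_tol:
            continue
        d = abs(a.mz - b.mz)
        if any(abs(d - v) <= mz_tol for v in deltas.values()):
            g.add_edge(a.id, b.id)
    return sorted(sorted(c) for c in nx.connected_components(g))
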