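"""Seeded generators for every input the pipeline consumes, with
ground-truth manifests.

Three generators emulate the three experimental data shapes:

* :func:`simulate_extract` -- an extract profiled by data-dependent LC-MS/MS:
  each library compound yields adduct features at a shared retention time,
  rule-generated MS2 spectra built from its class's diagnostic ions and
  neutral losses, and (optionally) co-eluting in-source fragment features;
* :func:`simulate_cohort` -- a treated-vs-blank intensity matrix with
  log-normal noise and planted exogenous markers;
* :func:`simulate_metabolized` -- marker features shifted from prototypes by
  phase I/II reaction multisets, with confirming MS2.

All randomness flows from one integer seed; identical configuration and
seed give identical output.  m/z jitter is uniform within +/-``mz_jitter``
(default 0.005 Da, well inside the 0.02 Da matching tolerance, so identity
recovery on clean data is decidable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import adduct_mz
from .feature_io import Feature, FeatureTable, Ms2Spectrum, Peak
from .libraries import (
    CompoundRecord,
    SignatureLibrary,
    default_compound_library,
    default_prototypes,
    default_signature_library,
)
from .metabolites import MetaboliteCandidate, ReactionSpec, build_metabolite_library

RT_RANGE = (0.5, 24.5)  # min, within the 0-25 min acquisition window


@dataclass
class ExtractConfig:
    """Settings for :func:`simulate_extract`."""

    seed: int = 0
    polarity: str = "negative"
    compounds: Sequence[CompoundRecord] | None = None
    in_source_prob: float = 0.3
    extra_adduct_prob: float = 0.3
    decoy_peak_rate: float = 0.05  # decoy peaks per true MS2 peak
    mz_jitter: float = 0.005  # Da, uniform half-width
    min_fragments: int = 2


@dataclass
class CohortConfig:
    """Settings for :func:`simulate_cohort`."""

    seed: int = 0
    n_per_group: int = 10
    n_features: int = 500
    n_markers: int = 10
    fold_change: float = 4.0
    sigma: float = 0.3  # sd of log10 intensity
    base_log10: tuple[float, float] = (4.0, 6.0)


@dataclass
class MetabolizedConfig:
    """Settings for :func:`simulate_metabolized`."""

    seed: int = 0
    polarity: str = "negative"
    n_markers: int = 30
    max_steps: int = 2
    mz_jitter: float = 0.005
    reactions: Sequence[ReactionSpec] | None = None


def _primary_adduct(polarity: str) -> str:
    return "[M-H]-" if polarity == "negative" else "[M+H]+"


def _secondary_adducts(polarity: str) -> list[str]:
    return ["[M+HCOO]-"] if polarity == "negative" else ["[M+Na]+", "[M+NH4]+"]


def _jitter(rng: np.random.Generator, width: float) -> float:
    return float(rng.uniform(-width, width)) if width > 0 else 0.0


def _class_rules(signatures: SignatureLibrary, polarity: str):
    diag = {}
    losses = {}
    for e in signatures.diagnostics(polarity):
        diag.setdefault(e.compound_class, []).append(e)
    for e in signatures.neutral_losses(polarity):
        if e.compound_class != "other":
            losses.setdefault(e.compound_class, []).append(e)
    return diag, losses


def _rule_spectrum(
    rng: np.random.Generator,
    precursor_mz: float,
    rt: float,
    polarity: str,
    compound_class: str,
    diag_rules: dict,
    loss_rules: dict,
    decoy_rate: float,
    jitter: float,
    title: str,
) -> Ms2Spectrum:
    """Rule-generated MS2: class diagnostics + conjugate-loss fragments + decoys."""
    peaks: list[Peak] = []
    for e in diag_rules.get(compound_class, []):
        # aglycone-core diagnostics may coincide with the precursor itself
        if e.mass <= precursor_mz + 0.01:
            peaks.append(Peak(e.mass + _jitter(rng, jitter),
                              float(rng.uniform(2e3, 1e4))))
    applicable = [e for e in loss_rules.get(compound_class, [])
                  if 50.0 < precursor_mz - e.mass]
    rng.shuffle(applicable)
    for e in applicable[:3]:
        peaks.append(Peak(precursor_mz - e.mass + _jitter(rng, jitter),
                          float(rng.uniform(1e3, 8e3))))
    n_decoys = rng.binomial(max(len(peaks), 1), decoy_rate) if decoy_rate > 0 else 0
    for _ in range(n_decoys):
        peaks.append(Peak(float(rng.uniform(50.0, max(precursor_mz - 1.0, 51.0))),
                          float(rng.uniform(1e2, 2e3))))
    return Ms2Spectrum(precursor_mz=precursor_mz, rt=rt, polarity=polarity,
                       peaks=peaks, title=title)


def simulate_extract(
    config: ExtractConfig,
    signatures: SignatureLibrary | None = None,
) -> tuple[FeatureTable, list[Ms2Spectrum], pd.DataFrame]:
    """Simulate an extract: features, DDA MS2 spectra and a truth manifest.

    Each compound emits its primary adduct feature (always) plus secondary
    adduct features with probability ``extra_adduct_prob``, all at a shared
    retention time drawn uniformly on 0.5-24.5 min.  With probability
    ``in_source_prob`` an extra co-eluting feature is planted at the
    primary precursor minus a class-appropriate neutral loss and flagged in
    the manifest.  The manifest has one row per generated feature.
    """
    rng = np.random.default_rng(config.seed)
    signatures = signatures or default_signature_library()
    compounds = list(config.compounds) if config.compounds is not None else [
        c for c in default_compound_library()
    ]
    if not compounds:
        raise ValueError("empty compound set")
    diag_rules, loss_rules = _class_rules(signatures, config.polarity)

    features: list[Feature] = []
    spectra: list[Ms2Spectrum] = []
    manifest_rows = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"F{counter:04d}"

    primary = _primary_adduct(config.polarity)
    # chromatographic positions: an evenly spaced grid over the acquisition
    # window in shuffled order, with a small random offset.  Spacing stays
    # far above rt_tol, so co-elution occurs only where it is planted and
    # ground-truth identity stays decidable.
    spacing = (RT_RANGE[1] - RT_RANGE[0]) / max(len(compounds), 1)
    grid = RT_RANGE[0] + spacing * (np.arange(len(compounds)) + 0.5)
    rng.shuffle(grid)
    offset_width = min(0.1, spacing / 4)
    for comp, rt_slot in zip(compounds, grid):
        rt = float(rt_slot + rng.uniform(-offset_width, offset_width))
        base_intensity = float(rng.lognormal(mean=11.0, sigma=1.0))
        adducts = [primary] + [
            a for a in _secondary_adducts(config.polarity)
            if rng.random() < config.extra_adduct_prob
        ]
        parent_id = None
        parent_mz = None
        for k, adduct in enumerate(adducts):
            fid = new_id()
            mz = adduct_mz(comp.formula, adduct) + _jitter(rng, config.mz_jitter)
            intensity = base_intensity * (1.0 if k == 0 else float(rng.uniform(0.05, 0.3)))
            features.append(Feature(fid, mz, rt, intensity, config.polarity))
            manifest_rows.append(
                dict(feature_id=fid, compound=comp.name, formula=str(comp.formula),
                     compound_class=comp.compound_class, adduct=adduct,
                     is_in_source_fragment=False, parent_id="")
            )
            if k == 0:
                parent_id, parent_mz = fid, mz
                spectra.append(
                    _rule_spectrum(
                        rng, mz, rt, config.polarity, comp.compound_class,
                        diag_rules, loss_rules, config.decoy_peak_rate,
                        config.mz_jitter, title=fid,
                    )
                )
        # planted in-source fragment off the primary adduct feature;
        # in-source cleavage sheds whole residues (>= 40 Da) and must not
        # sit on an inter-adduct spacing, which MS1 filtering attributes
        # to adduct grouping instead
        from .ms1 import _ADDUCT_EXEMPT_TOL, _inter_adduct_deltas

        adduct_deltas = _inter_adduct_deltas(config.polarity).values()
        applicable = [
            e for e in loss_rules.get(comp.compound_class, [])
            if parent_mz - e.mass > 60.0 and e.mass >= 40.0
            and all(abs(e.mass - d) > 2 * _ADDUCT_EXEMPT_TOL for d in adduct_deltas)
        ]
        if applicable and rng.random() < config.in_source_prob:
            loss = applicable[int(rng.integers(len(applicable)))]
            fid = new_id()
            mz = parent_mz - loss.mass + _jitter(rng, config.mz_jitter)
            features.append(
                Feature(fid, mz, rt, base_intensity * float(rng.uniform(0.2, 0.8)),
                        config.polarity)
            )
            manifest_rows.append(
                dict(feature_id=fid, compound=comp.name, formula=str(comp.formula),
                     compound_class=comp.compound_class, adduct=f"in-source ({loss.name})",
                     is_in_source_fragment=True, parent_id=parent_id)
            )
    table = FeatureTable(features, config.polarity, provenance=f"simulate_extract(seed={config.seed})")
    manifest = pd.DataFrame(manifest_rows)
    return table, spectra, manifest


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Two-group intensity matrix with planted exogenous markers.

    Null features share a log-normal distribution across groups; marker
    features are multiplied by ``fold_change`` in the treated group only.
    Returns (samples x features DataFrame, label array, manifest).
    """
    if config.n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    if not 0 <= config.n_markers <= config.n_features:
        raise ValueError("n_markers must be within [0, n_features]")
    rng = np.random.default_rng(config.seed)
    n = 2 * config.n_per_group
    k = config.n_features
    mu = rng.uniform(*config.base_log10, size=k)
    logx = rng.normal(loc=mu, scale=config.sigma, size=(n, k))
    labels = np.array(["treated"] * config.n_per_group + ["blank"] * config.n_per_group)
    marker_idx = rng.choice(k, size=config.n_markers, replace=False)
    logx[: config.n_per_group, marker_idx] += np.log10(config.fold_change)
    X = pd.DataFrame(
        10.0 ** logx,
        index=[f"S{i+1:02d}" for i in range(n)],
        columns=[f"feat{j+1:04d}" for j in range(k)],
    )
    manifest = pd.DataFrame(
        {
            "feature_id": X.columns,
            "is_marker": [j in set(marker_idx) for j in range(k)],
        }
    )
    return X, labels, manifest


def simulate_metabolized(
    config: MetabolizedConfig,
    prototypes: Sequence[CompoundRecord] | None = None,
) -> tuple[list[Feature], pd.DataFrame]:
    """Marker features shifted from prototypes by sampled reaction multisets.

    Each marker is a prototype plus 0..max_steps reactions; its MS2 carries
    the prototype core ion and the conjugate-loss fragment, so downstream
    annotation can confirm the assignment.
    """
    rng = np.random.default_rng(config.seed)
    prototypes = list(prototypes) if prototypes is not None else default_prototypes()
    lib = build_metabolite_library(
        prototypes, reactions=config.reactions, max_steps=config.max_steps
    )
    primary = _primary_adduct(config.polarity)
    pool = [c for c in lib if primary in c.mz]
    features: list[Feature] = []
    rows = []
    for i in range(config.n_markers):
        cand: MetaboliteCandidate = pool[int(rng.integers(len(pool)))]
        fid = f"M{i+1:03d}"
        mz = cand.mz[primary] + _jitter(rng, config.mz_jitter)
        rt = float(rng.uniform(*RT_RANGE))
        peaks = [Peak(adduct_mz(cand.prototype.formula, primary) + _jitter(rng, config.mz_jitter),
                      float(rng.uniform(2e3, 1e4)))]
        shift = cand.formula.mass - cand.prototype.formula.mass
        if shift > 0.02:
            peaks.append(Peak(mz - shift + _jitter(rng, config.mz_jitter),
                              float(rng.uniform(1e3, 8e3))))
        ms2 = Ms2Spectrum(precursor_mz=mz, rt=rt, polarity=config.polarity,
                          peaks=peaks, title=fid)
        features.append(
            Feature(fid, mz, rt, float(rng.lognormal(10.0, 1.0)),
                    config.polarity, ms2=ms2)
        )
        rows.append(
            dict(feature_id=fid, prototype=cand.prototype.name,
                 identification=cand.name, formula=str(cand.formula),
                 n_steps=cand.n_steps, adduct=primary,
                 source="plasma" if rng.random() < 0.5 else "urine")
        )
    return features, pd.DataFrame(rows)
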