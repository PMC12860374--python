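"""Feature tables and MS2 spectra: containers, CSV/MGF readers and writers,
and spectrum-to-feature association.

Retention times are minutes everywhere; MGF ``RTINSECONDS`` is converted on
read.  Feature tables are plain CSVs in the style of peak-picker exports
(id, m/z, RT, intensity), with a configurable column map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd
from pyteomics import mgf as _mgf

log = logging.getLogger(__name__)

DEFAULT_MZ_TOL = 0.02  # Da
DEFAULT_RT_TOL = 0.02  # min


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class Ms2Spectrum:
    """A fragment spectrum; peaks are kept sorted by ascending m/z."""

    precursor_mz: float
    rt: float  # minutes
    polarity: str  # "positive" | "negative"
    peaks: list[Peak] = field(default_factory=list)
    title: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted((Peak(float(m), float(i)) for m, i in self.peaks),
                            key=lambda p: (p.mz, p.intensity))
        for p in self.peaks:
            if p.mz <= 0 or p.intensity < 0:
                raise ValueError(f"invalid peak {p}")

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class Feature:
    """One deconvoluted LC-MS feature."""

    id: str
    mz: float
    rt: float  # minutes
    intensity: float
    polarity: str
    ms2: Ms2Spectrum | None = None
    is_isotope: bool = False
    is_in_source_fragment: bool = False
    annotated: bool = False

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"feature {self.id}: m/z must be positive")
        if self.rt < 0:
            raise ValueError(f"feature {self.id}: negative retention time")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"feature {self.id}: bad polarity {self.polarity!r}")


@dataclass
class FeatureTable:
    """A list of features of one polarity with unique ids."""

    features: list[Feature]
    polarity: str
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [f.id for f in self.features]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate feature ids in table")
        for f in self.features:
            if f.polarity != self.polarity:
                raise ValueError(f"feature {f.id} polarity differs from table")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def get(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.id == feature_id:
                return f
        raise KeyError(feature_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [f.id for f in self.features],
                "mz": [f.mz for f in self.features],
                "rt": [f.rt for f in self.features],
                "intensity": [f.intensity for f in self.features],
                "polarity": [f.polarity for f in self.features],
            }
        )


DEFAULT_COLUMN_MAP = {"id": "id", "mz": "mz", "rt": "rt", "intensity": "intensity"}


def read_feature_table(
    path: str | Path,
    polarity: str,
    column_map: dict[str, str] | None = None,
) -> FeatureTable:
    """Read a feature CSV; rows violating invariants are dropped with a log line."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {c.lower() for c in cmap.values()} - set(df.columns)
    if missing:
        raise ValueError(f"feature CSV {path}: missing columns {sorted(missing)}")
    features, dropped = [], 0
    for d in df.to_dict("records"):
        try:
            features.append(
                Feature(
                    id=str(d[cmap["id"].lower()]),
                    mz=float(d[cmap["mz"].lower()]),
                    rt=float(d[cmap["rt"].lower()]),
                    intensity=float(d[cmap["intensity"].lower()]),
                    polarity=polarity,
                )
            )
        except (ValueError, TypeError):
            dropped += 1
    if dropped:
        log.warning("%s: dropped %d invalid rows", path, dropped)
    return FeatureTable(features, polarity, provenance=str(path))


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# MGF

def read_mgf(path: str | Path) -> list[Ms2Spectrum]:
    """Read MGF BEGIN/END IONS blocks into spectra (peaks sorted by m/z).

    Polarity is taken from the CHARGE sign; RTINSECONDS is converted to
    minutes.  A block without peaks yields an empty spectrum with a warning.
    """
    spectra = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for block in reader:
            params = block["params"]
            pepmass = params.get("pepmass", (0.0,))
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            charge = params.get("charge")
            polarity = "positive"
            if charge:
                polarity = "negative" if int(charge[0]) < 0 else "positive"
            peaks = [Peak(float(m), float(i))
                     for m, i in zip(block["m/z array"], block["intensity array"])]
            if not peaks:
                log.warning("MGF %s: spectrum %r has no peaks",
                            path, params.get("title", ""))
            spectra.append(
                Ms2Spectrum(
                    precursor_mz=precursor,
                    rt=rt,
                    polarity=polarity,
                    peaks=peaks,
                    title=str(params.get("title", "")),
                )
            )
    return spectra


def write_mgf(spectra: Sequence[Ms2Spectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": [p.mz for p in s.peaks],
                "intensity array": [p.intensity for p in s.peaks],
                "params": {
                    "title": s.title,
                    "pepmass": s.precursor_mz,
                    "rtinseconds": s.rt * 60.0,
                    "charge": "1-" if s.polarity == "negative" else "1+",
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# spectrum association and trimming

def attach_ms2(
    table: FeatureTable,
    spectra: Iterable[Ms2Spectrum],
    mz_tol: float = DEFAULT_MZ_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
) -> FeatureTable:
    """Attach each spectrum to its nearest-precursor feature.

    A spectrum attaches to at most one feature (nearest m/z wins; ties break
    to the lower feature id); a feature keeps its nearest spectrum.  The
    assignment is independent of input order.
    """
    spectra = [s for s in spectra if s.polarity == table.polarity]
    best: dict[str, tuple[float, Ms2Spectrum]] = {}
    for s in spectra:
        candidates = [
            f for f in table
            if abs(f.mz - s.precursor_mz) <= mz_tol and abs(f.rt - s.rt) <= rt_tol
        ]
        if not candidates:
            continue
        winner = min(candidates, key=lambda f: (abs(f.mz - s.precursor_mz), f.id))
        d = abs(winner.mz - s.precursor_mz)
        prev = best.get(winner.id)
        if prev is None or (d, s.precursor_mz, s.title) < (abs(winner.mz - prev[1].precursor_mz),
                                                           prev[1].precursor_mz, prev[1].title):
            best[winner.id] = (d, s)
    features = [
        replace(f, ms2=best[f.id][1]) if f.id in best else f for f in table
    ]
    return FeatureTable(features, table.polarity, table.provenance)


def top_k_fragments(s: Ms2Spectrum, k: int = 20) -> Ms2Spectrum:
    """Keep the ``k`` most intense peaks (ties: lower m/z first), re-sorted by m/z."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(s.peaks, key=lambda p: (-p.intensity, p.mz))[:k]
    return Ms2Spectrum(
        precursor_mz=s.precursor_mz,
        rt=s.rt,
        polarity=s.polarity,
        peaks=ranked,
        title=s.title,
    )
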