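"""Feature / MS/MS spectrum data model, MGF and feature-CSV I/O, filters.

The MGF dialect is the minimal GNPS-style one: ``BEGIN IONS``/``END IONS``
blocks with ``PEPMASS``, ``RTINSECONDS`` and ``TITLE`` headers and
whitespace-separated peak lines.  The feature CSV schema is documented on
:func:`read_feature_csv`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CONDITIONS",
    "Feature",
    "FeatureTable",
    "MgfError",
    "MsmsSpectrum",
    "SchemaError",
    "precursor_exclusion",
    "read_feature_csv",
    "read_mgf",
    "window_filter",
    "write_feature_csv",
    "write_mgf",
]

CONDITIONS = ("PDA", "NaCl", "KBr", "KI")

FEATURE_COLUMNS = ("id", "mz", "rt_s", "intensity", "condition", "envelope", "msms_ref")


class MgfError(ValueError):
    """Malformed MGF structure (bad BEGIN/END IONS nesting etc.)."""


class SchemaError(ValueError):
    """Feature CSV violates its documented column contract."""


@dataclass
class MsmsSpectrum:
    """A fragment spectrum: peak arrays sorted by m/z plus precursor context."""

    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    rt: float = 0.0
    id: str = ""

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.mz.size > 1 and np.any(np.diff(self.mz) <= 0):
            raise ValueError("peak m/z values must be strictly increasing")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))


@dataclass
class Feature:
    """One LC-MS feature: monoisotopic [M+H]+ m/z, RT, MS1 envelope, MS/MS."""

    id: str
    mz: float
    rt: float
    intensity: float = 0.0
    envelope: Sequence[tuple[float, float]] = field(default_factory=tuple)
    msms: MsmsSpectrum | None = None
    condition: str = "PDA"

    def __post_init__(self):
        if self.rt < 0:
            raise ValueError(f"feature {self.id}: rt must be >= 0")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"feature {self.id}: condition {self.condition!r} not in {CONDITIONS}"
            )
        self.envelope = tuple((float(m), float(i)) for m, i in self.envelope)
        if self.envelope and abs(self.envelope[0][0] - self.mz) > 0.01:
            raise ValueError(
                f"feature {self.id}: envelope does not start at the feature m/z"
            )
        if self.msms is not None and self.msms.rt == 0.0:
            self.msms.rt = self.rt


class FeatureTable:
    """Ordered collection of features with unique ids."""

    def __init__(self, features: Iterable[Feature], provenance: dict | None = None):
        self.features: list[Feature] = list(features)
        self.provenance = dict(provenance or {})
        ids = [f.id for f in self.features]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate feature ids: {dupes}")
        self._by_id = {f.id: f for f in self.features}

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, feature_id: str) -> Feature:
        return self._by_id[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def with_msms(self) -> list[Feature]:
        return [f for f in self.features if f.msms is not None and len(f.msms)]


# ---------------------------------------------------------------------------
# MGF I/O


def read_mgf(path: str | Path) -> list[MsmsSpectrum]:
    """Parse an MGF file; records lacking PEPMASS are skipped with a warning."""
    spectra: list[MsmsSpectrum] = []
    in_block = False
    headers: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                if in_block:
                    raise MgfError(f"line {lineno}: nested BEGIN IONS")
                in_block, headers, peaks = True, {}, []
            elif line == "END IONS":
                if not in_block:
                    raise MgfError(f"line {lineno}: END IONS without BEGIN IONS")
                in_block = False
                if "PEPMASS" not in headers:
                    logger.warning(
                        "skipping MGF record ending at line %d: missing PEPMASS", lineno
                    )
                    continue
                mz, inten = (
                    zip(*peaks) if peaks else ((), ())
                )
                spectra.append(
                    MsmsSpectrum(
                        precursor_mz=float(headers["PEPMASS"].split()[0]),
                        mz=np.array(mz, dtype=float),
                        intensity=np.array(inten, dtype=float),
                        rt=float(headers.get("RTINSECONDS", 0.0)),
                        id=headers.get("TITLE", ""),
                    )
                )
            elif in_block:
                if "=" in line:
                    key, value = line.split("=", 1)
                    headers[key.upper()] = value
                else:
                    fields = line.split()
                    if len(fields) < 2:
                        raise MgfError(f"line {lineno}: malformed peak line {line!r}")
                    peaks.append((float(fields[0]), float(fields[1])))
    if in_block:
        raise MgfError("unterminated BEGIN IONS block at end of file")
    return spectra


def write_mgf(spectra: Iterable[MsmsSpectrum], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for s in spectra:
            handle.write("BEGIN IONS\n")
            if s.id:
                handle.write(f"TITLE={s.id}\n")
            handle.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            handle.write(f"RTINSECONDS={s.rt:.3f}\n")
            for mz, inten in zip(s.mz, s.intensity):
                handle.write(f"{mz:.6f} {inten:.4f}\n")
            handle.write("END IONS\n")


# ---------------------------------------------------------------------------
# Feature CSV I/O


def _format_envelope(envelope: Sequence[tuple[float, float]]) -> str:
    return ";".join(f"{m:.6f}:{i:.4f}" for m, i in envelope)


def _parse_envelope(text: str, feature_id: str) -> tuple[tuple[float, float], ...]:
    if not text:
        return ()
    out = []
    for pair in text.split(";"):
        try:
            m, i = pair.split(":")
            out.append((float(m), float(i)))
        except ValueError:
            raise SchemaError(
                f"feature {feature_id}: bad envelope segment {pair!r}"
            ) from None
    return tuple(out)


def read_feature_csv(
    path: str | Path, spectra: Mapping[str, MsmsSpectrum] | None = None
) -> FeatureTable:
    """Load a feature table.

    Columns (all mandatory): ``id``, ``mz``, ``rt_s``, ``intensity``,
    ``condition``, ``envelope`` (semicolon-delimited ``mz:intensity`` pairs,
    may be empty) and ``msms_ref`` (scan id into an accompanying MGF, may be
    empty).  ``spectra`` maps scan ids to parsed spectra; unknown refs raise.
    With ``spectra=None`` refs are left unresolved and msms stays None.
    """
    df = pd.read_csv(path, dtype={"id": str, "msms_ref": str}, keep_default_na=False)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature CSV missing mandatory column(s): {missing}")
    features = []
    for row in df.itertuples(index=False):
        msms = None
        if row.msms_ref and spectra is not None:
            if row.msms_ref not in spectra:
                raise SchemaError(
                    f"feature {row.id}: msms_ref {row.msms_ref!r} not found in MGF"
                )
            msms = spectra[row.msms_ref]
        features.append(
            Feature(
                id=row.id,
                mz=float(row.mz),
                rt=float(row.rt_s),
                intensity=float(row.intensity),
                condition=row.condition,
                envelope=_parse_envelope(str(row.envelope), row.id),
                msms=msms,
            )
        )
    return FeatureTable(features, provenance={"source": str(path)})


def write_feature_csv(table: FeatureTable, path: str | Path) -> None:
    rows = []
    for f in table:
        rows.append(
            {
                "id": f.id,
                "mz": f"{f.mz:.6f}",
                "rt_s": f"{f.rt:.3f}",
                "intensity": f"{f.intensity:.4f}",
                "condition": f.condition,
                "envelope": _format_envelope(f.envelope),
                "msms_ref": f.msms.id if f.msms is not None else "",
            }
        )
    pd.DataFrame(rows, columns=list(FEATURE_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Spectral preprocessing


def window_filter(
    s: MsmsSpectrum, top_k: int = 6, half_window: float = 50.0
) -> MsmsSpectrum:
    """Keep a peak iff it is among the ``top_k`` most intense within the
    ± ``half_window`` Da interval centred on itself."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    if len(s) <= top_k:
        return MsmsSpectrum(s.precursor_mz, s.mz.copy(), s.intensity.copy(), s.rt, s.id)
    keep = np.zeros(len(s), dtype=bool)
    for i in range(len(s)):
        lo = np.searchsorted(s.mz, s.mz[i] - half_window, side="left")
        hi = np.searchsorted(s.mz, s.mz[i] + half_window, side="right")
        window = s.intensity[lo:hi]
        if window.size <= top_k:
            keep[i] = True
        else:
            rank = int(np.sum(window > s.intensity[i]))
            keep[i] = rank < top_k
    return MsmsSpectrum(s.precursor_mz, s.mz[keep], s.intensity[keep], s.rt, s.id)


def precursor_exclusion(s: MsmsSpectrum, half_range: float = 17.0) -> MsmsSpectrum:
    """Drop all peaks within ± ``half_range`` Da of the precursor m/z."""
    if half_range <= 0:
        raise ValueError("half_range must be positive")
    keep = np.abs(s.mz - s.precursor_mz) > half_range
    return MsmsSpectrum(s.precursor_mz, s.mz[keep], s.intensity[keep], s.rt, s.id)


def preprocess(
    s: MsmsSpectrum,
    top_k: int = 6,
    half_window: float = 50.0,
    half_range: float = 17.0,
) -> MsmsSpectrum:
    """Window filter followed by precursor exclusion (network defaults)."""
    return precursor_exclusion(window_filter(s, top_k, half_window), half_range)
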