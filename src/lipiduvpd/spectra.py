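"""Centroid spectrum container, peak-list / mzML readers and internal
linear recalibration.

The exchange format for ion-trap and Orbitrap fragment spectra is either
centroided mzML (read through :mod:`pyteomics.mzml`) or a bare two-column
peak list (m/z, intensity; ``#`` comments and an optional header allowed),
since instrument metadata is frequently stripped when spectra are exported
for sharing. Metadata missing from the file is supplied by the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "CentroidSpectrum",
    "RecalibrationResult",
    "read_spectra",
    "read_peaklist",
    "write_peaklist",
    "recalibrate_linear",
    "match_peak",
]


@dataclass(frozen=True)
class CentroidSpectrum:
    """An MS2/MS3/MS4 centroid spectrum with acquisition metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 2
    polarity: str = "positive"
    precursor_mz: float | None = None
    activation: str | None = None  # CID, HCD or UVPD
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if mz.shape != intensity.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(~np.isfinite(mz)) or np.any(~np.isfinite(intensity)):
            raise ValueError("peaks contain NaN or infinite values")
        if np.any(intensity < 0):
            raise ValueError("negative intensities")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", intensity[order])
        if self.ms_level not in (1, 2, 3, 4):
            raise ValueError(f"unsupported MS level: {self.ms_level}")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity!r}")
        if self.activation is not None and self.activation not in ("CID", "HCD", "UVPD"):
            raise ValueError(f"unknown activation: {self.activation!r}")

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0


def match_peak(
    spectrum: CentroidSpectrum, target_mz: float, tol: float
) -> int | None:
    """Index of the most intense peak within ``tol`` Da of ``target_mz``,
    or None."""
    lo = np.searchsorted(spectrum.mz, target_mz - tol)
    hi = np.searchsorted(spectrum.mz, target_mz + tol, side="right")
    if hi <= lo:
        return None
    window = slice(lo, hi)
    return int(lo + np.argmax(spectrum.intensity[window]))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_peaklist(
    path: str | Path,
    *,
    ms_level: int = 2,
    polarity: str = "positive",
    precursor_mz: float | None = None,
    activation: str | None = None,
) -> CentroidSpectrum:
    """Read a two-column (m/z, intensity) peak list.

    Lines starting with ``#`` are comments; a single non-numeric first
    line is accepted as a header. A malformed data line raises with its
    line number.
    """
    path = Path(path)
    mz, intensity = [], []
    header_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            try:
                values = [float(p) for p in parts[:2]]
                if len(values) < 2:
                    raise ValueError
            except ValueError:
                if not header_seen and not mz:
                    header_seen = True
                    continue
                raise ValueError(
                    f"{path}: malformed peak list line {lineno}: {raw.rstrip()!r}"
                ) from None
            mz.append(values[0])
            intensity.append(values[1])
    return CentroidSpectrum(
        np.array(mz), np.array(intensity),
        ms_level=ms_level, polarity=polarity,
        precursor_mz=precursor_mz, activation=activation,
        meta={"source": str(path)},
    )


def write_peaklist(spectrum: CentroidSpectrum, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# ms_level={spectrum.ms_level} polarity={spectrum.polarity}")
        if spectrum.precursor_mz is not None:
            fh.write(f" precursor_mz={spectrum.precursor_mz:.4f}")
        if spectrum.activation:
            fh.write(f" activation={spectrum.activation}")
        fh.write("\nmz\tintensity\n")
        for mz, inten in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{mz:.5f}\t{inten:.3f}\n")


def write_mzml(spectra: Sequence[CentroidSpectrum], path: str | Path) -> None:
    """Write a minimal centroided mzML file (uncompressed 64-bit arrays).

    Covers the subset of PSI-MS metadata this package reads back: MS
    level, centroid flag, scan polarity, selected-ion m/z and activation.
    """
    import base64
    import struct
    from xml.sax.saxutils import escape

    def b64(values) -> str:
        return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode()

    def cv(accession: str, name: str, value: str = "") -> str:
        return (
            f'<cvParam cvRef="MS" accession="{accession}" '
            f'name="{escape(name)}" value="{escape(value)}"/>'
        )

    activation_cv = {
        "CID": ("MS:1000133", "collision-induced dissociation"),
        "HCD": ("MS:1000422", "beam-type collision-induced dissociation"),
        "UVPD": ("MS:1000435", "photodissociation"),
    }
    chunks = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<cvList count="1"><cv id="MS" fullName="PSI-MS" '
        'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/></cvList>',
        '<run id="run1">',
        f'<spectrumList count="{len(spectra)}">',
    ]
    for i, spec in enumerate(spectra):
        n = len(spec)
        chunks.append(
            f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{n}">'
        )
        chunks.append(cv("MS:1000511", "ms level", str(spec.ms_level)))
        chunks.append(cv("MS:1000127", "centroid spectrum"))
        if spec.polarity == "negative":
            chunks.append(cv("MS:1000129", "negative scan"))
        else:
            chunks.append(cv("MS:1000130", "positive scan"))
        if spec.precursor_mz is not None:
            act = ""
            if spec.activation in activation_cv:
                acc, name = activation_cv[spec.activation]
                act = f"<activation>{cv(acc, name)}</activation>"
            chunks.append(
                "<precursorList count=\"1\"><precursor>"
                "<selectedIonList count=\"1\"><selectedIon>"
                + cv("MS:1000744", "selected ion m/z", f"{spec.precursor_mz:.6f}")
                + "</selectedIon></selectedIonList>"
                + act
                + "</precursor></precursorList>"
            )
        chunks.append('<binaryDataArrayList count="2">')
        for accession, name, values in (
            ("MS:1000514", "m/z array", spec.mz),
            ("MS:1000515", "intensity array", spec.intensity),
        ):
            data = b64(list(values))
            chunks.append(f'<binaryDataArray encodedLength="{len(data)}">')
            chunks.append(cv("MS:1000523", "64-bit float"))
            chunks.append(cv("MS:1000576", "no compression"))
            chunks.append(cv(accession, name))
            chunks.append(f"<binary>{data}</binary></binaryDataArray>")
        chunks.append("</binaryDataArrayList></spectrum>")
    chunks += ["</spectrumList>", "</run>", "</mzML>"]
    Path(path).write_text("\n".join(c for c in chunks if c))


_ACTIVATION_NAMES = {
    "collision-induced dissociation": "CID",
    "in-source collision-induced dissociation": "CID",
    "beam-type collision-induced dissociation": "HCD",
    "photodissociation": "UVPD",
    "ultraviolet photodissociation": "UVPD",
}


def _decode_binary_array(bda) -> np.ndarray:
    import base64
    import zlib

    names = {cv.get("name") for cv in bda.iter("{*}cvParam")}
    node = bda.find("{*}binary")
    raw = base64.b64decode(node.text or "")
    if "zlib compression" in names:
        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in names else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path, defaults: dict) -> list[CentroidSpectrum]:
    """Minimal centroided-mzML reader (uncompressed or zlib, 32/64-bit)."""
    from lxml import etree

    out = []
    for _, elem in etree.iterparse(str(path), tag="{*}spectrum"):
        names = {
            cv.get("name"): cv.get("value")
            for cv in elem.iter("{*}cvParam")
        }
        if "profile spectrum" in names and "centroid spectrum" not in names:
            raise ValueError(
                f"{path}: profile-mode spectrum {elem.get('id')!r}; "
                "centroid the data before reading"
            )
        polarity = defaults.get("polarity", "positive")
        if "negative scan" in names:
            polarity = "negative"
        elif "positive scan" in names:
            polarity = "positive"
        precursor = None
        activation = defaults.get("activation")
        for ion in elem.iter("{*}selectedIon"):
            for cv in ion.iter("{*}cvParam"):
                if cv.get("name") == "selected ion m/z":
                    precursor = float(cv.get("value"))
        for act in elem.iter("{*}activation"):
            for cv in act.iter("{*}cvParam"):
                if cv.get("name") in _ACTIVATION_NAMES:
                    activation = _ACTIVATION_NAMES[cv.get("name")]
        mz = intensity = None
        for bda in elem.iter("{*}binaryDataArray"):
            sub = {cv.get("name") for cv in bda.iter("{*}cvParam")}
            if "m/z array" in sub:
                mz = _decode_binary_array(bda)
            elif "intensity array" in sub:
                intensity = _decode_binary_array(bda)
        if mz is None or intensity is None:
            raise ValueError(f"{path}: spectrum {elem.get('id')!r} lacks peak arrays")
        out.append(
            CentroidSpectrum(
                mz, intensity,
                ms_level=int(names.get("ms level") or defaults.get("ms_level", 2)),
                polarity=polarity,
                precursor_mz=precursor,
                activation=activation,
                meta={"source": str(path), "id": elem.get("id")},
            )
        )
        elem.clear()
    return out


def read_spectra(path: str | Path, format: str | None = None, **defaults) -> list[CentroidSpectrum]:
    """Read spectra from mzML or a TSV peak list.

    ``format`` is ``"mzML"`` or ``"peaklist_tsv"``; when None it is taken
    from the file extension. Keyword defaults (ms_level, polarity,
    precursor_mz, activation) fill metadata the file does not carry.
    """
    path = Path(path)
    if format is None:
        format = "mzML" if path.suffix.lower() == ".mzml" else "peaklist_tsv"
    if format == "mzML":
        return _read_mzml(path, defaults)
    if format == "peaklist_tsv":
        return [read_peaklist(path, **defaults)]
    raise ValueError(f"unknown spectrum format: {format!r}")


# ---------------------------------------------------------------------------
# Internal linear recalibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecalibrationResult:
    """Outcome of internal linear recalibration of an MS2 spectrum."""

    spectrum: CentroidSpectrum
    slope: float
    intercept: float
    rms_error: float
    n_matched: int
    applied: bool


def recalibrate_linear(
    spectrum: CentroidSpectrum,
    calibrant_mz: Sequence[float],
    tol: float = 0.3,
) -> RecalibrationResult:
    """Recalibrate m/z as ``a * mz + b`` fitted on internal calibrants.

    ``calibrant_mz`` are theoretical masses of species expected in the
    spectrum (here, intact released-lipid ions); each is matched to the
    most intense observed peak within ``tol``. With fewer than two
    matches the spectrum is returned unchanged and ``applied`` is False.
    """
    pairs = []
    for theo in calibrant_mz:
        idx = match_peak(spectrum, theo, tol)
        if idx is not None:
            pairs.append((spectrum.mz[idx], theo))
    if len(pairs) < 2:
        return RecalibrationResult(spectrum, 1.0, 0.0, math.nan, len(pairs), False)
    observed = np.array([p[0] for p in pairs])
    theoretical = np.array([p[1] for p in pairs])
    if np.ptp(observed) < 1e-9:
        raise ValueError("degenerate calibrants: identical observed m/z")
    slope, intercept = np.polyfit(observed, theoretical, 1)
    residuals = theoretical - (slope * observed + intercept)
    rms = float(np.sqrt(np.mean(residuals**2)))
    corrected = replace(
        spectrum,
        mz=slope * spectrum.mz + intercept,
        intensity=spectrum.intensity.copy(),
    )
    return RecalibrationResult(corrected, float(slope), float(intercept), rms, len(pairs), True)
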