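"""Centroided peak lists and their on-disk formats (TSV, MGF)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

__all__ = ["PeakList", "read_peaklist_tsv", "write_peaklist_tsv", "read_mgf"]


@dataclass
class PeakList:
    """Centroided (m/z, intensity) pairs with MS-level metadata.

    Peaks are sorted ascending by m/z on construction. ``ms_level`` is 1
    for a survey (intact-mass) spectrum and 2 for a fragmentation
    spectrum; ``precursor_mz``/``precursor_z`` describe the isolated ion
    for MS2 data when known.
    """

    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1
    precursor_mz: float | None = None
    precursor_z: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size and np.any(self.mz <= 0):
            raise ValueError("all m/z values must be positive")
        if self.mz.size and np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.ms_level not in (1, 2):
            raise ValueError("ms_level must be 1 or 2")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return self.mz.size

    def scaled(self, factor: float) -> "PeakList":
        """Return a copy with all intensities multiplied by ``factor``."""
        return PeakList(
            self.mz.copy(),
            self.intensity * factor,
            ms_level=self.ms_level,
            precursor_mz=self.precursor_mz,
            precursor_z=self.precursor_z,
            label=self.label,
        )


def read_peaklist_tsv(
    path: str | Path,
    ms_level: int = 1,
    precursor_mz: float | None = None,
    precursor_z: int | None = None,
) -> PeakList:
    """Read a two-column m/z-intensity TSV; a header row is optional."""
    path = Path(path)
    first = path.read_text().lstrip().splitlines()
    header = 0
    if first:
        token = first[0].split("\t")[0].strip()
        try:
            float(token)
            header = None
        except ValueError:
            header = 0
    df = pd.read_csv(path, sep="\t", header=header)
    if df.shape[1] < 2:
        raise ValueError(f"{path} must have two columns (m/z, intensity)")
    return PeakList(
        df.iloc[:, 0].to_numpy(float),
        df.iloc[:, 1].to_numpy(float),
        ms_level=ms_level,
        precursor_mz=precursor_mz,
        precursor_z=precursor_z,
        label=path.stem,
    )


def write_peaklist_tsv(pl: PeakList, path: str | Path) -> None:
    pd.DataFrame({"mz": pl.mz, "intensity": pl.intensity}).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_mgf(path: str | Path, ms_level: int = 2) -> list[PeakList]:
    """Read all spectra from an MGF file (fragment spectra by default)."""
    out: list[PeakList] = []
    with _mgf.MGF(str(path)) as reader:
        for spec in reader:
            params = spec.get("params", {})
            pep = params.get("pepmass")
            prec_mz = float(pep[0]) if pep else None
            charge = params.get("charge")
            prec_z = int(charge[0]) if charge else None
            out.append(
                PeakList(
                    np.asarray(spec["m/z array"], float),
                    np.asarray(spec["intensity array"], float),
                    ms_level=ms_level,
                    precursor_mz=prec_mz,
                    precursor_z=prec_z,
                    label=str(params.get("title", "")),
                )
            )
    return out
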