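"""MS2 peak-list (MGF) and extracted-ion-chromatogram table I/O.

MGF and a TSV of XIC areas are the interchange boundary of the pipeline:
the synthetic generator writes them and every downstream stage reads them.
Retention times are seconds everywhere.

The MGF reader is a strict line-level parser so that malformed input is
reported with the block ordinal and the offending line; the dialect it
accepts (TITLE/PEPMASS/CHARGE/RTINSECONDS) round-trips through standard
MGF tooling.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "Ms2Spectrum",
    "XicRecord",
    "MgfFormatError",
    "read_mgf",
    "write_mgf",
    "read_xic_table",
    "write_xic_table",
]


class MgfFormatError(ValueError):
    """Raised on malformed MGF input, naming the block and line."""


@dataclass
class Ms2Spectrum:
    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    retention_time: float  # seconds
    peaks: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.precursor_charge < 1:
            raise ValueError(f"precursor charge must be >= 1, got {self.precursor_charge}")
        if any(inten < 0 for _, inten in self.peaks):
            raise ValueError("negative peak intensity")
        self.peaks = sorted(self.peaks)

    @property
    def total_intensity(self) -> float:
        return sum(inten for _, inten in self.peaks)


@dataclass(frozen=True)
class XicRecord:
    """Integrated precursor chromatogram area for one peptide form.

    ``peptide_key`` is the canonical sequence+modification string from
    :func:`carbsite.chem.peptide_key`.
    """

    sample_id: str
    peptide_key: str
    charge: int
    apex_rt: float  # seconds
    area: float

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError(f"negative XIC area {self.area} for {self.peptide_key}")


_REQUIRED_MGF_KEYS = ("TITLE", "PEPMASS", "CHARGE", "RTINSECONDS")


def read_mgf(path: str | os.PathLike) -> list[Ms2Spectrum]:
    spectra: list[Ms2Spectrum] = []
    block = 0
    in_block = False
    params: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                if in_block:
                    raise MgfFormatError(
                        f"block {block + 1}, line {lineno}: BEGIN IONS inside an open block"
                    )
                in_block = True
                block += 1
                params, peaks = {}, []
            elif line == "END IONS":
                if not in_block:
                    raise MgfFormatError(f"line {lineno}: END IONS without BEGIN IONS")
                for key in _REQUIRED_MGF_KEYS:
                    if key not in params:
                        raise MgfFormatError(f"block {block}, line {lineno}: missing {key}")
                try:
                    spectra.append(
                        Ms2Spectrum(
                            spectrum_id=params["TITLE"],
                            precursor_mz=float(params["PEPMASS"].split()[0]),
                            precursor_charge=int(params["CHARGE"].rstrip("+")),
                            retention_time=float(params["RTINSECONDS"]),
                            peaks=peaks,
                        )
                    )
                except ValueError as exc:
                    raise MgfFormatError(f"block {block}: {exc}") from exc
                in_block = False
            elif in_block:
                if "=" in line:
                    key, _, value = line.partition("=")
                    params[key.upper()] = value
                else:
                    fields = line.split()
                    if len(fields) < 2:
                        raise MgfFormatError(
                            f"block {block}, line {lineno}: bad peak line {line!r}"
                        )
                    try:
                        peaks.append((float(fields[0]), float(fields[1])))
                    except ValueError:
                        raise MgfFormatError(
                            f"block {block}, line {lineno}: bad peak line {line!r}"
                        ) from None
            # lines outside blocks other than comments are ignored (MGF headers)
    if in_block:
        raise MgfFormatError(f"block {block}: truncated file, missing END IONS")
    return spectra


def write_mgf(spectra: list[Ms2Spectrum], path: str | os.PathLike) -> None:
    """m/z written to 5 decimals, intensity to 2."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.5f}\n")
            fh.write(f"CHARGE={s.precursor_charge}+\n")
            fh.write(f"RTINSECONDS={s.retention_time:.2f}\n")
            for mz, inten in s.peaks:
                fh.write(f"{mz:.5f} {inten:.2f}\n")
            fh.write("END IONS\n")


_XIC_COLUMNS = ["sample_id", "peptide_key", "charge", "apex_rt", "area"]


def read_xic_table(path: str | os.PathLike) -> list[XicRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "peptide_key": str})
    missing = [c for c in _XIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"XIC table {path} missing column(s) {missing}")
    return [
        XicRecord(
            sample_id=row.sample_id,
            peptide_key=row.peptide_key,
            charge=int(row.charge),
            apex_rt=float(row.apex_rt),
            area=float(row.area),
        )
        for row in df.itertuples(index=False)
    ]


def write_xic_table(records: list[XicRecord], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "peptide_key": r.peptide_key,
                "charge": r.charge,
                "apex_rt": round(r.apex_rt, 3),
                "area": round(r.area, 4),
            }
            for r in records
        ],
        columns=_XIC_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
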