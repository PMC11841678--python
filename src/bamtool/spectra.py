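"""MS/MS spectrum model and text-format I/O (MGF, MSP).

Readers are deliberately small: they cover the dialects the pipeline
emits and the common fields (precursor m/z, charge, adduct, structure
annotation as SMILES or InChI).  Records without a precursor m/z are
skipped with a warning; structurally malformed records raise.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from . import chem
from .chem import Molecule
from .errors import SpectrumFormatError

log = logging.getLogger(__name__)

#: adduct label -> (mass shift added to the neutral molecule per charge, polarity)
ADDUCT_SHIFTS = {
    "[M+H]+": chem.PROTON_MASS,
    "[M+Na]+": 22.98922,
    "[M+K]+": 38.96316,
    "[M-H]-": -chem.PROTON_MASS,
}

DEFAULT_ADDUCT = "[M+H]+"


@dataclass(frozen=True)
class Spectrum:
    """A peak list plus precursor metadata and an optional annotation."""

    id: str
    precursor_mz: float
    peaks: tuple  # tuple of (mz, intensity), ascending mz
    precursor_charge: int = 1
    adduct: str = DEFAULT_ADDUCT
    annotation: Optional[Molecule] = None

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"spectrum {self.id!r}: precursor_mz must be positive")
        if self.precursor_charge < 1:
            raise ValueError(f"spectrum {self.id!r}: precursor_charge must be >= 1")
        if len(self.peaks) < 1:
            raise ValueError(f"spectrum {self.id!r}: at least one peak required")
        peaks = tuple(sorted((float(mz), float(i)) for mz, i in self.peaks))
        for _, intensity in peaks:
            if intensity < 0:
                raise ValueError(f"spectrum {self.id!r}: negative intensity")
        mzs = [mz for mz, _ in peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            # merge exact-duplicate m/z values, keeping the larger intensity
            merged = {}
            for mz, i in peaks:
                merged[mz] = max(i, merged.get(mz, 0.0))
            peaks = tuple(sorted(merged.items()))
        object.__setattr__(self, "peaks", peaks)

    @property
    def neutral_mass(self) -> float:
        """Neutral monoisotopic mass implied by precursor m/z, charge, adduct."""
        shift = ADDUCT_SHIFTS.get(self.adduct, chem.PROTON_MASS)
        return (self.precursor_mz - shift) * self.precursor_charge

    def with_annotation(self, molecule: Optional[Molecule]) -> "Spectrum":
        return replace(self, annotation=molecule)


def _parse_annotation(smiles: Optional[str], inchi_text: Optional[str]) -> Optional[Molecule]:
    if smiles:
        try:
            return chem.canonicalize(smiles)
        except Exception:
            log.warning("unparseable SMILES annotation %r ignored", smiles)
    if inchi_text:
        try:
            return chem.from_inchi(inchi_text)
        except Exception:
            log.warning("unparseable InChI annotation %r ignored", inchi_text)
    return None


_CHARGE_RE = re.compile(r"^(\d+)([+-]?)$")


def _parse_charge(text: str) -> int:
    m = _CHARGE_RE.match(text.strip())
    if not m:
        return 1
    return max(1, int(m.group(1)))


def read_mgf(path) -> list[Spectrum]:
    """Read an MGF file into spectra (one per BEGIN IONS block)."""
    spectra: list[Spectrum] = []
    record = -1
    in_block = False
    params: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.upper() == "BEGIN IONS":
            record += 1
            in_block, params, peaks = True, {}, []
        elif line.upper() == "END IONS":
            if not in_block:
                raise SpectrumFormatError(record, f"stray END IONS at line {lineno}")
            spectrum = _finish_mgf_record(record, params, peaks)
            if spectrum is not None:
                spectra.append(spectrum)
            in_block = False
        elif in_block:
            if "=" in line:
                key, value = line.split("=", 1)
                params[key.strip().upper()] = value.strip()
            else:
                fields = line.split()
                if len(fields) < 2:
                    raise SpectrumFormatError(
                        record, f"bad peak line {lineno}: {line!r}"
                    )
                try:
                    peaks.append((float(fields[0]), float(fields[1])))
                except ValueError as exc:
                    raise SpectrumFormatError(
                        record, f"non-numeric peak at line {lineno}: {line!r}"
                    ) from exc
    if in_block:
        raise SpectrumFormatError(record, "unterminated BEGIN IONS block")
    return spectra


def _finish_mgf_record(record: int, params: dict, peaks: list) -> Optional[Spectrum]:
    if "PEPMASS" not in params:
        log.warning("MGF record #%d lacks PEPMASS; skipped", record)
        return None
    if not peaks:
        log.warning("MGF record #%d has no peaks; skipped", record)
        return None
    try:
        precursor_mz = float(params["PEPMASS"].split()[0])
    except ValueError as exc:
        raise SpectrumFormatError(record, f"bad PEPMASS {params['PEPMASS']!r}") from exc
    return Spectrum(
        id=params.get("TITLE", f"record_{record}"),
        precursor_mz=precursor_mz,
        precursor_charge=_parse_charge(params.get("CHARGE", "1+")),
        adduct=params.get("ADDUCT", params.get("IONMODE_ADDUCT", DEFAULT_ADDUCT)),
        peaks=tuple(peaks),
        annotation=_parse_annotation(params.get("SMILES"), params.get("INCHI")),
    )


def read_msp(path) -> list[Spectrum]:
    """Read an NIST-style MSP file (Name:/PrecursorMZ:/Num Peaks: blocks)."""
    spectra: list[Spectrum] = []
    fields: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    record = -1

    def finish() -> None:
        nonlocal fields, peaks
        if not fields and not peaks:
            return
        spectrum = _finish_msp_record(record, fields, peaks)
        if spectrum is not None:
            spectra.append(spectrum)
        fields, peaks = {}, []

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            finish()
            continue
        if ":" in line and not line[0].isdigit():
            key, value = line.split(":", 1)
            key = key.strip().lower()
            if key == "name":
                finish()
                record += 1
            fields[key] = value.strip()
        else:
            parts = line.replace(";", " ").split()
            if len(parts) >= 2:
                try:
                    peaks.append((float(parts[0]), float(parts[1])))
                except ValueError as exc:
                    raise SpectrumFormatError(record, f"bad peak line {line!r}") from exc
    finish()
    return spectra


def _finish_msp_record(record: int, fields: dict, peaks: list) -> Optional[Spectrum]:
    mz_text = (
        fields.get("precursormz")
        or fields.get("precursor_mz")
        or fields.get("pepmass")
    )
    if mz_text is None:
        log.warning("MSP record #%d lacks PrecursorMZ; skipped", record)
        return None
    if not peaks:
        log.warning("MSP record #%d has no peaks; skipped", record)
        return None
    return Spectrum(
        id=fields.get("name", f"record_{record}"),
        precursor_mz=float(mz_text.split()[0]),
        precursor_charge=_parse_charge(fields.get("charge", "1")),
        adduct=fields.get("precursortype", DEFAULT_ADDUCT),
        peaks=tuple(peaks),
        annotation=_parse_annotation(fields.get("smiles"), fields.get("inchi")),
    )


def read_spectra(path, format: Optional[str] = None) -> list[Spectrum]:
    """Read spectra from MGF or MSP, inferring the format from the suffix."""
    if format is None:
        format = Path(path).suffix.lstrip(".").upper() or "MGF"
    format = format.upper()
    if format == "MGF":
        return read_mgf(path)
    if format == "MSP":
        return read_msp(path)
    raise ValueError(f"unsupported spectrum format: {format!r}")


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    """Write spectra to an MGF file, annotations as SMILES= lines."""
    lines: list[str] = []
    for s in spectra:
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={s.id}")
        lines.append(f"PEPMASS={s.precursor_mz:.5f}")
        lines.append(f"CHARGE={s.precursor_charge}+")
        lines.append(f"ADDUCT={s.adduct}")
        if s.annotation is not None:
            lines.append(f"SMILES={s.annotation.structure}")
        for mz, intensity in s.peaks:
            lines.append(f"{mz:.5f} {intensity:.6f}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines))
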