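"""Diagnostic-ion classification of MS/MS spectra into motif evidence.

The diagnostic library (shipped as an editable table) encodes the key
fragment ions used to read *C. elegans* glycan spectra: the core Y1/Y2 ions
reporting the substitution state of the proximal and distal GlcnAc, the
B-ion families of phosphorylcholine-modified antennae, LacdiNAc, the
negative-mode trimethylamine loss of phosphorylcholine, and characteristic
precursor neutral losses.

Classification rules follow the way such spectra are read by hand:

* core Y1 ions compete -- the largest matching core ion defines the
  proximal substitution state (smaller ones occur as secondary fragments);
* a distal GalFuc is called from the Y2 at m/z 811 only in the *absence*
  of the m/z 608 Y1;
* an unmodified proximal GlcNAc is asserted (with reduced weight) for a
  fucosylated precursor lacking every fucosylated core Y1 -- absence
  reasoning is only applied when the precursor composition makes the ion
  possible;
* antennal B ions assert that the structure contains the corresponding
  subtree (supported when a candidate's theoretical B/internal fragments
  include the ion's composition).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .masses import TRIMETHYLAMINE, IonMode
from .model import Composition
from .spectra import PeakList

__all__ = [
    "DiagnosticIon",
    "Assertion",
    "EvidenceSet",
    "ClassifierConfig",
    "load_diagnostic_library",
    "classify_spectrum",
    "pc_diagnostic",
]


@dataclass(frozen=True)
class DiagnosticIon:
    label: int
    mz: Optional[float]
    mode: str  # "pos" / "neg"
    ion_type: str  # Y1-core / Y2 / B / B-o / loss / precursor-loss
    composition: Optional[str]
    motif: Optional[str]


@dataclass(frozen=True)
class Assertion:
    """One motif assertion: present/absent, with provenance and weight.

    ``mz`` records the diagnostic fragment m/z and ``loss`` a precursor
    neutral-loss mass; candidate structures are held against these values
    (a candidate conflicts only when it cannot produce the diagnostic)."""

    motif: str
    present: bool
    source: str
    weight: float = 1.0
    mz: Optional[float] = None
    loss: Optional[float] = None


@dataclass
class EvidenceSet:
    spectrum_id: Optional[str]
    assertions: list[Assertion] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def motifs(self, present: Optional[bool] = None) -> set[str]:
        return {
            a.motif
            for a in self.assertions
            if present is None or a.present is present
        }

    def add(self, assertion: Assertion) -> None:
        # no contradictory duplicates from one spectrum: keep the first,
        # drop an exact duplicate, refuse a contradiction silently becoming
        # two entries
        for existing in self.assertions:
            if existing.motif == assertion.motif:
                return
        self.assertions.append(assertion)


@dataclass(frozen=True)
class ClassifierConfig:
    tolerance: float = 0.3  # Da, on raw fragment m/z
    intensity_floor: float = 0.01  # relative to base peak; trace ions count
    absence_weight: float = 0.5
    presence_weight: float = 1.0


def load_diagnostic_library(path=None) -> list[DiagnosticIon]:
    """Read the diagnostic-ion table (packaged default if no path given)."""
    if path is None:
        text = resources.files("glycanpipe.data").joinpath("diagnostic_ions.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rows = [
        line for line in text.splitlines() if line.strip() and not line.startswith("#")
    ]
    reader = csv.reader(rows, delimiter="\t")
    header = next(reader)
    if header[:2] != ["label", "mz"]:
        raise ValueError("diagnostic library header not recognized")
    out: list[DiagnosticIon] = []
    seen: set[tuple[int, str, str]] = set()
    for row in reader:
        row = row + [""] * (6 - len(row))
        label = int(row[0])
        mz = float(row[1]) if row[1] else None
        mode, ion_type = row[2], row[3]
        comp = row[4] or None
        motif = row[5] or None
        key = (label, mode, ion_type)
        if key in seen:
            raise ValueError(f"duplicate diagnostic entry {key}")
        seen.add(key)
        out.append(DiagnosticIon(label, mz, mode, ion_type, comp, motif))
    return out


_LIBRARY: Optional[list[DiagnosticIon]] = None


def default_library() -> list[DiagnosticIon]:
    global _LIBRARY
    if _LIBRARY is None:
        _LIBRARY = load_diagnostic_library()
    return _LIBRARY


def _mode_token(mode: IonMode) -> str:
    return "pos" if mode.polarity == "positive" else "neg"


def _comp_fits(ion_comp: Composition, precursor: Composition, is_y: bool) -> bool:
    """Composition gate: the ion must be constructible from the precursor."""
    for k, v in ion_comp.counts().items():
        if v > precursor.counts()[k]:
            return False
    return True


def _find_peak(msms: PeakList, mz: float, cfg: ClassifierConfig, floor_abs: float):
    best = None
    for p in msms.peaks:
        if abs(p.mz - mz) <= cfg.tolerance and p.intensity >= floor_abs:
            if best is None or abs(p.mz - mz) < abs(best.mz - mz):
                best = p
    return best


def classify_spectrum(
    precursor_comp: Composition,
    msms: PeakList,
    mode: IonMode,
    cfg: Optional[ClassifierConfig] = None,
    library: Optional[list[DiagnosticIon]] = None,
    precursor_mz_obs: Optional[float] = None,
) -> EvidenceSet:
    """Convert an MS/MS peak list into motif-level evidence.

    ``precursor_comp`` is the assigned precursor composition (used to gate
    which diagnostics are possible), ``precursor_mz_obs`` the observed
    precursor m/z for neutral-loss matching (defaults to the peak-list
    metadata).
    """
    if not msms.peaks:
        raise ValueError("empty MS/MS peak list")
    cfg = cfg or ClassifierConfig()
    library = library if library is not None else default_library()
    token = _mode_token(mode)
    ev = EvidenceSet(msms.spectrum_id)
    floor_abs = cfg.intensity_floor * msms.base_intensity()
    prec_mz = precursor_mz_obs if precursor_mz_obs is not None else msms.precursor_mz
    if prec_mz is not None:
        # the residual precursor ion is not a fragment: exclude it from
        # diagnostic matching
        msms = PeakList(
            [p for p in msms.peaks if abs(p.mz - prec_mz) > cfg.tolerance],
            msms.precursor_mz, msms.polarity, msms.spectrum_id,
            msms.fraction, msms.retention_time,
        )
        if not msms.peaks:
            return ev

    core_hits: list[tuple[DiagnosticIon, float]] = []
    y608_seen = False
    y811 = None
    for ion in library:
        if ion.mode != token:
            ev.notes.append(f"skipped {ion.ion_type} {ion.label} (mode mismatch)")
            continue
        if ion.ion_type in ("loss", "precursor-loss"):
            continue  # handled against the precursor below
        if ion.mz is None:
            peak = next(
                (
                    p
                    for p in msms.peaks
                    if abs(p.mz - ion.label) <= 0.5 and p.intensity >= floor_abs
                ),
                None,
            )
            if peak is not None:
                ev.notes.append(f"uninterpreted diagnostic at m/z {ion.label} observed")
            continue
        comp = Composition.from_string(ion.composition) if ion.composition else None
        if comp is not None:
            is_y = ion.ion_type.startswith("Y")
            gate_comp = comp
            if not _comp_fits(gate_comp, precursor_comp, is_y):
                continue
            if is_y and precursor_comp.label_state != "PA":
                continue  # library core Y ions are pyridylaminated
        peak = _find_peak(msms, ion.mz, cfg, floor_abs)
        if peak is None:
            continue
        if ion.ion_type == "Y1-core":
            core_hits.append((ion, peak.mz))
            if ion.label == 608:
                y608_seen = True
        elif ion.ion_type == "Y2":
            y811 = ion
        elif ion.ion_type in ("B", "B-o") and ion.motif:
            ev.add(
                Assertion(
                    ion.motif, True, f"B {ion.label}", cfg.presence_weight,
                    mz=ion.mz,
                )
            )

    # core Y1 competition: the largest consistent core ion wins
    if core_hits:
        best = max(core_hits, key=lambda t: t[0].mz or 0.0)
        ion = best[0]
        ev.add(
            Assertion(
                ion.motif, True, f"Y1 {ion.label}", cfg.presence_weight, mz=ion.mz
            )
        )
    elif precursor_comp.fuc >= 1 and precursor_comp.label_state == "PA":
        # fucosylated composition but no fucosylated core Y1: the proximal
        # GlcNAc is unmodified (absence evidence, reduced weight)
        ev.add(
            Assertion(
                "proximal-unmodified", True, "absence of fucosylated Y1",
                cfg.absence_weight,
            )
        )
    if y811 is not None and not y608_seen:
        ev.add(
            Assertion(
                "distal-galfuc", True, "Y2 811 with Y1 608 absent",
                cfg.presence_weight, mz=y811.mz,
            )
        )

    # precursor neutral losses
    if prec_mz is not None:
        for ion in library:
            if ion.mode != token or ion.ion_type not in ("loss", "precursor-loss"):
                continue
            if ion.composition:
                comp = Composition.from_string(ion.composition)
                if not _comp_fits(comp, precursor_comp, False):
                    continue
            assert ion.mz is not None
            peak = _find_peak(msms, prec_mz - ion.mz, cfg, floor_abs)
            if peak is None:
                continue
            if ion.motif:
                ev.add(
                    Assertion(
                        ion.motif, True, f"precursor loss {ion.label}",
                        cfg.presence_weight, loss=ion.mz,
                    )
                )
            else:
                ev.notes.append(f"precursor loss of {ion.label} Da observed")
    return ev


def pc_diagnostic(
    msms: PeakList,
    precursor_mz: float,
    cfg: Optional[ClassifierConfig] = None,
) -> bool:
    """Negative-mode phosphorylcholine check: a [M-H-59] peak (trimethylamine
    loss) within tolerance of the precursor flags a PC-containing glycan."""
    cfg = cfg or ClassifierConfig()
    return msms.has_peak(precursor_mz - TRIMETHYLAMINE, cfg.tolerance)
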