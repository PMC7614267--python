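"""Readers and writers for the pipeline's native delimited-text formats.

All native formats are plain TSV with a versioned ``# glycanpipe:<kind>:v1``
header line and ``#key=value`` metadata lines -- inspectable and diff-able.
An optional mzXML adapter (pyteomics) extracts centroided peak lists per
scan for deposited raw data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .calibration import CalibrationCurve
from .digestion import DigestionObservation
from .spectra import Peak, PeakList

__all__ = [
    "InputError",
    "read_peaklist",
    "write_peaklist",
    "read_digestions",
    "write_digestions",
    "read_calibration",
    "write_truth_table",
    "read_truth_table",
    "write_report",
    "read_mzxml",
    "RunConfig",
    "load_config",
]


class InputError(ValueError):
    """Malformed input file; the message names the offending line."""


_PEAKLIST_MAGIC = "# glycanpipe:peaklist:v1"
_DIGEST_MAGIC = "# glycanpipe:digestions:v1"
_TRUTH_MAGIC = "# glycanpipe:truth:v1"

_META_FIELDS = {
    "precursor_mz": float,
    "polarity": str,
    "spectrum_id": str,
    "fraction": str,
    "retention_time": float,
}


def read_peaklist(path) -> PeakList:
    """Read a peak list: metadata lines, then a header and mz/intensity rows."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise InputError(f"{path}: empty input file")
    meta: dict = {}
    rows: list[tuple[int, str]] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, value = body.split("=", 1)
                key = key.strip()
                if key in _META_FIELDS:
                    meta[key] = _META_FIELDS[key](value.strip())
            continue
        rows.append((lineno, line))
    if not rows:
        raise InputError(f"{path}: no peak rows found")
    header = rows[0][1].split("\t")
    if header[0].lower() != "mz":
        raise InputError(f"{path}: line {rows[0][0]}: expected an 'mz' header column")
    has_intensity = len(header) > 1 and header[1].lower() == "intensity"
    peaks = []
    for lineno, line in rows[1:]:
        parts = line.split("\t")
        try:
            mz = float(parts[0])
            intensity = float(parts[1]) if has_intensity and len(parts) > 1 else 1.0
        except (ValueError, IndexError) as exc:
            raise InputError(f"{path}: line {lineno}: non-numeric value: {line!r}") from exc
        peaks.append(Peak(mz, intensity))
    return PeakList(peaks, **meta)


def write_peaklist(pl: PeakList, path) -> None:
    with open(path, "w") as fh:
        fh.write(_PEAKLIST_MAGIC + "\n")
        for key in _META_FIELDS:
            value = getattr(pl, key)
            if value is not None:
                fh.write(f"#{key}={value}\n")
        fh.write("mz\tintensity\n")
        for p in pl.peaks:
            fh.write(f"{p.mz:.6f}\t{p.intensity:.6f}\n")


def read_digestions(path) -> list[DigestionObservation]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise InputError(f"{path}: empty input file")
    out = []
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if not header_seen:
            if [p.lower() for p in parts[:3]] != ["parent_mz", "reagent", "product_mz"]:
                raise InputError(
                    f"{path}: line {lineno}: expected header parent_mz/reagent/product_mz"
                )
            header_seen = True
            continue
        try:
            parent = int(float(parts[0]))
            reagent = parts[1]
            product = int(float(parts[2]))
        except (ValueError, IndexError) as exc:
            raise InputError(f"{path}: line {lineno}: malformed row: {line!r}") from exc
        out.append(DigestionObservation(parent, reagent, product))
    return out


def write_digestions(observations: list[DigestionObservation], path) -> None:
    with open(path, "w") as fh:
        fh.write(_DIGEST_MAGIC + "\n")
        fh.write("parent_mz\treagent\tproduct_mz\n")
        for obs in observations:
            fh.write(f"{obs.parent_label}\t{obs.reagent}\t{obs.product_label}\n")


def read_calibration(path) -> CalibrationCurve:
    """Two-column table (rt, dp), tab- or comma-delimited, optional header."""
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split("\t")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except (ValueError, IndexError):
                if not rows:
                    continue  # header row
                raise InputError(f"{path}: line {lineno}: malformed row: {line!r}")
    if not rows:
        raise InputError(f"{path}: no calibration anchors found")
    return CalibrationCurve.from_table(rows)


def write_truth_table(records: list[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write(_TRUTH_MAGIC + "\n")
        fh.write("spectrum_id\tstructure\tcomposition\n")
        for r in records:
            fh.write(f"{r['spectrum_id']}\t{r['structure']}\t{r['composition']}\n")


def read_truth_table(path) -> list[dict]:
    out = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if not header_seen:
            header_seen = True
            continue
        if len(parts) < 3:
            raise InputError(f"{path}: line {lineno}: malformed truth row")
        out.append(
            {"spectrum_id": parts[0], "structure": parts[1], "composition": parts[2]}
        )
    return out


def write_report(results, path) -> None:
    """Structured-text report: one block per precursor with composition,
    ranked candidates, scores and the evidence trail."""
    from .annotate import AnnotationResult

    with open(path, "w") as fh:
        fh.write("# glycanpipe:report:v1\n")
        for result in results:
            assert isinstance(result, AnnotationResult)
            fh.write("\n== precursor ==\n")
            fh.write(f"composition: {result.composition}\n")
            fh.write(f"tier: {result.tier}\n")
            if result.reason:
                fh.write(f"note: {result.reason}\n")
            if result.evidence is not None:
                for a in result.evidence.assertions:
                    state = "present" if a.present else "absent"
                    fh.write(
                        f"evidence: {a.motif} ({state}, {a.source}, w={a.weight})\n"
                    )
            for ann in result.annotations:
                fh.write(
                    f"candidate[{ann.rank}] score={ann.score:.3f} "
                    f"{ann.structure.serialize()}\n"
                )
                for motif, verdict in ann.support:
                    fh.write(f"    {verdict}: {motif}\n")
            for structure, why in result.eliminated:
                fh.write(f"eliminated: {structure} ({why})\n")
            for conflict in result.conflicts:
                fh.write(f"conflict: {conflict}\n")


def read_mzxml(path) -> list[PeakList]:
    """Optional adapter: centroided peak lists per scan from an mzXML file.

    Requires pyteomics (optional dependency ``glycanpipe[mzxml]``).
    """
    try:
        from pyteomics import mzxml
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "mzXML support requires pyteomics (pip install glycanpipe[mzxml])"
        ) from exc
    out = []
    with mzxml.read(str(path)) as reader:
        for scan in reader:
            mzs = scan.get("m/z array")
            intensities = scan.get("intensity array")
            if mzs is None:
                continue
            peaks = [Peak(float(m), float(i)) for m, i in zip(mzs, intensities)]
            precursor = None
            if scan.get("precursorMz"):
                precursor = float(scan["precursorMz"][0]["precursorMz"])
            polarity = "negative" if scan.get("polarity") == "-" else "positive"
            out.append(
                PeakList(
                    peaks,
                    precursor_mz=precursor,
                    polarity=polarity,
                    spectrum_id=str(scan.get("num")),
                    retention_time=scan.get("retentionTime"),
                )
            )
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_KNOWN_CONFIG_KEYS = {
    "ion_mode",
    "label_state",
    "tolerance",
    "fragment_tolerance",
    "scoring",
    "reagent_panel",
    "diagnostic_library",
    "calibration",
    "seed",
    "output",
    "verbosity",
}


@dataclass
class RunConfig:
    ion_mode: str = "positive"
    label_state: str = "PA"
    tolerance: float = 0.25
    fragment_tolerance: float = 0.3
    scoring: dict = field(default_factory=dict)
    reagent_panel: Optional[str] = None
    diagnostic_library: Optional[str] = None
    calibration: Optional[str] = None
    seed: int = 0
    output: Optional[str] = None
    verbosity: int = 0


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected and every
    referenced file must exist at load time."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    unknown = set(doc) - _KNOWN_CONFIG_KEYS
    if unknown:
        raise InputError(f"{path}: unknown configuration keys: {sorted(unknown)}")
    cfg = RunConfig(**doc)
    for attr in ("reagent_panel", "diagnostic_library", "calibration"):
        ref = getattr(cfg, attr)
        if ref is not None and not os.path.exists(ref):
            raise InputError(f"{path}: referenced file does not exist: {ref}")
    return cfg
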