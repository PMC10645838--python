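"""PMAA mass spectra: reference library, diagnostic-ion classification,
and conversion of GC peak areas into class molar percentages.

Partially methylated alditol acetates carry acetyl groups exactly at the
carbons that were glycosidically linked (plus the ring carbon), so their
electron-impact spectra encode the linkage class of the parent residue.
Classification is a small diagnostic-ion cascade:

* base peak m/z 102 marks a glucitol backbone (glucose residue):
  m/z 233 reveals the extra C6 acetylation of internal glucose, otherwise
  m/z 205 marks terminal glucose;
* base peak m/z 129 marks a fructose backbone: m/z 189 (O6 acetylation)
  and m/z 190 (O1 acetylation) separate 2->6, 2->1 and the 1,6-di branch
  residue; the terminal-fructose epimers carry neither but show the
  161/162 mass pair.

A peak with both 189 and 190 plus the 161/162 pair is the convolved
glucitol-epimer peak of the 2->1 and 2->6 derivatives ("2-6/1-Fruf"), which
is a chromatographic artefact, not a residue class; quantification splits
its area between the resolved mannitol epimers.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Mapping, Sequence

from .linkages import CONVOLVED_26_1, LinkageClass


class SpectrumError(ValueError):
    pass


@dataclass(frozen=True)
class PMAASpectrum:
    """(m/z, relative intensity) list; intensities in % of the base peak."""

    peaks: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if self.peaks:
            for mz, inten in self.peaks:
                if mz <= 0 or int(mz) != mz:
                    raise SpectrumError(f"m/z must be a positive integer, got {mz}")
                if not 0 < inten <= 100:
                    raise SpectrumError(
                        f"intensity must lie in (0, 100], got {inten} at m/z {mz}"
                    )
            if abs(max(i for _, i in self.peaks) - 100) > 1e-6:
                raise SpectrumError("non-empty spectrum needs a base peak at 100")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, float]]) -> "PMAASpectrum":
        """Build from raw (m/z, intensity) pairs, rescaling to base peak 100."""
        pairs = [(int(mz), float(i)) for mz, i in pairs if i > 0]
        if not pairs:
            return cls(())
        top = max(i for _, i in pairs)
        return cls(tuple((mz, min(100.0, 100.0 * i / top)) for mz, i in pairs))

    @property
    def base_peak(self) -> int:
        if not self.peaks:
            raise SpectrumError("empty spectrum has no base peak")
        return max(self.peaks, key=lambda p: p[1])[0]

    def has(self, mz: int) -> bool:
        return any(m == mz for m, _ in self.peaks)

    def intensity(self, mz: int) -> float:
        return sum(i for m, i in self.peaks if m == mz)


@dataclass(frozen=True)
class ReferenceEntry:
    peak_number: int
    retention_time: float
    derivative_name: str
    linkage_class: str  # a LinkageClass value or the convolved "2-6/1-Fruf"
    spectrum: PMAASpectrum
    comment: str = ""


@dataclass
class ClassificationResult:
    label: str  # LinkageClass value, "2-6/1-Fruf", or "unclassified"
    evidence: list[str] = field(default_factory=list)
    cosine_best: tuple[int, float] | None = None  # (reference peak number, score)


def cosine_score(a: PMAASpectrum, b: PMAASpectrum) -> float:
    """Cosine of the angle between two spectra on the union of their m/z."""
    if not a.peaks or not b.peaks:
        raise SpectrumError("cosine of an empty spectrum is undefined")
    mzs = sorted({mz for mz, _ in a.peaks} | {mz for mz, _ in b.peaks})
    va = [a.intensity(mz) for mz in mzs]
    vb = [b.intensity(mz) for mz in mzs]
    na = math.sqrt(sum(x * x for x in va))
    nb = math.sqrt(sum(x * x for x in vb))
    return sum(x * y for x, y in zip(va, vb)) / (na * nb)


# ---------------------------------------------------------------------------
# MSP text format
# ---------------------------------------------------------------------------

def read_msp(source: str | IO[str]) -> list[ReferenceEntry]:
    """Parse an MSP text file into reference entries.

    Dialect: ``Name:`` opens a record, ``Num Peaks:`` announces the ion
    list (one ``mz intensity`` pair per line); unknown headers are kept in
    the comment-free metadata but otherwise ignored. Records lacking
    optional headers get peak_number 0 / rt nan / class "unknown".
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    entries: list[ReferenceEntry] = []
    meta: dict[str, str] = {}
    pairs: list[tuple[int, float]] = []
    in_peaks = False

    def flush() -> None:
        nonlocal meta, pairs, in_peaks
        if meta:
            entries.append(
                ReferenceEntry(
                    peak_number=int(meta.get("peaknumber", 0)),
                    retention_time=float(meta.get("rt", "nan")),
                    derivative_name=meta.get("name", ""),
                    linkage_class=meta.get("linkageclass", "unknown"),
                    spectrum=PMAASpectrum(tuple(pairs)),
                    comment=meta.get("comment", ""),
                )
            )
        meta, pairs, in_peaks = {}, [], False

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if ":" in line and not line[0].isdigit():
            key, _, val = line.partition(":")
            key = key.strip().lower().replace(" ", "")
            if key == "name" and "name" in meta:
                flush()
            meta[key] = val.strip()
            in_peaks = key == "numpeaks"
            continue
        if in_peaks or (meta and line[0].isdigit()):
            mz_s, _, i_s = line.replace("\t", " ").partition(" ")
            pairs.append((int(mz_s), float(i_s)))
    flush()
    return entries


def write_msp(entries: Sequence[ReferenceEntry], target: str | IO[str]) -> None:
    lines: list[str] = []
    for e in entries:
        lines.append(f"Name: {e.derivative_name}")
        if e.comment:
            lines.append(f"Comment: {e.comment}")
        lines.append(f"PeakNumber: {e.peak_number}")
        lines.append(f"RT: {e.retention_time:g}")
        lines.append(f"LinkageClass: {e.linkage_class}")
        lines.append(f"Num Peaks: {len(e.spectrum.peaks)}")
        for mz, inten in e.spectrum.peaks:
            lines.append(f"{mz} {inten:g}")
        lines.append("")
    text = "\n".join(lines)
    if hasattr(target, "write"):
        target.write(text)
    else:
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(text)


def load_reference_library() -> list[ReferenceEntry]:
    """The eight-peak PMAA reference library shipped with the package."""
    with resources.files("fructans.data").joinpath("pmaa_reference.msp").open(
        "r", encoding="utf-8"
    ) as fh:
        return read_msp(fh)


_REFERENCES: list[ReferenceEntry] | None = None


def reference_library() -> list[ReferenceEntry]:
    global _REFERENCES
    if _REFERENCES is None:
        _REFERENCES = load_reference_library()
    return _REFERENCES


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

UNCLASSIFIED = "unclassified"


def classify_spectrum(
    s: PMAASpectrum,
    references: Sequence[ReferenceEntry] | None = None,
    cosine_floor: float = 0.5,
) -> ClassificationResult:
    """Assign a linkage class by the diagnostic-ion cascade.

    The cascade depends only on which ions are present and which is the
    base peak, so it is invariant to uniform intensity rescaling. When no
    rule fires, the best cosine match against the reference library decides
    (evidence records the fallback); below ``cosine_floor`` the result is
    ``unclassified`` rather than an exception.
    """
    if not s.peaks:
        raise SpectrumError("cannot classify an empty spectrum")
    if references is None:
        references = reference_library()
    ev: list[str] = []
    base = s.base_peak

    if base == 102:
        ev.append("base peak m/z 102: glucitol backbone (glucose residue)")
        if s.has(233):
            ev.append("m/z 233 present: extra acetylation at C6 (internal glucose)")
            return ClassificationResult(LinkageClass.I_GLCP.value, ev)
        if s.has(205):
            ev.append("m/z 205 present, 233 absent: terminal glucose")
            return ClassificationResult(LinkageClass.T_GLCP.value, ev)
    elif base == 129:
        ev.append("base peak m/z 129: fructose backbone")
        has189, has190 = s.has(189), s.has(190)
        if not has189 and not has190:
            ev.append("neither m/z 189 nor 190: unsubstituted (terminal) fructose")
            return ClassificationResult(LinkageClass.T_FRUF.value, ev)
        if has189 and not has190:
            ev.append("m/z 189 (O6 acetylation) without 190: 2->6 linkage")
            return ClassificationResult(LinkageClass.B26_FRUF.value, ev)
        if has190 and not has189:
            ev.append("m/z 190 (O1 acetylation) without 189: 2->1 linkage")
            return ClassificationResult(LinkageClass.B21_FRUF.value, ev)
        ev.append("both m/z 189 and 190 present")
        if s.has(161) and s.has(162):
            ev.append("161/162 mass pair present: convolved 2->6/2->1 glucitol peak")
            return ClassificationResult(CONVOLVED_26_1, ev)
        ev.append("161/162 pair absent: doubly substituted branch fructose")
        return ClassificationResult(LinkageClass.DI_FRUF.value, ev)

    # fallback: nearest reference by cosine
    best = max(references, key=lambda r: cosine_score(s, r.spectrum))
    score = cosine_score(s, best.spectrum)
    ev.append(
        f"no diagnostic rule fired; best cosine {score:.3f} "
        f"against reference peak {best.peak_number}"
    )
    if score < cosine_floor:
        return ClassificationResult(UNCLASSIFIED, ev, (best.peak_number, score))
    return ClassificationResult(best.linkage_class, ev, (best.peak_number, score))


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

#: which census class each resolved GC peak reports
PEAK_CLASS = {
    1: LinkageClass.T_FRUF,
    2: LinkageClass.T_FRUF,
    3: LinkageClass.T_GLCP,
    4: LinkageClass.B26_FRUF,
    5: LinkageClass.B21_FRUF,
    6: None,  # convolved 2-6/1; split between peaks 4 and 5
    7: LinkageClass.I_GLCP,
    8: LinkageClass.DI_FRUF,
}


def quantify_molar_percent(areas: Mapping[int, float]) -> dict[LinkageClass, float]:
    """Convert per-peak GC areas into class molar percentages.

    Equal molar response is assumed across derivatives. The epimer pair
    (peaks 1 and 2) sums into t-Fruf; the convolved peak 6 is split between
    2->1 and 2->6 in proportion to the resolved mannitol-epimer peaks 5 and
    4 (50/50 when both are absent). Output sums to 100.
    """
    for p, a in areas.items():
        if p not in PEAK_CLASS:
            raise SpectrumError(f"unknown GC peak number {p}")
        if a < 0:
            raise SpectrumError(f"negative area for peak {p}")
    total = sum(areas.values())
    if total <= 0:
        raise SpectrumError("all GC peak areas are zero")
    raw = {c: 0.0 for c in LinkageClass}
    for p, a in areas.items():
        cls = PEAK_CLASS[p]
        if cls is not None:
            raw[cls] += a
    a6 = areas.get(6, 0.0)
    if a6 > 0:
        a4, a5 = areas.get(4, 0.0), areas.get(5, 0.0)
        if a4 + a5 > 0:
            raw[LinkageClass.B26_FRUF] += a6 * a4 / (a4 + a5)
            raw[LinkageClass.B21_FRUF] += a6 * a5 / (a4 + a5)
        else:
            raw[LinkageClass.B26_FRUF] += a6 / 2
            raw[LinkageClass.B21_FRUF] += a6 / 2
    return {c: 100.0 * v / total for c, v in raw.items()}
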