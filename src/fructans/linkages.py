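"""Shared vocabulary for PMAA linkage classes.

Six residue classes occur in glucose-containing fructans. Each fructose is
classified by which of its non-anomeric carbons (C1, C6) carry another
residue; glucose by whether its C6 does. The anomeric carbons (fructose C2,
glucose C1) are engaged in every glycosidic bond and carry no information,
so they are not part of the class definition.
"""
from __future__ import annotations

from enum import Enum


class LinkageClass(str, Enum):
    """PMAA linkage classes of fructan residues."""

    T_FRUF = "t-Fruf"        # terminal fructose, no substitution
    B21_FRUF = "2-1-Fruf"    # fructose substituted at C1 (inulin-type link)
    B26_FRUF = "2-6-Fruf"    # fructose substituted at C6 (levan-type link)
    DI_FRUF = "1,6-di-Fruf"  # fructose substituted at C1 and C6 (branch point)
    T_GLCP = "t-Glcp"        # terminal glucose (graminan / inulin series)
    I_GLCP = "i-Glcp"        # internal glucose, C6 substituted (neo series)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: GC peak 6 convolves the glucitol epimers of the 2->1 and 2->6 derivatives;
#: it is a spectral class, never a residue class.
CONVOLVED_26_1 = "2-6/1-Fruf"

FRUCTOSE_CLASSES = (
    LinkageClass.T_FRUF,
    LinkageClass.B21_FRUF,
    LinkageClass.B26_FRUF,
    LinkageClass.DI_FRUF,
)
GLUCOSE_CLASSES = (LinkageClass.T_GLCP, LinkageClass.I_GLCP)
ALL_CLASSES = FRUCTOSE_CLASSES + GLUCOSE_CLASSES

#: canonical CSV column name per class (molar-percent tables)
PCT_COLUMNS = {
    LinkageClass.T_FRUF: "t_fruf_pct",
    LinkageClass.B21_FRUF: "b21_pct",
    LinkageClass.B26_FRUF: "b26_pct",
    LinkageClass.DI_FRUF: "di_pct",
    LinkageClass.T_GLCP: "t_glcp_pct",
    LinkageClass.I_GLCP: "i_glcp_pct",
}

#: integer-census CSV columns (one structure or population of structures)
COUNT_COLUMNS = {
    LinkageClass.T_FRUF: "t_fruf",
    LinkageClass.B21_FRUF: "b21_fruf",
    LinkageClass.B26_FRUF: "b26_fruf",
    LinkageClass.DI_FRUF: "di_fruf",
    LinkageClass.T_GLCP: "t_glcp",
    LinkageClass.I_GLCP: "i_glcp",
}

#: glucose-normalised ratio CSV columns; the two glucose classes collapse to
#: one denominator ("there is only one glucose per molecule")
RATIO_COLUMNS = {
    LinkageClass.T_FRUF: "t_fruf_ratio",
    LinkageClass.B21_FRUF: "b21_ratio",
    LinkageClass.B26_FRUF: "b26_ratio",
    LinkageClass.DI_FRUF: "di_ratio",
    "Glcp": "glcp_ratio",
}
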