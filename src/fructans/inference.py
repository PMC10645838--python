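"""Glucose-normalised linkage inference (the molar-ratio procedure).

Because a fructan carries at most one glucose, dividing each linkage
class's molar percentage by the summed glucose percentage (terminal +
internal) expresses the composition as residues per molecule. The sum of
those ratios is the core degree of polymerization (core-DP). Integer
molecule numbers follow a verbal rounding rule: any ratio in (0, 1) counts
as one molecule; ratios >= 1 round half-up. Scaling the assigned counts by
the chromatographically determined maximum DP proposes larger structures.

`LinkageInference` wraps the procedure as a model object: construct from a
per-sample table (molar percentages or pre-normalised ratios), ``fit()``
and read the results (per-sample core-DP, assigned counts, cross-sample
means and standard deviations, branching frequency, neo fraction, scaled
counts and proposed structures) off the returned
:class:`LinkageInferenceResults`.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .linkages import LinkageClass, PCT_COLUMNS, RATIO_COLUMNS
from .structures import (
    FructanStructure,
    InfeasibleCensusError,
    assemble_core,
    extend_to_target_dp,
)

RATIO_KEYS = (
    LinkageClass.T_FRUF,
    LinkageClass.B21_FRUF,
    LinkageClass.B26_FRUF,
    LinkageClass.DI_FRUF,
    "Glcp",
)


class FSeriesError(ValueError):
    """Raised when a sample has no glucose: the glucose-normalised
    procedure does not apply to F-series fructans."""


def normalize_to_glucose(percent: Mapping) -> dict:
    """Molar percentages -> residues-per-molecule ratios.

    Divides every class percentage by the summed glucose percentage; the
    glucose term is 1.0 by construction. Scale-invariant in the input.
    """
    pct = {LinkageClass(k) if not isinstance(k, LinkageClass) else k: float(v)
           for k, v in percent.items()}
    glc = pct.get(LinkageClass.T_GLCP, 0.0) + pct.get(LinkageClass.I_GLCP, 0.0)
    if glc <= 0:
        raise FSeriesError(
            "sample contains no glucose; glucose-normalised ratios are "
            "undefined (F-series fructans fall outside this procedure)"
        )
    return {
        LinkageClass.T_FRUF: pct.get(LinkageClass.T_FRUF, 0.0) / glc,
        LinkageClass.B21_FRUF: pct.get(LinkageClass.B21_FRUF, 0.0) / glc,
        LinkageClass.B26_FRUF: pct.get(LinkageClass.B26_FRUF, 0.0) / glc,
        LinkageClass.DI_FRUF: pct.get(LinkageClass.DI_FRUF, 0.0) / glc,
        "Glcp": 1.0,
    }


def core_dp(ratios: Mapping) -> float:
    """Sum of the glucose-normalised ratios (average residues/molecule)."""
    return float(sum(ratios[k] for k in RATIO_KEYS))


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def assign_value(ratio: float) -> int:
    """Molecule number for one ratio: 0 stays 0; (0,1) counts as one
    molecule; >= 1 rounds half-up."""
    if ratio < 0:
        raise ValueError(f"negative ratio {ratio}")
    if ratio == 0:
        return 0
    if ratio < 1:
        return 1
    return round_half_up(ratio)


def assign_molecules(ratios: Mapping) -> dict:
    """Integer molecule numbers per class plus their sum (the assigned DP)."""
    counts = {k: assign_value(float(ratios[k])) for k in RATIO_KEYS}
    counts["DP"] = sum(counts[k] for k in RATIO_KEYS)
    return counts


def summarize(values: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Cross-sample mean and standard deviations per column.

    Both conventions are reported side by side: ``sd`` (sample, n-1
    denominator, the default in reports) and ``sd_pop`` (population, n
    denominator). With fewer than two rows the deviations are NaN.
    """
    mean = values.mean(axis=0).round(decimals)
    if len(values) >= 2:
        sd = values.std(axis=0, ddof=1)
        sd_pop = values.std(axis=0, ddof=0)
    else:
        sd = pd.Series(np.nan, index=values.columns)
        sd_pop = pd.Series(np.nan, index=values.columns)
    return pd.DataFrame(
        {"mean": mean, "sd": sd.round(2), "sd_pop": sd_pop.round(2)}
    )


def scale_counts(
    assigned: Mapping, hpaec_dp: float, mean_dp: float
) -> tuple[dict, float]:
    """Scale assigned molecule numbers toward the chromatographic max DP.

    factor = hpaec_dp / mean_dp; every non-glucose count is multiplied by
    the factor and re-rounded with the molecule-assignment rule; glucose
    stays at one. A factor below 1 is clamped to 1 with a warning.
    """
    import warnings

    factor = float(hpaec_dp) / float(mean_dp)
    if factor < 1:
        warnings.warn(
            f"HPAEC DP {hpaec_dp} below the mean assigned DP {mean_dp}; "
            "clamping scale factor to 1",
            stacklevel=2,
        )
        factor = 1.0
    scaled = {}
    for k in RATIO_KEYS:
        if k == "Glcp":
            scaled[k] = 1
        else:
            scaled[k] = assign_value(float(assigned[k]) * factor)
    scaled["DP"] = sum(scaled[k] for k in RATIO_KEYS)
    return scaled, factor


UNBRANCHED = math.inf


def branching_frequency(ratios: Mapping) -> float:
    """Number of 2->1 linkages per branch point (2-1 ratio / di ratio).

    Returns ``math.inf`` for unbranched samples (no di residues).
    """
    di = float(ratios[LinkageClass.DI_FRUF])
    if di == 0:
        return UNBRANCHED
    return float(ratios[LinkageClass.B21_FRUF]) / di


def neo_fraction(percent: Mapping) -> float:
    """Fraction of molecules with internal glucose: i-Glcp / (t+i)-Glcp.

    0.5 corresponds to a 1:1 graminan : neo-fructan mixture.
    """
    pct = {LinkageClass(k) if not isinstance(k, LinkageClass) else k: float(v)
           for k, v in percent.items()}
    t = pct.get(LinkageClass.T_GLCP, 0.0)
    i = pct.get(LinkageClass.I_GLCP, 0.0)
    if t + i <= 0:
        raise FSeriesError("no glucose present; neo fraction undefined")
    return i / (t + i)


@dataclass
class ProposedStructures:
    """Graminan/agavin cores from assigned counts, plus DP-extended forms."""

    graminan_core: FructanStructure
    agavin_core: FructanStructure
    graminan_extended: FructanStructure
    agavin_extended: FructanStructure

    def report(self) -> dict:
        out = {}
        for name in (
            "graminan_core",
            "agavin_core",
            "graminan_extended",
            "agavin_extended",
        ):
            s: FructanStructure = getattr(self, name)
            out[name] = {
                "dp": s.dp(),
                "topology": s.classify_topology(),
                "census": {str(k): v for k, v in s.census().items() if v},
                "condensed": s.condensed(),
            }
        return out


def propose_structures(
    assigned: Mapping, hpaec_dp: int = 20, mode: str = "backbone"
) -> ProposedStructures:
    """Assemble the minimum graminan and agavin cores and extend them.

    The graminan core places the glucose terminally. The agavin core keeps
    the same DP with an internal glucose, which the tree identity only
    permits after reassigning one 2->1 fructose as the neo-terminal cap
    (see docs/methods.md).
    """
    counts = {
        LinkageClass.T_FRUF: int(assigned[LinkageClass.T_FRUF]),
        LinkageClass.B21_FRUF: int(assigned[LinkageClass.B21_FRUF]),
        LinkageClass.B26_FRUF: int(assigned[LinkageClass.B26_FRUF]),
        LinkageClass.DI_FRUF: int(assigned[LinkageClass.DI_FRUF]),
        LinkageClass.T_GLCP: 1,
    }
    graminan = assemble_core(counts, "terminal")
    agavin_counts = dict(counts)
    agavin_counts[LinkageClass.T_GLCP] = 0
    agavin_counts[LinkageClass.I_GLCP] = 1
    agavin_counts[LinkageClass.T_FRUF] += 1
    if agavin_counts[LinkageClass.B21_FRUF] < 1:
        raise InfeasibleCensusError(
            "cannot form a same-DP agavin core: no 2-1 fructose available "
            "to reassign as the neo-terminal cap"
        )
    agavin_counts[LinkageClass.B21_FRUF] -= 1
    agavin = assemble_core(agavin_counts, "internal")
    return ProposedStructures(
        graminan_core=graminan,
        agavin_core=agavin,
        graminan_extended=extend_to_target_dp(graminan, hpaec_dp, mode),
        agavin_extended=extend_to_target_dp(agavin, hpaec_dp, mode),
    )


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class LinkageInference:
    """Model object for the glucose-normalised inference procedure.

    Parameters
    ----------
    table
        Per-sample linkage table indexed by sample id. ``kind="percent"``
        expects the molar-percentage columns (t_fruf_pct, b21_pct, b26_pct,
        di_pct, t_glcp_pct, i_glcp_pct); ``kind="ratio"`` expects
        pre-normalised ratio columns (t_fruf_ratio, ..., glcp_ratio).
    hpaec_dp
        Maximum countable degree of polymerization from anion-exchange
        chromatography; drives the structure-scaling step. Default 20.
    """

    def __init__(self, table: pd.DataFrame, kind: str = "percent", hpaec_dp: int = 20):
        if kind not in ("percent", "ratio"):
            raise ValueError(f"kind must be percent|ratio, got {kind!r}")
        if hpaec_dp < 2:
            raise ValueError("hpaec_dp must be at least 2 (sucrose)")
        self.table = table.copy()
        self.kind = kind
        self.hpaec_dp = hpaec_dp
        cols = PCT_COLUMNS.values() if kind == "percent" else RATIO_COLUMNS.values()
        missing = [c for c in cols if c not in table.columns]
        # the glcp_ratio column may be omitted: it is 1.0 by construction
        if kind == "ratio" and "glcp_ratio" in missing:
            self.table["glcp_ratio"] = 1.0
            missing.remove("glcp_ratio")
        if missing:
            raise ValueError(f"table is missing columns: {missing}")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, kind: str = "percent", hpaec_dp: int = 20
    ) -> "LinkageInference":
        return cls(df, kind=kind, hpaec_dp=hpaec_dp)

    @classmethod
    def from_csv(cls, path, kind: str = "percent", hpaec_dp: int = 20):
        from .io import read_census_csv

        return cls(read_census_csv(path, kind=kind), kind=kind, hpaec_dp=hpaec_dp)

    def fit(self) -> "LinkageInferenceResults":
        ratios = {}
        neo = {}
        for sample, row in self.table.iterrows():
            if self.kind == "percent":
                pct = {c: row[col] for c, col in PCT_COLUMNS.items()}
                ratios[sample] = normalize_to_glucose(pct)
                neo[sample] = neo_fraction(pct)
            else:
                ratios[sample] = {
                    k: float(row[RATIO_COLUMNS[k]]) for k in RATIO_KEYS
                }
        ratio_df = pd.DataFrame.from_dict(ratios, orient="index")[list(RATIO_KEYS)]
        core = ratio_df.sum(axis=1)
        assigned = pd.DataFrame.from_dict(
            {s: assign_molecules(r) for s, r in ratios.items()}, orient="index"
        )
        neo_series = pd.Series(neo) if neo else None
        return LinkageInferenceResults(self, ratio_df, core, assigned, neo_series)


class LinkageInferenceResults:
    """Estimates from :meth:`LinkageInference.fit`.

    Attributes
    ----------
    ratios : DataFrame           per-sample glucose-normalised ratios
    core_dp : Series             per-sample sum of ratios
    assigned : DataFrame         per-sample integer molecule numbers (+ DP)
    neo_fractions : Series|None  per-sample i-Glcp share (percent input only)
    """

    def __init__(self, model, ratios, core, assigned, neo_fractions):
        self.model = model
        self.ratios = ratios
        self.core_dp = core
        self.assigned = assigned
        self.neo_fractions = neo_fractions

    # -- scalar summaries ------------------------------------------------
    @property
    def mean_core_dp(self) -> float:
        return float(self.core_dp.mean())

    @property
    def mean_assigned_dp(self) -> float:
        return float(self.assigned["DP"].mean())

    @property
    def mean_assigned(self) -> pd.Series:
        return self.assigned.mean(axis=0)

    @property
    def branching_frequency(self) -> float:
        return branching_frequency(self.ratios.mean(axis=0))

    @property
    def neo_fraction(self) -> float | None:
        if self.neo_fractions is None:
            return None
        return float(self.neo_fractions.mean())

    def scale(self, mean_dp: float | None = None) -> tuple[dict, float]:
        """Scaled molecule numbers at the HPAEC DP. ``mean_dp`` defaults to
        the one-decimal reported mean assigned DP (table convention)."""
        if mean_dp is None:
            mean_dp = round(self.mean_assigned_dp, 1)
        rounded = {k: round_half_up(self.mean_assigned[k]) for k in RATIO_KEYS}
        return scale_counts(rounded, self.model.hpaec_dp, mean_dp)

    def propose_structures(self, mode: str = "backbone") -> ProposedStructures:
        counts = {k: round_half_up(self.mean_assigned[k]) for k in RATIO_KEYS}
        return propose_structures(counts, self.model.hpaec_dp, mode)

    # -- tabular/report output -------------------------------------------
    def ratio_summary(self) -> pd.DataFrame:
        df = self.ratios.copy()
        df["Core-DP"] = self.core_dp
        return summarize(df)

    def assigned_summary(self) -> pd.DataFrame:
        return summarize(self.assigned[list(RATIO_KEYS) + ["DP"]])

    def summary(self, decimals: int = 1) -> str:
        lines = ["Glucose-normalised linkage inference", ""]
        lines.append("Molar ratios (per glucose):")
        block = self.ratios.round(decimals).copy()
        block["Core-DP"] = self.core_dp.round(decimals)
        lines.append(block.to_string())
        lines.append("")
        lines.append("Assigned molecules per linkage type:")
        lines.append(self.assigned.to_string())
        lines.append("")
        lines.append("Cross-sample summary (mean / sd[n-1] / sd[n]):")
        summ = self.ratio_summary()
        lines.append(summ.to_string())
        lines.append(self.assigned_summary().to_string())
        scaled, factor = self.scale()
        lines.append("")
        lines.append(
            f"HPAEC DP {self.model.hpaec_dp}: scale factor {factor:.2f}, "
            f"scaled counts "
            + ", ".join(f"{k}={v}" for k, v in scaled.items())
        )
        bf = self.branching_frequency
        lines.append(
            f"Branching frequency: {bf:.1f} beta(2->1) linkages per branch point"
            if math.isfinite(bf)
            else "Branching frequency: unbranched (no di residues)"
        )
        if self.neo_fraction is not None:
            lines.append(f"Neo fraction (internal glucose share): {self.neo_fraction:.2f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        scaled, factor = self.scale()
        out = {
            "core_dp": {str(k): round(v, 4) for k, v in self.core_dp.items()},
            "mean_core_dp": round(self.mean_core_dp, 4),
            "assigned_dp": {str(k): int(v) for k, v in self.assigned["DP"].items()},
            "mean_assigned_dp": round(self.mean_assigned_dp, 4),
            "scale_factor": round(factor, 4),
            "scaled_counts": {str(k): v for k, v in scaled.items()},
            "branching_frequency": (
                None
                if not math.isfinite(self.branching_frequency)
                else round(self.branching_frequency, 4)
            ),
            "neo_fraction": (
                None if self.neo_fraction is None else round(self.neo_fraction, 4)
            ),
            "hpaec_dp": self.model.hpaec_dp,
        }
        return json.dumps(out, indent=2)
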