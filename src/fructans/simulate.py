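"""Forward simulation of every input the pipeline consumes.

The structure generator emulates a mixture of graminans and neo-fructans:
each molecule starts from sucrose, elongates an inulin backbone with a
geometric number of beta(2->1) fructoses, sprouts levan branches of
geometric length at each backbone unit with a fixed probability, and with
probability ``neo_fraction`` carries its glucose internally (a terminal
fructose on glucose C6). The default parameters are set so the expected
linkage census of one molecule matches the measured average composition of
the bulb extracts (about 2.2 beta(2->1) and 0.6 branch residues per
glucose, half the molecules neo-type); see docs/methods.md.

Downstream tables add multiplicative lognormal noise — positive by
construction and parameterised directly by a coefficient of variation,
which is how compositional GC/HPTLC measurements scatter.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linkages import LinkageClass, PCT_COLUMNS
from .pmaa import PMAASpectrum, reference_library
from .structures import ANOMERIC, FRUCTOSE, GLUCOSE, FructanStructure, Residue


@dataclass
class MixtureParams:
    """Population parameters of the simulated fructan mixture.

    mean_backbone_len : expected number of beta(2->1) elongation units
        beyond the sucrose fructose (geometric).
    branch_prob : probability that a backbone unit carries a levan branch.
    levan_branch_len_mean : expected length (>= 1) of a levan branch once
        it exists (geometric).
    neo_fraction : probability that a molecule carries internal glucose.
    """

    n_structures: int = 2000
    mean_backbone_len: float = 2.8
    branch_prob: float = 0.21
    levan_branch_len_mean: float = 1.1
    neo_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.branch_prob <= 1:
            raise ValueError("branch_prob must lie in [0, 1]")
        if not 0 <= self.neo_fraction <= 1:
            raise ValueError("neo_fraction must lie in [0, 1]")
        if self.mean_backbone_len < 0:
            raise ValueError("mean_backbone_len must be >= 0")
        if self.levan_branch_len_mean < 1:
            raise ValueError("levan_branch_len_mean is a chain length, >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def generate_structure(
    params: MixtureParams, rng: np.random.Generator
) -> FructanStructure:
    """Draw one fructan molecule from the mixture model."""
    residues: list[Residue] = [Residue("G", GLUCOSE)]
    edges: list[tuple[str, str, str]] = []
    n = 0

    def new_f() -> str:
        nonlocal n
        n += 1
        rid = f"F{n}"
        residues.append(Residue(rid, FRUCTOSE))
        return rid

    suc = new_f()
    edges.append(("G", suc, ANOMERIC))

    # geometric number of extra backbone units (mean = mean_backbone_len)
    mb = params.mean_backbone_len
    extra = int(rng.geometric(1.0 / (1.0 + mb))) - 1 if mb > 0 else 0
    backbone = [suc]
    cur = suc
    for _ in range(extra):
        nxt = new_f()
        edges.append((nxt, cur, "C1"))
        backbone.append(nxt)
        cur = nxt

    for unit in backbone:
        if params.branch_prob > 0 and rng.random() < params.branch_prob:
            length = int(rng.geometric(1.0 / params.levan_branch_len_mean))
            lev = unit
            for _ in range(length):
                nxt = new_f()
                edges.append((nxt, lev, "C6"))
                lev = nxt

    if params.neo_fraction > 0 and rng.random() < params.neo_fraction:
        neo = new_f()
        edges.append((neo, "G", "C6"))

    return FructanStructure(residues, edges)


def expected_census(params: MixtureParams) -> dict[LinkageClass, float]:
    """Analytic per-molecule expectation of the linkage census.

    With backbone length N = 1 + K (K geometric, mean m), branch
    probability q and levan length L (geometric >= 1, mean l):

    * di residues are branched non-tip backbone units: E = m q
    * 2-1 residues are unbranched non-tip backbone units: E = m (1 - q)
    * 2-6 residues are branched tips plus levan interiors:
      E = q + (1 + m) q (l - 1)
    * terminal fructoses are unbranched tips, levan caps and the neo cap:
      E = (1 - q) + (1 + m) q + nu
    """
    m = params.mean_backbone_len
    q = params.branch_prob
    lv = params.levan_branch_len_mean
    nu = params.neo_fraction
    return {
        LinkageClass.T_FRUF: (1 - q) + (1 + m) * q + nu,
        LinkageClass.B21_FRUF: m * (1 - q),
        LinkageClass.B26_FRUF: q + (1 + m) * q * (lv - 1),
        LinkageClass.DI_FRUF: m * q,
        LinkageClass.T_GLCP: 1 - nu,
        LinkageClass.I_GLCP: nu,
    }


def analytic_branching_frequency(params: MixtureParams) -> float:
    """Population ratio of 2->1 linkages per branch point: (1 - q) / q."""
    if params.branch_prob == 0:
        return float("inf")
    return (1 - params.branch_prob) / params.branch_prob


def population_census(
    params: MixtureParams, rng: np.random.Generator
) -> dict[LinkageClass, int]:
    """Aggregate integer census over ``n_structures`` drawn molecules."""
    total = {c: 0 for c in LinkageClass}
    for _ in range(params.n_structures):
        for c, v in generate_structure(params, rng).census().items():
            total[c] += v
    return total


def simulate_pmaa_table(
    params: MixtureParams,
    n_samples: int = 6,
    noise_cv: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-sample molar-percentage linkage table of one mixture.

    One population census is drawn, converted to molar percentages, and
    each biological sample observes it through multiplicative lognormal
    noise of the given coefficient of variation, renormalised to 100.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    total = population_census(params, rng)
    grand = sum(total.values())
    pct = np.array([100.0 * total[c] / grand for c in LinkageClass])

    sigma = float(np.sqrt(np.log1p(noise_cv**2)))
    rows = {}
    for i in range(n_samples):
        if sigma > 0:
            noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=len(pct))
        else:
            noise = np.ones(len(pct))
        v = pct * noise
        rows[f"S{i + 1}"] = 100.0 * v / v.sum()
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [PCT_COLUMNS[c] for c in LinkageClass]
    df.index.name = "sample"
    return df


#: diagnostic ions that the jitter must never drop, per linkage class
_DIAGNOSTIC = (102, 129, 161, 162, 189, 190, 205, 233)

#: reference GC peak used as the noiseless template of each class
CLASS_TEMPLATE_PEAK = {
    LinkageClass.T_FRUF.value: 1,
    LinkageClass.B21_FRUF.value: 5,
    LinkageClass.B26_FRUF.value: 4,
    LinkageClass.DI_FRUF.value: 8,
    LinkageClass.T_GLCP.value: 3,
    LinkageClass.I_GLCP.value: 7,
    "2-6/1-Fruf": 6,
}


def simulate_spectrum(
    linkage_class: str,
    jitter_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> PMAASpectrum:
    """Reference spectrum of a class with Gaussian intensity jitter.

    Intensities are perturbed by N(0, jitter_sd), truncated just above
    zero so no ion (in particular no diagnostic ion) is ever dropped, and
    re-normalised to base peak 100.
    """
    key = str(linkage_class)
    if key not in CLASS_TEMPLATE_PEAK:
        raise KeyError(f"unknown linkage class {linkage_class!r}")
    entry = next(
        e for e in reference_library() if e.peak_number == CLASS_TEMPLATE_PEAK[key]
    )
    if jitter_sd == 0:
        return entry.spectrum
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pairs = []
    for mz, inten in entry.spectrum.peaks:
        jittered = max(0.01, inten + rng.normal(0.0, jitter_sd))
        pairs.append((mz, jittered))
    return PMAASpectrum.from_pairs(pairs)


# ---------------------------------------------------------------------------
# HPTLC band tables
# ---------------------------------------------------------------------------

#: plate anchors (fructose, sucrose, neo-kestose) + mid-range bands + the
#: low-Rf fructooligosaccharide window where age discriminates
DEFAULT_RF_GRID = (
    0.57, 0.51, 0.40,
    0.33, 0.28, 0.24, 0.20,
    0.163, 0.14, 0.12, 0.10, 0.09, 0.078, 0.062,
)


def default_class_effects(rf_grid=DEFAULT_RF_GRID) -> dict[float, float]:
    """Old-vs-young multiplicative band effects: older bulbs are depleted
    in the simple sugars (high Rf) and enriched in the low-Rf
    fructooligosaccharide bands."""
    effects = {}
    for rf in rf_grid:
        if rf in (0.57, 0.51, 0.40):
            effects[rf] = 0.6
        elif rf <= 0.163:
            effects[rf] = 1.8
        else:
            effects[rf] = 1.0
    return effects


@dataclass
class HptlcSimParams:
    n_per_class: int = 6
    rf_grid: tuple = DEFAULT_RF_GRID
    class_effects: dict = field(default_factory=default_class_effects)
    noise_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if any(e <= 0 for e in self.class_effects.values()):
            raise ValueError("class effects must be positive")


def _baseline_intensity(rf: float) -> float:
    # simple sugars dominate a young bulb's plate; intensity tapers with DP
    return 20.0 + 100.0 * rf


def simulate_hptlc(params: HptlcSimParams) -> pd.DataFrame:
    """Two-class band table with columns ``rf_<value>`` plus ``label``.

    Young samples observe the baseline profile; old samples observe the
    baseline multiplied by ``class_effects``; both through lognormal noise
    at ``noise_cv``.
    """
    rng = np.random.default_rng(params.seed)
    base = np.array([_baseline_intensity(rf) for rf in params.rf_grid])
    eff = np.array([params.class_effects.get(rf, 1.0) for rf in params.rf_grid])
    sigma = float(np.sqrt(np.log1p(params.noise_cv**2)))
    rows, labels, idx = [], [], []
    for cls, profile in (("young", base), ("old", base * eff)):
        for i in range(params.n_per_class):
            if sigma > 0:
                noise = rng.lognormal(-sigma**2 / 2, sigma, size=len(profile))
            else:
                noise = np.ones(len(profile))
            rows.append(profile * noise)
            labels.append(cls)
            idx.append(f"{cls}{i + 1}")
    df = pd.DataFrame(
        rows, index=idx, columns=[f"rf_{rf:g}" for rf in params.rf_grid]
    )
    df.index.name = "sample"
    df["label"] = labels
    return df
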