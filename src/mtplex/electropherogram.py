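"""Capillary-electrophoresis peak simulation and decoding.

Peaks are (dye, apparent size, height-in-rfu) triples. Simulation emits
one peak per detected assay at the nominal fragment size (plus an optional
per-dye mobility offset) with lognormal height noise around the 3000-rfu
balancing target; per-assay detection follows a logistic dropout curve in
log10 template copies, the standard phenomenology for low-copy typing of
degraded DNA. Decoding inverts the panel's (size, dye) encoding: peaks
above the 50-rfu call floor are binned to (site, allele) within a size
tolerance, one allele -> that state, both alleles -> conflict
(heteroplasmy-like), none -> locus dropout (missing).

The dropout curve's shape and defaults (c50 = 2000 copies/uL, slope = 4
per log10) are simulation knobs chosen so that a ~28,000 copies/uL input
yields a near-complete 26-SNP profile while a tenth of that loses roughly
half the loci; they are config-exposed and not fitted to any instrument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .panel import Panel, detected_base_and_dye
from .phylogeny import ANCESTRAL, CONFLICT, DERIVED, MISSING, GenotypeProfile

DYES = ("green", "yellow", "blue", "red", "orange")  # orange = size standard


class DecodeConfigurationError(ValueError):
    """Size tolerance so large that panel bins overlap."""


@dataclass(frozen=True)
class Peak:
    dye: str
    size: float
    height: float

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError("peak height must be non-negative")
        if self.size <= 0:
            raise ValueError("peak size must be positive")
        if self.dye not in DYES:
            raise ValueError(f"unknown dye {self.dye!r}")


@dataclass
class PeakTable:
    sample_id: str
    peaks: list[Peak] = field(default_factory=list)


@dataclass
class DropoutModel:
    """Logistic per-assay detection probability in log10(copies/uL).

    ``c50`` is the template concentration at which detection probability
    is 0.5; ``slope`` is the logistic steepness per log10 copies;
    ``efficiency`` caps individual assays (default 1)."""

    c50: float = 2000.0
    slope: float = 4.0
    efficiency: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.c50 <= 0:
            raise ValueError("c50 must be positive")
        if self.slope < 0:
            raise ValueError("slope must be non-negative")


def dropout_probability(
    copies: float, model: DropoutModel, assay=None
) -> float:
    """Per-assay detection probability at a template concentration."""
    if copies < 0:
        raise ValueError("copies must be non-negative")
    eff = 1.0
    if assay is not None:
        site = getattr(assay, "site_id", assay)
        eff = model.efficiency.get(site, 1.0)
    if copies == 0:
        return 0.0
    if math.isinf(copies):
        return eff
    x = model.slope * (math.log10(copies) - math.log10(model.c50))
    return eff / (1.0 + math.exp(-x))


def _lognormal_heights(rng, mean: float, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def simulate_peaks(
    profile: GenotypeProfile,
    panel: Panel,
    copies: float,
    model: Optional[DropoutModel] = None,
    noise_cv: float = 0.2,
    seed: Optional[int] = None,
    mobility_offset: Optional[dict[str, float]] = None,
) -> PeakTable:
    """Simulate one SNaPshot electropherogram for a genotype profile.

    Missing states and stochastic dropouts emit nothing; per-site conflict
    states emit both allele peaks splitting the expected height.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    model = model or DropoutModel()
    offsets = mobility_offset or {}
    rng = np.random.default_rng(seed)
    peaks: list[Peak] = []
    for assay in panel:
        state = profile.states.get(assay.site_id, MISSING)
        if state == MISSING:
            continue
        p = dropout_probability(copies, model, assay)
        if rng.random() >= p:
            continue  # locus dropout
        if state == CONFLICT:
            alleles, scale = assay.alleles, 0.5
        else:
            alleles = (assay.ancestral_allele if state == ANCESTRAL
                       else assay.derived_allele,)
            scale = 1.0
        heights = _lognormal_heights(
            rng, panel.target_rfu * scale, noise_cv, len(alleles))
        for allele, height in zip(alleles, heights):
            _, dye = detected_base_and_dye(assay, allele, panel.dye_map)
            size = assay.nominal_frag_len + offsets.get(dye, 0.0)
            peaks.append(Peak(dye=dye, size=size, height=float(height)))
    return PeakTable(sample_id=profile.sample_id, peaks=peaks)


@dataclass
class DecodeResult:
    profile: GenotypeProfile
    off_panel: list[Peak] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _bins(panel: Panel) -> list[tuple[int, str, int, str]]:
    """(site, allele-state, nominal size, dye) for every decodable peak."""
    out = []
    for assay in panel:
        for allele, state in ((assay.ancestral_allele, ANCESTRAL),
                              (assay.derived_allele, DERIVED)):
            _, dye = detected_base_and_dye(assay, allele, panel.dye_map)
            out.append((assay.site_id, state, assay.nominal_frag_len, dye))
    return out


def decode_peaks(
    table: PeakTable,
    panel: Panel,
    min_rfu: Optional[float] = None,
    size_tolerance: Optional[float] = None,
) -> DecodeResult:
    """Decode an electropherogram peak table to a genotype profile.

    Peaks at or below ``min_rfu`` (strict > floor, default 50 rfu) are
    discarded; survivors are assigned to the unique (nominal size +/-
    tolerance, dye) bin. Orange size-standard peaks are ignored.
    """
    min_rfu = panel.min_peak_rfu if min_rfu is None else min_rfu
    tol = panel.size_tolerance_nt if size_tolerance is None else size_tolerance
    bins = _bins(panel)

    # Bins of the same dye must be disjoint under the tolerance.
    by_dye: dict[str, list[int]] = {}
    for _, _, nominal, dye in bins:
        by_dye.setdefault(dye, []).append(nominal)
    for dye, sizes in by_dye.items():
        sizes = sorted(set(sizes))
        gaps = [b - a for a, b in zip(sizes, sizes[1:])]
        if gaps and min(gaps) <= 2 * tol:
            raise DecodeConfigurationError(
                f"size tolerance {tol} nt makes {dye} bins overlap "
                f"(minimum same-dye spacing {min(gaps)} nt)")

    warnings: list[str] = []
    off_panel: list[Peak] = []
    best: dict[tuple[int, str], Peak] = {}
    for peak in table.peaks:
        if peak.dye == "orange":
            continue
        if not peak.height > min_rfu:
            continue
        hit = None
        for site, state, nominal, dye in bins:
            if peak.dye == dye and abs(peak.size - nominal) <= tol:
                hit = (site, state)
                break
        if hit is None:
            off_panel.append(peak)
            continue
        if hit in best:
            warnings.append(
                f"{table.sample_id}: two peaks in bin {hit}; keeping the higher")
            if peak.height <= best[hit].height:
                continue
        best[hit] = peak

    states: dict[int, str] = {}
    for assay in panel:
        site = assay.site_id
        has_anc = (site, ANCESTRAL) in best
        has_der = (site, DERIVED) in best
        if has_anc and has_der:
            states[site] = CONFLICT
        elif has_anc:
            states[site] = ANCESTRAL
        elif has_der:
            states[site] = DERIVED
        else:
            states[site] = MISSING
    profile = GenotypeProfile(sample_id=table.sample_id, states=states)
    return DecodeResult(profile=profile, off_panel=off_panel, warnings=warnings)


@dataclass
class BalancingEntry:
    site_id: int
    observed_rfu: float
    pct_diff_from_target: float
    current_conc: float
    adjusted_conc: float


@dataclass
class BalancingPlan:
    target_rfu: float
    entries: list[BalancingEntry]

    def as_conc(self) -> dict[int, float]:
        return {e.site_id: e.adjusted_conc for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])


def rebalance_concentrations(
    observed: dict[int, float],
    current_conc: dict[int, float],
    target_rfu: float = 3000.0,
    floor: float = 0.001,
    cap: float = 0.1,
) -> BalancingPlan:
    """Peak-balancing step: scale each primer concentration by the
    percentage shortfall of its peak against the target height; a failed
    (zero-height) assay has its concentration doubled."""
    entries = []
    for site, obs in observed.items():
        conc = current_conc[site]
        if conc <= 0:
            raise ValueError(f"site {site}: non-positive concentration {conc}")
        if obs < 0:
            raise ValueError(f"site {site}: negative observed height {obs}")
        pct = 100.0 * (obs - target_rfu) / target_rfu
        if obs == 0:
            adjusted = min(2.0 * conc, cap)
        else:
            adjusted = min(max(conc * target_rfu / obs, floor), cap)
        entries.append(BalancingEntry(
            site_id=site, observed_rfu=obs, pct_diff_from_target=pct,
            current_conc=conc, adjusted_conc=adjusted))
    return BalancingPlan(target_rfu=target_rfu, entries=entries)


# ---------------------------------------------------------------------------
# Peak-table TSV IO (sample, dye, size_nt, height_rfu — one row per peak,
# the shape of a genotyper tabular export).

def write_peak_tables(tables: list[PeakTable], path: Union[str, Path]) -> None:
    rows = [
        {"sample": t.sample_id, "dye": p.dye, "size_nt": p.size,
         "height_rfu": p.height}
        for t in tables for p in t.peaks
    ]
    pd.DataFrame(rows, columns=["sample", "dye", "size_nt", "height_rfu"]).to_csv(
        path, sep="\t", index=False)


def read_peak_tables(path: Union[str, Path]) -> dict[str, PeakTable]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    tables: dict[str, PeakTable] = {}
    for _, row in df.iterrows():
        t = tables.setdefault(row["sample"], PeakTable(sample_id=row["sample"]))
        t.peaks.append(Peak(dye=row["dye"], size=float(row["size_nt"]),
                            height=float(row["height_rfu"])))
    return tables
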