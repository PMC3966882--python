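"""Synthetic templates and study datasets for end-to-end testing.

Real mtDNA references are external downloads, but the panel definition
itself prints enough sequence (both PCR primers and the SBE probe of every
assay, plus each product size) to reconstruct a faithful local stand-in:
for each assay we lay the L primer, the probe footprint, the SNP base
(ancestral) and the reverse-complemented H primer into a window of exactly
the printed amplicon length, resolving the probe position by sequence
overlap with the primers (choosing the placement with maximal overlap;
where the probe touches neither primer any in-gap placement is equivalent
and the leftmost is used). Windows are anchored so the SNP base lands at
its rCRS coordinate in a 16,569-base scaffold whose remaining positions
are random filler. The result is a synthetic reference on which every
assay amplifies with its printed product length and types ancestral at
all 26 sites.

Haplogroup-bearing genomes substitute the derived allele along the
root-to-node path. The study simulator draws individuals with a
haplogroup frequency vector and per-period template copy numbers (a
preservation proxy), simulates two independent replicate
electropherograms each, and returns the truth for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .electropherogram import DropoutModel, PeakTable, simulate_peaks
from .insilico import (RCRS_LENGTH, AmbiguousAmpliconError, TemplateSeq,
                       VariantList, find_amplicon, genotype_from_sequence,
                       revcomp)
from .panel import Panel, SnpAssay
from .phylogeny import ANCESTRAL, HaploTree, profile_for

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class MiniReferenceError(ValueError):
    pass


@dataclass
class MiniReference:
    """Synthetic rCRS-anchored scaffold with one window per assay."""

    sequence: str
    windows: dict[int, tuple[int, int]]  # site -> (start, end), 1-based closed
    snp_offsets: dict[int, int]  # site -> 0-based offset of the SNP in window
    derived_bases: dict[int, str]  # site -> derived allele (L strand)
    seed: int

    def as_template(self, template_id: str = "mini-reference") -> TemplateSeq:
        return TemplateSeq(id=template_id, sequence=self.sequence, anchored=True)


def _assemble_window(assay: SnpAssay) -> tuple[dict[int, str], int]:
    """Resolve one amplicon window's fixed bases (primers, probe, SNP).

    Returns (offset -> base map, 0-based SNP offset). The probe placement
    is the consistent one with maximal sequence overlap with the primers,
    preferring layouts where the SNP base is not buried under a primer
    footprint (a derived allele there would perturb priming).
    """
    aln = assay.amplicon_len
    l_seq = assay.l_primer_seq
    rc_h = revcomp(assay.h_primer_seq)
    fixed: dict[int, str] = dict(enumerate(l_seq))
    h_start = aln - len(rc_h)
    if h_start < 0:
        raise MiniReferenceError(
            f"assay {assay.site_id}: primers longer than the printed amplicon")
    for i, b in enumerate(rc_h):
        pos = h_start + i
        if pos in fixed and fixed[pos] != b:
            raise MiniReferenceError(
                f"assay {assay.site_id}: L/H primer overlap disagrees at "
                f"window offset {pos}")
        fixed[pos] = b

    if assay.probe_orientation == "forward":
        foot = assay.probe_seq
        span = lambda k: range(k - len(foot), k)  # noqa: E731
    else:
        foot = revcomp(assay.probe_seq)
        span = lambda k: range(k + 1, k + 1 + len(foot))  # noqa: E731

    candidates: list[tuple[tuple[int, int, int], int]] = []
    for k in range(aln):
        positions = list(span(k))
        if positions[0] < 0 or positions[-1] >= aln:
            continue
        probe_bases = dict(zip(positions, foot))
        probe_bases[k] = assay.ancestral_allele
        if any(pos in fixed and fixed[pos] != b
               for pos, b in probe_bases.items()):
            continue
        overlap = sum(1 for pos in probe_bases if pos in fixed)
        rank = (int(k not in fixed), overlap, -k)
        candidates.append((rank, k))
    if not candidates:
        raise MiniReferenceError(
            f"assay {assay.site_id}: probe/primer sequences cannot be merged "
            f"into a window of the printed length {aln}")
    _, k = max(candidates)

    for pos, b in zip(span(k), foot):
        fixed[pos] = b
    fixed[k] = assay.ancestral_allele
    return fixed, k


def build_mini_reference(panel: Panel, seed: int = 0,
                         max_attempts: int = 5) -> MiniReference:
    """Assemble the synthetic reference and verify it behaves like one:
    every amplicon is found uniquely with its printed length and the
    typing result is all-ancestral.

    Neighbouring assays' amplicons may genuinely overlap (e.g. the panel's
    8875/8913 pair); their fixed bases are merged, and any disagreement in
    the overlap is a construction error. In-window filler is drawn from
    per-assay generators independent of ``seed`` (so the windows are
    byte-identical across scaffolds); only the inter-window filler depends
    on ``seed`` and is re-drawn (bounded retries) if it happens to create
    a spurious primer site.
    """
    placements: dict[int, tuple[int, int]] = {}
    offsets: dict[int, int] = {}
    fixed_global: dict[int, str] = {}  # 1-based scaffold position -> base
    fixed_owner: dict[int, int] = {}
    for a in panel:
        fixed, k = _assemble_window(a)
        start = a.site_id - k  # 1-based start so the SNP sits at site_id
        end = start + a.amplicon_len - 1
        if start < 1 or end > RCRS_LENGTH:
            raise MiniReferenceError(
                f"assay {a.site_id}: window {start}..{end} outside the scaffold")
        placements[a.site_id] = (start, end)
        offsets[a.site_id] = k
        for off, base in fixed.items():
            pos = start + off
            if pos in fixed_global and fixed_global[pos] != base:
                raise MiniReferenceError(
                    f"assays {fixed_owner[pos]} and {a.site_id}: overlapping "
                    f"windows disagree at position {pos}")
            fixed_global[pos] = base
            fixed_owner[pos] = a.site_id

    # In-window filler (positions inside some window but not sequence-fixed).
    in_window_filler: dict[int, str] = {}
    for a in sorted(panel, key=lambda x: x.site_id):
        start, end = placements[a.site_id]
        rng = np.random.default_rng(1_000_003 * a.site_id)
        for pos in range(start, end + 1):
            b = _BASES[rng.integers(4)].decode()
            if pos not in fixed_global and pos not in in_window_filler:
                in_window_filler[pos] = b

    window_positions = set(fixed_global) | set(in_window_filler)
    for attempt in range(max_attempts):
        rng = np.random.default_rng([seed, attempt])
        scaffold = rng.choice(_BASES, size=RCRS_LENGTH).astype("U1")
        for pos, b in fixed_global.items():
            scaffold[pos - 1] = b
        for pos, b in in_window_filler.items():
            scaffold[pos - 1] = b
        ref = MiniReference(
            sequence="".join(scaffold),
            windows=placements,
            snp_offsets=offsets,
            derived_bases={a.site_id: a.derived_allele for a in panel},
            seed=seed,
        )
        if _verify(ref, panel):
            return ref
    raise MiniReferenceError(
        f"could not build a clean scaffold in {max_attempts} attempts "
        f"(persistent spurious primer sites)")


def _verify(ref: MiniReference, panel: Panel) -> bool:
    template = ref.as_template()
    for a in panel:
        try:
            amp = find_amplicon(template, a)
        except AmbiguousAmpliconError:
            return False
        start, end = ref.windows[a.site_id]
        if amp is None or (amp.start, amp.end) != (start, end):
            return False
        if amp.length != a.amplicon_len:
            return False
    profile = genotype_from_sequence(template, panel)
    return all(st == ANCESTRAL for st in profile.states.values())


def make_genome(hg: str, ref: MiniReference, tree: HaploTree) -> TemplateSeq:
    """Template carrying the derived allele at every site on the
    root-to-``hg`` path and the ancestral state elsewhere."""
    sites = tree.path_sites(hg)  # KeyError on unknown label
    seq = list(ref.sequence)
    for site in sites:
        if site not in ref.derived_bases:
            raise MiniReferenceError(f"site {site} not in the mini reference")
        seq[site - 1] = ref.derived_bases[site]
    return TemplateSeq(id=hg, sequence="".join(seq), anchored=True)


def variants_for(hg: str, tree: HaploTree, panel: Panel) -> VariantList:
    """rCRS-relative variant list equivalent to :func:`make_genome`."""
    entries = tuple(
        (site, panel.assay_by_site(site).derived_allele)
        for site in tree.path_sites(hg))
    return VariantList(sample_id=hg, entries=entries)


# ---------------------------------------------------------------------------
# Study simulation

@dataclass
class StudySimConfig:
    """Generative settings for a replicate typing study.

    Defaults emulate the packaged case study: three cultural horizons with
    20/20/12 individuals, haplogroup frequencies close to the observed
    consensus spectrum, and per-period log10 copy-number means acting as a
    preservation proxy (Middle Horizon poorest, Late Intermediate best).
    """

    n_individuals: dict[str, int] = field(
        default_factory=lambda: {"EI": 20, "MH": 20, "LI": 12})
    hg_freqs: dict[str, float] = field(default_factory=lambda: {
        "B2": 0.40, "B2b": 0.10, "C1b": 0.25, "A2": 0.15, "D1": 0.05,
        "M": 0.05})
    copies_log10_mean: dict[str, float] = field(
        default_factory=lambda: {"EI": 3.6, "MH": 3.3, "LI": 4.0})
    copies_log10_sd: float = 0.5
    dropout: DropoutModel = field(default_factory=DropoutModel)
    noise_cv: float = 0.2

    def __post_init__(self) -> None:
        total = sum(self.hg_freqs.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"haplogroup frequencies sum to {total}, not 1")
        if any(n < 0 for n in self.n_individuals.values()):
            raise ValueError("negative individual count")
        missing = set(self.n_individuals) - set(self.copies_log10_mean)
        if missing:
            raise ValueError(f"periods without a copies mean: {sorted(missing)}")


@dataclass
class StudyDataset:
    truth: pd.DataFrame  # individual, period, hg, copies_1, copies_2
    replicates: dict[str, tuple[PeakTable, PeakTable]]


def make_study_dataset(
    cfg: StudySimConfig, panel: Panel, tree: HaploTree, seed: int = 0
) -> StudyDataset:
    """Simulate the full study: per individual, a true haplogroup, two
    replicate copy numbers, and two independently simulated
    electropherograms. Bit-reproducible for a fixed seed."""
    rng = np.random.default_rng(seed)
    hgs = list(cfg.hg_freqs)
    probs = np.array([cfg.hg_freqs[h] for h in hgs], dtype=float)
    probs = probs / probs.sum()

    rows = []
    replicates: dict[str, tuple[PeakTable, PeakTable]] = {}
    for period, n in sorted(cfg.n_individuals.items()):
        for i in range(n):
            ind = f"{period}-{i + 1:03d}"
            hg = hgs[rng.choice(len(hgs), p=probs)]
            profile = profile_for(hg, tree, panel, sample_id=ind)
            copies = []
            tables = []
            for _rep in range(2):
                c = float(10 ** rng.normal(
                    cfg.copies_log10_mean[period], cfg.copies_log10_sd))
                copies.append(c)
                rep_seed = int(rng.integers(2**31))
                tables.append(simulate_peaks(
                    profile, panel, copies=c, model=cfg.dropout,
                    noise_cv=cfg.noise_cv, seed=rep_seed))
            rows.append({"individual": ind, "period": period, "hg": hg,
                         "copies_1": copies[0], "copies_2": copies[1]})
            replicates[ind] = (tables[0], tables[1])
    return StudyDataset(truth=pd.DataFrame(rows), replicates=replicates)


def run_study_pipeline(
    dataset: StudyDataset, panel: Panel, tree: HaploTree,
    method: str = "snp26",
) -> pd.DataFrame:
    """Decode + call + consensus for every simulated individual; returns a
    frame with per-replicate display calls, the consensus, and whether the
    true haplogroup was recovered as a reliable consensus."""
    from .consensus import ReplicateCalls, consensus_call
    from .electropherogram import decode_peaks
    from .phylogeny import call_haplogroup

    rows = []
    for _, t in dataset.truth.iterrows():
        pt1, pt2 = dataset.replicates[t.individual]
        calls = []
        for pt in (pt1, pt2):
            decoded = decode_peaks(pt, panel)
            calls.append(call_haplogroup(decoded.profile, tree))
        rep = ReplicateCalls(
            individual_id=t.individual, period=t.period, method=method,
            call_1=calls[0].display_label, call_2=calls[1].display_label)
        result = consensus_call(rep, tree)
        rows.append({
            "individual": t.individual, "period": t.period, "true_hg": t.hg,
            "call_1": calls[0].display_label, "call_2": calls[1].display_label,
            "reliable": result.reliable, "consensus": result.consensus_label,
            "recovered": bool(result.reliable
                              and result.consensus_label == t.hg),
        })
    return pd.DataFrame(rows)
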