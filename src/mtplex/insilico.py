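"""Virtual PCR and single-base extension genotyping.

Primer matching follows the standard PCR fidelity assumption for short
amplicons: the 3'-terminal 10 nt of a primer must match the template
exactly (mismatches there abolish extension), while up to ``max_mismatch``
mismatches (default 2) are tolerated in the 5' remainder. ``N`` or other
degenerate template bases always count as mismatches. Coordinates are
1-based closed intervals on the L strand; an amplicon runs from the 5'
terminus of the L primer through the 5' terminus of the H primer, so its
length equals the printed product size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq

from .panel import Panel, SnpAssay
from .phylogeny import ANCESTRAL, CONFLICT, DERIVED, MISSING, GenotypeProfile

RCRS_LENGTH = 16_569
ANCHOR_LEN = 10  # 3'-terminal bases requiring an exact match


class AmbiguousAmpliconError(ValueError):
    """A primer pair has more than one consistent placement (non-specific)."""


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class TemplateSeq:
    """An mtDNA template (L strand, 5'->3'). ``anchored`` means rCRS
    coordinates apply (1-based position == string index + 1)."""

    id: str
    sequence: str
    anchored: bool = False

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"template {self.id}: invalid characters {sorted(bad)}")


@dataclass(frozen=True)
class VariantList:
    """rCRS-relative variants: (1-based position, observed base) pairs."""

    sample_id: str
    entries: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.entries]
        if len(positions) != len(set(positions)):
            raise ValueError(f"{self.sample_id}: duplicate variant positions")
        for pos, base in self.entries:
            if base.upper() not in "ACGT" or len(base) != 1:
                raise ValueError(f"{self.sample_id}: invalid base {base!r} at {pos}")


@dataclass(frozen=True)
class AmpliconMatch:
    """1-based closed interval of a located amplicon on the template."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _match_positions(template: str, query: str, max_mismatch: int,
                     anchor_end: str) -> list[int]:
    """0-based start positions where ``query`` matches ``template`` with an
    exact ``ANCHOR_LEN``-mer at the 3' end (``anchor_end``: 'right' for an
    L-strand footprint of a forward primer, 'left' for the footprint of a
    reverse-complemented H primer) and <= max_mismatch elsewhere."""
    n, m = len(template), len(query)
    if m < ANCHOR_LEN:
        raise ValueError("query shorter than the 3' anchor")
    if anchor_end == "right":
        anchor, rest, rest_off = query[-ANCHOR_LEN:], query[:-ANCHOR_LEN], 0
        anchor_off = m - ANCHOR_LEN
    else:
        anchor, rest, rest_off = query[:ANCHOR_LEN], query[ANCHOR_LEN:], ANCHOR_LEN
        anchor_off = 0
    hits = []
    i = template.find(anchor)
    while i != -1:
        start = i - anchor_off
        if 0 <= start and start + m <= n:
            window = template[start + rest_off: start + rest_off + len(rest)]
            mism = sum(1 for a, b in zip(rest, window) if a != b)
            if mism <= max_mismatch:
                hits.append(start)
        i = template.find(anchor, i + 1)
    return hits


def find_amplicon(
    template: TemplateSeq, assay: SnpAssay, max_mismatch: int = 2
) -> Optional[AmpliconMatch]:
    """Locate the assay's amplicon on a template.

    Returns None when either primer has no acceptable binding site
    (distinct from the :class:`AmbiguousAmpliconError` raised when a
    primer pair could prime more than one product).
    """
    seq = template.sequence.upper()
    if not seq:
        raise ValueError("empty template")
    l_hits = _match_positions(seq, assay.l_primer_seq, max_mismatch, "right")
    h_foot = revcomp(assay.h_primer_seq)
    h_hits = _match_positions(seq, h_foot, max_mismatch, "left")
    pairs = [
        (pl, ph + len(h_foot) - 1)
        for pl in l_hits for ph in h_hits
        if ph + len(h_foot) - 1 > pl  # H 5' terminus downstream of L 5'
    ]
    if not pairs:
        return None
    if len(pairs) > 1:
        raise AmbiguousAmpliconError(
            f"assay {assay.site_id}: {len(pairs)} candidate placements")
    start0, end0 = pairs[0]
    return AmpliconMatch(start=start0 + 1, end=end0 + 1)


def _probe_read(seq: str, amplicon: AmpliconMatch, assay: SnpAssay) -> Optional[str]:
    """L-strand base interrogated by the SBE probe inside the amplicon, or
    None when the probe cannot anneal / the read base falls outside."""
    region = seq[amplicon.start - 1: amplicon.end]
    if assay.probe_orientation == "forward":
        footprint = assay.probe_seq
    else:
        footprint = revcomp(assay.probe_seq)
    first = region.find(footprint)
    if first == -1 or region.find(footprint, first + 1) != -1:
        return None
    if assay.probe_orientation == "forward":
        idx = first + len(footprint)  # base 3' of the probe, L strand
    else:
        idx = first - 1  # probe extends leftwards on the L strand
    if idx < 0 or idx >= len(region):
        return None
    return region[idx]


def genotype_from_sequence(
    template: TemplateSeq, panel: Panel, max_mismatch: int = 2
) -> GenotypeProfile:
    """Type all panel sites on a template sequence.

    Per assay: no amplicon or no probe annealing -> missing; interrogated
    base equal to one of the two assay alleles -> that state; any other
    unambiguous base -> conflict (off-panel allele).
    """
    seq = template.sequence.upper()
    states: dict[int, str] = {}
    for assay in panel:
        amplicon = find_amplicon(template, assay, max_mismatch)
        if amplicon is None:
            states[assay.site_id] = MISSING
            continue
        base = _probe_read(seq, amplicon, assay)
        if base is None or base == "N":
            states[assay.site_id] = MISSING
        elif base == assay.ancestral_allele:
            states[assay.site_id] = ANCESTRAL
        elif base == assay.derived_allele:
            states[assay.site_id] = DERIVED
        else:
            states[assay.site_id] = CONFLICT
    return GenotypeProfile(sample_id=template.id, states=states)


def genotype_from_variants(variants: VariantList, panel: Panel) -> GenotypeProfile:
    """Type panel sites from an rCRS-relative variant list.

    Unlisted panel sites are assumed to match the reference (ancestral);
    a listed third base is a conflict.
    """
    lookup = {}
    for pos, base in variants.entries:
        if not 1 <= pos <= RCRS_LENGTH:
            raise ValueError(
                f"{variants.sample_id}: position {pos} outside 1..{RCRS_LENGTH}")
        lookup[pos] = base.upper()
    states: dict[int, str] = {}
    for assay in panel:
        base = lookup.get(assay.site_id, assay.ancestral_allele)
        if base == assay.ancestral_allele:
            states[assay.site_id] = ANCESTRAL
        elif base == assay.derived_allele:
            states[assay.site_id] = DERIVED
        else:
            states[assay.site_id] = CONFLICT
    return GenotypeProfile(sample_id=variants.sample_id, states=states)


def load_fasta(path: Union[str, Path], anchored: bool = True) -> list[TemplateSeq]:
    return [
        TemplateSeq(id=rec.id, sequence=str(rec.seq).upper(), anchored=anchored)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(templates: list[TemplateSeq], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for t in templates:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.sequence), 70):
                fh.write(t.sequence[i: i + 70] + "\n")
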