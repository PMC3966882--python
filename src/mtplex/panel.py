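"""The 26-SNP mitochondrial founder-lineage SNaPshot panel.

Each assay in the panel amplifies a short (56-90 bp) mtDNA fragment and
interrogates one coding-region SNP by single-base extension (SBE): a probe
anneals immediately 5' of the SNP and is extended by a single fluorescent
ddNTP. The incorporated base is read on a capillary sequencer as a
(fragment size, dye colour) pair. Probes carry 5' poly-CT tails that space
the nominal fragment sizes 4 nt apart so all 26 assays separate in one
capillary run, and the (size, dye) -> (site, allele) mapping is injective,
which is what makes electropherogram decoding unambiguous.

This module loads the packaged panel definition, computes nominal fragment
lengths and detected-allele dye encodings, and validates every structural
invariant the multiplex design relies on.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional, Union

#: Fluorescent ddNTP colour encoding of the four bases (SNaPshot chemistry).
DYE_MAP = {"A": "green", "C": "yellow", "G": "blue", "T": "red"}

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
BASES = frozenset("ACGT")

FRAG_LEN_MIN, FRAG_LEN_MAX = 32, 80
AMPLICON_MIN, AMPLICON_MAX = 56, 90
FRAG_SPACING = 4
PANEL_SIZE = 26


class PanelError(ValueError):
    """Base class for panel loading/validation problems."""


class PanelParseError(PanelError):
    """A panel definition row could not be parsed."""


class PanelValidationError(PanelError):
    """A structural invariant of the panel is violated."""


@dataclass(frozen=True)
class SnpAssay:
    """One SBE assay: a PCR primer pair plus a tailed extension probe.

    ``ancestral_allele``/``derived_allele`` are L-strand bases in rCRS
    orientation, taken from the site label (e.g. G12007A: ancestral G,
    derived A). ``probe_orientation`` is ``"forward"`` when the probe
    anneals to the H strand and reads the L-strand base directly, and
    ``"reverse"`` when it anneals to the L strand and reads the
    complement.
    """

    site_id: int
    hg_label: str
    ancestral_allele: str
    derived_allele: str
    l_primer_name: str
    l_primer_seq: str
    h_primer_name: str
    h_primer_seq: str
    pcr_conc: float
    amplicon_len: int
    n_ct_repeats: int
    extra_c: bool
    probe_seq: str
    probe_orientation: str
    probe_conc: float
    nominal_frag_len: int

    @property
    def tail_seq(self) -> str:
        return "ct" * self.n_ct_repeats + ("c" if self.extra_c else "")

    @property
    def alleles(self) -> tuple[str, str]:
        return self.ancestral_allele, self.derived_allele

    @property
    def detected_allele_dyes(self) -> tuple[tuple[str, str], tuple[str, str]]:
        """((base, dye) for ancestral, (base, dye) for derived) as read
        on the capillary, i.e. after strand complementation for reverse
        probes."""
        return (
            detected_base_and_dye(self, self.ancestral_allele),
            detected_base_and_dye(self, self.derived_allele),
        )


def fragment_length(assay: SnpAssay) -> int:
    """Nominal SBE product size in nt: poly-CT tail + probe (the extended
    ddNTP is not counted; sizes are binned relative to the same offset)."""
    if not assay.probe_seq:
        raise ValueError(f"assay {assay.site_id}: empty probe sequence")
    return 2 * assay.n_ct_repeats + int(assay.extra_c) + len(assay.probe_seq)


def detected_base_and_dye(
    assay: SnpAssay, template_allele: str, dye_map: Optional[dict] = None
) -> tuple[str, str]:
    """Base and dye colour observed on the capillary for a template allele.

    Forward probes incorporate the template base itself; reverse probes
    anneal to the opposite strand and incorporate its complement.
    """
    dye_map = DYE_MAP if dye_map is None else dye_map
    if template_allele not in assay.alleles:
        raise ValueError(
            f"assay {assay.site_id}: template base {template_allele!r} is "
            f"neither the ancestral ({assay.ancestral_allele}) nor derived "
            f"({assay.derived_allele}) allele"
        )
    if assay.probe_orientation == "forward":
        base = template_allele
    else:
        base = COMPLEMENT[template_allele]
    return base, dye_map[base]


@dataclass
class Panel:
    """The full multiplex: 26 assays plus decoding constants."""

    assays: list[SnpAssay]
    dye_map: dict = field(default_factory=lambda: dict(DYE_MAP))
    min_peak_rfu: float = 50.0
    target_rfu: float = 3000.0
    size_tolerance_nt: float = 1.5

    def __post_init__(self) -> None:
        self._by_site = {a.site_id: a for a in self.assays}

    def __iter__(self) -> Iterator[SnpAssay]:
        return iter(self.assays)

    def __len__(self) -> int:
        return len(self.assays)

    @property
    def sites(self) -> list[int]:
        return [a.site_id for a in self.assays]

    def assay_by_site(self, site_id: int) -> SnpAssay:
        try:
            return self._by_site[site_id]
        except KeyError:
            raise KeyError(f"no assay at site {site_id}") from None


@dataclass(frozen=True)
class CheckResult:
    check: str
    site: Optional[int]
    passed: bool
    detail: str = ""


_COLUMNS = [
    "site", "hg", "ancestral", "derived", "l_name", "l_seq", "h_name",
    "h_seq", "pcr_conc_uM", "amplicon_bp", "tail_ct", "tail_extra_c",
    "probe_seq", "orientation", "probe_conc_uM", "frag_nt",
]


def _parse_row(row: dict) -> SnpAssay:
    site_raw = row.get("site", "?")
    try:
        return SnpAssay(
            site_id=int(row["site"]),
            hg_label=row["hg"],
            ancestral_allele=row["ancestral"].upper(),
            derived_allele=row["derived"].upper(),
            l_primer_name=row["l_name"],
            l_primer_seq=row["l_seq"].upper(),
            h_primer_name=row["h_name"],
            h_primer_seq=row["h_seq"].upper(),
            pcr_conc=float(row["pcr_conc_uM"]),
            amplicon_len=int(row["amplicon_bp"]),
            n_ct_repeats=int(row["tail_ct"]),
            extra_c=bool(int(row["tail_extra_c"])),
            probe_seq=row["probe_seq"].upper(),
            probe_orientation=row["orientation"],
            probe_conc=float(row["probe_conc_uM"]),
            nominal_frag_len=int(row["frag_nt"]),
        )
    except (KeyError, ValueError) as exc:
        raise PanelParseError(f"malformed panel row for site {site_raw}: {exc}") from exc


def validate_panel(panel: Panel) -> list[CheckResult]:
    """Check every structural invariant; failures are report entries, not
    exceptions."""
    report: list[CheckResult] = []

    report.append(CheckResult(
        "panel_size", None, len(panel) == PANEL_SIZE,
        f"{len(panel)} assays (expected {PANEL_SIZE})"))

    sites = panel.sites
    dup = sorted({s for s in sites if sites.count(s) > 1})
    report.append(CheckResult(
        "unique_sites", None, not dup,
        f"duplicated sites: {dup}" if dup else "all site ids unique"))

    for a in panel:
        ok_alleles = (
            a.ancestral_allele in BASES and a.derived_allele in BASES
            and a.ancestral_allele != a.derived_allele
        )
        report.append(CheckResult(
            "alleles_valid", a.site_id, ok_alleles,
            f"{a.ancestral_allele}->{a.derived_allele}"))

        ok_orient = a.probe_orientation in ("forward", "reverse")
        report.append(CheckResult(
            "orientation_valid", a.site_id, ok_orient, a.probe_orientation))

        computed = fragment_length(a) if a.probe_seq else -1
        report.append(CheckResult(
            "fragment_arithmetic", a.site_id, computed == a.nominal_frag_len,
            f"tail+probe = {computed}, printed nt = {a.nominal_frag_len}"))

        report.append(CheckResult(
            "fragment_range", a.site_id,
            FRAG_LEN_MIN <= a.nominal_frag_len <= FRAG_LEN_MAX,
            f"{a.nominal_frag_len} nt"))

        report.append(CheckResult(
            "fragment_mod4", a.site_id,
            a.nominal_frag_len % FRAG_SPACING == 0,
            f"{a.nominal_frag_len} % {FRAG_SPACING} = "
            f"{a.nominal_frag_len % FRAG_SPACING}"))

        report.append(CheckResult(
            "amplicon_range", a.site_id,
            AMPLICON_MIN <= a.amplicon_len <= AMPLICON_MAX,
            f"{a.amplicon_len} bp"))

        if ok_alleles and ok_orient:
            expect = set(a.alleles) if a.probe_orientation == "forward" else {
                COMPLEMENT[b] for b in a.alleles}
            got = {b for b, _ in a.detected_allele_dyes}
            report.append(CheckResult(
                "detected_alleles", a.site_id, got == expect,
                f"detected {sorted(got)}, expected {sorted(expect)}"))

    # Decoding injectivity: (nominal size, dye) -> (site, allele) must be 1:1
    # across all assays and both alleles.
    seen: dict[tuple[int, str], tuple[int, str]] = {}
    collisions = []
    for a in panel:
        if (a.probe_orientation not in ("forward", "reverse")
                or not set(a.alleles) <= BASES):
            continue
        for allele in a.alleles:
            _, dye = detected_base_and_dye(a, allele, panel.dye_map)
            key = (a.nominal_frag_len, dye)
            if key in seen:
                collisions.append((key, seen[key], (a.site_id, allele)))
            else:
                seen[key] = (a.site_id, allele)
    report.append(CheckResult(
        "size_dye_injective", None, not collisions,
        f"colliding (size, dye) bins: {collisions}" if collisions
        else f"{len(seen)} distinct (size, dye) bins"))

    return report


def report_failures(report: list[CheckResult]) -> list[CheckResult]:
    return [r for r in report if not r.passed]


def load_panel(source: Union[str, Path, None] = None, strict: bool = True) -> Panel:
    """Load a panel definition TSV; ``source=None`` loads the packaged
    26-assay default. With ``strict`` (default), any invariant violation
    raises :class:`PanelValidationError` naming the check and site."""
    if source is None:
        text = (resources.files("mtplex.data") / "panel.tsv").read_text()
    else:
        text = Path(source).read_text()
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    if reader.fieldnames is None or [c for c in _COLUMNS if c not in reader.fieldnames]:
        missing = [] if reader.fieldnames is None else [
            c for c in _COLUMNS if c not in reader.fieldnames]
        raise PanelParseError(f"panel definition missing columns: {missing or _COLUMNS}")
    assays = [_parse_row(row) for row in reader]
    panel = Panel(assays=assays)
    if strict:
        failures = report_failures(validate_panel(panel))
        if failures:
            f = failures[0]
            where = f"site {f.site}" if f.site is not None else "panel"
            names = sorted({r.check for r in failures})
            raise PanelValidationError(
                f"invariant {f.check!r} violated at {where}: {f.detail} "
                f"(failed checks: {', '.join(names)})")
    return panel
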