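"""Panel-restricted mtDNA haplogroup phylogeny and genotype-to-call rules.

The typing scheme is a pruned mtDNA tree in which each of the 26 panel
SNPs annotates exactly one edge. The root is the reference (all-ancestral)
state: site labels are written with the non-American base first in rCRS
orientation, and the rCRS itself falls inside macro-haplogroup N, so a
profile that is ancestral at every site is simply "unassigned" (typically
a non-American lineage). Macro-haplogroup M (site 14783) is the only deep
node with its own panel SNP; the basal hg C and hg D nodes carry no panel
site and exist only to structure ancestor queries — they are never emitted
as calls (an M-side profile with no sub-haplogroup support is called "M").

A call can be:

* ``unambiguous`` — every site on the root-to-node path observed derived;
* ``tentative`` — the node's own site derived but >=1 path site above it
  unobserved (rendered with a "?" suffix, e.g. "D1?");
* ``unassigned`` — sites observed but none derived;
* ``conflict`` — derived sites on incompatible branches, or a derived site
  below an observed-ancestral path site;
* ``failed`` — no site observed at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .panel import Panel

ROOT = "reference"

#: Parent of every nameable node in the typing scheme. N, C and D are
#: structural (no panel SNP of their own).
TREE_PARENTS = {
    "N": ROOT,
    "M": ROOT,
    "A2": "N", "A2a": "A2", "A2b": "A2", "A2b1": "A2b",
    "B4b": "N", "B2": "B4b",
    "B2a": "B2", "B2b": "B2", "B2c": "B2", "B2d": "B2", "B2e": "B2",
    "B2f": "B2",
    "X2a": "N",
    "C": "M",
    "C1b": "C", "C1c1a": "C", "C1c2": "C", "C1d": "C", "C4c": "C",
    "C1d1": "C1d",
    "D": "M",
    "D1": "D", "D2a1": "D", "D2a2": "D", "D2b": "D", "D4b1": "D",
    "D4h3a": "D",
}

STRUCTURAL_NODES = frozenset({"N", "C", "D"})

ANCESTRAL, DERIVED, MISSING, CONFLICT = "ancestral", "derived", "missing", "conflict"
STATES = frozenset({ANCESTRAL, DERIVED, MISSING, CONFLICT})


class TreeConstructionError(ValueError):
    pass


@dataclass
class HaploTree:
    """Rooted haplogroup tree; each non-structural node owns one panel site."""

    parent: dict[str, str]
    site_of: dict[str, Optional[int]]

    def __post_init__(self) -> None:
        self.node_of_site = {
            s: n for n, s in self.site_of.items() if s is not None}
        self._depth: dict[str, int] = {ROOT: 0}
        for node in self.parent:
            self.depth(node)

    @property
    def nodes(self) -> list[str]:
        return [ROOT] + list(self.parent)

    @property
    def sites(self) -> list[int]:
        return sorted(self.node_of_site)

    def depth(self, node: str) -> int:
        if node not in self._depth:
            self._depth[node] = 1 + self.depth(self.parent[node])
        return self._depth[node]

    def path_nodes(self, node: str) -> list[str]:
        """Nodes from the root (exclusive) down to ``node`` (inclusive)."""
        if node == ROOT:
            return []
        if node not in self.parent:
            raise KeyError(f"unknown haplogroup {node!r}")
        path = []
        while node != ROOT:
            path.append(node)
            node = self.parent[node]
        return path[::-1]

    def path_sites(self, node: str) -> list[int]:
        """Panel sites annotating the root-to-node path, shallow first."""
        return [self.site_of[n] for n in self.path_nodes(node)
                if self.site_of[n] is not None]

    def is_ancestor(self, a: str, b: str) -> bool:
        """True iff ``a`` lies strictly above ``b``."""
        if a not in self.parent and a != ROOT:
            raise KeyError(f"unknown haplogroup {a!r}")
        return a != b and self.is_ancestor_or_equal(a, b)

    def is_ancestor_or_equal(self, a: str, b: str) -> bool:
        for known in (a, b):
            if known not in self.parent and known != ROOT:
                raise KeyError(f"unknown haplogroup {known!r}")
        node = b
        while True:
            if node == a:
                return True
            if node == ROOT:
                return False
            node = self.parent[node]

    def mrca(self, a: str, b: str) -> str:
        anc = set([a] + [ROOT] + self.path_nodes(a))
        node = b
        while node not in anc:
            node = self.parent[node]
        return node


def build_tree(panel: Panel, sites: Optional[Iterable[int]] = None) -> HaploTree:
    """Build the typing tree from a panel, optionally restricted to a site
    subset (edges through excluded sited nodes are contracted; structural
    nodes are always retained)."""
    include = set(panel.sites if sites is None else sites)
    unknown = include - set(panel.sites)
    if unknown:
        raise TreeConstructionError(f"sites not in panel: {sorted(unknown)}")

    site_of: dict[str, Optional[int]] = {n: None for n in STRUCTURAL_NODES}
    for assay in panel:
        if assay.site_id not in include:
            continue
        if assay.hg_label not in TREE_PARENTS:
            raise TreeConstructionError(
                f"panel site {assay.site_id} (hg {assay.hg_label!r}) has no "
                f"placement in the typing scheme")
        if site_of.get(assay.hg_label) is not None:
            raise TreeConstructionError(
                f"haplogroup {assay.hg_label!r} defined by two sites")
        site_of[assay.hg_label] = assay.site_id

    parent: dict[str, str] = {}
    for node in site_of:
        anc = TREE_PARENTS[node]
        while anc != ROOT and anc not in site_of:
            anc = TREE_PARENTS[anc]  # contract through excluded nodes
        parent[node] = anc
    return HaploTree(parent=parent, site_of=site_of)


@dataclass
class GenotypeProfile:
    """Per-site allele states for one sample (keys are panel sites)."""

    sample_id: str
    states: dict[int, str]

    def sites_in_state(self, state: str) -> list[int]:
        return sorted(s for s, st in self.states.items() if st == state)


@dataclass
class HaplogroupCall:
    label: str
    status: str  # unambiguous | tentative | unassigned | conflict | failed
    supporting_sites: list[int] = field(default_factory=list)
    missing_path_sites: list[int] = field(default_factory=list)
    conflicting_sites: list[int] = field(default_factory=list)

    @property
    def display_label(self) -> str:
        """Label as printed in a results table ("D1?" for tentative)."""
        if self.status == "tentative":
            return self.label + "?"
        if self.status in ("unassigned", "conflict", "failed"):
            return {"unassigned": "unassigned", "conflict": "conflict",
                    "failed": "-"}[self.status]
        return self.label

    def to_dict(self, sample_id: str = "") -> dict:
        return {
            "sample": sample_id,
            "label": self.display_label,
            "status": self.status,
            "supporting_sites": self.supporting_sites,
            "missing_path_sites": self.missing_path_sites,
            "conflicting_sites": self.conflicting_sites,
        }


def call_haplogroup(profile: GenotypeProfile, tree: HaploTree) -> HaplogroupCall:
    """Map a 26-site genotype profile to a sub-haplogroup call.

    The call is the deepest node whose defining site is derived, with the
    status graded by the state of the sites above it (see module
    docstring). Heteroplasmy-like per-site ``conflict`` states are treated
    as uninformative for the tree walk but are reported, and demote an
    otherwise-unambiguous call to tentative.
    """
    unknown_sites = set(profile.states) - set(tree.node_of_site)
    if unknown_sites:
        raise KeyError(f"profile sites not in panel tree: {sorted(unknown_sites)}")
    bad_states = {st for st in profile.states.values()} - STATES
    if bad_states:
        raise ValueError(f"unknown genotype states: {sorted(bad_states)}")

    states = profile.states
    conflict_state_sites = profile.sites_in_state(CONFLICT)
    derived_sites = profile.sites_in_state(DERIVED)
    observed = [s for s, st in states.items() if st != MISSING]

    if not observed:
        return HaplogroupCall(label="unassigned", status="failed")

    if not derived_sites:
        return HaplogroupCall(
            label="unassigned", status="unassigned",
            conflicting_sites=conflict_state_sites)

    derived_nodes = [tree.node_of_site[s] for s in derived_sites]
    maximal = [
        n for n in derived_nodes
        if not any(m != n and tree.is_ancestor(n, m) for m in derived_nodes)
    ]
    maximal = sorted(set(maximal), key=tree.depth)
    if len(maximal) > 1:
        return HaplogroupCall(
            label="unassigned", status="conflict",
            conflicting_sites=sorted(
                tree.site_of[n] for n in maximal) + conflict_state_sites)

    deepest = maximal[0]
    path = tree.path_sites(deepest)
    ancestral_on_path = [s for s in path if states.get(s) == ANCESTRAL]
    if ancestral_on_path:
        # A derived site sits below an observed-ancestral one: internally
        # inconsistent profile (e.g. contamination/mistyping).
        below = [s for s in path
                 if states.get(s) == DERIVED
                 and tree.depth(tree.node_of_site[s])
                 > min(tree.depth(tree.node_of_site[a]) for a in ancestral_on_path)]
        return HaplogroupCall(
            label="unassigned", status="conflict",
            conflicting_sites=sorted(set(ancestral_on_path + below))
            + conflict_state_sites)

    supporting = [s for s in path if states.get(s) == DERIVED]
    missing_on_path = [s for s in path
                       if states.get(s, MISSING) in (MISSING, CONFLICT)]
    if missing_on_path:
        return HaplogroupCall(
            label=deepest, status="tentative",
            supporting_sites=supporting,
            missing_path_sites=missing_on_path,
            conflicting_sites=conflict_state_sites)
    if conflict_state_sites:
        # Full path support, but heteroplasmy-like signal elsewhere: the
        # label stands, yet the profile is not clean enough to report as
        # unambiguous.
        return HaplogroupCall(
            label=deepest, status="tentative",
            supporting_sites=supporting,
            conflicting_sites=conflict_state_sites)
    return HaplogroupCall(
        label=deepest, status="unambiguous", supporting_sites=supporting)


def profile_for(
    hg: str, tree: HaploTree, panel: Panel, sample_id: Optional[str] = None
) -> GenotypeProfile:
    """Idealised full profile for a haplogroup: derived along its path,
    ancestral at every other panel site."""
    path = set(tree.path_sites(hg))
    return GenotypeProfile(
        sample_id=sample_id or hg,
        states={s: (DERIVED if s in path else ANCESTRAL) for s in panel.sites},
    )
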