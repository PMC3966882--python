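"""Replicate-pair consensus calling and study-level success summaries.

Ancient-DNA typing results are only trusted when two independently
extracted samples of the same individual can both be assigned
unambiguously and the two assignments are phylogenetically concordant
(equal, or one the ancestor of the other); the consensus is then the last
common node of the two calls. Tentative calls (a "?" suffix) and outright
failures ("?" / "-") never contribute to a reliable consensus.

The packaged fixture transcribes a published two-method comparison on
pre-Columbian Peruvian individuals from three cultural horizons (Early
Intermediate, Middle Horizon, Late Intermediate) typed both with the
26-SNP panel (``snp26``) and by classical HVR-I Sanger sequencing
(``hvr1``, consumed here as coded haplogroup labels).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .phylogeny import ROOT, HaploTree

PERIODS = ("EI", "MH", "LI", "control")
METHODS = ("snp26", "hvr1")

#: Individuals typed per period in the packaged study (listed fixture rows
#: cover only those with at least one unambiguous panel consensus).
DEFAULT_N_TESTED = {"EI": 20, "MH": 20, "LI": 12}

FAILURE_TOKENS = {"?", "-", ""}


def parse_call(raw: Optional[str]) -> tuple[Optional[str], bool]:
    """Split a printed call into (label, tentative). "?"/"-"/empty mean no
    call at all; a trailing "?" on a label marks a tentative call."""
    if raw is None:
        return None, False
    raw = raw.strip()
    if raw in FAILURE_TOKENS:
        return None, False
    if raw.endswith("?"):
        return raw[:-1], True
    return raw, False


@dataclass(frozen=True)
class ReplicateCalls:
    individual_id: str
    period: str
    method: str
    call_1: Optional[str]
    call_2: Optional[str]
    printed_consensus: Optional[str] = None

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise ValueError(f"unknown period {self.period!r}")


@dataclass(frozen=True)
class ConsensusResult:
    individual_id: str
    reliable: bool
    consensus_label: Optional[str]


def is_concordant(call_1: str, call_2: str, tree: HaploTree) -> bool:
    """True iff two unambiguous labels are equal or nested in the tree.

    Equal labels short-circuit before any tree lookup so that coded
    labels from outside the panel tree (e.g. HVR-I "B4"/"C1") compare;
    unequal labels must both be tree nodes (unknown -> KeyError).
    """
    if call_1 is None or call_2 is None:
        raise ValueError("is_concordant requires two non-null calls")
    if call_1 == call_2:
        return True
    return (tree.is_ancestor_or_equal(call_1, call_2)
            or tree.is_ancestor_or_equal(call_2, call_1))


def consensus_call(rep: ReplicateCalls, tree: HaploTree) -> ConsensusResult:
    """Reliable iff both replicates called unambiguously and concordant;
    the consensus is the shallower (last common) of the two labels."""
    label_1, tent_1 = parse_call(rep.call_1)
    label_2, tent_2 = parse_call(rep.call_2)
    if label_1 is None or label_2 is None or tent_1 or tent_2:
        return ConsensusResult(rep.individual_id, False, None)
    try:
        concordant = is_concordant(label_1, label_2, tree)
    except KeyError:
        return ConsensusResult(rep.individual_id, False, None)
    if not concordant:
        return ConsensusResult(rep.individual_id, False, None)
    if label_1 == label_2:
        consensus = label_1
    else:
        consensus = label_1 if tree.is_ancestor(label_1, label_2) else label_2
    return ConsensusResult(rep.individual_id, True, consensus)


@dataclass
class StudySummary:
    """Per period x method reliable-consensus counts and percentages."""

    table: pd.DataFrame  # columns: period, method, n_tested, n_reliable, pct_reliable
    totals: dict[str, dict[str, float]]  # method -> {n_tested, n_reliable, pct}

    def counts(self, method: str) -> dict[str, int]:
        sub = self.table[self.table.method == method]
        return dict(zip(sub.period, sub.n_reliable))


def summarize_study(
    records: Sequence[ReplicateCalls],
    n_tested: Optional[dict[str, int]] = None,
    tree: Optional[HaploTree] = None,
) -> StudySummary:
    if tree is None:
        raise ValueError("a haplogroup tree is required")
    n_tested = dict(DEFAULT_N_TESTED if n_tested is None else n_tested)
    missing = {r.period for r in records} - set(n_tested)
    if missing:
        raise ValueError(f"periods without an n_tested entry: {sorted(missing)}")

    methods = sorted({r.method for r in records}) or list(METHODS)
    rows = []
    totals: dict[str, dict[str, float]] = {}
    for method in methods:
        total_rel = 0
        total_n = 0
        for period in n_tested:
            subset = [r for r in records
                      if r.period == period and r.method == method]
            n_rel = sum(consensus_call(r, tree).reliable for r in subset)
            n = n_tested[period]
            if n_rel > n:
                raise ValueError(
                    f"{method}/{period}: {n_rel} reliable among n_tested={n}")
            rows.append({
                "period": period, "method": method, "n_tested": n,
                "n_reliable": n_rel, "pct_reliable": 100.0 * n_rel / n if n else 0.0,
            })
            total_rel += n_rel
            total_n += n
        totals[method] = {
            "n_tested": total_n, "n_reliable": total_rel,
            "pct_reliable": 100.0 * total_rel / total_n if total_n else 0.0,
        }
    return StudySummary(table=pd.DataFrame(rows), totals=totals)


def paired_outcomes(
    records: Sequence[ReplicateCalls],
    n_tested: Optional[dict[str, int]] = None,
    tree: Optional[HaploTree] = None,
    methods: tuple[str, str] = METHODS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual binary success for each method, padding every period
    to ``n_tested`` with individuals that failed both methods (unlisted
    samples yielded no reliable consensus by either route)."""
    n_tested = dict(DEFAULT_N_TESTED if n_tested is None else n_tested)
    by_ind: dict[str, dict[str, bool]] = {}
    periods: dict[str, str] = {}
    for r in records:
        by_ind.setdefault(r.individual_id, {})[r.method] = (
            consensus_call(r, tree).reliable)
        periods[r.individual_id] = r.period
    a, b = [], []
    for ind, res in by_ind.items():
        a.append(res.get(methods[0], False))
        b.append(res.get(methods[1], False))
    for period, n in n_tested.items():
        listed = sum(1 for p in periods.values() if p == period)
        if listed > n:
            raise ValueError(f"{period}: {listed} listed individuals > n_tested {n}")
        a.extend([False] * (n - listed))
        b.extend([False] * (n - listed))
    return np.asarray(a, dtype=int), np.asarray(b, dtype=int)


@dataclass
class ComparisonResult:
    n_pairs: int
    n_discordant: int
    n_favoring_a: int
    sign_test_p: float
    wilcoxon_stat: float
    wilcoxon_p: float


def compare_methods(
    outcomes_a: Sequence[int], outcomes_b: Sequence[int]
) -> ComparisonResult:
    """Paired comparison of two methods' binary success outcomes.

    Primary: exact two-sided sign test on discordant pairs. Also reported:
    Wilcoxon signed-rank on the paired 0/1 outcomes with ties dropped
    (on binary data this carries the same information as the sign test).
    """
    a = np.asarray(outcomes_a, dtype=int)
    b = np.asarray(outcomes_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("paired outcome vectors differ in length")
    diff = a - b
    n_disc = int(np.sum(diff != 0))
    n_favor_a = int(np.sum(diff > 0))
    if n_disc == 0:
        return ComparisonResult(len(a), 0, 0, 1.0, 0.0, 1.0)
    sign_p = stats.binomtest(n_favor_a, n_disc, 0.5).pvalue
    w = stats.wilcoxon(diff[diff != 0], zero_method="wilcox")
    return ComparisonResult(
        n_pairs=len(a), n_discordant=n_disc, n_favoring_a=n_favor_a,
        sign_test_p=float(sign_p), wilcoxon_stat=float(w.statistic),
        wilcoxon_p=float(w.pvalue))


# ---------------------------------------------------------------------------
# Fixture IO

def _records_from_frame(df: pd.DataFrame) -> list[ReplicateCalls]:
    return [
        ReplicateCalls(
            individual_id=row["individual"], period=row["period"],
            method=row["method"],
            call_1=None if pd.isna(row["call_1"]) else str(row["call_1"]),
            call_2=None if pd.isna(row["call_2"]) else str(row["call_2"]),
            printed_consensus=(None if "printed_consensus" not in row
                               or pd.isna(row["printed_consensus"])
                               else str(row["printed_consensus"])),
        )
        for _, row in df.iterrows()
    ]


def load_replicate_calls(path: Union[str, Path, None] = None) -> list[ReplicateCalls]:
    """Read a replicate-calls TSV; ``path=None`` loads the packaged study
    fixture."""
    if path is None:
        with resources.as_file(
                resources.files("mtplex.data") / "replicate_calls.tsv") as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    return _records_from_frame(df)


def write_replicate_calls(records: Sequence[ReplicateCalls],
                          path: Union[str, Path]) -> None:
    df = pd.DataFrame([
        {"individual": r.individual_id, "period": r.period, "method": r.method,
         "call_1": r.call_1, "call_2": r.call_2,
         "printed_consensus": r.printed_consensus}
        for r in records
    ])
    df.to_csv(path, sep="\t", index=False)
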