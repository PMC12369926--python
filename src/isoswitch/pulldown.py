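"""Spectral-count enrichment for bait-vs-control pulldowns, and emPAI.

Proteins recovered with a GST-SH3 bait are compared against a GST-only
control by a likelihood-ratio (G) test on summed spectral counts with
library-size offsets, BH-corrected across proteins; a protein is a
significant interactor when q <= alpha and its rate is higher in the bait.
The subset report compares interactor sets between two baits (e.g. the
neuronal and ubiquitous SH3 variants, where the neuronal set is expected
to be a subset).

emPAI (exponentially modified protein abundance index) is
10**(observed/observable) - 1, with observable peptides counted by an in
silico tryptic digest (cleave after K/R, not before P, no missed
cleavages) filtered on monoisotopic mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import mass as pmass
from pyteomics import parser as pparser
from scipy import stats
from statsmodels.stats.multitest import multipletests

BAITS = ("GST", "C_SH3", "N1_SH3")
SPECTRAL_COLUMNS = ["protein", "bait", "replicate", "count"]

DEFAULT_ALPHA = 0.05
DEFAULT_MASS_RANGE = (500.0, 5000.0)


@dataclass
class EnrichmentCall:
    protein: str
    bait: str
    p: float
    q: float
    significant: bool
    count_bait: int
    count_control: int


def _g_statistic(x: int, y: int, nx: float, ny: float) -> float:
    """2-cell G statistic for count x (library nx) vs y (library ny)."""
    total = x + y
    if total == 0:
        return 0.0
    ex = total * nx / (nx + ny)
    ey = total * ny / (nx + ny)
    g = 0.0
    if x:
        g += x * math.log(x / ex)
    if y:
        g += y * math.log(y / ey)
    return 2.0 * g


def enrichment_test(records: pd.DataFrame, bait: str, control: str = "GST",
                    alpha: float = DEFAULT_ALPHA) -> list[EnrichmentCall]:
    """Per-protein bait-vs-control enrichment calls.

    ``records`` is a long table (protein, bait, replicate, count).  Counts
    are summed over replicates; proteins absent from both samples are
    skipped.  With a single replicate per bait the test degrades to the
    pooled two-sample comparison (a warning-free design decision: the G
    test only ever sees summed counts).
    """
    sub = records[records["bait"].isin([bait, control])]
    sums = sub.pivot_table(index="protein", columns="bait", values="count",
                           aggfunc="sum", fill_value=0)
    for col in (bait, control):
        if col not in sums:
            sums[col] = 0
    lib = {col: float(sums[col].sum()) for col in (bait, control)}
    if lib[bait] == 0 or lib[control] == 0:
        raise ValueError("empty library for bait or control")

    sums = sums[(sums[bait] + sums[control]) > 0]
    pvals = np.array([
        stats.chi2.sf(_g_statistic(int(r[bait]), int(r[control]),
                                   lib[bait], lib[control]), df=1)
        for _, r in sums.iterrows()
    ])
    qvals = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals
    calls = []
    for (protein, row), p, q in zip(sums.iterrows(), pvals, qvals):
        enriched = row[bait] / lib[bait] > row[control] / lib[control]
        calls.append(EnrichmentCall(
            protein=protein, bait=bait, p=float(p), q=float(q),
            significant=bool(q <= alpha and enriched),
            count_bait=int(row[bait]), count_control=int(row[control]),
        ))
    calls.sort(key=lambda c: (c.q, c.protein))
    return calls


@dataclass
class SubsetReport:
    set_a: set[str]
    set_b: set[str]
    intersection: set[str]
    only_a: set[str]
    only_b: set[str]
    ratio_table: pd.DataFrame  # per-protein count ratio b/a on shared proteins


def subset_report(calls_a: list[EnrichmentCall],
                  calls_b: list[EnrichmentCall]) -> SubsetReport:
    """Set relations between the significant interactors of two baits."""
    sig_a = {c.protein for c in calls_a if c.significant}
    sig_b = {c.protein for c in calls_b if c.significant}
    counts_a = {c.protein: c.count_bait for c in calls_a}
    counts_b = {c.protein: c.count_bait for c in calls_b}
    shared = sorted(sig_a | sig_b)
    rows = []
    for protein in shared:
        ca = counts_a.get(protein, 0)
        cb = counts_b.get(protein, 0)
        rows.append({
            "protein": protein,
            "count_a": ca,
            "count_b": cb,
            "ratio_b_over_a": (cb / ca) if ca else math.inf,
        })
    return SubsetReport(
        set_a=sig_a,
        set_b=sig_b,
        intersection=sig_a & sig_b,
        only_a=sig_a - sig_b,
        only_b=sig_b - sig_a,
        ratio_table=pd.DataFrame(rows, columns=["protein", "count_a", "count_b",
                                                "ratio_b_over_a"]),
    )


def empai(n_observed: int, n_observable: int) -> float:
    """Exponentially modified protein abundance index."""
    if n_observable < 1:
        raise ValueError("need at least one observable peptide")
    if not 0 <= n_observed <= n_observable:
        raise ValueError("observed peptides must lie in [0, observable]")
    return 10.0 ** (n_observed / n_observable) - 1.0


def tryptic_peptides(protein_seq: str) -> list[str]:
    """Ordered tryptic peptides (after K/R, not before P, no missed cleavages)."""
    if not protein_seq:
        return []
    if set(protein_seq) - set(pparser.std_amino_acids):
        bad = sorted(set(protein_seq) - set(pparser.std_amino_acids))
        raise ValueError(f"unknown residues {bad}")
    return [pep for _, pep in
            pparser.icleave(protein_seq, pparser.expasy_rules["trypsin"], 0)]


def observable_peptides(protein_seq: str,
                        min_mass: float = DEFAULT_MASS_RANGE[0],
                        max_mass: float = DEFAULT_MASS_RANGE[1]) -> int:
    """Number of tryptic peptides with monoisotopic mass in [min, max]."""
    count = 0
    for pep in tryptic_peptides(protein_seq):
        m = pmass.fast_mass(pep)
        if min_mass <= m <= max_mass:
            count += 1
    return count
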