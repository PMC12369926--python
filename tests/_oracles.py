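"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own algorithms: sequence operations
work character by character, the splice-event oracle reasons over exonic
coverage sets rather than splice-site chains, and the motif oracle rescores
every window with explicit loops.
"""

from __future__ import annotations

import math

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_CODON_TABLE = {}


def _build_codon_table():
    bases = "TCAG"
    amino = ("FFLLSSSSYY**CC*W" "LLLLPPPPHHQQRRRR"
             "IIIMTTTTNNKKSSRR" "VVVVAAAADDEEGGGG")
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                _CODON_TABLE[b1 + b2 + b3] = amino[i]
                i += 1


_build_codon_table()


def naive_revcomp(seq: str) -> str:
    out = []
    for c in reversed(seq):
        out.append(_COMPLEMENT[c])
    return "".join(out)


def naive_translate(mrna: str, cds_start: int) -> tuple[str, bool]:
    """Codon-by-codon translation to the first stop; (protein, ran_off_end)."""
    aa = []
    i = cds_start
    while i + 3 <= len(mrna):
        codon = mrna[i:i + 3]
        res = _CODON_TABLE[codon]
        if res == "*":
            return "".join(aa), False
        aa.append(res)
        i += 3
    return "".join(aa), True


# ---------------------------------------------------------------------------
# Splice-event oracle: exhaustive case analysis on exon coverage
# ---------------------------------------------------------------------------

def _internal_sites(exons):
    sites = set()
    for i, (s, e) in enumerate(exons):
        if i > 0:
            sites.add((s, "S"))
        if i < len(exons) - 1:
            sites.add((e, "E"))
    return sites


def _covered(exons, x):
    return any(s <= x < e for s, e in exons)


def _diff_intervals(exons_a, exons_b, lo, hi):
    """Maximal intervals in [lo, hi) where exonic coverage differs."""
    points = sorted({lo, hi}
                    | {p for s, e in exons_a for p in (s, e) if lo <= p <= hi}
                    | {p for s, e in exons_b for p in (s, e) if lo <= p <= hi})
    out = []
    for x, y in zip(points, points[1:]):
        ca, cb = _covered(exons_a, x), _covered(exons_b, x)
        if ca != cb:
            # merge only runs covered by the same chain; abutting intervals
            # covered by opposite chains are distinct structures
            if out and out[-1][1] == x and out[-1][2] == ca:
                out[-1] = (out[-1][0], y, ca)
            else:
                out.append((x, y, ca))
    return [(x, y) for x, y, _ in out]


def _classify_single(interval, exons_a, exons_b, strand):
    """One differing interval: decide ES/IR/A5/A3 or complex."""
    x, y = interval
    cov_a = _covered(exons_a, x)
    inc, exc = (exons_a, exons_b) if cov_a else (exons_b, exons_a)
    if (x, y) in [tuple(e) for e in inc]:
        # a whole exon of the including chain; skipped if intronic in the other
        if not any(s < y and e > x for s, e in exc):
            return "ES"
    # whole intron of the excluding chain inside an exon of the including one
    introns_exc = [(e1, s2) for (_, e1), (s2, _) in zip(exc, exc[1:])]
    if (x, y) in introns_exc and any(s <= x and e >= y for s, e in inc):
        return "IR"
    # boundary move: including exon ends at y while excluding exon ends at x
    inc_ends = {e for _, e in inc}
    exc_ends = {e for _, e in exc}
    inc_starts = {s for s, _ in inc}
    exc_starts = {s for s, _ in exc}
    if y in inc_ends and x in exc_ends and x not in inc_starts:
        return "A5" if strand == "+" else "A3"
    if x in inc_starts and y in exc_starts and y not in inc_ends:
        return "A3" if strand == "+" else "A5"
    return "complex"


def oracle_classify(exons_a, exons_b, strand):
    """Events between two exon chains: list of (class, var_start, var_end).

    Returns None when the chains share no internal splice site.
    """
    shared = _internal_sites(exons_a) & _internal_sites(exons_b)
    span_a = (exons_a[0][0], exons_a[-1][1])
    span_b = (exons_b[0][0], exons_b[-1][1])
    if span_a[0] == span_b[0]:
        shared = shared | {(span_a[0], "A")}
    if span_a[1] == span_b[1]:
        shared = shared | {(span_a[1], "A")}
    if not shared:
        return None
    lo = min(p for p, _ in shared)
    hi = max(p for p, _ in shared)
    diffs = _diff_intervals(exons_a, exons_b, lo, hi)
    if not diffs:
        return []
    # group differing intervals into bubbles: no shared site between members
    shared_pos = sorted(p for p, _ in shared)
    groups: list[list[tuple[int, int]]] = []
    for iv in diffs:
        if groups and not any(groups[-1][-1][1] <= p <= iv[0] for p in shared_pos):
            groups[-1].append(iv)
        else:
            groups.append([iv])
    events = []
    for group in groups:
        var = (group[0][0], group[-1][1])
        if len(group) == 1:
            cls = _classify_single(group[0], exons_a, exons_b, strand)
        elif len(group) == 2:
            (x1, y1), (x2, y2) = group
            full_a = [tuple(e) for e in exons_a]
            full_b = [tuple(e) for e in exons_b]
            one_way = (x1, y1) in full_a and (x2, y2) in full_b
            other_way = (x1, y1) in full_b and (x2, y2) in full_a
            intr_a = not any(s < y1 and e > x1 for s, e in
                             (full_b if one_way else full_a))
            intr_b = not any(s < y2 and e > x2 for s, e in
                             (full_a if one_way else full_b))
            if (one_way or other_way) and intr_a and intr_b:
                cls = "ME"
            else:
                cls = "complex"
        else:
            cls = "complex"
        events.append((cls, var[0], var[1]))
    events.sort(key=lambda t: t[1], reverse=(strand == "-"))
    return events


# ---------------------------------------------------------------------------
# Motif-scan oracle
# ---------------------------------------------------------------------------

def naive_scan(seq, probs, threshold, pseudocount=1e-3, background=0.25):
    """Per-window rescored hits: list of (offset, score)."""
    alphabet = "ACGU"
    width = len(probs)
    hits = []
    for o in range(len(seq) - width + 1):
        score = 0.0
        ok = True
        for j in range(width):
            c = seq[o + j]
            if c == "T":
                c = "U"
            if c not in alphabet:
                ok = False
                break
            p = probs[j][alphabet.index(c)] + pseudocount * background
            q = background + pseudocount * background
            score += math.log2(p / q)
        if ok and score >= threshold:
            hits.append((o, score))
    return hits


# ---------------------------------------------------------------------------
# Phosphosite row-scan oracles
# ---------------------------------------------------------------------------

def naive_evidence_pass(rows):
    """Row dicts that survive the evidence rule, scanned one by one."""
    kept = []
    for row in rows:
        if row["LT_LIT"] >= 1:
            kept.append(row)
        elif row["MS_LIT"] + row["MS_CST"] >= 3:
            kept.append(row)
    return kept


def naive_crossref(phospho_rows, catalogue_rows, kinase_rows, src_kinases=("SRC",)):
    """Brute-force join of tyrosine sites onto the catalogue with Src flags."""
    cat = {r["protein"]: r for r in catalogue_rows}
    src_pairs = set()
    for r in kinase_rows:
        if r["kinase"] in src_kinases and r["residue"] == "Y":
            src_pairs.add((r["substrate"], r["position"]))
    out = []
    for row in phospho_rows:
        if row["residue"] != "Y":
            continue
        if row["protein"] not in cat:
            continue
        out.append({
            **row,
            "subclass": cat[row["protein"]]["subclass"],
            "src_substrate": (row["protein"], row["position"]) in src_pairs,
        })
    return out
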