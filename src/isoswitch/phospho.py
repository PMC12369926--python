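"""Phosphosite filtering and splicing-machinery cross-referencing.

Works on PhosphoSitePlus-style tables: one row per phosphosite with a
protein id, a residue token (e.g. ``Y416``), and evidence counts LT_LIT
(low-throughput literature reports), MS_LIT and MS_CST (high-throughput
literature and in-house reports).  A site is considered reliably observed
when it has at least one low-throughput report or at least three
high-throughput reports; by default the two high-throughput columns are
summed for that count (``ms_rule="summed"``), with ``ms_rule="either"``
requiring three in a single column instead.

The cross-reference restricts tyrosine sites to proteins in a
splicing-machinery catalogue (protein id, subclass, direct-role flag) and
flags those matching a kinase-substrate table entry for a Src-family
kinase at the same protein and position.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

RESIDUES = ("S", "T", "Y")

PHOSPHO_COLUMNS = ["protein", "residue", "position", "LT_LIT", "MS_LIT", "MS_CST"]
CATALOGUE_COLUMNS = ["protein", "subclass", "direct"]
KINASE_COLUMNS = ["kinase", "substrate", "residue", "position"]

_MOD_RSD = re.compile(r"^([STY])(\d+)(?:-p)?$")


def parse_mod_rsd(token: str) -> tuple[str, int]:
    """Split a MOD_RSD-style token like ``Y416`` or ``S12-p``."""
    m = _MOD_RSD.match(token.strip())
    if not m:
        raise ValueError(f"unparseable residue token {token!r}")
    return m.group(1), int(m.group(2))


def read_phospho_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "MOD_RSD" in df.columns:
        parsed = df["MOD_RSD"].map(parse_mod_rsd)
        df["residue"] = parsed.str[0]
        df["position"] = parsed.str[1]
        df = df.drop(columns=["MOD_RSD"])
    return df[PHOSPHO_COLUMNS]


def evidence_filter(records: pd.DataFrame, min_ms: int = 3,
                    ms_rule: str = "summed") -> pd.DataFrame:
    """Keep sites with LT_LIT >= 1 or enough high-throughput observations."""
    lt = records["LT_LIT"].fillna(0) >= 1
    if ms_rule == "summed":
        ms = (records["MS_LIT"].fillna(0) + records["MS_CST"].fillna(0)) >= min_ms
    elif ms_rule == "either":
        ms = (records["MS_LIT"].fillna(0) >= min_ms) | (records["MS_CST"].fillna(0) >= min_ms)
    else:
        raise ValueError(f"unknown ms_rule {ms_rule!r}")
    return records[lt | ms]


def split_by_residue(records: pd.DataFrame) -> tuple[dict[str, pd.DataFrame], int]:
    """Partition by residue into S/T/Y sets; returns (sets, n_rejected)."""
    known = records["residue"].isin(RESIDUES)
    sets = {r: records[records["residue"] == r] for r in RESIDUES}
    return sets, int((~known).sum())


def residue_percentages(records: pd.DataFrame) -> pd.Series:
    sets, _ = split_by_residue(records)
    total = sum(len(v) for v in sets.values())
    return pd.Series(
        {r: (100.0 * len(v) / total if total else 0.0) for r, v in sets.items()}
    )


def crossref_splicing(phospho_y: pd.DataFrame, catalogue: pd.DataFrame,
                      kinase_table: pd.DataFrame,
                      src_kinases: tuple[str, ...] = ("SRC",)) -> pd.DataFrame:
    """Tyrosine sites on catalogue proteins, flagged when Src substrates.

    A site is ``src_substrate`` when the kinase-substrate table holds a row
    with a Src-family kinase, the same substrate protein, residue Y, and
    the same position (exact match; isoform offsets are not reconciled).
    """
    sites = phospho_y[phospho_y["residue"] == "Y"]
    cat = catalogue.drop_duplicates("protein")
    merged = sites.merge(cat, on="protein", how="inner")
    src = kinase_table[
        kinase_table["kinase"].isin(src_kinases) & (kinase_table["residue"] == "Y")
    ][["substrate", "position"]].drop_duplicates()
    key = merged["protein"] + ":" + merged["position"].astype(int).astype(str)
    src_key = set(src["substrate"] + ":" + src["position"].astype(int).astype(str))
    merged["src_substrate"] = key.isin(src_key)
    return merged.reset_index(drop=True)


def subclass_proportions(annotated: pd.DataFrame,
                         catalogue: pd.DataFrame) -> pd.DataFrame:
    """Subclass x dataset percentage matrix.

    Columns: catalogue_proteins (share of catalogue proteins per subclass),
    all_y_sites, src_sites.  Each non-empty column sums to 100.
    """
    subclasses = sorted(catalogue["subclass"].unique())
    out = pd.DataFrame(index=subclasses, dtype=float)

    def pct(counts: pd.Series) -> pd.Series:
        total = counts.sum()
        aligned = counts.reindex(subclasses).fillna(0.0)
        return 100.0 * aligned / total if total else aligned * 0.0

    out["catalogue_proteins"] = pct(
        catalogue.drop_duplicates("protein")["subclass"].value_counts()
    )
    out["all_y_sites"] = pct(annotated["subclass"].value_counts())
    src_mask = annotated["src_substrate"].astype(bool)
    out["src_sites"] = pct(annotated.loc[src_mask, "subclass"].value_counts())
    out.index.name = "subclass"
    return out
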