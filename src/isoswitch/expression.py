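"""TPM quantification, expression filtering and differential expression.

The differential test here is a deliberately simple stand-in for
bootstrap-based RNA-seq DE engines: the effect size ``b`` is the difference
of group means of log2(TPM + 0.5) (knockdown minus control), the p-value a
Welch two-sample t-test on the same transform, and q-values are
Benjamini-Hochberg adjusted across all features that pass the expression
filter.  Downstream stages consume only (b, q) and a status label, so the
test engine is swappable without touching them.

Conventions: condition labels are "control" and "knockdown"; the
expression filter keeps a feature when either group mean is >= 1 TPM
(strictly-below-1-in-both removed, so a mean of exactly 1 is kept).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONTROL = "control"
KNOCKDOWN = "knockdown"

DEFAULT_TPM_FILTER = 1.0
DEFAULT_DE_Q = 0.05
LOG_PSEUDOCOUNT = 0.5


@dataclass
class GroupDesign:
    """Sample -> condition assignment for a two-group comparison."""

    conditions: dict[str, str]  # sample id -> CONTROL / KNOCKDOWN

    def __post_init__(self):
        labels = set(self.conditions.values())
        if labels != {CONTROL, KNOCKDOWN}:
            raise ValueError(f"expected conditions {{control, knockdown}}, got {labels}")

    def samples(self, condition: str) -> list[str]:
        return [s for s, c in self.conditions.items() if c == condition]

    @classmethod
    def from_tsv(cls, path) -> "GroupDesign":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "condition"])
        return cls(dict(zip(df["sample"], df["condition"])))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s, c in self.conditions.items():
                fh.write(f"{s}\t{c}\n")


def counts_to_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from a feature x sample count matrix.

    ``lengths`` gives effective feature lengths in bases.  Each column of
    the result sums to 1e6, except all-zero columns which stay zero.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])
        raise ValueError(f"missing lengths for features: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    tpm = rate.div(denom.replace(0.0, np.nan), axis=1) * 1e6
    return tpm.fillna(0.0)


def aggregate_gene(tpm: pd.DataFrame, tx2gene: dict[str, str]) -> pd.DataFrame:
    """Sum transcript TPM to gene level; total TPM per sample is conserved."""
    unmapped = [t for t in tpm.index if t not in tx2gene]
    if unmapped:
        raise ValueError(f"transcripts not mapped to genes: {unmapped[:5]}")
    genes = pd.Series({t: tx2gene[t] for t in tpm.index}, name="gene_id")
    out = tpm.groupby(genes).sum()
    out.index.name = "feature_id"
    return out


def expression_filter(tpm: pd.DataFrame, design: GroupDesign,
                      min_tpm: float = DEFAULT_TPM_FILTER) -> pd.Index:
    """Features whose mean TPM reaches ``min_tpm`` in at least one group."""
    mc = tpm[design.samples(CONTROL)].mean(axis=1)
    mk = tpm[design.samples(KNOCKDOWN)].mean(axis=1)
    return tpm.index[(mc >= min_tpm) | (mk >= min_tpm)]


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    """Welch t-test p-value; degenerate (zero-variance) inputs handled."""
    if np.allclose(a.var(ddof=1), 0) and np.allclose(b.var(ddof=1), 0):
        if np.isclose(a.mean(), b.mean()):
            return 1.0
        return 0.0
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return 1.0 if np.isnan(p) else float(p)


def de_test(tpm: pd.DataFrame, design: GroupDesign,
            q_threshold: float = DEFAULT_DE_Q,
            min_tpm: float = DEFAULT_TPM_FILTER) -> pd.DataFrame:
    """Two-group differential expression on a TPM matrix.

    Returns a DataFrame indexed by feature with columns mean_control_tpm,
    mean_kd_tpm, b, p, q, status.  Features failing the expression filter
    are reported with status "filtered" and missing statistics; q-values
    are BH-adjusted over tested features only.
    """
    ctrl, kd = design.samples(CONTROL), design.samples(KNOCKDOWN)
    if len(ctrl) < 2 or len(kd) < 2:
        raise ValueError("need >=2 replicates per group")
    kept = expression_filter(tpm, design, min_tpm)

    log_tpm = np.log2(tpm + LOG_PSEUDOCOUNT)
    out = pd.DataFrame(index=tpm.index)
    out["mean_control_tpm"] = tpm[ctrl].mean(axis=1)
    out["mean_kd_tpm"] = tpm[kd].mean(axis=1)
    out["b"] = log_tpm[kd].mean(axis=1) - log_tpm[ctrl].mean(axis=1)
    out["p"] = np.nan
    out["q"] = np.nan
    out["status"] = "filtered"

    a = log_tpm.loc[kept, ctrl].to_numpy()
    b = log_tpm.loc[kept, kd].to_numpy()
    pvals = np.array([_welch(a[i], b[i]) for i in range(len(kept))])
    if len(pvals):
        qvals = multipletests(pvals, method="fdr_bh")[1]
    else:
        qvals = pvals
    out.loc[kept, "p"] = pvals
    out.loc[kept, "q"] = qvals
    tested = out.index.isin(kept)
    sig = (out["q"] <= q_threshold).fillna(False).to_numpy()
    out.loc[tested, "status"] = "not_significant"
    out.loc[tested & sig & (out["b"] > 0).to_numpy(), "status"] = "up"
    out.loc[tested & sig & (out["b"] < 0).to_numpy(), "status"] = "down"
    out.index.name = "feature_id"
    return out


def both_direction_genes(de: pd.DataFrame, tx2gene: dict[str, str]) -> set[str]:
    """Genes with at least one upregulated and one downregulated transcript."""
    genes = de.index.to_series().map(tx2gene)
    up = set(genes[de["status"] == "up"])
    down = set(genes[de["status"] == "down"])
    return up & down


def read_counts_tsv(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a counts TSV with a ``length`` column after the feature id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    lengths = df.pop("length")
    return df, lengths


def write_counts_tsv(counts: pd.DataFrame, lengths: pd.Series, path) -> None:
    out = counts.copy()
    out.insert(0, "length", lengths.reindex(counts.index))
    out.to_csv(path, sep="\t")
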