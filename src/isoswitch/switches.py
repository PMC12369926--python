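"""Isoform fractions and isoform-switch detection.

A transcript's isoform fraction (IF) is its share of its gene's TPM in one
sample; dIF is the difference of condition mean IFs (knockdown minus
control).  A switch is a pair of isoforms of one gene whose usage moves in
opposite directions between conditions with at least one side significant
(default Q < 0.1).  Per-isoform significance comes from a moderated
two-sample t-test on smoothed-logit-transformed IFs — a stand-in for
count-model usage tests that preserves the selection rule they feed, with
empirical-Bayes variance shrinkage to give usable power at triplicate
scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .expression import CONTROL, KNOCKDOWN, GroupDesign

DEFAULT_SWITCH_Q = 0.1
DEFAULT_DIF_MIN = 0.05


@dataclass
class SwitchCall:
    gene_id: str
    isoform_up: str
    isoform_down: str
    dif_up: float
    dif_down: float
    q_up: float
    q_down: float
    best_pair: bool = True

    @property
    def gene_switch_q(self) -> float:
        return min(self.q_up, self.q_down)


def isoform_fractions(tpm: pd.DataFrame, tx2gene: dict[str, str],
                      design: GroupDesign) -> pd.DataFrame:
    """Per-sample IFs plus condition means and dIF.

    Samples where the gene's total TPM is zero give missing IF and are
    excluded from the condition means.  Genes with zero TPM in every sample
    of a condition are flagged untestable (missing mean on that side).
    """
    genes = pd.Series({t: tx2gene[t] for t in tpm.index})
    gene_tpm = tpm.groupby(genes).sum()
    denom = gene_tpm.loc[genes].set_axis(tpm.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        iftab = tpm / denom.replace(0.0, np.nan)

    out = iftab.copy()
    out.insert(0, "gene_id", genes)
    ctrl, kd = design.samples(CONTROL), design.samples(KNOCKDOWN)
    out["mean_if_control"] = iftab[ctrl].mean(axis=1)
    out["mean_if_kd"] = iftab[kd].mean(axis=1)
    out["dIF"] = out["mean_if_kd"] - out["mean_if_control"]
    out.index.name = "transcript_id"
    return out


def _smoothed_logit(x: np.ndarray, n: int) -> np.ndarray:
    z = (x * (n - 1) + 0.5) / n
    return np.log(z / (1 - z))


def _moderation_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) for variance shrinkage.

    Moment matching on log sample variances (the scaled-F model of
    moderated t statistics); returns d0 = inf when the observed spread of
    variances is no larger than pure chi-square sampling noise.
    """
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        return np.inf, float(np.median(s2)) if len(s2) else 1.0
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    target = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if target <= 0:
        return np.inf, float(np.exp(e.mean()))
    d0 = float(optimize.brentq(
        lambda x: special.polygamma(1, x / 2.0) - target, 1e-2, 1e3))
    s02 = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def usage_test(if_table: pd.DataFrame, design: GroupDesign) -> pd.DataFrame:
    """Per-isoform p and BH q for a change in usage between conditions.

    The statistic is a moderated two-sample t on smoothed-logit-transformed
    IFs: per-isoform pooled variances are shrunk toward an empirical-Bayes
    prior fitted across all isoforms, which recovers power at small
    replicate numbers where raw per-isoform variances are too unstable.
    Isoforms with fewer than two defined IFs in either condition are
    untestable and reported with missing p/q.
    """
    ctrl, kd = design.samples(CONTROL), design.samples(KNOCKDOWN)
    n_samples = len(ctrl) + len(kd)
    res = if_table[["gene_id", "dIF"]].copy()

    a = if_table[ctrl].to_numpy(dtype=float)
    b = if_table[kd].to_numpy(dtype=float)
    n1 = np.sum(~np.isnan(a), axis=1)
    n2 = np.sum(~np.isnan(b), axis=1)
    testable = (n1 >= 2) & (n2 >= 2)

    ta = _smoothed_logit(a, n_samples)
    tb = _smoothed_logit(b, n_samples)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        d = np.nanmean(tb, axis=1) - np.nanmean(ta, axis=1)
        va = np.nanvar(ta, axis=1, ddof=1)
        vb = np.nanvar(tb, axis=1, ddof=1)
    df_resid = int(np.max(n1 + n2 - 2, initial=2))
    s2 = ((n1 - 1) * va + (n2 - 1) * vb) / np.maximum(n1 + n2 - 2, 1)

    d0, s02 = _moderation_prior(s2[testable], df_resid)
    if np.isfinite(d0):
        s2_mod = (d0 * s02 + (n1 + n2 - 2) * s2) / (d0 + n1 + n2 - 2)
        df_total = n1 + n2 - 2 + d0
    else:
        s2_mod = np.full_like(s2, s02)
        df_total = np.full(len(s2), np.inf)

    with np.errstate(invalid="ignore", divide="ignore"):
        t = d / np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    pvals = np.where(np.isnan(t), 1.0, pvals)  # zero effect, zero variance
    pvals = np.where(testable, pvals, np.nan)

    res["p"] = pvals
    res["q"] = np.nan
    tested = ~np.isnan(pvals)
    if tested.any():
        res.loc[tested, "q"] = multipletests(pvals[tested], method="fdr_bh")[1]
    res.index.name = "transcript_id"
    return res


def detect_switches(usage: pd.DataFrame,
                    q_threshold: float = DEFAULT_SWITCH_Q,
                    dif_threshold: float = DEFAULT_DIF_MIN) -> list[SwitchCall]:
    """All opposite-usage isoform pairs with at least one significant side.

    For every gene, each (up, down) pair with dIF above/below the +/-
    ``dif_threshold`` floor and min(q) below ``q_threshold`` is emitted;
    per gene, the pair maximising |dIF_up| + |dIF_down| carries
    ``best_pair=True``.  Calls are sorted by gene switch q-value.
    """
    calls: list[SwitchCall] = []
    for gene_id, sub in usage.groupby("gene_id", sort=False):
        ups = sub[(sub["dIF"] > dif_threshold) & sub["q"].notna()]
        downs = sub[(sub["dIF"] < -dif_threshold) & sub["q"].notna()]
        gene_calls = []
        for iso_up, up in ups.iterrows():
            for iso_down, down in downs.iterrows():
                if min(up["q"], down["q"]) >= q_threshold:
                    continue
                gene_calls.append(SwitchCall(
                    gene_id=gene_id,
                    isoform_up=iso_up,
                    isoform_down=iso_down,
                    dif_up=float(up["dIF"]),
                    dif_down=float(down["dIF"]),
                    q_up=float(up["q"]),
                    q_down=float(down["q"]),
                    best_pair=False,
                ))
        if gene_calls:
            best = max(gene_calls, key=lambda c: abs(c.dif_up) + abs(c.dif_down))
            best.best_pair = True
        calls.extend(gene_calls)
    calls.sort(key=lambda c: (c.gene_switch_q, c.gene_id, c.isoform_up))
    return calls


def switches_to_frame(calls: list[SwitchCall]) -> pd.DataFrame:
    rows = [{
        "gene_id": c.gene_id,
        "isoform_up": c.isoform_up,
        "isoform_down": c.isoform_down,
        "dIF_up": c.dif_up,
        "dIF_down": c.dif_down,
        "q_up": c.q_up,
        "q_down": c.q_down,
        "gene_switch_q": c.gene_switch_q,
        "best_pair": c.best_pair,
    } for c in calls]
    return pd.DataFrame(rows, columns=[
        "gene_id", "isoform_up", "isoform_down", "dIF_up", "dIF_down",
        "q_up", "q_down", "gene_switch_q", "best_pair",
    ])
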