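"""PSO statistics: event-level percent-spliced-out, per-sample class
averages, median-of-ratios normalization, and the gene-by-gene Spearman
screen with a between-condition comparison of correlations.

PSO (percent spliced out) is 1 - PSI, where PSI is the inclusion level of a
retained-intron event (1 = fully retained). Per sample, PSO values of the
events of one class (e3UI or co3UI) are averaged, and each gene's normalized
expression is rank-correlated with that average across the samples of each
condition. P-values are Benjamini-Hochberg adjusted within each
(condition, class) stratum and conditions are compared per gene with the
Fisher r-to-z test for independent correlations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

E3UI = "e3UI"
CO3UI = "co3UI"

MIN_SAMPLES_PER_CONDITION = 4


class PSOTable:
    """Event x sample PSO values in [0, 1] (NaN = missing) plus a per-event
    class label (e3UI / co3UI)."""

    def __init__(self, values: pd.DataFrame, event_class: pd.Series) -> None:
        v = values.astype(float)
        bad = v.values[~np.isnan(v.values)]
        if bad.size and (bad.min() < 0 or bad.max() > 1):
            raise ValueError("PSO values must lie in [0, 1]")
        missing = set(v.index) - set(event_class.index)
        if missing:
            raise KeyError(f"events without class label: {sorted(missing)}")
        self.values = v
        self.event_class = event_class.loc[v.index]

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def pso_from_psi(psi: pd.DataFrame) -> pd.DataFrame:
    """Elementwise 1 - PSI; missing values preserved; out-of-range errors."""
    v = psi.astype(float)
    present = v.values[~np.isnan(v.values)]
    if present.size and (present.min() < 0 or present.max() > 1):
        raise ValueError("PSI values must lie in [0, 1]")
    return 1.0 - v


def read_psi_tsv(path) -> tuple[pd.DataFrame, pd.Series]:
    """rMATS-style event table: columns event_id, klass, <sample>...
    Returns (PSI matrix, class labels)."""
    df = pd.read_csv(path, sep="\t", comment="#").set_index("event_id")
    klass = df["klass"]
    return df.drop(columns=["klass"]), klass


def psi_naive_from_junction_counts(inclusion: pd.DataFrame,
                                   skipping: pd.DataFrame) -> pd.DataFrame:
    """Naive PSI = I / (I + S) from raw junction counts. This is NOT the
    rMATS estimator (no length correction, no likelihood model); provided
    only as a rough check when no rMATS output is available."""
    denom = inclusion + skipping
    return (inclusion / denom).where(denom > 0)


@dataclass(frozen=True)
class SamplePSOSummary:
    sample: str
    condition: str
    mean_pso_e3ui: float
    mean_pso_co3ui: float


def sample_average_pso(pso: PSOTable, klass: str) -> pd.Series:
    """Unweighted mean PSO over non-missing events of one class, per sample.

    All-NaN samples (or zero events of the class) yield NaN with a warning.
    """
    mask = pso.event_class == klass
    if not mask.any():
        warnings.warn(f"no events of class {klass!r}", stacklevel=2)
        return pd.Series(np.nan, index=pso.samples, name=f"mean_pso_{klass}")
    out = pso.values.loc[mask].mean(axis=0, skipna=True)
    out.name = f"mean_pso_{klass}"
    return out


def summarize_samples(pso: PSOTable,
                      condition_labels: Mapping[str, str]) -> pd.DataFrame:
    """Per-sample summary table: condition plus mean PSO of each class."""
    rows = pd.DataFrame(index=pso.samples)
    rows["condition"] = [condition_labels[s] for s in pso.samples]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rows["mean_pso_e3UI"] = sample_average_pso(pso, E3UI)
        rows["mean_pso_co3UI"] = sample_average_pso(pso, CO3UI)
    return rows


def size_factors_median_ratio(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq2 normalization).

    factor_s = median over genes g (with positive geometric mean across
    samples) of counts[g, s] / geomean_g. Genes with any zero count drop out
    of the reference (their geometric mean is zero).
    """
    logc = np.log(counts.where(counts > 0))
    log_geomean = logc.mean(axis=1, skipna=False)  # NaN if any sample is 0
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ratios = counts.loc[usable].div(np.exp(log_geomean[usable]), axis=0)
    return ratios.median(axis=0)


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    return counts / size_factors_median_ratio(counts)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-aware Spearman rho with two-sided p (t approximation), on
    pairwise-complete observations. Fewer than 4 complete pairs, or a
    zero-variance vector, yield (nan, nan)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    ok = np.isfinite(xa) & np.isfinite(ya)
    if ok.sum() < 4:
        return (math.nan, math.nan)
    xa, ya = xa[ok], ya[ok]
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return (math.nan, math.nan)
    res = sps.spearmanr(xa, ya)
    return (float(res.statistic), float(res.pvalue))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        if p[ok].min() < 0 or p[ok].max() > 1:
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def fisher_z_diff(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two independent correlations via the Fisher r-to-z transform.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided normal p.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both groups need n > 3")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be < 1")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * sps.norm.sf(abs(z))
    return (z, float(p))


def correlate_genes(
    expr: pd.DataFrame,
    summaries: pd.DataFrame,
    conditions: tuple[str, str] = ("normal", "cancer"),
    classes: tuple[str, ...] = (E3UI, CO3UI),
    bh_family: str = "per_stratum",
) -> pd.DataFrame:
    """Gene x (class) Spearman screen of normalized expression vs mean PSO.

    ``expr``: normalized gene x sample matrix. ``summaries``: output of
    :func:`summarize_samples` (index = sample, columns condition and
    mean_pso_<class>). For each gene and class, Spearman rho/p are computed
    within each condition; BH adjustment is applied over genes within each
    (condition, class) stratum (or globally with ``bh_family='global'``); the
    two conditions are compared per gene with :func:`fisher_z_diff`.
    Conditions with fewer than 4 samples yield missing results.
    """
    if bh_family not in ("per_stratum", "global"):
        raise ValueError(f"unknown bh_family {bh_family!r}")
    cond_a, cond_b = conditions
    samples = summaries.index.intersection(expr.columns)
    expr = expr[samples]
    summaries = summaries.loc[samples]

    frames = []
    for klass in classes:
        pso_col = f"mean_pso_{klass}"
        rows = {}
        ns = {}
        for cond in conditions:
            mask = summaries["condition"] == cond
            pso = summaries.loc[mask, pso_col].to_numpy()
            sub = expr.loc[:, mask.values]
            n_ok = int(np.isfinite(pso).sum())
            ns[cond] = n_ok
            if n_ok < MIN_SAMPLES_PER_CONDITION:
                warnings.warn(
                    f"condition {cond!r} has fewer than "
                    f"{MIN_SAMPLES_PER_CONDITION} usable samples", stacklevel=2
                )
                rho = np.full(len(expr.index), np.nan)
                pval = np.full(len(expr.index), np.nan)
            else:
                rho = np.empty(len(expr.index))
                pval = np.empty(len(expr.index))
                for i, (_, row) in enumerate(sub.iterrows()):
                    rho[i], pval[i] = spearman(row.to_numpy(), pso)
            rows[f"rho_{cond}"] = rho
            rows[f"p_{cond}"] = pval
        df = pd.DataFrame(rows, index=expr.index)
        df.insert(0, "klass", klass)
        df[f"padj_{cond_a}"] = bh_adjust(df[f"p_{cond_a}"])
        df[f"padj_{cond_b}"] = bh_adjust(df[f"p_{cond_b}"])
        z = np.full(len(df), np.nan)
        pd_ = np.full(len(df), np.nan)
        if ns[cond_a] > 3 and ns[cond_b] > 3:
            for i, (ra, rb) in enumerate(
                zip(df[f"rho_{cond_a}"], df[f"rho_{cond_b}"])
            ):
                if np.isfinite(ra) and np.isfinite(rb) and abs(ra) < 1 and abs(rb) < 1:
                    z[i], pd_[i] = fisher_z_diff(ra, ns[cond_a], rb, ns[cond_b])
        df["z_diff"] = z
        df["p_diff"] = pd_
        frames.append(df)
    out = pd.concat(frames)
    if bh_family == "global":
        out[f"padj_{cond_a}"] = bh_adjust(out[f"p_{cond_a}"])
        out[f"padj_{cond_b}"] = bh_adjust(out[f"p_{cond_b}"])
    out.index.name = "gene"
    return out
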