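"""Expression-level filters: Tx/G fraction, expressed calls, and the
broadly-expressed rule with junction-coverage evidence.

A transcript is *expressed* in a sample when its TPM exceeds 1 and it accounts
for more than 25% of its gene's total expression (both strict, as printed).
It is *broadly expressed* when it is expressed in at least 10% of either the
normal or the cancer samples and every one of its splice junctions is
supported by at least one read summed across samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MIN_TPM_DEFAULT = 1.0
MIN_FRACTION_DEFAULT = 0.25
MIN_SAMPLE_FRAC_DEFAULT = 0.10

JunctionKey = tuple[str, str, int, int]


class QuantTable:
    """Transcript x sample TPM matrix with a transcript-to-gene mapping.

    Gene TPM is the sum of member-transcript TPMs from the same
    quantification; the Tx/G fraction is undefined (NaN) where gene TPM is 0.
    """

    def __init__(self, tpm: pd.DataFrame, tx2gene: Mapping[str, str]) -> None:
        if (tpm.values < 0).any():
            raise ValueError("negative TPM values")
        missing = set(tpm.index) - set(tx2gene)
        if missing:
            raise KeyError(f"transcripts without gene mapping: {sorted(missing)}")
        self.tpm = tpm.astype(float)
        self.tx2gene = pd.Series({t: tx2gene[t] for t in tpm.index})
        self.gene_tpm = self.tpm.groupby(self.tx2gene).sum()
        denom = self.gene_tpm.loc[self.tx2gene.values].set_axis(self.tpm.index)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.fraction = self.tpm / denom
        self.fraction = self.fraction.where(denom > 0)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "QuantTable":
        """Read a TSV with columns transcript_id, gene_id, <sample>..."""
        df = pd.read_csv(path, sep="\t", comment="#")
        df = df.set_index("transcript_id")
        tx2gene = df["gene_id"].to_dict()
        return cls(df.drop(columns=["gene_id"]), tx2gene)

    @property
    def transcripts(self) -> pd.Index:
        return self.tpm.index

    @property
    def samples(self) -> pd.Index:
        return self.tpm.columns

    def max_tpm(self, transcript: str) -> float:
        return float(self.tpm.loc[transcript].max())


def fraction_expression(q: QuantTable, transcript: str, sample: str) -> float:
    """Transcript TPM / gene TPM for one cell; NaN where gene TPM is 0."""
    if transcript not in q.transcripts:
        raise KeyError(f"unknown transcript {transcript!r}")
    return float(q.fraction.loc[transcript, sample])


def is_expressed(
    q: QuantTable,
    transcript: str,
    sample: str,
    min_tpm: float = MIN_TPM_DEFAULT,
    min_fraction: float = MIN_FRACTION_DEFAULT,
) -> bool:
    """TPM > min_tpm AND Tx/G fraction > min_fraction (both strict)."""
    tpm = float(q.tpm.loc[transcript, sample])
    frac = fraction_expression(q, transcript, sample)
    return tpm > min_tpm and bool(frac > min_fraction)


def expressed_matrix(
    q: QuantTable,
    min_tpm: float = MIN_TPM_DEFAULT,
    min_fraction: float = MIN_FRACTION_DEFAULT,
) -> pd.DataFrame:
    """Boolean transcript x sample matrix of expressed calls (vectorized)."""
    return (q.tpm > min_tpm) & (q.fraction > min_fraction).fillna(False)


class JunctionCoverage:
    """Junction x sample integer read counts keyed by
    (chrom, strand, start, end); junctions absent from the table count 0."""

    def __init__(self, counts: pd.DataFrame) -> None:
        if (counts.values < 0).any():
            raise ValueError("negative junction counts")
        self.counts = counts

    @classmethod
    def from_tsv(cls, path: str | Path) -> "JunctionCoverage":
        df = pd.read_csv(path, sep="\t", comment="#")
        df = df.set_index(["chrom", "strand", "start", "end"])
        return cls(df)

    def total(self, junction: JunctionKey) -> int:
        if junction not in self.counts.index:
            return 0
        return int(self.counts.loc[junction].sum())


def broadly_expressed(
    q: QuantTable,
    jc: JunctionCoverage,
    transcript: str,
    junctions: Iterable[JunctionKey],
    condition_labels: Mapping[str, str],
    min_sample_frac: float = MIN_SAMPLE_FRAC_DEFAULT,
    min_tpm: float = MIN_TPM_DEFAULT,
    min_fraction: float = MIN_FRACTION_DEFAULT,
) -> bool:
    """Expressed in >= min_sample_frac of normal OR cancer samples (count
    threshold is the ceiling, e.g. 10% of 25 samples means >= 3), AND every
    junction of the transcript has total coverage >= 1 across all samples."""
    unlabelled = [s for s in q.samples if s not in condition_labels]
    if unlabelled:
        raise KeyError(f"samples without condition label: {unlabelled}")
    calls = {
        s: is_expressed(q, transcript, s, min_tpm, min_fraction)
        for s in q.samples
    }
    frac_ok = False
    for condition in sorted(set(condition_labels[s] for s in q.samples)):
        members = [s for s in q.samples if condition_labels[s] == condition]
        need = math.ceil(min_sample_frac * len(members))
        if sum(calls[s] for s in members) >= max(need, 1):
            frac_ok = True
            break
    if not frac_ok:
        return False
    return all(jc.total(j) >= 1 for j in junctions)


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """TSV with columns sample, condition."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["sample"].astype(str), df["condition"].astype(str)))
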