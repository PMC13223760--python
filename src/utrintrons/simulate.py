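"""Seeded synthetic fixtures: genome + reference GTF + assembly GTF +
quantification/PSI tables with a machine-readable truth table.

Every gene is laid out from a transcript-order plan (5' UTR, coding exons
separated by coding introns, stop codon, then a 3' UTR that may carry a
planted UTR intron) and realized on either strand. The planted classes are:

* ``none`` — the query is an exact copy of the reference (no 3UI);
* ``e3UI`` — annotated exclusively-UTR intron (a reference isoform carries
  the same post-stop intron, so it is known but shares no coding boundary);
* ``novel_e3UI`` — exclusively-UTR intron present in no reference transcript;
* ``co3UI`` — a second reference isoform reads through the first stop codon,
  making the same intron a coding intron of that isoform (the early-PTC
  situation), so the query's 3UI shares both boundaries with a coding intron.

Decoy transcripts (reference fragments, intron-contained exons, antisense
overlaps) can be planted per gene; merge filtering and strand-aware matching
must keep them out of the classifier output.

All randomness flows from a single integer seed; the same seed produces
byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import GenomeInterval, TranscriptModel, write_gtf

CONTIG = "chrS"
GC_DEFAULT = 0.42
MIN_INTRON_NT = 60

# transcript-order layout constants (nt)
UTR5_NT = 150
CDS_SEGMENT_NT = 120
CDS_INTRON_NT = 90
UTR3_TAIL_NT = 150
GENE_SPACER_NT = 300


class FixtureError(ValueError):
    """Unrealizable fixture plan."""


@dataclass(frozen=True)
class GenePlan:
    name: str
    klass: str  # none | e3UI | novel_e3UI | co3UI
    n_cds_introns: int = 1
    utr_intron_length: int = 90
    distance_to_stop: int = 20
    strand: str = "+"
    decoys: tuple[str, ...] = ()  # subset of {fragment, intronic, antisense}
    low_confidence_extra: bool = False

    def validate(self) -> None:
        if self.klass not in ("none", "e3UI", "novel_e3UI", "co3UI"):
            raise FixtureError(f"{self.name}: unknown class {self.klass!r}")
        if self.n_cds_introns < 0:
            raise FixtureError(f"{self.name}: negative intron count")
        if self.distance_to_stop < 0:
            raise FixtureError(f"{self.name}: negative stop distance")
        if self.klass != "none" and self.utr_intron_length < 4:
            raise FixtureError(
                f"{self.name}: UTR intron shorter than 4 nt cannot carry "
                "splice dinucleotides"
            )
        if self.klass == "co3UI" and UTR3_TAIL_NT < 40:
            raise FixtureError(f"{self.name}: tail too short for readthrough CDS")
        for d in self.decoys:
            if d not in ("fragment", "intronic", "antisense"):
                raise FixtureError(f"{self.name}: unknown decoy {d!r}")


@dataclass(frozen=True)
class RegulatorPlan:
    """Planted NMD-factor-like regulator: target Spearman correlation between
    its expression and the per-sample mean e3UI PSO, per condition. Defaults
    are the UPF1-like study conditions (negative coupling in normal tissue,
    essentially lost in cancer)."""

    gene_id: str = "REGULATOR"
    rho_normal: float = -0.34
    rho_cancer: float = 0.11

    def validate(self) -> None:
        for r in (self.rho_normal, self.rho_cancer):
            if not -1.0 < r < 1.0:
                raise FixtureError(f"target correlation {r} outside (-1, 1)")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    genes: tuple[GenePlan, ...]
    n_normal: int = 25
    n_cancer: int = 25
    gc: float = GC_DEFAULT
    tpm_log_mean: float = 1.0
    tpm_log_sigma: float = 0.8
    # retained-intron PSI (inclusion) Beta means; PSO = 1 - PSI. e3UIs are
    # over-spliced in cancer (PSI drops), co3UIs slightly more retained.
    psi_mean_normal: float = 0.60
    psi_delta_cancer_e3ui: float = -0.10
    psi_delta_cancer_co3ui: float = 0.05
    psi_concentration: float = 20.0
    n_background_genes: int = 100
    regulator: RegulatorPlan = field(default_factory=RegulatorPlan)

    def validate(self) -> None:
        if not self.genes:
            raise FixtureError("no genes planned")
        for g in self.genes:
            g.validate()
        self.regulator.validate()
        for m in (
            self.psi_mean_normal,
            self.psi_mean_normal + self.psi_delta_cancer_e3ui,
            self.psi_mean_normal + self.psi_delta_cancer_co3ui,
        ):
            if not 0.0 < m < 1.0:
                raise FixtureError(f"PSI mean {m} outside (0, 1)")

    @property
    def samples(self) -> list[str]:
        return [f"N{i:03d}" for i in range(1, self.n_normal + 1)] + [
            f"C{i:03d}" for i in range(1, self.n_cancer + 1)
        ]

    @property
    def condition_labels(self) -> dict[str, str]:
        return {
            s: ("normal" if s.startswith("N") else "cancer") for s in self.samples
        }


def default_gene_plans(n_genes: int) -> tuple[GenePlan, ...]:
    """A deterministic mixed plan cycling classes, intron counts, strands,
    stop distances (including the NMD-boundary-relevant 8/15/55/56/135) and
    decoy placements."""
    classes = ["e3UI", "novel_e3UI", "co3UI", "none"]
    # indices 3 and 7 land on class 'none' (4-cycle x 8-cycle), so keep the
    # NMD-boundary-relevant distances off those slots
    distances = [8, 15, 55, 35, 0, 56, 135, 210]
    lengths = [90, 60, 150, 305, 464]
    plans = []
    for i in range(n_genes):
        decoys: tuple[str, ...] = ()
        if i % 3 == 0:
            decoys = ("fragment", "antisense")
        if i % 3 == 1 and (i % 4) != 0:
            decoys = ("intronic",)
        plans.append(
            GenePlan(
                name=f"SYNG{i + 1:04d}",
                klass=classes[i % 4],
                n_cds_introns=i % 4,
                utr_intron_length=lengths[i % 5],
                distance_to_stop=distances[i % 8],
                strand="+-"[i % 2],
                decoys=decoys,
                low_confidence_extra=(i % 7 == 0),
            )
        )
    return tuple(plans)


def default_spec(seed: int, n_genes: int = 50, **kwargs) -> FixtureSpec:
    return FixtureSpec(seed=seed, genes=default_gene_plans(n_genes), **kwargs)


# ---------------------------------------------------------------------------
# gene layout
# ---------------------------------------------------------------------------

@dataclass
class _GeneBuild:
    refs: list[TranscriptModel]
    assembly: list[TranscriptModel]
    truth_rows: list[dict]
    decoy_rows: list[dict]
    window: int  # gene footprint length


def _iv(chrom: str, a: int, b: int, strand: str) -> GenomeInterval:
    return GenomeInterval(chrom, a, b, strand)


def _place(intervals, off: int, window: int, strand: str, chrom: str):
    """Map local forward-layout intervals to genomic coordinates; a minus
    gene is the mirror image of the forward layout within its window."""
    out = []
    for a, b in intervals:
        if strand == "+":
            out.append(_iv(chrom, off + a, off + b, strand))
        else:
            out.append(_iv(chrom, off + window - b, off + window - a, strand))
    return tuple(sorted(out, key=lambda x: x.start))


def _build_gene(plan: GenePlan, off: int, chrom: str = CONTIG) -> _GeneBuild:
    k = plan.n_cds_introns
    d = plan.distance_to_stop
    L = plan.utr_intron_length if plan.klass != "none" else 0

    exons_closed: list[tuple[int, int]] = []  # fully-specified upstream exons
    cds: list[tuple[int, int]] = []
    pos = UTR5_NT
    cur_start = 0
    for i in range(k + 1):
        cds.append((pos, pos + CDS_SEGMENT_NT))
        pos += CDS_SEGMENT_NT
        if i < k:
            exons_closed.append((cur_start, pos))
            pos += CDS_INTRON_NT
            cur_start = pos
            pos += 0
    stop = (pos, pos + 3)
    pos += 3 + d
    donor_at = pos  # local coordinate of the 3UI donor
    window = pos + L + UTR3_TAIL_NT

    ref1_exons = exons_closed + [(cur_start, window)]
    if plan.klass == "none":
        q_exons = ref1_exons
    else:
        q_exons = exons_closed + [(cur_start, donor_at), (donor_at + L, window)]
    start_codon = (UTR5_NT, UTR5_NT + 3)

    strand = plan.strand

    def tx(tid, exlist, cdslist=None, stop_local=None, start_local=None,
           attrs=None):
        return TranscriptModel(
            transcript_id=tid,
            gene_id=plan.name,
            chrom=chrom,
            strand=strand,
            exons=_place(exlist, off, window, strand, chrom),
            cds=_place(cdslist, off, window, strand, chrom) if cdslist else None,
            stop_codon=_place([stop_local], off, window, strand, chrom)[0]
            if stop_local else None,
            start_codon=_place([start_local], off, window, strand, chrom)[0]
            if start_local else None,
            attributes=attrs or {},
        )

    hc_attrs = {
        "transcript_support_level": "1",
        "tag": "appris_principal_1,basic",
        "transcript_biotype": "protein_coding",
    }
    refs = [
        tx(f"{plan.name}.ref1", ref1_exons, cds, stop, start_codon, dict(hc_attrs))
    ]
    if plan.klass == "e3UI":
        # annotated e3UI: a reference isoform carries the spliced 3' UTR
        refs.append(
            tx(f"{plan.name}.ref3", q_exons, cds, stop, start_codon,
               dict(hc_attrs))
        )
    if plan.klass == "co3UI":
        # readthrough isoform: CDS extends across the planted intron
        t0 = donor_at + L
        cds2 = cds[:-1] + [(cds[-1][0], donor_at), (t0, t0 + 30)]
        stop2 = (t0 + 30, t0 + 33)
        refs.append(
            tx(f"{plan.name}.ref2", q_exons, cds2, stop2, start_codon,
               dict(hc_attrs))
        )
    if plan.low_confidence_extra:
        lc_attrs = {
            "transcript_support_level": "NA",
            "transcript_biotype": "protein_coding",
        }
        refs.append(
            tx(f"{plan.name}.lc", ref1_exons, cds, stop, start_codon, lc_attrs)
        )

    qid = f"{plan.name}.q1"
    assembly = [tx(qid, q_exons)]
    truth_rows: list[dict] = []
    if plan.klass != "none":
        intron = _place([(donor_at, donor_at + L)], off, window, strand, chrom)[0]
        truth_rows.append(
            {
                "transcript_id": qid,
                "gene_id": plan.name,
                "chrom": chrom,
                "strand": strand,
                "intron_start": intron.start,
                "intron_end": intron.end,
                "klass": "co3UI" if plan.klass == "co3UI" else "e3UI",
                "novel": plan.klass == "novel_e3UI",
                "distance_to_stop": d,
            }
        )

    decoy_rows: list[dict] = []
    for kind in plan.decoys:
        if kind == "fragment":
            if k >= 1:
                e0_end = exons_closed[0][1]
                e1_start = exons_closed[0][1] + CDS_INTRON_NT
                frag = [(e0_end - 60, e0_end), (e1_start, e1_start + 60)]
            else:
                frag = [(20, 100)]
            assembly.append(tx(f"{plan.name}.frag", frag))
            decoy_rows.append({"transcript_id": f"{plan.name}.frag",
                               "kind": "fragment"})
        elif kind == "intronic":
            if k < 1:
                continue
            i0 = exons_closed[0][1]
            assembly.append(tx(f"{plan.name}.intr", [(i0 + 10, i0 + 60)]))
            decoy_rows.append({"transcript_id": f"{plan.name}.intr",
                               "kind": "intronic"})
        elif kind == "antisense":
            anti_strand = "-" if strand == "+" else "+"
            iv = _place([(UTR5_NT, UTR5_NT + 200)], off, window, strand, chrom)[0]
            assembly.append(
                TranscriptModel(
                    transcript_id=f"{plan.name}.as",
                    gene_id=f"{plan.name}.AS",
                    chrom=chrom,
                    strand=anti_strand,
                    exons=(GenomeInterval(chrom, iv.start, iv.end, anti_strand),),
                )
            )
            decoy_rows.append({"transcript_id": f"{plan.name}.as",
                               "kind": "antisense"})

    return _GeneBuild(refs, assembly, truth_rows, decoy_rows, window)


# ---------------------------------------------------------------------------
# genome sequence
# ---------------------------------------------------------------------------

def _plant(seq: np.ndarray, start: int, motif: str) -> None:
    seq[start:start + len(motif)] = np.frombuffer(motif.encode(), dtype="S1")


def _plant_signals(seq: np.ndarray, refs, assembly) -> None:
    """Overwrite splice dinucleotides (sense GT..AG), start and stop codons.

    On the minus strand the plus-strand genome reads CT..AC across the intron
    and CAT / TTA across the codons.
    """
    for tx in list(refs) + list(assembly):
        for i in tx.introns:
            if tx.strand == "+":
                _plant(seq, i.start, "GT")
                _plant(seq, i.end - 2, "AG")
            else:
                _plant(seq, i.start, "CT")
                _plant(seq, i.end - 2, "AC")
        if tx.start_codon is not None:
            sc = tx.start_codon
            _plant(seq, sc.start, "ATG" if tx.strand == "+" else "CAT")
        if tx.stop_codon is not None:
            st = tx.stop_codon
            _plant(seq, st.start, "TAA" if tx.strand == "+" else "TTA")


def _random_genome(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)


def write_fasta(seq: np.ndarray, name: str, path: Path, width: int = 80) -> None:
    raw = seq.tobytes().decode()
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(raw), width):
            fh.write(raw[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# expression / splicing tables
# ---------------------------------------------------------------------------

def _beta_params(mean: float, conc: float) -> tuple[float, float]:
    return mean * conc, (1.0 - mean) * conc


def _draw_psi(
    spec: FixtureSpec, truth: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Event x sample PSI (inclusion) table for the planted 3UIs."""
    rows = []
    index = []
    klasses = []
    n_n, n_c = spec.n_normal, spec.n_cancer
    for _, r in truth.iterrows():
        delta = (
            spec.psi_delta_cancer_co3ui
            if r["klass"] == "co3UI"
            else spec.psi_delta_cancer_e3ui
        )
        a_n, b_n = _beta_params(spec.psi_mean_normal, spec.psi_concentration)
        a_c, b_c = _beta_params(
            spec.psi_mean_normal + delta, spec.psi_concentration
        )
        vals = np.concatenate(
            [rng.beta(a_n, b_n, size=n_n), rng.beta(a_c, b_c, size=n_c)]
        )
        rows.append(vals)
        index.append(
            f"{r['transcript_id']}|{r['chrom']}:{r['intron_start']}-"
            f"{r['intron_end']}"
        )
        klasses.append(r["klass"])
    psi = pd.DataFrame(rows, index=pd.Index(index, name="event_id"),
                       columns=spec.samples)
    psi.insert(0, "klass", klasses)
    return psi


def _spearman_to_pearson(rho: float) -> float:
    """Gaussian-copula Pearson coefficient achieving Spearman rho."""
    return 2.0 * math.sin(math.pi * rho / 6.0)


def make_correlated_quant(
    spec: FixtureSpec, truth: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(gene x sample count matrix, event x sample PSI table).

    The regulator gene's expression is coupled to the per-sample mean e3UI
    PSO through a Gaussian copula on the PSO ranks, targeting the planned
    Spearman correlation within each condition; background genes are drawn
    independently of PSO so size-factor estimation has a stable reference.
    """
    psi = _draw_psi(spec, truth, rng)
    value_cols = spec.samples
    e3 = psi[psi["klass"] == "e3UI"]
    mean_pso = (1.0 - e3[value_cols]).mean(axis=0)

    base = np.exp(rng.normal(5.5, 1.2, size=spec.n_background_genes))
    counts = rng.poisson(
        base[:, None], size=(spec.n_background_genes, len(value_cols))
    ).astype(float)
    genes = [f"BG{i + 1:04d}" for i in range(spec.n_background_genes)]

    reg = np.empty(len(value_cols))
    labels = spec.condition_labels
    for cond, rho in (
        ("normal", spec.regulator.rho_normal),
        ("cancer", spec.regulator.rho_cancer),
    ):
        idx = [i for i, s in enumerate(value_cols) if labels[s] == cond]
        m = mean_pso.iloc[idx].to_numpy()
        n = len(idx)
        z = sps.norm.ppf((sps.rankdata(m) - 0.5) / n)
        rp = _spearman_to_pearson(rho)
        x = rp * z + math.sqrt(1.0 - rp * rp) * rng.standard_normal(n)
        reg[idx] = np.rint(800.0 * np.exp(0.35 * x))
    counts = np.vstack([reg, counts])
    genes = [spec.regulator.gene_id] + genes
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                             columns=value_cols)
    return counts_df, psi


# ---------------------------------------------------------------------------
# top-level fixture writer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fixture:
    outdir: Path
    genome_fa: Path
    reference_gtf: Path
    assembly_gtf: Path
    tpm_tsv: Path
    junctions_tsv: Path
    psi_tsv: Path
    counts_tsv: Path
    samples_tsv: Path
    truth_tsv: Path
    decoys_tsv: Path
    manifest_json: Path


def make_fixture(spec: FixtureSpec, outdir: str | Path) -> Fixture:
    """Write the complete fixture (genome, annotations, tables, truth)."""
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    refs: list[TranscriptModel] = []
    assembly: list[TranscriptModel] = []
    truth_rows: list[dict] = []
    decoy_rows: list[dict] = []
    off = GENE_SPACER_NT
    for plan in spec.genes:
        build = _build_gene(plan, off)
        refs.extend(build.refs)
        assembly.extend(build.assembly)
        truth_rows.extend(build.truth_rows)
        decoy_rows.extend(build.decoy_rows)
        off += build.window + GENE_SPACER_NT

    seq = _random_genome(rng, off, spec.gc)
    _plant_signals(seq, refs, assembly)

    fx = Fixture(
        outdir=outdir,
        genome_fa=outdir / "genome.fa",
        reference_gtf=outdir / "reference.gtf",
        assembly_gtf=outdir / "assembly.gtf",
        tpm_tsv=outdir / "tpm.tsv",
        junctions_tsv=outdir / "junction_counts.tsv",
        psi_tsv=outdir / "psi.tsv",
        counts_tsv=outdir / "gene_counts.tsv",
        samples_tsv=outdir / "samples.tsv",
        truth_tsv=outdir / "truth.tsv",
        decoys_tsv=outdir / "decoys.tsv",
        manifest_json=outdir / "manifest.json",
    )
    write_fasta(seq, CONTIG, fx.genome_fa)
    write_gtf(refs, fx.reference_gtf, include_cds=True)
    write_gtf(assembly, fx.assembly_gtf, include_cds=False)

    samples = spec.samples
    planted = {r["transcript_id"] for r in truth_rows}
    tpm_rows = []
    for tx in assembly:
        vals = rng.lognormal(spec.tpm_log_mean, spec.tpm_log_sigma,
                             size=len(samples))
        if tx.transcript_id in planted or tx.transcript_id.endswith(".q1"):
            vals[0] = max(vals[0], 2.0)  # planted queries pass the >1 TPM gate
        tpm_rows.append([tx.transcript_id, tx.gene_id] + [round(v, 4) for v in vals])
    pd.DataFrame(
        tpm_rows, columns=["transcript_id", "gene_id"] + samples
    ).to_csv(fx.tpm_tsv, sep="\t", index=False)

    jrows = []
    seen = set()
    for tx in assembly:
        for j in tx.introns.junctions():
            if j in seen:
                continue
            seen.add(j)
            cnts = rng.poisson(25, size=len(samples))
            if cnts.sum() == 0:
                cnts[0] = 1
            jrows.append(list(j) + cnts.tolist())
    pd.DataFrame(
        jrows, columns=["chrom", "strand", "start", "end"] + samples
    ).to_csv(fx.junctions_tsv, sep="\t", index=False)

    truth = pd.DataFrame(
        truth_rows,
        columns=["transcript_id", "gene_id", "chrom", "strand", "intron_start",
                 "intron_end", "klass", "novel", "distance_to_stop"],
    )
    truth.to_csv(fx.truth_tsv, sep="\t", index=False)
    pd.DataFrame(decoy_rows, columns=["transcript_id", "kind"]).to_csv(
        fx.decoys_tsv, sep="\t", index=False
    )

    counts_df, psi = make_correlated_quant(spec, truth, rng)
    psi_out = psi.copy()
    psi_out[samples] = psi_out[samples].round(6)
    psi_out.to_csv(fx.psi_tsv, sep="\t")
    counts_df.to_csv(fx.counts_tsv, sep="\t")

    pd.DataFrame(
        {"sample": samples,
         "condition": [spec.condition_labels[s] for s in samples]}
    ).to_csv(fx.samples_tsv, sep="\t", index=False)

    manifest = {
        "seed": spec.seed,
        "n_genes": len(spec.genes),
        "n_normal": spec.n_normal,
        "n_cancer": spec.n_cancer,
        "gc": spec.gc,
        "regulator": asdict(spec.regulator),
        "contig": CONTIG,
        "contig_length": int(off),
    }
    fx.manifest_json.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return fx
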