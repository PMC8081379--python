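"""File formats, configuration and end-to-end orchestration.

Conventions: genomic intervals are 0-based half-open internally (and in
BED); positions become 1-based only at VCF/TSV boundaries.  The pipeline
runs simulate -> call -> spectra -> decompose -> report from one validated
config and writes a manifest with a SHA-256 checksum per output, so a
rerun with the same config is verifiably byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pydantic import BaseModel, Field, model_validator

from . import group_stats, signatures, spectra, synthetic_data, variant_calling
from .channels import CHANNEL_LABELS
from .group_stats import TreatmentGroup
from .synthetic_data import ExperimentDesign, Gene, ReferenceGenome

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Formats

def write_fasta(ref: ReferenceGenome, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in ref.contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(genes: list[Gene], path) -> None:
    """6-column BED: 0-based half-open intervals, strand in column 6."""
    with open(path, "w") as fh:
        for i, g in enumerate(genes):
            fh.write(f"{g.contig}\t{g.start}\t{g.end}\tgene_{i + 1}\t0\t{g.strand}\n")


def read_bed(path) -> list[Gene]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns")
            try:
                genes.append(Gene(parts[0], int(parts[1]), int(parts[2]), parts[5]))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED record") from exc
    return genes


def read_reference(fasta_path, bed_path=None) -> ReferenceGenome:
    contigs = read_fasta(fasta_path)
    genes = read_bed(bed_path) if bed_path else []
    return ReferenceGenome(contigs=contigs, genes=genes)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"context": str, "contig": str})
    return df


def write_spectrum_table(mat: pd.DataFrame, path) -> None:
    """96-row channels x samples TSV with a leading channel-label column."""
    out = mat.copy()
    out.index.name = "channel"
    out.to_csv(path, sep="\t")


def read_spectrum_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = list(df.index)
    expected = list(CHANNEL_LABELS)
    if labels != expected:
        for got, want in zip(labels, expected):
            if got != want:
                raise ValueError(f"unexpected channel label {got!r} (expected {want!r})")
        raise ValueError(f"expected 96 channel rows, got {len(labels)}")
    return df


def write_vcf(calls: pd.DataFrame, ref: ReferenceGenome, sample: str, path) -> None:
    """VCF 4.2 for one clone's calls, with SCORE / VAF / TYPE INFO fields."""
    header = pysam.VariantHeader()
    for name, seq in ref.contigs.items():
        header.contigs.add(name, length=len(seq))
    header.info.add("SCORE", 1, "Float", "-log10 Fisher filter p-value")
    header.info.add("VAF", 1, "Float", "Alternate allele fraction in the mutated sample")
    header.info.add("TYPE", 1, "String", "Mutation type (SNV/INS/DEL)")
    sub = calls[calls["sample"] == sample]
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in sub.sort_values(["contig", "pos"]).itertuples(index=False):
            if row.type == "SNV":
                pos0, ref_allele, alt_allele = row.pos - 1, row.ref, row.alt
            elif row.type == "DEL":
                # counts row sits on the deleted base; anchor on the previous base
                pos0 = row.pos - 2
                seq = ref.contigs[row.contig]
                ref_allele = seq[pos0:row.pos]
                alt_allele = seq[pos0]
            else:  # INS; inserted base unknown from count data
                pos0 = row.pos - 1
                anchor = ref.contigs[row.contig][pos0]
                ref_allele, alt_allele = anchor, anchor + "N"
            rec = vcf.new_record(contig=row.contig, start=pos0,
                                 alleles=(ref_allele, alt_allele))
            rec.info["SCORE"] = float(row.score)
            rec.info["VAF"] = float(row.vaf)
            rec.info["TYPE"] = row.type
            vcf.write(rec)


def read_vcf(path, sample: str) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            mtype = rec.info["TYPE"]
            if mtype == "SNV":
                pos, ref_a, alt_a = rec.pos, rec.ref, rec.alts[0]
            elif mtype == "DEL":
                pos, ref_a, alt_a = rec.pos + 1, rec.ref, rec.alts[0]
            else:
                pos, ref_a, alt_a = rec.pos, rec.ref, rec.alts[0]
            rows.append({"sample": sample, "contig": rec.contig, "pos": pos,
                         "ref": ref_a, "alt": alt_a, "type": mtype,
                         "score": float(rec.info["SCORE"]),
                         "vaf": float(rec.info["VAF"])})
    return pd.DataFrame(rows, columns=["sample", "contig", "pos", "ref", "alt",
                                       "type", "score", "vaf"])


# ---------------------------------------------------------------------------
# Configuration

class GroupConfig(BaseModel):
    drug: str
    dose: str = "IC50"
    cell_line: str = "synthetic"
    n_clones: int = Field(4, ge=1)
    mean_snvs: float = Field(..., ge=0)
    direct_weight: float = Field(0.0, ge=0.0, le=1.0)


class SimulateConfig(BaseModel):
    genome_length: int = Field(3_000_000, ge=10_000)
    gene_fraction: float = Field(0.3, ge=0.0, lt=1.0)
    gc: float = Field(0.42, gt=0.0, lt=1.0)
    coverage_mean: float = Field(30.0, gt=0)
    seq_error_rate: float = Field(1e-3, ge=0.0, le=0.05)
    noise_site_multiplier: float = Field(10.0, ge=0)
    n_control_clones: int = Field(3, ge=1)
    ts_bias: float = Field(0.65, ge=0.0, le=1.0)
    direct_indel_rate: float = Field(0.08, ge=0)
    background_indel_rate: float = Field(0.05, ge=0)
    deletion_insertion_odds: float = Field(2.0, gt=0)
    groups: list[GroupConfig] = Field(default_factory=list)


class CallerConfig(BaseModel):
    min_vaf: float = 0.2
    min_other_ref_freq: float = 0.93
    min_cov: int = 7


class NMFConfig(BaseModel):
    k: int = Field(2, ge=1)
    restarts: int = Field(50, ge=1)
    max_iter: int = Field(2000, ge=1)
    tol: float = Field(1e-8, gt=0)
    fit_relative: bool = False


class PipelineConfig(BaseModel):
    """One-file, fully-seeded pipeline configuration.

    Either a ``simulate`` block or pre-existing ``reference``/``counts``
    paths (plus ``controls``) must be supplied.
    """

    seed: int = 0
    out_dir: str = "platmut_out"
    simulate: SimulateConfig | None = None
    reference: str | None = None
    genes: str | None = None
    counts: str | None = None
    controls: list[str] = Field(default_factory=list)
    caller: CallerConfig = Field(default_factory=CallerConfig)
    nmf: NMFConfig = Field(default_factory=NMFConfig)
    duration_days: float = 50.0
    cycle_hours: float = 16.0

    @model_validator(mode="after")
    def _check_inputs(self):
        if self.simulate is None:
            if self.reference is None:
                raise ValueError("config needs either a 'simulate' block or a 'reference' path")
            if self.counts is None:
                raise ValueError("config needs either a 'simulate' block or a 'counts' path")
        return self


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def default_demo_config(out_dir: str = "platmut_demo", seed: int = 7) -> PipelineConfig:
    """Three treatment arms x 4 clones on a 3 Mb genome, ~30x coverage."""
    return PipelineConfig(
        seed=seed,
        out_dir=out_dir,
        simulate=SimulateConfig(groups=[
            GroupConfig(drug="mock", dose="mock", mean_snvs=169, direct_weight=0.0),
            GroupConfig(drug="cisplatin", dose="IC50", mean_snvs=701, direct_weight=0.5),
            GroupConfig(drug="carboplatin", dose="IC50", mean_snvs=493, direct_weight=0.4),
        ]),
    )


# ---------------------------------------------------------------------------
# Orchestration

def _design_from_config(cfg: PipelineConfig) -> tuple[ExperimentDesign, list[TreatmentGroup]]:
    sim = cfg.simulate
    groups, mutations = [], {}
    for gc in sim.groups:
        prefix = f"{gc.drug}_{gc.dose}"
        g = TreatmentGroup(gc.drug, gc.dose, gc.cell_line,
                           tuple(f"{prefix}_{i + 1}" for i in range(gc.n_clones)))
        groups.append(g)
        mutations[g.name] = (gc.mean_snvs, gc.direct_weight)
    control = TreatmentGroup("control", "mock", sim.groups[0].cell_line if sim.groups
                             else "synthetic",
                             tuple(f"ctrl_{i + 1}" for i in range(sim.n_control_clones)))
    groups.append(control)
    mutations[control.name] = (0.0, 0.0)
    design = ExperimentDesign(
        groups=groups, mutations_per_clone=mutations,
        coverage_mean=sim.coverage_mean, seq_error_rate=sim.seq_error_rate,
        deletion_insertion_odds=sim.deletion_insertion_odds, seed=cfg.seed,
    )
    return design, groups


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run simulate -> call -> spectra -> decompose -> report; return the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "config": cfg.model_dump(), "stages": [],
                      "files": {}}

    def record(stage: str, *paths: Path):
        manifest["stages"].append(stage)
        for p in paths:
            manifest["files"][str(p.relative_to(out))] = _sha256(p)

    try:
        # -- simulate or load ------------------------------------------------
        if cfg.simulate is not None:
            sim = cfg.simulate
            design, groups = _design_from_config(cfg)
            ref = synthetic_data.make_reference(
                sim.genome_length, sim.gene_fraction, sim.gc, seed=cfg.seed)
            direct = synthetic_data.platinum_like_signature(
                ts_bias=sim.ts_bias, indel_rate=sim.direct_indel_rate)
            background = synthetic_data.background_signature(
                indel_rate=sim.background_indel_rate)
            truth = synthetic_data.plant_mutations(ref, design, direct, background)
            n_noise = int(sim.noise_site_multiplier * len(truth)) or 1000
            counts = synthetic_data.emit_counts(ref, truth, design, noise_sites=n_noise)
            controls = [s for g in groups if g.drug == "control" for s in g.samples]
            fasta, bed = out / "reference.fa", out / "genes.bed"
            truth_p, counts_p = out / "truth.tsv", out / "counts.tsv"
            write_fasta(ref, fasta)
            write_bed(ref.genes, bed)
            truth.to_csv(truth_p, sep="\t", index=False)
            write_counts(counts, counts_p)
            record("simulate", fasta, bed, truth_p, counts_p)
            stat_groups = [g for g in groups if g.drug != "control"]
        else:
            ref = read_reference(cfg.reference, cfg.genes)
            counts = read_counts(cfg.counts)
            controls = list(cfg.controls)
            stat_groups = []
            manifest["stages"].append("load")

        # -- call ------------------------------------------------------------
        params = variant_calling.CallerParams(**cfg.caller.model_dump())
        raw = variant_calling.detect_and_score(counts, params)
        if not controls:
            raise ValueError("no control clones available for calibration")
        calibration = variant_calling.calibrate_threshold(raw, controls)
        calls = variant_calling.call_mutations(counts, params, calibration, ref)
        calls_p = out / "calls.tsv"
        write_calls(calls, calls_p)
        calib_p = out / "calibration.json"
        calib_p.write_text(json.dumps({
            "snv_threshold": calibration.snv_threshold,
            "ins_threshold": calibration.ins_threshold,
            "del_threshold": calibration.del_threshold,
            "fp_counts": calibration.fp_counts.to_dict(orient="records"),
        }, indent=2, sort_keys=True) + "\n")
        vcf_paths = []
        for s in sorted(calls["sample"].unique()):
            p = out / f"{s}.vcf"
            write_vcf(calls, ref, s, p)
            vcf_paths.append(p)
        record("call", calls_p, calib_p, *vcf_paths)

        # -- spectra ---------------------------------------------------------
        analysis_samples = [s for g in stat_groups for s in g.samples] or \
            sorted(calls["sample"].unique())
        mat = spectra.spectrum_matrix(calls, analysis_samples)
        spec_p = out / "spectra.tsv"
        write_spectrum_table(mat, spec_p)
        sb = spectra.strand_bias(calls, ref.genes)
        sb_p = out / "strand_bias.tsv"
        sb.to_csv(sb_p, sep="\t", index=False)
        dbs, _multi = spectra.classify_dbs(calls)
        dbs_p = out / "dbs_spectrum.tsv"
        dbs.rename_axis("class").to_frame("count").to_csv(dbs_p, sep="\t")
        ind = spectra.indel_spectrum(calls, ref)
        ind_p = out / "indel_spectrum.tsv"
        ind.rename_axis("class").to_frame("count").to_csv(ind_p, sep="\t")
        record("spectra", spec_p, sb_p, dbs_p, ind_p)

        # -- decompose -------------------------------------------------------
        nonzero = mat.loc[:, mat.sum(axis=0) > 0]
        fit = signatures.nmf_fit(nonzero, k=cfg.nmf.k, restarts=cfg.nmf.restarts,
                                 max_iter=cfg.nmf.max_iter, tol=cfg.nmf.tol,
                                 seed=cfg.seed, fit_relative=cfg.nmf.fit_relative)
        sig_p, exp_p = out / "signatures.tsv", out / "exposures.tsv"
        write_spectrum_table(fit.signatures, sig_p)
        fit.exposures.rename_axis("component").to_csv(exp_p, sep="\t")
        norm = nonzero / nonzero.sum(axis=0)
        pca = signatures.pca_spectra(norm)
        pca_p = out / "pca.tsv"
        pca["coordinates"].iloc[:, :2].rename_axis("sample").to_csv(pca_p, sep="\t")
        record("decompose", sig_p, exp_p, pca_p)

        # -- report ----------------------------------------------------------
        report: dict = {"nmf_divergence": fit.divergence}
        if stat_groups:
            summary = group_stats.burden_table(calls, stat_groups)
            trend = group_stats.dose_trend(summary)
            expo = signatures.exposures_by_group(fit.exposures, stat_groups)
            report["burden"] = summary.groups.to_dict(orient="records")
            report["tests"] = summary.tests.to_dict(orient="records")
            report["dose_trend"] = trend.to_dict(orient="records")
            report["exposures_by_group"] = expo.to_dict(orient="records")
            snv = summary.groups[summary.groups["type"] == "SNV"]
            ref_rows = snv[(snv["dose"] != "mock") & snv["excess_over_mock"].notna()]
            if len(ref_rows):
                ref_excess = ref_rows["excess_over_mock"].max()
                rel = {}
                if ref_excess > 0:
                    for row in ref_rows.itertuples(index=False):
                        pct, rounded = group_stats.relative_mutagenicity(
                            row.excess_over_mock, ref_excess)
                        rel[f"{row.drug}_{row.dose}"] = {
                            "percent": pct, "percent_rounded": rounded}
                report["relative_mutagenicity_vs_max"] = rel
        report_p = out / "report.json"
        report_p.write_text(json.dumps(report, indent=2, sort_keys=True,
                                       default=float) + "\n")
        record("report", report_p)
    except Exception:
        manifest["failed_after"] = manifest["stages"][-1] if manifest["stages"] else None
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
        raise

    manifest_p = out / "manifest.json"
    manifest_p.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                     default=str) + "\n")
    return manifest
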