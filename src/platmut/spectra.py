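"""Mutation spectra, strand bias and rate normalization.

Tallies SNV calls into the frozen 96-channel trinucleotide spectrum,
merges adjacent SNVs into dinucleotide (doublet) substitutions, buckets
indels by length and homopolymer context, computes transcriptional strand
bias inside annotated genes, and normalizes mutation burdens to a
per-gigabase per-cell-cycle rate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .channels import (
    CHANNEL_LABELS,
    N_CHANNELS,
    PYRIMIDINES,
    SUBSTITUTION_CLASSES,
    classify_snv,
    revcomp,
)
from .synthetic_data import Gene

logger = logging.getLogger(__name__)

__all__ = [
    "classify_snv", "build_spectrum", "spectrum_matrix", "normalize_spectrum",
    "classify_dbs", "classify_indel", "strand_bias", "mutation_rate",
    "RateResult", "CHANNEL_LABELS",
]


def _per_sample_spectra(calls: pd.DataFrame, samples) -> pd.DataFrame:
    """96 x samples count matrix from context-annotated SNV calls."""
    mat = pd.DataFrame(
        np.zeros((N_CHANNELS, len(samples)), dtype=float),
        index=list(CHANNEL_LABELS), columns=list(samples),
    )
    snvs = calls[(calls["type"] == "SNV") & calls["sample"].isin(samples)]
    dropped = 0
    for row in snvs.itertuples(index=False):
        ctx = getattr(row, "context", "")
        if not isinstance(ctx, str) or len(ctx) != 3:
            dropped += 1
            continue
        try:
            ch = classify_snv(ctx, row.ref, row.alt)
        except ValueError:
            dropped += 1
            continue
        mat.iloc[ch, mat.columns.get_loc(row.sample)] += 1
    if dropped:
        logger.info("%d SNVs dropped from spectrum (unresolvable context)", dropped)
    return mat


def spectrum_matrix(calls: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Per-sample 96-channel count matrix (channels x samples)."""
    if not samples:
        raise ValueError("empty sample list")
    return _per_sample_spectra(calls, samples)


def build_spectrum(calls: pd.DataFrame, samples: list[str], mode: str = "sum") -> np.ndarray:
    """96-channel spectrum over a set of samples.

    ``mode='sum'`` adds per-sample spectra; ``mode='mean'`` averages them
    channel-wise (the convention for reporting a treatment group's
    spectrum).
    """
    if mode not in ("sum", "mean"):
        raise ValueError("mode must be 'sum' or 'mean'")
    mat = spectrum_matrix(calls, samples)
    vec = mat.sum(axis=1) if mode == "sum" else mat.mean(axis=1)
    return vec.to_numpy()


def normalize_spectrum(v: np.ndarray, triplet_content: np.ndarray | None = None) -> np.ndarray:
    """Relative-frequency spectrum, with an optional per-channel genome
    triplet-content correction (divide, then renormalize) for cross-genome
    comparisons."""
    v = np.asarray(v, dtype=float)
    if triplet_content is not None:
        v = v / np.asarray(triplet_content, dtype=float)
    s = v.sum()
    if s == 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return v / s


# ---------------------------------------------------------------------------
# Doublet (dinucleotide) substitutions

_DBS_CANONICAL_REFS = ("AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT")
_DBS_PALINDROMES = {"AT", "CG", "GC", "TA"}


def _dbs_label(ref2: str, alt2: str) -> str:
    if ref2 not in _DBS_CANONICAL_REFS:
        ref2, alt2 = revcomp(ref2), revcomp(alt2)
    if ref2 in _DBS_PALINDROMES:
        alt2 = min(alt2, revcomp(alt2))
    return f"{ref2}>{alt2}"


def classify_dbs(calls: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Merge adjacent same-sample SNVs into doublet substitutions.

    Returns ``(dbs_counts, multi_events)`` where ``dbs_counts`` is a label
    -> count series over the canonical doublet classes (reference doublet
    normalized to its lexicographically defined strand) and
    ``multi_events`` lists runs of three or more consecutive SNVs, which
    are excluded from the doublet classes.
    """
    counts: dict[str, int] = {}
    multi_rows = []
    snvs = calls[calls["type"] == "SNV"]
    for (sample, contig), sub in snvs.groupby(["sample", "contig"], sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        refs = sub["ref"].to_numpy()
        alts = sub["alt"].to_numpy()
        i = 0
        while i < len(pos):
            j = i
            while j + 1 < len(pos) and pos[j + 1] == pos[j] + 1:
                j += 1
            run = j - i + 1
            if run == 2:
                label = _dbs_label(refs[i] + refs[i + 1], alts[i] + alts[i + 1])
                counts[label] = counts.get(label, 0) + 1
            elif run >= 3:
                multi_rows.append({"sample": sample, "contig": contig,
                                   "start_pos": int(pos[i]), "length": run})
                logger.info("multi-nucleotide event of %d SNVs at %s:%d (%s)",
                            run, contig, pos[i], sample)
            i = j + 1
    return (pd.Series(counts, dtype=int).sort_index(),
            pd.DataFrame(multi_rows, columns=["sample", "contig", "start_pos", "length"]))


# ---------------------------------------------------------------------------
# Indel classes

_LEN_BUCKETS = ((1, "1"), (4, "2-4"), (np.inf, "5+"))
_RUN_BUCKETS = ((1, "0-1"), (4, "2-4"), (np.inf, "5+"))


def _bucket(value: int, buckets) -> str:
    for upper, label in buckets:
        if value <= upper:
            return label
    raise AssertionError


def homopolymer_run(sequence: str, pos0: int, base: str) -> int:
    """Length of the homopolymer run of ``base`` touching position ``pos0``."""
    n = 0
    i = pos0
    while i < len(sequence) and sequence[i] == base:
        n += 1
        i += 1
    i = pos0 - 1
    while i >= 0 and sequence[i] == base:
        n += 1
        i -= 1
    return n


def classify_indel(ref_allele: str, alt_allele: str, mtype: str,
                   sequence: str = "", pos0: int | None = None) -> tuple[str, str, str]:
    """Classify an indel as (type, length bucket, homopolymer-run bucket).

    Alleles use the anchored VCF convention (deletion ``AX>A``, insertion
    ``A>AB``).  The homopolymer run is measured for the first
    deleted/inserted base around the event site in ``sequence`` (0-based
    ``pos0`` of the event); without sequence context the run bucket is the
    minimal ``0-1``.
    """
    if mtype not in ("INS", "DEL"):
        raise ValueError(f"not an indel type: {mtype}")
    if mtype == "DEL":
        event = ref_allele[len(alt_allele):]
    else:
        event = alt_allele[len(ref_allele):]
    length = max(len(event), 1)
    run = 0
    if sequence and pos0 is not None and event and event[0] in "ACGT":
        run = homopolymer_run(sequence, pos0, event[0])
    return (mtype, _bucket(length, _LEN_BUCKETS), _bucket(run, _RUN_BUCKETS))


def indel_spectrum(calls: pd.DataFrame, ref=None) -> pd.Series:
    """Counts over (type, length, homopolymer) indel classes for a call set."""
    counts: dict[str, int] = {}
    indels = calls[calls["type"].isin(("INS", "DEL"))]
    for row in indels.itertuples(index=False):
        seq, pos0 = "", None
        if ref is not None and row.contig in ref.contigs:
            seq = ref.contigs[row.contig]
            # 0-based site of the first deleted base, or of the base right
            # after the insertion anchor
            pos0 = row.pos - 1 if row.type == "DEL" else row.pos
        t, lb, rb = classify_indel(row.ref, row.alt, row.type, seq, pos0)
        key = f"{t}:{lb}:{rb}"
        counts[key] = counts.get(key, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


# ---------------------------------------------------------------------------
# Transcriptional strand bias

def strand_bias(calls: pd.DataFrame, genes: list[Gene],
                per_channel: bool = False) -> pd.DataFrame:
    """Transcribed- vs untranscribed-strand SNV counts per substitution class.

    Only SNVs inside annotated genes are counted.  A mutation sits on the
    transcribed (template) strand when its pyrimidine strand is opposite
    the gene's coding strand.  Each class is tested against an equal split
    with a two-sided exact binomial test.  SNVs falling in overlapping
    genes on both strands are excluded.
    """
    gene_map: dict[str, list[Gene]] = {}
    for g in genes:
        gene_map.setdefault(g.contig, []).append(g)

    keys = list(CHANNEL_LABELS) if per_channel else list(SUBSTITUTION_CLASSES)
    trans = dict.fromkeys(keys, 0)
    untrans = dict.fromkeys(keys, 0)
    snvs = calls[calls["type"] == "SNV"]
    for row in snvs.itertuples(index=False):
        hits = {g.strand for g in gene_map.get(row.contig, [])
                if g.start <= row.pos - 1 < g.end}
        if not hits:
            continue
        if len(hits) == 2:
            logger.info("SNV at %s:%d inside genes on both strands; excluded",
                        row.contig, row.pos)
            continue
        gene_strand = hits.pop()
        pyr_strand = "+" if row.ref in PYRIMIDINES else "-"
        ctx = getattr(row, "context", "")
        try:
            ch = classify_snv(ctx, row.ref, row.alt) if len(ctx) == 3 else None
        except ValueError:
            ch = None
        if per_channel:
            if ch is None:
                continue
            key = CHANNEL_LABELS[ch]
        else:
            ref, alt = (row.ref, row.alt) if pyr_strand == "+" else (
                revcomp(row.ref), revcomp(row.alt))
            key = f"{ref}>{alt}"
        if pyr_strand != gene_strand:
            trans[key] += 1
        else:
            untrans[key] += 1

    rows = []
    for key in keys:
        t, u = trans[key], untrans[key]
        n = t + u
        if n == 0:
            continue
        p = float(binomtest(t, n, 0.5).pvalue)
        ratio = t / u if u else np.inf
        rows.append({"class": key, "transcribed": t, "untranscribed": u,
                     "ratio": ratio, "p_value": p})
    return pd.DataFrame(rows, columns=["class", "transcribed", "untranscribed",
                                       "ratio", "p_value"])


# ---------------------------------------------------------------------------
# Rate normalization

class RateResult:
    """Mutation burden normalized to mutations per Gb per cell cycle."""

    def __init__(self, mutations: float, duration_days: float,
                 cycle_hours: float, genome_gb: float):
        if duration_days <= 0 or cycle_hours <= 0 or genome_gb <= 0:
            raise ValueError("duration, cycle time and genome size must be positive")
        if mutations < 0:
            raise ValueError("mutation count must be non-negative")
        self.mutations = mutations
        self.duration_days = duration_days
        self.cycle_hours = cycle_hours
        self.genome_gb = genome_gb
        self.cycles = duration_days * 24.0 / cycle_hours
        self.rate_per_gb_per_cycle = mutations / (genome_gb * self.cycles)

    def __repr__(self):
        return (f"RateResult({self.mutations} mutations / {self.genome_gb} Gb "
                f"/ {self.cycles:.1f} cycles = "
                f"{self.rate_per_gb_per_cycle:.3g} per Gb per cycle)")


def mutation_rate(mutations: float, duration_days: float,
                  cycle_hours: float, genome_gb: float) -> RateResult:
    """Normalize a mutation count to a per-Gb per-cell-cycle rate.

    Example: 169 base substitutions accumulated over 50 days at a 16-h cell
    cycle on a 3.0 Gb genome give 0.75 per Gb per cycle.
    """
    return RateResult(mutations, duration_days, cycle_hours, genome_gb)
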