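"""Unique-mutation detection across isogenic clones.

A mutation is called in a clone only if that clone — and no other clone in
the cohort — shows the variant: candidate sites require exactly one sample
with an alternate-allele frequency above ``min_vaf`` while every other
sample is clean (reference-allele frequency above ``min_other_ref_freq``).
Candidates are scored with a one-sided Fisher exact test between the
mutated sample and the noisiest clean sample (the one with the lowest
reference-allele frequency); the score is -log10 of the p-value.  Score
thresholds are calibrated on control clones known to carry no unique
mutations so that at most 5 false-positive SNVs and 1 insertion and 1
deletion survive per control clone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .channels import BASES
from .synthetic_data import ReferenceGenome

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300

FP_BOUNDS = {"SNV": 5, "INS": 1, "DEL": 1}

CALL_COLUMNS = ("sample", "contig", "pos", "ref", "alt", "type", "score",
                "vaf", "context")


@dataclass(frozen=True)
class CallerParams:
    """Candidate-detection parameters (configurable; see pipeline config)."""

    min_vaf: float = 0.2
    min_other_ref_freq: float = 0.93
    min_cov: int = 7


@dataclass(frozen=True)
class SiteCounts:
    """Allele counts for one genomic site across the cohort."""

    contig: str
    pos: int  # 1-based
    ref_base: str
    samples: tuple[str, ...]
    cov: np.ndarray            # (S,)
    base_counts: np.ndarray    # (S, 4) in A,C,G,T order
    ins_support: np.ndarray    # (S,)
    del_support: np.ndarray    # (S,)

    def __post_init__(self):
        if (self.base_counts.sum(axis=1) > self.cov).any():
            raise ValueError("base counts exceed coverage")
        if self.pos < 1:
            raise ValueError("pos must be 1-based")


@dataclass(frozen=True)
class Candidate:
    sample: str
    alt: str          # alt base for SNV; 'INS'/'DEL' marker allele for indels
    type: str         # SNV / INS / DEL
    alt_count: int
    ref_count: int


@dataclass
class CalibrationResult:
    """Per-type score thresholds and residual FP counts on the control clones."""

    snv_threshold: float
    ins_threshold: float
    del_threshold: float
    fp_counts: pd.DataFrame = field(default_factory=pd.DataFrame)

    def threshold(self, mtype: str) -> float:
        return {"SNV": self.snv_threshold, "INS": self.ins_threshold,
                "DEL": self.del_threshold}[mtype]


def fisher_score(alt_mut: int, ref_mut: int, alt_other: int, ref_other: int) -> float:
    """-log10 of the one-sided Fisher exact p for the mutated sample having a
    higher alternate fraction than the comparison sample.

    The p-value is the hypergeometric tail P(X >= alt_mut) of the 2x2 table
    with rows (mutated, other) and columns (alt, ref); it is clamped below
    at 1e-300 before taking the log.
    """
    total = alt_mut + ref_mut + alt_other + ref_other
    p = float(hypergeom.sf(alt_mut - 1, total, alt_mut + alt_other, alt_mut + ref_mut))
    p = min(1.0, max(p, _P_FLOOR))
    return -math.log10(p)


def detect_candidates(site: SiteCounts, params: CallerParams = CallerParams()) -> Candidate | None:
    """Return the unique-mutation candidate at a site, if any.

    A candidate exists iff exactly one sample carries the variant at
    frequency >= ``min_vaf`` (coverage >= ``min_cov``) and every other
    sample is clean at reference frequency >= ``min_other_ref_freq``.
    Sites with a zero-coverage sample are skipped.  SNVs, insertions and
    deletions are assessed independently; SNV candidates win ties.
    """
    if (site.cov == 0).any():
        logger.debug("site %s:%d skipped: zero coverage", site.contig, site.pos)
        return None
    ref_idx = BASES.index(site.ref_base)
    cov = site.cov.astype(float)

    def unique_candidate(alt_counts: np.ndarray, clean_alt: np.ndarray,
                         mtype: str, alt_of) -> Candidate | None:
        vaf = alt_counts / cov
        hot = (vaf >= params.min_vaf) & (site.cov >= params.min_cov)
        if hot.sum() != 1:
            return None
        m = int(np.flatnonzero(hot)[0])
        ref_freq = 1.0 - clean_alt / cov
        others = np.ones(len(cov), dtype=bool)
        others[m] = False
        clean = (ref_freq >= params.min_other_ref_freq) & (site.cov >= params.min_cov)
        if not clean[others].all():
            return None
        return Candidate(site.samples[m], alt_of(m), mtype,
                         int(alt_counts[m]), int(site.cov[m] - alt_counts[m]))

    snv_alt = site.base_counts.copy()
    snv_alt[:, ref_idx] = 0
    best_alt = snv_alt.max(axis=1)
    nonref_total = site.cov - site.base_counts[:, ref_idx]
    cand = unique_candidate(
        best_alt, nonref_total, "SNV",
        lambda m: BASES[int(np.argmax(snv_alt[m]))],
    )
    if cand is not None:
        return cand
    for mtype, support in (("INS", site.ins_support), ("DEL", site.del_support)):
        cand = unique_candidate(support, support, mtype, lambda m: mtype)
        if cand is not None:
            return cand
    return None


def score_candidate(site: SiteCounts, candidate: Candidate) -> float:
    """Score a candidate against the non-mutated sample with the lowest
    reference-allele frequency (one-sided Fisher exact; -log10 p).
    A zero-coverage comparison sample yields an uninformative score of 0.
    """
    ref_idx = BASES.index(site.ref_base)
    m = site.samples.index(candidate.sample)
    others = [i for i in range(len(site.samples)) if i != m]
    if candidate.type == "SNV":
        alt_idx = BASES.index(candidate.alt)
        ref_cnt = site.base_counts[:, ref_idx]
        alt_cnt = site.base_counts[:, alt_idx]
    else:
        support = site.ins_support if candidate.type == "INS" else site.del_support
        alt_cnt = support
        ref_cnt = site.cov - support
    with np.errstate(divide="ignore", invalid="ignore"):
        ref_freq = np.where(site.cov > 0, ref_cnt / np.maximum(site.cov, 1), 0.0)
    o = min(others, key=lambda i: ref_freq[i])
    if site.cov[o] == 0:
        logger.warning("comparison sample has zero coverage at %s:%d",
                       site.contig, site.pos)
        return 0.0
    return fisher_score(candidate.alt_count, candidate.ref_count,
                        int(alt_cnt[o]), int(ref_cnt[o]))


def calibrate_threshold(
    control_calls: pd.DataFrame,
    control_samples: list[str],
) -> CalibrationResult:
    """Find the smallest score thresholds meeting the false-positive bounds.

    ``control_calls`` are unfiltered calls restricted to control clones
    that by construction carry no true unique mutations.  For each type the
    threshold is the smallest observed score T such that every control
    clone retains at most 5 SNVs (1 insertion, 1 deletion) with score >= T;
    if even the largest observed score leaves too many, the threshold is
    set just above it.
    """
    if not control_samples:
        raise ValueError("calibration requires at least one control clone")
    if len(control_calls) == 0:
        control_calls = pd.DataFrame(columns=list(CALL_COLUMNS[:-1]))
    thresholds: dict[str, float] = {}
    fp_rows = []
    for mtype, bound in FP_BOUNDS.items():
        sub = control_calls[(control_calls["type"] == mtype)
                            & control_calls["sample"].isin(control_samples)]
        scores = sub["score"].to_numpy(float)
        candidates = [0.0] + sorted(set(scores))
        chosen = None
        for t in candidates:
            ok = all(
                (sub.loc[sub["sample"] == s, "score"] >= t).sum() <= bound
                for s in control_samples
            )
            if ok:
                chosen = t
                break
        if chosen is None:
            chosen = float(np.nextafter(max(scores), np.inf))
        thresholds[mtype] = chosen
        for s in control_samples:
            n = int((sub.loc[sub["sample"] == s, "score"] >= chosen).sum())
            fp_rows.append({"sample": s, "type": mtype, "fp_at_threshold": n})
    return CalibrationResult(
        snv_threshold=thresholds["SNV"],
        ins_threshold=thresholds["INS"],
        del_threshold=thresholds["DEL"],
        fp_counts=pd.DataFrame(fp_rows),
    )


# ---------------------------------------------------------------------------
# Vectorized cohort-level calling

def _counts_arrays(counts: pd.DataFrame):
    samples = sorted({c.split(".")[0] for c in counts.columns if c.endswith(".cov")})
    n = len(counts)
    cov = np.stack([counts[f"{s}.cov"].to_numpy(np.int64) for s in samples], axis=1)
    bases = np.stack(
        [np.stack([counts[f"{s}.{b}"].to_numpy(np.int64) for b in BASES], axis=1)
         for s in samples], axis=1)  # (N, S, 4)
    ins = np.stack([counts[f"{s}.ins_support"].to_numpy(np.int64) for s in samples], axis=1)
    dele = np.stack([counts[f"{s}.del_support"].to_numpy(np.int64) for s in samples], axis=1)
    ref_idx = np.array([BASES.index(b) for b in counts["ref_base"]])
    assert bases.shape == (n, len(samples), 4)
    return samples, cov, bases, ins, dele, ref_idx


def _vector_fisher(alt_m, ref_m, alt_o, ref_o):
    total = alt_m + ref_m + alt_o + ref_o
    p = hypergeom.sf(alt_m - 1, total, alt_m + alt_o, alt_m + ref_m)
    p = np.clip(p, _P_FLOOR, 1.0)
    return -np.log10(p)


def detect_and_score(counts: pd.DataFrame, params: CallerParams = CallerParams()) -> pd.DataFrame:
    """Detect and score all unique-mutation candidates in a counts table.

    Vectorized over sites; equivalent to applying ``detect_candidates`` and
    ``score_candidate`` per site.  Returns unfiltered candidate calls.
    """
    samples, cov, bases, ins, dele, ref_idx = _counts_arrays(counts)
    n, S = cov.shape
    valid = ~(cov == 0).any(axis=1)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.info("%d sites skipped for zero coverage in some sample", n_skipped)
    covf = np.where(cov == 0, 1, cov).astype(float)

    rows = []

    def harvest(alt_counts, clean_alt, mtype, alt_base_idx=None):
        vaf = alt_counts / covf
        hot = (vaf >= params.min_vaf) & (cov >= params.min_cov)
        one_hot = valid & (hot.sum(axis=1) == 1)
        if not one_hot.any():
            return np.zeros(n, dtype=bool)
        m = np.argmax(hot, axis=1)
        ref_freq = 1.0 - clean_alt / covf
        clean = (ref_freq >= params.min_other_ref_freq) & (cov >= params.min_cov)
        # require every sample other than the mutated one to be clean
        clean_other = clean.copy()
        clean_other[np.arange(n), m] = True
        sel = one_hot & clean_other.all(axis=1)
        if not sel.any():
            return np.zeros(n, dtype=bool)
        idx = np.flatnonzero(sel)
        ms = m[idx]
        alt_mut = alt_counts[idx, ms]
        ref_mut = cov[idx, ms] - alt_mut
        # comparison sample: lowest ref-allele frequency among the others
        rf = ref_freq[idx].copy()
        rf[np.arange(len(idx)), ms] = np.inf
        o = np.argmin(rf, axis=1)
        if mtype == "SNV":
            ab = alt_base_idx[idx, ms]
            alt_o = bases[idx, o, ab]
            ref_o = bases[idx, o, ref_idx[idx]]
        else:
            support = ins if mtype == "INS" else dele
            alt_o = support[idx, o]
            ref_o = cov[idx, o] - alt_o
        zero_other = cov[idx, o] == 0
        scores = _vector_fisher(alt_mut.astype(float), ref_mut.astype(float),
                                alt_o.astype(float), ref_o.astype(float))
        scores = np.where(zero_other, 0.0, scores)
        contigs = counts["contig"].to_numpy()
        poss = counts["pos"].to_numpy()
        refb = counts["ref_base"].to_numpy()
        for j, i in enumerate(idx):
            if mtype == "SNV":
                alt_allele = BASES[int(alt_base_idx[i, ms[j]])]
            else:
                alt_allele = mtype
            rows.append({
                "sample": samples[int(ms[j])], "contig": contigs[i],
                "pos": int(poss[i]), "ref": refb[i], "alt": alt_allele,
                "type": mtype, "score": float(scores[j]),
                "vaf": float(alt_mut[j] / cov[i, ms[j]]),
            })
        return sel

    snv_alt = bases.copy()
    snv_alt[np.arange(n)[:, None], np.arange(S)[None, :], ref_idx[:, None]] = 0
    best_alt = snv_alt.max(axis=2)
    best_idx = snv_alt.argmax(axis=2)
    nonref = cov - bases[np.arange(n)[:, None], np.arange(S)[None, :], ref_idx[:, None]]
    harvest(best_alt, nonref, "SNV", best_idx)
    for mtype, support in (("INS", ins), ("DEL", dele)):
        harvest(support, support, mtype)
    calls = pd.DataFrame(rows, columns=list(CALL_COLUMNS[:-1]))
    if len(calls):
        # SNV candidates win ties at the same site (matches per-site logic)
        is_snv = (calls["type"] == "SNV").to_numpy()
        snv_sites = set(zip(calls.loc[is_snv, "contig"], calls.loc[is_snv, "pos"]))
        dup = ~is_snv & np.array(
            [(c, p) in snv_sites for c, p in zip(calls["contig"], calls["pos"])]
        )
        calls = calls[~dup]
    return calls.reset_index(drop=True)


def annotate_context(calls: pd.DataFrame, ref: ReferenceGenome) -> pd.DataFrame:
    """Attach the reference-strand trinucleotide context to SNV calls.

    Calls at contig edges keep an empty context and are excluded from
    96-channel spectra downstream.
    """
    contexts = []
    n_edge = 0
    for row in calls.itertuples(index=False):
        if row.type != "SNV":
            contexts.append("")
            continue
        ctx = ref.context(row.contig, row.pos - 1)
        if ctx is None or any(b not in BASES for b in ctx):
            n_edge += 1
            contexts.append("")
        else:
            contexts.append(ctx)
    if n_edge:
        logger.info("%d SNV calls lack a resolvable context", n_edge)
    out = calls.copy()
    out["context"] = contexts
    return out


def call_mutations(
    counts: pd.DataFrame,
    params: CallerParams,
    calibration: CalibrationResult,
    ref: ReferenceGenome | None = None,
) -> pd.DataFrame:
    """Full calling pass: detect, score, threshold-filter, annotate, sort."""
    calls = detect_and_score(counts, params)
    if len(calls):
        keep = np.array([
            row.score >= calibration.threshold(row.type)
            for row in calls.itertuples(index=False)
        ])
        calls = calls[keep]
    if ref is not None:
        calls = annotate_context(calls, ref)
    else:
        calls = calls.copy()
        calls["context"] = ""
    return (calls.sort_values(["sample", "contig", "pos"], kind="mergesort")
                 .reset_index(drop=True))
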