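"""In-silico isogenic-clone mutagenesis experiments.

This module is the forward model of the whole pipeline: it builds a random
reference genome with gene-strand annotations, plants unique mutations in
descendant clones drawn from a two-component signature mixture (a "direct"
platinum-adduct-like signature with transcribed-strand bias plus a broad
"background" signature), and emits noisy per-site allele-count tables that
emulate ~30x short-read coverage.  Every downstream stage — calling,
spectra, NMF decomposition, group statistics — can therefore be tested
against known planted truth without any sequencing data.

All randomness flows from a single master seed through named sub-streams
(``genome``, ``planting``, ``counts``) so each stage is independently
reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import (
    BASES,
    N_CHANNELS,
    PYRIMIDINES,
    channel_context,
    channel_parts,
    revcomp,
)
from .group_stats import TreatmentGroup

_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in _BASE_TO_CODE.items():
    _CODE_LUT[ord(_b)] = _i


def rng_stream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible random stream derived from one master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass(frozen=True)
class Gene:
    """A gene interval, 0-based half-open, with its coding strand."""

    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'


@dataclass
class ReferenceGenome:
    """Contigs (uppercase A/C/G/T strings) plus non-overlapping gene intervals."""

    contigs: dict[str, str]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self):
        for gene in self.genes:
            if gene.contig not in self.contigs:
                raise ValueError(f"gene on unknown contig {gene.contig!r}")
            if not (0 <= gene.start < gene.end <= len(self.contigs[gene.contig])):
                raise ValueError(f"gene {gene} outside contig bounds")
            if gene.strand not in "+-":
                raise ValueError(f"bad strand {gene.strand!r}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def context(self, contig: str, pos0: int) -> str | None:
        """Reference-strand 3-mer around ``pos0`` (0-based); None at contig edges."""
        seq = self.contigs[contig]
        if pos0 < 1 or pos0 > len(seq) - 2:
            return None
        return seq[pos0 - 1 : pos0 + 2]


@dataclass
class SignatureSpec:
    """A mutational process: 96-channel probabilities plus per-process extras.

    ``ts_bias`` is the probability that an in-gene mutation from this process
    sits on the transcribed (template) strand in the pyrimidine convention;
    0.5 means no bias.  ``indel_rate`` is the expected number of 1-bp indels
    planted per SNV of this process.
    """

    name: str
    channel_probs: np.ndarray
    ts_bias: float = 0.5
    indel_rate: float = 0.0

    def __post_init__(self):
        p = np.asarray(self.channel_probs, dtype=float)
        if p.shape != (N_CHANNELS,):
            raise ValueError(f"channel_probs must have shape (96,), got {p.shape}")
        if (p < 0).any():
            raise ValueError("channel_probs must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"channel_probs must sum to 1, got {p.sum()!r}")
        if not 0.0 <= self.ts_bias <= 1.0:
            raise ValueError("ts_bias must lie in [0, 1]")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be non-negative")
        self.channel_probs = p


@dataclass
class ExperimentDesign:
    """The experimental layout: groups of clones and their planting parameters.

    ``mutations_per_clone`` maps each group name to ``(mean SNV count,
    mixture weight of the direct signature)``.  Coverage is Poisson around
    ``coverage_mean`` and each sequenced base miscalls with probability
    ``seq_error_rate``.
    """

    groups: list[TreatmentGroup]
    mutations_per_clone: dict[str, tuple[float, float]]
    coverage_mean: float = 30.0
    seq_error_rate: float = 1e-3
    deletion_insertion_odds: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if not 0.0 <= self.seq_error_rate <= 0.05:
            raise ValueError("seq_error_rate must lie in [0, 0.05]")
        names = [g.name for g in self.groups]
        if len(names) != len(set(names)):
            raise ValueError(
                "duplicate group names (drug_dose must be unique per design); "
                "use distinct drug labels per cell line"
            )
        for g in self.groups:
            if g.name not in self.mutations_per_clone:
                raise ValueError(f"no mutations_per_clone entry for group {g.name!r}")
            mean, w = self.mutations_per_clone[g.name]
            if mean < 0:
                raise ValueError("mean SNV count must be >= 0")
            if not 0.0 <= w <= 1.0:
                raise ValueError("mixture weight must lie in [0, 1]")

    @property
    def samples(self) -> list[str]:
        return [s for g in self.groups for s in g.samples]


TRUTH_COLUMNS = ("contig", "pos", "clone", "ref", "alt", "type", "component",
                 "channel", "strand")


# ---------------------------------------------------------------------------
# Reference genome generation

def make_reference(
    length_bp: int,
    gene_fraction: float = 0.3,
    gc: float = 0.42,
    seed: int = 0,
    n_contigs: int = 1,
    gene_length_range: tuple[int, int] = (500, 3000),
) -> ReferenceGenome:
    """Generate a random reference genome with non-overlapping genes.

    Bases are drawn i.i.d. with stationary GC content ``gc``.  Gene
    intervals with random strands are placed without overlap so that they
    cover approximately ``gene_fraction`` of the genome.  Deterministic
    given ``seed``.
    """
    if length_bp < 10_000:
        raise ValueError("length_bp must be at least 10000")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie in (0, 1)")
    if not 0.0 <= gene_fraction < 1.0:
        raise ValueError("gene_fraction must lie in [0, 1)")
    rng = rng_stream(seed, "genome")
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    per_contig = length_bp // n_contigs
    lengths = [per_contig] * n_contigs
    lengths[-1] += length_bp - per_contig * n_contigs

    contigs: dict[str, str] = {}
    genes: list[Gene] = []
    lo, hi = gene_length_range
    if gene_fraction > 0 and min(lengths) < hi:
        raise ValueError("contigs too short to place a gene")
    for ci, clen in enumerate(lengths):
        name = f"chr{ci + 1}"
        codes = rng.choice(4, size=clen, p=probs)
        contigs[name] = "".join(BASES[c] for c in codes)
        if gene_fraction > 0:
            mean_gap = (lo + hi) / 2 * (1 - gene_fraction) / gene_fraction
            cursor = int(rng.exponential(mean_gap)) + 1
            while True:
                glen = int(rng.integers(lo, hi + 1))
                if cursor + glen > clen:
                    break
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(Gene(name, cursor, cursor + glen, strand))
                cursor += glen + int(rng.exponential(mean_gap)) + 1
    return ReferenceGenome(contigs=contigs, genes=genes)


# ---------------------------------------------------------------------------
# Context index: where in the genome each pyrimidine-centred 3-mer occurs

class ContextIndex:
    """Per-context position pools for channel-conditional site placement.

    Every interior genomic position is matched to its pyrimidine-centred
    trinucleotide context: directly if the reference middle base is C/T,
    via the reverse complement (strand ``-``) if it is A/G.  For each of the
    32 contexts the index keeps the matching positions split into
    intergenic / transcribed / untranscribed pools, where "transcribed"
    means the pyrimidine of the context lies on the gene's template strand.
    """

    def __init__(self, ref: ReferenceGenome):
        self.ref = ref
        self.contig_names = list(ref.contigs)
        gene_strand: dict[str, np.ndarray] = {}
        for name, seq in ref.contigs.items():
            arr = np.zeros(len(seq), dtype=np.int8)  # 0 none, +1 '+', -1 '-'
            gene_strand[name] = arr
        for g in ref.genes:
            gene_strand[g.contig][g.start:g.end] = 1 if g.strand == "+" else -1
        self.gene_strand = gene_strand

        # pools[context] = dict(all=, intergenic=, transcribed=, untranscribed=)
        # entries are (contig_idx, pos0, pyr_strand) int arrays
        ctx_rows: dict[str, list[np.ndarray]] = {}
        for ci, name in enumerate(self.contig_names):
            seq = ref.contigs[name]
            codes = _CODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
            if len(codes) < 3:
                continue
            left, mid, right = codes[:-2], codes[1:-1], codes[2:]
            fwd_key = left.astype(np.int32) * 16 + mid * 4 + right
            rev_key = (3 - right.astype(np.int32)) * 16 + (3 - mid) * 4 + (3 - left)
            is_pyr = (mid == 1) | (mid == 3)  # C or T
            key = np.where(is_pyr, fwd_key, rev_key)
            strand = np.where(is_pyr, 1, -1).astype(np.int8)
            pos0 = np.arange(1, len(codes) - 1)
            gs = gene_strand[name][pos0]
            # transcribed: pyrimidine strand is the template, i.e. opposite the gene strand
            klass = np.where(gs == 0, 0, np.where(strand != gs, 1, 2)).astype(np.int8)
            for ctx_code in np.unique(key):
                trinuc = BASES[ctx_code // 16] + BASES[(ctx_code // 4) % 4] + BASES[ctx_code % 4]
                sel = key == ctx_code
                rows = np.column_stack(
                    [np.full(sel.sum(), ci), pos0[sel], strand[sel], klass[sel]]
                )
                ctx_rows.setdefault(trinuc, []).append(rows)
        self.pools: dict[str, dict[str, np.ndarray]] = {}
        for trinuc, parts in ctx_rows.items():
            allrows = np.vstack(parts)
            self.pools[trinuc] = {
                "all": allrows,
                "intergenic": allrows[allrows[:, 3] == 0],
                "transcribed": allrows[allrows[:, 3] == 1],
                "untranscribed": allrows[allrows[:, 3] == 2],
            }


# ---------------------------------------------------------------------------
# Mutation planting

def plant_mutations(
    ref: ReferenceGenome,
    design: ExperimentDesign,
    direct: SignatureSpec,
    background: SignatureSpec,
    max_retries: int = 100,
) -> pd.DataFrame:
    """Plant unique heterozygous mutations per clone from a two-signature mixture.

    Per clone the SNV count is Poisson with the group mean; each SNV is
    assigned to the direct or background process by the group's mixture
    weight, a channel is drawn from that process's probabilities, and a
    genomic site is drawn uniformly among positions matching the channel's
    pyrimidine-centred context on either strand.  Direct-process mutations
    landing inside genes are placed on the transcribed strand with
    probability ``direct.ts_bias``.  1-bp indels are added at each process's
    ``indel_rate`` per SNV.  No two clones share a site.

    Returns the planted-truth table (columns ``contig, pos, clone, ref, alt,
    type, component, channel, strand``; ``pos`` is 1-based).
    """
    rng = rng_stream(design.seed, "planting")
    index = ContextIndex(ref)
    used: set[tuple[int, int]] = set()
    rows: list[dict] = []
    contig_names = index.contig_names
    specs = {"direct": direct, "background": background}

    def place_snv(clone: str, component: str, channel: int) -> None:
        spec = specs[component]
        trinuc = channel_context(channel)
        pools = index.pools.get(trinuc)
        if pools is None or len(pools["all"]) == 0:
            raise RuntimeError(
                f"no genomic site matches context {trinuc!r} for channel "
                f"{channel}; enlarge the reference or adjust the signature"
            )
        pool = pools["all"]
        for _ in range(max_retries):
            row = pool[rng.integers(len(pool))]
            ci, pos0, strand = int(row[0]), int(row[1]), int(row[2])
            if row[3] != 0 and component == "direct" and spec.ts_bias != 0.5:
                wanted = "transcribed" if rng.random() < spec.ts_bias else "untranscribed"
                sub = pools[wanted]
                if len(sub):
                    row = sub[rng.integers(len(sub))]
                    ci, pos0, strand = int(row[0]), int(row[1]), int(row[2])
            if (ci, pos0) in used:
                continue
            used.add((ci, pos0))
            contig = contig_names[ci]
            ref_base = ref.contigs[contig][pos0]
            _, pyr_ref, pyr_alt, _ = channel_parts(channel)
            if strand == 1:
                assert ref_base == pyr_ref
                alt = pyr_alt
            else:
                alt = revcomp(pyr_alt)
            rows.append({"contig": contig, "pos": pos0 + 1, "clone": clone,
                         "ref": ref_base, "alt": alt, "type": "SNV",
                         "component": component, "channel": channel,
                         "strand": "+" if strand == 1 else "-"})
            return
        raise RuntimeError(
            f"could not place a unique site for context {trinuc!r} "
            f"after {max_retries} retries"
        )

    def place_indel(clone: str, component: str) -> None:
        odds = design.deletion_insertion_odds
        is_del = rng.random() < odds / (1.0 + odds)
        for _ in range(max_retries):
            ci = int(rng.integers(len(contig_names)))
            contig = contig_names[ci]
            seq = ref.contigs[contig]
            pos0 = int(rng.integers(1, len(seq) - 1))
            if (ci, pos0) in used:
                continue
            used.add((ci, pos0))
            anchor = seq[pos0 - 1]
            if is_del:
                ref_allele, alt_allele, mtype = anchor + seq[pos0], anchor, "DEL"
            else:
                ins_base = BASES[int(rng.integers(4))]
                ref_allele, alt_allele, mtype = seq[pos0], seq[pos0] + ins_base, "INS"
            rows.append({"contig": contig, "pos": pos0 + 1, "clone": clone,
                         "ref": ref_allele, "alt": alt_allele, "type": mtype,
                         "component": component, "channel": -1, "strand": "."})
            return
        raise RuntimeError(f"could not place a unique indel site after {max_retries} retries")

    for group in design.groups:
        mean, w = design.mutations_per_clone[group.name]
        for clone in group.samples:
            n_snv = int(rng.poisson(mean))
            n_direct = int(rng.binomial(n_snv, w)) if n_snv else 0
            for component, n in (("direct", n_direct), ("background", n_snv - n_direct)):
                if n == 0:
                    continue
                channels = rng.choice(N_CHANNELS, size=n, p=specs[component].channel_probs)
                for ch in channels:
                    place_snv(clone, component, int(ch))
                n_ind = int(rng.poisson(specs[component].indel_rate * n))
                for _ in range(n_ind):
                    place_indel(clone, component)

    truth = pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))
    return truth.sort_values(["contig", "pos"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Allele-count emission

def counts_columns(samples: list[str]) -> list[str]:
    cols = ["contig", "pos", "ref_base"]
    for s in samples:
        cols += [f"{s}.cov", f"{s}.A", f"{s}.C", f"{s}.G", f"{s}.T",
                 f"{s}.ins_support", f"{s}.del_support"]
    return cols


def emit_counts(
    ref: ReferenceGenome,
    truth: pd.DataFrame,
    design: ExperimentDesign,
    noise_sites: int | None = None,
) -> pd.DataFrame:
    """Emit the per-site allele-count table over all samples.

    One row per planted site plus ``noise_sites`` randomly chosen clean
    sites (default: 10x the planted-site count).  Per sample and site,
    coverage is Poisson(``coverage_mean``); the mutated clone of a planted
    het site draws supporting reads Binomial(coverage, 0.5); everywhere
    else alternate reads arise only from ``seq_error_rate`` miscalls
    (uniform over the three non-reference bases).  Sporadic spurious
    ins/del support arises at the same error rate.
    """
    rng = rng_stream(design.seed, "counts")
    samples = design.samples
    contig_names = list(ref.contigs)
    if noise_sites is None:
        noise_sites = 10 * len(truth)

    planted = truth[["contig", "pos"]].copy()
    planted_keys = set(zip(truth["contig"], truth["pos"]))
    noise_rows = []
    lengths = {c: len(s) for c, s in ref.contigs.items()}
    total = sum(lengths.values())
    weights = np.array([lengths[c] for c in contig_names], dtype=float) / total
    guard = 0
    while len(noise_rows) < noise_sites:
        ci = int(rng.choice(len(contig_names), p=weights))
        contig = contig_names[ci]
        pos = int(rng.integers(2, lengths[contig]))  # 1-based, interior
        if (contig, pos) in planted_keys:
            guard += 1
            if guard > 100 * noise_sites + 1000:
                raise RuntimeError("cannot place noise sites; genome too saturated")
            continue
        planted_keys.add((contig, pos))
        noise_rows.append((contig, pos))

    sites = pd.concat(
        [planted, pd.DataFrame(noise_rows, columns=["contig", "pos"])],
        ignore_index=True,
    ).drop_duplicates().sort_values(["contig", "pos"], kind="mergesort").reset_index(drop=True)
    n_sites = len(sites)
    ref_base = np.array(
        [ref.contigs[c][p - 1] for c, p in zip(sites["contig"], sites["pos"])]
    )
    ref_idx = np.array([_BASE_TO_CODE[b] for b in ref_base])

    err = design.seq_error_rate
    # non-reference base slots, in base order, per site
    alt_slots = np.array([[b for b in range(4) if b != r] for r in ref_idx])

    data: dict[str, np.ndarray] = {}
    site_lookup = {(c, p): i for i, (c, p) in enumerate(zip(sites["contig"], sites["pos"]))}
    mutated: dict[str, list[tuple[int, str, str, str]]] = {s: [] for s in samples}
    for row in truth.itertuples(index=False):
        mutated[row.clone].append((site_lookup[(row.contig, row.pos)],
                                   row.type, row.ref, row.alt))

    for s in samples:
        cov = rng.poisson(design.coverage_mean, n_sites)
        n_err = rng.binomial(cov, err) if err > 0 else np.zeros(n_sites, dtype=np.int64)
        err_split = rng.multinomial(n_err, [1 / 3] * 3)
        bases = np.zeros((n_sites, 4), dtype=np.int64)
        bases[np.arange(n_sites), ref_idx] = cov - n_err
        np.add.at(bases, (np.arange(n_sites)[:, None], alt_slots), err_split)
        ins = rng.binomial(cov, err) if err > 0 else np.zeros(n_sites, dtype=np.int64)
        dele = rng.binomial(cov, err) if err > 0 else np.zeros(n_sites, dtype=np.int64)

        for i, mtype, mref, malt in mutated[s]:
            c = int(cov[i])
            support = int(rng.binomial(c, 0.5))
            rest = c - support
            ne = int(rng.binomial(rest, err)) if err > 0 else 0
            split = rng.multinomial(ne, [1 / 3] * 3)
            row = np.zeros(4, dtype=np.int64)
            row[ref_idx[i]] = rest - ne
            row[alt_slots[i]] += split
            if mtype == "SNV":
                row[_BASE_TO_CODE[malt]] += support
                bases[i] = row
            else:
                bases[i] = row
                if mtype == "INS":
                    ins[i] = support
                else:
                    dele[i] = support
        data[f"{s}.cov"] = cov
        for bi, b in enumerate(BASES):
            data[f"{s}.{b}"] = bases[:, bi]
        data[f"{s}.ins_support"] = ins
        data[f"{s}.del_support"] = dele

    out = pd.concat(
        [pd.DataFrame({"contig": sites["contig"], "pos": sites["pos"],
                       "ref_base": ref_base}),
         pd.DataFrame(data)],
        axis=1,
    )
    return out[counts_columns(samples)]


# ---------------------------------------------------------------------------
# Canonical signature and design presets

def platinum_like_signature(ts_bias: float = 0.65, indel_rate: float = 0.08) -> SignatureSpec:
    """The direct platinum-adduct signature: intrastrand-crosslink peaks.

    All mass sits on the channels expected from purine-purine crosslinks:
    C>A with a 3' C (GpG adducts read on the pyrimidine strand, NCC>NAC)
    and T>A with a 5' C (ApG adducts, CTN>CAN).  Broad-spectrum mutagenesis
    is modelled separately by the background component.
    """
    p = np.zeros(N_CHANNELS)
    for i in range(N_CHANNELS):
        five, r, a, three = channel_parts(i)
        if r == "C" and a == "A" and three == "C":
            p[i] = 0.60 / 4
        elif r == "T" and a == "A" and five == "C":
            p[i] = 0.40 / 4
    p /= p.sum()
    return SignatureSpec("platinum_direct", p, ts_bias=ts_bias, indel_rate=indel_rate)


def background_signature(indel_rate: float = 0.05) -> SignatureSpec:
    """A broad, featureless background signature with mildly elevated C>T."""
    p = np.ones(N_CHANNELS)
    for i in range(N_CHANNELS):
        _, r, a, _ = channel_parts(i)
        if r == "C" and a == "T":
            p[i] = 1.8
        elif r == "T" and a == "C":
            p[i] = 1.3
    p /= p.sum()
    return SignatureSpec("background", p, ts_bias=0.5, indel_rate=indel_rate)


def default_design(
    seed: int = 0,
    clones_per_group: int = 4,
    n_control_clones: int = 3,
    cell_line: str = "synthetic",
) -> ExperimentDesign:
    """The default three-arm experiment emulated by the demo pipeline.

    Group mean SNV burdens follow the human-lymphoblastoid-scale study
    conditions (mock ~169 SNVs per clone over the experiment; cisplatin
    mock+532; carboplatin mock+324) with direct-signature mixture weights
    decreasing from cisplatin to carboplatin.  Control clones carry no
    unique mutations and serve for false-positive calibration.
    """
    def mk(drug, dose, n, prefix):
        return TreatmentGroup(drug, dose, cell_line,
                              tuple(f"{prefix}{i + 1}" for i in range(n)))

    groups = [
        mk("mock", "mock", clones_per_group, "mock_"),
        mk("cisplatin", "IC50", clones_per_group, "cis_"),
        mk("carboplatin", "IC50", clones_per_group, "carbo_"),
    ]
    mutations = {
        "mock_mock": (169.0, 0.0),
        "cisplatin_IC50": (701.0, 0.5),
        "carboplatin_IC50": (493.0, 0.4),
    }
    if n_control_clones:
        groups.append(mk("control", "mock", n_control_clones, "ctrl_"))
        mutations["control_mock"] = (0.0, 0.0)
    return ExperimentDesign(groups=groups, mutations_per_clone=mutations, seed=seed)
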