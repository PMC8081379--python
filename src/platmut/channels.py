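"""The frozen 96-channel trinucleotide substitution canon.

Substitutions are reported pyrimidine-centred: a mutation whose reference
base is a purine is reverse-complemented (context and alleles) before
classification.  Channels are ordered by substitution class
``C>A, C>G, C>T, T>A, T>C, T>G``, each class expanded by the 5' flank then
the 3' flank in alphabetical order, giving labels like ``A[C>A]A`` ...
``T[T>G]T``.  This ordering is the single source of truth for every
spectrum, signature table and serialized file in the package.
"""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = "CT"
COMPLEMENT = str.maketrans("ACGT", "TGCA")

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

N_CHANNELS = 96

CHANNEL_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)

_LABEL_TO_INDEX = {label: i for i, label in enumerate(CHANNEL_LABELS)}


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(COMPLEMENT)[::-1]


def classify_snv(ref_context: str, ref: str, alt: str) -> int:
    """Map an SNV with its reference-strand trinucleotide context to a channel.

    Parameters
    ----------
    ref_context : the 3-mer around the mutated base on the reference strand.
    ref, alt : reference and alternate alleles on the reference strand.

    Returns the channel index (0..95).  Raises ``ValueError`` on malformed
    input; contexts containing bases outside A/C/G/T (e.g. N) are rejected
    and should be tallied by the caller as context-unresolvable drops.
    """
    if len(ref_context) != 3:
        raise ValueError(f"context must be a 3-mer, got {ref_context!r}")
    for b in ref_context + ref + alt:
        if b not in BASES:
            raise ValueError(f"ambiguous or invalid base in {ref_context!r} {ref}>{alt}")
    if ref_context[1] != ref:
        raise ValueError(f"middle of context {ref_context!r} does not match ref {ref!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if ref not in PYRIMIDINES:
        ref_context = revcomp(ref_context)
        ref = ref_context[1]
        alt = revcomp(alt)
    label = f"{ref_context[0]}[{ref}>{alt}]{ref_context[2]}"
    return _LABEL_TO_INDEX[label]


def channel_label(index: int) -> str:
    return CHANNEL_LABELS[index]


def channel_index(label: str) -> int:
    try:
        return _LABEL_TO_INDEX[label]
    except KeyError:
        raise ValueError(f"unknown channel label {label!r}") from None


def channel_parts(index: int) -> tuple[str, str, str, str]:
    """Decompose a channel into (5' flank, pyrimidine ref, alt, 3' flank)."""
    label = CHANNEL_LABELS[index]
    return label[0], label[2], label[4], label[6]


def channel_context(index: int) -> str:
    """Pyrimidine-strand trinucleotide context of a channel (e.g. ``ACG``)."""
    five, ref, _, three = channel_parts(index)
    return five + ref + three


#: The 32 pyrimidine-centred trinucleotide contexts, in channel-canon order.
PYRIMIDINE_CONTEXTS: tuple[str, ...] = tuple(
    dict.fromkeys(channel_context(i) for i in range(N_CHANNELS))
)
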