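"""Trinucleotide substitution classes.

Single-base substitutions are binned by the mutated base and its immediate
5' and 3' neighbours on the reference strand.  Classes are collapsed so the
mutated (middle) base is always a pyrimidine: a substitution with a purine
reference is reported on the opposite strand by reverse-complementing the
context and both alleles.  Six base changes (C>A, C>G, C>T, T>A, T>C, T>G)
times 4 x 4 flanking bases gives 96 classes, written ``X[R>A]Y``.
"""

from __future__ import annotations

from itertools import product

BASES = "ACGT"
PURINES = frozenset("AG")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def complement(base: str) -> str:
    return base.translate(_COMP)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMP)[::-1]


def canonical_class(context: str, ref_base: str, alt_base: str) -> str:
    """Map a substitution with its trinucleotide context to its pyrimidine-
    centred class label.

    Parameters
    ----------
    context : str
        Reference-strand trinucleotide; the middle base must equal ``ref_base``.
    ref_base, alt_base : str
        The reference and alternative alleles; must differ and contain no N.

    Returns
    -------
    str
        Label of the form ``"X[R>A]Y"`` with R in {C, T}.
    """
    context = context.upper()
    ref_base = ref_base.upper()
    alt_base = alt_base.upper()
    if len(context) != 3:
        raise ValueError(f"context must be a trinucleotide, got {context!r}")
    if "N" in context or ref_base == "N" or alt_base == "N":
        raise ValueError("N not allowed in context or alleles")
    if context[1] != ref_base:
        raise ValueError(
            f"middle base of context {context!r} does not match ref {ref_base!r}"
        )
    if alt_base == ref_base:
        raise ValueError("alt allele equals reference allele")
    if ref_base not in BASES or alt_base not in BASES:
        raise ValueError("alleles must be one of A/C/G/T")
    if ref_base in PURINES:
        context = revcomp(context)
        ref_base = complement(ref_base)
        alt_base = complement(alt_base)
    return f"{context[0]}[{ref_base}>{alt_base}]{context[2]}"


def all_class_labels() -> list[str]:
    """The 96 canonical substitution-context labels, sorted."""
    labels = set()
    for five, ref, three in product(BASES, "CT", BASES):
        for alt in BASES:
            if alt == ref:
                continue
            labels.add(f"{five}[{ref}>{alt}]{three}")
    return sorted(labels)


CLASS_LABELS: tuple[str, ...] = tuple(all_class_labels())

#: Six pyrimidine-centred base-change classes, e.g. "C>T".
CHANGE_CLASSES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def change_class(label: str) -> str:
    """Base-change class ("C>T", ...) of a 96-class label."""
    return label[2:5]
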