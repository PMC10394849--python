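"""Verbatim breeding-advice texts for phenotype-associated non-reference
variants, keyed by inheritance pattern and by whether the variant was found
homozygous or heterozygous.

The texts are clinical boilerplate and are reproduced byte-for-byte in
reports; they deliberately retain conditional phrasing ("If animal is
female: ...") rather than being specialized by an inferred sex — the tool
never infers sex from the VCF. The lookup is total: every inheritance
pattern, including UNKNOWN, maps to a non-empty text for both classes.
A homozygous call on the Y chromosome is haploid in reality (hemizygous),
so the homozygous Y-linked advice reuses the Y-linked text.
"""

from __future__ import annotations

from .voi import InheritancePattern

__all__ = [
    "HOMOZYGOUS",
    "HETEROZYGOUS",
    "breeding_advice",
    "HOMOZYGOUS_GENERAL_NOTE",
    "HETEROPLASMY_NOTE",
]

HOMOZYGOUS = "HOMOZYGOUS"
HETEROZYGOUS = "HETEROZYGOUS"

_NA_TEXT = (
    "Not able to provide breeding advice because inheritance pattern was not "
    "included in the input file"
)

_Y_LINKED_TEXT = (
    "The animal is male and can NOT be used for breeding purposes as every "
    "male offspring will inherit the defective Y chromosome"
)

_HOM_ADVICE: dict[InheritancePattern, str] = {
    InheritancePattern.AUTOSOMAL_DOMINANT: (
        "Animal can NOT be used for breeding purposes. Offspring would be "
        "carrier or homozygous and might develop symptoms"
    ),
    InheritancePattern.AUTOSOMAL_RECESSIVE: (
        "ONLY combine with wild type animal! Offspring will be carrier and, "
        "on its turn, can ONLY be combined with wild type animal ***"
    ),
    InheritancePattern.MITOCHONDRIAL: (
        "If animal is female: animal can NOT be used for breeding purposes. "
        "Mitochondria are inherited maternally"
    ),
    InheritancePattern.X_LINKED_DOMINANT: (
        "Do NOT use animal for breeding purposes because all offspring will "
        "inherit the defective X chromosome"
    ),
    InheritancePattern.X_LINKED_RECESSIVE: (
        "Do NOT use animal for breeding purposes as all male offspring will "
        "inherit the defective X chromosome and will thus be affected"
    ),
    InheritancePattern.Y_LINKED: _Y_LINKED_TEXT,
    InheritancePattern.UNKNOWN: _NA_TEXT,
}

_HET_ADVICE: dict[InheritancePattern, str] = {
    InheritancePattern.AUTOSOMAL_DOMINANT: (
        "Animal can NOT be used for breeding purposes"
    ),
    InheritancePattern.AUTOSOMAL_RECESSIVE: (
        "Animal can be used for breeding purposes but ONLY if combined with a "
        "wild type animal. Offspring will be ± 50% carrier and ± 50% "
        "wild type"
    ),
    InheritancePattern.MITOCHONDRIAL: (
        "If animal is female: animal can NOT be used for breeding purposes. "
        "Mitochondria are inherited maternally. If animal is male: animal can "
        "be used"
    ),
    InheritancePattern.X_LINKED_DOMINANT: (
        "If animal is female: do NOT use animal for breeding purposes because "
        "± 50% of the offspring will inherit the defective X chromosome\n"
        "If animal is male, only one X chromosome is present. Accordingly, "
        "affected animals can NOT be used for breeding purposes as all female "
        "offspring will be carrier and thus will be affected"
    ),
    InheritancePattern.X_LINKED_RECESSIVE: (
        "If animal is female: animal can NOT be used for breeding purposes as "
        "± 50% of male offspring will inherit the defective X chromosome "
        "and these male animals will develop symptoms\n"
        "If animal is male, only one X chromosome will be present. Affected "
        "animals can be used ONLY if combined with a wild type female animal. "
        "Female offspring will be carrier of the variant"
    ),
    InheritancePattern.Y_LINKED: _Y_LINKED_TEXT,
    InheritancePattern.UNKNOWN: _NA_TEXT,
}

HOMOZYGOUS_GENERAL_NOTE = (
    "***Important general side note: Do NOT use animal if this would harm the "
    "welfare of the animal itself, or the progeny. Furthermore, the animal "
    "must be capable of carrying out a healthy pregnancy"
)

HETEROPLASMY_NOTE = (
    "*Mitochondrial heteroplasmy is the situation in which more than one type "
    "of mtDNA is present within a cell. Levels of heteroplasmy can vary "
    "between cells and tissues of one individual and influence the threshold "
    "for disease phenotype"
)


def breeding_advice(inheritance: InheritancePattern, advice_class: str) -> str:
    """Return the verbatim advice text for one (inheritance, class) pair.

    ``advice_class`` is :data:`HOMOZYGOUS` or :data:`HETEROZYGOUS`. Total
    function — UNKNOWN inheritance yields the 'NA' text.
    """
    if advice_class == HOMOZYGOUS:
        return _HOM_ADVICE[inheritance]
    if advice_class == HETEROZYGOUS:
        return _HET_ADVICE[inheritance]
    raise ValueError(f"advice_class must be HOMOZYGOUS or HETEROZYGOUS, got {advice_class!r}")
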