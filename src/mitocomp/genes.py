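"""Canonical mitochondrial gene nomenclature and the ancestral insect gene order.

Animal mitogenomes carry 37 canonical genes: 13 protein-coding genes (PCGs),
22 tRNAs and 2 rRNAs, plus one long non-coding control region (CR).  GenBank
records name these genes inconsistently (``COI``/``COX1``/``cox1``,
``16S``/``rrnL`` ...); everything downstream of parsing works on the canonical
lower-case tokens defined here.

The two leucine and two serine tRNAs are distinguished by the codon family
they read: ``trnL1`` reads CUN, ``trnL2`` UUR, ``trnS1`` AGN, ``trnS2`` UCN.
When a record does not say which one it means, the anticodon settles it.
"""

from __future__ import annotations

import re

PCGS: tuple[str, ...] = (
    "atp6", "atp8", "cox1", "cox2", "cox3", "cytb",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)

TRNAS: tuple[str, ...] = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)

RRNAS: tuple[str, ...] = ("rrnL", "rrnS")

CR = "CR"
UNKNOWN = "?"

ALL_GENES: tuple[str, ...] = PCGS + TRNAS + RRNAS

KIND_OF: dict[str, str] = (
    {g: "PCG" for g in PCGS}
    | {g: "tRNA" for g in TRNAS}
    | {g: "rRNA" for g in RRNAS}
    | {CR: "CR"}
)

#: Ancestral insect mitochondrial gene order (Drosophila yakuba), signed:
#: +1 = majority (J) strand, -1 = minority (N) strand. CR sits between
#: rrnS and trnI on the circle.
YAKUBA_ORDER: tuple[tuple[str, int], ...] = (
    ("cox1", 1), ("trnL2", 1), ("cox2", 1), ("trnK", 1), ("trnD", 1),
    ("atp8", 1), ("atp6", 1), ("cox3", 1), ("trnG", 1), ("nad3", 1),
    ("trnA", 1), ("trnR", 1), ("trnN", 1), ("trnS1", 1), ("trnE", 1),
    ("trnF", -1), ("nad5", -1), ("trnH", -1), ("nad4", -1), ("nad4L", -1),
    ("trnT", 1), ("trnP", -1), ("nad6", 1), ("cytb", 1), ("trnS2", 1),
    ("nad1", -1), ("trnL1", -1), ("rrnL", -1), ("trnV", -1), ("rrnS", -1),
    (CR, 1),
    ("trnI", 1), ("trnQ", -1), ("trnM", 1), ("nad2", 1),
    ("trnW", 1), ("trnC", -1), ("trnY", -1),
)

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

# Codon-family tags appearing in qualifiers like "tRNA-Leu(UUR)".
_FAMILY_TAG = {
    "cun": "trnL1", "uur": "trnL2", "ttr": "trnL2",
    "agn": "trnS1", "ucn": "trnS2", "tcn": "trnS2",
}

# Anticodons (DNA or RNA alphabet, 5'->3') of the ambiguous tRNAs.
_ANTICODON = {
    "tag": "trnL1", "uag": "trnL1",
    "taa": "trnL2", "uaa": "trnL2",
    "tct": "trnS1", "ucu": "trnS1", "gct": "trnS1", "gcu": "trnS1",
    "tga": "trnS2", "uga": "trnS2",
}

_PCG_SYNONYMS = {
    "cox1": "cox1", "coi": "cox1", "co1": "cox1", "coxi": "cox1",
    "cox2": "cox2", "coii": "cox2", "co2": "cox2", "coxii": "cox2",
    "cox3": "cox3", "coiii": "cox3", "co3": "cox3", "coxiii": "cox3",
    "cytb": "cytb", "cob": "cytb", "cyb": "cytb", "cytochromeb": "cytb",
    "atp6": "atp6", "atpase6": "atp6",
    "atp8": "atp8", "atpase8": "atp8",
    "nad1": "nad1", "nd1": "nad1", "nadh1": "nad1",
    "nad2": "nad2", "nd2": "nad2", "nadh2": "nad2",
    "nad3": "nad3", "nd3": "nad3", "nadh3": "nad3",
    "nad4": "nad4", "nd4": "nad4", "nadh4": "nad4",
    "nad4l": "nad4L", "nd4l": "nad4L", "nadh4l": "nad4L",
    "nad5": "nad5", "nd5": "nad5", "nadh5": "nad5",
    "nad6": "nad6", "nd6": "nad6", "nadh6": "nad6",
}

_RRNA_SYNONYMS = {
    "rrnl": "rrnL", "16s": "rrnL", "lrrna": "rrnL", "lsu": "rrnL",
    "largesubunitribosomalrna": "rrnL", "16sribosomalrna": "rrnL",
    "rrns": "rrnS", "12s": "rrnS", "srrna": "rrnS", "ssu": "rrnS",
    "smallsubunitribosomalrna": "rrnS", "12sribosomalrna": "rrnS",
}

_CR_SYNONYMS = {"cr", "dloop", "controlregion", "atrichregion", "putativecontrolregion"}


def _squash(raw: str) -> str:
    return re.sub(r"[\s_\-.]+", "", raw.strip().lower())


def normalize_gene_name(raw: str, anticodon: str | None = None) -> str:
    """Map a raw GenBank gene/product label to its canonical token.

    Total function: any unrecognisable label maps to ``"?"``.  ``anticodon``
    (if supplied from a feature qualifier) disambiguates the leucine and
    serine tRNAs when the label itself does not.
    """
    if not raw:
        return UNKNOWN
    s = raw.strip().lower()

    # Explicit codon-family tag, e.g. "tRNA-Leu(UUR)", "trnL(CUN)".
    m = re.search(r"\(([acgutrny]{3})\)", s)
    family_hit = _FAMILY_TAG.get(m.group(1)) if m else None
    if family_hit:
        return family_hit

    squashed = _squash(re.sub(r"\([^)]*\)", "", s))

    if squashed in _PCG_SYNONYMS:
        return _PCG_SYNONYMS[squashed]
    if squashed in _RRNA_SYNONYMS:
        return _RRNA_SYNONYMS[squashed]
    if squashed in _CR_SYNONYMS:
        return CR

    # tRNA spellings: trnX, trnX1/trnX2, trnaX, "tRNA-Leu" (3-letter aa).
    m = re.fullmatch(r"trna?([a-z])([12])?", squashed)
    if m:
        letter, idx = m.group(1).upper(), m.group(2)
        if letter in {"L", "S"}:
            if idx:
                return f"trn{letter}{idx}"
            if anticodon:
                hit = _ANTICODON.get(anticodon.strip().lower())
                if hit and hit[3] == letter:
                    return hit
            return UNKNOWN
        name = f"trn{letter}"
        return name if name in TRNAS else UNKNOWN
    m = re.fullmatch(r"trna([a-z]{3})([12])?", squashed)
    if m and m.group(1) in _AA3_TO_1:
        letter, idx = _AA3_TO_1[m.group(1)], m.group(2)
        if letter in {"L", "S"}:
            if idx:
                return f"trn{letter}{idx}"
            if anticodon:
                hit = _ANTICODON.get(anticodon.strip().lower())
                if hit and hit[3] == letter:
                    return hit
            return UNKNOWN
        name = f"trn{letter}"
        return name if name in TRNAS else UNKNOWN

    return UNKNOWN
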