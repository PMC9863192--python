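"""Reading, writing and slicing annotated circular mitogenomes.

The in-memory model is :class:`MitogenomeRecord`: the majority (J) strand
sequence plus a coordinate-sorted list of typed, stranded
:class:`GeneFeature` entries.  Coordinates are 1-based inclusive (GenBank
convention); a feature crossing the replication origin is stored with
``wraps_origin=True`` rather than as a split location.

GenBank flat files are read and written through Biopython; the control
region is taken from an annotated D-loop feature when present, otherwise
inferred as the longest unannotated span of at least 200 bp (shorter gaps
are treated as intergenic spacers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .genes import CR, KIND_OF, UNKNOWN, normalize_gene_name

logger = logging.getLogger("mitocomp")

PARTITIONS = ("whole", "PCG", "tRNA", "rRNA", "CR")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Minimum unannotated span (bp) promoted to a control region.
CR_MIN_LENGTH = 200


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on the circular molecule.

    ``start``/``end`` are 1-based inclusive on the majority strand; for a
    feature with ``wraps_origin`` the interval runs start..length then
    1..end.  ``strand`` is '+' for the majority (J) strand, '-' for the
    minority (N) strand; the control region carries no strand.
    """

    canonical_name: str
    kind: str  # PCG | tRNA | rRNA | CR
    start: int
    end: int
    strand: str | None  # '+' | '-' | None (CR)
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.kind not in {"PCG", "tRNA", "rRNA", "CR"}:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind != "CR" and self.strand not in {"+", "-"}:
            raise ValueError(
                f"feature {self.canonical_name!r} of kind {self.kind} needs a strand"
            )

    def span(self, genome_length: int) -> int:
        if self.wraps_origin:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1


@dataclass
class MitogenomeRecord:
    """An annotated circular mitogenome (majority-strand sequence)."""

    id: str
    organism: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"{self.id}: ambiguity codes other than N are not supported: "
                f"{sorted(bad)}"
            )
        for f in self.features:
            if not (1 <= f.start <= self.length and 1 <= f.end <= self.length):
                raise ValueError(f"{self.id}: feature {f.canonical_name} out of range")
        self.features.sort(key=lambda f: f.start)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature_sequence(self, feature: GeneFeature) -> str:
        """Sequence of a feature 5'->3' on its own (coding) strand."""
        if feature.wraps_origin:
            raw = self.sequence[feature.start - 1:] + self.sequence[: feature.end]
        else:
            raw = self.sequence[feature.start - 1: feature.end]
        return revcomp(raw) if feature.strand == "-" else raw

    def features_of_kind(self, kind: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == kind]


def _feature_name(bio_feature) -> tuple[str, str | None]:
    q = bio_feature.qualifiers
    raw = (q.get("gene") or q.get("product") or q.get("note") or [""])[0]
    anticodon = None
    if "anticodon" in q:
        ac = q["anticodon"][0]
        # either a bare triplet or a full "(pos:..,aa:..,seq:tct)" clause
        if len(ac) == 3:
            anticodon = ac
        else:
            import re

            m = re.search(r"seq:([acgut]{3})", ac.lower())
            anticodon = m.group(1) if m else None
    return raw, anticodon


_KIND_BY_TYPE = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "CR"}


def read_genbank(path) -> MitogenomeRecord:
    """Parse one annotated mitogenome from a GenBank flat file.

    CDS/tRNA/rRNA/D-loop features are mapped to :class:`GeneFeature` with
    canonical names; a gene label that cannot be mapped is retained with
    ``canonical_name="?"`` and a logged warning.  If no D-loop is
    annotated, the longest unannotated span >= 200 bp becomes the CR.
    """
    rec = SeqIO.read(str(path), "genbank")
    seq = str(rec.seq).upper()
    if not seq:
        raise ValueError(f"{path}: GenBank record has no sequence block")

    features: list[GeneFeature] = []
    for bf in rec.features:
        kind = _KIND_BY_TYPE.get(bf.type)
        if kind is None:
            if bf.type not in {"source", "gene", "misc_feature"}:
                logger.warning("%s: skipping feature type %s", rec.id, bf.type)
            continue
        raw, anticodon = _feature_name(bf)
        if kind == "CR":
            name = CR
        else:
            name = normalize_gene_name(raw, anticodon=anticodon)
            if name is UNKNOWN or name == UNKNOWN:
                logger.warning("%s: unmappable gene name %r (kept as '?')", rec.id, raw)
            elif KIND_OF[name] != kind:
                logger.warning(
                    "%s: %r annotated as %s but canonical kind is %s; keeping '?'",
                    rec.id, raw, kind, KIND_OF[name],
                )
                name = UNKNOWN

        loc = bf.location
        wraps = False
        if isinstance(loc, CompoundLocation) and len(loc.parts) == 2:
            p1, p2 = loc.parts
            if int(p1.end) == len(seq) and int(p2.start) == 0:
                start, end, wraps = int(p1.start) + 1, int(p2.end), True
            else:
                start, end = int(loc.start) + 1, int(loc.end)
        else:
            start, end = int(loc.start) + 1, int(loc.end)
        strand = None if kind == "CR" else ("-" if loc.strand == -1 else "+")
        features.append(
            GeneFeature(name, kind, start, end, strand, wraps_origin=wraps)
        )

    record = MitogenomeRecord(
        id=rec.id or rec.name,
        organism=rec.annotations.get("organism", ""),
        sequence=seq,
        features=features,
    )
    if not record.features_of_kind("CR"):
        cr = infer_control_region(record)
        if cr is not None:
            record.features.append(cr)
            record.features.sort(key=lambda f: f.start)
    return record


def infer_control_region(
    record: MitogenomeRecord, min_length: int = CR_MIN_LENGTH
) -> GeneFeature | None:
    """Longest unannotated circular span >= ``min_length`` bp, as a CR feature."""
    n = record.length
    covered = [False] * n
    for f in record.features:
        if f.wraps_origin:
            idx = list(range(f.start - 1, n)) + list(range(0, f.end))
        else:
            idx = range(f.start - 1, f.end)
        for i in idx:
            covered[i] = True
    if all(covered):
        return None
    if not any(covered):
        return GeneFeature(CR, "CR", 1, n, None)
    # rotate so position 0 is covered, then scan linear runs of uncovered bases
    anchor = covered.index(True)
    rotated = covered[anchor:] + covered[:anchor]
    best: tuple[int, int] | None = None  # (length, start0 in original coords)
    i = 0
    while i < n:
        if not rotated[i]:
            j = i
            while j < n and not rotated[j]:
                j += 1
            glen = j - i
            if best is None or glen > best[0]:
                best = (glen, (i + anchor) % n)
            i = j
        else:
            i += 1
    if best is None or best[0] < min_length:
        return None
    glen, g0 = best
    start, end = g0 + 1, (g0 + glen - 1) % n + 1
    return GeneFeature(CR, "CR", start, end, None, wraps_origin=end < start)


def extract_partition(record: MitogenomeRecord, kind: str) -> list[tuple[str, str]]:
    """(name, sequence) pairs for one partition, 5'->3' on each coding strand.

    ``kind="whole"`` returns the full majority strand unmodified.  An empty
    partition yields an empty list.
    """
    if kind not in PARTITIONS:
        raise ValueError(f"unknown partition {kind!r}; expected one of {PARTITIONS}")
    if kind == "whole":
        return [(record.id, record.sequence)]
    return [
        (f.canonical_name, record.feature_sequence(f))
        for f in record.features_of_kind(kind)
    ]


def write_genbank(record: MitogenomeRecord, path) -> None:
    """Write a MitogenomeRecord as a GenBank flat file (round-trip safe)."""
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id.replace(".", "_")[:16],
        description=f"{record.organism} mitochondrion, complete genome",
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular"
    rec.annotations["organism"] = record.organism
    rec.annotations["date"] = "01-JAN-2000"  # fixed for byte-stable output

    type_of = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D-loop"}
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps_origin:
            loc = CompoundLocation(
                [
                    SimpleLocation(f.start - 1, record.length, strand),
                    SimpleLocation(0, f.end, strand),
                ]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        quals: dict[str, list[str]] = {"gene": [f.canonical_name]}
        if f.kind == "PCG":
            quals["transl_table"] = ["5"]
        elif f.kind == "CR":
            quals = {"note": ["control region"]}
        rec.features.append(SeqFeature(loc, type=type_of[f.kind], qualifiers=quals))
    SeqIO.write(rec, str(path), "genbank")


def export_fasta(entries: list[tuple[str, str]], path) -> None:
    """Write (name, sequence) pairs as multi-FASTA, 70-column wrapped.

    Names are written verbatim; note that round-tripping through strict
    FASTA parsers keeps only the first whitespace-delimited token as the id
    (the remainder survives in the description).
    """
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read multi-FASTA back as (description, sequence) pairs."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.description, str(rec.seq).upper()))
    return out


def with_features(record: MitogenomeRecord, features: list[GeneFeature]) -> MitogenomeRecord:
    """Copy of ``record`` with a replaced feature list (re-sorted, re-validated)."""
    return MitogenomeRecord(record.id, record.organism, record.sequence, list(features))


__all__ = [
    "GeneFeature",
    "MitogenomeRecord",
    "read_genbank",
    "write_genbank",
    "extract_partition",
    "export_fasta",
    "read_fasta",
    "infer_control_region",
    "normalize_gene_name",
    "revcomp",
    "PARTITIONS",
]
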