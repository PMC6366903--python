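"""Reference data model: genome, ORF coordinates, codon translation, gene sets.

All genomic coordinates in this package are 1-based and inclusive at both
ends, following the GFF3/VCF convention; this is the single place where that
convention is stated, and every other module inherits it.

The only codon table supported is the standard nuclear genetic code (budding
yeast nuclear genes); the mitochondrial code is deliberately out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "STOP",
    "VALID_BASES",
    "CodonTable",
    "Genome",
    "GeneSetCollection",
    "Orf",
    "load_gene_sets",
    "load_genome",
    "load_orfs",
    "reverse_complement",
    "translate",
    "write_gene_sets",
    "write_genome",
    "write_orfs",
]

VALID_BASES = frozenset("ACGTN")
STOP = "*"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


# Standard nuclear code in TCAG order (first base slowest).
_CODON_BASES = "TCAG"
_CODON_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"


def _standard_code() -> dict[str, str]:
    table = {}
    i = 0
    for b1 in _CODON_BASES:
        for b2 in _CODON_BASES:
            for b3 in _CODON_BASES:
                table[b1 + b2 + b3] = _CODON_AAS[i]
                i += 1
    return table


@dataclass(frozen=True)
class CodonTable:
    """Codon → amino-acid mapping; stop codons map to ``"*"``.

    Exactly 61 sense codons and 3 stop codons (standard nuclear code).
    """

    forward: Mapping[str, str] = field(default_factory=_standard_code)

    def __post_init__(self) -> None:
        if len(self.forward) != 64:
            raise ValueError(f"codon table has {len(self.forward)} entries, expected 64")
        n_stop = sum(1 for aa in self.forward.values() if aa == STOP)
        if n_stop != 3:
            raise ValueError(f"codon table has {n_stop} stop codons, expected 3")

    @classmethod
    def standard(cls) -> "CodonTable":
        return cls()

    def translate_codon(self, codon: str) -> str:
        """Amino acid for one codon; any N yields 'X' (unannotatable)."""
        codon = codon.upper()
        if len(codon) != 3:
            raise ValueError(f"codon {codon!r} is not 3 bases")
        if "N" in codon:
            return "X"
        try:
            return self.forward[codon]
        except KeyError:
            raise ValueError(f"invalid codon {codon!r}") from None

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.forward.items() if aa == STOP)


def translate(coding_sequence: str, table: CodonTable | None = None) -> tuple[str, bool]:
    """Translate a coding sequence up to (excluding) the first stop codon.

    Returns ``(protein, stop_seen)``.  Length must be a multiple of 3; a codon
    containing N translates to 'X'.
    """
    if table is None:
        table = CodonTable.standard()
    seq = coding_sequence.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"coding sequence length {len(seq)} is not a multiple of 3")
    aas: list[str] = []
    for i in range(0, len(seq), 3):
        aa = table.translate_codon(seq[i : i + 3])
        if aa == STOP:
            return "".join(aas), True
        aas.append(aa)
    return "".join(aas), False


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


@dataclass
class Genome:
    """Reference genome: contig name → uppercase DNA sequence (A/C/G/T/N)."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("genome has no contigs")
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            bad = set(seq) - VALID_BASES
            if bad:
                pos = next(i for i, b in enumerate(seq, start=1) if b in bad)
                raise ValueError(
                    f"contig {name!r} contains invalid base {seq[pos - 1]!r} at position {pos}"
                )

    def base(self, contig: str, pos: int) -> str:
        """Base at a 1-based position."""
        seq = self.contigs[contig]
        if not 1 <= pos <= len(seq):
            raise IndexError(f"position {pos} outside contig {contig!r} (length {len(seq)})")
        return seq[pos - 1]

    def slice(self, contig: str, start: int, end: int) -> str:
        """Sequence for the 1-based inclusive interval [start, end]."""
        seq = self.contigs[contig]
        if not (1 <= start <= end <= len(seq)):
            raise IndexError(f"[{start}, {end}] outside contig {contig!r} (length {len(seq)})")
        return seq[start - 1 : end]


def load_genome(path: str | Path) -> Genome:
    """Load a FASTA file into a :class:`Genome`, uppercasing sequences."""
    path = Path(path)
    contigs: dict[str, str] = {}
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    for rec in records:
        if rec.id in contigs:
            raise ValueError(f"{path}: duplicate contig name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: contig {rec.id!r} is empty")
        bad = set(seq) - VALID_BASES
        if bad:
            pos = next(i for i, b in enumerate(seq, start=1) if b in bad)
            raise ValueError(
                f"{path}: contig {rec.id!r} has invalid base {seq[pos - 1]!r} at position {pos}"
            )
        contigs[rec.id] = seq
    return Genome(contigs)


def write_genome(genome: Genome, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# ORFs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Orf:
    """A single intronless ORF: start codon through stop codon inclusive."""

    gene_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def protein_length(self) -> int:
        """Number of amino acids in the encoded protein (stop codon excluded)."""
        return self.length // 3 - 1

    def coding_sequence(self, genome: Genome) -> str:
        """Coding-strand sequence (reverse-complemented for minus strand)."""
        seq = genome.slice(self.contig, self.start, self.end)
        return reverse_complement(seq) if self.strand == "-" else seq

    def validate(self, genome: Genome, table: CodonTable | None = None) -> None:
        """Check ORF invariants against the genome; raise ValueError naming the failure."""
        if table is None:
            table = CodonTable.standard()
        if self.contig not in genome.contigs:
            raise ValueError(f"{self.gene_id}: contig {self.contig!r} not in genome")
        if self.end > len(genome.contigs[self.contig]):
            raise ValueError(f"{self.gene_id}: end {self.end} beyond contig bounds")
        if self.length % 3 != 0:
            raise ValueError(f"{self.gene_id}: length {self.length} not multiple of 3")
        cds = self.coding_sequence(genome)
        if not cds.startswith("ATG"):
            raise ValueError(f"{self.gene_id}: coding sequence does not begin with ATG")
        if table.translate_codon(cds[-3:]) != STOP:
            raise ValueError(f"{self.gene_id}: coding sequence does not end with a stop codon")
        protein, stop_seen = translate(cds, table)
        if not stop_seen or len(protein) != self.protein_length:
            raise ValueError(
                f"{self.gene_id}: internal stop codon at residue {len(protein) + 1}"
            )


def load_orfs(path: str | Path, genome: Genome, table: CodonTable | None = None) -> list[Orf]:
    """Load ORFs from a GFF3 subset (gene/CDS features with ID attributes).

    Every ORF is validated against the genome (ATG start, stop end, length
    divisible by 3, no internal stops; minus-strand ORFs on the reverse
    complement).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    seen: dict[str, Orf] = {}
    orfs: list[Orf] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in ("gene", "CDS"):
            continue
        ids = feat.attributes.get("ID") or feat.attributes.get("Parent")
        if not ids:
            raise ValueError(f"{path}: feature at {feat.seqid}:{feat.start} has no ID attribute")
        gene_id = ids[0]
        orf = Orf(gene_id=gene_id, contig=feat.seqid, start=feat.start, end=feat.end,
                  strand=feat.strand)
        if gene_id in seen:
            if seen[gene_id] != orf:
                raise ValueError(f"{path}: conflicting records for gene {gene_id!r}")
            continue
        seen[gene_id] = orf
        orfs.append(orf)
    for orf in orfs:
        orf.validate(genome, table)
    return orfs


def write_orfs(orfs: Iterable[Orf], path: str | Path,
               header_comments: Iterable[str] = ()) -> None:
    """Write ORFs as GFF3 `gene` features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header_comments:
            fh.write(f"# {line}\n")
        for orf in orfs:
            attrs = f"ID={orf.gene_id};Name={orf.gene_id}"
            fh.write(
                f"{orf.contig}\tsuppscreen\tgene\t{orf.start}\t{orf.end}\t.\t{orf.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets used for pathway triage (GMT semantics).

    Sets may overlap; member genes need not all exist in the gene model (the
    check is a warning, not an error, since gene sets are usually defined on
    the full genome annotation).
    """

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def validate_against(self, orfs: Iterable[Orf]) -> list[str]:
        """Warn about (and return) set members absent from the gene model."""
        known = {orf.gene_id for orf in orfs}
        missing = sorted(g for members in self.sets.values() for g in members if g not in known)
        if missing:
            warnings.warn(
                f"{len(missing)} gene-set member(s) not in the gene model: "
                + ", ".join(missing[:10]) + ("..." if len(missing) > 10 else ""),
                stacklevel=2,
            )
        return missing


def load_gene_sets(path: str | Path) -> GeneSetCollection:
    """Load a GMT file (set name, description, tab-separated gene ids).

    Duplicate gene ids within a set are deduplicated; an empty set or a
    duplicate set name is an error.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = members
            descriptions[name] = desc
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
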