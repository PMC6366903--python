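"""Variant-effect annotation against the ORF model.

A single-nucleotide variant inside an ORF is mapped, strand-aware, into its
codon; the reference and mutated codons are translated and compared:

* same amino acid                      → ``synonymous``
* mutated codon is a stop codon        → ``nonsense`` (stop-gain)
* reference codon is a stop, alt not   → ``stop_loss``
* codon 1 and the alt is not Met       → ``start_loss``
* anything else                        → ``missense``
* any N in either codon                → ``unannotatable``

Protein changes are labelled in the screen's allele-naming style, e.g.
``Q102STOP`` or ``H235A`` (reference amino acid, 1-based codon index, then
``STOP`` or the alternate amino acid) — not HGVS.

For a stop-gain, ``truncation_length`` counts the residues strictly
C-terminal to the stop position: ``protein_length − stop_codon_index``.  A
stop gained at codon 456 of a 796-residue protein therefore removes the last
340 amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .refmodel import STOP, CodonTable, Genome, Orf, reverse_complement

__all__ = [
    "EFFECT_SEVERITY",
    "NONSILENT_EFFECTS",
    "AnnotatedVariant",
    "OrfIndex",
    "annotate",
    "annotate_calls",
    "nonsilent_filter",
    "primary_effect",
    "truncation_length",
]

NONSILENT_EFFECTS = frozenset({"missense", "nonsense", "stop_loss", "start_loss"})

# most severe first; used to pick the primary annotation for overlapping ORFs
EFFECT_SEVERITY = [
    "nonsense",
    "start_loss",
    "stop_loss",
    "missense",
    "synonymous",
    "unannotatable",
    "intergenic",
]
_SEVERITY_RANK = {e: i for i, e in enumerate(EFFECT_SEVERITY)}


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant call plus its protein-level consequence in one ORF."""

    contig: str
    pos: int
    ref: str
    alt: str
    effect: str
    gene_id: str | None = None
    codon_index: int | None = None  # 1-based; protein_length + 1 for the stop codon
    aa_ref: str | None = None
    aa_alt: str | None = None
    protein_change: str | None = None
    truncation_length: int | None = None  # nonsense only


def truncation_length(stop_codon_index: int, protein_length: int) -> int:
    """Residues lost C-terminal to a premature stop (exclusive of the stop site).

    ``truncation_length(456, 796) == 340``.
    """
    if not 1 <= stop_codon_index <= protein_length:
        raise ValueError(
            f"stop codon index {stop_codon_index} outside [1, {protein_length}]"
        )
    return protein_length - stop_codon_index


class OrfIndex:
    """Interval index over ORFs for fast overlap lookup."""

    def __init__(self, orfs: Iterable[Orf]):
        self._trees: dict[str, IntervalTree] = {}
        for orf in orfs:
            tree = self._trees.setdefault(orf.contig, IntervalTree())
            # intervaltree is half-open; ORF coordinates are inclusive
            tree.addi(orf.start, orf.end + 1, orf)

    def overlapping(self, contig: str, pos: int) -> list[Orf]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(pos)), key=lambda o: o.gene_id)


def _annotate_in_orf(contig: str, pos: int, ref: str, alt: str, orf: Orf,
                     genome: Genome, table: CodonTable) -> AnnotatedVariant:
    if orf.strand == "+":
        offset = pos - orf.start
        coding_alt = alt
    else:
        offset = orf.end - pos
        coding_alt = reverse_complement(alt)
    codon_i = offset // 3  # 0-based codon
    within = offset % 3
    codon_start = codon_i * 3
    cds = orf.coding_sequence(genome)
    if codon_start + 3 > len(cds):
        raise ValueError(
            f"{orf.gene_id}: codon arithmetic inconsistent at {contig}:{pos} "
            "(ORF model corruption)"
        )
    ref_codon = cds[codon_start : codon_start + 3]
    if ref_codon[within] != (ref if orf.strand == "+" else reverse_complement(ref)):
        raise ValueError(
            f"{orf.gene_id}: reference base mismatch at {contig}:{pos} "
            f"(genome says {ref_codon[within]!r} in coding frame)"
        )
    alt_codon = ref_codon[:within] + coding_alt + ref_codon[within + 1 :]
    aa_ref = table.translate_codon(ref_codon)
    aa_alt = table.translate_codon(alt_codon)
    codon_index = codon_i + 1
    trunc: int | None = None

    if "X" in (aa_ref, aa_alt):
        effect = "unannotatable"
    elif aa_ref == aa_alt:
        effect = "synonymous"
    elif aa_alt == STOP:
        effect = "nonsense"
        trunc = truncation_length(codon_index, orf.protein_length)
    elif aa_ref == STOP:
        effect = "stop_loss"
    elif codon_index == 1 and aa_alt != "M":
        effect = "start_loss"
    else:
        effect = "missense"

    aa_alt_label = "STOP" if aa_alt == STOP else aa_alt
    aa_ref_label = "STOP" if aa_ref == STOP else aa_ref
    change = f"{aa_ref_label}{codon_index}{aa_alt_label}"
    return AnnotatedVariant(
        contig=contig, pos=pos, ref=ref, alt=alt, effect=effect,
        gene_id=orf.gene_id, codon_index=codon_index,
        aa_ref=aa_ref, aa_alt=aa_alt, protein_change=change,
        truncation_length=trunc,
    )


def annotate(contig: str, pos: int, ref: str, alt: str, genome: Genome,
             orfs: Sequence[Orf] | OrfIndex,
             table: CodonTable | None = None) -> list[AnnotatedVariant]:
    """Annotate one SNV: one record per overlapping ORF, or a single
    ``intergenic`` record if no ORF overlaps."""
    if table is None:
        table = CodonTable.standard()
    if genome.base(contig, pos) != ref:
        raise ValueError(
            f"reference mismatch at {contig}:{pos}: call says {ref!r}, "
            f"genome has {genome.base(contig, pos)!r}"
        )
    index = orfs if isinstance(orfs, OrfIndex) else OrfIndex(orfs)
    hits = index.overlapping(contig, pos)
    if not hits:
        return [AnnotatedVariant(contig=contig, pos=pos, ref=ref, alt=alt,
                                 effect="intergenic")]
    return [_annotate_in_orf(contig, pos, ref, alt, orf, genome, table) for orf in hits]


def primary_effect(annotations: Sequence[AnnotatedVariant]) -> AnnotatedVariant:
    """Most severe annotation among overlapping-ORF records (ties by gene_id)."""
    return min(annotations, key=lambda a: (_SEVERITY_RANK[a.effect], a.gene_id or ""))


_ANN_FIELDS = ["effect", "gene_id", "codon_index", "aa_ref", "aa_alt",
               "protein_change", "truncation_length"]


def annotate_calls(calls: pd.DataFrame, genome: Genome,
                   orfs: Sequence[Orf] | OrfIndex,
                   table: CodonTable | None = None,
                   primary_only: bool = False) -> pd.DataFrame:
    """Annotate a call table (one output row per call × overlapping ORF).

    Input columns must include contig, pos, ref, alt; all other columns
    (sample, af, filter, ...) are carried through.
    """
    if table is None:
        table = CodonTable.standard()
    index = orfs if isinstance(orfs, OrfIndex) else OrfIndex(orfs)
    rows = []
    for rec in calls.itertuples(index=True):
        anns = annotate(rec.contig, int(rec.pos), rec.ref, rec.alt, genome, index, table)
        if primary_only:
            anns = [primary_effect(anns)]
        for a in anns:
            rows.append((rec.Index, a))
    if not rows:
        return calls.iloc[0:0].assign(**{f: pd.Series(dtype=object) for f in _ANN_FIELDS})
    idx = [i for i, _ in rows]
    ann_df = pd.DataFrame(
        [{f: getattr(a, f) for f in _ANN_FIELDS} for _, a in rows]
    )
    out = calls.loc[idx].reset_index(drop=True)
    out = pd.concat([out, ann_df], axis=1)
    return out


def nonsilent_filter(annotated: pd.DataFrame, min_af: float = 0.7) -> pd.DataFrame:
    """Prioritization filter: nonsilent effect AND AF ≥ min_af (inclusive).

    Nonsilent means missense, nonsense, stop_loss or start_loss — the
    screen's "nonsynonymous" class plainly keeps stop-gains, since its top
    hits are nonsense alleles.  The default 0.7 is the stringent screen
    cutoff; 0.4 is the relaxed pathway-assignment cutoff.
    """
    keep = annotated["effect"].isin(NONSILENT_EFFECTS) & (annotated["af"] >= min_af)
    return annotated[keep].reset_index(drop=True)
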