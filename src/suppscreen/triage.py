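"""Cross-strain synthesis: recurrence tallies, prioritization, pathway assignment.

This is the step that turns per-strain variant lists into candidate genes
and pathways.  Two allele-frequency tiers are used: the stringent 0.7 filter
defines each strain's prioritized mutations and the recurrence table; the
relaxed 0.4 filter feeds pathway assignment, where a strain is assigned to
the first category (fixed order Rph1 → Rpd3L → chromatin silencing →
mRNA decay → hyperresistance) containing a gene hit by one of its nonsilent
variants.  Hyperresistance is a growth phenotype, never inferred from
sequence: it enters only via an externally supplied strain list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .effect import NONSILENT_EFFECTS, nonsilent_filter
from .refmodel import GeneSetCollection

__all__ = [
    "CATEGORY_ORDER",
    "RecurrenceTable",
    "StrainReport",
    "TriageConfig",
    "assign_pathway",
    "build_recurrence",
    "summarize_screen",
    "triage_screen",
]

CATEGORY_ORDER = ("rph1", "rpd3l", "chromatin_silencing", "mrna_decay",
                  "hyperresistance")
UNASSIGNED = "unassigned"


@dataclass
class TriageConfig:
    """Tiered AF cutoffs, pathway sets, and ranking depth for triage."""

    gene_sets: GeneSetCollection
    strict_af: float = 0.7
    relaxed_af: float = 0.4
    recurrence_top_k: int = 10
    category_order: Sequence[str] = CATEGORY_ORDER
    hyperresistant_strains: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0 < self.relaxed_af <= self.strict_af <= 1:
            raise ValueError("need 0 < relaxed_af <= strict_af <= 1")
        for cat in self.category_order:
            if cat != "hyperresistance" and cat not in self.gene_sets:
                raise ValueError(f"category {cat!r} has no gene set")


@dataclass
class StrainReport:
    """Per-strain triage outcome."""

    sample: str
    prioritized: pd.DataFrame  # strict-filter nonsilent variants
    candidates: pd.DataFrame  # relaxed-filter nonsilent variants
    assigned: str = UNASSIGNED
    evidence: pd.DataFrame | None = None  # variants supporting the assignment
    fails_strict: bool = False  # assignment evidence below the strict AF tier


class RecurrenceTable:
    """Per-gene strain counts for nonsilent / missense / nonsense hits.

    Counts are of strains, not variants: a strain with two hits in a gene
    contributes once.  Ranking is by strains-with-a-nonsilent-hit descending,
    ties broken lexicographically by gene id.
    """

    def __init__(self, table: pd.DataFrame):
        self.table = table

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.table.head(k)

    def __len__(self) -> int:
        return len(self.table)


def build_recurrence(annotated: pd.DataFrame) -> RecurrenceTable:
    """Tally, per gene, how many strains carry nonsilent / missense / nonsense hits.

    Input: annotated, strict-filtered variants with ``sample``, ``gene_id``
    and ``effect`` columns.
    """
    hits = annotated[annotated["effect"].isin(NONSILENT_EFFECTS)
                     & annotated["gene_id"].notna() & (annotated["gene_id"] != "")]
    if hits.empty:
        empty = pd.DataFrame(columns=["gene_id", "n_strains_nonsilent",
                                      "n_strains_missense", "n_strains_nonsense",
                                      "strains"])
        return RecurrenceTable(empty)

    def strain_count(df: pd.DataFrame) -> pd.Series:
        return df.groupby("gene_id", observed=True)["sample"].nunique()

    nonsilent = strain_count(hits)
    missense = strain_count(hits[hits["effect"] == "missense"])
    nonsense = strain_count(hits[hits["effect"] == "nonsense"])
    strains = hits.groupby("gene_id", observed=True)["sample"].apply(
        lambda s: ",".join(sorted(set(s))))
    table = pd.DataFrame({
        "n_strains_nonsilent": nonsilent,
        "n_strains_missense": missense.reindex(nonsilent.index, fill_value=0),
        "n_strains_nonsense": nonsense.reindex(nonsilent.index, fill_value=0),
        "strains": strains,
    }).fillna({"n_strains_missense": 0, "n_strains_nonsense": 0})
    table = table.astype({"n_strains_missense": int, "n_strains_nonsense": int})
    table = table.reset_index().sort_values(
        ["n_strains_nonsilent", "gene_id"], ascending=[False, True],
        kind="mergesort").reset_index(drop=True)
    return RecurrenceTable(table)


def assign_pathway(sample: str, annotated_sample: pd.DataFrame,
                   config: TriageConfig) -> StrainReport:
    """Assign one strain to the first matching category in the fixed order.

    ``annotated_sample`` holds the strain's annotated pass-set variants.  A
    category matches when a relaxed-filter (AF ≥ relaxed_af) nonsilent
    variant hits one of its member genes; hyperresistance matches when the
    strain is on the externally supplied phenotype list.  All matching
    variants are retained as evidence.
    """
    strict = nonsilent_filter(annotated_sample, config.strict_af)
    relaxed = nonsilent_filter(annotated_sample, config.relaxed_af)
    report = StrainReport(sample=sample, prioritized=strict, candidates=relaxed)
    for cat in config.category_order:
        if cat == "hyperresistance":
            if sample in config.hyperresistant_strains:
                report.assigned = cat
                report.evidence = relaxed.iloc[0:0]
                return report
            continue
        if cat not in config.gene_sets:
            raise ValueError(f"unknown category {cat!r} in config")
        members = config.gene_sets[cat]
        hit = relaxed[relaxed["gene_id"].isin(members)]
        if not hit.empty:
            report.assigned = cat
            report.evidence = hit.reset_index(drop=True)
            report.fails_strict = bool((hit["af"] < config.strict_af).all())
            return report
    return report


def triage_screen(annotated: pd.DataFrame, config: TriageConfig,
                  samples: Iterable[str] | None = None) -> list[StrainReport]:
    """Run pathway assignment for every strain in an annotated call table."""
    if samples is None:
        samples = sorted(annotated["sample"].unique())
    reports = []
    for sample in samples:
        sub = annotated[annotated["sample"] == sample]
        reports.append(assign_pathway(sample, sub, config))
    return reports


def summarize_screen(reports: Sequence[StrainReport]) -> dict:
    """Screen-level totals: category counts, fraction assigned, nonsense count,
    mean nonsilent mutations per strain (strict tier)."""
    n = len(reports)
    by_cat: dict[str, int] = {}
    for r in reports:
        by_cat[r.assigned] = by_cat.get(r.assigned, 0) + 1
    n_assigned = sum(c for cat, c in by_cat.items() if cat != UNASSIGNED)
    n_nonsense = sum(int((r.prioritized["effect"] == "nonsense").sum()) for r in reports)
    mean_nonsilent = (sum(len(r.prioritized) for r in reports) / n) if n else 0.0
    return {
        "n_strains": n,
        "n_assigned": n_assigned,
        "fraction_assigned": (n_assigned / n) if n else 0.0,
        "category_counts": by_cat,
        "n_nonsense_mutations": n_nonsense,
        "mean_nonsilent_per_strain": mean_nonsilent,
    }


def summary_table(reports: Sequence[StrainReport]) -> pd.DataFrame:
    """Per-strain one-row summary suitable for a TSV report."""
    rows = []
    for r in reports:
        ev = ""
        if r.evidence is not None and not r.evidence.empty:
            first = r.evidence.iloc[0]
            ev = f"{first['gene_id']}:{first['protein_change']}"
        rows.append({
            "sample": r.sample,
            "assigned": r.assigned,
            "evidence": ev,
            "fails_strict": r.fails_strict,
            "n_prioritized": len(r.prioritized),
            "n_candidates": len(r.candidates),
        })
    return pd.DataFrame(rows)
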