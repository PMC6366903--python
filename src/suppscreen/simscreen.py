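"""Synthetic suppressor-screen generator.

Emulates the statistical structure of a whole-genome-sequenced haploid
suppressor screen so every downstream stage is testable without real data:

* a compressed toy genome (~0.5 Mb, one contig) densely packed with valid
  ORFs, a small subset of which belong to named pathway gene sets
  (Rpd3L-expanded, chromatin silencing, nonsense-mediated mRNA decay);
* per strain, exactly one planted causal stop-gain in a gene drawn from a
  configurable category distribution, a Poisson(λ=14) number of background
  nonsilent coding mutations, a Poisson number of background synonymous
  mutations, and ancestral variants shared with the parental controls;
* per-site, per-sample base counts at ~200× negative-binomial coverage with
  post-quality-filter sequencing error (1e-3 per base) and occasional
  injected multiallelic noise sites.  True allele fractions for the clonal
  haploid variants follow Beta(49, 1) (mean 0.98), representing residual
  mapping noise around AF = 1.

Emission is sparse: only (site, sample) cells with non-reference evidence
are emitted, plus every sample at every truth site; absent cells mean
homozygous reference.  Truth-variant positions are drawn without replacement
genome-wide so that coincidental inter-strain site collisions match
genome-scale, not toy-scale, statistics (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .refmodel import (
    CodonTable,
    GeneSetCollection,
    Genome,
    Orf,
    STOP,
    reverse_complement,
    write_gene_sets,
    write_genome,
    write_orfs,
)
from .sitecounts import BASES, COUNT_COLUMNS, BaseCountMatrix, GroupDesign

__all__ = [
    "CATEGORY_GENES",
    "ScreenFixture",
    "SimConfig",
    "TruthTable",
    "simulate_counts",
    "simulate_genome",
    "simulate_screen",
    "simulate_strains",
]

_BASE_CODE = {b: i for i, b in enumerate(BASES)}
_CODE_BASE = np.array(list(BASES))

# Pathway rosters for the toy gene model.  Rpd3L-expanded and the GO-derived
# silencing / NMD sets mirror the screen's triage categories; everything else
# is an anonymous "other" gene.
CATEGORY_GENES: dict[str, tuple[str, ...]] = {
    "rph1": ("RPH1",),
    "rpd3l": ("RPD3", "SIN3", "SDS3", "SAP30", "RXT1", "RXT2", "RXT3",
              "PHO23", "UME1", "UME6", "DEP1", "CTI6"),
    "chromatin_silencing": ("SIR1", "SIR2", "SIR3", "SIR4", "ESC1", "SUM1",
                            "RIF1", "YKU70"),
    "mrna_decay": ("NMD2", "UPF3", "XRN1", "DCP2"),
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic screen.

    Defaults reproduce the screen's stated conditions: 95 suppressor strains
    sequenced against 2 parental controls at ~200× mean coverage, an average
    of 14 background nonsilent coding mutations per strain, and post-Q30
    error of 1e-3 per base.  ``seed`` is mandatory for reproducibility.
    """

    seed: int
    n_suppressor_strains: int = 95
    n_control_samples: int = 2
    background_nonsilent_mean: float = 14.0
    background_silent_mean: float = 10.0
    ancestral_variant_count: int = 50
    causal_category_probs: dict[str, float] = field(default_factory=lambda: {
        "rph1": 0.15, "rpd3l": 0.30, "chromatin_silencing": 0.10,
        "mrna_decay": 0.10, "other": 0.35,
    })
    coverage_mean: float = 200.0
    coverage_dispersion: float = 10.0  # negative-binomial size parameter r
    error_rate: float = 1e-3  # post-Q30 per-base substitution rate
    af_beta_a: float = 49.0  # clonal haploid allele-fraction Beta(a, b); mean 0.98
    af_beta_b: float = 1.0
    multiallelic_noise_rate: float = 1e-5  # per genome base
    genome_length: int = 540_000
    n_other_genes: int = 1500
    include_pathway_genes: bool = True
    other_orf_codons: int = 100  # incl. start and stop codons
    pathway_orf_codons: int = 30
    min_intergenic_gap: int = 10
    max_intergenic_gap: int = 50
    contig_name: str = "chr1"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("background_nonsilent_mean", "background_silent_mean",
                     "coverage_mean", "coverage_dispersion", "error_rate",
                     "multiallelic_noise_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        psum = sum(self.causal_category_probs.values())
        if psum > 1 + 1e-9 or any(p < 0 for p in self.causal_category_probs.values()):
            raise ValueError("causal_category_probs must be >= 0 and sum to <= 1")
        unknown = set(self.causal_category_probs) - (set(CATEGORY_GENES) | {"other"})
        if unknown:
            raise ValueError(f"unknown causal categories: {sorted(unknown)}")
        if self.n_control_samples < 1:
            raise ValueError("need at least one control sample")
        for name in ("other_orf_codons", "pathway_orf_codons"):
            if getattr(self, name) < 3:
                raise ValueError(f"{name} must be >= 3 (start, one sense, stop)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class TruthTable:
    """Ground truth for a simulated screen (the acceptance oracle).

    ``variants`` has one row per planted variant: sample ("all" for ancestral
    variants shared by every sample), contig, pos, ref, alt, role
    (causal / background_nonsilent / background_silent / ancestral), true
    allele fraction, gene_id (empty outside ORFs) and, for causal rows, the
    planted pathway category.  ``strains`` maps each strain to its causal
    gene and category.
    """

    variants: pd.DataFrame
    strains: pd.DataFrame

    ANCESTRAL_SAMPLE = "all"

    def __post_init__(self) -> None:
        causal = self.variants[self.variants["role"] == "causal"]
        per_strain = causal.groupby("sample").size()
        strains = set(self.strains["sample"])
        if set(per_strain.index) != strains or (per_strain != 1).any():
            raise ValueError("truth table must have exactly one causal record per strain")

    def for_sample(self, sample: str) -> pd.DataFrame:
        v = self.variants
        return v[(v["sample"] == sample) | (v["sample"] == self.ANCESTRAL_SAMPLE)]

    @property
    def ancestral(self) -> pd.DataFrame:
        return self.variants[self.variants["role"] == "ancestral"]

    def write_tsv(self, path: str | Path, header_comments: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            fh.write("## strains\n")
            self.strains.to_csv(fh, sep="\t", index=False)
            fh.write("## variants\n")
            self.variants.to_csv(fh, sep="\t", index=False)


@dataclass
class ScreenFixture:
    """Everything one simulated screen produces."""

    config: SimConfig
    genome: Genome
    orfs: list[Orf]
    gene_sets: GeneSetCollection
    truth: TruthTable
    design: GroupDesign
    counts: BaseCountMatrix

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = [f"seed={self.config.seed}"]
        paths = {
            "config": outdir / "sim_config.yaml",
            "genome": outdir / "genome.fa",
            "orfs": outdir / "orfs.gff3",
            "gene_sets": outdir / "gene_sets.gmt",
            "design": outdir / "design.tsv",
            "truth": outdir / "truth.tsv",
            "counts": outdir / "counts.tsv",
        }
        self.config.to_yaml(paths["config"])
        write_genome(self.genome, paths["genome"])
        write_orfs(self.orfs, paths["orfs"], header)
        write_gene_sets(self.gene_sets, paths["gene_sets"])
        self.design.write_tsv(paths["design"])
        self.truth.write_tsv(paths["truth"], header)
        self.counts.write_tsv(paths["counts"], header)
        return paths


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

_SENSE_CODONS = None


def _sense_codons(table: CodonTable) -> list[str]:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        _SENSE_CODONS = sorted(c for c, aa in table.forward.items() if aa != STOP and c != "ATG")
    return _SENSE_CODONS


def _random_cds(rng: np.random.Generator, n_codons: int, table: CodonTable) -> str:
    sense = _sense_codons(table)
    stops = sorted(table.stop_codons)
    body = rng.choice(len(sense), size=n_codons - 2)
    return "ATG" + "".join(sense[i] for i in body) + stops[rng.integers(len(stops))]


def simulate_genome(config: SimConfig,
                    table: CodonTable | None = None,
                    ) -> tuple[Genome, list[Orf], GeneSetCollection]:
    """Generate a toy genome packed with valid non-overlapping ORFs plus the
    pathway gene sets.

    Raises if the requested ORFs do not fit within ``genome_length``.
    """
    if table is None:
        table = CodonTable.standard()
    rng = np.random.default_rng([config.seed, 0xA])
    pathway_names = ([g for genes in CATEGORY_GENES.values() for g in genes]
                     if config.include_pathway_genes else [])
    other_names = [f"TOY{i + 1:04d}" for i in range(config.n_other_genes)]
    roster = [(name, config.pathway_orf_codons) for name in pathway_names] + [
        (name, config.other_orf_codons) for name in other_names
    ]
    order = rng.permutation(len(roster))

    chunks: list[str] = []
    orfs: list[Orf] = []
    pos = 0  # 0-based running offset
    for idx in order:
        name, n_codons = roster[idx]
        gap = int(rng.integers(config.min_intergenic_gap, config.max_intergenic_gap + 1))
        chunks.append("".join(_CODE_BASE[rng.integers(0, 4, size=gap)]))
        pos += gap
        cds = _random_cds(rng, n_codons, table)
        strand = "+" if rng.random() < 0.5 else "-"
        seq = cds if strand == "+" else reverse_complement(cds)
        start = pos + 1  # 1-based
        end = pos + len(seq)
        if end > config.genome_length:
            raise ValueError(
                f"requested ORFs do not fit: gene {name!r} would end at {end} "
                f"> genome_length {config.genome_length}"
            )
        chunks.append(seq)
        pos = end
        orfs.append(Orf(gene_id=name, contig=config.contig_name, start=start,
                        end=end, strand=strand))
    tail = config.genome_length - pos
    chunks.append("".join(_CODE_BASE[rng.integers(0, 4, size=tail)]))
    genome = Genome({config.contig_name: "".join(chunks)})

    sets = {cat: frozenset(genes) for cat, genes in CATEGORY_GENES.items()}
    descriptions = {
        "rph1": "Rph1 histone demethylase",
        "rpd3l": "Rpd3L histone deacetylase complex (expanded)",
        "chromatin_silencing": "chromatin silencing at the silent mating-type cassettes",
        "mrna_decay": "nuclear-transcribed mRNA catabolic process, nonsense-mediated decay",
    }
    gene_sets = GeneSetCollection(dict(sets), descriptions)
    if not orfs:
        import warnings

        warnings.warn("simulated genome has an empty gene model", stacklevel=2)
    return genome, orfs, gene_sets


# ---------------------------------------------------------------------------
# Strain simulation
# ---------------------------------------------------------------------------


def _codon_substitutions(cds: str, table: CodonTable):
    """Yield (codon_index0, within, coding_alt, aa_ref, aa_alt) over all
    single-base substitutions of a coding sequence."""
    for ci in range(len(cds) // 3):
        codon = cds[3 * ci : 3 * ci + 3]
        aa_ref = table.translate_codon(codon)
        for w in range(3):
            for b in BASES:
                if b == codon[w]:
                    continue
                alt_codon = codon[:w] + b + codon[w + 1 :]
                yield ci, w, b, aa_ref, table.translate_codon(alt_codon)


def _genome_position(orf: Orf, codon_index0: int, within: int) -> int:
    offset = codon_index0 * 3 + within
    return orf.start + offset if orf.strand == "+" else orf.end - offset


def _coding_to_genome_alt(orf: Orf, coding_alt: str) -> str:
    return coding_alt if orf.strand == "+" else reverse_complement(coding_alt)


def _stop_gain_options(cds: str, table: CodonTable) -> list[tuple[int, int, str, str]]:
    """Single substitutions creating a premature stop: (ci0, within, alt, aa_ref)."""
    out = []
    n_codons = len(cds) // 3
    for ci, w, b, aa_ref, aa_alt in _codon_substitutions(cds, table):
        if aa_alt == STOP and aa_ref != STOP and ci < n_codons - 1:
            out.append((ci, w, b, aa_ref))
    return out


def _class_options(cds: str, table: CodonTable, want_silent: bool):
    out = []
    for ci, w, b, aa_ref, aa_alt in _codon_substitutions(cds, table):
        if "X" in (aa_ref, aa_alt):
            continue
        silent = aa_ref == aa_alt
        nonsilent = (not silent) and (aa_alt == STOP or aa_ref == STOP
                                      or aa_alt != aa_ref)
        if want_silent and silent:
            out.append((ci, w, b))
        elif not want_silent and nonsilent:
            out.append((ci, w, b))
    return out


def simulate_strains(genome: Genome, orfs: list[Orf], gene_sets: GeneSetCollection,
                     config: SimConfig, table: CodonTable | None = None) -> TruthTable:
    """Plant mutations for every strain and the shared ancestral variants.

    Per strain: one causal stop-gain in a gene drawn from the configured
    category distribution; Poisson(background_nonsilent_mean) nonsilent and
    Poisson(background_silent_mean) synonymous coding substitutions, each
    verified against the codon table at construction; all truth positions
    are distinct genome-wide (see module docstring).
    """
    if table is None:
        table = CodonTable.standard()
    rng = np.random.default_rng([config.seed, 0xB])
    if config.n_suppressor_strains > 0 and not config.causal_category_probs:
        raise ValueError("strains requested but no causal categories configured")
    if config.causal_category_probs and not orfs:
        raise ValueError("causal mutations requested but the gene model is empty")

    by_gene = {o.gene_id: o for o in orfs}
    cds_cache = {o.gene_id: o.coding_sequence(genome) for o in orfs}
    category_members = {
        cat: [g for g in genes if g in by_gene]
        for cat, genes in CATEGORY_GENES.items()
    }
    pathway_genes = {g for genes in category_members.values() for g in genes}
    other_genes = [o.gene_id for o in orfs if o.gene_id not in pathway_genes]

    lengths = np.array([by_gene[o.gene_id].length for o in orfs], dtype=float)
    gene_ids = [o.gene_id for o in orfs]
    gene_weights = lengths / lengths.sum()

    cats = list(config.causal_category_probs)
    cat_probs = np.array([config.causal_category_probs[c] for c in cats], dtype=float)
    cat_probs = cat_probs / cat_probs.sum()

    # pos -> (ref, alt) for placed variants.  Positions are unique genome-wide
    # except that a causal (pos, alt) pair may recur across strains: recurrent
    # identical mutations are real (and drive the recurrence analysis), while
    # same-position different-alt collisions would spuriously look multiallelic.
    used_positions: dict[int, tuple[str, str]] = {}
    causal_positions: set[int] = set()
    contig = config.contig_name
    L = len(genome.contigs[contig])

    strains = [f"s{i + 1:03d}" for i in range(config.n_suppressor_strains)]
    var_rows: list[tuple] = []
    strain_rows: list[tuple] = []

    def draw_af() -> float:
        return float(rng.beta(config.af_beta_a, config.af_beta_b))

    def place_coding(sample: str, role: str, want_silent: bool) -> None:
        for _ in range(1000):
            gene = gene_ids[rng.choice(len(gene_ids), p=gene_weights)]
            orf = by_gene[gene]
            options = _class_options(cds_cache[gene], table, want_silent)
            if not options:
                continue
            ci, w, b = options[rng.integers(len(options))]
            pos = _genome_position(orf, ci, w)
            if pos in used_positions:
                continue
            ref = genome.base(contig, pos)
            alt = _coding_to_genome_alt(orf, b)
            used_positions[pos] = (ref, alt)
            var_rows.append((sample, contig, pos, ref, alt, role, draw_af(), gene, ""))
            return
        raise RuntimeError("could not place a background mutation (genome saturated?)")

    for sample in strains:
        # causal stop-gain
        cat = cats[rng.choice(len(cats), p=cat_probs)]
        pool = other_genes if cat == "other" else category_members.get(cat, [])
        if not pool:
            raise ValueError(f"no genes available for causal category {cat!r}")
        placed = False
        for _ in range(100):
            gene = pool[rng.integers(len(pool))]
            orf = by_gene[gene]
            usable = []
            for ci, w, b, aa_ref in _stop_gain_options(cds_cache[gene], table):
                pos = _genome_position(orf, ci, w)
                alt = _coding_to_genome_alt(orf, b)
                if pos not in used_positions:
                    usable.append((ci, w, b, pos, alt))
                elif pos in causal_positions and used_positions[pos][1] == alt:
                    usable.append((ci, w, b, pos, alt))  # recurrent identical hit
            if not usable:
                continue
            ci, w, b, pos, alt = usable[rng.integers(len(usable))]
            ref = genome.base(contig, pos)
            used_positions[pos] = (ref, alt)
            causal_positions.add(pos)
            var_rows.append((sample, contig, pos, ref, alt, "causal", draw_af(), gene, cat))
            strain_rows.append((sample, gene, cat))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"no codon in category {cat!r} can yield a stop by one substitution"
            )

        for _ in range(rng.poisson(config.background_nonsilent_mean)):
            place_coding(sample, "background_nonsilent", want_silent=False)
        for _ in range(rng.poisson(config.background_silent_mean)):
            place_coding(sample, "background_silent", want_silent=True)

    # ancestral variants shared by every sample, controls included
    for _ in range(config.ancestral_variant_count):
        for _ in range(1000):
            pos = int(rng.integers(1, L + 1))
            if pos in used_positions or genome.base(contig, pos) == "N":
                continue
            break
        else:
            raise RuntimeError("could not place ancestral variant")
        ref = genome.base(contig, pos)
        alts = [b for b in BASES if b != ref]
        alt = alts[rng.integers(3)]
        used_positions[pos] = (ref, alt)
        var_rows.append((TruthTable.ANCESTRAL_SAMPLE, contig, pos, ref, alt,
                         "ancestral", draw_af(), "", ""))

    variants = pd.DataFrame(
        var_rows,
        columns=["sample", "contig", "pos", "ref", "alt", "role", "true_af",
                 "gene_id", "category"],
    ).sort_values(["contig", "pos"], kind="mergesort").reset_index(drop=True)
    strains_df = pd.DataFrame(strain_rows, columns=["sample", "causal_gene",
                                                    "causal_category"])
    return TruthTable(variants, strains_df)


def make_design(config: SimConfig, experiment_id: str = "batch",
                preset: str = "batch95") -> GroupDesign:
    roles = {f"ctrl{i + 1:02d}": "control" for i in range(config.n_control_samples)}
    roles.update({f"s{i + 1:03d}": "suppressor"
                  for i in range(config.n_suppressor_strains)})
    return GroupDesign(experiment_id, roles, preset)


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------


def _split_errors(rng: np.random.Generator, n_err: np.ndarray) -> np.ndarray:
    """Split per-cell error totals uniformly over the 3 non-reference bases."""
    e1 = rng.binomial(n_err, 1.0 / 3.0)
    e2 = rng.binomial(n_err - e1, 0.5)
    e3 = n_err - e1 - e2
    return np.stack([e1, e2, e3], axis=1)


def simulate_counts(truth: TruthTable, genome: Genome, design: GroupDesign,
                    config: SimConfig) -> BaseCountMatrix:
    """Draw the sparse base-count matrix for a simulated screen.

    Depth per emitted cell is negative binomial (mean ``coverage_mean``, size
    ``coverage_dispersion``); variant alt counts are Binomial(depth, true AF);
    sequencing errors are scattered Poisson events at ``error_rate`` per
    sequenced base; multiallelic noise sites are injected at
    ``multiallelic_noise_rate`` per genome base.
    """
    rng = np.random.default_rng([config.seed, 0xC])
    contig = config.contig_name
    L = len(genome.contigs[contig])
    samples = design.samples
    ns = len(samples)
    sample_index = {s: i for i, s in enumerate(samples)}
    genome_codes = np.frombuffer(genome.contigs[contig].encode(), dtype=np.uint8)
    code_of = np.zeros(256, dtype=np.int8)
    for b, i in _BASE_CODE.items():
        code_of[ord(b)] = i

    mean, r = config.coverage_mean, config.coverage_dispersion
    p_nb = r / (r + mean) if mean > 0 else 1.0

    def draw_depth(n: int) -> np.ndarray:
        if mean == 0:
            return np.zeros(n, dtype=np.int64)
        return rng.negative_binomial(r, p_nb, size=n).astype(np.int64)

    truth_pos = truth.variants["pos"].to_numpy(np.int64)
    truth_pos_set = np.unique(truth_pos)

    # --- multiallelic noise sites -----------------------------------------
    n_noise = rng.poisson(config.multiallelic_noise_rate * L)
    noise_rows = []
    noise_positions: list[int] = []
    sup_idx = [sample_index[s] for s in design.suppressors]
    for _ in range(n_noise):
        while True:
            pos = int(rng.integers(1, L + 1))
            if pos not in truth_pos_set and genome.base(contig, pos) != "N":
                break
        noise_positions.append(pos)
        ref_code = int(code_of[genome_codes[pos - 1]])
        alt_codes = rng.permutation([c for c in range(4) if c != ref_code])[:2]
        carriers = rng.choice(sup_idx, size=min(2, len(sup_idx)), replace=False)
        for alt_code, si in zip(alt_codes, carriers):
            noise_rows.append((pos, int(si), int(alt_code)))
    noise_pos_set = np.unique(np.array(noise_positions, dtype=np.int64)) if noise_positions else np.empty(0, np.int64)

    # --- sequencing-error events over the rest of the genome --------------
    blocks = []
    if config.error_rate > 0 and mean > 0:
        lam = L * ns * mean * config.error_rate
        n_events = rng.poisson(lam)
        if n_events:
            ev_pos = rng.integers(1, L + 1, size=n_events)
            keep = ~np.isin(ev_pos, truth_pos_set)
            if len(noise_pos_set):
                keep &= ~np.isin(ev_pos, noise_pos_set)
            ev_pos = ev_pos[keep]
            m = len(ev_pos)
            ev_sample = rng.integers(0, ns, size=m)
            ev_off = rng.integers(1, 4, size=m)  # ref_code + offset mod 4
            if (genome_codes == ord("N")).any():
                ok = genome_codes[ev_pos - 1] != ord("N")
                ev_pos, ev_sample, ev_off = ev_pos[ok], ev_sample[ok], ev_off[ok]
            ref_codes = code_of[genome_codes[ev_pos - 1]].astype(np.int64)
            alt_codes = (ref_codes + ev_off) % 4
            key = ((ev_pos.astype(np.int64) * ns + ev_sample) * 4 + alt_codes)
            ukey, ucount = np.unique(key, return_counts=True)
            u_alt = (ukey % 4).astype(np.int64)
            u_cell = ukey // 4
            cell_ids, cell_inv = np.unique(u_cell, return_inverse=True)
            n_cells = len(cell_ids)
            cnt4 = np.zeros((n_cells, 4), dtype=np.int32)
            np.add.at(cnt4, (cell_inv, u_alt), ucount)
            cell_pos = (cell_ids // ns).astype(np.int64)
            cell_sample = (cell_ids % ns).astype(np.int64)
            depth = draw_depth(n_cells)
            err_tot = cnt4.sum(axis=1)
            depth = np.maximum(depth, err_tot)
            cell_ref = code_of[genome_codes[cell_pos - 1]].astype(np.int64)
            counts = cnt4
            counts[np.arange(n_cells), cell_ref] += depth - err_tot
            blocks.append((cell_pos, cell_sample, cell_ref, counts))

    # --- truth sites: every sample emitted --------------------------------
    # A (pos, alt) pair may recur across strains (recurrent causal hits), so
    # cells are laid out over unique sites with a carrier AF matrix.
    tv = truth.variants
    if len(tv):
        sites = (tv[["pos", "alt"]].drop_duplicates("pos")
                 .sort_values("pos").reset_index(drop=True))
        n_sites = len(sites)
        site_pos = sites["pos"].to_numpy(np.int64)
        site_ref = code_of[genome_codes[site_pos - 1]].astype(np.int64)
        site_alt = pd.Categorical(sites["alt"], categories=list(BASES)).codes.astype(np.int64)
        site_row = {int(p): i for i, p in enumerate(site_pos)}

        af_matrix = np.full((n_sites, ns), np.nan)
        for row in tv.itertuples(index=False):
            i = site_row[int(row.pos)]
            if row.sample == TruthTable.ANCESTRAL_SAMPLE:
                af_matrix[i, :] = row.true_af
            else:
                af_matrix[i, sample_index[row.sample]] = row.true_af

        pos_grid = np.repeat(site_pos, ns)
        ref_grid = np.repeat(site_ref, ns)
        alt_grid = np.repeat(site_alt, ns)
        sample_grid = np.tile(np.arange(ns), n_sites)
        af_grid = af_matrix.ravel()
        is_carrier = ~np.isnan(af_grid)

        depth = draw_depth(n_sites * ns)
        counts = np.zeros((n_sites * ns, 4), dtype=np.int32)
        alt_n = np.zeros(n_sites * ns, dtype=np.int64)
        if is_carrier.any():
            alt_n[is_carrier] = rng.binomial(depth[is_carrier], af_grid[is_carrier])
        non = ~is_carrier
        err_n = np.zeros(n_sites * ns, dtype=np.int64)
        if config.error_rate > 0 and non.any():
            err_n[non] = rng.binomial(depth[non], min(config.error_rate, 1.0))
        rows = np.arange(n_sites * ns)
        np.add.at(counts, (rows, alt_grid), alt_n)
        if err_n.any():
            idx = rows[err_n > 0]
            split = _split_errors(rng, err_n[idx])
            for k in range(3):
                alt_k = (ref_grid[idx] + 1 + k) % 4
                np.add.at(counts, (idx, alt_k), split[:, k])
        used = counts.sum(axis=1)
        depth = np.maximum(depth, used)
        counts[rows, ref_grid] += depth - used
        blocks.append((pos_grid, sample_grid, ref_grid, counts))

    # --- injected multiallelic sites --------------------------------------
    if noise_rows:
        pos_arr = np.array(sorted(noise_pos_set), dtype=np.int64)
        pos_grid = np.repeat(pos_arr, ns)
        sample_grid = np.tile(np.arange(ns), len(pos_arr))
        ref_grid = code_of[genome_codes[pos_grid - 1]].astype(np.int64)
        depth = draw_depth(len(pos_grid))
        counts = np.zeros((len(pos_grid), 4), dtype=np.int64)
        lookup = {(p, s): a for p, s, a in noise_rows}
        for i, (p, s) in enumerate(zip(pos_grid, sample_grid)):
            a = lookup.get((int(p), int(s)))
            if a is not None:
                counts[i, a] = rng.binomial(depth[i], 0.5)
        used = counts.sum(axis=1)
        depth = np.maximum(depth, used)
        counts[np.arange(len(pos_grid)), ref_grid] += depth - used
        blocks.append((pos_grid, sample_grid, ref_grid, counts))

    if not blocks:
        empty = pd.DataFrame(columns=["contig", "pos", "ref", "sample", *COUNT_COLUMNS])
        return BaseCountMatrix(empty, validate=False)

    pos_all = np.concatenate([b[0].astype(np.int64) for b in blocks])
    sample_all = np.concatenate([b[1].astype(np.int16) for b in blocks])
    ref_all = np.concatenate([b[2].astype(np.int8) for b in blocks])
    counts_all = np.concatenate([b[3].astype(np.int32) for b in blocks])
    del blocks

    order = np.lexsort((sample_all, pos_all))
    df = pd.DataFrame({
        "contig": pd.Categorical.from_codes(
            np.zeros(len(pos_all), dtype=np.int8), categories=[contig]),
        "pos": pos_all[order],
        "ref": pd.Categorical.from_codes(ref_all[order], categories=list(BASES)),
        "sample": pd.Categorical.from_codes(sample_all[order], categories=samples),
        "nA": counts_all[order, 0],
        "nC": counts_all[order, 1],
        "nG": counts_all[order, 2],
        "nT": counts_all[order, 3],
    })
    return BaseCountMatrix(df, presorted=True)


def simulate_screen(config: SimConfig) -> ScreenFixture:
    """Full fixture: genome + gene model + truth + design + counts."""
    table = CodonTable.standard()
    genome, orfs, gene_sets = simulate_genome(config, table)
    truth = simulate_strains(genome, orfs, gene_sets, config, table)
    design = make_design(config)
    counts = simulate_counts(truth, genome, design, config)
    return ScreenFixture(config, genome, orfs, gene_sets, truth, design, counts)
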