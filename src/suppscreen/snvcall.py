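"""Joint threshold-based SNV calling with multiallelic discard and control subtraction.

The calling rule set, applied per experiment:

1. *Threshold pass* — a non-reference allele is a candidate in a sample when
   its count ≥ ``min_alt_count`` **and** its allele frequency ≥ ``min_af``
   (both bounds inclusive).  Two named presets exist: ``pairwise`` (5, 0.25)
   for two-sample comparisons and ``batch95`` (20, 0.40) for the large batch
   of suppressor strains against shared controls.
2. *Multiallelic discard* — if two or more distinct alternate alleles at the
   same locus each pass the thresholds in at least one sample of the
   experiment, every candidate at that locus is discarded.
3. *Control subtraction* — a candidate is discarded when the same alternate
   allele reaches allele frequency ≥ ``control_af_cutoff`` (default 0.1) in
   any control sample.  The comparison is allele-specific; a record absent
   from a control is treated as AF 0.

Calling is per suppressor strain (no pooling of evidence across strains);
"joint" means the strains are filtered against the shared controls and the
multiallelic rule sees the whole experiment at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .sitecounts import BASES, COUNT_COLUMNS, BaseCountMatrix, GroupDesign

__all__ = [
    "FILTER_PASS",
    "FILTER_MULTIALLELIC",
    "FILTER_IN_CONTROL",
    "FILTER_BELOW_THRESHOLD",
    "ThresholdConfig",
    "VariantCall",
    "call_site",
    "call_experiment",
    "control_subtract",
    "discard_multiallelic",
    "write_vcf",
]

FILTER_PASS = "PASS"
FILTER_MULTIALLELIC = "multiallelic"
FILTER_IN_CONTROL = "in_control"
FILTER_BELOW_THRESHOLD = "below_threshold"

PRESETS: dict[str, tuple[int, float]] = {
    "pairwise": (5, 0.25),
    "batch95": (20, 0.40),
}

CALL_COLUMNS = ["contig", "pos", "ref", "alt", "sample", "alt_count", "depth", "af", "filter"]


@dataclass(frozen=True)
class ThresholdConfig:
    """Inclusive calling thresholds plus the control allele-frequency cutoff."""

    min_alt_count: int
    min_af: float
    control_af_cutoff: float = 0.1

    def __post_init__(self) -> None:
        if self.min_alt_count < 1:
            raise ValueError("min_alt_count must be >= 1")
        if not 0 < self.min_af <= 1:
            raise ValueError("min_af must be in (0, 1]")
        if not 0 < self.control_af_cutoff <= 1:
            raise ValueError("control_af_cutoff must be in (0, 1]")

    @classmethod
    def preset(cls, name: str, control_af_cutoff: float = 0.1) -> "ThresholdConfig":
        try:
            count, af = PRESETS[name]
        except KeyError:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
        return cls(count, af, control_af_cutoff)


@dataclass(frozen=True)
class VariantCall:
    """One (site, alt allele, sample) record with its evidence and filter status."""

    contig: str
    pos: int
    ref: str
    alt: str
    sample: str
    alt_count: int
    depth: int
    af: float
    filter: str = FILTER_PASS

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError("alt allele equals ref")


def call_site(record: Mapping, thresholds: ThresholdConfig) -> list[tuple[str, int, float]]:
    """Candidate alternate alleles at one (site, sample) record.

    Returns ``(alt, count, af)`` for every non-reference base with
    count ≥ min_alt_count and AF ≥ min_af (inclusive).  AF at depth 0 is 0.
    """
    depth = sum(int(record[c]) for c in COUNT_COLUMNS)
    out = []
    for base in BASES:
        if base == record["ref"]:
            continue
        count = int(record[f"n{base}"])
        af = count / depth if depth else 0.0
        if count >= thresholds.min_alt_count and af >= thresholds.min_af:
            out.append((base, count, af))
    return out


def _melt_candidates(records: pd.DataFrame, thresholds: ThresholdConfig) -> pd.DataFrame:
    """Long-form (contig, pos, ref, alt, sample, alt_count, depth, af) for
    alleles passing thresholds, over all samples in ``records``."""
    counts = records[COUNT_COLUMNS].to_numpy(np.int64)
    depth = counts.sum(axis=1)
    ref_code = pd.Categorical(records["ref"], categories=list(BASES)).codes
    frames = []
    for j, base in enumerate(BASES):
        c = counts[:, j]
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(depth > 0, c / np.maximum(depth, 1), 0.0)
        keep = (ref_code != j) & (c >= thresholds.min_alt_count) & (af >= thresholds.min_af)
        if keep.any():
            sub = records.loc[keep, ["contig", "pos", "ref", "sample"]].copy()
            sub["alt"] = base
            sub["alt_count"] = c[keep]
            sub["depth"] = depth[keep]
            sub["af"] = af[keep]
            frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=["contig", "pos", "ref", "sample", "alt",
                                     "alt_count", "depth", "af"])
    return pd.concat(frames, ignore_index=True)


def threshold_candidates(counts: BaseCountMatrix,
                         thresholds: ThresholdConfig) -> pd.DataFrame:
    """The threshold-calling stage alone: every (site, alt, sample) whose
    count and AF clear the thresholds, before any discard rule.

    Unlike the full pass set, this candidate set is monotone in the
    thresholds: raising either component can only remove candidates.
    """
    return _melt_candidates(counts.records, thresholds)


def discard_multiallelic(candidates: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split candidates into (kept, flagged) by the locus-level multiallelic rule.

    ``candidates`` must hold threshold-passing alleles across *all* samples of
    the experiment; a locus where ≥2 distinct alts pass anywhere is discarded
    wholesale.
    """
    if candidates.empty:
        return candidates, candidates
    n_alts = candidates.groupby(["contig", "pos"], observed=True)["alt"].transform("nunique")
    flagged = candidates[n_alts >= 2].copy()
    kept = candidates[n_alts < 2].copy()
    return kept, flagged


def _control_af_table(counts: BaseCountMatrix, design: GroupDesign,
                      loci: pd.DataFrame) -> pd.DataFrame:
    """Per-(contig, pos, alt) maximum control AF over all control samples."""
    ctrl = counts.records[counts.records["sample"].isin(design.controls)]
    ctrl = ctrl.merge(loci[["contig", "pos"]].drop_duplicates(), on=["contig", "pos"])
    if ctrl.empty:
        return pd.DataFrame(columns=["contig", "pos", "alt", "control_af"])
    cnt = ctrl[COUNT_COLUMNS].to_numpy(np.int64)
    depth = cnt.sum(axis=1)
    frames = []
    for j, base in enumerate(BASES):
        af = np.where(depth > 0, cnt[:, j] / np.maximum(depth, 1), 0.0)
        sub = ctrl[["contig", "pos"]].copy()
        sub["alt"] = base
        sub["control_af"] = af
        frames.append(sub)
    long = pd.concat(frames, ignore_index=True)
    return long.groupby(["contig", "pos", "alt"], as_index=False, observed=True)["control_af"].max()


def control_subtract(candidates: pd.DataFrame, counts: BaseCountMatrix,
                     design: GroupDesign,
                     thresholds: ThresholdConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split candidates into (kept, flagged) by allele-specific control AF.

    A candidate is flagged ``in_control`` when the same alt allele has
    AF ≥ control_af_cutoff in any control sample; absent control records
    count as AF 0.
    """
    if not design.controls:
        raise ValueError(f"experiment {design.experiment_id!r} has no control sample")
    if candidates.empty:
        return candidates, candidates
    ctrl_af = _control_af_table(counts, design, candidates)
    merged = candidates.merge(ctrl_af, on=["contig", "pos", "alt"], how="left")
    merged["control_af"] = merged["control_af"].astype(float).fillna(0.0)
    in_ctrl = merged["control_af"] >= thresholds.control_af_cutoff
    kept = merged[~in_ctrl].drop(columns="control_af")
    flagged = merged[in_ctrl].drop(columns="control_af")
    return kept.copy(), flagged.copy()


def call_experiment(counts: BaseCountMatrix, design: GroupDesign,
                    thresholds: ThresholdConfig,
                    multiallelic_scope: str = "experiment",
                    emit_below_threshold: bool = False) -> pd.DataFrame:
    """Run the full calling rule set over one experiment.

    Returns a DataFrame with columns
    ``contig, pos, ref, alt, sample, alt_count, depth, af, filter`` holding
    one row per candidate (suppressor-sample) allele, flagged
    PASS / multiallelic / in_control.  With ``emit_below_threshold`` the
    output also lists sub-threshold evidence for passing alleles in other
    suppressor samples, flagged ``below_threshold`` (context for review; never
    part of the pass set).  Output order is (contig, pos, alt, sample).

    ``multiallelic_scope`` is ``"experiment"`` (default: any two passing alts
    at a locus anywhere discard the locus) or ``"sample"`` (two passing alts
    within the same sample).
    """
    if multiallelic_scope not in ("experiment", "sample"):
        raise ValueError("multiallelic_scope must be 'experiment' or 'sample'")
    # samples absent from the records are legal (no non-ref evidence anywhere);
    # controls with no records simply contribute AF 0 everywhere.
    all_cand = _melt_candidates(counts.records, thresholds)

    # multiallelic rule over every sample (controls included)
    if multiallelic_scope == "experiment":
        _, multi = discard_multiallelic(all_cand)
        multi_loci = multi[["contig", "pos"]].drop_duplicates()
    else:
        n_alts = (all_cand.groupby(["contig", "pos", "sample"], observed=True)["alt"].transform("nunique")
                  if not all_cand.empty else pd.Series(dtype=int))
        multi_loci = (all_cand[n_alts >= 2][["contig", "pos"]].drop_duplicates()
                      if not all_cand.empty else all_cand)

    cand = all_cand[all_cand["sample"].isin(design.suppressors)].copy()
    if cand.empty:
        return pd.DataFrame(columns=CALL_COLUMNS)

    is_multi = cand.merge(multi_loci.assign(_m=True), on=["contig", "pos"],
                          how="left")["_m"].notna().to_numpy()
    multi_part = cand[is_multi].copy()
    multi_part["filter"] = FILTER_MULTIALLELIC
    rest = cand[~is_multi]

    kept, in_ctrl = control_subtract(rest, counts, design, thresholds)
    kept["filter"] = FILTER_PASS
    in_ctrl["filter"] = FILTER_IN_CONTROL

    parts = [kept, in_ctrl, multi_part]

    if emit_below_threshold and not kept.empty:
        pass_alleles = kept[["contig", "pos", "alt"]].drop_duplicates()
        sup = counts.records[counts.records["sample"].isin(design.suppressors)]
        sup = sup.merge(pass_alleles[["contig", "pos"]].drop_duplicates(), on=["contig", "pos"])
        if not sup.empty:
            cnt = sup[COUNT_COLUMNS].to_numpy(np.int64)
            depth = cnt.sum(axis=1)
            frames = []
            for j, base in enumerate(BASES):
                af = np.where(depth > 0, cnt[:, j] / np.maximum(depth, 1), 0.0)
                sub = sup[["contig", "pos", "ref", "sample"]].copy()
                sub["alt"] = base
                sub["alt_count"] = cnt[:, j]
                sub["depth"] = depth
                sub["af"] = af
                frames.append(sub)
            long = pd.concat(frames, ignore_index=True)
            long = long.merge(pass_alleles, on=["contig", "pos", "alt"])
            long = long[(long["alt_count"] > 0) & (long["alt"] != long["ref"])]
            called = pd.concat(parts)[["contig", "pos", "alt", "sample"]]
            long = long.merge(called.assign(_c=True), on=["contig", "pos", "alt", "sample"],
                              how="left")
            long = long[long["_c"].isna()].drop(columns="_c")
            below = (long[(long["alt_count"] < thresholds.min_alt_count)
                          | (long["af"] < thresholds.min_af)]).copy()
            below["filter"] = FILTER_BELOW_THRESHOLD
            parts.append(below)

    out = pd.concat(parts, ignore_index=True)[CALL_COLUMNS]
    out = out.sort_values(["contig", "pos", "alt", "sample"], kind="mergesort")
    return out.reset_index(drop=True)


def pass_set(calls: pd.DataFrame) -> pd.DataFrame:
    """Rows of a call table with FILTER == PASS."""
    return calls[calls["filter"] == FILTER_PASS].reset_index(drop=True)


def to_variant_calls(calls: pd.DataFrame) -> list[VariantCall]:
    return [
        VariantCall(r.contig, int(r.pos), r.ref, r.alt, r.sample,
                    int(r.alt_count), int(r.depth), float(r.af), r.filter)
        for r in calls.itertuples(index=False)
    ]


def write_vcf(calls: pd.DataFrame, counts: BaseCountMatrix, design: GroupDesign,
              path, header_comments: Iterable[str] = ()) -> None:
    """Write a per-experiment VCF v4.2 with per-sample DP:AD:AF:FT fields.

    One line per (contig, pos, ref, alt); the site FILTER is PASS if the
    allele passes in at least one sample, else the most common per-sample flag.
    """
    if calls.empty:
        site_keys = calls
    else:
        site_keys = calls[["contig", "pos", "ref", "alt"]].drop_duplicates()
    samples = design.samples
    rec = counts.records.set_index(["contig", "pos", "sample"]).sort_index()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in header_comments:
            fh.write(f"##suppscreen={line}\n")
        fh.write(f'##FILTER=<ID={FILTER_MULTIALLELIC},Description="Two or more alt alleles pass thresholds at this locus">\n')
        fh.write(f'##FILTER=<ID={FILTER_IN_CONTROL},Description="Alt allele frequency >= cutoff in a control sample">\n')
        fh.write(f'##FILTER=<ID={FILTER_BELOW_THRESHOLD},Description="Alt evidence below calling thresholds">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Post-filter depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Alt allele count">\n')
        fh.write('##FORMAT=<ID=AF,Number=1,Type=Float,Description="Alt allele frequency">\n')
        fh.write('##FORMAT=<ID=FT,Number=1,Type=String,Description="Per-sample filter">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        if calls.empty:
            return
        per_sample = calls.set_index(["contig", "pos", "alt", "sample"]).sort_index()
        base_col = {b: f"n{b}" for b in BASES}
        for key in site_keys.itertuples(index=False):
            flags = []
            cells = []
            for s in samples:
                try:
                    crow = rec.loc[(key.contig, key.pos, s)]
                except KeyError:
                    cells.append(".")
                    continue
                if isinstance(crow, pd.DataFrame):
                    crow = crow.iloc[0]
                dp = int(sum(crow[c] for c in COUNT_COLUMNS))
                ad = int(crow[base_col[key.alt]])
                af = ad / dp if dp else 0.0
                try:
                    vrow = per_sample.loc[(key.contig, key.pos, key.alt, s)]
                    ft = vrow["filter"] if not isinstance(vrow, pd.DataFrame) else vrow.iloc[0]["filter"]
                except KeyError:
                    ft = "."
                if ft != ".":
                    flags.append(ft)
                cells.append(f"{dp}:{ad}:{af:.4f}:{ft}")
            if FILTER_PASS in flags:
                site_filter = FILTER_PASS
            elif flags:
                site_filter = max(set(flags), key=flags.count)
            else:
                site_filter = "."
            fh.write(f"{key.contig}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\t{site_filter}\t.\t"
                     "DP:AD:AF:FT\t" + "\t".join(cells) + "\n")
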