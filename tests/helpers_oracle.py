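"""Independent brute-force implementation of the calling rules, used as the
test oracle.  Deliberately literal and loop-based; shares no code with the
package's vectorized caller."""

from __future__ import annotations

BASES = ("A", "C", "G", "T")


def brute_force_calls(records: list[dict], suppressors: set[str], controls: set[str],
                      min_alt_count: int, min_af: float,
                      control_af_cutoff: float) -> set[tuple]:
    """Apply threshold pass, locus-wide multiallelic discard, and
    allele-specific control subtraction by direct enumeration.

    Returns the pass set as {(contig, pos, alt, sample)}.
    """
    # rule 1: threshold-passing alleles, every sample
    passing = []
    for r in records:
        depth = sum(r[f"n{b}"] for b in BASES)
        for b in BASES:
            if b == r["ref"]:
                continue
            count = r[f"n{b}"]
            af = count / depth if depth > 0 else 0.0
            if count >= min_alt_count and af >= min_af:
                passing.append((r["contig"], r["pos"], b, r["sample"]))

    # rule 2: multiallelic loci (distinct passing alts anywhere in the experiment)
    alts_at_locus: dict[tuple, set] = {}
    for contig, pos, alt, _sample in passing:
        alts_at_locus.setdefault((contig, pos), set()).add(alt)
    multiallelic = {k for k, v in alts_at_locus.items() if len(v) >= 2}

    # rule 3: allele-specific max control AF
    control_af: dict[tuple, float] = {}
    for r in records:
        if r["sample"] not in controls:
            continue
        depth = sum(r[f"n{b}"] for b in BASES)
        for b in BASES:
            if b == r["ref"]:
                continue
            af = r[f"n{b}"] / depth if depth > 0 else 0.0
            key = (r["contig"], r["pos"], b)
            control_af[key] = max(control_af.get(key, 0.0), af)

    out = set()
    for contig, pos, alt, sample in passing:
        if sample not in suppressors:
            continue
        if (contig, pos) in multiallelic:
            continue
        if control_af.get((contig, pos, alt), 0.0) >= control_af_cutoff:
            continue
        out.add((contig, pos, alt, sample))
    return out


def random_locus_records(rng, contig: str, pos: int, samples: list[str]) -> list[dict]:
    """One random locus: mostly reference with occasional strong alt evidence,
    sometimes in controls, sometimes at two different alts."""
    ref = BASES[rng.integers(4)]
    rows = []
    for s in samples:
        depth = int(rng.integers(0, 120))
        counts = {b: 0 for b in BASES}
        counts[ref] = depth
        # sprinkle alt evidence of widely varying strength
        n_alt_events = rng.integers(0, 3)
        for _ in range(n_alt_events):
            b = BASES[rng.integers(4)]
            take = int(rng.integers(0, depth + 1))
            take = min(take, counts[ref])
            counts[ref] -= take
            counts[b] += take
        rows.append({"contig": contig, "pos": pos, "ref": ref, "sample": s,
                     **{f"n{b}": counts[b] for b in BASES}})
    return rows
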