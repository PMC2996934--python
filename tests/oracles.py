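"""Independent brute-force oracles used to cross-check the library.

Everything here is deliberately written the slow, obvious way (explicit
per-base walks, dict grouping, linear scans) and never calls the code path
it checks.
"""

from __future__ import annotations


def oracle_qualify(read, assembly, params) -> list[bool]:
    """Exhaustive per-base NQS re-evaluation via an explicit alignment walk."""
    w = params.flank_width
    ref = assembly.sequences[read.chrom]
    ann = []  # per read base: (ref position or None, cigar op index)
    p = read.start
    for opi, (op, n) in enumerate(read.cigar):
        if op == "M":
            for k in range(n):
                ann.append((p + k, opi))
            p += n
        elif op == "I":
            for _ in range(n):
                ann.append((None, opi))
        elif op == "D":
            p += n
    out = []
    for i in range(len(ann)):
        if i - w < 0 or i + w >= len(ann):
            out.append(False)
            continue
        ok = True
        if read.quals[i] < params.center_min_q:
            ok = False
        # full neighborhood must sit inside one aligned (M) segment
        ops_in_window = {ann[j][1] for j in range(i - w, i + w + 1)}
        if len(ops_in_window) != 1 or ann[i][0] is None:
            ok = False
        if ok:
            matches = 0
            for j in range(i - w, i + w + 1):
                if j == i:
                    continue
                if read.quals[j] < params.flank_min_q:
                    ok = False
                rp = ann[j][0]
                if rp is not None and ref[rp] != "N" and read.seq[j] == ref[rp]:
                    matches += 1
            if matches < params.min_flank_matches:
                ok = False
        out.append(ok)
    return out


def oracle_depths(reads, chrom, length) -> list[int]:
    """Interval-stabbing depth per position, one read M-interval at a time."""
    depth = [0] * length
    for read in reads:
        if read.chrom != chrom:
            continue
        p = read.start
        for op, n in read.cigar:
            if op == "M":
                for q in range(p, p + n):
                    depth[q] += 1
                p += n
            elif op == "D":
                p += n
    return depth


def oracle_merge(records):
    """Hash-group per-read records into (key -> {individual -> count})."""
    grouped = {}
    for rec in records:
        key = (rec.chrom, rec.pos, rec.vtype, rec.alt)
        grouped.setdefault(key, {}).setdefault(rec.individual, 0)
        grouped[key][rec.individual] += 1
    return grouped


def oracle_partition(discoverer_sets, special, primary_special):
    """Per-site (in_A, in_B) flags computed from first principles."""
    flags = []
    for disc in discoverer_sets:
        in_a = any(d not in special for d in disc)
        in_b = any(d not in primary_special for d in disc)
        flags.append((in_a, in_b))
    return flags


def oracle_bin_counts(positions, length, window):
    """Direct per-site window binning."""
    n_win = (length + window - 1) // window
    counts = [0] * n_win
    for p in positions:
        counts[p // window] += 1
    return counts


def oracle_n50(lengths):
    """Sort-and-scan cumulative N50."""
    total = sum(lengths)
    cum = 0
    for L in sorted(lengths, reverse=True):
        cum += L
        if cum >= total / 2:
            return L
    raise AssertionError("unreachable for non-empty input")


def oracle_gap_distance(sequence: str, pos: int) -> int:
    """Distance to the nearest N (or virtual gap just outside the contig)."""
    best = None
    chars = [(-1, "N")] + list(enumerate(sequence)) + [(len(sequence), "N")]
    for i, c in chars:
        if c == "N":
            d = abs(pos - i)
            best = d if best is None else min(best, d)
    return best
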