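"""Neighborhood Quality Standard base filtering and SNP/DIP calling.

Variants are called by comparing each read against the consensus reference.
A discrepant base is only reported when it passes the NQS rule — PHRED
quality >= 23 at the base itself, >= 15 at the five bases on either side,
and at least nine of those ten flanking bases perfectly matching the
reference — and when the column depth does not exceed a low coverage cap,
which guards against collapsed repeats in a light assembly.  Per-read
discoveries are merged into non-redundant sites that remember which
individuals found them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import AlignedRead, ReferenceAssembly

_N = ord("N")


class UndefinedRateError(ValueError):
    """Raised when a SNP rate is requested for an individual with zero SNPs."""


@dataclass(frozen=True)
class NqsParams:
    """NQS thresholds plus the calling-stage coverage cap.

    ``max_depth`` is a choice, not a reconstruction: the study states only
    that a low upper limit was placed on coverage.  The default of 8 is about
    2.5x the ~2.8-fold mean read redundancy.
    """

    center_min_q: int = 23
    flank_min_q: int = 15
    flank_width: int = 5
    min_flank_matches: int = 9
    max_depth: int = 8
    max_dip_length: int = 10

    def __post_init__(self):
        if self.min_flank_matches > 2 * self.flank_width:
            raise ValueError("min_flank_matches exceeds the flank base count")
        for name in (
            "center_min_q",
            "flank_min_q",
            "flank_width",
            "min_flank_matches",
            "max_depth",
            "max_dip_length",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class Discrepancy:
    """One qualified per-read discrepancy (the unit that merging consumes)."""

    chrom: str
    pos: int  # 0-based; anchor base for DIPs
    vtype: str  # 'SNP' | 'DIP'
    ref: str
    alt: str
    individual: str
    read_id: str


@dataclass
class VariantSite:
    """A merged, non-redundant SNP or DIP with its discoverer set."""

    chrom: str
    pos: int
    vtype: str
    ref: str
    alt: str
    support: dict[str, int] = field(default_factory=dict)

    @property
    def discoverers(self) -> frozenset[str]:
        return frozenset(self.support)

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.vtype, self.alt)


# ---------------------------------------------------------------------------
# Base qualification
# ---------------------------------------------------------------------------


def _read_arrays(read: AlignedRead, assembly: ReferenceAssembly):
    """Cached per-read (refpos, runid, match, qual) arrays.

    ``match`` is False for insertion bases and wherever the reference base is
    N, so N-adjacent neighborhoods fail the flank-match requirement.
    """
    cached = getattr(read, "_nqs_arrays", None)
    if cached is not None:
        return cached
    if read.chrom not in assembly:
        raise ValueError(f"read {read.read_id} references unknown chromosome {read.chrom}")
    refpos, runid = read.expand()
    ref_u8 = assembly.seq_u8(read.chrom)
    seq_u8 = read.seq_u8()
    match = np.zeros(len(read), dtype=bool)
    aligned = refpos >= 0
    ref_bases = ref_u8[refpos[aligned]]
    match[aligned] = (seq_u8[aligned] == ref_bases) & (ref_bases != _N)
    read._nqs_arrays = (refpos, runid, match, read.quals)
    return read._nqs_arrays


def qualify_read(
    read: AlignedRead, assembly: ReferenceAssembly, params: NqsParams
) -> np.ndarray:
    """Boolean NQS qualification for every base of one read (vectorized).

    A base qualifies iff its full (2*flank_width + 1)-base neighborhood lies
    within the read and within a single gap-free alignment run, the center
    quality is >= center_min_q, every flanking quality is >= flank_min_q, and
    at least min_flank_matches flanking bases match the reference.
    """
    cache = getattr(read, "_nqs_qualified", None)
    if cache is not None and cache[0] == params:
        return cache[1]
    refpos, runid, match, quals = _read_arrays(read, assembly)
    L = len(read)
    w = params.flank_width
    out = np.zeros(L, dtype=bool)
    if L >= 2 * w + 1:
        q = quals.astype(np.int16)
        okf = (q >= params.flank_min_q).astype(np.int32)
        cf = np.concatenate(([0], np.cumsum(okf)))
        cm = np.concatenate(([0], np.cumsum(match.astype(np.int32))))
        centers = slice(w, L - w)
        win_f = cf[2 * w + 1 :] - cf[: L - 2 * w]  # sums over [i-w, i+w]
        win_m = cm[2 * w + 1 :] - cm[: L - 2 * w]
        c_ok = q[centers] >= params.center_min_q
        flank_q_ok = (win_f - okf[centers]) == 2 * w
        flank_m_ok = (win_m - match[centers].astype(np.int32)) >= params.min_flank_matches
        same_run = (runid[: L - 2 * w] == runid[2 * w :]) & (runid[centers] >= 0)
        out[centers] = c_ok & flank_q_ok & flank_m_ok & same_run
    read._nqs_qualified = (params, out)
    return out


def qualify_base(
    read: AlignedRead, offset: int, assembly: ReferenceAssembly, params: NqsParams
) -> bool:
    """NQS qualification of a single read base (0-based read offset)."""
    if not 0 <= offset < len(read):
        raise IndexError(f"offset {offset} outside read of length {len(read)}")
    return bool(qualify_read(read, assembly, params)[offset])


def qualified_base_count(
    read: AlignedRead, assembly: ReferenceAssembly, params: NqsParams
) -> int:
    return int(qualify_read(read, assembly, params).sum())


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------


class Pileup:
    """Read pileup against the reference: depths plus on-demand columns.

    Depth counts reads whose M operations cover a position.  Columns are
    materialized lazily; whole-genome calling never builds them explicitly.
    """

    def __init__(
        self,
        reads: Sequence[AlignedRead],
        assembly: ReferenceAssembly,
        params: NqsParams | None = None,
    ):
        self.assembly = assembly
        self.params = params or NqsParams()
        self.by_chrom: dict[str, list[AlignedRead]] = {}
        for read in reads:
            if read.chrom not in assembly:
                raise ValueError(
                    f"read {read.read_id} references unknown chromosome {read.chrom}"
                )
            self.by_chrom.setdefault(read.chrom, []).append(read)
        self._depth: dict[str, np.ndarray] = {}
        self._excluded: dict[str, np.ndarray] = {}

    def depth(self, chrom: str) -> np.ndarray:
        d = self._depth.get(chrom)
        if d is None:
            L = self.assembly.length(chrom)
            diff = np.zeros(L + 1, dtype=np.int32)
            for read in self.by_chrom.get(chrom, []):
                for s, e in read.m_intervals():
                    diff[s] += 1
                    diff[e] -= 1
            d = np.cumsum(diff[:-1]).astype(np.int32)
            self._depth[chrom] = d
        return d

    def excluded_columns(self, chrom: str) -> np.ndarray:
        """Columns barred from calling: reference N, or within flank_width of an N-run."""
        m = self._excluded.get(chrom)
        if m is None:
            L = self.assembly.length(chrom)
            w = self.params.flank_width
            m = np.zeros(L, dtype=bool)
            for s, e in self.assembly.n_runs[chrom]:
                m[max(0, s - w) : min(L, e + w)] = True
            self._excluded[chrom] = m
        return m

    def column(self, chrom: str, pos: int) -> list[tuple[str, str, int, bool]]:
        """(individual, base, quality, qualified) for reads covering ``pos``."""
        out = []
        for read in self.by_chrom.get(chrom, []):
            if not read.start <= pos < read.end:
                continue
            refpos, _, _, _ = _read_arrays(read, self.assembly)
            hits = np.flatnonzero(refpos == pos)
            for i in hits:
                out.append(
                    (
                        read.individual,
                        read.seq[int(i)],
                        int(read.quals[int(i)]),
                        bool(qualify_read(read, self.assembly, self.params)[int(i)]),
                    )
                )
        return out

    def columns(self, chrom: str):
        """Yield (pos, column) for every covered position.  Toy scale only."""
        depth = self.depth(chrom)
        for pos in np.flatnonzero(depth > 0):
            yield int(pos), self.column(chrom, int(pos))


def build_pileup(
    reads: Sequence[AlignedRead],
    assembly: ReferenceAssembly,
    params: NqsParams | None = None,
) -> Pileup:
    return Pileup(reads, assembly, params)


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------


def call_snps(pileup: Pileup, params: NqsParams | None = None) -> list[Discrepancy]:
    """Emit a record for every qualified read base differing from the reference.

    Columns deeper than max_depth, reference-N columns and columns within
    flank_width of an N-run emit nothing.
    """
    params = params or pileup.params
    records: list[Discrepancy] = []
    for chrom, reads in pileup.by_chrom.items():
        depth = pileup.depth(chrom)
        excluded = pileup.excluded_columns(chrom)
        ref_u8 = pileup.assembly.seq_u8(chrom)
        for read in reads:
            qual = qualify_read(read, pileup.assembly, params)
            refpos, _, match, _ = _read_arrays(read, pileup.assembly)
            aligned = refpos >= 0
            mism = qual & aligned & ~match
            if not mism.any():
                continue
            seq_u8 = read.seq_u8()
            for i in np.flatnonzero(mism):
                p = int(refpos[i])
                if ref_u8[p] == _N or seq_u8[i] == _N:
                    continue
                if excluded[p] or depth[p] > params.max_depth:
                    continue
                records.append(
                    Discrepancy(
                        chrom=chrom,
                        pos=p,
                        vtype="SNP",
                        ref=chr(ref_u8[p]),
                        alt=chr(seq_u8[i]),
                        individual=read.individual,
                        read_id=read.read_id,
                    )
                )
    return records


def _qualify_gap_flank(
    read: AlignedRead,
    assembly: ReferenceAssembly,
    params: NqsParams,
    m_index: np.ndarray,
    m_runid: np.ndarray,
    k: int,
    allowed_runs: tuple[int, int],
) -> bool:
    """NQS for a base flanking a gap, with the gap excluded from its neighborhood.

    The neighborhood is the nearest ``flank_width`` aligned (M) bases on each
    side in read order; all of them must come from the two runs adjacent to
    the gap under test, which forbids any second gap from intersecting.
    """
    _, _, match, quals = _read_arrays(read, assembly)
    w = params.flank_width
    if k - w < 0 or k + w >= m_index.size:
        return False
    neigh = np.concatenate((m_index[k - w : k], m_index[k + 1 : k + w + 1]))
    runs = np.concatenate((m_runid[k - w : k], m_runid[k + 1 : k + w + 1]))
    if not np.isin(runs, allowed_runs).all():
        return False
    center = int(m_index[k])
    if quals[center] < params.center_min_q:
        return False
    if (quals[neigh] < params.flank_min_q).any():
        return False
    return int(match[neigh].sum()) >= params.min_flank_matches


def call_dips(
    reads: Sequence[AlignedRead],
    assembly: ReferenceAssembly,
    params: NqsParams | None = None,
    pileup: Pileup | None = None,
) -> list[Discrepancy]:
    """Record insertions/deletions of length <= max_dip_length from alignment gaps.

    A gap is reported when both read bases immediately flanking it satisfy
    the NQS rule with the gap excluded from their neighborhoods.  The same
    coverage cap and reference-N exclusions as SNP calling apply at the
    anchor column.
    """
    params = params or NqsParams()
    if pileup is None:
        pileup = Pileup(reads, assembly, params)
    records: list[Discrepancy] = []
    for read in reads:
        gaps = [(op, n) for op, n in read.cigar if op in "ID"]
        if not gaps:
            continue
        depth = pileup.depth(read.chrom)
        excluded = pileup.excluded_columns(read.chrom)
        refpos, runid, _, _ = _read_arrays(read, assembly)
        m_mask = refpos >= 0
        m_index = np.flatnonzero(m_mask)
        m_runid = runid[m_index]
        ref_seq = assembly.sequences[read.chrom]
        # walk the cigar tracking read and reference cursors
        r, p = 0, read.start
        run = -1
        for op, n in read.cigar:
            if op == "M":
                run += 1
                r += n
                p += n
                continue
            left_read = r - 1  # last M base before the gap (runs are M-ops)
            if op == "I":
                alt, ref_allele = read.seq[r : r + n], ""
                r += n
            else:
                alt, ref_allele = "", ref_seq[p : p + n]
                p += n
            if n > params.max_dip_length:
                continue
            anchor = p - n - 1 if op == "D" else p - 1
            if op == "I":
                anchor = p - 1
            if left_read < 0 or anchor < 0:
                continue
            k_arr = np.searchsorted(m_index, left_read)
            if k_arr >= m_index.size or m_index[k_arr] != left_read:
                continue  # gap not flanked by an aligned base
            k = int(k_arr)
            if k + 1 >= m_index.size:
                continue
            allowed = (int(m_runid[k]), int(m_runid[k + 1]))
            if excluded[anchor] or depth[anchor] > params.max_depth:
                continue
            if "N" in ref_allele:
                continue
            left_ok = _qualify_gap_flank(
                read, assembly, params, m_index, m_runid, k, allowed
            )
            right_ok = _qualify_gap_flank(
                read, assembly, params, m_index, m_runid, k + 1, allowed
            )
            if left_ok and right_ok:
                records.append(
                    Discrepancy(
                        chrom=read.chrom,
                        pos=anchor,
                        vtype="DIP",
                        ref=ref_allele,
                        alt=alt,
                        individual=read.individual,
                        read_id=read.read_id,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Merging and rates
# ---------------------------------------------------------------------------


def merge_sites(records: Iterable[Discrepancy]) -> list[VariantSite]:
    """Collapse per-read discoveries into non-redundant, alt-resolved sites."""
    sites: dict[tuple, VariantSite] = {}
    for rec in records:
        key = (rec.chrom, rec.pos, rec.vtype, rec.alt)
        site = sites.get(key)
        if site is None:
            site = VariantSite(
                chrom=rec.chrom, pos=rec.pos, vtype=rec.vtype, ref=rec.ref, alt=rec.alt
            )
            sites[key] = site
        site.support[rec.individual] = site.support.get(rec.individual, 0) + 1
    return [sites[k] for k in sorted(sites, key=lambda k: (k[0], k[1], k[2], k[3]))]


def per_individual_site_counts(sites: Sequence[VariantSite]) -> dict[str, int]:
    """Distinct sites discovered by each individual (each site once per cat)."""
    counts: dict[str, int] = {}
    for site in sites:
        for name in site.discoverers:
            counts[name] = counts.get(name, 0) + 1
    return counts


def snp_rate(
    individual: str,
    records: Iterable[Discrepancy],
    reads: Sequence[AlignedRead],
    assembly: ReferenceAssembly,
    params: NqsParams,
) -> float:
    """Bases-per-SNP for one cat: NQS bases in its reads / its SNP sites.

    The numerator counts qualified bases per read summed over reads (depth
    counted multiply, as traces are); the denominator counts distinct SNP
    sites discovered from that cat's reads.
    """
    site_keys = {
        (r.chrom, r.pos, r.alt)
        for r in records
        if r.individual == individual and r.vtype == "SNP"
    }
    if not site_keys:
        raise UndefinedRateError(f"no SNPs detected for {individual}")
    qualified = sum(
        qualified_base_count(read, assembly, params)
        for read in reads
        if read.individual == individual
    )
    return qualified / len(site_keys)


def rate_report(
    reads: Sequence[AlignedRead],
    records: Sequence[Discrepancy],
    assembly: ReferenceAssembly,
    params: NqsParams,
):
    """Per-individual TSV-ready rate table (qualified bases, SNPs, bases/SNP)."""
    import pandas as pd

    individuals = sorted({r.individual for r in reads})
    rows = []
    for name in individuals:
        qualified = sum(
            qualified_base_count(read, assembly, params)
            for read in reads
            if read.individual == name
        )
        snps = len(
            {
                (r.chrom, r.pos, r.alt)
                for r in records
                if r.individual == name and r.vtype == "SNP"
            }
        )
        rows.append(
            {
                "individual": name,
                "qualified_bases": qualified,
                "snp_sites": snps,
                "bases_per_snp": round(qualified / snps) if snps else None,
            }
        )
    return pd.DataFrame(rows)
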