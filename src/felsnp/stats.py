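"""SNP resource statistics: discoverer categories, densities and windows.

Sites are partitioned into three nested categories by which cats discovered
them: A excludes sites found only in the deeply sequenced inbred cat and/or
the wildcat, B excludes sites found only in the inbred cat, C is everything.
The remaining operations compute average SNP spacing (bases per SNP),
fixed-window SNP densities, window-occupancy curves across window sizes, the
informative-marker fraction estimated from validation genotypes, and the
assembly N50 utility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ReferenceAssembly
from .nqs import VariantSite

DEFAULT_SPECIAL = frozenset({"Cinnamon", "Nancy"})
DEFAULT_PRIMARY_SPECIAL = frozenset({"Cinnamon"})


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Category partition
# ---------------------------------------------------------------------------


@dataclass
class CategoryPartition:
    """Per-site A/B/C flags plus per-chromosome counts (A ⊆ B ⊆ C)."""

    special: frozenset[str]
    primary_special: frozenset[str]
    sites: list[VariantSite]
    in_a: np.ndarray = field(repr=False, default=None)
    in_b: np.ndarray = field(repr=False, default=None)

    def sites_in(self, category: str) -> list[VariantSite]:
        if category == "C":
            return list(self.sites)
        mask = self.in_a if category == "A" else self.in_b
        return [s for s, m in zip(self.sites, mask) if m]

    def counts(self) -> dict[str, int]:
        return {
            "A": int(self.in_a.sum()),
            "B": int(self.in_b.sum()),
            "C": len(self.sites),
        }

    def counts_by_chrom(self) -> pd.DataFrame:
        rows: dict[str, dict[str, int]] = {}
        for site, a, b in zip(self.sites, self.in_a, self.in_b):
            row = rows.setdefault(site.chrom, {"A": 0, "B": 0, "C": 0})
            row["C"] += 1
            row["B"] += int(b)
            row["A"] += int(a)
        return pd.DataFrame(
            [{"chromosome": c, **counts} for c, counts in sorted(rows.items())]
        )


def categorize(
    sites: Sequence[VariantSite],
    special: Iterable[str] = DEFAULT_SPECIAL,
    primary_special: Iterable[str] = DEFAULT_PRIMARY_SPECIAL,
    known_individuals: Iterable[str] | None = None,
) -> CategoryPartition:
    """Partition sites by discoverer into nested categories A ⊆ B ⊆ C.

    A site is in A iff some discoverer lies outside ``special`` (by default
    the inbred cat and the wildcat); in B iff some discoverer lies outside
    ``primary_special`` (the inbred cat); every site is in C.
    """
    special = frozenset(special)
    primary_special = frozenset(primary_special)
    if not primary_special <= special:
        raise ValueError("primary_special must be a subset of special")
    if known_individuals is not None:
        unknown = special - set(known_individuals)
        if unknown:
            raise ValueError(f"unknown individual name(s) in special: {sorted(unknown)}")
    in_a = np.array([bool(s.discoverers - special) for s in sites], dtype=bool)
    in_b = np.array([bool(s.discoverers - primary_special) for s in sites], dtype=bool)
    return CategoryPartition(
        special=special,
        primary_special=primary_special,
        sites=list(sites),
        in_a=in_a,
        in_b=in_b,
    )


# ---------------------------------------------------------------------------
# Spacing
# ---------------------------------------------------------------------------


def bases_per_snp(non_n_bases: int, snp_count: int) -> int | None:
    """Average SNP spacing, rounded half-up; None when the count is zero."""
    if non_n_bases < 0 or snp_count < 0:
        raise ValueError("inputs must be non-negative")
    if snp_count == 0:
        return None
    return round_half_up(non_n_bases / snp_count)


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


@dataclass
class WindowTable:
    """Fixed-size window SNP counts with undetermined (no-sequence) flags."""

    window: int
    table: pd.DataFrame  # chromosome, start, end, count, non_n_bases, determined
    low_threshold: int
    summary: dict

    def bedgraph_rows(self) -> list[tuple]:
        return [
            (r.chromosome, int(r.start), int(r.end), int(r.count))
            for r in self.table.itertuples()
        ]


def _window_non_n(assembly: ReferenceAssembly, chrom: str, window: int) -> np.ndarray:
    L = assembly.length(chrom)
    n_win = (L + window - 1) // window
    n_bases = np.zeros(n_win, dtype=np.int64)
    for s, e in assembly.n_runs[chrom]:
        first, last = s // window, (e - 1) // window
        for wdx in range(first, last + 1):
            lo = max(s, wdx * window)
            hi = min(e, (wdx + 1) * window)
            n_bases[wdx] += hi - lo
    sizes = np.full(n_win, window, dtype=np.int64)
    sizes[-1] = L - (n_win - 1) * window
    return sizes - n_bases


def window_density(
    sites: Sequence[VariantSite],
    assembly: ReferenceAssembly,
    window: int = 1_000_000,
    low_threshold: int = 100,
) -> WindowTable:
    """SNP counts in adjacent fixed windows tiling each chromosome.

    Windows with zero non-N bases are flagged undetermined; the final partial
    window at a chromosome end is kept as a shorter window.  The summary
    reports determined windows with fewer than ``low_threshold`` sites.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    for chrom in assembly.names:
        L = assembly.length(chrom)
        n_win = (L + window - 1) // window
        pos = np.array([s.pos for s in sites if s.chrom == chrom], dtype=np.int64)
        counts = np.bincount(pos // window, minlength=n_win) if pos.size else np.zeros(
            n_win, dtype=np.int64
        )
        non_n = _window_non_n(assembly, chrom, window)
        for wdx in range(n_win):
            rows.append(
                {
                    "chromosome": chrom,
                    "start": wdx * window,
                    "end": min(L, (wdx + 1) * window),
                    "count": int(counts[wdx]),
                    "non_n_bases": int(non_n[wdx]),
                    "determined": bool(non_n[wdx] > 0),
                }
            )
    table = pd.DataFrame(rows)
    det = table[table.determined]
    summary = {
        "windows": len(table),
        "determined_windows": int(table.determined.sum()),
        "below_threshold": int((det["count"] < low_threshold).sum()),
        "low_threshold": low_threshold,
    }
    return WindowTable(window=window, table=table, low_threshold=low_threshold, summary=summary)


def occupancy_curve(
    sites: Sequence[VariantSite],
    assembly: ReferenceAssembly,
    window_sizes: Sequence[int],
    include_unmapped: bool = False,
) -> pd.DataFrame:
    """Fraction of windows holding >= 1 site, for a range of window sizes.

    Undetermined (all-N) windows are excluded from the denominator unless
    ``include_unmapped`` is set.
    """
    if len(window_sizes) == 0:
        raise ValueError("window_sizes must be non-empty")
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in assembly.names:
        by_chrom[chrom] = np.array(
            sorted(s.pos for s in sites if s.chrom == chrom), dtype=np.int64
        )
    rows = []
    for window in window_sizes:
        if window <= 0:
            raise ValueError("window sizes must be positive")
        occupied = determined = 0
        for chrom in assembly.names:
            L = assembly.length(chrom)
            n_win = (L + window - 1) // window
            pos = by_chrom[chrom]
            counts = (
                np.bincount(pos // window, minlength=n_win)
                if pos.size
                else np.zeros(n_win, dtype=np.int64)
            )
            if include_unmapped:
                det = np.ones(n_win, dtype=bool)
            else:
                det = _window_non_n(assembly, chrom, window) > 0
            determined += int(det.sum())
            occupied += int((counts[det] > 0).sum())
        rows.append(
            {
                "window_size": window,
                "occupied_windows": occupied,
                "determined_windows": determined,
                "fraction": occupied / determined if determined else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Informative fraction
# ---------------------------------------------------------------------------


@dataclass
class InformativeReport:
    total: int
    singletons: int
    multi_cat: int
    singleton_pct: int
    multi_pct: int
    extrapolated: int | None  # nearest thousand


def informative_fraction(
    table: pd.DataFrame,
    restrict_to_domestic: bool = False,
    extrapolation_base: int | None = None,
    domestic: Iterable[str] | None = None,
) -> InformativeReport:
    """Singleton vs multi-cat fractions of genotyped variants, with extrapolation.

    A variant whose alternate allele is observed in exactly one cat may be a
    rare variant; one seen in two or more cats is likely informative
    (MAF >= 5%).  ``table`` needs a ``carriers`` column (cats showing the
    alternate allele) and, when restricting, a ``discovered_in`` column of
    comma-separated discoverer names.  The extrapolated count multiplies the
    whole-percent multi-cat fraction by ``extrapolation_base`` and reports to
    the nearest thousand, matching how the resource's ~849 k figure is formed.
    """
    if len(table) == 0:
        raise ValueError("empty genotype table")
    if "carriers" not in table.columns:
        raise ValueError("genotype table must have a 'carriers' column")
    sub = table
    if restrict_to_domestic:
        if domestic is None:
            raise ValueError("restrict_to_domestic requires the domestic cat set")
        domestic = set(domestic)
        mask = table["discovered_in"].map(
            lambda s: bool(set(str(s).split(",")) & domestic)
        )
        sub = table[mask]
        if len(sub) == 0:
            raise ValueError("no variants discovered from the domestic set")
    total = len(sub)
    singles = int((sub["carriers"] == 1).sum())
    multi = int((sub["carriers"] >= 2).sum())
    singleton_pct = round_half_up(100.0 * singles / total)
    multi_pct = round_half_up(100.0 * multi / total)
    extrapolated = None
    if extrapolation_base is not None:
        extrapolated = (
            round_half_up(multi_pct / 100.0 * extrapolation_base / 1000.0) * 1000
        )
    return InformativeReport(
        total=total,
        singletons=singles,
        multi_cat=multi,
        singleton_pct=singleton_pct,
        multi_pct=multi_pct,
        extrapolated=extrapolated,
    )


# ---------------------------------------------------------------------------
# N50
# ---------------------------------------------------------------------------


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that contigs of length >= L hold half the total bases."""
    if len(lengths) == 0:
        raise ValueError("empty length list")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if (arr <= 0).any():
        raise ValueError("contig lengths must be positive")
    half = arr.sum() / 2.0
    cum = np.cumsum(arr)
    return int(arr[np.searchsorted(cum, half)])


# ---------------------------------------------------------------------------
# Homozygous-tract fraction recovery
# ---------------------------------------------------------------------------


def estimate_homozygous_fraction(
    sites: Sequence[VariantSite],
    individual: str,
    assembly: ReferenceAssembly,
    window: int = 50_000,
) -> float:
    """Estimate the fraction of an individual's genome in homozygous tracts.

    Ratio estimator on fixed windows of the individual's discovered-site
    density: hom_fraction = 1 - overall_density / het_tract_density, where
    the heterozygous-tract density is the non-N-weighted mean over windows
    denser than 0.6x the 90th-percentile window density.  Mixed
    (tract-boundary) windows then contribute in proportion to their het
    content instead of being forced to one side.  Returns NaN when the
    individual discovered nothing.
    """
    counts: list[int] = []
    non_n: list[int] = []
    for chrom in assembly.names:
        L = assembly.length(chrom)
        n_win = (L + window - 1) // window
        pos = np.array(
            [s.pos for s in sites if s.chrom == chrom and individual in s.discoverers],
            dtype=np.int64,
        )
        c = np.bincount(pos // window, minlength=n_win) if pos.size else np.zeros(
            n_win, dtype=np.int64
        )
        counts.extend(int(x) for x in c)
        non_n.extend(int(x) for x in _window_non_n(assembly, chrom, window))
    counts = np.array(counts, dtype=float)
    non_n = np.array(non_n, dtype=float)
    det = non_n > 0
    if counts[det].sum() == 0:
        return float("nan")
    dens = counts[det] / non_n[det]
    cutoff = 0.6 * np.percentile(dens, 90)
    het = dens > cutoff
    if not het.any():
        return float("nan")
    het_density = counts[det][het].sum() / non_n[det][het].sum()
    overall = counts[det].sum() / non_n[det].sum()
    return float(np.clip(1.0 - overall / het_density, 0.0, 1.0))
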