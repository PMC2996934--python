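"""Empirical validation workflow: sampling, testability filter, rates.

Mirrors how a discovered-SNP resource is spot-checked by PCR re-sequencing:
candidates are drawn at random from sites discovered in a chosen set of
individuals, sites too close to an assembly gap to design primers are
dropped (at least 750 bases from any N-run or contig end), and confirmation
rates are computed from the resulting genotype table.  SNP and DIP rates use
deliberately different denominators — SNPs exclude low-quality amplimers,
DIPs count every record falling inside an amplicon — copying the resource's
own arithmetic rather than harmonizing the two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ReferenceAssembly
from .nqs import VariantSite
from .simulate import TruthSet
from .stats import round_half_up

AMPLIMER_STATUSES = ("ok", "low_quality", "not_tested")


@dataclass
class ValidationRecord:
    """One re-sequenced candidate site and its outcome."""

    site: VariantSite | None
    amplimer_status: str  # 'ok' | 'low_quality' | 'not_tested'
    confirmed: bool  # alternate allele observed in a discovering cat

    def __post_init__(self):
        if self.amplimer_status not in AMPLIMER_STATUSES:
            raise ValueError(f"bad amplimer status {self.amplimer_status!r}")
        if self.confirmed and self.amplimer_status != "ok":
            raise ValueError("confirmed is only evaluable when the amplimer is ok")


@dataclass
class RateReport:
    kind: str
    numerator: int
    denominator: int
    pct: int
    excluded: int


def sample_candidates(
    sites: Sequence[VariantSite],
    n: int,
    restrict_to: Iterable[str] | None,
    seed: int,
) -> list[VariantSite]:
    """Uniform sample without replacement from sites discovered in ``restrict_to``.

    Deterministic per seed; raises when fewer than ``n`` sites are eligible.
    Input order is preserved in the sample.
    """
    if restrict_to is None:
        eligible = list(sites)
    else:
        restrict = set(restrict_to)
        eligible = [s for s in sites if s.discoverers & restrict]
    if n > len(eligible):
        raise ValueError(f"requested {n} candidates, only {len(eligible)} eligible")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(eligible), size=n, replace=False))
    return [eligible[int(i)] for i in idx]


def filter_gap_distance(
    sample: Sequence[VariantSite],
    assembly: ReferenceAssembly,
    min_distance: int = 750,
) -> list[VariantSite]:
    """Keep sites at least ``min_distance`` bases from any gap, inclusive.

    Distance is measured from the site position to the nearest N character;
    contig termini count as virtual gaps flanking the sequence, so a site at
    position p is p+1 bases from the left end.
    """
    kept = []
    for site in sample:
        L = assembly.length(site.chrom)
        p = site.pos
        d = min(p + 1, L - p)
        for s, e in assembly.n_runs[site.chrom]:
            if p < s:
                d = min(d, s - p)
            elif p >= e:
                d = min(d, p - e + 1)
            else:
                d = 0
        if d >= min_distance:
            kept.append(site)
    return kept


def confirmation_rate(records: Sequence[ValidationRecord], kind: str = "SNP") -> RateReport:
    """Validation rate as a whole percentage.

    SNP mode: denominator counts records with an ok amplimer (low-quality
    excluded), numerator counts confirmed.  DIP mode: denominator counts all
    records falling in amplicons, including untested ones.
    """
    if len(records) == 0:
        raise ValueError("empty record list")
    if kind == "SNP":
        ok = [r for r in records if r.amplimer_status == "ok"]
        num = sum(r.confirmed for r in ok)
        den = len(ok)
        excluded = len(records) - den
    elif kind == "DIP":
        num = sum(r.confirmed for r in records)
        den = len(records)
        excluded = 0
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if den == 0:
        raise ValueError("no evaluable records")
    return RateReport(
        kind=kind,
        numerator=int(num),
        denominator=den,
        pct=round_half_up(100.0 * num / den),
        excluded=excluded,
    )


def score_against_truth(
    sample: Sequence[VariantSite], truth: TruthSet
) -> list[ValidationRecord]:
    """Score candidates as an error-free re-sequencing assay would.

    A site is confirmed when the truth catalog holds the same variant and
    some discovering cat truly carries the alternate allele.
    """
    index = {}
    for chrom, variants in truth.variants.items():
        for v in variants:
            index[(chrom, v.pos, v.vtype, v.alt)] = v
    records = []
    for site in sample:
        v = index.get(site.key)
        confirmed = v is not None and any(v.carried_by(name) for name in site.discoverers)
        records.append(
            ValidationRecord(site=site, amplimer_status="ok", confirmed=confirmed)
        )
    return records


def records_from_table(table: pd.DataFrame) -> list[ValidationRecord]:
    """Build records from a genotype TSV with 'status' and 'confirmed' columns."""
    records = []
    for row in table.itertuples():
        records.append(
            ValidationRecord(
                site=None,
                amplimer_status=str(row.status),
                confirmed=bool(int(row.confirmed)),
            )
        )
    return records


def records_from_counts(
    confirmed: int = 0, unconfirmed: int = 0, low_quality: int = 0, not_tested: int = 0
) -> list[ValidationRecord]:
    """Expand tally counts into a record list (order: confirmed first)."""
    return (
        [ValidationRecord(None, "ok", True) for _ in range(confirmed)]
        + [ValidationRecord(None, "ok", False) for _ in range(unconfirmed)]
        + [ValidationRecord(None, "low_quality", False) for _ in range(low_quality)]
        + [ValidationRecord(None, "not_tested", False) for _ in range(not_tested)]
    )
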