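"""Synthetic genomes, populations and Sanger-style fosmid paired-end reads.

The generator emulates the study design behind the feline SNP resource: a
consensus genome with N-gap runs; six domestic breed cats heterozygous at
~1 site per 600 bp; one deeply inbred cat (Cinnamon) whose genome is a mosaic
of homozygous and heterozygous tracts with a ~60% homozygous stationary
fraction; and one African wildcat (Nancy) carrying the shared domestic
polymorphism plus private fixed divergence.  Reads are ~700 bp paired Sanger
traces from ~37 kb fosmid inserts (<10% CV), with PHRED-scored bases and
sequencing errors injected at the rate the qualities imply.

Every simulated read carries its true gapped alignment to the reference, and
every injected error is recorded, so downstream calling can be scored against
an exact truth catalog with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import beta as beta_dist

from .io import (
    AlignedRead,
    ReferenceAssembly,
    VcfRecord,
    child_seed,
    ensure_dir,
    site_to_vcf_alleles,
    write_fasta,
    write_fastq,
    write_sam,
    write_vcf,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Minimum spacing between simulated variant sites, and the margin kept clear
#: around N-runs and chromosome ends.  Chosen to exceed the 11-base NQS
#: neighborhood so no two truth variants share a neighborhood.
SITE_MARGIN = 12

#: Per-class sequencing depth defaults, scaled from the study's per-cat read
#: counts (~700 bp reads against a 2.5 Gb genome): six lightly sequenced
#: domestic cats, a moderately sequenced wildcat and the deeply sequenced
#: inbred assembly cat.  Together ~3.2x, the study's total redundancy.
DEFAULT_CLASS_COVERAGE = {"domestic": 0.085, "wildcat": 0.38, "inbred": 2.29}


@dataclass(frozen=True)
class Individual:
    name: str
    sex: str  # 'F' or 'M'
    klass: str  # 'domestic' | 'inbred' | 'wildcat'


DEFAULT_INDIVIDUALS = (
    Individual("Pixel", "F", "domestic"),
    Individual("Zeelie", "F", "domestic"),
    Individual("Tipper", "M", "domestic"),
    Individual("Scooter", "M", "domestic"),
    Individual("Speedy", "F", "domestic"),
    Individual("Cocoa", "F", "domestic"),
    Individual("Nancy", "F", "wildcat"),
    Individual("Cinnamon", "F", "inbred"),
)

DEFAULT_CHROMOSOME_PLAN = (
    ("chrA1", 2_500_000, False),
    ("chrB1", 2_000_000, False),
    ("chrX", 500_000, True),
)


@dataclass
class PopulationModel:
    """Population structure and polymorphism rates of the simulated cats."""

    chromosome_plan: Sequence[tuple[str, int, bool]] = DEFAULT_CHROMOSOME_PLAN
    gap_mean_length: float = 500.0
    gap_start_prob: float = 1e-5
    domestic_het_rate: float = 1.0 / 600.0
    wildcat_extra_rate: float = 1.0 / 900.0
    inbred_homozygous_fraction: float = 0.60
    inbred_tract_mean_length: float = 500_000.0
    dip_fraction: float = 0.22  # DIP site density relative to shared SNP sites
    allele_freq_alpha: float = 0.5
    allele_freq_beta: float = 0.5
    individuals: Sequence[Individual] = DEFAULT_INDIVIDUALS
    consensus_from: str | None = None

    def __post_init__(self):
        self.individuals = tuple(
            Individual(*i) if not isinstance(i, Individual) else i
            for i in self.individuals
        )
        self.chromosome_plan = tuple(tuple(c) for c in self.chromosome_plan)
        for name, length, _ in self.chromosome_plan:
            if length <= 0:
                raise ValueError(f"non-positive length for {name}")
        for rate in (
            self.domestic_het_rate,
            self.wildcat_extra_rate,
            self.gap_start_prob,
        ):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"per-base rate outside [0,1): {rate}")
        if not 0.0 <= self.inbred_homozygous_fraction <= 1.0:
            raise ValueError("inbred_homozygous_fraction outside [0,1]")
        if self.dip_fraction < 0:
            raise ValueError("dip_fraction must be non-negative")
        names = [i.name for i in self.individuals]
        if len(set(names)) != len(names):
            raise ValueError("duplicate individual names")

    @property
    def genome_length(self) -> int:
        return sum(length for _, length, _ in self.chromosome_plan)

    def n_haplotypes(self, individual: Individual, is_x: bool) -> int:
        return 1 if (is_x and individual.sex == "M") else 2

    def by_class(self, klass: str) -> list[Individual]:
        return [i for i in self.individuals if i.klass == klass]

    def het_factor(self) -> float:
        """E[2p(1-p)] under the discretized Beta allele-frequency model.

        Shared polymorphic sites are placed at density het_rate / this factor
        so the expected per-individual heterozygosity equals the target rate.
        """
        n_hap = 2 * len(self.individuals)  # attainable frequency grid
        k = np.arange(1, n_hap)
        edges = (np.arange(n_hap + 1) - 0.5) / n_hap
        cdf = beta_dist.cdf(
            np.clip(edges, 0, 1), self.allele_freq_alpha, self.allele_freq_beta
        )
        mass = cdf[2:] - cdf[1:-1]
        mass[0] += cdf[1]
        mass[-1] += 1.0 - cdf[-1]
        mass /= mass.sum()
        f = k / n_hap
        return float(np.sum(mass * 2.0 * f * (1.0 - f)))

    def draw_frequency(self, rng: np.random.Generator, n: int) -> np.ndarray:
        n_hap = 2 * len(self.individuals)
        p = rng.beta(self.allele_freq_alpha, self.allele_freq_beta, size=n)
        k = np.clip(np.rint(p * n_hap), 1, n_hap - 1)
        return k / n_hap


@dataclass
class ReadModel:
    """Sanger-style fosmid paired-end read generator parameters."""

    read_length_mean: float = 700.0
    read_length_sd: float = 50.0
    read_length_min: int = 100
    read_length_max: int = 1000
    insert_mean: float = 37_000.0
    insert_cv: float = 0.08
    q_plateau: int = 40
    q_floor: int = 10
    q_ramp: float = 30.0  # read-end positions over which quality decays
    inject_errors: bool = True
    coverage: float | Mapping[str, float] | None = None

    def __post_init__(self):
        if not self.insert_cv < 0.10:
            raise ValueError("insert_cv must be < 0.10")
        for q in (self.q_plateau, self.q_floor):
            if not 0 <= q <= 60:
                raise ValueError("qualities must lie in [0, 60]")
        if self.read_length_min <= 11:
            raise ValueError(
                "minimum read length must exceed the NQS neighborhood (11 bases)"
            )
        self._profiles: dict[int, np.ndarray] = {}

    def coverage_for(self, individual: Individual) -> float:
        if self.coverage is None:
            return DEFAULT_CLASS_COVERAGE[individual.klass]
        if isinstance(self.coverage, Mapping):
            return float(self.coverage[individual.name])
        return float(self.coverage)

    def quality_profile(self, length: int) -> np.ndarray:
        """PHRED profile: plateau mid-read, logistic decay toward both ends."""
        cached = self._profiles.get(length)
        if cached is not None:
            return cached
        i = np.arange(length, dtype=float)
        s = self.q_ramp / 4.0
        left = 1.0 / (1.0 + np.exp(-(i - self.q_ramp) / s))
        right = 1.0 / (1.0 + np.exp(-((length - 1 - i) - self.q_ramp) / s))
        q = self.q_floor + (self.q_plateau - self.q_floor) * left * right
        prof = np.clip(np.rint(q), 2, 60).astype(np.uint8)
        self._profiles[length] = prof
        return prof


@dataclass
class TruthVariant:
    """A truth catalog entry; ``pos`` is 0-based (anchor base for DIPs)."""

    pos: int
    vtype: str  # 'SNP' | 'DIP'
    ref: str
    alt: str
    genotypes: dict[str, tuple[int, ...]]  # per-individual hap allele codes

    def carried_by(self, name: str) -> bool:
        return any(self.genotypes.get(name, ()))


class HaplotypeMap:
    """One haplotype sequence plus its block map to reference coordinates.

    Blocks are maximal gap-free match segments: parallel arrays of haplotype
    start, reference start and length.  Between consecutive blocks lies a
    pure insertion (haplotype-only bases) and/or deletion (reference-only).
    """

    def __init__(self, seq: str, hap_starts, ref_starts, lengths):
        self.seq = seq
        self.hs = np.asarray(hap_starts, dtype=np.int64)
        self.rs = np.asarray(ref_starts, dtype=np.int64)
        self.ln = np.asarray(lengths, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.seq)

    def extract(self, a: int, b: int) -> tuple[int, int, int, list[tuple[str, int]]]:
        """Alignment of haplotype interval [a, b) to the reference.

        Returns (a', b', ref_start, cigar).  The interval is trimmed so the
        alignment starts and ends on aligned (M) bases: leading bases that
        fall inside an insertion are skipped, trailing insertion bases are
        dropped.
        """
        if not 0 <= a < b <= len(self.seq):
            raise ValueError(f"haplotype interval [{a},{b}) out of range")
        i = int(np.searchsorted(self.hs, a, side="right")) - 1
        if i < 0:
            i, a = 0, int(self.hs[0])
        if a >= self.hs[i] + self.ln[i]:  # starts inside an insertion
            i += 1
            if i >= len(self.hs):
                raise ValueError("interval lies entirely in an insertion")
            a = int(self.hs[i])
        if a >= b:
            raise ValueError("interval collapsed to nothing after trimming")
        ref_start = int(self.rs[i] + (a - self.hs[i]))
        cigar: list[tuple[str, int]] = []
        cur, j = a, i
        while cur < b:
            block_end = int(self.hs[j] + self.ln[j])
            m = min(b, block_end) - cur
            if m > 0:
                cigar.append(("M", m))
                cur += m
            if cur >= b or j + 1 >= len(self.hs):
                break
            ins = int(self.hs[j + 1]) - block_end
            dele = int(self.rs[j + 1]) - int(self.rs[j] + self.ln[j])
            if ins > 0:
                take = min(ins, b - cur)
                cigar.append(("I", take))
                cur += take
                if cur >= b:
                    break
            if dele > 0:
                cigar.append(("D", dele))
            j += 1
        while cigar and cigar[-1][0] != "M":  # never end on a gap
            op, n = cigar.pop()
            if op == "I":
                cur -= n
        return a, cur, ref_start, cigar


@dataclass
class SimulatedRead(AlignedRead):
    """AlignedRead plus simulation provenance (recorded errors, origin)."""

    hap_index: int = 0
    mate: int = 1
    errors: list[tuple[int, str, str]] = field(default_factory=list)


@dataclass
class TruthSet:
    """Reference, per-individual haplotypes and the ground-truth catalog."""

    model: PopulationModel
    reference: ReferenceAssembly
    variants: dict[str, list[TruthVariant]]
    haplotypes: dict[tuple[str, str], list[HaplotypeMap]]
    hom_tracts: dict[str, list[tuple[int, int]]]
    seed: int

    @property
    def inbred_name(self) -> str | None:
        inbred = self.model.by_class("inbred")
        return inbred[0].name if inbred else None

    def truth_homozygous_fraction(self) -> float:
        """Realized fraction of the genome inside the inbred cat's hom tracts."""
        total = self.reference.total_length
        hom = sum(e - s for runs in self.hom_tracts.values() for s, e in runs)
        return hom / total if total else float("nan")

    def variant_count(self, name: str | None = None, vtype: str | None = None) -> int:
        n = 0
        for variants in self.variants.values():
            for v in variants:
                if vtype is not None and v.vtype != vtype:
                    continue
                if name is None or v.carried_by(name):
                    n += 1
        return n

    def het_site_count(self, name: str, vtype: str | None = None) -> int:
        n = 0
        for variants in self.variants.values():
            for v in variants:
                if vtype is not None and v.vtype != vtype:
                    continue
                g = v.genotypes.get(name, ())
                if len(set(g)) > 1:
                    n += 1
        return n

    def alt_site_keys(self, name: str | None = None, vtype: str | None = None):
        """Set of (chrom, pos, vtype, alt) keys carried by ``name`` (or anyone)."""
        keys = set()
        for chrom, variants in self.variants.items():
            for v in variants:
                if vtype is not None and v.vtype != vtype:
                    continue
                if name is None:
                    if any(any(g) for g in v.genotypes.values()):
                        keys.add((chrom, v.pos, v.vtype, v.alt))
                elif v.carried_by(name):
                    keys.add((chrom, v.pos, v.vtype, v.alt))
        return keys


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------


def _simulate_reference_chrom(
    length: int, model: PopulationModel, rng: np.random.Generator
) -> np.ndarray:
    seq = _BASES[rng.integers(0, 4, size=length)]
    n_gaps = rng.poisson(length * model.gap_start_prob)
    if n_gaps:
        starts = np.sort(rng.integers(0, length, size=n_gaps))
        lengths = rng.geometric(1.0 / model.gap_mean_length, size=n_gaps)
        for s, ln in zip(starts, lengths):
            seq[s : min(length, s + int(ln))] = ord("N")
    return seq


def _hom_tracts(
    length: int, model: PopulationModel, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Two-state tract process conditioned on its realized fraction.

    Tract lengths are geometric with the configured homozygous mean (the
    heterozygous mean follows from the stationary fraction).  Because the
    genome-wide homozygous fraction is a defining condition rather than an
    output, the mosaic is redrawn up to a fixed number of times and the
    realization closest to the configured fraction is kept (stopping early
    once within 0.025).
    """
    f = model.inbred_homozygous_fraction
    if f <= 0.0:
        return []
    if f >= 1.0:
        return [(0, length)]
    mean_hom = model.inbred_tract_mean_length
    mean_het = mean_hom * (1.0 - f) / f
    best: list[tuple[int, int]] = []
    best_err = float("inf")
    for _ in range(300):
        tracts = []
        pos = 0
        hom = bool(rng.random() < f)
        while pos < length:
            mean = mean_hom if hom else mean_het
            ln = int(rng.geometric(1.0 / mean))
            end = min(length, pos + ln)
            if hom:
                tracts.append((pos, end))
            pos = end
            hom = not hom
        frac = sum(e - s for s, e in tracts) / length
        err = abs(frac - f)
        if err < best_err:
            best, best_err = tracts, err
        if best_err <= 0.025:
            break
    return best


def _site_positions(
    n: int,
    length: int,
    n_runs: list[tuple[int, int]],
    rng: np.random.Generator,
) -> np.ndarray:
    """~n well-separated positions away from N-runs and chromosome ends."""
    if n <= 0 or length <= 4 * SITE_MARGIN:
        return np.empty(0, dtype=np.int64)
    cand = rng.integers(SITE_MARGIN, length - SITE_MARGIN, size=int(n * 1.6) + 32)
    cand = np.unique(cand)
    if n_runs:
        starts = np.array([s for s, _ in n_runs])
        ends = np.array([e for _, e in n_runs])
        idx = np.searchsorted(ends + SITE_MARGIN, cand, side="right")
        near = np.zeros(cand.size, dtype=bool)
        ok = idx < len(starts)
        near[ok] = cand[ok] >= starts[idx[ok]] - SITE_MARGIN
        cand = cand[~near]
    keep = np.ones(cand.size, dtype=bool)
    keep[1:] = np.diff(cand) >= SITE_MARGIN
    cand = cand[keep]  # one pass suffices: survivors of a cluster are spaced
    while True:  # re-check separation after removals
        gaps = np.diff(cand)
        bad = np.flatnonzero(gaps < SITE_MARGIN)
        if bad.size == 0:
            break
        keep = np.ones(cand.size, dtype=bool)
        keep[bad + 1] = False
        cand = cand[keep]
    rng.shuffle(cand)
    cand = cand[:n]
    return np.sort(cand)


def simulate_population(model: PopulationModel, seed: int) -> TruthSet:
    """Generate reference, haplotypes and the ground-truth variant catalog.

    Deterministic for a fixed seed; per-individual randomness is drawn from
    independent hash-derived streams, so adding or removing one individual
    does not perturb the genomes of the others.
    """
    het_factor = model.het_factor()
    shared_snp_rate = model.domestic_het_rate / het_factor if het_factor else 0.0
    shared_dip_rate = model.dip_fraction * shared_snp_rate
    has_wildcat = bool(model.by_class("wildcat"))
    wild_rate = model.wildcat_extra_rate if has_wildcat else 0.0
    rates = np.array([shared_snp_rate, shared_dip_rate, wild_rate])
    total_rate = rates.sum()

    sequences: dict[str, np.ndarray] = {}
    all_variants: dict[str, list[TruthVariant]] = {}
    haplotypes: dict[tuple[str, str], list[HaplotypeMap]] = {}
    hom_tracts: dict[str, list[tuple[int, int]]] = {}

    inbred = model.by_class("inbred")
    inbred_name = inbred[0].name if inbred else None

    for chrom, length, is_x in model.chromosome_plan:
        rng_ref = np.random.default_rng(child_seed(seed, "reference", chrom))
        ref_u8 = _simulate_reference_chrom(length, model, rng_ref)
        n_runs = _runs_from_u8(ref_u8)

        rng_sites = np.random.default_rng(child_seed(seed, "sites", chrom))
        n_sites = rng_sites.poisson(length * total_rate) if total_rate > 0 else 0
        pos = _site_positions(n_sites, length, n_runs, rng_sites)
        n = pos.size
        if total_rate > 0 and n:
            kinds = rng_sites.choice(3, size=n, p=rates / total_rate)
        else:
            kinds = np.empty(0, dtype=np.int64)
        freqs = model.draw_frequency(rng_sites, n)

        vtypes: list[str] = []
        refs: list[str] = []
        alts: list[str] = []
        for k, p in zip(kinds, pos):
            if k == 1:  # DIP, anchored at p
                ln = int(rng_sites.choice([1, 2, 3], p=[0.6, 0.3, 0.1]))
                if rng_sites.random() < 0.5:  # deletion
                    deleted = ref_u8[p + 1 : p + 1 + ln].tobytes().decode()
                    vtypes.append("DIP")
                    refs.append(deleted)
                    alts.append("")
                else:
                    ins = _BASES[rng_sites.integers(0, 4, size=ln)].tobytes().decode()
                    vtypes.append("DIP")
                    refs.append("")
                    alts.append(ins)
            else:  # SNP (shared or wildcat-private)
                ref_base = chr(ref_u8[p])
                others = [b for b in "ACGT" if b != ref_base]
                vtypes.append("SNP")
                refs.append(ref_base)
                alts.append(others[int(rng_sites.integers(0, 3))])

        # Per-individual genotype draws from independent streams.
        geno: dict[str, np.ndarray] = {}
        for ind in model.individuals:
            rng_g = np.random.default_rng(
                child_seed(seed, "genotypes", chrom, ind.name)
            )
            n_h = model.n_haplotypes(ind, is_x)
            g = (rng_g.random((n, n_h)) < freqs[:, None]).astype(np.uint8)
            wild_rows = kinds == 2
            if ind.klass == "wildcat":
                g[wild_rows] = 1  # fixed subspecies divergence
            else:
                g[wild_rows] = 0
            if ind.klass == "inbred":
                rng_t = np.random.default_rng(
                    child_seed(seed, "tracts", ind.name, chrom)
                )
                tracts = _hom_tracts(length, model, rng_t)
                hom_tracts[chrom] = tracts
                if tracts and n:
                    starts = np.array([s for s, _ in tracts])
                    ends = np.array([e for _, e in tracts])
                    idx = np.searchsorted(ends, pos, side="right")
                    in_hom = np.zeros(n, dtype=bool)
                    ok = idx < len(starts)
                    in_hom[ok] = pos[ok] >= starts[idx[ok]]
                    g[in_hom] = 0  # het sites only inside het tracts
            geno[ind.name] = g
        if inbred_name is not None and chrom not in hom_tracts:
            hom_tracts[chrom] = []

        # Optional consensus substitution: re-base SNPs onto one individual's
        # haplotype mosaic to emulate an assembly dominated by that cat.
        if model.consensus_from is not None:
            cname = model.consensus_from
            if cname not in geno:
                raise ValueError(f"consensus_from names unknown individual {cname}")
            rng_c = np.random.default_rng(child_seed(seed, "consensus", chrom))
            g_c = geno[cname]
            if n:
                hap_pick = rng_c.integers(0, g_c.shape[1], size=n)
                chosen = g_c[np.arange(n), hap_pick] == 1
                for i in np.flatnonzero(chosen):
                    if vtypes[i] == "SNP":
                        ref_u8[pos[i]] = ord(alts[i])
                        refs[i], alts[i] = alts[i], refs[i]
                        for g in geno.values():
                            g[i] = 1 - g[i]
                    else:
                        # DIP re-basing is not modeled; the consensus keeps the
                        # founder allele and the donor drops this DIP instead.
                        g_c[i] = 0

        # Drop sites nobody carries; freeze the catalog.
        if n:
            carried = np.zeros(n, dtype=bool)
            for g in geno.values():
                carried |= g.any(axis=1)
        else:
            carried = np.zeros(0, dtype=bool)
        keep_idx = np.flatnonzero(carried)
        variants = [
            TruthVariant(
                pos=int(pos[i]),
                vtype=vtypes[i],
                ref=refs[i],
                alt=alts[i],
                genotypes={
                    name: tuple(int(a) for a in g[i]) for name, g in geno.items()
                },
            )
            for i in keep_idx
        ]
        all_variants[chrom] = variants
        sequences[chrom] = ref_u8

        for ind in model.individuals:
            n_h = model.n_haplotypes(ind, is_x)
            haplotypes[(ind.name, chrom)] = [
                _build_haplotype(ref_u8, variants, ind.name, h) for h in range(n_h)
            ]

    reference = ReferenceAssembly(
        {chrom: seq.tobytes().decode() for chrom, seq in sequences.items()}
    )
    return TruthSet(
        model=model,
        reference=reference,
        variants=all_variants,
        haplotypes=haplotypes,
        hom_tracts=hom_tracts,
        seed=seed,
    )


def _runs_from_u8(u8: np.ndarray) -> list[tuple[int, int]]:
    from .io import _runs_of

    return _runs_of(u8 == ord("N"))


def _build_haplotype(
    ref_u8: np.ndarray, variants: list[TruthVariant], name: str, hap: int
) -> HaplotypeMap:
    arr = ref_u8.copy()
    indels: list[TruthVariant] = []
    for v in variants:
        g = v.genotypes.get(name, ())
        if hap >= len(g) or g[hap] == 0:
            continue
        if v.vtype == "SNP":
            arr[v.pos] = ord(v.alt)
        else:
            indels.append(v)
    L = len(arr)
    parts: list[bytes] = []
    hs, rs, ln = [], [], []
    hap_pos, ref_pos = 0, 0
    for v in indels:
        cut = v.pos + 1  # include the anchor base in the preceding block
        seg = arr[ref_pos:cut].tobytes()
        parts.append(seg)
        hs.append(hap_pos)
        rs.append(ref_pos)
        ln.append(cut - ref_pos)
        hap_pos += cut - ref_pos
        if v.ref:  # deletion of len(v.ref) reference bases
            ref_pos = cut + len(v.ref)
        else:  # insertion of v.alt after the anchor
            parts.append(v.alt.encode())
            hap_pos += len(v.alt)
            ref_pos = cut
    parts.append(arr[ref_pos:].tobytes())
    hs.append(hap_pos)
    rs.append(ref_pos)
    ln.append(L - ref_pos)
    return HaplotypeMap(b"".join(parts).decode(), hs, rs, ln)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    truth: TruthSet, read_model: ReadModel, seed: int
) -> list[SimulatedRead]:
    """Draw fosmid paired-end reads from random haplotypes.

    Reads are emitted in reference orientation with their true gapped
    alignment; sequencing errors are injected per base at 10^(-q/10) and
    recorded on the read.  Deterministic for a fixed seed.
    """
    model = truth.model
    ref = truth.reference
    chrom_info = [(c, length, is_x) for c, length, is_x in model.chromosome_plan]
    eligible = [(c, length, is_x) for c, length, is_x in chrom_info
                if length >= read_model.insert_mean]
    if not eligible:
        raise ValueError(
            f"insert mean {read_model.insert_mean} exceeds every chromosome length"
        )
    weights = np.array([length for _, length, _ in eligible], dtype=float)
    weights /= weights.sum()
    total_len = ref.total_length

    reads: list[SimulatedRead] = []
    for ind in model.individuals:
        cov = read_model.coverage_for(ind)
        n_pairs = int(round(cov * total_len / (2.0 * read_model.read_length_mean)))
        rng = np.random.default_rng(child_seed(seed, "reads", ind.name))
        if n_pairs <= 0:
            continue
        chrom_idx = rng.choice(len(eligible), size=n_pairs, p=weights)
        inserts = rng.normal(
            read_model.insert_mean,
            read_model.insert_cv * read_model.insert_mean,
            size=n_pairs,
        )
        lens = rng.normal(
            read_model.read_length_mean, read_model.read_length_sd, size=(n_pairs, 2)
        )
        lens = np.clip(
            np.rint(lens), read_model.read_length_min, read_model.read_length_max
        ).astype(int)
        for k in range(n_pairs):
            chrom, _, is_x = eligible[chrom_idx[k]]
            maps = truth.haplotypes[(ind.name, chrom)]
            hap_i = int(rng.integers(0, len(maps)))
            hap = maps[hap_i]
            L1, L2 = int(lens[k, 0]), int(lens[k, 1])
            ins = int(round(inserts[k]))
            ins = max(ins, L1 + L2)
            ins = min(ins, len(hap))
            start = int(rng.integers(0, len(hap) - ins + 1))
            pair_id = f"{ind.name}_{k:07d}"
            for mate, (a, b, strand) in enumerate(
                [(start, start + L1, "+"), (start + ins - L2, start + ins, "-")],
                start=1,
            ):
                read = _make_read(
                    hap, hap_i, a, b, strand, mate, pair_id, chrom, ind.name,
                    read_model, rng,
                )
                if read is not None:
                    reads.append(read)
    return reads


def _make_read(
    hap: HaplotypeMap,
    hap_i: int,
    a: int,
    b: int,
    strand: str,
    mate: int,
    pair_id: str,
    chrom: str,
    individual: str,
    read_model: ReadModel,
    rng: np.random.Generator,
) -> SimulatedRead | None:
    a2, b2, ref_start, cigar = hap.extract(a, b)
    if b2 - a2 < read_model.read_length_min or not cigar:
        return None
    seq = np.frombuffer(hap.seq[a2:b2].encode("ascii"), dtype=np.uint8).copy()
    L = len(seq)
    quals = read_model.quality_profile(L)
    if strand == "-":
        quals = quals[::-1]
    errors: list[tuple[int, str, str]] = []
    if read_model.inject_errors:
        p_err = np.power(10.0, -quals.astype(float) / 10.0)
        hits = np.flatnonzero(rng.random(L) < p_err)
        for i in hits:
            orig = seq[i]
            if orig == ord("N"):
                continue
            choices = _BASES[_BASES != orig]
            new = choices[int(rng.integers(0, 3))]
            seq[i] = new
            errors.append((int(i), chr(orig), chr(new)))
    return SimulatedRead(
        read_id=f"{pair_id}/{mate}",
        individual=individual,
        chrom=chrom,
        start=ref_start,
        strand=strand,
        seq=seq.tobytes().decode(),
        quals=quals.copy(),
        cigar=cigar,
        hap_index=hap_i,
        mate=mate,
        errors=errors,
    )


# ---------------------------------------------------------------------------
# Truth output
# ---------------------------------------------------------------------------


def truth_vcf_records(truth: TruthSet) -> tuple[list[VcfRecord], list[str]]:
    samples = [i.name for i in truth.model.individuals]
    records: list[VcfRecord] = []
    for chrom in truth.reference.names:
        for v in truth.variants.get(chrom, []):
            pos, ref, alt = site_to_vcf_alleles(
                truth.reference, chrom, v.pos, v.vtype, v.ref, v.alt
            )
            gts = ["/".join(str(a) for a in v.genotypes[s]) for s in samples]
            records.append(
                VcfRecord(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    info={"TYPE": v.vtype},
                    gts=gts,
                )
            )
    return records, samples


def write_truth(
    truth: TruthSet, out_dir, reads: Sequence[SimulatedRead] | None = None
) -> dict[str, str]:
    """Write reference FASTA and truth VCF (and reads as FASTQ + SAM if given)."""
    out = ensure_dir(out_dir)
    paths = {
        "reference": str(out / "reference.fasta"),
        "truth_vcf": str(out / "truth.vcf"),
    }
    write_fasta(truth.reference, paths["reference"])
    records, samples = truth_vcf_records(truth)
    contigs = {n: truth.reference.length(n) for n in truth.reference.names}
    write_vcf(records, paths["truth_vcf"], contigs=contigs, samples=samples)
    if reads is not None:
        paths["fastq"] = str(out / "reads.fastq")
        paths["sam"] = str(out / "alignments.sam")
        write_fastq(reads, paths["fastq"])
        write_sam(reads, truth.reference, paths["sam"])
    return paths
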