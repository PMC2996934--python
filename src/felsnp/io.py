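"""Standard-format readers/writers and the coordinate plumbing shared by all stages.

Every coordinate is 0-based, half-open inside the package.  SAM and VCF are
emitted 1-based per their own specifications; BED and bedGraph stay 0-based
half-open.  FASTA is read through Biopython and SAM through pysam; the VCF,
FASTQ, BED and bedGraph writers are deterministic plain-text emitters so that
two runs at the same seed produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_N = ord("N")
_VALID = frozenset(b"ACGTN")

CIGAR_OPS = "MID"
_PYSAM_OP = {"M": 0, "I": 1, "D": 2}
_PYSAM_OP_INV = {0: "M", 1: "I", 2: "D"}


def child_seed(seed: int, *tags) -> int:
    """Derive a stable 31-bit child seed from a global seed and a tag path.

    Stable hashing (not spawn order) so that adding an individual or a stage
    never perturbs the random stream of another.
    """
    key = ":".join([str(seed), *map(str, tags)]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") & 0x7FFFFFFF


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """0-based half-open runs of True in a boolean vector."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


class ReferenceAssembly:
    """Consensus contigs with indexed N-gap runs and non-N base tallies.

    Sequences are uppercase-normalized on construction.  N-runs are stored as
    sorted, disjoint 0-based half-open intervals per chromosome, and the non-N
    count always equals length minus the summed N-run lengths.
    """

    def __init__(self, sequences: Mapping[str, str], strict: bool = True):
        self.names: list[str] = []
        self.sequences: dict[str, str] = {}
        self._u8: dict[str, np.ndarray] = {}
        self.n_runs: dict[str, list[tuple[int, int]]] = {}
        self.non_n: dict[str, int] = {}
        for name, seq in sequences.items():
            if name in self.sequences:
                raise ValueError(f"duplicate sequence name: {name}")
            seq = seq.upper()
            u8 = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            if strict:
                bad = set(np.unique(u8).tobytes()) - _VALID
                if bad:
                    raise ValueError(
                        f"non-IUPAC characters in {name}: {sorted(chr(b) for b in bad)}"
                    )
            self.names.append(name)
            self.sequences[name] = seq
            self._u8[name] = u8
            runs = _runs_of(u8 == _N)
            self.n_runs[name] = runs
            self.non_n[name] = len(seq) - sum(e - s for s, e in runs)

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    def seq_u8(self, name: str) -> np.ndarray:
        """Sequence as a uint8 array (read-only view semantics)."""
        return self._u8[name]

    @property
    def total_length(self) -> int:
        return sum(map(len, self.sequences.values()))

    @property
    def total_non_n(self) -> int:
        return sum(self.non_n.values())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ReferenceAssembly)
            and self.names == other.names
            and self.sequences == other.sequences
        )


def read_fasta(path, strict: bool = True) -> ReferenceAssembly:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence name: {rec.id}")
        seqs[rec.id] = str(rec.seq)
    return ReferenceAssembly(seqs, strict=strict)


def write_fasta(assembly: ReferenceAssembly, path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(assembly.sequences[name]), id=name, description="")
        for name in assembly.names
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Aligned reads
# ---------------------------------------------------------------------------


@dataclass
class AlignedRead:
    """One individual's read with PHRED qualities and a gapped alignment.

    ``start`` is the 0-based reference position of the first aligned base;
    ``cigar`` is a list of (op, length) with op in {M, I, D}.  ``seq`` is
    stored in reference orientation; ``strand`` records the physical trace
    orientation.
    """

    read_id: str
    individual: str
    chrom: str
    start: int
    strand: str
    seq: str
    quals: np.ndarray  # uint8, PHRED
    cigar: list[tuple[str, int]]

    def __post_init__(self):
        self.quals = np.asarray(self.quals, dtype=np.uint8)
        read_len = sum(n for op, n in self.cigar if op in "MI")
        if read_len != len(self.seq):
            raise ValueError(
                f"{self.read_id}: CIGAR consumes {read_len} read bases, "
                f"sequence has {len(self.seq)}"
            )
        if len(self.quals) != len(self.seq):
            raise ValueError(f"{self.read_id}: quality/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def end(self) -> int:
        """0-based exclusive reference end."""
        return self.start + self.ref_span

    def seq_u8(self) -> np.ndarray:
        u8 = getattr(self, "_seq_u8", None)
        if u8 is None:
            u8 = np.frombuffer(self.seq.encode("ascii"), dtype=np.uint8)
            self._seq_u8 = u8
        return u8

    def expand(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-read-base (reference position, M-run id) arrays.

        Insertion bases get reference position -1 and run id -1.  Each M
        operation gets its own run id, so a gap between two M runs always
        changes the id.
        """
        cached = getattr(self, "_expanded", None)
        if cached is not None:
            return cached
        L = len(self.seq)
        refpos = np.full(L, -1, dtype=np.int64)
        runid = np.full(L, -1, dtype=np.int32)
        r, p, run = 0, self.start, 0
        for op, n in self.cigar:
            if op == "M":
                refpos[r : r + n] = np.arange(p, p + n)
                runid[r : r + n] = run
                run += 1
                r += n
                p += n
            elif op == "I":
                r += n
            elif op == "D":
                p += n
            else:  # pragma: no cover - constructor rejects these
                raise ValueError(f"unsupported CIGAR op {op}")
        self._expanded = (refpos, runid)
        return self._expanded

    def m_intervals(self) -> list[tuple[int, int]]:
        """Reference intervals covered by M operations (0-based half-open)."""
        out = []
        p = self.start
        for op, n in self.cigar:
            if op == "M":
                out.append((p, p + n))
                p += n
            elif op == "D":
                p += n
        return out


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def _sam_header(assembly: ReferenceAssembly, individuals: Sequence[str]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": assembly.length(n)} for n in assembly.names],
        "RG": [{"ID": ind, "SM": ind} for ind in individuals],
    }


def write_sam(reads: Sequence[AlignedRead], assembly: ReferenceAssembly, path) -> None:
    individuals = sorted({r.individual for r in reads})
    header = pysam.AlignmentHeader.from_dict(_sam_header(assembly, individuals))
    tid = {n: i for i, n in enumerate(assembly.names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for read in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = read.read_id
            a.query_sequence = read.seq
            a.flag = 16 if read.strand == "-" else 0
            a.reference_id = tid[read.chrom]
            a.reference_start = read.start
            a.mapping_quality = 60
            a.cigartuples = [(_PYSAM_OP[op], n) for op, n in read.cigar]
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in read.quals)
            )
            a.set_tag("RG", read.individual)
            fh.write(a)


def read_sam(path) -> list[AlignedRead]:
    """Parse a SAM file into AlignedReads (CIGAR restricted to M/I/D).

    SAM 1-based POS becomes the internal 0-based ``start``.  Base qualities
    are required; the individual is taken from the read-group tag.
    """
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if rec.query_qualities is None:
                raise ValueError(f"{rec.query_name}: missing base qualities")
            cigar = []
            for op, n in rec.cigartuples or []:
                if op not in _PYSAM_OP_INV:
                    raise ValueError(
                        f"{rec.query_name}: unsupported CIGAR op code {op}"
                    )
                cigar.append((_PYSAM_OP_INV[op], n))
            individual = rec.get_tag("RG") if rec.has_tag("RG") else "unknown"
            reads.append(
                AlignedRead(
                    read_id=rec.query_name,
                    individual=str(individual),
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    seq=rec.query_sequence,
                    quals=np.asarray(rec.query_qualities, dtype=np.uint8),
                    cigar=cigar,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def write_fastq(reads: Sequence[AlignedRead], path) -> None:
    """Emit reads as PHRED+33 FASTQ in physical (trace) orientation."""
    with open(path, "w") as fh:
        for read in reads:
            seq, quals = read.seq, read.quals
            if read.strand == "-":
                seq = revcomp(seq)
                quals = quals[::-1]
            qstr = "".join(chr(int(q) + 33) for q in quals)
            fh.write(f"@{read.read_id}\n{seq}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


@dataclass
class VcfRecord:
    """One VCF line in internal coordinates (pos is 0-based of the REF start)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = "."
    info: dict = field(default_factory=dict)
    gts: list[str] = field(default_factory=list)


_VCF_META = [
    '##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant class (SNP or DIP)">',
    '##INFO=<ID=DISC,Number=.,Type=String,Description="Individuals whose reads discovered the site">',
    '##INFO=<ID=SUP,Number=.,Type=Integer,Description="Supporting read count per discoverer (same order as DISC)">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def write_vcf(
    records: Iterable[VcfRecord],
    path,
    contigs: Mapping[str, int] | None = None,
    samples: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=felsnp\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        for line in _VCF_META:
            fh.write(line + "\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if samples:
            cols += ["FORMAT", *samples]
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            info = (
                ";".join(
                    f"{k}={','.join(map(str, v)) if isinstance(v, (list, tuple)) else v}"
                    for k, v in rec.info.items()
                )
                or "."
            )
            fields = [
                rec.chrom,
                str(rec.pos + 1),
                rec.id,
                rec.ref,
                rec.alt,
                ".",
                "PASS",
                info,
            ]
            if samples:
                fields += ["GT", *rec.gts]
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> tuple[list[VcfRecord], list[str]]:
    """Read a VCF (via pysam) back into internal records; POS returns 0-based."""
    records: list[VcfRecord] = []
    with pysam.VariantFile(str(path)) as fh:
        samples = list(fh.header.samples)
        last = None
        for rec in fh:
            key = (rec.chrom, rec.pos)
            if last is not None and rec.chrom == last[0] and rec.pos < last[1]:
                raise ValueError(f"VCF records out of order at {rec.chrom}:{rec.pos}")
            last = key
            info = {}
            for k, v in rec.info.items():
                info[k] = list(v) if isinstance(v, tuple) else v
            gts = []
            for s in samples:
                alleles = rec.samples[s]["GT"]
                gts.append(
                    "/".join("." if a is None else str(a) for a in alleles)
                )
            records.append(
                VcfRecord(
                    chrom=rec.chrom,
                    pos=rec.pos - 1,
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else ".",
                    id=rec.id or ".",
                    info=info,
                    gts=gts,
                )
            )
    return records, samples


# ---------------------------------------------------------------------------
# Anchor-base conversion for DIPs
# ---------------------------------------------------------------------------


def site_to_vcf_alleles(
    assembly: ReferenceAssembly, chrom: str, pos: int, vtype: str, ref: str, alt: str
) -> tuple[int, str, str]:
    """Internal site -> (VCF 0-based pos, REF, ALT) with the anchor convention.

    SNPs pass through.  Internally a DIP is anchored at the last matching
    reference base before the gap: a deletion stores the deleted bases in
    ``ref`` (``alt`` empty) and an insertion stores the inserted bases in
    ``alt`` (``ref`` empty).  VCF prepends the anchor base to both alleles.
    """
    if vtype == "SNP":
        return pos, ref, alt
    anchor = assembly.sequences[chrom][pos]
    return pos, anchor + ref, anchor + alt


def vcf_alleles_to_site(pos: int, ref: str, alt: str) -> tuple[int, str, str, str]:
    """Inverse of :func:`site_to_vcf_alleles`: -> (pos, vtype, ref, alt)."""
    if len(ref) == 1 and len(alt) == 1:
        return pos, "SNP", ref, alt
    if len(ref) > len(alt):  # deletion, alt is the anchor
        return pos, "DIP", ref[1:], ""
    return pos, "DIP", "", alt[1:]


# ---------------------------------------------------------------------------
# BED / bedGraph / TSV helpers
# ---------------------------------------------------------------------------


def write_bed(rows: Iterable[tuple], path) -> None:
    """rows: (chrom, start, end, name) 0-based half-open."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def write_bedgraph(rows: Iterable[tuple], path) -> None:
    """rows: (chrom, start, end, value) 0-based half-open."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def write_tsv(df, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
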