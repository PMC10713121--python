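"""Read-fragment (SNP) matrices: construction, filtering, encoding, splitting.

Aligned reads are reduced to an ``n x l`` matrix over {A, C, G, T, uncovered}
whose columns are called heterozygous SNP positions; every downstream stage
(the correlation model, clustering, consensus, metrics) consumes this matrix.
Internally bases are coded as int8: A=0, C=1, G=2, T=3, uncovered=-1.
Coordinates are 0-based half-open internally; 1-based only at the VCF edge.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
UNCOVERED = -1
GAP_CHAR = "-"

_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}


def encode_base(b: str) -> int:
    """Map a base character to its int8 code; anything but A/C/G/T is uncovered."""
    return _BASE_TO_CODE.get(b.upper(), UNCOVERED)


def decode_base(code: int) -> str:
    return BASES[code] if code >= 0 else GAP_CHAR


@dataclass
class ReadFragmentMatrix:
    """The n x l SNP matrix of read fragments.

    Attributes
    ----------
    entries : int8 array, shape (n, l)
        Base codes; ``UNCOVERED`` (-1) marks positions a fragment does not
        sample (including the insert between paired-end mates).
    read_ids : list of str
        One label per fragment row.
    snp_positions : int array, shape (l,)
        Strictly increasing 0-based reference coordinates of the columns.
    """

    entries: np.ndarray
    read_ids: list[str]
    snp_positions: np.ndarray

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=np.int8)
        self.snp_positions = np.asarray(self.snp_positions, dtype=np.int64)
        n, l = self.entries.shape
        if len(self.read_ids) != n:
            raise ValueError("read_ids length does not match row count")
        if len(self.snp_positions) != l:
            raise ValueError("snp_positions length does not match column count")
        if l >= 2 and not np.all(np.diff(self.snp_positions) > 0):
            raise ValueError("snp_positions must be strictly increasing")

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    @property
    def l(self) -> int:
        return self.entries.shape[1]

    def covered(self) -> np.ndarray:
        """Boolean (n, l) mask of covered cells."""
        return self.entries != UNCOVERED

    def restrict_columns(self, cols: np.ndarray) -> "ReadFragmentMatrix":
        """Sub-matrix over the given column indices (rows kept as-is)."""
        cols = np.asarray(cols)
        return ReadFragmentMatrix(
            self.entries[:, cols],
            list(self.read_ids),
            self.snp_positions[cols],
        )


@dataclass
class SnpCallSet:
    """Called heterozygous SNP positions with their retained alleles."""

    positions: list[int]
    alleles: list[dict[str, int]] = field(default_factory=list)
    vaf_threshold: float = 0.2


def call_snps(
    pileup: Mapping[int, Mapping[str, int]],
    vaf_threshold: float = 0.2,
    max_alleles: int | None = None,
) -> SnpCallSet:
    """Call heterozygous SNPs from per-position allele counts.

    A position is called when at least two distinct alleles each reach a
    variant allele frequency (VAF) >= ``vaf_threshold``, computed over the
    reads covering that position (not over all reads). At a called site at
    most ``max_alleles`` most frequent qualifying alleles are retained
    (e.g. the ploidy); pass None to keep all qualifying alleles.
    """
    if not 0.0 < vaf_threshold < 1.0:
        raise ValueError("vaf_threshold must be in (0, 1)")
    if not pileup:
        raise ValueError("no positions in pileup")
    positions: list[int] = []
    kept: list[dict[str, int]] = []
    for pos in sorted(pileup):
        counts = {b: c for b, c in pileup[pos].items() if c > 0 and b.upper() in _BASE_TO_CODE}
        depth = sum(counts.values())
        if depth == 0:
            continue
        qualifying = {b: c for b, c in counts.items() if c / depth >= vaf_threshold}
        if len(qualifying) < 2:
            continue
        if max_alleles is not None and len(qualifying) > max_alleles:
            top = sorted(qualifying.items(), key=lambda bc: (-bc[1], bc[0]))[:max_alleles]
            qualifying = dict(top)
        positions.append(int(pos))
        kept.append(qualifying)
    return SnpCallSet(positions, kept, vaf_threshold)


def build_fragment_matrix(
    alignments: Iterable[tuple[str, Sequence[tuple[int, str]]]],
    calls: SnpCallSet,
) -> ReadFragmentMatrix:
    """Assemble the read-fragment matrix from aligned read segments.

    ``alignments`` yields ``(read_id, segments)`` records, one per fragment;
    ``segments`` is a list of ``(start, sequence)`` pairs in reference
    coordinates. Paired-end mates belong to ONE record (one matrix row), so
    the insert between mates stays uncovered. The base at each called SNP is
    recorded if it is one of the retained alleles at that site; other bases
    (sequencing artefacts, N) are treated as uncovered.
    """
    positions = np.asarray(calls.positions, dtype=np.int64)
    pos_index = {int(p): j for j, p in enumerate(positions)}
    allowed = [set(a) if a else None for a in calls.alleles] if calls.alleles else None
    rows: list[np.ndarray] = []
    ids: list[str] = []
    for read_id, segments in alignments:
        row = np.full(len(positions), UNCOVERED, dtype=np.int8)
        for start, seq in segments:
            for offset, base in enumerate(seq):
                j = pos_index.get(start + offset)
                if j is None:
                    continue
                code = encode_base(base)
                if code == UNCOVERED:
                    continue
                if allowed is not None and allowed[j] is not None and base.upper() not in allowed[j]:
                    continue
                row[j] = code
        rows.append(row)
        ids.append(read_id)
    entries = np.vstack(rows) if rows else np.empty((0, len(positions)), dtype=np.int8)
    return ReadFragmentMatrix(entries, ids, positions)


def filter_fragments(m: ReadFragmentMatrix, min_snps: int = 2) -> ReadFragmentMatrix:
    """Drop fragments covering fewer than ``min_snps`` SNP columns.

    Fragments covering a single variant carry no phasing information.
    Row order is preserved; idempotent.
    """
    keep = m.covered().sum(axis=1) >= min_snps
    if not keep.any():
        raise ValueError("no informative fragments remain after filtering")
    return ReadFragmentMatrix(
        m.entries[keep],
        [rid for rid, k in zip(m.read_ids, keep) if k],
        m.snp_positions,
    )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def split_blocks(m: ReadFragmentMatrix) -> list[ReadFragmentMatrix]:
    """Split the matrix into independently phaseable haplotype blocks.

    A block boundary occurs (a) at any column covered by no read, and (b)
    between groups of columns not bridged by any single fragment — phasing
    across such a gap is impossible. Within each block, rows are restricted
    to fragments covering at least two of its columns. Blocks are returned
    in left-to-right column order.
    """
    cov = m.covered()
    nonempty = np.flatnonzero(cov.any(axis=0))
    blocks: list[ReadFragmentMatrix] = []
    # maximal runs of consecutive non-empty columns
    runs: list[np.ndarray] = []
    if nonempty.size:
        splits = np.flatnonzero(np.diff(nonempty) > 1) + 1
        runs = np.split(nonempty, splits)
    for run in runs:
        uf = _UnionFind(len(run))
        col_of = {int(c): i for i, c in enumerate(run)}
        for i in range(m.n):
            covered_here = [col_of[int(c)] for c in np.flatnonzero(cov[i]) if int(c) in col_of]
            for a, b in zip(covered_here, covered_here[1:]):
                uf.union(a, b)
        comp: dict[int, list[int]] = {}
        for i, c in enumerate(run):
            comp.setdefault(uf.find(i), []).append(int(c))
        for cols in sorted(comp.values(), key=lambda cs: cs[0]):
            sub = m.restrict_columns(np.asarray(cols))
            keep = sub.covered().sum(axis=1) >= 2
            if keep.any():
                sub = ReadFragmentMatrix(
                    sub.entries[keep],
                    [rid for rid, k in zip(sub.read_ids, keep) if k],
                    sub.snp_positions,
                )
            blocks.append(sub)
    return blocks


def one_hot(m: ReadFragmentMatrix) -> np.ndarray:
    """One-hot encode the matrix as an (n, 4, l) array.

    A -> (1,0,0,0), C -> (0,1,0,0), G -> (0,0,1,0), T -> (0,0,0,1);
    uncovered cells map to the all-zero vector, giving a symmetric distance
    between nucleotides.
    """
    n, l = m.entries.shape
    out = np.zeros((n, 4, l), dtype=np.float64)
    rows, cols = np.nonzero(m.entries >= 0)
    out[rows, m.entries[rows, cols], cols] = 1.0
    return out


def decode_one_hot(
    x: np.ndarray,
    read_ids: list[str] | None = None,
    snp_positions: np.ndarray | None = None,
) -> ReadFragmentMatrix:
    """Invert :func:`one_hot` (exact on covered cells)."""
    n, _, l = x.shape
    entries = np.where(x.any(axis=1), x.argmax(axis=1), UNCOVERED).astype(np.int8)
    if read_ids is None:
        read_ids = [f"read{i}" for i in range(n)]
    if snp_positions is None:
        snp_positions = np.arange(l)
    return ReadFragmentMatrix(entries, read_ids, snp_positions)


# ---------------------------------------------------------------------------
# I/O: tabular fragment format, SAM input, minimal VCF output
# ---------------------------------------------------------------------------

def write_fragments(m: ReadFragmentMatrix, path) -> None:
    """Write the tabular fragment format.

    One fragment per line: ``read_id TAB start_column TAB alleles`` where
    ``alleles`` runs from the fragment's first to last covered column with
    '-' marking uncovered cells. A leading '#' header line records the SNP
    positions so the matrix round-trips.
    """
    with open(path, "w") as fh:
        fh.write("#positions\t" + ",".join(str(int(p)) for p in m.snp_positions) + "\n")
        for i, rid in enumerate(m.read_ids):
            covered = np.flatnonzero(m.entries[i] != UNCOVERED)
            if covered.size == 0:
                fh.write(f"{rid}\t0\t\n")
                continue
            first, last = int(covered[0]), int(covered[-1])
            alleles = "".join(decode_base(int(c)) for c in m.entries[i, first : last + 1])
            fh.write(f"{rid}\t{first}\t{alleles}\n")


def read_fragments(path) -> ReadFragmentMatrix:
    """Read the tabular fragment format written by :func:`write_fragments`."""
    ids: list[str] = []
    starts: list[int] = []
    strings: list[str] = []
    positions: np.ndarray | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#positions"):
                _, plist = line.split("\t", 1)
                positions = np.asarray([int(p) for p in plist.split(",")], dtype=np.int64)
                continue
            parts = line.split("\t")
            rid, start = parts[0], int(parts[1])
            alleles = parts[2] if len(parts) > 2 else ""
            ids.append(rid)
            starts.append(start)
            strings.append(alleles)
    if positions is None:
        l = max((s + len(a) for s, a in zip(starts, strings)), default=0)
        positions = np.arange(l)
    entries = np.full((len(ids), len(positions)), UNCOVERED, dtype=np.int8)
    for i, (start, alleles) in enumerate(zip(starts, strings)):
        for off, ch in enumerate(alleles):
            entries[i, start + off] = encode_base(ch)
    return ReadFragmentMatrix(entries, ids, positions)


def read_sam_fragments(sam_path, calls: SnpCallSet) -> ReadFragmentMatrix:
    """Build the fragment matrix from coordinate-sorted SAM records.

    Paired-end mates sharing a query name are merged into one fragment row.
    Aligned pairs are taken from pysam's CIGAR-aware coordinate mapping, so
    insertions/deletions never shift SNP columns.
    """
    import pysam

    segments: dict[str, list[tuple[int, str]]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            pieces: list[tuple[int, str]] = []
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                base = rec.query_sequence[qpos]
                if pieces and rpos == pieces[-1][0] + len(pieces[-1][1]):
                    pieces[-1] = (pieces[-1][0], pieces[-1][1] + base)
                else:
                    pieces.append((rpos, base))
            if rec.query_name not in segments:
                segments[rec.query_name] = []
                order.append(rec.query_name)
            segments[rec.query_name].extend(pieces)
    return build_fragment_matrix(((rid, segments[rid]) for rid in order), calls)


def write_vcf(calls: SnpCallSet, path, contig: str = "ref") -> None:
    """Export called SNPs as a minimal VCF (positions 1-based on output)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=VAF,Number=A,Type=Float,Description="Variant allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for j, pos in enumerate(calls.positions):
            counts = calls.alleles[j] if j < len(calls.alleles) else {}
            if counts:
                ordered = sorted(counts.items(), key=lambda bc: (-bc[1], bc[0]))
                ref = ordered[0][0]
                alts = [b for b, _ in ordered[1:]]
                depth = sum(counts.values())
                vafs = ",".join(f"{c / depth:.4f}" for _, c in ordered[1:])
            else:
                ref, alts, vafs = "N", ["N"], "0"
            fh.write(
                f"{contig}\t{pos + 1}\t.\t{ref}\t{','.join(alts) or '.'}\t.\tPASS\tVAF={vafs}\n"
            )
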