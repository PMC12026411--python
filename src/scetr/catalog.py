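"""Tandem-repeat locus representation and catalog algebra.

A TR locus is an interval on a chromosome together with its repeat motif.
Coordinates are 0-based half-open (BED convention) throughout the package;
VCF I/O converts to 1-based on the way in and out.

Two motifs describe the same repeat if one is a cyclic rotation and/or the
reverse complement of the other (e.g. CAG, AGC and CTG all describe the same
triplet repeat read on either strand at any phase).  ``canonical_motif``
collapses this equivalence class to a single representative, which is the
identity used for catalog merging and cross-catalog harmonization.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_BASES = frozenset("ACGT")


class CatalogError(ValueError):
    pass


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_motif(motif: str) -> str:
    """Canonical representative of a motif's rotation/reverse-complement class.

    Returns the lexicographically smallest string over all cyclic rotations of
    ``motif`` and of its reverse complement.  Two motifs harmonize (describe
    the same repeat) iff their canonical representatives are equal.

    Raises
    ------
    CatalogError
        If ``motif`` is empty or contains a character outside A/C/G/T.
    """
    if not motif:
        raise CatalogError("empty motif")
    if not _VALID_BASES.issuperset(motif):
        raise CatalogError(f"motif {motif!r} contains non-ACGT characters")
    rc = revcomp(motif)
    doubled, doubled_rc = motif + motif, rc + rc
    n = len(motif)
    candidates = [doubled[i : i + n] for i in range(n)]
    candidates += [doubled_rc[i : i + n] for i in range(n)]
    return min(candidates)


def motif_rotations(motif: str) -> list[str]:
    """All cyclic rotations of ``motif`` (no reverse complement)."""
    doubled = motif + motif
    return [doubled[i : i + len(motif)] for i in range(len(motif))]


@dataclass(frozen=True)
class TRLocus:
    """A tandem-repeat locus: interval plus motif.

    ``ref_repeats`` is the number of motif copies in the reference sequence
    (the *r* of the PCR fragment-length conversion in the validation module);
    it is optional because simulated loci need not model a reference.
    """

    chrom: str
    start: int
    end: int
    motif: str
    ref_repeats: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise CatalogError(f"locus end must exceed start: {self}")
        if not self.motif or not _VALID_BASES.issuperset(self.motif):
            raise CatalogError(f"invalid motif {self.motif!r}")

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.motif}"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def motif_class(self) -> str:
        return canonical_motif(self.motif)

    def overlap_bp(self, other: "TRLocus") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def _check_sorted(catalog: Sequence[TRLocus]) -> None:
    keys = [(loc.chrom, loc.start) for loc in catalog]
    if keys != sorted(keys):
        raise CatalogError("catalog must be sorted by (chrom, start)")


def merge_catalogs(
    catalogs: Iterable[Sequence[TRLocus]],
    min_overlap: float = 0.66,
    denominator: str = "candidate",
) -> list[TRLocus]:
    """Sequentially merge TR catalogs, earlier catalogs taking precedence.

    Catalogs are parsed in order; a candidate locus is excluded iff some
    already-included locus covers at least ``min_overlap`` of its length
    (``denominator="candidate"``; ``"reciprocal"`` additionally requires the
    candidate to cover that fraction of the included locus) AND the two share
    a motif class.  Loci overlapping fully but carrying different motif
    classes are both retained.  Output is sorted and deduplicated.
    """
    if denominator not in ("candidate", "reciprocal"):
        raise CatalogError(f"unknown overlap denominator {denominator!r}")
    included: dict[str, list[TRLocus]] = {}
    starts: dict[str, list[int]] = {}
    max_len: dict[str, int] = {}

    def is_redundant(cand: TRLocus) -> bool:
        chrom_loci = included.get(cand.chrom)
        if not chrom_loci:
            return False
        # candidates overlapping cand must start after cand.start - max_len
        lo = bisect.bisect_left(starts[cand.chrom], cand.start - max_len[cand.chrom])
        hi = bisect.bisect_right(starts[cand.chrom], cand.end)
        cls = cand.motif_class
        for other in chrom_loci[lo:hi]:
            ov = cand.overlap_bp(other)
            if ov == 0 or other.motif_class != cls:
                continue
            frac_cand = ov / cand.length
            if denominator == "candidate":
                if frac_cand >= min_overlap:
                    return True
            else:
                if frac_cand >= min_overlap and ov / other.length >= min_overlap:
                    return True
        return False

    for catalog in catalogs:
        _check_sorted(catalog)
        for cand in catalog:
            if is_redundant(cand):
                continue
            chrom_loci = included.setdefault(cand.chrom, [])
            pos = bisect.bisect_left(starts.setdefault(cand.chrom, []), cand.start)
            # skip exact duplicates
            if any(
                loc == cand
                for loc in chrom_loci
                if loc.start == cand.start and loc.end == cand.end
            ):
                continue
            starts[cand.chrom].insert(pos, cand.start)
            chrom_loci.insert(pos, cand)
            max_len[cand.chrom] = max(max_len.get(cand.chrom, 0), cand.length)

    out: list[TRLocus] = []
    for chrom in sorted(included):
        out.extend(sorted(included[chrom], key=lambda l: (l.start, l.end, l.motif)))
    return out


def is_tr_representing_indel(
    indel: tuple[int, str, str], locus: TRLocus
) -> bool:
    """Whether an indel is an alternate encoding of a TR allele at ``locus``.

    ``indel`` is (position, ref allele, alt allele) with the position in the
    same 0-based system as the locus.  One allele must be a prefix of the
    other (pure insertion or deletion).  Returns True iff the position lies
    within the locus interval and the inserted/deleted sequence is a nonzero
    whole number of copies of some cyclic rotation of the locus motif.
    Partial motif copies (and hence impure indels) return False.
    """
    pos, ref, alt = indel
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise CatalogError("not an indel: ref == alt")
    longer, shorter = (ref, alt) if len(ref) > len(alt) else (alt, ref)
    if not longer.startswith(shorter):
        raise CatalogError("not a pure indel: one allele must be a prefix of the other")
    seq = longer[len(shorter):]
    if not (locus.start <= pos < locus.end):
        return False
    m = len(locus.motif)
    if len(seq) % m != 0:
        return False
    unit = seq[:m]
    if seq != unit * (len(seq) // m):
        return False
    return unit in motif_rotations(locus.motif)


def assign_window(
    gene: tuple[int, int],
    variants: Sequence,
    window: int = 100_000,
) -> list:
    """Variants whose interval intersects the gene's cis window.

    ``gene`` is (TSS, TES) on the strandless projection (TSS <= TES).  The
    window is the closed interval [TSS - window, TES + window]; a variant with
    half-open interval [start, end) is retained iff it intersects it.  Point
    variants (SNVs) are intervals of length 1.
    """
    tss, tes = gene
    if tss > tes:
        raise CatalogError("gene TSS must not exceed TES")
    lo, hi = tss - window, tes + window
    out = []
    for v in variants:
        start = getattr(v, "start")
        end = getattr(v, "end", start + 1)
        if end - 1 >= lo and start <= hi:
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# BED4+ I/O

def read_bed(path) -> list[TRLocus]:
    """Read a catalog from BED4+ (chrom, start, end, motif[, ref_repeats])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise CatalogError("catalog BED needs at least 4 columns")
    loci = []
    for row in df.itertuples(index=False):
        ref_repeats = float(row[4]) if df.shape[1] > 4 else None
        loci.append(TRLocus(str(row[0]), int(row[1]), int(row[2]), str(row[3]).upper(),
                            ref_repeats))
    return loci


def write_bed(loci: Sequence[TRLocus], path) -> None:
    rows = []
    for loc in loci:
        row = [loc.chrom, loc.start, loc.end, loc.motif]
        if loc.ref_repeats is not None:
            row.append(loc.ref_repeats)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
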