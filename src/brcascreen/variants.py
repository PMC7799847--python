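"""Variant representations, VCF I/O, and normalization.

Variants are held in two coordinate dialects:

* :class:`GenomicVariant` — VCF-anchored: 1-based POS of the first REF base,
  indels carry a shared anchor base (``pos 5, ATG>A``).
* :class:`TrimmedVariant` — ANNOVAR/table style: the anchor base is dropped,
  pure insertions/deletions use ``-`` for the empty side, and ``start``/``end``
  delimit the affected reference bases.

Normalization follows the standard vt/bcftools algorithm (right-trim with
left-extension from the reference, then left-trim), producing the left-most
minimal representation of each allele pair.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GenomicVariant",
    "TrimmedVariant",
    "RegionSpec",
    "VcfError",
    "NormalizationError",
    "ReferenceWindow",
    "FastaReference",
    "read_sites_vcf",
    "write_sites_vcf",
    "split_multiallelic",
    "normalize",
    "extract_region",
    "to_trimmed",
    "from_trimmed",
    "BRCA1_REGION",
    "BRCA2_REGION",
]

_ALLELE_RE = re.compile(r"^[ACGTN]+$", re.IGNORECASE)


class VcfError(ValueError):
    """Malformed VCF content (carries the offending line number when known)."""


class NormalizationError(ValueError):
    """Variant disagrees with the reference or left-alignment left the window."""


def _strip_chr(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True, order=True)
class GenomicVariant:
    """One bi-allelic substitution or indel in VCF coordinates.

    ``af`` maps a dataset tag (e.g. ``"3.5KJPN"``) to the allele frequency of
    ``alt`` in that dataset.  A missing tag means "not observed/reported", which
    is distinct from a frequency of zero.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    af: Mapping[str, float] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", _strip_chr(self.chrom))
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not _ALLELE_RE.match(allele):
                raise ValueError(f"{name} allele {allele!r} is not a non-empty A/C/G/T/N string")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref!r})")
        for tag, f in self.af.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"allele frequency for {tag!r} out of [0,1]: {f}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def end(self) -> int:
        """1-based position of the last REF base."""
        return self.pos + len(self.ref) - 1

    def is_normalized(self) -> bool:
        """Minimal representation: no shared leading+trailing base unless length 1."""
        if len(self.ref) == 1 or len(self.alt) == 1:
            return True
        return not (self.ref[0] == self.alt[0] and self.ref[-1] == self.alt[-1])


@dataclass(frozen=True, order=True)
class TrimmedVariant:
    """ANNOVAR-style variant: anchor base removed, ``-`` for the empty allele."""

    chrom: str
    start: int
    end: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", _strip_chr(self.chrom))
        if self.ref == "-" and self.alt == "-":
            raise ValueError("ref and alt cannot both be '-'")
        if self.ref == "-":  # pure insertion: end == start by convention
            if self.end != self.start:
                raise ValueError("pure insertion requires end == start")
        elif self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")

    @property
    def key(self) -> tuple[str, int, int, str, str]:
        return (self.chrom, self.start, self.end, self.ref, self.alt)


@dataclass(frozen=True)
class RegionSpec:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", _strip_chr(self.chrom))
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return _strip_chr(chrom) == self.chrom and self.start <= pos <= self.end


# hg19 gene intervals used as pipeline defaults (GeneCards boundaries).
BRCA1_REGION = RegionSpec("17", 41_196_312, 41_277_500)
BRCA2_REGION = RegionSpec("13", 32_889_611, 32_973_809)


class ReferenceWindow:
    """In-memory reference sequence accessor for one chromosome window.

    ``seq[0]`` corresponds to 1-based genomic position ``offset + 1``.
    """

    def __init__(self, chrom: str, seq: str, offset: int = 0):
        self.chrom = _strip_chr(chrom)
        self.seq = seq.upper()
        self.offset = offset

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return bases for 1-based inclusive [start, end]."""
        if _strip_chr(chrom) != self.chrom:
            raise KeyError(f"chromosome {chrom!r} not covered (window holds {self.chrom!r})")
        lo = start - self.offset - 1
        hi = end - self.offset
        if lo < 0 or hi > len(self.seq) or start > end:
            raise KeyError(f"positions {start}-{end} outside reference window")
        return self.seq[lo:hi]


class FastaReference:
    """Reference accessor backed by a FASTA file (via pyfaidx)."""

    def __init__(self, path: str | Path):
        import pyfaidx

        self._fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        self._names = {_strip_chr(name): name for name in self._fa.keys()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        name = self._names.get(_strip_chr(chrom))
        if name is None:
            raise KeyError(f"chromosome {chrom!r} not in FASTA")
        if start < 1 or start > end:
            raise KeyError(f"invalid positions {start}-{end}")
        seq = str(self._fa[name][start - 1 : end])
        if len(seq) != end - start + 1:
            raise KeyError(f"positions {start}-{end} outside {chrom} sequence")
        return seq


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def split_multiallelic(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    afs: Sequence[float] | None = None,
    dataset_tag: str = "AF",
) -> list[GenomicVariant]:
    """Decompose one multi-allelic site into bi-allelic records.

    The i-th output carries the i-th ALT and, when AFs are given, the i-th AF
    (the INFO/AF field has arity A).  REF and POS are left untouched —
    :func:`normalize` is a separate step.
    """
    if not alts:
        raise VcfError(f"site {chrom}:{pos} has an empty ALT list")
    if afs is not None and len(afs) != len(alts):
        raise VcfError(
            f"site {chrom}:{pos}: AF arity {len(afs)} != ALT arity {len(alts)}"
        )
    out = []
    for i, alt in enumerate(alts):
        af = {} if afs is None else {dataset_tag: float(afs[i])}
        out.append(GenomicVariant(chrom, pos, ref, alt, af))
    return out


def read_sites_vcf(path: str | Path, dataset_tag: str = "AF") -> list[GenomicVariant]:
    """Read a site-only VCF, splitting multi-allelic sites.

    Yields one :class:`GenomicVariant` per (site, ALT) in input order.  INFO/AF
    values are attached under ``dataset_tag``; a site without AF produces
    records with an empty ``af`` map (missing, not zero).
    """
    import gzip
    import pysam

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        n_header = 0
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1

    out: list[GenomicVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf):
            lineno = n_header + i + 1
            try:
                alts = list(rec.alts or [])
                if not alts:
                    raise VcfError("no ALT allele")
                raw_af = rec.info.get("AF") if "AF" in rec.info else None
                afs = None if raw_af is None else [float(x) for x in raw_af]
                if afs is not None and len(afs) != len(alts):
                    raise VcfError(f"AF arity {len(afs)} != ALT arity {len(alts)}")
                out.extend(
                    split_multiallelic(rec.chrom, rec.pos, rec.ref, alts, afs, dataset_tag)
                )
            except (ValueError, TypeError) as exc:
                raise VcfError(f"{path}: malformed VCF record at line {lineno}: {exc}") from exc
    return out


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _format_af(f: float) -> str:
    s = f"{f:.6g}"
    return s


def write_sites_vcf(
    path: str | Path,
    variants: Iterable[GenomicVariant],
    dataset_tag: str = "AF",
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a minimal site-only VCF 4.2 with AF as a Float INFO of arity A.

    Records are written one ALT per line (already bi-allelic).  Variants whose
    ``af`` lacks ``dataset_tag`` are written with ``INFO=.``.
    """
    variants = list(variants)
    contigs = ""
    if contig_lengths:
        contigs = "".join(
            f"##contig=<ID={c},length={l}>\n" for c, l in contig_lengths.items()
        )
    else:
        seen: list[str] = []
        for v in variants:
            if v.chrom not in seen:
                seen.append(v.chrom)
        contigs = "".join(f"##contig=<ID={c}>\n" for c in seen)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs))
        for v in variants:
            info = (
                f"AF={_format_af(v.af[dataset_tag])}" if dataset_tag in v.af else "."
            )
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t{info}\n")


# ---------------------------------------------------------------------------
# Normalization (vt/bcftools algorithm)
# ---------------------------------------------------------------------------

def normalize(v: GenomicVariant, ref_seq, window: int = 200) -> GenomicVariant:
    """Left-align and trim ``v`` to its minimal, left-most representation.

    ``ref_seq`` is any object with ``fetch(chrom, start, end)`` in 1-based
    inclusive coordinates.  ``window`` bounds how far left-extension may walk;
    exceeding it raises :class:`NormalizationError` asking for a larger window.
    """
    observed = ref_seq.fetch(v.chrom, v.pos, v.pos + len(v.ref) - 1)
    if observed.upper() != v.ref.upper():
        raise NormalizationError(
            f"{v.chrom}:{v.pos} REF {v.ref!r} disagrees with reference {observed!r}"
        )
    pos, ref, alt = v.pos, v.ref.upper(), v.alt.upper()
    left_limit = v.pos - window
    # right-trim; when one allele empties, extend left with the reference base
    while True:
        if ref[-1] == alt[-1] and (len(ref) > 1 and len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
        elif ref[-1] == alt[-1]:
            if pos - 1 < max(1, left_limit):
                raise NormalizationError(
                    f"{v.chrom}:{v.pos} left-alignment walked past the {window} bp "
                    "window; retry with a larger window"
                )
            try:
                base = ref_seq.fetch(v.chrom, pos - 1, pos - 1).upper()
            except KeyError as exc:
                raise NormalizationError(
                    f"{v.chrom}:{v.pos} left-alignment left the reference window; "
                    "retry with a larger window"
                ) from exc
            pos -= 1
            ref, alt = base + ref[:-1], base + alt[:-1]
        else:
            break
    # left-trim
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return replace(v, pos=pos, ref=ref, alt=alt)


def extract_region(
    variants: Iterable[GenomicVariant], region: RegionSpec
) -> list[GenomicVariant]:
    """Keep variants whose POS lies inside ``region`` (inclusive bounds).

    Membership is by POS of the (normalized) record only: an indel whose span
    crosses ``region.end`` but whose POS is inside is retained.
    """
    return [v for v in variants if region.contains(v.chrom, v.pos)]


# ---------------------------------------------------------------------------
# Coordinate dialect conversion
# ---------------------------------------------------------------------------

def to_trimmed(v: GenomicVariant) -> TrimmedVariant:
    """Convert a normalized VCF-anchored variant to the trimmed table dialect."""
    if not v.is_normalized():
        raise ValueError(f"variant {v} is not normalized (shared leading+trailing bases)")
    if v.is_snv:
        return TrimmedVariant(v.chrom, v.pos, v.pos, v.ref, v.alt)
    if len(v.ref) > 1 and len(v.alt) == 1 and v.ref[0] == v.alt:
        # deletion: drop the anchor base
        return TrimmedVariant(v.chrom, v.pos + 1, v.pos + len(v.ref) - 1, v.ref[1:], "-")
    if len(v.alt) > 1 and len(v.ref) == 1 and v.alt[0] == v.ref:
        # insertion after the anchor base
        return TrimmedVariant(v.chrom, v.pos, v.pos, "-", v.alt[1:])
    # block substitution (MNV / complex): alleles kept as-is
    return TrimmedVariant(v.chrom, v.pos, v.pos + len(v.ref) - 1, v.ref, v.alt)


def from_trimmed(t: TrimmedVariant, ref_seq) -> GenomicVariant:
    """Inverse of :func:`to_trimmed`; needs the reference for the anchor base."""
    if t.ref != "-" and t.alt != "-":
        if len(t.ref) == 1 and len(t.alt) == 1:
            return GenomicVariant(t.chrom, t.start, t.ref, t.alt)
        return GenomicVariant(t.chrom, t.start, t.ref, t.alt)  # block substitution
    if t.ref == "-":  # insertion: anchor base at start
        try:
            anchor = ref_seq.fetch(t.chrom, t.start, t.start)
        except KeyError as exc:
            raise NormalizationError(f"anchor base unavailable for {t}: {exc}") from exc
        return GenomicVariant(t.chrom, t.start, anchor, anchor + t.alt)
    # deletion: anchor base at start-1
    try:
        anchor = ref_seq.fetch(t.chrom, t.start - 1, t.start - 1)
    except KeyError as exc:
        raise NormalizationError(f"anchor base unavailable for {t}: {exc}") from exc
    return GenomicVariant(t.chrom, t.start - 1, anchor + t.ref, anchor)


def read_trimmed_tsv(path: str | Path) -> list[TrimmedVariant]:
    """Read a Chr/Start/End/Ref/Alt TSV into trimmed variants."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["Chr", "Start", "End", "Ref", "Alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        TrimmedVariant(row.Chr, int(row.Start), int(row.End), row.Ref, row.Alt)
        for row in df.itertuples()
    ]


def write_trimmed_tsv(path: str | Path, variants: Iterable[TrimmedVariant]) -> None:
    import pandas as pd

    rows = [
        {"Chr": t.chrom, "Start": t.start, "End": t.end, "Ref": t.ref, "Alt": t.alt}
        for t in variants
    ]
    pd.DataFrame(rows, columns=["Chr", "Start", "End", "Ref", "Alt"]).to_csv(
        path, sep="\t", index=False
    )
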