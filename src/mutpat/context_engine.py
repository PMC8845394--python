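"""COSMIC-style mutation contexts and count matrices.

Implements the channel systems used throughout the package:

* SBS with arbitrary flank extension ``ext`` (6 * 4**(2*ext) channels; the
  standard trinucleotide system is ``ext=1`` with 96 channels, ``ext=2``
  gives 1536),
* the 78-channel DBS system (reverse-complement-collapsed dinucleotide
  substitutions),
* the 83-channel indel (ID) system (length x homopolymer/repeat-unit
  structure, plus microhomology deletions),
* MBS by length category ({3..9, 10+}; no COSMIC consensus exists for MBSs),
* strand-annotated SBS channels (192 = 96 x 2) for transcriptional or
  replicative strand-bias profiles,
* region-lengthened channels (``A[C>A]A-promoter``).

Channel ordering follows the COSMIC published order (substitution class
major, then 5' flank, then 3' flank alphabetical) so that count matrices are
directly comparable with signature catalogs.  SBS channels are pyrimidine
collapsed: a purine-reference substitution is reverse complemented, with the
flanks swapped and complemented accordingly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import AmbiguousContextError, ChannelMismatchError, MutpatError
from .variant_typing import Variant, revcomp

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import Genome, RegionSet

logger = logging.getLogger("mutpat")

PYRIMIDINES = "CT"
PURINES = "AG"
SBS_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

# ---------------------------------------------------------------------------
# channel enumeration
# ---------------------------------------------------------------------------


def sbs_channels(ext: int = 1) -> list[str]:
    """All SBS channels for flank extension ``ext``, in COSMIC order."""
    if ext < 1:
        raise MutpatError("ext must be >= 1")
    flanks = ["".join(p) for p in product("ACGT", repeat=ext)]
    return [
        f"{up}[{sub}]{down}"
        for sub in SBS_CLASSES
        for up in flanks
        for down in flanks
    ]


_DBS_REFS = ("AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT")
_DBS_PALINDROMIC = frozenset(r for r in _DBS_REFS if revcomp(r) == r)


def dbs_channels() -> list[str]:
    """All 78 DBS channels, reverse-complement-collapsed, in fixed order."""
    chans = []
    for ref in _DBS_REFS:
        alts = set()
        for alt in ("".join(p) for p in product("ACGT", repeat=2)):
            if alt[0] == ref[0] or alt[1] == ref[1]:
                continue
            if ref in _DBS_PALINDROMIC:
                alt = min(alt, revcomp(alt))
            alts.add(alt)
        chans.extend(f"{ref}>{alt}" for alt in sorted(alts))
    return chans


def id_channels() -> list[str]:
    """All 83 indel channels in COSMIC order.

    Naming is ``{len}:{Del|Ins}:{C|T|R|M}:{k}`` where for 1-bp events the
    base is pyrimidine collapsed and ``k`` encodes the homopolymer length
    (deletions: length including the deleted copy minus one, capped at 5 for
    6+; insertions: pre-existing copies, capped at 5 for 5+); for longer
    repeat-mediated events ``R`` carries the analogous repeat-unit count and
    ``M`` the microhomology length of a deletion.
    """
    chans = []
    for base in "CT":
        chans += [f"1:Del:{base}:{k}" for k in range(6)]
    for base in "CT":
        chans += [f"1:Ins:{base}:{k}" for k in range(6)]
    for ln in (2, 3, 4, 5):
        chans += [f"{ln}:Del:R:{k}" for k in range(6)]
    for ln in (2, 3, 4, 5):
        chans += [f"{ln}:Ins:R:{k}" for k in range(6)]
    chans += ["2:Del:M:1"]
    chans += [f"3:Del:M:{k}" for k in (1, 2)]
    chans += [f"4:Del:M:{k}" for k in (1, 2, 3)]
    chans += [f"5:Del:M:{k}" for k in (1, 2, 3, 4, 5)]
    return chans


def mbs_channels() -> list[str]:
    """MBS length categories {3..9, 10+}."""
    return [str(k) for k in range(3, 10)] + ["10+"]


def stranded_sbs_channels(mode: str = "transcription", ext: int = 1) -> list[str]:
    labels = _STRAND_LABELS[mode]
    return [f"{ch}-{lab}" for ch in sbs_channels(ext) for lab in labels]


_STRAND_LABELS = {
    "transcription": ("transcribed", "untranscribed"),
    "replication": ("left", "right"),
}

# ---------------------------------------------------------------------------
# per-variant context extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SbsChannel:
    """Pyrimidine-collapsed SBS context rendered as ``UP[REF>ALT]DOWN``."""

    up: str
    ref_pyr: str
    alt: str
    down: str

    def __post_init__(self) -> None:
        if self.ref_pyr not in PYRIMIDINES:
            raise MutpatError("SBS channel reference must be a pyrimidine")

    def __str__(self) -> str:
        return f"{self.up}[{self.ref_pyr}>{self.alt}]{self.down}"


def sbs_context(variant: Variant, genome: "Genome", ext: int = 1) -> SbsChannel:
    """COSMIC context of an SBS, reading ``ext`` flanking bases per side."""
    if variant.mut_type != "SBS":
        raise MutpatError(f"sbs_context requires an SBS, got {variant.mut_type}")
    seq = genome.fetch(variant.contig, variant.pos - ext, variant.pos + ext + 1)
    ref, alt = variant.ref, variant.alt
    if seq[ext] != ref:
        raise MutpatError(
            f"REF mismatch at {variant.contig}:{variant.pos}: "
            f"genome has {seq[ext]!r}, variant has {ref!r}"
        )
    up, down = seq[:ext], seq[ext + 1 :]
    if ref in PURINES:
        ref, alt = revcomp(ref), revcomp(alt)
        up, down = revcomp(down), revcomp(up)
    if "N" in up or "N" in down:
        raise AmbiguousContextError(
            f"N in context of {variant.contig}:{variant.pos}"
        )
    return SbsChannel(up, ref, alt, down)


def dbs_context(variant: Variant) -> str:
    """Canonical COSMIC DBS channel name (``REF>ALT``) of a DBS variant."""
    if variant.mut_type != "DBS":
        raise MutpatError(f"dbs_context requires a DBS, got {variant.mut_type}")
    ref, alt = variant.ref, variant.alt
    if alt[0] == ref[0] or alt[1] == ref[1]:
        raise MutpatError(
            f"DBS {ref}>{alt} changes only one base and has no COSMIC channel"
        )
    if ref not in _DBS_REFS:
        ref, alt = revcomp(ref), revcomp(alt)
    if ref in _DBS_PALINDROMIC:
        alt = min(alt, revcomp(alt))
    if ref == alt:
        raise MutpatError("DBS REF equals ALT after canonicalization")
    return f"{ref}>{alt}"


def _left_align(seq: str, site: int, genome: "Genome", contig: str) -> tuple[str, int]:
    # shift an inserted/deleted sequence left while the preceding reference
    # base matches its last base (standard indel left-alignment)
    while site > 0:
        prev = genome.fetch(contig, site - 1, site)
        if prev != seq[-1] or prev == "N":
            break
        seq = prev + seq[:-1]
        site -= 1
    return seq, site


def _indel_allele(variant: Variant) -> tuple[str, str, int]:
    """(kind, inserted/deleted sequence, 0-based site) after anchor trimming.

    For deletions the site is the first deleted base; for insertions the
    insertion point, i.e. the reference position *before* which the sequence
    is inserted.
    """
    ref, alt = variant.ref, variant.alt
    i = 0
    while i < min(len(ref), len(alt)) and ref[i] == alt[i]:
        i += 1
    if variant.mut_type == "deletion":
        return "deletion", ref[i:], variant.pos + i
    return "insertion", alt[i:], variant.pos + i


def _run_length(genome: "Genome", contig: str, start: int, unit: str, limit: int = 8) -> int:
    """Number of consecutive copies of ``unit`` in the reference at ``start``."""
    n = 0
    ln = len(unit)
    end = genome.length(contig)
    while n < limit and start + ln <= end:
        if genome.fetch(contig, start, start + ln) != unit:
            break
        n += 1
        start += ln
    return n


def indel_context(variant: Variant, genome: "Genome") -> str:
    """COSMIC ID-83 channel of an insertion or deletion.

    The indel is left-aligned, then the 3' flank on the reference strand is
    scanned for additional copies of the event sequence; deletions without a
    flanking repeat copy are checked for microhomology on both flanks
    (maximum of the two) before falling back to the 1-unit repeat class.
    """
    if variant.mut_type not in ("insertion", "deletion"):
        raise MutpatError(
            f"indel_context requires an indel, got {variant.mut_type}"
        )
    kind, seq, site = _indel_allele(variant)
    if "N" in seq:
        raise AmbiguousContextError("N in inserted/deleted sequence")
    seq, site = _left_align(seq, site, genome, variant.contig)
    contig = variant.contig
    L = len(seq)
    len_class = min(L, 5)

    if L == 1:
        base = seq
        if base in PURINES:
            base = revcomp(base)  # flank run length is revcomp invariant
        if kind == "deletion":
            run = _run_length(genome, contig, site, seq, limit=7)
            return f"1:Del:{base}:{min(run, 6) - 1}"
        run = _run_length(genome, contig, site, seq, limit=6)
        return f"1:Ins:{base}:{min(run, 5)}"

    if kind == "insertion":
        units = _run_length(genome, contig, site, seq, limit=6)
        return f"{len_class}:Ins:R:{min(units, 5)}"

    # deletion of length >= 2: repeat units include the deleted copy itself
    units = 1 + _run_length(genome, contig, site + L, seq, limit=6)
    if units >= 2:
        return f"{len_class}:Del:R:{min(units, 6) - 1}"
    mh = _microhomology(genome, contig, site, seq)
    if mh >= 1:
        cap = 5 if L >= 5 else L - 1
        return f"{len_class}:Del:M:{min(mh, cap)}"
    return f"{len_class}:Del:R:0"


def _microhomology(genome: "Genome", contig: str, site: int, seq: str) -> int:
    """Length of flanking sequence identity of a deleted segment.

    Checks the common prefix of the deleted sequence with the 3' flank and
    its common suffix with the 5' flank; returns the maximum, capped at one
    below the deletion length (full identity would be a repeat).
    """
    L = len(seq)
    right = genome.fetch(
        contig, site + L, min(site + 2 * L - 1, genome.length(contig))
    )
    k1 = 0
    while k1 < len(right) and k1 < L - 1 and right[k1] == seq[k1]:
        k1 += 1
    left = genome.fetch(contig, max(site - (L - 1), 0), site)
    k2 = 0
    while k2 < len(left) and k2 < L - 1 and left[-1 - k2] == seq[-1 - k2]:
        k2 += 1
    return max(k1, k2)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


@dataclass
class MutationCountMatrix:
    """Channels x samples count table; the hub between contexts and signatures."""

    counts: pd.DataFrame
    dialect: str
    skipped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise MutpatError("counts must be non-negative")

    @property
    def channels(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative(self) -> pd.DataFrame:
        tot = self.counts.sum(axis=0)
        return self.counts / tot.replace(0, np.nan)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="channel")

    @classmethod
    def from_tsv(cls, path, dialect: str = "sbs") -> "MutationCountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, dialect)


def _tally(channel_of, variants, wanted_types, skipped):
    out = []
    for v in variants:
        if v.mut_type not in wanted_types:
            skipped["wrong_type"] = skipped.get("wrong_type", 0) + 1
            continue
        try:
            out.append(str(channel_of(v)))
        except AmbiguousContextError:
            skipped["ambiguous_context"] = skipped.get("ambiguous_context", 0) + 1
    return out


def count_matrix(
    variants_by_sample: Mapping[str, Sequence[Variant]],
    genome: "Genome | None" = None,
    dialect: str = "sbs",
    ext: int = 1,
) -> MutationCountMatrix:
    """Count mutation contexts per channel per sample.

    ``dialect`` is one of ``sbs`` (needs ``genome``; ``ext`` flanking bases),
    ``dbs``, ``indel`` (needs ``genome``) or ``mbs``.  Variants of the wrong
    type for the dialect are skipped and tallied in ``skipped``; variants
    whose context contains an N are excluded, never imputed.
    """
    dialect = dialect.lower()
    if dialect == "sbs":
        channels = sbs_channels(ext)
        chan_of = lambda v: sbs_context(v, genome, ext)  # noqa: E731
        wanted = ("SBS",)
    elif dialect == "dbs":
        channels = dbs_channels()
        chan_of = dbs_context
        wanted = ("DBS",)
    elif dialect == "indel":
        channels = id_channels()
        chan_of = lambda v: indel_context(v, genome)  # noqa: E731
        wanted = ("insertion", "deletion")
    elif dialect == "mbs":
        channels = mbs_channels()
        chan_of = lambda v: str(len(v.ref)) if len(v.ref) < 10 else "10+"  # noqa: E731
        wanted = ("MBS",)
    else:
        raise MutpatError(f"unknown dialect {dialect!r}")

    skipped: dict[str, int] = {}
    data = {}
    for sample, variants in variants_by_sample.items():
        names = _tally(chan_of, variants, wanted, skipped)
        counts = pd.Series(names).value_counts() if names else pd.Series(dtype=int)
        data[sample] = counts.reindex(channels, fill_value=0).astype(np.int64)
    if skipped:
        logger.warning("count_matrix skipped variants: %s", skipped)
    df = pd.DataFrame(data, index=channels, dtype=np.int64)
    df.index.name = "channel"
    return MutationCountMatrix(df, dialect if dialect != "sbs" else f"sbs_ext{ext}", skipped)


def _strand_label(variant: Variant, hits: list, mode: str) -> str | None:
    strands = {r.strand for r in hits}
    if len(strands) != 1 or strands == {"."}:
        return None
    strand = strands.pop()
    if mode == "replication":
        # '+' encodes a rightward-moving fork, '-' leftward
        return "right" if strand == "+" else "left"
    # transcription: the mutation's pyrimidine representation lies on the
    # annotated gene's coding (untranscribed) strand when REF pyrimidine on a
    # '+' gene or REF purine on a '-' gene
    pyr_on_plus = variant.ref in PYRIMIDINES
    coding_plus = strand == "+"
    return "untranscribed" if pyr_on_plus == coding_plus else "transcribed"


def count_matrix_stranded(
    variants_by_sample: Mapping[str, Sequence[Variant]],
    genome: "Genome",
    ranges: "RegionSet",
    mode: str = "transcription",
    ext: int = 1,
) -> MutationCountMatrix:
    """192-channel strand-annotated SBS count matrix.

    ``mode='transcription'`` uses gene strands from ``ranges``;
    ``mode='replication'`` interprets region strands as fork direction.
    Mutations outside the ranges, or covered by ranges of conflicting
    strand, are excluded and tallied.
    """
    from intervaltree import IntervalTree

    if mode not in _STRAND_LABELS:
        raise MutpatError(f"unknown strand mode {mode!r}")
    if all(r.strand == "." for r in ranges.entries):
        raise MutpatError("count_matrix_stranded requires stranded ranges")

    trees: dict[str, IntervalTree] = {}
    for r in ranges.entries:
        trees.setdefault(r.contig, IntervalTree()).addi(r.start, r.end, r)

    channels = stranded_sbs_channels(mode, ext)
    skipped: dict[str, int] = {}
    data = {}
    for sample, variants in variants_by_sample.items():
        names = []
        for v in variants:
            if v.mut_type != "SBS":
                skipped["wrong_type"] = skipped.get("wrong_type", 0) + 1
                continue
            hits = [iv.data for iv in trees.get(v.contig, IntervalTree()).at(v.pos)]
            if not hits:
                skipped["outside_ranges"] = skipped.get("outside_ranges", 0) + 1
                continue
            label = _strand_label(v, hits, mode)
            if label is None:
                skipped["ambiguous_strand"] = skipped.get("ambiguous_strand", 0) + 1
                continue
            try:
                names.append(f"{sbs_context(v, genome, ext)}-{label}")
            except AmbiguousContextError:
                skipped["ambiguous_context"] = skipped.get("ambiguous_context", 0) + 1
        counts = pd.Series(names).value_counts() if names else pd.Series(dtype=int)
        data[sample] = counts.reindex(channels, fill_value=0).astype(np.int64)
    if skipped:
        logger.warning("count_matrix_stranded skipped variants: %s", skipped)
    df = pd.DataFrame(data, index=channels, dtype=np.int64)
    df.index.name = "channel"
    return MutationCountMatrix(df, f"sbs_stranded_{mode}", skipped)


def pool_samples(
    m: MutationCountMatrix, grouping: Mapping[str, str]
) -> MutationCountMatrix:
    """Sum sample columns within groups (to increase statistical power)."""
    missing = [s for s in m.samples if s not in grouping]
    if missing:
        raise MutpatError(f"samples without a group: {missing}")
    order = list(dict.fromkeys(grouping[s] for s in m.samples))
    pooled = m.counts.T.groupby([grouping[s] for s in m.samples], sort=False).sum().T
    pooled = pooled[order]
    return MutationCountMatrix(pooled, m.dialect, dict(m.skipped))


def lengthen_mut_matrix(
    matrices_by_region: Mapping[str, MutationCountMatrix],
) -> MutationCountMatrix:
    """Stack per-region count matrices into region-aware channels.

    A context like ``A[C>A]A`` counted separately in promoters and enhancers
    becomes ``A[C>A]A-promoter`` and ``A[C>A]A-enhancer``; counts are
    conserved.
    """
    items = list(matrices_by_region.items())
    if not items:
        raise MutpatError("no matrices supplied")
    ref_samples = items[0][1].samples
    ref_dialect = items[0][1].dialect
    blocks = []
    for label, m in items:
        if m.samples != ref_samples:
            raise MutpatError(
                f"sample sets differ between regions ({label!r} vs {items[0][0]!r})"
            )
        if m.dialect != ref_dialect:
            raise MutpatError("dialects differ between regions")
        block = m.counts.copy()
        block.index = [f"{ch}-{label}" for ch in block.index]
        blocks.append(block)
    df = pd.concat(blocks, axis=0)
    df.index.name = "channel"
    return MutationCountMatrix(df, f"{ref_dialect}_region_long")
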