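"""Variant classification and merging of neighboring SBSs.

Somatic variants are classified by the lengths of their REF/ALT alleles into
single (SBS), double (DBS) and multi (MBS, >= 3 bp) base substitutions, and
into insertions/deletions after trimming the shared VCF anchor base.  Variant
callers emit DBS/MBS events either explicitly or as runs of neighboring SBSs;
:func:`merge_adjacent_snvs` converts the latter representation into the
former so that a CpC>TpT dinucleotide event is never counted as two
independent C>T substitutions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._errors import MutpatError

logger = logging.getLogger("mutpat")

_COMP = str.maketrans("ACGTN", "TGCAN")

VALID_TYPES = ("SBS", "DBS", "MBS", "insertion", "deletion", "other")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMP)[::-1]


def classify_variant(ref: str, alt: str) -> str:
    """Classify a REF/ALT allele pair.

    Equal allele lengths give SBS (1 bp), DBS (2 bp) or MBS (>= 3 bp).
    Unequal lengths are trimmed of their shared prefix and suffix (the VCF
    left-anchor convention); a pure remaining insertion or deletion is
    classified as such, anything else is ``other``.
    """
    ref, alt = ref.upper(), alt.upper()
    if not ref or not alt:
        raise MutpatError("REF and ALT must be non-empty")
    for allele in (ref, alt):
        if any(b not in "ACGT" for b in allele):
            raise MutpatError(f"non-ACGT character in allele {allele!r}")
    if ref == alt:
        raise MutpatError(f"REF equals ALT ({ref!r})")
    if len(ref) == len(alt):
        if len(ref) == 1:
            return "SBS"
        if len(ref) == 2:
            return "DBS"
        return "MBS"
    # shared-base trimming: prefix first (VCF anchors left), then suffix
    i = 0
    while i < min(len(ref), len(alt)) and ref[i] == alt[i]:
        i += 1
    r, a = ref[i:], alt[i:]
    j = 0
    while j < min(len(r), len(a)) and r[len(r) - 1 - j] == a[len(a) - 1 - j]:
        j += 1
    r = r[: len(r) - j]
    a = a[: len(a) - j]
    if not r and a:
        return "insertion"
    if r and not a:
        return "deletion"
    return "other"


@dataclass(frozen=True)
class Variant:
    """One somatic event; the atom of all downstream analyses.

    Coordinates are 0-based; ``pos`` is the position of the first REF base.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    sample: str = "sample"
    mut_type: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if not self.mut_type:
            object.__setattr__(self, "mut_type", classify_variant(self.ref, self.alt))
        elif self.mut_type not in VALID_TYPES:
            raise MutpatError(f"unknown mut_type {self.mut_type!r}")

    @property
    def end(self) -> int:
        """0-based exclusive end of the REF allele."""
        return self.pos + len(self.ref)


def _check_sorted(variants: Sequence[Variant]) -> None:
    by_key: dict[tuple[str, str], int] = {}
    for v in variants:
        key = (v.sample, v.contig)
        prev = by_key.get(key)
        if prev is not None and v.pos < prev:
            raise MutpatError(
                f"variants not sorted: {v.contig}:{v.pos} after {prev} "
                f"(sample {v.sample})"
            )
        by_key[key] = v.pos


def merge_adjacent_snvs(variants: Sequence[Variant]) -> list[Variant]:
    """Merge maximal runs of positionally adjacent SBSs into DBS/MBS events.

    Merging is per sample and per contig: a DBS is a single-cell event, so
    SBSs from different samples are never combined.  Non-adjacent SBSs and
    non-SBS variants pass through untouched.  Input must be position-sorted
    within each sample/contig; output preserves that ordering.
    """
    _check_sorted(variants)
    out: list[Variant] = []
    run: list[Variant] = []

    def flush() -> None:
        if not run:
            return
        if len(run) == 1:
            out.append(run[0])
        else:
            ref = "".join(v.ref for v in run)
            alt = "".join(v.alt for v in run)
            out.append(Variant(run[0].contig, run[0].pos, ref, alt, run[0].sample))
        run.clear()

    for v in variants:
        if v.mut_type != "SBS":
            flush()
            out.append(v)
            continue
        if (
            run
            and v.sample == run[-1].sample
            and v.contig == run[-1].contig
            and v.pos == run[-1].pos + 1
        ):
            run.append(v)
        else:
            flush()
            run.append(v)
    flush()
    return out


_TYPE_ALIASES = {
    "snv": ("SBS",),
    "sbs": ("SBS",),
    "dbs": ("DBS",),
    "mbs": ("MBS",),
    "indel": ("insertion", "deletion"),
    "insertion": ("insertion",),
    "deletion": ("deletion",),
    "all": ("SBS", "DBS", "MBS", "insertion", "deletion"),
}


def get_mut_type(
    variants: Sequence[Variant],
    mut_type: str = "all",
    predefined_dbs_mbs: bool = False,
) -> list[Variant]:
    """Select variants of one type, merging adjacent SBSs first by default.

    With ``predefined_dbs_mbs=True`` caller-provided DBS/MBS records are
    trusted as-is and no merging takes place.  SBSs that were part of an
    adjacent run are then returned as the merged DBS/MBS event and never as
    separate SBSs.
    """
    key = mut_type.lower()
    if key not in _TYPE_ALIASES:
        raise MutpatError(
            f"unknown type selector {mut_type!r}; choose from {sorted(_TYPE_ALIASES)}"
        )
    pool = list(variants) if predefined_dbs_mbs else merge_adjacent_snvs(variants)
    wanted = _TYPE_ALIASES[key]
    n_other = sum(1 for v in pool if v.mut_type == "other")
    if n_other:
        logger.warning(
            "%d complex substitution(s) classified 'other' are excluded "
            "from all counting",
            n_other,
        )
    return [v for v in pool if v.mut_type in wanted]
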