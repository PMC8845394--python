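"""External formats: FASTA genomes, VCF variants, region tables and signature catalogs.

Internal coordinates are 0-based half-open everywhere; VCF (1-based) and BED
(0-based half-open) are converted at this boundary and nowhere else.

Signature catalogs
------------------
The :func:`get_known_signatures` entry point mirrors the published catalog
interface (COSMIC v3.1/v3.2 SBS/DBS/ID, SIGNAL v1 SBS, SparseSignatures v1
SBS).  The catalogs bundled here are **synthetic stand-ins** for the
published matrices: deterministic probability profiles generated from fixed
seeds, with etiology-informed shapes for a handful of well-characterized
signatures (e.g. the CpG-deamination clock signature SBS1, the APOBEC
signatures SBS2/SBS13, the UV signature family SBS7, the POLE signature
SBS10a) and heterogeneous sparsity for the rest.  They have the correct
channel systems, column normalization and naming conventions, and realistic
statistical character, but their numerical values do not reproduce the
published catalogs.  Artifact flagging follows the publicly documented
COSMIC list (SBS27, SBS43, SBS45-SBS60): those columns are excluded unless
``include_artifacts`` is set.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ContigMissingError, MutpatError
from .context_engine import (
    PURINES,
    SBS_CLASSES,
    dbs_channels,
    id_channels,
    sbs_channels,
)
from .variant_typing import Variant, classify_variant

logger = logging.getLogger("mutpat")


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


class Genome:
    """Reference genome with uppercase subsequence access over {A,C,G,T,N}.

    Backed either by an in-memory dict of contig sequences or by an indexed
    FASTA file (pyfaidx).  Requested ranges outside a contig raise.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}
        self._lengths = {name: len(seq) for name, seq in self._seqs.items()}
        self._fasta = None

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        from pyfaidx import Fasta

        obj = cls.__new__(cls)
        obj._fasta = Fasta(str(path), sequence_always_upper=True)
        obj._seqs = None
        obj._lengths = {name: len(rec) for name, rec in obj._fasta.items()}
        return obj

    @property
    def contigs(self) -> list[str]:
        return list(self._lengths)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self._lengths)

    def length(self, contig: str) -> int:
        try:
            return self._lengths[contig]
        except KeyError:
            raise ContigMissingError(f"contig {contig!r} not in genome") from None

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Uppercase subsequence [start, end); errors outside the contig."""
        n = self.length(contig)
        if start < 0 or end > n or start > end:
            raise MutpatError(
                f"range [{start}, {end}) outside contig {contig!r} (length {n})"
            )
        if self._seqs is not None:
            return self._seqs[contig][start:end]
        return str(self._fasta[contig][start:end])


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


def read_vcf(
    path,
    sample_name: str,
    genome: Genome,
    pass_only: bool = True,
    strip_chr_prefix: bool = False,
) -> list[Variant]:
    """Read somatic variants from a VCF 4.x file.

    One :class:`Variant` per ALT allele (multi-allelic records are split);
    REF/ALT strings are taken verbatim and positions converted to 0-based.
    Only PASS records are kept by default (``pass_only=False`` disables; the
    quality of every downstream result depends on stringent input
    filtering).  Records whose REF disagrees with the genome, or whose
    contig is missing, raise; symbolic/non-ACGT ALTs are skipped with a
    warning.
    """
    import pysam

    variants: list[Variant] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf, start=1):
            try:
                contig = rec.contig
                if strip_chr_prefix and contig.startswith("chr"):
                    contig = contig[3:]
                if contig not in genome.lengths:
                    raise ContigMissingError(
                        f"contig {contig!r} (record {i}) not in genome; "
                        "exact contig-name match is required"
                    )
                filters = list(rec.filter.keys())
                if pass_only and filters and filters != ["PASS"]:
                    continue
                ref = rec.ref.upper()
                genome_ref = genome.fetch(contig, rec.start, rec.start + len(ref))
                if genome_ref != ref:
                    raise MutpatError(
                        f"REF {ref!r} at {contig}:{rec.pos} (record {i}) "
                        f"disagrees with genome base(s) {genome_ref!r}"
                    )
                for alt in rec.alts or ():
                    alt = alt.upper()
                    if not alt or any(b not in "ACGT" for b in alt) or alt == ref:
                        n_skipped += 1
                        continue
                    variants.append(Variant(contig, rec.start, ref, alt, sample_name))
            except (ContigMissingError, MutpatError):
                raise
            except Exception as exc:  # malformed record
                raise MutpatError(f"malformed VCF record {i} in {path}: {exc}") from exc
    if n_skipped:
        logger.warning("read_vcf skipped %d symbolic/non-ACGT ALT allele(s)", n_skipped)
    order = {c: k for k, c in enumerate(genome.contigs)}
    variants.sort(key=lambda v: (order.get(v.contig, len(order)), v.pos))
    return variants


# ---------------------------------------------------------------------------
# RegionSet
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Region:
    contig: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    label: str
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise MutpatError(f"negative coordinate in region {self}")
        if self.start >= self.end:
            raise MutpatError(f"start >= end in region {self}")
        if not self.label:
            raise MutpatError("region labels must be non-empty")
        if self.strand not in "+-.":
            raise MutpatError(f"bad strand {self.strand!r}")


@dataclass
class RegionSet:
    """Labeled genomic intervals (0-based half-open)."""

    entries: list[Region] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def sorted(self) -> "RegionSet":
        return RegionSet(sorted(self.entries, key=lambda r: (r.contig, r.start, r.end)))

    @property
    def labels(self) -> list[str]:
        return list(dict.fromkeys(r.label for r in self.entries))

    def total_bp(self) -> int:
        return sum(r.end - r.start for r in self.entries)

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.entries:
                fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.label}\t.\t{r.strand}\n")


def read_region_set(
    path,
    format: str = "bed",
    one_based: bool = False,
    label: str | None = None,
) -> RegionSet:
    """Read regions from a BED (0-based half-open) or TSV interval file.

    ``one_based=True`` interprets start/end columns as 1-based inclusive
    (common in plain TSV tables) and converts.  Labels come from the name
    column when present, else from ``label``, else ``"region"``.
    """
    if format not in ("bed", "tsv"):
        raise MutpatError(f"unknown region format {format!r}")
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("region file %s is empty", path)
        return RegionSet([])
    if df.shape[1] < 3:
        raise MutpatError(f"{path}: expected at least 3 columns")
    entries = []
    for row in df.itertuples(index=False):
        start, end = int(row[1]), int(row[2])
        if one_based:
            start -= 1
        lab = (
            str(row[3])
            if df.shape[1] > 3 and not pd.isna(row[3])
            else (label or "region")
        )
        strand = str(row[5]) if df.shape[1] > 5 and str(row[5]) in "+-" else "."
        entries.append(Region(str(row[0]), start, end, lab, strand))
    return RegionSet(entries)


# ---------------------------------------------------------------------------
# SignatureMatrix
# ---------------------------------------------------------------------------


@dataclass
class SignatureMatrix:
    """Channels x signatures probability matrix; columns sum to one."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if (v.values < 0).any():
            raise MutpatError("signature values must be non-negative")
        sums = v.sum(axis=0)
        if (sums <= 0).any():
            bad = list(sums.index[sums <= 0])
            raise MutpatError(f"all-zero signature column(s): {bad}")
        self.values = v / sums

    @property
    def channels(self) -> list[str]:
        return list(self.values.index)

    @property
    def signatures(self) -> list[str]:
        return list(self.values.columns)

    def __getitem__(self, name: str) -> pd.Series:
        return self.values[name]

    def select(self, names: Sequence[str]) -> "SignatureMatrix":
        return SignatureMatrix(self.values[list(names)].copy())

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="channel")

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)


# ---------------------------------------------------------------------------
# bundled (synthetic stand-in) signature catalogs
# ---------------------------------------------------------------------------

_COSMIC_V31_SBS = (
    ["SBS1", "SBS2", "SBS3", "SBS4", "SBS5", "SBS6"]
    + ["SBS7a", "SBS7b", "SBS7c", "SBS7d", "SBS8", "SBS9", "SBS10a", "SBS10b"]
    + [f"SBS{i}" for i in range(11, 17)]
    + ["SBS17a", "SBS17b"]
    + [f"SBS{i}" for i in range(18, 45)]
    + [f"SBS{i}" for i in range(45, 61)]
    + [f"SBS{i}" for i in range(84, 91)]
)
_COSMIC_V32_SBS = _COSMIC_V31_SBS + ["SBS91", "SBS92", "SBS93", "SBS94"]
_COSMIC_ARTIFACTS = frozenset({"SBS27", "SBS43"} | {f"SBS{i}" for i in range(45, 61)})

_CATALOGS: dict[tuple[str, str], list[str]] = {
    ("COSMIC_v3.1", "snv"): _COSMIC_V31_SBS,
    ("COSMIC_v3.2", "snv"): _COSMIC_V32_SBS,
    ("COSMIC_v3.1", "dbs"): [f"DBS{i}" for i in range(1, 12)],
    ("COSMIC_v3.2", "dbs"): [f"DBS{i}" for i in range(1, 12)],
    ("COSMIC_v3.1", "indel"): [f"ID{i}" for i in range(1, 19)],
    ("COSMIC_v3.2", "indel"): [f"ID{i}" for i in range(1, 19)],
    ("SIGNAL", "snv"): [f"RefSig{i}" for i in range(1, 49)],
    ("SparseSignatures", "snv"): [f"Sparse{i}" for i in range(1, 11)],
}

_BUILDS = {
    "COSMIC_v3.1": ("GRCh37", "GRCh38"),
    "COSMIC_v3.2": ("GRCh37", "GRCh38"),
    "SIGNAL": ("GRCh37",),
    "SparseSignatures": ("GRCh37",),
}

# etiology-informed SBS peak masks: (substitution, 5' bases, 3' bases, mass)
_SBS_SHAPES: dict[str, list[tuple[str, str, str, float]]] = {
    "SBS1": [("C>T", "ACGT", "G", 0.75)],  # 5-mC deamination at NpCpG
    "SBS2": [("C>T", "T", "AT", 0.75)],  # APOBEC
    "SBS4": [("C>A", "ACGT", "ACT", 0.55)],  # tobacco-adduct C>A
    "SBS6": [("C>T", "G", "ACGT", 0.55)],
    "SBS7a": [("C>T", "CT", "CT", 0.80)],  # UV pyrimidine dimers
    "SBS10a": [("C>A", "T", "T", 0.75)],  # POLE-exo domain
    "SBS10b": [("C>T", "T", "GT", 0.70)],
    "SBS13": [("C>G", "T", "AT", 0.80)],  # APOBEC (REV1 branch)
    "SBS17b": [("T>G", "C", "T", 0.80)],
    "SBS18": [("C>A", "ACGT", "AT", 0.55)],  # reactive oxygen species
    "SBS30": [("C>T", "ACGT", "ACT", 0.50)],  # NTHL1-type C>T
}
_SBS_FLAT = {"SBS3": 10.0, "SBS5": 6.0, "SBS40": 8.0}  # near-flat clock-like
_SBS_FAMILY = {  # members generated as perturbations of a shared base shape
    "SBS7b": "SBS7a",
    "SBS7c": "SBS7a",
    "SBS7d": "SBS7a",
    "SBS17a": "SBS17b",
}

_ID_SHAPES = {
    "ID1": ["1:Ins:T:4", "1:Ins:T:5"],  # polymerase slippage in T runs
    "ID2": ["1:Del:T:4", "1:Del:T:5"],
    "ID6": ["5:Del:M:5", "5:Del:M:4", "4:Del:M:3"],  # MH-mediated deletions
}
_DBS_SHAPES = {"DBS1": ["CC>TT"]}  # UV CC>TT dimer


def _rng_for(*parts: str) -> np.random.Generator:
    seed = zlib.crc32("|".join(parts).encode())
    return np.random.default_rng(seed)


def _sbs_profile(name: str, channels: list[str]) -> np.ndarray:
    rng = _rng_for("catalog-sbs", name)
    n = len(channels)
    if name in _SBS_FLAT:
        return rng.dirichlet(np.full(n, _SBS_FLAT[name]))
    base_name = _SBS_FAMILY.get(name)
    if base_name is not None:
        base = _sbs_profile(base_name, channels)
        own = rng.dirichlet(np.full(n, 0.15))
        p = 0.6 * base + 0.4 * own
        return p / p.sum()
    shapes = _SBS_SHAPES.get(name)
    if shapes is not None:
        p = rng.dirichlet(np.full(n, 0.10)) * (1 - sum(s[3] for s in shapes))
        for sub, ups, downs, mass in shapes:
            mask = np.array(
                [
                    ch[2:5] == sub and ch[0] in ups and ch[6] in downs
                    for ch in channels
                ],
                dtype=float,
            )
            weights = rng.dirichlet(np.full(int(mask.sum()), 1.5))
            p[mask.astype(bool)] += mass * weights
        return p / p.sum()
    alpha = float(np.exp(rng.uniform(np.log(0.05), np.log(2.0))))
    return rng.dirichlet(np.full(n, alpha))


def _generic_profile(kind: str, name: str, channels: list[str]) -> np.ndarray:
    rng = _rng_for(f"catalog-{kind}", name)
    n = len(channels)
    shapes = (_ID_SHAPES if kind == "indel" else _DBS_SHAPES).get(name)
    if shapes is not None:
        p = rng.dirichlet(np.full(n, 0.3)) * (1 - 0.7)
        idx = [channels.index(c) for c in shapes]
        w = rng.dirichlet(np.full(len(idx), 2.0))
        for i, wi in zip(idx, w):
            p[i] += 0.7 * wi
        return p / p.sum()
    alpha = float(np.exp(rng.uniform(np.log(0.1), np.log(2.0))))
    return rng.dirichlet(np.full(n, alpha))


@lru_cache(maxsize=None)
def _synthetic_catalog(source: str, mut_type: str) -> pd.DataFrame:
    names = _CATALOGS[(source, mut_type)]
    if mut_type == "snv":
        channels = sbs_channels(1)
        cols = {name: _sbs_profile(name, channels) for name in names}
    elif mut_type == "dbs":
        channels = dbs_channels()
        cols = {name: _generic_profile("dbs", name, channels) for name in names}
    else:
        channels = id_channels()
        cols = {name: _generic_profile("indel", name, channels) for name in names}
    df = pd.DataFrame(cols, index=channels)
    df.index.name = "channel"
    return df


def get_known_signatures(
    mut_type: str = "snv",
    source: str = "COSMIC_v3.1",
    include_artifacts: bool = False,
    genome_build: str = "GRCh37",
) -> SignatureMatrix:
    """Load a bundled signature catalog (synthetic stand-in; see module docs).

    Signatures flagged as possible sequencing artifacts (COSMIC SBS27,
    SBS43, SBS45-SBS60) are excluded unless ``include_artifacts`` is set.
    Only genome builds the sources publish are accepted; there is no
    lift-over.
    """
    mut_type = mut_type.lower()
    key = (source, mut_type)
    if key not in _CATALOGS:
        avail = sorted(f"{s}/{t}" for s, t in _CATALOGS)
        raise MutpatError(
            f"no bundled catalog for source={source!r} mut_type={mut_type!r}; "
            f"available: {avail}"
        )
    if genome_build not in _BUILDS[source]:
        raise MutpatError(
            f"{source} is published for {_BUILDS[source]}, not {genome_build!r}"
        )
    df = _synthetic_catalog(source, mut_type).copy()
    if not include_artifacts and source.startswith("COSMIC") and mut_type == "snv":
        keep = [c for c in df.columns if c not in _COSMIC_ARTIFACTS]
        df = df[keep]
    return SignatureMatrix(df)
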