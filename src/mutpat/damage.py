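"""Signature-specific damaging potential over a gene set.

For a set of protein-coding genes, every possible single-base change in
their CDS is enumerated and classified by codon translation as stop-gain,
missense or synonymous; the two intronic bases flanking each internal CDS
exon junction (the canonical donor/acceptor dinucleotides) contribute all
three possible changes as splice-site.  Each possible change is binned by
its SBS-96 context, giving per-context consequence ratios.  A signature's
damage potential per consequence is then the context-weighted sum of those
ratios, normalized against a hypothetical flat signature with weight 1/96
on every context — so the flat signature scores exactly 1 for every
consequence, and a score of 3.6 means "3.6 times as likely as a flat
mutational process to cause this consequence on these genes".

Only sequence context is considered; chromatin state and expression are
tissue specific and deliberately ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from ._errors import ChannelMismatchError, MutpatError
from .context_engine import PURINES, sbs_channels
from .io_formats import Genome, SignatureMatrix
from .variant_typing import revcomp

logger = logging.getLogger("mutpat")

CONSEQUENCES = ("stop_gain", "missense", "synonymous", "splice_site")

_CODON_TABLE = {}


def _codon_table() -> dict[str, str]:
    # standard genetic code via Biopython
    global _CODON_TABLE
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


@dataclass(frozen=True)
class Gene:
    """CDS exon structure of one protein-coding transcript."""

    name: str
    contig: str
    strand: str  # '+' or '-'
    cds_exons: tuple[tuple[int, int], ...]  # 0-based half-open, genomic order

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise MutpatError(f"gene {self.name}: strand must be + or -")
        prev_end = -1
        for start, end in self.cds_exons:
            if start >= end or start < prev_end:
                raise MutpatError(f"gene {self.name}: bad/unsorted CDS exons")
            prev_end = end

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_exons)


def read_gene_models(path, format: str = "gff3") -> list[Gene]:
    """Read CDS exon structures from GFF3 (CDS features) or BED12."""
    if format == "gff3":
        return _read_gff3(path)
    if format == "bed12":
        return _read_bed12(path)
    raise MutpatError(f"unknown gene model format {format!r}")


def _read_gff3(path) -> list[Gene]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        parent = (cds.attributes.get("Parent") or [cds.id or "gene"])[0]
        rec = genes.setdefault(
            parent, {"contig": cds.seqid, "strand": cds.strand, "exons": []}
        )
        rec["exons"].append((cds.start - 1, cds.end))  # GFF3 is 1-based inclusive
    out = []
    for name, rec in genes.items():
        out.append(
            Gene(name, rec["contig"], rec["strand"], tuple(sorted(rec["exons"])))
        )
    return out


def _read_bed12(path) -> list[Gene]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise MutpatError("BED12 requires 12 columns")
            chrom, chrom_start = f[0], int(f[1])
            name, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = []
            for size, off in zip(sizes, starts):
                s = chrom_start + off
                e = s + size
                s, e = max(s, thick_start), min(e, thick_end)  # clip to CDS
                if s < e:
                    exons.append((s, e))
            if exons:
                out.append(Gene(name, chrom, strand, tuple(exons)))
    return out


@dataclass
class ContextDamageTable:
    """Per (SBS-96 context, consequence): possible-change counts and ratios.

    ``n`` counts the genomic single-base changes of that context causing the
    consequence over the gene set; ``ratio`` divides by the total enumerated
    possibilities of that context, so ratios of one context sum to 1 across
    consequences.
    """

    table: pd.DataFrame  # columns: context, consequence, n, ratio

    def contexts(self) -> list[str]:
        return list(dict.fromkeys(self.table["context"]))

    def ratio(self, context: str, consequence: str) -> float:
        sel = self.table[
            (self.table["context"] == context)
            & (self.table["consequence"] == consequence)
        ]
        return float(sel["ratio"].iloc[0]) if len(sel) else 0.0


def _context_of(genome: Genome, contig: str, pos: int, alt: str) -> str:
    """Pyrimidine-collapsed SBS-96 channel of changing ``pos`` to ``alt``."""
    seq = genome.fetch(contig, pos - 1, pos + 2)
    ref = seq[1]
    up, down = seq[0], seq[2]
    if ref in PURINES:
        ref, alt = revcomp(ref), revcomp(alt)
        up, down = revcomp(down), revcomp(up)
    return f"{up}[{ref}>{alt}]{down}"


def enumerate_cds_mutations(
    genes: Sequence[Gene], genome: Genome
) -> ContextDamageTable:
    """Enumerate every possible CDS and splice-site single-base change.

    Every CDS position is mutated to each of its three alternative bases and
    classified by codon translation (stop_gain when the new codon is a stop
    and the old is not; synonymous when the amino acid is unchanged; else
    missense, which also absorbs the rare stop-loss change).  The two
    intronic bases on each side of internal exon junctions contribute all
    three changes as splice_site.  Genes whose CDS length is not a multiple
    of three are skipped with a warning.
    """
    code = _codon_table()
    counts: dict[tuple[str, str], int] = {}

    def bump(context: str, consequence: str) -> None:
        counts[(context, consequence)] = counts.get((context, consequence), 0) + 1

    for gene in genes:
        if gene.cds_length() % 3 != 0:
            logger.warning(
                "gene %s: CDS length %d not a multiple of 3; skipped",
                gene.name,
                gene.cds_length(),
            )
            continue
        # genomic positions of CDS bases in transcription order
        positions: list[int] = []
        for start, end in gene.cds_exons:
            positions.extend(range(start, end))
        if gene.strand == "-":
            positions = positions[::-1]
        cds = "".join(
            genome.fetch(gene.contig, p, p + 1) for p in positions
        )
        if gene.strand == "-":
            cds = "".join(revcomp(b) for b in cds)
        if "N" in cds:
            logger.warning("gene %s: N in CDS; skipped", gene.name)
            continue
        for i, pos in enumerate(positions):
            codon_i = i // 3
            offset = i % 3
            codon = cds[3 * codon_i : 3 * codon_i + 3]
            old_aa = code[codon]
            base = cds[i]  # coding-strand base
            for alt_coding in "ACGT":
                if alt_coding == base:
                    continue
                new_codon = codon[:offset] + alt_coding + codon[offset + 1 :]
                new_aa = code[new_codon]
                if new_aa == "*" and old_aa != "*":
                    consequence = "stop_gain"
                elif new_aa == old_aa:
                    consequence = "synonymous"
                else:
                    consequence = "missense"
                # genomic-strand ALT for context binning
                alt_genomic = alt_coding if gene.strand == "+" else revcomp(alt_coding)
                bump(_context_of(genome, gene.contig, pos, alt_genomic), consequence)
        # splice sites: 2 intronic bases at each internal junction
        for (s1, e1), (s2, e2) in zip(gene.cds_exons, gene.cds_exons[1:]):
            splice_positions = [e1, e1 + 1, s2 - 2, s2 - 1]
            for pos in splice_positions:
                if not (e1 <= pos < s2):  # intron too short to host both sites
                    continue
                ref = genome.fetch(gene.contig, pos, pos + 1)
                if ref == "N":
                    continue
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    bump(_context_of(genome, gene.contig, pos, alt), "splice_site")

    rows = []
    contexts = sorted({ctx for ctx, _ in counts})
    for ctx in contexts:
        total = sum(counts.get((ctx, cons), 0) for cons in CONSEQUENCES)
        for cons in CONSEQUENCES:
            n = counts.get((ctx, cons), 0)
            rows.append(
                {"context": ctx, "consequence": cons, "n": n, "ratio": n / total}
            )
    return ContextDamageTable(pd.DataFrame(rows))


def signature_potential_damage(
    t: ContextDamageTable, S: SignatureMatrix
) -> pd.DataFrame:
    """Weighted damage potential per signature, normalized to a flat signature.

    For each signature and consequence the per-context ratios are combined
    with the signature's channel weights; the flat signature (1/96 per
    context) provides the normalization so its own normalized ratio is
    exactly 1.  Contexts absent from the gene set contribute nothing to
    either numerator (a warning reports incomplete coverage).
    ``n_per_kmut`` is the expected number of such consequences per 1000
    mutations drawn from the signature.
    """
    contexts = t.contexts()
    missing = [c for c in S.channels if c not in contexts]
    if missing:
        logger.warning(
            "%d of %d signature channels not covered by the gene set",
            len(missing),
            len(S.channels),
        )
    ratio = {
        (row.context, row.consequence): row.ratio for row in t.table.itertuples()
    }
    n_channels = len(S.channels)
    rows = []
    flat = 1.0 / n_channels
    for cons in CONSEQUENCES:
        flat_ratio = sum(
            flat * ratio.get((ctx, cons), 0.0) for ctx in S.channels
        )
        for sig in S.signatures:
            weights = S[sig]
            weighted = sum(
                float(weights[ctx]) * ratio.get((ctx, cons), 0.0)
                for ctx in S.channels
            )
            rows.append(
                {
                    "signature": sig,
                    "consequence": cons,
                    "weighted_ratio": weighted,
                    "normalized_ratio": weighted / flat_ratio if flat_ratio > 0 else float("nan"),
                    "n_per_kmut": 1000 * weighted,
                }
            )
    return pd.DataFrame(rows)


def flat_signature(channels: Sequence[str] | None = None) -> SignatureMatrix:
    """The hypothetical flat signature: equal weight on every context."""
    channels = list(channels) if channels is not None else sbs_channels(1)
    df = pd.DataFrame({"flat": [1.0] * len(channels)}, index=channels)
    df.index.name = "channel"
    return SignatureMatrix(df)
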