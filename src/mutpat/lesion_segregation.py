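"""Lesion segregation: Watson/Crick strand asymmetry of substitutions.

Unrepaired DNA lesions that persist through replication segregate with
their sister chromatids into different daughter cells, leaving each cell
with long runs of mutations whose pyrimidine representation sits on one
strand.  A substitution is assigned to the "+" strand when its REF base is
a pyrimidine (C or T) and to the "-" strand when it is a purine (G or A).
Lesion segregation is then detected as an excess of adjacent same-strand
mutation pairs (exact binomial test against 1/2), optionally split by
substitution class, or summarized by the rl20 run statistic: the shortest
run length within the minimal set of longest same-strand runs that jointly
cover >= 20% of a sample's mutations.  Values above 5 indicate lesion
segregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._errors import MutpatError
from .context_engine import PYRIMIDINES, SBS_CLASSES
from .variant_typing import Variant, revcomp

logger = logging.getLogger("mutpat")


@dataclass
class StrandSeries:
    """Per-contig ordered positions with strand labels for one sample."""

    positions: dict[str, np.ndarray]  # contig -> increasing bp positions
    strands: dict[str, np.ndarray]  # contig -> '+'/'-' per mutation
    classes: dict[str, np.ndarray]  # contig -> pyrimidine substitution class
    sample: str = "sample"

    def chromosome_means(self) -> pd.Series:
        """Per-contig mean strand, with '+' = 1 and '-' = 0."""
        return pd.Series(
            {c: float((s == "+").mean()) for c, s in self.strands.items()}
        )

    @property
    def n_mutations(self) -> int:
        return sum(len(p) for p in self.positions.values())


def assign_strand(variants: Sequence[Variant], sample: str = "sample") -> StrandSeries:
    """Strand series of a sample's SBSs: C/T ref -> '+', G/A ref -> '-'."""
    per_contig: dict[str, list[tuple[int, str, str]]] = {}
    n_skip = 0
    for v in variants:
        if v.mut_type != "SBS":
            n_skip += 1
            continue
        strand = "+" if v.ref in PYRIMIDINES else "-"
        ref, alt = (v.ref, v.alt) if strand == "+" else (revcomp(v.ref), revcomp(v.alt))
        per_contig.setdefault(v.contig, []).append((v.pos, strand, f"{ref}>{alt}"))
    if n_skip:
        logger.warning("assign_strand excluded %d non-SBS variant(s)", n_skip)
    positions, strands, classes = {}, {}, {}
    for contig, rows in per_contig.items():
        rows.sort()
        positions[contig] = np.array([r[0] for r in rows])
        strands[contig] = np.array([r[1] for r in rows])
        classes[contig] = np.array([r[2] for r in rows])
        if len(rows) > 1 and (np.diff(positions[contig]) <= 0).any():
            raise MutpatError(f"duplicate positions on contig {contig}")
    return StrandSeries(positions, strands, classes, sample)


@dataclass
class LesionSegregationResult:
    sample: str
    mode: str
    fraction_same_strand: float | None = None
    p: float | None = None
    fdr: float | None = None
    rl20: int | None = None
    genomic_span_fraction: float | None = None
    per_type: pd.DataFrame | None = None
    insufficient: bool = False


def _adjacent_pairs(series: StrandSeries, per_class: str | None = None):
    """(same, total) adjacent same-contig pair counts, optionally per class."""
    same = total = 0
    for contig, strands in series.strands.items():
        if per_class is not None:
            mask = series.classes[contig] == per_class
            strands = strands[mask]
        if len(strands) < 2:
            continue
        eq = strands[1:] == strands[:-1]
        same += int(eq.sum())
        total += len(eq)
    return same, total


def _runs(strands: np.ndarray) -> list[int]:
    """Lengths of maximal same-strand runs (in mutations)."""
    if len(strands) == 0:
        return []
    change = np.flatnonzero(strands[1:] != strands[:-1])
    bounds = np.concatenate(([0], change + 1, [len(strands)]))
    return list(np.diff(bounds))


def calculate_rl20(series: StrandSeries) -> tuple[int, float]:
    """rl20 and the genomic span fraction of the runs that realize it.

    Each contig's strand series is decomposed into maximal same-strand runs;
    run lengths (in mutations) are sorted descending and the smallest prefix
    whose summed lengths reach 20% of the sample's mutations is taken.  rl20
    is the shortest run in that prefix (the run completing the threshold is
    included).  The genomic span fraction relates the bp extent of those
    runs to the bp extent of all mutations.
    """
    runs = []  # (length, span_bp)
    total_span = 0
    total_muts = series.n_mutations
    if total_muts == 0:
        raise MutpatError("no mutations in series")
    for contig, strands in series.strands.items():
        pos = series.positions[contig]
        if len(pos) == 0:
            continue
        total_span += int(pos[-1] - pos[0] + 1)
        start = 0
        for ln in _runs(strands):
            runs.append((ln, int(pos[start + ln - 1] - pos[start] + 1)))
            start += ln
    runs.sort(key=lambda r: -r[0])
    needed = 0.2 * total_muts
    acc = 0
    span = 0
    rl20 = runs[-1][0]
    for ln, sp in runs:
        acc += ln
        span += sp
        rl20 = ln
        if acc >= needed:
            break
    return rl20, span / max(total_span, 1)


def test_lesion_segregation(
    series: StrandSeries, mode: str = "binomial"
) -> LesionSegregationResult:
    """Test one sample's strand series for lesion segregation.

    ``binomial``: exact two-sided binomial test of the number of adjacent
    same-strand pairs against p = 1/2 (pairs never span contigs).
    ``split_by_type``: the same test within each of the six substitution
    classes.  ``rl20``: the run-length statistic (see
    :func:`calculate_rl20`).
    """
    if mode == "binomial":
        same, total = _adjacent_pairs(series)
        if total < 2:
            return LesionSegregationResult(series.sample, mode, insufficient=True)
        p = stats.binomtest(same, total, 0.5).pvalue
        return LesionSegregationResult(
            series.sample, mode, fraction_same_strand=same / total, p=float(p)
        )
    if mode == "split_by_type":
        rows = []
        for cls in SBS_CLASSES:
            same, total = _adjacent_pairs(series, per_class=cls)
            if total < 2:
                rows.append({"type": cls, "fraction_same_strand": np.nan, "p": np.nan})
                continue
            p = stats.binomtest(same, total, 0.5).pvalue
            rows.append(
                {"type": cls, "fraction_same_strand": same / total, "p": float(p)}
            )
        table = pd.DataFrame(rows)
        ok = table["p"].notna()
        if ok.any():
            table.loc[ok, "fdr"] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
        return LesionSegregationResult(series.sample, mode, per_type=table)
    if mode == "rl20":
        same, total = _adjacent_pairs(series)
        rl20, span_frac = calculate_rl20(series)
        return LesionSegregationResult(
            series.sample,
            mode,
            fraction_same_strand=(same / total) if total else None,
            rl20=rl20,
            genomic_span_fraction=span_frac,
        )
    raise MutpatError(f"unknown mode {mode!r}")


def test_lesion_segregation_samples(
    variants_by_sample: Mapping[str, Sequence[Variant]], mode: str = "binomial"
) -> pd.DataFrame:
    """Run the lesion-segregation test per sample with BH FDR across samples."""
    rows = []
    for sample, variants in variants_by_sample.items():
        series = assign_strand(variants, sample)
        res = test_lesion_segregation(series, mode)
        rows.append(
            {
                "sample": sample,
                "fraction_same_strand": res.fraction_same_strand,
                "p": res.p,
                "rl20": res.rl20,
                "genomic_span_fraction": res.genomic_span_fraction,
                "insufficient": res.insufficient,
            }
        )
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def plot_lesion_segregation(
    series: StrandSeries, out_png=None, out_tsv=None
) -> pd.DataFrame:
    """Jitter plot of strand per mutation along each contig, plus the
    per-mutation table (contig, position, strand, chromosome mean)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    means = series.chromosome_means()
    recs = []
    for contig in series.positions:
        for pos, strand in zip(series.positions[contig], series.strands[contig]):
            recs.append(
                {
                    "contig": contig,
                    "position": int(pos),
                    "strand": strand,
                    "chromosome_mean": means[contig],
                }
            )
    table = pd.DataFrame(recs)
    contigs = list(series.positions)
    fig, axes = plt.subplots(1, max(len(contigs), 1), figsize=(3 * max(len(contigs), 1), 2.5), squeeze=False)
    rng = np.random.default_rng(0)
    for ax, contig in zip(axes.ravel(), contigs):
        sub = table[table["contig"] == contig]
        y = (sub["strand"] == "+").astype(float) + rng.uniform(-0.1, 0.1, len(sub))
        ax.scatter(sub["position"], y, s=4)
        ax.axhline(means[contig], color="red", lw=1)
        ax.set_title(str(contig), fontsize=8)
        ax.set_yticks([0, 1], ["-", "+"])
    fig.tight_layout()
    if out_tsv is not None:
        table.to_csv(out_tsv, sep="\t", index=False)
    if out_png is not None:
        fig.savefig(out_png, dpi=120)
    plt.close(fig)
    return table
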