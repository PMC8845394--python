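"""Regional mutation analyses.

Splits mutations by labeled genomic regions, tests regional mutation loads
for enrichment/depletion with an exact Poisson test under a
surveyed-territory expectation (BH false-discovery-rate corrected across all
region x sample tests), stratifies the genome by local mutation density,
and scans the genome with a sliding window of consecutive mutations whose
SBS-96 profile is compared (cosine) against the profile of all remaining
mutations — an unsupervised way to find regions where a different mutational
process is active.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._errors import AmbiguousContextError, MutpatError
from .context_engine import sbs_channels, sbs_context
from .io_formats import Genome, Region, RegionSet
from .spectra import cosine_similarity
from .variant_typing import Variant, revcomp

logger = logging.getLogger("mutpat")


# ---------------------------------------------------------------------------
# split_muts_region
# ---------------------------------------------------------------------------


def split_muts_region(
    variants: Sequence[Variant],
    regions: RegionSet,
    include_other: bool = True,
    priority: Sequence[str] | None = None,
) -> dict[str, list[Variant]]:
    """Assign each variant to the label of a covering region.

    Overlap ties are broken by ``priority`` (first label wins; defaults to
    label order of first appearance in ``regions``), so each variant is
    assigned exactly once and counts are conserved.  Uncovered variants go
    to ``"other"`` when ``include_other`` is set, else they are dropped.
    """
    labels = regions.labels
    if priority is None:
        priority = labels
    rank = {lab: i for i, lab in enumerate(priority)}
    unknown = [lab for lab in labels if lab not in rank]
    if unknown:
        raise MutpatError(f"labels missing from priority order: {unknown}")

    trees: dict[str, IntervalTree] = {}
    for r in regions.entries:
        trees.setdefault(r.contig, IntervalTree()).addi(r.start, r.end, r.label)

    out: dict[str, list[Variant]] = {lab: [] for lab in priority}
    if include_other:
        out["other"] = []
    for v in variants:
        hits = {iv.data for iv in trees.get(v.contig, IntervalTree()).at(v.pos)}
        if hits:
            out[min(hits, key=lambda lab: rank[lab])].append(v)
        elif include_other:
            out["other"].append(v)
    return out


# ---------------------------------------------------------------------------
# enrichment / depletion
# ---------------------------------------------------------------------------


def poisson_two_sided(observed: int, expected: float) -> float:
    """Two-sided exact Poisson p-value (sum of outcomes no more likely).

    Sums the Poisson pmf at mean ``expected`` over all counts whose
    probability does not exceed that of ``observed`` (the "minlike"
    two-sided convention, as in exact Poisson tests).
    """
    if expected <= 0:
        raise MutpatError("expected count must be positive")
    k = int(observed)
    pk = stats.poisson.pmf(k, expected)
    hi = int(max(k, expected) + 40 * np.sqrt(expected) + 40)
    ks = np.arange(0, hi + 1)
    pmf = stats.poisson.pmf(ks, expected)
    p = pmf[pmf <= pk * (1 + 1e-10)].sum() + stats.poisson.sf(hi, expected)
    return float(min(p, 1.0))


@dataclass(frozen=True)
class EnrichmentResult:
    region: str
    sample: str
    observed: int
    expected: float
    ratio: float
    p: float
    fdr: float
    stars: str


def _stars(fdr: float) -> str:
    for i, cut in enumerate((0.001, 0.01, 0.05)):
        if fdr < cut:
            return "*" * (3 - i)
    return ""


def enrichment_depletion_test(
    observed: pd.DataFrame,
    surveyed_bp: Mapping[str, int],
    total_bp: int,
) -> pd.DataFrame:
    """Poisson enrichment/depletion of mutation load per region per sample.

    ``observed`` is a regions x samples count table; the expectation for a
    region is the sample's total mutation count scaled by the region's share
    of the surveyed territory.  P-values are two-sided exact Poisson;
    Benjamini-Hochberg FDR is computed across all region x sample tests and
    rendered as asterisks at fdr < 0.05 / 0.01 / 0.001.
    """
    if total_bp <= 0:
        raise MutpatError("total surveyed territory must be positive")
    rows = []
    for sample in observed.columns:
        total_muts = int(observed[sample].sum())
        if total_muts == 0:
            logger.warning("sample %s has zero mutations; tests skipped", sample)
            continue
        for region in observed.index:
            bp = surveyed_bp[region]
            if bp <= 0:
                raise MutpatError(f"surveyed_bp for {region!r} must be positive")
            expected = total_muts * bp / total_bp
            obs = int(observed.loc[region, sample])
            rows.append(
                {
                    "region": region,
                    "sample": sample,
                    "observed": obs,
                    "expected": expected,
                    "ratio": obs / expected,
                    "p": poisson_two_sided(obs, expected),
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
        out["stars"] = out["fdr"].map(_stars)
    return out


# ---------------------------------------------------------------------------
# mutation-density binning
# ---------------------------------------------------------------------------


def bin_mutation_density(
    variants: Sequence[Variant],
    genome: Genome,
    n_bins: int,
    tile_bp: int = 1_000_000,
) -> RegionSet:
    """Partition the genome into ``n_bins`` mutation-density strata.

    Local density is estimated on fixed tiles (default 1 Mb), tiles are
    assigned to quantile strata of the per-tile density, and each stratum is
    returned as a labeled RegionSet (``density_1`` = sparsest).  Together
    the strata cover the genome exactly once.
    """
    if n_bins < 2:
        raise MutpatError("n_bins must be >= 2")
    if len(variants) < n_bins:
        raise MutpatError(f"fewer mutations ({len(variants)}) than bins ({n_bins})")
    tiles: list[tuple[str, int, int]] = []
    for contig, length in genome.lengths.items():
        for start in range(0, length, tile_bp):
            tiles.append((contig, start, min(start + tile_bp, length)))
    counts = np.zeros(len(tiles))
    index = {}
    for i, (contig, start, _end) in enumerate(tiles):
        index.setdefault(contig, []).append((start, i))
    for v in variants:
        for start, i in index.get(v.contig, ()):
            if start <= v.pos < start + tile_bp:
                counts[i] += 1
                break
    density = counts / np.array([e - s for _, s, e in tiles])
    # quantile strata; identical densities share a stratum deterministically
    edges = np.quantile(density, np.linspace(0, 1, n_bins + 1)[1:-1])
    strata = np.searchsorted(edges, density, side="right")
    entries = [
        Region(contig, start, end, f"density_{strata[i] + 1}")
        for i, (contig, start, end) in enumerate(tiles)
    ]
    return RegionSet(entries)


# ---------------------------------------------------------------------------
# unsupervised regional similarity
# ---------------------------------------------------------------------------


@dataclass
class GenomicWindow:
    contig: str
    start: int
    end: int
    n_mutations: int
    window_profile: np.ndarray
    cosine_to_rest: float
    corrected: bool = False


@dataclass
class RegionalSimilarity:
    windows: list[GenomicWindow]
    settings: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": [w.contig for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
                "n_mutations": [w.n_mutations for w in self.windows],
                "cosine_to_rest": [w.cosine_to_rest for w in self.windows],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _trinuc_index() -> dict[str, int]:
    from itertools import product

    tris = sorted(
        {min(t, revcomp(t)) for t in ("".join(p) for p in product("ACGT", repeat=3))
         if t[1] in "CT" or revcomp(t)[1] in "CT"}
    )
    return {t: i for i, t in enumerate(tris)}


_TRI_INDEX = _trinuc_index()  # 32 pyrimidine-centred trinucleotides


def _count_trinucs(seq: str) -> np.ndarray:
    counts = np.zeros(len(_TRI_INDEX))
    for i in range(len(seq) - 2):
        t = seq[i : i + 3]
        if "N" in t:
            continue
        t = min(t, revcomp(t))
        idx = _TRI_INDEX.get(t)
        if idx is not None:
            counts[idx] += 1
    return counts


def _genome_trinucs(genome: Genome) -> np.ndarray:
    total = np.zeros(len(_TRI_INDEX))
    for contig, length in genome.lengths.items():
        total += _count_trinucs(genome.fetch(contig, 0, length))
    return total


def _oligo_corrected(profile: np.ndarray, trinucs: np.ndarray, channel_tri: np.ndarray) -> np.ndarray:
    freq = trinucs / max(trinucs.sum(), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = profile / freq[channel_tri]
    corrected[~np.isfinite(corrected)] = 0.0
    s = corrected.sum()
    return corrected / s if s > 0 else corrected


def determine_regional_similarity(
    variants: Sequence[Variant],
    genome: Genome,
    window_size: int = 100,
    stepsize: int = 25,
    oligo_correction: bool = False,
    max_window_size_gen: int = 10_000_000,
) -> RegionalSimilarity:
    """Sliding-window scan for regions whose profile differs from the genome.

    Windows of ``window_size`` consecutive SBSs per contig, advanced by
    ``stepsize`` mutations, are compared (cosine over SBS-96) against the
    profile of all *remaining* mutations.  Windows whose genomic span
    exceeds ``max_window_size_gen`` are dropped.  With ``oligo_correction``
    both profiles are first divided channel-wise by the trinucleotide
    frequencies of their own territory and renormalized, which removes
    similarity dips that merely reflect unusual local base composition.
    The scan is designed for large catalogs (on the order of 100,000
    substitutions genome-wide).
    """
    snvs = [v for v in variants if v.mut_type == "SBS"]
    if window_size > len(snvs):
        raise MutpatError("window_size exceeds the total number of mutations")
    channels = sbs_channels(1)
    chan_idx = {c: i for i, c in enumerate(channels)}
    channel_tri = np.array(
        [
            _TRI_INDEX[min(t, revcomp(t))]
            for t in (c[0] + c[2] + c[6] for c in channels)
        ]
    )

    per_contig: dict[str, list[tuple[int, int]]] = {}
    global_profile = np.zeros(len(channels))
    n_ambiguous = 0
    for v in snvs:
        try:
            ch = str(sbs_context(v, genome, 1))
        except AmbiguousContextError:
            n_ambiguous += 1
            continue
        idx = chan_idx[ch]
        global_profile[idx] += 1
        per_contig.setdefault(v.contig, []).append((v.pos, idx))
    if n_ambiguous:
        logger.warning("regional similarity excluded %d N-context mutations", n_ambiguous)

    genome_tri = _genome_trinucs(genome) if oligo_correction else None

    windows: list[GenomicWindow] = []
    for contig, muts in per_contig.items():
        muts.sort()
        if len(muts) < window_size:
            logger.warning(
                "contig %s has %d < window_size mutations; skipped", contig, len(muts)
            )
            continue
        positions = np.array([p for p, _ in muts])
        idxs = np.array([i for _, i in muts])
        for start in range(0, len(muts) - window_size + 1, stepsize):
            sel = idxs[start : start + window_size]
            lo = int(positions[start])
            hi = int(positions[start + window_size - 1]) + 1
            if hi - lo > max_window_size_gen:
                continue
            wprof = np.bincount(sel, minlength=len(channels)).astype(float)
            rest = global_profile - wprof
            if rest.sum() == 0:
                continue
            if oligo_correction:
                wtri = _count_trinucs(genome.fetch(contig, max(lo - 1, 0), min(hi + 1, genome.length(contig))))
                wp = _oligo_corrected(wprof, wtri, channel_tri)
                rp = _oligo_corrected(rest, genome_tri - wtri, channel_tri)
            else:
                wp, rp = wprof, rest
            cos = cosine_similarity(wp, rp)
            windows.append(
                GenomicWindow(contig, lo, hi, window_size, wprof, cos, oligo_correction)
            )
    settings = {
        "window_size": window_size,
        "stepsize": stepsize,
        "oligo_correction": oligo_correction,
        "max_window_size_gen": max_window_size_gen,
        "n_mutations": int(global_profile.sum()),
    }
    return RegionalSimilarity(windows, settings)


def plot_regional_similarity(
    result: RegionalSimilarity, out_png=None, out_tsv=None
) -> pd.DataFrame:
    """Cosine-to-rest along the genome; returns the plotted window table."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    table = result.to_frame()
    fig, ax = plt.subplots(figsize=(8, 3))
    offset = 0
    for contig, sub in table.groupby("contig", sort=False):
        mid = (sub["start"] + sub["end"]) / 2 + offset
        ax.scatter(mid, sub["cosine_to_rest"], s=8, label=str(contig))
        offset += sub["end"].max() if len(sub) else 0
    ax.set_ylabel("cosine similarity to rest of genome")
    ax.set_xlabel("genomic position (concatenated contigs)")
    ax.legend(fontsize=6)
    fig.tight_layout()
    if out_tsv is not None:
        table.to_csv(out_tsv, sep="\t", index=False)
    if out_png is not None:
        fig.savefig(out_png, dpi=120)
    plt.close(fig)
    return table
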