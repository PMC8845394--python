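"""Spectrum summaries, cosine similarities and the Monte-Carlo spectrum test.

The mutation *spectrum* collapses a count matrix to its substitution classes
(six for SBS data).  Spectra of sample groups are summarized as the mean
relative contribution per class with a dispersion measure (standard
deviation, 95% CI as mean +/- 1.96*SEM, or SEM).  Profiles and spectra are
compared with the cosine similarity, which is scale invariant and therefore
comparable between samples with different mutation loads.  Regional spectra
are compared with a chi-squared test whose null distribution is obtained by
Monte-Carlo simulation of contingency tables with fixed margins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._errors import ChannelMismatchError, MutpatError
from .context_engine import SBS_CLASSES, MutationCountMatrix
from .io_formats import SignatureMatrix
from .variant_typing import Variant

logger = logging.getLogger("mutpat")


# ---------------------------------------------------------------------------
# cosine similarity
# ---------------------------------------------------------------------------


def cosine_similarity(a, b) -> float:
    """Cosine similarity a.b / (|a||b|) of two non-negative profiles, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise MutpatError(f"vectors must be 1-D and equal length ({a.shape} vs {b.shape})")
    if (a < 0).any() or (b < 0).any():
        raise MutpatError("cosine similarity is defined here for non-negative profiles")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise MutpatError("cosine similarity of a zero vector is undefined")
    return float(np.dot(a, b) / (na * nb))


def _as_frame(x) -> pd.DataFrame:
    if isinstance(x, MutationCountMatrix):
        return x.counts
    if isinstance(x, SignatureMatrix):
        return x.values
    if isinstance(x, pd.DataFrame):
        return x
    raise MutpatError(f"cannot interpret {type(x).__name__} as a profile matrix")


def cos_sim_matrix(A, B) -> pd.DataFrame:
    """Pairwise cosine similarities between the columns of A and of B."""
    dfa, dfb = _as_frame(A), _as_frame(B)
    if list(dfa.index) != list(dfb.index):
        raise ChannelMismatchError("channel sets (and order) must be identical")
    va, vb = dfa.to_numpy(float), dfb.to_numpy(float)
    norms_a = np.linalg.norm(va, axis=0)
    norms_b = np.linalg.norm(vb, axis=0)
    if (norms_a == 0).any() or (norms_b == 0).any():
        raise MutpatError("zero column encountered")
    sim = (va.T @ vb) / np.outer(norms_a, norms_b)
    return pd.DataFrame(sim, index=dfa.columns, columns=dfb.columns)


# ---------------------------------------------------------------------------
# spectrum summaries
# ---------------------------------------------------------------------------


def _classes_of(m: MutationCountMatrix) -> pd.Series:
    """Map each channel to its spectrum class (six classes for SBS data)."""
    if m.dialect.startswith("sbs"):
        classes = []
        for ch in m.channels:
            i = ch.index("[")
            classes.append(ch[i + 1 : i + 4])
        return pd.Series(classes, index=m.channels)
    return pd.Series(m.channels, index=m.channels)


@dataclass
class SpectrumSummary:
    """Mean relative spectrum over samples with a per-class dispersion."""

    mean: pd.Series
    dispersion: pd.Series
    dispersion_mode: str
    n_mutations: pd.Series
    per_sample: pd.DataFrame  # classes x samples relative spectra
    single_sample: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_relative_contribution": self.mean,
                self.dispersion_mode: self.dispersion,
            }
        )


def spectrum_summary(
    m: MutationCountMatrix, dispersion_mode: str = "ci95"
) -> SpectrumSummary:
    """Per-class mean relative contribution and dispersion across samples.

    Relative spectra are computed per sample first, then averaged, so every
    sample carries equal weight regardless of its mutation load.  All-zero
    samples are excluded with a warning; a single-sample summary is flagged
    and gets zero-width dispersion.
    """
    if dispersion_mode not in ("stdev", "ci95", "sem"):
        raise MutpatError(f"unknown dispersion mode {dispersion_mode!r}")
    if not m.samples:
        raise MutpatError("need at least one sample")
    totals = m.totals()
    zero = [s for s in m.samples if totals[s] == 0]
    if zero:
        logger.warning("excluding all-zero sample(s) from spectrum: %s", zero)
    keep = [s for s in m.samples if totals[s] > 0]
    if not keep:
        raise MutpatError("all samples are empty")
    grouped = m.counts[keep].groupby(_classes_of(m), sort=False).sum()
    rel = grouped / grouped.sum(axis=0)
    mean = rel.mean(axis=1)
    n = len(keep)
    sd = rel.std(axis=1, ddof=1) if n > 1 else pd.Series(0.0, index=rel.index)
    sem = sd / np.sqrt(n)
    dispersion = {"stdev": sd, "ci95": 1.96 * sem, "sem": sem}[dispersion_mode]
    return SpectrumSummary(
        mean=mean,
        dispersion=dispersion,
        dispersion_mode=dispersion_mode,
        n_mutations=totals[keep],
        per_sample=rel,
        single_sample=(n == 1),
    )


# ---------------------------------------------------------------------------
# Monte-Carlo chi-squared comparison of regional spectra
# ---------------------------------------------------------------------------


def _chi2_stat(table: np.ndarray) -> float:
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = (table - expected) ** 2 / expected
    return float(np.nansum(terms))


def _simulate_fixed_margins(
    rng: np.random.Generator, row_sums: np.ndarray, col_sums: np.ndarray
) -> np.ndarray:
    # sequential multivariate hypergeometric draws give the uniform
    # conditional-on-margins null (as in Patefield's algorithm)
    table = np.zeros((len(row_sums), len(col_sums)), dtype=np.int64)
    remaining = col_sums.copy()
    for i, r in enumerate(row_sums[:-1]):
        draw = rng.multivariate_hypergeometric(remaining, int(r))
        table[i] = draw
        remaining = remaining - draw
    table[-1] = remaining
    return table


def compare_region_spectra(
    spectra: pd.DataFrame,
    n_sim: int = 2000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Chi-squared test of independence between regions and mutation classes.

    ``spectra`` is a regions x classes count table.  The p-value is obtained
    by Monte Carlo: tables are simulated under fixed row and column margins
    and ``p = (1 + #{simulated stat >= observed}) / (n_sim + 1)`` (add-one
    correction, so p is never exactly zero).  Zero-margin rows/columns are
    dropped with a warning.
    """
    if n_sim < 999:
        raise MutpatError("n_sim must be >= 999 for a stable Monte-Carlo p")
    table = spectra.to_numpy(np.int64)
    rows = table.sum(axis=1) > 0
    cols = table.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        logger.warning("dropping zero-margin rows/columns from spectrum table")
        table = table[rows][:, cols]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise MutpatError("need >= 2 regions and >= 2 classes with counts")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = _chi2_stat(table)
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    hits = 0
    for _ in range(n_sim):
        sim = _simulate_fixed_margins(rng, row_sums, col_sums)
        if _chi2_stat(sim) >= observed - 1e-12:
            hits += 1
    p = (1 + hits) / (n_sim + 1)
    return observed, p


def compare_region_spectra_samples(
    tables: Mapping[str, pd.DataFrame],
    n_sim: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Vectorized spectrum comparison with BH false-discovery-rate control."""
    rng = np.random.default_rng(seed)
    rows = []
    for sample, table in tables.items():
        stat, p = compare_region_spectra(table, n_sim=n_sim, rng=rng)
        rows.append({"sample": sample, "chi2": stat, "p": p})
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------


def downsample_variants(
    variants: Sequence[Variant],
    fraction: float | None = None,
    n: int | None = None,
    seed: int | None = None,
) -> list[Variant]:
    """Uniform random subsample without replacement (seeded, order preserving)."""
    if (fraction is None) == (n is None):
        raise MutpatError("give exactly one of fraction or n")
    total = len(variants)
    if fraction is not None:
        if not 0 < fraction <= 1:
            raise MutpatError("fraction must be in (0, 1]")
        if fraction == 1:
            return list(variants)
        n = int(round(fraction * total))
    if n > total:
        raise MutpatError(f"cannot draw {n} from {total} variants")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(total, size=n, replace=False))
    return [variants[i] for i in idx]


# ---------------------------------------------------------------------------
# figure writers (tidy table + image; the table is the test surface)
# ---------------------------------------------------------------------------


def _finish_figure(fig, out_png, out_tsv, table: pd.DataFrame) -> pd.DataFrame:
    if out_tsv is not None:
        table.to_csv(out_tsv, sep="\t", index=False)
    if out_png is not None:
        fig.savefig(out_png, dpi=120)
    import matplotlib.pyplot as plt

    plt.close(fig)
    return table


def plot_spectrum(
    summary: SpectrumSummary, out_png=None, out_tsv=None
) -> pd.DataFrame:
    """Bar plot of a spectrum summary with error bars; returns the plotted table."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    table = summary.to_frame().reset_index(names="mutation_class")
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(
        table["mutation_class"],
        table["mean_relative_contribution"],
        yerr=table[summary.dispersion_mode],
        capsize=3,
    )
    ax.set_ylabel("relative contribution")
    fig.tight_layout()
    return _finish_figure(fig, out_png, out_tsv, table)


def plot_96_profile(m: MutationCountMatrix, out_png=None, out_tsv=None) -> pd.DataFrame:
    """Per-sample relative 96-channel profiles as bar panels."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    rel = m.relative()
    table = rel.rename_axis("channel").reset_index().melt(
        id_vars="channel", var_name="sample", value_name="relative_contribution"
    )
    n = len(m.samples)
    fig, axes = plt.subplots(n, 1, figsize=(10, 1.8 * n), squeeze=False)
    for ax, sample in zip(axes.ravel(), m.samples):
        ax.bar(range(len(m.channels)), rel[sample].to_numpy())
        ax.set_ylabel(sample, fontsize=7)
        ax.set_xticks([])
    fig.tight_layout()
    return _finish_figure(fig, out_png, out_tsv, table)


def plot_profile_heatmap(
    m: MutationCountMatrix, out_png=None, out_tsv=None
) -> pd.DataFrame:
    """Heatmap of an extended-context profile: 5' flank rows, (class, 3') columns.

    Counts are pooled over samples and shown as relative contributions, the
    standard display for ext >= 2 matrices where per-channel bars become
    unreadable.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pooled = m.counts.sum(axis=1)
    rel = pooled / max(pooled.sum(), 1)
    recs = []
    for ch, val in rel.items():
        i = ch.index("[")
        recs.append(
            {
                "up": ch[:i],
                "class_down": ch[i + 1 : i + 4] + ":" + ch[i + 5 :],
                "relative_contribution": val,
            }
        )
    table = pd.DataFrame(recs)
    pivot = table.pivot(index="up", columns="class_down", values="relative_contribution")
    fig, ax = plt.subplots(figsize=(10, 6))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(pivot.index)), pivot.index, fontsize=6)
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, fontsize=5, rotation=90)
    fig.colorbar(im, ax=ax, label="relative contribution")
    fig.tight_layout()
    return _finish_figure(fig, out_png, out_tsv, table)


def plot_river(m: MutationCountMatrix, out_png=None, out_tsv=None) -> pd.DataFrame:
    """River-style overview: base usage per flank position, weighted by counts."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pooled = m.counts.sum(axis=1)
    ext = (len(m.channels[0]) - 7) // 2
    positions = list(range(-ext, 0)) + list(range(1, ext + 1))
    recs = []
    for pos_idx, pos in enumerate(positions):
        for base in "ACGT":
            w = 0.0
            for ch, cnt in pooled.items():
                i = ch.index("[")
                flanks = ch[:i] + ch[i + 6 :]
                if flanks[pos_idx] == base:
                    w += cnt
            recs.append({"position": pos, "base": base, "count": w})
    table = pd.DataFrame(recs)
    total = max(pooled.sum(), 1)
    table["fraction"] = table["count"] / total
    pivot = table.pivot(index="position", columns="base", values="fraction")
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.stackplot(pivot.index, pivot.T.to_numpy(), labels=list(pivot.columns))
    ax.set_xlabel("flank position relative to mutated base")
    ax.set_ylabel("base fraction")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return _finish_figure(fig, out_png, out_tsv, table)
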