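"""Signature refitting, bootstrapping, merging and de novo NMF extraction.

Refitting estimates non-negative per-sample contributions of known
signatures that best reconstruct an observed count profile
(``min_{c>=0} ||m - S c||_2``, solved exactly by non-negative least
squares).  Plain NNLS overfits: it spreads small spurious contributions
over many signatures.  Strict refitting combats this by backwards
elimination — iteratively removing the lowest-contributing signature and
refitting until the reconstruction cosine drops by more than ``max_delta``
in one step — or by best-subset search over all signature combinations of
each size.  Bootstrapped refitting resamples each sample's mutations
(multinomially from its observed profile) to quantify the stability of the
estimated contributions; correlations of contributions across bootstrap
iterations expose signature pairs the refit cannot distinguish.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from ._errors import ChannelMismatchError, MutpatError
from .context_engine import MutationCountMatrix
from .io_formats import SignatureMatrix
from .spectra import cosine_similarity

logger = logging.getLogger("mutpat")


def _check_channels(m: MutationCountMatrix, S: SignatureMatrix) -> None:
    if list(m.channels) != list(S.channels):
        raise ChannelMismatchError(
            "count matrix and signature matrix must share an identical, "
            "identically ordered channel set"
        )


def _nnls_fit(y: np.ndarray, S: np.ndarray) -> np.ndarray:
    coef, _ = nnls(S, y)
    return coef


@dataclass
class RefitResult:
    """Signature contributions (mutation counts) with reconstruction quality."""

    contribution: pd.DataFrame  # signatures x samples
    reconstructed: pd.DataFrame  # channels x samples
    cosine: pd.Series  # per sample cosine(original, reconstructed); NaN if undefined
    method: str
    params: dict = field(default_factory=dict)
    original: pd.DataFrame | None = None
    signature_values: pd.DataFrame | None = None


def _assemble(
    m: MutationCountMatrix,
    S: SignatureMatrix,
    contribs: dict[str, np.ndarray],
    method: str,
    params: dict,
) -> RefitResult:
    contribution = pd.DataFrame(contribs, index=S.signatures)
    recon = S.values.to_numpy() @ contribution.to_numpy()
    reconstructed = pd.DataFrame(recon, index=S.channels, columns=contribution.columns)
    cosines = {}
    for sample in contribution.columns:
        orig = m.counts[sample].to_numpy(float)
        rec = reconstructed[sample].to_numpy()
        if orig.sum() == 0 or rec.sum() == 0:
            cosines[sample] = np.nan
        else:
            cosines[sample] = cosine_similarity(orig, rec)
    return RefitResult(
        contribution,
        reconstructed,
        pd.Series(cosines),
        method,
        params,
        original=m.counts.copy(),
        signature_values=S.values.copy(),
    )


def fit_to_signatures(m: MutationCountMatrix, S: SignatureMatrix) -> RefitResult:
    """Plain NNLS refit of every sample against the full signature set."""
    _check_channels(m, S)
    Sv = S.values.to_numpy()
    contribs = {
        sample: _nnls_fit(m.counts[sample].to_numpy(float), Sv) for sample in m.samples
    }
    return _assemble(m, S, contribs, "regular", {})


def filter_low_contribution(r: RefitResult, min_mutations: float = 10) -> RefitResult:
    """Drop signatures contributing fewer than ``min_mutations`` and refit.

    The "regular_10+" heuristic: per sample, signatures under the threshold
    are removed and the remaining set is refit by NNLS.  Idempotent when all
    contributions already clear the threshold; a threshold of zero is the
    identity.
    """
    if r.original is None or r.signature_values is None:
        raise MutpatError("RefitResult lacks its original inputs")
    Sv = r.signature_values.to_numpy()
    sigs = list(r.signature_values.columns)
    contribs = {}
    for sample in r.contribution.columns:
        c = r.contribution[sample].to_numpy().copy()
        keep = c >= min_mutations if min_mutations > 0 else np.ones_like(c, bool)
        if min_mutations > 0 and keep.any():
            y = r.original[sample].to_numpy(float)
            refit = np.zeros_like(c)
            refit[keep] = _nnls_fit(y, Sv[:, keep])
            c = refit
        elif min_mutations > 0:
            c = np.zeros_like(c)
            logger.warning("all signatures dropped for sample %s", sample)
        contribs[sample] = c
    m = MutationCountMatrix(r.original.copy(), "refit_input")
    S = SignatureMatrix(r.signature_values.copy())
    out = _assemble(m, S, contribs, f"{r.method}_10+", {"min_mutations": min_mutations})
    return out


# ---------------------------------------------------------------------------
# strict refitting
# ---------------------------------------------------------------------------


def backwards_elimination_path(
    y: np.ndarray, S: pd.DataFrame
) -> list[tuple[list[str], np.ndarray, float]]:
    """Full backwards-elimination path of one sample.

    Starting from the NNLS fit on all signatures, repeatedly remove the
    signature with the lowest contribution (ties: lexicographically first;
    exact zeros are dropped one at a time like any lowest contribution) and
    refit.  Returns ``[(signature_names, contributions, cosine), ...]`` from
    the full set down to a single signature.  The path does not depend on
    any stopping threshold, so one path serves every ``max_delta``.
    """
    sigs = list(S.columns)
    Sv = S.to_numpy()
    path = []
    active = list(range(len(sigs)))
    while active:
        coef = _nnls_fit(y, Sv[:, active])
        recon = Sv[:, active] @ coef
        cos = cosine_similarity(y, recon) if y.sum() > 0 and recon.sum() > 0 else np.nan
        path.append(([sigs[i] for i in active], coef, cos))
        if len(active) == 1:
            break
        order = sorted(range(len(active)), key=lambda j: (coef[j], sigs[active[j]]))
        del active[order[0]]
    return path


def select_from_path(
    path: Sequence[tuple[list[str], np.ndarray, float]], max_delta: float
) -> tuple[list[str], np.ndarray, float]:
    """Apply the strict stop rule to an elimination path.

    Walk the path; when one elimination step lowers the cosine by more than
    ``max_delta``, stop and return the fit *before* that drop (the better
    reconstructing set)."""
    chosen = path[0]
    for nxt in path[1:]:
        if chosen[2] - nxt[2] > max_delta:
            break
        chosen = nxt
    return chosen


def fit_strict(
    m: MutationCountMatrix,
    S: SignatureMatrix,
    max_delta: float = 0.004,
    method: str = "backwards",
    force: bool = False,
) -> RefitResult:
    """Strict signature refit by backwards elimination or best-subset search.

    ``max_delta`` is the largest tolerated single-step drop in
    reconstruction cosine; larger values select fewer signatures.  A value
    of 0.015 is a practical working setting for trinucleotide catalogs.
    Best-subset search evaluates every combination of each size and is
    refused above 15 signatures unless ``force`` is set (combinatorial
    cost).  Samples are fit independently.
    """
    if not 0 < max_delta < 1:
        raise MutpatError("max_delta must be in (0, 1)")
    if method not in ("backwards", "best_subset"):
        raise MutpatError(f"unknown strict method {method!r}")
    _check_channels(m, S)
    if method == "best_subset" and len(S.signatures) > 15 and not force:
        raise MutpatError(
            "best-subset refitting against more than 15 signatures is "
            "combinatorially slow; pass force=True to override"
        )
    sigs = list(S.signatures)
    contribs = {}
    for sample in m.samples:
        y = m.counts[sample].to_numpy(float)
        if method == "backwards":
            path = backwards_elimination_path(y, S.values)
            names, coef, _cos = select_from_path(path, max_delta)
        else:
            names, coef = _best_subset_sample(y, S.values, max_delta)
        full = np.zeros(len(sigs))
        for name, c in zip(names, coef):
            full[sigs.index(name)] = c
        contribs[sample] = full
    return _assemble(
        m, S, contribs, f"strict_{method}", {"max_delta": max_delta}
    )


def _best_subset_sample(
    y: np.ndarray, S: pd.DataFrame, max_delta: float
) -> tuple[list[str], np.ndarray]:
    sigs = list(S.columns)
    Sv = S.to_numpy()
    prev_names, prev_coef = sigs, _nnls_fit(y, Sv)
    prev_cos = cosine_similarity(y, Sv @ prev_coef)
    for size in range(len(sigs) - 1, 0, -1):
        best = None
        for subset in combinations(range(len(sigs)), size):
            coef = _nnls_fit(y, Sv[:, subset])
            recon = Sv[:, subset] @ coef
            cos = cosine_similarity(y, recon) if recon.sum() > 0 else -1.0
            if best is None or cos > best[2]:
                best = (subset, coef, cos)
        if prev_cos - best[2] > max_delta:
            break
        prev_names = [sigs[i] for i in best[0]]
        prev_coef = best[1]
        prev_cos = best[2]
    return prev_names, prev_coef


# ---------------------------------------------------------------------------
# bootstrapped refitting
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Per-iteration contributions with stability summaries.

    ``presence_fraction`` is the fraction of bootstrap iterations in which a
    signature contributed (> 0) to a sample; ``mean_nonzero_contribution``
    the mean number of contributing mutations across the iterations in which
    the contribution was not zero.
    """

    iterations: np.ndarray  # n_boot x signatures x samples
    signatures: list[str]
    samples: list[str]
    settings: dict

    @property
    def presence_fraction(self) -> pd.DataFrame:
        frac = (self.iterations > 0).mean(axis=0)
        return pd.DataFrame(frac, index=self.signatures, columns=self.samples)

    @property
    def mean_nonzero_contribution(self) -> pd.DataFrame:
        present = self.iterations > 0
        with np.errstate(invalid="ignore"):
            mean = np.where(
                present.any(axis=0),
                self.iterations.sum(axis=0) / np.maximum(present.sum(axis=0), 1),
                0.0,
            )
        return pd.DataFrame(mean, index=self.signatures, columns=self.samples)


def fit_bootstrapped(
    m: MutationCountMatrix,
    S: SignatureMatrix,
    n_boot: int = 1000,
    method: str = "regular",
    max_delta: float = 0.004,
    seed: int | None = None,
) -> BootstrapResult:
    """Bootstrap the refit: resample each sample's mutations and refit.

    Each iteration redraws a sample's mutations multinomially from its
    observed channel profile (equivalent to resampling the mutation list
    with replacement) and refits with the regular or strict method.  Empty
    samples are skipped.
    """
    if n_boot < 2:
        raise MutpatError("n_boot must be >= 2")
    if method not in ("regular", "strict"):
        raise MutpatError(f"unknown bootstrap method {method!r}")
    _check_channels(m, S)
    rng = np.random.default_rng(seed)
    samples = [s for s in m.samples if m.counts[s].sum() > 0]
    skipped = [s for s in m.samples if s not in samples]
    if skipped:
        logger.warning("fit_bootstrapped skipped empty sample(s): %s", skipped)
    sigs = list(S.signatures)
    Sv = S.values.to_numpy()
    out = np.zeros((n_boot, len(sigs), len(samples)))
    for j, sample in enumerate(samples):
        counts = m.counts[sample].to_numpy()
        n_s = int(counts.sum())
        prob = counts / n_s
        for it in range(n_boot):
            y = rng.multinomial(n_s, prob).astype(float)
            if method == "regular":
                out[it, :, j] = _nnls_fit(y, Sv)
            else:
                path = backwards_elimination_path(y, S.values)
                names, coef, _ = select_from_path(path, max_delta)
                for name, c in zip(names, coef):
                    out[it, sigs.index(name), j] = c
    settings = {"n_boot": n_boot, "seed": seed, "method": method, "max_delta": max_delta}
    return BootstrapResult(out, sigs, samples, settings)


def bootstrap_correlation(b: BootstrapResult, sample: str) -> pd.DataFrame:
    """Pearson correlation of signature contributions across iterations.

    Negative correlations mark signature pairs the refit struggles to
    distinguish.  Signatures with zero variance over iterations are
    excluded; at least three iterations are required.
    """
    if b.iterations.shape[0] < 3:
        raise MutpatError("need at least 3 bootstrap iterations")
    j = b.samples.index(sample)
    data = b.iterations[:, :, j]
    keep = data.std(axis=0) > 0
    names = [s for s, k in zip(b.signatures, keep) if k]
    if not names:
        raise MutpatError("no signature has variance across iterations")
    corr = np.corrcoef(data[:, keep], rowvar=False)
    corr = np.atleast_2d(corr)
    return pd.DataFrame(corr, index=names, columns=names)


# ---------------------------------------------------------------------------
# merging / renaming / NMF extraction
# ---------------------------------------------------------------------------


def merge_signatures(S: SignatureMatrix, cos_cutoff: float = 0.8) -> SignatureMatrix:
    """Agglomeratively merge highly similar signatures.

    While any column pair has cosine >= ``cos_cutoff``, the most similar
    pair is replaced by its renormalized mean and the names concatenated
    with ';'; similarities are recomputed after each merge.  Terminates
    because each merge removes one column.
    """
    if not 0 < cos_cutoff < 1:
        raise MutpatError("cos_cutoff must be in (0, 1)")
    df = S.values.copy()
    while df.shape[1] > 1:
        cols = list(df.columns)
        best = None
        for a, b_ in combinations(cols, 2):
            cos = cosine_similarity(df[a], df[b_])
            if best is None or cos > best[2]:
                best = (a, b_, cos)
        if best[2] < cos_cutoff:
            break
        a, b_, _ = best
        merged = (df[a] + df[b_]) / 2
        df = df.drop(columns=[a, b_])
        df[f"{a};{b_}"] = merged / merged.sum()
    return SignatureMatrix(df)


@dataclass
class NmfResult:
    """De novo NMF factorization of a count matrix."""

    signatures: pd.DataFrame  # channels x rank, columns sum to 1
    contributions: pd.DataFrame  # rank x samples
    reconstruction_error: float
    rank: int
    n_runs: int
    seed: int | None


def extract_signatures(
    m: MutationCountMatrix,
    rank: int,
    n_runs: int = 10,
    seed: int | None = None,
) -> NmfResult:
    """Extract ``rank`` novel signatures by NMF with random restarts.

    Multiplicative-update NMF under Frobenius loss is run ``n_runs`` times
    from random initializations and the best (lowest reconstruction error)
    run kept.  Factor columns are normalized to probability vectors with the
    contributions rescaled accordingly.
    """
    from sklearn.decomposition import NMF

    if rank <= 0:
        raise MutpatError("rank must be positive")
    if rank >= min(len(m.channels), len(m.samples)):
        raise MutpatError("rank must be smaller than both matrix dimensions")
    if n_runs < 1:
        raise MutpatError("n_runs must be >= 1")
    X = m.counts.to_numpy(float)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_runs):
        model = NMF(
            n_components=rank,
            init="random",
            solver="mu",
            beta_loss="frobenius",
            max_iter=2000,
            tol=1e-8,
            random_state=int(rng.integers(2**31 - 1)),
        )
        W = model.fit_transform(X)
        H = model.components_
        err = float(np.linalg.norm(X - W @ H))
        if best is None or err < best[0]:
            best = (err, W, H)
    err, W, H = best
    scale = W.sum(axis=0)
    scale[scale == 0] = 1.0
    W = W / scale
    H = H * scale[:, None]
    names = [string.ascii_uppercase[i % 26] * (i // 26 + 1) for i in range(rank)]
    signatures = pd.DataFrame(W, index=m.channels, columns=names)
    contributions = pd.DataFrame(H, index=names, columns=m.samples)
    return NmfResult(signatures, contributions, err, rank, n_runs, seed)


def rank_survey(
    m: MutationCountMatrix,
    ranks: Sequence[int],
    n_runs: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Reconstruction error across candidate ranks (an elbow survey).

    Offered as the rank-selection aid: the error is non-increasing in rank
    on the same data, and the elbow marks the point of diminishing returns.
    """
    rows = []
    for rank in ranks:
        res = extract_signatures(m, rank, n_runs=n_runs, seed=seed)
        rows.append({"rank": rank, "reconstruction_error": res.reconstruction_error})
    return pd.DataFrame(rows)


def rename_extracted(
    N: NmfResult, reference: SignatureMatrix, cos_cutoff: float = 0.85
) -> NmfResult:
    """Rename extracted signatures after their closest known counterpart.

    An extracted signature whose best cosine against the reference catalog
    reaches ``cos_cutoff`` is renamed ``<reference>-like``; others keep
    their letter name.
    """
    if list(N.signatures.index) != list(reference.channels):
        raise ChannelMismatchError("extracted and reference channel sets differ")
    new_names = []
    for col in N.signatures.columns:
        sims = {
            ref: cosine_similarity(N.signatures[col], reference[ref])
            for ref in reference.signatures
        }
        ref_best = max(sims, key=sims.get)
        name = f"{ref_best}-like" if sims[ref_best] >= cos_cutoff else col
        while name in new_names:
            name += "'"
        new_names.append(name)
    signatures = N.signatures.copy()
    signatures.columns = new_names
    contributions = N.contributions.copy()
    contributions.index = new_names
    return NmfResult(
        signatures, contributions, N.reconstruction_error, N.rank, N.n_runs, N.seed
    )


# ---------------------------------------------------------------------------
# figure writers
# ---------------------------------------------------------------------------


def plot_bootstrapped_contribution(
    b: BootstrapResult, out_png=None, out_tsv=None
) -> pd.DataFrame:
    """Dot plot: presence fraction (color) and mean non-zero contribution (size)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pres = b.presence_fraction
    mean = b.mean_nonzero_contribution
    table = (
        pres.reset_index(names="signature")
        .melt(id_vars="signature", var_name="sample", value_name="presence_fraction")
        .merge(
            mean.reset_index(names="signature").melt(
                id_vars="signature",
                var_name="sample",
                value_name="mean_nonzero_contribution",
            ),
            on=["signature", "sample"],
        )
    )
    fig, ax = plt.subplots(figsize=(6, max(3, 0.25 * len(b.signatures))))
    xi = {s: i for i, s in enumerate(b.samples)}
    yi = {s: i for i, s in enumerate(b.signatures)}
    sc = ax.scatter(
        [xi[s] for s in table["sample"]],
        [yi[s] for s in table["signature"]],
        c=table["presence_fraction"],
        s=2 + table["mean_nonzero_contribution"],
        cmap="viridis",
        vmin=0,
        vmax=1,
    )
    ax.set_xticks(range(len(b.samples)), b.samples, rotation=90, fontsize=6)
    ax.set_yticks(range(len(b.signatures)), b.signatures, fontsize=6)
    fig.colorbar(sc, ax=ax, label="presence fraction")
    fig.tight_layout()
    if out_tsv is not None:
        table.to_csv(out_tsv, sep="\t", index=False)
    if out_png is not None:
        fig.savefig(out_png, dpi=120)
    plt.close(fig)
    return table


def plot_correlation_bootstrap(
    b: BootstrapResult, sample: str, out_png=None, out_tsv=None
) -> pd.DataFrame:
    """Heatmap of the bootstrap contribution correlations for one sample."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    corr = bootstrap_correlation(b, sample)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(corr)), corr.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    table = corr.reset_index(names="signature")
    if out_tsv is not None:
        table.to_csv(out_tsv, sep="\t", index=False)
    if out_png is not None:
        fig.savefig(out_png, dpi=120)
    plt.close(fig)
    return table


def plot_original_vs_reconstructed(
    r: RefitResult, out_png=None, out_tsv=None
) -> pd.DataFrame:
    """Bar graph of per-sample cosine between original and reconstructed profile."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    table = r.cosine.rename("cosine").reset_index(names="sample")
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(table["sample"], table["cosine"])
    ax.set_ylabel("cosine(original, reconstructed)")
    ax.set_ylim(0, 1.05)
    plt.setp(ax.get_xticklabels(), rotation=90, fontsize=6)
    fig.tight_layout()
    if out_tsv is not None:
        table.to_csv(out_tsv, sep="\t", index=False)
    if out_png is not None:
        fig.savefig(out_png, dpi=120)
    plt.close(fig)
    return table
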