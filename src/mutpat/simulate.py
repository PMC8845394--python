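"""Synthetic data generation and the refitting evaluation harness.

Three generators back all tests and benchmarks in the package:

* :func:`simulate_mixture_matrix` reproduces the signature-mixture
  simulation design used to benchmark refitting: each synthetic sample
  draws ``k_sigs`` signatures uniformly from a pool and samples
  ``muts_per_sig`` channel assignments multinomially from each, so a sample
  with 4 signatures at 50 mutations each carries 200 mutations.
* :func:`evaluate_refit` scores refitting output against the simulation
  truth: presence/absence precision and recall, the fraction of correctly
  attributed mutations, and the area under the recall-precision curve
  traced by sweeping the method's strictness parameter.
* :func:`generate_toy_genome_and_vcf` writes a random genome (FASTA) and a
  valid VCF of planted variants for round-trip tests of the IO and context
  machinery.

Sequencing errors, coverage and caller behavior are deliberately not
simulated; the generators operate on channels and planted variants only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import MutpatError
from .context_engine import MutationCountMatrix
from .io_formats import Genome, SignatureMatrix
from .signatures import (
    RefitResult,
    backwards_elimination_path,
    fit_to_signatures,
    select_from_path,
)

logger = logging.getLogger("mutpat")


# ---------------------------------------------------------------------------
# signature-mixture simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationTruth:
    """Ground truth of a simulated mixture matrix."""

    true_signatures: dict[str, tuple[str, ...]]  # sample -> signature names
    true_contribution: pd.DataFrame  # signatures x samples (mutation counts)
    muts_per_sig: int

    @property
    def samples(self) -> list[str]:
        return list(self.true_contribution.columns)


def simulate_mixture_matrix(
    S: SignatureMatrix,
    n_samples: int = 300,
    k_sigs: int = 4,
    muts_per_sig: int = 50,
    pool: Sequence[str] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[MutationCountMatrix, SimulationTruth]:
    """Simulate samples as equal-weight mixtures of random signatures.

    Per sample: ``k_sigs`` signatures are drawn uniformly without
    replacement from ``pool`` (default: the first 30 columns of ``S``, the
    commonly observed subset a user would typically refit against), and
    ``muts_per_sig`` mutations are drawn multinomially from each signature's
    channel probabilities.  Every sample therefore has exactly
    ``k_sigs * muts_per_sig`` mutations.
    """
    if muts_per_sig <= 0:
        raise MutpatError("muts_per_sig must be positive")
    if pool is None:
        pool = S.signatures[: min(30, len(S.signatures))]
    pool = list(pool)
    if k_sigs > len(pool):
        raise MutpatError("k_sigs exceeds the pool size")
    if rng is None:
        rng = np.random.default_rng(seed)
    channels = S.channels
    probs = {name: S[name].to_numpy() for name in pool}
    counts = {}
    true_sets = {}
    true_contrib = pd.DataFrame(
        0.0, index=pool, columns=[f"sample_{i + 1}" for i in range(n_samples)]
    )
    for i in range(n_samples):
        sample = f"sample_{i + 1}"
        chosen = tuple(rng.choice(pool, size=k_sigs, replace=False))
        vec = np.zeros(len(channels), dtype=np.int64)
        for name in chosen:
            vec += rng.multinomial(muts_per_sig, probs[name])
            true_contrib.loc[name, sample] += muts_per_sig
        counts[sample] = vec
        true_sets[sample] = chosen
    df = pd.DataFrame(counts, index=channels, dtype=np.int64)
    df.index.name = "channel"
    m = MutationCountMatrix(df, "sbs_ext1")
    return m, SimulationTruth(true_sets, true_contrib, muts_per_sig)


# ---------------------------------------------------------------------------
# evaluation harness
# ---------------------------------------------------------------------------


@dataclass
class RefitMetrics:
    precision: float
    recall: float
    attributed_fraction: float
    n_true_positive: int
    n_false_positive: int
    n_false_negative: int


def evaluate_refit(
    truth: SimulationTruth,
    contribution: pd.DataFrame,
    presence_threshold: float = 0.0,
) -> RefitMetrics:
    """Score one refit against the simulation truth.

    Presence calls are ``contribution > presence_threshold`` (default: any
    nonzero).  Precision and recall are computed over all sample x signature
    decisions; the attributed-mutation fraction credits, per true
    signature, the overlap ``min(attributed, true)`` relative to the total
    simulated mutations.
    """
    if list(contribution.columns) != truth.samples:
        raise MutpatError("samples of contribution and truth differ")
    tp = fp = fn = 0
    attributed = 0.0
    total = float(truth.true_contribution.to_numpy().sum())
    for sample in truth.samples:
        called = {
            sig
            for sig in contribution.index
            if contribution.loc[sig, sample] > presence_threshold
        }
        true = set(truth.true_signatures[sample])
        tp += len(called & true)
        fp += len(called - true)
        fn += len(true - called)
        for sig in true:
            est = (
                float(contribution.loc[sig, sample])
                if sig in contribution.index
                else 0.0
            )
            attributed += min(est, float(truth.true_contribution.loc[sig, sample]))
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return RefitMetrics(precision, recall, attributed / total, tp, fp, fn)


_DEFAULT_DELTA_GRID = tuple(np.geomspace(1e-4, 0.2, 20))


def strict_refit_curve(
    m: MutationCountMatrix,
    S: SignatureMatrix,
    truth: SimulationTruth,
    max_deltas: Sequence[float] = _DEFAULT_DELTA_GRID,
) -> pd.DataFrame:
    """Recall-precision curve of strict backwards refitting over ``max_delta``.

    The backwards-elimination path of each sample is computed once and the
    stop rule applied per ``max_delta``, which is equivalent to running the
    strict refit separately at each value.
    """
    sigs = list(S.signatures)
    paths = {
        sample: backwards_elimination_path(
            m.counts[sample].to_numpy(float), S.values
        )
        for sample in m.samples
    }
    rows = []
    for delta in max_deltas:
        contrib = pd.DataFrame(0.0, index=sigs, columns=m.samples)
        for sample, path in paths.items():
            names, coef, _ = select_from_path(path, delta)
            for name, c in zip(names, coef):
                contrib.loc[name, sample] = c
        metrics = evaluate_refit(truth, contrib)
        rows.append(
            {
                "max_delta": delta,
                "precision": metrics.precision,
                "recall": metrics.recall,
                "attributed_fraction": metrics.attributed_fraction,
            }
        )
    return pd.DataFrame(rows)


def regular_refit_curve(
    m: MutationCountMatrix,
    S: SignatureMatrix,
    truth: SimulationTruth,
    thresholds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Recall-precision curve of plain NNLS swept over the presence threshold."""
    fit = fit_to_signatures(m, S)
    if thresholds is None:
        thresholds = [0.0] + list(np.geomspace(0.5, 200, 25))
    rows = []
    for thr in thresholds:
        metrics = evaluate_refit(truth, fit.contribution, presence_threshold=thr)
        rows.append(
            {
                "presence_threshold": thr,
                "precision": metrics.precision,
                "recall": metrics.recall,
                "attributed_fraction": metrics.attributed_fraction,
            }
        )
    return pd.DataFrame(rows)


def recall_precision_auc(curve: pd.DataFrame) -> float:
    """Trapezoidal area under a recall-precision curve.

    Points are ordered by recall; duplicate recalls keep their best
    precision.  The area is taken over the recall range the sweep covers,
    extended to recall 0 at the precision of the strictest point (the
    conventional completion of a recall-precision curve).
    """
    pts = (
        curve.groupby("recall", as_index=False)["precision"].max().sort_values("recall")
    )
    recalls = pts["recall"].to_numpy()
    precisions = pts["precision"].to_numpy()
    if recalls[0] > 0:
        recalls = np.concatenate(([0.0], recalls))
        precisions = np.concatenate(([precisions[0]], precisions))
    return float(np.trapezoid(precisions, recalls))


def roc_auc(curve: pd.DataFrame, n_signatures: int, n_samples: int, n_true: int) -> float:
    """ROC-AUC companion to the recall-precision AUC (for comparison)."""
    total_neg = n_samples * n_signatures - n_samples * n_true
    fp = (1 - curve["precision"]) / curve["precision"].clip(lower=1e-12)
    # false positives implied by precision at each recall level
    tp = curve["recall"] * n_samples * n_true
    fpr = (fp * tp / total_neg).clip(upper=1.0)
    pts = pd.DataFrame({"fpr": fpr, "tpr": curve["recall"]}).sort_values("fpr")
    fprs = np.concatenate(([0.0], pts["fpr"].to_numpy(), [1.0]))
    tprs = np.concatenate(([0.0], pts["tpr"].to_numpy(), [1.0]))
    return float(np.trapezoid(tprs, fprs))


# ---------------------------------------------------------------------------
# toy genome + VCF plumbing
# ---------------------------------------------------------------------------


@dataclass
class PlantedVariant:
    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    kind: str


DEFAULT_PLAN = {
    "sbs": 10,
    "adjacent_pairs": 3,
    "dbs": 3,
    "mbs": 2,
    "insertion": 3,
    "deletion": 3,
}


def generate_toy_genome_and_vcf(
    outdir,
    seed: int = 0,
    n_contigs: int = 2,
    contig_len: int = 10_000,
    plan: Mapping[str, int] | None = None,
    sample: str = "toy",
):
    """Write a random genome (FASTA) and a VCF of planted variants.

    Variants are placed at non-overlapping sites with >= 2 bp of clearance
    so that only the requested adjacent SBS pairs merge.  Returns
    ``(fasta_path, vcf_path, truth)`` where ``truth`` is a DataFrame of the
    planted events (contig, 0-based position, ref, alt, kind).  The same
    seed reproduces byte-identical files.
    """
    import os

    plan = dict(DEFAULT_PLAN if plan is None else plan)
    rng = np.random.default_rng(seed)
    contigs = {
        f"chr{i + 1}": "".join(rng.choice(list("ACGT"), size=contig_len))
        for i in range(n_contigs)
    }
    genome = Genome(contigs)

    taken: dict[str, set[int]] = {c: set() for c in contigs}

    def claim(contig: str, lo: int, hi: int) -> bool:
        span = set(range(lo - 2, hi + 2))
        if span & taken[contig] or lo < 10 or hi > contig_len - 10:
            return False
        taken[contig] |= span
        return True

    def random_site(width: int) -> tuple[str, int]:
        for _ in range(10_000):
            contig = f"chr{int(rng.integers(n_contigs)) + 1}"
            pos = int(rng.integers(10, contig_len - width - 10))
            if claim(contig, pos, pos + width):
                return contig, pos
        raise MutpatError("could not place variant without overlap (plan too dense)")

    def other_base(b: str) -> str:
        return str(rng.choice([x for x in "ACGT" if x != b]))

    planted: list[PlantedVariant] = []
    for _ in range(plan.get("sbs", 0)):
        contig, pos = random_site(1)
        ref = contigs[contig][pos]
        planted.append(PlantedVariant(contig, pos, ref, other_base(ref), "sbs"))
    for _ in range(plan.get("adjacent_pairs", 0)):
        contig, pos = random_site(2)
        r1, r2 = contigs[contig][pos], contigs[contig][pos + 1]
        planted.append(PlantedVariant(contig, pos, r1, other_base(r1), "adjacent_pair"))
        planted.append(
            PlantedVariant(contig, pos + 1, r2, other_base(r2), "adjacent_pair")
        )
    for _ in range(plan.get("dbs", 0)):
        contig, pos = random_site(2)
        ref = contigs[contig][pos : pos + 2]
        alt = other_base(ref[0]) + other_base(ref[1])
        planted.append(PlantedVariant(contig, pos, ref, alt, "dbs"))
    for _ in range(plan.get("mbs", 0)):
        contig, pos = random_site(3)
        ref = contigs[contig][pos : pos + 3]
        alt = "".join(other_base(b) for b in ref)
        planted.append(PlantedVariant(contig, pos, ref, alt, "mbs"))
    for _ in range(plan.get("insertion", 0)):
        contig, pos = random_site(1)
        anchor = contigs[contig][pos]
        ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
        planted.append(PlantedVariant(contig, pos, anchor, anchor + ins, "insertion"))
    for _ in range(plan.get("deletion", 0)):
        ln = int(rng.integers(1, 4))
        contig, pos = random_site(ln + 1)
        ref = contigs[contig][pos : pos + ln + 1]
        planted.append(PlantedVariant(contig, pos, ref, ref[0], "deletion"))

    os.makedirs(outdir, exist_ok=True)
    fasta_path = os.path.join(outdir, "toy_genome.fa")
    with open(fasta_path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    vcf_path = os.path.join(outdir, "toy_variants.vcf")
    planted.sort(key=lambda v: (v.contig, v.pos))
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
        for name, seq in contigs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in planted:
            fh.write(
                f"{v.contig}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\n"
            )
    truth = pd.DataFrame(
        {
            "contig": [v.contig for v in planted],
            "pos": [v.pos for v in planted],
            "ref": [v.ref for v in planted],
            "alt": [v.alt for v in planted],
            "kind": [v.kind for v in planted],
        }
    )
    return fasta_path, vcf_path, truth
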