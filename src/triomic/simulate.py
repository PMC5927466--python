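"""Synthetic multi-omic time-course studies with planted, known effects.

Every generator emulates the default study layout — days 0/3/6/9 with 3
replicates for expression and methylation and 4 for metabolomics — and
records exactly which features carry which planted per-day effect, so every
downstream caller can be scored against ground truth without any external
data.  All randomness flows from a single integer seed through one
``numpy.random.Generator``; identical arguments and seed give bit-identical
studies.

Planted effects are placed on a contiguous random run of the non-baseline
days (a progressive time-course shape); the per-day magnitude is
``effect_sd`` with a random sign shared across that feature's days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import DEFAULT_DAYS, make_design

LOCATION_CLASSES = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR", "IGR")

# relative frequencies of gene-linked probe locations (array-like mix,
# gene bodies dominating)
_GENIC_CLASS_PROBS = {
    "TSS1500": 0.15,
    "TSS200": 0.12,
    "5UTR": 0.10,
    "1stExon": 0.08,
    "Body": 0.45,
    "3UTR": 0.10,
}


@dataclass
class ExpressionStudy:
    """RPKM matrix + design + per-gene per-day planted log2 effects."""

    rpkm: pd.DataFrame
    design: pd.DataFrame
    truth: pd.DataFrame  # genes x non-baseline days, planted log2 shift (0 = null)

    def truth_any(self) -> pd.Series:
        """Boolean per feature: does it carry any planted effect?"""
        return (self.truth != 0).any(axis=1)


@dataclass
class MetaboliteStudy:
    content: pd.DataFrame
    design: pd.DataFrame
    truth: pd.DataFrame

    def truth_any(self) -> pd.Series:
        return (self.truth != 0).any(axis=1)


@dataclass
class GeneAnnotation:
    """BED-like gene intervals (0-based half-open)."""

    table: pd.DataFrame  # gene_id, chrom, start, end, strand

    def to_bed(self) -> pd.DataFrame:
        t = self.table
        return pd.DataFrame(
            {
                "chrom": t["chrom"],
                "start": t["start"],
                "end": t["end"],
                "name": t["gene_id"],
                "score": 0,
                "strand": t["strand"],
            }
        )


@dataclass
class MethylationStudy:
    """Paired methylated/unmethylated intensities with QC hazards planted.

    ``truth`` holds the planted per-day beta shift in percentage points;
    ``failed`` marks unreadable cells; ``outlier`` records where replicate
    displacement was injected (diagnostic only — the QC stage must find
    these itself).
    """

    mcg: pd.DataFrame
    cg: pd.DataFrame
    failed: pd.DataFrame
    probe_annot: pd.DataFrame  # probe_id, gene_id (may be NA), location_class
    design: pd.DataFrame
    truth: pd.DataFrame
    baseline_beta: pd.Series = field(repr=False, default=None)
    outlier: pd.DataFrame | None = field(repr=False, default=None)

    def truth_any(self) -> pd.Series:
        return (self.truth != 0).any(axis=1)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed))


def _contiguous_day_run(rng: np.random.Generator, days: Sequence[int]) -> list[int]:
    """A uniformly chosen non-empty contiguous run of the day sequence."""
    k = len(days)
    runs = [(i, j) for i in range(k) for j in range(i, k)]
    i, j = runs[rng.integers(len(runs))]
    return list(days[i : j + 1])


def _plant_effects(
    rng: np.random.Generator,
    features: pd.Index,
    days: Sequence[int],
    n_planted: int,
    effect_sd: float,
    directions: np.ndarray | None = None,
    planted_idx: np.ndarray | None = None,
    effect_days: Sequence[int] | None = None,
) -> pd.DataFrame:
    truth = pd.DataFrame(0.0, index=features, columns=list(days))
    if planted_idx is None:
        planted_idx = rng.choice(len(features), size=n_planted, replace=False)
    for k, fi in enumerate(planted_idx):
        run = list(effect_days) if effect_days is not None else _contiguous_day_run(rng, days)
        sign = directions[k] if directions is not None else (1.0 if rng.random() < 0.5 else -1.0)
        truth.loc[features[fi], run] = sign * effect_sd
    return truth


def generate_expression(
    n_genes: int = 500,
    frac_deg: float = 0.2,
    effect_sd: float = 2.0,
    noise_sd: float = 0.25,
    seed: int = 0,
    n_reps: int = 3,
    days: Sequence[int] = DEFAULT_DAYS,
    cell_line: str = "DN-POLG",
    baseline_log2_mean: float = 3.0,
    baseline_log2_sd: float = 2.0,
    min_rpkm: float = 0.01,
    effect_days: Sequence[int] | None = None,
) -> ExpressionStudy:
    """Simulate an RPKM time course with planted differential genes.

    Baseline log2-RPKM is normal(``baseline_log2_mean``, ``baseline_log2_sd``)
    truncated so RPKM >= ``min_rpkm``; a fraction ``frac_deg`` of genes get a
    log2 shift of magnitude ``effect_sd`` on a contiguous run of the
    non-baseline days, and i.i.d. normal replicate noise of SD ``noise_sd``
    is added on the log2 scale.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if not 0.0 <= frac_deg <= 1.0:
        raise ValueError("frac_deg must lie in [0, 1]")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = _rng(seed)
    design = make_design(cell_line=cell_line, days=days, n_reps=n_reps)
    genes = pd.Index([f"gene{i:05d}" for i in range(n_genes)], name="gene_id")
    lo = np.log2(min_rpkm)
    base = rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_genes)
    while True:  # truncated normal by resampling
        bad = base < lo
        if not bad.any():
            break
        base[bad] = rng.normal(baseline_log2_mean, baseline_log2_sd, size=bad.sum())

    other_days = [d for d in days if d != days[0]]
    n_deg = int(round(frac_deg * n_genes))
    truth = _plant_effects(rng, genes, other_days, n_deg, effect_sd, effect_days=effect_days)

    day_per_sample = design["day"].to_numpy()
    shift = np.zeros((n_genes, len(design)))
    for j, d in enumerate(day_per_sample):
        if d != days[0]:
            shift[:, j] = truth[d].to_numpy()
    log2 = base[:, None] + shift + rng.normal(0.0, noise_sd, size=shift.shape)
    rpkm = pd.DataFrame(
        np.power(2.0, log2), index=genes, columns=design["sample_id"].tolist()
    )
    return ExpressionStudy(rpkm=rpkm, design=design, truth=truth)


def generate_metabolomics(
    n_metab: int = 200,
    frac_dem: float = 0.25,
    effect_sd: float = 0.6,
    noise_sd: float = 0.15,
    seed: int = 0,
    n_reps: int = 4,
    days: Sequence[int] = DEFAULT_DAYS,
    cell_line: str = "DN-POLG",
    baseline_log2_mean: float = 10.0,
    baseline_log2_sd: float = 1.5,
    effect_days: Sequence[int] | None = None,
) -> MetaboliteStudy:
    """Simulate a metabolite abundance time course (arbitrary detection units).

    Same generative scheme as :func:`generate_expression` but with 4
    replicates per time point by default and strictly positive abundances.
    """
    if n_metab < 2:
        raise ValueError("n_metab must be >= 2")
    if not 0.0 <= frac_dem <= 1.0:
        raise ValueError("frac_dem must lie in [0, 1]")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = _rng(seed)
    design = make_design(cell_line=cell_line, days=days, n_reps=n_reps)
    metabs = pd.Index([f"metab{i:04d}" for i in range(n_metab)], name="metabolite_id")
    base = rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_metab)

    other_days = [d for d in days if d != days[0]]
    n_dem = int(round(frac_dem * n_metab))
    truth = _plant_effects(rng, metabs, other_days, n_dem, effect_sd, effect_days=effect_days)

    day_per_sample = design["day"].to_numpy()
    shift = np.zeros((n_metab, len(design)))
    for j, d in enumerate(day_per_sample):
        if d != days[0]:
            shift[:, j] = truth[d].to_numpy()
    log2 = base[:, None] + shift + rng.normal(0.0, noise_sd, size=shift.shape)
    content = pd.DataFrame(
        np.power(2.0, log2), index=metabs, columns=design["sample_id"].tolist()
    )
    return MetaboliteStudy(content=content, design=design, truth=truth)


def generate_annotation(
    n_genes: int = 200,
    genome_length: int = 10_000_000,
    seed: int = 0,
    min_len: int = 500,
    max_len: int = 5000,
    chrom: str = "chr1",
) -> GeneAnnotation:
    """Non-overlapping gene intervals on a single synthetic chromosome."""
    rng = _rng(seed)
    lengths = rng.integers(min_len, max_len + 1, size=n_genes)
    total = int(lengths.sum())
    if total > genome_length:
        raise ValueError(
            f"{n_genes} genes of total length {total} do not fit in {genome_length}"
        )
    # distribute the leftover space as random gaps (stick breaking)
    slack = genome_length - total
    cuts = np.sort(rng.integers(0, slack + 1, size=n_genes))
    gaps = np.diff(np.concatenate([[0], cuts]))
    starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(lengths[:-1])])
    strand = np.where(rng.random(n_genes) < 0.5, "+", "-")
    table = pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
            "chrom": chrom,
            "start": starts.astype(int),
            "end": (starts + lengths).astype(int),
            "strand": strand,
        }
    )
    return GeneAnnotation(table=table)


def generate_methylation(
    n_probes: int = 1000,
    frac_dml: float = 0.1,
    delta_beta: float = 20.0,
    fail_rate: float = 0.02,
    outlier_rate: float = 0.02,
    seed: int = 0,
    noise_sd: float = 2.0,
    n_reps: int = 3,
    days: Sequence[int] = DEFAULT_DAYS,
    cell_line: str = "DN-POLG",
    annotation: GeneAnnotation | None = None,
    igr_fraction: float = 0.2,
    favor_genes: Sequence[str] | None = None,
    favor_prob: float = 0.0,
    favor_classes: Sequence[str] = ("TSS1500", "TSS200"),
    effect_days: Sequence[int] | None = None,
) -> MethylationStudy:
    """Simulate paired mCG/CG array intensities with planted beta shifts.

    Per-probe baseline beta is drawn from a bimodal mixture on [0, 100]
    (mostly-unmethylated and mostly-methylated modes).  Planted probes shift
    by ``delta_beta`` percentage points (sign random, flipped if the shifted
    beta would leave [1, 99]) on a contiguous run of non-baseline days.
    Replicate noise of SD ``noise_sd`` points is added to beta; intensities
    are then constructed so that ``mcg/(mcg+cg)*100`` reproduces the noisy
    beta.  A fraction ``fail_rate`` of cells is marked failed and a fraction
    ``outlier_rate`` is displaced by >= 3x the replicate noise scale
    (outliers are injected before the failed mask; a cell can be both).

    ``favor_genes``/``favor_prob`` bias planted probes toward the promoter
    classes of the named genes, which couples methylation truth to a DEG
    truth set for integration studies.
    """
    if not (-100.0 < delta_beta < 100.0):
        raise ValueError("delta_beta must lie in (-100, 100)")
    if not 0.0 <= fail_rate <= 0.2:
        raise ValueError("fail_rate must lie in [0, 0.2]")
    if not 0.0 <= outlier_rate <= 0.2:
        raise ValueError("outlier_rate must lie in [0, 0.2]")
    rng = _rng(seed)
    design = make_design(cell_line=cell_line, days=days, n_reps=n_reps)
    n_samples = len(design)
    probes = pd.Index([f"cg{i:06d}" for i in range(n_probes)], name="probe_id")
    if annotation is None:
        annotation = generate_annotation(
            n_genes=max(50, n_probes // 5), seed=int(rng.integers(2**31))
        )
    gene_ids = annotation.table["gene_id"].to_numpy()

    # probe -> gene / location class assignment
    is_igr = rng.random(n_probes) < igr_fraction
    classes = np.array(list(_GENIC_CLASS_PROBS))
    probs = np.array(list(_GENIC_CLASS_PROBS.values()))
    probs = probs / probs.sum()
    loc = np.where(
        is_igr, "IGR", rng.choice(classes, size=n_probes, p=probs)
    ).astype(object)
    gene_of = np.where(is_igr, None, rng.choice(gene_ids, size=n_probes)).astype(object)
    probe_annot = pd.DataFrame(
        {"probe_id": probes, "gene_id": gene_of, "location_class": loc}
    ).set_index("probe_id")

    # bimodal baseline beta: unmethylated and methylated modes
    low = rng.beta(2, 10, size=n_probes) * 100.0
    high = rng.beta(8, 2, size=n_probes) * 100.0
    base = np.where(rng.random(n_probes) < 0.6, low, high)

    # planted probe selection, optionally biased toward favored promoters
    n_dml = int(round(frac_dml * n_probes))
    if favor_genes and favor_prob > 0 and n_dml > 0:
        favored_pool = np.flatnonzero(
            pd.Series(gene_of).isin(set(favor_genes)).to_numpy()
            & pd.Series(loc).isin(set(favor_classes)).to_numpy()
        )
        picked: list[int] = []
        available = set(range(n_probes))
        pool = [i for i in favored_pool if i in available]
        while len(picked) < n_dml and available:
            if pool and rng.random() < favor_prob:
                i = pool[int(rng.integers(len(pool)))]
            else:
                i = int(rng.choice(sorted(available)))
            if i in available:
                picked.append(i)
                available.discard(i)
                pool = [j for j in pool if j != i]
        planted_idx = np.array(picked, dtype=int)
    else:
        planted_idx = rng.choice(n_probes, size=n_dml, replace=False)

    # signs: random, but kept realisable inside the beta bounds
    directions = np.where(rng.random(len(planted_idx)) < 0.5, 1.0, -1.0)
    for k, pi in enumerate(planted_idx):
        if not 1.0 <= base[pi] + directions[k] * delta_beta <= 99.0:
            directions[k] = -directions[k]
    other_days = [d for d in days if d != days[0]]
    truth = _plant_effects(
        rng, probes, other_days, n_dml, delta_beta,
        directions=directions, planted_idx=planted_idx, effect_days=effect_days,
    )

    day_per_sample = design["day"].to_numpy()
    shift = np.zeros((n_probes, n_samples))
    for j, d in enumerate(day_per_sample):
        if d != days[0]:
            shift[:, j] = truth[d].to_numpy()
    beta = base[:, None] + shift + rng.normal(0.0, noise_sd, size=shift.shape)

    # outliers first, then the failed mask (a cell can be both)
    outlier = rng.random(beta.shape) < outlier_rate
    displacement = (3.0 + rng.exponential(1.0, size=beta.shape)) * noise_sd
    sign = np.where(rng.random(beta.shape) < 0.5, 1.0, -1.0)
    beta = np.where(outlier, beta + sign * displacement, beta)
    beta = np.clip(beta, 0.0, 100.0)
    failed = rng.random(beta.shape) < fail_rate

    total = rng.lognormal(np.log(2000.0), 0.3, size=beta.shape)
    mcg = total * beta / 100.0
    cg = np.clip(total - mcg, 0.0, None)  # beta=100 can round to -1e-13
    cols = design["sample_id"].tolist()
    return MethylationStudy(
        mcg=pd.DataFrame(mcg, index=probes, columns=cols),
        cg=pd.DataFrame(cg, index=probes, columns=cols),
        failed=pd.DataFrame(failed, index=probes, columns=cols),
        probe_annot=probe_annot,
        design=design,
        truth=truth,
        baseline_beta=pd.Series(base, index=probes, name="baseline_beta"),
        outlier=pd.DataFrame(outlier, index=probes, columns=cols),
    )


# ---------------------------------------------------------------------------
# serialisation helpers (TSV / BED; all plain text)

def write_expression(study: ExpressionStudy, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.rpkm.to_csv(out / "rpkm.tsv", sep="\t")
    study.design.to_csv(out / "design.tsv", sep="\t", index=False)
    _write_truth(study.truth, out / "truth.tsv")


def write_metabolomics(study: MetaboliteStudy, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.content.to_csv(out / "content.tsv", sep="\t")
    study.design.to_csv(out / "design.tsv", sep="\t", index=False)
    _write_truth(study.truth, out / "truth.tsv")


def write_methylation(study: MethylationStudy, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.mcg.to_csv(out / "mcg.tsv", sep="\t")
    study.cg.to_csv(out / "cg.tsv", sep="\t")
    study.failed.astype(int).to_csv(out / "failed.tsv", sep="\t")
    study.probe_annot.to_csv(out / "probe_annot.tsv", sep="\t")
    study.design.to_csv(out / "design.tsv", sep="\t", index=False)
    _write_truth(study.truth, out / "truth.tsv")


def write_annotation(annot: GeneAnnotation, path: str | Path) -> None:
    annot.to_bed().to_csv(path, sep="\t", index=False, header=False)


def _write_truth(truth: pd.DataFrame, path: Path) -> None:
    long = truth.reset_index().melt(
        id_vars=truth.index.name or "index", var_name="day", value_name="effect"
    )
    long.to_csv(path, sep="\t", index=False)
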