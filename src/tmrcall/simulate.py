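"""Synthetic WGBS + expression cohorts with planted methylation--expression coupling.

The generator emulates the statistical structure the discovery pipeline
assumes: per-sample latent log-expression for each transcript, CpG-level
beta values that are independent of expression everywhere except inside
*planted windows*, negative-binomial read coverage producing
coverage-dependent missingness, binomial methylated-read sampling, and
low-mappability decoy intervals.

Inside a planted window the per-sample beta is
``expit(logit(m_c) - gamma * z_std + noise_sd * eps)`` where ``z_std`` is
the standardized latent log-expression; ``gamma`` is calibrated by
bisection so the realized Spearman magnitude between the window-mean
observed beta and expression matches the requested coupling strength,
including the blurring from binomial read sampling.  Transcripts carrying positive windows reuse
the negative-coupling draws with the whole transcript's methylated counts
reflected (``meth -> coverage - meth``; the background beta family is
symmetric under reflection), which makes a direction flip an exact mirror:
identical boundaries, opposite sign.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .caller import CallerConfig, discover_tmrs
from .correlation import spearman
from .expression import median_of_ratios_normalize
from .intervals import GenomicInterval
from .methylome import MethylomeMatrix

__all__ = [
    "TranscriptSpec",
    "PlantedWindow",
    "SimulationConfig",
    "SimulatedTruth",
    "default_config",
    "simulate_cohort",
    "saturation_curve",
    "write_cohort",
]


@dataclass(frozen=True)
class TranscriptSpec:
    transcript_id: str
    chrom: str
    start: int
    strand: str
    n_cpgs: int


@dataclass(frozen=True)
class PlantedWindow:
    transcript_id: str
    start_cpg: int  # index of first coupled CpG within the transcript
    n_cpgs: int
    direction: str  # "negative" | "positive"
    coupling: float  # target |Spearman| of observed beta vs expression

    def __post_init__(self) -> None:
        if not 0.0 < self.coupling <= 1.0:
            raise ValueError("coupling must lie in (0, 1]")
        if self.direction not in ("negative", "positive"):
            raise ValueError("direction must be 'negative' or 'positive'")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    seed: int = 0
    n_samples: int = 120
    transcripts: tuple = ()
    planted: tuple = ()
    coverage_mean: float = 30.0  # negative-binomial mean reads per CpG per sample
    coverage_dispersion: float = 5.0  # NB size; smaller = more overdispersed
    beta_concentration: float = 10.0  # Beta(m*k, (1-m)*k) for background CpGs
    noise_sd: float = 1.0  # logit-scale noise inside planted windows
    cpg_gap_mean: float = 80.0  # mean gap between consecutive CpGs (bp)
    island_cpgs: int = 20  # TSS-proximal CpGs with denser spacing
    island_gap_mean: float = 16.0
    library_factor_sd: float = 0.3  # log-normal library size factors
    expr_log_mean_range: tuple = (np.log(50.0), np.log(500.0))
    expr_sd: float = 0.8  # per-transcript latent log-expression SD
    mappability_decoys: tuple = ()  # GenomicInterval with score < 1


@dataclass
class SimulatedTruth:
    """Planted windows as genomic intervals plus per-CpG coupling flags."""

    windows: list  # (transcript_id, GenomicInterval, direction, (start_cpg, end_cpg))
    coupled_cpgs: dict  # transcript_id -> bool array over its CpGs

    def to_bed_records(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(iv.chrom, iv.start, iv.end, strand=iv.strand,
                            name=f"{tid}:{direction}")
            for tid, iv, direction, _ in self.windows
        ]


def default_config(
    seed: int = 0,
    n_samples: int = 120,
    n_transcripts: int = 100,
    n_cpgs: int = 60,
    n_planted: int = 20,
    planted_cpgs: int = 12,
    coupling: float = 0.8,
    direction: str = "negative",
    n_decoys: int = 4,
) -> SimulationConfig:
    """The package's reference cohort: 120 samples, 100 transcripts of 60
    CpGs, 20 planted 12-CpG windows at coupling 0.8, and a few
    low-mappability decoy intervals over signal-free transcripts."""
    transcripts = tuple(
        TranscriptSpec(
            transcript_id=f"T{t:03d}",
            chrom="chr1",
            start=50_000 + t * 40_000,
            strand="+" if t % 2 == 0 else "-",
            n_cpgs=n_cpgs,
        )
        for t in range(n_transcripts)
    )
    start_cpg = max(0, (n_cpgs - planted_cpgs) // 2)
    planted = tuple(
        PlantedWindow(f"T{t:03d}", start_cpg, planted_cpgs, direction, coupling)
        for t in range(n_planted)
    )
    # decoys over the last few (signal-free) transcripts
    decoys = tuple(
        GenomicInterval("chr1", 50_000 + t * 40_000, 50_000 + t * 40_000 + 2_000, score=0.5)
        for t in range(n_transcripts - n_decoys, n_transcripts)
    )
    return SimulationConfig(
        seed=seed,
        n_samples=n_samples,
        transcripts=transcripts,
        planted=planted,
        mappability_decoys=decoys,
    )


def _calibrate_gamma(
    coupling: float,
    window_cpgs: int,
    noise_sd: float,
    coverage_mean: float,
    coverage_dispersion: float,
    seed: int,
    n_draws: int = 3000,
) -> float:
    """Bisection on the coupling slope so the realized window-mean |Spearman|
    matches the target.

    The calibration unit is the planted window: per draw, ``window_cpgs``
    CpGs with mid-range baselines are sampled through the full observation
    model (logistic coupling, coverage, binomial reads) and their mean beta
    is correlated with the latent expression.  The map gamma -> realized
    correlation magnitude is monotone; a fixed generator state per
    evaluation keeps it deterministic for the bisection.
    """
    from scipy.special import expit, logit

    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_draws)
    eps = rng.standard_normal((window_cpgs, n_draws))
    alpha = logit(rng.uniform(0.35, 0.65, size=window_cpgs))[:, None]
    p_nb = coverage_dispersion / (coverage_dispersion + coverage_mean)
    cov = np.maximum(
        1, rng.negative_binomial(coverage_dispersion, p_nb, size=(window_cpgs, n_draws))
    )

    def realized(gamma: float) -> float:
        beta = expit(alpha - gamma * z[None, :] + noise_sd * eps)
        local = np.random.default_rng(seed + 1)
        meth = local.binomial(cov, beta)
        obs = (meth / cov).mean(axis=0)
        rho, _ = spearman(obs, z)
        return abs(rho)

    lo, hi = 1e-3, 80.0
    if realized(hi) < coupling:
        raise ValueError(
            f"coupling {coupling} unreachable with noise_sd={noise_sd} and "
            f"coverage_mean={coverage_mean}"
        )
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if realized(mid) < coupling:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[MethylomeMatrix, pd.DataFrame, list[TranscriptModel], SimulatedTruth]:
    """Draw one cohort: methylome matrix, raw count table, transcript models, truth.

    Deterministic under ``config.seed``.  The returned methylome is
    unmasked; run the caller's coverage masking downstream.
    """
    from scipy.special import expit, logit

    rng = np.random.default_rng(config.seed)
    samples = [f"S{i:03d}" for i in range(config.n_samples)]
    lib = np.exp(rng.normal(0.0, config.library_factor_sd, size=config.n_samples))

    planted_by_tid: dict[str, list[PlantedWindow]] = {}
    for w in config.planted:
        planted_by_tid.setdefault(w.transcript_id, []).append(w)
    gamma_cache: dict[tuple[float, int], float] = {}
    for w in config.planted:
        key = (w.coupling, w.n_cpgs)
        if key not in gamma_cache:
            gamma_cache[key] = _calibrate_gamma(
                w.coupling,
                w.n_cpgs,
                config.noise_sd,
                config.coverage_mean,
                config.coverage_dispersion,
                seed=int(config.seed) % (2**31 - 1) + 7_001,
            )

    chroms: list[str] = []
    positions: list[int] = []
    meth_cols: list[np.ndarray] = []
    total_cols: list[np.ndarray] = []
    counts = np.zeros((len(config.transcripts), config.n_samples))
    models: list[TranscriptModel] = []
    truth_windows = []
    coupled: dict[str, np.ndarray] = {}
    lo_mu, hi_mu = config.expr_log_mean_range
    p_nb = config.coverage_dispersion / (config.coverage_dispersion + config.coverage_mean)

    for t_idx, spec in enumerate(config.transcripts):
        # latent expression and raw counts
        mu_t = rng.uniform(lo_mu, hi_mu)
        z = rng.normal(mu_t, config.expr_sd, size=config.n_samples)
        counts[t_idx] = np.round(np.exp(z) * lib)
        z_std = (z - z.mean()) / z.std()

        # CpG positions: dense TSS-proximal stretch then sparser body
        n = spec.n_cpgs
        n_island = min(config.island_cpgs, n)
        gaps = np.concatenate(
            [
                2 + rng.poisson(max(config.island_gap_mean - 2, 0), size=n_island),
                2 + rng.poisson(max(config.cpg_gap_mean - 2, 0), size=n - n_island),
            ]
        )
        if spec.strand == "-":
            gaps = gaps[::-1]  # dense stretch stays TSS-proximal
        pos = spec.start + np.cumsum(gaps)
        body = GenomicInterval(spec.chrom, int(pos[0]) - 1, int(pos[-1]) + 2, strand=spec.strand)
        models.append(
            TranscriptModel(
                transcript_id=spec.transcript_id,
                gene_id=f"G_{spec.transcript_id}",
                gene_name=spec.transcript_id,
                biotype="protein_coding",
                body=body,
            )
        )

        flags = np.zeros(n, dtype=bool)
        windows = planted_by_tid.get(spec.transcript_id, [])
        for w in windows:
            if w.start_cpg + w.n_cpgs > n:
                raise ValueError(f"planted window exceeds CpG range of {spec.transcript_id}")
            flags[w.start_cpg : w.start_cpg + w.n_cpgs] = True
        coupled[spec.transcript_id] = flags

        # baseline methylation level per CpG (mid-range inside planted windows
        # so the logistic coupling is not saturated)
        m_c = rng.uniform(0.05, 0.95, size=n)
        m_c[flags] = rng.uniform(0.35, 0.65, size=int(flags.sum()))

        beta = np.empty((n, config.n_samples))
        bg = ~flags
        a = m_c[bg] * config.beta_concentration
        b = (1.0 - m_c[bg]) * config.beta_concentration
        beta[bg] = rng.beta(a[:, None], b[:, None], size=(int(bg.sum()), config.n_samples))
        if flags.any():
            gamma = np.array([gamma_cache[(w.coupling, w.n_cpgs)] for w in windows])
            eta = np.empty((int(flags.sum()), config.n_samples))
            row = 0
            for w, g in zip(windows, gamma):
                k = w.n_cpgs
                eps = rng.standard_normal((k, config.n_samples))
                alpha = logit(m_c[w.start_cpg : w.start_cpg + k])[:, None]
                eta[row : row + k] = alpha - g * z_std[None, :] + config.noise_sd * eps
                row += k
            beta[flags] = expit(eta)

        cov = rng.negative_binomial(config.coverage_dispersion, p_nb, size=(n, config.n_samples))
        meth = rng.binomial(cov, beta)
        # positive-coupling transcripts are generated by reflecting the whole
        # transcript's methylated counts (meth -> coverage - meth) of the
        # negative-coupling draws: the beta background family is symmetric
        # under reflection, every Spearman correlation flips sign exactly,
        # and a direction flip therefore mirrors boundaries exactly
        directions = {w.direction for w in windows}
        if len(directions) > 1:
            raise ValueError(
                f"mixed planted directions on {spec.transcript_id}; use one "
                "direction per transcript"
            )
        if directions == {"positive"}:
            meth = cov - meth

        for w in windows:
            iv = GenomicInterval(
                spec.chrom,
                int(pos[w.start_cpg]),
                int(pos[w.start_cpg + w.n_cpgs - 1]) + 1,
                strand=spec.strand,
            )
            truth_windows.append((spec.transcript_id, iv, w.direction, (w.start_cpg, w.start_cpg + w.n_cpgs - 1)))

        chroms.extend([spec.chrom] * n)
        positions.extend(int(x) for x in pos)
        meth_cols.append(meth)
        total_cols.append(cov)

    meth_all = np.vstack(meth_cols)
    total_all = np.vstack(total_cols)
    order = np.array(
        sorted(range(len(positions)), key=lambda i: (chroms[i], positions[i])),
        dtype=np.int64,
    )
    chrom_arr = np.array(chroms, dtype=object)[order]
    pos_arr = np.array(positions, dtype=np.int64)[order]
    meth_all = meth_all[order]
    total_all = total_all[order]
    beta_obs = np.full(meth_all.shape, np.nan)
    np.divide(meth_all, total_all, out=beta_obs, where=total_all > 0)
    methylome = MethylomeMatrix(
        chroms=chrom_arr,
        positions=pos_arr,
        samples=samples,
        meth=meth_all,
        total=total_all,
        beta=beta_obs,
    )
    counts_df = pd.DataFrame(
        counts, index=[s.transcript_id for s in config.transcripts], columns=samples
    )
    return methylome, counts_df, models, SimulatedTruth(truth_windows, coupled)


def flip_directions(config: SimulationConfig) -> SimulationConfig:
    """Config with every planted window's coupling direction reversed."""
    flipped = tuple(
        replace(w, direction="positive" if w.direction == "negative" else "negative")
        for w in config.planted
    )
    return replace(config, planted=flipped)


def saturation_curve(
    config: SimulationConfig,
    subset_sizes: Sequence[int],
    replicates: int = 3,
    seed: int = 0,
    caller_config: CallerConfig = CallerConfig(),
) -> pd.DataFrame:
    """Mean recovered-TMR count as a function of cohort size.

    Simulates the cohort once, then for each subset size draws random
    sample subsets (without replacement) and reruns discovery.  Subsets
    smaller than the correlation minimum yield zero regions by
    construction.  Returns a tidy table (n_samples, replicate, n_tmrs).
    """
    methylome, counts, models, _ = simulate_cohort(config)
    rng = np.random.default_rng(seed)
    rows = []
    for size in subset_sizes:
        if size > config.n_samples:
            raise ValueError(f"subset size {size} exceeds cohort size {config.n_samples}")
        for rep in range(replicates):
            if size == config.n_samples:
                chosen = list(methylome.samples)
            else:
                chosen = sorted(
                    rng.choice(methylome.samples, size=size, replace=False).tolist()
                )
            sub_meth = methylome.subset_samples(chosen)
            sub_expr = median_of_ratios_normalize(counts[chosen])
            if size < caller_config.min_samples:
                n_tmrs = 0
            else:
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    tmrs, _, _ = discover_tmrs(sub_meth, sub_expr, models, caller_config)
                n_tmrs = len(tmrs)
            rows.append({"n_samples": size, "replicate": rep, "n_tmrs": n_tmrs})
    return pd.DataFrame(rows)


def write_cohort(config: SimulationConfig, out_dir) -> dict:
    """Materialize a cohort in the same plain-text dialects the readers consume.

    Writes per-sample methylation call files (``beta`` dialect), the raw
    count TSV, a transcript GTF, the planted-truth BED, and a mappability
    bedGraph (decoys at their scores, everything else 1.0).
    """
    from .annotation import write_transcript_models
    from .intervals import iter_uncovered, write_interval_track
    from .methylome import write_methylome

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    methylome, counts, models, truth = simulate_cohort(config)
    sample_paths = write_methylome(methylome, out / "methylome", dialect="beta")
    counts.to_csv(out / "counts.tsv", sep="\t", index_label="transcript_id")
    write_transcript_models(models, out / "transcripts.gtf")
    write_interval_track(truth.to_bed_records(), out / "truth.bed")
    span_end = max(m.body.end for m in models) + 10_000
    full = GenomicInterval("chr1", 0, span_end, score=1.0)
    decoys = list(config.mappability_decoys)
    pieces = [
        GenomicInterval(iv.chrom, iv.start, iv.end, score=1.0)
        for iv in iter_uncovered(full, decoys)
    ] + decoys
    pieces.sort(key=lambda iv: (iv.chrom, iv.start))
    write_interval_track(pieces, out / "mappability.bedgraph")
    sheet = out / "samples.tsv"
    with open(sheet, "wt") as fh:
        fh.write("sample\tfile\n")
        for s, p in sample_paths.items():
            fh.write(f"{s}\t{p}\n")
    return {
        "methylome_dir": out / "methylome",
        "sample_sheet": sheet,
        "counts": out / "counts.tsv",
        "gtf": out / "transcripts.gtf",
        "truth": out / "truth.bed",
        "mappability": out / "mappability.bedgraph",
    }
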