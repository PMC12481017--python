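"""Shared fixtures: synthetic cohorts and small text fixtures.

The heavy planted/null/flipped cohorts are session-scoped; several test
modules (and the acceptance tests) share one simulation + discovery run.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import tmrcall as tc
from tmrcall.simulate import flip_directions

COHORT_SEED = 1  # canonical seed for the reference cohorts


@pytest.fixture(scope="session")
def planted_cohort():
    """Reference cohort: 120 samples, 100 transcripts, 20 planted negative windows."""
    cfg = tc.default_config(seed=COHORT_SEED)
    methylome, counts, models, truth = tc.simulate_cohort(cfg)
    expression = tc.median_of_ratios_normalize(counts)
    return cfg, methylome, counts, models, truth, expression


@pytest.fixture(scope="session")
def planted_run(planted_cohort):
    cfg, methylome, counts, models, truth, expression = planted_cohort
    tmrs, tracks, summary = tc.discover_tmrs(methylome, expression, models)
    return dict(
        cfg=cfg, methylome=methylome, counts=counts, models=models,
        truth=truth, expression=expression, tmrs=tmrs, tracks=tracks, summary=summary,
    )


@pytest.fixture(scope="session")
def flipped_run(planted_cohort):
    """Same cohort with every planted coupling direction reversed."""
    cfg = flip_directions(planted_cohort[0])
    methylome, counts, models, truth = tc.simulate_cohort(cfg)
    expression = tc.median_of_ratios_normalize(counts)
    tmrs, tracks, summary = tc.discover_tmrs(methylome, expression, models)
    return dict(cfg=cfg, truth=truth, tmrs=tmrs, tracks=tracks, summary=summary)


@pytest.fixture(scope="session")
def null_run():
    """Matched cohort with no planted coupling anywhere."""
    cfg = dataclasses.replace(tc.default_config(seed=COHORT_SEED), planted=())
    methylome, counts, models, truth = tc.simulate_cohort(cfg)
    expression = tc.median_of_ratios_normalize(counts)
    tmrs, tracks, summary = tc.discover_tmrs(methylome, expression, models)
    return dict(
        cfg=cfg, methylome=methylome, counts=counts, models=models,
        expression=expression, tmrs=tmrs, tracks=tracks, summary=summary,
    )


TOY_GTF = """\
chr1\thavana\ttranscript\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; gene_name "A"; transcript_type "protein_coding";
chr1\thavana\ttranscript\t301\t500\t.\t-\t.\tgene_id "G2"; transcript_id "T2"; gene_name "B"; transcript_type "protein_coding";
chr2\thavana\ttranscript\t1001\t1400\t.\t+\t.\tgene_id "G3"; transcript_id "T3"; gene_name "C"; transcript_type "lncRNA";
"""


@pytest.fixture()
def toy_gtf(tmp_path):
    path = tmp_path / "toy.gtf"
    path.write_text(TOY_GTF)
    return path


@pytest.fixture()
def small_methylome():
    """Tiny 5-site x 4-sample matrix with hand-set counts."""
    chroms = np.array(["chr1"] * 5, dtype=object)
    positions = np.array([100, 150, 200, 260, 320], dtype=np.int64)
    samples = ["a", "b", "c", "d"]
    total = np.array(
        [
            [20, 20, 20, 20],
            [20, 9, 20, 20],
            [0, 20, 20, 20],
            [20, 20, 20, 20],
            [20, 20, 20, 5],
        ],
        dtype=np.int64,
    )
    meth = np.array(
        [
            [4, 8, 12, 16],
            [10, 4, 10, 10],
            [0, 20, 0, 20],
            [20, 0, 20, 0],
            [5, 5, 5, 5],
        ],
        dtype=np.int64,
    )
    beta = np.full((5, 4), np.nan)
    np.divide(meth, total, out=beta, where=total > 0)
    return tc.MethylomeMatrix(chroms, positions, samples, meth, total, beta)
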